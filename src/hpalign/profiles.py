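"""Numeric profiles: hydropathy scales, FASTA input, window averaging.

A :class:`NumericProfile` is an ordered sequence of signed values, one per
residue (or, generally, per position of any numeric series).  For protein
hydropathy, each residue is mapped to its scale value (Kyte-Doolittle by
default) and the raw values are smoothed with a boxcar mean over an odd
window, the average being assigned to the centre position; the untiled
half-windows at either end carry no value, so a window of 15 on an
M-residue protein yields a profile covering residues 8..M-7 (1-based).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "STANDARD_AA",
    "HydropathyScale",
    "NumericProfile",
    "load_scale",
    "list_scales",
    "read_fasta",
    "sequence_to_values",
    "window_average",
    "hydropathy_profile",
    "read_numeric_profile",
    "write_numeric_profile",
]

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class HydropathyScale:
    """A named per-residue scalar scale over the 20 standard amino acids."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(STANDARD_AA):
            missing = sorted(set(STANDARD_AA) - keys)
            extra = sorted(keys - set(STANDARD_AA))
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard "
                f"residues (missing {missing}, extra {extra})"
            )
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} contains non-finite values")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


@dataclass(frozen=True)
class NumericProfile:
    """An ordered series of signed values with optional averaging metadata.

    Parameters
    ----------
    id:
        Identifier of the underlying record (FASTA id or file stem).
    values:
        The per-position values, length >= 1, all finite.
    source:
        ``"raw"`` for values read or mapped directly, ``"window_averaged"``
        after boxcar smoothing.
    avg_window:
        The (odd) averaging window, present only when ``source`` is
        ``"window_averaged"``.
    """

    id: str
    values: np.ndarray
    source: str = "raw"
    avg_window: int | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("profile values must be a non-empty 1-D array")
        if not np.all(np.isfinite(vals)):
            raise ValueError("profile values must be finite")
        if self.source not in ("raw", "window_averaged"):
            raise ValueError(f"unknown profile source {self.source!r}")
        if self.source == "window_averaged":
            if self.avg_window is None or self.avg_window < 1 or self.avg_window % 2 == 0:
                raise ValueError("window_averaged profiles need a positive odd avg_window")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def start_offset(self) -> int:
        """0-based offset of the first profile position in the original sequence."""
        if self.source == "window_averaged":
            return (self.avg_window - 1) // 2
        return 0


def _read_scale_stream(lines: Iterable[str], name: str) -> HydropathyScale:
    values: dict[str, float] = {}
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        letter, value = line.split("\t")
        values[letter] = float(value)
    return HydropathyScale(name=name, values=values)


def list_scales() -> list[str]:
    """Names of the scale tables shipped with the package."""
    pkg = resources.files("hpalign.data")
    return sorted(
        p.name[: -len(".tsv")]
        for p in pkg.iterdir()
        if p.name.endswith(".tsv") and p.name != "robinson_robinson.tsv"
    )


def load_scale(name_or_path: str = "kyte_doolittle") -> HydropathyScale:
    """Load a packaged scale by name, or any scale TSV by path.

    The TSV format is two tab-separated columns (one-letter residue, value);
    ``#`` lines are comments.  Dashes in names are normalised to underscores
    so ``"kyte-doolittle"`` works.
    """
    name = name_or_path.replace("-", "_")
    pkg = resources.files("hpalign.data")
    candidate = pkg / f"{name}.tsv"
    if candidate.is_file():
        return _read_scale_stream(candidate.read_text().splitlines(), name)
    path = Path(name_or_path)
    if path.is_file():
        return _read_scale_stream(path.read_text().splitlines(), path.stem)
    raise FileNotFoundError(
        f"no packaged scale named {name!r} (have {list_scales()}) and no file "
        f"at {name_or_path!r}"
    )


def read_fasta(path, *, on_nonstandard: str = "skip") -> list[tuple[str, str]]:
    """Read a protein FASTA file into ``(id, sequence)`` pairs in file order.

    Sequences are uppercased.  Records containing characters outside the 20
    standard residues are excluded with a warning under the default
    ``on_nonstandard="skip"`` policy; ``"error"`` aborts instead.
    """
    if on_nonstandard not in ("skip", "error"):
        raise ValueError("on_nonstandard must be 'skip' or 'error'")
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    standard = set(STANDARD_AA)
    kept = []
    for rec_id, seq in records:
        bad = sorted(set(seq) - standard)
        if bad:
            if on_nonstandard == "error":
                raise ValueError(
                    f"record {rec_id!r} contains nonstandard residues {bad}"
                )
            warnings.warn(
                f"skipping record {rec_id!r}: nonstandard residues {bad}",
                stacklevel=2,
            )
            continue
        kept.append((rec_id, seq))
    return kept


def sequence_to_values(seq: str, scale: HydropathyScale) -> np.ndarray:
    """Map each residue of ``seq`` to its scale value, preserving order."""
    out = np.empty(len(seq), dtype=float)
    for k, residue in enumerate(seq):
        try:
            out[k] = scale.values[residue]
        except KeyError:
            raise KeyError(
                f"residue {residue!r} at position {k + 1} is not in scale "
                f"{scale.name!r}"
            ) from None
    return out


def window_average(
    values: Sequence[float] | np.ndarray,
    window: int = 15,
    *,
    id: str = "",
) -> NumericProfile:
    """Boxcar-average ``values`` over an odd ``window``, centre-assigned.

    The output has length ``len(values) - (window - 1)``: the first and last
    ``(window - 1)/2`` positions of the input receive no value.
    """
    vals = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if vals.size < window:
        raise ValueError(
            f"need at least {window} values for a window of {window}, got {vals.size}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(vals, window)
    return NumericProfile(
        id=id, values=windows.mean(axis=1), source="window_averaged", avg_window=window
    )


def hydropathy_profile(
    rec_id: str,
    seq: str,
    scale: HydropathyScale | None = None,
    window: int = 15,
) -> NumericProfile:
    """Sequence -> scale values -> window-averaged hydropathy profile."""
    if scale is None:
        scale = load_scale()
    return window_average(sequence_to_values(seq, scale), window, id=rec_id)


def read_numeric_profile(path, *, id: str | None = None) -> NumericProfile:
    """Read a raw numeric profile: one value per line, or a two-column TSV
    of (1-based contiguous position, value)."""
    path = Path(path)
    values: list[float] = []
    tsv = None
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if tsv is None:
                tsv = len(fields) == 2
            if tsv and len(fields) != 2 or not tsv and len(fields) != 1:
                raise ValueError(f"{path}:{lineno}: inconsistent column count")
            try:
                if tsv:
                    pos = int(fields[0])
                    value = float(fields[1])
                else:
                    value = float(fields[0])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric token in {line!r}"
                ) from None
            if tsv and pos != len(values) + 1:
                raise ValueError(
                    f"{path}:{lineno}: positions must be contiguous and 1-based "
                    f"(expected {len(values) + 1}, got {pos})"
                )
            values.append(value)
    if not values:
        raise ValueError(f"no values found in {path}")
    return NumericProfile(id=id if id is not None else path.stem, values=np.array(values))


def write_numeric_profile(profile: NumericProfile, path) -> None:
    """Write a profile as one value per line (full precision round-trip)."""
    with open(path, "w") as handle:
        for v in profile.values:
            handle.write(repr(float(v)) + "\n")
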