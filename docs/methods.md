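# Methods

## Problem and model

`hpalign` compares two one-dimensional numeric profiles — ordered series of
signed values such as per-residue hydropathy — by the *horizontal* shapes of
their trends rather than by position-wise identity. Each profile `v` of
length `M` is first expanded into its internal signed distance matrix

    D[i][j] = v_j − v_i ,

an antisymmetric `M×M` matrix that encodes every internal rise and fall of
the series. Because only internal differences enter, any constant offset
between two data sets cancels identically at this stage.

Two profiles are compared block-wise. For a block size `W` (default 5), the
`W×W` sub-blocks of the two distance matrices starting at positions `i` and
`j` are compared by the average absolute difference of their equivalenced
entries,

    S[i][j] = (1/W²) Σ_{k,l} | b1[k][l] − b2[k][l] | ,

where by default each sub-block is first scaled so that its largest absolute
internal distance is 1 (a flat, zero-variance block is left all-zero and
therefore matches any other flat block; this 0/0 convention is deliberate
and can be avoided by disabling normalization). With scaling on, every
`S` entry lies in `[0, 2]` and `S = 0` means identical shape; positive
rescaling of either profile also cancels, so the first stage is a pure
shape comparison. The average is taken over all `W²` ordered cell pairs,
diagonal zeros included; the alternative `W(W−1)` denominator would merely
rescale the cutoff `C`.

### Path search

An alignment is an ordered list of block-start pairs `(i_k, j_k)` with
`i_{k+1} ≥ i_k + W` and `j_{k+1} ≥ j_k + W` (blocks non-overlapping and
order-preserving). A path is *admissible* when every visited cell satisfies
`S[i_k][j_k] ≤ C` (which implies the block-average condition `APD ≤ C`) and
when each junction between consecutive blocks skips at most `GapMax` cells
of `S`, counting skips in both sequences together:
`(i_{k+1} − i_k − W) + (j_{k+1} − j_k − W) ≤ GapMax`. The bound is applied
per junction; `Gaps` reported for an alignment is the total over all
junctions. Paths may start at any cell. Defaults `C = 0.40`, `GapMax = 4`.

The engine finds every admissible path of maximal block count (a backward
dynamic programme gives, for each cell, the longest admissible path length
starting there; a depth-first walk then reconstructs all maximal paths in
lexicographic order of their block-start sequences). Among these longest
candidates the optimal alignment is the one with the smallest RMSD of the
aligned values after translating both aligned sets to their centres of
mass:

    RMSD² = (1/n) Σ_t ((a_t − ā) − (b_t − b̄))² ,  n = W·(number of blocks).

Ties in RMSD are broken in favour of the first path in enumeration order,
which makes the result deterministic. Because the centering couples all
aligned positions, RMSD is not additively decomposable along the path and
candidate paths must be enumerated; the identity
`RMSD² = mean(d²) − mean(d)²` over the differences `d_t = a_t − b_t` lets
the walk accumulate per-block sums of `d` and `d²` so each complete
candidate costs O(1) to score. The number of co-optimal longest paths can
be combinatorially large for long, weakly-constrained inputs, so
enumeration is capped at `path_cap` (default 100,000) candidates in
lexicographic order; truncation is flagged on the result. The reported
RMSD of the winning path is recomputed with the direct centered formula,
which is exact (0.0) for exact matches where the running-sum form would
leave ~1e−8 of cancellation noise.

### Scoring and significance

The optimal alignment is summarized by the Optimal Path Score

    OPS = (L − Gaps) / RMSD ,

with `L = W·blocks` the number of aligned residues. OPS increases with
aligned length, is penalized by gaps, and is `+inf` for an exact match.
The algebraic form is a package choice satisfying those constraints; any
fixed monotone transform would be equally valid *provided the probability
model is recalibrated against it*, which this package always does — a
model records the exact search parameters it was built with and refuses to
score alignments produced under different ones.

Significance is empirical. Pairs of random amino-acid sequences are drawn
from background residue frequencies (Robinson & Robinson 1991 by default),
profiled (Kyte-Doolittle values, 15-residue centered boxcar average, the
untiled seven positions at each end dropped), and optimally aligned. The
null OPS scores, pooled by optimal alignment length `L`, are fit per
length by scaled inverse chi-squared densities

    f(s | ν, σ²) = ((νσ²/2)^{ν/2} / Γ(ν/2)) · s^{−(1+ν/2)} · e^{−νσ²/(2s)} ,

equivalently `InvGamma(shape = ν/2, scale = νσ²/2)`, which is how the
package evaluates it (scipy.stats.invgamma). Fitting is minimum
chi-squared on variable-width bins holding at least 20 points each
(equal-count bins of exactly 20, the last absorbing the remainder; outer
edges 0 and ∞ so expected counts cover the support). A fit is accepted
when the chi-squared goodness-of-fit probability (dof = bins − 3) is at
least 0.05. Note that with data-dependent equal-count bins this test is
mildly anti-conservative, so occasional rejections of true-model data are
expected; rejected lengths are simply excluded from the next stage.

The accepted per-length parameters follow smooth length laws

    ν(L) = m·L          (least squares through the origin)
    σ²(L) = exp(a + b·ln(L + c))   (fit in the log domain)

The log-domain form guarantees positive σ² for all lengths; read literally
in the linear domain the same three-coefficient expression would go
negative. Given an observed alignment of length `L` and score `s`, the
p-value is the upper tail of the modelled null,

    p = P(S ≥ s) = γ_reg(ν/2, νσ²/(2s)) ,

the regularized lower incomplete gamma function — the unique orientation
under which larger scores are more significant. An infinite score maps to
p = 0. Lengths outside the calibrated range produce a warning
(extrapolation), and `L + c ≤ 0` is a domain error.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `W` | 5 | residues | block size; horizontal resolution of shape matching |
| `C` | 0.40 | — | per-cell shape cutoff on the scaled block distance (0 = exact shape only) |
| `GapMax` | 4 | cells | per-junction combined skip budget |
| `normalize` | on | — | per-block scaling to max abs distance 1 |
| `path_cap` | 100,000 | paths | co-optimal enumeration safety bound |
| `avg_window` | 15 | residues | hydropathy boxcar window (odd, centre-assigned) |
| `min_count` | 20 | scores | minimum bin occupancy in calibration |

A probability model is valid only for the `(W, C, GapMax, normalize)` and
data type it was calibrated with; a mismatch at use time is a hard error.

## Synthetic data and what passing tests show

The calibration generator draws i.i.d. residues from a background
frequency table, so its profiles have the amplitude and local correlation
structure (induced by the 15-residue averaging) of natural sequences but
none of their long-range organisation — no transmembrane periodicity,
domain structure, or compositional bias. Tests that pass on these inputs
demonstrate the correctness of the algorithmic machinery and the internal
consistency of the significance model; they do not by themselves establish
biological sensitivity or specificity on real proteomes. The planted-signal
tests (an offset, lightly noised copy of a query hidden among random
profiles; two noised families in an all-vs-all clustering) probe the
workflows' ability to recover a known signal under exactly this null.

Default calibration scale: 8 profile lengths spanning 50–400 with 2,000
pairs per length (16,000 alignments, a few minutes on one CPU). This is
the package's reduced protocol; the full-scale historical protocol (many
lengths between 10 and 500, ≥20,000 pairs each) is reachable through the
same `CalibrationConfig` fields. Calibration sequence lengths are
specified as *profile* lengths; generated sequences are longer by
`avg_window − 1` so the averaged profile hits the requested length.

## Numerical choices and degenerate inputs

- Coordinates are 0-based internally and 1-based in all user-facing
  output; a window-averaged profile of an `M`-residue protein covers
  residues `(w+1)/2 … M−(w−1)/2` of the original sequence.
- Exact (RMSD = 0) matches among calibration pairs would contribute
  unbounded scores; they are excluded from the sample and counted in the
  model's provenance (`n_exact`), as are no-match pairs (`n_no_match`).
- Non-match between two profiles is a distinguished result (`L = 0`), not
  an exception, and exits the CLI with status 0.
- Nonstandard residues (B, J, O, U, X, Z, `*`) exclude the whole FASTA
  record with a warning by default; a strict mode aborts instead. No scale
  values are invented for them.
- The inverse chi-squared minimum-chi-squared optimisation runs in
  log-parameter space (Nelder-Mead, three starts) from moment-based
  initial values; non-convergent lengths are flagged and excluded exactly
  like goodness-of-fit rejections.
- The σ² length law is fit with bounded nonlinear least squares from four
  starts for `c`, falling back to a fixed-`c` linear fit when the
  three-parameter geometry is degenerate (few points).
- Model files are JSON with `schema: 1` and full provenance (seed, pair
  counts, per-length fits, exclusion counters). Building twice with the
  same seed yields byte-identical files; for that reason the optional
  `date` field defaults to absent.

## Design choices made where the design was open

- **Gap semantics.** "Up to GapMax skipped cells" is applied per junction
  (combined over both sequences). A global whole-alignment budget was
  considered and rejected: with a budget as small as 4 it saturates
  random-alignment lengths at a small value regardless of profile length,
  which undermines the length-law calibration.
- **OPS form.** `(L − Gaps)/RMSD` is the simplest form satisfying the
  required monotonicities with a heavy right tail. The per-length null
  fits are driven by the score distribution's coefficient of variation, so
  the fitted ν values are stable under monotone re-expressions of the
  score, while the σ² scale is not; σ² values from this package are
  therefore meaningful only relative to its own score definition.
- **Admissibility.** The cutoff is enforced per cell, which implies the
  average (APD) condition; enforcing only the average would admit paths
  through individually poor blocks.
- **Equal-count binning.** The ≥20-point floor is realised as exactly-20
  equal-count bins because it maximises the number of informative bins at
  a fixed floor; the last bin absorbs the remainder.

## Known limitations

- The co-optimal enumeration cap makes the minimum-RMSD selection exact
  only when the candidate count is below `path_cap`; for long weakly
  constrained profiles the reported optimum is the best of the first
  100,000 candidates in a deterministic order (flagged via `truncated`).
- Significance is purely empirical; there is no extreme-value theory
  behind the length laws, and p-values for alignment lengths outside the
  calibrated range are extrapolations.
- Only pairwise alignment is supported (no multi-profile alignment, no
  affine gap model, no local re-scoring within blocks).
- The shipped calibration machinery defaults to hydropathy; other data
  types (stability profiles, translation-efficiency indices, arbitrary
  numeric tracks) are supported by the same pipeline but require their own
  calibration run.
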