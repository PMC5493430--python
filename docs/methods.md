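# Methods

## The model

`kbt2` tests, pathway by pathway, the self-contained null hypothesis that a
pathway's proteins are not differentially expressed between two phenotypes.
The data are quantitative-proteomics expression ratios (experiment/control),
typically from a single SILAC-style experiment, so a sample covariance of
the ratios cannot be estimated.  Instead the per-pathway covariance matrix
**S** is assembled from external knowledge:

- s_ii = d, a constant expressing confidence in the data (default d = 0.4,
  the STRING "medium confidence" level);
- s_ij = +c_ij when proteins i and j have a PPI confidence score c_ij and
  their ratios have the same sign (x_i·x_j ≥ 0; a zeroed ratio counts as
  same-signed);
- s_ij = −c_ij when the ratios disagree in sign;
- s_ij = 0 when no score exists.

With x the vector of processed ratios over the q mapped pathway members,
the statistic is

    T² = xᵀ S⁻¹ x  ~  χ²_q

and the p-value is the upper tail of χ² with q degrees of freedom.  When S
is numerically singular the Moore–Penrose pseudoinverse replaces the
inverse and q becomes the numeric rank of S.  The χ² reference is exact
when x ~ MVN(0, S) with S positive definite; the qualification threshold
(below) and the rule-built S both perturb it, so p-values are analytic
approximations, not permutation quantities.

## Preprocessing

Applied in a fixed order: identifier mapping → log2 transform →
winsorization → multi-identifier resolution → direction qualification →
standardization.

- **log2**: fold ratios must be positive; non-positive rows are dropped and
  counted.  Pre-logged input passes through.
- **Winsorization** (threshold on the log2 scale, default 10 ≈ 1024-fold):
  an out-of-range value is replaced by the maximum permitted magnitude —
  the largest |v| ≤ threshold among the input values — with its own sign,
  so (−7, −1, 3, 4, 6) at threshold 5 becomes (−4, −1, 3, 4, 4).  If no
  input value is in range the hard bound ±threshold is used (with a
  warning).
- **Identifier resolution**: a ratio carrying several identifiers is fanned
  out to all of them first; an identifier then carrying several ratios
  receives their median (midpoint of the central pair for even counts).
- **Qualification** (fold threshold ≥ 1, default 1.5): a protein is
  direction-qualified iff |log2 ratio| ≥ log2(threshold), judged on the
  pre-standardization ratios because fold change is a raw-scale notion.
  Unqualified proteins remain mapped pathway members (contributing d to the
  matrix and one potential degree of freedom) but enter x as 0.
- **Standardization** divides all ratios by their sample standard deviation
  (n−1 denominator); it requires at least two distinct values.

Whether qualification should compare raw or standardized ratios is a
genuinely open design point; we chose raw and made the threshold
configurable.  Winsorization precedes identifier resolution, following the
processing order the pipeline documents.

## Numerical choices

- Rank: number of singular values above rel_tol × the largest, with
  rel_tol = 1e-10·q.  Rank 0 (all-zero S) yields T² = 0, p = 1, flagged.
- The rule-built S need not be positive semidefinite (scores may exceed the
  0.4 diagonal).  A genuinely negative T² (< −1e-12) is reported as
  computed, flagged `indefinite`, and assigned p = 1 so indefiniteness can
  never fabricate significance; magnitudes within 1e-12 of zero are treated
  as roundoff and clamped to 0.
- Mapped members are ordered lexicographically so matrices and outputs are
  reproducible across runs.
- Raw p ≤ α (default α = 0.05) is the significance decision; a
  Benjamini–Hochberg column is written for information only.

## Pathway integration

Significant pathways are de-redundified greedily: repeatedly take the
remaining pathway with the largest mapped-protein set as *delegate* (ties
broken lexicographically by pathway id), absorb every remaining pathway
whose mapped set is a subset (inclusive) of the delegate's, and continue
until none remain.  A group is retained iff its delegate's p ≤ α; pathways
absorbed by a non-significant delegate are not re-tested against other
delegates.  The subset relation uses mapped sets (pathway ∩ data) by
default; a switch restricts it to qualified (non-zero) proteins.  The
procedure assumes no hierarchy relation among the input pathways.

## Robustness experiments

Sensitivity of each pathway's significance to corrupted knowledge is
measured by rebuilding S under two corruptions and re-testing:

- **permuted**: ⌊fraction·|pairs|⌋ pairs (uniform, without replacement)
  have their score resampled with replacement from the empirical multiset
  of all scores ("same score distribution"); a value-shuffle variant of the
  same idea is not the default since resampling matches the distributional
  phrasing more directly.
- **purged**: the chosen pairs are deleted outright.

Defaults are 100 experiments at fractions 0.3 and 0.6 in both modes, with
experiment e seeded base_seed+e; the expression vector x is fixed
throughout (corrupting scores cannot alter expression data).  The report
gives retention_pct, the percentage of experiments with p ≤ α.  With every
score purged, S = d·I and T² collapses to the closed form Σx_i²/d, which
the tests use as an exact oracle.

## Synthetic data

The generator emulates the three inputs at the scale of a small proteomic
screen: 200 quantified proteins; an Erdős–Rényi scored network with edge
density 0.05 and scores uniform on (0.4, 1.0], mirroring an
experimental-channel export filtered at the medium-confidence floor; 20
pathways of 5–30 members with 30% of them strict subsets of another
pathway (guaranteeing integration cases); background log2 ratios
N(0, 0.5²), which leave most unperturbed proteins below the 1.5-fold
qualification threshold; and a coherent +1.0 log2-unit (2-fold) shift on
the members of one target pathway — the same order as the 1.85-fold
responsiveness criterion used in the kind of phosphoproteomic screen this
models.  All draws are pure functions of the design and its seed.

What the generator does **not** emulate: mass-spectrometry measurement
error models, peptide/phosphosite-level structure, missingness, replicate
structure, or the topology of curated pathway databases.  Passing tests on
these fixtures demonstrate the algorithms' correctness and calibration
under the model's own assumptions, not performance on real screens.

Calibration checks bypass the qualification threshold (equivalent to
setting it to 1), because zeroing sub-threshold entries makes the null
distribution non-χ²; under MVN(0, S) data with the matching positive-
definite S, the empirical type-I error at α = 0.05 sits within 3
Monte-Carlo standard errors of α over 10,000 draws.  The calibration
demonstration preset uses a 20×20 equicorrelation matrix (diagonal 1,
off-diagonal 0.5; eigenvalues 10.5 and 0.5): evaluated with the true
matrix the test is calibrated; evaluated with an identity matrix —
correlated data misread as independent — the rejection rate departs from
the nominal level beyond 3 SE.  Because the rule-built S can be
indefinite, the generator exposes `make_psd_rulebook_sigma`, which shifts
the diagonal by |λmin|+1e-6 when needed so calibration sampling has a
valid covariance.

## Problem sizes used in the test suite

The suite exercises the statistic on pathways of up to ~30 members,
calibration on 10,000 draws in 20 dimensions, integration properties on
200 random nested collections, and robustness on the default 200-protein
study at 100 experiments — sizes at which every check completes in seconds
while still covering the regimes (degenerate ranks, indefinite matrices,
nested collections) where the method's edge cases live.

## Known limitations

- The χ² reference is exact only without qualification and with a
  positive-definite S equal to the data's true covariance; the thresholded
  statistic's null is acknowledged as non-χ².
- Confidence scores above the diagonal constant can make S indefinite; such
  pathways are flagged and never reported significant, which is
  conservative but discards their information.
- Greedy integration is order-determined: a pathway nested in two disjoint
  delegates is absorbed by whichever is processed first (larger, then
  lexicographically earlier).
- No multiple-testing correction enters the decision rule; the BH column is
  informational.
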