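# Methods

## Pipeline model and assumptions

The pipeline analyzes a protein × sample matrix of spectral counts for
a two-group comparison ("high" minus "low" throughout). Counts are
treated as relative abundances after total-count normalization; no
peptide-level modeling is attempted (protein-level counts are the
input). The log2 transform with a small pseudo-count is used as a
variance-stabilizing device, and group-level statistics (M, A, pooled
variance) assume exchangeable samples within groups.

### Normalization

Each sample j is scaled by `T̄ / T_j`, where `T_j` is its total count
and `T̄` the grand mean of totals. The operation is idempotent and
equalizes column sums exactly. A zero-total sample is a hard error.
Any other common scaling target would shift every log2 abundance (and
hence A) by a constant and leave M unchanged; the grand mean keeps the
output on the scale of the input counts. Note that M is exactly
invariant to a common rescaling of the raw counts only at
pseudo-count 0: with a positive pseudo-count the invariance is
approximate (the pseudo-count is fixed while the values scale).

### MA table

Per-sample `log2(value + pseudo_count)` with pseudo_count 0.05
(handling zeros), then group means, `M = mean_high − mean_low`,
`A_raw = (mean_high + mean_low)/2`, and `A = A_raw + a_offset` with
offset 4. The pseudo-count is added after normalization, so the MA axes
describe the normalized data. With equal group sizes A_raw equals the
all-sample mean; with unequal sizes the group-level definition is used.
A protein absent everywhere maps to `A = log2(0.05) + 4 ≈ −0.32`, which
is why A can be negative for sub-pseudo-count abundances.

### Moderated t

The pooled two-group variance s²_g (d_g = n_h + n_l − 2 df) is shrunk
toward a global prior by the standard moment estimator on log
variances: with `e_g = log s²_g − digamma(d_g/2) + log(d_g/2)`, solve
`trigamma(d0/2) = var(e) − trigamma(d_g/2)` for d0 (infinite when the
right side is ≤ 0, i.e. no excess spread beyond chi-square noise) and
set `s0² = exp(mean(e) + digamma(d0/2) − log(d0/2))`. The inverse
trigamma is computed by Newton iteration on the nearly linear
reciprocal scale (tolerance 1e-10). Zero variances have no defined log
and are excluded from the moment fit with a warning; they are still
moderated. The moderated variance is the convex combination
`s̃² = (d0 s0² + d_g s²)/(d0 + d_g)`; the statistic is referred to a
Student t with d0 + d_g df (standard normal when d0 = ∞; d0 = 0
reproduces the ordinary pooled t exactly). p = 1 whenever M = 0, and a
zero moderated variance with M ≠ 0 yields a warned p = 0 sentinel.

The signed fold change is computed on the normalized count scale,
`r = (mean_high + c)/(mean_low + c)` with the same pseudo-count c,
reported as r when r ≥ 1 and −1/r otherwise (+1.0 at equality). The
pseudo-count keeps folds finite when one group is entirely absent. The
DE filter keeps 1.3 ≤ |fold| ≤ 15 (both bounds inclusive) and p < 0.05
(strict).

### PIF and extreme sets

`PIF = A · M` using the justified A by default: the offset makes the
abundance weight positive for essentially every observed protein, so
PIF and M share sign. A raw-A mode (`use_justified=False`) is kept for
comparison. Per-tail size is `round(f · N)` with rounding half away
from zero (f = 0.05, N = 1817 gives 91). Boundary ties are broken by
larger |M|, then lexicographic protein id, making selection fully
deterministic. Tail membership depends only on the PIF ordering, so it
is invariant to any increasing transform of the scores. No p-value gate
is applied to tail membership.

### Compartment (mitoproteome) skew

Annotation symbols are matched case-insensitively after trimming.
Among matched proteins, ties (M exactly 0) are excluded and reported;
the two-sided p doubles the smaller exact binomial tail (capped at 1),
with the minimum-likelihood-sum alternative behind
`method="minlike"`. Sign is taken from M.

### Clustering

The top-40 PIF proteins' log2 abundances are row-standardized (mean 0,
sample sd 1, ddof = 1; constant rows dropped with a warning) and
clustered on both axes with Euclidean distance and average linkage —
the published figure's software offers several settings without
reporting a choice, so both are configurable and exact tree
reproduction is not claimed. The two-cluster sample partition cuts the
column dendrogram at its last merge; purity is the best of the two
cluster-to-group mappings, so it lies in [0.5, 1] for two balanced
groups. Leaf order is scipy's recursive order with deterministic ties;
no optimal-leaf-ordering seriation is applied.

### Enrichment and upstream regulators

Term enrichment is the upper-tail hypergeometric p of the observed
overlap (terms without background members are skipped), with
Benjamini–Hochberg q-values over tested terms. Regulator scoring is
unweighted: every informative edge contributes ±1 according to
(expected direction × observed sign), giving
`z = (n_act − n_inh)/√N`, so |z| ≤ √N with equality iff all informative
targets agree. Literature-derived edge weights used by commercial
tools are proprietary and unprinted, which is why published z values
for mixed-sign regulators cannot be reproduced from target counts
alone; fully consistent regulators (z = ±√N) are exact. Observed signs
are the fold signs of DE-filtered proteins only. Classification
requires overlap p < 0.05; |z| strictly above 2.0 calls
activated/inhibited, otherwise strong (≥ 1.7, including exactly 2.0),
moderate (≥ 1.5), weak (> 1.0) qualified calls carrying the sign.

## Synthetic-data generator

The generator emulates the structure of a 1817-protein, 4-vs-4
spectral-count experiment:

- **Baseline abundance**: lognormal, natural-log mean 2.0 and sd 1.5 —
  median ≈ 7 counts, mean ≈ 23, with a heavy right tail into the
  thousands, matching the dominance of a few very abundant muscle
  proteins and a large low-count stratum with many zeros.
- **Counts**: negative binomial with variance μ + φμ², φ = 0.2, a
  typical spectral-count overdispersion; φ = 0 is the exact Poisson
  limit. No generative model is published for the original data, so
  these are explicit stand-ins.
- **Effects**: a fraction (default 0.1) of proteins receive a
  multiplicative 2^effect on the "high" group mean; effects are
  half-normal (sd 1 log2 unit) with random sign, or a fixed magnitude
  via `effect_log2_magnitude` for power studies.
- **Compartment**: `n_compartment` (default 228) random proteins; their
  planted effects are positive with probability `compartment_up_prob`
  (default 0.75, a directional bias of the kind the compartment overlay
  is meant to detect).
- **Regulator networks**: targets drawn from planted DE proteins; a
  per-regulator latent state (±1) and a `consistency` proportion fix
  exactly `round(c·N)` sign-consistent edges, so the downstream z is
  `±(2·round(c·N) − N)/√N` when all targets are informative.
- **Determinism**: one master seed; per-stage generators derive from
  spawned seed sequences, so outputs are bit-identical under a fixed
  seed.

What the generator does **not** emulate: peptide-to-protein inference,
missingness mechanisms beyond sampling zeros, batch or gel-slice
effects, and correlated protein modules. Passing tests on this
generator therefore demonstrate correctness of the computations and
behavior under a plausible count model, not performance on real
proteomes.

## Test design and problem sizes

Closed-form examples are frozen against independent oracles
(binomial-coefficient enumeration for hypergeometric/Fisher/binomial
tails, brute-force sorts for tail selection, scipy's pooled t for the
d0 = 0 limit, scaled-chi-square simulations for prior recovery).
Simulation-based properties use fixed seeds and scaled problem sizes
chosen to keep the full suite fast: null calibration pools five
2000-protein replicates; prior recovery uses 5000 variances; sign
recovery uses 1000 proteins with planted |log2 FC| = 2 on an abundant
baseline (lognormal mean log 200, sd 0.4); clustering separation uses
ten 300-protein replicates with strong planted effects.

## Known limitations

- **Type-I calibration of the moderated t on counts.** The single
  global variance prior assumes exchangeable variances, but the
  variance of log2(count + 0.05) depends strongly on abundance.
  Shrinkage therefore deflates low-abundance variances (liberal) and
  inflates mid/high-abundance ones (conservative); under the
  generator's null the pooled rejection rate at α = 0.05 comes out
  slightly below nominal, and the suite's calibration check records
  this. Abundance-dependent priors (limma-trend/voom style) would fix
  it but are outside this pipeline's scope.
- **Compartment skew test on pipeline M signs.** Per-sample
  normalization offsets are shared across proteins, so null M signs
  are positively correlated and the binomial test — exact for
  independent signs — is anti-conservative on pipeline output. The
  suite verifies the test's calibration on independent signs and
  separately documents the inflation on pipeline signs. Strong
  reported skews survive this caveat; borderline p-values should be
  read cautiously.
- **Fold-sign antisymmetry** under group relabeling holds everywhere
  except the exact r = 1 boundary, where the +1.0 convention applies
  to both orientations.
- **Clustering reproduction** is qualitative: distance/linkage choices
  affect leaf orders and the exact dendrogram, and purity is the only
  quantitative claim tested.
- **Regulator scoring** is unweighted and direction-only; it cannot
  reproduce weighted scores or resolve regulators whose printed target
  directions are ambiguous.
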