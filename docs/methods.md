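# Methods

## Scope and models

`solvselect` covers the computational workflow of solvent substitution for
lipid extraction: catalog pre-filtering, three similarity screens (Hansen,
Abraham, PCA), consensus candidate selection, and the analytics used to
validate candidates experimentally (spike recovery, class-level fold
changes). Raw-data processing (peak picking, retention-time alignment,
lipid annotation) is out of scope; the package starts from peak-area tables.

### Hansen screen

The Hansen distance uses the standard convention with the factor 4 on the
dispersion term, `Ra² = 4(Δδd)² + (Δδp)² + (Δδh)²`. This was fixed before
implementation by checking that handbook δ values reproduce the published
chloroform-screen distances exactly at two-decimal rounding
(1,1,2-trichloroethane 2.59, CPME 2.87, 2-MeTHF 2.97, thiophene 3.12, DCM
3.32, THF 4.01, toluene 4.09, pyrrolidine 3.81, fluorobenzene 4.80). The
bundled Hansen table carries only entries that pass this check; a few
published screen entries (piperidine, tetrahydrothiophene, iso-butyl
acetate) are not reproducible from common handbook values and are therefore
not bundled rather than back-fitted. The short-listing threshold uses a
strict `Ra < ra_max` inequality (default 5 MPa^0.5, the conventional
substitution window being 4–6); full precision is kept internally and 2 d.p.
used only for display.

### Abraham screen

Similarity is the mean absolute difference over shared descriptors, default
symbol set {E, S, A, B, V}. With classical solute descriptors this
reproduces the published Δ = 0.039 for (E)-1,2-dichloroethene vs chloroform;
other published screen values evidently used a different descriptor table,
so the symbol set and values are data, not code. Missing descriptors are
handled by pairwise deletion with the count used (`n_descriptors_used`)
surfaced, and fewer than two shared descriptors is an error — a
one-descriptor "similarity" is not meaningful. Δ is displayed at 3 d.p.

### Catalog filtering

A record survives iff (hazard class not excluded OR name on the exception
list) AND boiling point ≤ `bp_max`. Decisions taken where the rules were
open: "above 125 °C removed" is read strictly (125.0 kept); unclassified
hazard labels are retained by default, since only explicit "hazardous"
entries are filtered and silently dropping unlabeled solvents would bias the
screen; exception matching is case-insensitive after whitespace
normalization, with a configurable alias map because catalog naming
conventions vary. Missing numeric cells are represented as missing (NaN)
from read time onward and never imputed or zero-filled; the PCA stage is
the only consumer that must handle them, and does.

### PCA (autoscaling + NIPALS)

Autoscaling centres each descriptor to mean 0 and scales to sample (n−1)
standard deviation 1, both computed over observed cells only. Population
vs sample SD is a genuine toss-up in chemometrics software; sample SD was
chosen and is the single convention used everywhere. Zero-variance or
nearly empty columns are dropped with a warning record instead of raising,
so one degenerate descriptor cannot kill a screen.

NIPALS extracts components sequentially: alternate regressions of the
loading on the score and the score on the loading, every inner product
running over observed cells only; the loading is renormalized each
iteration; convergence is declared when the relative change of the score
vector drops below `tol` (default 1e-8; `max_iter` 500, both configurable —
the oracle-comparison tests tighten them). Deflation subtracts the rank-1
reconstruction at observed cells only. The initial score is the residual
column with the largest observed variance, making the fit deterministic.
Explained variance per component is the observed-cell sum-of-squares removed
by that component's deflation relative to the total observed sum of squares.
Component signs are fixed by orienting each loading so its
largest-magnitude element is positive. Non-convergence flags the component
in `convergence_info` and continues. On complete data the fit matches
spectral-decomposition PCA to < 1e-6 (tested up to 50 × 30); with missing
cells the score columns are no longer exactly orthogonal, which is inherent
to NIPALS-style skipping, not a defect. Projection of new rows solves a
per-row least-squares problem against the loading submatrix of observed
cells, which reproduces training scores exactly on complete data. Default
`n_components` is 2, matching the PC1/PC2 plane actually used for selection.

### Consensus selection

Categorization is a strict partition (both / either / neither) over the
candidate universe. The practical judgments of a substitution study —
aromatic odor, chemotype balance, availability, ad-hoc exclusions — are
encoded as declarative rules over per-solvent boolean flags with a
per-record audit trail (`excluded_by`), because a subjective step is only
reproducible if its inputs are data. The chlorinated cap (default 2) admits
chlorinated candidates in record order until the cap is reached and flags
the surplus `over-represented-chemotype`; record order therefore expresses
preference. Negative controls are the neither-category solvents with the
smallest |PC1 offset| from the reference — chemically plausible lookalikes
that neither similarity model endorsed. No PC2 dispersion criterion is
imposed numerically; window half-widths are configuration.

### Recovery and fold change

Recovery is the ratio of group means (pre/post) times 100. The pre/post
design is unpaired, so no per-replicate ratio is defined; the reported
dispersion is the first-order propagation `R · sqrt(cv_pre² + cv_post²)`
(flagged in the result rather than hidden, since ±SD conventions vary).
Per-method summaries are unweighted means with sample SD, rounded to integer
percent for display; a single-lipid summary reports SD 0 with
`sd_defined=False`.

Class-level comparison normalizes each species to its class-matched
deuterated standard per (method, replicate), sums within class, and tests
method vs reference with a classical Student's t-test (equal variance,
two-sided), following the usual presentation of such comparisons; Welch is
available via `equal_var=False`. Tiers use the thresholds
0.001/0.005/0.01/0.05. No multiple-testing correction is applied by
default, matching per-class starred reporting; the p-values are returned so
any correction can be layered on. Degenerate noiseless groups (relative SD
below 1e-12) short-circuit the test: equal means give p = 1, unequal give
p = 0.

## Synthetic data

The catalog generator plants: (i) a rank-`n_latent` descriptor block
(latent scores × orthonormal loadings + Gaussian noise, default SD 0.05 on
autoscale-order values) whose first latent axis separates a
chloroform-like cluster from the rest; (ii) a Hansen cluster of
`reference_cluster_size` solvents (default 12, shortlist-sized) with exact
distances drawn inside `0.95 × cluster_radius` and all others outside
`1.2 × cluster_radius`, so rank order against the reference is
deterministic; (iii) Abraham descriptors whose spread grows with Hansen
distance, correlating the two screens as they are in real catalogs; (iv)
uniform-at-random missing descriptor cells (default 5 %; the mechanism is
pluggable because no particular missingness model is canonical), with a
guarantee that every row and column stays observable; and (v) a hazard
class / boiling point composition such that the default filter retains
exactly `n_pass_filter` solvents (defaults 272 → 83, the composition of the
pharmaceutical solvent-selection catalog this stands in for, which is not
publicly deposited), with the reference itself hazardous at 61 °C so the
exception path is exercised.

The peak-area generator uses multiplicative log-normal noise,
`area = base · exp(cv · z)` — areas are positive and MS intensity noise is
scale-proportional; `cv` is the SD of the linearized log factor. Post-spike
areas sit at a per-lipid baseline, pre-spike areas at baseline ×
recovery/100, each with independent noise (the groups are physically
distinct samples). The endogenous species table applies the planted class
effect to species areas but not to standards, so the normalized class sums
carry exactly the planted fold change in the noiseless limit. Defaults — a
13-standard panel, 3+3 replicates, cv 5 % — mirror a typical spike design.

What the simulations do not emulate: concentration-dependent ionization or
matrix suppression, correlated noise across lipids in a run, heavy-tailed
outliers, drift, or informative missingness. Passing tests therefore show
the estimators and screens are correct under the stated noise model, not
that any particular solvent performs well on real plasma.

## Estimator accuracy under the default noise model

For the per-lipid ratio-of-means estimator at true recovery R with
per-replicate cv and n replicates per group, the delta method gives a
relative error SD of `cv · sqrt(2/n)`, i.e. a mean absolute error of about
`R · cv · sqrt(2/n) · sqrt(2/π)` ≈ 3.1 percentage points at R = 95 %,
cv = 5 %, n = 3 (the Monte-Carlo tests reproduce this). The estimator is
essentially unbiased (< 0.2 pp). The panel-average recovery over the
13-standard panel — the per-solvent headline number — has MAE ≈ 0.9 pp
under the same conditions. Improving per-lipid accuracy requires more
replicates, not a different estimator.

## Problem sizes

Default analyses run in seconds on one CPU: catalogs of a few hundred
solvents with ≤ 30 descriptors, NIPALS on ≤ 100 × 30 blocks, Monte-Carlo
studies of 200 replications. These sizes match the intended use (solvent
catalogs are small); nothing in the implementation is specific to them.

## Known limitations

* The bundled Hansen/Abraham tables cover the chloroform case study, not a
  general parameter database; users screening other references must supply
  their own catalog.
* NIPALS extracts components greedily; with many missing cells the
  components are approximate in the usual NIPALS sense (no EM refinement).
* The fold-change t-test assumes approximately normal replicate class sums;
  with n = 6 replicates this is a convention, not a guarantee.
* Practical-rule flags (aromatic, chlorinated, availability) must be
  provided in the catalog; the package does not derive them from structure.
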