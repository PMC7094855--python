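# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Normalization and QC

The study design is 4 time points (t0 = uninjured control, t6, t12, t24
hours post-injury) × 4 replicate arrays, one-color signals with per-feature
per-array flag calls.

**Flag collapse.** A feature's 16 flags collapse with the precedence
Cm > NDt > Dt: any Compromised array excludes the feature (the conservative
reading — one corrupted measurement poisons the geometric mean), any Not
Detected array demotes it to NDt (kept, since "not detected" is a valid
biological zero), and Dt requires detection on every array. Retained =
{Dt, NDt}.

**Representative track.** (1) signals below background (negative after the
scanner's background subtraction) are set to 1, so their log2 is 0; (2) the
four replicates at one time collapse to their geometric mean — the natural
mean for multiplicative intensity noise; (3) log2; (4) the 75th percentile
of each time point's column is subtracted, anchoring inter-array scale on
the upper-quartile signal under the assumption that most genes do not
fluctuate. Percentiles use linear interpolation between order statistics
(numpy's default; configurable via `percentile_shift(..., method=)`), and
are computed over **all features present in the table**, including ones QC
later removes — the QC filter restricts downstream stages only. Fold
changes are ratios of the non-log (2^shifted) values to control, so the
control column's FC is identically 1.

**Per-array track.** ANOVA and Tukey need replicates, which step (2)
destroys, so a parallel track applies clip → log2 → per-array
75th-percentile shift without collapsing. This reconciliation (collapse for
FC/CA, keep replicates for testing) is an explicit design choice; both
tracks share steps (1), (3) and the percentile convention. The per-array
shift makes the track covariant under per-array rescaling: multiplying one
array by 2^k leaves its shifted values unchanged.

## Differential calling

Per gene, classical one-way fixed-effects ANOVA over the four groups
(scipy). Genes with zero between- and within-group variance have an
undefined F and become no-calls. BH correction is applied per test family:
ANOVA p-values across genes form one family; each control contrast's Tukey
p-values across tested genes form another. Genes passing the ANOVA screen
(BH-corrected p < α = 0.05) get all-pairs Tukey HSD — the studentized range
is taken over all four group means, as the procedure requires — but only
the three control-vs-time contrasts drive calls: U/D where the corrected
contrast p < α, signed by the mean difference. Everything else is `-`.
Each gene's (t6, t12, t24) call triple is one of 27 fluctuation patterns.

Threshold gene sets use strict inequalities: "more than 3-fold up" is
FC > 3, "more than 3-fold down" is FC < 1/3 (reciprocal thresholds; the
5-fold down bound 1/5 = 0.2). The 5-fold set is a subset of the 3-fold set
in the same direction by construction.

**Tukey p-value evaluation.** Exact p-values come from scipy's studentized
range distribution (numerical integration, ~7 ms per value). Screening
thousands of genes with it is wasteful, so for > 64 values the survival
function is evaluated through a cached 711-point monotone grid per
(k, df) pair and linear interpolation; the absolute error is ≈ 2×10⁻⁵,
negligible against the α = 0.05 decision boundary and the BH step. The
`method` argument ("exact" / "interp" / "auto") exposes the choice.

## Degree transform and correspondence analysis

`d(FC) = (180/π)·arctan(1/FC)` maps (0, ∞) onto (0°, 90°), strictly
decreasing, with d(1) = 45° and the complement identity
d(FC) + d(1/FC) = 90°. The reciprocal orientation (small FC → large degree)
is the one consistent with both anchor facts: a fold change of 1 is 45°,
and the value rises toward 90° as the fold change shrinks. Unlike the log
ratio the transform is bounded, so extreme ratios (beyond ~10-fold either
way) are compressed rather than dominating the ordination. Degrees, not
radians, enter CA (an overall positive rescaling of the matrix would not
change CA anyway, since CA analyses relative profiles).

CA is the classical chi-square ordination implemented from first
principles: correspondence matrix P = N/n, masses r and c, standardized
residuals S = (P − rcᵀ)/√(rcᵀ), SVD S = UΣVᵀ, principal coordinates
F = D_r^(−1/2)UΣ and G = D_c^(−1/2)VΣ, inertias σ², contribution rates
σ²/Σσ². For a 3-column table there are at most two non-trivial axes, so the
biplot is exact: Euclidean distances between full-rank row principal
coordinates equal chi-square distances between row profiles (verified
against a brute-force oracle in the tests), and P reconstitutes exactly at
rank 2. The symmetric map (rows **and** columns in principal coordinates)
is used because gene-to-time-score Euclidean distances are consumed
downstream.

**Sign convention.** SVD axes are orientation-ambiguous. Each axis is
flipped jointly for rows and columns so that the last time column (t24)
scores non-negatively on axis 1 and the first (t6) non-positively on
axis 2 — arbitrary but fixed; all invariance tests treat coordinates as
equivalent up to joint sign flips. Degenerate input (all rows identical)
returns zero inertia with every score at the origin, not an error.

`transition_check` verifies the CA transition identities (each row
coordinate is the profile-weighted average of column coordinates divided by
the singular value, and symmetrically) to 10⁻⁸ after every pipeline run.

## Biplot geometry

A row's principal coordinates are a **linear** function of its degree
profile (the transition formula), so each locus {d_a = d_b} — equivalently
{FC_a = FC_b} — maps to an exact straight line on the plot, and the three
loci are concurrent at the image of the uniform profile (the flat-FC
point). That is why the six strict orderings of (FC6, FC12, FC24) occupy
six line-bounded areas (A: FC6<FC12<FC24, B: FC6<FC24<FC12,
C: FC24<FC6<FC12, D: FC24<FC12<FC6, E: FC12<FC24<FC6, F: FC12<FC6<FC24)
and why the boundaries generally miss the origin: the uniform profile
coincides with the centroid profile only when the column masses are equal.
Exact FC ties get a `tie` marker rather than an arbitrary area label.

The empirical fitting procedure estimates each boundary from data rather
than from the transition algebra: among the q = 100 genes whose
|log(FC_a/FC_b)| is smallest (nearest the boundary), the two with maximal
Euclidean separation on the plot anchor the line — a reproducible stand-in
for manually picking genes "at the ends" of the boundary. q = 100 mirrors
the top-100 near-unity convention used when examining boundary gene
populations. Point P is the least-squares point minimizing summed squared
distances to the three fitted lines (equal to the common intersection when
they are concurrent). Vertical fitted boundaries (equal anchor x) are
rejected as errors rather than special-cased; they do not arise for
non-degenerate anchor pairs.

Distance sets rank genes by Euclidean biplot distance to an anchor (a
time-series score, or one of the top-5 most up-/downregulated "query"
genes at a time point), with deterministic lexicographic gene-id
tie-breaks; top-100 ⊂ top-300 ⊂ top-1000 by construction.

## Enrichment

Fisher over-representation is the hypergeometric upper tail P(X ≥ x) on
the 2×2 set × term table. The universe defaults to all QC-retained genes,
including unannotated ones; term members outside the universe are dropped.
PAGE scores pathway-level shifts: Z = (Sm − μ)·√m/δ with μ, δ the mean and
(ddof = 1) standard deviation of all universe gene scores and Sm the term
mean; scores are log2 fold changes at the gene set's defining time point
(the canonical PAGE input). p-values are two-sided normal. BH families are
per (gene set × catalog category) for Fisher and per gene set over pathway
terms for PAGE. GMT catalogs carry no category field, so category is
assigned per file, the way gene-set collections are distributed.

## Synthetic data

The generator draws per-gene log2 baselines N(7, 2²) (lognormal signals
spanning the typical array dynamic range), assigns each gene one of the 27
patterns, adds ±`effect_log2fc` (default 3, i.e. 8-fold — a strong injury
response) at the flagged time points, adds N(0, 0.25²) replicate noise on
the log2 scale (additive Gaussian on log signals, the standard microarray
noise model), and draws flags independently per feature × array (NDt 5%,
Cm 1%). The default pattern mix — 40% unchanged, 12% all-down, 5% all-up,
the rest uniform — loosely reflects the dominance of unchanged and
downregulated genes in injured-muscle screens. None of these values are
estimates; they are documented assumptions chosen once.

The catalog planter constructs `n_enriched_terms` terms containing exactly
`round(enrichment_fraction × term_size)` genes of planted pattern (U,U,U)
(by construction, not sampling), the rest drawn from the remaining genes;
other terms are uniform draws.

What the generator does **not** emulate: probe sequences, dye or spatial
array effects, correlated flags, heteroskedastic (intensity-dependent)
noise, or correlated genes. Passing tests therefore demonstrate
correctness of the algorithms under a clean generative model, not
robustness to every artifact of real array data.

One subtlety the tests make explicit: the 75th-percentile shift means
realized fold changes equal planted fold changes only up to a per-time-point
constant 2^−(q_t − q_0), where q_t is the time point's 75th percentile.
For a shift-free pattern mix the constant is 0 and the match is exact; for
mixes with many planted shifts the normalization's "most genes unchanged"
assumption is violated by design, and the tests assert the offset-corrected
form. For the same reason a study in which *every* gene is planted (U,U,U)
is normalized flat — the per-array percentile shift removes a global shift
by construction — so recovery of such plantings is tested at the
differential module's own interface (per-array log2 values), which is
equivalent to assuming no inter-array technical offsets.

## Problem sizes and determinism

Simulation-backed tests use 1,500–10,000 genes: large enough for the
binomial/Monte-Carlo tolerances they assert (3 standard errors), small
enough to keep the whole suite around ten seconds. The boundary-recovery
bound of 99% correctly-sided genes is asserted on a 10,000-gene study where
anchor genes land essentially on the true boundary; a 3,000-gene companion
test uses 98% because anchors sit measurably off the boundary at that size.
All randomness flows through seeded `numpy.random.default_rng` streams
(spawned sub-streams per generator component), hypothesis runs
derandomized, and the pipeline's outputs are byte-reproducible for a fixed
config — asserted by test.

## Known limitations

* Tukey HSD assumes equal variances and balanced groups; Tukey–Kramer
  standard errors handle mild imbalance but no Welch-style correction is
  attempted.
* The BH family definitions (per test type; per set × category) are
  reasonable conventions, not uniquely determined by the procedure.
* Boundary anchor selection is a stand-in for a manual choice; alternative
  rules (e.g. total-least-squares on all near-boundary genes) would give
  slightly different lines.
* The loader side covers the signals/flags TSV and GMT dialects plus an
  adapter from Feature-Extraction-style boolean flag columns; it does not
  parse vendor series formats directly.
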