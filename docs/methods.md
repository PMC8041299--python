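# Methods

This note records the statistical model behind `lipidblocks`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
generator does and does not emulate.

## Data model

A `LipidomeDataset` is a non-negative samples × species matrix with sample
metadata (tissue ∈ {gut, liver, muscle}, life stage ∈ {FW, SW}, diet group,
day, tank, fish) and parsed species annotations. The diet factor has eight
levels: the two day-0 controls (`D0_FO`, `D0_VO`, fish kept on fish oil or
vegetable oil since first feeding) and the switched groups sampled 1, 5/6
and 20 days after crossing over (`FOVO` = fish-oil history switched to
vegetable oil, `VOFO` the reverse). The nominal "day 5/6" level is a single
factor level: the freshwater arm was sampled on day 5, the seawater arm on
day 6. Within a tissue the design is balanced with n = 4 fish per
diet-group × stage cell (2 fish per tank × 2 tanks). Tissues are always
analyzed separately.

## Nomenclature

Species names follow class-level shorthand `CLASS-C:DB` with the 14 classes
a positive-ionization lipidomics workflow resolves (TG, DG, MG, PC, PE,
LPC, LPE, PG, SM, CER, GluCer, GalCer, CE, COH). Parsing is strict (a
typo'd class token is an error naming the token), the canonical form
round-trips, and ether/plasmalogen prefixes (`PC-O-`, `PE-P-`) are parsed
but excluded from composition enumeration, since one of their chains is a
radyl, not a fatty acyl. Composition enumeration is exact: for classes with
a known chain count (TG 3; DG/PC/PE/PG 2; LPC/LPE/MG/CE 1) it returns every
multiset from the acyl pool whose summed carbons and double bonds equal the
species totals, in deterministic lexicographic order. Multisets, not
sequences: class-level MS cannot resolve sn-positions. The default pool
{16:0, 16:1, 18:0, 18:1, 18:2, 18:3, 20:4, 20:5, 22:5, 22:6} covers the
fatty acids that dominate fish-oil and vegetable-oil feeds; it is a
parameter, not a constant. Note the enumeration reports what is
*arithmetically consistent*: a shorthand like PC-38:8 cannot contain
16:0 + 22:6 (that pair sums to 38:6) — from the default pool its only
candidate is 18:3 + 20:5.

## Identification filters

Class assignment uses closed retention-time × m/z rectangles, validated as
pairwise disjoint (rectangles sharing even an edge are rejected, otherwise
a boundary feature would have two classes); a feature on a window edge is
assigned, not dropped. Mass accuracy is |Δm|/m·10⁶ with the conventional
5 ppm gate. The isotope-envelope score is cosine similarity in percent with
an 80% gate; the upstream vendor software does not document its metric, so
cosine — the standard envelope comparison — is used and is swappable. The
per-class windows of any real chromatographic method must be user-supplied;
no defaults are shipped because they are instrument-specific.

## Normalization

`normalize_to_all` divides each sample by a scalar factor: the exponential
of the median of log ratios to a reference sample, computed over species
nonzero in both (zeros are treated as missing and never logged; a sample
sharing fewer than 10 nonzero species with the reference is an error
naming the sample). `reference="auto"` picks the sample whose log total
abundance is the (lower) median. The factors are relative — the reference's
own factor is exactly 1 — and the scheme is idempotent for a fixed
reference. A `total_sum` mode (factor = total/total_ref) is selectable;
median-of-log-ratios is the default because it is robust to the minority
of species that genuinely change between samples, which is the entire
point of a diet-switch experiment.

## Multiblock preprocessing

Per tissue, species are partitioned into five blocks (TG, DG, PC, PE,
Other) — the partition is configurable but must define exactly five
blocks. Each block is column-autoscaled (mean 0, sd 1 with the n−1
denominator conventional in chemometrics; a zero-variance species is an
error listing the species) and then divided by √(total SS), so every
block's total sum of squares is exactly 1 and a class with 120 species
cannot drown one with 20. All transform parameters (means, sds, block
divisor) are stored, making the chain invertible to ~1e-10 relative error.

## Consensus PCA

Components are extracted one at a time. The super score t is initialized
as the concatenated-matrix column of maximal variance and iterated as

    p_b = X_bᵀ t / tᵀt        (block loadings)
    t   = Σ_b X_b p_b          (consensus update; loading jointly
                                unit-normalized for scale stability)

to tolerance 1e-10 on the relative change of t, with up to 5000
iterations. Non-convergence is a recorded warning, not an error: at a
small top-eigenvalue gap the power-type iteration is slow, and the
5000-iteration ceiling was set so that the score agrees with the direct
SVD route to better than 1e-6 even then. Each block is deflated by the
super score, which is what makes the global solution *exactly* PCA of the
column-concatenated matrix — the independent oracle asserted throughout
the tests. One candidate consensus update, taking the super weight as
w = Tᵀt/tᵀt with block scores X_b p_b/(p_bᵀp_b) and renormalizing, makes
every super-weight entry identically 1/√B and converges to a measurably
different direction (cosine ≈ 0.99 to the leading singular vector on
random five-block data); it was rejected because it cannot reproduce the
concatenated-PCA solution that defines the method's global scores here.
Block scores t_b = X_b p_b/(p_bᵀp_b) and unit-norm super weights with
entries ∝ ‖p_b‖² report each class's share of the consensus. Signs are
fixed deterministically (the largest-|loading| entry is positive), so
reruns are bit-identical, and explained variance is reported per component
as a fraction of the preprocessed total SS, globally and per block; global
EV is non-increasing and sums to 1 over all extractable components.

Correlation loadings are Pearson correlations of each normalized
(pre-centering) species with the global score vectors; Pearson correlation
is centering- and scale-invariant, so this equals the correlation with the
autoscaled data. A species' explained variance over the plotted pair is
r₁² + r₂², i.e. its squared distance from the origin: the 100% circle has
radius 1 and the 50% circle radius √0.5 ≈ 0.707. (Describing the inner
circle as "radius 0.5" is a common shorthand in score-plot figure legends
but is inconsistent with the sum-of-squares definition; the plots here
draw √0.5.)

## Differential abundance

Per species, a balanced fixed-effects two-way ANOVA with interaction is
fitted on log₂-transformed normalized abundance (log transformation
stabilizes the multiplicative error; the fold changes reported alongside
are computed on the untransformed normalized scale, matching how fold
changes are conventionally quoted). The balanced decomposition is closed
form and vectorized across species; SS_total = SS_diet + SS_stage +
SS_interaction + SS_error holds exactly, and zero error SS (degenerate
data) yields NA p-values with a flag rather than an arbitrary number.

Tukey's HSD uses the studentized range Q with family k = all 16 diet ×
stage cells — the most conservative coherent family — and df = 16(n−1);
the family is configurable. The reported contrasts are FW vs SW within
each diet group. The adjusted p is non-decreasing in k and never below
the unadjusted pairwise p. Because one pipeline run needs thousands of
studentized-range tail probabilities and generic scalar routines cost
~10 ms each, the package evaluates the classical double integral by
two-level Gauss–Legendre quadrature, vectorized over all q values at a
common (k, df); the tests pin it to `scipy.stats.studentized_range` at
~1e-12 and to `scipy.stats.tukey_hsd` end-to-end.

A species is significant when, on some FW-vs-SW contrast, |log₂FC| > 1
AND p < 0.05 (Tukey-adjusted by default; the ANOVA stage main effect is a
config option). NA fold changes (non-positive means) never pass. Flagged
species are row-scaled (mean 0, sd 1 across the 16 cell means), clustered
with average linkage on Euclidean distance, and the tree is cut into a
configured number of groups (default 4, labeled A, B, … in dendrogram
leaf order, so labels are deterministic). The group count is a parameter
because no principled cut rule exists at class level; choose it per
tissue by inspection of the heatmap.

## Kinetics

The working model of remodeling is first-order relaxation on the log₂
scale: after a switch at day 0, E[log₂ y(t)] = y_target + (y_source −
y_target)·e^(−kt), with one rate constant per (stage, tissue) shared by
species — multiplicative remodeling, consistent with dilution of the old
lipid pool by new intake. `fit_switch_rate` re-estimates k by nonlinear
least squares over the switched-group means of all diet-responsive
species jointly (both switch directions), anchoring each species' source
and target levels at the day-0 control means; species whose steady states
differ by < 0.5 log₂ units carry no kinetic signal and are excluded. A
joint fit is used because k is a property of the tissue's turnover, not
of one species, and a single-species fit at n = 4 is too noisy to mean
anything.

`estimate_stage_log2fc` estimates a species' life-stage effect from the
day-0 cells only, averaging log₂ abundance within each diet control and
then across the two controls before differencing SW − FW. The day-0
restriction keeps switch kinetics (which differ between stages in both
rate and sampling day) out of the contrast, and pooling the two diet
histories doubles the fish per stage while cancelling any diet effect
symmetric across histories.

## Synthetic generator

`generate_experiment` emulates the full factorial design with ~300
species: 120 TG, 80 PC, 50 PE, 20 DG, 30 Other, drawn from
chemically plausible (class, C, DB) grids (double bonds capped at roughly
one per three carbons, the DHA-level ceiling). Baseline log₂ abundances
place TG/PC/PE far above the minor classes (>90% of total abundance).
Half the species are diet-responsive with |μ_FO − μ_VO| ~ |N(1.8, 0.5)|
log₂ units, signed by unsaturation (DB ≥ 8 richer under fish oil); 40% of
PC/PE species carry a ±1.5 log₂ stage offset (90% of them lower in
seawater); the remainder are null. Rate constants default to SW gut 0.60,
FW gut 0.30, liver 0.35/0.30, muscle 0.06/0.05 d⁻¹ — the seawater gut
twice as fast as freshwater, gut and liver near steady state by day 20,
muscle far from it. Tanks share an additive N(0, 0.05²) log₂ offset, and
measurement noise is log-normal with CV 15% (σ_ln = √log(1+CV²)).
Identical configs (including the mandatory seed) give bit-identical data.

The `SyntheticTruth` record carries every species' steady states, offsets
and labels, and evaluates the noise-free expected value of any design cell
in closed form, so expected contrasts (e.g. the day-20 switched-vs-control
residual (μ_src − μ_tgt)·e^(−20k)) are available analytically for
benchmarking.

What the generator does *not* emulate: censoring/missing features,
heteroscedastic or intensity-dependent noise, correlated species within a
pathway, drift or batch structure, tissue-specific stage offsets (the
planted offsets are shared across tissues, which is why the per-tissue
significant counts coincide on default settings), or raw MS artifacts
(retention times and isotope envelopes exist only as toy inputs for the
identification filters). Passing tests therefore demonstrate correctness
of the statistical machinery under the stated model, not robustness to
every pathology of real LC-MS data.

## Pipeline and determinism

`run_pipeline` executes simulate/ingest → normalize → blocks → CPCA →
differential per tissue, writing delimited text with fixed `%.10g` float
formatting, and a manifest with the seed, a config hash (excluding the
output directory) and a SHA-256 checksum per file. Stages are pure
functions of (inputs, config, seed), so two runs with the same seed are
byte-identical — asserted in the tests. Configs (YAML/JSON) reject unknown
keys, including inside the nested simulation block. Plots (global/block
score plots, the correlation-loading circle plot, the row-scaled heatmap)
are written only when enabled.

Problem sizes in the test suite and acceptance script — 20 random
five-block datasets for the CPCA oracle, 2000 null species for the type-I
calibration, 200 replicate experiments (one tissue, 40 species) for
parameter recovery — were chosen so the full suite completes in well under
a minute while keeping the binomial/Monte-Carlo intervals tight enough to
be meaningful.

## Known limitations

- ANOVA requires strictly positive normalized abundances (no zero
  imputation); real zero-inflated species must be filtered or imputed
  upstream.
- The Tukey family and the cluster-group count are conventions, not
  inferences; both are exposed as config.
- The identification module ships no real class windows.
- Multiblock PLS, sparse variants and cross-validated component selection
  are out of scope.
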