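# Methods

`ntrprox` implements the statistical core of a BioID proximity-labeling
screen of nuclear transport receptors (NTRs): a panel of BirA* fusion
cell lines (one per receptor construct) plus control lines, each
measured by label-free LC-MS/MS in biological quadruplicate and
technical duplicate.  The package answers two questions: which proteins
interact with the NTR machinery at all (the NTR-interacting proteome,
NIP), and which proteins are *specific* to an individual receptor
(candidate transport cargo).

## Missing values and imputation

Label-free intensities are missing for two reasons that demand opposite
treatment.  For every pairwise comparison of two sample groups, a
protein's pattern is classified from the per-group observed counts
alone (quadruplicate rules, stated for groups of four):

| observed counts | class | action |
| --- | --- | --- |
| 4/4 and 4/4 | COMPLETE | none |
| ≤1 in one group, ≥3 in the other | MNAR | MinDet: fill with the minimum observed value of the same run |
| exactly one missing in each group | MAR | kNN: mean of the k = 10 nearest protein profiles' values in that run |
| anything else | EXCLUDED | protein dropped from this comparison |

MNAR (missing not at random) absences concentrate in one group and are
read as biological: the protein sits below the detection limit there,
so the deterministic column-minimum fill preserves the direction of the
difference.  MAR absences are isolated and are reconstructed from
similar proteins; neighbour distance is the Euclidean distance over
mutually observed columns divided by the shared-column count, so rows
sharing few columns are not favoured.  When one group is the pooled
control set (16 columns) the count thresholds become the equivalent
fractions (≤ 1/4 observed vs ≥ 3/4; "one missing of four" becomes a
missing fraction in (0, 1/4]).  Classification is per comparison, so a
protein may be excluded from one contrast yet tested in another.

After imputation each comparison's submatrix is quantile-normalized:
column *c*'s i-th smallest value is replaced by the mean of all
columns' i-th smallest values; ties receive the mean over their rank
range.  Normalization is per comparison by default (consistent with
per-comparison imputation); a global mode is available by normalizing
before splitting.

Identification filtering precedes everything: protein groups need at
least two unique peptides and observation in at least three biological
replicates of at least one cell line (a biological replicate counts as
observed if any of its technical replicates is).  Technical duplicates
are then averaged (mean of observed values) into one column per
(line, biological replicate).

## Moderated testing

Each contrast is a two-group comparison with equal residual df *d* for
all proteins (complete-case after imputation).  Per-protein pooled
variances s²_g are shrunk toward a prior estimated by the method of
moments on log variances: with

    e_g = ln s²_g − ψ(d/2) + ln(d/2)

the excess of Var(e) over the sampling term ψ′(d/2) identifies the
prior df d₀ through ψ′(d₀/2), inverted by bisection on (10⁻³, 10³)
with tolerance 10⁻¹⁰ and guard ε = 10⁻⁸ (zero or negative excess gives
d₀ = ∞ and the pure point prior s₀² = exp(ē) — note exp(ē) includes
the log-scale bias correction (d/2)/e^ψ(d/2), which is what the
moment equations imply and what limma's fitFDist returns).  The
moderated statistic is

    t̃_g = (x̄_A − x̄_B) / (s̃_g √(1/n_A + 1/n_B)),
    s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d),

with one-sided p-values from the t distribution on d₀ + d df (normal
for d₀ = ∞).  Hyperparameters are fitted per comparison, because each
comparison has a different imputation footprint.  A test asserts exact
agreement with limma's `eBayes` (via Rscript) on a shared fixture; the
implementation itself is pure Python/NumPy.

## NIP and background calling

Every NTR sample is compared one-sidedly against the pooled control set
(both directions).  Per protein and direction, the per-comparison
p-values are combined by Simes-based closed testing: the reported
statistic is the minimum adjusted elementary p-value, i.e. the maximum
Simes p-value over every intersection hypothesis containing the
comparison, minimized over comparisons (Hommel's O(m²) shortcut; a test
verifies it against exhaustive enumeration of all 2^m − 1
intersections).  It is small exactly when the protein is enriched in at
least one comparison.  Note this is *not* the same number as the plain
Simes combination min_i m·p₍ᵢ₎/i of the full set — the two coincide
only for m ≤ 2 — although both are valid global tests; the plain
combination is also exposed.  The per-protein statistics are BH-adjusted
across proteins within each direction; NIP = adjusted p < 0.1 in the
NTR-enriched direction, background proteome = the control-enriched
direction.  A protein passing both (rare; logged) is assigned the
smaller adjusted p.

## Specificity scoring

All S·(S−1) directed NTR-vs-NTR comparisons are run (each unordered
pair fitted once).  For protein g and sample s, the contrasts where g
is enriched in s at one-sided p < 0.01 contribute their p-values and
fold changes:

    score(g, s) = −log₁₀ ∏ p_i        (0 when no contrast qualifies)
    avgFC(g, s) = mean of the matching moderated log2 fold changes
    X²(g, s)    = −2 Σ ln p_i  ~  χ²_{2k}  →  Fisher p

The product penalizes shared machinery by construction: a protein
pulled down by every receptor wins few pairwise contrasts and scores
near zero, while a single-receptor cargo beats all other samples and
accumulates k ≈ S−1 factors.  Fisher's combination is applied to the
*selected* (already significant) p-values; together with the shared
columns across a sample's contrasts this makes the combined p-values
anti-conservative.  That is a property of the scoring scheme itself,
retained deliberately; the final BH adjustment (over the full protein ×
sample grid, entries without evidence at p = 1) and the 0.01 cut are
applied to these combined values, and the realized false-discovery
proportion should be read against this caveat (see the simulation
notes below).  The moderated fold-change estimates are what "adjusted
FC" refers to.

## Network propagation with topology-bias correction

Specificity scores are smoothed over a protein-protein interaction
network (STRING-style edge list, combined score > 0.7; scores on the
0–1000 scale are detected by a maximum above 1 and divided by 1000).
With W the weighted adjacency and D the weighted-degree diagonal, the
operator is the symmetric normalization W̃ = D^(−1/2) W D^(−1/2)
(isolated nodes keep zero rows), and T = 30 iterations of

    F ← α W̃ F + (1 − α) F₀,    α = 0.5, F(0) = F₀

approximate the closed form (1−α)(I − αW̃)^(−1)F₀ to within
α^(T+1)·‖F₀‖∞ (≈ 10⁻⁹ relative; a test checks 10⁻⁶ agreement on
graphs up to 200 nodes).  High-degree nodes accumulate score regardless
of signal; each node's topology bias is measured by propagating the
constant vector mean(F₀)·1 with the same parameters and subtracting
the result.  Constant input then yields exactly zero corrected scores.
Per sample, the top floor(0.02·n) nodes by corrected score are
extracted (ties at the cut broken by ascending identifier) and the
induced subgraph is decomposed into connected components, largest
first, with edge densities — a deliberate, simple stand-in for external
dense-module mining tools.

## Biotinylation sites

Directly identified biotinylated peptides localize contacts to
residues.  Sites are kept when observed in at least two of four
biological replicates of at least one line; intensities are per-run
median-normalized on the log2 scale (the minimal location
normalization; quantile mode available) and then per-site
median-centered, making profiles comparable across samples and
invariant to per-run additive shifts.  Residues map to every annotated
domain containing them (1-based inclusive; overlaps all reported);
unannotated positions are labeled linker/disordered.  Per (protein,
line), observed-site counts are paired with mean iBAQ and summarized by
a per-protein Spearman correlation across lines (undefined below three
paired lines or for constant series).

## Synthetic data

The generator plants a known answer behind the full pipeline.  Log2
intensities follow

    y[g,r] = a_g + δ·[g cargo of bait(r)] + δ_c·[g control-enriched, r control]
               + b[g, line, bio] + t[g, run]

with a_g ~ N(μ, τ²), biological noise b shared across technical
replicates, and technical noise t.  Dropout is the union of a logistic
MNAR component, P(miss) = 1/(1 + exp(k(y − m))), and an independent
Bernoulli(ρ) MAR component.  Defaults: μ = 25, τ = 2 on the log2 scale
(typical LFQ intensity magnitudes), σ_b = 0.5 > σ_t = 0.2 (biological
exceeds technical variation), δ = δ_c = 2, cargo fraction 0.3 (roughly
a third of identified proteins enriched somewhere, as in this kind of
screen), control-enriched fraction 0.1, m = 20, k = 1, ρ = 0.05 —
about 8% overall missingness, concentrated at low abundance.  The
interaction network is a planted-partition graph: complexes (disjoint
blocks of cargo sharing one receptor) are wired with p_in = 0.8,
background pairs with p_out = 0.01, and realized edges get weights
uniform on (0.7, 1).  Site tables inherit the protein's simulated
intensity plus a site offset and noise, with the same dropout model.
All randomness derives from one seed through CRC-named substreams, so
each artifact is independently reproducible.

What the generator does **not** emulate: peptide-level identification
FDR, match-between-runs artifacts, batch effects beyond run-level
location shifts, correlated (complex-wise) abundance changes, or
heavy-tailed intensity noise.  Passing recovery tests therefore shows
the statistical machinery is wired correctly and calibrated under its
own assumptions — not that real screens achieve these error rates.

The reference simulation (1,000 proteins, 6 NTR + 2 control lines,
quadruplicate × duplicate, seed 0) runs the whole pipeline in a few
seconds; sizes were chosen so the suite stays interactive while the
calibration checks (10,000-protein nulls, 5,000-protein prior
recovery) retain enough resolution.  On it, cargo–receptor pairs are
recovered with sensitivity ≈ 0.99 at a false-discovery proportion
≈ 0.10.  The FDP hovers at its bound across seeds (≈ 0.08–0.15): the
residual false calls are exactly the anti-conservative Fisher
combinations described above — a sample's contrasts share its four
columns, so one fortunate biological draw yields several correlated
sub-0.01 p-values.  This is inherent to the scoring scheme, inherited
knowingly, and documented rather than patched.

## Numerical and degenerate-input choices

* Intensity zeros and empty cells both mean missing; no distinction is
  kept.
* Duplicate (protein, position) site rows are summed per run at read
  time (peptides sharing a modified residue).
* A MinDet target column with no observed value raises an error; a kNN
  target with no eligible neighbour falls back to the row mean with a
  warning.
* In MNAR rows with a single observed value, that value is kept and
  only missing cells are imputed (observed data are never overwritten).
* p-values are clipped into (0, 1]; FC = 0 gives p = 0.5 exactly.
* Empty specificity evidence returns score 0, Fisher p 1, undefined
  avgFC.
* select_top uses floor rounding (pinned by 2% of 15,478 = 309) and
  deterministic identifier tie-breaks.
* Protein-to-network identifier mapping defaults to the identity
  (gene-symbol namespace); a user-supplied mapping table is accepted,
  since deposited quantification tables and network nodes rarely share
  a namespace out of the box.

## Known limitations

* Only two-group contrasts; no arbitrary design matrices or
  trend/robust variants of the variance moderation.
* The specificity score has no calibrated null distribution by design
  (post-selection product); interpret it as a ranking statistic.
* Connected components are a crude stand-in for density-based module
  mining on the induced subgraph.
* Per-comparison quantile normalization can differ from a single global
  normalization when missingness is extreme.
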