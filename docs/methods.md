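# Methods

## Scientific setting

Enteroviruses and rhinoviruses (EV/RV) express a single polyprotein cleaved
into capsid proteins VP1–VP4 and several non-structural proteins.  CE1 is a
consensus epitope inside VP1.  Pan-viral serology by phage-immunoprecipitation
sequencing yields, per individual and displayed peptide, an epitope binding
signal (EBS): a non-negative enrichment Z-score used as a relative measure of
antibody reactivity.  The package implements the computational chain that
links CE1-directed humoral immunity to hepatocellular-carcinoma (HCC)
outcomes and to a molecular-mimic tumor surface antigen (ASPH, aspartate
β-hydroxylase), and ships a synthetic-data module that generates every input
with the statistical structure those analyses assume.

## Catalog partition

Peptides are located on their source polyprotein by 1-based closed residue
intervals (the UniProt chain convention, used in every file this package
reads or writes).  A peptide is **CE1-VP1** when it shares at least
`min_ce1_overlap` residues (default 1) with the CE1 window of a VP1 chain,
**non-CE1 VP1** when it intersects VP1 but not the window, and **non-VP1**
otherwise.  A peptide spanning a chain boundary counts as VP1-intersecting if
at least one residue lies in VP1.  The assignment is a partition: every
peptide receives exactly one label, and the interval arithmetic is checked in
the test suite against a brute-force per-residue set-intersection oracle,
including every one-residue boundary case.

## Antibody repertoire breadth (ARB)

For one individual and one peptide group with S peptides, let
P_i = EBS_i / Σ_j EBS_j.  Then

    ARB = − Σ_i P_i ln P_i / ln S

the Shannon entropy of the reactivity distribution normalized by its maximum,
with 0·ln 0 := 0 by continuity.  ARB is 1 exactly when reactivity is uniform,
0 exactly when a single peptide carries all signal, and invariant to scaling
an individual's EBS vector — so cohorts with different assay depths compare
directly.  ARB is **undefined** (NaN, not 0) when the group's total signal is
zero or S < 2: an individual with no reactivity has no breadth, and ln 1 = 0
would divide by zero.  Downstream analyses drop undefined values and log the
count.  The binary indicator used for survival stratification is strictly
ARB > 0.5; the four default reporting categories are [0, 0.25],
(0.25, 0.5], (0.5, 0.75], (0.75, 1] (configurable edges).

CE1 seroreactivity is the arithmetic mean EBS over a panel of CE1 peptides,
default panel size 40.  Fixed-panel mode is the default (the panel is
supplied, as when it originates from prior work); data-driven mode selects
the k peptides with highest cohort-mean EBS, ties broken by lexicographic
peptide id.  Seropositivity is score > `seropositivity_threshold`; the
threshold defaults to 0 (any detectable panel reactivity) because no
published cutoff exists — it is a prominent configuration knob, not a claim.

## Association layer

All tests are two-sided; no multiplicity correction is applied by default
(a Benjamini–Hochberg utility is provided).  Standard fits delegate to
established implementations behind this module's interface:

* diagnosis logistic regression — `statsmodels` maximum likelihood; reports
  the odds ratio both per unit of the EBS summary and per sample standard
  deviation, since either scaling is defensible; non-convergence and
  (quasi-)separation are flagged on the result, never silently returned;
* group-mean comparison — Student t by default (Welch by option);
* contingency tables — Pearson chi-square without continuity correction,
  df = (r−1)(c−1), zero margins rejected;
* survival — Kaplan–Meier product-limit curves per stratum and the k-sample
  log-rank test with the standard hypergeometric variance for ties
  (`lifelines`); records with missing survival metadata are dropped from
  survival operations only, with logged counts;
* correlation — Spearman with mid-rank ties; the p-value uses the
  t-approximation, with exact permutation enumeration available for n ≤ 8.

## Mimicry screen

The funnel mirrors the IP-MS experiment: per protein, cell line and antibody,
the fold change is (target + c)/(control + c) with pseudocount c = 1.0
intensity unit (data-independent-acquisition intensities can be missing or
zero; the pseudocount makes the ratio defined and is configurable).
Enrichment is strict: FC > 100.  Within a cell line either antibody may carry
the call (`antibody_mode="any"`, matching enrichment "by one antibody or the
other"; "all" available); across cell lines the default demands enrichment in
every line.  Enriched proteins are intersected with a surface-proteome
membership list after case-folding and isoform-suffix stripping ("P12345-2" →
"P12345", configurable).

Candidates are aligned to the query epitope by an in-package Smith–Waterman
with BLOSUM62 and affine gaps: a gap of length k costs open + k·extend
(defaults 11 + k).  The traceback is deterministic (highest-scoring cell,
earliest on ties; move preference diagonal > up > left).  Each aligned column
is flagged identity / conserved (different residues, BLOSUM62 > 0) /
mismatch / gap.  The expect value is Karlin–Altschul,
E = K·m·n·exp(−λ·S), with standard gapped-BLOSUM62 constants K = 0.041,
λ = 0.267 and m, n the query and subject lengths — no database-size
correction, because the screen uses E only to rank a few dozen candidates,
not to assert absolute significance.  Ranking is ascending E, ties by
descending raw score, then lexicographic id.  Local alignment is the
appropriate flavor here: a 17-residue epitope against proteins hundreds of
residues long should report the short homology block, not a global
alignment.  The aligner is verified against two independent routes: a
matched-pair-chain dynamic program (O(n⁴), closed-form inter-pair gap costs —
structurally unlike the affine three-state recursion) on short pairs, and
Biopython's `PairwiseAligner` scores on longer pairs.

Dose–response competition readouts are summarized by two-way ANOVA
(condition × dose), Type-II sums of squares by default for robustness to
unbalanced designs.

## Transcriptome signatures

Expression (assumed log-scale) is Z-scored per gene **within each dataset**
(sample standard deviation, n−1) before integration, so cohorts profiled on
different platforms pool without platform dominance; zero-variance genes
become all-zero rows with a warning.  Antibody-dependent cellular
cytotoxicity (ADCC) activity is operationalized as the unweighted mean of the
within-dataset Z-scores of a fixed 20-gene signature (TNFRSF9, TNF, BCL2,
IL21R, BIRC3, IKZF2, CCR7, CD69, MKI67, CD226, CLEC2B, CXCR4, TIA1, TNFSF10,
GZMA, TLR6, TLR1, CD244, CD38, TLR3) — the minimal aggregation consistent
with a gene-list definition; the aggregator is replaceable.  NK-infiltration
scores arrive precomputed (e.g. xCell); tumors are NK-high iff score > 0.01
strictly — a score exactly at the cutoff is low, a convention this package
fixes and documents.  The ASPH-high/low survival split uses the within-cohort
median of normalized ASPH expression with ties assigned low, so the two
strata differ in size by at most one.

## Synthetic-data generator

The generator produces inputs whose encoded effects the pipeline can
recover; its defaults are the study conditions of the analyses it emulates.

**Serology cohort.**  The default catalog reproduces the published partition
sizes exactly — 59 CE1-VP1, 281 non-CE1 VP1, 1,671 non-VP1 peptides, 56-mer
tiles over five synthetic polyproteins with the canonical chain layout — by
construction: tile start positions are sampled only from coordinate ranges
consistent with the requested group.  The default cohort size is 1,917
individuals split 640/640/637 (healthy / chronic liver disease / HCC); the
real cohort's three-way composition is not public, so an even split is used.
EBS values are zero-inflated log-normal (log-mean 1.0, log-sd 1.0): a
per-individual responder type (broad with probability 0.6 for the CE1-VP1
block, 0.1 elsewhere) sets the per-peptide reactivity probability (0.8 broad,
0.08 restricted).  This yields the qualitative shape the analyses assume —
CE1-VP1 breadth right-shifted with most individuals above 0.5, other groups
left-skewed near zero.  Diagnosis is sampled from a logistic model in mean
CE1-VP1 EBS whose slope encodes the requested odds ratio and whose intercept
is solved numerically (Brent) to hit the requested HCC prevalence; class
counts are therefore targets in expectation, not exact, which is what makes
the odds ratio recoverable.  The healthy-group location shift is added to
nonzero CE1 signals *after* diagnosis sampling; with shift 0 the encoded OR
is exactly recoverable, with shift > 0 both mechanisms contribute to the
healthy-vs-HCC contrast.  Survival (HCC subjects) is exponential with
baseline hazard ln 2 / 730 d⁻¹ (median ≈ 2 years) multiplied by the hazard
ratio when the realized CE1-VP1 ARB is ≤ 0.5 or undefined; censoring is
independent exponential with rate μ = λ̄·c/(1−c) so the marginal censoring
probability is approximately the requested c.

**IP-MS tables.**  Control intensities are log-normal around 10⁵; target
intensity is control × fold change × log-normal noise (CV 0.1).  Background
fold changes are log-normal with median 2 (essentially never > 100 in both
cell lines); a 5% "sticky" background fraction is enriched everywhere,
emulating abundant non-surface binders so the surface filter has work to do;
10% of background proteins appear in the surface list.  Spiked mimics carry a
query-derived subsequence at a uniformly random internal offset, with
round(identity·L) residues identical and the rest substituted uniformly at
random, and always appear in the surface list.

**Expression cohort.**  Defaults mirror the 97-tumor integrative cohort
(48 seropositive, two datasets).  The target gene and a latent ADCC axis are
drawn per serostatus stratum from a Gaussian copula whose Pearson parameter
r = 2·sin(π·ρ_s/6) achieves the requested Spearman ρ_s; each signature gene
is the latent axis plus N(0, 0.5²) noise, and every gene receives
dataset-specific location/scale distortions so within-dataset Z-scoring is
actually exercised.  NK scores straddle the 0.01 cutoff with
stratum-specific high fractions.  Survival hazards implement a serostatus
benefit confined to one ASPH stratum, with the stratum computed by the same
within-dataset-Z median rule the analysis applies downstream.

**What the generator does not emulate:** raw reads or spectra, antibody
affinity maturation, isotypes, batch effects beyond affine per-dataset
distortion, correlated peptide cross-reactivity within a group, or
non-exponential survival.  Passing recovery tests therefore demonstrate that
the pipeline's estimators are correct and calibrated under the stated
generative models — not that real serology obeys those models.  The EBS
marginal family in particular is a modeling convenience, not a claim about
the data.

## Problem sizes and numerical choices

The test suite and acceptance script size their simulations to what the
estimators need rather than to the full published cohorts: odds-ratio
recovery uses 100–200 replicates at n = 2,000 with a reduced non-CE1 catalog
(the estimator never sees those columns); log-rank power uses ~1,050 HCC
subjects per replicate giving ≈ 500 per breadth arm; copula recovery uses
500 per stratum; null calibration uses 500–1,000 replicates at n = 200.
Entropy and Z-score computations are plain float64; the ARB uniform case is
exact to 1e−12.  Alignment scores are integers; traceback ties are broken
diagonal > up > left and the best cell is the earliest maximum in row-major
order, making every report reproducible.  Pipeline reruns under a fixed seed
are byte-identical for all result files; the run log (wall-clock times) is
the sole exception, and the machine-readable run report omits timings for
that reason.

## Known limitations

* The Karlin–Altschul constants are treated as fixed; for gap parameters far
  from (11, 1) they would need re-estimation.
* The logistic model reports both per-unit and per-SD odds ratios but fits a
  single linear term; dose–response nonlinearity is out of scope.
* Exact Spearman p-values are limited to n ≤ 8 by enumeration cost.
* The ADCC "activity" score is a stand-in aggregation over a published gene
  list; alternative aggregators (median, first principal component) can be
  supplied but are not defaults.
* Cox proportional-hazards modeling and competing risks are deliberately
  absent; the survival layer is the Kaplan–Meier / log-rank pair.
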