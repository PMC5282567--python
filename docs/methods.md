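# Methods

This note documents the statistical models, algorithmic definitions and
design choices behind `cernet`, in the spirit of the model documentation
shipped by packages such as statsmodels or msprime. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The synthetic study

The generator (`cernet.simulate`) emulates a pooled/grouped case-control
ncRNA study of skeletal muscle: three feature-by-sample matrices (miRNA
microarray signal; lncRNA and mRNA FPKM), sequences, loci, qPCR Ct tables,
and a serum biomarker with clinical covariates. Defaults are the study
scale the package is tested at: 20 cases vs 20 controls and 2000 features
(200 miRNA, 500 lncRNA, 1300 mRNA), 10% differentially expressed at
|log2FC| = 2 with log2-scale noise SD 0.5, and 50 planted ceRNA triads.
These sizes were chosen as what a practitioner would call a realistic
desk-scale version of such a study; they also keep every recovery test
comfortably fast.

### Expression model

For feature *i* and sample *s*,

    log2 x_is = b_i + d_i·1[s is case] + Σ_t a_it z_ts + ε_is,
    ε_is ~ N(0, noise_sd)

where `b_i` is a uniform baseline (log2 signal 9.5–13 for miRNA, log2 FPKM
5.5–9 for the sequencing classes — high enough that planted features clear
the abundance screens), `d_i = ±planted_log2fc` for DE features and 0
otherwise, and `z_ts ~ N(0,1)` is a latent factor shared by the members of
triad *t* with loading `+a` on the lncRNA and mRNA and `−a` on the miRNA
(`a = 0.3` by default). Values are `2**log2`, hence strictly positive.
Noise is log-normal rather than negative binomial because both value types
(array intensity, FPKM) are continuous.

Triad lncRNAs and mRNAs are drawn without replacement from the planted DE
sets, so `n_triads ≤ round(frac_de·n_lncrna)` and likewise for mRNA is
validated at construction; triad miRNAs may repeat across triads, matching
the many-targets-per-miRNA structure of real networks. The miRNA's planted
direction is always opposite to that of both partners.

Discovery-stage pooling can be emulated with `expression.pool_samples`,
which collapses each group to its mean pseudo-sample; per-sample matrices
remain available for validation-stage statistics, since which stages of a
real study used pooled material is usually not recoverable from the
publication.

### Sequences and planted seed sites

Mature miRNAs are random RNA 22-mers with pairwise-distinct seed regions
(nucleotides 2–8). Each planted (miRNA, target) edge receives at least one
exact 7mer-m8 (reverse complement of nucleotides 2–8) or 8mer (the same
followed by A) site at a random non-overlapping position; all other
(miRNA, target) combinations carry **no** 7mer-m8/8mer site. Weak sites
(6mer, 7mer-A1) may occur by chance in negatives and are tolerated — they
are not used as edge evidence.

Guaranteeing site absence needs care: with ~200 seeds and 400–600-nt
targets the expected number of chance strong sites per target is ~5–7, so
plain rejection sampling essentially never accepts. The generator therefore
plants the required sites and then *repairs* chance sites by point-mutating
one base inside each offending match (never inside a planted interval),
rescanning until clean, with bounded retries; an unrepairable target raises
`SiteConstraintError`. The recorded truth stores the site intervals actually
found by scanning the final sequence.

### Annotation, qPCR and clinical tables

Loci live on a pseudo-genome of 10 chromosomes × 10 Mb.
`round(cis_fraction · n_triads)` of the triad lncRNA–mRNA pairs are placed
on one chromosome with an interval gap uniform in [0, cis window]
(default window 100 kb); the remaining triad pairs are placed on distinct
chromosomes; everything else is uniform. BED intervals are 0-based
half-open.

Ct values follow `Ct = base_g + offset_s − d_g·1[case] + N(0, ct_noise_sd)`
per replicate (triplicates by default), where `d_g` is the planted signed
log2FC and `offset_s` a per-sample loading shift. Reference analogues (U6,
GAPDH, cel-miR-39) have `d_g = 0`. The per-sample offset cancels exactly in
ΔCt, which is why the 2^−ΔΔCT identities hold to machine precision in the
noise-free case.

The serum marker is binormal on a latent scale: N(0,1) in controls,
N(−Δ,1) in cases with `Δ = √2·Φ⁻¹(AUC)` so the planted AUC is hit exactly
in expectation (the marker is *reduced* in cases, like a repressed
circulating miRNA). Covariates use a single-factor Gaussian copula on the
marker's pooled-mixture CDF: the latent Pearson correlation is
`2·sin(π·ρ_s/6)` so the *Spearman* correlation equals the requested value
in expectation; marginals are then transformed monotonically to plausible
scales (lognormal lactate in mmol/L, probit-scaled severity score and
percent mutation load). Monotone transforms leave both AUC and rank
correlations untouched. Defaults plant ρ_s = −0.43 (lactate), −0.644
(severity), −0.709 (mutation load). The implied correlation matrix is
checked for positive semi-definiteness and rejected otherwise.

What the generator does **not** model: read- or probe-level measurement,
batch effects, library-composition bias, mtDNA heteroplasmy dynamics,
missing clinical data, cohort heterogeneity. Passing recovery tests
therefore demonstrates the pipeline's correctness under its own
assumptions, not robustness to every artefact of real data.

## Differential expression

Group means get a pseudocount of half the smallest positive matrix value
before the ratio, keeping fold changes finite and symmetric for zero-mean
features. The default test is Welch's *t* on log2 values when both groups
have ≥ 3 samples; otherwise Mann-Whitney U, exact (tie-aware enumeration of
all C(n₁+n₂, n₁) assignments, two-sided via the extremity of
min(U, n₁n₂−U)) when the smaller group has ≤ 8 samples and the
tie-corrected normal approximation above that. "Corrected p" is
Benjamini–Hochberg (Bonferroni switchable).

All comparison thresholds are strict (<, >) except the abundance floors,
which are ≥, and the floor applies to the *larger* group mean ("abundantly
expressed in either group"). The candidate screen also requires a
computable, nonzero p, which excludes degenerate all-tie features. The field
reports several mutually inconsistent screens for this kind of study; the
defaults here (|FC| > 2 with q < 0.05 for the DE screen; |log2FC| > 1.5,
p < 0.01, 30 copies / 500 signal for the candidate screen) follow the
thresholds that drive the published gene lists, and all four numbers are
config-exposed. Whether "30 copies" means FPKM or raw fragments is never
stated in practice; the filter applies it in the matrix's native units.

## Target prediction

Canonical seed sites only, on the given transcript strand, T mapped to U:
8mer = rc(2–8)+A, 7mer-m8 = rc(2–8), 7mer-A1 = rc(2–7)+A, 6mer = rc(2–7).
Overlapping candidates are reported at the strongest type only
(8mer > 7mer-m8 > 7mer-A1 > 6mer). G:U wobble pairs are not matches. Edge
evidence defaults to ≥ 1 site of type 7mer-m8 or better, with the count of
such sites as the score — weak-site-only pairs are deliberately not edges,
since chance 6mers are abundant. External database exports can be ingested
as TSV instead of (or in addition to) scanning.

cis pairing: same chromosome and interval gap ≤ window (0 for overlap),
strand ignored, gap = window still pairs; window default 100 kb. trans
pairing: |Pearson r| ≥ 0.9 across shared samples by default (Spearman
switchable); both cutoffs are conventional rather than canonical and are
config-exposed.

## Network assembly

"Inverse correlation" is operationalized as *opposite DE direction* — the
screen a pooled-discovery design can actually support — with an optional
sample-level gate (`require_r`) demanding Pearson r ≤ −threshold on the
per-sample profiles. Every emitted edge carries both endpoint directions
and is constructed to violate nothing: the edge type itself refuses equal
directions.

A triad (l, m, g) exists when miRNA m has an edge to lncRNA l and to mRNA
g; the sign constraint forces l and g to share a direction opposite to m.
The miRNA-centered network keeps miRNAs with ≥ 1 mRNA target and ≥ 1 lncRNA
partner; the lncRNA-centered network carries all triad edges plus direct
lncRNA–mRNA edges within a triad's (l, g) pair. Because one miRNA may
anchor several triads, the integrated triad count can legitimately exceed
the number of planted triads (the cross product of its partners). Venn
partitions compare {mRNAs targeted by DE miRNAs} vs {mRNAs paired with DE
lncRNAs} in the miRNA-centered summary, and {miRNAs pairing with lncRNAs}
vs {miRNAs targeting mRNAs} in the lncRNA-centered one. "Network focus" for
candidate nomination is membership in ≥ 1 triad plus degree rank
(`hub_nodes`, ties lexicographic).

Node identity is the feature id string; one id cannot carry two classes or
directions. Exports: GraphML with full node/edge attributes (round-trips
exactly through our own reader) and SIF with the relation token
`represses`.

## Enrichment

Upper-tail hypergeometric p computed in log space (gammaln + logsumexp),
exact against full enumeration for every N ≤ 12 argument combination. The
universe is the intersection of the expression matrix's genes with the
collection's genes (overridable); BH runs within each namespace (GO
division / pathway database), which is parsed from the term-id prefix
before the first ':' ("BP:T0001" → "BP", no prefix → "default"), since the
GMT format itself carries no namespace column. Terms smaller than 3 after
universe intersection are skipped. The rich factor is k/K over the
intersected universe — the fraction of a term recovered by the query —
which is the natural reading when the denominator is otherwise undefined.

## Biomarker statistics

2^−ΔΔCT with amplification efficiency fixed at 2; replicates are averaged
(arithmetic mean of Ct) before ΔCt, and replicate SD > 0.5 cycles sets a QC
flag rather than dropping the sample. ΔΔCt subtracts the calibrator group's
mean ΔCt, so the calibrator's mean rq is 1 by construction when computed on
group-mean ΔCt. Efficiency-corrected (Pfaffl) models are out of scope.

ROC: AUC = (concordant + 0.5·tied) / (n₁·n₂), computed via average ranks —
exactly the pair-counting definition. The curve is oriented so AUC ≥ 0.5
and the orientation (higher- or lower-in-case) is reported; thresholds sit
at midpoints between consecutive unique values with sentinels beyond both
extremes; the optimal cutoff maximizes Youden's J with ties broken toward
higher sensitivity, and is reported on the original measurement scale
(e.g. the rq scale for qPCR markers). Confidence intervals use the DeLong
placement-value variance with a normal approximation, truncated to [0, 1];
paired AUC comparison uses the DeLong covariance. A degenerate
zero-variance comparison (e.g. a marker against itself) reports ΔAUC = 0,
p = 1.

Correlations default to Spearman (clinical covariates are typically
skewed), i.e. Pearson on average ranks; p is an exact full-permutation
value for n ≤ 10 (enumerated in chunks; 10! ≈ 3.6M is the practical
ceiling) and the t approximation on n−2 df above that.

## Pipeline and reproducibility

One root seed drives everything; the simulator derives an independent
stream per output kind from (seed, stream-id), so stage skipping never
shifts another stage's randomness. All tables are UTF-8, tab-separated,
LF-terminated with headers; reruns of the same config+seed are
byte-identical, with wall-clock timestamps confined to `run.log` and the
`timestamps` field of `report.json`, which the comparison helper
(`pipeline.output_hashes`) canonicalizes away. The config hash covers every
semantic parameter and excludes the output location. `validate_outputs`
checks schemas (DETable invariants, GraphML parseability, enrichment
bounds, CI bracketing) and cross-file referential integrity (edge endpoints
exist in the DE tables, triad edges exist in the edge list), reporting
every violation.

## Known limitations

* Seed-site scanning is a stand-in for dedicated target databases; it
  implements canonical site taxonomy only — no context scores,
  conservation, thermodynamics or secondary structure.
* The anticorrelation filter's default gate is the DE screen; the stricter
  candidate gate is available but changes network size materially.
* DeLong CIs undercover for very small samples (< 10 per class); a seeded
  bootstrap is the usual remedy and the threshold table makes this easy to
  add downstream.
* The generator's group effect is homogeneous across DE features (one
  |log2FC| magnitude); effect-size spectra, correlated noise and batch
  structure are not modelled.
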