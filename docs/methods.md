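# Methods

## The measurement model

A fractionation experiment partitions a cell extract into compartments
(ribosome-free top of a sucrose gradient, 70S ribosomal fractions,
flotation-purified membranes, or the input/elution pair of a protein
pull-down) and sequences each next to the total extract. The quantity of
interest per gene is its **enrichment ratio**
`E(g) = RPKM_fraction(g) / RPKM_extract(g)`.

RPKM is computed for mRNAs only: rRNA-, tRNA- and other non-coding
loci-mapped reads are removed first and the per-library read total is
recomputed over the retained mRNA rows (a flag restores the all-mapped
denominator). Replicates are summed per fraction before RPKM, after a
pairwise Spearman consistency check (default ρ ≥ 0.9, configurable): the
ratio of pooled counts is the minimum-variance per-gene estimate and
matches how fraction libraries are usually combined. A gene enters a
landscape only if detected — RPKM at or above `min_rpkm` (default 1.0, a
conventional detection floor; no published threshold exists for this
kind of data) — in *both* the fraction and the reference; undetected
genes are dropped and reported, never imputed with pseudocounts, which
would manufacture ratios where there is no signal.

Because a fraction redistributes a fixed sequencing budget, RPKM ratios
are **compositional**: only enrichment relative to the pool average is
identifiable. The synthetic generator therefore closes its planted
multipliers (baseline·length-weighted mean 1 per fraction) so that a
planted multiplier *is* the true RPKM ratio. Practically this means a
"two-fold MPR effect" plants a two-fold MPR-vs-CPR contrast, with MPRs
at ≈2/c and CPRs at ≈1/c, c the weighted mean of the raw multipliers.

## Landscape statistics

Genes are ranked ascending by enrichment; the percentile of rank `r`
among `N` genes is `100·(r−½)/N`, ties broken by gene id so a landscape
is reproducible byte for byte. The class **quota curve** is a moving
average: windows of width 10 percentiles stepped by 1 (both
configurable; the width matches the decile summaries such plots usually
show), each reporting class members / genes in window, truncated at the
edges.

**Tail overrepresentation** asks whether a class is enriched among the
`K = round(f·N)` most (or least) enriched genes: `p = P(X ≥ k)` for
`X ~ Hypergeometric(N, n, K)`, evaluated by exact integer summation
(`math.comb`) rather than a floating recursion — the test-set sizes here
(hundreds to thousands) make this instantaneous and it is verifiable
against exhaustive subset enumeration. Multiple tails tested in one run
are corrected by Benjamini–Hochberg (via statsmodels). BH over the
performed tests is a deliberate choice: annotation-database tools
correct over an annotation universe that is not reconstructible from a
count table, so their corrected p-values are not comparable to ours.

Class-distribution comparisons use the Mann–Whitney U (midranks for
ties; exact null distribution when `n₁·n₂ ≤ 400` and tie-free, else the
tie-corrected normal approximation) and the two-sample
Kolmogorov–Smirnov test (exact when `n₁·n₂ ≤ 100`), both two-sided by
default — with no stated direction, a one-sided test would smuggle in a
conclusion. Both are scipy implementations; the exact Mann–Whitney p is
cross-checked against full permutation enumeration in the test suite.

**Binder groups**: from a pull-down (elution/input) landscape, weak
binders are the class members among the bottom 30% of all genes; strong
binders are the *same number* of class members taken from the top of the
binding-sorted list (an equal-sized contrast group); both are then
intersected with any supplied shared-detection gene sets.

## CSP-recognition motif scanning

Five element definitions, all on the DNA alphabet with U mapped to T,
scanned on the sense strand of coding sequences:

| rule | definition |
|------|------------|
| R1 | TTCTTTT |
| R2 | GTCTTTT or GTCTTTG |
| R3 | GTCTTTT, GTCTTTA, or the hexamer TTTTTT |
| R4 | 7-base T run with exactly one purine interruption at positions 2–5, G excluded at 3 |
| R5 | 7-base T run with at most one interruption at positions 2–6, G excluded at 3, purines excluded at 6 |

Two readings were genuinely open. R5's "interrupted at a single
position" is read as *at most* one interruption, so an uninterrupted U7
also counts — it is the limiting U-rich element; `cspe_rule(
require_interruption=True)` gives the strict reading. R4 requires
exactly one purine: a pure run there would be scored by R3's hexamer
instead. Second, overlapping raw windows of one rule are collapsed
greedily left-to-right into maximal sites, because a U-rich stretch of
length > 7 would otherwise be counted once per sliding window; raw
window counts are also reported (`collapse=False`,
`total_raw_windows`) since either convention is defensible for census
totals. Note one window can satisfy several rules (TTCTTTT is both R1
and a legal R5 window), so per-rule counts are not disjoint.

## qPCR quantification

Relative concentration fraction/extract is `2^(Ct_extract −
Ct_fraction)` (threshold cycle at 0.2 fluorescence units); the portion
of a transcript's molecules in a fraction scales this by RNA yields,
`portion = rel · m_fraction / m_extract`. When an endogenous control
(RnpB or SsrA) is measured, the transcript's relative concentration is
divided by the control's in the same fraction. Primer efficiency passes
QC when the dilution-series slope lies in [−3.6, −3] (perfect doubling
gives −log₂10 ≈ −3.322) with R² > 0.995.

## Clustering

Log2 condition/reference RPKM ratios are computed over genes detected in
every relevant library. K-means uses k-means++ initialisation with 20
restarts under Euclidean distance (scikit-learn), deterministic per
seed; ratios are left unstandardised by default since log2 ratios are
already commensurate (z-scoring available by flag). The Davies–Bouldin
index `DB = (1/K)·Σᵢ maxⱼ≠ᵢ (Sᵢ+Sⱼ)/Mᵢⱼ` (S: mean intra-cluster distance
to centroid, M: centroid separation) guides the choice of K; `select_k`
automates the usual manual inspection by taking the smallest local
minimum of the profile, returning the full profile for override.
Coincident centroids yield a +inf sentinel. Single-gene clusters are
merged into the nearest-centroid cluster (ties to the lower label,
logged), after which centroids and DB are recomputed.

## The synthetic-data generator

The generator emulates the study design the pipeline targets: triplicate
libraries per fraction; library size 5×10⁶ mapped reads; CDS lengths
log-normal with median 900 nt clipped to [100, 6000] (typical bacterial
CDS scale); per-gene baseline abundances log-normal (σ = 1); and a
per-fraction **rRNA load** — the share of reads consumed by non-mRNA
features, 0.85 in the extract, 0.95 in the 70S fraction, 0.90 on the
membrane, 0.15 at the ribosome-free top, 0.15/0.30 for pull-down
input/elution — reproducing the fact that mRNAs sequence far more
efficiently where ribosomes are absent. Counts are negative binomial
with mean `m` and variance `m + φm²`; φ defaults to 0.02, typical of
isogenic exponentially growing bacterial cultures, where per-gene
biological dispersions of 0.01–0.05 are the norm (Poisson at φ = 0).
Seeding uses one master seed with per-library substreams keyed by
(seed, stream, fraction index, replicate), so adding a library never
perturbs existing ones.

qPCR panels are generated by inverting the portion formula (extract Cts
uniform in [18, 24]; optional Gaussian Ct noise, default 0), making the
noise-free forward/inverse round trip exact by construction. Motif
fixtures place planted windows, separated by non-T flanks, into a
background that contains no TTT run — every built-in rule window
contains a T-run of ≥ 3, so such a background provably carries no
accidental matches — and each gene is additionally rejection-checked by
scanning. Truth is recorded per planted rule (cross-rule matches of a
planted window are real and expected).

What the generator does **not** emulate: positional read coverage,
GC/length bias, operon structure and co-transcription, partial
degradation, cross-fraction contamination, or genuinely heavy-tailed
abundance distributions. Passing tests therefore demonstrate that the
estimators recover what they define on well-behaved overdispersed count
data — not that a real fractionation experiment is free of the
systematic effects above.

## Validation problem sizes

The simulation benchmarks use 100 planted-effect simulations (100 MPRs
at a two-fold membrane effect, 500 null CPRs, 5×10⁶ reads, triplicates)
for recovery error and detection power, and 1000 null simulations
(50 MPRs / 100 CPRs, 2×10⁵ reads) for type-I calibration — sizes at
which the binomial error of the measured rates is a fraction of the
tolerances being checked. Enumeration cross-checks cover every
hypergeometric configuration with N ≤ 12, every Mann–Whitney group-size
pair up to 6, and 1000 random 200-nt T-rich sequences per motif rule.

## Known limitations

* The detection threshold defining "detected in all fractions" is a
  convention (RPKM ≥ 1); shared-gene-set sizes depend on it directly.
* Exact reproduction of any published landscape requires the original
  aligned count tables; the package consumes count tables and does not
  align reads.
* The hypergeometric tail test treats the tail cut as fixed
  (`K = round(f·N)`, boundary genes included by rank); it is a
  conditional test, not a scan statistic over cut choices.
* K-means with Euclidean distance assumes roughly isotropic clusters in
  log-ratio space; elongated or nested expression-response groups will
  be split or merged.
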