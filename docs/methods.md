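# Methods

## Problem setting

Ten published re-sequenced orang-utan genomes carried metadata — lab
identifier, studbook number, individual name, species, sex — that did
not all match the animals the DNA actually came from. `identikin`
re-implements, as a reusable and fully tested pipeline, the kind of
analysis that detects and corrects such switches: molecular sex and
species are inferred per sample, kinship to independently genotyped
relatives is compared with pedigree expectations, and identities are
assigned only where every available line of evidence concords.

## Sex inference

For a sample with idxstats-style counts, the statistic is the
length-normalized X:Y coverage ratio
`(mapped_X / len_X) / (mapped_Y / len_Y)`. Under perfect mapping a male
(X and Y each haploid) sits near 1 and a female near `1/mismap_rate`
(her only Y-mapped reads are mismapped autosomal/X reads), so the two
sexes separate by well over an order of magnitude at any realistic
mismapping rate. Because the absolute scale depends on aligner, Y
assembly completeness and normalization convention — published ranges
for this statistic (males 0.369–0.569, females 4.114–5.827) are not
length-normalized in any way we can reconstruct — thresholds are never
hard-coded: `calibrate_thresholds` takes known-sex individuals, widens
the male maximum and shrinks the female minimum by a margin (default
0.25), and refuses to calibrate if the widened bands overlap. Ratios
between the bands are `undetermined`, which the resolver treats as
matching either sex. Ties at a threshold resolve toward the labeled
side.

## Ancestry

Genotype dosages follow the binomial admixture likelihood
`g_im ~ Bin(2, p_im)`, `p_im = Σ_k q_ik f_km`.

* `supervised_q` maximizes over `q` on the simplex with `F` **given**,
  via the standard EM update; the log-likelihood is non-decreasing by
  construction and the tests assert it.
* `supervised_admixture` is the estimator the pipeline uses: panel rows
  have `q` pinned to their labeled population and `F` is re-estimated
  each iteration from panel *and* unlabeled samples. With small
  reference panels this matters: at the default divergence (Fst 0.1)
  and nine diploids per population, the noise variance of a plug-in
  frequency estimate (`p(1−p)/18`) is comparable to the
  between-population drift variance (`Fst·p(1−p)`), and maximizing the
  likelihood against fixed noisy frequencies leaks 0.1–0.2 of ancestry
  mass into the wrong components no matter how many SNPs are used. The
  joint fit averages that noise over all genotyped samples and brings
  the error down to a few percent. All samples to be analyzed (queries
  and relatives) are fit together for the same reason.
* `unsupervised_admixture` block-relaxes `q` and `f` updates (used by
  cross-validation); component labels are unidentifiable, so recovery
  tests compare up to permutation.
* `cv_error` masks random genotype *cells* (not samples), refits on the
  unmasked cells, and scores masked cells by squared deviation between
  dosage and its fitted expectation `2Σ q f` — a deliberate,
  documented simplification of a held-out deviance. "Bootstrapping" the
  procedure means repeating it over re-randomized fold assignments and
  reporting mean ± SD.
* `classify_species` calls the majority population when its proportion
  reaches `major_min` (default 0.85) and "admixed" otherwise; an
  admixed call excludes all purebred registry candidates, which is a
  flag, not an error.

### Variant filtering and LD pruning

`filter_variants` keeps biallelic autosomal SNPs with complete calls
and minor-allele frequency ≥ 5 % (inclusive). `ld_prune` mirrors the
greedy sliding-window algorithm behind `--indep-pairwise 50 10 0.1`:
windows of 50 SNPs advancing by 10 within each chromosome; while any
retained pair in a window exceeds r² = 0.1 (squared correlation of
mean-centred dosages — composite LD, appropriate for unphased data),
the lower-MAF member is removed, ties dropping the later coordinate.
The invariant is anchored to the sweep's own windows: re-scanning the
output with that geometry (`max_window_r2`) finds no offending pair.

Two consequences of these pinned parameters shaped the pipeline:

* **Statistics on the panel only.** The pipeline computes pruning r²
  and MAF on the reference panel and applies the retained SNP set to
  everyone. Pruning on the pooled matrix conditions SNP retention on
  the query genotypes themselves and measurably distorts their ancestry
  fits.
* **Aggressive chance pruning.** With 27 panel samples, an independent
  SNP pair exceeds r² = 0.1 by chance ~11 % of the time, so most SNPs
  in a dense window are removed even without real LD. The default
  synthetic scenario therefore generates 40,000 raw SNPs (35,000
  sampled after the MAF filter) so that roughly 5,000 reach the model —
  enough for kinship standard errors near 0.01 and ancestry errors of a
  few percent, while keeping a full scenario analysis near ten seconds
  on one CPU.

### Microarray probe QC

`filter_probes` applies the cluster-geometry rules as *exclusion*
criteria — a probe is kept only if none fires (dim intensities, poor
cluster separation, misplaced or over-dispersed theta clusters, low
GenTrain score). The source protocol lists the thresholds without
stating their direction; the exclusion reading is implemented because
each threshold describes pathological cluster geometry, and the choice
is surfaced here rather than asserted as the only possible intent. The
condition "het theta < 0.3 and > 0.7" is read as exclusion when the
heterozygote theta lies outside [0.3, 0.7].

## Kinship

`individual_freqs` builds μ_im = Σ_k q_ik f_km (clamped to
[1e−6, 1−1e−6]); `kinship_phi` is the individual-specific-frequency
moment estimator given in the README. Its properties under correct μ:
self-kinship 0.5, unrelated pairs centred at 0 even across populations,
parent–offspring at 0.25. When μ is estimated from the same data the
estimate deflates by roughly 1/(2n_eff) — the published observed
coefficients show the same deflation (e.g. 0.162 and 0.19 against an
expectation of 0.25) — which is why confirmation uses a tolerance
rather than equality.

`ibd_deltas` fits (δ₀, δ₁, δ₂) by least squares of the observed 3×3
joint-genotype table against per-state expected tables (shared allele at
the pair-mean frequency, private alleles at each individual's own — a
documented approximation), constrained to the probability simplex. The
QP is solved exactly by active-set enumeration over the three supports;
degenerate (collinear) state tables are rejected. At 10⁴ SNPs the
estimator has a per-pair δ₀ standard error of a few hundredths, and
because the truth for close relatives lies on the simplex boundary the
mean of repeated estimates sits slightly inside it (≈0.02); calibration
checks therefore compare means against a 0.05 tolerance.

Pedigree expectations are computed two independent ways: the classical
recursion φ(a,a) = (1+φ(sire,dam))/2, φ(a,b) = (φ(sire_a,b)+φ(dam_a,b))/2
(founders unrelated and non-inbred, memoized), and exact
inheritance-vector enumeration for (δ₀, δ₁, δ₂) — every
parent-to-child transmission is a fair coin; all 2^T vectors are
enumerated for T ≤ 20 transmissions with a seeded vectorized Monte
Carlo fallback (500,000 draws) beyond that. The identity
φ = δ₁/4 + δ₂/2 ties the two routes together and is asserted exactly.
Inbred endpoints are rejected: only the nine condensed identity states
would be exact there, and they are out of scope.

## Identity resolution

Three channels per sample: the **exclusion set** (registry individuals
matching inferred sex — undetermined matches both — and inferred
species, with "admixed" matching none); **kinship confirmation** (a
candidate is supported when a hit links the sample to one of its known
relatives with Φ̂ > floor and |Φ̂ − Φ_exp| ≤ τ; support for more than
one candidate is ambiguous and confirms none); and the optional
**records candidate**. Defaults τ = 0.1 and floor = 0.02: τ must
exceed the deflation observed in real confirmed links (up to 0.089)
while staying below the 0.125 gap between first- and second-degree
expectations, and the floor sits several standard errors above the
unrelated-pair noise at the default SNP counts. One passing hit
suffices provided no passing hit supports a different candidate — how
the original analysts weighed a failing hit against passing ones for
the same candidate is not recorded, so this is a documented choice.

Channels are intersected per sample (any disagreement → `conflict`);
singleton intersections are assigned with propagation; remaining samples
go through bipartite matching where only *forced* edges — pairings
present in every maximum matching, detected by edge-removal — are
assigned. Anything the matching could permute is genuinely ambiguous
and stays `unresolved`; no sample is ever force-assigned. A corrected
lab id comes from the records channel, which can also mark a reported
id as invalidated (distinct from being silent). The discrepancy summary
counts relabelled samples (individual or lab id changed), misattributed
samples (individual changed) and reported names whose reported sex
contradicts the registry.

## Synthetic scenarios

`make_scenario` emulates the study design: three populations under the
Balding–Nichols model (frequencies Beta-drifted around shared ancestral
values; divergence parameter 0.1 by default, chosen to give clean
three-way separation at the default SNP counts while remaining a
non-trivial test of the ancestry adjustment — the true divergence
between the real lineages is not a quantity this artifact models); a
27-sample labelled panel; ten query individuals matching the study's
species/sex mix (five Bornean, four Sumatran, one Tapanuli analogue;
five of each sex); eight relatives gene-dropped on template pedigrees
matching the study's relationship degrees (a shared child of two
queries, children, grandchildren, a great-grandchild; the Tapanuli
query's descendants have a Sumatran mate line, mirroring the captive
hybrids); Poisson per-chromosome read counts (5× depth, 1 % Y
mismapping, great-ape-like chromosome lengths — all configurable); and
a reported-metadata table that differs from the truth by exactly the
planted permutation (default: a single nine-cycle, so nine of ten
labels are wrong). Queries without genotyped relatives receive a
records-channel candidate, as in the study, where three samples were
assigned on records concordance alone.

All randomness derives from one scenario seed through named substreams,
so stages are independently reproducible and a scenario is byte-stable
under its seed.

What the generator deliberately does **not** emulate: read-level data
and sequencing error (counts and genotypes are drawn at the model
level), linkage (SNPs are independent by construction; LD pruning is
exercised on synthetic duplicated-SNP blocks via `add_ld_duplicates`),
genotyping error and missingness in the relatives' array data, and
pedigree founders of mixed ancestry (founders are purebred unless
configured otherwise). Passing end-to-end tests therefore demonstrates
the logic and calibration of the pipeline under its stated model, not
robustness to every artifact of real sequencing data.

## Numerical choices

Frequencies are clamped to [1e−6, 1−1e−6] everywhere a likelihood is
evaluated; panel frequency estimates carry a half-count pseudocount
`(alt+0.5)/(2n+1)`. EM stops when the log-likelihood improves by less
than `tol` (pipeline default 1e−5, max 2000 iterations — plain EM, as
accelerated update schemes are out of scope). Pruning tie-breaks
(lower MAF first, then later coordinate) and the resolver's
lexicographic processing order make every run deterministic.
Zero-variance SNP columns have undefined correlation and are treated as
uncorrelated. A zero Y count yields an infinite X:Y ratio, handled as
"strongly female" and excluded from threshold calibration minima.

## Problem sizes used in the shipped tests

Unit tests run at hundreds-to-thousands of SNPs; calibration checks use
20 replicate families at 10⁴ SNPs with correct μ (SNPs retained by
population MAF, so retention does not condition on the genotypes under
test); ancestry recovery uses 5 seeds at 10⁴ SNPs; cross-validation
model-order checks use 30 samples × 2000 SNPs with 10 fold
randomizations; end-to-end recovery uses 20 seeded default scenarios.
These sizes keep the full suite within a few minutes on a single CPU
while leaving every statistical margin comfortably wide of its
threshold.

## Known limitations

* The resolver is rule-based with flags, not a probabilistic identity
  posterior; it will leave truly ambiguous cases unresolved rather than
  rank them.
* Kinship requires complete cases over the shared SNP set; per-pair
  missingness handling is limited to recording `n_snps`.
* Inbred pairs, X-linked kinship and pedigree reconstruction are out of
  scope.
* The Φ̂ deflation under jointly estimated frequencies is absorbed by
  the confirmation tolerance rather than corrected; a leave-pair-out
  frequency scheme would remove it at some complexity cost.
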