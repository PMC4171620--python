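# Methods

## Statistical model

The quantity under test is the over-representation of regulatory
annotations among top GWAS SNPs, measured in independent LD blocks. The
pipeline for any SNP set S is

    S → [optional one-hop LD expansion, r² ≥ 0.5]
      → annotation filter (eSNP: cis-eQTL with q < 0.2; tSNP: class C1 or C2)
      → block count: connected components under pairwise r² ≥ 0.5.

The observed statistic applies this to the top associated SNPs; the null
distribution applies it to N = 1000 (default) null sets built by either
MAF-matched randomization or phenotype permutation. The empirical p is the
add-one right-tail estimator (1 + #{null ≥ obs}) / (N + 1). We chose the
add-one form because it is the standard bias-corrected permutation
estimator, never returns zero, and renders the 1000-iteration minimum as
"< 0.001"; with ties counted toward the tail it is conservative. Reported
"expected blocks" is the null mean and the s.d. is the sample standard
deviation (N − 1 denominator). p-values are reported per analysis without
multiplicity adjustment across modes/populations; users comparing many
catalog/population combinations should adjust externally.

### Association scan

Per SNP, the allelic Pearson χ² with 1 df on the 2×2 allele-count table
(each sample contributes two alleles; dosage k gives k minor + (2−k) major),
no continuity correction, complete-case per marker. This is the classic
single-SNP case/control test and, being a closed-form table statistic, is
cheap enough to re-run inside every permutation. It is a strategy point: any
per-SNP p-value function could replace it (e.g. a Cochran–Armitage trend
test), and results on real data will track whatever scan produced the
original study's p-values. Top-SNP selection uses strict inequality
(p < threshold). Monomorphic or all-missing-in-a-group SNPs are flagged
degenerate (χ² = 0, p = 1) and can never enter a top set at any threshold
below 1.

### LD conventions

* r² is the squared Pearson correlation of genotype dosages over
  pairwise-complete samples (composite LD): phase-free, computable from any
  genotype matrix, standard GWAS practice. Monomorphic columns have
  undefined r², returned as "unknown".
* Unknown pairs (unlisted in an LD table, beyond the distance window,
  different chromosomes, undefined) are treated as r² = 0 everywhere — the
  only convention under which table-backed and genotype-backed sources
  satisfy one contract.
* Block partition rule: **single linkage** (connected components of the
  r² ≥ 0.5 graph) by default. A mutual "any two members linked" reading
  would be a clique cover, which is NP-hard and order-dependent in greedy
  form; single linkage is deterministic, permutation-invariant, and merges
  more aggressively, giving fewer blocks on both the observed and null side
  of the test. A greedy-clique alternative (sorted-order first-fit) is
  provided behind the same interface for sensitivity analysis; the rule
  used is recorded in the partition object.
* LD expansion is one hop, inclusive at r² ≥ 0.5: proxies of proxies are
  not added. Applying expansion twice can therefore grow the set further;
  the pipeline never does.
* Genotype-backed r² uses a 250 kb distance window by default (the
  convention of HapMap pairwise-LD files), configurable.

### Null constructions

Randomization: the observed set's 10-bin MAF histogram (bins
[0, 0.05) … [0.45, 0.50], top bin closed) is reproduced exactly by every
null set, drawn uniformly without replacement within bins; draws are
independent across iterations. Infeasible demand in a bin raises an error
naming the bin. For SNP lists without genotypes (catalog-replication runs)
this is the only applicable null, and list SNPs absent from the supplied
panel are dropped before binning.

Permutation: labels are permuted uniformly at random with case/control
counts preserved exactly; each iteration re-runs scan → top-SNP selection →
expansion → annotation → block count. Iteration i's RNG stream is derived
from (seed, i), so iterations are order-independent and could be evaluated
in parallel with bitwise-identical results.

## Synthetic studies

The generator stands in for the real inputs of such analyses (GWAS
genotypes, platform SNP panels, eQTL and TFBS catalogs, HapMap-style LD
tables), which are controlled-access or versioned external resources. It
emulates the features the method is sensitive to and nothing more:

* **LD structure**: block-diagonal. Within a block every SNP shares one
  population MAF and copies a per-haplotype latent ancestor allele with
  probability c = within_block_r2^(1/4) (else draws fresh), giving expected
  pairwise genotype r² = c⁴ = within_block_r2 inside blocks and exactly 0
  between. Real LD decays continuously; blocks suffice to exercise every
  LD-dependent code path while keeping block-count ground truth exact, so
  passing tests validate the machinery, not the realism of human LD decay.
* **Phenotype**: logistic in the causal dosages (first SNP of each causal
  block) with slope ln(OR); the intercept is centred at the mean causal
  dosage so prevalence ≈ 50%, making retrospective rejection sampling
  efficient. Sampling is bounded (default 200 batches) and raises on
  infeasible configs. Real cohorts have low prevalence and ascertainment
  structure; only the case/control allele-frequency contrast matters here.
* **Catalogs**: planted eSNPs get cis entries with q ~ U[0, 0.2) — strictly
  inside the filter so planted truth and filter output coincide exactly —
  plus decoy cis entries (q ~ U[0.2, 1]) and decoy trans entries at the base
  rate, which must be rejected by the q and cis filters. Planted tSNP
  categories are drawn with class 1 ≈ 40% of mass, 95% of it in 1f
  (mirroring the dominance of eQTL-backed evidence in real regulatory
  catalogs), and class 2 split evenly over 2a–2c.
* **Missingness**: none is generated; missing-data handling is exercised by
  hand-built fixtures in the I/O and association tests.

Defaults (1000+1000 samples, 100 blocks × 5 SNPs, within-block r² 0.8, MAF
~ U(0.05, 0.5), 20 causal blocks at OR 2, base annotation rates 0.05,
enrichment factor 5) describe a study where the planted signal is
detectable but not trivial; the calibration analyses set OR = 1 and
enrichment factor 1 with 300+300 samples.

One RNG is seeded per study and consumed in documented order, so identical
config + seed reproduce byte-identical fixture files. The emitted panel
records the *realized* sample MAF with the minor allele re-oriented from
the data (ties at 0.5 broken lexicographically), using the same integer
allele arithmetic as the PLINK-text reader — this makes write → read round
trips exact, which the tests assert field-for-field across 50 seeds.

## Numerical and formatting choices

* Genotype codes are int8 with −1 as the missing sentinel, never conflated
  with zero dosage. Phenotypes follow PLINK text coding (1 = control,
  2 = case).
* Monomorphic SNPs read from PLINK text get minor allele "0" (unobserved),
  MAF 0, all dosages 0.
* Duplicate LD pairs keep the maximum r² (the inclusive choice for
  expansion) with a logged warning; pairs are stored canonically
  (lexicographic), lookups are symmetric.
* Floats are written in shortest round-trip decimal form and parsed with
  Python float parsing, so TSV round trips are bit-exact.
* Analysis scripts and acceptance runs use p < 0.01 for top-SNP selection
  on the 500-SNP synthetic panels. The moderate cutoff used on ~5·10⁵-SNP
  platforms (10⁻³) would leave a 500-SNP null scan with an expected top-set
  size of 0.5, collapsing the null block-count distribution to zero; 0.01
  is the scaled analog that keeps the statistic non-degenerate. The cutoff
  is a free parameter of the method, not of the implementation.
* Problem sizes in the test-suite and acceptance analyses (20–50 replicate
  studies, 200 permutations each, 300–2000 samples) are chosen so the whole
  battery runs in minutes on one core while leaving the binomial tolerances
  of each check meaningful; the statistical conclusions they support are
  stated with those n's attached.

## Known limitations

* Counting semantics ("single linkage" vs strict clique) change absolute
  block counts; comparisons should fix one rule, as the default does.
* The randomization and permutation tests answer subtly different
  questions (platform-wide frequency-matched resampling vs label
  exchangeability); the package's own analyses show the former's null mean
  exceeding the latter's under strong LD, so a non-significant
  randomization result alone is weak evidence of absence.
* trans-eQTL analysis is supported via `cis_only=False` but untested as an
  analysis path: trans signals are typically too sparse for a stable
  block-count null.
* No covariate adjustment, genomic control, or imputation; the scan is a
  pure allelic test. Real-data p-values will differ from any published
  scan that used a different statistic or QC.
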