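# Methods

This note documents the statistical procedures implemented in `rohscan`,
the conventions chosen where the field's tools disagree, and what the
synthetic-data tests do and do not demonstrate.

## Input model

The unit of analysis is a genotype panel: an ordered table of autosomal
biallelic SNP sites and a dense matrix of per-individual genotype codes
(0 hom-ref, 1 het, 2 hom-alt, −1 missing). Panels are read from VCF v4.x
(GT required; phased and unphased calls are equivalent; gzip accepted) and
written back losslessly. Chromosome labels are normalized by stripping a
leading `chr`. Multi-allelic and non-SNP records are dropped at ingestion.

## Site quality control

Filters run in a fixed order — biallelic (structural), autosome, site
quality, missingness, MAF, HWE — and each removed site is counted at its
first failure, making the report additive: input = retained + Σ removed.
Comparisons follow the usual phrasing of population filters: MAF > 0.05,
missing rate < 0.1 and HWE p > 10⁻⁶ are strict, so a site exactly at a
threshold is removed; quality ≥ 20 is inclusive and skipped for sites
without a quality value.

The HWE test is the exact conditional (Levene) test: given the observed
allele counts, the heterozygote count h has probability proportional to
2^h · n! / (n_AA! n_Aa! n_aa!), and the two-sided p-value sums the
probabilities of all configurations no more probable than the observed one.
Probabilities are computed with log-gamma accumulation and normalized by the
modal configuration; ties are admitted with a 1+10⁻¹² relative tolerance.
A chi-square (1 df) alternative is available via `hwe_method="chisq"`.
A read-time option masks genotype calls with FORMAT DP at or below a depth
threshold (default off), since some call sets apply a per-genotype depth
requirement upstream. Statistical imputation is out of scope; an optional
naive modal-genotype imputation flag exists for parity experiments only, and
the ROH scan's missing-call budget makes it unnecessary.

## Diversity statistics

Per-site nucleotide diversity uses the without-replacement estimator
π = n/(n−1)(1 − Σ xᵢ²) over the two allele frequencies, with n the
non-missing allele copies; it equals the mean pairwise difference over all
pairs of observed allele copies, which is the oracle the tests enumerate.
MAF, π and Hₒ are undefined (NaN, flagged) when no calls remain; aggregate
means are taken over defined values only.

The relatedness matrix is the GCTA estimator with allele frequencies taken
from the analyzed panel itself and pairwise-complete site counts N (missing
genotypes drop out of p̂ per site and of N per pair). Monomorphic sites are
excluded. One structural consequence is worth stating: because the centered
dosages use sample frequencies, Σⱼ (x_ij − 2p̂ᵢ) = 0 at every site, which
forces the per-site sum of off-diagonal products to equal minus the sum of
squares. The mean off-diagonal entry among n unrelated individuals is
therefore not 0 but approximately −1/(n−1) (≈ −0.0204 at n = 50), a known
small-sample property of sample-frequency GRMs rather than an implementation
artifact; the diagonal remains centered on 1. The measured values on
simulated independent individuals reproduce this to three decimals.

## ROH detection

The scan is the window-based method of PLINK `--homozyg` and detectRUNS,
with all parameters explicit in `ROHParams`:

| parameter | default | meaning |
|---|---|---|
| window_size | 50 SNPs | sliding-window width |
| max_het_in_window | 1 | heterozygous calls allowed per window |
| max_missing_in_window | 5 | missing calls allowed per window |
| window_pass_threshold | 0.05 | min fraction of homozygous covering windows (≥, inclusive) |
| min_snp_in_run | 100 | SNPs required per run |
| min_length_bp | 500 kb | minimum run span |
| max_kb_per_snp | 50 | density bound (≥ 1 SNP / 50 kb) |
| max_gap_bp | 100 kb | max distance between consecutive run SNPs |

Conventions: the pass proportion is inclusive (a SNP passes at exactly the
threshold), implemented with a 10⁻⁹ epsilon so that exact rational ties like
1/20 vs 0.05 compare as equal in floating point; the brute-force enumeration
oracle in the tests shares only this final comparison convention. Run length
is end − start + 1 (inclusive). Gap splitting applies between consecutive
flagged SNPs, not inside windows. Missing calls count toward a run's SNP
total (they occupy positions) but never as heterozygotes.

Edge handling is configurable because the field's tools differ and the
choice changes flags near chromosome ends: `shrink` (default, the
detectRUNS convention) divides by the actual number of covering windows,
which shrinks from `window_size` to 1 at the first/last SNP; `skip` keeps
the full-window denominator, making edge SNPs strictly harder to flag. A
chromosome with fewer SNPs than one window is scanned as a single truncated
window (denominator 1 under `shrink`, `window_size` under `skip`).

## Summaries and F_ROH

Length classes are left-closed bins over [0.5, 1), [1, 2), [2, 5), [5, ∞)
Mb by default; display percentages round half away from zero while exact
fractions are retained. F_ROH divides an individual's total ROH length by
the summed autosome lengths of a user-supplied genome table (FAI
accepted). The denominator is genuinely ambiguous in practice — reports
rarely state whether it is the full autosome length or the SNP-covered
span — so both are implemented (`denominator="genome"` default,
`"snp_span"` alternative); with dense SNP coverage they differ by well
under a percentage point of F.

## Islands

Per-SNP incidence counts distinct individuals with at least one covering
segment, so overlapping segments of one animal count once. Significance is
strict (> 0.30): with 30 animals, at least 10 must share the site.
Published region lists seldom state how significant SNPs were grouped into
regions; the clustering here is a transparent gap rule (consecutive
significant SNPs ≤ 250 kb apart, configurable), island bounds are the
outermost significant SNPs, and the incidence track is always exportable so
any other grouping can be applied downstream. Gap clustering cannot, for
example, reproduce a published split between two regions 67 bp apart —
whatever criterion produced such a split, it was not a gap rule, and we do
not guess it. Region length in kb is round-half-away((end − start + 1)/1000).

## Synthetic panels

The generator draws, per site, a position uniform on the chromosome, an
alternate-allele frequency uniform on [0.05, 0.5], and background genotypes
from Hardy–Weinberg proportions independently per individual. Autozygous
tracts are planted per individual either explicitly or to a target genome
fraction F: tract lengths are sampled from a mixture over the 0.5–1 / 1–2 /
2–5 / 5–10 Mb classes with weights 0.737 / 0.222 / 0.040 / 0.001 —
matching the length spectrum of a lightly inbred cattle population, where
roughly three quarters of ROH are sub-megabase — and the last tract absorbs
the remainder so the planted total meets F exactly. Within a tract both
allele copies descend from one Bernoulli(p) draw per site (the
population-genetic meaning of autozygosity), optionally flipped to a
heterozygous call with a tract-error probability; missingness is applied
last, uniformly. All randomness flows from the single seed and panels are
byte-reproducible.

Deliberate simplifications: sites carry no linkage disequilibrium, allele
frequencies have no site-class structure, missingness is uncorrelated, and
tract boundaries are independent of SNP positions. Consequently the
recovery tests demonstrate the detector's window logic, boundary behavior
and parameter filters — not robustness to LD-induced background
homozygosity, which in real data produces short chance runs and motivates
the 100-SNP/500-kb minima in the first place.

The recovery preset used by the tests and the acceptance script is 10
individuals × 2 chromosomes of 50 Mb × 10,000 SNPs each (5 kb mean
spacing), tracts of 1–5 Mb, planted F from 2% to 16%, zero error. At that
density a 1 Mb tract holds ≈ 200 SNPs, comfortably above the run minima;
measured per-individual recall and precision exceed 0.95 (flag extension a
few SNPs past tract boundaries costs ~1–2% precision) and per-individual
|F_ROH − F_planted| stays below 0.003. The population-scale scenario in the
acceptance script (30 individuals × 20,000 SNPs) keeps runtimes in seconds
while exercising every stage at realistic per-animal autozygosity.

## Numerical and degenerate-input choices

Undefined ratios are NaN and flagged, never silently zero: precision with
no detections, recall with no truth, MAF with no calls, island percentages
of an empty segment list. An all-sites-removed filter pass warns and
returns an empty panel rather than raising. Duplicate (chrom, pos) records,
sample-less VCFs and tracts outside their chromosome are errors. Segment
tables are deterministic byte-for-byte given identical input.
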