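# Methods

## Scope and model

The package operates downstream of genotype calling: its inputs are a
biallelic SNP matrix (minimal GT-only VCF), a group assignment (popmap), and
a soft-masked reference (FASTA). Read QC, alignment and the genotype caller
are out of scope; so is Bayesian admixture estimation — the hybrid-index
module provides the monitoring function that an admixture analysis serves,
with a simpler, panel-specific model.

### Diagnostic screen

A site is diagnostic for species A vs B when the two species are fixed for
alternate alleles. The screen applies, in order:

1. **Fixed difference.** Every called individual of species A homozygous for
   one allele, every called individual of species B homozygous for the
   other. Both groups must reach a per-group call rate of `min_call_rate`
   (default 0.85, mirroring an upstream 85%-presence filter). The strict
   reading — any missing call disqualifies the site — is available as
   `require_no_missing=True`; the default evaluates "each individual" over
   called genotypes, because genotype matrices that have already passed an
   85%-presence filter still contain missing calls and discarding every such
   site would conflate missingness with polymorphism.
2. **Obligate heterozygosity.** Every called individual of each hybrid group
   heterozygous (Hobs = 1 over called individuals), same call-rate gate,
   applied per hybrid group.
3. **Clean flanks.** For a site at 1-based P with flank length L (default
   40 bp): reference bases [P−L, P−1] and [P+1, P+L] must exist (no contig
   edge), contain only uppercase A/C/G/T — lowercase (soft-masked) and N
   bases are read as repetitive sequence, the standard genome-assembly
   convention and the only machine-checkable reading of a "no repeats"
   criterion — and contain no other site of the supplied variant list. The
   neighbour window is the closed interval [P−L, P+L]: a second variant at
   distance exactly L rejects the site, at L+1 it does not. "Other sites"
   means the full filtered discovery set, not just diagnostic candidates:
   any known variant under a probe arm compromises assay design. The
   uppercase reference base at P must equal the site's ref allele; a
   mismatch indicates coordinate slippage between VCF and reference and
   rejects the site with a warning.

Each stage returns a subset of its input, so survivor counts are
non-increasing along the cascade and are logged.

### Screening statistics

Per site and group, over called genotypes only: sample allele frequencies,
call rate, Hobs (fraction heterozygous), Hexp = 2pq at the sample frequency,
and F_IS = (Hexp − Hobs)/Hexp with the convention F_IS = 0 when Hexp = 0.
This estimator is algebraically confined to [−1, 1]: given het fraction h,
the sample frequencies satisfy pq ≥ (h/2)(1 − h/2), so Hobs/Hexp ≤
1/(1 − h/2) ≤ 2. No small-sample (2n/(2n−1)) correction is applied to Hexp;
the plain 2pq estimator is the common textbook form, and the choice is
documented because π-based estimators (as in STACKS) differ by O(1/n) — at
n = 6–7 individuals the uncorrected sample F_IS is biased by about
−1/(2n−1) ≈ −0.08 relative to the population value, which matters when
interpreting group means (see the generator notes below). Groups with zero
called individuals carry NaN, never silent zeros; groups with one called
individual are flagged `low_confidence` but still computed.

Retention filters mirror a `populations` run with `-p 4 -r 0.85
--min_maf 0.1`: keep a site when at least `min_populations` groups reach
call rate `min_fraction_per_pop` and the pooled MAF (over all called alleles
across every group) reaches `min_maf`. MAF pooling is a documented choice —
some STACKS versions apply `min_maf` per population with retain-if-any
semantics — and per-group frequencies are reported alongside so either
convention can be audited. Tightening any threshold can only remove sites
(monotonicity), which the tests assert.

An allele (ref or alt) is **private** to group g when its count is positive
in g and zero in every other group, over called genotypes. Both the
in-group frequency of the private allele and the pooled MAF of the site are
reported: "mean MAF of private alleles" is ambiguous between the two scales
(a rare allele at in-group frequency ~0.2 contributes pooled MAF ~0.05 when
the group is a quarter of the cohort), so both are surfaced.

### In-silico double digest

Recognition sites are scanned case-insensitively on the plus strand
(repeats are cut like any other sequence; masking only matters for flank
filtering); an occurrence starting at 0-based s cuts at s + cut_offset using
top-strand cleavage coordinates (PstI CTGCA^G → offset 5, MseI T^TAA →
offset 1). Sticky-end overhangs are ignored for length — the purpose is a
fragment-length distribution, not a chemistry model. The union of both
enzymes' cuts partitions each contig [0, L); cuts falling exactly on a
terminus are dropped (they create no internal boundary), and a coordinate
cut by both enzymes raises an error since its end label would be ambiguous
(impossible for PstI/MseI, but the contract is defined). Size selection
takes a closed length window with an optional `adapter_allowance` subtracted
from both bounds — library windows are often quoted on adaptor-ligated
molecules and no adapter length is assumed by default — and an end rule:
`AB_ONLY` (one end from each enzyme, the fragments standard ddRAD adapter
chemistry amplifies; the default), `AA_ONLY`, `BB_ONLY`, or `ANY`. A
whole-genome fragment count is obtained with `ANY` and an unbounded window.

### Hybrid index and class assignment

At a diagnostic locus, genotypes are re-oriented to species-allele counts
(0, 1 or 2 copies of the species-B allele). Over typed markers: hybrid index
h = B-allele fraction; interspecific heterozygosity = het fraction; class
assignment maximizes the multinomial log-likelihood of the genotype counts
under the six canonical classes (pure A/B, F1, F2, BC to A/B) with genotype
probabilities mixed as (1−ε)·model + ε·uniform over the three genotypes.
ε defaults to 0.01: without it, any single miscall sends a pure class's
likelihood to −∞. Ties are broken by the fixed class order with a `tie`
flag. The 95% interval on h is a Wilson interval treating the 2·n_typed
alleles as independent draws; diagnostic markers are genome-wide and
unlinked by design intent, but within-individual allele pairs are not
literally independent, so the interval is an approximation (conservative
for backcrosses, where the two alleles at a locus are positively
constrained). The classifier covers first- and second-generation classes
only: a fixed-difference panel without linkage information cannot separate
deeper backcrosses, which map to the nearest class.

## Synthetic data: what it emulates

The generator reproduces the *sampling structure* of a two-species
reciprocal-cross panel: group sizes (7, 6, 9, 8), fixed interspecific
differences, shared polymorphism with species-specific frequencies, rare
group-private alleles, and hybrids formed gamete-wise. Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_per_group` | (7, 6, 9, 8) | SK, WT, SW, WS individuals |
| `n_diagnostic_clean` | 50 | true positives for the screen |
| `n_diagnostic_confounded` | 25 | 5 per failure mode (below) |
| `n_shared` | 400 | polymorphic in both species |
| `n_private_per_group` | (10, 10, 10, 10) | single-group alleles |
| `maf_range` | (0.1, 0.5) | shared-site alt frequency, uniform |
| `private_freq` | 0.19 | target in-group frequency of private alleles |
| `fis_parental` | 0.15 | within-species inbreeding coefficient |
| `missing_rate`, `genotyping_error` | 0, 0 | applied last, in this order |
| `contig_length`, `mask_fraction` | 70 kb, 0.08 | toy reference |

Design choices that deserve justification:

* **Gamete-wise F1s.** Each hybrid genotype draws one allele from each
  species' allele frequency rather than from explicit parents, because the
  sampled parental individuals are not the parents of the sampled hybrids.
  At fixed-difference sites this makes every hybrid heterozygous by
  construction; at shared sites it produces the Wahlund-type excess
  Hobs − Hexp = (pA−pB)²/2 that drives hybrid mean F_IS below zero.
* **Confounders enumerate the screen's failure modes** — a companion
  variant planted exactly 40 bp away, a soft-masked flank base, a position
  within 40 bp of the contig start, one homozygous hybrid, one heterozygous
  parental — so each filter clause has a dedicated fixture and the truth
  table records the stage at which each must fall out.
* **Parental inbreeding, `fis_parental` = 0.15.** Captive parental herds
  descend from few founders and show a mild within-group heterozygote
  deficit (positive F_IS). This matters doubly here: under exact
  Hardy–Weinberg sampling the uncorrected sample F_IS estimator has
  expectation ≈ −1/(2n−1) ≈ −0.08 at n = 7, so a generator without
  inbreeding would show *negative* mean parental F_IS purely as estimator
  bias — the opposite of what real parental groups display. F = 0.15 yields
  realized parental means of roughly +0.02 to +0.07, qualitatively matching
  captive populations, while leaving hybrid means strongly negative
  (≈ −0.2). Genotypes are drawn from the standard inbreeding-adjusted
  frequencies (q²+Fpq, 2pq(1−F), p²+Fpq).
* **Private alleles are planted, not emergent.** A hybrid group cannot own
  a private allele under the gamete model (its gametes come from the two
  species' pools), so private sites are drawn directly: the owning group at
  `private_freq` (conditioned on at least one observed copy, emulating the
  ascertainment that an *observed* private allele implies), all other
  groups monomorphic. This represents rare or de-novo variants observed in
  exactly one sampled group.
* **Determinism.** One seed feeds two spawned generator streams (reference,
  then genotypes); sites are processed in positional order with a fixed
  per-site draw sequence, so identical configurations give byte-identical
  FASTA/VCF/popmap/truth outputs. Masked-flank confounders lowercase one
  flank base of the reference in place.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: linkage and LD structure (sites are placed ≥
100 bp apart and drawn independently), sequencing-depth-dependent error and
allelic dropout (error is a symmetric uniform miscall), population
substructure within species, later-generation hybrids or introgression
gradients, and any relationship between the toy reference's composition and
a real genome's repeat landscape. In particular, exact precision/recall = 1
on clean synthetic data demonstrates the logic of the screen, not the false
positive rate expected under real genotyping noise; the `missing_rate` and
`genotyping_error` knobs exist to probe robustness.

## Numerical and degenerate-input conventions

* F_IS = 0/0 → 0 (monomorphic samples); groups with no calls → NaN.
* Heterozygotes are always written `0/1` in VCF output (round-trip
  determinism); phased input separators are accepted and ignored.
* VCF/marker positions are 1-based; BED and fragment arithmetic 0-based
  half-open; BED marker intervals are length 1.
* Class log-likelihood ties (within 1e-9) resolve to the first class in
  (PURE_A, PURE_B, F1, F2, BC_A, BC_B) with `tie=True`.
* Zero typed markers → NaN statistics and no class call, never a default
  class.
* The digestion of an empty window or empty fragment list returns empty
  results; histogram bins are half-open [k·w, (k+1)·w).

## Problem sizes

The shipped analyses and checks run on one 70-kb contig, 515 sites and 30
individuals, with classifier calibration at 200 markers × 200 replicates
per class and statistics oracles on 1,000 random small matrices — sizes
chosen so the whole suite re-runs in seconds while every code path
(including each confounder category) is exercised. All sizes scale through
`SimConfig` and the script flags.

## Known limitations

* The screen treats the site list it is given as the universe of known
  variants; flank cleanliness is only as good as the supplied discovery set.
* Pooled-MAF filtering and the 2pq-based F_IS differ in detail from STACKS'
  per-population MAF semantics and π-based F_IS; both choices are
  documented above and surfaced in the outputs so results can be reconciled
  against a STACKS run.
* The Wilson interval on h ignores within-locus allele dependence.
* Only biallelic SNPs are supported; multi-allelic records are rejected at
  parse time rather than decomposed.
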