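# Methods

This note documents the statistical procedures, the synthetic-data
model that backs the tests, and the design choices made where the
published descriptions of these methods leave room.

## Data model

Genotypes live in a `GenotypeDataset`: an `n × N` matrix of allele-B
dosages in {0, 1, 2, missing} with a locus map (autosome label,
1-based bp position, two allele symbols) and sample metadata (id,
sex). When reading PLINK text files, allele B is the minor allele
observed in the data (ties at MAF 0.5 broken lexicographically), so
dosage is a minor-allele count, as PLINK's A1 convention; when reading
VCF, REF/ALT fix the roles instead. Monomorphic loci are retained —
the polymorphism proportion needs them — with a placeholder second
allele. Only autosomes are intended to be analysed; a chromosome
whitelist can be applied at load.

## Quality control

Filter order is fixed: samples below the sample call-rate threshold
are removed first; locus statistics are then computed on the surviving
samples, and loci are removed by call rate, then Hardy–Weinberg, then
MAF, with each locus attributed to the first filter it fails. Three
presets mirror how the statistics are conventionally filtered:

| preset       | filters                  | used for                         |
|--------------|--------------------------|----------------------------------|
| `pn_track`   | call rates + HWE         | P_N                              |
| `core_track` | call rates + HWE + MAF   | Ne, H_o, H_e, G, KS, IBS, tree   |
| `roh_track`  | call rates only          | ROH / F_ROH                      |

The ROH track deliberately skips the HWE and MAF filters: runs of
homozygosity are precisely the loci a HWE filter would distort, and
low-MAF loci carry ROH signal. The HWE test is the exact conditional
test (sum of probabilities of heterozygote counts no more likely than
the observed one, given the allele counts; no mid-p), computed by the
standard recurrence; this is what PLINK's `--hwe` applies, and the
1e-6 default threshold is idiomatic for that workflow.

## Diversity statistics

- `P_N`: fraction of loci with MAF > 0 by default; a MAF threshold
  variant (e.g. ≥ 0.01) is available because "polymorphic" is
  sometimes operationalised that way on chips.
- `H_o`: per locus, heterozygotes / called samples; averaged over loci.
- `H_e`: Nei's unbiased gene diversity `(2n/(2n−1))(1 − p² − q²)` with
  `n` the called samples at that locus; averaged over loci.
- `r²`: squared Pearson correlation of unphased dosages over samples
  called at both loci (composite LD, PLINK `--r2`). The estimator is a
  deliberate choice — with 50-ish samples haplotype-phase estimation
  adds noise without benefit here.
- Map distances use a uniform genetic map, default 1 cM/Mb, the usual
  convention when no linkage map accompanies the chip.

### Effective population size

Sved's drift–LD relation `E[r²] ≈ 1/(1 + 4·Ne·c)` is inverted per
distance bin: `Ne = (1/4c)(1/r²_adj − 1)` with `c` the bin midpoint in
**Morgans** (Sved's derivation is in Morgans; a `centimorgan` unit
switch exists because the literature sometimes states cM, but with cM
units the estimates are 100× smaller). `r²_adj` optionally subtracts a
finite-sample term (`1/n` or `1/(2n)`, off by default). A bin at
distance `c` reflects the population roughly `t = 1/(2c)` generations
ago; the single summary Ne is the harmonic mean over bins by default
(small Ne values dominate, matching the inbreeding interpretation),
with the largest-`c` (most recent) bin available as an alternative.
Default bins span 0.005–0.05 M (0.5–5 Mb on the default map).

## Relatedness

VanRaden's first method: `Z` is the dosage matrix with column `k`
centered by `2p_k`; missing dosages are imputed to the centered value
0 (mean imputation); `G = ZZ′ / (2Σ p_k(1−p_k))`. Frequencies default
to those observed in the cohort — no base-population frequencies exist
for an unpedigreed herd. Kinship is `KS = G_jk/√(G_jj G_kk)`, exactly
1 on the diagonal; pairs with a non-positive diagonal product (an
animal whose centered dosages vanish) are reported as undefined rather
than silently dropped.

Note an intrinsic property of observed-frequency G on a structured
cohort: frequencies absorb part of the family means, so kinship within
large families is shrunk below the pedigree expectation and unrelated
pairs sit slightly below zero. On balanced cohorts of many independent
families (the validation setting) the effect is O(1/n) and sib-pair
KS means recover 0.5 / 0.25 to well within ±0.02; on a heavily
structured 54-animal herd it is visible (half-sib KS ≈ 0.15–0.2) but
does not cross the 0.1 family threshold in the herd-shaped preset.

IBS distance is `1 − allele-sharing proportion` with sharing
`(2 − |x_i − x_j|)/2` per jointly called locus (PLINK
`--distance 1-ibs`); a pair with no jointly called locus is an error.

## Trees and families

Neighbor joining is the classical Saitou–Nei algorithm: join the pair
minimizing `Q_ij = (m−2)d_ij − r_i − r_j`, standard limb lengths,
3-way join at the end (unrooted tree with trifurcating root). Exact
ties are broken by the lexicographically smallest pair of subtree
labels, making the output deterministic. Negative limb lengths are
kept internally and clamped to 0 in Newick output by default (the
usual viewer behaviour). On exactly additive inputs the true tree is
recovered to floating-point accuracy (property-tested).

Families: boars are grouped by single-linkage connected components of
the `KS ≥ 0.1` graph — the minimal faithful reading of a "kinship at
least 0.1" grouping criterion; any stricter linkage rule would need
information the criterion does not give. Sows are attached to the
family whose boars have the highest mean KS with them, gated by a
single-boar qualifying threshold (same 0.1): the gate implements
"kinship below threshold with *all* boars ⇒ separate group", and the
mean decides among qualifying families. Both the tree and the
threshold families are emitted so either view of the herd's structure
can be inspected.

## Runs of homozygosity

Two-stage sliding-window scan, matching PLINK `--homozyg` semantics:
50-SNP windows slide along each chromosome (truncated end windows are
not evaluated); a window is homozygous if it has ≤ 1 heterozygous and
≤ 1 missing call; a SNP is eligible when ≥ 5% of the evaluated windows
covering it are homozygous (the divisor is the actual covering-window
count, so chromosome ends use fewer windows); maximal eligible runs
are split at inter-SNP gaps > 1,000 kb and kept when they have
**more than** 30 SNPs, are **longer than** 1,000 kb, and average at
least 1 SNP per 1,000 kb. The strict inequalities follow the published
description of this parameterisation rather than PLINK's ≥ defaults;
missing calls inside a run do not terminate it (they are budgeted per
window). Bit-exact PLINK concordance at chromosome edges is not
promised — PLINK's hit-proportion rounding there varies between
versions — only algorithmic fidelity, which the exhaustive-checker
tests pin down.

`F_ROH` divides the merged per-animal ROH coverage by the autosomal
genome length `L`. The default `L` is 2,450,462.292 kb (the autosomal
coverage of a ~57k porcine breeding array); for simulated genomes `L`
must be the simulated genome length, and the pipeline sets this
automatically for the built-in preset.

## Synthetic data: what it emulates and what it does not

All generators are bit-reproducible from (config, seed); every
stochastic operation draws from its own seeded stream.

- **Founders**: unrelated individuals in linkage equilibrium, dosage
  ~ Binomial(2, p) with p uniform on 0.05–0.95 by default (a
  flat-ish chip ascertainment profile); an optional monomorphic
  fraction models chip loci fixed in the target herd. Missingness is
  independent per call.
- **Gene dropping**: founder genotypes are randomly phased; each
  offspring inherits one recombinant haplotype per parent with
  crossovers a Poisson process (no interference) on a uniform map,
  default 1 cM/Mb. An `independent_loci` mode makes every locus
  segregate independently — used when the validation question is about
  expectations over many unlinked markers rather than linkage.
- **LD panels**: locus *pairs*, each on its own chromosome, built from
  correlated Bernoulli haplotypes with haplotype correlation
  `ρ = √(1/(1+4·Ne·c))` and equal allele frequency within the pair, so
  the expected dosage `r²` equals the Sved value at the pair's map
  distance. A latent-Gaussian construction thresholded to genotypes
  was rejected because discretisation attenuates the realized
  correlation below its target; the Bernoulli-pair construction hits
  the target exactly in expectation. Only within-pair LD exists — the
  panel is a calibration instrument for the Ne estimator, not a
  coalescent simulation.
- **Implanted ROH**: within a planned span, heterozygous calls are
  resolved to either homozygote with probability ½ each — exactly the
  marginal distribution autozygosity induces given the genotype —
  while homozygous and missing calls are untouched. This preserves
  allele frequencies and cross-individual relatedness, and raises the
  G diagonal like genuine inbreeding does.
- **Herd-shaped preset** (`papershape`): 54 animals — 3 paternal
  half-sib boars in one sire line, 3 boars in singleton lines, 23 sows
  sharing a sire with some boar, 25 unrelated sows — on ~50k SNPs
  across 18 autosomes of 136.137 Mb each (total ≈ 2.45 Gb), 48.5%
  monomorphic loci, 2% missingness, and per-animal implanted
  autozygosity: 35–60 tracts of 3–8 Mb with lengths
  `3 + 5·Beta(1, 1.8)` Mb, right-skewed so most tracts fall below 6 Mb
  and the implied mean F_ROH is ≈ 0.09. These values describe a small
  closed conservation herd genotyped on a breeding array.

What passing tests on these data do **not** show: behaviour under real
ascertainment bias, genotyping error, population-level historical LD
(pedigree truth and LD truth are generated by separate instruments,
because controlling both exactly in one simulator is out of scope), or
non-uniform recombination maps. In particular the preset's LD-based Ne
is large — linkage-equilibrium founders carry no drift LD — so the Ne
slot of the preset's summary exercises plumbing, while the Ne
*estimator* is validated separately against panels with planted LD.

## Numerical and degenerate-input choices

- HWE ties: probabilities equal to the observed one (within 1e-12
  relative) are included in the p-value, as in the exact-test
  convention; fully missing loci get p = NaN and pass no judgement.
- Zero-variance locus pairs are skipped (and counted) in r²; a bin
  with no pairs is an error at the API level and skipped with a
  warning at the pipeline level; corrected r² ≤ 0 yields an undefined
  Ne for that bin.
- NJ's pair search uses only the upper triangle of Q: the broadcast
  evaluation of `(m−2)d − r_i − r_j` is symmetric only to the last
  ulp, and an argmin landing strictly below the diagonal would evade a
  deterministic tie-break.
- All-monomorphic panels make G undefined (zero denominator) and raise.
- Problem sizes in the validation suite (20k unlinked SNPs and 200
  pairs for sib-pair kinship, 4k-locus LD panels at Ne ∈ {20, 50, 200},
  4k-SNP two-chromosome genomes for ROH recovery, 100 random trees of
  ≤ 12 taxa, the 50k-SNP preset end to end) were chosen so each check
  is decisively powered while the whole suite stays interactive on a
  laptop-class single core.

## Known limitations

- PLINK binary (.bed) files, phased data, and sex chromosomes are out
  of scope; the CLI consumes PLINK *text* or VCF.
- `G` uses VanRaden's method 1 only (no per-locus standardisation, no
  KING-robust kinship); IBS distance is not corrected for allele
  frequency.
- The boar-family criterion is sensitive to the frequency-centering
  shrinkage discussed above when one family dominates the cohort;
  with very unbalanced herds a threshold below 0.1 may be more
  faithful to pedigree truth.
- Ne from LD on ~50 animals is noisy and sensitive to the map
  assumption and the `r²` correction; per-bin tables are always
  emitted so the profile, not just the summary, can be judged.
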