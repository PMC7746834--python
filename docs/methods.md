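# Methods

`msatpop` implements the complete analysis chain used in conservation
genetics of very small populations genotyped noninvasively at
microsatellite loci: replicate-based consensus genotyping and quality
control, individual identification, diversity and inbreeding statistics,
likelihood parentage, linkage-disequilibrium effective population size,
and a current-vs-historical allele-loss comparison. This note records
the models, the defaults and why, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Data model

Alleles are binned fragment lengths in base pairs; a diploid call is an
unordered allele pair. Raw lengths are snapped onto a per-locus grid
anchored at the modal rounded length and spaced by the repeat-motif
length (2/3/4 bp), with exact half-way ties broken downward. Binning is
idempotent. A snap distance exceeding half a motif is only possible when
a declared size range truncates the grid; more than 10% of such calls at
a locus aborts binning for that locus.

Consensus genotypes travel as GenePop files (2- or 3-digit codes,
missing = 00/000); replicate-level calls as tidy CSV, because GenePop
has no replicate concept. Electropherogram peak screening is upstream of
this package: a call either arrives or is recorded as a failed
amplification.

## Consensus calling and quality metrics

The multi-tubes rule: a heterozygote is accepted when each allele is
seen in at least `min_het_obs` (default 2) successful replicates; a
homozygote when its allele is the only one seen at least twice and it
appears in at least `min_hom_reps` (default 3) successful replicates.
Alleles seen once are treated as contradicted false alleles. Everything
else is missing.

Reliability metrics, all conditional on cells with a called consensus:

* **ADO rate** — fraction of successful replicates at
  heterozygous-consensus cells that are homozygous for one consensus
  allele. This is the observed per-replicate rate; under the standard
  error model in which each allele of a heterozygote drops independently
  with probability `p` and double dropouts register as failed
  amplifications, its expectation is `2p/(1+p)`. The inverted per-allele
  estimate `p̂ = x/(2−x)` is reported alongside (`ado_per_allele`).
* **FA rate** — fraction of successful replicates at called cells
  containing at least one allele absent from the consensus.
* **PCR success rate** — replicates exactly matching the consensus over
  replicates attempted. Failed replicates count in this denominator (a
  failed PCR is not a correct genotype) but are excluded from the
  ADO/FA denominators, which condition on successful amplification.
* **Quality index** — per cell, the proportion of attempted replicates
  matching the consensus; averaged per locus, per sample, and globally.
  The global QI equals the defined-cell-weighted mean of either
  marginal, an identity exercised in the tests.

Because the ADO denominators condition on *callable* cells, cells with
many dropouts are censored at low replicate counts: at three replicates
and `p = 0.2` the per-allele estimate is biased down to roughly 0.12.
The estimator is consistent as the replicate count grows (≈ 0.19 at six
replicates); recovery tests therefore run at six replicates.

## Individual identification

Per-locus probability of identity for unrelated individuals and full
sibs:

    PID    = 2(Σp_i²)² − Σp_i⁴
    PIDsib = 0.25 + 0.5Σp_i² + 0.5(Σp_i²)² − 0.25Σp_i⁴

Cumulative products over loci sorted most→least informative give the
discriminating power of a panel; the default thresholds are PID < 0.001
and PIDsib < 0.01. PID frequencies are computed from the deduplicated
individual set after clustering, avoiding pseudo-replication from
multiply-sampled individuals.

Sample matching compares genotypes over co-typed loci: zero mismatches
over at least `min_overlap` (default 5) loci is "same"; exactly one
mismatch is "inconclusive" (a single residual allelic dropout can fake
one mismatch); more is "different". Three design choices refine plain
transitive closure, all motivated by the asymmetry of dropout (it
fabricates homozygotes, never heterozygotes, since false alleles are
filtered at consensus):

1. **Sex markers are part of the identity.** Samples with conflicting
   known sex calls are never the same individual (males show 2–3 bands,
   females 1; conflicting replicate band counts give "unknown").
2. **Conflict-aware closure.** "Same" edges are applied
   largest-overlap-first and never join two components containing a
   "different" pair: a clear multi-locus mismatch outweighs an exact
   match over a minimal locus overlap (which full sibs can produce by
   chance).
3. **Orphan reconciliation.** A singleton sample joins the unique
   cluster against whose heterozygote-preferring merged genotype it
   shows no hard conflict and at most one dropout-explainable
   (orphan-homozygote vs cluster-heterozygote) conflict. This is the
   deterministic analogue of the manual review such flagged pairs
   receive in field studies; ambiguous orphans stay separate.

Two individuals with identical multilocus genotypes and the same sex
are genuinely indistinguishable to any genotype-matching method; the
simulator-based recovery tests therefore score clustering against the
partition of true individuals by (genotype, sex).

## Diversity, inbreeding, Hardy–Weinberg

Per locus: Na, effective alleles `1/Σp²`, Ho, `He = 1 − Σp²` (the
uncorrected form, matching the conventions of the standard desktop
packages; the unbiased `uHe = 2n/(2n−1)·He` is reported alongside),
`PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j²`, and the Weir–Cockerham
single-population inbreeding coefficient

    f = 1 − Σ_a c_a / Σ_a (b_a + c_a),
    b_a = n/(n−1) [ p_a(1−p_a) − (2n−1)/(4n) h_a ],   c_a = h_a/2,

with `h_a` the observed frequency of heterozygotes carrying allele a.
`f` converges to `1 − Ho/He` in large samples and is undefined (NaN)
at monomorphic loci. Summary rows report the across-locus mean, SD
(ddof = 1) and SE; note that published tables in this field sometimes
print the SE under the label "S.D.".

The Hardy–Weinberg test is the exact conditional test: the probability
of a genotype array given its allele counts is

    P ∝ 2^H / Π_{i≤j} n_ij!

with H heterozygotes, and the p-value sums arrays no more probable than
the observed one. All arrays are enumerated by depth-first search when
their number does not exceed `max_enumeration` (default 10⁶; the search
aborts at the cap); otherwise a seeded Monte-Carlo permutation sampler
(Guo–Thompson style, default 10⁵ draws, vectorised) reports the
estimate with its standard error, including the observed table in the
count so p > 0. A one-sided heterozygote-deficit variant (arrays with
at most the observed H) backs the null-allele flag. Exact-test p-values
are discrete and conservative in small samples — a property of the
test, not the implementation — so the uniformity calibration is run at
n = 100 individuals and four alleles, where the null distribution is
dense.

Null alleles are screened with two closed-form estimators,
Chakraborty's `(He−Ho)/(He+Ho)` and Brookfield-1 `(He−Ho)/(1+He)`,
plus the one-sided exact-test flag. Resampling-based null-allele
algorithms are out of scope.

The sex-ratio test reports both the plain Pearson chi-square against
1:1, `Σ(O−E)²/E` with `E = N/2`, and the Yates-corrected
`Σ(max(|O−E|−0.5,0))²/E`, each with its df = 1 upper-tail p. Published
tables in this literature occasionally label plain Pearson values as
Yates-corrected; reporting both makes the discrepancy visible.

## Parentage

Parent-pair assignment uses trio likelihoods with a
Hardy–Weinberg-mistyping error model: each observed genotype is the
true one with probability `1 − e` and a random HWE genotype with
probability `e`. Per locus,

    P(obs_o | obs_f, obs_m) = Σ_{g_f,g_m} P(g_f|obs_f) P(g_m|obs_m)
                              Σ_{g_o} T(g_o|g_f,g_m) P(obs_o|g_o)

with Mendelian transmission T and HWE priors; a parent untyped at a
locus is integrated over HWE, loci multiply, and offspring-missing loci
are skipped. The hypothesis space per offspring is all
(candidate male, candidate female) pairs plus one "both parents
unsampled" alternative, under a flat prior; an assignment is emitted at
posterior ≥ 0.95. The default `e` is the ADO-derived per-genotype error
from the QC stage, floored at 0.01. With `e = 0`, an assigned pair is
never Mendelian-excluded at any locus.

This is a pairwise method in the CERVUS tradition; full-pedigree
sibship MCMC is out of scope (the populations targeted here have a
handful of candidates). Offspring sharing both assigned parents are
labelled full sibs afterwards. Two recovery metrics are reported, as is
standard for parentage software: the fraction of offspring whose true
pair is top-ranked (the assignment *rate* at a fixed threshold is a
property of marker informativeness — with ten loci of 2–6 alleles even
error-free genotypes leave ~18% of offspring below the 0.95 posterior),
and the error rate among threshold assignments. When every individual
is run as a potential offspring, reciprocal spurious assignments can
create pedigree cycles; the pipeline retracts the weakest assignment on
each cycle, while the library default raises an error.

## LD effective population size

Drift in a closed random-mating population of effective size Ne
generates squared correlation ≈ 1/(3Ne) between unlinked loci. For each
locus pair and each retained allele pair, the Burrows composite
disequilibrium (no phase needed) over the S individuals typed at both
loci is

    Δ̂ = S/(S−1) [ (1/S) Σ_i g_A g_B / 2 − 2 p̂_A p̂_B ],
    r̂² = Δ̂² / [ p̂_A(1−p̂_A) p̂_B(1−p̂_B) ]

with g the 0/1/2 allele dosages. Alleles rarer than `Pcrit` (default
0.010) are screened out; a locus needs two passing alleles to stay in,
and a truly biallelic locus contributes only its more frequent allele
(the two dosage columns are perfectly anticorrelated and would double
count). Every allele-pair comparison is weighted equally; S enters as
the comparison-weighted harmonic mean.

The sampling component and the inversion to Ne use the published
random-mating small-sample corrections of the NeEstimator-v2/LDNe
lineage, stored as swappable data:

    S ≥ 30:  E[r²_sample] = 1/S + 3.19/S²,
             Ne = (1/3 + √(1/9 − 2.76 r²')) / (2 r²')
    S < 30:  E[r²_sample] = 0.0018 + 0.907/S + 4.44/S²,
             Ne = (0.618 + √(0.618² − 5.24 r²')) / (2 r²')

where `r²' = mean r̂² − E[r²_sample]`; `r²' ≤ 0` yields an infinite
point estimate with a finite lower bound. The headline 95% CI is a
jackknife over loci (leave-one-locus-out means of r̂², normal-theory
interval transformed through the Ne formula): pairwise r̂² values
sharing a locus are correlated, so the also-reported parametric
chi-square CI (df = number of comparisons) is anti-conservative.
Validation on Wright–Fisher populations (true Ne = 50, S = 50, 20 loci,
20 generations, `Pcrit = 0.02` ≈ 1/2S, 20 seeds) gives a median point
estimate within a factor of two of truth and jackknife coverage ≥ 80%.
On a dozen family-structured individuals the drift signal is often
swamped (r²' ≤ 0 → infinite estimate) — expected behaviour at that
sample size, not an error.

## Temporal comparison

Allele loss per locus is the set difference between current and
historical allele sets (matched by binned length), reported
symmetrically as losses and gains with per-cohort counts. "Frequency
classes 1–10" are ten equal-width bins on (0,1], class k covering
((k−1)/10, k/10] — the half-open convention is this package's
interpretation, stated here because the usual presentation never
defines it. Historical cohorts enter as plain frequency/count CSV
tables; they are published data, not recomputed.

## The synthetic-data generator

The generator emulates the sampling regime of a fecal-DNA study of a
tiny, group-living, socially monogamous primate population:

* 10 loci, mixed di/tri/tetranucleotide motifs, 2–6 founder alleles per
  locus (the default panel mirrors a published ten-marker set), founder
  frequencies Dirichlet-distributed (concentration 1.0, floored at 0.02
  so every declared allele is representable);
* 3 family groups of one monogamous adult pair each with 1, 2 and 3
  offspring — 12 sampled individuals; founders draw genotypes from the
  founder frequencies, offspring by Mendelian sampling; mutation is off
  (a closed population over ≤ 3 generations);
* male-biased offspring sex (P(male) = 0.75); sex markers reflect the
  true sex without error;
* 3 fecal samples per individual × 3 PCR replicates; per replicate:
  amplification fails with `p_amp_fail`; each allele of a heterozygote
  then drops independently with `p_ado` (both dropping = failed
  amplification; homozygotes cannot drop out); finally with `p_fa` one
  reported allele copy is replaced by a different allele, stutter
  (±1 repeat) weighted 3:1 over the rest of the locus grid.

Default noise (`p_amp_fail = 0.06`, `p_ado = 0.04`, `p_fa = 0.01`) was
calibrated so the simulated QC profile matches the performance a
well-run fecal-DNA study reports — global quality index ≈ 0.89–0.92 and
amplification success ≈ 93–94% — and fixed before any recovery testing.
Recovery tests that stress the estimators use their own, much higher,
noise settings.

What the generator does **not** emulate: locus-specific amplification
quality, DNA-quantity covariates shared across loci within a sample,
null alleles, age structure, immigration, or the field metadata
(territory, observation history) that real studies use to resolve
ambiguous identifications. Passing recovery tests therefore demonstrate
correctness of the statistical machinery under the stated error model,
not robustness to every failure mode of degraded samples.

A separate Wright–Fisher simulator (constant size, discrete
generations, random mating with replacement, unlinked loci started
equifrequent) provides samples of known effective size for validating
the LD-Ne estimator; loci fixed in the sample are flagged.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; the pipeline funnels
one run seed into the simulator and all seeded tests/aggregations, and
rerunning a configuration reproduces its output byte for byte. The
validation studies use: 10 seeds × 12 individuals for identification
and parentage recovery, 75 samples × 6 replicates for error-rate
recovery, 20 Wright–Fisher populations for Ne, and 500 replicates at
n = 100 for the HWE calibration — sizes at which the sampling error of
each check is comfortably below its acceptance margin.
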