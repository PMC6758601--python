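# Methods

This note documents the models, conventions and numerical choices behind
`raddisc`, and what the synthetic-data validation does and does not show.

## Partitioned D-statistics

### Frequency weighting

Clades are treated as populations: per site, each of the five roles (P1,
P2, P3a, P3b, O) gets the pooled derived-allele frequency over its
samples' non-missing dosages (dosage sum / ploidy sum). Pattern counts
are site sums of frequency products — for example the ABBAA weight is
(1−p̂₁)p̂₂p̂₃ₐ(1−p̂₃ᵦ)(1−p̂ₒ) — rather than tallies from a single sampled
allele per lineage. With fixed differences (all frequencies 0 or 1) the
weighted totals reduce exactly to the literal integer pattern tally; with
polymorphic pools they are fractional, which is why published tables of
such counts show non-integer values. All six discordant pattern classes
are accumulated: ABBAA/BABAA feed D1, ABABA/BAABA feed D2, ABBBA/BABBA
feed D12.

One table convention is worth flagging for anyone comparing against
published five-taxon D tables: the count-column header for the D12 class
is sometimes printed as "n ABAAA". ABAAA is an uninformative autapomorphy
of P2; the D12 definition requires the derived allele shared by both P3
lineages, i.e. the ABBBA class, and that is what this package counts.

### Polarization

Alleles are oriented per site so the outgroup's minor allele is derived:
if p̂ₒ > 0.5 every role's frequency is flipped to 1−p̂. Sites with
p̂ₒ = 0.5 exactly cannot be oriented and are dropped. Residual outgroup
polymorphism after the flip is handled by the (1−p̂ₒ) factor in every
pattern product, which smoothly down-weights sites where the outgroup is
not clean.

### Coverage rule

Coverage is evaluated at locus level, matching how RAD dropout operates
(a sample loses whole loci, not single sites): a site is usable only if,
at its locus, every clade participating in any role retains at least
`min_clade_cov` (default 1/3) of its samples. All usable SNPs in a locus
contribute; an optional one-SNP-per-locus thinning was considered and
rejected as the default because the locus bootstrap already accounts for
within-locus correlation when assessing significance.

### Significance

The resampling unit is the locus: loci are drawn with replacement,
per-locus pattern totals are summed (pattern accumulation is additive
over loci, so this is exactly equivalent to re-running the whole
frequency→polarize→count pipeline on the resampled dataset), D is
recomputed per replicate, and Z = |D_obs| / SD(D_replicates) with 1,000
replicates by default. The significance threshold defaults to z* = 2.55.
Degenerate cases: a zero denominator defines D = 0 with a flag (keeps
result tables total); bootstrap SD = 0 yields Z = +∞ with a degeneracy
flag, except when D_obs is also 0, where the 0/0 ratio is reported as
Z = 0 — no signal provides no evidence. Configuration enumeration finds
every role assignment in which {P1,P2} and {P3a,P3b} are sister cherries
of the clade tree and reports all 8 sign/swap variants by default
(`canonical` collapses them); the per-configuration tests share loci and
are not independent of one another.

## Quartet Sampling

Each internal branch of the unrooted focal tree splits the taxa into four
subsets; a replicate draws one taxon per subset uniformly, rejecting
draws whose six pairwise non-missing overlaps fall below `min_overlap`
(defaults 300,000 bp, with 140,000 appropriate for sparser matrices;
retries up to `max_attempts`, then records a failed-overlap replicate).
The quartet is resolved by evaluating the three unrooted topologies under
JC69 maximum likelihood: Felsenstein pruning over the (at most 15) site
equality classes, five branch lengths fitted by cyclic one-dimensional
search (vectorized grid line searches per coordinate; sweeps stop when
the lnL gain drops below 1e-6, at most 25 sweeps). The best topology
must beat the runner-up by ΔlnL ≥ 2.0 or the replicate is uninformative;
exact ties are uninformative. An unweighted-parsimony engine
(`engine="parsimony"`) is provided chiefly as an independent cross-check
on conflict-free data.

Scores, with t0/t1/t2 the concordant/discordant tallies, s = t0+t1+t2:

* QC = 1 + Σ pᵢ log₃ pᵢ if the concordant count holds the plurality,
  else −(1 + Σ pᵢ log₃ pᵢ); undefined (rendered "-") when s = 0.
* QD = 1 − |t1−t2|/(t1+t2); undefined when t1+t2 = 0.
* QI = s / (successfully drawn replicates). Scoring against successful
  rather than attempted draws was an open choice; successful draws keep
  QI a property of the data rather than of the overlap rule.
* QF(taxon) = concordant / informative replicates containing the taxon.

Identical ordered draws are resolved once and cached within a run; the
run is deterministic for a fixed seed, with one substream per branch.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume:

* **Gene trees** from the multispecies coalescent on a rooted ultrametric
  species tree in coalescent units (2N generations); per-branch relative
  population sizes (default 1). Admixture pulses are implemented backward
  in time: at the pulse time each lineage in the recipient branch
  independently reassigns to the donor with probability `fraction` —
  standard, exact and cheap compared with forward migration.
* **Sequences** by JC69 along each gene tree, site-independent, uniform
  root state, no rate heterogeneity; `mu` is expected substitutions per
  site per coalescent unit. The statistics under test are model-light, so
  the substitution oracle is kept simple.
* **Missingness** as independent Bernoulli dropout per (sample, locus),
  optionally per-clade to mimic the divergence-dependent dropout of RAD
  loci; an erased block is all-missing in both the alignment (N-fill) and
  the SNP matrix. Mutation-at-cut-site dropout is not modeled.
* **Filtering** retains loci with ≥ `min_n` covering samples and reports
  locus count, concatenated length and SNP count.

Seeding: one master seed; stages (gene trees, sequences, dropout) derive
substreams via fixed offsets, so `generate_dataset` is byte-reproducible.

The stock five-clade model places clades I–IV on a balanced quartet with
cherries at 1.0, the quartet join at 1.5, clade V at 2.5 and the root
(distant outgroup) at 4.0 coalescent units, with haploid samples (two
haploid samples can stand in for a diploid; downstream statistics consume
frequencies only, so ploidy is presentation). These depths give the
moderate ILS expected in a recent island radiation — internal branches of
half a coalescent unit leave substantial discordance without erasing
clade structure. No divergence-time estimates exist for the real system,
so the units are generic coalescent units, not a calibrated history.

**What passing tests show.** The generator reproduces the processes the
statistics assume (neutral MSC, independent loci, locus-wise dropout). It
does not emulate read-level error, reference bias, paralogy/assembly
artifacts, rate variation, selection or gene flow that is continuous in
time; calibration and power results on synthetic data therefore validate
the implementation and the statistics' behavior under their own model,
not robustness to those violations.

## Validation conditions and problem sizes

The validation suite uses deliberate desk-scale reductions (an empirical
RAD matrix may have tens of thousands of loci): null calibration uses 200
datasets of 500 loci × 64 bp (4 samples per clade) and checks
P(|Z| > 3) ≤ 0.08 per statistic; pulse-recovery uses 50 replicates of
1,000 loci with a 0.3-fraction pulse; Quartet Sampling limits use 8
species with long (3-unit) internal branches for the concordance limit
and near-zero (0.005-unit) internal branches with 4 samples per species
for the star regime, 100 replicates per branch, scoring the species
backbone branches; the filter cascade uses 100 samples with per-clade
dropout between 0.15 and 0.5 over thresholds {10, 32, 50, 67, 85}.

## Known limitations

* The D framework assumes the symmetric five-taxon topology; pectinate
  clade trees yield no testable configuration (reported, not guessed).
* Polytomies adjacent to a focal branch are rejected in Quartet Sampling
  rather than heuristically resolved.
* The JC69 quartet engine is deliberately minimal; for empirical data
  with strong base-composition or rate heterogeneity its ΔlnL values are
  conservative approximations of a full-model ML engine's.
* VCF handling keeps biallelic SNPs only and reads genotypes as unphased
  dosages; multiallelic records are dropped, not decomposed.
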