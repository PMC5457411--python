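# Methods

## The generative model

A simulated experiment follows one template (default: a fixed 150-nt ACGT
sequence with composition A48/C38/G25/T39) through five stages.

**Linear amplification (tagging).** Each of `n_templates` molecules gets a
fresh UMI (uniform over 4^14 14-mers; collisions are allowed and left to
the downstream filters) and is treated as the product of a single
synthesis event: the number of substitutions is Binomial(L,
`la_error_rate`). Although the laboratory protocol runs three LA cycles,
every LA product is a first-generation copy of the plasmid template, so
one synthesis event per tagged molecule is the faithful model and matches
the single LA-rate column of the published rate table.

**First PCR (branching process).** Each molecule spawns one copy per
cycle with probability `efficiency − 1` (efficiency ∈ [1, 2]; the default
1.8 gives the expected 1.8^20 ≈ 1.3e5-fold amplification over 20 cycles).
Each newly synthesized copy acquires Binomial(L, rate) fresh
substitutions. Two equivalent implementations exist:

* `simulate_pcr_population` builds the tree explicitly (guarded to
  expected populations ≤ 2e5) — used as the oracle;
* `sample_lineage` / `simulate_first_pcr` simulate only the
  population-size trajectory N_t forward (B_t new copies per cycle), then
  walk one uniformly chosen final molecule backward: at cycle t the
  molecule is one of the new copies with probability B_t/N_t, which adds
  one synthesis event. By exchangeability this reproduces exactly the
  distribution of a uniform draw from the explicit tree; a seeded
  two-sample test in the suite verifies the equivalence at 8 cycles.

**Substitution placement.** Each error event picks its class with
probability proportional to (spectrum weight × template fraction of the
class's source base), then a uniform position among that base's
positions. Class counts therefore come out proportional to f_src·w, and
the composition-normalized spectrum estimator (count / f_src,
renormalized) is unbiased for the generator weights w — the property the
spectrum-recovery test exercises. The plain alternative (uniform per-base
error probability with the alt drawn from the conditional spectrum row)
does *not* have this property: on the default template it turns a
0.6-weight class into a ~0.52 recovered share. Within one lineage a
position errs at most once (no double hits or back-mutations), keeping
the truth invariant "sequence differs from template exactly at the union
of recorded error positions" exact; at study-like settings a double hit
would occur in ~1e-4 of molecules, so the simplification is negligible.

**Bottleneck.** A UMI whose first PCR produced N molecules survives the
dilution with probability 1 − (1 − f)^N, and the surviving molecule is the
already-sampled uniform lineage draw. The default `dilution_fraction`
1e-6 mirrors the ~1e6-fold downsampling of a ~1.3e5-fold amplified pool
(≈ 0.13 expected survivors per UMI); tests and examples raise it to keep
most UMIs. At most one molecule per UMI ever survives.

**Second PCR and sequencing.** Each sequenced molecule emits k reads
(default: negative binomial with mean 10, shape 10, so the ≥5-read filter
retains most UMIs; the read-count distribution is not specified by the
protocol and is configurable). A read is the UMI prefix plus the molecule
sequence truncated to `read_length`. Second-PCR errors are modeled per
read: all reads of a molecule share that molecule's second-PCR
population-size trajectory, but each read walks an independent lineage
through it — shared subtrees within a read family are not modeled, which
slightly understates the (already tiny) chance that an early second-PCR
error wins a consensus. Sequencing noise flips each base (UMI included)
with probability 10^(−Q/10) to a uniformly chosen other base; per-base
qualities are constant at `phred_quality` or normal-jittered via
`phred_sd`, and the written quality strings reflect the scores used. In
the non-bottlenecked protocol each read additionally carries the errors of
an independently sampled *first*-PCR lineage, so only LA errors survive
consensus — the configuration that measures the LA rate.

The unamplified-control generator adds quality-independent "bridge-PCR"
errors (cluster-generation errors that present as high-quality base
calls) on top of quality-dependent sequencing noise, for the
quality-threshold analysis.

## Processing and statistics

**Filters.** UMI extraction keys groups by the exact leading 14-mer.
The coverage filter removes groups with <5 reads. The parent-child
collapse removes a tag when some tag at Hamming distance 1 has >20× its
coverage, or distance 2 has >200× (strict inequalities, evaluated on
pre-removal coverages; the highest-coverage candidate parent is used, and
removed reads are discarded, not reassigned). Candidate parents are found
by pigeonhole hashing of three substring parts rather than neighborhood
enumeration. The ratio is read as child:parent — the only direction under
which a low-coverage satellite is removed.

**Consensus.** Per position the plurality base wins; ties break by summed
Phred quality, then in favor of the reference (biasing ties toward
no-call). Positions covered by fewer than `min_reads` reads are emitted
as reference and flagged. Alignment is positional — the assay is
fixed-length and substitution-only, so no gapped aligner is involved —
and no post-hoc variant filtering is applied.

**Rates.** rate = E/(U·L·C) with a normal-approximation binomial CI
(z = 1.96); the exact Clopper–Pearson interval appears only as a test
oracle. LA correction subtracts `la_rate/C`, flooring at zero with a
warning. L defaults to the printed 150 but is configurable: back-
calculating the published rates from their raw counts implies an
effective denominator of ~154 bases (primer-adjacent bases), and the
published corrected rates are reproduced to ≤0.01 (1e-5 units) by
`rate − la_rate·(150/153.9)/C`, consistent with a count-space subtraction
over the physical 150-nt template. Similarly the published low-yield
(Phusion) rows back-calculate with C = 20 even though that assay ran 25
cycles, so the divisor is independently configurable. Recurrence analysis
outer-joins two experiments' calls on (position, ref, alt), imputes
missing frequencies at the 1/coverage detection floor, and correlates
log10 frequencies (the scatter is log-scaled in practice).

**Spectra and fingerprints.** Spectrum shares divide class counts by the
template fraction of the source base(s) and renormalize to 1. Profiles
are raw frequencies over (position × 3 alternative bases), clustered with
average linkage (the linkage is not dictated by the assay; it is
configurable) on correlation distance across samples and Euclidean
distance across units, with lexicographic label ordering for
reproducibility; zero-variance profiles are dropped with a warning, and
dendrograms export to Newick.

**Modeling.** The consensus-error probability is the closed form
1 − (1 − P[Binom(n, p) ≥ k])^L. The ANOVA uses sequential (type I) sums
of squares in the order polymerase, nucleotide, polymerase×nucleotide,
position bin (ceil(position/15)), GC content (15-bp window, truncated at
template ends with the actual window length as denominator), matching the
narrative order of factor contributions; the order is configurable since
sequential decompositions are order-dependent. Zero-rate cells are
excluded before the log transform by default; a pseudocount option exists.
Positional normalization z-scales log10 rates within (sample, base)
strata, dropping strata smaller than 2.

## What the simulations do and do not show

The generator reproduces the statistical skeleton of the assay —
branching amplification, bottleneck survival, coverage distributions, UMI
sequencing errors and satellite tags, spectrum-shaped substitutions, and
the separation of LA, first-PCR, second-PCR and sequencing error layers.
It does not model indels, chimeras, template switching, primer artifacts,
per-cycle dNTP-depletion kinetics, context-dependent (beyond base
identity) error rates, positional hot-spots, or nucleotide-specific
sequencing error. Passing recovery tests therefore demonstrates that the
pipeline is an unbiased, correctly calibrated estimator under the stated
model, not that real data are free of those unmodeled effects; published
headline quantities that depend on the original sequencing lane (spectrum
percentages per enzyme, variance shares, the empirical inter-experiment
correlation) are treated as structural references, with the corresponding
properties (class recovery, factor ordering, replicate co-clustering,
positive recurrence correlation) checked on synthetic data instead.

## Problem sizes and numerics

Test and acceptance simulations use 1e4–2e5 molecules per check — enough
that every assertion sits ≥4 standard errors from its threshold (binomial
or Poisson error propagation, noted per test) while the whole suite runs
in minutes on one CPU. Seeds are fixed throughout; identical seed and
configuration give byte-identical FASTQ and truth tables. Stochastic
acceptance checks (CI coverage, two-sample equivalence at α = 0.01) are
seeded so that their nominal false-alarm probability is not re-rolled per
run. Spectrum weights must sum to 1 within 1e-9; variance percentages sum
to 100 within 1e-6, with a constant-response guard that reports 0%
explained rather than a 0/0 ratio.
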