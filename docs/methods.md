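# Methods

This note documents the models, conventions and numerical choices behind
`bgnoise`: what the simulator emulates, how each estimator is defined, and
where the design was genuinely open.

## 1. The error processes and how the simulator represents them

A capture-based targeted sequencing protocol layers several independent
error sources between the DNA molecule and the base call. The simulator
represents each as a distinct injection step, applied in physical order
(fragmentation → capture → PCR duplication → sequencing), and records every
injected lesion in a truth ledger keyed by molecule, position, strand and
process label.

**Fragmentation.** Fragments are drawn with log-normal lengths
(parameterized by median and SD; the right skew matches both sheared gDNA
and cfDNA libraries) and cleavage-weighted break points: each cut bond's
flanking dinucleotide is sampled in proportion to a 16-entry weight table,
renormalized over locally available dinucleotides (implemented as
weight-proportional start sampling plus a ±8 bp weighted jitter of the end
cut, which preserves the length law). Two tables are shipped: an "acoustic"
table with CG > CA > TA ~ GA (cuts 5′ of A), and a distinct, milder
"plasma-nuclease" table. The weights are defined on the reference plus
strand; a cut observed from the minus-strand 5′ end therefore displays the
reverse complement of the weighted dinucleotide, which is the physically
correct strand symmetry. Recovery tests for the cleavage ranking tally cut
bonds on the plus strand (or use forward-read windows), where the weights
act directly.

**Shearing damage.** Acoustic shearing oxidizes guanine. Lesions are
injected as completed substitutions on the G-carrying strand of the duplex
(G→T for the C:G>A:T type at rate `shear_energy · p_ox`, G→C for the
C:G>G:C type at `shear_energy · p_ox2`), multiplied by `ncg_multiplier`
when the pair belongs to a CpG dinucleotide (the NCG:CGN context). Modeling
the completed substitution rather than chemistry-resolved 8-oxo-G with a
miscoding probability is deliberate: only the observable substitution
matters to the estimators. Each molecule's reads derive from one duplex
strand (chosen 50/50), so a lesion is read out only when it sits on that
strand; the ledger records both the lesioned strand and this visibility
(`on_template`). Break-point damage substitutes the first 5′ base of a
fragment end with G or T (equal odds) at probability `p_bp` when that base
is A, independently for the two termini (plus strand at the fragment start,
minus strand at the end). Plasma mode (`mode="none"`) forces all three
rates to zero — cfDNA never sees the shearing step.

**Uniform template damage.** Real libraries carry residual molecule-level
errors in every class whose origin the protocol comparison cannot resolve.
A uniform per-base template error `p_template` (random alternative base,
always read out) supplies this baseline; without it the un-sheared sample
would be implausibly clean outside the capture-damage classes.

**Capture damage.** Hybrid selection with strand-specific baits damages the
captured strand, producing strand-asymmetric classes. The package models
the observable directly: per captured molecule, before duplication, each
reference-C base converts to A with `p_hs_CA` and to T with `p_hs_CT`
(reference projection; `captured_strand="+"` swaps the roles to G>T/G>A).
The underlying chemistry is deliberately not asserted — oxidation of G on
the captured strand explains the C>A excess, but the co-occurring C>T
excess is not attributable to deamination of the same strand, an ambiguity
the protocol literature itself leaves open. What the estimators consume is
only the projected asymmetry, and that is what the simulator defines.

**Duplication and sequencing.** PCR copy number is `1 + Poisson(dup_mean −
1)` (mean-parameterized, minimum one copy); duplicates share fragment
coordinates and template substitutions. Sequencing-run errors hit each read
base independently at `p_seq` with a uniformly random wrong base. Base
qualities follow a two-point model reproducing the biphasic quality
distribution: correct bases get Q37 with probability `1 −
q_low_given_correct` (else Q12); error bases get Q37 with probability
`q_high_given_error` (else Q12). Only the Q37 component survives the Q30
analysis gate, so `p_seq · q_high_given_error` is the surviving run-error
rate.

**Germline and somatic variation.** Cohort SNP sites are shared across
subjects; each subject is heterozygous (allele fraction 0.5), homozygous
(1.0) or non-carrier per site, and the genotype is shared by the subject's
plasma/PBL/FNA triplet. Somatic spikes (position, alternative base, allele
fraction) are applied at molecule level to the FNA-like sample only.

### Default parameters

Defaults are the package's standing study conditions and are chosen to
reproduce the error landscape reported for deep targeted panels
(per-process rates of order 10⁻⁵–10⁻⁴ per base after quality filtration,
overall background ≈ 0.007–0.008%, C>A/G>T ≈ 1.7, roughly two-thirds of
C:G>A:T attributable to shearing, ≈ 40% elevation of C:G>G:C, ≈ 18% of
surviving errors inconsistent between mates):

| parameter | default | meaning |
|---|---|---|
| `p_template` | 6×10⁻⁵ /base | uniform molecule-level baseline |
| `p_ox`, `p_ox2` | 5.8×10⁻⁵, 1.0×10⁻⁵ /G | shearing oxidation (per duplex strand, read-out halves it) |
| `ncg_multiplier` | 5 | CpG-context boost of oxidation |
| `p_bp` | 5×10⁻⁴ /A-terminus | break-point A>K; ~15× the per-class baseline so the position-1 spike is clear without dominating the 1–50 bp mean |
| `p_hs_CA`, `p_hs_CT` | 1.5×10⁻⁵, 6×10⁻⁶ /C | capture-strand damage |
| `p_seq` | 10⁻³ /base | raw sequencing-run error |
| `q_high_given_error` | 0.006 | run errors surviving Q30 |
| `q_low_given_correct` | 0.13 | correct bases below Q30 (≈ 87% of raw bases at Q≥30) |
| `dup_mean` | 1.5 | PCR copies per molecule |
| `fragment_median`, `fragment_sd` | 170, 45 bp | mono-nucleosomal scale |
| `snp_density` | 5×10⁻⁴ /base | cohort polymorphic sites |

The expected mate-overlap inconsistent fraction under this model is
`2·p_seq·q_high·p_hi / (2·p_seq·q_high·p_hi + λ_template·p_hi²)` with
`p_hi = 1 − q_low_given_correct` — the factor 2 because either mate can
carry the run error, the squared `p_hi` because a template error must pass
the quality gate in both mates to be scored.

## 2. Analysis conventions

**Coordinates** are 0-based half-open internally; SAM output is 1-based.
Alignments are ungapped by construction (indels and chimeras are out of
scope); clipped reads are excluded wherever fragment ends matter.

**Duplicates** are keyed by fragment (start, end, orientation) — finer than
start-only and matched to fragment-level PCR duplication; the surviving
pair has the highest summed base quality, ties broken by input
(coordinate) order for determinism.

**Pileup double counting.** Bases where mates overlap are counted twice in
the pileup; rates are per sequenced base, and the overlap module analyzes
those bases explicitly and separately. Whether published denominators
collapse mate overlaps is typically unstated; the choice here is explicit.

**Background classification** is exhaustive and exclusive per (position,
alt): depth exclusion removes the whole position (paired depth, and FNA
depth when a biopsy is present); the germline gate (≥ 5% in *either*
paired sample — the conservative reading, protecting rates from SNP
leakage) and the FNA frequency gate (> 2.5%) remove single alleles.
Zero-count alt alleles are background and define error-free capacity.
Plasma and PBL pileups are aligned on their co-covered sites; a reference
base disagreement or empty intersection is an error.

**Rates.** For class X>Y only positions where (position, Y) is
background-category contribute, to numerator and denominator alike; the
same rule drives the context table, so marginalizing the 16 contexts
reproduces the class counts exactly (asserted). Context is read from the
strand carrying the pyrimidine of the collapsed class. Cohort statistics
are reported as mean ± SD over per-sample values, with pooled-count
versions available — the two differ (a mean of per-sample ratios is not the
ratio of pooled rates), and both are labeled.

**Capture asymmetry** is `(f_excess − f_baseline)/f_excess`. Published
"one-third / one-fifth" phrasings do not pin the denominator; this
definition is fixed here and documented rather than asserted as anyone
else's.

**Overlap scoring** requires both mate bases at a site to pass the quality
gate; a high-quality alt facing a low-quality partner is excluded rather
than counted inconsistent, so quality censoring is not conflated with
discordance. Overlap regions sit at read ends, where run errors are
enriched; no positional reweighting is attempted, so the inconsistent
fraction is an upper-leaning estimate of the run-error share.

**Break-point windows** span 100 bases labeled −50..−1, +1..+50 (no zero);
+1 is the first read base and distance 0 the bond straddling the break. In
the default `fragment` mode, reverse-strand windows are reverse-complemented
so +1 is always the first sequenced base — break-point phenomena (first-base
A enrichment, A>K localization) are properties of the cut strand and align
only in this orientation. `plus_strand` mode reports windows in reference
orientation instead (the usual display convention); for reverse reads the
cut bond then sits between labels +1 and +2 rather than at distance 0.
Window positions covered by the read use read bases (quality-gated, −1 when
censored); positions outside use reference bases. Positional rates use R1
reads only (their early cycles have better quality than R2's), in read
orientation, positions capped at 50; the fold change divides each position's
rate by the class's 1–50 mean, so the mean fold change is 1 by construction.

**Down-sampling** operates on whole read pairs (preserving pairing for
dedup and overlap), without replacement, deterministic under the seed. The
false-positive curve re-runs dedup → pileup → background call per
subsample with the paired-depth gate released (otherwise the low-depth bins
it is meant to measure would be empty); germline and somatic gates stay
active. Exceedance fractions count all background site-alleles in the
denominator; only alleles with ≥ 1 supporting base can exceed a positive
threshold, which is what the implementation enumerates.

The depth module also provides a direct overdispersed error model —
per-site rates drawn from a Gamma(shape 0.1) with mean 7×10⁻⁵ — because
the order-of-magnitude inflation of >1% false positives at low depth is a
property of strongly site-specific error rates, not of a uniform rate:
under a uniform 7×10⁻⁵ the probability of 5 errors in 400 reads is
astronomically small, while the gamma tail supplies the rare hot sites
that dominate the exceedance fraction at every depth.

**Paired comparison** uses a two-sided Wilcoxon signed-rank on per-subject
rates by default (the robust choice when the underlying test is unnamed;
a paired t is available by flag), Bonferroni-corrected by the number of
classes tested (echoed in the output), requiring ≥ 6 matched pairs. SNP
concordance is the Pearson correlation of paired germline allele
frequencies and needs ≥ 3 SNPs with genotype variety (all-heterozygous
panels have no between-SNP variance beyond counting noise, and their
correlation is uninformative by design, not by defect).

## 3. Problem sizes used in the shipped tests and acceptance run

The test suite and `scripts/acceptance.py` run the pipeline at reduced
panel sizes chosen so every check retains its statistical meaning: exact
oracle equivalence on a 10-kb, ~2,000-read instance; parameter recovery on
matched pairs of 10⁵ fragments over a 30–50 kb reference (≈ 550–650×
unique depth, the deep-panel regime where the > 500× gate is active);
break-point localization with the break-point rate at 10× its default (the
regime where per-class position-1 detection has > 90% power); null checks
on an 8-subject cohort of 4×10⁴-fragment samples with the paired-depth
gate at 200×; and the test-layer type-I control over 200 parametric
replicates. The simulator's error rates themselves are never changed
between null and alternative scenarios except for the parameter under
test.

## 4. What the simulator does not model

No indels, structural variants, clipped or chimeric alignments, mapping
quality, GC-biased capture efficiency, site-specific error hot spots in
the read simulator (the overdispersed model lives in the depth module),
quality scores beyond the two-point model, strand-displaced (staggered)
cuts, or biological background from pre-neoplastic tissue. Passing
recovery tests therefore demonstrate that the estimators measure what they
claim under these idealized conditions — unbiased counting, correct strand
and position bookkeeping, correct null behavior — not that real libraries
contain no error sources beyond the five modeled here. In particular, real
PBL data can show a *higher* mate-inconsistent fraction than plasma, while
this generator predicts a slightly lower one (shearing adds consistent
template errors only); resolving that would require a read-cycle-dependent
run-error profile, which is out of scope.
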