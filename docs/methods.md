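# Methods

## Scope and data model

The package models the full desk-scale loop for evaluating long-read SV
detection: a diploid SV simulator, a context-specific read simulator with
trainable error profiles, a truth-matching benchmark, and a rule-based
multi-caller merger. Coordinates are 1-based inclusive throughout the
library (the VCF convention); conversions to 0-based half-open happen only
at I/O boundaries.

An SV event carries its type (DEL, INS, DUP, INVDUP, INV, TRA, CSUB), start,
the reference span it consumes (0 for pure insertions, which land *after*
`start`), its length, an inserted sequence where applicable, a copy count
for duplications, and a genotype (HET on haplotype 1 or 2, or HOM). Events
must be ≥ 50 bp — the conventional SV size floor — except in "toy mode"
(`min_length=1`), which exists so worked examples and unit tests can stay
tiny. Events sharing a haplotype may not overlap on the reference; nesting
is deliberately not supported.

## SV simulation

**Placement.** Random positions follow a two-component mixture: terminal
windows of `telomere_window_bp` on every chromosome carry a density
multiplier `telomere_weight` (w) relative to the interior, reflecting the
elevated SV density near chromosome ends. With telomeric mass fraction
u = 2·window·n_chroms / genome, the expected telomeric fraction of events
is w·u / (1 + (w−1)·u); weight 1 recovers the uniform genome. Collisions are
rejection-sampled up to 1000 attempts per event, then fail loudly — silent
under-delivery of requested counts would corrupt downstream recall numbers.

**Lengths** are log-uniform between a per-type (min, max); the defaults
(50 bp – 10 kb) span the bulk of germline SV sizes.

**Type semantics.** DUP appends `copies` extra copies of the unit after the
original; INVDUP appends reverse-complemented copies. CSUB deletes
`ref_span` bases and inserts a replacement copied from a random distant
reference locus (list input takes the sequence verbatim). TRA is represented
as a reciprocal exchange of chromosome-end segments between two chromosomes
and emitted as two breakend (BND) pairs sharing an EVENT id; because each
translocation reserves both tails, at most one translocation can occupy a
given chromosome tail per haplotype, and translocations are placed before
all point-like events. The simulator does not model small indels, SNVs, or
clonal substructure.

**Application.** Events apply right-to-left (descending start) per
chromosome so stored reference coordinates stay valid; translocation cuts
are shifted by the net length change of earlier events on the same
chromosome. Outputs are haplotype 1, haplotype 2, and a merged genome
carrying every event (phasing ignored, i.e. effectively homozygous — the
merged file answers "one sequence containing all variants"). Output length
equals reference length plus the signed sum of per-event deltas
(+len for INS, +len·copies for DUP/INVDUP, −span for DEL, len−span for
CSUB, 0 for INV and genome-total TRA); this identity is exact and is
asserted over a thousand random event sets in the test-suite.

**Truth output.** DEL/INS/CSUB are written sequence-resolved with the
left-anchored VCF indel encoding (right-anchored at position 1);
DUP/INVDUP/INV use symbolic ALTs with SVTYPE/SVLEN/END. Genotypes are
phased (`1|0`, `0|1`, `1|1`) so write→parse round-trips reproduce the exact
event list, including haplotype assignment.

## Error profiles

A profile stores, per 3-mer context of the reference (64 contexts), the
substitution, insertion and deletion rate of the middle base, a
substitution-target distribution, and genome-wide insertion/deletion
run-length distributions (support 1..L_max, default L_max = 100; longer
training indels are clipped with a warning since at that size they are SVs,
not errors). Overall accuracy is defined as 1 − E[erroneous bases per
template base] under a uniform context mix and is always recomputed, never
stored.

**Generative process (one pass over the template).** Every template base
not interior to a deletion run is a *decision point*: a single uniform draw
selects deletion (probability del_rate, run length from the deletion-length
law; interior bases of the run make no decisions) or substitution
(sub_rate), mutually exclusive — hence the invariant sub + del ≤ 1. Every
*emitted* base then draws an insertion (ins_rate) for the gap 3′ of it,
with random inserted bases. The first and last template base lack a full
3-mer and use the profile's mean rates.

**Training** tabulates exactly the decision structure above from
CIGAR-resolved alignments: deletion-run starts and aligned bases are
decision points (denominator for sub/del rates), aligned bases are the
insertion denominator, interior deleted bases are excluded everywhere, and
the first/last aligned position of each read is skipped. Reads from the
minus strand are tabulated against reverse-complement contexts, with the
deletion-run head and insertion anchor mapped into read orientation —
errors arise in sequencing orientation, and ignoring this would smear any
strand-asymmetric context structure. With this pairing the retrained rates
are unbiased estimators of the generating rates, which the closure test
verifies at 200× coverage of a 100 kb genome. Contexts never observed
receive the genome-wide mean rate; unobserved substitution targets default
to uniform over the three alternatives. The trainer accepts SAM/BAM
(via pysam) or raw reads, which are infix-aligned in both orientations with
edlib at toy scale.

**Accuracy rescaling** multiplies all context rates by one factor found by
bisection so the recomputed overall accuracy hits the target within 1e-6,
preserving relative context differences; contexts pushed past sub + del = 1
(or an insertion rate past 1) saturate at the boundary with a warning, and
a target below the fully-saturated accuracy raises. Scaling to the current
accuracy is the identity and scaling is monotone per rate.

Profiles serialize to a sectioned plain-text format (`[meta]`,
`[contexts]`, `[ins_lengths]`, `[del_lengths]`); load∘save is the identity
to 1e-9 and a missing context line is an error naming the 3-mer.

## Read simulation

Read lengths follow a log-normal law anchored at the requested median
(σ = ln(max/min)/4) and truncated to [min, max]; the two halves of the
distribution are sampled with equal probability, so the sample median
equals the requested median for any (min, median, max), symmetric or not.
Each read: haplotype by fair coin (Bernoulli per read, not stratified),
chromosome weighted by length, start uniform — or window-weighted
(depth × window length) under a sequencing-depth profile, where zero-depth
windows receive no starts — strand by fair coin with reverse-complemented
output, then the error process above. Reads clip at template ends unless
`circular` wrap-around is enabled. Generation stops once the drawn template
bases reach coverage × genome size (or the depth profile's total), so the
realized coverage is exact up to one read. Simulation is single-threaded
and driven by one generator, so output is byte-identical for a fixed seed.
FASTQ quality strings are a constant Q = −10·log₁₀(1 − accuracy)
placeholder. Each read keeps its exact edit list; `to_alignment()` converts
it into a truth CIGAR (back-to-back deletion ops are *not* merged, because
they are distinct decision events), which is what the closure test feeds
back to the trainer — using truth alignments isolates the
simulator/trainer pair from aligner idiosyncrasies.

## Benchmarking

Filtering keeps calls with FILTER PASS ('.' and missing count as PASS,
since many callers emit them for clean calls), length ≥ 50 bp (length 0 =
undetermined is kept — breakends carry no length), and read support ≥ 3
(≥ 5 at depths ≥ 30×; calls without any support field pass).

Matching: within 1600 bp of a truth event; if the call length is
determined, within a 35% margin of the truth length above 300 bp and exact
at or below ("no margin for short SVs" is read as *exact length*; the
alternative reading — skip the length check entirely below 300 bp — is one
flag away, `short_len_margin`). Type and genotype never gate matching.
Assignment is one-to-one, greedy by |Δpos| with ties broken by smaller
|Δlen| then input order. Scoring weights 0.4/0.2/0.2/0.2
(position/length/type/genotype) with linear decay of the position and
length components over their tolerance; undetermined-length matches get a
zero length component. The total score subtracts one point per false
positive (an FP is weighted like one maximal per-SV score) and is floored
at zero before expressing it as a percentage of the truth count. Since no
caller emits the complex-substitution type, CSUB truth events can match but
never collect the type component unless a caller literally reports CSUB.
Per-type recall uses truth types; per-type precision uses called types
(and is undefined for types never called).

## Combining

Caller VCFs are normalized into call records (support read from
SUPPORT/RE/SR/SU/DV INFO keys or DV/AD FORMAT fields), calls below the
minimum alternative-allele coverage (3) are dropped, and calls are
clustered under the same sameness tolerances as the benchmark (1600 bp /
35%) — the merger and the benchmark should agree on what "the same SV"
means. Each caller contributes at most one call per cluster (nearest to the
cluster anchor wins; the displaced call stands alone). A cluster is emitted
when ≥ 2 distinct callers support it (≥ 3 for six inputs) or a rescue rule
matches (defaults: SVIM homozygous, any type; Sniffles heterozygous
INS/DEL); `--no-singletons` disables all rescues. Consensus position and
length come from the highest-priority caller present on the position/length
ranking (pbsv, cuteSV, Sniffles, SVIM, NanoVar, NanoSV), the genotype from
the genotype ranking (cuteSV first), and the type from the highest-priority
caller reporting a concrete (non-BND) type, with conflicts logged. Both
rankings beyond their stated leaders are configuration defaults and fully
user-overridable. A missing anchor caller (cuteSV/Sniffles/pbsv) warns but
does not fail. Combining an output with itself is a no-op.

## Fixtures and pseudo-callers

Pseudo-callers apply parameterized, seeded distortions to a truth set:
per-event drop (false negatives), Gaussian position jitter, multiplicative
length jitter, genotype flips, type confusion maps (e.g. INS→DUP, CSUB→DEL
— failure modes real callers exhibit), and injected false positives at a
fixed per-Mb rate. The FP count is deterministic (rounded rate × genome
size) and FPs are placed beyond twice the match window from every truth
event, so the benchmark's reported FP count equals the injected count
exactly — an identity the tests rely on. The round-trip driver chains
genome → SVs → reads → pseudo-callers → benchmark → combine → benchmark,
derives every stage's seed from one global seed, and reports one table; the
test-suite runs it on 2×120 kb at 3× with 40 SVs, and the CLI defaults to
2×500 kb, 200 SVs, 15×.

## What the synthetic conditions do and do not show

Toy genomes are i.i.d. uniform (or GC-tilted) sequence: no repeats, no
segmental duplications, no homopolymer excess. Consequently the simulator's
error profile is exercised, but alignment ambiguity — the dominant failure
mode of real SV calling in repetitive regions — is absent, and pseudo-caller
error models are stipulated rather than emergent. Passing tests therefore
certify the bookkeeping, matching arithmetic, estimator consistency and
merging logic, not caller performance on real genomes. Problem sizes in the
tests (100 kb closure genome at 200×, 1.2 Mb pseudo-caller genome with
1000 events, 6 kb conservation genomes × 1000 sets) were chosen as the
smallest at which the statistical checks have meaningful power.

## Numerical and degenerate-input choices

* Per-event placement retries: 1000, then a loud failure.
* Accuracy bisection: 100 iterations, 1e-6 acceptance on the target.
* Zero coverage yields an empty, valid read set; an empty truth set is a
  benchmarking error; fewer than two combiner inputs is an error.
* Degenerate read-length range (min = median = max) is a constant law.
* Greedy matching ties break deterministically (|Δpos|, |Δlen|, input
  order), making every reported metric reproducible bit-for-bit.
* All stage seeds derive from one seed via `numpy` SeedSequence and stay
  below 2³¹.
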