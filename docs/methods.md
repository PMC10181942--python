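# Methods

## The simulated clade

The generator produces a single-chromosome ancestor (uniform random
nucleotides) carrying non-overlapping gene models — 1–3 coding exons each,
total CDS length divisible by 3, introns of 50–200 bp — and evolves it down
a balanced bifurcating tree (a user Newick topology is accepted; branch
lengths are not interpreted, every edge applies one round of events).

Per branch: substitutions hit each site independently at
`substitution_rate_per_branch` (default 0.002); each gene family is lost
with probability `family_loss_prob` (loss removes the gene *sequence*, so
absence is physical, not just an annotation gap); `family_gain_rate` is the
Poisson mean of new single-exon genes inserted into intergenic space, each
founding a new family. Structural variants of the five classes (INS, DEL,
INV, DUP as tandem duplication, TRA as cut-and-paste) are implanted on
terminal branches only, placed uniformly in intergenic sequence (optionally
targeted at gene bodies to exercise the consequence classifier), with
lengths log-uniform within the per-type range. Truth coordinates are
recorded on the branch's pre-SV frame; with gain/loss rates at zero this is
the ancestor frame, which is the configuration used for caller
benchmarking.

Implanted SVs keep a minimum separation (`sv_min_separation`, 300 bp).
Without it, two independently drawn deletions can abut and coalesce into a
single larger call, making per-event recall ill-defined; the separation
makes each truth record independently recoverable and is part of the
benchmark's definition, as in other SV benchmark simulators.

LTR retrotransposons are modelled as standalone 5′/3′ sequence pairs per
genome (alternately tagged Gypsy/Copia): both ends start identical and each
end substitutes per site with probability μ·age, giving end-to-end
divergence 2μ·age in expectation — exactly the assumption the dating
formula inverts. Elements are not embedded in the genome sequence because
LTR discovery is out of scope; dating needs only the pairs.

The population module draws presence/absence calls per accession from
per-group Bernoulli frequencies, with group sizes defaulting to the
four-group design of the motivating system (wild 19, SP 22, SLC 24,
SLL 47) and a dedicated missing state (−1) drawn independently at
`missing_rate`. Phenotypes are y = Σβ·g + confounder + N(0, σ²); the
optional confounder is the sum of the genotype matrix's own top principal
components, so it is genuinely collinear with genetic structure and
removable by PC covariates.

All randomness flows from one `numpy.random.Generator` seeded by the
config; identical (config, seed) reruns are byte-identical, which the test
suite asserts on the full pipeline's artifact tree.

### What the generator does not emulate

No recombination, diploidy/heterozygosity, selection, nested or overlapping
SVs, sequencing error, or TE taxonomy. Sequence composition is i.i.d.
uniform, so alignment is easier than in repeat-rich real genomes: passing
recall benchmarks here demonstrates the correctness of the chaining and
calling logic, not performance on megabase tandem arrays or centromeres.

## Pangenome classification

Families are single-linkage components over pairwise global-alignment
identity (edlib edit distance / max length), with a k-mer Jaccard
prefilter; the threshold defaults to 0.8. Single linkage is deterministic
and order-free, which the tests rely on; a hook accepts externally computed
cluster tables in the same shape.

The rescue rule re-examines every (family, genome) cell with no annotated
member: each member CDS is located in the target genome by edlib infix
alignment and refined by a local Smith–Waterman (match +1, mismatch −2,
gap −6/−2). Coverage is the aligned query span over query length; identity
is matching columns over all alignment columns including internal gaps —
counting gap columns prevents the aligner from "improving" identity by
gapping away mismatches. Both must be **strictly** greater than 0.80
(reading "more than 80%" literally), and the aligned genomic span must
overlap no annotated gene. Rescued cells count as present for
classification. CDS space (not protein) is used for both clustering and
rescue; a single contiguous alignment is required.

Core/dispensable/specific follow the standard definitions (all N / 2..N−1 /
exactly 1), asserted to partition the family set on every run. Growth
curves are seeded permutations of genome order with cumulative union and
intersection; the 4-genome case is validated against exhaustive enumeration
of all 24 orderings.

## SV detection

Anchors are k-mers (default k = 21; k ≥ 11 enforced) occurring exactly once
in the reference and exactly once in the query in a single orientation.
Forward anchors sharing a diagonal (q − r) form blocks, split where the
anchor gap exceeds 500 bp so length-preserving rearrangements cannot hide
inside one block; reverse anchors sharing an anti-diagonal (q + r) form
inversion blocks. The backbone is the maximum-anchor-weight chain of
forward blocks increasing in both genomes, tolerating up to k bp of
overlap between neighbours (chance k-mers spanning an SV junction can
extend a block by up to k − 1 bp).

Between consecutive backbone blocks: query gap − reference gap ≥ 20 bp is
an INS; the reverse a DEL; gaps on both sides whose query side is an
integer tandem multiple (edlib distance to m concatenated copies < 20% of
length) are DUP with copy ratio m (or 1/m for contractions) — the integer
is reported because the anchor-eroded gap ratio jitters around it. Reverse
blocks are INV over their reference span; forward blocks off the backbone
are TRA (the reference span is the moved segment). Breakpoints are accurate
to ±k by construction, which is the tolerance used in benchmarks.
Emulating the two-caller design of pan-SV studies, the pipeline runs the
caller at k = 21 and k = 31 and merges both call sets.

Filters implement the published retention rules at strict boundaries:
INS/DEL/TRA > 50 bp; INV < 1 Mb; DUP > 50 bp with ratio ≥ 2 or ≤ 0.5; any
SV whose recorded sequence contains N is removed. Each removal is
attributable to exactly one rule, and the filtered set is a subset of the
input.

Merging is single-linkage over calls on the same chromosome with both
|Δstart| ≤ 50 and |Δend| ≤ 50 (per-breakpoint reading of the 50-bp merge
distance; type/strand agreement optional and off by default, support
minimum 1, size minimum 0 — the published parameter set). The
representative is the member of median length (lower median), ties broken
by lowest (chrom, start); merging is idempotent and invariant to input
order, both property-tested against a brute-force union-find oracle.

## Divergence scan

Group frequencies exclude missing calls from numerator and denominator; a
group with all calls missing yields an undefined (NaN) frequency and is
flagged, never silently treated as 0. The 2×2 present/absent table pools
SLC and SLL as "cultivated" against the wild group; SP is excluded from the
test (the wild group is defined without SP). p-values come from
`scipy.stats.fisher_exact` (two-sided); the test suite proves equality with
exhaustive hypergeometric enumeration over all tables with margins ≤ 30.
BH adjustment is the step-up q(i) = min over j ≥ i of m·p(j)/j, capped at 1,
verified to 1e-12 against statsmodels on random p-vectors. The divergence
flag is q **strictly** < 0.01. Frequency spectra use half-open bins
[0, 0.25), … with the last bin closed at 1.

Consequence classification: an insertion inside a coding exon shifts the
frame iff its length mod 3 ≠ 0; a deletion's removed *coding* base count
decides frame (so a deletion straddling exon/intron boundaries is judged by
what it removes from the CDS, not its total length); a deletion covering at
least one entire coding exon is exon_loss, taking precedence as the more
specific and severe call. The upstream window is 3 kb 5′ of the TSS on the
gene's strand — the distance is a package convention (the source analysis
names no distance) and is exposed as a flag. One record per (SV, gene)
pair. The classifier is validated against a literal per-base overlap
simulator on random fixtures.

## LTR dating

K defaults to the uncorrected p-distance between the aligned LTR ends
(mirroring EMBOSS distmat defaults), with gap and N columns excluded from
numerator and denominator; JC69 (−¾ ln(1 − 4p/3)) is available and is ≥ the
p-distance everywhere, undefined at p ≥ 0.75 (reported as missing).
T = K/(2μ) with μ = 1.3 × 10⁻⁸ site⁻¹ yr⁻¹ interpreted per year. Insertion
ages simulated at 2 Myr are recovered in the modal 250-kyr bin; the back
mutation bias at these divergences (≈0.2% of K) is far below bin width.

## Association scan

The per-marker model is OLS of phenotype on dosage plus covariates, fit by
normal equations with a pseudo-inverse; beta, se and the two-sided t-test
agree with statsmodels to 1e-10 on shared fixtures. Missing genotypes are
dropped per marker (mean-imputed only for PCA and LD pruning); markers
monomorphic after dropping are skipped and logged. PC covariates come from
the SVD of the centred, imputed genotype matrix, signs fixed by the
largest-|score| convention.

Marker filters are strict (> 0.01 MAF, < 0.1 missing). The effective test
count follows the windowed pruning procedure (50-marker window, step 5,
remove the lower-MAF member of any pair with r² > 0.1) and the genome-wide
threshold is 1/n_eff; n_eff is defined *by this procedure* and labelled as
such. PVE uses the published formula with "s.e. × (beta)" read as se(beta)
— the standard error of the effect — since literal multiplication would
double-count beta; after the 2·MAF(1−MAF) cancellation this is
beta²/(beta² + N·se²), which the tests pin down via the se = beta/√N ⇒
PVE = ½ identity and MAF-invariance. Peaks cluster significant markers
within a window (default 800 kb, reusing the overlap flank); a peak is
shared between marker classes iff a peak of the other class lies within
the flank of its lead, and the three classes partition the peak multiset.

Kinship/mixed-model correction (EMMAX-style) is deliberately out of scope;
the five PCs are the structure correction, which suffices for the
PC-generated confounding the simulator produces but not for cryptic
relatedness in real cohorts.

## Problem sizes and numerical choices

Benchmarks run at sizes where every oracle is exact and the whole suite
stays interactive: 8-genome clades (~30 families) for classification
recovery, a 500-kb genome at 1% divergence with 60 SVs (100 bp–10 kb) for
caller recall (≥ 90% with ±k breakpoints), 10 null + 200 power replicates
at the 19-vs-71 group design for the divergence scan, 200 elements for LTR
burst recovery, 400 samples for effect recovery. Degenerate inputs fail
loudly by contract: infeasible gene placement, unknown SVs in a frequency
spec, empty LTR sequences, MAF ∈ {0,1} in PVE, fewer samples than PCs.
Floating-point ties in BH use a stable mergesort; all cluster labels and
representatives are chosen by deterministic (chrom, start) orderings so
outputs never depend on dict or input order.
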