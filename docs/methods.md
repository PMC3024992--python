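# Methods

This note documents the models and procedures implemented in `mhcamp`, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical conventions that affect results.

## The genotyping problem

The target is a 188-bp analysis window of MHC class IIB exon 2, amplified
from a family of dozens of similar loci with one degenerate primer pair and
sequenced as tagged amplicons (one amplicon = one individual × one PCR).
Because alleles cannot be assigned to loci, genotyping reduces to deciding,
for every unique read sequence, whether it is a true allele or an artifact,
and then bounding the locus number from per-individual allele counts.
Frequencies are always computed *within* amplicons: the amplicon is the
unit in which PCR artifacts arise and recur.

## Demultiplexing and the misassignment bound

Reads have the layout `tag (6 bp) + forward primer + target`. The primer is
matched under IUPAC expansion with 0 mismatches by default (a `≤ m`
mismatch option exists); the tag is read immediately 5′ of the match, and
the first 188 bases after the primer are retained. Reads whose post-primer
segment is shorter than the window are dropped — the procedure analyses
fixed-length segments — and reverse-complement scanning is on by default.
The reverse primer is deliberately not required: demanding it discards a
substantial share of otherwise usable reads. Reads with unused tags that
are one substitution from a used tag are never rescued.

With `u` used tags out of `4^6 = 4096`, the unused fraction of tag space is
`(4096 − u)/4096 ≈ 99%`. A tag error therefore lands on an unused tag with
near certainty, so the observed fraction of unused-tag reads bounds the
(unobservable) rate at which reads land on *other used* tags from above.
The bound times mean coverage gives the expected number of misassigned
reads per amplicon; values below ~2 are harmless for any rule requiring an
allele in multiple reads.

## Artifact filtering

**Replication criterion.** A variant is a candidate allele only if it
occurs in ≥ `min_pcrs` (2) amplicons with ≥ `min_copies` (3) reads in each.
Independent PCRs rarely reproduce the same substitution error three times,
so this removes essentially all substitution artifacts; every amplicon
(including replicates of one individual) counts as an independent PCR.

**Chimera classification.** A PCR chimera must co-occur, in the amplicon
where it arose, with both parents at strictly higher abundance. Candidates
are sorted by MPAF (maximum per-amplicon frequency, denominator = the
amplicon's total reads) and processed ascending. For each variant below the
grey-zone bound (`grey_zone_upper` = 1.5% MPAF) the `n_check_amplicons` (3)
amplicons with its highest read count are examined (ties broken by amplicon
frequency, then amplicon id); the variant is labelled a chimera only if a
single-crossover explanation from two strictly more abundant variants
exists in *all* of them, and every label carries a reproducible witness
(parent pair + breakpoint). Variants above the grey zone are accepted
(a seeded spot-check utility exists; a `full_scan` flag forces examination
of everything). Design choices, all deliberate:

* single-crossover model only (a double-crossover search exists behind a
  flag but is quadratic in length and off by default);
* ties in abundance do not qualify as parents — equal-count variants would
  otherwise annihilate each other;
* one pass in ascending MPAF order; a variant already labelled chimera
  remains available as a parent (no re-evaluation cascade);
* any variant observed in the amplicon may serve as parent, not only
  post-filter candidates — this is the more conservative direction for
  chimera calls.

**Threshold derivation and scaling.** The derived threshold is the smallest
putative-allele MPAF strictly above the largest chimera MPAF (the smallest
frequency above which no chimera was seen); with no chimeras it is the
smallest allele MPAF. For sequence classes where alleles are too similar
for reliable per-variant classification (low-divergence pseudogene
clusters), the expressed-class threshold is scaled by the ratio of mean
per-amplicon read proportions — this assumes the PCR recombination rate
per read is class-independent, so expected chimera frequency scales with
class abundance. Scaling is exact arithmetic
(`t × p_target / p_base`, linear to 1e−12).

**Homopolymer indels.** A variant differing from a more abundant variant by
exactly one 1-bp insertion or deletion inside a homopolymer run of length ≥
3 (measured in the more abundant sequence), with no other differences, is
flagged as a sequencing artifact — the dominant pyrosequencing error mode.

## Cluster assignment and phylogenetics

The diagnostic rule ships as configuration with defaults matching the
biology of the system: the first window base separates cluster I (C/T) from
cluster II (G); within cluster II, a 9-bp plus a 1-bp deletion (net 10 —
a frameshift) marks group II.A; an intact frame with no internal stop marks
an expressed allele; anything else is unclassified. Deletion signatures are
detected by global pairwise alignment against a functional reference, not
by hard-coded coordinates. The default reference is the majority-rule
consensus of candidate sequences whose direct translation is stop-free —
a data-driven surrogate for a known expressed allele, overridable by a
user-supplied FASTA. The codon phase of the window start defaults to 0 and
is configurable. A frameshift is defined as any indel-event prefix with net
length ≢ 0 (mod 3); translation is not scanned past the first frame loss.

TN93 distances use pairwise deletion (sites with a gap or ambiguity in
either sequence are excluded); base frequencies come from the two sequences
jointly; non-positive logarithm arguments return infinity (saturation)
rather than a number. Neighbour joining is the canonical Q-matrix
agglomeration (via scikit-bio) and is validated against additive matrices,
where NJ provably recovers the generating topology and branch lengths.
Bootstrap support resamples alignment columns (default 1000 replicates,
seeded); replicates with saturated distances are skipped and count against
support.

## Genotyping and locus bounds

Per amplicon, accepted alleles with ≥ `min_reads` (2) reads are called.
The conservative count then discards every call explainable as a single
crossover of two strictly more abundant *called* alleles in that amplicon —
in one pass over calls in descending abundance, with discarded alleles
remaining in the parent pool, so verdicts are order-independent. This
deliberately over-excludes: a true recombinant allele co-occurring with its
evolutionary parents is indistinguishable from a PCR chimera and is
dropped (a targeted test documents this failure mode). The minimum locus
number is `ceil(max_alleles / ploidy)` with ploidy fixed at 2 (a named
constant, not an option buried in arithmetic).

Replicate concordance follows the printed evidentiary asymmetry: an allele
is *shared* when it has ≥ 1 read in every replicate of an individual, and
*single-replicate* when it has ≥ 2 reads in exactly one replicate and 0 in
all others (with ≥ 3 replicates, "exactly one with evidence, zero
elsewhere" generalises the two-replicate rule).

## Selection statistics

Nei–Gojobori (1986) counting with the MEGA-style stop-codon convention:
at each codon position, the synonymous site fraction is (synonymous
one-step changes)/(non-stop one-step changes), so every sense codon
contributes exactly 3 sites (e.g. Phe TTT → s = 1/3; Trp TGG → s = 0,
n = 3). Multi-difference codon pairs average over all minimal mutational
pathways with equal weights; pathways through stops are excluded, with a
fallback to all pathways when every one is blocked. Site counts are
averaged between the two sequences; pN = Nd/n̄, pS = Sd/s̄; the
Jukes–Cantor correction `d = −(3/4)·ln(1 − 4p/3)` flags saturation at
p ≥ 3/4. Note that Biopython's NG86 counts stop neighbours as nonsynonymous
sites with denominator 3, so the two implementations agree approximately,
not exactly (the test suite uses a pathway-enumeration oracle for exact
checks and Biopython only as a loose cross-check).

`mean_rates` averages pairwise dN, dS over all unordered pairs restricted
to a codon partition (all / ABS / non-ABS). Standard errors come from a
seeded, bit-reproducible codon bootstrap (default 1000 replicates) that
resamples codon columns within the partition; per-pair, per-codon
contribution arrays are precomputed so the bootstrap is vectorised. The
Z-test is `Z = (dN − dS)/√(SE_dN² + SE_dS²)` against the normal reference,
one-tailed for the positive-selection alternative by default (two-sided
available). Calibration: on neutrally evolved alignments with the
dimensions of the real fragment (62 codons, ~10 sequences, ~8% per-site
divergence) the one-tailed test holds its nominal 5% level; on much
smaller alignments (≤ 40 codons, few sequences) it becomes visibly
anticonservative (~7–8%), an intrinsic property of the normal-reference
bootstrap Z-test, not of this implementation.

ABS positions are configuration (a text file of 1-based codon indices),
never hard-coded: which alignment codons contact antigen depends on how the
amplified fragment maps onto the class II β-chain structure, which only the
user can decide.

## The simulator

Defaults are the study conditions: window 188 bp, 6-bp tags, coverage
drawn Normal(541, 166) truncated at 50, per-base PCR substitution rate
1e−3, 5% chimeric reads, 9 expressed / 10 cluster-I / 5 group-II.A diploid
loci drawing from pools of 40 / 25 / 9 alleles, and per-base tag corruption
5.5e−4 (so ~0.33% of reads carry a corrupted tag). Cluster amplification
weights (1.0 / 3.9 / 1.3) are set so mean read proportions approximate
0.164 / 0.718 / 0.118 for expressed / cluster I / II.A given the locus
counts. Expressed alleles derive from a common stop-free ancestor mutated
at half the 10% target pairwise divergence (stops reverted to the ancestral
codon, diagnostic G preserved); cluster I alleles are ≤ 1 substitution from
a cluster ancestor carrying a C/T first base and a shared 1–2 bp mid-window
deletion (pairwise Hamming ≤ 2); II.A alleles likewise, with 9-bp + 1-bp
deletions. Templates carry 15 bp of slack beyond the window so deletions
pull downstream sequence into the window, as in real reads.

Per-allele amplification skew is log-normal (σ = 0.5 per amplicon),
mimicking the unequal amplification that makes idealised equal-amplification
coverage models optimistic. Chimeric reads are allocated to a small number
of per-amplicon chimera *events* (parent pair + uniform breakpoint, ~4
reads each): chimeric molecules form in early PCR cycles and are then
amplified, which is what makes identical chimeras recur within and across
amplicons — with fully independent per-read chimeras, no chimera would ever
meet the replication criterion and the classification stage would be
untestable. Chimeras never seed further chimeras (single-generation
model), and a drawn crossover that reproduces a parent sequence is redrawn.
In low-divergence pools a chimera can still coincide with a *third* true
allele (typically the cluster ancestor); such reads are counted toward the
allele they equal, and the resulting out-of-genotype calls are exactly the
cases the conservative within-amplicon chimera exclusion removes. The
homopolymer indel model applies, per run of length ℓ ≥ 3, an indel with
probability rate × (ℓ − 2) — the simplest monotone length scaling. Tag
corruption is i.i.d. per tag base; corrupted tags may coincide with used
tags, which is precisely the misassignment channel the demultiplexer
bounds.

Not emulated: flowgram-level 454 signal, quality scores, indel errors
outside homopolymers, paired orientation mixtures, contamination, and
PCR-cycle-resolved chimera genealogies. Passing tests therefore show the
procedure's correctness under a faithful but idealised error model, not
performance on any particular instrument's noise profile.

Scales used in the test suite (chosen as desk-scale study conditions):
the stress scenario is 40 amplicons (32 individuals, 25% replicated) at
coverage ~500 with 5% chimeric reads; property suites use 1000 random
amplicons (chimera oracle), 50 additive matrices (NJ), 200 random 30-codon
pairs (Nei–Gojobori) and 1000 neutral alignments (Z-test calibration).

## Degenerate inputs and numerical conventions

* Zero-total amplicons are rejected at table construction; zero-read
  variants cannot enter a table.
* `derive_threshold` raises when no allele MPAF exceeds the largest chimera
  MPAF (no safe zone exists) and when the classification is empty.
* A zero expressed-divergence pool with more than one allele is rejected as
  degenerate rather than silently producing identical "alleles".
* TN93 and Jukes–Cantor saturation is reported as infinity plus exclusion
  from bootstrap aggregation, never as a clamped number.
* Witness search order (parents by descending count then sequence, smallest
  breakpoint) and check-amplicon tie-breaks are fixed, so every
  classification is deterministic and reproducible.
* All stochastic components (simulator, bootstraps, spot-checks) take
  explicit seeds; identical seeds give byte-identical output.
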