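# Methods

## Detection model

A group II intron is called from three kinds of evidence interval ("domain
hits") on a replicon: the reverse-transcriptase (RT) domain of the
intron-encoded protein, RNA domains V–VI, and RNA domains I–IV.  Internally
every interval is 0-based half-open on the forward strand with an explicit
strand; emitted files are 1-based inclusive.  The caller never folds RNA or
models splice sites — it is a distance-and-threshold integrator over
externally produced (or built-in-scanner) homology evidence, which is what
makes it cheap enough for thousands of genomes.

Evidence thresholds (all configurable through `FilterConfig`, defaults in
parentheses, comparison directions exact):

| evidence | rule |
|---|---|
| RT (protein vs nucleotide) | e-value ≤ 1e−10 **and** coverage > 0.40 (strict) |
| RT typing | among co-located surviving hits (same strand, ≥ 1 nt overlap) the highest bit score wins and its query's IEP type labels the locus |
| domains V/VI (covariance model) | bit score > 24 (strict) |
| domains I–IV, alignment route | e-value ≤ 1e−10 and coverage > 0.60 (strict) |
| domains I–IV, covariance-model route | e-value ≤ 1e−2 |

Assembly (`AssemblyConfig`): an RT hit joins a domain V/VI hit when both are
on the same strand, the RT lies upstream in intron orientation (the RT sits
in domain IV, 5′ of domain V), and the nearest-boundary gap is ≤ 1,300 nt —
the empirical 99th-percentile RT-to-domain-V distance in curated introns.
Overlapping intervals clamp the gap to 0; on circular replicons gaps wrap
the origin.  When several pairings are feasible the smallest gap wins, ties
breaking toward the higher RT bit score; each hit joins at most one call.
Greedy nearest-gap pairing is the model here, not a shortcut: the nearest
domain V is the one that belongs to the same intron, and a global
minimum-total-gap matching can differ from it only in contrived overlapping
arrangements (tandem candidates within one 1,300 nt window).  Unpaired
domain V/VI hits with upstream domain I–IV evidence under the same distance
rule become ORF-less calls.  Overlapping domain V/VI hits are collapsed to
the highest-scoring one before assembly.  Nested introns (twintrons) are a
known blind spot: the outer intron's domains are separated by the entire
inner intron and fail the distance rule by construction.

## IEP classification

For each IEP-containing call the region from 1,000 nt upstream of the RT hit
to 200 nt downstream of the domain V/VI hit is extracted in intron
orientation (clamped at linear replicon ends, wrapped on circular ones).
Reference IEP peptides are aligned to the region by translated local search;
stop codons strictly inside the best reference span mark the IEP
*interrupted* (a stop at the final codon is terminal, not internal).
Otherwise the longest ORF overlapping the RT hit is taken (stop-to-stop
segments per frame, first ATG/GTG/TTG start, genetic code 11, "as long as
possible" — so an upstream in-frame start can overestimate the true
initiation site), and the 15 conserved peptide motifs of the call's IEP type
are scored against it: a motif is present when its best ungapped window
reaches 60 % of its self-score.  Five or more missing motifs make the IEP a
*short ORF*; otherwise it is *canonical*.  Interrupted takes precedence over
short-ORF, reproducing a pipeline in which interrupted frames are set aside
before any ORF analysis.  The "≥ 5 of 15" cut and the 60 % per-motif
threshold are fixed readings of decisions that were originally manual; both
are exposed as configuration.

Clustering is greedy-incremental at 85 % identity: sequences longest-first
(ties lexicographic on id), each joining the first cluster whose
representative it matches, else founding its own.  Identity uses the shorter
sequence as denominator (CD-HIT convention) and is computed as
1 − d/|shorter|, where d is the infix (free-end-gap) edit distance of the
shorter sequence inside the longer (edlib).  Stop characters are removed
before clustering, so peptide length shrinks by exactly the number of stops.

## 5′ ends and terminators

Per-type 5′-end consensus alignments become position log-odds profiles:
per column, log2 of (count + 0.1 pseudocount over non-gap total + 0.4)
against a uniform 0.25 background; all-gap columns are dropped; N scores 0
bits.  This PWM scan replaces a profile-HMM scan; the decision rule is kept:
best window within 1,200 nt upstream of the IEP start, accepted at ≥ 10
bits.  Bacterial-G [g1] calls always return no 5′ end (no published
consensus).  CL1 profiles serve CL1A/CL1B and CL2 serves CL2A/CL2B.

Terminator distance = (intron 5′ base) − (terminator 3′ base) along the
strand axis, non-negative, nearest same-strand terminator within 5,000 nt
(the search cap is a package choice; reported distances are typically binned
0–100 … > 1,000).  Terminators downstream of the 5′ end are never matched.
Shape: L if the 10 nt immediately 3′ of the stem–loop contain ≥ 4 T (DNA
sense of U), else I.  The 10 nt tail window is a package decision — the
shape definition names no tail extent.

## Replication geometry and GC skew

*ter* = (*ori* + ⌊L/2⌋) mod L.  Replichore 1 is the ascending arc
*ori* → *ter*; the top (+) strand is leading there and lagging on replichore
2, the bottom strand mirrored.  Positions exactly at *ori* or *ter* belong
to replichore 1.  This convention is stated explicitly because the IB score
depends on it: IB = n_lagging/n_leading, +∞ (flagged, category strong) when
n_leading = 0 with lagging calls present, undefined when both are 0;
IB ≥ 5 strong, 2 ≤ IB < 5 moderate.

GC skew is (G − C)/(G + C) per full window (default 10,000 nt; N excluded
from counts; a window without G or C scores 0 and is flagged; replicons
shorter than one window fall back to a single window).  GCSI cuts the
replicon into 4,096 equal windows (trailing remainder ignored) and combines
two intermediates: `sr`, the discrete-Fourier power at frequency 1 over the
mean power of all nonzero frequencies (how dominant a single two-replichore
cycle is), and `dist`, the range of the cumulative windowed skew — with a
leading zero so the range is exactly reverse-complement invariant — per
window, × 1000.  GCSI = sqrt((sr/6000)·(dist/600)), clipped to [0, 1].  The
normalisation constants are configuration, chosen so that genomes with a
clear two-replichore skew of amplitude ~0.1 score near 0.1, the magnitude
typical of real bacterial chromosomes, and shuffled genomes score near 0.
Genome-level summaries report the GCSI of the longest replicon per assembly.

## Synthetic data

The generator emulates exactly what the detector consumes.  Background
genomes are i.i.d. with a chosen GC fraction and a per-replichore G/C
imbalance of ± amplitude switching at *ori* and *ter*.  Planted elements are
built from a deterministic synthetic parts library (fixed internal seed):
per IEP type a canonical IEP peptide assembled from 15 random motifs
(10–50 aa) with the central motifs 5–11 serving as the RT domain; one
domain V/VI nucleotide motif; domain I–IV motifs; and per-type 5′ consensus
alignments.  An IEP-intron plant is 5′ consensus → spacer → ORF (with an
in-frame stop immediately before the start codon, since upstream intron RNA
is non-coding) → gap → domain V/VI motif; interruptions replace inter-motif
linker codons upstream of the RT with stops, deletions remove motifs outside
the RT span (at most 8, keeping the RT detectable).  Decoys cover each
false-call mode: RT with its nearest domain V/VI at 2,000 nt, a domain V/VI
emitted at 23.9 bits, and domain I evidence on the opposite strand.  Plants
emit both ready-made hit tables (tabular and tblout dialects) and raw
sequence for the built-in scanner, plus a truth table whose expected
outcomes are recomputed from any `AssemblyConfig` (so tightening the gap
threshold flips expectations accordingly).

What the generator does **not** emulate: real RNA secondary structure,
homology gradients between IEP types (parts are random, so cross-type
confusion is easier than in reality, not harder), compositional
heterogeneity (GC islands, repeats), twintrons, and indel-rich divergence.
Passing tests therefore demonstrate the correctness of the decision rules
and arithmetic, not search sensitivity on diverged natural introns — that
sensitivity lives in the external search tools whose output this package
ingests.

The built-in scanner finds candidates by exact k-mer seeding (k = 4 aa, two
seeds per diagonal band, for translated searches; k = 11 nt for nucleotide)
and rescales each candidate window with a Smith–Waterman local alignment
(BLOSUM62, gap −11/−1 for protein; +2/−3, gap −5/−2 for nucleotide).
Bit scores and e-values use fixed Karlin–Altschul-style constants and are
fixture-scale statistics only — never comparable with external-tool
e-values.

## Problem sizes and numerical choices

The test and acceptance suites run at desk scale as a design choice: ten
1 Mb genomes with 5 + 2 planted introns and 3 decoys each for end-to-end
recovery; 60 planted IEPs for status recovery; 50 mutated peptide families
for clustering; 100 × 20 kb genomes for GCSI bounds, 4 × 409.6 kb for
amplitude monotonicity, 20 shuffles of a 204.8 kb genome for the null.
Degenerate inputs are defined rather than left to chance: empty hit lists
yield empty call lists, an all-gap profile column is dropped, a window with
no G/C has skew 0, ties in clustering order break lexicographically, and
every random path is seeded, so reruns are byte-identical.

## Known limitations

Twintron outer introns are not assembled.  Tandem duplicated domain V/VI
regions flanking one IEP can yield an extra ORF-less call alongside the
IEP-containing one (a `collapse_duplicated_dvvi` option merges calls sharing
an RT hit).  Pseudogenised IEPs are reported as calls with non-canonical
status rather than suppressed.  The ORF start can be overestimated when an
upstream in-frame start codon precedes the true initiation site.  Circular
wrapping is honoured in gap arithmetic and region extraction but 5′-profile
windows do not wrap the origin.
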