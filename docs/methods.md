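# Methods

This note records the models behind `conifer-div`, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions that affect results.

## Read filtering

Two library compositions share four primitives.  A read passes the
quality gate when *strictly more than* 90% of its bases have Phred
quality *strictly above* 35 — both comparisons are strict, so an
all-Q35 read fails.  Adapter traces are occurrences of the first
`min_overlap` (default 10) bases of the adapter with at most
`max_mismatch` (default 1) mismatches; because mismatches only
accumulate with prefix length, testing the 10-base prefix is exactly the
existence test for "some adapter prefix of ≥ 10 bases matches here",
and catches both internal fragments and 3' read-through.  The de novo
path rejects any read with a trace, filters homopolymer runs longer
than 20 bp, and finally removes the first 10 and last 11 bases (start
bias in nucleotide composition, end decay in quality), so a clean 76 bp
read leaves at 55 bp.  The mapping path truncates at the leftmost trace
and keeps the read only if more than 30 bp remain.  End trimming
rejects reads that would retain fewer than 2 bases.  By default the
quality gate is judged on the raw read; `quality_before_trim=False`
judges it on the trimmed interior instead (the source protocol does not
say which was used; the raw-read reading is the more literal one, and
the flag exposes the alternative).

## ORF prediction and classification

All six frames are scanned; within each frame the maximal intervals
between stop codons are the candidates, the first ATG in an interval
(if any) defining the start.  ATG is the only recognised start codon.
Coordinates are 0-based half-open on the forward strand; minus-frame
ORFs carry a negative frame label and their coding sequence is the
reverse complement of the reported slice.  The reported extent is
trimmed to start at the ATG when present and to end before the 3' stop.

The presence pattern of {start, upstream stop, downstream stop} maps to
six categories (see README).  Two of the eight boolean patterns are not
in the category list; to make classification total, (no start, both
stops) joins category 4 ("stop2 present, no start") and (no start,
upstream stop only) joins category 6.  Predictions shorter than
`min_aa` (default 10) amino acids are dropped at scan time.  Selection
takes the longest candidate, preferring a category-1/2 candidate within
5 aa of the longest; exact-length ties go to the plus strand, then the
5'-most start, then the lowest frame number, so selection is fully
deterministic.  Only category-1 predictions of ≥ 10 aa are flagged
full-length by default (`--full-length-categories 1,2` widens this to
the reading under which a category-2 ORF, whose 5' stop merely fell
outside the assembled fragment, also counts).

## Orthology and alignment QC

Tabular 12-column hits are filtered on e-value ≤ 1e-5, bit score ≥ 200
and percent identity ≥ 90 (spruce–pine profile) or ≥ 80 (spruce–yew);
the "score 200" threshold is read as the bit score, the 12th column of
the standard tabular format.  A reciprocal best hit requires each
sequence to be the other's unique best subject, best meaning highest
bit score, then lowest e-value, then lexicographically smallest subject
id — the final lexicographic step makes the best hit unique and the
output deterministic.

Peptides of an RBH pair are globally aligned (Needleman–Wunsch, affine
gaps) with BLOSUM62, gap open 10 / extend 1 — conventional alignment
configuration, not data-derived.  QC computes identity over all columns
(gap columns count as non-identical; a flag restricts the denominator
to ungapped columns) and the longest run of consecutive non-identical
columns, gaps counting as mismatches by default.  The thresholds are
"fewer than k consecutive mismatches", so a run of exactly k fails: k=5
for spruce–pine, k=7 for spruce–yew, with overall identity ≥ 50%.
Back-translation maps each aligned residue to its source codon and each
gap to `---`; ungapping either row reproduces the coding sequence
byte-for-byte, and a mismatch between peptide and coding input is an
error naming the offending residue.

The bundled `naive_search` scorer (edit-distance identity, 2·matches as
a score stand-in) exists only so the RBH machinery can be exercised
self-contained; it is not a substitute for a real similarity search.

## Divergence estimation

**NG86 counting.**  Synonymous sites per codon are counted by
single-mutant enumeration: at each position, the fraction of the three
alternative nucleotides that preserve the amino acid, averaged over the
two sequences.  Mutations into stop codons count as non-synonymous, so
S + N = 3 × (compared codon columns) exactly.  For codons differing at
2–3 positions, differences are averaged with equal weight over the
mutational pathways whose intermediates avoid stop codons (all pathways
as a guarded fallback).  Proportions pS = Sd/S and pN = Nd/N are
Jukes–Cantor corrected; a proportion at or beyond 3/4 raises a
saturation error carrying the raw values rather than returning a
number.  Columns with gaps, ambiguity codes or stops are skipped.

**GY94 pairwise ML.**  The rate matrix over the 61 sense codons assigns
single-nucleotide exchanges the rate πⱼ · κ^[transition] ·
ω^[non-synonymous], scaled to one expected substitution per codon per
unit branch length, with F3x4 codon frequencies (products of
position-specific nucleotide frequencies, + 0.5 pseudocount per
nucleotide so rare bases never get zero mass) estimated from the pair.
The pair likelihood Π πᵢ P(t)ᵢⱼ is evaluated from a 61×61
cross-tabulation of codon columns, so each evaluation costs one matrix
exponential regardless of alignment length.  Optimisation is L-BFGS-B
on log(t), log(κ), log(ω) with box constraints (t ∈ [1e-7, 20],
κ ∈ [0.05, 50], ω ∈ [1e-4, 50]), one heuristic start (t from the raw
codon difference fraction) plus seed-controlled random restarts
(3 starts by default), and an `ftol` of 1e-8 on the objective.
Standard errors come from a finite-difference Hessian in log-parameters
via the delta method and are reported as missing when the curvature is
unusable (boundary fits, e.g. identical sequences).  dS and dN
decompose the fitted flux: with ρ_S the synonymous fraction of
stationary substitution flux and ρ_S1 its value at ω = 1 (the
mutational-opportunity definition of sites), dS = t·ρ_S/(3·ρ_S1) and
symmetrically for dN, which makes dN/dS equal ω identically.

Loci with dS = 0 have an undefined ratio; they are reported as missing
and excluded from ω summaries (counted separately), because a small dS
inflates the ratio exactly as a large dN would.  Across-locus means are
unweighted (a length-weighted variant is a one-liner over the per-locus
table).  Bootstrap CIs are percentile intervals over locus resamples of
the mean, seed-deterministic, defaulting to 1000 replicates at the 95%
level.  The per-year rate is r = d̄S/2T; both branches accumulate
divergence since the split, hence the factor 2.

## SNP filter tiers

A candidate SNP carries quality, depth and strand-split allele counts
(DP4).  The ladder is: quality ≥ 60; plus alternate-read fraction in
[0.25, 0.75] (inclusive ends); plus depth ≥ 20 and DP4 ≥ 10.  "DP4 ≥
10" is read as ≥ 10 alternate-supporting reads with at least one on
each strand (`alt-sum`); `each-strand` (≥ 10 per strand) and
`total-sum` (all four counts summed) are selectable because the gloss
"read direction for alternate alleles" does not pin the semantics down.
Allele frequency is computed from read counts, not genotype
likelihoods: with a single individual and expression-dependent depth,
likelihood models calibrated for genome sequencing are the wrong tool.
Tiers are ranked by |ts/tv − reference| with reference 1.3; a tier
keeping nothing, or with zero transversions, is reported but unranked.

## Assembly summaries

N50/N90: sort lengths descending, return the length at which the
running sum first reaches 50%/90% of the total (first crossing; ties
resolved by the sorted order).  The length filter keeps contigs of
≥ 151 bp.  RPKM = count · 10⁹ / (length · total mapped); the
paired/single numerator unit is a documentation flag, the arithmetic is
identical.

## Synthetic-data generators

All generators take explicit seeds, never touch global random state,
and return truth tables beside the data.

*Codon pairs* are drawn exactly from the finite-time law of the GY94
process: the ancestor codon from the stationary distribution, the
descendant from the corresponding row of exp(Qt) — no approximation,
and much faster than event-by-event simulation at the 20 000-codon
sizes used for recovery studies.  Default positional nucleotide
frequencies are mildly uneven (roughly plant-coding-like); they are a
configurable choice, not a calibration.  The generator's expected
NG86-style dS (stationary synonymous flux over NG86 site counts) serves
as the recovery oracle for the counting estimator.

*Transcripts* are assembled codon-wise so that exactly the labelled
category holds on the labelled strand/frame: UTR codons avoid in-frame
stops and ATGs, ORF interiors avoid stops (and starts, where the
category forbids one).  ORF lengths default to uniform 100–300 aa and
UTRs to 0–30 codons; the source assembly's own length histograms are
enriched for short fragments, so these defaults are deliberately
configurable rather than calibrated.  Because other frames of a random
sequence can legitimately contain long ORFs, each transcript is
rejection-sampled until no competing frame has a candidate within 6 aa
of the planted one — the planted prediction is then provably the
selected one, which is what makes exact recovery testing meaningful.
The cost is that the generator does not produce the ambiguous
borderline transcripts real assemblies contain; recovery rates measured
on it say nothing about such cases.

*Variant tables* draw per-site genotypes (heterozygous with probability
`het_fraction` = 0.05 over 50 000 sites by default), Poisson depth
(mean 30), binomial allele counts with reference-allele probability
`ase_skew` (0.5 = balanced expression) and a binomial strand split.
True heterozygotes pick a transition alternate with probability
r/(1+r) so the realised ts/tv hits the target 1.3 in expectation;
injected errors (2% of non-variant sites) pick uniformly among the
three alternates (ts/tv 0.5 — unbiased) at alternate fractions drawn
from U(0.05, 0.24).  Quality is 10 × alternate reads, capped at 255 —
monotone in support, deliberately crude.  Only sites with at least one
alternate read become candidates.  The generator does not model
mapping artifacts, indels or linked errors, so tier behaviour on it
reflects the allele-frequency logic only.

*Reads* are 76 bp with adapter read-through (insert shorter than the
read) at probability 0.2, homopolymer runs > 20 bp at 0.05 and
degraded 3' qualities at 0.2.  Truth flags are recomputed from the
final bases/qualities — including the adapter flag, which records the
leftmost adapter trace under the same ≥ 10 bp / ≤ 1 mismatch definition
the filter uses — so labels stay exact when artifacts overwrite each
other.  Base composition is i.i.d. uniform; there is no quality-error
coupling, PCR duplication or paired-end structure.

## Problem sizes and verification

The test suite verifies the NG86 counting path against an independently
coded brute-force oracle on 1000 random alignments of up to 30 codons
(exact agreement on S, N, Sd, Nd), recovers GY94 ω = 0.2 within ±10% on
20 replicates of 20 000 codons, measures percentile-bootstrap coverage
over 500 sets of 100 gamma-distributed loci (93–97% observed for the
nominal 95%), and checks ORF-category recovery on 1000 planted
transcripts.  These sizes were chosen so the whole suite runs in well
under a minute of estimator time while keeping Monte Carlo noise far
from the asserted margins.  `scripts/acceptance.py` re-runs the same
computations from scratch under a caller-supplied seed.

## Known limitations

* Pairwise comparisons only: no branch or site models, no tree-based
  ML, and deliberately no positive-selection test — with pairwise data
  an ω above 1 is more often a small-dS artifact than selection.
* The GY94 estimator and the codon simulator share the same model
  family by design (recovery tests are then well-specified); recovery
  results do not certify behaviour under model violation
  (selection heterogeneity, non-stationary composition).
* The e-value caps observed in the source study's final orthologue sets
  describe an outcome of its filters, not a rule, and are not applied.
* Whether published across-locus means were length-weighted is unknown;
  unweighted is implemented as the default reading.
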