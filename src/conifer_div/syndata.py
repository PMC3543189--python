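"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators, one per downstream stage:

* orthologous codon-sequence pairs evolved under a GY94 codon model with
  known omega, kappa and divergence, for divergence-estimator recovery;
* transcripts with planted 5'UTR / ORF / 3'UTR structure spanning the six
  ORF categories, for the ORF caller;
* diploid variant tables with controlled heterozygote fraction, ts/tv
  ratio, depth and allele-expression skew, for the SNP filter tiers;
* short reads with adapter read-through, quality decay and homopolymer
  artifacts, for the read-QC stages.

Every generator takes an explicit seed and is deterministic given it;
there is no global random state.  Truth labels are returned alongside
each fixture so tests can score recovery exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from . import gy94
from ._codons import (
    AMINO_ACID,
    NUCLEOTIDES,
    SENSE_CODONS,
    START_CODON,
    STOP_CODONS,
    is_transition,
    revcomp,
    translate_codon,
)
from .readqc import ReadRecord, find_adapter

# Mild plant-coding-like positional nucleotide bias for the F3x4
# equilibrium; configurable per call, uniform would also be valid.
DEFAULT_POSITION_FREQS = np.array(
    [
        [0.27, 0.21, 0.31, 0.21],  # codon position 1: A C G T
        [0.30, 0.23, 0.18, 0.29],  # position 2
        [0.26, 0.24, 0.23, 0.27],  # position 3
    ]
)

ILLUMINA_ADAPTER = "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAG"


# ---------------------------------------------------------------------------
# codon pairs


@dataclass(frozen=True)
class CodonPairTruth:
    """Ground truth for one simulated orthologous coding-sequence pair.

    ``t`` is the expected number of substitutions per codon along the
    whole path separating the two sequences (the sum of both branches of
    the pairwise comparison).
    """

    omega: float
    kappa: float
    t: float
    n_codons: int
    seed: int
    position_freqs: np.ndarray = field(default_factory=lambda: DEFAULT_POSITION_FREQS.copy())

    def validate(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")


def simulate_codon_pair(truth: CodonPairTruth) -> tuple[str, str]:
    """Evolve one sequence from the GY94 equilibrium and a second along
    branch length ``t``, sampling each codon exactly from the finite-time
    law pi_i * P(t)_ij (matrix exponential of the rate matrix).

    Returns two stop-free coding sequences of length 3 * n_codons.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    pi = gy94.f3x4_frequencies(truth.position_freqs)
    ancestors = rng.choice(gy94.N_CODONS, size=truth.n_codons, p=pi)
    if truth.t == 0:
        descendants = ancestors
    else:
        Q = gy94.rate_matrix(truth.kappa, truth.omega, pi)
        P = expm(Q * truth.t)
        P = np.clip(P, 0.0, None)
        P /= P.sum(axis=1, keepdims=True)
        descendants = np.empty_like(ancestors)
        for i in np.unique(ancestors):
            mask = ancestors == i
            descendants[mask] = rng.choice(gy94.N_CODONS, size=mask.sum(), p=P[i])
    seq_a = "".join(SENSE_CODONS[i] for i in ancestors)
    seq_b = "".join(SENSE_CODONS[j] for j in descendants)
    return seq_a, seq_b


def _ng86_syn_site_fraction(pi: np.ndarray) -> float:
    """Expected NG86 synonymous sites per codon at stationarity,
    counted the Nei–Gojobori way (per position, the fraction of the three
    alternative nucleotides giving the same amino acid; changes into stop
    codons count as non-synonymous)."""
    s_bar = 0.0
    for i, codon in enumerate(SENSE_CODONS):
        s = 0.0
        for pos in range(3):
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                mut = codon[:pos] + nt + codon[pos + 1 :]
                if mut not in STOP_CODONS and AMINO_ACID[mut] == AMINO_ACID[codon]:
                    s += 1 / 3
        s_bar += pi[i] * s
    return s_bar


def expected_ng86_divergence(truth: CodonPairTruth) -> tuple[float, float]:
    """The (dS, dN) values implied by the generator's own substitution
    accounting: expected synonymous/non-synonymous substitution flux per
    codon over the pair path, divided by the expected NG86 site counts at
    stationarity.  Serves as the recovery oracle for the counting
    estimator; multiple hits are left to the estimator's own correction.
    """
    pi = gy94.f3x4_frequencies(truth.position_freqs)
    rho_s, rho_n = gy94.flux_fractions(truth.kappa, truth.omega, pi)
    s_sites = _ng86_syn_site_fraction(pi)
    n_sites = 3.0 - s_sites
    return truth.t * rho_s / s_sites, truth.t * rho_n / n_sites


# ---------------------------------------------------------------------------
# transcripts with planted ORF structure


@dataclass(frozen=True)
class TranscriptRecord:
    id: str
    seq: str


@dataclass(frozen=True)
class TranscriptTruth:
    transcript_id: str
    category: int
    frame: int  # +1..+3 forward, -1..-3 reverse
    start_nt: int  # 0-based half-open, forward-strand coordinates
    end_nt: int
    aa_length: int


_SAFE_CODONS = tuple(c for c in SENSE_CODONS if c != START_CODON)  # no stop, no start
_STOPS = tuple(sorted(STOP_CODONS))


def _max_competing_aa(seq: str, planted_frame: int) -> int:
    """Longest candidate ORF (in aa) over all frames except the planted
    one; per maximal inter-stop interval the candidate runs from the
    first ATG if present, else spans the whole interval."""
    best = 0
    for sign, s in ((+1, seq), (-1, revcomp(seq))):
        for off in range(3):
            frame = sign * (off + 1)
            if frame == planted_frame:
                continue
            codons = [s[i : i + 3] for i in range(off, len(s) - 2, 3)]
            interval: list[str] = []
            for codon in itertools.chain(codons, ["TAA"]):  # sentinel stop
                if codon in STOP_CODONS:
                    if interval:
                        if START_CODON in interval:
                            length = len(interval) - interval.index(START_CODON)
                        else:
                            length = len(interval)
                        best = max(best, length)
                    interval = []
                else:
                    interval.append(codon)
    return best


def simulate_transcripts(
    n: int,
    category_mix: "np.ndarray | list[float] | None" = None,
    seed: int = 0,
    orf_aa_range: tuple[int, int] = (100, 300),
    utr_codon_range: tuple[int, int] = (0, 30),
    both_strands: bool = True,
    dominance_margin: int = 6,
    max_resample: int = 200,
) -> tuple[list[TranscriptRecord], list[TranscriptTruth]]:
    """Construct ``n`` transcripts, each planted so that exactly its
    labelled category applies on the labelled strand/frame.

    The planted ORF is rejection-sampled until no other frame contains a
    candidate ORF within ``dominance_margin`` amino acids of it, so that
    downstream ORF selection provably recovers the planted prediction.
    UTR codons avoid in-frame stops and ATGs so no competing candidate
    arises within the planted frame.
    """
    if category_mix is None:
        category_mix = np.full(6, 1 / 6)
    mix = np.asarray(category_mix, dtype=float)
    if mix.shape != (6,) or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
        raise ValueError("category_mix must be 6 non-negative probabilities summing to 1")
    lo, hi = orf_aa_range
    if lo < 1:
        raise ValueError("ORFs must span at least one codon")
    rng = np.random.default_rng(seed)

    records: list[TranscriptRecord] = []
    truths: list[TranscriptTruth] = []
    for idx in range(n):
        category = int(rng.choice(6, p=mix)) + 1
        for _ in range(max_resample):
            orf_len = int(rng.integers(lo, hi + 1))
            n5 = int(rng.integers(utr_codon_range[0], utr_codon_range[1] + 1))
            n3 = int(rng.integers(utr_codon_range[0], utr_codon_range[1] + 1))
            lead = "".join(rng.choice(list(NUCLEOTIDES), size=int(rng.integers(0, 3))))
            tail = "".join(rng.choice(list(NUCLEOTIDES), size=int(rng.integers(0, 3))))

            utr5 = list(rng.choice(_SAFE_CODONS, size=n5))
            utr3 = list(rng.choice(_SAFE_CODONS, size=n3))
            body = list(rng.choice(SENSE_CODONS, size=orf_len - 1))
            nostart_body = list(rng.choice(_SAFE_CODONS, size=orf_len))
            stop1 = str(rng.choice(_STOPS))
            stop2 = str(rng.choice(_STOPS))

            if category == 1:
                codons = utr5 + [stop1, START_CODON] + body + [stop2] + utr3
                orf_codon_start = n5 + 1
            elif category == 2:
                codons = utr5 + [START_CODON] + body + [stop2] + utr3
                orf_codon_start = n5
            elif category == 3:
                codons = utr5 + [stop1, START_CODON] + body
                orf_codon_start = n5 + 1
            elif category == 4:
                codons = nostart_body + [stop2] + utr3
                orf_codon_start = 0
            elif category == 5:
                codons = utr5 + [START_CODON] + body
                orf_codon_start = n5
            else:  # category 6: no start, no stop in the planted frame
                codons = nostart_body
                orf_codon_start = 0
            seq = lead + "".join(codons) + tail

            start_nt = len(lead) + 3 * orf_codon_start
            end_nt = start_nt + 3 * orf_len
            frame = len(lead) + 1  # +1..+3

            if both_strands and rng.random() < 0.5:
                L = len(seq)
                seq = revcomp(seq)
                start_nt, end_nt = L - end_nt, L - start_nt
                frame = -frame

            if _max_competing_aa(seq, frame) <= orf_len - dominance_margin:
                break
        else:
            raise RuntimeError(
                "could not construct a dominance-separated transcript; "
                "widen orf_aa_range or lower dominance_margin"
            )
        tid = f"tx{idx:05d}"
        records.append(TranscriptRecord(tid, seq))
        truths.append(TranscriptTruth(tid, category, frame, start_nt, end_nt, orf_len))
    return records, truths


# ---------------------------------------------------------------------------
# variant tables


@dataclass(frozen=True)
class VariantTruth:
    """Study conditions for the variant-table generator.

    ``ase_skew`` is the probability that a read at a true heterozygote
    carries the reference allele (0.5 = balanced expression).
    """

    n_sites: int = 50_000
    het_fraction: float = 0.05
    tstv_target: float = 1.3
    mean_depth: float = 30.0
    error_rate: float = 0.02
    ase_skew: float = 0.5

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not 0 <= self.het_fraction <= 1:
            raise ValueError("het_fraction must be in [0, 1]")
        if self.tstv_target <= 0:
            raise ValueError("tstv_target must be > 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")
        if not 0 < self.ase_skew < 1:
            raise ValueError("ase_skew must be in (0, 1)")


@dataclass(frozen=True)
class VariantSiteTruth:
    site_id: str
    is_variant: bool  # true heterozygote (vs injected error)
    is_transition: bool


_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}


def simulate_variants(truth: VariantTruth, seed: int = 0):
    """Draw per-site genotypes, depths and strand-split allele counts.

    Only sites with at least one alternate read are emitted (a site with
    no alternate support is not a candidate SNP).  Returns the candidate
    records plus a parallel truth table.  Alternate alleles of true
    heterozygotes are transitions with probability r/(1+r) so the true
    ts/tv ratio hits ``tstv_target`` in expectation; injected errors pick
    among the three alternates uniformly (ts/tv 0.5, i.e. unbiased).
    Variant quality is monotone in alternate-read support.
    """
    from .varfilter import VariantRecord  # local import to avoid cycle at module load

    truth.validate()
    rng = np.random.default_rng(seed)
    p_ts = truth.tstv_target / (1.0 + truth.tstv_target)

    records: list[VariantRecord] = []
    site_truths: list[VariantSiteTruth] = []
    bases = list(NUCLEOTIDES)
    for i in range(truth.n_sites):
        depth = int(rng.poisson(truth.mean_depth))
        if depth == 0:
            continue
        ref = bases[int(rng.integers(4))]
        is_het = rng.random() < truth.het_fraction
        if is_het:
            if rng.random() < p_ts:
                alt = _TRANSITION_OF[ref]
            else:
                choices = [b for b in bases if b != ref and b != _TRANSITION_OF[ref]]
                alt = choices[int(rng.integers(2))]
            alt_total = int(rng.binomial(depth, 1.0 - truth.ase_skew))
        elif rng.random() < truth.error_rate:
            choices = [b for b in bases if b != ref]
            alt = choices[int(rng.integers(3))]
            err_frac = rng.uniform(0.05, 0.24)
            alt_total = int(rng.binomial(depth, err_frac))
        else:
            continue
        if alt_total == 0:
            continue
        ref_total = depth - alt_total
        alt_fwd = int(rng.binomial(alt_total, 0.5))
        ref_fwd = int(rng.binomial(ref_total, 0.5))
        quality = float(min(255, 10 * alt_total))
        site_id = f"site{i:06d}"
        records.append(
            VariantRecord(
                site_id=site_id,
                ref_base=ref,
                alt_base=alt,
                quality=quality,
                depth=depth,
                ref_fwd=ref_fwd,
                ref_rev=ref_total - ref_fwd,
                alt_fwd=alt_fwd,
                alt_rev=alt_total - alt_fwd,
            )
        )
        site_truths.append(VariantSiteTruth(site_id, is_het, is_transition(ref, alt)))
    return records, site_truths


# ---------------------------------------------------------------------------
# reads


@dataclass(frozen=True)
class ReadTruth:
    """Content-derived labels for one simulated read: the leftmost
    adapter trace (>= 10 bp prefix overlap, <= 1 mismatch), any
    homopolymer run over 20 bp, and the strict 90%-over-Q35 rule — all
    recomputed from the final bases/qualities so planted artifacts that
    overwrite each other stay labelled correctly."""

    read_id: str
    adapter_pos: int  # -1 if no adapter trace
    has_long_homopolymer: bool  # any run > 20 bp
    passes_quality: bool  # quality > 35 for more than 90% of bases


def simulate_reads(
    n: int,
    read_len: int = 76,
    adapter: str = ILLUMINA_ADAPTER,
    adapter_prob: float = 0.2,
    homopolymer_prob: float = 0.05,
    low_quality_prob: float = 0.2,
    seed: int = 0,
) -> tuple[list[ReadRecord], list[ReadTruth]]:
    """Short single-end reads with three planted artifact classes:
    adapter read-through (insert shorter than the read), homopolymer
    runs, and degraded 3' qualities.  Truth flags are computed from the
    final bases/qualities, so they stay exact when artifacts interact.
    """
    if read_len < 31:
        raise ValueError("read_len must be >= 31")
    if len(adapter) < 8:
        raise ValueError("adapter must be at least 8 bp")
    rng = np.random.default_rng(seed)
    bases_arr = np.array(list(NUCLEOTIDES))

    reads: list[ReadRecord] = []
    truths: list[ReadTruth] = []
    for i in range(n):
        bases = list(rng.choice(bases_arr, size=read_len))
        adapter_pos = -1
        if rng.random() < adapter_prob:
            adapter_pos = int(rng.integers(12, read_len - 5))
            tail_len = read_len - adapter_pos
            ins = (adapter * (tail_len // len(adapter) + 1))[:tail_len]
            bases[adapter_pos:] = list(ins)
        if rng.random() < homopolymer_prob:
            run_len = int(rng.integers(21, min(35, read_len) + 1))
            start = int(rng.integers(0, read_len - run_len + 1))
            base = bases_arr[int(rng.integers(4))]
            bases[start : start + run_len] = [base] * run_len

        quals = rng.integers(38, 41, size=read_len)
        if rng.random() < low_quality_prob:
            n_bad = int(rng.integers(int(0.12 * read_len), int(0.5 * read_len)))
            quals[read_len - n_bad :] = rng.integers(2, 25, size=n_bad)
        quals = quals.astype(int)

        seq = "".join(bases)
        read = ReadRecord(id=f"read{i:06d}", bases=seq, quals=list(map(int, quals)))
        adapter_pos = find_adapter(seq, adapter)
        run, longest, prev = 0, 0, ""
        for b in seq:
            run = run + 1 if b == prev else 1
            prev = b
            longest = max(longest, run)
        passes_q = (np.sum(quals > 35) / read_len) > 0.90
        reads.append(read)
        truths.append(ReadTruth(read.id, adapter_pos, longest > 20, bool(passes_q)))
    return reads, truths


# ---------------------------------------------------------------------------
# writers (plain-text fixtures)


def write_fasta(records, path) -> None:
    """Write (id, seq) pairs or TranscriptRecords as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqs = []
    for rec in records:
        if isinstance(rec, TranscriptRecord):
            seqs.append(SeqRecord(Seq(rec.seq), id=rec.id, description=""))
        else:
            rid, seq = rec
            seqs.append(SeqRecord(Seq(seq), id=rid, description=""))
    seqio_write(seqs, str(path), "fasta")


def write_fastq(reads: list[ReadRecord], path) -> None:
    """Sanger Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            fh.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")


def write_truth_tsv(truths, path) -> None:
    """Write any list of truth dataclasses as a TSV with a header."""
    import dataclasses

    if not truths:
        raise ValueError("no truth rows to write")
    fields = [f.name for f in dataclasses.fields(truths[0])]
    with open(path, "w") as fh:
        fh.write("\t".join(fields) + "\n")
        for t in truths:
            fh.write("\t".join(str(getattr(t, f)) for f in fields) + "\n")
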