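"""Reciprocal-best-hit orthology, protein-alignment QC and codon
back-translation.

Tabular similarity-search hits (the 12-column BLAST-like format) are
filtered on e-value, bit score and percent identity; reciprocal best
hits across the two directions are taken as putative 1:1 orthologues.
Their peptides are globally aligned, the alignment is gated on overall
identity and on the longest run of consecutive mismatches, and the
protein alignment is back-translated onto the coding nucleotides to
yield the codon alignment consumed by the divergence estimators.

Species-pair thresholds in the source study: identity >= 90% with runs
of < 5 consecutive mismatches for spruce vs pine, >= 80% and < 7 for
spruce vs yew.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from ._codons import STOP_CODONS
from .orf import translate


@dataclass(frozen=True)
class HitRecord:
    """One row of 12-column tabular similarity-search output."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class AlignmentQC:
    identity: float
    max_mismatch_run: int
    n_columns: int
    passed: bool


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-aware paired codon sequences; rows are nucleotide strings over
    codons and '---', equal length, length divisible by 3."""

    id_a: str
    id_b: str
    row_a: str
    row_b: str

    def __post_init__(self):
        if len(self.row_a) != len(self.row_b):
            raise ValueError("codon alignment rows differ in length")
        if len(self.row_a) % 3 != 0:
            raise ValueError("codon alignment length not a multiple of 3")

    @property
    def n_codon_columns(self) -> int:
        return len(self.row_a) // 3

    def codon_columns(self):
        """(codon_a, codon_b) per column, including gapped columns."""
        for i in range(0, len(self.row_a), 3):
            yield self.row_a[i : i + 3], self.row_b[i : i + 3]

    def ungapped(self, which: str) -> str:
        row = self.row_a if which == "a" else self.row_b
        return "".join(c for c in (row[i : i + 3] for i in range(0, len(row), 3)) if c != "---")


@dataclass(frozen=True)
class OrthologPair:
    id_a: str
    id_b: str
    evalue_ab: float
    evalue_ba: float


# ---------------------------------------------------------------------------
# tabular hits


def read_hits(path) -> list[HitRecord]:
    """Parse 12-column tabular hits; malformed rows are reported with
    their line number."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                hits.append(
                    HitRecord(
                        query_id=parts[0],
                        subject_id=parts[1],
                        pct_identity=float(parts[2]),
                        align_len=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        q_start=int(parts[6]),
                        q_end=int(parts[7]),
                        s_start=int(parts[8]),
                        s_end=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return hits


def write_hits(hits, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t{h.align_len}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.q_start}\t{h.q_end}\t{h.s_start}\t"
                f"{h.s_end}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


def filter_hits(hits, min_score: float = 200.0, max_evalue: float = 1e-5,
                min_identity: float = 90.0) -> list[HitRecord]:
    """Keep hits with evalue <= max_evalue, bit score >= min_score and
    percent identity >= min_identity."""
    return [
        h
        for h in hits
        if h.evalue <= max_evalue and h.bitscore >= min_score and h.pct_identity >= min_identity
    ]


def _best_hits(hits) -> dict[str, HitRecord]:
    """Unique best subject per query: highest bit score, then lowest
    e-value, then lexicographically smallest subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (
            (-h.bitscore, h.evalue, h.subject_id) < (-cur.bitscore, cur.evalue, cur.subject_id)
        ):
            best[h.query_id] = h
    return best


def reciprocal_best(hits_ab, hits_ba) -> list[OrthologPair]:
    """Putative 1:1 orthologues: (a, b) such that b is a's best subject
    and a is b's best subject.  Each id appears in at most one pair."""
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = []
    for a, hit in sorted(best_ab.items()):
        b = hit.subject_id
        back = best_ba.get(b)
        if back is not None and back.subject_id == a:
            pairs.append(OrthologPair(id_a=a, id_b=b, evalue_ab=hit.evalue, evalue_ba=back.evalue))
    return pairs


# ---------------------------------------------------------------------------
# protein alignment and QC


def make_aligner(matrix: str = "BLOSUM62", gap_open: float = 10.0,
                 gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_proteins(pep_a: str, pep_b: str, aligner: Align.PairwiseAligner | None = None
                   ) -> tuple[str, str]:
    """Global (Needleman–Wunsch, affine-gap) alignment of two peptides;
    deterministic for fixed parameters (first optimal traceback)."""
    if not pep_a or not pep_b:
        raise ValueError("peptides must be non-empty")
    if aligner is None:
        aligner = make_aligner()
    alignment = aligner.align(pep_a, pep_b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    return row_a, row_b


def align_qc(row_a: str, row_b: str, min_identity: float = 0.50,
             max_consec_mismatch: int = 5, gaps_are_mismatches: bool = True,
             identity_over_gapped: bool = True) -> AlignmentQC:
    """Identity and consecutive-mismatch gate for a protein alignment.

    A column is identical iff both residues are equal and neither is a
    gap.  The alignment fails if identity < ``min_identity`` or any run
    of non-identical columns reaches ``max_consec_mismatch`` (the
    threshold reads "fewer than k consecutive mismatches", so a run of
    exactly k fails).
    """
    if len(row_a) != len(row_b):
        raise ValueError("alignment rows differ in length")
    if not row_a:
        raise ValueError("empty alignment")
    n_cols = len(row_a)
    n_ident = 0
    n_ungapped = 0
    run = 0
    max_run = 0
    for a, b in zip(row_a, row_b):
        is_gap = a == "-" or b == "-"
        if not is_gap:
            n_ungapped += 1
        identical = not is_gap and a == b
        if identical:
            n_ident += 1
            run = 0
        else:
            if is_gap and not gaps_are_mismatches:
                run = 0
            else:
                run += 1
                max_run = max(max_run, run)
    denom = n_cols if identity_over_gapped else max(n_ungapped, 1)
    identity = n_ident / denom
    passed = identity >= min_identity and max_run < max_consec_mismatch
    return AlignmentQC(identity=identity, max_mismatch_run=max_run,
                       n_columns=n_cols, passed=passed)


def back_translate(row_a: str, row_b: str, coding_a: str, coding_b: str,
                   id_a: str = "a", id_b: str = "b") -> CodonAlignment:
    """Map each amino-acid column to its source codon and each gap to
    '---'; ungapping either output row reproduces its coding sequence."""
    out = []
    for row, coding in ((row_a, coding_a), (row_b, coding_b)):
        codons = [coding[i : i + 3] for i in range(0, len(coding), 3)]
        if codons and codons[-1].upper() in STOP_CODONS:
            codons = codons[:-1]
        peptide = translate("".join(codons))
        ungapped = row.replace("-", "")
        if peptide != ungapped:
            for k, (p, r) in enumerate(zip(peptide, ungapped)):
                if p != r:
                    raise ValueError(
                        f"peptide/coding mismatch at residue {k}: alignment has "
                        f"{r!r}, coding sequence translates to {p!r}"
                    )
            raise ValueError(
                f"peptide length {len(ungapped)} does not match coding "
                f"sequence ({len(peptide)} aa)"
            )
        it = iter(codons)
        out.append("".join("---" if aa == "-" else next(it) for aa in row))
    return CodonAlignment(id_a=id_a, id_b=id_b, row_a=out[0], row_b=out[1])


def write_codon_alignment(aln: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{aln.id_a}\n{aln.row_a}\n>{aln.id_b}\n{aln.row_b}\n")


def read_codon_alignments(path) -> list[CodonAlignment]:
    """Aligned FASTA holding consecutive row pairs."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2 != 0:
        raise ValueError(f"{path}: expected an even number of aligned rows")
    alns = []
    for i in range(0, len(records), 2):
        alns.append(
            CodonAlignment(
                id_a=records[i].id,
                id_b=records[i + 1].id,
                row_a=str(records[i].seq).upper(),
                row_b=str(records[i + 1].seq).upper(),
            )
        )
    return alns


# ---------------------------------------------------------------------------
# self-contained similarity scorer (test/demo plumbing only)


def naive_search(queries, subjects, min_overlap_frac: float = 0.5):
    """A deliberately simple all-vs-all nucleotide scorer emitting
    12-column-style hits, so the RBH machinery can be exercised without
    an external search engine.  Identity comes from an edit-distance
    alignment; the bit-score stand-in is 2 * matched bases.  Not a
    substitute for a real similarity search on real data.
    """
    import edlib

    hits = []
    for qid, qseq in queries:
        for sid, sseq in subjects:
            res = edlib.align(qseq, sseq, task="distance", mode="NW")
            dist = res["editDistance"]
            align_len = max(len(qseq), len(sseq))
            matches = align_len - dist
            if matches < min_overlap_frac * min(len(qseq), len(sseq)):
                continue
            identity = 100.0 * matches / align_len
            score = 2.0 * matches
            evalue = 2.0 ** (-score / 10.0)
            hits.append(
                HitRecord(
                    query_id=qid, subject_id=sid, pct_identity=identity,
                    align_len=align_len, mismatches=dist, gap_opens=0,
                    q_start=1, q_end=len(qseq), s_start=1, s_end=len(sseq),
                    evalue=evalue, bitscore=score,
                )
            )
    return hits
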