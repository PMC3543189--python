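"""Six-frame ORF scanning, six-category classification and selection.

Candidate reading frames are the maximal intervals between stop codons
in each of the six frames.  Within an interval the first ATG (if any)
defines the start; the bounding stops are called stop1 (5') and stop2
(3').  The presence pattern of {start, stop1, stop2} assigns each
candidate to one of six categories:

  1. start with both stop1 and stop2           (putative full-length)
  2. start and stop2 only
  3. start and stop1 only
  4. stop2 but no start
  5. start only, no stop at all
  6. neither start nor stop

Two boolean patterns the category list does not name are folded in so
the mapping is total: (no start, stop1+stop2) -> 4 and
(no start, stop1 only) -> 6.

Per transcript, the longest candidate is selected — unless the runner-up
is within 5 amino acids and sits in category 1 or 2 while the longest
does not, in which case the category-1/2 candidate wins.  Category-1
predictions of at least 10 amino acids are flagged full-length.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._codons import START_CODON, STOP_CODONS, revcomp, translate_codon

FULL_LENGTH_CATEGORIES = (1,)


@dataclass(frozen=True)
class OrfPrediction:
    """A candidate reading frame.  Coordinates are 0-based half-open on
    the forward strand regardless of frame sign; for minus frames the
    coding sequence is the reverse complement of seq[start_nt:end_nt]."""

    transcript_id: str
    frame: int  # +1,+2,+3,-1,-2,-3
    start_nt: int
    end_nt: int
    has_start: bool
    has_stop1: bool
    has_stop2: bool

    @property
    def aa_length(self) -> int:
        return (self.end_nt - self.start_nt) // 3

    @property
    def category(self) -> int:
        return categorize(self.has_start, self.has_stop1, self.has_stop2)

    def coding_sequence(self, seq: str) -> str:
        sub = seq[self.start_nt : self.end_nt]
        return sub if self.frame > 0 else revcomp(sub)


def categorize(has_start: bool, has_stop1: bool, has_stop2: bool) -> int:
    """Total mapping from the three presence booleans to the category."""
    if has_start:
        if has_stop1 and has_stop2:
            return 1
        if has_stop2:
            return 2
        if has_stop1:
            return 3
        return 5
    return 4 if has_stop2 else 6


def translate(coding: str) -> str:
    """Standard-code translation of a coding sequence; a single terminal
    stop is dropped, an internal stop or a non-triplet length is an
    error."""
    if len(coding) % 3 != 0:
        raise ValueError(f"coding sequence length {len(coding)} is not a multiple of 3")
    codons = [coding[i : i + 3] for i in range(0, len(coding), 3)]
    if codons and codons[-1].upper() in STOP_CODONS:
        codons = codons[:-1]
    peptide = []
    for i, codon in enumerate(codons):
        aa = translate_codon(codon)
        if aa == "*":
            raise ValueError(f"internal stop codon {codon} at codon {i}")
        peptide.append(aa)
    return "".join(peptide)


def scan_orfs(seq: str, transcript_id: str = "", min_aa: int = 10) -> list[OrfPrediction]:
    """All candidate ORFs over the six frames of ``seq``.

    Candidates shorter than ``min_aa`` amino acids are dropped.  The
    reported extent is already trimmed: it starts at the ATG when a
    start is present (else just after stop1 / at the frame edge) and
    ends just before stop2 (else at the last whole codon).
    """
    seq = seq.upper()
    L = len(seq)
    if L < 3:
        return []
    preds: list[OrfPrediction] = []
    for sign in (+1, -1):
        s = seq if sign > 0 else revcomp(seq)
        for off in range(3):
            frame = sign * (off + 1)
            n_codons = (L - off) // 3
            # stop positions (codon indices) in this frame
            stops = [
                k
                for k in range(n_codons)
                if s[off + 3 * k : off + 3 * k + 3] in STOP_CODONS
            ]
            bounds = [-1] + stops + [n_codons]
            for b_idx in range(len(bounds) - 1):
                lo = bounds[b_idx]  # codon index of stop1, or -1
                hi = bounds[b_idx + 1]  # codon index of stop2, or n_codons
                first, last = lo + 1, hi  # interval codons [first, last)
                if last <= first:
                    continue
                has_stop1 = lo >= 0
                has_stop2 = hi < n_codons
                start_codon = None
                for k in range(first, last):
                    if s[off + 3 * k : off + 3 * k + 3] == START_CODON:
                        start_codon = k
                        break
                if start_codon is not None:
                    first = start_codon
                aa_len = last - first
                if aa_len < min_aa:
                    continue
                # coordinates on the scanned strand
                start_s = off + 3 * first
                end_s = off + 3 * last
                if sign > 0:
                    start_nt, end_nt = start_s, end_s
                else:
                    start_nt, end_nt = L - end_s, L - start_s
                preds.append(
                    OrfPrediction(
                        transcript_id=transcript_id,
                        frame=frame,
                        start_nt=start_nt,
                        end_nt=end_nt,
                        has_start=start_codon is not None,
                        has_stop1=has_stop1,
                        has_stop2=has_stop2,
                    )
                )
    return preds


def _selection_key(p: OrfPrediction):
    # longest first; ties: + strand before -, then 5'-most, then frame
    return (-p.aa_length, 0 if p.frame > 0 else 1, p.start_nt, abs(p.frame))


def select_orf(candidates: list[OrfPrediction], tie_aa: int = 5,
               preferred_categories: tuple[int, ...] = (1, 2)) -> OrfPrediction:
    """The most likely ORF among a transcript's candidates: the longest,
    except that within a ``tie_aa`` amino-acid window a category-1/2
    candidate outranks one from the other categories."""
    if not candidates:
        raise ValueError("no ORF candidates to select from")
    ranked = sorted(candidates, key=_selection_key)
    best = ranked[0]
    if best.category not in preferred_categories:
        window = [
            p
            for p in ranked
            if best.aa_length - p.aa_length <= tie_aa
            and p.category in preferred_categories
        ]
        if window:
            return window[0]
    return best


def is_full_length(p: OrfPrediction, min_aa: int = 10,
                   categories: tuple[int, ...] = FULL_LENGTH_CATEGORIES) -> bool:
    """Putative full-length: category 1 (start between stop1 and stop2)
    with at least ``min_aa`` amino acids."""
    return p.category in categories and p.aa_length >= min_aa


def predict(records, min_aa: int = 10):
    """Scan and select one ORF per transcript.

    Yields (record, prediction) pairs; transcripts with no candidate of
    at least ``min_aa`` amino acids are skipped.
    """
    for rec in records:
        candidates = scan_orfs(rec.seq, rec.id, min_aa=min_aa)
        if not candidates:
            continue
        yield rec, select_orf(candidates)


def write_predictions_tsv(pairs, path) -> None:
    """TSV of selected predictions (one row per transcript)."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tframe\tstart_nt\tend_nt\tcategory\taa_length\tfull_length\n")
        for _, p in pairs:
            fh.write(
                f"{p.transcript_id}\t{p.frame:+d}\t{p.start_nt}\t{p.end_nt}\t"
                f"{p.category}\t{p.aa_length}\t{int(is_full_length(p))}\n"
            )
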