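"""Read filtering producing the de novo and mapping libraries.

Two compositions of four primitive filters:

* de novo library: quality filter -> adapter rejection -> homopolymer
  filter -> end trimming (first 10 / last 11 bases), yielding 55 bp
  reads from 76 bp input;
* mapping library: quality filter -> adapter trimming, retaining the
  trimmed read only if longer than 30 bp.

Quality comparisons are strict: a read passes when strictly more than
90% of its bases have Phred quality strictly above 35.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


class ReadTooShortError(ValueError):
    """End trimming would leave nothing of the read."""


@dataclass(frozen=True)
class ReadRecord:
    """A read with per-base Phred qualities (Sanger scale)."""

    id: str
    bases: str
    quals: list[int]

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise ValueError(f"{self.id}: bases and qualities differ in length")

    def __len__(self) -> int:
        return len(self.bases)


def quality_pass(read: ReadRecord, q_min: int = 35, frac: float = 0.90) -> bool:
    """True iff strictly more than ``frac`` of bases have quality
    strictly greater than ``q_min``."""
    if len(read) == 0:
        raise ValueError("empty read")
    n_good = sum(1 for q in read.quals if q > q_min)
    return n_good / len(read) > frac


def find_adapter(
    bases: str, adapter: str, min_overlap: int = 10, max_mismatch: int = 1
) -> int:
    """Leftmost position showing a trace of the adapter, or -1.

    A trace is an occurrence of the adapter prefix of ``min_overlap``
    bases with at most ``max_mismatch`` mismatches.  Since mismatches
    only accumulate with prefix length, this is exactly the existence
    test for "some adapter prefix of at least min_overlap bases matches
    here" — it catches both internal fragments and read-through hanging
    off the 3' end.
    """
    if len(adapter) < 8:
        raise ValueError("adapter must be at least 8 bp")
    k = min(min_overlap, len(adapter))
    prefix = adapter[:k]
    L = len(bases)
    for i in range(0, L - k + 1):
        mism = 0
        for a, b in zip(bases[i : i + k], prefix):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return i
    return -1


def adapter_process(
    read: ReadRecord,
    adapter: str,
    mode: str,
    min_len: int = 31,
    min_overlap: int = 10,
    max_mismatch: int = 1,
) -> ReadRecord | None:
    """De novo mode rejects any read with an adapter trace; mapping mode
    truncates at the leftmost match and keeps the read only if at least
    ``min_len`` (i.e. longer than 30 bp) remains.  Returns None on
    rejection."""
    if mode not in ("denovo", "mapping"):
        raise ValueError(f"unknown mode {mode!r}")
    pos = find_adapter(read.bases, adapter, min_overlap, max_mismatch)
    if pos < 0:
        return read
    if mode == "denovo":
        return None
    if pos < min_len:
        return None
    return replace(read, bases=read.bases[:pos], quals=read.quals[:pos])


def homopolymer_pass(read: ReadRecord, max_run: int = 20) -> bool:
    """False iff any single-base run longer than ``max_run`` exists."""
    run, prev = 0, ""
    for b in read.bases:
        run = run + 1 if b == prev else 1
        prev = b
        if run > max_run:
            return False
    return True


def end_trim(read: ReadRecord, head: int = 10, tail: int = 11) -> ReadRecord:
    """Drop the first ``head`` and last ``tail`` bases (nucleotide
    composition bias at read starts, quality decay at read ends).
    A read that would retain fewer than 2 bases is rejected — a 1 bp
    remainder carries no usable sequence."""
    if len(read) - head - tail < 2:
        raise ReadTooShortError(
            f"{read.id}: {len(read)} bp read cannot lose {head}+{tail} bp"
        )
    return replace(read, bases=read.bases[head : len(read) - tail],
                   quals=read.quals[head : len(read) - tail])


def build_library(
    reads,
    mode: str,
    adapter: str,
    q_min: int = 35,
    q_frac: float = 0.90,
    max_run: int = 20,
    head: int = 10,
    tail: int = 11,
    min_len: int = 31,
    min_overlap: int = 10,
    max_mismatch: int = 1,
    quality_before_trim: bool = True,
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Compose the stages into one of the two libraries.

    Returns the kept reads and a per-stage report; at every stage
    kept + rejected = input to that stage.  ``quality_before_trim``
    evaluates the 90%-over-Q35 rule on the raw read (default); with
    False the de novo path trims first and judges quality on the
    55 bp interior.
    """
    if mode not in ("denovo", "mapping"):
        raise ValueError(f"unknown mode {mode!r}")
    report = {"input": 0, "fail_quality": 0, "fail_adapter": 0}
    if mode == "denovo":
        report.update({"fail_homopolymer": 0, "fail_too_short": 0})
    kept: list[ReadRecord] = []
    for read in reads:
        report["input"] += 1
        if quality_before_trim and not quality_pass(read, q_min, q_frac):
            report["fail_quality"] += 1
            continue
        processed = adapter_process(read, adapter, mode, min_len, min_overlap, max_mismatch)
        if processed is None:
            report["fail_adapter"] += 1
            continue
        if mode == "denovo":
            if not homopolymer_pass(processed, max_run):
                report["fail_homopolymer"] += 1
                continue
            try:
                processed = end_trim(processed, head, tail)
            except ReadTooShortError:
                report["fail_too_short"] += 1
                continue
        if not quality_before_trim and not quality_pass(processed, q_min, q_frac):
            report["fail_quality"] += 1
            continue
        kept.append(processed)
    report["kept"] = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# FASTQ I/O


def read_fastq(path, offset: int = 33) -> list[ReadRecord]:
    """Parse FASTQ; ``offset=64`` handles the old Illumina 1.3 dialect."""
    reads = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            bases = fh.readline().rstrip("\n")
            plus = fh.readline()
            quals = fh.readline().rstrip("\n")
            lineno += 4
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed FASTQ record near line {lineno}")
            reads.append(
                ReadRecord(
                    id=header[1:].split()[0],
                    bases=bases.upper(),
                    quals=[ord(c) - offset for c in quals],
                )
            )
    return reads


def write_fastq(reads, path, offset: int = 33) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + offset) for q in read.quals)
            fh.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")


def write_report(report: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tcount\n")
        for stage, count in report.items():
            fh.write(f"{stage}\t{count}\n")
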