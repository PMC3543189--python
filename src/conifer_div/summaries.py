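"""Assembly and expression summary statistics: N50/N90, the minimum
contig-length filter, and RPKM."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Contig:
    id: str
    length: int
    mapped_reads: int = 0

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"{self.id}: contig length must be >= 1")
        if self.mapped_reads < 0:
            raise ValueError(f"{self.id}: mapped read count must be >= 0")


def n_stat(lengths, fraction: float = 0.5) -> int:
    """Nxx statistic: sort lengths descending and return the length at
    which the running sum first reaches ``fraction`` of the total
    (N50 for 0.5, N90 for 0.9)."""
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise ValueError("no contig lengths given")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    threshold = fraction * sum(lengths)
    running = 0
    for length in lengths:
        running += length
        if running >= threshold:
            return length
    return lengths[-1]  # unreachable, guards float edge cases


def length_filter(contigs, min_len: int = 151):
    """Keep contigs of at least ``min_len`` bp (i.e. longer than
    min_len - 1)."""
    return [c for c in contigs if c.length >= min_len]


def rpkm(count: float, length_bp: int, total_mapped: int, paired: bool = True) -> float:
    """Reads per kilobase of transcript per million mapped reads.

    ``paired=True`` treats the counts as read-pair (fragment) hits,
    ``paired=False`` as single-end hits; the arithmetic is identical,
    the flag only documents the numerator unit in reports.
    """
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    return count * 1e9 / (length_bp * total_mapped)


def assembly_report(contigs) -> dict[str, float]:
    """Summary block: counts, mean/total length, N50/N90, mean RPKM."""
    contigs = list(contigs)
    if not contigs:
        raise ValueError("empty contig set")
    lengths = [c.length for c in contigs]
    total_mapped = sum(c.mapped_reads for c in contigs)
    report = {
        "n_contigs": len(contigs),
        "total_bp": int(sum(lengths)),
        "mean_length": float(np.mean(lengths)),
        "n50": n_stat(lengths, 0.5),
        "n90": n_stat(lengths, 0.9),
    }
    if total_mapped > 0:
        report["mean_rpkm"] = float(
            np.mean([rpkm(c.mapped_reads, c.length, total_mapped) for c in contigs])
        )
    return report


def read_contigs_tsv(path):
    """TSV with columns id, length, mapped_reads."""
    contigs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["id", "length"]:
            raise ValueError(f"{path}: expected columns id, length[, mapped_reads]")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            contigs.append(
                Contig(
                    id=parts[0],
                    length=int(parts[1]),
                    mapped_reads=int(parts[2]) if len(parts) > 2 else 0,
                )
            )
    return contigs


def contigs_from_fasta(path, counts: dict[str, int] | None = None):
    from Bio import SeqIO

    counts = counts or {}
    return [
        Contig(id=rec.id, length=len(rec.seq), mapped_reads=counts.get(rec.id, 0))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
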