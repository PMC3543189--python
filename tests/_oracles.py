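"""Independent brute-force oracles used by the tests.

Deliberately shares no code with the package: amino acids come from
Biopython's translation table, enumeration is naive, and everything is
written for clarity over speed.
"""

from __future__ import annotations

import itertools

from Bio.Seq import Seq

BASES = "ACGT"


def aa_of(codon: str) -> str:
    return str(Seq(codon).translate())


def is_stop(codon: str) -> bool:
    return aa_of(codon) == "*"


def oracle_syn_sites(codon: str) -> float:
    """Synonymous sites of one codon by direct single-mutant listing;
    a mutation creating a stop codon counts as non-synonymous."""
    s = 0.0
    for pos in range(3):
        for nt in BASES:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if not is_stop(mutant) and aa_of(mutant) == aa_of(codon):
                s += 1.0 / 3.0
    return s


def oracle_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) difference counts between two sense
    codons: equal-weight average over every mutational order whose
    intermediates avoid stop codons (all orders if none avoids them)."""
    positions = [k for k in range(3) if c1[k] != c2[k]]
    clean, blocked = [], []
    for order in itertools.permutations(positions):
        current = c1
        sd = nd = 0.0
        hit_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if is_stop(nxt):
                hit_stop = True
            if not is_stop(nxt) and not is_stop(current) and aa_of(nxt) == aa_of(current):
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        (blocked if hit_stop else clean).append((sd, nd))
    pool = clean if clean else blocked
    return (sum(p[0] for p in pool) / len(pool), sum(p[1] for p in pool) / len(pool))


def oracle_ng86_counts(codons_a: list[str], codons_b: list[str]):
    """S, N, Sd, Nd for an aligned pair of sense-codon lists."""
    assert len(codons_a) == len(codons_b)
    sites_a = sum(oracle_syn_sites(c) for c in codons_a)
    sites_b = sum(oracle_syn_sites(c) for c in codons_b)
    S = (sites_a + sites_b) / 2.0
    N = 3.0 * len(codons_a) - S
    Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if ca != cb:
            sd, nd = oracle_pair_differences(ca, cb)
            Sd += sd
            Nd += nd
    return S, N, Sd, Nd


def oracle_global_alignment_score(
    a: str, b: str, match: float, mismatch: float, gap_open: float, gap_extend: float
) -> float:
    """Optimal global affine-gap alignment score by exhaustive
    enumeration of all alignments (exponential; tiny inputs only).

    Gap scoring convention matches Biopython's PairwiseAligner:
    a gap of length L costs gap_open + (L - 1) * gap_extend.
    """

    best = [float("-inf")]

    def extend(i: int, j: int, score: float, state: str):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            extend(i + 1, j + 1, score + s, "m")
        if i < len(a):
            cost = -gap_extend if state == "ga" else -gap_open
            extend(i + 1, j, score + cost, "ga")
        if j < len(b):
            cost = -gap_extend if state == "gb" else -gap_open
            extend(i, j + 1, score + cost, "gb")

    extend(0, 0, 0.0, "start")
    return best[0]
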