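"""Tiered SNP filtering calibrated by the transition/transversion ratio.

Candidate SNPs from a single sequenced individual carry a high false-
positive load, and the usual genotype-likelihood machinery is unreliable
when read depth tracks expression rather than copy number.  The approach
here filters candidates through nested tiers — quality; quality plus a
minor-allele-frequency window; quality, AF, depth and strand-split
alternate-read support (DP4) — and ranks the tiers by how closely the
ts/tv ratio of the surviving set matches an external reference ratio
(about 1.3 for spruce Sanger population data).  Sequencing errors are
ts/tv-unbiased (ratio 0.5), so a kept set enriched for true variants
moves toward the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._codons import is_transition

DP4_RULES = ("alt-sum", "each-strand", "total-sum")


@dataclass(frozen=True)
class VariantRecord:
    """One candidate SNP with strand-split allele counts (DP4)."""

    site_id: str
    ref_base: str
    alt_base: str
    quality: float
    depth: int
    ref_fwd: int
    ref_rev: int
    alt_fwd: int
    alt_rev: int

    def __post_init__(self):
        if self.ref_base == self.alt_base:
            raise ValueError(f"{self.site_id}: ref and alt bases are identical")
        if self.ref_fwd + self.ref_rev + self.alt_fwd + self.alt_rev > self.depth:
            raise ValueError(f"{self.site_id}: allele counts exceed depth")

    @property
    def alt_total(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def alt_frac(self) -> float:
        supporting = self.ref_fwd + self.ref_rev + self.alt_total
        return self.alt_total / supporting if supporting else 0.0


@dataclass(frozen=True)
class FilterTier:
    """One row of the filtering ladder; None disables a constraint.
    The allele-frequency window is on the alternate-read fraction and is
    inclusive at both ends."""

    name: str
    min_quality: float
    af_window: tuple[float, float] | None = None
    min_depth: int | None = None
    min_dp4: int | None = None
    dp4_rule: str = "alt-sum"

    def __post_init__(self):
        if self.dp4_rule not in DP4_RULES:
            raise ValueError(f"dp4_rule must be one of {DP4_RULES}")

    def accepts(self, rec: VariantRecord) -> bool:
        if rec.quality < self.min_quality:
            return False
        if self.af_window is not None:
            lo, hi = self.af_window
            if not (lo <= rec.alt_frac <= hi):
                return False
        if self.min_depth is not None and rec.depth < self.min_depth:
            return False
        if self.min_dp4 is not None:
            if self.dp4_rule == "alt-sum":
                # alternate support >= threshold, seen on both strands
                if rec.alt_total < self.min_dp4 or rec.alt_fwd < 1 or rec.alt_rev < 1:
                    return False
            elif self.dp4_rule == "each-strand":
                if rec.alt_fwd < self.min_dp4 or rec.alt_rev < self.min_dp4:
                    return False
            else:  # total-sum over all four DP4 counts
                if rec.ref_fwd + rec.ref_rev + rec.alt_total < self.min_dp4:
                    return False
        return True


#: The three tiers of the source study's filtering ladder.
DEFAULT_TIERS = (
    FilterTier(name="qual60", min_quality=60),
    FilterTier(name="qual60_af", min_quality=60, af_window=(0.25, 0.75)),
    FilterTier(name="qual60_af_depth_dp4", min_quality=60, af_window=(0.25, 0.75),
               min_depth=20, min_dp4=10),
)


@dataclass(frozen=True)
class TierCounts:
    tier: str
    n: int
    transitions: int
    transversions: int

    @property
    def ratio(self) -> float | None:
        return tstv_ratio(self.transitions, self.transversions) if self.transversions else None


def classify_substitution(ref: str, alt: str) -> str:
    """'transition' for A<->G and C<->T, 'transversion' for the other
    eight ordered base pairs."""
    ref, alt = ref.upper(), alt.upper()
    for b in (ref, alt):
        if b not in "ACGT":
            raise ValueError(f"ambiguous or invalid base {b!r}")
    if ref == alt:
        raise ValueError("identical bases do not form a substitution")
    return "transition" if is_transition(ref, alt) else "transversion"


def apply_tier(records, tier: FilterTier) -> tuple[list[VariantRecord], TierCounts]:
    kept = [r for r in records if tier.accepts(r)]
    ts = sum(1 for r in kept if is_transition(r.ref_base, r.alt_base))
    return kept, TierCounts(tier=tier.name, n=len(kept), transitions=ts,
                            transversions=len(kept) - ts)


def tstv_ratio(ts: int, tv: int) -> float:
    """Transitions over transversions; undefined (error) when tv = 0."""
    if tv <= 0:
        raise ZeroDivisionError("no transversions: ts/tv ratio undefined")
    return ts / tv


def calibrate(records, tiers=DEFAULT_TIERS, reference_ratio: float = 1.3):
    """Rank tiers by closeness of their kept-set ts/tv ratio to the
    reference.  Returns (ranked list of (TierCounts, |ratio - ref|),
    unrankable TierCounts with an undefined ratio or empty kept set).
    """
    if not tiers:
        raise ValueError("at least one tier required")
    records = list(records)
    ranked = []
    unrankable = []
    for tier in tiers:
        _, counts = apply_tier(records, tier)
        if counts.n == 0 or counts.ratio is None:
            unrankable.append(counts)
        else:
            ranked.append((counts, abs(counts.ratio - reference_ratio)))
    ranked.sort(key=lambda pair: pair[1])
    return ranked, unrankable


# ---------------------------------------------------------------------------
# I/O: VCF and a plain TSV dialect

_TSV_COLUMNS = ["site_id", "ref_base", "alt_base", "quality", "depth",
                "ref_fwd", "ref_rev", "alt_fwd", "alt_rev"]


def read_tsv(path) -> list[VariantRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected columns {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_TSV_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(_TSV_COLUMNS)} columns")
            records.append(
                VariantRecord(
                    site_id=parts[0], ref_base=parts[1], alt_base=parts[2],
                    quality=float(parts[3]), depth=int(parts[4]),
                    ref_fwd=int(parts[5]), ref_rev=int(parts[6]),
                    alt_fwd=int(parts[7]), alt_rev=int(parts[8]),
                )
            )
    return records


def write_tsv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.site_id}\t{r.ref_base}\t{r.alt_base}\t{r.quality:g}\t{r.depth}\t"
                f"{r.ref_fwd}\t{r.ref_rev}\t{r.alt_fwd}\t{r.alt_rev}\n"
            )


def read_vcf(path) -> list[VariantRecord]:
    """Read biallelic SNVs from a VCF; DP from INFO/DP and strand-split
    counts from INFO/DP4 (ref-fwd, ref-rev, alt-fwd, alt-rev), the
    mpileup convention."""
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref == alt:
                continue
            info = rec.info
            dp4 = info.get("DP4")
            if dp4 is None or len(dp4) != 4:
                continue
            depth = info.get("DP", sum(dp4))
            records.append(
                VariantRecord(
                    site_id=f"{rec.chrom}:{rec.pos}",
                    ref_base=ref, alt_base=alt,
                    quality=float(rec.qual) if rec.qual is not None else 0.0,
                    depth=int(depth),
                    ref_fwd=int(dp4[0]), ref_rev=int(dp4[1]),
                    alt_fwd=int(dp4[2]), alt_rev=int(dp4[3]),
                )
            )
    return records


def write_report(tier_counts, path) -> None:
    """Table-style report: tier, SNP count, transitions, transversions,
    ratio."""
    with open(path, "w") as fh:
        fh.write("tier\tsnps\ttransitions\ttransversions\tratio\n")
        for c in tier_counts:
            ratio = f"{c.ratio:.2f}" if c.ratio is not None else "NA"
            fh.write(f"{c.tier}\t{c.n}\t{c.transitions}\t{c.transversions}\t{ratio}\n")
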