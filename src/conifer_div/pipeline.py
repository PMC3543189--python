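"""End-to-end orchestration of the analysis stages on synthetic data.

``run_pipeline`` wires the stages together — read QC, ORF prediction,
orthology with alignment QC, codon-alignment divergence (NG86 and GY94
ML), per-year rate conversion, SNP-tier calibration and assembly
summaries — over inputs drawn by :mod:`conifer_div.syndata`, and writes
per-stage outputs plus a machine-readable manifest.  Runs are
deterministic for a fixed seed.

Species-pair threshold profiles follow the two comparisons of the source
data: spruce-vs-pine (hit identity >= 90%, mismatch runs < 5) and
spruce-vs-yew (>= 80%, < 7).
"""

from __future__ import annotations

import configparser
import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import moldiv, orf, ortho, readqc, summaries, syndata, varfilter

logger = logging.getLogger("conifer_div")

PAIR_PROFILES = {
    "spruce-pine": {"min_identity_pct": 90.0, "max_consec_mismatch": 5},
    "spruce-yew": {"min_identity_pct": 80.0, "max_consec_mismatch": 7},
}


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end run; every threshold defaults to
    the study's value.  Round-trips losslessly through ``save``/``load``.
    """

    seed: int = 1

    # reads
    n_reads: int = 2000
    read_len: int = 76
    adapter: str = syndata.ILLUMINA_ADAPTER
    adapter_prob: float = 0.2
    homopolymer_prob: float = 0.05
    low_quality_prob: float = 0.2

    # transcripts / ORFs
    n_transcripts: int = 200
    min_aa: int = 10

    # orthology / divergence
    pair_profile: str = "spruce-pine"
    n_loci: int = 30
    n_codons: int = 200
    omega: float = 0.2
    kappa: float = 2.0
    t_mean: float = 0.35
    min_score: float = 200.0
    max_evalue: float = 1e-5
    min_protein_identity: float = 0.50
    n_boot: int = 1000
    t_million_years_low: float = 120.0
    t_million_years_high: float = 160.0

    # variants
    n_sites: int = 20000
    het_fraction: float = 0.05
    tstv_target: float = 1.3
    mean_depth: float = 30.0
    error_rate: float = 0.02
    ase_skew: float = 0.5

    def __post_init__(self):
        if self.pair_profile not in PAIR_PROFILES:
            raise ValueError(f"unknown pair profile {self.pair_profile!r}")

    @property
    def profile(self) -> dict:
        return PAIR_PROFILES[self.pair_profile]

    def save(self, path) -> None:
        cp = configparser.ConfigParser()
        cp["pipeline"] = {f.name: repr(getattr(self, f.name)) for f in dataclasses.fields(self)}
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        if not cp.read(str(path)):
            raise FileNotFoundError(path)
        import ast

        kwargs = {k: ast.literal_eval(v) for k, v in cp["pipeline"].items()}
        return cls(**kwargs)


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage in order; returns (and writes) the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seeds = np.random.SeedSequence(config.seed).spawn(5)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng_seeds]
    manifest: dict = {"seed": config.seed, "stage_seeds": seeds, "stages": {}}

    # --- reads -> QC ------------------------------------------------------
    t0 = _stage("readqc")
    reads, read_truth = syndata.simulate_reads(
        config.n_reads, read_len=config.read_len, adapter=config.adapter,
        adapter_prob=config.adapter_prob, homopolymer_prob=config.homopolymer_prob,
        low_quality_prob=config.low_quality_prob, seed=seeds[0],
    )
    syndata.write_fastq(reads, outdir / "reads.fastq")
    syndata.write_truth_tsv(read_truth, outdir / "reads.truth.tsv")
    denovo, denovo_report = readqc.build_library(reads, "denovo", config.adapter)
    mapping, mapping_report = readqc.build_library(reads, "mapping", config.adapter)
    readqc.write_fastq(denovo, outdir / "denovo.fastq")
    readqc.write_fastq(mapping, outdir / "mapping.fastq")
    manifest["stages"]["readqc"] = {
        "denovo": denovo_report, "mapping": mapping_report,
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # --- transcripts -> ORFs ---------------------------------------------
    t0 = _stage("orf")
    transcripts, tx_truth = syndata.simulate_transcripts(config.n_transcripts, seed=seeds[1])
    syndata.write_fasta(transcripts, outdir / "transcripts.fasta")
    syndata.write_truth_tsv(tx_truth, outdir / "transcripts.truth.tsv")
    predictions = list(orf.predict(transcripts, min_aa=config.min_aa))
    orf.write_predictions_tsv(predictions, outdir / "orf_predictions.tsv")
    truth_by_id = {t.transcript_id: t for t in tx_truth}
    n_match = sum(
        1 for _, p in predictions if p.category == truth_by_id[p.transcript_id].category
    )
    manifest["stages"]["orf"] = {
        "input": len(transcripts),
        "predicted": len(predictions),
        "category_matches_truth": n_match,
        "full_length": sum(1 for _, p in predictions if orf.is_full_length(p)),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # --- orthologue loci -> divergence ------------------------------------
    t0 = _stage("orthologs")
    locus_rng = np.random.default_rng(seeds[2])
    species_a, species_b = [], []
    for i in range(config.n_loci):
        t_locus = float(locus_rng.gamma(8.0, config.t_mean / 8.0))
        truth = syndata.CodonPairTruth(
            omega=config.omega, kappa=config.kappa, t=t_locus,
            n_codons=config.n_codons, seed=int(locus_rng.integers(2**31)),
        )
        seq_a, seq_b = syndata.simulate_codon_pair(truth)
        species_a.append((f"locusA{i:04d}", seq_a))
        species_b.append((f"locusB{i:04d}", seq_b))
    syndata.write_fasta(species_a, outdir / "species_a.fasta")
    syndata.write_fasta(species_b, outdir / "species_b.fasta")

    profile = config.profile
    hits_ab = ortho.filter_hits(
        ortho.naive_search(species_a, species_b),
        min_score=config.min_score, max_evalue=config.max_evalue,
        min_identity=profile["min_identity_pct"],
    )
    hits_ba = ortho.filter_hits(
        ortho.naive_search(species_b, species_a),
        min_score=config.min_score, max_evalue=config.max_evalue,
        min_identity=profile["min_identity_pct"],
    )
    ortho.write_hits(hits_ab, outdir / "hits_ab.tsv")
    ortho.write_hits(hits_ba, outdir / "hits_ba.tsv")
    pairs = ortho.reciprocal_best(hits_ab, hits_ba)

    seq_a_by_id = dict(species_a)
    seq_b_by_id = dict(species_b)
    alignments = []
    n_qc_fail = 0
    for pair in pairs:
        coding_a, coding_b = seq_a_by_id[pair.id_a], seq_b_by_id[pair.id_b]
        pep_a, pep_b = orf.translate(coding_a), orf.translate(coding_b)
        row_a, row_b = ortho.align_proteins(pep_a, pep_b)
        qc = ortho.align_qc(
            row_a, row_b, min_identity=config.min_protein_identity,
            max_consec_mismatch=profile["max_consec_mismatch"],
        )
        if not qc.passed:
            n_qc_fail += 1
            continue
        alignments.append(
            ortho.back_translate(row_a, row_b, coding_a, coding_b,
                                 id_a=pair.id_a, id_b=pair.id_b)
        )
    with open(outdir / "codon_alignments.fasta", "w") as fh:
        for aln in alignments:
            fh.write(f">{aln.id_a}\n{aln.row_a}\n>{aln.id_b}\n{aln.row_b}\n")
    manifest["stages"]["orthologs"] = {
        "loci_simulated": config.n_loci,
        "hits_ab": len(hits_ab), "hits_ba": len(hits_ba),
        "rbh_pairs": len(pairs), "alignment_qc_failed": n_qc_fail,
        "alignments": len(alignments),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # --- divergence + rates ----------------------------------------------
    t0 = _stage("dnds")
    ng_estimates, ml_results = [], []
    for aln in alignments:
        ng_estimates.append(moldiv.ng86(aln))
        ml_results.append(moldiv.gy94_pairwise_ml(aln, seed=seeds[3], n_restarts=2))
    moldiv.write_estimates_tsv(ng_estimates, outdir / "dnds_ng86.tsv")
    moldiv.write_estimates_tsv(
        [r.to_estimate() for r in ml_results], outdir / "dnds_gy94ml.tsv"
    )
    summary = moldiv.summarize_loci([r.to_estimate() for r in ml_results])
    ds_values = [r.dS for r in ml_results]
    ci = moldiv.bootstrap_ci(ds_values, n_boot=config.n_boot, seed=seeds[3])
    rate_high = moldiv.yearly_rate(summary.mean_dS, config.t_million_years_low * 1e6)
    rate_low = moldiv.yearly_rate(summary.mean_dS, config.t_million_years_high * 1e6)
    manifest["stages"]["dnds"] = {
        "n_loci": summary.n_loci,
        "mean_dS": summary.mean_dS, "mean_dN": summary.mean_dN,
        "mean_omega": summary.mean_omega,
        "n_omega_undefined": summary.n_omega_undefined,
        "n_omega_gt_1": summary.n_omega_gt_1,
        "dS_ci95": list(ci),
        "yearly_rate_range": [rate_low.rate, rate_high.rate],
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # --- variants ---------------------------------------------------------
    t0 = _stage("snpfilter")
    var_truth = syndata.VariantTruth(
        n_sites=config.n_sites, het_fraction=config.het_fraction,
        tstv_target=config.tstv_target, mean_depth=config.mean_depth,
        error_rate=config.error_rate, ase_skew=config.ase_skew,
    )
    records, site_truth = syndata.simulate_variants(var_truth, seed=seeds[4])
    varfilter.write_tsv(records, outdir / "variants.tsv")
    syndata.write_truth_tsv(site_truth, outdir / "variants.truth.tsv")
    ranked, unrankable = varfilter.calibrate(records, reference_ratio=config.tstv_target)
    varfilter.write_report([c for c, _ in ranked] + unrankable, outdir / "snp_tiers.tsv")
    manifest["stages"]["snpfilter"] = {
        "candidates": len(records),
        "tiers": {
            c.tier: {"n": c.n, "ts": c.transitions, "tv": c.transversions,
                     "ratio": c.ratio}
            for c, _ in ranked
        },
        "best_tier": ranked[0][0].tier if ranked else None,
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # --- assembly summaries ----------------------------------------------
    t0 = _stage("stats")
    count_rng = np.random.default_rng(seeds[1])
    contigs = [
        summaries.Contig(rec.id, len(rec.seq), int(count_rng.poisson(len(rec.seq) / 3)))
        for rec in transcripts
    ]
    kept_contigs = summaries.length_filter(contigs, min_len=151)
    manifest["stages"]["stats"] = {
        "contigs": len(contigs),
        "contigs_after_length_filter": len(kept_contigs),
        **summaries.assembly_report(kept_contigs),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
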