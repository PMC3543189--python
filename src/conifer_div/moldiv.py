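"""Pairwise synonymous/non-synonymous divergence estimation.

Two estimators over a codon alignment of one orthologue pair:

* :func:`ng86` — the Nei–Gojobori counting method: synonymous site
  fractions per codon from single-mutant enumeration averaged over the
  two sequences, observed differences resolved by equal-weight pathway
  enumeration (pathways through stop codons excluded), and a
  Jukes–Cantor correction of the proportions,

      d = -(3/4) * ln(1 - 4p/3),   valid for p < 3/4.

* :class:`PairwiseCodonML` — maximum likelihood under the Goldman–Yang
  codon model with F3x4 equilibrium frequencies estimated from the pair,
  maximising over (t, kappa, omega); `fit()` returns a results object
  with the estimates, approximate standard errors, the dN/dS
  decomposition of the fitted flux, and a `summary()` table.  This
  mirrors a pairwise (runmode -2) codeml analysis with CodonFreq = 2 and
  the transition/transversion ratio estimated from the data.

Locus-set utilities: unweighted summaries across loci, a percentile
bootstrap CI for the mean, and the conversion of mean synonymous
divergence into a per-year substitution rate, r = dS / (2 T).

Loci with dS = 0 have an undefined dN/dS; they are reported as missing
and excluded from ratio summaries (a small dS inflates the ratio exactly
as a large dN would, so forcing a number would be misleading).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from . import gy94
from ._codons import AMINO_ACID, NUCLEOTIDES, SENSE_CODONS, STOP_CODONS
from .ortho import CodonAlignment


class SaturationError(ValueError):
    """A difference proportion at or beyond 3/4: the Jukes–Cantor
    correction is undefined (the alignment is saturated)."""

    def __init__(self, message: str, pS: float | None = None, pN: float | None = None):
        super().__init__(message)
        self.pS = pS
        self.pN = pN


@dataclass(frozen=True)
class DivergenceEstimate:
    locus_id: str
    method: str  # "NG86" or "GY94ML"
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float | None  # None when dS == 0
    n_codons_compared: int
    t: float | None = None
    kappa: float | None = None
    lnL: float | None = None
    converged: bool = True


@dataclass(frozen=True)
class RateEstimate:
    dS_mean: float
    T_years: float
    rate: float  # substitutions / site / year


# ---------------------------------------------------------------------------
# NG86 counting

def _codon_syn_sites(codon: str) -> float:
    """Synonymous sites of one codon: per position, the fraction of the
    three alternative nucleotides preserving the amino acid.  Changes
    into stop codons count as non-synonymous, so syn + nonsyn sites sum
    to exactly 3 per codon."""
    s = 0.0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut not in STOP_CODONS and AMINO_ACID[mut] == AMINO_ACID[codon]:
                s += 1.0 / 3.0
    return s


_SYN_SITES = {c: _codon_syn_sites(c) for c in SENSE_CODONS}
_PATHWAY_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) difference counts between two sense
    codons, averaged with equal weight over all mutational pathways that
    avoid stop codons.  If every pathway passes through a stop (does not
    occur for sense-codon pairs under the standard code, but guarded),
    all pathways are used."""
    key = (c1, c2)
    cached = _PATHWAY_CACHE.get(key)
    if cached is not None:
        return cached
    diffs = [k for k in range(3) if c1[k] != c2[k]]
    results = []
    blocked_results = []
    for order in itertools.permutations(diffs):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            step_syn = (
                nxt not in STOP_CODONS
                and cur not in STOP_CODONS
                and AMINO_ACID[nxt] == AMINO_ACID[cur]
            )
            if step_syn:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked_results if blocked else results).append((sd, nd))
    pool = results if results else blocked_results
    sd = sum(r[0] for r in pool) / len(pool)
    nd = sum(r[1] for r in pool) / len(pool)
    _PATHWAY_CACHE[key] = (sd, nd)
    return sd, nd


def _is_clean_codon(codon: str) -> bool:
    return all(c in "ACGT" for c in codon) and codon not in STOP_CODONS


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction of a difference proportion."""
    if not 0 <= p < 0.75:
        raise SaturationError(f"proportion {p} outside [0, 0.75): correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_counts(aln: CodonAlignment) -> tuple[float, float, float, float, int]:
    """The raw counting step of NG86: (S, N, Sd, Nd, compared columns).
    Codon columns containing gaps, ambiguity codes or stop codons are
    skipped.  Never raises on saturation — the correction step does."""
    s_sites_a = s_sites_b = 0.0
    sd = nd = 0.0
    n_cols = 0
    for ca, cb in aln.codon_columns():
        ca, cb = ca.upper(), cb.upper()
        if not (_is_clean_codon(ca) and _is_clean_codon(cb)):
            continue
        n_cols += 1
        s_sites_a += _SYN_SITES[ca]
        s_sites_b += _SYN_SITES[cb]
        if ca != cb:
            d_s, d_n = _pathway_counts(ca, cb)
            sd += d_s
            nd += d_n
    S = 0.5 * (s_sites_a + s_sites_b)
    N = 3.0 * n_cols - S
    return S, N, sd, nd, n_cols


def ng86(aln: CodonAlignment, locus_id: str | None = None) -> DivergenceEstimate:
    """Nei–Gojobori counting estimate for one codon alignment.

    Raises :class:`SaturationError` (carrying the raw proportions) when
    either difference proportion reaches 3/4.
    """
    locus = locus_id if locus_id is not None else f"{aln.id_a}|{aln.id_b}"
    S, N, sd, nd, n_cols = ng86_counts(aln)
    if n_cols == 0:
        raise ValueError(f"{locus}: no comparable (gap- and ambiguity-free) codon columns")
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    if pS >= 0.75 or pN >= 0.75:
        raise SaturationError(
            f"{locus}: difference proportion saturated (pS={pS:.4f}, pN={pN:.4f})",
            pS=pS, pN=pN,
        )
    dS = jc_correct(pS)
    dN = jc_correct(pN)
    omega = (dN / dS) if dS > 0 else None
    return DivergenceEstimate(
        locus_id=locus, method="NG86", S=S, N=N, Sd=sd, Nd=nd,
        pS=pS, pN=pN, dS=dS, dN=dN, omega=omega, n_codons_compared=n_cols,
    )


# ---------------------------------------------------------------------------
# GY94 pairwise maximum likelihood


@dataclass(frozen=True)
class PairwiseCodonMLResults:
    """Fitted pairwise GY94 model for one orthologue pair.

    ``t`` is the total divergence separating the pair (substitutions per
    codon), ``kappa`` the transition/transversion rate ratio and
    ``omega`` the dN/dS ratio.  ``bse`` holds approximate standard
    errors (delta method on the log-scale curvature); they are None when
    the curvature is not usable (e.g. boundary fits).
    """

    locus_id: str
    t: float
    kappa: float
    omega: float
    lnL: float
    S: float
    N: float
    dS: float
    dN: float
    n_codons_compared: int
    converged: bool
    bse: dict[str, float | None] = field(default_factory=dict)

    @property
    def params(self) -> dict[str, float]:
        return {"t": self.t, "kappa": self.kappa, "omega": self.omega}

    def to_estimate(self) -> DivergenceEstimate:
        pS = pN = float("nan")
        omega = self.omega if self.dS > 0 else None
        return DivergenceEstimate(
            locus_id=self.locus_id, method="GY94ML", S=self.S, N=self.N,
            Sd=float("nan"), Nd=float("nan"), pS=pS, pN=pN, dS=self.dS,
            dN=self.dN, omega=omega, n_codons_compared=self.n_codons_compared,
            t=self.t, kappa=self.kappa, lnL=self.lnL, converged=self.converged,
        )

    def summary(self) -> str:
        lines = [
            "Pairwise codon model (GY94, F3x4)",
            "=" * 46,
            f"locus:            {self.locus_id}",
            f"codon columns:    {self.n_codons_compared}",
            f"log-likelihood:   {self.lnL:.4f}",
            f"converged:        {self.converged}",
            "-" * 46,
            f"{'param':<8}{'estimate':>12}{'std err':>12}",
        ]
        for name in ("t", "kappa", "omega"):
            se = self.bse.get(name)
            se_str = f"{se:.4f}" if se is not None else "--"
            lines.append(f"{name:<8}{getattr(self, name):>12.4f}{se_str:>12}")
        lines += [
            "-" * 46,
            f"S = {self.S:.1f}   N = {self.N:.1f}",
            f"dS = {self.dS:.4f}   dN = {self.dN:.4f}   dN/dS = {self.omega:.4f}",
        ]
        return "\n".join(lines)


class PairwiseCodonML:
    """Maximum-likelihood pairwise divergence under GY94 + F3x4.

    The likelihood of the pair is prod over codon columns of
    pi_i * P(t)_ij, with P the transition-matrix exponential of the
    normalised GY94 rate matrix; by reversibility the assignment of the
    two rows is immaterial.  Columns with gaps, ambiguity or stops are
    excluded.  Codon frequencies are F3x4, estimated from the compared
    columns of both rows (with a small pseudocount so rare nucleotides
    never get zero mass).
    """

    def __init__(self, aln: CodonAlignment, locus_id: str | None = None,
                 pseudocount: float = 0.5):
        self.locus_id = locus_id if locus_id is not None else f"{aln.id_a}|{aln.id_b}"
        from ._codons import CODON_INDEX

        counts = np.zeros((gy94.N_CODONS, gy94.N_CODONS))
        pos_freqs = np.full((3, 4), pseudocount)
        nt_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        n_diff_cols = 0
        for ca, cb in aln.codon_columns():
            ca, cb = ca.upper(), cb.upper()
            if not (_is_clean_codon(ca) and _is_clean_codon(cb)):
                continue
            counts[CODON_INDEX[ca], CODON_INDEX[cb]] += 1.0
            if ca != cb:
                n_diff_cols += 1
            for pos in range(3):
                pos_freqs[pos, nt_idx[ca[pos]]] += 1
                pos_freqs[pos, nt_idx[cb[pos]]] += 1
        self.n_codons_compared = int(counts.sum())
        if self.n_codons_compared == 0:
            raise ValueError(f"{self.locus_id}: no comparable codon columns")
        if self.n_codons_compared < 50:
            warnings.warn(
                f"{self.locus_id}: only {self.n_codons_compared} codon columns; "
                "pairwise ML estimates will be unstable",
                stacklevel=2,
            )
        self.counts = counts
        self.pi = gy94.f3x4_frequencies(pos_freqs)
        self.p_diff = n_diff_cols / self.n_codons_compared
        self._log_pi = np.log(self.pi)
        self._nonzero = counts > 0

    def loglike(self, t: float, kappa: float, omega: float) -> float:
        if t < 0 or kappa <= 0 or omega < 0:
            return -np.inf
        Q = gy94.rate_matrix(kappa, omega, self.pi)
        P = expm(Q * t)
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = self._log_pi[:, None] + np.log(np.clip(P, 1e-300, None))
        return float(np.sum(self.counts[self._nonzero] * logp[self._nonzero]))

    _BOUNDS = [(math.log(1e-7), math.log(20.0)),
               (math.log(0.05), math.log(50.0)),
               (math.log(1e-4), math.log(50.0))]

    def fit(self, n_restarts: int = 3, seed: int = 0, tol: float = 1e-8,
            compute_bse: bool = True) -> PairwiseCodonMLResults:
        """Box-constrained quasi-Newton maximisation on log-parameters
        with random restarts (seed-controlled)."""
        rng = np.random.default_rng(seed)

        def neg(x):
            return -self.loglike(math.exp(x[0]), math.exp(x[1]), math.exp(x[2]))

        t0 = max(1e-4, -math.log(max(1e-12, 1.0 - self.p_diff)))
        starts = [np.log([t0, 2.0, 0.3])]
        for _ in range(max(0, n_restarts - 1)):
            starts.append(
                np.log([
                    float(np.exp(rng.uniform(math.log(0.01), math.log(3.0)))),
                    float(np.exp(rng.uniform(math.log(0.5), math.log(8.0)))),
                    float(np.exp(rng.uniform(math.log(0.02), math.log(3.0)))),
                ])
            )
        best = None
        any_converged = False
        for x0 in starts:
            res = minimize(neg, x0, method="L-BFGS-B", bounds=self._BOUNDS,
                           options={"ftol": tol, "gtol": 1e-8, "maxiter": 500})
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        t_hat, kappa_hat, omega_hat = (math.exp(v) for v in best.x)
        lnL = -float(best.fun)

        rho_s, rho_n = gy94.flux_fractions(kappa_hat, omega_hat, self.pi)
        rho_s1, rho_n1 = gy94.mutational_site_fractions(kappa_hat, self.pi)
        L = self.n_codons_compared
        S = 3.0 * L * rho_s1
        N = 3.0 * L * rho_n1
        dS = t_hat * rho_s / (3.0 * rho_s1)
        dN = t_hat * rho_n / (3.0 * rho_n1)

        bse: dict[str, float | None] = {}
        if compute_bse:
            bse = self._standard_errors(best.x)
        return PairwiseCodonMLResults(
            locus_id=self.locus_id, t=t_hat, kappa=kappa_hat, omega=omega_hat,
            lnL=lnL, S=S, N=N, dS=dS, dN=dN,
            n_codons_compared=L, converged=any_converged, bse=bse,
        )

    def _standard_errors(self, x_hat: np.ndarray) -> dict[str, float | None]:
        """Delta-method SEs from a finite-difference Hessian of the
        log-likelihood in log-parameters."""
        names = ("t", "kappa", "omega")
        h = 1e-4
        k = len(x_hat)

        def f(x):
            return self.loglike(*(math.exp(v) for v in x))

        H = np.zeros((k, k))
        f0 = f(x_hat)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h
                ej = np.zeros(k); ej[j] = h
                if i == j:
                    H[i, i] = (f(x_hat + ei) - 2 * f0 + f(x_hat - ei)) / h**2
                else:
                    H[i, j] = H[j, i] = (
                        f(x_hat + ei + ej) - f(x_hat + ei - ej)
                        - f(x_hat - ei + ej) + f(x_hat - ei - ej)
                    ) / (4 * h**2)
        out: dict[str, float | None] = {}
        try:
            cov = np.linalg.inv(-H)
            for i, name in enumerate(names):
                var_log = cov[i, i]
                if var_log <= 0 or not np.isfinite(var_log):
                    out[name] = None
                else:
                    # delta method: se(theta) = theta * se(log theta)
                    out[name] = float(math.exp(x_hat[i]) * math.sqrt(var_log))
        except np.linalg.LinAlgError:
            out = {name: None for name in names}
        return out


def gy94_pairwise_ml(aln: CodonAlignment, locus_id: str | None = None,
                     n_restarts: int = 3, seed: int = 0) -> PairwiseCodonMLResults:
    """Convenience wrapper: build the model and fit it."""
    return PairwiseCodonML(aln, locus_id=locus_id).fit(n_restarts=n_restarts, seed=seed)


# ---------------------------------------------------------------------------
# locus-set summaries


@dataclass(frozen=True)
class LocusSummary:
    n_loci: int
    mean_dS: float
    mean_dN: float
    mean_omega: float | None
    n_omega_defined: int
    n_omega_undefined: int
    n_omega_gt_1: int
    omega_values: tuple[float, ...]


def summarize_loci(estimates) -> LocusSummary:
    """Unweighted across-locus means; loci with undefined dN/dS are
    excluded from the ratio summaries and counted separately."""
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no divergence estimates to summarise")
    ds = [e.dS for e in estimates]
    dn = [e.dN for e in estimates]
    omegas = [e.omega for e in estimates if e.omega is not None]
    return LocusSummary(
        n_loci=len(estimates),
        mean_dS=float(np.mean(ds)),
        mean_dN=float(np.mean(dn)),
        mean_omega=float(np.mean(omegas)) if omegas else None,
        n_omega_defined=len(omegas),
        n_omega_undefined=len(estimates) - len(omegas),
        n_omega_gt_1=sum(1 for w in omegas if w > 1),
        omega_values=tuple(omegas),
    )


def bootstrap_ci(values, n_boot: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean over loci."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is very small; interval will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def yearly_rate(dS_mean: float, T_years: float) -> RateEstimate:
    """Per-year synonymous substitution rate r = dS / (2 T): the pairwise
    divergence accumulates along both branches since the split."""
    if dS_mean < 0:
        raise ValueError("dS_mean must be >= 0")
    if T_years <= 0:
        raise ValueError("divergence time must be positive")
    return RateEstimate(dS_mean=dS_mean, T_years=T_years, rate=dS_mean / (2.0 * T_years))


def write_estimates_tsv(estimates, path) -> None:
    cols = ["locus_id", "method", "S", "N", "Sd", "Nd", "pS", "pN",
            "dS", "dN", "omega", "t", "kappa", "lnL", "n_codons_compared", "converged"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in estimates:
            row = []
            for c in cols:
                v = getattr(e, c)
                row.append("NA" if v is None else str(v))
            fh.write("\t".join(row) + "\n")
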