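"""Goldman–Yang codon substitution model machinery.

The GY94 model assigns, between sense codons differing at a single
nucleotide position, the instantaneous rate

    q_ij = pi_j * kappa^[transition] * omega^[non-synonymous]

with all multi-position exchanges forbidden.  ``pi`` is the codon
equilibrium distribution; under the F3x4 parameterisation it is the
product of position-specific nucleotide frequencies, renormalised over
the 61 sense codons.  The matrix is scaled so that one unit of branch
length equals one expected substitution per codon at stationarity.

Both the simulator (:mod:`conifer_div.syndata`) and the pairwise ML
estimator (:mod:`conifer_div.moldiv`) build on these functions, which
keeps simulation and estimation under literally the same model.
"""

from __future__ import annotations

import numpy as np

from ._codons import AMINO_ACID, SENSE_CODONS, is_transition

N_CODONS = len(SENSE_CODONS)  # 61

# Precomputed structure of single-step exchanges: for each ordered sense
# codon pair differing at one position, whether the change is a
# transition and whether it is non-synonymous.
_single_i: list[int] = []
_single_j: list[int] = []
_single_ts: list[bool] = []
_single_nonsyn: list[bool] = []
for _i, _ci in enumerate(SENSE_CODONS):
    for _j, _cj in enumerate(SENSE_CODONS):
        if _i == _j:
            continue
        diffs = [k for k in range(3) if _ci[k] != _cj[k]]
        if len(diffs) != 1:
            continue
        _k = diffs[0]
        _single_i.append(_i)
        _single_j.append(_j)
        _single_ts.append(is_transition(_ci[_k], _cj[_k]))
        _single_nonsyn.append(AMINO_ACID[_ci] != AMINO_ACID[_cj])

_SINGLE_I = np.array(_single_i)
_SINGLE_J = np.array(_single_j)
_SINGLE_TS = np.array(_single_ts)
_SINGLE_NONSYN = np.array(_single_nonsyn)
del _single_i, _single_j, _single_ts, _single_nonsyn


def f3x4_frequencies(position_freqs: np.ndarray) -> np.ndarray:
    """Codon equilibrium frequencies from 3x4 positional nucleotide
    frequencies (rows = codon positions, columns = A,C,G,T order of
    :data:`conifer_div._codons.NUCLEOTIDES`), renormalised over sense
    codons."""
    f = np.asarray(position_freqs, dtype=float)
    if f.shape != (3, 4):
        raise ValueError("position_freqs must be a 3x4 array")
    if np.any(f < 0):
        raise ValueError("nucleotide frequencies must be non-negative")
    f = f / f.sum(axis=1, keepdims=True)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    pi = np.array(
        [f[0, idx[c[0]]] * f[1, idx[c[1]]] * f[2, idx[c[2]]] for c in SENSE_CODONS]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate positional frequencies: all sense codons have zero mass")
    return pi / total


def rate_matrix(kappa: float, omega: float, pi: np.ndarray, normalize: bool = True) -> np.ndarray:
    """GY94 instantaneous rate matrix over the 61 sense codons.

    With ``normalize=True`` the matrix is scaled to one expected
    substitution per codon per unit time at stationarity, so branch
    lengths are in substitutions per codon.
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ValueError("pi must have one entry per sense codon")
    rates = pi[_SINGLE_J].copy()
    rates[_SINGLE_TS] *= kappa
    rates[_SINGLE_NONSYN] *= omega
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[_SINGLE_I, _SINGLE_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        scale = -(pi * np.diag(Q)).sum()
        if scale <= 0:
            raise ValueError("rate matrix has zero total flux")
        Q /= scale
    return Q


def flux_fractions(kappa: float, omega: float, pi: np.ndarray) -> tuple[float, float]:
    """Fractions of the stationary substitution flux that are synonymous
    and non-synonymous, (rho_S, rho_N), summing to 1."""
    pi = np.asarray(pi, dtype=float)
    rates = pi[_SINGLE_J].copy()
    rates[_SINGLE_TS] *= kappa
    rates[_SINGLE_NONSYN] *= omega
    flux = pi[_SINGLE_I] * rates
    total = flux.sum()
    syn = flux[~_SINGLE_NONSYN].sum()
    return syn / total, (total - syn) / total


def mutational_site_fractions(kappa: float, pi: np.ndarray) -> tuple[float, float]:
    """Synonymous/non-synonymous site proportions: the flux fractions of
    the neutral (omega = 1) process with the same kappa and pi.  This is
    the codeml-style definition of S and N under the ML model."""
    return flux_fractions(kappa, 1.0, pi)
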