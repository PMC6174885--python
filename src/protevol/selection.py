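"""Site-specific stationary amino-acid distributions under stability selection.

Both models assume independently evolving sites whose distributions are tied
together by a global constraint on folding stability, with a Lagrange
multiplier Lambda measuring the strength of selection (related to effective
population size):

- Wild-type (WT): site i's distribution weights each amino acid a by the
  exponentiated log-fitness of the single-point mutant of the PDB sequence,
  P^i_a ∝ P^mut_a exp(Lambda * phi(mut(A_i -> a))).
- Mean-field (MF): the stability contribution of amino acid a at site i is
  evaluated against the current mean field of all other sites (native contact
  terms and misfolding moments use distribution-averaged interaction
  energies), and the distributions are iterated to a self-consistent fixed
  point.

Lambda is fitted by maximizing the log-likelihood of the PDB sequence, which
has a single well-defined maximum in the non-degenerate case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar

from .alphabet import N_AA, one_hot, seq_to_indices
from .contacts import ContactMap, DecoyStats
from .mutation import MutationModel
from .stability import (
    ContactPotential,
    StabilityParams,
    log_fitness,
    rem_free_energy,
    unfolded_free_energy,
)

log = logging.getLogger(__name__)

__all__ = [
    "SiteDistributions",
    "EvolParams",
    "kimura_fixation",
    "site_delta_g_matrix",
    "wt_phi_matrix",
    "distributions_from_phi",
    "wt_distributions",
    "mf_distributions",
    "fit_lambda",
    "ConvergenceError",
]

PROB_FLOOR = 1e-12


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last residual {residual:.3e})")
        self.residual = residual


@dataclass
class SiteDistributions:
    """L x n site-specific stationary frequencies with the fitted Lambda."""

    P: np.ndarray
    lam: float
    model_tag: str

    def __post_init__(self) -> None:
        p = np.asarray(self.P, dtype=float)
        if p.ndim != 2:
            raise ValueError("P must be (L, n_states)")
        if (p <= 0).any():
            raise ValueError("site distributions must be strictly positive")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("site distributions must be row-stochastic")
        if self.lam < 0:
            raise ValueError("Lambda must be non-negative")
        self.P = p

    @property
    def length(self) -> int:
        return self.P.shape[0]

    def log_likelihood(self, seq: str) -> float:
        idx = seq_to_indices(seq)
        return float(np.log(self.P[np.arange(len(idx)), idx]).sum())


@dataclass
class EvolParams:
    """Population-genetic parameters for the fixation-probability oracles."""

    N: int = 100
    kT: float = 1.0

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 2:
            raise ValueError("N must be an integer >= 2")


def kimura_fixation(phi_wt, phi_mut, N: int):
    """Kimura fixation probability of a mutant with log-fitness change
    dphi = phi_mut - phi_wt in a population of size N.

    P_fix = (e^{-dphi} - 1)/(e^{-N dphi} - 1); continuous neutral limit 1/N.
    """
    if int(N) != N or N < 2:
        raise ValueError("N must be an integer >= 2")
    d = np.asarray(phi_mut, dtype=float) - np.asarray(phi_wt, dtype=float)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        out = np.where(
            np.abs(d) < 1e-9,
            (1.0 + (N - 1) * d / 2.0) / N,  # series around the neutral limit
            np.where(
                -N * d > 700.0,
                np.exp((N - 1) * d),  # strongly deleterious: avoid overflow
                np.expm1(-d) / np.expm1(-N * d),
            ),
        )
    return out if out.ndim else float(out)


def site_delta_g_matrix(
    cmap: ContactMap,
    pot: ContactPotential,
    stats: DecoyStats | None,
    params: StabilityParams,
    weights: np.ndarray,
) -> np.ndarray:
    """(L, n) matrix of DeltaG with site i set to amino acid a and all other
    sites averaged under the row distributions ``weights``.

    With one-hot ``weights`` this is the exact single-point-mutant DeltaG of
    the corresponding sequence (the WT model's input); with soft rows it is
    the mean-field evaluation: native contact terms use sum_b P^j_b U(a, b)
    and the misfolding moments are computed from distribution-averaged pair
    energies on each decoy map.
    """
    W = np.asarray(weights, dtype=float)
    L = cmap.length
    if W.shape[0] != L:
        raise ValueError("weights rows must match the contact map length")
    U = pot.U
    if W.shape[1] != U.shape[0]:
        raise ValueError("weights columns must match the potential size")
    C = cmap.contacts.astype(float)
    ubar = W @ U  # (L, n): mean interaction of amino a with site j
    pairU = ubar @ W.T  # (L, L): distribution-averaged pair energies
    tot_nat = 0.5 * float(np.sum(C * pairU))
    row_nat = (C * pairU).sum(axis=1)
    g_nat = (tot_nat - row_nat)[:, None] + C @ ubar

    g_u = unfolded_free_energy(L, params)
    if stats is None:
        return g_nat - g_u

    if stats.length != L:
        raise ValueError("decoy statistics length does not match contact map")
    D = stats.maps.astype(float)  # (K, L, L)
    tot = 0.5 * np.einsum("kij,ij->k", D, pairU)
    row = np.einsum("kij,ij->ki", D, pairU)
    fld = np.einsum("kij,ja->kia", D, ubar)
    e = (tot[:, None, None] - row[:, :, None]) + fld  # decoy energies per (i, a)
    mu = e.mean(axis=0)
    d = e - mu
    m2 = (d**2).mean(axis=0)
    m3 = (d**3).mean(axis=0)
    g_misf = rem_free_energy(mu, m2, m3, L, params)
    T = params.T
    g_nonnat = -T * np.logaddexp(-g_misf / T, -g_u / T)
    return g_nat - g_nonnat


def wt_phi_matrix(
    cmap: ContactMap,
    pdb_seq: str,
    pot: ContactPotential,
    stats: DecoyStats | None,
    params: StabilityParams,
    kT: float = 1.0,
) -> np.ndarray:
    """(L, n) log-fitness of every single-point mutant of the PDB sequence."""
    if len(pdb_seq) != cmap.length:
        raise ValueError("PDB sequence length does not match contact map")
    W = one_hot(pdb_seq, n_states=pot.n_states)
    dg = site_delta_g_matrix(cmap, pot, stats, params, W)
    return log_fitness(dg, kT=kT)


def distributions_from_phi(
    phi: np.ndarray, mut: MutationModel, lam: float, model_tag: str
) -> SiteDistributions:
    """Rows ∝ P^mut_a exp(Lambda * phi_ia), floored and renormalized."""
    logw = np.log(mut.P_mut)[None, :] + lam * phi
    logw = logw - logw.max(axis=1, keepdims=True)
    p = np.exp(logw)
    p = p / p.sum(axis=1, keepdims=True)
    p = np.maximum(p, PROB_FLOOR)
    p = p / p.sum(axis=1, keepdims=True)
    return SiteDistributions(P=p, lam=lam, model_tag=model_tag)


def wt_distributions(
    cmap: ContactMap,
    pdb_seq: str,
    pot: ContactPotential,
    stats: DecoyStats | None,
    params: StabilityParams,
    mut: MutationModel,
    lam: float,
    kT: float = 1.0,
) -> SiteDistributions:
    """Wild-type model: P^i_a ∝ P^mut_a exp(Lambda * phi(mut(A_i -> a)))."""
    phi = wt_phi_matrix(cmap, pdb_seq, pot, stats, params, kT=kT)
    return distributions_from_phi(phi, mut, lam, "WT")


class _MFState:
    """Incrementally maintained mean-field arrays for Gauss-Seidel sweeps.

    Keeps, for the current row distributions P: the per-site mean
    interactions ubar = P U, the distribution-averaged pair energies
    pairU = P U P^T, and the native/decoy contact sums needed to evaluate the
    field of any single site in O(K n) after an O(K L n) rank-1 update.
    """

    def __init__(self, cmap, pot, stats, params, P):
        self.C = cmap.contacts.astype(float)
        self.D = stats.maps.astype(float) if stats is not None else None
        self.U = pot.U
        self.params = params
        self.L = cmap.length
        self.g_u = unfolded_free_energy(self.L, params)
        self.P = P.copy()
        self._recompute()

    def _recompute(self) -> None:
        self.ubar = self.P @ self.U
        self.pairU = self.P @ self.ubar.T
        self.nat_fld = self.C @ self.ubar
        self.row_nat = (self.C * self.pairU).sum(axis=1)
        self.tot_nat = 0.5 * float(np.sum(self.C * self.pairU))
        if self.D is not None:
            self.fld = np.einsum("kij,ja->kia", self.D, self.ubar)
            self.row_d = np.einsum("kij,ij->ki", self.D, self.pairU)
            self.tot_d = 0.5 * np.einsum("kij,ij->k", self.D, self.pairU)

    def site_delta_g(self, i: int) -> np.ndarray:
        g_nat = (self.tot_nat - self.row_nat[i]) + self.nat_fld[i]
        if self.D is None:
            return g_nat - self.g_u
        e = (self.tot_d - self.row_d[:, i])[:, None] + self.fld[:, i, :]
        mu = e.mean(axis=0)
        d = e - mu
        g_misf = rem_free_energy(
            mu, (d**2).mean(axis=0), (d**3).mean(axis=0), self.L, self.params
        )
        T = self.params.T
        return g_nat - (-T * np.logaddexp(-g_misf / T, -self.g_u / T))

    def update_site(self, i: int, p_new: np.ndarray) -> None:
        delta = p_new - self.P[i]
        self.P[i] = p_new
        d_ubar = delta @ self.U
        self.ubar[i] += d_ubar
        old_row = self.pairU[i].copy()
        new_row = self.ubar @ self.P[i]
        self.pairU[i, :] = new_row
        self.pairU[:, i] = new_row
        d_pair = new_row - old_row
        self.tot_nat += float(self.C[i] @ d_pair)
        self.row_nat += self.C[:, i] * d_pair
        self.row_nat[i] = float(self.C[i] @ new_row)
        self.nat_fld += np.outer(self.C[:, i], d_ubar)
        if self.D is not None:
            self.tot_d += self.D[:, i, :] @ d_pair
            self.row_d += self.D[:, :, i] * d_pair[None, :]
            self.row_d[:, i] = self.D[:, i, :] @ new_row
            self.fld += self.D[:, :, i, None] * d_ubar[None, None, :]


def mf_distributions(
    cmap: ContactMap,
    pot: ContactPotential,
    stats: DecoyStats | None,
    params: StabilityParams,
    mut: MutationModel,
    lam: float,
    pdb_seq: str | None = None,
    kT: float = 1.0,
    damping: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> SiteDistributions:
    """Mean-field model: self-consistent fixed point of the site fields.

    Solved by Gauss-Seidel sweeps: sites are updated sequentially to their
    conditional distribution given the current mean field of all others
    (the stable relaxation for these self-consistency equations; synchronous
    updates spiral into collective limit cycles at strong selection). The
    maintained arrays are refreshed from scratch each sweep to avoid
    floating-point drift. ``max_iter`` counts sweeps. ``pdb_seq`` is accepted
    for interface symmetry (the MF field does not depend on it).
    """
    L = cmap.length
    n = pot.n_states
    if mut.n_states != n:
        raise ValueError("mutation model and potential have different sizes")
    if stats is not None and stats.length != L:
        raise ValueError("decoy statistics length does not match contact map")
    log_pmut = np.log(mut.P_mut)
    P = np.tile(mut.P_mut, (L, 1))
    residual = np.inf
    for _ in range(max_iter):
        state = _MFState(cmap, pot, stats, params, P)
        # synchronous residual against the current field
        dg = site_delta_g_matrix(cmap, pot, stats, params, P)
        target = distributions_from_phi(log_fitness(dg, kT=kT), mut, lam, "MF").P
        residual = float(np.abs(target - P).max())
        if residual < tol:
            return SiteDistributions(P=target, lam=lam, model_tag="MF")
        for i in range(L):
            phi_i = log_fitness(state.site_delta_g(i), kT=kT)
            logw = log_pmut + lam * phi_i
            logw -= logw.max()
            p_i = np.exp(logw)
            p_i /= p_i.sum()
            p_i = np.maximum(p_i, PROB_FLOOR)
            p_i /= p_i.sum()
            if damping != 1.0:
                p_i = (1.0 - damping) * state.P[i] + damping * p_i
                p_i /= p_i.sum()
            state.update_site(i, p_i)
        P = state.P
    raise ConvergenceError("mean-field iteration did not converge", residual)


def fit_lambda(
    builder: Callable[[float], SiteDistributions],
    pdb_seq: str,
    lambda_init: float = 1.0,
    lambda_cap: float = 2.0**16,
) -> tuple[float, SiteDistributions]:
    """Maximize the PDB-sequence log-likelihood over Lambda >= 0.

    The upper bracket is doubled until the likelihood decreases, then the
    maximum is located by bounded scalar minimization; deterministic. A flat
    likelihood (e.g. zero potential) returns the lower bracket with a logged
    warning.
    """
    idx = seq_to_indices(pdb_seq)

    cache: dict[float, float] = {}

    def ll(lam: float) -> float:
        if lam not in cache:
            p = builder(lam).P
            cache[lam] = float(np.log(p[np.arange(len(idx)), idx]).sum())
        return cache[lam]

    ll0 = ll(0.0)
    lmax = lambda_init
    while ll(lmax * 2) > ll(lmax) and lmax < lambda_cap:
        lmax *= 2
    probes = [ll0, ll(lmax), ll(lmax * 2)]
    if max(probes) - min(probes) < 1e-10:
        log.warning("log-likelihood is flat in Lambda; returning the lower bracket")
        return 0.0, builder(0.0)
    if not np.isfinite(probes).any():
        raise ValueError("likelihood non-finite at all probed Lambda values")
    res = minimize_scalar(
        lambda lam: -ll(lam),
        bounds=(0.0, 2 * lmax),
        method="bounded",
        options={"xatol": 1e-5 * max(1.0, lmax)},
    )
    lam_hat = float(res.x)
    return lam_hat, builder(lam_hat)
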