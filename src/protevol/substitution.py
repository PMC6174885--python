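"""Site-specific substitution processes via the Halpern-Bruno construction.

Given a site's stationary distribution P^i and the global mutation model
(P^mut, E^mut), the selective factors F^sel,i_a = P^i_a / P^mut_a determine
the site exchangeability

    E^i_ab = E^mut_ab * (ln F_b - ln F_a) / (F_b - F_a),

which is symmetric, so Q^i_ab = E^i_ab P^i_b satisfies detailed balance with
stationary distribution P^i. The pairwise flux decomposes into a global
mutational part and a site-specific selective part,

    R^i_ab = (P^mut_a P^mut_b E^mut_ab) F_a F_b (ln F_b - ln F_a)/(F_b - F_a),

and the site substitution rate is R^i = sum_{a!=b} R^i_ab, equal to one at
neutral sites under a normalized mutation model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mutation import MutationModel, hb_factor
from .selection import SiteDistributions

__all__ = [
    "SiteProcess",
    "selective_factors",
    "hb_exchangeability",
    "site_rate_matrix",
    "site_flux",
    "sequence_entropy",
    "build_site_processes",
]


@dataclass
class SiteProcess:
    """Full substitution process of one site (entropy in nats)."""

    F_sel: np.ndarray
    E: np.ndarray
    Q: np.ndarray
    R_pair: np.ndarray
    rate: float
    entropy: float


def selective_factors(P_i: np.ndarray, P_mut: np.ndarray) -> np.ndarray:
    """F^sel_a = P^i_a / P^mut_a; both distributions strictly positive."""
    p = np.asarray(P_i, dtype=float)
    q = np.asarray(P_mut, dtype=float)
    if (p <= 0).any() or (q <= 0).any():
        raise ValueError("distributions must be strictly positive")
    return p / q


def hb_exchangeability(E_mut: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Site exchangeability E^i_ab = E^mut_ab (ln F_b - ln F_a)/(F_b - F_a).

    The neutral limit E^mut_ab / F_b applies when the factors coincide.
    Symmetric whenever E^mut is; diagonal stored as zero.
    """
    F = np.asarray(F, dtype=float)
    e = np.asarray(E_mut, dtype=float) * hb_factor(F[:, None], F[None, :])
    np.fill_diagonal(e, 0.0)
    return e


def site_rate_matrix(E_i: np.ndarray, P_i: np.ndarray) -> np.ndarray:
    """Q^i_ab = E^i_ab P^i_b off-diagonal; diagonal = negative row sum."""
    q = np.asarray(E_i, dtype=float) * np.asarray(P_i, dtype=float)[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def site_flux(
    F: np.ndarray, P_mut: np.ndarray, E_mut: np.ndarray
) -> tuple[np.ndarray, float]:
    """Pairwise flux matrix (mutational flux times selective enhancement) and
    the scalar site rate R = sum_{a!=b} R_ab."""
    F = np.asarray(F, dtype=float)
    P_mut = np.asarray(P_mut, dtype=float)
    r = (
        np.outer(P_mut, P_mut)
        * np.asarray(E_mut, dtype=float)
        * np.outer(F, F)
        * hb_factor(F[:, None], F[None, :])
    )
    np.fill_diagonal(r, 0.0)
    return r, float(r.sum())


def sequence_entropy(P_i: np.ndarray, bits: bool = False) -> float:
    """Shannon entropy of a site distribution (nats by default; 0 log 0 = 0)."""
    p = np.asarray(P_i, dtype=float)
    nz = p > 0
    s = float(-(p[nz] * np.log(p[nz])).sum())
    return s / np.log(2.0) if bits else s


def build_site_processes(
    dists: SiteDistributions, mut: MutationModel
) -> list[SiteProcess]:
    """Halpern-Bruno process for every site of a fitted distribution set."""
    if dists.P.shape[1] != mut.n_states:
        raise ValueError("distributions and mutation model sizes differ")
    out = []
    for i in range(dists.length):
        p = dists.P[i]
        f = selective_factors(p, mut.P_mut)
        e = hb_exchangeability(mut.E_mut, f)
        q = site_rate_matrix(e, p)
        r_pair, rate = site_flux(f, mut.P_mut, mut.E_mut)
        out.append(
            SiteProcess(
                F_sel=f,
                E=e,
                Q=q,
                R_pair=r_pair,
                rate=rate,
                entropy=sequence_entropy(p),
            )
        )
    return out
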