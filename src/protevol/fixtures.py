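"""Synthetic inputs: toy potentials, decoy ensembles, sampled sequences.

Everything here is seeded and validates against the package's type invariants
at creation, so the full pipeline (and its tests) runs without any external
data. The reference hydrophobicity scale is the one behind the shipped
synthetic potential: a Kyte-Doolittle-derived 20-vector rescaled to unit L2
norm with mean 0.14 over the amino acids (the mean hydrophobicity of the
uniform distribution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AA_ORDER, N_AA, THREE_TO_ONE
from .contacts import ContactMap, ResidueChain, synth_chain
from .selection import SiteDistributions
from .stability import ContactPotential

__all__ = [
    "FixtureSpec",
    "reference_h",
    "make_potential",
    "make_decoys",
    "sample_sequences",
    "toy_pdb_text",
]

_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class FixtureSpec:
    """Everything a fixture build needs; ``seed`` fixes all randomness."""

    seed: int = 0
    L: int = 40
    n_decoys: int = 12
    compactness: float = 1.0
    potential_kind: str = "rank1"  # rank1 | shipped | random-symmetric
    epsilon: float = -4.0
    noise: float = 0.05


def reference_h(target_mean: float = 0.14) -> np.ndarray:
    """Unit-norm hydrophobicity scale with the stated mean, in PAML order."""
    k = np.array([_KYTE_DOOLITTLE[a] for a in AA_ORDER])
    m = k.mean()
    ss = ((k - m) ** 2).sum()
    a = np.sqrt((1.0 - N_AA * target_mean**2) / ss)
    return a * (k - m) + target_mean


def make_potential(spec: FixtureSpec) -> ContactPotential:
    """Build a test potential of the requested kind.

    ``rank1`` is exactly U = eps*h*h^T; ``random-symmetric`` adds seeded
    symmetric Gaussian noise of scale ``spec.noise``; ``shipped`` loads the
    packaged potential.
    """
    if spec.potential_kind == "shipped":
        from .stability import shipped_potential

        return shipped_potential()
    h = reference_h()
    u = spec.epsilon * np.outer(h, h)
    if spec.potential_kind == "random-symmetric":
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(scale=spec.noise, size=(N_AA, N_AA))
        u = u + 0.5 * (noise + noise.T)
    elif spec.potential_kind != "rank1":
        raise ValueError(f"unknown potential kind {spec.potential_kind!r}")
    return ContactPotential(u)


def make_decoys(spec: FixtureSpec) -> list[ContactMap]:
    """Seeded compact decoy contact maps of length L.

    Contacts at separation s >= 3 are drawn independently with probability
    p(s) = compactness * max(0.4/s, 0.03), the separation-decaying profile of
    the compact chains from :func:`protevol.contacts.synth_chain` (short-range
    decay with a flat long-range tail); density increases monotonically with
    ``compactness``.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.L
    seps = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
    prob = np.where(
        seps >= 3,
        np.minimum(1.0, spec.compactness * np.maximum(0.4 / np.maximum(seps, 1), 0.03)),
        0.0,
    )
    decoys = []
    for _ in range(spec.n_decoys):
        upper = np.triu(rng.random((L, L)) < prob, k=3)
        decoys.append(ContactMap((upper | upper.T).astype(np.uint8)))
    return decoys


def sample_sequences(P: SiteDistributions, n: int, seed: int) -> list[str]:
    """Site-independent sequence draws from the rows of P."""
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P.P, axis=1)
    out = []
    for _ in range(n):
        u = rng.random(P.length)
        idx = (u[:, None] > cum).sum(axis=1)
        out.append("".join(AA_ORDER[i] for i in np.minimum(idx, P.P.shape[1] - 1)))
    return out


def toy_pdb_text(chain: ResidueChain, chain_id: str = "A") -> str:
    """Render a residue chain as minimal PDB ATOM records (one CA-like pseudo
    atom per coordinate) so the parser round-trips fixtures."""
    one_to_three = {v: k for k, v in THREE_TO_ONE.items()}
    lines = []
    serial = 1
    for idx, aa, atoms in chain.residues:
        res3 = one_to_three[aa]
        for k, xyz in enumerate(atoms):
            name = "CA" if k == 0 else f"C{k}"
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {res3} {chain_id}{idx:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def evolve_sequence(
    cmap: ContactMap,
    pot,
    stats,
    params,
    mut,
    lam: float,
    seed: int,
    n_sweeps: int = 30,
    start: str | None = None,
) -> str:
    """Gibbs-sample a sequence from the stability-constrained stationary
    distribution P(A) ∝ prod_i P^mut(A_i) * exp(lam * phi(A)).

    Site conditionals are exact: each site is redrawn from the softmax of
    lam * phi over its 20 mutants with all other sites held fixed (the
    one-hot single-site field). The result is an equilibrated "wild type"
    adapted to the structure — the natural input for the wild-type selection
    model, which presumes a sequence shaped by the same fitness landscape.
    """
    from .alphabet import one_hot, N_AA as _N
    from .selection import _MFState
    from .stability import log_fitness

    rng = np.random.default_rng(seed)
    L = cmap.length
    if start is None:
        start = "".join(rng.choice(list(AA_ORDER), size=L))
    state = _MFState(cmap, pot, stats, params, one_hot(start, pot.n_states))
    log_pmut = np.log(mut.P_mut)
    for sweep in range(n_sweeps):
        for i in rng.permutation(L):
            phi_i = log_fitness(state.site_delta_g(i))
            logw = log_pmut + lam * phi_i
            logw -= logw.max()
            p = np.exp(logw)
            p /= p.sum()
            a = rng.choice(pot.n_states, p=p)
            row = np.zeros(pot.n_states)
            row[a] = 1.0
            state.update_site(int(i), row)
    idx = state.P.argmax(axis=1)
    return "".join(AA_ORDER[i] for i in idx)


def compact_protein_fixture(
    spec: FixtureSpec,
) -> tuple[ResidueChain, ContactMap, list[ContactMap]]:
    """Convenience bundle: a compact toy chain, its native map, and decoys.

    The decoys are alternative compact chains from the same generator (with
    shifted seeds), density-matched to the native: of 3x the requested number
    of candidates, the ``n_decoys`` whose total contact count is closest to
    the native's are kept (compact decoy sets are compactness-matched to the
    native; without matching, random density fluctuations of the generator
    would dominate the native-vs-misfolded energy gap).
    """
    chain, cmap = synth_chain(spec.L, spec.seed, spec.compactness)
    n_native = int(cmap.contacts.sum())
    candidates = [
        synth_chain(spec.L, spec.seed + 1 + k, spec.compactness)[1]
        for k in range(3 * spec.n_decoys)
    ]
    candidates.sort(key=lambda d: (abs(int(d.contacts.sum()) - n_native)))
    return chain, cmap, candidates[: spec.n_decoys]
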