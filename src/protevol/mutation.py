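"""Global mutation models: background frequencies and exchangeabilities.

Four models are supported, all normalized so the neutral substitution rate
(average flux under mutation alone) equals one:

- ``emp``: empirical exchangeability matrix (WAG or JTT, PAML ``.dat``).
- ``flux``: the empirical matrix with the average selective factors of a
  stability-constrained run divided out, so that the model's site-averaged
  flux reproduces the empirical flux pair by pair.
- ``nuc_opt``: codon-level mutation process (nucleotide frequencies +
  transition/transversion ratio kappa) with parameters maximizing the
  multinomial likelihood of observed amino-acid counts.
- ``nuc_var``: the codon-level process with user-supplied nucleotide
  frequencies, typically parameterized by equilibrium GC content.

The codon process assigns fitness zero to stop codons, which breaks detailed
balance at the codon level, so the stationary distribution of the 61 sense
codons is computed numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import minimize

from .alphabet import (
    AA_INDEX,
    AA_ORDER,
    CODON_TABLE,
    N_AA,
    NUCLEOTIDES,
    SENSE_CODONS,
    TRANSITIONS,
)

__all__ = [
    "MutationModel",
    "NucleotideParams",
    "CodonProcess",
    "load_empirical",
    "load_shipped_empirical",
    "codon_mutation_model",
    "optimize_nucleotide_params",
    "flux_exchangeability",
    "normalize",
    "hb_factor",
    "gc_params",
    "observed_frequencies",
]


@dataclass
class MutationModel:
    """Background amino-acid frequencies P^mut and exchangeability E^mut.

    After :func:`normalize`, sum_{a!=b} P_a P_b E_ab = 1 (the neutral flux).
    The diagonal of E is stored as zero by convention.
    """

    P_mut: np.ndarray
    E_mut: np.ndarray
    label: str = "emp"

    def __post_init__(self) -> None:
        p = np.asarray(self.P_mut, dtype=float)
        e = np.asarray(self.E_mut, dtype=float)
        if p.ndim != 1 or e.shape != (p.size, p.size):
            raise ValueError("inconsistent shapes for P_mut / E_mut")
        if (p <= 0).any():
            raise ValueError("background frequencies must be strictly positive")
        if not np.allclose(e, e.T, atol=1e-10):
            raise ValueError("exchangeability matrix must be symmetric")
        if (e < -1e-12).any():
            raise ValueError("exchangeability entries must be non-negative")
        self.P_mut = p / p.sum()
        e = 0.5 * (e + e.T)
        np.fill_diagonal(e, 0.0)
        self.E_mut = np.clip(e, 0.0, None)

    @property
    def n_states(self) -> int:
        return self.P_mut.size

    def neutral_flux(self) -> float:
        return float(self.P_mut @ self.E_mut @ self.P_mut)

    def to_json_dict(self) -> dict:
        return {
            "label": self.label,
            "alphabet": AA_ORDER if self.n_states == N_AA else None,
            "P_mut": self.P_mut.tolist(),
            "E_mut": self.E_mut.tolist(),
        }


@dataclass
class NucleotideParams:
    """Nucleotide-level mutation parameters for the codon model.

    ``f_nuc`` is indexed in the order T, C, A, G; ``kappa`` multiplies
    transition rates (transversions have factor 1).
    """

    f_nuc: np.ndarray
    kappa: float = 2.0

    def __post_init__(self) -> None:
        f = np.asarray(self.f_nuc, dtype=float)
        if f.shape != (4,) or (f < 0).any():
            raise ValueError("f_nuc must be 4 non-negative frequencies")
        if f.sum() <= 0:
            raise ValueError("f_nuc must not be all zero")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        self.f_nuc = f / f.sum()

    def freq(self, nucleotide: str) -> float:
        return float(self.f_nuc[NUCLEOTIDES.index(nucleotide)])


@dataclass
class CodonProcess:
    """Mutation process over the 61 sense codons (stop codons have rate 0)."""

    Q: np.ndarray
    pi: np.ndarray
    codons: list[str] = field(default_factory=lambda: list(SENSE_CODONS))

    def stationarity_residual(self) -> float:
        return float(np.abs(self.pi @ self.Q).max())


def gc_params(gc: float, kappa: float = 2.0) -> NucleotideParams:
    """Nucleotide frequencies with equilibrium G+C content ``gc`` (strand
    symmetric: f_G = f_C = gc/2, f_A = f_T = (1-gc)/2)."""
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    at = (1.0 - gc) / 2.0
    return NucleotideParams(f_nuc=np.array([at, gc / 2, at, gc / 2]), kappa=kappa)


def observed_frequencies(seqs: str | list[str], pseudocount: float = 1.0) -> np.ndarray:
    """Amino-acid frequencies of the input sequence(s), with a pseudocount so
    unobserved amino acids keep non-zero background probability."""
    if isinstance(seqs, str):
        seqs = [seqs]
    counts = np.full(N_AA, float(pseudocount))
    for s in seqs:
        for a in s:
            counts[AA_INDEX[a]] += 1.0
    return counts / counts.sum()


def normalize(model: MutationModel) -> MutationModel:
    """Scale E so the neutral average flux sum_{a!=b} P_a P_b E_ab equals 1."""
    c = model.neutral_flux()
    if c <= 0:
        raise ValueError("cannot normalize a model with zero neutral flux")
    return MutationModel(model.P_mut, model.E_mut / c, model.label)


def _parse_dat_tokens(dat_text: str) -> list[float]:
    values: list[float] = []
    for tok in dat_text.split():
        try:
            values.append(float(tok))
        except ValueError:
            break  # trailing annotation (amino-acid labels) ends the numbers
    return values


def load_empirical(dat_text: str, label: str = "emp") -> MutationModel:
    """Read a PAML ``.dat`` empirical matrix (WAG/JTT layout).

    190 lower-triangular exchangeabilities followed by 20 frequencies; any
    trailing annotation is ignored. The model is returned normalized.
    """
    values = _parse_dat_tokens(dat_text)
    n_tri = N_AA * (N_AA - 1) // 2
    if len(values) < n_tri + N_AA:
        raise ValueError(
            f"malformed .dat file: expected {n_tri} exchangeabilities + "
            f"{N_AA} frequencies, found {len(values)} numbers"
        )
    e = np.zeros((N_AA, N_AA))
    k = 0
    for i in range(1, N_AA):
        for j in range(i):
            e[i, j] = e[j, i] = values[k]
            k += 1
    p = np.array(values[n_tri : n_tri + N_AA])
    return normalize(MutationModel(P_mut=p, E_mut=e, label=label))


def load_shipped_empirical(name: str = "wag") -> MutationModel:
    """Load the WAG or JTT matrix distributed with the package."""
    text = resources.files("protevol.data").joinpath(f"{name.lower()}.dat").read_text()
    return load_empirical(text, label="emp")


def _codon_generator(params: NucleotideParams) -> np.ndarray:
    n = len(SENSE_CODONS)
    q = np.zeros((n, n))
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [(x, y) for x, y in zip(c1, c2) if x != y]
            if len(diff) != 1:
                continue
            n_from, n_to = diff[0]
            rate = params.freq(n_to)
            if (n_from, n_to) in TRANSITIONS:
                rate *= params.kappa
            q[i, j] = rate
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def codon_mutation_model(
    params: NucleotideParams, label: str = "nuc_var"
) -> tuple[CodonProcess, MutationModel]:
    """Amino-acid mutation model induced by a codon-level process.

    Single-nucleotide changes only; targets that are stop codons are removed
    from the state space (fitness zero). The stationary distribution of the
    61 sense codons is the null space of the generator's transpose (power
    iteration fallback); P^mut sums it over synonymous codons and E^mut is
    built from symmetrized equilibrium fluxes between codon pairs.
    """
    if (params.f_nuc <= 0).any():
        raise ValueError("zero nucleotide frequency makes the codon chain reducible")
    q = _codon_generator(params)
    pi = _stationary(q)
    process = CodonProcess(Q=q, pi=pi)

    aa_of = np.array([AA_INDEX[CODON_TABLE[c]] for c in SENSE_CODONS])
    p_mut = np.bincount(aa_of, weights=pi, minlength=N_AA)
    flux_c = pi[:, None] * q  # equilibrium codon-level fluxes
    np.fill_diagonal(flux_c, 0.0)
    flux_aa = np.zeros((N_AA, N_AA))
    np.add.at(flux_aa, (aa_of[:, None], aa_of[None, :]), flux_c)
    flux_aa = 0.5 * (flux_aa + flux_aa.T)  # detailed balance only approximate
    np.fill_diagonal(flux_aa, 0.0)
    e = flux_aa / np.outer(p_mut, p_mut)
    model = normalize(MutationModel(P_mut=p_mut, E_mut=e, label=label))
    return process, model


def _stationary(q: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    ns = null_space(q.T, rcond=1e-10)
    if ns.shape[1] >= 1:
        pi = np.real(ns[:, 0])
        pi = np.abs(pi)
        pi = pi / pi.sum()
        if np.abs(pi @ q).max() < 1e-8:
            return _polish(pi, q, tol)
    # power-iteration fallback on the uniformized chain
    dt = 0.5 / np.abs(np.diag(q)).max()
    p = np.eye(q.shape[0]) + dt * q
    pi = np.full(q.shape[0], 1.0 / q.shape[0])
    for _ in range(200000):
        nxt = pi @ p
        if np.abs(nxt - pi).max() < 1e-15:
            break
        pi = nxt
    return _polish(pi / pi.sum(), q, tol)


def _polish(pi: np.ndarray, q: np.ndarray, tol: float) -> np.ndarray:
    dt = 0.5 / np.abs(np.diag(q)).max()
    p = np.eye(q.shape[0]) + dt * q
    for _ in range(10000):
        if np.abs(pi @ q).max() < tol:
            break
        pi = pi @ p
        pi = pi / pi.sum()
    return pi


def optimize_nucleotide_params(
    observed_counts: np.ndarray,
    kappa_grid: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 10.0),
    freq_search: bool = True,
) -> NucleotideParams:
    """Maximize sum_a n_obs(a) log P^mut_a over nucleotide parameters.

    Nelder-Mead over the frequency simplex (softmax parameterization, fixed
    starting point) for each kappa on the grid; deterministic.
    """
    counts = np.asarray(observed_counts, dtype=float)
    if counts.shape != (N_AA,) or (counts < 0).any():
        raise ValueError("observed_counts must be 20 non-negative numbers")
    if counts.sum() == 0:
        raise ValueError("observed_counts must not be all zero")

    def loglik(f_nuc: np.ndarray, kappa: float) -> float:
        _, model = codon_mutation_model(NucleotideParams(f_nuc, kappa))
        return float(counts @ np.log(model.P_mut))

    def softmax3(x: np.ndarray) -> np.ndarray:
        z = np.concatenate([x, [0.0]])
        z = np.exp(z - z.max())
        return z / z.sum()

    best: tuple[float, NucleotideParams] | None = None
    for kappa in kappa_grid:
        res = minimize(
            lambda x, k=kappa: -loglik(softmax3(x), k),
            x0=np.zeros(3),
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 2000},
        )
        cand = NucleotideParams(softmax3(res.x), kappa)
        score = -res.fun
        if best is None or score > best[0] + 1e-12:
            best = (score, cand)
    assert best is not None
    return best[1]


def hb_factor(fa, fb, tol: float = 1e-9):
    """(ln F_b - ln F_a)/(F_b - F_a), with the l'Hopital limit 1/F_b when the
    log-factors differ by less than ``tol``. Broadcasts over arrays."""
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if (fa <= 0).any() or (fb <= 0).any():
        raise ValueError("selective factors must be strictly positive")
    la, lb = np.log(fa), np.log(fb)
    near = np.abs(lb - la) < tol
    denom = np.where(near, 1.0, fb - fa)
    out = np.where(near, 1.0 / fb, (lb - la) / denom)
    return out


def flux_exchangeability(
    emp: MutationModel,
    site_factors: np.ndarray,
    p_mut: np.ndarray | None = None,
) -> MutationModel:
    """Exchangeability matrix whose site-averaged model flux reproduces the
    empirical flux.

    ``site_factors`` is the (L, 20) matrix of selective factors F^sel from a
    stability-constrained run. The empirical flux P^emp_a P^emp_b E^emp_ab is
    divided by the background flux and the site-averaged selection term
    (1/L) sum_i F_a F_b (ln F_b - ln F_a)/(F_b - F_a); the result is
    symmetrized and renormalized.
    """
    f = np.asarray(site_factors, dtype=float)
    if f.ndim != 2 or f.shape[1] != emp.n_states:
        raise ValueError("site_factors must be (L, n_states)")
    if (f <= 0).any():
        raise ValueError("selective factors must be strictly positive")
    p = emp.P_mut if p_mut is None else np.asarray(p_mut, dtype=float)
    sel = np.mean(
        f[:, :, None] * f[:, None, :] * hb_factor(f[:, :, None], f[:, None, :]),
        axis=0,
    )
    emp_flux = np.outer(emp.P_mut, emp.P_mut) * emp.E_mut
    denom = np.outer(p, p) * sel
    off = ~np.eye(emp.n_states, dtype=bool)
    if (denom[off] <= 0).any():
        a, b = np.argwhere(off & (denom <= 0))[0]
        raise ValueError(
            f"zero average selective term for pair ({AA_ORDER[a]}, {AA_ORDER[b]})"
        )
    e = np.zeros_like(emp_flux)
    e[off] = emp_flux[off] / denom[off]
    return normalize(MutationModel(P_mut=p, E_mut=e, label="flux"))
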