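"""Folding free energy of a sequence on a fixed native contact map.

The native state is scored by pairwise contact energies E(C, A) =
sum_{i<j} C_ij U(A_i, A_j). The unfolded state costs conformational entropy,
G_U = -T*L*S_U. The misfolded state is a random-energy-model (REM) estimate
over an ensemble of compact decoy contact maps, expanded to the third central
moment of the contact energy:

    G_misf = <E> - m2/(2T) + m3/(6T^2) - L*S_C*T,

held constant below the freezing temperature (the stationary point of the
expression in T). The folding free energy is the Boltzmann combination

    DeltaG = G_nat - T*log(exp(-G_misf/T) + exp(-G_U/T)),

and fitness is the fraction of folded protein, f = 1/(1 + exp(DeltaG/kT)).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.special import expit, log_expit, logsumexp

from .alphabet import AA_ORDER, N_AA, seq_to_indices
from .contacts import ContactMap, DecoyStats

__all__ = [
    "ContactPotential",
    "StabilityParams",
    "FreeEnergyBreakdown",
    "load_potential",
    "shipped_potential",
    "contact_energy",
    "native_free_energy",
    "unfolded_free_energy",
    "misfolding_free_energy",
    "rem_free_energy",
    "delta_g",
    "fitness",
    "log_fitness",
    "hydrophobicity_scale",
]

# canonical hydrophobics fixing the sign of the principal eigenvector
_HYDROPHOBIC = [AA_ORDER.index(a) for a in "ILVF"]


@dataclass
class ContactPotential:
    """Symmetric contact-interaction energies U(a,b) in kT units.

    For amino-acid potentials the matrix is 20x20 with 210 independent
    entries. Smaller alphabets are allowed for toy models. ``h`` is the
    hydrophobicity scale derived from the principal eigenvector (see
    :func:`hydrophobicity_scale`).
    """

    U: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.U, dtype=float)
        if u.ndim != 2 or u.shape[0] != u.shape[1]:
            raise ValueError("potential must be a square matrix")
        if not np.allclose(u, u.T, atol=1e-12):
            raise ValueError("potential must be symmetric")
        self.U = 0.5 * (u + u.T)

    @property
    def n_states(self) -> int:
        return self.U.shape[0]

    @property
    def n_independent(self) -> int:
        """Number of independent entries of the symmetric matrix (210 for 20)."""
        n = self.n_states
        return n * (n + 1) // 2

    @property
    def h(self) -> np.ndarray:
        return hydrophobicity_scale(self)


@dataclass
class StabilityParams:
    """Thermodynamic parameters (k_B = 1).

    T: temperature; S_U: conformational entropy per residue of the unfolded
    chain; S_C: log-number of compact decoy conformations per residue;
    freeze_clamp: hold G_misf constant below the REM freezing temperature.
    """

    T: float = 0.5
    S_U: float = 0.140
    S_C: float = 0.065
    freeze_clamp: bool = True

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if not (self.S_U >= self.S_C >= 0):
            raise ValueError("require S_U >= S_C >= 0")


@dataclass
class FreeEnergyBreakdown:
    G_nat: float
    G_U: float
    G_misf: float
    delta_G: float

    def to_dict(self) -> dict[str, float]:
        return {
            "G_nat": self.G_nat,
            "G_U": self.G_U,
            "G_misf": self.G_misf,
            "delta_G": self.delta_G,
        }

    def to_tsv(self) -> str:
        d = self.to_dict()
        return (
            "\t".join(d) + "\n" + "\t".join(f"{v:.10g}" for v in d.values()) + "\n"
        )


def load_potential(text: str) -> ContactPotential:
    """Parse a whitespace-delimited lower-triangular 20x20 potential file.

    Lines starting with ``#`` are comments; the amino-acid ordering is the
    PAML ordering documented in the shipped file's header. Exactly 210
    numbers are required.
    """
    values: list[float] = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        values.extend(float(tok) for tok in line.split())
    if len(values) != N_AA * (N_AA + 1) // 2:
        raise ValueError(
            f"expected {N_AA * (N_AA + 1) // 2} entries, found {len(values)}"
        )
    u = np.zeros((N_AA, N_AA))
    k = 0
    for i in range(N_AA):
        for j in range(i + 1):
            u[i, j] = u[j, i] = values[k]
            k += 1
    return ContactPotential(u)


def shipped_potential() -> ContactPotential:
    """The potential distributed with the package (synthetic; see its header)."""
    text = (
        resources.files("protevol.data")
        .joinpath("potential_synthetic.dat")
        .read_text()
    )
    return load_potential(text)


def pair_energies(seq: str, pot: ContactPotential) -> np.ndarray:
    """Symmetric L x L matrix u_ij = U(A_i, A_j)."""
    if pot.n_states != N_AA:
        raise ValueError("sequence scoring requires a 20-state potential")
    idx = seq_to_indices(seq)
    return pot.U[np.ix_(idx, idx)]


def contact_energy(cmap: ContactMap, seq: str, pot: ContactPotential) -> float:
    """E(C, A) = sum_{i<j} C_ij U(A_i, A_j)."""
    if len(seq) != cmap.length:
        raise ValueError("sequence length does not match contact map")
    u = pair_energies(seq, pot)
    return float(0.5 * np.sum(cmap.contacts * u))


def native_free_energy(cmap: ContactMap, seq: str, pot: ContactPotential) -> float:
    """Native free energy; conformational entropy of the folded state neglected."""
    return contact_energy(cmap, seq, pot)


def unfolded_free_energy(L: int, params: StabilityParams) -> float:
    return -params.T * L * params.S_U


def _freezing_temperature(m2, L: int, S_C: float) -> np.ndarray:
    """REM freezing temperature sqrt(m2 / (2 L S_C)).

    This is the stationary point of the quadratic REM free energy
    (dG/dT = m2/(2T^2) - L*S_C = 0), at which the misfolded-ensemble entropy
    vanishes. The third-moment correction is kept in the evaluated free
    energy but not in the freezing point: the cubic stationarity condition
    can lose its positive root entirely (a saddle-node in the moments), which
    would make the free energy a discontinuous function of the sequence
    composition, whereas the quadratic form is smooth everywhere.
    Vectorized; 0 where m2 = 0 or S_C = 0.
    """
    m2 = np.asarray(m2, dtype=float)
    ls = L * S_C
    if ls <= 0:
        return np.zeros_like(m2)
    return np.sqrt(np.maximum(m2, 0.0) / (2.0 * ls))


_FREEZE_SMOOTHING = 16  # p-norm order of the smooth max(T, T_freeze)


def rem_free_energy(mean, m2, m3, L: int, params: StabilityParams) -> np.ndarray:
    """REM misfolding free energy from central moments of the contact energy.

    Broadcasts over arrays of moments. The freeze clamp evaluates the
    expression at a smooth maximum of T and the freezing temperature,
    T_eff = (T^p + T_f^p)^(1/p) with p = 16: the hard clamp would make the
    free energy non-differentiable exactly where T_f crosses T, which
    destabilizes the mean-field fixed point; the p-norm keeps the map smooth
    while deviating from max(T, T_f) by at most ~4% in T_eff at the crossing
    (a finite-size smoothing of the freezing transition).
    """
    mean = np.asarray(mean, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    m3 = np.asarray(m3, dtype=float)
    T = params.T
    if params.freeze_clamp:
        tf = _freezing_temperature(m2, L, params.S_C)
        p = _FREEZE_SMOOTHING
        T = (T**p + tf**p) ** (1.0 / p)
    return mean - m2 / (2.0 * T) + m3 / (6.0 * T**2) - L * params.S_C * T


def misfolding_free_energy(
    seq: str, pot: ContactPotential, stats: DecoyStats, params: StabilityParams
) -> float:
    """REM estimate over the decoy set, third central moment included."""
    if stats.length != len(seq):
        raise ValueError("decoy statistics length does not match sequence")
    mean, m2, m3 = stats.energy_moments(pair_energies(seq, pot))
    return float(rem_free_energy(mean, m2, m3, len(seq), params))


def delta_g(
    cmap: ContactMap,
    seq: str,
    pot: ContactPotential,
    stats: DecoyStats | None,
    params: StabilityParams,
) -> FreeEnergyBreakdown:
    """Folding free energy with the non-native state as a Boltzmann average.

    With ``stats=None`` misfolding is disabled and DeltaG = G_nat - G_U.
    """
    g_nat = native_free_energy(cmap, seq, pot)
    g_u = unfolded_free_energy(len(seq), params)
    if stats is None:
        return FreeEnergyBreakdown(g_nat, g_u, np.inf, g_nat - g_u)
    g_misf = misfolding_free_energy(seq, pot, stats, params)
    T = params.T
    g_nonnat = -T * logsumexp([-g_misf / T, -g_u / T])
    return FreeEnergyBreakdown(g_nat, g_u, g_misf, g_nat - g_nonnat)


def fitness(delta_G, kT: float = 1.0):
    """Fraction of folded protein, f = 1/(1 + exp(DeltaG/kT)), in (0, 1)."""
    if kT <= 0:
        raise ValueError("kT must be positive")
    return expit(-np.asarray(delta_G, dtype=float) / kT)


def log_fitness(delta_G, kT: float = 1.0):
    """log f computed stably (no overflow for strongly destabilized sequences)."""
    if kT <= 0:
        raise ValueError("kT must be positive")
    return log_expit(-np.asarray(delta_G, dtype=float) / kT)


def hydrophobicity_scale(pot: ContactPotential) -> np.ndarray:
    """Hydrophobicity scale h(a): principal eigenvector of U.

    The eigenvector of largest |eigenvalue| (contact potentials are dominated
    by a rank-1 hydrophobicity term, U(a,b) ~ eps*h(a)*h(b) with eps < 0),
    normalized to unit L2 norm with the sign fixed so that the canonical
    hydrophobics I, L, V, F have positive mean component. With the shipped
    potential the mean of h over the 20 amino acids is 0.14, the average
    hydrophobicity of the uniform distribution.
    """
    w, v = np.linalg.eigh(pot.U)
    h = v[:, np.argmax(np.abs(w))]
    if pot.n_states == N_AA:
        if h[_HYDROPHOBIC].mean() < 0:
            h = -h
    elif h.sum() < 0:
        h = -h
    return h
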