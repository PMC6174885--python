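"""Native contact maps and decoy-ensemble contact statistics.

A protein structure is reduced to its binary contact matrix: residues i and j
are in contact when any pair of their heavy atoms lies closer than a cutoff
(4.5 A by default) and the chain separation |i-j| is at least 3; shorter-range
contacts form in essentially every conformation and carry no information about
the native fold, so they are zeroed.

The misfolded ensemble is represented by a set of alternative compact contact
maps ("decoys"); the statistics of the contact indicators over that set are
what the random-energy-model misfolding free energy consumes.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_ORDER, THREE_TO_ONE

log = logging.getLogger(__name__)

__all__ = [
    "ResidueChain",
    "ContactMap",
    "DecoyStats",
    "parse_structure",
    "contact_matrix",
    "decoy_contact_statistics",
    "synth_chain",
]


@dataclass
class ResidueChain:
    """Ordered residues of a single protein chain.

    ``residues`` holds (1-based index, one-letter amino acid, heavy-atom
    coordinates in Angstrom) triples with strictly increasing indices.
    """

    residues: list[tuple[int, str, np.ndarray]]

    def __post_init__(self) -> None:
        idx = [r[0] for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")
        for i, aa, atoms in self.residues:
            if aa not in AA_ORDER:
                raise ValueError(f"residue {i}: non-canonical amino acid {aa!r}")
            if len(atoms) == 0:
                raise ValueError(f"residue {i} has no heavy atoms")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r[1] for r in self.residues)


@dataclass
class ContactMap:
    """Symmetric binary native contact matrix with the |i-j| <= 2 exclusion."""

    contacts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.contacts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.array_equal(c, c.T):
            raise ValueError("contact matrix must be symmetric")
        if not np.isin(c, (0, 1)).all():
            raise ValueError("contact matrix must be binary")
        L = c.shape[0]
        ii, jj = np.indices((L, L))
        if c[np.abs(ii - jj) <= 2].any():
            raise ValueError("contacts with |i-j| <= 2 must be zero")
        self.contacts = c.astype(np.uint8)

    @property
    def length(self) -> int:
        return self.contacts.shape[0]

    def n_contacts_per_site(self) -> np.ndarray:
        return self.contacts.sum(axis=1).astype(int)

    def to_tsv(self) -> str:
        """Serialize as 3-column TSV (i, j, 1) with 1-based indices, i < j."""
        ii, jj = np.nonzero(np.triu(self.contacts))
        lines = ["i\tj\tcontact"]
        lines += [f"{i + 1}\t{j + 1}\t1" for i, j in zip(ii, jj)]
        return "\n".join(lines) + "\n"


@dataclass
class DecoyStats:
    """Contact statistics of a decoy ensemble of maps of a common length.

    The (windowed) decoy indicator matrices are stored explicitly; pair and
    triple central co-moments of the contacts — and hence the second and third
    central moments of the contact energy E for any sequence — are evaluated
    exactly from them, which coincides with direct averaging over the decoy
    set. ``mean_by_separation`` tabulates <C_ij> collapsed onto separation
    classes s = |i-j| (the tabulated form used for reporting).
    """

    length: int
    maps: np.ndarray  # (n_decoys, L, L) uint8
    mean_by_separation: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.maps, dtype=np.uint8)
        if m.ndim != 3 or m.shape[1] != self.length or m.shape[2] != self.length:
            raise ValueError("decoy maps must be (n_decoys, L, L)")
        self.maps = m
        mean = m.mean(axis=0)
        L = self.length
        seps = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
        out = np.zeros(L)
        for s in range(1, L):
            sel = seps == s
            out[s] = mean[sel].mean()
        self.mean_by_separation = out

    @property
    def n_decoys(self) -> int:
        return self.maps.shape[0]

    @property
    def mean_contact(self) -> np.ndarray:
        """Exact <C_ij> over the decoy set."""
        return self.maps.mean(axis=0)

    def energy_moments(self, pair_energy: np.ndarray) -> tuple[float, float, float]:
        """Central moments (<E>, m2, m3) of E = sum_{i<j} C_ij u_ij.

        ``pair_energy`` is the symmetric L x L matrix u_ij = U(A_i, A_j).
        """
        u = np.asarray(pair_energy)
        e = 0.5 * np.einsum("kij,ij->k", self.maps.astype(float), u)
        mu = e.mean()
        d = e - mu
        return float(mu), float((d**2).mean()), float((d**3).mean())

    def to_tsv(self) -> str:
        lines = ["separation\tmean_contact"]
        lines += [
            f"{s}\t{self.mean_by_separation[s]:.10g}" for s in range(1, self.length)
        ]
        return "\n".join(lines) + "\n"


def parse_structure(pdb_text: str, chain_id: str) -> ResidueChain:
    """Extract one chain from PDB text: first model, ATOM records, heavy atoms.

    Non-standard residues are skipped with a warning; HETATM ligands and
    hydrogens are excluded. Residues are renumbered consecutively from 1 so
    that chain breaks do not distort separation classes (logged when the
    author numbering is discontinuous).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("x", io.StringIO(pdb_text))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError("PDB text contains no model") from None
    if chain_id not in [c.id for c in model]:
        raise ValueError(f"chain {chain_id!r} not found in structure")
    chain = model[chain_id]

    residues: list[tuple[int, str, np.ndarray]] = []
    author_numbers: list[int] = []
    for res in chain:
        hetflag, resseq, _ = res.id
        if hetflag.strip():  # HETATM (ligands, waters)
            continue
        name = res.get_resname().upper()
        if name not in THREE_TO_ONE:
            log.warning("skipping non-standard residue %s %s", name, resseq)
            continue
        coords = _heavy_atom_coords(res)
        if coords.size == 0:
            log.warning("skipping residue %s %s with no heavy atoms", name, resseq)
            continue
        residues.append((len(residues) + 1, THREE_TO_ONE[name], coords))
        author_numbers.append(resseq)
    if not residues:
        raise ValueError(f"chain {chain_id!r} has no standard residues")
    if any(b - a != 1 for a, b in zip(author_numbers, author_numbers[1:])):
        log.info("chain %s has non-consecutive author numbering; renumbered 1..L", chain_id)
    return ResidueChain(residues)


def _heavy_atom_coords(res) -> np.ndarray:
    coords = []
    for atom in res:
        if atom.element == "H" or atom.get_name().startswith("H"):
            continue
        if atom.is_disordered():
            # keep highest occupancy; ties resolved toward altloc 'A'
            alts = sorted(
                atom.disordered_get_list(),
                key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
            )
            coords.append(alts[0].get_coord())
        else:
            coords.append(atom.get_coord())
    return np.asarray(coords, dtype=float)


def contact_matrix(
    chain: ResidueChain, cutoff: float = 4.5, min_separation: int = 3
) -> ContactMap:
    """Binary contact map: heavy-atom pair strictly closer than ``cutoff`` A
    and chain separation |i-j| >= ``min_separation``."""
    L = len(chain)
    if L < min_separation + 1:
        raise ValueError("chain too short for the requested minimum separation")
    c = np.zeros((L, L), dtype=np.uint8)
    coords = [r[2] for r in chain.residues]
    for i in range(L):
        for j in range(i + min_separation, L):
            d = np.linalg.norm(coords[i][:, None, :] - coords[j][None, :, :], axis=-1)
            if d.min() < cutoff:
                c[i, j] = c[j, i] = 1
    return ContactMap(c)


def decoy_contact_statistics(decoys: list[ContactMap], target_length: int) -> DecoyStats:
    """Collect contact statistics of a decoy set, reindexed to ``target_length``.

    Decoys longer than the target contribute every contiguous length-L window
    (threading-style); shorter decoys are an error.
    """
    if len(decoys) < 2:
        raise ValueError("need at least 2 decoys")
    windows = []
    for d in decoys:
        if d.length < target_length:
            raise ValueError(
                f"decoy of length {d.length} shorter than target {target_length}"
            )
        for s in range(d.length - target_length + 1):
            windows.append(d.contacts[s : s + target_length, s : s + target_length])
    return DecoyStats(length=target_length, maps=np.stack(windows))


def synth_chain(
    L: int, seed: int, compactness: float = 1.0, cutoff: float = 6.0
) -> tuple[ResidueChain, ContactMap]:
    """Generate a reproducible toy chain and its contact map.

    Residues are single pseudo-atoms placed by a persistent random walk with
    bond length 3.8 A; ``compactness`` blends in an attraction towards the
    running centroid, so the mean contact number increases monotonically with
    it (0 gives a near-straight chain with essentially no contacts). Amino
    acids are drawn uniformly. A soft excluded volume keeps non-bonded
    pseudo-atoms from overlapping. The default cutoff is larger than the
    4.5 A heavy-atom value because each residue is a single C-beta-like
    pseudo-atom: 6.0 A reproduces realistic per-residue contact numbers
    (mean ~5, buried sites ~10+).
    """
    if L < 10:
        raise ValueError("L must be >= 10")
    rng = np.random.default_rng(seed)
    bond = 3.8
    # radius of a globule with roughly constant residue density
    r0 = 2.8 * L ** (1.0 / 3.0)
    pos = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    for _ in range(1, L):
        centroid = np.mean(pos, axis=0)
        for _attempt in range(60):
            noise = rng.normal(scale=0.45, size=3)
            out_vec = pos[-1] - centroid
            dist = np.linalg.norm(out_vec)
            # pull back toward the globule only outside the target radius
            pull = -out_vec / dist * (dist / r0) ** 2 if dist > 1e-9 else np.zeros(3)
            step = (1.0 - compactness) * direction + compactness * pull + noise
            step = step / np.linalg.norm(step)
            cand = pos[-1] + bond * step
            prior = np.asarray(pos[:-1])
            if prior.size == 0 or np.linalg.norm(prior - cand, axis=1).min() > 3.2:
                break
        direction = step
        pos.append(cand)
    aa = rng.choice(list(AA_ORDER), size=L)
    residues = [(i + 1, aa[i], np.asarray([pos[i]])) for i in range(L)]
    chain = ResidueChain(residues)
    return chain, contact_matrix(chain, cutoff=cutoff)
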