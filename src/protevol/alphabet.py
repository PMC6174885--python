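"""Amino-acid alphabet and genetic-code conventions used across the package.

The canonical ordering is the PAML ``.dat`` ordering (A R N D C Q E G H I L K
M F P S T W Y V); every 20-vector and 20x20 matrix in the package is indexed
in this order unless stated otherwise.
"""

from __future__ import annotations

import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
N_AA = len(AA_ORDER)
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

# Three-letter residue names of the 20 canonical amino acids (PDB convention).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

NUCLEOTIDES = "TCAG"
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _standard_code() -> tuple[dict[str, str], frozenset[str]]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    return dict(table.forward_table), frozenset(table.stop_codons)


#: codon -> one-letter amino acid for the 61 sense codons (standard code)
CODON_TABLE, STOP_CODONS = _standard_code()
SENSE_CODONS = sorted(CODON_TABLE)


def seq_to_indices(seq: str) -> np.ndarray:
    """Map an amino-acid string onto integer indices in ``AA_ORDER``."""
    try:
        return np.array([AA_INDEX[a] for a in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"non-canonical amino acid {exc.args[0]!r} in sequence") from None


def indices_to_seq(idx: np.ndarray) -> str:
    return "".join(AA_ORDER[i] for i in idx)


def one_hot(seq: str, n_states: int = N_AA) -> np.ndarray:
    """(L, n_states) indicator matrix of a sequence."""
    idx = seq_to_indices(seq)
    out = np.zeros((len(idx), n_states))
    out[np.arange(len(idx)), idx] = 1.0
    return out
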