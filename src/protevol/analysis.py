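"""End-to-end analyses: per-site tables, entropy/rate curves, GC sweeps.

The per-site table carries, for every position, the native contact count, the
mean hydrophobicity of its stationary distribution, its sequence entropy and
its substitution rate. Binned curves against site hydrophobicity reproduce
the characteristic patterns of stability-constrained evolution: a bell-shaped
entropy curve peaking at the hydrophobicity of the uniform distribution, and
a rate curve whose peak tracks the hydrophobicity of the mutation process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactMap, DecoyStats, ResidueChain, contact_matrix, parse_structure, decoy_contact_statistics
from .mutation import (
    MutationModel,
    codon_mutation_model,
    flux_exchangeability,
    gc_params,
    load_shipped_empirical,
    observed_frequencies,
    optimize_nucleotide_params,
    normalize,
)
from .selection import SiteDistributions, fit_lambda, mf_distributions, wt_phi_matrix, distributions_from_phi
from .stability import ContactPotential, StabilityParams, hydrophobicity_scale
from .substitution import build_site_processes

__all__ = [
    "BinnedCurve",
    "ProteinResult",
    "analyze_protein",
    "run_protein",
    "branch_split",
    "gc_sweep",
    "binned_curve",
    "curve_is_unimodal",
    "build_mutation_model",
]


@dataclass
class BinnedCurve:
    """Binned means of a per-site quantity against a per-site coordinate."""

    bin_centers: np.ndarray
    bin_means: np.ndarray
    bin_counts: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (np.asarray(self.bin_counts) < 1).any():
            raise ValueError("reported bins must be non-empty")
        if not np.isfinite(self.bin_means).all():
            raise ValueError("bin means must be finite")

    def peak_center(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.bin_means))])


@dataclass
class ProteinResult:
    table: pd.DataFrame
    summary: dict
    dists: SiteDistributions
    mut: MutationModel


def binned_curve(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int = 10,
    kind: str = "equal_count",
    labels: dict | None = None,
) -> BinnedCurve:
    """Bin y against x with equal-count (default) or equal-width bins."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if kind == "equal_count":
        order = np.argsort(x, kind="stable")
        splits = np.array_split(order, n_bins)
        splits = [s for s in splits if s.size]
        centers = np.array([x[s].mean() for s in splits])
        means = np.array([y[s].mean() for s in splits])
        counts = np.array([s.size for s in splits])
    elif kind == "equal_width":
        edges = np.linspace(x.min(), x.max() + 1e-12, n_bins + 1)
        which = np.digitize(x, edges) - 1
        centers, means, counts = [], [], []
        for b in range(n_bins):
            sel = which == b
            if sel.any():
                centers.append(x[sel].mean())
                means.append(y[sel].mean())
                counts.append(int(sel.sum()))
        centers, means, counts = map(np.array, (centers, means, counts))
    else:
        raise ValueError(f"unknown binning kind {kind!r}")
    return BinnedCurve(centers, means, counts, labels or {})


def curve_is_unimodal(values: np.ndarray, tol: float = 1e-9) -> bool:
    """Up-then-down shape check with one permitted plateau.

    Differences within ``tol`` count as flat; the sign sequence of the
    remaining differences must be a (possibly empty) run of + followed by a
    (possibly empty) run of -.
    """
    d = np.diff(np.asarray(values, dtype=float))
    signs = [int(np.sign(v)) for v in d if abs(v) > tol]
    seen_down = False
    for s in signs:
        if s < 0:
            seen_down = True
        elif seen_down:
            return False
    return True


def build_mutation_model(
    name: str,
    seq: str | None = None,
    gc: float | None = None,
    kappa: float = 2.0,
    exchange: str = "wag",
    pmut_source: str = "observed",
    site_factors: np.ndarray | None = None,
) -> MutationModel:
    """Construct one of the four global mutation models.

    ``emp``/``flux`` start from the shipped WAG or JTT matrix; their
    background frequencies come from the input sequence (pseudocounted) or,
    with ``pmut_source='dat'``, from the .dat file. ``flux`` additionally
    needs the per-site selective factors of a previous stability-constrained
    run. ``nuc_opt`` optimizes nucleotide parameters against the sequence
    composition; ``nuc_var`` uses the supplied GC content.
    """
    if name in ("emp", "flux"):
        emp = load_shipped_empirical(exchange)
        if pmut_source == "observed":
            if seq is None:
                raise ValueError("observed background frequencies need a sequence")
            emp = normalize(MutationModel(observed_frequencies(seq), emp.E_mut, "emp"))
        elif pmut_source != "dat":
            raise ValueError(f"unknown pmut_source {pmut_source!r}")
        if name == "emp":
            return emp
        if site_factors is None:
            raise ValueError("the flux model needs site selective factors")
        return flux_exchangeability(emp, site_factors)
    if name == "nuc_opt":
        if seq is None:
            raise ValueError("nuc_opt needs a sequence to optimize against")
        counts = observed_frequencies(seq, pseudocount=0.0) * len(seq)
        params = optimize_nucleotide_params(np.round(counts).astype(int))
        _, model = codon_mutation_model(params, label="nuc_opt")
        return model
    if name == "nuc_var":
        if gc is None:
            raise ValueError("nuc_var needs a GC content")
        _, model = codon_mutation_model(gc_params(gc, kappa), label="nuc_var")
        return model
    raise ValueError(f"unknown mutation model {name!r}")


def analyze_protein(
    cmap: ContactMap,
    seq: str,
    pot: ContactPotential,
    stats: DecoyStats | None,
    sparams: StabilityParams,
    mut_model: str | MutationModel = "flux",
    sel_model: str = "MF",
    lam: float | str = "auto",
    gc: float | None = None,
    kappa: float = 2.0,
    exchange: str = "wag",
    pmut_source: str = "observed",
) -> ProteinResult:
    """Full pipeline on in-memory objects: fit the selection model, build the
    site processes, and tabulate per-site entropy, rate and hydrophobicity.

    For the ``flux`` mutation model the selective factors are taken from the
    run itself (fitted under the empirical exchangeabilities, which share the
    same background frequencies and hence the same site distributions).
    """
    want_flux = mut_model == "flux"
    if isinstance(mut_model, str):
        base = build_mutation_model(
            "emp" if want_flux else mut_model,
            seq=seq,
            gc=gc,
            kappa=kappa,
            exchange=exchange,
            pmut_source=pmut_source,
        )
    else:
        base = mut_model

    if sel_model == "WT":
        phi = wt_phi_matrix(cmap, seq, pot, stats, sparams)
        builder = lambda l: distributions_from_phi(phi, base, l, "WT")
    elif sel_model == "MF":
        builder = lambda l: mf_distributions(cmap, pot, stats, sparams, base, l)
    else:
        raise ValueError(f"unknown selection model {sel_model!r}")

    if lam == "auto":
        lam_hat, dists = fit_lambda(builder, seq)
    else:
        lam_hat = float(lam)
        dists = builder(lam_hat)

    mut = base
    if want_flux:
        factors = dists.P / base.P_mut[None, :]
        mut = flux_exchangeability(base, factors)

    procs = build_site_processes(dists, mut)
    h = hydrophobicity_scale(pot)
    ncont = cmap.n_contacts_per_site()
    table = pd.DataFrame(
        {
            "site": np.arange(1, cmap.length + 1),
            "aa": list(seq),
            "n_contacts": ncont,
            "hydrophobicity": dists.P @ h,
            "entropy": [p.entropy for p in procs],
            "rate": [p.rate for p in procs],
        }
    )
    summary = {
        "length": cmap.length,
        "sel_model": sel_model,
        "mut_model": mut.label,
        "lambda": lam_hat,
        "mean_hydrophobicity": float(table["hydrophobicity"].mean()),
        "mean_rate": float(table["rate"].mean()),
        "mean_entropy": float(table["entropy"].mean()),
    }
    return ProteinResult(table=table, summary=summary, dists=dists, mut=mut)


def run_protein(
    pdb_text: str,
    chain_id: str,
    pot: ContactPotential,
    sparams: StabilityParams,
    decoys: list[ContactMap] | None = None,
    **kwargs,
) -> ProteinResult:
    """Parse a PDB chain and run :func:`analyze_protein` on it."""
    chain = parse_structure(pdb_text, chain_id)
    cmap = contact_matrix(chain)
    stats = (
        decoy_contact_statistics(decoys, cmap.length) if decoys is not None else None
    )
    return analyze_protein(cmap, chain.sequence, pot, stats, sparams, **kwargs)


def branch_split(
    table: pd.DataFrame, contact_threshold: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition sites into low-contact and high-contact branches.

    Default threshold is the median contact count; sites strictly below it go
    to the low branch, the rest to the high branch.
    """
    if contact_threshold is None:
        contact_threshold = float(table["n_contacts"].median())
    low = table[table["n_contacts"] < contact_threshold]
    high = table[table["n_contacts"] >= contact_threshold]
    return low, high


def gc_sweep(
    cmap: ContactMap,
    seq: str,
    pot: ContactPotential,
    stats: DecoyStats | None,
    sparams: StabilityParams,
    gc_values: tuple[float, ...] = (0.2, 0.35, 0.5, 0.65, 0.8),
    sel_model: str = "WT",
    kappa: float = 2.0,
    n_bins: int = 8,
) -> dict[float, dict]:
    """One full run per GC value under the nuc_var codon mutation model.

    Returns, for each GC, the per-site table and the binned entropy and rate
    curves against site hydrophobicity.
    """
    out: dict[float, dict] = {}
    for gc in gc_values:
        res = analyze_protein(
            cmap, seq, pot, stats, sparams,
            mut_model="nuc_var", sel_model=sel_model, gc=gc, kappa=kappa,
        )
        t = res.table
        labels = {"gc": gc, "sel_model": sel_model, "mut_model": "nuc_var"}
        out[gc] = {
            "table": t,
            "summary": res.summary,
            "entropy_curve": binned_curve(
                t["hydrophobicity"], t["entropy"], n_bins=n_bins,
                labels={**labels, "quantity": "entropy"},
            ),
            "rate_curve": binned_curve(
                t["hydrophobicity"], t["rate"], n_bins=n_bins,
                labels={**labels, "quantity": "rate"},
            ),
        }
    return out
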