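"""Site-specific distributions under MF and WT selection, and Lambda fitting."""

import itertools

import numpy as np
import pytest

import protevol as pe
from protevol.alphabet import AA_ORDER, one_hot, seq_to_indices
from protevol.contacts import ContactMap, DecoyStats
from protevol.fixtures import FixtureSpec, compact_protein_fixture, sample_sequences
from protevol.mutation import MutationModel
from protevol.selection import (
    distributions_from_phi,
    fit_lambda,
    kimura_fixation,
    site_delta_g_matrix,
    wt_phi_matrix,
)
from protevol.stability import ContactPotential, StabilityParams, log_fitness


class TestKimuraFixation:
    def test_neutral_limit(self):
        assert kimura_fixation(0.0, 0.0, 50) == pytest.approx(1 / 50, rel=1e-9)

    def test_strongly_deleterious(self):
        assert kimura_fixation(0.0, -5.0, 100) < 1e-20

    def test_strongly_beneficial(self):
        assert kimura_fixation(0.0, 5.0, 100) == pytest.approx(1 - np.exp(-5), rel=1e-3)

    def test_continuity_at_zero(self):
        eps = 1e-7
        assert kimura_fixation(0.0, eps, 10) == pytest.approx(1 / 10, rel=1e-5)
        assert kimura_fixation(0.0, -eps, 10) == pytest.approx(1 / 10, rel=1e-5)

    def test_invalid_population_size(self):
        with pytest.raises(ValueError):
            kimura_fixation(0.0, 0.0, 1)


@pytest.fixture(scope="module")
def small_system(pot, sparams):
    spec = FixtureSpec(seed=2, L=12, n_decoys=6, compactness=1.0)
    _, cmap, decoys = compact_protein_fixture(spec)
    stats = pe.decoy_contact_statistics(decoys, 12)
    return cmap, stats


class TestWildTypeModel:
    def test_lambda_zero_returns_background(self, small_system, pot, sparams, wag):
        cmap, stats = small_system
        seq = "ILKWAVDEGHNC"
        dists = pe.wt_distributions(cmap, seq, pot, stats, sparams, wag, lam=0.0)
        assert np.allclose(dists.P, np.tile(wag.P_mut, (12, 1)), atol=1e-12)

    def test_large_lambda_concentrates_on_best_mutant(self, small_system, pot, sparams, wag):
        cmap, stats = small_system
        seq = "ILKWAVDEGHNC"
        phi = wt_phi_matrix(cmap, seq, pot, stats, sparams)
        dists = pe.wt_distributions(cmap, seq, pot, stats, sparams, wag, lam=1e6)
        assert (dists.P.argmax(axis=1) == phi.argmax(axis=1)).mean() > 0.9

    def test_matches_explicit_mutant_scan(self, small_system, pot, sparams):
        """The vectorized one-hot field equals mutating the sequence one site
        at a time and calling the scalar free-energy pipeline."""
        cmap, stats = small_system
        seq = "ILKWAVDEGHNC"
        phi = wt_phi_matrix(cmap, seq, pot, stats, sparams)
        for i in (0, 5, 11):
            for a in "IKD":
                mutant = seq[:i] + a + seq[i + 1:]
                br = pe.delta_g(cmap, mutant, pot, stats, sparams)
                expected = pe.log_fitness(br.delta_G)
                assert phi[i, AA_ORDER.index(a)] == pytest.approx(expected, abs=1e-10)

    def test_row_stochastic(self, small_system, pot, sparams, wag):
        cmap, stats = small_system
        dists = pe.wt_distributions(cmap, "ILKWAVDEGHNC", pot, stats, sparams, wag, lam=3.0)
        assert np.allclose(dists.P.sum(axis=1), 1.0, atol=1e-12)
        assert (dists.P > 0).all()


def _toy_three_letter():
    """4-site chain, 3-letter alphabet, one long-range contact, tiny decoys."""
    cm = np.zeros((4, 4), int)
    cm[0, 3] = cm[3, 0] = 1
    cmap = ContactMap(cm)
    d_empty = np.zeros((4, 4), int)
    d_contact = np.zeros((4, 4), int)
    d_contact[0, 3] = d_contact[3, 0] = 1
    stats = DecoyStats(4, np.stack([d_empty, d_contact, d_contact]))
    h3 = np.array([0.5, 0.1, -0.2])
    rng = np.random.default_rng(2)
    noise = rng.normal(scale=0.05, size=(3, 3))
    pot3 = ContactPotential(-4.0 * np.outer(h3, h3) + 0.5 * (noise + noise.T))
    params = StabilityParams(T=0.5, S_U=0.2, S_C=0.1)
    mut = MutationModel(np.array([0.5, 0.3, 0.2]), np.ones((3, 3)), "toy")
    return cmap, stats, pot3, params, mut


class TestMeanFieldModel:
    def test_lambda_zero_returns_background(self, small_system, pot, sparams, wag):
        cmap, stats = small_system
        dists = pe.mf_distributions(cmap, pot, stats, sparams, wag, lam=0.0)
        assert np.allclose(dists.P, np.tile(wag.P_mut, (12, 1)), atol=1e-9)

    def test_zero_potential_is_background_for_any_lambda(self, small_system, sparams, wag):
        cmap, stats = small_system
        zpot = ContactPotential(np.zeros((20, 20)))
        dists = pe.mf_distributions(cmap, zpot, stats, sparams, wag, lam=5.0)
        assert np.allclose(dists.P, np.tile(wag.P_mut, (12, 1)), atol=1e-9)

    def test_marginals_match_exact_enumeration(self):
        """MF rows against the exact sequence-level Boltzmann distribution
        enumerated over all 3^4 sequences (KL per site < 0.05)."""
        cmap, stats, pot3, params, mut = _toy_three_letter()
        lam = 2.0
        exact = np.zeros((4, 3))
        for assignment in itertools.product(range(3), repeat=4):
            w = np.zeros((4, 3))
            w[np.arange(4), assignment] = 1.0
            dg = site_delta_g_matrix(cmap, pot3, stats, params, w)[0, assignment[0]]
            weight = np.prod(mut.P_mut[list(assignment)]) * np.exp(lam * log_fitness(dg))
            for i, a in enumerate(assignment):
                exact[i, a] += weight
        exact /= exact.sum(axis=1, keepdims=True)
        mf = pe.mf_distributions(cmap, pot3, stats, params, mut, lam=lam)
        kl = (exact * np.log(exact / mf.P)).sum(axis=1)
        assert kl.max() < 0.05

    def test_agrees_with_wt_at_small_lambda(self, pot, sparams, wag):
        spec = FixtureSpec(seed=4, L=10, n_decoys=6, compactness=1.0)
        chain, cmap, decoys = compact_protein_fixture(spec)
        stats = pe.decoy_contact_statistics(decoys, 10)
        lam = 0.2
        mf = pe.mf_distributions(cmap, pot, stats, sparams, wag, lam=lam)
        wt = pe.wt_distributions(cmap, chain.sequence, pot, stats, sparams, wag, lam=lam)
        kl = (mf.P * np.log(mf.P / wt.P)).sum(axis=1)
        assert kl.max() < 0.1

    def test_buried_sites_more_hydrophobic(self, protein50, pot, sparams, wag):
        from scipy.stats import spearmanr

        cmap, stats = protein50["cmap"], protein50["stats"]
        mf = pe.mf_distributions(cmap, pot, stats, sparams, wag, lam=20.0)
        h = pe.hydrophobicity_scale(pot)
        rho = spearmanr(cmap.n_contacts_per_site(), mf.P @ h).statistic
        assert rho > 0

    def test_entropy_vs_hydrophobicity_bell_shape(self, protein50, pot, sparams, wag):
        cmap, stats = protein50["cmap"], protein50["stats"]
        mf = pe.mf_distributions(cmap, pot, stats, sparams, wag, lam=20.0)
        h = pe.hydrophobicity_scale(pot)
        S = -(mf.P * np.log(mf.P)).sum(axis=1)
        curve = pe.binned_curve(mf.P @ h, S, n_bins=6)
        assert pe.curve_is_unimodal(curve.bin_means, tol=0.01)


class TestFitLambda:
    def test_recovers_generating_strength(self, protein50, pot, sparams, wag):
        cmap, stats, seq = protein50["cmap"], protein50["stats"], protein50["seq"]
        phi = wt_phi_matrix(cmap, seq, pot, stats, sparams)
        builder = lambda l: distributions_from_phi(phi, wag, l, "WT")
        gen = builder(2.0)
        lams = [fit_lambda(builder, sample_sequences(gen, 1, 50 + s)[0])[0]
                for s in range(3)]
        assert all(abs(l - 2.0) / 2.0 < 0.6 for l in lams)  # tight check in acceptance

    def test_flat_likelihood_returns_lower_bracket(self, small_system, sparams, wag, caplog):
        cmap, stats = small_system
        zpot = ContactPotential(np.zeros((20, 20)))
        builder = lambda l: pe.mf_distributions(cmap, zpot, stats, sparams, wag, lam=l)
        with caplog.at_level("WARNING"):
            lam, _ = fit_lambda(builder, "ILKWAVDEGHNC")
        assert lam == 0.0
        assert any("flat" in r.message for r in caplog.records)

    def test_local_maximum_certificate(self, protein50, pot, sparams, wag):
        cmap, stats, seq = protein50["cmap"], protein50["stats"], protein50["seq"]
        phi = wt_phi_matrix(cmap, seq, pot, stats, sparams)
        builder = lambda l: distributions_from_phi(phi, wag, l, "WT")
        lam, dists = fit_lambda(builder, seq)
        idx = seq_to_indices(seq)

        def ll(l):
            p = builder(l).P
            return float(np.log(p[np.arange(len(idx)), idx]).sum())

        assert ll(lam) >= ll(lam * 1.05) - 1e-6
        assert ll(lam) >= ll(max(lam * 0.95, 0.0)) - 1e-6
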