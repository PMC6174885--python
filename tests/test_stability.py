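"""Contact energies, REM misfolding free energy, Delta G and fitness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import protevol as pe
from protevol.alphabet import AA_ORDER
from protevol.contacts import ContactMap
from protevol.stability import (
    ContactPotential,
    StabilityParams,
    load_potential,
    pair_energies,
)


@pytest.fixture(scope="module")
def toy_map():
    m = np.zeros((6, 6), int)
    m[0, 3] = m[3, 0] = 1
    m[1, 5] = m[5, 1] = 1
    m[2, 5] = m[5, 2] = 1
    return ContactMap(m)


class TestContactEnergy:
    def test_zero_potential(self, toy_map):
        pot = ContactPotential(np.zeros((20, 20)))
        assert pe.contact_energy(toy_map, "AILVAG", pot) == 0.0

    def test_single_contact_value(self):
        m = np.zeros((6, 6), int)
        m[0, 4] = m[4, 0] = 1
        u = np.zeros((20, 20))
        i, j = AA_ORDER.index("A"), AA_ORDER.index("W")
        u[i, j] = u[j, i] = -1.5
        assert pe.contact_energy(ContactMap(m), "AGGGWG", ContactPotential(u)) == -1.5

    def test_matches_exhaustive_pair_loop(self, toy_map, pot):
        seq = "ILKWAV"
        expected = 0.0
        for i in range(6):
            for j in range(i + 1, 6):
                if toy_map.contacts[i, j]:
                    expected += pot.U[AA_ORDER.index(seq[i]), AA_ORDER.index(seq[j])]
        assert pe.contact_energy(toy_map, seq, pot) == pytest.approx(expected, abs=1e-12)
        assert pe.native_free_energy(toy_map, seq, pot) == pytest.approx(expected)

    def test_length_mismatch_raises(self, toy_map, pot):
        with pytest.raises(ValueError):
            pe.contact_energy(toy_map, "AIL", pot)

    def test_non_canonical_letter_raises(self, toy_map, pot):
        with pytest.raises(ValueError):
            pe.contact_energy(toy_map, "AILVAX", pot)


class TestUnfoldedFreeEnergy:
    def test_formula_and_linearity(self):
        p = StabilityParams(T=1.0, S_U=0.5, S_C=0.1)
        assert pe.unfolded_free_energy(0, p) == 0.0
        assert pe.unfolded_free_energy(10, p) == pytest.approx(-5.0)
        assert pe.unfolded_free_energy(20, p) == pytest.approx(
            2 * pe.unfolded_free_energy(10, p)
        )


class TestMisfoldingFreeEnergy:
    def test_zero_potential_is_pure_entropy(self, toy_decoys):
        stats = pe.decoy_contact_statistics(toy_decoys, 6)
        p = StabilityParams(T=0.7, S_U=0.3, S_C=0.2)
        pot = ContactPotential(np.zeros((20, 20)))
        got = pe.misfolding_free_energy("AILVAG", pot, stats, p)
        assert got == pytest.approx(-6 * 0.2 * 0.7, abs=1e-12)

    def test_matches_direct_cumulant_expansion(self, pot):
        """Five explicit length-8 decoys against an independently coded
        third-order cumulant expansion with the same freezing smoothing."""
        rng = np.random.default_rng(4)
        decoys = []
        for _ in range(5):
            upper = np.triu(rng.random((8, 8)) < 0.4, k=3)
            decoys.append(ContactMap((upper | upper.T).astype(int)))
        stats = pe.decoy_contact_statistics(decoys, 8)
        seq = "ILWAVKDE"
        p = StabilityParams(T=0.8, S_U=0.3, S_C=0.1)
        # independent oracle: explicit per-decoy double loops
        energies = []
        for d in decoys:
            e = 0.0
            for i in range(8):
                for j in range(i + 1, 8):
                    if d.contacts[i, j]:
                        e += pot.U[AA_ORDER.index(seq[i]), AA_ORDER.index(seq[j])]
            energies.append(e)
        e = np.array(energies)
        mu = e.mean()
        m2 = ((e - mu) ** 2).mean()
        m3 = ((e - mu) ** 3).mean()
        tf = np.sqrt(m2 / (2 * 8 * p.S_C))
        teff = (p.T**16 + tf**16) ** (1 / 16)
        expected = mu - m2 / (2 * teff) + m3 / (6 * teff**2) - 8 * p.S_C * teff
        got = pe.misfolding_free_energy(seq, pot, stats, p)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_high_temperature_limit(self, pot, toy_decoys):
        stats = pe.decoy_contact_statistics(toy_decoys, 6)
        seq = "ILWAVK"
        p = StabilityParams(T=1e7, S_U=0.3, S_C=0.1)
        mean, _, _ = stats.energy_moments(pair_energies(seq, pot))
        got = pe.misfolding_free_energy(seq, pot, stats, p)
        assert got + 6 * p.S_C * p.T - mean == pytest.approx(0.0, abs=1e-5)

    def test_length_mismatch_raises(self, pot, toy_decoys):
        stats = pe.decoy_contact_statistics(toy_decoys, 6)
        with pytest.raises(ValueError):
            pe.misfolding_free_energy("IL", pot, stats, StabilityParams())


class TestDeltaG:
    def test_breakdown_recombines(self, pot, toy_decoys):
        m = np.zeros((6, 6), int)
        m[0, 4] = m[4, 0] = 1
        cmap = ContactMap(m)
        stats = pe.decoy_contact_statistics(toy_decoys, 6)
        p = StabilityParams()
        br = pe.delta_g(cmap, "ILWAVK", pot, stats, p)
        g_nonnat = -p.T * np.logaddexp(-br.G_misf / p.T, -br.G_U / p.T)
        assert br.delta_G == pytest.approx(br.G_nat - g_nonnat, abs=1e-12)

    def test_dominant_nonnative_state_limits(self, pot, toy_decoys):
        m = np.zeros((6, 6), int)
        m[0, 4] = m[4, 0] = 1
        cmap = ContactMap(m)
        stats = pe.decoy_contact_statistics(toy_decoys, 6)
        p = StabilityParams()
        # hydrophobic sequence: misfolded ensemble dominates the unfolded state
        br = pe.delta_g(cmap, "IIIIII", pot, stats, p)
        assert br.G_misf < br.G_U
        if br.G_U - br.G_misf > 10 * p.T:
            assert br.delta_G == pytest.approx(br.G_nat - br.G_misf, abs=1e-3)
        # zero potential: the unfolded state dominates (S_U > S_C)
        zpot = ContactPotential(np.zeros((20, 20)))
        p2 = StabilityParams(T=1.0, S_U=3.0, S_C=0.01)
        br2 = pe.delta_g(cmap, "KDEKDE", zpot, stats, p2)
        assert br2.delta_G == pytest.approx(br2.G_nat - br2.G_U, abs=1e-6)

    def test_misfolding_disabled(self, pot):
        m = np.zeros((6, 6), int)
        m[0, 4] = m[4, 0] = 1
        cmap = ContactMap(m)
        p = StabilityParams(T=1.0, S_U=0.5, S_C=0.1)
        br = pe.delta_g(cmap, "ILWAVK", pot, None, p)
        assert br.delta_G == pytest.approx(br.G_nat + 6 * 0.5)

    def test_boltzmann_average_lowers_free_energy(self, pot, toy_decoys):
        """The combined non-native free energy is below each single term."""
        m = np.zeros((6, 6), int)
        m[0, 4] = m[4, 0] = 1
        cmap = ContactMap(m)
        stats = pe.decoy_contact_statistics(toy_decoys, 6)
        p = StabilityParams()
        br = pe.delta_g(cmap, "ILWAVK", pot, stats, p)
        g_nonnat = br.G_nat - br.delta_G
        assert g_nonnat <= min(br.G_misf, br.G_U) + 1e-12


class TestFitness:
    def test_reference_points(self):
        assert pe.fitness(0.0) == pytest.approx(0.5)
        assert pe.fitness(-np.log(9.0)) == pytest.approx(0.9)
        assert pe.fitness(1e4) < 1e-300 or pe.fitness(1e4) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_monotone_decreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert pe.fitness(lo) >= pe.fitness(hi)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-200, 200))
    def test_complementarity(self, dg):
        assert pe.fitness(dg) + pe.fitness(-dg) == pytest.approx(1.0, abs=1e-12)

    def test_log_fitness_stable_for_destabilized(self):
        assert np.isfinite(pe.log_fitness(5000.0))
        assert pe.log_fitness(5000.0) == pytest.approx(-5000.0)


class TestHydrophobicityScale:
    def test_rank1_recovery(self, rank1_pot):
        from protevol.fixtures import reference_h

        h = pe.hydrophobicity_scale(rank1_pot)
        ref = reference_h()
        assert np.allclose(np.abs(h @ ref), 1.0, atol=1e-12)

    def test_sign_convention(self, pot):
        h = pe.hydrophobicity_scale(pot)
        assert h[AA_ORDER.index("I")] > 0

    def test_shipped_uniform_mean(self, pot):
        assert pe.hydrophobicity_scale(pot).mean() == pytest.approx(0.14, abs=0.005)

    def test_shipped_parameter_count(self, pot):
        assert pot.n_independent == 210


class TestPotentialIO:
    def test_strict_parser_round_trip(self, pot):
        rows = [" ".join(f"{pot.U[i, j]:.8f}" for j in range(i + 1)) for i in range(20)]
        text = "# comment line\n" + "\n".join(rows) + "\n"
        again = load_potential(text)
        assert np.allclose(again.U, pot.U, atol=1e-8)

    def test_wrong_entry_count_raises(self):
        with pytest.raises(ValueError, match="expected 210"):
            load_potential("1.0 2.0 3.0\n")
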