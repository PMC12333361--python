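"""Feature derivations: condensed Fukui index, Q, orbital gap, logP."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cidnp_screen.features import (
    ChargeTable,
    LogPFlag,
    condensed_fukui,
    estimate_log_p,
    fukui_per_atom,
    geminate_polarization_q,
    lumo_homo_gap,
)

# constants looked up independently of the package (CODATA 2022; h is an
# exact SI defining constant since 2019)
_MU_B = 9.2740100657e-24  # J/T
_HBAR = 6.62607015e-34 / (2 * np.pi)  # J s


def _charge_table(q_n, q_nm1, site_map=None, atoms=None):
    q_n = np.asarray(q_n, dtype=float)
    atoms = atoms or [f"C{i}" for i in range(len(q_n))]
    return ChargeTable("mol", atoms, q_n, np.asarray(q_nm1, dtype=float), site_map or {})


class TestCondensedFukui:
    def test_whole_electron_localized_on_one_atom(self):
        ct = _charge_table([0.0, 0.0], [1.0, 0.0], {"1": "C0", "2": "C1"})
        assert condensed_fukui(ct) == {"1": 1.0, "2": 0.0}

    def test_uniform_removal_splits_evenly(self):
        ct = _charge_table([0.0] * 4, [0.25] * 4, {str(i): f"C{i}" for i in range(4)})
        assert condensed_fukui(ct) == {str(i): 0.25 for i in range(4)}

    def test_random_charges_match_elementwise_difference_oracle(self):
        rng = np.random.default_rng(42)
        q_n = rng.normal(0, 0.3, 10)
        delta = rng.dirichlet(np.ones(10))  # sums to the one removed electron
        ct = _charge_table(q_n, q_n + delta)
        f = fukui_per_atom(ct)
        np.testing.assert_allclose(f, delta, atol=1e-12)
        assert abs(f.sum() - 1.0) < 1e-6

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=20), st.integers(min_value=0, max_value=2**32 - 1))
    def test_normalization_property(self, n_atoms, seed):
        """Sum of f- over all atoms equals the one removed electron."""
        rng = np.random.default_rng(seed)
        q_n = rng.normal(0, 0.5, n_atoms)
        ct = _charge_table(q_n, q_n + rng.dirichlet(np.ones(n_atoms)))
        assert abs(fukui_per_atom(ct).sum() - 1.0) < 1e-6

    def test_unknown_heavy_atom_raises_mapping_error(self):
        ct = _charge_table([0.0, 0.0], [1.0, 0.0], {"1": "Zz9"})
        with pytest.raises(KeyError, match="unknown atom"):
            condensed_fukui(ct)

    def test_charge_conservation_enforced(self):
        with pytest.raises(ValueError, match="one electron removed"):
            _charge_table([0.0, 0.0], [0.3, 0.3])


class TestGeminatePolarizationQ:
    def test_zero_hyperfine_gives_zero(self):
        assert geminate_polarization_q(0.0, 2.0034, 2.0020, 14.1) == 0.0

    def test_equal_g_factors_give_zero(self):
        assert geminate_polarization_q(5.0, 2.0034, 2.0034, 14.1) == 0.0

    def test_hand_computed_reference_value(self):
        """a_iso = 1 MHz, |dg| = 1e-3, B0 = 14.1 T vs an independent
        CODATA-constant computation."""
        g_mol = 2.0034 - 1e-3
        expected = (1.0 / 12.0) * (2 * np.pi * 1e6) ** 2 * (2.0034 - g_mol) * (_MU_B / _HBAR) * 14.1
        got = geminate_polarization_q(1.0, 2.0034, g_mol, 14.1)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_scaling_laws(self):
        base = geminate_polarization_q(3.0, 2.004, 2.002, 14.1)
        assert geminate_polarization_q(6.0, 2.004, 2.002, 14.1) == pytest.approx(4 * base, rel=1e-12)
        assert geminate_polarization_q(3.0, 2.004, 2.002, 28.2) == pytest.approx(2 * base, rel=1e-12)
        assert geminate_polarization_q(3.0, 2.004, 2.000, 14.1) == pytest.approx(2 * base, rel=1e-12)

    def test_sign_of_a_iso_is_irrelevant(self):
        assert geminate_polarization_q(-3.0, 2.004, 2.002, 14.1) == geminate_polarization_q(
            3.0, 2.004, 2.002, 14.1
        )

    def test_negative_field_rejected(self):
        with pytest.raises(ValueError, match="b0"):
            geminate_polarization_q(1.0, 2.004, 2.002, -14.1)


class TestGapAndLogP:
    def test_gap_is_simple_subtraction(self):
        assert lumo_homo_gap(-5.5, -2.5) == 3.0
        assert lumo_homo_gap(-2.5, -2.5) == 0.0

    def test_gap_vectorizes_like_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        homo = rng.uniform(-8, -4, 20)
        np.testing.assert_allclose(lumo_homo_gap(homo, -2.87), -2.87 - homo)

    def test_supplied_log_p_passes_through(self):
        assert estimate_log_p(supplied=2.1) == (2.1, LogPFlag.SUPPLIED)

    def test_missing_both_inputs_errors(self):
        with pytest.raises(ValueError, match="logP"):
            estimate_log_p()

    def test_benzene_atom_contribution_estimate(self):
        # Wildman-Crippen atom-contribution logP of benzene is about 1.69
        value, flag = estimate_log_p(smiles="c1ccccc1")
        assert flag == LogPFlag.ESTIMATED
        assert value == pytest.approx(1.69, abs=0.5)


class TestAssembleFeatures:
    def test_two_sites_give_two_rows_with_all_features(self, config):
        from cidnp_screen.features import assemble_features
        from cidnp_screen.records import FEATURE_COLUMNS, MoleculeRecord, SiteRecord

        mol = MoleculeRecord(
            "M1", "indole", "H", ip=7.5, nucleophilicity=3.2, lumo_homo=3.9,
            delta_g=1.5e-3, log_p=2.2, mechanism="ET",
            sites=[
                SiteRecord("M1", "3", a_iso=40.0, fukui=0.3, q_value=0.0, sne=120.0),
                SiteRecord("M1", "4", a_iso=10.0, fukui=0.1, q_value=0.0, sne=20.0),
            ],
        )
        table = assemble_features([mol], config)
        assert len(table) == 2
        assert list(table.features().columns) == list(FEATURE_COLUMNS)
        # Q recomputed from a_iso and delta_g at the configured scale
        from cidnp_screen.features import geminate_polarization_q

        expected = geminate_polarization_q(40.0, config.g_dye, config.g_dye - 1.5e-3, config.b0)
        assert table.frame["q_value"].iloc[0] == pytest.approx(expected / config.q_scale)

    def test_row_count_equals_total_sites(self, table):
        counts = table.frame.groupby("molecule_id").size()
        assert len(table) == counts.sum()
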