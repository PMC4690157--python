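"""Closed-system forward model: conservation laws and limits."""

import numpy as np
import pytest

from sulfrac.forward_model import (
    BranchFractionation,
    ReactionScheme,
    cumulative_rayleigh_factor,
    effective_alpha,
    mass_balance_check,
    simulate,
)
from sulfrac.isotope_core import DeltaTriple, delta_to_ratio


class TestEffectiveAlpha:
    def test_equal_branches_collapse(self):
        b = BranchFractionation(a34_red=0.98, a34_ox=0.98)
        assert effective_alpha(b, ReactionScheme(j=0.3)).a34 == pytest.approx(0.98)

    @pytest.mark.parametrize(
        "j, expected",
        [(1.0, 0.99), (0.0, (0.98 + 2.0) / 3.0)],
        ids=["all-thiosulfate", "all-trithionate"],
    )
    def test_weighting_arithmetic(self, j, expected):
        b = BranchFractionation(a34_red=0.98, a34_ox=1.00)
        assert effective_alpha(b, ReactionScheme(j=j)).a34 == pytest.approx(
            expected, abs=1e-15
        )

    def test_weights_sum_to_one_exactly(self):
        for j in np.linspace(0, 1, 11):
            s = ReactionScheme(j=float(j))
            assert s.w_red + s.w_ox == 1.0


class TestTrajectoryConservation:
    @pytest.fixture()
    def traj(self, truth_branch, scheme, delta0):
        return simulate(truth_branch, scheme, 15.0, delta0, np.linspace(0.99, 0.5, 12))

    def test_sulfur_atom_conservation_exact(self, traj):
        total = (
            traj.conc_sulfite
            + 2 * traj.conc_thiosulfate
            + 3 * traj.conc_trithionate
        )
        assert total == pytest.approx(15.0, rel=1e-12)

    def test_isotope_mass_balance_all_isotopes(self, traj, scheme, delta0):
        r0 = delta_to_ratio(delta0)
        for iso, r0x in (("33", r0.r33), ("34", r0.r34), ("36", r0.r36)):
            lhs = traj.f * traj.r_sulfite[iso] + (1 - traj.f) * (
                scheme.w_red * traj.r_reduced[iso]
                + scheme.w_ox * traj.r_sulfonate[iso]
            )
            assert lhs == pytest.approx(r0x, rel=1e-9)

    def test_product_split_recovers_input_j(self, traj, scheme):
        j_back = (
            2 * traj.conc_thiosulfate
            / (2 * traj.conc_thiosulfate + 3 * traj.conc_trithionate)
        )
        assert j_back == pytest.approx(scheme.j, rel=1e-12)

    def test_residual_sulfite_rayleigh_enrichment_monotone(self, traj):
        # net removal is depleting (a_total < 1), so residual sulfite
        # delta-34 must rise monotonically as f falls
        d34 = 1000.0 * (traj.r_sulfite["34"] / traj.scale.r34_ref - 1.0)
        assert np.all(np.diff(d34) > 0)

    def test_no_fractionation_means_no_isotope_evolution(self, delta0):
        b = BranchFractionation(a34_red=1.0, a34_ox=1.0)
        traj = simulate(b, ReactionScheme(j=0.19), 10.0, DeltaTriple(3.0, 1.5, 6.0),
                        np.linspace(0.95, 0.5, 5))
        r0 = delta_to_ratio(DeltaTriple(3.0, 1.5, 6.0))
        for iso in ("33", "34", "36"):
            ref = getattr(r0, f"r{iso}")
            assert traj.r_sulfite[iso] == pytest.approx(ref, rel=1e-14)
            assert traj.r_reduced[iso] == pytest.approx(ref, rel=1e-14)
            assert traj.r_sulfonate[iso] == pytest.approx(ref, rel=1e-14)


class TestNearCompleteLimit:
    def test_cumulative_factor_limit_is_alpha(self):
        for alpha in (0.98, 0.995, 1.003):
            near = cumulative_rayleigh_factor(np.array([1 - 1e-8]), alpha)[0]
            assert near == pytest.approx(alpha, rel=1e-7)
            assert cumulative_rayleigh_factor(np.array([1.0]), alpha)[0] == alpha

    def test_f_equal_one_has_empty_product_pools(self, truth_branch, scheme, delta0):
        traj = simulate(truth_branch, scheme, 15.0, delta0, np.array([1.0, 0.9]))
        assert np.isnan(traj.r_reduced["34"][0])
        assert np.isnan(traj.r_sulfonate["34"][0])
        assert not np.isnan(traj.r_reduced["34"][1])

    def test_product_pool_tends_to_instantaneous_alpha(self, delta0):
        b = BranchFractionation(a34_red=0.985, a34_ox=1.0)
        traj = simulate(b, ReactionScheme(j=0.19), 15.0, delta0,
                        np.array([1 - 1e-8]))
        a_tot = effective_alpha(b, ReactionScheme(j=0.19)).a34
        expected = (0.985 / a_tot) * delta_to_ratio(delta0).r34 * a_tot
        assert traj.r_reduced["34"][0] == pytest.approx(expected, rel=1e-7)


class TestMassBalanceCheck:
    def test_noise_free_recovery_is_unity(self, truth_branch, scheme, delta0):
        traj = simulate(truth_branch, scheme, 15.0, delta0, np.linspace(0.99, 0.6, 10))
        qc = mass_balance_check(traj.conc_sulfite, traj.conc_thiosulfate,
                                traj.conc_trithionate, 15.0)
        assert qc["recovery"].to_numpy() == pytest.approx(1.0, rel=1e-12)
        assert (qc["flag"] == "pass5").all()

    @pytest.mark.parametrize(
        "concs, expected_recovery, expected_flag",
        [
            ((6.0, 0.5, 1.0), 1.0, "pass5"),
            ((6.8, 0.5, 1.0), 1.08, "pass10"),
            ((8.0, 0.5, 1.0), 1.2, "fail"),
        ],
    )
    def test_flag_thresholds(self, concs, expected_recovery, expected_flag):
        qc = mass_balance_check([concs[0]], [concs[1]], [concs[2]], 10.0)
        assert qc["recovery"][0] == pytest.approx(expected_recovery)
        assert qc["flag"][0] == expected_flag

    def test_invalid_initial_concentration(self):
        with pytest.raises(ValueError):
            mass_balance_check([1.0], [0.0], [0.0], 0.0)


class TestValidation:
    def test_f_grid_must_be_descending_in_unit_interval(self, truth_branch, scheme, delta0):
        with pytest.raises(ValueError):
            simulate(truth_branch, scheme, 15.0, delta0, np.array([0.5, 0.9]))
        with pytest.raises(ValueError):
            simulate(truth_branch, scheme, 15.0, delta0, np.array([1.2, 0.9]))

    def test_branch_parameter_domains(self):
        with pytest.raises(Exception):
            BranchFractionation(a34_red=0.5, a34_ox=1.0)
        with pytest.raises(Exception):
            BranchFractionation(a34_red=0.99, a34_ox=1.0, lam33_red=3.0)


def test_serialization_prepends_t0_row(truth_branch, scheme, delta0):
    traj = simulate(truth_branch, scheme, 15.0, delta0, np.linspace(0.95, 0.8, 4))
    frame = traj.to_frame()
    assert len(frame) == 5
    t0 = frame.iloc[0]
    assert t0["conc_sulfite_mM"] == 15.0
    assert t0["conc_thiosulfate_mM"] == 0.0 and t0["conc_trithionate_mM"] == 0.0
    assert np.isnan(t0["d34_reduced"]) and t0["d34_sulfite"] == 0.0
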