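"""Inversion correctness: the forward model is the oracle."""

import math

import numpy as np
import pytest

from sulfrac.cli_io import TimePoint
from sulfrac.forward_model import BranchFractionation, ReactionScheme, simulate
from sulfrac.inversion import (
    EmptyWindowError,
    NumericallyInvalidPoint,
    invert_experiment_frame,
    invert_point,
    invert_series,
    scan_secondary,
)
from sulfrac.isotope_core import VCDT, DeltaTriple
from sulfrac.synthetic_data import ExperimentDesign, NoiseModel, generate


def _invert_noise_free(branch, scheme, f_grid, delta0=DeltaTriple(0.0, 0.0, 0.0),
                       threshold=0.0):
    traj = simulate(branch, scheme, 15.0, delta0, np.asarray(f_grid))
    return invert_series(traj.to_frame(), f_threshold=threshold)


class TestForwardInverseIdentity:
    """invert(simulate(theta)) must return theta to numerical precision."""

    @pytest.mark.parametrize("a34_red", [0.96, 0.9849, 1.0, 1.04])
    @pytest.mark.parametrize("a34_ox", [0.96, 1.0032, 1.04])
    @pytest.mark.parametrize("j", [0.0, 0.19, 0.5, 1.0])
    def test_branch_alpha_recovery_sweep(self, a34_red, a34_ox, j):
        branch = BranchFractionation(a34_red=a34_red, a34_ox=a34_ox,
                                     lam33_red=0.515, lam33_ox=0.495)
        res = _invert_noise_free(branch, ReactionScheme(j=j),
                                 [0.99, 0.9, 0.75, 0.5])
        for p in res.points:
            assert p.alpha_red.a34 == pytest.approx(a34_red, rel=1e-10)
            assert p.alpha_ox.a34 == pytest.approx(a34_ox, rel=1e-10)
            assert p.j == pytest.approx(j, abs=1e-12)
            if a34_red != 1.0:
                assert p.lam33_red == pytest.approx(0.515, abs=1e-9)
            if a34_ox != 1.0:
                assert p.lam33_ox == pytest.approx(0.495, abs=1e-9)

    def test_identity_when_no_fractionation(self):
        tp = TimePoint(conc_sulfite_mM=12.0, conc_thiosulfate_mM=0.5,
                       conc_trithionate_mM=0.6,
                       delta_sulfite=DeltaTriple(2.0, 1.0, 4.0),
                       delta_sulfonate=DeltaTriple(2.0, 1.0, 4.0),
                       delta_reduced=DeltaTriple(2.0, 1.0, 4.0))
        p = invert_point(tp, DeltaTriple(2.0, 1.0, 4.0), 15.0)
        assert p.alpha_total.a34 == pytest.approx(1.0, abs=1e-12)
        assert p.alpha_red.a34 == pytest.approx(1.0, abs=1e-12)
        assert p.eps34_red == pytest.approx(0.0, abs=1e-9)
        assert p.lam33_red is None  # undefined without major fractionation

    def test_lambda_constant_across_f_for_constant_alpha(self, truth_branch, scheme):
        res = _invert_noise_free(truth_branch, scheme,
                                 [0.99, 0.95, 0.9, 0.8, 0.7, 0.6, 0.5])
        lams = [p.lam33_red for p in res.points]
        assert np.ptp(lams) < 1e-10
        eps = [p.eps34_red for p in res.points]
        assert np.ptp(eps) < 1e-8

    def test_near_total_limit_alpha_total_is_rp_over_ra0(self):
        # as f -> 1 the net-fractionation solution tends to R_p / R_a0
        f = 1 - 1e-7
        tp = TimePoint(conc_sulfite_mM=15.0 * f,
                       conc_thiosulfate_mM=0.19 * 15.0 * (1 - f) / 2,
                       conc_trithionate_mM=0.81 * 15.0 * (1 - f) / 3,
                       delta_sulfite=DeltaTriple(0.0),
                       delta_sulfonate=DeltaTriple(-5.0),
                       delta_reduced=DeltaTriple(-5.0))
        p = invert_point(tp, DeltaTriple(0.0), 15.0, f=f)
        assert p.alpha_total.a34 == pytest.approx(0.995, abs=1e-8)


class TestWindowing:
    def test_noise_free_window_equals_every_point(self, truth_branch, scheme):
        res = _invert_noise_free(truth_branch, scheme,
                                 np.linspace(0.99, 0.85, 8), threshold=0.85)
        for p in res.points:
            assert res.window.eps34_red == pytest.approx(p.eps34_red, abs=1e-9)
            assert res.window.lam33_red == pytest.approx(p.lam33_red, abs=1e-11)

    def test_threshold_excludes_late_points(self, truth_branch, scheme):
        traj = simulate(truth_branch, scheme, 15.0, DeltaTriple(0.0, 0.0, 0.0),
                        np.array([0.99, 0.9, 0.8, 0.7]))
        res = invert_series(traj.to_frame(), f_threshold=0.85)
        assert res.window.n_points == 2
        assert min(res.window.f_used) >= 0.85

    def test_empty_window_raises(self, truth_branch, scheme):
        traj = simulate(truth_branch, scheme, 15.0, DeltaTriple(0.0, 0.0, 0.0),
                        np.array([0.7, 0.6]))
        with pytest.raises(EmptyWindowError):
            invert_series(traj.to_frame(), f_threshold=0.85)

    def test_plain_weighting_available(self, truth_branch, scheme):
        traj = simulate(truth_branch, scheme, 15.0, DeltaTriple(0.0, 0.0, 0.0),
                        np.linspace(0.99, 0.86, 6))
        ivw = invert_series(traj.to_frame(), weighting="ivw")
        plain = invert_series(traj.to_frame(), weighting="plain")
        assert ivw.window.eps34_red == pytest.approx(plain.window.eps34_red, abs=1e-9)

    def test_major_isotope_only_series_skips_lambda(self, truth_branch, scheme):
        traj = simulate(truth_branch, scheme, 15.0, DeltaTriple(d34=0.0),
                        np.linspace(0.99, 0.86, 6))
        res = invert_series(traj.to_frame())
        assert res.window.lam33_red is None
        assert res.window.eps34_red == pytest.approx(15.3, abs=1e-6)


class TestInvalidPoints:
    def test_no_product_point_is_skipped_with_reason(self, truth_branch, scheme):
        traj = simulate(truth_branch, scheme, 15.0, DeltaTriple(0.0, 0.0, 0.0),
                        np.linspace(0.99, 0.86, 6))
        frame = traj.to_frame()
        frame.loc[2, "conc_thiosulfate_mM"] = 0.0
        frame.loc[2, "conc_trithionate_mM"] = 0.0
        frame.loc[2, "conc_sulfite_mM"] = 15.0
        res = invert_series(frame)
        assert len(res.skipped) == 1
        assert "no product" in res.skipped[0][1]

    def test_unphysical_ratio_combination_raises(self):
        tp = TimePoint(conc_sulfite_mM=1.0, conc_thiosulfate_mM=2.0,
                       conc_trithionate_mM=2.0,
                       delta_sulfite=DeltaTriple(0.0),
                       delta_sulfonate=DeltaTriple(999.0),
                       delta_reduced=DeltaTriple(999.0))
        with pytest.raises(NumericallyInvalidPoint):
            # tiny f with strongly enriched products drives the
            # mass-balance argument non-positive
            invert_point(tp, DeltaTriple(0.0), 15.0, f=0.01)


class TestNoisyRecovery:
    def test_windowed_epsilon_unbiased_under_default_noise(self, early_design):
        reps = 500
        rng = np.random.default_rng(7)
        est = []
        for s in rng.integers(0, 2**31 - 1, reps):
            frame = generate(early_design, NoiseModel(), seed=int(s))
            est.append(invert_experiment_frame(frame).pooled.eps34_red)
        assert abs(np.mean(est) - 15.3) < 0.1

    def test_pooling_tightens_sigma(self, early_design):
        frame = generate(early_design, NoiseModel(), seed=1)
        multi = invert_experiment_frame(frame)
        single = list(multi.per_series.values())[0].window
        assert multi.pooled.sigma_eps34_red < single.sigma_eps34_red


class TestSecondaryReactionScan:
    def test_construction_oracle_at_half_mixture(self):
        a_ref, a_star = 0.985, 0.97
        r_so3, r_ox = VCDT.r34_ref * 1.001, VCDT.r34_ref * 0.999
        r_red = 0.5 * a_ref * r_so3 + 0.5 * a_star * r_ox
        scan = scan_secondary(a_ref, r_red, r_so3, r_ox, x_grid=np.array([0.5]))
        assert scan.alpha_unk[0] == pytest.approx(a_star, rel=1e-12)

    def test_identity_when_both_pools_equivalent(self):
        a_ref = 0.985
        r = VCDT.r34_ref
        scan = scan_secondary(a_ref, a_ref * r, r, r)
        assert scan.alpha_unk == pytest.approx(a_ref, rel=1e-12)
        assert not scan.unphysical.any()

    def test_zero_numerator_flagged_unphysical(self):
        r = VCDT.r34_ref
        # choose R_red so the numerator vanishes at X = 0.5
        scan = scan_secondary(1.0, 0.5 * r, r, r, x_grid=np.array([0.5, 0.6]))
        assert scan.alpha_unk[0] == pytest.approx(0.0, abs=1e-15)
        assert scan.unphysical[0]

    def test_grid_excludes_degenerate_endpoint(self):
        with pytest.raises(ValueError):
            scan_secondary(0.985, 1.0, 1.0, 1.0, x_grid=np.array([1.0]))


def test_eps_sign_conventions_match_branch_direction(truth_branch, scheme):
    """The depleting reduced branch reports positive r-p epsilon, the
    enriching sulfonate branch a negative one."""
    res = _invert_noise_free(truth_branch, scheme, [0.95, 0.9])
    assert res.window.eps34_red > 0
    assert res.window.eps34_ox < 0
    assert res.window.eps34_red == pytest.approx(15.3, abs=1e-9)
    assert res.window.eps34_ox == pytest.approx(-3.2, abs=1e-9)


def test_f_from_products_mode_agrees_noise_free(truth_branch, scheme):
    traj = simulate(truth_branch, scheme, 15.0, DeltaTriple(0.0, 0.0, 0.0),
                    np.linspace(0.99, 0.86, 6))
    a = invert_series(traj.to_frame(), f_from="sulfite")
    b = invert_series(traj.to_frame(), f_from="products")
    assert a.window.eps34_red == pytest.approx(b.window.eps34_red, abs=1e-9)
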