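import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helixscan.binding import (
    CompetitionParams,
    DirectBindingParams,
    TitrationCurve,
    anisotropy_competition,
    anisotropy_direct,
    fit_competition,
    fit_direct,
    frac_bound_competition,
    frac_bound_direct,
    solve_equilibrium_numeric,
)
from helixscan.simulate import GeneratorConfig, gen_competition_titration, gen_direct_titration

# assay constants: calibrated tracer Kd, tracer and protein concentrations (nM)
KD1, LST, PT = 13.0, 50.0, 250.0


def bisect_bound_fraction(kd, lt, pt, iters=200):
    """Independent oracle: bisection on bound tracer b in [0, min(lt, pt)]
    for the mass balance kd*b = (lt-b)*(pt-b)."""
    lo, hi = 0.0, min(lt, pt)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if kd * mid < (lt - mid) * (pt - mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi) / lt


class TestDirectModel:
    def test_no_protein_gives_zero(self):
        assert frac_bound_direct(13.0, 50.0, 0.0) == 0.0

    def test_infinitely_tight_excess_protein_saturates(self):
        assert frac_bound_direct(0.0, 50.0, 250.0) == pytest.approx(1.0)

    def test_assay_conditions_against_bisection_oracle(self):
        frac = frac_bound_direct(KD1, LST, PT)
        assert frac == pytest.approx(bisect_bound_fraction(KD1, LST, PT), rel=1e-12)
        assert frac == pytest.approx(0.940, abs=5e-4)

    def test_zero_tracer_is_domain_error(self):
        with pytest.raises(ValueError):
            frac_bound_direct(13.0, 0.0, 250.0)

    def test_anisotropy_is_linear_map_of_fraction(self):
        p = DirectBindingParams(r0=0.05, rb=0.25, Kd=KD1, Lt=LST, Pt=PT)
        frac = frac_bound_direct(KD1, LST, PT)
        assert anisotropy_direct(p) == pytest.approx(0.05 + 0.20 * frac)
        assert anisotropy_direct(p) == pytest.approx(0.238, abs=1e-3)

    def test_anisotropy_limits(self):
        assert anisotropy_direct(
            DirectBindingParams(r0=0.05, rb=0.25, Kd=KD1, Lt=LST, Pt=0.0)
        ) == pytest.approx(0.05)
        assert anisotropy_direct(
            DirectBindingParams(r0=0.05, rb=0.25, Kd=0.0, Lt=LST, Pt=250.0)
        ) == pytest.approx(0.25)


class TestCompetitionModel:
    def test_competitor_free_reduction_matches_direct(self):
        p = CompetitionParams(Kd1=KD1, Kd2=18.6, Lst=LST, Lt=0.0, Pt=PT)
        assert frac_bound_competition(p) == pytest.approx(
            frac_bound_direct(KD1, LST, PT), rel=1e-9
        )

    def test_non_binding_competitor_limit(self):
        base = frac_bound_competition(
            CompetitionParams(Kd1=KD1, Kd2=18.6, Lst=LST, Lt=0.0, Pt=PT)
        )
        weak = frac_bound_competition(
            CompetitionParams(Kd1=KD1, Kd2=1e12, Lst=LST, Lt=5e4, Pt=PT)
        )
        assert weak == pytest.approx(base, rel=1e-6)

    def test_mp292_conditions_match_numerical_oracle(self):
        # oracle-derived golden value frozen from solve_equilibrium_numeric
        p = CompetitionParams(Kd1=KD1, Kd2=18.6, Lst=LST, Lt=500.0, Pt=PT)
        bound_tracer, _ = solve_equilibrium_numeric(p)
        assert frac_bound_competition(p) == pytest.approx(bound_tracer / LST, rel=1e-9)
        assert frac_bound_competition(p) == pytest.approx(0.5106975030570965, rel=1e-9)

    def test_anisotropy_reduction_and_midpoint(self):
        p0 = CompetitionParams(Kd1=KD1, Kd2=18.6, Lst=LST, Lt=0.0, Pt=PT)
        direct = anisotropy_direct(
            DirectBindingParams(r0=0.05, rb=0.25, Kd=KD1, Lt=LST, Pt=PT)
        )
        assert anisotropy_competition(0.05, 0.25, p0) == pytest.approx(direct, rel=1e-9)
        # frac = 0.5 by construction -> midpoint of (r0, rb)
        assert 0.05 + (0.25 - 0.05) * 0.5 == pytest.approx(0.15)

    def test_validity_condition_exposed_and_enforced_by_fits(self):
        p = CompetitionParams(Kd1=KD1, Kd2=10.0, Lst=250.0, Lt=0.0, Pt=50.0)
        assert not p.assay_valid
        curve = TitrationCurve(x=np.geomspace(1, 1e4, 8), r=np.linspace(0.2, 0.06, 8))
        with pytest.raises(ValueError, match="Pt > Lst"):
            fit_competition(curve, Lst=250.0, Pt=50.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        kd1=st.floats(0.1, 1e6), kd2=st.floats(0.1, 1e6),
        lst=st.floats(1.0, 1e5), scale=st.floats(1.01, 1e3),
        lt=st.floats(0.0, 1e5),
    )
    def test_closed_form_matches_oracle_everywhere(self, kd1, kd2, lst, scale, lt):
        p = CompetitionParams(Kd1=kd1, Kd2=kd2, Lst=lst, Lt=lt, Pt=lst * scale)
        bound_tracer, bound_comp = solve_equilibrium_numeric(p)
        closed = frac_bound_competition(p)
        assert closed == pytest.approx(bound_tracer / lst, rel=1e-6, abs=1e-12)
        # conservation from the oracle
        assert bound_tracer <= lst * (1 + 1e-12)
        assert bound_comp <= p.Lt * (1 + 1e-12) + 1e-12
        assert bound_tracer + bound_comp <= p.Pt * (1 + 1e-9)


class TestMonotonicity:
    def test_pairwise_monotonicity_on_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            kd1, kd2 = 10 ** rng.uniform(-1, 6, 2)
            lst = 10 ** rng.uniform(0, 4)
            pt = lst * 10 ** rng.uniform(0.01, 2)
            lt = 10 ** rng.uniform(0, 5)
            base = frac_bound_competition(
                CompetitionParams(Kd1=kd1, Kd2=kd2, Lst=lst, Lt=lt, Pt=pt)
            )
            eps = 1e-9
            up = lambda **kw: frac_bound_competition(
                CompetitionParams(**{**dict(Kd1=kd1, Kd2=kd2, Lst=lst, Lt=lt, Pt=pt), **kw})
            )
            assert up(Lt=lt * 2) <= base + eps        # more competitor displaces
            assert up(Kd1=kd1 * 2) <= base + eps      # weaker tracer binds less
            assert up(Kd2=kd2 * 2) >= base - eps      # weaker competitor displaces less
            assert up(Pt=pt * 2) >= base - eps        # more protein binds more


class TestNumericOracle:
    def test_zero_protein(self):
        p = CompetitionParams(Kd1=1.0, Kd2=1.0, Lst=10.0, Lt=10.0, Pt=0.0)
        assert solve_equilibrium_numeric(p) == (0.0, 0.0)

    def test_symmetry_of_identical_ligands(self):
        p = CompetitionParams(Kd1=5.0, Kd2=5.0, Lst=40.0, Lt=40.0, Pt=100.0)
        bt, bc = solve_equilibrium_numeric(p)
        assert bt == pytest.approx(bc, rel=1e-9)

    def test_single_ligand_reduction_to_quadratic(self):
        p = CompetitionParams(Kd1=13.0, Kd2=100.0, Lst=50.0, Lt=0.0, Pt=250.0)
        bt, bc = solve_equilibrium_numeric(p)
        assert bc == 0.0
        assert bt / 50.0 == pytest.approx(bisect_bound_fraction(13.0, 50.0, 250.0), rel=1e-9)


class TestFitting:
    def test_direct_noiseless_round_trip(self, noiseless_cfg):
        curve, _ = gen_direct_titration(Kd=13.0, r0=0.05, rb=0.25, cfg=noiseless_cfg)
        fit = fit_direct(curve)
        assert fit.converged
        assert fit.estimates["Kd"] == pytest.approx(13.0, rel=1e-6)
        assert fit.estimates["r0"] == pytest.approx(0.05, rel=1e-6)
        assert fit.estimates["rb"] == pytest.approx(0.25, rel=1e-6)

    def test_competition_noiseless_round_trip(self, noiseless_cfg):
        curve, _ = gen_competition_titration(Kd2=18.6, cfg=noiseless_cfg)
        fit = fit_competition(curve)
        assert fit.converged
        assert fit.estimates["Kd2"] == pytest.approx(18.6, rel=1e-6)

    def test_round_trip_arbitrary_truths(self, noiseless_cfg):
        for kd2 in (1.0, 100.0, 3600.0):
            grid = np.geomspace(1.0, 1e6, 14)
            curve, _ = gen_competition_titration(Kd2=kd2, lt_grid=grid, cfg=noiseless_cfg)
            fit = fit_competition(curve)
            assert fit.estimates["Kd2"] == pytest.approx(kd2, rel=1e-5)

    def test_zero_dynamic_range_flagged(self):
        curve = TitrationCurve(x=np.geomspace(1, 1e4, 8), r=np.full(8, 0.1))
        fit = fit_direct(curve)
        assert (not fit.converged) or math.isinf(fit.standard_errors["Kd"])

    def test_baseline_below_free_tracer_diagnostic(self, noiseless_cfg):
        curve, _ = gen_competition_titration(Kd2=10.0, r0=0.02, cfg=noiseless_cfg)
        fit = fit_competition(curve, free_tracer_r0=0.05)
        assert "baseline_below_free_tracer" in fit.flags

    def test_nonconvergence_never_raises(self):
        curve = TitrationCurve(x=np.geomspace(1, 100, 6), r=np.array([np.inf] * 6))
        fit = fit_direct(curve)
        assert not fit.converged
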