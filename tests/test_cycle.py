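"""Tests for TI post-processing, restraint corrections and cycle assembly."""

import numpy as np
import pytest

from pahbind import (
    CycleComponents,
    ErrorRule,
    FBHWRestraint,
    GeneratorConfig,
    LambdaWindow,
    TIProfile,
    assemble_cycle,
    block_average,
    fbhw_volume,
    gen_ti_profile,
    gibbs_from_kd,
    integrate_ti,
    kd_from_dg,
    restraint_correction,
    symmetry_correction,
)
from pahbind.constants import R_KJ_PER_MOL_K
from pahbind.exceptions import DomainError, ValidationError

# Cycle legs (kJ/mol) for the three simulated ligands in the two cavities,
# with the assembled transfer energies they must reproduce.
CYCLE_ROWS = [
    # dg1, s1, dg3, s3, dg_transfer, sigma
    (79.2, 1.2, 4.9, 1.0, -72.8, 1.1),   # naphthalene, cavity 2
    (74.7, 1.4, 4.9, 1.0, -68.3, 1.2),   # naphthalene, cavity 3
    (80.2, 3.8, 10.1, 1.1, -68.6, 2.8),  # phenanthrene, cavity 2
    (58.7, 3.8, 10.1, 1.1, -47.1, 2.8),  # phenanthrene, cavity 3
    (76.3, 8.8, 12.5, 1.1, -62.3, 6.3),  # pyrene, cavity 2
    (62.7, 2.9, 12.5, 1.1, -48.7, 2.2),  # pyrene, cavity 3
]
DG2 = -1.5  # analytic restraint/standard-state correction, kJ/mol


class TestBlockAverage:
    def test_constant_series(self):
        mean, sigma = block_average(np.full(100, 3.7), 10)
        assert mean == 3.7 and sigma == 0.0

    def test_iid_sigma_matches_monte_carlo_truth(self):
        rng = np.random.default_rng(7)
        sigmas = [block_average(rng.standard_normal(4000), 10)[1]
                  for _ in range(500)]
        # truth for i.i.d. unit noise: SE of the mean = 1/sqrt(4000)
        assert np.mean(sigmas) * np.sqrt(4000) == pytest.approx(1.0, rel=0.1)

    def test_ar1_sigma_shows_theoretical_inflation(self):
        phi = 0.9
        rng = np.random.default_rng(11)
        n = 4000
        innov = np.sqrt(1 - phi * phi)
        sigmas = []
        for _ in range(300):
            eps = rng.normal(0, innov, n)
            x = np.empty(n)
            x[0] = rng.normal()
            for i in range(1, n):
                x[i] = phi * x[i - 1] + eps[i]
            sigmas.append(block_average(x, 10)[1])
        expected = np.sqrt((1 + phi) / (1 - phi)) / np.sqrt(n)
        assert np.mean(sigmas) == pytest.approx(expected, rel=0.2)

    def test_errors(self):
        with pytest.raises(DomainError):
            block_average(np.ones(5), 10)
        with pytest.raises(DomainError):
            block_average(np.ones(100), 1)


def uniform_profile(values, sigmas=None):
    lam = np.linspace(0, 1, len(values))
    sigmas = sigmas if sigmas is not None else np.zeros(len(values))
    return TIProfile([LambdaWindow(l, v, s) for l, v, s in zip(lam, values, sigmas)])


class TestIntegrateTI:
    def test_exact_on_constants_and_linears(self):
        lam = np.array([0.0, 0.1, 0.35, 0.8, 1.0])
        const = TIProfile([LambdaWindow(l, 7.25) for l in lam])
        assert integrate_ti(const)[0] == pytest.approx(7.25, rel=1e-14)
        linear = TIProfile([LambdaWindow(l, 2.0 + 3.0 * l) for l in lam])
        assert integrate_ti(linear)[0] == pytest.approx(3.5, rel=1e-14)

    def test_cubic_within_trapezoid_error_bound(self):
        # f = 1 + l - 4 l^2 + 2 l^3 on 21 uniform points; max|f''| on [0,1] = 8+12-...
        coeffs = np.array([1.0, 1.0, -4.0, 2.0])
        lam = np.linspace(0, 1, 21)
        vals = np.polynomial.polynomial.polyval(lam, coeffs)
        exact = np.polynomial.polynomial.polyval(
            1.0, np.concatenate(([0.0], coeffs / np.arange(1, 5))))
        got = integrate_ti(TIProfile([LambdaWindow(l, v) for l, v in zip(lam, vals)]))[0]
        h = lam[1] - lam[0]
        max_f2 = max(abs(-8.0 + 12.0 * l) for l in (0.0, 1.0))
        assert abs(got - exact) <= h * h * max_f2 / 12.0

    def test_linearity(self):
        lam = np.linspace(0, 1, 11)
        f = np.sin(3 * lam)
        g = np.exp(lam)
        a, b = 2.5, -1.25
        pf = TIProfile([LambdaWindow(l, v) for l, v in zip(lam, f)])
        pg = TIProfile([LambdaWindow(l, v) for l, v in zip(lam, g)])
        pc = TIProfile([LambdaWindow(l, a * x + b * y) for l, x, y in zip(lam, f, g)])
        assert integrate_ti(pc)[0] == pytest.approx(
            a * integrate_ti(pf)[0] + b * integrate_ti(pg)[0], rel=1e-12)

    def test_sigma_propagates_through_weights(self):
        lam = np.linspace(0, 1, 5)
        sig = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        prof = uniform_profile(np.zeros(5), sig)
        w = np.array([0.125, 0.25, 0.25, 0.25, 0.125])
        assert integrate_ti(prof)[1] == pytest.approx(
            float(np.sqrt(np.sum(w ** 2 * sig ** 2))), rel=1e-12)

    def test_simpson_beats_trapezoid_on_smooth_profile(self):
        lam = np.linspace(0, 1, 21)
        vals = np.exp(lam)
        prof = TIProfile([LambdaWindow(l, v) for l, v in zip(lam, vals)])
        exact = np.e - 1.0
        assert abs(integrate_ti(prof, rule="simpson")[0] - exact) < \
            abs(integrate_ti(prof, rule="trapezoid")[0] - exact)

    def test_missing_endpoint_rejected(self):
        lam = np.array([0.0, 0.5, 0.9])
        with pytest.raises(DomainError):
            TIProfile([LambdaWindow(l, 1.0) for l in lam])

    def test_profile_invariants(self):
        with pytest.raises(ValidationError):
            TIProfile([LambdaWindow(0.0, 1.0), LambdaWindow(1.0, 1.0)])
        with pytest.raises(ValidationError):
            TIProfile([LambdaWindow(0.0, 1.0), LambdaWindow(0.0, 2.0),
                       LambdaWindow(1.0, 1.0)])


class TestFBHWVolume:
    def test_stiff_spring_converges_to_hard_sphere(self):
        r = FBHWRestraint(k=1e12, r0=0.55)
        hard = (4.0 / 3.0) * np.pi * 0.55 ** 3
        assert fbhw_volume(r, 300.0) == pytest.approx(hard, rel=1e-3)

    def test_default_restraint_near_090(self):
        v = fbhw_volume(FBHWRestraint(), 300.0)
        assert 0.88 <= v <= 0.90

    def test_printed_formula_disagrees_and_is_reported(self):
        # the typeset closed form overstates the Gaussian-tail terms
        v_num = fbhw_volume(FBHWRestraint(), 300.0, "numeric")
        v_formula = fbhw_volume(FBHWRestraint(), 300.0, "printed_formula")
        assert v_formula == pytest.approx(1.06, abs=0.01)
        assert v_formula > v_num

    def test_monotonicity(self):
        base = FBHWRestraint()
        v = fbhw_volume(base, 300.0)
        assert fbhw_volume(base, 400.0) > v                      # warmer
        assert fbhw_volume(FBHWRestraint(r0=0.7), 300.0) > v     # wider well
        assert fbhw_volume(FBHWRestraint(k=5000.0), 300.0) < v   # stiffer

    def test_hard_sphere_limit_of_restraint_correction(self):
        r0 = 0.55
        v_hard = fbhw_volume(FBHWRestraint(k=1e14, r0=r0), 300.0)
        expected = R_KJ_PER_MOL_K * 300.0 * np.log((4 / 3) * np.pi * r0 ** 3 / 1.660)
        assert restraint_correction(v_hard, 1.660, 300.0) == pytest.approx(
            expected, abs=1e-4)


class TestCorrections:
    @pytest.mark.parametrize("v,expected", [
        (1.660, 0.0),
        (0.90, -1.5),
        (2 * 1.660, R_KJ_PER_MOL_K * 300.0 * np.log(2.0)),
    ])
    def test_restraint_correction(self, v, expected):
        assert restraint_correction(v, 1.660, 300.0) == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize("sigma,expected", [(1, 0.0), (4, -3.5), (8, -5.2)])
    def test_symmetry_correction(self, sigma, expected):
        assert symmetry_correction(sigma, 300.0) == pytest.approx(expected, abs=0.05)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            restraint_correction(-1.0, 1.66, 300.0)
        with pytest.raises(DomainError):
            symmetry_correction(0, 300.0)


class TestAssembleCycle:
    @pytest.mark.parametrize("dg1,s1,dg3,s3,dg_exp,sig_exp", CYCLE_ROWS)
    def test_reproduces_reference_rows(self, dg1, s1, dg3, s3, dg_exp, sig_exp):
        res = assemble_cycle(CycleComponents(dg1=dg1, dg2=DG2, dg3=dg3,
                                             sigma1=s1, sigma3=s3))
        assert res.dg_transfer == pytest.approx(dg_exp, abs=0.05)
        assert res.sigma == pytest.approx(sig_exp, abs=0.05)

    def test_zero_cycle(self):
        res = assemble_cycle(CycleComponents(dg1=0, dg2=0, dg3=0))
        assert res.dg_transfer == 0.0 and res.sigma == 0.0

    def test_rss_rule_is_sqrt2_larger(self):
        c = CycleComponents(dg1=79.2, dg2=DG2, dg3=4.9, sigma1=1.2, sigma3=1.0)
        a = assemble_cycle(c, ErrorRule.rss_over_sqrt2)
        b = assemble_cycle(c, ErrorRule.rss)
        assert b.sigma == pytest.approx(a.sigma * np.sqrt(2.0), rel=1e-12)
        assert b.dg_transfer == a.dg_transfer

    def test_symmetry_flag_adds_exact_correction(self):
        base = CycleComponents(dg1=76.3, dg2=DG2, dg3=12.5, symmetry_number=8)
        with_symm = CycleComponents(dg1=76.3, dg2=DG2, dg3=12.5,
                                    symmetry_number=8, include_symmetry=True)
        delta = assemble_cycle(with_symm).dg_transfer - assemble_cycle(base).dg_transfer
        assert delta == pytest.approx(symmetry_correction(8, 300.0), rel=1e-12)


class TestKdFromDg:
    def test_round_trip_with_gibbs(self):
        for dg in (-72.8, -27.1, 0.0, 5.0):
            assert gibbs_from_kd(kd_from_dg(dg, 297.0), 297.0) == pytest.approx(
                dg, abs=1e-12)

    def test_reference_values(self):
        assert kd_from_dg(-27.1, 297.0) == pytest.approx(1.7e-5, rel=0.02)
        # the simulated transfer energy implies sub-picomolar affinity,
        # quantifying the simulation/experiment gap
        assert kd_from_dg(-72.8, 300.0) == pytest.approx(2.2e-13, rel=0.05)


def test_ti_cycle_end_to_end_with_synthetic_profiles():
    """A full synthetic cycle: TI on both legs, corrections, assembly."""
    lam = np.linspace(0, 1, 11)
    cfg1 = GeneratorConfig(seed=21)
    cfg3 = GeneratorConfig(seed=22)
    prof1 = gen_ti_profile([79.2], lam, 2000, 0.4, 0.5, cfg1)
    prof3 = gen_ti_profile([4.9], lam, 2000, 0.3, 0.5, cfg3)
    dg1, s1 = integrate_ti(prof1)
    dg3, s3 = integrate_ti(prof3)
    dg2 = restraint_correction(fbhw_volume(FBHWRestraint(), 300.0))
    res = assemble_cycle(CycleComponents(dg1=dg1, dg2=dg2, dg3=dg3,
                                         sigma1=s1, sigma3=s3))
    expected = -79.2 - dg2 + 4.9
    assert res.dg_transfer == pytest.approx(expected, abs=3 * np.hypot(s1, s3))
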