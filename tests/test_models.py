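"""Core surface family: Hill curves, null/full surfaces, PDE structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hillmix as hm
from hillmix.models import _surface_terms, interaction_subsets

MIDAZOLAM = hm.HillCurve("midazolam", 0.0, 1.0, 0.144, 4.8)
PROPOFOL = hm.HillCurve("propofol", 0.0, 1.0, 1.078, 11.1)


def random_curves(rng, n, e0=0.0):
    return [
        hm.HillCurve(
            f"c{i}",
            e0,
            float(rng.uniform(max(e0, 0.6), 1.0)),
            float(np.exp(rng.uniform(-1.5, 1.5))),
            float(rng.uniform(0.5, 8.0)),
        )
        for i in range(n)
    ]


def random_full_model(rng, n, e0=0.0):
    curves = random_curves(rng, n, e0)
    emax = np.array([c.emax for c in curves])
    pert = hm.PerturbationSet(
        rng.uniform(-0.3, 1.0 - emax),
        rng.uniform(-2.0, 2.0, n),
        np.exp(rng.uniform(-0.7, 0.7, n)),
    )
    inter = hm.InteractionSet(n)
    for t in interaction_subsets(n):
        inter.d_m[t] = float(rng.uniform(-0.2, 2.0))
        inter.d_emax[t] = float(rng.uniform(-0.3, 0.3))
        inter.d_slope[t] = float(rng.uniform(-3.0, 3.0))
    return hm.MixtureModel(curves, pert, inter)


class TestHillCurve:
    @pytest.mark.parametrize(
        "dose, expected",
        [
            (0.144, 0.5),  # effect at the median-effect dose is the midpoint
            (0.0, 0.0),  # zero-dose baseline
            (0.288, 1.0 / (1.0 + 2.0**-4.8)),  # hand evaluation at 2x EC50
        ],
    )
    def test_known_values(self, dose, expected):
        assert hm.hill_effect(MIDAZOLAM, dose) == pytest.approx(expected, abs=1e-12)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            hm.hill_effect(MIDAZOLAM, -0.1)

    def test_range_and_limits(self):
        doses = np.geomspace(1e-4, 1e3, 50)
        vals = hm.hill_effect(MIDAZOLAM, doses)
        assert np.all((vals >= 0) & (vals <= 1))
        assert np.all(np.diff(vals) >= 0)
        assert hm.hill_effect(MIDAZOLAM, 1e6) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(e0=0.5, emax=0.3),  # e0 > emax
            dict(ec50=-1.0),
            dict(ec50=0.0),
            dict(slope=0.0),
            dict(emax=1.4),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(name="x", e0=0.0, emax=1.0, ec50=1.0, slope=2.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            hm.HillCurve(**base)


class TestScaledDoses:
    def test_examples(self):
        model = hm.MixtureModel([MIDAZOLAM, PROPOFOL])
        m = hm.scaled_doses(model, [0.144, 0.0])
        assert m[0] == pytest.approx(1.0)
        assert m[1] == 0.0

    def test_shifted_uses_perturbed_median(self):
        c = hm.HillCurve("a", 0, 1, 0.5, 2.0)
        pert = hm.PerturbationSet([0.0], [0.0], [2.0])
        model = hm.MixtureModel([c], pert)
        assert hm.scaled_doses(model, [2.0], shifted=True)[0] == pytest.approx(2.0)
        assert hm.scaled_doses(model, [2.0], shifted=False)[0] == pytest.approx(4.0)

    @given(st.floats(1e-6, 1e3), st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_zero_iff_zero_dose(self, dose, ec50):
        model = hm.MixtureModel([hm.HillCurve("a", 0, 1, ec50, 2.0)])
        assert hm.scaled_doses(model, [dose])[0] > 0
        assert hm.scaled_doses(model, [0.0])[0] == 0.0


class TestNullSurface:
    @given(st.floats(0.0, 1.0), st.floats(0.05, 5.0))
    @settings(max_examples=40, deadline=None)
    def test_sham_compliance_binary(self, p, total):
        """Splitting one drug's dose over clones leaves the effect unchanged."""
        a = hm.HillCurve("a", 0.0, 0.9, 1.3, 3.1)
        clone = hm.HillCurve("b", a.e0, a.emax, a.ec50, a.slope)
        model = hm.MixtureModel([a, clone])
        split = hm.u_null(model, [p * total, (1 - p) * total])
        assert split == pytest.approx(hm.hill_effect(a, total), abs=1e-10)

    def test_sham_compliance_ternary_random_splits(self, rng):
        a = hm.HillCurve("a", 0.1, 0.85, 0.7, 2.4)
        clones = [hm.HillCurve(f"c{i}", a.e0, a.emax, a.ec50, a.slope) for i in range(3)]
        model = hm.MixtureModel(clones)
        for _ in range(50):
            total = float(np.exp(rng.uniform(-2, 2)))
            w = rng.dirichlet([1.0, 1.0, 1.0])
            val = hm.u_null(model, w * total)
            assert val == pytest.approx(hm.hill_effect(a, total), abs=1e-10)

    def test_single_compound_axis_reduces_to_hill(self, rng):
        curves = random_curves(rng, 3)
        model = hm.MixtureModel(curves)
        for i, c in enumerate(curves):
            for dose in (0.05, c.ec50, 5.0):
                d = np.zeros(3)
                d[i] = dose
                assert hm.u_null(model, d) == pytest.approx(
                    hm.hill_effect(c, dose), abs=1e-10
                )

    def test_zero_dose_returns_baseline(self):
        model = hm.MixtureModel([MIDAZOLAM, PROPOFOL])
        assert hm.u_null(model, [0.0, 0.0]) == 0.0
        m2 = hm.MixtureModel(
            [hm.HillCurve("a", 0.2, 0.9, 1.0, 2.0), hm.HillCurve("b", 0.2, 1.0, 2.0, 3.0)]
        )
        assert hm.u_null(m2, [0.0, 0.0]) == pytest.approx(0.2)

    def test_monotone_in_each_dose_equal_slopes_and_maxima(self, rng):
        """Per-dose monotonicity holds when slope and maximum are shared.

        (With unequal slopes the dose-weighted mixed slope can grow toward
        the steeper drug and locally lower the response below the combined
        EC50 — a genuine property of the surface, not asserted here.)
        """
        curves = [
            hm.HillCurve("a", 0, 0.9, 0.5, 3.0),
            hm.HillCurve("b", 0, 0.9, 2.0, 3.0),
        ]
        model = hm.MixtureModel(curves)
        base = np.exp(rng.uniform(-2, 2, size=(200, 2)))
        for axis in range(2):
            bumped = base.copy()
            bumped[:, axis] *= 1.01
            assert np.all(
                hm.u_null(model, bumped) >= hm.u_null(model, base) - 1e-12
            )

    def test_monotone_along_rays_unequal_slopes(self, rng):
        curves = [
            hm.HillCurve("a", 0, 1.0, 0.5, 1.7),
            hm.HillCurve("b", 0, 1.0, 2.0, 6.0),
        ]
        model = hm.MixtureModel(curves)
        for _ in range(20):
            w = rng.dirichlet([1.0, 1.0])
            totals = np.geomspace(0.05, 20.0, 40)
            vals = hm.u_null(model, totals[:, None] * w[None, :])
            assert np.all(np.diff(vals) >= -1e-12)


class TestFullSurface:
    def test_null_limit(self, rng):
        curves = random_curves(rng, 3)
        model = hm.MixtureModel(curves)
        d = np.exp(rng.uniform(-2, 2, size=(20, 3)))
        np.testing.assert_allclose(
            hm.u_ricc(model, d), hm.u_null(model, d), atol=1e-14
        )

    def test_interaction_only_pure_limit(self):
        """Interaction terms vanish automatically on single-compound axes."""
        inter = hm.InteractionSet(2, d_emax={(0, 1): 0.4}, d_slope={(0, 1): -3.0},
                                  d_m={(0, 1): 1.2})
        model = hm.MixtureModel([MIDAZOLAM, PROPOFOL], None, inter)
        for dose in (0.05, 0.144, 1.0):
            assert hm.u_ricc(model, [dose, 0.0]) == pytest.approx(
                hm.hill_effect(MIDAZOLAM, dose), abs=1e-10
            )
            assert hm.u_ricc(model, [0.0, dose]) == pytest.approx(
                hm.hill_effect(PROPOFOL, dose), abs=1e-10
            )

    def test_perturbed_pure_limit_matches_shifted_hill(self):
        """With perturbations active the axis limit is the perturbed curve."""
        pert = hm.PerturbationSet([-0.2, 0.0], [1.5, 0.0], [2.0, 1.0])
        model = hm.MixtureModel([MIDAZOLAM, PROPOFOL], pert)
        shifted = hm.HillCurve(
            "m'", 0.0, MIDAZOLAM.emax - 0.2, MIDAZOLAM.ec50 * 2.0, MIDAZOLAM.slope + 1.5
        )
        for dose in (0.05, 0.2, 1.0):
            assert hm.u_ricc(model, [dose, 0.0]) == pytest.approx(
                hm.hill_effect(shifted, dose), abs=1e-10
            )

    def test_high_dose_limit_is_perturbed_maximum(self):
        pert = hm.PerturbationSet([-0.3, 0.0], [0.0, 0.0], [1.0, 1.0])
        model = hm.MixtureModel([MIDAZOLAM, PROPOFOL], pert)
        val = hm.u_ricc(model, [1e8, 0.5])
        assert val == pytest.approx(MIDAZOLAM.emax - 0.3, abs=1e-4)

    def test_continuity_in_parameters(self, rng):
        curves = random_curves(rng, 2)
        d = np.exp(rng.uniform(-1.5, 1.5, size=(30, 2)))
        null = hm.u_null(hm.MixtureModel(curves), d)
        for eps in (1e-4, 1e-7, 1e-9):
            pert = hm.PerturbationSet([0.0, -eps], [eps, -eps], [1.0 + eps, 1.0])
            inter = hm.InteractionSet(
                2, d_m={(0, 1): eps}, d_emax={(0, 1): -eps}, d_slope={(0, 1): eps}
            )
            vals = hm.u_ricc(hm.MixtureModel(curves, pert, inter), d)
            assert np.max(np.abs(vals - null)) < 50 * eps

    def test_negative_bracket_names_subset(self):
        inter = hm.InteractionSet(2, d_m={(0, 1): -5.0})
        model = hm.MixtureModel([MIDAZOLAM, PROPOFOL], None, inter)
        with pytest.raises(hm.BracketError, match="midazolam"):
            hm.u_ricc(model, [0.144, 1.078])

    def test_emax_constraint_enforced(self):
        pert = hm.PerturbationSet([0.4, 0.0], [0.0, 0.0], [1.0, 1.0])
        curve = hm.HillCurve("a", 0, 0.8, 1.0, 2.0)
        with pytest.raises(ValueError, match="exceeds 1"):
            hm.MixtureModel([curve, PROPOFOL], pert)


class TestPDEResidual:
    def test_null_and_full_random_models(self, rng):
        """The governing PDE is satisfied for arbitrary valid parameters."""
        for n in (2, 3):
            for _ in range(6):
                model = random_full_model(rng, n)
                pts = rng.uniform(-1.5, 1.5, size=(5, n))
                for x in pts:
                    assert abs(hm.pde_residual(model, x, "null")) < 1e-6
                    assert abs(hm.pde_residual(model, x, "ricc")) < 1e-6

    def test_anesthetic_interaction_model_grid(self):
        inter = hm.InteractionSet(
            2, d_emax={(0, 1): 0.13}, d_slope={(0, 1): -12.89}, d_m={(0, 1): 1.11}
        )
        model = hm.MixtureModel([MIDAZOLAM, PROPOFOL], None, inter)
        xs = np.linspace(np.log(0.05), np.log(0.2), 5)
        ys = np.linspace(np.log(0.3), np.log(1.5), 5)
        worst = max(
            abs(hm.pde_residual(model, [x, y], "ricc")) for x in xs for y in ys
        )
        assert worst < 1e-6

    def test_nonzero_baseline_riccati_form(self, rng):
        model = random_full_model(rng, 2, e0=0.15)
        for x in rng.uniform(-1, 1, size=(6, 2)):
            assert abs(hm.pde_residual(model, x, "ricc")) < 1e-6

    def test_corrupted_surface_fails(self):
        """A surface with its slope field inflated is not a PDE solution."""
        model = hm.MixtureModel([MIDAZOLAM, PROPOFOL])
        x = np.array([np.log(0.1), np.log(0.5)])
        u, umax, gamma, umin, _ = _surface_terms(model, np.exp(x)[None, :], null=True)
        step = 1e-5
        dsum = 0.0
        for i in range(2):
            for sgn in (1, -1):
                xp = x.copy()
                xp[i] += sgn * step
                up, *_ = _surface_terms(model, np.exp(xp)[None, :], null=True)
                dsum += sgn * up[0] / (2 * step)
        bad_rhs = 1.1 * gamma[0] * (u[0] - umin[0]) * (umax[0] - u[0]) / (umax[0] - umin[0])
        assert abs(dsum - bad_rhs) > 1e-3


class TestParameterCount:
    @pytest.mark.parametrize("n, expected", [(2, 9), (3, 21), (4, 45)])
    def test_published_counts(self, n, expected):
        assert hm.parameter_count(n) == expected

    def test_matches_subset_enumeration(self):
        for n in range(2, 7):
            n_inter = len(interaction_subsets(n))
            assert hm.parameter_count(n) == 3 * n + 3 * n_inter

    def test_domain_error(self):
        with pytest.raises(ValueError):
            hm.parameter_count(1)

    def test_interaction_triple_count(self):
        for n in (2, 3, 4):
            assert len(interaction_subsets(n)) == 2**n - n - 1
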