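import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ahmbench as ab
from ahmbench.ahm_models import balance_step, class_survival, kill_rate
from ahmbench.records import record_median


@pytest.mark.parametrize("h,c,expected", [(0.1, 0.0, 0.1), (0.1, 0.2, 0.125)])
def test_kill_rate(h, c, expected):
    assert kill_rate(h, c) == pytest.approx(expected)


def test_kill_rate_exceeding_one_rejected():
    with pytest.raises(ValueError, match="exceeds"):
        kill_rate(0.9, 0.2)  # K = 1.125


@pytest.mark.parametrize("s0,k,expected", [(0.9, 0.0, 0.9), (0.9, 0.2, 0.72), (1.0, 0.5, 0.5)])
def test_survival_additive(s0, k, expected):
    assert ab.survival_additive(s0, k) == pytest.approx(expected)


@pytest.mark.parametrize("s0,k,expected", [
    (0.9, 0.05, 0.9),   # below threshold C = 0.1
    (0.9, 0.3, 0.7),    # above threshold: 1 - K
    (0.9, 0.1, 0.9),    # continuous at the threshold
])
def test_survival_compensatory(s0, k, expected):
    assert ab.survival_compensatory(s0, k) == pytest.approx(expected)


@settings(deadline=None, max_examples=200)
@given(st.floats(0.05, 0.999), st.floats(0.0, 0.95))
def test_compensatory_dominates_additive(s0, k):
    """S_c >= S_a everywhere, strictly except at K=0 (when s0 < 1)."""
    sa, sc = ab.survival_additive(s0, k), ab.survival_compensatory(s0, k)
    assert sc >= sa - 1e-15
    if k > 1e-12 and s0 < 1:  # strictness is numerically meaningless for tiny K
        assert sc > sa


def test_additive_linear_compensatory_flat():
    ks = np.linspace(0, 0.09, 10)
    sa = np.array([ab.survival_additive(0.9, k) for k in ks])
    sc = np.array([ab.survival_compensatory(0.9, k) for k in ks])
    np.testing.assert_allclose(np.diff(sa), -0.9 * np.diff(ks))  # slope -s0
    assert np.all(sc == 0.9)  # zero slope on [0, 1 - s0]


@pytest.mark.parametrize("a0,a1,a2,n,w,expected", [
    (0.8, 0.0, 0.0, 5.0, 2.0, 0.8),          # constants only
    (0.8, -0.1, 0.2, 7.0, 1.0, 0.3),         # 0.8 - 0.7 + 0.2
    (0.1, -0.1, 0.0, 7.0, 0.0, 0.0),         # zero-truncation
])
def test_reproduction_rate(a0, a1, a2, n, w, expected):
    p = ab.ReproParams(a0=a0, a1=a1, a2=a2)
    assert ab.reproduction_rate(p, n, w) == pytest.approx(expected)


class TestBalanceStep:
    def test_pure_survival_is_identity(self):
        bp = ab.BalanceParams(m=0.3)
        s = ab.ClassSurvival(1.0, 1.0, 1.0, 1.0)
        assert balance_step(bp, 7.3, s, 0.0) == pytest.approx(7.3)

    def test_uniform_adult_survival(self):
        bp = ab.BalanceParams(m=0.5)
        s = ab.ClassSurvival(0.9, 0.9, 0.0, 0.0)
        assert balance_step(bp, 8.0, s, 0.0) == pytest.approx(0.9 * 8.0)

    def test_full_numeric_case(self):
        bp = ab.BalanceParams(m=0.55, phi_ratio=1.2)
        s = ab.ClassSurvival(s_am=0.85, s_af=0.70, s_jm=0.65, s_jf=0.60)
        expected = 8 * (0.55 * 0.85 + 0.45 * (0.70 + 0.9 * (0.60 + 0.65 * 1.2)))
        assert balance_step(bp, 8.0, s, 0.9) == pytest.approx(expected, rel=1e-14)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0.5, 20.0), st.floats(1.01, 5.0))
    def test_homogeneous_without_density_dependence(self, n, factor):
        """With a1 = 0 the map is degree-1 homogeneous: doubling N doubles N'."""
        p = ab.default_params()
        repro = ab.ReproParams(a0=0.7, a1=0.0, a2=0.2)
        s = class_survival(p.survival, {"am": 0.14, "af": 0.09, "jm": 0.18, "jf": 0.12},
                          "additive")
        one = balance_step(p.balance, n, s, ab.reproduction_rate(repro, n, 0.3))
        scaled = balance_step(p.balance, factor * n, s,
                              ab.reproduction_rate(repro, factor * n, 0.3))
        assert scaled == pytest.approx(factor * one, rel=1e-12)

    @pytest.mark.parametrize("model_id", ab.AHM_MODEL_IDS)
    def test_unique_fixed_point_monotone_convergence(self, model_id):
        """With a1 < 0 the deterministic map contracts monotonically to one
        positive fixed point from above and below."""
        p = ab.default_params()
        harvest = {"am": 0.14, "af": 0.09, "jm": 0.18, "jf": 0.12}
        form = "additive" if model_id.startswith("Sa") else "compensatory"
        s = class_survival(p.survival, harvest, form)

        def step(n):
            return balance_step(p.balance, n, s,
                                ab.reproduction_rate(p.repro(model_id), n, 0.0))

        traj = {}
        for start in (2.0, 30.0):
            n = start
            path = [n]
            for _ in range(300):
                n = step(n)
                path.append(n)
            traj[start] = path
        # one positive fixed point, reached from either side
        fix = traj[2.0][-1]
        assert fix > 0
        assert traj[30.0][-1] == pytest.approx(fix, rel=1e-6)
        assert step(fix) == pytest.approx(fix, rel=1e-9)
        for path in traj.values():
            # contraction: the distance to the fixed point never grows after a
            # short burn-in (strong density dependence approaches it with
            # damped oscillation rather than strictly monotonically)
            dist = np.abs(np.array(path[3:]) - fix)
            assert np.all(np.diff(dist) <= 1e-9)


class TestAHMForecast:
    HARVEST = {"am": 0.14, "af": 0.09, "jm": 0.18, "jf": 0.12}

    def test_noise_free_is_degenerate_at_balance_output(self):
        p = ab.default_params()
        p0 = ab.ahm_models.with_process_sd(p, 0.0)
        rec = ab.ahm_forecast("SaRw", 1995, 8.0, 0.3, self.HARVEST, p0)
        assert rec.sd == 0.0
        s = class_survival(p.survival, self.HARVEST, "additive")
        r = ab.reproduction_rate(p.repro_weak, 8.0, 0.3)
        assert rec.mean == pytest.approx(balance_step(p.balance, 8.0, s, r), rel=1e-14)
        assert rec.target_year == 1996

    def test_compensatory_at_least_additive_mean(self):
        p = ab.default_params()
        low = {c: 0.02 for c in self.HARVEST}  # below every compensatory threshold
        sa = ab.ahm_forecast("SaRw", 1995, 8.0, 0.0, low, p)
        sc = ab.ahm_forecast("ScRw", 1995, 8.0, 0.0, low, p)
        assert sc.mean >= sa.mean

    def test_unknown_model_id(self):
        with pytest.raises(ValueError, match="unknown AHM model"):
            ab.ahm_forecast("SxRy", 1995, 8.0, 0.0, self.HARVEST, ab.default_params())

    def test_lognormal_moments_match_monte_carlo(self):
        """Forecast mean/sd agree with 100k draws of the stated lognormal."""
        p = ab.default_params()
        rec = ab.ahm_forecast("SaRw", 1995, 8.0, 0.3, self.HARVEST, p)
        rng = np.random.default_rng(2024)
        draws = record_median(rec) * np.exp(rng.normal(0.0, rec.params["sigma"], 100_000))
        se_mean = draws.std(ddof=1) / math.sqrt(len(draws))
        assert rec.mean == pytest.approx(draws.mean(), abs=3 * se_mean)
        # sd of the sample sd: ~ sd / sqrt(2(n-1)) for nearly-normal draws
        se_sd = draws.std(ddof=1) / math.sqrt(2 * (len(draws) - 1))
        assert rec.sd == pytest.approx(draws.std(ddof=1), abs=4 * se_sd)
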