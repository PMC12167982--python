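"""Frailty birth process vs self-exciting point-process twin."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from twinmodels import (
    ContactParams,
    EventTrajectory,
    make_rng,
    snm_log_lik,
    snm_simulate,
    thinning_simulate,
    twin_intensity,
    twin_log_lik,
)
from twinmodels.contact import (
    integrated_baseline,
    snm_log_lik_quadrature,
    twin_compensator_increment,
    _inverse_compensator,
)
from twinmodels.contact import twin_simulate as pp_twin_simulate

DEFAULT = ContactParams()  # alpha=1, pi0=0.25, pi_j=0.25*sqrt(j)


def _random_history(gen, n_events, t_max=5.0):
    return np.sort(gen.uniform(0, t_max, size=n_events))


class TestIntensity:
    def test_empty_history_closed_form(self):
        # lambda_1(t) = pi0*alpha/(pi0*t + alpha)
        p = ContactParams(alpha=2.0, pi0=0.5, scale=0.5, rho=1.0)
        for t in (0.5, 1.0, 7.0):
            assert twin_intensity(p, [], t) == pytest.approx(
                0.5 * 2.0 / (0.5 * t + 2.0), rel=1e-12
            )

    def test_denominator_telescopes_to_baseline(self):
        """pi_m*t - sum (pi_j - pi_{j-1}) t_j + alpha == A_m + pi_m (t - t_m)."""
        gen = make_rng(71).generator()
        p = DEFAULT
        for _ in range(20):
            hist = _random_history(gen, int(gen.integers(1, 7)))
            m = len(hist)
            t = hist[-1] + gen.uniform(0.01, 2.0)
            pis = p.pi_array(m)
            direct = p.alpha + pis[m] * t - np.sum((pis[1:] - pis[:-1]) * hist)
            via_baseline = integrated_baseline(p, hist) + pis[m] * (t - hist[-1])
            assert direct == pytest.approx(via_baseline, rel=1e-12)
            lam = twin_intensity(p, hist, t)
            assert lam == pytest.approx(pis[m] * (m + p.alpha) / direct, rel=1e-12)

    def test_decreasing_between_events_jump_at_events(self):
        p = DEFAULT
        hist = [1.0, 2.5]
        ts = np.linspace(2.6, 6.0, 50)
        lams = [twin_intensity(p, hist, t) for t in ts]
        assert np.all(np.diff(lams) < 0)
        # just after the second event the rate exceeds the rate just before
        before = twin_intensity(p, [1.0], 2.5 - 1e-9)
        after = twin_intensity(p, hist, 2.5 + 1e-9)
        assert after > before  # pi_2 >= pi_1 for the power family

    def test_recent_events_raise_the_rate(self):
        """Shifting all events earlier lowers the intensity (increasing pi)."""
        p = ContactParams(alpha=1.0, pi0=0.25, scale=0.25, rho=1.0)
        t = 6.0
        recent = np.array([3.0, 4.0, 5.0])
        old = recent - 2.0
        assert twin_intensity(p, recent, t) > twin_intensity(p, old, t)

    def test_requires_time_beyond_history(self):
        with pytest.raises(ValueError):
            twin_intensity(DEFAULT, [1.0, 2.0], 1.5)


class TestTimeChange:
    def test_first_interval_inverse_closed_form(self):
        # k=0, alpha=1, pi0=0.25: s_1(z) = 4(e^z - 1)
        for z in (0.1, 1.0, 3.0):
            assert _inverse_compensator(DEFAULT, 0, 1.0, z) == pytest.approx(
                4.0 * np.expm1(z), rel=1e-12
            )

    def test_compensator_inverse_identity_by_quadrature(self):
        gen = make_rng(73).generator()
        p = DEFAULT
        for _ in range(10):
            hist = _random_history(gen, int(gen.integers(0, 6)))
            m = len(hist)
            start = hist[-1] if m else 0.0
            z = gen.exponential()
            s = _inverse_compensator(p, m, integrated_baseline(p, hist), z)
            val, err = quad(lambda t: twin_intensity(p, hist, t), start, start + s,
                            limit=200)
            assert val == pytest.approx(z, abs=max(1e-8, 10 * err))
            # and the closed-form increment agrees
            assert twin_compensator_increment(p, hist, s) == pytest.approx(z, rel=1e-12)

    def test_twin_matches_thinning_sampler(self):
        """Time-change and Ogata thinning draw the same first-event law."""
        n = 4000
        a = pp_twin_simulate(DEFAULT, 10.0, n, make_rng(75))
        b = thinning_simulate(DEFAULT, 10.0, n, make_rng(76))
        fa = [tr.times[0] for tr in a.trajectories() if len(tr)]
        fb = [tr.times[0] for tr in b.trajectories() if len(tr)]
        assert stats.ks_2samp(fa, fb).pvalue > 0.01
        # total-count distribution agrees too
        ca = [len(tr) for tr in a.trajectories()]
        cb = [len(tr) for tr in b.trajectories()]
        assert stats.ks_2samp(ca, cb).pvalue > 0.01


class TestLikelihoods:
    def test_empty_trajectory_survival(self):
        p = ContactParams(alpha=1.5, pi0=0.4, scale=0.4, rho=0.5)
        traj = EventTrajectory([], 8.0)
        expected = -1.5 * np.log(1 + 0.4 * 8.0 / 1.5)
        assert snm_log_lik(p, traj) == pytest.approx(expected, rel=1e-12)
        assert twin_log_lik(p, traj) == pytest.approx(expected, rel=1e-12)

    def test_frailty_and_twin_likelihoods_agree(self):
        panel = snm_simulate(DEFAULT, 10.0, 30, make_rng(77))
        for traj in panel.trajectories():
            a, b = snm_log_lik(DEFAULT, traj), twin_log_lik(DEFAULT, traj)
            assert a == pytest.approx(b, abs=1e-8)

    def test_quadrature_oracle_agreement(self):
        gen = make_rng(79).generator()
        for _ in range(8):
            p = ContactParams(
                alpha=gen.uniform(0.5, 3.0),
                pi0=gen.uniform(0.1, 1.0),
                scale=gen.uniform(0.1, 1.0),
                rho=gen.uniform(0.0, 1.0),
            )
            traj = snm_simulate(p, 8.0, 1, make_rng(int(gen.integers(1 << 20)))).trajectories()[0]
            assert snm_log_lik(p, traj) == pytest.approx(
                snm_log_lik_quadrature(p, traj), abs=1e-6
            )

    def test_mismatched_parameters_detected(self):
        traj = snm_simulate(DEFAULT, 10.0, 1, make_rng(81)).trajectories()[0]
        other = ContactParams(alpha=2.0)
        assert abs(snm_log_lik(other, traj) - twin_log_lik(DEFAULT, traj)) > 1e-3


class TestCountDistributions:
    def test_constant_rate_counts_are_negative_binomial(self):
        """Gamma-mixed Poisson closed form for pi_j = pi constant."""
        p = ContactParams(alpha=1.0, pi=lambda j: 0.5)
        t = 4.0
        n = 10_000
        panel = snm_simulate(p, t, n, make_rng(83))
        counts = np.array([len(tr) for tr in panel.trajectories()])
        nb = stats.nbinom(1.0, 1.0 / (1.0 + 0.5 * t))
        obs = np.bincount(counts).astype(float)
        exp = nb.pmf(np.arange(len(obs))) * n
        exp[-1] += n - exp.sum()  # fold the tail mass into the last cell
        while exp[-1] < 10 and len(exp) > 2:
            exp[-2] += exp[-1]
            obs[-2] += obs[-1]
            exp, obs = exp[:-1], obs[:-1]
        assert stats.chisquare(obs, f_exp=exp).pvalue > 0.01

    def test_count_distribution_interface(self):
        from twinmodels.contact import count_distribution

        pmfs = count_distribution(DEFAULT, [2.0, 5.0], 500, make_rng(85), "snm")
        assert set(pmfs) == {2.0, 5.0}
        for pmf in pmfs.values():
            assert pmf.sum() == pytest.approx(1.0)

    def test_snm_and_twin_counts_indistinguishable(self):
        n = 4000
        a = snm_simulate(DEFAULT, 10.0, n, make_rng(87))
        b = pp_twin_simulate(DEFAULT, 10.0, n, make_rng(88))
        ca = [len(tr) for tr in a.trajectories()]
        cb = [len(tr) for tr in b.trajectories()]
        assert stats.ks_2samp(ca, cb).pvalue > 0.01


def test_pi_rule_validation():
    with pytest.raises(ValueError):
        ContactParams(alpha=0.0)
    bad = ContactParams(pi=lambda j: -1.0)
    with pytest.raises(ValueError):
        bad.pi(0)
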