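"""The Pólya urn and its latent-propensity twin for binary panel data.

The urn starts with one black and one red ball; at each step a ball is drawn
uniformly and returned together with another ball of the same colour.  Writing
``Y_n = 1`` for a black draw, the scheme is a pure reinforcement process: the
conditional probability of black at step ``n`` is ``(1 + sum_{k<n} Y_k) /
(n + 1)``, so past black draws beget future ones.

Its statistically indistinguishable twin is a pure heterogeneity model: draw a
propensity ``p ~ Uniform[0, 1]`` once per unit, then make all draws i.i.d.
Bernoulli(p).  The two processes have identical joint distributions over
entire sequences — any sequence with ``k`` ones out of ``n`` has probability
``k! (n-k)! / (n+1)!`` under both — so no statistical test can tell them
apart.  :func:`polya_log_prob` deliberately computes the sequential product of
urn conditionals while :func:`mixture_log_prob` integrates the propensity out
through the Beta function; their agreement is the exact-equivalence oracle
used throughout the test-suite.

All probabilities are accumulated in log space (log-gamma) so that sequences
hundreds of draws long do not underflow.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betaln, gammaln

from .panel import (
    BinaryTrajectory,
    GenerativeModel,
    Panel,
    RandomStreams,
)

__all__ = [
    "PolyaUrn",
    "UniformBernoulliMixture",
    "polya_simulate",
    "mixture_simulate",
    "polya_log_prob",
    "mixture_log_prob",
    "black_count_pmf",
]


def _check_n_draws(n_draws: int) -> None:
    if n_draws < 1:
        raise ValueError(f"n_draws must be a positive integer, got {n_draws}")


class PolyaUrn(GenerativeModel):
    """Pólya urn reinforcement model, started from ``n_black`` / ``n_red`` balls.

    The default (1, 1) start is the canonical exchangeable case whose twin is
    the uniform-propensity Bernoulli mixture; a general ``(a, b)`` start has a
    Beta(a, b)-propensity twin and is exposed for completeness.
    """

    name = "polya_urn"
    kind = BinaryTrajectory

    def __init__(self, n_black: int = 1, n_red: int = 1):
        if n_black < 1 or n_red < 1:
            raise ValueError("initial ball counts must be positive integers")
        self.n_black = int(n_black)
        self.n_red = int(n_red)

    def _sample_unit(self, size, generator) -> BinaryTrajectory:
        n_draws = int(size)
        _check_n_draws(n_draws)
        u = generator.uniform(size=n_draws)
        black, total = self.n_black, self.n_black + self.n_red
        y = np.empty(n_draws, dtype=np.int8)
        for n in range(n_draws):
            draw = u[n] < black / total
            y[n] = draw
            black += draw
            total += 1
        return BinaryTrajectory(y)

    def log_likelihood(self, traj: BinaryTrajectory) -> float:
        y = np.asarray(traj.values, dtype=np.int64)
        if y.size == 0:
            raise ValueError("sequence must be non-empty")
        n = np.arange(1, y.size + 1)
        ones_before = np.concatenate(([0], np.cumsum(y)[:-1]))
        total0 = self.n_black + self.n_red
        p_black = (self.n_black + ones_before) / (total0 - 1 + n)
        return float(np.sum(np.where(y == 1, np.log(p_black), np.log1p(-p_black))))


class UniformBernoulliMixture(GenerativeModel):
    """Heterogeneity twin: ``p ~ Beta(a, b)`` per unit, then i.i.d. Bernoulli(p).

    With the default ``a = b = 1`` (uniform propensity) this is the exact twin
    of the (1, 1)-start Pólya urn.  The propensity is latent: it is drawn,
    used, and discarded inside the simulator.
    """

    name = "uniform_bernoulli_mixture"
    kind = BinaryTrajectory

    def __init__(self, a: float = 1.0, b: float = 1.0):
        if a <= 0 or b <= 0:
            raise ValueError("Beta propensity parameters must be positive")
        self.a = float(a)
        self.b = float(b)

    def _sample_unit(self, size, generator) -> BinaryTrajectory:
        n_draws = int(size)
        _check_n_draws(n_draws)
        p = generator.beta(self.a, self.b)
        return BinaryTrajectory((generator.uniform(size=n_draws) < p).astype(np.int8))

    def log_likelihood(self, traj: BinaryTrajectory) -> float:
        y = np.asarray(traj.values, dtype=np.int64)
        if y.size == 0:
            raise ValueError("sequence must be non-empty")
        k = int(y.sum())
        n = y.size
        # integral of p^k (1-p)^(n-k) against the Beta(a, b) prior density
        return float(betaln(self.a + k, self.b + n - k) - betaln(self.a, self.b))


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def polya_simulate(n_draws: int, n_units: int, rng: RandomStreams) -> Panel:
    """Simulate ``n_units`` Pólya urn sequences of ``n_draws`` draws each."""
    _check_n_draws(n_draws)
    return PolyaUrn().simulate(n_units, n_draws, rng)


def mixture_simulate(n_draws: int, n_units: int, rng: RandomStreams) -> Panel:
    """Simulate the uniform-propensity Bernoulli twin panel."""
    _check_n_draws(n_draws)
    return UniformBernoulliMixture().simulate(n_units, n_draws, rng)


def polya_log_prob(seq: BinaryTrajectory) -> float:
    """Log probability of a binary sequence under the (1, 1)-start Pólya urn.

    Computed as the sequential product of urn conditionals (not the closed
    form), so it can serve as one independent side of the equivalence oracle.
    """
    return PolyaUrn().log_likelihood(seq)


def mixture_log_prob(seq: BinaryTrajectory) -> float:
    """Log probability under the uniform-propensity mixture, via log-Beta."""
    return UniformBernoulliMixture().log_likelihood(seq)


def black_count_pmf(n_draws: int) -> np.ndarray:
    """Exact pmf of the number of black draws in ``n_draws`` Pólya steps.

    ``P(K = k) = C(n, k) * Beta(k+1, n-k+1)``; for the (1, 1) start this is
    uniform on ``{0, ..., n}``, the closed-form reference for the simulated
    black-minus-red spread.
    """
    _check_n_draws(n_draws)
    k = np.arange(n_draws + 1)
    log_binom = gammaln(n_draws + 1) - gammaln(k + 1) - gammaln(n_draws - k + 1)
    log_pmf = log_binom + betaln(k + 1, n_draws - k + 1)
    pmf = np.exp(log_pmf)
    return pmf / pmf.sum()
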