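"""The Q-model of citation impact and its sequential-normal reinforcement twin.

In the Q-model a scientist's n-th paper earns ``c_n = Q * p_n`` citations,
with a fixed lognormal talent factor ``Q`` and i.i.d. lognormal luck ``p_n``.
On the log scale, ``Y_n = T + X_n`` with ``T ~ N(mu_T, var_T)`` drawn once per
unit and ``X_n ~ N(0, var_X)`` i.i.d. — a stationary heterogeneity model
whose joint law is multivariate normal with an exchangeable covariance
``var_T * J + var_X * I``.

Its reinforcement twin has no latent trait at all.  Given the history
``y_1, ..., y_n``, the next outcome is normal with

    mean      mu_{n+1} = (c*a + sum_k y_k) / (n + c)
    variance  sigma_{n+1}^2 = b * (1 + 1/(n + c))

so each observation feeds back the running average of past outcomes; for
``n = 0`` the first draw is N(a, b + b/c).  Under the parameter map

    a = mu_T,   b = var_X,   c = var_X / var_T

the two processes have identical joint distributions.  The twin's conditional
law is exactly the Bayesian posterior predictive of the Q-model (a
conjugate-normal update in which every past observation is equally
informative about the talent), which is why the equivalence holds and why the
twin's noise variance shrinks toward ``b`` as the history grows.

The settled-dispositions special case ``(a, b, c) = (0, 1, 1)`` gives the
belief-updating recursion

    y_n' = ((n-1)/n) * ybar_{n-1}' + sqrt(1 + 1/n) * v_n,   v_n ~ N(0, 1),

exposed as :func:`sdm_twin_step` with caller-supplied innovations so the
recursion can be checked deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal

from .panel import GenerativeModel, Panel, RandomStreams, RealTrajectory

__all__ = [
    "QModelParams",
    "TwinParams",
    "map_q_to_twin",
    "map_twin_to_q",
    "QModel",
    "GaussianTwin",
    "q_simulate",
    "twin_simulate",
    "twin_conditional",
    "q_joint_moments",
    "q_log_pdf",
    "twin_log_pdf",
    "sdm_twin_step",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class QModelParams:
    """Heterogeneity parameterization: T ~ N(mu_T, var_T), X_n ~ N(0, var_X)."""

    mu_T: float
    var_T: float
    var_X: float

    def __post_init__(self):
        if self.var_T <= 0:
            raise ValueError(f"var_T must be positive, got {self.var_T}")
        if self.var_X <= 0:
            raise ValueError(f"var_X must be positive, got {self.var_X}")


@dataclass(frozen=True)
class TwinParams:
    """Reinforcement parameterization (a, b, c) of the sequential-normal twin."""

    a: float
    b: float
    c: float

    def __post_init__(self):
        if self.b <= 0:
            raise ValueError(f"b must be positive, got {self.b}")
        if self.c <= 0:
            raise ValueError(f"c must be positive, got {self.c}")


def map_q_to_twin(q: QModelParams) -> TwinParams:
    """Parameter map under which the twin reproduces the Q-model's joint law."""
    return TwinParams(a=q.mu_T, b=q.var_X, c=q.var_X / q.var_T)


def map_twin_to_q(t: TwinParams) -> QModelParams:
    """Inverse map: mu_T = a, var_X = b, var_T = b/c."""
    return QModelParams(mu_T=t.a, var_T=t.b / t.c, var_X=t.b)


def twin_conditional(t: TwinParams, history) -> tuple[float, float]:
    """Mean and variance of the next outcome given the unit's history.

    ``history`` may be a :class:`RealTrajectory`, an array, or empty (n = 0),
    in which case the unconditional first-draw law ``(a, b + b/c)`` is
    returned.
    """
    values = history.values if isinstance(history, RealTrajectory) else np.asarray(
        history, dtype=float
    )
    n = values.size
    mean = (t.c * t.a + values.sum()) / (n + t.c)
    variance = t.b * (1.0 + 1.0 / (n + t.c))
    return float(mean), float(variance)


class QModel(GenerativeModel):
    """Latent-talent heterogeneity model: Y_n = T + X_n on the log scale."""

    name = "q_model"
    kind = RealTrajectory

    def __init__(self, params: QModelParams):
        self.params = params

    def _sample_unit(self, size, generator) -> RealTrajectory:
        n_obs = int(size)
        if n_obs < 1:
            raise ValueError(f"n_obs must be >= 1, got {n_obs}")
        p = self.params
        talent = generator.normal(p.mu_T, np.sqrt(p.var_T))
        luck = generator.normal(0.0, np.sqrt(p.var_X), size=n_obs)
        return RealTrajectory(talent + luck)

    def log_likelihood(self, traj: RealTrajectory) -> float:
        return q_log_pdf(self.params, traj)


class GaussianTwin(GenerativeModel):
    """Pure reinforcement twin: sequential normal draws, no latent variable."""

    name = "gaussian_twin"
    kind = RealTrajectory

    def __init__(self, params: TwinParams):
        self.params = params

    def _sample_unit(self, size, generator) -> RealTrajectory:
        n_obs = int(size)
        if n_obs < 1:
            raise ValueError(f"n_obs must be >= 1, got {n_obs}")
        t = self.params
        eps = generator.standard_normal(n_obs)
        y = np.empty(n_obs)
        running_sum = 0.0
        for n in range(n_obs):
            mean = (t.c * t.a + running_sum) / (n + t.c)
            sd = np.sqrt(t.b * (1.0 + 1.0 / (n + t.c)))
            y[n] = mean + sd * eps[n]
            running_sum += y[n]
        return RealTrajectory(y)

    def log_likelihood(self, traj: RealTrajectory) -> float:
        return twin_log_pdf(self.params, traj)


def q_simulate(q: QModelParams, n_units: int, n_obs: int, rng: RandomStreams) -> Panel:
    """Simulate a Q-model panel (talent drawn once per unit, then discarded)."""
    return QModel(q).simulate(n_units, n_obs, rng)


def twin_simulate(t: TwinParams, n_units: int, n_obs: int, rng: RandomStreams) -> Panel:
    """Simulate the reinforcement twin panel by sequential conditional draws."""
    return GaussianTwin(t).simulate(n_units, n_obs, rng)


def q_joint_moments(q: QModelParams, n_obs: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form mean vector and covariance of ``(Y_1, ..., Y_n)``.

    The shared talent puts ``var_T`` in every cell of the covariance and the
    idiosyncratic luck adds ``var_X`` on the diagonal.
    """
    if n_obs < 1:
        raise ValueError(f"n_obs must be >= 1, got {n_obs}")
    mean = np.full(n_obs, q.mu_T)
    cov = np.full((n_obs, n_obs), q.var_T) + q.var_X * np.eye(n_obs)
    return mean, cov


def q_log_pdf(q: QModelParams, traj) -> float:
    """Joint log density of a trajectory under the Q-model (multivariate normal)."""
    values = traj.values if isinstance(traj, RealTrajectory) else np.asarray(
        traj, dtype=float
    )
    if values.size == 0:
        raise ValueError("trajectory must be non-empty")
    mean, cov = q_joint_moments(q, values.size)
    return float(multivariate_normal.logpdf(values, mean=mean, cov=cov))


def twin_log_pdf(t: TwinParams, traj) -> float:
    """Joint log density under the twin: chain-rule sum of conditional normals."""
    values = traj.values if isinstance(traj, RealTrajectory) else np.asarray(
        traj, dtype=float
    )
    if values.size == 0:
        raise ValueError("trajectory must be non-empty")
    n = np.arange(values.size, dtype=float)  # history length before each draw
    prior_sums = np.concatenate(([0.0], np.cumsum(values)[:-1]))
    means = (t.c * t.a + prior_sums) / (n + t.c)
    variances = t.b * (1.0 + 1.0 / (n + t.c))
    resid = values - means
    return float(np.sum(-0.5 * (_LOG_2PI + np.log(variances) + resid**2 / variances)))


def sdm_twin_step(history, v: float) -> float:
    """One step of the settled-dispositions twin recursion with innovation ``v``.

    With ``n = len(history) + 1`` the new outcome is
    ``((n-1)/n) * mean(history) + sqrt(1 + 1/n) * v``; the caller supplies the
    standard-normal innovation so the recursion is deterministic and exactly
    matches the (a, b, c) = (0, 1, 1) twin for shared innovations.
    """
    values = history.values if isinstance(history, RealTrajectory) else np.asarray(
        history, dtype=float
    )
    n = values.size + 1
    past_mean = values.mean() if values.size else 0.0
    return float((n - 1) / n * past_mean + np.sqrt(1.0 + 1.0 / n) * v)
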