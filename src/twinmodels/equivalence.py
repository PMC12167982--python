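"""Machinery for asserting statistical indistinguishability of two models.

Twin pairs in this package are equivalent in the strongest sense — equal
joint distributions over entire trajectories — and the checks here probe that
claim from three angles: exact likelihood agreement trajectory by trajectory,
agreement of per-index marginals in simulated panels, and agreement of mean
vectors and cross-time covariance matrices.  A deliberate perturbation of one
model's parameters must make the corresponding check fail; the test-suite
exercises that sensitivity so the checks cannot pass vacuously.

A :func:`mixture_model` builds the hybrid that draws each unit's entire
trajectory from model A with probability ``q`` and from B otherwise; when A
and B are twins, every hybrid shares their common law.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel import (
    BinaryTrajectory,
    EventTrajectory,
    GenerativeModel,
    Panel,
    RealTrajectory,
    Trajectory,
)

__all__ = [
    "CheckResult",
    "ComparisonReport",
    "likelihood_equality_check",
    "marginal_compare",
    "cross_moment_compare",
    "mixture_model",
    "MixtureModel",
]


@dataclass
class CheckResult:
    name: str
    statistic: float
    threshold: float
    passed: bool
    detail: str = ""


@dataclass
class ComparisonReport:
    """Named checks with statistics and thresholds; passes iff all checks do."""

    title: str
    checks: list[CheckResult] = field(default_factory=list)
    settings: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def add(self, name, statistic, threshold, passed, detail="") -> None:
        self.checks.append(
            CheckResult(name, float(statistic), float(threshold), bool(passed), detail)
        )

    def to_dict(self) -> dict:
        return {
            "title": self.title,
            "passed": self.passed,
            "settings": self.settings,
            "checks": [vars(c) for c in self.checks],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def __str__(self) -> str:
        lines = [f"# {self.title}: {'PASS' if self.passed else 'FAIL'}"]
        for c in self.checks:
            flag = "pass" if c.passed else "FAIL"
            lines.append(
                f"  [{flag}] {c.name}: stat={c.statistic:.3e} thr={c.threshold:.3e}"
                + (f" ({c.detail})" if c.detail else "")
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Checks
# ---------------------------------------------------------------------------

def likelihood_equality_check(
    model_a: GenerativeModel,
    model_b: GenerativeModel,
    trajectories: Sequence[Trajectory],
    rel_tol: float = 1e-8,
) -> ComparisonReport:
    """Maximum relative log-likelihood discrepancy across trajectories.

    For true twins the joint densities coincide, so the discrepancy is pure
    floating-point noise; a parameter mismatch shows up immediately.
    """
    if model_a.kind is not model_b.kind:
        raise TypeError(
            f"models score different kinds: {model_a.kind.__name__} vs "
            f"{model_b.kind.__name__}"
        )
    if len(trajectories) == 0:
        raise ValueError("need at least one trajectory")
    worst = 0.0
    for traj in trajectories:
        la = model_a.log_likelihood(traj)
        lb = model_b.log_likelihood(traj)
        rel = abs(la - lb) / max(1.0, abs(la), abs(lb))
        worst = max(worst, rel)
    report = ComparisonReport(
        title=f"likelihood equality: {model_a.name} vs {model_b.name}",
        settings={"n_trajectories": len(trajectories), "rel_tol": rel_tol},
    )
    report.add("max_rel_loglik_diff", worst, rel_tol, worst <= rel_tol)
    return report


def _index_samples(panel: Panel, index: int) -> np.ndarray:
    """Cross-section at 1-based observation index, units shorter than it skipped."""
    vals = [t.values[index - 1] for t in panel.trajectories() if len(t) >= index]
    return np.asarray(vals, dtype=float)


def _event_counts(panel: Panel, t: float) -> np.ndarray:
    return np.asarray(
        [np.searchsorted(traj.times, t, side="right") for traj in panel.trajectories()]
    )


def marginal_compare(
    panel_a: Panel,
    panel_b: Panel,
    indices: Sequence,
    alpha: float = 0.01,
) -> ComparisonReport:
    """Two-sample marginal tests at each index/time, Holm-adjusted.

    Real panels use the two-sample Kolmogorov–Smirnov test; binary and event
    panels compare category counts with a chi-square test (tail states with
    expected count below 5 are pooled).  Passes iff no Holm-adjusted p-value
    falls below ``alpha``.
    """
    if len(list(indices)) == 0:
        raise ValueError("need at least one index")
    if panel_a.kind is not panel_b.kind:
        raise TypeError("panels are of different kinds")
    pvals = []
    names = []
    for idx in indices:
        if panel_a.kind is EventTrajectory:
            xa, xb = _event_counts(panel_a, idx), _event_counts(panel_b, idx)
            p = _count_chi2(xa, xb)
        elif panel_a.kind is BinaryTrajectory:
            xa, xb = _index_samples(panel_a, int(idx)), _index_samples(panel_b, int(idx))
            p = _count_chi2(xa.astype(int), xb.astype(int))
        else:
            xa, xb = _index_samples(panel_a, int(idx)), _index_samples(panel_b, int(idx))
            p = stats.ks_2samp(xa, xb, method="asymp").pvalue
        pvals.append(p)
        names.append(f"index_{idx}")
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    report = ComparisonReport(
        title="marginal comparison",
        settings={
            "alpha": alpha,
            "n_units": (len(panel_a), len(panel_b)),
            "indices": [float(i) for i in indices],
        },
    )
    for name, p, rej in zip(names, p_adj, reject):
        report.add(name, p, alpha, not rej, detail="holm-adjusted p")
    return report


def _count_chi2(xa: np.ndarray, xb: np.ndarray) -> float:
    """Chi-square homogeneity test on two count samples with tail pooling."""
    top = int(max(xa.max(initial=0), xb.max(initial=0)))
    ca = np.bincount(xa, minlength=top + 1).astype(float)
    cb = np.bincount(xb, minlength=top + 1).astype(float)
    # pool sparse tail categories so expected counts stay reasonable
    while len(ca) > 2 and (ca[-1] + cb[-1]) < 10:
        ca[-2] += ca[-1]
        cb[-2] += cb[-1]
        ca, cb = ca[:-1], cb[:-1]
    keep = (ca + cb) > 0
    table = np.vstack([ca[keep], cb[keep]])
    if table.shape[1] < 2:
        return 1.0
    return float(stats.chi2_contingency(table, correction=False)[1])


def cross_moment_compare(
    panel_a: Panel,
    panel_b: Panel,
    max_lag: Optional[int] = None,
    n_se: float = 3.0,
) -> ComparisonReport:
    """Compare mean vectors and cross-time covariance matrices within n_se SEs.

    Requires rectangular real panels.  Standard errors of covariance entries
    are estimated from fourth moments; an entry fails when the two panels'
    estimates differ by more than ``n_se`` combined standard errors.
    """
    if panel_a.kind is not RealTrajectory or panel_b.kind is not RealTrajectory:
        raise TypeError("cross_moment_compare requires real-valued panels")
    xa = panel_a.values_matrix()
    xb = panel_b.values_matrix()
    if xa.shape[1] != xb.shape[1]:
        raise ValueError("panels must have equal trajectory lengths")
    n_obs = xa.shape[1]
    lag = n_obs if max_lag is None else min(max_lag + 1, n_obs)

    report = ComparisonReport(
        title="cross-moment comparison",
        settings={"n_se": n_se, "n_units": (xa.shape[0], xb.shape[0]), "n_obs": n_obs},
    )

    mean_a, mean_b = xa.mean(axis=0), xb.mean(axis=0)
    se_mean = np.sqrt(xa.var(axis=0, ddof=1) / xa.shape[0]
                      + xb.var(axis=0, ddof=1) / xb.shape[0])
    z_mean = np.abs(mean_a - mean_b) / se_mean
    report.add("mean_vector", z_mean.max(), n_se, z_mean.max() <= n_se,
               detail="max |diff| in SE units")

    def cov_and_se(x: np.ndarray):
        n = x.shape[0]
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / (n - 1)
        # Var(s_ij) ~ (E[(xi-mi)^2(xj-mj)^2] - cov_ij^2) / n
        second = (xc**2).T @ (xc**2) / n
        cross = np.einsum("ni,nj->ij", xc, xc) / n
        var_s = (second - cross**2) / n
        return cov, np.sqrt(np.maximum(var_s, 1e-300))

    cov_a, se_a = cov_and_se(xa)
    cov_b, se_b = cov_and_se(xb)
    se = np.sqrt(se_a**2 + se_b**2)
    z_cov = np.abs(cov_a - cov_b) / se
    mask = np.abs(np.subtract.outer(np.arange(n_obs), np.arange(n_obs))) < lag
    worst = z_cov[mask].max()
    report.add("cross_covariance", worst, n_se, worst <= n_se,
               detail=f"max |diff| in SE units over lags < {lag}")
    return report


# ---------------------------------------------------------------------------
# Hybrid mixture
# ---------------------------------------------------------------------------

class MixtureModel(GenerativeModel):
    """Hybrid that draws each unit's whole trajectory from A w.p. q, else B.

    The likelihood is the q-weighted mixture of the component likelihoods,
    evaluated with log-sum-exp.  Mixing two models that share one law leaves
    that law unchanged for every q.
    """

    def __init__(self, model_a: GenerativeModel, model_b: GenerativeModel, q: float):
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"q must be in [0, 1], got {q}")
        if model_a.kind is not model_b.kind:
            raise TypeError("mixture components must share a trajectory kind")
        self.model_a = model_a
        self.model_b = model_b
        self.q = float(q)
        self.kind = model_a.kind
        self.name = f"mixture({model_a.name},{model_b.name},q={q})"

    def _sample_unit(self, size, generator) -> Trajectory:
        pick_a = generator.uniform() < self.q
        model = self.model_a if pick_a else self.model_b
        return model._sample_unit(size, generator)

    def log_likelihood(self, traj: Trajectory) -> float:
        if self.q == 1.0:
            return self.model_a.log_likelihood(traj)
        if self.q == 0.0:
            return self.model_b.log_likelihood(traj)
        la = self.model_a.log_likelihood(traj) + np.log(self.q)
        lb = self.model_b.log_likelihood(traj) + np.log1p(-self.q)
        return float(np.logaddexp(la, lb))


def mixture_model(
    model_a: GenerativeModel, model_b: GenerativeModel, q: float
) -> MixtureModel:
    """Build the hybrid mixture of two generative models."""
    return MixtureModel(model_a, model_b, q)
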