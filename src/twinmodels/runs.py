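"""Permutation runs test of exchangeability for longitudinal panels.

A stationary heterogeneity model (observations conditionally i.i.d. given a
latent unit trait) necessarily produces *exchangeable* sequences: shuffling
the observations within a unit leaves the joint law unchanged.  The runs test
probes this empirically.  Each unit's real-valued record is dichotomized
against its own median (values at the median are handled by a configurable
tie policy), the number of runs — maximal blocks of consecutive equal
symbols — is summed across all units, and the same pooled statistic is
recomputed for panels in which every unit's record has been independently
reshuffled.  Under within-unit exchangeability the observed statistic is one
more draw from the permutation distribution; systematically fewer runs than
the shuffles (streakiness) is evidence against exchangeability.

The two-sided p-value is ``2 * min(x, 1 - x)`` where ``x`` is the proportion
of permuted pooled sums strictly below the observed one.  When the observed
statistic falls outside the whole permutation sample (``x`` is 0 or 1), the
result is reported as the upper bound ``2 / n_perm`` with ``p_is_bound`` set.

Units with fewer than ``min_len`` retained observations (default 3, the
minimum for shuffling to be able to change the run count) are excluded.

The companion diagnostic :func:`conditional_variance_profile` checks the
sharper prediction of the Gaussian twin pair: the variance of the next
outcome around its history-conditional mean must shrink like
``b * (1 + 1/(n + c))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .gaussian import TwinParams, twin_conditional
from .panel import (
    BinaryTrajectory,
    EventTrajectory,
    Panel,
    RandomStreams,
    RealTrajectory,
    Trajectory,
    make_rng,
)

__all__ = [
    "RunsTestResult",
    "dichotomize",
    "count_runs",
    "pooled_runs",
    "permutation_runs_test",
    "conditional_variance_profile",
]

TIE_POLICIES = ("drop", "assign-low", "assign-high")


@dataclass
class RunsTestResult:
    """Outcome of the pooled permutation runs test."""

    observed_runs: int
    n_permutations: int
    x: float  # proportion of permuted pooled sums strictly below the observed
    p_two_sided: float
    p_is_bound: bool
    n_records_used: int
    permuted_sums: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        return {
            "observed_runs": self.observed_runs,
            "n_permutations": self.n_permutations,
            "x": self.x,
            "p_two_sided": self.p_two_sided,
            "p_is_bound": self.p_is_bound,
            "n_records_used": self.n_records_used,
        }

    def __str__(self) -> str:
        p = f"p <= {self.p_two_sided:.3g}" if self.p_is_bound else f"p = {self.p_two_sided:.3g}"
        return (
            f"pooled runs = {self.observed_runs} over {self.n_records_used} records; "
            f"x = {self.x:.4f}; two-sided {p} ({self.n_permutations} permutations)"
        )


def dichotomize(
    traj: Trajectory, rule: str = "median", tie_policy: str = "drop"
) -> BinaryTrajectory:
    """Reduce a trajectory to 0/1 by comparison with its own median.

    ``rule="median"`` codes values above the unit median as 1 and below as 0;
    values exactly at the median follow ``tie_policy`` (``drop`` removes them,
    ``assign-low``/``assign-high`` codes them 0/1).  ``rule="as-is"`` passes
    already-binary data through unchanged.
    """
    if tie_policy not in TIE_POLICIES:
        raise ValueError(f"tie_policy must be one of {TIE_POLICIES}")
    if isinstance(traj, EventTrajectory):
        raise TypeError("dichotomize applies to real or binary trajectories")
    if rule == "as-is":
        if isinstance(traj, BinaryTrajectory):
            return traj
        values = np.asarray(traj.values)
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError('rule "as-is" requires 0/1 data')
        return BinaryTrajectory(values.astype(np.int8))
    if rule != "median":
        raise ValueError(f'rule must be "median" or "as-is", got {rule!r}')
    values = np.asarray(traj.values, dtype=float)
    if values.size < 1:
        raise ValueError("trajectory must have at least one observation")
    med = np.median(values)
    if tie_policy == "drop":
        keep = values != med
        return BinaryTrajectory((values[keep] > med).astype(np.int8))
    fill = 0 if tie_policy == "assign-low" else 1
    out = np.where(values > med, 1, np.where(values < med, 0, fill))
    return BinaryTrajectory(out.astype(np.int8))


def count_runs(seq) -> int:
    """Number of maximal blocks of consecutive equal symbols (0 for empty)."""
    values = seq.values if isinstance(seq, BinaryTrajectory) else np.asarray(seq)
    if values.size == 0:
        return 0
    return int(1 + np.count_nonzero(np.diff(values.astype(np.int64))))


def _retained_records(
    panel: Panel, rule: str, tie_policy: str, min_len: int
) -> list[np.ndarray]:
    records = []
    for traj in panel.trajectories():
        binary = dichotomize(traj, rule=rule, tie_policy=tie_policy)
        if len(binary) >= min_len:
            records.append(np.asarray(binary.values, dtype=np.int8))
    return records


def pooled_runs(
    panel: Panel,
    min_len: int = 3,
    rule: str = "as-is",
    tie_policy: str = "drop",
) -> int:
    """Sum of run counts over all records with at least ``min_len`` retained
    observations; shorter records cannot be affected by a shuffle and are
    excluded."""
    records = _retained_records(panel, rule, tie_policy, min_len)
    if not records:
        raise ValueError("no record survives the minimum-length filter")
    return int(sum(count_runs(r) for r in records))


def permutation_runs_test(
    panel: Panel,
    n_perm: int = 10_000,
    rng: Optional[RandomStreams] = None,
    rule: str = "median",
    tie_policy: str = "drop",
    min_len: int = 3,
    smoothed: bool = False,
    keep_permutations: bool = False,
) -> RunsTestResult:
    """Pooled runs test against the within-unit permutation null.

    Binary panels should use ``rule="as-is"``; real panels are dichotomized
    at the unit median first.  Each of the ``n_perm`` permuted datasets
    independently reshuffles every retained record (one substream per unit,
    vectorized across permutations).  ``smoothed=True`` uses the add-one
    estimate ``x = (#below + 1) / (n_perm + 1)`` instead of the plain
    proportion.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if rng is None:
        rng = make_rng(0)
    records = _retained_records(panel, rule, tie_policy, min_len)
    if not records:
        raise ValueError("no record survives the minimum-length filter")
    observed = int(sum(count_runs(r) for r in records))

    sums = np.zeros(n_perm, dtype=np.int64)
    for i, rec in enumerate(records):
        gen = rng.substream("runs-perm", i).generator()
        keys = gen.random((n_perm, rec.size))
        order = np.argsort(keys, axis=1, kind="stable")
        shuffled = rec[order]
        sums += 1 + np.count_nonzero(np.diff(shuffled, axis=1), axis=1)

    below = int(np.count_nonzero(sums < observed))
    x = (below + 1) / (n_perm + 1) if smoothed else below / n_perm
    p_is_bound = False
    p = 2.0 * min(x, 1.0 - x)
    if x == 0.0 or x == 1.0:
        p = 2.0 / n_perm
        p_is_bound = True
    p = float(min(max(p, np.nextafter(0.0, 1.0)), 1.0))
    return RunsTestResult(
        observed_runs=observed,
        n_permutations=n_perm,
        x=float(x),
        p_two_sided=p,
        p_is_bound=p_is_bound,
        n_records_used=len(records),
        permuted_sums=sums if keep_permutations else None,
    )


def conditional_variance_profile(
    panel: Panel, t: TwinParams, min_units: int = 2
) -> pd.DataFrame:
    """Residual variance of ``Y_{n+1}`` around the twin conditional mean, by n.

    For each history length ``n`` the sample variance across units of
    ``Y_{n+1} - mu_{n+1}(history; t)`` is tabulated next to the predicted
    ``b * (1 + 1/(n + c))``.  A flat empirical profile against a falling
    prediction is the diagnostic signature that the twin's (equivalently the
    latent-trait model's) variance schedule does not hold in the data.
    Lengths with fewer than ``min_units`` available units are skipped with a
    warning.
    """
    if panel.kind is not RealTrajectory:
        raise TypeError("conditional_variance_profile requires a real-valued panel")
    max_len = max((len(tr) for tr in panel.trajectories()), default=0)
    rows = []
    for n in range(max_len):  # history length; predicts observation n+1
        residuals = []
        for traj in panel.trajectories():
            if len(traj) >= n + 1:
                mean, _ = twin_conditional(t, traj.values[:n])
                residuals.append(traj.values[n] - mean)
        if len(residuals) < min_units:
            warnings.warn(
                f"history length {n}: only {len(residuals)} unit(s); skipped",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "n": n,
                "n_units": len(residuals),
                "residual_variance": float(np.var(residuals, ddof=1)),
                "predicted_variance": t.b * (1.0 + 1.0 / (n + t.c)),
            }
        )
    return pd.DataFrame(rows, columns=["n", "n_units", "residual_variance", "predicted_variance"])
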