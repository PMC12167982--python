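"""CSV readers/writers for panels and the built-in scenario fixture generator.

The on-disk exchange format is long (tidy) CSV, UTF-8, comma-separated, with
a header and '.' decimal:

* value panels: ``unit_id[,item_id],index,value`` with 1-based integer
  ``index`` unique per (unit, item);
* event panels: ``unit_id[,item_id],event_time[,horizon]`` with strictly
  increasing positive event times per unit and a per-unit ``horizon`` column
  (or a horizon supplied by the caller).

Wide-format files are rejected: ragged panels and multi-item survey data only
fit the long form.  Raw positive counts (e.g. citations) can be log-mapped on
read with ``log_transform=True`` — zeros are an error rather than silently
shifted, because the models are defined on exact logs and a pseudo-count
would change the law.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import binary, contact, gaussian
from .equivalence import mixture_model
from .panel import (
    BinaryTrajectory,
    EventTrajectory,
    Panel,
    RealTrajectory,
    make_rng,
)

__all__ = ["read_panel", "write_panel", "generate_fixtures", "PanelFormatError", "SCENARIOS"]


class PanelFormatError(ValueError):
    """Raised for malformed panel files (missing columns, duplicates, ...)."""


def _key_of(row_unit, row_item) -> tuple:
    item = None if row_item is None or (isinstance(row_item, float) and np.isnan(row_item)) else str(row_item)
    return (str(row_unit), item)


def read_panel(
    path: Union[str, Path],
    kind: str = "auto",
    log_transform: bool = False,
    horizon: Optional[float] = None,
) -> Panel:
    """Read a long-format CSV panel.

    ``kind`` is ``"auto"`` (inferred from columns/values), ``"real"``,
    ``"binary"`` or ``"event"``.  For event files without a ``horizon``
    column, pass a global ``horizon``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "unit_id" not in df.columns:
        raise PanelFormatError(f"{path}: missing required column 'unit_id'")
    has_item = "item_id" in df.columns
    if "event_time" in df.columns:
        return _read_event_panel(df, path, has_item, horizon)
    if "index" not in df.columns or "value" not in df.columns:
        raise PanelFormatError(
            f"{path}: need columns (index, value) for value panels or "
            "event_time for event panels; wide-format files are not accepted "
            "(see the docs for the long-format converter)"
        )
    return _read_value_panel(df, path, has_item, kind, log_transform)


def _read_value_panel(df, path, has_item, kind, log_transform) -> Panel:
    records = {}
    group_cols = ["unit_id", "item_id"] if has_item else ["unit_id"]
    dup_cols = group_cols + ["index"]
    dup = df.duplicated(subset=dup_cols)
    if dup.any():
        offending = df.loc[dup, dup_cols].iloc[0].tolist()
        raise PanelFormatError(f"{path}: duplicate key {tuple(offending)}")
    for key_vals, grp in df.groupby(group_cols, sort=True, dropna=False):
        if not has_item:
            key_vals = (key_vals if not isinstance(key_vals, tuple) else key_vals[0], None)
        key = _key_of(key_vals[0], key_vals[1] if len(key_vals) > 1 else None)
        grp = grp.sort_values("index")
        idx = grp["index"].to_numpy()
        if not np.issubdtype(idx.dtype, np.number) or np.any(idx != np.round(idx)) or idx.min() < 1:
            raise PanelFormatError(f"{path}: indices must be integers >= 1 for {key}")
        values = grp["value"].to_numpy(dtype=float)
        if log_transform:
            if np.any(values <= 0):
                raise PanelFormatError(
                    f"{path}: log transform requires strictly positive values ({key})"
                )
            values = np.log(values)
        records[key] = values
    use_binary = kind == "binary" or (
        kind == "auto"
        and not log_transform
        and all(np.isin(v, (0.0, 1.0)).all() for v in records.values())
    )
    cls = BinaryTrajectory if use_binary else RealTrajectory
    return Panel({k: cls(v) for k, v in records.items()})


def _read_event_panel(df, path, has_item, horizon) -> Panel:
    records = {}
    group_cols = ["unit_id", "item_id"] if has_item else ["unit_id"]
    has_horizon = "horizon" in df.columns
    if not has_horizon and horizon is None:
        raise PanelFormatError(
            f"{path}: event panel needs a 'horizon' column or an explicit horizon"
        )
    for key_vals, grp in df.groupby(group_cols, sort=True, dropna=False):
        if not has_item:
            key_vals = (key_vals if not isinstance(key_vals, tuple) else key_vals[0], None)
        key = _key_of(key_vals[0], key_vals[1] if len(key_vals) > 1 else None)
        times = np.sort(grp["event_time"].to_numpy(dtype=float))
        # empty-record marker: a single NaN event time means "no events"
        times = times[~np.isnan(times)]
        if np.any(np.diff(times) <= 0):
            raise PanelFormatError(f"{path}: duplicate event times for {key}")
        h = float(grp["horizon"].iloc[0]) if has_horizon else float(horizon)
        try:
            records[key] = EventTrajectory(times, h)
        except ValueError as exc:
            raise PanelFormatError(f"{path}: {key}: {exc}") from exc
    return Panel(records)


def write_panel(panel: Panel, path: Union[str, Path]) -> None:
    """Write a panel as long CSV with deterministic (unit, item, index) order."""
    path = Path(path)
    keys = sorted(panel, key=lambda k: (k[0], k[1] or ""))
    has_item = any(k[1] is not None for k in keys)
    rows = []
    if panel.kind is EventTrajectory:
        for unit, item in keys:
            traj = panel[(unit, item)]
            base = {"unit_id": unit, **({"item_id": item} if has_item else {})}
            if len(traj) == 0:
                rows.append({**base, "event_time": np.nan, "horizon": traj.horizon})
            for t in traj.times:
                rows.append({**base, "event_time": t, "horizon": traj.horizon})
        columns = (["unit_id"] + (["item_id"] if has_item else [])
                   + ["event_time", "horizon"])
    else:
        is_binary = panel.kind is BinaryTrajectory
        for unit, item in keys:
            traj = panel[(unit, item)]
            for n, v in enumerate(traj.values, start=1):
                rows.append(
                    {
                        "unit_id": unit,
                        **({"item_id": item} if has_item else {}),
                        "index": n,
                        "value": int(v) if is_binary else float(v),
                    }
                )
        columns = (["unit_id"] + (["item_id"] if has_item else []) + ["index", "value"])
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scenario fixtures
# ---------------------------------------------------------------------------

#: Default simulation scenarios.  The Gaussian pair uses the citation-model
#: parameters (mu_T=0, var_T=0.2, var_X=1) over 30 units x 10 observations;
#: the settled-dispositions pair is the unit-variance special case over 10
#: units; the contact pair uses (alpha=1, pi_0=0.25, pi_j=0.25*j^0.5) over 30
#: units to horizon 10.
SCENARIOS = (
    "polya",
    "mixture",
    "q_model",
    "q_twin",
    "sdm",
    "sdm_twin",
    "snm",
    "snm_twin",
    "hybrid",
)

_FIG_Q = gaussian.QModelParams(mu_T=0.0, var_T=0.2, var_X=1.0)
_SDM_Q = gaussian.QModelParams(mu_T=0.0, var_T=1.0, var_X=1.0)


def generate_fixtures(
    scenario: str,
    seed: int,
    n_units: Optional[int] = None,
    length: Optional[float] = None,
    q: float = 0.5,
) -> tuple[Panel, dict]:
    """Simulate a named scenario and return ``(panel, parameter_record)``.

    ``length`` is a number of observations for discrete scenarios and a time
    horizon for the event scenarios.  ``q`` is the mixing weight of the
    ``hybrid`` scenario (Q-model with probability q, its twin otherwise).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    rng = make_rng(seed)
    twin = gaussian.map_q_to_twin(_FIG_Q)
    sdm_twin = gaussian.map_q_to_twin(_SDM_Q)
    contact_params = contact.ContactParams()  # alpha=1, pi0=0.25, 0.25*j^0.5

    if scenario in ("polya", "mixture"):
        n_units = 30 if n_units is None else n_units
        n_draws = 10 if length is None else int(length)
        sim = binary.polya_simulate if scenario == "polya" else binary.mixture_simulate
        panel = sim(n_draws, n_units, rng)
        params = {"n_draws": n_draws}
    elif scenario in ("q_model", "q_twin", "hybrid"):
        n_units = 30 if n_units is None else n_units
        n_obs = 10 if length is None else int(length)
        if scenario == "q_model":
            panel = gaussian.q_simulate(_FIG_Q, n_units, n_obs, rng)
        elif scenario == "q_twin":
            panel = gaussian.twin_simulate(twin, n_units, n_obs, rng)
        else:
            hybrid = mixture_model(
                gaussian.QModel(_FIG_Q), gaussian.GaussianTwin(twin), q
            )
            panel = hybrid.simulate(n_units, n_obs, rng)
        params = {
            "mu_T": _FIG_Q.mu_T, "var_T": _FIG_Q.var_T, "var_X": _FIG_Q.var_X,
            "a": twin.a, "b": twin.b, "c": twin.c, "n_obs": n_obs,
            **({"q": q} if scenario == "hybrid" else {}),
        }
    elif scenario in ("sdm", "sdm_twin"):
        n_units = 10 if n_units is None else n_units
        n_obs = 10 if length is None else int(length)
        if scenario == "sdm":
            panel = gaussian.q_simulate(_SDM_Q, n_units, n_obs, rng)
        else:
            panel = gaussian.twin_simulate(sdm_twin, n_units, n_obs, rng)
        params = {"mu_T": 0.0, "var_T": 1.0, "var_X": 1.0, "n_obs": n_obs}
    else:  # snm, snm_twin
        n_units = 30 if n_units is None else n_units
        horizon = 10.0 if length is None else float(length)
        sim = contact.snm_simulate if scenario == "snm" else contact.twin_simulate
        panel = sim(contact_params, horizon, n_units, rng)
        params = {"alpha": 1.0, "pi0": 0.25, "scale": 0.25, "rho": 0.5,
                  "horizon": horizon}
    record = {"scenario": scenario, "seed": seed, "n_units": n_units, **params}
    return panel, record
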