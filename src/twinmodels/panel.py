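"""Core containers for longitudinal panel data and the generative-model contract.

A *trajectory* is the ordered record of one unit of observation (a person, a
paper, a song): binary draws, real-valued (log-scale) outcomes, or event times
of a counting process observed on ``(0, horizon]``.  A :class:`Panel` is a
ragged collection of trajectories keyed by unit id (and an optional item id,
for multi-item surveys where each unit answers several items over time).

Observation indices are 1-based (``n = 1, 2, ...``); continuous time starts at
0.  Trajectories carry values only — model parameters live outside the panel,
so one panel can be scored under several competing models.

Randomness follows a seed-plus-named-substreams contract
(:class:`RandomStreams`): every simulator derives one substream per unit, so a
panel is bit-reproducible from its seed regardless of the order in which units
are generated.  No global random state is touched anywhere.
"""

from __future__ import annotations

import hashlib
from abc import ABC, abstractmethod
from collections.abc import Iterator, Mapping
from typing import Union

import numpy as np

__all__ = [
    "BinaryTrajectory",
    "RealTrajectory",
    "EventTrajectory",
    "Trajectory",
    "Panel",
    "GenerativeModel",
    "RandomStreams",
    "make_rng",
    "panels_allclose",
]


# ---------------------------------------------------------------------------
# Randomness contract
# ---------------------------------------------------------------------------

def _key_to_int(key: Union[int, str]) -> int:
    """Map a substream key to a non-negative integer, stably across runs."""
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError(f"substream keys must be non-negative, got {key}")
        return int(key)
    if isinstance(key, str):
        digest = hashlib.sha256(key.encode("utf-8")).digest()[:8]
        return int.from_bytes(digest, "big")
    raise TypeError(f"substream key must be int or str, got {type(key).__name__}")


class RandomStreams:
    """A seeded stream of randomness with deterministic named substreams.

    Two instances built from the same seed and the same chain of
    ``substream`` keys yield bit-identical :class:`numpy.random.Generator`
    output; substreams with different keys are statistically independent
    (distinct ``SeedSequence`` spawn keys).
    """

    __slots__ = ("_seed_sequence",)

    def __init__(self, seed_sequence: np.random.SeedSequence):
        self._seed_sequence = seed_sequence

    @classmethod
    def from_seed(cls, seed: int) -> "RandomStreams":
        if not isinstance(seed, (int, np.integer)) or seed < 0:
            raise ValueError(f"seed must be a non-negative integer, got {seed!r}")
        return cls(np.random.SeedSequence(int(seed)))

    def substream(self, *keys: Union[int, str]) -> "RandomStreams":
        """Derive an independent child stream identified by ``keys``."""
        spawn = tuple(self._seed_sequence.spawn_key) + tuple(
            _key_to_int(k) for k in keys
        )
        child = np.random.SeedSequence(
            entropy=self._seed_sequence.entropy, spawn_key=spawn
        )
        return RandomStreams(child)

    def generator(self) -> np.random.Generator:
        """A fresh generator at the start of this stream (deterministic)."""
        return np.random.default_rng(self._seed_sequence)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        ss = self._seed_sequence
        return f"RandomStreams(entropy={ss.entropy}, spawn_key={ss.spawn_key})"


def make_rng(seed: int) -> RandomStreams:
    """Create the root :class:`RandomStreams` for a simulation run."""
    return RandomStreams.from_seed(seed)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

class BinaryTrajectory:
    """An ordered sequence of 0/1 outcomes, indexed n = 1, 2, ..."""

    __slots__ = ("values",)

    def __init__(self, values):
        arr = np.asarray(values)
        if arr.ndim != 1:
            raise ValueError("trajectory values must be one-dimensional")
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("binary trajectory entries must be 0 or 1")
        self.values = arr.astype(np.int8)
        self.values.flags.writeable = False

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, BinaryTrajectory) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):
        return hash(self.values.tobytes())

    def __repr__(self) -> str:
        return f"BinaryTrajectory({self.values.tolist()!r})"


class RealTrajectory:
    """An ordered sequence of finite real outcomes (e.g. log citation counts)."""

    __slots__ = ("values",)

    def __init__(self, values):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("trajectory values must be one-dimensional")
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("real trajectory entries must be finite")
        self.values = arr
        self.values.flags.writeable = False

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, RealTrajectory) and np.array_equal(
            self.values, other.values
        )

    def __repr__(self) -> str:
        return f"RealTrajectory({self.values.tolist()!r})"


class EventTrajectory:
    """Strictly increasing event times in ``(0, horizon]`` of a counting process."""

    __slots__ = ("times", "horizon")

    def __init__(self, times, horizon: float):
        arr = np.asarray(times, dtype=float)
        horizon = float(horizon)
        if arr.ndim != 1:
            raise ValueError("event times must be one-dimensional")
        if not horizon > 0:
            raise ValueError(f"horizon must be positive, got {horizon}")
        if arr.size:
            if not np.isfinite(arr).all():
                raise ValueError("event times must be finite")
            if arr[0] <= 0:
                raise ValueError("event times must be strictly positive")
            if np.any(np.diff(arr) <= 0):
                raise ValueError("event times must be strictly increasing (no ties)")
            if arr[-1] > horizon:
                raise ValueError("event times must not exceed the horizon")
        self.times = arr
        self.times.flags.writeable = False
        self.horizon = horizon

    def __len__(self) -> int:
        return self.times.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EventTrajectory)
            and self.horizon == other.horizon
            and np.array_equal(self.times, other.times)
        )

    def __repr__(self) -> str:
        return f"EventTrajectory({self.times.tolist()!r}, horizon={self.horizon})"


Trajectory = Union[BinaryTrajectory, RealTrajectory, EventTrajectory]

_KINDS = (BinaryTrajectory, RealTrajectory, EventTrajectory)


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

def _normalize_key(key):
    if isinstance(key, tuple):
        if len(key) != 2:
            raise ValueError(f"panel keys are (unit_id, item_id), got {key!r}")
        unit, item = key
        return str(unit), (None if item is None else str(item))
    return str(key), None


class Panel(Mapping):
    """A ragged collection of same-kind trajectories keyed by (unit, item).

    Keys are ``(unit_id, item_id)`` pairs; a bare unit id is accepted and
    stored as ``(unit_id, None)``.  Ragged lengths are allowed; all
    trajectories must be of one kind (binary, real, or event).
    """

    __slots__ = ("_records", "_kind")

    def __init__(self, records: Mapping):
        normalized = {}
        kind = None
        for key, traj in records.items():
            nkey = _normalize_key(key)
            if nkey in normalized:
                raise ValueError(f"duplicate panel key {nkey!r}")
            if not isinstance(traj, _KINDS):
                raise TypeError(
                    f"panel values must be trajectories, got {type(traj).__name__}"
                )
            if kind is None:
                kind = type(traj)
            elif type(traj) is not kind:
                raise TypeError(
                    "all trajectories in a panel must be of the same kind "
                    f"({kind.__name__} vs {type(traj).__name__})"
                )
            normalized[nkey] = traj
        self._records = normalized
        self._kind = kind

    # Mapping interface ----------------------------------------------------
    def __getitem__(self, key) -> Trajectory:
        return self._records[_normalize_key(key)]

    def __iter__(self) -> Iterator:
        return iter(self._records)

    def __len__(self) -> int:
        return len(self._records)

    # Conveniences ---------------------------------------------------------
    @property
    def kind(self):
        """Trajectory class shared by all records (None for an empty panel)."""
        return self._kind

    def trajectories(self):
        return list(self._records.values())

    def values_matrix(self) -> np.ndarray:
        """Stack a rectangular real/binary panel into an (n_units, n_obs) array."""
        if self._kind is EventTrajectory:
            raise TypeError("values_matrix is undefined for event panels")
        lengths = {len(t) for t in self._records.values()}
        if len(lengths) > 1:
            raise ValueError("panel is ragged; values_matrix needs equal lengths")
        return np.array([t.values for t in self._records.values()], dtype=float)

    def __repr__(self) -> str:
        kind = self._kind.__name__ if self._kind else "empty"
        return f"Panel({len(self)} records, kind={kind})"


def panels_allclose(a: Panel, b: Panel, atol: float = 1e-12) -> bool:
    """True when two panels have equal keys and numerically equal trajectories."""
    if set(a) != set(b):
        return False
    if a.kind is not b.kind:
        return False
    for key in a:
        ta, tb = a[key], b[key]
        if isinstance(ta, EventTrajectory):
            if len(ta) != len(tb) or abs(ta.horizon - tb.horizon) > atol:
                return False
            if not np.allclose(ta.times, tb.times, atol=atol, rtol=0):
                return False
        else:
            if len(ta) != len(tb):
                return False
            if not np.allclose(ta.values, tb.values, atol=atol, rtol=0):
                return False
    return True


# ---------------------------------------------------------------------------
# Generative model contract
# ---------------------------------------------------------------------------

class GenerativeModel(ABC):
    """Abstract contract shared by all simulators in this package.

    Concrete models fall into three families: *heterogeneity* models draw a
    latent unit trait once and then conditionally i.i.d. observations;
    *reinforcement* models make each observation a function of the unit's own
    past observations plus fresh noise; *mixed* models combine both.  All
    latent draws (the trait, the innovations) are internal to ``simulate`` and
    are never exposed — only the observable trajectory is returned.

    ``simulate`` must be reproducible given a :class:`RandomStreams`;
    ``log_likelihood`` must be finite on any trajectory the model assigns
    positive density/probability.
    """

    #: short identifier used in reports and the CLI
    name: str = "abstract"
    #: trajectory class produced/scored by this model
    kind: type = RealTrajectory

    @abstractmethod
    def _sample_unit(self, size, generator: np.random.Generator) -> Trajectory:
        """Draw one unit's trajectory. ``size`` is a length or a horizon."""

    @abstractmethod
    def log_likelihood(self, traj: Trajectory) -> float:
        """Exact log probability / log density of one trajectory."""

    def simulate(self, n_units: int, size, rng: RandomStreams) -> Panel:
        """Simulate a panel of ``n_units`` trajectories.

        Each unit uses its own substream ``rng.substream("unit", i)``, so the
        output is independent of the order in which units are generated.
        """
        if n_units < 1:
            raise ValueError(f"n_units must be >= 1, got {n_units}")
        records = {}
        for i in range(n_units):
            gen = rng.substream("unit", i).generator()
            records[f"u{i:06d}"] = self._sample_unit(size, gen)
        return Panel(records)

    def log_likelihood_panel(self, panel: Panel) -> float:
        """Sum of per-trajectory log likelihoods (units are independent)."""
        return float(sum(self.log_likelihood(t) for t in panel.trajectories()))
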