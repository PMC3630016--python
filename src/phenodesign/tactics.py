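"""Plant-relocation tactics on the conveyor system.

Four tactics are modelled, each applied to 72 plants that start in a band of
3 lanes x 24 positions:

* ``bench`` and ``same_lane`` -- plants keep their cell for the whole run.
* ``half_lane`` -- after each imaging, the 12 carts in the western half of a
  lane move to the eastern half of the same lane and the 12 carts in the
  eastern half move to the western half of the next lane; from the eastern
  half of the last cycle lane they return to the western half of the first.
  The cycle spans lanes 4-11 (16 half-lane slots) and within-group east-west
  order is preserved (p -> p+12 within a lane, p -> p-12 into the next).
* ``next_lane`` -- plants advance one whole lane per move, position
  unchanged, cycling over lanes 12-24 (from lane 24 back to lane 12).

Schedules use absolute Smarthouse lane numbers, so a field surface used with
a moving tactic must cover the tactic's cycle lanes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .field import FieldSurface, UniformityData
from .layout import GridLayout

TACTIC_NAMES = ("bench", "same_lane", "half_lane", "next_lane")

#: Default home lanes (start band) and cycle lanes per tactic.
_DEFAULTS = {
    "bench": ((1, 3), (1, 3)),
    "same_lane": ((1, 3), (1, 3)),
    "half_lane": ((4, 6), (4, 11)),
    "next_lane": ((12, 14), (12, 24)),
}


@dataclass(frozen=True)
class Tactic:
    name: str
    home_lanes: tuple[int, int] = None  # type: ignore[assignment]
    cycle_lanes: tuple[int, int] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.name not in TACTIC_NAMES:
            raise ValueError(f"tactic must be one of {TACTIC_NAMES}")
        home, cycle = _DEFAULTS[self.name]
        if self.home_lanes is None:
            object.__setattr__(self, "home_lanes", home)
        if self.cycle_lanes is None:
            object.__setattr__(
                self, "cycle_lanes", cycle if self.moves else tuple(self.home_lanes)
            )
        h0, h1 = self.home_lanes
        c0, c1 = self.cycle_lanes
        if not (c0 <= h0 <= h1 <= c1):
            raise ValueError("home_lanes must lie within cycle_lanes")
        if not self.moves and tuple(self.cycle_lanes) != tuple(self.home_lanes):
            raise ValueError(f"{self.name} must have cycle_lanes == home_lanes")

    @property
    def moves(self) -> bool:
        return self.name in ("half_lane", "next_lane")


@dataclass(frozen=True)
class Schedule:
    """Per-plant, per-time-point cell occupancy.

    lanes/positions have shape (n_plants, n_timepoints); plant i starts at
    (lanes[i, 0], positions[i, 0]).
    """

    tactic: Tactic
    lanes: np.ndarray
    positions: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lanes = np.asarray(self.lanes, dtype=int)
        positions = np.asarray(self.positions, dtype=int)
        if lanes.shape != positions.shape or lanes.ndim != 2:
            raise ValueError("lanes and positions must share shape (n_plants, n_timepoints)")
        object.__setattr__(self, "lanes", lanes)
        object.__setattr__(self, "positions", positions)

    @property
    def n_plants(self) -> int:
        return self.lanes.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.lanes.shape[1]

    def occupancy_injective(self) -> bool:
        """True when no two plants share a cell at any time point."""
        for t in range(self.n_timepoints):
            cells = set(zip(self.lanes[:, t], self.positions[:, t]))
            if len(cells) != self.n_plants:
                return False
        return True

    def to_frame(self) -> pd.DataFrame:
        n, t = self.lanes.shape
        return pd.DataFrame(
            {
                "plant": np.repeat(np.arange(1, n + 1), t),
                "timepoint": np.tile(np.arange(1, t + 1), n),
                "lane": self.lanes.ravel(),
                "position": self.positions.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _half_lane_step(lane: np.ndarray, pos: np.ndarray, c0: int, c1: int):
    """One half-lane move, order-preserving within each group of 12."""
    west = pos <= 12
    new_lane = np.where(west, lane, np.where(lane == c1, c0, lane + 1))
    new_pos = np.where(west, pos + 12, pos - 12)
    return new_lane, new_pos


def _next_lane_step(lane: np.ndarray, pos: np.ndarray, c0: int, c1: int):
    return np.where(lane == c1, c0, lane + 1), pos


def build_schedule(tactic: Tactic, layout: GridLayout, n_timepoints: int = 14) -> Schedule:
    """Enumerate every plant's cell at every time point.

    The 72 plants start in the tactic's home band of 3 lanes x 24 positions
    (requires ``layout.n_positions == 24`` for the moving tactics, whose
    half-lane groups are groups of 12).
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    h0, h1 = tactic.home_lanes
    n_home_lanes = h1 - h0 + 1
    if n_home_lanes != 3 or layout.n_positions != 24:
        raise ValueError(
            "tactic schedules are defined for a start band of 3 lanes x 24 positions"
        )
    if h1 > layout.n_lanes or tactic.cycle_lanes[1] > layout.n_lanes:
        raise ValueError("tactic lanes exceed the layout")
    lane0 = np.repeat(np.arange(h0, h1 + 1), layout.n_positions)
    pos0 = np.tile(np.arange(1, layout.n_positions + 1), n_home_lanes)
    n_plants = lane0.size
    lanes = np.empty((n_plants, n_timepoints), dtype=int)
    positions = np.empty_like(lanes)
    lanes[:, 0], positions[:, 0] = lane0, pos0
    c0, c1 = tactic.cycle_lanes
    step = {"half_lane": _half_lane_step, "next_lane": _next_lane_step}.get(tactic.name)
    for t in range(1, n_timepoints):
        if step is None:
            lanes[:, t], positions[:, t] = lanes[:, t - 1], positions[:, t - 1]
        else:
            lanes[:, t], positions[:, t] = step(lanes[:, t - 1], positions[:, t - 1], c0, c1)
    return Schedule(
        tactic=tactic,
        lanes=lanes,
        positions=positions,
        metadata={"n_timepoints": n_timepoints},
    )


def exposure_matrix(schedule: Schedule, partition: str = "lane") -> pd.DataFrame:
    """Time points each plant spends in each part of a partition.

    partition is 'cell', 'lane' or 'half' (west/east).  Rows are plants,
    columns parts; every row sums to n_timepoints.
    """
    if partition == "cell":
        labels = [
            [(l, p) for l, p in zip(schedule.lanes[i], schedule.positions[i])]
            for i in range(schedule.n_plants)
        ]
    elif partition == "lane":
        labels = schedule.lanes.tolist()
    elif partition == "half":
        labels = np.where(schedule.positions <= 12, "west", "east").tolist()
    else:
        raise ValueError("partition must be 'cell', 'lane' or 'half'")
    rows = [pd.Series(row).value_counts() for row in labels]
    out = pd.DataFrame(rows).fillna(0).astype(int)
    out.index = pd.RangeIndex(1, schedule.n_plants + 1, name="plant")
    return out.sort_index(axis=1)


def shaded_exposure(schedule: Schedule, shaded_lanes) -> np.ndarray:
    """Number of time points each plant spends in a shaded lane."""
    shaded = np.isin(schedule.lanes, sorted(set(shaded_lanes)))
    return shaded.sum(axis=1)


@dataclass(frozen=True)
class GrowthParams:
    """Log-scale multiplicative growth.

    Each of the n_timepoints - 1 intervals between imagings adds
    ``rate * m(cell)`` to log-area, where m(cell) is the occupied cell's
    expectation divided by the surface's overall mean (the relative
    microclimate multiplier), plus Gaussian log-noise with sd ``log_sd``.
    """

    baseline_rate: float = 0.18
    initial_value: float = 7.0
    log_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline growth rate must be nonnegative")
        if self.initial_value <= 0:
            raise ValueError("initial value must be positive")


def simulate_tactic_response(
    schedule: Schedule,
    field_surface: FieldSurface,
    growth: GrowthParams,
    seed: int | None = None,
) -> tuple[pd.DataFrame, UniformityData]:
    """Grow plants along a schedule over a microclimate surface.

    Returns the full trajectory table (plant, timepoint, value) and the
    final values arranged as UniformityData on the home band's 3x24 grid.
    Fixed seed => bit-identical output.
    """
    lay = field_surface.layout
    if schedule.lanes.max() > lay.n_lanes or schedule.positions.max() > lay.n_positions:
        raise ValueError("schedule leaves the field surface's layout")
    rng = np.random.default_rng(growth.seed if seed is None else seed)
    mult = field_surface.expectation / field_surface.expectation.mean()
    n, nt = schedule.n_plants, schedule.n_timepoints
    log_area = np.full(n, np.log(growth.initial_value))
    traj = np.empty((n, nt))
    traj[:, 0] = np.exp(log_area)
    for t in range(1, nt):
        # increment accrues in the cell occupied since the previous imaging
        m = mult[schedule.lanes[:, t - 1] - 1, schedule.positions[:, t - 1] - 1]
        log_area = log_area + growth.baseline_rate * m
        if growth.log_sd > 0:
            log_area = log_area + rng.normal(0.0, growth.log_sd, size=n)
        traj[:, t] = np.exp(log_area)
    frame = pd.DataFrame(
        {
            "plant": np.repeat(np.arange(1, n + 1), nt),
            "timepoint": np.tile(np.arange(1, nt + 1), n),
            "value": traj.ravel(),
        }
    )
    h0, h1 = schedule.tactic.home_lanes
    home_layout = GridLayout(n_lanes=h1 - h0 + 1, n_positions=24)
    final = traj[:, -1].reshape(home_layout.n_lanes, home_layout.n_positions)
    data = UniformityData(
        layout=home_layout,
        values=final,
        metadata={"tactic": schedule.tactic.name, "n_timepoints": nt},
    )
    return frame, data
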