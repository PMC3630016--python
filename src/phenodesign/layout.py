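"""Geometry of a conveyor greenhouse zone.

A Smarthouse is a grid of carts addressed by (lane, position): lanes are
numbered 1..n_lanes from south to north, positions 1..n_positions from west
to east.  A *zone* is a contiguous band of lanes; the *side split* divides
positions into a western and an eastern half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridLayout:
    """Lanes-by-positions grid with zone and side partitions.

    Parameters
    ----------
    n_lanes, n_positions
        Grid dimensions.  The default zone is the 3 lanes x 24 positions
        (72 carts) band used throughout the design comparisons.
    zone_bounds
        Ordered list of inclusive (first_lane, last_lane) ranges.  They must
        be disjoint, contiguous and cover 1..n_lanes.
    side_split
        Position index ending the western half; defaults to n_positions // 2.
    """

    n_lanes: int = 3
    n_positions: int = 24
    zone_bounds: tuple[tuple[int, int], ...] = field(default=None)  # type: ignore[assignment]
    side_split: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_lanes < 1 or self.n_positions < 1:
            raise ValueError("grid dimensions must be positive")
        if self.zone_bounds is None:
            object.__setattr__(self, "zone_bounds", ((1, self.n_lanes),))
        else:
            object.__setattr__(self, "zone_bounds", tuple(tuple(b) for b in self.zone_bounds))
        if self.side_split is None:
            object.__setattr__(self, "side_split", self.n_positions // 2)
        self._validate_zones()
        if not (1 <= self.side_split <= self.n_positions):
            raise ValueError("side_split outside 1..n_positions")

    def _validate_zones(self) -> None:
        expected = 1
        for lo, hi in self.zone_bounds:
            if lo != expected or hi < lo:
                raise ValueError(
                    "zone_bounds must be disjoint, contiguous and cover "
                    f"1..{self.n_lanes}; got {self.zone_bounds}"
                )
            expected = hi + 1
        if expected != self.n_lanes + 1:
            raise ValueError(f"zone_bounds do not cover 1..{self.n_lanes}")

    # -- derived quantities ------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.n_lanes * self.n_positions

    @property
    def n_zones(self) -> int:
        return len(self.zone_bounds)

    @property
    def lanes(self) -> np.ndarray:
        """Lane index of every cell, shape (n_lanes, n_positions)."""
        return np.repeat(np.arange(1, self.n_lanes + 1), self.n_positions).reshape(
            self.n_lanes, self.n_positions
        )

    @property
    def positions(self) -> np.ndarray:
        """Position index of every cell, shape (n_lanes, n_positions)."""
        return np.tile(np.arange(1, self.n_positions + 1), (self.n_lanes, 1))

    def zone_of_lane(self, lane: int) -> int:
        """1-based zone index containing ``lane``."""
        for z, (lo, hi) in enumerate(self.zone_bounds, start=1):
            if lo <= lane <= hi:
                return z
        raise ValueError(f"lane {lane} outside 1..{self.n_lanes}")

    @property
    def zones(self) -> np.ndarray:
        """Zone index of every cell, shape (n_lanes, n_positions)."""
        per_lane = np.array([self.zone_of_lane(l) for l in range(1, self.n_lanes + 1)])
        return np.repeat(per_lane, self.n_positions).reshape(self.n_lanes, self.n_positions)

    @property
    def sides(self) -> np.ndarray:
        """1 for the western half (positions <= side_split), 2 for the eastern."""
        return np.where(self.positions <= self.side_split, 1, 2)

    def centered_positions(self) -> np.ndarray:
        """Linear position scores centered on the whole layout."""
        return self.positions - (self.n_positions + 1) / 2.0


DEFAULT_ZONE_LAYOUT = GridLayout(n_lanes=3, n_positions=24)
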