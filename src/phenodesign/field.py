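"""Synthetic uniformity-trial data for a conveyor greenhouse zone.

A uniformity trial observes a response (here: total projected plant area on
the final imaging day, in thousands of pixels) on every cart of a zone with
no treatments applied.  The generator reproduces the variance structure seen
in such facilities: a west->east linear position trend, additive lane
effects with optional multiplicative shading of northern lanes,
heterogeneous zone variances, and optional first-order autoregressive (AR1)
correlation of the noise along positions within a lane.

Default calibration targets a plant-to-plant coefficient of variation in
the 20-30% band around a zone mean of 71.62 thousand pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .layout import GridLayout

#: Zone mean (thousand pixels) and matching sd back-computed from a 28.2% CV.
DEFAULT_ZONE_MEAN = 71.62
DEFAULT_ZONE_SD = 20.2
#: Default west->east linear trend, response units per position step.
DEFAULT_POS_SLOPE = 0.5


class InvalidParameterError(ValueError):
    """A field parameter is inconsistent with the layout."""


def _per_zone(value, n_zones: int, name: str) -> np.ndarray:
    """Broadcast a scalar or per-zone sequence/mapping to an array of length n_zones."""
    if isinstance(value, Mapping):
        try:
            arr = np.array([float(value[z]) for z in range(1, n_zones + 1)])
        except KeyError as exc:  # pragma: no cover - defensive
            raise InvalidParameterError(f"{name} missing zone {exc}") from exc
    elif np.isscalar(value):
        arr = np.full(n_zones, float(value))
    else:
        arr = np.asarray(value, dtype=float)
        if arr.shape != (n_zones,):
            raise InvalidParameterError(f"{name} must have one entry per zone")
    return arr


@dataclass(frozen=True)
class FieldParams:
    """Microclimate parameters of a zone.

    zone_mean / zone_sd are scalars or per-zone values (response units);
    pos_slope is the linear position-trend coefficient (units per position
    step, applied to centered position scores); lane_effects are additive
    per-lane offsets encoding a south->north decline; shaded lanes have
    their expectation multiplied by shade_penalty; ar1_rho correlates noise
    along positions within a lane.
    """

    zone_mean: object = DEFAULT_ZONE_MEAN
    zone_sd: object = DEFAULT_ZONE_SD
    pos_slope: float = DEFAULT_POS_SLOPE
    lane_effects: Sequence[float] | None = None
    shaded_lanes: frozenset[int] = field(default_factory=frozenset)
    shade_penalty: float = 1.0
    ar1_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shaded_lanes", frozenset(self.shaded_lanes))
        if not (0.0 < self.shade_penalty <= 1.0):
            raise InvalidParameterError("shade_penalty must lie in (0, 1]")
        if not (-1.0 < self.ar1_rho < 1.0):
            raise InvalidParameterError("|ar1_rho| must be < 1")

    def validate_for(self, layout: GridLayout) -> None:
        means = _per_zone(self.zone_mean, layout.n_zones, "zone_mean")
        sds = _per_zone(self.zone_sd, layout.n_zones, "zone_sd")
        if np.any(sds < 0):
            raise InvalidParameterError("zone_sd must be nonnegative")
        del means
        if self.lane_effects is not None and len(self.lane_effects) != layout.n_lanes:
            raise InvalidParameterError("lane_effects must have one entry per lane")
        bad = [l for l in self.shaded_lanes if not 1 <= l <= layout.n_lanes]
        if bad:
            raise InvalidParameterError(f"shaded lane(s) {sorted(bad)} outside 1..{layout.n_lanes}")

    def zone_means(self, layout: GridLayout) -> np.ndarray:
        return _per_zone(self.zone_mean, layout.n_zones, "zone_mean")

    def zone_sds(self, layout: GridLayout) -> np.ndarray:
        return _per_zone(self.zone_sd, layout.n_zones, "zone_sd")


@dataclass(frozen=True)
class FieldSurface:
    """Deterministic expectation per cell (no noise)."""

    layout: GridLayout
    expectation: np.ndarray  # (n_lanes, n_positions)

    def __post_init__(self) -> None:
        exp = np.asarray(self.expectation, dtype=float)
        if exp.shape != (self.layout.n_lanes, self.layout.n_positions):
            raise ValueError("expectation shape does not match layout")
        object.__setattr__(self, "expectation", exp)


@dataclass(frozen=True)
class UniformityData:
    """One response value per cell of a layout, plus generation metadata."""

    layout: GridLayout
    values: np.ndarray  # (n_lanes, n_positions)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.layout.n_lanes, self.layout.n_positions):
            raise ValueError("values shape does not match layout")
        if not np.all(np.isfinite(vals)):
            raise ValueError("all cell values must be finite")
        object.__setattr__(self, "values", vals)

    def to_frame(self) -> pd.DataFrame:
        lay = self.layout
        return pd.DataFrame(
            {
                "lane": lay.lanes.ravel(),
                "position": lay.positions.ravel(),
                "zone": lay.zones.ravel(),
                "value": self.values.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "UniformityData":
        df = pd.read_csv(path)
        required = {"lane", "position", "zone", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"uniformity CSV must have columns {sorted(required)}")
        n_lanes = int(df["lane"].max())
        n_positions = int(df["position"].max())
        # reconstruct zone bounds from the lane -> zone mapping
        lane_zone = df.drop_duplicates("lane").sort_values("lane")["zone"].to_numpy()
        bounds = []
        start = 1
        for lane in range(2, n_lanes + 1):
            if lane_zone[lane - 1] != lane_zone[lane - 2]:
                bounds.append((start, lane - 1))
                start = lane
        bounds.append((start, n_lanes))
        layout = GridLayout(n_lanes=n_lanes, n_positions=n_positions, zone_bounds=tuple(bounds))
        values = np.full((n_lanes, n_positions), np.nan)
        values[df["lane"].to_numpy() - 1, df["position"].to_numpy() - 1] = df["value"].to_numpy()
        if np.isnan(values).any():
            raise ValueError("uniformity CSV does not cover every cell exactly once")
        return cls(layout=layout, values=values)


def make_field(layout: GridLayout, params: FieldParams) -> FieldSurface:
    """Deterministic expectation surface.

    Per cell: zone_mean + pos_slope * (position - mean position)
    + lane_effect(lane), multiplied by shade_penalty on shaded lanes.
    Centered position scores make zone_mean the prediction at the centre of
    a lane.
    """
    params.validate_for(layout)
    means = params.zone_means(layout)
    exp = means[layout.zones - 1].astype(float)
    exp += params.pos_slope * layout.centered_positions()
    if params.lane_effects is not None:
        exp += np.asarray(params.lane_effects, dtype=float)[:, None]
    if params.shaded_lanes:
        shaded = np.isin(layout.lanes[:, 0], list(params.shaded_lanes))
        exp[shaded, :] *= params.shade_penalty
    return FieldSurface(layout=layout, expectation=exp)


def _ar1_noise(rng: np.random.Generator, n_lanes: int, n_positions: int, rho: float) -> np.ndarray:
    """Stationary unit-variance AR1 noise along positions, independent lanes."""
    z = rng.standard_normal((n_lanes, n_positions))
    if rho == 0.0:
        return z
    e = np.empty_like(z)
    e[:, 0] = z[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for t in range(1, n_positions):
        e[:, t] = rho * e[:, t - 1] + scale * z[:, t]
    return e


def simulate_uniformity(
    field_surface: FieldSurface,
    params: FieldParams,
    seed: int | None = None,
) -> UniformityData:
    """Add per-zone Gaussian noise (stationary AR1 along positions) to a surface.

    With a fixed seed the output is bit-identical across calls.
    """
    layout = field_surface.layout
    params.validate_for(layout)
    use_seed = params.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    sds = params.zone_sds(layout)
    noise = _ar1_noise(rng, layout.n_lanes, layout.n_positions, params.ar1_rho)
    values = field_surface.expectation + sds[layout.zones - 1] * noise
    meta = {
        "seed": int(use_seed),
        "pos_slope": params.pos_slope,
        "ar1_rho": params.ar1_rho,
        "zone_mean": list(params.zone_means(layout)),
        "zone_sd": list(sds),
        "shade_penalty": params.shade_penalty,
        "shaded_lanes": sorted(params.shaded_lanes),
    }
    return UniformityData(layout=layout, values=values, metadata=meta)


def simulate_default_zone(seed: int = 0, **overrides) -> UniformityData:
    """One 3x24 zone simulated with the default calibration."""
    layout = overrides.pop("layout", GridLayout())
    params = replace(FieldParams(seed=seed), **overrides)
    return simulate_uniformity(make_field(layout, params), params, seed=seed)


def summarize(data: UniformityData, grouping: str = "zone") -> pd.DataFrame:
    """Per-group mean, sd (n-1 divisor) and CV% = 100*sd/mean.

    grouping is one of 'zone', 'lane' or 'grid'.  Groups with mean zero get
    CV = NaN and cv_defined = False rather than being dropped.
    """
    df = data.to_frame()
    if grouping == "grid":
        df["_group"] = 1
    elif grouping in ("zone", "lane"):
        df["_group"] = df[grouping]
    else:
        raise ValueError("grouping must be 'zone', 'lane' or 'grid'")
    out = (
        df.groupby("_group")["value"]
        .agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
        .rename(columns={"_group": grouping if grouping != "grid" else "grid"})
    )
    defined = out["mean"] != 0
    out["cv_pct"] = np.where(defined, 100.0 * out["sd"] / out["mean"].where(defined), np.nan)
    out["cv_defined"] = defined
    return out
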