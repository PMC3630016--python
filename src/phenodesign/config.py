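"""Flat key-value run configuration.

The config file format is one ``key = value`` per line, ``#`` comments,
UTF-8.  Lists are comma separated; lane ranges accept ``a-b`` spans
(e.g. ``shaded_lanes = 19-24``).  A RunConfig round-trips losslessly
through its file form.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path


def parse_lane_set(text: str) -> tuple[int, ...]:
    """'19-24' or '1,3,5' (or a mix) -> sorted tuple of lane indices."""
    out: set[int] = set()
    text = text.strip()
    if not text:
        return ()
    for part in text.split(","):
        part = part.strip()
        if "-" in part:
            lo, hi = part.split("-")
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(part))
    return tuple(sorted(out))


def _format_lane_set(lanes) -> str:
    return ",".join(str(x) for x in sorted(lanes))


@dataclass
class RunConfig:
    """Everything a pipeline run needs; all seeds explicit."""

    n_lanes: int = 3
    n_positions: int = 24
    zone_mean: float = 71.62
    zone_sd: float = 20.2
    pos_slope: float = 0.5
    lane_effects: tuple[float, ...] = ()
    shaded_lanes: tuple[int, ...] = ()
    shade_penalty: float = 1.0
    ar1_rho: float = 0.0
    tactic: str = ""  # empty: plain uniformity simulation
    n_timepoints: int = 14
    growth_rate: float = 0.18
    growth_log_sd: float = 0.02
    initial_value: float = 7.0
    menu: tuple[str, ...] = ("CRD", "CRD+Adj", "TFD", "RCBD3x12", "RIBD3x1")
    n_samples: int = 500
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "phenodesign_run"

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            val = getattr(self, f.name)
            if f.name in ("lane_effects", "menu"):
                val = ",".join(str(x) for x in val)
            elif f.name == "shaded_lanes":
                val = _format_lane_set(val)
            lines.append(f"{f.name} = {val}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            raw[key] = val
        kwargs = {}
        for f in fields(cls):
            if f.name not in raw:
                continue
            val = raw.pop(f.name)
            if f.name == "lane_effects":
                kwargs[f.name] = tuple(float(x) for x in val.split(",") if x.strip())
            elif f.name == "shaded_lanes":
                kwargs[f.name] = parse_lane_set(val)
            elif f.name == "menu":
                kwargs[f.name] = tuple(x.strip() for x in val.split(",") if x.strip())
            elif f.type in ("int", int):
                kwargs[f.name] = int(val)
            elif f.type in ("float", float):
                kwargs[f.name] = float(val)
            else:
                kwargs[f.name] = val
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)

    def as_dict(self) -> dict:
        return asdict(self)
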