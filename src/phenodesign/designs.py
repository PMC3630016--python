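"""Construction of the candidate experimental designs.

Designs assign v treatment labels, each replicated r times, to the cells of
a lanes x positions grid.  The menu covers completely randomized designs,
randomized complete block designs, resolved incomplete-block and row-column
designs (built by a seeded interchange optimizer on a concurrence-balance
objective), and (nearly) trend-free designs that make treatment totals of
the centered linear position scores as small as possible so that a fitted
position trend does not disturb treatment estimates.

Randomization of the optimized designs is restricted: the position order
may be reversed across the whole layout, lanes may be permuted, and block
contents may be permuted between congruent block slots within a replicate;
trend-free designs may instead be regenerated with a fresh optimizer run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import GridLayout

#: Interchange-optimizer budget (swap proposals); first strictly improving
#: swap in a seeded random scan is accepted.
DEFAULT_N_PROPOSALS = 20_000


class DesignError(ValueError):
    """Infeasible or inconsistent design request."""


# ---------------------------------------------------------------------------
# blocking arrangements (uniformity-trial precision sweep)
# ---------------------------------------------------------------------------

BLOCK_SERIES = ("within-lane", "cross-lane", "row-column")


@dataclass(frozen=True)
class BlockingArrangement:
    """Rectangular blocking of a layout.

    series 'within-lane' uses blocks of 1 lane x k positions, 'cross-lane'
    blocks spanning all lanes x k positions, and 'row-column' blocks of all
    lanes x k positions with row (lane) and column (position) factors
    nested inside each block.
    """

    series: str
    block_lanes: int
    block_positions: int

    def __post_init__(self) -> None:
        if self.series not in BLOCK_SERIES:
            raise DesignError(f"series must be one of {BLOCK_SERIES}")
        if self.block_lanes < 1 or self.block_positions < 1:
            raise DesignError("block dimensions must be positive")

    @property
    def label(self) -> str:
        return f"{self.block_lanes}x{self.block_positions}"


def _check_divides(total: int, part: int, name: str) -> None:
    if total % part:
        raise DesignError(f"{name}={part} does not divide the layout's {total}")


def _tile(layout: GridLayout, shape_lanes: int, shape_positions: int) -> np.ndarray:
    """Tile the grid with rectangles; returns a 1-based factor array."""
    _check_divides(layout.n_lanes, shape_lanes, "block_lanes")
    _check_divides(layout.n_positions, shape_positions, "block_positions")
    lane_band = (layout.lanes - 1) // shape_lanes
    pos_band = (layout.positions - 1) // shape_positions
    return lane_band * (layout.n_positions // shape_positions) + pos_band + 1


@dataclass(frozen=True)
class BlockFactors:
    """Cell-wise block factor, optionally with rows/columns nested in blocks."""

    block: np.ndarray
    row: np.ndarray | None = None
    column: np.ndarray | None = None

    @property
    def n_blocks(self) -> int:
        return int(self.block.max())


def make_blocks(layout: GridLayout, arrangement: BlockingArrangement) -> BlockFactors:
    """Partition the layout into equal rectangular blocks."""
    block = _tile(layout, arrangement.block_lanes, arrangement.block_positions)
    if arrangement.series == "row-column":
        row = (layout.lanes - 1) % arrangement.block_lanes + 1
        column = (layout.positions - 1) % arrangement.block_positions + 1
        return BlockFactors(block=block, row=row, column=column)
    return BlockFactors(block=block)


def figure_style_sweep(layout: GridLayout) -> list[BlockingArrangement]:
    """The three standard series of blocking arrangements for a 3x24 zone.

    (i) within-lane blocks of 2,3,4,6,8,12,24 carts; (ii) cross-lane blocks
    of 1,2,3,4,6,8,12 positions; (iii) rows-and-columns in blocks of 3 lanes
    by 2,3,4,6,8,12,24 positions.
    """
    sweep = [BlockingArrangement("within-lane", 1, k) for k in (2, 3, 4, 6, 8, 12, 24)]
    sweep += [BlockingArrangement("cross-lane", layout.n_lanes, k) for k in (1, 2, 3, 4, 6, 8, 12)]
    sweep += [BlockingArrangement("row-column", layout.n_lanes, k) for k in (2, 3, 4, 6, 8, 12, 24)]
    return sweep


# ---------------------------------------------------------------------------
# the Design container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Design:
    """Treatment assignment with block/row/column/replicate annotations.

    All factor arrays have shape (n_lanes, n_positions) and 1-based levels;
    absent factors are None.  provenance records the generator family, its
    seed and, for trend-free designs, the achieved Q statistic.
    """

    layout: GridLayout
    treatment: np.ndarray
    v: int
    r: int
    replicate: np.ndarray | None = None
    block: np.ndarray | None = None
    row: np.ndarray | None = None
    column: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        treat = np.asarray(self.treatment, dtype=int)
        if treat.shape != (self.layout.n_lanes, self.layout.n_positions):
            raise DesignError("treatment array shape does not match layout")
        object.__setattr__(self, "treatment", treat)

    def validate(self) -> None:
        """Raise DesignError on any violated structural invariant."""
        counts = np.bincount(self.treatment.ravel(), minlength=self.v + 1)[1:]
        if len(counts) != self.v or not np.all(counts == self.r):
            raise DesignError("every treatment must appear exactly r times")
        if self.replicate is not None:
            for rep in np.unique(self.replicate):
                labels = self.treatment[self.replicate == rep]
                if len(np.unique(labels)) != self.v or labels.size != self.v:
                    raise DesignError(f"replicate {rep} is not a complete set of treatments")
        if self.block is not None:
            for b in np.unique(self.block):
                labels = self.treatment[self.block == b]
                if len(np.unique(labels)) != labels.size:
                    raise DesignError(f"block {b} repeats a treatment")

    def to_frame(self) -> pd.DataFrame:
        lay = self.layout
        df = pd.DataFrame(
            {
                "lane": lay.lanes.ravel(),
                "position": lay.positions.ravel(),
                "treatment": self.treatment.ravel(),
            }
        )
        for name in ("replicate", "block", "row", "column"):
            arr = getattr(self, name)
            df[name] = arr.ravel() if arr is not None else pd.NA
        return df[["lane", "position", "replicate", "block", "row", "column", "treatment"]]

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary_dict(self) -> dict:
        return {
            "v": self.v,
            "r": self.r,
            "n_cells": self.layout.n_cells,
            **{k: v for k, v in self.provenance.items()},
        }

    def write_summary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary_dict(), indent=2, default=str))

    @classmethod
    def from_csv(cls, path: str | Path, provenance: dict | None = None) -> "Design":
        df = pd.read_csv(path)
        n_lanes, n_positions = int(df["lane"].max()), int(df["position"].max())
        layout = GridLayout(n_lanes=n_lanes, n_positions=n_positions)
        idx = (df["lane"].to_numpy() - 1, df["position"].to_numpy() - 1)

        def grid(col: str) -> np.ndarray | None:
            if col not in df or df[col].isna().all():
                return None
            out = np.zeros((n_lanes, n_positions), dtype=int)
            out[idx] = df[col].to_numpy()
            return out

        treatment = grid("treatment")
        v = int(treatment.max())
        r = layout.n_cells // v
        return cls(
            layout=layout,
            treatment=treatment,
            v=v,
            r=r,
            replicate=grid("replicate"),
            block=grid("block"),
            row=grid("row"),
            column=grid("column"),
            provenance=provenance or {"family": "csv"},
        )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _replicate_shape(layout: GridLayout, r: int) -> tuple[int, int]:
    """Replicates are r side-by-side vertical slices spanning all lanes."""
    _check_divides(layout.n_positions, r, "replicate count")
    return layout.n_lanes, layout.n_positions // r


def _fill_replicates(layout: GridLayout, rep: np.ndarray, v: int, rng) -> np.ndarray:
    """Independent random permutation of 1..v into each replicate's cells."""
    treat = np.zeros((layout.n_lanes, layout.n_positions), dtype=int)
    for k in np.unique(rep):
        cells = np.where(rep.ravel() == k)[0]
        if cells.size != v:
            raise DesignError(f"replicate {k} has {cells.size} cells, expected v={v}")
        treat.ravel()[cells] = rng.permutation(v) + 1
    return treat


def trend_q(
    treatment: np.ndarray, layout: GridLayout, block: np.ndarray | None = None
) -> float:
    """Q = sum over treatments of (sum of centered position scores)^2.

    Scores are centered per block when a block factor is given, otherwise on
    the whole layout.  Q == 0 means the design is trend-free (treatments
    orthogonal to the linear position trend).
    """
    scores = _trend_scores(layout, block)
    v = int(treatment.max())
    sums = np.bincount(treatment.ravel() - 1, weights=scores.ravel(), minlength=v)
    return float(np.sum(sums**2))


def _trend_scores(layout: GridLayout, block: np.ndarray | None) -> np.ndarray:
    pos = layout.positions.astype(float)
    if block is None:
        return pos - pos.mean()
    scores = pos.copy()
    for b in np.unique(block):
        scores[block == b] -= pos[block == b].mean()
    return scores


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_crd(v: int, r: int, layout: GridLayout, seed: int = 0) -> Design:
    """Completely randomized design: a uniform random permutation of the
    treatment multiset over all cells."""
    if v * r != layout.n_cells:
        raise DesignError(f"v*r = {v * r} must equal the {layout.n_cells} cells")
    rng = np.random.default_rng(seed)
    labels = rng.permutation(np.repeat(np.arange(1, v + 1), r))
    return Design(
        layout=layout,
        treatment=labels.reshape(layout.n_lanes, layout.n_positions),
        v=v,
        r=r,
        provenance={"family": "crd", "seed": int(seed)},
    )


def make_rcbd(
    v: int, layout: GridLayout, rep_shape: tuple[int, int] | None = None, seed: int = 0
) -> Design:
    """Randomized complete block design; each replicate block is an
    independent random permutation of all v treatments."""
    if layout.n_cells % v:
        raise DesignError("number of cells must be a multiple of v")
    r = layout.n_cells // v
    if rep_shape is None:
        rep_shape = _replicate_shape(layout, r)
    if rep_shape[0] * rep_shape[1] != v:
        raise DesignError(f"replicate shape {rep_shape} does not hold v={v} cells")
    rep = _tile(layout, *rep_shape)
    rng = np.random.default_rng(seed)
    treat = _fill_replicates(layout, rep, v, rng)
    return Design(
        layout=layout,
        treatment=treat,
        v=v,
        r=r,
        replicate=rep,
        block=rep,
        provenance={"family": "rcbd", "seed": int(seed), "rep_shape": rep_shape},
    )


def _interchange(
    treat_flat: np.ndarray,
    eligible_pairs,
    delta_fn,
    apply_fn,
    n_proposals: int,
    rng,
) -> int:
    """Generic seeded first-improvement interchange scan.

    eligible_pairs(rng) yields candidate (i, j) flat cell indices; delta_fn
    returns the objective change of swapping them (None if the swap is
    disallowed); apply_fn commits the swap.  Returns proposals used.
    """
    used = 0
    for _ in range(n_proposals):
        used += 1
        i, j = eligible_pairs(rng)
        if treat_flat[i] == treat_flat[j]:
            continue
        delta = delta_fn(i, j)
        if delta is not None and delta < -1e-9:
            apply_fn(i, j)
    return used


def make_resolved_ibd(
    v: int,
    r: int,
    layout: GridLayout,
    block_shape: tuple[int, int],
    seed: int = 0,
    n_proposals: int = DEFAULT_N_PROPOSALS,
    n_restarts: int = 4,
) -> Design:
    """Resolved incomplete block design.

    Replicates are vertical slices of the layout; blocks of ``block_shape``
    tile each replicate.  A seeded interchange optimizer minimizes the sum
    of squared pairwise treatment concurrences (equivalently their spread,
    since the total concurrence count is fixed), swapping treatments between
    blocks within a replicate.  No treatment ever appears twice in a block.
    """
    rep_shape = _replicate_shape(layout, r)
    if rep_shape[0] * rep_shape[1] != v:
        raise DesignError(f"replicates of {rep_shape} must hold v={v} cells")
    block_size = block_shape[0] * block_shape[1]
    if block_size > v:
        raise DesignError("block size may not exceed v")
    if rep_shape[0] % block_shape[0] or rep_shape[1] % block_shape[1]:
        raise DesignError(f"blocks {block_shape} do not tile replicates {rep_shape}")
    rep = _tile(layout, *rep_shape)
    block = _tile(layout, *block_shape)
    rng = np.random.default_rng(seed)

    rep_flat, block_flat = rep.ravel(), block.ravel()
    rep_cells = {k: np.where(rep_flat == k)[0] for k in np.unique(rep_flat)}
    rep_ids = sorted(rep_cells)

    best = None
    for _ in range(max(1, n_restarts)):
        treat = _fill_replicates(layout, rep, v, rng).ravel()
        lam = _concurrence(treat, block_flat, v)
        obj = [float(np.sum(np.triu(lam, 1) ** 2))]

        def eligible(rng):
            cells = rep_cells[rep_ids[rng.integers(len(rep_ids))]]
            i, j = cells[rng.integers(cells.size)], cells[rng.integers(cells.size)]
            return i, j

        def delta(i, j):
            if block_flat[i] == block_flat[j]:
                return None
            ta, tb = treat[i] - 1, treat[j] - 1
            in_a = treat[block_flat == block_flat[i]] - 1
            in_b = treat[block_flat == block_flat[j]] - 1
            if tb in in_a or ta in in_b:
                return None  # would repeat a treatment within a block
            changes: dict[tuple[int, int], int] = {}

            def bump(x, y, d):
                key = (min(x, y), max(x, y))
                changes[key] = changes.get(key, 0) + d

            for u in in_a:
                if u != ta:
                    bump(ta, u, -1)
                    bump(tb, u, +1)
            for u in in_b:
                if u != tb:
                    bump(tb, u, -1)
                    bump(ta, u, +1)
            d_obj = 0.0
            for (x, y), d in changes.items():
                lam_xy = lam[x, y]
                d_obj += (lam_xy + d) ** 2 - lam_xy**2
            return d_obj

        def apply(i, j):
            d = delta(i, j)
            ta, tb = treat[i] - 1, treat[j] - 1
            for u in treat[block_flat == block_flat[i]] - 1:
                if u != ta:
                    _lam_add(lam, ta, u, -1)
                    _lam_add(lam, tb, u, +1)
            for u in treat[block_flat == block_flat[j]] - 1:
                if u != tb:
                    _lam_add(lam, tb, u, -1)
                    _lam_add(lam, ta, u, +1)
            treat[i], treat[j] = treat[j], treat[i]
            obj[0] += d

        _interchange(treat, eligible, delta, apply, n_proposals, rng)
        if best is None or obj[0] < best[0] - 1e-9:
            best = (obj[0], treat.copy())

    obj_val, treat = best
    design = Design(
        layout=layout,
        treatment=treat.reshape(layout.n_lanes, layout.n_positions),
        v=v,
        r=r,
        replicate=rep,
        block=block,
        provenance={
            "family": "ibd",
            "seed": int(seed),
            "block_shape": tuple(block_shape),
            "rep_shape": rep_shape,
            "concurrence_ss": float(obj_val),
        },
    )
    design.validate()
    return design


def _concurrence(treat_flat: np.ndarray, block_flat: np.ndarray, v: int) -> np.ndarray:
    lam = np.zeros((v, v), dtype=int)
    for b in np.unique(block_flat):
        members = treat_flat[block_flat == b] - 1
        for a in range(len(members)):
            for c in range(a + 1, len(members)):
                _lam_add(lam, members[a], members[c], 1)
    return lam


def _lam_add(lam: np.ndarray, x: int, y: int, d: int) -> None:
    lam[min(x, y), max(x, y)] += d


def make_row_column(
    v: int,
    layout: GridLayout,
    rep_shape: tuple[int, int] | None = None,
    seed: int = 0,
    n_proposals: int = DEFAULT_N_PROPOSALS,
    n_restarts: int = 4,
) -> Design:
    """Resolved row-column design.

    Each replicate is a rows x columns rectangle holding every treatment
    once.  The interchange optimizer balances, across replicates, how often
    each treatment occupies each row (lane) and each column (position),
    minimizing the sum of squared occurrence counts.
    """
    if layout.n_cells % v:
        raise DesignError("number of cells must be a multiple of v")
    r = layout.n_cells // v
    if rep_shape is None:
        rep_shape = _replicate_shape(layout, r)
    if rep_shape[0] * rep_shape[1] != v:
        raise DesignError(f"replicate shape {rep_shape} does not hold v={v} cells")
    rep = _tile(layout, *rep_shape)
    row = (layout.lanes - 1) % rep_shape[0] + 1
    col = (layout.positions - 1) % rep_shape[1] + 1
    rng = np.random.default_rng(seed)

    rep_flat, row_flat, col_flat = rep.ravel(), row.ravel(), col.ravel()
    rep_cells = {k: np.where(rep_flat == k)[0] for k in np.unique(rep_flat)}
    rep_ids = sorted(rep_cells)
    n_rows, n_cols = rep_shape

    best = None
    for _ in range(max(1, n_restarts)):
        treat = _fill_replicates(layout, rep, v, rng).ravel()
        n_row = np.zeros((v, n_rows), dtype=int)
        n_col = np.zeros((v, n_cols), dtype=int)
        for c in range(treat.size):
            n_row[treat[c] - 1, row_flat[c] - 1] += 1
            n_col[treat[c] - 1, col_flat[c] - 1] += 1
        obj = [float(np.sum(n_row**2) + np.sum(n_col**2))]

        def eligible(rng):
            cells = rep_cells[rep_ids[rng.integers(len(rep_ids))]]
            return cells[rng.integers(cells.size)], cells[rng.integers(cells.size)]

        def delta(i, j):
            ta, tb = treat[i] - 1, treat[j] - 1
            d = 0.0
            for t, frm, to in ((ta, i, j), (tb, j, i)):
                for counts, fac in ((n_row, row_flat), (n_col, col_flat)):
                    a, b = fac[frm] - 1, fac[to] - 1
                    if a != b:
                        d += (counts[t, a] - 1) ** 2 - counts[t, a] ** 2
                        d += (counts[t, b] + 1) ** 2 - counts[t, b] ** 2
            return d

        def apply(i, j):
            ta, tb = treat[i] - 1, treat[j] - 1
            d = delta(i, j)
            for t, frm, to in ((ta, i, j), (tb, j, i)):
                for counts, fac in ((n_row, row_flat), (n_col, col_flat)):
                    counts[t, fac[frm] - 1] -= 1
                    counts[t, fac[to] - 1] += 1
            treat[i], treat[j] = treat[j], treat[i]
            obj[0] += d

        _interchange(treat, eligible, delta, apply, n_proposals, rng)
        if best is None or obj[0] < best[0] - 1e-9:
            best = (obj[0], treat.copy())

    obj_val, treat = best
    design = Design(
        layout=layout,
        treatment=treat.reshape(layout.n_lanes, layout.n_positions),
        v=v,
        r=r,
        replicate=rep,
        row=row,
        column=col,
        provenance={
            "family": "row_column",
            "seed": int(seed),
            "rep_shape": rep_shape,
            "balance_ss": float(obj_val),
        },
    )
    design.validate()
    return design


def make_trend_free(
    v: int,
    r: int,
    layout: GridLayout,
    rep_shape: tuple[int, int] | None = None,
    seed: int = 0,
    n_proposals: int = DEFAULT_N_PROPOSALS,
) -> Design:
    """(Nearly) trend-free design.

    Minimizes Q = sum_t (sum of centered position scores of t's cells)^2 by
    seeded interchange.  With ``rep_shape`` the design is a complete-block
    design whose blocks are the replicates, scores are centered per block
    and swaps stay within a block; without it the assignment is free over
    the whole layout with whole-layout centering.  Q == 0 is trend-free,
    otherwise nearly trend-free; the achieved Q is recorded in provenance.
    """
    if v * r != layout.n_cells:
        raise DesignError(f"v*r = {v * r} must equal the {layout.n_cells} cells")
    rng = np.random.default_rng(seed)
    if rep_shape is not None:
        if rep_shape[0] * rep_shape[1] != v:
            raise DesignError(f"replicate shape {rep_shape} does not hold v={v} cells")
        rep = _tile(layout, *rep_shape)
        treat = _fill_replicates(layout, rep, v, rng).ravel()
        group_flat = rep.ravel()
    else:
        rep = None
        treat = rng.permutation(np.repeat(np.arange(1, v + 1), r))
        group_flat = np.ones(layout.n_cells, dtype=int)
    scores = _trend_scores(layout, rep).ravel()
    sums = np.bincount(treat - 1, weights=scores, minlength=v)
    obj = [float(np.sum(sums**2))]
    groups = {k: np.where(group_flat == k)[0] for k in np.unique(group_flat)}
    group_ids = sorted(groups)
    n_cells = layout.n_cells

    def eligible(rng):
        if rep is None:
            return rng.integers(n_cells), rng.integers(n_cells)
        cells = groups[group_ids[rng.integers(len(group_ids))]]
        return cells[rng.integers(cells.size)], cells[rng.integers(cells.size)]

    def delta(i, j):
        ta, tb = treat[i] - 1, treat[j] - 1
        dx = scores[j] - scores[i]
        sa, sb = sums[ta], sums[tb]
        return (sa + dx) ** 2 + (sb - dx) ** 2 - sa**2 - sb**2

    def apply(i, j):
        ta, tb = treat[i] - 1, treat[j] - 1
        dx = scores[j] - scores[i]
        obj[0] += delta(i, j)
        sums[ta] += dx
        sums[tb] -= dx
        treat[i], treat[j] = treat[j], treat[i]

    _interchange(treat, eligible, delta, apply, n_proposals, rng)
    q = float(np.sum(sums**2))
    design = Design(
        layout=layout,
        treatment=treat.reshape(layout.n_lanes, layout.n_positions),
        v=v,
        r=r,
        replicate=rep,
        block=rep,
        provenance={
            "family": "trend_free",
            "seed": int(seed),
            "rep_shape": rep_shape,
            "q": q,
            "trend_free": bool(q < 1e-9),
            "n_proposals": int(n_proposals),
        },
    )
    design.validate()
    return design


# ---------------------------------------------------------------------------
# restricted randomization
# ---------------------------------------------------------------------------


def randomize(design: Design, seed: int = 0, regenerate: bool = False) -> Design:
    """Draw one randomization of a design.

    CRDs and RCBDs are fully re-randomized within their structure.  The
    optimized designs get only the allowed restricted moves: position order
    reversed across the whole layout with probability 1/2, lanes permuted,
    and, when blocks are present, block contents permuted between congruent
    block slots within each replicate.  With ``regenerate=True`` a
    trend-free design is instead rebuilt by a fresh optimizer run.
    """
    family = design.provenance.get("family")
    rng = np.random.default_rng(seed)
    if family == "crd":
        return make_crd(design.v, design.r, design.layout, seed=seed)
    if family == "rcbd":
        return make_rcbd(
            design.v, design.layout, design.provenance.get("rep_shape"), seed=seed
        )
    if family == "trend_free" and regenerate:
        return make_trend_free(
            design.v,
            design.r,
            design.layout,
            rep_shape=design.provenance.get("rep_shape"),
            seed=seed,
            n_proposals=design.provenance.get("n_proposals", DEFAULT_N_PROPOSALS),
        )

    treat = design.treatment.copy()
    blk = design.block if design.block is not None else None
    # permute block contents between congruent slots within each replicate
    if blk is not None:
        rep = design.replicate if design.replicate is not None else np.ones_like(blk)
        # when blocks coincide with replicates, permute whole block contents
        # across the (congruent) replicate slots instead
        one_block_per_rep = all(
            np.unique(blk[rep == k]).size == 1 for k in np.unique(rep)
        )
        groups = [np.unique(blk)] if one_block_per_rep else [
            np.unique(blk[rep == k]) for k in np.unique(rep)
        ]
        new_treat = treat.copy()
        for blocks_in_group in groups:
            perm = rng.permutation(len(blocks_in_group))
            for src, dst in zip(blocks_in_group, blocks_in_group[perm]):
                src_cells = np.argwhere(blk == src)
                dst_cells = np.argwhere(blk == dst)
                new_treat[tuple(dst_cells.T)] = treat[tuple(src_cells.T)]
        treat = new_treat
    # random lane permutation
    treat = treat[rng.permutation(design.layout.n_lanes), :]
    # whole-layout position reversal with probability 1/2
    if rng.random() < 0.5:
        treat = treat[:, ::-1]
    out = replace(
        design,
        treatment=np.ascontiguousarray(treat),
        provenance={**design.provenance, "randomization_seed": int(seed)},
    )
    out.validate()
    return out
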