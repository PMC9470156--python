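"""Tradeoff-breaking detection on trait-observation tables.

Operators for tables of paired trait measurements — rows of
``(group, x, y)``, e.g. photosynthesis vs nitrogenase activity per
species, or collective persistence vs cell number per lineage.  The
analysis mirrors how tradeoff plots are read in practice: standardise
the two traits, fit per-group and pooled least-squares lines, draw the
convex hull of each group's accessible phenotypes, and flag the
observations that sit on the both-traits-high side of the pooled
(negative-slope) tradeoff line by more than ``k_sd`` residual standard
deviations — candidate tradeoff breakers.

A seeded generator produces synthetic tables with the same structure
(groups strung along a shared negative-slope line, plus planted
breakers displaced perpendicularly toward high/high) and ships the
ground-truth flags in its metadata, so flag precision and recall are
directly measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraitObservationTable",
    "TradeoffFit",
    "standardise",
    "fit_tradeoff_line",
    "convex_hull",
    "flag_tradeoff_breaking",
    "synth_observations",
    "analyse",
]

REQUIRED_COLUMNS = ("group", "x", "y")


@dataclass
class TraitObservationTable:
    """Rows of paired trait values with a group label."""

    data: pd.DataFrame
    trait_names: tuple[str, str] = ("trait_x", "trait_y")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"table lacks required columns {missing}")
        xy = self.data[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("trait values must be finite")

    @classmethod
    def from_csv(cls, path) -> "TraitObservationTable":
        return cls(data=pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class TradeoffFit:
    """Pooled and per-group line fits plus hulls and breaker flags."""

    pooled_slope: float
    pooled_intercept: float
    group_fits: dict[str, tuple[float, float]]
    residuals: np.ndarray
    hulls: dict[str, np.ndarray]
    flags: np.ndarray


def standardise(table: TraitObservationTable, ddof: int = 1) -> TraitObservationTable:
    """Z-score both traits across the pooled table.

    Uses the sample SD (``ddof=1``) by default; pass ``ddof=0`` for the
    population convention.  Raises on a zero-variance trait.
    """
    df = table.data.copy()
    for col, name in zip(("x", "y"), table.trait_names):
        v = df[col].to_numpy(dtype=float)
        if len(v) < 2:
            raise ValueError("standardise needs at least 2 rows")
        sd = v.std(ddof=ddof)
        if sd == 0:
            raise ValueError(f"trait {name!r} has zero variance")
        df[col] = (v - v.mean()) / sd
    return TraitObservationTable(
        data=df, trait_names=table.trait_names,
        metadata={**table.metadata, "standardised": True},
    )


def fit_tradeoff_line(
    table: TraitObservationTable, scope: str = "pooled"
) -> tuple[float, float, np.ndarray] | dict[str, tuple[float, float, np.ndarray]]:
    """Ordinary least squares of ``y`` on ``x``.

    ``scope="pooled"`` fits one line to all rows and returns
    ``(slope, intercept, residuals)``; ``scope="group"`` returns a dict
    keyed by group label.
    """
    if scope == "group":
        return {
            str(gname): _ols(sub["x"].to_numpy(float), sub["y"].to_numpy(float))
            for gname, sub in table.data.groupby("group", sort=True)
        }
    if scope != "pooled":
        raise ValueError(f"scope must be 'pooled' or 'group', got {scope!r}")
    return _ols(table.data["x"].to_numpy(float), table.data["y"].to_numpy(float))


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    if len(np.unique(x)) < 2:
        raise ValueError("OLS needs at least 2 distinct x values")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), resid


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Counter-clockwise convex hull by Andrew's monotone chain.

    Collinear points on hull edges are excluded.  Raises on fewer than
    three points or an all-collinear set (reporting the degenerate
    segment endpoints).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("convex_hull needs >= 3 planar points")
    uniq = np.unique(pts, axis=0)
    order = np.lexsort((uniq[:, 1], uniq[:, 0]))
    P = uniq[order]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def half(seq):
        out: list[np.ndarray] = []
        for p in seq:
            while len(out) >= 2 and cross(out[-2], out[-1], p) <= 0:
                out.pop()
            out.append(p)
        return out

    lower = half(P)
    upper = half(P[::-1])
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:
        raise ValueError(
            f"degenerate hull: points are collinear between {P[0].tolist()} and {P[-1].tolist()}"
        )
    return hull


def flag_tradeoff_breaking(
    table: TraitObservationTable,
    fit: tuple[float, float, np.ndarray] | None = None,
    k_sd: float = 2.0,
) -> np.ndarray:
    """Boolean flags for candidate tradeoff-breaking rows.

    A row is flagged when its residual from the pooled tradeoff line
    exceeds ``k_sd`` times the residual SD *on the both-traits-high
    side* — i.e. a positive residual when the pooled slope is negative
    (above a falling line means high in both traits at once).
    """
    if len(table.data) < 4:
        raise ValueError("flagging needs at least 4 rows for a stable residual SD")
    slope, intercept, resid = fit if fit is not None else fit_tradeoff_line(table)
    sd = resid.std(ddof=1)
    y_scale = 1.0 + float(np.abs(table.data["y"]).max())
    if sd <= 1e-12 * y_scale:  # perfectly collinear up to round-off
        return np.zeros(len(resid), dtype=bool)
    signed = resid if slope < 0 else -resid
    return signed > k_sd * sd


def synth_observations(
    n_groups: int = 5,
    n_per_group: int = 10,
    slope: float = -1.0,
    noise_sd: float = 0.05,
    n_breakers: int = 2,
    breaker_shift: float = 0.5,
    seed: int | None = None,
) -> TraitObservationTable:
    """Seeded synthetic trait table with planted tradeoff breakers.

    Groups are strung along a shared line of negative ``slope`` (group
    centres spaced along the line, points jittered along it), with
    Gaussian noise of SD ``noise_sd`` added to ``y``.  ``n_breakers``
    rows are displaced by ``breaker_shift`` perpendicular to the line
    toward the high/high quadrant; ground-truth flags are stored in
    ``metadata["true_flags"]``.  Reliable recovery needs the planted
    displacement to clear the flagging threshold comfortably — the
    defaults put breakers ten noise SDs off the line.
    """
    if seed is None:
        raise ValueError("synth_observations requires an explicit seed")
    if slope >= 0:
        raise ValueError("tradeoff structure requires slope < 0")
    rng = np.random.default_rng(seed)
    rows = []
    centres = np.linspace(0.0, 1.0, n_groups)
    for gi, cx in enumerate(centres):
        along = cx + rng.uniform(-0.15, 0.15, size=n_per_group)
        x = along
        y = 1.0 + slope * along + rng.normal(0.0, noise_sd, size=n_per_group)
        for xi, yi in zip(x, y):
            rows.append((f"group_{gi+1}", xi, yi))
    df = pd.DataFrame(rows, columns=["group", "x", "y"])
    flags = np.zeros(len(df), dtype=bool)
    if n_breakers > 0:
        idx = rng.choice(len(df), size=n_breakers, replace=False)
        # unit normal to the line y = slope*x + c pointing toward high/high
        norm = np.array([-slope, 1.0]) / np.hypot(slope, 1.0)
        df.loc[idx, "x"] += breaker_shift * norm[0]
        df.loc[idx, "y"] += breaker_shift * norm[1]
        flags[idx] = True
    return TraitObservationTable(
        data=df,
        metadata={
            "true_flags": flags,
            "seed": seed,
            "slope": slope,
            "noise_sd": noise_sd,
            "breaker_shift": breaker_shift,
        },
    )


def analyse(table: TraitObservationTable, k_sd: float = 2.0) -> TradeoffFit:
    """Full pipeline: pooled and per-group fits, hulls, breaker flags."""
    slope, intercept, resid = fit_tradeoff_line(table)
    group_fits = {
        g: (s, c) for g, (s, c, _) in fit_tradeoff_line(table, scope="group").items()
    }
    hulls = {}
    for gname, sub in table.data.groupby("group", sort=True):
        pts = sub[["x", "y"]].to_numpy(float)
        if len(pts) >= 3:
            try:
                hulls[str(gname)] = convex_hull(pts)
            except ValueError:
                pass  # collinear group: no hull
    flags = flag_tradeoff_breaking(table, (slope, intercept, resid), k_sd=k_sd)
    return TradeoffFit(
        pooled_slope=slope,
        pooled_intercept=intercept,
        group_fits=group_fits,
        residuals=resid,
        hulls=hulls,
        flags=flags,
    )
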