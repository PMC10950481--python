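"""Positional distributions of detected elements and TSS-dataset QC.

Many core promoter elements occupy a strict position relative to the TSS
(an initiator at -2, a DPE at +28 from the initiator A+1). In a TSS dataset
of good positional accuracy, detected motifs therefore pile up at their
expected position; in a noisy dataset the same motifs smear out. This module
turns a hit list into per-element positional distributions — for each
position, the number of hits, the fraction (%) of that element's hits at the
position, and the mean and median score — and summarizes them into a modal
position and a concentration statistic (fraction of hits within +/-2 bases
of the mode) that can be compared across datasets to appraise TSS quality.

Axes: independent elements are profiled by their start (or anchor base)
position relative to the TSS; initiator-dependent elements are profiled by
their spacing on the anchor-A+1 axis, computed from composite calls. All
axes are zero-free (+1 is the reference base). Both mean and median scores
are emitted; some displays of this statistic use one, some the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .composite import AnnotatedHit, CompositeCall
from .motif_model import MotifModelError
from .scanner import MotifHit

__all__ = [
    "AXES",
    "PositionalDistribution",
    "QcSummary",
    "position_distribution",
    "spacing_distribution",
    "qc_summary",
    "compare_datasets",
    "export_distribution_table",
    "read_distribution_table",
]

AXES = ("start", "anchor", "spacing")

_TABLE_COLUMNS = ["element", "axis", "position", "n", "fraction_pct", "mean_score", "median_score"]


@dataclass(frozen=True)
class PositionalDistribution:
    """Per-position occurrence fractions and score summaries for one element.

    ``table`` has one row per occupied position with columns
    (position, n, fraction_pct, mean_score, median_score); fractions are
    percentages of ``total_hits`` and sum to 100 over the occupied positions.
    """

    element: str
    axis: str
    table: pd.DataFrame
    total_hits: int


@dataclass(frozen=True)
class QcSummary:
    """Modal position and positional concentration of one element."""

    element: str
    axis: str
    total_hits: int
    modal_position: int | None
    modal_fraction_pct: float
    concentration_pct: float  # fraction of hits within +/-2 bases of the mode


def _linear(pos: int) -> int:
    """Zero-free axis label -> signed base offset (used for +/-2 windows)."""
    return pos - 1 if pos > 0 else pos


def _build_distribution(
    element: str, axis: str, positions: Sequence[int], scores: Sequence[float]
) -> PositionalDistribution:
    if len(positions) == 0:
        table = pd.DataFrame(
            columns=["position", "n", "fraction_pct", "mean_score", "median_score"]
        )
        return PositionalDistribution(element=element, axis=axis, table=table, total_hits=0)
    df = pd.DataFrame({"position": positions, "score": scores})
    # fixed within-group order makes the float aggregates independent of
    # input hit order
    df = df.sort_values(["position", "score"], kind="mergesort")
    grouped = (
        df.groupby("position")["score"]
        .agg(n="size", mean_score="mean", median_score="median")
        .reset_index()
        .sort_values("position", kind="mergesort")
        .reset_index(drop=True)
    )
    total = int(grouped["n"].sum())
    grouped["fraction_pct"] = 100.0 * grouped["n"] / total
    grouped = grouped[["position", "n", "fraction_pct", "mean_score", "median_score"]]
    return PositionalDistribution(element=element, axis=axis, table=grouped, total_hits=total)


def position_distribution(
    hits: Iterable[MotifHit | AnnotatedHit],
    element: str,
    axis: str = "start",
) -> PositionalDistribution:
    """Distribution of one element's hits on a TSS-relative axis.

    ``axis="start"`` uses the hit's 5'-most base, ``axis="anchor"`` the
    element's anchor base; ``axis="spacing"`` uses the composite spacing of
    annotated hits (hits without a composite call — orphans — are excluded).
    An element with no hits yields an empty distribution, not an error. The
    spacing axis of dependent elements can equivalently be computed from
    composite calls with :func:`spacing_distribution`.
    """
    if axis not in AXES:
        raise MotifModelError(
            f"unknown axis {axis!r} for position_distribution (use one of {AXES})"
        )
    positions: list[int] = []
    scores: list[float] = []
    for h in hits:
        ann = h if isinstance(h, AnnotatedHit) else None
        hit = ann.hit if ann is not None else h
        if hit.element != element:
            continue
        if axis == "spacing":
            if ann is None or ann.spacing is None:
                continue
            positions.append(ann.spacing)
        else:
            positions.append(hit.start_tss_rel if axis == "start" else hit.anchor_tss_rel)
        scores.append(hit.score)
    return _build_distribution(element, axis, positions, scores)


def spacing_distribution(
    calls: Iterable[CompositeCall], element: str
) -> PositionalDistribution:
    """Distribution of a dependent element's start on the anchor-A+1 axis.

    Consumes composite calls, so orphan hits (no qualifying initiator) are
    excluded by construction.
    """
    positions: list[int] = []
    scores: list[float] = []
    for c in calls:
        if c.dependent.element != element:
            continue
        positions.append(c.spacing)
        scores.append(c.dependent.score)
    return _build_distribution(element, "spacing", positions, scores)


def qc_summary(distributions: Iterable[PositionalDistribution]) -> list[QcSummary]:
    """Modal position, modal fraction and +/-2 concentration per element.

    The mode is the position with maximal fraction; ties resolve toward the
    position nearest the hit-weighted mean of the axis (then the smaller
    position), so a flat profile reports its central position rather than an
    edge. Concentration counts hits whose position lies within 2 bases of
    the mode on the linearized axis (the zero-free labels are first mapped
    to base offsets, so a window never gains a free position by straddling
    the missing 0); unoccupied positions contribute nothing.
    """
    summaries: list[QcSummary] = []
    for dist in distributions:
        if dist.total_hits == 0:
            summaries.append(
                QcSummary(
                    element=dist.element,
                    axis=dist.axis,
                    total_hits=0,
                    modal_position=None,
                    modal_fraction_pct=0.0,
                    concentration_pct=0.0,
                )
            )
            continue
        t = dist.table
        lin = t["position"].map(_linear)
        max_frac = t["fraction_pct"].max()
        tied = t["fraction_pct"] >= max_frac - 1e-12
        center = float((lin * t["n"]).sum()) / dist.total_hits
        cand = t[tied].assign(_lin=lin[tied])
        cand = cand.assign(_dist=(cand["_lin"] - center).abs())
        best = cand.sort_values(["_dist", "position"], kind="mergesort").iloc[0]
        mode = int(best["position"])
        mode_lin = _linear(mode)
        near = t.loc[(lin - mode_lin).abs() <= 2, "n"].sum()
        summaries.append(
            QcSummary(
                element=dist.element,
                axis=dist.axis,
                total_hits=dist.total_hits,
                modal_position=mode,
                modal_fraction_pct=float(best["fraction_pct"]),
                concentration_pct=100.0 * float(near) / dist.total_hits,
            )
        )
    return summaries


def compare_datasets(
    datasets: Mapping[str, Iterable[PositionalDistribution]],
) -> pd.DataFrame:
    """Rank datasets by positional concentration, element by element.

    Returns a long-format frame with one row per (element, dataset) carrying
    the QC summary columns, plus ``winner`` — the dataset with the highest
    +/-2 concentration for that element (the dataset whose TSS positions are
    most consistent with the element's spacing constraint).
    """
    rows = []
    for ds_name, dists in datasets.items():
        for s in qc_summary(list(dists)):
            rows.append(
                {
                    "element": s.element,
                    "dataset": ds_name,
                    "axis": s.axis,
                    "total_hits": s.total_hits,
                    "modal_position": s.modal_position,
                    "modal_fraction_pct": s.modal_fraction_pct,
                    "concentration_pct": s.concentration_pct,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    winners = (
        df.sort_values(["concentration_pct", "dataset"], ascending=[False, True], kind="mergesort")
        .groupby("element", sort=False)
        .first()["dataset"]
    )
    df["winner"] = df["element"].map(winners)
    return df.sort_values(["element", "dataset"], kind="mergesort").reset_index(drop=True)


def export_distribution_table(
    distributions: Iterable[PositionalDistribution], path
) -> None:
    """Write distributions as a long-format, plot-ready TSV.

    Columns: element, axis, position, n, fraction_pct, mean_score,
    median_score — the data matrix behind a heat-colored positional bar
    plot. An empty list yields a header-only file.
    """
    frames = []
    for dist in distributions:
        t = dist.table.copy()
        t.insert(0, "axis", dist.axis)
        t.insert(0, "element", dist.element)
        frames.append(t)
    if frames:
        out = pd.concat(frames, ignore_index=True)[_TABLE_COLUMNS]
    else:
        out = pd.DataFrame(columns=_TABLE_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_distribution_table(path) -> list[PositionalDistribution]:
    """Inverse of :func:`export_distribution_table` (at 6-digit precision)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise MotifModelError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (element, axis), grp in df.groupby(["element", "axis"], sort=False):
        table = grp[["position", "n", "fraction_pct", "mean_score", "median_score"]].reset_index(
            drop=True
        )
        out.append(
            PositionalDistribution(
                element=element,
                axis=axis,
                table=table,
                total_hits=int(table["n"].sum()),
            )
        )
    return out
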