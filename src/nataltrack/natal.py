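"""Hatch-region assignment from hatch-day occupancy grids.

Converts the final (hatch-day) occupancy grid of a backtracked larva
into north/south region probabilities, applies the Best-estimate or
certainty-threshold decision rules, and builds revised training sets
(optionally restricted to larvae < 8 mm TL, the sizes treated as purely
passive drifters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nataltrack.flowfield import M_PER_DEG_LAT, RegionPartition
from nataltrack.backtrack import CaptureRecord, OccupancyGrid

THRESHOLDS = ("best", 0.60, 0.70, 0.80, 0.90)
UNASSIGNED = "unassigned"


@dataclass
class NatalAssignment:
    """Region probabilities and per-rule decisions for one record."""

    record_id: str
    p_north: float
    p_south: float
    p_out: float
    best_region: str
    assigned: dict                 # threshold ("best" or float) -> label
    null_region: str
    total_length_mm: float = float("nan")

    def __post_init__(self):
        if abs(self.p_north + self.p_south + self.p_out - 1.0) > 1e-9:
            raise ValueError("region probabilities must sum to 1")


def null_assign(records, partition: RegionPartition | None = None):
    """Label each record by its capture latitude (the null condition)."""
    partition = partition or RegionPartition()
    return [str(partition.label_of_latitude(r.capture_lat)) for r in records]


def _grid_latitudes(grid: OccupancyGrid):
    return grid.origin_lat + grid.y_axis / M_PER_DEG_LAT


def region_probability(hatch_day_grid: np.ndarray, grid: OccupancyGrid,
                       partition: RegionPartition | None = None):
    """Sum hatch-day cell probabilities north/south of the boundary.

    A cell is north iff its centre latitude is strictly above the
    boundary; any deficit from 1 (freeze-policy out-of-domain mass) is
    reported as ``p_out`` and belongs to neither region.
    """
    partition = partition or RegionPartition()
    lats = _grid_latitudes(grid)
    north_rows = lats > partition.boundary_latitude
    p_north = float(hatch_day_grid[north_rows].sum())
    p_south = float(hatch_day_grid[~north_rows].sum())
    p_out = max(0.0, 1.0 - p_north - p_south)
    return p_north, p_south, p_out


def _best_region(hatch_day_grid, grid, partition):
    """Region of the single most probable hatch cell.

    Ties between equal-probability cells in different regions fall back
    to the larger summed region probability; a full tie is unassigned.
    """
    lats = _grid_latitudes(grid)
    north_rows = lats > partition.boundary_latitude
    pmax = hatch_day_grid.max()
    iy, _ = np.nonzero(hatch_day_grid == pmax)
    modal_north = set(north_rows[iy])
    if len(modal_north) == 1:
        return partition.north_label if modal_north.pop() \
            else partition.south_label
    p_n, p_s, _ = region_probability(hatch_day_grid, grid, partition)
    if p_n > p_s:
        return partition.north_label
    if p_s > p_n:
        return partition.south_label
    return UNASSIGNED


def assign(p_north: float, p_south: float, threshold,
           best_region: str | None = None,
           partition: RegionPartition | None = None) -> str:
    """Apply one decision rule to region probabilities.

    ``threshold`` is ``"best"`` (most probable single cell, passed in as
    ``best_region``) or a certainty τ: the region whose summed
    probability reaches τ, else unassigned.
    """
    partition = partition or RegionPartition()
    if threshold == "best":
        if best_region is None:
            raise ValueError("best-rule assignment needs best_region")
        return best_region
    tau = float(threshold)
    if p_north >= tau:
        return partition.north_label
    if p_south >= tau:
        return partition.south_label
    return UNASSIGNED


def assign_record(record: CaptureRecord, grid: OccupancyGrid,
                  partition: RegionPartition | None = None,
                  thresholds=THRESHOLDS) -> NatalAssignment:
    """Full assignment for one backtracked record (all decision rules)."""
    partition = partition or RegionPartition()
    hatch = grid.hatch_day_grid
    p_n, p_s, p_out = region_probability(hatch, grid, partition)
    best = _best_region(hatch, grid, partition)
    decided = {}
    for tau in thresholds:
        decided[tau] = assign(p_n, p_s, tau, best_region=best,
                              partition=partition)
    return NatalAssignment(
        record_id=record.id, p_north=p_n, p_south=p_s, p_out=p_out,
        best_region=best, assigned=decided,
        null_region=str(partition.label_of_latitude(record.capture_lat)),
        total_length_mm=record.total_length_mm)


def revise_training_set(records, assignments, threshold,
                        size_cutoff_mm: float | None = None,
                        partition: RegionPartition | None = None):
    """Build the revised reference set for one scenario.

    Retains records that received a region at ``threshold`` (``"best"``,
    a τ, or ``None`` for the null scenario) and, when ``size_cutoff_mm``
    is given, are shorter than the cutoff.  Returns
    ``(labels_by_record_id, summary_dict)`` where the summary reports n
    retained and the percentage labelled north.
    """
    partition = partition or RegionPartition()
    amap = {a.record_id: a for a in assignments}
    labels = {}
    for rec in records:
        if size_cutoff_mm is not None and \
                not rec.total_length_mm < size_cutoff_mm:
            continue
        if threshold is None:       # null scenario: capture label
            labels[rec.id] = str(partition.label_of_latitude(rec.capture_lat))
            continue
        a = amap.get(rec.id)
        if a is None:
            continue
        label = a.assigned.get(threshold, UNASSIGNED)
        if label != UNASSIGNED:
            labels[rec.id] = label
    n = len(labels)
    n_north = sum(1 for v in labels.values() if v == partition.north_label)
    summary = {
        "scenario": "null" if threshold is None else str(threshold),
        "size_cutoff_mm": size_cutoff_mm,
        "n_retained": n,
        "pct_north": 100.0 * n_north / n if n else float("nan"),
        "empty": n == 0,
    }
    return labels, summary


def assignment_table(assignments) -> pd.DataFrame:
    """Flatten assignments to a tidy table (one row per record)."""
    rows = []
    for a in assignments:
        row = {"id": a.record_id, "p_NS": a.p_north, "p_SS": a.p_south,
               "p_out": a.p_out, "best": a.best_region,
               "null_region": a.null_region, "TL_mm": a.total_length_mm}
        for tau, label in a.assigned.items():
            if tau != "best":
                row[f"assigned@{tau:.2f}"] = label
        rows.append(row)
    return pd.DataFrame(rows)
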