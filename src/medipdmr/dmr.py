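"""DMR calling: seed windows, edge extension, merging and feature annotation.

A DMR starts from any genomic window whose differential p-value is strictly
below the seed threshold.  Its edges are then extended until no window with
p < 0.1 remains within 1000 bp of the DMR boundary ("within" inclusive, gap
measured between the boundary coordinate and the candidate window's nearest
edge).  Seeds whose extensions touch or overlap are merged, so a DMR set is
always non-overlapping and genome-ordered.

Because every seed threshold used here is below the 0.1 extension level, the
set of windows reachable by extension does not depend on the seed threshold;
tightening the threshold can only remove DMRs, never split or create them.
This is the monotonicity behind the threshold sweep tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Edge-extension p-value level.
EXTENSION_P = 0.1

#: Neighborhood distance for edge extension (bp).
NEIGHBOR_DISTANCE = 1000

DMR_COLUMNS = [
    "name", "chrom", "start", "end", "length", "n_windows",
    "n_significant_windows", "min_p", "cpg_count", "cpg_density",
    "control_fraction", "direction",
]


def find_seeds(results: pd.DataFrame, seed_p: float) -> np.ndarray:
    """Indices of windows with p strictly below the seed threshold."""
    return np.flatnonzero(results["p_value"].to_numpy() < seed_p)


@dataclass
class DMRSet:
    """A called set of DMRs together with its defining thresholds."""

    dmrs: pd.DataFrame
    seed_p: float
    extension_p: float = EXTENSION_P
    neighbor_distance: int = NEIGHBOR_DISTANCE
    label: str = ""

    def __len__(self) -> int:
        return len(self.dmrs)

    @property
    def n_multiple_window(self) -> int:
        """DMRs containing at least two windows significant at the seed level."""
        if not len(self.dmrs):
            return 0
        return int((self.dmrs["n_significant_windows"] >= 2).sum())


def _components(
    starts: np.ndarray,
    ends: np.ndarray,
    p: np.ndarray,
    seed_p: float,
    extension_p: float,
    neighbor_bp: int,
) -> list[tuple[int, int]]:
    """Seed-containing runs of extendable windows for one chromosome.

    Windows are sorted, non-overlapping.  Extension absorbs any window with
    p below the extension (or seed) level whose nearest edge is within
    ``neighbor_bp`` of the current boundary; iterating to a fixed point is
    equivalent to chaining consecutive extendable windows whose gaps are all
    <= ``neighbor_bp`` (the rescan oracle in the test-suite checks this).
    Returns (first_window_index, last_window_index) spans of components that
    contain at least one seed.
    """
    ext = np.flatnonzero((p < extension_p) | (p < seed_p))
    if ext.size == 0:
        return []
    gaps = starts[ext[1:]] - ends[ext[:-1]]
    breaks = np.flatnonzero(gaps > neighbor_bp)
    comp_bounds = np.concatenate(([0], breaks + 1, [ext.size]))
    out = []
    is_seed = p < seed_p
    for a, b in zip(comp_bounds[:-1], comp_bounds[1:]):
        members = ext[a:b]
        if is_seed[members].any():
            out.append((int(members[0]), int(members[-1])))
    return out


def extend_and_merge(
    results: pd.DataFrame,
    seed_p: float,
    extension_p: float = EXTENSION_P,
    neighbor_distance: int = NEIGHBOR_DISTANCE,
    label: str = "",
) -> DMRSet:
    """Call DMRs from a genome-ordered window test result table.

    ``results`` needs ``chrom``, ``start``, ``end``, ``p_value`` columns and,
    for full feature annotation, ``depth_control``/``depth_total`` (from
    :func:`medipdmr.difftest.window_test`) and ``cpg_count``.  Windows of the
    DMR are all result windows lying inside the merged coordinate span, which
    may include interior windows above the extension level.
    """
    records = []
    for chrom, sub in results.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        p = sub["p_value"].to_numpy()
        for i0, i1 in _components(starts, ends, p, seed_p, extension_p, neighbor_distance):
            span_start = int(starts[i0])
            span_end = int(ends[i1])
            members = sub.iloc[i0 : i1 + 1]
            records.append(_annotate_dmr(str(chrom), span_start, span_end, members, seed_p))
    dmrs = pd.DataFrame(records, columns=DMR_COLUMNS)
    return DMRSet(
        dmrs=dmrs, seed_p=seed_p, extension_p=extension_p,
        neighbor_distance=neighbor_distance, label=label,
    )


def _annotate_dmr(
    chrom: str, start: int, end: int, members: pd.DataFrame, seed_p: float
) -> dict:
    """Feature annotation for one DMR from its member windows.

    Direction is read off the control share of the summed normalized depth
    over the *significant* member windows: a control fraction above 0.5 means
    the exposure group lost depth (methylation decrease), below 0.5 a gain
    (increase); exactly 0.5 is flagged "unchanged".
    """
    p = members["p_value"].to_numpy()
    sig = p < seed_p
    length = end - start
    rec = {
        "name": f"{chrom}:{start + 1}",  # 1-based display name
        "chrom": chrom,
        "start": start,
        "end": end,
        "length": length,
        "n_windows": len(members),
        "n_significant_windows": int(sig.sum()),
        "min_p": float(p.min()),
    }
    if "cpg_count" in members.columns:
        cpg = int(members["cpg_count"].sum())
        rec["cpg_count"] = cpg
        rec["cpg_density"] = cpg / (length / 100.0)
    else:
        rec["cpg_count"] = np.nan
        rec["cpg_density"] = np.nan
    if {"depth_control", "depth_total"} <= set(members.columns) and sig.any():
        dc = float(members.loc[sig, "depth_control"].sum())
        dt = float(members.loc[sig, "depth_total"].sum())
        cf = dc / dt if dt > 0 else float("nan")
        rec["control_fraction"] = cf
        if np.isnan(cf) or cf == 0.5:
            rec["direction"] = "unchanged"
        elif cf < 0.5:
            rec["direction"] = "increase"
        else:
            rec["direction"] = "decrease"
    else:
        rec["control_fraction"] = np.nan
        rec["direction"] = "unchanged"
    return rec


def threshold_sweep(
    results: pd.DataFrame,
    thresholds: Sequence[float],
    extension_p: float = EXTENSION_P,
    neighbor_distance: int = NEIGHBOR_DISTANCE,
) -> pd.DataFrame:
    """DMR counts at a sweep of seed thresholds (the shape of a Table-1 panel).

    Returns one row per threshold with the all-window DMR count and the
    multiple-window count (DMRs with >= 2 windows below the seed threshold).
    Counts are non-increasing as the threshold tightens.
    """
    rows = []
    for thr in thresholds:
        ds = extend_and_merge(results, thr, extension_p, neighbor_distance)
        rows.append({
            "threshold": thr,
            "n_dmrs": len(ds),
            "n_multiple_window": ds.n_multiple_window,
        })
    return pd.DataFrame(rows)
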