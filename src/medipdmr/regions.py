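"""Chromosomal DMR clusters, DMR-set overlaps, and gene association.

Cluster detection is a fixed-span sliding binomial scan: windows of width
``span`` (default 5 Mb) stepped by half a span are tested for an excess of
DMR midpoints against Binomial(n_total, span / genome_length), BH-corrected
across all scanned windows; overlapping significant windows are merged into
maximal regions, and a reported cluster must hold at least two DMRs.

Interval distance is 0 when two intervals intersect, otherwise the gap
between their nearest edges; overlap of flank-extended DMRs and the 10 kb
gene-association rule both build on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .difftest import bh_adjust
from .dmr import DMRSet

GENE_FLANK = 10_000
CLUSTER_SPAN = 5_000_000


def _as_frame(dmrset) -> pd.DataFrame:
    return dmrset.dmrs if isinstance(dmrset, DMRSet) else dmrset


def interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """0 if [a_start, a_end) and [b_start, b_end) intersect, else the gap."""
    if a_start < b_end and b_start < a_end:
        return 0
    return b_start - a_end if b_start >= a_end else a_start - b_end


def scan_clusters(
    dmrset,
    chrom_sizes: Mapping[str, int],
    span: int = CLUSTER_SPAN,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Sliding binomial scan for chromosomal over-representation of DMRs.

    Returns one row per merged significant region: coordinates, the DMR
    count inside, the expected count under uniform placement, the raw
    binomial upper-tail p of the best scan window, and its BH adjustment.
    """
    dmrs = _as_frame(dmrset)
    if span <= 0:
        raise ValueError("span must be > 0")
    n_total = len(dmrs)
    if n_total == 0:
        raise ValueError("scan_clusters requires at least one DMR")
    genome_len = float(sum(chrom_sizes.values()))
    mids = ((dmrs["start"] + dmrs["end"]) // 2).to_numpy()
    chroms = dmrs["chrom"].to_numpy()

    scan_rows = []
    step = max(1, span // 2)
    for chrom, length in chrom_sizes.items():
        length = int(length)
        starts = np.arange(0, max(length - span, 0) + 1, step, dtype=np.int64)
        if starts.size == 0:
            starts = np.array([0], dtype=np.int64)  # chromosome shorter than span
        cmids = np.sort(mids[chroms == str(chrom)])
        for s in starts:
            e = min(s + span, length)
            c = int(np.searchsorted(cmids, e) - np.searchsorted(cmids, s))
            prob = (e - s) / genome_len
            pval = float(stats.binom.sf(c - 1, n_total, prob)) if c > 0 else 1.0
            scan_rows.append((str(chrom), int(s), int(e), c, n_total * prob, pval))
    scan = pd.DataFrame(
        scan_rows, columns=["chrom", "start", "end", "n_dmrs", "expected", "p_value"]
    )
    scan["adjusted_p"] = bh_adjust(scan["p_value"].to_numpy())
    hits = scan[(scan["adjusted_p"] <= alpha) & (scan["n_dmrs"] >= 2)]

    merged = []
    for chrom, sub in hits.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for row in sub.itertuples():
            if cur is not None and row.start <= cur["end"]:
                cur["end"] = max(cur["end"], row.end)
                cur["p_value"] = min(cur["p_value"], row.p_value)
                cur["adjusted_p"] = min(cur["adjusted_p"], row.adjusted_p)
            else:
                if cur is not None:
                    merged.append(cur)
                cur = {"chrom": chrom, "start": row.start, "end": row.end,
                       "p_value": row.p_value, "adjusted_p": row.adjusted_p}
        if cur is not None:
            merged.append(cur)
    out = pd.DataFrame(merged, columns=["chrom", "start", "end", "p_value", "adjusted_p"])
    if len(out):
        counts, expect = [], []
        for row in out.itertuples():
            cmids = mids[chroms == row.chrom]
            counts.append(int(((cmids >= row.start) & (cmids < row.end)).sum()))
            expect.append(n_total * (row.end - row.start) / genome_len)
        out.insert(3, "n_dmrs", counts)
        out.insert(4, "expected", expect)
        out = out[out["n_dmrs"] >= 2].reset_index(drop=True)
    else:
        out.insert(3, "n_dmrs", pd.Series(dtype=int))
        out.insert(4, "expected", pd.Series(dtype=float))
    return out


@dataclass
class OverlapReport:
    """Venn-style overlap counts between up to three DMR sets.

    ``membership[label]`` maps a sorted tuple of set labels (always including
    ``label`` itself) to the number of that set's DMRs whose flank-extended
    interval intersects exactly those sets.  Counting is per-DMR of each set
    in turn, so the report carries both directions of every asymmetric
    many-to-many overlap; the first listed set is the headline counting unit.
    """

    labels: list[str]
    flank: int
    membership: dict[str, dict[tuple[str, ...], int]] = field(default_factory=dict)

    def set_size(self, label: str) -> int:
        return sum(self.membership[label].values())

    def exclusive(self, label: str) -> int:
        return self.membership[label].get((label,), 0)

    def shared(self, label: str, *others: str) -> int:
        """Count of ``label`` DMRs overlapping all of ``others`` (at least)."""
        need = set(others)
        return sum(
            c for combo, c in self.membership[label].items() if need <= set(combo)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"unit_set": lab, "overlap_with": "&".join(combo), "count": c}
            for lab in self.labels
            for combo, c in sorted(self.membership[lab].items())
        ]
        return pd.DataFrame(rows, columns=["unit_set", "overlap_with", "count"])


class _IntervalIndex:
    """Sorted-start + cummax-end index answering interval intersection."""

    def __init__(self, df: pd.DataFrame, flank: int = 0):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            s = sub["start"].to_numpy(dtype=np.int64) - flank
            e = sub["end"].to_numpy(dtype=np.int64) + flank
            order = np.argsort(s, kind="stable")
            s, e = s[order], e[order]
            self.by_chrom[str(chrom)] = (s, np.maximum.accumulate(e), e)

    def intersects(self, chrom: str, start: int, end: int) -> bool:
        entry = self.by_chrom.get(str(chrom))
        if entry is None:
            return False
        s, cummax_e, _ = entry
        i = int(np.searchsorted(s, end, side="left"))  # intervals starting before `end`
        return i > 0 and cummax_e[i - 1] > start


def overlap_sets(sets: Sequence, flank: int = 0, labels: Sequence[str] | None = None) -> OverlapReport:
    """Venn overlap between 1-3 DMR sets with optional flank extension.

    Two DMRs overlap iff their intervals, each widened by ``flank`` bp on
    both sides, intersect on the same chromosome.
    """
    frames = [_as_frame(s) for s in sets]
    if not 1 <= len(frames) <= 3:
        raise ValueError("overlap_sets takes 1-3 DMR sets")
    if labels is None:
        labels = [
            getattr(s, "label", "") or f"set{i + 1}" for i, s in enumerate(sets)
        ]
    labels = list(labels)
    indexes = [_IntervalIndex(f, flank=flank) for f in frames]
    report = OverlapReport(labels=labels, flank=flank)
    for i, (lab, df) in enumerate(zip(labels, frames)):
        combos: dict[tuple[str, ...], int] = {}
        for row in df.itertuples():
            hit = [lab]
            for j, other in enumerate(indexes):
                if j == i:
                    continue
                if other.intersects(row.chrom, row.start - flank, row.end + flank):
                    hit.append(labels[j])
            key = tuple(sorted(hit, key=labels.index))
            combos[key] = combos.get(key, 0) + 1
        report.membership[lab] = combos
    return report


def associate_genes(
    dmrset,
    genes: pd.DataFrame,
    flank: int = GENE_FLANK,
) -> tuple[pd.DataFrame, float]:
    """Genes within ``flank`` bp of each DMR, plus the percent of DMRs with >= 1.

    ``genes`` needs ``chrom``/``start``/``end`` and optionally ``name``
    columns.  Distance 0 means intersection; the default 10 kb flank follows
    the promoter-scale association convention.  Returns the DMR table with a
    ``genes`` column (``;``-joined names) and ``n_genes``, and the percentage
    of DMRs with at least one associated gene.
    """
    dmrs = _as_frame(dmrset).copy()
    if "name" not in genes.columns:
        genes = genes.assign(name=[f"gene{i+1}" for i in range(len(genes))])
    by_chrom = {
        str(c): (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64),
                 sub["name"].to_numpy())
        for c, sub in genes.groupby("chrom", sort=False)
    }
    assoc, n_genes = [], []
    for row in dmrs.itertuples():
        entry = by_chrom.get(str(row.chrom))
        if entry is None:
            assoc.append("")
            n_genes.append(0)
            continue
        gs, ge, gn = entry
        hit = (gs <= row.end + flank) & (ge >= row.start - flank)
        # exclude pure-touch cases that exceed the flank once gap is computed
        names = []
        for s, e, name in zip(gs[hit], ge[hit], gn[hit]):
            if interval_distance(row.start, row.end, int(s), int(e)) <= flank:
                names.append(str(name))
        assoc.append(";".join(names))
        n_genes.append(len(names))
    dmrs["genes"] = assoc
    dmrs["n_genes"] = n_genes
    pct = 100.0 * float(np.mean(np.array(n_genes) > 0)) if len(dmrs) else 0.0
    return dmrs, pct
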