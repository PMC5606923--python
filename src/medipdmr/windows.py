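"""Fixed-width genome windows, CpG annotation, and fragment counting.

The analysis unit throughout the package is a fixed 100 bp genomic window.
Windows are 0-based half-open (BED convention) and tile each chromosome
completely; the final window of a chromosome is truncated to the chromosome
end rather than dropped, and is flagged via ``end - start < window_size``.

Read counting follows MeDIP fragment-coverage semantics: each aligned read is
extended to the sonication fragment length (default 300 bp) from its 5' end,
strand-aware, and increments *every* window its extended fragment overlaps —
not midpoint assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Window width used throughout the pipeline (bp).
WINDOW_SIZE = 100

#: Sonication target fragment length used for read extension (bp).
FRAGMENT_EXTENSION = 300

WINDOW_COLUMNS = ["chrom", "start", "end"]


def partition_genome(
    chrom_sizes: Mapping[str, int] | Sequence[tuple[str, int]],
    window_size: int = WINDOW_SIZE,
) -> pd.DataFrame:
    """Tile each chromosome with fixed-width windows.

    Parameters
    ----------
    chrom_sizes
        Mapping (or ``(name, length)`` pairs) of chromosome name to length in
        bp.  Chromosome order is preserved in the output.
    window_size
        Window width in bp (>= 1).

    Returns
    -------
    DataFrame with columns ``chrom``, ``start``, ``end``; per chromosome of
    length ``L`` there are ``ceil(L / window_size)`` windows, the last one
    truncated to ``L``.  A zero-length chromosome contributes no windows.
    """
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    pairs = list(chrom_sizes.items()) if isinstance(chrom_sizes, Mapping) else list(chrom_sizes)
    names = [c for c, _ in pairs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names in chrom_sizes")
    frames = []
    for chrom, length in pairs:
        length = int(length)
        if length < 0:
            raise ValueError(f"negative length for chromosome {chrom!r}")
        if length == 0:
            continue
        starts = np.arange(0, length, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, length)
        frames.append(pd.DataFrame({"chrom": str(chrom), "start": starts, "end": ends}))
    if not frames:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    return pd.concat(frames, ignore_index=True)


def annotate_cpg(
    windows: pd.DataFrame,
    cpg_positions: Mapping[str, np.ndarray] | pd.DataFrame,
) -> pd.DataFrame:
    """Attach CpG counts and densities (per 100 bp) to a window table.

    ``cpg_positions`` is either a mapping ``chrom -> sorted 0-based position
    array`` or a DataFrame with ``chrom``/``pos`` (or ``chrom``/``start``)
    columns.  A CpG at position ``p`` belongs to the window with
    ``start <= p < end``.  Positions at or beyond the chromosome end (last
    window end) are rejected.
    """
    if isinstance(cpg_positions, pd.DataFrame):
        pos_col = "pos" if "pos" in cpg_positions.columns else "start"
        by_chrom = {
            str(c): np.asarray(sub[pos_col], dtype=np.int64)
            for c, sub in cpg_positions.groupby("chrom", sort=False)
        }
    else:
        by_chrom = {str(c): np.asarray(v, dtype=np.int64) for c, v in cpg_positions.items()}

    out = windows.copy()
    counts = np.zeros(len(out), dtype=np.int64)
    for chrom, idx in out.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        pos = np.sort(by_chrom.get(str(chrom), np.empty(0, dtype=np.int64)))
        if pos.size:
            chrom_end = int(out.loc[idx, "end"].max())
            if pos.min() < 0 or pos.max() >= chrom_end:
                raise ValueError(
                    f"CpG position outside chromosome {chrom!r} (length {chrom_end})"
                )
            starts = out.loc[idx, "start"].to_numpy()
            ends = out.loc[idx, "end"].to_numpy()
            counts[idx] = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)
    out["cpg_count"] = counts
    out["cpg_density"] = counts / ((out["end"] - out["start"]) / 100.0)
    return out


@dataclass
class CountMatrix:
    """Window x sample read counts plus sample metadata.

    Attributes
    ----------
    windows
        Window table (``chrom``, ``start``, ``end`` and optionally
        ``cpg_count``/``cpg_density``), genome-ordered.
    samples
        One row per sample; must carry an ``id`` column.  Conventional extra
        columns: ``lineage`` (control/exposure), ``generation`` (F1/F2/F3),
        ``phenotypes`` (``;``-joined labels), ``pool``.
    counts
        Integer array of shape ``(n_windows, n_samples)``.
    """

    windows: pd.DataFrame
    samples: pd.DataFrame
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.counts.shape != (len(self.windows), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.windows)} windows x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if "id" not in self.samples.columns:
            raise ValueError("samples table requires an 'id' column")
        if self.samples["id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        self.samples = self.samples.reset_index(drop=True)
        self.windows = self.windows.reset_index(drop=True)
        self.samples = self.samples.assign(library_size=self.counts.sum(axis=0))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["id"])

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample totals (always equal to the column sums)."""
        return self.counts.sum(axis=0)

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        """Column indices for the given sample ids (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.samples["id"])}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return np.array([lookup[s] for s in ids], dtype=np.intp)

    def ids_where(self, **conditions) -> list[str]:
        """Sample ids matching equality conditions on metadata columns."""
        mask = np.ones(len(self.samples), dtype=bool)
        for col, val in conditions.items():
            mask &= (self.samples[col] == val).to_numpy()
        return list(self.samples.loc[mask, "id"])


def _extend_reads(reads: pd.DataFrame, fragment_extension: int) -> tuple[np.ndarray, np.ndarray]:
    """5'-anchored fragment extension; strand-aware when a strand column exists."""
    starts = reads["start"].to_numpy(dtype=np.int64)
    if "strand" in reads.columns:
        strand = reads["strand"].astype(str).to_numpy()
        if "end" in reads.columns:
            ends_in = reads["end"].to_numpy(dtype=np.int64)
        else:
            ends_in = starts + 1
        minus = strand == "-"
        ext_start = np.where(minus, ends_in - fragment_extension, starts)
        ext_end = ext_start + fragment_extension
    else:
        ext_start = starts
        ext_end = starts + fragment_extension
    return ext_start, ext_end


def count_reads(
    reads_by_sample: Mapping[str, pd.DataFrame],
    windows: pd.DataFrame,
    fragment_extension: int = FRAGMENT_EXTENSION,
    samples: pd.DataFrame | None = None,
) -> tuple[CountMatrix, dict[str, int]]:
    """Build the window x sample count matrix from aligned read positions.

    Each read (``chrom``, ``start`` and optionally ``end``, ``strand``) is
    extended to ``fragment_extension`` bp from its 5' end (rightward when no
    strand is given), clipped to the chromosome, and incremented into every
    window the extended fragment overlaps.  Reads on chromosomes absent from
    the window table are logged and skipped; the per-sample skip counts are
    returned alongside the matrix.
    """
    chrom_info: dict[str, tuple[int, int, int]] = {}
    offset = 0
    for chrom, sub in windows.groupby("chrom", sort=False):
        n = len(sub)
        length = int(sub["end"].max())
        chrom_info[str(chrom)] = (offset, n, length)
        offset += n
    window_size = int((windows["end"] - windows["start"]).max()) if len(windows) else 1

    sample_names = list(reads_by_sample)
    counts = np.zeros((len(windows), len(sample_names)), dtype=np.int64)
    skipped: dict[str, int] = {}
    for j, name in enumerate(sample_names):
        reads = reads_by_sample[name]
        n_skip = 0
        if len(reads):
            known = reads["chrom"].astype(str).map(lambda c: c in chrom_info)
            n_skip = int((~known).sum())
            reads = reads.loc[known.to_numpy()]
        skipped[name] = n_skip
        if n_skip:
            logger.warning("sample %s: skipped %d reads on unknown chromosomes", name, n_skip)
        for chrom, sub in (reads.groupby("chrom", sort=False) if len(reads) else []):
            off, nwin, length = chrom_info[str(chrom)]
            s, e = _extend_reads(sub, fragment_extension)
            s = np.clip(s, 0, length)
            e = np.clip(e, 0, length)
            keep = e > s
            s, e = s[keep], e[keep]
            first = s // window_size
            last = (e - 1) // window_size
            # extension < a few window widths: loop over the small per-read span
            max_span = int((last - first).max()) + 1 if len(s) else 0
            for k in range(max_span):
                idx = first + k
                sel = idx <= last
                np.add.at(counts[:, j], off + idx[sel], 1)
    meta = samples if samples is not None else pd.DataFrame({"id": sample_names})
    return CountMatrix(windows=windows.copy(), samples=meta.copy(), counts=counts), skipped
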