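"""Readers and writers for the pipeline's plain-text formats.

All genomic coordinates are 0-based half-open (BED convention).  The count
matrix TSV has a first column of window ids ``chrom:start-end`` and one
column per sample; sample metadata lives in a ``<stem>.samples.tsv`` sidecar
so the matrix itself stays a plain numeric table.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .windows import CountMatrix

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column ``name<TAB>length`` file, order preserved."""
    out: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, length = line.split()[:2]
        if name in out:
            raise ValueError(f"duplicate chromosome {name!r} in {path}")
        out[name] = int(length)
    return out


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    Path(path).write_text("".join(f"{c}\t{l}\n" for c, l in sizes.items()))


def read_bed(path) -> pd.DataFrame:
    """BED3-BED6 as a DataFrame; missing trailing columns are omitted."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = BED6_COLUMNS[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    """Matrix TSV (window id + per-sample counts) and samples sidecar."""
    path = Path(path)
    w = matrix.windows
    ids = w["chrom"].astype(str) + ":" + w["start"].astype(str) + "-" + w["end"].astype(str)
    table = pd.DataFrame(matrix.counts, columns=matrix.sample_ids)
    table.insert(0, "window", ids.to_numpy())
    table.to_csv(path, sep="\t", index=False)
    matrix.samples.to_csv(_samples_sidecar(path), sep="\t", index=False)


def _samples_sidecar(path: Path) -> Path:
    return path.with_suffix(".samples.tsv")


_WINDOW_ID = re.compile(r"^(.+):(\d+)-(\d+)$")


def read_count_matrix(path) -> CountMatrix:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"window": str})
    parsed = table["window"].str.extract(_WINDOW_ID)
    windows = pd.DataFrame({
        "chrom": parsed[0],
        "start": parsed[1].astype(np.int64),
        "end": parsed[2].astype(np.int64),
    })
    counts = table.drop(columns="window").to_numpy(dtype=np.int64)
    sidecar = _samples_sidecar(path)
    if sidecar.exists():
        samples = pd.read_csv(sidecar, sep="\t", dtype={"id": str}).fillna("")
    else:
        samples = pd.DataFrame({"id": list(table.columns[1:])})
    return CountMatrix(windows=windows, samples=samples, counts=counts)


def read_cohort(path) -> pd.DataFrame:
    """Cohort TSV; ``+`` / ``-`` / blank cells map to the package's call coding."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    meta_cols = {"animal_id", "lineage", "generation", "sex"}
    for col in df.columns:
        if col in meta_cols:
            continue
        vals = set(df[col].unique())
        if vals <= {"+", "-", ""}:
            df[col] = df[col].map({"+": "present", "-": "absent", "": "not-examined"})
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    meta_cols = {"animal_id", "lineage", "generation", "sex"}
    for col in out.columns:
        if col in meta_cols:
            continue
        vals = set(map(str, out[col].unique()))
        if vals <= {"present", "absent", "not-examined"}:
            out[col] = out[col].map({"present": "+", "absent": "-", "not-examined": ""})
    out.to_csv(path, sep="\t", index=False)


def read_reads(path) -> pd.DataFrame:
    """Aligned read intervals from BED or SAM (mapped primary records)."""
    path = Path(path)
    if path.suffix.lower() in (".sam", ".bam"):
        import pysam

        rows = []
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                rows.append((
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end or rec.reference_start + rec.query_length,
                    "-" if rec.is_reverse else "+",
                ))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return read_bed(path)


def read_genes(path) -> pd.DataFrame:
    """Gene intervals from BED or GFF3 (``gene`` features only)."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        rows = []
        for line in path.read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or f"{f[0]}:{f[3]}"
            # GFF3 is 1-based inclusive; convert to 0-based half-open
            rows.append((f[0], int(f[3]) - 1, int(f[4]), name))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return read_bed(path)


def write_dmr_set(dmrset, prefix) -> tuple[Path, Path]:
    """DMR BED (score = -log10 min p) plus the full-feature TSV."""
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    tsv_path = prefix.with_suffix(".tsv")
    df = dmrset.dmrs.copy()
    with np.errstate(divide="ignore"):
        score = np.where(df["min_p"] > 0, -np.log10(df["min_p"]), 999.0)
    bed = df[["chrom", "start", "end", "name"]].assign(score=np.round(score, 4))
    write_bed(bed, bed_path)
    df.to_csv(tsv_path, sep="\t", index=False)
    return bed_path, tsv_path


def write_truth_bed(truth: pd.DataFrame, path) -> None:
    """Planted-DMR ledger as BED with the fold change in the score column."""
    bed = truth[["chrom", "start", "end"]].copy()
    bed["name"] = truth["direction"] + ":" + truth["phenotype"].replace("", "any")
    bed["score"] = truth["fold_change"]
    write_bed(bed, path)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(obj, path) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def write_manifest(path, stage: str, params: Mapping) -> None:
    """Plain-text run manifest: stage, package version, parameters.

    Deliberately carries no timestamps so identical runs stay byte-identical.
    """
    from . import __version__

    lines = [f"stage\t{stage}", f"medipdmr_version\t{__version__}"]
    for k, v in params.items():
        lines.append(f"{k}\t{v}")
    Path(path).write_text("\n".join(lines) + "\n")
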