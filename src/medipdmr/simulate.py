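"""Synthetic genomes, MeDIP-like count matrices and pathology cohorts.

The generator emulates the statistical structure the pipeline assumes:

* a CpG-desert genome (modal window density ~1.5 CpG / 100 bp) with a small
  fraction of high-density island patches;
* negative-binomial window counts (Var = mu + phi mu^2; phi = 0 is Poisson)
  with lognormal per-sample library-size variation;
* planted DMRs — short runs of windows whose exposure-group (or carrier)
  mean is multiplied or divided by a fold change;
* cohorts of animals with binary phenotype calls, where a phenotype can be
  deterministically linked to carrying a subset of the planted DMRs so that
  signature recovery can be measured against ground truth.

All randomness flows from a single integer seed through named sub-streams
(one ``numpy.random.SeedSequence`` child per stage, in a fixed order), so
identical configurations reproduce byte-identical outputs and each stage is
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .windows import CountMatrix, partition_genome

# fixed order of the per-stage random sub-streams
_STREAMS = ("genome", "counts", "cohort", "measures")


@dataclass
class PlantedDMR:
    """A planted differentially methylated region, in window coordinates."""

    chrom: str
    start_window: int
    n_windows: int
    fold_change: float
    direction: str = "increase"

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")
        if self.direction not in ("increase", "decrease"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the scaled-down study conditions the package is tested
    under: two 2.5 Mb chromosomes of 100 bp windows (5e4 windows), 6 samples
    per group at a mean window depth of 30 reads, NB dispersion 0.1, and 20%
    library-size variation.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 2_500_000
    window_size: int = 100
    cpg_rate_desert: float = 1.5       # CpG per 100 bp outside islands
    cpg_island_fraction: float = 0.02  # fraction of windows in island patches
    cpg_rate_island: float = 10.0      # CpG per 100 bp inside islands
    n_samples_per_group: int = 6
    mean_depth: float = 30.0           # reads per window per sample
    dispersion: float = 0.1            # NB phi >= 0
    library_size_cv: float = 0.2
    generation: str = "F3"
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    phenotype_link: dict[str, list[int]] = field(default_factory=dict)
    disease_frequencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chrom_length < self.window_size:
            raise ValueError("chrom_length must be >= window_size")
        if self.window_size < 1 or self.chrom_length < 1:
            raise ValueError("non-positive lengths rejected")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for label, freq in self.disease_frequencies.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"frequency for {label!r} outside [0, 1]")
        for label, idxs in self.phenotype_link.items():
            if label not in self.disease_frequencies:
                raise ValueError(f"phenotype_link label {label!r} has no frequency")
            for i in idxs:
                if not 0 <= i < len(self.planted_dmrs):
                    raise ValueError(f"phenotype_link index {i} out of range")
        self._check_planted_disjoint()

    def _check_planted_disjoint(self) -> None:
        spans: dict[str, list[tuple[int, int]]] = {}
        for d in self.planted_dmrs:
            spans.setdefault(d.chrom, []).append((d.start_window, d.start_window + d.n_windows))
        for chrom, ivs in spans.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping planted DMRs on {chrom}")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chrom)}

    def rng(self, stream: str) -> np.random.Generator:
        """Stage generator derived from the global seed via a named sub-stream."""
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS.index(stream)])


@dataclass
class SimOutput:
    """Everything one simulation produces, plus the ground-truth ledger."""

    config: SimConfig
    windows: pd.DataFrame           # chrom/start/end/cpg_count/cpg_density
    cpg_positions: pd.DataFrame     # chrom/pos, consistent with window counts
    matrix: CountMatrix
    truth: pd.DataFrame             # planted-DMR ledger (coords, fold, phenotype)
    cohort: pd.DataFrame


def simulate_genome(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the window table with CpG counts and the CpG position list.

    Island membership is drawn per window patch (geometric patch lengths,
    mean 10 windows) until the configured fraction of windows is covered;
    CpG counts are Poisson at the desert or island rate.  Positions are
    placed uniformly within their window so the BED output and the window
    counts agree exactly.
    """
    rng = config.rng("genome")
    windows = partition_genome(config.chrom_sizes, config.window_size)
    n = len(windows)
    island = np.zeros(n, dtype=bool)
    target = int(round(config.cpg_island_fraction * n))
    while island.sum() < target:
        start = int(rng.integers(0, n))
        length = 1 + int(rng.geometric(1 / 10.0))
        island[start : start + length] = True
    widths = (windows["end"] - windows["start"]).to_numpy()
    rate = np.where(island, config.cpg_rate_island, config.cpg_rate_desert)
    counts = rng.poisson(rate * widths / 100.0)
    windows = windows.assign(
        cpg_count=counts, cpg_density=counts / (widths / 100.0), island=island
    )
    pos_frames = []
    starts = windows["start"].to_numpy()
    chroms = windows["chrom"].to_numpy()
    nz = np.flatnonzero(counts)
    for i in nz:
        offs = np.sort(rng.integers(0, widths[i], size=counts[i]))
        pos_frames.append(pd.DataFrame({"chrom": chroms[i], "pos": starts[i] + offs}))
    cpg = (
        pd.concat(pos_frames, ignore_index=True)
        if pos_frames
        else pd.DataFrame({"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=np.int64)})
    )
    return windows, cpg


def _window_global_indices(config: SimConfig, d: PlantedDMR) -> np.ndarray:
    wins_per_chrom = -(-config.chrom_length // config.window_size)
    chrom_ord = list(config.chrom_sizes)
    if d.chrom not in chrom_ord:
        raise ValueError(f"planted DMR on unknown chromosome {d.chrom!r}")
    off = chrom_ord.index(d.chrom) * wins_per_chrom
    if d.start_window + d.n_windows > wins_per_chrom:
        raise ValueError("planted DMR extends past chromosome end")
    return off + d.start_window + np.arange(d.n_windows)


def simulate_counts(
    config: SimConfig,
    windows: pd.DataFrame,
    carriers: Mapping[int, Sequence[str]] | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw the NB count matrix and return it with the true-DMR ledger.

    Samples are named ``C1..Cn`` (control lineage) and ``E1..En`` (exposure
    lineage).  ``carriers`` maps a planted-DMR index to the sample ids that
    receive its fold change; by default every exposure sample carries every
    planted DMR, and control samples never do.  Counts are gamma-Poisson
    draws with per-sample lognormal library factors (mean 1, CV as
    configured).
    """
    rng = config.rng("counts")
    n = config.n_samples_per_group
    sample_ids = [f"C{i+1}" for i in range(n)] + [f"E{i+1}" for i in range(n)]
    lineage = ["control"] * n + ["exposure"] * n
    exposure_ids = sample_ids[n:]

    if config.library_size_cv > 0:
        sigma2 = np.log1p(config.library_size_cv**2)
        lib_factor = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=2 * n)
    else:
        lib_factor = np.ones(2 * n)

    n_win = len(windows)
    mean = np.full((n_win, 2 * n), float(config.mean_depth), dtype=float)
    truth_rows = []
    link_of = {i: lab for lab, idxs in config.phenotype_link.items() for i in idxs}
    for di, d in enumerate(config.planted_dmrs):
        gidx = _window_global_indices(config, d)
        carry = list(carriers.get(di, exposure_ids)) if carriers is not None else exposure_ids
        cols = [sample_ids.index(s) for s in carry]
        fold = d.fold_change if d.direction == "increase" else 1.0 / d.fold_change
        mean[np.ix_(gidx, cols)] *= fold
        truth_rows.append({
            "chrom": d.chrom,
            "start": int(windows.iloc[gidx[0]]["start"]),
            "end": int(windows.iloc[gidx[-1]]["end"]),
            "n_windows": d.n_windows,
            "fold_change": d.fold_change,
            "direction": d.direction,
            "phenotype": link_of.get(di, ""),
            "carriers": ";".join(carry),
        })
    mean = mean * lib_factor[None, :]

    phi = config.dispersion
    if phi == 0:
        counts = rng.poisson(mean)
    else:
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
        counts = rng.poisson(lam)

    samples = pd.DataFrame({
        "id": sample_ids,
        "lineage": lineage,
        "generation": config.generation,
        "pool": "",
        "phenotypes": "",
    })
    matrix = CountMatrix(windows=windows, samples=samples, counts=counts)
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "start", "end", "n_windows", "fold_change",
                 "direction", "phenotype", "carriers"],
    )
    return matrix, truth


def simulate_cohort(config: SimConfig, carrier_sets: Mapping[str, set[str]] | None = None) -> pd.DataFrame:
    """Per-animal binary phenotype calls (one animal per sperm sample).

    Unlinked phenotypes are independent Bernoulli draws at the configured
    frequency (control and exposure animals alike for simplicity of the null;
    the pipeline's incidence statistics compare lineages downstream).
    Phenotypes named in ``phenotype_link`` are instead set by carrier status:
    ``carrier_sets[label]`` gives the positive animals.
    """
    rng = config.rng("cohort")
    n = config.n_samples_per_group
    ids = [f"C{i+1}" for i in range(n)] + [f"E{i+1}" for i in range(n)]
    lineage = ["control"] * n + ["exposure"] * n
    cohort = pd.DataFrame({
        "animal_id": ids,
        "lineage": lineage,
        "generation": config.generation,
        "sex": "male",
    })
    for label, freq in sorted(config.disease_frequencies.items()):
        if label in config.phenotype_link:
            carriers = carrier_sets.get(label, set()) if carrier_sets else set()
            calls = [aid in carriers for aid in ids]
        else:
            calls = rng.random(len(ids)) < freq
        cohort[label] = np.where(calls, "present", "absent")
    return cohort


def _draw_carriers(config: SimConfig) -> tuple[dict[str, set[str]], dict[int, list[str]]]:
    """Assign linked-phenotype carrier animals among the exposure lineage."""
    rng = config.rng("measures")
    n = config.n_samples_per_group
    exposure_ids = [f"E{i+1}" for i in range(n)]
    carrier_sets: dict[str, set[str]] = {}
    per_dmr: dict[int, list[str]] = {}
    for label in sorted(config.phenotype_link):
        freq = config.disease_frequencies[label]
        k = int(round(freq * n))
        chosen = list(rng.choice(exposure_ids, size=k, replace=False)) if k else []
        carrier_sets[label] = set(chosen)
        for di in config.phenotype_link[label]:
            per_dmr[di] = sorted(carrier_sets[label])
    return carrier_sets, per_dmr


def simulate(config: SimConfig) -> SimOutput:
    """Full simulation: genome, counts with planted truth, and cohort."""
    windows, cpg = simulate_genome(config)
    carrier_sets, per_dmr = _draw_carriers(config)
    matrix, truth = simulate_counts(config, windows, carriers=per_dmr or None)
    cohort = simulate_cohort(config, carrier_sets=carrier_sets)
    phen = {aid: [] for aid in cohort["animal_id"]}
    for label in config.disease_frequencies:
        for aid, call in zip(cohort["animal_id"], cohort[label]):
            if call == "present":
                phen[aid].append(label)
    matrix.samples["phenotypes"] = [";".join(phen[a]) for a in matrix.samples["id"]]
    return SimOutput(
        config=config, windows=windows, cpg_positions=cpg,
        matrix=matrix, truth=truth, cohort=cohort,
    )


def plant_random_dmrs(
    config: SimConfig,
    n_dmrs: int,
    n_windows: int = 5,
    fold_change: float = 4.0,
    direction: str = "increase",
    min_gap_windows: int = 25,
    seed: int | None = None,
) -> SimConfig:
    """Return a config with ``n_dmrs`` non-overlapping DMRs planted at random.

    Regions are separated by at least ``min_gap_windows`` windows (default
    2.5 kb at 100 bp windows) so that edge extension cannot bridge distinct
    planted regions and recovery counting stays unambiguous.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    wins_per_chrom = -(-config.chrom_length // config.window_size)
    chroms = list(config.chrom_sizes)
    stride = n_windows + min_gap_windows
    slots = [
        (c, s)
        for c in chroms
        for s in range(0, wins_per_chrom - n_windows, stride)
    ]
    if n_dmrs > len(slots):
        raise ValueError("genome too small for the requested number of planted DMRs")
    chosen = rng.choice(len(slots), size=n_dmrs, replace=False)
    planted = [
        PlantedDMR(chrom=slots[i][0], start_window=slots[i][1],
                   n_windows=n_windows, fold_change=fold_change, direction=direction)
        for i in sorted(chosen)
    ]
    return replace(config, planted_dmrs=planted)
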