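"""Within-lineage disease epimutation signatures and their permutation null.

A signature is simply the DMR set from running the full window-test +
edge-extension pipeline on case versus non-case individuals of the exposed
lineage (seed threshold p < 1e-5 for both the lean and testis-disease
signatures).  Its significance is assessed by regrouping the same animals at
random into two groups of the original sizes, re-running the pipeline
``n_perm`` times (default 20), and reporting the add-one empirical p-value

    p = (1 + #{null counts >= observed}) / (n_perm + 1)

so that an observed count exceeding all 20 null counts gives p = 1/21 < 0.05
and the p-value can never be zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .difftest import estimate_common_dispersion, window_test
from .dmr import EXTENSION_P, NEIGHBOR_DISTANCE, DMRSet, extend_and_merge
from .regions import OverlapReport, overlap_sets
from .windows import CountMatrix

N_PERMUTATIONS = 20
SIGNATURE_SEED_P = 1e-5


@dataclass
class SignatureComparison:
    """A case / non-case split of individuals for signature derivation.

    The non-case group is conventionally cleaned of animals carrying any
    other scored disease before construction (as for the study's testis
    comparison); this class only enforces disjointness.
    """

    phenotype: str
    case_ids: list[str]
    noncase_ids: list[str]
    seed_p: float = SIGNATURE_SEED_P

    def __post_init__(self) -> None:
        if set(self.case_ids) & set(self.noncase_ids):
            raise ValueError("case and non-case groups overlap")
        if len(self.case_ids) < 2 or len(self.noncase_ids) < 2:
            raise ValueError("need >= 2 samples on each side of the comparison")


@dataclass
class PermutationResult:
    phenotype: str
    observed: int
    null_counts: list[int]
    n_perm: int
    empirical_p: float
    null_mean: float
    seed: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "phenotype": [self.phenotype],
            "observed_dmrs": [self.observed],
            "null_mean": [self.null_mean],
            "null_max": [max(self.null_counts)],
            "n_perm": [self.n_perm],
            "empirical_p": [self.empirical_p],
        })


def build_signature(
    matrix: CountMatrix,
    comparison: SignatureComparison,
    phi: float | None = None,
    extension_p: float = EXTENSION_P,
    neighbor_distance: int = NEIGHBOR_DISTANCE,
) -> DMRSet:
    """Case vs non-case DMR set at the comparison's seed threshold.

    The non-case group plays the "control" role, so a DMR direction of
    "increase" means cases gained methylation (read depth).  Swapping the
    two groups changes only direction labels, never the DMR count.
    """
    results = window_test(matrix, comparison.noncase_ids, comparison.case_ids, phi=phi)
    if "cpg_count" in matrix.windows.columns:
        results = results.assign(cpg_count=matrix.windows["cpg_count"].to_numpy())
    return extend_and_merge(
        results, comparison.seed_p, extension_p, neighbor_distance,
        label=comparison.phenotype,
    )


def permutation_null(
    matrix: CountMatrix,
    comparison: SignatureComparison,
    n_perm: int = N_PERMUTATIONS,
    seed: int = 0,
    phi: float | None = None,
    reestimate_phi: bool = False,
) -> PermutationResult:
    """Random-regrouping null distribution of the signature DMR count.

    Case and non-case ids are pooled; ``n_perm`` distinct regroupings
    preserving the two group sizes (and differing from the observed
    labeling) are drawn, and the pipeline is re-run on each.  By default the
    common dispersion is estimated once from the observed comparison and
    reused across permutations, keeping the null and the observed statistic
    on the same model; pass ``reestimate_phi=True`` to re-fit per draw.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pool = list(comparison.case_ids) + list(comparison.noncase_ids)
    n_case = len(comparison.case_ids)
    if n_case >= len(pool):
        raise ValueError("case group size must be smaller than the pooled set")
    if phi is None:
        phi = estimate_common_dispersion(
            matrix, [comparison.case_ids, comparison.noncase_ids]
        ).phi

    observed = len(build_signature(matrix, comparison, phi=phi))

    rng = np.random.default_rng(seed)
    seen = {frozenset(comparison.case_ids)}
    draws: list[list[str]] = []
    attempts = 0
    while len(draws) < n_perm:
        attempts += 1
        if attempts > 1000 * n_perm:
            raise RuntimeError("could not draw enough distinct regroupings")
        perm = rng.permutation(pool)
        key = frozenset(perm[:n_case])
        if key in seen:
            continue
        seen.add(key)
        draws.append(list(perm[:n_case]))

    null_counts = []
    for case in draws:
        noncase = [s for s in pool if s not in set(case)]
        cmp = SignatureComparison(
            phenotype=f"{comparison.phenotype}-perm",
            case_ids=case, noncase_ids=noncase, seed_p=comparison.seed_p,
        )
        null_counts.append(
            len(build_signature(matrix, cmp, phi=None if reestimate_phi else phi))
        )

    empirical_p = (1 + sum(c >= observed for c in null_counts)) / (n_perm + 1)
    return PermutationResult(
        phenotype=comparison.phenotype,
        observed=observed,
        null_counts=null_counts,
        n_perm=n_perm,
        empirical_p=float(empirical_p),
        null_mean=float(np.mean(null_counts)),
        seed=seed,
    )


def signature_overlap(sets, flank: int = 0, labels=None) -> OverlapReport:
    """Overlap report between signatures (and optionally the lineage DMR set)."""
    return overlap_sets(sets, flank=flank, labels=labels)


def pool_and_subsample(
    matrix: CountMatrix,
    pools: dict[str, list[str]],
    target_total: int,
    seed: int = 0,
    equalize: bool = True,
) -> CountMatrix:
    """In-silico pooling of samples followed by hypergeometric subsampling.

    ``pools`` maps a pool id to its member sample ids (the members must not
    repeat across pools).  With ``equalize=True`` each member column is first
    downsampled (without replacement across windows) to the smallest member
    total — the in-silico analogue of pooling equivalent amounts of DNA —
    then member columns are summed, and each pooled column is subsampled to
    exactly ``target_total`` reads via a multivariate hypergeometric draw.
    Pooling before subsampling conserves member totals exactly.
    """
    rng = np.random.default_rng(seed)
    all_members = [s for members in pools.values() for s in members]
    if len(set(all_members)) != len(all_members):
        raise ValueError("pools must not share member samples")
    cols = []
    meta_rows = []
    for pool_id, members in pools.items():
        idx = matrix.sample_index(members)
        sub = matrix.counts[:, idx]
        totals = sub.sum(axis=0)
        if equalize and len(members) > 1:
            floor = int(totals.min())
            eq = np.empty_like(sub)
            for j in range(sub.shape[1]):
                eq[:, j] = _subsample_column(sub[:, j], floor, rng)
            sub = eq
        pooled = sub.sum(axis=1)
        pooled_total = int(pooled.sum())
        if target_total > pooled_total:
            raise ValueError(
                f"target_total {target_total} exceeds pooled total {pooled_total} "
                f"for pool {pool_id!r}"
            )
        cols.append(_subsample_column(pooled, target_total, rng))
        lineages = matrix.samples.loc[idx, "lineage"].unique() if "lineage" in matrix.samples else ["" ]
        meta_rows.append({
            "id": pool_id,
            "lineage": lineages[0] if len(lineages) == 1 else "mixed",
            "generation": matrix.samples.loc[idx[0], "generation"] if "generation" in matrix.samples else "",
            "pool": ";".join(members),
            "phenotypes": "",
        })
    counts = np.stack(cols, axis=1)
    return CountMatrix(
        windows=matrix.windows.copy(),
        samples=pd.DataFrame(meta_rows),
        counts=counts,
    )


def _subsample_column(column: np.ndarray, target: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``target`` reads without replacement across windows (exact total)."""
    total = int(column.sum())
    if target == total:
        return column.copy()
    if target > total:
        raise ValueError("cannot subsample above the column total")
    return rng.multivariate_hypergeometric(
        column.astype(np.int64), target, method="marginals"
    )
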