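"""Cohort phenotype classification rules and frequency statistics.

Disease calls follow a control-referenced threshold rule: a tissue is
diseased when its abnormality count exceeds the control mean plus two sample
standard deviations (strictly; the primordial-follicle-loss variant uses the
control mean minus two SD).  Lean / obese metabolic classification uses the
control mean +/- 1.5 SD on adipocyte area or BMI, with strict inequalities
at both cutoffs so boundary values are "normal".  Incidence statistics
tabulate animals with exactly one versus two-or-more diseases, compared
between lineages with Fisher's exact test; continuous measures use
Student's t (pooled variance; Welch behind a flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: SD multiplier for control-referenced disease calls.
DISEASE_K_SD = 2.0

#: SD multiplier for the lean / obese metabolic cutoffs.
METABOLIC_K_SD = 1.5

#: Published adipocyte-area cutoffs (lean_cut, obese_cut), reported in "um"
#: by the source study, carried as given.
ADIPOCYTE_AREA_CUTOFFS: dict[str, tuple[float, float]] = {
    "female": (2671.0, 3912.0),
    "male": (2425.0, 3912.0),
}

#: Published BMI cutoffs in g/cm^2 (lean_cut, obese_cut) per sex.
BMI_CUTOFFS: dict[str, tuple[float, float]] = {
    "female": (0.6040, 0.7763),
    "male": (0.7894, 0.9954),
}

PRESENT, ABSENT, NOT_EXAMINED = "present", "absent", "not-examined"


@dataclass
class PhenotypeCutoffs:
    """(lean_cut, obese_cut) pair for one metric; lean_cut < obese_cut."""

    lean_cut: float
    obese_cut: float

    def __post_init__(self) -> None:
        if not self.lean_cut < self.obese_cut:
            warnings.warn("degenerate cutoffs: lean_cut >= obese_cut", stacklevel=2)


def disease_call_high(
    control_values: Sequence[float],
    test_value: float,
    k: float = DISEASE_K_SD,
    side: str = "high",
) -> str:
    """Control mean +/- k*SD threshold rule for a disease call.

    ``side="high"`` flags values strictly above mean + k*SD (histopathology
    abnormality counts, cyst counts); ``side="low"`` flags values strictly
    below mean - k*SD (primordial follicle loss).  Sample (n-1) SD is used.
    """
    vals = np.asarray([v for v in control_values if v == v], dtype=float)
    if vals.size < 2:
        raise ValueError("need >= 2 control values for a disease call")
    mean = vals.mean()
    sd = vals.std(ddof=1)
    if side == "high":
        return PRESENT if test_value > mean + k * sd else ABSENT
    if side == "low":
        return PRESENT if test_value < mean - k * sd else ABSENT
    raise ValueError(f"unknown side {side!r}")


def derive_cutoffs(control_values: Sequence[float], k: float = METABOLIC_K_SD) -> PhenotypeCutoffs:
    """(mean - k*SD, mean + k*SD) of the control population (sample SD)."""
    vals = np.asarray(list(control_values), dtype=float)
    if vals.size < 2:
        raise ValueError("need >= 2 control values to derive cutoffs")
    mean = vals.mean()
    sd = vals.std(ddof=1)
    if sd == 0:
        warnings.warn("constant control values: cutoffs collapse to the mean", stacklevel=2)
    return PhenotypeCutoffs(lean_cut=mean - k * sd, obese_cut=mean + k * sd)


def classify_metabolic(value: float | None, cutoffs: PhenotypeCutoffs | tuple[float, float]) -> str:
    """lean / normal / obese by strict inequality; boundaries are normal."""
    if value is None or value != value:
        return NOT_EXAMINED
    lean_cut, obese_cut = (
        (cutoffs.lean_cut, cutoffs.obese_cut)
        if isinstance(cutoffs, PhenotypeCutoffs)
        else cutoffs
    )
    if value < lean_cut:
        return "lean"
    if value > obese_cut:
        return "obese"
    return "normal"


def adipocyte_mean_area(per_image_areas: Sequence[Sequence[float]], top_n: int = 20) -> float:
    """Mean of the ``top_n`` largest cell areas from each image.

    Five images of 20 cells each give the conventional 100-cell average.
    An image with fewer than ``top_n`` cells contributes all of them (with a
    warning).
    """
    if len(per_image_areas) == 0:
        raise ValueError("need at least one image")
    chosen: list[float] = []
    for areas in per_image_areas:
        areas = sorted(areas, reverse=True)
        if len(areas) < top_n:
            warnings.warn(
                f"image with only {len(areas)} cells (< top_n={top_n}); using all",
                stacklevel=2,
            )
        chosen.extend(areas[:top_n])
    return float(np.mean(chosen))


def bmi(weight_g: float, length_cm: float) -> float:
    """Body mass index, weight (g) / length (cm)^2."""
    if length_cm <= 0:
        raise ValueError("length must be > 0")
    return weight_g / length_cm**2


def weight_per_dna(sample_weight_ug: float, dna_ug: float) -> float:
    """Adiposity proxy: fat-sample weight (ug) per DNA content (ug)."""
    if dna_ug <= 0:
        raise ValueError("DNA quantity must be > 0")
    return sample_weight_ug / dna_ug


def _normalize_call(value) -> str:
    if isinstance(value, str):
        v = value.strip()
        if v in ("+", PRESENT):
            return PRESENT
        if v in ("-", ABSENT):
            return ABSENT
        if v in ("", NOT_EXAMINED):
            return NOT_EXAMINED
        raise ValueError(f"unrecognized disease call {value!r}")
    if value is None or value != value:
        return NOT_EXAMINED
    return PRESENT if bool(value) else ABSENT


def disease_counts(cohort: pd.DataFrame, disease_columns: Sequence[str]) -> pd.Series:
    """Number of disease categories called present per animal."""
    calls = cohort[list(disease_columns)].map(_normalize_call)
    return (calls == PRESENT).sum(axis=1)


def incidence(
    cohort: pd.DataFrame,
    disease_columns: Sequence[str],
    group_by: Sequence[str] = ("lineage",),
) -> pd.DataFrame:
    """Single (exactly 1) and multiple (>= 2) disease incidence per group.

    Animals with every category not-examined still count in the group total;
    per-category denominators are a per-test concern handled by the caller.
    The tallies conserve: zero + single + multiple = group size.
    """
    n_dis = disease_counts(cohort, disease_columns)
    out = []
    for key, sub in cohort.groupby(list(group_by), sort=False):
        if not isinstance(key, tuple):
            key = (key,)
        nd = n_dis.loc[sub.index]
        total = len(sub)
        single = int((nd == 1).sum())
        multiple = int((nd >= 2).sum())
        rec = dict(zip(group_by, key))
        rec.update({
            "n_animals": total,
            "n_zero": total - single - multiple,
            "n_single": single,
            "n_multiple": multiple,
            "single_rate": single / total if total else float("nan"),
            "multiple_rate": multiple / total if total else float("nan"),
        })
        out.append(rec)
    return pd.DataFrame(out)


def fisher_test(affected_a: int, total_a: int, affected_b: int, total_b: int) -> float:
    """Two-sided Fisher's exact p for affected/total in two groups."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("group totals must be > 0")
    if affected_a > total_a or affected_b > total_b:
        raise ValueError("affected count exceeds total")
    table = [[affected_a, total_a - affected_a], [affected_b, total_b - affected_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sample t-test (pooled variance by default, Welch behind a flag).

    Degenerate zero-variance inputs with equal means return (0.0, 1.0)
    with a warning rather than NaN.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            warnings.warn("zero variance in both groups with equal means", stacklevel=2)
            return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def compare_incidence(
    cohort: pd.DataFrame,
    disease_columns: Sequence[str],
    lineage_col: str = "lineage",
    control_label: str = "control",
) -> pd.DataFrame:
    """Per-disease and single/multiple incidence with Fisher p vs control.

    Each disease category's denominator excludes not-examined animals for
    that category.  Returns one row per (lineage, statistic).
    """
    lineages = list(cohort[lineage_col].unique())
    if control_label not in lineages:
        raise ValueError(f"no {control_label!r} animals in cohort")
    rows = []
    ctrl = cohort[cohort[lineage_col] == control_label]
    inc = incidence(cohort, disease_columns, group_by=(lineage_col,))
    inc = inc.set_index(lineage_col)
    for lin in lineages:
        sub = cohort[cohort[lineage_col] == lin]
        for col in disease_columns:
            calls = sub[col].map(_normalize_call)
            examined = calls != NOT_EXAMINED
            aff, tot = int((calls == PRESENT).sum()), int(examined.sum())
            c_calls = ctrl[col].map(_normalize_call)
            c_exam = c_calls != NOT_EXAMINED
            c_aff, c_tot = int((c_calls == PRESENT).sum()), int(c_exam.sum())
            p = (
                fisher_test(aff, tot, c_aff, c_tot)
                if lin != control_label and tot and c_tot
                else float("nan")
            )
            rows.append({
                lineage_col: lin, "statistic": col,
                "affected": aff, "total": tot, "fisher_p": p,
            })
        for stat, n_col in (("single_disease", "n_single"), ("multiple_disease", "n_multiple")):
            aff = int(inc.loc[lin, n_col])
            tot = int(inc.loc[lin, "n_animals"])
            c_aff = int(inc.loc[control_label, n_col])
            c_tot = int(inc.loc[control_label, "n_animals"])
            p = fisher_test(aff, tot, c_aff, c_tot) if lin != control_label else float("nan")
            rows.append({
                lineage_col: lin, "statistic": stat,
                "affected": aff, "total": tot, "fisher_p": p,
            })
    return pd.DataFrame(rows)
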