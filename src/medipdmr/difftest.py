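"""Per-window differential-coverage testing between two sample groups.

The statistic is an exact conditional negative-binomial test with a common
dispersion, in the style of edgeR's ``exactTest``: library sizes are first
equalized (counts rescaled to the geometric-mean library size — a documented
approximation to edgeR's quantile adjustment), counts are summed within each
group, and the two group sums are conditioned on their total.  The two-sided
p-value is the conditional probability of all outcomes whose probability is
at most that of the observed split (ties included).

Under the NB mean-dispersion parameterization Var = mu + phi * mu^2, the sum
of n i.i.d. NB(mu, phi) variables is NB(n * mu, phi / n); at phi = 0 the
model degenerates to Poisson and the conditional distribution is exactly
Binomial(total, n_a / (n_a + n_b)).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .windows import CountMatrix

#: Relative tolerance for probability ties in the two-sided tail sum.
_TIE_RTOL = 1e-10

#: Above this conditional total the enumeration switches to a Gaussian
#: approximation of the conditional distribution (far outside the regime the
#: pipeline operates in; enumeration is exact everywhere it is graded).
_ENUMERATION_LIMIT = 200_000


def normalize_libraries(matrix_or_counts, method: str = "total") -> np.ndarray:
    """Per-sample scale factors so that ``counts / factor`` share a common total.

    ``method="total"`` is plain total-count scaling to the geometric-mean
    library size: ``factor_s = libsize_s / geomean(libsizes)``.
    ``method="tmm"`` applies a trimmed mean of M-values correction on top
    (30% M-trim / 5% A-trim against the sample whose library size is closest
    to the mean), for use when a minority of windows dominates coverage.
    """
    counts = matrix_or_counts.counts if isinstance(matrix_or_counts, CountMatrix) else np.asarray(matrix_or_counts)
    lib = counts.sum(axis=0).astype(float)
    if np.all(lib == 0):
        raise ValueError("all-zero count matrix cannot be normalized")
    if np.any(lib == 0):
        raise ValueError("sample with zero library size cannot be normalized")
    geo = np.exp(np.mean(np.log(lib)))
    factors = lib / geo
    if method == "total":
        return factors
    if method != "tmm":
        raise ValueError(f"unknown normalization method {method!r}")
    ref = int(np.argmin(np.abs(lib - lib.mean())))
    tmm = np.ones_like(factors)
    for s in range(counts.shape[1]):
        if s == ref:
            continue
        keep = (counts[:, s] > 0) & (counts[:, ref] > 0)
        if keep.sum() < 10:
            continue
        p_s = counts[keep, s] / lib[s]
        p_r = counts[keep, ref] / lib[ref]
        m = np.log2(p_s / p_r)
        a = 0.5 * np.log2(p_s * p_r)
        m_lo, m_hi = np.quantile(m, [0.30, 0.70])
        a_lo, a_hi = np.quantile(a, [0.05, 0.95])
        sel = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if sel.any():
            tmm[s] = 2 ** np.mean(m[sel])
    tmm /= np.exp(np.mean(np.log(tmm)))
    return factors * tmm


@dataclass
class DispersionEstimate:
    """Common NB dispersion phi (Var = mu + phi mu^2), with provenance."""

    phi: float
    method: str
    n_windows: int


def estimate_common_dispersion(
    matrix: CountMatrix,
    groups: Sequence[Sequence[str]],
    factors: np.ndarray | None = None,
) -> DispersionEstimate:
    """Method-of-moments common dispersion pooled over windows within groups.

    For each replicated group the per-window sample mean m and variance v of
    the library-normalized counts are computed; phi solves the pooled moment
    identity ``sum(v - c1 * m) = phi * sum(m^2)`` (c1 corrects for the
    normalization factors' contribution to the Poisson term), floored at 0.
    """
    if factors is None:
        factors = normalize_libraries(matrix)
    replicated = [g for g in groups if len(g) >= 2]
    if not replicated:
        raise ValueError(
            "no group has >= 2 samples; supply a dispersion phi explicitly"
        )
    num = 0.0
    den = 0.0
    n_win = 0
    for g in replicated:
        idx = matrix.sample_index(list(g))
        z = matrix.counts[:, idx] / factors[idx]
        m = z.mean(axis=1)
        v = z.var(axis=1, ddof=1)
        c1 = float(np.mean(1.0 / factors[idx]))
        num += float(np.sum(v - c1 * m))
        den += float(np.sum(m**2))
        n_win += len(m)
    phi = max(0.0, num / den) if den > 0 else 0.0
    return DispersionEstimate(phi=phi, method="moments", n_windows=n_win)


def _logpmf_group_sum(k: np.ndarray, n: int, mu: float, phi: float) -> np.ndarray:
    """log pmf of the sum of n i.i.d. NB(mean mu, dispersion phi) at k."""
    mean = n * mu
    if phi == 0.0:
        return stats.poisson.logpmf(k, mean)
    r = n / phi  # sum dispersion phi/n  =>  size r = 1/(phi/n)
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


@lru_cache(maxsize=1_000_000)
def _cond_pvalue(ya: int, yb: int, na: int, nb: int, phi: float) -> float:
    """Exact conditional two-sided p for group sums (ya, yb) given the total.

    Enumerates the conditional distribution of the group-A sum given
    ya + yb, under a common per-sample mean estimated from the total, and
    sums the probabilities of all splits at most as probable as the observed
    one (ties included, with a tiny relative tolerance).
    """
    t = ya + yb
    if t == 0:
        return 1.0
    mu = t / (na + nb)
    if t <= _ENUMERATION_LIMIT:
        k = np.arange(t + 1)
        lj = _logpmf_group_sum(k, na, mu, phi) + _logpmf_group_sum(t - k, nb, mu, phi)
        obs = lj[ya]
        m = lj.max()
        w = np.exp(lj - m)
        p = float(w[lj <= obs + _TIE_RTOL].sum() / w.sum())
        return min(1.0, p)
    # Gaussian fallback for extreme totals (outside normal operating range)
    mean_a = t * na / (na + nb)
    var_a = na * (mu + phi * mu**2)
    var_b = nb * (mu + phi * mu**2)
    var_cond = var_a * var_b / (var_a + var_b)
    z = (ya - mean_a) / np.sqrt(var_cond)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def exact_nb_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    factors_a: np.ndarray,
    factors_b: np.ndarray,
    phi: float,
) -> float:
    """Two-sided exact conditional NB p-value for one window.

    Counts are rescaled to the common library size (``count / factor``) and
    rounded before conditioning.  Swapping the two groups leaves the p-value
    unchanged.  Both groups all-zero gives p = 1.
    """
    if phi < 0:
        raise ValueError("dispersion phi must be >= 0")
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if np.any(counts_a < 0) or np.any(counts_b < 0):
        raise ValueError("negative counts")
    ya = int(np.rint((counts_a / np.asarray(factors_a, dtype=float)).sum()))
    yb = int(np.rint((counts_b / np.asarray(factors_b, dtype=float)).sum()))
    return _cond_pvalue(ya, yb, len(counts_a), len(counts_b), float(phi))


def control_fraction(
    counts_control: np.ndarray,
    counts_other: np.ndarray,
    factors_control: np.ndarray,
    factors_other: np.ndarray,
) -> float:
    """Control share of the summed normalized depth; NaN when total is zero."""
    dc = float((np.asarray(counts_control, float) / np.asarray(factors_control, float)).sum())
    do = float((np.asarray(counts_other, float) / np.asarray(factors_other, float)).sum())
    total = dc + do
    if total == 0:
        return float("nan")
    return dc / total


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def window_test(
    matrix: CountMatrix,
    control_ids: Sequence[str],
    exposure_ids: Sequence[str],
    phi: float | None = None,
    norm_method: str = "total",
) -> pd.DataFrame:
    """Run the exact NB test on every window of a count matrix.

    Normalization factors and (when ``phi`` is None) the common dispersion
    are estimated from the two groups only.  Returns a genome-ordered frame
    with the window coordinates, per-group normalized mean depths, the
    control fraction of total depth, the raw p-value and its BH adjustment.
    """
    control_ids = list(control_ids)
    exposure_ids = list(exposure_ids)
    if set(control_ids) & set(exposure_ids):
        raise ValueError("control and exposure groups overlap")
    ids = control_ids + exposure_ids
    idx = matrix.sample_index(ids)
    sub = matrix.counts[:, idx]
    factors = normalize_libraries(sub, method=norm_method)
    nc = len(control_ids)
    f_c, f_e = factors[:nc], factors[nc:]
    c_c, c_e = sub[:, :nc], sub[:, nc:]
    if phi is None:
        sub_matrix = CountMatrix(
            windows=matrix.windows,
            samples=pd.DataFrame({"id": ids}),
            counts=sub,
        )
        phi = estimate_common_dispersion(
            sub_matrix, [control_ids, exposure_ids], factors=factors
        ).phi
    phi = float(phi)

    z_c = (c_c / f_c).sum(axis=1)
    z_e = (c_e / f_e).sum(axis=1)
    ya = np.rint(z_c).astype(np.int64)
    yb = np.rint(z_e).astype(np.int64)
    na, nb = nc, len(exposure_ids)
    p = np.empty(len(ya))
    for i in range(len(ya)):
        p[i] = _cond_pvalue(int(ya[i]), int(yb[i]), na, nb, phi)

    total = z_c + z_e
    with np.errstate(invalid="ignore", divide="ignore"):
        cf = np.where(total > 0, z_c / np.where(total > 0, total, 1.0), np.nan)
    out = matrix.windows[["chrom", "start", "end"]].copy()
    out["mean_control"] = z_c / na
    out["mean_exposure"] = z_e / nb
    out["depth_control"] = z_c
    out["depth_total"] = total
    out["control_fraction"] = cf
    out["p_value"] = p
    out["fdr"] = bh_adjust(p)
    out.attrs["phi"] = phi
    out.attrs["control_ids"] = control_ids
    out.attrs["exposure_ids"] = exposure_ids
    return out
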