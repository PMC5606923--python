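"""Independent brute-force oracles used by the test-suite.

Each oracle is deliberately written against different primitives than the
implementation it checks (math.lgamma instead of scipy pmfs, O(n^2) loops
instead of sorted sweeps, rescan-to-fixed-point instead of component
chaining), so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# exact conditional NB test
# ---------------------------------------------------------------------------

def _log_group_sum_pmf(k: int, n: int, mu: float, phi: float) -> float:
    """log pmf of the sum of n iid NB(mean mu, Var mu + phi mu^2) at k."""
    mean = n * mu
    if mean == 0:
        return 0.0 if k == 0 else -math.inf
    if phi == 0.0:
        return k * math.log(mean) - mean - math.lgamma(k + 1)
    r = n / phi
    p = r / (r + mean)
    return (
        math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
        + r * math.log(p) + k * math.log1p(-p)
    )


def enumerate_exact_p(ya: int, yb: int, na: int, nb: int, phi: float) -> float:
    """Full enumeration of the conditional two-sided p (ties included)."""
    t = ya + yb
    if t == 0:
        return 1.0
    mu = t / (na + nb)
    logs = [
        _log_group_sum_pmf(a, na, mu, phi) + _log_group_sum_pmf(t - a, nb, mu, phi)
        for a in range(t + 1)
    ]
    m = max(logs)
    probs = [math.exp(v - m) for v in logs]
    obs = probs[ya]
    tail = sum(p for p in probs if p <= obs * (1.0 + 1e-10))
    return min(1.0, tail / sum(probs))


# ---------------------------------------------------------------------------
# fragment counting
# ---------------------------------------------------------------------------

def count_reads_bruteforce(reads, windows, fragment_extension: int) -> np.ndarray:
    """O(reads x windows) interval-intersection tally for one sample.

    ``reads`` is a DataFrame with chrom/start and optional end/strand;
    ``windows`` a chrom/start/end frame.  Mirrors the documented 5'-anchored
    extension convention independently of the implementation's arithmetic.
    """
    counts = np.zeros(len(windows), dtype=np.int64)
    wc = windows["chrom"].to_numpy()
    ws = windows["start"].to_numpy()
    we = windows["end"].to_numpy()
    chrom_len = {c: int(we[wc == c].max()) for c in np.unique(wc)}
    for row in reads.itertuples():
        chrom = str(row.chrom)
        if chrom not in chrom_len:
            continue
        strand = getattr(row, "strand", "+")
        if strand == "-":
            end5 = getattr(row, "end", row.start + 1)
            s, e = end5 - fragment_extension, end5
        else:
            s, e = row.start, row.start + fragment_extension
        s = max(0, s)
        e = min(chrom_len[chrom], e)
        for i in range(len(windows)):
            if wc[i] == chrom and s < we[i] and ws[i] < e:
                counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# DMR edge extension
# ---------------------------------------------------------------------------

def extend_rescan_oracle(starts, ends, p, seed_p, extension_p=0.1, neighbor_bp=1000):
    """Rescan-to-fixed-point DMR extension for one chromosome.

    Starts one interval per seed window, then repeatedly rescans *all*
    windows: any window below the extension (or seed) level whose nearest
    edge lies within ``neighbor_bp`` of an interval is absorbed; touching or
    overlapping intervals are merged.  Iterates until nothing changes.
    Returns sorted (start, end) coordinate spans.
    """
    starts = np.asarray(starts)
    ends = np.asarray(ends)
    p = np.asarray(p)
    extendable = (p < extension_p) | (p < seed_p)
    intervals = [[int(starts[i]), int(ends[i])] for i in np.flatnonzero(p < seed_p)]
    if not intervals:
        return []
    ext_idx = np.flatnonzero(extendable)
    while True:
        before = [tuple(iv) for iv in intervals]
        for iv in intervals:
            for j in ext_idx:
                s, e = int(starts[j]), int(ends[j])
                if s >= iv[0] and e <= iv[1]:
                    continue
                if s < iv[1] and iv[0] < e:
                    gap = 0
                else:
                    gap = s - iv[1] if s >= iv[1] else iv[0] - e
                if gap <= neighbor_bp:
                    iv[0] = min(iv[0], s)
                    iv[1] = max(iv[1], e)
        intervals.sort()
        merged = [intervals[0][:]]
        for s, e in intervals[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        intervals = merged
        if [tuple(iv) for iv in intervals] == before:
            return [tuple(iv) for iv in intervals]


# ---------------------------------------------------------------------------
# interval overlap
# ---------------------------------------------------------------------------

def overlap_pairs_bruteforce(df_a, df_b, flank: int) -> np.ndarray:
    """For each interval of df_a: does any flank-extended df_b interval hit it?"""
    out = np.zeros(len(df_a), dtype=bool)
    for i, a in enumerate(df_a.itertuples()):
        for b in df_b.itertuples():
            if str(a.chrom) != str(b.chrom):
                continue
            if (a.start - flank) < (b.end + flank) and (b.start - flank) < (a.end + flank):
                out[i] = True
                break
    return out


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_enumeration(a: int, ta: int, b: int, tb: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Conditions on both margins of the 2x2 table [[a, ta-a], [b, tb-b]] and
    sums the probabilities of all tables no more probable than the observed.
    """
    k = a + b  # affected margin
    def log_table_prob(x: int) -> float:
        # x affected in group A out of ta, k-x in group B out of tb
        if x < 0 or x > ta or (k - x) < 0 or (k - x) > tb:
            return -math.inf
        return (
            math.lgamma(ta + 1) - math.lgamma(x + 1) - math.lgamma(ta - x + 1)
            + math.lgamma(tb + 1) - math.lgamma(k - x + 1) - math.lgamma(tb - k + x + 1)
        )
    logs = [log_table_prob(x) for x in range(0, k + 1)]
    finite = [v for v in logs if v > -math.inf]
    m = max(finite)
    probs = [math.exp(v - m) if v > -math.inf else 0.0 for v in logs]
    obs = probs[a]
    tail = sum(p for p in probs if p <= obs * (1.0 + 1e-9))
    return min(1.0, tail / sum(probs))


# ---------------------------------------------------------------------------
# random p-value landscapes for DMR-builder checks
# ---------------------------------------------------------------------------

def random_landscape(rng: np.random.Generator, n_windows: int = 80,
                     drop_fraction: float = 0.2, chrom: str = "chr1"):
    """A genome-ordered window result frame with a spiky p landscape.

    A fraction of windows is dropped to create coordinate gaps (as when
    empty windows are filtered), and p-values mix deep seeds (1e-12..1e-3),
    extension-level values (<0.1) and inert background.
    """
    import pandas as pd

    keep = rng.random(n_windows) > drop_fraction
    idx = np.flatnonzero(keep)
    starts = idx * 100
    ends = starts + 100
    u = rng.random(len(idx))
    p = np.where(
        u < 0.05, 10.0 ** rng.uniform(-12, -3, len(idx)),
        np.where(u < 0.20, rng.uniform(0, 0.1, len(idx)),
                 rng.uniform(0.1, 1.0, len(idx))),
    )
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "p_value": p})
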