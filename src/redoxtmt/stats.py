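"""Differential-oxidation inference and distribution summaries.

Per-site two-sample Student's t-tests, permutation-based FDR (q-values
estimated from balanced label permutations, Perseus-style), the
dual-criterion differential call (q < 0.1 with a p < 0.05 fallback when no
site passes, and a minimum 5-percentage-point change), one-way ANOVA with
Fisher's LSD pairwise tests, and Pearson correlation over shared sites.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import ChannelDesign, ParameterError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def _t_rows(x_a: np.ndarray, x_b: np.ndarray, equal_var: bool = True
            ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t over matrices with NaN as missing.

    Returns (t, df); rows with fewer than 2 valid values in either group get
    NaN. The zero-variance-both-groups convention is t=0 (equal means) or
    +/-inf (unequal means).
    """
    n_a = np.sum(~np.isnan(x_a), axis=1).astype(float)
    n_b = np.sum(~np.isnan(x_b), axis=1).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m_a = np.nanmean(x_a, axis=1)
        m_b = np.nanmean(x_b, axis=1)
        v_a = np.nanvar(x_a, axis=1, ddof=1)
        v_b = np.nanvar(x_b, axis=1, ddof=1)
    valid = (n_a >= 2) & (n_b >= 2)
    diff = m_a - m_b
    if equal_var:
        df = n_a + n_b - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            sp2 = ((n_a - 1) * v_a + (n_b - 1) * v_b) / df
            se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(v_a / n_a + v_b / n_b)
            df = se ** 4 / ((v_a / n_a) ** 2 / (n_a - 1)
                            + (v_b / n_b) ** 2 / (n_b - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / se
    # zero-variance conventions
    zero_se = valid & (se == 0)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_se & (diff == 0), 0.0, t)
        t = np.where(zero_se & (diff != 0), np.sign(diff) * np.inf, t)
    t = np.where(valid, t, np.nan)
    df = np.where(valid, df, np.nan)
    return t, df


def two_sample_t(values_a, values_b, equal_var: bool = True
                 ) -> tuple[float, float]:
    """Classic two-sided Student's t-test (pooled variance by default).

    Missing (NaN) values are dropped. With fewer than two values in a group
    the result is (nan, nan). When both groups have zero variance the
    convention is t=0, p=1 for equal means (avoiding spurious infinities on
    saturated 0 %/100 % oxidation sites) and |t|=inf, p=0 otherwise.
    """
    a = np.asarray(values_a, dtype=float)[None, :]
    b = np.asarray(values_b, dtype=float)[None, :]
    t, df = _t_rows(a, b, equal_var=equal_var)
    t_val, df_val = float(t[0]), float(df[0])
    if math.isnan(t_val):
        return (math.nan, math.nan)
    if math.isinf(t_val):
        return (t_val, 0.0)
    p = 2.0 * float(sps.t.sf(abs(t_val), df_val))
    return (t_val, min(p, 1.0))


# ---------------------------------------------------------------------------
# permutation-based FDR
# ---------------------------------------------------------------------------

def _balanced_assignments(n_total: int, n_a: int, observed: np.ndarray,
                          n_permutations: int, seed: int) -> list[np.ndarray]:
    """Label permutations preserving group sizes.

    Exhaustive when the number of balanced assignments (minus the observed
    one and its label-swap complement, which would reproduce the observed
    statistics and put a hard floor under every q-value) is at most
    ``n_permutations``; otherwise uniformly sampled with the given seed.
    Each assignment is a boolean mask marking group A membership.
    """
    observed = np.asarray(observed, dtype=bool)
    complement = ~observed
    total = math.comb(n_total, n_a)
    out: list[np.ndarray] = []
    if total - 2 <= n_permutations:
        for combo in combinations(range(n_total), n_a):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(combo)] = True
            if np.array_equal(mask, observed) or np.array_equal(mask, complement):
                continue
            out.append(mask)
    else:
        rng = np.random.default_rng(seed)
        while len(out) < n_permutations:
            mask = np.zeros(n_total, dtype=bool)
            mask[rng.choice(n_total, size=n_a, replace=False)] = True
            if np.array_equal(mask, observed) or np.array_equal(mask, complement):
                continue
            out.append(mask)
    return out


def permutation_fdr(ox: pd.DataFrame, group_labels: dict, *,
                    n_permutations: int = 1000, seed: int = 0,
                    equal_var: bool = True) -> pd.Series:
    """q-values from balanced label permutations of the two-group t-test.

    For each site, q = (mean over permutations of the count of null |t| at
    or above the site's |t|) / (count of observed |t| at or above it),
    clipped to [0, 1] and made monotone non-increasing in |t|. Sites whose
    observed t is undefined get a missing q.
    """
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    # canonical sample order: the sampled null then depends only on the
    # sample set and seed, so swapping the two group labels leaves q intact
    samples = sorted((s for s in ox.columns if s in group_labels), key=str)
    labels = np.array([group_labels[s] for s in samples])
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ParameterError(f"need exactly two groups, got {groups}")
    mask_a = labels == groups[0]
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ParameterError("need >= 2 samples per group")

    x = ox[samples].to_numpy(dtype=float)
    t_obs, _ = _t_rows(x[:, mask_a], x[:, ~mask_a], equal_var=equal_var)
    abs_obs = np.abs(t_obs)
    defined = ~np.isnan(abs_obs)

    perms = _balanced_assignments(len(samples), int(mask_a.sum()), mask_a,
                                  n_permutations, seed)
    null_stats = []
    for mask in perms:
        t_null, _ = _t_rows(x[:, mask], x[:, ~mask], equal_var=equal_var)
        null_stats.append(np.abs(t_null[~np.isnan(t_null)]))
    null_pool = np.sort(np.concatenate(null_stats)) if null_stats else \
        np.empty(0)

    obs_sorted = np.sort(abs_obs[defined])
    q = np.full(len(ox), np.nan)
    vals = abs_obs[defined]
    n_ge_null = len(null_pool) - np.searchsorted(null_pool, vals, side="left")
    n_ge_obs = len(obs_sorted) - np.searchsorted(obs_sorted, vals, side="left")
    raw = (n_ge_null / len(perms)) / n_ge_obs
    raw = np.clip(raw, 0.0, 1.0)

    # enforce monotone non-increasing q in |t| (suffix minimum over the
    # descending-|t| ordering, as in step-up multiple-testing corrections)
    order = np.argsort(-vals, kind="stable")
    q_sorted = raw[order]
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    mono = np.empty_like(raw)
    mono[order] = q_sorted
    q[defined] = mono
    return pd.Series(q, index=ox.index, name="q_value")


# ---------------------------------------------------------------------------
# differential oxidation
# ---------------------------------------------------------------------------

def call_differential(delta: float, p_value: float, q_value: float, *,
                      delta_min: float = 5.0, q_max: float = 0.1,
                      p_fallback: float = 0.05,
                      criterion: str = "fdr") -> str:
    """The dual-criterion call for one site.

    ``criterion='fdr'`` requires q < q_max; ``criterion='p_fallback'``
    requires p < p_fallback. Either way |delta| must exceed ``delta_min``
    percentage points. Returns 'oxidized', 'reduced' or 'ns'.
    """
    if criterion == "fdr":
        significant = (q_value == q_value) and q_value < q_max
    elif criterion == "p_fallback":
        significant = (p_value == p_value) and p_value < p_fallback
    else:
        raise ParameterError(f"unknown criterion {criterion!r}")
    if not significant or abs(delta) <= delta_min or delta != delta:
        return "ns"
    return "oxidized" if delta > 0 else "reduced"


def differential_oxidation(ox: pd.DataFrame, design: ChannelDesign,
                           group_a: str, group_b: str, *,
                           delta_min: float = 5.0, q_max: float = 0.1,
                           p_fallback: float = 0.05,
                           allow_fallback: bool = True,
                           n_permutations: int = 1000, seed: int = 0,
                           equal_var: bool = True) -> pd.DataFrame:
    """Per-site differential oxidation between two conditions.

    delta = mean(B) - mean(A) in percentage points. The primary criterion
    is the permutation-FDR q < q_max; if no site satisfies it together with
    the change threshold and ``allow_fallback`` is set, the comparison
    falls back to p < p_fallback (recorded in ``criterion_used``).
    """
    for cond in (group_a, group_b):
        if cond not in design.conditions:
            raise ParameterError(f"unknown condition {cond!r}")
    samples_a = [s for s in design.samples_for(group_a) if s in ox.columns]
    samples_b = [s for s in design.samples_for(group_b) if s in ox.columns]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ParameterError("both conditions need >= 2 replicates")

    x_a = ox[samples_a].to_numpy(dtype=float)
    x_b = ox[samples_b].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(x_a, axis=1)
        mean_b = np.nanmean(x_b, axis=1)
    delta = mean_b - mean_a

    t, df = _t_rows(x_b, x_a, equal_var=equal_var)  # sign matches delta
    with np.errstate(invalid="ignore"):
        p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.minimum(p, 1.0)

    labels = {s: "A" for s in samples_a}
    labels.update({s: "B" for s in samples_b})
    q = permutation_fdr(ox[samples_a + samples_b], labels,
                        n_permutations=n_permutations, seed=seed,
                        equal_var=equal_var).to_numpy()

    primary_hits = (q < q_max) & (np.abs(delta) > delta_min)
    primary_hits &= ~np.isnan(q) & ~np.isnan(delta)
    if primary_hits.any() or not allow_fallback:
        criterion = "fdr"
    else:
        criterion = "p_fallback"
        logger.info("no site met q<%g with |delta|>%g; falling back to p<%g",
                    q_max, delta_min, p_fallback)

    calls = [
        call_differential(d, pv, qv, delta_min=delta_min, q_max=q_max,
                          p_fallback=p_fallback, criterion=criterion)
        for d, pv, qv in zip(delta, p, q)
    ]
    out = pd.DataFrame(
        {
            "mean_ox_a": mean_a,
            "mean_ox_b": mean_b,
            "delta": delta,
            "t_statistic": t,
            "p_value": p,
            "q_value": q,
            "call": calls,
            "criterion_used": criterion,
        },
        index=ox.index,
    )
    out.index.name = "site_key"
    return out


# ---------------------------------------------------------------------------
# distribution summaries
# ---------------------------------------------------------------------------

@dataclass
class DistributionSummary:
    """Quartile statistics and interval counts of oxidation per column."""

    stats: pd.DataFrame            # column x (median, q1, q3, min, max, n)
    interval_counts: pd.DataFrame  # bin x column


def distribution_summary(ox: pd.DataFrame,
                         interval_edges=(0, 10, 20, 30, 40, 50, 60, 70, 80,
                                         90, 100)) -> DistributionSummary:
    """Median/quartiles/range and interval counts per sample or condition.

    Bins are right-open with the final bin closed (numpy histogram
    convention), so the edge sequence (0, 50, 100) yields [0,50) and
    [50,100].
    """
    edges = np.asarray(interval_edges, dtype=float)
    if len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ParameterError("interval_edges must be strictly increasing")
    rows = {}
    counts = {}
    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-2], edges[1:-1])]
    labels.append(f"[{edges[-2]:g},{edges[-1]:g}]")
    for col in ox.columns:
        vals = ox[col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            rows[col] = dict(median=np.nan, q1=np.nan, q3=np.nan,
                             min=np.nan, max=np.nan, n=0)
            counts[col] = np.zeros(len(labels), dtype=int)
            continue
        rows[col] = dict(
            median=float(np.median(vals)),
            q1=float(np.percentile(vals, 25)),
            q3=float(np.percentile(vals, 75)),
            min=float(vals.min()),
            max=float(vals.max()),
            n=int(vals.size),
        )
        counts[col], _ = np.histogram(vals, bins=edges)
    stats_df = pd.DataFrame(rows).T[["median", "q1", "q3", "min", "max", "n"]]
    counts_df = pd.DataFrame(counts, index=labels)
    return DistributionSummary(stats=stats_df, interval_counts=counts_df)


# ---------------------------------------------------------------------------
# ANOVA with Fisher's LSD
# ---------------------------------------------------------------------------

def anova_fisher_lsd(groups) -> tuple[float, float, dict]:
    """One-way ANOVA F/p plus unprotected pairwise LSD t-tests.

    Pairwise tests use the pooled within-group mean square with N - k
    degrees of freedom. Groups with fewer than two values are excluded with
    a warning; with fewer than two usable groups the result is undefined
    (nan, nan, {}).
    """
    cleaned = []
    index_map = []
    for gi, g in enumerate(groups):
        vals = np.asarray(pd.Series(g).dropna(), dtype=float)
        if len(vals) < 2:
            warnings.warn(f"group {gi} has fewer than 2 values; excluded",
                          stacklevel=2)
            continue
        cleaned.append(vals)
        index_map.append(gi)
    if len(cleaned) < 2:
        return (math.nan, math.nan, {})

    k = len(cleaned)
    ns = np.array([len(g) for g in cleaned], dtype=float)
    means = np.array([g.mean() for g in cleaned])
    n_total = ns.sum()
    grand = np.concatenate(cleaned).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in cleaned))
    df_b, df_w = k - 1, int(n_total) - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w if df_w > 0 else math.nan

    if ms_within == 0:
        if ss_between == 0:
            f_stat, p_anova = 0.0, 1.0
        else:
            f_stat, p_anova = math.inf, 0.0
    else:
        f_stat = ms_between / ms_within
        p_anova = float(sps.f.sf(f_stat, df_b, df_w))

    pairwise = {}
    for (ia, a), (ib, b) in combinations(zip(index_map, cleaned), 2):
        d = a.mean() - b.mean()
        if ms_within == 0:
            t_val = 0.0 if d == 0 else math.copysign(math.inf, d)
            p_val = 1.0 if d == 0 else 0.0
        else:
            se = math.sqrt(ms_within * (1.0 / len(a) + 1.0 / len(b)))
            t_val = d / se
            p_val = 2.0 * float(sps.t.sf(abs(t_val), df_w))
        pairwise[(ia, ib)] = (t_val, min(p_val, 1.0))
    return (f_stat, p_anova, pairwise)


# ---------------------------------------------------------------------------
# cross-dataset correlation
# ---------------------------------------------------------------------------

def correlate_shared_sites(ox_a: pd.Series, ox_b: pd.Series
                           ) -> tuple[float, int]:
    """Pearson correlation over the sites non-missing in both profiles."""
    joined = pd.concat([ox_a, ox_b], axis=1, join="inner").dropna()
    n = len(joined)
    if n < 3:
        logger.warning("correlate_shared_sites: only %d shared sites "
                       "(>= 3 required)", n)
        return (math.nan, n)
    r = float(sps.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1]).statistic)
    return (r, n)
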