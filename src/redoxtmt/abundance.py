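"""Quantitative-proteomics track: valid-value filtering, median
normalization, and differential abundance with permutation FDR.

Raw reporter intensities (zeros = missing) are log2-transformed, rows with
fewer than ``min_valid`` valid values across all channels are dropped, and
each channel is median-centred to the grand mean of the channel medians —
the standard isobaric convention. Differential abundance reuses the pooled
two-sample t-test and the balanced-permutation FDR of the redox track on
log2 abundances; proteins with q below the threshold are significant.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .io_formats import ParameterError
from .stats import _t_rows, permutation_fdr
from scipy import stats as sps

logger = logging.getLogger(__name__)


def prepare_abundance(raw: pd.DataFrame, min_valid: int = 9,
                      already_log2: bool = False) -> pd.DataFrame:
    """Log2-transform, filter on valid values, median-centre channels.

    ``raw`` is protein x channel. Zeros (and negative placeholders) are
    treated as missing. ``min_valid`` counts across all channels. With
    ``already_log2`` the input is taken as log2 abundances where NaN is
    missing. After centring, every channel's median equals the grand mean
    of the pre-centring channel medians.
    """
    if min_valid < 0:
        raise ParameterError("min_valid must be non-negative")
    if min_valid > raw.shape[1]:
        raise ParameterError(
            f"min_valid={min_valid} exceeds channel count {raw.shape[1]}"
        )
    x = raw.to_numpy(dtype=float).copy()
    if already_log2:
        log2 = x
    else:
        x[x <= 0] = np.nan
        with np.errstate(invalid="ignore"):
            log2 = np.log2(x)
    table = pd.DataFrame(log2, index=raw.index, columns=raw.columns)

    keep = table.notna().sum(axis=1) >= min_valid
    table = table.loc[keep]
    logger.info("prepare_abundance: kept %d of %d proteins (min_valid=%d)",
                int(keep.sum()), len(keep), min_valid)
    if table.empty:
        warnings.warn("all rows were filtered out by the valid-value "
                      "threshold", stacklevel=2)
        return table

    medians = table.median()
    grand = medians.mean()
    return table - medians + grand


def differential_abundance(table: pd.DataFrame, design: pd.DataFrame,
                           group_a: str, group_b: str, *,
                           q_max: float = 0.1, n_permutations: int = 1000,
                           seed: int = 0,
                           equal_var: bool = True) -> pd.DataFrame:
    """Per-protein differential abundance between two conditions.

    ``design`` maps channels to conditions (columns ``channel_id`` and
    ``condition``). Returns per protein: group means, log2 difference
    (B - A), t, p, q and the significance flag (q < q_max).
    """
    conditions = set(design["condition"])
    for cond in (group_a, group_b):
        if cond not in conditions:
            raise ParameterError(f"unknown condition {cond!r}")
    ch_a = [c for c in design.loc[design["condition"] == group_a, "channel_id"]
            if c in table.columns]
    ch_b = [c for c in design.loc[design["condition"] == group_b, "channel_id"]
            if c in table.columns]
    if len(ch_a) < 2 or len(ch_b) < 2:
        raise ParameterError("both conditions need >= 2 channels")

    x_a = table[ch_a].to_numpy(dtype=float)
    x_b = table[ch_b].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(x_a, axis=1)
        mean_b = np.nanmean(x_b, axis=1)
    diff = mean_b - mean_a

    t, df = _t_rows(x_b, x_a, equal_var=equal_var)
    with np.errstate(invalid="ignore"):
        p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, np.minimum(p, 1.0))

    labels = {c: "A" for c in ch_a}
    labels.update({c: "B" for c in ch_b})
    q = permutation_fdr(table[ch_a + ch_b], labels,
                        n_permutations=n_permutations, seed=seed,
                        equal_var=equal_var).to_numpy()

    out = pd.DataFrame(
        {
            "mean_log2_a": mean_a,
            "mean_log2_b": mean_b,
            "log2_diff": diff,
            "t_statistic": t,
            "p_value": p,
            "q_value": q,
            "significant": (q < q_max) & ~np.isnan(q),
        },
        index=table.index,
    )
    out.index.name = "accession"
    return out
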