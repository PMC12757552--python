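"""Raw reporter intensities -> normalized per-site oxidation percentages.

Processing order follows the standard sequential-iodoTMT workflow:

1. log2-transform non-zero intensities (zeros encode "not observed");
2. per plex run and per label class (SH or Sox), shift each channel so its
   median equals the mean of the channel medians of that class — an
   additive log2 shift, i.e. a multiplicative correction on linear scale;
3. back-transform, and per sample compute oxidation % = Sox/(SH+Sox)*100.

Normalization is per plex run because channel medians are only comparable
within one multiplexed MS run, and per label class because the SH and Sox
medians differ for real biological reasons (most of the proteome is
reduced); forcing them to a common target would destroy the global
oxidation scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_formats import ChannelDesign, DesignError, ParameterError, ReporterTable

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    """A channel cannot be normalized (e.g. it has no non-zero values)."""


def normalize_channels(table: ReporterTable, design: ChannelDesign) -> ReporterTable:
    """Median-align reporter channels within each plex run and label class.

    Each channel's median of log2-transformed non-zero intensities is
    shifted to the mean of the medians of its (plex_run, label_class)
    group. Zeros are excluded from the medians (log2(0) is undefined) and
    remain zero in the output. With a single channel in a group the
    operation is the identity.
    """
    cols = table.intensities.columns
    for run, ch in design.columns:
        if (run, ch) not in cols:
            raise DesignError(
                f"design channel {ch!r} (plex run {run!r}) missing from table"
            )

    values = table.intensities.to_numpy(dtype=float).copy()
    col_list = list(cols)
    medians = np.empty(len(col_list))
    for j, (run, ch) in enumerate(col_list):
        nonzero = values[:, j] > 0
        if not nonzero.any():
            raise NormalizationError(
                f"channel {ch!r} (plex run {run!r}) has no non-zero intensities"
            )
        medians[j] = np.median(np.log2(values[nonzero, j]))

    frame = design.frame
    for run in frame["plex_run"].unique():
        for label in ("SH", "Sox"):
            chans = frame[(frame["plex_run"] == run)
                          & (frame["label_class"] == label)]["channel_id"]
            idx = [col_list.index((run, ch)) for ch in chans]
            if not idx:
                continue
            target = medians[idx].mean()
            for j in idx:
                shift = target - medians[j]
                nz = values[:, j] > 0
                values[nz, j] = values[nz, j] * (2.0 ** shift)

    out = pd.DataFrame(values, index=table.intensities.index, columns=cols)
    return ReporterTable(intensities=out, meta=table.meta)


def compute_oxidation(table: ReporterTable, design: ChannelDesign,
                      strict_pair_na: bool = False) -> pd.DataFrame:
    """Per-site per-sample oxidation % = Sox/(SH+Sox)*100.

    Expects normalized intensities. By default a single zero within an
    SH/Sox pair yields a boundary value (0 % when Sox=0, 100 % when SH=0)
    and only a zero sum yields missing. With ``strict_pair_na=True`` a zero
    in *either* channel makes the pair missing — the behaviour implied by
    log2-transforming before the ratio, where zeros are undefined; prefer
    it whenever zeros represent censoring rather than true absence.
    """
    samples = design.samples
    out = {}
    for _, row in samples.iterrows():
        sample = row["sample_id"]
        sh_col = design.channel(sample, "SH")
        sox_col = design.channel(sample, "Sox")
        for col in (sh_col, sox_col):
            if col not in table.intensities.columns:
                raise DesignError(
                    f"sample {sample!r}: channel {col[1]!r} (plex run "
                    f"{col[0]!r}) absent from table columns"
                )
        sh = table.intensities[sh_col].to_numpy(dtype=float)
        sox = table.intensities[sox_col].to_numpy(dtype=float)
        total = sh + sox
        with np.errstate(invalid="ignore", divide="ignore"):
            ox = np.where(total > 0, sox / np.where(total > 0, total, 1.0) * 100.0,
                          np.nan)
        if strict_pair_na:
            ox = np.where((sh > 0) & (sox > 0), ox, np.nan)
        out[sample] = ox
    result = pd.DataFrame(out, index=table.intensities.index)
    result.index.name = "site_key"
    return result


def filter_min_valid(ox: pd.DataFrame, design: ChannelDesign,
                     min_valid: int = 1,
                     scope: str = "per_condition") -> pd.DataFrame:
    """Keep sites with at least ``min_valid`` non-missing values in scope.

    ``scope='per_condition'`` requires the threshold within every
    condition; ``scope='overall'`` counts across all samples. The retained
    and dropped counts are logged.
    """
    if min_valid < 0:
        raise ParameterError("min_valid must be non-negative")
    if scope not in ("per_condition", "overall"):
        raise ParameterError(f"unknown scope {scope!r}")
    if scope == "overall":
        if min_valid > ox.shape[1]:
            raise ParameterError(
                f"min_valid={min_valid} exceeds sample count {ox.shape[1]}"
            )
        keep = ox.notna().sum(axis=1) >= min_valid
    else:
        keep = pd.Series(True, index=ox.index)
        for cond in design.conditions:
            samples = [s for s in design.samples_for(cond) if s in ox.columns]
            if min_valid > len(samples):
                raise ParameterError(
                    f"min_valid={min_valid} exceeds sample count "
                    f"{len(samples)} in condition {cond!r}"
                )
            keep &= ox[samples].notna().sum(axis=1) >= min_valid
    logger.info("filter_min_valid: kept %d of %d sites (min_valid=%d, scope=%s)",
                int(keep.sum()), len(keep), min_valid, scope)
    return ox.loc[keep]


@dataclass
class CVSummary:
    """Replicate reproducibility: per-site CV (%) and per-condition medians."""

    per_site: pd.DataFrame        # site_key x condition, CV in percent
    median_cv: pd.Series          # condition -> median CV in percent


def replicate_cv(ox: pd.DataFrame, design: ChannelDesign) -> CVSummary:
    """Coefficient of variation of oxidation across biological replicates.

    CV = 100 * sd / mean over non-missing replicate values, using the
    sample (n-1) standard deviation; undefined (missing) with fewer than
    two values or a zero mean.
    """
    per_site = {}
    for cond in design.conditions:
        samples = [s for s in design.samples_for(cond) if s in ox.columns]
        sub = ox[samples]
        n = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        cv = 100.0 * sd / mean
        cv[(n < 2) | (mean == 0)] = np.nan
        per_site[cond] = cv
    per_site_df = pd.DataFrame(per_site)
    per_site_df.index.name = "site_key"
    return CVSummary(per_site=per_site_df, median_cv=per_site_df.median())


def quantify(table: ReporterTable, design: ChannelDesign,
             min_valid: int = 1, scope: str = "per_condition",
             strict_pair_na: bool = False,
             ) -> tuple[ReporterTable, pd.DataFrame, CVSummary]:
    """Full quantification stage: normalize, ratio, filter, CV summary."""
    normalized = normalize_channels(table, design)
    ox = compute_oxidation(normalized, design, strict_pair_na=strict_pair_na)
    ox = filter_min_valid(ox, design, min_valid=min_valid, scope=scope)
    return normalized, ox, replicate_cv(ox, design)


def condition_means(ox: pd.DataFrame, design: ChannelDesign) -> pd.DataFrame:
    """Mean oxidation per site per condition over non-missing replicates."""
    out = {}
    for cond in design.conditions:
        samples = [s for s in design.samples_for(cond) if s in ox.columns]
        out[cond] = ox[samples].mean(axis=1)
    df = pd.DataFrame(out)
    df.index.name = "site_key"
    return df
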