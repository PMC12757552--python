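"""Join oxidation sites to known cysteine-modification annotations.

Sites are matched to RedoxDB-style records (accession, 1-based position,
modification type) by exact accession + position. A multi-Cys peptide
matches when *any* of its Cys positions hits a record — the permissive
reconciliation between peptide-level quantification and site-level
annotation. The global S-glutathionylation (P-SSG) index aggregates
oxidation over annotated sites per sample; both the median and the mean are
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AnnotationRecord, CysPeptideKey

logger = logging.getLogger(__name__)


@dataclass
class SiteAnnotationJoin:
    """One quantified site with its (possibly empty) annotation matches."""

    site_key: str
    matches: tuple[AnnotationRecord, ...] = ()
    matched_positions: tuple[int, ...] = ()
    match_basis: str = "exact_position"

    @property
    def is_annotated(self) -> bool:
        return bool(self.matches)


def map_sites_to_annotations(sites, annotations,
                             modification_filter: str | None = None
                             ) -> list[SiteAnnotationJoin]:
    """Exact accession+position join of quantified sites to annotations.

    ``modification_filter`` restricts matches to one modification type
    (e.g. "S-glutathionylation"). Returns one join per input site, in input
    order, with matches sorted deterministically.
    """
    by_pos: dict[tuple[str, int], list[AnnotationRecord]] = {}
    for rec in annotations:
        if modification_filter is not None and \
                rec.modification_type != modification_filter:
            continue
        by_pos.setdefault((rec.protein_accession, rec.position), []).append(rec)

    joins = []
    for site in sites:
        matches: list[AnnotationRecord] = []
        positions: list[int] = []
        for pos in site.cys_positions:
            hits = by_pos.get((site.protein_accession, pos), [])
            if hits:
                matches.extend(hits)
                positions.append(pos)
        matches.sort(key=lambda r: (r.position, r.modification_type, r.source))
        joins.append(SiteAnnotationJoin(
            site_key=site.site_key,
            matches=tuple(matches),
            matched_positions=tuple(sorted(positions)),
        ))
    n_matched = sum(j.is_annotated for j in joins)
    logger.info("annotation join: %d of %d sites matched%s", n_matched,
                len(joins),
                f" ({modification_filter})" if modification_filter else "")
    return joins


def pssg_index(ox: pd.DataFrame, joins) -> pd.DataFrame:
    """Per-sample aggregate oxidation over annotated sites.

    ``joins`` should already be filtered to the modification of interest
    (pass ``modification_filter="S-glutathionylation"`` upstream for the
    P-SSG index). Returns per sample the median and mean oxidation over
    annotated sites with non-missing values, plus the site count; samples
    with no annotated non-missing site are undefined (NaN, n=0).
    """
    annotated = [j.site_key for j in joins if j.is_annotated]
    annotated = [sk for sk in annotated if sk in ox.index]
    if not annotated:
        logger.warning("pssg_index: no annotated sites present in the table")
        return pd.DataFrame(
            {"median_ox": np.nan, "mean_ox": np.nan, "n_sites": 0},
            index=ox.columns,
        )
    sub = ox.loc[annotated]
    out = pd.DataFrame({
        "median_ox": sub.median(),
        "mean_ox": sub.mean(),
        "n_sites": sub.notna().sum(),
    })
    out.index.name = "sample_id"
    empty = out["n_sites"] == 0
    if empty.any():
        logger.warning("pssg_index: sample(s) %s have no non-missing "
                       "annotated sites", list(out.index[empty]))
    return out


def keys_from_meta(meta: pd.DataFrame) -> list[CysPeptideKey]:
    """Build peptide keys from a ReporterTable metadata frame."""
    keys = []
    for _, row in meta.iterrows():
        keys.append(CysPeptideKey(
            protein_accession=row["accession"],
            peptide_sequence=row["sequence"],
            cys_positions=tuple(int(p) for p in
                                str(row["cys_positions"]).split(",")),
            all_accessions=tuple(str(row["all_accessions"]).split(";")),
        ))
    return keys
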