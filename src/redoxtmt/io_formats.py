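"""Readers and writers for every table the pipeline touches.

All files are tab-separated with a header row; missing values are written as
the literal string ``NA``. Reporter tables come from a database-search
export (one row per cysteine peptide or PSM, one intensity column per
reporter channel); a configurable column map absorbs search-engine renames.

The quantified unit throughout is the *unique Cys peptide*: a protein
accession plus the sorted 1-based protein coordinates of its cysteines,
rendered as e.g. ``P04406:Cys152`` or ``Q16822:Cys123,Cys130``. PSM-level
duplicates sharing a key are summed channel-wise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = "NA"

LABEL_CLASSES = ("SH", "Sox")

#: default column names of the reporter-table dialect
DEFAULT_COLUMN_MAP = {
    "accession": "Accession",
    "sequence": "Sequence",
    "positions": "Positions in Proteins",
    "contaminant": "Contaminant",
}

_TRUTHY = {"true", "t", "1", "yes", "y", "+"}
_FALSY = {"false", "f", "0", "no", "n", "-", ""}


class FormatError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class DesignError(ValueError):
    """A channel design violates the SH/Sox pairing invariants."""


class ParameterError(ValueError):
    """An operation was called with an out-of-range parameter."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class CysPeptideKey:
    """Identity of a quantified cysteine peptide.

    ``cys_positions`` are 1-based protein coordinates, sorted ascending.
    When a peptide maps to several proteins the first listed accession is
    primary and the full list is kept as provenance.
    """

    protein_accession: str
    peptide_sequence: str
    cys_positions: tuple[int, ...]
    all_accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.cys_positions:
            raise FormatError(f"peptide {self.peptide_sequence!r}: no Cys positions")
        if "C" not in self.peptide_sequence:
            raise FormatError(
                f"peptide {self.peptide_sequence!r} contains no cysteine"
            )
        if tuple(sorted(self.cys_positions)) != self.cys_positions:
            object.__setattr__(self, "cys_positions", tuple(sorted(self.cys_positions)))
        if not self.all_accessions:
            object.__setattr__(self, "all_accessions", (self.protein_accession,))

    @property
    def site_key(self) -> str:
        cys = ",".join(f"Cys{p}" for p in self.cys_positions)
        return f"{self.protein_accession}:{cys}"


@dataclass(frozen=True)
class AnnotationRecord:
    """A known modification (or domain) at a 1-based protein position."""

    protein_accession: str
    position: int
    modification_type: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(
                f"annotation {self.protein_accession}: position {self.position} "
                "must be a 1-based coordinate"
            )


@dataclass
class ChannelDesign:
    """Mapping of reporter channels to samples, conditions and label classes.

    ``frame`` has one row per channel with columns
    ``channel_id, plex_run, sample_id, condition, replicate, label_class``.
    Every sample carries exactly one SH and one Sox channel within its plex
    run, and ``(plex_run, channel_id)`` pairs are unique.
    """

    frame: pd.DataFrame

    REQUIRED = ("channel_id", "plex_run", "sample_id", "condition",
                "replicate", "label_class")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise DesignError(f"channel design missing column(s): {missing}")
        df = df.copy()
        for col in ("channel_id", "plex_run", "sample_id", "condition",
                    "label_class"):
            df[col] = df[col].astype(str)
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            bad = df.loc[df["replicate"] < 1, "sample_id"].tolist()
            raise DesignError(f"non-positive replicate for sample(s) {bad}")
        bad_class = sorted(set(df["label_class"]) - set(LABEL_CLASSES))
        if bad_class:
            raise DesignError(
                f"label_class must be one of {LABEL_CLASSES}, got {bad_class}"
            )
        dup = df.duplicated(subset=["plex_run", "channel_id"])
        if dup.any():
            pairs = df.loc[dup, ["plex_run", "channel_id"]].values.tolist()
            raise DesignError(f"duplicate (plex_run, channel_id) pairs: {pairs}")
        # each sample: exactly one SH and one Sox channel, in a single plex run
        for sample, grp in df.groupby("sample_id", sort=False):
            counts = grp["label_class"].value_counts()
            if counts.get("SH", 0) != 1 or counts.get("Sox", 0) != 1:
                raise DesignError(
                    f"sample {sample!r} must have exactly one SH and one Sox "
                    f"channel, found {counts.to_dict()}"
                )
            if grp["plex_run"].nunique() != 1:
                raise DesignError(f"sample {sample!r} spans multiple plex runs")
            if grp["condition"].nunique() != 1 or grp["replicate"].nunique() != 1:
                raise DesignError(
                    f"sample {sample!r} has inconsistent condition/replicate"
                )
        self.frame = df.reset_index(drop=True)

    # -- convenience views -------------------------------------------------
    @property
    def samples(self) -> pd.DataFrame:
        """One row per sample: sample_id, plex_run, condition, replicate."""
        return (self.frame[["sample_id", "plex_run", "condition", "replicate"]]
                .drop_duplicates()
                .reset_index(drop=True))

    @property
    def columns(self) -> list[tuple[str, str]]:
        """(plex_run, channel_id) pairs in design order."""
        return list(zip(self.frame["plex_run"], self.frame["channel_id"]))

    def channel(self, sample_id: str, label_class: str) -> tuple[str, str]:
        """Return the (plex_run, channel_id) of a sample's SH or Sox channel."""
        sel = self.frame[(self.frame["sample_id"] == sample_id)
                         & (self.frame["label_class"] == label_class)]
        if sel.empty:
            raise DesignError(f"no {label_class} channel for sample {sample_id!r}")
        row = sel.iloc[0]
        return row["plex_run"], row["channel_id"]

    def samples_for(self, condition: str) -> list[str]:
        sel = self.samples
        return sel.loc[sel["condition"] == condition, "sample_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.frame["condition"]:
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class ReporterTable:
    """Cys-peptide x channel raw intensity matrix; zeros encode "not observed".

    ``intensities`` is indexed by ``site_key`` with a ``(plex_run,
    channel_id)`` MultiIndex on columns. ``meta`` carries the peptide
    identity fields for the same index.
    """

    intensities: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        vals = self.intensities.to_numpy(dtype=float)
        if vals.size and (np.nan_to_num(vals) < 0).any():
            raise FormatError("reporter intensities must be non-negative")

    @property
    def site_keys(self) -> pd.Index:
        return self.intensities.index

    def keys(self) -> list[CysPeptideKey]:
        """Reconstruct CysPeptideKey objects from the metadata table."""
        out = []
        for sk, row in self.meta.iterrows():
            out.append(CysPeptideKey(
                protein_accession=row["accession"],
                peptide_sequence=row["sequence"],
                cys_positions=tuple(
                    int(p) for p in str(row["cys_positions"]).split(",")
                ),
                all_accessions=tuple(str(row["all_accessions"]).split(";")),
            ))
        return out


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

_POS_SPLIT = re.compile(r"[;,\s]+")


def _parse_positions(cell: str, row_number: int) -> tuple[int, ...]:
    """Parse a positions cell: integers optionally prefixed 'Cys'/'C'."""
    tokens = [t for t in _POS_SPLIT.split(str(cell).strip()) if t]
    if not tokens:
        raise FormatError(f"row {row_number}: empty Cys position field")
    positions = []
    for tok in tokens:
        m = re.fullmatch(r"(?:Cys|C)?(\d+)", tok)
        if m is None:
            raise FormatError(
                f"row {row_number}: cannot parse Cys position {tok!r}"
            )
        pos = int(m.group(1))
        if pos < 1:
            raise FormatError(f"row {row_number}: position {pos} is not 1-based")
        positions.append(pos)
    return tuple(sorted(set(positions)))


def _parse_flag(cell, row_number: int) -> bool:
    if isinstance(cell, (bool, np.bool_)):
        return bool(cell)
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return False
    text = str(cell).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise FormatError(f"row {row_number}: cannot parse contaminant flag {cell!r}")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, na_values=[MISSING],
                       keep_default_na=False)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_channel_design(path) -> ChannelDesign:
    """Read and validate a channel design TSV."""
    df = _read_tsv(path)
    return ChannelDesign(df)


def read_reporter_table(path, design: ChannelDesign,
                        column_map: dict | None = None) -> ReporterTable:
    """Read a search-engine reporter-intensity export.

    Applies the two identification-level filters (contaminant rows and
    peptides without cysteine are dropped), aggregates rows sharing a
    peptide key by summing intensities channel-wise, and returns rows
    sorted by ``site_key``.

    ``column_map`` may override the default dialect names for keys
    ``accession, sequence, positions, contaminant`` and may carry
    ``intensity_columns``: a mapping ``(plex_run, channel_id) -> column``.
    Setting ``contaminant`` to None skips the contaminant filter (for
    exports without the flag).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    intensity_cols: dict[tuple[str, str], str] = {}
    if column_map:
        intensity_cols = dict(column_map.get("intensity_columns", {}))
        cmap.update({k: v for k, v in column_map.items()
                     if k in DEFAULT_COLUMN_MAP})
        if "contaminant" in column_map and column_map["contaminant"] is None:
            cmap["contaminant"] = None

    df = _read_tsv(path)

    for role in ("accession", "sequence", "positions"):
        if cmap[role] not in df.columns:
            raise FormatError(
                f"reporter table is missing required column {cmap[role]!r} "
                f"(role: {role})"
            )
    if cmap["contaminant"] is not None and cmap["contaminant"] not in df.columns:
        raise FormatError(
            f"reporter table is missing required column {cmap['contaminant']!r} "
            "(role: contaminant); map it to None to skip the filter"
        )

    # resolve one intensity column per design channel
    columns: list[tuple[str, str]] = []
    colnames: list[str] = []
    for run, ch in design.columns:
        name = intensity_cols.get((run, ch), ch)
        if name not in df.columns:
            raise DesignError(
                f"design channel {ch!r} (plex run {run!r}) has no matching "
                f"intensity column {name!r} in the reporter table"
            )
        columns.append((run, ch))
        colnames.append(name)

    records: dict[str, dict] = {}
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based, after header
        if cmap["contaminant"] is not None and _parse_flag(row[cmap["contaminant"]], rownum):
            continue
        seq = str(row[cmap["sequence"]]).strip().upper()
        if "C" not in seq:
            continue
        accessions = tuple(
            a.strip() for a in str(row[cmap["accession"]]).split(";") if a.strip()
        )
        if not accessions:
            raise FormatError(f"row {rownum}: empty accession")
        key = CysPeptideKey(
            protein_accession=accessions[0],
            peptide_sequence=seq,
            cys_positions=_parse_positions(row[cmap["positions"]], rownum),
            all_accessions=accessions,
        )
        values = np.empty(len(colnames))
        for j, cname in enumerate(colnames):
            cell = row[cname]
            try:
                values[j] = 0.0 if (cell is None or cell != cell or cell == "") \
                    else float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"row {rownum}: non-numeric intensity {cell!r} in "
                    f"column {cname!r}"
                ) from None
        if (values < 0).any():
            raise FormatError(f"row {rownum}: negative intensity")
        sk = key.site_key
        if sk in records:
            records[sk]["values"] = records[sk]["values"] + values
        else:
            records[sk] = {"key": key, "values": values}

    order = sorted(records)
    intens = pd.DataFrame(
        [records[sk]["values"] for sk in order],
        index=pd.Index(order, name="site_key"),
        columns=pd.MultiIndex.from_tuples(columns, names=["plex_run", "channel_id"]),
    )
    meta = pd.DataFrame(
        {
            "accession": [records[sk]["key"].protein_accession for sk in order],
            "sequence": [records[sk]["key"].peptide_sequence for sk in order],
            "cys_positions": [",".join(map(str, records[sk]["key"].cys_positions))
                              for sk in order],
            "all_accessions": [";".join(records[sk]["key"].all_accessions)
                               for sk in order],
        },
        index=pd.Index(order, name="site_key"),
    )
    return ReporterTable(intensities=intens, meta=meta)


def read_annotation_table(path) -> set[AnnotationRecord]:
    """Read a modification/domain annotation TSV into a deduplicated set."""
    df = _read_tsv(path)
    for col in ("accession", "position", "modification_type"):
        if col not in df.columns:
            raise FormatError(f"annotation table is missing column {col!r}")
    has_source = "source" in df.columns
    out: set[AnnotationRecord] = set()
    seen: set[tuple] = set()
    for i, row in df.iterrows():
        rownum = i + 2
        try:
            pos = int(str(row["position"]).strip())
        except (TypeError, ValueError):
            raise FormatError(
                f"row {rownum}: non-integer position {row['position']!r}"
            ) from None
        if pos < 1:
            raise FormatError(f"row {rownum}: position {pos} is not 1-based")
        ident = (str(row["accession"]), pos, str(row["modification_type"]))
        if ident in seen:
            continue
        seen.add(ident)
        out.add(AnnotationRecord(
            protein_accession=ident[0],
            position=pos,
            modification_type=ident[2],
            source=str(row["source"]) if has_source and row["source"] == row["source"] else "",
        ))
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_results(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV: header, NA for missing, full precision.

    The index is written when it carries a name (e.g. ``site_key``), so
    ``read_results(path, index_col=...)`` round-trips bit-exactly (floats
    are serialized with shortest round-trip repr).
    """
    write_index = table.index.name is not None
    table.to_csv(path, sep="\t", na_rep=MISSING, index=write_index)


def read_results(path, index_col: str | None = None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=False)
    if index_col is not None:
        df = df.set_index(index_col)
    return df


def write_reporter_table(table: ReporterTable, intensities_path, meta_path=None) -> None:
    flat = table.intensities.copy()
    flat.columns = [f"{run}|{ch}" for run, ch in flat.columns]
    write_results(flat, intensities_path)
    if meta_path is not None:
        write_results(table.meta, meta_path)


def write_channel_design(design: ChannelDesign, path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)
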