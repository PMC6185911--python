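"""Count-table, metadata and taxonomy containers with TSV/BIOM round-trip I/O.

The central object is :class:`CountTable`, a samples × taxa matrix of
non-negative integer read counts as produced by an amplicon denoiser (ZOTU
or OTU table).  Sample metadata assigns each sample to a host-species group
(or ``"seawater"``) plus an HMA/LMA/SW habitat class, and an optional
taxonomy table carries a lineage per taxon.  All validation of the
cross-references between these inputs lives here, so downstream analysis
modules can assume clean, consistent tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEAWATER_GROUP",
    "HABITAT_CLASSES",
    "RANKS",
    "CountTable",
    "SampleMetadata",
    "TaxonomyTable",
    "ValidationReport",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "read_taxonomy",
    "validate_pair",
]

#: Reserved group label for water samples.
SEAWATER_GROUP = "seawater"

#: Recognised habitat classes: High/Low Microbial Abundance sponges, seawater.
HABITAT_CLASSES = ("HMA", "LMA", "SW")

#: Ordered taxonomic ranks carried by :class:`TaxonomyTable` (broad → narrow).
RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class TableFormatError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    ser = pd.Series(ids)
    dup = ser[ser.duplicated()]
    if not dup.empty:
        raise TableFormatError(f"duplicate {what} identifier(s): {sorted(set(dup))}")


@dataclass
class CountTable:
    """Samples × taxa matrix of non-negative integer read counts.

    ``data`` is indexed by sample id with taxon ids as columns.  Invariants
    (unique ids, integral non-negative counts, positive row sums) are checked
    on construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.size == 0:
            raise TableFormatError("empty count table")
        _check_unique(list(self.data.index), "sample")
        _check_unique(list(self.data.columns), "taxon")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise TableFormatError("counts must be numeric")
        neg = np.argwhere(values < 0)
        if neg.size:
            s, t = neg[0]
            raise TableFormatError(
                f"negative count at sample {self.data.index[s]!r}, "
                f"taxon {self.data.columns[t]!r}"
            )
        frac = np.argwhere(values != np.floor(values))
        if frac.size:
            s, t = frac[0]
            raise TableFormatError(
                f"non-integer count at sample {self.data.index[s]!r}, "
                f"taxon {self.data.columns[t]!r}"
            )
        zero = values.sum(axis=1) == 0
        if zero.any():
            bad = list(self.data.index[zero])
            raise TableFormatError(f"sample(s) with zero total reads: {bad}")
        self.data = self.data.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row_sums(self) -> pd.Series:
        return self.data.sum(axis=1)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        ids = [s for s in sample_ids]
        missing = set(ids) - set(self.data.index)
        if missing:
            raise KeyError(f"unknown sample id(s): {sorted(missing)}")
        return CountTable(self.data.loc[ids].copy())

    def equals(self, other: "CountTable") -> bool:
        """Element-wise equality up to the declared sample/taxon ordering."""
        a = self.data.sort_index(axis=0).sort_index(axis=1)
        b = other.data.sort_index(axis=0).sort_index(axis=1)
        return a.equals(b)


@dataclass
class SampleMetadata:
    """Per-sample grouping: host species (or seawater), habitat class, site.

    ``data`` is indexed by sample id with columns ``group``,
    ``habitat_class``, ``location`` and ``replicate``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "sample")
        required = {"group", "habitat_class"}
        missing = required - set(self.data.columns)
        if missing:
            raise TableFormatError(f"metadata missing required column(s): {sorted(missing)}")
        df = self.data.copy()
        df["habitat_class"] = df["habitat_class"].astype(str).str.upper()
        bad = set(df["habitat_class"]) - set(HABITAT_CLASSES)
        if bad:
            raise TableFormatError(f"unknown habitat_class value(s): {sorted(bad)}")
        is_sw_group = df["group"] == SEAWATER_GROUP
        is_sw_class = df["habitat_class"] == "SW"
        mismatch = df.index[is_sw_group != is_sw_class]
        if len(mismatch):
            raise TableFormatError(
                "habitat_class must be SW exactly for group "
                f"'{SEAWATER_GROUP}'; offending sample(s): {list(mismatch)}"
            )
        if "location" not in df.columns:
            df["location"] = "unknown"
        if "replicate" not in df.columns:
            df["replicate"] = df.groupby("group").cumcount() + 1
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance (sponges then/or seawater)."""
        return list(dict.fromkeys(self.data["group"]))

    @property
    def sponge_groups(self) -> list[str]:
        return [g for g in self.groups if g != SEAWATER_GROUP]

    def samples_of(self, group: str) -> list[str]:
        if group not in set(self.data["group"]):
            raise KeyError(f"unknown group: {group!r}")
        return list(self.data.index[self.data["group"] == group])

    def habitat_of(self, group: str) -> str:
        classes = set(self.data.loc[self.data["group"] == group, "habitat_class"])
        if len(classes) != 1:
            raise TableFormatError(f"group {group!r} maps to several habitat classes: {classes}")
        return classes.pop()

    def grouping(self, samples: Sequence[str], by: str = "group") -> pd.Series:
        """Label vector over ``samples`` (``by`` = 'group' or 'habitat_class')."""
        return self.data.loc[list(samples), by]


@dataclass
class TaxonomyTable:
    """taxon id → lineage at the ranks in :data:`RANKS` (missing ranks NaN)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "taxon")
        for rank in self.data.columns:
            if rank not in RANKS:
                raise TableFormatError(f"unknown rank column {rank!r}; expected {RANKS}")
        # keep ranks in canonical broad→narrow order
        cols = [r for r in RANKS if r in self.data.columns]
        self.data = self.data[cols]

    def label_at(self, rank: str, proteobacteria_to_class: bool = False) -> pd.Series:
        """Per-taxon label at ``rank``; unassigned taxa map to 'Unclassified'.

        With ``proteobacteria_to_class`` the phylum label of Proteobacteria
        taxa is replaced by their class, the usual convention for composition
        summaries of marine bacterial communities.
        """
        if rank not in RANKS:
            raise TableFormatError(f"unknown rank {rank!r}")
        if rank in self.data.columns:
            labels = self.data[rank].copy()
        else:
            labels = pd.Series(np.nan, index=self.data.index)
        if proteobacteria_to_class and rank == "phylum" and "class" in self.data.columns:
            is_proteo = self.data["phylum"] == "Proteobacteria"
            labels[is_proteo] = self.data.loc[is_proteo, "class"]
        return labels.fillna("Unclassified").replace("", "Unclassified")


@dataclass
class ValidationReport:
    """Cross-reference report between a count table and its metadata."""

    only_in_table: list[str] = field(default_factory=list)
    only_in_metadata: list[str] = field(default_factory=list)
    shared: list[str] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return not self.only_in_table and not self.only_in_metadata


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path: str | Path, format: str = "tsv", samples_as_rows: bool = False) -> CountTable:
    """Read a count table from TSV (taxa as rows by default) or BIOM 1.0 JSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.size == 0:
            raise TableFormatError(f"empty table: {path}")
        _check_unique(list(df.index), "row")
        _check_unique(list(df.columns), "column")
        if not samples_as_rows:
            df = df.T  # TSV convention: first column taxon ids, columns samples
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return CountTable(df)
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown count-table format {format!r}")


def write_count_table(table: CountTable, path: str | Path, format: str = "tsv",
                      samples_as_rows: bool = False) -> None:
    path = Path(path)
    if format == "tsv":
        df = table.data if samples_as_rows else table.data.T
        label = "#SampleID" if samples_as_rows else "#TaxonID"
        df.to_csv(path, sep="\t", index_label=label)
    elif format == "biom":
        _write_biom(table, path)
    else:
        raise ValueError(f"unknown count-table format {format!r}")


def _read_biom(path: Path) -> CountTable:
    # BIOM 1.0 JSON dialect: rows are observations (taxa), columns samples.
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape, dtype=np.int64)
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            mat[r, c] = v
    else:
        mat = np.asarray(doc["data"], dtype=np.int64)
    df = pd.DataFrame(mat.T, index=samples, columns=taxa)
    return CountTable(df)


def _write_biom(table: CountTable, path: Path) -> None:
    mat = table.data.to_numpy().T  # observations × samples
    rows, cols = np.nonzero(mat)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "spongecore",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [mat.shape[0], mat.shape[1]],
        "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": [[int(r), int(c), int(mat[r, c])] for r, c in zip(rows, cols)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample metadata TSV (sample_id, group, habitat_class[, ...])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise TableFormatError("metadata must have a 'sample_id' column")
    df = df.set_index("sample_id")
    if "replicate" in df.columns:
        df["replicate"] = df["replicate"].astype(int)
    return SampleMetadata(df)


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a taxonomy TSV (taxon_id plus any subset of the rank columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "taxon_id" not in df.columns:
        raise TableFormatError("taxonomy must have a 'taxon_id' column")
    return TaxonomyTable(df.set_index("taxon_id"))


def validate_pair(table: CountTable, meta: SampleMetadata) -> ValidationReport:
    """List samples present in exactly one of table/metadata.

    An empty intersection is a hard error; otherwise the caller decides
    (via :meth:`CountTable.subset_samples`) whether to proceed on the
    intersection.
    """
    t = set(table.sample_ids)
    m = set(meta.sample_ids)
    shared = sorted(t & m)
    if not shared:
        raise TableFormatError("count table and metadata share no samples")
    return ValidationReport(
        only_in_table=sorted(t - m),
        only_in_metadata=sorted(m - t),
        shared=shared,
    )
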