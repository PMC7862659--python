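"""Tabular I/O and the joint data model for tuber-microbiome studies.

The study design is a crossed factorial: potato cultivar x soil of origin x
storage timepoint, with three replicate tubers per cell.  Counts are 16S rRNA
amplicon reads clustered into operational taxonomic units (OTUs).  All on-disk
formats are plain UTF-8 TSV; the classic BIOM-TSV dialect (a single leading
``#`` comment/header line) is accepted on read.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CULTIVARS = ("A", "F", "H", "LC")
SOILS = ("PS", "KA", "KB", "K", "T")
TIMEPOINTS = ("T0", "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T7_Sprouts")
STABILITY_CLASSES = ("short", "medium", "long")

METADATA_COLUMNS = ("sample_id", "cultivar", "soil", "timepoint", "replicate",
                    "storage_days")


class TableFormatError(ValueError):
    """A file violates the expected tabular format (named cell/row)."""


class ValidationError(ValueError):
    """Parsed data violate the joint data model."""


@dataclasses.dataclass
class CountTable:
    """Integer sample x OTU abundance matrix.

    Parameters
    ----------
    sample_ids, otu_ids
        Ordered, unique identifiers.  Identifiers are opaque strings; design
        factors are never parsed out of sample names.
    counts
        Non-negative integer matrix, shape ``(n_samples, n_otus)``.
    taxonomy
        Optional map ``otu_id -> lineage string``.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}")
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            if len(set(ids)) != len(ids):
                dups = sorted({x for x in ids if ids.count(x) > 1})
                raise ValidationError(f"duplicate {name} ids: {dups}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids,
                            columns=self.otu_ids)

    def select_otus(self, otu_ids: Sequence[str]) -> "CountTable":
        """Subset columns, preserving this table's OTU order."""
        keep = set(otu_ids)
        missing = keep - set(self.otu_ids)
        if missing:
            raise ValidationError(f"unknown OTU ids: {sorted(missing)}")
        idx = [k for k, o in enumerate(self.otu_ids) if o in keep]
        otus = [self.otu_ids[k] for k in idx]
        tax = ({o: self.taxonomy[o] for o in otus if o in self.taxonomy}
               if self.taxonomy else None)
        return CountTable(list(self.sample_ids), otus, self.counts[:, idx], tax)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        """Subset rows in the order given."""
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        idx = [pos[s] for s in sample_ids]
        return CountTable(list(sample_ids), list(self.otu_ids),
                          self.counts[idx, :], self.taxonomy)


@dataclasses.dataclass
class StudyMetadata:
    """Per-sample design factors plus the storage-stability phenotype.

    ``storage_days`` is the number of days from harvest until the tubers of a
    cultivar x soil batch sprouted; it is constant within a batch.
    ``stability_class`` (short/medium/long) is derived later from tertiles of
    the batch-level storage days and may be unset.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.name != "sample_id":
            if "sample_id" in df.columns:
                df = df.set_index("sample_id")
            else:
                raise ValidationError("metadata needs a sample_id column")
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        for col in ("cultivar", "soil", "timepoint", "replicate",
                    "storage_days"):
            if col not in df.columns:
                raise ValidationError(f"metadata missing column {col!r}")
        for col, levels in (("cultivar", CULTIVARS), ("soil", SOILS),
                            ("timepoint", TIMEPOINTS)):
            bad = sorted(set(df[col].astype(str)) - set(levels))
            if bad:
                raise ValidationError(
                    f"unknown {col} level(s) {bad}; allowed: {list(levels)}")
        df["replicate"] = df["replicate"].astype(int)
        df["storage_days"] = df["storage_days"].astype(float)
        if (df["storage_days"] <= 0).any():
            raise ValidationError("storage_days must be positive")
        if "stability_class" in df.columns:
            known = set(STABILITY_CLASSES)
            bad = sorted(set(df["stability_class"].dropna()) - known)
            if bad:
                raise ValidationError(f"unknown stability class(es) {bad}")
        # replicate indices must be distinct within each design cell
        cell = df.groupby(["cultivar", "soil", "timepoint"], observed=True)
        for key, sub in cell:
            if sub["replicate"].duplicated().any():
                raise ValidationError(
                    f"duplicate replicate index in cell {key}")
        # storage_days is a batch-level (cultivar x soil) attribute
        per_batch = df.groupby(["cultivar", "soil"],
                               observed=True)["storage_days"].nunique()
        if (per_batch > 1).any():
            bad = per_batch[per_batch > 1].index.tolist()
            raise ValidationError(
                f"storage_days varies within cultivar x soil batch(es) {bad}")
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def storage_days(self) -> pd.Series:
        return self.frame["storage_days"]

    def batches(self) -> pd.DataFrame:
        """One row per cultivar x soil batch with its storage_days."""
        return (self.frame.reset_index()
                .groupby(["cultivar", "soil"], observed=True)
                .agg(storage_days=("storage_days", "first"))
                .reset_index())

    def aligned_to(self, table: CountTable) -> "StudyMetadata":
        """Reorder to a count table's samples; error on unmatched samples."""
        missing = [s for s in table.sample_ids if s not in self.frame.index]
        if missing:
            raise ValidationError(
                f"samples present in counts but absent from metadata: "
                f"{missing}")
        return StudyMetadata(self.frame.loc[table.sample_ids].copy())


@dataclasses.dataclass
class KeyOtu:
    """An OTU supported by both selection routes (random forest + network)."""

    otu_id: str
    direction: str  # short / medium / long
    r_storage: float  # signed Spearman rho with the storage-days node (0 if none)
    p_storage: float
    rf_importance_rank: int
    taxonomy: str = ""
    evidence: frozenset = frozenset({"rf", "network"})


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    skip = 0
    # classic BIOM-TSV: '# Constructed from biom file' banner before the header
    if first.startswith("#") and not first.lstrip("#").lstrip().startswith(
            ("OTU", "sample", "Sample", "otu")):
        skip = 1
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip, dtype=str)
    df.index = df.index.astype(str).str.lstrip("#")
    df.index.name = (df.index.name or "").lstrip("#") or None
    return df


def read_count_table(path: str | Path, orientation: str = "samples-as-rows",
                     taxonomy_column: str = "taxonomy") -> CountTable:
    """Read a tab-separated count matrix.

    Parameters
    ----------
    orientation
        ``"samples-as-rows"`` or ``"otus-as-rows"``.  The returned table is
        always samples x OTUs.
    taxonomy_column
        If a column (or row, under ``otus-as-rows``) with this name is
        present it is split off as the OTU lineage map.
    """
    if orientation not in ("samples-as-rows", "otus-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_tsv(path)
    taxonomy: dict[str, str] | None = None
    if orientation == "otus-as-rows":
        if taxonomy_column in df.columns:
            taxonomy = df[taxonomy_column].to_dict()
            df = df.drop(columns=[taxonomy_column])
        df = df.T
    elif taxonomy_column in df.index:
        taxonomy = df.loc[taxonomy_column].to_dict()
        df = df.drop(index=taxonomy_column)
    mat = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"non-integer count {raw!r} at row {df.index[i]!r}, "
                    f"column {col!r} of {path}") from None
            if val < 0:
                raise TableFormatError(
                    f"negative count {val} at row {df.index[i]!r}, "
                    f"column {col!r} of {path}")
            mat[i, j] = val
    return CountTable(list(df.index), list(df.columns), mat, taxonomy)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
    if table.taxonomy:
        tax_path = Path(path).with_suffix(".taxonomy.tsv")
        pd.Series(table.taxonomy, name="taxonomy").rename_axis(
            "otu_id").to_csv(tax_path, sep="\t")


def read_metadata(path: str | Path) -> StudyMetadata:
    """Read and validate the per-sample design table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"metadata file missing column(s) {missing}")
    return StudyMetadata(df)


def write_metadata(meta: StudyMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t")


_KEY_OTU_COLUMNS = ("otu_id", "taxonomy", "direction", "r_storage",
                    "p_storage", "rf_importance_rank")


def write_key_otu_report(key_otus: Iterable[KeyOtu], path: str | Path) -> None:
    """Write the key-OTU report as TSV (lossless round trip)."""
    rows = [{"otu_id": k.otu_id, "taxonomy": k.taxonomy,
             "direction": k.direction, "r_storage": repr(float(k.r_storage)),
             "p_storage": repr(float(k.p_storage)),
             "rf_importance_rank": k.rf_importance_rank}
            for k in key_otus]
    pd.DataFrame(rows, columns=_KEY_OTU_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_key_otu_report(path: str | Path) -> list[KeyOtu]:
    df = pd.read_csv(path, sep="\t", dtype={"otu_id": str, "taxonomy": str,
                                            "direction": str})
    out = []
    for _, row in df.iterrows():
        tax = row["taxonomy"]
        out.append(KeyOtu(otu_id=row["otu_id"],
                          direction=row["direction"],
                          r_storage=float(row["r_storage"]),
                          p_storage=float(row["p_storage"]),
                          rf_importance_rank=int(row["rf_importance_rank"]),
                          taxonomy="" if pd.isna(tax) else str(tax)))
    return out
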