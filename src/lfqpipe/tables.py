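"""Quantification-table and study-design I/O in the MaxQuant dialect.

The pipeline consumes two tab-delimited quantification tables as written by
MaxQuant-era search engines: a peptide-level table (``peptides.txt``) with
per-sample intensities and fragmentation-spectrum (MS/MS) counts, and a
protein-group-level table (``proteinGroups.txt``) whose abundances come from
the label-free quantification (LFQ) column family.  A third, three-column
design table assigns each sample a class (whole-tissue-lysate control,
laser-capture-microdissection control, or experimental) and, for experimental
samples, a biological group label such as ``ER+`` / ``ER-``.

Conventions of the dialect, applied on read:

* an intensity of ``0`` (or a blank cell) means *not observed* and becomes
  missing (NaN) — downstream missing-data statistics rely on this reading;
* decoy entries are flagged by a marker (``+`` by default) in the ``Reverse``
  column;
* a peptide is *unique* iff it maps to exactly one protein group in the
  ``Proteins`` column (``;``-separated identifiers).

All column names are overridable through the dialect dataclasses, so other
tab-delimited exports can be adapted without touching the core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TableFormatError",
    "TableDataError",
    "DesignValidationError",
    "PeptideDialect",
    "ProteinDialect",
    "PeptideQuantTable",
    "ProteinQuantTable",
    "StudyDesign",
    "SAMPLE_CLASSES",
    "read_peptide_table",
    "write_peptide_table",
    "read_protein_table",
    "write_protein_table",
    "read_design",
    "write_design",
    "check_sample_axes",
    "write_results_table",
    "convert_xlsx_to_tsv",
]

SAMPLE_CLASSES = ("WTL-CTRL", "LCM-CTRL", "EXPERIMENTAL")


class TableFormatError(ValueError):
    """A mandatory column or structural element of the dialect is absent."""


class TableDataError(ValueError):
    """Cell-level content violates the dialect (non-numeric, duplicate key...)."""


class DesignValidationError(ValueError):
    """The study design is inconsistent with itself or with the tables."""


@dataclass(frozen=True)
class PeptideDialect:
    """Column naming for peptide-level tables (MaxQuant ``peptides.txt``)."""

    sequence_col: str = "Sequence"
    proteins_col: str = "Proteins"
    reverse_col: str = "Reverse"
    reverse_marker: str = "+"
    intensity_prefix: str = "Intensity "
    msms_prefix: str = "MS/MS Count "


@dataclass(frozen=True)
class ProteinDialect:
    """Column naming for protein-group tables (MaxQuant ``proteinGroups.txt``)."""

    id_col: str = "Protein IDs"
    entry_col: str = "Entry name"
    reverse_col: str = "Reverse"
    reverse_marker: str = "+"
    lfq_prefix: str = "LFQ intensity "
    msms_prefix: str = "MS/MS Count "


def _split_ids(cell: str) -> tuple[str, ...]:
    return tuple(tok for tok in str(cell).split(";") if tok.strip())


def _parse_numeric(raw: pd.Series, column: str) -> pd.Series:
    """Parse a string column to float, reporting the first offending cell."""
    stripped = raw.str.strip()
    values = pd.to_numeric(stripped.replace("", np.nan), errors="coerce")
    bad = values.isna() & (stripped != "") & ~stripped.str.lower().isin(["nan", "na"])
    if bad.any():
        row = bad[bad].index[0]
        raise TableDataError(
            f"non-numeric value {raw.loc[row]!r} in column {column!r}, row {row!r}"
        )
    return values.astype(float)


@dataclass
class PeptideQuantTable:
    """Peptide rows with per-sample intensities and spectral counts.

    ``intensity`` and ``msms`` share the same index (peptide sequence) and the
    same ordered sample columns.  Intensities are linear-scale positive floats
    with NaN for *not observed*; ``msms`` holds non-negative integer spectral
    counts (0 where nothing was fragmented).
    """

    intensity: pd.DataFrame
    msms: pd.DataFrame
    protein_groups: pd.Series  # peptide -> tuple of protein-group ids
    is_reverse: pd.Series      # peptide -> bool

    def __post_init__(self) -> None:
        idx = self.intensity.index
        for name, other in (("msms", self.msms.index),
                            ("protein_groups", self.protein_groups.index),
                            ("is_reverse", self.is_reverse.index)):
            if not idx.equals(other):
                raise TableDataError(f"peptide axis of {name} differs from intensity")
        if not idx.is_unique:
            dup = idx[idx.duplicated()][0]
            raise TableDataError(f"duplicate peptide key {dup!r}")
        if not self.intensity.columns.equals(self.msms.columns):
            raise TableDataError("sample axis of msms differs from intensity")
        vals = self.intensity.to_numpy()
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise TableDataError("observed intensities must be positive")
        if (self.msms.to_numpy() < 0).any():
            raise TableDataError("spectral counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.intensity.columns)

    @property
    def peptide_keys(self) -> pd.Index:
        return self.intensity.index

    @property
    def is_unique(self) -> pd.Series:
        return self.protein_groups.map(len) == 1

    def select(self, keys) -> "PeptideQuantTable":
        """Row subset preserving the given key order."""
        return PeptideQuantTable(
            intensity=self.intensity.loc[keys],
            msms=self.msms.loc[keys],
            protein_groups=self.protein_groups.loc[keys],
            is_reverse=self.is_reverse.loc[keys],
        )

    def equals(self, other: "PeptideQuantTable") -> bool:
        return (
            self.intensity.equals(other.intensity)
            and self.msms.equals(other.msms)
            and self.protein_groups.equals(other.protein_groups)
            and self.is_reverse.equals(other.is_reverse)
        )


@dataclass
class ProteinQuantTable:
    """Protein-group rows with per-sample (LFQ) abundances and MS/MS counts."""

    abundance: pd.DataFrame
    msms: pd.DataFrame
    entry_names: pd.Series  # protein-group id -> tuple of database entry names
    is_reverse: pd.Series

    def __post_init__(self) -> None:
        idx = self.abundance.index
        if not idx.is_unique:
            dup = idx[idx.duplicated()][0]
            raise TableDataError(f"duplicate protein_group_id {dup!r}")
        for name, other in (("msms", self.msms.index),
                            ("entry_names", self.entry_names.index),
                            ("is_reverse", self.is_reverse.index)):
            if not idx.equals(other):
                raise TableDataError(f"protein axis of {name} differs from abundance")
        if not self.abundance.columns.equals(self.msms.columns):
            raise TableDataError("sample axis of msms differs from abundance")
        vals = self.abundance.to_numpy()
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise TableDataError("observed abundances must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def protein_group_ids(self) -> pd.Index:
        return self.abundance.index

    def by_entry_name(self, entry: str) -> pd.Index:
        """Protein-group ids whose entry-name list contains ``entry``."""
        hit = self.entry_names.map(lambda names: entry in names)
        return self.entry_names.index[hit]

    def select(self, keys) -> "ProteinQuantTable":
        return ProteinQuantTable(
            abundance=self.abundance.loc[keys],
            msms=self.msms.loc[keys],
            entry_names=self.entry_names.loc[keys],
            is_reverse=self.is_reverse.loc[keys],
        )

    def equals(self, other: "ProteinQuantTable") -> bool:
        return (
            self.abundance.equals(other.abundance)
            and self.msms.equals(other.msms)
            and self.entry_names.equals(other.entry_names)
            and self.is_reverse.equals(other.is_reverse)
        )


@dataclass
class StudyDesign:
    """Sample → class + biological-group mapping with deterministic order."""

    frame: pd.DataFrame  # index sample_id; columns sample_class, group_label, order_index

    def __post_init__(self) -> None:
        if len(self.frame) == 0:
            raise DesignValidationError("design contains no samples")
        if not self.frame.index.is_unique:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise DesignValidationError(f"duplicate sample_id {dup!r}")
        bad = ~self.frame["sample_class"].isin(SAMPLE_CLASSES)
        if bad.any():
            tok = self.frame.loc[bad, "sample_class"].iloc[0]
            raise DesignValidationError(f"unknown sample_class {tok!r}")
        exp = self.frame["sample_class"] == "EXPERIMENTAL"
        empty = exp & (self.frame["group_label"].fillna("") == "")
        if empty.any():
            sid = self.frame.index[empty][0]
            raise DesignValidationError(
                f"EXPERIMENTAL sample {sid!r} lacks a group_label"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.frame.sort_values("order_index").index)

    def class_samples(self, sample_class: str) -> list[str]:
        sub = self.frame[self.frame["sample_class"] == sample_class]
        return list(sub.sort_values("order_index").index)

    @property
    def experimental(self) -> list[str]:
        return self.class_samples("EXPERIMENTAL")

    def groups(self) -> dict[str, list[str]]:
        """Biological groups of the experimental samples, in design order."""
        out: dict[str, list[str]] = {}
        sub = self.frame[self.frame["sample_class"] == "EXPERIMENTAL"]
        for sid, row in sub.sort_values("order_index").iterrows():
            out.setdefault(row["group_label"], []).append(sid)
        return out

    def group_pair(self) -> tuple[str, list[str], str, list[str]]:
        """The two-group contrast (label1, samples1, label2, samples2)."""
        grp = self.groups()
        if len(grp) != 2:
            raise DesignValidationError(
                f"expected exactly 2 experimental groups, found {len(grp)}"
            )
        (l1, s1), (l2, s2) = grp.items()
        return l1, s1, l2, s2

    def subset(self, sample_ids) -> "StudyDesign":
        return StudyDesign(self.frame.loc[list(sample_ids)].copy())


def read_peptide_table(path, dialect: PeptideDialect | None = None) -> PeptideQuantTable:
    """Load a tab-delimited peptide table; zeros/blanks become missing."""
    dialect = dialect or PeptideDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (dialect.sequence_col, dialect.proteins_col):
        if col not in df.columns:
            raise TableFormatError(f"missing mandatory column {col!r}")
    int_cols = [c for c in df.columns if c.startswith(dialect.intensity_prefix)]
    if not int_cols:
        raise TableFormatError(
            f"no intensity columns with prefix {dialect.intensity_prefix!r}"
        )
    samples = [c[len(dialect.intensity_prefix):] for c in int_cols]
    df = df.set_index(df[dialect.sequence_col].astype(str))
    df.index.name = "peptide_key"
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][0]
        raise TableDataError(f"duplicate peptide key {dup!r}")

    intensity = pd.DataFrame(index=df.index)
    msms = pd.DataFrame(index=df.index)
    for s, col in zip(samples, int_cols):
        vals = _parse_numeric(df[col], col)
        intensity[s] = vals.where(vals > 0)  # 0 / blank -> missing
        mcol = dialect.msms_prefix + s
        if mcol in df.columns:
            msms[s] = (
                _parse_numeric(df[mcol], mcol).fillna(0.0).round().astype(int)
            )
        else:
            msms[s] = 0
    if dialect.reverse_col in df.columns:
        is_reverse = df[dialect.reverse_col].str.strip() == dialect.reverse_marker
    else:
        is_reverse = pd.Series(False, index=df.index)
    protein_groups = df[dialect.proteins_col].map(_split_ids)
    return PeptideQuantTable(
        intensity=intensity,
        msms=msms,
        protein_groups=protein_groups.rename("protein_groups"),
        is_reverse=is_reverse.rename("is_reverse").astype(bool),
    )


def write_peptide_table(table: PeptideQuantTable, path,
                        dialect: PeptideDialect | None = None) -> None:
    """Write a peptide table back to the dialect (missing → 0)."""
    dialect = dialect or PeptideDialect()
    out = pd.DataFrame(index=table.peptide_keys)
    out[dialect.sequence_col] = table.peptide_keys
    out[dialect.proteins_col] = table.protein_groups.map(";".join)
    out[dialect.reverse_col] = np.where(table.is_reverse, dialect.reverse_marker, "")
    for s in table.samples:
        out[dialect.intensity_prefix + s] = table.intensity[s].fillna(0.0)
    for s in table.samples:
        out[dialect.msms_prefix + s] = table.msms[s]
    out.to_csv(path, sep="\t", index=False)


def read_protein_table(path, dialect: ProteinDialect | None = None) -> ProteinQuantTable:
    """Load a tab-delimited protein-group table (LFQ abundance family)."""
    dialect = dialect or ProteinDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect.id_col not in df.columns:
        raise TableFormatError(f"missing mandatory column {dialect.id_col!r}")
    lfq_cols = [c for c in df.columns if c.startswith(dialect.lfq_prefix)]
    if not lfq_cols:
        raise TableFormatError(
            f"no abundance columns with prefix {dialect.lfq_prefix!r}"
        )
    samples = [c[len(dialect.lfq_prefix):] for c in lfq_cols]
    df = df.set_index(df[dialect.id_col].astype(str))
    df.index.name = "protein_group_id"
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()][0]
        raise TableDataError(f"duplicate protein_group_id {dup!r}")

    abundance = pd.DataFrame(index=df.index)
    msms = pd.DataFrame(index=df.index)
    for s, col in zip(samples, lfq_cols):
        vals = _parse_numeric(df[col], col)
        abundance[s] = vals.where(vals > 0)
        mcol = dialect.msms_prefix + s
        if mcol in df.columns:
            msms[s] = _parse_numeric(df[mcol], mcol).fillna(0.0).round().astype(int)
        else:
            msms[s] = 0
    if dialect.entry_col in df.columns:
        entry_names = df[dialect.entry_col].map(_split_ids)
    else:
        entry_names = pd.Series(df.index, index=df.index).map(lambda x: (x,))
    if dialect.reverse_col in df.columns:
        is_reverse = df[dialect.reverse_col].str.strip() == dialect.reverse_marker
    else:
        is_reverse = pd.Series(False, index=df.index)
    return ProteinQuantTable(
        abundance=abundance,
        msms=msms,
        entry_names=entry_names.rename("entry_names"),
        is_reverse=is_reverse.rename("is_reverse").astype(bool),
    )


def write_protein_table(table: ProteinQuantTable, path,
                        dialect: ProteinDialect | None = None) -> None:
    dialect = dialect or ProteinDialect()
    out = pd.DataFrame(index=table.protein_group_ids)
    out[dialect.id_col] = table.protein_group_ids
    out[dialect.entry_col] = table.entry_names.map(";".join)
    out[dialect.reverse_col] = np.where(table.is_reverse, dialect.reverse_marker, "")
    for s in table.samples:
        out[dialect.lfq_prefix + s] = table.abundance[s].fillna(0.0)
    for s in table.samples:
        out[dialect.msms_prefix + s] = table.msms[s]
    out.to_csv(path, sep="\t", index=False)


def read_design(path) -> StudyDesign:
    """Read the 3-column tab-delimited design file (sample_id, class, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "sample_class", "group_label"]
    for col in required[:2]:
        if col not in df.columns:
            raise DesignValidationError(f"design lacks column {col!r}")
    if "group_label" not in df.columns:
        df["group_label"] = ""
    if len(df) == 0:
        raise DesignValidationError("design file is empty")
    frame = pd.DataFrame(
        {
            "sample_class": df["sample_class"].str.strip().values,
            "group_label": df["group_label"].str.strip().values,
            "order_index": np.arange(len(df)),
        },
        index=pd.Index(df["sample_id"].str.strip(), name="sample_id"),
    )
    return StudyDesign(frame)


def write_design(design: StudyDesign, path) -> None:
    out = design.frame.sort_values("order_index")[["sample_class", "group_label"]]
    out.to_csv(path, sep="\t", index=True, index_label="sample_id")


def check_sample_axes(design: StudyDesign,
                      peptides: PeptideQuantTable | None = None,
                      proteins: ProteinQuantTable | None = None) -> None:
    """Fail fast if any quantified sample is absent from the design.

    Extra design samples (a superset design) are accepted with a warning.
    When both tables are given their sample axes must agree exactly.
    """
    known = set(design.frame.index)
    referenced: set[str] = set()
    for name, table in (("peptide", peptides), ("protein", proteins)):
        if table is None:
            continue
        referenced.update(table.samples)
        missing = [s for s in table.samples if s not in known]
        if missing:
            raise DesignValidationError(
                f"{name} table sample(s) {missing} not present in the design"
            )
    if peptides is not None and proteins is not None:
        if list(peptides.samples) != list(proteins.samples):
            raise DesignValidationError(
                "peptide and protein tables have different sample axes"
            )
    extra = sorted(known - referenced) if referenced else []
    if extra:
        warnings.warn(
            f"design contains {len(extra)} sample(s) absent from the tables: {extra}",
            stacklevel=2,
        )


def write_results_table(frame: pd.DataFrame, path, index_label: str | None = None) -> None:
    """Write a results table: TSV, fixed column order, NA for missing, 6 s.d.

    Successive writes of the same frame are byte-identical.
    """
    if frame is None or len(frame) == 0:
        raise TableDataError("refusing to write an empty results table")
    frame.to_csv(
        path,
        sep="\t",
        na_rep="NA",
        float_format="%.6g",
        index=True,
        index_label=index_label or frame.index.name or "id",
    )


def convert_xlsx_to_tsv(xlsx_path, tsv_path, sheet: int | str = 0) -> None:
    """Convert one sheet of an XLSX workbook to the tab-delimited dialect.

    Utility for supplementary workbooks distributed as spreadsheets; the
    pipeline core reads only the tab-delimited dialect.
    """
    df = pd.read_excel(xlsx_path, sheet_name=sheet)
    df.to_csv(tsv_path, sep="\t", index=False)
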