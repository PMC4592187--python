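"""Expression matrices, sample sheets, RPKM normalization and missing-value rules.

The in-memory containers are thin wrappers around :class:`pandas.DataFrame`:
an :class:`ExpressionTable` is a gene x sample numeric matrix tagged with a
unit (``counts``, ``rpkm`` or ``log2rpkm``), and a :class:`DesignSheet` maps
each sample to its factor levels in the two-stressor factorial design — a
dose of stressor A (0 = vehicle), an on/off flag for stressor B (e.g.
irradiated or not), a time point and a replicate index.

All files are UTF-8, tab-delimited, with ``NA`` as the missing-value token;
writers always emit ``\\n`` line endings, readers accept ``\\r\\n``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

UNITS = ("counts", "rpkm", "log2rpkm")

__all__ = [
    "ExpressionTable",
    "DesignSheet",
    "ParseError",
    "make_condition_id",
    "compute_rpkm",
    "apply_single_missing_rule",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "read_lengths_tsv",
    "write_lengths_tsv",
]


class ParseError(ValueError):
    """Raised for malformed TSV inputs; the message carries the line number."""


def make_condition_id(doseA: float, flagB: bool, time) -> str:
    """Canonical key for one cell of the factorial design, e.g. ``A1_B1_t8``."""
    return f"A{float(doseA):g}_B{int(bool(flagB))}_t{time}"


@dataclass
class ExpressionTable:
    """Gene x sample expression matrix with explicit missing values (NaN).

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns. Missing
        entries are NaN; for ``counts``/``rpkm`` units all present values
        must be non-negative.
    unit
        One of ``counts``, ``rpkm``, ``log2rpkm``.
    """

    values: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        idx, cols = self.values.index, self.values.columns
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValueError(f"duplicate gene ids: {dups[:10]}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dups[:10]}")
        self.values = self.values.astype(float)
        if self.unit in ("counts", "rpkm"):
            arr = self.values.to_numpy()
            if np.any(arr[~np.isnan(arr)] < 0):
                raise ValueError(f"negative values not allowed for unit {self.unit!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "ExpressionTable":
        return ExpressionTable(self.values.loc[:, list(sample_ids)].copy(), self.unit)

    def equals(self, other: "ExpressionTable") -> bool:
        return (
            self.unit == other.unit
            and self.values.index.equals(other.values.index)
            and self.values.columns.equals(other.values.columns)
            and np.allclose(
                self.values.to_numpy(), other.values.to_numpy(), equal_nan=True
            )
        )


@dataclass
class DesignSheet:
    """Per-sample factor assignments for the factorial design.

    ``table`` is indexed by sample id with columns ``doseA`` (float, 0 means
    vehicle), ``flagB`` (bool), ``time`` (label), ``replicate`` (int) and the
    derived ``condition_id`` grouping key.
    """

    table: pd.DataFrame

    REQUIRED = ("doseA", "flagB", "time", "replicate")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"design sheet missing columns: {missing}")
        if t.index.duplicated().any():
            dups = sorted(set(t.index[t.index.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dups[:10]}")
        t = t.copy()
        t["doseA"] = t["doseA"].astype(float)
        if (t["doseA"] < 0).any():
            raise ValueError("doseA must be non-negative")
        t["flagB"] = t["flagB"].astype(bool)
        t["replicate"] = t["replicate"].astype(int)
        t["condition_id"] = [
            make_condition_id(d, b, tt)
            for d, b, tt in zip(t["doseA"], t["flagB"], t["time"])
        ]
        dup = t.duplicated(subset=["condition_id", "replicate"])
        if dup.any():
            raise ValueError(
                "replicate indices not unique within condition: "
                f"{t.index[dup].tolist()[:10]}"
            )
        self.table = t

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def condition_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.table["condition_id"]:
            seen.setdefault(c, None)
        return list(seen)

    def samples(self, condition_id: str) -> list[str]:
        """Sample ids belonging to one condition cell (possibly empty)."""
        mask = self.table["condition_id"] == condition_id
        return list(self.table.index[mask])

    def subset(self, sample_ids) -> "DesignSheet":
        return DesignSheet(self.table.loc[list(sample_ids)].drop(columns="condition_id"))

    def equals(self, other: "DesignSheet") -> bool:
        a = self.table[list(self.REQUIRED)]
        b = other.table[list(self.REQUIRED)]
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True


# ---------------------------------------------------------------------------
# RPKM and the single-missing-replicate rule
# ---------------------------------------------------------------------------

def compute_rpkm(
    counts: ExpressionTable,
    lengths: pd.Series,
    library_sizes="derive",
) -> ExpressionTable:
    """Reads per kilobase of transcript per million reads.

    ``rpkm[g, s] = counts[g, s] / (length_kb[g] * library_size[s] / 1e6)``.

    Parameters
    ----------
    counts
        Raw count table (unit ``counts``). Missing counts stay missing.
    lengths
        Per-gene transcript length in bp, indexed by gene id; every gene in
        ``counts`` must have a positive length.
    library_sizes
        Per-sample total read counts (Series indexed by sample id), or the
        string ``"derive"`` to use per-sample column sums of the matrix
        itself (missing entries excluded).
    """
    if counts.unit != "counts":
        raise ValueError(f"expected a counts table, got unit {counts.unit!r}")
    lengths = pd.Series(lengths).astype(float)
    missing_len = [g for g in counts.gene_ids if g not in lengths.index]
    if missing_len:
        raise ValueError(f"genes without length: {missing_len[:10]}")
    lengths = lengths.loc[counts.gene_ids]
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])
        raise ValueError(f"non-positive gene lengths: {bad[:10]}")

    if isinstance(library_sizes, str) and library_sizes == "derive":
        lib = counts.values.sum(axis=0, skipna=True)
    else:
        lib = pd.Series(library_sizes).astype(float)
        missing_lib = [s for s in counts.sample_ids if s not in lib.index]
        if missing_lib:
            raise ValueError(f"samples without library size: {missing_lib[:10]}")
        lib = lib.loc[counts.sample_ids]
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"non-positive library sizes: {bad[:10]}")

    length_kb = lengths.to_numpy() / 1e3
    lib_m = lib.to_numpy() / 1e6
    rpkm = counts.values.to_numpy() / (length_kb[:, None] * lib_m[None, :])
    return ExpressionTable(
        pd.DataFrame(rpkm, index=counts.gene_ids, columns=counts.sample_ids), "rpkm"
    )


def apply_single_missing_rule(
    table: ExpressionTable, design: DesignSheet
) -> ExpressionTable:
    """Convert lone zero replicates to missing, condition by condition.

    Within each condition's replicate set for each gene: if exactly one
    present value is zero and every other present value is positive (and at
    least two values are present), the zero becomes NA. All other patterns —
    two or more zeros, all zeros, no zeros — are left unchanged, so the rule
    is idempotent. Conditions with fewer than two samples are untouched.
    """
    vals = table.values.copy()
    for cond in design.condition_ids():
        cols = [s for s in design.samples(cond) if s in vals.columns]
        if len(cols) < 2:
            continue
        sub = vals[cols].to_numpy()
        present = ~np.isnan(sub)
        zeros = (sub == 0) & present
        n_present = present.sum(axis=1)
        n_zero = zeros.sum(axis=1)
        n_pos = ((sub > 0) & present).sum(axis=1)
        rows = (n_zero == 1) & (n_pos == n_present - 1) & (n_present >= 2)
        if rows.any():
            sub[rows[:, None] & zeros] = np.nan
            vals.loc[:, cols] = sub
    return ExpressionTable(vals, table.unit)


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def _read_tsv_numeric(path, index_label: str) -> pd.DataFrame:
    """Read a TSV with a string index column and numeric body ('NA' = missing).

    Raises :class:`ParseError` with a 1-based line number for duplicate ids,
    ragged rows and non-numeric cells.
    """
    raw = pd.read_csv(
        path,
        sep="\t",
        dtype=str,
        header=0,
        index_col=0,
        keep_default_na=False,
        skip_blank_lines=False,
    )
    idx = raw.index.astype(str)
    if idx.duplicated().any():
        dup = idx[idx.duplicated()][0]
        line = int(np.nonzero(idx == dup)[0][1]) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}: duplicate {index_label} {dup!r} at line {line}")
    out = {}
    for col in raw.columns:
        cells = raw[col].astype(str).str.strip()
        cells = cells.mask(cells == "NA")
        converted = pd.to_numeric(cells, errors="coerce")
        bad = converted.isna() & cells.notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ParseError(
                f"{path}: non-numeric cell {cells.iloc[row]!r} in column "
                f"{col!r} at line {row + 2}"
            )
        out[col] = converted
    df = pd.DataFrame(out, index=idx)
    df.index.name = index_label
    return df


def read_expression_tsv(path, unit: str = "counts") -> ExpressionTable:
    """Read a gene x sample expression TSV (first column ``gene_id``)."""
    df = _read_tsv_numeric(path, "gene_id")
    if df.columns.duplicated().any():
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ParseError(f"{path}: duplicate sample ids {dups[:10]} in header")
    return ExpressionTable(df, unit)


def write_expression_tsv(table: ExpressionTable, path) -> None:
    table.values.to_csv(
        path, sep="\t", na_rep="NA", index_label="gene_id", lineterminator="\n"
    )


def read_design_tsv(path) -> DesignSheet:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "doseA", "flagB", "time", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: design sheet missing columns {missing}")
    df = df.set_index("sample_id")
    try:
        table = pd.DataFrame(
            {
                "doseA": pd.to_numeric(df["doseA"]),
                "flagB": pd.to_numeric(df["flagB"]).astype(bool),
                "time": [_maybe_int(t) for t in df["time"]],
                "replicate": pd.to_numeric(df["replicate"]).astype(int),
            },
            index=df.index,
        )
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric design value ({exc})") from exc
    return DesignSheet(table)


def _maybe_int(label: str):
    try:
        return int(label)
    except (TypeError, ValueError):
        return label


def write_design_tsv(design: DesignSheet, path) -> None:
    out = design.table[list(DesignSheet.REQUIRED)].copy()
    out["flagB"] = out["flagB"].astype(int)
    out.to_csv(path, sep="\t", index_label="sample_id", lineterminator="\n")


def read_lengths_tsv(path) -> pd.Series:
    df = _read_tsv_numeric(path, "gene_id")
    if "length_bp" not in df.columns:
        raise ParseError(f"{path}: expected columns gene_id, length_bp")
    lengths = df["length_bp"].astype(float)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = list(lengths.index[lengths.isna() | (lengths <= 0)])
        raise ParseError(f"{path}: missing or non-positive lengths for {bad[:10]}")
    return lengths


def write_lengths_tsv(lengths: pd.Series, path) -> None:
    out = pd.DataFrame({"length_bp": pd.Series(lengths).astype(int)})
    out.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")
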