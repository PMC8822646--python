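"""Tabular input/output with strict validation.

All study inputs are plain delimiter-separated text files:

* a gene x sample read-count matrix carrying per-sample mapped-read totals
  (either as a reserved ``__mapped_totals__`` row or a two-column sidecar);
* a sample sheet describing patients, disease group (IPF vs control),
  Ashcroft fibrosis score and the sampled lung segment;
* the kinome-panel gene annotation: transcript length, gene category and a
  flag marking kinases with clinically available inhibitors.

Validation is strict and fails loudly with the offending identifiers or
cell coordinates; valid inputs never raise.
"""
from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TOTALS_ROW = "__mapped_totals__"
GROUP_IPF = "IPF"
GROUP_CONTROL = "control"
#: Ashcroft score at or above which a sample counts as severely fibrotic.
SEVERE_ASHCROFT = 6

_GROUP_ALIASES = {"ipf": GROUP_IPF, "control": GROUP_CONTROL, "ctrl": GROUP_CONTROL}
_CATEGORIES = ("kinase", "cancer_related")


class ValidationError(ValueError):
    """An input table violates its documented contract."""


def _check_unique(ids: Sequence, kind: str) -> None:
    dup = [k for k, c in Counter(ids).items() if c > 1]
    if dup:
        raise ValidationError(f"duplicate {kind} id(s): {sorted(map(str, dup))}")


@dataclasses.dataclass(frozen=True)
class GenePanel:
    """Gene-panel annotation: transcript lengths, category and inhibitor flag.

    ``frame`` is indexed by gene symbol with columns ``transcript_length_bp``
    (positive int), ``category`` (``kinase`` or ``cancer_related``) and
    ``inhibitor_available`` (bool marking the clinically actionable subpanel).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        required = {"transcript_length_bp", "category", "inhibitor_available"}
        missing = required - set(f.columns)
        if missing:
            raise ValidationError(f"gene panel missing column(s): {sorted(missing)}")
        if len(f) == 0:
            raise ValidationError("gene panel is empty")
        _check_unique(list(f.index), "gene")
        lengths = f["transcript_length_bp"]
        if not np.all(np.isfinite(lengths)) or np.any(lengths != np.floor(lengths)):
            raise ValidationError("transcript_length_bp must be integral")
        if (lengths < 1).any():
            bad = list(f.index[lengths < 1])
            raise ValidationError(f"transcript_length_bp < 1 for gene(s): {bad}")
        bad_cat = sorted(set(f["category"]) - set(_CATEGORIES))
        if bad_cat:
            raise ValidationError(f"unknown gene category value(s): {bad_cat}")
        norm = f.assign(
            transcript_length_bp=lengths.astype(np.int64),
            inhibitor_available=f["inhibitor_available"].astype(bool),
        )
        object.__setattr__(self, "frame", norm)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def lengths(self) -> pd.Series:
        return self.frame["transcript_length_bp"]

    @property
    def inhibitor_genes(self) -> list[str]:
        return list(self.frame.index[self.frame["inhibitor_available"]])

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t") -> "GenePanel":
        df = _read_table(path, sep, "gene panel")
        df = df.set_index(df.columns[0])
        df.index.name = "gene_id"
        if "transcript_length_bp" in df.columns:
            df["transcript_length_bp"] = pd.to_numeric(
                df["transcript_length_bp"], errors="coerce")
        if "inhibitor_available" in df.columns:
            df["inhibitor_available"] = _parse_bool(df["inhibitor_available"])
        return cls(df)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        out = self.frame.copy()
        out["inhibitor_available"] = out["inhibitor_available"].astype(int)
        out.to_csv(path, sep=sep, index_label="gene_id")


def _parse_bool(col: pd.Series) -> pd.Series:
    mapping = {"1": True, "0": False, "true": True, "false": False,
               "yes": True, "no": False}
    def one(v):
        s = str(v).strip().lower()
        if s not in mapping:
            raise ValidationError(f"cannot parse boolean flag value {v!r}")
        return mapping[s]
    return col.map(one)


@dataclasses.dataclass(frozen=True)
class SampleSheet:
    """Per-sample metadata: patient, group, Ashcroft score, segment label.

    Ashcroft scores are integers 0-8 and are mandatory for IPF samples;
    control samples may leave the score blank (recorded as missing).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if len(f) == 0:
            raise ValidationError("no samples in sample sheet")
        required = {"patient_id", "group", "ashcroft_score", "segment_label"}
        missing = required - set(f.columns)
        if missing:
            raise ValidationError(f"sample sheet missing column(s): {sorted(missing)}")
        _check_unique(list(f.index), "sample")
        group = f["group"].map(lambda g: _GROUP_ALIASES.get(str(g).strip().lower()))
        if group.isna().any():
            bad = sorted(set(f["group"][group.isna()].astype(str)))
            raise ValidationError(f"unknown group value(s): {bad}")
        score = pd.to_numeric(f["ashcroft_score"], errors="coerce")
        raw_present = f["ashcroft_score"].notna() & (f["ashcroft_score"].astype(str).str.strip() != "")
        if (raw_present & score.isna()).any():
            bad = list(f.index[raw_present & score.isna()])
            raise ValidationError(f"non-numeric ashcroft_score for sample(s): {bad}")
        present = score.notna()
        if present.any():
            vals = score[present]
            if np.any(vals != np.floor(vals)) or (vals < 0).any() or (vals > 8).any():
                raise ValidationError("ashcroft_score must be an integer in 0..8")
        missing_ipf = list(f.index[(group == GROUP_IPF) & ~present])
        if missing_ipf:
            raise ValidationError(
                f"IPF sample(s) missing Ashcroft score: {missing_ipf}")
        per_patient = pd.DataFrame({"patient": f["patient_id"], "group": group})
        n_groups = per_patient.groupby("patient")["group"].nunique()
        mixed = list(n_groups.index[n_groups > 1])
        if mixed:
            raise ValidationError(f"patient(s) assigned to both groups: {mixed}")
        norm = f.assign(group=group, ashcroft_score=score)
        norm.index.name = "sample_id"
        object.__setattr__(self, "frame", norm)

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.frame["patient_id"]))

    def samples_of(self, patient: str) -> list[str]:
        sel = self.frame.index[self.frame["patient_id"] == patient]
        if len(sel) == 0:
            raise KeyError(f"unknown patient id: {patient}")
        return list(sel)

    def group_of(self, patient: str) -> str:
        return str(self.frame.loc[self.frame["patient_id"] == patient, "group"].iloc[0])

    @property
    def ipf_samples(self) -> list[str]:
        return list(self.frame.index[self.frame["group"] == GROUP_IPF])

    @property
    def control_samples(self) -> list[str]:
        return list(self.frame.index[self.frame["group"] == GROUP_CONTROL])

    def severe_samples(self, threshold: float = SEVERE_ASHCROFT) -> list[str]:
        """IPF samples with Ashcroft score at or above ``threshold``."""
        f = self.frame
        m = (f["group"] == GROUP_IPF) & (f["ashcroft_score"] >= threshold)
        return list(f.index[m])

    def moderate_samples(self, threshold: float = SEVERE_ASHCROFT) -> list[str]:
        """IPF samples with Ashcroft score below ``threshold``."""
        f = self.frame
        m = (f["group"] == GROUP_IPF) & (f["ashcroft_score"] < threshold)
        return list(f.index[m])

    def stratum_of(self, sample: str, threshold: float = SEVERE_ASHCROFT) -> str:
        """True severity stratum: ``severe`` / ``non_severe``.

        Control samples count as non-severe (normal lung); IPF samples are
        stratified by their Ashcroft score.
        """
        if sample not in self.frame.index:
            raise KeyError(f"unknown sample id: {sample}")
        row = self.frame.loc[sample]
        if row["group"] == GROUP_CONTROL:
            return "non_severe"
        return "severe" if row["ashcroft_score"] >= threshold else "non_severe"

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t") -> "SampleSheet":
        df = _read_table(path, sep, "sample sheet")
        df = df.set_index(df.columns[0])
        df.index.name = "sample_id"
        return cls(df)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        out = self.frame.copy()
        out["ashcroft_score"] = out["ashcroft_score"].astype("Int64")
        out.to_csv(path, sep=sep, index_label="sample_id")


@dataclasses.dataclass(frozen=True)
class CountMatrix:
    """Raw integer read counts (genes x samples) with per-sample mapped totals.

    ``mapped_totals`` carries the mapping-wide read total per sample; it is
    never inferred from the panel column sums because a targeted panel
    captures only a subset of the library.
    """

    counts: pd.DataFrame
    mapped_totals: pd.Series

    def __post_init__(self) -> None:
        c = self.counts
        _check_unique(list(c.index), "gene")
        _check_unique(list(c.columns), "sample")
        vals = c.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            g, s = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"missing/non-finite count at ({c.index[g]}, {c.columns[s]})")
        bad = np.argwhere((vals < 0) | (vals != np.floor(vals)))
        if len(bad):
            g, s = bad[0]
            raise ValidationError(
                f"negative or non-integer count {vals[g, s]!r} at "
                f"({c.index[g]}, {c.columns[s]})")
        totals = pd.to_numeric(self.mapped_totals, errors="coerce")
        if list(totals.index) != list(c.columns):
            try:
                totals = totals.loc[c.columns]
            except KeyError as exc:
                raise ValidationError(f"mapped totals missing for sample(s): {exc}")
        if totals.isna().any() or (totals <= 0).any():
            bad_s = list(totals.index[totals.isna() | (totals <= 0)])
            raise ValidationError(f"non-positive mapped total for sample(s): {bad_s}")
        colsum = vals.sum(axis=0)
        over = colsum > totals.to_numpy(dtype=float)
        if over.any():
            raise ValidationError(
                f"panel column sum exceeds mapped total for sample(s): "
                f"{list(c.columns[over])}")
        object.__setattr__(self, "counts", c.astype(np.int64))
        object.__setattr__(self, "mapped_totals", totals.astype(np.int64))

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def _read_table(path: str | Path, sep: str, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    try:
        df = pd.read_csv(path, sep=sep, comment="#", dtype=str,
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"no samples: {what} file {path} is empty")
    if df.shape[0] == 0:
        raise ValidationError(f"no samples: {what} file {path} has no data rows")
    return df.apply(lambda col: col.str.strip() if col.dtype == object else col)


def _header_fields(path: Path, sep: str) -> list[str]:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return line.rstrip("\n").split(sep)
    raise ValidationError(f"file {path} has no header line")


def read_count_matrix(path: str | Path, sep: str = "\t",
                      totals_path: str | Path | None = None) -> CountMatrix:
    """Read a gene x sample count table.

    Mapped totals come from a reserved ``__mapped_totals__`` row inside the
    file or from a two-column sidecar (``sample_id``, ``mapped_total``).
    They are required: silently substituting panel column sums would corrupt
    the per-million denominator of RPKM.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count matrix file not found: {path}")
    header = _header_fields(path, sep)
    _check_unique(header[1:], "sample")
    try:
        df = pd.read_csv(path, sep=sep, comment="#", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"count matrix file {path} is empty")
    totals: pd.Series | None = None
    if TOTALS_ROW in df.index:
        totals = df.loc[TOTALS_ROW]
        df = df.drop(index=TOTALS_ROW)
    elif totals_path is not None:
        tdf = pd.read_csv(totals_path, sep=sep, comment="#", index_col=0)
        totals = tdf.iloc[:, 0]
    if totals is None:
        raise ValidationError(
            "mapped totals missing: provide a __mapped_totals__ row or a "
            "totals sidecar (they are never inferred from column sums)")
    return CountMatrix(df, totals)


def write_count_matrix(cm: CountMatrix, path: str | Path, sep: str = "\t") -> None:
    out = cm.counts.copy()
    out.loc[TOTALS_ROW] = cm.mapped_totals
    out.to_csv(path, sep=sep, index_label="gene_id")


def write_result_table(table: pd.DataFrame, path: str | Path, sep: str = "\t",
                       sort_by: str | Sequence[str] | None = None,
                       ascending: bool = False,
                       float_format: str = "%.6g",
                       header_comment: str | Iterable[str] | None = None,
                       index: bool = True) -> None:
    """Write a result table deterministically.

    Rows are sorted by ``sort_by`` (with the index as a tie-break so the
    order is total), floats are printed with fixed precision, and an
    optional ``#``-prefixed comment block records the generating options.
    """
    if table is None or len(table) == 0:
        raise ValidationError("refusing to write an empty result table")
    out = table
    if sort_by is not None:
        keys = [sort_by] if isinstance(sort_by, str) else list(sort_by)
        out = out.sort_values(keys, ascending=ascending, kind="mergesort")
    with open(path, "w") as fh:
        if header_comment:
            lines = ([header_comment] if isinstance(header_comment, str)
                     else list(header_comment))
            for line in lines:
                fh.write(f"# {line}\n")
        out.to_csv(fh, sep=sep, float_format=float_format, index=index)


def read_result_table(path: str | Path, sep: str = "\t",
                      index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)
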