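"""Core data model and readers/writers shared by every analysis stage.

The in-memory containers are thin, validated wrappers around pandas objects:
an :class:`OmicsMatrix` is a features x samples intensity table tagged with
its modality (metabolite or gene) and scale (raw or log2), :class:`SampleMeta`
annotates each sample column with its batch (senescence inducer), time point,
replicate index and role, and :class:`GeneSetCollection` holds GMT gene sets.
All downstream stages consume these objects only; no stage re-parses files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

Modality = Literal["metabolite", "gene"]
Scale = Literal["raw", "log"]

ROLES = ("baseline", "treated", "qc")


class FormatError(ValueError):
    """Raised when an input file violates the expected text format."""


class ValidationError(ValueError):
    """Raised when matrices and metadata are mutually inconsistent."""


@dataclass
class OmicsMatrix:
    """Features x samples intensity matrix with modality and scale tags.

    ``values`` is a DataFrame indexed by feature id with sample ids as
    columns.  On the raw scale all finite values must be strictly positive
    (mass-spec peak areas); missing intensities are NaN, never zero.
    """

    values: pd.DataFrame
    modality: Modality
    scale: Scale = "raw"

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique())
            raise FormatError(f"duplicate feature ids: {dups}")
        if cols.duplicated().any():
            dups = sorted(cols[cols.duplicated()].unique())
            raise FormatError(f"duplicate sample ids: {dups}")
        if self.modality not in ("metabolite", "gene"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.scale not in ("raw", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "raw":
            vals = self.values.to_numpy(dtype=float)
            finite = np.isfinite(vals)
            if (vals[finite] <= 0).any():
                raise ValueError(
                    "raw-scale matrix contains non-positive values; encode "
                    "missing intensities as NaN"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy_with(self, values: pd.DataFrame, scale: Scale | None = None) -> "OmicsMatrix":
        return OmicsMatrix(values=values, modality=self.modality,
                           scale=self.scale if scale is None else scale)

    def impute_missing(self) -> "OmicsMatrix":
        """Replace NaNs by half the feature's minimum observed positive value.

        Features that are entirely missing stay missing.
        """
        vals = self.values.copy()
        mins = vals.min(axis=1, skipna=True)
        fill = mins / 2.0
        for fid in vals.index[vals.isna().any(axis=1)]:
            if np.isfinite(fill.loc[fid]):
                vals.loc[fid] = vals.loc[fid].fillna(fill.loc[fid])
        return self.copy_with(vals)


@dataclass
class SampleMeta:
    """Per-sample annotations: batch (inducer), time in days, replicate, role."""

    table: pd.DataFrame  # columns: sample_id, batch, timepoint_days, replicate, role

    REQUIRED = ("sample_id", "batch", "timepoint_days", "replicate", "role")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            dups = sorted(self.table.loc[self.table["sample_id"].duplicated(), "sample_id"])
            raise FormatError(f"duplicate sample ids in metadata: {dups}")
        bad_roles = set(self.table["role"]) - set(ROLES)
        if bad_roles:
            raise FormatError(f"unknown roles {sorted(bad_roles)}; expected {ROLES}")
        if (self.table["timepoint_days"].astype(float) < 0).any():
            raise ValueError("timepoint_days must be non-negative")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def batches(self) -> list[str]:
        return sorted(self.table["batch"].unique())

    def for_samples(self, sample_ids: Iterable[str]) -> "SampleMeta":
        ids = list(sample_ids)
        sub = self.table.set_index("sample_id").loc[ids].reset_index()
        return SampleMeta(sub)

    def select(self, batch: str | None = None, role: str | None = None,
               timepoint: float | None = None) -> list[str]:
        t = self.table
        mask = pd.Series(True, index=t.index)
        if batch is not None:
            mask &= t["batch"] == batch
        if role is not None:
            mask &= t["role"] == role
        if timepoint is not None:
            mask &= np.isclose(t["timepoint_days"].astype(float), timepoint)
        return list(t.loc[mask, "sample_id"])

    def timepoints(self, batch: str) -> list[float]:
        t = self.table
        tp = t.loc[(t["batch"] == batch) & (t["role"] != "qc"), "timepoint_days"]
        return sorted(tp.astype(float).unique())

    def identity(self, sample_id: str) -> tuple[float, int, str]:
        """Cross-batch sample identity: (timepoint, replicate, role)."""
        row = self.table.set_index("sample_id").loc[sample_id]
        return (float(row["timepoint_days"]), int(row["replicate"]), str(row["role"]))


@dataclass
class StudyView:
    """A matrix/metadata pair validated and ordered by (batch, time, replicate)."""

    matrix: OmicsMatrix
    meta: SampleMeta

    def batch_matrix(self, batch: str, role: str | None = None) -> OmicsMatrix:
        ids = self.meta.select(batch=batch, role=role)
        return self.matrix.copy_with(self.matrix.values[ids])


def align(matrix: OmicsMatrix, meta: SampleMeta) -> StudyView:
    """Validate coverage and return a view ordered by (batch, time, replicate).

    Every matrix sample must have exactly one metadata row; the ordering is
    deterministic so repeated runs produce identical column orders.
    """
    meta_ids = set(meta.sample_ids)
    orphans = [s for s in matrix.sample_ids if s not in meta_ids]
    if orphans:
        raise ValidationError(f"samples missing from metadata: {orphans}")
    sub = meta.for_samples(matrix.sample_ids)
    order = sub.table.sort_values(
        ["batch", "timepoint_days", "replicate", "role", "sample_id"],
        kind="mergesort",
    )["sample_id"]
    ordered = matrix.copy_with(matrix.values[list(order)])
    return StudyView(matrix=ordered, meta=sub.for_samples(list(order)))


# ---------------------------------------------------------------------------
# file I/O

def read_matrix(path: str | Path, modality: Modality, scale: Scale = "raw") -> OmicsMatrix:
    """Read a TSV intensity matrix (first column feature id, header sample ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.columns.duplicated().any():
        dups = sorted(df.columns[df.columns.duplicated()].unique())
        raise FormatError(f"{path}: duplicate sample column(s) {dups}")
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"{path}: duplicate feature row(s) {dups}")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str),
                       dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col].replace({"": np.nan, "NA": np.nan}),
                                  errors="coerce")
        bad = converted.isna() & df[col].notna() & ~df[col].isin(["", "NA", "nan", "NaN"])
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        out[col] = converted.to_numpy()
    return OmicsMatrix(values=out, modality=modality, scale=scale)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = matrix.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")


def read_meta(path: str | Path) -> SampleMeta:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str, "role": str})
    df["timepoint_days"] = df["timepoint_days"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    return SampleMeta(df)


def write_meta(meta: SampleMeta, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta.table.to_csv(path, sep="\t", index=False)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT); members keep file order, duplicates dropped."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> list[str]:
        return self.sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def ids(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse an MSigDB-dialect GMT file: set id, description, members."""
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            set_id, desc = fields[0], fields[1]
            members: list[str] = []
            seen: set[str] = set()
            had_dup = False
            for m in fields[2:]:
                if not m:
                    continue
                if m in seen:
                    had_dup = True
                    continue
                seen.add(m)
                members.append(m)
            if had_dup:
                warnings.warn(f"{path}:{lineno}: duplicated members in set "
                              f"{set_id!r} were deduplicated")
            if not members:
                raise FormatError(f"{path}:{lineno}: set {set_id!r} has no members")
            coll.sets[set_id] = members
            coll.descriptions[set_id] = desc
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for set_id, members in coll.sets.items():
            desc = coll.descriptions.get(set_id, "")
            fh.write("\t".join([set_id, desc, *members]) + "\n")
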