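"""On-disk formats: count matrix TSV, sample sheet CSV, GMT gene sets, result TSVs.

The pipeline entry point is a transcript x sample matrix of non-negative
integer counts (RSEM-style expected counts rounded upstream) plus a sample
sheet describing the 2-condition x 2-fraction x replicate design.  All
readers validate strictly and all writers use a fixed canonical dialect
(UTF-8, tab/comma separators, "." decimal point, 6 significant digits for
floats, literal "NA" for missing) so that write-then-read round-trips are
exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CONDITIONS = ("exposed", "control")
FRACTIONS = ("input", "rip")

_ID_RE = re.compile(r"^[A-Za-z0-9._-]+$")


class FormatError(ValueError):
    """A file violates the documented dialect or a type invariant."""


@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: one row per library.

    Parameters
    ----------
    frame
        DataFrame with columns ``sample_id`` (unique), ``condition``
        (``exposed``/``control``), ``fraction`` (``input``/``rip``) and
        ``replicate`` (positive int).
    warnings
        Validation warnings carried on the sheet (e.g. a used
        condition/fraction cell with fewer than two biological replicates).
    """

    frame: pd.DataFrame
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "fraction", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        ids = self.frame["sample_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise FormatError(f"duplicate sample_id values: {dups}")
        bad_cond = set(self.frame["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise FormatError(f"unknown condition value(s): {sorted(bad_cond)!r}")
        bad_frac = set(self.frame["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise FormatError(f"unknown fraction value(s): {sorted(bad_frac)!r}")
        reps = self.frame["replicate"]
        if not (reps.astype(int) == reps).all() or (reps < 1).any():
            raise FormatError("replicate must be a positive integer")
        # under-replication is a warning, not an error: flag cells with < 2 reps
        warns = list(self.warnings)
        cell_sizes = self.frame.groupby(["condition", "fraction"], observed=True).size()
        for (cond, frac), n in cell_sizes.items():
            if n < 2:
                msg = f"design cell ({cond}, {frac}) has {n} replicate(s); >= 2 expected"
                if msg not in warns:
                    warns.append(msg)
        object.__setattr__(self, "warnings", tuple(warns))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def select(self, condition: str | None = None, fraction: str | None = None) -> "SampleSheet":
        """Subset the sheet; under-replication warnings are re-derived."""
        mask = pd.Series(True, index=self.frame.index)
        if condition is not None:
            mask &= self.frame["condition"] == condition
        if fraction is not None:
            mask &= self.frame["fraction"] == fraction
        return SampleSheet(self.frame[mask].reset_index(drop=True))


@dataclass(frozen=True)
class CountMatrix:
    """Transcripts x samples non-negative integer counts with sample metadata."""

    counts: pd.DataFrame  # index = transcript ids, columns = sample ids
    samples: SampleSheet

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = sorted(self.counts.index[self.counts.index.duplicated()].unique())
            raise FormatError(f"duplicate transcript id(s): {dups}")
        if list(self.counts.columns) != self.samples.sample_ids:
            extra = set(self.counts.columns) - set(self.samples.sample_ids)
            missing = set(self.samples.sample_ids) - set(self.counts.columns)
            if extra or missing:
                raise FormatError(
                    "count columns and sample sheet disagree; "
                    f"only in counts: {sorted(extra)}, only in sheet: {sorted(missing)}"
                )
            # same set, wrong order -> normalize to sheet order
            object.__setattr__(self, "counts", self.counts[self.samples.sample_ids])
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("counts must be numeric")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at transcript {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        if not np.all(values == np.floor(values)):
            i, j = np.argwhere(values != np.floor(values))[0]
            raise FormatError(
                f"non-integer count {values[i, j]!r} at transcript "
                f"{self.counts.index[i]!r}, sample {self.counts.columns[j]!r}"
            )
        canonical = self.counts.astype(np.int64)
        canonical.index.name = "transcript_id"
        canonical.columns.name = None
        object.__setattr__(self, "counts", canonical)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sheet: SampleSheet) -> "CountMatrix":
        return CountMatrix(self.counts[sheet.sample_ids], sheet)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: set name -> (description, member ids)."""

    sets: Mapping[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet CSV (columns sample_id, condition, fraction, replicate).

    Column names are matched case-insensitively; condition and fraction
    values are folded to lowercase before enum validation.
    """
    frame = pd.read_csv(path, dtype=str)
    frame.columns = [c.strip().lower() for c in frame.columns]
    required = ["sample_id", "condition", "fraction", "replicate"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"sample sheet {path} missing columns: {missing}")
    frame = frame[required].copy()
    frame["condition"] = frame["condition"].str.strip().str.lower()
    frame["fraction"] = frame["fraction"].str.strip().str.lower()
    try:
        frame["replicate"] = frame["replicate"].astype(int)
    except ValueError as exc:
        raise FormatError(f"non-integer replicate in {path}: {exc}") from exc
    return SampleSheet(frame.reset_index(drop=True))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, index=False)


def read_counts(path: str | Path, samples: SampleSheet) -> CountMatrix:
    """Read a counts TSV (first column transcript id, remaining columns samples).

    Headers must equal the sample sheet's sample_ids as a set; column order
    is normalized to sheet order.  Cells must be non-negative integers.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    header = set(frame.columns)
    expected = set(samples.sample_ids)
    if header != expected:
        raise FormatError(
            f"count file {path} header mismatch; only in file: "
            f"{sorted(header - expected)}, only in sheet: {sorted(expected - header)}"
        )
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(frame.columns):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            if coerced.isna().any():
                row = frame.index[coerced.isna()][0]
                raise FormatError(
                    f"non-numeric count at transcript {row!r}, sample {col!r} in {path}"
                )
        frame = frame.apply(pd.to_numeric)
    return CountMatrix(frame, samples)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Write counts in the canonical TSV dialect (round-trip exact)."""
    out = matrix.counts.copy()
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: tab-separated lines of name, description, members...

    Members are deduplicated per set; an empty file yields an empty
    collection.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = parts
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            member_set = frozenset(m for m in members if m)
            if not member_set:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = (desc, member_set)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection:
            desc = collection.description(name)
            members = sorted(collection.members(name))
            fh.write("\t".join([name, desc, *members]) + "\n")


def _render_value(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if np.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV: floats at 6 significant digits, NaN as NA.

    Column order is preserved as given; the caller owns the documented
    ordering for each result type.
    """
    rendered = table.copy()
    for col in rendered.columns:
        if pd.api.types.is_float_dtype(rendered[col]):
            rendered[col] = rendered[col].map(_render_value)
    rendered.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results` ("NA" -> NaN)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def make_sample_sheet(rows: Iterable[tuple[str, str, str, int]]) -> SampleSheet:
    """Build a SampleSheet from (sample_id, condition, fraction, replicate) tuples."""
    frame = pd.DataFrame(rows, columns=["sample_id", "condition", "fraction", "replicate"])
    return SampleSheet(frame)
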