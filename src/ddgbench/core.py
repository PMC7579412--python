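"""Domain types and tabular I/O for mutation, prediction, and benchmark tables.

Mutation tables are ProTherm-style TSV/CSV files, one experimental point
mutation per row.  Column names vary between exports, so reading goes
through a configurable :class:`Dialect` that maps the canonical field names
to the file's columns.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .taxonomy import (
    CANONICAL_AA,
    CategoryLabel,
    LABEL_BY_STRING,
    ValidationError,
    classify_mutation,
)

__all__ = [
    "MutationRecord",
    "PredictionRecord",
    "BenchmarkSet",
    "Dialect",
    "DEFAULT_DIALECT",
    "PROTHERM_DIALECT",
    "ConfigurationError",
    "RowError",
    "read_mutation_table",
    "write_mutation_table",
    "read_benchmark",
    "write_benchmark",
    "read_prediction_table",
    "write_prediction_table",
]


class ConfigurationError(ValueError):
    """A table cannot be read with the given dialect (e.g. missing column)."""


@dataclass(frozen=True)
class MutationRecord:
    """One experimental point mutation with its measured ΔΔG.

    ``ddg_exp`` is in kcal/mol with positive = destabilizing.  ``position``
    is the author residue numbering as a string; an insertion code, if any,
    is kept as an opaque suffix ("100A") and compared string-exactly.
    """

    pdb_id: str
    chain: str
    position: str
    wt_aa: str
    mut_aa: str
    ddg_exp: float
    ph: float | None = None
    source_ref: str | None = None
    record_id: str = ""

    def __post_init__(self):
        wt, mut = self.wt_aa.upper(), self.mut_aa.upper()
        if wt not in CANONICAL_AA:
            raise ValidationError(f"non-canonical wild-type residue {self.wt_aa!r}")
        if mut not in CANONICAL_AA:
            raise ValidationError(f"non-canonical mutant residue {self.mut_aa!r}")
        if wt == mut:
            raise ValidationError(f"wt and mutant residues are identical: {wt}")
        if not math.isfinite(self.ddg_exp):
            raise ValidationError(f"ddg_exp must be finite, got {self.ddg_exp!r}")
        object.__setattr__(self, "wt_aa", wt)
        object.__setattr__(self, "mut_aa", mut)
        object.__setattr__(self, "position", str(self.position).strip())
        if not self.record_id:
            object.__setattr__(self, "record_id", self.default_record_id())

    def default_record_id(self) -> str:
        return f"{self.pdb_id}_{self.chain}_{self.wt_aa}{self.position}{self.mut_aa}"

    @property
    def parent_id(self) -> str:
        """Identifier of the parent backbone (structure chain)."""
        return f"{self.pdb_id}_{self.chain}"


@dataclass(frozen=True)
class PredictionRecord:
    """A predicted ΔΔG for one mutation record, from one replicate run."""

    record_id: str
    ddg_pred: float
    replicate: int = 1

    def __post_init__(self):
        if not math.isfinite(self.ddg_pred):
            raise ValidationError(f"ddg_pred must be finite, got {self.ddg_pred!r}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be ≥ 1, got {self.replicate}")


@dataclass
class BenchmarkSet:
    """An ordered benchmark of mutation records with a category index."""

    records: list[MutationRecord]
    category_index: dict[CategoryLabel, list[str]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record_ids in benchmark: {dupes}")

    @classmethod
    def from_records(
        cls,
        records: Sequence[MutationRecord],
        burial: Mapping[str, CategoryLabel] | None = None,
        provenance: dict | None = None,
    ) -> "BenchmarkSet":
        """Build a set, classifying every record (with burial labels if given)."""
        index: dict[CategoryLabel, list[str]] = {}
        for rec in records:
            b = burial.get(rec.record_id) if burial else None
            for label in classify_mutation(rec.wt_aa, rec.mut_aa, b):
                index.setdefault(label, []).append(rec.record_id)
        return cls(list(records), index, provenance or {})

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labels_of(self, record_id: str) -> frozenset[CategoryLabel]:
        return frozenset(
            label for label, ids in self.category_index.items() if record_id in set(ids)
        )

    def category(self, label: CategoryLabel) -> list[MutationRecord]:
        wanted = set(self.category_index.get(label, ()))
        return [r for r in self.records if r.record_id in wanted]

    def burial_labels(self) -> dict[str, CategoryLabel]:
        out: dict[str, CategoryLabel] = {}
        for label in (CategoryLabel.BURIED, CategoryLabel.SURFACE):
            for rid in self.category_index.get(label, ()):
                out[rid] = label
        return out


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping from canonical field names to file columns."""

    pdb_id: str = "pdb_id"
    chain: str = "chain"
    position: str = "position"
    wt_aa: str = "wt_aa"
    mut_aa: str = "mut_aa"
    ddg_exp: str = "ddg_exp"
    ph: str | None = "ph"
    source_ref: str | None = "source_ref"
    record_id: str | None = "record_id"

    REQUIRED = ("pdb_id", "chain", "position", "wt_aa", "mut_aa", "ddg_exp")


DEFAULT_DIALECT = Dialect()
#: Alias set matching common ProTherm-derived exports.
PROTHERM_DIALECT = Dialect(
    pdb_id="PDB", chain="CHAIN", position="POSITION", wt_aa="WILD_TYPE",
    mut_aa="MUTANT", ddg_exp="DDG", ph="PH", source_ref="REFERENCE",
    record_id=None,
)


@dataclass(frozen=True)
class RowError:
    """A data row that failed field-level validation."""

    row_number: int
    reason: str


def _read_table(path) -> pd.DataFrame:
    text = Path(path).read_text()
    try:
        sep = csv.Sniffer().sniff(text.splitlines()[0], delimiters=",\t").delimiter
    except (csv.Error, IndexError):
        sep = "\t"
    return pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)


def read_mutation_table(
    path,
    dialect: Dialect = DEFAULT_DIALECT,
    on_error: str = "raise",
) -> tuple[list[MutationRecord], list[RowError]]:
    """Read a TSV/CSV mutation table into records, preserving row order.

    Parameters
    ----------
    path
        File with comma- or tab-separated columns (delimiter sniffed).
    dialect
        Mapping of canonical field names to the file's column names.
    on_error
        "raise": any invalid row raises :class:`ValidationError`.
        "collect": invalid rows are returned as :class:`RowError` entries
        alongside the valid records — reported, never silently dropped.
    """
    if on_error not in ("raise", "collect"):
        raise ConfigurationError(f"on_error must be 'raise' or 'collect', got {on_error!r}")
    df = _read_table(path)
    for name in Dialect.REQUIRED:
        col = getattr(dialect, name)
        if col not in df.columns:
            raise ConfigurationError(
                f"required column {col!r} (field {name}) not found in {path}"
            )

    records: list[MutationRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))

        def get(name, default=None):
            col = getattr(dialect, name)
            if col is None or col not in row:
                return default
            val = str(row[col]).strip()
            return val if val else default

        try:
            ph_raw = get("ph")
            records.append(
                MutationRecord(
                    pdb_id=get("pdb_id", ""),
                    chain=get("chain", ""),
                    position=get("position", ""),
                    wt_aa=get("wt_aa", "?") or "?",
                    mut_aa=get("mut_aa", "?") or "?",
                    ddg_exp=float(get("ddg_exp", "nan")),
                    ph=float(ph_raw) if ph_raw is not None else None,
                    source_ref=get("source_ref"),
                    record_id=get("record_id", "") or "",
                )
            )
        except (ValidationError, ValueError) as exc:
            if on_error == "raise":
                raise ValidationError(f"row {i}: {exc}") from exc
            errors.append(RowError(row_number=i, reason=str(exc)))
    return records, errors


_MUTATION_COLUMNS = [
    "record_id", "pdb_id", "chain", "position", "wt_aa", "mut_aa",
    "ddg_exp", "ph", "source_ref",
]


def _records_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "pdb_id": r.pdb_id,
                "chain": r.chain,
                "position": r.position,
                "wt_aa": r.wt_aa,
                "mut_aa": r.mut_aa,
                "ddg_exp": repr(r.ddg_exp),
                "ph": "" if r.ph is None else repr(r.ph),
                "source_ref": r.source_ref or "",
            }
            for r in records
        ],
        columns=_MUTATION_COLUMNS,
    )


def write_mutation_table(records: Sequence[MutationRecord], path) -> None:
    """Write records as TSV in the default dialect, preserving order."""
    _records_frame(records).to_csv(path, sep="\t", index=False)


def write_benchmark(benchmark: BenchmarkSet, path) -> None:
    """Write a benchmark as TSV with a semicolon-joined ``categories`` column."""
    df = _records_frame(benchmark.records)
    df["categories"] = [
        ";".join(sorted(label.value for label in benchmark.labels_of(r.record_id)))
        for r in benchmark.records
    ]
    try:
        df.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise IOError(f"cannot write benchmark to {path}: {exc}") from exc


def read_benchmark(path) -> BenchmarkSet:
    """Read a benchmark TSV written by :func:`write_benchmark`."""
    df = _read_table(path)
    records: list[MutationRecord] = []
    burial: dict[str, CategoryLabel] = {}
    for _, row in df.iterrows():
        rec = MutationRecord(
            pdb_id=row["pdb_id"],
            chain=row["chain"],
            position=row["position"],
            wt_aa=row["wt_aa"],
            mut_aa=row["mut_aa"],
            ddg_exp=float(row["ddg_exp"]),
            ph=float(row["ph"]) if str(row.get("ph", "")).strip() else None,
            source_ref=str(row["source_ref"]) or None if "source_ref" in row else None,
            record_id=row["record_id"],
        )
        records.append(rec)
        for name in str(row.get("categories", "")).split(";"):
            label = LABEL_BY_STRING.get(name)
            if label in (CategoryLabel.BURIED, CategoryLabel.SURFACE):
                burial[rec.record_id] = label
    return BenchmarkSet.from_records(records, burial=burial)


def read_prediction_table(path) -> list[PredictionRecord]:
    """Read a prediction TSV/CSV with columns record_id, ddg_pred[, replicate]."""
    df = _read_table(path)
    for col in ("record_id", "ddg_pred"):
        if col not in df.columns:
            raise ConfigurationError(f"required column {col!r} not found in {path}")
    has_rep = "replicate" in df.columns
    return [
        PredictionRecord(
            record_id=row["record_id"],
            ddg_pred=float(row["ddg_pred"]),
            replicate=int(row["replicate"]) if has_rep and str(row["replicate"]).strip() else 1,
        )
        for _, row in df.iterrows()
    ]


def write_prediction_table(predictions: Sequence[PredictionRecord], path) -> None:
    pd.DataFrame(
        [
            {"record_id": p.record_id, "ddg_pred": repr(p.ddg_pred), "replicate": p.replicate}
            for p in predictions
        ],
        columns=["record_id", "ddg_pred", "replicate"],
    ).to_csv(path, sep="\t", index=False)
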