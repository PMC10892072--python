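"""Core domain types, CSV I/O and hazard/potency label derivation.

A substance is one chemical from a skin-sensitization testing battery:
its SMILES string, human-evidence potency category (1-6), in vitro assay
readouts (DPRA peptide depletion, KeratinoSens EC1.5, h-CLAT, SENS-IS),
and an open-ended set of named physicochemical descriptors.

The 6-level human potency scale collapses to the labels the two-stage
classifier uses: categories 1-2 are strong sensitizers (1A), 3-4 weak
sensitizers (1B), 5-6 non-sensitizers (NC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import SchemaError, ValidationError

SENSIS_LEVELS = ("extreme", "strong", "moderate", "weak", "negative")

#: canonical field -> default CSV column name
DEFAULT_SCHEMA: dict[str, str] = {
    "id": "id",
    "name": "name",
    "smiles": "smiles",
    "potency_category": "potency_category",
    "dpra_c_depletion": "dpra_c_depletion",
    "dpra_k_depletion": "dpra_k_depletion",
    "keratinosens_ec15": "keratinosens_ec15",
    "hclat_positive": "hclat_positive",
    "sensis_class": "sensis_class",
}

_NUMERIC_FIELDS = ("dpra_c_depletion", "dpra_k_depletion", "keratinosens_ec15")


@dataclass(frozen=True)
class StageLabels:
    """Hazard (sensitizer vs non-sensitizer) and potency (1A/1B) labels."""

    hazard: str  # "sensitizer" | "non_sensitizer"
    potency: str  # "1A" | "1B" | "not_applicable"

    def __post_init__(self) -> None:
        if (self.potency == "not_applicable") != (self.hazard == "non_sensitizer"):
            raise ValidationError(
                "potency must be not_applicable exactly for non-sensitizers"
            )


@dataclass
class SubstanceRecord:
    """One chemical with structure, assay readouts and human potency evidence.

    Missing assay values are ``None`` (never 0): incomplete rows must stay
    detectable so they can be removed before model fitting.
    """

    id: str
    smiles: str
    name: str | None = None
    potency_category: int | None = None
    dpra_c_depletion: float | None = None
    dpra_k_depletion: float | None = None
    keratinosens_ec15: float | None = None
    hclat_positive: int | None = None
    sensis_class: str | None = None
    descriptors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.smiles or not str(self.smiles).strip():
            raise ValidationError(f"record {self.id!r}: SMILES must be non-empty")
        if self.potency_category is not None and self.potency_category not in range(1, 7):
            raise ValidationError(
                f"record {self.id!r}: potency_category {self.potency_category} not in 1..6"
            )
        if self.keratinosens_ec15 is not None and not self.keratinosens_ec15 > 0:
            raise ValidationError(
                f"record {self.id!r}: keratinosens_ec15 must be > 0"
            )
        for f in ("dpra_c_depletion", "dpra_k_depletion"):
            v = getattr(self, f)
            if v is not None and not math.isfinite(v):
                raise ValidationError(f"record {self.id!r}: {f} must be finite")
        if self.sensis_class is not None and self.sensis_class not in SENSIS_LEVELS:
            raise ValidationError(
                f"record {self.id!r}: sensis_class {self.sensis_class!r} "
                f"not one of {SENSIS_LEVELS}"
            )

    @property
    def labels(self) -> StageLabels:
        if self.potency_category is None:
            raise ValidationError(f"record {self.id!r} has no potency category")
        return derive_labels(self.potency_category)


@dataclass
class Dataset:
    """An ordered collection of substances with a shared descriptor vocabulary."""

    records: list[SubstanceRecord]
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate substance ids: {dupes}")
        if not self.feature_names and self.records:
            self.feature_names = sorted(
                {k for r in self.records for k in r.descriptors}
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, ids: Sequence[str]) -> "Dataset":
        wanted = set(ids)
        return Dataset(
            [r for r in self.records if r.id in wanted], list(self.feature_names)
        )


def derive_labels(potency_category: int) -> StageLabels:
    """Collapse the 6-level human potency category to stage labels.

    Categories 1-2 -> (sensitizer, 1A); 3-4 -> (sensitizer, 1B);
    5-6 -> (non_sensitizer, not_applicable).
    """
    if potency_category not in (1, 2, 3, 4, 5, 6):
        raise ValidationError(f"potency category {potency_category!r} not in 1..6")
    if potency_category <= 2:
        return StageLabels("sensitizer", "1A")
    if potency_category <= 4:
        return StageLabels("sensitizer", "1B")
    return StageLabels("non_sensitizer", "not_applicable")


def validate_smiles_syntax(smiles: str) -> bool:
    """Cheap syntactic SMILES check: balanced (), [] and paired ring closures.

    This is deliberately not a chemistry parser; configure an optional
    chemistry backend (e.g. rdkit) for real structure validation.
    """
    if not smiles or not smiles.strip():
        return False
    depth_round = depth_square = 0
    ring_open: dict[str, int] = {}
    i, n = 0, len(smiles)
    while i < n:
        c = smiles[i]
        if c == "(":
            depth_round += 1
        elif c == ")":
            depth_round -= 1
            if depth_round < 0:
                return False
        elif c == "[":
            depth_square += 1
        elif c == "]":
            depth_square -= 1
            if depth_square < 0:
                return False
        elif c == "%" and i + 2 < n and smiles[i + 1 : i + 3].isdigit():
            key = smiles[i + 1 : i + 3]
            ring_open[key] = ring_open.get(key, 0) ^ 1
            i += 2
        elif c.isdigit() and depth_square == 0:
            ring_open[c] = ring_open.get(c, 0) ^ 1
        i += 1
    return depth_round == 0 and depth_square == 0 and not any(ring_open.values())


def _parse_float(cell) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    try:
        v = float(cell)
    except (TypeError, ValueError):
        return None
    return v if math.isfinite(v) else None


def _parse_binary(cell) -> int | None:
    v = _parse_float(cell)
    if v is None:
        return None
    return int(v > 0.5)


def read_dataset(path, schema: Mapping[str, str] | None = None) -> Dataset:
    """Read a substance table from CSV.

    ``schema`` maps canonical field names (keys of :data:`DEFAULT_SCHEMA`) to
    the file's column headers; unmapped fields fall back to the defaults.
    Columns not claimed by the schema are treated as named descriptors.
    Unparseable numeric cells become missing values; row count is preserved.
    """
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    for mandatory in ("id", "smiles"):
        if cols[mandatory] not in df.columns:
            raise SchemaError(
                f"mandatory column {cols[mandatory]!r} (field {mandatory!r}) "
                f"missing from {path}"
            )
    claimed = {v for k, v in cols.items() if v in df.columns}
    descriptor_cols = [c for c in df.columns if c not in claimed]

    records = []
    for _, row in df.iterrows():
        cat = _parse_float(row.get(cols["potency_category"]))
        sensis = row.get(cols["sensis_class"]) if cols["sensis_class"] in df.columns else None
        if isinstance(sensis, float) and math.isnan(sensis):
            sensis = None
        name = row.get(cols["name"]) if cols["name"] in df.columns else None
        if isinstance(name, float) and math.isnan(name):
            name = None
        records.append(
            SubstanceRecord(
                id=str(row[cols["id"]]),
                smiles=str(row[cols["smiles"]]),
                name=name,
                potency_category=None if cat is None else int(cat),
                dpra_c_depletion=_parse_float(row.get(cols["dpra_c_depletion"])),
                dpra_k_depletion=_parse_float(row.get(cols["dpra_k_depletion"])),
                keratinosens_ec15=_parse_float(row.get(cols["keratinosens_ec15"])),
                hclat_positive=_parse_binary(row.get(cols["hclat_positive"])),
                sensis_class=sensis,
                descriptors={
                    c: v
                    for c in descriptor_cols
                    if (v := _parse_float(row[c])) is not None
                },
            )
        )
    return Dataset(records, descriptor_cols)


def to_frame(dataset: Dataset) -> pd.DataFrame:
    """Flatten a Dataset to a DataFrame in the canonical CSV column layout."""
    rows = []
    for r in dataset.records:
        row: dict = {
            "id": r.id,
            "name": r.name,
            "smiles": r.smiles,
            "potency_category": r.potency_category,
            "dpra_c_depletion": r.dpra_c_depletion,
            "dpra_k_depletion": r.dpra_k_depletion,
            "keratinosens_ec15": r.keratinosens_ec15,
            "hclat_positive": r.hclat_positive,
            "sensis_class": r.sensis_class,
        }
        for f in dataset.feature_names:
            row[f] = r.descriptors.get(f)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA) + list(dataset.feature_names))


def write_dataset(dataset: Dataset, path) -> None:
    """Write a Dataset back to CSV in the same dialect :func:`read_dataset` reads."""
    to_frame(dataset).to_csv(path, index=False)
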