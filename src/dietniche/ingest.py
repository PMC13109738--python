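"""Data model and tabular I/O for stomach-content datasets.

The canonical on-disk representation is long format: one row per prey item,
with the flushed individual's identifiers and morphometrics repeated on each
of its rows.  A stomach that contained no prey is encoded by a single row
whose prey columns are empty.  Columns are fixed (see :data:`COLUMNS`);
measurements are in mm (masses in g) with decimal points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd


class SchemaError(ValueError):
    """The input table is missing required columns."""


class RowError(ValueError):
    """A data row could not be parsed; carries the 1-based file line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class TaxonRank(str, Enum):
    ORDER = "order"
    CATEGORY = "category"


#: canonical long-format column order
COLUMNS = [
    "sample_id",
    "species",
    "sex",
    "svl_mm",
    "hl_mm",
    "mw_mm",
    "bm_g",
    "microhabitat",
    "prey_order",
    "prey_category",
    "prey_length_mm",
    "prey_width_mm",
]

_MORPHO_COLS = ["svl_mm", "hl_mm", "mw_mm", "bm_g"]


@dataclass(frozen=True)
class PreyTaxon:
    """A prey assignment: insect order (or non-insect group) plus the finest
    identified bin below it (family, larval bin, or residual "Other" bin).

    When a prey item is identified only to order level (e.g. Gastropoda), the
    category label repeats the order label and ``rank`` is ``ORDER``.
    """

    order_label: str
    category_label: str
    rank: TaxonRank = TaxonRank.CATEGORY

    def __post_init__(self):
        if not self.category_label:
            raise ValueError("category_label must be non-empty")
        if not self.order_label:
            raise ValueError("order_label must be non-empty")


@dataclass
class PreyItem:
    """One prey item with measured maximum length and width (mm).

    ``length_mm`` and ``width_mm`` may be None for items recovered too damaged
    to measure; such items count toward abundance and occurrence but carry no
    volume.  Width exceeding length is recorded as measured (validation flags
    it as a warning).
    """

    taxon: PreyTaxon
    length_mm: Optional[float] = None
    width_mm: Optional[float] = None

    @property
    def volume_mm3(self) -> Optional[float]:
        """Prolate-spheroid volume 4pi/3 * (L/2) * (W/2)^2, or None if a
        dimension is missing."""
        if self.length_mm is None or self.width_mm is None:
            return None
        return (4.0 * math.pi / 3.0) * (self.length_mm / 2.0) * (self.width_mm / 2.0) ** 2


@dataclass
class StomachSample:
    """One flushed individual: morphometrics plus its (possibly empty) prey list."""

    sample_id: str
    species: str
    sex: Sex = Sex.UNKNOWN
    svl_mm: Optional[float] = None
    hl_mm: Optional[float] = None
    mw_mm: Optional[float] = None
    bm_g: Optional[float] = None
    microhabitat: Optional[str] = None
    items: list[PreyItem] = field(default_factory=list)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def total_volume_mm3(self) -> float:
        """Summed prolate-spheroid volume of measurable items (mm^3)."""
        return sum(it.volume_mm3 for it in self.items if it.volume_mm3 is not None)


@dataclass
class DietDataset:
    """A collection of stomach samples from one or more predator species."""

    samples: list[StomachSample] = field(default_factory=list)

    @property
    def species_set(self) -> set[str]:
        return {s.species for s in self.samples}

    def species_samples(self, species: str) -> list[StomachSample]:
        out = [s for s in self.samples if s.species == species]
        if not out:
            raise KeyError(f"species {species!r} not in dataset")
        return out

    def n_stomachs(self, species: Optional[str] = None) -> int:
        if species is None:
            return len(self.samples)
        return len(self.species_samples(species))

    def n_items(self, species: Optional[str] = None) -> int:
        samples = self.samples if species is None else self.species_samples(species)
        return sum(s.n_items for s in samples)

    def subset(self, species: Iterable[str]) -> "DietDataset":
        keep = set(species)
        return DietDataset([s for s in self.samples if s.species in keep])

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format DataFrame (one row per item; one empty-prey row per
        empty stomach), columns per :data:`COLUMNS`."""
        rows = []
        for s in self.samples:
            base = {
                "sample_id": s.sample_id,
                "species": s.species,
                "sex": s.sex.value,
                "svl_mm": s.svl_mm,
                "hl_mm": s.hl_mm,
                "mw_mm": s.mw_mm,
                "bm_g": s.bm_g,
                "microhabitat": s.microhabitat,
            }
            if not s.items:
                rows.append({**base, "prey_order": None, "prey_category": None,
                             "prey_length_mm": None, "prey_width_mm": None})
            for it in s.items:
                rows.append({**base,
                             "prey_order": it.taxon.order_label,
                             "prey_category": it.taxon.category_label,
                             "prey_length_mm": it.length_mm,
                             "prey_width_mm": it.width_mm})
        return pd.DataFrame(rows, columns=COLUMNS)


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``level`` is 'error' or 'warning'."""

    level: str
    code: str
    message: str
    sample_id: Optional[str] = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f" [{self.sample_id}]" if self.sample_id else ""
        return f"{self.level.upper()} {self.code}{where}: {self.message}"


def _parse_float(value, column: str, line: int, required: bool = False) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() == "":
        if required:
            raise RowError(f"missing value in column {column!r}", line)
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowError(f"non-numeric value {value!r} in column {column!r}", line) from None


def read_diet_table(path: str | Path, dialect: str = "csv") -> DietDataset:
    """Read a long-format stomach-content table into a :class:`DietDataset`.

    Rows sharing a ``sample_id`` are merged into one stomach; rows with empty
    prey columns become empty-item stomachs.  Lines starting with ``#`` are
    treated as comments (provenance headers).

    Raises :class:`SchemaError` if a required column is missing and
    :class:`RowError` (with the offending line number) for unparseable cells.
    """
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    path = Path(path)
    # count leading comment lines so reported line numbers match the file
    n_comments = 0
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            if raw.startswith("#"):
                n_comments += 1
            else:
                break
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#", skip_blank_lines=True)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return _dataset_from_strings(df, first_data_line=n_comments + 2)


def _dataset_from_strings(df: pd.DataFrame, first_data_line: int = 2) -> DietDataset:
    samples: dict[str, StomachSample] = {}
    for pos, (_, row) in enumerate(df.iterrows()):
        line = first_data_line + pos
        sid = str(row["sample_id"]).strip() if pd.notna(row["sample_id"]) else ""
        if not sid:
            raise RowError("empty sample_id", line)
        species = str(row["species"]).strip() if pd.notna(row["species"]) else ""
        if not species:
            raise RowError("empty species", line)
        sex_raw = str(row["sex"]).strip().lower() if pd.notna(row["sex"]) else "unknown"
        try:
            sex = Sex(sex_raw) if sex_raw else Sex.UNKNOWN
        except ValueError:
            raise RowError(f"unknown sex {sex_raw!r}", line) from None
        morpho = {c: _parse_float(row[c], c, line) for c in _MORPHO_COLS}
        habitat = str(row["microhabitat"]).strip() if pd.notna(row["microhabitat"]) else None
        habitat = habitat or None

        if sid not in samples:
            samples[sid] = StomachSample(sample_id=sid, species=species, sex=sex,
                                         microhabitat=habitat, **morpho)
        sample = samples[sid]
        if sample.species != species:
            raise RowError(f"sample_id {sid!r} appears with conflicting species", line)

        cat = str(row["prey_category"]).strip() if pd.notna(row["prey_category"]) else ""
        order = str(row["prey_order"]).strip() if pd.notna(row["prey_order"]) else ""
        if not cat and not order:
            continue  # empty-stomach row
        if not order:
            raise RowError(f"prey_category {cat!r} without prey_order", line)
        cat = cat or order
        rank = TaxonRank.ORDER if cat == order else TaxonRank.CATEGORY
        length = _parse_float(row["prey_length_mm"], "prey_length_mm", line)
        width = _parse_float(row["prey_width_mm"], "prey_width_mm", line)
        sample.items.append(PreyItem(PreyTaxon(order, cat, rank), length, width))
    return DietDataset(list(samples.values()))


def write_diet_table(dataset: DietDataset, path: str | Path, dialect: str = "csv",
                     header_comments: Optional[list[str]] = None) -> None:
    """Write ``dataset`` in the canonical long format.

    ``header_comments`` lines (without '#') are emitted as '# ...' above the
    header, typically a provenance block.  Floats are written with Python's
    shortest round-trip repr, so read(write(d)) reproduces d exactly.
    """
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    df = dataset.to_dataframe()
    # shortest-repr float formatting: format via object dtype to avoid pandas
    # float padding; None -> empty string
    out = df.astype(object).where(pd.notna(df), "")
    for c in ["svl_mm", "hl_mm", "mw_mm", "bm_g", "prey_length_mm", "prey_width_mm"]:
        out[c] = out[c].map(lambda v: repr(float(v)) if v != "" else "")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep=sep, index=False)


def validate(dataset: DietDataset) -> list[Finding]:
    """Consistency checks; returns findings, never raises or mutates.

    Errors: duplicate sample ids, non-positive morphometrics or prey
    dimensions.  Warnings: empty stomachs, width > length, unknown sex,
    items missing dimensions (excluded from volume sums).
    """
    findings: list[Finding] = []
    seen: set[str] = set()
    for s in dataset.samples:
        if s.sample_id in seen:
            findings.append(Finding("error", "duplicate_id",
                                    f"sample_id {s.sample_id!r} occurs more than once",
                                    s.sample_id))
        seen.add(s.sample_id)
        for name in _MORPHO_COLS:
            v = getattr(s, name)
            if v is not None and v <= 0:
                findings.append(Finding("error", "nonpositive_measurement",
                                        f"{name} = {v} must be > 0", s.sample_id))
        if s.sex is Sex.UNKNOWN:
            findings.append(Finding("warning", "unknown_sex", "sex not recorded", s.sample_id))
        if not s.items:
            findings.append(Finding("warning", "empty_stomach", "no prey items", s.sample_id))
        for it in s.items:
            for name, v in (("prey_length_mm", it.length_mm), ("prey_width_mm", it.width_mm)):
                if v is not None and v <= 0:
                    findings.append(Finding("error", "nonpositive_measurement",
                                            f"{name} = {v} must be > 0", s.sample_id))
            if it.length_mm is None or it.width_mm is None:
                findings.append(Finding("warning", "missing_dimension",
                                        f"item {it.taxon.category_label} lacks a measured "
                                        "dimension; excluded from volume sums", s.sample_id))
            elif it.width_mm > it.length_mm:
                findings.append(Finding("warning", "width_exceeds_length",
                                        f"item {it.taxon.category_label}: W={it.width_mm} > "
                                        f"L={it.length_mm}", s.sample_id))
    return findings
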