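"""Prey volume and per-category dietary composition metrics.

Composition tables report, per prey category i within one predator species:

* ``F_count`` — number of stomachs containing >= 1 item of i;
* ``pct_f``   — i's share of occurrence records, F_count(i) / sum_j F_count(j) * 100
                (normalised so the column sums to 100; the per-stomach
                occurrence fraction F_count / non-empty stomachs is exposed
                separately as ``occ_fraction``);
* ``pct_n``   — i's share of total prey items;
* ``pct_v``   — i's share of total prey volume (prolate-spheroid, per item);
* ``IRI``     — index of relative importance, (pct_f + pct_n + pct_v) / 3.

At order level, counts and volumes aggregate over the order's categories and
F_count is recomputed as the number of stomachs containing the order, while
pct_f keeps the category-level occurrence-record basis (so the order table is
the category table aggregated by order, column-wise additive for pct_f,
pct_n, pct_v and IRI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .ingest import DietDataset, TaxonRank


def prolate_spheroid_volume(length_mm: float, width_mm: float) -> float:
    """Volume (mm^3) of a prolate spheroid with long axis ``length_mm`` and
    equatorial diameter ``width_mm``: V = 4pi/3 * (L/2) * (W/2)^2.

    Strictly increasing in both arguments; equals the sphere volume
    pi d^3 / 6 when L = W = d.
    """
    if not (length_mm > 0 and width_mm > 0):
        raise ValueError(f"dimensions must be positive, got L={length_mm}, W={width_mm}")
    return (4.0 * math.pi / 3.0) * (length_mm / 2.0) * (width_mm / 2.0) ** 2


def iri(pct_f: float, pct_n: float, pct_v: float) -> float:
    """Index of relative importance: arithmetic mean of the three percentage
    components (each on the 0-100 scale)."""
    return (pct_f + pct_n + pct_v) / 3.0


@dataclass(frozen=True)
class CategoryRow:
    label: str
    order_label: str
    f_count: int          # stomachs containing the taxon
    n_count: int          # prey items
    v_sum: float          # summed item volume, mm^3
    pct_f: float          # share of occurrence records (column sums to 100)
    occ_fraction: float   # F_count / non-empty stomachs (conventional %F basis)
    pct_n: float
    pct_v: float
    iri: float


@dataclass
class CategoryTable:
    """Dietary composition of one predator species at one taxonomic level."""

    species: str
    level: TaxonRank
    n_stomachs: int           # all stomachs of the species
    n_nonempty: int           # stomachs with >= 1 item
    n_items: int
    total_volume_mm3: float
    rows: list[CategoryRow]

    def to_dataframe(self, digits: Optional[int] = None) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rows])
        if digits is not None:
            for c in ("v_sum", "pct_f", "occ_fraction", "pct_n", "pct_v", "iri"):
                df[c] = df[c].round(digits)
        return df

    def row(self, label: str) -> CategoryRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(f"taxon {label!r} not in table for {self.species}")


def category_table(dataset: DietDataset, species: str,
                   level: TaxonRank | str = TaxonRank.CATEGORY) -> CategoryTable:
    """Compute the %F/%N/%V/IRI composition table for ``species``.

    Items lacking a measured dimension contribute to N and F but not V.
    Empty stomachs are counted in ``n_stomachs`` but take no part in any
    numerator or denominator.
    """
    level = TaxonRank(level)
    samples = dataset.species_samples(species)
    nonempty = [s for s in samples if s.items]
    n_items = sum(s.n_items for s in samples)
    if n_items == 0:
        raise ValueError(f"no prey items recorded for species {species!r}")

    def item_key(it):
        return it.taxon.category_label

    # per-category tallies (always computed at the finest level first)
    cat_order: dict[str, str] = {}
    n_count: dict[str, int] = {}
    v_sum: dict[str, float] = {}
    cat_occ: dict[str, int] = {}    # stomachs containing the category
    order_occ: dict[str, int] = {}  # stomachs containing the order
    for s in nonempty:
        cats_here, orders_here = set(), set()
        for it in s.items:
            key = item_key(it)
            cat_order[key] = it.taxon.order_label
            n_count[key] = n_count.get(key, 0) + 1
            if it.volume_mm3 is not None:
                v_sum[key] = v_sum.get(key, 0.0) + it.volume_mm3
            cats_here.add(key)
            orders_here.add(it.taxon.order_label)
        for c in cats_here:
            cat_occ[c] = cat_occ.get(c, 0) + 1
        for o in orders_here:
            order_occ[o] = order_occ.get(o, 0) + 1

    total_occ = sum(cat_occ.values())  # occurrence records at category level
    total_v = sum(v_sum.values())

    if level is TaxonRank.CATEGORY:
        labels = sorted(n_count)
        groups = {lab: [lab] for lab in labels}
        f_counts = {lab: cat_occ[lab] for lab in labels}
    else:
        labels = sorted({cat_order[c] for c in n_count})
        groups = {lab: [c for c in n_count if cat_order[c] == lab] for lab in labels}
        f_counts = {lab: order_occ[lab] for lab in labels}

    rows = []
    for lab in labels:
        cats = groups[lab]
        n = sum(n_count[c] for c in cats)
        v = sum(v_sum.get(c, 0.0) for c in cats)
        occ_records = sum(cat_occ[c] for c in cats)
        pct_f = 100.0 * occ_records / total_occ
        pct_n = 100.0 * n / n_items
        pct_v = 100.0 * v / total_v if total_v > 0 else 0.0
        rows.append(CategoryRow(
            label=lab,
            order_label=cat_order[cats[0]] if level is TaxonRank.CATEGORY else lab,
            f_count=f_counts[lab],
            n_count=n,
            v_sum=v,
            pct_f=pct_f,
            occ_fraction=f_counts[lab] / len(nonempty),
            pct_n=pct_n,
            pct_v=pct_v,
            iri=iri(pct_f, pct_n, pct_v),
        ))
    rows.sort(key=lambda r: (-r.iri, r.label))
    return CategoryTable(species=species, level=level, n_stomachs=len(samples),
                         n_nonempty=len(nonempty), n_items=n_items,
                         total_volume_mm3=total_v, rows=rows)


@dataclass
class StomachSummary:
    """Per-species summary of prey counts and sizes.

    Count statistics are over all stomachs (empty stomachs contribute zero
    items to the mean only through ``n_stomachs``; the study's means equal
    total items / stomachs flushed).  Width/length statistics pool individual
    items; volume statistics are over per-stomach total volumes of non-empty
    stomachs, matching how field studies report "stomach contents volume".
    """

    species: str
    n_stomachs: int
    n_nonempty: int
    n_items: int
    count_mean: float
    count_sd: float
    count_min: int
    count_max: int
    width_mean: Optional[float]
    width_sd: Optional[float]
    width_min: Optional[float]
    width_max: Optional[float]
    length_mean: Optional[float]
    length_sd: Optional[float]
    length_min: Optional[float]
    length_max: Optional[float]
    volume_mean: Optional[float]
    volume_sd: Optional[float]
    volume_min: Optional[float]
    volume_max: Optional[float]

    def to_dict(self) -> dict:
        return dict(vars(self))


def _stats(values):
    if not values:
        return (None, None, None, None)
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)) if n > 1 else 0.0
    return (mean, sd, min(values), max(values))


def stomach_summary(dataset: DietDataset, species: str) -> StomachSummary:
    """Mean/SD/min/max of per-stomach item counts, item widths/lengths, and
    per-stomach total volumes for ``species``."""
    samples = dataset.species_samples(species)
    counts = [s.n_items for s in samples]
    widths = [it.width_mm for s in samples for it in s.items if it.width_mm is not None]
    lengths = [it.length_mm for s in samples for it in s.items if it.length_mm is not None]
    volumes = [s.total_volume_mm3 for s in samples if s.items]
    cm, cs, cmin, cmax = _stats(counts)
    wm, ws, wmin, wmax = _stats(widths)
    lm, ls, lmin, lmax = _stats(lengths)
    vm, vs, vmin, vmax = _stats(volumes)
    return StomachSummary(
        species=species, n_stomachs=len(samples),
        n_nonempty=sum(1 for s in samples if s.items),
        n_items=sum(counts),
        count_mean=cm, count_sd=cs, count_min=cmin, count_max=cmax,
        width_mean=wm, width_sd=ws, width_min=wmin, width_max=wmax,
        length_mean=lm, length_sd=ls, length_min=lmin, length_max=lmax,
        volume_mean=vm, volume_sd=vs, volume_min=vmin, volume_max=vmax,
    )
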