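"""Correlation statistics linking predator morphometrics and diet volume.

Two association measures are exposed behind one result type: Pearson's
product-moment r (for the strongly linear allometric trait pairs such as
SVL-BM) and Kendall's tau-b (tie-corrected rank association, used for
SVL versus per-individual stomach-content volume).  The tidy per-individual
table feeding any downstream regression is exported by
:func:`per_individual_table`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import DietDataset


@dataclass(frozen=True)
class CorrelationResult:
    statistic: float
    p: float
    n: int
    method: str  # "pearson" | "kendall_tau_b"

    def to_dict(self) -> dict:
        return dict(vars(self))


def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    return x, y


def pearson(x, y) -> CorrelationResult:
    """Pearson r with two-sided p from the t distribution (n - 2 df)."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), x.size, "pearson")


def kendall_tau_b(x, y) -> CorrelationResult:
    """Kendall tau-b: (C - D) / sqrt((n0 - n1)(n0 - n2)) with tie corrections;
    two-sided p via the normal approximation."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("tau-b undefined when all values of a vector are tied")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return CorrelationResult(float(res.statistic), float(res.pvalue), x.size, "kendall_tau_b")


def per_individual_table(dataset: DietDataset) -> pd.DataFrame:
    """Tidy per-individual table: morphometrics, total prey volume (mm^3),
    and item count — one row per flushed stomach."""
    rows = [{
        "sample_id": s.sample_id,
        "species": s.species,
        "sex": s.sex.value,
        "svl_mm": s.svl_mm,
        "hl_mm": s.hl_mm,
        "mw_mm": s.mw_mm,
        "bm_g": s.bm_g,
        "total_prey_volume_mm3": s.total_volume_mm3,
        "n_items": s.n_items,
    } for s in dataset.samples]
    return pd.DataFrame(rows)


def svl_volume_tests(dataset: DietDataset) -> dict[str, CorrelationResult]:
    """Kendall tau-b of SVL versus per-individual stomach-content volume,
    per species (individuals with missing SVL skipped)."""
    out: dict[str, CorrelationResult] = {}
    df = per_individual_table(dataset)
    for species, sub in df.groupby("species"):
        sub = sub.dropna(subset=["svl_mm"])
        if len(sub) >= 3:
            out[str(species)] = kendall_tau_b(sub["svl_mm"], sub["total_prey_volume_mm3"])
    return out
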