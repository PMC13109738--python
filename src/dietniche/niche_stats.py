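"""Dietary diversity, evenness, trophic niche breadth, and niche overlap.

All indices operate on a species' *niche profile*: the vector of prey-category
counts n_i (or proportions p_i = n_i / N) over the categories registered in
its diet.

* Simpson heterogeneity, finite-sample form:
  D = sum n_i (n_i - 1) / (N (N - 1)); 1 - D is the probability that two
  randomly drawn prey items belong to different categories.
* Shannon diversity H' = -sum p_i ln p_i and evenness J' = H' / ln S.
* Levins niche breadth B = 1 / sum p_i^2, standardised to [0, 1] by
  B_sta = (B - 1) / (n - 1) with n the number of registered categories
  (near 0: specialist; near 1: generalist).
* Pianka pairwise overlap
  O_jk = sum_i P_ij P_ik / sqrt(sum_i P_ij^2 * sum_i P_ik^2),
  the cosine similarity of the two proportion vectors aligned on the union of
  their categories; 0 = disjoint diets, 1 = identical proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ingest import DietDataset, TaxonRank

_PROP_TOL = 1e-9


@dataclass
class NicheProfile:
    """A species' distribution over prey categories at a given level."""

    species: str
    level: TaxonRank
    labels: list[str]
    proportions: np.ndarray
    counts: Optional[np.ndarray] = None  # integer counts when known

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        if len(self.labels) != self.proportions.size:
            raise ValueError("labels and proportions length mismatch")
        if np.any(self.proportions < 0):
            raise ValueError("proportions must be non-negative")
        if abs(self.proportions.sum() - 1.0) > _PROP_TOL:
            raise ValueError(f"proportions must sum to 1 (got {self.proportions.sum()!r})")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.size != self.proportions.size:
                raise ValueError("counts and proportions length mismatch")

    @property
    def n_categories(self) -> int:
        return len(self.labels)

    @classmethod
    def from_counts(cls, species: str, labels: Sequence[str], counts: Sequence[int],
                    level: TaxonRank | str = TaxonRank.CATEGORY) -> "NicheProfile":
        counts = np.asarray(counts, dtype=int)
        if counts.sum() <= 0:
            raise ValueError("counts must sum to a positive total")
        return cls(species, TaxonRank(level), list(labels),
                   counts / counts.sum(), counts)

    @classmethod
    def from_percentages(cls, species: str, labels: Sequence[str], pct: Sequence[float],
                         level: TaxonRank | str = TaxonRank.CATEGORY) -> "NicheProfile":
        """Build from printed percentage columns (e.g. a published %N column);
        renormalises so rounding residue does not violate the sum-to-1 invariant."""
        pct = np.asarray(pct, dtype=float)
        if np.any(pct < 0) or pct.sum() <= 0:
            raise ValueError("percentages must be non-negative with positive sum")
        return cls(species, TaxonRank(level), list(labels), pct / pct.sum())

    @classmethod
    def from_dataset(cls, dataset: DietDataset, species: str,
                     level: TaxonRank | str = TaxonRank.CATEGORY) -> "NicheProfile":
        """Numeric-proportion profile (item counts) of ``species`` in ``dataset``."""
        level = TaxonRank(level)
        tallies: dict[str, int] = {}
        for s in dataset.species_samples(species):
            for it in s.items:
                key = it.taxon.order_label if level is TaxonRank.ORDER else it.taxon.category_label
                tallies[key] = tallies.get(key, 0) + 1
        if not tallies:
            raise ValueError(f"no prey items recorded for species {species!r}")
        labels = sorted(tallies)
        return cls.from_counts(species, labels, [tallies[k] for k in labels], level)


@dataclass(frozen=True)
class DiversityResult:
    species: str
    D: float
    one_minus_D: float
    H: float
    S: int
    H_max: float
    J: Optional[float]  # None when S < 2 (evenness undefined)


@dataclass(frozen=True)
class BreadthResult:
    species: str
    B: float
    n: int
    B_sta: float


@dataclass
class OverlapMatrix:
    species: list[str]
    O: np.ndarray

    def pair(self, a: str, b: str) -> float:
        return float(self.O[self.species.index(a), self.species.index(b)])


def simpson(counts: Sequence[int]) -> tuple[float, float]:
    """Finite-sample Simpson index from integer category counts.

    Returns ``(D, 1 - D)`` with D = sum n_i (n_i - 1) / (N (N - 1)), the
    probability that two items drawn without replacement share a category.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    N = int(counts.sum())
    if N < 2:
        raise ValueError(f"need at least 2 items to compute Simpson's D (got N={N})")
    D = float((counts * (counts - 1)).sum() / (N * (N - 1)))
    return D, 1.0 - D


def shannon(proportions: Sequence[float]) -> float:
    """Shannon diversity H' = -sum p ln p (natural log, zero terms skipped)."""
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("proportions must be non-negative and sum to 1")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def evenness(H: float, S: int) -> float:
    """Shannon evenness J' = H' / ln S; requires S >= 2 categories."""
    if S < 2:
        raise ValueError("evenness requires at least 2 categories")
    return H / math.log(S)


def diversity(profile: NicheProfile) -> DiversityResult:
    """Full diversity summary of a profile (Simpson needs counts)."""
    if profile.counts is None:
        raise ValueError("diversity() needs a count-bearing profile for Simpson's D")
    D, one_minus = simpson(profile.counts)
    H = shannon(profile.proportions)
    S = int(np.count_nonzero(profile.proportions))
    H_max = math.log(S) if S >= 1 else 0.0
    J = evenness(H, S) if S >= 2 else None
    return DiversityResult(profile.species, D, one_minus, H, S, H_max, J)


def levins(profile: NicheProfile | Sequence[float],
           species: str = "") -> BreadthResult:
    """Levins standardised niche breadth B_sta = (B - 1) / (n - 1), B = 1/sum p^2.

    ``n`` is the number of categories registered in the diet (nonzero
    proportion).  Accepts a :class:`NicheProfile` or a bare proportion vector.
    """
    if isinstance(profile, NicheProfile):
        p = profile.proportions
        species = species or profile.species
    else:
        p = np.asarray(profile, dtype=float)
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("proportions must sum to 1")
    p = p[p > 0]
    n = p.size
    if n < 2:
        raise ValueError("niche breadth requires at least 2 registered categories")
    B = 1.0 / float((p ** 2).sum())
    return BreadthResult(species, B, n, (B - 1.0) / (n - 1.0))


def _aligned(profiles: Sequence[NicheProfile]) -> tuple[list[str], np.ndarray]:
    labels = sorted(set().union(*(set(p.labels) for p in profiles)))
    idx = {lab: i for i, lab in enumerate(labels)}
    M = np.zeros((len(profiles), len(labels)))
    for r, prof in enumerate(profiles):
        for lab, v in zip(prof.labels, prof.proportions):
            M[r, idx[lab]] = v
    return labels, M


def pianka(profile_j: NicheProfile, profile_k: NicheProfile) -> float:
    """Pianka pairwise niche overlap, aligned on the union of categories.

    O_jk = sum P_ij P_ik / sqrt(sum P_ij^2 * sum P_ik^2), in [0, 1] by
    Cauchy-Schwarz; 1 iff the proportion vectors are identical, 0 iff the
    diets share no category.
    """
    if profile_j.level is not profile_k.level:
        raise ValueError("profiles must be at the same taxonomic level")
    _, M = _aligned([profile_j, profile_k])
    pj, pk = M[0], M[1]
    denom = math.sqrt(float((pj ** 2).sum()) * float((pk ** 2).sum()))
    if denom == 0:
        raise ValueError("cannot compute overlap with a zero-norm profile")
    return float((pj * pk).sum()) / denom


def overlap_matrix(profiles: Sequence[NicheProfile]) -> OverlapMatrix:
    """Symmetric matrix of pairwise Pianka overlaps (unit diagonal)."""
    if len(profiles) < 1:
        raise ValueError("need at least one profile")
    k = len(profiles)
    O = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            O[i, j] = O[j, i] = pianka(profiles[i], profiles[j])
    return OverlapMatrix([p.species for p in profiles], O)
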