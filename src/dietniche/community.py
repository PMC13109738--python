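"""Per-stomach prey matrices, Bray-Curtis dissimilarity, ANOSIM, and NMDS.

The community-level comparison treats each non-empty stomach as a sample and
each prey taxon (order or finer category) as a variable, with cell values
either item counts ("abundance") or summed prolate-spheroid volumes
("volume").  Species differences are tested with the rank-based ANOSIM
permutation test on the Bray-Curtis dissimilarity matrix and visualised with
non-metric multidimensional scaling (NMDS, Kruskal stress-1); stress below
0.2 is conventionally read as an adequate 2-D representation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

from .ingest import DietDataset, TaxonRank

logger = logging.getLogger(__name__)


@dataclass
class SampleByTaxonMatrix:
    sample_ids: list[str]
    species_labels: list[str]       # group label of each row
    taxa: list[str]
    values: np.ndarray              # (samples x taxa), non-negative
    basis: str                      # "abundance" or "volume"
    level: TaxonRank
    dropped_empty: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.taxa)):
            raise ValueError("matrix shape inconsistent with labels")
        if np.any(self.values < 0):
            raise ValueError("matrix entries must be non-negative")


@dataclass
class DissimilarityMatrix:
    ids: list[str]
    d: np.ndarray  # square symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("dissimilarity matrix must be square")

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p: float
    n_permutations: int
    seed: int
    groups: tuple[str, ...]

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n_permutations": self.n_permutations,
                "seed": self.seed, "groups": list(self.groups)}


@dataclass
class NmdsResult:
    coordinates: np.ndarray
    stress: float
    dims: int
    converged: bool
    seed: int
    n_restarts: int
    n_iter: int
    stress_history: list[float]


def build_matrix(dataset: DietDataset, value: str = "abundance",
                 level: TaxonRank | str = TaxonRank.CATEGORY,
                 species: Optional[Sequence[str]] = None) -> SampleByTaxonMatrix:
    """Assemble the stomach x taxon matrix.

    Stomachs with no prey are dropped (a Bray-Curtis row needs a positive
    sum) and logged; with ``value="volume"`` items lacking dimensions
    contribute zero volume.
    """
    if value not in ("abundance", "volume"):
        raise ValueError(f"value must be 'abundance' or 'volume', got {value!r}")
    level = TaxonRank(level)
    samples = dataset.samples if species is None else [
        s for s in dataset.samples if s.species in set(species)]
    nonempty = [s for s in samples if s.items]
    dropped = [s.sample_id for s in samples if not s.items]
    if dropped:
        logger.warning("dropping %d empty stomach(s): %s", len(dropped), ", ".join(dropped))
    if not nonempty:
        raise ValueError("no non-empty stomachs to build a matrix from")

    def taxon_of(it):
        return it.taxon.order_label if level is TaxonRank.ORDER else it.taxon.category_label

    taxa = sorted({taxon_of(it) for s in nonempty for it in s.items})
    idx = {t: j for j, t in enumerate(taxa)}
    M = np.zeros((len(nonempty), len(taxa)))
    for i, s in enumerate(nonempty):
        for it in s.items:
            j = idx[taxon_of(it)]
            if value == "abundance":
                M[i, j] += 1.0
            elif it.volume_mm3 is not None:
                M[i, j] += it.volume_mm3
    return SampleByTaxonMatrix(
        sample_ids=[s.sample_id for s in nonempty],
        species_labels=[s.species for s in nonempty],
        taxa=taxa, values=M, basis=value, level=level, dropped_empty=dropped)


def bray_curtis(m: SampleByTaxonMatrix) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity d_jk = sum|x_j - x_k| / sum(x_j + x_k)."""
    sums = m.values.sum(axis=1)
    if np.any(sums <= 0):
        bad = [m.sample_ids[i] for i in np.nonzero(sums <= 0)[0]]
        raise ValueError(f"all-zero row(s) for sample(s): {', '.join(bad)}")
    d = squareform(pdist(m.values, metric="braycurtis"))
    return DissimilarityMatrix(list(m.sample_ids), d)


def _anosim_r(rank_matrix: np.ndarray, labels: np.ndarray, iu: tuple) -> float:
    same = labels[:, None] == labels[None, :]
    within = rank_matrix[iu][same[iu]]
    between = rank_matrix[iu][~same[iu]]
    n = labels.size
    denom = n * (n - 1) / 4.0
    return float((between.mean() - within.mean()) / denom)


def anosim(d: DissimilarityMatrix, groups: Sequence[str],
           n_permutations: int = 999, seed: int = 0) -> AnosimResult:
    """Clarke's analysis of similarities on a dissimilarity matrix.

    r = (mean rank of between-group dissimilarities - mean rank of
    within-group ones) / (n(n-1)/4), ranks over all pairs with mid-rank ties;
    r near 1 means groups are more dissimilar to each other than internally.
    The p-value is one-sided by random relabelling with the +1 correction:
    p = (1 + #{permuted r >= observed r}) / (1 + n_permutations).
    """
    labels = np.asarray(list(groups))
    n = labels.size
    if n != len(d.ids):
        raise ValueError("groups length must match the dissimilarity matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2 or np.any(counts < 2):
        raise ValueError("ANOSIM needs >= 2 groups with >= 2 members each")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    ranks = np.zeros_like(d.d)
    iu = np.triu_indices(n, k=1)
    ranks[iu] = rankdata(d.d[iu])
    ranks = ranks + ranks.T
    r_obs = _anosim_r(ranks, labels, iu)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, perm, iu) >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return AnosimResult(r=r_obs, p=p, n_permutations=n_permutations, seed=seed,
                        groups=tuple(sorted(uniq.tolist())))


# ---------------------------------------------------------------------------
# NMDS: SMACOF with isotonic (monotone) regression of configuration
# distances on the input dissimilarities, minimising Kruskal stress-1.
# ---------------------------------------------------------------------------

def _stress1(dhat: np.ndarray, dconf: np.ndarray) -> float:
    denom = float((dconf ** 2).sum())
    if denom == 0:
        return 0.0
    return math.sqrt(float(((dhat - dconf) ** 2).sum()) / denom)


def _pcoa_init(d: np.ndarray, dims: int, rng: np.random.Generator) -> np.ndarray:
    """Classical-scaling (principal-coordinate) start configuration."""
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    X = np.zeros((n, dims))
    for k in range(dims):
        if k < vals.size and vals[k] > 1e-12:
            X[:, k] = vecs[:, k] * math.sqrt(vals[k])
        else:  # degenerate axis: tiny random jitter so SMACOF can move
            X[:, k] = rng.normal(scale=1e-6, size=n)
    return X


def _nmds_single(d: np.ndarray, X: np.ndarray, max_iter: int, tol: float):
    """One SMACOF run; stress-1 is enforced non-increasing (an uphill step
    reverts the update and stops)."""
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    delta = d[iu]
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    history: list[float] = []
    converged = False
    prev_stress = None
    for it in range(max_iter):
        dconf = squareform(pdist(X))
        dc = dconf[iu]
        dhat = iso.fit_transform(delta, dc)
        stress = _stress1(dhat, dc)
        if prev_stress is not None and stress > prev_stress + 1e-12:
            break  # uphill: keep previous configuration
        history.append(stress)
        X_best = X
        if prev_stress is not None and prev_stress - stress < tol:
            converged = True
            break
        prev_stress = stress
        # Guttman transform with disparities dhat
        Dhat = np.zeros_like(dconf)
        Dhat[iu] = dhat
        Dhat = Dhat + Dhat.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dconf > 0, Dhat / np.where(dconf > 0, dconf, 1.0), 0.0)
        B = -ratio
        B[np.diag_indices(n)] = ratio.sum(axis=1)
        X = (B @ X) / n
    return X_best, history[-1], history, converged


def nmds(d: DissimilarityMatrix, dims: int = 2, seed: int = 0,
         n_restarts: int = 4, max_iter: int = 300, tol: float = 1e-7) -> NmdsResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    The first start is the deterministic classical-scaling configuration;
    the remaining ``n_restarts - 1`` starts are seeded random Gaussians.  The
    run with the lowest final Kruskal stress-1 wins.  Non-convergence within
    ``max_iter`` flags the result rather than raising.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    D = np.asarray(d.d, dtype=float)
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        X0 = _pcoa_init(D, dims, rng) if r == 0 else rng.normal(size=(D.shape[0], dims))
        X, stress, history, converged = _nmds_single(D, X0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, history, converged)
    X, stress, history, converged = best
    return NmdsResult(coordinates=X, stress=stress, dims=dims, converged=converged,
                      seed=seed, n_restarts=max(1, n_restarts),
                      n_iter=len(history), stress_history=history)
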