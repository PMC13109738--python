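"""Seeded generator of stomach-content datasets with the study's structure.

Each species is described by a :class:`SpeciesDietSpec`:

* a multinomial over prey categories (defaults: the study's printed numeric
  proportions per species);
* a per-stomach item-count model — negative binomial parameterised by mean
  and SD (the study's count SDs exceed the means, ruling out Poisson),
  truncated by resampling to the printed min-max range;
* prey length/width models — log-normals moment-matched to the printed
  mean/SD and truncated to the printed ranges, with W <= L enforced by
  swapping (sizes are shared across categories, as only pooled size
  statistics are published; ``category_size_overrides`` provides a hook);
* correlated morphometrics (SVL, HL, MW, BM) — a latent Gaussian copula with
  the published pairwise Pearson r targets and truncated-normal marginals
  from the published mean/SD/min/max.

Generation is deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from . import study
from .ingest import DietDataset, PreyItem, PreyTaxon, Sex, StomachSample, TaxonRank

_TRAITS = ("svl_mm", "hl_mm", "mw_mm", "bm_g")
#: latent correlations for head length, unpublished; strong allometric coupling
_HL_DEFAULT_R = {("svl_mm", "hl_mm"): 0.90, ("hl_mm", "mw_mm"): 0.85, ("hl_mm", "bm_g"): 0.85}


@dataclass
class TruncatedDist:
    """Mean/SD moment specification truncated to [lo, hi] by resampling."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self):
        if self.mean <= 0 or self.sd <= 0 or self.lo > self.hi:
            raise ValueError(f"invalid distribution parameters: {self}")


@dataclass
class CountModel(TruncatedDist):
    """Negative-binomial per-stomach item count (k = m^2/(s^2 - m))."""

    def __post_init__(self):
        super().__post_init__()
        if self.sd ** 2 <= self.mean:
            raise ValueError("count model needs over-dispersion (sd^2 > mean)")

    @property
    def k(self) -> float:
        return self.mean ** 2 / (self.sd ** 2 - self.mean)

    @property
    def p(self) -> float:
        return self.k / (self.k + self.mean)

    def truncated_mean(self) -> float:
        """Analytic mean of the range-truncated count distribution."""
        ks = np.arange(int(self.lo), int(self.hi) + 1)
        pmf = stats.nbinom.pmf(ks, self.k, self.p)
        return float((ks * pmf).sum() / pmf.sum())

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        out = np.empty(size, dtype=int)
        filled = 0
        while filled < size:
            draw = rng.negative_binomial(self.k, self.p, size=2 * (size - filled) + 16)
            ok = draw[(draw >= self.lo) & (draw <= self.hi)]
            take = min(ok.size, size - filled)
            out[filled:filled + take] = ok[:take]
            filled += take
        return out


@dataclass
class LogNormalDist(TruncatedDist):
    """Log-normal moment-matched to (mean, sd), truncated to [lo, hi]."""

    @property
    def sigma(self) -> float:
        return math.sqrt(math.log(1.0 + (self.sd / self.mean) ** 2))

    @property
    def mu(self) -> float:
        return math.log(self.mean) - self.sigma ** 2 / 2.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        out = np.empty(size)
        filled = 0
        while filled < size:
            draw = rng.lognormal(self.mu, self.sigma, size=2 * (size - filled) + 16)
            ok = draw[(draw >= self.lo) & (draw <= self.hi)]
            take = min(ok.size, size - filled)
            out[filled:filled + take] = ok[:take]
            filled += take
        return out


@dataclass
class SizeModel:
    """Prey maximum length and width (mm)."""

    length: LogNormalDist
    width: LogNormalDist

    def sample(self, rng: np.random.Generator, size: int) -> tuple[np.ndarray, np.ndarray]:
        L = self.length.sample(rng, size)
        W = self.width.sample(rng, size)
        swap = W > L
        L[swap], W[swap] = W[swap], L[swap].copy()
        return L, W


@dataclass
class MorphoModel:
    """Correlated predator morphometrics via a latent Gaussian copula."""

    marginals: dict[str, TruncatedDist]          # per trait
    correlations: dict[tuple[str, str], float]   # pairwise latent targets

    def correlation_matrix(self) -> np.ndarray:
        R = np.eye(len(_TRAITS))
        for (a, b), r in self.correlations.items():
            i, j = _TRAITS.index(a), _TRAITS.index(b)
            R[i, j] = R[j, i] = r
        # guard against a non-PSD assembled matrix: clip eigenvalues
        vals, vecs = np.linalg.eigh(R)
        if vals.min() < 1e-10:
            vals = np.clip(vals, 1e-10, None)
            R = vecs @ np.diag(vals) @ vecs.T
            dd = np.sqrt(np.diag(R))
            R = R / np.outer(dd, dd)
        return R

    def sample(self, rng: np.random.Generator, size: int) -> dict[str, np.ndarray]:
        R = self.correlation_matrix()
        z = rng.multivariate_normal(np.zeros(len(_TRAITS)), R, size=size,
                                    method="eigh")
        u = stats.norm.cdf(z)
        out = {}
        for j, name in enumerate(_TRAITS):
            m = self.marginals[name]
            a, b = (m.lo - m.mean) / m.sd, (m.hi - m.mean) / m.sd
            out[name] = stats.truncnorm.ppf(u[:, j], a, b, loc=m.mean, scale=m.sd)
        return out


@dataclass
class SpeciesDietSpec:
    species: str
    categories: list[tuple[str, str]]            # (order_label, category_label)
    category_probs: np.ndarray
    count_model: CountModel
    size_model: SizeModel
    morpho_model: MorphoModel
    sex_ratio: float = 0.5                       # male fraction
    category_size_overrides: dict[str, SizeModel] = field(default_factory=dict)

    def __post_init__(self):
        self.category_probs = np.asarray(self.category_probs, dtype=float)
        if self.category_probs.size != len(self.categories):
            raise ValueError("category_probs length must match categories")
        if np.any(self.category_probs < 0) or abs(self.category_probs.sum() - 1.0) > 1e-9:
            raise ValueError("category_probs must be non-negative and sum to 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")

    def analytic_profile(self):
        """The generating proportion vector as a NicheProfile (for comparing
        pipeline estimates against the generator's own parameters)."""
        from .niche_stats import NicheProfile
        return NicheProfile(self.species, TaxonRank.CATEGORY,
                            [c for _, c in self.categories], self.category_probs)


@dataclass
class GeneratorConfig:
    specs: list[SpeciesDietSpec]
    n_stomachs: dict[str, int]
    seed: int

    def __post_init__(self):
        for sp in self.specs:
            n = self.n_stomachs.get(sp.species)
            if n is None or n < 1:
                raise ValueError(f"n_stomachs must be >= 1 for {sp.species!r}")

    def spec_hash(self) -> str:
        """Stable digest of the configuration (for provenance headers)."""
        payload = {
            "seed": self.seed,
            "n_stomachs": self.n_stomachs,
            "specs": [{
                "species": sp.species,
                "categories": sp.categories,
                "probs": [round(float(p), 12) for p in sp.category_probs],
                "count": vars(sp.count_model),
                "length": vars(sp.size_model.length),
                "width": vars(sp.size_model.width),
                "sex_ratio": sp.sex_ratio,
            } for sp in self.specs],
        }
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _species_code(species: str) -> str:
    genus, _, rest = species.partition(" ")
    return (genus[:1] + rest[:3]).upper() or species[:4].upper()


def generate(config: GeneratorConfig) -> DietDataset:
    """Draw a full dataset; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    samples: list[StomachSample] = []
    for sp in config.specs:
        n = config.n_stomachs[sp.species]
        code = _species_code(sp.species)
        counts = sp.count_model.sample(rng, n)
        morpho = sp.morpho_model.sample(rng, n)
        sexes = [Sex.MALE if u < sp.sex_ratio else Sex.FEMALE for u in rng.random(n)]
        for i in range(n):
            items = []
            cat_idx = rng.choice(len(sp.categories), size=counts[i], p=sp.category_probs)
            for order_label, cat_label in (sp.categories[j] for j in cat_idx):
                size_model = sp.category_size_overrides.get(cat_label, sp.size_model)
                L, W = size_model.sample(rng, 1)
                rank = TaxonRank.ORDER if cat_label == order_label else TaxonRank.CATEGORY
                items.append(PreyItem(PreyTaxon(order_label, cat_label, rank),
                                      round(float(L[0]), 1), round(float(W[0]), 1)))
            samples.append(StomachSample(
                sample_id=f"{code}-{i + 1:03d}",
                species=sp.species,
                sex=sexes[i],
                svl_mm=round(float(morpho["svl_mm"][i]), 2),
                hl_mm=round(float(morpho["hl_mm"][i]), 2),
                mw_mm=round(float(morpho["mw_mm"][i]), 2),
                bm_g=round(float(morpho["bm_g"][i]), 2),
                items=items,
            ))
    return DietDataset(samples)


def study_species_spec(species: str) -> SpeciesDietSpec:
    """Spec for one study species with all defaults from the published tables."""
    comp = study.COMPOSITION[species]
    categories = [(order, cat) for order, cat, *_ in comp]
    pct_n = np.array([pn for _, _, _, pn, _, _ in comp])
    males, females = study.SEX_COUNTS[species]
    morph = study.MORPHOMETRICS[species]
    corr = dict(study.MORPHO_CORRELATIONS[species])
    corr.update(_HL_DEFAULT_R)
    return SpeciesDietSpec(
        species=species,
        categories=categories,
        category_probs=pct_n / pct_n.sum(),
        count_model=CountModel(*study.PREY_COUNT[species]),
        size_model=SizeModel(length=LogNormalDist(*study.PREY_LENGTH_MM[species]),
                             width=LogNormalDist(*study.PREY_WIDTH_MM[species])),
        morpho_model=MorphoModel(
            marginals={t: TruncatedDist(*morph[t]) for t in _TRAITS},
            correlations=corr),
        sex_ratio=males / (males + females),
    )


def default_study_config(seed: int) -> GeneratorConfig:
    """Three species specs with the study's stomach counts (26 / 42 / 48)."""
    specs = [study_species_spec(s) for s in study.SPECIES]
    return GeneratorConfig(specs=specs, n_stomachs=dict(study.N_STOMACHS), seed=seed)
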