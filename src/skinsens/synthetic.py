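"""Synthetic Cosmetics-Europe-like substance tables with tunable effect size.

The generator emulates the statistical structure of a human skin-
sensitization battery: a 6-category imbalanced human potency label, assay
readouts monotonically tied to potency, EC1.5 right-censored at 2000,
correlated physicochemical-descriptor blocks, a scalar embedding feature,
and optional sporadic missing assay values.

The generative model is latent-score based. Each substance gets a latent
potency score

    u = (7 - category) / 6 + Normal(0, noise_sd)

(so category 1, the most potent, has the highest u), and every readout is
a monotone, noisy function of ``beta * u`` where ``beta`` is the global
effect-size multiplier:

* EC1.5      = min(2000, exp(8 - 4 beta u + eps))        (lower when potent)
* C/K depletion = 100 logistic(-3 + 6 beta u + eps)      (higher when potent)
* h-CLAT     ~ Bernoulli(logistic(-1 + 3 beta u))
* SENS-IS    = 5-level call from thresholding beta (u - 1/2) + eps
* descriptors: block-correlated Gaussians, first block shifted by beta u
* roberta_embedding_mean = 0.5 beta u + Normal(0, 1)

With beta = 0 every feature is pure noise (the null condition for
calibration checks); the defaults beta = 1, n = 122 mirror the scale of
the real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._smiles_pool import SMILES_POOL
from .data_model import Dataset, SubstanceRecord
from .exceptions import ValidationError
from .preprocess import EC15_CAP

#: default category mix: test-set composition (5 1A / 12 1B / 8 NC of 25)
#: extrapolated to the 6 categories.
DEFAULT_CATEGORY_PROBS = (0.10, 0.10, 0.24, 0.24, 0.16, 0.16)

_SENSIS_CUTS = (-0.35, -0.15, 0.05, 0.25)  # negative | weak | moderate | strong | extreme
_SENSIS_ORDER = ("negative", "weak", "moderate", "strong", "extreme")

ASSAY_FIELDS = (
    "dpra_c_depletion",
    "dpra_k_depletion",
    "keratinosens_ec15",
    "hclat_positive",
    "sensis_class",
)


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the study-scale conditions."""

    n: int = 122
    category_probs: tuple = DEFAULT_CATEGORY_PROBS
    effect: float = 1.0  # global effect-size multiplier (beta)
    noise_sd: float = 0.05  # latent-score noise
    assay_noise_sd: float = 0.5  # readout noise (EC1.5 log scale, depletion logit scale)
    missing_rate: float = 0.0  # per-assay missingness (see inject_missing)
    n_descriptors: int = 30
    n_corr_blocks: int = 4
    block_r: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        probs = np.asarray(self.category_probs, dtype=float)
        if probs.shape != (6,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ValidationError("category_probs must be 6 non-negative values summing to 1")
        if self.effect < 0:
            raise ValidationError("effect must be >= 0")
        if not 0 <= self.missing_rate <= 1:
            raise ValidationError("missing_rate must be in [0, 1]")
        if self.noise_sd < 0 or self.assay_noise_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if not 0 <= self.block_r < 1:
            raise ValidationError("block_r must be in [0, 1)")
        if self.n_descriptors < 1 or self.n_corr_blocks < 1:
            raise ValidationError("need at least one descriptor and one block")
        if self.n_corr_blocks > self.n_descriptors:
            raise ValidationError("more correlation blocks than descriptors")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def descriptor_names(config: SyntheticConfig) -> list[str]:
    return [f"desc_{i:03d}" for i in range(config.n_descriptors)]


def generate(config: SyntheticConfig | None = None, **overrides) -> Dataset:
    """Draw a synthetic substance table under the generative model above."""
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        raise ValidationError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    n, beta = config.n, config.effect

    categories = rng.choice(np.arange(1, 7), size=n, p=np.asarray(config.category_probs))
    u = (7 - categories) / 6 + rng.normal(0, config.noise_sd, n)

    a_sd = config.assay_noise_sd
    ec15 = np.minimum(EC15_CAP, np.exp(8 - 4 * beta * u + rng.normal(0, a_sd, n)))
    c_dep = 100 * _logistic(-3 + 6 * beta * u + rng.normal(0, a_sd, n))
    k_dep = 100 * _logistic(-3.5 + 6 * beta * u + rng.normal(0, a_sd, n))
    hclat = rng.random(n) < _logistic(-1 + 3 * beta * u)
    sensis_score = beta * (u - 0.5) + rng.normal(0, 0.3, n)
    sensis_idx = np.searchsorted(_SENSIS_CUTS, sensis_score)
    sensis = [_SENSIS_ORDER[i] for i in sensis_idx]

    # block-correlated descriptors; the first block carries the signal
    names = descriptor_names(config)
    blocks = np.array_split(np.arange(config.n_descriptors), config.n_corr_blocks)
    desc = np.empty((n, config.n_descriptors))
    r = config.block_r
    for b, cols in enumerate(blocks):
        shared = rng.normal(0, 1, n)
        for j in cols:
            desc[:, j] = np.sqrt(r) * shared + np.sqrt(1 - r) * rng.normal(0, 1, n)
        if b == 0:
            desc[:, cols] += (beta * u)[:, None]

    embedding = 0.5 * beta * u + rng.normal(0, 1, n)
    perm = rng.permutation(len(SMILES_POOL))
    smiles = [SMILES_POOL[perm[i % len(SMILES_POOL)]] for i in range(n)]

    width = max(3, len(str(n)))
    records = []
    for i in range(n):
        descriptors = {names[j]: float(desc[i, j]) for j in range(config.n_descriptors)}
        descriptors["roberta_embedding_mean"] = float(embedding[i])
        records.append(
            SubstanceRecord(
                id=f"S{i + 1:0{width}d}",
                smiles=smiles[i],
                potency_category=int(categories[i]),
                dpra_c_depletion=float(c_dep[i]),
                dpra_k_depletion=float(k_dep[i]),
                keratinosens_ec15=float(ec15[i]),
                hclat_positive=int(hclat[i]),
                sensis_class=sensis[i],
                descriptors=descriptors,
            )
        )
    dataset = Dataset(records, names + ["roberta_embedding_mean"])
    if config.missing_rate > 0:
        dataset = inject_missing(
            dataset,
            {f: config.missing_rate for f in ASSAY_FIELDS},
            seed=int(rng.integers(2**31)),
        )
    return dataset


def inject_missing(dataset: Dataset, rates: dict[str, float], seed: int = 0) -> Dataset:
    """Independently mask assay fields to missing with per-field rates."""
    for f, rate in rates.items():
        if f not in ASSAY_FIELDS:
            raise ValidationError(f"unknown assay field {f!r}")
        if not 0 <= rate <= 1:
            raise ValidationError(f"rate for {f!r} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for r in dataset:
        kw = {
            "id": r.id,
            "smiles": r.smiles,
            "name": r.name,
            "potency_category": r.potency_category,
            "dpra_c_depletion": r.dpra_c_depletion,
            "dpra_k_depletion": r.dpra_k_depletion,
            "keratinosens_ec15": r.keratinosens_ec15,
            "hclat_positive": r.hclat_positive,
            "sensis_class": r.sensis_class,
            "descriptors": dict(r.descriptors),
        }
        for f, rate in rates.items():
            if rng.random() < rate:
                kw[f] = None
        records.append(SubstanceRecord(**kw))
    return Dataset(records, list(dataset.feature_names))
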