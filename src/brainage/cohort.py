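"""Synthetic-cohort generation for end-to-end parameter-recovery testing.

Real brain-age studies are built on access-controlled biobank imaging, so this
module fabricates every input the pipeline consumes, with known ground truth:

* a Voronoi-grown brain parcellation (:func:`generate_atlas`),
* T1-like volumes whose regional mean intensity drifts linearly with each
  subject's "brain age" — chronological age plus an optional planted gap
  ``delta_true`` (:func:`generate_volumes`),
* trait tables whose columns are linked to the standardized planted gap
  through linear / logistic / cumulative-logistic models
  (:func:`generate_traits`),
* two-sample GWAS summary statistics with a planted causal effect and a
  controllable fraction of pleiotropic (invalid) instruments
  (:func:`generate_mr_summary`).

All randomness flows from explicit per-call seeds; there is no global RNG
state, so identical arguments give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Atlas",
    "VolumeSample",
    "CohortTruth",
    "TraitSpec",
    "MRSimConfig",
    "generate_atlas",
    "generate_volumes",
    "generate_traits",
    "generate_mr_summary",
    "stack_volumes",
    "DELTA_SD_DEFAULT",
]

# Spread of the planted brain-age gap, in years.  Chosen to match the
# dispersion typically reported for brain-age deltas in large cohorts
# (standard deviation close to 3.7 years).
DELTA_SD_DEFAULT = 3.72


@dataclass(frozen=True)
class Atlas:
    """Integer-labelled parcellation: 0 = background, 1..R = regions."""

    labels: np.ndarray

    def __post_init__(self):
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def region_mask(self, region_id: int) -> np.ndarray:
        mask = self.labels == region_id
        if not mask.any():
            raise KeyError(f"region {region_id} not present in atlas")
        return mask


@dataclass
class VolumeSample:
    """One subject's voxel grid with identifier and chronological age."""

    subject_id: str
    voxels: np.ndarray
    age: float


@dataclass
class CohortTruth:
    """Ground truth recorded alongside a generated cohort."""

    delta_true: np.ndarray          # per-subject planted gap, years
    signal_regions: tuple[int, ...]  # region ids carrying age signal
    effect_size: float               # intensity change per year in signal regions
    noise_sd: float
    seed: int
    pure_noise: bool = False         # flagged when no signal regions were requested


@dataclass(frozen=True)
class TraitSpec:
    """How one synthetic trait is linked to the standardized brain-age gap.

    ``link_effect`` is the effect per SD of the true gap: a regression beta
    for continuous traits, a log-odds ratio for binary and ordinal traits.
    ``baseline`` is the intercept (continuous), the prevalence (binary) or
    ignored in favour of evenly spaced cutpoints (ordinal).
    """

    name: str
    kind: str                       # "continuous" | "binary" | "ordinal"
    link_effect: float = 0.0
    baseline: float = 0.0
    missing_rate: float = 0.0
    noise_sd: float = 1.0           # residual SD for continuous traits
    n_levels: int = 4               # ordinal only

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "ordinal"):
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.kind == "binary" and not 0.0 < self.baseline < 1.0:
            raise ValueError("binary baseline is a prevalence in (0, 1)")
        if self.kind == "ordinal" and self.n_levels < 2:
            raise ValueError("ordinal traits need at least 2 levels")


@dataclass(frozen=True)
class MRSimConfig:
    """Configuration for a two-sample summary-statistic MR simulation."""

    n_variants: int = 30
    theta: float = 0.06             # true causal effect of exposure on outcome
    pleiotropy_mean: float = 0.0    # mean direct (horizontal) effect of invalid instruments
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    # Instrument (exposure) effects come from large discovery GWAS and must
    # pass genome-wide significance, so they are precisely estimated: with
    # strengths drawn in [0.03, 0.15], se_x = 0.004 keeps every |z| >= 7.5.
    # The outcome scan is typically smaller, hence the larger se_y.
    se_x: float = 0.004
    se_y: float = 0.01
    n_exposure: int = 100_000       # notional discovery sample sizes (reported only)
    n_outcome: int = 100_000
    flip_fraction: float = 0.3      # share of variants emitted in opposite allele orientation
    palindromic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("invalid_fraction must be in [0, 1]")
        if self.se_x < 0 or self.se_y < 0:
            raise ValueError("se_x and se_y must be non-negative")
        if not 0.0 <= self.flip_fraction <= 1.0:
            raise ValueError("flip_fraction must be in [0, 1]")
        if not 0.0 <= self.palindromic_fraction <= 1.0:
            raise ValueError("palindromic_fraction must be in [0, 1]")


def generate_atlas(shape: Sequence[int], n_regions: int, seed: int) -> Atlas:
    """Partition a central ellipsoidal mask into ``n_regions`` contiguous blobs.

    Region seeds are drawn uniformly inside the mask and every foreground
    voxel is assigned to its nearest seed (a Voronoi tessellation), which
    guarantees disjoint, nonempty, roughly compact regions.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 4 for s in shape):
        raise ValueError("shape must be 3D with every dimension >= 4")
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")

    # ellipsoidal foreground mask occupying the central ~90% of each axis
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = sum(((g - (s - 1) / 2.0) / (0.45 * s)) ** 2 for g, s in zip(grids, shape))
    mask = r2 <= 1.0
    coords = np.argwhere(mask)
    if len(coords) < n_regions:
        raise ValueError(
            f"shape {shape} has only {len(coords)} foreground voxels; "
            f"cannot host {n_regions} nonempty regions")

    rng = np.random.default_rng(seed)
    seed_idx = rng.choice(len(coords), size=n_regions, replace=False)
    seeds = coords[seed_idx].astype(float)

    labels = np.zeros(shape, dtype=np.int32)
    # nearest-seed assignment; ties resolve to the lowest seed index (argmin)
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    labels[tuple(coords.T)] = d2.argmin(axis=1) + 1
    return Atlas(labels=labels)


def generate_volumes(
    atlas: Atlas,
    n_subjects: int,
    age_range: tuple[float, float] = (45.0, 80.0),
    signal_regions: Sequence[int] = (),
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    delta_sd: float = DELTA_SD_DEFAULT,
) -> tuple[list[VolumeSample], CohortTruth]:
    """Simulate a cohort of volumes with planted regional age signal.

    Each subject's "brain age" is ``age + delta_true`` where ``delta_true ~
    N(0, delta_sd)``.  Inside every signal region the voxel mean is the
    region's baseline intensity shifted by ``effect_size * (brain_age -
    age-range midpoint)``; all other regions keep an age-independent baseline.
    Independent Gaussian voxel noise of scale ``noise_sd`` is added on top.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    region_ids = set(int(r) for r in atlas.region_ids)
    signal_regions = tuple(int(r) for r in signal_regions)
    if not set(signal_regions) <= region_ids:
        raise ValueError("signal_regions must be a subset of atlas.region_ids")

    rng = np.random.default_rng(seed)
    lo, hi = age_range
    ages = rng.uniform(lo, hi, size=n_subjects)
    delta = (rng.normal(0.0, delta_sd, size=n_subjects) if delta_sd > 0
             else np.zeros(n_subjects))
    midpoint = 0.5 * (lo + hi)

    # fixed per-region baseline intensities, common to all subjects
    all_ids = sorted(region_ids)
    baselines = {rid: b for rid, b in
                 zip(all_ids, rng.uniform(50.0, 150.0, size=len(all_ids)))}

    signal_mask = np.isin(atlas.labels, signal_regions)
    base_vol = np.zeros(atlas.shape, dtype=np.float32)
    for rid in all_ids:
        base_vol[atlas.labels == rid] = baselines[rid]

    samples: list[VolumeSample] = []
    for i in range(n_subjects):
        vox = base_vol.copy()
        if signal_regions:
            brain_age = ages[i] + delta[i]
            vox[signal_mask] += np.float32(effect_size * (brain_age - midpoint))
        if noise_sd > 0:
            vox += rng.normal(0.0, noise_sd, size=atlas.shape).astype(np.float32)
        samples.append(VolumeSample(subject_id=f"sub-{i:05d}", voxels=vox,
                                    age=float(ages[i])))

    truth = CohortTruth(delta_true=delta, signal_regions=signal_regions,
                        effect_size=effect_size, noise_sd=noise_sd, seed=seed,
                        pure_noise=not signal_regions)
    return samples, truth


def stack_volumes(samples: Sequence[VolumeSample]) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Stack a cohort into ``(ids, volumes (N,D,H,W), ages (N,))`` arrays."""
    ids = [s.subject_id for s in samples]
    X = np.stack([s.voxels for s in samples]).astype(np.float32)
    ages = np.array([s.age for s in samples], dtype=np.float64)
    return ids, X, ages


def generate_traits(
    delta_true: np.ndarray,
    trait_specs: Sequence[TraitSpec],
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
    n_centres: int = 3,
) -> pd.DataFrame:
    """Simulate a typed trait table linked to the standardized planted gap.

    Returns a DataFrame with ``subject_id``, covariates (``age``, ``sex``,
    ``centre`` — generated if not supplied) and one column per spec.
    Missingness is applied completely at random at each spec's rate.
    """
    delta_true = np.asarray(delta_true, dtype=float)
    n = len(delta_true)
    rng = np.random.default_rng(seed)
    sd = delta_true.std(ddof=0)
    z = delta_true / sd if sd > 0 else np.zeros(n)

    if covariates is None:
        covariates = pd.DataFrame({
            "subject_id": [f"sub-{i:05d}" for i in range(n)],
            "age": rng.uniform(45.0, 80.0, size=n),
            "sex": rng.integers(0, 2, size=n),
            "centre": rng.integers(0, n_centres, size=n).astype(str),
        })
    else:
        covariates = covariates.copy()
        if len(covariates) != n:
            raise ValueError("covariates must have one row per subject")

    out = covariates.reset_index(drop=True)
    trait_cols: dict[str, pd.Series] = {}
    for spec in trait_specs:
        if spec.kind == "continuous":
            vals = spec.baseline + spec.link_effect * z
            if spec.noise_sd > 0:
                vals = vals + rng.normal(0.0, spec.noise_sd, size=n)
            col = pd.Series(vals, dtype=float)
        elif spec.kind == "binary":
            logit0 = np.log(spec.baseline / (1.0 - spec.baseline))
            p = 1.0 / (1.0 + np.exp(-(logit0 + spec.link_effect * z)))
            draws = (rng.uniform(size=n) < p).astype(float)
            counts = np.bincount(draws.astype(int), minlength=2)
            if counts.min() < 2:
                raise ValueError(
                    f"binary trait {spec.name!r} realized a class with "
                    f"{counts.min()} members; degenerate for an association scan")
            col = pd.Series(draws, dtype=float)
        else:  # ordinal, cumulative-logistic with evenly spaced cutpoints
            k = spec.n_levels
            cuts = np.log(np.arange(1, k) / (k - np.arange(1, k)))  # even quantile cuts
            eta = spec.link_effect * z
            # P(Y <= j) = expit(cut_j - eta); draw by inverse CDF
            cum = 1.0 / (1.0 + np.exp(-(cuts[None, :] - eta[:, None])))
            u = rng.uniform(size=n)
            col = pd.Series((u[:, None] > cum).sum(axis=1).astype(float))
        if spec.missing_rate > 0:
            miss = rng.uniform(size=n) < spec.missing_rate
            col[miss] = np.nan
        trait_cols[spec.name] = col
    if trait_cols:
        out = pd.concat([out, pd.DataFrame(trait_cols)], axis=1)
    return out


_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def generate_mr_summary(cfg: MRSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate harmonisable exposure/outcome GWAS summary-statistic tables.

    Per variant *j* the true instrument strength ``gamma_j`` is drawn
    positive; the exposure effect is ``gamma_j`` plus sampling noise, and the
    outcome effect is ``theta * gamma_j + alpha_j`` plus noise, where
    ``alpha_j`` is zero for valid instruments and drawn from the pleiotropy
    distribution for the invalid fraction.  A configurable subset of variants
    is emitted in the outcome table with flipped allele orientation (and
    negated effect) so that harmonisation is exercised.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_variants

    gamma = rng.uniform(0.03, 0.15, size=m)          # true instrument strengths, > 0
    n_invalid = int(round(cfg.invalid_fraction * m))
    invalid = np.zeros(m, dtype=bool)
    if n_invalid:
        invalid[rng.choice(m, size=n_invalid, replace=False)] = True
    alpha = np.where(invalid,
                     rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=m), 0.0)

    beta_x = gamma + (rng.normal(0.0, cfg.se_x, size=m) if cfg.se_x > 0 else 0.0)
    beta_y = cfg.theta * gamma + alpha + (rng.normal(0.0, cfg.se_y, size=m)
                                          if cfg.se_y > 0 else 0.0)
    se_x = np.full(m, max(cfg.se_x, 1e-12))
    se_y = np.full(m, max(cfg.se_y, 1e-12))
    eaf = rng.uniform(0.1, 0.9, size=m)

    n_pal = int(round(cfg.palindromic_fraction * m))
    pal = np.zeros(m, dtype=bool)
    if n_pal:
        pal[rng.choice(m, size=n_pal, replace=False)] = True
    pairs = []
    for j in range(m):
        pool = _PALINDROMIC if pal[j] else _NONPALINDROMIC
        pairs.append(pool[rng.integers(0, len(pool))])
    ea = np.array([p[0] for p in pairs])
    oa = np.array([p[1] for p in pairs])

    ids = np.array([f"rs{j + 1:06d}" for j in range(m)])

    def pvals(beta, se):
        from scipy.stats import norm
        z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        return 2.0 * norm.sf(np.abs(z))

    exposure = pd.DataFrame({
        "variant_id": ids, "effect_allele": ea, "other_allele": oa,
        "beta": beta_x, "se": se_x, "pval": pvals(beta_x, se_x), "eaf": eaf,
    })

    flip = rng.uniform(size=m) < cfg.flip_fraction
    out_ea = np.where(flip, oa, ea)
    out_oa = np.where(flip, ea, oa)
    out_beta = np.where(flip, -beta_y, beta_y)
    out_eaf = np.where(flip, 1.0 - eaf, eaf)
    outcome = pd.DataFrame({
        "variant_id": ids, "effect_allele": out_ea, "other_allele": out_oa,
        "beta": out_beta, "se": se_y, "pval": pvals(beta_y, se_y), "eaf": out_eaf,
    })

    truth = {
        "theta": cfg.theta, "gamma": gamma, "alpha": alpha,
        "invalid": invalid, "flipped": flip, "palindromic": pal,
        "seed": cfg.seed,
    }
    return exposure, outcome, truth
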