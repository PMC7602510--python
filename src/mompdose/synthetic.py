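"""Seeded generators emulating the statistical structure of each input.

Every generator is a pure function of its configuration (seed
included): protein profiles around the two PDX archetypes, Hill-shaped
viability dose matrices with a controllable Loewe interaction,
ellipsoidal PET phantoms with known uptake, two-class radiomic feature
tables with correlated blocks and conserved shape features, and
exponential caliper growth curves.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .metrics import PETStudy, TumourMeasurement, caliper_volume
from .profiles import CRC0076, CRC0344, PROTEINS, ProteinProfile
from .radiomics import FeatureTable
from .synergy import DoseMatrix, HillCurve

__all__ = [
    "GeneratorConfig", "gen_protein_profiles", "gen_dose_matrix",
    "gen_pet_phantom", "gen_feature_table", "gen_growth_curves",
    "random_profile",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Shared generator configuration.

    ``log_sd`` is the lognormal measurement noise of protein levels (in
    log units, i.e. a geometric sd of exp(log_sd)); archetype medians
    default to the two reference PDX profiles.
    """

    seed: int = 0
    n_samples: int = 20
    log_sd: float = 0.25
    archetypes: tuple = (CRC0076, CRC0344)

    def __post_init__(self):
        if self.log_sd < 0:
            raise ValueError("log_sd must be >= 0")


def gen_protein_profiles(config: GeneratorConfig = GeneratorConfig()
                         ) -> list[ProteinProfile]:
    """Lognormal draws around the two PDX archetypes.

    Samples 0 and 1 are the two anchor profiles verbatim; the remaining
    draws alternate archetypes with multiplicative lognormal noise on
    every protein.
    """
    rng = np.random.default_rng(config.seed)
    a, b = config.archetypes
    out = [a, b]
    for i in range(max(config.n_samples - 2, 0)):
        base = (a, b)[i % 2]
        noise = rng.lognormal(mean=0.0, sigma=config.log_sd,
                              size=len(PROTEINS))
        values = {p: getattr(base, p) * n for p, n in zip(PROTEINS, noise)}
        out.append(ProteinProfile(
            sample_id=f"{base.sample_id}-syn{i:03d}",
            p53_functional=base.p53_functional, **values))
    return out[:config.n_samples] if config.n_samples < 2 else out


def random_profile(rng: np.random.Generator, sample_id: str, *,
                   effector_range=(150.0, 500.0),
                   anti_range=(10.0, 120.0)) -> ProteinProfile:
    """A small random profile (uniform draws) for oracle-scale tests."""
    lo_e, hi_e = effector_range
    lo_a, hi_a = anti_range
    return ProteinProfile(
        sample_id=sample_id,
        bak=float(rng.uniform(lo_e, hi_e)),
        bax=float(rng.uniform(lo_e, hi_e)),
        bcl2=float(rng.uniform(lo_a, hi_a)),
        bclxl=float(rng.uniform(lo_a, hi_a)),
        mcl1=float(rng.uniform(lo_a, hi_a)),
    )


def _loewe_fa(d_chemo: float, d_drug: float, chemo: HillCurve,
              drug: HillCurve, interaction: float) -> float:
    """Fraction affected of a Loewe-consistent combination surface.

    Solves d_c/D_c(fa) + d_d/D_d(fa) = interaction for fa; interaction
    < 1 builds in synergy (the observed doses achieve the fa that
    additivity would need 1/interaction times more drug for).
    """
    if d_chemo == 0 and d_drug == 0:
        return 0.0
    # single-agent margins follow the plain curves: the interaction term
    # describes the combination only
    if d_drug == 0:
        return max(float(chemo.fraction_affected(d_chemo)), 0.0)
    if d_chemo == 0:
        return max(float(drug.fraction_affected(d_drug)), 0.0)
    fa_cap = min(chemo.fa_max, drug.fa_max) - 1e-9

    def excess(fa):
        total = 0.0
        if d_chemo > 0:
            total += d_chemo / chemo.dose_for_fa(fa)
        if d_drug > 0:
            total += d_drug / drug.dose_for_fa(fa)
        return total - interaction

    lo, hi = 1e-9, fa_cap
    if excess(lo) < 0:
        return 0.0
    if excess(hi) > 0:
        # joint solution capped by the weaker agent's plateau; a second
        # agent must never reduce the effect below the stronger margin
        return max(fa_cap,
                   float(chemo.fraction_affected(d_chemo)),
                   float(drug.fraction_affected(d_drug)))
    return float(brentq(excess, lo, hi, xtol=1e-12))


@dataclass(frozen=True)
class DoseMatrixConfig:
    seed: int = 0
    chemo_doses: tuple = (0.0, 0.2, 1.0, 5.0, 25.0, 125.0)   # OX µM
    drug_doses: tuple = (0.0, 0.04, 0.2, 1.0, 5.0, 25.0)     # ABT-199 µM
    chemo_curve: HillCurve = field(
        default_factory=lambda: HillCurve(100.0, 5.0, 2.0, 1.2))
    drug_curve: HillCurve = field(
        default_factory=lambda: HillCurve(100.0, 8.0, 0.8, 1.0))
    interaction: float = 1.0        # Loewe CI of the surface; <1 = synergy
    noise_sd: float = 0.0           # viability % Gaussian noise


def gen_dose_matrix(config: DoseMatrixConfig = DoseMatrixConfig()
                    ) -> DoseMatrix:
    """6x6 viability surface consistent with a target Loewe index."""
    rng = np.random.default_rng(config.seed)
    nc, nd = len(config.chemo_doses), len(config.drug_doses)
    viability = np.empty((nc, nd))
    for i, dc in enumerate(config.chemo_doses):
        for j, dd in enumerate(config.drug_doses):
            fa = _loewe_fa(dc, dd, config.chemo_curve, config.drug_curve,
                           config.interaction)
            viability[i, j] = config.chemo_curve.e0 * (1.0 - fa)
    if config.noise_sd > 0:
        viability = viability + rng.normal(0.0, config.noise_sd,
                                           viability.shape)
    viability = np.clip(viability, 0.0, 120.0)
    return DoseMatrix(config.chemo_doses, config.drug_doses, viability,
                      control_viability=float(config.chemo_curve.e0))


@dataclass(frozen=True)
class PhantomConfig:
    seed: int = 0
    shape: tuple = (24, 24, 24)
    semi_axes: tuple = (6.0, 5.0, 4.0)        # voxels
    tumour_suv: float = 2.5
    background_suv: float = 0.4
    injected_dose_MBq: float = 8.9            # typical mouse FDG dose
    body_weight_g: float = 22.0
    uptake_min: float = 60.0
    noise_sd: float = 0.0                     # SUV-scale Gaussian noise
    n_hot_voxels: int = 0
    hot_suv: float = 0.0


def gen_pet_phantom(config: PhantomConfig = PhantomConfig()) -> PETStudy:
    """Ellipsoidal tumour phantom with known SUV.

    Voxel activities are constructed so that after decay correction to
    injection time and SUV normalisation the tumour reads exactly
    ``tumour_suv``; optional seeded hot voxels inside the tumour allow
    the top-voxel SUVmax rule to be verified against ground truth.
    """
    rng = np.random.default_rng(config.seed)
    grid = np.indices(config.shape, dtype=float)
    centre = [(s - 1) / 2.0 for s in config.shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a
             in zip(grid, centre, config.semi_axes))
    mask = r2 <= 1.0
    suv = np.full(config.shape, config.background_suv)
    suv[mask] = config.tumour_suv
    if config.n_hot_voxels > 0:
        inside = np.flatnonzero(mask)
        hot = rng.choice(inside, size=config.n_hot_voxels, replace=False)
        suv.ravel()[hot] = config.hot_suv
    if config.noise_sd > 0:
        suv = suv + rng.normal(0.0, config.noise_sd, config.shape)
        suv = np.clip(suv, 0.0, None)
    dose_kBq = config.injected_dose_MBq * 1000.0
    # activity at scan start: undo the decay correction the analysis applies
    activity = suv * (dose_kBq / config.body_weight_g) \
        * 2.0 ** (-config.uptake_min / 109.77)
    return PETStudy(activity, mask, config.injected_dose_MBq,
                    config.body_weight_g, config.uptake_min)


@dataclass(frozen=True)
class FeatureTableConfig:
    """Two-class radiomic table generator.

    Defaults mirror the pre-treatment study design: 45 samples from two
    PDX classes, 833 features with a small informative subset shifted
    by ``shift`` class-separation units (in feature sd), latent-factor
    correlated blocks, and near-constant shape features.
    """

    seed: int = 0
    n_samples: int = 45
    n_features: int = 833
    n_informative: int = 7
    shift: float = 2.0
    n_shape: int = 14
    n_blocks: int = 12
    block_size: int = 8
    block_loading: float = 0.97     # within-block latent-factor loading
    include_post: bool = False
    post_drift: float = 0.0         # global pre->post mean drift (sd units)
    classes: tuple = ("CRC0076", "CRC0344")


def _feature_names(config: FeatureTableConfig):
    names, families = [], {}
    kinds = ["firstorder", "texture", "wavelet", "other"]
    for i in range(config.n_shape):
        name = f"shape_feat{i:03d}"
        names.append(name)
        families[name] = "shape"
    i = 0
    while len(names) < config.n_features:
        kind = kinds[i % len(kinds)]
        name = f"{kind}_feat{i:03d}"
        names.append(name)
        families[name] = kind
        i += 1
    return names, families


def gen_feature_table(config: FeatureTableConfig = FeatureTableConfig()
                      ) -> FeatureTable:
    """Seeded two-class feature table with known informative features.

    The informative features are the first ``n_informative`` non-shape,
    non-block features (names containing ``_inf``); correlated blocks
    share a latent factor so within-block |Spearman rho| exceeds the
    0.85 filter cutoff by construction; shape features are near-constant.
    """
    rng = np.random.default_rng(config.seed)
    names, families = _feature_names(config)
    non_shape = [n for n in names if families[n] != "shape"]

    n_block_feats = config.n_blocks * config.block_size
    if config.n_informative + n_block_feats > len(non_shape):
        raise ValueError("not enough non-shape features for the requested "
                         "informative + block layout")
    informative = non_shape[:config.n_informative]
    block_feats = non_shape[config.n_informative:
                            config.n_informative + n_block_feats]
    # rename informative features so ground truth is recoverable
    renamed = {}
    for f in informative:
        new = f.replace("_feat", "_inf")
        renamed[f] = new
        families[new] = families.pop(f)
    names = [renamed.get(n, n) for n in names]
    informative = [renamed[f] for f in renamed]

    n = config.n_samples
    labels = np.array([config.classes[i % 2] for i in range(n)])
    X = pd.DataFrame(index=[f"S{i:03d}" for i in range(n)], columns=names,
                     dtype=float)
    X.loc[:, :] = rng.normal(0.0, 1.0, (n, len(names)))

    sign = np.where(labels == config.classes[0], 0.5, -0.5)
    for f in informative:
        X[f] = rng.normal(0.0, 1.0, n) + sign * config.shift

    loading = config.block_loading
    resid = math.sqrt(max(1.0 - loading ** 2, 1e-12))
    for b in range(config.n_blocks):
        factor = rng.normal(0.0, 1.0, n)
        for k in range(config.block_size):
            f = block_feats[b * config.block_size + k]
            X[f] = loading * factor + resid * rng.normal(0.0, 1.0, n)

    for f in names:
        if families[f] == "shape":
            X[f] = 1.0 + 1e-6 * rng.normal(0.0, 1.0, n)  # conserved shape

    index = pd.Index(X.index, name="sample_id")
    tables = [FeatureTable(X.set_axis(index),
                           pd.Series(labels, index=index, name="label"),
                           pd.Series("pre", index=index, name="timepoint"),
                           families)]
    if config.include_post:
        Xp = X + config.post_drift \
            + rng.normal(0.0, 0.3, X.shape)
        post_index = pd.Index([f"{i}-post" for i in X.index],
                              name="sample_id")
        tables.append(FeatureTable(
            Xp.set_axis(post_index),
            pd.Series(labels, index=post_index, name="label"),
            pd.Series("post", index=post_index, name="timepoint"),
            families))
        data = pd.concat([t.data for t in tables])
        return FeatureTable(
            data,
            pd.concat([t.labels for t in tables]),
            pd.concat([t.timepoint for t in tables]),
            families)
    return tables[0]


@dataclass(frozen=True)
class GrowthConfig:
    seed: int = 0
    n_per_group: int = 6
    groups: tuple = ("vehicle", "abt199", "folfox", "combination")
    growth_rates: tuple = (0.08, 0.06, 0.03, 0.01)   # per day
    start_volume_mm3: float = 360.0
    days: tuple = (0, 2, 4, 7, 9, 11, 14, 16, 18, 21, 23, 25, 28)
    noise_sd: float = 0.0            # lognormal volume noise (log units)
    aspect_ratio: float = 0.75       # d / D of the generated ellipsoid


def gen_growth_curves(config: GrowthConfig = GrowthConfig()) -> pd.DataFrame:
    """Exponential per-animal growth converted to caliper (d, D) pairs.

    The generated axes satisfy the caliper volume formula exactly, so
    recomputing the volume from (d, D) recovers the intended volume.
    """
    rng = np.random.default_rng(config.seed)
    a = config.aspect_ratio
    rows = []
    for g, rate in zip(config.groups, config.growth_rates):
        for i in range(config.n_per_group):
            animal = f"{g}-{i:02d}"
            start = config.start_volume_mm3
            for day in config.days:
                v = start * math.exp(rate * day)
                if config.noise_sd > 0:
                    v *= rng.lognormal(0.0, config.noise_sd)
                # V = pi/6 d^2 D with d = a D  ->  D = (6V / (pi a^2))^(1/3)
                D = (6.0 * v / (math.pi * a ** 2)) ** (1.0 / 3.0)
                d = a * D
                rows.append({"animal_id": animal, "day": day,
                             "d_mm": d, "D_mm": D, "group": g})
    df = pd.DataFrame(rows)
    df["volume_mm3"] = [
        caliper_volume(TumourMeasurement(r.d_mm, r.D_mm, int(r.day)))
        for r in df.itertuples()]
    return df
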