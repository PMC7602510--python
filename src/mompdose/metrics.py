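"""Preclinical quantification formulas and statistics.

Caliper tumour volume, decay-corrected PET standardized uptake values
over a volume of interest, Allred and Ki-67 histology scores, paired
pre/post response tests and Holm multiple-testing adjustment.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import ValidationError

#: Physical half-life of F-18 in minutes.
F18_HALF_LIFE_MIN = 109.77


@dataclass(frozen=True)
class TumourMeasurement:
    """One caliper reading: minor axis d and major axis D (mm)."""

    d: float
    D: float
    day: int = 0

    def __post_init__(self):
        if not (0 <= self.d <= self.D):
            raise ValidationError(
                f"require 0 <= d <= D, got d={self.d!r}, D={self.D!r}")


def caliper_volume(m: TumourMeasurement) -> float:
    """Ellipsoid caliper volume, mm^3: 4/3 pi (d/2)^2 (D/2)."""
    return (4.0 / 3.0) * math.pi * (m.d / 2.0) ** 2 * (m.D / 2.0)


def decay_correct(activity, elapsed_min: float,
                  half_life_min: float = F18_HALF_LIFE_MIN):
    """Correct a measured activity back to injection time.

    ``corrected = activity * 2**(elapsed/half_life)`` — the activity
    that was present when the tracer was injected.
    """
    if not half_life_min > 0:
        raise ValidationError(f"half_life_min must be > 0, got {half_life_min!r}")
    if elapsed_min < 0:
        raise ValidationError(f"elapsed_min must be >= 0, got {elapsed_min!r}")
    return np.asarray(activity, dtype=float) * 2.0 ** (elapsed_min / half_life_min)


@dataclass(frozen=True)
class PETStudy:
    """A PET acquisition with its tumour VOI mask.

    ``voxel_values`` are activity concentrations (kBq/mL) at scan start;
    ``injected_dose_MBq`` and ``body_weight_g`` normalise them to SUV
    (1 g/mL tissue density convention, so SUV is dimensionless);
    ``uptake_min`` is the injection-to-scan interval used for decay
    correction of the injected dose reference frame.
    """

    voxel_values: np.ndarray
    voi_mask: np.ndarray
    injected_dose_MBq: float
    body_weight_g: float
    uptake_min: float = 0.0
    voxel_volume_mL: float = 1e-3

    def __post_init__(self):
        v = np.asarray(self.voxel_values, dtype=float)
        m = np.asarray(self.voi_mask, dtype=bool)
        if v.shape != m.shape:
            raise ValidationError(
                f"mask shape {m.shape} does not match image shape {v.shape}")
        if not self.injected_dose_MBq > 0:
            raise ValidationError("injected_dose_MBq must be > 0")
        if not self.body_weight_g > 0:
            raise ValidationError("body_weight_g must be > 0")
        if self.uptake_min < 0:
            raise ValidationError("uptake_min must be >= 0")
        object.__setattr__(self, "voxel_values", v)
        object.__setattr__(self, "voi_mask", m)

    @classmethod
    def from_nifti(cls, image_path, mask_path, sidecar_path):
        """Load an image/mask NIfTI pair plus a JSON sidecar holding
        ``injected_dose_MBq``, ``body_weight_g`` and ``uptake_min``."""
        import nibabel as nib
        img = nib.load(str(image_path))
        msk = nib.load(str(mask_path))
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        zooms = img.header.get_zooms()[:3]
        voxel_volume_mL = float(np.prod(zooms)) / 1000.0  # mm^3 -> mL
        return cls(
            voxel_values=np.asarray(img.dataobj, dtype=float),
            voi_mask=np.asarray(msk.dataobj) > 0.5,
            injected_dose_MBq=float(meta["injected_dose_MBq"]),
            body_weight_g=float(meta["body_weight_g"]),
            uptake_min=float(meta.get("uptake_min", 0.0)),
            voxel_volume_mL=voxel_volume_mL)


def suv_statistics(p: PETStudy, *,
                   half_life_min: float = F18_HALF_LIFE_MIN,
                   n_max_voxels: int = 4) -> dict:
    """SUVmean over the VOI and SUVmax as the mean of the most intense
    voxels (four by convention).

    Voxel activities are decay-corrected to injection time before
    normalisation by injected dose per body weight (dose in kBq, weight
    in g, activity in kBq/mL, tissue density 1 g/mL).  The top-voxel
    selection is deterministic: ties are broken by linear voxel index.
    """
    n_voi = int(p.voi_mask.sum())
    if n_voi == 0:
        raise ValidationError("VOI mask is empty")
    if n_voi < n_max_voxels:
        raise ValidationError(
            f"VOI contains {n_voi} voxels; need >= {n_max_voxels}")
    corrected = decay_correct(p.voxel_values, p.uptake_min, half_life_min)
    dose_kBq = p.injected_dose_MBq * 1000.0
    suv = corrected / (dose_kBq / p.body_weight_g)
    voi = suv[p.voi_mask]
    # stable sort on (-value, linear index): deterministic under ties
    order = np.lexsort((np.arange(voi.size), -voi))
    top = voi[order[:n_max_voxels]]
    return {"suv_mean": float(voi.mean()), "suv_max": float(top.mean()),
            "n_voxels": n_voi}


def relative_change(pre_value: float, post_value: float) -> float:
    """Post/pre ratio (e.g. SUVmean at week 2 normalised to baseline)."""
    if not pre_value > 0:
        raise ZeroDivisionError(f"pre_value must be > 0, got {pre_value!r}")
    return post_value / pre_value


@dataclass(frozen=True)
class AllredInput:
    """One observer's scores for one section: proportion 0-5, intensity 0-3."""

    proportion_score: int
    intensity_score: int
    observer_id: str = ""
    section_id: str = ""

    def __post_init__(self):
        if self.proportion_score not in range(6):
            raise ValidationError(
                f"proportion_score must be an integer in 0..5, "
                f"got {self.proportion_score!r}")
        if self.intensity_score not in range(4):
            raise ValidationError(
                f"intensity_score must be an integer in 0..3, "
                f"got {self.intensity_score!r}")


def allred_total(inputs) -> float:
    """Per-input sum (0-8) of proportion and intensity, averaged over inputs."""
    inputs = list(inputs)
    if not inputs:
        raise ValidationError("need at least one Allred input")
    return float(np.mean([i.proportion_score + i.intensity_score
                          for i in inputs]))


def ki67_index(stained_count: int, total_count: int) -> float:
    """Ki-67 proliferation index: stained cells as % of total cells."""
    if total_count <= 0:
        raise ValidationError(f"total_count must be > 0, got {total_count!r}")
    if not 0 <= stained_count <= total_count:
        raise ValidationError(
            f"need 0 <= stained <= total, got {stained_count}/{total_count}")
    return 100.0 * stained_count / total_count


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    p_value: float
    n: int
    mean_difference: float
    degenerate: bool = False
    note: str = ""


def paired_response_test(pre, post) -> PairedTestResult:
    """Two-sided paired t-test of post vs pre values (paired by animal).

    Zero-variance differences are reported explicitly: identical
    vectors give t = 0, p = 1; a constant non-zero shift has no valid t
    statistic and is flagged ``degenerate`` with p = NaN.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size < 2:
        raise ValidationError("pre and post must be equal-length vectors, n >= 2")
    diff = post - pre
    n = diff.size
    sd = diff.std(ddof=1)
    mean = float(diff.mean())
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(0.0, 1.0, n, 0.0)
        return PairedTestResult(
            math.inf if mean > 0 else -math.inf, math.nan, n, mean,
            degenerate=True,
            note="differences have zero variance with non-zero mean; "
                 "t statistic undefined")
    t, p = stats.ttest_rel(post, pre)
    return PairedTestResult(float(t), float(p), n, mean)


def holm_adjust(p_values):
    """Step-down Holm adjustment, returned in input order.

    Sort ascending, multiply the i-th smallest (1-based) by (m - i + 1),
    enforce monotone non-decreasing, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-D sequence")
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def pre_post_suv_analysis(pre_values, post_values, groups) -> pd.DataFrame:
    """Per-group paired tests of post vs pre PET values with Holm
    adjustment across groups.

    ``groups`` labels each animal; returns one row per group with the
    raw and adjusted p-values and the mean post/pre ratio.
    """
    df = pd.DataFrame({"pre": np.asarray(pre_values, dtype=float),
                       "post": np.asarray(post_values, dtype=float),
                       "group": list(groups)})
    rows = []
    for g, sub in df.groupby("group", sort=True):
        res = paired_response_test(sub["pre"].to_numpy(),
                                   sub["post"].to_numpy())
        ratio = float(np.mean([relative_change(a, b) for a, b
                               in zip(sub["pre"], sub["post"])]))
        rows.append({"group": g, "n": res.n, "t_statistic": res.t_statistic,
                     "p_value": res.p_value, "mean_post_pre_ratio": ratio,
                     "degenerate": res.degenerate})
    out = pd.DataFrame(rows)
    valid = out["p_value"].notna()
    adjusted = np.full(len(out), np.nan)
    if valid.any():
        adjusted[valid.to_numpy()] = holm_adjust(out.loc[valid, "p_value"])
    out["p_holm"] = adjusted
    return out


def read_caliper_csv(path) -> pd.DataFrame:
    """Caliper CSV ``animal_id,day,d_mm,D_mm,group`` with a computed
    ``volume_mm3`` column appended."""
    df = pd.read_csv(path)
    need = {"animal_id", "day", "d_mm", "D_mm", "group"}
    if not need <= set(df.columns):
        raise ValidationError(f"caliper CSV needs columns {sorted(need)}")
    df["volume_mm3"] = [
        caliper_volume(TumourMeasurement(r.d_mm, r.D_mm, int(r.day)))
        for r in df.itertuples()]
    return df
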