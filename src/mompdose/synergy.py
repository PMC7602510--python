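"""Drug-combination analysis of chemo x BH3-mimetic viability matrices.

A 6x6 dose-matrix assay measures viability under increasing chemotherapy
(oxaliplatin, with 5-FU co-dosed at a fixed 5:1 ratio) crossed with
increasing ABT-199.  The analysis converts viability to fraction
affected, fits four-parameter logistic (Hill) curves to the single-agent
margins, and scores each combination point by the Loewe combination
index

    CI = d_chemo / D_chemo(fa) + d_drug / D_drug(fa)

where D_x(fa) is the single-agent dose producing the observed fraction
affected by inversion of the fitted Hill curve.  CI < 1 indicates
synergy, CI = 1 additivity (a drug combined with itself scores exactly
1), CI > 1 antagonism.  Isobologram points are the single-agent
intercepts at a fixed fa plus the combination point.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .profiles import ValidationError

#: Fixed 5-FU : OX concentration ratio of the chemotherapy arm.
FU_OX_RATIO = 5.0

#: Default fraction-affected levels at which CI is reported.
DEFAULT_FA_LEVELS = (0.25, 0.5, 0.75)


class FitDegenerateError(RuntimeError):
    """Response too flat (or inverted) to support a Hill fit."""


class UndefinedCIError(RuntimeError):
    """The observed fa is unreachable by a single agent's fitted curve."""


@dataclass(frozen=True)
class DoseMatrix:
    """Viability (%) over a chemo x drug dose grid (doses in µM).

    ``chemo_doses`` are OX concentrations; 5-FU is co-dosed at
    ``FU_OX_RATIO`` times the OX concentration.
    """

    chemo_doses: tuple
    drug_doses: tuple
    viability: np.ndarray          # (n_chemo, n_drug), percent
    control_viability: float = 100.0

    def __post_init__(self):
        c = tuple(float(x) for x in self.chemo_doses)
        d = tuple(float(x) for x in self.drug_doses)
        for name, doses in (("chemo_doses", c), ("drug_doses", d)):
            if list(doses) != sorted(doses) or doses[0] != 0.0:
                raise ValidationError(
                    f"{name} must be ascending and include 0")
        v = np.asarray(self.viability, dtype=float)
        if v.shape != (len(c), len(d)):
            raise ValidationError(
                f"viability shape {v.shape} does not match dose grid "
                f"({len(c)}, {len(d)})")
        if np.any(v < 0) or np.any(v > 120):
            raise ValidationError("viability must lie in [0, 120] percent")
        object.__setattr__(self, "chemo_doses", c)
        object.__setattr__(self, "drug_doses", d)
        object.__setattr__(self, "viability", v)

    @classmethod
    def from_long_csv(cls, path, control_viability: float = 100.0):
        """Read a long-form CSV with columns chemo_uM, drug_uM, viability_pct."""
        df = pd.read_csv(path)
        need = {"chemo_uM", "drug_uM", "viability_pct"}
        if not need <= set(df.columns):
            raise ValidationError(
                f"dose-matrix CSV needs columns {sorted(need)}")
        wide = df.pivot_table(index="chemo_uM", columns="drug_uM",
                              values="viability_pct").sort_index(axis=0)
        wide = wide.sort_index(axis=1)
        return cls(tuple(wide.index), tuple(wide.columns), wide.to_numpy(),
                   control_viability)


@dataclass(frozen=True)
class HillCurve:
    """Four-parameter logistic viability curve (response in %, dose µM).

    ``e0`` is the zero-dose response, ``emax`` the plateau at infinite
    dose (``emax <= e0`` for a cytotoxic agent), ``ec50`` the midpoint
    dose and ``hill`` the slope.
    """

    e0: float
    emax: float
    ec50: float
    hill: float

    def __post_init__(self):
        if not self.ec50 > 0:
            raise ValidationError(f"ec50 must be > 0, got {self.ec50!r}")
        if not self.hill > 0:
            raise ValidationError(f"hill must be > 0, got {self.hill!r}")
        if self.emax > self.e0:
            raise ValidationError("emax must not exceed e0")

    def response(self, dose):
        dose = np.asarray(dose, dtype=float)
        frac = dose ** self.hill / (self.ec50 ** self.hill + dose ** self.hill)
        return self.e0 + (self.emax - self.e0) * frac

    def fraction_affected(self, dose):
        return 1.0 - self.response(dose) / self.e0

    @property
    def fa_max(self) -> float:
        """Largest fraction affected the curve can reach (dose -> inf)."""
        return 1.0 - self.emax / self.e0

    def dose_for_fa(self, fa: float) -> float:
        """Single-agent dose producing fraction affected ``fa`` (inversion)."""
        if not 0.0 < fa < 1.0:
            raise ValidationError(f"fa must lie in (0, 1), got {fa!r}")
        target = self.e0 * (1.0 - fa)
        if target <= self.emax:
            raise UndefinedCIError(
                f"fa = {fa:.3f} is unreachable (curve plateau fa_max = "
                f"{self.fa_max:.3f})")
        return self.ec50 * ((self.e0 - target) / (target - self.emax)
                            ) ** (1.0 / self.hill)


def fraction_affected_matrix(m: DoseMatrix) -> np.ndarray:
    """FA = clamp(1 - viability/control, 0, 1)."""
    if not m.control_viability > 0:
        raise ZeroDivisionError("control viability must be > 0")
    return np.clip(1.0 - m.viability / m.control_viability, 0.0, 1.0)


def _hill4(dose, e0, emax, ec50, hill):
    dose = np.asarray(dose, dtype=float)
    # log-space logistic avoids overflow at extreme dose/ec50 ratios
    with np.errstate(divide="ignore"):
        z = hill * (np.log(ec50) - np.log(np.where(dose > 0, dose, 1.0)))
    frac = 1.0 / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))
    frac = np.where(dose <= 0, 0.0, frac)
    return e0 + (emax - e0) * frac


@dataclass
class HillResults:
    """Fitted Hill curve with residual diagnostics."""

    curve: HillCurve
    doses: np.ndarray
    responses: np.ndarray
    residual_sd: float

    def summary(self) -> str:
        c = self.curve
        return ("Hill (4PL) fit\n"
                f"  e0    {c.e0:9.3f} %\n"
                f"  emax  {c.emax:9.3f} %\n"
                f"  ec50  {c.ec50:9.4g} µM\n"
                f"  hill  {c.hill:9.3f}\n"
                f"  residual sd {self.residual_sd:.3f} % "
                f"(n = {len(self.doses)})")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(self.doses[self.doses > 0],
                    self.responses[self.doses > 0], "o")
        grid = np.geomspace(max(self.doses[self.doses > 0].min() / 10, 1e-6),
                            self.doses.max() * 10, 200)
        ax.semilogx(grid, self.curve.response(grid), "-")
        ax.set_xlabel("dose (µM)")
        ax.set_ylabel("viability (%)")
        return ax


class HillModel:
    """Least-squares 4-parameter logistic model of a single-agent response.

    Initialisation is deterministic from data quantiles, so repeated
    fits of the same data give identical results.
    """

    def __init__(self, doses, responses):
        self.doses = np.asarray(doses, dtype=float)
        self.responses = np.asarray(responses, dtype=float)
        if self.doses.shape != self.responses.shape or self.doses.size < 4:
            raise ValidationError(
                "need >= 4 (dose, response) points of equal length")

    def fit(self) -> HillResults:
        d, r = self.doses, self.responses
        span = float(r.max() - r.min())
        if span < 5.0:
            raise FitDegenerateError(
                f"response range {span:.2f}% is too flat to fit")
        e0_0 = float(r[np.argmin(d)])
        emax_0 = float(r.min())
        mid = 0.5 * (e0_0 + emax_0)
        pos = d[d > 0]
        below = d[r <= mid]
        ec50_0 = float(below.min()) if below.size and below.min() > 0 \
            else float(np.median(pos))
        p0 = (e0_0, emax_0, ec50_0, 1.0)
        bounds = ([0.0, 0.0, 1e-9, 0.05], [200.0, 200.0, 1e6, 20.0])
        popt, _ = curve_fit(_hill4, d, r, p0=p0, bounds=bounds,
                            maxfev=20000)
        e0, emax, ec50, hill = (float(v) for v in popt)
        if emax > e0:
            raise FitDegenerateError(
                "fitted response increases with dose (emax > e0)")
        curve = HillCurve(e0, emax, ec50, hill)
        resid = r - curve.response(d)
        return HillResults(curve, d, r, float(np.std(resid)))


def fit_hill_curve(doses, responses) -> HillCurve:
    """Functional wrapper over :class:`HillModel`."""
    return HillModel(doses, responses).fit().curve


def loewe_index(d_chemo: float, d_drug: float, curve_chemo: HillCurve,
                curve_drug: HillCurve, observed_fa: float) -> float:
    """Loewe combination index of one combination point."""
    if not 0.0 < observed_fa < 1.0:
        raise ValidationError(
            f"observed_fa must lie in (0, 1), got {observed_fa!r}")
    ci = 0.0
    if d_chemo > 0:
        ci += d_chemo / curve_chemo.dose_for_fa(observed_fa)
    if d_drug > 0:
        ci += d_drug / curve_drug.dose_for_fa(observed_fa)
    if d_chemo == 0 and d_drug == 0:
        raise ValidationError("combination point has zero dose of both agents")
    return ci


def isobologram_points(fa: float, curve_chemo: HillCurve,
                       curve_drug: HillCurve,
                       combinations=()) -> dict:
    """Axis intercepts of the Loewe additivity line at ``fa`` plus any
    observed combination points ``(d_chemo, d_drug)``."""
    return {
        "fa": fa,
        "chemo_intercept_uM": curve_chemo.dose_for_fa(fa),
        "drug_intercept_uM": curve_drug.dose_for_fa(fa),
        "combinations": [tuple(map(float, c)) for c in combinations],
    }


def analyze_dose_matrix(m: DoseMatrix, fa_levels=DEFAULT_FA_LEVELS) -> dict:
    """Full synergy analysis of a dose matrix.

    Fits the two single-agent margins, computes the FA matrix, scores
    every interior combination point by its Loewe CI, and assembles
    isobologram coordinates at the requested fa levels.  Combination
    points whose fa is unreachable by a margin are reported with
    ``ci = None`` and a reason, never silently dropped.
    """
    fa = fraction_affected_matrix(m)
    chemo_fit = HillModel(np.asarray(m.chemo_doses), m.viability[:, 0]).fit()
    drug_fit = HillModel(np.asarray(m.drug_doses), m.viability[0, :]).fit()

    ci_records = []
    for i, dc in enumerate(m.chemo_doses):
        for j, dd in enumerate(m.drug_doses):
            if i == 0 and j == 0:
                continue
            point_fa = float(fa[i, j])
            record = {"chemo_uM": dc, "drug_uM": dd, "fa": point_fa,
                      "ci": None, "note": ""}
            if not 0.0 < point_fa < 1.0:
                record["note"] = "fa outside (0, 1)"
            else:
                try:
                    record["ci"] = loewe_index(dc, dd, chemo_fit.curve,
                                               drug_fit.curve, point_fa)
                except UndefinedCIError as err:
                    record["note"] = str(err)
            ci_records.append(record)

    isobolograms = []
    for level in fa_levels:
        try:
            isobolograms.append(isobologram_points(level, chemo_fit.curve,
                                                   drug_fit.curve))
        except UndefinedCIError as err:
            isobolograms.append({"fa": level, "error": str(err)})

    return {
        "chemo_curve": chemo_fit.curve, "drug_curve": drug_fit.curve,
        "fraction_affected": fa, "ci_table": ci_records,
        "isobolograms": isobolograms,
    }
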