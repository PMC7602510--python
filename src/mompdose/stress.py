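"""Minimal apoptotic stress dose: search, dose-response and calibration.

The model's summary statistic for a sample is the smallest BH3-only
bolus ("stress dose", nM) whose trajectory reaches MOMP within the
simulated window.  Because MOMP occurrence is monotone in the bolus, the
minimal dose is located by bisection on the occurrence predicate.

`StressDoseCalibration` is the fitted-model object of the package: it
adjusts the two free kinetic constants (k_act, k_oligo) so that the
computed baseline stress doses of reference samples match measured /
published target doses, and returns a results object carrying the
fitted parameters, per-sample fitted doses and diagnostics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .kinetics import KineticParameters
from .network import SimulationError, build_initial_state, simulate_network
from .profiles import (DrugSpec, NO_DRUG, ProteinProfile, StressInput,
                       ValidationError)

__all__ = [
    "StressDoseResult", "DoseResponseCurve", "SensitizationMetrics",
    "CalibrationError", "CalibrationResults", "StressDoseCalibration",
    "compute_stress_dose", "dose_response_curve", "sensitization_metrics",
    "momp_occurs", "DEFAULT_DOSE_GRID",
]

#: Default ABT-199 dose grid (nM) spanning the 0-10 uM window.
DEFAULT_DOSE_GRID = (0.0, 100.0, 500.0, 1000.0, 2000.0, 5000.0, 10000.0)

BRACKET_CEILING = 1e6   # nM
BISECT_TOL = 1.0        # nM; published stress doses are integer nM
MAX_BISECT_ITER = 40


@dataclass(frozen=True)
class StressDoseResult:
    sample_id: str
    drug_dose: float
    stress_dose: float
    converged: bool
    iterations: int
    bracket_ceiling_hit: bool
    lower: float = 0.0
    upper: float = 0.0

    def __post_init__(self):
        if self.stress_dose < 0:
            raise ValidationError("stress_dose must be >= 0")


@dataclass(frozen=True)
class DoseResponseCurve:
    sample_id: str
    drug_doses: tuple
    stress_doses: tuple

    def __post_init__(self):
        if len(self.drug_doses) != len(self.stress_doses):
            raise ValidationError("drug_doses and stress_doses lengths differ")

    def plot(self, ax=None, **kw):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.asarray(self.drug_doses) / 1e3, self.stress_doses,
                marker="o", label=self.sample_id, **kw)
        ax.set_xlabel("ABT-199 dose (µM)")
        ax.set_ylabel("stress dose (nM)")
        ax.legend()
        return ax


@dataclass(frozen=True)
class SensitizationMetrics:
    baseline_dose: float
    treated_dose: float
    absolute_reduction: float
    relative_reduction: float
    combination_benefit_flag: bool


class PartialCurveError(RuntimeError):
    """A member dose of a dose-response sweep failed; carries completed part."""

    def __init__(self, message, completed_doses, completed_results):
        super().__init__(message)
        self.completed_doses = completed_doses
        self.completed_results = completed_results


def momp_occurs(profile: ProteinProfile, drug: DrugSpec,
                params: KineticParameters, total_dose: float, *,
                activator_fraction: float = 0.8) -> bool:
    """Does a bolus of ``total_dose`` nM trigger MOMP within the horizon?"""
    stress = StressInput.for_profile(total_dose, profile, activator_fraction)
    state = build_initial_state(profile, drug, stress)
    traj = simulate_network(state, params, drug, stop_at_momp=True)
    return traj.momp_time is not None


def compute_stress_dose(profile: ProteinProfile, drug: DrugSpec | None,
                        params: KineticParameters, *,
                        tol: float = BISECT_TOL,
                        ceiling: float = BRACKET_CEILING,
                        max_iter: int = MAX_BISECT_ITER,
                        guess: float | None = None) -> StressDoseResult:
    """Minimal stress dose triggering MOMP, by bisection on [0, ceiling].

    Returns the upper end of the final bracket, i.e. the smallest dose
    (within ``tol``) whose trajectory reaches MOMP.  If MOMP does not
    occur even at the ceiling the result carries
    ``bracket_ceiling_hit=True`` and ``stress_dose=ceiling``.

    ``guess`` warm-starts the bracket (the answer is unchanged because
    the MOMP predicate is monotone in the dose; the bracket is expanded
    until it provably straddles the boundary).
    """
    drug = drug if drug is not None else NO_DRUG

    def occurs(dose: float) -> bool:
        try:
            return momp_occurs(profile, drug, params, dose)
        except SimulationError as err:
            raise SimulationError(
                f"simulation failed at stress dose {dose:.6g} nM: {err}",
                err.last_time) from err

    iterations = 0
    if occurs(0.0):
        return StressDoseResult(profile.sample_id, drug.dose, 0.0, True, 0,
                                False, 0.0, 0.0)
    lo, hi = 0.0, ceiling
    if guess is not None and 0.0 < guess < ceiling:
        g_lo, g_hi = guess / 2.0, guess * 2.0
        while g_hi < ceiling and not occurs(g_hi):
            iterations += 1
            g_lo, g_hi = g_hi, min(g_hi * 4.0, ceiling)
        if g_hi < ceiling or occurs(ceiling):
            hi = g_hi
            while g_lo > tol and occurs(g_lo):
                iterations += 1
                hi, g_lo = g_lo, g_lo / 4.0
            lo = g_lo if not occurs(g_lo) else 0.0
        else:
            return StressDoseResult(profile.sample_id, drug.dose, ceiling,
                                    False, iterations, True, lo, ceiling)
    elif not occurs(ceiling):
        return StressDoseResult(profile.sample_id, drug.dose, ceiling, False,
                                1, True, 0.0, ceiling)

    while hi - lo > tol and iterations < max_iter:
        mid = 0.5 * (lo + hi)
        if occurs(mid):
            hi = mid
        else:
            lo = mid
        iterations += 1
    return StressDoseResult(profile.sample_id, drug.dose, hi,
                            hi - lo <= tol, iterations, False, lo, hi)


def dose_response_curve(profile: ProteinProfile, drug: DrugSpec,
                        params: KineticParameters,
                        drug_doses=DEFAULT_DOSE_GRID, **kw
                        ) -> DoseResponseCurve:
    """Stress dose at each drug dose of an ascending grid."""
    doses = [float(d) for d in drug_doses]
    if any(d < 0 for d in doses) or doses != sorted(doses):
        raise ValidationError("drug doses must be sorted ascending and >= 0")
    results = []
    guess = None
    for d in doses:
        try:
            res = compute_stress_dose(profile, drug.at_dose(d), params,
                                      guess=guess, **kw)
        except SimulationError as err:
            raise PartialCurveError(
                f"dose-response failed at drug dose {d:.6g} nM: {err}",
                doses[:len(results)], results) from err
        results.append(res)
        guess = res.stress_dose if not res.bracket_ceiling_hit else None
    return DoseResponseCurve(profile.sample_id, tuple(doses),
                             tuple(r.stress_dose for r in results))


def sensitization_metrics(curve: DoseResponseCurve,
                          treated_dose_index: int = -1,
                          tau: float = 0.33) -> SensitizationMetrics:
    """Reduction of the stress dose by the drug relative to baseline.

    The baseline is the curve's zero-dose entry; the benefit flag marks
    a relative reduction of at least ``tau``.
    """
    if not curve.drug_doses or curve.drug_doses[0] != 0.0:
        raise ValidationError("dose-response curve must include dose 0 first")
    baseline = curve.stress_doses[0]
    treated = curve.stress_doses[treated_dose_index]
    absolute = baseline - treated
    relative = absolute / baseline if baseline > 0 else 0.0
    relative = min(max(relative, 0.0), 1.0)
    return SensitizationMetrics(baseline, treated, absolute, relative,
                                relative >= tau)


class CalibrationError(RuntimeError):
    """Calibration residual above threshold; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class CalibrationResults:
    """Fitted kinetic constants and diagnostics from a calibration run."""

    params: KineticParameters
    k_act: float
    k_oligo: float
    sample_ids: list
    target_doses: np.ndarray
    fitted_doses: np.ndarray
    residual: float                 # sum of squared log-errors
    n_function_evals: int
    converged: bool
    model: "StressDoseCalibration" = field(repr=False, default=None)

    @property
    def ratios(self) -> np.ndarray:
        return self.fitted_doses / self.target_doses

    def predict(self, profile: ProteinProfile, drug: DrugSpec | None = None,
                **kw) -> StressDoseResult:
        """Stress dose for a new sample under the fitted kinetics."""
        return compute_stress_dose(profile, drug, self.params, **kw)

    def summary(self) -> str:
        lines = [
            "Stress-dose calibration results",
            "=" * 46,
            f"  k_act    {self.k_act:.6e}  nM^-1 h^-1",
            f"  k_oligo  {self.k_oligo:.6e}  nM^-1 h^-1",
            f"  residual (sum sq log-error)  {self.residual:.3e}",
            f"  function evaluations         {self.n_function_evals}",
            f"  converged                    {self.converged}",
            "-" * 46,
            f"  {'sample':<12}{'target nM':>10}{'fitted nM':>12}{'ratio':>8}",
        ]
        for sid, tgt, fit in zip(self.sample_ids, self.target_doses,
                                 self.fitted_doses):
            lines.append(f"  {sid:<12}{tgt:>10.0f}{fit:>12.1f}{fit/tgt:>8.3f}")
        return "\n".join(lines)


class StressDoseCalibration:
    """Calibrate (k_act, k_oligo) to published baseline stress doses.

    Minimises the sum of squared log-errors between computed and target
    baseline stress doses over (log10 k_act, log10 k_oligo), holding
    every other kinetic parameter fixed.  Deterministic local search
    (Nelder-Mead) from the supplied starting parameters.

    Parameters
    ----------
    profiles : sequence of ProteinProfile
    target_doses : sequence of float
        Target baseline stress doses (nM), one per profile; must be > 0.
    params_init : KineticParameters, optional
        Starting point; defaults to the package defaults.
    drug : DrugSpec, optional
        Drug present during the calibrated runs (default: none).
    """

    def __init__(self, profiles, target_doses,
                 params_init: KineticParameters | None = None,
                 drug: DrugSpec | None = None):
        self.profiles = list(profiles)
        self.targets = np.asarray([float(t) for t in target_doses])
        if len(self.profiles) != len(self.targets) or len(self.profiles) < 1:
            raise ValidationError(
                "need one target dose per profile (at least one pair)")
        if np.any(self.targets <= 0):
            raise ValidationError("target doses must be > 0")
        self.params_init = params_init or KineticParameters()
        self.drug = drug if drug is not None else NO_DRUG
        self._guesses: dict[str, float] = {}

    def _doses_at(self, log_k: np.ndarray) -> np.ndarray:
        params = self.params_init.with_rates(10.0 ** log_k[0],
                                             10.0 ** log_k[1])
        doses = []
        for p, tgt in zip(self.profiles, self.targets):
            res = compute_stress_dose(p, self.drug, params,
                                      guess=self._guesses.get(p.sample_id, tgt))
            dose = res.stress_dose if not res.bracket_ceiling_hit else np.nan
            if np.isfinite(dose) and dose > 0:
                self._guesses[p.sample_id] = dose
            doses.append(dose)
        return np.asarray(doses)

    def objective(self, log_k: np.ndarray) -> float:
        doses = self._doses_at(log_k)
        if np.any(~np.isfinite(doses)) or np.any(doses <= 0):
            return 1e6
        return float(np.sum((np.log(doses) - np.log(self.targets)) ** 2))

    def fit(self, max_iter: int = 200) -> CalibrationResults:
        x0 = np.log10([self.params_init.k_act, self.params_init.k_oligo])
        opt = minimize(self.objective, x0, method="Nelder-Mead",
                       options={"maxiter": max_iter, "xatol": 1e-4,
                                "fatol": 1e-10})
        k_act, k_oligo = 10.0 ** opt.x
        params = self.params_init.with_rates(k_act, k_oligo)
        fitted = self._doses_at(opt.x)
        residual = float(np.sum((np.log(fitted) - np.log(self.targets)) ** 2))
        ratios = fitted / self.targets
        results = CalibrationResults(
            params=params, k_act=k_act, k_oligo=k_oligo,
            sample_ids=[p.sample_id for p in self.profiles],
            target_doses=self.targets, fitted_doses=fitted,
            residual=residual, n_function_evals=int(opt.nfev),
            converged=bool(opt.success), model=self)
        if np.any(ratios < 0.5) or np.any(ratios > 2.0):
            raise CalibrationError(
                "calibration failed: a fitted/target ratio is outside "
                f"[0.5, 2] (ratios {np.round(ratios, 3).tolist()})",
                diagnostics={"results": results})
        return results
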