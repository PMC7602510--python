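"""Deterministic ODE model of the BCL-2 interaction network.

The network tracks 27 species: the two BH3-only stress pools (a direct
activator A and an MCL-1-selective sensitizer N), inactive/active BAX
and BAK, the three free anti-apoptotics, the free drug, every
anti-apoptotic:partner and anti-apoptotic:drug complex, and the
irreversible BAX/BAK pore pools.

Reactions (mass action throughout):

1.  Catalytic activation  A + BAX_i -> A + BAX_a  at ``k_act * A * BAX_i``
    (translocation is folded into activation); likewise for BAK.
2.  Reversible binding  X + P <-> XP  for every anti-apoptotic
    X in {BCL-2, BCL-xL, MCL-1} and partner P in {A, N, BAX_a, BAK_a},
    with on-rate ``k_on`` and off-rate ``k_on * Kd(X, P)``.
3.  Drug binding  X + D <-> XD  with the drug's per-target Kds; drug
    mass is conserved (no clearance over the stress window).
4.  Irreversible homo-dimerisation  2 BAX_a -> pore  at
    ``k_oligo * BAX_a**2``; likewise for BAK.
5.  First-order decay of the free stress species A and N at
    ``k_deg_bh3``.

MOMP is called when the pore fraction
``(2*pores_BAX + 2*pores_BAK) / (BAX_total + BAK_total)`` crosses the
configured threshold within the simulated window.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .kinetics import ANTI, PARTNERS, KineticParameters
from .profiles import (DrugSpec, NO_DRUG, ProteinProfile, StressInput,
                       ValidationError)

__all__ = [
    "SPECIES", "NetworkState", "TrajectoryResult", "SimulationError",
    "build_initial_state", "simulate_network", "detect_momp",
    "equilibrium_free_fractions", "family_totals",
]


class SimulationError(RuntimeError):
    """Integrator failure; carries the last valid time reached."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


def _species_list() -> tuple[str, ...]:
    names = ["activator", "sensitizer", "bax_i", "bax_a", "bak_i", "bak_a",
             "bcl2", "bclxl", "mcl1", "drug"]
    for x in ANTI:
        for p in PARTNERS:
            names.append(f"{x}:{p}")
    names += [f"{x}:drug" for x in ANTI]
    names += ["pore_bax", "pore_bak"]
    return tuple(names)


SPECIES: tuple[str, ...] = _species_list()
IDX = {name: i for i, name in enumerate(SPECIES)}
N_SPECIES = len(SPECIES)

#: Conserved families: family name -> [(species, multiplicity), ...]
_CONSERVED: dict[str, list[tuple[str, int]]] = {
    "bax": [("bax_i", 1), ("bax_a", 1), ("pore_bax", 2)]
           + [(f"{x}:bax_a", 1) for x in ANTI],
    "bak": [("bak_i", 1), ("bak_a", 1), ("pore_bak", 2)]
           + [(f"{x}:bak_a", 1) for x in ANTI],
    "drug": [("drug", 1)] + [(f"{x}:drug", 1) for x in ANTI],
}
for _x in ANTI:
    _CONSERVED[_x] = ([(_x, 1), (f"{_x}:drug", 1)]
                      + [(f"{_x}:{p}", 1) for p in PARTNERS])


def family_totals(y: np.ndarray) -> dict[str, float]:
    """Mass totals of each conserved family given a state vector."""
    return {fam: float(sum(m * y[IDX[s]] for s, m in members))
            for fam, members in _CONSERVED.items()}


class _ReactionSystem:
    """Network compiled to stoichiometry and rate-index arrays.

    Every rate is ``k * y[a] * y[b]`` (``b`` may be a dummy index whose
    value is pinned at 1 for unimolecular steps), which makes both the
    right-hand side and the analytic Jacobian a pair of small matrix
    products.
    """

    def __init__(self, params: KineticParameters, drug: DrugSpec):
        I = IDX
        reactions: list[tuple[float, tuple[int, ...], dict[int, float]]] = []

        reactions.append((params.k_act, (I["activator"], I["bax_i"]),
                          {I["bax_i"]: -1, I["bax_a"]: +1}))
        reactions.append((params.k_act, (I["activator"], I["bak_i"]),
                          {I["bak_i"]: -1, I["bak_a"]: +1}))

        for x in ANTI:
            for p in PARTNERS:
                c = I[f"{x}:{p}"]
                reactions.append((params.k_on, (I[x], I[p]),
                                  {I[x]: -1, I[p]: -1, c: +1}))
                reactions.append((params.k_on * params.kd(x, p), (c,),
                                  {I[x]: +1, I[p]: +1, c: -1}))
            c = I[f"{x}:drug"]
            reactions.append((params.k_on, (I[x], I["drug"]),
                              {I[x]: -1, I["drug"]: -1, c: +1}))
            reactions.append((params.k_on * drug.kd_for(x), (c,),
                              {I[x]: +1, I["drug"]: +1, c: -1}))

        reactions.append((params.k_oligo, (I["bax_a"], I["bax_a"]),
                          {I["bax_a"]: -2, I["pore_bax"]: +1}))
        reactions.append((params.k_oligo, (I["bak_a"], I["bak_a"]),
                          {I["bak_a"]: -2, I["pore_bak"]: +1}))

        reactions.append((params.k_deg_bh3, (I["activator"],),
                          {I["activator"]: -1}))
        reactions.append((params.k_deg_bh3, (I["sensitizer"],),
                          {I["sensitizer"]: -1}))

        nr = len(reactions)
        self.n_reactions = nr
        self.k = np.array([r[0] for r in reactions])
        # dummy column N_SPECIES holds the constant 1.0
        self.ra = np.array([r[1][0] for r in reactions], dtype=np.intp)
        self.rb = np.array(
            [r[1][1] if len(r[1]) > 1 else N_SPECIES for r in reactions],
            dtype=np.intp)
        S = np.zeros((N_SPECIES, nr))
        for j, (_, _, stoich) in enumerate(reactions):
            for i, v in stoich.items():
                S[i, j] += v
        self.S = S
        self._rows = np.arange(nr)
        self._ye = np.ones(N_SPECIES + 1)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        ye = self._ye
        ye[:N_SPECIES] = y
        rates = self.k * ye[self.ra] * ye[self.rb]
        return self.S @ rates

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        ye = self._ye
        ye[:N_SPECIES] = y
        dR = np.zeros((self.n_reactions, N_SPECIES + 1))
        np.add.at(dR, (self._rows, self.ra), self.k * ye[self.rb])
        np.add.at(dR, (self._rows, self.rb), self.k * ye[self.ra])
        return self.S @ dR[:, :N_SPECIES]


@dataclass(frozen=True)
class NetworkState:
    """State vector of the network at one time point (all nM)."""

    time: float
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.concentrations, dtype=float)
        if y.shape != (N_SPECIES,):
            raise ValidationError(
                f"state vector must have {N_SPECIES} entries, got {y.shape}")
        object.__setattr__(self, "concentrations", y)

    def __getitem__(self, species: str) -> float:
        return float(self.concentrations[IDX[species]])

    @property
    def totals(self) -> dict[str, float]:
        return family_totals(self.concentrations)


def build_initial_state(profile: ProteinProfile, drug: DrugSpec,
                        stress: StressInput) -> NetworkState:
    """Initial condition: all proteins free, effectors inactive, the
    stress bolus and drug applied at t = 0, no complexes or pores."""
    y = np.zeros(N_SPECIES)
    y[IDX["activator"]] = stress.activator_dose
    y[IDX["sensitizer"]] = stress.sensitizer_dose
    y[IDX["bax_i"]] = profile.bax
    y[IDX["bak_i"]] = profile.bak
    y[IDX["bcl2"]] = profile.bcl2
    y[IDX["bclxl"]] = profile.bclxl
    y[IDX["mcl1"]] = profile.mcl1
    y[IDX["drug"]] = drug.dose
    return NetworkState(0.0, y)


@dataclass
class TrajectoryResult:
    """Simulated trajectory with dense output for event location."""

    time_grid: np.ndarray
    states: np.ndarray                     # (n_times, n_species)
    pore_fraction: np.ndarray
    momp_time: float | None
    momp_threshold: float
    effector_total: float
    conservation_error: float
    species: tuple[str, ...] = SPECIES
    sol: object | None = field(default=None, repr=False)

    def state_at(self, t):
        if self.sol is None:
            raise ValueError("trajectory carries no dense output")
        return self.sol(t)

    def pore_fraction_at(self, t):
        """Pore fraction at arbitrary times (dense output if available,
        otherwise linear interpolation of the stored grid)."""
        if self.sol is not None:
            y = self.sol(t)
            pores = 2.0 * (y[IDX["pore_bax"]] + y[IDX["pore_bak"]])
            return pores / max(self.effector_total, 1e-300)
        return np.interp(t, self.time_grid, self.pore_fraction)

    def to_tidy_frame(self) -> pd.DataFrame:
        """Long-form (time, species, concentration) table."""
        n_t = len(self.time_grid)
        return pd.DataFrame({
            "time_h": np.repeat(self.time_grid, N_SPECIES),
            "species": list(self.species) * n_t,
            "concentration_nM": self.states.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_tidy_frame().to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "momp_time_h": self.momp_time,
            "momp_threshold": self.momp_threshold,
            "pore_fraction_at_horizon": float(self.pore_fraction[-1]),
            "conservation_error": self.conservation_error,
        }

    def summary_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)

    def plot(self, ax=None, species=("bax_a", "bak_a", "activator")):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for s in species:
            ax.plot(self.time_grid, self.states[:, IDX[s]], label=s)
        ax2 = ax.twinx()
        ax2.plot(self.time_grid, self.pore_fraction, "k--",
                 label="pore fraction")
        ax2.axhline(self.momp_threshold, color="r", lw=0.5)
        ax2.set_ylabel("pore fraction")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration (nM)")
        ax.legend(loc="upper left")
        return ax


def simulate_network(state: NetworkState, params: KineticParameters,
                     drug: DrugSpec | None = None, *,
                     stop_at_momp: bool = False,
                     t_eval: np.ndarray | None = None,
                     rtol: float = 1e-8, atol: float = 1e-6,
                     ) -> TrajectoryResult:
    """Integrate the reaction network over [0, horizon].

    Uses a stiff-capable integrator (LSODA) with an analytic Jacobian
    and dense output; MOMP crossing is located by the integrator's event
    root-finder on the dense solution.
    """
    drug = drug if drug is not None else NO_DRUG
    system = _ReactionSystem(params, drug)
    y0 = state.concentrations
    eff_total = float(y0[IDX["bax_i"]] + y0[IDX["bax_a"]]
                      + y0[IDX["bak_i"]] + y0[IDX["bak_a"]]
                      + sum(y0[IDX[f"{x}:bax_a"]] + y0[IDX[f"{x}:bak_a"]]
                            for x in ANTI)
                      + 2.0 * (y0[IDX["pore_bax"]] + y0[IDX["pore_bak"]]))
    denom = max(eff_total, 1e-300)
    ip_bax, ip_bak = IDX["pore_bax"], IDX["pore_bak"]

    def momp_event(t, y):
        return 2.0 * (y[ip_bax] + y[ip_bak]) / denom - params.momp_threshold

    momp_event.direction = 1
    momp_event.terminal = stop_at_momp

    sol = solve_ivp(system.rhs, (0.0, params.horizon), y0, method="LSODA",
                    jac=system.jac, rtol=rtol, atol=atol, dense_output=True,
                    events=momp_event, t_eval=t_eval)
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise SimulationError(
            f"integration failed at t = {last:.4g} h: {sol.message}", last)
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        raise SimulationError("non-finite state encountered",
                              float(sol.t[-1]))
    pf = 2.0 * (states[:, ip_bax] + states[:, ip_bak]) / denom
    momp_time = float(sol.t_events[0][0]) if sol.t_events[0].size else None

    totals0 = family_totals(y0)
    totals_end = family_totals(states[-1])
    cons_err = 0.0
    for fam, t0 in totals0.items():
        scale = max(abs(t0), 1.0)
        cons_err = max(cons_err, abs(totals_end[fam] - t0) / scale)

    return TrajectoryResult(
        time_grid=sol.t, states=states, pore_fraction=pf,
        momp_time=momp_time, momp_threshold=params.momp_threshold,
        effector_total=eff_total, conservation_error=cons_err, sol=sol.sol)


def detect_momp(traj: TrajectoryResult,
                threshold: float | None = None) -> float | None:
    """Earliest time at which the pore fraction reaches ``threshold``.

    Located by root-finding on the trajectory's dense output (falls
    back to interpolation for trajectories without one); ``None`` if the
    threshold is never reached within the horizon.
    """
    if threshold is None:
        threshold = traj.momp_threshold
    if not (0.0 < threshold <= 1.0):
        raise ValidationError(f"threshold must lie in (0, 1], got {threshold!r}")
    pf = np.asarray([traj.pore_fraction_at(t) for t in traj.time_grid])
    if pf[0] >= threshold:
        return float(traj.time_grid[0])
    above = np.nonzero(pf >= threshold)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    f = lambda t: traj.pore_fraction_at(t) - threshold
    return float(brentq(f, traj.time_grid[i - 1], traj.time_grid[i],
                        xtol=1e-10))


def equilibrium_free_fractions(profile: ProteinProfile, drug: DrugSpec,
                               kd_matrix: dict | None = None, *,
                               stress: StressInput | None = None,
                               tol: float = 1e-12,
                               max_iter: int = 200_000) -> dict[str, float]:
    """Free anti-apoptotic concentrations of the binding-only subsystem.

    Solves the coupled competitive mass-action equilibrium (damped
    fixed point on the free ligand pools) for the three anti-apoptotics
    against the drug — and, when ``stress`` is given, the activator and
    sensitizer pools as well.  Serves as a closed-form-anchored oracle
    for the long-time ODE limit when activation, pore formation and
    BH3 decay are switched off.

    Returns ``{"bcl2": free nM, "bclxl": ..., "mcl1": ...}``.
    """
    from .kinetics import DEFAULT_KD_MATRIX
    kd_matrix = kd_matrix if kd_matrix is not None else DEFAULT_KD_MATRIX
    x_tot = {"bcl2": profile.bcl2, "bclxl": profile.bclxl,
             "mcl1": profile.mcl1}

    # ligand name -> (total, {anti: kd})
    ligands: dict[str, tuple[float, dict[str, float]]] = {
        "drug": (drug.dose, {x: drug.kd_for(x) for x in ANTI}),
    }
    if stress is not None:
        ligands["activator"] = (
            stress.activator_dose,
            {x: kd_matrix[(x, "activator")] for x in ANTI})
        ligands["sensitizer"] = (
            stress.sensitizer_dose,
            {x: kd_matrix[(x, "sensitizer")] for x in ANTI})

    free_l = {name: tot for name, (tot, _) in ligands.items()}
    x_free = dict(x_tot)
    for _ in range(max_iter):
        x_new = {
            x: x_tot[x] / (1.0 + sum(free_l[l] / kds[x]
                                     for l, (_, kds) in ligands.items()))
            for x in ANTI}
        l_new = {}
        for l, (tot, kds) in ligands.items():
            l_new[l] = tot / (1.0 + sum(x_new[x] / kds[x] for x in ANTI))
        delta = 0.0
        for l, (tot, _) in ligands.items():
            mixed = 0.5 * (free_l[l] + l_new[l])
            delta = max(delta, abs(mixed - free_l[l]) / max(tot, 1e-12))
            free_l[l] = mixed
        x_free = x_new
        if delta < tol:
            return {x: float(x_free[x]) for x in ANTI}
    raise SimulationError(
        f"equilibrium fixed point did not converge in {max_iter} iterations")
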