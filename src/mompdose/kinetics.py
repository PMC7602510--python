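"""Kinetic parameters of the BCL-2 interaction network.

Rates use nM and hours.  Bimolecular steps share a single association
rate ``k_on``; each reversible pair is characterised by its equilibrium
dissociation constant, so the off-rate is ``k_on * Kd``.  Pairs that do
not interact biologically carry a sentinel Kd of 1e9 nM, which is
indistinguishable from "non-binding" at cellular concentrations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import yaml

from .profiles import ValidationError

ANTI = ("bcl2", "bclxl", "mcl1")
PARTNERS = ("activator", "sensitizer", "bax_a", "bak_a")

#: Sentinel Kd (nM) for pairs that do not bind.
NON_BINDING = 1e9

#: Interaction Kd matrix (nM).  Selectivity pattern: BCL-2 neutralises the
#: activator and active BAX but not BAK or the sensitizer; BCL-xL binds
#: everything except the sensitizer; MCL-1 guards BAK and is the sole
#: sensitizer (NOXA-like) target.
DEFAULT_KD_MATRIX: dict[tuple[str, str], float] = {
    ("bcl2", "activator"): 10.0,
    ("bcl2", "bax_a"): 20.0,
    ("bcl2", "bak_a"): NON_BINDING,
    ("bcl2", "sensitizer"): NON_BINDING,
    ("bclxl", "activator"): 5.0,
    ("bclxl", "bax_a"): 20.0,
    ("bclxl", "bak_a"): 50.0,
    ("bclxl", "sensitizer"): NON_BINDING,
    ("mcl1", "activator"): 10.0,
    ("mcl1", "bax_a"): NON_BINDING,
    ("mcl1", "bak_a"): 10.0,
    ("mcl1", "sensitizer"): 10.0,
}

_YAML_KEYS = {"k_act", "k_oligo", "k_on", "k_deg_bh3", "momp_threshold",
              "horizon", "kd_matrix"}


@dataclass(frozen=True)
class KineticParameters:
    """All rate constants, the interaction Kd matrix, the MOMP criterion
    and the simulation horizon.

    Parameters
    ----------
    k_act : float
        Activator-catalysed BAX/BAK activation rate (nM^-1 h^-1).
    k_oligo : float
        Effector homo-dimerisation (pore formation) rate (nM^-1 h^-1).
    k_on : float
        Shared association rate for every binding reaction (nM^-1 h^-1).
    k_deg_bh3 : float
        First-order decay of the free BH3-only stress species (h^-1).
    kd_matrix : dict
        (anti-apoptotic, partner) -> Kd in nM.
    momp_threshold : float
        Fraction of total BAX+BAK that must reside in pores to call MOMP.
    horizon : float
        Simulated stress window in hours.

    ``k_act`` and ``k_oligo`` are the two free constants adjusted by
    calibration; everything else is fixed.
    """

    k_act: float = 3e-4
    k_oligo: float = 1e-4
    k_on: float = 1e-4
    k_deg_bh3: float = 1.0
    kd_matrix: dict = field(default_factory=lambda: dict(DEFAULT_KD_MATRIX))
    momp_threshold: float = 0.10
    horizon: float = 12.0

    def __post_init__(self) -> None:
        for name in ("k_act", "k_oligo", "k_on", "k_deg_bh3"):
            v = float(getattr(self, name))
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")
            object.__setattr__(self, name, v)
        if not (0.0 < self.momp_threshold <= 1.0):
            raise ValidationError(
                f"momp_threshold must lie in (0, 1], got {self.momp_threshold!r}")
        if not self.horizon > 0:
            raise ValidationError(f"horizon must be > 0, got {self.horizon!r}")
        kd = dict(self.kd_matrix)
        for x in ANTI:
            for p in PARTNERS:
                v = float(kd.get((x, p), NON_BINDING))
                if not (math.isfinite(v) and v > 0):
                    raise ValidationError(f"Kd({x}, {p}) must be > 0, got {v!r}")
                kd[(x, p)] = v
        extra = set(kd) - {(x, p) for x in ANTI for p in PARTNERS}
        if extra:
            raise ValidationError(f"unknown kd_matrix entries: {sorted(extra)}")
        object.__setattr__(self, "kd_matrix", kd)

    def kd(self, anti: str, partner: str) -> float:
        return self.kd_matrix[(anti, partner)]

    def with_rates(self, k_act: float | None = None,
                   k_oligo: float | None = None) -> "KineticParameters":
        return replace(
            self,
            k_act=self.k_act if k_act is None else k_act,
            k_oligo=self.k_oligo if k_oligo is None else k_oligo,
        )

    def replace(self, **changes) -> "KineticParameters":
        return replace(self, **changes)


# Rates calibrated once against the two reference PDX baselines (stress
# doses 4271 nM for CRC0076 and 2601 nM for CRC0344 at zero drug); see
# docs/methods.md.  Recomputed from scratch by the calibration model.
REFERENCE_K_ACT = 1.205635e-03
REFERENCE_K_OLIGO = 2.455599e-05


def reference_parameters() -> KineticParameters:
    """Defaults with (k_act, k_oligo) calibrated to the PDX baselines."""
    return KineticParameters(k_act=REFERENCE_K_ACT, k_oligo=REFERENCE_K_OLIGO)


def load_kinetics_yaml(path) -> KineticParameters:
    """Load kinetic parameters from YAML; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("kinetics YAML must be a mapping")
    unknown = set(raw) - _YAML_KEYS
    if unknown:
        raise ValidationError(f"unknown kinetics keys: {sorted(unknown)}")
    kwargs = {k: v for k, v in raw.items() if k != "kd_matrix"}
    if "kd_matrix" in raw:
        kd = {}
        for x, partners in raw["kd_matrix"].items():
            if x not in ANTI:
                raise ValidationError(f"unknown anti-apoptotic {x!r} in kd_matrix")
            for p, v in partners.items():
                if p not in PARTNERS:
                    raise ValidationError(f"unknown partner {p!r} in kd_matrix")
                kd[(x, p)] = float(v)
        base = dict(DEFAULT_KD_MATRIX)
        base.update(kd)
        kwargs["kd_matrix"] = base
    return KineticParameters(**kwargs)


def dump_kinetics_yaml(params: KineticParameters, path) -> None:
    kd: dict[str, dict[str, float]] = {x: {} for x in ANTI}
    for (x, p), v in params.kd_matrix.items():
        kd[x][p] = v
    data = {
        "k_act": params.k_act, "k_oligo": params.k_oligo,
        "k_on": params.k_on, "k_deg_bh3": params.k_deg_bh3,
        "momp_threshold": params.momp_threshold, "horizon": params.horizon,
        "kd_matrix": kd,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
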