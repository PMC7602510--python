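"""Protein profiles, drug specifications and stress inputs.

All concentrations are absolute intracellular levels in nM; time is in
hours throughout the package.  A :class:`ProteinProfile` holds the five
modelled BCL-2 family proteins for one sample — the pore-forming
effectors BAX and BAK and the anti-apoptotic guardians BCL-2, BCL-xL and
MCL-1 — plus the sample's p53 functional status, which governs whether
genotoxic stress can induce the MCL-1-selective sensitizer (NOXA-like)
arm of the BH3-only response.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

PROTEINS = ("bak", "bax", "bcl2", "bclxl", "mcl1")
ANTI_APOPTOTIC = ("bcl2", "bclxl", "mcl1")
EFFECTORS = ("bax", "bak")

PROFILE_CSV_COLUMNS = [
    "sample_id", "bak_nM", "bax_nM", "bcl2_nM", "bclxl_nM", "mcl1_nM",
    "p53_functional",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True)
class ProteinProfile:
    """Absolute BCL-2 family protein concentrations for one sample (nM)."""

    sample_id: str
    bak: float
    bax: float
    bcl2: float
    bclxl: float
    mcl1: float
    p53_functional: bool = True

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        for name in PROTEINS:
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{name} must be finite and >= 0, got {v!r}")
            object.__setattr__(self, name, v)

    @property
    def total_anti_apoptotic(self) -> float:
        return self.bcl2 + self.bclxl + self.mcl1

    @property
    def total_effector(self) -> float:
        return self.bax + self.bak

    def with_(self, **changes) -> "ProteinProfile":
        return replace(self, **changes)


@dataclass(frozen=True)
class DrugSpec:
    """A BH3-mimetic: per-target dissociation constants (nM) and dose (nM)."""

    name: str
    kd_bcl2: float
    kd_bclxl: float
    kd_mcl1: float
    dose: float = 0.0

    def __post_init__(self) -> None:
        for field in ("kd_bcl2", "kd_bclxl", "kd_mcl1"):
            v = float(getattr(self, field))
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"{field} must be finite and > 0, got {v!r}")
            object.__setattr__(self, field, v)
        d = float(self.dose)
        if not (math.isfinite(d) and d >= 0):
            raise ValidationError(f"dose must be finite and >= 0, got {d!r}")
        object.__setattr__(self, "dose", d)

    def kd_for(self, target: str) -> float:
        return {"bcl2": self.kd_bcl2, "bclxl": self.kd_bclxl,
                "mcl1": self.kd_mcl1}[target]

    def at_dose(self, dose: float) -> "DrugSpec":
        return replace(self, dose=dose)


#: Venetoclax: BCL-2-selective BH3 mimetic (dissociation constants in nM).
ABT199 = DrugSpec("ABT-199", kd_bcl2=0.01, kd_bclxl=48.0, kd_mcl1=444.0)

#: A ligand so weak it never occupies a target; used for drug-free runs.
NO_DRUG = DrugSpec("none", kd_bcl2=1e12, kd_bclxl=1e12, kd_mcl1=1e12, dose=0.0)


@dataclass(frozen=True)
class StressInput:
    """Composition of the BH3-only bolus delivered at t = 0.

    The total dose is split between a direct activator (BIM/PUMA-like,
    engages BAX/BAK and all three anti-apoptotics) and an
    MCL-1-selective sensitizer (NOXA-like).  The two fractions must sum
    to one.
    """

    total_dose: float
    activator_fraction: float = 0.8
    mcl1_sensitizer_fraction: float = 0.2

    def __post_init__(self) -> None:
        t = float(self.total_dose)
        if not (math.isfinite(t) and t >= 0):
            raise ValidationError(f"total_dose must be finite and >= 0, got {t!r}")
        object.__setattr__(self, "total_dose", t)
        for field in ("activator_fraction", "mcl1_sensitizer_fraction"):
            v = float(getattr(self, field))
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{field} must lie in [0, 1], got {v!r}")
            object.__setattr__(self, field, v)
        if abs(self.activator_fraction + self.mcl1_sensitizer_fraction - 1.0) > 1e-9:
            raise ValidationError("activator and sensitizer fractions must sum to 1")

    @classmethod
    def for_profile(cls, total_dose: float, profile: ProteinProfile,
                    activator_fraction: float = 0.8) -> "StressInput":
        """Stress composition respecting the sample's p53 status.

        p53-deficient samples cannot induce the NOXA/PUMA sensitizer arm,
        so the entire dose is delivered as activator.
        """
        if profile.p53_functional:
            return cls(total_dose, activator_fraction, 1.0 - activator_fraction)
        return cls(total_dose, 1.0, 0.0)

    @property
    def activator_dose(self) -> float:
        return self.total_dose * self.activator_fraction

    @property
    def sensitizer_dose(self) -> float:
        return self.total_dose * self.mcl1_sensitizer_fraction


# ---------------------------------------------------------------------------
# Reference PDX profiles.
#
# The BCL-2 levels of the two colorectal PDX archetypes are fixed at their
# measured absolute concentrations (5772 nM for CRC0076, 1980 nM for
# CRC0344).  The remaining four proteins were not published as numbers;
# the values below are the package's documented archetype defaults
# (BCL-2-high / lower-BCL-xL vs BCL-xL-high / lower-BCL-2, effector loads
# in the range reported for CRC tissue) and can be overridden from a
# profile CSV transcribed from a supplementary table.
# ---------------------------------------------------------------------------

CRC0076 = ProteinProfile(
    "CRC0076", bak=1000.0, bax=1800.0, bcl2=5772.0, bclxl=600.0, mcl1=700.0)
CRC0344 = ProteinProfile(
    "CRC0344", bak=1500.0, bax=1500.0, bcl2=1980.0, bclxl=1800.0, mcl1=600.0)


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValidationError(f"cannot interpret {x!r} as a boolean p53 status")


def read_profiles_csv(path) -> list[ProteinProfile]:
    """Read sample profiles from the canonical CSV layout.

    Columns: ``sample_id,bak_nM,bax_nM,bcl2_nM,bclxl_nM,mcl1_nM,p53_functional``.
    """
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"profile CSV is missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(ProteinProfile(
            sample_id=str(row["sample_id"]),
            bak=row["bak_nM"], bax=row["bax_nM"], bcl2=row["bcl2_nM"],
            bclxl=row["bclxl_nM"], mcl1=row["mcl1_nM"],
            p53_functional=_parse_bool(row["p53_functional"]),
        ))
    return out


def write_profiles_csv(profiles, path) -> None:
    rows = [{
        "sample_id": p.sample_id, "bak_nM": p.bak, "bax_nM": p.bax,
        "bcl2_nM": p.bcl2, "bclxl_nM": p.bclxl, "mcl1_nM": p.mcl1,
        "p53_functional": p.p53_functional,
    } for p in profiles]
    pd.DataFrame(rows, columns=PROFILE_CSV_COLUMNS).to_csv(path, index=False)
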