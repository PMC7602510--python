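"""Absolute protein quantification from quantitative Western blots.

Densitometry readings are background-subtracted, normalised to the
in-lane loading control, and converted to absolute nM concentrations by
reference to a standard cell line (conventionally HeLa) whose absolute
BCL-2 family protein levels were determined with recombinant protein
ladders.  The conversion is a simple ratio::

    conc = (sample_normalised / standard_normalised) * standard_absolute_nM

so it is invariant to global gain changes and linear in net band
intensity.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd
import yaml

from .profiles import PROTEINS, ProteinProfile, ValidationError

#: Proteins a blot may report; PUMA/BIM are reportable extras, not model inputs.
BLOT_PROTEINS = ("bak", "bax", "bcl2", "bclxl", "mcl1", "puma", "bim")

_ALIAS = {
    "bak": "bak", "bax": "bax", "bcl-2": "bcl2", "bcl2": "bcl2",
    "bcl-xl": "bclxl", "bclxl": "bclxl", "mcl-1": "mcl1", "mcl1": "mcl1",
    "puma": "puma", "bim": "bim",
}

DENSITOMETRY_CSV_COLUMNS = [
    "sample_id", "protein", "band_intensity", "band_background",
    "loading_intensity", "loading_background",
]


def canonical_protein(name: str) -> str:
    key = str(name).strip().lower()
    if key not in _ALIAS:
        raise ValidationError(f"unknown protein name {name!r}")
    return _ALIAS[key]


@dataclass(frozen=True)
class BlotMeasurement:
    """One densitometry reading: band and loading-control intensities (a.u.)."""

    sample_id: str
    protein: str
    band_intensity: float
    band_background: float
    loading_intensity: float
    loading_background: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "protein", canonical_protein(self.protein))
        for name in ("band_intensity", "band_background",
                     "loading_intensity", "loading_background"):
            v = float(getattr(self, name))
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")
            object.__setattr__(self, name, v)
        if self.band_background > self.band_intensity:
            warnings.warn(
                f"{self.sample_id}/{self.protein}: band background exceeds "
                "band intensity; net intensity clamped to 0", stacklevel=2)
        if self.loading_intensity - self.loading_background <= 0:
            raise ValidationError(
                f"{self.sample_id}/{self.protein}: loading net intensity "
                "must be > 0")


@dataclass(frozen=True)
class StandardProfile:
    """Standard cell line: absolute nM level and normalised densitometry
    value per protein."""

    standard_id: str
    absolute_nM: dict
    normalised: dict

    def __post_init__(self) -> None:
        abs_ = {canonical_protein(k): float(v)
                for k, v in self.absolute_nM.items()}
        norm = {canonical_protein(k): float(v)
                for k, v in self.normalised.items()}
        for label, d in (("absolute_nM", abs_), ("normalised", norm)):
            for k, v in d.items():
                if not (math.isfinite(v) and v > 0):
                    raise ValidationError(
                        f"standard {label}[{k}] must be > 0, got {v!r}")
        object.__setattr__(self, "absolute_nM", abs_)
        object.__setattr__(self, "normalised", norm)


def normalize_band(m: BlotMeasurement) -> float:
    """Net band intensity over net loading intensity (dimensionless).

    Negative net band intensities are clamped to 0 (with a warning at
    construction time).
    """
    net_band = max(m.band_intensity - m.band_background, 0.0)
    net_loading = m.loading_intensity - m.loading_background
    return net_band / net_loading


def to_absolute_profile(measurements, standard: StandardProfile, *,
                        sample_id: str | None = None,
                        p53_functional: bool = True):
    """Convert one sample's blot measurements to a :class:`ProteinProfile`.

    Replicate lanes of the same protein are averaged after
    normalisation.  PUMA/BIM measurements are returned as a separate
    extras dict rather than entering the five-protein profile.

    Returns ``(profile, extras_nM)``.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValidationError("no measurements supplied")
    sids = {m.sample_id for m in measurements}
    if sample_id is None:
        if len(sids) != 1:
            raise ValidationError(
                f"measurements span multiple samples {sorted(sids)}; "
                "pass sample_id explicitly")
        sample_id = next(iter(sids))

    by_protein: dict[str, list[float]] = {}
    for m in measurements:
        by_protein.setdefault(m.protein, []).append(normalize_band(m))

    concentrations: dict[str, float] = {}
    for protein, values in by_protein.items():
        mean_norm = sum(values) / len(values)
        if protein not in standard.normalised or \
           protein not in standard.absolute_nM:
            raise ValidationError(
                f"standard {standard.standard_id!r} lacks values for "
                f"{protein!r}")
        concentrations[protein] = (mean_norm / standard.normalised[protein]
                                   * standard.absolute_nM[protein])

    missing = [p for p in PROTEINS if p not in concentrations]
    if missing:
        raise ValidationError(
            f"sample {sample_id!r} is missing measurements for: {missing}")
    extras = {p: c for p, c in concentrations.items() if p not in PROTEINS}
    profile = ProteinProfile(
        sample_id=sample_id,
        **{p: concentrations[p] for p in PROTEINS},
        p53_functional=p53_functional)
    return profile, extras


def read_densitometry_csv(path) -> list[BlotMeasurement]:
    df = pd.read_csv(path)
    missing = [c for c in DENSITOMETRY_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"densitometry CSV is missing columns: {missing}")
    return [BlotMeasurement(
        sample_id=str(r["sample_id"]), protein=r["protein"],
        band_intensity=r["band_intensity"],
        band_background=r["band_background"],
        loading_intensity=r["loading_intensity"],
        loading_background=r["loading_background"],
    ) for _, r in df.iterrows()]


def load_standard_yaml(path) -> StandardProfile:
    """Standards YAML: ``standard_id`` plus per-protein ``absolute_nM``
    and ``normalised`` mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    unknown = set(raw) - {"standard_id", "absolute_nM", "normalised"}
    if unknown:
        raise ValidationError(f"unknown standards keys: {sorted(unknown)}")
    return StandardProfile(raw["standard_id"], raw["absolute_nM"],
                           raw["normalised"])


def quantify_samples(measurements, standard: StandardProfile, *,
                     p53_status: dict | None = None) -> list[ProteinProfile]:
    """Quantify every sample present in a densitometry table.

    ``p53_status`` optionally maps sample_id -> bool (default True).
    """
    p53_status = p53_status or {}
    by_sample: dict[str, list[BlotMeasurement]] = {}
    for m in measurements:
        by_sample.setdefault(m.sample_id, []).append(m)
    profiles = []
    for sid in sorted(by_sample):
        profile, _ = to_absolute_profile(
            by_sample[sid], standard,
            p53_functional=p53_status.get(sid, True))
        profiles.append(profile)
    return profiles
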