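"""Protein-chemistry bookkeeping for rapeseed protein isolation.

Covers the explicit formulas used around the extraction workflow:

* protein extraction yield from Kjeldahl protein contents
  (m1 = m0*mp/100, m3 = m2*P/100, yield = 100*m3/m1);
* Bradford soluble-protein concentration from A595 with the BSA
  calibration factor (default 1.9899);
* Folin-Ciocalteu total phenolic content as gallic-acid equivalents
  (mg GAE/100 g) from a user-supplied linear calibration curve;
* amino-acid profile summaries (EAA/NEAA/TAA sums and ratios, WHO
  essential-amino-acid threshold flags) on the 16-analyte acid-hydrolysis
  panel (no Trp/Cys);
* the TCA-soluble protein gain used as the in vitro digestibility index.

The module ships the measured amino-acid profiles of the five rapeseed
protein isolates (Pdp, Pe, Pus, Pdp-us, Popt) as a packaged CSV fixture.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "protein_mass_in_feed",
    "protein_mass_in_isolate",
    "extraction_yield",
    "protein_yield",
    "YieldResult",
    "BradfordReading",
    "bradford_concentration",
    "FolinCalibration",
    "tpc_gae",
    "AminoAcidProfile",
    "AASummary",
    "aa_summary",
    "digestibility_gain",
    "load_reference_profiles",
    "EAA",
    "NEAA",
    "BRADFORD_FACTOR",
    "WHO_LYS_THRESHOLD",
]

#: BSA calibration factor of the Bradford assay (mg/mL per absorbance unit)
BRADFORD_FACTOR = 1.9899
#: WHO adult minimum for lysine, g per 100 g protein
WHO_LYS_THRESHOLD = 4.5

#: essential amino acids of the acid-hydrolysis panel
EAA = ("Thr", "Val", "Met", "Ile", "Leu", "Phe", "Lys", "His")
#: non-essential amino acids of the panel
NEAA = ("Asp", "Ser", "Glu", "Gly", "Ala", "Tyr", "Arg", "Pro")


def _check_fraction(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"{name} must be a percentage in [0, 100], got {value}")
    return value


def _check_mass(name: str, value: float) -> float:
    value = float(value)
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")
    return value


def protein_mass_in_feed(m0: float, mp: float) -> float:
    """Protein mass (g) in ``m0`` g of cake with ``mp`` % protein: m0*mp/100."""
    return _check_mass("m0", m0) * _check_fraction("mp", mp) / 100.0


def protein_mass_in_isolate(m2: float, p: float) -> float:
    """Protein mass (g) in ``m2`` g of dried isolate with ``p`` % protein."""
    return _check_mass("m2", m2) * _check_fraction("p", p) / 100.0


def extraction_yield(m1: float, m3: float) -> float:
    """Extraction yield (%) = 100 * m3 / m1, with m1 the protein in the feed."""
    m1, m3 = _check_mass("m1", m1), _check_mass("m3", m3)
    if m1 == 0:
        raise ValueError("feed protein mass m1 must be positive")
    return 100.0 * m3 / m1


@dataclass(frozen=True)
class YieldResult:
    m1: float          # protein in the feed, g
    m3: float          # protein in the isolate, g
    yield_pct: float


def protein_yield(m0: float, mp: float, m2: float, p: float) -> YieldResult:
    """Chain the three yield formulas from raw masses and protein contents."""
    m1 = protein_mass_in_feed(m0, mp)
    m3 = protein_mass_in_isolate(m2, p)
    if m3 > m2:
        raise ValueError("isolate protein mass cannot exceed isolate mass")
    return YieldResult(m1=m1, m3=m3, yield_pct=extraction_yield(m1, m3))


@dataclass(frozen=True)
class BradfordReading:
    abs595: float
    dilution: float = 1.0
    volume: float = 1.0       # aliquot volume, mL
    factor: float = BRADFORD_FACTOR

    def __post_init__(self) -> None:
        if self.abs595 < 0:
            raise ValueError("absorbance must be non-negative")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.volume <= 0:
            raise ValueError("aliquot volume must be positive")


def bradford_concentration(reading: BradfordReading) -> float:
    """Soluble protein, mg/mL: Abs * factor * dilution / V."""
    return reading.abs595 * reading.factor * reading.dilution / reading.volume


@dataclass(frozen=True)
class FolinCalibration:
    """Linear gallic-acid calibration Abs = slope*conc + intercept.

    ``slope`` in absorbance per (mg GA/mL), fitted on the 0-1 mg/mL range;
    ``extract_volume`` (mL) and ``sample_mass`` (g) describe the extraction.
    """

    slope: float
    intercept: float = 0.0
    extract_volume: float = 1.0
    sample_mass: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if self.extract_volume <= 0 or self.sample_mass <= 0:
            raise ValueError("extract_volume and sample_mass must be positive")


def tpc_gae(absorbance: float, calib: FolinCalibration, dilution: float = 1.0) -> float:
    """Total phenolic content, mg GAE per 100 g sample.

    conc (mg GA/mL) = (Abs - intercept)/slope;
    TPC = conc * dilution * extract_volume / sample_mass * 100.
    """
    if absorbance < calib.intercept:
        raise ValueError(
            f"absorbance {absorbance} below calibration intercept {calib.intercept}: "
            "negative concentration"
        )
    conc = (absorbance - calib.intercept) / calib.slope
    return conc * dilution * calib.extract_volume / calib.sample_mass * 100.0


@dataclass(frozen=True)
class AminoAcidProfile:
    """Per-analyte values, g amino acid per 100 g protein, for one isolate.

    The 16-analyte set (8 EAA + 8 NEAA) is fixed; Trp and Cys are destroyed
    by acid hydrolysis and are not part of the panel.
    """

    values: dict[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        missing = [a for a in EAA + NEAA if a not in self.values]
        extra = [a for a in self.values if a not in EAA + NEAA]
        if missing or extra:
            raise ValueError(
                f"profile must contain exactly the 16 panel analytes; "
                f"missing {missing}, unexpected {extra}"
            )
        for a, v in self.values.items():
            if v < 0:
                raise ValueError(f"{a} value must be non-negative, got {v}")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class AASummary:
    eaa_sum: float
    neaa_sum: float
    taa_sum: float
    eaa_over_neaa_pct: float       # unrounded
    eaa_over_taa_pct: float        # unrounded
    who_flags: dict[str, bool]     # per-EAA pass/fail against threshold table
    label: str = ""

    @property
    def eaa_over_neaa_printed(self) -> int:
        """Ratio as reported: nearest whole percent, half away from zero."""
        return _round_half_away(self.eaa_over_neaa_pct)

    @property
    def eaa_over_taa_printed(self) -> int:
        return _round_half_away(self.eaa_over_taa_pct)


def aa_summary(
    profile: AminoAcidProfile, who_thresholds: dict[str, float] | None = None
) -> AASummary:
    """EAA/NEAA/TAA sums, their ratios, and WHO threshold flags.

    ``who_thresholds`` maps essential amino acids to minimum g/100 g protein
    requirements; the default carries only the lysine 4.5 threshold.
    """
    if who_thresholds is None:
        who_thresholds = {"Lys": WHO_LYS_THRESHOLD}
    unknown = [a for a in who_thresholds if a not in EAA]
    if unknown:
        raise ValueError(f"thresholds for non-EAA analytes: {unknown}")
    eaa_sum = sum(profile.values[a] for a in EAA)
    neaa_sum = sum(profile.values[a] for a in NEAA)
    taa_sum = eaa_sum + neaa_sum
    if neaa_sum == 0 or taa_sum == 0:
        raise ValueError("EAA/NEAA and EAA/TAA ratios undefined: zero denominator")
    flags = {a: profile.values[a] >= t for a, t in who_thresholds.items()}
    return AASummary(
        eaa_sum=eaa_sum,
        neaa_sum=neaa_sum,
        taa_sum=taa_sum,
        eaa_over_neaa_pct=100.0 * eaa_sum / neaa_sum,
        eaa_over_taa_pct=100.0 * eaa_sum / taa_sum,
        who_flags=flags,
        label=profile.label,
    )


def digestibility_gain(control_mg_ml: float, digested_mg_ml: float) -> float:
    """TCA-soluble protein gain (mg/mL): digested minus undigested control.

    A negative gain (digestion *reduced* TCA-soluble protein) is physically
    suspect and triggers a warning, but is returned as-is.
    """
    control = _check_mass("control_mg_ml", control_mg_ml)
    digested = _check_mass("digested_mg_ml", digested_mg_ml)
    gain = digested - control
    if gain < 0:
        warnings.warn(
            f"negative digestibility gain ({gain:.3g} mg/mL): TCA-soluble protein "
            "decreased after digestion",
            stacklevel=2,
        )
    return gain


def load_reference_profiles() -> dict[str, AminoAcidProfile]:
    """Measured amino-acid profiles of the five isolates, from the packaged CSV.

    Keys are the isolate labels (Pdp, Pe, Pus, Pdp-us, Popt); tabulated
    values are means over replicate determinations (sds not propagated).
    """
    with resources.files("dephenolize.data").joinpath(
        "rapeseed_aa_profiles.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    profiles = {}
    for label in df.columns[2:]:
        values = dict(zip(df["amino_acid"], df[label].astype(float)))
        profiles[label] = AminoAcidProfile(values=values, label=label)
    return profiles
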