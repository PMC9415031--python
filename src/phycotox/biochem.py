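"""Biochemical endpoint calculators.

Four families of wet-lab readouts are reduced to comparable endpoint values:

* antioxidant enzyme activities from kinetic absorbance traces
  (ascorbate peroxidase APX, catalase CAT, glutathione reductase GR by the
  Beer-Lambert slope method; superoxide dismutase SOD by inhibition of
  pyrogallol autoxidation against a no-extract blank);
* lipid peroxidation as malondialdehyde (MDA) from TBARS endpoint
  absorbances at 532 nm with 600 nm turbidity correction;
* membrane saturation state of a fatty-acid (FA) profile: double bond index
  (DBI) plus SFA/UFA and PUFA/SFA ratios;
* the cellular energy allocation (CEA) budget: energy available Ea from
  carbohydrate, protein and lipid masses via their combustion energies, and
  energy consumption Ec from electron-transport-system (ETS) activity via
  INT-formazan stoichiometry and the oxyenthalpic equivalent of oxygen.

Every calculator is homogeneous of degree 1 in its raw signal, so dilution
and normalization factors enter multiplicatively and are kept explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

__all__ = [
    "KineticTrace",
    "EnzymeActivity",
    "PeroxidationResult",
    "FattyAcidProfile",
    "EnergyBudget",
    "EXTINCTION_MM_CM",
    "slope_activity",
    "sod_activity",
    "mda_concentration",
    "dbi",
    "cellular_energy_allocation",
]

#: default molar extinction coefficients, mM⁻¹·cm⁻¹, at the assay wavelength
#: (APX: ascorbate at 290 nm; CAT: H2O2 at 240 nm, 39.4 M⁻¹cm⁻¹;
#:  GR: NADPH at 340 nm)
EXTINCTION_MM_CM = {"APX": 2.8, "CAT": 0.0394, "GR": 6.22}

#: expected slope sign per assay ("decrease": substrate consumed)
ASSAY_DIRECTION = {"APX": "decrease", "CAT": "decrease", "GR": "decrease",
                   "SOD": "increase", "ETS": "increase"}

#: combustion energies, mJ per mg of fraction
COMBUSTION_MJ_PER_MG = {"carbohydrate": 17_500.0, "protein": 24_000.0,
                        "lipid": 39_500.0}

#: oxyenthalpic equivalent: 480 kJ per mol O2 = 480 mJ per µmol O2
OXYENTHALPIC_MJ_PER_UMOL_O2 = 480.0

#: per-unsaturation-class weights of the double bond index
DBI_WEIGHTS = {
    # as-printed convention: monoenes weighted 2
    "paper": {"saturated": 0, "monoene": 2, "diene": 2, "triene": 3,
              "tetraene": 4, "pentaene": 5},
    # classical convention: weight = number of double bonds
    "classic": {"saturated": 0, "monoene": 1, "diene": 2, "triene": 3,
                "tetraene": 4, "pentaene": 5},
}

_CLASS_BY_BONDS = {0: "saturated", 1: "monoene", 2: "diene", 3: "triene",
                   4: "tetraene", 5: "pentaene"}


@dataclass
class KineticTrace:
    """Absorbance vs time for one enzymatic assay well."""

    sample_id: str
    treatment: str
    assay: str  # APX | SOD | CAT | GR | ETS
    times_s: np.ndarray
    absorbance: np.ndarray
    path_length_cm: float = 1.0
    protein_mg: float | None = None
    mass_fw_g: float | None = None
    volume_ml: float = 1.0
    dilution: float = 1.0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.assay not in ("APX", "SOD", "CAT", "GR", "ETS"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.times_s.size < 4:
            raise ValueError("kinetic trace needs at least 4 time points")
        if not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class EnzymeActivity:
    sample_id: str
    treatment: str
    assay: str
    activity: float
    units: str
    slope_au_per_min: float
    r_squared: float
    inhibition_percent: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class PeroxidationResult:
    sample_id: str
    treatment: str
    mda_um: float  # µM in the reaction extract
    mda_nmol_per_g_fw: float


@dataclass
class FattyAcidProfile:
    """Percent composition by FA species with double-bond counts.

    ``percents`` and ``double_bonds`` are keyed by species name (e.g. "16:0",
    "18:3").  Percentages must sum to 100 within ``sum_tolerance``.
    """

    sample_id: str
    treatment: str
    percents: dict[str, float]
    double_bonds: dict[str, int]
    total_mg_per_g_fw: float | None = None
    sum_tolerance: float = 1.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.percents.values()):
            raise ValueError("percentages must be non-negative")
        total = sum(self.percents.values())
        if abs(total - 100.0) > self.sum_tolerance:
            raise ValueError(f"percentages sum to {total:.3f}, not 100")

    def unsaturation_class(self, species: str) -> str:
        if species not in self.double_bonds:
            raise ValueError(f"no double-bond count for species {species!r}")
        nb = self.double_bonds[species]
        if nb not in _CLASS_BY_BONDS:
            raise ValueError(f"species {species!r}: unsupported bond count {nb}")
        return _CLASS_BY_BONDS[nb]


@dataclass
class EnergyBudget:
    sample_id: str
    treatment: str
    carbohydrate_mg_per_mg_fw: float
    protein_mg_per_mg_fw: float
    lipid_mg_per_mg_fw: float
    Ea_mj_per_mg_fw: float
    formazan_umol_per_mg_fw: float
    Ec_mj_per_mg_fw: float
    cea: float


def _regression_window(times: np.ndarray, absorbance: np.ndarray,
                       min_r2: float) -> tuple[int, int]:
    """Longest contiguous window (>= 4 points) with R² >= min_r2.

    Ties broken toward the earliest window; falls back to the full trace when
    no window qualifies.
    """
    n = times.size
    for length in range(n, 3, -1):
        for start in range(0, n - length + 1):
            sl = slice(start, start + length)
            res = sstats.linregress(times[sl], absorbance[sl])
            if res.rvalue ** 2 >= min_r2:
                return (start, start + length)
    return (0, n)


def slope_activity(
    trace: KineticTrace,
    epsilon_mm_cm: float | None = None,
    direction: str | None = None,
    linear_window: str = "full",
    min_r2: float = 0.95,
) -> EnzymeActivity:
    """Beer-Lambert enzyme activity from the slope of a kinetic trace.

    activity (µmol·min⁻¹·mg protein⁻¹) =
        |dA/dt| [min⁻¹] / (ε [mM⁻¹cm⁻¹] · path [cm]) · volume [mL]
        · dilution / protein [mg]

    ``direction`` declares the expected sign of the slope ("decrease" for
    substrate-consuming assays); a slope of the opposite sign yields zero
    activity with a warning.  ``linear_window='auto'`` restricts the
    regression to the longest early window with R² >= 0.98 (deterministic
    earliest-window tie-break); default is the full trace.
    """
    if trace.assay not in ("APX", "CAT", "GR"):
        raise ValueError("slope_activity handles APX/CAT/GR; use sod_activity for SOD")
    epsilon = epsilon_mm_cm if epsilon_mm_cm is not None else EXTINCTION_MM_CM[trace.assay]
    direction = direction or ASSAY_DIRECTION[trace.assay]
    t, a = trace.times_s, trace.absorbance
    flags: list[str] = []

    if linear_window == "auto":
        i0, i1 = _regression_window(t, a, 0.98)
        t, a = t[i0:i1], a[i0:i1]

    res = sstats.linregress(t, a)
    slope_per_min = res.slope * 60.0
    r2 = res.rvalue ** 2 if np.isfinite(res.rvalue) else 1.0
    if r2 < min_r2:
        flags.append(f"low linearity (R^2 = {r2:.3f})")

    wrong_sign = (direction == "decrease" and slope_per_min > 0) or (
        direction == "increase" and slope_per_min < 0
    )
    if wrong_sign and abs(slope_per_min) > 0:
        warnings.warn(
            f"{trace.assay} slope sign opposite to expected {direction}; activity 0",
            stacklevel=2,
        )
        flags.append("wrong slope sign")
        activity = 0.0
    else:
        rate_mm_per_min = abs(slope_per_min) / (epsilon * trace.path_length_cm)
        umol_per_min = rate_mm_per_min * trace.volume_ml * trace.dilution
        protein = trace.protein_mg if trace.protein_mg is not None else 1.0
        activity = umol_per_min / protein

    return EnzymeActivity(
        sample_id=trace.sample_id,
        treatment=trace.treatment,
        assay=trace.assay,
        activity=activity,
        units="umol min^-1 mg protein^-1",
        slope_au_per_min=slope_per_min,
        r_squared=r2,
        flags=flags,
    )


def sod_activity(sample_trace: KineticTrace, blank_trace: KineticTrace) -> EnzymeActivity:
    """Superoxide dismutase activity by inhibition of pyrogallol autoxidation.

    inhibition% = 100·(1 − slope_sample/slope_blank); one unit corresponds to
    50 % inhibition, normalized per mg protein.  The blank is the no-extract
    autoxidation trace over the same interval and must have a positive slope.
    """
    s_res = sstats.linregress(sample_trace.times_s, sample_trace.absorbance)
    b_res = sstats.linregress(blank_trace.times_s, blank_trace.absorbance)
    if b_res.slope <= 0:
        raise ValueError("invalid autoxidation blank: non-positive slope")
    inhibition = 100.0 * (1.0 - s_res.slope / b_res.slope)
    protein = sample_trace.protein_mg if sample_trace.protein_mg is not None else 1.0
    units_value = inhibition / 50.0 / protein
    return EnzymeActivity(
        sample_id=sample_trace.sample_id,
        treatment=sample_trace.treatment,
        assay="SOD",
        activity=units_value,
        units="U mg protein^-1 (1 U = 50% inhibition)",
        slope_au_per_min=s_res.slope * 60.0,
        r_squared=s_res.rvalue ** 2 if np.isfinite(s_res.rvalue) else 1.0,
        inhibition_percent=inhibition,
    )


def mda_concentration(
    a532: float,
    a600: float,
    dilution: float = 1.0,
    mass_fw_g: float = 1.0,
    extract_volume_ml: float = 1.0,
    path_length_cm: float = 1.0,
    sample_id: str = "",
    treatment: str = "",
) -> PeroxidationResult:
    """Malondialdehyde from TBARS endpoint absorbances (ε = 155 mM⁻¹·cm⁻¹).

    Concentration = (A532 − A600) / (155 mM⁻¹cm⁻¹ · path), scaled by the
    dilution factor; also expressed per g fresh weight via the extract volume.
    A negative corrected absorbance yields zero with a warning.
    """
    if not (np.isfinite(a532) and np.isfinite(a600)):
        raise ValueError("absorbances must be finite")
    corrected = a532 - a600
    if corrected < 0:
        warnings.warn("A532 < A600: corrected absorbance negative, MDA set to 0",
                      stacklevel=2)
        corrected = 0.0
    mda_mm = corrected / (155.0 * path_length_cm) * dilution
    mda_um = mda_mm * 1000.0
    nmol_per_g = mda_um * extract_volume_ml / mass_fw_g
    return PeroxidationResult(sample_id, treatment, mda_um, nmol_per_g)


def dbi(profile: FattyAcidProfile, convention: str = "paper") -> dict[str, float]:
    """Double bond index plus SFA/UFA and PUFA/SFA saturation ratios.

    DBI = Σ weight(class)·%class / 100, with class weights per the chosen
    convention (``'paper'``: monoenes weighted 2; ``'classic'``: weight = the
    double-bond count).  Raises for any species with nonzero percentage and no
    class assignment.
    """
    if convention not in DBI_WEIGHTS:
        raise ValueError("convention must be 'paper' or 'classic'")
    weights = DBI_WEIGHTS[convention]
    class_pct = {c: 0.0 for c in weights}
    for species, pct in profile.percents.items():
        if pct == 0:
            continue
        class_pct[profile.unsaturation_class(species)] += pct

    index = sum(weights[c] * p for c, p in class_pct.items()) / 100.0
    sfa = class_pct["saturated"]
    ufa = sum(p for c, p in class_pct.items() if c != "saturated")
    pufa = ufa - class_pct["monoene"]
    return {
        "dbi": index,
        "sfa_percent": sfa,
        "ufa_percent": ufa,
        "sfa_ufa": sfa / ufa if ufa > 0 else float("nan"),
        "pufa_sfa": pufa / sfa if sfa > 0 else float("nan"),
    }


def cellular_energy_allocation(
    carbohydrate_mg_per_mg_fw: float,
    protein_mg_per_mg_fw: float,
    lipid_mg_per_mg_fw: float,
    formazan_umol_per_mg_fw: float,
    sample_id: str = "",
    treatment: str = "",
) -> EnergyBudget:
    """Cellular energy allocation budget.

    Ea (mJ·mg⁻¹ FW) converts the three reserve fractions with their combustion
    energies (17 500 / 24 000 / 39 500 mJ·mg⁻¹ for carbohydrate / protein /
    lipid).  Ec converts ETS activity: 2 µmol INT-formazan per µmol O2
    consumed, 480 mJ per µmol O2.  CEA = Ea/Ec, NaN when Ec = 0.
    """
    if min(carbohydrate_mg_per_mg_fw, protein_mg_per_mg_fw, lipid_mg_per_mg_fw) < 0:
        raise ValueError("fraction masses must be non-negative")
    if formazan_umol_per_mg_fw < 0:
        raise ValueError("formazan rate must be non-negative")
    ea = (
        COMBUSTION_MJ_PER_MG["carbohydrate"] * carbohydrate_mg_per_mg_fw
        + COMBUSTION_MJ_PER_MG["protein"] * protein_mg_per_mg_fw
        + COMBUSTION_MJ_PER_MG["lipid"] * lipid_mg_per_mg_fw
    )
    o2_umol = formazan_umol_per_mg_fw / 2.0
    ec = o2_umol * OXYENTHALPIC_MJ_PER_UMOL_O2
    if ec > 0:
        cea = ea / ec
    else:
        warnings.warn("Ec = 0: CEA undefined", stacklevel=2)
        cea = float("nan")
    return EnergyBudget(
        sample_id=sample_id,
        treatment=treatment,
        carbohydrate_mg_per_mg_fw=carbohydrate_mg_per_mg_fw,
        protein_mg_per_mg_fw=protein_mg_per_mg_fw,
        lipid_mg_per_mg_fw=lipid_mg_per_mg_fw,
        Ea_mj_per_mg_fw=ea,
        formazan_umol_per_mg_fw=formazan_umol_per_mg_fw,
        Ec_mj_per_mg_fw=ec,
        cea=cea,
    )
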