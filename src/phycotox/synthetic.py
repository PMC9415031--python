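"""Synthetic six-treatment datasets for every pipeline stage.

The generators emulate a dose-response exposure design with six herbicide
concentrations (0, 10, 50, 100, 250, 500 µg·L⁻¹) and the replicate structure
of the corresponding assays (18 fluorescence transients, 30 emission spectra,
3 pigment/enzyme/fatty-acid extracts, 5 energy-budget replicates per
treatment).  Treatment effects are encoded as editable per-treatment
multiplier profiles on the generating parameters (trapping efficiency, V_J,
red/far-red ratio, pigment concentrations, enzyme slopes, fatty-acid class
percentages, energy fractions); the defaults reproduce the qualitative
dose-response pattern the package targets — strongest photochemical
suppression at 250 µg·L⁻¹ with partial recovery at 500 µg·L⁻¹ — with
group-mean anchors for the red/far-red ratio and the pigment pool taken from
published treatment means for this design.

Every generator draws from a dedicated, named random substream of the root
seed (no shared state across cohorts) and returns the raw objects together
with a ground-truth table, enabling parameter-recovery tests in all other
modules.  Noise is multiplicative Gaussian (signals are positive) truncated
away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biochem import KineticTrace
from .lif import EmissionSpectrum
from .ojip import FluorescenceTransient
from .pigments import DEFAULT_TEMPLATES, AbsorbanceSpectrum, PigmentTemplate, template_matrix
from .rlc import RapidLightCurve, platt_model

__all__ = [
    "SimulationConfig",
    "null_config",
    "generate_ojip",
    "connectivity_transient",
    "generate_lif",
    "generate_pigment_spectra",
    "generate_rlc",
    "generate_assays",
]

TREATMENTS = ("0", "10", "50", "100", "250", "500")

# named substreams: every cohort is independent of the others
_STREAMS = {"ojip": 1, "lif": 2, "pigments": 3, "rlc": 4, "enzymes": 5,
            "mda": 6, "fatty_acids": 7, "energy": 8}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def _jitter(rng: np.random.Generator, value, cv: float, floor_frac: float = 0.05):
    """Multiplicative Gaussian noise truncated away from zero."""
    if cv <= 0:
        return value
    v = np.asarray(value, dtype=float)
    out = v * (1.0 + cv * rng.standard_normal(v.shape))
    return np.maximum(out, floor_frac * np.abs(v))


def _profile(values_by_treatment: dict[str, float]) -> dict[str, float]:
    missing = [t for t in TREATMENTS if t not in values_by_treatment]
    if missing:
        raise ValueError(f"effect profile missing treatments {missing}")
    return dict(values_by_treatment)


def _flat(value: float = 1.0) -> dict[str, float]:
    return {t: value for t in TREATMENTS}


@dataclass
class OjipSimParams:
    """Closed-form O-J-I-P rise: F(t) = F0 + FV·Σ wᵢ·(1 − exp(−(t−t_O)/τᵢ)),
    three phases with time constants ~0.3 / 7 / 80 ms; phase weights are
    solved so that the relative variable fluorescence hits the configured V_J
    and V_I at the J and I step times.  PSII connectivity distorts the fast
    phase through the connected-units hyperbola with curvature C."""

    f0: float = 500.0
    phi_p0: float = 0.80
    vj: float = 0.50
    vi: float = 0.80
    taus_us: tuple[float, float, float] = (300.0, 7000.0, 80000.0)
    connectivity: float = 0.25  # hyperbola curvature C (p_G = C/(1+C))
    t_start_us: float = 10.0
    t_end_us: float = 300_000.0
    n_points: int = 70
    t_o_us: float = 50.0
    t_j_us: float = 2000.0
    t_i_us: float = 30000.0
    # dose-response effect profiles (multipliers on the base parameters)
    amplitude_effect: dict[str, float] = field(
        default_factory=lambda: _profile(
            {"0": 1.00, "10": 1.00, "50": 1.00, "100": 0.97, "250": 0.85, "500": 0.90}))
    phi_p0_effect: dict[str, float] = field(
        default_factory=lambda: _profile(
            {"0": 1.00, "10": 0.99, "50": 0.95, "100": 0.96, "250": 0.88, "500": 0.92}))
    vj_effect: dict[str, float] = field(
        default_factory=lambda: _profile(
            {"0": 1.00, "10": 1.02, "50": 1.10, "100": 1.08, "250": 1.22, "500": 1.12}))
    vi_effect: dict[str, float] = field(
        default_factory=lambda: _profile(
            {"0": 1.00, "10": 1.00, "50": 1.03, "100": 1.02, "250": 1.06, "500": 1.04}))
    connectivity_by_treatment: dict[str, float] = field(
        default_factory=lambda: _profile(
            {"0": 0.25, "10": 0.28, "50": 0.45, "100": 0.45, "250": 0.65, "500": 0.65}))
    # between-sample biological variability (CV) and per-point measurement noise
    cv_amplitude: float = 0.05
    cv_phi_p0: float = 0.02
    cv_vj: float = 0.03
    cv_point: float = 0.005


@dataclass
class LifSimParams:
    """Two-Gaussian chlorophyll emission (red ~681 nm, far-red ~731 nm).

    Group means of the red/far-red ratio and of the red peak position follow
    the published treatment means for this exposure design; between-sample
    scatter matches the published dispersion (ratio CV ≈ 0.45)."""

    grid_nm: tuple[float, float, float] = (640.0, 800.0, 0.5)  # start, stop, step
    red_amplitude: float = 1000.0
    # narrow red band: with red/far-red ratios of 40-100 a broad red band
    # would bury the far-red maximum under its own tail at the 700 nm window
    # edge; 5.5 nm keeps the far-red peak detectable across the ratio range
    red_sigma_nm: float = 5.5
    farred_sigma_nm: float = 10.0
    farred_center_nm: float = 731.3
    red_center_by_treatment: dict[str, float] = field(
        default_factory=lambda: _profile(
            {"0": 681.06, "10": 680.97, "50": 680.88,
             "100": 681.16, "250": 681.09, "500": 681.32}))
    ratio_by_treatment: dict[str, float] = field(
        default_factory=lambda: _profile(
            {"0": 41.12, "10": 37.25, "50": 103.63,
             "100": 73.45, "250": 53.78, "500": 70.80}))
    cv_ratio: float = 0.45
    sd_red_center_nm: float = 0.28
    sd_farred_center_nm: float = 8.8
    cv_point: float = 0.01


#: per-treatment pigment content targets, µg·g⁻¹ FW (columns follow TREATMENTS)
PIGMENT_TARGETS_UG_PER_G = {
    "chlorophyll_a": (56.03, 15.80, 18.00, 14.40, 32.23, 55.53),
    "chlorophyll_b": (38.90, 10.31, 12.05, 8.64, 20.27, 31.20),
    "pheophytin_a": (2.12, 0.25, 0.46, 0.10, 0.96, 0.42),
    "pheophytin_b": (0.0, 0.0, 0.0, 0.06, 0.0, 0.90),
    "lutein": (3.02, 0.59, 0.82, 0.70, 2.52, 4.04),
    "beta_carotene": (1.32, 0.40, 0.53, 0.52, 0.57, 2.06),
    "zeaxanthin": (1.40, 0.55, 0.56, 0.55, 0.60, 2.43),
    "antheraxanthin": (0.0, 0.13, 0.49, 0.76, 0.72, 3.81),
    "violaxanthin": (0.80, 0.44, 0.34, 0.13, 0.03, 0.18),
    "auroxanthin": (4.98, 1.93, 1.81, 1.59, 1.52, 6.11),
}


@dataclass
class PigmentSimParams:
    mass_fw_g: float = 0.1
    extract_volume_ml: float = 1.0
    path_length_cm: float = 1.0
    targets: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(PIGMENT_TARGETS_UG_PER_G))
    cv_concentration: float = 0.20
    noise_sd_frac_of_max: float = 0.005
    baseline_const: float = 0.01
    baseline_slope: float = 0.005  # over the full scan width


@dataclass
class RlcSimParams:
    irradiances: tuple[float, ...] = (10, 20, 50, 100, 200, 300, 500, 800, 1200)
    alpha: float = 0.30
    ps: float = 60.0
    beta: float = 0.010
    beta_effect: dict[str, float] = field(
        default_factory=lambda: _profile(
            {"0": 1.0, "10": 1.0, "50": 1.0, "100": 0.4, "250": 1.0, "500": 1.0}))
    cv_alpha: float = 0.05
    noise_cv_of_max: float = 0.02


@dataclass
class AssaySimParams:
    """Kinetic traces and endpoint tables for the biochemical layer."""

    trace_times_s: tuple[float, float, float] = (0.0, 300.0, 15.0)  # start, stop, step
    protein_mg: float = 0.5
    # base slopes, a.u.·min⁻¹ (sign per assay direction)
    apx_slope: float = -0.0060
    cat_slope: float = -0.0020
    gr_slope: float = -0.0030
    sod_blank_slope: float = 0.0040
    sod_inhibition_pct: float = 40.0
    apx_effect: dict[str, float] = field(
        default_factory=lambda: _profile(
            {"0": 1.0, "10": 1.1, "50": 1.8, "100": 1.8, "250": 1.9, "500": 2.0}))
    sod_effect: dict[str, float] = field(
        default_factory=lambda: _profile(
            {"0": 1.0, "10": 1.0, "50": 1.0, "100": 1.0, "250": 0.6, "500": 1.0}))
    cat_effect: dict[str, float] = field(default_factory=_flat)
    gr_effect: dict[str, float] = field(default_factory=_flat)
    cv_slope: float = 0.10
    trace_noise_sd_au: float = 0.002
    trace_start_au: float = 1.0

    # TBARS endpoints
    mda_a532: float = 0.40
    mda_a600: float = 0.02
    mda_effect: dict[str, float] = field(default_factory=_flat)
    cv_mda: float = 0.15
    mda_mass_fw_g: float = 0.1
    mda_extract_volume_ml: float = 1.0

    # fatty-acid profile (percent composition; double-bond counts alongside)
    fa_base_percent: dict[str, float] = field(default_factory=lambda: {
        "14:0": 2.0, "16:0": 38.0, "16:1n-9": 2.0, "16:1n-7": 3.0, "16:4": 5.0,
        "18:0": 2.0, "18:1": 12.0, "18:2": 8.0, "18:3": 18.0, "18:4": 10.0})
    fa_double_bonds: dict[str, int] = field(default_factory=lambda: {
        "14:0": 0, "16:0": 0, "16:1n-9": 1, "16:1n-7": 1, "16:4": 4,
        "18:0": 0, "18:1": 1, "18:2": 2, "18:3": 3, "18:4": 4})
    fa_effects: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "250": {"16:1n-9": 1.5, "18:1": 1.3, "18:0": 0.6, "18:2": 0.7},
        "500": {"18:0": 0.6}})
    fa_total_mg_per_g_fw: float = 2.5
    fa_total_effect: dict[str, float] = field(
        default_factory=lambda: _profile(
            {"0": 1.0, "10": 0.97, "50": 0.95, "100": 0.93, "250": 0.90, "500": 0.92}))
    cv_fa: float = 0.08

    # energy budget (per mg FW)
    carbohydrate_mg_per_mg_fw: float = 0.030
    protein_mg_per_mg_fw_energy: float = 0.012
    lipid_mg_per_mg_fw: float = 0.002
    formazan_umol_per_mg_fw: float = 1.2
    carb_effect: dict[str, float] = field(
        default_factory=lambda: _profile(
            {"0": 1.0, "10": 1.0, "50": 1.0, "100": 0.75, "250": 1.0, "500": 1.0}))
    prot_effect: dict[str, float] = field(
        default_factory=lambda: _profile(
            {"0": 1.0, "10": 1.0, "50": 1.0, "100": 0.80, "250": 1.0, "500": 1.5}))
    lip_effect: dict[str, float] = field(
        default_factory=lambda: _profile(
            {"0": 1.0, "10": 1.0, "50": 1.0, "100": 0.80, "250": 1.0, "500": 1.0}))
    formazan_effect: dict[str, float] = field(default_factory=_flat)
    cv_energy: float = 0.10


@dataclass
class SimulationConfig:
    """Replicate counts follow the assay design the package emulates:
    18 transients, 30 emission spectra, 3 pigment/enzyme/FA extracts,
    3 peroxidation replicates and 5 energy replicates per treatment."""

    treatments: tuple[str, ...] = TREATMENTS
    seed: int = 0
    n_ojip: int = 18
    n_lif: int = 30
    n_pigment: int = 3
    n_enzyme: int = 3
    n_fa: int = 3
    n_mda: int = 3
    n_energy: int = 5
    n_rlc: int = 18
    ojip: OjipSimParams = field(default_factory=OjipSimParams)
    lif: LifSimParams = field(default_factory=LifSimParams)
    pigments: PigmentSimParams = field(default_factory=PigmentSimParams)
    rlc: RlcSimParams = field(default_factory=RlcSimParams)
    assays: AssaySimParams = field(default_factory=AssaySimParams)

    def __post_init__(self) -> None:
        for name in ("n_ojip", "n_lif", "n_pigment", "n_enzyme", "n_fa",
                     "n_mda", "n_energy", "n_rlc"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")


def null_config(seed: int = 0, **kwargs) -> SimulationConfig:
    """A configuration with every treatment effect set to 1 (no dose response);
    noise levels unchanged.  Useful for type-I-error and null-pipeline checks."""
    cfg = SimulationConfig(seed=seed, **kwargs)
    o = cfg.ojip
    cfg.ojip = replace(o, amplitude_effect=_flat(), phi_p0_effect=_flat(),
                       vj_effect=_flat(), vi_effect=_flat(),
                       connectivity_by_treatment=_flat(o.connectivity))
    lf = cfg.lif
    cfg.lif = replace(lf, ratio_by_treatment=_flat(lf.ratio_by_treatment["0"]),
                      red_center_by_treatment=_flat(lf.red_center_by_treatment["0"]))
    pg = cfg.pigments
    cfg.pigments = replace(pg, targets={k: (v[0],) * 6 for k, v in pg.targets.items()})
    cfg.rlc = replace(cfg.rlc, beta_effect=_flat())
    a = cfg.assays
    cfg.assays = replace(a, apx_effect=_flat(), sod_effect=_flat(),
                         cat_effect=_flat(), gr_effect=_flat(), mda_effect=_flat(),
                         fa_effects={}, fa_total_effect=_flat(),
                         carb_effect=_flat(), prot_effect=_flat(),
                         lip_effect=_flat(), formazan_effect=_flat())
    return cfg


# ---------------------------------------------------------------------------
# OJIP transients
# ---------------------------------------------------------------------------

def _connected(g: np.ndarray, C: float) -> np.ndarray:
    return (1.0 + C) * g / (1.0 + C * g)


def _ojip_curve(t_us: np.ndarray, f0: float, fv: float, weights: np.ndarray,
                taus_us: tuple[float, float, float], C: float,
                t_o_us: float) -> np.ndarray:
    ts = np.maximum(t_us - t_o_us, 0.0)
    phases = [1.0 - np.exp(-ts / tau) for tau in taus_us]
    phases[0] = _connected(phases[0], C)
    v = sum(w * p for w, p in zip(weights, phases))
    return f0 + fv * v


def _solve_weights(vj: float, vi: float, taus_us, C: float,
                   t_o_us: float, t_j_us: float, t_i_us: float) -> np.ndarray:
    """Phase weights such that relative variable fluorescence equals V_J at the
    J step and V_I at the I step, and sums to 1 at saturation."""
    def phase_vals(t):
        ts = t - t_o_us
        g = [1.0 - np.exp(-ts / tau) for tau in taus_us]
        g[0] = float(_connected(np.array([g[0]]), C)[0])
        return g

    A = np.array([phase_vals(t_j_us), phase_vals(t_i_us), [1.0, 1.0, 1.0]])
    w = np.linalg.solve(A, np.array([vj, vi, 1.0]))
    if np.any(w <= 0):
        raise ValueError(
            f"phase weights {w} not all positive for VJ={vj:.3f}, VI={vi:.3f}; "
            "targets incompatible with the three-phase model")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("phase weights do not sum to 1")
    return w


def generate_ojip(config: SimulationConfig) -> tuple[list[FluorescenceTransient], pd.DataFrame]:
    """Simulate a cohort of fluorescence induction transients.

    Returns the transients (log-spaced sampling, 10 µs – 300 ms) and a
    ground-truth table with, per sample, the generating F0, FM, phiP0, V_J,
    V_I, M0, the normalized complementary area S_M (dense numerical
    integration of the closed-form curve over the measurement protocol) and
    the connectivity C and p_G.
    """
    p = config.ojip
    rng = _rng(config.seed, "ojip")
    # log-spaced protocol that, like real instruments, samples the nominal
    # step times exactly
    t_grid = np.unique(np.concatenate([
        np.geomspace(p.t_start_us, p.t_end_us, p.n_points),
        [p.t_o_us, 300.0, p.t_j_us, p.t_i_us],
    ]))
    t_dense = np.geomspace(p.t_o_us, p.t_end_us, 20001)

    transients: list[FluorescenceTransient] = []
    rows = []
    for trt in config.treatments:
        C = p.connectivity_by_treatment[trt]
        for i in range(config.n_ojip):
            f0 = float(_jitter(rng, p.f0 * p.amplitude_effect[trt], p.cv_amplitude))
            phi = float(np.clip(
                _jitter(rng, p.phi_p0 * p.phi_p0_effect[trt], p.cv_phi_p0), 0.05, 0.95))
            vj = float(np.clip(_jitter(rng, p.vj * p.vj_effect[trt], p.cv_vj), 0.05, 0.90))
            vi = float(np.clip(p.vi * p.vi_effect[trt], vj + 0.05, 0.97))
            fv = f0 * phi / (1.0 - phi)
            w = _solve_weights(vj, vi, p.taus_us, C, p.t_o_us, p.t_j_us, p.t_i_us)

            clean = _ojip_curve(t_grid, f0, fv, w, p.taus_us, C, p.t_o_us)
            noisy = np.asarray(_jitter(rng, clean, p.cv_point))
            sid = f"ojip-{trt}-{i:02d}"
            transients.append(FluorescenceTransient(sid, trt, t_grid.copy(), noisy))

            dense = _ojip_curve(t_dense, f0, fv, w, p.taus_us, C, p.t_o_us)
            fm_protocol = float(dense[-1])
            area_ms = float(np.trapezoid(fm_protocol - dense, t_dense)) / 1000.0
            vk = (float(_ojip_curve(np.array([300.0]), f0, fv, w, p.taus_us, C,
                                    p.t_o_us)[0]) - f0) / fv
            rows.append({
                "sample_id": sid, "treatment": trt, "F0": f0, "FM": f0 + fv,
                "FM_protocol": fm_protocol, "phiP0": phi, "VJ": vj, "VI": vi,
                "VK": vk, "M0": 4.0 * vk, "SM": area_ms / fv,
                "C": C, "pG": C / (1.0 + C),
            })
    return transients, pd.DataFrame(rows)


def connectivity_transient(
    C: float,
    f0: float = 500.0,
    fj: float = 1500.0,
    fm: float = 2500.0,
    tau_oj_us: float = 300.0,
    t_o_us: float = 50.0,
    t_j_us: float = 2000.0,
    n_points: int = 120,
    sample_id: str = "conn",
    treatment: str = "0",
) -> FluorescenceTransient:
    """A transient whose O-J rise is exactly the connected-units hyperbola.

    The fast rise follows W = (1+C)·E/(1+C·E) with E = 1 − exp(−(t−t_O)/τ);
    the slower I and P phases start at the J step, leaving the O-J window an
    uncontaminated realization of the connectivity model — the generate-then-
    fit oracle for ``estimate_grouping``.
    """
    t = np.unique(np.concatenate([
        np.geomspace(10.0, 300_000.0, n_points),
        [t_o_us, 300.0, t_j_us, 30_000.0],
    ]))
    ts = np.maximum(t - t_o_us, 0.0)
    E = 1.0 - np.exp(-ts / tau_oj_us)
    W = _connected(E, C) if C > 0 else E
    slow = np.maximum(t - t_j_us, 0.0)
    rise_slow = 0.6 * (1.0 - np.exp(-slow / 7000.0)) + 0.4 * (1.0 - np.exp(-slow / 60000.0))
    F = f0 + (fj - f0) * W + (fm - fj) * rise_slow
    return FluorescenceTransient(sample_id, treatment, t, F)


# ---------------------------------------------------------------------------
# LIF emission spectra
# ---------------------------------------------------------------------------

def generate_lif(config: SimulationConfig) -> tuple[list[EmissionSpectrum], pd.DataFrame]:
    """Simulate two-band chlorophyll emission spectra with treatment-dependent
    red/far-red ratio means; stores per-sample true peak positions and ratio."""
    p = config.lif
    rng = _rng(config.seed, "lif")
    start, stop, step = p.grid_nm
    wl = np.arange(start, stop + step / 2, step)

    spectra: list[EmissionSpectrum] = []
    rows = []
    for trt in config.treatments:
        for i in range(config.n_lif):
            ratio = float(_jitter(rng, p.ratio_by_treatment[trt], p.cv_ratio,
                                  floor_frac=0.1))
            red_c = p.red_center_by_treatment[trt] + p.sd_red_center_nm * rng.standard_normal()
            far_c = float(np.clip(
                p.farred_center_nm + p.sd_farred_center_nm * rng.standard_normal(),
                705.0, 755.0))
            a_red = p.red_amplitude
            a_far = a_red / ratio
            clean = (
                a_red * np.exp(-0.5 * ((wl - red_c) / p.red_sigma_nm) ** 2)
                + a_far * np.exp(-0.5 * ((wl - far_c) / p.farred_sigma_nm) ** 2)
            )
            noisy = np.asarray(_jitter(rng, clean, p.cv_point, floor_frac=0.0))
            noisy = np.maximum(noisy, 0.0)
            sid = f"lif-{trt}-{i:02d}"
            spectra.append(EmissionSpectrum(sid, trt, wl.copy(), noisy))
            rows.append({"sample_id": sid, "treatment": trt, "ratio": ratio,
                         "lambda_red": red_c, "lambda_farred": far_c})
    return spectra, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pigment absorbance spectra
# ---------------------------------------------------------------------------

def generate_pigment_spectra(
    config: SimulationConfig,
    templates: list[PigmentTemplate] | None = None,
) -> tuple[list[AbsorbanceSpectrum], pd.DataFrame]:
    """Mix the shipped pigment templates at per-treatment concentration
    targets, add affine baseline drift and measurement noise; the truth table
    stores each sample's realized pigment concentrations (µg·g⁻¹ FW)."""
    templates = templates if templates is not None else DEFAULT_TEMPLATES
    p = config.pigments
    rng = _rng(config.seed, "pigments")
    wl = np.arange(350.0, 750.0 + 0.25, 0.5)
    T = template_matrix(templates, wl)
    names = [t.name for t in templates]
    for n in p.targets:
        if n not in names:
            raise ValueError(f"target pigment {n!r} not in template registry")

    spectra: list[AbsorbanceSpectrum] = []
    rows = []
    width = wl.max() - wl.min()
    for it, trt in enumerate(config.treatments):
        for i in range(config.n_pigment):
            conc = {}
            for n in names:
                target = p.targets.get(n, (0.0,) * len(config.treatments))[it]
                conc[n] = float(_jitter(rng, target, p.cv_concentration)) if target > 0 else 0.0
            # unit chain: tissue µg/g FW -> extract µg/mL -> peak absorbance a.u.
            coefs = np.array([
                conc[n] * p.mass_fw_g / p.extract_volume_ml
                * tpl.specific_coefficient * p.path_length_cm
                for n, tpl in zip(names, templates)
            ])
            clean = T @ coefs
            b0 = p.baseline_const * rng.uniform(0.0, 1.0)
            b1 = p.baseline_slope * rng.uniform(-1.0, 1.0)
            drift = b0 + b1 * (wl - wl.mean()) / width
            noise = p.noise_sd_frac_of_max * clean.max() * rng.standard_normal(wl.shape)
            sid = f"pig-{trt}-{i:02d}"
            spectra.append(AbsorbanceSpectrum(
                sid, trt, wl.copy(), clean + drift + noise,
                mass_fw_g=p.mass_fw_g, extract_volume_ml=p.extract_volume_ml,
                path_length_cm=p.path_length_cm))
            row = {"sample_id": sid, "treatment": trt}
            row.update(conc)
            rows.append(row)
    return spectra, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rapid light curves
# ---------------------------------------------------------------------------

def generate_rlc(config: SimulationConfig) -> tuple[list[RapidLightCurve], pd.DataFrame]:
    """Simulate rapid light curves from the exponential-saturation model with
    photoinhibition; truth stores each sample's α, Ps, β."""
    p = config.rlc
    rng = _rng(config.seed, "rlc")
    E = np.asarray(p.irradiances, dtype=float)
    curves: list[RapidLightCurve] = []
    rows = []
    for trt in config.treatments:
        for i in range(config.n_rlc):
            alpha = float(_jitter(rng, p.alpha, p.cv_alpha))
            beta = p.beta * p.beta_effect[trt]
            clean = platt_model(E, alpha, p.ps, beta)
            noise = p.noise_cv_of_max * clean.max() * rng.standard_normal(E.shape)
            sid = f"rlc-{trt}-{i:02d}"
            curves.append(RapidLightCurve(sid, trt, E.copy(),
                                          np.maximum(clean + noise, 0.0)))
            rows.append({"sample_id": sid, "treatment": trt,
                         "alpha": alpha, "Ps": p.ps, "beta": beta})
    return curves, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# kinetic and endpoint assays
# ---------------------------------------------------------------------------

def generate_assays(config: SimulationConfig) -> dict[str, object]:
    """Simulate the biochemical layer: kinetic traces for APX/CAT/GR, paired
    SOD sample+blank traces, TBARS endpoints, fatty-acid percentage tables and
    energy-budget inputs.

    Returns a dict with keys ``kinetic`` (list of KineticTrace),
    ``sod_pairs`` (list of (sample, blank) KineticTrace pairs), ``mda``
    (DataFrame), ``fatty_acids`` (DataFrame), ``energy`` (DataFrame) and a
    ``truth`` dict of ground-truth tables per endpoint.
    """
    a = config.assays
    start, stop, step = a.trace_times_s
    times = np.arange(start, stop + step / 2, step)

    kinetic: list[KineticTrace] = []
    sod_pairs: list[tuple[KineticTrace, KineticTrace]] = []
    truth_kinetic = []
    rng = _rng(config.seed, "enzymes")
    for trt in config.treatments:
        for i in range(config.n_enzyme):
            for assay, base, eff in (
                ("APX", a.apx_slope, a.apx_effect),
                ("CAT", a.cat_slope, a.cat_effect),
                ("GR", a.gr_slope, a.gr_effect),
            ):
                slope = float(_jitter(rng, base * eff[trt], a.cv_slope,
                                      floor_frac=0.0))
                trace_clean = a.trace_start_au + slope / 60.0 * times
                noise = a.trace_noise_sd_au * rng.standard_normal(times.shape)
                sid = f"{assay.lower()}-{trt}-{i:02d}"
                kinetic.append(KineticTrace(
                    sid, trt, assay, times.copy(), trace_clean + noise,
                    protein_mg=a.protein_mg))
                truth_kinetic.append({"sample_id": sid, "treatment": trt,
                                      "assay": assay,
                                      "slope_au_per_min": slope})
            # SOD: paired sample + blank autoxidation traces
            inhib = float(np.clip(
                _jitter(rng, a.sod_inhibition_pct * a.sod_effect[trt], a.cv_slope),
                0.0, 100.0))
            blank_slope = a.sod_blank_slope
            samp_slope = blank_slope * (1.0 - inhib / 100.0)
            sid = f"sod-{trt}-{i:02d}"
            samp = KineticTrace(
                sid, trt, "SOD", times.copy(),
                0.05 + samp_slope * times + a.trace_noise_sd_au * rng.standard_normal(times.shape),
                protein_mg=a.protein_mg)
            blank = KineticTrace(
                f"{sid}-blank", trt, "SOD", times.copy(),
                0.05 + blank_slope * times + a.trace_noise_sd_au * rng.standard_normal(times.shape))
            sod_pairs.append((samp, blank))
            truth_kinetic.append({"sample_id": sid, "treatment": trt,
                                  "assay": "SOD", "inhibition_pct": inhib})

    rng = _rng(config.seed, "mda")
    mda_rows = []
    for trt in config.treatments:
        for i in range(config.n_mda):
            corrected = float(_jitter(rng, (a.mda_a532 - a.mda_a600) * a.mda_effect[trt],
                                      a.cv_mda))
            mda_rows.append({
                "sample_id": f"mda-{trt}-{i:02d}", "treatment": trt,
                "a532": corrected + a.mda_a600, "a600": a.mda_a600,
                "mass_fw_g": a.mda_mass_fw_g,
                "extract_volume_ml": a.mda_extract_volume_ml,
                "true_mda_um": corrected / 155.0 * 1000.0,
            })
    mda = pd.DataFrame(mda_rows)

    rng = _rng(config.seed, "fatty_acids")
    fa_rows = []
    for trt in config.treatments:
        mults = a.fa_effects.get(trt, {})
        for i in range(config.n_fa):
            raw = {
                sp: max(float(_jitter(rng, pct * mults.get(sp, 1.0), a.cv_fa)), 0.0)
                for sp, pct in a.fa_base_percent.items()
            }
            total = sum(raw.values())
            total_fa = float(_jitter(rng, a.fa_total_mg_per_g_fw * a.fa_total_effect[trt],
                                     a.cv_fa))
            for sp, v in raw.items():
                fa_rows.append({
                    "sample_id": f"fa-{trt}-{i:02d}", "treatment": trt,
                    "species": sp, "percent": 100.0 * v / total,
                    "double_bonds": a.fa_double_bonds[sp],
                    "total_mg_per_g_fw": total_fa,
                })
    fatty = pd.DataFrame(fa_rows)

    rng = _rng(config.seed, "energy")
    energy_rows = []
    for trt in config.treatments:
        for i in range(config.n_energy):
            energy_rows.append({
                "sample_id": f"en-{trt}-{i:02d}", "treatment": trt,
                "carbohydrate_mg_per_mg_fw": float(_jitter(
                    rng, a.carbohydrate_mg_per_mg_fw * a.carb_effect[trt], a.cv_energy)),
                "protein_mg_per_mg_fw": float(_jitter(
                    rng, a.protein_mg_per_mg_fw_energy * a.prot_effect[trt], a.cv_energy)),
                "lipid_mg_per_mg_fw": float(_jitter(
                    rng, a.lipid_mg_per_mg_fw * a.lip_effect[trt], a.cv_energy)),
                "formazan_umol_per_mg_fw": float(_jitter(
                    rng, a.formazan_umol_per_mg_fw * a.formazan_effect[trt], a.cv_energy)),
            })
    energy = pd.DataFrame(energy_rows)

    return {
        "kinetic": kinetic,
        "sod_pairs": sod_pairs,
        "mda": mda,
        "fatty_acids": fatty,
        "energy": energy,
        "truth": {"kinetic": pd.DataFrame(truth_kinetic)},
    }
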