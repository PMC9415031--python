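"""Laser-induced fluorescence (LIF) spectral features.

Chlorophyll emission of green tissue shows a red band near 680 nm and a
far-red band near 735 nm.  The red/far-red ratio tracks chlorophyll content
and reabsorption and shifts under stress, which makes it a convenient
non-invasive stress indicator.  This module reduces an emission spectrum to
the two band maxima (wavelength and intensity, with sub-grid parabolic peak
refinement) and their ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["EmissionSpectrum", "LifConfig", "LifFeatures", "extract_lif_features"]


@dataclass(frozen=True)
class LifConfig:
    """Feature-extraction settings.

    ``ratio_mode='peak'`` (default) forms the ratio from the detected band
    maxima; ``'fixed'`` uses the intensities interpolated at
    ``fixed_red_nm``/``fixed_farred_nm`` (classical F680/F735).
    ``smooth_points`` > 1 applies a centered moving average before peak
    detection (off by default for reproducibility).
    """

    red_window_nm: tuple[float, float] = (650.0, 700.0)
    farred_window_nm: tuple[float, float] = (700.0, 760.0)
    ratio_mode: str = "peak"  # "peak" | "fixed"
    fixed_red_nm: float = 680.0
    fixed_farred_nm: float = 735.0
    smooth_points: int = 1

    def __post_init__(self) -> None:
        if self.ratio_mode not in ("peak", "fixed"):
            raise ValueError("ratio_mode must be 'peak' or 'fixed'")
        if self.smooth_points < 1 or self.smooth_points % 2 == 0:
            raise ValueError("smooth_points must be an odd integer >= 1")


@dataclass
class EmissionSpectrum:
    sample_id: str
    treatment: str
    wavelengths_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths_nm.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must have equal length")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.wavelengths_nm[0] > 650.0 or self.wavelengths_nm[-1] < 760.0:
            raise ValueError("spectrum must cover at least 650-760 nm")
        if np.any(self.intensities < 0):
            raise ValueError("negative intensities (baseline not handled upstream)")


@dataclass
class LifFeatures:
    sample_id: str
    treatment: str
    lambda_red: float
    lambda_farred: float
    f_red: float
    f_farred: float
    ratio: float
    red_flagged: bool = False
    farred_flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "treatment": self.treatment,
            "lambda_red": self.lambda_red,
            "lambda_farred": self.lambda_farred,
            "f_red": self.f_red,
            "f_farred": self.f_farred,
            "ratio": self.ratio,
            "red_flagged": self.red_flagged,
            "farred_flagged": self.farred_flagged,
        }


def _moving_average(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y
    kernel = np.ones(width) / width
    pad = width // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")


def _window_peak(
    wl: np.ndarray, y: np.ndarray, lo: float, hi: float
) -> tuple[float, float, bool]:
    """Argmax within [lo, hi] with three-point parabolic refinement.

    Returns (peak wavelength, peak intensity, flagged).  The peak is flagged
    when it sits on the window boundary (no interior maximum) or the window is
    flat, in which case no refinement is applied.
    """
    sel = np.flatnonzero((wl >= lo) & (wl <= hi))
    ws, ys = wl[sel], y[sel]
    i = int(np.argmax(ys))
    flagged = False
    if ys.max() == ys.min():
        return float(ws[i]), float(ys[i]), True
    if i == 0 or i == len(ws) - 1:
        return float(ws[i]), float(ys[i]), True
    # parabola through the three points around the maximum (uniform grid)
    y0, y1, y2 = ys[i - 1], ys[i], ys[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(ws[i]), float(ys[i]), flagged
    delta = 0.5 * (y0 - y2) / denom
    step = ws[i + 1] - ws[i]
    lam = float(ws[i] + delta * step)
    peak = float(y1 - 0.25 * (y0 - y2) * delta)
    return lam, peak, flagged


def extract_lif_features(
    spectrum: EmissionSpectrum, config: LifConfig | None = None
) -> LifFeatures:
    """Reduce an emission spectrum to red / far-red peak features and ratio.

    A boundary-pinned or flat window is flagged (``red_flagged`` /
    ``farred_flagged``) and the ratio is still computed from the boundary
    values, with a warning.
    """
    config = config or LifConfig()
    wl = spectrum.wavelengths_nm
    y = _moving_average(spectrum.intensities, config.smooth_points)

    lam_r, f_r, flag_r = _window_peak(wl, y, *config.red_window_nm)
    lam_fr, f_fr, flag_fr = _window_peak(wl, y, *config.farred_window_nm)
    if flag_fr:
        warnings.warn(
            "far-red maximum at window boundary or flat; ratio uses boundary value",
            stacklevel=2,
        )

    if config.ratio_mode == "fixed":
        f_num = float(np.interp(config.fixed_red_nm, wl, y))
        f_den = float(np.interp(config.fixed_farred_nm, wl, y))
    else:
        f_num, f_den = f_r, f_fr
    ratio = f_num / f_den if f_den > 0 else float("nan")

    return LifFeatures(
        sample_id=spectrum.sample_id,
        treatment=spectrum.treatment,
        lambda_red=lam_r,
        lambda_farred=lam_fr,
        f_red=f_r,
        f_farred=f_fr,
        ratio=ratio,
        red_flagged=flag_r,
        farred_flagged=flag_fr,
    )
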