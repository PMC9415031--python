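"""CSV serialization of the raw and derived data objects.

All raw inputs are long-format UTF-8 CSVs with comma separators:

* transients:   ``sample_id,treatment,time_us,fluorescence``
* emission:     ``sample_id,treatment,wavelength_nm,intensity``
* absorbance:   ``sample_id,treatment,wavelength_nm,absorbance`` plus a
  per-sample metadata table ``sample_id,mass_fw_g,extract_volume_ml,path_length_cm``
* rapid light curves: ``sample_id,treatment,par,retr``
* kinetic assays: ``sample_id,treatment,assay,time_s,absorbance``
* fatty acids:  ``sample_id,treatment,species,percent,double_bonds``

Derived results are written as wide CSVs, one row per sample; NaN (the
undefined-marker for degenerate quantities) serializes as an empty cell.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .biochem import KineticTrace
from .lif import EmissionSpectrum
from .ojip import FluorescenceTransient
from .pigments import AbsorbanceSpectrum
from .rlc import RapidLightCurve

__all__ = [
    "transients_to_frame", "frame_to_transients",
    "spectra_to_frame", "frame_to_spectra",
    "absorbance_to_frames", "frames_to_absorbance",
    "rlc_to_frame", "frame_to_rlc",
    "kinetic_to_frame", "frame_to_kinetic",
    "write_csv", "read_csv",
]

_FLOAT_FMT = "%.10g"  # fixed formatting keeps reruns byte-identical


def write_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"sample_id": str, "treatment": str})


def transients_to_frame(transients: list[FluorescenceTransient]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": np.repeat([t.sample_id for t in transients],
                                   [t.times_us.size for t in transients]),
            "treatment": np.repeat([t.treatment for t in transients],
                                   [t.times_us.size for t in transients]),
            "time_us": np.concatenate([t.times_us for t in transients]),
            "fluorescence": np.concatenate([t.values for t in transients]),
        }
    )


def frame_to_transients(frame: pd.DataFrame) -> list[FluorescenceTransient]:
    out = []
    for sid, grp in frame.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_us")
        out.append(FluorescenceTransient(
            str(sid), str(grp["treatment"].iloc[0]),
            grp["time_us"].to_numpy(float), grp["fluorescence"].to_numpy(float)))
    return out


def spectra_to_frame(spectra: list[EmissionSpectrum]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": np.repeat([s.sample_id for s in spectra],
                                   [s.wavelengths_nm.size for s in spectra]),
            "treatment": np.repeat([s.treatment for s in spectra],
                                   [s.wavelengths_nm.size for s in spectra]),
            "wavelength_nm": np.concatenate([s.wavelengths_nm for s in spectra]),
            "intensity": np.concatenate([s.intensities for s in spectra]),
        }
    )


def frame_to_spectra(frame: pd.DataFrame) -> list[EmissionSpectrum]:
    out = []
    for sid, grp in frame.groupby("sample_id", sort=False):
        grp = grp.sort_values("wavelength_nm")
        out.append(EmissionSpectrum(
            str(sid), str(grp["treatment"].iloc[0]),
            grp["wavelength_nm"].to_numpy(float), grp["intensity"].to_numpy(float)))
    return out


def absorbance_to_frames(
    spectra: list[AbsorbanceSpectrum],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format scan table plus the per-sample extraction metadata table."""
    scans = pd.DataFrame(
        {
            "sample_id": np.repeat([s.sample_id for s in spectra],
                                   [s.wavelengths_nm.size for s in spectra]),
            "treatment": np.repeat([s.treatment for s in spectra],
                                   [s.wavelengths_nm.size for s in spectra]),
            "wavelength_nm": np.concatenate([s.wavelengths_nm for s in spectra]),
            "absorbance": np.concatenate([s.absorbance for s in spectra]),
        }
    )
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in spectra],
            "mass_fw_g": [s.mass_fw_g for s in spectra],
            "extract_volume_ml": [s.extract_volume_ml for s in spectra],
            "path_length_cm": [s.path_length_cm for s in spectra],
        }
    )
    return scans, meta


def frames_to_absorbance(
    scans: pd.DataFrame, meta: pd.DataFrame
) -> list[AbsorbanceSpectrum]:
    meta = meta.set_index("sample_id")
    out = []
    for sid, grp in scans.groupby("sample_id", sort=False):
        grp = grp.sort_values("wavelength_nm")
        m = meta.loc[str(sid)]
        out.append(AbsorbanceSpectrum(
            str(sid), str(grp["treatment"].iloc[0]),
            grp["wavelength_nm"].to_numpy(float), grp["absorbance"].to_numpy(float),
            mass_fw_g=float(m["mass_fw_g"]),
            extract_volume_ml=float(m["extract_volume_ml"]),
            path_length_cm=float(m["path_length_cm"])))
    return out


def rlc_to_frame(curves: list[RapidLightCurve]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": np.repeat([c.sample_id for c in curves],
                                   [c.irradiances.size for c in curves]),
            "treatment": np.repeat([c.treatment for c in curves],
                                   [c.irradiances.size for c in curves]),
            "par": np.concatenate([c.irradiances for c in curves]),
            "retr": np.concatenate([c.retr for c in curves]),
        }
    )


def frame_to_rlc(frame: pd.DataFrame) -> list[RapidLightCurve]:
    out = []
    for sid, grp in frame.groupby("sample_id", sort=False):
        grp = grp.sort_values("par")
        out.append(RapidLightCurve(
            str(sid), str(grp["treatment"].iloc[0]),
            grp["par"].to_numpy(float), grp["retr"].to_numpy(float)))
    return out


def kinetic_to_frame(traces: list[KineticTrace]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": np.repeat([t.sample_id for t in traces],
                                   [t.times_s.size for t in traces]),
            "treatment": np.repeat([t.treatment for t in traces],
                                   [t.times_s.size for t in traces]),
            "assay": np.repeat([t.assay for t in traces],
                               [t.times_s.size for t in traces]),
            "time_s": np.concatenate([t.times_s for t in traces]),
            "absorbance": np.concatenate([t.absorbance for t in traces]),
        }
    )


def frame_to_kinetic(frame: pd.DataFrame, protein_mg: float | None = None) -> list[KineticTrace]:
    out = []
    for sid, grp in frame.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_s")
        out.append(KineticTrace(
            str(sid), str(grp["treatment"].iloc[0]), str(grp["assay"].iloc[0]),
            grp["time_s"].to_numpy(float), grp["absorbance"].to_numpy(float),
            protein_mg=protein_mg))
    return out
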