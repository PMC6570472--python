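"""End-to-end orchestration: RF frame -> parametric maps -> features.

Per image plane, analysis windows are tiled over the core and margin
ROIs; each window yields the line-fit parameters (MBF/SS/SI), the
form-factor estimates (ASD/AAC) and the spacing estimate (SAS), which are
assembled into parametric maps; attenuation (ACE) is estimated once per
plane from the depth progression of the core window spectra.  Plane
feature vectors are averaged into one vector per patient.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import schema
from .rf_io import PatientRecord, RFFrame, ROISet
from .rf_simulator import Pulse
from .spectral import (estimate_ace, estimate_sas, fit_form_factor,
                       fit_spectral_params, normalized_spectrum,
                       tile_windows)
from .texture import ParametricMap, aggregate_patient, build_map, \
    plane_features

logger = logging.getLogger(__name__)

__all__ = ["extract_plane_maps", "extract_patient_features"]


def extract_plane_maps(frame: RFFrame, rois: ROISet, reference: Pulse,
                       overlap: float = 0.94, window_mm: float = 2.0,
                       nfft: int = 1024,
                       sas_prominence: float = 0.30,
                       ) -> Tuple[Dict[str, ParametricMap],
                                  Dict[str, ParametricMap],
                                  Optional[float]]:
    """Parametric maps for both ROIs and the core attenuation scalar."""
    maps: Dict[str, Dict[str, ParametricMap]] = {}
    ace_value: Optional[float] = None
    for roi_label in ("core", "margin"):
        grid = tile_windows(rois, frame, window_mm=window_mm,
                            overlap=overlap, which=roi_label)
        est = {p: [] for p in schema.MAP_PARAMS}
        spectra = []
        for w in grid.windows:
            spec = normalized_spectrum(w, frame, reference, nfft=nfft)
            spectra.append(spec)
            line = fit_spectral_params(spec)
            ff = fit_form_factor(spec, sound_speed=frame.sound_speed)
            sas = estimate_sas(spec, sound_speed=frame.sound_speed,
                               prominence_threshold=sas_prominence)
            est["MBF"].append(line.mbf)
            est["SS"].append(line.ss)
            est["SI"].append(line.si)
            est["ASD"].append(ff.asd)
            est["AAC"].append(ff.aac)
            est["SAS"].append(sas.sas if sas.present else np.nan)
        maps[roi_label] = {
            p: build_map(est[p], grid, parameter=p, roi_label=roi_label,
                         units=schema.PARAM_UNITS[p])
            for p in schema.MAP_PARAMS}
        if roi_label == "core" and len(spectra) >= 3:
            depths = [s.window_depth_cm for s in spectra]
            if max(depths) - min(depths) >= 1.0:
                ace_value = estimate_ace(spectra).ace
            else:
                logger.info("core depth span %.2f cm too small for ACE",
                            max(depths) - min(depths))
    return maps["core"], maps["margin"], ace_value


def extract_patient_features(record: PatientRecord, reference: Pulse,
                             overlap: float = 0.94,
                             **kwargs) -> pd.Series:
    """One 52-entry feature vector (49 QUS + ER/PR/HER2) per patient."""
    planes = []
    for frame, rois in record.planes:
        core_maps, margin_maps, ace = extract_plane_maps(
            frame, rois, reference, overlap=overlap, **kwargs)
        planes.append(plane_features(core_maps, margin_maps, ace=ace))
    molecular = {"ER": record.er, "PR": record.pr, "HER2": record.her2}
    return aggregate_patient(planes, molecular=molecular)
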