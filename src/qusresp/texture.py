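"""Parametric maps, Haralick texture, core-vs-margin contrast metrics and
per-patient feature aggregation.

A parametric map places one spectral-parameter estimate at each analysis
window centre; cells outside the ROI are absent (NaN) and are excluded
from every statistic.  Texture is computed on core maps only; the margin
contributes mean intensities and the core-to-margin contrast metrics.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import schema
from .spectral import WindowGrid

logger = logging.getLogger(__name__)

__all__ = ["ParametricMap", "GLCMFeatures", "build_map", "glcm_features",
           "cmr_cmcr", "plane_features", "aggregate_patient"]

CMCR_CAP = 1e6


@dataclass
class ParametricMap:
    """Grid of per-window estimates for one parameter over one ROI."""

    parameter: str
    values: np.ndarray          # 2-D, NaN where absent
    roi_label: str = "core"
    units: str = ""

    @property
    def present(self) -> np.ndarray:
        return np.isfinite(self.values)


def build_map(window_estimates: Sequence[float], grid: WindowGrid,
              parameter: str = "", roi_label: str = "core",
              units: str = "") -> ParametricMap:
    """Place window estimates at window-centre grid positions.

    Map resolution equals the window step; grid cells not covered by a
    kept window are absent.
    """
    est = np.asarray(window_estimates, dtype=float)
    if len(est) != len(grid.windows):
        raise ValueError("need exactly one estimate per window")
    if len(est) == 0:
        return ParametricMap(parameter, np.full((0, 0), np.nan),
                             roi_label, units)
    ax = np.array([w.ax_start for w in grid.windows])
    lat = np.array([w.lat_start for w in grid.windows])
    ai = np.round((ax - ax.min()) / grid.ax_step).astype(int)
    lj = np.round((lat - lat.min()) / grid.lat_step).astype(int)
    vals = np.full((ai.max() + 1, lj.max() + 1), np.nan)
    vals[ai, lj] = est
    return ParametricMap(parameter, vals, roi_label, units)


@dataclass
class GLCMFeatures:
    con: float
    cor: float
    ene: float
    hom: float


_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))   # 0, 45, 90, 135 degrees


def _quantize(values: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization over the map's own min-max range.

    Absent cells map to -1.  Quantizing over the map's own range makes the
    texture features invariant to affine rescaling of the values.
    """
    q = np.full(values.shape, -1, dtype=int)
    present = np.isfinite(values)
    vmin = values[present].min()
    vmax = values[present].max()
    scaled = (values[present] - vmin) / (vmax - vmin) * levels
    q[present] = np.minimum(scaled.astype(int), levels - 1)
    return q


def _features_from_cooccurrence(P: np.ndarray) -> GLCMFeatures:
    levels = P.shape[0]
    i = np.arange(levels, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    con = float(np.sum(P * (ii - jj) ** 2))
    ene = float(np.sum(P ** 2))
    hom = float(np.sum(P / (1.0 + np.abs(ii - jj))))
    mu_i = float(np.sum(P * ii))
    mu_j = float(np.sum(P * jj))
    var_i = float(np.sum(P * (ii - mu_i) ** 2))
    var_j = float(np.sum(P * (jj - mu_j) ** 2))
    if var_i <= 0 or var_j <= 0:
        cor = 0.0   # zero-variance convention: bounded, no NaN downstream
    else:
        cor = float(np.sum(P * (ii - mu_i) * (jj - mu_j))
                    / math.sqrt(var_i * var_j))
    return GLCMFeatures(con=con, cor=cor, ene=ene, hom=hom)


def glcm_features(pmap: ParametricMap | np.ndarray,
                  levels: int = 16) -> Optional[GLCMFeatures]:
    """Gray-level co-occurrence texture of a (possibly masked) map.

    Present cells are quantized to ``levels`` equal-width bins over the
    map's min-max; co-occurrence is counted at distance 1 for the four
    principal offsets, symmetrically, skipping pairs that involve an
    absent cell; each offset's normalized matrix yields
    contrast / correlation / energy / homogeneity, and the four offsets
    are averaged.  Fewer than 4 present cells: features are absent
    (returns None).  A constant map follows the single-bin convention
    (CON=0, ENE=1, HOM=1, COR=0).
    """
    values = pmap.values if isinstance(pmap, ParametricMap) else \
        np.asarray(pmap, dtype=float)
    present = np.isfinite(values)
    if present.sum() < 4:
        return None
    vmin = values[present].min()
    vmax = values[present].max()
    if vmax == vmin:
        return GLCMFeatures(con=0.0, cor=0.0, ene=1.0, hom=1.0)
    q = _quantize(values, levels)
    per_offset: List[GLCMFeatures] = []
    for di, dj in _OFFSETS:
        a, b = _shifted_pairs(q, di, dj)
        if len(a) == 0:
            continue
        P = np.zeros((levels, levels))
        np.add.at(P, (a, b), 1.0)
        np.add.at(P, (b, a), 1.0)
        P /= P.sum()
        per_offset.append(_features_from_cooccurrence(P))
    if not per_offset:
        return None
    return GLCMFeatures(
        con=float(np.mean([f.con for f in per_offset])),
        cor=float(np.mean([f.cor for f in per_offset])),
        ene=float(np.mean([f.ene for f in per_offset])),
        hom=float(np.mean([f.hom for f in per_offset])))


def _shifted_pairs(q: np.ndarray, di: int, dj: int):
    """Valid co-occurring level pairs for one offset (absent skipped)."""
    n, m = q.shape
    i0, i1 = max(0, -di), min(n, n - di)
    j0, j1 = max(0, -dj), min(m, m - dj)
    a = q[i0:i1, j0:j1]
    b = q[i0 + di:i1 + di, j0 + dj:j1 + dj]
    ok = (a >= 0) & (b >= 0)
    return a[ok].ravel(), b[ok].ravel()


def cmr_cmcr(core_map: ParametricMap,
             margin_map: ParametricMap) -> Tuple[Optional[float], float]:
    """Core-to-margin ratio and core-to-margin contrast ratio.

    ``cmr = mean(core) / mean(margin)`` (absent when the margin mean is
    zero); ``cmcr = |mean(core) - mean(margin)| / (sd(core) + sd(margin))``
    — a contrast-to-noise-style definition, isolated here so an
    alternative is a one-line change.  Statistics use present cells only;
    the denominator is floored at machine epsilon and the result capped.
    """
    core = core_map.values[core_map.present]
    margin = margin_map.values[margin_map.present]
    if core.size == 0 or margin.size == 0:
        raise ValueError("both maps must contain present cells")
    mc, mm = float(core.mean()), float(margin.mean())
    if mm == 0.0:
        warnings.warn("margin mean is zero; CMR absent", stacklevel=2)
        cmr = None
    else:
        cmr = mc / mm
    sd = float(core.std(ddof=0) + margin.std(ddof=0))
    cmcr = abs(mc - mm) / max(sd, np.finfo(float).eps)
    return cmr, float(min(cmcr, CMCR_CAP))


def plane_features(core_maps: Dict[str, ParametricMap],
                   margin_maps: Dict[str, ParametricMap],
                   ace: Optional[float] = None,
                   levels: int = 16) -> pd.Series:
    """Assemble the 49-entry QUS feature vector for one image plane.

    ``core_maps`` / ``margin_maps`` hold the six mapped parameters
    (MBF, SS, SI, SAS, ASD, AAC); attenuation enters as the single
    core-ROI scalar ``ace``.  Features that cannot be computed on this
    plane are NaN and excluded from patient aggregation.
    """
    out = pd.Series(np.nan, index=schema.qus_feature_names(), dtype=float)
    for p in schema.MAP_PARAMS:
        cm = core_maps.get(p)
        mm = margin_maps.get(p)
        if cm is not None and cm.present.any():
            out[f"{p}_MEAN_CORE"] = float(cm.values[cm.present].mean())
            tex = glcm_features(cm, levels=levels)
            if tex is None:
                logger.info("plane texture absent for %s (too few cells)", p)
            else:
                out[f"{p}_CON"] = tex.con
                out[f"{p}_COR"] = tex.cor
                out[f"{p}_ENE"] = tex.ene
                out[f"{p}_HOM"] = tex.hom
        if mm is not None and mm.present.any():
            out[f"{p}_MEAN_MARGIN"] = float(mm.values[mm.present].mean())
        if (cm is not None and cm.present.any()
                and mm is not None and mm.present.any()):
            cmr, cmcr = cmr_cmcr(cm, mm)
            if cmr is not None:
                out[f"{p}_CMR"] = cmr
            out[f"{p}_CMCR"] = cmcr
    if ace is not None:
        out["ACE_MEAN_CORE"] = float(ace)
    return out


def aggregate_patient(planes: Sequence[pd.Series],
                      molecular: Optional[Dict[str, int]] = None) -> pd.Series:
    """Unweighted mean of per-plane feature vectors for one patient.

    Features absent on some planes are averaged over the planes where
    they are present; a feature absent everywhere stays absent (logged).
    Molecular fields pass through untouched.
    """
    if len(planes) == 0:
        raise ValueError("need at least one plane")
    if not 4 <= len(planes) <= 7:
        warnings.warn(f"{len(planes)} planes outside the usual 4-7 range",
                      stacklevel=2)
    stacked = pd.concat(planes, axis=1)
    agg = stacked.mean(axis=1, skipna=True)
    missing = agg.index[agg.isna()]
    if len(missing):
        logger.info("features absent on all planes: %s", list(missing))
    if molecular is not None:
        for key in schema.MOLECULAR:
            if key in molecular:
                agg[key] = molecular[key]
    return agg
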