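"""Data model for beamformed RF planes, B-mode rendering and dual-ROI masks.

Coordinate convention: axial index 0 is the transducer face; positions are
pixel centres; depth of axial sample ``i`` is ``i * c / (2 * fs)``.  Masks
are boolean grids aligned to the RF sample grid.  The two regions of
interest are the manually contoured tumour core and a surrounding margin
band obtained by Euclidean dilation of the core in physical millimetres
(axial and lateral pixel pitches differ, so dilation in pixels would be
anisotropic).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import shapely
from scipy.ndimage import distance_transform_edt
from scipy.signal import hilbert
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

__all__ = ["RFFrame", "ROISet", "PatientRecord", "envelope_bmode", "build_rois",
           "save_frame", "load_frame", "save_bmode_png"]


@dataclass
class RFFrame:
    """One beamformed RF scan plane (axial x lateral sample grid)."""

    samples: np.ndarray
    fs: float
    line_pitch: float          # m
    sound_speed: float = 1540.0
    centre_frequency: float = 6e6
    plane_index: int = 0
    ground_truth: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D axial x lateral grid")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")
        if self.fs <= 2 * self.centre_frequency:
            raise ValueError(
                f"sampling rate {self.fs:g} Hz violates Nyquist for centre "
                f"frequency {self.centre_frequency:g} Hz")

    @property
    def n_axial(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    @property
    def axial_pitch(self) -> float:
        """Axial sample spacing in metres (round-trip corrected)."""
        return self.sound_speed / (2.0 * self.fs)

    @property
    def depth_mm(self) -> np.ndarray:
        return np.arange(self.n_axial) * self.axial_pitch * 1e3

    @property
    def lateral_mm(self) -> np.ndarray:
        return np.arange(self.n_lines) * self.line_pitch * 1e3


@dataclass
class ROISet:
    """Tumour-core mask and derived margin band aligned to an RF frame."""

    core_mask: np.ndarray
    margin_mask: np.ndarray
    margin_thickness_mm: float = 5.0

    def __post_init__(self):
        self.core_mask = np.asarray(self.core_mask, dtype=bool)
        self.margin_mask = np.asarray(self.margin_mask, dtype=bool)
        if self.core_mask.shape != self.margin_mask.shape:
            raise ValueError("core and margin masks must share a grid")
        if np.any(self.core_mask & self.margin_mask):
            raise ValueError("core and margin masks must be disjoint")


@dataclass
class PatientRecord:
    """All planes and labels for one patient."""

    patient_id: str
    planes: list          # list of (RFFrame, ROISet)
    mr_score: int
    er: int
    pr: int
    her2: int
    recurrence_free_5yr: int

    def __post_init__(self):
        if self.mr_score not in {1, 2, 3, 4, 5}:
            raise ValueError("mr_score must be in 1..5")
        n = len(self.planes)
        if n == 0:
            raise ValueError("patient record needs at least one plane")
        if not 4 <= n <= 7:
            warnings.warn(
                f"patient {self.patient_id}: {n} planes outside the usual "
                "4-7 range", stacklevel=2)


def envelope_bmode(frame: RFFrame, dynamic_range_db: float = 60.0) -> np.ndarray:
    """Log-compressed envelope image in [0, 1].

    Envelope is the per-line analytic-signal magnitude; compression maps
    the top ``dynamic_range_db`` decibels to (0, 1].  An all-zero frame
    maps to an all-zero image (a floor avoids log of zero).
    """
    env = np.abs(hilbert(frame.samples, axis=0))
    peak = env.max()
    if peak == 0.0:
        return np.zeros_like(env)
    floor = peak * 10.0 ** (-dynamic_range_db / 20.0)
    img = 20.0 * np.log10(np.maximum(env, floor) / peak)
    return (img + dynamic_range_db) / dynamic_range_db


def _as_polygon(core_polygon: Sequence) -> Polygon:
    verts = np.asarray(core_polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValueError("polygon must be an (N>=3) x 2 array of "
                         "(axial_mm, lateral_mm) vertices")
    poly = Polygon(verts)
    if (not poly.is_valid) or poly.area <= 0.0:
        raise ValueError("polygon is degenerate or self-intersecting")
    return poly


def build_rois(core_polygon: Sequence, frame: RFFrame,
               margin_thickness_mm: float = 5.0) -> ROISet:
    """Rasterize a core contour and derive the margin band by dilation.

    The core mask contains every pixel whose centre lies inside or on the
    contour; the margin is the set of outside pixels within
    ``margin_thickness_mm`` Euclidean millimetres of the core, clipped at
    the frame edges.
    """
    poly = _as_polygon(core_polygon)
    dz_mm = frame.axial_pitch * 1e3
    dx_mm = frame.line_pitch * 1e3
    zz, xx = np.meshgrid(frame.depth_mm, frame.lateral_mm, indexing="ij")
    core = shapely.intersects_xy(poly, zz.ravel(), xx.ravel())
    core = core.reshape(frame.samples.shape)
    if not core.any():
        warnings.warn("core polygon covers no pixel centres", stacklevel=2)
    # Euclidean distance from each outside pixel to the core, in mm.
    dist = distance_transform_edt(~core, sampling=(dz_mm, dx_mm))
    margin = (dist > 0) & (dist <= margin_thickness_mm)
    return ROISet(core_mask=core, margin_mask=margin,
                  margin_thickness_mm=margin_thickness_mm)


# ---------------------------------------------------------------------------
# Disk formats: HDF5 RF plane + JSON ground-truth sidecar, PNG QA overlay.

def save_frame(frame: RFFrame, path) -> None:
    """Write one plane as HDF5 (`/rf` float32) with a JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("rf", data=frame.samples.astype(np.float32))
        ds.attrs["fs"] = frame.fs
        ds.attrs["line_pitch_m"] = frame.line_pitch
        ds.attrs["c"] = frame.sound_speed
        ds.attrs["f0"] = frame.centre_frequency
        ds.attrs["plane_index"] = frame.plane_index
    if frame.ground_truth is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(frame.ground_truth, indent=1,
                                      sort_keys=True, default=float))


def load_frame(path) -> RFFrame:
    path = Path(path)
    with h5py.File(path, "r") as f:
        ds = f["rf"]
        frame = RFFrame(
            samples=ds[()].astype(float),
            fs=float(ds.attrs["fs"]),
            line_pitch=float(ds.attrs["line_pitch_m"]),
            sound_speed=float(ds.attrs["c"]),
            centre_frequency=float(ds.attrs["f0"]),
            plane_index=int(ds.attrs.get("plane_index", 0)),
        )
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        frame.ground_truth = json.loads(sidecar.read_text())
    return frame


def save_bmode_png(frame: RFFrame, path, rois: Optional[ROISet] = None,
                   dynamic_range_db: float = 60.0) -> None:
    """QA rendering: B-mode image with optional ROI outlines."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    img = envelope_bmode(frame, dynamic_range_db)
    fig, ax = plt.subplots(figsize=(5, 5))
    extent = [0, frame.lateral_mm[-1], frame.depth_mm[-1], 0]
    ax.imshow(img, cmap="gray", aspect="auto", extent=extent)
    if rois is not None:
        ax.contour(frame.lateral_mm, frame.depth_mm, rois.core_mask,
                   levels=[0.5], colors="r", linewidths=0.8)
        ax.contour(frame.lateral_mm, frame.depth_mm, rois.margin_mask,
                   levels=[0.5], colors="y", linewidths=0.8)
    ax.set_xlabel("lateral (mm)")
    ax.set_ylabel("depth (mm)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
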