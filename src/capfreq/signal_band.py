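"""ROI time-series I/O, temporal band decomposition and per-ROI normalization.

Resting-state BOLD fluctuations are conventionally partitioned into the
"typical" low-frequency range (0.01-0.08 Hz) and four sub-bands, slow-5
(0.01-0.027 Hz) through slow-2 (0.198-0.25 Hz).  This module holds the band
definitions, reads/writes ROI-by-time matrices, extracts ROI series from 4D
NIfTI images with an integer-label atlas, applies zero-phase band-pass
filtering, and z-scores each ROI independently so that |Z| measures the
deviation of a frame from that ROI's baseline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "BandDefinition",
    "ROITimeSeries",
    "SubjectMeta",
    "BANDS",
    "get_band",
    "band_center",
    "load_roi_timeseries",
    "write_roi_timeseries",
    "extract_roi_timeseries",
    "bandpass",
    "zscore_rois",
    "discard_initial_frames",
]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got [{self.f_low}, {self.f_high}]"
            )

    def validate_for_tr(self, tr: float) -> None:
        """Check f_high against the Nyquist frequency 1/(2*TR)."""
        nyq = 0.5 / tr
        if self.f_high > nyq + 1e-12:
            raise ValueError(
                f"band {self.name!r}: f_high={self.f_high} Hz exceeds "
                f"Nyquist {nyq} Hz for TR={tr} s"
            )


#: Built-in bands: the typical low-frequency range and the four sub-bands.
BANDS: dict[str, BandDefinition] = {
    "typical": BandDefinition("typical", 0.01, 0.08),
    "slow5": BandDefinition("slow5", 0.01, 0.027),
    "slow4": BandDefinition("slow4", 0.027, 0.073),
    "slow3": BandDefinition("slow3", 0.073, 0.198),
    "slow2": BandDefinition("slow2", 0.198, 0.25),
}

#: Sub-bands ordered from lowest to highest frequency.
SUB_BANDS = ("slow5", "slow4", "slow3", "slow2")


def get_band(name: str) -> BandDefinition:
    try:
        return BANDS[name]
    except KeyError:
        raise KeyError(f"unknown band {name!r}; known: {sorted(BANDS)}") from None


def band_center(band: BandDefinition) -> float:
    """Arithmetic center frequency (f_low + f_high)/2 in Hz.

    Used to express state persistence in cycles of the band's center
    frequency, which removes the trivial slowing that narrower, lower bands
    impose on any signal passed through them.
    """
    return 0.5 * (band.f_low + band.f_high)


@dataclass
class ROITimeSeries:
    """A subject's frames x ROIs matrix with its sampling interval and band tag."""

    subject_id: str
    data: np.ndarray  # (T, R) float
    tr: float
    band: BandDefinition | None = None  # None = broadband / unfiltered
    roi_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D frames x ROIs matrix")
        if self.n_frames < 2:
            raise ValueError(f"need at least 2 frames, got {self.n_frames}")
        if self.n_rois < 1:
            raise ValueError("need at least 1 ROI")
        if not np.all(np.isfinite(self.data)):
            t, r = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite value at frame {t}, ROI "
                f"{self.roi_names[r] if self.roi_names else r}"
            )
        if not self.roi_names:
            self.roi_names = [f"roi{i:03d}" for i in range(self.n_rois)]
        if len(self.roi_names) != self.n_rois:
            raise ValueError("roi_names length does not match number of columns")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject demographics and head-motion summary."""

    subject_id: str
    group: str  # "HC" or "SZ"
    age: float
    sex: str  # "M" or "F"
    mean_fd: float  # mean framewise displacement, mm

    def __post_init__(self) -> None:
        if self.group not in ("HC", "SZ"):
            raise ValueError(f"group must be HC or SZ, got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.mean_fd < 0:
            raise ValueError("mean_fd must be non-negative")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_roi_timeseries(
    path: str | Path, tr: float, subject_id: str | None = None
) -> ROITimeSeries:
    """Read a frames x ROIs TSV/CSV matrix (one header row of ROI names).

    Raises ValueError naming the offending row/column on missing or
    non-numeric cells, and on matrices with fewer than two frames.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=0,
                     float_precision="round_trip")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        t, r = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path.name}: missing/non-numeric cell at data row {t}, "
            f"column {df.columns[r]!r}"
        )
    return ROITimeSeries(
        subject_id=subject_id or path.stem,
        data=numeric.to_numpy(dtype=float),
        tr=tr,
        band=None,
        roi_names=[str(c) for c in df.columns],
    )


def write_roi_timeseries(
    ts: ROITimeSeries, path: str | Path, sidecar: bool = True
) -> Path:
    """Write a TSV/CSV matrix plus a JSON sidecar with acquisition metadata."""
    path = Path(path)
    pd.DataFrame(ts.data, columns=ts.roi_names).to_csv(
        path, sep=_sep_for(path), index=False, float_format="%.17g"
    )
    if sidecar:
        meta = {
            "subject_id": ts.subject_id,
            "tr": ts.tr,
            "band": ts.band.name if ts.band else "broadband",
            "n_frames": ts.n_frames,
            "n_rois": ts.n_rois,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def extract_roi_timeseries(
    image_4d: str | Path, atlas: str | Path, tr: float | None = None,
    subject_id: str | None = None,
) -> ROITimeSeries:
    """Average a 4D NIfTI image within each nonzero atlas label.

    The atlas must be integer-labeled on the same voxel grid as the image;
    label 0 is background.  One output column per label, labels ascending.
    """
    import nibabel as nib

    img = nib.load(str(image_4d))
    atl = nib.load(str(atlas))
    if img.shape[:3] != atl.shape[:3]:
        raise ValueError(
            f"grid mismatch: image {img.shape[:3]} vs atlas {atl.shape[:3]}"
        )
    labels_vol = np.asanyarray(atl.dataobj)
    if not np.allclose(labels_vol, np.round(labels_vol)):
        raise ValueError("atlas is not integer-labeled")
    labels_vol = np.round(labels_vol).astype(int)
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, got shape {img.shape}")
    labels = np.unique(labels_vol)
    labels = labels[labels != 0]
    if labels.size == 0:
        raise ValueError("atlas contains no nonzero labels")
    flat = data.reshape(-1, data.shape[3])
    lab_flat = labels_vol.reshape(-1)
    cols = []
    for lab in labels:
        mask = lab_flat == lab
        if not mask.any():
            raise ValueError(f"atlas label {lab} has no voxels")
        cols.append(flat[mask].mean(axis=0))
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    return ROITimeSeries(
        subject_id=subject_id or Path(str(image_4d)).stem,
        data=np.column_stack(cols),
        tr=tr,
        band=None,
        roi_names=[str(int(lab)) for lab in labels],
    )


def discard_initial_frames(ts: ROITimeSeries, n_discard: int = 5) -> ROITimeSeries:
    """Drop the first ``n_discard`` frames (scanner equilibration), e.g. 240 -> 235."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if ts.n_frames - n_discard < 2:
        raise ValueError("too few frames would remain after discarding")
    return replace(ts, data=ts.data[n_discard:])


def bandpass(ts: ROITimeSeries, band: BandDefinition, order: int = 4) -> ROITimeSeries:
    """Zero-phase Butterworth band-pass of each ROI column.

    Columns are linearly detrended, then filtered forward-and-backward
    (``sosfiltfilt``) with a Butterworth band-pass of the given order, so the
    output has zero net phase shift and frame-wise state timing is preserved.
    """
    band.validate_for_tr(ts.tr)
    fs = 1.0 / ts.tr
    # a band ending exactly at Nyquist (e.g. slow-2 at TR=2 s) needs its
    # digital edge nudged strictly below fs/2
    f_high = min(band.f_high, 0.999 * (fs / 2))
    sos = sps.butter(order, [band.f_low, f_high], btype="bandpass", fs=fs,
                     output="sos")
    # sosfiltfilt pads with edge reflections; require enough frames for it.
    ntaps = 2 * sos.shape[0] + 1
    padlen = 3 * ntaps
    if ts.n_frames <= padlen:
        raise ValueError(
            f"{ts.n_frames} frames is too short for order-{order} zero-phase "
            f"filtering (needs > {padlen})"
        )
    detrended = sps.detrend(ts.data, axis=0, type="linear")
    filtered = sps.sosfiltfilt(sos, detrended, axis=0)
    return replace(ts, data=filtered, band=band)


def zscore_rois(ts: ROITimeSeries) -> ROITimeSeries:
    """Z-score each ROI column independently (population-SD convention).

    After this, each column has mean 0 and unit SD, and the absolute Z value
    of a frame measures that ROI's momentary deviation from its baseline.
    A constant column is a data defect and raises, naming the ROI.
    """
    mean = ts.data.mean(axis=0)
    sd = ts.data.std(axis=0, ddof=0)
    # constant columns can leave a ~1e-16 numerical residue in the SD
    dead = np.nonzero(sd <= 1e-12 * np.maximum(1.0, np.abs(mean)))[0]
    if dead.size:
        raise ValueError(
            f"subject {ts.subject_id}: constant (zero-variance) ROI "
            f"{ts.roi_names[dead[0]]!r}"
        )
    return replace(ts, data=(ts.data - mean) / sd)
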