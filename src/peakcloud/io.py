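"""Reading and writing the interchange formats.

* profile mzML (read, MS1) via pyteomics;
* annotated point-cloud CSV (rt, mz, intensity, label) — the training
  dataset format, one integer instance id per point, -1 for noise;
* detected feature table CSV (feature_id, mz, rt, volume, window_id).

RT is minutes everywhere internally; second-based mzML timestamps are
converted at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyteomics.xml as _pyteomics_xml

# pyteomics >= 5 only uses its optional `psims` controlled-vocabulary backend
# for cvParam *type* refinement; mzML carries explicit name/unitName
# attributes, so parsing is complete without it.  Run with the CV disabled so
# mzML reading has no optional dependency.
_pyteomics_xml._has_psims = True
_pyteomics_xml.load_psims = lambda: None
from pyteomics import mzml as _mzml  # noqa: E402

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["rt", "mz", "intensity", "label"]


@dataclass
class RawSpectrum:
    """One profile scan: rt in minutes, ascending m/z, matched intensities."""

    rt: float
    mz_array: np.ndarray
    intensity_array: np.ndarray
    ms_level: int = 1

    def __post_init__(self):
        self.mz_array = np.asarray(self.mz_array, dtype=float)
        self.intensity_array = np.asarray(self.intensity_array, dtype=float)
        if len(self.mz_array) != len(self.intensity_array):
            raise ValueError("mz and intensity arrays differ in length")
        if len(self.mz_array) > 1 and np.any(np.diff(self.mz_array) <= 0):
            raise ValueError("mz_array must be strictly ascending")
        if np.any(self.intensity_array < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class AnnotatedCloud:
    """Raw-coordinate point cloud with per-point instance labels."""

    points: np.ndarray   # (n, 3) columns rt, mz, intensity
    labels: np.ndarray   # (n,) int, -1 = noise

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.points) != len(self.labels):
            raise ValueError("labels length must equal point count")

    def __len__(self):
        return len(self.points)

    @property
    def n_instances(self) -> int:
        pos = self.labels[self.labels >= 0]
        return int(pos.max() + 1) if len(pos) else 0


def _scan_rt_minutes(spectrum: dict) -> float:
    scan = spectrum["scanList"]["scan"][0]
    t = scan.get("scan start time", scan.get("scan time"))
    unit = getattr(t, "unit_info", None)
    t = float(t)
    if unit is not None and "second" in str(unit):
        t /= 60.0
    return t


def read_mzml(path, ms_level: int = 1) -> list[RawSpectrum]:
    """Read spectra of one MS level from an mzML file, ascending RT.

    Centroid-flagged spectra are returned with a warning — downstream
    detection assumes profile peak shapes.
    """
    spectra = []
    n_centroid = 0
    with _mzml.read(str(path)) as reader:
        for spec in reader:
            if int(spec.get("ms level", 1)) != ms_level:
                continue
            if "centroid spectrum" in spec:
                n_centroid += 1
            spectra.append(RawSpectrum(
                rt=_scan_rt_minutes(spec),
                mz_array=spec["m/z array"],
                intensity_array=spec["intensity array"],
                ms_level=ms_level))
    if n_centroid:
        log.warning("%d centroid-flagged spectra in %s; profile data expected",
                    n_centroid, path)
    spectra.sort(key=lambda s: s.rt)
    return spectra


def spectra_to_points(spectra: list[RawSpectrum]) -> np.ndarray:
    """Flatten scans into the global (n, 3) point set (rt, mz, intensity),
    dropping zero-intensity profile samples, ordered (rt asc, mz asc)."""
    if not spectra:
        raise ValueError("no spectra to flatten")
    chunks = []
    for s in sorted(spectra, key=lambda s: s.rt):
        keep = s.intensity_array > 0
        if keep.any():
            chunks.append(np.column_stack([
                np.full(keep.sum(), s.rt), s.mz_array[keep],
                s.intensity_array[keep]]))
    if not chunks:
        return np.empty((0, 3))
    return np.vstack(chunks)


def read_annotated_csv(path) -> AnnotatedCloud:
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation CSV {path} is missing column(s): "
                         f"{', '.join(missing)}")
    return AnnotatedCloud(
        points=df[["rt", "mz", "intensity"]].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int))


def write_annotated_csv(cloud: AnnotatedCloud, path) -> None:
    df = pd.DataFrame({
        "rt": cloud.points[:, 0],
        "mz": cloud.points[:, 1],
        "intensity": cloud.points[:, 2],
        "label": cloud.labels})
    df.to_csv(path, index=False, float_format="%.10g")


def write_feature_table(features, path) -> None:
    """Detected-feature CSV sorted by (mz, rt); m/z to 6 decimals, rt to 4."""
    rows = sorted(features, key=lambda f: (f.mz, f.rt))
    df = pd.DataFrame({
        "feature_id": np.arange(len(rows)),
        "mz": [f.mz for f in rows],
        "rt": [f.rt for f in rows],
        "volume": [f.volume for f in rows],
        "window_id": [f.window_id for f in rows]})
    with open(path, "w") as fh:
        fh.write("feature_id,mz,rt,volume,window_id\n")
        for _, r in df.iterrows():
            fh.write(f"{int(r.feature_id)},{r.mz:.6f},{r.rt:.4f},"
                     f"{r.volume:.8g},{int(r.window_id)}\n")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
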