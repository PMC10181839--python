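"""Synthetic profile LC-HRMS point clouds with instance annotations.

Emulates the structure of a manually annotated training corpus: each cloud
is an extraction window of profile MS1 data containing several 3D
Gaussian-like elution features of varying amplitude and shape, overlapping
with configurable probability, over sparse chemical noise.  Intensities at
the acquisition grid node (rt_i, mz_j) are

    I_ij = Σ_f A_f · exp(−(rt_i−rt_f)²/2σ_rt,f² − (mz_j−mz_f)²/2σ_mz,f²) · (1+ε_ij)

with multiplicative detector noise ε.  Grid nodes below an intensity floor
are dropped (a profile instrument records no signal there after
thresholding), every surviving node is labeled with the feature that
dominates it, and uniformly scattered noise points carry label −1.

The per-feature σ_mz follows the analyzer resolution model through
FWHM = 2·sqrt(2 ln 2)·σ, so simulated peak widths scale with m/z exactly as
the normalization assumes.
"""

from __future__ import annotations

import base64
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AnnotatedCloud, write_annotated_csv
from .preprocess import (FWHM_TO_SIGMA, Analyzer, ResolutionModel,
                         theoretical_mz_fwhm)

TRUTH_COLUMNS = ["feature_id", "rt", "mz", "amplitude", "sigma_rt", "sigma_mz",
                 "true_volume"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic corpus.

    Defaults describe a TOF acquisition (R = 30 000) over a 1.2 min × 0.15 Da
    extraction window: 1.5 s scan interval, ~4 profile samples per m/z FWHM,
    feature RT FWHM 0.08–0.18 min, amplitudes spanning 500–20 000 counts
    (log-uniform), 5% multiplicative detector noise, and sparse chemical
    noise in the 5–150 count range.
    """

    rt_extent: tuple = (0.0, 1.2)        # minutes
    mz_extent: tuple = (500.0, 500.15)   # Da
    scan_interval: float = 0.025         # minutes between scans
    mz_spacing: float = 0.004            # Da between profile samples
    n_features: tuple = (2, 5)           # inclusive range per cloud
    amplitude: tuple = (500.0, 20000.0)  # counts, log-uniform
    rt_fwhm: tuple = (0.08, 0.18)        # minutes
    resolution: ResolutionModel = field(default_factory=lambda: ResolutionModel(
        Analyzer.TOF, 30000.0, 500.0))
    overlap_fraction: float = 0.25       # features seeded within 2σ of another
    noise_density: float = 600.0         # noise points per (min · Da)
    noise_intensity: tuple = (5.0, 150.0)  # counts, log-uniform
    mult_noise: float = 0.05             # σ of multiplicative noise ε
    floor_fraction: float = 0.01         # floor = fraction · min amplitude
    rt_margin: float = 0.2               # keep feature centers off the edges
    mz_margin: float = 0.025

    @property
    def floor(self) -> float:
        return self.floor_fraction * self.amplitude[0]


def _sample_features(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = int(rng.integers(cfg.n_features[0], cfg.n_features[1] + 1))
    rows = []
    for i in range(n):
        a = float(np.exp(rng.uniform(*np.log(cfg.amplitude))))
        s_rt = float(rng.uniform(*cfg.rt_fwhm)) / FWHM_TO_SIGMA
        overlap = rows and rng.random() < cfg.overlap_fraction
        if overlap:
            host = rows[int(rng.integers(len(rows)))]
            # seed within 2σ of the host in each dimension (but >= 1σ away
            # in the joint sense, so the pair stays resolvable)
            for _ in range(50):
                rt_c = host["rt"] + rng.uniform(-2, 2) * host["sigma_rt"]
                mz_c = host["mz"] + rng.uniform(-2, 2) * host["sigma_mz"]
                d = np.hypot((rt_c - host["rt"]) / host["sigma_rt"],
                             (mz_c - host["mz"]) / host["sigma_mz"])
                if d >= 1.0:
                    break
        else:
            rt_c = rng.uniform(cfg.rt_extent[0] + cfg.rt_margin,
                               cfg.rt_extent[1] - cfg.rt_margin)
            mz_c = rng.uniform(cfg.mz_extent[0] + cfg.mz_margin,
                               cfg.mz_extent[1] - cfg.mz_margin)
        rt_c = float(np.clip(rt_c, cfg.rt_extent[0] + cfg.rt_margin / 2,
                             cfg.rt_extent[1] - cfg.rt_margin / 2))
        mz_c = float(np.clip(mz_c, cfg.mz_extent[0] + cfg.mz_margin / 2,
                             cfg.mz_extent[1] - cfg.mz_margin / 2))
        s_mz = theoretical_mz_fwhm(mz_c, cfg.resolution) / FWHM_TO_SIGMA
        rows.append(dict(feature_id=i, rt=rt_c, mz=mz_c, amplitude=a,
                         sigma_rt=s_rt, sigma_mz=s_mz))
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS[:-1])


def generate_cloud(cfg: SimConfig, seed: int) -> tuple[AnnotatedCloud, pd.DataFrame]:
    """One annotated cloud plus its truth table.

    ``true_volume`` is each feature's own contribution summed over the full
    acquisition grid (no floor), i.e. the discrete analogue of
    A·2π·σ_rt·σ_mz/(Δrt·Δmz).
    """
    rng = np.random.default_rng(seed)
    truth = _sample_features(cfg, rng)
    rts = np.arange(cfg.rt_extent[0], cfg.rt_extent[1] - 1e-12, cfg.scan_interval)
    mzs = np.arange(cfg.mz_extent[0], cfg.mz_extent[1] - 1e-12, cfg.mz_spacing)

    grid_rt, grid_mz = np.meshgrid(rts, mzs, indexing="ij")
    total = np.zeros_like(grid_rt)
    contrib = np.zeros((len(truth), *grid_rt.shape))
    volumes = []
    for i, f in truth.iterrows():
        c = (f.amplitude
             * np.exp(-0.5 * ((grid_rt - f.rt) / f.sigma_rt) ** 2
                      - 0.5 * ((grid_mz - f.mz) / f.sigma_mz) ** 2))
        contrib[i] = c
        total += c
        volumes.append(float(c.sum()))
    truth["true_volume"] = volumes

    keep = total >= cfg.floor
    if len(truth) and keep.any():
        eps = rng.normal(0.0, cfg.mult_noise, size=keep.sum())
        intensity = total[keep] * np.clip(1.0 + eps, 0.05, None)
        labels = contrib[:, keep].argmax(axis=0)
        pts = np.column_stack([grid_rt[keep], grid_mz[keep], intensity])
    else:
        pts = np.empty((0, 3))
        labels = np.empty(0, dtype=int)

    # chemical noise: uniform over the window, rt snapped to the scan grid
    area = ((cfg.rt_extent[1] - cfg.rt_extent[0])
            * (cfg.mz_extent[1] - cfg.mz_extent[0]))
    n_noise = rng.poisson(cfg.noise_density * area)
    if n_noise:
        n_rt = rts[rng.integers(0, len(rts), n_noise)]
        n_mz = rng.uniform(cfg.mz_extent[0], cfg.mz_extent[1], n_noise)
        n_i = np.exp(rng.uniform(*np.log(cfg.noise_intensity), n_noise))
        pts = np.vstack([pts, np.column_stack([n_rt, n_mz, n_i])])
        labels = np.concatenate([labels, np.full(n_noise, -1)])

    order = np.lexsort((pts[:, 1], pts[:, 0])) if len(pts) else np.empty(0, int)
    cloud = AnnotatedCloud(points=pts[order], labels=labels[order])
    # instance ids contiguous even if a feature lost every node to the floor
    present = np.unique(cloud.labels[cloud.labels >= 0])
    remap = {int(old): new for new, old in enumerate(present)}
    cloud.labels = np.array([remap.get(int(l), -1) for l in cloud.labels], int)
    truth = truth[truth.feature_id.isin(present)].reset_index(drop=True)
    truth["feature_id"] = np.arange(len(truth))
    return cloud, truth


def generate_dataset(cfg: SimConfig, n_clouds: int, seed: int,
                     out_dir=None) -> list[tuple[AnnotatedCloud, pd.DataFrame]]:
    """Reproducible corpus of annotated clouds; optionally written to disk as
    cloud_XXXX.csv / truth_XXXX.csv plus a manifest echoing the config."""
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=n_clouds)
    out = [generate_cloud(cfg, int(s)) for s in child_seeds]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, (cloud, truth) in enumerate(out):
            write_annotated_csv(cloud, out_dir / f"cloud_{i:04d}.csv")
            truth.to_csv(out_dir / f"truth_{i:04d}.csv", index=False)
        manifest = asdict(cfg)
        manifest["resolution"] = {
            "analyzer": cfg.resolution.analyzer.value,
            "ref_resolution": cfg.resolution.ref_resolution,
            "ref_mz": cfg.resolution.ref_mz}
        manifest.update(n_clouds=n_clouds, seed=seed)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


# --------------------------------------------------------------------- mzML
def _encode_array(values: np.ndarray) -> str:
    raw = np.asarray(values, dtype="<f8").tobytes()
    return base64.b64encode(zlib.compress(raw)).decode()


def write_mzml(points: np.ndarray, path) -> None:
    """Write grid-aligned points as a minimal profile MS1 mzML file.

    Points sharing an RT value become one scan; arrays are 64-bit,
    zlib-compressed, base64-encoded per the mzML 1.1.0 conventions.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    rts = np.unique(points[:, 0])
    spectra_xml = []
    for i, rt in enumerate(rts):
        rows = points[points[:, 0] == rt]
        rows = rows[np.argsort(rows[:, 1])]
        mz_b = _encode_array(rows[:, 1])
        in_b = _encode_array(rows[:, 2])
        spectra_xml.append(f"""
      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(rows)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.8f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(in_b)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{in_b}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>""")
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/*checkout*/obo/obo/ontology/phenotype/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="peakcloud" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="peakcloud"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="peakcloud">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="run1" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{len(rts)}" defaultDataProcessingRef="DP1">{''.join(spectra_xml)}
    </spectrumList>
  </run>
</mzML>
"""
    Path(path).write_text(doc)
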