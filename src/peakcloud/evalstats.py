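"""Evaluation statistics for detection and quantification benchmarks.

Detected features are matched one-to-one to a reference library under m/z
and RT tolerances; matched features yield fold changes between sample
groups, quantification-accuracy calls against a tolerance-widened expected
range, replicate CVs, and differential-marker calls (fold change outside a
20%-widened (0.5, 2) band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MARKER_BAND = (0.5, 2.0)


@dataclass
class MatchResult:
    pairs: list            # (detected_index, truth_index)
    unmatched_truth: list
    unmatched_detected: list
    delta_mz: np.ndarray   # per pair, Da
    delta_rt: np.ndarray   # per pair, minutes

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def _to_xy(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        return table[["mz", "rt"]].to_numpy(dtype=float)
    arr = np.asarray([(f.mz, f.rt) for f in table], dtype=float)
    return arr.reshape(-1, 2)


def match_features(detected, truth, tol_mz: float, tol_rt: float) -> MatchResult:
    """Greedy one-to-one matching by ascending combined normalized distance
    sqrt((Δmz/tol_mz)² + (Δrt/tol_rt)²); pairs exceeding either tolerance
    never match.  Greedy-by-distance is deterministic and independent of
    input order."""
    if tol_mz <= 0 or tol_rt <= 0:
        raise ValueError("tolerances must be positive")
    det = _to_xy(detected)
    tru = _to_xy(truth)
    cand = []
    for i, (dmz, drt) in enumerate(det):
        dm = np.abs(tru[:, 0] - dmz)
        dr = np.abs(tru[:, 1] - drt)
        ok = (dm <= tol_mz) & (dr <= tol_rt)
        for j in np.nonzero(ok)[0]:
            d = np.hypot(dm[j] / tol_mz, dr[j] / tol_rt)
            cand.append((d, i, int(j)))
    cand.sort()
    used_d, used_t, pairs = set(), set(), []
    for _, i, j in cand:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        pairs.append((i, j))
    pairs.sort()
    dmz = np.array([det[i, 0] - tru[j, 0] for i, j in pairs])
    drt = np.array([det[i, 1] - tru[j, 1] for i, j in pairs])
    return MatchResult(
        pairs=pairs,
        unmatched_truth=[j for j in range(len(tru)) if j not in used_t],
        unmatched_detected=[i for i in range(len(det)) if i not in used_d],
        delta_mz=dmz, delta_rt=drt)


def fold_change(quants_b, quants_a) -> float:
    """FC = mean(B) / mean(A) over replicate volumes."""
    a = float(np.mean(quants_a))
    b = float(np.mean(quants_b))
    if a <= 0 or b <= 0:
        raise ValueError("group means must be positive for a fold change")
    return b / a


def accurate_quant(fc: float, theo_fc: float, measured_fc: float,
                   tol: float = 0.20) -> bool:
    """True iff `fc` lies within the tolerance-widened envelope of the
    theoretical and 2D-measured fold changes:
    [(1−tol)·min, (1+tol)·max]."""
    lo = (1.0 - tol) * min(theo_fc, measured_fc)
    hi = (1.0 + tol) * max(theo_fc, measured_fc)
    return lo <= fc <= hi


def cv(values) -> float:
    """Coefficient of variation: sample standard deviation / mean."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("CV needs at least two replicates")
    m = v.mean()
    if m <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(v.std(ddof=1) / m)


def is_marker(fc: float, tol: float = 0.20,
              band: tuple = MARKER_BAND) -> bool:
    """A feature is a differential marker iff its fold change falls outside
    the tolerance-widened band: fc < (1−tol)·band_lo or fc > (1+tol)·band_hi
    (0.4 / 2.4 at the defaults)."""
    if fc <= 0:
        raise ValueError("fold change must be positive")
    return fc < (1.0 - tol) * band[0] or fc > (1.0 + tol) * band[1]


def marker_accuracy(measured_fcs, theo_fcs, tol: float = 0.20,
                    band: tuple = MARKER_BAND) -> tuple[int, int, float]:
    """(true markers, false markers, accuracy).  A called marker is *true*
    iff its theoretical fold change lies outside the (unwidened) band."""
    true_m = false_m = 0
    for fc, theo in zip(measured_fcs, theo_fcs):
        if not is_marker(fc, tol, band):
            continue
        if theo <= band[0] or theo >= band[1]:
            true_m += 1
        else:
            false_m += 1
    total = true_m + false_m
    return true_m, false_m, (true_m / total if total else float("nan"))


def detection_metrics(match: MatchResult, truth_size: int) -> tuple[float, float]:
    """(recall, precision) of a match result."""
    if truth_size <= 0:
        raise ValueError("truth set must be non-empty")
    n_det = match.n_matched + len(match.unmatched_detected)
    recall = match.n_matched / truth_size
    precision = match.n_matched / n_det if n_det else float("nan")
    return recall, precision


def consensus_features(tables: list, tol_mz: float, tol_rt: float):
    """Features of the first table that match a partner in *every* other
    table (raw-tolerance intersection across replicate runs).  Returns the
    surviving row indices of the first table."""
    if not tables:
        return []
    keep = set(range(len(_to_xy(tables[0]))))
    for other in tables[1:]:
        m = match_features(tables[0], other, tol_mz, tol_rt)
        keep &= {i for i, _ in m.pairs}
    return sorted(keep)
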