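"""Quantitative evaluation of source estimates against ground truth.

Ground truth can be a simulated source patch, a resection-mask surrogate
(region set) or a set of seizure-onset-zone electrode positions.  Spatial
metrics operate on the Otsu-thresholded energy map; all distances are
Euclidean between region centroids (and electrode points) and reported in
millimeters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from skimage.filters import threshold_otsu

from .head_model import SourceSpace
from .network import SourceEstimate

__all__ = [
    "GroundTruth",
    "EvaluationReport",
    "otsu_threshold",
    "extent_metrics",
    "localization_error",
    "spatial_dispersion",
    "soz_localization_error",
    "temporal_correlation",
    "evaluate",
]


@dataclass
class GroundTruth:
    true_regions: tuple = ()
    soz_points: np.ndarray | None = None  # (k, 3) m
    true_waveforms: np.ndarray | None = None  # regions-in-truth x time


@dataclass
class EvaluationReport:
    """All metrics for one estimate; rates in [0, 1], distances in mm."""

    sensitivity: float = np.nan
    specificity: float = np.nan
    precision: float = np.nan
    f1: float = np.nan
    harmonic_mean: float = np.nan
    geometric_mean: float = np.nan
    spatial_dispersion: float = np.nan
    localization_error: float = np.nan
    soz_localization_error: float = np.nan
    temporal_correlation: float = np.nan
    flags: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_csv_row(self) -> str:
        keys = [k for k in asdict(self) if k != "flags"]
        return ",".join(f"{getattr(self, k):.6g}" for k in keys)


def otsu_threshold(energy_map: np.ndarray):
    """Otsu's histogram threshold (256 bins) on a per-region energy map.

    Returns ``(suprathreshold_indices, threshold)``.  The threshold
    maximizes the between-class variance, so the suprathreshold set is
    invariant to positive rescaling of the map.
    """
    energy_map = np.asarray(energy_map, float)
    if np.ptp(energy_map) == 0:
        raise ValueError("constant energy map has no Otsu boundary")
    thr = float(threshold_otsu(energy_map, nbins=256))
    return np.flatnonzero(energy_map > thr), thr


def extent_metrics(est_regions, true_regions, n_regions: int) -> dict:
    """Set-overlap metrics of the thresholded estimate vs. the truth.

    sensitivity = |est ∩ true| / |true|;
    specificity = 1 - |est \\ true| / |Ω \\ true|;
    precision = |est ∩ true| / |est|; f1 = harmonic(precision, sensitivity);
    plus harmonic and geometric means of (sensitivity, specificity).
    An empty estimate yields zero sensitivity/precision with a flag.
    """
    est = set(map(int, est_regions))
    true = set(map(int, true_regions))
    if not true:
        raise ValueError("ground-truth region set is empty")
    flags = []
    tp = len(est & true)
    sens = tp / len(true)
    spec = 1.0 - len(est - true) / (n_regions - len(true))
    if est:
        prec = tp / len(est)
    else:
        prec, flags = 0.0, ["empty_estimate"]
    f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
    harm = 2 * sens * spec / (sens + spec) if sens + spec > 0 else 0.0
    geom = float(np.sqrt(sens * spec))
    return dict(sensitivity=sens, specificity=spec, precision=prec, f1=f1,
                harmonic_mean=harm, geometric_mean=geom, flags=flags)


def _pairwise_min_dist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """For each row of ``a``, distance (mm) to the nearest row of ``b``."""
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return d.min(axis=1) * 1000.0


def localization_error(est_regions, true_regions, space: SourceSpace) -> float:
    """Symmetrized mean nearest-centroid distance between the two sets (mm)."""
    est = np.asarray(sorted(set(map(int, est_regions))))
    true = np.asarray(sorted(set(map(int, true_regions))))
    if est.size == 0 or true.size == 0:
        raise ValueError("localization error needs two non-empty region sets")
    c = space.centroids
    d1 = _pairwise_min_dist(c[est], c[true]).mean()
    d2 = _pairwise_min_dist(c[true], c[est]).mean()
    return float((d1 + d2) / 2.0)


def spatial_dispersion(est: SourceEstimate, true_regions, space: SourceSpace,
                       est_regions=None) -> float:
    """Energy-weighted mean distance of reconstructed regions to the truth (mm).

    ``SD = sum_i d_i J_i / sum_i J_i`` over the suprathreshold regions,
    where ``d_i`` is the minimum centroid distance to the true set (zero
    inside it) and ``J_i`` the estimated energy.
    """
    true = np.asarray(sorted(set(map(int, true_regions))))
    if true.size == 0:
        raise ValueError("true region set is empty")
    if est_regions is None:
        est_regions, _ = otsu_threshold(est.energy_map)
    est_regions = np.asarray(sorted(set(map(int, est_regions))))
    energies = est.energy_map[est_regions]
    total = energies.sum()
    if total <= 0:
        raise ValueError("zero total energy in the reconstructed set")
    d = _pairwise_min_dist(space.centroids[est_regions], space.centroids[true])
    return float(np.sum(d * energies) / total)


def soz_localization_error(est_regions, soz_points, space: SourceSpace) -> float:
    """Mean of the two directed electrode<->estimate average distances (mm)."""
    est = np.asarray(sorted(set(map(int, est_regions))))
    soz = np.atleast_2d(np.asarray(soz_points, float))
    if est.size == 0 or soz.size == 0:
        raise ValueError("need non-empty estimate and SOZ point set")
    c = space.centroids[est]
    le1 = _pairwise_min_dist(soz, c).mean()  # SOZ electrodes -> estimate
    le2 = _pairwise_min_dist(c, soz).mean()  # estimate -> SOZ electrodes
    return float((le1 + le2) / 2.0)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant signal")
    return float(np.corrcoef(x, y)[0, 1])


def temporal_correlation(est_waveforms, reference, mode: str = "simulation") -> float:
    """Waveform agreement between estimate and reference.

    simulation mode: for each estimated region the maximum Pearson r over
    the reference (simulated) waveforms, averaged over estimated regions.
    clinical mode: Pearson r between the mean estimated waveform and the
    reference channel.  No lag search in either mode.
    """
    est = np.atleast_2d(np.asarray(est_waveforms, float))
    if mode == "clinical":
        return _pearson(est.mean(axis=0), np.asarray(reference, float))
    ref = np.atleast_2d(np.asarray(reference, float))
    best = []
    for row in est:
        best.append(max(_pearson(row, r) for r in ref))
    return float(np.mean(best))


def evaluate(est: SourceEstimate, gt: GroundTruth, space: SourceSpace,
             correlation_mode: str = "simulation") -> EvaluationReport:
    """Full report: threshold the energy map, then all applicable metrics."""
    report = EvaluationReport()
    try:
        est_regions, _ = otsu_threshold(est.energy_map)
    except ValueError:
        report.flags.append("constant_energy_map")
        return report
    if gt.true_regions:
        ext = extent_metrics(est_regions, gt.true_regions, space.region_count)
        report.flags.extend(ext.pop("flags"))
        for k, v in ext.items():
            setattr(report, k, v)
        if est_regions.size:
            report.localization_error = localization_error(
                est_regions, gt.true_regions, space
            )
            report.spatial_dispersion = spatial_dispersion(
                est, gt.true_regions, space, est_regions
            )
    if gt.soz_points is not None and est_regions.size:
        report.soz_localization_error = soz_localization_error(
            est_regions, gt.soz_points, space
        )
    if gt.true_waveforms is not None and est_regions.size:
        try:
            if correlation_mode == "simulation":
                report.temporal_correlation = temporal_correlation(
                    est.waveforms[est_regions], gt.true_waveforms, "simulation"
                )
            else:
                report.temporal_correlation = temporal_correlation(
                    est.waveforms, gt.true_waveforms, "clinical"
                )
        except ValueError:
            report.flags.append("constant_waveform")
    return report
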