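"""Per-chart Gaussian intensity statistics and the generic-tissue model.

Each atlas chart (one labeled structure in one atlas) carries its own
intensity mean and variance; the target is conditionally Gaussian given the
deformed chart, so the per-voxel log-likelihood is a Gaussian log-density.
A 3-class Gaussian mixture over CSF/GM/WM supplies generic tissue labels for
ROI voxels outside the structures of interest, so that every voxel can be
labeled and dark/bright background does not get over-assigned to structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from likefusion.synthetic import CSF_LABEL, GM_LABEL, WM_LABEL, TISSUE_NAMES
from likefusion.volumes import IntensityVolume, LabelVolume, RoiBox

__all__ = [
    "ChartStats", "GMMParams", "estimate_chart_stats", "voxel_loglik",
    "fit_tissue_gmm", "label_generic_tissue", "TISSUE_LABEL_IDS",
]

logger = logging.getLogger(__name__)

TISSUE_LABEL_IDS = (CSF_LABEL, GM_LABEL, WM_LABEL)  # sorted by expected T1 mean


@dataclass
class ChartStats:
    """Per-label intensity statistics for one atlas: label -> (mean, var, n)."""

    means: dict[int, float] = field(default_factory=dict)
    variances: dict[int, float] = field(default_factory=dict)
    counts: dict[int, int] = field(default_factory=dict)

    def has(self, label: int) -> bool:
        return label in self.means

    def to_json(self) -> dict:
        return {str(k): {"mean": self.means[k], "var": self.variances[k],
                         "n": self.counts[k]} for k in self.means}

    @classmethod
    def from_json(cls, obj: dict) -> "ChartStats":
        stats = cls()
        for k, rec in obj.items():
            stats.means[int(k)] = float(rec["mean"])
            stats.variances[int(k)] = float(rec["var"])
            stats.counts[int(k)] = int(rec["n"])
        return stats


def estimate_chart_stats(atlas_image: IntensityVolume, atlas_labels: LabelVolume,
                         include_background: bool = True) -> ChartStats:
    """Empirical mean and unbiased variance per label.

    The variance is clamped to ``max(1e-6, 0.01 * global intensity variance)``
    so noise-free synthetic structures do not produce degenerate likelihoods.
    Label 0 (background) gets a chart too when present and requested, acting
    as the catch-all chart when no generic tissue labels are provided.
    """
    if atlas_image.grid.dims != atlas_labels.grid.dims:
        raise ValueError("image and labels must share one grid")
    values = atlas_image.values.astype(np.float64)
    floor = max(1e-6, 0.01 * float(values.var()))
    stats = ChartStats()
    ids = np.unique(atlas_labels.labels)
    for k in ids.tolist():
        if k == 0 and not include_background:
            continue
        sel = values[atlas_labels.labels == k]
        if sel.size < 1:
            raise ValueError(f"label {k} has zero voxels")
        var = float(sel.var(ddof=1)) if sel.size > 1 else 0.0
        stats.means[k] = float(sel.mean())
        stats.variances[k] = max(var, floor)
        stats.counts[k] = int(sel.size)
    return stats


def voxel_loglik(intensity, label: int, stats: ChartStats):
    """Gaussian log-density of the intensity under one atlas chart."""
    if not stats.has(label):
        raise KeyError(f"label {label} absent from chart statistics")
    mu = stats.means[label]
    var = stats.variances[label]
    x = np.asarray(intensity, dtype=np.float64)
    out = -0.5 * np.log(2.0 * np.pi * var) - (x - mu) ** 2 / (2.0 * var)
    return float(out) if np.isscalar(intensity) else out


@dataclass
class GMMParams:
    """1-D Gaussian mixture, components sorted by mean (CSF, GM, WM convention)."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    responsibilities: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return len(self.means)

    def predict_component(self, intensities: np.ndarray) -> np.ndarray:
        """Maximum-responsibility component per sample; ties -> lowest index."""
        x = np.asarray(intensities, dtype=np.float64).reshape(-1, 1)
        log_resp = (np.log(self.weights)[None, :]
                    - 0.5 * np.log(2 * np.pi * self.variances)[None, :]
                    - (x - self.means[None, :]) ** 2 / (2 * self.variances)[None, :])
        return np.argmax(log_resp, axis=1)  # argmax takes the first (lowest) on ties


def fit_tissue_gmm(intensities: np.ndarray, n_components: int = 3,
                   seed: int = 0, max_iter: int = 200) -> GMMParams:
    """EM fit of a C-component 1-D Gaussian mixture, k-means initialized.

    Deterministic given the seed; the EM data log-likelihood is non-decreasing
    by construction.  Components are reported sorted by ascending mean.
    (k-means initialization is robust to very unequal tissue shares, where
    quantile seeding can drop two components into the dominant class.)
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size < 10 * n_components:
        raise ValueError(f"need at least {10 * n_components} samples, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("all intensities identical; mixture fit is degenerate")
    gmm = GaussianMixture(
        n_components=n_components,
        covariance_type="diag",
        init_params="kmeans",
        reg_covar=max(1e-6, 1e-4 * float(x.var())),
        random_state=seed,
        max_iter=max_iter,
        n_init=1,
    )
    gmm.fit(x.reshape(-1, 1))
    order = np.argsort(gmm.means_.ravel())
    resp = gmm.predict_proba(x.reshape(-1, 1))[:, order]
    return GMMParams(
        weights=gmm.weights_[order],
        means=gmm.means_.ravel()[order],
        variances=gmm.covariances_.ravel()[order],
        responsibilities=resp,
    )


def label_generic_tissue(target: IntensityVolume, roi: RoiBox,
                         structure_mask: np.ndarray, gmm: GMMParams) -> LabelVolume:
    """Assign CSF/GM/WM labels to ROI voxels outside the structure mask.

    Every ROI voxel ends up labeled (structure voxels keep label 0 here so the
    caller can overlay its structure segmentation).  Ties go to the lower
    tissue label id, i.e. the darker tissue.
    """
    if gmm.n_components != 3:
        raise ValueError("generic tissue labeling expects a 3-component mixture")
    labels = np.zeros(target.grid.dims, dtype=np.int32)
    sl = roi.slices()
    roi_vals = target.values[sl]
    outside = ~np.asarray(structure_mask[sl], dtype=bool)
    comp = gmm.predict_component(roi_vals[outside])
    tissue_ids = np.array(TISSUE_LABEL_IDS, dtype=np.int32)
    block = labels[sl]
    block[outside] = tissue_ids[comp]
    labels[sl] = block
    return LabelVolume(target.grid, labels, TISSUE_NAMES)


def augment_atlas_tissue(atlas_image: IntensityVolume, atlas_labels: LabelVolume,
                         roi: RoiBox, seed: int = 0) -> LabelVolume:
    """Relabel an atlas's background ROI voxels as CSF/GM/WM charts.

    Fits a 3-class mixture to the atlas's own background intensities inside
    the ROI and classifies them; the tissue charts then participate in fusion
    exactly like structure charts.
    """
    sl = roi.slices()
    background = atlas_labels.labels[sl] == 0
    vals = atlas_image.values[sl][background]
    gmm = fit_tissue_gmm(vals, 3, seed=seed)
    comp = gmm.predict_component(vals)
    tissue_ids = np.array(TISSUE_LABEL_IDS, dtype=np.int32)
    new_labels = atlas_labels.labels.copy()
    block = new_labels[sl]
    block[background] = tissue_ids[comp]
    new_labels[sl] = block
    dictionary = dict(atlas_labels.dictionary)
    dictionary.update(TISSUE_NAMES)
    return LabelVolume(atlas_labels.grid, new_labels, dictionary)
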