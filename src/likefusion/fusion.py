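"""Likelihood-fusion EM segmentation.

The target volume is modeled as a conditionally Gaussian random field given
deformed atlas charts; the latent per-voxel atlas selector is marginalized by
EM.  The E-step computes per-voxel convex atlas weights (conditional means of
the selector indicators) from window-aggregated per-atlas log-likelihoods; the
M-step assigns each voxel the label maximizing the fused (convexly weighted)
per-atlas log-likelihoods.  A single optimized diffeomorphism per atlas (the
mode approximation of the nuisance integral over deformations) is computed
once and reused across EM iterations.

Numerical contract: the recorded fused objective is the EM free energy after
the exact E-step, ``sum_x logsumexp_a b_a(x)`` with ``b_a`` the aggregated
per-atlas terms; the M-step maximizes that same surrogate exactly (its weights
are the window-summed adjoint of the selector weights), so the objective trace
is provably non-decreasing and any decrease beyond 1e-6 is a hard error.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.special import logsumexp

from likefusion.intensity import (
    ChartStats,
    augment_atlas_tissue,
    estimate_chart_stats,
    fit_tissue_gmm,
    label_generic_tissue,
    TISSUE_LABEL_IDS,
)
from likefusion.lddmm import (
    Diffeomorphism,
    KernelParams,
    RegistrationConfig,
    VelocityField,
    geodesic_energy,
    lddmm_match,
    warp_labels,
)
from likefusion.synthetic import Atlas, TISSUE_NAMES
from likefusion.volumes import IntensityVolume, LabelVolume, RoiBox, compute_roi

__all__ = [
    "FusionConfig", "FusionResult", "run_fusion", "single_atlas_map",
    "initialize_segmentation", "compute_selector", "fused_label_scores",
    "maximize_segmentation", "remove_outlier_atlases",
    "transformation_log_prior", "per_atlas_label_scores",
]

logger = logging.getLogger(__name__)

LOG_FLOOR = -30.0  # floor for log of zero/absent label priors, nats


@dataclass(frozen=True)
class FusionConfig:
    """Settings for :func:`run_fusion`.

    epsilon is the convergence threshold on the fraction of voxels changing
    label; lambda_prior weighs the transformation prior (exponential of the
    geodesic energy) inside the selector; outlier_cut is the ``mean - c*sd``
    multiplier of the robust atlas-rejection rule.
    """

    max_iters: int = 100
    epsilon: float = 1e-4
    selector_radius: int = 2
    lambda_prior: float = 0.0
    outlier_cut: float = 1.5
    remove_outliers: bool = True
    use_tissue_charts: bool = True
    fill_generic_tissue: bool = True
    roi_margin: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.lambda_prior < 0:
            raise ValueError("lambda_prior must be >= 0")
        if self.selector_radius < 0:
            raise ValueError("selector_radius must be >= 0")


@dataclass
class RegisteredAtlas:
    """One atlas after registration to the target."""

    atlas_id: str
    diffeo: Diffeomorphism
    velocity: VelocityField | None
    warped_labels: LabelVolume          # hard labels on the target grid
    prior: np.ndarray                   # (K, *roi) label prior aligned to label_ids
    stats: ChartStats
    geodesic: float = 0.0
    reg_trace: pd.DataFrame | None = None


@dataclass
class FusionResult:
    segmentation: LabelVolume           # full grid; 0 outside the ROI
    roi: RoiBox
    label_ids: list[int]
    retained_ids: list[str]
    weights: np.ndarray                 # (N_retained, *roi) selector weights
    trace: pd.DataFrame                 # iteration, objective, changed_frac, w_mean_*
    outlier_report: pd.DataFrame | None
    registered: list[RegisteredAtlas]
    n_iterations: int


# ---------------------------------------------------------------------------
# building blocks


def _boxsum(arr: np.ndarray, radius: int) -> np.ndarray:
    """Window sum over a (2r+1)^3 box with zero padding (self-adjoint)."""
    if radius == 0:
        return arr
    size = 2 * radius + 1
    return uniform_filter(arr, size=size, mode="constant", cval=0.0) * size ** 3


def per_atlas_label_scores(target_values: np.ndarray, registered: Sequence[RegisteredAtlas],
                           label_ids: Sequence[int]) -> np.ndarray:
    """Per-atlas, per-label log score field C[a, k, x] = log N(I(x); chart a,k)
    + log prior_a(k|x), both floored at ``LOG_FLOOR`` when absent/zero."""
    tgt = target_values.astype(np.float64)
    n_a, n_k = len(registered), len(label_ids)
    scores = np.empty((n_a, n_k, *tgt.shape), dtype=np.float64)
    for ai, ra in enumerate(registered):
        for ki, k in enumerate(label_ids):
            if ra.stats.has(k):
                mu = ra.stats.means[k]
                var = ra.stats.variances[k]
                gauss = -0.5 * np.log(2 * np.pi * var) - (tgt - mu) ** 2 / (2 * var)
                gauss = np.maximum(gauss, LOG_FLOOR)
            else:
                logger.debug("atlas %s lacks chart for label %s; flooring", ra.atlas_id, k)
                gauss = np.full_like(tgt, LOG_FLOOR)
            logprior = np.log(np.maximum(ra.prior[ki], np.exp(LOG_FLOOR)))
            scores[ai, ki] = gauss + logprior
    return scores


def atlas_loglik_field(scores: np.ndarray, segmentation_idx: np.ndarray) -> np.ndarray:
    """Gather each atlas's per-voxel log-likelihood at the current labels.

    ``scores`` is the (N, K, *dims) output of :func:`per_atlas_label_scores`;
    ``segmentation_idx`` holds label *indices* into that K axis.
    """
    idx = segmentation_idx[None, None]
    return np.take_along_axis(scores, idx, axis=1)[:, 0]


def transformation_log_prior(velocity: VelocityField | None, kernel: KernelParams,
                             lam: float) -> float:
    """-lambda * geodesic energy: the log of the deformation-metric prior."""
    if lam == 0.0 or velocity is None:
        return 0.0
    return -lam * geodesic_energy(velocity, kernel)


def _selector_terms(loglik_fields: np.ndarray, trans_log_priors: np.ndarray,
                    log_atlas_prior: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Aggregated per-atlas terms b_a(x) and the softmax weights q(x, a)."""
    n_a = loglik_fields.shape[0]
    b = np.empty_like(loglik_fields)
    for ai in range(n_a):
        b[ai] = _boxsum(loglik_fields[ai], radius)
        b[ai] += trans_log_priors[ai] + log_atlas_prior[ai]
    bmax = b.max(axis=0, keepdims=True)
    q = np.exp(b - bmax)
    q /= q.sum(axis=0, keepdims=True)
    return b, q


def compute_selector(loglik_fields: np.ndarray, trans_log_priors: Sequence[float] | None = None,
                     atlas_prior: Sequence[float] | None = None, radius: int = 2) -> np.ndarray:
    """Per-voxel convex atlas weights: the conditional means of the selector.

    Each atlas's log-likelihood field is aggregated over a local box of
    ``radius`` voxels (chart-local evidence), shifted by its transformation
    log-prior and log atlas prior, and normalized across atlases by a
    max-subtracted softmax.  Rows sum to 1 at every voxel.
    """
    loglik_fields = np.asarray(loglik_fields, dtype=np.float64)
    n_a = loglik_fields.shape[0]
    if n_a < 1:
        raise ValueError("need at least one atlas")
    tlp = np.zeros(n_a) if trans_log_priors is None else np.asarray(trans_log_priors, float)
    if atlas_prior is None:
        lap = np.full(n_a, -np.log(n_a))
    else:
        ap = np.asarray(atlas_prior, dtype=float)
        lap = np.log(ap / ap.sum())
    _, q = _selector_terms(loglik_fields, tlp, lap, radius)
    return q


def fused_label_scores(weights: np.ndarray, per_label_scores: np.ndarray) -> np.ndarray:
    """Likelihood fusion: S(x, k) = sum_a q(x, a) * C[a, k, x]."""
    return np.einsum("a...,ak...->k...", weights, per_label_scores)


def initialize_segmentation(priors: np.ndarray, label_ids: Sequence[int]) -> np.ndarray:
    """Majority vote: per-voxel argmax of the atlas-averaged label prior.

    ``priors`` is (N, K, *dims).  Ties go to the lowest label id (label_ids
    are sorted ascending, argmax takes the first).  Returns label id values.
    """
    if priors.shape[0] < 1:
        raise ValueError("empty atlas set")
    mean_prior = priors.mean(axis=0)
    idx = np.argmax(mean_prior, axis=0)
    return np.asarray(label_ids, dtype=np.int32)[idx]


def maximize_segmentation(scores: np.ndarray, label_ids: Sequence[int],
                          prior_mass: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel argmax over labels; exact ties broken toward the label with
    the larger summed prior mass at that voxel, then the lowest label id."""
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    smax = scores.max(axis=0, keepdims=True)
    is_tie = scores == smax
    if prior_mass is not None and is_tie.sum(axis=0).max() > 1:
        tie_score = np.where(is_tie, prior_mass, -np.inf)
        idx = np.argmax(tie_score, axis=0)
    else:
        idx = np.argmax(scores, axis=0)
    return np.asarray(label_ids, dtype=np.int32)[idx]


def remove_outlier_atlases(initial_segmentation: np.ndarray,
                           warped_labels: Sequence[np.ndarray],
                           structure_ids: Sequence[int],
                           atlas_ids: Sequence[str] | None = None,
                           cut: float = 1.5) -> tuple[list[int], pd.DataFrame]:
    """Robust atlas rejection by agreement with the initial segmentation.

    Each atlas is scored by its mean Dice (over structure labels) against the
    initialization; atlases scoring below ``mean - cut*sd`` are removed, but
    at least ``max(1, ceil(N/2))`` atlases are always retained (best-scoring
    kept).  Returns retained indices and a per-atlas report.
    """
    from likefusion.evaluate import _dice_arrays

    n = len(warped_labels)
    if n < 2:
        raise ValueError("outlier removal needs at least 2 atlases")
    if atlas_ids is None:
        atlas_ids = [f"atlas_{i}" for i in range(n)]
    scores = np.array([
        np.mean([_dice_arrays(w == k, initial_segmentation == k) for k in structure_ids])
        for w in warped_labels
    ])
    m, s = scores.mean(), scores.std()
    threshold = m - cut * s
    keep = [i for i in range(n) if s == 0 or scores[i] >= threshold]
    floor_n = max(1, int(np.ceil(n / 2)))
    if len(keep) < floor_n:
        keep = list(np.argsort(scores)[::-1][:floor_n])
    keep = sorted(keep)
    report = pd.DataFrame({
        "atlas_id": list(atlas_ids),
        "mean_dice_vs_init": scores,
        "retained": [i in keep for i in range(n)],
    })
    return keep, report


# ---------------------------------------------------------------------------
# the full pipeline


def register_atlases(target: IntensityVolume, atlases: Sequence[Atlas],
                     reg_config: RegistrationConfig = RegistrationConfig(),
                     kernel: KernelParams = KernelParams(),
                     ) -> list[tuple[Diffeomorphism, VelocityField, pd.DataFrame]]:
    """Optimized mapping of every atlas onto the target (the mode
    approximation: one diffeomorphism per atlas, reused across EM
    iterations).  Reusable across fusion and single-atlas runs."""
    out = []
    for atlas in atlases:
        logger.info("registering %s", atlas.atlas_id)
        out.append(lddmm_match(atlas.image, target, reg_config, kernel))
    return out


def run_fusion(target: IntensityVolume, atlases: Sequence[Atlas],
               reg_config: RegistrationConfig = RegistrationConfig(),
               fusion_config: FusionConfig = FusionConfig(),
               kernel: KernelParams = KernelParams(),
               registrations: Sequence[tuple] | None = None) -> FusionResult:
    """Segment ``target`` by likelihood fusion over registered atlases.

    1. register every atlas once (mode approximation) and propagate labels;
    2. build chart statistics and interpolated label priors (with generic
       CSF/GM/WM charts for atlas background when enabled);
    3. reject outlier atlases against the majority-vote initialization;
    4. alternate selector (E) and segmentation (M) steps until the fraction
       of changed voxels drops below epsilon or 100 iterations.
    """
    if not atlases:
        raise ValueError("need at least one atlas")
    for atlas in atlases:
        if atlas.image.grid.dims != target.grid.dims:
            raise ValueError("all atlases and the target must share one grid")

    fc = fusion_config
    if registrations is None:
        registrations = register_atlases(target, atlases, reg_config, kernel)
    elif len(registrations) != len(atlases):
        raise ValueError("registrations must match atlases one-to-one")

    # propagated hard labels determine the cuboid ROI
    warped_hard_full = [warp_labels(a.labels, d, "nearest")
                        for a, (d, *_) in zip(atlases, registrations)]
    roi = compute_roi(warped_hard_full, margin_vox=fc.roi_margin)

    # label universe: structures from all atlases, plus generic tissue charts
    structure_ids = sorted({k for a in atlases for k in a.labels.dictionary})
    dictionary: dict[int, str] = {}
    for a in atlases:
        dictionary.update(a.labels.dictionary)
    if fc.use_tissue_charts:
        label_ids = structure_ids + [k for k in TISSUE_LABEL_IDS if k not in structure_ids]
        dictionary.update(TISSUE_NAMES)
    else:
        label_ids = [0] + structure_ids  # catch-all background chart
        dictionary = {0: "background", **dictionary}

    registered: list[RegisteredAtlas] = []
    for i, (atlas, (diffeo, velocity, trace)) in enumerate(zip(atlases, registrations)):
        geo = geodesic_energy(velocity, kernel) if fc.lambda_prior > 0 and velocity is not None else 0.0
        # seed from the atlas id, not the list position: atlas order must not matter
        aug_seed = int(np.random.SeedSequence(
            [fc.seed, zlib.crc32(atlas.atlas_id.encode())]).generate_state(1)[0] % (2 ** 31))
        if fc.use_tissue_charts:
            full_box = RoiBox((0, 0, 0), atlas.labels.grid.dims)
            chart_labels = augment_atlas_tissue(atlas.image, atlas.labels, full_box,
                                                seed=aug_seed)
        else:
            chart_labels = atlas.labels
        stats = estimate_chart_stats(atlas.image, chart_labels)
        prob = warp_labels(chart_labels, diffeo, "prob")
        prior = np.zeros((len(label_ids), *roi.shape), dtype=np.float64)
        for ki, k in enumerate(label_ids):
            if k in prob.label_ids:
                prior[ki] = prob.prob_of(k)[roi.slices()]
        registered.append(RegisteredAtlas(
            atlas.atlas_id, diffeo, velocity, warped_hard_full[i], prior, stats,
            geodesic=geo, reg_trace=trace))

    priors = np.stack([ra.prior for ra in registered])
    init_seg = initialize_segmentation(priors, label_ids)

    outlier_report = None
    if fc.remove_outliers and len(registered) >= 2:
        warped_roi = [ra.warped_labels.labels[roi.slices()] for ra in registered]
        keep, outlier_report = remove_outlier_atlases(
            init_seg, warped_roi, structure_ids,
            atlas_ids=[ra.atlas_id for ra in registered], cut=fc.outlier_cut)
        if len(keep) < len(registered):
            logger.info("removed outlier atlases: %s",
                        [ra.atlas_id for i, ra in enumerate(registered) if i not in keep])
        registered = [registered[i] for i in keep]
        priors = priors[keep]
        init_seg = initialize_segmentation(priors, label_ids)

    n_a = len(registered)
    target_roi = target.values[roi.slices()]
    scores_c = per_atlas_label_scores(target_roi, registered, label_ids)
    prior_mass = priors.sum(axis=0)
    tlp = np.array([transformation_log_prior(ra.velocity, kernel, fc.lambda_prior)
                    for ra in registered])
    log_atlas_prior = np.full(n_a, -np.log(n_a))

    lut = np.full(max(label_ids) + 1, -1, dtype=np.int64)
    lut[np.asarray(label_ids)] = np.arange(len(label_ids))
    seg_idx = lut[init_seg]

    rows = []
    weights = np.ones((n_a, *roi.shape)) / n_a
    prev_objective = -np.inf
    iteration = 0
    for iteration in range(1, fc.max_iters + 1):
        ll = atlas_loglik_field(scores_c, seg_idx)
        b, q = _selector_terms(ll, tlp, log_atlas_prior, fc.selector_radius)
        objective = float(np.sum(logsumexp(b, axis=0)))
        tol = 1e-6 * max(1.0, abs(prev_objective))
        if objective < prev_objective - tol:
            raise RuntimeError(
                f"fused objective decreased at iteration {iteration}: "
                f"{prev_objective:.6f} -> {objective:.6f}")
        prev_objective = objective
        weights = q
        w_sum_err = float(np.abs(q.sum(axis=0) - 1.0).max())
        w_min = float(q.min())
        assert w_sum_err <= 1e-8 and w_min >= 0.0, "selector weights left the simplex"
        # exact M-step weights: window-summed adjoint of the selector weights
        m_w = np.stack([_boxsum(q[ai], fc.selector_radius) for ai in range(n_a)])
        m_w /= np.maximum(m_w.sum(axis=0, keepdims=True), 1e-300)
        fused = fused_label_scores(m_w, scores_c)
        new_idx = lut[maximize_segmentation(fused, label_ids, prior_mass)]
        changed = float(np.mean(new_idx != seg_idx))
        seg_idx = new_idx
        row = {"iteration": iteration, "objective": objective, "changed_frac": changed,
               "w_min": w_min, "w_sum_err": w_sum_err}
        for ai, ra in enumerate(registered):
            row[f"w_mean_{ra.atlas_id}"] = float(q[ai].mean())
        rows.append(row)
        logger.info("iter %d: objective %.4f, changed %.2e", iteration, objective, changed)
        if changed < fc.epsilon:
            break

    seg_roi = np.asarray(label_ids, dtype=np.int32)[seg_idx]
    full = np.zeros(target.grid.dims, dtype=np.int32)
    full[roi.slices()] = seg_roi

    if fc.fill_generic_tissue and np.any(full[roi.slices()] == 0):
        smask = np.zeros(target.grid.dims, dtype=bool)
        smask[roi.slices()] = prior_mass[
            [i for i, k in enumerate(label_ids) if k != 0]].sum(axis=0) > 0.5
        sl = roi.slices()
        bg = target.values[sl][~smask[sl]]
        if bg.size >= 30:
            gmm = fit_tissue_gmm(bg, 3, seed=fc.seed)
            generic = label_generic_tissue(target, roi, full > 0, gmm)
            fill = (full == 0) & (generic.labels > 0)
            full[fill] = generic.labels[fill]
            dictionary.update(TISSUE_NAMES)

    out_dict = {k: v for k, v in dictionary.items() if k != 0}
    segmentation = LabelVolume(target.grid, full, out_dict)
    trace = pd.DataFrame(rows)
    return FusionResult(segmentation, roi, list(label_ids),
                        [ra.atlas_id for ra in registered], weights, trace,
                        outlier_report, registered, iteration)


def single_atlas_map(target: IntensityVolume, atlas: Atlas,
                     reg_config: RegistrationConfig = RegistrationConfig(),
                     fusion_config: FusionConfig = FusionConfig(),
                     kernel: KernelParams = KernelParams(),
                     registration: tuple | None = None) -> FusionResult:
    """Single-atlas MAP segmentation: the N=1 reduction of the fusion model."""
    regs = [registration] if registration is not None else None
    return run_fusion(target, [atlas], reg_config, fusion_config, kernel,
                      registrations=regs)
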