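"""Dice overlap, accuracy tables, and the Monte Carlo permutation test.

The Dice overlap between an automated and a gold-standard segmentation of a
structure is ``2 TP / (2 TP + FP + FN)``.  Group differences are assessed by
Fisher's method of randomization: the Welch t-statistic on the observed split
is compared against its distribution over uniformly random relabelings.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from likefusion.volumes import LabelVolume

__all__ = ["dice", "dice_table", "permutation_test", "compare_single_vs_multi"]


def _dice_arrays(auto_mask: np.ndarray, gold_mask: np.ndarray) -> float:
    tp = int(np.count_nonzero(auto_mask & gold_mask))
    fp = int(np.count_nonzero(auto_mask & ~gold_mask))
    fn = int(np.count_nonzero(~auto_mask & gold_mask))
    if tp + fp + fn == 0:
        return 1.0  # both empty, by convention
    return 2.0 * tp / (2.0 * tp + fp + fn)


def dice(auto: LabelVolume, gold: LabelVolume, label: int) -> float:
    """2 TP / (2 TP + FP + FN); 1 by convention when both sets are empty."""
    if auto.grid.dims != gold.grid.dims:
        raise ValueError("volumes must share one grid")
    return _dice_arrays(auto.labels == label, gold.labels == label)


def dice_table(auto: LabelVolume, gold: LabelVolume,
               labels: Sequence[int] | None = None) -> pd.DataFrame:
    """Per-structure Dice with TP/FP/FN counts and volumes."""
    if auto.grid.dims != gold.grid.dims:
        raise ValueError("volumes must share one grid")
    if labels is None:
        labels = sorted(set(gold.dictionary) | set(auto.dictionary))
    rows = []
    names = {**auto.dictionary, **gold.dictionary}
    for k in labels:
        a = auto.labels == k
        g = gold.labels == k
        tp = int(np.count_nonzero(a & g))
        fp = int(np.count_nonzero(a & ~g))
        fn = int(np.count_nonzero(~a & g))
        d = 1.0 if tp + fp + fn == 0 else 2.0 * tp / (2.0 * tp + fp + fn)
        rows.append({"label": k, "structure": names.get(k, str(k)), "dice": d,
                     "tp": tp, "fp": fp, "fn": fn,
                     "auto_volume": tp + fp, "gold_volume": tp + fn})
    return pd.DataFrame(rows)


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    va = a.var(ddof=1) / len(a)
    vb = b.var(ddof=1) / len(b)
    denom = np.sqrt(va + vb)
    if denom == 0:
        raise ValueError("degenerate groups: zero pooled variance")
    return float((a.mean() - b.mean()) / denom)


def _welch_t_batch(values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Welch t for many group-A index masks over one pooled sample (vectorized)."""
    n = values.size
    na = masks.sum(axis=1)
    nb = n - na
    sum_a = masks @ values
    sum_sq_a = masks @ (values ** 2)
    tot, tot_sq = values.sum(), (values ** 2).sum()
    mean_a = sum_a / na
    mean_b = (tot - sum_a) / nb
    var_a = (sum_sq_a - na * mean_a ** 2) / (na - 1)
    var_b = (tot_sq - sum_sq_a - nb * mean_b ** 2) / (nb - 1)
    denom = np.sqrt(np.maximum(var_a / na + var_b / nb, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / denom
    return np.where(denom == 0, 0.0, t)


def permutation_test(group_a: Sequence[float], group_b: Sequence[float],
                     n_perm: int = 10_000, seed: int = 0,
                     exhaustive: bool = False) -> float:
    """Fisher randomization p-value for a difference between two groups.

    Welch t on the true split, compared two-sidedly (|t|) against t values
    from uniformly random relabelings.  Monte Carlo mode uses add-one
    smoothing, ``p = (#{|t_perm| >= |t_obs|} + 1) / (n_perm + 1)``, so finite
    sampling never reports p = 0; exhaustive mode enumerates every split of
    size len(group_a) and reports the exact fraction (the identity split
    guarantees p > 0).  Deterministic given the seed.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t_obs = abs(_welch_t(a, b))
    pooled = np.concatenate([a, b])
    n, na = pooled.size, len(a)
    if exhaustive:
        combos = list(combinations(range(n), na))
        masks = np.zeros((len(combos), n), dtype=np.float64)
        for i, c in enumerate(combos):
            masks[i, list(c)] = 1.0
        t_perm = np.abs(_welch_t_batch(pooled, masks))
        return float(np.mean(t_perm >= t_obs - 1e-12))
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=np.float64)
    for i in range(n_perm):
        masks[i, rng.choice(n, size=na, replace=False)] = 1.0
    t_perm = np.abs(_welch_t_batch(pooled, masks))
    count = int(np.count_nonzero(t_perm >= t_obs - 1e-12))
    return float((count + 1) / (n_perm + 1))


def compare_single_vs_multi(fusion_tables: Sequence[pd.DataFrame],
                            single_tables: dict[str, Sequence[pd.DataFrame]],
                            n_perm: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Tabulate fusion vs single-atlas Dice per structure across targets.

    ``fusion_tables`` holds one :func:`dice_table` per target from the fusion
    run; ``single_tables`` maps atlas id -> per-target tables from that
    atlas's single-atlas MAP run.  The report has one row per (structure,
    atlas) plus one fusion row per structure, and a randomization p-value
    comparing the pooled single-atlas Dice values against the fusion values
    when both sides have at least two targets.
    """
    rows = []
    structures = fusion_tables[0][["label", "structure"]].drop_duplicates()
    for _, srow in structures.iterrows():
        k, name = int(srow["label"]), srow["structure"]
        fusion_vals = [float(t.loc[t["label"] == k, "dice"].iloc[0]) for t in fusion_tables]
        single_vals_all = []
        for atlas_id, tables in single_tables.items():
            vals = [float(t.loc[t["label"] == k, "dice"].iloc[0]) for t in tables]
            single_vals_all.extend(vals)
            rows.append({"structure": name, "label": k, "method": f"single:{atlas_id}",
                         "mean_dice": float(np.mean(vals)), "n": len(vals), "p_vs_fusion": np.nan})
        p = np.nan
        if len(fusion_vals) >= 2 and len(single_vals_all) >= 2:
            try:
                p = permutation_test(single_vals_all, fusion_vals, n_perm=n_perm, seed=seed)
            except ValueError:
                p = np.nan
        rows.append({"structure": name, "label": k, "method": "fusion",
                     "mean_dice": float(np.mean(fusion_vals)), "n": len(fusion_vals),
                     "p_vs_fusion": p})
    return pd.DataFrame(rows)
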