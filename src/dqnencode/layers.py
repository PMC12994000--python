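"""Mapping layer-wise encoding accuracy onto the cortical hierarchy.

Every voxel surviving the group significance gate is assigned to the
network layer whose layer-specific encoding model predicted it best
("winner layer"). Per ROI, the composition of winner layers is summarized
as a proportion vector over the five hidden layers, and the balance of
early (conv1-3) versus late (lstm, layer4) layers is tested across ROIs on
the log-ratio scale, which makes t-tests valid on compositional data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .network import HIDDEN_LAYERS

EARLY_LAYERS = ("conv1", "conv2", "conv3")
LATE_LAYERS = ("lstm", "layer4")


@dataclass
class LayerAssignment:
    winner: np.ndarray        # per-voxel layer label ("" outside the gate)
    winner_r: np.ndarray      # winning layer-wise mean correlation
    eligible_mask: np.ndarray
    n_ties: int = 0


def assign_winner_layer(
    layerwise_r: pd.DataFrame, eligibility: np.ndarray
) -> LayerAssignment:
    """Argmax over layer-wise correlations per eligible voxel.

    layerwise_r: voxels x layers table with all five hidden-layer columns.
    Exact ties are broken toward the earlier layer in network order
    (conservative for hierarchy claims) and counted.
    """
    missing = [l for l in HIDDEN_LAYERS if l not in layerwise_r.columns]
    if missing:
        raise ValueError(f"missing layer columns {missing}")
    r = layerwise_r[list(HIDDEN_LAYERS)].to_numpy(dtype=float)
    eligibility = np.asarray(eligibility, dtype=bool)
    if eligibility.shape[0] != r.shape[0]:
        raise ValueError("eligibility mask must align with the voxel table")
    best = r.max(axis=1)
    # argmax returns the first (earliest-layer) index on ties
    idx = r.argmax(axis=1)
    n_ties = int((np.sum(r == best[:, None], axis=1) > 1)[eligibility].sum())
    if n_ties:
        warnings.warn(f"{n_ties} exact winner-layer tie(s); earlier layer kept",
                      RuntimeWarning)
    winner = np.where(eligibility, np.array(HIDDEN_LAYERS, dtype=object)[idx], "")
    winner_r = np.where(eligibility, best, np.nan)
    return LayerAssignment(winner.astype(str), winner_r, eligibility, n_ties)


def roi_layer_proportions(
    assignment: LayerAssignment, roi_masks: dict
) -> pd.DataFrame:
    """Fraction of eligible voxels per ROI assigned to each layer.

    roi_masks maps ROI name -> boolean mask over voxels (handled
    independently per ROI). ROIs with no eligible voxels are excluded with
    a warning. Each returned row sums to 1.
    """
    rows = {}
    for name, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        sel = mask & assignment.eligible_mask
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"ROI {name!r} has no eligible voxels; excluded", RuntimeWarning)
            continue
        winners = assignment.winner[sel]
        rows[name] = [float(np.sum(winners == l)) / n for l in HIDDEN_LAYERS]
    if not rows:
        raise ValueError("no ROI has eligible voxels")
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(HIDDEN_LAYERS))


def early_late_logratio(proportions: np.ndarray, pseudo_count: float = 0.0) -> float:
    """log of (early layer mass / late layer mass) with symmetric pseudo-count.

    proportions: length-5 composition in HIDDEN_LAYERS order. The additive
    pseudo-count keeps the ratio finite when one side is empty; a sensible
    default is 1/(2 * n_voxels_in_roi).
    """
    p = np.asarray(proportions, dtype=float)
    if p.shape != (len(HIDDEN_LAYERS),):
        raise ValueError(f"expected a {len(HIDDEN_LAYERS)}-part composition")
    early = p[:3].sum()
    late = p[3:].sum()
    return float(np.log((early + pseudo_count) / (late + pseudo_count)))


def compare_roi_ratios(logratios: pd.DataFrame, roi_pairs: list | None = None) -> pd.DataFrame:
    """Paired t-tests on per-subject early/late log-ratios across ROI pairs.

    logratios: subjects x ROIs table. All pairs are tested by default;
    p values are Bonferroni-adjusted over the number of pairs.
    """
    if logratios.shape[0] < 2:
        raise ValueError("need at least 2 subjects for paired tests")
    if logratios.isna().any().any():
        raise ValueError("unpaired (missing) log-ratio data")
    pairs = roi_pairs or list(combinations(logratios.columns, 2))
    k = len(pairs)
    rows = []
    for a, b in pairs:
        diff = logratios[a] - logratios[b]
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(logratios[a], logratios[b])
        rows.append({"roi_a": a, "roi_b": b, "mean_diff": float(diff.mean()),
                     "t": float(t), "p_raw": float(p),
                     "p_adj": float(min(1.0, k * p))})
    return pd.DataFrame(rows)
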