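"""Second-level (across-subject) statistics for encoding accuracy maps.

Per-subject correlation maps are Fisher Z-transformed, tested voxel-wise
against zero with one-sample t-tests, and corrected for family-wise error
by Bonferroni over the in-mask voxels (a conservative, assumption-free
stand-in for random-field-theory correction, which needs smoothness
estimates of real maps). ROI-level questions use two-sample t-tests,
repeated-measures ANOVA with Greenhouse-Geisser correction and partial
eta-squared effect sizes, user-supplied contrasts with Bonferroni
adjustment, and within-subject (Cousineau-Morey) normalized confidence
intervals for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

FISHER_CLIP = 1.0 - 1e-7


@dataclass
class GroupMap:
    z_maps: np.ndarray          # subjects x voxels
    t_map: np.ndarray           # voxels
    p_corrected: np.ndarray     # voxels, FWE-adjusted
    significant_mask: np.ndarray  # voxels, bool at alpha
    excluded: np.ndarray        # voxels with undefined t (zero variance)
    alpha: float = 0.05


def fisher_z(r_map: np.ndarray) -> np.ndarray:
    """atanh transform of correlations; |r| = 1 clipped just inside (-1, 1)."""
    r = np.asarray(r_map, dtype=float)
    n_clip = int(np.sum(np.abs(r) >= 1))
    if n_clip:
        warnings.warn(f"fisher_z clipped {n_clip} value(s) at |r|=1", RuntimeWarning)
    return np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))


def one_sample_fwe(z_maps: np.ndarray, alpha: float = 0.05) -> GroupMap:
    """Voxel-wise one-sample t against 0 with Bonferroni FWE control.

    z_maps: subjects x voxels Fisher-Z values (>= 3 subjects). Voxels with
    zero across-subject variance have no defined t and are excluded.
    """
    z = np.atleast_2d(np.asarray(z_maps, dtype=float))
    n_sub, n_vox = z.shape
    if n_sub < 3:
        raise ValueError("need at least 3 subjects for a group test")
    sd = z.std(axis=0, ddof=1)
    excluded = sd == 0
    t_map = np.full(n_vox, np.nan)
    p_corr = np.ones(n_vox)
    valid = ~excluded
    if valid.any():
        t, p = stats.ttest_1samp(z[:, valid], 0.0, axis=0)
        t_map[valid] = t
        p_corr[valid] = np.minimum(p * n_vox, 1.0)  # Bonferroni over in-mask voxels
    sig = np.zeros(n_vox, dtype=bool)
    sig[valid] = p_corr[valid] < alpha
    return GroupMap(z, t_map, p_corr, sig, excluded, alpha)


def two_sample_roi_test(z_a: np.ndarray, z_b: np.ndarray) -> tuple[float, float]:
    """Two-sample t on subject-level ROI-mean Fisher-Z values."""
    a = np.asarray(z_a, dtype=float)
    b = np.asarray(z_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 subjects")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def rm_anova_gg(data: pd.DataFrame, dv: str, within, subject: str) -> pd.DataFrame:
    """Repeated-measures ANOVA with Greenhouse-Geisser correction.

    data must be a complete, balanced long-format table. ``within`` is one
    factor name or a list of two. Returns one row per effect with F,
    GG-corrected degrees of freedom (eps * uncorrected df), epsilon,
    partial eta-squared, and the GG-corrected p value.
    """
    within_list = [within] if isinstance(within, str) else list(within)
    expected = 1
    for f in within_list:
        expected *= data[f].nunique()
    counts = data.groupby(subject, observed=True)[dv].count()
    cells = data.groupby([subject] + within_list, observed=True)[dv].count()
    if counts.nunique() != 1 or counts.iloc[0] != expected or cells.max() != 1:
        raise ValueError("design must be complete and balanced (no missing cells)")
    aov = pg.rm_anova(
        data=data, dv=dv, within=within_list if len(within_list) > 1 else within_list[0],
        subject=subject, detailed=True, effsize="np2", correction=True,
    )
    if "ddof1" not in aov.columns:  # one-way layout: effect rows + Error row
        err = aov.loc[aov["Source"] == "Error", "DF"].iloc[0]
        aov = aov[aov["Source"] != "Error"].copy()
        aov["ddof1"] = aov["DF"]
        aov["ddof2"] = err
    else:
        aov = aov[aov["Source"] != "Error"].copy()
    eps = (aov["eps"] if "eps" in aov.columns else pd.Series(1.0, index=aov.index))
    aov["eps"] = eps.fillna(1.0).astype(float)
    aov["df1_gg"] = aov["ddof1"] * aov["eps"]
    aov["df2_gg"] = aov["ddof2"] * aov["eps"]
    pcol = next((c for c in ("p_GG_corr", "p-GG-corr") if c in aov.columns), "p_unc")
    aov["p_gg"] = aov[pcol].fillna(aov["p_unc"])
    return aov[["Source", "F", "ddof1", "ddof2", "eps", "df1_gg", "df2_gg",
                "np2", "p_gg"]].reset_index(drop=True)


def contrast_tests(
    data: np.ndarray,
    contrasts: list,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Within-subject contrast t-tests with Bonferroni adjustment.

    data: subjects x conditions matrix of per-subject means; each contrast
    is a zero-sum weight vector over conditions. The contrast score per
    subject is data @ w, tested against 0 with a one-sample t.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    k = len(contrasts)
    rows = []
    for i, w in enumerate(contrasts):
        w = np.asarray(w, dtype=float)
        if w.shape != (x.shape[1],):
            raise ValueError("contrast length must equal the number of conditions")
        if abs(w.sum()) > 1e-10:
            raise ValueError(f"contrast {i} weights must sum to 0 (got {w.sum()})")
        scores = x @ w
        t, p = stats.ttest_1samp(scores, 0.0)
        p_adj = min(1.0, k * p) if correction == "bonferroni" else p
        rows.append({"contrast": i, "estimate": scores.mean(), "t": float(t),
                     "p_raw": float(p), "p_adj": float(p_adj)})
    return pd.DataFrame(rows)


def normalized_ci(data: np.ndarray, level: float = 0.95) -> np.ndarray:
    """Within-subject (Cousineau-Morey) CI half-widths per condition.

    Each subject's mean is removed and the grand mean restored, the
    condition-wise CI of the adjusted scores is computed, and the
    half-width is inflated by sqrt(M/(M-1)) for M conditions.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    n, m = x.shape
    if m < 2:
        raise ValueError("Morey normalization needs at least 2 conditions")
    adjusted = x - x.mean(axis=1, keepdims=True) + x.mean()
    sem = adjusted.std(axis=0, ddof=1) / np.sqrt(n)
    t_crit = stats.t.ppf((1.0 + level) / 2.0, n - 1)
    return t_crit * sem * np.sqrt(m / (m - 1.0))
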