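"""Predictor construction and nuisance removal for the encoding GLM.

The temporal pipeline that turns unit activation series (45 Hz) into
GLM-ready predictors on the scanner's volume grid is, in order:

1. drop units that were never active,
2. z-score along time then across units ("dual" standardization),
3. convolve with a canonical double-gamma haemodynamic response function,
4. linearly resample to the acquisition times (one sample per TR),
5. remove slow drift with a discrete-cosine high-pass basis (128 s cutoff),
6. re-standardize each predictor along time.

Voxel data are residualized against the six head-motion parameters plus the
same high-pass basis before any model fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .frames import FrameSequence
from .network import FeatureTimeSeries

#: rows with variance below this are treated as constant
VARIANCE_EPS = 1e-12


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scanner timing: TR 0.987 s, 45 Hz stimulus rate, 128 s high-pass."""

    tr_seconds: float = 0.987
    stim_rate_hz: float = 45.0
    highpass_cutoff_seconds: float = 128.0
    n_volumes: int = 425

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.highpass_cutoff_seconds <= 2 * self.tr_seconds:
            raise ValueError("high-pass cutoff must exceed 2*TR")

    @staticmethod
    def volumes_for_duration(duration_seconds: float, tr_seconds: float = 0.987) -> int:
        """Volume count under the floor convention: floor(duration / TR)."""
        return int(np.floor(duration_seconds / tr_seconds))


@dataclass(frozen=True)
class HrfSpec:
    """Canonical double-gamma HRF (SPM convention).

    Peak gamma with delay 6 s / dispersion 1 s, undershoot with delay 16 s /
    dispersion 1 s, peak:undershoot amplitude ratio 6, 32 s support. With
    shape a = delay/dispersion and scale = dispersion the peak density's
    mode sits at (a-1)*scale = 5 s.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    duration: float = 32.0

    def __post_init__(self) -> None:
        for name in ("peak_delay", "undershoot_delay", "peak_dispersion",
                     "undershoot_dispersion", "peak_undershoot_ratio", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"HrfSpec.{name} must be positive")


@dataclass
class DesignMatrix:
    """Predictors x volumes matrix with per-predictor layer labels."""

    values: np.ndarray
    predictor_layer: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.predictor_layer = np.asarray(self.predictor_layer).astype(str)
        if self.values.ndim != 2:
            raise ValueError("design values must be P x N")
        if self.predictor_layer.shape[0] != self.values.shape[0]:
            raise ValueError("one layer label per predictor required")

    @property
    def n_predictors(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_volumes(self) -> int:
        return int(self.values.shape[1])


@dataclass
class VoxelSeries:
    """Voxels x volumes BOLD matrix with grid coordinates."""

    values: np.ndarray
    voxel_coordinates: np.ndarray
    mask_id: str = "mask"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_coordinates = np.asarray(self.voxel_coordinates)
        if self.values.ndim != 2:
            raise ValueError("voxel values must be V x N")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voxel values must be finite")
        if self.voxel_coordinates.shape[0] != self.values.shape[0]:
            raise ValueError("one coordinate row per voxel required")

    @property
    def n_voxels(self) -> int:
        return int(self.values.shape[0])


def drop_inactive_units(
    f: FeatureTimeSeries, extra_sessions: list | None = None
) -> FeatureTimeSeries:
    """Remove units that were never active during feature generation.

    A unit survives if its series is nonzero anywhere; when
    ``extra_sessions`` (other sessions of the same subject) are given the
    union of all sessions decides, so predictor identity is constant across
    cross-validation folds.
    """
    active = np.any(f.values != 0, axis=1)
    for other in extra_sessions or []:
        if other.n_units != f.n_units:
            raise ValueError("sessions disagree on unit count")
        active |= np.any(other.values != 0, axis=1)
    if not active.any():
        raise ValueError("all units inactive: degenerate feature set")
    return FeatureTimeSeries(f.values[active], f.unit_layer[active], f.rate_hz)


def active_unit_mask(sessions: list) -> np.ndarray:
    """Boolean mask of units active in at least one of the sessions."""
    active = np.zeros(sessions[0].n_units, dtype=bool)
    for s in sessions:
        active |= np.any(s.values != 0, axis=1)
    return active


def zscore_rows(m: np.ndarray) -> np.ndarray:
    """Z-score each row along time with the n-1 (sample) sd."""
    m = np.asarray(m, dtype=float)
    sd = m.std(axis=1, ddof=1)
    bad = np.where(sd * sd < VARIANCE_EPS)[0]
    if bad.size:
        raise ValueError(f"constant rows cannot be z-scored: units {bad.tolist()[:10]}")
    return (m - m.mean(axis=1, keepdims=True)) / sd[:, None]


def zscore_dual(m: np.ndarray, order: str = "temporal_first") -> np.ndarray:
    """Standardize along both the temporal and the feature dimension.

    ``temporal_first`` (default) z-scores each unit's series over time, then
    z-scores each time point across units; ``feature_first`` reverses the
    two passes. The feature pass is skipped when only one row exists (an
    across-feature sd is then undefined).
    """
    m = np.asarray(m, dtype=float)
    if order not in ("temporal_first", "feature_first"):
        raise ValueError("order must be 'temporal_first' or 'feature_first'")

    def _feature_pass(x: np.ndarray) -> np.ndarray:
        if x.shape[0] < 2:
            return x
        sd = x.std(axis=0, ddof=1)
        sd = np.where(sd * sd < VARIANCE_EPS, 1.0, sd)
        return (x - x.mean(axis=0, keepdims=True)) / sd

    if order == "temporal_first":
        return _feature_pass(zscore_rows(m))
    return zscore_rows(_feature_pass(m))


def hrf_kernel(h: HrfSpec = HrfSpec(), rate_hz: float = 45.0) -> np.ndarray:
    """Sample the double-gamma HRF at ``rate_hz`` over its support.

    Difference of two gamma densities (shape = delay/dispersion,
    scale = dispersion), undershoot scaled by 1/ratio, peak normalized to 1.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    t = np.arange(0.0, h.duration, 1.0 / rate_hz)
    peak = stats.gamma.pdf(t, a=h.peak_delay / h.peak_dispersion, scale=h.peak_dispersion)
    under = stats.gamma.pdf(
        t, a=h.undershoot_delay / h.undershoot_dispersion, scale=h.undershoot_dispersion
    )
    kernel = peak - under / h.peak_undershoot_ratio
    return kernel / kernel.max()


def convolve_hrf(m: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution of each row with the HRF, truncated to T."""
    m = np.atleast_2d(np.asarray(m, dtype=float))
    t = m.shape[1]
    out = np.empty_like(m)
    for i in range(m.shape[0]):
        out[i] = np.convolve(m[i], kernel)[:t]
    return out


def resample_to_tr(m: np.ndarray, acq: AcquisitionSpec, rate_hz: float | None = None) -> np.ndarray:
    """Linearly interpolate each row at the acquisition times k*TR."""
    m = np.atleast_2d(np.asarray(m, dtype=float))
    rate = acq.stim_rate_hz if rate_hz is None else rate_hz
    t_stim = np.arange(m.shape[1]) / rate
    t_acq = np.arange(acq.n_volumes) * acq.tr_seconds
    if t_acq[-1] > t_stim[-1] + 1e-9:
        raise ValueError(
            f"acquisition extends to {t_acq[-1]:.3f}s but stimulus ends at {t_stim[-1]:.3f}s"
        )
    out = np.empty((m.shape[0], acq.n_volumes))
    for i in range(m.shape[0]):
        out[i] = np.interp(t_acq, t_stim, m[i])
    return out


def dct_highpass_basis(n_volumes: int, tr_seconds: float, cutoff_seconds: float) -> np.ndarray:
    """Orthonormal DCT drift basis: constant plus cosines with period > cutoff.

    Component k of the type-II cosine set has period 2*N*TR/k; all k with
    k < 2*N*TR/cutoff are included. Returns an (N, K+1) orthonormal matrix.
    """
    if cutoff_seconds <= 2 * tr_seconds:
        raise ValueError("cutoff must exceed 2*TR")
    n = n_volumes
    k_max = int(np.floor(2.0 * n * tr_seconds / cutoff_seconds))
    grid = np.arange(n)
    cols = [np.ones(n) / np.sqrt(n)]
    for k in range(1, k_max + 1):
        c = np.cos(np.pi * k * (2 * grid + 1) / (2.0 * n))
        cols.append(c * np.sqrt(2.0 / n))
    return np.column_stack(cols)


def highpass_dct(m: np.ndarray, acq: AcquisitionSpec) -> np.ndarray:
    """Residualize each row against the DCT drift basis (cutoff 128 s)."""
    m = np.atleast_2d(np.asarray(m, dtype=float))
    if m.shape[1] < 4:
        raise ValueError("need at least 4 time points for high-pass filtering")
    basis = dct_highpass_basis(m.shape[1], acq.tr_seconds, acq.highpass_cutoff_seconds)
    return m - (m @ basis) @ basis.T


def assemble_design(
    f: FeatureTimeSeries,
    layer_selection: str | list = "all",
    acq: AcquisitionSpec = AcquisitionSpec(),
    hrf: HrfSpec = HrfSpec(),
    extra_sessions: list | None = None,
    zscore_order: str = "temporal_first",
) -> DesignMatrix:
    """Full predictor pipeline: filter, standardize, convolve, resample, detrend.

    ``extra_sessions`` carries the subject's other sessions so the
    inactive-unit filter uses the whole session set. Layer labels travel
    with their units through every stage.
    """
    selected = f.select_layers(layer_selection)
    extras = [s.select_layers(layer_selection) for s in (extra_sessions or [])]
    active = drop_inactive_units(selected, extras or None)
    z = zscore_dual(active.values, order=zscore_order)
    conv = convolve_hrf(z, hrf_kernel(hrf, rate_hz=active.rate_hz))
    tr_grid = resample_to_tr(conv, acq, rate_hz=active.rate_hz)
    filtered = highpass_dct(tr_grid, acq)
    final = zscore_rows(filtered)
    return DesignMatrix(values=final, predictor_layer=active.unit_layer, standardized=True)


def motion_residualize(
    v: VoxelSeries, motion: np.ndarray, acq: AcquisitionSpec = AcquisitionSpec()
) -> VoxelSeries:
    """OLS-residualize voxels against motion, drift basis, and a constant.

    The six rigid-body motion parameters and the 128 s DCT basis are
    regressed out of every voxel; the residuals are the motion-corrected
    series used by the encoding models.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2:
        raise ValueError("motion must be a 2-D parameters x volumes array")
    if motion.shape[0] > motion.shape[1] and motion.shape[1] == 6:
        motion = motion.T  # accept volumes x 6 layout
    n = v.values.shape[1]
    if motion.shape[1] != n:
        raise ValueError("motion parameters not aligned with voxel series")
    basis = dct_highpass_basis(n, acq.tr_seconds, acq.highpass_cutoff_seconds)
    reg = np.column_stack([motion.T, basis])
    if np.linalg.matrix_rank(reg) < reg.shape[1]:
        raise ValueError("rank-deficient nuisance regressor matrix")
    coef, *_ = np.linalg.lstsq(reg, v.values.T, rcond=None)
    resid = v.values.T - reg @ coef
    return VoxelSeries(resid.T, v.voxel_coordinates, v.mask_id)


def pixel_control_design(
    seq: FrameSequence,
    acq: AcquisitionSpec = AcquisitionSpec(),
    hrf: HrfSpec = HrfSpec(),
    block_factor: int = 1,
    zscore_order: str = "temporal_first",
) -> DesignMatrix:
    """Control model: raw screen pixels (optionally block-averaged) as predictors."""
    frames = seq.frames.astype(float)
    t, h, w = frames.shape
    if block_factor > 1:
        if h % block_factor or w % block_factor:
            raise ValueError("block_factor must divide the frame size")
        frames = frames.reshape(
            t, h // block_factor, block_factor, w // block_factor, block_factor
        ).mean(axis=(2, 4))
    series = frames.reshape(t, -1).T
    varying = series.var(axis=1) >= VARIANCE_EPS
    if not varying.any():
        raise ValueError("all pixel predictors constant: degenerate stimulus")
    labels = np.array(["conv1"] * int(varying.sum()))  # pixel-level = earliest stage
    f = FeatureTimeSeries(series[varying], labels, seq.rate_hz)
    z = zscore_dual(f.values, order=zscore_order)
    conv = convolve_hrf(z, hrf_kernel(hrf, rate_hz=f.rate_hz))
    tr_grid = resample_to_tr(conv, acq, rate_hz=f.rate_hz)
    return DesignMatrix(
        values=zscore_rows(highpass_dct(tr_grid, acq)),
        predictor_layer=labels,
        standardized=True,
    )


def motor_control_design(
    actions: np.ndarray,
    acq: AcquisitionSpec = AcquisitionSpec(),
    hrf: HrfSpec = HrfSpec(),
    rate_hz: float = 45.0,
    known_actions: list | None = None,
) -> DesignMatrix:
    """Control model: one indicator predictor per button press code.

    Action code 0 denotes "no press" and produces no predictor; each other
    code (or code combination the log contains) becomes an impulse train.
    """
    actions = np.asarray(actions)
    codes = [c for c in np.unique(actions) if c != 0]
    if known_actions is not None:
        unknown = set(codes) - set(known_actions)
        if unknown:
            raise ValueError(f"unknown action codes {sorted(unknown)}")
    if not codes:
        raise ValueError("no button presses in the action log: all predictors inactive")
    series = np.stack([(actions == c).astype(float) for c in codes])
    labels = np.array(["output"] * len(codes))  # motor codes sit at the action end
    z = zscore_rows(series)
    if len(codes) > 1:
        z = zscore_dual(series)
    conv = convolve_hrf(z, hrf_kernel(hrf, rate_hz=rate_hz))
    tr_grid = resample_to_tr(conv, acq, rate_hz=rate_hz)
    return DesignMatrix(
        values=zscore_rows(highpass_dct(tr_grid, acq)),
        predictor_layer=labels,
        standardized=True,
    )
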