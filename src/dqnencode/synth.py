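"""Synthetic study generator with recoverable ground truth.

Everything the real study measures has a seeded synthetic counterpart here:

* a toy visuomotor game (bouncing ball + tracking paddle on an 84x84
  grid) standing in for arcade gameplay, with episode terminals, action and
  reward logs at 45 Hz and 18,900 frames per 7-minute session;
* fixture network weights (variance-scaled random initialization) so the
  feature extractor runs without reinforcement-learning training;
* smooth per-layer activation series for cohorts where the network forward
  pass itself is not under test;
* BOLD voxel series generated as sparse linear mixtures of pipeline-
  processed layer predictors plus motion confounds and AR(1) noise, with
  every voxel's source layer, support, weights and noise ceiling recorded.

The generative model is deliberately the linear encoding model the
analysis assumes, which makes parameter recovery well-posed: a voxel with
signal variance s and noise variance n has correlation ceiling
sqrt(s/(s+n)) = sqrt(SNR/(1+SNR)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .design import AcquisitionSpec, DesignMatrix, HrfSpec, VoxelSeries, assemble_design
from .frames import FrameSequence
from .network import HIDDEN_LAYERS, FeatureTimeSeries, NetworkSpec, NetworkWeights, init_weights


@dataclass
class ToyGameConfig:
    """Toy game emulating the study's stimulus statistics."""

    grid_size: int = 84
    ball_size: int = 3
    paddle_width: int = 12
    paddle_height: int = 2
    ball_speed: float = 1.5
    paddle_speed: float = 2.0
    miss_prob: float = 0.02       # per-frame chance the scripted policy freezes
    session_minutes: float = 7.0
    rate_hz: float = 45.0
    n_sessions: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 2 * self.ball_size + self.paddle_height + 2:
            raise ValueError("degenerate grid: too small for the sprites")

    @property
    def session_frames(self) -> int:
        """Frames per session: duration_minutes * 60 * rate (7 min -> 18,900)."""
        return int(round(self.session_minutes * 60.0 * self.rate_hz))


def _render(cfg: ToyGameConfig, bx: float, by: float, px: float,
            background: np.ndarray | None = None) -> np.ndarray:
    g = cfg.grid_size
    frame = (np.zeros((g, g), dtype=np.uint8) if background is None
             else background.copy())
    x0, y0 = int(round(bx)), int(round(by))
    frame[max(0, y0):min(g, y0 + cfg.ball_size), max(0, x0):min(g, x0 + cfg.ball_size)] = 255
    p0 = int(round(px))
    frame[g - cfg.paddle_height:, max(0, p0):min(g, p0 + cfg.paddle_width)] = 180
    return frame


def generate_toy_game(cfg: ToyGameConfig = ToyGameConfig()) -> list[FrameSequence]:
    """Render seeded sessions of the toy game.

    A ball bounces off the walls and ceiling; a scripted paddle tracks it,
    occasionally freezing (miss_prob) so that genuine episode terminals
    occur. Actions: 0 stay, 1 left, 2 right. Reward +1 per paddle bounce.
    The last frame of each session is always flagged terminal (end of
    session ends the episode), so every session has at least one terminal.
    """
    rng = np.random.default_rng(cfg.seed)
    g, t_total = cfg.grid_size, cfg.session_frames
    sessions = []
    for _ in range(cfg.n_sessions):
        # static playfield texture (screens are not blank in real games)
        background = rng.integers(0, 60, size=(g, g)).astype(np.uint8)
        frames = np.empty((t_total, g, g), dtype=np.uint8)
        terminal = np.zeros(t_total, dtype=bool)
        actions = np.zeros(t_total, dtype=int)
        rewards = np.zeros(t_total)

        def reset_ball():
            angle = rng.uniform(np.pi / 4, 3 * np.pi / 4)
            return (rng.uniform(g / 4, 3 * g / 4), float(cfg.ball_size),
                    cfg.ball_speed * np.cos(angle), cfg.ball_speed * np.sin(angle))

        bx, by, vx, vy = reset_ball()
        px = (g - cfg.paddle_width) / 2.0
        frozen = 0
        for t in range(t_total):
            target = bx + cfg.ball_size / 2.0 - cfg.paddle_width / 2.0
            if frozen > 0:
                frozen -= 1
                actions[t] = 0
            elif rng.random() < cfg.miss_prob:
                frozen = int(rng.integers(20, 90))
                actions[t] = 0
            else:
                step = np.clip(target - px, -cfg.paddle_speed, cfg.paddle_speed)
                px = float(np.clip(px + step, 0, g - cfg.paddle_width))
                actions[t] = 0 if step == 0 else (1 if step < 0 else 2)
            bx += vx
            by += vy
            if bx <= 0 or bx >= g - cfg.ball_size:
                vx = -vx
                bx = float(np.clip(bx, 0, g - cfg.ball_size))
            if by <= 0:
                vy = -vy
                by = 0.0
            bottom = g - cfg.paddle_height - cfg.ball_size
            if by >= bottom:
                caught = (bx + cfg.ball_size > px) and (bx < px + cfg.paddle_width)
                if caught:
                    vy = -abs(vy)
                    by = float(bottom)
                    rewards[t] = 1.0
                else:
                    terminal[t] = True
                    bx, by, vx, vy = reset_ball()
            frames[t] = _render(cfg, bx, by, px, background)
        terminal[-1] = True
        sessions.append(FrameSequence(frames, terminal, actions, rewards, cfg.rate_hz))
    return sessions


def make_fixture_weights(spec: NetworkSpec, seed: int = 0, scale: float = 1.0) -> NetworkWeights:
    """Seeded variance-scaled fixture weights (training is out of scope)."""
    return init_weights(spec, seed=seed, scale=scale)


def synth_layer_features(
    n_timepoints: int,
    units_per_layer: int = 8,
    rate_hz: float = 45.0,
    smooth_seconds: float = 0.5,
    seed: int = 0,
    layers: tuple = HIDDEN_LAYERS,
) -> FeatureTimeSeries:
    """Smooth random activation series with per-layer nonlinearity.

    Gaussian-filtered white noise per unit; conv/layer4 series pass through
    ReLU (non-negative, many exact zeros, like real rectified units), lstm
    series through tanh (bounded in [-1, 1]).
    """
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    sigma = smooth_seconds * rate_hz
    for layer in layers:
        raw = gaussian_filter1d(
            rng.standard_normal((units_per_layer, n_timepoints)), sigma, axis=1
        )
        raw /= raw.std(axis=1, keepdims=True)
        if layer == "lstm":
            act = np.tanh(raw)
        elif layer == "output":
            act = raw
        else:
            act = np.maximum(raw, 0.0)
        blocks.append(act)
        labels += [layer] * units_per_layer
    return FeatureTimeSeries(np.concatenate(blocks), np.array(labels), rate_hz)


def ar1_noise(rng: np.random.Generator, shape: tuple, sd: float, phi: float) -> np.ndarray:
    """AR(1) series with marginal standard deviation ``sd``."""
    n_series, n = shape
    x = np.empty(shape)
    x[:, 0] = rng.normal(0.0, sd, n_series)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    e = rng.normal(0.0, innov_sd, (n_series, n))
    for t in range(1, n):
        x[:, t] = phi * x[:, t - 1] + e[:, t]
    return x


def smooth_motion(rng: np.random.Generator, n_volumes: int, n_params: int = 6) -> np.ndarray:
    """Six slow head-motion nuisance series (params x volumes), unit variance."""
    m = gaussian_filter1d(rng.standard_normal((n_params, n_volumes)), 8.0, axis=1)
    return (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, keepdims=True)


def simulate_bold(
    features_by_session: dict,
    voxel_layers: np.ndarray,
    sparsity: int = 3,
    snr: float = 1.0,
    phi: float = 0.3,
    motion: list | None = None,
    motion_amp: float = 0.0,
    seed: int = 0,
    voxel_coordinates: np.ndarray | None = None,
) -> tuple[list, pd.DataFrame]:
    """Generate voxel series as sparse mixtures of layer predictors.

    features_by_session: layer label -> list of per-session DesignMatrix
    (predictors already on the TR grid via the design pipeline).
    voxel_layers: per-voxel source layer label. Each voxel draws
    ``sparsity`` predictors from its designated layer, mixes them with
    Gaussian weights identical across sessions, optionally adds motion
    confounds, and adds AR(1) noise scaled to the requested SNR
    (signal variance / noise variance).

    Returns (one VoxelSeries per session, ground-truth table).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    voxel_layers = np.asarray(voxel_layers).astype(str)
    n_vox = voxel_layers.size
    layer_names = list(features_by_session)
    n_sessions = len(features_by_session[layer_names[0]])
    n_vols = [features_by_session[layer_names[0]][s].n_volumes for s in range(n_sessions)]

    signals = [np.zeros((n_vox, n)) for n in n_vols]
    records = []
    for v in range(n_vox):
        layer = voxel_layers[v]
        if layer not in features_by_session:
            raise ValueError(f"voxel {v} requests unknown layer {layer!r}")
        designs = features_by_session[layer]
        p = designs[0].n_predictors
        k = min(sparsity, p)
        support = rng.choice(p, size=k, replace=False)
        w = rng.normal(0.0, 1.0, k)
        sig = [d.values[support].T @ w for d in designs]
        var_sig = np.var(np.concatenate(sig))
        noise_sd = np.sqrt(var_sig / snr)
        for s in range(n_sessions):
            signals[s][v] = sig[s]
        records.append({
            "voxel": v, "source_layer": layer,
            "support": tuple(int(i) for i in support),
            "weights": tuple(float(x) for x in w),
            "noise_sd": float(noise_sd), "phi": phi,
            "ceiling_r": float(np.sqrt(snr / (1.0 + snr))),
        })
    truth = pd.DataFrame(records)

    coords = (voxel_coordinates if voxel_coordinates is not None
              else np.arange(n_vox)[:, None])
    out = []
    for s in range(n_sessions):
        noise = ar1_noise(rng, (n_vox, n_vols[s]), 1.0, phi) * truth["noise_sd"].to_numpy()[:, None]
        values = signals[s] + noise
        if motion is not None and motion_amp > 0:
            gam = rng.normal(0.0, motion_amp, (n_vox, motion[s].shape[0]))
            values = values + gam @ motion[s]
        out.append(VoxelSeries(values, coords, mask_id="synthetic"))
    return out, truth


def make_toy_rois(
    volume_shape: tuple = (20, 20, 20),
    n_rois: int = 5,
    voxels_per_roi: int = 200,
) -> dict:
    """Disjoint rectangular ROI masks mimicking a cortical hierarchy.

    ROIs are slabs along the first axis, each holding ``voxels_per_roi``
    voxels; each ROI is meant to source its voxels from one network layer
    in simulate_bold. Raises if the slabs cannot fit disjointly.
    """
    nx, ny, nz = volume_shape
    per_slab = ny * nz
    slab_depth = int(np.ceil(voxels_per_roi / per_slab))
    if n_rois * slab_depth > nx:
        raise ValueError("ROIs do not fit disjointly in the volume")
    masks = {}
    for i in range(n_rois):
        mask = np.zeros(volume_shape, dtype=bool)
        flat = np.zeros(slab_depth * per_slab, dtype=bool)
        flat[:voxels_per_roi] = True
        mask[i * slab_depth:(i + 1) * slab_depth] = flat.reshape(slab_depth, ny, nz)
        masks[f"roi{i + 1}"] = mask
    union = np.sum([m.astype(int) for m in masks.values()], axis=0)
    if union.max() > 1:
        raise ValueError("ROI masks overlap")
    return masks


@dataclass
class SyntheticSubject:
    """One synthetic participant: designs, voxel data, and provenance."""

    designs_by_layer: dict            # layer -> list of per-session DesignMatrix
    design_all: list                  # per-session DesignMatrix over all layers
    voxels: list                      # per-session VoxelSeries (motion-residualized upstream)
    motion: list                      # per-session 6 x N motion tables
    truth: pd.DataFrame


def simulate_cohort(
    n_subjects: int = 10,
    n_sessions: int = 5,
    n_volumes: int = 200,
    units_per_layer: int = 8,
    voxels_per_roi: int = 200,
    rois: tuple = ("roi1", "roi2", "roi3", "roi4", "roi5"),
    roi_layers: tuple = HIDDEN_LAYERS,
    sparsity: int = 3,
    snr: float = 1.0,
    phi: float = 0.3,
    motion_amp: float = 0.0,
    acq: AcquisitionSpec | None = None,
    hrf: HrfSpec = HrfSpec(),
    seed: int = 0,
) -> list:
    """Seeded cohort: every ROI's voxels are sourced from one network layer.

    Per subject and session, smooth layer features at 45 Hz run through the
    full predictor pipeline; ROI r's voxels mix predictors of
    ``roi_layers[r]``. Returns a list of SyntheticSubject.
    """
    acq = acq or AcquisitionSpec(n_volumes=n_volumes)
    n_stim = int(np.ceil(acq.n_volumes * acq.tr_seconds * 45.0)) + 45
    master = np.random.default_rng(seed)
    voxel_layers = np.concatenate(
        [[roi_layers[i]] * voxels_per_roi for i in range(len(rois))]
    )
    subjects = []
    for _ in range(n_subjects):
        sub_seed = int(master.integers(2 ** 31))
        rng = np.random.default_rng(sub_seed)
        sessions = [
            synth_layer_features(n_stim, units_per_layer, seed=int(rng.integers(2 ** 31)))
            for _ in range(n_sessions)
        ]
        designs_by_layer = {
            layer: [assemble_design(f, layer, acq, hrf, extra_sessions=[g for g in sessions if g is not f])
                    for f in sessions]
            for layer in HIDDEN_LAYERS
        }
        design_all = [
            assemble_design(f, list(HIDDEN_LAYERS), acq, hrf,
                            extra_sessions=[g for g in sessions if g is not f])
            for f in sessions
        ]
        motion = [smooth_motion(rng, acq.n_volumes) for _ in range(n_sessions)]
        voxels, truth = simulate_bold(
            designs_by_layer, voxel_layers, sparsity=sparsity, snr=snr, phi=phi,
            motion=motion, motion_amp=motion_amp, seed=int(rng.integers(2 ** 31)),
        )
        truth["roi"] = np.concatenate([[r] * voxels_per_roi for r in rois])
        subjects.append(SyntheticSubject(designs_by_layer, design_all, voxels, motion, truth))
    return subjects
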