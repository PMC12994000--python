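"""Stimulus state construction from raw game frames.

Raw gameplay screens arrive as a grayscale intensity stack sampled at 45 Hz.
A *state* is the element-wise maximum of the current and previous raw frame
(suppressing sprite flicker on alternating-frame renderers), downsampled to
84x84 — the input resolution of the game-playing networks. States are then
grouped into depth-4 temporal stacks, one per time step, which form the
network input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

STATE_SIZE = 84
FRAME_RATE_HZ = 45.0


@dataclass
class FrameSequence:
    """A session's stimulus states plus aligned behavioural logs.

    frames          : (T, H, W) uint8 grayscale states in [0, 255]
    terminal_flags  : (T,) bool, True at the last state of each episode
    actions         : (T,) int action identifiers
    rewards         : (T,) float rewards
    rate_hz         : sampling rate (45 Hz for this paradigm)
    """

    frames: np.ndarray
    terminal_flags: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    rate_hz: float = FRAME_RATE_HZ

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        t = self.frames.shape[0]
        if t < 1:
            raise ValueError("FrameSequence needs at least one frame")
        self.terminal_flags = np.asarray(self.terminal_flags, dtype=bool)
        self.actions = np.asarray(self.actions)
        self.rewards = np.asarray(self.rewards, dtype=float)
        for name in ("terminal_flags", "actions", "rewards"):
            if getattr(self, name).shape != (t,):
                raise ValueError(f"{name} must have length T={t}")
        lo, hi = self.frames.min(), self.frames.max()
        if lo < 0 or hi > 255:
            raise ValueError("frame intensities must lie in [0, 255]")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def duration_seconds(self) -> float:
        return self.n_frames / self.rate_hz


def _resize_frame(frame: np.ndarray, target: int) -> np.ndarray:
    """Downsample one grayscale frame to target x target.

    Uses exact block averaging when the input dimensions are integer
    multiples of the target (area-style, deterministic); otherwise falls back
    to anti-aliased resampling.
    """
    h, w = frame.shape
    if h == target and w == target:
        return frame.astype(float)
    if h % target == 0 and w % target == 0:
        fh, fw = h // target, w // target
        return frame.reshape(target, fh, target, fw).mean(axis=(1, 3))
    out = _sk_resize(
        frame.astype(float), (target, target),
        anti_aliasing=True, preserve_range=True, mode="reflect",
    )
    return out


def preprocess_frames(
    raw: np.ndarray,
    target_size: int = STATE_SIZE,
    terminal_flags: np.ndarray | None = None,
    actions: np.ndarray | None = None,
    rewards: np.ndarray | None = None,
    rate_hz: float = FRAME_RATE_HZ,
) -> FrameSequence:
    """Build flicker-suppressed 84x84 states from raw frames.

    State t is the element-wise maximum of raw frames t and t-1 (state 0 is
    frame 0 alone), then resized to ``target_size`` square.
    """
    raw = np.asarray(raw)
    if raw.ndim != 3:
        raise ValueError("raw must be a T x H x W intensity array")
    if raw.shape[0] < 1:
        raise ValueError("raw frame stack is empty")
    if raw.min() < 0 or raw.max() > 255:
        raise ValueError("raw intensities must lie in [0, 255]")

    t = raw.shape[0]
    flicker = raw.astype(float).copy()
    flicker[1:] = np.maximum(raw[1:], raw[:-1])

    states = np.empty((t, target_size, target_size), dtype=np.uint8)
    for i in range(t):
        states[i] = np.clip(np.rint(_resize_frame(flicker[i], target_size)), 0, 255)

    zeros = np.zeros(t)
    return FrameSequence(
        frames=states,
        terminal_flags=zeros.astype(bool) if terminal_flags is None else terminal_flags,
        actions=zeros.astype(int) if actions is None else actions,
        rewards=zeros if rewards is None else rewards,
        rate_hz=rate_hz,
    )


def stack_states(seq: FrameSequence, depth: int = 4, pad: bool = True) -> np.ndarray:
    """Group states into temporal stacks of ``depth`` consecutive states.

    Stack t holds states t-depth+1 ... t (oldest first). With ``pad`` the
    first depth-1 stacks repeat state 0, so one stack exists per state;
    without padding only full stacks are returned and ``depth`` must not
    exceed the session length.

    Returns an array of shape (n_stacks, depth, H, W).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    frames = seq.frames
    t = frames.shape[0]
    if pad:
        padded = np.concatenate([np.repeat(frames[:1], depth - 1, axis=0), frames])
    else:
        if depth > t:
            raise ValueError(f"depth={depth} exceeds sequence length {t} with padding disabled")
        padded = frames
    n = padded.shape[0] - depth + 1
    idx = np.arange(depth)[None, :] + np.arange(n)[:, None]
    return padded[idx]
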