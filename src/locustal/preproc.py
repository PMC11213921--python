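"""Raw calcium stacks -> aligned, detrended dF/F0 movies.

The fixed order of operations is: spatial denoising (3x3 median then Gaussian
sigma = 1 px), linear bleach detrending on the per-frame median intensity
(slope removed, level preserved), rigid phase-correlation alignment against
the stimulus-mean template, a 3-frame temporal box filter, and dF/F0 with the
mean of the five pre-onset frames as the per-pixel baseline F0.  Two
preprocessed repetitions of the same stimulus can be rigidly registered and
averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .synthetic import CalciumMovie

__all__ = [
    "DffMovie",
    "denoise_frames",
    "detrend_bleach",
    "align_frames",
    "delta_f_over_f",
    "average_repetitions",
    "preprocess",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DffMovie:
    """dF/F0 stack (n_frames, h, w) with its per-pixel baseline F0.

    ``window`` is the (start, stop) frame range used for response magnitudes
    downstream; ``invalid_mask`` marks pixels whose F0 fell below the guard.
    """

    stack: np.ndarray
    F0: np.ndarray
    stimulus: str
    onset_frame: int
    frame_rate: float
    window: tuple
    invalid_mask: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]


def _copy_with(m: CalciumMovie, stack: np.ndarray) -> CalciumMovie:
    return CalciumMovie(stack, m.stimulus, m.onset_frame, m.frame_rate)


def denoise_frames(m: CalciumMovie) -> CalciumMovie:
    """Per frame: 3x3 median filter then 2-D Gaussian (sigma = 1 px),
    reflect boundaries.  Suppresses shot noise and isolated hot pixels."""
    if m.frame_shape[0] < 3 or m.frame_shape[1] < 3:
        raise ValueError("frames must be at least 3x3")
    out = np.empty_like(m.stack, dtype=float)
    for f in range(m.n_frames):
        med = ndimage.median_filter(m.stack[f], size=3, mode="reflect")
        out[f] = ndimage.gaussian_filter(med, sigma=1.0, mode="reflect")
    return _copy_with(m, out)


def detrend_bleach(m: CalciumMovie):
    """Remove the linear bleaching trend, preserving the intensity level.

    A line a*t + b is least-squares fitted to the per-frame median intensity;
    a*t is subtracted from every pixel of frame t so F0 stays on the raw
    intensity scale.  Returns ``(movie, fitted_slope)``.
    """
    if m.n_frames < 3:
        raise ValueError("need at least 3 frames to fit a trend")
    t = np.arange(m.n_frames, dtype=float)
    med = np.median(m.stack.reshape(m.n_frames, -1), axis=1)
    a, _b = np.polyfit(t, med, 1)
    out = m.stack - (a * t)[:, None, None]
    return _copy_with(m, out), float(a)


def align_frames(m: CalciumMovie, upsample_factor: int = 20,
                 max_shift_frac: float = 0.1):
    """Rigid per-frame alignment by phase correlation against the
    stimulus-mean template, applied with subpixel spline interpolation.

    Returns ``(movie, shifts)`` with shifts shaped (n_frames, 2) in
    (row, col).  Degenerate flat frames get zero shift with a warning, and
    so do implausibly large estimates (> ``max_shift_frac`` of the frame
    size) — phase correlation on a near-featureless frame, e.g. a pre-onset
    baseline frame of a low-background preparation, peaks at a random
    wrap-around offset rather than the true small drift.
    """
    if m.n_frames < 2:
        raise ValueError("need at least 2 frames to align")
    template = m.stack.mean(axis=0)
    shifts = np.zeros((m.n_frames, 2))
    out = np.empty_like(m.stack, dtype=float)
    cap = max_shift_frac * min(m.frame_shape)
    flat_template = template.std() == 0
    for f in range(m.n_frames):
        frame = m.stack[f]
        if flat_template or frame.std() == 0:
            log.warning("align_frames: flat frame %d, zero shift assumed", f)
            out[f] = frame
            continue
        shift, _err, _ = phase_cross_correlation(
            template, frame, upsample_factor=upsample_factor, normalization=None
        )
        if np.abs(shift).max() > cap:
            log.warning("align_frames: frame %d shift %s exceeds %.1f px cap;"
                        " treated as failed estimate (zero shift)",
                        f, shift, cap)
            out[f] = frame
            continue
        shifts[f] = shift
        out[f] = ndimage.shift(frame, shift, order=1, mode="nearest")
    return _copy_with(m, out), shifts


def delta_f_over_f(
    m: CalciumMovie, box_frames: int = 3, baseline_frames: int = 5,
    window_frames: int = 10, eps_frac: float = 1e-6,
) -> DffMovie:
    """Temporal box filter then per-pixel dF/F0 = (F - F0)/F0.

    The box filter (``box_frames`` wide) is renormalized at the temporal
    edges (no phantom frames).  F0 is the per-pixel mean of the
    ``baseline_frames`` frames immediately preceding stimulus onset, taken
    from the same filtered trace.  Pixels whose F0 falls below eps_frac of
    the dynamic range are masked invalid (logged), not errors.
    """
    if m.onset_frame < baseline_frames + 1:
        raise ValueError("onset too early for the requested baseline")
    kernel = np.ones(box_frames)
    norm = np.convolve(np.ones(m.n_frames), kernel, mode="same")
    smooth = ndimage.convolve1d(m.stack.astype(float), kernel, axis=0,
                                mode="constant", cval=0.0)
    smooth /= norm[:, None, None]

    F0 = smooth[m.onset_frame - baseline_frames:m.onset_frame].mean(axis=0)
    eps = eps_frac * max(np.ptp(m.stack), 1.0)
    invalid = F0 <= eps
    n_bad = int(invalid.sum())
    if n_bad:
        log.warning("delta_f_over_f: %d pixels with F0 <= eps masked", n_bad)
    F0_safe = np.where(invalid, 1.0, F0)
    dff = (smooth - F0_safe) / F0_safe
    dff[:, invalid] = np.nan
    window = (m.onset_frame, min(m.onset_frame + window_frames, m.n_frames))
    return DffMovie(dff, F0, m.stimulus, m.onset_frame, m.frame_rate,
                    window, invalid if n_bad else None)


def average_repetitions(a: DffMovie, b: DffMovie) -> DffMovie:
    """Register repetition b onto a (phase correlation on the time-mean
    images) and average frame-wise."""
    if a.stimulus != b.stimulus:
        raise ValueError("repetitions must share the stimulus")
    if a.stack.shape != b.stack.shape:
        raise ValueError("repetitions must share the stack shape")
    mean_a = np.nan_to_num(a.stack.mean(axis=0))
    mean_b = np.nan_to_num(b.stack.mean(axis=0))
    if mean_a.std() == 0 or mean_b.std() == 0:
        shift = np.zeros(2)
    else:
        shift, _err, _ = phase_cross_correlation(
            mean_a, mean_b, upsample_factor=20, normalization=None
        )
    moved = np.empty_like(b.stack)
    for f in range(b.n_frames):
        moved[f] = ndimage.shift(b.stack[f], shift, order=1, mode="nearest")
    return DffMovie((a.stack + moved) / 2.0, (a.F0 + b.F0) / 2.0, a.stimulus,
                    a.onset_frame, a.frame_rate, a.window, a.invalid_mask)


def preprocess(m: CalciumMovie, align: bool = True, **dff_kwargs):
    """Full fixed-order preprocessing: denoise -> detrend -> align -> box
    filter + dF/F0.  Returns ``(DffMovie, info)`` with the fitted bleach
    slope and per-frame shifts logged in ``info``."""
    den = denoise_frames(m)
    det, slope = detrend_bleach(den)
    if align:
        ali, shifts = align_frames(det)
    else:
        ali, shifts = det, np.zeros((m.n_frames, 2))
    dff = delta_f_over_f(ali, **dff_kwargs)
    return dff, {"bleach_slope": slope, "shifts": shifts}
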