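"""Raw movies to normalized differential-contrast kymographs.

The raw signal is the channel's scattering intensity modulated by the
illumination profile and slow global gain drift; molecules appear as small
dark dips riding on it.  Preprocessing (i) collapses the transverse axis,
(ii) estimates the empty-channel background per pixel by a temporal median
(robust at the sparse occupancies of interest, <~2 molecules per field of
view), and (iii) converts to differential relative contrast,

    contrast[t, x] = raw[t, x] / (gain[t] * background[x]) - 1,

where the per-frame gain is the mean raw/background ratio over
molecule-free pixels; this removes global intensity drift exactly and
static illumination inhomogeneity through the background division.
"""

from __future__ import annotations

import warnings

import numpy as np

from .kymograph import Kymograph

__all__ = ["collapse_transverse", "estimate_background", "normalize", "preprocess"]


def collapse_transverse(frames: np.ndarray, rows: slice | None = None) -> np.ndarray:
    """Average a (t, y, x) intensity stack over the transverse (y) axis.

    ``rows`` optionally restricts to the rows covering the channel; default
    uses all rows.  Returns a (t, x) kymograph array.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("expected a 3-D stack (t, y, x)")
    sel = frames[:, rows, :] if rows is not None else frames
    if sel.shape[1] == 0:
        raise ValueError("empty transverse row selection")
    return sel.mean(axis=1)


def estimate_background(
    kymo_raw: Kymograph | np.ndarray,
    window: int | None = None,
    occupancy_threshold: float = 0.5,
) -> np.ndarray:
    """Empty-channel background: per-pixel temporal median of the movie.

    With a rolling ``window`` (frames) the median is computed per block for
    long recordings with slow drift; by default the whole movie is used.
    Emits a warning when the estimated molecule occupancy of some pixel
    exceeds ``occupancy_threshold`` (the median then leaks molecular
    signal — the documented failure mode for stuck molecules).

    Returns the background with the same shape as the movie when a rolling
    window is used, else a single line of length n_pixels.
    """
    raw = kymo_raw.contrast if isinstance(kymo_raw, Kymograph) else np.asarray(kymo_raw)
    if raw.ndim != 2:
        raise ValueError("expected a 2-D kymograph (frames x pixels)")

    if window is None:
        bg = np.median(raw, axis=0)
    else:
        if window < 2:
            raise ValueError("rolling window must span at least 2 frames")
        n = raw.shape[0]
        bg = np.empty_like(raw, dtype=float)
        for start in range(0, n, window):
            block = slice(start, min(start + window, n))
            bg[block] = np.median(raw[block], axis=0)[None, :]

    # occupancy check: fraction of frames far below the *empty-channel*
    # level.  The per-pixel 90th percentile is used as that reference
    # (robust even when a pixel is occupied most of the time, where the
    # median itself would already track the dip), with a global robust
    # noise scale.
    ref = np.quantile(raw, 0.9, axis=0)
    med = np.median(raw, axis=0)
    scale = max(1.4826 * float(np.median(np.abs(raw - med[None, :]))), 1e-30)
    occupancy = (raw < (ref - 5.0 * scale)[None, :]).mean(axis=0)
    worst = float(occupancy.max(initial=0.0))
    if worst > occupancy_threshold:
        warnings.warn(
            f"estimated molecule occupancy up to {worst:.0%} of frames at some "
            "pixels; temporal-median background is biased there",
            stacklevel=2,
        )
    return bg


def normalize(
    kymo_raw: Kymograph,
    background: np.ndarray,
    gain_sigma_clip: float = 5.0,
) -> Kymograph:
    """Differential relative contrast from a raw movie and its background.

    Per frame, a global intensity factor (the mean raw/background ratio over
    molecule-free pixels, found by sigma-clipping dips) is divided out
    first, then contrast = raw / (gain * background) - 1.  Invariant to
    global per-frame intensity scaling and static illumination profiles.
    """
    raw = kymo_raw.contrast
    background = np.asarray(background, dtype=float)
    if background.ndim == 1:
        bg = background[None, :]
    else:
        bg = background
    if np.any(bg <= 0):
        raise ValueError("background must be positive everywhere")

    ratio = raw / bg
    gain0 = np.median(ratio, axis=1, keepdims=True)
    resid = ratio - gain0
    mad = np.median(np.abs(resid), axis=1, keepdims=True)
    scale = np.maximum(1.4826 * mad, 1e-30)
    free = resid > -gain_sigma_clip * scale  # molecule dips are negative
    counts = free.sum(axis=1, keepdims=True)
    gain = np.where(
        counts > 0,
        np.sum(np.where(free, ratio, 0.0), axis=1, keepdims=True)
        / np.maximum(counts, 1),
        gain0,
    )
    contrast = ratio / gain - 1.0

    meta = dict(kymo_raw.metadata)
    meta["kind"] = "contrast"
    return Kymograph(contrast, kymo_raw.dt, kymo_raw.pixel_pitch, kymo_raw.origin, meta)


def preprocess(kymo_raw: Kymograph, window: int | None = None) -> Kymograph:
    """Background-estimate and normalize a raw intensity kymograph."""
    bg = estimate_background(kymo_raw, window=window)
    return normalize(kymo_raw, bg)
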