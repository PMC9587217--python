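"""LFP cleaning and extraction of artifact-minimal analysis blocks.

The cleaning chain, in fixed order: reject channels with outlying RMS
amplitude or variance (> mean + 3 SD across channels), common-average
re-reference, local detrending of slow (<~2 Hz) fluctuations, and
regression-based removal of 60 Hz line noise and all harmonics below
Nyquist.  Each session is then split into twenty 30-second clips;
within each clip, samples beyond four scaled median absolute deviations
are replaced by monotone piecewise-cubic interpolation, and the
5-second window with the fewest interpolated samples (earliest on ties)
becomes that clip's analysis block.  Minimal filtering is deliberate:
notch or high-pass filters distort the phase relations that conditional
Granger causality depends on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import resample

from .session import BlockSet, SessionRecording

__all__ = [
    "reject_bad_electrodes",
    "common_average_reference",
    "local_detrend",
    "remove_line_noise",
    "interpolate_artifacts",
    "extract_blocks",
    "preprocess_session",
    "PreprocessReport",
]

#: Gaussian-consistency factor: median(|x - med|) * 1.4826 estimates SD.
MAD_SCALE = 1.4826


@dataclass
class PreprocessReport:
    """What the cleaning chain did to one session."""

    rejected_channels: list
    interpolated_fraction: list
    block_starts: list


def reject_bad_electrodes(rec: SessionRecording) -> tuple[SessionRecording, list[int]]:
    """Drop channels whose RMS amplitude or variance is > mean + 3 SD.

    Statistics are taken across channels; rejection happens before
    re-referencing so bad channels never contaminate the common average.
    Returns the reduced recording and the rejected (original) indices.
    """
    if rec.n_channels < 8:
        raise ValueError("need at least 8 channels for rejection statistics")
    rms = np.sqrt(np.mean(rec.lfp**2, axis=1))
    var = np.var(rec.lfp, axis=1)
    bad = np.zeros(rec.n_channels, dtype=bool)
    for stat in (rms, var):
        bad |= stat > stat.mean() + 3 * stat.std()
    if bad.all():
        raise RuntimeError("all channels flagged as bad; cannot proceed")
    keep = np.nonzero(~bad)[0]
    rejected = [int(rec.retained_channels[i]) for i in np.nonzero(bad)[0]]
    out = SessionRecording(
        lfp=rec.lfp[keep].copy(),
        fs=rec.fs,
        layout=rec.layout,
        retained_channels=rec.retained_channels[keep],
        session_id=rec.session_id,
    )
    return out, rejected


def common_average_reference(rec: SessionRecording) -> SessionRecording:
    """Subtract the mean across retained channels at every sample."""
    if rec.n_channels < 2:
        raise ValueError("common average undefined for a single channel")
    lfp = rec.lfp - rec.lfp.mean(axis=0, keepdims=True)
    return SessionRecording(
        lfp=lfp,
        fs=rec.fs,
        layout=rec.layout,
        retained_channels=rec.retained_channels,
        session_id=rec.session_id,
    )


def local_detrend(
    rec: SessionRecording, window: float = 0.5, step: float = 0.25
) -> SessionRecording:
    """Subtract a running local linear trend (removes <~2 Hz drift).

    A straight line is fitted in a sliding window centred every ``step``
    seconds; the fitted values at the window centres are interpolated
    across the whole recording and subtracted.
    """
    T = rec.n_samples
    w = int(round(window * rec.fs))
    st = int(round(step * rec.fs))
    if w > T:
        raise ValueError("detrend window longer than the recording")
    if w < 2:
        raise ValueError("detrend window too short")
    centers = np.arange(w // 2, T - (w - w // 2) + 1, st)
    if centers.size < 2:
        centers = np.array([w // 2, T - (w - w // 2)])
    trend_pts = np.empty((rec.n_channels, centers.size))
    half_lo = w // 2
    for k, c in enumerate(centers):
        seg = rec.lfp[:, c - half_lo : c - half_lo + w]
        # the local linear fit evaluated at the window centre is the
        # window mean (the slope term vanishes there)
        trend_pts[:, k] = seg.mean(axis=1)
    tgrid = np.arange(T)
    trend = np.empty_like(rec.lfp)
    for ch in range(rec.n_channels):
        trend[ch] = np.interp(tgrid, centers, trend_pts[ch])
    return SessionRecording(
        lfp=rec.lfp - trend,
        fs=rec.fs,
        layout=rec.layout,
        retained_channels=rec.retained_channels,
        session_id=rec.session_id,
    )


def remove_line_noise(
    rec: SessionRecording, base: float = 60.0, clip_len: float = 30.0
) -> SessionRecording:
    """Regress out sinusoids at the line frequency and all harmonics.

    The signal is resampled to the nearest rate that is an integer
    multiple of ``base`` (1020 Hz for 1 kHz recordings), a sine+cosine
    pair per harmonic below the original Nyquist is least-squares fitted
    per 30-s clip and subtracted, and the signal is resampled back.
    """
    fs = rec.fs
    if fs <= 2 * base:
        raise ValueError("sampling rate must exceed twice the line frequency")
    mult = int(np.ceil(fs / base))
    fs_int = mult * base
    T = rec.n_samples
    Tn = int(round(T * fs_int / fs))
    # FFT resampling: lossless round-trip for band-limited content
    x = resample(rec.lfp, Tn, axis=1) if Tn != T else rec.lfp.copy()
    harmonics = np.arange(base, fs / 2, base)
    nclip = max(1, int(round(Tn / (clip_len * fs_int))))
    bounds = np.linspace(0, Tn, nclip + 1).astype(int)
    for a, b in zip(bounds[:-1], bounds[1:]):
        t = np.arange(a, b) / fs_int
        cols = []
        for h in harmonics:
            cols.append(np.sin(2 * np.pi * h * t))
            cols.append(np.cos(2 * np.pi * h * t))
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, x[:, a:b].T, rcond=None)
        x[:, a:b] -= (X @ beta).T
    if Tn != T:
        x = resample(x, T, axis=1)
    if x.shape[1] > T:
        x = x[:, :T]
    elif x.shape[1] < T:
        x = np.pad(x, ((0, 0), (0, T - x.shape[1])), mode="edge")
    return SessionRecording(
        lfp=x,
        fs=fs,
        layout=rec.layout,
        retained_channels=rec.retained_channels,
        session_id=rec.session_id,
    )


def interpolate_artifacts(
    clip: np.ndarray, fs: float, mad_k: float = 4.0, pad: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Replace outlier samples by monotone piecewise-cubic interpolation.

    Per channel, samples more than ``mad_k`` scaled MADs from the median
    are flagged, the ``pad`` samples on each side are included, and the
    gap is filled with a PCHIP fit through the remaining samples.  An
    all-constant channel has MAD 0 and is left untouched.  Returns the
    cleaned clip and the boolean interpolation mask.
    """
    clip = np.asarray(clip, dtype=float)
    if clip.shape[1] < fs:
        raise ValueError("clip must be at least 1 s long")
    out = clip.copy()
    mask = np.zeros(clip.shape, dtype=bool)
    for ch in range(clip.shape[0]):
        x = clip[ch]
        med = np.median(x)
        mad = np.median(np.abs(x - med)) * MAD_SCALE
        if mad == 0:
            continue
        flagged = np.abs(x - med) > mad_k * mad
        if not flagged.any():
            continue
        idx = np.nonzero(flagged)[0]
        grow = np.zeros(x.size, dtype=bool)
        for i in idx:
            grow[max(0, i - pad) : i + pad + 1] = True
        good = np.nonzero(~grow)[0]
        if good.size < 2:
            mask[ch] = True
            out[ch] = med
            continue
        interp = PchipInterpolator(good, x[good])
        bad = np.nonzero(grow)[0]
        out[ch, bad] = interp(bad)
        mask[ch] = grow
    return out, mask


def extract_blocks(
    rec: SessionRecording,
    n_clips: int = 20,
    clip_len: float = 30.0,
    block_len: float = 5.0,
    mad_k: float = 4.0,
    pad: int = 5,
) -> BlockSet:
    """Pick the least-interpolated ``block_len`` window from each clip.

    The session is split into ``n_clips`` non-overlapping clips; within
    each, artifacts are interpolated and the block window (1-sample
    stride) minimising the total interpolated-sample count is retained,
    ties broken by the earliest start.  Selection ignores any task
    events, so blocks reflect spontaneous activity.
    """
    fs = rec.fs
    need = n_clips * clip_len
    if rec.duration < need:
        raise ValueError(
            f"recording of {rec.duration:.1f} s too short; need >= {need:.0f} s "
            f"({n_clips} clips x {clip_len:.0f} s)"
        )
    cs = int(round(clip_len * fs))
    bs = int(round(block_len * fs))
    blocks, starts, fracs = [], [], []
    for k in range(n_clips):
        clip = rec.lfp[:, k * cs : (k + 1) * cs]
        cleaned, mask = interpolate_artifacts(clip, fs, mad_k=mad_k, pad=pad)
        per_sample = mask.sum(axis=0)
        csum = np.concatenate([[0], np.cumsum(per_sample)])
        window_counts = csum[bs:] - csum[:-bs]
        best = int(np.argmin(window_counts))  # argmin takes the earliest tie
        blocks.append(cleaned[:, best : best + bs])
        starts.append(k * cs / fs + best / fs)
        fracs.append(float(mask[:, best : best + bs].mean()))
        if mask.mean() > 0.5:
            warnings.warn(f"clip {k}: >50% samples interpolated; block unusable", stacklevel=2)
    return BlockSet(
        blocks=blocks,
        fs=fs,
        block_starts=np.array(starts),
        interpolated_fraction=np.array(fracs),
        session_id=rec.session_id,
    )


def preprocess_session(
    rec: SessionRecording,
    n_clips: int = 20,
    clip_len: float = 30.0,
    block_len: float = 5.0,
    detrend_window: float = 0.5,
    detrend_step: float = 0.25,
    line_base: float = 60.0,
    reject: bool = True,
) -> tuple[BlockSet, PreprocessReport]:
    """Run the full cleaning chain in its fixed order."""
    rejected: list[int] = []
    if reject:
        rec, rejected = reject_bad_electrodes(rec)
    rec = common_average_reference(rec)
    rec = local_detrend(rec, window=detrend_window, step=detrend_step)
    rec = remove_line_noise(rec, base=line_base)
    blocks = extract_blocks(rec, n_clips=n_clips, clip_len=clip_len, block_len=block_len)
    report = PreprocessReport(
        rejected_channels=rejected,
        interpolated_fraction=list(blocks.interpolated_fraction),
        block_starts=list(blocks.block_starts),
    )
    return blocks, report
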