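"""Construction of task functional connectomes from ROI time series.

The processing chain, in the order the pipeline enforces:

1. motion metrics — framewise displacement (FD) from the six rigid-body
   parameters and RMSD of the percent BOLD signal between consecutive
   volumes;
2. contaminated-volume flagging at FD > 0.5 mm or RMSD > 0.3 % and
   replacement by linear interpolation between the nearest clean
   neighbours (before any filtering);
3. zero-phase band-pass filtering in the 0.01-0.08 Hz band, discarding
   the first few volumes for filter settling;
4. nuisance residualization (motion metrics, white-matter and
   ventricular signals) by ordinary least squares per node;
5. Fisher-Z correlation matrices over nodes.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

__all__ = [
    "compute_fd",
    "compute_rmsd",
    "flag_contaminated",
    "replace_volumes",
    "bandpass",
    "residualize",
    "connectome_from_timeseries",
    "process_timeseries",
]

logger = logging.getLogger(__name__)

FD_THRESHOLD_MM = 0.5
RMSD_THRESHOLD_PCT = 0.3
ROTATION_RADIUS_MM = 50.0


def compute_fd(motion: np.ndarray, rotation_radius_mm: float = ROTATION_RADIUS_MM) -> np.ndarray:
    """Framewise displacement from six rigid-body motion parameters.

    ``FD_t`` is the sum over the six parameters of the absolute backward
    difference, with the three rotations (radians) converted to arc
    length on a sphere of ``rotation_radius_mm`` (Power convention).
    Frame 0 has no predecessor and gets FD = 0.

    Parameters
    ----------
    motion : (frames, 6) array
        Columns 0-2 translations in mm, columns 3-5 rotations in radians.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a (frames, 6) array")
    if motion.shape[0] < 2:
        raise ValueError("FD requires at least 2 frames")
    scaled = motion.copy()
    scaled[:, 3:] *= rotation_radius_mm
    fd = np.abs(np.diff(scaled, axis=0)).sum(axis=1)
    return np.concatenate([[0.0], fd])


def compute_rmsd(bold: np.ndarray) -> np.ndarray:
    """RMSD of the percent BOLD signal between consecutive volumes.

    Each node's series is expressed as percent of its temporal mean;
    RMSD_t is the root mean square over nodes of the change from frame
    t-1 to t.  Frame 0 is 0.  Doubling the raw signal leaves RMSD
    unchanged by construction.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 2 or bold.shape[0] < 2:
        raise ValueError("bold must be (frames, nodes) with at least 2 frames")
    means = bold.mean(axis=0)
    if np.any(means == 0):
        raise ValueError("a node has zero temporal mean; percent signal undefined")
    pct = 100.0 * bold / means
    rmsd = np.sqrt(np.mean(np.diff(pct, axis=0) ** 2, axis=1))
    return np.concatenate([[0.0], rmsd])


def flag_contaminated(
    fd: np.ndarray,
    rmsd: np.ndarray,
    fd_thresh: float = FD_THRESHOLD_MM,
    rmsd_thresh: float = RMSD_THRESHOLD_PCT,
) -> np.ndarray:
    """Flag volumes with FD > 0.5 mm or RMSD > 0.3 % (strict inequalities)."""
    fd = np.asarray(fd, dtype=float)
    rmsd = np.asarray(rmsd, dtype=float)
    if fd.shape != rmsd.shape:
        raise ValueError("fd and rmsd must have the same length")
    return (fd > fd_thresh) | (rmsd > rmsd_thresh)


def replace_volumes(ts: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace flagged volumes by linear interpolation between clean frames.

    Flagged runs at either end of the series, which have a clean
    neighbour on one side only, take that neighbour's value (hold).
    Replacement happens before band-pass filtering.
    """
    ts = np.asarray(ts, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if ts.ndim != 2 or mask.shape != (ts.shape[0],):
        raise ValueError("ts must be (frames, nodes) with one mask entry per frame")
    good = ~mask
    if not good.any():
        raise ValueError("all frames flagged; nothing to interpolate from")
    if good.all():
        return ts.copy()
    t = np.arange(ts.shape[0])
    out = ts.copy()
    for j in range(ts.shape[1]):
        # np.interp holds the boundary value for queries outside [t_good.min, max]
        out[mask, j] = np.interp(t[mask], t[good], ts[good, j])
    return out


def bandpass(
    ts: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    tr_s: float = 2.0,
    discard: int = 8,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass, then drop the first ``discard`` frames.

    The 0.01-0.08 Hz band keeps the slow BOLD fluctuations while
    suppressing drift (DC removed entirely) and respiratory/cardiac
    frequencies.  The initial frames are discarded for filter settling,
    comparable in number to the filter order.
    """
    ts = np.asarray(ts, dtype=float)
    nyquist = 0.5 / tr_s
    if not 0 < low_hz < high_hz < nyquist:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist "
            f"({nyquist} Hz at TR={tr_s}s)"
        )
    if ts.shape[0] <= discard + 6 * order:
        raise ValueError("series too short for filtering and discard")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_s, output="sos")
    filtered = signal.sosfiltfilt(sos, ts, axis=0)
    return filtered[discard:]


def residualize(ts: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Residualize each node on the nuisance regressors plus an intercept.

    Rank-deficient nuisance sets are reduced by dropping dependent
    columns with a logged warning.  Residuals are orthogonal to every
    retained nuisance column.
    """
    ts = np.asarray(ts, dtype=float)
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim == 1:
        nuisance = nuisance[:, None]
    if nuisance.shape[0] != ts.shape[0]:
        raise ValueError("nuisance rows must match frames")
    X = np.hstack([nuisance, np.ones((ts.shape[0], 1))])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        keep, cols = [], []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
            else:
                cols.append(j)
        logger.warning("dropping %d collinear nuisance column(s): %s", len(cols), cols)
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, ts, rcond=None)
    return ts - X @ beta


def connectome_from_timeseries(ts: np.ndarray, clip: float = 1e-7) -> np.ndarray:
    """Fisher-Z correlation matrix over nodes.

    Entry (i, j) is ``atanh(r_ij)`` of the node time courses; the
    diagonal is set to 0.  Zero-variance nodes get NaN rows/columns
    (missing edges, resolved later by conjunction masking).  Perfect
    correlations are clipped to ``atanh(1 - clip)`` since atanh is
    unbounded.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 5:
        raise ValueError("need a (frames, nodes) array with at least 5 frames")
    var = ts.var(axis=0)
    degenerate = var == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts, rowvar=False)
    if degenerate.any():
        logger.warning("%d zero-variance node(s); their edges set missing", degenerate.sum())
        r[degenerate, :] = np.nan
        r[:, degenerate] = np.nan
    at_limit = np.abs(r) >= 1 - clip
    np.fill_diagonal(at_limit, False)
    if np.any(at_limit & np.isfinite(r)):
        logger.warning("clipping %d perfectly correlated edge value(s)", int(at_limit.sum() // 2))
        r = np.clip(r, -(1 - clip), 1 - clip)
    with np.errstate(divide="ignore"):  # diagonal r=1 is overwritten below
        z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return z


def process_timeseries(
    ts: np.ndarray,
    motion: np.ndarray,
    extra_nuisance: np.ndarray | None = None,
    tr_s: float = 2.0,
    fd_thresh: float = FD_THRESHOLD_MM,
    rmsd_thresh: float = RMSD_THRESHOLD_PCT,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    discard: int = 8,
) -> np.ndarray:
    """Full chain from raw ROI series to a Fisher-Z connectome.

    Enforces the stage order: flag & replace -> band-pass -> residualize
    (on FD, RMSD and any extra nuisance series) -> correlate.
    """
    fd = compute_fd(motion)
    rmsd = compute_rmsd(ts)
    mask = flag_contaminated(fd, rmsd, fd_thresh, rmsd_thresh)
    clean = replace_volumes(ts, mask)
    filtered = bandpass(clean, low_hz, high_hz, tr_s=tr_s, discard=discard)
    nuis = [fd[discard:, None], rmsd[discard:, None]]
    if extra_nuisance is not None:
        extra = np.asarray(extra_nuisance, dtype=float)
        if extra.ndim == 1:
            extra = extra[:, None]
        nuis.append(extra[discard:])
    resid = residualize(filtered, np.hstack(nuis))
    return connectome_from_timeseries(resid)
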