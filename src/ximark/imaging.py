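"""Live-cell quantification of mintbody enrichment at the Xist domain.

Per cell and frame, the Xist channel is segmented (Otsu threshold, largest
connected component above a minimum area, with a contrast guard so frames
without a domain yield an empty mask), the mintbody mean inside the domain is
divided by the nuclear background — the out-of-domain nuclear mean sampled at
every 10th timepoint and linearly interpolated to all frames — and the
resulting enrichment-ratio traces are aligned to each cell's Xist onset
(first frame with a detected domain).  Aggregates report the mean with the
25th/75th percentiles over cells; enrichment onset is the first time-since-
onset at which a one-sample t-test of the cell ratios against 1.0 stays
BH-significant for two consecutive timepoints, and the two marks' divergence
is located the same way with an unpaired t-test per timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops


@dataclass
class CellTrace:
    """Per-cell time series of domain enrichment."""

    cell_id: str
    frame_interval: float  # minutes
    ratio: np.ndarray  # NaN where no domain detected
    domain_area: np.ndarray
    background: np.ndarray
    onset_frame: Optional[int]
    excluded: bool = False  # e.g. mitotic cells, flagged by the caller


def segment_domain(
    frame: np.ndarray,
    min_area: int = 10,
    min_contrast: float = 1.5,
) -> np.ndarray:
    """Binary mask of the Xist domain in one (projected) frame.

    Otsu threshold over the nuclear region, keep the largest connected
    component of at least ``min_area`` pixels, and require the component's
    mean to exceed ``min_contrast`` times the out-of-component mean; an empty
    mask (no domain yet) is a valid result.
    """
    frame = np.asarray(frame, dtype=float)
    empty = np.zeros(frame.shape, dtype=bool)
    if not np.isfinite(frame).all():
        raise ValueError("frame contains non-finite values")
    if np.ptp(frame) == 0:
        return empty
    try:
        thr = threshold_otsu(frame)
    except ValueError:
        return empty
    mask = frame > thr
    if not mask.any():
        return empty
    lab = label(mask)
    regions = regionprops(lab)
    largest = max(regions, key=lambda r: r.area)
    if largest.area < min_area:
        return empty
    comp = lab == largest.label
    inside = float(frame[comp].mean())
    outside_px = frame[~comp]
    outside = float(outside_px.mean()) if outside_px.size else np.inf
    if outside <= 0 or inside / outside < min_contrast:
        return empty
    return comp


def enrichment_trace(
    xist_stack: np.ndarray,
    mint_stack: np.ndarray,
    cell_id: str = "cell",
    frame_interval: float = 15.0,
    background_every: int = 10,
    min_area: int = 10,
    min_contrast: float = 1.5,
) -> CellTrace:
    """Background-normalized mintbody enrichment within the Xist domain.

    The nuclear background is the mintbody mean over pixels outside the
    domain mask, measured at every ``background_every``-th frame and linearly
    interpolated to all frames.  The ratio is NaN on frames without a
    detected domain; ``onset_frame`` is the first frame with one (None if
    the movie never shows a domain).
    """
    if xist_stack.shape != mint_stack.shape:
        raise ValueError("channel stacks must share a shape")
    frames = xist_stack.shape[0]
    masks = [
        segment_domain(xist_stack[f], min_area=min_area, min_contrast=min_contrast)
        for f in range(frames)
    ]
    areas = np.array([m.sum() for m in masks], dtype=float)
    onset = next((f for f in range(frames) if areas[f] > 0), None)

    # every Nth frame plus the final frame, so interpolation never has to
    # extrapolate a drifting background
    sample_frames = np.unique(
        np.append(np.arange(0, frames, background_every), frames - 1)
    )
    bg_samples = []
    for f in sample_frames:
        outside = mint_stack[f][~masks[f]]
        bg_samples.append(float(outside.mean()))
    background = np.interp(np.arange(frames), sample_frames, bg_samples)
    if (background <= 0).any():
        raise ValueError("non-positive background estimate")

    ratio = np.full(frames, np.nan)
    for f in range(frames):
        if areas[f] > 0:
            ratio[f] = float(mint_stack[f][masks[f]].mean()) / background[f]
    return CellTrace(
        cell_id=cell_id,
        frame_interval=frame_interval,
        ratio=ratio,
        domain_area=areas,
        background=background,
        onset_frame=onset,
    )


def align_traces(traces: Sequence[CellTrace]) -> Tuple[np.ndarray, np.ndarray, float]:
    """Cells x time matrix of ratios re-indexed to time since Xist onset.

    Traces without a detected onset or flagged ``excluded`` are dropped.
    Returns (matrix with NaN padding, times in minutes, frame_interval).
    """
    usable = [t for t in traces if t.onset_frame is not None and not t.excluded]
    if not usable:
        raise ValueError("no traces with a detected onset")
    interval = usable[0].frame_interval
    if any(t.frame_interval != interval for t in usable):
        raise ValueError("traces have mismatched frame intervals")
    width = max(len(t.ratio) - t.onset_frame for t in usable)
    mat = np.full((len(usable), width), np.nan)
    for i, t in enumerate(usable):
        seg = t.ratio[t.onset_frame :]
        mat[i, : len(seg)] = seg
    times = np.arange(width) * interval
    return mat, times, interval


def aggregate_traces(
    traces: Sequence[CellTrace],
    min_cells: int = 30,
) -> pd.DataFrame:
    """Mean enrichment with quartiles per time-since-onset.

    Requires at least ``min_cells`` traces with a defined onset.  Returns a
    DataFrame (time_min, mean, q25, q75, n).
    """
    mat, times, _ = align_traces(traces)
    if mat.shape[0] < min_cells:
        raise ValueError(f"only {mat.shape[0]} usable cells (need {min_cells})")
    n = np.sum(~np.isnan(mat), axis=0)
    keep = n >= 1
    return pd.DataFrame(
        {
            "time_min": times[keep],
            "mean": np.nanmean(mat[:, keep], axis=0),
            "q25": np.nanpercentile(mat[:, keep], 25, axis=0),
            "q75": np.nanpercentile(mat[:, keep], 75, axis=0),
            "n": n[keep].astype(int),
        }
    )


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    out = np.full(pvals.shape, np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        out[ok] = stats.false_discovery_control(pvals[ok], method="bh")
    return out


def detect_onset_delay(
    traces: Sequence[CellTrace],
    alpha: float = 0.05,
    min_cells: int = 2,
) -> Tuple[Optional[float], pd.DataFrame]:
    """Minutes from Xist onset to sustained mintbody enrichment.

    Per time-since-onset, a one-sample t-test (alternative: ratios > 1.0)
    over cells, BH-adjusted across timepoints; the onset is the first
    timepoint whose adjusted p < alpha and whose successor also passes
    (a run-of-2 guard against isolated flukes).  Returns (minutes or None,
    per-timepoint table).
    """
    mat, times, _ = align_traces(traces)
    pvals = np.full(times.shape, np.nan)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        col = col[np.isfinite(col)]
        if col.size >= min_cells and np.ptp(col) > 0:
            pvals[j] = stats.ttest_1samp(col, 1.0, alternative="greater").pvalue
    adj = _bh_adjust(pvals)
    table = pd.DataFrame({"time_min": times, "pvalue": pvals, "p_adjusted": adj})
    sig = adj < alpha
    for j in range(len(sig) - 1):
        if sig[j] and sig[j + 1]:
            return float(times[j]), table
    return None, table


def compare_mark_traces(
    traces_a: Sequence[CellTrace],
    traces_b: Sequence[CellTrace],
    alpha: float = 0.05,
    min_cells: int = 2,
) -> Tuple[Optional[float], pd.DataFrame]:
    """Per-timepoint divergence of two marks' enrichment ratios.

    Unpaired (Welch) t-test between the two cell populations at each shared
    time-since-onset, BH-adjusted; reports the first sustained (run-of-2)
    divergence time in minutes and the per-timepoint table.  Timepoints with
    fewer than ``min_cells`` cells in either group are flagged low-power and
    excluded from the sustained-run search.
    """
    mat_a, times_a, int_a = align_traces(traces_a)
    mat_b, times_b, int_b = align_traces(traces_b)
    if int_a != int_b:
        raise ValueError("frame intervals differ between the two marks")
    width = min(mat_a.shape[1], mat_b.shape[1])
    times = times_a[:width]
    pvals = np.full(width, np.nan)
    low_power = np.zeros(width, dtype=bool)
    for j in range(width):
        a = mat_a[:, j][np.isfinite(mat_a[:, j])]
        b = mat_b[:, j][np.isfinite(mat_b[:, j])]
        if a.size >= 2 and b.size >= 2:
            pvals[j] = stats.ttest_ind(a, b, equal_var=False).pvalue
            low_power[j] = a.size < min_cells or b.size < min_cells
    adj = _bh_adjust(pvals)
    table = pd.DataFrame(
        {"time_min": times, "pvalue": pvals, "p_adjusted": adj,
         "low_power": low_power}
    )
    sig = (adj < alpha) & ~low_power
    for j in range(width - 1):
        if sig[j] and sig[j + 1]:
            return float(times[j]), table
    return None, table
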