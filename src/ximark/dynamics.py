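"""Accumulation dynamics: log-logistic fits, ED50/IC35, comparisons, profiles.

Per-window accumulation y(t) is fitted with the four-parameter log-logistic
model

    f(t) = c + (d - c) / (1 + exp(b (ln t - ln e))),

the drc "LL.4" form: c and d are the asymptotes, e is the inflection time in
hours (f(e) = (c+d)/2 exactly, so e is the ED50), and b the slope (negative
for increasing curves; f(0) is evaluated as the limit, c for b < 0).  Fits
with high residual sums of squares (>= mean + 1.5 SD over converged fits) are
rejected; rejected, non-converged, or late (e > 24 h) windows are assigned an
ED50 of 24 h.  The effective dose at fraction p of the c-to-d range has the
closed form t = e ((1-p)/p)^(1/b); IC35 is p = 0.35 and always precedes the
ED50 on a monotone curve.

Mark-vs-mark timing is compared with a paired Wilcoxon signed-rank test on
windows whose ED50 is below 24 h for both marks.  Silencing classes
(early/intermediate/late) come from 1-D k-means (k = 3) on per-gene IC35
values.  Metagene profiles use scale-regions semantics: gene bodies rescaled
to a fixed number of bins, flanks in fixed-width bins, minus-strand features
reversed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import pearsonr, wilcoxon
from sklearn.cluster import KMeans
from statsmodels.nonparametric.smoothers_lowess import lowess

ED50_CAP_H = 24.0


@dataclass
class SigmoidFit:
    """LL.4 parameters and diagnostics for one window's accumulation curve."""

    b: float
    c: float
    d: float
    e: float
    residual_sum: float
    converged: bool

    @property
    def ed50(self) -> float:
        return self.e

    def ed_fraction(self, p: float) -> float:
        """Time at which the curve has traversed fraction p of its response.

        The fraction is measured along the direction of progression, from
        f(0) towards f(inf), so t_p < e for p < 0.5 on either orientation:
        t = e ((1-p)/p)^(1/b) for increasing curves (b < 0) and
        t = e (p/(1-p))^(1/b) for decreasing ones (b > 0).
        """
        if not 0 < p < 1:
            raise ValueError("p must be in (0, 1)")
        ratio = (1.0 - p) / p if self.b < 0 else p / (1.0 - p)
        return float(self.e * ratio ** (1.0 / self.b))

    @property
    def ic35(self) -> float:
        return self.ed_fraction(0.35)


def ll4_curve(t, b, c, d, e):
    """Evaluate the LL.4 model; t = 0 uses the limit (c for b < 0)."""
    from .simulate import ll4

    return ll4(t, b, c, d, e)


def _residuals_and_jac(t: np.ndarray, y: np.ndarray):
    logt = np.where(t > 0, np.log(np.maximum(t, 1e-300)), 0.0)
    pos = t > 0

    def resid(theta):
        b, c, d, e = theta
        z = np.where(pos, b * (logt - np.log(e)), 0.0)
        z = np.clip(z, -500, 500)
        u = 1.0 / (1.0 + np.exp(z))
        f = c + (d - c) * u
        if b < 0:
            lim = c
        elif b > 0:
            lim = d
        else:
            lim = 0.5 * (c + d)
        f = np.where(pos, f, lim)
        return f - y

    def jac(theta):
        b, c, d, e = theta
        z = np.where(pos, b * (logt - np.log(e)), 0.0)
        z = np.clip(z, -500, 500)
        ez = np.exp(z)
        u = 1.0 / (1.0 + ez)
        du = ez * u * u  # = X / (1+X)^2, ->0 in both limits
        J = np.empty((t.size, 4))
        J[:, 0] = np.where(pos, -(d - c) * du * (logt - np.log(e)), 0.0)
        J[:, 1] = np.where(pos, 1.0 - u, 1.0 if b < 0 else (0.0 if b > 0 else 0.5))
        J[:, 2] = np.where(pos, u, 0.0 if b < 0 else (1.0 if b > 0 else 0.5))
        J[:, 3] = np.where(pos, (d - c) * du * b / e, 0.0)
        return J

    return resid, jac


def fit_ll4(
    timepoints: Sequence[float],
    values: Sequence[float],
    max_e_factor: float = 10.0,
) -> SigmoidFit:
    """Nonlinear least-squares LL.4 fit of one accumulation track.

    Needs >= 4 (t, y) pairs.  Initialization: c = min(y), d = max(y),
    e = median of positive timepoints, slope sign from the direction of the
    y-vs-t trend; e is bounded in (0, ``max_e_factor`` * max t].
    Non-convergence (including flat input) is a valid outcome reported via
    the ``converged`` flag, never an exception.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValueError("timepoints and values must have the same length")
    if t.size < 4:
        raise ValueError("need at least 4 points to fit 4 parameters")
    if (t < 0).any():
        raise ValueError("timepoints must be non-negative")
    span = float(np.ptp(y))
    if span == 0.0:
        return SigmoidFit(0.0, y[0], y[0], np.nan, 0.0, False)

    resid, jac = _residuals_and_jac(t, y)
    tmax = float(t.max())
    lo = np.array([-50.0, -np.inf, -np.inf, 1e-6])
    hi = np.array([50.0, np.inf, np.inf, max_e_factor * tmax])
    slope = np.polyfit(t, y, 1)[0]
    b0 = -1.0 if slope >= 0 else 1.0
    e0 = float(np.median(t[t > 0]))

    best = None
    for b_init in (b0, -b0):
        x0 = np.array([b_init, float(y.min()), float(y.max()), e0])
        try:
            res = least_squares(resid, x0, jac=jac, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        # the slope-sign heuristic is almost always right; only fall back to
        # the opposite orientation when the first attempt failed outright
        if best.success:
            break
    if best is None:
        return SigmoidFit(np.nan, np.nan, np.nan, np.nan, np.inf, False)
    b, c, d, e = best.x
    sse = float(2.0 * best.cost)
    converged = bool(best.success) and abs(d - c) > 1e-9 * max(span, 1.0)
    return SigmoidFit(float(b), float(c), float(d), float(e), sse, converged)


def fit_tracks(
    tracks: pd.DataFrame,
    value_col: str = "t0_subtracted",
    group_cols: Sequence[str] = ("mark", "chrom", "start", "end"),
) -> pd.DataFrame:
    """Fit every (group) track of a long table; one row per window."""
    rows = []
    for key, grp in tracks.groupby(list(group_cols)):
        grp = grp.sort_values("timepoint")
        fit = fit_ll4(grp["timepoint"].to_numpy(), grp[value_col].to_numpy())
        rec = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        rec.update(
            b=fit.b, c=fit.c, d=fit.d, e=fit.e,
            residual_sum=fit.residual_sum, converged=fit.converged,
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def filter_fits(fits: pd.DataFrame) -> pd.Series:
    """Retain converged fits with residual_sum < mean + 1.5 SD.

    The mean and SD are taken over converged fits.  Degenerate case: when all
    converged residuals are identical (SD = 0) the strict comparison would
    reject everything, so all converged fits are retained instead.
    Returns a boolean Series aligned with ``fits``.
    """
    conv = fits["converged"].astype(bool)
    if conv.sum() < 2:
        raise ValueError("need at least 2 converged fits")
    res = fits.loc[conv, "residual_sum"]
    mu, sd = res.mean(), res.std(ddof=1)
    if sd == 0:
        return conv.copy()
    return conv & (fits["residual_sum"] < mu + 1.5 * sd)


def cap_ed50(fits: pd.DataFrame, retained: pd.Series, cap: float = ED50_CAP_H) -> pd.Series:
    """ED50 per window in (0, cap]: late, rejected or failed fits get ``cap``."""
    e = fits["e"].to_numpy(dtype=float)
    ok = retained.to_numpy() & fits["converged"].to_numpy(dtype=bool)
    out = np.where(ok & np.isfinite(e) & (e <= cap) & (e > 0), e, cap)
    return pd.Series(out, index=fits.index, name="ed50_capped")


def compare_marks(
    ed50_a: pd.Series,
    ed50_b: pd.Series,
    cap: float = ED50_CAP_H,
    min_pairs: int = 10,
) -> Dict[str, float]:
    """Paired Wilcoxon signed-rank test on shared windows with ED50 < cap.

    The two Series must share an index (window identity).  Identical vectors
    give p = 1 (no nonzero signed ranks).
    """
    common = ed50_a.index.intersection(ed50_b.index)
    a = ed50_a.loc[common]
    b = ed50_b.loc[common]
    keep = (a < cap) & (b < cap)
    a, b = a[keep], b[keep]
    if len(a) < min_pairs:
        raise ValueError(f"only {len(a)} shared windows with ED50 < {cap}")
    diff = a - b
    if (diff == 0).all():
        return {"n": float(len(a)), "statistic": 0.0, "pvalue": 1.0,
                "median_difference": 0.0}
    stat, p = wilcoxon(a, b, zero_method="wilcox", method="approx")
    return {
        "n": float(len(a)),
        "statistic": float(stat),
        "pvalue": float(p),
        "median_difference": float(diff.median()),
    }


def ic35_classes(
    ic35_values: pd.Series,
    seed: int = 0,
    n_clusters: int = 3,
    n_init: int = 50,
) -> pd.Series:
    """1-D k-means silencing classes, labelled by ascending cluster centre.

    Returns "early" / "intermediate" / "late" per gene.
    """
    vals = ic35_values.dropna()
    if vals.nunique() < n_clusters:
        raise ValueError("fewer distinct IC35 values than clusters")
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    labels = km.fit_predict(vals.to_numpy().reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    names = ["early", "intermediate", "late"][:n_clusters]
    mapping = {int(cl): names[rank] for rank, cl in enumerate(order)}
    out = pd.Series(
        [mapping[int(l)] for l in labels], index=vals.index, name="silencing_class"
    )
    return out.reindex(ic35_values.index)


def category_correlation(
    acc_a: pd.Series,
    acc_b: pd.Series,
    min_n: int = 10,
) -> Dict[str, float]:
    """Pearson correlation of log 24-h accumulations over shared features.

    Non-positive values cannot be logged and are dropped; their count is
    reported.  Fewer than ``min_n`` positive pairs is an error.
    """
    common = acc_a.index.intersection(acc_b.index)
    a = acc_a.loc[common].astype(float)
    b = acc_b.loc[common].astype(float)
    keep = (a > 0) & (b > 0) & np.isfinite(a) & np.isfinite(b)
    dropped = int(len(common) - keep.sum())
    a, b = a[keep], b[keep]
    if len(a) < min_n:
        raise ValueError(f"only {len(a)} positive pairs (need {min_n})")
    rho, p = pearsonr(np.log(a), np.log(b))
    return {"rho": float(rho), "pvalue": float(p), "n": float(len(a)),
            "n_dropped": float(dropped)}


# ---------------------------------------------------------------------------
# metagene profiles


def _bin_means(arr: np.ndarray, edges: np.ndarray) -> np.ndarray:
    out = np.empty(len(edges) - 1)
    for i in range(len(edges) - 1):
        s, e = edges[i], edges[i + 1]
        if e <= 0 or s >= arr.size or e <= s:
            out[i] = np.nan
        else:
            out[i] = float(np.mean(arr[max(s, 0) : min(e, arr.size)]))
    return out


def metagene_profile(
    signal: Mapping[str, np.ndarray],
    features: pd.DataFrame,
    flank: int = 30_000,
    bin_size: int = 500,
    body_bins: int = 20,
) -> pd.DataFrame:
    """Scale-regions average profile over a feature set.

    ``signal`` maps chromosome to a per-base array; ``features`` has chrom,
    start, end, strand.  Gene bodies are rescaled to ``body_bins`` bins
    (integer base partition), flanks use fixed ``bin_size`` bins; bases
    outside the chromosome are excluded from bin means.  Minus-strand
    features are reversed so profiles read 5' -> 3'.  Features shorter than
    one body bin are skipped.  Returns a DataFrame (bin, segment, position,
    mean, n_features).
    """
    n_flank = flank // bin_size
    profiles = []
    for row in features.itertuples(index=False):
        arr = signal.get(row.chrom)
        if arr is None:
            continue
        length = row.end - row.start
        if length < body_bins:
            continue
        up_edges = np.array(
            [row.start - flank + i * bin_size for i in range(n_flank + 1)]
        )
        body_edges = row.start + (np.arange(body_bins + 1) * length) // body_bins
        down_edges = np.array([row.end + i * bin_size for i in range(n_flank + 1)])
        vec = np.concatenate(
            [
                _bin_means(arr, up_edges),
                _bin_means(arr, body_edges),
                _bin_means(arr, down_edges),
            ]
        )
        if row.strand == "-":
            vec = vec[::-1]
        profiles.append(vec)
    if not profiles:
        raise ValueError("no usable features")
    mat = np.vstack(profiles)
    segments = (["upstream"] * n_flank + ["body"] * body_bins
                + ["downstream"] * n_flank)
    positions = (
        [-(flank - i * bin_size) for i in range(n_flank)]
        + list(np.linspace(0.0, 1.0, body_bins, endpoint=False))
        + [i * bin_size for i in range(1, n_flank + 1)]
    )
    return pd.DataFrame(
        {
            "bin": np.arange(mat.shape[1]),
            "segment": segments,
            "position": positions,
            "mean": np.nanmean(mat, axis=0),
            "n_features": np.sum(~np.isnan(mat), axis=0),
        }
    )


def loess_trend(x: Sequence[float], y: Sequence[float], frac: float = 0.5) -> np.ndarray:
    """LOESS-smoothed y over sorted x (for spatial-gradient summaries)."""
    sm = lowess(np.asarray(y, float), np.asarray(x, float), frac=frac,
                return_sorted=True)
    return sm
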