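"""Allele assignment, window counting, and normalization.

Fragments carry the bases they observed at known SNP positions; a fragment is
assigned to the B6 haplotype (the Xist-induced, inactivating allele) when all
informative SNPs agree with allele 1, to Cast when all agree with allele 2,
``unassigned`` when no covered SNP is informative and ``conflicting`` on a
mixture.  Bases matching neither allele are treated as sequencing errors
(uninformative), not failures.

Counting is featureCounts-like for a non-overlapping window set: each
fragment is counted once, in the window with the largest overlap (ties go to
the leftmost window); fragments overlapping no window are dropped.

Between-sample normalization uses the trimmed mean of M-values (TMM,
Robinson & Oshlack 2010) computed on B6 counts over autosomal consensus
peaks: per-peak M (log2 count ratio after library-size scaling) and A (mean
log2 abundance), two-sided rank trimming of 30% on M and 5% on A, and an
inverse-asymptotic-variance weighted mean of the retained M values.  Factors
are reported relative to the chosen reference sample.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

ALLELES = ("B6", "Cast", "unassigned")


# ---------------------------------------------------------------------------
# allele assignment


def assign_allele(
    fragment_snp_bases: Sequence[Tuple[int, str]],
    snp_lookup: Mapping[int, Tuple[str, str]],
) -> str:
    """Call one fragment's allele from its observed SNP bases.

    ``snp_lookup`` maps 1-based position to (allele1, allele2) for one
    chromosome.  Every position must be a known SNP.
    """
    votes = set()
    for pos, base in fragment_snp_bases:
        if pos not in snp_lookup:
            raise KeyError(f"position {pos} is not in the SNP table")
        a1, a2 = snp_lookup[pos]
        if base == a1:
            votes.add("B6")
        elif base == a2:
            votes.add("Cast")
        # otherwise uninformative (sequencing error)
    if votes == {"B6"}:
        return "B6"
    if votes == {"Cast"}:
        return "Cast"
    if not votes:
        return "unassigned"
    return "conflicting"


def _parse_tags(tags: str) -> List[Tuple[int, str]]:
    if not tags or tags != tags:  # empty or NaN
        return []
    out = []
    for item in str(tags).split(","):
        pos, base = item.split(":")
        out.append((int(pos), base))
    return out


def assign_alleles(fragments: pd.DataFrame, snps: pd.DataFrame) -> pd.Series:
    """Vectorized allele calls for a fragment table (adds no columns).

    ``fragments`` needs ``chrom`` and ``snp_bases`` ("pos:base,..." 1-based);
    ``snps`` is the SNP table (chrom, pos, allele1, allele2).
    """
    lookup: Dict[str, Dict[int, Tuple[str, str]]] = {}
    for chrom, grp in snps.groupby("chrom"):
        lookup[chrom] = dict(
            zip(grp["pos"].astype(int), zip(grp["allele1"], grp["allele2"]))
        )
    calls = [
        assign_allele(_parse_tags(tags), lookup.get(chrom, {}))
        for chrom, tags in zip(fragments["chrom"], fragments["snp_bases"])
    ]
    return pd.Series(calls, index=fragments.index, name="allele")


# ---------------------------------------------------------------------------
# window counting


def count_windows(
    fragments: pd.DataFrame,
    windows: pd.DataFrame,
    allele_calls: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Count fragments per (window, sample, allele).

    ``windows`` (chrom, start, end) must be non-overlapping per chromosome.
    Conflicting fragments are folded into the ``unassigned`` column (they are
    never allelic evidence) but remain counted.  Returns a long DataFrame
    (chrom, start, end, sample_id, B6, Cast, unassigned) containing every
    window, including empty ones.
    """
    if (fragments["end"] <= fragments["start"]).any():
        raise ValueError("zero- or negative-length fragments")
    frags = fragments.copy()
    if allele_calls is None:
        allele_calls = frags["allele"]
    frags["allele"] = np.where(
        allele_calls.isin(["B6", "Cast"]), allele_calls, "unassigned"
    )

    win_sorted = windows.sort_values(["chrom", "start"]).reset_index(drop=True)
    per_chrom = {
        chrom: (grp["start"].to_numpy(), grp["end"].to_numpy(), grp.index.to_numpy())
        for chrom, grp in win_sorted.groupby("chrom")
    }
    # check non-overlap within the set
    for chrom, (ws, we, _) in per_chrom.items():
        if len(ws) > 1 and (ws[1:] < we[:-1]).any():
            raise ValueError(f"overlapping windows on {chrom}")

    assigned = np.full(len(frags), -1, dtype=int)
    fr_chrom = frags["chrom"].to_numpy()
    fr_start = frags["start"].to_numpy()
    fr_end = frags["end"].to_numpy()
    for chrom, (ws, we, widx) in per_chrom.items():
        sel = np.flatnonzero(fr_chrom == chrom)
        if len(sel) == 0:
            continue
        s, e = fr_start[sel], fr_end[sel]
        i0 = np.searchsorted(ws, s, side="right") - 1
        # fast path: fragment fully inside the window containing its start
        inside = (i0 >= 0) & (s >= ws[np.clip(i0, 0, None)]) & (
            e <= we[np.clip(i0, 0, None)]
        )
        assigned[sel[inside]] = widx[i0[inside]]
        # general path: boundary-straddling or out-of-window fragments
        for n in np.flatnonzero(~inside):
            fs, fe, first = s[n], e[n], i0[n]
            best, best_ov = -1, 0
            i = max(first, 0)
            while i < len(ws) and ws[i] < fe:
                ov = min(fe, we[i]) - max(fs, ws[i])
                if ov > best_ov:  # strict: ties keep the leftmost window
                    best, best_ov = i, ov
                i += 1
            if best >= 0:
                assigned[sel[n]] = widx[best]

    kept = frags[assigned >= 0].copy()
    kept["window_idx"] = assigned[assigned >= 0]
    counts = (
        kept.groupby(["window_idx", "sample_id", "allele"], observed=True)
        .size()
        .unstack("allele", fill_value=0)
        .reset_index()
    )
    for a in ALLELES:
        if a not in counts.columns:
            counts[a] = 0
    samples = sorted(frags["sample_id"].unique())
    full = (
        pd.MultiIndex.from_product(
            [win_sorted.index, samples], names=["window_idx", "sample_id"]
        )
        .to_frame(index=False)
        .merge(counts, how="left", on=["window_idx", "sample_id"])
        .fillna(0)
    )
    out = win_sorted.loc[full["window_idx"], ["chrom", "start", "end"]].reset_index(
        drop=True
    )
    out["sample_id"] = full["sample_id"].to_numpy()
    for a in ALLELES:
        out[a] = full[a].astype(int).to_numpy()
    return out


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    log_ratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference (published formulas)."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        raise ValueError("sample shares no nonzero peaks with the reference")
    m = np.log2((obs / lib_obs) / (ref / lib_ref))
    a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * log_ratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_expr_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 1.0
    w = 1.0 / v[keep2]
    return float(2.0 ** (np.sum(w * m[keep2]) / np.sum(w)))


def tmm_factors(
    peak_counts: pd.DataFrame,
    reference_sample: str,
    log_ratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
) -> pd.DataFrame:
    """TMM normalization factors relative to a reference sample.

    ``peak_counts`` is peaks x samples (columns are sample ids); counts are
    the B6 reads over autosomal consensus peaks.  Returns a DataFrame
    (sample_id, tmm_factor, peak_total).
    """
    if peak_counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    if reference_sample not in peak_counts.columns:
        raise ValueError(f"reference sample {reference_sample!r} not in matrix")
    libs = peak_counts.sum(axis=0).astype(float)
    if (libs <= 0).any():
        bad = libs.index[libs <= 0].tolist()
        raise ValueError(f"samples with non-positive totals: {bad}")
    ref = peak_counts[reference_sample].to_numpy()
    rows = []
    for sample in peak_counts.columns:
        if sample == reference_sample:
            f = 1.0
        else:
            try:
                f = _tmm_pair(
                    peak_counts[sample].to_numpy(), ref,
                    libs[sample], libs[reference_sample],
                    log_ratio_trim, abs_expr_trim,
                )
            except ValueError as err:
                raise ValueError(f"sample {sample!r}: {err}") from None
        rows.append({"sample_id": sample, "tmm_factor": f, "peak_total": libs[sample]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# accumulation tracks


def normalize_tracks(
    counts: pd.DataFrame,
    factors: pd.DataFrame,
    samples: pd.DataFrame,
    induced_chrom: str,
    scale: float = 1.0e7,
) -> pd.DataFrame:
    """Normalized B6 accumulation tracks per window and timepoint.

    Per sample the B6 count is scaled by ``scale / (total * tmm_factor)``
    (``total`` = fragments retained by windowing in that sample, all alleles),
    replicates sharing (mark, timepoint) are averaged, and the t = 0 value is
    subtracted from every timepoint.  A further variant rescales the
    subtracted track by the induced-chromosome-wide mean of its 24-h value
    (the effective dynamic range).  Returns a long DataFrame with columns
    (mark, chrom, start, end, timepoint, norm, t0_subtracted, rescaled_24h).
    """
    fac = factors.set_index("sample_id")["tmm_factor"]
    missing = set(counts["sample_id"].unique()) - set(fac.index)
    if missing:
        raise ValueError(f"factors missing for samples: {sorted(missing)}")
    meta = samples.set_index("sample_id")
    totals = counts.groupby("sample_id")[["B6", "Cast", "unassigned"]].sum().sum(axis=1)

    df = counts.copy()
    df["norm"] = [
        b6 * scale / (totals[s] * fac[s])
        for s, b6 in zip(df["sample_id"], df["B6"])
    ]
    df["mark"] = meta.loc[df["sample_id"], "mark"].to_numpy()
    df["timepoint"] = meta.loc[df["sample_id"], "timepoint"].to_numpy()

    out_rows = []
    for mark, grp in df.groupby("mark"):
        avg = (
            grp.groupby(["chrom", "start", "end", "timepoint"])["norm"]
            .mean()
            .reset_index()
        )
        if not (avg["timepoint"] == 0).any():
            raise ValueError(f"mark {mark!r} has no t = 0 samples")
        wide = avg.pivot_table(
            index=["chrom", "start", "end"], columns="timepoint", values="norm"
        )
        sub = wide.sub(wide[0.0], axis=0)
        on_x = sub.index.get_level_values("chrom") == induced_chrom
        t24_mean = sub.loc[on_x, 24.0].mean()
        resc = sub / t24_mean if t24_mean != 0 else sub * np.nan
        long = pd.concat(
            {
                "norm": wide.stack(),
                "t0_subtracted": sub.stack(),
                "rescaled_24h": resc.stack(),
            },
            axis=1,
        ).reset_index()
        long.insert(0, "mark", mark)
        out_rows.append(long)
    out = pd.concat(out_rows, ignore_index=True)
    return out.sort_values(
        ["mark", "chrom", "start", "timepoint"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# coverage tracks and allelic fractions


def write_coverage_track(
    fragments: pd.DataFrame,
    library_total: int,
    path,
    scale: float = 1.0e7,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> None:
    """bedGraph of per-base coverage scaled by ``scale / library_total``.

    ``fragments`` holds the intervals of one allele/sample; ``library_total``
    is the full library's fragment count (all alleles).  Equal-value runs are
    merged; zero-coverage runs are omitted.
    """
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    for _, grp in fragments.groupby("chrom", sort=False):
        if (np.diff(grp["start"].to_numpy()) < 0).any():
            raise ValueError("fragments must be sorted by start within chromosome")
    frags = fragments
    factor = scale / library_total
    with open(path, "w") as fh:
        for chrom, grp in frags.groupby("chrom", sort=True):
            size = (
                chrom_sizes[chrom]
                if chrom_sizes is not None
                else int(grp["end"].max())
            )
            cov = np.zeros(size + 1)
            np.add.at(cov, grp["start"].to_numpy(), 1.0)
            np.add.at(cov, grp["end"].to_numpy(), -1.0)
            cov = np.cumsum(cov)[:size]
            edges = np.flatnonzero(np.diff(cov) != 0) + 1
            starts = np.concatenate([[0], edges])
            ends = np.concatenate([edges, [size]])
            for s, e in zip(starts, ends):
                if cov[s] > 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{cov[s] * factor:.6g}\n")


def allelic_fraction(counts: pd.DataFrame, by: str = "chrom") -> pd.DataFrame:
    """B6 / (B6 + Cast) per chromosome or per window.

    Scopes with no informative reads get NaN.  ``by`` is "chrom" or "window".
    """
    keys = ["chrom"] if by == "chrom" else ["chrom", "start", "end"]
    g = counts.groupby(keys)[["B6", "Cast"]].sum().reset_index()
    denom = g["B6"] + g["Cast"]
    g["b6_fraction"] = np.where(denom > 0, g["B6"] / denom.replace(0, np.nan), np.nan)
    return g
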