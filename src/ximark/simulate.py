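"""Synthetic data with known ground truth for the whole pipeline.

The generator emulates a doxycycline (DOX) induction time course in a hybrid
(B6 x Cast) diploid cell line: an inducible Xist allele on the "B6" haplotype
of one chromosome silences it and repressive histone marks accumulate there
following a four-parameter log-logistic curve, while the "Cast" haplotype and
all autosomal windows stay flat.  Everything the downstream modules consume —
diploid genome with SNPs, allele-tagged sequencing fragments, gene/peak/TPM
annotations, planted chromosome-specific microsatellite repeats, and
two-channel time-lapse movies with a growing Xist domain and delayed mintbody
enrichment — is produced here together with serialisable ground truth.

Count noise is negative binomial (gamma-weighted multinomial, so per-sample
totals are exact), reducing to multinomial/Poisson at dispersion 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RepeatPlant:
    """A microsatellite-like repeat planted into the synthetic genome.

    ``unit`` must be a 22- or 23-nt sequence ending in "GG" (PAM-adjacent).
    ``n_in_region`` copies are planted as a tandem cluster at ``region_start``
    on ``chrom``; ``n_outside_region`` further copies are scattered elsewhere
    on the same chromosome; ``n_off_chrom`` copies are scattered over the
    other chromosomes.
    """

    chrom: str
    region_start: int
    unit: str
    n_in_region: int
    n_outside_region: int = 0
    n_off_chrom: int = 0

    def __post_init__(self) -> None:
        if len(self.unit) not in (22, 23) or not self.unit.endswith("GG"):
            raise ValueError("repeat unit must be 22 or 23 nt and end in 'GG'")


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic DOX time course.

    Defaults mirror the experimental design being emulated: five timepoints
    at up to 4-h resolution over 24 h of induction, biological duplicates,
    10-kb analysis windows, and a single induced chromosome ("cX") whose B6
    allele accumulates signal sigmoidally.
    """

    seed: int = 0
    chromosomes: Sequence[Tuple[str, int]] = (("cX", 300_000), ("c1", 200_000))
    induced_chrom: str = "cX"
    snp_rate_per_kb: float = 8.0
    timepoints: Sequence[float] = (0.0, 4.0, 8.0, 12.0, 24.0)
    marks: Sequence[str] = ("H4K20me1", "H3K27me3")
    n_replicates: int = 2
    library_size: int = 12_000
    dispersion: float = 0.02
    fragment_length: int = 150
    window_width: int = 10_000
    # per-mark, per-window LL.4 truth (b, c, d, e) for the induced B6 allele;
    # filled in by default_windows_truth() when absent
    windows_truth: Optional[Dict[str, pd.DataFrame]] = None
    cast_weight: float = 1.0
    autosome_weight: float = 1.0
    repeat_plants: Sequence[RepeatPlant] = ()

    def __post_init__(self) -> None:
        tps = list(self.timepoints)
        if any(l <= 0 for _, l in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if sorted(tps) != tps or len(set(tps)) != len(tps):
            raise ValueError("timepoints must be strictly increasing")
        if 0.0 not in tps or 24.0 not in tps:
            raise ValueError("timepoints must include 0 and 24 h")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return dict(self.chromosomes)

    def windows_of(self, chrom: str) -> List[Tuple[int, int]]:
        size = self.chrom_sizes[chrom]
        w = self.window_width
        return [(s, min(s + w, size)) for s in range(0, size, w)]


def ll4(t, b, c, d, e):
    """Four-parameter log-logistic curve c + (d-c)/(1+exp(b(ln t - ln e))).

    Increasing accumulation curves have b < 0 (f(0)=c, f(inf)=d).  t = 0 is
    evaluated as the limit.
    """
    t = np.asarray(t, dtype=float)
    b, c, d, e = float(b), float(c), float(d), float(e)
    out = np.empty(t.shape, dtype=float)
    pos = t > 0
    with np.errstate(over="ignore"):
        z = np.clip(b * (np.log(t[pos]) - np.log(e)), -500, 500)
        out[pos] = c + (d - c) / (1.0 + np.exp(z))
    if b < 0:
        lim = c
    elif b > 0:
        lim = d
    else:
        lim = 0.5 * (c + d)
    out[~pos] = lim
    return out


def default_windows_truth(
    config: SimConfig,
    rng: np.random.Generator,
    mark_e_median: Optional[Mapping[str, float]] = None,
) -> Dict[str, pd.DataFrame]:
    """Per-window LL.4 truth for the induced chromosome, one table per mark.

    Window plateau amplitudes share a lognormal component across marks (so
    24-h accumulations of the two marks correlate, as they do at intergenic
    windows in the system being emulated); inflection times e are lognormal
    around a per-mark median (H4K20me1 earlier than H3K27me3 by default).
    """
    if mark_e_median is None:
        mark_e_median = {}
    defaults = {"H4K20me1": 7.0, "H3K27me3": 10.0}
    wins = config.windows_of(config.induced_chrom)
    n = len(wins)
    shared_amp = rng.lognormal(mean=0.0, sigma=0.4, size=n)
    truth: Dict[str, pd.DataFrame] = {}
    for mark in config.marks:
        med = mark_e_median.get(mark, defaults.get(mark, 8.0))
        e = rng.lognormal(mean=np.log(med), sigma=0.25, size=n)
        d = shared_amp * rng.lognormal(mean=0.0, sigma=0.15, size=n)
        c = 0.25 * d
        truth[mark] = pd.DataFrame(
            {
                "chrom": config.induced_chrom,
                "start": [s for s, _ in wins],
                "end": [e_ for _, e_ in wins],
                "b": -2.0,
                "c": c,
                "d": d,
                "e": e,
            }
        )
    return truth


# ---------------------------------------------------------------------------
# genome, SNPs, repeats


def simulate_genome(config: SimConfig, rng: Optional[np.random.Generator] = None):
    """Build the diploid toy genome.

    Returns ``(haplotypes, snps, repeats_truth)`` where ``haplotypes`` maps
    chromosome name to a pair ``(b6_seq, cast_seq)`` differing only at SNP
    positions, ``snps`` is the SNP table (1-based ``pos``; ``allele1`` = B6,
    ``allele2`` = Cast) and ``repeats_truth`` records every planted repeat
    copy's coordinates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    haplotypes: Dict[str, Tuple[str, str]] = {}
    snp_rows = []
    repeat_rows = []
    occupied: Dict[str, List[Tuple[int, int]]] = {name: [] for name, _ in config.chromosomes}

    seqs = {
        name: rng.choice(BASES, size=length)
        for name, length in config.chromosomes
    }

    def plant(chrom: str, start: int, unit: str, plant_id: int, in_region: bool) -> None:
        seq = seqs[chrom]
        if start < 0 or start + len(unit) > len(seq):
            raise ValueError(f"repeat plant outside chromosome {chrom}")
        for s, e in occupied[chrom]:
            if start < e and start + len(unit) > s:
                raise ValueError(
                    f"repeat plant at {chrom}:{start} overlaps a previous plant"
                )
        seq[start : start + len(unit)] = list(unit)
        occupied[chrom].append((start, start + len(unit)))
        repeat_rows.append(
            {
                "plant_id": plant_id,
                "unit": unit,
                "chrom": chrom,
                "start": start,
                "end": start + len(unit),
                "in_region": in_region,
            }
        )

    for pid, rp in enumerate(config.repeat_plants):
        if rp.chrom not in seqs:
            raise ValueError(f"unknown chromosome {rp.chrom!r} in repeat plant")
        k = len(rp.unit)
        # tandem cluster inside the focal region
        for i in range(rp.n_in_region):
            plant(rp.chrom, rp.region_start + i * k, rp.unit, pid, True)
        # scattered same-chromosome copies, far from the cluster
        size = len(seqs[rp.chrom])
        for i in range(rp.n_outside_region):
            for _ in range(200):
                pos = int(rng.integers(0, size - k))
                try:
                    plant(rp.chrom, pos, rp.unit, pid, False)
                    break
                except ValueError:
                    continue
            else:
                raise RuntimeError("could not place scattered repeat copy")
        # off-chromosome copies, round-robin over the other chromosomes
        others = [name for name, _ in config.chromosomes if name != rp.chrom]
        for i in range(rp.n_off_chrom):
            oc = others[i % len(others)]
            osize = len(seqs[oc])
            for _ in range(200):
                pos = int(rng.integers(0, osize - k))
                try:
                    plant(oc, pos, rp.unit, pid, False)
                    break
                except ValueError:
                    continue
            else:
                raise RuntimeError("could not place off-chromosome repeat copy")

    for name, length in config.chromosomes:
        b6 = seqs[name]
        cast = b6.copy()
        n_snps = rng.poisson(config.snp_rate_per_kb * length / 1000.0)
        # SNPs never fall inside planted repeats (repositioned by rejection)
        blocked = sorted(occupied[name])
        positions: List[int] = []
        taken = set()
        attempts = 0
        while len(positions) < n_snps and attempts < 50 * max(n_snps, 1):
            attempts += 1
            pos = int(rng.integers(0, length))
            if pos in taken:
                continue
            if any(s <= pos < e for s, e in blocked):
                continue
            taken.add(pos)
            positions.append(pos)
        positions.sort()
        for pos in positions:
            ref = b6[pos]
            alt = rng.choice(BASES[BASES != ref])
            cast[pos] = alt
            snp_rows.append(
                {"chrom": name, "pos": pos + 1, "allele1": str(ref), "allele2": str(alt)}
            )
        haplotypes[name] = ("".join(b6), "".join(cast))

    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "allele1", "allele2"])
    repeats_truth = pd.DataFrame(
        repeat_rows,
        columns=["plant_id", "unit", "chrom", "start", "end", "in_region"],
    )
    return haplotypes, snps, repeats_truth


def genome_to_fasta(haplotypes: Mapping[str, Tuple[str, str]], which: int = 0) -> str:
    """FASTA text of one haplotype (0 = B6 reference, 1 = Cast)."""
    parts = []
    for name, pair in haplotypes.items():
        seq = pair[which]
        parts.append(f">{name}\n")
        parts.extend(seq[i : i + 80] + "\n" for i in range(0, len(seq), 80))
    return "".join(parts)


# ---------------------------------------------------------------------------
# counts and fragments


def _nb_counts(weights: np.ndarray, total: int, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """Multinomial counts with gamma-perturbed weights (NB marginals).

    The per-sample total is exactly ``total``; marginal variance per cell is
    approximately m + dispersion * m**2.
    """
    w = np.asarray(weights, dtype=float).copy()
    if w.sum() <= 0:
        raise ValueError("non-positive total weight")
    if dispersion > 0:
        shape = 1.0 / dispersion
        w *= rng.gamma(shape, scale=1.0 / shape, size=w.shape)
    p = w / w.sum()
    return rng.multinomial(total, p)


def sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = []
    for mark in config.marks:
        for t in config.timepoints:
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{mark}_t{t:g}_r{rep}",
                        "mark": mark,
                        "timepoint": float(t),
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def simulate_window_counts(config: SimConfig, rng: Optional[np.random.Generator] = None):
    """Per-window, per-allele fragment counts for every sample.

    Returns ``(counts, expected)``: long tables with one row per
    (sample, chrom, window, allele).  The induced chromosome's B6 allele
    follows the per-window LL.4 truth; Cast and autosomal windows are
    time-constant.  ``expected`` holds the pre-noise expectations.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = config.windows_truth
    if truth is None:
        truth = default_windows_truth(config, rng)
    sheet = sample_sheet(config)

    # assemble the (window, allele) weight skeleton once per mark/timepoint
    rows_meta = []
    for name, _ in config.chromosomes:
        for (ws, we) in config.windows_of(name):
            for allele in ("B6", "Cast"):
                rows_meta.append((name, ws, we, allele))
    meta = pd.DataFrame(rows_meta, columns=["chrom", "start", "end", "allele"])

    counts_rows = []
    expected_rows = []
    for _, smp in sheet.iterrows():
        mark, t = smp["mark"], smp["timepoint"]
        tt = truth[mark].set_index("start")
        weights = np.empty(len(meta))
        for i, (chrom, ws, we, allele) in enumerate(meta.itertuples(index=False)):
            if chrom == config.induced_chrom:
                if allele == "B6":
                    p = tt.loc[ws]
                    weights[i] = ll4(np.array([t]), p["b"], p["c"], p["d"], p["e"])[0]
                else:
                    weights[i] = config.cast_weight
            else:
                weights[i] = config.autosome_weight
        counts = _nb_counts(weights, config.library_size, config.dispersion, rng)
        expected = config.library_size * weights / weights.sum()
        for i in range(len(meta)):
            base = {
                "sample_id": smp["sample_id"],
                "chrom": meta.iloc[i]["chrom"],
                "start": int(meta.iloc[i]["start"]),
                "end": int(meta.iloc[i]["end"]),
                "allele": meta.iloc[i]["allele"],
            }
            counts_rows.append({**base, "count": int(counts[i])})
            expected_rows.append({**base, "expected": float(expected[i])})
    return pd.DataFrame(counts_rows), pd.DataFrame(expected_rows)


def simulate_fragments(
    config: SimConfig,
    haplotypes: Mapping[str, Tuple[str, str]],
    snps: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
):
    """Allele-tagged fragments for every sample, with per-fragment truth.

    Fragments are placed uniformly inside their window, carry the observed
    bases at any SNPs they cover (from their true haplotype; no sequencing
    errors), and are returned as a tabular alignment
    (chrom, start, end 0-based half-open, sample_id, snp_bases "pos:base,..."
    with 1-based positions).  The truth table records each fragment's true
    allele.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    counts, expected = simulate_window_counts(config, rng)

    snp_pos: Dict[str, np.ndarray] = {}
    snp_base: Dict[str, Dict[str, np.ndarray]] = {}
    for chrom, grp in snps.groupby("chrom"):
        grp = grp.sort_values("pos")
        snp_pos[chrom] = grp["pos"].to_numpy() - 1  # 0-based internally
        snp_base[chrom] = {
            "B6": grp["allele1"].to_numpy(),
            "Cast": grp["allele2"].to_numpy(),
        }

    chrom_parts, start_parts, end_parts, sample_parts, allele_parts = [], [], [], [], []
    flen = config.fragment_length
    for row in counts.itertuples(index=False):
        if row.count == 0:
            continue
        ws, we = row.start, row.end
        span = max(we - ws - flen, 1)
        starts = ws + rng.integers(0, span, size=row.count)
        ends = np.minimum(starts + flen, we)
        chrom_parts.append(np.repeat(row.chrom, row.count))
        start_parts.append(starts)
        end_parts.append(ends)
        sample_parts.append(np.repeat(row.sample_id, row.count))
        allele_parts.append(np.repeat(row.allele, row.count))
    frags = pd.DataFrame(
        {
            "chrom": np.concatenate(chrom_parts),
            "start": np.concatenate(start_parts).astype(int),
            "end": np.concatenate(end_parts).astype(int),
            "sample_id": np.concatenate(sample_parts),
            "true_allele": np.concatenate(allele_parts),
        }
    )
    frags.insert(0, "fragment_id", np.arange(len(frags)))

    tags = np.full(len(frags), "", dtype=object)
    fr_start = frags["start"].to_numpy()
    fr_end = frags["end"].to_numpy()
    fr_allele = frags["true_allele"].to_numpy()
    for chrom, pos in snp_pos.items():
        sel = np.flatnonzero((frags["chrom"] == chrom).to_numpy())
        if sel.size == 0 or pos.size == 0:
            continue
        lo = np.searchsorted(pos, fr_start[sel], side="left")
        hi = np.searchsorted(pos, fr_end[sel], side="left")
        for i in np.flatnonzero(hi > lo):
            idx = sel[i]
            bases = snp_base[chrom][fr_allele[idx]][lo[i] : hi[i]]
            tags[idx] = ",".join(
                f"{p + 1}:{b}" for p, b in zip(pos[lo[i] : hi[i]], bases)
            )
    frags["snp_bases"] = tags
    frags = frags[
        ["fragment_id", "chrom", "start", "end", "sample_id", "snp_bases",
         "true_allele"]
    ]
    truth = frags[["fragment_id", "true_allele"]].copy()
    fragments = frags.drop(columns=["true_allele"])
    return fragments, {"fragment_truth": truth, "expected_counts": expected}


def simulate_tracks(
    e_true: np.ndarray,
    timepoints: Sequence[float] = (0.0, 4.0, 8.0, 12.0, 24.0),
    depth: float = 800.0,
    dispersion: float = 0.02,
    n_replicates: int = 2,
    b: float = -2.0,
    c: float = 0.0,
    d: float = 1.0,
    rng: Optional[np.random.Generator] = None,
):
    """Fast track-level simulation for parameter-recovery studies.

    For each window with true inflection time ``e_true[i]``, draws NB counts
    with mean ``depth * LL4(t)`` per replicate and returns normalized values
    ``counts / depth`` with shape (windows, replicates, timepoints).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    e_true = np.asarray(e_true, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    out = np.empty((len(e_true), n_replicates, len(t)))
    for i, e in enumerate(e_true):
        mean = depth * ll4(t, b, c, d, e)
        for r in range(n_replicates):
            if dispersion > 0:
                nshape = 1.0 / dispersion
                lam = rng.gamma(nshape, scale=np.maximum(mean, 0) / nshape)
            else:
                lam = np.maximum(mean, 0)
            out[i, r] = rng.poisson(lam) / depth
    return out


# ---------------------------------------------------------------------------
# annotations (genes, peaks, TPM, premarking signal)


def simulate_annotations(config: SimConfig, rng: Optional[np.random.Generator] = None,
                         n_active: int = 18, n_silent: int = 24,
                         n_bivalent: int = 3, n_low_tpm: int = 3,
                         gene_length: int = 4_000, spacing: int = 6_000,
                         desert_spacing: int = 30_000, desert_frac: float = 0.3):
    """Gene models with planted activity categories plus matching evidence.

    Per chromosome, lays out genes of four true categories along the sequence:
    ``initially_active`` (TSS inside both H3K9ac and H3K4me3 consensus peaks,
    TPM >= 1, low H3K27me3 premarking), ``silent`` (no peaks, TPM < 1),
    ``bivalent_excluded`` (peaks + high H3K27me3 premarking) and
    ``tpm_excluded`` (peaks, low premarking, TPM < 1).  A fraction of the
    inter-gene gaps are ``desert_spacing``-wide gene deserts so that some
    tiles are intergenic.  Emits refFlat-like
    gene models, two replicate peak BEDs per mark, a 2-sample TPM table, the
    per-gene H3K27me3 t0 signal, and the truth table.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    cats = (
        ["initially_active"] * n_active
        + ["silent"] * n_silent
        + ["bivalent_excluded"] * n_bivalent
        + ["tpm_excluded"] * n_low_tpm
    )
    gene_rows, truth_rows, tpm_rows, k27_rows = [], [], [], []
    peaks: Dict[str, Dict[int, List[Tuple[str, int, int]]]] = {
        "H3K9ac": {1: [], 2: []},
        "H3K4me3": {1: [], 2: []},
    }
    gid = 0
    for name, length in config.chromosomes:
        order = rng.permutation(len(cats))
        pos = int(rng.integers(2_000, 6_000))
        for idx in order:
            cat = cats[idx]
            if pos + gene_length + 2_000 > length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = pos, pos + gene_length
            gene = f"g{gid:04d}"
            gene_rows.append(
                {
                    "gene": gene,
                    "transcript": f"{gene}.1",
                    "chrom": name,
                    "strand": strand,
                    "tx_start": start,
                    "tx_end": end,
                }
            )
            tss = start if strand == "+" else end - 1
            marked = cat in ("initially_active", "bivalent_excluded", "tpm_excluded")
            if marked:
                for mark in ("H3K9ac", "H3K4me3"):
                    for rep in (1, 2):
                        jit = int(rng.integers(-200, 201))
                        peaks[mark][rep].append((name, max(0, tss - 500 + jit), tss + 500 + jit))
            if cat in ("initially_active", "bivalent_excluded"):
                tpm = float(rng.uniform(2.0, 50.0))
            elif cat == "tpm_excluded":
                tpm = float(rng.uniform(0.0, 0.5))
            else:
                tpm = float(rng.uniform(0.0, 0.5))
            tpm_rows.append({"gene": gene, "tpm_1": tpm * float(rng.uniform(0.8, 1.2)),
                             "tpm_2": tpm * float(rng.uniform(0.8, 1.2))})
            if cat == "bivalent_excluded":
                k27 = float(rng.normal(0.10, 0.02))
            elif cat == "initially_active":
                k27 = float(abs(rng.normal(0.010, 0.003)))
            else:
                k27 = float(rng.normal(0.10, 0.02))
            k27_rows.append({"gene": gene, "h3k27me3_t0": max(k27, 0.0)})
            truth_rows.append({"gene": gene, "chrom": name, "true_category": cat})
            gid += 1
            gap = desert_spacing if rng.random() < desert_frac else spacing
            pos = end + gap + int(rng.integers(0, 2_000))
    genes = pd.DataFrame(gene_rows)
    peak_beds = {
        mark: {rep: pd.DataFrame(v, columns=["chrom", "start", "end"]).sort_values(
            ["chrom", "start"]).reset_index(drop=True)
            for rep, v in reps.items()}
        for mark, reps in peaks.items()
    }
    return {
        "genes": genes,
        "peaks": peak_beds,
        "tpm": pd.DataFrame(tpm_rows),
        "h3k27me3_t0": pd.DataFrame(k27_rows),
        "truth": pd.DataFrame(truth_rows),
    }


# ---------------------------------------------------------------------------
# movies


def simulate_movie(
    onset_frame: int,
    delay_frames: int,
    amplitude: float,
    frames: int = 40,
    shape: Tuple[int, int] = (48, 48),
    radius: int = 6,
    background: float = 100.0,
    xist_contrast: float = 9.0,
    ramp_frames: int = 8,
    noise_sd: float = 10.0,
    enrichment_profile: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Two-channel (Xist, mintbody) synthetic time-lapse of one nucleus.

    The Xist channel gains a disk-shaped domain (intensity
    ``(1 + xist_contrast) * background`` inside) at ``onset_frame`` that
    persists; the mintbody channel has uniform nuclear background plus, from
    ``onset_frame + delay_frames`` on, added intensity inside the domain
    ramping linearly to ``amplitude * background`` over ``ramp_frames``
    frames.  ``enrichment_profile`` (length ``frames``, in units of
    ``amplitude * background``) overrides the default ramp, e.g. to model a
    mark that plateaus or keeps rising.  Gaussian pixel noise ``noise_sd`` is
    added to both channels.  Frames are 2-D maximum projections.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if onset_frame + delay_frames >= frames:
        raise ValueError("onset_frame + delay_frames must be < frames")
    if rng is None:
        rng = np.random.default_rng(0)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = ny // 2, nx // 2
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2

    xist = np.full((frames, ny, nx), background, dtype=float)
    mint = np.full((frames, ny, nx), background, dtype=float)
    if enrichment_profile is None:
        prof = np.zeros(frames)
        t0 = onset_frame + delay_frames
        for f in range(t0, frames):
            prof[f] = min(1.0, (f - t0 + 1) / ramp_frames)
    else:
        prof = np.asarray(enrichment_profile, dtype=float)
        if prof.shape != (frames,):
            raise ValueError("enrichment_profile must have length frames")
    for f in range(frames):
        if f >= onset_frame:
            xist[f][disk] += xist_contrast * background
        if prof[f] > 0:
            mint[f][disk] += prof[f] * amplitude * background
    if noise_sd > 0:
        xist += rng.normal(0.0, noise_sd, xist.shape)
        mint += rng.normal(0.0, noise_sd, mint.shape)
    truth = {
        "onset_frame": onset_frame,
        "delay_frames": delay_frames,
        "amplitude": amplitude,
        "radius": radius,
        "center": (cy, cx),
        "profile": prof,
    }
    return xist, mint, truth


def simulate_experiment_movies(
    n_cells: int = 30,
    delay_frames: int = 3,
    amplitude: float = 0.5,
    frames: int = 40,
    onset_range: Tuple[int, int] = (8, 24),
    noise_sd: float = 10.0,
    rng: Optional[np.random.Generator] = None,
    **movie_kwargs,
):
    """A cohort of per-cell movies with onsets staggered over 2-6 h.

    ``amplitude <= 0`` yields null movies (domain present, no mintbody
    enrichment) for false-positive-rate studies.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    movies = []
    for _ in range(n_cells):
        onset = int(rng.integers(onset_range[0], onset_range[1] + 1))
        if amplitude > 0:
            x, m, tr = simulate_movie(
                onset, delay_frames, amplitude, frames=frames,
                noise_sd=noise_sd, rng=rng, **movie_kwargs,
            )
        else:
            x, m, tr = simulate_movie(
                onset, delay_frames, 1.0, frames=frames, noise_sd=noise_sd,
                enrichment_profile=np.zeros(frames), rng=rng, **movie_kwargs,
            )
            tr["amplitude"] = 0.0
        movies.append((x, m, tr))
    return movies
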