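"""Chromosome-specific microsatellite sgRNA target search.

Candidate protospacer+PAM units are 22- and 23-mers matching N{20,21}GG on
either strand.  A k-mer and its reverse complement are one candidate,
canonicalized lexicographically, and the per-chromosome frequency f_c(s)
counts occurrences of both orientations, overlapping occurrences included
(tandem microsatellites overlap by construction).  The chromosome specificity
of s in c is

    spec(s, c) = f_c(s) / (1 + sum_{i != c} f_i(s)),

and candidates are retained when it is strictly greater than the threshold
(default 19).  Within a chromosome, a focal region R spanning < 1 Mb with
n_R(s) copies left outside qualifies when the region specificity
(f_c - n_R) / (1 + sum_off + n_R) is at least 20, i.e.

    n_R(s) <= (f_c(s) - 20 * sum_off - 20) / 21.

Maximal qualifying occurrence windows are reported as the smallest interval
enclosing their in-region occurrences.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import pandas as pd

from .simulate import revcomp

_VALID = set("ACGTN")


@dataclass
class KmerStats:
    """Per-chromosome occurrence counts for one canonical candidate k-mer."""

    sequence: str
    per_chrom: Dict[str, int] = field(default_factory=dict)

    def count_on(self, chrom: str) -> int:
        return self.per_chrom.get(chrom, 0)

    def total_off(self, chrom: str) -> int:
        return sum(v for c, v in self.per_chrom.items() if c != chrom)

    @property
    def total(self) -> int:
        return sum(self.per_chrom.values())


@dataclass
class FocalRegion:
    """A sub-megabase interval concentrating nearly all copies of a k-mer."""

    chrom: str
    start: int
    end: int
    in_region_count: int
    n_outside: int
    specificity_in_region: float


def canonical(s: str) -> str:
    return min(s, revcomp(s))


def _is_candidate(kmer: str) -> bool:
    """PAM-adjacent on either strand: ends in GG or starts with CC."""
    return kmer.endswith("GG") or kmer.startswith("CC")


def enumerate_candidates(
    genome: Mapping[str, str],
    min_copies: int = 20,
    k_values: Sequence[int] = (22, 23),
) -> List[KmerStats]:
    """All canonical N{20,21}GG k-mers with f_c(s) >= min_copies somewhere.

    Counts are exact and include overlapping occurrences; positions containing
    N never match; non-ACGTN characters raise.  Candidates are returned sorted
    by sequence.
    """
    if min_copies < 1:
        raise ValueError("min_copies must be >= 1")
    counts: Dict[str, Counter] = defaultdict(Counter)
    for chrom, seq in genome.items():
        seq = seq.upper()
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"invalid characters in {chrom}: {sorted(bad)}")
        for k in k_values:
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer or not _is_candidate(kmer):
                    continue
                counts[canonical(kmer)][chrom] += 1
    out = [
        KmerStats(sequence=s, per_chrom=dict(c))
        for s, c in counts.items()
        if max(c.values()) >= min_copies
    ]
    out.sort(key=lambda st: st.sequence)
    return out


def specificity(stats: KmerStats, chrom: str) -> float:
    """f_c / (1 + sum of off-chromosome frequencies); denominator >= 1."""
    return stats.count_on(chrom) / (1.0 + stats.total_off(chrom))


def kmer_occurrences(seq: str, s: str) -> List[int]:
    """Sorted start positions of s and revcomp(s) in seq (overlaps included)."""
    seq = seq.upper()
    targets = {s, revcomp(s)}
    positions = []
    for t in targets:
        i = seq.find(t)
        while i != -1:
            positions.append(i)
            i = seq.find(t, i + 1)
    return sorted(set(positions)) if len(targets) == 1 else sorted(positions)


def find_focal_regions(
    occurrences: Sequence[int],
    stats: KmerStats,
    chrom: str,
    max_span: int = 1_000_000,
) -> List[FocalRegion]:
    """Maximal sub-``max_span`` occurrence clusters passing the n_R bound.

    ``occurrences`` are the sorted start positions of the k-mer (either
    orientation) on ``chrom``; the window span is measured from the first
    occurrence start to the last occurrence end and must be strictly less
    than ``max_span``.  Nested sub-windows are suppressed.  A negative bound
    (f_c too small or off-chromosome copies too many) yields no regions.
    """
    occ = sorted(int(p) for p in occurrences)
    fc = stats.count_on(chrom)
    if len(occ) != fc:
        raise ValueError("occurrence list length must equal f_c(s)")
    if fc == 0:
        return []
    k = len(stats.sequence)
    off = stats.total_off(chrom)
    bound = (fc - 20.0 * off - 20.0) / 21.0
    if bound < 0:
        return []
    regions: List[FocalRegion] = []
    j_prev = -1
    j = 0
    for i in range(len(occ)):
        if j < i:
            j = i
        while j + 1 < len(occ) and occ[j + 1] + k - occ[i] < max_span:
            j += 1
        if j <= j_prev:  # nested in the previous maximal window
            continue
        j_prev = j
        n_in = j - i + 1
        n_r = fc - n_in
        if n_r <= bound:
            spec_r = (fc - n_r) / (1.0 + off + n_r)
            regions.append(
                FocalRegion(
                    chrom=chrom,
                    start=occ[i],
                    end=occ[j] + k,
                    in_region_count=n_in,
                    n_outside=n_r,
                    specificity_in_region=spec_r,
                )
            )
    return regions


def find_targets(
    genome: Mapping[str, str],
    target_chrom: str,
    min_copies: int = 20,
    min_specificity: float = 19.0,
    max_span: int = 1_000_000,
) -> pd.DataFrame:
    """End-to-end search on one chromosome.

    Returns one row per (candidate sequence, focal region) with the counts
    and specificities; empty DataFrame (with columns) when nothing passes.
    """
    if target_chrom not in genome:
        raise ValueError(f"unknown chromosome {target_chrom!r}")
    rows = []
    for stats in enumerate_candidates(genome, min_copies=min_copies):
        if stats.count_on(target_chrom) < min_copies:
            continue
        if specificity(stats, target_chrom) <= min_specificity:
            continue
        occ = kmer_occurrences(genome[target_chrom], stats.sequence)
        for reg in find_focal_regions(occ, stats, target_chrom, max_span=max_span):
            rows.append(
                {
                    "sequence": stats.sequence,
                    "chrom": reg.chrom,
                    "start": reg.start,
                    "end": reg.end,
                    "fc": stats.count_on(target_chrom),
                    "sum_off": stats.total_off(target_chrom),
                    "n_in_region": reg.in_region_count,
                    "n_outside": reg.n_outside,
                    "region_specificity": reg.specificity_in_region,
                }
            )
    cols = [
        "sequence", "chrom", "start", "end", "fc", "sum_off",
        "n_in_region", "n_outside", "region_specificity",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["chrom", "start", "sequence"]).reset_index(drop=True)


def report_targets(
    targets: pd.DataFrame,
    bed_path,
    tsv_path,
    merge_identical: bool = False,
) -> None:
    """Write the focal-region BED and the per-candidate TSV report.

    With ``merge_identical`` the BED collapses distinct candidate sequences
    sharing identical region coordinates into one record; the TSV always
    keeps one row per candidate.
    """
    df = targets.sort_values(["chrom", "start", "sequence"])
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    bed = df[["chrom", "start", "end", "sequence"]]
    if merge_identical:
        bed = bed.drop_duplicates(subset=["chrom", "start", "end"])
    with open(bed_path, "w") as fh:
        for row in bed.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.sequence}\n")
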