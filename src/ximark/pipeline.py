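"""End-to-end pipeline: simulate -> sgRNA search -> annotate -> count ->
normalize -> fit -> compare -> metagene -> imaging, with a checksummed
manifest for reproducibility.

All randomness flows from ``PipelineConfig.seed`` through per-stage child
generators, so re-running with the same config produces byte-identical text
outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import allelic, dynamics, imaging, io, sgrna, simulate, windows


@dataclass
class PipelineConfig:
    """Everything the demo pipeline needs, serialized into every run."""

    seed: int = 0
    chromosomes: Sequence[Tuple[str, int]] = (("cX", 700_000), ("c1", 600_000))
    induced_chrom: str = "cX"
    snp_rate_per_kb: float = 8.0
    timepoints: Sequence[float] = (0.0, 4.0, 8.0, 12.0, 24.0)
    marks: Sequence[str] = ("H4K20me1", "H3K27me3")
    n_replicates: int = 2
    library_size: int = 40_000
    dispersion: float = 0.02
    fragment_length: int = 150
    window_width: int = 10_000
    # sgRNA search
    sgrna_min_copies: int = 20
    sgrna_min_specificity: float = 19.0
    sgrna_max_span: int = 20_000
    # annotation
    h3k27me3_threshold: object = "auto"
    tpm_cutoff: float = 1.0
    # statistics
    alpha: float = 0.05
    # imaging
    n_cells: int = 30
    frame_interval: float = 15.0
    movie_frames: int = 40
    movie_noise_sd: float = 10.0
    run_imaging: bool = True
    run_sgrna: bool = True

    def __post_init__(self) -> None:
        self.chromosomes = tuple((str(n), int(l)) for n, l in self.chromosomes)
        self.timepoints = tuple(float(t) for t in self.timepoints)
        self.marks = tuple(str(m) for m in self.marks)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chromosomes"] = [list(c) for c in self.chromosomes]
        d["timepoints"] = list(self.timepoints)
        d["marks"] = list(self.marks)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "chromosomes" in raw:
            raw["chromosomes"] = [tuple(c) for c in raw["chromosomes"]]
        return cls(**raw)


def _default_repeat_plants(config: PipelineConfig, rng: np.random.Generator):
    """One qualifying chromosome-specific repeat plus one off-target decoy."""

    def unit(k: int) -> str:
        body = "".join(rng.choice(simulate.BASES, size=k - 2))
        return body + "GG"

    size = dict(config.chromosomes)[config.induced_chrom]
    return [
        simulate.RepeatPlant(
            chrom=config.induced_chrom, region_start=size // 10, unit=unit(23),
            n_in_region=25, n_outside_region=0, n_off_chrom=0,
        ),
        simulate.RepeatPlant(
            chrom=config.induced_chrom, region_start=(6 * size) // 10, unit=unit(22),
            n_in_region=22, n_outside_region=0, n_off_chrom=8,
        ),
    ]


def plant_qualifies(plant: simulate.RepeatPlant, min_specificity: float = 19.0) -> bool:
    """Whether a planted repeat's parameters satisfy both reporting criteria.

    Assumes the scattered same-chromosome copies fall outside the focal
    cluster's window, so the achievable n_R equals ``n_outside_region``.
    """
    fc = plant.n_in_region + plant.n_outside_region
    off = plant.n_off_chrom
    if fc / (1.0 + off) <= min_specificity:
        return False
    return plant.n_outside_region <= (fc - 20.0 * off - 20.0) / 21.0


def _simulate_chip_peaks(config: PipelineConfig, rng: np.random.Generator,
                         n_peaks: int = 30, width: int = 2_000, jitter: int = 200):
    """Autosomal per-mark, per-replicate peak intervals for TMM."""
    sizes = dict(config.chromosomes)
    autosomes = [c for c in sizes if c != config.induced_chrom]
    out: Dict[str, Dict[int, pd.DataFrame]] = {}
    for mark in config.marks:
        centers = []
        for chrom in autosomes:
            n = max(4, n_peaks // len(autosomes))
            pos = np.sort(rng.choice(
                np.arange(width, sizes[chrom] - width, 2 * width),
                size=min(n, (sizes[chrom] - 2 * width) // (2 * width)),
                replace=False,
            ))
            centers.extend((chrom, int(p)) for p in pos)
        reps = {}
        for rep in (1, 2):
            rows = []
            for chrom, c in centers:
                j = int(rng.integers(-jitter, jitter + 1))
                rows.append({"chrom": chrom, "start": max(0, c - width // 2 + j),
                             "end": c + width // 2 + j})
            reps[rep] = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
        out[mark] = reps
    return out


def _imaging_stage(config: PipelineConfig, rng: np.random.Generator, outdir: Path):
    """Two-mark live-imaging simulation and quantification.

    Both marks start enriching 3 frames (45 min) after Xist onset with the
    same initial rate; H4K20me1 plateaus at 0.5x background extra while
    H3K27me3 keeps rising to 1.0x, so their traces diverge about 2.5 h after
    onset.
    """
    frames = config.movie_frames
    delay = 3
    traces: Dict[str, List[imaging.CellTrace]] = {}
    for mark in config.marks[:2]:
        mark_traces = []
        for cell in range(config.n_cells):
            onset = int(rng.integers(8, 25))
            t0 = onset + delay
            prof = np.zeros(frames)
            for f in range(t0, frames):
                k = f - t0 + 1
                if mark == "H4K20me1":
                    prof[f] = 0.5 * min(1.0, k / 8.0)
                else:
                    prof[f] = 1.0 * min(1.0, k / 16.0)
            xist, mint, _ = simulate.simulate_movie(
                onset, delay, amplitude=1.0, frames=frames,
                noise_sd=config.movie_noise_sd,
                enrichment_profile=prof, rng=rng,
            )
            np.save(outdir / f"movie_{mark}_cell{cell:02d}.npy",
                    np.stack([xist, mint]).astype(np.float32))
            mark_traces.append(
                imaging.enrichment_trace(
                    xist, mint, cell_id=f"{mark}_{cell}",
                    frame_interval=config.frame_interval,
                )
            )
        traces[mark] = mark_traces
    results = {}
    agg_tables = []
    for mark, trs in traces.items():
        agg = imaging.aggregate_traces(trs, min_cells=min(30, config.n_cells))
        agg.insert(0, "mark", mark)
        agg_tables.append(agg)
        onset_min, _ = imaging.detect_onset_delay(trs, alpha=config.alpha)
        results[f"onset_delay_min_{mark}"] = onset_min
    m0, m1 = config.marks[:2]
    div_min, div_table = imaging.compare_mark_traces(
        traces[m0], traces[m1], alpha=config.alpha
    )
    results["divergence_min"] = div_min
    io.write_tsv(pd.concat(agg_tables, ignore_index=True), outdir / "imaging_aggregates.tsv")
    io.write_tsv(div_table, outdir / "imaging_divergence.tsv")
    return results


def run_all(config: PipelineConfig, outdir) -> Dict[str, object]:
    """Execute every stage; returns the metrics dict written to metrics.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    rngs = {name: np.random.default_rng(child) for name, child in zip(
        ["genome", "truth", "annot", "frags", "peaks", "silencing", "imaging"],
        ss.spawn(7),
    )}
    metrics: Dict[str, object] = {}
    text_outputs: List[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        io.write_tsv(df, path)
        text_outputs.append(path)

    # --- simulate ------------------------------------------------------
    sim_cfg = simulate.SimConfig(
        seed=config.seed,
        chromosomes=tuple(config.chromosomes),
        induced_chrom=config.induced_chrom,
        snp_rate_per_kb=config.snp_rate_per_kb,
        timepoints=tuple(config.timepoints),
        marks=tuple(config.marks),
        n_replicates=config.n_replicates,
        library_size=config.library_size,
        dispersion=config.dispersion,
        fragment_length=config.fragment_length,
        window_width=config.window_width,
        repeat_plants=_default_repeat_plants(config, rngs["genome"]),
    )
    haplotypes, snps, repeats_truth = simulate.simulate_genome(sim_cfg, rngs["genome"])
    genome = {name: pair[0] for name, pair in haplotypes.items()}
    fasta_path = outdir / "genome.fa"
    io.write_fasta(genome, fasta_path)
    text_outputs.append(fasta_path)
    emit(snps, "snps.tsv")
    emit(repeats_truth, "repeats_truth.tsv")

    sim_cfg.windows_truth = simulate.default_windows_truth(sim_cfg, rngs["truth"])
    for mark, df in sim_cfg.windows_truth.items():
        emit(df, f"truth_windows_{mark}.tsv")

    ann = simulate.simulate_annotations(sim_cfg, rngs["annot"])
    emit(ann["genes"], "genes.tsv")
    emit(ann["tpm"], "tpm.tsv")
    emit(ann["h3k27me3_t0"], "h3k27me3_t0.tsv")
    emit(ann["truth"], "genes_truth.tsv")

    fragments, frag_truth = simulate.simulate_fragments(
        sim_cfg, haplotypes, snps, rngs["frags"]
    )
    emit(fragments, "fragments.tsv")
    emit(frag_truth["fragment_truth"], "fragments_truth.tsv")

    # --- sgRNA search --------------------------------------------------
    if config.run_sgrna:
        targets = sgrna.find_targets(
            genome, config.induced_chrom,
            min_copies=config.sgrna_min_copies,
            min_specificity=config.sgrna_min_specificity,
            max_span=config.sgrna_max_span,
        )
        sgrna.report_targets(targets, outdir / "sgrna_targets.bed",
                             outdir / "sgrna_targets.tsv")
        text_outputs += [outdir / "sgrna_targets.bed", outdir / "sgrna_targets.tsv"]
        found = set(map(sgrna.canonical, targets["sequence"]))
        tp = fn = fp = tn = 0
        for plant in sim_cfg.repeat_plants:
            hit = sgrna.canonical(plant.unit) in found
            if plant_qualifies(plant, config.sgrna_min_specificity):
                tp += hit
                fn += not hit
            else:
                fp += hit
                tn += not hit
        metrics["sgrna_sensitivity"] = tp / max(tp + fn, 1)
        metrics["sgrna_specificity"] = tn / max(tn + fp, 1)

    # --- annotation ----------------------------------------------------
    tiles = windows.tile_genome(dict(config.chromosomes), config.window_width)
    emit(tiles, "tiles.tsv")
    k9_cons = windows.consensus_peaks(list(ann["peaks"]["H3K9ac"].values()))
    k4_cons = windows.consensus_peaks(list(ann["peaks"]["H3K4me3"].values()))
    emit(k9_cons, "consensus_H3K9ac.tsv")
    emit(k4_cons, "consensus_H3K4me3.tsv")

    k27 = dict(zip(ann["h3k27me3_t0"]["gene"], ann["h3k27me3_t0"]["h3k27me3_t0"]))
    if config.h3k27me3_threshold == "auto":
        tss = windows._tss_table(ann["genes"])
        marked = []
        for row in tss.itertuples(index=False):
            from . import intervals as iv

            sub9 = k9_cons[k9_cons["chrom"] == row.chrom]
            sub4 = k4_cons[k4_cons["chrom"] == row.chrom]
            in_both = iv.contains_point(
                list(zip(sub9["start"], sub9["end"])), row.tss
            ) and iv.contains_point(list(zip(sub4["start"], sub4["end"])), row.tss)
            marked.append((row.gene, in_both))
        marked_genes = {g for g, m in marked if m}
        act_vals = [v for g, v in k27.items() if g in marked_genes]
        inact_vals = [v for g, v in k27.items() if g not in marked_genes]
        try:
            threshold = windows.h3k27me3_threshold(act_vals, inact_vals)
        except ValueError:
            threshold = windows.H3K27ME3_THRESHOLD_DEFAULT
    else:
        threshold = float(config.h3k27me3_threshold)
    metrics["h3k27me3_threshold"] = threshold

    calls = windows.classify_genes(
        ann["genes"], k9_cons, k4_cons, k27, ann["tpm"], threshold=threshold
    )
    emit(calls, "gene_categories.tsv")
    truth_cat = ann["truth"].set_index("gene")["true_category"]
    expect = truth_cat.map(
        {
            "initially_active": "initially_active",
            "silent": "silent",
            "bivalent_excluded": "excluded",
            "tpm_excluded": "excluded",
        }
    )
    got = calls.set_index("gene")["category"].reindex(expect.index)
    metrics["gene_classification_accuracy"] = float((got == expect).mean())

    intergenic = windows.intergenic_windows(tiles, ann["genes"])
    emit(intergenic, "intergenic_windows.tsv")

    # --- counting ------------------------------------------------------
    calls_allele = allelic.assign_alleles(fragments, snps)
    counts = allelic.count_windows(fragments, tiles, calls_allele)
    emit(counts, "window_counts.tsv")
    sheet = simulate.sample_sheet(sim_cfg)
    emit(sheet, "samples.tsv")

    gene_feats = windows.gene_extents(ann["genes"])
    gene_counts = allelic.count_windows(
        fragments, gene_feats[["chrom", "start", "end"]], calls_allele
    )
    gene_counts = gene_counts.merge(gene_feats, on=["chrom", "start", "end"])
    emit(gene_counts, "gene_counts.tsv")

    # --- TMM + tracks --------------------------------------------------
    chip_peaks = _simulate_chip_peaks(config, rngs["peaks"])
    factor_tables = []
    for mark in config.marks:
        cons = windows.consensus_peaks(list(chip_peaks[mark].values()))
        pk_counts = allelic.count_windows(fragments, cons, calls_allele)
        mark_samples = sheet[sheet["mark"] == mark]["sample_id"]
        mat = (
            pk_counts[pk_counts["sample_id"].isin(mark_samples)]
            .pivot_table(index=["chrom", "start", "end"], columns="sample_id",
                         values="B6", fill_value=0)
        )
        ref = sheet[(sheet["mark"] == mark) & (sheet["timepoint"] == 0)]
        factor_tables.append(
            allelic.tmm_factors(mat, reference_sample=ref["sample_id"].iloc[0])
        )
    factors = pd.concat(factor_tables, ignore_index=True)
    emit(factors, "tmm_factors.tsv")

    tracks = allelic.normalize_tracks(counts, factors, sheet, config.induced_chrom)
    emit(tracks, "tracks.tsv")

    frac = allelic.allelic_fraction(counts, by="chrom")
    emit(frac, "allelic_fraction.tsv")

    # --- dynamics ------------------------------------------------------
    x_tracks = tracks[tracks["chrom"] == config.induced_chrom]
    fits = dynamics.fit_tracks(x_tracks, value_col="t0_subtracted")
    ed50_by_mark = {}
    fit_tables = []
    for mark, grp in fits.groupby("mark"):
        grp = grp.reset_index(drop=True)
        retained = dynamics.filter_fits(grp)
        capped = dynamics.cap_ed50(grp, retained)
        grp = grp.assign(retained=retained, ed50_capped=capped)
        fit_tables.append(grp)
        ed50_by_mark[mark] = grp.set_index(["chrom", "start", "end"])["ed50_capped"]
        metrics[f"ed50_median_h_{mark}"] = float(capped.median())
    fits_out = pd.concat(fit_tables, ignore_index=True)
    emit(fits_out, "ll4_fits.tsv")

    m0, m1 = config.marks[:2]
    try:
        comp = dynamics.compare_marks(ed50_by_mark[m0], ed50_by_mark[m1])
        metrics["wilcoxon_pvalue"] = comp["pvalue"]
        metrics["ed50_median_difference_h"] = comp["median_difference"]
    except ValueError as err:
        metrics["wilcoxon_pvalue"] = None
        metrics["comparison_note"] = str(err)

    # --- Fig-4F-style correlations ------------------------------------
    def acc24(track_df, keys):
        sel = track_df[(track_df["timepoint"] == 24.0)
                       & (track_df["chrom"] == config.induced_chrom)]
        return sel.set_index(keys)["t0_subtracted"]

    gene_tracks = allelic.normalize_tracks(
        gene_counts[["chrom", "start", "end", "sample_id", "B6", "Cast", "unassigned"]],
        factors, sheet, config.induced_chrom,
    )
    cat_map = calls.set_index("gene")["category"]
    gene_pos = gene_feats.set_index(["chrom", "start", "end"])["gene"]
    for cat, label_ in (("initially_active", "active_genes"), ("silent", "silent_genes")):
        sub_genes = gene_pos[gene_pos.map(cat_map).eq(cat)]
        accs = {}
        for mark in (m0, m1):
            tr = gene_tracks[gene_tracks["mark"] == mark]
            accs[mark] = acc24(tr, ["chrom", "start", "end"]).reindex(sub_genes.index)
        try:
            cc = dynamics.category_correlation(accs[m0], accs[m1])
            metrics[f"correlation_{label_}"] = cc["rho"]
        except ValueError:
            metrics[f"correlation_{label_}"] = None
    inter_idx = pd.MultiIndex.from_frame(intergenic[["chrom", "start", "end"]])
    accs = {
        mark: acc24(tracks[tracks["mark"] == mark], ["chrom", "start", "end"]).reindex(
            inter_idx
        )
        for mark in (m0, m1)
    }
    try:
        cc = dynamics.category_correlation(accs[m0], accs[m1])
        metrics["correlation_intergenic"] = cc["rho"]
    except ValueError:
        metrics["correlation_intergenic"] = None

    # --- metagene ------------------------------------------------------
    sample_24 = sheet[(sheet["mark"] == m0) & (sheet["timepoint"] == 24.0)][
        "sample_id"
    ].iloc[0]
    sel = fragments[(fragments["sample_id"] == sample_24)]
    sizes = dict(config.chromosomes)
    signal = {}
    for chrom, size in sizes.items():
        cov = np.zeros(size + 1)
        sub = sel[sel["chrom"] == chrom]
        np.add.at(cov, sub["start"].to_numpy(), 1.0)
        np.add.at(cov, sub["end"].to_numpy(), -1.0)
        signal[chrom] = np.cumsum(cov)[:size]
    profs = []
    for cat in ("initially_active", "silent"):
        genes_cat = gene_feats[gene_feats["gene"].map(cat_map).eq(cat)]
        if len(genes_cat) == 0:
            continue
        prof = dynamics.metagene_profile(
            signal, genes_cat, flank=10_000, bin_size=500, body_bins=20
        )
        prof.insert(0, "category", cat)
        profs.append(prof)
    if profs:
        emit(pd.concat(profs, ignore_index=True), "metagene.tsv")

    # --- silencing classes (IC35) --------------------------------------
    active_genes = calls[calls["category"] == "initially_active"]["gene"].tolist()
    if len(active_genes) >= 6:
        rng_s = rngs["silencing"]
        groups = np.array([2.0, 8.0, 18.0])
        true_e = groups[np.arange(len(active_genes)) % 3]
        expr = simulate.simulate_tracks(
            true_e, timepoints=tuple(config.timepoints), depth=800.0,
            dispersion=config.dispersion, n_replicates=2,
            b=2.0, c=0.05, d=1.0, rng=rng_s,
        ).mean(axis=1)
        ic35 = {}
        for g, tr in zip(active_genes, expr):
            fit = dynamics.fit_ll4(config.timepoints, tr)
            if fit.converged and fit.b > 0:
                ic35[g] = fit.ic35
        ic_series = pd.Series(ic35)
        try:
            classes = dynamics.ic35_classes(ic_series, seed=config.seed)
            out = pd.DataFrame(
                {"gene": ic_series.index, "ic35_h": ic_series.to_numpy(),
                 "silencing_class": classes.to_numpy(),
                 "true_e_h": [true_e[active_genes.index(g)] for g in ic_series.index]}
            )
            emit(out, "silencing_classes.tsv")
            metrics["silencing_class_groups"] = int(out["silencing_class"].nunique())
        except ValueError:
            pass

    # --- imaging -------------------------------------------------------
    if config.run_imaging:
        metrics.update(_imaging_stage(config, rngs["imaging"], outdir))

    # --- manifest ------------------------------------------------------
    config_path = outdir / "config.yaml"
    config.to_yaml(config_path)
    text_outputs.append(config_path)
    metrics_clean = {
        k: (None if v is None else (float(v) if isinstance(v, (int, float, np.floating)) else v))
        for k, v in metrics.items()
    }
    metrics_path = outdir / "metrics.json"
    with open(metrics_path, "w") as fh:
        json.dump(metrics_clean, fh, indent=2, sort_keys=True)
        fh.write("\n")
    text_outputs.append(metrics_path)
    io.write_manifest(outdir, config.to_dict(), text_outputs)
    return metrics_clean
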