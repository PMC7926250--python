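"""Readers and writers for the pipeline's plain-text formats.

Coordinates are 0-based half-open in fragment/BED/window tables and 1-based
in the SNP table (VCF convention).  All TSV output uses a fixed float format
so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Mapping

import pandas as pd

FLOAT_FORMAT = "%.6g"


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    """Load a FASTA into a name -> sequence dict (pyfaidx-backed)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def write_movie_tiff(stack, path) -> None:
    """Save a (T, Y, X) image stack as a multi-page float32 TIFF."""
    import numpy as np
    import tifffile

    tifffile.imwrite(str(path), np.asarray(stack, dtype="float32"))


def read_movie_tiff(path):
    """Load a multi-page TIFF time-lapse as a (T, Y, X) float array."""
    import tifffile

    return tifffile.imread(str(path)).astype(float)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, config_dict: dict, files) -> Path:
    """Checksummed manifest of a results directory (deterministic JSON)."""
    outdir = Path(outdir)
    entries = {
        str(Path(f).relative_to(outdir)): sha256_of(f)
        for f in sorted(map(str, files))
    }
    manifest = {"config": config_dict, "outputs": entries}
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
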