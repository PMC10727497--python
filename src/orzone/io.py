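"""Plain-text readers and writers for every format the package consumes.

All formats are deliberately uncompressed text so that synthetic runs
are fully inspectable: MTX + features/barcodes for count matrices,
bedGraph for coverage, bins/pixels TSV for binned contacts, .3dg for
haplotype-resolved 3D structures, spots TSV for spatial coordinates,
YAML for simulator configuration and JSON for run manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from orzone.sim import RheostatParams


# -- count matrices (MTX + features + barcodes) -----------------------------

def write_mtx(adata, prefix) -> None:
    """Write an AnnData as matrix.mtx + features.tsv + barcodes.tsv
    (genes x cells orientation, as customary for the triplet format)."""
    from scipy import io as sio
    from scipy import sparse

    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(prefix / "matrix.mtx"), sparse.csr_matrix(adata.X).T.astype(int))
    var = adata.var.reset_index()
    var.to_csv(prefix / "features.tsv", sep="\t", index=False)
    adata.obs.reset_index().to_csv(prefix / "barcodes.tsv", sep="\t", index=False)


def read_mtx(prefix):
    import anndata as ad
    from scipy import io as sio
    from scipy import sparse

    prefix = Path(prefix)
    X = sparse.csr_matrix(sio.mmread(str(prefix / "matrix.mtx")).T)
    var = pd.read_csv(prefix / "features.tsv", sep="\t").set_index("gene_id")
    obs = pd.read_csv(prefix / "barcodes.tsv", sep="\t")
    obs = obs.set_index(obs.columns[0])
    return ad.AnnData(X=X, obs=obs, var=var)


# -- bedGraph ----------------------------------------------------------------

def write_bedgraph(track, path) -> None:
    """Write a CoverageTrack (see :mod:`orzone.chip`) as 4-column bedGraph."""
    rows = []
    for chrom in sorted(track.intervals):
        starts, ends, values = track.intervals[chrom]
        for s, e, v in zip(starts, ends, values):
            rows.append((chrom, int(s), int(e), float(v)))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_bedgraph(path, library_size: float | None = None, normalized: bool = False):
    from orzone.chip import CoverageTrack

    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"], dtype={"chrom": str})
    intervals = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        intervals[chrom] = (
            sub["start"].to_numpy(int),
            sub["end"].to_numpy(int),
            sub["value"].to_numpy(float),
        )
    return CoverageTrack(intervals=intervals, library_size=library_size,
                         normalized=normalized)


# -- binned contacts (bins TSV + pixels TSV) --------------------------------

def write_contacts(matrix, prefix) -> None:
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    matrix.bins.to_csv(prefix / "bins.tsv", sep="\t", index=False)
    matrix.pixels.to_csv(prefix / "pixels.tsv", sep="\t", index=False)
    meta = {
        "resolution": int(matrix.resolution),
        "normalization": matrix.normalization,
        "total_raw": float(matrix.total_raw),
    }
    (prefix / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_contacts(prefix):
    from orzone.hic import ContactMatrix

    prefix = Path(prefix)
    bins = pd.read_csv(prefix / "bins.tsv", sep="\t", dtype={"chrom": str})
    pixels = pd.read_csv(prefix / "pixels.tsv", sep="\t")
    meta = json.loads((prefix / "meta.json").read_text())
    return ContactMatrix(bins=bins, pixels=pixels, resolution=meta["resolution"],
                         normalization=meta["normalization"],
                         total_raw=meta["total_raw"])


# -- .3dg structures ---------------------------------------------------------

def write_3dg(structure: pd.DataFrame, path) -> None:
    """Whitespace-delimited: haplotype-chromosome, position, x, y, z."""
    structure.to_csv(path, sep="\t", index=False, header=False,
                     float_format="%.6f")


def read_3dg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "pos", "x", "y", "z"], dtype={"chrom": str})
    if df.duplicated(["chrom", "pos"]).any():
        raise ValueError(f"{path}: duplicate (haplotype-chromosome, position) keys")
    if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
        raise ValueError(f"{path}: non-finite coordinates")
    return df


# -- spatial spots -----------------------------------------------------------

def write_spots(adata, prefix) -> None:
    """Spots TSV (barcode, x, y, band if present) + MTX counts."""
    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    write_mtx(adata, prefix)
    cols = [c for c in ("x", "y", "band_zone") if c in adata.obs.columns]
    adata.obs.reset_index()[["barcode", *cols]].to_csv(
        prefix / "spots.tsv", sep="\t", index=False
    )


def read_spots(prefix):
    prefix = Path(prefix)
    adata = read_mtx(prefix)
    spots = pd.read_csv(prefix / "spots.tsv", sep="\t").set_index("barcode")
    for c in spots.columns:
        adata.obs[c] = spots[c]
    return adata


# -- simulator configuration -------------------------------------------------

def write_params(params: RheostatParams, path) -> None:
    d = dataclasses.asdict(params)
    d["n_per_zone"] = list(d["n_per_zone"])
    d["promoter_strength"] = [float(v) for v in d["promoter_strength"]]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_params(path) -> RheostatParams:
    d = yaml.safe_load(Path(path).read_text())
    d["n_per_zone"] = tuple(d["n_per_zone"])
    d["promoter_strength"] = tuple(d["promoter_strength"])
    return RheostatParams(**d)


# -- manifests ---------------------------------------------------------------

def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir, params: RheostatParams, extra: dict | None = None) -> dict:
    """Record parameters, seed and the hash of every file under ``outdir``."""
    outdir = Path(outdir)
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": params.seed,
        "params": yaml.safe_load(yaml.safe_dump(
            {**dataclasses.asdict(params),
             "n_per_zone": list(params.n_per_zone),
             "promoter_strength": [float(v) for v in params.promoter_strength]}
        )),
        "files": {str(p.relative_to(outdir)): file_sha256(p) for p in files},
    }
    if extra:
        manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
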