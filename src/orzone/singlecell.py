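"""Single-cell QC and polygenic OR profiling.

Works on AnnData count matrices (cells x genes) whose ``var`` carries
boolean ``is_or`` and ``is_mito`` flags.  The profiling follows the
field's detection convention for rare OR transcripts: an OR counts as
expressed in a cell when it reaches at least 3 UMIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

OR_UMI_THRESHOLD = 3


@dataclass
class PolygenicProfile:
    """Per-cell polygenic OR state.

    ``dominant_or`` maximises UMIs among expressed ORs; UMI ties break
    to the dorsal-most zone, then lexicographic gene id.
    """

    cell_id: str
    expressed_ors: dict = field(default_factory=dict)
    dominant_or: str | None = None
    dominant_zone: object = None
    zone_composition: dict = field(default_factory=dict)


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def qc_filter_cells(adata, min_genes: int = 1000, min_umi: int = 20000,
                    max_mito: float = 0.05):
    """Drop low-quality cells; return (filtered AnnData, report).

    A cell is kept when it has at least ``min_genes`` genes detected (>=1
    UMI), at least ``min_umi`` total UMIs, and a mitochondrial read
    fraction strictly below ``max_mito``.  The report counts removals
    per criterion (a cell can fail several).
    """
    if "is_mito" not in adata.var.columns:
        raise ValueError("var must carry an is_mito flag")
    X = sparse.csr_matrix(adata.X)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    mito_umi = np.asarray(X[:, adata.var["is_mito"].to_numpy()].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(n_umi > 0, mito_umi / np.maximum(n_umi, 1), 0.0)
    fail_genes = n_genes < min_genes
    fail_umi = n_umi < min_umi
    fail_mito = mito_frac >= max_mito
    keep = ~(fail_genes | fail_umi | fail_mito)
    report = {
        "n_input": int(adata.n_obs),
        "n_kept": int(keep.sum()),
        "removed_low_genes": int(fail_genes.sum()),
        "removed_low_umi": int(fail_umi.sum()),
        "removed_high_mito": int(fail_mito.sum()),
        "removed_total": int((~keep).sum()),
    }
    if report["n_kept"] == 0:
        warnings.warn("QC removed every cell", stacklevel=2)
    return adata[keep].copy(), report


def detect_expressed_ors(adata, min_umi: int = OR_UMI_THRESHOLD) -> dict:
    """Map cell_id -> set of OR gene ids with UMI >= ``min_umi``."""
    if "is_or" not in adata.var.columns:
        raise ValueError("var must carry an is_or flag")
    or_mask = adata.var["is_or"].to_numpy(bool)
    or_names = adata.var_names[or_mask].to_numpy()
    X = _dense(adata.X)[:, or_mask]
    return {
        cid: set(or_names[X[i] >= min_umi])
        for i, cid in enumerate(adata.obs_names)
    }


def _dominant(expressed: dict, zone_of: dict):
    # max UMI; ties to dorsal-most zone then lexicographic id
    def key(g):
        z = zone_of.get(g)
        return (-expressed[g], 99 if z is None or not np.isfinite(z) else z, g)

    return min(expressed, key=key)


DORSAL_BAND = {1, 2}
VENTRAL_BAND = {3, 4, 5}


def polygenic_zone_profile(adata, annotation: pd.DataFrame,
                           min_umi: int = OR_UMI_THRESHOLD):
    """Per-cell zone composition of expressed ORs plus an origin summary.

    Cells must carry an ``origin`` obs column ("dorsal" = zones 1-2
    dissection, "ventral" = zones 3-5); cells without one are skipped
    with a warning.  The summary counts, per origin, cells expressing at
    least one dorsal-band OR and at least one ventral-band OR — the
    comparison behind the observation that ventral progenitors
    co-transcribe dorsal-identity ORs more often than ventral-identity
    ones.
    """
    zone_of = dict(zip(annotation["gene_id"], annotation["zone"]))
    class_of = dict(zip(annotation["gene_id"], annotation["or_class"]))
    or_mask = adata.var["is_or"].to_numpy(bool)
    or_names = adata.var_names[or_mask].to_numpy()
    X = _dense(adata.X)[:, or_mask]

    origins = adata.obs.get("origin")
    profiles = []
    summary: dict = {}
    for i, cid in enumerate(adata.obs_names):
        origin = None if origins is None else str(origins.iloc[i])
        if origin not in ("dorsal", "ventral"):
            warnings.warn(f"cell {cid} lacks a dorsal/ventral origin; skipped",
                          stacklevel=2)
            continue
        hits = X[i] >= min_umi
        expressed = {g: int(u) for g, u in zip(or_names[hits], X[i][hits])}
        comp: dict = {}
        for g in expressed:
            if class_of.get(g) == "I":
                lab = "I"
            else:
                z = zone_of.get(g)
                lab = int(z) if z is not None and np.isfinite(z) else "unknown"
            comp[lab] = comp.get(lab, 0) + 1
        prof = PolygenicProfile(cell_id=str(cid), expressed_ors=expressed,
                                zone_composition=comp)
        if expressed:
            prof.dominant_or = _dominant(expressed, zone_of)
            if class_of.get(prof.dominant_or) == "I":
                prof.dominant_zone = "I"
            else:
                z = zone_of.get(prof.dominant_or)
                prof.dominant_zone = int(z) if z is not None and np.isfinite(z) else None
        profiles.append(prof)

        s = summary.setdefault(origin, {"n_cells": 0, "cells_with_dorsal_band_or": 0,
                                        "cells_with_ventral_band_or": 0})
        s["n_cells"] += 1
        numeric = {lab for lab in comp if isinstance(lab, int)}
        if numeric & DORSAL_BAND or "I" in comp:
            s["cells_with_dorsal_band_or"] += 1
        if numeric & VENTRAL_BAND:
            s["cells_with_ventral_band_or"] += 1
    return profiles, summary


def threshold_de_table(de_table: pd.DataFrame, min_fold: float = 3.0,
                       max_padj: float = 0.05, min_expr: float = 15.0,
                       top_n: int | None = None) -> list:
    """Apply conjunctive differential-expression filters and return gene ids.

    Requires columns ``gene`` and ``padj``, a fold column (``fold`` or
    ``log2fc``) and an expression column (``expr`` or ``tpm``).  Filters:
    padj < ``max_padj``, |fold| >= ``min_fold``, expression >=
    ``min_expr``.  ``top_n`` keeps the most significant genes with a
    deterministic (padj, |fold| descending, gene id) order.
    """
    if de_table.empty:
        return []
    cols = set(de_table.columns)
    if "gene" not in cols or "padj" not in cols:
        raise ValueError("DE table must have 'gene' and 'padj' columns")
    if "fold" in cols:
        fold = de_table["fold"].abs()
    elif "log2fc" in cols:
        fold = 2.0 ** de_table["log2fc"].abs()
    else:
        raise ValueError("DE table must have a 'fold' or 'log2fc' column")
    if "expr" in cols:
        expr = de_table["expr"]
    elif "tpm" in cols:
        expr = de_table["tpm"]
    else:
        raise ValueError("DE table must have an 'expr' or 'tpm' column")
    keep = (de_table["padj"] < max_padj) & (fold >= min_fold) & (expr >= min_expr)
    sub = de_table.loc[keep].assign(_absfold=fold[keep])
    sub = sub.sort_values(["padj", "_absfold", "gene"],
                          ascending=[True, False, True], kind="mergesort")
    genes = sub["gene"].tolist()
    return genes[:top_n] if top_n is not None else genes


def assign_stage_by_markers(adata, marker_sets: dict) -> pd.Series:
    """Assign each cell the stage whose marker genes score highest
    (mean log1p counts) — a deliberate simplification of graph
    clustering plus marker inspection."""
    X = _dense(adata.X)
    logX = np.log1p(X)
    scores = {}
    for stage, genes in marker_sets.items():
        idx = [adata.var_names.get_loc(g) for g in genes if g in adata.var_names]
        scores[stage] = logX[:, idx].mean(axis=1) if idx else np.zeros(adata.n_obs)
    frame = pd.DataFrame(scores, index=adata.obs_names)
    return frame.idxmax(axis=1)
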