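"""Spatial-spot zonal analysis.

Spots (AnnData, spots x genes, obs carries x/y coordinates) are
filtered on OR content, normalised (log1p of median-depth-scaled
counts, a documented stand-in for variance-stabilising transforms),
clustered on OR genes only (seeded k-means on a 5-PC embedding), scored
against top-n zone signatures, and assigned the zone with the largest
summed normalised OR counts.  Spots without any OR transcript are
assigned "none".  Class I ORs form their own signature but are merged
with zone 1 in summaries, since class I genes are expressed within
zone 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse

ZONE_ORDER = ["I", 1, 2, 3, 4, 5]


def _dense(X):
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def filter_spots(adata, min_or_genes: int = 2, min_or_umis: int = 3):
    """Keep spots with >= ``min_or_genes`` distinct ORs detected and
    >= ``min_or_umis`` total OR UMIs.  Returns (kept, all-with-flag):
    removed spots stay available for assignment (a spot with zero OR
    transcripts is later labelled "none")."""
    or_mask = adata.var["is_or"].to_numpy(bool)
    X = sparse.csr_matrix(adata.X)[:, or_mask]
    n_or_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    n_or_umis = np.asarray(X.sum(axis=1)).ravel()
    keep = (n_or_genes >= min_or_genes) & (n_or_umis >= min_or_umis)
    adata = adata.copy()
    adata.obs["passed_or_filter"] = keep
    return adata[keep].copy(), adata


def normalize_spots(adata, layer: str = "normalized"):
    """log1p of counts scaled to the median spot depth (in-place layer)."""
    X = _dense(adata.X).astype(float)
    depth = X.sum(axis=1)
    med = np.median(depth[depth > 0]) if (depth > 0).any() else 1.0
    scaled = X / np.maximum(depth, 1e-12)[:, None] * med
    adata.layers[layer] = np.log1p(scaled)
    return adata


def cluster_spots(adata, n_pcs: int = 5, k: int = 5, seed: int = 0) -> np.ndarray:
    """Seeded k-means on the first ``n_pcs`` principal components of the
    normalised, OR-restricted matrix.  Deterministic under seed."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    if adata.n_obs < k:
        raise ValueError(f"fewer spots ({adata.n_obs}) than clusters ({k})")
    if "normalized" not in adata.layers:
        normalize_spots(adata)
    or_mask = adata.var["is_or"].to_numpy(bool)
    M = np.asarray(adata.layers["normalized"])[:, or_mask]
    n_pcs = min(n_pcs, min(M.shape) - 1) or 1
    emb = PCA(n_components=n_pcs, random_state=seed).fit_transform(M)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(emb)


def top_expressed_signatures(adata, annotation: pd.DataFrame, top_n: int = 20) -> dict:
    """Top-``top_n`` highest-expressed OR genes per zonal category
    (class I separate), by total normalised expression."""
    if "normalized" not in adata.layers:
        normalize_spots(adata)
    or_mask = adata.var["is_or"].to_numpy(bool)
    names = adata.var_names[or_mask]
    totals = np.asarray(adata.layers["normalized"])[:, or_mask].sum(axis=0)
    zone_of = dict(zip(annotation["gene_id"], annotation["zone"]))
    cls_of = dict(zip(annotation["gene_id"], annotation["or_class"]))
    out: dict = {}
    for lab in ZONE_ORDER:
        if lab == "I":
            members = [g for g in names if cls_of.get(g) == "I"]
        else:
            members = [
                g for g in names
                if cls_of.get(g) == "II" and zone_of.get(g) == lab
            ]
        ranked = sorted(members, key=lambda g: (-totals[names.get_loc(g)], g))
        out[lab] = ranked[:top_n]
    return out


def zone_signature_score(adata, signatures: dict) -> pd.DataFrame:
    """Per-spot mean normalised expression of each signature's genes.

    Signature genes absent from the matrix score zero (with a warning).
    """
    if not signatures or all(len(v) == 0 for v in signatures.values()):
        raise ValueError("signatures must be non-empty")
    if "normalized" not in adata.layers:
        normalize_spots(adata)
    M = np.asarray(adata.layers["normalized"])
    scores = {}
    for lab, genes in signatures.items():
        if not genes:
            scores[lab] = np.zeros(adata.n_obs)
            continue
        missing = [g for g in genes if g not in adata.var_names]
        if missing:
            warnings.warn(f"signature {lab}: {len(missing)} absent genes scored 0",
                          stacklevel=2)
        cols = np.zeros((adata.n_obs, len(genes)))
        for j, g in enumerate(genes):
            if g in adata.var_names:
                cols[:, j] = M[:, adata.var_names.get_loc(g)]
        scores[lab] = cols.mean(axis=1)
    return pd.DataFrame(scores, index=adata.obs_names)


def zone_gene_sets(annotation: pd.DataFrame) -> dict:
    """Every OR mapped to exactly one zone set; class I its own set."""
    sets: dict = {lab: [] for lab in ZONE_ORDER}
    for g in annotation.itertuples():
        if g.or_class == "I":
            sets["I"].append(g.gene_id)
        elif np.isfinite(g.zone):
            sets[int(g.zone)].append(g.gene_id)
    return sets


def assign_spot_zone(adata, gene_sets: dict, merge_class_i: bool = True) -> pd.Series:
    """Assign each spot the zone with the largest summed normalised OR counts.

    Spots with zero raw OR transcripts are labelled "none"; exact ties
    break to the dorsal-most zone; class I wins are reported merged
    with zone 1 (class I ORs are expressed within zone 1).
    """
    if "normalized" not in adata.layers:
        normalize_spots(adata)
    M = np.asarray(adata.layers["normalized"])
    raw = _dense(adata.X)
    or_mask = adata.var["is_or"].to_numpy(bool)
    has_or = raw[:, or_mask].sum(axis=1) > 0

    sums = np.zeros((adata.n_obs, len(ZONE_ORDER)))
    for li, lab in enumerate(ZONE_ORDER):
        idx = [adata.var_names.get_loc(g) for g in gene_sets.get(lab, [])
               if g in adata.var_names]
        if idx:
            sums[:, li] = M[:, idx].sum(axis=1)
    # argmax with dorsal-most tie-break: ZONE_ORDER is already sorted
    # dorsal-first, and np.argmax returns the first maximum
    best = np.argmax(sums, axis=1)
    labels = []
    for i in range(adata.n_obs):
        if not has_or[i]:
            labels.append("none")
            continue
        lab = ZONE_ORDER[best[i]]
        if lab == "I" and merge_class_i:
            lab = 1
        labels.append(lab)
    return pd.Series(labels, index=adata.obs_names, name="zone")


def dorsalization_index(assign_control: pd.Series, assign_perturbed: pd.Series) -> dict:
    """Summary of a perturbation-induced dorsomedial shift.

    ``index``: among perturbed spots assigned neither zone 1 nor
    "none", the fraction assigned zone 2 (1.0 = complete dorsomedial
    homeosis).  ``shift_table``: control-assignment x
    perturbed-assignment counts over the common spots.
    """
    pert = assign_perturbed
    eligible = ~pert.isin([1, "none"])
    index = float((pert[eligible] == 2).mean()) if eligible.any() else 0.0
    common = assign_control.index.intersection(pert.index)
    shift = pd.crosstab(assign_control.loc[common], pert.loc[common],
                        rownames=["control"], colnames=["perturbed"])
    return {
        "index": index,
        "shift_table": shift,
        "n_control": int(len(assign_control)),
        "n_perturbed": int(len(pert)),
    }


def assignment_accuracy(assign: pd.Series, truth: pd.Series) -> float:
    """Fraction of spots whose assigned zone equals the generating band."""
    common = assign.index.intersection(truth.index)
    a = assign.loc[common]
    t = truth.loc[common]
    ok = [(x == y) for x, y in zip(a, t)]
    return float(np.mean(ok))
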