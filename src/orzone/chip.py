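"""Heterochromatin gene-body densities and the dorsoventral gradient.

Coverage lives in a :class:`CoverageTrack` (stepwise per-chromosome
intervals).  Tracks are normalised to a 10-million-read library before
densities are computed; gene-body density is the per-bp mean of
normalised depth over the gene.  The dorsoventral trend of class II OR
densities is quantified by a rank correlation against zone with a
seeded permutation null (the published figures show box plots only, so
the statistic is an explicit, swappable design choice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LIBRARY_TARGET = 10_000_000


@dataclass
class CoverageTrack:
    """Stepwise coverage: chrom -> (starts, ends, values) arrays."""

    intervals: dict = field(default_factory=dict)
    library_size: float | None = None
    normalized: bool = False

    def normalize(self) -> "CoverageTrack":
        """Scale to a library size of 10 million reads (idempotence guarded)."""
        if self.normalized:
            raise ValueError("track already normalized")
        if not self.library_size or self.library_size <= 0:
            raise ValueError("library_size required for normalization")
        f = LIBRARY_TARGET / self.library_size
        scaled = {
            c: (s.copy(), e.copy(), v * f) for c, (s, e, v) in self.intervals.items()
        }
        return CoverageTrack(intervals=scaled, library_size=self.library_size,
                             normalized=True)

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base depth over [start, end) (zero where uncovered)."""
        out = np.zeros(end - start)
        if chrom not in self.intervals:
            return out
        s, e, v = self.intervals[chrom]
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        for i in range(lo, hi):
            a, b = max(s[i], start), min(e[i], end)
            if a < b:
                out[a - start: b - start] = v[i]
        return out


def gene_body_density(track: CoverageTrack, gene) -> float:
    """Normalised reads per bp over the gene body [start, end).

    ``gene`` is any object with chrom/start/end attributes or a mapping.
    """
    if not track.normalized:
        raise ValueError("normalize the track to the 10M-read target first")
    chrom, start, end = _gene_fields(gene)
    if chrom not in track.intervals:
        raise ValueError(f"gene on {chrom} outside the track extent")
    s, e, v = track.intervals[chrom]
    if len(e) and end > e.max() and start >= e.max():
        raise ValueError(f"gene {chrom}:{start}-{end} outside the track extent")
    # interval-overlap sum; equivalent to the per-base oracle
    lo = np.searchsorted(e, start, side="right")
    hi = np.searchsorted(s, end, side="left")
    total = 0.0
    for i in range(lo, hi):
        total += v[i] * max(0, min(e[i], end) - max(s[i], start))
    return total / (end - start)


def _gene_fields(gene):
    if isinstance(gene, dict):
        return gene["chrom"], int(gene["start"]), int(gene["end"])
    return gene.chrom, int(gene.start), int(gene.end)


def density_table(track: CoverageTrack, annotation: pd.DataFrame) -> pd.DataFrame:
    """Gene-body densities for every OR in the annotation."""
    rows = []
    for g in annotation.itertuples():
        rows.append(
            {
                "gene_id": g.gene_id,
                "zone": int(g.zone) if np.isfinite(g.zone) else np.nan,
                "or_class": g.or_class,
                "density": gene_body_density(track, g),
            }
        )
    return pd.DataFrame(rows)


def track_from_densities(table: pd.DataFrame, annotation: pd.DataFrame,
                         library_size: float = LIBRARY_TARGET) -> CoverageTrack:
    """Paint per-gene densities uniformly over gene bodies (for bedGraph
    export of simulated ChIP; round-trips through gene_body_density)."""
    dens = dict(zip(table["gene_id"], table["density"]))
    per_chrom: dict = {}
    for g in annotation.sort_values(["chrom", "start"]).itertuples():
        per_chrom.setdefault(g.chrom, []).append((g.start, g.end, dens[g.gene_id]))
    intervals = {
        c: (
            np.array([r[0] for r in rows]),
            np.array([r[1] for r in rows]),
            np.array([r[2] for r in rows], dtype=float),
        )
        for c, rows in per_chrom.items()
    }
    return CoverageTrack(intervals=intervals, library_size=library_size,
                         normalized=True)


def scaled_metagene_matrix(track: CoverageTrack, genes: pd.DataFrame,
                           body_len: int = 6000, flank: int = 2000,
                           n_bins: int = 100) -> pd.DataFrame:
    """Scaled metagene matrix: gene bodies resampled to ``body_len`` with
    unscaled flanks, minus-strand genes reversed, rows ordered by
    (zone, gene id).  Columns are labelled by the offset of each bin
    start relative to the scaled TSS.
    """
    if not track.normalized:
        raise ValueError("normalize the track first")
    total_len = body_len + 2 * flank
    edges = np.linspace(0, total_len, n_bins + 1).astype(int)
    order = genes.assign(_z=genes["zone"].fillna(99)).sort_values(
        ["_z", "gene_id"], kind="mergesort"
    )
    rows, index = [], []
    for g in order.itertuples():
        length = g.end - g.start
        if length < 2:
            warnings.warn(f"gene {g.gene_id} shorter than 2 bp; interpolating",
                          stacklevel=2)
        up = track.per_base(g.chrom, max(0, g.start - flank), g.start)
        if len(up) < flank:  # gene too close to the chromosome start
            up = np.concatenate([np.zeros(flank - len(up)), up])
        body = track.per_base(g.chrom, g.start, g.end)
        down = track.per_base(g.chrom, g.end, g.end + flank)
        scaled_body = np.interp(
            np.linspace(0, max(length - 1, 1), body_len),
            np.arange(length), body,
        )
        profile = np.concatenate([up, scaled_body, down])
        if g.strand == "-":
            profile = profile[::-1]
        binned = np.add.reduceat(profile, edges[:-1]) / np.diff(edges)
        rows.append(binned)
        index.append(g.gene_id)
    cols = edges[:-1] - flank
    return pd.DataFrame(rows, index=index, columns=cols)


def zonal_gradient_stat(table: pd.DataFrame, n_perm: int = 10_000,
                        seed: int = 0, zones=None) -> dict:
    """Dorsoventral trend of class II OR densities.

    Returns per-zone summaries, the Spearman rank correlation of
    density against zone (negative = heterochromatin decreasing towards
    ventral identities), and a two-sided permutation p-value from
    seeded zone-label shuffles.  Class I ORs are excluded (they sit at
    background and are separately regulated).
    """
    sub = table[(table["or_class"] != "I") & table["zone"].notna()]
    if zones is not None:
        sub = sub[sub["zone"].isin(zones)]
    zone = sub["zone"].to_numpy(float)
    dens = sub["density"].to_numpy(float)
    if len(np.unique(zone)) < 2:
        raise ValueError("need at least 2 zones for a gradient")
    per_zone = (
        sub.groupby(sub["zone"].astype(int))["density"]
        .agg(["mean", "median", "count"])
        .to_dict("index")
    )
    if np.allclose(dens, dens[0]):
        return {"per_zone": per_zone, "trend": 0.0, "p_perm": 1.0}
    rho = stats.spearmanr(zone, dens).statistic
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r = stats.spearmanr(rng.permutation(zone), dens).statistic
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    return {
        "per_zone": per_zone,
        "trend": float(rho),
        "p_perm": (hits + 1) / (n_perm + 1),
    }


def fit_silencing_params(tables: dict, annotation: pd.DataFrame, params) -> dict:
    """Recover the silencing rheostat (sigma_own, lambda) from ChIP tables.

    ``tables`` maps tissue zone -> density table (densities on the
    expected-silenced-fraction scale emitted by the simulator).  The
    transcription side of the model (a0, promoter strengths, escape
    scale) is treated as known acquisition metadata; the two silencing
    parameters are fit by bounded least squares on all class II genes
    with non-negative dorsal offset.
    """
    from scipy.optimize import least_squares

    s = np.asarray(params.promoter_strength, float)
    d_list, dens_list, w_list = [], [], []
    zone_of = dict(zip(annotation["gene_id"], annotation["zone"]))
    cls_of = dict(zip(annotation["gene_id"], annotation["or_class"]))
    for tissue_zone, table in tables.items():
        for g in table.itertuples():
            if cls_of.get(g.gene_id) == "I":
                continue
            z_o = int(zone_of[g.gene_id])
            if z_o > tissue_zone:
                continue  # not permitted, never silenced
            w = params.base_rate * s[z_o - 1]
            d_list.append(tissue_zone - z_o)
            w_list.append(w)
            dens_list.append(g.density)
    d = np.array(d_list, float)
    w = np.array(w_list, float)
    dens = np.array(dens_list, float)
    p_tx = 1.0 - np.exp(-w)
    escape = np.exp(-w / params.escape_scale)

    def resid(theta):
        sig0, lam = theta
        sigma = sig0 + (1 - sig0) * (1 - np.exp(-lam * d))
        return p_tx * sigma * escape - dens

    fit = least_squares(resid, x0=[0.5, 1.0], bounds=([0.0, 1e-3], [1.0, 20.0]))
    return {"sil_own": float(fit.x[0]), "sil_shape": float(fit.x[1]),
            "cost": float(fit.cost), "n_genes": int(len(d))}
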