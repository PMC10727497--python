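"""Single-cell 3D genome structure analysis.

Structures are haplotype-resolved bead tables (.3dg convention: one
bead per 20 kb per haplotype chromosome, coordinates in particle-radius
units; 10 radii correspond to roughly 600 nm, but all geometry here
stays in particle-radius units).  The module computes pairwise OR
distances, calls OR aggregates (compartments) as connected components
of the proximity graph, and compares per-cell OR contact densities
between groups with a Wilcoxon rank-sum test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

DEFAULT_RADIUS = 10.0


@dataclass
class AggregateSet:
    """OR aggregates of one cell: disjoint components of size >= 2."""

    components: list
    radius: float
    zone_composition: list = field(default_factory=list)

    @property
    def sizes(self) -> list:
        return [len(c) for c in self.components]

    def summary(self) -> dict:
        n_chroms = [
            len({m.split("!")[0].split("(")[0] for m in comp})
            for comp in self.components
        ]
        return {
            "n_aggregates": len(self.components),
            "sizes": self.sizes,
            "mean_size": float(np.mean(self.sizes)) if self.components else 0.0,
            "chromosomes_per_aggregate": n_chroms,
        }


def resolve_loci(structure: pd.DataFrame, loci) -> pd.DataFrame:
    """Map loci (name, chrom, pos) to the nearest bead on each haplotype.

    Returns a table with one row per (locus, haplotype), ids suffixed
    with the haplotype-chromosome.  A locus whose chromosome has no
    beads raises, naming the locus.
    """
    hap_chroms = structure["chrom"].unique()
    by_hap = {c: structure[structure["chrom"] == c] for c in hap_chroms}
    rows = []
    for name, chrom, pos in loci:
        matches = [hc for hc in hap_chroms if hc.split("(")[0] == chrom]
        if not matches:
            raise ValueError(f"locus {name} ({chrom}:{pos}) off any chromosome")
        for hc in sorted(matches):
            sub = by_hap[hc]
            i = (sub["pos"] - pos).abs().idxmin()
            bead = sub.loc[i]
            rows.append(
                {
                    "locus_id": f"{name}!{hc}",
                    "name": name,
                    "chrom": hc,
                    "pos": int(bead["pos"]),
                    "x": bead["x"],
                    "y": bead["y"],
                    "z": bead["z"],
                }
            )
    return pd.DataFrame(rows)


def pairwise_distances(structure: pd.DataFrame, loci) -> pd.DataFrame:
    """Euclidean distance matrix between resolved loci (both haplotypes)."""
    res = resolve_loci(structure, loci)
    xyz = res[["x", "y", "z"]].to_numpy(float)
    d = cdist(xyz, xyz)
    return pd.DataFrame(d, index=res["locus_id"], columns=res["locus_id"])


def or_aggregates(structure: pd.DataFrame, or_loci, radius: float = DEFAULT_RADIUS,
                  zone_of: dict | None = None) -> AggregateSet:
    """Call OR aggregates: connected components (size >= 2) of the graph
    joining OR beads within ``radius``.

    ``or_loci`` is a list of (name, chrom, pos); ``zone_of`` optionally
    maps name -> zonal identity for the per-component composition and
    the per-zone in-aggregate fractions.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    res = resolve_loci(structure, or_loci)
    xyz = res[["x", "y", "z"]].to_numpy(float)
    n = len(res)
    adj = cdist(xyz, xyz) <= radius
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    ids = res["locus_id"].to_numpy()
    comps = []
    for lab in np.unique(labels):
        members = ids[labels == lab]
        if len(members) >= 2:
            comps.append(sorted(members))
    comps.sort(key=lambda c: (-len(c), c[0]))
    zone_comp = []
    if zone_of is not None:
        for comp in comps:
            zc: dict = {}
            for m in comp:
                z = zone_of.get(m.split("!")[0])
                zc[z] = zc.get(z, 0) + 1
            zone_comp.append(zc)
    return AggregateSet(components=comps, radius=radius, zone_composition=zone_comp)


def in_aggregate_fraction_by_zone(agg: AggregateSet, or_loci, zone_of: dict) -> dict:
    """Fraction of each zone's OR loci (x2 haplotypes) inside any aggregate."""
    member = {m for comp in agg.components for m in comp}
    totals: dict = {}
    hits: dict = {}
    for name, _, _ in or_loci:
        z = zone_of.get(name)
        totals[z] = totals.get(z, 0) + 2  # two haplotypes per locus
    for m in member:
        z = zone_of.get(m.split("!")[0])
        hits[z] = hits.get(z, 0) + 1
    return {z: hits.get(z, 0) / t for z, t in totals.items() if t}


def contact_density(cell_contacts: pd.DataFrame, group_loci,
                    neighborhood: int = 50_000) -> float:
    """OR-OR contact density of one cell.

    Counts contacts whose both ends fall within ``neighborhood`` bp of
    a group locus (haplotype-aware), normalised by the number of
    eligible unordered locus pairs.  ``group_loci`` rows are
    (name, chrom, pos) with plain chromosome names; both haplotypes of
    each locus are eligible.
    """
    loci = [(n, c, p) for n, c, p in group_loci]
    n_hap_loci = 2 * len(loci)
    n_pairs = n_hap_loci * (n_hap_loci - 1) // 2
    if n_pairs == 0:
        return 0.0
    if cell_contacts.empty:
        warnings.warn("empty contact list; density 0", stacklevel=2)
        return 0.0

    by_chrom: dict = {}
    for _, c, p in loci:
        by_chrom.setdefault(c, []).append(p)
    pos_arrays = {c: np.sort(np.array(v)) for c, v in by_chrom.items()}

    def near(chrom_hap, pos):
        c = chrom_hap.split("(")[0]
        arr = pos_arrays.get(c)
        if arr is None:
            return False
        i = np.searchsorted(arr, pos)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(arr[j] - pos) <= neighborhood:
                return True
        return False

    total = 0.0
    counts = cell_contacts["count"] if "count" in cell_contacts else None
    for k, row in enumerate(cell_contacts.itertuples()):
        if near(row.chrom_a, row.pos_a) and near(row.chrom_b, row.pos_b):
            total += float(counts.iloc[k]) if counts is not None else 1.0
    return total / n_pairs


def filter_cells_by_contacts(contact_lists: dict, min_contacts: int = 20_000) -> dict:
    """Keep cells with at least ``min_contacts`` total contacts (the
    read-count QC applied to synthetic contact counts)."""
    out = {}
    for cid, df in contact_lists.items():
        n = int(df["count"].sum()) if "count" in df else len(df)
        if n >= min_contacts:
            out[cid] = df
    return out


def rank_sum_test(group_a, group_b) -> dict:
    """Wilcoxon–Mann–Whitney rank-sum test, two-sided.

    Exact enumeration of the U null distribution when the smaller group
    has at most 8 values and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  Identical
    groups give p = 1.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return {"U": len(a) * len(b) / 2.0, "p_two_sided": 1.0}
    ranks = pd.Series(pooled).rank().to_numpy()
    ra = ranks[: len(a)].sum()
    n1, n2 = len(a), len(b)
    u_a = ra - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < len(pooled)

    if min(n1, n2) <= 8 and not has_ties:
        # exact: enumerate all C(n1+n2, n1) assignments of ranks to group A
        all_ranks = np.arange(1, n1 + n2 + 1)
        target = min(u_a, n1 * n2 - u_a)
        count = 0
        total = 0
        for comb in combinations(all_ranks, n1):
            total += 1
            u = sum(comb) - n1 * (n1 + 1) / 2.0
            if min(u, n1 * n2 - u) <= target + 1e-9:
                count += 1
        return {"U": float(u_a), "p_two_sided": min(1.0, count / total)}

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return {"U": float(u_a), "p_two_sided": 1.0}
    z = (u_a - mu - math.copysign(0.5, u_a - mu)) / math.sqrt(var)
    from scipy.stats import norm

    p = 2.0 * norm.sf(abs(z))
    return {"U": float(u_a), "p_two_sided": float(min(1.0, p))}
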