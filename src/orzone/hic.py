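"""Binned contact matrices and zone-pair trans aggregation.

A :class:`ContactMatrix` stores a bin table plus upper-triangle sparse
pixels.  Raw counts are normalised to counts/billion before analysis.
The zone-pair map averages trans (interchromosomal) pixel values over
all bin pairs whose zonal label sets contain the two zones — class I
bins excluded by default, multi-label bins contributing to every zone
they carry, and unobserved trans pixels counting as zeros (informative
absences at fixed sequencing depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from orzone.annotation import CLASS_I_LABEL, GenomicBin

CPB = 1_000_000_000


@dataclass
class ContactMatrix:
    """bins: (chrom, start, end); pixels: (bin1_id, bin2_id, count), i <= j."""

    bins: pd.DataFrame
    pixels: pd.DataFrame
    resolution: int
    normalization: str = "raw"
    total_raw: float = 0.0

    def __post_init__(self) -> None:
        if (self.pixels["bin1_id"] > self.pixels["bin2_id"]).any():
            raise ValueError("pixels must be upper-triangle (bin1_id <= bin2_id)")


def normalize_cpb(matrix: ContactMatrix) -> ContactMatrix:
    """Scale raw pixel counts to counts/billion.

    The symmetric total (off-diagonal pixels counted twice) defines the
    library size, so the normalised symmetric sum is exactly 1e9.
    Normalising twice is an error.
    """
    if matrix.normalization != "raw":
        raise ValueError("matrix is already normalized")
    diag = matrix.pixels["bin1_id"] == matrix.pixels["bin2_id"]
    total = float((matrix.pixels["count"] * np.where(diag, 1, 2)).sum())
    if total == 0:
        raise ValueError("cannot normalize an empty matrix (total_raw = 0)")
    pixels = matrix.pixels.copy()
    pixels["count"] = pixels["count"] * (CPB / total)
    return ContactMatrix(bins=matrix.bins, pixels=pixels,
                         resolution=matrix.resolution,
                         normalization="counts_per_billion", total_raw=total)


def extract_cis_block(matrix: ContactMatrix, region_a, region_b,
                      resolution: int = 100_000, cap: float = 150.0):
    """Dense cis block between two non-overlapping same-chromosome regions.

    Native bins are aggregated by sum into ``resolution``-sized bins.
    Returns (raw_block, display_block); the display copy is capped at
    ``cap`` (the figure colour-scale convention), the raw block is not.
    Regions are (chrom, start, end) tuples.
    """
    (ca, sa, ea), (cb, sb, eb) = region_a, region_b
    if ca != cb:
        raise ValueError("regions must be on the same chromosome")
    if max(sa, sb) < min(ea, eb):
        raise ValueError("regions overlap")
    if resolution % matrix.resolution != 0:
        raise ValueError("target resolution must be a multiple of the native one")
    bins = matrix.bins
    na = int(np.ceil((ea - sa) / resolution))
    nb = int(np.ceil((eb - sb) / resolution))
    block = np.zeros((na, nb))

    on_chrom = bins["chrom"] == ca
    starts = bins["start"].to_numpy()
    in_a = on_chrom & (starts >= sa) & (starts < ea)
    in_b = on_chrom & (starts >= sb) & (starts < eb)
    a_of = {i: (starts[i] - sa) // resolution for i in np.flatnonzero(in_a)}
    b_of = {i: (starts[i] - sb) // resolution for i in np.flatnonzero(in_b)}
    for p in matrix.pixels.itertuples():
        i, j, c = p.bin1_id, p.bin2_id, p.count
        for x, y in ((i, j), (j, i)):
            if x in a_of and y in b_of:
                block[a_of[x], b_of[y]] += c
    return block, np.minimum(block, cap)


@dataclass
class ZonePairMap:
    """Mean trans contacts between class II zonal categories (5x5)."""

    values: np.ndarray
    n_pairs: np.ndarray
    zones: tuple = (1, 2, 3, 4, 5)
    missing: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.missing is None:
            self.missing = self.n_pairs == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.zones),
                            columns=list(self.zones))


def zone_pair_trans_map(matrix: ContactMatrix, bins: list,
                        exclude_class_i: bool = True,
                        use_primary_only: bool = False) -> ZonePairMap:
    """Average interchromosomal contacts between zone-labelled bins.

    ``bins`` are :class:`~orzone.annotation.GenomicBin` produced at the
    matrix resolution.  For zones (p, q) the cell is the mean pixel
    value over all trans bin pairs where one bin carries label p and
    the other label q (multi-label bins contribute to every zone they
    carry, or only their primary zone with ``use_primary_only``).
    Missing pixels count as zero.
    """
    if matrix.normalization == "raw":
        raise ValueError("normalize the matrix before aggregation")
    bin_id = {}
    for i, row in enumerate(matrix.bins.itertuples()):
        bin_id[(row.chrom, row.start)] = i
    chrom_of = matrix.bins["chrom"].to_numpy()

    zone_bins: dict[int, list] = {z: [] for z in (1, 2, 3, 4, 5)}
    for b in bins:
        if b.resolution != matrix.resolution:
            raise ValueError("bin annotation resolution differs from matrix")
        key = (b.chrom, b.start)
        if key not in bin_id:
            continue
        labels = {b.primary_zone} if use_primary_only else set(b.zone_labels)
        for lab in labels:
            if lab == CLASS_I_LABEL:
                if not exclude_class_i:
                    continue  # class I has no numeric zone cell
                continue
            zone_bins[int(lab)].append(bin_id[key])

    lookup = {}
    for p in matrix.pixels.itertuples():
        lookup[(p.bin1_id, p.bin2_id)] = p.count

    values = np.zeros((5, 5))
    n_pairs = np.zeros((5, 5), dtype=int)
    for pi, p in enumerate((1, 2, 3, 4, 5)):
        for qi, q in enumerate((1, 2, 3, 4, 5)):
            if qi < pi:
                continue
            total, n = 0.0, 0
            for i in zone_bins[p]:
                for j in zone_bins[q]:
                    if chrom_of[i] == chrom_of[j]:
                        continue
                    if p == q and j <= i:
                        continue  # unordered pairs within a zone
                    a, b = (i, j) if i < j else (j, i)
                    total += lookup.get((a, b), 0.0)
                    n += 1
            if n:
                values[pi, qi] = values[qi, pi] = total / n
            n_pairs[pi, qi] = n_pairs[qi, pi] = n
    if n_pairs.sum() == 0:
        raise ValueError("no trans bin pairs between annotated zones")
    return ZonePairMap(values=values, n_pairs=n_pairs)


def annotate_matrix_bins(matrix: ContactMatrix, annotation: pd.DataFrame) -> list:
    """Zone-label the matrix's own bins from an OR annotation table
    (thin wrapper over :func:`orzone.annotation.annotate_bins` that
    keeps only bins present in the matrix)."""
    from orzone.annotation import annotate_bins

    labelled = annotate_bins(annotation, matrix.resolution)
    present = {(r.chrom, r.start) for r in matrix.bins.itertuples()}
    return [b for b in labelled if (b.chrom, b.start) in present]


__all__ = [
    "ContactMatrix",
    "ZonePairMap",
    "normalize_cpb",
    "extract_cis_block",
    "zone_pair_trans_map",
    "annotate_matrix_bins",
    "GenomicBin",
]
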