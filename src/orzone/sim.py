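"""Generative "two opposing rheostats" model of zonal OR gene choice.

The model formalises a verbal picture of singular OR choice in the
mouse olfactory epithelium: in each dorsoventral zone, progenitor
(INP) cells transcribe a *polygenic* mixture of OR genes drawn from the
zone-appropriate and all more-dorsal repertoires; heterochromatic
silencing, whose strength grows with the dorsal offset between the OR's
native zone and the cell's zone, then prunes that mixture during
differentiation; a mature neuron (mOSN) finally picks one survivor with
probability proportional to its transcriptional propensity.

Everything downstream — UMI counts, ChIP coverage, Hi-C contacts,
single-cell 3D structures and spatial spots — is emitted from the same
latent per-cell state, so every analysis module in the package can be
exercised against a known ground truth.

Functional forms (all are this package's own formalisation of the
verbal model; see ``docs/methods.md``):

* permission: a class II OR of zone ``z_o`` may be transcribed in a cell
  of zone ``z_c`` with multiplier ``A = 1`` if ``z_o <= z_c`` else the
  ectopic leak ``epsilon``; class I ORs only in zone-1 cells; an
  experimentally induced allele bypasses permission,
* propensity: ``w = a0 * s(z_o) * A``, times ``(1 + tau)`` for the
  induced allele; transcription probability ``1 - exp(-w)``,
* silencing of a transcribed OR at dorsal offset ``d = max(z_c - z_o, 0)``:
  ``sigma(d) = sigma_own + (1 - sigma_own) * (1 - exp(-lam * d))``,
  multiplied by the induction-escape factor ``exp(-w / theta)``,
* NFI triple knockout: cells of zone >= 2 behave with effective zone
  ``min(z_c, 2)`` for class II permission and silencing offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from orzone.annotation import ANNOTATION_COLUMNS, bin_zone

STAGES = ("GBC", "INP", "iOSN", "mOSN")

# substream tags for the single master seed
_S_GENOME, _S_TISSUE, _S_CHIP, _S_HIC, _S_STRUCT, _S_SPATIAL, _S_COUNTS = range(7)


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-derived substream: identical (seed, key) -> identical draws,
    independent of execution order."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key)))


@dataclass
class RheostatParams:
    """All parameters of the generative zonal-choice model.

    Repertoire sizes default to a ~1/10 scale of the published census
    (class I 115; class II 261/283/164/144/44 over zones 1..5) so that
    whole-tissue simulations stay desk-sized while preserving the
    strongly dorsal-skewed composition of the real repertoire.
    """

    # genome
    n_class_i: int = 12
    n_per_zone: tuple = (26, 28, 16, 14, 5)
    n_clusters: int = 6
    n_chromosomes: int = 3
    chrom_length: int = 6_000_000
    gene_length: int = 3_000
    gene_spacing: int = 100_000
    structure_resolution: int = 20_000

    # transcription rheostat (dorsal-high promoter strength gradient)
    promoter_strength: tuple = (1.0, 0.95, 0.90, 0.85, 0.80)
    base_rate: float = 1.5  # a0
    ectopic_leak: float = 0.0  # epsilon

    # silencing rheostat
    sil_own: float = 0.1  # sigma_own
    sil_shape: float = 3.5  # lam
    escape_scale: float = 1.0e6  # theta

    # perturbations
    nfi_ko: bool = False
    induced_or: str | None = None
    induction: float = 0.0  # tau

    # sampling / emission
    seq_depth: float = 1.0
    or_high_mean: float = 60.0
    or_low_mean: float = 0.3
    residual_mean: float = 0.05
    ambient: float = 0.01
    noise: float = 0.02  # ChIP measurement noise (lognormal sd)
    n_housekeeping: int = 1200
    hk_mean: float = 25.0
    n_mito: int = 10
    mito_mean: float = 50.0
    marker_mean: float = 30.0
    hic_scale: float = 200.0
    hic_noise: float = 0.05
    cis_scale: float = 100.0
    step_length: float = 8.0
    attractor_radius: float = 50.0
    attractor_sd: float = 2.0
    contact_radius: float = 6.0
    contact_mult: float = 15.0

    seed: int = 0

    def __post_init__(self) -> None:
        s = np.asarray(self.promoter_strength, dtype=float)
        if len(s) != 5 or np.any(s <= 0) or np.any(np.diff(s) > 0):
            raise ValueError("promoter_strength must be 5 positive non-increasing values")
        for name in ("ectopic_leak", "sil_own"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.base_rate <= 0 or self.sil_shape <= 0 or self.escape_scale <= 0:
            raise ValueError("base_rate, sil_shape and escape_scale must be positive")
        if self.induction < 0:
            raise ValueError("induction must be non-negative")


@dataclass
class SimulatedCell:
    """Latent state of one simulated cell."""

    cell_id: str
    stage: str
    dv_zone: int
    transcribed: dict = field(default_factory=dict)  # gene_id -> propensity
    silenced: set = field(default_factory=set)
    chosen: str | None = None
    n_choice_attempts: int = 0


@dataclass
class SimulatedTissue:
    cells: list
    genome: pd.DataFrame
    params: RheostatParams

    def cells_of(self, dv_zone=None, stage=None):
        out = self.cells
        if dv_zone is not None:
            out = [c for c in out if c.dv_zone == dv_zone]
        if stage is not None:
            out = [c for c in out if c.stage == stage]
        return out


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def build_genome(params: RheostatParams, seed: int | None = None) -> pd.DataFrame:
    """Place the OR repertoire in mixed-zone clusters on synthetic chromosomes.

    Genes are interleaved across zonal identities before being chunked
    into ``n_clusters`` contiguous clusters, so every cluster mixes
    zones (clusters of mixed zonal constitution are the rule in the
    real genome).  Reproducible for a given seed.
    """
    if params.n_class_i + sum(params.n_per_zone) == 0:
        raise ValueError("genome must contain at least one OR gene")
    if params.n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes for trans-contact analyses")
    rng = _rng(params.seed if seed is None else seed, _S_GENOME)

    # one entry per gene: (class, zone)
    pools = [[("I", 1)] * params.n_class_i] + [
        [("II", z)] * n for z, n in zip(range(1, 6), params.n_per_zone)
    ]
    interleaved = []
    idx = [0] * len(pools)
    while any(i < len(p) for i, p in zip(idx, pools)):
        for k, p in enumerate(pools):
            if idx[k] < len(p):
                interleaved.append(p[idx[k]])
                idx[k] += 1
    n_genes = len(interleaved)
    n_clusters = max(1, min(params.n_clusters, n_genes))
    bounds = np.linspace(0, n_genes, n_clusters + 1).astype(int)

    rows, counters = [], {"I": 0, 1: 0, 2: 0, 3: 0, 4: 0, 5: 0}
    for ci in range(n_clusters):
        members = interleaved[bounds[ci]: bounds[ci + 1]]
        chrom = ci % params.n_chromosomes
        per_chrom_cluster = ci // params.n_chromosomes
        span = params.chrom_length // (1 + (n_clusters - 1) // params.n_chromosomes)
        pos = per_chrom_cluster * span + int(rng.integers(50_000, 150_000))
        for or_class, zone in members:
            spacing = int(rng.integers(params.gene_spacing // 2, params.gene_spacing * 3 // 2))
            start = pos
            end = start + params.gene_length
            pos = end + spacing
            if or_class == "I":
                counters["I"] += 1
                gene_id = f"OrI-{counters['I']}"
                zidx = round(float(rng.uniform(1.0, 1.2)), 3)
            else:
                counters[zone] += 1
                gene_id = f"Or{zone}-{counters[zone]}"
                zidx = round(float(rng.uniform(max(1.0, zone - 0.45), min(5.0, zone + 0.45))), 3)
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": f"chr{chrom + 1}",
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "or_class": or_class,
                    "zonal_index": zidx,
                    "cluster_id": f"cluster_{ci + 1}",
                }
            )
    df = pd.DataFrame(rows)
    if df["end"].max() > params.chrom_length:
        raise ValueError("chrom_length too small for repertoire; increase it")
    df["zone"] = bin_zone(df["zonal_index"].to_numpy())
    return df[ANNOTATION_COLUMNS]


# ---------------------------------------------------------------------------
# per-gene probabilities
# ---------------------------------------------------------------------------

def effective_zone(dv_zone: int, params: RheostatParams) -> int:
    """NFI knockout clamps class II regulation to an effective zone of 2."""
    return min(dv_zone, 2) if params.nfi_ko else dv_zone


def gene_propensities(params: RheostatParams, genome: pd.DataFrame, dv_zone: int):
    """Per-gene (propensity w, transcription probability, silencing probability).

    Vectors aligned with ``genome`` rows for a cell of ``dv_zone``.
    """
    if dv_zone not in (1, 2, 3, 4, 5):
        raise ValueError("dv_zone must be in 1..5")
    z_eff = effective_zone(dv_zone, params)
    s = np.asarray(params.promoter_strength, dtype=float)
    zones = genome["zone"].to_numpy(dtype=float)
    is_class_i = (genome["or_class"] == "I").to_numpy()
    z_int = np.where(is_class_i, 1, zones).astype(int)

    strength = s[z_int - 1]
    permission = np.where(z_int <= z_eff, 1.0, params.ectopic_leak)
    permission = np.where(is_class_i, 1.0 if z_eff == 1 else 0.0, permission)
    induced = (genome["gene_id"] == params.induced_or).to_numpy() if params.induced_or else np.zeros(len(genome), bool)
    # transgenic induction bypasses zonal permission
    permission = np.where(induced, 1.0, permission)

    w = params.base_rate * strength * permission
    w = np.where(induced, w * (1.0 + params.induction), w)
    p_tx = 1.0 - np.exp(-w)

    d = np.maximum(z_eff - z_int, 0)
    sigma = params.sil_own + (1.0 - params.sil_own) * (1.0 - np.exp(-params.sil_shape * d))
    with np.errstate(over="ignore"):
        escape = np.exp(-w / params.escape_scale)
    p_sil = np.where(is_class_i, 0.0, sigma * escape)  # class I is never silenced
    p_sil = np.where(w > 0, p_sil, 0.0)
    return w, p_tx, p_sil


def simulate_cell(
    params: RheostatParams,
    genome: pd.DataFrame,
    dv_zone: int,
    stage: str = "mOSN",
    seed: int | None = None,
    cell_id: str = "cell",
    rng: np.random.Generator | None = None,
) -> SimulatedCell:
    """Draw one cell's latent state (transcription, silencing, choice).

    GBC cells transcribe no ORs; INP cells carry the polygenic
    transcribed set; iOSN cells add the silencing state; mOSN cells
    additionally choose one surviving OR with probability proportional
    to propensity, redrawing (fresh randomness) if every transcribed OR
    was silenced.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    if rng is None:
        rng = _rng(params.seed if seed is None else seed, _S_TISSUE, dv_zone)
    cell = SimulatedCell(cell_id=cell_id, stage=stage, dv_zone=dv_zone)
    if stage == "GBC":
        return cell
    w, p_tx, p_sil = gene_propensities(params, genome, dv_zone)
    gene_ids = genome["gene_id"].to_numpy()
    for attempt in range(1, 1001):
        tx = rng.random(len(w)) < p_tx
        cell.transcribed = dict(zip(gene_ids[tx], w[tx]))
        if stage == "INP":
            cell.n_choice_attempts = attempt
            return cell
        sil = tx & (rng.random(len(w)) < p_sil)
        cell.silenced = set(gene_ids[sil])
        if stage == "iOSN":
            cell.n_choice_attempts = attempt
            return cell
        surv = tx & ~sil
        if surv.any():
            probs = w[surv] / w[surv].sum()
            cell.chosen = str(rng.choice(gene_ids[surv], p=probs))
            cell.n_choice_attempts = attempt
            return cell
    raise RuntimeError(
        f"no surviving OR after 1000 redraws (dv_zone={dv_zone}, params seed={params.seed})"
    )


def simulate_tissue(
    params: RheostatParams,
    n_cells_per_zone: int,
    stage_mix: dict | None = None,
    zones=(1, 2, 3, 4, 5),
) -> SimulatedTissue:
    """Simulate a whole tissue: ``n_cells_per_zone`` cells per zone.

    ``stage_mix`` maps stage -> fraction (default all mOSN).  Each cell
    uses a counter-derived random substream, so the tissue is
    reproducible bit-for-bit and independent of iteration order.
    """
    if n_cells_per_zone < 1:
        raise ValueError("n_cells_per_zone must be >= 1")
    stage_mix = stage_mix or {"mOSN": 1.0}
    stages, fracs = zip(*sorted(stage_mix.items()))
    cum = np.cumsum(fracs) / np.sum(fracs)
    genome = build_genome(params)
    cells = []
    for z in zones:
        for i in range(n_cells_per_zone):
            rng = _rng(params.seed, _S_TISSUE, z, i)
            stage = stages[int(np.searchsorted(cum, rng.random(), side="right"))]
            cells.append(
                simulate_cell(
                    params, genome, z, stage=stage, cell_id=f"z{z}_c{i}", rng=rng
                )
            )
    return SimulatedTissue(cells=cells, genome=genome, params=params)


def apply_nfi_knockout(params: RheostatParams) -> RheostatParams:
    """Return a copy of the parameters with the NFI triple knockout applied."""
    return replace(params, nfi_ko=True)


def expected_zone_breadth(params: RheostatParams, genome: pd.DataFrame, dv_zone: int) -> float:
    """Closed-form expected number of distinct class II zonal identities
    transcribed by one cell of ``dv_zone`` (Monte-Carlo oracle)."""
    _, p_tx, _ = gene_propensities(params, genome, dv_zone)
    cii = (genome["or_class"] == "II").to_numpy()
    total = 0.0
    for z in range(1, 6):
        mask = cii & (genome["zone"].to_numpy() == z)
        if mask.any():
            total += 1.0 - np.prod(1.0 - p_tx[mask])
    return total


def choice_frequency(
    params: RheostatParams,
    genome: pd.DataFrame,
    dv_zone: int,
    gene_id: str,
    n_mc: int = 2000,
    seed: int | None = None,
) -> float:
    """Rao-Blackwellised estimate of P(chosen OR == ``gene_id``).

    Monte-Carlo draws the survivor set of the *competing* repertoire and
    averages the analytic conditional choice probability of the target,
    which keeps the estimator informative even when the target's
    survival probability is tiny (deep silencing in ventral zones).
    """
    rng = _rng(params.seed if seed is None else seed, _S_TISSUE, dv_zone, 999_999)
    w, p_tx, p_sil = gene_propensities(params, genome, dv_zone)
    t = int(np.flatnonzero(genome["gene_id"].to_numpy() == gene_id)[0])
    p_surv_t = p_tx[t] * (1.0 - p_sil[t])
    rest = np.ones(len(w), bool)
    rest[t] = False
    acc = 0.0
    for _ in range(n_mc):
        alive = rest & (rng.random(len(w)) < p_tx) & (rng.random(len(w)) >= p_sil)
        w_rest = w[alive].sum()
        acc += w[t] / (w[t] + w_rest) if (w[t] + w_rest) > 0 else 0.0
    return float(p_surv_t * acc / n_mc)


# ---------------------------------------------------------------------------
# emission: single-cell UMI counts
# ---------------------------------------------------------------------------

def emit_sc_counts(tissue: SimulatedTissue, params: RheostatParams | None = None):
    """Emit a cells x genes UMI count matrix (AnnData) from the latent state.

    OR genes: INP/iOSN cells get Poisson counts on transcribed,
    un-silenced ORs with mean ``or_low_mean * propensity * seq_depth``;
    mOSN cells get the chosen OR at ``or_high_mean * seq_depth`` and
    surviving non-chosen ORs at ``residual_mean``.  Housekeeping,
    mitochondrial and stage-marker genes are added for QC realism, and
    ``ambient`` adds uniform background to every gene.
    """
    import anndata as ad
    from scipy import sparse

    params = params or tissue.params
    if not tissue.cells:
        raise ValueError("tissue has no cells")
    genome = tissue.genome
    or_ids = list(genome["gene_id"])
    hk = [f"Hk-{i + 1}" for i in range(params.n_housekeeping)]
    mito = [f"mt-Gene{i + 1}" for i in range(params.n_mito)]
    markers = [f"Marker-{s}" for s in STAGES]
    var = pd.DataFrame(
        {
            "gene_id": or_ids + hk + mito + markers,
            "is_or": [True] * len(or_ids) + [False] * (len(hk) + len(mito) + len(markers)),
            "is_mito": [False] * len(or_ids + hk) + [True] * len(mito) + [False] * len(markers),
        }
    ).set_index("gene_id")
    var["or_class"] = [*genome["or_class"]] + [""] * (len(hk) + len(mito) + len(markers))
    var["zone"] = [*genome["zone"]] + [np.nan] * (len(hk) + len(mito) + len(markers))

    n_genes = len(var)
    or_index = {g: i for i, g in enumerate(or_ids)}
    depth = params.seq_depth
    X = np.zeros((len(tissue.cells), n_genes))
    obs_rows = []
    for ci, cell in enumerate(tissue.cells):
        rng = _rng(params.seed, _S_COUNTS, cell.dv_zone, ci)
        mean = np.full(n_genes, params.ambient * depth)
        if cell.stage in ("INP", "iOSN"):
            for g, w in cell.transcribed.items():
                if g not in cell.silenced:
                    mean[or_index[g]] += params.or_low_mean * w * depth
        elif cell.stage == "mOSN":
            for g, w in cell.transcribed.items():
                if g not in cell.silenced and g != cell.chosen:
                    mean[or_index[g]] += params.residual_mean * depth
            if cell.chosen is not None:
                mean[or_index[cell.chosen]] += params.or_high_mean * depth
        mean[len(or_ids): len(or_ids) + len(hk)] += params.hk_mean * depth
        mean[len(or_ids) + len(hk): len(or_ids) + len(hk) + len(mito)] += params.mito_mean * depth
        mean[-len(markers):] += 0.5 * depth
        mean[n_genes - len(markers) + STAGES.index(cell.stage)] += params.marker_mean * depth
        X[ci] = rng.poisson(mean)
        obs_rows.append(
            {
                "cell_id": cell.cell_id,
                "stage": cell.stage,
                "dv_zone": cell.dv_zone,
                "origin": "dorsal" if cell.dv_zone <= 2 else "ventral",
                "chosen_or": cell.chosen or "",
            }
        )
    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    return ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)


# ---------------------------------------------------------------------------
# emission: ChIP-seq gene-body densities
# ---------------------------------------------------------------------------

def expected_silencing(params: RheostatParams, genome: pd.DataFrame, dv_zone: int) -> np.ndarray:
    """Analytic per-gene probability of being (transcribed and) silenced
    in a cell of ``dv_zone`` — the infinite-cell limit of the mean
    silencing indicator."""
    _, p_tx, p_sil = gene_propensities(params, genome, dv_zone)
    return p_tx * p_sil


def emit_chip_coverage(
    tissue: SimulatedTissue,
    zone: int,
    exact: bool = False,
    noise: float | None = None,
) -> pd.DataFrame:
    """Per-OR heterochromatin density table for one zone's cells.

    Density is the fraction of the zone's (post-silencing-stage) cells
    in which the OR is silenced; ``exact=True`` uses the analytic
    expectation instead of the finite-cell average.  Multiplicative
    lognormal measurement noise with sd ``noise`` (default
    ``params.noise``) is applied when positive.  Class I ORs are never
    silenced and therefore sit at background.
    """
    params = tissue.params
    noise = params.noise if noise is None else noise
    genome = tissue.genome
    if exact:
        dens = expected_silencing(params, genome, zone)
    else:
        cells = [c for c in tissue.cells_of(dv_zone=zone) if c.stage in ("iOSN", "mOSN")]
        if not cells:
            raise ValueError(f"no post-silencing cells of zone {zone} in tissue")
        gene_ids = genome["gene_id"].to_numpy()
        counts = np.zeros(len(gene_ids))
        idx = {g: i for i, g in enumerate(gene_ids)}
        for c in cells:
            for g in c.silenced:
                counts[idx[g]] += 1
        dens = counts / len(cells)
    if noise > 0:
        rng = _rng(params.seed, _S_CHIP, zone, 1 if exact else 0)
        dens = dens * np.exp(rng.normal(0.0, noise, size=len(dens)))
    return pd.DataFrame(
        {
            "gene_id": genome["gene_id"],
            "zone": genome["zone"].astype(int),
            "or_class": genome["or_class"],
            "density": dens,
        }
    )


# ---------------------------------------------------------------------------
# emission: Hi-C contact matrices
# ---------------------------------------------------------------------------

def emit_hic_contacts(tissue: SimulatedTissue, zone: int, resolution: int = 50_000):
    """Emit a raw binned contact matrix for one zone's cell population.

    Trans intensity between two OR-containing bins is proportional to
    the product of their residing ORs' expected silencing probabilities
    (silenced ORs co-aggregate); cis pixels add a power-law distance
    decay; every pixel receives uniform background and Poisson sampling.
    """
    from orzone.hic import ContactMatrix

    params = tissue.params
    genome = tissue.genome
    if params.chrom_length % resolution != 0:
        raise ValueError("resolution must divide chrom_length")
    nb = params.chrom_length // resolution
    chroms = [f"chr{c + 1}" for c in range(params.n_chromosomes)]
    bins = pd.DataFrame(
        {
            "chrom": np.repeat(chroms, nb),
            "start": np.tile(np.arange(nb) * resolution, params.n_chromosomes),
        }
    )
    bins["end"] = bins["start"] + resolution

    sil = expected_silencing(params, genome, zone)
    S = np.zeros(len(bins))
    offset = {c: i * nb for i, c in enumerate(chroms)}
    acc: dict[int, list] = {}
    for g, p in zip(genome.itertuples(), sil):
        first, last = g.start // resolution, (g.end - 1) // resolution
        for b in range(first, last + 1):
            acc.setdefault(offset[g.chrom] + b, []).append(p)
    for b, vals in acc.items():
        S[b] = float(np.mean(vals))

    rng = _rng(params.seed, _S_HIC, zone)
    chrom_of = np.repeat(np.arange(params.n_chromosomes), nb)
    pos_of = np.tile(np.arange(nb), params.n_chromosomes)
    i, j = np.triu_indices(len(bins))
    same = chrom_of[i] == chrom_of[j]
    intensity = np.full(len(i), params.hic_noise)
    intensity += params.hic_scale * S[i] * S[j]
    dist = np.abs(pos_of[i] - pos_of[j])
    intensity[same] += params.cis_scale / (1.0 + dist[same]) ** 1.2
    counts = rng.poisson(intensity).astype(float)
    keep = counts > 0
    pixels = pd.DataFrame({"bin1_id": i[keep], "bin2_id": j[keep], "count": counts[keep]})
    diag = pixels["bin1_id"] == pixels["bin2_id"]
    total = float((pixels["count"] * np.where(diag, 1, 2)).sum())
    return ContactMatrix(bins=bins, pixels=pixels, resolution=resolution,
                         normalization="raw", total_raw=total)


# ---------------------------------------------------------------------------
# emission: single-cell 3D structures and contacts
# ---------------------------------------------------------------------------

def emit_structure(cell: SimulatedCell, params: RheostatParams,
                   genome: pd.DataFrame, seed: int | None = None) -> pd.DataFrame:
    """Emit a haplotype-resolved bead structure (.3dg-style table).

    Each haplotype chromosome is a persistent (worm-like) random walk of
    beads at ``structure_resolution`` spacing, in particle-radius units.
    Beads of silenced OR genes (both haplotypes) are displaced to a
    small random number of shared attractor points near the nuclear
    centre — the OR compartments; un-silenced OR beads stay on the
    backbone.  Stochastic placement: same silenced set, different seed
    -> different aggregate membership.
    """
    import zlib

    stable_id = zlib.crc32(cell.cell_id.encode()) % (2**31)
    rng = _rng(params.seed if seed is None else seed, _S_STRUCT, stable_id)
    nb = params.chrom_length // params.structure_resolution
    n_att = 1 + rng.poisson(2)
    attractors = rng.normal(0.0, params.attractor_radius / 2.0, size=(n_att, 3))

    sil_beads = {}
    for g in genome.itertuples():
        if g.gene_id in cell.silenced:
            mid = (g.start + g.end) // 2
            bead = int(round(mid / params.structure_resolution))
            sil_beads[(g.chrom, min(bead, nb - 1))] = True

    rows = []
    for c in range(params.n_chromosomes):
        chrom = f"chr{c + 1}"
        for hap in ("pat", "mat"):
            origin = rng.normal(0.0, 120.0, size=3)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = origin.copy()
            for b in range(nb):
                if b > 0:
                    turn = rng.normal(0.0, 0.15, size=3)
                    direction = direction + turn
                    direction /= np.linalg.norm(direction)
                    pos = pos + params.step_length * direction
                xyz = pos
                if (chrom, b) in sil_beads:
                    att = attractors[rng.integers(n_att)]
                    xyz = att + rng.normal(0.0, params.attractor_sd, size=3)
                rows.append(
                    (
                        f"{chrom}({hap})",
                        b * params.structure_resolution,
                        float(xyz[0]),
                        float(xyz[1]),
                        float(xyz[2]),
                    )
                )
    return pd.DataFrame(rows, columns=["chrom", "pos", "x", "y", "z"])


def emit_dipc_contacts(structure: pd.DataFrame, params: RheostatParams,
                       seed: int = 0) -> pd.DataFrame:
    """Emit a single-cell contact list from a 3D structure.

    Bead pairs closer than ``contact_radius`` and backbone-adjacent
    bead pairs each emit a Poisson(``contact_mult``) number of contacts.
    """
    from scipy.spatial.distance import pdist, squareform

    rng = _rng(seed, _S_STRUCT, 777)
    xyz = structure[["x", "y", "z"]].to_numpy()
    d = squareform(pdist(xyz))
    close = np.triu(d <= params.contact_radius, k=1)
    chroms = structure["chrom"].to_numpy()
    pos = structure["pos"].to_numpy()
    adjacent = np.zeros_like(close)
    same = (chroms[:-1] == chroms[1:])
    idx = np.flatnonzero(same)
    adjacent[idx, idx + 1] = True
    pairs = np.argwhere(close | adjacent)
    counts = rng.poisson(params.contact_mult, size=len(pairs))
    keep = counts > 0
    pairs, counts = pairs[keep], counts[keep]
    return pd.DataFrame(
        {
            "chrom_a": chroms[pairs[:, 0]],
            "pos_a": pos[pairs[:, 0]],
            "chrom_b": chroms[pairs[:, 1]],
            "pos_b": pos[pairs[:, 1]],
            "count": counts,
        }
    )


# ---------------------------------------------------------------------------
# emission: spatial spots
# ---------------------------------------------------------------------------

def emit_spatial(tissue: SimulatedTissue, grid_shape: tuple = (15, 8),
                 params: RheostatParams | None = None, band_purity: float = 0.8):
    """Emit a spatial spot matrix from a five-band tissue section.

    Grid rows map monotonically to the five dorsoventral bands (rows
    must be a multiple of 5).  Each spot pools 5-30 mOSN expression
    profiles from its band's zone; rows at band boundaries draw a
    ``1 - band_purity`` fraction of their cells from the neighbouring
    band.  Returns an AnnData with obs columns x, y and band_zone.
    """
    import anndata as ad
    from scipy import sparse

    params = params or tissue.params
    rows, cols = grid_shape
    if rows % 5 != 0:
        raise ValueError("grid rows must be a multiple of 5 (one block per zone band)")
    per_band = rows // 5
    by_zone = {z: tissue.cells_of(dv_zone=z, stage="mOSN") for z in range(1, 6)}
    for z, cells in by_zone.items():
        if not cells:
            raise ValueError(f"tissue has no mOSN cells in zone {z}")

    genome = tissue.genome
    or_ids = list(genome["gene_id"])
    hk = [f"Hk-{i + 1}" for i in range(20)]
    var = pd.DataFrame(
        {
            "gene_id": or_ids + hk,
            "is_or": [True] * len(or_ids) + [False] * len(hk),
        }
    ).set_index("gene_id")
    var["or_class"] = [*genome["or_class"]] + [""] * len(hk)
    var["zone"] = [*genome["zone"]] + [np.nan] * len(hk)
    or_index = {g: i for i, g in enumerate(or_ids)}

    X = np.zeros((rows * cols, len(var)))
    obs_rows = []
    for r in range(rows):
        band = r // per_band + 1
        within = r % per_band
        neighbour = None
        if within == 0 and band > 1:
            neighbour = band - 1
        elif within == per_band - 1 and band < 5:
            neighbour = band + 1
        for q in range(cols):
            si = r * cols + q
            rng = _rng(params.seed, _S_SPATIAL, r, q)
            n_cells = int(rng.integers(5, 31))
            mean = np.full(len(var), params.ambient)
            mean[len(or_ids):] += params.hk_mean / 10.0
            for _ in range(n_cells):
                z = band
                if neighbour is not None and rng.random() > band_purity:
                    z = neighbour
                cell = by_zone[z][int(rng.integers(len(by_zone[z])))]
                if cell.chosen is not None:
                    mean[or_index[cell.chosen]] += params.or_high_mean
                for g in cell.transcribed:
                    if g not in cell.silenced and g != cell.chosen:
                        mean[or_index[g]] += params.residual_mean
            X[si] = rng.poisson(mean)
            obs_rows.append(
                {"barcode": f"spot_r{r}_c{q}", "x": float(q), "y": float(r), "band_zone": band}
            )
    obs = pd.DataFrame(obs_rows).set_index("barcode")
    return ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)
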