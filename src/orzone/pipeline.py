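"""End-to-end demonstration pipeline.

Runs simulate -> annotate -> sc-profile -> chip-gradient -> hic-zonemap
-> dipc-aggregates -> spatial-assign on synthetic tissue, writing every
intermediate in the package's text formats plus a manifest with
parameter values, the seed and a hash of every output file.  Two runs
with the same configuration are hash-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from orzone import annotation as ann
from orzone import chip, dipc, hic, io, singlecell, spatial
from orzone import sim


@dataclass
class RunConfig:
    """Pipeline configuration; defaults give a small but complete demo."""

    outdir: str = "orzone_run"
    seed: int = 0
    params: sim.RheostatParams = field(default_factory=sim.RheostatParams)
    annotation_path: str | None = None  # external annotation instead of simulated
    n_cells_per_zone: int = 150
    n_structures_per_group: int = 6
    grid_shape: tuple = (15, 8)
    bin_resolution: int = 50_000
    n_perm: int = 2000
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.annotation_path is not None and not Path(self.annotation_path).exists():
            raise ValueError(f"annotation_path does not exist: {self.annotation_path}")
        self.params = dataclasses.replace(self.params, seed=self.seed)


def _write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest.  A stage failure aborts
    with the stage name and cause."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ctx: dict = {"config": config}
    stages = [
        ("simulate", stage_simulate),
        ("annotate", stage_annotate),
        ("sc-profile", stage_sc_profile),
        ("chip-gradient", stage_chip_gradient),
        ("hic-zonemap", stage_hic_zonemap),
        ("dipc-aggregates", stage_dipc_aggregates),
        ("spatial-assign", stage_spatial_assign),
    ]
    for name, fn in stages:
        try:
            fn(ctx, out)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    return io.write_manifest(out, config.params)


def stage_simulate(ctx: dict, out: Path) -> None:
    config: RunConfig = ctx["config"]
    params = config.params
    tissue = sim.simulate_tissue(
        params, config.n_cells_per_zone, stage_mix={"INP": 0.5, "mOSN": 0.5}
    )
    ko_tissue = sim.simulate_tissue(
        sim.apply_nfi_knockout(params), config.n_cells_per_zone,
        stage_mix={"mOSN": 1.0},
    )
    ctx["tissue"], ctx["ko_tissue"] = tissue, ko_tissue
    if config.annotation_path:
        ctx["genome"] = ann.read_or_annotation(config.annotation_path)
    else:
        ctx["genome"] = tissue.genome
    ann.write_or_annotation(ctx["genome"], out / "or_annotation.tsv")
    io.write_params(params, out / "params.yaml")


def stage_annotate(ctx: dict, out: Path) -> None:
    config: RunConfig = ctx["config"]
    genome = ctx["genome"]
    _write_json(out / "census.json", ann.zone_census(genome))
    bins = ann.annotate_bins(genome, config.bin_resolution)
    pd.DataFrame(
        {
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "resolution": [b.resolution for b in bins],
            "zone_labels": [",".join(str(z) for z in sorted(b.zone_labels, key=str))
                            for b in bins],
            "primary_zone": [b.primary_zone for b in bins],
        }
    ).to_csv(out / "zone_bins.tsv", sep="\t", index=False)
    ann.to_bed6(genome, out / "or_annotation.bed")
    ctx["bins"] = bins


def stage_sc_profile(ctx: dict, out: Path) -> None:
    tissue = ctx["tissue"]
    adata = sim.emit_sc_counts(tissue)
    io.write_mtx(adata, out / "sc_counts")
    filtered, report = singlecell.qc_filter_cells(adata)
    profiles, summary = singlecell.polygenic_zone_profile(filtered, ctx["genome"])
    singular = 0
    mosn = filtered.obs["stage"] == "mOSN"
    expressed = singlecell.detect_expressed_ors(filtered[mosn])
    if len(expressed):
        singular = float(np.mean([len(v) == 1 for v in expressed.values()]))
    _write_json(out / "sc_profile.json",
                {"qc": report, "polygenic_summary": summary,
                 "mosn_singular_fraction": singular})


def stage_chip_gradient(ctx: dict, out: Path) -> None:
    config: RunConfig = ctx["config"]
    tissue = ctx["tissue"]
    table = sim.emit_chip_coverage(tissue, zone=5)
    table.to_csv(out / "chip_density_zone5.tsv", sep="\t", index=False)
    track = chip.track_from_densities(table, ctx["genome"])
    io.write_bedgraph(track, out / "chip_zone5.bedgraph")
    stat = chip.zonal_gradient_stat(table, n_perm=config.n_perm, seed=config.seed)
    meta = chip.scaled_metagene_matrix(track, ctx["genome"], n_bins=50)
    meta.to_csv(out / "chip_metagene_zone5.tsv", sep="\t")
    _write_json(out / "chip_gradient.json",
                {"trend": stat["trend"], "p_perm": stat["p_perm"],
                 "per_zone": {str(k): v for k, v in stat["per_zone"].items()}})


def stage_hic_zonemap(ctx: dict, out: Path) -> None:
    config: RunConfig = ctx["config"]
    matrix = sim.emit_hic_contacts(ctx["tissue"], zone=5,
                                   resolution=config.bin_resolution)
    io.write_contacts(matrix, out / "hic_zone5")
    norm = hic.normalize_cpb(matrix)
    bins = hic.annotate_matrix_bins(norm, ctx["genome"])
    zmap = hic.zone_pair_trans_map(norm, bins)
    zmap.to_frame().to_csv(out / "zone_pair_map_zone5.tsv", sep="\t")


def stage_dipc_aggregates(ctx: dict, out: Path) -> None:
    config: RunConfig = ctx["config"]
    tissue = ctx["tissue"]
    genome = ctx["genome"]
    or_loci = [(g.gene_id, g.chrom, (g.start + g.end) // 2)
               for g in genome.itertuples()]
    zone_of = {g.gene_id: ("I" if g.or_class == "I" else int(g.zone))
               for g in genome.itertuples()}
    (out / "structures").mkdir(exist_ok=True)
    report: dict = {}
    densities_by_group: dict = {}
    for group, zone in (("dorsal", 1), ("ventral", 5)):
        cells = tissue.cells_of(dv_zone=zone, stage="mOSN")[: config.n_structures_per_group]
        sizes, densities = [], []
        for cell in cells:
            structure = sim.emit_structure(cell, tissue.params, genome)
            io.write_3dg(structure, out / "structures" / f"{cell.cell_id}.3dg")
            agg = dipc.or_aggregates(structure, or_loci, zone_of=zone_of)
            sizes.append(agg.summary()["mean_size"])
            contacts = sim.emit_dipc_contacts(structure, tissue.params,
                                              seed=config.seed)
            densities.append(dipc.contact_density(contacts, or_loci))
        densities_by_group[group] = densities
        report[group] = {"mean_aggregate_size": float(np.mean(sizes)),
                         "mean_contact_density": float(np.mean(densities)),
                         "n_cells": len(cells)}
    test = dipc.rank_sum_test(densities_by_group["dorsal"],
                              densities_by_group["ventral"])
    report["rank_sum"] = {"U": test["U"], "p_two_sided": test["p_two_sided"]}
    _write_json(out / "dipc_aggregates.json", report)
    ctx["dipc_report"] = report


def stage_spatial_assign(ctx: dict, out: Path) -> None:
    config: RunConfig = ctx["config"]
    genome = ctx["genome"]
    results = {}
    assignments = {}
    for label, tissue in (("control", ctx["tissue"]), ("nfi_ko", ctx["ko_tissue"])):
        spots = sim.emit_spatial(tissue, grid_shape=config.grid_shape)
        io.write_spots(spots, out / f"spatial_{label}")
        kept, flagged = spatial.filter_spots(spots)
        spatial.normalize_spots(flagged)
        assign = spatial.assign_spot_zone(flagged, spatial.zone_gene_sets(genome))
        assign.to_frame().assign(band=flagged.obs["band_zone"].values).to_csv(
            out / f"spatial_assignment_{label}.tsv", sep="\t"
        )
        truth = flagged.obs["band_zone"]
        results[label] = {
            "n_spots": int(spots.n_obs),
            "n_passed_filter": int(kept.n_obs),
            "accuracy_vs_band": spatial.assignment_accuracy(assign, truth),
        }
        assignments[label] = assign
    dors = spatial.dorsalization_index(assignments["control"], assignments["nfi_ko"])
    results["dorsalization_index"] = dors["index"]
    dors["shift_table"].to_csv(out / "spatial_shift_table.tsv", sep="\t")
    _write_json(out / "spatial_assign.json", results)
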