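"""Generative model: determinism, permission/silencing structure, emissions."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from orzone import annotation as ann
from orzone import dipc, sim


def test_build_genome_deterministic_and_mixed_clusters():
    p = sim.RheostatParams(n_class_i=2, n_per_zone=(2, 2, 2, 2, 2), n_clusters=2,
                           seed=4)
    g1, g2 = sim.build_genome(p), sim.build_genome(p)
    pd.testing.assert_frame_equal(g1, g2)
    assert len(g1) == 12
    for _, cluster in g1.groupby("cluster_id"):
        assert cluster["zone"].nunique() >= 2


def test_build_genome_seed_changes_coordinates_not_census(params, genome):
    other = sim.build_genome(params, seed=params.seed + 1)
    assert ann.zone_census(other) == ann.zone_census(genome)
    assert not other["start"].equals(genome["start"])


def test_build_genome_empty_repertoire_errors():
    with pytest.raises(ValueError):
        sim.build_genome(sim.RheostatParams(n_class_i=0, n_per_zone=(0,) * 5))


def test_promoter_strength_must_be_non_increasing():
    with pytest.raises(ValueError):
        sim.RheostatParams(promoter_strength=(1.0, 1.1, 0.9, 0.8, 0.7))


def test_zone1_cell_transcribes_only_dorsal_repertoire(params, genome):
    cell = sim.simulate_cell(params, genome, 1, "INP", seed=2)
    zones = {genome.set_index("gene_id").loc[g, "zone"] for g in cell.transcribed}
    assert zones <= {1}


def test_silenced_subset_of_transcribed_and_single_choice(params, genome):
    for z in (1, 3, 5):
        cell = sim.simulate_cell(params, genome, z, "mOSN", seed=z)
        assert cell.silenced <= set(cell.transcribed)
        assert cell.chosen in cell.transcribed
        assert cell.chosen not in cell.silenced


def test_tissue_reproducible_same_seed(params):
    t1 = sim.simulate_tissue(params, 5)
    t2 = sim.simulate_tissue(params, 5)
    assert [c.chosen for c in t1.cells] == [c.chosen for c in t2.cells]
    assert all(c.chosen is not None for c in t1.cells)
    assert len(t1.cells) == 25


def test_repertoire_breadth_increases_with_zone(params, genome):
    """Mean number of distinct transcribed class II zonal identities grows
    from dorsal to ventral cells and matches the closed form."""
    zone_of = dict(zip(genome["gene_id"], genome["zone"]))
    cls_of = dict(zip(genome["gene_id"], genome["or_class"]))
    means = []
    for z in (1, 2, 3, 4, 5):
        breadth = []
        for i in range(200):
            cell = sim.simulate_cell(
                params, genome, z, "INP",
                rng=np.random.default_rng([21, z, i]),
            )
            breadth.append(
                len({zone_of[g] for g in cell.transcribed if cls_of[g] == "II"})
            )
        means.append(np.mean(breadth))
        expected = sim.expected_zone_breadth(params, genome, z)
        assert abs(means[-1] - expected) < 0.15
    assert all(a < b for a, b in zip(means, means[1:]))


def test_nfi_ko_clamps_ventral_to_zone2(params, genome):
    ko = sim.apply_nfi_knockout(params)
    cell = sim.simulate_cell(ko, genome, 5, "INP", seed=6)
    zones = {genome.set_index("gene_id").loc[g, "zone"] for g in cell.transcribed}
    assert zones <= {1, 2}


def test_nfi_ko_zone1_cells_identical_to_control(params, genome):
    ko = sim.apply_nfi_knockout(params)
    for i in range(10):
        a = sim.simulate_cell(params, genome, 1, "mOSN",
                              rng=np.random.default_rng([31, i]))
        b = sim.simulate_cell(ko, genome, 1, "mOSN",
                              rng=np.random.default_rng([31, i]))
        assert a.chosen == b.chosen and a.silenced == b.silenced


def test_nfi_ko_choices_are_zone2_identity(params, genome, zone_of):
    ko = sim.apply_nfi_knockout(params)
    for z in (2, 5):
        chosen = [
            sim.simulate_cell(ko, genome, z, "mOSN",
                              rng=np.random.default_rng([41, z, i])).chosen
            for i in range(400)
        ]
        frac_z2 = np.mean([zone_of[c] == 2 for c in chosen])
        assert frac_z2 >= 0.95


def test_choice_frequency_matches_empirical(params, genome):
    target = "Or2-1"
    est = sim.choice_frequency(params, genome, 2, target, n_mc=4000, seed=9)
    emp = np.mean(
        [
            sim.simulate_cell(params, genome, 2, "mOSN",
                              rng=np.random.default_rng([51, i])).chosen == target
            for i in range(4000)
        ]
    )
    assert est == pytest.approx(emp, abs=0.015)


def test_induced_allele_dominates_everywhere_at_high_induction(params, genome):
    p = dataclasses.replace(params, induced_or="Or1-1", induction=1e7)
    for z in (1, 3, 5):
        assert sim.choice_frequency(p, genome, z, "Or1-1", n_mc=300) > 0.95


def test_sc_counts_without_ambient_only_on_transcribed(params):
    p = dataclasses.replace(params, ambient=0.0)
    tissue = sim.simulate_tissue(p, 10, stage_mix={"INP": 1.0}, zones=(5,))
    adata = sim.emit_sc_counts(tissue)
    or_mask = adata.var["is_or"].to_numpy()
    X = adata.X.toarray()
    for i, cell in enumerate(tissue.cells):
        nz = set(adata.var_names[or_mask][X[i, or_mask] > 0])
        assert nz <= set(cell.transcribed)


def test_mosn_counts_singular(params, mosn_tissue):
    from orzone import singlecell

    adata = sim.emit_sc_counts(mosn_tissue)
    expressed = singlecell.detect_expressed_ors(adata)
    frac_singular = np.mean([len(v) == 1 for v in expressed.values()])
    assert frac_singular >= 0.99


def test_chip_zone5_dorsal_exceeds_ventral(mosn_tissue):
    table = sim.emit_chip_coverage(mosn_tissue, 5)
    cii = table[table["or_class"] == "II"]
    assert cii[cii.zone == 1]["density"].mean() > cii[cii.zone == 5]["density"].mean()
    assert table[table["or_class"] == "I"]["density"].max() == 0.0


def test_chip_nfi_ko_ventral_zones_at_background(params):
    ko = sim.apply_nfi_knockout(params)
    tissue = sim.simulate_tissue(ko, 30, stage_mix={"mOSN": 1.0}, zones=(5,))
    table = sim.emit_chip_coverage(tissue, 5, noise=0.0)
    assert table[table["zone"].isin([4, 5]) & (table["or_class"] == "II")][
        "density"
    ].max() == 0.0


def test_structure_backbone_has_no_spurious_aggregates(params, genome, or_loci):
    """A cell with nothing silenced leaves all OR beads on backbones,
    which should almost never sit within aggregate radius."""
    with_agg = 0
    for s in range(20):
        cell = sim.SimulatedCell(cell_id=f"bare{s}", stage="mOSN", dv_zone=1)
        structure = sim.emit_structure(cell, params, genome, seed=s)
        if dipc.or_aggregates(structure, or_loci).components:
            with_agg += 1
    assert with_agg <= 1  # >= 95% of seeds aggregate-free


def test_ventral_aggregates_larger_than_dorsal(params, mosn_tissue, or_loci):
    sizes = {}
    for zone in (1, 5):
        vals = []
        for cell in mosn_tissue.cells_of(dv_zone=zone)[:8]:
            structure = sim.emit_structure(cell, params, mosn_tissue.genome)
            agg = dipc.or_aggregates(structure, or_loci)
            vals.append(agg.summary()["mean_size"])
        sizes[zone] = np.mean(vals)
    assert sizes[5] > sizes[1]


def test_same_silencing_different_seed_changes_membership(params, mosn_tissue, or_loci):
    cell = mosn_tissue.cells_of(dv_zone=5)[0]
    a = dipc.or_aggregates(
        sim.emit_structure(cell, params, mosn_tissue.genome, seed=1), or_loci
    )
    b = dipc.or_aggregates(
        sim.emit_structure(cell, params, mosn_tissue.genome, seed=2), or_loci
    )
    assert a.components != b.components


def test_spatial_pure_bands_have_matching_dominant_zone(params, mosn_tissue, zone_of):
    adata = sim.emit_spatial(mosn_tissue, grid_shape=(10, 3), band_purity=1.0)
    X = adata.X.toarray()
    or_names = adata.var_names[adata.var["is_or"]]
    Xor = X[:, adata.var["is_or"].to_numpy()]
    for i in range(adata.n_obs):
        zone_sum = {}
        for g, c in zip(or_names, Xor[i]):
            z = zone_of[g]
            z = 1 if z == "I" else z
            zone_sum[z] = zone_sum.get(z, 0) + c
        dominant = max(zone_sum, key=zone_sum.get)
        assert dominant == adata.obs["band_zone"].iloc[i]


def test_hic_all_noise_map_is_flat(params, mosn_tissue, genome):
    from orzone import hic

    flat = dataclasses.replace(params, hic_scale=0.0, hic_noise=2.0)
    tissue = sim.SimulatedTissue(cells=mosn_tissue.cells, genome=genome, params=flat)
    matrix = sim.emit_hic_contacts(tissue, 5)
    norm = hic.normalize_cpb(matrix)
    zmap = hic.zone_pair_trans_map(norm, hic.annotate_matrix_bins(norm, genome))
    vals = zmap.values[~zmap.missing]
    mean = vals.mean()
    # every pair is a cpb-scaled Poisson(hic_noise) draw, so the relative
    # standard error of a map cell is 1/sqrt(hic_noise * n_pairs)
    for (pi, qi), v in np.ndenumerate(zmap.values):
        if zmap.missing[pi, qi]:
            continue
        rel_se = 1.0 / np.sqrt(2.0 * zmap.n_pairs[pi, qi])
        assert abs(v - mean) / mean < 3.5 * rel_se
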