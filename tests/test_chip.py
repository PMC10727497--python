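"""Coverage tracks, gene-body densities, metagenes and the zonal trend."""

import numpy as np
import pandas as pd
import pytest

from orzone import chip, io, sim


def _track(intervals, library_size=chip.LIBRARY_TARGET, normalized=False):
    conv = {
        c: (
            np.array([r[0] for r in rows]),
            np.array([r[1] for r in rows]),
            np.array([r[2] for r in rows], dtype=float),
        )
        for c, rows in intervals.items()
    }
    return chip.CoverageTrack(intervals=conv, library_size=library_size,
                              normalized=normalized)


def gene(chrom="chr1", start=0, end=2000):
    return {"chrom": chrom, "start": start, "end": end}


def test_density_normalization_arithmetic():
    # 200 raw reads of depth spread uniformly over a 2 kb gene at library
    # size 20M: normalization halves it to 100, density 100/2000 = 0.05
    track = _track({"chr1": [(0, 2000, 0.1)]}, library_size=20_000_000)
    norm = track.normalize()
    assert chip.gene_body_density(norm, gene()) == pytest.approx(0.05)


def test_density_requires_normalized_track_and_idempotence_guard():
    track = _track({"chr1": [(0, 2000, 1.0)]}, library_size=1e7)
    with pytest.raises(ValueError, match="normalize"):
        chip.gene_body_density(track, gene())
    norm = track.normalize()
    with pytest.raises(ValueError, match="already"):
        norm.normalize()


def test_density_zero_coverage():
    track = _track({"chr1": [(5000, 6000, 3.0)]}, normalized=True)
    assert chip.gene_body_density(track, gene(start=0, end=2000)) == 0.0


def test_density_outside_track_errors():
    track = _track({"chr1": [(0, 1000, 1.0)]}, normalized=True)
    with pytest.raises(ValueError, match="chr9"):
        chip.gene_body_density(track, gene(chrom="chr9"))


def test_density_matches_per_base_oracle():
    rng = np.random.default_rng(2)
    pos, rows = 0, []
    for _ in range(50):
        length = int(rng.integers(10, 400))
        rows.append((pos, pos + length, float(rng.integers(0, 6))))
        pos += length + int(rng.integers(0, 100))
    track = _track({"chr1": rows}, normalized=True)
    g = gene(start=123, end=7321)
    per_base = track.per_base("chr1", g["start"], g["end"])
    assert chip.gene_body_density(track, g) == pytest.approx(
        per_base.sum() / (g["end"] - g["start"])
    )


def test_density_additive_over_track_chunks():
    rows = [(0, 1000, 2.0), (1000, 3000, 5.0), (3000, 4000, 1.0)]
    whole = _track({"chr1": rows}, normalized=True)
    parts = [_track({"chr1": [r]}, normalized=True) for r in rows]
    g = gene(start=500, end=3500)
    total = sum(chip.gene_body_density(p, g) for p in parts)
    assert chip.gene_body_density(whole, g) == pytest.approx(total)


def test_metagene_uniform_coverage_constant_rows():
    track = _track({"chr1": [(0, 100_000, 2.0)]}, normalized=True)
    genes = pd.DataFrame(
        [{"gene_id": "OrA", "chrom": "chr1", "start": 10_000, "end": 14_000,
          "strand": "+", "or_class": "II", "zone": 2}]
    )
    m = chip.scaled_metagene_matrix(track, genes, n_bins=20)
    assert np.allclose(m.to_numpy(), 2.0)
    # row mean over body columns equals the gene-body density
    assert m.loc["OrA"].mean() == pytest.approx(
        chip.gene_body_density(track, gene(start=10_000, end=14_000))
    )


def test_metagene_flank_signal_stays_in_flank_columns():
    track = _track({"chr1": [(8_000, 10_000, 4.0)]}, normalized=True)  # 5' flank only
    genes = pd.DataFrame(
        [{"gene_id": "OrA", "chrom": "chr1", "start": 10_000, "end": 16_000,
          "strand": "+", "or_class": "II", "zone": 2}]
    )
    m = chip.scaled_metagene_matrix(track, genes, n_bins=100)
    cols = m.columns.to_numpy()
    assert (m.loc["OrA", cols >= 0] == 0).all()
    assert (m.loc["OrA", cols < 0] > 0).all()


def test_metagene_minus_strand_reverses_profile():
    track = _track({"chr1": [(10_000, 11_000, 6.0)]}, normalized=True)
    base = {"gene_id": "OrA", "chrom": "chr1", "start": 10_000, "end": 16_000,
            "or_class": "II", "zone": 2}
    plus = chip.scaled_metagene_matrix(
        _copy_track(track), pd.DataFrame([{**base, "strand": "+"}]), n_bins=50)
    minus = chip.scaled_metagene_matrix(
        _copy_track(track), pd.DataFrame([{**base, "strand": "-"}]), n_bins=50)
    assert np.allclose(plus.to_numpy()[0], minus.to_numpy()[0][::-1])


def _copy_track(track):
    return chip.CoverageTrack(intervals=track.intervals,
                              library_size=track.library_size,
                              normalized=track.normalized)


def test_metagene_matches_per_base_resampling_oracle():
    rng = np.random.default_rng(7)
    rows = [(i * 100, (i + 1) * 100, float(rng.integers(0, 10))) for i in range(300)]
    track = _track({"chr1": rows}, normalized=True)
    g = {"gene_id": "OrA", "chrom": "chr1", "start": 5_000, "end": 9_000,
         "strand": "+", "or_class": "II", "zone": 3}
    m = chip.scaled_metagene_matrix(track, pd.DataFrame([g]), body_len=6000,
                                    flank=2000, n_bins=100)
    up = track.per_base("chr1", 3_000, 5_000)
    body = track.per_base("chr1", 5_000, 9_000)
    down = track.per_base("chr1", 9_000, 11_000)
    scaled = np.interp(np.linspace(0, len(body) - 1, 6000),
                       np.arange(len(body)), body)
    profile = np.concatenate([up, scaled, down])
    oracle = profile.reshape(100, -1).mean(axis=1)
    assert np.allclose(m.to_numpy()[0], oracle, atol=1e-9)


def _table(zones, densities, or_class="II"):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(zones))],
            "zone": zones,
            "or_class": [or_class] * len(zones),
            "density": densities,
        }
    )


def test_trend_is_minus_one_for_perfect_ordering():
    t = _table([1, 1, 2, 3, 4, 5], [9, 9, 7, 5, 3, 1])
    stat = chip.zonal_gradient_stat(t, n_perm=200, seed=0)
    assert stat["trend"] == pytest.approx(-1.0)
    assert stat["p_perm"] < 0.05


def test_trend_constant_densities():
    t = _table([1, 2, 3, 4, 5], [2.0] * 5)
    stat = chip.zonal_gradient_stat(t, n_perm=100, seed=0)
    assert stat["trend"] == 0.0 and stat["p_perm"] == 1.0


def test_trend_single_zone_errors():
    with pytest.raises(ValueError):
        chip.zonal_gradient_stat(_table([2, 2, 2], [1, 2, 3]))


def test_trend_excludes_class_i():
    t = pd.concat([
        _table([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]),
        _table([1, 1], [0.0, 0.0], or_class="I"),
    ])
    stat = chip.zonal_gradient_stat(t, n_perm=100, seed=0)
    assert stat["trend"] == pytest.approx(-1.0)


def test_permutation_p_uniform_under_null():
    """Under shuffled labels the permutation p-value is approximately
    uniform: across null tables, P(p < 0.25) stays within binomial error."""
    rng = np.random.default_rng(3)
    hits = 0
    n_tables = 40
    for _ in range(n_tables):
        t = _table(rng.integers(1, 6, size=30), rng.normal(5, 1, size=30))
        if chip.zonal_gradient_stat(t, n_perm=199, seed=1)["p_perm"] < 0.25:
            hits += 1
    assert 2 <= hits <= 19  # mean 10, sd ~2.7 under uniformity


def test_noiseless_emission_trend_and_nfi_attenuation(params, mosn_tissue):
    table = sim.emit_chip_coverage(mosn_tissue, 5, exact=True, noise=0.0)
    stat = chip.zonal_gradient_stat(table, n_perm=300, seed=0)
    assert stat["trend"] == pytest.approx(-1.0)
    ko = sim.apply_nfi_knockout(params)
    ko_tissue = sim.SimulatedTissue(cells=[], genome=mosn_tissue.genome, params=ko)
    ko_table = sim.emit_chip_coverage(ko_tissue, 5, exact=True, noise=0.0)
    sub = chip.zonal_gradient_stat(ko_table, zones=(3, 4, 5), n_perm=100, seed=0)
    assert abs(sub["trend"]) < abs(
        chip.zonal_gradient_stat(table, zones=(3, 4, 5), n_perm=100, seed=0)["trend"]
    )


def test_silencing_parameter_recovery(params):
    tissue = sim.simulate_tissue(params, 400, stage_mix={"mOSN": 1.0},
                                 zones=(1, 3, 5))
    tables = {z: sim.emit_chip_coverage(tissue, z) for z in (1, 3, 5)}
    fit = chip.fit_silencing_params(tables, tissue.genome, params)
    assert fit["sil_own"] == pytest.approx(params.sil_own, rel=0.2)
    assert fit["sil_shape"] == pytest.approx(params.sil_shape, rel=0.2)


def test_bedgraph_roundtrip(tmp_path, mosn_tissue):
    table = sim.emit_chip_coverage(mosn_tissue, 5, noise=0.0)
    track = chip.track_from_densities(table, mosn_tissue.genome)
    path = tmp_path / "zone5.bedgraph"
    io.write_bedgraph(track, path)
    back = io.read_bedgraph(path, library_size=chip.LIBRARY_TARGET, normalized=True)
    table2 = chip.density_table(back, mosn_tissue.genome)
    assert np.allclose(table["density"].to_numpy(),
                       table2["density"].to_numpy(), atol=1e-9)
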