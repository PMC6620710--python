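"""Generator contracts: determinism, geometry, planted-parameter manifests."""
import json
import math

import numpy as np
import pytest

from agomet import association as assoc
from agomet import clip as clip_mod
from agomet import io, synth


def test_truth_validation():
    with pytest.raises(ValueError):
        synth.SyntheticTruth(p_met_given_ago=1.5)
    with pytest.raises(ValueError):
        synth.SyntheticTruth(promoter_span=700)  # < 15 x 50 bp
    with pytest.raises(ValueError):
        synth.SyntheticTruth(line1_pattern_probs=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        synth.SyntheticTruth(multiplicity_range=(2, 99))
    with pytest.raises(ValueError):
        # planted labels would leak onto neighboring probes
        synth.SyntheticTruth(promoter_span=750, assoc_d_max=40,
                             site_offset_max=20)


def test_planted_or_odds_arithmetic():
    truth = synth.SyntheticTruth(p_met_given_ago=0.6367, p_met_given_noago=0.3)
    assert truth.planted_or == pytest.approx(
        (0.6367 / 0.3633) / (0.3 / 0.7), rel=1e-12)
    assert truth.planted_or == pytest.approx(4.0893, abs=5e-4)
    null = synth.SyntheticTruth(p_met_given_ago=0.3, p_met_given_noago=0.3)
    assert null.planted_or == pytest.approx(1.0)


def test_implied_correlation_closed_form():
    truth = synth.SyntheticTruth(corr_slope=5.0, corr_site_count_mean=2.0,
                                 corr_noise_sd=41.0)
    # r = slope*sqrt(var k)/sqrt(slope^2 var k + sd^2) = 10/(sqrt(2)*sqrt(1731))
    assert truth.implied_r == pytest.approx(10 / math.sqrt(2 * 1731), rel=1e-12)
    assert truth.implied_r == pytest.approx(0.170, abs=5e-4)
    assert synth.SyntheticTruth(corr_noise_sd=0.0).implied_r == pytest.approx(1.0)
    assert synth.SyntheticTruth(corr_slope=0.0).implied_r == 0.0


def test_promoter_array_geometry():
    truth = synth.SyntheticTruth(seed=1, promoter_count=100)
    probes, promoters = synth.gen_promoter_array(truth,
                                                 np.random.default_rng(1))
    assert len(probes) == 1500
    assert ((probes["end"] - probes["start"]) == 50).all()
    # promoters do not overlap
    for _, grp in promoters.groupby("chrom"):
        grp = grp.sort_values("start")
        assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()
    io.validate_probe_table(probes)


def test_contiguous_tiling_at_minimal_span():
    truth = synth.SyntheticTruth(seed=2, promoter_count=20, promoter_span=750,
                                 assoc_d_max=20, site_offset_max=10)
    probes, _ = synth.gen_promoter_array(truth, np.random.default_rng(2))
    for _, grp in probes.groupby("promoter_id"):
        grp = grp.sort_values("probe_index")
        assert (grp["start"].to_numpy()[1:] == grp["end"].to_numpy()[:-1]).all()


def test_association_plant_is_exactly_recoverable(assoc_dataset):
    """Manifest AGO+/MET+ counts match the analysis labeling round trip."""
    outdir, truth, manifest = assoc_dataset
    synth.verify_manifest(outdir)  # asserts internally
    probes = io.read_probe_table(outdir / "probes.tsv")
    sites = io.read_bed(outdir / "sites.bed")
    ago = assoc.label_probes_by_proximity(probes, sites, truth.assoc_d_max)
    assert int(ago.sum()) == manifest["n_ago_pos"]


def test_null_plant_recovers_or_one():
    truth = synth.SyntheticTruth(seed=31, promoter_count=700,
                                 p_met_given_ago=0.4, p_met_given_noago=0.4)
    rng = np.random.default_rng(truth.seed)
    probes, _ = synth.gen_promoter_array(truth, rng)
    probes, sites, manifest = synth.gen_probe_association(truth, probes, rng)
    ago = assoc.label_probes_by_proximity(probes, sites, truth.assoc_d_max)
    met, _ = assoc.dichotomize_methylation(
        probes["methylation"].to_numpy(), "threshold", truth.met_threshold)
    res = assoc.association_stats(assoc.build_contingency(met, ago))
    t = res.table
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    assert abs(math.log(res.odds_ratio)) <= 3 * se


def test_correlation_plant_recovery():
    truth = synth.SyntheticTruth(seed=41, promoter_count=4000)
    rng = np.random.default_rng(truth.seed)
    probes, proms = synth.gen_promoter_array(truth, rng)
    probes, sites, manifest = synth.gen_promoter_correlation_data(
        truth, probes, proms, rng)
    res = assoc.promoter_correlation(probes, sites)
    # the pipeline recovers the generator's sample r exactly...
    assert res.r == pytest.approx(manifest["sample_r"], abs=1e-9)
    # ...and the sample r sits within 3 SE of the closed-form plant
    tol = 3 * (1 - truth.implied_r ** 2) / math.sqrt(truth.promoter_count)
    assert abs(res.r - truth.implied_r) <= tol


def test_clip_generator_no_multimap_and_no_edit_modes(tmp_path):
    truth = synth.SyntheticTruth(seed=51, clip_n_reads=120,
                                 multimap_fraction=0.0, edit_fraction=0.0)
    mapped, mappings, manifest = synth.gen_clip_reads(
        truth, np.random.default_rng(truth.seed))
    reads = clip_mod.reads_from_tables(mapped, mappings)
    kept, removed = clip_mod.filter_multimappers(reads)
    assert removed == 0 and manifest["n_reads_over_30_locations"] == 0
    perfect = clip_mod.reads_to_sites(kept, "AGO4", 1, "perfect_only")
    approx = clip_mod.reads_to_sites(kept, "AGO4", 1, "include_approximate")
    assert {s.interval for s in perfect} == {s.interval for s in approx}


def test_clip_manifest_survival_counts(clip_dataset):
    outdir, _, _ = clip_dataset
    synth.verify_manifest(outdir)


def test_gel_generator_pattern_to_band_mapping(rng):
    lane, _, _ = synth.gen_gel_lane("LINE1", 500, (1.0, 0.0, 0.0), rng)
    present = {s for s, v in lane.bands.items() if v > 0}
    assert present == {50, 42}
    lane, _, _ = synth.gen_gel_lane("ALU", 500, (0.0, 0.0, 0.0, 1.0), rng)
    present = {s for s, v in lane.bands.items() if v > 0}
    assert present == {133}


def test_gel_noiseless_estimator_roundtrip(rng):
    from agomet.cobra import estimate_lane
    for assay, probs in (("LINE1", (0.5, 0.3, 0.2)), ("ALU", (0.4, 0.2, 0.1, 0.3))):
        lane, true_pct, _ = synth.gen_gel_lane(assay, 2000, probs, rng)
        assert estimate_lane(lane).percent == pytest.approx(true_pct, abs=1e-9)


def test_gel_manifest_verifies(tmp_path):
    truth = synth.SyntheticTruth(seed=61)
    synth.emit_gel_dataset(truth, tmp_path / "gel")
    synth.verify_manifest(tmp_path / "gel")


def test_correlation_manifest_verifies(tmp_path):
    truth = synth.SyntheticTruth(seed=71, promoter_count=300)
    synth.emit_correlation_dataset(truth, tmp_path / "corr")
    synth.verify_manifest(tmp_path / "corr")


def test_generators_are_byte_identical_under_seed(tmp_path):
    truth = synth.SyntheticTruth(seed=81, promoter_count=60, clip_n_reads=80)
    for emit, files in [
        (synth.emit_association_dataset,
         ["probes.tsv", "promoters.tsv", "sites.bed", "manifest.json"]),
        (synth.emit_correlation_dataset,
         ["probes.tsv", "promoters.tsv", "sites.bed", "manifest.json"]),
        (synth.emit_clip_dataset,
         ["mapped_sequences.tsv", "genome_mappings.tsv", "manifest.json"]),
        (synth.emit_gel_dataset, ["lanes.tsv", "manifest.json"]),
    ]:
        d1 = tmp_path / emit.__name__ / "run1"
        d2 = tmp_path / emit.__name__ / "run2"
        emit(truth, d1)
        emit(truth, d2)
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


def test_multi_chromosome_generation_exercises_distance_sentinel():
    truth = synth.SyntheticTruth(seed=91, promoter_count=40, n_chromosomes=3)
    probes, promoters = synth.gen_promoter_array(truth,
                                                 np.random.default_rng(91))
    assert set(promoters["chrom"]) == {"chrS1", "chrS2", "chrS3"}
    only_chr1_sites = synth.gen_probe_association(
        truth, probes, np.random.default_rng(91))[1]
    dist = assoc.nearest_site_distance(
        probes[probes["chrom"] == "chrS2"],
        only_chr1_sites[only_chr1_sites["chrom"] == "chrS1"])
    assert np.isinf(dist).all()
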