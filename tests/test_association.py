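"""Contingency statistics, labeling, correlation and profile operations."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from agomet import association as assoc
from agomet import synth


def make_probes(centers, methylation=None, chrom="chrS1"):
    centers = np.asarray(centers)
    if methylation is None:
        methylation = np.ones(len(centers))
    n = len(centers)
    return pd.DataFrame(
        {
            "promoter_id": [f"P{i}" for i in range(n)],
            "gene": "G",
            "probe_index": 1,
            "chrom": chrom,
            "start": centers - 25,
            "end": centers + 25,
            "strand": "+",
            "methylation": methylation,
        }
    )


def make_sites(centers, chrom="chrS1", name="AGO4", strand="+", length=20):
    centers = np.asarray(centers)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": centers - length // 2,
            "end": centers - length // 2 + length,
            "name": name,
            "score": 1,
            "strand": strand,
        }
    )


# ---------------------------------------------------------------------------
# dichotomization

def test_median_split():
    labels, info = assoc.dichotomize_methylation(np.array([1.0, 2.0, 3.0, 4.0]))
    assert labels.tolist() == [False, False, True, True]
    assert info.cutoff == 2.5 and info.n_met_pos == 2


def test_median_ties_go_to_met_minus():
    labels, _ = assoc.dichotomize_methylation(np.array([1.0, 2.0, 2.0, 3.0]))
    assert labels.tolist() == [False, False, False, True]


def test_threshold_rule():
    labels, info = assoc.dichotomize_methylation(
        np.array([0.5, 1.0, 2.0]), rule="threshold", threshold=0.0)
    assert labels.all() and info.rule == "threshold"


def test_all_identical_values_flagged_all_met_minus():
    labels, info = assoc.dichotomize_methylation(np.full(5, 3.3))
    assert not labels.any() and info.all_identical


def test_planted_met_fraction_within_binomial_bounds():
    """Latent P(MET+) = 0.5 at n = 10,000 -> count inside the central 99%
    binomial interval (the dichotomizer recovers the latent state exactly
    because the two components are far apart)."""
    rng = np.random.default_rng(42)
    n = 10_000
    latent = rng.random(n) < 0.5
    values = np.where(latent, rng.normal(80, 5, n), rng.normal(20, 5, n))
    labels, _ = assoc.dichotomize_methylation(values, rule="threshold",
                                              threshold=50)
    lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
    assert lo <= labels.sum() <= hi
    assert labels.sum() == latent.sum()


# ---------------------------------------------------------------------------
# proximity labeling

def test_proximity_threshold_crossing():
    probes = make_probes([125])
    sites = make_sites([310])
    assert not assoc.label_probes_by_proximity(probes, sites, d_max=100).any()
    assert assoc.label_probes_by_proximity(probes, sites, d_max=200).all()
    assert assoc.label_probes_by_proximity(probes, sites, d_max=185).all()
    assert not assoc.label_probes_by_proximity(probes, sites, d_max=184).any()


def test_no_sites_means_all_ago_negative():
    probes = make_probes([100, 200, 300])
    empty = make_sites([]).iloc[:0]
    labels = assoc.label_probes_by_proximity(probes, empty, d_max=10_000)
    assert not labels.any()


def test_cross_chromosome_sites_never_count():
    probes = make_probes([100], chrom="chrS1")
    sites = make_sites([100], chrom="chrS2")
    assert not assoc.label_probes_by_proximity(probes, sites, d_max=10**9).any()
    assert math.isinf(assoc.nearest_site_distance(probes, sites)[0])


# ---------------------------------------------------------------------------
# contingency statistics

def chi2_sf_oracle(x: float) -> float:
    """Upper tail of chi-square(1) by direct numerical integration of the
    density (independent of the implementation's tail function)."""
    pdf = lambda t: math.exp(-t / 2) / math.sqrt(2 * math.pi * t)
    val, _ = integrate.quad(pdf, x, np.inf)
    return val


def test_closed_form_table():
    res = assoc.association_stats(assoc.ContingencyTable(30, 10, 10, 30))
    assert res.odds_ratio == pytest.approx(9.0, abs=1e-12)
    assert res.chi_square == pytest.approx(20.0, abs=1e-12)
    assert not res.continuity_note
    # CI from ln OR = 2.1972, SE = sqrt(1/30+1/10+1/10+1/30) = 0.5164
    se = math.sqrt(2 / 30 + 2 / 10)
    lo = math.exp(math.log(9) - 1.959963984540054 * se)
    hi = math.exp(math.log(9) + 1.959963984540054 * se)
    assert res.ci_low == pytest.approx(lo, rel=1e-12)
    assert res.ci_high == pytest.approx(hi, rel=1e-12)
    assert res.p_value == pytest.approx(chi2_sf_oracle(20.0), rel=1e-4)


def test_against_independent_libraries():
    """Cross-check OR/CI against statsmodels and chi2/p against scipy's
    contingency machinery on several tables."""
    sm = pytest.importorskip("statsmodels.stats.contingency_tables")
    for cells in [(30, 10, 10, 30), (120, 47, 33, 260), (5, 9, 14, 2)]:
        a, b, c, d = cells
        res = assoc.association_stats(assoc.ContingencyTable(a, b, c, d))
        t22 = sm.Table2x2(np.array([[a, b], [c, d]]))
        assert res.odds_ratio == pytest.approx(t22.oddsratio, rel=1e-12)
        lo, hi = t22.oddsratio_confint(0.05)
        assert res.ci_low == pytest.approx(lo, rel=1e-9)
        assert res.ci_high == pytest.approx(hi, rel=1e-9)
        chi2, p, _, _ = stats.chi2_contingency([[a, b], [c, d]],
                                               correction=False)
        assert res.chi_square == pytest.approx(chi2, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)


def test_zero_cell_haldane_correction():
    res = assoc.association_stats(assoc.ContingencyTable(10, 0, 5, 5))
    assert res.continuity_note
    assert res.odds_ratio == pytest.approx((10.5 * 5.5) / (0.5 * 5.5), abs=1e-12)
    assert res.odds_ratio == pytest.approx(21.0)
    assert res.ci_low <= res.odds_ratio <= res.ci_high


def test_degenerate_margin_chi2_undefined():
    res = assoc.association_stats(assoc.ContingencyTable(0, 0, 5, 5))
    assert math.isnan(res.chi_square) and math.isnan(res.p_value)
    assert res.continuity_note and res.odds_ratio > 0


def test_ci_brackets_or_when_uncorrected():
    res = assoc.association_stats(assoc.ContingencyTable(12, 7, 9, 21))
    assert res.ci_low <= res.odds_ratio <= res.ci_high


@given(st.tuples(*[st.integers(1, 400)] * 4))
@settings(derandomize=True, max_examples=200)
def test_or_reciprocal_and_chi2_symmetry(cells):
    a, b, c, d = cells
    base = assoc.association_stats(assoc.ContingencyTable(a, b, c, d))
    swapped = assoc.association_stats(assoc.ContingencyTable(c, d, a, b))
    assert swapped.odds_ratio == pytest.approx(1 / base.odds_ratio, rel=1e-12)
    transposed = assoc.association_stats(assoc.ContingencyTable(a, c, b, d))
    assert transposed.chi_square == pytest.approx(base.chi_square, rel=1e-12)


@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1,
                max_size=300))
@settings(derandomize=True, max_examples=100)
def test_every_probe_lands_in_exactly_one_cell(labels):
    met = np.array([m for m, _ in labels])
    ago = np.array([g for _, g in labels])
    t = assoc.build_contingency(met, ago)
    assert t.n == len(labels)


# ---------------------------------------------------------------------------
# promoter correlation

def _perfect_linear_dataset(n_prom=12):
    """Probe table where promoter methylation sum equals its site count."""
    rows = []
    sites = []
    for i in range(n_prom):
        base = i * 10_000
        k = i % 5
        for j in range(15):
            s = base + j * 100
            rows.append(("P%03d" % i, "G", j + 1, "chrS1", s, s + 50, "+",
                         k / 15.0))
        for m in range(k):
            sites.append(base + 100 + m * 150)
    probes = pd.DataFrame(rows, columns=["promoter_id", "gene", "probe_index",
                                         "chrom", "start", "end", "strand",
                                         "methylation"])
    return probes, make_sites(sites)


def test_perfect_linear_relation_gives_r_one():
    probes, sites = _perfect_linear_dataset()
    res = assoc.promoter_correlation(probes, sites)
    assert res.r == pytest.approx(1.0, abs=1e-12)
    assert res.p_value < 1e-10


def test_independent_x_y_r_near_zero():
    truth = synth.SyntheticTruth(seed=77, promoter_count=10_000, corr_slope=0.0)
    rng = np.random.default_rng(truth.seed)
    probes, proms = synth.gen_promoter_array(truth, rng)
    probes, sites, manifest = synth.gen_promoter_correlation_data(
        truth, probes, proms, rng)
    assert manifest["implied_r"] == 0.0
    res = assoc.promoter_correlation(probes, sites)
    assert abs(res.r) < 0.05


def test_zero_variance_reported_as_degenerate():
    probes, _ = _perfect_linear_dataset()
    empty = make_sites([]).iloc[:0]
    res = assoc.promoter_correlation(probes, empty)
    assert res.degenerate and math.isnan(res.r)


def test_too_few_promoters_rejected():
    probes, sites = _perfect_linear_dataset(n_prom=2)
    with pytest.raises(ValueError):
        assoc.promoter_correlation(probes, sites)


# ---------------------------------------------------------------------------
# exclusivity filter

def test_multi_protein_promoters_excluded():
    probes, _ = _perfect_linear_dataset(n_prom=4)
    # P000: AGO1+AGO4 -> excluded; P001: AGO4 only; P002: none; P003: 3x AGO4
    sites = pd.concat([
        make_sites([200], name="AGO1"),
        make_sites([400], name="AGO4"),
        make_sites([10_200], name="AGO4"),
        make_sites([30_200, 30_400, 30_600], name="AGO4"),
    ], ignore_index=True)
    kept, report = assoc.select_exclusive_promoters(probes, sites)
    kept_ids = set(kept["promoter_id"].unique())
    assert kept_ids == {"P001", "P002", "P003"}
    assert not report.loc[report["promoter_id"] == "P000", "kept"].iloc[0]
    # background promoters (zero binding) are retained
    assert "P002" in kept_ids


# ---------------------------------------------------------------------------
# profiles

def test_proximity_profile_decay_and_cumulativity(assoc_dataset):
    """Probes near planted sites carry the methylation boost, so the profile
    decays with distance while probe membership grows cumulatively."""
    outdir, truth, _ = assoc_dataset
    from agomet import io
    probes = io.read_probe_table(outdir / "probes.tsv")
    sites = io.read_bed(outdir / "sites.bed")
    prof = assoc.proximity_profile(probes, sites, [30, 200, 100_000])
    assert prof["n_probes"].is_monotonic_increasing
    assert prof["mean_methylation"].iloc[0] > prof["mean_methylation"].iloc[-1]


def test_proximity_profile_edge_cases():
    probes = make_probes([100], methylation=[7.0])
    sites = make_sites([150])
    prof = assoc.proximity_profile(probes, sites, [10, 100])
    assert prof["n_probes"].tolist() == [0, 1]
    assert math.isnan(prof["mean_methylation"].iloc[0])
    assert prof["mean_methylation"].iloc[1] == 7.0
    with pytest.raises(ValueError):
        assoc.proximity_profile(probes, sites, [100, 100])


def test_tss_profile_strand_aware_offsets():
    promoters = pd.DataFrame(
        {"promoter_id": ["F", "R"], "gene": ["GF", "GR"],
         "chrom": ["chrS1", "chrS1"], "start": [0, 10_000],
         "end": [1500, 11_500], "tss": [100, 11_000], "strand": ["+", "-"]})
    sites = pd.concat([
        make_sites([150], strand="+"),    # +50 downstream of the + gene, sense
        make_sites([10_900], strand="-"),  # +100 downstream of the - gene, sense
        make_sites([100], strand="-"),     # at the + TSS, antisense
    ], ignore_index=True)
    prof = assoc.tss_binding_profile(sites, promoters, bin_width=50)
    by_bin = prof.set_index("bin_start")
    assert by_bin.loc[50, "sense"] == 1
    assert by_bin.loc[100, "sense"] == 1
    assert by_bin.loc[0, "antisense"] == 1
    assert prof["sense"].sum() == 2 and prof["antisense"].sum() == 1


# ---------------------------------------------------------------------------
# group comparison

def test_identical_groups_paired_undefined():
    res = assoc.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
    assert math.isnan(res.p_value)


def test_constant_shift_zero_variance_diffs_undefined():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    res = assoc.compare_groups(a + 2.0, a, paired=True)
    assert math.isnan(res.p_value)


def test_unpaired_type_one_error_rate():
    """1,000 null comparisons at alpha = 0.05 reject ~5% of the time."""
    rng = np.random.default_rng(5)
    a = rng.normal(50, 8, size=(1000, 20))
    b = rng.normal(50, 8, size=(1000, 20))
    p = stats.ttest_ind(a, b, axis=1).pvalue
    # spot-check our wrapper against the vectorized reference
    ours = assoc.compare_groups(a[0], b[0], paired=False)
    assert ours.p_value == pytest.approx(p[0], rel=1e-12)
    rate = float(np.mean(p < 0.05))
    assert 0.03 <= rate <= 0.07


def test_paired_length_mismatch_rejected():
    with pytest.raises(ValueError):
        assoc.compare_groups([1.0, 2.0], [1.0], paired=True)
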