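"""Enrichment statistics: overlap oracles, shuffle nulls, matched controls,
Fisher tests, aggregate profiles, correlations and the crossover-count GLM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comapper import enrichment
from comapper.enrichment import (
    ColdRegionError, SignalTrack, aggregate_profile, bin_positions, bin_track,
    binned_stats, element_counts, glm_crossovers, overlap_counts,
    poisson_fit_counts, promoter_quartile_analysis, sample_cold_regions,
    shuffle_mc, signal_mc, te_family_fisher, validate_cold_regions,
)


def _random_bed(rng, n, chroms=("c1", "c2"), span=100_000, max_len=500):
    chrom = rng.choice(chroms, size=n)
    start = rng.integers(0, span - max_len, size=n)
    return pd.DataFrame({"chrom": chrom, "start": start,
                         "end": start + rng.integers(1, max_len, size=n)})


# ---------------------------------------------------------------------------
# SignalTrack
# ---------------------------------------------------------------------------

def test_signal_track_integral_matches_per_base_sum():
    rng = np.random.default_rng(1)
    starts = np.arange(0, 10_000, 100)
    track = pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 100,
                          "value": rng.random(starts.size)})
    sig = SignalTrack(track)
    base = np.repeat(track["value"].to_numpy(), 100)  # per-base signal
    for a, b in [(0, 10_000), (37, 512), (150, 151), (9_950, 10_000), (250, 250)]:
        assert sig.integral("c", a, b)[0] == pytest.approx(base[a:b].sum(), abs=1e-9)


def test_signal_track_zero_outside_coverage_and_unknown_chrom():
    sig = SignalTrack(pd.DataFrame({"chrom": ["c"], "start": [100], "end": [200],
                                    "value": [2.0]}))
    assert sig.integral("c", 0, 100)[0] == 0.0
    assert sig.integral("c", 50, 150)[0] == pytest.approx(100.0)
    assert sig.integral("other", 0, 1000)[0] == 0.0
    assert sig.mean("c", 100, 200)[0] == pytest.approx(2.0)


def test_signal_track_rejects_overlapping_intervals():
    with pytest.raises(ValueError):
        SignalTrack(pd.DataFrame({"chrom": ["c", "c"], "start": [0, 50],
                                  "end": [100, 150], "value": [1.0, 1.0]}))


# ---------------------------------------------------------------------------
# Overlap counting / shuffle MC
# ---------------------------------------------------------------------------

def test_overlap_counts_matches_brute_force():
    rng = np.random.default_rng(2)
    q = _random_bed(rng, 60)
    f = _random_bed(rng, 80)
    f["feature"] = rng.choice(["gene", "te", "promoter"], size=len(f))
    out = overlap_counts(q, f)
    for cls in ["gene", "te", "promoter"]:
        sub = f[f["feature"] == cls]
        expect = 0
        for _, qq in q.iterrows():
            hit = any(
                qq["chrom"] == ff["chrom"] and qq["start"] < ff["end"] and qq["end"] > ff["start"]
                for _, ff in sub.iterrows()
            )
            expect += hit
        assert out.loc[cls, "n_overlap"] == expect
    assert (out["rate"] == out["n_overlap"] / len(q)).all()


def test_shuffle_mc_pvalue_floor_and_bounds():
    rng = np.random.default_rng(3)
    lengths = {"c1": 100_000, "c2": 100_000}
    q = _random_bed(rng, 20)
    f = _random_bed(rng, 30)
    f["feature"] = "x"
    res = shuffle_mc(q, lengths, f, n_perm=99, seed=4)
    for col in ("p_enrich", "p_deplete"):
        assert (res[col] >= 1 / 100).all()
        assert (res[col] <= 1.0).all()
    # observed + null columns are present and consistent
    assert res.loc["x", "n_queries"] == 20
    assert res.loc["x", "null_mean_rate"] >= 0


def test_shuffle_mc_detects_gross_enrichment():
    # all queries inside the feature, feature covers 1% of the chromosome
    q = pd.DataFrame({"chrom": "c", "start": np.arange(10) * 50 + 5_000,
                      "end": np.arange(10) * 50 + 5_020})
    f = pd.DataFrame({"chrom": ["c"], "start": [5_000], "end": [6_000], "feature": ["x"]})
    res = shuffle_mc(q, {"c": 100_000}, f, n_perm=200, seed=5)
    assert res.loc["x", "p_enrich"] == pytest.approx(1 / 201)
    assert res.loc["x", "rate"] == 1.0


def test_element_counts_multiplicity():
    regions = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100]})
    feats = pd.DataFrame({"chrom": ["c"] * 3, "start": [10, 50, 200], "end": [20, 60, 300]})
    assert element_counts(regions, feats)[0] == 2


# ---------------------------------------------------------------------------
# Cold regions
# ---------------------------------------------------------------------------

def _cold_setup(seed=7):
    rng = np.random.default_rng(seed)
    lengths = {"c": 10_000_000}
    co = pd.DataFrame({"chrom": "c",
                       "start": np.sort(rng.choice(8_000_000, 12, replace=False)) + 1_000_000})
    co["end"] = co["start"] + 2_000
    # constant GC and uniform dense SNVs make criteria satisfiable
    gc = SignalTrack(pd.DataFrame({"chrom": ["c"], "start": [0],
                                   "end": [10_000_000], "value": [0.38]}))
    snvs = pd.DataFrame({"chrom": "c", "pos": np.arange(1, 10_000_000, 500)})
    return co, lengths, gc, snvs


def test_cold_regions_pass_independent_validator():
    co, lengths, gc, snvs = _cold_setup()
    cold = sample_cold_regions(co, lengths, gc, snvs, seed=8)
    assert len(cold) == len(co)
    report = validate_cold_regions(cold, co, gc, snvs)
    assert report.all(axis=None)


def test_cold_regions_fail_loudly_when_unmatchable():
    co, lengths, gc, _ = _cold_setup()
    # SNVs only inside the crossovers: no control interval can match density
    snvs = pd.DataFrame({"chrom": "c",
                         "pos": np.concatenate([np.arange(s + 1, e, 50)
                                                for s, e in zip(co["start"], co["end"])])})
    with pytest.raises(ColdRegionError, match="snv_density") as exc:
        sample_cold_regions(co, lengths, gc, snvs, seed=9, max_tries=50)
    assert exc.value.report is not None and len(exc.value.report)


# ---------------------------------------------------------------------------
# Fisher tests
# ---------------------------------------------------------------------------

def _fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher p: sum of hypergeometric pmfs <= pmf(observed)."""
    n1, n2 = a + b, c + d
    k = a + c
    pmf_obs = stats.hypergeom.pmf(a, n1 + n2, n1, k)
    total = 0.0
    for x in range(max(0, k - n2), min(k, n1) + 1):
        p = stats.hypergeom.pmf(x, n1 + n2, n1, k)
        if p <= pmf_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def test_te_family_fisher_matches_hypergeometric_enumeration():
    rng = np.random.default_rng(11)
    co = _random_bed(rng, 40, chroms=("c",))
    cold = _random_bed(rng, 40, chroms=("c",))
    te = _random_bed(rng, 120, chroms=("c",))
    te["family"] = rng.choice(["stowaway", "mutator", "harbinger"], size=len(te))
    out = te_family_fisher(co, cold, te).set_index("family")
    for fam, r in out.iterrows():
        expect = _fisher_two_sided_enumeration(
            int(r["co_with"]), int(r["co_without"]), int(r["cold_with"]), int(r["cold_without"])
        )
        assert r["p"] == pytest.approx(expect, rel=1e-9)
        assert r["p_bonferroni"] == pytest.approx(min(r["p"] * len(out), 1.0))


# ---------------------------------------------------------------------------
# Aggregate profile
# ---------------------------------------------------------------------------

def test_aggregate_profile_matches_naive_per_base_oracle():
    rng = np.random.default_rng(13)
    starts = np.arange(0, 40_000, 200)
    track = pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 200,
                          "value": rng.random(starts.size)})
    sig = SignalTrack(track)
    base = np.repeat(track["value"].to_numpy(), 200)
    anchors = pd.DataFrame({"chrom": ["c", "c"], "start": [10_000, 22_000],
                            "end": [10_500, 23_000], "strand": ["+", "-"]})
    prof = aggregate_profile(anchors, sig, body_bins=50, flank=5_000, flank_bin=10)

    def naive(s, e, strand):
        body_edges = s + (e - s) * np.arange(51) / 50
        body = [base[int(np.floor(a)):int(np.ceil(b))].mean() if int(np.ceil(b)) > int(np.floor(a))
                else 0.0 for a, b in zip(body_edges[:-1], body_edges[1:])]
        up = [base[a:a + 10].mean() for a in range(s - 5_000, s, 10)]
        down = [base[a:a + 10].mean() for a in range(e, e + 5_000, 10)]
        vec = np.array(up + body + down)
        return vec[::-1] if strand == "-" else vec

    expect = (naive(10_000, 10_500, "+") + naive(22_000, 23_000, "-")) / 2
    # flank bins align with the 200-bp track exactly; body bins are exact only
    # when bin edges are integers, which holds for these anchor lengths
    np.testing.assert_allclose(prof.profile, expect, atol=1e-9)
    assert prof.n_anchors == 2
    assert prof.profile.size == 2 * 500 + 50


def test_aggregate_profile_permutation_band():
    rng = np.random.default_rng(14)
    starts = np.arange(0, 50_000, 100)
    track = pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 100,
                          "value": rng.random(starts.size)})
    sig = SignalTrack(track)
    anchors = pd.DataFrame({"chrom": ["c"] * 3, "start": [10_000, 20_000, 30_000],
                            "end": [10_200, 20_200, 30_200]})
    prof = aggregate_profile(anchors, sig, body_bins=50, flank=1_000, flank_bin=10,
                             n_perm=20, chrom_lengths={"c": 50_000}, seed=15)
    assert prof.null_mean is not None and prof.null_sd is not None
    assert prof.null_mean.size == prof.profile.size
    assert np.all(prof.null_sd >= 0)


def test_aggregate_profile_requires_usable_anchors():
    sig = SignalTrack(pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1000],
                                    "value": [1.0]}))
    anchors = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [110]})  # < body_bins
    with pytest.raises(ValueError):
        aggregate_profile(anchors, sig, body_bins=50)


# ---------------------------------------------------------------------------
# signal MC, binned stats
# ---------------------------------------------------------------------------

def test_signal_mc_detects_local_hotspot():
    # signal 10x higher inside the queried region than elsewhere
    track = pd.DataFrame({"chrom": ["c"] * 2, "start": [0, 500_000],
                          "end": [500_000, 501_000], "value": [1.0, 10.0]})
    track = pd.concat([track, pd.DataFrame({"chrom": ["c"], "start": [501_000],
                                            "end": [2_000_000], "value": [1.0]})],
                      ignore_index=True)
    sig = SignalTrack(track)
    q = pd.DataFrame({"chrom": ["c"], "start": [500_000], "end": [501_000]})
    res = signal_mc(q, sig, {"c": 2_000_000}, n_perm=200, seed=16)
    assert res["observed"] == pytest.approx(10.0)
    assert res["p_enrich"] == pytest.approx(1 / 201)
    assert res["p_deplete"] == pytest.approx(1.0)


def test_bin_positions_counts_and_edges():
    lengths = {"c": 1_000}
    pos = pd.DataFrame({"chrom": "c", "pos": [1, 100, 101, 1_000]})
    out = bin_positions(pos, lengths, bin_size=100)
    assert out["value"].sum() == 4
    assert out.iloc[0]["value"] == 2  # bases 1..100
    assert out.iloc[1]["value"] == 1  # base 101
    assert out.iloc[-1]["value"] == 1  # base 1000 in the final bin


def test_binned_stats_matches_scipy_spearman():
    rng = np.random.default_rng(17)
    starts = np.arange(0, 50) * 100
    x = rng.random(50)
    y = 2 * x + rng.normal(0, 0.1, 50)
    tx = pd.DataFrame({"chrom": "c", "start": starts, "value": x})
    ty = pd.DataFrame({"chrom": "c", "start": starts, "value": y})
    res = binned_stats({"x": tx, "y": ty})
    rho, p = stats.spearmanr(x, y)
    assert res.rho.loc["x", "y"] == pytest.approx(rho)
    assert res.pvalues.loc["x", "y"] == pytest.approx(p)
    assert res.rho.loc["x", "x"] == pytest.approx(1.0)
    assert "c" in res.per_chrom


def test_binned_stats_constant_track_gives_nan():
    starts = np.arange(0, 30) * 100
    tx = pd.DataFrame({"chrom": "c", "start": starts, "value": np.ones(30)})
    ty = pd.DataFrame({"chrom": "c", "start": starts, "value": np.arange(30.0)})
    res = binned_stats({"x": tx, "y": ty})
    assert np.isnan(res.rho.loc["x", "y"])


def test_bin_track_sum_and_mean():
    track = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1_000], "value": [2.0]})
    sig = SignalTrack(track)
    out_sum = bin_track(sig, {"c": 1_000}, 100, how="sum")
    np.testing.assert_allclose(out_sum["value"], 200.0)
    out_mean = bin_track(sig, {"c": 1_000}, 100, how="mean")
    np.testing.assert_allclose(out_mean["value"], 2.0)


# ---------------------------------------------------------------------------
# Poisson fit / GLM / quartile analyses
# ---------------------------------------------------------------------------

def test_poisson_fit_statistic_matches_manual_chisquare():
    counts = np.array([0] * 30 + [1] * 40 + [2] * 20 + [3] * 8 + [4] * 2)
    fit = poisson_fit_counts(counts)
    lam = counts.mean()
    probs = [stats.poisson.pmf(c, lam) for c in range(3)] + [stats.poisson.sf(2, lam)]
    expected = np.array(probs) * counts.size
    observed = np.array([30, 40, 20, 10])
    manual = ((observed - expected) ** 2 / expected).sum()
    assert fit.statistic == pytest.approx(manual)
    assert fit.lam == pytest.approx(lam)
    assert fit.pvalue == pytest.approx(stats.chi2.sf(manual, 2))


def test_poisson_fit_accepts_true_poisson_data():
    rng = np.random.default_rng(19)
    counts = rng.poisson(1.2, size=500)
    fit = poisson_fit_counts(counts)
    assert fit.pvalue > 0.001
    assert not fit.small_sample


def test_glm_recovers_log_linear_slope():
    rng = np.random.default_rng(23)
    x = rng.random(400)
    y = rng.poisson(np.exp(0.3 + 1.5 * x))
    data = pd.DataFrame({"y": y, "x": x})
    res = glm_crossovers(data, "y", ["x"])
    assert res.model.params[1] == pytest.approx(1.5, abs=0.2)
    assert res.anova.iloc[0]["p"] < 1e-6
    assert res.dropped == []
    assert 0.5 < res.overdispersion < 2.0


def test_glm_drops_collinear_covariate():
    rng = np.random.default_rng(29)
    x = rng.random(200)
    data = pd.DataFrame({"y": rng.poisson(1.0, 200), "x": x, "x2": 2 * x + 1})
    res = glm_crossovers(data, "y", ["x", "x2"])
    assert res.dropped == ["x2"]
    assert list(res.anova["term"]) == ["x"]


def test_promoter_quartile_analysis_detects_planted_association():
    rng = np.random.default_rng(31)
    n = 200
    starts = np.arange(n) * 10_000
    prom = pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 1_000})
    # recombination rate alternates by block; TEs planted only in hot promoters
    rate = np.where(np.arange(n) < n // 2, 10.0, 0.1)
    track = pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 10_000,
                          "rate": rate})
    hot = prom[rate == 10.0].sample(60, random_state=1)
    te = pd.DataFrame({"chrom": "c", "start": hot["start"] + 100,
                       "end": hot["start"] + 300})
    res = promoter_quartile_analysis(prom, te, track, n_perm=500, seed=32)
    assert res["quartile_test"]["p"] < 1e-4
    assert res["quartile_test"]["mean_top"] > res["quartile_test"]["mean_bottom"]
    assert res["carrier_test"] is not None
    assert res["carrier_test"]["p_enrich"] < 0.05
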