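import json

import numpy as np
import pandas as pd
import pytest

from dermtrends.anchoring import PairwiseComparison, adjusted_proportion
from dermtrends.gt_io import CENSORED, TopicSeries, impute_censored
from dermtrends.simulate import (
    LatentTopicModel,
    gt_transform_pairwise,
    gt_transform_single,
    make_world_fixture,
    nonadjusted_region_values,
    simulate_latent,
    simulate_region_breakdown,
    write_world,
)

MONTHS = pd.period_range("2004-01", "2019-12", freq="M")


def flat_model(topic_id="t", level=40.0, ratio=1.0, noise=0.0):
    return LatentTopicModel(
        topic_id=topic_id, baseline=level, slope=0.0,
        monthly_pattern=np.zeros(12), noise_sd=noise, popularity_ratio=ratio,
    )


def test_noiseless_flat_model_is_constant():
    x = simulate_latent(flat_model(level=40.0, ratio=0.5), MONTHS, seed=0)
    assert np.all(x == 20.0)


def test_slope_twelve_increases_one_per_month():
    m = LatentTopicModel("t", baseline=10.0, slope=12.0, monthly_pattern=np.zeros(12))
    x = simulate_latent(m, MONTHS, seed=0)
    assert np.diff(x) == pytest.approx(np.ones(191))


def test_fixed_seed_is_bit_identical():
    m = flat_model(noise=3.0)
    assert np.array_equal(simulate_latent(m, MONTHS, 123), simulate_latent(m, MONTHS, 123))
    assert not np.array_equal(simulate_latent(m, MONTHS, 123), simulate_latent(m, MONTHS, 124))


def test_model_invariants_enforced():
    with pytest.raises(ValueError, match="sum to 0"):
        LatentTopicModel("t", 10.0, 0.0, np.ones(12))
    with pytest.raises(ValueError, match="non-positive"):
        LatentTopicModel("t", 1.0, 0.0, np.zeros(12), december_dip=-5.0)


def test_gt_transform_single_tokens():
    x = np.array([50.0, 100.0, 0.3, 0.0])
    tokens, scale = gt_transform_single(x)
    assert tokens == [50, 100, CENSORED, 0]
    assert scale == 1.0


def test_gt_transform_scale_invariance():
    rng = np.random.default_rng(1)
    x = rng.uniform(0.01, 80, 60)
    base, _ = gt_transform_single(x)
    for c in (7.0, 0.013, 1e4):
        assert gt_transform_single(c * x)[0] == base


def test_gt_transform_rejects_all_zero():
    with pytest.raises(ValueError, match="mask"):
        gt_transform_single(np.zeros(12))


def test_gt_transform_pairwise_joint_scale():
    b = np.linspace(10, 50, 24)
    a = 2.0 * b
    tok_a, tok_b, scale = gt_transform_pairwise(a, b)
    assert max(t for t in tok_a if t != CENSORED) == 100
    assert max(t for t in tok_b if t != CENSORED) == 50
    assert tok_a == gt_transform_pairwise(a, a)[1]  # identical series, identical tokens


def test_pairwise_proportion_recovery_noise_free():
    # known flat ratio 0.3: imputation + ratio-of-means recovers it to rounding
    ref = simulate_latent(flat_model("scar", 50.0), MONTHS, 0)
    top = simulate_latent(flat_model("t", 50.0, ratio=0.3), MONTHS, 0)
    tok_t, tok_r, _ = gt_transform_pairwise(top, ref)
    c = PairwiseComparison(
        topic=impute_censored(TopicSeries("t", "world", MONTHS, np.array(tok_t, dtype=object))),
        reference=impute_censored(TopicSeries("scar", "world", MONTHS, np.array(tok_r, dtype=object))),
    )
    assert adjusted_proportion(c).value == pytest.approx(0.3, abs=0.01)


def test_region_breakdown_shares():
    w = make_world_fixture("paper-like", 5)
    # overwrite with deterministic weights for exact share checks
    w.country_weights = {
        "AA": {"itch": 1.0, "scar": 1.0},
        "BB": {"itch": 4.0, "scar": 1.0},
        "CC": {"itch": 1.0, "scar": 1.0},
    }
    w.country_volume = {"AA": 10.0, "BB": 10.0, "CC": 0.1}
    w.masking_threshold = 1.0
    table, truth = simulate_region_breakdown(w, "itch")
    assert table.shares["AA"] == (50, 50)
    assert table.shares["BB"] == (80, 20)
    assert table.shares["CC"] is None  # below the masking threshold
    assert truth["BB"] == pytest.approx(80.0)


def test_unknown_preset_rejected():
    with pytest.raises(ValueError, match="preset"):
        make_world_fixture("bogus", 0)


def test_paper_like_world_structure():
    w = make_world_fixture("paper-like", 11)
    assert len(w.topics) == 34 and w.reference_id == "scar"
    ratios = [m.popularity_ratio for m in w.topics.values()]
    assert min(ratios) == pytest.approx(0.01) and max(ratios) == pytest.approx(2.21)
    assert all(m.slope > 0 for m in w.topics.values())
    aseasonal = [tid for tid, m in w.topics.items() if np.allclose(m.monthly_pattern, 0)]
    assert aseasonal == ["hair_loss"]
    # roughly a tenth of the countries mask for low volume
    frac = len(w.masked_countries()) / len(w.countries)
    assert 0.04 <= frac <= 0.2


def test_fixture_determinism_across_calls():
    w1, w2 = make_world_fixture("paper-like", 9), make_world_fixture("paper-like", 9)
    assert w1.country_volume == w2.country_volume
    for tid in w1.topics:
        assert np.array_equal(w1.topics[tid].monthly_pattern, w2.topics[tid].monthly_pattern)


def test_southern_preset_shifts_peaks_six_months():
    north = make_world_fixture("paper-like", 4)
    south = make_world_fixture("southern", 4)
    for tid in north.topics:
        p_n = north.topics[tid].monthly_pattern
        if np.allclose(p_n, 0):
            continue
        assert int(np.argmax(south.topics[tid].monthly_pattern)) == (
            int(np.argmax(p_n)) + 6
        ) % 12


def test_exclusion_rule_exercised_by_fixture():
    from dermtrends.anchoring import exclude_low_volume

    w = make_world_fixture("paper-like", 2)
    excluded = exclude_low_volume(nonadjusted_region_values(w))
    sparse = set(w.countries[-6:-1])
    assert sparse <= excluded  # the designed sparse countries fail the rule


def test_write_world_layout_and_ground_truth(tmp_path):
    w = make_world_fixture("paper-like", 3)
    out = write_world(w, tmp_path / "fix")
    assert (out / "pairwise_itch.csv").exists()
    assert (out / "single_scar.csv").exists()
    assert (out / "region_itch.csv").exists()
    assert (out / "region_nonadjusted.csv").exists()
    truth = json.loads((out / "ground_truth.json").read_text())
    assert truth["reference"] == "scar"
    assert truth["topics"]["itch"]["popularity_ratio"] == pytest.approx(2.21)
    assert "scar" not in truth["scales"]["pairwise"]


def test_end_to_end_rank_correlation_of_proportions():
    # pipeline-estimated proportions preserve the true popularity ordering
    from scipy.stats import spearmanr
    from dermtrends.simulate import simulate_pairwise_series

    rhos = []
    for seed in (1, 2, 3):
        w = make_world_fixture("paper-like", seed)
        est, tru = [], []
        for tid in w.topics:
            if tid == w.reference_id:
                continue
            a, b, _ = simulate_pairwise_series(w, tid)
            c = PairwiseComparison(topic=impute_censored(a), reference=impute_censored(b))
            est.append(adjusted_proportion(c).value)
            tru.append(w.true_mean_ratio(tid))
        rhos.append(spearmanr(est, tru).statistic)
    assert min(rhos) >= 0.95
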