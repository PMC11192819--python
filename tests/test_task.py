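"""Stimulus generation, recall simulation, bid generation and the BDM auction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from memval.task import (
    ENDOWMENT,
    GenerativeModelParams,
    RecallSet,
    Sequence,
    SpcParams,
    bdm_payoff,
    default_generator_params,
    generate_dataset,
    generate_sequence,
    read_csv,
    simulate_bid,
    simulate_recall,
    to_frame,
    write_csv,
)


class TestGenerateSequence:
    def test_structure(self, rng):
        for _ in range(500):
            s = generate_sequence(rng)
            assert len(s.values) == 7
            assert s.dist_hi - s.dist_lo == 58
            assert s.dist_lo == s.dist_mean - 29 and s.dist_hi == s.dist_mean + 29
            assert 40 <= s.dist_mean <= 70
            assert all(s.dist_lo <= v <= s.dist_hi for v in s.values)
            assert all(11 <= v <= 99 for v in s.values)
            assert s.true_value == pytest.approx(np.mean(s.values))

    def test_values_uniform_within_sequence_distribution(self):
        """Pooled stimulus values, re-centred on each sequence's mean, follow
        the discrete uniform law on {-29..29} (chi-square GOF at level 0.001)."""
        rng = np.random.default_rng(7)
        offsets = []
        means = []
        for _ in range(10_000):
            s = generate_sequence(rng)
            offsets.extend(v - s.dist_mean for v in s.values)
            means.append(s.dist_mean)
        counts = np.bincount(np.asarray(offsets) + 29, minlength=59)
        _, p = stats.chisquare(counts)
        assert p > 0.001
        mean_counts = np.bincount(np.asarray(means) - 40, minlength=31)
        _, p_mean = stats.chisquare(mean_counts)
        assert p_mean > 0.001


class TestSimulateRecall:
    def test_certainty_and_impossibility(self, rng):
        seq = generate_sequence(rng)
        everything = SpcParams(p_recall=(1,) * 7, intrusion_rate=0.0)
        out = simulate_recall(seq, everything, "RE", rng)
        assert sorted(out.reports) == sorted(seq.values)
        nothing = SpcParams(p_recall=(0,) * 7, intrusion_rate=0.0)
        assert simulate_recall(seq, nothing, "RE", rng).reports == ()

    def test_per_position_rates_match_parameters(self):
        rng = np.random.default_rng(21)
        spc = SpcParams(p_recall=(0.8, 0.6, 0.5, 0.4, 0.4, 0.5, 0.7), intrusion_rate=0.0)
        hits = np.zeros(7)
        n = 10_000
        done = 0
        while done < n:
            seq = generate_sequence(rng)
            if len(set(seq.values)) < 7:
                continue  # distinct values make position identification exact
            done += 1
            reports = simulate_recall(seq, spc, "RE", rng).reports
            for pos, v in enumerate(seq.values):
                hits[pos] += v in reports
        assert np.all(np.abs(hits / n - spc.p_recall) <= 0.02)

    def test_er_order_attenuates_recency(self):
        rng = np.random.default_rng(3)
        spc = SpcParams(p_recall=(0.5,) * 7, recency_attenuation_ER=0.4, intrusion_rate=0.0)
        last_re, last_er = 0, 0
        for _ in range(4000):
            seq = generate_sequence(rng)
            last_re += seq.values[-1] in simulate_recall(seq, spc, "RE", rng).reports
            last_er += seq.values[-1] in simulate_recall(seq, spc, "ER", rng).reports
        assert last_er / 4000 < 0.3 < last_re / 4000 * 1.2

    def test_intrusions_never_presented_and_output_capped(self):
        rng = np.random.default_rng(5)
        spc = SpcParams(p_recall=(1,) * 7, intrusion_rate=5.0, max_outputs=8)
        for _ in range(200):
            seq = generate_sequence(rng)
            out = simulate_recall(seq, spc, "RE", rng)
            assert len(out.reports) <= 8
            for v in set(out.reports) - set(seq.values):
                assert seq.dist_lo <= v <= seq.dist_hi

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            SpcParams(p_recall=(1.2,) * 7)
        with pytest.raises(ValueError):
            SpcParams(p_recall=(0.5,) * 6)


class TestSimulateBid:
    def test_noiseless_identities(self, rng):
        seq = Sequence(values=(20, 30, 40, 50, 60, 70, 80), dist_mean=50)
        p = GenerativeModelParams(model_id="presented", b0=0, tau=0, beta_presented=1, sigma=1e-12)
        assert simulate_bid(seq, RecallSet((50,)), p, 0.0, rng) == pytest.approx(50.0)
        p = GenerativeModelParams(model_id="recalled", b0=0, tau=0, beta_recall=1, sigma=1e-12)
        assert simulate_bid(seq, RecallSet((50, 60)), p, 0.0, rng) == pytest.approx(55.0)

    def test_empty_recall_raises_for_recall_models(self, rng):
        seq = Sequence(values=(50,) * 7, dist_mean=50)
        for model in ("recalled", "both"):
            p = GenerativeModelParams(model_id=model)
            with pytest.raises(ValueError):
                simulate_bid(seq, RecallSet(()), p, 0.0, rng)

    def test_noise_is_centred(self):
        rng = np.random.default_rng(9)
        seq = Sequence(values=(40, 45, 50, 55, 60, 48, 52), dist_mean=50)
        p = GenerativeModelParams(model_id="presented", b0=5, tau=0, beta_presented=0.9, sigma=2)
        mu = 5 + 0.9 * seq.true_value
        bids = [simulate_bid(seq, RecallSet((50,)), p, 0.0, rng) for _ in range(20_000)]
        assert np.mean(bids) == pytest.approx(mu, abs=3 * 2 / np.sqrt(20_000))


class TestBdmPayoff:
    def test_stated_rule(self):
        assert bdm_payoff(30, 55, 60) == 100.0
        assert bdm_payoff(70, 55, 60) == pytest.approx(105.0)
        # tie resolves as a purchase
        assert bdm_payoff(55, 55, 60) == pytest.approx(105.0)

    def test_invalid_bid_rejected(self):
        with pytest.raises(ValueError):
            bdm_payoff(150, 55, 60)
        with pytest.raises(ValueError):
            bdm_payoff(-1, 55, 60)

    @pytest.mark.parametrize("true_value", [42.0, 47.3, 55.0, 62.8, 68.0])
    def test_incentive_compatibility(self, true_value):
        """Expected earnings over a fine price grid are maximised at
        bid = true value (exhaustive-grid oracle)."""
        prices = np.linspace(40, 70, 6001)
        bids = np.linspace(0, 100, 2001)

        def expected_earnings(bid):
            return np.mean([bdm_payoff(bid, pr, true_value) for pr in prices])

        ee = np.array([expected_earnings(b) for b in bids])
        best = bids[np.argmax(ee)]
        assert best == pytest.approx(true_value, abs=0.05)
        assert expected_earnings(true_value) >= ee.max() - 1e-9

    @pytest.mark.parametrize("true_value", [40.0, 70.0])
    def test_incentive_compatibility_boundary(self, true_value):
        """At the edges of the price support, bidding the true value still
        attains the maximum (below 40 every bid forgoes all purchases, so the
        optimum is a plateau rather than a unique point)."""
        prices = np.linspace(40, 70, 6001)
        bids = np.linspace(0, 100, 2001)
        ee = np.array(
            [np.mean([bdm_payoff(b, pr, true_value) for pr in prices]) for b in bids]
        )
        at_truth = np.mean([bdm_payoff(true_value, pr, true_value) for pr in prices])
        assert at_truth >= ee.max() - 1e-6


class TestGenerateDataset:
    def test_trial_counts_and_counterbalance(self):
        data = generate_dataset(5, default_generator_params("presented"), seed=4)
        df = to_frame(data)
        assert (df.groupby("participant_id").size() == 32).all()
        orders = df.groupby(["participant_id", "task_order"]).size().unstack()
        assert (orders["RE"] == 16).all() and (orders["ER"] == 16).all()
        assert ((df["bid"] >= 0) & (df["bid"] <= ENDOWMENT)).all()

    def test_same_seed_bitwise_identical(self):
        a = to_frame(generate_dataset(3, default_generator_params("both"), seed=42))
        b = to_frame(generate_dataset(3, default_generator_params("both"), seed=42))
        pd.testing.assert_frame_equal(a, b)

    def test_csv_roundtrip(self, tmp_path):
        data = generate_dataset(2, default_generator_params("recalled"), seed=8)
        path = tmp_path / "trials.csv"
        write_csv(data, path)
        df = read_csv(path)
        pd.testing.assert_frame_equal(
            df.drop(columns="recalls"), to_frame(data).drop(columns="recalls")
        )
        assert list(df["recalls"]) == list(to_frame(data)["recalls"])

    def test_earnings_follow_auction_rule(self):
        data = generate_dataset(2, default_generator_params("presented"), seed=12)
        for r in data:
            assert r.earnings == pytest.approx(
                bdm_payoff(r.bid, r.selling_price, r.sequence.true_value)
            )
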