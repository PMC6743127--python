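"""Indirect-comparison machinery: sampler correctness against conjugate and
brute-force oracles, DIC mechanics, rank probabilities, diagnostics."""

import numpy as np
import pytest
from scipy import stats

from dpi_usability.bayes import (
    DICResult,
    MCMCConfig,
    ModelSpec,
    compute_dic,
    diagnose,
    effective_sample_size,
    fit_model,
    rank_probabilities,
    select_model,
    split_rhat,
    summarize_effects,
)
from dpi_usability.errors import DisconnectedNetworkError
from dpi_usability.scoring import GUSRecord

from conftest import make_draws


def rec(rid, device, total, stratum="experienced", group=2):
    total = int(total)
    return GUSRecord(rid, stratum, group, device, (0, 0, 0, 0, total), total)


def paired_records(rng, n=25, d_true=4.0, tau=4.0):
    """Every respondent scores Breezhaler and Diskus (complete pairing)."""
    out = []
    for i in range(n):
        mu = rng.normal(25, 5)
        out.append(rec(f"R{i:02d}", "Breezhaler", np.clip(round(mu + rng.normal(0, tau)), 0, 50)))
        out.append(rec(f"R{i:02d}", "Diskus", np.clip(round(mu + d_true + rng.normal(0, tau)), 0, 50)))
    return out


SMALL = MCMCConfig(seed=99, chains=2, iterations=3000, burn_in=500)


class TestSelectModel:
    @pytest.mark.parametrize(
        "fe, re, expected",
        [
            (53.512, 53.921, "FE"),  # experienced-stratum published pair
            (58.652, 58.702, "FE"),  # naive-stratum published pair
            (60.0, 56.9, "RE"),      # 3.1-point advantage flips to RE
            (60.0, 57.0, "RE"),      # exactly 3 points still flips
            (60.0, 57.1, "FE"),      # 2.9 points does not
        ],
    )
    def test_three_point_rule(self, fe, re, expected):
        dic_fe = DICResult("FE", fe, 0.0, fe)
        dic_re = DICResult("RE", re, 0.0, re)
        assert select_model(dic_fe, dic_re) == expected


class TestFitModel:
    def test_identical_scores_concentrate_effects_at_zero(self):
        records = [r for i in range(8) for r in
                   (rec(f"R{i}", "Breezhaler", 30), rec(f"R{i}", "Diskus", 30))]
        draws = fit_model(records, ModelSpec("FE"), SMALL)
        j = draws.devices.index("Diskus")
        assert abs(draws.d[:, j].mean()) < 0.01

    def test_fe_posterior_mean_matches_paired_difference_oracle(self):
        rng = np.random.default_rng(7)
        records = paired_records(rng)
        y = {(r.respondent_id, r.device): r.gus_total for r in records}
        diffs = [
            y[(f"R{i:02d}", "Diskus")] - y[(f"R{i:02d}", "Breezhaler")]
            for i in range(25)
        ]
        draws = fit_model(records, ModelSpec("FE"), SMALL)
        j = draws.devices.index("Diskus")
        d_draws = draws.d[:, j]
        mcse = d_draws.std() / np.sqrt(effective_sample_size(d_draws, draws.chain))
        assert abs(d_draws.mean() - np.mean(diffs)) <= 3 * max(mcse, 1e-3)

    def test_identical_seed_reproduces_draws_exactly(self):
        rng = np.random.default_rng(3)
        records = paired_records(rng, n=10)
        cfg = MCMCConfig(seed=5, chains=2, iterations=600, burn_in=100)
        a = fit_model(records, ModelSpec("FE"), cfg)
        b = fit_model(records, ModelSpec("FE"), cfg)
        assert np.array_equal(a.d, b.d)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.tau, b.tau)

    def test_record_order_does_not_change_results(self):
        rng = np.random.default_rng(3)
        records = paired_records(rng, n=10)
        cfg = MCMCConfig(seed=5, chains=2, iterations=600, burn_in=100)
        a = fit_model(records, ModelSpec("FE"), cfg)
        shuffled = list(records)
        np.random.default_rng(1).shuffle(shuffled)
        b = fit_model(shuffled, ModelSpec("FE"), cfg)
        assert np.array_equal(a.d, b.d)

    def test_disconnected_network_rejected(self):
        records = [
            rec("R1", "Breezhaler", 30), rec("R1", "Diskus", 28),
            rec("R2", "Ellipta", 30, group=1), rec("R2", "Nexthaler", 28, group=1),
        ]
        with pytest.raises(DisconnectedNetworkError):
            fit_model(records, ModelSpec("FE"), SMALL)

    def test_mixed_strata_rejected(self):
        records = [
            rec("R1", "Breezhaler", 30), rec("R1", "Diskus", 28),
            rec("R2", "Breezhaler", 30, stratum="naive"),
            rec("R2", "Diskus", 28, stratum="naive"),
        ]
        with pytest.raises(ValueError, match="strata"):
            fit_model(records, ModelSpec("FE"), SMALL)

    def test_single_chain_config_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            MCMCConfig(seed=1, chains=1, iterations=100, burn_in=10)


class TestREIdentifiedCombination:
    """sigma and tau are jointly identified only through sigma^2 + 2 tau^2.

    A single score per respondent-device cell makes the within-respondent
    contrast covariance (sigma^2/2 + tau^2) exactly half the contrast
    variance (sigma^2 + 2 tau^2) whatever the split, so on heterogeneity-free
    data the RE fit cannot collapse sigma itself toward zero; what it must
    recover is the identified combination, which equals the FE fit's 2 tau^2.
    """

    def test_identified_variance_combination_matches_fe(self, experienced_records):
        fe = fit_model(experienced_records, ModelSpec("FE"), SMALL)
        re = fit_model(experienced_records, ModelSpec("RE"), SMALL)
        combo_re = float(np.mean(re.sigma**2 + 2 * re.tau**2))
        combo_fe = float(np.mean(2 * fe.tau**2))
        assert combo_re == pytest.approx(combo_fe, rel=0.15)
        # the simulation truth: residual_sd 5 with no heterogeneity -> 2*25
        assert combo_re == pytest.approx(50.0, rel=0.25)
        # and the pooled device effects agree between the two models
        np.testing.assert_allclose(
            re.d.mean(axis=0), fe.d.mean(axis=0), atol=0.5
        )


class TestComputeDIC:
    def small_fit(self):
        rng = np.random.default_rng(21)
        records = paired_records(rng, n=8)
        cfg = MCMCConfig(seed=13, chains=2, iterations=400, burn_in=100)
        return records, fit_model(records, ModelSpec("FE"), cfg)

    def test_single_draw_gives_zero_pd(self):
        records = [
            rec("R0", "Breezhaler", 24), rec("R0", "Diskus", 26),
            rec("R1", "Breezhaler", 25), rec("R1", "Diskus", 27),
        ]
        draws = make_draws(
            d=[[0.0, 1.5]], mu=[[24.0, 26.0]], tau=[2.0],
            devices=("Breezhaler", "Diskus"),
        )
        draws.respondent_ids = ("R0", "R1")
        draws.n_obs = 4
        res = compute_dic(draws, records)
        assert res.pD == pytest.approx(0.0, abs=1e-9)
        assert res.DIC == pytest.approx(res.Dbar)

    def test_dbar_matches_brute_force_marginal_likelihood(self):
        records, draws = self.small_fit()
        m_mu, s_mu = draws.prior_mu
        by_resp: dict[str, list[GUSRecord]] = {}
        for r in records:
            by_resp.setdefault(r.respondent_id, []).append(r)
        j = draws.devices.index("Diskus")
        total = np.zeros(draws.n_kept)
        for rid in sorted(by_resp):
            recs = sorted(by_resp[rid], key=lambda r: r.device)
            y = np.array([r.gus_total for r in recs], float)
            for t in range(draws.n_kept):
                mean = np.array([m_mu, m_mu + draws.d[t, j]])
                cov = draws.tau[t] ** 2 * np.eye(2) + s_mu**2
                total[t] += stats.multivariate_normal.logpdf(y, mean, cov)
        res = compute_dic(draws, records)
        assert res.Dbar == pytest.approx(float((-2 * total).mean()), rel=1e-9)

    def test_mismatched_records_rejected(self):
        records, draws = self.small_fit()
        with pytest.raises(ValueError, match="match"):
            compute_dic(draws, records[:-2])


class TestSummaries:
    def test_reference_summary_equals_anchor_summary(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(25, 2, size=(500, 10))
        d = np.column_stack([np.zeros(500), rng.normal(3, 1, 500)])
        draws = make_draws(d=d, mu=mu, tau=np.ones(500))
        summaries = {s.device: s for s in summarize_effects(draws)}
        anchor = mu.mean(axis=1)
        ref = summaries["Breezhaler"]
        assert ref.mean == pytest.approx(anchor.mean())
        assert ref.cri_low == pytest.approx(np.quantile(anchor, 0.025))
        assert ref.cri_high == pytest.approx(np.quantile(anchor, 0.975))

    def test_means_and_quantiles_match_direct_recomputation(self):
        rng = np.random.default_rng(1)
        mu = rng.normal(25, 2, size=(400, 5))
        d = np.column_stack([np.zeros(400), rng.normal(2, 1, 400), rng.normal(-1, 1, 400)])
        draws = make_draws(d=d, mu=mu, devices=("Breezhaler", "Diskus", "Ellipta"))
        g = mu.mean(axis=1)[:, None] + d
        summaries = summarize_effects(draws)
        assert [s.mean for s in summaries] == sorted(
            (float(v) for v in g.mean(axis=0)), reverse=True
        )
        for s in summaries:
            k = draws.devices.index(s.device)
            assert s.cri_low == pytest.approx(np.quantile(g[:, k], 0.025))
            assert s.cri_high == pytest.approx(np.quantile(g[:, k], 0.975))
        assert all(s.cri_low <= s.mean <= s.cri_high for s in summaries)


class TestRankProbabilities:
    def test_strict_winner_has_rank_one_probability_one(self):
        d = np.column_stack([np.zeros(200), np.full(200, 5.0), np.full(200, -2.0)])
        draws = make_draws(d=d, devices=("Breezhaler", "Diskus", "Ellipta"))
        m = rank_probabilities(draws)
        assert m.loc["Diskus", 1] == 1.0
        assert m.loc["Breezhaler", 2] == 1.0
        assert m.loc["Ellipta", 3] == 1.0

    def test_mirror_image_draws_split_rank_one_evenly(self):
        x = np.concatenate([np.full(100, 1.0), np.full(100, -1.0)])
        d = np.column_stack([np.zeros(200), x])
        m = rank_probabilities(make_draws(d=d))
        assert m.loc["Breezhaler", 1] == 0.5
        assert m.loc["Diskus", 1] == 0.5

    def test_ties_break_by_canonical_device_order(self):
        d = np.zeros((50, 2))
        m = rank_probabilities(make_draws(d=d))
        assert m.loc["Breezhaler", 1] == 1.0
        assert m.loc["Diskus", 2] == 1.0

    def test_hundred_draw_toy_matches_exhaustive_counting(self):
        rng = np.random.default_rng(12)
        d = rng.normal(0, 2, size=(100, 3))
        d[:, 0] = 0.0
        mu = rng.normal(25, 1, size=(100, 4))
        devices = ("Breezhaler", "Diskus", "Ellipta")
        draws = make_draws(d=d, mu=mu, devices=devices)
        m = rank_probabilities(draws)
        # independent oracle: explicit per-draw sort
        counts = {dev: [0, 0, 0] for dev in devices}
        for t in range(100):
            g = mu[t].mean() + d[t]
            order = sorted(range(3), key=lambda k: (-g[k], k))
            for rank_pos, k in enumerate(order):
                counts[devices[k]][rank_pos] += 1
        for dev in devices:
            for r in range(3):
                assert m.loc[dev, r + 1] == counts[dev][r] / 100

    def test_rows_and_columns_are_stochastic(self):
        rng = np.random.default_rng(2)
        d = rng.normal(size=(300, 4))
        d[:, 0] = 0
        m = rank_probabilities(
            make_draws(d=d, devices=("Breezhaler", "Diskus", "Ellipta", "Genuair"))
        )
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(m.sum(axis=0), 1.0, atol=1e-12)


class TestDiagnostics:
    def test_identical_noise_chains_have_rhat_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        chain = np.repeat([0, 1], 1000)
        assert split_rhat(x, chain) == pytest.approx(1.0, abs=0.05)

    def test_disjoint_chains_flagged(self):
        x = np.concatenate([np.random.default_rng(0).normal(0, 1, 500),
                            np.random.default_rng(1).normal(30, 1, 500)])
        chain = np.repeat([0, 1], 500)
        assert split_rhat(x, chain) > 1.5

    def test_split_rhat_matches_arviz_oracle(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(8)
        # mildly autocorrelated chains with different means
        chains = []
        for shift in (0.0, 0.3):
            z = rng.normal(size=800)
            ar = np.empty(800)
            ar[0] = z[0]
            for t in range(1, 800):
                ar[t] = 0.5 * ar[t - 1] + z[t]
            chains.append(ar + shift)
        x = np.concatenate(chains)
        chain = np.repeat([0, 1], 800)
        ours = split_rhat(x, chain)
        ref = float(az.rhat(np.vstack(chains).reshape(2, 800), method="split"))
        assert ours == pytest.approx(ref, abs=1e-6)

    def test_diagnose_requires_two_chains(self):
        draws = make_draws(d=np.zeros((100, 2)))
        with pytest.raises(ValueError, match="2 chains"):
            diagnose(draws)

    def test_diagnose_reports_all_parameters(self):
        rng = np.random.default_rng(4)
        d = rng.normal(size=(400, 2))
        d[:, 0] = 0
        draws = make_draws(d=d, tau=np.abs(rng.normal(2, 0.1, 400)),
                           chain=np.repeat([0, 1], 200))
        report = diagnose(draws)
        assert set(report["rhat"]) == {"d[Diskus]", "tau"}
        assert report["converged"] in (True, False)
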