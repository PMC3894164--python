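import numpy as np
import pandas as pd
import pytest

from cgap.analysis import (
    CorrelationAudit,
    PSiteKineticsTable,
    cis_trans_test,
    correlation_audit,
    distance_distributions,
    predict_vphos,
    proximity_census,
    summarize_campaign,
    triangular_null_density,
)
from cgap.protocols import EventRecord, tabulate_events


class TestCisTransTest:
    def test_published_count_pairs(self):
        assert cis_trans_test([253, 167]).p_value < 0.0001
        assert cis_trans_test([138, 54]).p_value < 0.05
        assert cis_trans_test([50, 50]).p_value == pytest.approx(1.0)

    def test_two_category_matches_scipy_binomial(self):
        from scipy.stats import binomtest

        for k, n in [(3, 10), (30, 40), (200, 420)]:
            got = cis_trans_test([k, n - k]).p_value
            assert got == pytest.approx(binomtest(k, n, 0.5).pvalue)

    def test_multicategory_exact_enumeration(self):
        # three categories, tiny n: compare against direct enumeration
        res = cis_trans_test([6, 1, 1])
        assert res.method == "multinomial-exact"
        from itertools import product
        from math import factorial

        n = 8
        p_obs = factorial(n) / (factorial(6) * factorial(1) * factorial(1)) * (1 / 3) ** n
        total = 0.0
        for a in range(n + 1):
            for b in range(n + 1 - a):
                c = n - a - b
                p = factorial(n) / (factorial(a) * factorial(b) * factorial(c)) * (1 / 3) ** n
                if p <= p_obs + 1e-12:
                    total += p
        assert res.p_value == pytest.approx(total, rel=1e-9)

    def test_monte_carlo_branch_agrees_with_exact(self, monkeypatch):
        import cgap.analysis as analysis

        counts = [40, 20, 30]
        res_mc = cis_trans_test(counts, seed=2)
        assert res_mc.method == "monte-carlo"
        assert res_mc.standard_error > 0
        # force exact enumeration on the same counts for a dual-route check
        monkeypatch.setattr(analysis, "EXACT_ENUMERATION_LIMIT", 100)
        res_ex = cis_trans_test(counts)
        assert res_ex.method == "multinomial-exact"
        assert abs(res_mc.p_value - res_ex.p_value) <= 3 * res_mc.standard_error

    def test_monte_carlo_reproducible(self):
        a = cis_trans_test([50, 30, 40], seed=7).p_value
        b = cis_trans_test([50, 30, 40], seed=7).p_value
        assert a == b

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cis_trans_test([0, 0])
        with pytest.raises(ValueError):
            cis_trans_test([5])
        with pytest.raises(ValueError):
            cis_trans_test([-1, 5])


class TestCensus:
    def _members(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return [rng.uniform(-50, 50, size=(6, 3)) for _ in range(n)]

    def test_closed_ball_boundary(self):
        coords = np.zeros((2, 3))
        coords[1, 0] = 40.0
        counts = proximity_census([coords], anchor_bead=0, site_beads={"s": 1}, radius=40.0)
        assert counts["s"] == 1

    def test_empty_ensemble(self):
        counts = proximity_census([], anchor_bead=0, site_beads={"s": 1})
        assert counts["s"] == 0

    def test_matches_per_frame_oracle(self):
        members = self._members(20)
        sites = {"a": 1, "b": 4}
        counts = proximity_census(members, 0, sites, radius=40.0)
        for label, bead in sites.items():
            expected = sum(
                1 for c in members if np.linalg.norm(c[bead] - c[0]) <= 40.0
            )
            assert counts[label] == expected

    def test_distance_distribution_counts_and_subset(self):
        members = self._members(30, seed=3)
        out = distance_distributions(members, 0, {"a": 2}, subset_radius=30.0)
        a = out["a"]
        assert a["hist"].sum() == 30
        expected_subset = [
            k for k, c in enumerate(members) if np.linalg.norm(c[2] - c[0]) <= 30.0
        ]
        assert list(a["subset_members"]) == expected_subset

    def test_identical_distances_single_bin(self):
        coords = np.zeros((2, 3))
        coords[1, 2] = 10.0
        out = distance_distributions([coords] * 5, 0, {"a": 1})
        assert (out["a"]["hist"] > 0).sum() == 1


class TestVphos:
    def test_uniform_frequencies_preserve_kinetics_ordering(self):
        kin = PSiteKineticsTable.packaged()
        sites = ["992", "1068", "1086", "1114", "1148", "1173"]
        pred = predict_vphos({s: 10 for s in sites}, kin)
        v = pred.frame["v_phos"]
        kk = pred.frame["kcat_km"]
        assert list(v.sort_values().index) == list(kk.sort_values().index)

    def test_table_consistency_inversion(self):
        # published v_phos for site 992 is 8.4 at kcat/KM 74.9: a campaign
        # with that relative frequency must reproduce it
        kin = PSiteKineticsTable.packaged()
        # relative binding frequency 8.4/74.9 ~ 0.1121
        pred = predict_vphos({"992": 1121, "rest": 8879}, kin)
        assert pred.frame.loc["992", "v_phos"] == pytest.approx(8.4, abs=0.05)

    def test_scale_invariance(self):
        kin = PSiteKineticsTable.packaged()
        counts = {"992": 10, "1068": 20, "1148": 5}
        a = predict_vphos(counts, kin).frame["v_phos"]
        b = predict_vphos({k: 2 * v for k, v in counts.items()}, kin).frame["v_phos"]
        ratio = (a / b).dropna()
        assert np.allclose(ratio, ratio.iloc[0])

    def test_missing_kinetics_flagged(self):
        kin = PSiteKineticsTable.packaged()
        pred = predict_vphos({"1045": 5, "992": 5}, kin)
        assert np.isnan(pred.frame.loc["1045", "v_phos"])
        assert not np.isnan(pred.frame.loc["992", "v_phos"])

    def test_charge_stripped_flag_enforced(self):
        kin = PSiteKineticsTable.packaged()
        with pytest.raises(ValueError, match="charge-stripped"):
            predict_vphos({"992": 5}, kin, charge_stripped=False)

    def test_packaged_table_contents(self):
        kin = PSiteKineticsTable.packaged()
        assert kin.kcat_km("992") == pytest.approx(74.9)
        assert kin.kcat_km("1086") == pytest.approx(12.1)
        assert np.isnan(kin.kcat_km("1101"))


class _FakeEnsemble:
    def __init__(self, traj, times):
        self.trajectory_id = np.asarray(traj)
        self.sample_time_ns = np.asarray(times)


class TestCorrelationAudit:
    def test_triangular_null_properties(self):
        t = 10.0
        dts = np.linspace(0, t, 100)
        dens = triangular_null_density(dts, t)
        assert dens[0] == pytest.approx(2.0 / t)
        assert dens[-1] == pytest.approx(0.0)
        assert np.trapezoid(dens, dts) == pytest.approx(1.0, rel=1e-3)

    def test_uniform_pairs_match_triangular_density(self):
        rng = np.random.default_rng(0)
        t = 10.0
        n = 10_000
        gaps = np.abs(rng.uniform(0, t, n) - rng.uniform(0, t, n))
        edges = np.linspace(0, t, 11)
        obs, _ = np.histogram(gaps, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        exp = triangular_null_density(centers, t) * np.diff(edges) * n
        chi2 = np.sum((obs - exp) ** 2 / exp)
        from scipy.stats import chi2 as chi2_dist

        assert chi2_dist.sf(chi2, df=len(obs) - 1) > 0.01

    def test_same_trajectory_pairs_only(self):
        records = [
            EventRecord(0, 0, 0, "s", "A", True, 1.0),
            EventRecord(1, 1, 1, "s", "A", True, 1.0),
            EventRecord(2, 2, 2, "s", "A", True, 1.0),
        ]
        ens = _FakeEnsemble([0, 0, 1], [1.0, 4.0, 2.0])
        audit = correlation_audit(records, ens, total_time_ns=10.0)
        assert list(audit.delta_t) == [3.0]

    def test_all_distinct_trajectories_empty_audit(self):
        records = [
            EventRecord(0, 0, 0, "s", "A", True, 1.0),
            EventRecord(1, 1, 1, "s", "A", True, 1.0),
        ]
        ens = _FakeEnsemble([0, 1], [1.0, 2.0])
        audit = correlation_audit(records, ens, total_time_ns=10.0)
        assert len(audit.delta_t) == 0
        assert audit.excess_small_gap() == 0.0


class TestSummary:
    def _records(self):
        recs = []
        k = 0
        for site, chain, cis, count in [
            ("992A", "A", True, 6),
            ("1045B", "B", False, 3),
            ("1045A", "A", True, 2),
        ]:
            for _ in range(count):
                recs.append(EventRecord(k, k, 0, site, chain, cis, elapsed_ns=460.0))
                k += 1
        recs.append(EventRecord(k, k, 0, None, None, None, elapsed_ns=460.0))
        return recs

    def test_published_mean_event_time_arithmetic(self):
        # 420 events over 193 us -> 0.46 us to two decimals
        recs = [
            EventRecord(i, i, 0, "x", "A", True, elapsed_ns=193_000.0 / 420)
            for i in range(420)
        ]
        table = tabulate_events(recs)
        report = summarize_campaign(table)
        assert round(report["mean_event_time_us"], 2) == 0.46
        assert report["n_events"] == 420

    def test_totals_and_conservation(self):
        recs = self._records()
        table = tabulate_events(recs)
        report = summarize_campaign(table)
        assert report["cis_events"] + report["trans_events"] == report["n_events"] == 11
        assert report["n_timeouts"] == 1
        assert table.n_trials == 12

    def test_site_exclusion_recomputes_test(self):
        recs = self._records()
        table = tabulate_events(recs)
        report = summarize_campaign(table, exclude_sites=["992"])
        sub = report["excluded"]
        assert sub["cis_events"] == 2 and sub["trans_events"] == 3
        assert 0 < sub["cis_trans_p"] <= 1.0

    def test_mean_event_time_consistency(self):
        table = tabulate_events(self._records())
        assert table.mean_event_time_ns == pytest.approx(
            table.total_simulated_ns / table.n_events
        )
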