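"""Exact test, Holm-Sidak, ANOVA contract, spike counting, warmth analysis, report."""

import itertools
import json
from math import comb

import numpy as np
import pytest

import somnotherm as st
from somnotherm.sigio import NREM, WAKE, Hypnogram
from somnotherm.stats_report import (ContingencyTable, build_report,
                                     count_interictal_spikes, fisher_exact_rxc,
                                     holm_sidak, two_way_anova, warmth_experiment)


# ---------------------------------------------------------------------------
# Brute-force oracle for the exact test (independent of the implementation)
# ---------------------------------------------------------------------------

def _table_prob(t, row_sums, col_sums, n):
    num = 1
    for rs in row_sums:
        num *= comb(n, rs)
        n -= rs
    den = 1
    for j, cs in enumerate(col_sums):
        col = [row[j] for row in t]
        m = cs
        for v in col:
            den *= comb(m, v)
            m -= v
    # P = prod_j C(cs_j over column entries) / C(n over row sums)
    return den / num


def _oracle_p(observed):
    observed = [list(r) for r in observed]
    row_sums = [sum(r) for r in observed]
    col_sums = [sum(c) for c in zip(*observed)]
    n = sum(row_sums)
    r, c = len(row_sums), len(col_sums)
    p_obs = _table_prob(observed, row_sums, col_sums, n)
    total = 0.0
    ranges = [range(min(row_sums[i], col_sums[j]) + 1)
              for i in range(r - 1) for j in range(c - 1)]
    for free in itertools.product(*ranges):
        t = [[0] * c for _ in range(r)]
        it = iter(free)
        ok = True
        for i in range(r - 1):
            for j in range(c - 1):
                t[i][j] = next(it)
            t[i][c - 1] = row_sums[i] - sum(t[i][:c - 1])
            if t[i][c - 1] < 0:
                ok = False
                break
        if not ok:
            continue
        for j in range(c):
            t[r - 1][j] = col_sums[j] - sum(t[i][j] for i in range(r - 1))
            if t[r - 1][j] < 0:
                ok = False
                break
        if not ok:
            continue
        p = _table_prob(t, row_sums, col_sums, n)
        if p <= p_obs * (1 + 1e-10):
            total += p
    return total


class TestFisherExact:
    def test_hand_enumerated_2x2(self):
        """[[3,1],[1,3]] with margins (4,4)/(4,4): p = 34/70."""
        res = fisher_exact_rxc(np.array([[3, 1], [1, 3]]))
        assert res.p_value == pytest.approx(34 / 70, abs=1e-12)

    def test_identical_rows_give_p_one(self):
        for row in ([5, 3], [4, 4, 2], [1, 2, 3]):
            res = fisher_exact_rxc(np.array([row, row]))
            assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_matches_scipy_on_2x2(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(0)
        for _ in range(50):
            t = rng.integers(1, 12, size=(2, 2))
            ours = fisher_exact_rxc(t).p_value
            theirs = fisher_exact(t, alternative="two-sided")[1]
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_matches_r_fisher_test_2x3(self):
        """Frozen cross-implementation oracle (R stats::fisher.test)."""
        res = fisher_exact_rxc(np.array([[12, 8, 5], [4, 9, 14]]))
        assert res.p_value == pytest.approx(0.01569266729, abs=1e-9)

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fisher_exact_rxc(np.array([[0, 0], [1, 2]]))

    def test_large_table_requires_monte_carlo(self):
        t = np.full((2, 3), 200)
        with pytest.raises(ValueError, match="monte_carlo"):
            fisher_exact_rxc(t)

    def test_monte_carlo_agrees_with_enumeration(self):
        t = np.array([[10, 5, 3], [4, 8, 9]])
        exact = fisher_exact_rxc(t).p_value
        mc = fisher_exact_rxc(t, monte_carlo=True, n_mc=40000, seed=1).p_value
        assert mc == pytest.approx(exact, abs=0.01)

    def test_random_tables_match_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        n_cases = 0
        while n_cases < 60:
            shape = (2, rng.integers(2, 4))
            t = rng.integers(0, 8, size=shape)
            if t.sum() > 40 or np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
                continue
            n_cases += 1
            assert fisher_exact_rxc(t).p_value == pytest.approx(
                _oracle_p(t.tolist()), abs=1e-10), t

    def test_null_calibration(self):
        """Rejection rate under independence stays at or below nominal."""
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            t = rng.multinomial(15, [1 / 3] * 3, size=2)
            if np.any(t.sum(axis=0) == 0):
                continue
            if fisher_exact_rxc(t).p_value <= 0.05:
                rejections += 1
        assert rejections / reps <= 0.06


class TestHolmSidak:
    def test_single_p_passthrough(self):
        assert holm_sidak([0.04]) == pytest.approx([0.04])

    def test_hand_computed_triple(self):
        """Step-down Sidak of (0.01, 0.04, 0.03), evaluated by hand."""
        adj = holm_sidak([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.029701, 0.0591, 0.0591], abs=1e-6)

    def test_all_ones(self):
        assert holm_sidak([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.uniform(0, 1, size=rng.integers(1, 10))
            adj = np.array(holm_sidak(p))
            assert np.all(adj >= p - 1e-12)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 8)
        _, adj_sm, _, _ = multipletests(p, method="holm-sidak")
        assert holm_sidak(p) == pytest.approx(list(adj_sm), abs=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.2])


def _balanced_anova_oracle(y, a, b):
    """Closed-form balanced two-way ANOVA from cell/marginal means."""
    y, a, b = np.asarray(y, float), np.asarray(a), np.asarray(b)
    la, lb = np.unique(a), np.unique(b)
    n_cell = len(y) / (len(la) * len(lb))
    grand = y.mean()
    ss_a = sum((y[a == ai].mean() - grand) ** 2 for ai in la) * len(y) / len(la)
    ss_b = sum((y[b == bi].mean() - grand) ** 2 for bi in lb) * len(y) / len(lb)
    ss_cells = sum((y[(a == ai) & (b == bi)].mean() - grand) ** 2
                   for ai in la for bi in lb) * n_cell
    ss_ab = ss_cells - ss_a - ss_b
    ss_e = sum(((y[(a == ai) & (b == bi)]
                 - y[(a == ai) & (b == bi)].mean()) ** 2).sum()
               for ai in la for bi in lb)
    df_a, df_b = len(la) - 1, len(lb) - 1
    df_ab = df_a * df_b
    df_e = len(y) - len(la) * len(lb)
    return (ss_a / df_a) / (ss_e / df_e), (ss_b / df_b) / (ss_e / df_e), \
           (ss_ab / df_ab) / (ss_e / df_e)


class TestTwoWayAnova:
    def _balanced_data(self, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        a = np.repeat(["x", "y"], 20)
        b = np.tile(np.repeat(["u", "v"], 10), 2)
        y = rng.normal(0, 1, 40) + shift * (a == "y")
        return y, a, b

    def test_null_calibration(self):
        """Identical cell means: F small, p large (100 seeded replicates)."""
        ps = []
        for seed in range(100):
            y, a, b = self._balanced_data(seed)
            ps.append(two_way_anova(y, a, b)["factor_a"].p_value)
        assert np.median(ps) > 0.3

    def test_power_for_large_shift(self):
        y, a, b = self._balanced_data(1, shift=5.0)
        res = two_way_anova(y, a, b)
        assert res["factor_a"].p_value < 0.001

    def test_matches_closed_form_on_balanced_design(self):
        y, a, b = self._balanced_data(2, shift=1.0)
        res = two_way_anova(y, a, b)
        f_a, f_b, f_ab = _balanced_anova_oracle(y, a, b)
        assert res["factor_a"].statistic == pytest.approx(f_a, abs=1e-8)
        assert res["factor_b"].statistic == pytest.approx(f_b, abs=1e-8)
        assert res["interaction"].statistic == pytest.approx(f_ab, abs=1e-8)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            two_way_anova([1, 2, 3], ["x", "x", "x"], ["u", "v", "u"])

    def test_repeated_requires_subject(self):
        y, a, b = self._balanced_data(3)
        with pytest.raises(ValueError, match="subject"):
            two_way_anova(y, a, b, repeated=True)


class TestSpikeCounting:
    def test_clean_wt_signal_no_detections(self, wt_session):
        count, _ = count_interictal_spikes(wt_session.recording)
        assert count == 0

    def test_injected_spikes_recovered(self):
        from somnotherm.synthgen import inject_interictal_spikes, make_preset

        rng = np.random.default_rng(5)
        rec = st.SignalRecording([("ECoG", rng.normal(0, 20, 250 * 600)),
                                  ("EMG", rng.normal(0, 10, 250 * 600))], 250.0)
        preset = make_preset("DS", spike_rate_per_min=2.0)
        spiked, truth = inject_interictal_spikes(rec, preset, seed=6)
        assert len(truth) >= 15
        count, times = count_interictal_spikes(spiked)
        matched = sum(1 for t in truth if np.any(np.abs(times - t) < 0.1))
        assert matched / len(truth) >= 0.9
        assert np.all(np.diff(times) >= 0.2)  # refractory merging

    def test_infinite_threshold_detects_nothing(self, ds_session):
        count, _ = count_interictal_spikes(ds_session.recording, k_sd=np.inf)
        assert count == 0


def _warmth_sessions(preset_name, n, seed0):
    """Ground-truth hypnograms for RT+WARM sessions (no signal synthesis)."""
    from somnotherm.synthgen import make_preset, simulate_hypnogram

    preset = make_preset(preset_name)
    blocks = [("RT", 3600.0), ("WARM", 3600.0)]
    out = []
    for i in range(n):
        spec = st.SessionSpec(f"{preset_name}{i}", preset, 7200.0, 250.0,
                              blocks, seed=seed0 + i)
        out.append({"subject_id": f"{preset_name}{i}", "genotype": preset_name,
                    "hypnogram": simulate_hypnogram(spec), "ambient_blocks": blocks})
    return out


class TestWarmthExperiment:
    def test_wt_warmth_raises_nrem_ds_does_not(self):
        sessions = _warmth_sessions("WT", 7, 100) + _warmth_sessions("DS", 7, 200)
        table, results = warmth_experiment(sessions)
        diffs = results["paired_differences"]
        assert diffs["WT"] > 5.0
        assert abs(diffs["DS"]) < 5.0
        assert "anova" in results
        assert 0 <= results["anova"]["interaction"].p_value <= 1

    def test_rescued_matches_wt_boost(self):
        sessions = (_warmth_sessions("WT", 7, 300)
                    + _warmth_sessions("DS_RESCUED", 7, 400))
        _, results = warmth_experiment(sessions)
        d = results["paired_differences"]
        assert abs(d["DS_RESCUED"] - d["WT"]) < 6.0

    def test_exclude_start_window(self):
        sessions = _warmth_sessions("WT", 2, 500)
        table, _ = warmth_experiment(sessions, exclude_start_s=900.0)
        assert len(table) == 4
        assert table["pct_nrem"].between(0, 100).all()


class TestBuildReport:
    def test_empty_cohort_produces_valid_outputs(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            summary = build_report(tmp_path, subject_summaries=[])
        assert (tmp_path / "summary.json").exists()
        assert (tmp_path / "per_subject_delta_ratios.csv").exists()
        json.loads((tmp_path / "summary.json").read_text())
        assert any("empty" in r.message for r in caplog.records)

    def test_rerun_byte_identical(self, tmp_path):
        table = ContingencyTable(["WT", "DS"], ["negative", "unchanged", "positive"],
                                 np.array([[22, 11, 1], [8, 27, 2]]))
        res = fisher_exact_rxc(table)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            build_report(d, subject_summaries=[], contingency=table,
                         contingency_test=res, config={"epsilon_c": 0.1})
        for name in ("summary.json", "transition_contingency.csv",
                     "per_subject_delta_ratios.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
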