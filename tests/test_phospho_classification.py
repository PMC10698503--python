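import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beadphos.errors import InputError
from beadphos.phospho_classification import (
    call_interactors,
    call_regulated,
    classify_sites,
    classify_specificity,
    impute_missing,
    interactome_union,
    join_sites_interactome,
    normalize_tmt,
    summary_statistics,
    welch_ttest,
)

from conftest import welch_oracle


class TestNormalizeTmt:
    def test_channel_sums_equalized(self, rng):
        raw = pd.DataFrame(rng.uniform(1, 100, (50, 4)), columns=list("abcd"))
        out = normalize_tmt(raw)
        sums = (2.0**out).sum(axis=0)
        assert np.allclose(sums, sums.iloc[0], rtol=1e-9)

    def test_unequal_totals_rescaled_relatively(self):
        # channel totals 2e6 and 1e6: after adjustment the second channel is
        # doubled relative to the first (channel sums equalized)
        raw = pd.DataFrame({"c1": [2e6], "c2": [1e6]})
        out = 2.0 ** normalize_tmt(raw)
        ratio_before = raw["c2"][0] / raw["c1"][0]
        ratio_after = out["c2"][0] / out["c1"][0]
        assert ratio_after == pytest.approx(2 * ratio_before, rel=1e-12)

    def test_equal_totals_identity_up_to_log2(self):
        raw = pd.DataFrame({"c1": [4.0, 6.0], "c2": [8.0, 2.0]})
        out = normalize_tmt(raw)
        assert np.allclose(out.to_numpy(), np.log2(raw.to_numpy()))

    def test_zero_total_names_channel(self):
        raw = pd.DataFrame({"good": [1.0], "dead": [0.0]})
        with pytest.raises(InputError, match="dead"):
            normalize_tmt(raw)


class TestWelch:
    def test_matches_hand_formula(self, rng):
        for _ in range(25):
            x = rng.normal(0, 1, rng.integers(2, 8))
            y = rng.normal(0.5, 2, rng.integers(2, 8))
            t, df, p = welch_ttest(x, y)
            t0, df0, p0 = welch_oracle(x, y)
            assert abs(t - t0) < 1e-10
            assert abs(df - df0) < 1e-10
            assert abs(p - p0) < 1e-10

    def test_worked_example(self):
        """inhibitor {6.0, 6.1, 5.9} vs control {5.0, 5.1, 4.9}:
        log2fc = 1.0 > 0.58 and p well below 0.05 -> regulated."""
        inh = [6.0, 6.1, 5.9]
        ctl = [5.0, 5.1, 4.9]
        log2fc, p, flag = call_regulated(inh, ctl)
        assert log2fc == pytest.approx(1.0)
        assert p < 0.05
        assert flag
        # the t statistic agrees with the hand formula
        t, df, p2 = welch_ttest(inh, ctl)
        t0, df0, _ = welch_oracle(inh, ctl)
        assert t == pytest.approx(t0, abs=1e-10)
        assert df == pytest.approx(df0, abs=1e-10)

    def test_zero_fold_change_not_regulated(self):
        _, _, flag = call_regulated([5.0, 5.1, 4.9], [5.0, 5.0, 5.0])
        assert not flag

    def test_conjunctive_gate_rejects_small_fold(self):
        # highly significant but log2fc = 0.50 < 0.58: gate must reject
        inh = [5.50, 5.501, 5.499]
        ctl = [5.00, 5.001, 4.999]
        log2fc, p, flag = call_regulated(inh, ctl)
        assert log2fc == pytest.approx(0.5)
        assert p < 1e-6
        assert not flag

    def test_degenerate_equal_constant_groups(self):
        t, df, p = welch_ttest([5.0, 5.0], [5.0, 5.0])
        assert p == 1.0
        _, _, flag = call_regulated([5.0, 5.0], [5.0, 5.0])
        assert not flag

    def test_needs_two_replicates(self):
        with pytest.raises(InputError):
            welch_ttest([1.0], [1.0, 2.0])

    def test_permutation_oracle_ranking(self, rng):
        """Welch p-values rank like an exact permutation test on t (n=4 vs 4,
        all 70 label splits) across simulated sites: Spearman > 0.95."""
        n_sites = 120
        welch_p, perm_p = [], []
        combos = list(itertools.combinations(range(8), 4))
        for _ in range(n_sites):
            eff = rng.uniform(0, 1.5)
            x = rng.normal(eff, 0.5, 4)
            y = rng.normal(0.0, 0.5, 4)
            _, _, p = welch_ttest(x, y)
            welch_p.append(p)
            pooled = np.concatenate([x, y])
            t_obs = abs(welch_oracle(x, y)[0])
            count = 0
            for idx in combos:
                sel = np.zeros(8, dtype=bool)
                sel[list(idx)] = True
                count += abs(welch_oracle(pooled[sel], pooled[~sel])[0]) >= t_obs - 1e-12
            perm_p.append(count / len(combos))
        rho = stats.spearmanr(welch_p, perm_p).statistic
        assert rho > 0.95


class TestClassification:
    def test_four_way_partition(self):
        assert classify_specificity(True, False) == "PP1"
        assert classify_specificity(False, True) == "B55"
        assert classify_specificity(True, True) == "ambiguous"
        assert classify_specificity(False, False) == "unregulated"

    @staticmethod
    def _site_table(effects, noise=0.05, seed=0):
        """effects: list of (pp1_effect, b55_effect) per site."""
        rng = np.random.default_rng(seed)
        n = len(effects)
        base = np.full(n, 20.0)
        cols = {"site_id": [f"s{i}" for i in range(n)]}
        e1 = np.array([e[0] for e in effects])
        e2 = np.array([e[1] for e in effects])
        for arm, eff in (("pp1", e1), ("b55", e2)):
            for r in range(1, 4):
                cols[f"{arm}_ctrl_r{r}"] = base + rng.normal(0, noise, n)
                cols[f"{arm}_inhib_r{r}"] = base + eff + rng.normal(0, noise, n)
        return pd.DataFrame(cols)

    def test_classes_recovered_on_clear_effects(self):
        effects = [(1.5, 0.0), (0.0, 1.5), (1.5, 1.5), (0.0, 0.0)]
        calls = classify_sites(self._site_table(effects))
        assert calls["class"].tolist() == ["PP1", "B55", "ambiguous", "unregulated"]

    def test_partition_counts_sum(self):
        effects = [(1.5, 0.0)] * 5 + [(0.0, 1.5)] * 3 + [(0.0, 0.0)] * 10
        calls = classify_sites(self._site_table(effects))
        stats_ = summary_statistics(calls)
        assert sum(stats_["class_counts"].values()) == len(calls)

    def test_requires_two_replicates(self):
        df = pd.DataFrame(
            {"pp1_inhib_r1": [1.0], "pp1_ctrl_r1": [1.0],
             "b55_inhib_r1": [1.0], "b55_ctrl_r1": [1.0]}
        )
        with pytest.raises(InputError):
            classify_sites(df)

    def test_alpha_zero_gives_no_regulated(self):
        effects = [(2.0, 0.0), (0.0, 2.0), (2.0, 2.0)]
        calls = classify_sites(self._site_table(effects), alpha=0.0)
        assert (calls["class"] == "unregulated").all()

    def test_summary_overlap_fraction(self):
        # 3 PP1-only + 2 B55-only + 1 ambiguous -> overlap 1/6
        effects = [(1.5, 0.0)] * 3 + [(0.0, 1.5)] * 2 + [(1.5, 1.5)]
        calls = classify_sites(self._site_table(effects))
        s = summary_statistics(calls)
        assert s["class_counts"] == {
            "PP1": 3, "B55": 2, "ambiguous": 1, "unregulated": 0
        }
        assert s["overlap_fraction_of_regulated"] == pytest.approx(1 / 6)

    def test_acceptor_percentages(self):
        effects = [(1.5, 0.0)] * 4
        tbl = self._site_table(effects)
        tbl["acceptor"] = ["S", "S", "S", "S"]
        s = summary_statistics(classify_sites(tbl))
        assert s["acceptor_pct"]["PP1"]["S"] == pytest.approx(100.0)
        assert s["acceptor_pct"]["PP1"]["T"] == pytest.approx(0.0)


class TestImputation:
    def test_no_missing_identity(self, rng):
        tbl = pd.DataFrame(rng.normal(20, 2, (30, 3)), columns=list("abc"))
        out = impute_missing(tbl, seed=1)
        pd.testing.assert_frame_equal(out, tbl)

    def test_distributional_parameters(self):
        """Sample mu = 20, sigma = 2: imputed values center on 16.4, SD 0.6."""
        rng = np.random.default_rng(42)
        observed = rng.normal(20, 2, 50000)
        col = np.concatenate([observed, np.full(10000, np.nan)])
        tbl = pd.DataFrame({"a": col})
        out = impute_missing(tbl, seed=7)
        imputed = out["a"].to_numpy()[50000:]
        mu, sigma = observed.mean(), observed.std(ddof=1)
        assert imputed.mean() == pytest.approx(mu - 1.8 * sigma, abs=0.05)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sigma, abs=0.02)

    def test_deterministic_under_seed(self, rng):
        tbl = pd.DataFrame(rng.normal(20, 2, (40, 2)), columns=list("ab"))
        tbl.iloc[::5, 0] = np.nan
        a = impute_missing(tbl, seed=3)
        b = impute_missing(tbl, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_observed_rejected(self):
        tbl = pd.DataFrame({"a": [1.0] * 5 + [np.nan] * 5})
        with pytest.raises(InputError):
            impute_missing(tbl)


class TestInteractors:
    @staticmethod
    def _table(rows):
        """rows: {protein: (bait triple, ctrl triple)}"""
        recs = {}
        for pid, (bait, ctrl) in rows.items():
            recs[pid] = list(bait) + list(ctrl)
        cols = ["bait_r1", "bait_r2", "bait_r3", "ctrl_r1", "ctrl_r2", "ctrl_r3"]
        return pd.DataFrame.from_dict(recs, orient="index", columns=cols)

    def test_clear_enrichment_called(self):
        tbl = self._table({"p1": ((12.0, 12.1, 11.9), (10.0, 10.1, 9.9))})
        out = call_interactors(tbl, bait="PP1")
        assert out["interactor"].iloc[0]
        assert out["log2_enrichment"].iloc[0] == pytest.approx(2.0)

    def test_gate_consistency(self, rng):
        """interactor flag always equals (p < alpha AND log2fc >= 1)."""
        rows = {
            f"p{i}": (tuple(rng.normal(11, s, 3)), tuple(rng.normal(10, s, 3)))
            for i, s in enumerate([0.05, 0.5, 2.0, 5.0] * 5)
        }
        out = call_interactors(self._table(rows), bait="PP1", fold_min=2)
        for _, r in out.iterrows():
            assert r["interactor"] == (
                r["p_value"] < 0.05 and r["log2_enrichment"] >= 1.0
            )

    def test_insignificant_enrichment_rejected(self):
        # 4-fold mean enrichment but huge replicate scatter: p fails
        tbl = self._table({"p1": ((14.0, 8.0, 14.0), (10.0, 10.2, 9.8))})
        out = call_interactors(tbl, bait="PP1")
        assert out["p_value"].iloc[0] > 0.05
        assert not out["interactor"].iloc[0]

    def test_missing_values_rejected(self):
        tbl = self._table({"p1": ((12.0, np.nan, 11.9), (10.0, 10.1, 9.9))})
        with pytest.raises(InputError):
            call_interactors(tbl, bait="PP1")

    def test_union_across_methods(self):
        a = pd.DataFrame(
            {"protein_id": ["p1", "p2"], "bait": "PP1", "interactor": [True, False]}
        )
        b = pd.DataFrame(
            {"protein_id": ["p1", "p2"], "bait": "PP1", "interactor": [False, True]}
        )
        out = interactome_union([a, b]).set_index("protein_id")
        assert out.loc["p1", "interactor"] and out.loc["p2", "interactor"]

    def test_planted_sensitivity(self):
        """Planted study conditions (5% true interactors, log2 effect 2,
        n = 3, noise SD 0.5): sensitivity >= 0.8, false calls consistent
        with the alpha-level null rate."""
        rng = np.random.default_rng(2024)
        n = 2000
        truth = rng.random(n) < 0.05
        base = rng.normal(25, 2, n)
        cols = {}
        for r in range(1, 4):
            cols[f"ctrl_r{r}"] = base + rng.normal(0, 0.5, n)
            cols[f"bait_r{r}"] = base + 2.0 * truth + rng.normal(0, 0.5, n)
        tbl = pd.DataFrame(cols, index=[f"p{i}" for i in range(n)])
        out = call_interactors(tbl, bait="PP1")
        called = out["interactor"].to_numpy()
        sensitivity = (called & truth).sum() / truth.sum()
        assert sensitivity >= 0.8
        # false positives need p < 0.05 AND >= 2-fold: rate well below alpha
        fp_rate = (called & ~truth).sum() / (~truth).sum()
        assert fp_rate < 0.05


class TestJoin:
    @staticmethod
    def _calls(rows):
        return pd.DataFrame(rows, columns=["site_id", "protein_id", "class"])

    @staticmethod
    def _interactors(pids, flags, bait="PP1"):
        return pd.DataFrame(
            {"protein_id": pids, "bait": bait, "interactor": flags}
        )

    def test_simple_count(self):
        calls = self._calls(
            [("s1", "pA", "PP1"), ("s2", "pB", "PP1"), ("s3", "pC", "PP1")]
        )
        inter = self._interactors(["pA", "pB", "pC"], [True, True, False])
        out = join_sites_interactome(calls, inter, site_class="PP1", bait="PP1")
        assert out["n_on_interactors"] == 2
        assert out["n_off_interactors"] == 1

    def test_empty_interactome(self):
        calls = self._calls([("s1", "pA", "PP1")])
        inter = self._interactors(["pA"], [False])
        out = join_sites_interactome(calls, inter, site_class="PP1", bait="PP1")
        assert out["n_on_interactors"] == 0

    def test_unmapped_excluded_and_counted(self):
        calls = self._calls([("s1", "pA", "PP1"), ("s2", "pZ", "PP1")])
        inter = self._interactors(["uniA"], [True])
        out = join_sites_interactome(
            calls, inter, site_class="PP1", bait="PP1", id_map={"pA": "uniA"}
        )
        assert out["n_on_interactors"] == 1
        assert out["n_unmapped"] == 1

    def test_bookkeeping_matches_planted_construction(self, rng):
        pids = [f"p{i}" for i in range(50)]
        flags = rng.random(50) < 0.3
        inter = self._interactors(pids, flags)
        members = {p for p, f in zip(pids, flags) if f}
        calls = self._calls(
            [(f"s{i}", pids[rng.integers(50)], "PP1") for i in range(200)]
        )
        out = join_sites_interactome(calls, inter, site_class="PP1", bait="PP1")
        expected = int(calls["protein_id"].isin(members).sum())
        assert out["n_on_interactors"] == expected
        assert out["n_on_interactors"] + out["n_off_interactors"] == len(calls)
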