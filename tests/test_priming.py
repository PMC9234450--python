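"""Preprocessing, repeated-measures ANOVA, simple effects, reports."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.anova import AnovaRM

from prosodikit.errors import DomainError, ValidationError
from prosodikit.priming import (
    PreprocessConfig,
    cell_means,
    congruity_report,
    oneway_anova,
    preprocess,
    rm_anova,
    simple_effect,
    ss_decomposition,
    trials_to_frame,
)
from prosodikit.synthetic import SynthTrialConfig, gen_trials, study2_trial_config


def random_table(seed, levels=(2, 2, 2), n_subj=12, factors=None):
    """Balanced long-format frame with given factor level counts."""
    rng = np.random.default_rng(seed)
    factors = factors or ["prime_type", "prime_valence", "target_valence"]
    level_names = [
        [f"{fac[:2]}{i}" for i in range(k)] for fac, k in zip(factors, levels)
    ]
    rows = []
    for s in range(n_subj):
        offset = rng.normal(0, 0.1)
        grids = np.meshgrid(*level_names, indexing="ij")
        for combo in zip(*(g.ravel() for g in grids)):
            rows.append(
                {"participant_id": f"s{s:02d}",
                 **dict(zip(factors, combo)),
                 "log_rt": 6.4 + offset + rng.normal(0, 0.15)}
            )
    return pd.DataFrame(rows), factors


class TestPreprocess:
    def _trials(self, n=200, seed=0):
        records, _ = gen_trials(SynthTrialConfig(n_participants=4, seed=seed))
        return records[:n]

    def test_no_op_path_is_pure_log(self):
        records = self._trials()
        accurate = [r for r in records if r.accurate]
        processed, report = preprocess(accurate, PreprocessConfig(sd_mult=50.0))
        np.testing.assert_allclose(
            processed["log_rt"], np.log(processed["rt_ms"].astype(float))
        )
        assert report.n_winsorized_low == report.n_winsorized_high == 0

    def test_inaccurate_trials_dropped_and_proportion_reported(self):
        records = self._trials()
        processed, report = preprocess(records)
        n_bad = sum(not r.accurate for r in records)
        assert report.n_inaccurate_dropped == n_bad
        assert report.prop_inaccurate == pytest.approx(n_bad / len(records))
        assert len(processed) == len(records) - n_bad

    def test_single_outlier_lands_exactly_on_cutoff(self):
        records, _ = gen_trials(SynthTrialConfig(n_participants=16, seed=2,
                                                 error_rate=0.0))
        frame = trials_to_frame(records)
        frame.loc[17, "rt_ms"] = 60_000.0  # one wild latency
        processed, report = preprocess(frame)
        logs = np.log(frame["rt_ms"].astype(float))
        hi = logs.mean() + 2.5 * logs.std(ddof=1)
        assert report.n_winsorized_high >= 1
        assert processed.loc[17, "log_rt"] == pytest.approx(hi)
        assert processed["log_rt"].max() <= hi + 1e-12

    def test_idempotent_under_frozen_cutoffs(self):
        records = self._trials()
        first, report = preprocess(records)
        cutoffs = (report.cutoff_low, report.cutoff_high)
        again, _ = preprocess(records, frozen_cutoffs=cutoffs)
        np.testing.assert_allclose(
            first["log_rt"].to_numpy(), again["log_rt"].to_numpy()
        )

    def test_practice_phase_excluded(self):
        records = self._trials(80)
        frame = trials_to_frame(records)
        frame.loc[:9, "phase"] = "practice"
        processed, report = preprocess(frame)
        assert report.n_practice_dropped == 10
        assert (processed["phase"] == "experimental").all()


class TestCellMeans:
    def test_two_trials_per_cell_average(self):
        df, factors = random_table(0, n_subj=1)
        doubled = pd.concat([df, df.assign(log_rt=df["log_rt"] + 0.2)])
        table = cell_means(doubled, factors)
        expected = df["log_rt"].to_numpy() + 0.1
        np.testing.assert_allclose(
            np.sort(table.data.to_numpy().ravel()), np.sort(expected)
        )

    def test_trial_order_invariance(self):
        records, _ = gen_trials(SynthTrialConfig(n_participants=6, seed=5))
        processed, _ = preprocess(records)
        shuffled = processed.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(
            cell_means(processed).data, cell_means(shuffled).data
        )

    def test_matches_naive_groupby_oracle(self):
        records, _ = gen_trials(SynthTrialConfig(n_participants=78, seed=7))
        processed, _ = preprocess(records)
        table = cell_means(processed)
        for pid in table.participants[:5]:
            sub = processed[processed["participant_id"] == pid]
            for col in table.data.columns:
                mask = np.ones(len(sub), dtype=bool)
                for fac, level in zip(table.factors, col):
                    mask &= (sub[fac] == level).to_numpy()
                assert table.data.loc[pid, col] == pytest.approx(
                    sub[mask]["log_rt"].mean()
                )

    def test_participant_with_empty_cell_excluded_and_listed(self):
        df, factors = random_table(1, n_subj=5)
        df = df[~((df["participant_id"] == "s00") & (df["prime_type"] == "pr0"))]
        table = cell_means(df, factors)
        assert table.excluded == ("s00",)
        assert "s00" not in table.participants


class TestRmAnova:
    def test_null_data_gives_zero_ss_and_f(self):
        df, factors = random_table(2, n_subj=6)
        df["log_rt"] = 5.0
        for effect in rm_anova(cell_means(df, factors)):
            assert effect.ss_effect == pytest.approx(0.0, abs=1e-18)
            assert effect.F == 0.0

    @pytest.mark.parametrize("levels", [(2, 2, 2), (3, 2, 2)])
    def test_matches_statsmodels_anovarm(self, levels):
        df, factors = random_table(3, levels=levels, n_subj=14)
        mine = {e.name: e for e in rm_anova(cell_means(df, factors))}
        ref = AnovaRM(df, "log_rt", "participant_id", within=factors).fit().anova_table
        for name, row in ref.iterrows():
            assert mine[name].F == pytest.approx(row["F Value"], rel=1e-9)
            assert mine[name].df1 == int(row["Num DF"])
            assert mine[name].df2 == int(row["Den DF"])
            assert mine[name].p == pytest.approx(row["Pr > F"], abs=1e-12)

    def test_f_equals_squared_paired_t_for_two_level_factor(self):
        df, factors = random_table(4, levels=(2, 2, 2), n_subj=10)
        table = cell_means(df, factors)
        effects = {e.name: e for e in rm_anova(table)}
        arr = table.array()  # (subj, a, b, c)
        diffs = arr[:, 0].mean(axis=(1, 2)) - arr[:, 1].mean(axis=(1, 2))
        t = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(len(diffs)))
        assert effects["prime_type"].F == pytest.approx(t**2, rel=1e-12)

    def test_ss_conservation(self):
        df, factors = random_table(5, levels=(3, 2, 2), n_subj=9)
        table = cell_means(df, factors)
        arr = table.array()
        total = ((arr - arr.mean()) ** 2).sum()
        assert sum(ss_decomposition(table).values()) == pytest.approx(
            total, rel=1e-12
        )

    def test_invariant_to_level_relabeling(self):
        df, factors = random_table(6, n_subj=8)
        base = {e.name: e.F for e in rm_anova(cell_means(df, factors))}
        relabeled = df.replace(
            {"prime_valence": {"pr0": "zz_late", "pr1": "aa_early"}}
        )
        flipped = {e.name: e.F for e in rm_anova(cell_means(relabeled, factors))}
        for name in base:
            assert flipped[name] == pytest.approx(base[name], rel=1e-9)

    def test_log_base_does_not_change_inference(self):
        records, _ = gen_trials(SynthTrialConfig(n_participants=20, seed=8))
        nat, _ = preprocess(records, PreprocessConfig(log_base="natural"))
        ten, _ = preprocess(records, PreprocessConfig(log_base="base10"))
        f_nat = {e.name: e for e in rm_anova(cell_means(nat))}
        f_ten = {e.name: e for e in rm_anova(cell_means(ten))}
        for name in f_nat:
            assert f_nat[name].F == pytest.approx(f_ten[name].F, rel=1e-9)
            assert f_nat[name].partial_eta_sq == pytest.approx(
                f_ten[name].partial_eta_sq, rel=1e-9
            )


class TestSimpleEffect:
    def _table(self, seed=0, n_subj=10):
        df, factors = random_table(seed, n_subj=n_subj)
        return cell_means(df, factors)

    def _cells(self):
        a = {"prime_type": "pr0", "prime_valence": "pr0", "target_valence": "ta0"}
        b = {"prime_type": "pr0", "prime_valence": "pr1", "target_valence": "ta0"}
        return a, b

    def test_equal_cells_give_null_result(self):
        table = self._table()
        a, _ = self._cells()
        res = simple_effect(table, a, a)
        assert res.t == 0.0 and res.dz == 0.0 and res.ci_low <= 0 <= res.ci_high

    def test_constant_difference_is_degenerate_not_crash(self):
        table = self._table()
        data = table.data.copy()
        a, b = self._cells()
        key_a = tuple(a.values())
        data[key_a] = data[tuple(b.values())] + 0.05
        from prosodikit.priming import CellMeansTable

        frozen = CellMeansTable(table.factors, table.levels, data)
        res = simple_effect(frozen, a, b)
        assert res.degenerate and math.isinf(res.t) and res.t > 0

    def test_ci_straddles_zero_iff_t_below_critical(self):
        from scipy import stats

        for seed in range(8):
            table = self._table(seed)
            a, b = self._cells()
            res = simple_effect(table, a, b)
            crit = stats.t.ppf(0.975, res.df)
            assert (res.ci_low <= 0 <= res.ci_high) == (abs(res.t) < crit)

    def test_too_few_participants_rejected(self):
        table = self._table(n_subj=2)
        a, b = self._cells()
        with pytest.raises(DomainError):
            simple_effect(table, a, b)


class TestOnewayAnova:
    def test_identical_groups_give_zero_f(self):
        effect = oneway_anova({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert effect.F == 0.0

    def test_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(11)
        groups = {k: rng.normal(k_i, 1, 9) for k_i, k in enumerate("abc")}
        effect = oneway_anova(groups)
        ref = stats.f_oneway(*groups.values())
        assert effect.F == pytest.approx(ref.statistic, rel=1e-12)
        assert effect.p == pytest.approx(ref.pvalue, rel=1e-9)


class TestCongruityReport:
    def test_structural_cardinality_study1_shape(self):
        records, _ = gen_trials(SynthTrialConfig(n_participants=12, seed=1))
        report = congruity_report(records)
        assert report["design"] == "2x2x2"
        assert len(report["cell_means_ms"]) == 8
        assert len(report["anova"]) == 7
        assert len(report["simple_effects"]) == 4
        assert len(report["simple_interactions"]) == 2

    def test_study2_shape(self):
        records, _ = gen_trials(study2_trial_config(seed=1, n_participants=10))
        report = congruity_report(records)
        assert report["design"] == "3x2x2"
        assert len(report["cell_means_ms"]) == 12
        assert len(report["anova"]) == 7
        assert len(report["simple_effects"]) == 6

    def test_reports_are_byte_identical_across_runs(self):
        records, _ = gen_trials(SynthTrialConfig(n_participants=8, seed=3))
        a = json.dumps(congruity_report(records), sort_keys=True)
        b = json.dumps(congruity_report(records), sort_keys=True)
        assert a == b

    def test_congruity_contrast_signs_recover_planted_effect(self):
        config = SynthTrialConfig(
            n_participants=60, seed=4,
            delta={"prosodic": -0.12, "control": 0.0},
        )
        records, _ = gen_trials(config)
        report = congruity_report(records)
        prosodic = [s for s in report["simple_effects"]
                    if s["prime_type"] == "prosodic"]
        # incongruent − congruent should be clearly positive for both targets
        assert all(s["mean_diff"] > 0.05 for s in prosodic)
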