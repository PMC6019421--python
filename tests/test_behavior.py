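"""Behavioral statistics against independent brute-force oracles.

The oracles deliberately avoid the implementation's code paths: t and F
tail probabilities come from numerical integration of the densities,
inverse-normal values from bisection on an erf-based CDF, and the ANOVA
sums of squares from explicit loops over participants and cells.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from maskcue import behavior as bh
from maskcue.types import Category, TrialRecord

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def t_sf_oracle(t, df):
    """P(T > t) by numerical integration of the t density."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    pdf = lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2)
    val, _ = quad(pdf, t, np.inf)
    return val


def f_sf_oracle(f, d1, d2):
    from scipy.integrate import quad as _q
    from math import gamma
    c = (gamma((d1 + d2) / 2) / (gamma(d1 / 2) * gamma(d2 / 2))
         * (d1 / d2) ** (d1 / 2))
    pdf = lambda x: c * x ** (d1 / 2 - 1) * (1 + d1 * x / d2) ** (-(d1 + d2) / 2)
    val, _ = _q(pdf, f, np.inf)
    return val


def norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def inv_norm_oracle(p, lo=-10.0, hi=10.0):
    """Inverse standard-normal CDF by bisection."""
    for _ in range(200):
        mid = (lo + hi) / 2
        if norm_cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def paired_t_oracle(x, y):
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    m = sum(d) / n
    var = sum((v - m) ** 2 for v in d) / (n - 1)
    t = m / math.sqrt(var / n)
    return t, 2 * t_sf_oracle(abs(t), n - 1)


def pearson_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2 * t_sf_oracle(abs(t), n - 2)


def make_trials(pid, n_mask, hits, n_face, fas):
    out = []
    for i in range(n_mask):
        out.append(TrialRecord(pid, f"m{i}", Category.HIGH_REALISM_MASK, "mask",
                               "mask" if i < hits else "face"))
    for i in range(n_face):
        out.append(TrialRecord(pid, f"f{i}", Category.REAL_FACE, "face",
                               "mask" if i < fas else "face"))
    return out


# ---------------------------------------------------------------------------
# condition accuracy
# ---------------------------------------------------------------------------

class TestConditionAccuracy:
    def test_direct_count(self):
        trials = make_trials("p1", 4, 3, 4, 0)
        acc, stats = bh.condition_accuracy(trials)
        mask_acc = acc.loc[acc["condition"] == "high_realism_mask", "accuracy"]
        assert float(mask_acc.iloc[0]) == 0.75

    def test_all_correct_means_one_with_zero_se(self):
        trials = make_trials("p1", 4, 4, 4, 0) + make_trials("p2", 4, 4, 4, 0)
        _, stats = bh.condition_accuracy(trials)
        for s in stats.values():
            assert s.mean == 1.0 and s.se == 0.0

    def test_missing_condition_rejected(self):
        trials = make_trials("p1", 4, 4, 4, 0) + [
            TrialRecord("p2", "m0", Category.HIGH_REALISM_MASK, "mask", "mask")]
        with pytest.raises(ValueError, match="p2"):
            bh.condition_accuracy(trials)


# ---------------------------------------------------------------------------
# paired t / pearson
# ---------------------------------------------------------------------------

class TestPairedT:
    def test_identical_samples_give_null_result(self):
        r = bh.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.value == 0.0 and r.p == 1.0

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(0)
        r = bh.paired_t(rng.normal(size=30), rng.normal(size=30))
        assert r.df == (29,)

    def test_three_pair_hand_computation(self):
        x, y = (1.0, 2.0, 3.0), (0.0, 1.0, 1.0)
        t_ref, p_ref = paired_t_oracle(x, y)
        r = bh.paired_t(x, y)
        assert r.value == pytest.approx(t_ref, rel=1e-9)
        assert r.p == pytest.approx(p_ref, rel=1e-7)

    def test_oracle_equivalence_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            t_ref, p_ref = paired_t_oracle(x, y)
            r = bh.paired_t(x, y)
            assert r.value == pytest.approx(t_ref, rel=1e-9, abs=1e-12)
            assert r.p == pytest.approx(p_ref, rel=1e-7, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert bh.paired_t(x, y).value == pytest.approx(-bh.paired_t(y, x).value)

    def test_zero_variance_nonzero_mean_gives_infinite_t(self):
        r = bh.paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert math.isinf(r.value) and r.p < 1e-300

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bh.paired_t([1.0], [2.0])


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 4.0, 8.0]
        assert bh.pearson(x, x).value == pytest.approx(1.0)
        assert bh.pearson(x, [-v for v in x]).value == pytest.approx(-1.0)

    def test_five_point_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0]
        r_ref, p_ref = pearson_oracle(x, y)
        r = bh.pearson(x, y)
        assert r.value == pytest.approx(r_ref, rel=1e-12)
        assert r.p == pytest.approx(p_ref, rel=1e-7)
        assert r.df == (3,)

    def test_oracle_equivalence_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 15))
            x = rng.normal(size=n)
            y = 0.3 * x + rng.normal(size=n)
            r_ref, p_ref = pearson_oracle(list(x), list(y))
            r = bh.pearson(x, y)
            assert r.value == pytest.approx(r_ref, rel=1e-9, abs=1e-12)
            assert r.p == pytest.approx(p_ref, rel=1e-7, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=9), rng.normal(size=9)
        assert bh.pearson(x, y).value == pytest.approx(bh.pearson(y, x).value)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            bh.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# signal detection
# ---------------------------------------------------------------------------

class TestSDT:
    def test_chance_observer(self):
        s = bh.sdt(make_trials("p", 10, 5, 10, 5), correction="none")
        assert s.dprime == pytest.approx(0.0, abs=1e-12)
        assert s.criterion == pytest.approx(0.0, abs=1e-12)
        assert s.pcorrect == 0.5

    def test_symmetric_rates_give_zero_criterion(self):
        # F = 1 - H -> C = 0 exactly; d' = 2 z(H) via bisection oracle
        s = bh.sdt(make_trials("p", 10, 9, 10, 1), correction="none")
        assert s.criterion == pytest.approx(0.0, abs=1e-9)
        z9 = inv_norm_oracle(0.9)
        assert s.dprime == pytest.approx(2 * z9, abs=1e-8)

    def test_oracle_equivalence_on_random_counts(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n_sig = int(rng.integers(5, 40))
            n_noise = int(rng.integers(5, 40))
            hits = int(rng.integers(0, n_sig + 1))
            fas = int(rng.integers(0, n_noise + 1))
            s = bh.sdt(make_trials("p", n_sig, hits, n_noise, fas),
                       correction="loglinear")
            h = (hits + 0.5) / (n_sig + 1)
            f = (fas + 0.5) / (n_noise + 1)
            zh, zf = inv_norm_oracle(h), inv_norm_oracle(f)
            assert s.dprime == pytest.approx(zh - zf, abs=1e-8)
            assert s.criterion == pytest.approx(-(zh + zf) / 2, abs=1e-8)
            assert s.pcorrect == pytest.approx(
                (hits / n_sig + 1 - fas / n_noise) / 2, rel=1e-12)

    def test_pcorrect_uses_raw_rates(self):
        # the extreme-rate correction must not leak into p(correct)
        s = bh.sdt(make_trials("p", 10, 10, 10, 0), correction="loglinear")
        assert s.pcorrect == 1.0
        assert 0 < s.hit_rate_corrected < 1

    def test_label_swap_negates_criterion_keeps_dprime(self):
        trials = make_trials("p", 12, 9, 15, 4)
        swapped = [TrialRecord(
            t.participant_id, t.stimulus_id,
            Category.REAL_FACE if t.condition != Category.REAL_FACE
            else Category.HIGH_REALISM_MASK,
            "face" if t.truth == "mask" else "mask",
            "face" if t.response == "mask" else "mask") for t in trials]
        a = bh.sdt(trials)
        b = bh.sdt(swapped)
        assert a.dprime == pytest.approx(b.dprime, rel=1e-9)
        assert a.criterion == pytest.approx(-b.criterion, rel=1e-9)

    def test_degenerate_rate_without_correction_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            bh.sdt(make_trials("p", 10, 10, 10, 2), correction="none")

    def test_printed_group_rates_reproduce_pcorrect(self):
        # group-mean rates 0.737 / 0.912 -> p(correct) = 0.825 by linearity
        assert bh.pcorrect_from_rates(0.737, 1 - 0.912) == pytest.approx(0.8245, abs=5e-4)


# ---------------------------------------------------------------------------
# quintiles
# ---------------------------------------------------------------------------

class TestQuintileSplit:
    def test_thirty_participants_give_groups_of_six(self):
        scores = {f"p{i:02d}": i / 30 for i in range(30)}
        split = bh.quintile_split(scores)
        assert split.groupby("quintile").size().tolist() == [6] * 5
        assert (split["subgroup"] == "high").sum() == 6
        assert (split["subgroup"] == "low").sum() == 6

    def test_five_distinct_scores(self):
        split = bh.quintile_split({"a": 0.1, "b": 0.5, "c": 0.3, "d": 0.9, "e": 0.7})
        high = split.loc[split["subgroup"] == "high", "participant_id"].tolist()
        assert high == ["d"]

    def test_ties_broken_by_participant_id(self):
        # exhaustive stable-sort oracle on a 10-participant tie case
        scores = {f"p{i}": (0.5 if i < 6 else 0.8) for i in range(10)}
        split = bh.quintile_split(scores)
        order = split.sort_values("rank")["participant_id"].tolist()
        oracle = sorted(scores, key=lambda k: (scores[k], k))
        assert order == oracle
        low = set(split.loc[split["subgroup"] == "low", "participant_id"])
        assert low == set(oracle[:2])

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            bh.quintile_split({"a": 1, "b": 2, "c": 3, "d": 4})


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

def anova_oracle(mask_acc, face_acc, subgroup):
    """Explicit cell-means sums-of-squares decomposition (loops, no arrays)."""
    pids = sorted(mask_acc)
    y = {p: {"mask": mask_acc[p], "face": face_acc[p]} for p in pids}
    groups = sorted({subgroup[p] for p in pids})
    conds = ["mask", "face"]
    all_vals = [y[p][c] for p in pids for c in conds]
    grand = sum(all_vals) / len(all_vals)
    ss_total = sum((v - grand) ** 2 for v in all_vals)
    ss_subj = sum(2 * ((y[p]["mask"] + y[p]["face"]) / 2 - grand) ** 2 for p in pids)
    ss_group = 0.0
    for g in groups:
        vals = [y[p][c] for p in pids if subgroup[p] == g for c in conds]
        ss_group += len(vals) * (sum(vals) / len(vals) - grand) ** 2
    ss_cond = 0.0
    for c in conds:
        vals = [y[p][c] for p in pids]
        ss_cond += len(vals) * (sum(vals) / len(vals) - grand) ** 2
    ss_cells = 0.0
    for g in groups:
        for c in conds:
            vals = [y[p][c] for p in pids if subgroup[p] == g]
            ss_cells += len(vals) * (sum(vals) / len(vals) - grand) ** 2
    ss_inter = ss_cells - ss_group - ss_cond
    ss_err_b = ss_subj - ss_group
    ss_err_w = ss_total - ss_subj - ss_cond - ss_inter
    df_err = len(pids) - 2
    return {
        "image_type": (ss_cond / (ss_err_w / df_err), ss_cond, ss_err_w),
        "subgroup": (ss_group / (ss_err_b / df_err), ss_group, ss_err_b),
        "interaction": (ss_inter / (ss_err_w / df_err), ss_inter, ss_err_w),
    }


class TestMixedAnova:
    def _random_case(self, rng, n_per_group=6):
        pids = [f"p{i:02d}" for i in range(2 * n_per_group)]
        sub = {p: ("low" if i < n_per_group else "high") for i, p in enumerate(pids)}
        mask = {p: float(rng.uniform(0.3, 1.0)) for p in pids}
        face = {p: float(rng.uniform(0.5, 1.0)) for p in pids}
        return mask, face, sub

    def test_dfs_for_two_groups_of_six(self):
        rng = np.random.default_rng(0)
        mask, face, sub = self._random_case(rng)
        res = bh.mixed_anova_2x2(mask, face, sub)
        for r in res.values():
            assert r.df == (1, 10)

    def test_identical_conditions_give_zero_image_type_effect(self):
        rng = np.random.default_rng(1)
        mask, face, sub = self._random_case(rng)
        res = bh.mixed_anova_2x2(mask, dict(mask), sub)
        assert res["image_type"].value == pytest.approx(0.0, abs=1e-20)

    def test_four_participant_hand_decomposition(self):
        mask = {"a": 0.2, "b": 0.4, "c": 0.7, "d": 0.9}
        face = {"a": 0.6, "b": 0.5, "c": 0.8, "d": 1.0}
        sub = {"a": "low", "b": "low", "c": "high", "d": "high"}
        res = bh.mixed_anova_2x2(mask, face, sub)
        ref = anova_oracle(mask, face, sub)
        for key in res:
            f_ref, ss_eff, ss_err = ref[key]
            assert res[key].value == pytest.approx(f_ref, rel=1e-9)
            assert res[key].effect_size == pytest.approx(
                ss_eff / (ss_eff + ss_err), rel=1e-9)

    def test_oracle_equivalence_on_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            mask, face, sub = self._random_case(rng, n_per_group=int(rng.integers(2, 8)))
            res = bh.mixed_anova_2x2(mask, face, sub)
            ref = anova_oracle(mask, face, sub)
            for key in res:
                f_ref = ref[key][0]
                assert res[key].value == pytest.approx(f_ref, rel=1e-9, abs=1e-9)
                assert res[key].p == pytest.approx(
                    f_sf_oracle(f_ref, 1, 2 * len(mask) // 2 - 2), rel=1e-6, abs=1e-9)

    def test_sums_of_squares_conserve_total(self):
        # conservation is implied when the oracle agrees, but assert directly
        rng = np.random.default_rng(9)
        mask, face, sub = self._random_case(rng)
        ref = anova_oracle(mask, face, sub)
        pids = sorted(mask)
        vals = [v for p in pids for v in (mask[p], face[p])]
        grand = sum(vals) / len(vals)
        ss_total = sum((v - grand) ** 2 for v in vals)
        parts = (ref["subgroup"][1] + ref["subgroup"][2]
                 + ref["image_type"][1] + ref["interaction"][1]
                 + ref["image_type"][2])
        assert parts == pytest.approx(ss_total, rel=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        mask, face, sub = self._random_case(rng)
        res = bh.mixed_anova_2x2(mask, face, sub)
        rows = [(p, c, {"mask": mask, "face": face}[c][p], sub[p])
                for p in mask for c in ("mask", "face")]
        df = pd.DataFrame(rows, columns=["pid", "cond", "y", "group"])
        ref = pg.mixed_anova(df, dv="y", within="cond", between="group",
                             subject="pid")
        ref = ref.set_index("Source")
        assert res["subgroup"].value == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert res["image_type"].value == pytest.approx(ref.loc["cond", "F"], rel=1e-6)
        assert res["interaction"].value == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6)

    def test_tiny_subgroup_rejected(self):
        with pytest.raises(ValueError):
            bh.mixed_anova_2x2({"a": 1.0, "b": 0.5}, {"a": 1.0, "b": 0.5},
                               {"a": "low", "b": "high"})


# ---------------------------------------------------------------------------
# RT summary
# ---------------------------------------------------------------------------

class TestRTSummary:
    @staticmethod
    def _with_rt(trials, rt):
        return [TrialRecord(t.participant_id, t.stimulus_id, t.condition,
                            t.truth, t.response, rt) for t in trials]

    def test_constant_rts(self):
        trials = self._with_rt(make_trials("p1", 4, 4, 4, 0)
                               + make_trials("p2", 4, 4, 4, 0), 1000.0)
        _, stats = bh.rt_summary(trials)
        for s in stats.values():
            assert s.mean == 1000.0 and s.se == 0.0

    def test_incorrect_trials_excluded(self):
        correct = self._with_rt(make_trials("p1", 4, 4, 4, 0), 1000.0)
        wrong = [TrialRecord("p1", "slow", Category.HIGH_REALISM_MASK,
                             "mask", "face", 99999.0)]
        _, stats = bh.rt_summary(correct + wrong)
        assert stats["high_realism_mask"].mean == 1000.0

    def test_missing_rt_rejected(self):
        with pytest.raises(ValueError, match="rt_ms"):
            bh.rt_summary(make_trials("p1", 4, 4, 4, 0))

    def test_simulated_panel_matches_analytic_rt_medians(self, exp2_trials,
                                                         exp2_stimuli, exp2_panel):
        # Monte-Carlo check: observed mean log-RT within 3 SE of the value
        # implied by the margin-dependent log-normal RT model
        import maskcue as mc
        from maskcue.synth import band_statistics

        stats = band_statistics(exp2_stimuli)
        logs = np.log([t.rt_ms for t in exp2_trials])
        # analytic expectation of log RT: E[log median(margin)] over trials
        preds = []
        for oi, obs in enumerate(exp2_panel):
            rngs = np.random.default_rng(
                np.random.SeedSequence([11, 303, oi]))
            d = stats @ obs.band_weights
            margin = np.abs(d - obs.criterion)
            preds.append(np.log(mc.synth.rt_median_model(margin)))
        pred_mean = np.concatenate(preds).mean()
        se = logs.std() / np.sqrt(len(logs))
        # internal noise widens margins relative to the noise-free margin,
        # shifting log medians down; allow that bias plus sampling error
        assert abs(logs.mean() - pred_mean) < 0.15 + 3 * se
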