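import numpy as np
import pandas as pd
import pytest

from ecosyn.core import ValidationError
from ecosyn.stats import (
    measure_table,
    mixed_rm_anova,
    synergy_analysis,
    tukey_posthoc,
)
from ecosyn.stats import _gg_epsilon

TIMES = ["baseline", "prediazepam", "postdiazepam"]


def make_table(values, conditions=("sham", "magnet")):
    """values[cond] = array (n_subjects, k_times)."""
    rows = []
    for cond in conditions:
        for i, subj in enumerate(values[cond]):
            for t, v in zip(TIMES, subj):
                rows.append(
                    dict(subject_id=f"{cond}{i}", condition=cond, time=t, value=float(v))
                )
    return pd.DataFrame(rows)


def random_table(rng, n_per_group=None):
    n = n_per_group or int(rng.integers(3, 9))
    return make_table({
        "sham": rng.normal(0, 1, (n, 3)) + rng.normal(0, 1, (n, 1)),
        "magnet": rng.normal(0.5, 1, (n, 3)) + rng.normal(0, 1, (n, 1)),
    })


def oracle_anova(df):
    """Brute-force split-plot decomposition via nested least-squares fits.

    Builds explicit indicator design matrices and measures each effect as the
    residual-sum-of-squares drop when its columns enter the model — an
    independent route to the same sums of squares.
    """
    df = df.sort_values(["condition", "subject_id", "time"])
    y = df["value"].to_numpy(dtype=float)
    conds = pd.get_dummies(df["condition"]).to_numpy(dtype=float)
    subjs = pd.get_dummies(df["subject_id"]).to_numpy(dtype=float)
    times = pd.get_dummies(df["time"]).to_numpy(dtype=float)
    inter = np.einsum("ij,ik->ijk", conds, times).reshape(len(df), -1)
    ones = np.ones((len(df), 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ beta) ** 2))

    m0 = rss(ones)
    m_cond = rss(np.hstack([ones, conds]))
    m_subj = rss(np.hstack([ones, conds, subjs]))
    m_time = rss(np.hstack([ones, conds, subjs, times]))
    m_full = rss(np.hstack([ones, conds, subjs, times, inter]))
    return {
        "condition": m0 - m_cond,
        "subjects_within": m_cond - m_subj,
        "time": m_subj - m_time,
        "condition:time": m_time - m_full,
        "error": m_full,
    }


class TestMeasureTable:
    def test_incomplete_subject_excluded_listwise(self):
        df = make_table({"sham": np.ones((3, 3)), "magnet": np.zeros((3, 3))})
        df = df[~((df.subject_id == "sham0") & (df.time == "postdiazepam"))]
        clean = measure_table(df)
        assert "sham0" not in set(clean["subject_id"])
        assert clean.groupby("subject_id")["time"].nunique().eq(3).all()

    def test_duplicate_cell_rejected(self):
        df = make_table({"sham": np.ones((3, 3)), "magnet": np.zeros((3, 3))})
        with pytest.raises(ValidationError):
            measure_table(pd.concat([df, df.iloc[:1]]))

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError):
            measure_table(pd.DataFrame({"subject_id": [], "value": []}))


class TestMixedRmAnova:
    def test_all_equal_values_give_zero_f(self):
        df = make_table({"sham": np.full((4, 3), 5.0), "magnet": np.full((4, 3), 5.0)})
        rep = mixed_rm_anova(df)
        assert all(e.F == 0.0 for e in rep.effects.values())

    def test_matches_brute_force_oracle_on_random_designs(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            df = random_table(rng)
            rep = mixed_rm_anova(df)
            oracle = oracle_anova(df)
            for effect in ("condition", "time", "condition:time"):
                assert rep.effects[effect].ss == pytest.approx(
                    oracle[effect], rel=1e-10, abs=1e-10
                )
            assert rep.ss_subjects_within == pytest.approx(oracle["subjects_within"], rel=1e-10)
            assert rep.ss_error_within == pytest.approx(oracle["error"], rel=1e-10, abs=1e-10)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        df = random_table(rng, n_per_group=6)
        rep = mixed_rm_anova(df)
        ref = pg.mixed_anova(
            data=df.rename(columns={"subject_id": "subject"}),
            dv="value", within="time", subject="subject", between="condition",
        ).set_index("Source")
        assert rep.effects["condition"].F == pytest.approx(ref.loc["condition", "F"])
        assert rep.effects["time"].F == pytest.approx(ref.loc["time", "F"])
        assert rep.effects["condition:time"].F == pytest.approx(ref.loc["Interaction", "F"])
        assert rep.effects["time"].p_uncorrected == pytest.approx(ref.loc["time", "p_unc"])

    def test_gg_epsilon_bounds_on_random_covariances(self):
        rng = np.random.default_rng(9)
        k = 3
        for _ in range(50):
            A = rng.normal(size=(k, k + 2))
            cov = A @ A.T + np.eye(k) * 0.1
            y = rng.multivariate_normal(np.zeros(k), cov, size=12)
            groups = np.repeat(["a", "b"], 6)
            eps = _gg_epsilon(y, groups)
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12

    def test_gg_epsilon_near_one_under_compound_symmetry(self):
        rng = np.random.default_rng(10)
        k = 3
        cov = np.full((k, k), 0.6) + np.eye(k) * 0.8
        y = rng.multivariate_normal(np.zeros(k), cov, size=400)
        eps = _gg_epsilon(y, np.repeat(["a", "b"], 200))
        assert eps > 0.97

    def test_single_subject_group_rejected(self):
        df = make_table({"sham": np.random.rand(1, 3), "magnet": np.random.rand(4, 3)})
        with pytest.raises(ValidationError):
            mixed_rm_anova(df)


class TestTukey:
    def test_identical_groups_nonsignificant(self):
        base = np.tile([1.0, 2.0, 3.0], (5, 1))
        rng = np.random.default_rng(2)
        df = make_table({
            "sham": base + rng.normal(0, 0.5, base.shape),
            "magnet": base + rng.normal(0, 0.5, base.shape),
        })
        rep = tukey_posthoc(df, effect="condition")
        assert len(rep.comparisons) == 1
        assert rep.comparisons[0].p_adj > 0.3

    def test_widely_separated_groups_significant(self):
        rng = np.random.default_rng(3)
        df = make_table({
            "sham": rng.normal(0.0, 1.0, (6, 3)),
            "magnet": rng.normal(10.0, 1.0, (6, 3)),  # 10 pooled SDs apart
        })
        rep = tukey_posthoc(df, effect="condition")
        assert rep.comparisons[0].p_adj < 0.001

    def test_three_time_levels_give_three_rows(self):
        rng = np.random.default_rng(4)
        df = random_table(rng, n_per_group=4)
        rep = tukey_posthoc(df, effect="time")
        assert len(rep.comparisons) == 3

    def test_cells_family_has_fifteen_pairs(self):
        rng = np.random.default_rng(5)
        rep = tukey_posthoc(random_table(rng, n_per_group=4), effect="cells")
        assert len(rep.comparisons) == 15  # C(6, 2)

    def test_adjusted_p_never_below_unadjusted(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            rep = tukey_posthoc(random_table(rng), effect="cells")
            for c in rep.comparisons:
                assert c.p_adj >= c.p_unadjusted - 1e-12

    def test_symmetry_up_to_sign(self):
        rng = np.random.default_rng(7)
        rep = tukey_posthoc(random_table(rng, n_per_group=4), effect="condition")
        c = rep.comparisons[0]
        assert c.q == pytest.approx(abs(c.mean_diff) / (c.se / np.sqrt(2)))


class TestSynergyAnalysis:
    def test_report_structure_and_alpha_marking(self):
        rng = np.random.default_rng(8)
        frames = []
        for measure in ("spike_rate", "rms_reduction"):
            df = random_table(rng, n_per_group=6)
            df["measure"] = measure
            frames.append(df)
        rep = synergy_analysis(pd.concat(frames, ignore_index=True))
        assert set(rep.anova["measure"]) == {"spike_rate", "rms_reduction"}
        assert set(rep.anova["effect"]) == {"condition", "time", "condition:time"}
        assert (rep.tukey.groupby("measure").size() == 15).all()
        assert "Mixed rm-ANOVA" in rep.summary()

    def test_single_subject_groups_propagate_error(self):
        df = make_table({"sham": np.random.rand(1, 3), "magnet": np.random.rand(1, 3)})
        df["measure"] = "spike_rate"
        with pytest.raises(ValidationError, match="spike_rate"):
            synergy_analysis(df)
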