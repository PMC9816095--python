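"""Inferential layer: two-way mixed repeated-measures ANOVA and Tukey HSD.

The design is the experiment's: CONDITION (sham vs magnet) varies between
subjects — each animal receives only one treatment — while TIME (baseline,
prediazepam, postdiazepam) varies within subjects.  The ANOVA is the classic
split-plot sums-of-squares decomposition with two error strata:
subjects-within-condition for the between effect, and the subject × time
residual for the within effects.  Sphericity of the within factor is never
assumed silently: the Greenhouse–Geisser epsilon is always estimated from the
pooled within-subject covariance and reported, and the corrected p-value is
used for within effects whenever epsilon < 0.75.

Tukey's HSD uses the studentized-range distribution with the error stratum
appropriate to the family being compared; condition-at-time cell comparisons
use the two strata pooled, the standard recommendation for between×within
simple effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError

__all__ = [
    "TIME_LEVELS",
    "measure_table",
    "EffectResult",
    "RmAnovaReport",
    "mixed_rm_anova",
    "TukeyComparison",
    "TukeyReport",
    "tukey_posthoc",
    "synergy_analysis",
    "SynergyReport",
]

logger = logging.getLogger(__name__)

TIME_LEVELS = ["baseline", "prediazepam", "postdiazepam"]
ALPHA = 0.05
GG_TRIGGER = 0.75  # apply the GG-corrected p when epsilon falls below this


def measure_table(df: pd.DataFrame, time_levels: Optional[List[str]] = None) -> pd.DataFrame:
    """Validate and clean a long-format measure table.

    Expects columns ``subject_id, condition, time, value`` with one value per
    subject × time cell.  Subjects missing any time level are excluded
    listwise with a logged warning (a complete within-subject design is
    required).  Returns a copy with categorical time ordered as given.
    """
    required = {"subject_id", "condition", "time", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"measure table lacks columns: {sorted(missing)}")
    if time_levels is None:
        time_levels = [t for t in TIME_LEVELS if t in set(df["time"])] or sorted(
            set(df["time"])
        )
    out = df.loc[df["time"].isin(time_levels)].copy()
    dup = out.duplicated(["subject_id", "time"])
    if dup.any():
        raise ValidationError(
            f"duplicate subject × time cells: "
            f"{out.loc[dup, ['subject_id', 'time']].values.tolist()}"
        )
    counts = out.groupby("subject_id")["time"].nunique()
    incomplete = counts[counts < len(time_levels)].index.tolist()
    if incomplete:
        logger.warning("excluding subjects with missing cells: %s", incomplete)
        out = out[~out["subject_id"].isin(incomplete)]
    if out.empty:
        raise ValidationError("no complete subjects remain in the measure table")
    na = out["value"].isna()
    if na.any():
        bad = out.loc[na, "subject_id"].unique().tolist()
        logger.warning("excluding subjects with missing values: %s", bad)
        out = out[~out["subject_id"].isin(bad)]
        counts = out.groupby("subject_id")["time"].nunique()
        out = out[out["subject_id"].isin(counts[counts == len(time_levels)].index)]
    if out.empty:
        raise ValidationError("no complete subjects remain in the measure table")
    out["time"] = pd.Categorical(out["time"], categories=time_levels, ordered=True)
    cond_per_subj = out.groupby("subject_id")["condition"].nunique()
    if (cond_per_subj > 1).any():
        raise ValidationError("a subject appears under more than one condition")
    return out.sort_values(["condition", "subject_id", "time"]).reset_index(drop=True)


@dataclass(frozen=True)
class EffectResult:
    """One ANOVA effect line."""

    ss: float
    df_num: float
    df_den: float
    ms: float
    F: float
    p_uncorrected: float
    gg_epsilon: Optional[float] = None  # within effects only
    p_gg: Optional[float] = None

    @property
    def p(self) -> float:
        """Working p-value: GG-corrected when epsilon < 0.75, else uncorrected."""
        if self.gg_epsilon is not None and self.gg_epsilon < GG_TRIGGER:
            return float(self.p_gg)
        return float(self.p_uncorrected)


@dataclass
class RmAnovaReport:
    """Effect table plus error strata of one mixed rm-ANOVA."""

    effects: Dict[str, EffectResult]
    ss_subjects_within: float
    df_subjects_within: float
    ss_error_within: float
    df_error_within: float
    n_subjects: Dict[str, int] = field(default_factory=dict)
    k_within: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in self.effects.items():
            rows.append(
                {
                    "effect": name,
                    "SS": e.ss,
                    "df_num": e.df_num,
                    "df_den": e.df_den,
                    "MS": e.ms,
                    "F": e.F,
                    "p_uncorrected": e.p_uncorrected,
                    "gg_epsilon": e.gg_epsilon,
                    "p_gg": e.p_gg,
                    "p": e.p,
                }
            )
        return pd.DataFrame(rows)


def _gg_epsilon(wide: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the pooled within-group covariance.

    ``wide`` is subjects × k; group labels remove the between-condition mean
    so the pooled covariance reflects within-subject structure only.
    """
    k = wide.shape[1]
    resid = np.empty_like(wide, dtype=float)
    n_params = 0
    for g in np.unique(groups):
        sel = groups == g
        resid[sel] = wide[sel] - wide[sel].mean(axis=0, keepdims=True)
        n_params += 1
    dof = wide.shape[0] - n_params
    if dof < 1:
        return 1.0
    S = resid.T @ resid / dof
    # double-center
    row = S.mean(axis=0, keepdims=True)
    col = S.mean(axis=1, keepdims=True)
    Sc = S - row - col + S.mean()
    denom = (k - 1) * float(np.sum(Sc**2))
    if denom <= 0:
        return 1.0
    eps = float(np.trace(Sc) ** 2 / denom)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mixed_rm_anova(df: pd.DataFrame) -> RmAnovaReport:
    """Two-way mixed ANOVA: between CONDITION, within TIME.

    Requires at least two subjects per condition and a complete design (use
    :func:`measure_table` to validate/exclude first).  Returns the full effect
    table with both uncorrected and Greenhouse–Geisser-corrected p-values for
    the within effects.
    """
    df = measure_table(df)
    times = list(df["time"].cat.categories)
    k = len(times)
    if k < 2:
        raise ValidationError("need at least two time levels")
    wide = df.pivot_table(index=["condition", "subject_id"], columns="time",
                          values="value", observed=False)
    if wide.isna().any().any():
        raise ValidationError(
            f"incomplete design: missing cells {wide[wide.isna().any(axis=1)].index.tolist()}"
        )
    groups = np.asarray([idx[0] for idx in wide.index])
    y = wide.to_numpy(dtype=float)
    n_by_group = {g: int((groups == g).sum()) for g in np.unique(groups)}
    if len(n_by_group) < 2:
        raise ValidationError("need both conditions present")
    if min(n_by_group.values()) < 2:
        raise ValidationError(
            f"need >= 2 subjects per condition, got {n_by_group}"
        )
    n_subj = y.shape[0]
    grand = y.mean()

    subj_means = y.mean(axis=1)
    group_means = {g: y[groups == g].mean() for g in n_by_group}
    time_means = y.mean(axis=0)
    cell_means = {g: y[groups == g].mean(axis=0) for g in n_by_group}

    ss_total = float(((y - grand) ** 2).sum())
    ss_cond = float(k * sum(n_by_group[g] * (group_means[g] - grand) ** 2 for g in n_by_group))
    ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_sw = ss_between_subj - ss_cond  # subjects within condition
    ss_time = float(n_subj * ((time_means - grand) ** 2).sum())
    ss_inter = float(
        sum(
            n_by_group[g]
            * ((cell_means[g] - group_means[g] - time_means + grand) ** 2).sum()
            for g in n_by_group
        )
    )
    ss_err = ss_total - ss_cond - ss_sw - ss_time - ss_inter

    a = len(n_by_group)
    df_cond = a - 1
    df_sw = n_subj - a
    df_time = k - 1
    df_inter = (a - 1) * (k - 1)
    df_err = (n_subj - a) * (k - 1)

    ms_cond = ss_cond / df_cond
    ms_sw = ss_sw / df_sw
    ms_time = ss_time / df_time
    ms_inter = ss_inter / df_inter
    ms_err = ss_err / df_err

    eps = _gg_epsilon(y, groups)

    def f_p(ms_num, df_num, ms_den, df_den):
        F = ms_num / ms_den if ms_den > 0 else 0.0
        return F, float(sps.f.sf(F, df_num, df_den))

    F_cond, p_cond = f_p(ms_cond, df_cond, ms_sw, df_sw)
    F_time, p_time = f_p(ms_time, df_time, ms_err, df_err)
    F_int, p_int = f_p(ms_inter, df_inter, ms_err, df_err)

    effects = {
        "condition": EffectResult(
            ss=ss_cond, df_num=df_cond, df_den=df_sw, ms=ms_cond,
            F=F_cond, p_uncorrected=p_cond,
        ),
        "time": EffectResult(
            ss=ss_time, df_num=df_time, df_den=df_err, ms=ms_time,
            F=F_time, p_uncorrected=p_time, gg_epsilon=eps,
            p_gg=float(sps.f.sf(F_time, df_time * eps, df_err * eps)),
        ),
        "condition:time": EffectResult(
            ss=ss_inter, df_num=df_inter, df_den=df_err, ms=ms_inter,
            F=F_int, p_uncorrected=p_int, gg_epsilon=eps,
            p_gg=float(sps.f.sf(F_int, df_inter * eps, df_err * eps)),
        ),
    }
    return RmAnovaReport(
        effects=effects,
        ss_subjects_within=ss_sw,
        df_subjects_within=df_sw,
        ss_error_within=ss_err,
        df_error_within=df_err,
        n_subjects=n_by_group,
        k_within=k,
    )


@dataclass(frozen=True)
class TukeyComparison:
    group_a: str
    group_b: str
    mean_diff: float  # mean(a) - mean(b)
    se: float
    q: float
    p_adj: float
    p_unadjusted: float  # plain two-group t-test p on the same stratum


@dataclass
class TukeyReport:
    effect: str
    comparisons: List[TukeyComparison]
    ms_error: float
    df_error: float
    k_groups: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.comparisons])


def _tukey_rows(means, counts, scale_n, ms, dfe, k) -> List[TukeyComparison]:
    """All pairwise Tukey(-Kramer) comparisons over ``means``.

    ``scale_n`` multiplies the per-group n (e.g. k time levels per subject
    when comparing condition means of a within design).
    """
    names = list(means)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gA, gB = names[i], names[j]
            diff = means[gA] - means[gB]
            nA, nB = counts[gA] * scale_n, counts[gB] * scale_n
            se_q = np.sqrt(ms / 2.0 * (1.0 / nA + 1.0 / nB))
            q = abs(diff) / se_q if se_q > 0 else 0.0
            p_adj = float(sps.studentized_range.sf(q, k, dfe)) if se_q > 0 else 1.0
            t = q / np.sqrt(2.0)
            p_un = float(2 * sps.t.sf(t, dfe))
            rows.append(
                TukeyComparison(
                    group_a=str(gA), group_b=str(gB), mean_diff=float(diff),
                    se=float(se_q * np.sqrt(2.0)), q=float(q),
                    p_adj=min(1.0, p_adj), p_unadjusted=min(1.0, p_un),
                )
            )
    return rows


def tukey_posthoc(df: pd.DataFrame, effect: str = "cells") -> TukeyReport:
    """Tukey HSD over cell means of a mixed-design measure table.

    ``effect`` selects the family and error stratum:

    * ``"condition"`` — between-group means, subjects-within-condition stratum;
    * ``"time"`` — within-factor means, the subject × time residual stratum;
    * ``"cells"`` — all condition × time cell means, with the two strata
      pooled (appropriate for condition-at-time simple effects).
    """
    df = measure_table(df)
    report = mixed_rm_anova(df)
    k_w = report.k_within
    ms_sw = report.ss_subjects_within / report.df_subjects_within
    ms_err = report.ss_error_within / report.df_error_within
    counts_subjects = report.n_subjects

    if effect == "condition":
        means = df.groupby("condition", observed=False)["value"].mean().to_dict()
        if len(means) < 2:
            raise ValidationError("need >= 2 condition groups")
        rows = _tukey_rows(means, counts_subjects, k_w, ms_sw,
                           report.df_subjects_within, len(means))
        return TukeyReport(effect, rows, ms_sw, report.df_subjects_within, len(means))
    if effect == "time":
        means = df.groupby("time", observed=False)["value"].mean().to_dict()
        counts = {t: sum(counts_subjects.values()) for t in means}
        rows = _tukey_rows(means, counts, 1, ms_err,
                           report.df_error_within, len(means))
        return TukeyReport(effect, rows, ms_err, report.df_error_within, len(means))
    if effect == "cells":
        cells = df.groupby(["condition", "time"], observed=False)["value"].mean()
        means = {f"{c}@{t}": v for (c, t), v in cells.items()}
        counts = {
            f"{c}@{t}": counts_subjects[c] for (c, t) in cells.index
        }
        ms_pool = (
            report.ss_subjects_within + report.ss_error_within
        ) / (report.df_subjects_within + report.df_error_within)
        df_pool = report.df_subjects_within + report.df_error_within
        rows = _tukey_rows(means, counts, 1, ms_pool, df_pool, len(means))
        return TukeyReport(effect, rows, ms_pool, df_pool, len(means))
    raise ValidationError(f"unknown effect family {effect!r}")


@dataclass
class SynergyReport:
    """ANOVA + Tukey results for every measure of a cohort."""

    anova: pd.DataFrame  # one row per measure × effect
    tukey: pd.DataFrame  # one row per measure × cell pair
    alpha: float = ALPHA

    def summary(self) -> str:
        lines = ["Mixed rm-ANOVA (between: condition, within: time)", ""]
        for _, r in self.anova.iterrows():
            star = " *" if r["p"] < self.alpha else ""
            eps = f", GG eps={r['gg_epsilon']:.3f}" if np.isfinite(r.get("gg_epsilon") or np.nan) else ""
            lines.append(
                f"{r['measure']:>24s}  {r['effect']:<15s} "
                f"F({r['df_num']:g}, {r['df_den']:g}) = {r['F']:.3f}, "
                f"p = {r['p']:.4f}{eps}{star}"
            )
        lines.append("")
        lines.append(f"Tukey HSD cell comparisons significant at alpha={self.alpha}:")
        sig = self.tukey[self.tukey["p_adj"] < self.alpha]
        if sig.empty:
            lines.append("  (none)")
        for _, r in sig.iterrows():
            lines.append(
                f"  {r['measure']:>24s}  {r['group_a']} vs {r['group_b']}: "
                f"diff = {r['mean_diff']:.3f}, p_adj = {r['p_adj']:.4f}"
            )
        return "\n".join(lines)


def synergy_analysis(measures: pd.DataFrame, alpha: float = ALPHA) -> SynergyReport:
    """Run the full CONDITION × TIME analysis on every measure of a cohort.

    ``measures`` is tidy long format: one row per subject × phase × measure
    with columns ``subject_id, condition, time, measure, value`` (``time``
    holds the phase labels).  Each measure gets a mixed rm-ANOVA plus Tukey
    cell comparisons; the returned report marks contrasts significant at
    ``alpha``.
    """
    required = {"subject_id", "condition", "time", "measure", "value"}
    if not required <= set(measures.columns):
        raise ValidationError(f"measures table needs columns {sorted(required)}")
    anova_rows, tukey_rows = [], []
    for measure, sub in measures.groupby("measure"):
        try:
            rep = mixed_rm_anova(sub)
            tk = tukey_posthoc(sub, effect="cells")
        except ValidationError as exc:
            raise ValidationError(f"measure {measure!r}: {exc}") from exc
        af = rep.to_frame()
        af.insert(0, "measure", measure)
        anova_rows.append(af)
        tf = tk.to_frame()
        tf.insert(0, "measure", measure)
        tukey_rows.append(tf)
    return SynergyReport(
        anova=pd.concat(anova_rows, ignore_index=True),
        tukey=pd.concat(tukey_rows, ignore_index=True),
        alpha=alpha,
    )
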