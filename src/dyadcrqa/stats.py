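"""Cohort-level inference over CRQA outputs.

Covers the analyses the pipeline reports: condition x lag-bin repeated-
measures ANOVAs on binned DCRPs, paired and one-sample tests on per-dyad
CORM values with a Shapiro-Wilk normality gate and nonparametric fallbacks,
and two-sample rank tests on time budgets.  All statistics on CORM inputs are
invariant under a global positive rescaling of those inputs (t, V and W
depend only on signs and ranks of differences, or on ratios), so conclusions
do not hinge on the CORM normalization constant.

No multiple-testing correction is applied; reports state this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


class DegenerateInputError(ValueError):
    """Input has no variance where the test requires some."""


class DesignError(ValueError):
    """Unbalanced or incomplete factorial layout."""


@dataclass
class TestResult:
    """One inferential test: statistic, df, p, effect descriptors."""

    name: str
    test: str
    statistic: float
    p: float
    df: float | tuple | None = None
    n: int | None = None
    parametric_used: bool | None = None
    effects: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise ValueError(f"non-finite statistic in {self.name}")
        if not 0 <= self.p <= 1:
            raise ValueError(f"p outside [0, 1] in {self.name}")

    @property
    def significant(self) -> bool:
        return self.p < ALPHA

    def to_row(self) -> dict:
        df = self.df
        if isinstance(df, tuple):
            df = "/".join(f"{v:g}" for v in df)
        return {
            "analysis": self.name, "statistic": self.test,
            "value": self.statistic, "df": df, "p": self.p,
            "parametric_used": self.parametric_used, "n": self.n,
            **{f"effect_{k}": v for k, v in self.effects.items()},
        }


@dataclass
class CohortProfiles:
    """Binned DCRPs per dyad x condition in long form.

    ``data`` has columns dyad, condition, bin, rr with one row per cell; all
    profiles share the bin geometry (``bin_lags_s`` gives the bin centers).
    """

    data: pd.DataFrame
    bin_lags_s: np.ndarray

    @classmethod
    def from_arrays(cls, profiles: dict[str, np.ndarray], bin_lags_s: np.ndarray,
                    dyad_ids: Sequence[str] | None = None) -> "CohortProfiles":
        """Build from {condition: (n_dyads x n_bins) array}."""
        rows = []
        for cond, arr in profiles.items():
            arr = np.asarray(arr, dtype=float)
            ids = dyad_ids if dyad_ids is not None else [str(k) for k in range(len(arr))]
            for d, dyad in enumerate(ids):
                for b in range(arr.shape[1]):
                    rows.append((dyad, cond, b, arr[d, b]))
        return cls(pd.DataFrame(rows, columns=["dyad", "condition", "bin", "rr"]),
                   np.asarray(bin_lags_s, dtype=float))


def _check_balanced(df: pd.DataFrame) -> tuple[list, list, list]:
    dyads = sorted(df["dyad"].unique())
    conds = sorted(df["condition"].unique())
    bins = sorted(df["bin"].unique())
    counts = df.groupby(["dyad", "condition", "bin"]).size()
    if (counts != 1).any():
        dup = counts[counts != 1].index[0]
        raise DesignError(f"cell {dup} has {counts[counts != 1].iloc[0]} observations")
    expected = len(dyads) * len(conds) * len(bins)
    if len(df) != expected:
        have = set(map(tuple, df[["dyad", "condition", "bin"]].itertuples(index=False)))
        missing = [(d, c, b) for d in dyads for c in conds for b in bins
                   if (d, c, b) not in have]
        raise DesignError(f"missing cells (first few): {missing[:5]}")
    return dyads, conds, bins


def _rm_f(ss_eff: float, df_eff: int, ss_err: float, df_err: int,
          scale: float) -> tuple[float, float]:
    """F and p with the zero-SS conventions of a noiseless fixture.

    A null effect measured without error (SS_effect ~ 0) is reported as
    F = 0, p = 1 rather than 0/0; a nonzero effect with zero error SS is
    reported at machine ceiling with p = 0.
    """
    tiny = 1e-12 * max(scale, 1.0)
    if ss_eff <= tiny:
        return 0.0, 1.0
    if ss_err <= tiny:
        return float(np.finfo(float).max), 0.0
    f = (ss_eff / df_eff) / (ss_err / df_err)
    return float(f), float(sps.f.sf(f, df_eff, df_err))


def profile_anova(profiles: CohortProfiles) -> dict[str, TestResult]:
    """Two-way fully within-subject ANOVA: condition x lag bin, dyad as unit.

    Balanced closed-form sums of squares; each effect is tested against its
    own effect-by-dyad interaction (the standard repeated-measures error
    term).  Returns results keyed 'condition', 'lag', 'interaction'.
    """
    df = profiles.data
    dyads, conds, bins = _check_balanced(df)
    ns, na, nb = len(dyads), len(conds), len(bins)
    if ns < 2 or na < 2 or nb < 2:
        raise DesignError("need >= 2 dyads, >= 2 conditions and >= 2 bins")
    y = (df.set_index(["dyad", "condition", "bin"])["rr"]
           .unstack(["condition", "bin"])
           .loc[dyads]
           .to_numpy().reshape(ns, na, nb))
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = ns * nb * np.sum((m_a - grand) ** 2)
    ss_b = ns * na * np.sum((m_b - grand) ** 2)
    ss_ab = ns * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_sa = nb * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_sb = na * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :] - grand)
    ss_sab = np.sum(resid ** 2)
    scale = float(np.sum((y - grand) ** 2))

    out = {}
    specs = [
        ("condition", ss_a, na - 1, ss_sa, (na - 1) * (ns - 1)),
        ("lag", ss_b, nb - 1, ss_sb, (nb - 1) * (ns - 1)),
        ("interaction", ss_ab, (na - 1) * (nb - 1), ss_sab, (na - 1) * (nb - 1) * (ns - 1)),
    ]
    for name, ss_eff, df_eff, ss_err, df_err in specs:
        f, p = _rm_f(ss_eff, df_eff, ss_err, df_err, scale)
        out[name] = TestResult(
            name=f"profile_anova:{name}", test="F", statistic=f, p=p,
            df=(df_eff, df_err), n=ns, parametric_used=True,
            effects={"ss_effect": float(ss_eff), "ss_error": float(ss_err)},
            notes=["repeated-measures, dyad as unit"],
        )
    return out


def normality_gate(x: np.ndarray, alpha: float = ALPHA) -> tuple[bool, dict]:
    """Shapiro-Wilk gate: True -> parametric path.

    Returns (parametric, info); a constant vector is degenerate and routed
    nonparametric with ``info['degenerate'] = True``.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise DegenerateInputError("need n >= 3 for the normality gate")
    if np.ptp(x) == 0:
        return False, {"degenerate": True, "shapiro_p": None}
    w, p = sps.shapiro(x)
    return bool(p >= alpha), {"degenerate": False, "shapiro_W": float(w),
                              "shapiro_p": float(p)}


def _signed_rank(d: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank with V = positive-rank sum (R convention),
    p two-sided."""
    v = sps.wilcoxon(d, alternative="greater").statistic
    p = sps.wilcoxon(d).pvalue
    return float(v), float(p)


def _descriptives(x: np.ndarray) -> dict:
    x = np.asarray(x, dtype=float)
    return {
        "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)),
        "median": float(np.median(x)),
        "mad": float(np.median(np.abs(x - np.median(x)))),
    }


def _t_ci(x: np.ndarray, conf: float = 0.95) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    m = x.mean()
    se = x.std(ddof=1) / np.sqrt(len(x))
    h = sps.t.ppf(0.5 + conf / 2, len(x) - 1) * se
    return float(m - h), float(m + h)


def compare_corm_paired(a: np.ndarray, b: np.ndarray, name: str = "corm_paired") -> TestResult:
    """Paired comparison of per-dyad CORM values (a - b).

    Paired t-test when the differences pass the normality gate, otherwise a
    Wilcoxon signed-rank test (statistic V = positive-rank sum).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D vectors")
    if len(a) < 3:
        raise DegenerateInputError("need n >= 3 pairs")
    d = a - b
    if np.ptp(d) == 0 and d[0] == 0:
        raise DegenerateInputError("all paired differences are zero")
    parametric, gate = normality_gate(d)
    effects = {"mean_diff": float(d.mean()), "median_diff": float(np.median(d)),
               **{f"a_{k}": v for k, v in _descriptives(a).items()},
               **{f"b_{k}": v for k, v in _descriptives(b).items()}}
    if parametric:
        t, p = sps.ttest_rel(a, b)
        lo, hi = _t_ci(d)
        effects.update(ci_low=lo, ci_high=hi)
        return TestResult(name, "t", float(t), float(p), df=len(a) - 1, n=len(a),
                          parametric_used=True, effects=effects,
                          notes=[f"normality gate: {gate}"])
    v, p = _signed_rank(d)
    return TestResult(name, "V", float(v), float(p), n=len(a),
                      parametric_used=False, effects=effects,
                      notes=[f"normality gate: {gate}"])


def corm_vs_zero(values: np.ndarray, name: str = "corm_vs_zero") -> TestResult:
    """One-sample test of per-dyad CORM values against zero."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise DegenerateInputError("need n >= 3 values")
    if np.ptp(x) == 0 and x[0] == 0:
        raise DegenerateInputError("all values are zero")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance")
    parametric, gate = normality_gate(x)
    effects = _descriptives(x)
    if parametric:
        t, p = sps.ttest_1samp(x, 0.0)
        lo, hi = _t_ci(x)
        effects.update(ci_low=lo, ci_high=hi)
        return TestResult(name, "t", float(t), float(p), df=len(x) - 1, n=len(x),
                          parametric_used=True, effects=effects,
                          notes=[f"normality gate: {gate}"])
    v, p = _signed_rank(x)
    return TestResult(name, "V", float(v), float(p), n=len(x),
                      parametric_used=False, effects=effects,
                      notes=[f"normality gate: {gate}"])


def compare_durations(
    trained_fracs: np.ndarray,
    untrained_fracs: np.ndarray,
    paired: bool = False,
    name: str = "durations",
) -> TestResult:
    """Rank test on per-participant time fractions.

    Unpaired (default): two-sample rank-sum; W follows the convention of R's
    ``wilcox.test`` — the Mann-Whitney U of the first sample, i.e. the rank
    sum of the first sample minus n1(n1+1)/2 (the alternative rank-sum value
    is logged).  Paired: Wilcoxon signed-rank V.
    """
    x = np.asarray(trained_fracs, dtype=float)
    y = np.asarray(untrained_fracs, dtype=float)
    if min(len(x), len(y)) < 3:
        raise DegenerateInputError("need n >= 3 per group")
    effects = {**{f"trained_{k}": v for k, v in _descriptives(x).items()},
               **{f"untrained_{k}": v for k, v in _descriptives(y).items()}}
    notes = []
    if np.ptp(np.concatenate([x, y])) == 0:
        notes.append("degenerate: all observations tied; exact ties handled by "
                     "the normal approximation with tie correction")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired comparison needs equal lengths")
        if np.ptp(x - y) == 0 and (x - y)[0] == 0:
            raise DegenerateInputError("all paired differences are zero")
        v, p = _signed_rank(x - y)
        return TestResult(name, "V", float(v), float(p), n=len(x),
                          parametric_used=False, effects=effects, notes=notes)
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    rank_sum = u + len(x) * (len(x) + 1) / 2
    notes.append(f"rank-sum convention: sum of trained ranks = {rank_sum:g}")
    return TestResult(name, "W", float(u), float(p), n=len(x) + len(y),
                      parametric_used=False, effects=effects, notes=notes)
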