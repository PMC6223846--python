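"""Discrimination-learning analysis: learning curves, the discrimination
score d, and the two stimulus-free negative controls.

The discrimination score of a fish is the difference between its composite
appetitive scores for the rewarded and the unrewarded odor, averaged over
the last ``n_last`` trials of each stimulus class:

    d = mean(ζ_comp, last n CS+ trials) - mean(ζ_comp, last n CS- trials)

Cohort-level inference uses a Wilcoxon signed-rank test of the per-fish d
against zero, and a Wilcoxon rank-sum test pooling all individual CS+ and
CS- trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CS_MINUS, CS_PLUS, TrialSchedule, WindowSpec
from .params import ParameterPanel
from .zeta import score_panel

__all__ = [
    "signed_rank_test",
    "rank_sum_test",
    "median_filter_trials",
    "LearningCurveResult",
    "learning_curve",
    "DiscriminationModel",
    "DiscriminationResults",
    "discrimination_score",
    "preodor_control",
    "UnpairedControlResult",
    "unpaired_control",
]

_EXACT_N = 25  # exact rank-test null distributions up to this sample size


def signed_rank_test(d) -> float:
    """Two-sided Wilcoxon signed-rank p-value of ``d`` against zero.

    Exact distribution for n <= 25, normal approximation with continuity
    correction above.
    """
    d = np.asarray(d, dtype=float)
    if len(d) < 2 or np.all(d == 0):
        return 1.0
    method = "exact" if len(d) <= _EXACT_N else "approx"
    try:
        return float(stats.wilcoxon(d, correction=True, method=method).pvalue)
    except ValueError:
        return float(stats.wilcoxon(d, correction=True, method="approx").pvalue)


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return 1.0
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    method = "exact" if max(len(x), len(y)) <= _EXACT_N else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def median_filter_trials(series, window: int = 5) -> np.ndarray:
    """Centered running median over a trial series.

    The output is shorter by ``(window - 1) // 2`` trials at each end (the
    first and last two trials for the default window of five); no padding
    is applied.
    """
    series = np.asarray(series, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if len(series) < window:
        raise ValueError(f"need at least {window} trials for the median filter")
    sw = np.lib.stride_tricks.sliding_window_view(series, window)
    return np.median(sw, axis=1)


@dataclass
class LearningCurveResult:
    """Per-day medians of the composite score, averaged over fish.

    ``table`` has one row per (day, label) with the cohort mean and SEM of
    the per-fish daily medians; ``day_p`` maps day -> rank-sum p-value
    comparing all individual CS+ and CS- trials of that day. Significance
    flags: '*' for 0.01 <= p < 0.05, '**' for p < 0.01.
    """

    table: pd.DataFrame
    day_p: pd.Series
    cs_plus: str = CS_PLUS
    cs_minus: str = CS_MINUS

    @property
    def flags(self) -> pd.Series:
        def flag(p: float) -> str:
            if p < 0.01:
                return "**"
            if p < 0.05:
                return "*"
            return ""

        return self.day_p.map(flag)

    def summary(self) -> str:
        lines = ["Learning curve (per-day median composite score, cohort mean +/- SEM)"]
        piv = self.table.pivot(index="day", columns="label", values=["mean", "sem"])
        for day in piv.index:
            mp = piv.loc[day, ("mean", self.cs_plus)]
            mm = piv.loc[day, ("mean", self.cs_minus)]
            sp = piv.loc[day, ("sem", self.cs_plus)]
            sm = piv.loc[day, ("sem", self.cs_minus)]
            p = self.day_p.get(day, np.nan)
            lines.append(
                f"  day {day}: {self.cs_plus} {mp:+.3f}+/-{sp:.3f}  "
                f"{self.cs_minus} {mm:+.3f}+/-{sm:.3f}  p={p:.3g} {self.flags.get(day, '')}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Learning curve with per-day significance markers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for lab, style in ((self.cs_plus, "o-"), (self.cs_minus, "s--")):
            sub = self.table[self.table["label"] == lab]
            ax.errorbar(sub["day"], sub["mean"], yerr=sub["sem"], fmt=style, label=lab)
        ax.set_xlabel("training day")
        ax.set_ylabel(r"composite score $\zeta_{comp}$")
        ax.legend()
        return ax


def learning_curve(
    scores: pd.DataFrame,
    value_col: str = "zeta_comp",
    cs_plus: str = CS_PLUS,
    cs_minus: str = CS_MINUS,
) -> LearningCurveResult:
    """Build the per-day learning curve from a cohort trial-score table.

    Daily medians are computed per fish first and then averaged over fish;
    per-day significance compares all individual CS+ vs CS- trials of that
    day with a rank-sum test.
    """
    per_fish = (
        scores.groupby(["fish_id", "day", "label"])[value_col].median().reset_index()
    )
    table = (
        per_fish.groupby(["day", "label"])[value_col]
        .agg(mean="mean", sem="sem", n_fish="count")
        .reset_index()
    )
    day_p = {}
    for day, grp in scores.groupby("day"):
        xp = grp.loc[grp["label"] == cs_plus, value_col].to_numpy()
        xm = grp.loc[grp["label"] == cs_minus, value_col].to_numpy()
        day_p[day] = rank_sum_test(xp, xm)
    return LearningCurveResult(
        table=table, day_p=pd.Series(day_p).sort_index(), cs_plus=cs_plus, cs_minus=cs_minus
    )


@dataclass
class DiscriminationResults:
    """Estimates and inference for the cohort discrimination score."""

    d_per_fish: pd.Series
    mean_d: float
    sem_d: float
    p_signed_rank: float
    pooled_ranksum_p: float
    n_last: int

    @property
    def n_fish(self) -> int:
        return len(self.d_per_fish)

    def summary(self) -> str:
        sem = "n/a" if not math.isfinite(self.sem_d) else f"{self.sem_d:.3f}"
        return "\n".join(
            [
                "Discrimination score d (CS+ minus CS- composite, "
                f"last {self.n_last} trials per class)",
                f"  n fish                 : {self.n_fish}",
                f"  mean d +/- SEM         : {self.mean_d:+.3f} +/- {sem}",
                f"  signed-rank p (d vs 0) : {self.p_signed_rank:.3g}",
                f"  pooled rank-sum p      : {self.pooled_ranksum_p:.3g}",
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar([0], [self.mean_d], yerr=[self.sem_d if math.isfinite(self.sem_d) else 0])
        ax.scatter(
            np.zeros(self.n_fish) + 0.15, self.d_per_fish.to_numpy(), s=12, color="k", zorder=3
        )
        ax.set_xticks([0])
        ax.set_xticklabels(["cohort"])
        ax.set_ylabel("discrimination score d")
        return ax


class DiscriminationModel:
    """End-of-training discrimination model for a cohort trial-score table.

    Parameters
    ----------
    scores : DataFrame with columns ``fish_id, trial, label`` and the
        composite-score column (default ``zeta_comp``).
    n_last : number of final trials of each stimulus class entering d.
    """

    def __init__(
        self,
        scores: pd.DataFrame,
        n_last: int = 12,
        value_col: str = "zeta_comp",
        cs_plus: str = CS_PLUS,
        cs_minus: str = CS_MINUS,
    ):
        self.scores = scores
        self.n_last = n_last
        self.value_col = value_col
        self.cs_plus = cs_plus
        self.cs_minus = cs_minus

    @classmethod
    def from_scores(cls, scores: pd.DataFrame, **kwargs) -> "DiscriminationModel":
        return cls(scores, **kwargs)

    def fit(self) -> DiscriminationResults:
        d = {}
        short: list[str] = []
        for fish, grp in self.scores.groupby("fish_id"):
            grp = grp.sort_values("trial")
            xp = grp.loc[grp["label"] == self.cs_plus, self.value_col].to_numpy()
            xm = grp.loc[grp["label"] == self.cs_minus, self.value_col].to_numpy()
            if len(xp) < self.n_last or len(xm) < self.n_last:
                short.append(str(fish))
                continue
            d[fish] = float(xp[-self.n_last :].mean() - xm[-self.n_last :].mean())
        if short:
            raise ValueError(
                f"fewer than {self.n_last} trials per class for fish: {', '.join(short)}"
            )
        d_ser = pd.Series(d, name="d")
        mean_d = float(d_ser.mean())
        sem_d = float(d_ser.sem()) if len(d_ser) > 1 else float("nan")
        p_signed = signed_rank_test(d_ser.to_numpy())
        pooled = rank_sum_test(
            self.scores.loc[self.scores["label"] == self.cs_plus, self.value_col],
            self.scores.loc[self.scores["label"] == self.cs_minus, self.value_col],
        )
        return DiscriminationResults(
            d_per_fish=d_ser,
            mean_d=mean_d,
            sem_d=sem_d,
            p_signed_rank=p_signed,
            pooled_ranksum_p=pooled,
            n_last=self.n_last,
        )


def discrimination_score(scores: pd.DataFrame, n_last: int = 12, **kwargs) -> DiscriminationResults:
    """Functional shorthand for ``DiscriminationModel(scores, n_last).fit()``."""
    return DiscriminationModel(scores, n_last=n_last, **kwargs).fit()


def preodor_control(
    panels: list[ParameterPanel],
    schedules: list[TrialSchedule],
    windows: WindowSpec | None = None,
    n_last: int = 12,
) -> DiscriminationResults:
    """Stimulus-free re-analysis: shift all windows so the "response"
    window lies 60-30 s *before* odor application.

    With the default 30-s windows the shifted response window is
    [-60, -30] s, baseline [-90, -60] s, reference [-120, -90] s relative
    to onset. Any apparent discrimination here would indicate a bias in
    the training or analysis procedure.
    """
    windows = windows or WindowSpec()
    shift = windows.preodor_shift_s
    frames = [
        score_panel(panel, sched, windows, offset_s=shift)
        for panel, sched in zip(panels, schedules)
    ]
    return DiscriminationModel(pd.concat(frames, ignore_index=True), n_last=n_last).fit()


@dataclass
class UnpairedControlResult:
    """Discrimination results for repeated random balanced CS assignments."""

    results: list[DiscriminationResults]
    assignments: list[dict[str, str]]  # fish_id -> odor taken as CS+
    seed: int

    @property
    def d_values(self) -> np.ndarray:
        return np.array([r.mean_d for r in self.results])

    @property
    def p_values(self) -> np.ndarray:
        return np.array([r.p_signed_rank for r in self.results])

    @property
    def mean_d(self) -> float:
        return float(self.d_values.mean())

    @property
    def sd_d(self) -> float:
        return float(self.d_values.std(ddof=1))

    def summary(self) -> str:
        lines = [
            f"Unpaired control: {len(self.results)} random balanced CS assignments "
            f"(seed {self.seed})",
            f"  d over assignments (mean +/- SD): {self.mean_d:+.3f} +/- {self.sd_d:.3f}",
            f"  signed-rank p range             : {self.p_values.min():.3g} - "
            f"{self.p_values.max():.3g}",
            f"  assignments significant at 0.05 : {(self.p_values < 0.05).sum()}",
        ]
        return "\n".join(lines)


def unpaired_control(
    scores: pd.DataFrame,
    n_assignments: int = 10,
    seed: int = 0,
    n_last: int = 12,
    odors: tuple[str, str] = ("A", "B"),
) -> UnpairedControlResult:
    """Analyze odor-unpaired data under random balanced CS assignments.

    ``scores`` must carry an ``odor`` column; trials were never predictive
    of food. For each of ``n_assignments`` seeded random assignments, half
    of the fish take the first odor as CS+ and half the second (the cohort
    size must be even), and the full discrimination analysis is run. With
    an unbiased pipeline no assignment should be significant. Duplicate
    assignments can occur for tiny cohorts and are retained.
    """
    fish_ids = sorted(scores["fish_id"].unique())
    if len(fish_ids) % 2 != 0:
        raise ValueError("unpaired control requires an even number of fish")
    if "odor" not in scores.columns:
        raise ValueError("scores table must carry an 'odor' column")
    rng = np.random.default_rng(seed)
    results: list[DiscriminationResults] = []
    assignments: list[dict[str, str]] = []
    half = len(fish_ids) // 2
    for _ in range(n_assignments):
        perm = rng.permutation(len(fish_ids))
        assign = {
            fish_ids[j]: (odors[0] if rank < half else odors[1])
            for rank, j in enumerate(perm)
        }
        relabeled = scores.copy()
        plus_odor = relabeled["fish_id"].map(assign)
        relabeled["label"] = np.where(relabeled["odor"] == plus_odor, CS_PLUS, CS_MINUS)
        res = DiscriminationModel(relabeled, n_last=n_last).fit()
        results.append(res)
        assignments.append(assign)
    return UnpairedControlResult(results=results, assignments=assignments, seed=seed)
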