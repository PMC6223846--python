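"""The ζ-score transform and composite appetitive scores.

Raw parameter time series fluctuate between trials, so responses are
expressed relative to each trial's own pre-stimulus baseline and to the
fish's spontaneous variability:

1. subtract the mean value during the 30-s baseline window ending at odor
   onset from each trial's series;
2. average the series over all CS+ trials and over all CS- trials, and
   subtract the mean of these two class averages from every trial's
   series, centering the family of series on zero at each time point;
3. divide every series of the fish by the standard deviation (across all
   trials, both classes pooled, sample SD) of the time-averaged values in
   the reference window — a pre-baseline window of the same length as the
   response window — normalizing to stimulus-free trial-to-trial
   variability.

The resulting dimensionless ζ scores are related to z-scores but are
normalized to a fixed pre-stimulus window and cannot be read as calibrated
z-scores. Signs for Distance and Circling are inverted so positive ζ is
always more appetitive than the mean. Time-averaging ζ over the response
window yields one scalar per trial and parameter; the six scalars combine
into a composite score by Stouffer's rule (sum over √6), optionally with
auto-/cross-covariance weights that discount redundant parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScheduleError, TrialSchedule, WindowSpec
from .params import PARAMETERS, SIGN_INVERTED, ParameterPanel

__all__ = [
    "ZetaPanel",
    "zeta_transform",
    "trial_scores",
    "stouffer_composite",
    "weights_from_covariance",
    "weighted_composite",
    "cohort_covariance",
    "parameter_correlations",
]

N_PARAMS = len(PARAMETERS)


@dataclass
class ZetaPanel:
    """Per-fish ζ time series and response-window trial scalars."""

    fish_id: str
    labels: list[str]
    days: list[int]
    trial_index: list[int]
    rel_t: dict[str, np.ndarray] = field(default_factory=dict)
    zeta_series: dict[str, np.ndarray] = field(default_factory=dict)  # (n_trials, L)
    response_mask: dict[str, np.ndarray] = field(default_factory=dict)

    def trial_matrix(self) -> np.ndarray:
        """(n_trials, 6) response-window trial averages, parameter-ordered."""
        cols = [
            self.zeta_series[p][:, self.response_mask[p]].mean(axis=1) for p in PARAMETERS
        ]
        return np.column_stack(cols)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: fish_id, trial, day, label, parameter, zeta_trial."""
        mat = self.trial_matrix()
        rows = []
        for j, p in enumerate(PARAMETERS):
            rows.append(
                pd.DataFrame(
                    {
                        "fish_id": self.fish_id,
                        "trial": self.trial_index,
                        "day": self.days,
                        "label": self.labels,
                        "parameter": p,
                        "zeta_trial": mat[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _window_masks(rel_t: np.ndarray, windows: WindowSpec, tol: float):
    ref = (rel_t >= -windows.span_before_s - tol) & (rel_t < -windows.baseline_s - tol / 2)
    base = (rel_t >= -windows.baseline_s - tol / 2) & (rel_t < -tol / 2)
    resp = (rel_t >= -tol / 2) & (rel_t <= windows.response_s + tol)
    return ref, base, resp


def zeta_transform(
    panel: ParameterPanel,
    schedule: TrialSchedule,
    windows: WindowSpec | None = None,
    offset_s: float = 0.0,
) -> ZetaPanel:
    """Transform a parameter panel into per-trial ζ time series.

    ``offset_s`` shifts all three analysis windows relative to odor onset;
    the stimulus-free re-analysis uses ``offset_s = -(baseline + response)``
    so the "response" window lies 60-30 s before odor application.
    """
    windows = windows or WindowSpec()
    labels = schedule.labels
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"expected exactly two trial classes, got {classes}")
    counts = {c: labels.count(c) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError("need at least two trials per stimulus class")
    lab_arr = np.asarray(labels)

    out = ZetaPanel(
        fish_id=panel.fish_id,
        labels=list(labels),
        days=[tr.day for tr in schedule],
        trial_index=[tr.index for tr in schedule],
    )
    for name in PARAMETERS:
        t, v = panel.series[name]
        if len(t) < 2:
            raise ValueError(f"parameter {name} has too few samples")
        dt = float(t[1] - t[0])
        fs = 1.0 / dt
        L = int(round((windows.span_before_s + windows.response_s) * fs)) + 1
        mat = np.empty((len(schedule), L))
        rel_ref = None
        for i, tr in enumerate(schedule):
            start = tr.onset_s + offset_s - windows.span_before_s
            i0 = int(round((start - t[0]) * fs))
            if i0 < 0 or i0 + L > len(v):
                raise ScheduleError(
                    f"trial {tr.index} lacks coverage of the analysis windows "
                    f"(parameter {name}, offset {offset_s:+.0f} s)"
                )
            mat[i] = v[i0 : i0 + L]
            if rel_ref is None:
                rel_ref = t[i0 : i0 + L] - (tr.onset_s + offset_s)
        ref_m, base_m, resp_m = _window_masks(rel_ref, windows, tol=dt / 2)

        # (1) per-trial baseline subtraction
        mat -= mat[:, base_m].mean(axis=1, keepdims=True)
        # (2) subtract the mean of the two class-average series
        class_avgs = [mat[lab_arr == c].mean(axis=0) for c in classes]
        mat -= 0.5 * (class_avgs[0] + class_avgs[1])
        # (3) normalize to reference-window trial-to-trial variability
        ref_avgs = mat[:, ref_m].mean(axis=1)
        sd = float(np.std(ref_avgs, ddof=1))
        if sd <= 0.0 or not np.isfinite(sd):
            raise ValueError(
                f"zero trial-to-trial reference variability for parameter {name}"
            )
        mat /= sd
        if name in SIGN_INVERTED:
            mat = -mat
        out.rel_t[name] = rel_ref
        out.zeta_series[name] = mat
        out.response_mask[name] = resp_m
    return out


def trial_scores(zpanel: ZetaPanel) -> pd.DataFrame:
    """Response-window time average of ζ, one scalar per trial/parameter."""
    return zpanel.to_frame()


def stouffer_composite(scores) -> np.ndarray | float:
    """Combine the six parameter ζ scores: sum divided by √6.

    Accepts a length-6 vector (returns a float) or an (n, 6) matrix
    (returns length-n array).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.shape[-1] != N_PARAMS:
        raise ValueError(f"expected {N_PARAMS} parameter scores, got shape {arr.shape}")
    out = arr.sum(axis=-1) / np.sqrt(N_PARAMS)
    return float(out) if np.ndim(out) == 0 else out


def weights_from_covariance(cov: np.ndarray) -> np.ndarray:
    """Per-parameter weights: auto-covariance over the sum of auto- and
    cross-covariances, ``w_i = C_ii / sum_j C_ij``."""
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (N_PARAMS, N_PARAMS):
        raise ValueError(f"covariance must be {N_PARAMS}x{N_PARAMS}")
    row_sums = cov.sum(axis=1)
    if np.any(row_sums <= 0):
        bad = PARAMETERS[int(np.argmin(row_sums))]
        raise ValueError(f"degenerate covariance weighting (non-positive row sum for {bad})")
    return np.diag(cov) / row_sums


def weighted_composite(trial_score_matrix: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Covariance-weighted composite score per trial.

    ``(sum_i w_i ζ_i) / sqrt(sum_i w_i^2)``, which reduces exactly to the
    unweighted Stouffer composite when the covariance is diagonal with
    equal variances (all weights 1).
    """
    w = weights_from_covariance(cov)
    mat = np.atleast_2d(np.asarray(trial_score_matrix, dtype=float))
    if mat.shape[1] != N_PARAMS:
        raise ValueError(f"trial score matrix must have {N_PARAMS} columns")
    out = mat @ w / np.sqrt((w**2).sum())
    return out


def score_panel(
    panel: ParameterPanel,
    schedule: TrialSchedule,
    windows: WindowSpec | None = None,
    offset_s: float = 0.0,
    cov: np.ndarray | None = None,
) -> pd.DataFrame:
    """ζ-transform a parameter panel and reduce it to per-trial composites.

    Returns one row per trial with columns ``fish_id, trial, day, label,
    odor, zeta_comp`` (plus ``zeta_comp_weighted`` when a cohort covariance
    is supplied).
    """
    zpanel = zeta_transform(panel, schedule, windows, offset_s=offset_s)
    mat = zpanel.trial_matrix()
    df = pd.DataFrame(
        {
            "fish_id": zpanel.fish_id,
            "trial": zpanel.trial_index,
            "day": zpanel.days,
            "label": zpanel.labels,
            "odor": [tr.odor for tr in schedule],
            "zeta_comp": stouffer_composite(mat),
        }
    )
    if cov is not None:
        df["zeta_comp_weighted"] = weighted_composite(mat, cov)
    return df


def cohort_covariance(trial_matrices) -> np.ndarray:
    """Parameter covariance of trial scores pooled over fish.

    Each fish's (n_trials, 6) matrix is mean-centered per parameter before
    pooling, so between-fish offsets do not inflate the covariance.
    """
    centered = []
    for m in trial_matrices:
        m = np.asarray(m, dtype=float)
        centered.append(m - m.mean(axis=0, keepdims=True))
    stacked = np.vstack(centered)
    return np.cov(stacked, rowvar=False, ddof=1)


def parameter_correlations(trial_matrices) -> np.ndarray:
    """Mean trial-by-trial Pearson correlation matrix across fish.

    Correlations are computed between the trial-score series of each
    parameter pair within each fish and then averaged over fish; a fish
    with a zero-variance series is excluded from that pair's average.
    """
    acc = np.zeros((N_PARAMS, N_PARAMS))
    cnt = np.zeros((N_PARAMS, N_PARAMS))
    for m in trial_matrices:
        m = np.asarray(m, dtype=float)
        sd = m.std(axis=0)
        ok = sd > 0
        if ok.sum() < 2:
            continue
        c = np.corrcoef(m[:, ok], rowvar=False)
        idx = np.where(ok)[0]
        acc[np.ix_(idx, idx)] += c
        cnt[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    np.fill_diagonal(mean, 1.0)
    return mean
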