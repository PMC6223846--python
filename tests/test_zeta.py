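"""ζ transform against a hand-computed oracle, plus composite-score algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import zetafish as zf
from zetafish.config import CS_MINUS, CS_PLUS, TrialSchedule, WindowSpec
from zetafish.params import PARAMETERS, ParameterPanel
from zetafish.zeta import (
    cohort_covariance,
    parameter_correlations,
    score_panel,
    stouffer_composite,
    weighted_composite,
    weights_from_covariance,
    zeta_transform,
)

SQRT6 = np.sqrt(6.0)


def _sched(n_trials=4):
    assert n_trials % 2 == 0
    return TrialSchedule.alternating(
        n_days=1, trials_per_day_per_stimulus=n_trials // 2, iti_s=160.0, first_onset_s=160.0
    )


def _panel_from_windows(sched, ref, base, resp, fs=30.0):
    """Panel whose series take per-trial constants in the three windows."""
    T = sched.onsets[-1] + 120.0
    n = int(T * fs) + 1
    t = np.arange(n) / fs

    def fill(tv):
        v = np.zeros_like(tv)
        for i, tr in enumerate(sched):
            on = tr.onset_s
            v[(tv >= on - 60) & (tv < on - 30)] = ref[i]
            v[(tv >= on - 30) & (tv < on)] = base[i]
            v[(tv >= on) & (tv <= on + 30)] = resp[i]
        return v

    series = {}
    for p in PARAMETERS:
        if p == "Circling":
            tb = np.arange(int(T)) + 0.5
            series[p] = (tb, fill(tb))
        else:
            series[p] = (t, fill(t.copy()))
    return ParameterPanel("toy", series)


def _random_panel(sched, seed=0, fs=30.0):
    rng = np.random.default_rng(seed)
    T = sched.onsets[-1] + 120.0
    n = int(T * fs) + 1
    t = np.arange(n) / fs
    series = {}
    for p in PARAMETERS:
        if p == "Circling":
            tb = np.arange(int(T)) + 0.5
            series[p] = (tb, rng.normal(1.0, 0.5, size=len(tb)))
        else:
            series[p] = (t, rng.normal(2.0, 1.0, size=n))
    return ParameterPanel("toy", series)


def test_zeta_hand_computed_spreadsheet_oracle():
    """Four trials, responses {2,0,2,0}, references {1,-1,1,-1}: the three
    transform steps give ζ_trial = ±(2-1)/std([1,-1,1,-1]) = ±0.866."""
    sched = _sched(4)
    panel = _panel_from_windows(sched, ref=[1, -1, 1, -1], base=[0] * 4, resp=[2, 0, 2, 0])
    zp = zeta_transform(panel, sched, WindowSpec())
    mat = zp.trial_matrix()
    j = PARAMETERS.index("Speed")
    assert mat[:, j] == pytest.approx([0.866, -0.866, 0.866, -0.866], abs=1e-3)
    # sign inversion for Distance and Circling
    jd = PARAMETERS.index("Distance")
    assert mat[:, jd] == pytest.approx([-0.866, 0.866, -0.866, 0.866], abs=1e-3)


def test_zeta_identical_responses_center_to_zero():
    """Trials identical in baseline and response (reference varies) have
    ζ_trial exactly 0: the class-mean centering removes the shared signal."""
    sched = _sched(4)
    panel = _panel_from_windows(sched, ref=[1, -1, 2, -2], base=[0] * 4, resp=[3, 3, 3, 3])
    zp = zeta_transform(panel, sched, WindowSpec())
    assert np.allclose(zp.trial_matrix(), 0.0, atol=1e-12)


def test_zeta_degenerate_reference_variability_raises():
    sched = _sched(4)
    panel = _panel_from_windows(sched, ref=[0] * 4, base=[0] * 4, resp=[1, 0, 1, 0])
    with pytest.raises(ValueError, match="Speed"):
        zeta_transform(panel, sched, WindowSpec())


def test_zeta_label_swap_antisymmetry():
    sched = _sched(6)
    panel = _random_panel(sched, seed=3)
    swapped = sched.with_labels(
        [CS_MINUS if l == CS_PLUS else CS_PLUS for l in sched.labels]
    )
    m1 = zeta_transform(panel, sched, WindowSpec()).trial_matrix()
    m2 = zeta_transform(panel, swapped, WindowSpec()).trial_matrix()
    # the transform is symmetric in the two classes
    assert np.allclose(m1, m2, atol=1e-12)
    lab1 = np.array(sched.labels)
    lab2 = np.array(swapped.labels)
    d1 = m1[lab1 == CS_PLUS].mean(axis=0) - m1[lab1 == CS_MINUS].mean(axis=0)
    d2 = m2[lab2 == CS_PLUS].mean(axis=0) - m2[lab2 == CS_MINUS].mean(axis=0)
    assert np.allclose(d1, -d2, atol=1e-12)


def test_zeta_affine_rescaling_invariance():
    """Replacing a raw series s by a*s + b (a > 0) leaves ζ unchanged:
    baseline subtraction removes b, reference-SD normalization removes a."""
    sched = _sched(6)
    panel = _random_panel(sched, seed=7)
    t, v = panel.series["Zlevel"]
    panel2 = ParameterPanel("toy", dict(panel.series))
    panel2.series["Zlevel"] = (t, 3.7 * v - 11.0)
    z1 = zeta_transform(panel, sched, WindowSpec()).zeta_series["Zlevel"]
    z2 = zeta_transform(panel2, sched, WindowSpec()).zeta_series["Zlevel"]
    assert np.allclose(z1, z2, atol=1e-9)


def test_zeta_class_centering_machine_precision():
    sched = _sched(6)
    panel = _random_panel(sched, seed=11)
    zp = zeta_transform(panel, sched, WindowSpec())
    lab = np.array(zp.labels)
    for p in PARAMETERS:
        series = zp.zeta_series[p]
        center = 0.5 * (
            series[lab == CS_PLUS].mean(axis=0) + series[lab == CS_MINUS].mean(axis=0)
        )
        assert np.allclose(center, 0.0, atol=1e-10)
    mat = zp.trial_matrix()
    center = 0.5 * (mat[lab == CS_PLUS].mean(axis=0) + mat[lab == CS_MINUS].mean(axis=0))
    assert np.allclose(center, 0.0, atol=1e-10)


# ---------------------------------------------------------------- composites


def test_stouffer_analytic_anchors():
    assert stouffer_composite(np.zeros(6)) == 0.0
    assert stouffer_composite(np.ones(6)) == pytest.approx(SQRT6)
    # alternating +/-1 scores cancel: sum 0, composite 0
    assert stouffer_composite([1, -1, 1, -1, 1, -1]) == 0.0
    assert stouffer_composite([1, -1, 1, -1, 1, 1]) == pytest.approx(2.0 / SQRT6)
    with pytest.raises(ValueError):
        stouffer_composite([1.0, 2.0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-100, 100), min_size=6, max_size=6),
    st.lists(st.floats(-100, 100), min_size=6, max_size=6),
    st.floats(-5, 5),
    st.permutations(range(6)),
)
def test_stouffer_linear_and_permutation_invariant(a, b, c, perm):
    a, b = np.array(a), np.array(b)
    assert stouffer_composite(a + c * b) == pytest.approx(
        stouffer_composite(a) + c * stouffer_composite(b), rel=1e-9, abs=1e-9
    )
    assert stouffer_composite(a[list(perm)]) == pytest.approx(
        stouffer_composite(a), rel=1e-12, abs=1e-12
    )


def test_weighted_composite_identity_covariance_reduces_to_stouffer():
    rng = np.random.default_rng(1)
    mat = rng.normal(size=(20, 6))
    w = weighted_composite(mat, np.eye(6))
    assert np.allclose(w, stouffer_composite(mat), atol=1e-12)


def test_weighted_composite_redundant_pair_shares_weight():
    """Two perfectly correlated parameters jointly carry the weight of one
    independent parameter."""
    cov = np.eye(6)
    cov[0, 1] = cov[1, 0] = 1.0  # parameters 0 and 1 fully redundant
    w = weights_from_covariance(cov)
    assert w[0] == pytest.approx(0.5) and w[1] == pytest.approx(0.5)
    assert w[0] + w[1] == pytest.approx(w[2])


def test_weights_match_bruteforce_on_random_psd():
    rng = np.random.default_rng(5)
    A = rng.normal(size=(6, 6))
    cov = A @ A.T + 0.5 * np.eye(6)
    w = weights_from_covariance(cov)
    expected = [cov[i, i] / sum(cov[i, j] for j in range(6)) for i in range(6)]
    assert np.allclose(w, expected, atol=1e-12)
    mat = rng.normal(size=(7, 6))
    out = weighted_composite(mat, cov)
    brute = [sum(w[i] * mat[k, i] for i in range(6)) / np.sqrt(sum(wi**2 for wi in w))
             for k in range(7)]
    assert np.allclose(out, brute, atol=1e-10)


def test_degenerate_weight_row_rejected():
    cov = np.eye(6)
    cov[2] = cov[:, 2] = -1.0
    cov[2, 2] = 1.0
    with pytest.raises(ValueError, match="degenerate"):
        weights_from_covariance(cov)


# ---------------------------------------------------------------- correlations


def test_parameter_correlations_identical_and_anticorrelated():
    rng = np.random.default_rng(2)
    base = rng.normal(size=30)
    mat = np.column_stack([base, base, -base] + [rng.normal(size=30) for _ in range(3)])
    mean = parameter_correlations([mat, mat])
    assert mean[0, 1] == pytest.approx(1.0)
    assert mean[0, 2] == pytest.approx(-1.0)
    assert np.allclose(np.diag(mean), 1.0)


def test_parameter_correlations_null_near_zero():
    """Independent series, 62 fish x 36 trials: mean off-diagonal ~ 0."""
    rng = np.random.default_rng(9)
    mats = [rng.normal(size=(36, 6)) for _ in range(62)]
    mean = parameter_correlations(mats)
    off = mean[~np.eye(6, dtype=bool)]
    assert abs(off.mean()) < 0.05
    assert np.all(np.abs(off) < 0.1)


def test_zero_variance_series_excluded_not_fatal():
    rng = np.random.default_rng(3)
    m_ok = rng.normal(size=(20, 6))
    m_bad = m_ok.copy()
    m_bad[:, 0] = 5.0  # constant -> excluded from pairs involving param 0
    mean = parameter_correlations([m_ok, m_bad])
    ok_only = parameter_correlations([m_ok])
    assert mean[0, 1] == pytest.approx(ok_only[0, 1])


def test_cohort_covariance_centers_per_fish():
    rng = np.random.default_rng(8)
    m = rng.normal(size=(50, 6))
    shifted = m + 100.0  # between-fish offset must not inflate covariance
    c1 = cohort_covariance([m, m])
    c2 = cohort_covariance([m, shifted])
    assert np.allclose(c1, c2, atol=1e-9)


def test_score_panel_composite_matches_manual(config):
    sched = _sched(6)
    panel = _random_panel(sched, seed=13)
    df = score_panel(panel, sched, config.windows)
    zp = zeta_transform(panel, sched, config.windows)
    assert np.allclose(df["zeta_comp"].to_numpy(), stouffer_composite(zp.trial_matrix()))
    assert list(df["label"]) == sched.labels
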