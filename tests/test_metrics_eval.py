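"""Metrics: overlap scores, HD95 vs a brute-force oracle, stratification,
aggregation, paired statistics, and the efficiency profiler."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lcmamba import nn
from lcmamba.metrics_eval import (InputError, aggregate_stats, boundary_pixels,
                                  compare_paired, efficiency_profile,
                                  evaluate_cases, hd95, holm_adjust,
                                  overlap_metrics, size_class_of,
                                  stratify_lesions, summarize, wilcoxon_paired)


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------

def test_identity_masks_score_one():
    m = np.zeros((10, 10), dtype=int)
    m[2:6, 3:8] = 1
    r = overlap_metrics(m, m)
    for k in ("dice", "miou", "recall", "precision", "f2"):
        assert r[k] == 1.0


def test_disjoint_masks_score_zero():
    a = np.zeros((8, 8), dtype=int)
    b = np.zeros((8, 8), dtype=int)
    a[0:2, 0:2] = 1
    b[5:7, 5:7] = 1
    r = overlap_metrics(a, b)
    assert r["dice"] == r["recall"] == r["precision"] == r["f2"] == 0.0


def test_overlap_worked_example():
    """|P|=4, |G|=2, overlap 2: dice=2/3, recall=1, precision=0.5, f2=5/6."""
    p = np.zeros((4, 4), dtype=int)
    g = np.zeros((4, 4), dtype=int)
    p[0, :4] = 1
    g[0, :2] = 1
    r = overlap_metrics(p, g)
    assert r["dice"] == pytest.approx(2 * 2 / 6)
    assert r["recall"] == 1.0
    assert r["precision"] == 0.5
    assert r["f2"] == pytest.approx(5 * 0.5 * 1 / (4 * 0.5 + 1))


def test_empty_conventions():
    e = np.zeros((5, 5), dtype=int)
    f = np.zeros((5, 5), dtype=int)
    f[2, 2] = 1
    both = overlap_metrics(e, e)
    assert both["dice"] == both["miou"] == 1.0
    assert overlap_metrics(e, f)["dice"] == 0.0
    assert overlap_metrics(f, e)["dice"] == 0.0
    assert hd95(e, e) == 0.0
    assert hd95(e, f, 2.0) == pytest.approx(np.hypot(5, 5) * 2.0)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(seed=st.integers(0, 10_000))
def test_dice_f1_iou_identity(seed):
    """dice = 2*iou/(1+iou) for foreground IoU, on random masks."""
    rng = np.random.default_rng(seed)
    p = (rng.random((9, 9)) > 0.5).astype(int)
    g = (rng.random((9, 9)) > 0.5).astype(int)
    r = overlap_metrics(p, g)
    assert r["dice"] == pytest.approx(2 * r["iou_fg"] / (1 + r["iou_fg"]), abs=1e-12)


def test_f2_equals_precision_when_balanced():
    """F2 collapses to precision when precision == recall."""
    p = np.zeros((6, 6), dtype=int)
    g = np.zeros((6, 6), dtype=int)
    p[0, :3] = 1   # |P| = 3
    g[0, 1:4] = 1  # |G| = 3, overlap 2 -> prec = rec = 2/3
    r = overlap_metrics(p, g)
    assert r["precision"] == pytest.approx(r["recall"])
    assert r["f2"] == pytest.approx(r["precision"])


def test_shape_mismatch_rejected():
    with pytest.raises(InputError):
        overlap_metrics(np.zeros((3, 3), dtype=int), np.zeros((4, 4), dtype=int))


# ---------------------------------------------------------------------------
# HD95
# ---------------------------------------------------------------------------

def brute_force_hd(pred, gt, spacing, percentile=95.0):
    """All-pairs boundary distance oracle (O(n^2))."""
    def boundary(m):
        pts = []
        H, W = m.shape
        for i in range(H):
            for j in range(W):
                if not m[i, j]:
                    continue
                nb = [m[a, b] for a in (i - 1, i, i + 1) for b in (j - 1, j, j + 1)
                      if 0 <= a < H and 0 <= b < W]
                if (not all(nb)) or i in (0, H - 1) or j in (0, W - 1):
                    pts.append((i, j))
        return np.array(pts, dtype=float)

    bp, bg = boundary(pred), boundary(gt)
    d_pg = [min(np.hypot(*(p - q)) for q in bg) for p in bp]
    d_gp = [min(np.hypot(*(p - q)) for q in bp) for p in bg]
    return float(np.percentile(np.array(d_pg + d_gp) * spacing, percentile))


def test_hd95_identity_zero():
    m = np.zeros((9, 9), dtype=int)
    m[3:6, 3:6] = 1
    assert hd95(m, m) == 0.0


def test_hd95_two_points_seven_apart():
    a = np.zeros((12, 12), dtype=int)
    b = np.zeros((12, 12), dtype=int)
    a[5, 2] = 1
    b[5, 9] = 1
    assert hd95(a, b, 1.0) == pytest.approx(7.0)


@pytest.mark.parametrize("seed", range(4))
def test_hd95_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(40 + seed)
    p = np.zeros((14, 14), dtype=int)
    g = np.zeros((14, 14), dtype=int)
    # random rectangles keep boundary sets small (<200 pixels)
    r = rng.integers(1, 6, 8)
    p[r[0]:r[0] + r[1] + 1, r[2]:r[2] + r[3] + 1] = 1
    g[r[4]:r[4] + r[5] + 1, r[6]:r[6] + r[7] + 1] = 1
    assert hd95(p, g, 0.7) == pytest.approx(brute_force_hd(p, g, 0.7), abs=1e-9)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(seed=st.integers(0, 9999))
def test_hd95_not_exceeding_max_hausdorff(seed):
    rng = np.random.default_rng(seed)
    p = (rng.random((10, 10)) > 0.6).astype(int)
    g = (rng.random((10, 10)) > 0.6).astype(int)
    if p.any() and g.any():
        assert hd95(p, g) <= hd95(p, g, percentile=100.0) + 1e-12


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def test_stratify_empty():
    assert stratify_lesions(np.zeros((6, 6), dtype=int), 1.0) == []


def test_stratify_314px_at_half_mm_is_small():
    """A 314-px component at 0.5 mm spacing: d = 2*sqrt(314/pi)*0.5 ~ 10 mm."""
    mask = np.zeros((40, 40), dtype=int)
    yy, xx = np.mgrid[0:40, 0:40]
    mask[((yy - 20) ** 2 + (xx - 20) ** 2) <= 100.2] = 1  # 317 px
    for i, j in np.argwhere(mask)[:3]:                    # trim to 314
        mask[i, j] = 0
    assert mask.sum() == 314
    recs = stratify_lesions(mask, 0.5)
    assert len(recs) == 1
    expected_d = 2 * np.sqrt(314 / np.pi) * 0.5
    assert recs[0].equiv_diameter_mm == pytest.approx(expected_d)
    assert abs(expected_d - 10.0) < 0.05
    assert recs[0].size_class == "Small"


def test_stratify_5000px_is_large():
    """5000 px at 1 mm: d ~ 79.8 mm -> Large."""
    mask = np.zeros((100, 100), dtype=int)
    yy, xx = np.mgrid[0:100, 0:100]
    mask[((yy - 50) ** 2 + (xx - 50) ** 2) <= (39.9) ** 2] = 1
    recs = stratify_lesions(mask, 1.0)
    assert len(recs) == 1
    assert recs[0].size_class == "Large"
    d = 2 * np.sqrt(recs[0].area_px / np.pi)
    assert recs[0].equiv_diameter_mm == pytest.approx(d)


def test_size_classes_partition_diameter_axis():
    """Every diameter lands in exactly one stratum; cuts at 20/50 mm."""
    for d in [0.1, 19.999, 20.0, 35.0, 50.0, 50.001, 300.0]:
        assert size_class_of(d) in ("Small", "Medium", "Large")
    assert size_class_of(19.999) == "Small"
    assert size_class_of(20.0) == "Medium"
    assert size_class_of(50.0) == "Medium"
    assert size_class_of(50.001) == "Large"


def test_stratify_uses_8_connectivity():
    m = np.zeros((6, 6), dtype=int)
    m[0, 0] = m[1, 1] = 1  # diagonal neighbours: one component
    assert len(stratify_lesions(m, 1.0)) == 1


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_aggregate_constant_sample():
    r = aggregate_stats([0.9, 0.9, 0.9])
    assert r["mean"] == 0.9 and r["sd"] == 0.0
    assert r["ci95_low"] == r["ci95_high"] == 0.9


def test_aggregate_two_point_sample():
    r = aggregate_stats([0.8, 1.0])
    assert r["mean"] == pytest.approx(0.9)
    assert r["sd"] == pytest.approx(np.sqrt(((0.8 - 0.9) ** 2 + (1.0 - 0.9) ** 2)))
    assert r["sd"] == pytest.approx(0.1414, abs=1e-4)


def test_aggregate_single_and_empty():
    r = aggregate_stats([0.5])
    assert r["sd"] == 0.0 and r["ci95_low"] == r["ci95_high"] == 0.5
    with pytest.raises(InputError):
        aggregate_stats([])


def test_t_ci_coverage_simulation():
    """The t-interval covers the true mean ~95% of the time (1000 reps)."""
    rng = np.random.default_rng(123)
    mu = 0.7
    hits = 0
    for _ in range(1000):
        x = rng.normal(mu, 0.1, size=10)
        r = aggregate_stats(x)
        hits += r["ci95_low"] <= mu <= r["ci95_high"]
    assert abs(hits / 1000 - 0.95) < 0.025


# ---------------------------------------------------------------------------
# paired statistics
# ---------------------------------------------------------------------------

def test_wilcoxon_identical_scores():
    assert wilcoxon_paired([0.8, 0.9, 0.7], [0.8, 0.9, 0.7]) == 1.0


def test_wilcoxon_uniform_sign_exact_p():
    """n = 10 all-positive differences: exact two-sided p = 2/2^10."""
    a = np.linspace(0.8, 0.9, 10)
    b = a - np.linspace(0.01, 0.02, 10)
    assert wilcoxon_paired(a, b) == pytest.approx(2 / 2**10, rel=1e-9)


def test_holm_adjustment_worked_example():
    np.testing.assert_allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])


def test_holm_monotone_and_bounded():
    adj = holm_adjust([0.001, 0.02, 0.04, 0.5])
    assert np.all(np.diff(adj[np.argsort([0.001, 0.02, 0.04, 0.5])]) >= 0)
    assert np.all(adj <= 1.0)


def test_compare_paired_table():
    rng = np.random.default_rng(0)
    a = rng.normal(0.9, 0.02, 15)
    df = compare_paired([
        ("self", a, a.copy()),
        ("shifted", a, a - 0.05),
    ])
    assert df.loc[df.comparison == "self", "p_raw"].item() == 1.0
    assert df.loc[df.comparison == "shifted", "p_holm"].item() < 0.05


# ---------------------------------------------------------------------------
# case-level reporting
# ---------------------------------------------------------------------------

def test_evaluate_cases_and_reaggregation(tmp_path):
    """Summary aggregates equal a recomputation from the per-case rows."""
    rng = np.random.default_rng(7)
    gts, preds = [], []
    for _ in range(6):
        g = np.zeros((32, 32), dtype=int)
        cy, cx, r = rng.integers(8, 24), rng.integers(8, 24), rng.integers(3, 6)
        yy, xx = np.mgrid[0:32, 0:32]
        g[(yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2] = 1
        p = np.roll(g, rng.integers(0, 2), axis=0)
        gts.append(g)
        preds.append(p)
    per_case = evaluate_cases(preds, gts, [1.0] * 6)
    summary = summarize(per_case)
    assert summary["aggregate"]["dice"]["mean"] == pytest.approx(
        per_case["dice"].mean())
    # round-trip through CSV
    csv, js = tmp_path / "m.csv", tmp_path / "m.json"
    from lcmamba.metrics_eval import write_report
    write_report(per_case, summary, csv, js)
    loaded = pd.read_csv(csv)
    assert loaded["dice"].mean() == pytest.approx(summary["aggregate"]["dice"]["mean"])


# ---------------------------------------------------------------------------
# efficiency profiling
# ---------------------------------------------------------------------------

def test_single_conv_param_count_hand_oracle():
    """3x3 conv, 3 -> 8 channels with bias: 3*3*3*8 + 8 = 224 parameters."""
    conv = nn.Conv2d(3, 8, 3)
    assert conv.num_params() == 224


def test_conv_flops_double_with_height():
    conv = nn.Conv2d(3, 8, 3)
    _, m1 = conv.profile((1, 3, 32, 32))
    _, m2 = conv.profile((1, 3, 64, 32))
    assert m2 == 2 * m1


def test_efficiency_report_positive():
    from lcmamba.model import build_model
    rep = efficiency_profile(build_model("nano"), (64, 64))
    assert rep.params_millions > 0 and rep.flops_giga > 0
    assert rep.convention == "1 MAC = 1 FLOP"
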