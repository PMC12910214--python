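"""Evaluation suite: overlap metrics, HD95, lesion-size stratification,
aggregation with confidence intervals, paired significance testing, and the
parameter/FLOP efficiency profiler.

Conventions (stated in every written report):

* empty prediction AND empty ground truth -> dice = miou = 1, hd95 = 0;
  exactly one empty -> dice = 0 and hd95 = image diagonal x spacing;
* mIoU averages foreground and background IoU (foreground-only IoU is also
  exported);
* boundary pixels are mask XOR its one-pixel erosion, distances from the
  exact Euclidean distance transform, both directions pooled before the
  95th percentile;
* lesion strata by equivalent circular diameter d = 2*sqrt(area/pi)*spacing:
  Small d < 20 mm, Medium 20 <= d <= 50 mm, Large d > 50 mm;
* CIs are Student-t on per-case scores (bootstrap percentile optional);
* 1 multiply-accumulate counted as 1 FLOP.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("lcmamba")

_STRUCT8 = np.ones((3, 3), dtype=bool)

METRIC_NAMES = ("dice", "miou", "iou_fg", "recall", "precision", "f2", "hd95_mm")

CONVENTIONS = {
    "empty_empty": "dice=miou=1, hd95=0",
    "one_empty": "dice=0, hd95=diagonal*spacing",
    "miou": "mean of foreground and background IoU",
    "hd95_boundary": "mask XOR 1-px erosion; exact EDT; directions pooled",
    "strata_mm": "Small<20, Medium[20,50], Large>50",
    "ci": "Student-t on per-case scores",
    "flops": "1 MAC = 1 FLOP",
}


class InputError(ValueError):
    pass


def _binarize(m: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(m)
    if not np.isin(a, (0, 1)).all():
        raise InputError(f"{name} must be binary")
    return a.astype(bool)


# ---------------------------------------------------------------------------
# Overlap metrics
# ---------------------------------------------------------------------------

def overlap_metrics(pred: np.ndarray, gt: np.ndarray) -> dict[str, float]:
    """Dice, mIoU (fg+bg mean), foreground IoU, recall, precision, F2."""
    p = _binarize(pred, "pred")
    g = _binarize(gt, "gt")
    if p.shape != g.shape:
        raise InputError("pred and gt shapes differ")
    tp = float(np.sum(p & g))
    fp = float(np.sum(p & ~g))
    fn = float(np.sum(~p & g))
    tn = float(np.sum(~p & ~g))

    if tp + fp + fn == 0:  # both empty
        return {"dice": 1.0, "miou": 1.0, "iou_fg": 1.0, "recall": 1.0,
                "precision": 1.0, "f2": 1.0}
    dice = 2 * tp / (2 * tp + fp + fn)
    iou_fg = tp / (tp + fp + fn)
    iou_bg = tn / (tn + fp + fn) if (tn + fp + fn) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f2 = (5 * precision * recall / (4 * precision + recall)
          if (precision + recall) else 0.0)
    return {"dice": dice, "miou": 0.5 * (iou_fg + iou_bg), "iou_fg": iou_fg,
            "recall": recall, "precision": precision, "f2": f2}


# ---------------------------------------------------------------------------
# HD95
# ---------------------------------------------------------------------------

def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Boolean boundary: mask XOR its one-pixel erosion."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.zeros_like(m)
    return m ^ ndimage.binary_erosion(m, structure=_STRUCT8)


def hausdorff_distances(pred: np.ndarray, gt: np.ndarray,
                        spacing_mm: float = 1.0) -> np.ndarray:
    """Pooled boundary-to-boundary nearest distances (both directions), mm."""
    bp, bg = boundary_pixels(pred), boundary_pixels(gt)
    dt_g = ndimage.distance_transform_edt(~bg)
    dt_p = ndimage.distance_transform_edt(~bp)
    return np.concatenate([dt_g[bp], dt_p[bg]]) * spacing_mm


def hd95(pred: np.ndarray, gt: np.ndarray, spacing_mm: float = 1.0,
         percentile: float = 95.0) -> float:
    """95th percentile of the pooled symmetric boundary distances, in mm."""
    if spacing_mm <= 0:
        raise InputError("spacing must be positive")
    p = _binarize(pred, "pred")
    g = _binarize(gt, "gt")
    if p.shape != g.shape:
        raise InputError("pred and gt shapes differ")
    if not p.any() and not g.any():
        return 0.0
    if p.any() != g.any():
        return float(np.hypot(*p.shape) * spacing_mm)
    d = hausdorff_distances(p, g, spacing_mm)
    return float(np.percentile(d, percentile))


# ---------------------------------------------------------------------------
# Lesion-size stratification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionRecord:
    component_id: int
    area_px: int
    equiv_diameter_mm: float
    size_class: str  # "Small" | "Medium" | "Large"


def size_class_of(diameter_mm: float) -> str:
    if diameter_mm < 20.0:
        return "Small"
    if diameter_mm <= 50.0:
        return "Medium"
    return "Large"


def stratify_lesions(gt: np.ndarray, spacing_mm: float) -> list[LesionRecord]:
    """8-connected components with equivalent circular diameter and stratum."""
    if spacing_mm <= 0:
        raise InputError("spacing must be positive")
    g = _binarize(gt, "gt")
    labels, n = ndimage.label(g, structure=_STRUCT8)
    records = []
    for cid in range(1, n + 1):
        area = int(np.sum(labels == cid))
        d = 2.0 * np.sqrt(area / np.pi) * spacing_mm
        records.append(LesionRecord(cid, area, float(d), size_class_of(d)))
    return records


# ---------------------------------------------------------------------------
# Aggregation and paired testing
# ---------------------------------------------------------------------------

def aggregate_stats(scores, method: str = "t", n_boot: int = 2000,
                    seed: int = 0) -> dict[str, float]:
    """Mean, sample SD (n-1) and a 95% CI over per-case scores.

    ``method="t"`` uses mean +- t_{0.975,n-1} * SD/sqrt(n); ``"bootstrap"``
    uses the percentile bootstrap.  n = 1 gives SD 0 and a degenerate CI.
    """
    x = np.asarray(list(scores), dtype=float)
    if x.size == 0:
        raise InputError("empty score list")
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if n > 1 else 0.0
    if n == 1 or sd == 0.0:
        lo = hi = mean
    elif method == "t":
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        lo, hi = mean - half, mean + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = rng.choice(x, size=(n_boot, n), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return {"mean": mean, "sd": sd, "ci95_low": float(lo), "ci95_high": float(hi),
            "n": n}


def wilcoxon_paired(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value; zero differences dropped."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError("paired score lists must have equal length")
    d = a - b
    if np.all(d == 0):
        logger.info("wilcoxon: all paired differences are zero; p = 1")
        return 1.0
    return float(stats.wilcoxon(a, b, zero_method="wilcox",
                                alternative="two-sided", method="auto").pvalue)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(list(pvalues), dtype=float)
    return multipletests(p, method="holm")[1]


def compare_paired(families: list[tuple[str, np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Paired Wilcoxon per (label, scores_a, scores_b) with Holm adjustment."""
    rows = [(label, wilcoxon_paired(a, b)) for label, a, b in families]
    raw = [r[1] for r in rows]
    adj = holm_adjust(raw)
    return pd.DataFrame({
        "comparison": [r[0] for r in rows],
        "p_raw": raw,
        "p_holm": adj,
        "significant": adj < 0.05,
    })


# ---------------------------------------------------------------------------
# Case-level reporting
# ---------------------------------------------------------------------------

def evaluate_cases(preds, gts, spacings) -> pd.DataFrame:
    """Per-case metric table: one row per case, one column per metric.

    Each case also carries the size class of its largest ground-truth lesion
    (or "none" when the mask is empty)."""
    preds, gts = list(preds), list(gts)
    spacings = list(spacings)
    if not (len(preds) == len(gts) == len(spacings)):
        raise InputError("preds, gts and spacings must have equal length")
    rows = []
    for i, (p, g, s) in enumerate(zip(preds, gts, spacings)):
        m = overlap_metrics(p, g)
        m["hd95_mm"] = hd95(p, g, s)
        lesions = stratify_lesions(g, s)
        m["size_class"] = (max(lesions, key=lambda r: r.area_px).size_class
                           if lesions else "none")
        m["case"] = i
        rows.append(m)
    return pd.DataFrame(rows).set_index("case")


def summarize(per_case: pd.DataFrame, ci_method: str = "t") -> dict:
    """Aggregate a per-case table into mean/SD/CI overall and per stratum."""
    out = {"aggregate": {}, "strata": {}, "conventions": CONVENTIONS}
    for m in METRIC_NAMES:
        if m in per_case:
            out["aggregate"][m] = aggregate_stats(per_case[m], method=ci_method)
    for cls, sub in per_case.groupby("size_class"):
        out["strata"][cls] = {
            m: aggregate_stats(sub[m], method=ci_method)
            for m in METRIC_NAMES if m in sub
        }
    return out


def write_report(per_case: pd.DataFrame, summary: dict, csv_path, json_path) -> None:
    per_case.to_csv(csv_path)
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# Efficiency profiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EfficiencyReport:
    params_millions: float
    flops_giga: float
    input_size: tuple[int, int]
    convention: str = "1 MAC = 1 FLOP"

    def to_dict(self) -> dict:
        return asdict(self)


def efficiency_profile(model, input_size: tuple[int, int] = (256, 256)) -> EfficiencyReport:
    """Trainable parameter count and forward MAC count at batch size 1."""
    H, W = input_size
    params, macs = model.profile((1, 3, H, W))
    return EfficiencyReport(params_millions=params / 1e6,
                            flops_giga=macs / 1e9,
                            input_size=(H, W))
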