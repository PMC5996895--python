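"""Segmentation scoring and the cross-validated evaluation protocol.

Provides the Dice coefficient, lesion-volume agreement (standard deviation
of predicted-minus-expert volume residuals), the per-patient optimal
two-threshold baseline (the best possible segmentation obtainable from an
intensity band on a single image, an upper bound for threshold-based
methods), outer leave-one-out cross-validation of the segmenter, and the
paired Wilcoxon signed-rank comparison between methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats

from .preprocess import PreprocessConfig, build_feature_table, preprocess_case
from .segmenter import LesionSegmenter
from .volumes import PatientCase, Volume

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "dice",
    "dice_from_counts",
    "volume_ml",
    "residual_sd",
    "BandResult",
    "optimal_two_threshold_dice",
    "wilcoxon_signed_rank",
    "run_loocv",
    "LoocvResult",
    "summarize_records",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(
    pred: Volume | np.ndarray, truth: Volume | np.ndarray, mask: np.ndarray | None = None
) -> ConfusionCounts:
    p = (pred.data if isinstance(pred, Volume) else pred).astype(bool)
    t = (truth.data if isinstance(truth, Volume) else truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError("grid mismatch between prediction and truth")
    if mask is not None:
        p, t = p[mask], t[mask]
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def dice_from_counts(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:  # both masks empty
        return 1.0
    return 2.0 * c.tp / denom


def dice(a: Volume | np.ndarray, b: Volume | np.ndarray) -> float:
    """Dice overlap 2TP/(2TP+FP+FN); 1.0 when both masks are empty."""
    return dice_from_counts(confusion_counts(a, b))


def volume_ml(mask: Volume) -> float:
    """Mask volume in millilitres (voxel count x voxel volume / 1000)."""
    return float(np.count_nonzero(mask.data) * mask.voxel_volume_mm3 / 1000.0)


def residual_sd(predicted_ml, expert_ml) -> float:
    """Sample standard deviation (n-1) of predicted-minus-expert volumes."""
    r = np.asarray(predicted_ml, dtype=float) - np.asarray(expert_ml, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 records")
    return float(np.std(r, ddof=1))


class BandResult(NamedTuple):
    lo: float
    hi: float
    dice: float


def optimal_two_threshold_dice(
    v: Volume,
    expert: Volume,
    brain: Volume,
    *,
    max_candidates: int | None = None,
) -> BandResult:
    """Per-patient best intensity band lo <= v <= hi by Dice.

    Candidate thresholds are the observed distinct in-brain values (exact
    optimum); the returned ``lo``/``hi`` are ``-inf``/``+inf`` when the
    band is unbounded on that side.  Ties favor the widest band (most
    candidate values included), then the smallest ``lo``.  With
    ``max_candidates`` the distinct values are subsampled to a quantile
    grid (approximation for large volumes).
    """
    brain_mask = brain.data.astype(bool)
    vals = np.asarray(v.data)[brain_mask].astype(np.float64)
    labels = np.asarray(expert.data)[brain_mask].astype(bool)
    n_expert = int(labels.sum())
    if n_expert == 0:
        raise ValueError("expert mask is empty")
    order = np.argsort(vals, kind="stable")
    vs = vals[order]
    ys = labels[order]
    # group equal values
    boundaries = np.nonzero(np.diff(vs) > 0)[0]
    ends = np.concatenate([boundaries, [vs.size - 1]])  # last index of each group
    distinct = vs[ends]
    if max_candidates is not None and distinct.size > max_candidates:
        qs = np.linspace(0, 1, max_candidates)
        grid = np.quantile(distinct, qs)
        keep = np.searchsorted(distinct, grid, side="left")
        keep = np.unique(np.clip(keep, 0, distinct.size - 1))
        ends = ends[keep]
        distinct = distinct[keep]
    ccnt = ends + 1.0  # cumulative voxel count up to each group end
    cpos = np.cumsum(ys)[ends].astype(np.float64)
    m = distinct.size

    best = (-1.0, -1, -1)  # (dice, width, -lo_index) ordering handled manually
    best_ij = (0, 0)
    for i in range(m):
        lo_cnt = ccnt[i - 1] if i > 0 else 0.0
        lo_pos = cpos[i - 1] if i > 0 else 0.0
        inband = ccnt[i:] - lo_cnt
        tp = cpos[i:] - lo_pos
        d = 2.0 * tp / (n_expert + inband)
        jr = d.size - 1 - int(np.argmax(d[::-1]))  # last argmax -> widest band
        cand = (float(d[jr]), jr)  # width = jr (j - i in relative terms: jr)
        j_abs = i + jr
        width = j_abs - i
        if (cand[0] > best[0]) or (cand[0] == best[0] and width > best[1]):
            best = (cand[0], width, i)
            best_ij = (i, j_abs)
    i, j = best_ij
    lo = -np.inf if i == 0 else float(distinct[i])
    hi = np.inf if j == m - 1 else float(distinct[j])
    return BandResult(lo=lo, hi=hi, dice=float(best[0]))


def band_mask(v: Volume, brain: Volume, lo: float, hi: float) -> Volume:
    data = (v.data >= lo) & (v.data <= hi) & brain.data.astype(bool)
    return v.with_data(data.astype(np.uint8))


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (statistic, p).

    Uses the exact null distribution for small samples without ties/zeros
    and the tie-corrected normal approximation otherwise (scipy's "auto").
    All-zero differences yield p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if np.allclose(a, b):
        return 0.0, 1.0
    res = scipy.stats.wilcoxon(a, b, zero_method="wilcox", method="auto")
    return float(res.statistic), float(res.pvalue)


# --- leave-one-out cross-validation -----------------------------------------

METHODS = ("atlas", "threshold_dwi", "threshold_adc")


@dataclass
class LoocvResult:
    records: pd.DataFrame
    summary: dict

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def run_loocv(
    cases: list[PatientCase],
    segmenter: LesionSegmenter | None = None,
    *,
    band_max_candidates: int | None = None,
) -> LoocvResult:
    """Outer leave-one-out evaluation of the segmenter and baselines.

    For every held-out patient a segmenter is fitted on the remaining
    cases (including its inner depth selection), applied to the held-out
    case, and scored; the per-patient optimal two-threshold baselines on
    normalized DWI and on ADC are computed on the same case.  No voxel of
    the held-out patient influences its own model: per-case preprocessing
    uses only that case's own volumes, so feature maps are shared across
    folds without leakage.
    """
    if len(cases) < 4:
        raise ValueError("outer LOOCV requires at least 4 cases")
    for c in cases:
        if c.expert_mask is None:
            raise ValueError(f"case {c.patient_id} has no expert mask")
    seg = segmenter or LesionSegmenter()
    pcfg = seg.preprocess_config()
    features = {c.patient_id: preprocess_case(c, pcfg) for c in cases}
    table = build_feature_table(cases, pcfg, features=features)
    tree_cache: dict = {}

    records = []
    chosen_depths = {}
    for case in cases:
        pid = case.patient_id
        fold = LesionSegmenter(**seg.get_params())
        fold._fit_table(
            table[table["patient_id"] != pid].reset_index(drop=True),
            tree_cache=tree_cache,
        )
        chosen_depths[pid] = fold.depth_
        res = fold.predict(case, features=features[pid])
        expert_ml = volume_ml(case.expert_mask)
        records.append(
            {
                "patient_id": pid,
                "method": "atlas",
                "dice": res.dice,
                "predicted_volume_ml": res.volume_ml,
                "expert_volume_ml": expert_ml,
                "detail": f"depth={fold.depth_}",
            }
        )
        for channel, method in (("dwi_norm", "threshold_dwi"), ("adc", "threshold_adc")):
            band = optimal_two_threshold_dice(
                features[pid][channel],
                case.expert_mask,
                case.brain_mask,
                max_candidates=band_max_candidates,
            )
            bm = band_mask(features[pid][channel], case.brain_mask, band.lo, band.hi)
            records.append(
                {
                    "patient_id": pid,
                    "method": method,
                    "dice": band.dice,
                    "predicted_volume_ml": volume_ml(bm),
                    "expert_volume_ml": expert_ml,
                    "detail": f"lo={band.lo:.6g},hi={band.hi:.6g}",
                }
            )
    df = pd.DataFrame(records)
    summary = summarize_records(df)
    summary["chosen_depths"] = chosen_depths
    return LoocvResult(records=df, summary=summary)


def summarize_records(df: pd.DataFrame) -> dict:
    """Medians, interquartile ranges, residual SDs and paired Wilcoxon
    comparisons of the evaluated methods."""
    summary: dict = {"n_patients": int(df["patient_id"].nunique()), "methods": {}}
    for method, grp in df.groupby("method"):
        d = grp["dice"].to_numpy(dtype=float)
        summary["methods"][method] = {
            "median_dice": float(np.median(d)),
            "dice_iqr": [float(np.percentile(d, 25)), float(np.percentile(d, 75))],
            "residual_sd_ml": residual_sd(
                grp["predicted_volume_ml"], grp["expert_volume_ml"]
            )
            if len(grp) >= 2
            else None,
        }
    summary["wilcoxon"] = {}
    pivot = df.pivot(index="patient_id", columns="method", values="dice")
    for other in pivot.columns:
        if other == "atlas" or "atlas" not in pivot.columns:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = wilcoxon_signed_rank(pivot["atlas"], pivot[other])
        summary["wilcoxon"][f"atlas_vs_{other}"] = {"statistic": stat, "p_value": p}
    return summary
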