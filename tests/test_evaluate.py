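import numpy as np
import pytest

from strokeseg import (
    LesionSegmenter,
    Volume,
    dice,
    optimal_two_threshold_dice,
    residual_sd,
    run_loocv,
    volume_ml,
    wilcoxon_signed_rank,
)
from strokeseg.evaluate import (
    ConfusionCounts,
    band_mask,
    confusion_counts,
    dice_from_counts,
    summarize_records,
)
from strokeseg.volumes import PatientCase


def _vol(data, spacing=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(data), np.diag(list(spacing) + [1.0]))


def brute_force_band(v, expert, brain):
    """Independent O(m^2) search over all candidate (lo, hi) pairs with the
    same tie rules (widest band, then smallest lo)."""
    b = brain.data.astype(bool)
    vals = v.data[b]
    lab = expert.data[b].astype(bool)
    distinct = np.unique(vals)
    cands_lo = np.concatenate([[-np.inf], distinct])
    best = None
    for i, lo in enumerate(cands_lo):
        for j, hi in enumerate(np.concatenate([distinct, [np.inf]])):
            if np.isfinite(lo) and np.isfinite(hi) and hi < lo:
                continue
            band = (vals >= lo) & (vals <= hi)
            tp = int((band & lab).sum())
            d = 2 * tp / (lab.sum() + band.sum()) if (lab.sum() + band.sum()) else 1.0
            width = int(band.sum())  # wider band includes more voxels
            key = (d, width, -lo if np.isfinite(lo) else np.inf)
            if best is None or d > best[0] + 1e-15 or (
                abs(d - best[0]) <= 1e-15 and width > best[1]
            ):
                best = (d, width, lo, hi)
    return best[0]


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((6, 6, 6), dtype=np.uint8)
        m[2:4, 2:4, 2:4] = 1
        assert dice(_vol(m), _vol(m)) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 6), dtype=np.uint8)
        b = np.zeros_like(a)
        a[0, 0, 0] = 1
        b[5, 5, 5] = 1
        assert dice(_vol(a), _vol(b)) == 0.0

    def test_worked_counts(self):
        assert dice_from_counts(ConfusionCounts(tp=5, fp=3, fn=2, tn=100)) == (
            pytest.approx(2 / 3)
        )

    def test_empty_conventions(self):
        z = _vol(np.zeros((4, 4, 4), dtype=np.uint8))
        one = _vol(np.eye(4, dtype=np.uint8)[..., None] * np.ones((1, 1, 4), dtype=np.uint8))
        assert dice(z, z) == 1.0
        assert dice(z, one) == 0.0

    def test_symmetry(self, rng):
        a = _vol((rng.uniform(size=(5, 5, 5)) > 0.5).astype(np.uint8))
        b = _vol((rng.uniform(size=(5, 5, 5)) > 0.5).astype(np.uint8))
        assert dice(a, b) == dice(b, a)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice(_vol(np.zeros((4, 4, 4))), _vol(np.zeros((4, 4, 5))))

    def test_confusion_totals(self, rng):
        a = (rng.uniform(size=(6, 6, 6)) > 0.5).astype(np.uint8)
        b = (rng.uniform(size=(6, 6, 6)) > 0.5).astype(np.uint8)
        c = confusion_counts(_vol(a), _vol(b))
        assert c.total == a.size


class TestVolumes:
    def test_unit_voxels(self):
        m = np.zeros((10, 10, 10), dtype=np.uint8)
        m.ravel()[:1000] = 1
        assert volume_ml(_vol(m)) == pytest.approx(1.0)

    def test_empty(self):
        assert volume_ml(_vol(np.zeros((5, 5, 5), dtype=np.uint8))) == 0.0

    def test_anisotropic_spacing(self):
        m = np.zeros((10, 10, 10), dtype=np.uint8)
        m.ravel()[:100] = 1
        assert volume_ml(_vol(m, spacing=(2, 2, 2))) == pytest.approx(0.8)


class TestResidualSd:
    def test_exact_match_zero(self):
        assert residual_sd([3.0, 4.0, 5.0], [3.0, 4.0, 5.0]) == 0.0

    def test_two_point(self):
        assert residual_sd([1.0, -1.0], [0.0, 0.0]) == pytest.approx(np.sqrt(2))

    def test_three_point(self):
        assert residual_sd([0.0, 0.0, 3.0], [0.0, 0.0, 0.0]) == pytest.approx(np.sqrt(3))

    def test_needs_two(self):
        with pytest.raises(ValueError):
            residual_sd([1.0], [0.0])


class TestOptimalBand:
    def test_realizable_band_is_perfect(self, rng):
        vals = rng.normal(size=(8, 8, 8))
        brain = _vol(np.ones((8, 8, 8), dtype=np.uint8))
        expert = _vol((vals >= 0.5).astype(np.uint8))
        if expert.data.sum() == 0:
            pytest.skip("degenerate draw")
        res = optimal_two_threshold_dice(_vol(vals), expert, brain)
        assert res.dice == 1.0
        assert res.hi == np.inf

    def test_constant_image_all_or_nothing(self):
        brain = _vol(np.ones((6, 6, 6), dtype=np.uint8))
        expert = np.zeros((6, 6, 6), dtype=np.uint8)
        expert[1:3, 1:3, 1:3] = 1
        res = optimal_two_threshold_dice(
            _vol(np.full((6, 6, 6), 7.0)), _vol(expert), brain
        )
        e, b = expert.sum(), 6**3
        assert res.dice == pytest.approx(2 * e / (e + b))

    def test_empty_expert_rejected(self):
        brain = _vol(np.ones((4, 4, 4), dtype=np.uint8))
        with pytest.raises(ValueError, match="empty"):
            optimal_two_threshold_dice(
                _vol(np.zeros((4, 4, 4))), _vol(np.zeros((4, 4, 4), dtype=np.uint8)), brain
            )

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            vals = rng.integers(0, 12, size=(6, 6, 6)).astype(float)
            expert = (rng.uniform(size=(6, 6, 6)) < 0.2).astype(np.uint8)
            if expert.sum() == 0:
                expert[0, 0, 0] = 1
            brain = _vol(np.ones((6, 6, 6), dtype=np.uint8))
            got = optimal_two_threshold_dice(_vol(vals), _vol(expert), brain)
            assert got.dice == pytest.approx(
                brute_force_band(_vol(vals), _vol(expert), brain), abs=1e-12
            )

    def test_beats_random_fixed_bands(self, rng):
        vals = rng.normal(size=(7, 7, 7))
        expert = (rng.uniform(size=(7, 7, 7)) < 0.15).astype(np.uint8)
        expert[0, 0, 0] = 1
        brain = _vol(np.ones((7, 7, 7), dtype=np.uint8))
        v, e = _vol(vals), _vol(expert)
        best = optimal_two_threshold_dice(v, e, brain)
        for _ in range(20):
            lo, hi = np.sort(rng.normal(size=2))
            m = band_mask(v, brain, lo, hi)
            assert dice(m, e) <= best.dice + 1e-12

    def test_quantile_approximation_close(self, rng):
        vals = rng.normal(size=(10, 10, 8))
        expert = (vals > 1.0).astype(np.uint8)
        brain = _vol(np.ones((10, 10, 8), dtype=np.uint8))
        exact = optimal_two_threshold_dice(_vol(vals), _vol(expert), brain)
        approx = optimal_two_threshold_dice(
            _vol(vals), _vol(expert), brain, max_candidates=64
        )
        assert approx.dice <= exact.dice + 1e-12
        assert approx.dice > 0.8 * exact.dice


class TestWilcoxon:
    def test_identical_pairs(self):
        assert wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0]) == (0.0, 1.0)

    def test_shifted_sample_significant(self, rng):
        a = rng.normal(size=15)
        stat, p = wilcoxon_signed_rank(a + 2.0, a)
        assert p < 0.01

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def result(small_cohort):
    return run_loocv(small_cohort)


class TestLoocv:
    def test_record_bookkeeping(self, result, small_cohort):
        df = result.records
        assert set(df["method"]) == {"atlas", "threshold_dwi", "threshold_adc"}
        atlas = df[df["method"] == "atlas"]
        assert len(atlas) == len(small_cohort)
        assert (atlas["dice"] >= 0).all() and (atlas["dice"] <= 1).all()
        assert (df["predicted_volume_ml"] >= 0).all()

    def test_summary_quantities(self, result):
        s = result.summary
        for method, stats in s["methods"].items():
            lo, hi = stats["dice_iqr"]
            assert 0 <= lo <= stats["median_dice"] <= hi <= 1
            assert stats["residual_sd_ml"] >= 0
        assert "atlas_vs_threshold_adc" in s["wilcoxon"]
        p = s["wilcoxon"]["atlas_vs_threshold_adc"]["p_value"]
        assert 0 < p <= 1

    def test_requires_four_cases(self, small_cohort):
        with pytest.raises(ValueError, match="4 cases"):
            run_loocv(small_cohort[:3])

    def test_no_leakage_from_held_out_labels(self, small_cohort, result):
        """Perturbing the held-out patient's expert mask must not change
        the model applied to that patient (only its scoring)."""
        poisoned = list(small_cohort)
        case0 = poisoned[0]
        expert = case0.expert_mask.data.copy()
        ii, jj, kk = np.nonzero(expert)
        expert[ii[: len(ii) // 2], jj[: len(ii) // 2], kk[: len(ii) // 2]] = 0
        poisoned[0] = PatientCase(
            case0.patient_id,
            case0.dwi,
            case0.adc,
            case0.b0,
            case0.brain_mask,
            case0.expert_mask.with_data(expert),
        )
        res2 = run_loocv(poisoned)
        pid = case0.patient_id
        a1 = result.records.query("method=='atlas' and patient_id==@pid").iloc[0]
        a2 = res2.records.query("method=='atlas' and patient_id==@pid").iloc[0]
        # same model, same prediction -> identical predicted volume and depth
        assert a1["predicted_volume_ml"] == a2["predicted_volume_ml"]
        assert a1["detail"] == a2["detail"]
        assert result.summary["chosen_depths"][pid] == res2.summary["chosen_depths"][pid]
        # but the score against the altered expert mask differs
        assert a1["expert_volume_ml"] != a2["expert_volume_ml"]


def test_summarize_records_medians():
    import pandas as pd

    df = pd.DataFrame(
        {
            "patient_id": ["a", "b", "c"] * 2,
            "method": ["atlas"] * 3 + ["threshold_adc"] * 3,
            "dice": [0.8, 0.9, 0.7, 0.4, 0.5, 0.6],
            "predicted_volume_ml": [1, 2, 3, 4, 5, 6],
            "expert_volume_ml": [1, 2, 3, 1, 2, 3],
        }
    )
    s = summarize_records(df)
    assert s["methods"]["atlas"]["median_dice"] == 0.8
    assert s["methods"]["threshold_adc"]["median_dice"] == 0.5
    assert s["methods"]["threshold_adc"]["residual_sd_ml"] == 0.0
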