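"""The end-to-end lesion segmenter.

:class:`LesionSegmenter` is a scikit-learn-style estimator over patient
cases: ``fit`` builds the mirror-corrected feature table from a training
cohort, selects the tree depth by leave-one-patient-out AUC, grows the
final Youden tree on all training voxels and prunes it; ``predict``
preprocesses a new case, evaluates voxelwise probabilities and applies the
morphological regularization to produce the final lesion mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .depth import DepthSelectionResult, prune_tree, select_depth
from .preprocess import (
    FEATURE_NAMES,
    PreprocessConfig,
    build_feature_table,
    preprocess_case,
)
from .regularize import RegularizeConfig, regularize_map
from .tree import YoudenTreeClassifier
from .volumes import PatientCase, Volume

__all__ = ["LesionSegmenter", "SegmentationResult"]


@dataclass
class SegmentationResult:
    """Per-patient output of the segmenter."""

    patient_id: str
    probability: Volume
    mask: Volume
    volume_ml: float
    dice: float | None = None
    expert_volume_ml: float | None = None


class LesionSegmenter(BaseEstimator):
    """Diffusion-lesion segmenter: mirror-corrected features, Youden tree,
    LOO-AUC depth pruning, morphological regularization.

    Parameters mirror the three stage configs; see
    :class:`~strokeseg.preprocess.PreprocessConfig` and
    :class:`~strokeseg.regularize.RegularizeConfig`.

    Attributes (after fit)
    ----------------------
    tree_ : YoudenTreeClassifier
        The pruned tree used for prediction.
    full_tree_ : YoudenTreeClassifier
        The unpruned tree grown on all training voxels.
    depth_ : int
        Pruning depth actually applied.
    depth_result_ : DepthSelectionResult or None
        Leave-one-patient-out depth search outcome.
    """

    def __init__(
        self,
        smooth_sigma_mm: float = 2.0,
        critical_radius_vox: int = 1,
        contralateral: str = "auto",
        reg_smooth_sigma_mm: float = 2.0,
        prob_threshold: float = 0.25,
        struct_radius_vox: int = 1,
        max_depth: int | None = None,
        depth_selection: bool = True,
    ):
        self.smooth_sigma_mm = smooth_sigma_mm
        self.critical_radius_vox = critical_radius_vox
        self.contralateral = contralateral
        self.reg_smooth_sigma_mm = reg_smooth_sigma_mm
        self.prob_threshold = prob_threshold
        self.struct_radius_vox = struct_radius_vox
        self.max_depth = max_depth
        self.depth_selection = depth_selection

    # -- config plumbing -------------------------------------------------

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            smooth_sigma_mm=self.smooth_sigma_mm,
            critical_radius_vox=self.critical_radius_vox,
            contralateral=self.contralateral,
        )

    def regularize_config(self) -> RegularizeConfig:
        return RegularizeConfig(
            smooth_sigma_mm=self.reg_smooth_sigma_mm,
            prob_threshold=self.prob_threshold,
            struct_radius_vox=self.struct_radius_vox,
        )

    # -- fitting ---------------------------------------------------------

    def fit(self, cases: list[PatientCase], y=None, *, features=None, tree_cache=None):
        """Train on a cohort of cases with expert masks.

        ``features`` may carry precomputed per-case maps (dict patient_id
        -> dict of feature Volumes); ``tree_cache`` lets nested
        cross-validation reuse leave-one-out trees.
        """
        if len(cases) < 1:
            raise ValueError("need at least one training case")
        pcfg = self.preprocess_config()
        table = build_feature_table(cases, pcfg, features=features)
        return self._fit_table(table, tree_cache=tree_cache)

    def _fit_table(self, table: pd.DataFrame, *, tree_cache=None):
        n_patients = table["patient_id"].nunique()
        self.depth_result_ = None
        if self.depth_selection and n_patients >= 3:
            self.depth_result_ = select_depth(
                table, max_depth=self.max_depth, tree_cache=tree_cache
            )
        X = table[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
        y01 = table["label"].to_numpy()
        if tree_cache is not None:
            from .depth import _fit_cached

            self.full_tree_ = _fit_cached(
                X, y01, table["patient_id"].astype(str).to_numpy(),
                self.max_depth, tree_cache,
            )
        else:
            self.full_tree_ = YoudenTreeClassifier(max_depth=self.max_depth).fit(X, y01)
        if self.depth_result_ is not None:
            self.depth_ = int(self.depth_result_.chosen_depth)
        else:
            self.depth_ = self.full_tree_.height_
        self.tree_ = prune_tree(self.full_tree_, self.depth_)
        self.n_training_voxels_ = int(len(table))
        return self

    # -- prediction ------------------------------------------------------

    def predict_proba_volume(
        self, case: PatientCase, *, features=None
    ) -> Volume:
        """Voxelwise lesion-probability map (0 outside the brain mask)."""
        if not hasattr(self, "tree_"):
            raise ValueError("segmenter is not fitted")
        maps = features or preprocess_case(case, self.preprocess_config())
        brain = case.brain_mask.data.astype(bool)
        X = np.column_stack([maps[name].data[brain] for name in FEATURE_NAMES])
        prob = np.zeros(case.shape, dtype=np.float64)
        prob[brain] = self.tree_.predict_proba(X)[:, 1]
        return case.dwi.with_data(prob)

    def predict(self, case: PatientCase, *, features=None) -> SegmentationResult:
        """Segment one case; Dice is filled in when an expert mask exists."""
        from .evaluate import dice as dice_fn
        from .evaluate import volume_ml

        prob = self.predict_proba_volume(case, features=features)
        mask = regularize_map(prob, case.brain_mask, self.regularize_config())
        result = SegmentationResult(
            patient_id=case.patient_id,
            probability=prob,
            mask=mask,
            volume_ml=volume_ml(mask),
        )
        if case.expert_mask is not None:
            result.dice = dice_fn(mask, case.expert_mask)
            result.expert_volume_ml = volume_ml(case.expert_mask)
        return result

    def score(self, cases, y=None) -> float:
        """Mean Dice against expert masks."""
        scores = [self.predict(c).dice for c in cases]
        return float(np.mean([s for s in scores if s is not None]))

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        if not hasattr(self, "tree_"):
            raise ValueError("segmenter is not fitted")
        return {
            "format_version": 1,
            "params": self.get_params(),
            "chosen_depth": self.depth_,
            "depth_selection_result": (
                self.depth_result_.to_dict() if self.depth_result_ else None
            ),
            "tree": self.tree_.to_dict(),
            "full_tree_height": self.full_tree_.height_
            if hasattr(self, "full_tree_")
            else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LesionSegmenter":
        seg = cls(**d["params"])
        seg.tree_ = YoudenTreeClassifier.from_dict(d["tree"])
        seg.full_tree_ = seg.tree_
        seg.depth_ = int(d["chosen_depth"])
        dres = d.get("depth_selection_result")
        seg.depth_result_ = DepthSelectionResult.from_dict(dres) if dres else None
        return seg
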