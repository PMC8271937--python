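"""Feature fusion, match scoring and ROC/AUC/EER evaluation for identification.

Each trial contributes a static vector Fs = [arch index, foot angle, axis
ratio] and a dynamic vector Fd = [step angle, step width, trace similarity].
The features carry incommensurate units, so they are min-max normalized over
the enrollment gallery before any distance is computed; the fused template is
the weighted concatenation

    S = [2 alpha * Fd, 2 (1 - alpha) * Fs],       alpha in [0, 1],

where the factor 2 makes ``alpha = 0.5`` reproduce the plain concatenation
``[Fd, Fs]`` exactly.  ``alpha = 1`` keeps only dynamic features (the
shoe-wearing case); ``alpha = 0`` only static.  A matching pair scores

    error  = mean((s_i - t_i)^2),        score = 1 - error,

so identical normalized templates score 1.  Genuine scores come from
within-subject trial pairs, imposter scores from between-subject pairs; the
ROC is swept over every distinct observed score, the AUC is the trapezoidal
area, and the EER is the interpolated operating point where the false match
rate equals the false non-match rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    DegenerateFeatureError,
    DimensionError,
    EvaluationError,
    ParameterError,
)

__all__ = [
    "FEATURE_COLUMNS",
    "STATIC_COLUMNS",
    "DYNAMIC_COLUMNS",
    "MatchEvaluation",
    "normalize_gallery",
    "apply_normalization",
    "assemble_features",
    "matching_error",
    "matching_score",
    "score_all_pairs",
    "roc_eer",
    "evaluate_population",
]

STATIC_COLUMNS = ["arch_index", "foot_angle_deg", "axis_ratio"]
DYNAMIC_COLUMNS = ["step_angle_deg", "step_width", "trace_similarity"]
FEATURE_COLUMNS = STATIC_COLUMNS + DYNAMIC_COLUMNS


@dataclass
class MatchEvaluation:
    """Genuine/imposter scores with the derived ROC curve, AUC and EER."""

    genuine_scores: np.ndarray
    imposter_scores: np.ndarray
    roc_points: np.ndarray  # (k, 2) of (false match rate, true match rate)
    auc: float
    eer: float
    meta: dict = field(default_factory=dict)

    @property
    def n_genuine(self) -> int:
        return len(self.genuine_scores)

    @property
    def n_imposter(self) -> int:
        return len(self.imposter_scores)


def normalize_gallery(df: pd.DataFrame,
                      feature_cols: Sequence[str] = FEATURE_COLUMNS) -> Dict[str, tuple]:
    """Per-feature (min, max) over the enrollment gallery.

    A constant feature cannot be scaled to [0, 1] and raises
    :class:`DegenerateFeatureError` naming the feature.
    """
    if len(df) < 2:
        raise ParameterError("gallery needs >= 2 vectors")
    norm = {}
    for col in feature_cols:
        lo = float(df[col].min())
        hi = float(df[col].max())
        if hi <= lo:
            raise DegenerateFeatureError(f"feature {col!r} is constant in the gallery")
        norm[col] = (lo, hi)
    return norm


def apply_normalization(df: pd.DataFrame, norm: Dict[str, tuple]):
    """Min-max scale features to [0, 1]; out-of-range probe values are clipped.

    Returns ``(normalized copy, clipped-value count)``.  Idempotent on data
    already inside the gallery range.
    """
    out = df.copy()
    clipped = 0
    for col, (lo, hi) in norm.items():
        scaled = (out[col].to_numpy(dtype=float) - lo) / (hi - lo)
        clipped += int(np.count_nonzero((scaled < 0) | (scaled > 1)))
        out[col] = np.clip(scaled, 0.0, 1.0)
    return out, clipped


def assemble_features(Fs, Fd, alpha_weight: float = 0.5) -> np.ndarray:
    """Weighted fusion of normalized static and dynamic features.

    ``S = [2 alpha * Fd, 2 (1 - alpha) * Fs]``; the x2 convention makes
    ``alpha = 0.5`` identical to the unweighted concatenation ``[Fd, Fs]``.
    """
    if not 0.0 <= alpha_weight <= 1.0:
        raise ParameterError(f"alpha_weight {alpha_weight} outside [0, 1]")
    Fs = np.asarray(Fs, dtype=float)
    Fd = np.asarray(Fd, dtype=float)
    return np.concatenate([2.0 * alpha_weight * Fd, 2.0 * (1.0 - alpha_weight) * Fs])


def matching_error(s, t) -> float:
    """Mean squared component difference between two fused templates."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    if s.shape != t.shape or s.ndim != 1 or s.size < 1:
        raise DimensionError(f"template shapes differ: {s.shape} vs {t.shape}")
    return float(np.mean((s - t) ** 2))


def matching_score(s, t) -> float:
    """Similarity score ``1 - matching_error``; 1 for identical templates."""
    return 1.0 - matching_error(s, t)


def score_all_pairs(subject_ids, templates) -> Tuple[np.ndarray, np.ndarray]:
    """Scores of all unordered trial pairs, split into genuine and imposter.

    Genuine = within-subject pairs, imposter = between-subject pairs.  Raises
    :class:`EvaluationError` when no genuine pair can be formed.
    """
    ids = np.asarray(subject_ids)
    S = np.asarray(templates, dtype=float)
    if S.ndim != 2 or len(ids) != len(S):
        raise DimensionError("templates must be (n, d) matching subject_ids")
    n = len(S)
    if n < 2:
        raise EvaluationError("need >= 2 trials to form pairs")
    diff = S[:, None, :] - S[None, :, :]
    err = np.mean(diff**2, axis=2)
    scores = 1.0 - err
    iu, ju = np.triu_indices(n, k=1)
    same = ids[iu] == ids[ju]
    genuine = scores[iu[same], ju[same]]
    imposter = scores[iu[~same], ju[~same]]
    if len(genuine) == 0:
        raise EvaluationError("no genuine pair: every subject has a single trial")
    return genuine, imposter


def roc_eer(genuine, imposter) -> MatchEvaluation:
    """ROC sweep, trapezoidal AUC and interpolated EER.

    The threshold set is every distinct observed score plus +/- infinity
    endpoints, so the ROC is the exact step function (ties share a threshold
    and contribute diagonal segments, matching the Mann-Whitney statistic with
    the half-tie convention).  The EER solves FMR(t) = FNMR(t) by linear
    interpolation between adjacent thresholds.
    """
    g = np.sort(np.asarray(genuine, dtype=float))
    i = np.sort(np.asarray(imposter, dtype=float))
    if len(g) == 0 or len(i) == 0:
        raise EvaluationError("both genuine and imposter score lists must be non-empty")
    thresholds = np.unique(np.concatenate([g, i]))
    # accept if score >= t; +inf end gives (0, 0), -inf end gives (1, 1)
    tmr = 1.0 - np.searchsorted(g, thresholds, side="left") / len(g)
    fmr = 1.0 - np.searchsorted(i, thresholds, side="left") / len(i)
    # both rates fall as the threshold rises; reversing gives the ROC in
    # ascending FMR order with tied-FMR points correctly ordered
    fmr = np.concatenate([[1.0], fmr, [0.0]])[::-1]
    tmr = np.concatenate([[1.0], tmr, [0.0]])[::-1]
    auc = float(np.trapezoid(tmr, fmr))

    fnmr = 1.0 - tmr
    d = fmr - fnmr  # increases along the sweep from -1-ish to +1
    k = int(np.searchsorted(d >= 0, True))
    if k == 0:
        eer = float(fmr[0])
    elif d[k - 1] == d[k]:
        eer = float(fmr[k])
    else:
        lam = -d[k - 1] / (d[k] - d[k - 1])
        eer = float(fmr[k - 1] + lam * (fmr[k] - fmr[k - 1]))
    roc = np.column_stack([fmr, tmr])
    return MatchEvaluation(genuine_scores=g, imposter_scores=i, roc_points=roc,
                           auc=auc, eer=eer)


def evaluate_population(pop: pd.DataFrame, alpha_weight: float = 0.5,
                        feature_cols: Sequence[str] = FEATURE_COLUMNS) -> MatchEvaluation:
    """End-to-end evaluation of a feature table: normalize, fuse, score, ROC.

    ``pop`` needs columns ``subject_id``, ``trial_id`` and the six features.
    The whole table acts as the enrollment gallery for normalization.
    """
    norm = normalize_gallery(pop, feature_cols)
    normed, clipped = apply_normalization(pop, norm)
    Fs = normed[STATIC_COLUMNS].to_numpy(dtype=float)
    Fd = normed[DYNAMIC_COLUMNS].to_numpy(dtype=float)
    S = np.stack([assemble_features(fs, fd, alpha_weight) for fs, fd in zip(Fs, Fd)])
    genuine, imposter = score_all_pairs(normed["subject_id"].to_numpy(), S)
    ev = roc_eer(genuine, imposter)
    ev.meta.update({"alpha_weight": alpha_weight, "normalization": norm,
                    "clipped_values": clipped,
                    "n_subjects": int(pop["subject_id"].nunique()),
                    "n_trials": int(len(pop))})
    return ev
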