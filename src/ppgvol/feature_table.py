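"""Subject-level feature tables and the candidate pool for selection.

Trial features are averaged per subject, collapsed to nine named base
waveform features plus age, and expanded with all squared and pairwise
interaction terms.  Feature names encode their construction:

* bases: ``age, amp_rest, amp_vals, sd_rest, sd_vals, width_rest,
  width_vals, ratio_rms, ratio_auc, ratio_amplitude``
* squares: ``sq(x)``
* interactions: ``ix(x,y)`` with ``x < y`` lexicographically

The three-feature constructions of the published final models are
exposed by name through :func:`final_model_features`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import PPGVolError, UsageError
from .ppg_features import TrialFeatures, trial_features
from .synthetic_cohort import SubjectRecord

__all__ = [
    "FeatureMatrix",
    "BASE_FEATURES",
    "aggregate_trials",
    "subject_base_features",
    "features_from_cohort",
    "build_candidate_pool",
    "final_model_features",
    "matrix_from_frame",
]

log = logging.getLogger(__name__)

#: Waveform base features (age joins them in the pool).
BASE_FEATURES = [
    "amp_rest",
    "amp_vals",
    "sd_rest",
    "sd_vals",
    "width_rest",
    "width_vals",
    "ratio_rms",
    "ratio_auc",
    "ratio_amplitude",
]

#: Published three-term models, in table order.  Pair names are stored in
#: canonical (sorted) orientation; the product is commutative.
FINAL_MODEL_TERMS = {
    "regression": [
        ("ratio_rms", "ratio_auc"),
        ("sd_rest", "age"),
        ("amp_vals", "ratio_auc"),
    ],
    "classify_15": [
        ("width_rest", "ratio_auc"),
        ("amp_vals", "sd_vals"),
        ("sd_vals", "age"),
    ],
    "classify_10": [
        ("amp_rest", "width_rest"),
        ("amp_vals", "age"),
        "age",
    ],
}


@dataclass
class FeatureMatrix:
    """Aligned model inputs: subjects x named features, plus targets."""

    subject_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # (n_subjects, n_features)
    target: np.ndarray  # filling pressure, mmHg
    labels_15: np.ndarray  # bool
    labels_10: np.ndarray  # bool
    bnp: Optional[np.ndarray] = None  # pg/ml comparator, not in the pool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise UsageError("values shape must be (n_subjects, n_features)")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise UsageError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise UsageError("feature values must be finite")

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError as exc:
            raise UsageError(f"unknown feature {name!r}") from exc
        return self.values[:, j]

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        cols = np.column_stack([self.column(n) for n in names])
        return FeatureMatrix(
            subject_ids=list(self.subject_ids),
            feature_names=list(names),
            values=cols,
            target=self.target,
            labels_15=self.labels_15,
            labels_10=self.labels_10,
            bnp=self.bnp,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        df["filling_pressure"] = self.target
        df["overload_15"] = self.labels_15
        df["overload_10"] = self.labels_10
        if self.bnp is not None:
            df["bnp"] = self.bnp
        return df


def aggregate_trials(trials: Sequence[TrialFeatures]) -> dict[str, float]:
    """Subject-level base features: arithmetic mean across valid trials."""
    if len(trials) == 0:
        raise UsageError("need at least one valid trial to aggregate")
    rows = [
        {
            "amp_rest": tf.end_rest.mean_amplitude,
            "amp_vals": tf.end_valsalva.mean_amplitude,
            "sd_rest": tf.end_rest.sd_amplitude,
            "sd_vals": tf.end_valsalva.sd_amplitude,
            "width_rest": tf.end_rest.mean_width,
            "width_vals": tf.end_valsalva.mean_width,
            "ratio_rms": tf.ratio_rms,
            "ratio_auc": tf.ratio_auc,
            "ratio_amplitude": tf.ratio_amplitude,
        }
        for tf in trials
    ]
    return {k: float(np.mean([r[k] for r in rows])) for k in BASE_FEATURES}


def subject_base_features(
    subject: SubjectRecord, window_len: float = 5.0
) -> Optional[dict[str, float]]:
    """Extract and aggregate one subject's trials; None if all trials fail."""
    per_trial: list[TrialFeatures] = []
    for k, (rec, ann) in enumerate(subject.trials):
        try:
            per_trial.append(trial_features(rec, ann, window_len=window_len))
        except PPGVolError as exc:
            log.info(
                "subject %s trial %d dropped: %s", subject.subject_id, k + 1, exc
            )
    if not per_trial:
        log.warning("subject %s dropped: no valid trials", subject.subject_id)
        return None
    return aggregate_trials(per_trial)


def features_from_cohort(
    subjects: Sequence[SubjectRecord], window_len: float = 5.0
) -> pd.DataFrame:
    """Per-subject base-feature table (one row per retained subject)."""
    rows = []
    for subj in subjects:
        base = subject_base_features(subj, window_len=window_len)
        if base is None:
            continue
        row = {"subject_id": subj.subject_id, "age": subj.age, **base,
               "bnp": subj.bnp, "filling_pressure": subj.filling_pressure,
               "overload_15": subj.overload_15, "overload_10": subj.overload_10}
        rows.append(row)
    if not rows:
        raise UsageError("no subject yielded valid features")
    return pd.DataFrame(rows)


def _pair_name(x: str, y: str) -> str:
    a, b = sorted((x, y))
    return f"ix({a},{b})"


def build_candidate_pool(base_table: pd.DataFrame) -> FeatureMatrix:
    """Expand the base table into the full candidate pool.

    Column order is deterministic: bases, squares, interactions, each
    block lexicographic — with b bases the pool has b + b + b(b-1)/2
    columns (65 for the 10 defaults).
    """
    required = ["age"] + BASE_FEATURES
    missing = [c for c in required if c not in base_table.columns]
    if missing:
        raise UsageError(f"base table missing columns {missing}")
    bases = sorted(required)
    data: dict[str, np.ndarray] = {}
    for b in bases:
        data[b] = base_table[b].to_numpy(dtype=float)
    names = list(bases)
    for b in bases:
        names.append(f"sq({b})")
        data[f"sq({b})"] = data[b] ** 2
    for x, y in combinations(bases, 2):
        name = _pair_name(x, y)
        names.append(name)
        data[name] = data[x] * data[y]
    values = np.column_stack([data[n] for n in names])
    return FeatureMatrix(
        subject_ids=[str(s) for s in base_table["subject_id"]],
        feature_names=names,
        values=values,
        target=base_table["filling_pressure"].to_numpy(dtype=float),
        labels_15=base_table["overload_15"].to_numpy(dtype=bool),
        labels_10=base_table["overload_10"].to_numpy(dtype=bool),
        bnp=base_table["bnp"].to_numpy(dtype=float)
        if "bnp" in base_table.columns
        else None,
    )


def final_model_features(matrix: FeatureMatrix, case: str) -> FeatureMatrix:
    """Restrict the pool to the published three-term model for ``case``.

    ``case`` is one of ``regression``, ``classify_15``, ``classify_10``;
    columns come back in published order.
    """
    if case not in FINAL_MODEL_TERMS:
        raise UsageError(
            f"unknown case {case!r}; expected one of {sorted(FINAL_MODEL_TERMS)}"
        )
    names = [
        term if isinstance(term, str) else _pair_name(*term)
        for term in FINAL_MODEL_TERMS[case]
    ]
    return matrix.select(names)


def matrix_from_frame(df: pd.DataFrame) -> FeatureMatrix:
    """Rebuild the candidate pool from a saved base-feature table."""
    return build_candidate_pool(df)
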