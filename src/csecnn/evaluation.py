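"""Cross-validated evaluation of the per-seed-region classifiers.

Subjects are partitioned into k stratified folds (default 6) so that each
clinical stratum (NS, SI, SA) is represented in every fold.  For each seed
region and each fold, one fold is the test set, the next fold estimates
generalization error for early stopping, and the remaining k-2 folds train
the network.  Reference normalization is fitted inside each fold on
training-fold NS subjects only (default), so no test-subject information
reaches the features.

Per-region accuracies are aggregated into a report with means, Student-t
95% confidence intervals, a strict > threshold flag on the mean, and a
"reliable" flag requiring every fold to clear the threshold.  A majority
vote over the per-region predictions gives a subject-level ensemble call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .cnn import CNNVolumeClassifier, ModelSpec, desk_scale_spec
from .entropy import RawCSEMatrix
from .simulate import AtlasVolume, GROUPS
from .volumes import fit_reference_stats, normalize_matrix, paint_cse_volume

__all__ = [
    "FoldAssignment",
    "make_folds",
    "run_seed_roi_cv",
    "run_full_cv",
    "accuracy_ci",
    "rank_rois",
    "ensemble_predict",
    "summary_t_test",
    "binomial_chance_band",
]


@dataclass
class FoldAssignment:
    """Mapping subject_id -> fold index 1..k."""

    k: int
    mapping: dict[str, int]
    seed: int

    def fold_members(self, fold: int) -> list[str]:
        return [sid for sid, f in self.mapping.items() if f == fold]

    def sizes(self) -> list[int]:
        return [len(self.fold_members(f)) for f in range(1, self.k + 1)]


def make_folds(manifest: pd.DataFrame, k: int = 6, seed: int = 0) -> FoldAssignment:
    """Stratified partition into k roughly equal folds.

    Each stratum is shuffled and dealt out evenly; leftover subjects go to
    the currently smallest folds (ties broken toward lower fold index), so
    fold sizes never differ by more than one.  For the 35/26/22 cohort at
    k = 6 this yields fold sizes {14, 14, 14, 14, 14, 13}.
    """
    n = len(manifest)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects ({n})")
    rng = np.random.default_rng(seed)
    mapping: dict[str, int] = {}
    totals = np.zeros(k, dtype=int)
    for group in GROUPS:
        members = list(manifest.loc[manifest["group"] == group, "subject_id"])
        if not members:
            continue
        order = rng.permutation(len(members))
        members = [members[i] for i in order]
        base, rem = divmod(len(members), k)
        pos = 0
        counts = np.full(k, base)
        if rem:
            # least-filled folds first keeps the global sizes within one
            receive = np.lexsort((np.arange(k), totals))[:rem]
            counts[receive] += 1
        for fold in range(k):
            for sid in members[pos : pos + counts[fold]]:
                mapping[sid] = fold + 1
            pos += counts[fold]
            totals[fold] += counts[fold]
    return FoldAssignment(k=k, mapping=mapping, seed=seed)


def accuracy_ci(
    accuracies: Sequence[float], level: float = 0.95
) -> tuple[float, float, float]:
    """Mean and Student-t confidence interval over per-fold accuracies,
    clamped to [0, 1]."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least 2 fold accuracies for an interval")
    mean = float(acc.mean())
    sd = float(acc.std(ddof=1))
    half = float(scipy.stats.t.ppf((1 + level) / 2, acc.size - 1)) * sd / np.sqrt(acc.size)
    return mean, max(0.0, mean - half), min(1.0, mean + half)


def rank_rois(
    report: pd.DataFrame, threshold: float = 0.75
) -> tuple[list[int], list[int]]:
    """Regions with mean accuracy strictly above threshold (sorted by mean,
    descending) and regions clearing it in every single fold."""
    if report.empty:
        raise ValueError("report is empty")
    fold_cols = [c for c in report.columns if c.startswith("acc_fold")]
    above = report.loc[report["mean_accuracy"] > threshold].sort_values(
        "mean_accuracy", ascending=False
    )
    reliable = report.loc[(report[fold_cols] > threshold).all(axis=1)]
    return list(above["roi_label"]), list(reliable["roi_label"])


def ensemble_predict(votes: Sequence[int]) -> int:
    """Majority vote over per-seed-region predicted labels; ties go to the
    suicidality class (1)."""
    votes = np.asarray(votes)
    if votes.size == 0:
        raise ValueError("need at least one vote")
    ones = int((votes == 1).sum())
    zeros = votes.size - ones
    return 1 if ones >= zeros else 0


def summary_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Pooled-variance two-sample t statistic from summary statistics."""
    if min(n1, n2) < 2:
        raise ValueError("both groups need n >= 2")
    if min(sd1, sd2) < 0:
        raise ValueError("standard deviations must be nonnegative")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    diff = mean1 - mean2
    if pooled_var == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    se = np.sqrt(pooled_var * (1 / n1 + 1 / n2))
    return float(diff / se)


def binomial_chance_band(
    n: int, p0: float, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial central band for the accuracy of a chance classifier
    that guesses the majority class, as a fraction of n."""
    alpha = 1 - level
    lo = scipy.stats.binom.ppf(alpha / 2, n, p0) / n
    hi = scipy.stats.binom.ppf(1 - alpha / 2, n, p0) / n
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# cross-validation drivers


def _fold_split(folds: FoldAssignment, fold: int) -> tuple[list[str], list[str], list[str]]:
    """Test fold, rotated validation fold (next index), training folds."""
    val_fold = fold % folds.k + 1
    test = folds.fold_members(fold)
    val = folds.fold_members(val_fold)
    train = [
        sid for f in range(1, folds.k + 1)
        if f not in (fold, val_fold)
        for sid in folds.fold_members(f)
    ]
    return test, val, train


def run_seed_roi_cv(
    matrices: Mapping[str, RawCSEMatrix],
    manifest: pd.DataFrame,
    folds: FoldAssignment,
    atlas: AtlasVolume,
    seed_roi: int,
    spec: ModelSpec | None = None,
    max_epochs: int = 400,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    early_stop_patience: int = 60,
    seed: int = 0,
    normalization: str = "fold",
) -> dict:
    """k-fold cross-validation of one seed region's classifier.

    Returns per-fold test accuracies, pooled test predictions keyed by
    subject, and the reference-statistics hashes used per fold (for
    leakage audits).  ``normalization`` is "fold" (reference statistics
    fitted on training-fold NS subjects; the default, leakage-free) or
    "global" (all NS subjects).
    """
    if normalization not in ("fold", "global"):
        raise ValueError(f"unknown normalization mode {normalization!r}")
    targets = dict(zip(manifest["subject_id"], manifest["binary_target"]))
    groups = dict(zip(manifest["subject_id"], manifest["group"]))
    missing = [sid for sid in folds.mapping if sid not in matrices]
    if missing:
        raise ValueError(f"subjects without CSE matrices: {missing}")
    all_ns = [sid for sid in folds.mapping if groups[sid] == "NS"]
    accuracies = []
    predictions: dict[str, int] = {}
    stats_hashes = []
    for fold in range(1, folds.k + 1):
        test, val, train = _fold_split(folds, fold)
        if normalization == "global":
            ref_ids = all_ns
        else:
            ref_ids = [sid for sid in train if groups[sid] == "NS"]
        stats = fit_reference_stats([matrices[sid] for sid in ref_ids], ref_ids)
        stats_hashes.append(stats.content_hash())

        def volumes_for(ids: list[str]) -> np.ndarray:
            return np.stack([
                paint_cse_volume(
                    normalize_matrix(matrices[sid], stats), seed_roi, atlas
                ).values
                for sid in ids
            ])

        clf = CNNVolumeClassifier(
            spec=spec,
            max_epochs=max_epochs,
            batch_size=batch_size,
            learning_rate=learning_rate,
            early_stop_patience=early_stop_patience,
            random_state=seed + 7 * fold + 1000 * seed_roi,
        )
        clf.fit(
            volumes_for(train),
            np.array([targets[sid] for sid in train]),
            validation_data=(
                volumes_for(val),
                np.array([targets[sid] for sid in val]),
            ),
        )
        pred = clf.predict(volumes_for(test))
        truth = np.array([targets[sid] for sid in test])
        accuracies.append(float((pred == truth).mean()))
        predictions.update(dict(zip(test, (int(p) for p in pred))))
    return {
        "seed_roi": seed_roi,
        "fold_accuracies": accuracies,
        "predictions": predictions,
        "stats_hashes": stats_hashes,
    }


def run_full_cv(
    matrices: Mapping[str, RawCSEMatrix],
    manifest: pd.DataFrame,
    folds: FoldAssignment,
    atlas: AtlasVolume,
    spec: ModelSpec | None = None,
    reduced: bool = False,
    threshold: float = 0.75,
    ci_level: float = 0.95,
    seed: int = 0,
    normalization: str = "fold",
    **train_kwargs,
) -> dict:
    """Cross-validate every seed region and assemble the accuracy report.

    Returns a dict with the report DataFrame (one row per region: per-fold
    accuracies, mean, pooled accuracy, CI bounds, threshold and
    reliability flags), per-subject per-region predictions, ensemble
    votes, and the per-fold reference hashes.
    """
    if spec is None and reduced:
        spec = desk_scale_spec(atlas.data.shape)
    targets = dict(zip(manifest["subject_id"], manifest["binary_target"]))
    rows = []
    all_predictions: dict[int, dict[str, int]] = {}
    hashes = {}
    for seed_roi in atlas.labels:
        result = run_seed_roi_cv(
            matrices, manifest, folds, atlas, seed_roi,
            spec=spec, seed=seed, normalization=normalization, **train_kwargs,
        )
        acc = result["fold_accuracies"]
        mean, lo, hi = accuracy_ci(acc, ci_level)
        preds = result["predictions"]
        pooled = float(
            np.mean([preds[sid] == targets[sid] for sid in preds])
        )
        row = {"roi_label": seed_roi}
        row.update({f"acc_fold{f+1}": a for f, a in enumerate(acc)})
        row.update({
            "mean_accuracy": mean,
            "pooled_accuracy": pooled,
            "ci_low": lo,
            "ci_high": hi,
            "above_threshold": mean > threshold,
            "reliable": all(a > threshold for a in acc),
        })
        rows.append(row)
        all_predictions[seed_roi] = preds
        hashes[seed_roi] = result["stats_hashes"]
    report = pd.DataFrame(rows)
    subjects = list(folds.mapping)
    ensemble = {
        sid: ensemble_predict([all_predictions[roi][sid] for roi in atlas.labels])
        for sid in subjects
    }
    confusion = pd.crosstab(
        pd.Series({sid: targets[sid] for sid in subjects}, name="truth"),
        pd.Series(ensemble, name="ensemble"),
        dropna=False,
    )
    return {
        "report": report,
        "predictions": all_predictions,
        "ensemble": ensemble,
        "confusion": confusion,
        "stats_hashes": hashes,
    }
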