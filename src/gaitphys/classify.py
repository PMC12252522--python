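"""Subject-level balanced leave-one-out classification of gait groups.

The scoring protocol: features are cycle-level rows (one per subject,
side, cycle); for a pair of clinical groups, each realisation first
subsamples the larger group's subjects to the smaller group's size, then
performs subject-level leave-one-out cross-validation with a random
forest (500 trees by default).  A held-out subject's class is the
majority vote over its cycle rows, and the realisation's *precision* is
the fraction of subjects classified correctly.  The reported score is the
mean over independent realisations: 0.5 is an uninformed classifier,
1.0 a perfect one.

Each leave-one-out training fold additionally drops one randomly chosen
subject of the *opposite* group.  Without this, every training fold
under-represents the held-out subject's class (9 v 10 after balancing),
which majority voting amplifies into a strongly pessimistic bias — the
uninformed baseline lands far below 1/2 instead of at it.  Fold
rebalancing keeps the baseline at the nominal 0.5 while leaving
informative-feature behaviour unchanged.

Sides (left/right) of a subject always travel together: folds are formed
on subject identity, so train and test subject sets are disjoint by
construction (asserted).  Missing feature values are imputed with
training-fold medians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Cohort, extract_subwindow, resample_cycle
from .metrics import compute_features, features_to_wide

__all__ = [
    "TaskSpec",
    "ScoreSummary",
    "loo_classification_score",
    "feature_importance",
    "cross_dataset_score",
    "resolution_sweep",
    "subwindow_sweep",
    "ID_COLUMNS",
]

ID_COLUMNS = ("subject_id", "group", "side", "cycle")


@dataclass(frozen=True)
class TaskSpec:
    """A group-pair classification task."""

    group_a: str
    group_b: str
    feature_columns: tuple[str, ...] | None = None
    n_realisations: int = 100
    n_trees: int = 500
    seed: int = 0
    backend: str = "fast"  # "fast" (compiled) or "sklearn"

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("the two groups must be distinct")
        if self.n_realisations < 1:
            raise ValueError("n_realisations must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.backend not in ("fast", "sklearn"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class ScoreSummary:
    """Mean +/- sd of subject-level precision over realisations."""

    mean_precision: float
    sd_precision: float
    n_realisations: int
    per_realisation: np.ndarray
    realisation_seeds: np.ndarray | None = None
    #: (realisation, held-out subject, train subject tuple) per LOO fold
    fold_log: list[tuple[int, str, tuple[str, ...]]] | None = None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ScoreSummary(mean={self.mean_precision:.3f}, "
            f"sd={self.sd_precision:.3f}, n={self.n_realisations})"
        )


def _summarise(scores: list[float], seeds: list[int]) -> ScoreSummary:
    arr = np.asarray(scores, dtype=float)
    return ScoreSummary(
        mean_precision=float(arr.mean()),
        sd_precision=float(arr.std()),
        n_realisations=arr.size,
        per_realisation=arr,
        realisation_seeds=np.asarray(seeds),
    )


def _prepare(features: pd.DataFrame, task: TaskSpec):
    """Select the two groups' rows and resolve feature columns to numpy."""
    df = features[features["group"].isin([task.group_a, task.group_b])]
    if task.feature_columns is not None:
        feat_cols = list(task.feature_columns)
        for col in feat_cols:
            if df[col].isna().all():
                raise ValueError(f"feature column {col!r} is entirely missing")
    else:
        # auto selection: silently usable numeric columns; metrics that are
        # undefined everywhere (e.g. BDS below its minimum length) drop out
        feat_cols = []
        dropped = []
        for c in df.columns:
            if c in ID_COLUMNS:
                continue
            if df[c].isna().all():
                dropped.append(c)
            else:
                feat_cols.append(c)
        if dropped:
            warnings.warn(
                f"dropping entirely-missing feature columns: {dropped[:4]}"
                + ("..." if len(dropped) > 4 else "")
            )
    if not feat_cols:
        raise ValueError("no feature columns selected")
    subj_group = df.groupby("subject_id")["group"].agg(
        lambda g: g.unique()[0] if g.nunique() == 1 else None
    )
    if subj_group.isna().any():
        raise ValueError("a subject appears in more than one group")
    for g in (task.group_a, task.group_b):
        if (subj_group == g).sum() < 3:
            raise ValueError(f"need >= 3 subjects in group {g!r}")
    X = df[feat_cols].to_numpy(dtype=np.float64)
    y = (df["group"] == task.group_b).to_numpy(dtype=np.int64)
    subjects = df["subject_id"].to_numpy()
    return X, y, subjects, subj_group, feat_cols


def _make_forest(task: TaskSpec, seed: int):
    if task.backend == "fast":
        from ._forest import FastRandomForest

        return FastRandomForest(n_estimators=task.n_trees, random_state=seed)
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(
        n_estimators=task.n_trees, random_state=seed, n_jobs=1
    )


def _impute(train_X: np.ndarray, *others: np.ndarray):
    """Median imputation fitted on the training block only."""
    med = np.nanmedian(train_X, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    out = []
    for block in (train_X,) + others:
        block = block.copy()
        nan_r, nan_c = np.nonzero(np.isnan(block))
        block[nan_r, nan_c] = med[nan_c]
        out.append(block)
    return out


def _majority_vote(proba: np.ndarray) -> int:
    """Subject-level class from row probabilities; ties -> mean probability."""
    votes = (proba[:, 1] > 0.5).mean()
    if votes > 0.5:
        return 1
    if votes < 0.5:
        return 0
    return int(proba[:, 1].mean() > 0.5)


def _balanced_subjects(subj_group, task: TaskSpec, rng) -> tuple[list, list]:
    a = sorted(subj_group.index[subj_group == task.group_a])
    b = sorted(subj_group.index[subj_group == task.group_b])
    n = min(len(a), len(b))
    if len(a) > n:
        a = sorted(rng.choice(a, size=n, replace=False))
    if len(b) > n:
        b = sorted(rng.choice(b, size=n, replace=False))
    assert len(a) == len(b), "groups must be balanced after subsampling"
    return a, b


def _realisation_rngs(task: TaskSpec):
    seeds = [
        int(np.random.SeedSequence(task.seed, spawn_key=(r,)).generate_state(1)[0]
            % (2**31 - 1))
        for r in range(task.n_realisations)
    ]
    return seeds, [np.random.default_rng(s) for s in seeds]


def loo_classification_score(features: pd.DataFrame, task: TaskSpec) -> ScoreSummary:
    """Balanced subject-level leave-one-out score for one group pair.

    ``features`` is the wide table from :func:`~gaitphys.metrics.features_to_wide`
    (or any table with the same identity columns and numeric features).
    """
    X, y, subjects, subj_group, _ = _prepare(features, task)
    seeds, rngs = _realisation_rngs(task)
    scores: list[float] = []
    used_seeds: list[int] = []
    fold_log: list[tuple[int, str, tuple[str, ...]]] = []
    for r, (seed, rng) in enumerate(zip(seeds, rngs)):
        a, b = _balanced_subjects(subj_group, task, rng)
        selected = a + b
        sel_mask = np.isin(subjects, selected)
        correct = 0
        aborted = False
        for held in selected:
            opposite = b if held in a else a
            drop = opposite[int(rng.integers(0, len(opposite)))]
            train_mask = sel_mask & (subjects != held) & (subjects != drop)
            test_mask = subjects == held
            assert not np.any(train_mask & test_mask), "train/test fold overlap"
            fold_log.append(
                (r, held, tuple(s for s in selected if s not in (held, drop)))
            )
            y_tr = y[train_mask]
            if y_tr.min() == y_tr.max():
                warnings.warn(
                    f"degenerate fold (single class) holding out {held!r}; "
                    "realisation aborted"
                )
                aborted = True
                break
            X_tr, X_te = _impute(X[train_mask], X[test_mask])
            forest = _make_forest(task, int(rng.integers(0, 2**31 - 1)))
            forest.fit(X_tr, y_tr)
            pred = _majority_vote(forest.predict_proba(X_te))
            truth = int(held in b)
            correct += int(pred == truth)
        if not aborted:
            scores.append(correct / len(selected))
            used_seeds.append(seed)
    if not scores:
        raise RuntimeError("every realisation aborted on a degenerate fold")
    summary = _summarise(scores, used_seeds)
    summary.fold_log = fold_log
    return summary


def feature_importance(features: pd.DataFrame, task: TaskSpec) -> pd.DataFrame:
    """Impurity-based importances averaged over balanced realisations.

    Returns a table sorted by decreasing raw importance with a
    ``relative_importance`` column rescaled so the top feature is
    exactly 1.0.
    """
    X, y, subjects, subj_group, feat_cols = _prepare(features, task)
    seeds, rngs = _realisation_rngs(task)
    total = np.zeros(len(feat_cols))
    for seed, rng in zip(seeds, rngs):
        a, b = _balanced_subjects(subj_group, task, rng)
        mask = np.isin(subjects, a + b)
        (X_tr,) = _impute(X[mask])
        forest = _make_forest(task, int(rng.integers(0, 2**31 - 1)))
        forest.fit(X_tr, y[mask])
        total += forest.feature_importances_
    raw = total / task.n_realisations
    top = raw.max()
    rel = raw / top if top > 0 else np.zeros_like(raw)
    table = pd.DataFrame(
        {"feature": feat_cols, "raw_importance": raw, "relative_importance": rel}
    ).sort_values("raw_importance", ascending=False, ignore_index=True)
    return table


def cross_dataset_score(
    train: pd.DataFrame, test: pd.DataFrame, task: TaskSpec
) -> ScoreSummary:
    """Train on one cohort's features, score subjects of another.

    Per realisation the training table is balanced by subject subsampling
    and the model is fitted once; every test subject is then classified
    by majority vote over its rows.  Imputation medians come from the
    training block only, so no test information leaks into the fit.
    """
    tr_cols = [c for c in train.columns if c not in ID_COLUMNS]
    te_cols = [c for c in test.columns if c not in ID_COLUMNS]
    if tr_cols != te_cols:
        raise ValueError("train and test feature columns differ")
    X_tr_all, y_tr_all, subj_tr, subj_group_tr, _ = _prepare(train, task)
    X_te_all, y_te_all, subj_te, subj_group_te, _ = _prepare(test, task)
    test_subjects = sorted(subj_group_te.index)
    seeds, rngs = _realisation_rngs(task)
    scores: list[float] = []
    used_seeds: list[int] = []
    for seed, rng in zip(seeds, rngs):
        a, b = _balanced_subjects(subj_group_tr, task, rng)
        mask = np.isin(subj_tr, a + b)
        X_tr, X_te = _impute(X_tr_all[mask], X_te_all)
        forest = _make_forest(task, int(rng.integers(0, 2**31 - 1)))
        forest.fit(X_tr, y_tr_all[mask])
        proba = forest.predict_proba(X_te)
        correct = 0
        for s in test_subjects:
            rows = subj_te == s
            pred = _majority_vote(proba[rows])
            correct += int(pred == int(subj_group_te[s] == task.group_b))
        scores.append(correct / len(test_subjects))
        used_seeds.append(seed)
    return _summarise(scores, used_seeds)


def _score_cohort(cohort: Cohort, task: TaskSpec, engine: str,
                  metric_kwargs: dict, resnet_spec) -> ScoreSummary:
    if engine == "features":
        wide = features_to_wide(compute_features(cohort, **metric_kwargs))
        return loo_classification_score(wide, task)
    if engine == "resnet":
        from .resnet import resnet_score

        return resnet_score(cohort, task, spec=resnet_spec)
    raise ValueError(f"unknown engine {engine!r}")


def resolution_sweep(
    cohort: Cohort,
    lengths: list[int],
    task: TaskSpec,
    engine: str = "features",
    metric_kwargs: dict | None = None,
    resnet_spec=None,
) -> dict[int, ScoreSummary]:
    """Classification score as a function of samples per gait cycle.

    Every cycle is linearly resampled to each target length before
    feature extraction (or model training), so the curve isolates the
    effect of time resolution.
    """
    if sorted(lengths) != list(lengths):
        raise ValueError("lengths must be sorted ascending")
    if min(lengths) < 8:
        raise ValueError("lengths must be >= 8")
    out: dict[int, ScoreSummary] = {}
    for L in lengths:
        resampled = cohort.map_cycles(lambda c: resample_cycle(c, L))
        out[L] = _score_cohort(resampled, task, engine, metric_kwargs or {},
                               resnet_spec)
    return out


def subwindow_sweep(
    cohort: Cohort,
    starts: list[float] = (0, 20, 40, 60),
    lengths: list[float] = (20, 40, 60, 80, 100),
    task: TaskSpec = None,
    engine: str = "features",
    metric_kwargs: dict | None = None,
    resnet_spec=None,
) -> dict[tuple[float, float], ScoreSummary]:
    """Score per (start%, length%) sub-window of the gait cycle.

    Cells with ``start + length > 100`` (or too few samples to embed) are
    absent from the result rather than filled with a placeholder.
    """
    if task is None:
        raise ValueError("task must be provided")
    out: dict[tuple[float, float], ScoreSummary] = {}
    for start in starts:
        for length in lengths:
            if start + length > 100:
                continue
            try:
                windowed = cohort.map_cycles(
                    lambda c: extract_subwindow(c, start, length)
                )
            except ValueError:
                continue
            out[(start, length)] = _score_cohort(
                windowed, task, engine, metric_kwargs or {}, resnet_spec
            )
    return out
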