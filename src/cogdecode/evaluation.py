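"""Validation battery: half-split decoding scores, baselines, transfer
summaries, learning curves, and classification-map similarity structure.

Decoding is always evaluated *across subjects*: each study's subjects are
split into two halves (repeated, 20 repeats by default), models are trained
on one half and scored on the other.  The multi-study model is compared to
single-study baselines fit either directly on voxels or on the functional
network projection.  Gains are summarized per study and over study-by-split
experiments.  Per-contrast difficulty uses one-vs-rest balanced accuracy,
whose chance level is 0.5 for every study regardless of the number of
contrasts.

Classification-map structure is summarized by the cosine-similarity matrix,
average-linkage hierarchical clustering on ``1 - cosine``, the cophenetic
correlation coefficient (how faithfully the tree reproduces the pairwise
distances), and the mean absolute off-diagonal cosine.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.linear_model import LogisticRegression

from .core_data import MultiStudyCorpus, StudyDataset
from .functional_units import Dictionary, project_maps
from .model import TrainConfig, predict, train_multistudy

__all__ = [
    "SplitScheme",
    "ScoreTable",
    "SimilarityReport",
    "subject_half_splits",
    "split_corpus",
    "fit_baseline",
    "accuracy_per_study",
    "balanced_accuracy_per_contrast",
    "transfer_gain_summary",
    "evaluate_methods",
    "learning_curve",
    "similarity_clustering",
]

BASELINE_L2_GRID = (1e-4, 1e-2, 1.0)


class SplitError(RuntimeError):
    pass


@dataclass
class SplitScheme:
    """Per-repeat, per-study disjoint train/test subject halves."""

    n_repeats: int
    seed: int
    # assignments[repeat][study_id] = (train_subject_ids, test_subject_ids)
    assignments: list[dict[str, tuple[np.ndarray, np.ndarray]]]


@dataclass
class ScoreTable:
    """Long-format evaluation results.

    ``accuracy``: columns (repeat, study, method, accuracy).
    ``balanced``: columns (repeat, study, contrast, method,
    balanced_accuracy); missing contrasts are recorded as NaN.
    """

    accuracy: pd.DataFrame
    balanced: pd.DataFrame


def subject_half_splits(
    corpus: MultiStudyCorpus, n_repeats: int = 20, seed: int = 0
) -> SplitScheme:
    """Random half-splits of each study's subjects, repeated.

    Every contrast must appear on both sides of every split; a study/repeat
    that fails this after 100 resamplings raises a ``SplitError``.
    """
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(n_repeats):
        per_study = {}
        for study in corpus.studies:
            subjects = np.unique(study.subject_ids)
            if len(subjects) < 2:
                raise SplitError(f"study {study.study_id!r} has fewer than 2 subjects")
            ok = False
            for _try in range(100):
                perm = rng.permutation(subjects)
                half = len(subjects) // 2
                train, test = np.sort(perm[:half]), np.sort(perm[half:])
                if _covers_all_contrasts(study, train) and _covers_all_contrasts(
                    study, test
                ):
                    ok = True
                    break
            if not ok:
                raise SplitError(
                    f"could not cover every contrast on both sides of a half-split "
                    f"for study {study.study_id!r}"
                )
            per_study[study.study_id] = (train, test)
        assignments.append(per_study)
    return SplitScheme(n_repeats=n_repeats, seed=seed, assignments=assignments)


def _covers_all_contrasts(study: StudyDataset, subjects: np.ndarray) -> bool:
    rows = np.isin(study.subject_ids, subjects)
    return len(np.unique(study.labels[rows])) == study.n_contrasts


def split_corpus(
    corpus: MultiStudyCorpus, assignment: dict[str, tuple[np.ndarray, np.ndarray]]
) -> tuple[MultiStudyCorpus, MultiStudyCorpus]:
    """Materialize the train and test corpora of one split."""
    train_studies, test_studies = [], []
    for study in corpus.studies:
        train_subj, test_subj = assignment[study.study_id]
        train_studies.append(study.subset(np.isin(study.subject_ids, train_subj)))
        test_studies.append(study.subset(np.isin(study.subject_ids, test_subj)))
    return (
        MultiStudyCorpus(studies=train_studies, mask=corpus.mask),
        MultiStudyCorpus(studies=test_studies, mask=corpus.mask),
    )


class _Baseline:
    """Single-study l2 multinomial decoder on voxels or network loadings."""

    def __init__(self, mode: str, dictionary: Dictionary | None, clf, offset, scale):
        self.mode = mode
        self.dictionary = dictionary
        self.clf = clf
        self.offset = offset
        self.scale = scale

    def _features(self, maps: np.ndarray) -> np.ndarray:
        if self.mode == "voxel":
            return np.asarray(maps, dtype=float)
        return (project_maps(maps, self.dictionary) - self.offset) / self.scale

    def predict(self, maps: np.ndarray) -> np.ndarray:
        return self.clf.predict(self._features(maps))


def fit_baseline(
    study: StudyDataset,
    mode: str = "voxel",
    dictionary: Dictionary | None = None,
    l2_grid: tuple[float, ...] = BASELINE_L2_GRID,
    standardize: bool = True,
) -> _Baseline:
    """Fit the per-study baseline with inner 2-fold regularization choice.

    ``mode='voxel'`` classifies raw maps; ``mode='network'`` classifies
    standardized functional-network loadings ``s(D x)`` (standardization
    estimated on this study's training fold).  The l2 strength is chosen on
    a deterministic subject-wise inner split from a fixed small grid.
    """
    if mode not in ("voxel", "network"):
        raise ValueError("mode must be 'voxel' or 'network'")
    if mode == "network" and dictionary is None:
        raise ValueError("network mode requires a dictionary")
    if len(np.unique(study.labels)) < 2:
        raise ValueError(f"single-class fold for study {study.study_id!r}")
    if mode == "network":
        feats = project_maps(study.maps, dictionary)
        if standardize:
            offset = feats.mean(axis=0)
            scale = feats.std(axis=0)
            scale[scale < 1e-8] = 1.0
        else:
            offset = np.zeros(feats.shape[1])
            scale = np.ones(feats.shape[1])
        X = (feats - offset) / scale
    else:
        offset = scale = None
        X = study.maps
    y = study.labels
    n_subjects = study.n_subjects

    def make_clf(alpha: float, n_subj: int) -> LogisticRegression:
        return LogisticRegression(
            C=1.0 / (2.0 * alpha * max(n_subj, 1)), tol=1e-8, max_iter=2000
        )

    best_alpha = l2_grid[0]
    if len(l2_grid) > 1:
        subjects = np.unique(study.subject_ids)
        inner_folds = []
        half = len(subjects) // 2
        for hold in (subjects[:half], subjects[half:]):
            val = np.isin(study.subject_ids, hold)
            if 0 < val.sum() < len(y) and _covers(y[~val]) and _covers(y[val]):
                inner_folds.append(val)
        if inner_folds:
            scores = []
            for alpha in l2_grid:
                accs = []
                for val in inner_folds:
                    clf = make_clf(alpha, len(np.unique(study.subject_ids[~val])))
                    clf.fit(X[~val], y[~val])
                    accs.append(np.mean(clf.predict(X[val]) == y[val]))
                scores.append(np.mean(accs))
            best_alpha = l2_grid[int(np.argmax(scores))]
    clf = make_clf(best_alpha, n_subjects)
    clf.fit(X, y)
    return _Baseline(mode, dictionary, clf, offset, scale)


def _covers(labels: np.ndarray) -> bool:
    return len(np.unique(labels)) >= 2


def accuracy_per_study(predictions: np.ndarray, truth: np.ndarray) -> float:
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have the same length")
    return float(np.mean(predictions == truth))


def balanced_accuracy_per_contrast(
    predictions: np.ndarray, truth: np.ndarray, n_contrasts: int
) -> dict[int, float]:
    """One-vs-rest (sensitivity + specificity) / 2 per contrast label.

    Chance level is 0.5 for every contrast.  Contrasts absent from the fold
    are reported as NaN rather than 0.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have the same length")
    out: dict[int, float] = {}
    for c in range(1, n_contrasts + 1):
        pos = truth == c
        if pos.sum() == 0:
            out[c] = float("nan")
            continue
        sens = np.mean(predictions[pos] == c)
        neg = ~pos
        spec = np.mean(predictions[neg] != c) if neg.sum() else float("nan")
        out[c] = float((sens + spec) / 2.0) if neg.sum() else float("nan")
    return out


def transfer_gain_summary(
    scores: ScoreTable | pd.DataFrame, method_a: str, method_b: str
) -> dict:
    """Accuracy deltas of method_a over method_b across study-by-split cells.

    Reports the per-study mean delta, the corpus mean and median gain, the
    fraction of study-by-split experiments improved, and the fraction of
    studies improved on average.
    """
    acc = scores.accuracy if isinstance(scores, ScoreTable) else scores
    a = acc[acc["method"] == method_a].set_index(["repeat", "study"])["accuracy"]
    b = acc[acc["method"] == method_b].set_index(["repeat", "study"])["accuracy"]
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise ValueError("methods do not cover identical repeats x studies")
    delta = (a - b.reindex(a.index)).rename("delta")
    per_study = delta.groupby("study").mean()
    return {
        "per_study_mean_delta": per_study,
        "mean_gain": float(delta.mean()),
        "median_gain": float(delta.median()),
        "fraction_experiments_improved": float((delta > 0).mean()),
        "fraction_studies_improved": float((per_study > 0).mean()),
    }


def evaluate_methods(
    corpus: MultiStudyCorpus,
    dictionary: Dictionary,
    cfg: TrainConfig,
    splits: SplitScheme,
    methods: tuple[str, ...] = ("multistudy", "voxel", "network"),
) -> ScoreTable:
    """Half-split evaluation of the multi-study model against baselines.

    For each repeat: the multi-study model is trained jointly on all train
    halves; each baseline is trained per study on its own train half; all
    are scored on the held-out halves.
    """
    acc_rows, bal_rows = [], []
    for r, assignment in enumerate(splits.assignments):
        train_corpus, test_corpus = split_corpus(corpus, assignment)
        predictions: dict[str, dict[str, np.ndarray]] = {m: {} for m in methods}
        if "multistudy" in methods:
            model = train_multistudy(train_corpus, dictionary, replace(cfg, seed=cfg.seed + r))
            for study in test_corpus.studies:
                predictions["multistudy"][study.study_id] = predict(
                    model, study.study_id, study.maps
                )
        for mode in ("voxel", "network"):
            if mode not in methods:
                continue
            for train_study, test_study in zip(train_corpus.studies, test_corpus.studies):
                baseline = fit_baseline(train_study, mode=mode, dictionary=dictionary)
                predictions[mode][test_study.study_id] = baseline.predict(test_study.maps)
        for study in test_corpus.studies:
            for method in methods:
                pred = predictions[method][study.study_id]
                acc_rows.append(
                    {
                        "repeat": r,
                        "study": study.study_id,
                        "method": method,
                        "accuracy": accuracy_per_study(pred, study.labels),
                    }
                )
                for c, ba in balanced_accuracy_per_contrast(
                    pred, study.labels, study.n_contrasts
                ).items():
                    bal_rows.append(
                        {
                            "repeat": r,
                            "study": study.study_id,
                            "contrast": study.contrast_names[c - 1],
                            "method": method,
                            "balanced_accuracy": ba,
                        }
                    )
    return ScoreTable(
        accuracy=pd.DataFrame.from_records(acc_rows),
        balanced=pd.DataFrame.from_records(bal_rows),
    )


def learning_curve(
    corpus: MultiStudyCorpus,
    dictionary: Dictionary,
    cfg: TrainConfig,
    subject_counts: list[int],
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy of multi-study vs voxel decoding as training subjects shrink.

    For each repeat, the test halves stay fixed while the training halves
    are subsampled to each requested subject count (clipped per study to
    availability, with a ``clipped`` flag in the output).  Columns:
    repeat, n_subjects_requested, study, method, accuracy, clipped.
    """
    splits = subject_half_splits(corpus, n_repeats=n_repeats, seed=seed)
    rng = np.random.default_rng(seed + 1)
    rows = []
    for r, assignment in enumerate(splits.assignments):
        full_train, test_corpus = split_corpus(corpus, assignment)
        for count in subject_counts:
            sub_studies = []
            clipped: dict[str, bool] = {}
            for study in full_train.studies:
                subjects = np.unique(study.subject_ids)
                clipped[study.study_id] = count > len(subjects)
                m = min(count, len(subjects))
                keep = None
                for _try in range(100):
                    cand = rng.choice(subjects, size=m, replace=False)
                    if _covers_all_contrasts(study, cand):
                        keep = cand
                        break
                if keep is None:
                    raise SplitError(
                        f"cannot keep all contrasts with {m} subjects in "
                        f"study {study.study_id!r}"
                    )
                sub_studies.append(study.subset(np.isin(study.subject_ids, keep)))
            sub_corpus = MultiStudyCorpus(studies=sub_studies, mask=corpus.mask)
            model = train_multistudy(
                sub_corpus, dictionary, replace(cfg, seed=cfg.seed + r)
            )
            for train_study, test_study in zip(sub_corpus.studies, test_corpus.studies):
                baseline = fit_baseline(train_study, mode="voxel")
                for method, pred in (
                    ("multistudy", predict(model, test_study.study_id, test_study.maps)),
                    ("voxel", baseline.predict(test_study.maps)),
                ):
                    rows.append(
                        {
                            "repeat": r,
                            "n_subjects_requested": count,
                            "study": test_study.study_id,
                            "method": method,
                            "accuracy": accuracy_per_study(pred, test_study.labels),
                            "clipped": clipped[test_study.study_id],
                        }
                    )
    return pd.DataFrame.from_records(rows)


@dataclass
class SimilarityReport:
    names: list[str]
    cosine: np.ndarray  # symmetric, unit diagonal
    linkage: np.ndarray  # scipy linkage matrix (average linkage)
    cophenetic_coefficient: float
    mean_abs_cosine: float

    def to_newick(self) -> str:
        from skbio import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.names)
        return str(tree)


def similarity_clustering(maps: np.ndarray, names: list[str]) -> SimilarityReport:
    """Cosine similarity structure of a set of classification maps.

    Average-linkage agglomeration on distance ``1 - cosine``; the cophenetic
    coefficient is the Pearson correlation between the condensed original
    distances and the tree's cophenetic distances.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    if maps.shape[0] < 3:
        raise ValueError("similarity clustering needs at least 3 maps")
    if len(names) != maps.shape[0]:
        raise ValueError("one name per map is required")
    norms = np.linalg.norm(maps, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm map passed to similarity clustering")
    unit = maps / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(cos, 1.0)
    n = cos.shape[0]
    iu = np.triu_indices(n, k=1)
    condensed = 1.0 - cos[iu]
    if np.allclose(condensed, condensed[0]):
        raise ValueError(
            "all pairwise distances equal: cophenetic coefficient undefined"
        )
    Z = sch.linkage(condensed, method="average")
    coph, _ = sch.cophenet(Z, condensed)
    mean_abs = float(np.mean(np.abs(cos[iu])))
    return SimilarityReport(
        names=list(names),
        cosine=cos,
        linkage=Z,
        cophenetic_coefficient=float(coph),
        mean_abs_cosine=mean_abs,
    )
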