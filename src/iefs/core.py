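"""The five-stage iterative ensemble feature selection (IEFS) framework.

A K-class problem is binarized one-versus-all into K tasks.  For each task,
balanced sampling (random undersampling or SMOTE) and filter feature
selection alternate for T steps: step i moves M_i samples toward class
balance and eliminates N_i features, where

    M_i = (S_M - S_m) / T        N_i = (N_M - N_n) / T

with S_M / S_m the majority / minority sizes, N_M the full feature count
and N_n the target signature size.  Non-integer intervals are realised as
floor per step with the last step absorbing the remainder, so the sums
bridge the gaps exactly.  After the T-th step the task is balanced and
holds exactly N_n features (FCBF may legitimately return fewer; the model
is then flagged short).  A binary classifier is trained on the filtered,
balanced data, and the K classifiers predict by majority vote, with ties
broken by positive-class confidence, then training class size, then
canonical class order.
"""

from __future__ import annotations

import io
import json
import pickle
import zipfile
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .datasets import ExpressionDataset, RunConfig
from .exceptions import PipelineError, ValidationError
from .filters import fcbf_select_n, mrmr_select, rank_by_relevance
from .sampling import BinaryTask, random_undersample, smote_oversample

__all__ = [
    "IterationSchedule",
    "SignatureModel",
    "EnsembleModel",
    "binarize",
    "build_schedule",
    "iefs_fit_binary",
    "ova_fit",
    "ova_predict",
    "save_model",
    "load_model",
    "derive_seed",
]


def derive_seed(seed: int, *indices: int) -> int:
    """Deterministic hierarchical sub-seed (always in [0, 2^31))."""
    h = int(seed) % (2**31)
    for ix in indices:
        h = (h * 1_000_003 + int(ix) + 1) % (2**31)
    return h


@dataclass(frozen=True)
class IterationSchedule:
    """Per-step sample interval M and feature interval N for T steps."""

    T: int
    M: tuple
    N: tuple

    def __post_init__(self) -> None:
        if self.T < 1 or len(self.M) != self.T or len(self.N) != self.T:
            raise ValidationError("schedule lists must have length T >= 1")
        if any(m < 0 for m in self.M) or any(n < 0 for n in self.N):
            raise ValidationError("schedule intervals must be >= 0")


def build_schedule(S_M: int, S_m: int, N_M: int, N_n: int, T: int) -> IterationSchedule:
    """Split the sample gap S_M - S_m and feature gap N_M - N_n over T steps.

    Each step gets the floor of gap/T; the last step absorbs the remainder.
    """
    if not (S_M >= S_m >= 1):
        raise ValidationError(f"need S_M >= S_m >= 1, got {S_M}, {S_m}")
    if not (N_M >= N_n >= 1):
        raise ValidationError(f"need N_M >= N_n >= 1, got {N_M}, {N_n}")
    if T < 1:
        raise ValidationError("T must be >= 1")

    def split(gap: int) -> tuple:
        base = gap // T
        steps = [base] * T
        steps[-1] += gap - base * T
        return tuple(steps)

    return IterationSchedule(T=T, M=split(S_M - S_m), N=split(N_M - N_n))


def binarize(dataset: ExpressionDataset, target_class: str) -> BinaryTask:
    """One-versus-all view: target class positive, everything else negative."""
    labels = dataset.labels.astype(str)
    if target_class not in set(labels):
        raise ValidationError(f"unknown class {target_class!r}")
    return BinaryTask(
        X=dataset.matrix.copy(),
        y=labels == target_class,
        positive_class=str(target_class),
    )


@dataclass
class SignatureModel:
    """Selected signature plus trained binary classifier for one class."""

    positive_class: str
    selected_features: list[int]  # original column indices, selection order
    feature_ids: list[str]
    classifier: object
    schedule: IterationSchedule
    short: bool = False
    n_pos_train: int = 0
    classifier_kind: str = "knn"

    def confidences(self, X: np.ndarray) -> np.ndarray:
        """Positive-class confidence in [0, 1] for each row of ``X``
        (already projected onto ``selected_features``)."""
        if self.classifier_kind == "knn":
            proba = self.classifier.predict_proba(X)
            pos_col = list(self.classifier.classes_).index(1)
            return proba[:, pos_col]
        d = self.classifier.decision_function(X)
        return 1.0 / (1.0 + np.exp(-d))

    def votes(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict(X).astype(int)


@dataclass
class EnsembleModel:
    """One SignatureModel per class plus the majority-vote policy."""

    members: list[SignatureModel]
    class_order: list[str]
    training_class_sizes: dict[str, int]
    feature_ids: list[str]
    config: RunConfig
    tie_policy: str = "confidence,training-prior,class-order"

    def __post_init__(self) -> None:
        if len(self.members) != len(self.class_order):
            raise ValidationError("exactly one member per class required")
        member_classes = [m.positive_class for m in self.members]
        if member_classes != list(self.class_order):
            raise ValidationError("members must follow class_order")


def _make_classifier(config: RunConfig, n_train: int):
    if config.classifier == "knn":
        return KNeighborsClassifier(n_neighbors=min(config.knn_k, n_train))
    # WEKA-era default SVM: linear kernel, C = 1
    return SVC(kernel="linear", C=1.0)


def _select(task: BinaryTask, n_keep: int, config: RunConfig):
    """Run the configured selector; returns (current-column order, short)."""
    if config.selector == "ranking":
        ranked = rank_by_relevance(task.X, task.y, n_keep, n_bins=config.n_bins)
        return ranked.feature_indices.tolist(), False
    if config.selector == "fcbf":
        sub = fcbf_select_n(task.X, task.y, n_keep, n_bins=config.n_bins)
        return list(sub.feature_indices), sub.short
    sub = mrmr_select(task.X, task.y, n_keep,
                      window=max(config.mrmr_window, n_keep),
                      n_bins=config.n_bins)
    return list(sub.feature_indices), False


def iefs_fit_binary(task: BinaryTask, config: RunConfig) -> SignatureModel:
    """Alternate sampling and selection for T steps, then fit the classifier.

    Within one step sampling precedes selection, and elimination applies to
    the working task, so later SMOTE distances use surviving features only.
    With sampler 'none' and T=1 this collapses to the plain one-shot filter
    baseline.
    """
    n_features0 = task.X.shape[1]
    if config.n_features > n_features0:
        raise ValidationError(
            f"target n_features={config.n_features} exceeds {n_features0}"
        )
    schedule = build_schedule(
        S_M=task.majority_size, S_m=task.minority_size,
        N_M=n_features0, N_n=config.n_features, T=config.T,
    )
    short = False
    for i, (m_i, n_i) in enumerate(zip(schedule.M, schedule.N)):
        try:
            if config.sampler == "undersample" and m_i > 0:
                task = random_undersample(task, m_i, seed=derive_seed(config.seed, i))
            elif config.sampler == "oversample" and m_i > 0:
                task = smote_oversample(task, m_i, k=config.smote_k,
                                        seed=derive_seed(config.seed, i))
            keep = task.X.shape[1] - n_i
            order, step_short = _select(task, keep, config)
            short = short or step_short
            task = task.select_features(order)
        except Exception as exc:
            raise PipelineError(
                f"class {task.positive_class!r}, step {i + 1}: {exc}"
            ) from exc
    clf = _make_classifier(config, n_train=task.X.shape[0])
    clf.fit(task.X, task.y.astype(int))
    return SignatureModel(
        positive_class=task.positive_class,
        selected_features=task.feature_indices.tolist(),
        feature_ids=[],
        classifier=clf,
        schedule=schedule,
        short=short,
        n_pos_train=task.n_pos,
        classifier_kind=config.classifier,
    )


def ova_fit(dataset: ExpressionDataset, config: RunConfig) -> EnsembleModel:
    """Fit one IEFS signature model per class, independently per class.

    Each class uses its own RNG substream (seed + class index), so adding a
    class never perturbs the other classes' results.
    """
    classes = dataset.classes
    members = []
    for k, cls in enumerate(classes):
        task = binarize(dataset, cls)
        sub_config = config.replace(seed=derive_seed(config.seed, k))
        try:
            model = iefs_fit_binary(task, sub_config)
        except PipelineError as exc:
            raise PipelineError(f"class {cls!r}: {exc}") from exc
        model.feature_ids = [dataset.feature_ids[j] for j in model.selected_features]
        members.append(model)
    return EnsembleModel(
        members=members,
        class_order=classes,
        training_class_sizes=dataset.class_counts(),
        feature_ids=list(dataset.feature_ids),
        config=config,
    )


def _project(model: EnsembleModel, matrix: np.ndarray,
             feature_ids: list[str] | None):
    """Column positions of each member's signature in the prediction input."""
    if feature_ids is None:
        if matrix.shape[1] != len(model.feature_ids):
            raise ValidationError(
                "matrix width differs from training features; pass feature_ids"
            )
        pos = {fid: j for j, fid in enumerate(model.feature_ids)}
    else:
        pos = {fid: j for j, fid in enumerate(feature_ids)}
    cols_per_member = []
    for member in model.members:
        cols = []
        for fid in member.feature_ids:
            if fid not in pos:
                raise ValidationError(
                    f"feature {fid!r} required by class {member.positive_class!r} "
                    f"is missing from the input"
                )
            cols.append(pos[fid])
        cols_per_member.append(np.asarray(cols, dtype=int))
    return cols_per_member


def ova_predict(model: EnsembleModel, matrix: np.ndarray,
                feature_ids: list[str] | None = None):
    """Majority vote across the K one-versus-all members.

    Returns ``(labels, confidences)`` where ``confidences`` has one column
    per class in ``model.class_order``.  Ties (including the zero-vote
    case) fall back to the highest positive-class confidence, then the
    largest training class, then class order.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValidationError("expected a 2-D matrix of samples x features")
    cols = _project(model, matrix, feature_ids)
    n = matrix.shape[0]
    K = len(model.members)
    votes = np.zeros((n, K), dtype=int)
    conf = np.zeros((n, K))
    for k, member in enumerate(model.members):
        Xk = matrix[:, cols[k]]
        votes[:, k] = member.votes(Xk)
        conf[:, k] = member.confidences(Xk)
    sizes = np.array([model.training_class_sizes[c] for c in model.class_order])
    out = np.empty(n, dtype=object)
    for i in range(n):
        best = _vote_winner(votes[i], conf[i], sizes)
        out[i] = model.class_order[best]
    return out, conf


def _vote_winner(votes: np.ndarray, conf: np.ndarray, sizes: np.ndarray) -> int:
    top = votes.max()
    tied = np.flatnonzero(votes == top)
    if len(tied) > 1 or top == 0:
        tied = np.flatnonzero(votes == top)  # zero-vote fallback: all classes
        best_conf = conf[tied].max()
        tied = tied[conf[tied] == best_conf]
    if len(tied) > 1:
        big = sizes[tied].max()
        tied = tied[sizes[tied] == big]
    return int(tied[0])


# ---------------------------------------------------------------------------
# persistence: zip archive of plain-text signatures + pickled classifiers
# ---------------------------------------------------------------------------

def save_model(model: EnsembleModel, path) -> None:
    """Write the ensemble to a single zip archive.

    The archive holds one plain-text signature file per class (one gene id
    per line, selection order) as the interchange surface, a JSON manifest
    with the run configuration, and the pickled classifiers.
    """
    manifest = {
        "class_order": model.class_order,
        "tie_policy": model.tie_policy,
        "training_class_sizes": model.training_class_sizes,
        "config": model.config.to_dict(),
        "feature_ids": model.feature_ids,
        "members": [
            {
                "positive_class": m.positive_class,
                "selected_features": m.selected_features,
                "feature_ids": m.feature_ids,
                "short": m.short,
                "n_pos_train": m.n_pos_train,
                "classifier_kind": m.classifier_kind,
                "schedule": {"T": m.schedule.T, "M": list(m.schedule.M),
                             "N": list(m.schedule.N)},
            }
            for m in model.members
        ],
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
        for m in model.members:
            zf.writestr(f"signatures/{m.positive_class}.txt",
                        "\n".join(m.feature_ids) + "\n")
        buf = io.BytesIO()
        pickle.dump([m.classifier for m in model.members], buf)
        zf.writestr("classifiers.pkl", buf.getvalue())


def load_model(path) -> EnsembleModel:
    with zipfile.ZipFile(path, "r") as zf:
        manifest = json.loads(zf.read("manifest.json"))
        classifiers = pickle.loads(zf.read("classifiers.pkl"))
    members = []
    for meta, clf in zip(manifest["members"], classifiers):
        members.append(SignatureModel(
            positive_class=meta["positive_class"],
            selected_features=list(meta["selected_features"]),
            feature_ids=list(meta["feature_ids"]),
            classifier=clf,
            schedule=IterationSchedule(
                T=meta["schedule"]["T"],
                M=tuple(meta["schedule"]["M"]),
                N=tuple(meta["schedule"]["N"]),
            ),
            short=meta["short"],
            n_pos_train=meta["n_pos_train"],
            classifier_kind=meta["classifier_kind"],
        ))
    return EnsembleModel(
        members=members,
        class_order=list(manifest["class_order"]),
        training_class_sizes={k: int(v) for k, v in
                              manifest["training_class_sizes"].items()},
        feature_ids=list(manifest["feature_ids"]),
        config=RunConfig.from_mapping(manifest["config"]),
        tie_policy=manifest["tie_policy"],
    )
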