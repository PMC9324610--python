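"""Experimental protocols: subject-grouped cross-validation, personalized
classification, out-of-distribution detection, generalization to unseen
classes, embedding/reference-size sweeps, and Gini-importance feature
selection.

Model kinds evaluated side by side under one cross-validation plan:

* ``FCN`` — impersonal classifier; direct softmax predictions.
* ``PEF`` — personalized engineered features; per-subject k-NN over scaled
  statistical features.
* ``PDF`` — personalized deep features; k-NN over embeddings from a
  cross-entropy-trained core.
* ``PTN`` — personalized triplet network; k-NN over embeddings trained with
  mixed subject/random triplets.
* ``PTN_random`` — triplet training with unconstrained random triplets only.

For every test subject the time series of each activity is split along the
temporal axis (first half reference, second half test) *before* windowing,
so reference and test segments can never share a source sample; every
experiment asserts this. Accuracy statistics aggregate over subjects, not
folds, and all model kinds compared under one plan see identical folds,
identical test segments, and identical seeded class splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score

from .fcn import FCNConfig, FCNModel, build_fcn, embed, predict_labels, train_classifier
from .features import FeatureScaler, compute_feature_matrix, fit_scaler
from .personalize import (
    ReferenceStore,
    knn_classify_batch,
    ood_score_batch,
    softmax_confidence,
)
from .preprocessing import (
    ActivityRecording,
    SegmentSet,
    SplitSpec,
    segment_recordings,
    segments_overlap,
    temporal_reference_split,
)
from .triplet import (
    TripletLossConfig,
    TripletSamplerConfig,
    train_triplet_embedder,
)

MODEL_KINDS = ("FCN", "PEF", "PDF", "PTN", "PTN_random")
PERSONALIZED_KINDS = ("PEF", "PDF", "PTN", "PTN_random")


# ---- cross-validation plan --------------------------------------------------


@dataclass
class CVPlan:
    """Subject-to-fold assignment, identical for every model kind compared."""

    folds: list[np.ndarray]  # each entry: array of subject ids in that test fold
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    @property
    def subjects(self) -> np.ndarray:
        return np.concatenate(self.folds)

    def plan_hash(self) -> str:
        return "|".join(",".join(map(str, f)) for f in self.folds)


def grouped_kfold(subject_ids, n_folds: int = 5, seed: int = 0) -> CVPlan:
    """Disjoint, exhaustive, size-balanced (+-1) subject folds, seeded."""
    subjects = np.unique(np.asarray(subject_ids))
    if subjects.shape[0] < n_folds:
        raise ValueError(f"{subjects.shape[0]} subjects cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    shuffled = subjects[rng.permutation(subjects.shape[0])]
    return CVPlan(folds=[np.sort(f) for f in np.array_split(shuffled, n_folds)], seed=seed)


# ---- results ---------------------------------------------------------------


@dataclass
class ExperimentResult:
    """Per-subject metric values plus subject-level mean and std (ddof=1)."""

    model_kind: str
    metric: str
    per_subject: dict
    mean: float
    std: float
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_per_subject(cls, model_kind: str, metric: str, per_subject: dict, **extras):
        vals = np.asarray(list(per_subject.values()), dtype=float)
        return cls(
            model_kind=model_kind,
            metric=metric,
            per_subject=dict(per_subject),
            mean=float(vals.mean()),
            std=float(vals.std(ddof=1)) if vals.shape[0] > 1 else 0.0,
            extras=extras,
        )

    @property
    def spread(self) -> float:
        vals = np.asarray(list(self.per_subject.values()), dtype=float)
        return float(vals.max() - vals.min())


def significantly_different(a: ExperimentResult, b: ExperimentResult) -> bool:
    """Reporting convention: means more than two standard deviations apart."""
    return abs(a.mean - b.mean) > 2.0 * max(a.std, b.std)


# ---- configuration ----------------------------------------------------------


@dataclass
class EvalConfig:
    """Shared knobs for every experiment under one comparison."""

    window_seconds: float = 4.0
    overlap: float = 0.8
    resample_hz: float | None = None
    reference_fraction: float = 0.5
    k: int = 3
    fcn: FCNConfig = field(default_factory=FCNConfig)
    sampler: TripletSamplerConfig = field(default_factory=TripletSamplerConfig)
    loss: TripletLossConfig = field(default_factory=TripletLossConfig)
    epochs: int | None = None  # None -> fcn.epochs
    n_features: int | None = None  # PEF Gini-selected subset size


# ---- embedding pipelines ----------------------------------------------------


class FeaturePipeline:
    """Engineered features -> fitted scaler -> optional Gini-selected subset."""

    def __init__(self, scaler: FeatureScaler, selected: np.ndarray | None = None):
        self.scaler = scaler
        self.selected = selected

    def transform(self, segments: SegmentSet) -> np.ndarray:
        rows = self.scaler.transform(compute_feature_matrix(segments))
        if self.selected is not None:
            rows = rows[:, self.selected]
        return rows


class DeepEmbedder:
    """Unit-norm embeddings from a trained FCN core."""

    def __init__(self, model: FCNModel):
        self.model = model

    def transform(self, segments: SegmentSet) -> np.ndarray:
        return embed(self.model, segments).rows


class OracleEmbedder:
    """Perfectly separable embedding: one distinct unit vector per class.

    A diagnostic stand-in for a converged model; personalized accuracy under
    it must be exactly 1.
    """

    def __init__(self, classes) -> None:
        self.classes = {c: i for i, c in enumerate(np.unique(np.asarray(classes)))}

    def transform(self, segments: SegmentSet) -> np.ndarray:
        rows = np.zeros((len(segments), len(self.classes)))
        for i, lab in enumerate(segments.labels):
            rows[i, self.classes[lab]] = 1.0
        return rows


def _derived_seed(config: EvalConfig, plan: CVPlan, fold: int) -> int:
    return (config.fcn.seed + 7919 * plan.seed + fold) % (2**31 - 1)


def _fit_pipeline(
    model_kind: str,
    train_segments: SegmentSet,
    config: EvalConfig,
    seed: int,
    n_classes: int,
):
    """Train the per-fold model for one kind; returns (pipeline, model_or_None)."""
    n_channels = train_segments.segments[0].n_channels
    if model_kind == "PEF":
        feats = compute_feature_matrix(train_segments)
        scaler = fit_scaler(feats)
        selected = None
        if config.n_features is not None:
            selected = gini_feature_selection(
                scaler.transform(feats), train_segments.labels, config.n_features, seed=seed
            )
        return FeaturePipeline(scaler, selected), None
    if model_kind in ("FCN", "PDF"):
        cfg = replace(config.fcn, n_channels=n_channels, n_classes=n_classes, seed=seed)
        model = build_fcn(cfg, with_classifier_head=True)
        train_classifier(model, train_segments, epochs=config.epochs)
        return DeepEmbedder(model), model
    if model_kind in ("PTN", "PTN_random"):
        cfg = replace(config.fcn, n_channels=n_channels, n_classes=None, seed=seed)
        model = build_fcn(cfg, with_classifier_head=False)
        mode = "random" if model_kind == "PTN_random" else config.sampler.mode
        sampler = replace(config.sampler, mode=mode, seed=seed)
        train_triplet_embedder(
            model, train_segments, sampler, config.loss, epochs=config.epochs
        )
        return DeepEmbedder(model), model
    raise ValueError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")


# ---- shared per-subject plumbing --------------------------------------------


def assert_no_leakage(ref_segments: SegmentSet, test_segments: SegmentSet) -> int:
    """Count (and require zero) reference/test pairs sharing source samples."""
    pairs = 0
    for r in ref_segments:
        for t in test_segments:
            if segments_overlap(r, t):
                pairs += 1
    if pairs:
        raise AssertionError(f"{pairs} reference/test segment pairs share source samples")
    return pairs


def _subject_split_segments(
    recordings: list[ActivityRecording], config: EvalConfig
) -> tuple[SegmentSet, SegmentSet]:
    """Temporal reference/test split + windowing for one subject's recordings."""
    spec = SplitSpec(reference_fraction=config.reference_fraction)
    refs, tests = [], []
    for rec in recordings:
        ref_rec, test_rec = temporal_reference_split(rec, spec)
        refs.append(ref_rec)
        tests.append(test_rec)
    ref_segments = segment_recordings(refs, config.window_seconds, config.overlap, config.resample_hz)
    test_segments = segment_recordings(tests, config.window_seconds, config.overlap, config.resample_hz)
    assert_no_leakage(ref_segments, test_segments)
    return ref_segments, test_segments


def _split_dataset(dataset, plan: CVPlan, fold: int):
    test_subjects = set(plan.folds[fold].tolist())
    train_recs = [r for r in dataset if r.subject_id not in test_subjects]
    test_recs = [r for r in dataset if r.subject_id in test_subjects]
    return train_recs, test_recs


# ---- experiments -------------------------------------------------------------


def run_classification_experiment(
    dataset: list[ActivityRecording],
    model_kind: str,
    plan: CVPlan,
    config: EvalConfig | None = None,
    folds: list[int] | None = None,
    embedder_override=None,
) -> ExperimentResult:
    """Per-subject classification accuracy under subject-grouped CV.

    All model kinds are scored on the same temporal test-half segments of
    each test subject; personalized kinds additionally enroll the temporal
    reference half as their k-NN store.
    """
    config = config or EvalConfig()
    folds = list(range(plan.n_folds)) if folds is None else folds
    per_subject: dict = {}
    for fold in folds:
        train_recs, test_recs = _split_dataset(dataset, plan, fold)
        train_segments = segment_recordings(
            train_recs, config.window_seconds, config.overlap, config.resample_hz
        )
        classes = np.unique(train_segments.labels)
        seed = _derived_seed(config, plan, fold)
        if embedder_override is not None:
            pipeline, model = embedder_override, None
        else:
            pipeline, model = _fit_pipeline(model_kind, train_segments, config, seed, classes.shape[0])
        for subject in plan.folds[fold]:
            subj_recs = [r for r in test_recs if r.subject_id == subject]
            ref_segments, test_segments = _subject_split_segments(subj_recs, config)
            if len(test_segments) == 0:
                warnings.warn(f"subject {subject} has no test segments; excluded")
                continue
            if model_kind == "FCN" and embedder_override is None:
                preds = predict_labels(model, test_segments)
            else:
                if len(ref_segments) < config.k:
                    warnings.warn(f"subject {subject} has fewer than k reference segments; excluded")
                    continue
                store = ReferenceStore(
                    subject, pipeline.transform(ref_segments), ref_segments.labels
                )
                preds = knn_classify_batch(store, pipeline.transform(test_segments), k=config.k)
            per_subject[str(subject)] = float(np.mean(preds == test_segments.labels))
    return ExperimentResult.from_per_subject(
        model_kind, "accuracy", per_subject, plan_hash=plan.plan_hash(), leakage_pairs=0
    )


def _seeded_class_split(classes: np.ndarray, fraction: float, plan: CVPlan, fold: int):
    """Seeded, fold-indexed class split shared by every model kind."""
    rng = np.random.default_rng(plan.seed * 1000 + fold)
    k = classes.shape[0]
    n_first = int(round(fraction * k))
    perm = rng.permutation(k)
    return classes[np.sort(perm[:n_first])], classes[np.sort(perm[n_first:])]


def ood_experiment(
    dataset: list[ActivityRecording],
    model_kind: str,
    plan: CVPlan,
    config: EvalConfig | None = None,
    in_class_fraction: float = 0.7,
    folds: list[int] | None = None,
) -> ExperimentResult:
    """Out-of-distribution detection AUROC, aggregated by subject.

    Models are trained on a seeded 70% subset of the activity classes; test
    subjects are scored on all classes. Personalized kinds score each test
    segment by mean distance to its 3 nearest in-distribution reference
    embeddings; the impersonal FCN baseline uses 1 - max softmax.
    """
    config = config or EvalConfig()
    folds = list(range(plan.n_folds)) if folds is None else folds
    per_subject: dict = {}
    all_classes = np.unique(np.concatenate([np.unique(r.labels) for r in dataset]))
    for fold in folds:
        in_classes, out_classes = _seeded_class_split(all_classes, in_class_fraction, plan, fold)
        if in_classes.shape[0] < 2 or out_classes.shape[0] < 1:
            raise ValueError(
                f"degenerate class split: {in_classes.shape[0]} in / {out_classes.shape[0]} out"
            )
        in_set = set(in_classes.tolist())
        train_recs, test_recs = _split_dataset(dataset, plan, fold)
        train_segments = segment_recordings(
            train_recs, config.window_seconds, config.overlap, config.resample_hz
        )
        train_segments = train_segments.subset(
            np.array([lab in in_set for lab in train_segments.labels])
        )
        seed = _derived_seed(config, plan, fold)
        pipeline, model = _fit_pipeline(model_kind, train_segments, config, seed, in_classes.shape[0])
        for subject in plan.folds[fold]:
            subj_recs = [r for r in test_recs if r.subject_id == subject]
            ref_segments, test_segments = _subject_split_segments(subj_recs, config)
            y_out = np.array([lab not in in_set for lab in test_segments.labels])
            if y_out.all() or not y_out.any():
                warnings.warn(f"subject {subject} lacks both in- and out-classes; excluded")
                continue
            if model_kind == "FCN":
                scores = 1.0 - softmax_confidence(model, test_segments)
            else:
                ref_mask = np.array([lab in in_set for lab in ref_segments.labels])
                ref_in = ref_segments.subset(ref_mask)
                if len(ref_in) < 3:
                    warnings.warn(f"subject {subject} has <3 in-distribution references; excluded")
                    continue
                store = ReferenceStore(subject, pipeline.transform(ref_in), ref_in.labels)
                scores = ood_score_batch(store, pipeline.transform(test_segments), k=3)
            per_subject[str(subject)] = float(roc_auc_score(y_out, scores))
    return ExperimentResult.from_per_subject(
        model_kind, "auroc", per_subject, plan_hash=plan.plan_hash(),
        in_class_fraction=in_class_fraction,
    )


def generalization_experiment(
    dataset: list[ActivityRecording],
    model_kind: str,
    plan: CVPlan,
    config: EvalConfig | None = None,
    withheld_fraction: float = 0.3,
    folds: list[int] | None = None,
    embedder_override=None,
) -> ExperimentResult:
    """Accuracy over ALL classes when 30% were withheld from embedder training.

    Reference stores include the withheld classes (few-shot enrollment of
    novel activities); the impersonal FCN cannot participate because its
    softmax output size is fixed at training time. ``extras`` carries the
    per-subject accuracy restricted to withheld-class segments.
    """
    if model_kind not in PERSONALIZED_KINDS:
        raise ValueError("generalization requires a personalized model kind")
    config = config or EvalConfig()
    folds = list(range(plan.n_folds)) if folds is None else folds
    per_subject: dict = {}
    withheld_acc: dict = {}
    all_classes = np.unique(np.concatenate([np.unique(r.labels) for r in dataset]))
    for fold in folds:
        if withheld_fraction > 0:
            withheld, kept = _seeded_class_split(all_classes, withheld_fraction, plan, fold)
        else:
            withheld, kept = all_classes[:0], all_classes
        withheld_set = set(withheld.tolist())
        train_recs, test_recs = _split_dataset(dataset, plan, fold)
        train_segments = segment_recordings(
            train_recs, config.window_seconds, config.overlap, config.resample_hz
        )
        train_segments = train_segments.subset(
            np.array([lab not in withheld_set for lab in train_segments.labels])
        )
        seed = _derived_seed(config, plan, fold)
        if embedder_override is not None:
            pipeline = embedder_override
        else:
            pipeline, _ = _fit_pipeline(model_kind, train_segments, config, seed, kept.shape[0])
        for subject in plan.folds[fold]:
            subj_recs = [r for r in test_recs if r.subject_id == subject]
            ref_segments, test_segments = _subject_split_segments(subj_recs, config)
            if len(ref_segments) < config.k or len(test_segments) == 0:
                warnings.warn(f"subject {subject} lacks usable segments; excluded")
                continue
            store = ReferenceStore(subject, pipeline.transform(ref_segments), ref_segments.labels)
            preds = knn_classify_batch(store, pipeline.transform(test_segments), k=config.k)
            correct = preds == test_segments.labels
            per_subject[str(subject)] = float(np.mean(correct))
            on_withheld = np.array([lab in withheld_set for lab in test_segments.labels])
            if on_withheld.any():
                withheld_acc[str(subject)] = float(np.mean(correct[on_withheld]))
    return ExperimentResult.from_per_subject(
        model_kind, "accuracy", per_subject,
        plan_hash=plan.plan_hash(),
        withheld_fraction=withheld_fraction,
        withheld_accuracy_per_subject=withheld_acc,
        n_classes_total=int(all_classes.shape[0]),
    )


def embedding_size_sweep(
    dataset: list[ActivityRecording],
    sizes: list[int],
    plan: CVPlan,
    model_kind: str = "PTN",
    config: EvalConfig | None = None,
    folds: list[int] | None = None,
) -> list[ExperimentResult]:
    """Classification accuracy as a function of embedding dimensionality.

    Deep kinds adjust the final dense projection; PEF keeps the top-n
    features ranked by Gini importance.
    """
    config = config or EvalConfig()
    results = []
    for size in sizes:
        if size <= 0:
            raise ValueError("embedding sizes must be positive")
        if model_kind == "PEF":
            cfg = replace(config, n_features=size)
        else:
            cfg = replace(config, fcn=replace(config.fcn, embedding_dim=size))
        res = run_classification_experiment(dataset, model_kind, plan, cfg, folds=folds)
        res.extras["embedding_size"] = size
        results.append(res)
    return results


def _enrollment_order(segments: SegmentSet) -> np.ndarray:
    """Round-robin enrollment order: earliest segment of each class first.

    Sort key is (temporal rank within class, class id); taking the first n
    indices mimics a subject enrolling a few examples of every activity in
    turn, and makes small reference budgets drop whole classes only when the
    budget is below the class count.
    """
    labels = segments.labels
    starts = segments.intervals[:, 0]
    sources = segments.source_ids
    ranks = np.empty(len(segments), dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        order = idx[np.lexsort((starts[idx], sources[idx]))]
        ranks[order] = np.arange(idx.shape[0])
    return np.lexsort((labels.astype(str), ranks))


def reference_size_sweep(
    dataset: list[ActivityRecording],
    plan: CVPlan,
    model_kind: str = "PTN",
    sizes: tuple[int, ...] = (4, 8, 16, 24),
    config: EvalConfig | None = None,
    folds: list[int] | None = None,
) -> list[ExperimentResult]:
    """Accuracy versus per-subject reference budget, on a fixed test set.

    The embedder is trained once per fold; each budget n keeps the first n
    reference segments in enrollment order (see :func:`_enrollment_order`)
    and re-runs k-NN inference on the identical test segments.
    """
    if model_kind not in PERSONALIZED_KINDS:
        raise ValueError("reference-size sweep applies to personalized kinds")
    config = config or EvalConfig()
    folds = list(range(plan.n_folds)) if folds is None else folds
    per_subject_by_size: dict[int, dict] = {s: {} for s in sizes}
    for fold in folds:
        train_recs, test_recs = _split_dataset(dataset, plan, fold)
        train_segments = segment_recordings(
            train_recs, config.window_seconds, config.overlap, config.resample_hz
        )
        classes = np.unique(train_segments.labels)
        seed = _derived_seed(config, plan, fold)
        pipeline, _ = _fit_pipeline(model_kind, train_segments, config, seed, classes.shape[0])
        for subject in plan.folds[fold]:
            subj_recs = [r for r in test_recs if r.subject_id == subject]
            ref_segments, test_segments = _subject_split_segments(subj_recs, config)
            if len(test_segments) == 0 or len(ref_segments) == 0:
                continue
            order = _enrollment_order(ref_segments)
            test_rows = pipeline.transform(test_segments)
            ref_rows = pipeline.transform(ref_segments)
            labels = ref_segments.labels
            for size in sizes:
                n = min(size, len(ref_segments))
                if n < size:
                    warnings.warn(
                        f"subject {subject}: only {n} reference segments available for budget {size}"
                    )
                if n < config.k:
                    continue
                keep = order[:n]
                store = ReferenceStore(subject, ref_rows[keep], labels[keep])
                preds = knn_classify_batch(store, test_rows, k=config.k)
                per_subject_by_size[size][str(subject)] = float(np.mean(preds == test_segments.labels))
    results = []
    for size in sizes:
        res = ExperimentResult.from_per_subject(
            model_kind, "accuracy", per_subject_by_size[size], plan_hash=plan.plan_hash()
        )
        res.extras["reference_size"] = size
        results.append(res)
    return results


# ---- feature selection & metrics ---------------------------------------------


def gini_feature_selection(features: np.ndarray, labels, n_select: int, seed: int = 0) -> np.ndarray:
    """Top-n feature indices by mean impurity decrease of a seeded
    250-tree extremely-randomized-trees classifier."""
    from sklearn.ensemble import ExtraTreesClassifier

    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if n_select > features.shape[1]:
        raise ValueError("cannot select more features than available")
    if np.unique(labels).shape[0] < 2:
        raise ValueError("feature selection requires at least 2 classes")
    forest = ExtraTreesClassifier(n_estimators=250, random_state=seed)
    forest.fit(features, labels)
    imp = forest.feature_importances_
    order = np.lexsort((np.arange(imp.shape[0]), -imp))
    return np.sort(order[:n_select])


def auroc(y_true, scores) -> float:
    """Area under the ROC curve (larger score = positive class)."""
    return float(roc_auc_score(np.asarray(y_true), np.asarray(scores)))
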