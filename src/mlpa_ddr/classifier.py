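"""Nested two-stage SVM classifier and ordination of FI profiles.

Stage 1 decides functional vs dysfunctional from the six cluster-I gene
fold inductions (the irradiation-response axis). Only if stage 1 calls a
sample dysfunctional is stage 2 consulted, which decides p53- vs
ATM-dysfunctional from all ten panel genes. Stage 2 is fitted exclusively
on biallelic TP53- and ATM-defective training samples.

Features are log2(FI), standardized per feature with statistics learned on
the training data only: fold inductions are ratio-scale and right-skewed,
and the log makes induction and repression symmetric. Default SVM: linear
kernel with C = 10 — close to a hard-margin maximum-margin rule, so
linearly separable training cohorts are classified perfectly while some
regularization remains; kernel and C are configurable.

Also provides classical (Torgerson) multidimensional scaling of log2-FI
vectors for visual confirmation that genotype groups separate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from .panel_model import (
    CallValue,
    FoldInductionProfile,
    FunctionalCall,
    GenotypeLabel,
    PanelDefinition,
    SampleMetadata,
    TRAINING_GENOTYPES,
    logger,
)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the nested classifier.

    cv: "loo" for leave-one-out, or an integer k for seeded k-fold.
    class_weight: None or "balanced" (no weighting by default).
    """

    kernel: str = "linear"
    C: float = 10.0
    class_weight: str | None = None
    log_base: float = 2.0
    standardize: bool = True
    cv: str | int = "loo"
    seed: int = 0


@dataclass
class _Stage:
    """One fitted margin classifier plus its preprocessing statistics."""

    feature_order: list[str]
    mean: np.ndarray
    scale: np.ndarray
    svm: SVC

    def transform(self, profile: FoldInductionProfile, log_base: float) -> np.ndarray:
        x = np.array(
            [profile.fi[g] for g in self.feature_order], dtype=float
        )
        x = np.log(x) / np.log(log_base)
        return (x - self.mean) / self.scale

    def margin(self, profile: FoldInductionProfile, log_base: float) -> float:
        z = self.transform(profile, log_base).reshape(1, -1)
        return float(self.svm.decision_function(z)[0])


@dataclass
class NestedClassifier:
    stage1: _Stage
    stage2: _Stage
    config: TrainingConfig

    # -- prediction --------------------------------------------------------

    def predict(self, profile: FoldInductionProfile) -> FunctionalCall:
        """Classify one profile. Positive stage-1 margin means
        dysfunctional; positive stage-2 margin means p53-dysfunctional."""
        missing = [
            g
            for g in set(self.stage1.feature_order) | set(self.stage2.feature_order)
            if g not in profile.fi
        ]
        if missing:
            raise ValueError(
                f"sample {profile.sample_id}: missing features {sorted(missing)}"
            )
        m1 = self.stage1.margin(profile, self.config.log_base)
        if m1 <= 0:
            return FunctionalCall(
                sample_id=profile.sample_id,
                value=CallValue.FUNCTIONAL,
                stage1_margin=m1,
            )
        m2 = self.stage2.margin(profile, self.config.log_base)
        value = (
            CallValue.P53_DYSFUNCTIONAL if m2 > 0 else CallValue.ATM_DYSFUNCTIONAL
        )
        return FunctionalCall(
            sample_id=profile.sample_id,
            value=value,
            stage1_margin=m1,
            stage2_margin=m2,
        )

    def predict_many(
        self, profiles: Iterable[FoldInductionProfile]
    ) -> list[FunctionalCall]:
        return [self.predict(p) for p in profiles]

    # -- serialization (linear kernel only) --------------------------------

    def to_json(self, path: str | Path) -> None:
        if self.config.kernel != "linear":
            raise NotImplementedError(
                "model serialization is defined for the linear kernel only"
            )

        def stage_doc(s: _Stage) -> dict:
            return {
                "feature_order": s.feature_order,
                "mean": s.mean.tolist(),
                "scale": s.scale.tolist(),
                "coef": s.svm.coef_[0].tolist(),
                "intercept": float(s.svm.intercept_[0]),
            }

        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "config": {
                "kernel": self.config.kernel,
                "C": self.config.C,
                "class_weight": self.config.class_weight,
                "log_base": self.config.log_base,
                "standardize": self.config.standardize,
            },
            "stage1": stage_doc(self.stage1),
            "stage2": stage_doc(self.stage2),
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "NestedClassifier":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        cfg = TrainingConfig(**doc["config"])

        def stage_from(d: dict) -> _Stage:
            svm = _LinearDecision(np.asarray(d["coef"]), float(d["intercept"]))
            return _Stage(
                feature_order=list(d["feature_order"]),
                mean=np.asarray(d["mean"], dtype=float),
                scale=np.asarray(d["scale"], dtype=float),
                svm=svm,  # type: ignore[arg-type]
            )

        return cls(
            stage1=stage_from(doc["stage1"]),
            stage2=stage_from(doc["stage2"]),
            config=cfg,
        )


class _ConstantDecision:
    """Degenerate stage: the training fold contained a single class, so
    the decision function is the constant margin of that class."""

    def __init__(self, margin: float) -> None:
        self.margin = margin

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.full(X.shape[0], self.margin)


class _LinearDecision:
    """Deserialized linear decision function (duck-types SVC for
    decision_function)."""

    def __init__(self, coef: np.ndarray, intercept: float) -> None:
        self.coef_ = coef.reshape(1, -1)
        self.intercept_ = np.array([intercept])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef_[0] + self.intercept_[0]


# ---------------------------------------------------------------------------
# Fitting


def _feature_matrix(
    profiles: Sequence[FoldInductionProfile],
    feature_order: Sequence[str],
    log_base: float,
) -> np.ndarray:
    X = np.array(
        [[p.fi[g] for g in feature_order] for p in profiles], dtype=float
    )
    return np.log(X) / np.log(log_base)


def _fit_stage(
    profiles: Sequence[FoldInductionProfile],
    y: np.ndarray,
    feature_order: Sequence[str],
    config: TrainingConfig,
) -> _Stage:
    X = _feature_matrix(profiles, feature_order, config.log_base)
    if config.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Z = (X - mean) / scale
    if np.unique(y).size < 2:
        svm = _ConstantDecision(1.0 if y[0] == 1 else -1.0)
        return _Stage(
            feature_order=list(feature_order), mean=mean, scale=scale, svm=svm  # type: ignore[arg-type]
        )
    svm = SVC(kernel=config.kernel, C=config.C, class_weight=config.class_weight)
    svm.fit(Z, y)
    return _Stage(
        feature_order=list(feature_order), mean=mean, scale=scale, svm=svm
    )


_STAGE1_LABEL = {
    GenotypeLabel.WT: 0,  # functional
    GenotypeLabel.TP53_BIALLELIC: 1,  # dysfunctional
    GenotypeLabel.ATM_BIALLELIC: 1,
}
_STAGE2_LABEL = {
    GenotypeLabel.ATM_BIALLELIC: 0,
    GenotypeLabel.TP53_BIALLELIC: 1,  # positive margin = p53-dysfunctional
}


def fit(
    profiles: Sequence[FoldInductionProfile],
    metadata: Iterable[SampleMetadata],
    panel: PanelDefinition,
    config: TrainingConfig | None = None,
    allow_degenerate: bool = False,
) -> NestedClassifier:
    """Fit the nested classifier.

    Only WT and biallelic-defective samples are used; monoallelic samples
    are silently excluded from fitting (they are prediction targets, not
    reference classes). A missing training class is an error unless
    ``allow_degenerate`` (used by cross-validation on tiny cohorts, where
    a one-class stage degrades to a constant decision); fewer than two
    samples of a class is flagged as degenerate.
    """
    if config is None:
        config = TrainingConfig()
    meta = {m.sample_id: m for m in metadata}

    train = [
        p
        for p in profiles
        if p.sample_id in meta and meta[p.sample_id].genotype in TRAINING_GENOTYPES
    ]
    by_class: dict[GenotypeLabel, int] = {g: 0 for g in TRAINING_GENOTYPES}
    for p in train:
        by_class[meta[p.sample_id].genotype] += 1
    absent = sorted(g.value for g, n in by_class.items() if n == 0)
    if absent and not allow_degenerate:
        raise ValueError(f"training set lacks required classes: {absent}")
    thin = sorted(g.value for g, n in by_class.items() if 0 < n < 2)
    if absent or thin:
        logger.warning(
            "degenerate training set: absent=%s, single-sample=%s", absent, thin
        )

    cluster1 = [g.gene_id for g in panel.classification_genes if g.cluster == "I"]
    all_genes = [g.gene_id for g in panel.classification_genes]

    y1 = np.array([_STAGE1_LABEL[meta[p.sample_id].genotype] for p in train])
    stage1 = _fit_stage(train, y1, cluster1, config)

    biallelic = [
        p
        for p in train
        if meta[p.sample_id].genotype
        in (GenotypeLabel.TP53_BIALLELIC, GenotypeLabel.ATM_BIALLELIC)
    ]
    y2 = np.array([_STAGE2_LABEL[meta[p.sample_id].genotype] for p in biallelic])
    stage2 = _fit_stage(biallelic, y2, all_genes, config)

    return NestedClassifier(stage1=stage1, stage2=stage2, config=config)


# ---------------------------------------------------------------------------
# Cross-validation


def cross_validate(
    profiles: Sequence[FoldInductionProfile],
    metadata: Iterable[SampleMetadata],
    panel: PanelDefinition,
    config: TrainingConfig | None = None,
):
    """Internal cross-validation of the training cohort.

    Leave-one-out by default: each held-out sample is predicted by a model
    (including preprocessing statistics) fitted on the remaining samples.
    With ``config.cv = k`` a seeded stratification-free k-fold is used.
    Returns an EvaluationReport over the held-out predictions.
    """
    from .evaluation import evaluate  # local import avoids a cycle

    if config is None:
        config = TrainingConfig()
    meta_list = list(metadata)
    meta = {m.sample_id: m for m in meta_list}
    train = [
        p
        for p in profiles
        if p.sample_id in meta and meta[p.sample_id].genotype in TRAINING_GENOTYPES
    ]

    n = len(train)
    if config.cv == "loo":
        folds = [[i] for i in range(n)]
    else:
        k = int(config.cv)
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(n)
        folds = [list(perm[i::k]) for i in range(k)]

    calls: list[FunctionalCall] = []
    for held_out in folds:
        held = set(held_out)
        fold_train = [p for i, p in enumerate(train) if i not in held]
        model = fit(fold_train, meta_list, panel, config, allow_degenerate=True)
        for i in held_out:
            calls.append(model.predict(train[i]))
    return evaluate(calls, meta_list)


def cross_validate_nested(
    fi_by_probe,
    metadata: Iterable[SampleMetadata],
    panel: PanelDefinition,
    config: TrainingConfig | None = None,
    contrasts=None,
):
    """Cross-validation with probe selection redone inside every fold.

    The non-nested variant (``cross_validate``) reuses one cohort-wide
    probe selection and therefore gives optimistically biased error
    estimates; this variant removes that bias at the cost of per-fold
    selection.
    """
    from .evaluation import evaluate
    from .probe_selection import resolve_profile, select_probes

    if config is None:
        config = TrainingConfig()
    meta_list = list(metadata)
    meta = {m.sample_id: m for m in meta_list}
    samples = [
        s
        for s in fi_by_probe.columns
        if s in meta and meta[s].genotype in TRAINING_GENOTYPES
    ]

    calls: list[FunctionalCall] = []
    for held in samples:
        rest = [s for s in samples if s != held]
        sel = select_probes(
            fi_by_probe[rest], meta_list, panel, contrasts=contrasts
        )
        train_profiles, _ = resolve_profile(fi_by_probe[rest], sel)
        model = fit(train_profiles, meta_list, panel, config)
        held_profiles, bad = resolve_profile(fi_by_probe[[held]], sel)
        if bad:
            raise ValueError(f"held-out sample {held} not evaluable")
        calls.append(model.predict(held_profiles[0]))
    return evaluate(calls, meta_list)


# ---------------------------------------------------------------------------
# Classical multidimensional scaling


@dataclass
class MdsEmbedding:
    """2-D classical-MDS ordination of FI profiles."""

    coordinates: Mapping[str, tuple[float, float]]
    eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))


def mds_embed(
    profiles: Sequence[FoldInductionProfile],
    n_components: int = 2,
    log_base: float = 2.0,
) -> MdsEmbedding:
    """Classical (Torgerson) scaling of Euclidean distances between
    log2-FI vectors.

    Deterministic up to rotation/reflection; reflections are canonicalized
    by making each axis's largest-magnitude coordinate positive. For input
    that is exactly Euclidean in ``n_components`` dimensions the embedding
    reproduces the pairwise distances.
    """
    if len(profiles) < 3:
        raise ValueError("mds_embed requires at least 3 profiles")
    genes = sorted(profiles[0].fi)
    X = _feature_matrix(profiles, genes, log_base)

    # Torgerson double-centering of squared Euclidean distances
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    J = np.eye(len(profiles)) - np.full((len(profiles),) * 2, 1 / len(profiles))
    B = -0.5 * J @ sq @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    lam = np.clip(eigval[:n_components], 0.0, None)
    Y = eigvec[:, :n_components] * np.sqrt(lam)
    for j in range(Y.shape[1]):
        i = int(np.argmax(np.abs(Y[:, j])))
        if Y[i, j] < 0:
            Y[:, j] = -Y[:, j]

    return MdsEmbedding(
        coordinates={
            p.sample_id: (float(Y[i, 0]), float(Y[i, 1]))
            for i, p in enumerate(profiles)
        },
        eigenvalues=eigval,
    )
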