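"""Routed multi-class SVM classification of MADS-box proteins.

Nine model recipes are registered (five per-region class-similarity models,
the M-domain DNA-binding and K-domain coiled-coil encodings, and the two
combined M/K models).  Each is trained as an RBF-kernel SVM with one-vs-one
pairwise-coupled probability estimates, hyperparameters chosen by a log-2
grid search under stratified 3-fold cross-validation.  At prediction time a
filtration step inspects which domains the query contains and routes it to
the feasible model with the highest recorded cross-validation accuracy; the
whole-sequence model is reserved for queries with the complete M,I,K,C
domain content.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.svm import SVC

from .align import ScoringScheme
from .domain_scan import (
    DomainAnnotation,
    DomainScanConfig,
    RegionTag,
    annotate_domains,
    domain_content_key,
)
from .features import (
    EncoderConfigs,
    ReferenceDatabase,
    RegionUnavailableError,
    build_feature_vector,
    build_reference_databases,
    compute_block,
)
from .seqio import CLASS_ORDER, GeneClass, LabeledDataset, ProteinSequence

logger = logging.getLogger(__name__)

#: Hyperparameter grid (coarse, log-2 steps).
DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))


class NotMikcError(ValueError):
    """Stage-1 rejection: the query is not recognized as MIKC-type."""


@dataclass(frozen=True)
class ModelRecipe:
    """A feature recipe: required domains plus ordered (kind, region) blocks."""

    recipe_id: str
    required_regions: frozenset[RegionTag]
    blocks: tuple[tuple[str, RegionTag], ...]


_FULL_CONTENT = frozenset({RegionTag.M, RegionTag.I, RegionTag.K, RegionTag.C_TERM})

_RECIPES: tuple[ModelRecipe, ...] = (
    # The whole-sequence model is only feasible for complete MIKC inputs.
    ModelRecipe("whole-sim", _FULL_CONTENT, (("sim", RegionTag.WHOLE),)),
    ModelRecipe("m-sim", frozenset({RegionTag.M}), (("sim", RegionTag.M),)),
    ModelRecipe("i-sim", frozenset({RegionTag.I}), (("sim", RegionTag.I),)),
    ModelRecipe("k-sim", frozenset({RegionTag.K}), (("sim", RegionTag.K),)),
    ModelRecipe("c-sim", frozenset({RegionTag.C_TERM}), (("sim", RegionTag.C_TERM),)),
    ModelRecipe("m-bindn", frozenset({RegionTag.M}), (("bindn", RegionTag.M),)),
    ModelRecipe("k-coils", frozenset({RegionTag.K}), (("coils", RegionTag.K),)),
    ModelRecipe(
        "m-sim+bindn",
        frozenset({RegionTag.M}),
        (("sim", RegionTag.M), ("bindn", RegionTag.M)),
    ),
    ModelRecipe(
        "k-sim+coils",
        frozenset({RegionTag.K}),
        (("sim", RegionTag.K), ("coils", RegionTag.K)),
    ),
)


def registered_recipes() -> list[ModelRecipe]:
    """The nine registered model recipes, in fixed registration order."""
    return list(_RECIPES)


def get_recipe(recipe_id: str) -> ModelRecipe:
    for r in _RECIPES:
        if r.recipe_id == recipe_id:
            return r
    raise KeyError(f"unknown recipe {recipe_id!r}")


@dataclass
class Prediction:
    """Predicted class plus normalized per-class confidence scores."""

    sequence_id: str
    predicted: GeneClass
    confidence: dict[GeneClass, float]
    model_used: str

    def __post_init__(self) -> None:
        total = sum(self.confidence.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"confidences sum to {total}, expected 1")

    def confidence_row(self, ndigits: int = 2) -> list[float]:
        return [round(self.confidence.get(c, 0.0), ndigits) for c in CLASS_ORDER]


@dataclass
class TrainedModel:
    """A fitted recipe model with its scaler and CV accuracy."""

    recipe: ModelRecipe
    scaler_min: np.ndarray
    scaler_max: np.ndarray
    classifier: SVC
    class_order: tuple[GeneClass, ...]
    cv_accuracy: float
    seed: int
    best_params: dict = field(default_factory=dict)

    def scale(self, X: np.ndarray, *, clamp: bool = True) -> np.ndarray:
        span = self.scaler_max - self.scaler_min
        span = np.where(span > 0, span, 1.0)
        Z = (X - self.scaler_min) / span
        if clamp:
            Z = np.clip(Z, 0.0, 1.0)
        return Z

    def predict_proba_ordered(self, X: np.ndarray) -> np.ndarray:
        """Probabilities rearranged into the fixed eight-class order."""
        proba = self.classifier.predict_proba(X)
        out = np.zeros((proba.shape[0], len(CLASS_ORDER)))
        col = {label: i for i, label in enumerate(self.classifier.classes_)}
        for j, cls in enumerate(CLASS_ORDER):
            if cls.value in col:
                out[:, j] = proba[:, col[cls.value]]
        return out


# ---------------------------------------------------------------------------
# Feature assembly helpers (shared block cache)
# ---------------------------------------------------------------------------

class FeatureEncoder:
    """Computes recipe feature matrices with a per-block cache.

    Similarity blocks depend on the reference databases and are cached per
    encoder instance (one encoder per training context / CV fold); sequence-
    intrinsic blocks (DNA-binding, coiled-coil) can share a cross-fold cache.
    """

    def __init__(
        self,
        refdbs: Mapping[RegionTag, ReferenceDatabase],
        scheme: ScoringScheme,
        configs: EncoderConfigs,
        intrinsic_cache: dict | None = None,
    ):
        self.refdbs = refdbs
        self.scheme = scheme
        self.configs = configs
        self._sim_cache: dict = {}
        self._intrinsic = intrinsic_cache if intrinsic_cache is not None else {}

    def block(
        self,
        seq: ProteinSequence,
        annotation: DomainAnnotation,
        kind: str,
        region: RegionTag,
        exclude_self_id: str | None,
    ) -> np.ndarray:
        if kind == "sim":
            key = (seq.id, region, exclude_self_id)
            cache = self._sim_cache
        else:
            key = (kind, seq.id, region)
            cache = self._intrinsic
        if key not in cache:
            cache[key] = compute_block(
                seq, annotation, kind, region, self.refdbs,
                self.scheme, self.configs, exclude_self_id=exclude_self_id,
            )
        return cache[key]

    def vector(
        self,
        seq: ProteinSequence,
        annotation: DomainAnnotation,
        recipe: ModelRecipe,
        exclude_self_id: str | None = None,
    ) -> np.ndarray:
        return np.concatenate([
            self.block(seq, annotation, kind, region, exclude_self_id)
            for kind, region in recipe.blocks
        ])

    def matrix(
        self,
        entries: Sequence[tuple[ProteinSequence, GeneClass, DomainAnnotation]],
        recipe: ModelRecipe,
        *,
        exclude_self: bool,
    ) -> tuple[list[str], np.ndarray, np.ndarray]:
        """(ids, X, y) for the entries that have the recipe's regions."""
        ids, rows, labels = [], [], []
        for seq, cls, ann in entries:
            if not recipe.required_regions <= ann.present_regions:
                logger.warning(
                    "skipping %s for recipe %s: missing region(s)",
                    seq.id, recipe.recipe_id,
                )
                continue
            vec = self.vector(
                seq, ann, recipe, exclude_self_id=seq.id if exclude_self else None
            )
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"non-finite feature for sequence {seq.id!r}")
            ids.append(seq.id)
            rows.append(vec)
            labels.append(cls.value)
        X = np.vstack(rows) if rows else np.zeros((0, 0))
        return ids, X, np.array(labels)


def _annotated_entries(
    train: LabeledDataset,
) -> list[tuple[ProteinSequence, GeneClass, DomainAnnotation]]:
    entries = []
    for seq, cls, ann in train.entries:
        if ann is None:
            raise ValueError(
                f"training sequence {seq.id!r} lacks a domain annotation; "
                "annotate the dataset first"
            )
        entries.append((seq, cls, ann))
    return entries


def _fit_svm(
    X: np.ndarray, y: np.ndarray, seed: int, hyper: Mapping | None
) -> tuple[SVC, float, dict]:
    """Grid-searched RBF SVM fit; returns (fitted probabilistic SVC,
    CV accuracy of the best parameters, best parameters)."""
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) < 2 or counts.min() < 2:
        raise ValueError(
            "degenerate training set: need >= 2 classes with >= 2 members each"
        )
    c_grid = tuple(hyper.get("C", DEFAULT_C_GRID)) if hyper else DEFAULT_C_GRID
    g_grid = tuple(hyper.get("gamma", DEFAULT_GAMMA_GRID)) if hyper else DEFAULT_GAMMA_GRID
    n_splits = min(3, int(counts.min()))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": list(c_grid), "gamma": list(g_grid)},
        cv=cv,
        scoring="accuracy",
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X, y)
    best = SVC(
        kernel="rbf",
        probability=True,
        random_state=seed,
        **search.best_params_,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        best.fit(X, y)
    return best, float(search.best_score_), dict(search.best_params_)


def train_model(
    train: LabeledDataset,
    recipe: ModelRecipe | str,
    refdbs: Mapping[RegionTag, ReferenceDatabase],
    scheme: ScoringScheme | None = None,
    configs: EncoderConfigs | None = None,
    hyper: Mapping | None = None,
    seed: int = 0,
    encoder: FeatureEncoder | None = None,
) -> TrainedModel:
    """Train one recipe model on an annotated, labeled training set.

    Features are built with self-exclusion against the reference databases
    (a reference is never aligned with itself), min-max scaled to [0, 1], and
    fed to a grid-searched RBF SVM with probability calibration.  Training
    sequences lacking a required region are skipped with a warning.
    """
    if isinstance(recipe, str):
        recipe = get_recipe(recipe)
    scheme = scheme or ScoringScheme()
    configs = configs or EncoderConfigs()
    if encoder is None:
        encoder = FeatureEncoder(refdbs, scheme, configs)
    entries = _annotated_entries(train)
    ids, X, y = encoder.matrix(entries, recipe, exclude_self=True)
    if X.shape[0] == 0:
        raise ValueError(f"no training sequence has the regions for {recipe.recipe_id}")
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    Z = (X - lo) / span
    clf, cv_acc, best_params = _fit_svm(Z, y, seed, hyper)
    return TrainedModel(
        recipe=recipe,
        scaler_min=lo,
        scaler_max=hi,
        classifier=clf,
        class_order=CLASS_ORDER,
        cv_accuracy=cv_acc,
        seed=seed,
        best_params=best_params,
    )


def train_all_models(
    train: LabeledDataset,
    refdbs: Mapping[RegionTag, ReferenceDatabase],
    scheme: ScoringScheme | None = None,
    configs: EncoderConfigs | None = None,
    seed: int = 0,
) -> list[TrainedModel]:
    """Train every registered recipe, sharing feature blocks across recipes."""
    scheme = scheme or ScoringScheme()
    configs = configs or EncoderConfigs()
    encoder = FeatureEncoder(refdbs, scheme, configs)
    return [
        train_model(train, r, refdbs, scheme, configs, seed=seed, encoder=encoder)
        for r in registered_recipes()
    ]


@dataclass
class CrossValidationResult:
    recipe_id: str
    fold_accuracies: list[float]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def cross_validate(
    train: LabeledDataset,
    recipe: ModelRecipe | str,
    k: int = 3,
    seed: int = 0,
    scheme: ScoringScheme | None = None,
    configs: EncoderConfigs | None = None,
) -> CrossValidationResult:
    """k-fold cross-validation of one recipe with per-fold reference rebuild."""
    if isinstance(recipe, str):
        recipe = get_recipe(recipe)
    return cross_validate_recipes(
        train, [recipe], k=k, seed=seed, scheme=scheme, configs=configs
    )[recipe.recipe_id]


def cross_validate_recipes(
    train: LabeledDataset,
    recipes: Sequence[ModelRecipe] | None = None,
    k: int = 3,
    seed: int = 0,
    scheme: ScoringScheme | None = None,
    configs: EncoderConfigs | None = None,
) -> dict[str, CrossValidationResult]:
    """Stratified k-fold CV of several recipes with shared feature blocks.

    Reference databases are rebuilt per fold from that fold's training split
    only, so no test-fold sequence ever contributes to the features its own
    prediction is based on.  Fold assignment is deterministic per seed; when
    a class has fewer members than k the fold assignment falls back to
    non-stratified with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    recipes = list(recipes) if recipes is not None else registered_recipes()
    scheme = scheme or ScoringScheme()
    configs = configs or EncoderConfigs()
    entries = _annotated_entries(train)
    y = np.array([cls.value for _, cls, _ in entries])
    idx = np.arange(len(entries))
    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(idx, y)
    else:
        logger.warning(
            "class with fewer than %d members: falling back to non-stratified folds", k
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(idx)

    results = {r.recipe_id: CrossValidationResult(r.recipe_id, []) for r in recipes}
    intrinsic_cache: dict = {}
    for fold, (tr_idx, te_idx) in enumerate(splits):
        fold_train = LabeledDataset(
            name=f"{train.name}_fold{fold}_train",
            entries=[train.entries[i] for i in tr_idx],
        )
        fold_dbs = build_reference_databases(fold_train)
        encoder = FeatureEncoder(fold_dbs, scheme, configs, intrinsic_cache)
        tr_entries = [entries[i] for i in tr_idx]
        te_entries = [entries[i] for i in te_idx]
        for recipe in recipes:
            ids_tr, X_tr, y_tr = encoder.matrix(tr_entries, recipe, exclude_self=True)
            ids_te, X_te, y_te = encoder.matrix(te_entries, recipe, exclude_self=False)
            if len(ids_te) == 0 or len(np.unique(y_tr)) < 2:
                results[recipe.recipe_id].fold_accuracies.append(float("nan"))
                continue
            lo, hi = X_tr.min(axis=0), X_tr.max(axis=0)
            span = np.where(hi - lo > 0, hi - lo, 1.0)
            Z_tr = (X_tr - lo) / span
            Z_te = np.clip((X_te - lo) / span, 0.0, 1.0)
            clf, _, _ = _fit_svm(Z_tr, y_tr, seed, None)
            acc = float(np.mean(clf.predict(Z_te) == y_te))
            results[recipe.recipe_id].fold_accuracies.append(acc)
    return results


# ---------------------------------------------------------------------------
# Routing and prediction
# ---------------------------------------------------------------------------

def select_model(
    annotation: DomainAnnotation, models: Sequence[TrainedModel]
) -> TrainedModel:
    """Filtration step: route by domain content to the best feasible model.

    Feasible models are those whose required regions are all present in the
    annotation; among them the one with the highest CV accuracy wins, ties
    broken by recipe registration order.  Non-MIKC inputs are rejected.
    """
    if not annotation.is_mikc:
        raise NotMikcError(
            f"{annotation.sequence_id}: rejected: not MIKC-type (no MADS domain match)"
        )
    present = annotation.present_regions
    feasible = [m for m in models if m.recipe.required_regions <= present]
    if not feasible:
        raise ValueError(
            f"{annotation.sequence_id}: no feasible model for domain content "
            f"{domain_content_key(annotation) or '(none)'}"
        )
    order = {r.recipe_id: i for i, r in enumerate(registered_recipes())}
    return max(
        feasible,
        key=lambda m: (m.cv_accuracy, -order.get(m.recipe.recipe_id, len(order))),
    )


def predict_with_model(
    seq: ProteinSequence,
    annotation: DomainAnnotation,
    model: TrainedModel,
    refdbs: Mapping[RegionTag, ReferenceDatabase],
    scheme: ScoringScheme | None = None,
    configs: EncoderConfigs | None = None,
) -> Prediction:
    """Predict with a specific model (no routing); confidences sum to 1."""
    fv = build_feature_vector(
        seq, annotation, model.recipe, refdbs, scheme, configs, exclude_self_id=None
    )
    Z = model.scale(fv.flat[None, :])
    proba = model.predict_proba_ordered(Z)[0]
    proba = proba / proba.sum()
    predicted = CLASS_ORDER[int(np.argmax(proba))]  # argmax; earliest wins ties
    return Prediction(
        sequence_id=seq.id,
        predicted=predicted,
        confidence={c: float(p) for c, p in zip(CLASS_ORDER, proba)},
        model_used=model.recipe.recipe_id,
    )


def predict(
    seq: ProteinSequence,
    models: Sequence[TrainedModel],
    refdbs: Mapping[RegionTag, ReferenceDatabase],
    scheme: ScoringScheme | None = None,
    configs: EncoderConfigs | None = None,
    annotation: DomainAnnotation | None = None,
    scan_config: DomainScanConfig | None = None,
) -> Prediction:
    """Stage-1 annotate (unless an annotation is supplied), route, predict."""
    if annotation is None:
        annotation = annotate_domains(seq, scan_config)
    model = select_model(annotation, models)
    return predict_with_model(seq, annotation, model, refdbs, scheme, configs)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-gene prediction rows plus accuracy and a confusion matrix."""

    rows: pd.DataFrame
    n_correct: int
    n_total: int
    confusion: pd.DataFrame

    @property
    def accuracy_percent(self) -> float:
        """Accuracy as a percentage rounded to two decimals (e.g. 92.31)."""
        if self.n_total == 0:
            return float("nan")
        return round(100.0 * self.n_correct / self.n_total, 2)

    @classmethod
    def from_rows(cls, rows: pd.DataFrame) -> "EvaluationReport":
        n_total = len(rows)
        n_correct = int(rows["correct"].sum())
        order = [c.value for c in CLASS_ORDER]
        confusion = pd.DataFrame(0, index=order, columns=order + ["rejected"])
        for _, row in rows.iterrows():
            pred = row["predicted_class"] if pd.notna(row["predicted_class"]) else "rejected"
            confusion.loc[row["gene_class"], pred] += 1
        return cls(rows=rows, n_correct=n_correct, n_total=n_total, confusion=confusion)

    def to_tsv(self, path) -> None:
        out = self.rows.copy()
        for c in CLASS_ORDER:
            out[c.value] = out[c.value].map(lambda v: f"{v:.2f}" if pd.notna(v) else "")
        out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def evaluate(
    labeled: LabeledDataset,
    models: Sequence[TrainedModel],
    refdbs: Mapping[RegionTag, ReferenceDatabase],
    scheme: ScoringScheme | None = None,
    configs: EncoderConfigs | None = None,
    use_given_annotations: bool = False,
    scan_config: DomainScanConfig | None = None,
) -> EvaluationReport:
    """Per-gene report (true class, predicted class, eight confidences,
    correctness) plus overall accuracy and confusion matrix.

    Rejected or unroutable genes count as incorrect, with an empty predicted
    class.
    """
    records = []
    for seq, cls, ann in labeled.entries:
        annotation = ann if (use_given_annotations and ann is not None) else None
        try:
            pred = predict(
                seq, models, refdbs, scheme, configs,
                annotation=annotation, scan_config=scan_config,
            )
            row = {
                "gene": seq.id,
                "gene_class": cls.value,
                "predicted_class": pred.predicted.value,
                "model_used": pred.model_used,
                "correct": pred.predicted is cls,
            }
            row.update({c.value: pred.confidence[c] for c in CLASS_ORDER})
        except (NotMikcError, ValueError) as exc:
            logger.warning("evaluation: %s", exc)
            row = {
                "gene": seq.id,
                "gene_class": cls.value,
                "predicted_class": None,
                "model_used": None,
                "correct": False,
            }
            row.update({c.value: float("nan") for c in CLASS_ORDER})
        records.append(row)
    return EvaluationReport.from_rows(pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# Model bundles on disk
# ---------------------------------------------------------------------------

def save_models(models: Sequence[TrainedModel], outdir: str | Path) -> None:
    """Save each model as a bundle subdirectory (recipe JSON, scaler TSV,
    serialized classifier, metadata)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for model in models:
        d = outdir / model.recipe.recipe_id
        d.mkdir(parents=True, exist_ok=True)
        recipe = {
            "recipe_id": model.recipe.recipe_id,
            "required_regions": sorted(r.label for r in model.recipe.required_regions),
            "blocks": [[kind, region.label] for kind, region in model.recipe.blocks],
        }
        (d / "recipe.json").write_text(json.dumps(recipe, indent=2), encoding="utf-8")
        with (d / "scaler.tsv").open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("feature\tmin\tmax\n")
            for i, (lo, hi) in enumerate(zip(model.scaler_min, model.scaler_max)):
                fh.write(f"{i}\t{lo:.10g}\t{hi:.10g}\n")
        joblib.dump(model.classifier, d / "classifier.joblib")
        meta = {
            "cv_accuracy": model.cv_accuracy,
            "seed": model.seed,
            "best_params": model.best_params,
            "class_order": [c.value for c in CLASS_ORDER],
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")


def load_models(indir: str | Path) -> list[TrainedModel]:
    """Load every model bundle found under a directory."""
    indir = Path(indir)
    models = []
    for d in sorted(p for p in indir.iterdir() if p.is_dir()):
        recipe_info = json.loads((d / "recipe.json").read_text(encoding="utf-8"))
        recipe = get_recipe(recipe_info["recipe_id"])
        scaler = pd.read_csv(d / "scaler.tsv", sep="\t")
        meta = json.loads((d / "meta.json").read_text(encoding="utf-8"))
        models.append(
            TrainedModel(
                recipe=recipe,
                scaler_min=scaler["min"].to_numpy(),
                scaler_max=scaler["max"].to_numpy(),
                classifier=joblib.load(d / "classifier.joblib"),
                class_order=CLASS_ORDER,
                cv_accuracy=float(meta["cv_accuracy"]),
                seed=int(meta["seed"]),
                best_params=meta.get("best_params", {}),
            )
        )
    order = {r.recipe_id: i for i, r in enumerate(registered_recipes())}
    models.sort(key=lambda m: order.get(m.recipe.recipe_id, len(order)))
    return models
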