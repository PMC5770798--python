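"""Kernel SVM classifiers and the three-stage hierarchical predictor.

Stage 1 separates HSPs from non-HSPs at a probability threshold (default
0.5); stage 2 assigns one of the six chaperone families (HSP20/40/60/70/
90/100) by maximum one-vs-rest probability; stage 3 sub-types sequences
called HSP40 into the four DnaJ classes (Type-I..IV) and runs only for
those sequences. All stages share one feature pipeline: an encoder spec
plus an optional selected-feature list.

The default kernel is radial with cost 1 and gamma = 1 / n_features,
matching the libsvm defaults, and features are standardized to zero mean
and unit variance on the training data (the default behaviour of the
reference SVM front ends built on libsvm; raw compositional descriptors
are orders of magnitude smaller than the kernel's natural length scale).
Probability outputs come from a Platt calibration fit on the training
data; fits are deterministic given seed.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import features as _features
from .seqio import LabeledDataset, ProteinSequence

FAMILIES = ("HSP20", "HSP40", "HSP60", "HSP70", "HSP90", "HSP100")
DNAJ_TYPES = ("Type-I", "Type-II", "Type-III", "Type-IV")
POSITIVE_LABEL = "HSP"
NEGATIVE_LABEL = "non-HSP"

KERNEL_KINDS = ("linear", "polynomial", "radial", "sigmoid")
#: canonical tie-break order when kernels score equally
KERNEL_TIE_ORDER = ("radial", "linear", "polynomial", "sigmoid")
_SKLEARN_KERNEL = {
    "linear": "linear",
    "polynomial": "poly",
    "radial": "rbf",
    "sigmoid": "sigmoid",
}


@dataclass(frozen=True)
class KernelSpec:
    kind: str = "radial"
    cost: float = 1.0
    gamma: float | str = "auto"  # "auto" = 1 / n_features
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel {self.kind!r}; expected one of {KERNEL_KINDS}")
        if not self.cost > 0:
            raise ValueError("cost must be positive")

    def to_estimator(self, seed: int) -> SVC:
        return SVC(
            kernel=_SKLEARN_KERNEL[self.kind],
            C=self.cost,
            gamma=self.gamma,
            degree=self.degree,
            coef0=self.coef0,
            probability=True,
            random_state=seed,
        )


class FeatureMismatchError(ValueError):
    """Input feature names/order differ from what a classifier expects."""


@dataclass
class TrainedClassifier:
    """A fitted kernel SVM bound to a fixed, ordered feature-name contract.

    Inputs are standardized with the training-set column means and
    standard deviations before hitting the kernel.
    """

    estimator: SVC
    kernel: KernelSpec
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    seed: int
    scale_mean: np.ndarray | None = None
    scale_std: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if tuple(map(str, X.columns)) != self.feature_names:
                raise FeatureMismatchError(
                    "feature names/order differ from the training contract"
                )
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if values.shape[1] != len(self.feature_names):
                raise FeatureMismatchError(
                    f"expected {len(self.feature_names)} features, got {values.shape[1]}"
                )
        if self.scale_mean is not None:
            values = (values - self.scale_mean) / self.scale_std
        return values

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(self._check(X))

    def predict_proba(self, X) -> np.ndarray:
        return self.estimator.predict_proba(self._check(X))

    @property
    def classes_(self):
        return self.estimator.classes_

    def proba_of(self, X, label: str) -> np.ndarray:
        classes = list(self.estimator.classes_)
        return self.predict_proba(X)[:, classes.index(label)]


def fit_svm(
    X: pd.DataFrame,
    y,
    kernel: KernelSpec | None = None,
    seed: int = 0,
    scale: bool = True,
) -> TrainedClassifier:
    """Fit a kernel SVM with Platt-calibrated probabilities.

    ``scale=True`` (default) standardizes every feature to zero mean and
    unit variance on the training data; constant columns are left
    centered. The scaling statistics travel with the classifier.
    """
    kernel = kernel or KernelSpec()
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    values = X.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("feature matrix contains NaN")
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.shape[0] < 2:
        raise ValueError("at least two classes are required")
    if counts.min() < 2:
        small = classes[counts < 2].tolist()
        raise ValueError(f"class(es) with fewer than 2 examples: {small}")
    mean = std = None
    if scale:
        mean = values.mean(axis=0)
        std = values.std(axis=0, ddof=1) if values.shape[0] > 1 else np.ones(values.shape[1])
        std = np.where(std > 0, std, 1.0)
        values = (values - mean) / std
    with warnings.catch_warnings():
        # probability=True is the libsvm-native Platt fit; sklearn 1.9
        # deprecates the flag in favour of a wrapper with identical output
        warnings.simplefilter("ignore", FutureWarning)
        est = kernel.to_estimator(seed).fit(values, y)
    digest = hashlib.sha256(values.tobytes() + np.asarray(y, dtype="U").tobytes()).hexdigest()
    return TrainedClassifier(
        estimator=est,
        kernel=kernel,
        feature_names=tuple(map(str, X.columns)),
        classes=tuple(map(str, classes)),
        seed=seed,
        scale_mean=mean,
        scale_std=std,
        provenance={"n_train": int(values.shape[0]), "train_digest": digest,
                    "scaling": "per-feature z-score from training data"
                    if scale else "none"},
    )


def make_svm_fitter(kernel: KernelSpec | None = None, seed: int = 0):
    """A ``fit_fn(X, y)`` closure for the evaluation module."""
    return lambda X, y: fit_svm(X, y, kernel=kernel, seed=seed)


def kernel_screen(
    X: pd.DataFrame,
    y,
    kernels=None,
    folds: int = 5,
    seed: int = 0,
    pos_label=None,
):
    """Cross-validated metrics per kernel and the best kernel.

    Best = highest mean accuracy; ties are broken by the canonical order
    radial, linear, polynomial, sigmoid.
    """
    from .evaluation import CVPlan, cross_validate  # local import avoids cycle

    kernels = list(kernels) if kernels is not None else [KernelSpec(k) for k in KERNEL_TIE_ORDER]
    if not kernels:
        raise ValueError("at least one kernel is required")
    plan = CVPlan(scheme="kfold", k=folds, stratified=True, seed=seed)
    reports = {}
    for spec in kernels:
        result = cross_validate(X, y, make_svm_fitter(spec, seed), plan, pos_label=pos_label)
        reports[spec.kind] = result.mean
    def sort_key(spec: KernelSpec):
        return (-reports[spec.kind].accuracy, KERNEL_TIE_ORDER.index(spec.kind))
    best = min(kernels, key=sort_key)
    return reports, best


# ---------------------------------------------------------------------------
# Hierarchical model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineSpec:
    """Encoder spec plus the selected-feature subset shared by all stages."""

    encoder: dict
    selected_features: tuple[str, ...] | None = None

    def encode(self, seqs) -> pd.DataFrame:
        X = _features.encode_dataset(seqs, dict(self.encoder))
        if self.selected_features is not None:
            missing = [f for f in self.selected_features if f not in X.columns]
            if missing:
                raise FeatureMismatchError(
                    f"encoder does not produce selected feature(s): {missing[:5]}"
                )
            X = X.loc[:, list(self.selected_features)]
        return X


@dataclass
class HierarchicalModel:
    stage1: TrainedClassifier
    stage2: TrainedClassifier
    stage3: TrainedClassifier | None
    pipeline: PipelineSpec
    threshold: float = 0.5


@dataclass
class PredictionRecord:
    serial: int
    id: str
    call: str
    probabilities: dict[str, float] = field(default_factory=dict)
    error: str | None = None

    @property
    def probability(self) -> float:
        """Probability of the deepest stage that produced the call."""
        for key in ("stage3", "stage2", "stage1"):
            if key in self.probabilities:
                return self.probabilities[key]
        return float("nan")


def build_hierarchical(
    stage1: TrainedClassifier,
    stage2: TrainedClassifier,
    stage3: TrainedClassifier | None,
    pipeline: PipelineSpec,
    threshold: float = 0.5,
) -> HierarchicalModel:
    """Compose the three stage classifiers, checking class and feature
    contracts."""
    if set(stage1.classes) != {POSITIVE_LABEL, NEGATIVE_LABEL}:
        raise ValueError(
            f"stage 1 must be {POSITIVE_LABEL}/{NEGATIVE_LABEL}, got {stage1.classes}"
        )
    missing = sorted(set(FAMILIES) - set(stage2.classes))
    if missing:
        raise ValueError(f"stage 2 is missing family class(es): {missing}")
    if stage3 is not None:
        missing3 = sorted(set(DNAJ_TYPES) - set(stage3.classes))
        if missing3:
            raise ValueError(f"stage 3 is missing DnaJ class(es): {missing3}")
    stages = [stage1, stage2] + ([stage3] if stage3 is not None else [])
    expected = (
        pipeline.selected_features
        if pipeline.selected_features is not None
        else stage1.feature_names
    )
    for i, st in enumerate(stages, start=1):
        if st.feature_names != tuple(expected):
            raise FeatureMismatchError(
                f"stage {i} feature space differs from the pipeline contract"
            )
    return HierarchicalModel(stage1, stage2, stage3, pipeline, threshold)


def hierarchical_predict(
    model: HierarchicalModel, seqs: list[ProteinSequence]
) -> list[PredictionRecord]:
    """Run the staged prediction flow over a batch of sequences.

    Stage 1 decides HSP vs non-HSP at the model threshold; non-HSP halts.
    Stage 2 assigns the maximum-probability family; an HSP40 call triggers
    DnaJ sub-typing when a stage-3 classifier is present. Per-sequence
    encoding failures are reported inline without aborting the batch.
    Output order matches input order, serial numbers start at 1.
    """
    records: list[PredictionRecord] = []
    encoded: dict[int, pd.Series] = {}
    for i, seq in enumerate(seqs):
        try:
            encoded[i] = model.pipeline.encode([seq]).iloc[0]
        except Exception as exc:  # noqa: BLE001 - reported inline per contract
            records.append(
                PredictionRecord(serial=i + 1, id=seq.id, call="error", error=str(exc))
            )
    ok = sorted(encoded)
    if not ok:
        return sorted(records, key=lambda r: r.serial)
    X = pd.DataFrame([encoded[i] for i in ok],
                     index=[seqs[i].id for i in ok])
    X.columns = list(model.stage1.feature_names)
    p_hsp = model.stage1.proba_of(X, POSITIVE_LABEL)
    is_hsp = p_hsp >= model.threshold

    fam_calls = np.empty(len(ok), dtype=object)
    fam_probs = np.full(len(ok), np.nan)
    if is_hsp.any():
        proba2 = model.stage2.predict_proba(X.iloc[is_hsp])
        classes2 = np.asarray(model.stage2.classes_)
        arg = proba2.argmax(axis=1)
        fam_calls[is_hsp] = classes2[arg]
        fam_probs[np.flatnonzero(is_hsp)] = proba2[np.arange(len(arg)), arg]

    sub_calls = np.empty(len(ok), dtype=object)
    sub_probs = np.full(len(ok), np.nan)
    if model.stage3 is not None:
        is_40 = np.array([c == "HSP40" for c in fam_calls])
        if is_40.any():
            proba3 = model.stage3.predict_proba(X.iloc[is_40])
            classes3 = np.asarray(model.stage3.classes_)
            arg3 = proba3.argmax(axis=1)
            sub_calls[is_40] = classes3[arg3]
            sub_probs[np.flatnonzero(is_40)] = proba3[np.arange(len(arg3)), arg3]

    for row, i in enumerate(ok):
        probs = {"stage1": float(p_hsp[row])}
        if not is_hsp[row]:
            call = NEGATIVE_LABEL
            probs["stage1"] = float(1.0 - p_hsp[row])
        else:
            fam = str(fam_calls[row])
            probs["stage2"] = float(fam_probs[row])
            if fam == "HSP40" and sub_calls[row] is not None:
                probs["stage3"] = float(sub_probs[row])
                call = f"HSP40 ({sub_calls[row]})"
            else:
                call = fam
        records.append(
            PredictionRecord(serial=i + 1, id=seqs[i].id, call=call, probabilities=probs)
        )
    return sorted(records, key=lambda r: r.serial)


def write_predictions(records: list[PredictionRecord], path) -> None:
    """Four-column prediction table: serial, id, prediction, probability."""
    df = pd.DataFrame(
        {
            "serial": [r.serial for r in records],
            "id": [r.id for r in records],
            "prediction": [r.call for r in records],
            "probability": [r.probability for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Training the full pipeline
# ---------------------------------------------------------------------------

def train_pipeline(
    benchmark: LabeledDataset,
    dnaj: LabeledDataset | None = None,
    encoder: dict | None = None,
    k: int | None = None,
    kernel: KernelSpec | None = None,
    seed: int = 0,
    selection_technique: str = "random_forest",
    threshold: float = 0.5,
) -> HierarchicalModel:
    """Train all stages from a family-labeled benchmark.

    ``benchmark`` labels are the six family names plus ``non-HSP``;
    ``dnaj`` (optional) carries DnaJ type labels for stage 3. Features are
    selected on the stage-1 (HSP vs non-HSP) problem and shared by all
    stages.
    """
    from . import selection as _selection

    encoder = encoder or {"name": "gpc_combined", "gaps": (0, 1, 2, 3)}
    kernel = kernel or KernelSpec()
    X = _features.encode_dataset(benchmark, encoder)
    y1 = np.where(np.asarray(benchmark.labels) == NEGATIVE_LABEL,
                  NEGATIVE_LABEL, POSITIVE_LABEL)
    selected = None
    if k is not None:
        k = min(k, X.shape[1])
        ranked = _selection.rank_features(X, y1, selection_technique, seed=seed)
        selected = _selection.select_top_k(ranked, k).selected
        X = X.loc[:, list(selected)]
    pipeline = PipelineSpec(encoder=encoder, selected_features=selected)

    stage1 = fit_svm(X, y1, kernel=kernel, seed=seed)
    hsp_mask = y1 == POSITIVE_LABEL
    stage2 = fit_svm(
        X.iloc[hsp_mask],
        np.asarray(benchmark.labels)[hsp_mask],
        kernel=kernel,
        seed=seed,
    )
    stage3 = None
    if dnaj is not None:
        X3 = pipeline.encode(dnaj)
        stage3 = fit_svm(X3, np.asarray(dnaj.labels), kernel=kernel, seed=seed)
    return build_hierarchical(stage1, stage2, stage3, pipeline, threshold)


# ---------------------------------------------------------------------------
# Model bundle serialization
# ---------------------------------------------------------------------------

def save_bundle(model: HierarchicalModel, directory) -> None:
    """Serialize a hierarchical model to a directory with JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "hspkit-bundle-1",
        "threshold": model.threshold,
        "pipeline": {
            "encoder": model.pipeline.encoder,
            "selected_features": list(model.pipeline.selected_features)
            if model.pipeline.selected_features is not None
            else None,
        },
        "stages": {},
    }
    for name, st in (("stage1", model.stage1), ("stage2", model.stage2),
                     ("stage3", model.stage3)):
        if st is None:
            continue
        meta["stages"][name] = {
            "kernel": asdict(st.kernel),
            "classes": list(st.classes),
            "seed": st.seed,
            "feature_count": len(st.feature_names),
            "provenance": st.provenance,
        }
        joblib.dump(
            {"estimator": st.estimator, "feature_names": st.feature_names,
             "kernel": asdict(st.kernel), "classes": st.classes, "seed": st.seed,
             "scale_mean": st.scale_mean, "scale_std": st.scale_std,
             "provenance": st.provenance},
            directory / f"{name}.joblib",
        )
    with open(directory / "meta.json", "w") as out:
        json.dump(meta, out, indent=2)


def load_bundle(directory) -> HierarchicalModel:
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"not a model bundle (no meta.json): {directory}")
    with open(meta_path) as handle:
        meta = json.load(handle)
    stages = {}
    for name in ("stage1", "stage2", "stage3"):
        path = directory / f"{name}.joblib"
        if not path.exists():
            stages[name] = None
            continue
        blob = joblib.load(path)
        stages[name] = TrainedClassifier(
            estimator=blob["estimator"],
            kernel=KernelSpec(**blob["kernel"]),
            feature_names=tuple(blob["feature_names"]),
            classes=tuple(blob["classes"]),
            seed=blob["seed"],
            scale_mean=blob["scale_mean"],
            scale_std=blob["scale_std"],
            provenance=blob["provenance"],
        )
    pipeline = PipelineSpec(
        encoder=meta["pipeline"]["encoder"],
        selected_features=tuple(meta["pipeline"]["selected_features"])
        if meta["pipeline"]["selected_features"] is not None
        else None,
    )
    return HierarchicalModel(
        stage1=stages["stage1"],
        stage2=stages["stage2"],
        stage3=stages["stage3"],
        pipeline=pipeline,
        threshold=meta.get("threshold", 0.5),
    )
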