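"""Classifier-ensemble ranking models.

Training data is simulated from the knowledge base: for each disease a fixed
number of synthetic patients is drawn by keeping each annotated term with
probability ``1 - dropout`` and adding ``Poisson(noise_rate)`` random terms
from the rest of the vocabulary.  Patients are embedded as IC-weighted,
ancestor-propagated sparse rows over a shared vocabulary, six pluggable
classifier backends are trained on them, and predictions are combined by a
validation-accuracy-weighted convex average.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from . import ensemble as ens
from .errors import InputError, TrainingError
from .knowledge_base import DiseasePhenotypeKB, query_vector
from .ontology import InformationContentTable, OntologyGraph
from .similarity_models import RankedResult, _sort_items

ALGORITHMS = (
    "logistic_regression",
    "knn",
    "random_forest",
    "extra_trees",
    "naive_bayes",
    "deep_neural_network",
)


@dataclass
class PatientRecord:
    patient_id: str
    phenotypes: list[str]
    true_disease: str | None = None
    source: str = "synthetic_train"


@dataclass
class ClassifierSpec:
    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise InputError(f"unknown algorithm: {self.algorithm!r}")


@dataclass
class FeatureMatrix:
    row_ids: list[str]
    vocabulary: list[str]
    X: sparse.csr_matrix
    labels: list[str | None]
    n_dropped: int = 0


@dataclass
class TrainedEnsemble:
    members: list[tuple[ClassifierSpec, object, float]]
    label_set: list[str]
    vocabulary: list[str]


def generate_training_patients(
    kb: DiseasePhenotypeKB,
    per_disease: int = 10,
    dropout: float = 0.2,
    noise_rate: float = 2.0,
    seed: int = 0,
    source: str = "synthetic_train",
) -> list[PatientRecord]:
    """Simulate ``per_disease`` labelled patients for every KB disease.

    Each patient keeps every annotated term independently with probability
    ``1 - dropout``, then gains ``k ~ Poisson(noise_rate)`` noise terms drawn
    uniformly (without replacement) from the KB vocabulary minus the
    disease's own set.  A patient left with zero kept terms receives one
    uniformly chosen annotated term so records are never empty.  Fully
    reproducible from ``seed``.
    """
    if not (0.0 <= dropout < 1.0):
        raise InputError(f"dropout must be in [0, 1), got {dropout}")
    if noise_rate < 0.0:
        raise InputError(f"noise_rate must be >= 0, got {noise_rate}")
    if len(kb) == 0:
        raise InputError("knowledge base has no diseases")
    rng = np.random.default_rng(seed)
    vocabulary = sorted(kb.term_universe)
    out: list[PatientRecord] = []
    for did in kb.disease_ids():
        annotated = sorted(kb.phenotypes_of(did))
        other = [t for t in vocabulary if t not in set(annotated)]
        for i in range(per_disease):
            keep = [t for t in annotated if rng.random() >= dropout]
            if not keep:
                keep = [annotated[rng.integers(len(annotated))]]
            k = int(rng.poisson(noise_rate))
            k = min(k, len(other))
            noise = (
                [other[j] for j in rng.choice(len(other), size=k, replace=False)]
                if k
                else []
            )
            out.append(
                PatientRecord(
                    patient_id=f"{did}#{i}",
                    phenotypes=sorted(set(keep) | set(noise)),
                    true_disease=did,
                    source=source,
                )
            )
    return out


def build_features(
    patients: Sequence[PatientRecord],
    graph: OntologyGraph,
    ic: InformationContentTable,
    vocabulary: Sequence[str],
    drop_zero_rows: bool = False,
) -> FeatureMatrix:
    """Embed patients as IC-weighted propagated rows over ``vocabulary``.

    Patients with no resolvable term are dropped (tallied in ``n_dropped``
    and reported via a warning).  ``drop_zero_rows`` additionally removes
    patients whose resolvable terms all have zero weight.
    """
    vocab = list(vocabulary)
    index = {t: i for i, t in enumerate(vocab)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    row_ids: list[str] = []
    labels: list[str | None] = []
    dropped = 0
    r = 0
    for p in patients:
        try:
            entries, _ = query_vector(p.phenotypes, graph, ic, index)
        except InputError:
            dropped += 1
            continue
        if drop_zero_rows and not entries:
            dropped += 1
            continue
        for t, w in entries.items():
            rows.append(r)
            cols.append(index[t])
            vals.append(w)
        row_ids.append(p.patient_id)
        labels.append(p.true_disease)
        r += 1
    if dropped:
        warnings.warn(f"dropped {dropped} patient record(s) during feature construction")
    X = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(row_ids), len(vocab)), dtype=np.float64
    )
    return FeatureMatrix(row_ids=row_ids, vocabulary=vocab, X=X, labels=labels, n_dropped=dropped)


def make_estimator(spec: ClassifierSpec, n_features: int):
    """Instantiate the sklearn backend for a classifier spec.

    Hyperparameters in the spec override the defaults; backend randomness is
    tied to ``spec.seed``.
    """
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "logistic_regression":
        hp.setdefault("max_iter", 1000)
        return LogisticRegression(**hp)
    if spec.algorithm == "knn":
        hp.setdefault("n_neighbors", 5)
        return KNeighborsClassifier(**hp)
    if spec.algorithm == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.algorithm == "extra_trees":
        hp.setdefault("n_estimators", 100)
        return ExtraTreesClassifier(random_state=spec.seed, **hp)
    if spec.algorithm == "naive_bayes":
        return MultinomialNB(**hp)
    if spec.algorithm == "deep_neural_network":
        hp.setdefault("hidden_layer_sizes", (min(256, max(1, n_features)),))
        hp.setdefault("max_iter", 500)
        return MLPClassifier(random_state=spec.seed, **hp)
    raise InputError(f"unknown algorithm: {spec.algorithm!r}")


def _member_proba(model, X: sparse.csr_matrix, label_set: list[str]) -> np.ndarray:
    """Probability rows over the full ``label_set`` (zeros for unseen labels)."""
    proba = model.predict_proba(X)
    out = np.zeros((X.shape[0], len(label_set)))
    col = {lbl: j for j, lbl in enumerate(label_set)}
    for i, cls in enumerate(model.classes_):
        out[:, col[cls]] = proba[:, i]
    return out


def train_ensemble(
    fm: FeatureMatrix,
    specs: Sequence[ClassifierSpec],
    validation_fraction: float = 0.2,
    seed: int = 0,
) -> TrainedEnsemble:
    """Train every backend and weight members by validation top-1 accuracy.

    With ``validation_fraction > 0`` a stratified split is held out; each
    member's weight is its top-1 accuracy on that split, normalized across
    members (uniform fallback when all accuracies are zero or when
    ``validation_fraction == 0``).  A backend that fails to train is dropped
    with a warning; all backends failing is a :class:`TrainingError`.
    """
    if not specs:
        raise InputError("at least one classifier spec is required")
    if not (0.0 <= validation_fraction < 1.0):
        raise InputError("validation_fraction must be in [0, 1)")
    y = np.array([lbl if lbl is not None else "" for lbl in fm.labels])
    if (y == "").any():
        raise InputError("all feature rows must carry a true-disease label")
    label_set = sorted(set(y))

    if validation_fraction > 0:
        X_tr, X_va, y_tr, y_va = train_test_split(
            fm.X,
            y,
            test_size=validation_fraction,
            stratify=y,
            random_state=seed,
        )
    else:
        X_tr, y_tr = fm.X, y
        X_va = y_va = None

    trained: list[tuple[ClassifierSpec, object, float]] = []
    accuracies: list[float] = []
    for spec in specs:
        model = make_estimator(spec, n_features=len(fm.vocabulary))
        try:
            model.fit(X_tr, y_tr)
            if X_va is not None:
                proba = _member_proba(model, X_va, label_set)
                pred = [label_set[j] for j in proba.argmax(axis=1)]
                acc = float(np.mean([p == t for p, t in zip(pred, y_va)]))
            else:
                acc = 1.0
        except Exception as exc:  # noqa: BLE001 - backend failures are non-fatal
            warnings.warn(f"dropping member {spec.algorithm!r}: training failed ({exc})")
            continue
        trained.append((spec, model, acc))
        accuracies.append(acc)

    if not trained:
        raise TrainingError("every ensemble member failed to train")
    total = sum(accuracies)
    if total <= 0:
        weights = [1.0 / len(trained)] * len(trained)
    else:
        weights = [a / total for a in accuracies]
    members = [(spec, model, w) for (spec, model, _), w in zip(trained, weights)]
    return TrainedEnsemble(members=members, label_set=label_set, vocabulary=fm.vocabulary)


def ensemble_distributions(ensemble: TrainedEnsemble, X: sparse.csr_matrix) -> np.ndarray:
    """Combined probability rows over ``ensemble.label_set`` for ``X``."""
    combined = np.zeros((X.shape[0], len(ensemble.label_set)))
    for _, model, w in ensemble.members:
        combined += w * _member_proba(model, X, ensemble.label_set)
    return combined


def rank_ml(
    query: Sequence[str],
    ensemble: TrainedEnsemble,
    graph: OntologyGraph,
    ic: InformationContentTable,
    model_name: str = "cpml",
) -> RankedResult:
    """Rank candidate diseases for a term query through the ensemble."""
    entries, _ = query_vector(query, graph, ic, ensemble.vocabulary)
    index = {t: i for i, t in enumerate(ensemble.vocabulary)}
    row = sparse.csr_matrix(
        (
            list(entries.values()),
            ([0] * len(entries), [index[t] for t in entries]),
        ),
        shape=(1, len(ensemble.vocabulary)),
        dtype=np.float64,
    )
    combined = ensemble_distributions(ensemble, row)[0]
    scores = {d: float(s) for d, s in zip(ensemble.label_set, combined)}
    dist = ens.ScoreDistribution(scores, normalized=True)
    return RankedResult(items=_sort_items(dist.scores), query_terms=list(query), model=model_name)


def save_ensemble(ensemble: TrainedEnsemble, path: str | Path) -> None:
    """Persist a trained ensemble: JSON manifest + pickled member blobs."""
    import json

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "label_set": ensemble.label_set,
        "vocabulary": ensemble.vocabulary,
        "members": [
            {
                "algorithm": spec.algorithm,
                "hyperparameters": spec.hyperparameters,
                "seed": spec.seed,
                "weight": w,
                "blob": f"member_{i}.pkl",
            }
            for i, (spec, _, w) in enumerate(ensemble.members)
        ],
    }
    (path / "ensemble.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    for i, (_, model, _) in enumerate(ensemble.members):
        with open(path / f"member_{i}.pkl", "wb") as fh:
            pickle.dump(model, fh)


def load_ensemble(path: str | Path) -> TrainedEnsemble:
    import json

    path = Path(path)
    manifest = json.loads((path / "ensemble.json").read_text())
    members = []
    for m in manifest["members"]:
        with open(path / m["blob"], "rb") as fh:
            model = pickle.load(fh)
        spec = ClassifierSpec(m["algorithm"], m.get("hyperparameters", {}), m.get("seed", 0))
        members.append((spec, model, m["weight"]))
    return TrainedEnsemble(
        members=members,
        label_set=manifest["label_set"],
        vocabulary=manifest["vocabulary"],
    )
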