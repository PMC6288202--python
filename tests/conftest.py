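import pytest

from raredx import ml_models as ml
from raredx.knowledge_base import DiseasePhenotypeKB, DiseaseRecord
from raredx.ontology import compute_ic, parse_obo, tfidf_hierarchy_weights
from raredx.synthetic_data import (
    SyntheticSpec,
    make_gene_map,
    make_patient_cohort,
    make_toy_kb,
    make_toy_ontology,
)

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: T:0000001
name: root

[Term]
id: T:0000002
name: middle
alt_id: T:0000009
is_a: T:0000001

[Term]
id: T:0000003
name: leaf
is_a: T:0000002
"""

DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: T:0000001
name: root

[Term]
id: T:0000002
name: left
is_a: T:0000001

[Term]
id: T:0000003
name: right
is_a: T:0000001

[Term]
id: T:0000004
name: bottom
is_a: T:0000002
is_a: T:0000003
"""

T1, T2, T3, T4 = "T:0000001", "T:0000002", "T:0000003", "T:0000004"


@pytest.fixture
def chain_graph():
    return parse_obo(CHAIN_OBO)


@pytest.fixture
def diamond_graph():
    return parse_obo(DIAMOND_OBO)


def make_kb(annotations: dict[str, set[str]], mode: str = "curated_only") -> DiseasePhenotypeKB:
    """Direct KB construction helper for hand-built toy cases."""
    diseases = {
        did: DiseaseRecord(did, did, {t: "curated" for t in terms})
        for did, terms in annotations.items()
    }
    return DiseasePhenotypeKB(diseases=diseases, mode=mode)


@pytest.fixture
def diamond_kb():
    # propagated closures: D1 -> all four, D2 -> {T2,T1}, D3 -> {T3,T1}, D4 -> {T1}
    return make_kb({"D:1": {T4}, "D:2": {T2}, "D:3": {T3}, "D:4": {T1}})


@pytest.fixture(scope="session")
def desk_setup():
    """Desk-scale synthetic world: ontology, KB, IC, weights, gene map."""
    spec = SyntheticSpec(n_terms=200, n_diseases=30, seed=11)
    graph, obo = make_toy_ontology(spec)
    kb = make_toy_kb(graph, spec)
    gm = make_gene_map(graph, spec)
    ic = compute_ic(graph, kb)
    wm = tfidf_hierarchy_weights(graph, kb, ic)
    return {"spec": spec, "graph": graph, "obo": obo, "kb": kb, "gm": gm, "ic": ic, "wm": wm}


@pytest.fixture(scope="session")
def ml_setup():
    """50-disease noisy fixture with a trained 3-member ensemble and a
    held-out test cohort; shared by the ML and sensitivity acceptance tests."""
    spec = SyntheticSpec(n_terms=300, n_diseases=50, seed=42, dropout=0.2, noise_rate=2.0)
    graph, _ = make_toy_ontology(spec)
    kb = make_toy_kb(graph, spec)
    ic = compute_ic(graph, kb)
    wm = tfidf_hierarchy_weights(graph, kb, ic)
    train_patients = ml.generate_training_patients(
        kb, per_disease=10, dropout=0.2, noise_rate=2.0, seed=spec.seed
    )
    fm = ml.build_features(train_patients, graph, ic, wm.vocabulary)
    specs = [
        ml.ClassifierSpec("logistic_regression", seed=spec.seed),
        ml.ClassifierSpec("naive_bayes", seed=spec.seed),
        ml.ClassifierSpec("random_forest", seed=spec.seed),
    ]
    ensemble = ml.train_ensemble(fm, specs, validation_fraction=0.2, seed=spec.seed)
    test_cohort = make_patient_cohort(kb, spec, per_disease=5)
    return {
        "spec": spec,
        "graph": graph,
        "kb": kb,
        "ic": ic,
        "wm": wm,
        "ensemble": ensemble,
        "test_cohort": test_cohort,
    }
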