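import numpy as np
import pytest

from raredx import ml_models as ml
from raredx.errors import InputError, TrainingError
from raredx.knowledge_base import MODE_ALL, MODE_CURATED
from raredx.ontology import compute_ic, tfidf_hierarchy_weights
from raredx.synthetic_data import SyntheticSpec, make_toy_kb, make_toy_ontology

from conftest import make_kb


@pytest.fixture(scope="module")
def separable():
    """Small fully separable world: disjoint annotation sets, no noise."""
    spec = SyntheticSpec(n_terms=120, n_diseases=5, terms_per_disease=(6, 8), seed=9)
    graph, _ = make_toy_ontology(spec)
    kb = make_toy_kb(graph, spec, disjoint_support=True)
    ic = compute_ic(graph, kb)
    wm = tfidf_hierarchy_weights(graph, kb, ic)
    patients = ml.generate_training_patients(kb, per_disease=10, dropout=0.0, noise_rate=0.0, seed=1)
    fm = ml.build_features(patients, graph, ic, wm.vocabulary)
    return {"graph": graph, "kb": kb, "ic": ic, "wm": wm, "patients": patients, "fm": fm}


class TestGeneratePatients:
    def test_degenerate_generator_copies_annotations(self, separable):
        kb = separable["kb"]
        patients = ml.generate_training_patients(kb, per_disease=1, dropout=0.0, noise_rate=0.0, seed=0)
        assert len(patients) == len(kb)
        for p in patients:
            assert set(p.phenotypes) == kb.phenotypes_of(p.true_disease)

    def test_count_is_per_disease_times_diseases(self, separable):
        patients = ml.generate_training_patients(separable["kb"], per_disease=10, seed=0)
        assert len(patients) == 10 * len(separable["kb"])

    def test_seeding_contract(self, separable):
        kb = separable["kb"]
        a = ml.generate_training_patients(kb, per_disease=3, dropout=0.3, noise_rate=2, seed=5)
        b = ml.generate_training_patients(kb, per_disease=3, dropout=0.3, noise_rate=2, seed=5)
        c = ml.generate_training_patients(kb, per_disease=3, dropout=0.3, noise_rate=2, seed=6)
        assert [p.phenotypes for p in a] == [p.phenotypes for p in b]
        assert [p.phenotypes for p in a] != [p.phenotypes for p in c]

    def test_no_empty_records(self, separable):
        patients = ml.generate_training_patients(
            separable["kb"], per_disease=20, dropout=0.95, noise_rate=0.0, seed=2
        )
        assert all(p.phenotypes for p in patients)

    def test_invalid_rates_raise(self, separable):
        with pytest.raises(InputError):
            ml.generate_training_patients(separable["kb"], dropout=1.0)
        with pytest.raises(InputError):
            ml.generate_training_patients(separable["kb"], noise_rate=-1.0)


class TestBuildFeatures:
    def test_exact_patient_row_equals_kb_row(self, separable):
        kb, graph, ic, wm = (separable[k] for k in ("kb", "graph", "ic", "wm"))
        did = kb.disease_ids()[0]
        p = ml.PatientRecord("p0", sorted(kb.phenotypes_of(did)), did)
        fm = ml.build_features([p], graph, ic, wm.vocabulary)
        row = {wm.vocabulary[j]: fm.X[0, j] for j in fm.X[0].nonzero()[1]}
        assert row == pytest.approx(wm.row(did))

    def test_duplicate_terms_idempotent(self, separable):
        kb, graph, ic, wm = (separable[k] for k in ("kb", "graph", "ic", "wm"))
        terms = sorted(kb.phenotypes_of(kb.disease_ids()[0]))
        fm1 = ml.build_features([ml.PatientRecord("a", terms)], graph, ic, wm.vocabulary)
        fm2 = ml.build_features([ml.PatientRecord("a", terms + terms)], graph, ic, wm.vocabulary)
        assert (fm1.X != fm2.X).nnz == 0

    def test_unresolvable_patient_dropped_with_warning(self, separable):
        graph, ic, wm = (separable[k] for k in ("graph", "ic", "wm"))
        good = ml.PatientRecord("g", sorted(separable["kb"].phenotypes_of("RD:00001")), "RD:00001")
        bad = ml.PatientRecord("b", ["X:0000001"], "RD:00002")
        with pytest.warns(UserWarning, match="dropped 1"):
            fm = ml.build_features([good, bad], graph, ic, wm.vocabulary)
        assert fm.row_ids == ["g"] and fm.n_dropped == 1

    def test_labels_copied(self, separable):
        fm = separable["fm"]
        assert all(lbl is not None for lbl in fm.labels)


class TestTrainEnsemble:
    def test_single_member_uniform_weight(self, separable):
        ens = ml.train_ensemble(
            separable["fm"], [ml.ClassifierSpec("naive_bayes")], validation_fraction=0.0
        )
        assert [w for _, _, w in ens.members] == [1.0]

    def test_separable_validation_accuracy_one(self, separable):
        specs = [
            ml.ClassifierSpec("logistic_regression"),
            ml.ClassifierSpec("naive_bayes"),
            ml.ClassifierSpec("random_forest"),
        ]
        ens = ml.train_ensemble(separable["fm"], specs, validation_fraction=0.2, seed=0)
        # every member perfectly separates -> equal (uniform) weights
        for _, _, w in ens.members:
            assert w == pytest.approx(1.0 / 3.0)

    def test_weights_sum_to_one(self, separable):
        specs = [ml.ClassifierSpec("knn"), ml.ClassifierSpec("naive_bayes")]
        ens = ml.train_ensemble(separable["fm"], specs, validation_fraction=0.2, seed=1)
        assert sum(w for _, _, w in ens.members) == pytest.approx(1.0)

    def test_no_specs_raises(self, separable):
        with pytest.raises(InputError):
            ml.train_ensemble(separable["fm"], [])

    def test_failing_backend_dropped(self, separable):
        specs = [
            ml.ClassifierSpec("naive_bayes"),
            ml.ClassifierSpec("knn", hyperparameters={"n_neighbors": 10_000}),
        ]
        with pytest.warns(UserWarning, match="dropping member"):
            ens = ml.train_ensemble(separable["fm"], specs, validation_fraction=0.2, seed=0)
        assert len(ens.members) == 1

    def test_all_backends_failing_raises(self, separable):
        specs = [ml.ClassifierSpec("knn", hyperparameters={"n_neighbors": 10_000})]
        with pytest.warns(UserWarning):
            with pytest.raises(TrainingError):
                ml.train_ensemble(separable["fm"], specs, validation_fraction=0.2)

    @pytest.mark.filterwarnings("ignore::UserWarning")  # MLP convergence chatter
    @pytest.mark.parametrize("algorithm", ml.ALGORITHMS)
    def test_every_backend_trains_and_predicts(self, separable, algorithm):
        spec = ml.ClassifierSpec(algorithm, seed=0)
        if algorithm == "deep_neural_network":
            spec.hyperparameters = {"hidden_layer_sizes": (32,), "max_iter": 200}
        ens = ml.train_ensemble(separable["fm"], [spec], validation_fraction=0.0)
        proba = ml.ensemble_distributions(ens, separable["fm"].X[:3])
        assert proba.shape == (3, len(ens.label_set))
        assert np.all(proba >= 0)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)


@pytest.fixture(scope="module")
def trained(separable):
    specs = [ml.ClassifierSpec("logistic_regression"), ml.ClassifierSpec("naive_bayes")]
    return ml.train_ensemble(separable["fm"], specs, validation_fraction=0.2, seed=0)


class TestRankMl:
    def test_separable_exact_query_ranks_first(self, separable, trained):
        kb, graph, ic = separable["kb"], separable["graph"], separable["ic"]
        for did in kb.disease_ids():
            result = ml.rank_ml(sorted(kb.phenotypes_of(did)), trained, graph, ic)
            assert result.items[0][0] == did

    def test_single_member_identity(self, separable):
        graph, ic, kb = separable["graph"], separable["ic"], separable["kb"]
        ens = ml.train_ensemble(
            separable["fm"], [ml.ClassifierSpec("naive_bayes")], validation_fraction=0.0
        )
        query = sorted(kb.phenotypes_of(kb.disease_ids()[0]))
        result = ml.rank_ml(query, ens, graph, ic)
        _, model, _ = ens.members[0]
        fm = ml.build_features([ml.PatientRecord("q", query)], graph, ic, ens.vocabulary)
        expected = model.predict_proba(fm.X)[0]
        got = dict(result.items)
        for j, cls in enumerate(model.classes_):
            assert got[cls] == pytest.approx(expected[j])

    def test_distribution_contract(self, separable, trained):
        graph, ic, kb = separable["graph"], separable["ic"], separable["kb"]
        result = ml.rank_ml(sorted(kb.phenotypes_of("RD:00002")), trained, graph, ic)
        scores = [s for _, s in result.items]
        assert all(s >= 0 for s in scores)
        assert sum(scores) == pytest.approx(1.0, abs=1e-9)

    def test_unresolvable_query_raises(self, separable, trained):
        with pytest.raises(InputError):
            ml.rank_ml(["X:0000001"], trained, separable["graph"], separable["ic"])

    def test_reproducible_rankings(self, separable):
        graph, ic, kb, fm = (separable[k] for k in ("graph", "ic", "kb", "fm"))
        specs = [ml.ClassifierSpec("random_forest", seed=7)]
        e1 = ml.train_ensemble(fm, specs, validation_fraction=0.2, seed=7)
        e2 = ml.train_ensemble(fm, specs, validation_fraction=0.2, seed=7)
        q = sorted(kb.phenotypes_of("RD:00003"))
        assert ml.rank_ml(q, e1, graph, ic).items == ml.rank_ml(q, e2, graph, ic).items


class TestPersistence:
    def test_save_load_round_trip(self, separable, tmp_path):
        graph, ic, kb = separable["graph"], separable["ic"], separable["kb"]
        specs = [ml.ClassifierSpec("naive_bayes"), ml.ClassifierSpec("logistic_regression")]
        ens = ml.train_ensemble(separable["fm"], specs, validation_fraction=0.2, seed=0)
        ml.save_ensemble(ens, tmp_path / "ens")
        again = ml.load_ensemble(tmp_path / "ens")
        assert again.label_set == ens.label_set
        assert again.vocabulary == ens.vocabulary
        q = sorted(kb.phenotypes_of("RD:00001"))
        assert ml.rank_ml(q, again, graph, ic).items == ml.rank_ml(q, ens, graph, ic).items


class TestApmlCpmlRelation:
    def test_identical_when_no_text_mined_layer(self):
        spec = SyntheticSpec(n_terms=100, n_diseases=8, seed=4)
        graph, _ = make_toy_ontology(spec)
        kb_c = make_toy_kb(graph, spec, mode=MODE_CURATED)
        kb_a = make_toy_kb(graph, spec, mode=MODE_ALL)  # no text-mined terms drawn
        for did in kb_c.disease_ids():
            assert kb_c.phenotypes_of(did) == kb_a.phenotypes_of(did)

        def pipeline(kb):
            ic = compute_ic(graph, kb)
            wm = tfidf_hierarchy_weights(graph, kb, ic)
            pats = ml.generate_training_patients(kb, per_disease=6, dropout=0.2, noise_rate=1, seed=3)
            fm = ml.build_features(pats, graph, ic, wm.vocabulary)
            ens = ml.train_ensemble(fm, [ml.ClassifierSpec("naive_bayes")], seed=3)
            q = sorted(kb.phenotypes_of(kb.disease_ids()[0]))
            return ml.rank_ml(q, ens, graph, ic).items

        assert pipeline(kb_c) == pipeline(kb_a)
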