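import numpy as np
import pandas as pd
import pytest

from madsbox.classify import (
    EvaluationReport,
    NotMikcError,
    cross_validate,
    evaluate,
    get_recipe,
    load_models,
    predict,
    registered_recipes,
    save_models,
    select_model,
    train_model,
)
from madsbox.domain_scan import DomainAnnotation, RegionTag, annotate_domains
from madsbox.features import build_reference_databases
from madsbox.seqio import CLASS_ORDER, GeneClass
from madsbox.simdata import SyntheticFamilySpec, generate_families, truncate


class TestRegisteredRecipes:
    def test_exactly_nine_with_unique_ids(self):
        recipes = registered_recipes()
        assert len(recipes) == 9
        assert len({r.recipe_id for r in recipes}) == 9

    def test_m_combined_recipe_requires_only_m(self):
        assert get_recipe("m-sim+bindn").required_regions == frozenset({RegionTag.M})

    def test_whole_recipe_requires_full_domain_content(self):
        assert get_recipe("whole-sim").required_regions == frozenset(
            {RegionTag.M, RegionTag.I, RegionTag.K, RegionTag.C_TERM}
        )


@pytest.fixture(scope="module")
def trained_small(small_dataset, scheme, encoder_configs):
    dbs = build_reference_databases(small_dataset)
    model = train_model(
        small_dataset, "c-sim", dbs, scheme, encoder_configs, seed=3
    )
    return small_dataset, dbs, model


class TestTrainModel:
    def test_separable_synthetic_features_reach_perfect_cv(self, trained_small):
        _, _, model = trained_small
        # class-signature k-mers in the C domain make c-sim separable
        assert model.cv_accuracy == 1.0

    def test_shuffled_labels_give_chance_level_cv(self, small_dataset, scheme, encoder_configs):
        rng = np.random.default_rng(0)
        entries = list(small_dataset.entries)
        labels = [cls for _, cls, _ in entries]
        rng.shuffle(labels)
        shuffled = type(small_dataset)(
            name="shuffled",
            entries=[(s, l, a) for (s, _, a), l in zip(entries, labels)],
        )
        dbs = build_reference_databases(shuffled)
        model = train_model(shuffled, "c-sim", dbs, scheme, encoder_configs, seed=3)
        # chance is 1/8; allow 3 sigma of binomial noise at n=24
        n = len(shuffled)
        sigma = np.sqrt(0.125 * 0.875 / n)
        assert model.cv_accuracy <= 0.125 + 4 * sigma

    def test_same_seed_reproduces_predictions(self, small_dataset, scheme, encoder_configs):
        dbs = build_reference_databases(small_dataset)
        m1 = train_model(small_dataset, "c-sim", dbs, scheme, encoder_configs, seed=5)
        m2 = train_model(small_dataset, "c-sim", dbs, scheme, encoder_configs, seed=5)
        probe = small_dataset.entries[:5]
        for seq, _, ann in probe:
            p1 = predict(seq, [m1], dbs, scheme, encoder_configs, annotation=ann)
            p2 = predict(seq, [m2], dbs, scheme, encoder_configs, annotation=ann)
            assert p1.predicted is p2.predicted
            assert p1.confidence == p2.confidence

    def test_degenerate_class_sizes_error(self, small_dataset, scheme, encoder_configs):
        tiny = small_dataset.subset(
            [e[0].id for e in small_dataset.entries[:3]], name="tiny"
        )
        dbs = build_reference_databases(small_dataset)
        with pytest.raises(ValueError, match="degenerate"):
            train_model(tiny, "c-sim", dbs, scheme, encoder_configs, seed=0)


class TestCrossValidate:
    def test_three_folds_in_unit_interval(self, small_dataset, scheme, encoder_configs):
        res = cross_validate(small_dataset, "c-sim", k=3, seed=2,
                             scheme=scheme, configs=encoder_configs)
        assert len(res.fold_accuracies) == 3
        assert all(0.0 <= a <= 1.0 for a in res.fold_accuracies)

    def test_same_seed_gives_identical_folds(self, small_dataset, scheme, encoder_configs):
        r1 = cross_validate(small_dataset, "c-sim", k=3, seed=2,
                            scheme=scheme, configs=encoder_configs)
        r2 = cross_validate(small_dataset, "c-sim", k=3, seed=2,
                            scheme=scheme, configs=encoder_configs)
        assert r1.fold_accuracies == r2.fold_accuracies


class TestSelectModel:
    def test_full_sequence_feasible_set_is_all_nine(self, pipeline):
        seq, cls, ann = pipeline.bundle.test.entries[0]
        chosen = select_model(ann, pipeline.models)
        best = max(pipeline.models, key=lambda m: m.cv_accuracy)
        assert chosen.cv_accuracy == best.cv_accuracy

    def test_m_only_fragment_routes_to_an_m_recipe(self, pipeline):
        seq, cls, ann = pipeline.bundle.fragment_sets["M"].entries[0]
        chosen = select_model(ann, pipeline.models)
        assert chosen.recipe.required_regions <= {RegionTag.M}

    def test_non_mikc_is_rejected(self, pipeline):
        ann = DomainAnnotation("q", {}, is_mikc=False)
        with pytest.raises(NotMikcError):
            select_model(ann, pipeline.models)

    def test_routing_soundness_over_random_truncations(self, pipeline):
        """model_used never requires a region absent from the annotation."""
        rng = np.random.default_rng(4)
        order = (RegionTag.M, RegionTag.I, RegionTag.K, RegionTag.C_TERM)
        for seq, cls, ann in pipeline.bundle.test.entries:
            start = int(rng.integers(0, 4))
            stop = int(rng.integers(start, 4)) + 1
            keep = set(order[start:stop])
            frag, frag_ann = truncate(seq, ann, keep)
            if not frag_ann.is_mikc:
                continue
            chosen = select_model(frag_ann, pipeline.models)
            assert chosen.recipe.required_regions <= frag_ann.present_regions


class TestPredict:
    def test_confidences_sum_to_one(self, pipeline):
        for seq, cls, ann in pipeline.bundle.test.entries[:4]:
            p = predict(seq, pipeline.models, pipeline.refdbs,
                        pipeline.scheme, pipeline.configs)
            assert abs(sum(p.confidence.values()) - 1.0) < 1e-6
            assert p.predicted is max(p.confidence, key=lambda c: p.confidence[c])

    def test_held_out_members_recover_their_class(self, pipeline):
        rows = pipeline.heldout_report.rows
        d_rows = rows[rows["gene_class"] == "D"]
        assert (d_rows["predicted_class"] == "D").all()
        assert (d_rows["D"] > 0.5).all()

    def test_m_only_fragment_uses_an_m_model(self, pipeline):
        seq, cls, ann = pipeline.bundle.fragment_sets["M"].entries[0]
        p = predict(seq, pipeline.models, pipeline.refdbs,
                    pipeline.scheme, pipeline.configs)
        assert p.model_used in {"m-sim", "m-bindn", "m-sim+bindn"}


class TestEvaluateArithmetic:
    @staticmethod
    def _rows(n_correct, n_total):
        records = []
        for i in range(n_total):
            cls = CLASS_ORDER[i % 8].value
            ok = i < n_correct
            pred = cls if ok else CLASS_ORDER[(i + 1) % 8].value
            row = {"gene": f"g{i}", "gene_class": cls, "predicted_class": pred,
                   "model_used": "whole-sim", "correct": ok}
            row.update({c.value: 1.0 / 8 for c in CLASS_ORDER})
            records.append(row)
        return pd.DataFrame.from_records(records)

    def test_24_of_26_is_92_31_percent(self):
        report = EvaluationReport.from_rows(self._rows(24, 26))
        assert report.accuracy_percent == 92.31

    def test_14_of_15_is_93_33_percent(self):
        report = EvaluationReport.from_rows(self._rows(14, 15))
        assert report.accuracy_percent == 93.33

    def test_all_correct_has_clean_confusion(self):
        report = EvaluationReport.from_rows(self._rows(16, 16))
        assert report.accuracy_percent == 100.0
        off_diag = report.confusion.to_numpy().sum() - np.trace(
            report.confusion.to_numpy()[:, :8]
        )
        assert off_diag == 0


class TestModelBundles:
    def test_save_load_round_trip_predictions(self, tmp_path, trained_small,
                                              scheme, encoder_configs):
        dataset, dbs, model = trained_small
        save_models([model], tmp_path / "models")
        loaded = load_models(tmp_path / "models")
        assert len(loaded) == 1
        assert loaded[0].recipe.recipe_id == "c-sim"
        assert loaded[0].cv_accuracy == model.cv_accuracy
        seq, _, ann = dataset.entries[0]
        p1 = predict(seq, [model], dbs, scheme, encoder_configs, annotation=ann)
        p2 = predict(seq, loaded, dbs, scheme, encoder_configs, annotation=ann)
        assert p1.predicted is p2.predicted
        assert p1.confidence == pytest.approx(p2.confidence)
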