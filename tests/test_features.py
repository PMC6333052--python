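import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from madsbox.align import local_align
from madsbox.coils import CoilsProfile
from madsbox.domain_scan import DomainAnnotation, RegionTag
from madsbox.features import (
    BINDN_BLOCK_LENGTH,
    ClassSimilarityVector,
    EncoderConfigs,
    ReferenceDatabase,
    RegionUnavailableError,
    build_feature_vector,
    build_reference_databases,
    encode_bindn_block,
    encode_class_similarity,
    encode_coils_block,
)
from madsbox.seqio import CLASS_ORDER, GeneClass, LabeledDataset, ProteinSequence


def _random_protein(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


def _simdb(per_class):
    return ReferenceDatabase(region=RegionTag.WHOLE, per_class=per_class)


class TestBuildReferenceDatabases:
    def test_five_databases_whole_has_everything(self, small_dataset):
        dbs = build_reference_databases(small_dataset)
        assert set(dbs) == {RegionTag.WHOLE, *(t for t in RegionTag if t is not RegionTag.WHOLE)}
        assert dbs[RegionTag.WHOLE].n_sequences == len(small_dataset)
        counts = small_dataset.class_counts()
        for cls in CLASS_ORDER:
            assert len(dbs[RegionTag.WHOLE].per_class[cls]) == counts[cls]

    def test_sequence_without_k_absent_from_k_database(self, small_dataset):
        entries = []
        for i, (seq, cls, ann) in enumerate(small_dataset.entries):
            if i == 0:
                spans = {RegionTag.M: ann.spans[RegionTag.M]}
                ann = DomainAnnotation(ann.sequence_id, spans, is_mikc=True,
                                       sequence_length=len(seq.residues))
            entries.append((seq, cls, ann))
        ds = LabeledDataset(name="t", entries=entries)
        dbs = build_reference_databases(ds)
        k_ids = {s.id for members in dbs[RegionTag.K].per_class.values() for s in members}
        whole_ids = {s.id for members in dbs[RegionTag.WHOLE].per_class.values() for s in members}
        first = entries[0][0].id
        assert first not in k_ids and first in whole_ids

    def test_missing_class_is_an_error(self, small_dataset):
        ds = LabeledDataset(
            name="noA",
            entries=[e for e in small_dataset.entries if e[1] is not GeneClass.A],
        )
        with pytest.raises(ValueError, match="class"):
            build_reference_databases(ds)

    def test_empty_training_set_is_an_error(self):
        with pytest.raises(ValueError):
            build_reference_databases(LabeledDataset(name="empty", entries=[]))

    def test_region_sequences_are_span_restricted(self, small_dataset):
        dbs = build_reference_databases(small_dataset)
        seq, cls, ann = small_dataset.entries[0]
        m_members = {s.id: s for s in dbs[RegionTag.M].per_class[cls]}
        s, e = ann.spans[RegionTag.M]
        assert m_members[seq.id].residues == seq.residues[s:e]


class TestEncodeClassSimilarity:
    def test_dissimilar_query_encodes_all_zero(self, scheme):
        rng = np.random.default_rng(5)
        per_class = {
            cls: [ProteinSequence(f"{cls.value}_0", _random_protein(rng, 25))]
            for cls in CLASS_ORDER
        }
        # a short query unrelated to every reference: nothing passes the gate
        query = ProteinSequence("q", "MA")
        vec = encode_class_similarity(query, _simdb(per_class), scheme)
        assert (vec.values == 0).all()

    def test_exact_copy_yields_self_bit_score_and_zero_elsewhere(self, scheme):
        rng = np.random.default_rng(6)
        query = ProteinSequence("q", _random_protein(rng, 60))
        per_class = {
            cls: [ProteinSequence(f"{cls.value}_0", _random_protein(rng, 60))]
            for cls in CLASS_ORDER
        }
        per_class[GeneClass.D] = [ProteinSequence("copy", query.residues)]
        vec = encode_class_similarity(query, _simdb(per_class), scheme)
        self_bits = local_align(query, query, scheme).bit_score
        d_idx = CLASS_ORDER.index(GeneClass.D)
        assert vec.values[d_idx] == pytest.approx(self_bits)
        others = np.delete(vec.values, d_idx)
        assert (others == 0).all()

    def test_self_exclusion_on_singleton_class(self, scheme):
        rng = np.random.default_rng(7)
        member = ProteinSequence("ref1", _random_protein(rng, 60))
        per_class = {cls: [] for cls in CLASS_ORDER}
        per_class[GeneClass.E] = [member]
        vec = encode_class_similarity(
            member, _simdb(per_class), scheme, exclude_self_id="ref1"
        )
        assert (vec.values == 0).all()

    def test_permutation_invariance_and_threshold_monotonicity(self, scheme):
        rng = np.random.default_rng(8)
        base = _random_protein(rng, 70)
        def mutant():
            chars = list(base)
            for i in rng.choice(70, size=10, replace=False):
                chars[i] = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"))
            return "".join(chars)
        members = [ProteinSequence(f"m{i}", mutant()) for i in range(4)]
        per_class = {cls: [] for cls in CLASS_ORDER}
        per_class[GeneClass.A] = members
        db_fwd = _simdb(dict(per_class))
        per_class[GeneClass.A] = members[::-1]
        db_rev = _simdb(dict(per_class))
        q = ProteinSequence("q", base)
        v1 = encode_class_similarity(q, db_fwd, scheme).values
        v2 = encode_class_similarity(q, db_rev, scheme).values
        np.testing.assert_array_equal(v1, v2)
        loose = encode_class_similarity(q, db_fwd, scheme, evalue_threshold=1e-2).values
        strict = encode_class_similarity(q, db_fwd, scheme, evalue_threshold=1e-30).values
        assert (loose >= strict).all()

    def test_vector_shape_is_validated(self):
        with pytest.raises(ValueError):
            ClassSimilarityVector(values=np.zeros(7), evalue_threshold=1e-5)


class TestEncodeBindnBlock:
    def test_full_length_layout(self):
        vec = encode_bindn_block("A" * 57)
        assert vec.shape == (BINDN_BLOCK_LENGTH,)
        triplet = vec[:3]
        for i in range(57):
            np.testing.assert_array_equal(vec[3 * i: 3 * i + 3], triplet)

    def test_short_m_domain_is_zero_padded(self):
        vec = encode_bindn_block("A" * 50)
        assert (vec[150:] == 0).all()
        assert (vec[:150] != 0).any()

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            encode_bindn_block("")

    def test_x_encodes_scale_means(self):
        vx = encode_bindn_block("X")[:3]
        all_res = np.array([encode_bindn_block(r)[:3] for r in "ACDEFGHIKLMNPQRSTVWY"])
        np.testing.assert_allclose(vx, all_res.mean(axis=0), atol=1e-12)


class TestEncodeCoilsBlock:
    def test_constant_profile(self):
        prof = CoilsProfile(probabilities=np.full(30, 0.8), per_window_scores={})
        np.testing.assert_allclose(encode_coils_block(prof, (0, 30)), [0.8, 0.8, 1.0])

    def test_zero_profile(self):
        prof = CoilsProfile(probabilities=np.zeros(30), per_window_scores={})
        np.testing.assert_allclose(encode_coils_block(prof, (5, 25)), [0, 0, 0])

    def test_length_one_span(self):
        prof = CoilsProfile(probabilities=np.array([0.3]), per_window_scores={})
        np.testing.assert_allclose(encode_coils_block(prof, (0, 1)), [0.3, 0.3, 0.0])

    def test_empty_span_is_an_error(self):
        prof = CoilsProfile(probabilities=np.zeros(10), per_window_scores={})
        with pytest.raises(ValueError):
            encode_coils_block(prof, (4, 4))


class TestBuildFeatureVector:
    def test_block_lengths_per_recipe(self, small_dataset, scheme, encoder_configs):
        dbs = build_reference_databases(small_dataset)
        seq, cls, ann = small_dataset.entries[0]
        whole = build_feature_vector(seq, ann, "whole-sim", dbs, scheme, encoder_configs)
        assert whole.flat.shape == (8,)
        combo = build_feature_vector(seq, ann, "m-sim+bindn", dbs, scheme, encoder_configs)
        assert combo.flat.shape == (8 + BINDN_BLOCK_LENGTH,)
        kcoils = build_feature_vector(seq, ann, "k-sim+coils", dbs, scheme, encoder_configs)
        assert kcoils.flat.shape == (8 + 3,)

    def test_missing_region_is_named_in_error(self, small_dataset, scheme, encoder_configs):
        dbs = build_reference_databases(small_dataset)
        seq, cls, ann = small_dataset.entries[0]
        m_only = DomainAnnotation(
            ann.sequence_id, {RegionTag.M: ann.spans[RegionTag.M]},
            is_mikc=True, sequence_length=len(seq.residues),
        )
        with pytest.raises(RegionUnavailableError, match="region unavailable: K"):
            build_feature_vector(seq, m_only, "k-sim+coils", dbs, scheme, encoder_configs)

    def test_deterministic(self, small_dataset, scheme, encoder_configs):
        dbs = build_reference_databases(small_dataset)
        seq, cls, ann = small_dataset.entries[3]
        v1 = build_feature_vector(seq, ann, "c-sim", dbs, scheme, encoder_configs).flat
        v2 = build_feature_vector(seq, ann, "c-sim", dbs, scheme, encoder_configs).flat
        np.testing.assert_array_equal(v1, v2)
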