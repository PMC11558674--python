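"""Embedding container I/O, transforms, clustering, and the target split."""

import numpy as np
import pytest

import pcmolkit as pk
from pcmolkit.embeddings import averaged_matrix, cosine_similarity_fn
from pcmolkit.errors import (ConfigurationError, FormatError, NotFoundError,
                             ValidationError)


def _emb(acc="T1", L=5, seed=0, **kw):
    rng = np.random.default_rng(seed)
    return pk.AlphaFoldEmbedding(
        accession=acc,
        evoformer=rng.standard_normal((L, 384)),
        structure=rng.standard_normal((L, 384)),
        **kw,
    )


class TestContainer:
    def test_round_trip_identity(self, tmp_path):
        emb = _emb(L=5, family="FAM0", species="Homo sapiens")
        pk.save_container([emb], tmp_path / "c.npz", tmp_path / "meta.tsv")
        back = pk.load_embedding(
            tmp_path / "c.npz", "T1",
            {"T1": {"family": "FAM0", "species": "Homo sapiens",
                    "orthologue_group": ""}},
        )
        assert back.accession == emb.accession
        assert back.family == "FAM0"
        np.testing.assert_array_equal(back.evoformer, emb.evoformer)
        np.testing.assert_array_equal(back.structure, emb.structure)

    def test_mismatched_stream_lengths_raise_format_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(FormatError):
            pk.AlphaFoldEmbedding(
                "T1", rng.standard_normal((5, 384)), rng.standard_normal((6, 384))
            )

    def test_missing_accession_raises(self, tmp_path):
        pk.save_container([_emb()], tmp_path / "c.npz")
        with pytest.raises(NotFoundError):
            pk.load_embedding(tmp_path / "c.npz", "NOPE")

    def test_non_finite_entries_rejected(self):
        bad = np.ones((4, 384))
        bad[2, 7] = np.nan
        with pytest.raises(ValidationError):
            pk.AlphaFoldEmbedding("T1", bad, np.ones((4, 384)))

    def test_wrong_width_rejected(self):
        with pytest.raises(ValidationError):
            pk.AlphaFoldEmbedding("T1", np.ones((4, 100)), np.ones((4, 100)))


class TestAverage:
    def test_constant_matrix(self):
        emb = pk.AlphaFoldEmbedding("T", np.full((7, 384), 3.5), np.full((7, 384), -1.0))
        assert np.allclose(pk.average_embedding(emb, "evoformer"), 3.5)
        assert np.allclose(pk.average_embedding(emb, "structure"), -1.0)

    def test_single_residue_identity(self):
        emb = _emb(L=1)
        np.testing.assert_array_almost_equal(
            pk.average_embedding(emb), emb.evoformer[0]
        )

    def test_matches_bruteforce_column_means(self):
        emb = _emb(L=3, seed=5)
        avg = pk.average_embedding(emb, "structure")
        for k in range(384):
            expected = sum(emb.structure[i, k] for i in range(3)) / 3
            assert abs(avg[k] - expected) < 1e-6
        assert avg.shape == (384,)

    def test_invariant_under_row_permutation(self):
        emb = _emb(L=9, seed=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(9)
        emb2 = pk.AlphaFoldEmbedding("T1", emb.evoformer[perm], emb.structure[perm])
        np.testing.assert_allclose(
            pk.average_embedding(emb), pk.average_embedding(emb2), atol=1e-5
        )


class TestShuffle:
    def test_entry_multisets_preserved(self):
        emb = _emb(L=6, seed=1)
        out = pk.shuffle_embedding(emb, seed=4)
        for s in ("evoformer", "structure"):
            assert np.array_equal(
                np.sort(out.stream(s).ravel()), np.sort(emb.stream(s).ravel())
            )
            assert out.stream(s).shape == emb.stream(s).shape

    def test_determinism(self):
        emb = _emb(L=6, seed=1)
        a, b = pk.shuffle_embedding(emb, 9), pk.shuffle_embedding(emb, 9)
        np.testing.assert_array_equal(a.evoformer, b.evoformer)
        np.testing.assert_array_equal(a.structure, b.structure)

    def test_single_residue_still_permutes_features(self):
        emb = _emb(L=1, seed=3)
        out = pk.shuffle_embedding(emb, seed=0)
        assert not np.array_equal(out.evoformer, emb.evoformer)
        assert np.array_equal(
            np.sort(out.evoformer[0]), np.sort(emb.evoformer[0])
        )


class TestStratifiedSplit:
    def _family_fixture(self, n_per_family=25, families=4, seed=0):
        out = []
        for f in range(families):
            for t in range(n_per_family):
                out.append(_emb(f"F{f}T{t}", L=4, seed=f * 100 + t, family=f"FAM{f}"))
        return out

    def test_quota_arithmetic_100_targets(self):
        embs = self._family_fixture()
        split = pk.stratified_split(embs, 0.25, seed=0)
        assert len(split.test_accessions) == 25
        assert split.train_accessions | split.test_accessions == {
            e.accession for e in embs
        }
        assert not (split.train_accessions & split.test_accessions)

    def test_orthologues_move_together(self):
        embs = self._family_fixture(n_per_family=6, families=2)
        for e in embs[:2]:
            e.orthologue_group = "OG1"
        for seed in range(10):
            split = pk.stratified_split(embs, 0.34, seed=seed)
            pair = {embs[0].accession, embs[1].accession}
            assert pair <= split.test_accessions or pair <= split.train_accessions

    def test_determinism(self):
        embs = self._family_fixture(n_per_family=10, families=3)
        s1 = pk.stratified_split(embs, 0.3, seed=5)
        s2 = pk.stratified_split(embs, 0.3, seed=5)
        assert s1 == s2

    def test_single_member_family_goes_to_train(self):
        embs = self._family_fixture(n_per_family=5, families=2)
        lone = _emb("LONE", L=4, seed=77, family="FAMX")
        split = pk.stratified_split(embs + [lone], 0.4, seed=1)
        assert "LONE" in split.train_accessions

    def test_empty_test_set_rejected(self):
        embs = self._family_fixture(n_per_family=2, families=1)
        with pytest.raises(ConfigurationError):
            pk.stratified_split(embs, 0.01, seed=0)

    def test_partition_properties_on_random_fixtures(self):
        rng = np.random.default_rng(12)
        for trial in range(50):
            families = int(rng.integers(2, 5))
            per_family = int(rng.integers(3, 8))
            embs = self._family_fixture(per_family, families, seed=trial)
            if trial % 3 == 0:
                embs[0].orthologue_group = embs[1].orthologue_group = "OG"
            frac = float(rng.uniform(0.2, 0.5))
            seed = int(rng.integers(0, 1000))
            split = pk.stratified_split(embs, frac, seed=seed)
            accs = {e.accession for e in embs}
            assert split.train_accessions | split.test_accessions == accs
            assert not (split.train_accessions & split.test_accessions)
            assert split == pk.stratified_split(embs, frac, seed=seed)
            groups = {}
            for e in embs:
                if e.orthologue_group:
                    groups.setdefault(e.orthologue_group, []).append(e.accession)
            for members in groups.values():
                in_test = [m in split.test_accessions for m in members]
                assert all(in_test) or not any(in_test)

    def test_similarity_concentrates_related_targets(self):
        # two tight sub-clusters inside one family: the weighting should
        # usually pull both members of a sub-cluster into the same side
        base = np.random.default_rng(0).standard_normal((1, 384)) * 10
        embs = []
        for i in range(8):
            center = base if i < 4 else -base
            mat = center + np.random.default_rng(i).standard_normal((4, 384)) * 0.1
            embs.append(pk.AlphaFoldEmbedding(f"T{i}", mat, mat, family="FAM0"))
        together = 0
        for seed in range(20):
            split = pk.stratified_split(embs, 0.5, cosine_similarity_fn, seed=seed)
            first = {f"T{i}" for i in range(4)}
            together += len(first & split.test_accessions) in (0, 4)
        # with similarity weighting this exceeds the uniform-split rate
        assert together >= 8


class TestClusterRecovery:
    def test_planted_families_recovered_at_default_separation(self):
        spec = pk.FixtureSpec(num_families=4, targets_per_family=8,
                              length_range=(20, 40), count_range=(10, 10), seed=5)
        embs = pk.make_embeddings(spec)
        assert pk.cluster_families_ari(embs) >= 0.9

    def test_no_structure_at_zero_separation(self):
        spec = pk.FixtureSpec(num_families=4, targets_per_family=8,
                              length_range=(20, 40), count_range=(10, 10),
                              family_separation=0.0, seed=5)
        embs = pk.make_embeddings(spec)
        assert abs(pk.cluster_families_ari(embs)) < 0.2
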