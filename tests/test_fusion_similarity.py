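"""Fusion similarity model: gradients, symmetry, training, benchmarks."""

import numpy as np
import pytest

from chemfuse._autograd import Tensor
from chemfuse.fusion_similarity import (
    FusionConfig,
    FusionModel,
    PairSample,
    _bundles_to_arrays,
    build_pair_dataset,
    compare_similarity_metrics,
    enrichment_at_k,
    pair_score,
    tanimoto,
    train_fusion,
)


def tiny_model(seed=0, dropout=0.0):
    cfg = FusionConfig(hidden_dim=8, n_heads=2, mlp_dims=(6,), dropout=dropout, seed=seed)
    return FusionModel(selfies_dim=5, fp_dim=12, desc_dim=6, config=cfg)


def random_inputs(rng, n=4):
    return (rng.random((n, 12)), rng.random((n, 6)), rng.random((n, 5)))


class TestAutogradCorrectness:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        m = tiny_model()
        fa, da, sa = random_inputs(rng)
        fb, db, sb = random_inputs(rng)
        y = rng.integers(0, 2, size=(4, 1)).astype(float)

        def loss():
            s = m.score_pairs_raw(fa, da, sa, fb, db, sb)
            return ((s - Tensor(y)) ** 2).mean()

        L = loss()
        L.backward()
        for p in m.parameters:
            flat, grad = p.data.ravel(), p.grad.ravel()
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                eps, old = 1e-6, flat[idx]
                flat[idx] = old + eps
                lp = float(loss().data)
                flat[idx] = old - eps
                lm = float(loss().data)
                flat[idx] = old
                fd = (lp - lm) / (2 * eps)
                assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestModelContracts:
    def test_embedding_length_and_determinism(self):
        rng = np.random.default_rng(1)
        m = tiny_model()
        f, d, s = random_inputs(rng, 1)
        e1 = m.embed(f, d, s).data
        e2 = m.embed(f, d, s).data
        assert e1.shape == (1, 3 * m.config.hidden_dim)
        assert np.array_equal(e1, e2)

    def test_symmetry_over_many_random_pairs(self):
        rng = np.random.default_rng(2)
        m = tiny_model()
        fa, da, sa = random_inputs(rng, 1000)
        fb, db, sb = random_inputs(rng, 1000)
        s_ab = m.score_pairs_raw(fa, da, sa, fb, db, sb).data
        s_ba = m.score_pairs_raw(fb, db, sb, fa, da, sa).data
        assert np.abs(s_ab - s_ba).max() < 1e-7
        assert (s_ab > 0).all() and (s_ab < 1).all()

    def test_untrained_zero_bias_scores_near_half(self):
        m = tiny_model()
        for W in m.mlp_W:
            W.data[:] = 0.0
        rng = np.random.default_rng(3)
        fa, da, sa = random_inputs(rng)
        s = m.score_pairs_raw(fa, da, sa, *random_inputs(rng)).data
        assert np.abs(s - 0.5).max() < 1e-12

    def test_uniform_attention_hook_reproduces_value_mean(self):
        # with weights forced uniform the attended vector is the mean of the
        # two value projections
        rng = np.random.default_rng(4)
        m = tiny_model()
        f, d, s = random_inputs(rng, 3)
        m.force_uniform_attention = True
        emb_uniform = m.embed(f, d, s).data
        m.force_uniform_attention = False

        h, H = m.config.hidden_dim, m.config.n_heads
        Xf = f
        Xd = (d - m.desc_mean) / m.desc_std
        fe = np.maximum(Xf @ m.W_f.data + m.b_f.data, 0)
        fe = (fe - m.bn_f.running_mean) / np.sqrt(m.bn_f.running_var + m.bn_f.eps) * m.bn_f.gamma.data + m.bn_f.beta.data
        de = np.maximum(Xd @ m.W_d.data + m.b_d.data, 0)
        de = (de - m.bn_d.running_mean) / np.sqrt(m.bn_d.running_var + m.bn_d.eps) * m.bn_d.gamma.data + m.bn_d.beta.data
        vmean = 0.5 * (fe @ m.W_v.data + de @ m.W_v.data)
        expected = vmean @ m.W_o.data + m.b_o.data
        assert np.allclose(emb_uniform[:, :h], expected, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        m = tiny_model()
        with pytest.raises(ValueError, match="do not match"):
            m.embed(np.zeros((1, 9)), np.zeros((1, 6)), np.zeros((1, 5)))

    def test_checkpoint_roundtrip(self, tmp_path, trained_fusion, small_bundles):
        path = tmp_path / "model.npz"
        trained_fusion.save(path)
        loaded = FusionModel.load(path)
        a, b = small_bundles[0], small_bundles[1]
        assert pair_score(loaded, a, b) == pytest.approx(pair_score(trained_fusion, a, b), abs=1e-12)
        assert loaded.vocab == trained_fusion.vocab


class TestPairDataset:
    def make_labels(self, pic50s):
        from chemfuse.activity_rules import classify_activity

        return [classify_activity(p) for p in pic50s]

    def make_table(self, n):
        from chemfuse.chem_io import MoleculeRecord, table_from_records

        smis = ["C" * (i + 1) for i in range(n)]
        return table_from_records([MoleculeRecord(id=f"m{i}", smiles=s) for i, s in enumerate(smis)])

    def test_exhaustive_enumeration_counts(self):
        # 3 high + 2 low: C(3,2)=3 positives; 2x3 cross + C(2,2)=7 negatives
        table = self.make_table(5)
        labels = self.make_labels([8, 8, 8, 4, 4])
        pairs = build_pair_dataset(table, labels, balance=False, seed=0)
        assert sum(p.label == 1 for p in pairs) == 3
        assert sum(p.label == 0 for p in pairs) == 7

    def test_medium_molecules_excluded(self):
        table = self.make_table(6)
        labels = self.make_labels([8, 8, 6, 6, 4, 4])
        pairs = build_pair_dataset(table, labels, balance=False, seed=0)
        used = {i for p in pairs for i in (p.a_idx, p.b_idx)}
        assert used.isdisjoint({2, 3})

    def test_label_semantics(self):
        table = self.make_table(5)
        labels = self.make_labels([8, 8, 8, 4, 4])
        for p in build_pair_dataset(table, labels, balance=False, seed=0):
            klasses = {labels[p.a_idx].klass, labels[p.b_idx].klass}
            if p.label == 1:
                assert klasses == {"high"}
            else:
                assert "low" in klasses

    def test_balance_and_determinism(self):
        table = self.make_table(12)
        labels = self.make_labels([8] * 5 + [4] * 7)
        p1 = build_pair_dataset(table, labels, max_pairs=10, balance=True, seed=5)
        p2 = build_pair_dataset(table, labels, max_pairs=10, balance=True, seed=5)
        assert p1 == p2
        assert sum(p.label == 1 for p in p1) == sum(p.label == 0 for p in p1)

    def test_too_few_members_rejected(self):
        table = self.make_table(3)
        labels = self.make_labels([8, 4, 4])
        with pytest.raises(ValueError):
            build_pair_dataset(table, labels)

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            PairSample(3, 3, 1)


class TestTraining:
    def test_loss_decreases_and_history_complete(self, trained_fusion):
        h = trained_fusion.history
        assert h["train_loss"][-1] < h["train_loss"][0]
        assert len(h["train_loss"]) == len(h["val_loss"]) == len(h["lr"])

    def test_validation_pairs_never_used_for_gradients(self, trained_fusion):
        h = trained_fusion.history
        assert set(h["val_pair_indices"]).isdisjoint(h["train_pair_indices"])

    def test_same_seed_reproduces_validation_loss(self, small_table, small_labels, small_vocab, small_bundles):
        pairs = build_pair_dataset(small_table, small_labels, max_pairs=200, seed=7)
        cfg = FusionConfig(hidden_dim=32, n_heads=2, mlp_dims=(16,), max_epochs=3, seed=7)
        losses = []
        for _ in range(2):
            m = FusionModel(len(small_vocab) + 1, 1024, config=cfg, vocab=small_vocab)
            train_fusion(m, pairs, small_bundles)
            losses.append(m.history["val_loss"][-1])
        assert losses[0] == pytest.approx(losses[1], abs=1e-6)

    def test_self_similarity_beats_random_decoy(self, trained_fusion, small_bundles, small_labels):
        rng = np.random.default_rng(0)
        high = [i for i, l in enumerate(small_labels) if l.klass == "high"]
        low = [i for i, l in enumerate(small_labels) if l.klass == "low"]
        wins = 0
        probes = 50
        for _ in range(probes):
            x = int(rng.choice(high))
            decoy = int(rng.choice(low))
            s_self = pair_score(trained_fusion, small_bundles[x], small_bundles[x])
            s_decoy = pair_score(trained_fusion, small_bundles[x], small_bundles[decoy])
            wins += s_self > s_decoy
        assert wins >= 0.9 * probes


class TestTanimoto:
    def test_identical_nonzero(self):
        v = np.array([1, 0, 1, 1], dtype=np.uint8)
        assert tanimoto(v, v) == 1.0

    def test_disjoint(self):
        assert tanimoto(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0.0

    def test_partial_overlap(self):
        a = np.zeros(8); a[[1, 2, 3]] = 1
        b = np.zeros(8); b[[2, 3, 4]] = 1
        assert tanimoto(a, b) == 0.5

    def test_both_empty_convention(self):
        z = np.zeros(16)
        assert tanimoto(z, z) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(np.zeros(4), np.zeros(5))

    def test_matches_brute_force_set_arithmetic(self):
        rng = np.random.default_rng(8)
        fps = (rng.random((50, 64)) < 0.3).astype(np.uint8)
        for i in range(50):
            for j in range(i, 50):
                a_set = set(np.flatnonzero(fps[i]))
                b_set = set(np.flatnonzero(fps[j]))
                union = a_set | b_set
                expected = len(a_set & b_set) / len(union) if union else 1.0
                assert tanimoto(fps[i], fps[j]) == expected


class TestComparisonAndEnrichment:
    def test_unified_records(self, trained_fusion, small_table, small_bundles, small_labels):
        pairs = build_pair_dataset(small_table, small_labels, max_pairs=100, seed=3)
        df, corr = compare_similarity_metrics(trained_fusion, small_table, small_bundles, pairs)
        assert len(df) == len(pairs)
        assert ((df.fusion_score > 0) & (df.fusion_score < 1)).all()
        assert ((df.tanimoto >= 0) & (df.tanimoto <= 1)).all()
        assert corr["n"] == len(pairs)
        # brute-force Pearson on the exported records
        x, t = df.fusion_score.to_numpy(), df.tanimoto.to_numpy()
        expected = np.sum((x - x.mean()) * (t - t.mean())) / (
            len(x) * x.std() * t.std()
        )
        assert corr["pearson_r"] == pytest.approx(expected, abs=1e-10)

    def test_duplicate_pair_has_unit_tanimoto(self, trained_fusion, small_table, small_bundles, small_labels):
        import pandas as pd

        pairs = [PairSample(0, 1, 0)]
        fp0 = small_bundles[0].fp
        small_bundles_dup = list(small_bundles)
        df, _ = compare_similarity_metrics(trained_fusion, small_table, small_bundles_dup, pairs)
        assert isinstance(df, pd.DataFrame)
        assert tanimoto(fp0, fp0) == 1.0

    def test_enrichment_all_top_high(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        high = np.array([True, True, False, False, False])
        e = enrichment_at_k(scores, high, k=2)
        assert e["fraction"] == 1.0
        assert e["fold"] == pytest.approx(1.0 / 0.4)

    def test_enrichment_k_equals_n_is_base_rate(self):
        rng = np.random.default_rng(1)
        scores = rng.random(40)
        high = rng.random(40) < 0.3
        e = enrichment_at_k(scores, high, k=40)
        assert e["fraction"] == e["base_rate"]

    def test_random_scores_null_fold_near_one(self):
        rng = np.random.default_rng(2)
        n, k = 400, 40
        high = np.zeros(n, dtype=bool)
        high[:100] = True
        folds = []
        for _ in range(100):
            scores = rng.random(n)
            folds.append(enrichment_at_k(scores, high, k)["fold"])
        # Monte-Carlo CI around the permutation-null mean of 1
        assert np.mean(folds) == pytest.approx(1.0, abs=0.1)

    def test_zero_base_rate_flagged(self):
        e = enrichment_at_k(np.array([0.5, 0.4]), np.array([False, False]), k=1)
        assert e["fold"] is None

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError):
            enrichment_at_k(np.array([0.5]), np.array([True]), k=0)
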