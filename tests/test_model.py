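"""Model contracts: gradients, normalization, causality, determinism,
checkpointing, and short-run training behavior."""

import numpy as np
import pytest

import pcmolkit as pk
from pcmolkit.autograd import Tensor, masked_cross_entropy
from pcmolkit.codec import SPECIALS, Vocabulary
from pcmolkit.errors import ConfigurationError, ContractError

SMALL = dict(d=16, num_blocks=2, num_heads=2, encoder_context=16,
             decoder_context=20, dropout=0.0, batch_size=4, learning_rate=1e-3)


@pytest.fixture()
def small_model():
    vocab = Vocabulary(SPECIALS + tuple("CNO=()1c"))
    return pk.ConditionedLM(pk.ModelConfig(**SMALL), vocab, seed=1)


def _emb(L=6, seed=0):
    rng = np.random.default_rng(seed)
    return pk.AlphaFoldEmbedding(
        "T", rng.standard_normal((L, 384)), rng.standard_normal((L, 384))
    )


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Full-model gradient check in float64 with O(1)-scaled weights."""
        vocab = Vocabulary(SPECIALS + tuple("CNO"))
        cfg = pk.ModelConfig(d=8, num_blocks=1, num_heads=2, encoder_context=6,
                             decoder_context=12, dropout=0.0, batch_size=2,
                             learning_rate=1e-3)
        model = pk.ConditionedLM(cfg, vocab, seed=3, dtype=np.float64)
        for p in model.params.values():
            p.data = p.data * 3.0  # lift gradients above finite-difference noise
        rng = np.random.default_rng(0)
        B, T, L = 2, 5, 4
        tokens = rng.integers(0, len(vocab), (B, T))
        targets = rng.integers(0, len(vocab), (B, T))
        mask = np.ones((B, T)); mask[1, -1] = 0
        enc = rng.standard_normal((B, L, cfg.conditioning_width))
        enc_pad = np.zeros((B, L), bool); enc_pad[0, -1] = True

        def loss_val():
            return float(
                masked_cross_entropy(model.forward(tokens, enc, enc_pad), targets, mask).data
            )

        loss = masked_cross_entropy(model.forward(tokens, enc, enc_pad), targets, mask)
        for p in model.params.values():
            p.grad = None
        loss.backward()
        eps, check_rng = 1e-5, np.random.default_rng(1)
        for name, p in model.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            flat = p.data.reshape(-1)
            for i in check_rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps; lp = loss_val()
                flat[i] = orig - eps; lm = loss_val()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = g.reshape(-1)[i]
                assert abs(num - ana) / max(1e-3, abs(num) + abs(ana)) < 1e-5, name


class TestForwardContracts:
    def test_distributions_normalize(self, small_model):
        rng = np.random.default_rng(0)
        tokens = rng.integers(0, 12, (3, 7))
        enc = rng.standard_normal((3, 5, 768))
        logits = small_model.forward(tokens, enc)
        probs = Tensor(logits.data).softmax().data
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_causal_mask_blocks_future_edits(self, small_model):
        rng = np.random.default_rng(1)
        tokens = rng.integers(0, 12, (1, 8))
        enc = rng.standard_normal((1, 5, 768))
        base = small_model.forward(tokens, enc).data
        edited = tokens.copy()
        edited[0, -1] = (edited[0, -1] + 1) % 12
        out = small_model.forward(edited, enc).data
        np.testing.assert_array_equal(base[0, :-1], out[0, :-1])

    def test_eval_mode_deterministic(self, small_model):
        rng = np.random.default_rng(2)
        tokens = rng.integers(0, 12, (2, 6))
        enc = rng.standard_normal((2, 4, 768))
        a = small_model.forward(tokens, enc).data
        b = small_model.forward(tokens, enc).data
        assert np.array_equal(a, b)

    def test_untrained_loss_near_log_vocab(self, small_model):
        rng = np.random.default_rng(3)
        tokens = rng.integers(0, 12, (8, 10))
        targets = rng.integers(0, 12, (8, 10))
        enc = rng.standard_normal((8, 6, 768))
        loss = float(
            masked_cross_entropy(
                small_model.forward(tokens, enc), targets, np.ones((8, 10))
            ).data
        )
        logv = np.log(len(small_model.vocab))
        assert abs(loss - logv) / logv < 0.05

    def test_context_window_contracts(self, small_model):
        rng = np.random.default_rng(4)
        enc = rng.standard_normal((1, 5, 768))
        with pytest.raises(ContractError):
            small_model.forward(np.zeros((1, 21), int), enc)
        with pytest.raises(ContractError):
            small_model.forward(
                np.zeros((1, 5), int), rng.standard_normal((1, 17, 768))
            )


class TestProjection:
    def test_zero_parameters_give_zero_output(self, small_model):
        small_model.params["proj_w"].data[:] = 0
        small_model.params["proj_b"].data[:] = 0
        out = small_model.project_embedding(_emb(L=4))
        assert out.shape == (4, 16)
        assert np.all(out == 0)

    def test_homogeneity_with_zero_bias(self, small_model):
        small_model.params["proj_b"].data[:] = 0
        e1 = _emb(L=3, seed=5)
        e2 = pk.AlphaFoldEmbedding("T", 2 * e1.evoformer, 2 * e1.structure)
        np.testing.assert_allclose(
            small_model.project_embedding(e2),
            2 * small_model.project_embedding(e1),
            atol=1e-4,
        )

    def test_encoder_context_boundary(self):
        vocab = Vocabulary(SPECIALS + ("C",))
        cfg = pk.ModelConfig(d=8, num_blocks=1, num_heads=2, encoder_context=8,
                             decoder_context=12, batch_size=2, learning_rate=1e-3)
        model = pk.ConditionedLM(cfg, vocab, seed=0)
        model.project_embedding(_emb(L=8))  # exactly at the limit
        with pytest.raises(ContractError):
            model.project_embedding(_emb(L=9))


@pytest.fixture(scope="module")
def quick_run():
    spec = pk.FixtureSpec(num_families=2, targets_per_family=2,
                          length_range=(10, 16), count_range=(10, 10), seed=2)
    embs = pk.make_embeddings(spec)
    ligs = pk.make_ligands(spec)
    corpus = [(s.accession, r.smiles) for s in ligs for r in s.records]
    vocab = pk.build_vocabulary([s for _, s in corpus])
    cfg = pk.ModelConfig(d=32, num_blocks=2, num_heads=4, encoder_context=32,
                         decoder_context=102, dropout=0.0, batch_size=10,
                         learning_rate=3e-3)
    model, state = pk.train(corpus, embs, cfg, vocab, epochs=40, seed=0)
    return {"model": model, "state": state, "embs": embs, "corpus": corpus,
            "vocab": vocab, "cfg": cfg}


class TestTrainingAndSampling:

    def test_loss_decreases(self, quick_run):
        trace = quick_run["state"].loss_trace
        assert trace[-1] < trace[0] * 0.6
        assert all(np.isfinite(trace))

    def test_training_is_seed_deterministic(self, quick_run):
        model2, state2 = pk.train(
            quick_run["corpus"], quick_run["embs"], pk.ModelConfig(
                **{k: getattr(quick_run["cfg"], k) for k in
                   ("d", "num_blocks", "num_heads", "encoder_context",
                    "decoder_context", "dropout", "batch_size", "learning_rate")}
            ), quick_run["vocab"], epochs=40, seed=0,
        )
        assert state2.loss_trace == quick_run["state"].loss_trace

    def test_unknown_accession_fails_before_training(self, quick_run):
        with pytest.raises(ConfigurationError):
            quick_run["model"].fit([("MISSING", "CCO")], quick_run["embs"], epochs=1)

    def test_sampling_determinism_and_temperature_contract(self, quick_run):
        model, emb = quick_run["model"], quick_run["embs"][0]
        s1, v1 = model.sample(emb, n=5, temperature=1.0, seed=4)
        s2, v2 = model.sample(emb, n=5, temperature=1.0, seed=4)
        assert s1 == s2 and v1 == v2
        g, _ = model.sample(emb, n=3, temperature=0.0, seed=0)
        assert len(set(g)) == 1  # greedy ignores the seed
        with pytest.raises(ConfigurationError):
            model.sample(emb, n=1, temperature=-0.5)

    def test_checkpoint_round_trip_bitwise(self, quick_run, tmp_path):
        model = quick_run["model"]
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = pk.ConditionedLM.load(path)
        rng = np.random.default_rng(5)
        tokens = rng.integers(0, len(model.vocab), (2, 9))
        enc = rng.standard_normal((2, 6, 768)).astype(np.float32)
        assert np.array_equal(
            model.forward(tokens, enc).data, loaded.forward(tokens, enc).data
        )
        assert loaded.vocab == model.vocab
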