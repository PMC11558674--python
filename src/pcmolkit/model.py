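"""Encoder-decoder SMILES transformer conditioned on protein embeddings.

The decoder is a stack of Pre-LN transformer blocks over SMILES tokens:
layer normalization precedes each sublayer, self-attention is causally
masked, and every block cross-attends to the protein side with all residue
positions unmasked, so target identity can steer every generation step.
The protein side is the per-residue embedding matrix passed through a
fully connected projection to the model width ``d`` plus learned encoder
positional embeddings; no further self-attention stack is applied to it,
since the matrices are already the output of a deep structure-prediction
network. Positional embeddings on both sides are learned. Dropout is
applied before the position-wise feed-forward sublayer of each block.

Training uses the ordinary autoregressive objective: teacher-forced
next-token prediction, mean negative log-likelihood in nats per token,
padding positions masked out of the loss.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .autograd import Adam, Tensor, constant, embedding, masked_cross_entropy
from .codec import Vocabulary, encode_corpus
from .embeddings import AlphaFoldEmbedding
from .errors import ConfigurationError, ContractError

CHECKPOINT_SCHEMA = "pcmolkit-checkpoint-1"

NEG_INF = -1e9


@dataclass
class ModelConfig:
    """Hyperparameters; defaults follow the published full-scale setup."""

    d: int = 768
    num_blocks: int = 16
    num_heads: int = 32
    encoder_context: int = 1536
    decoder_context: int = 102
    dropout: float = 0.1
    batch_size: int = 96
    learning_rate: float = 9.0e-5
    vocab_size: int = 0
    embedding_feature_width: int = 384
    stream_mode: str = "concat"  # evoformer | structure | concat

    def __post_init__(self):
        if self.d % self.num_heads != 0:
            raise ConfigurationError("d must be divisible by num_heads")
        if not (0.0 <= self.dropout < 1.0):
            raise ConfigurationError("dropout must lie in [0, 1)")
        if self.stream_mode not in ("evoformer", "structure", "concat"):
            raise ConfigurationError(f"unknown stream_mode {self.stream_mode!r}")
        for name in ("d", "num_blocks", "num_heads", "encoder_context",
                     "decoder_context", "batch_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    @property
    def head_dim(self) -> int:
        return self.d // self.num_heads

    @property
    def conditioning_width(self) -> int:
        streams = 2 if self.stream_mode == "concat" else 1
        return self.embedding_feature_width * streams


@dataclass
class TrainState:
    """Loss trace of one training run; loss is nats per token."""

    epoch: int = 0
    step: int = 0
    seed: int = 0
    loss_trace: list[float] = field(default_factory=list)

    @property
    def final_loss(self) -> float:
        return self.loss_trace[-1]


def _linear_params(rng, n_in, n_out, std, dtype):
    w = Tensor((rng.standard_normal((n_in, n_out)) * std).astype(dtype), True)
    b = Tensor(np.zeros(n_out, dtype=dtype), True)
    return w, b


class ConditionedLM:
    """The target-conditioned autoregressive SMILES language model."""

    def __init__(
        self,
        config: ModelConfig,
        vocab: Vocabulary,
        seed: int = 0,
        dtype=np.float32,
    ):
        if config.vocab_size and config.vocab_size != len(vocab):
            raise ConfigurationError("config.vocab_size disagrees with vocabulary")
        config.vocab_size = len(vocab)
        self.config = config
        self.vocab = vocab
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c = config
        std = 0.02
        p: dict[str, Tensor] = {}
        p["tok_emb"] = Tensor(
            (rng.standard_normal((c.vocab_size, c.d)) * std).astype(dtype), True
        )
        p["pos_dec"] = Tensor(
            (rng.standard_normal((c.decoder_context, c.d)) * std).astype(dtype), True
        )
        p["pos_enc"] = Tensor(
            (rng.standard_normal((c.encoder_context, c.d)) * std).astype(dtype), True
        )
        p["proj_w"], p["proj_b"] = _linear_params(
            rng, c.conditioning_width, c.d, std, dtype
        )
        for i in range(c.num_blocks):
            for ln in ("ln1", "ln2", "ln3"):
                p[f"b{i}.{ln}.g"] = Tensor(np.ones(c.d, dtype=dtype), True)
                p[f"b{i}.{ln}.b"] = Tensor(np.zeros(c.d, dtype=dtype), True)
            for att in ("self", "cross"):
                for m in ("q", "k", "v", "o"):
                    w, b = _linear_params(rng, c.d, c.d, std, dtype)
                    p[f"b{i}.{att}.{m}_w"], p[f"b{i}.{att}.{m}_b"] = w, b
            p[f"b{i}.ffn.w1"], p[f"b{i}.ffn.b1"] = _linear_params(
                rng, c.d, 4 * c.d, std, dtype
            )
            p[f"b{i}.ffn.w2"], p[f"b{i}.ffn.b2"] = _linear_params(
                rng, 4 * c.d, c.d, std, dtype
            )
        p["lnf.g"] = Tensor(np.ones(c.d, dtype=dtype), True)
        p["lnf.b"] = Tensor(np.zeros(c.d, dtype=dtype), True)
        p["head_w"], p["head_b"] = _linear_params(rng, c.d, c.vocab_size, 0.01, dtype)
        self.params = p

    # -- conditioning ------------------------------------------------------

    def conditioning_matrix(self, emb: AlphaFoldEmbedding) -> np.ndarray:
        """The raw per-residue conditioning input [L x conditioning_width]."""
        mode = self.config.stream_mode
        if mode == "concat":
            mat = np.concatenate([emb.evoformer, emb.structure], axis=1)
        else:
            mat = emb.stream(mode)
        return mat.astype(self.dtype)

    def project_embedding(self, emb: AlphaFoldEmbedding) -> np.ndarray:
        """Projection layer output [L x d] for one target (no positions added)."""
        mat = self.conditioning_matrix(emb)
        if mat.shape[0] > self.config.encoder_context:
            raise ContractError(
                f"L={mat.shape[0]} exceeds encoder context "
                f"{self.config.encoder_context}"
            )
        out = constant(mat) @ self.params["proj_w"] + self.params["proj_b"]
        return out.data

    def _encode_protein(self, enc: np.ndarray) -> Tensor:
        """Project a padded conditioning batch [B x Lm x width] and add positions."""
        lm = enc.shape[1]
        if lm > self.config.encoder_context:
            raise ContractError("conditioning length exceeds encoder context")
        h = constant(enc) @ self.params["proj_w"] + self.params["proj_b"]
        return h + embedding(self.params["pos_enc"], np.arange(lm))

    # -- forward -----------------------------------------------------------

    def _attention(self, h: Tensor, kv: Tensor, prefix: str, mask: np.ndarray | None) -> Tensor:
        c = self.config
        p = self.params
        B = h.shape[0]
        tq, tk = h.shape[1], kv.shape[1]

        def heads(x: Tensor, t: int) -> Tensor:
            return x.reshape(B, t, c.num_heads, c.head_dim).transpose(0, 2, 1, 3)

        q = heads(h @ p[f"{prefix}.q_w"] + p[f"{prefix}.q_b"], tq)
        k = heads(kv @ p[f"{prefix}.k_w"] + p[f"{prefix}.k_b"], tk)
        v = heads(kv @ p[f"{prefix}.v_w"] + p[f"{prefix}.v_b"], tk)
        scores = (q @ k.transpose(0, 1, 3, 2)).scale(1.0 / math.sqrt(c.head_dim))
        if mask is not None:
            scores = scores + constant(mask.astype(self.dtype))
        ctx = scores.softmax() @ v
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, tq, c.d)
        return ctx @ p[f"{prefix}.o_w"] + p[f"{prefix}.o_b"]

    def forward(
        self,
        tokens: np.ndarray,
        enc: np.ndarray,
        enc_pad: np.ndarray | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Logits [B x T x V] for a token batch and a conditioning batch.

        ``tokens``: int array [B x T] (teacher-forced inputs). ``enc``:
        [B x Lm x conditioning_width] padded conditioning matrices;
        ``enc_pad``: boolean [B x Lm], True where padded. Eval mode
        (``train=False``) is deterministic.
        """
        tokens = np.asarray(tokens)
        if tokens.ndim != 2:
            raise ContractError("tokens must be [batch x positions]")
        B, T = tokens.shape
        if T > self.config.decoder_context:
            raise ContractError(
                f"{T} positions exceed decoder context {self.config.decoder_context}"
            )
        if enc.ndim != 3 or enc.shape[0] != B or enc.shape[2] != self.config.conditioning_width:
            raise ContractError("conditioning batch shape mismatch")
        if train and rng is None:
            raise ConfigurationError("training forward needs an RNG for dropout")
        p = self.params
        drop = self.config.dropout if train else 0.0

        enc_h = self._encode_protein(enc)
        causal = np.triu(np.full((T, T), NEG_INF), k=1)[None, None]
        cross_mask = None
        if enc_pad is not None and enc_pad.any():
            cross_mask = np.where(enc_pad, NEG_INF, 0.0)[:, None, None, :]

        x = embedding(p["tok_emb"], tokens) + embedding(p["pos_dec"], np.arange(T))
        for i in range(self.config.num_blocks):
            h = x.layer_norm(p[f"b{i}.ln1.g"], p[f"b{i}.ln1.b"])
            x = x + self._attention(h, h, f"b{i}.self", causal)
            h = x.layer_norm(p[f"b{i}.ln2.g"], p[f"b{i}.ln2.b"])
            x = x + self._attention(h, enc_h, f"b{i}.cross", cross_mask)
            h = x.layer_norm(p[f"b{i}.ln3.g"], p[f"b{i}.ln3.b"])
            if drop > 0.0:
                h = h.dropout(drop, rng)
            x = x + ((h @ p[f"b{i}.ffn.w1"] + p[f"b{i}.ffn.b1"]).gelu()
                     @ p[f"b{i}.ffn.w2"] + p[f"b{i}.ffn.b2"])
        x = x.layer_norm(p["lnf.g"], p["lnf.b"])
        return x @ p["head_w"] + p["head_b"]

    def token_distributions(self, tokens: np.ndarray, emb: AlphaFoldEmbedding) -> np.ndarray:
        """Eval-mode per-position next-token distributions for one prefix."""
        enc = self.conditioning_matrix(emb)[None]
        logits = self.forward(np.asarray(tokens)[None], enc)
        return Tensor(logits.data).softmax().data[0]

    # -- training ----------------------------------------------------------

    def fit(
        self,
        corpus: Sequence[tuple[str, str]],
        embeddings: Mapping[str, AlphaFoldEmbedding] | Sequence[AlphaFoldEmbedding],
        epochs: int,
        seed: int = 0,
        shuffle_seed_per_target: int | None = None,
        lr_schedule: str = "cosine",
        verbose: bool = False,
    ) -> TrainState:
        """Teacher-forced training on (accession, SMILES) pairs.

        ``shuffle_seed_per_target`` activates the corrupted-conditioning
        regime: every target's embedding is row- and column-shuffled once
        (seeded by this value) before training, destroying protein
        information while preserving value statistics.

        ``lr_schedule``: "cosine" (default; 5% linear warmup then cosine
        decay to zero over the run, which lets small corpora be driven to
        the memorization floor) or "constant".
        """
        if lr_schedule not in ("cosine", "constant"):
            raise ConfigurationError(f"unknown lr_schedule {lr_schedule!r}")
        from .embeddings import shuffle_embedding

        if not isinstance(embeddings, Mapping):
            embeddings = {e.accession: e for e in embeddings}
        missing = sorted({a for a, _ in corpus} - set(embeddings))
        if missing:
            raise ConfigurationError(f"no embedding for accession(s) {missing}")

        cond: dict[str, np.ndarray] = {}
        for acc in sorted({a for a, _ in corpus}):
            emb = embeddings[acc]
            if shuffle_seed_per_target is not None:
                emb = shuffle_embedding(emb, shuffle_seed_per_target)
            mat = self.conditioning_matrix(emb)
            if mat.shape[0] > self.config.encoder_context:
                raise ContractError(f"{acc}: protein longer than encoder context")
            cond[acc] = mat

        seqs, dropped = encode_corpus(
            [s for _, s in corpus], self.vocab, self.config.decoder_context
        )
        if dropped:
            raise ConfigurationError(f"{dropped} corpus strings exceed the context")
        accs = [a for a, _ in corpus]

        rng = np.random.default_rng(seed)
        opt = Adam(self.params, lr=self.config.learning_rate)
        state = TrainState(seed=seed)
        pad = self.vocab.pad_id
        n = len(seqs)
        steps_per_epoch = math.ceil(n / self.config.batch_size)
        total_steps = max(1, epochs * steps_per_epoch)
        warmup = max(1, int(0.05 * total_steps))
        base_lr = self.config.learning_rate
        for epoch in range(epochs):
            order = rng.permutation(n)
            tot_loss, tot_tok = 0.0, 0
            for start in range(0, n, self.config.batch_size):
                idx = order[start : start + self.config.batch_size]
                batch = [seqs[i] for i in idx]
                tmax = max(len(s) for s in batch)
                toks = np.full((len(batch), tmax), pad, dtype=np.int64)
                for r, s in enumerate(batch):
                    toks[r, : len(s)] = s
                inputs, targets = toks[:, :-1], toks[:, 1:]
                mask = targets != pad
                mats = [cond[accs[i]] for i in idx]
                lmax = max(m.shape[0] for m in mats)
                enc = np.zeros(
                    (len(batch), lmax, self.config.conditioning_width), dtype=self.dtype
                )
                enc_pad = np.ones((len(batch), lmax), dtype=bool)
                for r, m in enumerate(mats):
                    enc[r, : m.shape[0]] = m
                    enc_pad[r, : m.shape[0]] = False
                if lr_schedule == "cosine":
                    t = state.step
                    if t < warmup:
                        opt.lr = base_lr * (t + 1) / warmup
                    else:
                        frac = (t - warmup) / max(1, total_steps - warmup)
                        opt.lr = base_lr * 0.5 * (1.0 + math.cos(math.pi * frac))
                logits = self.forward(inputs, enc, enc_pad, train=True, rng=rng)
                loss = masked_cross_entropy(logits, targets, mask)
                opt.zero_grad()
                loss.backward()
                opt.step()
                ntok = int(mask.sum())
                tot_loss += float(loss.data) * ntok
                tot_tok += ntok
                state.step += 1
            state.epoch = epoch + 1
            state.loss_trace.append(tot_loss / tot_tok)
            if verbose and (epoch + 1) % 10 == 0:
                print(f"epoch {epoch + 1}: {state.loss_trace[-1]:.4f} nats/token")
        return state

    def evaluate_loss(
        self,
        corpus: Sequence[tuple[str, str]],
        embeddings: Mapping[str, AlphaFoldEmbedding] | Sequence[AlphaFoldEmbedding],
    ) -> float:
        """Eval-mode mean NLL (nats per token) over a corpus."""
        if not isinstance(embeddings, Mapping):
            embeddings = {e.accession: e for e in embeddings}
        pad = self.vocab.pad_id
        tot, ntok = 0.0, 0
        for acc, smi in corpus:
            seqs, _ = encode_corpus([smi], self.vocab, self.config.decoder_context)
            ids = np.asarray(seqs[0])[None]
            enc = self.conditioning_matrix(embeddings[acc])[None]
            logits = self.forward(ids[:, :-1], enc)
            targets = ids[:, 1:]
            mask = targets != pad
            loss = masked_cross_entropy(logits, targets, mask)
            tot += float(loss.data) * int(mask.sum())
            ntok += int(mask.sum())
        return tot / ntok

    # -- sampling ----------------------------------------------------------

    def sample(
        self,
        emb: AlphaFoldEmbedding,
        n: int,
        temperature: float = 1.0,
        seed: int = 0,
        shuffle_seed: int | None = None,
    ) -> tuple[list[str], list[bool]]:
        """Draw ``n`` SMILES strings conditioned on one target.

        Token-by-token multinomial sampling from the temperature-scaled
        distribution, starting at BOS, stopping at EOS or the decoder
        context limit. ``temperature == 0`` switches to greedy argmax
        decoding; negative temperatures are rejected. ``shuffle_seed``
        corrupts the conditioning embedding first (ablation control).
        Returns the decoded strings and per-string validity flags.
        """
        from .bioactivity import is_valid_smiles
        from .codec import decode
        from .embeddings import shuffle_embedding

        if n < 1:
            raise ConfigurationError("n must be >= 1")
        if temperature < 0:
            raise ConfigurationError("temperature must be >= 0")
        if shuffle_seed is not None:
            emb = shuffle_embedding(emb, shuffle_seed)
        rng = np.random.default_rng(seed)
        c = self.config
        enc1 = self.conditioning_matrix(emb)
        enc = np.repeat(enc1[None], n, axis=0)
        toks = np.full((n, 1), self.vocab.bos_id, dtype=np.int64)
        finished = np.zeros(n, dtype=bool)
        for _step in range(c.decoder_context - 1):
            logits = self.forward(toks, enc).data[:, -1, :]
            if temperature == 0:
                nxt = logits.argmax(axis=-1)
            else:
                z = logits / temperature
                z = z - z.max(axis=-1, keepdims=True)
                prob = np.exp(z)
                prob /= prob.sum(axis=-1, keepdims=True)
                # one independent draw per sequence, fixed rng order
                nxt = np.array(
                    [rng.choice(len(self.vocab), p=prob[i]) for i in range(n)]
                )
            nxt = np.where(finished, self.vocab.pad_id, nxt)
            toks = np.concatenate([toks, nxt[:, None]], axis=1)
            finished |= nxt == self.vocab.eos_id
            if finished.all():
                break
        smiles = [decode(row, self.vocab, strict=False) for row in toks]
        valid = [is_valid_smiles(s) and s != "" for s in smiles]
        return smiles, valid

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: parameters + config + vocabulary."""
        arrays = {f"param/{k}": t.data for k, t in self.params.items()}
        arrays["meta/schema"] = np.array(CHECKPOINT_SCHEMA)
        arrays["meta/config"] = np.array(json.dumps(asdict(self.config)))
        arrays["meta/vocab"] = np.array(json.dumps(list(self.vocab.tokens)))
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ConditionedLM":
        with np.load(path) as data:
            schema = str(data["meta/schema"])
            if schema != CHECKPOINT_SCHEMA:
                raise ConfigurationError(f"unknown checkpoint schema {schema!r}")
            config = ModelConfig(**json.loads(str(data["meta/config"])))
            vocab = Vocabulary(tuple(json.loads(str(data["meta/vocab"]))))
            model = cls(config, vocab, seed=0)
            for k in model.params:
                model.params[k] = Tensor(data[f"param/{k}"], True)
        model.dtype = next(iter(model.params.values())).data.dtype.type
        return model


def train(
    corpus: Sequence[tuple[str, str]],
    embeddings,
    config: ModelConfig,
    vocab: Vocabulary,
    epochs: int,
    seed: int = 0,
    **kwargs,
) -> tuple[ConditionedLM, TrainState]:
    """Build a model and fit it; convenience wrapper around ConditionedLM."""
    model = ConditionedLM(config, vocab, seed=seed)
    state = model.fit(corpus, embeddings, epochs=epochs, seed=seed, **kwargs)
    return model, state
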