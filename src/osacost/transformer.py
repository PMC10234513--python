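"""Encoder–decoder Transformer over multivariate visit sequences.

The encoder reads a patient's history window: per visit, learned embeddings
for cost type, age (integer years), gender, specialist and a log-spaced
days-from-diagnosis bucket are summed, plus a sinusoidal positional encoding
over visit order.  CLS/SEP/PAD positions embed through the cost-type table
while the other variable tables contribute a dedicated neutral index there.
The decoder predicts the cost-type token sequence autoregressively with
causal self-attention and cross-attention into the encoder memory; training
is teacher-forced, inference greedy.

Built on the package's own NumPy autodiff engine; sized for single-CPU desk
scale and fully seeded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor

__all__ = ["ModelConfig", "SeqTransformer", "sinusoidal_encoding"]

NEG_INF = -1e9


@dataclass
class ModelConfig:
    """Architecture and vocabulary sizes of one sequence model."""

    d_model: int = 64
    n_heads: int = 4
    n_encoder_layers: int = 2
    n_decoder_layers: int = 2
    feedforward_width: int = 128
    dropout: float = 0.1
    max_input_len: int = 64
    max_target_len: int = 24
    vocab_sizes: dict = field(default_factory=dict)  # cost_type/age/gender/specialist/diff_bucket
    seed: int = 0

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        for name in ("d_model", "n_heads", "n_encoder_layers", "n_decoder_layers",
                     "feedforward_width", "max_input_len", "max_target_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def sinusoidal_encoding(length: int, d_model: int) -> np.ndarray:
    """Classic fixed sin/cos positional encoding, shape (length, d_model)."""
    pos = np.arange(length)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    enc = np.zeros((length, d_model))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


class SeqTransformer:
    """Encoder–decoder model shared by the augmenter (M1) and the cost
    predictor (M2); the two differ only in decoding horizon and loss."""

    INPUT_VARIABLES = ("cost_type", "age", "gender", "specialist", "diff_bucket")

    def __init__(self, config: ModelConfig):
        required = set(self.INPUT_VARIABLES)
        if not required <= set(config.vocab_sizes):
            missing = required - set(config.vocab_sizes)
            raise ValueError(f"vocab_sizes missing entries for {sorted(missing)}")
        self.config = config
        self.params: dict[str, Tensor] = {}
        rng = np.random.Generator(np.random.PCG64(config.seed))
        self._init_params(rng)
        self._train_rng = np.random.Generator(np.random.PCG64(config.seed + 1))
        self.training = False

    # -- parameter construction ----------------------------------------------

    def _add(self, name: str, array: np.ndarray) -> None:
        self.params[name] = Tensor(array, requires_grad=True, name=name)

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        d = cfg.d_model
        for var in self.INPUT_VARIABLES:
            self._add(f"emb.{var}", rng.normal(0.0, 0.02, (cfg.vocab_sizes[var], d)))

        def linear(name, din, dout):
            bound = np.sqrt(6.0 / (din + dout))
            self._add(f"{name}.w", rng.uniform(-bound, bound, (din, dout)))
            self._add(f"{name}.b", np.zeros(dout))

        def block(prefix, cross: bool):
            for proj in ("q", "k", "v", "o"):
                linear(f"{prefix}.self.{proj}", d, d)
            if cross:
                for proj in ("q", "k", "v", "o"):
                    linear(f"{prefix}.cross.{proj}", d, d)
            linear(f"{prefix}.ff1", d, cfg.feedforward_width)
            linear(f"{prefix}.ff2", cfg.feedforward_width, d)
            n_norms = 3 if cross else 2
            for j in range(n_norms):
                self._add(f"{prefix}.ln{j}.g", np.ones(d))
                self._add(f"{prefix}.ln{j}.b", np.zeros(d))

        for i in range(cfg.n_encoder_layers):
            block(f"enc.{i}", cross=False)
        for i in range(cfg.n_decoder_layers):
            block(f"dec.{i}", cross=True)
        linear("out", d, cfg.vocab_sizes["cost_type"])

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def train(self) -> None:
        self.training = True

    def eval(self) -> None:
        self.training = False

    def reseed_dropout(self, seed: int) -> None:
        self._train_rng = np.random.Generator(np.random.PCG64(seed))

    # -- building blocks ------------------------------------------------------

    def _linear(self, name: str, x: Tensor) -> Tensor:
        return x @ self.params[f"{name}.w"] + self.params[f"{name}.b"]

    def _dropout(self, x: Tensor) -> Tensor:
        p = self.config.dropout
        if not self.training or p <= 0.0:
            return x
        keep = (self._train_rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(keep)

    def _layer_norm(self, prefix: str, x: Tensor) -> Tensor:
        return x.layer_norm(self.params[f"{prefix}.g"], self.params[f"{prefix}.b"])

    def _attention(self, prefix: str, q_in: Tensor, kv_in: Tensor,
                   bad_key_mask: np.ndarray | None,
                   causal: bool) -> Tensor:
        """Multi-head attention. bad_key_mask: (B, Tk) True where key invalid."""
        cfg = self.config
        H = cfg.n_heads
        dh = cfg.d_model // H
        B, Tq, _ = q_in.shape
        Tk = kv_in.shape[1]

        def heads(t, T):
            return t.reshape(B, T, H, dh).transpose(0, 2, 1, 3)  # (B,H,T,dh)

        q = heads(self._linear(f"{prefix}.q", q_in), Tq)
        k = heads(self._linear(f"{prefix}.k", kv_in), Tk)
        v = heads(self._linear(f"{prefix}.v", kv_in), Tk)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))  # (B,H,Tq,Tk)
        if bad_key_mask is not None:
            scores = scores.masked_fill(bad_key_mask[:, None, None, :], NEG_INF)
        if causal:
            future = np.triu(np.ones((Tq, Tk), dtype=bool), k=1)
            scores = scores.masked_fill(future[None, None, :, :], NEG_INF)
        attn = self._dropout(scores.softmax(axis=-1))
        mixed = (attn @ v).transpose(0, 2, 1, 3).reshape(B, Tq, cfg.d_model)
        return self._linear(f"{prefix}.o", mixed)

    def _ff(self, prefix: str, x: Tensor) -> Tensor:
        return self._linear(f"{prefix}.ff2",
                            self._dropout(self._linear(f"{prefix}.ff1", x).relu()))

    # -- embedding -------------------------------------------------------------

    def embed_visit_sequence(self, tokens: dict[str, np.ndarray]) -> Tensor:
        """Sum per-variable embeddings plus positional encoding.

        tokens: per variable, an int array of shape (B, L); all equal length.
        """
        shapes = {v: np.asarray(tokens[v]).shape for v in self.INPUT_VARIABLES}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"per-variable token shapes differ: {shapes}")
        for var in self.INPUT_VARIABLES:
            idx = np.asarray(tokens[var])
            size = self.config.vocab_sizes[var]
            if idx.min() < 0 or idx.max() >= size:
                bad = int(np.argwhere((idx < 0) | (idx >= size))[0][-1])
                raise ValueError(
                    f"out-of-vocabulary index for variable {var!r} "
                    f"at position {bad} (vocab size {size})"
                )
        B, L = np.asarray(tokens["cost_type"]).shape
        out = None
        for var in self.INPUT_VARIABLES:
            e = self.params[f"emb.{var}"].embedding(np.asarray(tokens[var]))
            out = e if out is None else out + e
        pos = Tensor(sinusoidal_encoding(L, self.config.d_model)[None, :, :])
        return out + pos

    def _embed_decoder(self, cost_ids: np.ndarray) -> Tensor:
        B, T = cost_ids.shape
        e = self.params["emb.cost_type"].embedding(cost_ids)
        pos = Tensor(sinusoidal_encoding(T, self.config.d_model)[None, :, :])
        return e + pos

    # -- forward ----------------------------------------------------------------

    def encode(self, input_tokens: dict[str, np.ndarray],
               input_mask: np.ndarray) -> Tensor:
        x = self._dropout(self.embed_visit_sequence(input_tokens))
        bad = ~np.asarray(input_mask, dtype=bool)
        for i in range(self.config.n_encoder_layers):
            p = f"enc.{i}"
            x = self._layer_norm(f"{p}.ln0",
                                 x + self._dropout(self._attention(f"{p}.self", x, x, bad, causal=False)))
            x = self._layer_norm(f"{p}.ln1", x + self._dropout(self._ff(p, x)))
        return x

    def decode(self, memory: Tensor, memory_mask: np.ndarray,
               decoder_ids: np.ndarray,
               decoder_pad_mask: np.ndarray | None = None) -> Tensor:
        """Run the decoder stack; returns logits (B, T, vocab)."""
        x = self._dropout(self._embed_decoder(decoder_ids))
        mem_bad = ~np.asarray(memory_mask, dtype=bool)
        dec_bad = None if decoder_pad_mask is None else ~np.asarray(decoder_pad_mask, dtype=bool)
        for i in range(self.config.n_decoder_layers):
            p = f"dec.{i}"
            x = self._layer_norm(f"{p}.ln0",
                                 x + self._dropout(self._attention(f"{p}.self", x, x, dec_bad, causal=True)))
            x = self._layer_norm(f"{p}.ln1",
                                 x + self._dropout(self._attention(f"{p}.cross", x, memory, mem_bad, causal=False)))
            x = self._layer_norm(f"{p}.ln2", x + self._dropout(self._ff(p, x)))
        return self._linear("out", x)

    def forward(self, input_tokens: dict[str, np.ndarray], input_mask: np.ndarray,
                target_ids: np.ndarray, target_mask: np.ndarray,
                cls_id: int) -> Tensor:
        """Teacher-forced pass: logits[:, j] predicts target_ids[:, j].

        The decoder input is the target sequence shifted right with CLS in
        front, so position j attends only to true targets before j.
        """
        target_ids = np.asarray(target_ids)
        if target_ids.shape != np.asarray(target_mask).shape:
            raise ValueError("target_ids and target_mask shapes differ")
        B, T = target_ids.shape
        dec_in = np.empty((B, T), dtype=np.int64)
        dec_in[:, 0] = cls_id
        dec_in[:, 1:] = target_ids[:, :-1]
        # decoder input j is valid when it is CLS or a real previous target
        dec_in_mask = np.empty((B, T), dtype=bool)
        dec_in_mask[:, 0] = True
        dec_in_mask[:, 1:] = np.asarray(target_mask, dtype=bool)[:, :-1]
        memory = self.encode(input_tokens, input_mask)
        return self.decode(memory, input_mask, dec_in, dec_in_mask)

    # -- inference ----------------------------------------------------------------

    def greedy_decode(self, input_tokens: dict[str, np.ndarray],
                      input_mask: np.ndarray, cls_id: int, sep_id: int,
                      pad_id: int, max_steps: int) -> tuple[list[list[int]], list[np.ndarray]]:
        """Greedy autoregressive decoding for a batch.

        Starts from CLS and repeatedly appends the argmax cost type, stopping
        per sequence at SEP or after max_steps.  CLS and PAD are never
        emitted.  Returns per-batch-item lists of emitted type indices and
        per-item arrays of softmax rows (n_emitted_plus_stop, vocab).
        """
        if max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        was_training = self.training
        self.eval()
        try:
            memory = self.encode(input_tokens, input_mask)
            B = memory.shape[0]
            dec = np.full((B, 1), cls_id, dtype=np.int64)
            done = np.zeros(B, dtype=bool)
            emitted: list[list[int]] = [[] for _ in range(B)]
            prob_rows: list[list[np.ndarray]] = [[] for _ in range(B)]
            for _ in range(max_steps):
                logits = self.decode(memory, input_mask, dec).data[:, -1, :]
                masked = logits.copy()
                masked[:, cls_id] = -np.inf
                masked[:, pad_id] = -np.inf
                shifted = masked - masked.max(axis=-1, keepdims=True)
                e = np.exp(shifted)
                probs = e / e.sum(axis=-1, keepdims=True)
                choice = np.argmax(masked, axis=-1)  # ties -> lowest index
                for b in range(B):
                    if done[b]:
                        continue
                    prob_rows[b].append(probs[b])
                    if choice[b] == sep_id:
                        done[b] = True
                    else:
                        emitted[b].append(int(choice[b]))
                if done.all():
                    break
                dec = np.concatenate([dec, choice[:, None]], axis=1)
            return emitted, [np.array(rows) for rows in prob_rows]
        finally:
            self.training = was_training

    # -- persistence -----------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {k: v.data for k, v in self.params.items()}
        np.savez(path.with_suffix(".npz"), **arrays)
        cfg = asdict(self.config)
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SeqTransformer":
        path = Path(path)
        cfg = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(cfg)
        with np.load(path.with_suffix(".npz")) as data:
            for k in model.params:
                model.params[k].data = data[k]
        return model


def iterate_minibatches(n: int, batch_size: int,
                        rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffled index batches covering 0..n-1 once."""
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]
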