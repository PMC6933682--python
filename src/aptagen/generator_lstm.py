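"""Character-level LSTM sequence generator.

A two-layer LSTM (128 hidden units by default) reads one nucleotide at a
time and predicts the next.  The output projection maps the top hidden
state to a 4-way logit vector ``z_t``; ``softmax(z_t)`` is the next-
nucleotide distribution and the loss is the mean negative log-likelihood
of the observed next characters.

The network is implemented directly in NumPy with analytic gradients
(truncated backpropagation through time over one chunk), which keeps the
forward pass, the gradients, and sampling bit-reproducible under a fixed
seed and lets the test suite verify the gradients against central finite
differences.

Generation starts from the maximum-entropy input ``(0.25, 0.25, 0.25,
0.25)``; at each step one nucleotide is drawn from the softmax (with
optional temperature) and fed back as the next input, until the target
length is reached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence as TypingSequence, Set, Tuple, Union

import numpy as np

from .sequence_io import Alphabet, Sequence, StreamChunks, decode_indices

__all__ = [
    "GeneratorModel",
    "TrainConfig",
    "EpochRecord",
    "TrainingTrace",
    "softmax",
    "sequence_loss",
    "train",
    "select_checkpoint",
    "sample_sequence",
    "generate_pool",
    "iu_ratio",
]

_GATES = 4  # input, forget, cell, output


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along *axis* (shift by the max)."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax input must be finite")
    shifted = z - z.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class GeneratorModel:
    """Two-layer LSTM character model over the 4-letter nucleotide alphabet.

    Parameters
    ----------
    layers, hidden_size:
        Stack depth and hidden width (defaults 2 and 128).
    alphabet:
        DNA or RNA; controls how sampled class indices are rendered.
    seq_len:
        Length of generated sequences (and of the truncated-BPTT window
        when trained on matching chunks).
    seed:
        Seed for weight initialization.  LSTM weights are drawn uniform
        in [-0.08, 0.08]; forget-gate biases start at 1; the output
        projection starts at zero, so an untrained model emits the
        uniform distribution exactly.
    """

    def __init__(
        self,
        layers: int = 2,
        hidden_size: int = 128,
        alphabet: Alphabet = Alphabet.DNA,
        seq_len: int = 20,
        seed: int = 0,
        dtype=np.float64,
    ) -> None:
        self.layers = layers
        self.hidden_size = hidden_size
        self.alphabet = alphabet
        self.seq_len = seq_len
        self.seed = seed
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        H = hidden_size
        scale = 0.08
        self.params: Dict[str, np.ndarray] = {}
        for l in range(layers):
            d_in = 4 if l == 0 else H
            self.params[f"Wx{l}"] = rng.uniform(-scale, scale, (d_in, _GATES * H)).astype(self.dtype)
            self.params[f"Wh{l}"] = rng.uniform(-scale, scale, (H, _GATES * H)).astype(self.dtype)
            b = np.zeros(_GATES * H, dtype=self.dtype)
            b[H : 2 * H] = 1.0  # forget-gate bias
            self.params[f"b{l}"] = b
        self.params["Wy"] = np.zeros((H, 4), dtype=self.dtype)
        self.params["by"] = np.zeros(4, dtype=self.dtype)

    # ------------------------------------------------------------------
    # state helpers

    def zero_state(self, batch: int) -> List[Tuple[np.ndarray, np.ndarray]]:
        H = self.hidden_size
        return [
            (np.zeros((batch, H), dtype=self.dtype), np.zeros((batch, H), dtype=self.dtype))
            for _ in range(self.layers)
        ]

    def step(
        self,
        x: np.ndarray,
        state: List[Tuple[np.ndarray, np.ndarray]],
    ) -> Tuple[np.ndarray, List[Tuple[np.ndarray, np.ndarray]]]:
        """One forward timestep: input ``x (B, 4)`` -> logits ``(B, 4)``."""
        H = self.hidden_size
        new_state = []
        inp = np.asarray(x, dtype=self.dtype)
        for l in range(self.layers):
            h_prev, c_prev = state[l]
            a = inp @ self.params[f"Wx{l}"] + h_prev @ self.params[f"Wh{l}"] + self.params[f"b{l}"]
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            new_state.append((h, c))
            inp = h
        logits = inp @ self.params["Wy"] + self.params["by"]
        return logits, new_state

    # ------------------------------------------------------------------
    # training forward/backward over one chunk

    def _forward_chunk(self, X: np.ndarray, x0_override: Optional[np.ndarray] = None):
        """Forward over a chunk of class indices ``X (B, S)``.

        Returns logits ``(S, B, 4)`` and the caches needed for backprop.
        The hidden state starts at zero (chunk-local truncated BPTT).
        """
        B, S = X.shape
        H = self.hidden_size
        state = self.zero_state(B)
        logits = np.empty((S, B, 4), dtype=self.dtype)
        caches = []
        eye = np.eye(4, dtype=self.dtype)
        for t in range(S):
            x = eye[X[:, t]] if x0_override is None or t > 0 else x0_override
            inp = x
            layer_caches = []
            new_state = []
            for l in range(self.layers):
                h_prev, c_prev = state[l]
                a = inp @ self.params[f"Wx{l}"] + h_prev @ self.params[f"Wh{l}"] + self.params[f"b{l}"]
                i = _sigmoid(a[:, :H])
                f = _sigmoid(a[:, H : 2 * H])
                g = np.tanh(a[:, 2 * H : 3 * H])
                o = _sigmoid(a[:, 3 * H :])
                c = f * c_prev + i * g
                hc = np.tanh(c)
                h = o * hc
                layer_caches.append((inp, h_prev, c_prev, i, f, g, o, c, hc))
                new_state.append((h, c))
                inp = h
            state = new_state
            logits[t] = inp @ self.params["Wy"] + self.params["by"]
            caches.append(layer_caches)
        return logits, caches

    def loss_and_grads(self, X: np.ndarray, Y: np.ndarray):
        """Mean NLL loss and analytic parameter gradients for one chunk."""
        if X.shape != Y.shape:
            raise ValueError("input and target chunks must have the same shape")
        B, S = X.shape
        H = self.hidden_size
        logits, caches = self._forward_chunk(X)
        probs = softmax(logits, axis=-1)
        n = B * S
        rows = np.arange(B)
        loss = 0.0
        for t in range(S):
            loss -= np.log(probs[t][rows, Y[:, t]]).sum()
        loss /= n

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dh_next = [np.zeros((B, H), dtype=self.dtype) for _ in range(self.layers)]
        dc_next = [np.zeros((B, H), dtype=self.dtype) for _ in range(self.layers)]
        Wy = self.params["Wy"]
        for t in range(S - 1, -1, -1):
            dlogits = probs[t].copy()
            dlogits[rows, Y[:, t]] -= 1.0
            dlogits /= n
            _, _, _, _, _, _, o_top, _, hc_top = caches[t][self.layers - 1]
            h_top = o_top * hc_top
            grads["Wy"] += h_top.T @ dlogits
            grads["by"] += dlogits.sum(axis=0)
            d_from_above = dlogits @ Wy.T
            for l in range(self.layers - 1, -1, -1):
                inp, h_prev, c_prev, i, f, g, o, c, hc = caches[t][l]
                dh = d_from_above + dh_next[l]
                dc = dc_next[l] + dh * o * (1.0 - hc * hc)
                do = dh * hc
                di = dc * g
                dg = dc * i
                df = dc * c_prev
                dc_next[l] = dc * f
                da = np.concatenate(
                    [
                        di * i * (1.0 - i),
                        df * f * (1.0 - f),
                        dg * (1.0 - g * g),
                        do * o * (1.0 - o),
                    ],
                    axis=1,
                )
                grads[f"Wx{l}"] += inp.T @ da
                grads[f"Wh{l}"] += h_prev.T @ da
                grads[f"b{l}"] += da.sum(axis=0)
                dh_next[l] = da @ self.params[f"Wh{l}"].T
                d_from_above = da @ self.params[f"Wx{l}"].T
        return float(loss), grads

    def chunk_loss(self, X: np.ndarray, Y: np.ndarray) -> float:
        """Mean NLL of a chunk without gradients (validation)."""
        B, S = X.shape
        logits, _ = self._forward_chunk(X)
        probs = softmax(logits, axis=-1)
        rows = np.arange(B)
        total = 0.0
        for t in range(S):
            total -= np.log(probs[t][rows, Y[:, t]]).sum()
        return float(total / (B * S))

    # ------------------------------------------------------------------
    # (de)serialization

    def copy_params(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: Dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].astype(self.dtype, copy=True)

    def save(self, path: Union[str, Path]) -> None:
        """Serialize parameters plus configuration to an .npz checkpoint."""
        config = dict(
            layers=self.layers,
            hidden_size=self.hidden_size,
            alphabet=self.alphabet.value,
            seq_len=self.seq_len,
            seed=self.seed,
            dtype=self.dtype.name,
        )
        np.savez(path, __config__=json.dumps(config), **self.params)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "GeneratorModel":
        with np.load(path, allow_pickle=False) as data:
            config = json.loads(str(data["__config__"]))
            model = cls(
                layers=config["layers"],
                hidden_size=config["hidden_size"],
                alphabet=Alphabet(config["alphabet"]),
                seq_len=config["seq_len"],
                seed=config["seed"],
                dtype=np.dtype(config["dtype"]),
            )
            model.set_params({k: data[k] for k in model.params})
        return model


def sequence_loss(
    model: GeneratorModel,
    xs: TypingSequence,
    ys: TypingSequence[int],
) -> float:
    """Mean negative log-likelihood of next-character targets.

    ``xs`` is a list of one-hot vectors (or raw 4-vectors) fed in order;
    ``ys`` the matching 1-based true class indices.  Natural log.
    """
    if len(xs) != len(ys):
        raise ValueError("xs and ys must have equal length")
    if len(xs) == 0:
        raise ValueError("empty input")
    state = model.zero_state(1)
    total = 0.0
    for x, y in zip(xs, ys):
        vec = np.asarray(getattr(x, "values", x), dtype=float).reshape(1, 4)
        logits, state = model.step(vec, state)
        p = softmax(logits[0])
        total -= np.log(p[int(y) - 1])
    return float(total / len(xs))


@dataclass
class TrainConfig:
    """RMSProp training hyperparameters (char-rnn-style defaults)."""

    learning_rate: float = 2e-3
    decay: float = 0.95
    epsilon: float = 1e-8
    clip_norm: float = 5.0
    shuffle: bool = True
    temperature: float = 1.0
    iu_probe_size: int = 0  # per-epoch IU-ratio probe pool; 0 disables


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    iu_ratio: float
    params: Dict[str, np.ndarray] = field(repr=False)


@dataclass
class TrainingTrace:
    records: List[EpochRecord]
    config: TrainConfig
    model_template: GeneratorModel = field(repr=False)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                dict(epoch=r.epoch, train_loss=r.train_loss, val_loss=r.val_loss, iu_ratio=r.iu_ratio)
                for r in self.records
            ]
        )


def _global_norm(grads: Dict[str, np.ndarray]) -> float:
    return float(np.sqrt(sum(float(np.sum(g * g)) for g in grads.values())))


def train(
    model: GeneratorModel,
    chunks: StreamChunks,
    epochs: int = 50,
    config: Optional[TrainConfig] = None,
    train_seqs: Optional[Iterable[Union[Sequence, str]]] = None,
    seed: Optional[int] = None,
) -> TrainingTrace:
    """Train with RMSProp; one checkpoint and one validation pass per epoch.

    Truncated BPTT runs over each chunk (window = chunk length); the
    hidden state is reset between chunks.  Training-chunk order is
    shuffled each epoch under the training seed.  If ``train_seqs`` is
    given and ``config.iu_probe_size > 0``, an IU-ratio probe pool is
    sampled from the current weights each epoch.

    Raises ``RuntimeError`` naming the epoch if the loss diverges.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if not chunks.train_chunks:
        raise ValueError("no training chunks")
    cfg = config or TrainConfig()
    rng = np.random.default_rng(model.seed if seed is None else seed)
    cache = {k: np.zeros_like(v) for k, v in model.params.items()}
    train_set: Optional[Set[str]] = None
    if train_seqs is not None:
        train_set = {s.residues if isinstance(s, Sequence) else str(s) for s in train_seqs}
    records: List[EpochRecord] = []
    order = np.arange(len(chunks.train_chunks))
    for epoch in range(1, epochs + 1):
        if cfg.shuffle:
            rng.shuffle(order)
        losses = []
        for idx in order:
            X, Y = chunks.train_chunks[idx]
            try:
                loss, grads = model.loss_and_grads(X, Y)
            except ValueError as exc:  # non-finite activations
                raise RuntimeError(f"training diverged at epoch {epoch}: {exc}") from exc
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            norm = _global_norm(grads)
            if norm > cfg.clip_norm:
                scale = cfg.clip_norm / norm
                for g in grads.values():
                    g *= scale
            for k, p in model.params.items():
                c = cache[k]
                g = grads[k]
                c *= cfg.decay
                c += (1.0 - cfg.decay) * g * g
                p -= cfg.learning_rate * g / (np.sqrt(c) + cfg.epsilon)
            losses.append(loss)
        val_losses = [model.chunk_loss(X, Y) for X, Y in chunks.val_chunks]
        val_loss = float(np.mean(val_losses)) if val_losses else float(np.mean(losses))
        iu = float("nan")
        if train_set is not None and cfg.iu_probe_size > 0:
            probe_seed = int(rng.integers(0, 2**31 - 1))
            probe = generate_pool(
                model, cfg.iu_probe_size, seed=probe_seed, temperature=cfg.temperature
            )
            iu = iu_ratio(train_set, {s.residues for s in probe})
        records.append(
            EpochRecord(
                epoch=epoch,
                train_loss=float(np.mean(losses)),
                val_loss=val_loss,
                iu_ratio=iu,
                params=model.copy_params(),
            )
        )
    return TrainingTrace(records=records, config=cfg, model_template=model)


def select_checkpoint(trace: TrainingTrace) -> GeneratorModel:
    """Return the per-epoch checkpoint with minimum validation loss.

    Ties go to the earliest epoch.
    """
    if not trace.records:
        raise ValueError("empty training trace")
    best = min(trace.records, key=lambda r: (r.val_loss, r.epoch))
    tpl = trace.model_template
    model = GeneratorModel(
        layers=tpl.layers,
        hidden_size=tpl.hidden_size,
        alphabet=tpl.alphabet,
        seq_len=tpl.seq_len,
        seed=tpl.seed,
        dtype=tpl.dtype,
    )
    model.set_params(best.params)
    return model


_START = np.full((1, 4), 0.25)


def _sample_batch(
    model: GeneratorModel,
    length: int,
    uniforms: np.ndarray,
    temperature: float,
) -> np.ndarray:
    """Autoregressive sampling for a batch given pre-drawn uniforms (B, L)."""
    B = uniforms.shape[0]
    state = model.zero_state(B)
    x = np.tile(_START, (B, 1)).astype(model.dtype)
    eye = np.eye(4, dtype=model.dtype)
    out = np.empty((B, length), dtype=np.int64)
    for t in range(length):
        logits, state = model.step(x, state)
        probs = softmax(logits / temperature, axis=-1)
        cum = np.cumsum(probs, axis=1)
        cum[:, -1] = 1.0  # guard rounding
        idx = (uniforms[:, t : t + 1] < cum).argmax(axis=1)
        out[:, t] = idx
        x = eye[idx]
    return out


def sample_sequence(
    model: GeneratorModel,
    length: Optional[int] = None,
    seed: Union[int, np.random.SeedSequence] = 0,
    temperature: float = 1.0,
    seq_id: str = "gen",
) -> Sequence:
    """Sample one sequence of *length* nucleotides from the model.

    The hidden state starts at zero and the first input is the uniform
    vector (0.25, 0.25, 0.25, 0.25); each subsequent input is the
    one-hot vector of the character just drawn from the (temperature-
    scaled) softmax.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    length = model.seq_len if length is None else length
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    uniforms = rng.random((1, length))
    idx = _sample_batch(model, length, uniforms, temperature)[0]
    return Sequence(seq_id, decode_indices(idx, model.alphabet), model.alphabet)


def generate_pool(
    model: GeneratorModel,
    count: int,
    seed: int = 0,
    length: Optional[int] = None,
    temperature: float = 1.0,
    batch: int = 8192,
    id_prefix: str = "gen",
) -> List[Sequence]:
    """Sample *count* independent sequences (per-sequence state reset).

    Each sequence has its own RNG stream spawned from *seed*, so
    ``generate_pool(model, 1, seed)`` equals ``sample_sequence`` with the
    first spawned child seed.  Duplicates are retained.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    length = model.seq_len if length is None else length
    children = np.random.SeedSequence(seed).spawn(count)
    out: List[Sequence] = []
    for start in range(0, count, batch):
        stop = min(start + batch, count)
        uniforms = np.stack(
            [np.random.default_rng(children[i]).random(length) for i in range(start, stop)]
        )
        idx = _sample_batch(model, length, uniforms, temperature)
        for row, i in zip(idx, range(start, stop)):
            out.append(
                Sequence(f"{id_prefix}_{i}", decode_indices(row, model.alphabet), model.alphabet)
            )
    return out


def iu_ratio(
    training: Iterable[Union[Sequence, str]],
    generated: Iterable[Union[Sequence, str]],
) -> float:
    """Intersection-over-union of two sequence sets (memorization probe)."""
    t = {s.residues if isinstance(s, Sequence) else str(s) for s in training}
    g = {s.residues if isinstance(s, Sequence) else str(s) for s in generated}
    if not t and not g:
        raise ValueError("both sequence sets are empty")
    return len(t & g) / len(t | g)
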