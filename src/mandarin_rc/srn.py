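"""From-scratch Elman simple recurrent network for next-word prediction.

Architecture: 28 localist input units, a 40-unit logistic hidden layer fed by
the input and by a 40-unit context layer (an exact copy of the previous
step's hidden activations), and 28 output units.  Training is plain
stochastic gradient descent with classical momentum, one weight update per
word (batch size 1), one pass through the corpus by default.  The context is
treated as a frozen input during backpropagation — the defining single-step
training scheme of the original SRN, with no backpropagation through time.

Output units are logistic with a per-unit cross-entropy loss by default
(the historical simulator default; trained output vectors then sum to
*around* 1 without being normalised); a softmax output with multinomial
cross-entropy is available via ``output_activation="softmax"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from mandarin_rc.grammar import Corpus, N_UNITS, Sentence

__all__ = [
    "SRNConfig",
    "SRNState",
    "TrainingRecord",
    "init_network",
    "forward_step",
    "predict_sentence",
    "train_on_corpus",
    "train_on_sentence",
    "evaluate_loss",
    "ActivationTrace",
    "save_checkpoint",
    "load_checkpoint",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # clip to keep exp() finite for extreme pre-activations
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


@dataclass(frozen=True)
class SRNConfig:
    """Hyperparameters of one network.

    ``context_reset`` is the value every context unit takes at the start of
    a sentence; 0.5 is the logistic resting activation (logistic(0)).
    """

    n_input: int = N_UNITS
    n_hidden: int = 40
    n_output: int = N_UNITS
    learning_rate: float = 0.05
    momentum: float = 0.9
    init_low: float = -1.0
    init_high: float = 1.0
    epochs: int = 1
    context_reset: float = 0.5
    output_activation: str = "logistic"  # or "softmax"
    loss: str = "sum_squared"            # or "cross_entropy"

    def __post_init__(self) -> None:
        if self.output_activation not in ("logistic", "softmax"):
            raise ValueError(
                f"unknown output activation {self.output_activation!r}"
            )
        if self.loss not in ("sum_squared", "cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.output_activation == "softmax" and self.loss == "sum_squared":
            raise ValueError("softmax outputs require the cross-entropy loss")
        if not -self.init_low == self.init_high:
            raise ValueError("weight init range must be symmetric about 0")


@dataclass
class SRNState:
    """All trainable parameters, momentum velocities and the context layer.

    Weight matrices map *from* the named source layer *to* the named target
    layer: ``w_ih`` input->hidden (n_hidden x n_input), ``w_ch``
    context->hidden (n_hidden x n_hidden), ``w_ho`` hidden->output
    (n_output x n_hidden).
    """

    config: SRNConfig
    w_ih: np.ndarray
    w_ch: np.ndarray
    w_ho: np.ndarray
    b_h: np.ndarray
    b_o: np.ndarray
    v_w_ih: np.ndarray
    v_w_ch: np.ndarray
    v_w_ho: np.ndarray
    v_b_h: np.ndarray
    v_b_o: np.ndarray
    context: np.ndarray
    seed: int | None = None

    def reset_context(self) -> None:
        self.context = np.full(self.config.n_hidden, self.config.context_reset)

    def parameters(self) -> dict[str, np.ndarray]:
        return {"w_ih": self.w_ih, "w_ch": self.w_ch, "w_ho": self.w_ho,
                "b_h": self.b_h, "b_o": self.b_o}

    def velocities(self) -> dict[str, np.ndarray]:
        return {"w_ih": self.v_w_ih, "w_ch": self.v_w_ch, "w_ho": self.v_w_ho,
                "b_h": self.v_b_h, "b_o": self.v_b_o}

    def copy(self) -> "SRNState":
        return SRNState(
            config=self.config,
            **{k: v.copy() for k, v in self.parameters().items()},
            **{f"v_{k}": v.copy() for k, v in self.velocities().items()},
            context=self.context.copy(),
            seed=self.seed,
        )


def init_network(config: SRNConfig, seed: int) -> SRNState:
    """Create a network with i.i.d. uniform weights on the init range.

    Biases are initialised like any other incoming weight.  Velocities start
    at zero and the context at ``config.context_reset``.
    """
    rng = np.random.default_rng(seed)

    def u(*shape: int) -> np.ndarray:
        return rng.uniform(config.init_low, config.init_high, size=shape)

    nh, ni, no = config.n_hidden, config.n_input, config.n_output
    return SRNState(
        config=config,
        w_ih=u(nh, ni), w_ch=u(nh, nh), w_ho=u(no, nh),
        b_h=u(nh), b_o=u(no),
        v_w_ih=np.zeros((nh, ni)), v_w_ch=np.zeros((nh, nh)),
        v_w_ho=np.zeros((no, nh)), v_b_h=np.zeros(nh), v_b_o=np.zeros(no),
        context=np.full(nh, config.context_reset),
        seed=seed,
    )


def forward_step(state: SRNState, word_index: int) -> np.ndarray:
    """Present one word; return the output activations.

    hidden = logistic(W_ih·onehot + W_ch·context + b_h); the new hidden
    activations replace the context for the next step.
    """
    if not 0 <= word_index < state.config.n_input:
        raise ValueError(f"word index {word_index} outside 0..{state.config.n_input - 1}")
    h = _sigmoid(state.w_ih[:, word_index] + state.w_ch @ state.context + state.b_h)
    z = state.w_ho @ h + state.b_o
    y = _softmax(z) if state.config.output_activation == "softmax" else _sigmoid(z)
    state.context = h
    return y


def _word_gradients(
    state: SRNState, word_index: int, target_index: int, context: np.ndarray
) -> tuple[dict[str, np.ndarray], float, np.ndarray]:
    """Loss gradients for a single input/target pair with a frozen context.

    Returns (gradients keyed like ``state.parameters()``, loss, new hidden
    activations).  The default loss for logistic outputs is the summed
    squared error ``0.5 * sum((y - t)^2)`` (output delta ``(y - t) *
    y * (1 - y)``); ``loss="cross_entropy"`` uses the per-unit binary
    cross-entropy instead (delta ``y - t``).  Softmax outputs always use the
    multinomial cross-entropy (delta ``y - t``).
    """
    h = _sigmoid(state.w_ih[:, word_index] + state.w_ch @ context + state.b_h)
    z = state.w_ho @ h + state.b_o
    t = np.zeros(state.config.n_output)
    t[target_index] = 1.0
    if state.config.output_activation == "softmax":
        y = _softmax(z)
        loss = -float(np.log(max(y[target_index], 1e-300)))
        delta_o = y - t
    elif state.config.loss == "cross_entropy":
        y = _sigmoid(z)
        yc = np.clip(y, 1e-12, 1.0 - 1e-12)
        loss = -float(np.sum(t * np.log(yc) + (1.0 - t) * np.log(1.0 - yc)))
        delta_o = y - t
    else:
        y = _sigmoid(z)
        loss = 0.5 * float(np.sum((y - t) ** 2))
        delta_o = (y - t) * y * (1.0 - y)
    delta_h = (state.w_ho.T @ delta_o) * h * (1.0 - h)
    grads = {
        "w_ho": np.outer(delta_o, h),
        "b_o": delta_o,
        "w_ch": np.outer(delta_h, context),
        "b_h": delta_h,
    }
    g_ih = np.zeros_like(state.w_ih)
    g_ih[:, word_index] = delta_h  # one-hot input: only one column receives gradient
    grads["w_ih"] = g_ih
    return grads, loss, h


def _momentum_update(state: SRNState, grads: dict[str, np.ndarray]) -> None:
    """Classical momentum: v <- mu*v - lr*grad; w <- w + v."""
    lr, mu = state.config.learning_rate, state.config.momentum
    params = state.parameters()
    vels = state.velocities()
    for k, g in grads.items():
        v = vels[k]
        v *= mu
        v -= lr * g
        params[k] += v


@dataclass
class TrainingRecord:
    """Per-sentence mean prediction loss over the training pass(es)."""

    sentence_losses: list[float] = field(default_factory=list)
    epochs: int = 1

    def mean_loss(self, last: int | None = None) -> float:
        losses = self.sentence_losses[-last:] if last else self.sentence_losses
        return float(np.mean(losses))


def train_on_sentence(state: SRNState, tokens: Sequence[int]) -> float:
    """One pass over one sentence; returns the mean per-word loss.

    The context is reset, then for every word except the final EOS the
    target is the next word's one-hot vector and the weights are updated
    immediately (batch size 1).  The final EOS has no target: sentences are
    independent and no cross-sentence prediction is trained.
    """
    state.reset_context()
    total = 0.0
    n = 0
    for t in range(len(tokens) - 1):
        grads, loss, h = _word_gradients(state, tokens[t], tokens[t + 1], state.context)
        state.context = h
        _momentum_update(state, grads)
        total += loss
        n += 1
    return total / max(n, 1)


def train_on_corpus(
    state: SRNState, corpus: Corpus | Sequence[Sentence], config: SRNConfig | None = None
) -> tuple[SRNState, TrainingRecord]:
    """Train in place on the corpus in its given order; returns the state and
    the per-sentence loss record.

    ``config`` defaults to ``state.config``; passing a different epoch count
    re-runs the corpus that many times.
    """
    config = config or state.config
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    record = TrainingRecord(epochs=config.epochs)
    for _ in range(config.epochs):
        for sent in corpus:
            tokens = sent.tokens
            if any(not 0 <= t < state.config.n_input for t in tokens):
                raise ValueError("corpus token outside the network vocabulary")
            record.sentence_losses.append(train_on_sentence(state, tokens))
    return state, record


def evaluate_loss(state: SRNState, corpus: Corpus | Sequence[Sentence]) -> float:
    """Mean per-word prediction loss over a corpus, without weight updates."""
    total = 0.0
    n = 0
    for sent in corpus:
        ctx = np.full(state.config.n_hidden, state.config.context_reset)
        for t in range(len(sent.tokens) - 1):
            _, loss, h = _word_gradients(state, sent.tokens[t], sent.tokens[t + 1], ctx)
            ctx = h
            total += loss
            n += 1
    return total / max(n, 1)


@dataclass
class ActivationTrace:
    """Output and hidden activations for each position of one sentence."""

    outputs: np.ndarray  # (len, n_output)
    hidden: np.ndarray   # (len, n_hidden)

    def __len__(self) -> int:
        return len(self.outputs)


def predict_sentence(state: SRNState, sentence: Sentence | Sequence[int]) -> ActivationTrace:
    """Forward pass over a sentence with no learning.

    The context is reset at the sentence start; ``outputs[t]`` is the
    activation produced when token ``t`` is the input.  The caller's state is
    not mutated beyond the documented context reset (a scratch copy of the
    context is used).
    """
    tokens = sentence.tokens if isinstance(sentence, Sentence) else tuple(sentence)
    ctx = np.full(state.config.n_hidden, state.config.context_reset)
    outputs = np.empty((len(tokens), state.config.n_output))
    hidden = np.empty((len(tokens), state.config.n_hidden))
    for t, w in enumerate(tokens):
        h = _sigmoid(state.w_ih[:, w] + state.w_ch @ ctx + state.b_h)
        z = state.w_ho @ h + state.b_o
        y = (_softmax(z) if state.config.output_activation == "softmax"
             else _sigmoid(z))
        outputs[t] = y
        hidden[t] = h
        ctx = h
    return ActivationTrace(outputs=outputs, hidden=hidden)


def save_checkpoint(state: SRNState, path: str | Path) -> None:
    """Round-trippable checkpoint: parameters, velocities, context, config."""
    cfg = state.config
    np.savez(
        Path(path),
        **state.parameters(),
        **{f"v_{k}": v for k, v in state.velocities().items()},
        context=state.context,
        seed=np.array(-1 if state.seed is None else state.seed),
        config=np.array(
            [cfg.n_input, cfg.n_hidden, cfg.n_output, cfg.learning_rate,
             cfg.momentum, cfg.init_low, cfg.init_high, cfg.epochs,
             cfg.context_reset, 1.0 if cfg.output_activation == "softmax" else 0.0,
             1.0 if cfg.loss == "cross_entropy" else 0.0]
        ),
    )


def load_checkpoint(path: str | Path) -> SRNState:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")  # np.savez appends .npz
    with np.load(path) as data:
        c = data["config"]
        config = SRNConfig(
            n_input=int(c[0]), n_hidden=int(c[1]), n_output=int(c[2]),
            learning_rate=float(c[3]), momentum=float(c[4]),
            init_low=float(c[5]), init_high=float(c[6]), epochs=int(c[7]),
            context_reset=float(c[8]),
            output_activation="softmax" if c[9] == 1.0 else "logistic",
            loss="cross_entropy" if c[10] == 1.0 else "sum_squared",
        )
        seed = int(data["seed"])
        return SRNState(
            config=config,
            w_ih=data["w_ih"], w_ch=data["w_ch"], w_ho=data["w_ho"],
            b_h=data["b_h"], b_o=data["b_o"],
            v_w_ih=data["v_w_ih"], v_w_ch=data["v_w_ch"], v_w_ho=data["v_w_ho"],
            v_b_h=data["v_b_h"], v_b_o=data["v_b_o"],
            context=data["context"],
            seed=None if seed == -1 else seed,
        )
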