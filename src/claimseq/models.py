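"""Neural architectures for history encoding.

The pipeline is: token embedding e(·) → per-position features (optionally
concatenated with a learned reduction of a sinusoidal encoding of the
absolute event day) → a sequence encoder (identity for the max-pool
baseline, stacked LSTM, or a small transformer) → a readout that collapses
positions into one history vector f(S), optionally through exponential
time-decay channels, → a linear prediction head.

Time decay (the package's central temporal model): each event's feature
vector is down-weighted by exp(−a·t) where t is the elapsed days between
the event and the prediction cutoff (time 0) and a = ln2 / half-life.  One
channel per half-life is max-pooled and the channels are concatenated, so
with hidden width 1024 and the default half-lives (∞, 50, 100 days) the
history vector is 3072-dimensional.

PAD positions are masked out of pooling and attention; the EOS token is a
real pooling candidate carrying t = 0, which keeps patients with no prior
observations well-defined.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .events import EOS, PAD, LabeledSample

CHECKPOINT_VERSION = "claimseq-checkpoint-1"
_NEG_INF = -1e30

__all__ = [
    "DecaySpec",
    "EncoderConfig",
    "decay_weight",
    "decay_pool",
    "time_encode",
    "count_head_params",
    "SequenceModel",
    "batch_samples",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class DecaySpec:
    """Exponential-decay channels given as half-lives in days.

    A half-life of ∞ means no decay (rate a = 0, every event weighted 1);
    otherwise a = ln2 / half_life so the weight at one half-life is 1/2.
    """

    half_lives: tuple[float, ...] = (math.inf, 50.0, 100.0)

    def __post_init__(self) -> None:
        if not self.half_lives:
            raise ValueError("at least one half-life is required")
        if any(h <= 0 for h in self.half_lives):
            raise ValueError("half-lives must be positive (or inf for no decay)")

    @property
    def rates(self) -> tuple[float, ...]:
        return tuple(0.0 if math.isinf(h) else math.log(2.0) / h for h in self.half_lives)

    @property
    def n_channels(self) -> int:
        return len(self.half_lives)


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture and readout configuration for history encoding.

    ``architecture``: ``maxpool_baseline`` (identity encoder), ``recurrent``
    (stacked LSTM) or ``attention`` (small transformer).  ``readout``
    collapses positions: ``max_pool`` (default; also ``mean_pool`` and
    ``sum_pool`` for the pooling comparison) or ``eos`` (the EOS-position
    output — meaningless for the order-free baseline, hence forbidden
    there).  ``time_mode``: ``none``, ``decay`` (decay channels at the
    readout) or ``encode`` (sinusoidal absolute-day features reduced to
    ``d_time`` dims and concatenated to the embedding).
    """

    architecture: str = "maxpool_baseline"
    depth: int = 1
    readout: str = "max_pool"
    time_mode: str = "none"
    d_hidden: int = 1024
    d_time: int = 64
    enc_width: int | None = None
    decay: DecaySpec = field(default_factory=DecaySpec)
    n_heads: int = 2

    def __post_init__(self) -> None:
        if self.architecture not in ("maxpool_baseline", "recurrent", "attention"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.readout not in ("max_pool", "mean_pool", "sum_pool", "eos"):
            raise ValueError(f"unknown readout {self.readout!r}")
        if self.time_mode not in ("none", "decay", "encode"):
            raise ValueError(f"unknown time_mode {self.time_mode!r}")
        if self.architecture == "maxpool_baseline" and self.readout != "max_pool":
            raise ValueError(
                "maxpool_baseline requires readout='max_pool': without an "
                "encoder the EOS position carries no history"
            )
        if self.time_mode == "decay" and self.readout == "eos":
            raise ValueError("decay channels require a pooling readout")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.time_mode == "encode" and self.effective_enc_width % 2:
            raise ValueError("enc_width must be even (sin/cos pairs)")
        if self.architecture == "attention" and self.d_hidden % self.n_heads:
            raise ValueError("d_hidden must be divisible by n_heads")

    @property
    def effective_enc_width(self) -> int:
        return self.d_hidden if self.enc_width is None else self.enc_width

    @property
    def d_position(self) -> int:
        """Per-position feature width entering the encoder/readout."""
        return self.d_hidden + (self.d_time if self.time_mode == "encode" else 0)

    @property
    def history_dim(self) -> int:
        """Dimension of the history vector f(S) under this configuration."""
        base = self.d_position
        if self.time_mode == "decay":
            return self.decay.n_channels * base
        return base


def decay_weight(t_days, a: float):
    """Exponential decay multiplier exp(−a·t) for elapsed time t ≥ 0.

    At t equal to the half-life (a = ln2/h) the weight is exactly 1/2.
    Negative t (an event after the cutoff) is rejected — such events must
    never enter the observation window.
    """
    t = np.asarray(t_days, dtype=np.float64)
    if a < 0:
        raise ValueError("decay rate a must be non-negative")
    if (t < 0).any():
        raise ValueError("elapsed time t must be non-negative (event after cutoff?)")
    out = np.exp(-a * t)
    return float(out) if np.isscalar(t_days) else out


def decay_pool(
    embedded_events: np.ndarray,
    times: np.ndarray,
    decay_spec: DecaySpec,
) -> np.ndarray:
    """Concatenated decay-channel max-pool of embedded events.

    For each half-life channel, every event embedding is multiplied by its
    decay weight and the coordinate-wise maximum over events is taken; the
    channels are concatenated, giving ``n_channels * d`` outputs.  Callers
    include the EOS row (t = 0) so the empty-history case stays defined.
    """
    embedded = np.asarray(embedded_events, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if embedded.ndim != 2 or embedded.shape[0] != times.shape[0]:
        raise ValueError("expected (n_events, d) embeddings and n_events times")
    if embedded.shape[0] == 0:
        raise ValueError("empty event set: include the EOS embedding (t=0)")
    channels = [
        (embedded * decay_weight(times, a)[:, None]).max(axis=0)
        for a in decay_spec.rates
    ]
    return np.concatenate(channels)


def time_encode(julian_days, enc_width: int) -> np.ndarray:
    """Sinusoidal encoding of absolute day numbers.

    Positional-encoding style: ``enc_width/2`` geometrically spaced
    frequencies, a sin and a cos coordinate each, all bounded in [−1, 1].
    Absolute Julian days stand in for the serial position, so the encoding
    is a function of the calendar date alone; a learned linear layer
    reduces it before concatenation with the concept embedding.
    """
    if enc_width % 2:
        raise ValueError("enc_width must be even")
    days = np.asarray(julian_days, dtype=np.float64)
    k = np.arange(enc_width // 2, dtype=np.float64)
    inv_freq = 1.0 / (10000.0 ** (2.0 * k / enc_width))
    phase = days[..., None] * inv_freq
    return np.concatenate([np.sin(phase), np.cos(phase)], axis=-1)


def count_head_params(d_hidden: int, d_dict: int) -> int:
    """Weight count of the 1-out-of-N linear prediction head this package's
    pairwise pre-training objective avoids (d_hidden × d_dict)."""
    if d_hidden <= 0 or d_dict <= 0:
        raise ValueError("dimensions must be positive")
    return d_hidden * d_dict


def batch_samples(samples: Sequence[LabeledSample]):
    """Stack equal-length samples into (tokens, days, index_days, labels)."""
    tokens = np.stack([s.tokens for s in samples])
    days = np.stack([s.days_before_index for s in samples])
    index_days = np.array([s.index_day for s in samples], dtype=np.float64)
    labels = np.array(
        [-1 if s.label is None else s.label for s in samples], dtype=np.float64
    )
    return tokens, days, index_days, labels


class SequenceModel:
    """History encoder + linear head with named parameters.

    Parameters are initialized symmetric-uniform scaled by fan-in from a
    fixed seed.  The embedding parameter is named ``emb`` so optimizers can
    freeze it during phase 1 of fine-tuning.
    """

    def __init__(self, config: EncoderConfig, n_tokens: int, seed: int = 0):
        self.config = config
        self.n_tokens = n_tokens
        rng = np.random.default_rng(seed)
        d = config.d_hidden
        self.params: dict[str, Tensor] = {}

        def uniform(name: str, shape: tuple[int, ...], fan_in: int) -> None:
            bound = 1.0 / math.sqrt(fan_in)
            self.params[name] = Tensor(
                rng.uniform(-bound, bound, size=shape), requires_grad=True
            )

        uniform("emb", (n_tokens, d), d)
        if config.time_mode == "encode":
            uniform("time_w", (config.effective_enc_width, config.d_time),
                    config.effective_enc_width)
            uniform("time_b", (config.d_time,), config.effective_enc_width)
        d_pos = config.d_position
        if config.architecture == "recurrent":
            for layer in range(config.depth):
                d_in = d_pos if layer == 0 else d_pos
                uniform(f"lstm{layer}_wx", (d_in, 4 * d_pos), d_in)
                uniform(f"lstm{layer}_wh", (d_pos, 4 * d_pos), d_pos)
                b = np.zeros(4 * d_pos)
                b[d_pos : 2 * d_pos] = 1.0  # forget-gate bias
                self.params[f"lstm{layer}_b"] = Tensor(b, requires_grad=True)
        elif config.architecture == "attention":
            for layer in range(config.depth):
                for w in ("wq", "wk", "wv", "wo"):
                    uniform(f"attn{layer}_{w}", (d_pos, d_pos), d_pos)
                uniform(f"attn{layer}_ff1", (d_pos, 2 * d_pos), d_pos)
                self.params[f"attn{layer}_ff1b"] = Tensor(
                    np.zeros(2 * d_pos), requires_grad=True)
                uniform(f"attn{layer}_ff2", (2 * d_pos, d_pos), 2 * d_pos)
                self.params[f"attn{layer}_ff2b"] = Tensor(
                    np.zeros(d_pos), requires_grad=True)
                for ln in ("ln1", "ln2"):
                    self.params[f"attn{layer}_{ln}_g"] = Tensor(
                        np.ones(d_pos), requires_grad=True)
                    self.params[f"attn{layer}_{ln}_b"] = Tensor(
                        np.zeros(d_pos), requires_grad=True)
        uniform("head_w", (config.history_dim, 1), config.history_dim)
        self.params["head_b"] = Tensor(np.zeros(1), requires_grad=True)

    # -- building blocks ----------------------------------------------------

    def embed(self, tokens: np.ndarray) -> Tensor:
        """Look up embeddings e(·) for an integer token array."""
        return self.params["emb"].take_rows(np.asarray(tokens))

    def _position_features(
        self, tokens: np.ndarray, days: np.ndarray, index_days: np.ndarray | None
    ) -> Tensor:
        x = self.embed(tokens)
        if self.config.time_mode == "encode":
            if index_days is None:
                raise ValueError("time_mode='encode' requires index days")
            abs_days = np.asarray(index_days)[:, None] - np.asarray(days)
            te = Tensor(time_encode(abs_days, self.config.effective_enc_width))
            reduced = te @ self.params["time_w"] + self.params["time_b"]
            x = ad.concat([x, reduced], axis=-1)
        return x

    def _lstm(self, x: Tensor, mask: np.ndarray) -> Tensor:
        b_sz, length, d = x.shape
        h_prev = Tensor(np.zeros((b_sz, d)))
        c_prev = Tensor(np.zeros((b_sz, d)))
        for layer in range(self.config.depth):
            wx = self.params[f"lstm{layer}_wx"]
            wh = self.params[f"lstm{layer}_wh"]
            bias = self.params[f"lstm{layer}_b"]
            h_prev = Tensor(np.zeros((b_sz, d)))
            c_prev = Tensor(np.zeros((b_sz, d)))
            outputs = []
            for t in range(length):
                xt = x[:, t, :]
                z = xt @ wx + h_prev @ wh + bias
                i = z[:, 0:d].sigmoid()
                f = z[:, d : 2 * d].sigmoid()
                g = z[:, 2 * d : 3 * d].tanh()
                o = z[:, 3 * d : 4 * d].sigmoid()
                c_new = f * c_prev + i * g
                h_new = o * c_new.tanh()
                m = mask[:, t]  # (B, 1): broadcasts over hidden dims
                h_prev = ad.where(m, h_new, h_prev)
                c_prev = ad.where(m, c_new, c_prev)
                outputs.append(h_prev.reshape(b_sz, 1, d))
            x = ad.concat(outputs, axis=1)
        return x

    def _layernorm(self, x: Tensor, gain: Tensor, bias: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / (var + 1e-6).sqrt() * gain + bias

    def _attention(self, x: Tensor, mask: np.ndarray, causal: bool = False) -> Tensor:
        b_sz, length, d = x.shape
        h = self.config.n_heads
        dk = d // h
        key_bias = np.where(mask[:, None, None, :], 0.0, _NEG_INF)  # [B,1,1,L]
        if causal:
            tri = np.tril(np.ones((length, length)))
            key_bias = key_bias + np.where(tri[None, None], 0.0, _NEG_INF)
        for layer in range(self.config.depth):
            def split(t: Tensor) -> Tensor:
                return t.reshape(b_sz, length, h, dk).transpose(0, 2, 1, 3)

            q = split(x @ self.params[f"attn{layer}_wq"])
            k = split(x @ self.params[f"attn{layer}_wk"])
            v = split(x @ self.params[f"attn{layer}_wv"])
            scores = q @ k.transpose(0, 1, 3, 2) * (1.0 / math.sqrt(dk))
            scores = scores + Tensor(key_bias)
            attn = ad.softmax(scores, axis=-1)
            ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b_sz, length, d)
            x = self._layernorm(
                x + ctx @ self.params[f"attn{layer}_wo"],
                self.params[f"attn{layer}_ln1_g"],
                self.params[f"attn{layer}_ln1_b"],
            )
            ff = (x @ self.params[f"attn{layer}_ff1"] + self.params[f"attn{layer}_ff1b"]
                  ).relu() @ self.params[f"attn{layer}_ff2"] + self.params[f"attn{layer}_ff2b"]
            x = self._layernorm(
                x + ff,
                self.params[f"attn{layer}_ln2_g"],
                self.params[f"attn{layer}_ln2_b"],
            )
        return x

    def _encode_positions(
        self, x: Tensor, mask: np.ndarray, causal: bool = False
    ) -> Tensor:
        if self.config.architecture == "maxpool_baseline" or self.config.depth == 0:
            return x
        if self.config.architecture == "recurrent":
            return self._lstm(x, mask[..., None])
        return self._attention(x, mask, causal=causal)

    def _readout(
        self, h: Tensor, tokens: np.ndarray, days: np.ndarray, mask: np.ndarray
    ) -> Tensor:
        cfg = self.config
        mask3 = mask[..., None]
        if cfg.time_mode == "decay":
            channels = []
            for a in cfg.decay.rates:
                w = np.exp(-a * np.asarray(days, dtype=np.float64))[..., None]
                decayed = h * Tensor(w)
                channels.append(ad.where(mask3, decayed, Tensor(_NEG_INF)).max(axis=1))
            return ad.concat(channels, axis=-1)
        if cfg.readout == "max_pool":
            return ad.where(mask3, h, Tensor(_NEG_INF)).max(axis=1)
        if cfg.readout == "mean_pool":
            masked = ad.where(mask3, h, Tensor(0.0))
            return masked.sum(axis=1) / mask3.sum(axis=1)
        if cfg.readout == "sum_pool":
            return ad.where(mask3, h, Tensor(0.0)).sum(axis=1)
        # eos readout: gather the EOS position of each row
        rows = np.arange(tokens.shape[0])
        eos_pos = np.argmax(tokens == EOS, axis=1)
        return h[rows, eos_pos, :]

    # -- public surface -----------------------------------------------------

    def encode_history(
        self,
        tokens: np.ndarray,
        days: np.ndarray,
        index_days: np.ndarray | None = None,
    ) -> Tensor:
        """History vectors f(S) for a batch: (B, L) tokens → (B, history_dim).

        PAD positions are masked everywhere; in decay mode every channel
        weights events by exp(−a·t) with t = days-before-index (EOS has
        t = 0).  Front- and back-padded batches behave identically.
        """
        tokens = np.asarray(tokens)
        mask = tokens != PAD
        x = self._position_features(tokens, days, index_days)
        h = self._encode_positions(x, mask)
        return self._readout(h, tokens, days, mask)

    def encode_prefixes(self, tokens: np.ndarray, days: np.ndarray) -> Tensor:
        """Per-position prefix encodings for dense pre-training.

        Position j holds f(S_{j+1}), the encoding of the first j+1 events.
        Sequences must be *back*-padded.  The identity (max-pool) encoder
        uses a running maximum; the recurrent encoder's hidden states are
        already causal; attention uses a causal mask, then a running max
        for the pooled readout.
        """
        tokens = np.asarray(tokens)
        mask = tokens != PAD
        x = self._position_features(tokens, days, None)
        if self.config.architecture == "maxpool_baseline" or self.config.depth == 0:
            return ad.where(mask[..., None], x, Tensor(_NEG_INF)).cummax(axis=1)
        h = self._encode_positions(x, mask, causal=True)
        if self.config.readout == "max_pool":
            return ad.where(mask[..., None], h, Tensor(_NEG_INF)).cummax(axis=1)
        return h  # recurrent hidden state / last-position output per prefix

    def predict_logit(self, history_vector: Tensor) -> Tensor:
        """Affine map of history vectors to scalar outcome logits."""
        if history_vector.shape[-1] != self.config.history_dim:
            raise ValueError(
                f"history vector dim {history_vector.shape[-1]} != "
                f"configured {self.config.history_dim}"
            )
        h = Tensor._lift(history_vector)
        out = h @ self.params["head_w"] + self.params["head_b"]
        return out.reshape(*out.shape[:-1])

    def forward_logits(
        self,
        tokens: np.ndarray,
        days: np.ndarray,
        index_days: np.ndarray | None = None,
    ) -> Tensor:
        return self.predict_logit(self.encode_history(tokens, days, index_days))

    def scores(self, samples: Sequence[LabeledSample]) -> np.ndarray:
        """Outcome probabilities sigmoid(logit) for prepared samples."""
        tokens, days, index_days, _ = batch_samples(samples)
        return self.forward_logits(tokens, days, index_days).sigmoid().data


# ---------------------------------------------------------------------------
# Checkpoints


def _config_to_json(config: EncoderConfig) -> str:
    d = asdict(config)
    d["decay"] = list(config.decay.half_lives)
    return json.dumps(d)


def _config_from_json(payload: str) -> EncoderConfig:
    d = json.loads(payload)
    d["decay"] = DecaySpec(half_lives=tuple(d["decay"]))
    return EncoderConfig(**d)


def save_checkpoint(path, model: SequenceModel, dictionary_fingerprint: str) -> None:
    """Persist config, dictionary fingerprint and all named parameters.

    The container is self-describing and reloads bit-exactly.
    """
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": _config_to_json(model.config),
        "n_tokens": model.n_tokens,
        "dictionary_fingerprint": dictionary_fingerprint,
        "param_names": sorted(model.params),
    }
    arrays = {f"param_{k}": v.data for k, v in model.params.items()}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_checkpoint(path) -> tuple[SequenceModel, str]:
    """Rebuild a model from a checkpoint; returns (model, fingerprint)."""
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']!r}")
        config = _config_from_json(meta["config"])
        model = SequenceModel(config, n_tokens=meta["n_tokens"], seed=0)
        for name in meta["param_names"]:
            model.params[name].data = archive[f"param_{name}"].copy()
    return model, meta["dictionary_fingerprint"]
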