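"""Encoder-decoder model for coding-potential prediction and RNA-to-protein translation.

The encoder embeds one-hot nucleotide rows and runs either a stack of local
Fourier-filter layers (:mod:`rnacoding.lfnet`) or residual dilated 1-D
convolutions. The decoder is a small transformer stack (masked
self-attention, encoder-decoder attention, feed-forward) that emits a
leading classification token (``<PC>``/``<NC>``) followed, for coding
transcripts, by the protein sequence. A pointer head alternatively maps the
encoder states to a distribution over input positions for start-codon
prediction.

All computation is pure-functional over a parameter pytree (a nested dict of
numpy arrays) and uses :mod:`autograd.numpy`, so gradients with respect to
both parameters and the one-hot input coordinates are available. Inputs are
dense ``(N, L, 4)`` arrays — one-hot for real sequences, but any dense rows
(e.g. points on an integrated-gradients path) are accepted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import autograd.numpy as anp
import numpy as np

from .lfnet import LfnetConfig, apply_filter, init_filterbank, istft, lfnet_forward, stft
from .sequences import RNA_ALPHABET

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Output vocabulary. Class tokens are legal only at the first output position.
PAD, SOS, EOS, TOK_PC, TOK_NC = 0, 1, 2, 3, 4
OUTPUT_TOKENS = ["<pad>", "<sos>", "<eos>", "<PC>", "<NC>"] + list(AMINO_ACIDS)
TOKEN_INDEX = {t: i for i, t in enumerate(OUTPUT_TOKENS)}
V_OUT = len(OUTPUT_TOKENS)
V_IN = 4

_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}


def one_hot(sequence: str) -> np.ndarray:
    """(L, 4) one-hot encoding in A, C, G, U order."""
    idx = [_BASE_INDEX[b] for b in sequence]
    x = np.zeros((len(sequence), V_IN))
    x[np.arange(len(sequence)), idx] = 1.0
    return x


def encode_protein(protein: str) -> list[int]:
    return [TOKEN_INDEX[a] for a in protein]


def target_tokens(transcript, task: str, max_protein_len: Optional[int] = None) -> list[int]:
    """Gold output token sequence (without <sos>) for a training task."""
    cls = TOK_PC if transcript.is_coding else TOK_NC
    if task == "class":
        return [cls]
    prot = transcript.protein or ""
    if max_protein_len is not None:
        prot = prot[:max_protein_len]
    return [cls] + encode_protein(prot) + [EOS]


@dataclass(frozen=True)
class ModelConfig:
    encoder_type: str = "lfnet"  # lfnet | cnn
    n_encoder_layers: int = 2
    n_decoder_layers: int = 1
    hidden_dim: int = 32
    n_heads: int = 4
    window_length: int = 54
    softshrink_threshold: float = 0.0
    cnn_kernel: int = 9
    cnn_dilation_doubling: bool = True
    ff_mult: int = 2
    max_decode_len: int = 120
    encoder_positions: str = "sinusoidal"  # sinusoidal | none

    def __post_init__(self) -> None:
        if self.encoder_type not in ("lfnet", "cnn"):
            raise ValueError(f"unknown encoder type {self.encoder_type!r}")
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")

    @property
    def lfnet_config(self) -> LfnetConfig:
        return LfnetConfig(
            window_length=self.window_length,
            hidden_dim=self.hidden_dim,
            softshrink_threshold=self.softshrink_threshold,
        )


# ---------------------------------------------------------------------------
# Parameter initialisation
# ---------------------------------------------------------------------------


def _dense(rng, n_in, n_out, scale=None):
    scale = scale if scale is not None else 1.0 / np.sqrt(n_in)
    return {"w": scale * rng.randn(n_in, n_out), "b": np.zeros(n_out)}


def _layernorm_params(dim):
    return {"g": np.ones(dim), "b": np.zeros(dim)}


def init_params(config: ModelConfig, seed: int = 0) -> dict:
    rng = np.random.RandomState(seed)
    D = config.hidden_dim
    p: dict = {"embed_in": 0.5 * rng.randn(V_IN, D)}
    enc_layers = []
    for _ in range(config.n_encoder_layers):
        layer = {
            "ln1": _layernorm_params(D),
            "ln2": _layernorm_params(D),
            "ff1": _dense(rng, D, config.ff_mult * D),
            "ff2": _dense(rng, config.ff_mult * D, D),
        }
        if config.encoder_type == "lfnet":
            w_re, w_im = init_filterbank(config.lfnet_config, rng)
            layer["w_re"], layer["w_im"] = w_re, w_im
        else:
            layer["conv"] = (1.0 / np.sqrt(config.cnn_kernel * D)) * rng.randn(
                config.cnn_kernel, D, D
            )
            layer["conv_b"] = np.zeros(D)
        enc_layers.append(layer)
    p["encoder"] = enc_layers

    dec_layers = []
    for _ in range(config.n_decoder_layers):
        dec_layers.append(
            {
                "ln1": _layernorm_params(D),
                "ln2": _layernorm_params(D),
                "ln3": _layernorm_params(D),
                "self_q": _dense(rng, D, D),
                "self_k": _dense(rng, D, D),
                "self_v": _dense(rng, D, D),
                "self_o": _dense(rng, D, D),
                "cross_q": _dense(rng, D, D),
                "cross_k": _dense(rng, D, D),
                "cross_v": _dense(rng, D, D),
                "cross_o": _dense(rng, D, D),
                "ff1": _dense(rng, D, config.ff_mult * D),
                "ff2": _dense(rng, config.ff_mult * D, D),
            }
        )
    p["decoder"] = dec_layers
    p["embed_out"] = 0.5 * rng.randn(V_OUT, D)
    p["ln_out"] = _layernorm_params(D)
    p["proj_out"] = _dense(rng, D, V_OUT)
    p["pointer"] = _dense(rng, D, 1)
    return p


def n_parameters(params) -> int:
    if isinstance(params, dict):
        return sum(n_parameters(v) for v in params.values())
    if isinstance(params, (list, tuple)):
        return sum(n_parameters(v) for v in params)
    return int(np.asarray(params).size)


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------


def _layernorm(h, p, eps=1e-5):
    mu = anp.mean(h, axis=-1, keepdims=True)
    var = anp.var(h, axis=-1, keepdims=True)
    return (h - mu) / anp.sqrt(var + eps) * p["g"] + p["b"]


def _apply_dense(h, p):
    return anp.matmul(h, p["w"]) + p["b"]


def _gelu(x):
    return 0.5 * x * (1.0 + anp.tanh(0.7978845608028654 * (x + 0.044715 * x**3)))


def _softmax(x, axis=-1):
    x = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(x)
    return e / anp.sum(e, axis=axis, keepdims=True)


def _conv1d(h, kernel, bias, dilation: int):
    """Same-padded dilated 1-D convolution; ``kernel`` is (K, D_in, D_out)."""
    K = kernel.shape[0]
    L = h.shape[-2]
    c = K // 2
    out = None
    for k in range(K):
        off = (k - c) * dilation
        if off == 0:
            shifted = h
        elif off > 0:
            pad = anp.zeros(h.shape[:-2] + (off, h.shape[-1]))
            shifted = anp.concatenate([h[..., off:, :], pad], axis=-2)
        else:
            pad = anp.zeros(h.shape[:-2] + (-off, h.shape[-1]))
            shifted = anp.concatenate([pad, h[..., :off, :]], axis=-2)
        term = anp.matmul(shifted, kernel[k])
        out = term if out is None else out + term
    return out + bias


def sinusoidal_positions(n: int, dim: int) -> np.ndarray:
    pos = np.arange(n)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


# ---------------------------------------------------------------------------
# Encoder
# ---------------------------------------------------------------------------


def encode(x, params, config: ModelConfig, mask=None):
    """Per-position hidden states for dense input rows.

    Parameters
    ----------
    x : array (N, L, 4) or (L, 4)
        Dense input rows (one-hot for real sequences).
    mask : array (N, L), optional
        1 for real positions, 0 for padding.

    Returns
    -------
    H : array with the same leading shape and trailing dim ``hidden_dim``.
    """
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if mask is None:
        mask = np.ones(x.shape[:2])
    m = mask[..., None]
    h = anp.matmul(x, params["embed_in"])
    if config.encoder_positions == "sinusoidal":
        h = h + sinusoidal_positions(x.shape[-2], config.hidden_dim)
    h = h * m
    lf_cfg = config.lfnet_config
    for li, layer in enumerate(params["encoder"]):
        if config.encoder_type == "lfnet":
            # pre-LN residual form: the filter block sees the normalised h,
            # but the residual carries the unnormalised stream
            z = _layernorm(h, layer["ln1"]) * m
            h = h + istft(
                apply_filter(stft(z, lf_cfg), layer["w_re"], layer["w_im"], lf_cfg.softshrink_threshold),
                lf_cfg,
                z.shape[-2],
            )
        else:
            dilation = 2**li if config.cnn_dilation_doubling else 1
            h = h + _gelu(
                _conv1d(_layernorm(h, layer["ln1"]) * m, layer["conv"], layer["conv_b"], dilation)
            )
        h = h * m
        h = h + anp.matmul(_gelu(_apply_dense(_layernorm(h, layer["ln2"]), layer["ff1"])), layer["ff2"]["w"]) + layer["ff2"]["b"]
        h = h * m
    return h[0] if squeeze else h


def cnn_receptive_field(config: ModelConfig) -> int:
    """Effective receptive field of the dilated CNN stack."""
    rf = 1
    for li in range(config.n_encoder_layers):
        dilation = 2**li if config.cnn_dilation_doubling else 1
        rf += (config.cnn_kernel - 1) * dilation
    return rf


# ---------------------------------------------------------------------------
# Decoder
# ---------------------------------------------------------------------------


def _attention(q, k, v, n_heads, mask_bias=None):
    """Multi-head scaled dot-product attention.

    q: (N, T, D), k/v: (N, S, D); returns (context (N, T, D), attn (N, H, T, S)).
    """
    N, T, D = q.shape[0], q.shape[1], q.shape[2]
    S = k.shape[1]
    dh = D // n_heads

    def split(z, n):
        z = anp.reshape(z, (N, n, n_heads, dh))
        return anp.swapaxes(z, 1, 2)  # N, H, n, dh

    qh, kh, vh = split(q, T), split(k, S), split(v, S)
    scores = anp.matmul(qh, anp.swapaxes(kh, 2, 3)) / np.sqrt(dh)  # N,H,T,S
    if mask_bias is not None:
        scores = scores + mask_bias
    attn = _softmax(scores, axis=-1)
    ctx = anp.matmul(attn, vh)  # N,H,T,dh
    ctx = anp.reshape(anp.swapaxes(ctx, 1, 2), (N, T, D))
    return ctx, attn


def decode_tokens(tokens, H, params, config: ModelConfig, enc_mask=None, return_attention=False):
    """Teacher-forced decoder pass.

    Parameters
    ----------
    tokens : int array (N, T)
        Decoder input tokens, beginning with ``<sos>``; ``<pad>`` only as a
        trailing suffix.
    H : array (N, L, D)
        Encoder states.

    Returns
    -------
    logits : (N, T, V_OUT)
        Next-token logits at every prefix length.
    attentions : list over layers of (N, heads, T, L) encoder-decoder
        attention (empty unless ``return_attention``).
    """
    tokens = np.asarray(tokens)
    if tokens.ndim == 1:
        raise ValueError("tokens must be batched (N, T)")
    if not (tokens[:, 0] == SOS).all():
        raise ValueError("decoder prefix must begin with <sos>")
    # padding is permitted only as a trailing suffix
    for row in tokens:
        nz = np.nonzero(row == PAD)[0]
        if nz.size and not (row[nz[0] :] == PAD).all():
            raise ValueError("padding token inside a decoder prefix")
    N, T = tokens.shape
    D = config.hidden_dim
    h = params["embed_out"][tokens] + sinusoidal_positions(T, D)
    causal = np.triu(np.full((T, T), -1e9), k=1)[None, None]
    enc_bias = None
    if enc_mask is not None:
        enc_bias = ((enc_mask - 1.0) * 1e9)[:, None, None, :]
    attns = []
    for layer in params["decoder"]:
        z = _layernorm(h, layer["ln1"])
        ctx, _ = _attention(
            _apply_dense(z, layer["self_q"]),
            _apply_dense(z, layer["self_k"]),
            _apply_dense(z, layer["self_v"]),
            config.n_heads,
            mask_bias=causal,
        )
        h = h + _apply_dense(ctx, layer["self_o"])
        z = _layernorm(h, layer["ln2"])
        ctx, attn = _attention(
            _apply_dense(z, layer["cross_q"]),
            _apply_dense(H, layer["cross_k"]),
            _apply_dense(H, layer["cross_v"]),
            config.n_heads,
            mask_bias=enc_bias,
        )
        h = h + _apply_dense(ctx, layer["cross_o"])
        if return_attention:
            attns.append(attn)
        z = _layernorm(h, layer["ln3"])
        h = h + anp.matmul(_gelu(_apply_dense(z, layer["ff1"])), layer["ff2"]["w"]) + layer["ff2"]["b"]
    logits = _apply_dense(_layernorm(h, params["ln_out"]), params["proj_out"])
    return (logits, attns) if return_attention else (logits, [])


def decode_step(prefix_tokens, H, params, config: ModelConfig, enc_mask=None):
    """Next-token logits and cross-attention maps for a single prefix.

    ``prefix_tokens`` is a 1-D int sequence starting with ``<sos>``. Returns
    ``(logits (V_OUT,), attention maps list of (heads, T, L))``.
    """
    prefix = np.asarray(prefix_tokens)[None]
    H_b = H[None] if H.ndim == 2 else H
    logits, attns = decode_tokens(prefix, H_b, params, config, enc_mask, return_attention=True)
    return logits[0, -1], [a[0] for a in attns]


def first_token_logits(x, params, config: ModelConfig, mask=None):
    """Logits at the first decode position (prefix = <sos>) for batched input."""
    squeeze = x.ndim == 2
    xb = x[None] if squeeze else x
    H = encode(xb, params, config, mask)
    N = xb.shape[0]
    tokens = np.full((N, 1), SOS, dtype=int)
    logits, _ = decode_tokens(tokens, H, params, config, mask)
    out = logits[:, 0, :]
    return out[0] if squeeze else out


def score_pc_nc(x, params, config: ModelConfig, mask=None):
    """S = l_<PC> - l_<NC> at the first decode position (the attribution scalar)."""
    logits = first_token_logits(x, params, config, mask)
    return logits[..., TOK_PC] - logits[..., TOK_NC]


def pointer_forward(H, params, mask=None):
    """Distribution over input positions from a linear projection of encoder states."""
    squeeze = H.ndim == 2
    Hb = H[None] if squeeze else H
    scores = anp.matmul(Hb, params["pointer"]["w"])[..., 0] + params["pointer"]["b"][0]
    if mask is not None:
        scores = scores + (mask - 1.0) * 1e9
    probs = _softmax(scores, axis=-1)
    return probs[0] if squeeze else probs


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def _flatten_tree(tree, prefix=""):
    if isinstance(tree, dict):
        for k, v in tree.items():
            yield from _flatten_tree(v, f"{prefix}{k}/")
    elif isinstance(tree, (list, tuple)):
        for i, v in enumerate(tree):
            yield from _flatten_tree(v, f"{prefix}{i}/")
    else:
        yield prefix[:-1], np.asarray(tree)


def save_checkpoint(path, params, config: ModelConfig, extra: Optional[dict] = None) -> None:
    arrays = dict(_flatten_tree(params))
    meta = {"config": asdict(config), "extra": extra or {}}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def _unflatten(arrays: dict) -> dict:
    root: dict = {}
    for key, val in arrays.items():
        parts = key.split("/")
        node = root
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = val

    def fix(node):
        if isinstance(node, dict) and node and all(k.isdigit() for k in node):
            return [fix(node[str(i)]) for i in range(len(node))]
        if isinstance(node, dict):
            return {k: fix(v) for k, v in node.items()}
        return node

    return fix(root)


def load_checkpoint(path):
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    arrays = {k: data[k] for k in data.files if k != "__meta__"}
    params = _unflatten(arrays)
    config = ModelConfig(**meta["config"])
    return params, config, meta.get("extra", {})
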