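"""Pair-encoding transformer with an MLM head and a phosphosite classifier.

Pre-LayerNorm encoder: learned token, position, and segment embeddings
(segment 0 = peptide span, 1 = kinase span), multi-head self-attention
with additive masking of batch padding, and a GELU feed-forward block.
The MLM head is a linear map to the vocabulary; the classification head
reads *only* the embedding at the peptide-center token and applies one
hidden layer of width ``embed_dim`` followed by a two-way output.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autograd import (
    Tensor,
    embedding,
    gelu,
    layer_norm,
    scaled_dot_attention,
)

NEG_INF = -1e9


@dataclass
class ModelConfig:
    n_layers: int = 6
    n_heads: int = 12
    embed_dim: int = 768
    ffn_dim: int | None = None  # defaults to 4 * embed_dim
    vocab_size: int = 25
    max_len: int = 512
    n_segments: int = 2

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )
        if self.ffn_dim is None:
            self.ffn_dim = 4 * self.embed_dim

    @classmethod
    def tiny(cls) -> "ModelConfig":
        """Desk-scale configuration (2 layers, 4 heads, 64 dims).

        Head width 16 keeps the batched attention matmuls efficient on one
        CPU; fewer heads save time but lose the attention-pattern diversity
        the kinase-motif interaction needs to emerge.
        """
        return cls(n_layers=2, n_heads=4, embed_dim=64, ffn_dim=128, max_len=256)


class TransformerEncoder:
    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        self._build()

    # -- parameters -------------------------------------------------------
    def _param(self, name: str, shape: tuple[int, ...], scale: float | None = None) -> Tensor:
        """Xavier-normal weights by default: std = sqrt(2 / (fan_in + fan_out)).

        Width-aware scaling matters here — a fixed small std starves
        gradient variance at desk-scale widths and the classifier never
        escapes its initial indifference.
        """
        if scale == 0.0:
            data = np.zeros(shape)
        else:
            std = scale if scale is not None else np.sqrt(2.0 / (shape[-2] + shape[-1]))
            data = self.rng.normal(0.0, std, size=shape)
        t = Tensor(data, requires_grad=True)
        self.params[name] = t
        return t

    def _build(self) -> None:
        c = self.config
        d, f = c.embed_dim, c.ffn_dim
        emb_std = 1.0 / np.sqrt(d)
        self._param("tok_emb", (c.vocab_size, d), scale=emb_std)
        self._param("pos_emb", (c.max_len, d), scale=emb_std)
        self._param("seg_emb", (c.n_segments, d), scale=emb_std)
        for i in range(c.n_layers):
            p = f"layer{i}."
            self.params[p + "ln1_g"] = Tensor(np.ones(d), requires_grad=True)
            self.params[p + "ln1_b"] = Tensor(np.zeros(d), requires_grad=True)
            for proj in ("w_q", "w_k", "w_v"):
                self._param(p + proj, (d, d))
            for proj in ("b_q", "b_k", "b_v"):
                self.params[p + proj] = Tensor(np.zeros(d), requires_grad=True)
            self._param(p + "w_o", (d, d))
            self.params[p + "b_o"] = Tensor(np.zeros(d), requires_grad=True)
            self.params[p + "ln2_g"] = Tensor(np.ones(d), requires_grad=True)
            self.params[p + "ln2_b"] = Tensor(np.zeros(d), requires_grad=True)
            self._param(p + "w_ff1", (d, f))
            self.params[p + "b_ff1"] = Tensor(np.zeros(f), requires_grad=True)
            self._param(p + "w_ff2", (f, d))
            self.params[p + "b_ff2"] = Tensor(np.zeros(d), requires_grad=True)
        self.params["lnf_g"] = Tensor(np.ones(d), requires_grad=True)
        self.params["lnf_b"] = Tensor(np.zeros(d), requires_grad=True)
        # the zero-initialized MLM output starts as the uniform predictor
        self._param("mlm_w", (d, c.vocab_size), scale=0.0)
        self.params["mlm_b"] = Tensor(np.zeros(c.vocab_size), requires_grad=True)
        self._param("cls_w1", (d, d))
        self.params["cls_b1"] = Tensor(np.zeros(d), requires_grad=True)
        self._param("cls_w2", (d, 2))
        self.params["cls_b2"] = Tensor(np.zeros(2), requires_grad=True)

    def zero_classifier_head(self) -> None:
        """Zero the classifier output layer: every pair then scores exactly
        p = 0.5 (symmetric logits)."""
        self.params["cls_w2"].data[:] = 0.0
        self.params["cls_b2"].data[:] = 0.0

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- forward ----------------------------------------------------------
    def forward(
        self,
        ids: np.ndarray,
        attend: np.ndarray | None = None,
        segments: np.ndarray | None = None,
        collect_attention: bool = False,
    ) -> tuple[Tensor, list[np.ndarray]]:
        """Encode a padded token batch.

        ``ids``: (B, T) int64; ``attend``: (B, T) bool, False on batch
        padding; ``segments``: (B, T) int64. Returns the final hidden
        states (B, T, embed_dim) and, when requested, the per-layer
        attention weights as numpy arrays of shape (B, heads, T, T).
        """
        c = self.config
        ids = np.atleast_2d(np.asarray(ids, dtype=np.int64))
        B, T = ids.shape
        if T > c.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {c.max_len}")
        if ids.max() >= c.vocab_size or ids.min() < 0:
            raise ValueError("token id outside vocabulary")
        if attend is None:
            attend = np.ones((B, T), dtype=bool)
        if segments is None:
            segments = np.zeros((B, T), dtype=np.int64)
        segments = np.atleast_2d(segments)
        attend = np.atleast_2d(attend)

        x = (
            embedding(self.params["tok_emb"], ids)
            + embedding(self.params["pos_emb"], np.arange(T))  # (T,d), broadcast over batch
            + embedding(self.params["seg_emb"], segments)
        )
        bias = np.where(attend, 0.0, NEG_INF)[:, None, None, :]  # (B,1,1,T)
        H, dh = c.n_heads, c.embed_dim // c.n_heads
        attentions: list[np.ndarray] = []
        for i in range(c.n_layers):
            p = f"layer{i}."
            h = layer_norm(x, self.params[p + "ln1_g"], self.params[p + "ln1_b"])
            q = (h @ self.params[p + "w_q"] + self.params[p + "b_q"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            k = (h @ self.params[p + "w_k"] + self.params[p + "b_k"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            v = (h @ self.params[p + "w_v"] + self.params[p + "b_v"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
            ctx, attn = scaled_dot_attention(q, k, v, bias, 1.0 / np.sqrt(dh))
            if collect_attention:
                attentions.append(attn.copy())
            ctx = ctx.transpose(0, 2, 1, 3).reshape(B, T, c.embed_dim)
            x = x + (ctx @ self.params[p + "w_o"] + self.params[p + "b_o"])
            h2 = layer_norm(x, self.params[p + "ln2_g"], self.params[p + "ln2_b"])
            ff = gelu(h2 @ self.params[p + "w_ff1"] + self.params[p + "b_ff1"])
            x = x + (ff @ self.params[p + "w_ff2"] + self.params[p + "b_ff2"])
        x = layer_norm(x, self.params["lnf_g"], self.params["lnf_b"])
        return x, attentions

    def mlm_logits(self, hidden: Tensor) -> Tensor:
        return hidden @ self.params["mlm_w"] + self.params["mlm_b"]

    def classifier_logits(self, hidden: Tensor, center_index: int) -> Tensor:
        """Two-way logits from the center-token embedding only."""
        center = hidden[:, center_index, :]  # (B, d)
        h = gelu(center @ self.params["cls_w1"] + self.params["cls_b1"])
        return h @ self.params["cls_w2"] + self.params["cls_b2"]

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        from .autograd import DTYPE

        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=DTYPE).copy()

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "params.npz", **self.state_dict())
        (directory / "model_config.json").write_text(json.dumps(asdict(self.config), indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "TransformerEncoder":
        directory = Path(directory)
        cfg = ModelConfig(**json.loads((directory / "model_config.json").read_text()))
        model = cls(cfg, seed=0)
        with np.load(directory / "params.npz") as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model
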