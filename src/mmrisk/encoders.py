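"""Per-modality token encoders (the unimodal branch).

Each of the four channels — lab panel, aligned monitoring series,
waveform embeddings, text embeddings — is mapped into the shared working
dimension ``D`` by a learnable linear projection, refined by its own
single-layer transformer encoder (no parameter sharing between
modalities), and reduced to one summary vector by mean pooling over
non-padding tokens.  Tokenization: the lab vector becomes a single token
(optionally split into fixed-size groups), the aligned series one token
per grid step (with learned positional embeddings), and the external
waveform/text embedding matrices one token per row.

Absent modalities flow through with a per-sample ``present`` flag; their
summaries are forced to the zero vector and the fusion module masks them
out entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor
from .nn import Linear, Module, Parameter, TransformerEncoderLayer

__all__ = ["ModalityTokens", "ModalityEncoder", "EmbeddingProvider"]


@dataclass
class ModalityTokens:
    """A batch of token sequences for one modality.

    ``tokens`` is (B, T, D); ``pad_keep`` marks real (non-padding) token
    positions; ``present`` marks which samples actually have the modality.
    """

    modality: str
    tokens: Tensor
    pad_keep: np.ndarray
    present: np.ndarray

    def __post_init__(self):
        self.pad_keep = np.asarray(self.pad_keep, dtype=bool)
        self.present = np.asarray(self.present, dtype=bool)
        b, t, _ = self.tokens.shape
        if self.pad_keep.shape != (b, t):
            raise ValueError("pad_keep shape mismatch")
        if self.present.shape != (b,):
            raise ValueError("present shape mismatch")


class EmbeddingProvider:
    """Contract for external precomputed token embeddings.

    Stands in for a frozen waveform or text foundation-model encoder: for
    a patient id, return a dense (tokens, dim) matrix, or ``None`` when
    the modality is absent for that patient.
    """

    def __init__(self, modality: str, dim_out: int, matrices: dict[str, np.ndarray]):
        self.modality = modality
        self.dim_out = dim_out
        self._matrices = matrices

    def __call__(self, patient_id: str) -> np.ndarray | None:
        mat = self._matrices.get(patient_id)
        if mat is not None and mat.shape[1] != self.dim_out:
            raise ValueError(f"{self.modality} embedding dim != {self.dim_out}")
        return mat


class ModalityEncoder(Module):
    """Projection + single-layer transformer + mean-pool summary for one modality."""

    def __init__(
        self,
        modality: str,
        input_dim: int,
        dim: int,
        n_heads: int,
        rng: np.random.Generator,
        max_len: int = 1,
        use_positional: bool = False,
        lab_group_size: int | None = None,
        dropout: float = 0.1,
    ):
        self.modality = modality
        self.input_dim = input_dim
        self.dim = dim
        self.lab_group_size = lab_group_size
        if lab_group_size is not None:
            if input_dim % lab_group_size:
                raise ValueError("lab_group_size must divide the feature count")
            proj_in = lab_group_size
            max_len = input_dim // lab_group_size
        else:
            proj_in = input_dim
        self.proj = Linear(proj_in, dim, rng)
        self.use_positional = use_positional
        self.pos = Parameter(0.02 * rng.normal(size=(max_len, dim))) if use_positional else None
        self.encoder = TransformerEncoderLayer(dim, n_heads, rng, dropout=dropout)

    def project(self, features, present: np.ndarray) -> ModalityTokens:
        """Map raw per-sample features to (B, T, D) tokens.

        2-D input (B, F) is treated as one token per sample (or one per
        feature group when ``lab_group_size`` is set); 3-D input (B, T, F)
        as one token per step/row.
        """
        x = as_tensor(features)
        if x.ndim == 2:
            b, f = x.shape
            if f != self.input_dim:
                raise ValueError(f"{self.modality}: expected {self.input_dim} features, got {f}")
            if self.lab_group_size is not None:
                x = x.reshape(b, f // self.lab_group_size, self.lab_group_size)
            else:
                x = x.reshape(b, 1, f)
        elif x.ndim == 3:
            if x.shape[-1] != self.input_dim:
                raise ValueError(
                    f"{self.modality}: expected {self.input_dim}-dim steps, got {x.shape[-1]}"
                )
        else:
            raise ValueError("features must be 2-D or 3-D")
        tokens = self.proj(x)
        if self.use_positional:
            t = tokens.shape[1]
            if t > self.pos.shape[0]:
                raise ValueError("sequence longer than positional table")
            pos = _slice_rows(self.pos, t)
            tokens = tokens + pos
        b, t, _ = tokens.shape
        return ModalityTokens(
            self.modality, tokens, np.ones((b, t), dtype=bool), np.asarray(present, bool)
        )

    def encode(
        self, tokens: ModalityTokens, rng: np.random.Generator | None = None
    ) -> ModalityTokens:
        """Single-layer masked self-attention refinement within the modality."""
        if not tokens.present.any():
            raise ValueError(f"encode called on absent modality {self.modality!r}")
        out = self.encoder(tokens.tokens, pad_keep=tokens.pad_keep, rng=rng)
        return ModalityTokens(tokens.modality, out, tokens.pad_keep, tokens.present)

    def summarize(self, tokens: ModalityTokens) -> Tensor:
        """Mean over non-padding tokens; exact zero vector for absent samples."""
        return summarize(tokens)


def summarize(tokens: ModalityTokens) -> Tensor:
    keep = tokens.pad_keep[:, :, None].astype(float)
    counts = np.maximum(keep.sum(axis=1), 1.0)
    pooled = (tokens.tokens * keep).sum(axis=1) * (1.0 / counts)
    return pooled * tokens.present[:, None].astype(float)


def _slice_rows(param: Parameter, t: int) -> Tensor:
    """First ``t`` rows of a (max_len, D) table, differentiable."""
    out = Tensor(param.data[:t])

    def backward(g):
        full = np.zeros_like(param.data)
        full[:t] = g
        param._accum(full)

    if param.requires_grad:
        out.requires_grad = True
        out._parents = (param,)
        out._backward = backward
    return out
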