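"""Masked-attention latent fusion and the end-to-end risk classifier.

The model has a dual-branch layout:

* **Unimodal branch** — each present modality is projected and refined by
  its own single-layer transformer encoder
  (:class:`~mmrisk.encoders.ModalityEncoder`) and reduced to a summary
  vector.
* **Fusion branch** — a learnable latent token matrix ``H ∈ R^{L×D}`` is
  expanded over the batch and updated once per modality, in the fixed
  order (lab, time, ecg, note), by masked multi-head cross-attention with
  a gated residual:

  ``H <- MHCA(H, K_m, V_m, M) ⊙ M_u + H``

  where ``M`` blocks attention to padding/absent keys and the binary
  update gate ``M_u`` zeroes the whole update for samples missing the
  modality, so their latent state passes through bit-for-bit unchanged.

The four modality summaries plus the pooled latent summary are fused by
attention pooling: a learnable scoring layer produces one score per
source, a masked softmax normalizes over *present* sources only (absent
sources get weight exactly 0), and the fused vector is the weighted sum.
A small feed-forward head maps it to the event probability.

Missing-modality exactness is structural, not approximate: an absent
modality's raw features can be perturbed arbitrarily without changing
the output, because the update gate and the pooling mask multiply every
path out of that modality by exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .autodiff import Tensor, as_tensor, concat, masked_softmax
from .encoders import ModalityEncoder, ModalityTokens, summarize
from .nn import Dropout, LayerNorm, Linear, Module, MultiHeadAttention, Parameter
from .types import MODALITIES, MultimodalRecord

__all__ = [
    "ModelConfig",
    "LatentState",
    "AttentionMask",
    "FusionOutput",
    "masked_self_attention",
    "masked_cross_attention",
    "update_latent",
    "attention_pool",
    "LatentFusionClassifier",
    "collate",
]

BLOCKED = -1e9  # additive-mask value for a blocked position
POOL_SOURCES = MODALITIES + ("fusion",)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults mirror the full-scale configuration (working dimension 768,
    256 latent tokens, 8 heads); :meth:`small` gives the reduced
    configuration used throughout the tests and the desk-scale
    experiments (D=32, L=8).
    """

    dim: int = 768
    n_heads: int = 8
    latent_len: int = 256
    dropout: float = 0.1
    lab_dim: int = 20
    series_dim: int = 5
    n_grid: int = 12
    ecg_dim: int = 16
    note_dim: int = 16
    lab_group_size: int | None = None
    modality_order: tuple[str, ...] = MODALITIES
    seed: int = 0

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        base = dict(dim=32, latent_len=8)
        base.update(overrides)
        return cls(**base)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["modality_order"] = tuple(raw.get("modality_order", MODALITIES))
        return cls(**raw)


@dataclass
class LatentState:
    """The fused latent representation, (B, L, D) after batch expansion."""

    tokens: Tensor

    @property
    def shape(self):
        return self.tokens.shape


@dataclass
class AttentionMask:
    """Key-level additive mask plus the per-sample update gate.

    ``additive_mask`` is (B, T_k): 0 = attend, a large negative = blocked.
    ``update_gate`` is (B,) binary; it is broadcast over (L, D) so a
    sample's whole latent update is either kept or zeroed.
    """

    additive_mask: np.ndarray
    update_gate: np.ndarray

    @classmethod
    def for_modality(cls, tokens: ModalityTokens) -> "AttentionMask":
        keep = tokens.pad_keep & tokens.present[:, None]
        additive = np.where(keep, 0.0, BLOCKED)
        return cls(additive, tokens.present.astype(float))


@dataclass
class FusionOutput:
    fused_vector: np.ndarray
    attention_weights: dict[str, np.ndarray]
    probability: np.ndarray


def masked_self_attention(
    attn: MultiHeadAttention,
    x: Tensor,
    additive_mask: np.ndarray | None = None,
    return_weights: bool = False,
):
    """Within-modality interaction: scaled dot-product self-attention.

    ``additive_mask`` follows the 0 / -1e9 convention over key positions;
    blocked keys receive attention weight exactly 0.
    """
    keep = None if additive_mask is None else np.asarray(additive_mask) > BLOCKED / 2
    return attn(x, x, x, key_keep=keep, return_weights=return_weights)


def masked_cross_attention(
    attn: MultiHeadAttention,
    latent: Tensor,
    keys: Tensor,
    additive_mask: np.ndarray | None = None,
    return_weights: bool = False,
):
    """Latent queries attend to one modality's keys/values.

    A sample whose keys are all blocked contributes a zero update row
    (softmax over the empty set is defined as the zero vector).
    """
    keep = None if additive_mask is None else np.asarray(additive_mask) > BLOCKED / 2
    return attn(latent, keys, keys, key_keep=keep, return_weights=return_weights)


def update_latent(
    attn: MultiHeadAttention,
    state: LatentState,
    modality_tokens: ModalityTokens,
    mask: AttentionMask,
) -> LatentState:
    """One gated residual latent update from one modality."""
    b = state.tokens.shape[0]
    gate = np.asarray(mask.update_gate, dtype=float)
    if gate.shape != (b,):
        raise ValueError("update gate must be one binary entry per sample")
    update = masked_cross_attention(attn, state.tokens, modality_tokens.tokens,
                                    additive_mask=mask.additive_mask)
    gated = update * gate[:, None, None]
    return LatentState(gated + state.tokens)


def attention_pool(
    summaries: list[tuple[str, Tensor, np.ndarray]],
    score_layer: Linear,
    dropout: Dropout | None = None,
    rng: np.random.Generator | None = None,
):
    """Masked softmax fusion over per-source summary vectors.

    ``summaries`` holds (source, (B, D) vector, (B,) present) triples.
    Present sources are scored by the learnable linear layer and softmaxed
    (absent sources are excluded before normalization and reported with
    weight exactly 0); dropout, when given an RNG, regularizes the
    normalized weights during training.  Returns the weighted-sum fused
    vector and the weight tensor in source order.
    """
    present = np.stack([p for _, _, p in summaries], axis=1)
    if not present.any(axis=1).all():
        raise ValueError("at least one source must be present for every sample")
    scores = concat([score_layer(v) for _, v, _ in summaries], axis=1)  # (B, S)
    weights = masked_softmax(scores, present, axis=1)
    if dropout is not None and rng is not None:
        weights = dropout(weights, rng)
    stacked = concat([v.reshape(v.shape[0], 1, v.shape[1]) for _, v, _ in summaries], axis=1)
    fused = (stacked * weights.reshape(*weights.shape, 1)).sum(axis=1)
    return fused, weights


def collate(records: list[MultimodalRecord]) -> dict:
    """Stack preprocessed records into dense per-modality batches.

    Absent-modality features are passed through as given (zeros when the
    record stores none); presence flags carry the masking semantics.
    """
    b = len(records)
    first = records[0]
    if first.aligned_series is None:
        raise ValueError("records must be preprocessed (aligned_series missing)")
    out = {
        "lab": np.stack([
            r.lab if r.lab is not None else np.zeros_like(first.lab) for r in records
        ]),
        "time": np.stack([r.aligned_series for r in records]),
        "ecg": np.stack([
            r.ecg_emb if r.ecg_emb is not None else np.zeros_like(first.ecg_emb)
            for r in records
        ]),
        "note": np.stack([
            r.note_emb if r.note_emb is not None else np.zeros_like(first.note_emb)
            for r in records
        ]),
        "present": {
            m: np.array([r.present.get(m, False) for r in records], dtype=bool)
            for m in MODALITIES
        },
        "labels": np.array([r.label for r in records], dtype=float),
        "patient_ids": [r.patient_id for r in records],
    }
    for key in ("lab", "time", "ecg", "note"):
        if not np.all(np.isfinite(out[key])):
            raise ValueError(f"non-finite values in {key} batch; preprocess first")
    return out


class LatentFusionClassifier(Module):
    """End-to-end multimodal risk classifier with masked latent fusion."""

    def __init__(self, config: ModelConfig):
        if config.dim % config.n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, h = config.dim, config.n_heads
        self.encoders = {
            "lab": ModalityEncoder("lab", config.lab_dim, d, h, rng,
                                   lab_group_size=config.lab_group_size,
                                   dropout=config.dropout),
            "time": ModalityEncoder("time", config.series_dim, d, h, rng,
                                    max_len=config.n_grid, use_positional=True,
                                    dropout=config.dropout),
            "ecg": ModalityEncoder("ecg", config.ecg_dim, d, h, rng,
                                   dropout=config.dropout),
            "note": ModalityEncoder("note", config.note_dim, d, h, rng,
                                    dropout=config.dropout),
        }
        # attribute scan needs Module-typed attributes for parameter discovery
        self.enc_lab = self.encoders["lab"]
        self.enc_time = self.encoders["time"]
        self.enc_ecg = self.encoders["ecg"]
        self.enc_note = self.encoders["note"]
        self.latent = Parameter(0.02 * rng.normal(size=(config.latent_len, d)))
        self.cross_attn = MultiHeadAttention(d, h, rng)
        self.score_layer = Linear(d, 1, rng)
        self.head_norm = LayerNorm(d)
        self.head1 = Linear(d, d, rng)
        self.head2 = Linear(d, 1, rng)
        self.drop = Dropout(config.dropout)

    # -- forward --------------------------------------------------------------
    def forward(
        self,
        batch: dict,
        rng: np.random.Generator | None = None,
        return_details: bool = False,
    ):
        """Compute event probabilities for a collated batch.

        ``rng`` enables dropout (training mode); without it the forward
        pass is deterministic.  With ``return_details`` the per-source
        pooling weights and the final latent state are also returned.
        """
        b = len(batch["labels"])
        encoded: dict[str, ModalityTokens] = {}
        summaries: list[tuple[str, Tensor, np.ndarray]] = []
        for m in self.config.modality_order:
            enc = self.encoders[m]
            tokens = enc.project(batch[m], batch["present"][m])
            tokens = ModalityTokens(m, self.drop(tokens.tokens, rng),
                                    tokens.pad_keep, tokens.present)
            if tokens.present.any():
                tokens = enc.encode(tokens, rng=rng)
            encoded[m] = tokens
            summaries.append((m, summarize(tokens), tokens.present))

        state = LatentState(_expand_latent(self.latent, b))
        for m in self.config.modality_order:
            tokens = encoded[m]
            state = update_latent(self.cross_attn, state, tokens,
                                  AttentionMask.for_modality(tokens))

        fusion_summary = state.tokens.mean(axis=1)
        summaries.append(("fusion", fusion_summary, np.ones(b, dtype=bool)))

        fused, weights = attention_pool(summaries, self.score_layer,
                                        dropout=self.drop, rng=rng)
        h = self.drop(self.head1(self.head_norm(fused)).gelu(), rng)
        probs = self.head2(h).reshape(b).sigmoid()
        if return_details:
            return probs, FusionOutput(
                fused_vector=fused.data,
                attention_weights={s: weights.data[:, i]
                                   for i, s in enumerate(POOL_SOURCES)},
                probability=probs.data,
            ), state
        return probs

    def predict_proba(
        self, records: list[MultimodalRecord], batch_size: int = 64
    ) -> np.ndarray:
        out = []
        for i in range(0, len(records), batch_size):
            probs = self.forward(collate(records[i:i + batch_size]))
            out.append(probs.data)
        return np.concatenate(out) if out else np.empty(0)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        np.savez(path, *[p.data for p in self.parameters()])

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict([data[k] for k in data.files])


def _expand_latent(latent: Parameter, batch: int) -> Tensor:
    """Broadcast the (L, D) learnable latent over the batch, differentiably."""
    l, d = latent.shape
    out = Tensor(np.broadcast_to(latent.data, (batch, l, d)).copy())
    if latent.requires_grad:
        out.requires_grad = True
        out._parents = (latent,)
        out._backward = lambda g: latent._accum(g.sum(axis=0))
    return out
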