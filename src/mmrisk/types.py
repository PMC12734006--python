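"""Shared domain containers for multimodal patient records."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The four input channels, in the fixed order used by the fusion loop.
MODALITIES = ("lab", "time", "ecg", "note")


@dataclass
class RawSeries:
    """One irregularly sampled monitoring variable for one patient.

    ``points`` is an ordered list of ``(timestamp_hours, value)`` pairs with
    strictly increasing timestamps; a value of NaN marks a missing
    measurement at an observed time point.
    """

    variable_id: str
    points: list[tuple[float, float]]

    def __post_init__(self):
        times = [t for t, _ in self.points]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"timestamps not strictly increasing in {self.variable_id}")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.points], dtype=float)


@dataclass
class MultimodalRecord:
    """One patient's multimodal bundle.

    ``series`` holds the raw irregular monitoring series; preprocessing
    fills ``aligned_series`` with a (grid_steps, n_variables) matrix on the
    uniform per-variable time grid.  ``ecg_emb`` / ``note_emb`` are token
    matrices from the (frozen, external) waveform and text encoders.
    ``present`` flags which of the four modalities exist for this patient;
    raw features may still be populated for an absent modality but carry no
    influence on the model output.
    """

    patient_id: str
    lab: np.ndarray | None
    series: list[RawSeries]
    ecg_emb: np.ndarray | None
    note_emb: np.ndarray | None
    present: dict[str, bool]
    label: int
    aligned_series: np.ndarray | None = None
    latent_risk: float | None = None  # generator ground truth, for diagnostics
    risk_components: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.present) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities in presence flags: {unknown}")
        if not any(self.present.get(m, False) for m in MODALITIES):
            raise ValueError(f"record {self.patient_id} has no present modality")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
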