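"""Synthetic multimodal cohorts with a known outcome-generating mechanism.

The generator emulates the structure of a post-procedural mortality
cohort: rare outcomes (~4-5% prevalence), a static laboratory panel with
scattered missing values, asynchronous multi-rate ICU monitoring series,
and waveform/text channels available only as dense embedding matrices.
Patients can lack whole modalities (e.g. no ICU stay means no monitoring
series), independently of outcome by default (MCAR) or linked to the
latent risk when ``mnar=True``.

Outcome model
-------------
Each patient draws one independent standard-normal factor per modality,
``z_m``.  The latent risk score is the linear combination
``r = sum_m beta_m * z_m`` with the configured effect sizes, and the label
is Bernoulli with ``P(y=1) = sigmoid(b0 + r)``, where the intercept
``b0`` is solved numerically so the population prevalence matches the
spec.  Each modality's observable features are noisy linear functions of
its own factor, so recovering the risk requires integrating information
across modalities:

* lab feature ``j`` = ``w_j * beta_lab * z_lab + N(0,1)`` with loadings
  ``w = (1.0, 0.4, 0.2, 0, ...)`` — lab feature 0 is the strongest single
  input feature (the "planted" signal used by attribution tests), with a
  loading gap wide enough that no sibling readout of the same factor
  rivals it;
* monitoring variable ``v`` observations = ``w_v * beta_time * z_time``
  plus a circadian drift and observation noise, sampled at a
  patient-specific Poisson rate;
* waveform/text embeddings = ``beta_m * z_m`` times a fixed random
  direction matrix plus token-level Gaussian noise (surrogates for frozen
  foundation-model encoders).

The direction matrices and loadings are structural: they are drawn from
``structure_seed`` and shared by every cohort so that a model trained on
one cohort transfers to fresh cohorts drawn with different patient seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .types import MODALITIES, MultimodalRecord, RawSeries

__all__ = ["CohortSpec", "generate_cohort", "generate_irregular_series", "LAB_LOADINGS"]

#: Within-modality feature loadings (head of the vector; remainder is 0).
LAB_LOADINGS = (1.0, 0.4, 0.2)
SERIES_LOADINGS = (1.0, 0.4, 0.2)
EMB_ROW_NORM = 2.0  # L2 norm of each embedding direction row


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 800
    prevalence: float = 0.042
    n_lab_features: int = 20
    n_series_variables: int = 5
    series_rate_range: tuple[float, float] = (0.25, 2.0)  # observations per hour
    series_duration_hours: float = 48.0
    lab_missing_rate: float = 0.10
    series_missing_rate: float = 0.10
    modality_missing_probs: dict[str, float] = field(
        default_factory=lambda: {"lab": 0.0, "time": 0.30, "ecg": 0.10, "note": 0.10}
    )
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"lab": 3.0, "time": 2.5, "ecg": 2.5, "note": 2.0}
    )
    ecg_tokens: int = 4
    ecg_dim: int = 16
    note_tokens: int = 4
    note_dim: int = 16
    mnar: bool = False
    seed: int = 2025
    structure_seed: int = 7

    def validate(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        for name in ("n_patients", "n_lab_features", "n_series_variables",
                     "ecg_tokens", "ecg_dim", "note_tokens", "note_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.series_rate_range
        if not 0.0 < lo <= hi:
            raise ValueError("series_rate_range must be a positive interval")
        if self.series_duration_hours <= 0:
            raise ValueError("series_duration_hours must be positive")
        for name in ("lab_missing_rate", "series_missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if set(self.modality_missing_probs) != set(MODALITIES):
            raise ValueError(f"modality_missing_probs must cover exactly {MODALITIES}")
        for m, p in self.modality_missing_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"modality_missing_probs[{m}] must lie in [0, 1]")
        if all(p >= 1.0 for p in self.modality_missing_probs.values()):
            raise ValueError("every modality always missing: no usable records possible")
        missing = set(MODALITIES) - set(self.effect_sizes)
        if missing:
            raise ValueError(f"effect_sizes missing modalities: {missing}")


def _solve_intercept(prevalence: float, risk_sd: float) -> float:
    """Intercept b0 with E[sigmoid(b0 + risk_sd * Z)] = prevalence, Z ~ N(0,1)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    weights = weights / weights.sum()

    def mean_prev(b0: float) -> float:
        return float(np.sum(weights * expit(b0 + risk_sd * nodes)) - prevalence)

    return brentq(mean_prev, -40.0, 40.0, xtol=1e-12)


def _loadings(head: tuple[float, ...], n: int) -> np.ndarray:
    w = np.zeros(n)
    k = min(len(head), n)
    w[:k] = head[:k]
    return w


def generate_irregular_series(
    rate_range: tuple[float, float],
    duration: float,
    missing_rate: float,
    seed: int | np.random.Generator,
    variable_id: str = "var",
    level: float = 0.0,
) -> RawSeries:
    """Sample one irregular monitoring series from a homogeneous point process.

    The observation rate is drawn uniformly from ``rate_range`` (per hour);
    observation count is Poisson with mean ``rate * duration`` (floored at
    two points so the series is usable downstream); values are ``level``
    plus a circadian drift and unit-variance noise; a ``missing_rate``
    fraction of values is replaced by NaN.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = rng.uniform(*rate_range)
    n_obs = max(2, int(rng.poisson(rate * duration)))
    times = np.sort(rng.uniform(0.0, duration, size=n_obs))
    # enforce strict monotonicity against (measure-zero) duplicate draws
    for i in range(1, n_obs):
        if times[i] <= times[i - 1]:
            times[i] = np.nextafter(times[i - 1], np.inf)
    values = level + 0.3 * np.sin(2.0 * np.pi * times / 24.0) + rng.normal(0.0, 1.0, n_obs)
    if missing_rate > 0:
        values = np.where(rng.random(n_obs) < missing_rate, np.nan, values)
    return RawSeries(variable_id, list(zip(times.tolist(), values.tolist())))


def generate_cohort(spec: CohortSpec) -> list[MultimodalRecord]:
    """Generate a deterministic multimodal cohort from ``spec``.

    Returns one :class:`MultimodalRecord` per patient.  Records carry the
    ground-truth ``latent_risk`` so downstream tests can compare learned
    scores against the generating mechanism.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    struct = np.random.default_rng(spec.structure_seed)

    beta = {m: float(spec.effect_sizes[m]) for m in MODALITIES}
    risk_sd = float(np.sqrt(sum(b * b for b in beta.values())))
    b0 = _solve_intercept(spec.prevalence, risk_sd) if risk_sd > 0 else float(
        np.log(spec.prevalence / (1.0 - spec.prevalence))
    )

    w_lab = _loadings(LAB_LOADINGS, spec.n_lab_features)
    w_series = _loadings(SERIES_LOADINGS, spec.n_series_variables)
    # fixed embedding directions: surrogate for frozen external encoders.
    # Rows are normalized to a fixed moderate norm so the signal is diffuse
    # across coordinates, as in real foundation-model embeddings — no single
    # coordinate rivals the planted lab signal — while each coordinate keeps
    # enough signal-to-noise for the channel to be learnable.
    a_ecg = struct.normal(size=(spec.ecg_tokens, spec.ecg_dim))
    a_ecg *= EMB_ROW_NORM / np.linalg.norm(a_ecg, axis=1, keepdims=True)
    a_note = struct.normal(size=(spec.note_tokens, spec.note_dim))
    a_note *= EMB_ROW_NORM / np.linalg.norm(a_note, axis=1, keepdims=True)

    records: list[MultimodalRecord] = []
    for i in range(spec.n_patients):
        z = {m: float(rng.normal()) for m in MODALITIES}
        risk = sum(beta[m] * z[m] for m in MODALITIES)
        label = int(rng.random() < expit(b0 + risk))

        lab = w_lab * beta["lab"] * z["lab"] + rng.normal(size=spec.n_lab_features)
        if spec.lab_missing_rate > 0:
            lab = np.where(rng.random(spec.n_lab_features) < spec.lab_missing_rate,
                           np.nan, lab)

        series = [
            generate_irregular_series(
                spec.series_rate_range,
                spec.series_duration_hours,
                spec.series_missing_rate,
                rng,
                variable_id=f"v{v}",
                level=w_series[v] * beta["time"] * z["time"],
            )
            for v in range(spec.n_series_variables)
        ]

        ecg = beta["ecg"] * z["ecg"] * a_ecg + rng.normal(
            size=(spec.ecg_tokens, spec.ecg_dim))
        note = beta["note"] * z["note"] * a_note + rng.normal(
            size=(spec.note_tokens, spec.note_dim))

        present = _draw_presence(spec, rng, risk)

        records.append(
            MultimodalRecord(
                patient_id=f"p{i:05d}",
                lab=lab,
                series=series,
                ecg_emb=ecg,
                note_emb=note,
                present=present,
                label=label,
                latent_risk=risk,
                risk_components=z,
            )
        )
    return records


def _draw_presence(
    spec: CohortSpec, rng: np.random.Generator, risk: float
) -> dict[str, bool]:
    probs = dict(spec.modality_missing_probs)
    if spec.mnar:
        # risk-linked missingness: sicker patients more often lack a channel
        for m in probs:
            if 0.0 < probs[m] < 1.0:
                logit = np.log(probs[m] / (1.0 - probs[m]))
                probs[m] = float(expit(logit + 0.5 * risk))
    while True:
        present = {m: bool(rng.random() >= probs[m]) for m in MODALITIES}
        if any(present.values()):
            return present
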