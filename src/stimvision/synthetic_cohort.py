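"""Synthetic aperture traces, patient sessions, and planted-structure cohorts.

Every downstream module is testable without any recorded data: this module
generates (i) quasi-periodic open-close aperture signals with controllable
amplitude, frequency, per-cycle decrement, cycle-to-cycle variability and
additive noise, (ii) whole patient sessions (off-baseline plus candidate
stimulation programs with per-program effect profiles and one designated best
program that dominates every oriented feature), (iii) improvement matrices
with planted low-rank sparse domain structure, and (iv) clinician-concordance
datasets with a planted mixed-model slope.

All generators are pure functions of their spec and seed: identical inputs
give identical outputs.

Signal model.  A trace is a concatenation of raised-cosine open-close cycles.
Cycle k (of K) has amplitude ``A0 * (1 + d_A/100 * (k - (K-1)/2))`` and rate
``f0 * (1 + d_f/100 * (k - (K-1)/2))`` — decrements are linear in cycle index
and *centred on the mean*, so ``A0``/``f0`` are the per-trace means and the
planted percent-per-cycle decrements coincide exactly with the extracted
decay slopes (which are expressed as percent of the per-trace mean per
cycle).  Cycle periods get multiplicative Gaussian jitter; white Gaussian
noise is added per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .signal_features import ApertureTrace

__all__ = [
    "TraceSpec",
    "ProgramEffect",
    "SessionSpec",
    "PlantedDomainSpec",
    "generate_aperture_trace",
    "generate_patient_session",
    "default_session_spec",
    "generate_domain_structured_cohort",
    "generate_concordance_dataset",
]


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of one synthetic aperture trace.

    Defaults emulate a moderately bradykinetic medication-off recording:
    ~1.2 Hz open-close at 0.5 normalized aperture with a 3%/cycle amplitude
    decrement, mild cycle-timing jitter, 10-12 s duration, 60 Hz sampling.
    """

    base_amplitude: float = 0.5
    base_frequency: float = 1.2  # Hz
    amplitude_decay: float = -3.0  # percent of mean amplitude per cycle
    frequency_decay: float = -2.0  # percent of mean rate per cycle
    cycle_jitter_cv: float = 0.02
    noise_sd: float = 0.005
    duration: float = 12.0  # s
    sampling_rate: float = 60.0
    baseline_offset: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_jitter_cv < 0 or self.noise_sd < 0:
            raise ValueError("jitter and noise must be non-negative")
        if self.duration * self.base_frequency < 2:
            raise ValueError("spec must allow at least 2 cycles")


def generate_aperture_trace(
    spec: TraceSpec,
    patient_id: str = "",
    hand: str = "right",
    condition: str = "",
) -> ApertureTrace:
    """Render a quasi-sinusoidal open-close trace from a spec.

    Raises
    ------
    ValueError
        If the decay parameters produce a non-positive amplitude or rate for
        any cycle within the requested duration.
    """
    rng = np.random.default_rng(spec.seed)
    n_cycles = max(2, int(round(spec.duration * spec.base_frequency)))
    centred = np.arange(n_cycles) - (n_cycles - 1) / 2.0
    amplitudes = spec.base_amplitude * (1.0 + spec.amplitude_decay / 100.0 * centred)
    rates = spec.base_frequency * (1.0 + spec.frequency_decay / 100.0 * centred)
    if np.any(amplitudes <= 0) or np.any(rates <= 0):
        raise ValueError("decay parameters produce non-positive amplitude or rate")
    jitter = rng.normal(1.0, spec.cycle_jitter_cv, size=n_cycles)
    jitter = np.clip(jitter, 0.5, 1.5)
    periods = jitter / rates
    # cycles exactly fill the requested duration (no flat tail after the last
    # cycle); a common period rescaling leaves the planted %-per-cycle decay
    # and the jitter CV unchanged
    periods *= spec.duration / periods.sum()

    fs = spec.sampling_rate
    n_samples = int(round(spec.duration * fs))
    t = np.arange(n_samples) / fs
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    samples = np.full(n_samples, spec.baseline_offset)
    for k in range(n_cycles):
        in_cycle = (t >= boundaries[k]) & (t < boundaries[k + 1])
        phase = (t[in_cycle] - boundaries[k]) / periods[k]
        samples[in_cycle] = spec.baseline_offset + amplitudes[k] * 0.5 * (
            1.0 - np.cos(2.0 * np.pi * phase)
        )
    if spec.noise_sd > 0:
        samples = samples + rng.normal(0.0, spec.noise_sd, size=n_samples)
    return ApertureTrace(
        samples=samples,
        sampling_rate=fs,
        patient_id=patient_id,
        hand=hand,
        condition=condition,
    )


@dataclass(frozen=True)
class ProgramEffect:
    """Multiplicative effect of a stimulation program on the trace spec.

    Gains > 1 raise amplitude/frequency; factors < 1 shrink decrement
    magnitude and timing jitter.  A program that raises amplitude and
    frequency while shrinking decay and jitter improves every oriented
    feature family at once.
    """

    amplitude_gain: float = 1.0
    frequency_gain: float = 1.0
    decay_factor: float = 1.0
    jitter_factor: float = 1.0

    def apply(self, base: TraceSpec, seed: int) -> TraceSpec:
        return replace(
            base,
            base_amplitude=base.base_amplitude * self.amplitude_gain,
            base_frequency=base.base_frequency * self.frequency_gain,
            amplitude_decay=base.amplitude_decay * self.decay_factor,
            frequency_decay=base.frequency_decay * self.decay_factor,
            cycle_jitter_cv=base.cycle_jitter_cv * self.jitter_factor,
            seed=seed,
        )


@dataclass(frozen=True)
class SessionSpec:
    """One patient-hand session: off-baseline plus candidate programs."""

    base: TraceSpec
    effects: tuple[ProgramEffect, ...]
    best_program: int  # index into effects
    patient_id: str = "P00"
    hand: str = "right"
    baseline_label: str = "OFF"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.best_program < len(self.effects)):
            raise ValueError("best_program index out of range")


def default_session_spec(
    seed: int = 0,
    n_programs: int = 10,
    patient_id: str = "P00",
    noise_sd: float = 0.005,
) -> SessionSpec:
    """A session whose designated best program dominates every feature.

    Program effects are drawn once per session seed: the best program gets
    +40% amplitude, +30% frequency and decay/jitter halved; the others get
    independent gains drawn below the best program's on every axis (some
    slightly worse than baseline), so oriented improvement of the best
    program strictly dominates.
    """
    rng = np.random.default_rng(seed)
    best = int(rng.integers(0, n_programs))
    effects = []
    for p in range(n_programs):
        if p == best:
            effects.append(
                ProgramEffect(
                    amplitude_gain=1.4,
                    frequency_gain=1.3,
                    decay_factor=0.5,
                    jitter_factor=0.5,
                )
            )
        else:
            effects.append(
                ProgramEffect(
                    amplitude_gain=float(rng.uniform(0.9, 1.25)),
                    frequency_gain=float(rng.uniform(0.9, 1.2)),
                    decay_factor=float(rng.uniform(0.65, 1.1)),
                    jitter_factor=float(rng.uniform(0.65, 1.1)),
                )
            )
    base = TraceSpec(noise_sd=noise_sd, seed=seed)
    return SessionSpec(
        base=base,
        effects=tuple(effects),
        best_program=best,
        patient_id=patient_id,
        seed=seed,
    )


def generate_patient_session(spec: SessionSpec) -> tuple[list[ApertureTrace], str]:
    """Render all traces for a session (baseline first).

    Returns the traces and the label of the planted best program.  Per-trial
    seeds are derived deterministically from the session seed.
    """
    rng = np.random.default_rng(spec.seed)
    trial_seeds = rng.integers(0, 2**31 - 1, size=len(spec.effects) + 1)
    traces = [
        generate_aperture_trace(
            replace(spec.base, seed=int(trial_seeds[0])),
            patient_id=spec.patient_id,
            hand=spec.hand,
            condition=spec.baseline_label,
        )
    ]
    for p, effect in enumerate(spec.effects):
        label = f"Pr{p + 1:02d}"
        traces.append(
            generate_aperture_trace(
                effect.apply(spec.base, seed=int(trial_seeds[p + 1])),
                patient_id=spec.patient_id,
                hand=spec.hand,
                condition=label,
            )
        )
    return traces, f"Pr{spec.best_program + 1:02d}"


@dataclass(frozen=True)
class PlantedDomainSpec:
    """Low-rank sparse structure for improvement matrices.

    The matrix is scores @ loadings.T + noise with sparse, disjoint-support
    loading columns (each domain loads a contiguous block of features),
    emulating distinct kinematic domains.
    """

    n_patients: int = 40
    n_features: int = 23
    k: int = 3
    score_sd: tuple[float, ...] = (3.0, 2.0, 1.2)
    noise_sd: float = 0.1  # relative to unit loading scale
    sparsity: float = 0.65  # fraction of zero loadings per column
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sparsity < 1):
            raise ValueError("sparsity fraction must lie in (0, 1)")
        if len(self.score_sd) != self.k:
            raise ValueError("score_sd must have k entries")


def planted_loadings(spec: PlantedDomainSpec) -> np.ndarray:
    """Sparse unit-norm loading columns with disjoint, seed-dependent supports.

    Features are randomly partitioned per seed, so two specs with different
    seeds plant structurally independent domains.
    """
    rng = np.random.default_rng(spec.seed)
    # sparsity is the zero fraction per column; disjoint supports cap the
    # active set at an equal share of the features
    n_active = max(
        2,
        min(
            int(round(spec.n_features * (1.0 - spec.sparsity))),
            spec.n_features // spec.k,
        ),
    )
    order = rng.permutation(spec.n_features)
    loadings = np.zeros((spec.n_features, spec.k))
    for j in range(spec.k):
        idx = order[j * n_active : (j + 1) * n_active]
        signs = rng.choice([-1.0, 1.0], size=len(idx))
        mags = rng.uniform(0.5, 1.0, size=len(idx))
        loadings[idx, j] = signs * mags
        loadings[:, j] /= np.linalg.norm(loadings[:, j])
    return loadings


def generate_domain_structured_cohort(
    spec: PlantedDomainSpec,
    true_loadings: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Improvement matrix with planted sparse loadings.

    Returns the patients x features matrix and the true loading matrix
    (features x k, unit-norm columns) for recovery scoring.  Passing
    ``true_loadings`` overrides the seed-derived loadings, e.g. to build two
    cohorts sharing some domains.
    """
    rng = np.random.default_rng(spec.seed)
    loadings = planted_loadings(spec) if true_loadings is None else np.asarray(true_loadings, dtype=float)
    if loadings.shape != (spec.n_features, spec.k):
        raise ValueError("true_loadings shape must be (n_features, k)")
    scores = rng.normal(0.0, 1.0, size=(spec.n_patients, spec.k)) * np.array(spec.score_sd)
    signal = scores @ loadings.T
    noise = rng.normal(0.0, spec.noise_sd * np.std(signal), size=signal.shape)
    matrix = pd.DataFrame(
        signal + noise, columns=[f"feature_{j:02d}" for j in range(spec.n_features)]
    )
    return matrix, loadings


def generate_concordance_dataset(
    beta: float = 0.70,
    cluster_sd: float = 0.3,
    residual_sd: float = 0.5,
    n_clusters: int = 15,
    n_per_cluster: int = 10,
    seed: int = 0,
    discretize: bool = True,
) -> pd.DataFrame:
    """Clinician-concordance records with a planted mixed-model slope.

    The latent clinical improvement is ``intercept_cluster + beta * ddwis +
    eps``; program scores are derived as baseline minus improvement and, when
    ``discretize``, rounded and clipped to the 0-4 MDS-UPDRS item scale
    (baseline scores live on the item scale throughout).  The delta-DWIS
    distribution is centred so that programs mostly improve on a moderately
    affected baseline: contact with the scale ends is then rare and the
    planted slope stays the estimand (rounding alone adds outcome noise but
    no slope bias, whereas censoring at the scale ends would attenuate it).
    """
    if cluster_sd < 0 or residual_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_clusters):
        intercept = rng.normal(0.0, cluster_sd)
        baseline = int(rng.integers(2, 4))  # moderately affected off therapy
        for r in range(n_per_cluster):
            ddwis = float(rng.normal(1.2, 0.5))
            latent = intercept + beta * ddwis + rng.normal(0.0, residual_sd)
            score = baseline - latent
            if discretize:
                score = float(np.clip(np.round(score), 0, 4))
            rows.append(
                {
                    "patient_hand": f"PH{c:02d}",
                    "program": f"Pr{r + 1:02d}",
                    "delta_dwis": ddwis,
                    "baseline_score": float(baseline),
                    "program_score": score,
                }
            )
    return pd.DataFrame(rows)
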