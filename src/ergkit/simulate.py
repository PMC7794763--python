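"""Synthetic scotopic flash ERG generator with exact ground truth.

The waveform model is the minimal composite reproducing dark-adapted flash
ERG morphology: a negative a-wave lobe, a slower positive b-wave lobe, and
high-frequency oscillatory potentials (OPs) on the b-wave's rising limb,

``v(t) = −A_a·g(t; t_a, k_a) + A_b·g(t; t_b, k_b)
        + A_op·exp(−(t−t₀)/τ)·sin(2πf(t−t₀))·[t ≥ t₀] + drift·t + noise``

where ``g(t; tp, k) = (t/tp)^k · exp(k(1 − t/tp))`` for ``t > 0`` is a
unit-peak gamma kernel peaking at ``tp``.  Amplitudes scale with flash
strength through a saturating (Naka–Rushton-style) law
``s(L) = I/(I + I₅₀)`` with ``I = 10^L``.  No biophysical fidelity is
claimed; the model exists to provide analytically known feature values.

Ground truth is computed from the *noiseless* composite on a 10×
oversampled grid by exhaustive search, so it is invariant to the noise
level, and any single sweep is independently regenerable through a
documented counter-based seeding scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .signal import AveragedTrace, ERGFeatures, Trace


@dataclass(frozen=True)
class SimParams:
    """Generator parameters (amplitudes µV, times ms, frequency Hz).

    Defaults describe a bright-flash mouse scotopic ERG: 150 µV a-wave
    troughing at 15 ms, 450 µV b-wave peaking at 55 ms, ±40 µV OPs at
    100 Hz starting at 18 ms with 25 ms decay, 10 µV additive sample noise.
    """

    a_amp_uV: float = 150.0
    a_peak_ms: float = 15.0
    a_shape: float = 4.0
    b_amp_uV: float = 450.0
    b_peak_ms: float = 55.0
    b_shape: float = 8.0
    op_amp_uV: float = 40.0
    op_freq_hz: float = 100.0
    op_onset_ms: float = 18.0
    op_decay_ms: float = 25.0
    noise_sd_uV: float = 10.0
    drift_uV_per_s: float = 0.0
    sampling_interval_ms: float = 0.5
    pretrial_ms: float = 20.0
    posttrial_ms: float = 200.0
    luminance_levels: tuple[float, ...] = (-2.0, -1.0, -0.01, 0.6, 1.4)
    amp_semisaturation: float = -1.5
    seed: int = 0

    def __post_init__(self):
        if min(self.a_amp_uV, self.b_amp_uV, self.op_amp_uV) < 0:
            raise ValueError("amplitudes must be >= 0")
        if min(self.a_shape, self.b_shape) <= 1:
            raise ValueError("gamma shapes must exceed 1")
        fs = 1000.0 / self.sampling_interval_ms
        if fs < 4 * self.op_freq_hz:
            raise ValueError("sampling rate must be >= 4x the OP frequency")


def time_grid(p: SimParams, oversample: int = 1) -> np.ndarray:
    """Uniform grid from −pretrial to +posttrial; built from integer indices
    so every trial shares bit-identical sample times."""
    dt = p.sampling_interval_ms / oversample
    n0 = -round(p.pretrial_ms / dt)
    n1 = round(p.posttrial_ms / dt)
    return np.arange(n0, n1 + 1) * dt


def _gamma_kernel(t: np.ndarray, tp: float, k: float) -> np.ndarray:
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / tp
    out[pos] = x**k * np.exp(k * (1.0 - x))
    return out


def luminance_scale(luminance_log: float, semisaturation_log: float) -> float:
    """Saturating amplitude scale in (0, 1): I/(I + I50) on linear intensity."""
    return 1.0 / (1.0 + 10.0 ** (semisaturation_log - luminance_log))


def op_component(p: SimParams, t: np.ndarray, scale: float = 1.0) -> np.ndarray:
    s = t - p.op_onset_ms
    out = np.zeros_like(t)
    on = s >= 0
    out[on] = (
        scale
        * p.op_amp_uV
        * np.exp(-s[on] / p.op_decay_ms)
        * np.sin(2 * np.pi * p.op_freq_hz * s[on] / 1000.0)
    )
    return out


def smooth_component(p: SimParams, t: np.ndarray, scale: float = 1.0) -> np.ndarray:
    return scale * (
        -p.a_amp_uV * _gamma_kernel(t, p.a_peak_ms, p.a_shape)
        + p.b_amp_uV * _gamma_kernel(t, p.b_peak_ms, p.b_shape)
    )


def composite(p: SimParams, t: np.ndarray, luminance_log: float) -> np.ndarray:
    """Noiseless deterministic waveform (components + drift) at one luminance."""
    scale = luminance_scale(luminance_log, p.amp_semisaturation)
    v = smooth_component(p, t, scale) + op_component(p, t, scale)
    return v + p.drift_uV_per_s * t / 1000.0


def synth_sweep(
    p: SimParams, luminance_log: float, trial_seed: int | np.random.SeedSequence
) -> Trace:
    """One noisy sweep; identical (params, luminance, seed) gives identical bytes."""
    t = time_grid(p)
    rng = np.random.default_rng(trial_seed)
    v = composite(p, t, luminance_log) + rng.normal(0.0, p.noise_sd_uV, t.size)
    return Trace(t, v)


def _synth_trials(
    p: SimParams, luminance_log: float, n_trials: int, seed: int | np.random.SeedSequence
) -> list[Trace]:
    """n sweeps sharing one RNG stream (vectorised noise draw)."""
    t = time_grid(p)
    rng = np.random.default_rng(seed)
    clean = composite(p, t, luminance_log)
    noise = rng.normal(0.0, p.noise_sd_uV, (n_trials, t.size))
    return [Trace(t, clean + noise[i]) for i in range(n_trials)]


def ground_truth(p: SimParams, luminance_log: float, oversample: int = 10) -> ERGFeatures:
    """Exact features of the noiseless composite by dense-grid exhaustive search.

    The baseline is the pretrial mean; the a-trough is the global minimum of
    the composite after onset; the b-peak is the maximum of the OP-free
    (smooth) composite after the trough; OP implicit times are the first
    four positive peaks of the OP component itself.  All searches run on an
    ``oversample``× finer grid than the sampling interval.
    """
    t = time_grid(p, oversample=oversample)
    scale = luminance_scale(luminance_log, p.amp_semisaturation)
    drift = p.drift_uV_per_s * t / 1000.0
    smooth = smooth_component(p, t, scale) + drift
    op = op_component(p, t, scale)
    full = smooth + op

    f = ERGFeatures()
    pre = t < 0
    f.baseline_uV = float(full[pre].mean())
    post = t >= 0
    i_min = int(np.argmin(np.where(post, full, np.inf)))
    f.a_amp_uV = max(0.0, f.baseline_uV - float(full[i_min]))
    f.a_implicit_ms = float(t[i_min])
    after = t >= t[i_min]
    i_max = int(np.argmax(np.where(after, smooth, -np.inf)))
    f.b_amp_uV = max(0.0, float(smooth[i_max]) - float(full[i_min]))
    f.b_implicit_ms = float(t[i_max])

    # positive peaks of the damped sinusoid: local maxima on the dense grid
    rising = (op[1:-1] > op[:-2]) & (op[1:-1] >= op[2:]) & (op[1:-1] > 0)
    peak_idx = np.nonzero(rising)[0] + 1
    for k, i in enumerate(peak_idx[:4]):
        f.op_implicit_ms[k] = float(t[i])
        f.op_amp_uV[k] = float(op[i])
    return f


@dataclass(frozen=True)
class CellEffect:
    """Per-(genotype, treatment) cell effect on the base waveform."""

    b_factor: float = 1.0
    a_factor: float = 1.0
    op_delay_ms: float = 0.0

    def __post_init__(self):
        if self.b_factor <= 0 or self.a_factor <= 0:
            raise ValueError("effect factors must be > 0")


@dataclass(frozen=True)
class EffectSpec:
    """Cell effects plus between-animal variability (SDs of the per-animal draws)."""

    cells: dict[tuple[str, str], CellEffect] = field(default_factory=dict)
    b_factor_sd: float = 0.10
    a_factor_sd: float = 0.10
    op_delay_sd_ms: float = 1.0
    eye_factor_sd: float = 0.03

    def cell(self, genotype: str, treatment: str) -> CellEffect:
        return self.cells.get((genotype, treatment), CellEffect())


#: documented counter scheme: spawn_key identifies what a child stream is for
PARAM_STREAM = 0
SWEEP_STREAM = 1


def _child_seed(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master, spawn_key=key)


def animal_params(
    base: SimParams, eff: EffectSpec, cell: CellEffect, rng: np.random.Generator
) -> SimParams:
    """Draw one animal's waveform parameters around the cell effect."""
    b_f = max(0.05, rng.normal(cell.b_factor, eff.b_factor_sd))
    a_f = max(0.05, rng.normal(cell.a_factor, eff.a_factor_sd))
    delay = rng.normal(cell.op_delay_ms, eff.op_delay_sd_ms)
    return replace(
        base,
        b_amp_uV=base.b_amp_uV * b_f,
        a_amp_uV=base.a_amp_uV * a_f,
        op_onset_ms=base.op_onset_ms + delay,
    )


def eye_params(p: SimParams, eff: EffectSpec, rng: np.random.Generator) -> SimParams:
    """Small independent per-eye amplitude jitter."""
    f = max(0.05, rng.normal(1.0, eff.eye_factor_sd))
    return replace(p, b_amp_uV=p.b_amp_uV * f, a_amp_uV=p.a_amp_uV * f)


def trials_for_luminance(p: SimParams, luminance_log: float, dim: int = 10, bright: int = 5) -> int:
    """Trial count per flash strength: 10 repeats for the dimmer half of the
    luminance range, 5 for the brighter half."""
    levels = sorted(p.luminance_levels)
    mid = 0.5 * (levels[0] + levels[-1])
    return dim if luminance_log < mid else bright


def simulate_cohort(
    design: dict[tuple[str, str], int],
    base: SimParams,
    eff: EffectSpec,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a factorial cohort; returns (sweep table, ground-truth table).

    ``design`` maps (genotype, treatment) → number of animals.  Each animal
    gets two eyes with independent jitter; every (cell, animal, eye,
    luminance, trial) stream derives from the master seed by a fixed
    spawn-key counter, so any sweep regenerates independently.
    """
    for cell, n in design.items():
        if n < 2:
            raise ValueError(f"need >= 2 animals per cell, got {n} in {cell}")
    sweep_rows: list[pd.DataFrame] = []
    truth_rows = []
    for ci, ((geno, treat), n_animals) in enumerate(sorted(design.items())):
        cell = eff.cell(geno, treat)
        for ai in range(n_animals):
            animal_id = f"{geno}-{treat}-{ai+1:02d}"
            prng = np.random.default_rng(_child_seed(seed, ci, ai, PARAM_STREAM))
            p_animal = animal_params(base, eff, cell, prng)
            for ei, eye in enumerate(("left", "right")):
                p_eye = eye_params(p_animal, eff, prng)
                for li, lum in enumerate(sorted(base.luminance_levels)):
                    n_trials = trials_for_luminance(base, lum)
                    for trial in range(1, n_trials + 1):
                        ss = _child_seed(seed, ci, ai, SWEEP_STREAM, ei, li, trial)
                        tr = synth_sweep(p_eye, lum, ss)
                        sweep_rows.append(
                            pd.DataFrame(
                                {
                                    "animal_id": animal_id,
                                    "eye": eye,
                                    "luminance_log": lum,
                                    "trial": trial,
                                    "time_ms": tr.time_ms,
                                    "voltage_uV": tr.voltage_uV,
                                }
                            )
                        )
                    gt = ground_truth(p_eye, lum)
                    truth_rows.append(
                        {
                            "animal_id": animal_id,
                            "genotype": geno,
                            "treatment": treat,
                            "eye": eye,
                            "luminance_log": lum,
                            "a_amp_uV": gt.a_amp_uV,
                            "a_implicit_ms": gt.a_implicit_ms,
                            "b_amp_uV": gt.b_amp_uV,
                            "b_implicit_ms": gt.b_implicit_ms,
                            **{f"op{k+1}_implicit_ms": gt.op_implicit_ms[k] for k in range(4)},
                        }
                    )
    sweeps = pd.concat(sweep_rows, ignore_index=True)
    return sweeps, pd.DataFrame(truth_rows)
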