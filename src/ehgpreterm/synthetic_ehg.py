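"""Synthetic EHG cohort generator.

Emulates the geometry of TPEHG-style recordings — 20 Hz, ~30 min, three
correlated bipolar channels — and the physiological premise that preterm
records carry stronger and more frequent uterine contraction bursts than
term records.  A burst is a Hann-windowed chirp inside the contraction band
(0.1-3 Hz by default) arriving as a Poisson process; out-of-band drift
(<0.08 Hz) and high-frequency noise (>4 Hz) are added so the band-pass
preprocessing stage has observable work.

This is an effect-size model, not uterine electrophysiology: it controls
class separability through the rate/amplitude gap and makes every
downstream stage testable without the PhysioNet download.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_ehg import EHGRecord

__all__ = ["SimParams", "TERM_PARAMS", "PRETERM_PARAMS",
           "generate_record", "generate_cohort", "burst_component"]


@dataclass(frozen=True)
class SimParams:
    """Generator settings for one record class.

    Amplitudes are in the arbitrary millivolt-scale units of the output
    signal; ``burst_rate_per_min`` is the mean Poisson contraction rate.
    """

    fs: float = 20.0
    duration_s: float = 1800.0
    burst_rate_per_min: float = 0.3
    burst_amp: float = 1.0
    burst_band: tuple[float, float] = (0.1, 3.0)
    burst_len_s: tuple[float, float] = (20.0, 60.0)
    drift_amp: float = 2.0
    hf_noise_amp: float = 0.5
    noise_sd: float = 0.25
    channel_corr: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.burst_band
        if not (0.0 < lo < hi):
            raise ValueError(f"invalid burst band {self.burst_band}")
        if self.fs <= 2.0 * hi:
            raise ValueError(
                f"fs={self.fs} must exceed twice the band edge {hi}")
        for name in ("burst_rate_per_min", "burst_amp", "drift_amp",
                     "hf_noise_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.channel_corr <= 1.0:
            raise ValueError("channel_corr must lie in [0, 1]")


#: default study conditions: preterm strictly dominates term in both the
#: contraction rate and the contraction amplitude
TERM_PARAMS = SimParams(burst_rate_per_min=0.3, burst_amp=1.0)
PRETERM_PARAMS = SimParams(burst_rate_per_min=0.8, burst_amp=2.0)


def default_params(label: str) -> SimParams:
    if label == "preterm":
        return PRETERM_PARAMS
    if label == "term":
        return TERM_PARAMS
    raise ValueError(f"unknown label {label!r}")


def burst_component(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Noise-free sum of contraction bursts (the latent uterine source)."""
    n = int(round(params.fs * params.duration_s))
    t = np.arange(n) / params.fs
    out = np.zeros(n)
    lam = params.burst_rate_per_min * params.duration_s / 60.0
    n_bursts = rng.poisson(lam)
    lo, hi = params.burst_band
    for _ in range(n_bursts):
        length = rng.uniform(*params.burst_len_s)
        start = rng.uniform(0.0, max(params.duration_s - length, 0.0))
        i0 = int(start * params.fs)
        m = int(length * params.fs)
        if m < 8 or i0 + m > n:
            continue
        # chirp between two in-band frequencies, Hann-windowed
        f0 = rng.uniform(lo, hi)
        f1 = np.clip(f0 * rng.uniform(0.5, 2.0), lo, hi)
        tau = t[:m]
        phase = 2 * np.pi * (f0 * tau + (f1 - f0) * tau**2 / (2 * length))
        amp = params.burst_amp * rng.uniform(0.7, 1.3)
        out[i0:i0 + m] += amp * np.hanning(m) * np.sin(phase + rng.uniform(0, 2 * np.pi))
    return out


def _drift(params: SimParams, rng: np.random.Generator, n: int) -> np.ndarray:
    t = np.arange(n) / params.fs
    out = np.zeros(n)
    for _ in range(3):
        f = rng.uniform(0.01, 0.05)
        out += rng.uniform(0.5, 1.0) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return params.drift_amp * out


def _hf_noise(params: SimParams, rng: np.random.Generator, n: int) -> np.ndarray:
    t = np.arange(n) / params.fs
    out = np.zeros(n)
    for _ in range(3):
        f = rng.uniform(5.0, 9.0)
        out += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return params.hf_noise_amp * out / 3.0


def _weeks_for(label: str, group: str, rng: np.random.Generator) -> tuple[float, float]:
    """Gestational (recording, delivery) weeks consistent with label/group."""
    if group == "early":
        rec = rng.uniform(22.0, 25.9)
    elif group == "late":
        rec = rng.uniform(26.0, 32.0)
    else:
        raise ValueError(f"unknown group {group!r}")
    if label == "preterm":
        low = max(rec + 1.0, 30.0)
        dlv = rng.uniform(low, 36.9)
    else:
        dlv = rng.uniform(37.1, 42.0)
    return round(rec, 1), round(dlv, 1)


def generate_record(label: str, group: str = "early",
                    params: SimParams | None = None,
                    record_id: str | None = None) -> EHGRecord:
    """Generate one labeled synthetic EHG record.

    The three channels are noisy views of a single latent contraction
    source; ``params.channel_corr`` sets the fraction of the additive noise
    shared between channels.  Deterministic for a fixed ``params.seed``.
    """
    params = params if params is not None else default_params(label)
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.fs * params.duration_s))

    source = burst_component(params, rng)
    source = source + _drift(params, rng, n) + _hf_noise(params, rng, n)
    shared = rng.standard_normal(n)
    rho = params.channel_corr
    channels = np.empty((3, n))
    for c in range(3):
        own = rng.standard_normal(n)
        noise = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
        gain = rng.uniform(0.9, 1.1)
        channels[c] = gain * source + params.noise_sd * noise

    rec_week, dlv_week = _weeks_for(label, group, rng)
    if record_id is None:
        record_id = f"syn_{group}_{label}_{params.seed:08d}"
    return EHGRecord(record_id, params.fs, channels, rec_week, dlv_week,
                     provenance="synthetic")


def generate_cohort(n_term: int, n_preterm: int, group: str = "early",
                    term_params: SimParams | None = None,
                    preterm_params: SimParams | None = None,
                    seed: int = 0) -> list[EHGRecord]:
    """Generate a labeled cohort with independent per-record seeds.

    Per-record seeds are spawned from the master ``seed`` so that cohorts
    are reproducible and records mutually independent.
    """
    if n_term < 0 or n_preterm < 0:
        raise ValueError("cohort sizes must be non-negative")
    term_params = term_params if term_params is not None else TERM_PARAMS
    preterm_params = (preterm_params if preterm_params is not None
                      else PRETERM_PARAMS)
    seeds = np.random.SeedSequence(seed).generate_state(n_term + n_preterm)
    records = []
    for i in range(n_term):
        p = replace(term_params, seed=int(seeds[i]) % (2**31))
        records.append(generate_record(
            "term", group, p, record_id=f"syn_{group}_term_{i:04d}"))
    for i in range(n_preterm):
        p = replace(preterm_params, seed=int(seeds[n_term + i]) % (2**31))
        records.append(generate_record(
            "preterm", group, p, record_id=f"syn_{group}_preterm_{i:04d}"))
    return records
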