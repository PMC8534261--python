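"""Synthetic wearable-bioimpedance study generator.

Emulates the statistical structure of a multi-day, multi-subject
wrist-device study: per-subject latent limb and finger Cole spectra,
day-to-day physiological drift that is much stronger in the fingers
than in the limb, an inverse finger-impedance/hand-temperature
dependence with a flat limb response, per-finger contact-placement
artifacts, and small multiplicative device noise.

The measurement model is additive in path impedance: a wrist-finger
channel ``(0, i)`` reads ``Z_limb + Z_fi`` and a finger-finger channel
``(i, j)`` reads ``Z_fi + Z_fj``, which is what makes the pure limb
spectrum recoverable downstream by sum-and-subtract cancellation.

Finger day drift is decomposed into a shared "whole hand" lognormal
component and an independent per-finger component (``day_shared_frac``
of the log-variance is shared).  Fully common drift would cancel
exactly in ratiometric features and fully independent drift would not
cancel at all; the split reproduces the observed intermediate
reproducibility of ratio features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .cole import ColeParams, cole_magnitude
from .records import (
    DEFAULT_FREQUENCIES,
    PAIRS,
    ConditionSpec,
    SessionRecord,
    StudyData,
)

__all__ = [
    "GeneratorConfig",
    "SubjectGroundTruth",
    "draw_subject",
    "apply_condition",
    "simulate_session",
    "simulate_study",
]

SCENARIOS = ("nominal", "temperature_sweep", "placement_sweep")


@dataclass(frozen=True)
class GeneratorConfig:
    """Population and condition parameters of the synthetic study.

    Ranges are uniform-draw bounds for the per-subject Cole parameters;
    sigmas are lognormal day-drift scales (dimensionless, log domain).
    """

    # population ranges
    limb_r0: tuple[float, float] = (120.0, 260.0)
    finger_r0: tuple[float, float] = (300.0, 900.0)
    r_inf_frac: tuple[float, float] = (0.4, 0.7)
    fc_hz: tuple[float, float] = (30e3, 200e3)
    alpha: tuple[float, float] = (0.6, 0.9)
    # day-to-day drift
    sigma_day_finger: float = 0.05
    sigma_day_limb: float = 0.005
    day_shared_frac: float = 0.7
    # temperature model (fingers only)
    kappa_per_degc: float = 0.01
    t_ref_c: float = 33.0
    temp_range_c: tuple[float, float] = (18.0, 32.0)
    # placement
    placement_factors: tuple[float, float, float] = (0.90, 1.00, 1.12)
    placement_finger: int = 1
    placement_jitter: tuple[float, float] | None = None
    # device
    noise_rel: float = 2e-5
    frequencies: np.ndarray = field(
        default_factory=lambda: DEFAULT_FREQUENCIES.copy()
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.day_shared_frac <= 1.0):
            raise ValueError("day_shared_frac must lie in [0, 1]")
        if self.kappa_per_degc < 0.0:
            raise ValueError("kappa_per_degc must be non-negative")
        if self.noise_rel < 0.0:
            raise ValueError("noise_rel must be non-negative")
        if self.placement_finger not in (1, 2, 3, 4):
            raise ValueError("placement_finger must be one of 1..4")


@dataclass(frozen=True)
class SubjectGroundTruth:
    """Latent per-subject spectra parameters (synthetic studies only)."""

    subject_id: str
    limb: ColeParams
    fingers: tuple[ColeParams, ColeParams, ColeParams, ColeParams]

    def limb_spectrum(self, frequencies: np.ndarray) -> np.ndarray:
        return cole_magnitude(self.limb, frequencies)

    def finger_spectrum(self, finger: int, frequencies: np.ndarray) -> np.ndarray:
        """Spectrum of finger ``finger`` in 1..4."""
        return cole_magnitude(self.fingers[finger - 1], frequencies)


def _draw_cole(rng: np.random.Generator, r0_range: tuple[float, float],
               cfg: GeneratorConfig) -> ColeParams:
    r0 = rng.uniform(*r0_range)
    r_inf = r0 * rng.uniform(*cfg.r_inf_frac)
    fc = rng.uniform(*cfg.fc_hz)
    alpha = rng.uniform(*cfg.alpha)
    return ColeParams(r_inf=r_inf, r0=r0, fc=fc, alpha=alpha)


def draw_subject(rng: np.random.Generator, cfg: GeneratorConfig,
                 subject_id: str) -> SubjectGroundTruth:
    """Draw one subject's latent limb and four finger dispersions."""
    limb = _draw_cole(rng, cfg.limb_r0, cfg)
    fingers = tuple(_draw_cole(rng, cfg.finger_r0, cfg) for _ in range(4))
    return SubjectGroundTruth(subject_id=subject_id, limb=limb, fingers=fingers)


def apply_condition(
    base: np.ndarray,
    role: Literal["limb", "finger"],
    cond: ConditionSpec,
    subject_day_factor: float = 1.0,
    *,
    finger: int | None = None,
    kappa_per_degc: float = 0.01,
    t_ref_c: float = 33.0,
) -> np.ndarray:
    """Condition a latent spectrum for one session.

    The day factor applies to both roles.  Fingers additionally pick up
    a temperature factor ``1 + kappa * (T_ref - T_hand)`` (impedance
    rises as the hand cools) and their placement factor from ``cond``;
    the limb is temperature- and placement-invariant by construction.
    """
    base = np.asarray(base, dtype=float)
    if np.any(base <= 0.0):
        raise ValueError("base spectrum must be strictly positive")
    if role not in ("limb", "finger"):
        raise ValueError(f"role must be 'limb' or 'finger', got {role!r}")
    factor = float(subject_day_factor)
    if role == "finger":
        if finger is None or finger not in (1, 2, 3, 4):
            raise ValueError("finger index in 1..4 required for role='finger'")
        factor *= 1.0 + kappa_per_degc * (t_ref_c - cond.hand_temp_c)
        factor *= cond.placement_factors[finger - 1]
    if factor <= 0.0:
        raise ValueError(f"condition factor must stay positive, got {factor}")
    return base * factor


@dataclass(frozen=True)
class DayFactors:
    """Per-subject-day drift multipliers (one limb, four fingers)."""

    limb: float = 1.0
    fingers: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)


def draw_day_factors(rng: np.random.Generator, cfg: GeneratorConfig) -> DayFactors:
    """Lognormal day drift: fingers share a hand component plus own noise."""
    w = cfg.day_shared_frac
    z_shared = rng.standard_normal()
    z_own = rng.standard_normal(4)
    log_f = cfg.sigma_day_finger * (np.sqrt(w) * z_shared + np.sqrt(1.0 - w) * z_own)
    limb = float(np.exp(cfg.sigma_day_limb * rng.standard_normal()))
    return DayFactors(limb=limb, fingers=tuple(np.exp(log_f)))


def simulate_session(
    truth: SubjectGroundTruth,
    cond: ConditionSpec,
    rng: np.random.Generator,
    cfg: GeneratorConfig | None = None,
    day_factors: DayFactors | None = None,
    repeat_index: int = 1,
    placement_label: str = "",
) -> SessionRecord:
    """Simulate the 10 channel spectra of one device placement.

    Channel ``(0, i)`` is conditioned limb + conditioned finger ``i``;
    channel ``(i, j)`` is conditioned finger ``i`` + conditioned finger
    ``j``; every channel is then perturbed by multiplicative noise
    ``Normal(1, cond.noise_rel)`` per frequency.
    """
    cfg = cfg or GeneratorConfig()
    day_factors = day_factors or DayFactors()
    f = cfg.frequencies
    limb = apply_condition(truth.limb_spectrum(f), "limb", cond, day_factors.limb)
    fingers = [
        apply_condition(
            truth.finger_spectrum(i, f), "finger", cond, day_factors.fingers[i - 1],
            finger=i, kappa_per_degc=cfg.kappa_per_degc, t_ref_c=cfg.t_ref_c,
        )
        for i in (1, 2, 3, 4)
    ]
    channels = np.empty((len(PAIRS), f.size))
    for k, (a, b) in enumerate(PAIRS):
        if a == 0:
            channels[k] = limb + fingers[b - 1]
        else:
            channels[k] = fingers[a - 1] + fingers[b - 1]
    if cond.noise_rel > 0.0:
        channels = channels * rng.normal(1.0, cond.noise_rel, size=channels.shape)
    return SessionRecord(
        subject_id=truth.subject_id,
        day_index=cond.day_index,
        repeat_index=repeat_index,
        frequencies=f,
        channels=channels,
        condition=cond,
        placement_label=placement_label,
    )


def _session_condition(
    cfg: GeneratorConfig,
    scenario: str,
    day: int,
    repeat: int,
    repeats_per_day: int,
    rng: np.random.Generator,
) -> tuple[ConditionSpec, str]:
    """Condition and placement label for one (day, repeat) slot."""
    temp = cfg.t_ref_c
    placement = [1.0, 1.0, 1.0, 1.0]
    label = ""
    if scenario == "temperature_sweep":
        # cool from the high end of the range to the low end across repeats
        hi, lo = max(cfg.temp_range_c), min(cfg.temp_range_c)
        if repeats_per_day == 1:
            temp = hi
        else:
            temp = hi + (lo - hi) * (repeat - 1) / (repeats_per_day - 1)
    elif scenario == "placement_sweep":
        k = (repeat - 1) % len(cfg.placement_factors)
        placement[cfg.placement_finger - 1] = cfg.placement_factors[k]
        label = f"P{k + 1}"
    elif scenario == "nominal":
        if cfg.placement_jitter is not None:
            lo, hi = cfg.placement_jitter
            placement = list(rng.uniform(lo, hi, size=4))
    else:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    cond = ConditionSpec(
        day_index=day,
        hand_temp_c=temp,
        placement_factors=tuple(placement),
        noise_rel=cfg.noise_rel,
    )
    return cond, label


def simulate_study(
    n_subjects: int,
    n_days: int,
    repeats_per_day: int,
    scenario: str = "nominal",
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> tuple[StudyData, list[SubjectGroundTruth]]:
    """Simulate a full multi-day study; deterministic given ``seed``.

    Returns the study dataset together with the latent per-subject
    ground truths (for oracle checks; real studies have no such thing).
    """
    if min(n_subjects, n_days, repeats_per_day) < 1:
        raise ValueError("n_subjects, n_days and repeats_per_day must all be >= 1")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    cfg = config or GeneratorConfig()
    root = np.random.SeedSequence(seed)
    pop_ss, cond_ss = root.spawn(2)
    rng_pop = np.random.default_rng(pop_ss)
    width = max(2, len(str(n_subjects)))
    truths = [
        draw_subject(rng_pop, cfg, f"S{k + 1:0{width}d}") for k in range(n_subjects)
    ]
    day_streams = cond_ss.spawn(n_subjects * n_days)

    sessions: list[SessionRecord] = []
    for s, truth in enumerate(truths):
        for day in range(1, n_days + 1):
            rng_day = np.random.default_rng(day_streams[s * n_days + (day - 1)])
            factors = draw_day_factors(rng_day, cfg)
            for rep in range(1, repeats_per_day + 1):
                cond, label = _session_condition(
                    cfg, scenario, day, rep, repeats_per_day, rng_day
                )
                sessions.append(
                    simulate_session(
                        truth, cond, rng_day, cfg,
                        day_factors=factors, repeat_index=rep, placement_label=label,
                    )
                )

    channels = np.stack([s.channels for s in sessions])
    meta = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in sessions],
            "day_index": [s.day_index for s in sessions],
            "repeat_index": [s.repeat_index for s in sessions],
            "hand_temp_c": [s.condition.hand_temp_c for s in sessions],
            "placement_label": [s.placement_label for s in sessions],
        }
    )
    return StudyData(channels=channels, meta=meta, frequencies=cfg.frequencies), truths


def noiseless(cfg: GeneratorConfig | None = None) -> GeneratorConfig:
    """Copy of ``cfg`` with device noise switched off."""
    return replace(cfg or GeneratorConfig(), noise_rel=0.0)
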