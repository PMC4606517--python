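"""Synthetic smFRET trajectories and equilibrium-binding isotherms.

The trace simulator emulates a flow-injection single-molecule binding
experiment: surface-immobilized acceptor-labeled targets, donor-labeled
protein-guide complexes delivered at ``flow_start_time``, first arrival at
each target exponential with rate kon_obs x [protein], and bound dwells drawn
from a one- or two-component exponential mixture.  ``p_long`` is the
event-count fraction of long-lived events, which is exactly the quantity the
amplitude-weighted percentage formula A1*tau1/(A1*tau1 + A2*tau2) estimates
from a fitted dwell histogram, so simulation truth is directly comparable to
fitted population fractions.

The isotherm simulator draws dot-blot style titrations from the single-site
model with ligand depletion (the labeled target at 0.1 nM is comparable to
the sub-nanomolar Kd values of interest, so free protein != total protein).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .traces import FretTrace

__all__ = [
    "TraceSimConfig",
    "IsothermSimConfig",
    "IsothermDataset",
    "simulate_traces",
    "simulate_isotherm",
    "fraction_bound_depletion",
    "fraction_bound_hyperbolic",
    "DEFAULT_TITRATION_NM",
]

# Protein concentrations (nM) spanning the 0-70 nM titration used in the
# dot-blot assays; roughly log-spaced above zero so the sub-nM Kd region
# is well sampled.
DEFAULT_TITRATION_NM: tuple[float, ...] = (
    0.0, 0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4, 12.8, 25.0, 50.0, 70.0,
)


@dataclass
class TraceSimConfig:
    """Parameters for simulating donor/acceptor traces of one condition.

    Rates are per second; concentrations in nM; times in seconds.  ``p_long``
    is the probability that a binding event is drawn from the long-lived
    (``tau_long``) population; the remainder come from ``tau_short``.
    """

    kon_obs: float = 0.033          # s^-1 nM^-1, apparent association rate
    concentration: float = 1.0      # nM protein-guide complex after flow
    p_long: float = 0.5
    tau_short: float = 1.6          # s
    tau_long: float = 8.7           # s
    frame_interval: float = 0.1     # s, camera time resolution
    trace_duration: float = 300.0   # s
    n_molecules: int = 200
    fret_bound: float = 0.85
    fret_unbound: float = 0.05
    intensity_total: float = 1000.0
    noise_sd: float = 60.0
    flow_start_time: float = 5.0    # s
    bleach_time: Optional[float] = None  # s; None disables photobleaching
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0.0 <= self.p_long <= 1.0, "p_long must be in [0, 1]"),
            (self.tau_short > 0, "tau_short must be positive"),
            (self.tau_long >= self.tau_short, "tau_long must be >= tau_short"),
            (self.frame_interval > 0, "frame_interval must be positive"),
            (self.trace_duration > self.frame_interval,
             "trace_duration must exceed frame_interval"),
            (self.n_molecules >= 1, "n_molecules must be >= 1"),
            (self.fret_unbound < self.fret_bound,
             "fret_unbound must be below fret_bound"),
            (self.kon_obs >= 0, "kon_obs must be non-negative"),
            (self.concentration >= 0, "concentration must be non-negative"),
            (self.intensity_total > 0, "intensity_total must be positive"),
            (self.noise_sd >= 0, "noise_sd must be non-negative"),
            (0 <= self.flow_start_time < self.trace_duration,
             "flow_start_time must lie within the trace"),
            (self.bleach_time is None or self.bleach_time > 0,
             "bleach_time must be positive when set"),
        ]
        numeric = [
            self.kon_obs, self.concentration, self.p_long, self.tau_short,
            self.tau_long, self.frame_interval, self.trace_duration,
            self.fret_bound, self.fret_unbound, self.intensity_total,
            self.noise_sd, self.flow_start_time,
        ]
        if not all(math.isfinite(float(v)) for v in numeric):
            raise ValueError("all numeric config values must be finite")
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)


@dataclass
class IsothermSimConfig:
    """Parameters for a synthetic dot-blot binding titration."""

    kd_true: float                           # nM
    receptor_total: float = 0.1              # nM labeled target
    titration_points: Sequence[float] = DEFAULT_TITRATION_NM
    noise_sd_fraction_bound: float = 0.02
    n_replicates: int = 3
    bmax: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.kd_true) and self.kd_true > 0):
            raise ValueError("kd_true must be positive and finite")
        if self.receptor_total <= 0:
            raise ValueError("receptor_total must be positive")
        pts = np.asarray(self.titration_points, dtype=float)
        if pts.size < 2 or np.any(pts < 0) or not np.all(np.isfinite(pts)):
            raise ValueError("titration_points must be >= 2 non-negative values")
        if self.noise_sd_fraction_bound < 0:
            raise ValueError("noise_sd_fraction_bound must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0 < self.bmax <= 1.05):
            raise ValueError("bmax must be in (0, 1.05]")


@dataclass
class IsothermDataset:
    """Titration of fraction target bound vs protein concentration.

    ``fraction_bound`` has shape (n_replicates, n_concentrations).
    """

    condition: str
    concentrations: np.ndarray
    fraction_bound: np.ndarray
    receptor_total: float

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.fraction_bound = np.atleast_2d(
            np.asarray(self.fraction_bound, dtype=float)
        )
        if self.fraction_bound.shape[1] != self.concentrations.size:
            raise ValueError("fraction_bound columns must match concentrations")

    @property
    def n_replicates(self) -> int:
        return int(self.fraction_bound.shape[0])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.n_replicates):
            for c, fb in zip(self.concentrations, self.fraction_bound[r]):
                rows.append((self.condition, r + 1, c, fb))
        return pd.DataFrame(
            rows, columns=["condition", "replicate", "conc_nM", "fraction_bound"]
        )


# ---------------------------------------------------------------------------
# trace simulation


def _sample_state_path(
    rng: np.random.Generator, cfg: TraceSimConfig
) -> list[tuple[float, float]]:
    """Sample (start, end) bound intervals for one molecule, in seconds.

    Continuous-time alternating renewal process: exponential waits to each
    binding at rate kon_obs*concentration (first and subsequent arrivals
    alike), dwell from the two-component exponential mixture.
    """
    rate = cfg.kon_obs * cfg.concentration
    end = cfg.trace_duration
    intervals: list[tuple[float, float]] = []
    t = cfg.flow_start_time
    if rate <= 0:
        return intervals
    while t < end:
        t += rng.exponential(1.0 / rate)
        if t >= end:
            break
        tau = cfg.tau_long if rng.random() < cfg.p_long else cfg.tau_short
        dwell = rng.exponential(tau)
        intervals.append((t, min(t + dwell, end)))
        t += dwell
    return intervals


def simulate_traces(config: TraceSimConfig) -> list[FretTrace]:
    """Simulate donor/acceptor traces with per-frame ground-truth states.

    Each molecule gets an independent random stream spawned from the config
    seed, so output is reproducible and independent of ``n_molecules`` order.
    The per-frame state is the continuous-time state sampled at the frame
    time; intensities split ``intensity_total`` by the state's FRET
    efficiency, plus independent Gaussian noise on each channel.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(config.n_molecules)
    n_frames = int(round(config.trace_duration / config.frame_interval))
    time = np.arange(n_frames) * config.frame_interval
    width = len(str(config.n_molecules - 1)) if config.n_molecules > 1 else 1

    traces: list[FretTrace] = []
    for m in range(config.n_molecules):
        rng = np.random.default_rng(streams[m])
        intervals = _sample_state_path(rng, config)
        state = np.zeros(n_frames, dtype=np.int8)
        for a, b in intervals:
            i0 = int(np.searchsorted(time, a, side="left"))
            i1 = int(np.searchsorted(time, b, side="left"))
            state[i0:i1] = 1
        if config.bleach_time is not None:
            t_bleach = rng.exponential(config.bleach_time)
            state[time >= t_bleach] = 0
        eff = np.where(state == 1, config.fret_bound, config.fret_unbound)
        acceptor = eff * config.intensity_total
        donor = (1.0 - eff) * config.intensity_total
        if config.noise_sd > 0:
            donor = donor + rng.normal(0.0, config.noise_sd, n_frames)
            acceptor = acceptor + rng.normal(0.0, config.noise_sd, n_frames)
        traces.append(
            FretTrace(
                molecule_id=f"mol{m:0{width}d}",
                time=time,
                donor=donor,
                acceptor=acceptor,
                true_state=state,
            )
        )
    return traces


def true_dwells(
    config: TraceSimConfig,
    seed: int | None = None,
    n_events: int | None = None,
    quantize: bool = False,
) -> np.ndarray:
    """Draw dwell times directly from the configured mixture.

    Convenience sampler for estimator studies that do not need full traces:
    the dwell law is identical to the one embedded in ``simulate_traces``.
    With ``quantize`` the dwells are rounded to the frame grid, as a
    camera running at ``frame_interval`` would report them.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = n_events if n_events is not None else config.n_molecules
    is_long = rng.random(n) < config.p_long
    taus = np.where(is_long, config.tau_long, config.tau_short)
    d = rng.exponential(taus)
    if quantize:
        d = np.round(d / config.frame_interval) * config.frame_interval
    return d


# ---------------------------------------------------------------------------
# isotherm simulation


def fraction_bound_depletion(
    protein_total: np.ndarray | float,
    kd: float,
    receptor_total: float,
    bmax: float = 1.0,
) -> np.ndarray:
    """Single-site fraction of receptor bound, accounting for ligand depletion.

    Exact root of the quadratic mass-balance for P + R <-> PR:
    bound/R = ((P+R+Kd) - sqrt((P+R+Kd)^2 - 4 P R)) / (2 R), scaled by bmax.
    """
    p = np.asarray(protein_total, dtype=float)
    r = float(receptor_total)
    s = p + r + kd
    disc = np.clip(s * s - 4.0 * p * r, 0.0, None)
    return bmax * (s - np.sqrt(disc)) / (2.0 * r)


def fraction_bound_hyperbolic(
    protein_total: np.ndarray | float, kd: float, bmax: float = 1.0
) -> np.ndarray:
    """No-depletion (Langmuir) isotherm: bmax * P / (P + Kd)."""
    p = np.asarray(protein_total, dtype=float)
    return bmax * p / (p + kd)


def simulate_isotherm(
    config: IsothermSimConfig, condition: str = "synthetic"
) -> IsothermDataset:
    """Simulate a replicated dot-blot titration.

    The noiseless curve is the quadratic-depletion solution at the true Kd;
    each replicate adds i.i.d. Gaussian noise to fraction bound, clamped to
    [0, 1].
    """
    conc = np.asarray(config.titration_points, dtype=float)
    clean = fraction_bound_depletion(
        conc, config.kd_true, config.receptor_total, config.bmax
    )
    rng = np.random.default_rng(config.seed)
    fb = np.tile(clean, (config.n_replicates, 1))
    if config.noise_sd_fraction_bound > 0:
        fb = fb + rng.normal(0.0, config.noise_sd_fraction_bound, fb.shape)
    fb = np.clip(fb, 0.0, 1.0)
    return IsothermDataset(
        condition=condition,
        concentrations=conc,
        fraction_bound=fb,
        receptor_total=config.receptor_total,
    )
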