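"""Deterministic synthetic test substrates.

The walking model's downstream stages (predictor extraction, oscillator
reproduction, gait analytics) all consume time series plus gait events.
This module generates those substrates without requiring an optimized
walking gait: quasi-periodic interneuron-like signals with controlled
cycle-period jitter and amplitude noise, consistent touchdown/takeoff
event trains, and isolated single-muscle test rigs.

Every generator is reproducible from its seed and designed to run in
well under a second at the default sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .muscle import DEFAULT_MUSCLES, MTUParams, MuscleBank
from .reflex import PathwaySpec, build_default_pathways

__all__ = [
    "SyntheticGaitSignals",
    "make_synthetic_gait",
    "single_muscle_rig",
    "load_reference_params",
]


def load_reference_params() -> np.ndarray:
    """The shipped reference controller parameters.

    Produced by the in-repo scaled-down optimization run
    (``scripts/find_reference_gait.py``, seeded); the gait walks for
    seconds rather than indefinitely and serves as a deterministic
    substrate for integration tests and examples.
    """
    import json
    import os

    path = os.path.join(os.path.dirname(__file__), "_reference",
                        "reference_params.json")
    with open(path) as fh:
        return np.asarray(json.load(fh)["params"], dtype=float)


@dataclass
class SyntheticGaitSignals:
    """Quasi-periodic per-pathway signals emulating a steady, symmetric
    gait, with the event trains and ground-truth shapes that produced
    them.  Layout matches the trajectory log: ``in_sen[limb][k]`` is the
    trace of pathway ``k`` of that limb."""

    times: np.ndarray  # (n_t,)
    in_sen: np.ndarray  # (2, n_path, n_t)
    touchdowns: list  # [array, array]
    takeoffs: list  # [array, array]
    true_shapes: dict  # pathway index -> callable theta -> value
    pathways: list
    period: float
    duty: float
    seed: int


def _base_shape(k: int, phase: str, duty: float):
    """Smooth 1-periodic template of pathway ``k``: a raised-cosine burst
    inside the pathway's active window.  Deterministic per index."""
    frac = (k * 0.37 + 0.11) % 1.0
    amp = 0.35 + 0.5 * frac
    if phase == "swing":
        w0, w1 = duty, 1.0
    elif phase == "cycle":
        w0, w1 = 0.0, 1.0
    else:  # stance, stance_end
        w0, w1 = 0.0, duty
    width = (w1 - w0) * (0.5 + 0.35 * ((k * 0.23) % 1.0))
    center = w0 + (w1 - w0) * (0.3 + 0.4 * ((k * 0.61) % 1.0))

    def shape(theta):
        theta = np.mod(np.asarray(theta, dtype=float), 1.0)
        u = (theta - center) / width
        out = amp * 0.5 * (1.0 + np.cos(2 * np.pi * u))
        out = np.where(np.abs(u) <= 0.5, out, 0.0)
        return out

    return shape


def make_synthetic_gait(period: float = 1.0, jitter: float = 0.02,
                        noise: float = 0.02, n_cycles: int = 50,
                        seed: int = 0, dt: float = 1e-3,
                        duty: float = 0.618,
                        pathways: list[PathwaySpec] | None = None,
                        ) -> SyntheticGaitSignals:
    """Synthetic interneuron signals of a steady symmetric gait.

    Each muscle-sensor pathway carries a smooth periodic burst inside
    its active phase window; the cycle period is perturbed per cycle by
    a relative ``jitter`` and the amplitude by a relative ``noise``
    (both Gaussian, seeded).  The right limb is the left one shifted by
    half a cycle.  Ground-truth shapes are retained so round-trip tests
    can compare against them.
    """
    if n_cycles < 2:
        raise ValueError("need at least 2 cycles")
    pathways = list(pathways) if pathways is not None else build_default_pathways()
    rng = np.random.default_rng(seed)
    n_path = len(pathways)

    periods = period * (1.0 + jitter * rng.standard_normal(n_cycles))
    periods = np.clip(periods, 0.5 * period, 1.5 * period)
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    t_end = starts[-1]
    times = np.arange(0.0, t_end, dt)
    n_t = len(times)

    shapes = {}
    for k, p in enumerate(pathways):
        if p.is_muscle_sensor:
            shapes[k] = _base_shape(k, p.phase, duty)

    in_sen = np.zeros((2, n_path, n_t))
    touchdowns = [None, None]
    takeoffs = [None, None]
    for limb in range(2):
        offset = 0.0 if limb == 0 else 0.5 * period
        td = starts[:-1] + offset
        to = starts[:-1] + duty * periods + offset
        td = td[td < t_end]
        to = to[to < t_end]
        touchdowns[limb] = td
        takeoffs[limb] = to
        # map each sample to its cycle and normalized phase
        idx = np.searchsorted(starts, times - offset, side="right") - 1
        idx = np.clip(idx, 0, n_cycles - 1)
        theta = (times - offset - starts[idx]) / periods[idx]
        theta = np.mod(theta, 1.0)
        amp_noise = 1.0 + noise * rng.standard_normal(n_cycles)
        for k, shape in shapes.items():
            sig = shape(theta) * amp_noise[idx]
            sig = sig + 0.25 * noise * rng.standard_normal(n_t)
            in_sen[limb, k] = np.clip(sig, 0.0, 1.0)
    return SyntheticGaitSignals(times, in_sen, touchdowns, takeoffs,
                                shapes, pathways, period, duty, seed)


def single_muscle_rig(params: MTUParams | None = None,
                      protocol: str = "isometric",
                      duration: float = 0.5, dt: float = 1e-3,
                      stim: float = 1.0, l_total: float | None = None,
                      load: float | None = None) -> dict:
    """Run one MTU through a boundary protocol and return its traces.

    Protocols:

    * ``isometric`` — total MTU length held fixed (default: reference
      length), stimulation stepped to ``stim``;
    * ``passive`` — stimulation at the tone floor, MTU stretched by 5%;
    * ``quick_release`` — isometric buildup, then the MTU shortens
      against a constant load (fraction ``load`` of F_max) by moving the
      total length at the velocity that balances the load.
    """
    p = params or DEFAULT_MUSCLES[3]  # SOL by default
    bank = MuscleBank((p,), n_sub=20)
    l_ref = p.l_opt + p.l_slack
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    f = np.zeros(n)
    lce = np.zeros(n)
    act = np.zeros(n)
    vce = np.zeros(n)

    if protocol == "isometric":
        l_tot = np.full(n, l_total if l_total is not None else l_ref)
        s = np.full(n, stim)
    elif protocol == "passive":
        l_tot = np.full(n, 1.05 * l_ref)
        s = np.full(n, 0.01)
    elif protocol == "quick_release":
        if load is None:
            load = 0.25
        half = n // 2
        l_tot = np.full(n, l_ref)
        s = np.full(n, stim)
        # after release, the load fixes the tendon force; shorten the MTU
        # at the CE speed that the force-velocity relation dictates
        from .muscle import force_length, inverse_force_velocity
        v = float(inverse_force_velocity(
            load / max(float(force_length(p.l_opt, p)) * stim, 1e-9), p))
        for i in range(half, n):
            l_tot[i] = l_ref + v * (i - half) * dt
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    bank.reset(np.array([l_tot[0]]))
    for i in range(n):
        bank.step(np.array([l_tot[i]]), np.array([s[i]]), dt)
        f[i] = bank.force[0]
        lce[i] = bank.l_ce[0]
        act[i] = bank.act[0]
        vce[i] = bank.v_ce[0]
    return {"t": t, "force": f, "l_ce": lce, "activation": act,
            "v_ce": vce, "l_total": l_tot, "stim": s, "params": p}
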