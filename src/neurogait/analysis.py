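"""Gait metrics and scan protocols.

Implements the package's analytics: cost of transport, golden-ratio
gait-harmony analysis, cycle-normalized correlation against reference
trajectories, feedback activity, the per-pathway feedback-sensitivity
scan and the supraspinal (omega, mu) grid scan.

Gait-harmony ratios, for each gait cycle::

    GR0 = cycle duration / stance duration      (inverse duty factor)
    GR1 = stance duration / swing duration
    GR2 = swing duration / double-support duration

Double support is the *total* time per cycle during which both feet are
loaded (both double-support phases), which makes all three ratios equal
the golden ratio phi = (1+sqrt 5)/2 at a duty factor of exactly 1/phi —
the configuration reported for human walking at preferred speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import pearsonr

__all__ = [
    "GaitMetrics",
    "GOLDEN_RATIO",
    "cost_of_transport",
    "gait_ratios",
    "cycle_normalize_correlate",
    "mean_normalized_cycle",
    "feedback_activity",
    "feedback_sensitivity_scan",
    "engine_cell_evaluator",
    "engine_stability_probe",
    "passive_reproduction_correlations",
    "supraspinal_grid_scan",
    "classify_gait",
    "gait_metrics_from_log",
]

GOLDEN_RATIO = (1.0 + math.sqrt(5.0)) / 2.0


@dataclass
class GaitMetrics:
    mean_speed: float = math.nan  # [m/s]
    stride_length: float = math.nan  # [m]
    step_duration: float = math.nan  # [s]
    cot: float = math.nan  # [J/(kg*m)]
    gr0: float = math.nan
    gr1: float = math.nan
    gr2: float = math.nan
    stable: bool = False
    symmetry: float = math.nan  # relative L/R stride-length difference


def cost_of_transport(energy: float, mass: float, distance: float) -> float:
    """CoT = E / (m d), the metabolic energy per unit mass and distance."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    if mass <= 0:
        raise ValueError("mass must be positive")
    return energy / (mass * distance)


def _interval_overlap(a0: float, a1: float, intervals) -> float:
    total = 0.0
    for b0, b1 in intervals:
        lo = max(a0, b0)
        hi = min(a1, b1)
        if hi > lo:
            total += hi - lo
    return total


def _stance_intervals(touchdowns: np.ndarray, takeoffs: np.ndarray,
                      t_end: float) -> list[tuple[float, float]]:
    out = []
    for td in touchdowns:
        nxt = takeoffs[takeoffs > td]
        out.append((float(td), float(nxt[0]) if len(nxt) else t_end))
    return out


def gait_ratios(touchdowns_i: np.ndarray, takeoffs_i: np.ndarray,
                touchdowns_c: np.ndarray, takeoffs_c: np.ndarray,
                ) -> tuple[float, float, float]:
    """Golden-ratio harmony triplet averaged over the ipsilateral cycles.

    Needs at least three ipsilateral touchdowns (two complete cycles).
    ``GR2`` is nan when no double support is detected (duty factor at or
    below one half); all ratios are invariant to a rescaling of time.
    """
    td = np.asarray(touchdowns_i, dtype=float)
    to = np.asarray(takeoffs_i, dtype=float)
    if len(td) < 3:
        raise ValueError("need at least 2 complete cycles")
    t_end = max(td[-1], to[-1] if len(to) else td[-1])
    td_c = np.asarray(touchdowns_c, dtype=float)
    to_c = np.asarray(takeoffs_c, dtype=float)
    contra = _stance_intervals(td_c, to_c, t_end)
    # double support is only measurable for cycles whose start is covered
    # by the contralateral record (a stance already in progress at the
    # window start would otherwise be missed)
    ds_valid_from = float(np.min(to_c)) if len(to_c) else math.inf
    gr0s, gr1s, gr2s = [], [], []
    for i in range(len(td) - 1):
        cycle = td[i + 1] - td[i]
        nxt = to[(to > td[i]) & (to < td[i + 1])]
        if len(nxt) == 0:
            continue
        stance = float(nxt[0] - td[i])
        swing = cycle - stance
        if stance <= 0 or swing <= 0:
            continue
        # total double support: both feet loaded, anywhere in the cycle
        ds = _interval_overlap(td[i], td[i] + stance, contra)
        gr0s.append(cycle / stance)
        gr1s.append(stance / swing)
        if ds > 1e-12 and td[i] >= ds_valid_from:
            gr2s.append(swing / ds)
    if not gr0s:
        raise ValueError("no complete stance/swing cycle found")
    gr2 = float(np.mean(gr2s)) if gr2s else math.nan
    return float(np.mean(gr0s)), float(np.mean(gr1s)), gr2


def mean_normalized_cycle(signal: np.ndarray, times: np.ndarray,
                          events: np.ndarray, n_points: int = 1000
                          ) -> np.ndarray:
    """Mean stride shape on an ``n_points`` cycle grid.

    Strides are cut at consecutive events and each is time-normalized
    with a cubic-spline resampling to ``n_points`` samples before
    averaging.
    """
    times = np.asarray(times, dtype=float)
    signal = np.asarray(signal, dtype=float)
    ev = np.asarray(events, dtype=float)
    ev = ev[(ev >= times[0]) & (ev <= times[-1])]
    if len(ev) < 3:
        raise ValueError("need at least 2 complete strides")
    grid = np.linspace(0.0, 1.0, n_points, endpoint=False)
    acc = np.zeros(n_points)
    count = 0
    for i in range(len(ev) - 1):
        sel = (times >= ev[i]) & (times <= ev[i + 1])
        if sel.sum() < 4:
            continue
        t = times[sel]
        s = signal[sel]
        theta = (t - ev[i]) / (ev[i + 1] - ev[i])
        theta, idx = np.unique(theta, return_index=True)
        sp = CubicSpline(theta, s[idx])
        acc += sp(grid)
        count += 1
    if count < 2:
        raise ValueError("need at least 2 complete strides")
    return acc / count


def cycle_normalize_correlate(signal: np.ndarray, times: np.ndarray,
                              events: np.ndarray, reference: np.ndarray
                              ) -> float:
    """Pearson correlation between the mean normalized stride of a
    signal and a reference cycle (resampled to the same grid).

    Returns nan when either side is constant (correlation undefined).
    """
    reference = np.asarray(reference, dtype=float)
    mean = mean_normalized_cycle(signal, times, events, n_points=len(reference))
    if np.std(mean) < 1e-12 or np.std(reference) < 1e-12:
        return math.nan
    return float(pearsonr(mean, reference).statistic)


def feedback_activity(alpha: np.ndarray) -> float:
    """Feedback activity, percent: 100 * sum(alpha_i) / N."""
    a = np.asarray(alpha, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("alpha components must lie in [0, 1]")
    return float(100.0 * a.mean())


def feedback_sensitivity_scan(is_stable, n_steps: int = 10) -> float:
    """Feedback sensitivity of one pathway by progressive replacement.

    ``is_stable(beta)`` must report whether the gait remains stable when
    the pathway is blended with its oscillator predictor at feedforward
    proportion ``beta = 1 - alpha`` (all other pathways pure feedback).
    ``beta`` is swept over the 11-point grid 0, 0.1, ..., 1.0; the
    sensitivity is ``1 - beta_max_stable``: 0 means the pathway is fully
    replaceable without destabilizing the gait.
    """
    betas = np.round(np.linspace(0.0, 1.0, n_steps + 1), 10)
    if not is_stable(float(betas[0])):
        raise ValueError("base gait (beta = 0) is unstable")
    beta_stable = 0.0
    for b in betas[1:]:
        if is_stable(float(b)):
            beta_stable = float(b)
        else:
            break
    return float(round(1.0 - beta_stable, 10))


def classify_gait(log, cv_threshold: float = 0.05,
                  asym_threshold: float = 0.05) -> dict:
    """Stability / asymmetry classification of one episode log.

    Stable: no fall and a cycle-duration coefficient of variation below
    5%.  Asymmetric: left/right mean stride lengths differ by more than
    5%.
    """
    out = {"fell": bool(log.fell), "stable": False, "asymmetric": False,
           "speed": math.nan}
    if log.fell:
        return out
    td = log.touchdowns
    if len(td[0]) < 3 or len(td[1]) < 3:
        return out
    cycles = np.diff(td[0])
    cv = float(np.std(cycles) / np.mean(cycles))
    stride = [np.mean(np.diff(np.interp(td[s], log.times, log.q[:, 0])))
              for s in range(2)]
    asym = abs(stride[0] - stride[1]) / max(abs(stride[0]), 1e-9)
    duration = log.times[-1] - log.times[0]
    out["speed"] = float(log.distance / max(duration, 1e-9))
    out["stable"] = cv < cv_threshold
    out["asymmetric"] = asym > asym_threshold
    out["cycle_cv"] = cv
    out["stride_asymmetry"] = float(asym)
    return out


def supraspinal_grid_scan(evaluate, omega_range=(0.2, 2.5),
                          mu_range=(0.1, 4.0), n: int = 11) -> dict:
    """Grid scan over the two supraspinal commands.

    ``evaluate(omega, mu)`` must return a dict with at least ``stable``,
    ``asymmetric`` and ``speed`` keys (the engine-backed evaluator runs
    one episode per cell).  Returns the omega/mu grids plus an (n, n)
    speed array, nan in cells classified unstable or asymmetric, and the
    per-cell status codes.
    """
    omegas = np.linspace(*omega_range, n)
    mus = np.linspace(*mu_range, n)
    speed = np.full((n, n), math.nan)
    status = np.empty((n, n), dtype=object)
    for i, om in enumerate(omegas):
        for j, mu in enumerate(mus):
            res = evaluate(float(om), float(mu))
            if res.get("stable", False) and not res.get("asymmetric", False):
                speed[i, j] = res["speed"]
                status[i, j] = "stable"
            else:
                status[i, j] = ("asymmetric" if res.get("asymmetric", False)
                                else "unstable")
    return {"omega": omegas, "mu": mus, "speed": speed, "status": status}


def engine_cell_evaluator(pathways, config, recording, episode_config=None,
                          controller_factory=None):
    """Engine-backed evaluator for the supraspinal grid scan.

    Returns a callable ``evaluate(omega, mu)`` that rebuilds the
    predictor network from the recording (fresh oscillator state per
    cell), applies the supraspinal commands, runs one episode and
    classifies it.  ``controller_factory`` supplies a fresh reflex
    controller per cell (delay lines are stateful); None uses defaults.
    """
    from .cpg import apply_supraspinal, build_cpg_network
    from .engine import EpisodeConfig, run_episode

    def evaluate(omega: float, mu: float) -> dict:
        net = build_cpg_network(pathways, config, recording)
        apply_supraspinal(net, mu_osc=mu, mu_cst=mu, omega=omega)
        controller = controller_factory() if controller_factory else None
        cfg = episode_config or EpisodeConfig(duration=30.0)
        log = run_episode(cfg, controller=controller, cpg=net)
        return classify_gait(log)

    return evaluate


def engine_stability_probe(pathways, recording, pathway_name: str,
                           episode_config=None, controller_factory=None,
                           mode: str = "osc"):
    """Engine-backed stability callback for the feedback-sensitivity scan.

    Returns ``is_stable(beta)`` which blends pathway ``pathway_name``
    with its predictor at feedforward proportion ``beta`` (all other
    pathways pure feedback), runs one episode, and reports the stability
    classification.
    """
    from .cpg import CombinationConfig, build_cpg_network
    from .engine import EpisodeConfig, run_episode

    def is_stable(beta: float) -> bool:
        cfg = CombinationConfig(modes={pathway_name: mode},
                                alpha={pathway_name: 1.0 - beta})
        net = build_cpg_network(pathways, cfg, recording)
        controller = controller_factory() if controller_factory else None
        econf = episode_config or EpisodeConfig(duration=30.0)
        log = run_episode(econf, controller=controller, cpg=net)
        return classify_gait(log)["stable"]

    return is_stable


def passive_reproduction_correlations(gait, train_cycles: int = 40,
                                      burn_in_cycles: int = 2) -> dict:
    """Quality of the oscillator predictors run in passive mode.

    Shaping functions are extracted from the first ``train_cycles``
    cycles of the recording; the oscillators are then run passively (no
    action on the muscles), synchronized only by the event trains, over
    the held-out remainder, and each pathway's reproduction is scored by
    the Pearson correlation with the original signal.  The oscillators
    are started ``burn_in_cycles`` before the held-out window so every
    clock has synchronized at least once before scoring.

    Returns ``{"per_pathway": {(limb, name): r}, "min": r_min}``.
    """
    from .cpg import CombinationConfig, build_cpg_network, passive_reproduction

    names = [p.name for p in gait.pathways if p.is_muscle_sensor]
    cfg = CombinationConfig(modes={n: "osc" for n in names},
                            alpha={n: 0.0 for n in names})
    td0 = np.asarray(gait.touchdowns[0], dtype=float)
    if len(td0) <= train_cycles:
        raise ValueError("recording shorter than the training window")
    t_split = td0[train_cycles]
    t_burn = td0[max(train_cycles - burn_in_cycles, 0)]

    class _Window:
        pass

    rec = _Window()
    sel = gait.times < t_split
    rec.times = gait.times[sel]
    rec.in_sen = gait.in_sen[:, :, sel]
    rec.touchdowns = [np.asarray(td)[np.asarray(td) < t_split]
                      for td in gait.touchdowns]
    rec.takeoffs = [np.asarray(to)[np.asarray(to) < t_split]
                    for to in gait.takeoffs]
    net = build_cpg_network(gait.pathways, cfg, rec)

    run = gait.times >= t_burn
    t_run = gait.times[run]
    rep = passive_reproduction(
        net, t_run,
        [np.asarray(td)[np.asarray(td) >= t_burn] for td in gait.touchdowns],
        [np.asarray(to)[np.asarray(to) >= t_burn] for to in gait.takeoffs])
    score = t_run >= t_split
    out = {}
    for limb in range(2):
        for k, p in enumerate(gait.pathways):
            if not p.is_muscle_sensor:
                continue
            r = pearsonr(gait.in_sen[limb, k, run][score],
                         rep[limb, k][score]).statistic
            out[(limb, p.name)] = float(r)
    return {"per_pathway": out, "min": min(out.values())}


def gait_metrics_from_log(log, mass: float, energy: float | None = None
                          ) -> GaitMetrics:
    """Summary metrics of one episode log."""
    from .optimize import metabolic_energy
    m = GaitMetrics()
    duration = log.times[-1] - log.times[0] if log.n_steps > 1 else math.nan
    m.mean_speed = float(log.distance / duration) if duration else math.nan
    cls = classify_gait(log)
    m.stable = cls["stable"]
    m.symmetry = cls.get("stride_asymmetry", math.nan)
    td, to = log.touchdowns, log.takeoffs
    if len(td[0]) >= 3:
        cycles = np.diff(td[0])
        m.step_duration = float(np.mean(cycles) / 2.0)
        m.stride_length = float(np.mean(np.diff(
            np.interp(td[0], log.times, log.q[:, 0]))))
        try:
            m.gr0, m.gr1, m.gr2 = gait_ratios(td[0], to[0], td[1], to[1])
        except ValueError:
            pass
    if energy is None:
        energy = metabolic_energy(log)
    if log.distance > 0:
        m.cot = cost_of_transport(energy, mass, log.distance)
    return m
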