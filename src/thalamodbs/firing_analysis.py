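"""Quantification of thalamocortical firing regimes across stimulation frequency.

The no-stimulation run defines a reference level ``Lambda`` (the median
of the TC firing-rate series) around which the relay cells oscillate.
For any stimulated run, ``Delta2`` is the total time the rate spends
above Lambda (up state) and ``Delta1`` the time below (down state); the
high-to-low firing ratio ``HtoLR = Delta2 / Delta1`` summarizes the
regime.  Sweeping stimulation frequency from 0 to 150 Hz yields the
frequency profile of HtoLR, the frequency of its abrupt jump and the
band above which the relay cells stop firing.  A sensitivity analysis
perturbs the seven excitability gains uniformly by a fraction zeta and
checks whether the four regime signatures (NS/LFS/IFS/HFS feature
vectors) are preserved under nearest-centroid assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import feature_extraction as fx
from . import model_core as mc
from .stimulation import StimProtocol

__all__ = [
    "FiringSummary",
    "SweepResult",
    "SensitivityReport",
    "lambda_threshold",
    "htolr",
    "frequency_sweep",
    "phase_portrait",
    "sensitivity_analysis",
    "THETA_PARAMS",
]

#: The seven excitability gains perturbed in the sensitivity study.
THETA_PARAMS = ("A_C", "B_C", "G_C", "A_Th", "B_Th", "G_Th", "A_Rt")


@dataclass
class FiringSummary:
    lambda_thr: float
    delta1: float            # seconds below Lambda
    delta2: float            # seconds above Lambda
    htolr: float             # Delta2 / Delta1 (inf when Delta1 == 0)
    saturated: bool = False  # True when Delta1 == 0


@dataclass
class SweepResult:
    freqs: np.ndarray
    htolr_curve: np.ndarray
    lambda_thr: float
    jump_freq: float | None
    zero_band: float | None
    delta1: np.ndarray
    delta2: np.ndarray
    seeds: list[int] = field(default_factory=list)


@dataclass
class SensitivityReport:
    zetas: list[float]
    theta0: dict[str, float]
    n_draws: int
    conditions: list[str]
    preserved_fraction: dict[float, dict[str, float]]
    n_diverged: int = 0


def lambda_threshold(ns_rate: np.ndarray) -> float:
    """Reference firing level: median of the no-stimulation TC rate series."""
    ns_rate = np.asarray(ns_rate, dtype=np.float64)
    if ns_rate.size == 0:
        raise ValueError("empty rate series")
    return float(np.median(ns_rate))


def htolr(rate: np.ndarray, lambda_thr: float, dt: float) -> FiringSummary:
    """Up-state / down-state time ratio of a firing-rate series.

    Samples exactly at the threshold belong to neither interval, so
    ``delta1 + delta2 <= duration`` with equality except for ties.
    """
    rate = np.asarray(rate, dtype=np.float64)
    if rate.size == 0:
        raise ValueError("empty rate series")
    d2 = float(np.count_nonzero(rate > lambda_thr)) * dt
    d1 = float(np.count_nonzero(rate < lambda_thr)) * dt
    if d1 == 0.0:
        return FiringSummary(lambda_thr, d1, d2, float("inf"), saturated=True)
    return FiringSummary(lambda_thr, d1, d2, d2 / d1)


def _detect_jump(freqs: np.ndarray, curve: np.ndarray) -> float | None:
    """Midpoint of the largest single-step increase (ties -> lower frequency)."""
    finite = np.isfinite(curve)
    if finite.sum() < 2:
        return None
    steps = np.diff(curve)
    steps = np.where(np.isfinite(steps), steps, -np.inf)
    if np.all(steps <= 0):
        return None
    i = int(np.argmax(steps))
    return float(0.5 * (freqs[i] + freqs[i + 1]))


def _detect_zero_band(freqs: np.ndarray, curve: np.ndarray,
                      tol: float = 0.0) -> float | None:
    """Lowest frequency beyond which the ratio stays at zero."""
    zero = curve <= tol
    if not zero[-1]:
        return None
    i = len(zero) - 1
    while i > 0 and zero[i - 1]:
        i -= 1
    return float(freqs[i])


def frequency_sweep(
    params: mc.ModelParameters,
    freqs: np.ndarray | None = None,
    seg_duration: float = 20.0,
    burn_in: float = 2.0,
    seeds: tuple[int, ...] | list[int] = (0, 1, 2),
    **protocol_kwargs,
) -> SweepResult:
    """HtoLR of the TC firing rate as a function of stimulation frequency.

    Lambda is computed once from the no-stimulation runs (same seeds) and
    reused at every frequency; per frequency the up/down times of the
    individual seeds are pooled before forming the ratio.  The jump
    frequency is the midpoint of the largest single-step increase of the
    curve, and the zero band the lowest frequency after which the ratio
    stays at zero.
    """
    if freqs is None:
        freqs = np.arange(0.0, 150.0 + 1e-9, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(np.diff(freqs) <= 0) or freqs.min() < 0 or freqs.max() > 150:
        raise ValueError("frequency grid must be strictly increasing in [0, 150]")
    seeds = list(seeds)
    duration = burn_in + seg_duration
    dt_out = 1.0 / mc.OUTPUT_RATE

    ns_rates = [
        mc.simulate(params, None, duration=duration, seed=s).trim(burn_in).rate["TC"]
        for s in seeds
    ]
    lam = lambda_threshold(np.concatenate(ns_rates))

    curve = np.empty_like(freqs)
    d1s = np.empty_like(freqs)
    d2s = np.empty_like(freqs)
    for i, f in enumerate(freqs):
        d1 = d2 = 0.0
        for s, ns_rate in zip(seeds, ns_rates):
            if f == 0.0:
                rate = ns_rate
            else:
                res = mc.simulate(
                    params, StimProtocol(f_s=float(f), **protocol_kwargs),
                    duration=duration, seed=s)
                rate = res.trim(burn_in).rate["TC"]
            summ = htolr(rate, lam, dt_out)
            d1 += summ.delta1
            d2 += summ.delta2
        d1s[i], d2s[i] = d1, d2
        curve[i] = d2 / d1 if d1 > 0 else np.inf
    return SweepResult(
        freqs=freqs,
        htolr_curve=curve,
        lambda_thr=lam,
        jump_freq=_detect_jump(freqs, curve),
        zero_band=_detect_zero_band(freqs, curve),
        delta1=d1s,
        delta2=d2s,
        seeds=seeds,
    )


def phase_portrait(lfp_cortex: np.ndarray, rate_tc: np.ndarray) -> np.ndarray:
    """Paired (TC firing, cortical LFP) trajectory for phase-plane plots."""
    lfp = np.asarray(lfp_cortex, dtype=np.float64)
    rate = np.asarray(rate_tc, dtype=np.float64)
    if lfp.shape != rate.shape:
        raise ValueError("traces must share one time grid")
    return np.column_stack([rate, lfp])


# ---------------------------------------------------------------------------
# Sensitivity to excitability perturbations
# ---------------------------------------------------------------------------

#: Default stimulation frequency per condition of the sensitivity study.
SENSITIVITY_CONDITIONS = {"NS": 0.0, "LFS": 2.0, "IFS": 50.0, "HFS": 100.0}

#: Conditions whose feature vectors belong to one regime cluster; a draw
#: is preserved when its nearest reference centroid lies in the same
#: group as its own condition.
CONDITION_GROUPS = [{"NS", "IFS"}, {"LFS"}, {"HFS"}]


def _condition_feature(params, f_s, n_segments, seg_duration, burn_in, seed,
                       dico, max_atoms, min_residual_fraction):
    protocol = None if f_s == 0 else StimProtocol(f_s=f_s)
    segs, _ = mc.simulate_segments(
        params, protocol, n_segments, seg_duration, burn_in=burn_in, seed=seed)
    feats = [
        fx.band_features(seg, mc.OUTPUT_RATE, dictionary=dico,
                         max_atoms=max_atoms,
                         min_residual_fraction=min_residual_fraction).e
        for seg in segs
    ]
    return np.mean(feats, axis=0)


def sensitivity_analysis(
    theta0: mc.ModelParameters,
    zetas: list[float],
    n_draws: int = 20,
    conditions: dict[str, float] | None = None,
    seed: int = 0,
    n_segments: int = 2,
    seg_duration: float = 5.0,
    burn_in: float = 2.0,
    max_atoms: int = 60,
    min_residual_fraction: float = 0.05,
) -> SensitivityReport:
    """Robustness of the regime signatures to excitability perturbations.

    For each zeta, ``n_draws`` parameter vectors are drawn with every
    component of Theta = (A_C, B_C, G_C, A_Th, B_Th, G_Th, A_Rt)
    multiplied by an independent uniform factor in [1-zeta, 1+zeta].
    Each perturbed model is simulated under every condition with the same
    noise seed as the unperturbed reference run (a paired design, so the
    identity perturbation reproduces the reference exactly), and its
    feature vector is assigned to the nearest reference centroid; the
    draw is preserved for a condition when that centroid's condition lies
    in the same regime group.  Diverged runs count as not preserved.
    """
    conditions = SENSITIVITY_CONDITIONS if conditions is None else conditions
    if any(not (0 <= z < 1) for z in zetas):
        raise ValueError("zeta values must lie in [0, 1)")
    if n_draws < 1:
        raise ValueError("need at least one draw")
    cond_names = list(conditions)
    group_of = {c: i for i, g in enumerate(CONDITION_GROUPS) for c in g}
    for c in cond_names:
        if c not in group_of:
            raise ValueError(f"no regime group defined for condition {c!r}")

    n_samples = int(round(seg_duration * mc.OUTPUT_RATE))
    dico = fx.build_dictionary(n_samples, mc.OUTPUT_RATE)
    seeds = mc.spawn_seeds(seed, len(cond_names))
    refs = {
        c: _condition_feature(theta0, conditions[c], n_segments, seg_duration,
                              burn_in, s, dico, max_atoms,
                              min_residual_fraction)
        for c, s in zip(cond_names, seeds)
    }
    ref_matrix = np.vstack([refs[c] for c in cond_names])

    rng = np.random.default_rng(seed)
    preserved = {z: {c: 0 for c in cond_names} for z in zetas}
    n_div = 0
    for z in zetas:
        for d in range(n_draws):
            factors = rng.uniform(1.0 - z, 1.0 + z, size=len(THETA_PARAMS))
            overrides = {
                name: getattr(theta0, name) * f
                for name, f in zip(THETA_PARAMS, factors)
            }
            perturbed = theta0.copy(**overrides)
            for ci, c in enumerate(cond_names):
                try:
                    v = _condition_feature(
                        perturbed, conditions[c], n_segments, seg_duration,
                        burn_in, seeds[ci], dico, max_atoms,
                        min_residual_fraction)
                except mc.SimulationDiverged:
                    n_div += 1
                    continue
                nearest = cond_names[int(np.argmin(
                    np.linalg.norm(ref_matrix - v, axis=1)))]
                if group_of[nearest] == group_of[c]:
                    preserved[z][c] += 1
    return SensitivityReport(
        zetas=list(zetas),
        theta0={name: getattr(theta0, name) for name in THETA_PARAMS},
        n_draws=n_draws,
        conditions=cond_names,
        preserved_fraction={
            z: {c: preserved[z][c] / n_draws for c in cond_names} for z in zetas
        },
        n_diverged=n_div,
    )
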