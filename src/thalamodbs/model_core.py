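"""Neural mass model of the thalamocortical loop.

Three interconnected compartments are simulated at the population level:

* cortex: pyramidal cells ``P`` (plus the Jansen-style collateral
  excitatory loop through a virtual subpopulation ``P'``) and two
  GABAergic interneuron populations, ``IC1`` (soma-targeting, fast
  GABA_A kinetics) and ``IC2`` (dendrite-targeting, slow kinetics);
* thalamus: excitatory thalamocortical relay cells ``TC``;
* reticular nucleus: two GABAergic populations ``Rt1`` (fast) and
  ``Rt2`` (slow) inhibiting the relay cells.

Every synaptic pathway is a second-order "pulse-to-wave" filter with
impulse response ``h(t) = (W / tau_w) * t * exp(-t / tau_w)`` (peak
``W * exp(-1)`` at ``t = tau_w``) driven by the connectivity-scaled
presynaptic firing rate; each population's firing rate is the static
sigmoid of the sum of its postsynaptic potentials.  Thalamic input to the
pyramidal population passes through a synapse subject to short-term
depression (gain ``kappa(t) * A_C``, see :mod:`thalamodbs.plasticity_std`),
and thalamic relay cells directly excite cortical interneurons, which is
the structural substrate of feed-forward inhibition.  DBS enters as an
additive depolarization of TC, Rt1 and Rt2
(:mod:`thalamodbs.stimulation`).

The system is integrated with a fixed-step classical Runge-Kutta (RK4)
scheme; stochastic inputs are Gaussian pulse-density noises held constant
within a step and scaled so that their spectral density is independent of
the integration step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np
from numba import njit
from scipy.optimize import brentq

from . import stimulation as _stim
from .plasticity_std import StdParams, _kappa_step, lowpass_coefficients
from .stimulation import StimProtocol

__all__ = [
    "SynapticKernel",
    "SigmoidParams",
    "ModelParameters",
    "SimulationResult",
    "SimulationDiverged",
    "psp_impulse_response",
    "kernel_decay_factor",
    "sigmoid_rate",
    "default_parameters",
    "simulate",
    "simulate_segments",
    "POPULATIONS",
    "NOISE_REF_RATE",
    "DEFAULT_DT",
    "OUTPUT_RATE",
]

#: Population labels, in storage order.
POPULATIONS = ("P", "IC1", "IC2", "TC", "Rt1", "Rt2")

#: Reference sampling rate (Hz) at which the noise SDs of the parameter
#: table are defined; per-step noise is scaled by 1/sqrt(rate*dt) so the
#: injected spectral density does not depend on the integration step.
NOISE_REF_RATE = 512.0

#: Default integration step (s) and output sampling rate (Hz).
DEFAULT_DT = 1.0 / 4096.0
OUTPUT_RATE = 512.0


# ---------------------------------------------------------------------------
# Elementary building blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapticKernel:
    """Second-order PSP kernel with gain ``W`` (mV) and time constant ``tau_w`` (s)."""

    W: float
    tau_w: float

    def __post_init__(self):
        if self.W <= 0 or self.tau_w <= 0:
            raise ValueError("kernel gain and time constant must be positive")


@dataclass(frozen=True)
class SigmoidParams:
    """Wave-to-pulse sigmoid: ``S(v) = 2 e0 / (1 + exp(r (v0 - v)))``."""

    e0: float = 2.5
    v0: float = 6.0
    r: float = 0.56


def psp_impulse_response(kernel: SynapticKernel, t: np.ndarray | float) -> np.ndarray:
    """Impulse response ``h(t) = (W/tau_w) t exp(-t/tau_w)`` of a synapse.

    ``h`` vanishes at the onset and peaks at ``W exp(-1)`` for
    ``t = tau_w``; negative times are rejected.
    """
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("time grid must be non-negative")
    return (kernel.W / kernel.tau_w) * t * np.exp(-t / kernel.tau_w)


def kernel_decay_factor() -> float:
    """Decay time of the PSP kernel in units of ``tau_w``.

    Numerically solves ``h(t) = h(tau_w)/e`` for the root beyond the peak
    (dimensionless equation ``x exp(-x) = exp(-2)``).  The classical value
    is 3.146.
    """
    f = lambda x: x * math.exp(-x) - math.exp(-2.0)
    return brentq(f, 1.0 + 1e-9, 20.0, xtol=1e-12)


def sigmoid_rate(v: np.ndarray | float, p: SigmoidParams = SigmoidParams()) -> np.ndarray | float:
    """Average firing rate for a mean membrane potential (saturates at ``2 e0``)."""
    return 2.0 * p.e0 / (1.0 + np.exp(p.r * (p.v0 - np.asarray(v, dtype=np.float64))))


# ---------------------------------------------------------------------------
# Parameter set
# ---------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """Full parameter set of the thalamocortical loop model.

    Defaults reproduce the published table for the pathological
    (optimized) regime; connectivity constants ``C_src_tgt`` weight the
    presynaptic firing rate of each pathway.  ``Pp`` denotes the virtual
    excitatory subpopulation of the pyramidal collateral loop.
    """

    # synaptic gains (mV)
    A_C: float = 6.0
    B_C: float = 14.0
    G_C: float = 16.5
    A_Th: float = 3.5
    B_Th: float = 30.0
    G_Th: float = 22.0
    A_Rt: float = 3.5
    # time constants (s)
    tau_ac: float = 1.0 / 80.0
    tau_bc: float = 1.0 / 35.0
    tau_gc: float = 1.0 / 180.0
    tau_aTh: float = 1.0 / 100.0
    tau_bTh: float = 1.0 / 20.0
    tau_gTh: float = 1.0 / 150.0
    tau_aRt: float = 1.0 / 100.0
    # sigmoid
    e0: float = 2.5
    v0: float = 6.0
    r: float = 0.56
    # connectivity constants
    C_P_Pp: float = 135.0
    C_Pp_P: float = 108.0
    C_P_IC2: float = 33.75
    C_IC2_P: float = 33.75
    C_P_IC1: float = 40.5
    C_IC2_IC1: float = 13.5
    C_IC1_P: float = 91.125
    C_TC_P: float = 120.0
    C_TC_IC1: float = 30.0
    C_TC_IC2: float = 45.0
    C_TC_Rt1: float = 20.0
    C_TC_Rt2: float = 20.0
    C_P_Rt1: float = 30.0
    C_P_Rt2: float = 30.0
    C_P_TC: float = 20.0
    C_Rt1_TC: float = 35.0
    C_Rt2_TC: float = 5.0
    # nonspecific inputs (pulse density, s^-1); SDs defined at 512 Hz sampling
    mu_P1: float = 0.0
    mu_P2: float = 70.0
    sigma_P1: float = 20.6
    sigma_P2: float = 35.6
    # stimulation impact weights
    S_TC: float = 5.0
    S_Rt1: float = 4.0
    S_Rt2: float = 4.0
    # short-term depression of the TC->P synapse
    std: StdParams = field(default_factory=StdParams)

    def validate(self) -> None:
        for f in fields(self):
            if f.name == "std":
                continue
            v = getattr(self, f.name)
            if f.name.startswith("tau") and v <= 0:
                raise ValueError(f"{f.name} must be positive")
            if v < 0 and f.name not in ("mu_P1", "mu_P2"):
                raise ValueError(f"{f.name} must be non-negative")
        self.std.validate()

    def copy(self, **overrides) -> "ModelParameters":
        std = overrides.pop("std", replace(self.std))
        return replace(self, std=std, **overrides)

    def sigmoid(self) -> SigmoidParams:
        return SigmoidParams(self.e0, self.v0, self.r)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "std"}
        d.update(
            eta=self.std.eta,
            tau_std=self.std.tau_std,
            std_window=self.std.window,
            kappa_floor=self.std.floor,
            lp_cutoff=self.std.lp_cutoff,
            std_enabled=self.std.enabled,
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        d = dict(d)
        std = StdParams(
            eta=d.pop("eta", 0.8),
            tau_std=d.pop("tau_std", 8.0),
            window=d.pop("std_window", 0.45),
            floor=d.pop("kappa_floor", 0.6),
            lp_cutoff=d.pop("lp_cutoff", 10.0),
            enabled=bool(d.pop("std_enabled", True)),
        )
        valid = {f.name for f in fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(std=std, **d)

    def without_ffi(self) -> "ModelParameters":
        """Ablate feed-forward inhibition (thalamic drive to interneurons)."""
        return self.copy(C_TC_IC1=0.0, C_TC_IC2=0.0)

    def without_std(self) -> "ModelParameters":
        """Ablate short-term depression (static TC->P synapse)."""
        return self.copy(std=replace(self.std, enabled=False))


#: Named excitability presets (cortical EPSP/IPSP gains).
PRESETS = {
    "pathological": dict(A_C=6.0, B_C=14.0, G_C=16.5),
    "normal": dict(A_C=3.0, B_C=50.0, G_C=22.0),
}


def default_parameters(preset: str = "pathological") -> ModelParameters:
    """Parameter set of the published table for a named excitability preset."""
    try:
        overrides = PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}"
        ) from None
    return ModelParameters(**overrides)


# ---------------------------------------------------------------------------
# Integrator
# ---------------------------------------------------------------------------
#
# Filter bank (13 second-order pathways); state is (y, dy/dt) per filter.
#
#  idx  kernel            drive                                  target
#   0   (A_C, tau_ac)     C_Pp_P*r_Pp + p_P(t)                    +v_P
#   1   (k*A_C, tau_ac)   C_TC_P*r_TC        (STD-modulated)      +v_P
#   2   (G_C, tau_gc)     C_IC1_P*r_IC1                           -v_P
#   3   (B_C, tau_bc)     C_IC2_P*r_IC2                           -v_P
#   4   (A_C, tau_ac)     C_P_Pp*r_P                              v_Pp
#   5   (A_C, tau_ac)     C_P_IC1*r_P + C_TC_IC1*r_TC             +v_IC1
#   6   (B_C, tau_bc)     C_IC2_IC1*r_IC2                         -v_IC1
#   7   (A_C, tau_ac)     C_P_IC2*r_P + C_TC_IC2*r_TC             v_IC2
#   8   (A_Th, tau_aTh)   C_P_TC*r_P + p_TC(t)                    +v_TC
#   9   (G_Th, tau_gTh)   C_Rt1_TC*r_Rt1                          -v_TC
#  10   (B_Th, tau_bTh)   C_Rt2_TC*r_Rt2                          -v_TC
#  11   (A_Rt, tau_aRt)   C_P_Rt1*r_P + C_TC_Rt1*r_TC             v_Rt1
#  12   (A_Rt, tau_aRt)   C_P_Rt2*r_P + C_TC_Rt2*r_TC             v_Rt2
#
# Stimulation adds S_TC*u, S_Rt1*u, S_Rt2*u directly to v_TC, v_Rt1, v_Rt2.

_N_FILT = 13


def _pack(params: ModelParameters, weights: tuple[float, float, float]) -> np.ndarray:
    p = params
    W = [p.A_C, p.A_C, p.G_C, p.B_C, p.A_C, p.A_C, p.B_C, p.A_C,
         p.A_Th, p.G_Th, p.B_Th, p.A_Rt, p.A_Rt]
    tau = [p.tau_ac, p.tau_ac, p.tau_gc, p.tau_bc, p.tau_ac, p.tau_ac,
           p.tau_bc, p.tau_ac, p.tau_aTh, p.tau_gTh, p.tau_bTh,
           p.tau_aRt, p.tau_aRt]
    conn = [p.C_Pp_P, p.C_TC_P, p.C_IC1_P, p.C_IC2_P, p.C_P_Pp,
            p.C_P_IC1, p.C_TC_IC1, p.C_IC2_IC1, p.C_P_IC2, p.C_TC_IC2,
            p.C_P_TC, p.C_Rt1_TC, p.C_Rt2_TC, p.C_P_Rt1, p.C_TC_Rt1,
            p.C_P_Rt2, p.C_TC_Rt2]
    sig = [p.e0, p.v0, p.r]
    return np.array(W + tau + conn + sig + list(weights), dtype=np.float64)


@njit(cache=True, inline="always")
def _sig(v, e0, v0, r):  # pragma: no cover - jitted
    return 2.0 * e0 / (1.0 + np.exp(r * (v0 - v)))


@njit(cache=True)
def _accel(y, z, u, p_p, p_tc, kap, P, drv, out):  # pragma: no cover - jitted
    """Second derivatives of the 13 pathway filters at state (y, z)."""
    e0 = P[43]; v0 = P[44]; r = P[45]
    s_tc = P[46]; s_rt1 = P[47]; s_rt2 = P[48]
    v_p = y[0] + y[1] - y[2] - y[3]
    v_pp = y[4]
    v_i1 = y[5] - y[6]
    v_i2 = y[7]
    v_tc = y[8] - y[9] - y[10] + s_tc * u
    v_r1 = y[11] + s_rt1 * u
    v_r2 = y[12] + s_rt2 * u
    r_p = _sig(v_p, e0, v0, r)
    r_pp = _sig(v_pp, e0, v0, r)
    r_i1 = _sig(v_i1, e0, v0, r)
    r_i2 = _sig(v_i2, e0, v0, r)
    r_tc = _sig(v_tc, e0, v0, r)
    r_r1 = _sig(v_r1, e0, v0, r)
    r_r2 = _sig(v_r2, e0, v0, r)
    drv[0] = P[26] * r_pp + p_p          # collateral + cortical noise
    drv[1] = P[27] * r_tc                # TC -> P (STD-gated)
    drv[2] = P[28] * r_i1
    drv[3] = P[29] * r_i2
    drv[4] = P[30] * r_p
    drv[5] = P[31] * r_p + P[32] * r_tc
    drv[6] = P[33] * r_i2
    drv[7] = P[34] * r_p + P[35] * r_tc
    drv[8] = P[36] * r_p + p_tc          # cortical drive + subcortical noise
    drv[9] = P[37] * r_r1
    drv[10] = P[38] * r_r2
    drv[11] = P[39] * r_p + P[40] * r_tc
    drv[12] = P[41] * r_p + P[42] * r_tc
    for k in range(13):
        w = P[k]
        if k == 1:
            w = kap * w
        tau = P[13 + k]
        out[k] = (w / tau) * drv[k] - (2.0 / tau) * z[k] - y[k] / (tau * tau)


@njit(cache=True)
def _integrate(n_steps, dt, P, std_par, bq_b, bq_a, p_p, p_tc, u,
               stride, n_out):  # pragma: no cover - jitted
    y = np.zeros(_N_FILT)
    z = np.zeros(_N_FILT)
    a1 = np.empty(_N_FILT); a2 = np.empty(_N_FILT)
    a3 = np.empty(_N_FILT); a4 = np.empty(_N_FILT)
    yt = np.empty(_N_FILT); zt = np.empty(_N_FILT)
    z2s = np.empty(_N_FILT); z3s = np.empty(_N_FILT)
    drv = np.empty(_N_FILT)
    y_out = np.empty((n_out, _N_FILT))
    kappa_out = np.empty(n_out)

    eta = std_par[0]; tau_std = std_par[1]; window = std_par[2]
    floor = std_par[3]; std_on = std_par[4] > 0.5
    e0 = P[43]; v0 = P[44]; r = P[45]; s_tc = P[46]

    kappa = 1.0
    kappa_eta = 1.0
    t_eta = -1e30
    t_end = -1e30
    prev_df = 0.0
    s1 = 0.0; s2 = 0.0  # biquad state (direct form II transposed)
    b0 = bq_b[0]; b1 = bq_b[1]; b2 = bq_b[2]
    ac1 = bq_a[1]; ac2 = bq_a[2]

    half = 0.5 * dt
    sixth = dt / 6.0
    status = 0
    fail_step = -1

    for i in range(n_steps):
        ui = u[i]
        # --- short-term depression bookkeeping (at the step's start time)
        v_tc = y[8] - y[9] - y[10] + s_tc * ui
        d_ap = _sig(v_tc, e0, v0, r)
        df = b0 * d_ap + s1
        s1 = b1 * d_ap - ac1 * df + s2
        s2 = b2 * d_ap - ac2 * df
        if std_on:
            if i == 0:
                prev_df = eta if df > eta else df
            kappa, kappa_eta, t_eta, t_end = _kappa_step(
                kappa, kappa_eta, t_eta, t_end, prev_df, df, i * dt, dt,
                eta, tau_std, window, floor)
            prev_df = df

        if i % stride == 0:
            j = i // stride
            for k in range(_N_FILT):
                y_out[j, k] = y[k]
            kappa_out[j] = kappa
            ok = True
            for k in range(_N_FILT):
                if not np.isfinite(y[k]):
                    ok = False
            if not ok:
                status = 1
                fail_step = i
                break

        # --- RK4 step with inputs held constant over the step
        pp = p_p[i]; pt = p_tc[i]
        _accel(y, z, ui, pp, pt, kappa, P, drv, a1)
        for k in range(_N_FILT):
            yt[k] = y[k] + half * z[k]
            z2s[k] = z[k] + half * a1[k]
        _accel(yt, z2s, ui, pp, pt, kappa, P, drv, a2)
        for k in range(_N_FILT):
            yt[k] = y[k] + half * z2s[k]
            z3s[k] = z[k] + half * a2[k]
        _accel(yt, z3s, ui, pp, pt, kappa, P, drv, a3)
        for k in range(_N_FILT):
            yt[k] = y[k] + dt * z3s[k]
            zt[k] = z[k] + dt * a3[k]
        _accel(yt, zt, ui, pp, pt, kappa, P, drv, a4)
        for k in range(_N_FILT):
            y[k] += sixth * (z[k] + 2.0 * z2s[k] + 2.0 * z3s[k] + zt[k])
            z[k] += sixth * (a1[k] + 2.0 * a2[k] + 2.0 * a3[k] + a4[k])

    return y_out, kappa_out, status, fail_step


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

class SimulationDiverged(RuntimeError):
    """Raised when the state becomes non-finite; carries the failure time."""

    def __init__(self, t_fail: float):
        super().__init__(f"simulation state diverged at t = {t_fail:.4f} s")
        self.t_fail = t_fail


@dataclass
class SimulationResult:
    """Uniformly sampled traces produced by :func:`simulate`.

    ``lfp_cortex`` / ``lfp_thalamus`` are the summed postsynaptic
    potentials on P and TC (the stimulation artifact is excluded from the
    LFPs but included in the membrane potentials ``v``); ``rate[X]`` is
    the pointwise sigmoid of ``v[X]``.
    """

    t: np.ndarray
    lfp_cortex: np.ndarray
    lfp_thalamus: np.ndarray
    v: dict[str, np.ndarray]
    rate: dict[str, np.ndarray]
    kappa: np.ndarray
    u_stim: np.ndarray
    meta: dict

    @property
    def fs(self) -> float:
        return float(self.meta["output_rate"])

    def trim(self, burn_in: float) -> "SimulationResult":
        """Drop the initial ``burn_in`` seconds (integration transient)."""
        i0 = int(round(burn_in * self.fs))
        return SimulationResult(
            t=self.t[i0:],
            lfp_cortex=self.lfp_cortex[i0:],
            lfp_thalamus=self.lfp_thalamus[i0:],
            v={k: a[i0:] for k, a in self.v.items()},
            rate={k: a[i0:] for k, a in self.rate.items()},
            kappa=self.kappa[i0:],
            u_stim=self.u_stim[i0:],
            meta={**self.meta, "burn_in_removed": burn_in},
        )

    def to_frame(self):
        """All traces as a pandas DataFrame (one column per trace)."""
        import pandas as pd

        cols = {"t": self.t, "lfp_cortex": self.lfp_cortex,
                "lfp_thalamus": self.lfp_thalamus}
        for k in POPULATIONS:
            cols[f"v_{k}"] = self.v[k]
        for k in POPULATIONS:
            cols[f"rate_{k}"] = self.rate[k]
        cols["kappa"] = self.kappa
        cols["u_stim"] = self.u_stim
        return pd.DataFrame(cols)


def simulate(
    params: ModelParameters,
    protocol: StimProtocol | None = None,
    duration: float = 30.0,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    output_rate: float = OUTPUT_RATE,
) -> SimulationResult:
    """Integrate the full thalamocortical model.

    Parameters
    ----------
    params : ModelParameters
        Model parameter set (see :func:`default_parameters`).
    protocol : StimProtocol or None
        DBS pulse-train description; None means no stimulation.
    duration : float
        Simulated time in seconds (includes any burn-in the caller wants
        to discard afterwards with :meth:`SimulationResult.trim`).
    dt : float
        Integration step; must divide the output sampling period.  With a
        pulse protocol the step must resolve the 1 ms pulses
        (dt <= pulse_width / 2).
    seed : int
        Seed of the Gaussian pulse-density noises; identical seeds give
        identical outputs.
    output_rate : float
        Rate (Hz) at which traces are stored.
    """
    params.validate()
    if duration <= 0:
        raise ValueError("duration must be positive")
    stride_f = 1.0 / (dt * output_rate)
    stride = int(round(stride_f))
    if stride < 1 or abs(stride_f - stride) > 1e-9:
        raise ValueError("dt must divide the output sampling period")
    n_out = int(round(duration * output_rate))
    n_steps = n_out * stride

    weights = (params.S_TC, params.S_Rt1, params.S_Rt2)
    if protocol is not None:
        protocol.validate()
        if dt > protocol.pulse_width / 2.0:
            raise ValueError("dt must resolve the stimulation pulses")
        if protocol.weights is not None:
            weights = protocol.weights
        u = _stim.build_stim_signal(protocol, duration, dt)
        if u.shape[0] < n_steps:
            u = np.concatenate([u, np.zeros(n_steps - u.shape[0])])
        u = u[:n_steps]
    else:
        u = np.zeros(n_steps)

    rng = np.random.default_rng(seed)
    scale = 1.0 / math.sqrt(NOISE_REF_RATE * dt)
    p_p = params.mu_P1 + params.sigma_P1 * scale * rng.standard_normal(n_steps)
    p_tc = params.mu_P2 + params.sigma_P2 * scale * rng.standard_normal(n_steps)

    bq_b, bq_a = lowpass_coefficients(params.std.lp_cutoff, dt,
                                      order=params.std.lp_order)
    std_par = np.array(
        [params.std.eta, params.std.tau_std, params.std.window,
         params.std.floor, 1.0 if params.std.enabled else 0.0]
    )
    P = _pack(params, weights)

    y_out, kappa_out, status, fail_step = _integrate(
        n_steps, dt, P, std_par, bq_b, bq_a, p_p, p_tc, u, stride, n_out)
    if status != 0:
        raise SimulationDiverged(fail_step * dt)

    u_out = u[::stride][:n_out]
    t = np.arange(n_out) / output_rate
    lfp_c = y_out[:, 0] + y_out[:, 1] - y_out[:, 2] - y_out[:, 3]
    lfp_t = y_out[:, 8] - y_out[:, 9] - y_out[:, 10]
    v = {
        "P": lfp_c,
        "IC1": y_out[:, 5] - y_out[:, 6],
        "IC2": y_out[:, 7],
        "TC": lfp_t + params.S_TC * u_out,
        "Rt1": y_out[:, 11] + params.S_Rt1 * u_out,
        "Rt2": y_out[:, 12] + params.S_Rt2 * u_out,
    }
    if protocol is not None and protocol.weights is not None:
        s_tc, s_r1, s_r2 = protocol.weights
        v["TC"] = lfp_t + s_tc * u_out
        v["Rt1"] = y_out[:, 11] + s_r1 * u_out
        v["Rt2"] = y_out[:, 12] + s_r2 * u_out
    sig = params.sigmoid()
    rate = {k: np.asarray(sigmoid_rate(a, sig)) for k, a in v.items()}
    meta = {
        "seed": int(seed),
        "dt": float(dt),
        "duration": float(duration),
        "output_rate": float(output_rate),
        "protocol": None if protocol is None else {
            "f_s": protocol.f_s, "A_fs": protocol.A_fs,
            "pulse_width": protocol.pulse_width, "tau_rep": protocol.tau_rep,
            "t_on": protocol.t_on, "t_off": protocol.t_off,
            "weights": list(weights),
        },
    }
    return SimulationResult(t, lfp_c, lfp_t, v, rate, kappa_out, u_out, meta)


def simulate_segments(
    params: ModelParameters,
    protocol: StimProtocol | None,
    n_segments: int,
    seg_duration: float,
    burn_in: float = 2.0,
    seed: int = 0,
    **kwargs,
) -> tuple[list[np.ndarray], SimulationResult]:
    """One long run cut into equal cortical-LFP segments after burn-in."""
    duration = burn_in + n_segments * seg_duration
    res = simulate(params, protocol, duration=duration, seed=seed, **kwargs)
    trimmed = res.trim(burn_in)
    n_seg_samples = int(round(seg_duration * res.fs))
    segs = [
        trimmed.lfp_cortex[i * n_seg_samples:(i + 1) * n_seg_samples].copy()
        for i in range(n_segments)
    ]
    return segs, res


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) derived from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
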