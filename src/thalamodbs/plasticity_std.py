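"""Short-term depression (STD) of the thalamocortical synapse.

The efficacy of the TC -> P glutamatergic projection is modulated by a
time-varying coefficient ``kappa(t)`` that multiplies the cortical EPSP
gain ``A_C``.  The coefficient is driven by the density of action
potentials arriving from the thalamus: the TC firing-rate signal is
low-pass filtered (10 Hz cutoff, restricting the effect to low-frequency
drive), and whenever the filtered signal exceeds a threshold ``eta`` the
coefficient decays exponentially with time constant ``tau_std``.  Each
decay episode lasts at most ``window`` seconds, but while the drive stays
suprathreshold episodes chain back-to-back, so a sustained drive produces
a continuous exponential decay down to the hard floor ``kappa = 0.6``
(i.e. the EPSP drop saturates at 40 %).  Outside active episodes kappa
recovers toward 1 with the same time constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import butter, lfilter

__all__ = [
    "StdParams",
    "KappaState",
    "lowpass_firing",
    "lowpass_coefficients",
    "kappa_trajectory",
]


@dataclass
class StdParams:
    """Parameters of the phenomenological depression dynamics.

    Attributes
    ----------
    eta : float
        Firing-rate threshold (s^-1) on the filtered thalamic output above
        which depression is engaged.
    tau_std : float
        Exponential decay / recovery time constant (s).
    window : float
        Duration (s) of a single decay episode after a threshold crossing.
    floor : float
        Hard lower bound of kappa; ``1 - floor`` is the maximal fractional
        EPSP drop (0.4 by default).
    lp_cutoff : float
        Cutoff (Hz) of the causal low-pass applied to the firing-rate
        signal before threshold detection.
    lp_order : int
        Order of the low-pass (1 = single-pole, 2 = Butterworth).  The
        single-pole default responds quickly enough to register the brief
        stimulus-locked thalamic bursts that engage depression at
        low-frequency stimulation while still averaging out fast drive.
    enabled : bool
        When False the synapse is static (kappa identically 1); used for
        mechanism-ablation experiments.
    """

    eta: float = 0.8
    tau_std: float = 8.0
    window: float = 0.45
    floor: float = 0.6
    lp_cutoff: float = 10.0
    lp_order: int = 1
    enabled: bool = True

    def validate(self) -> None:
        if not (0.0 < self.floor <= 1.0):
            raise ValueError("kappa floor must lie in (0, 1]")
        if self.window <= 0.0:
            raise ValueError("decay window must be positive")
        if self.tau_std <= 0.0:
            raise ValueError("tau_std must be positive")
        if self.lp_cutoff <= 0.0:
            raise ValueError("lp_cutoff must be positive")


@dataclass
class KappaState:
    """Instantaneous state of the depression variable."""

    kappa: float = 1.0
    t_eta: float = -np.inf
    kappa_eta: float = 1.0
    active: bool = False


def lowpass_coefficients(cutoff: float, dt: float,
                         order: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Causal low-pass (b, a) at sampling step ``dt``, padded to biquad form.

    ``order=1`` gives a single-pole filter with pole at ``exp(-2*pi*fc*dt)``,
    ``order=2`` a Butterworth; both have unit DC gain.
    """
    nyquist = 0.5 / dt
    if cutoff >= nyquist:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    if order == 1:
        pole = np.exp(-2.0 * np.pi * cutoff * dt)
        b = np.array([1.0 - pole, 0.0, 0.0])
        a = np.array([1.0, -pole, 0.0])
    elif order == 2:
        b, a = butter(2, cutoff, fs=1.0 / dt)
    else:
        raise ValueError("filter order must be 1 or 2")
    return np.ascontiguousarray(b, dtype=np.float64), np.ascontiguousarray(a, dtype=np.float64)


def lowpass_firing(d_ap: np.ndarray, cutoff: float, dt: float,
                   order: int = 1) -> np.ndarray:
    """Causally low-pass filter a uniformly sampled firing-rate series."""
    b, a = lowpass_coefficients(cutoff, dt, order=order)
    return lfilter(b, a, np.asarray(d_ap, dtype=np.float64))


@njit(cache=True)
def _kappa_step(kappa, kappa_eta, t_eta, t_end, prev_df, df, t, dt,
                eta, tau_std, window, floor):  # pragma: no cover - jitted
    """Advance the kappa state by one sample.

    A decay episode starts at an upward crossing of ``eta`` (anchor
    ``t_eta``, level ``kappa_eta``) and stays active until ``window``
    seconds after the last suprathreshold sample (a sliding envelope:
    back-to-back retriggering under sustained drive chains seamlessly
    into one continuous exponential decay).  Within an episode kappa
    follows ``kappa_eta * exp(-(t - t_eta)/tau_std)`` clipped at
    ``floor``; outside episodes it relaxes toward 1 with the same time
    constant.
    """
    active = t <= t_end
    if df > eta:
        if not active and prev_df <= eta:
            t_eta = t
            kappa_eta = kappa
        t_end = t + window
        active = True
    if active:
        kappa = kappa_eta * np.exp(-(t - t_eta) / tau_std)
        if kappa < floor:
            kappa = floor
    else:
        kappa += dt * (1.0 - kappa) / tau_std
        if kappa > 1.0:
            kappa = 1.0
    return kappa, kappa_eta, t_eta, t_end


@njit(cache=True)
def _kappa_loop(d_f, dt, eta, tau_std, window, floor):  # pragma: no cover
    n = d_f.shape[0]
    out = np.empty(n)
    kappa = 1.0
    kappa_eta = 1.0
    t_eta = -1e30
    t_end = -1e30
    # A series that starts above threshold counts as an initial crossing.
    prev = eta if d_f[0] > eta else d_f[0]
    for i in range(n):
        kappa, kappa_eta, t_eta, t_end = _kappa_step(
            kappa, kappa_eta, t_eta, t_end, prev, d_f[i], i * dt, dt,
            eta, tau_std, window, floor)
        out[i] = kappa
        prev = d_f[i]
    return out


def kappa_trajectory(d_f: np.ndarray, params: StdParams | None = None,
                     dt: float = 1.0 / 512.0) -> np.ndarray:
    """Kappa series driven by an already low-pass-filtered rate series.

    Parameters
    ----------
    d_f : array
        Filtered thalamic firing-rate series, uniform sampling.
    params : StdParams
        Depression parameters (defaults used when omitted).
    dt : float
        Sampling step of ``d_f`` in seconds.

    Returns
    -------
    ndarray
        kappa(t), guaranteed to lie in ``[params.floor, 1]``.
    """
    p = params or StdParams()
    p.validate()
    d_f = np.ascontiguousarray(d_f, dtype=np.float64)
    if d_f.size == 0:
        return np.empty(0)
    if not p.enabled:
        return np.ones_like(d_f)
    return _kappa_loop(d_f, float(dt), p.eta, p.tau_std, p.window, p.floor)
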