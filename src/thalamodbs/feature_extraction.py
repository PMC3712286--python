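"""Matching-pursuit band-energy characterization of LFP segments.

A signal segment is greedily decomposed over a multi-scale dictionary of
Gabor atoms (Gaussian-windowed sinusoids at ten durations between 0.125
and 5 s), Fourier atoms (full-segment sinusoids) and Dirac atoms (single
samples).  Each extracted atom carries its type, central frequency,
scale, phase, amplitude, onset position and energy.  Atoms are then
binned by central frequency into the nine classical EEG bands
(delta1 ... gamma) and the normalized per-band energies form a 9-D
feature vector; a fixed 3-D projection of the vector is used for
visualization of stimulation regimes.

Inner products with all Gabor atoms of one scale are evaluated with a
windowed FFT (the dictionary's frequency grid has spacing 1/scale and
its position grid hop scale/2, which are exactly the STFT bins and
frames), and the optimal amplitude/phase of a real atom is obtained in
closed form from the projection onto the cosine/sine pair and its
2x2 Gram matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BANDS",
    "BAND_NAMES",
    "Atom",
    "AtomTable",
    "FeatureVector",
    "MPDictionary",
    "build_dictionary",
    "default_scales",
    "atom_waveform",
    "matching_pursuit",
    "reconstruct",
    "feature_vector",
    "project_3d",
    "band_features",
]

#: Classical EEG bands (name, lower edge, upper edge) in Hz.  Intervals
#: are half-open [lo, hi) except the last, which includes its upper edge.
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta1", 0.0, 1.9),
    ("delta2", 1.9, 3.4),
    ("theta1", 3.4, 5.4),
    ("theta2", 5.4, 7.4),
    ("alpha1", 7.4, 10.0),
    ("alpha2", 10.0, 12.0),
    ("beta1", 12.0, 18.0),
    ("beta2", 18.0, 24.0),
    ("gamma", 24.0, 128.0),
)
BAND_NAMES = tuple(b[0] for b in BANDS)

#: Highest central frequency represented in the dictionary (Hz).
F_MAX = 128.0


def default_scales(n: int = 10, lo: float = 0.125, hi: float = 5.0) -> np.ndarray:
    """Ten log-spaced atom durations (s) between 0.125 and 5 s."""
    return np.geomspace(lo, hi, n)


@dataclass
class Atom:
    """One extracted time-frequency atom.

    ``amplitude`` is the coefficient on the unit-L2-norm analytic atom;
    ``position`` is the onset (window start) in seconds.  Dirac atoms
    carry no central frequency (``f_c`` is NaN).
    """

    kind: str
    f_c: float
    scale: float
    phase: float
    amplitude: float
    position: float
    energy: float


@dataclass
class AtomTable:
    """Ordered matching-pursuit decomposition of one segment."""

    atoms: list[Atom] = field(default_factory=list)
    total_energy: float = 0.0
    residual_energy: float = 0.0  # fraction of total_energy left unexplained
    n_samples: int = 0
    fs: float = 0.0

    def __len__(self) -> int:
        return len(self.atoms)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(a.kind, a.f_c, a.scale, a.phase, a.amplitude, a.position, a.energy)
             for a in self.atoms],
            columns=["kind", "f_c", "scale", "phase", "amplitude", "position",
                     "energy"],
        )


@dataclass
class FeatureVector:
    """Normalized band-energy distribution of a segment.

    ``e`` holds the nine non-negative fractions ordered delta1..gamma and
    sums to 1 unless the segment carried no band-assignable energy, in
    which case ``is_zero`` is set and ``e`` is all zeros.
    """

    e: np.ndarray
    n_dirac_excluded: int = 0
    is_zero: bool = False

    def __getitem__(self, band: str) -> float:
        return float(self.e[BAND_NAMES.index(band)])


# ---------------------------------------------------------------------------
# Dictionary
# ---------------------------------------------------------------------------

class MPDictionary:
    """Precomputed Gabor/Fourier/Dirac dictionary for segments of fixed size.

    All atoms have unit L2 norm.  For each Gabor scale the candidate
    central frequencies sit on the grid ``k / scale`` (k = 0 .. 128*scale)
    and positions on a grid with hop ``scale / 2``; Fourier atoms are
    full-segment sinusoids on the grid ``k / duration``.
    """

    def __init__(self, n_samples: int, sampling_rate: float,
                 scales: np.ndarray | None = None):
        if sampling_rate < 256:
            raise ValueError("sampling rate must be at least 256 Hz")
        self.fs = float(sampling_rate)
        self.n = int(n_samples)
        duration = self.n / self.fs
        scales = default_scales() if scales is None else np.asarray(scales, float)
        kept = []
        for s in scales:
            if s > duration + 1e-12:
                warnings.warn(
                    f"dropping scale {s:g} s: segment is only {duration:g} s",
                    stacklevel=2)
            else:
                kept.append(float(s))
        self.scales = np.array(kept)
        self._gabor = []
        for s in self.scales:
            n_s = int(round(s * self.fs))
            if n_s < 2:
                continue
            t = np.arange(n_s) / self.fs
            w = np.exp(-0.5 * ((t - s / 2.0) / (s / 8.0)) ** 2)
            hop = max(1, n_s // 2)
            k_max = min(int(np.floor(F_MAX * n_s / self.fs)), n_s // 4)
            w0 = float(np.dot(w, w))
            # V_k = sum w^2 exp(-i 4 pi f t) at f = k fs / n_s -> FFT bin 2k of w^2
            v_full = np.fft.rfft(w * w)
            v = v_full[0:2 * k_max + 1:2]
            g11 = 0.5 * (w0 + v.real)
            g22 = 0.5 * (w0 - v.real)
            g12 = -0.5 * v.imag
            det = g11 * g22 - g12 * g12
            self._gabor.append(dict(
                scale=s, n_s=n_s, hop=hop, k_max=k_max, w=w, w0=w0,
                g11=g11, g22=g22, g12=g12, det=det,
            ))
        # Fourier atoms: rectangular window over the whole segment
        self._fourier_kmax = min(int(np.floor(F_MAX * self.n / self.fs)),
                                 self.n // 4)


def build_dictionary(n_samples: int, sampling_rate: float,
                     scales: np.ndarray | None = None) -> MPDictionary:
    """Dictionary specification for segments of ``n_samples`` at ``sampling_rate``."""
    return MPDictionary(n_samples, sampling_rate, scales)


def atom_waveform(kind: str, f_c: float, scale: float, phase: float,
                  position: float, fs: float, n_samples: int) -> np.ndarray:
    """Unit-L2-norm discrete waveform of one atom, embedded in ``n_samples``.

    Gabor atoms are Gaussian-windowed cosines supported on
    ``[position, position + scale)``; Fourier atoms rectangular-windowed
    cosines; Dirac atoms single-sample impulses.
    """
    out = np.zeros(n_samples)
    i0 = int(round(position * fs))
    if kind == "dirac":
        if not 0 <= i0 < n_samples:
            raise ValueError("dirac atom outside segment")
        out[i0] = 1.0
        return out
    n_s = int(round(scale * fs))
    if i0 < 0 or i0 + n_s > n_samples:
        raise ValueError("atom support outside segment")
    t = np.arange(n_s) / fs
    if kind == "gabor":
        w = np.exp(-0.5 * ((t - scale / 2.0) / (scale / 8.0)) ** 2)
    elif kind == "fourier":
        w = np.ones(n_s)
    else:
        raise ValueError(f"unknown atom kind {kind!r}")
    g = w * np.cos(2.0 * np.pi * f_c * t + phase)
    norm = np.linalg.norm(g)
    if norm == 0:
        raise ValueError("degenerate atom (zero norm)")
    out[i0:i0 + n_s] = g / norm
    return out


# ---------------------------------------------------------------------------
# Matching pursuit
# ---------------------------------------------------------------------------

def _gabor_energies(res: np.ndarray, sc: dict) -> np.ndarray:
    """Projection energies onto all (position, frequency) atoms of one scale."""
    n_s, hop, k_max = sc["n_s"], sc["hop"], sc["k_max"]
    n_frames = 1 + (res.shape[0] - n_s) // hop
    idx = np.arange(n_frames)[:, None] * hop + np.arange(n_s)[None, :]
    frames = res[idx] * sc["w"]
    c = np.fft.rfft(frames, axis=1)[:, :k_max + 1]
    b1 = c.real
    b2 = -c.imag
    g11, g22, g12, det = sc["g11"], sc["g22"], sc["g12"], sc["det"]
    safe = det > 1e-10 * sc["w0"] ** 2
    e = np.empty_like(b1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_full = (g22 * b1 * b1 - 2.0 * g12 * b1 * b2 + g11 * b2 * b2) / det
        e_deg = b1 * b1 / g11
    e[:, safe] = e_full[:, safe]
    e[:, ~safe] = e_deg[:, ~safe]
    return e


def _gabor_component(res: np.ndarray, sc: dict, frame: int, k: int):
    """Optimal (alpha, beta) component of one Gabor atom and its waveform."""
    n_s, hop = sc["n_s"], sc["hop"]
    i0 = frame * hop
    seg = res[i0:i0 + n_s]
    t = np.arange(n_s)
    cosv = sc["w"] * np.cos(2.0 * np.pi * k * t / n_s)
    sinv = sc["w"] * np.sin(2.0 * np.pi * k * t / n_s)
    b1 = float(np.dot(seg, cosv))
    b2 = float(np.dot(seg, sinv))
    g11 = sc["g11"][k]
    g22 = sc["g22"][k]
    g12 = sc["g12"][k]
    det = sc["det"][k]
    if det > 1e-10 * sc["w0"] ** 2:
        alpha = (g22 * b1 - g12 * b2) / det
        beta = (-g12 * b1 + g11 * b2) / det
    else:
        alpha = b1 / g11
        beta = 0.0
    comp = alpha * cosv + beta * sinv
    return i0, comp, alpha, beta


def matching_pursuit(
    signal: np.ndarray,
    sampling_rate: float,
    dictionary: MPDictionary | None = None,
    max_atoms: int = 200,
    min_residual_fraction: float = 0.05,
) -> AtomTable:
    """Greedy decomposition of a segment over the multi-scale dictionary.

    At each iteration the atom with the largest projection energy onto the
    current residual is extracted (with analytically optimal phase and
    amplitude) and subtracted; iteration stops when ``max_atoms`` have
    been extracted or the residual energy falls below
    ``min_residual_fraction`` of the input energy.  Atom energies are the
    measured residual-energy drops, so the table satisfies
    ``sum(energies) + residual = total`` to rounding error.
    """
    x = np.ascontiguousarray(signal, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    if dictionary is None:
        dictionary = build_dictionary(x.shape[0], sampling_rate)
    if dictionary.n != x.shape[0] or dictionary.fs != sampling_rate:
        raise ValueError("dictionary does not match the segment geometry")
    fs = dictionary.fs
    n = dictionary.n
    total = float(np.dot(x, x))
    table = AtomTable(total_energy=total, residual_energy=0.0,
                      n_samples=n, fs=fs)
    if total == 0.0:
        return table

    res = x.copy()
    e_res = total
    # Fourier machinery: rectangular window; the cos/sin pair is exactly
    # orthogonal with norm^2 = n/2 on the FFT grid (n for the DC atom).
    kf = dictionary._fourier_kmax
    tf = np.arange(n)

    for _ in range(max_atoms):
        best = None  # (energy, payload)
        for sc in dictionary._gabor:
            if sc["n_s"] > n:
                continue
            e = _gabor_energies(res, sc)
            j = int(np.argmax(e))
            fr, k = divmod(j, e.shape[1])
            if best is None or e[fr, k] > best[0]:
                best = (float(e[fr, k]), ("gabor", sc, fr, k))
        cf = np.fft.rfft(res)[:kf + 1]
        ef = np.abs(cf) ** 2 / (n / 2.0)
        ef[0] = cf[0].real ** 2 / n
        kbest = int(np.argmax(ef))
        if best is None or ef[kbest] > best[0]:
            best = (float(ef[kbest]), ("fourier", kbest))
        kd = int(np.argmax(np.abs(res)))
        if res[kd] ** 2 > best[0]:
            best = (float(res[kd] ** 2), ("dirac", kd))

        if best[0] <= 1e-300:
            break
        payload = best[1]
        if payload[0] == "gabor":
            _, sc, fr, k = payload
            i0, comp, alpha, beta = _gabor_component(res, sc, fr, k)
            res[i0:i0 + sc["n_s"]] -= comp
            e_new = float(np.dot(res, res))
            energy = e_res - e_new
            amp = float(np.linalg.norm(comp))
            atom = Atom(
                kind="gabor",
                f_c=k * fs / sc["n_s"],
                scale=sc["scale"],
                phase=float(-np.arctan2(beta, alpha)) % (2.0 * np.pi),
                amplitude=amp,
                position=i0 / fs,
                energy=energy,
            )
        elif payload[0] == "fourier":
            _, k = payload
            if k == 0:
                alpha = float(np.sum(res)) / n
                comp = np.full(n, alpha)
                phase = 0.0
            else:
                c = cf[k]
                alpha = 2.0 * c.real / n
                beta = -2.0 * c.imag / n
                comp = alpha * np.cos(2.0 * np.pi * k * tf / n) \
                    + beta * np.sin(2.0 * np.pi * k * tf / n)
                phase = float(-np.arctan2(beta, alpha)) % (2.0 * np.pi)
            res -= comp
            e_new = float(np.dot(res, res))
            energy = e_res - e_new
            atom = Atom(
                kind="fourier",
                f_c=k * fs / n,
                scale=n / fs,
                phase=phase,
                amplitude=float(np.linalg.norm(comp)),
                position=0.0,
                energy=energy,
            )
        else:
            _, kd = payload
            amp = float(res[kd])
            res[kd] = 0.0
            e_new = float(np.dot(res, res))
            energy = e_res - e_new
            atom = Atom(
                kind="dirac",
                f_c=float("nan"),
                scale=1.0 / fs,
                phase=0.0,
                amplitude=amp,
                position=kd / fs,
                energy=energy,
            )
        table.atoms.append(atom)
        e_res = e_new
        if e_res / total <= min_residual_fraction:
            break

    table.residual_energy = max(e_res, 0.0) / total
    return table


def reconstruct(table: AtomTable, n_samples: int | None = None,
                sampling_rate: float | None = None) -> np.ndarray:
    """Sum of amplitude-scaled analytic atoms of a decomposition table."""
    n = table.n_samples if n_samples is None else int(n_samples)
    fs = table.fs if sampling_rate is None else float(sampling_rate)
    out = np.zeros(n)
    for a in table.atoms:
        if a.kind == "dirac":
            out[int(round(a.position * fs))] += a.amplitude
        else:
            out += a.amplitude * atom_waveform(
                a.kind, a.f_c, a.scale, a.phase, a.position, fs, n)
    return out


# ---------------------------------------------------------------------------
# Band energies and feature vectors
# ---------------------------------------------------------------------------

def _band_index(f_c: float) -> int | None:
    if np.isnan(f_c):
        return None
    for i, (_, lo, hi) in enumerate(BANDS):
        if lo <= f_c < hi:
            return i
    if f_c == BANDS[-1][2]:  # upper edge of gamma is inclusive
        return len(BANDS) - 1
    return None


def feature_vector(table: AtomTable) -> FeatureVector:
    """9-D normalized band-energy distribution of a decomposition.

    Per-band energy is the sum of the energies of the atoms whose central
    frequency falls in the band (half-open intervals, boundary values go
    to the higher band); the vector is normalized by the total
    band-assignable energy.  Dirac atoms carry no central frequency and
    are excluded (their count is reported).
    """
    e = np.zeros(len(BANDS))
    n_dirac = 0
    for a in table.atoms:
        if a.kind == "dirac":
            n_dirac += 1
            continue
        idx = _band_index(a.f_c)
        if idx is not None:
            e[idx] += max(a.energy, 0.0)
    total = e.sum()
    if total <= 0.0:
        return FeatureVector(e=np.zeros(len(BANDS)),
                             n_dirac_excluded=n_dirac, is_zero=True)
    return FeatureVector(e=e / total, n_dirac_excluded=n_dirac)


def project_3d(v: FeatureVector | np.ndarray) -> np.ndarray:
    """Fixed 3-D projection of a 9-D band-energy vector.

    Coordinates: [e(delta2)+e(theta1), e(theta2)+e(alpha1)+e(alpha2)+e(beta1),
    e(beta2)+e(gamma)]; the delta1 fraction is not represented.
    """
    e = v.e if isinstance(v, FeatureVector) else np.asarray(v, dtype=float)
    if e.shape != (9,):
        raise ValueError("expected a 9-component band-energy vector")
    return np.array([e[1] + e[2], e[3] + e[4] + e[5] + e[6], e[7] + e[8]])


def band_features(signal: np.ndarray, sampling_rate: float,
                  dictionary: MPDictionary | None = None,
                  demean: bool = True, **stop) -> FeatureVector:
    """Convenience: matching pursuit followed by band-energy summary.

    The segment mean is removed first (``demean``): like AC-coupled
    recordings, the band-energy distribution describes fluctuations, not
    the DC offset of the simulated potential.
    """
    x = np.asarray(signal, dtype=np.float64)
    if demean:
        x = x - x.mean()
    return feature_vector(
        matching_pursuit(x, sampling_rate, dictionary=dictionary, **stop))
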