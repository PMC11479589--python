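"""Spectral mode-locking analysis and the Arnold-tongue frequency-ratio surface.

A forced oscillator inside a synchronization tongue adopts a rational
multiple of the forcing frequency ``f``.  The observable here is the ratio
``nu/f`` where ``nu`` is the dominant peak of the mean-subtracted periodogram
of the ``y`` trace after transient removal.  Sweeping the forcing frequency
(in units of the natural frequency ``nu0``) and amplitude ``beta_prime``
yields a surface whose rational plateaus (``nu/f = 1, 1/2, 2, ...``) are the
Arnold tongues.  On the 1/2 tongue individual cells peak on either the even
or the odd forcing pulses; a population with both parities present averages
to a small oscillation at ``f`` itself, not ``f/2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import EnsembleSpec, simulate_ensemble
from .integrate import DEFAULT_DT, simulate
from .model import OptoParams
from .phase import detect_peaks, natural_period
from .protocols import LightProtocol

__all__ = [
    "ToneAnalysis",
    "TongueSurface",
    "AlternatePeakResult",
    "power_spectrum",
    "dominant_frequency",
    "frequency_ratio",
    "tongue_surface",
    "alternate_peak_population",
]

PLATEAU_RATIOS = (1.0, 0.5, 2.0, 1.5, 2.0 / 3.0)
PLATEAU_NAMES = ("1", "1/2", "2", "3/2", "2/3")
PLATEAU_TOL = 0.02


@dataclass
class ToneAnalysis:
    """Dominant-frequency summary of one forced trajectory."""

    frequencies: np.ndarray
    power: np.ndarray
    dominant_frequency: float
    forcing_frequency: float

    @property
    def ratio(self) -> float:
        return self.dominant_frequency / self.forcing_frequency

    @property
    def resolution(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def power_spectrum(signal: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean-subtracted periodogram of a uniformly sampled signal.

    Returns (frequencies, power); the frequency resolution is 1/duration.
    No window is applied — the consumers only read the arg-max bin of long,
    near-periodic records.
    """
    signal = np.asarray(signal, float)
    if len(signal) < 16:
        raise ValueError("signal too short for a meaningful spectrum")
    detrended = signal - signal.mean()
    spec = np.abs(np.fft.rfft(detrended)) ** 2
    freqs = np.fft.rfftfreq(len(signal), d=dt)
    return freqs, spec


def dominant_frequency(
    freqs: np.ndarray, power: np.ndarray, subharmonic_guard: bool = True
) -> float:
    """Frequency of the strongest nonzero bin, with a fundamental-vs-harmonic guard.

    Relaxation-shaped waveforms can put more power into the second harmonic
    than the fundamental; when the bin nearest half the arg-max frequency
    carries at least 25% of the maximum power it is preferred.
    """
    if len(freqs) < 3:
        raise ValueError("spectrum too short")
    idx = 1 + int(np.argmax(power[1:]))
    f_max = freqs[idx]
    if subharmonic_guard:
        half_idx = int(np.argmin(np.abs(freqs - f_max / 2.0)))
        lo, hi = max(1, half_idx - 1), min(len(freqs), half_idx + 2)
        if half_idx >= 1 and np.max(power[lo:hi]) >= 0.25 * power[idx]:
            idx = lo + int(np.argmax(power[lo:hi]))
    return float(freqs[idx])


def _forced_tone(
    params: OptoParams,
    TL: float,
    beta_prime: float,
    tau: float,
    n_periods: int,
    discard_periods: int,
    dt: float,
) -> ToneAnalysis:
    forced = OptoParams(
        base=params.base, beta_prime_on=beta_prime, beta_prime_off=params.beta_prime_off
    )
    protocol = (
        LightProtocol.pulse_train(0.0, TL, tau, n_periods)
        if beta_prime > 0
        else LightProtocol.constant("off")
    )
    traj = simulate(forced, protocol, t_end=n_periods * TL, dt=dt)
    keep = traj.times >= discard_periods * TL
    freqs, power = power_spectrum(traj.y[keep], dt)
    nu = dominant_frequency(freqs, power)
    return ToneAnalysis(
        frequencies=freqs, power=power, dominant_frequency=nu, forcing_frequency=1.0 / TL
    )


def frequency_ratio(
    params: OptoParams,
    f_over_nu0: float,
    beta_prime: float,
    tau: float = 2.0,
    nu0: float | None = None,
    n_periods: int = 40,
    discard_periods: int = 10,
    dt: float = DEFAULT_DT,
) -> ToneAnalysis:
    """Locking ratio nu/f for forcing at ``f = f_over_nu0 * nu0``.

    ``nu0`` (the free-running frequency) is measured once if not supplied.
    The run covers ``n_periods`` forcing periods with the first
    ``discard_periods`` dropped before the periodogram.
    """
    if f_over_nu0 <= 0:
        raise ValueError("f_over_nu0 must be > 0")
    if nu0 is None:
        nu0 = 1.0 / natural_period(params, dt=dt)
    TL = 1.0 / (f_over_nu0 * nu0)
    if tau >= TL and beta_prime > 0:
        raise ValueError("pulse duration must be shorter than the forcing period")
    return _forced_tone(params, TL, beta_prime, tau, n_periods, discard_periods, dt)


@dataclass
class TongueSurface:
    """Grid of locking ratios over forcing frequency and amplitude."""

    f_over_nu0: np.ndarray
    beta_primes: np.ndarray
    ratio: np.ndarray  # shape (len(f_over_nu0), len(beta_primes))
    labels: np.ndarray  # same shape, dtype object
    nu0: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.f_over_nu0):
            for j, bp in enumerate(self.beta_primes):
                rows.append(
                    {
                        "f_over_nu0": f,
                        "beta_prime": bp,
                        "ratio": self.ratio[i, j],
                        "label": self.labels[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _plateau_label(ratio: float, tol: float = PLATEAU_TOL) -> str:
    for target, name in zip(PLATEAU_RATIOS, PLATEAU_NAMES):
        if abs(ratio - target) < tol:
            return name
    return "unlocked"


def tongue_surface(
    params: OptoParams,
    f_grid: np.ndarray | None = None,
    beta_prime_grid: np.ndarray | None = None,
    tau: float = 2.0,
    n_periods: int = 40,
    discard_periods: int = 10,
    dt: float = DEFAULT_DT,
) -> TongueSurface:
    """Locking-ratio surface over a forcing frequency x amplitude grid.

    Defaults scan ``f/nu0`` in [0.4, 2.4] (step 0.1) and
    ``beta_prime`` in {0, 10, 20, 40, 80, 120} 1/h.  Cells at
    ``beta_prime = 0`` are unforced and carry no plateau label.
    """
    if f_grid is None:
        f_grid = np.round(np.arange(0.4, 2.45, 0.1), 10)
    if beta_prime_grid is None:
        beta_prime_grid = np.array([0.0, 10.0, 20.0, 40.0, 80.0, 120.0])
    f_grid = np.asarray(f_grid, float)
    beta_prime_grid = np.asarray(beta_prime_grid, float)

    nu0 = 1.0 / natural_period(params, dt=dt)
    ratio = np.empty((len(f_grid), len(beta_prime_grid)))
    labels = np.empty(ratio.shape, dtype=object)
    for i, f in enumerate(f_grid):
        for j, bp in enumerate(beta_prime_grid):
            tone = frequency_ratio(
                params, f, bp, tau=tau, nu0=nu0,
                n_periods=n_periods, discard_periods=discard_periods, dt=dt,
            )
            ratio[i, j] = tone.ratio
            labels[i, j] = _plateau_label(tone.ratio) if bp > 0 else "unforced"
    return TongueSurface(
        f_over_nu0=f_grid, beta_primes=beta_prime_grid, ratio=ratio, labels=labels, nu0=nu0
    )


@dataclass
class AlternatePeakResult:
    """Population behaviour on the 1/2 tongue: per-cell pulse-parity labels."""

    times: np.ndarray
    population_mean: np.ndarray
    parities: np.ndarray  # per cell: 0, 1, or -1 for unlocked
    n_unlocked: int
    forcing_frequency: float
    TL: float

    @property
    def dominant_population_frequency(self) -> float:
        dt = self.times[1] - self.times[0]
        keep = self.times >= 10 * self.TL
        freqs, power = power_spectrum(self.population_mean[keep], dt)
        return dominant_frequency(freqs, power)


def alternate_peak_population(
    spec: EnsembleSpec,
    f_over_nu0: float = 2.0,
    beta_prime: float = 80.0,
    tau: float = 2.0,
    n_periods: int = 40,
    discard_periods: int = 10,
    dt: float = DEFAULT_DT,
) -> AlternatePeakResult:
    """Classify cells forced near twice their natural frequency by pulse parity.

    Each cell locked on the 1/2 tongue peaks once every second pulse; the
    parity label records whether its peaks align with even or odd pulses.
    Cells whose peak-to-pulse assignment is inconsistent after the transient
    are counted as unlocked (label -1) and excluded from the parity census.
    """
    params = spec.params_template
    nu0 = 1.0 / natural_period(params, dt=dt)
    TL = 1.0 / (f_over_nu0 * nu0)
    protocol = LightProtocol.pulse_train(0.0, TL, tau, n_periods)
    forced = OptoParams(
        base=params.base, beta_prime_on=beta_prime, beta_prime_off=params.beta_prime_off
    )
    forced_spec = EnsembleSpec(
        n_cells=spec.n_cells,
        alpha_mean=spec.alpha_mean,
        alpha_sd=spec.alpha_sd,
        seed=spec.seed,
        params_template=forced,
        initial_condition_mode=spec.initial_condition_mode,
    )
    result = simulate_ensemble(forced_spec, protocol, t_end=n_periods * TL, dt=dt)

    parities = np.full(spec.n_cells, -1)
    t_min = discard_periods * TL
    for i in range(spec.n_cells):
        peaks = detect_peaks(result.times, result.y[i])
        peaks = peaks[peaks >= t_min]
        if len(peaks) < 3:
            continue
        pulse_idx = np.round(peaks / TL).astype(int)
        spacing = np.diff(pulse_idx)
        if np.all(spacing == 2):
            parities[i] = int(pulse_idx[0] % 2)
    n_unlocked = int(np.sum(parities < 0))

    return AlternatePeakResult(
        times=result.times,
        population_mean=result.population_mean,
        parities=parities,
        n_unlocked=n_unlocked,
        forcing_frequency=1.0 / TL,
        TL=TL,
    )
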