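"""Populations of independent optorepressilators with distributed growth rates.

Cell-to-cell variability enters only through the dilution rate ``alpha``,
drawn per cell from a normal distribution (mean 0.75 1/h; s.d. 0.034 1/h for
plate-reader-like populations, 0.071 1/h for mother-machine-like ones).
Because the period scales roughly with 1/alpha, the period dispersion
progressively dephases an initially synchronized population and damps the
population-mean signal — the central failure mode that optical entrainment
rescues.  Cells are uncoupled; the population mean is the plain arithmetic
mean of the per-cell y traces on the common time grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .integrate import DEFAULT_DT, _check_finite_trajectory, _euler_core, _time_grid
from .model import OptoParams, digital_period, RepressilatorParams
from .phase import detect_peaks, natural_period
from .protocols import LightProtocol

__all__ = [
    "EnsembleSpec",
    "EnsembleResult",
    "draw_growth_rates",
    "initial_states",
    "simulate_ensemble",
    "periods_to_half_amplitude",
]

INITIAL_CONDITION_MODES = ("synchronized_green", "synchronized_iptg", "random_phase")


@dataclass(frozen=True)
class EnsembleSpec:
    """Population description: size, growth-rate distribution, starting state.

    ``initial_condition_mode``:

    * ``synchronized_green`` — every cell at its post-green reset state
      ``(0, 0, beta/alpha_i, 0)``;
    * ``synchronized_iptg`` — the fixed point of the IPTG-cut network,
      ``(beta/alpha_i, beta/alpha_i, 0, 0)`` (IPTG disables LacI repression);
    * ``random_phase`` — each cell at a uniformly random phase of its own
      free-running limit cycle.
    """

    n_cells: int = 200
    alpha_mean: float = 0.75
    alpha_sd: float = 0.034
    seed: int = 0
    params_template: OptoParams = field(default_factory=OptoParams)
    initial_condition_mode: str = "synchronized_green"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.alpha_sd < 0:
            raise ValueError("alpha_sd must be >= 0")
        if self.initial_condition_mode not in INITIAL_CONDITION_MODES:
            raise ValueError(
                f"unknown initial_condition_mode {self.initial_condition_mode!r}; "
                f"choose one of {INITIAL_CONDITION_MODES}"
            )

    def cell_params(self, alpha: float) -> OptoParams:
        t = self.params_template
        return OptoParams(
            base=RepressilatorParams(alpha=alpha, beta=t.beta, n=t.n),
            beta_prime_on=t.beta_prime_on,
            beta_prime_off=t.beta_prime_off,
        )


def draw_growth_rates(spec: EnsembleSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-cell dilution rates: i.i.d. normal, non-positive draws redrawn."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    alphas = rng.normal(spec.alpha_mean, spec.alpha_sd, size=spec.n_cells)
    while np.any(alphas <= 0):
        bad = alphas <= 0
        alphas[bad] = rng.normal(spec.alpha_mean, spec.alpha_sd, size=int(bad.sum()))
    return alphas


def initial_states(
    spec: EnsembleSpec,
    alphas: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Per-cell initial state vectors, shape (n_cells, 4)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if alphas is None:
        alphas = draw_growth_rates(spec, rng)
    beta = spec.params_template.beta
    mode = spec.initial_condition_mode

    if mode == "synchronized_green":
        states = np.zeros((len(alphas), 4))
        states[:, 2] = beta / alphas
        return states
    if mode == "synchronized_iptg":
        states = np.zeros((len(alphas), 4))
        states[:, 0] = beta / alphas
        states[:, 1] = beta / alphas
        return states
    # random_phase: run every cell onto its limit cycle, then sample each
    # cell's state at a uniform random time within one of its own periods.
    return _random_phase_states(spec, alphas, rng, dt)


def _estimated_periods(spec: EnsembleSpec, alphas: np.ndarray) -> np.ndarray:
    """Per-cell period estimates from the digital formula, rescaled so the
    template cell matches its simulated free-running period."""
    template = spec.params_template
    t0_sim = natural_period(template)
    t0_dig = digital_period(template.base)
    dig_i = 3.0 * np.log(template.beta / alphas) / alphas
    return t0_sim * dig_i / t0_dig


def _random_phase_states(
    spec: EnsembleSpec, alphas: np.ndarray, rng: np.random.Generator, dt: float
) -> np.ndarray:
    periods = _estimated_periods(spec, alphas)
    t_trans = 5.0 * float(np.max(periods))
    window = float(np.max(periods))

    m = len(alphas)
    y0 = np.zeros((m, 4))
    y0[:, 2] = spec.params_template.beta / alphas

    beta, n = spec.params_template.beta, spec.params_template.n
    steps_trans = int(round(t_trans / dt))
    bp = np.zeros(steps_trans)
    settled = _euler_core(y0, alphas, beta, n, bp, dt, record="last")

    steps_win = int(round(window / dt)) + 1
    bp_win = np.zeros(steps_win)
    states = _euler_core(settled, alphas, beta, n, bp_win, dt, record="full")
    u = rng.uniform(size=m)
    idx = np.minimum((u * periods / dt).astype(int), steps_win)
    return states[idx, np.arange(m), :]


@dataclass
class EnsembleResult:
    """Per-cell y traces plus the population mean on a common grid."""

    times: np.ndarray
    alphas: np.ndarray
    y: np.ndarray  # (n_cells, n_times)
    population_mean: np.ndarray
    spec: EnsembleSpec
    protocol: LightProtocol
    states: np.ndarray | None = None  # (n_times, n_cells, 4) when recorded

    def cell_trajectory(self, i: int):
        """Full :class:`~optoclock.integrate.Trajectory` of cell ``i``.

        Requires the ensemble to have been simulated with ``record_full=True``.
        """
        from .integrate import Trajectory

        if self.states is None:
            raise ValueError("full states were not recorded; pass record_full=True")
        return Trajectory(
            times=self.times,
            states=self.states[:, i, :],
            protocol=self.protocol,
            params=self.spec.cell_params(float(self.alphas[i])),
            dt=float(self.times[1] - self.times[0]),
        )

    def to_csv(self, path: str | Path) -> None:
        """Long-format export (cell_id, time_h, y) with the mean as cell_id 'mean'."""
        frames = [
            pd.DataFrame(
                {"cell_id": str(i), "time_h": self.times, "y": self.y[i]}
            )
            for i in range(self.y.shape[0])
        ]
        frames.append(
            pd.DataFrame(
                {"cell_id": "mean", "time_h": self.times, "y": self.population_mean}
            )
        )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        sidecar = {
            "seed": self.spec.seed,
            "alphas": self.alphas.tolist(),
            "n_cells": int(self.spec.n_cells),
            "alpha_mean": self.spec.alpha_mean,
            "alpha_sd": self.spec.alpha_sd,
            "initial_condition_mode": self.spec.initial_condition_mode,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar) + "\n")


def simulate_ensemble(
    spec: EnsembleSpec,
    protocol: LightProtocol,
    t_end: float,
    dt: float = DEFAULT_DT,
    record_full: bool = False,
) -> EnsembleResult:
    """Integrate all cells independently and average their y traces."""
    rng = np.random.default_rng(spec.seed)
    alphas = draw_growth_rates(spec, rng)
    y0 = initial_states(spec, alphas=alphas, rng=rng, dt=dt)

    times = _time_grid(t_end, dt)
    params = spec.params_template
    bp = protocol.beta_prime(times[:-1], params).astype(float)

    if record_full:
        states = _euler_core(y0, alphas, params.beta, params.n, bp, dt, record="full")
        _check_finite_trajectory(times, states)
        y = states[:, :, 1].T
    else:
        ys = _euler_core(y0, alphas, params.beta, params.n, bp, dt, record="y")
        _check_finite_trajectory(times, ys)
        states = None
        y = ys.T

    return EnsembleResult(
        times=times,
        alphas=alphas,
        y=y,
        population_mean=y.mean(axis=0),
        spec=spec,
        protocol=protocol,
        states=states,
    )


def periods_to_half_amplitude(
    times: np.ndarray,
    signal: np.ndarray,
    min_separation: float = 2.0,
    min_prominence: float = 0.02,
) -> float:
    """Elapsed periods until the oscillation amplitude first halves.

    The amplitude at each cycle is the peak-to-trough contrast: the height of
    a local maximum minus the signal minimum before the next maximum.  (A
    long-run-baseline reference would overstate the decay here, because the
    dephased mean settles far above the early troughs.)  Peaks whose contrast
    falls below 5% of the first cycle's are treated as noise.  The crossing
    time is linearly interpolated between the bracketing peaks, measured from
    the first peak, and divided by the mean peak-to-peak period.  Returns
    ``math.inf`` when the amplitude never drops below half (undamped signal).
    """
    times = np.asarray(times, float)
    signal = np.asarray(signal, float)
    peaks = detect_peaks(times, signal, min_separation=min_separation,
                         min_prominence=min_prominence)
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks to define an envelope")
    period = float(np.mean(np.diff(peaks)))

    peak_heights = np.interp(peaks, times, signal)
    heights = np.empty(len(peaks) - 1)
    for k in range(len(peaks) - 1):
        between = (times > peaks[k]) & (times < peaks[k + 1])
        trough = float(np.min(signal[between])) if between.any() else peak_heights[k + 1]
        heights[k] = peak_heights[k] - trough
    peaks = peaks[:-1]

    first = heights[0]
    if first <= 0:
        raise ValueError("first peak carries no amplitude")
    keep = heights >= 0.05 * first
    peaks, heights = peaks[keep], heights[keep]

    half = 0.5 * first
    below = np.nonzero(heights < half)[0]
    if len(below) == 0:
        return math.inf
    j = int(below[0])
    if j == 0:
        return 0.0
    # linear interpolation of the envelope between the bracketing peaks
    t_cross = peaks[j - 1] + (half - heights[j - 1]) * (peaks[j] - peaks[j - 1]) / (
        heights[j] - heights[j - 1]
    )
    return float((t_cross - peaks[0]) / period)
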