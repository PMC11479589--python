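"""Peak/phase extraction, phase response curves, and circle-map entrainment.

Phases are measured in cycles, zero at an expression peak of the ``y``
protein (the TetR/CFP node); pulse "arrival" is the pulse onset.  A light
pulse arriving at phase ``phi`` shifts subsequent oscillations by
``delta_phi(phi)``; the sign convention is "advance = positive", so a pulse
arriving before the peak (``phi < 0``) produces ``delta_phi > 0`` and a
pulse on the decaying edge (``phi > 0``) produces a delay.  Peak times only
fix the shift mod 1; the curve's branch is chosen by continuity from the
small-shift delay region, which keeps early-pulse advances larger than half
a cycle on the advance branch instead of aliasing them to delays.  Under a
periodic train of pulses with period ``TL`` the
pulse-arrival phases evolve by the circle map

    phi_{n+1} = phi_n + TL/T0 - 1 + delta_phi(phi_n)

whose fixed points ``delta_phi(phi*) = 1 - TL/T0`` are entrained states,
stable when the phase response curve's slope there lies in (-2, 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import json
import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .integrate import DEFAULT_DT, Trajectory, _euler_core, default_initial_state, simulate
from .model import OptoParams
from .protocols import LightProtocol

__all__ = [
    "PhaseResponseCurve",
    "EntrainedState",
    "OutsideLockingRangeError",
    "NotEntrainedError",
    "wrap_phase",
    "detect_peaks",
    "natural_period",
    "phase_response",
    "compute_prc",
    "circle_map_step",
    "iterate_circle_map",
    "entrained_phase",
    "measured_entrained_phase",
]


class OutsideLockingRangeError(ValueError):
    """No entrained fixed point exists for the requested forcing period."""


class NotEntrainedError(RuntimeError):
    """A pulse-train trajectory whose pulse-arrival phase drifts (no locking)."""


def wrap_phase(phi) -> np.ndarray | float:
    """Wrap a phase (cycles) into [-0.5, 0.5)."""
    return (np.asarray(phi) + 0.5) % 1.0 - 0.5


def detect_peaks(
    times: np.ndarray,
    signal: np.ndarray,
    min_separation: float = 2.0,
    min_prominence: float = 0.05,
) -> np.ndarray:
    """Times of local maxima, refined by parabolic interpolation.

    Peaks must be at least ``min_separation`` hours apart and have prominence
    at least ``min_prominence`` times the signal's full range.  Returns an
    empty array for flat or featureless signals.
    """
    times = np.asarray(times, float)
    signal = np.asarray(signal, float)
    if len(times) != len(signal):
        raise ValueError("times and signal must have equal length")
    span = float(np.max(signal) - np.min(signal)) if len(signal) else 0.0
    if span == 0.0:
        return np.array([])
    dt = times[1] - times[0]
    idx, _ = find_peaks(
        signal,
        distance=max(1, int(round(min_separation / dt))),
        prominence=min_prominence * span,
    )
    peak_times = []
    for i in idx:
        if 0 < i < len(signal) - 1:
            a, b, c = signal[i - 1], signal[i], signal[i + 1]
            denom = a - 2 * b + c
            shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
            peak_times.append(times[i] + shift * dt)
        else:
            peak_times.append(times[i])
    return np.asarray(peak_times)


def natural_period(
    params: OptoParams,
    t_end: float = 160.0,
    dt: float = DEFAULT_DT,
    discard_cycles: int = 2,
) -> float:
    """Free-running period T0 under constant red light.

    Mean y-peak spacing after discarding the first ``discard_cycles`` cycles.
    The default parameter set gives T0 close to 17.5 h.
    """
    traj = simulate(params, LightProtocol.constant("off"), t_end=t_end, dt=dt)
    peaks = detect_peaks(traj.times, traj.y)
    peaks = peaks[discard_cycles:]
    if len(peaks) < 4:
        raise ValueError(
            f"need >= 4 post-transient peaks to estimate the period, got {len(peaks)}"
        )
    return float(np.mean(np.diff(peaks)))


@dataclass
class PhaseResponseCurve:
    """Sampled map phi -> delta_phi for a fixed pulse (tau, beta_prime).

    ``phis`` live in [-0.5, 0.5) cycles; interpolation is linear and periodic
    in phi.  ``delta_phis`` are branch-resolved (continuous across the
    advance/delay crossover), so large advances may exceed +0.5 cycles; all
    values are equivalent mod 1 for the circle map.
    """

    phis: np.ndarray
    delta_phis: np.ndarray
    pulse_tau: float
    pulse_beta_prime: float
    T0: float

    def __post_init__(self) -> None:
        if len(self.phis) != len(self.delta_phis):
            raise ValueError("phis and delta_phis must have equal length")

    def __call__(self, phi) -> np.ndarray | float:
        """Periodic linear interpolation of delta_phi at phase(s) ``phi``."""
        phi = wrap_phase(phi)
        xp = np.concatenate([self.phis - 1.0, self.phis, self.phis + 1.0])
        fp = np.tile(self.delta_phis, 3)
        return np.interp(phi, xp, fp)

    def slope(self, phi: float, h: float = 0.01) -> float:
        """Central-difference slope d(delta_phi)/d(phi) of the interpolant."""
        return float((self(phi + h) - self(phi - h)) / (2 * h))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"phi": self.phis, "delta_phi": self.delta_phis})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
        meta = {
            "tau": self.pulse_tau,
            "beta_prime": self.pulse_beta_prime,
            "T0": self.T0,
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2) + "\n")


@dataclass
class EntrainedState:
    """A fixed point of the circle map: entrained phase, slope, stability."""

    phi_star: float
    slope: float
    stable: bool


def _phase_shifts_raw(
    params: OptoParams,
    phis: np.ndarray,
    tau: float,
    beta_prime_pulse: float,
    k: int = 3,
    dt: float = DEFAULT_DT,
    T0: float | None = None,
    establish_cycles: int = 5,
) -> tuple[np.ndarray, float]:
    """Mod-1 phase shifts for a batch of pulse-arrival phases (shared reference run).

    A single unperturbed reference trajectory provides the anchor peak (the
    ``establish_cycles``-th y peak, well past the initial transient).  Each
    perturbed copy receives one pulse starting at ``anchor + phi * T0``; the
    shift is read at the ``k``-th peak after the pulse ends, wrapped to
    [-0.5, 0.5), so a full-period index mismatch cannot corrupt the value.
    """
    if beta_prime_pulse < 0:
        raise ValueError("beta_prime_pulse must be >= 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if T0 is None:
        T0 = natural_period(params, dt=dt)
    phis = wrap_phase(np.asarray(phis, dtype=float))

    t_end = (establish_cycles + k + 5) * T0
    protocol = LightProtocol.constant("off")
    ref = simulate(params, protocol, t_end=t_end, dt=dt)
    ref_peaks = detect_peaks(ref.times, ref.y)
    if len(ref_peaks) < establish_cycles + k + 2:
        raise ValueError("reference run too short to establish the limit cycle")
    anchor = ref_peaks[establish_cycles - 1]

    pulse_starts = anchor + phis * T0
    if np.any(pulse_starts < ref_peaks[0]):
        raise ValueError("pulse scheduled before the reference cycle is established")

    times = ref.times
    steps = len(times) - 1
    m = len(phis)
    t_left = times[:-1]
    bp = np.zeros((steps, m))
    if tau > 0:
        for j, ps in enumerate(pulse_starts):
            bp[(t_left >= ps) & (t_left < ps + tau), j] = beta_prime_pulse

    y0 = np.tile(default_initial_state(params), (m, 1))
    ys = _euler_core(y0, params.alpha, params.beta, params.n, bp, dt, record="y")

    shifts = np.empty(m)
    for j in range(m):
        pert_peaks = detect_peaks(times, ys[:, j])
        t_after = pulse_starts[j] + tau
        ref_after = ref_peaks[ref_peaks > t_after]
        pert_after = pert_peaks[pert_peaks > t_after]
        if len(ref_after) < k or len(pert_after) < k:
            raise ValueError("trajectory too short to reach the k-th post-pulse peak")
        shifts[j] = wrap_phase((ref_after[k - 1] - pert_after[k - 1]) / T0)
    return shifts, T0


_SUPPORT_PHASES = np.arange(24) / 24.0 - 0.5  # hidden grid for branch tracking


def _unwrap_branch(phis_sorted: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Choose the phase-shift branch by continuity along the phase axis.

    Peak-time differences only determine the shift mod 1.  Anchoring on the
    small-delay region near phi = +0.25 and walking outward, each value is
    placed on the branch closest to its neighbour.  This keeps the advance
    branch positive even where the advance exceeds half a cycle (early pulses
    re-anchor the clock), instead of aliasing it to a spurious delay.
    """
    out = np.empty_like(raw)
    anchor = int(np.argmin(np.abs(phis_sorted - 0.25)))
    out[anchor] = wrap_phase(raw[anchor])
    for i in range(anchor + 1, len(raw)):
        out[i] = out[i - 1] + wrap_phase(raw[i] - out[i - 1])
    for i in range(anchor - 1, -1, -1):
        out[i] = out[i + 1] + wrap_phase(raw[i] - out[i + 1])
    return out


def _phase_shifts(
    params: OptoParams,
    phis: np.ndarray,
    tau: float,
    beta_prime_pulse: float,
    k: int = 3,
    dt: float = DEFAULT_DT,
    T0: float | None = None,
    establish_cycles: int = 5,
) -> tuple[np.ndarray, float]:
    """Branch-resolved phase shifts at arbitrary pulse-arrival phases.

    Requested phases are evaluated together with a fixed support grid dense
    enough for :func:`_unwrap_branch` to track the shift branch continuously.
    """
    phis_req = wrap_phase(np.asarray(phis, dtype=float))
    allph = np.concatenate([np.atleast_1d(phis_req), _SUPPORT_PHASES])
    uniq, inverse = np.unique(np.round(allph, 9), return_inverse=True)
    raw, T0 = _phase_shifts_raw(
        params, uniq, tau, beta_prime_pulse,
        k=k, dt=dt, T0=T0, establish_cycles=establish_cycles,
    )
    unwrapped = _unwrap_branch(uniq, raw)
    return unwrapped[inverse[: len(np.atleast_1d(phis_req))]], T0


def phase_response(
    params: OptoParams,
    phi: float,
    tau: float = 2.0,
    beta_prime_pulse: float = 80.0,
    k: int = 3,
    dt: float = DEFAULT_DT,
    T0: float | None = None,
) -> float:
    """Phase shift (cycles, advance positive) from one pulse arriving at ``phi``."""
    shifts, _ = _phase_shifts(
        params, np.array([phi]), tau, beta_prime_pulse, k=k, dt=dt, T0=T0
    )
    return float(shifts[0])


def compute_prc(
    params: OptoParams,
    tau: float = 2.0,
    beta_prime_pulse: float = 80.0,
    n_points: int = 64,
    k: int = 3,
    dt: float = DEFAULT_DT,
    T0: float | None = None,
) -> PhaseResponseCurve:
    """Phase response curve on a uniform grid of pulse-arrival phases."""
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    phis = -0.5 + np.arange(n_points) / n_points
    shifts, T0 = _phase_shifts(params, phis, tau, beta_prime_pulse, k=k, dt=dt, T0=T0)
    return PhaseResponseCurve(
        phis=phis,
        delta_phis=shifts,
        pulse_tau=tau,
        pulse_beta_prime=beta_prime_pulse,
        T0=T0,
    )


def circle_map_step(phi_n: float, prc: PhaseResponseCurve, TL: float) -> float:
    """One iteration phi_{n+1} = wrap(phi_n + TL/T0 - 1 + delta_phi(phi_n))."""
    return float(wrap_phase(phi_n + TL / prc.T0 - 1.0 + prc(phi_n)))


def iterate_circle_map(
    phi0: float, prc: PhaseResponseCurve, TL: float, n_steps: int
) -> np.ndarray:
    """The phase sequence phi_0 ... phi_n under repeated pulses."""
    phis = np.empty(n_steps + 1)
    phis[0] = wrap_phase(phi0)
    for i in range(n_steps):
        phis[i + 1] = circle_map_step(phis[i], prc, TL)
    return phis


def entrained_phase(
    prc: PhaseResponseCurve,
    TL: float,
    n_scan: int = 2048,
    tol: float = 1e-4,
) -> EntrainedState:
    """The stable circle-map fixed point for forcing period ``TL``.

    Solves ``delta_phi(phi*) = 1 - TL/T0 (mod 1)`` — the map lives on the
    circle, so the detuning only matters modulo whole cycles — by bracketing
    sign changes of the wrapped mismatch on a fine grid followed by
    bisection, then classifies stability from the local slope (stable iff
    -2 < slope < 0).  Raises :class:`OutsideLockingRangeError` when no
    stable fixed point exists, ``ValueError`` when several coexist.
    """
    target = float(wrap_phase(1.0 - TL / prc.T0))

    def mismatch(phi: float | np.ndarray):
        return wrap_phase(np.asarray(prc(phi)) - target)

    grid = np.linspace(-0.5, 0.5, n_scan + 1)
    g = np.asarray(mismatch(grid))

    roots: list[float] = []
    for a, b, ga, gb in zip(grid[:-1], grid[1:], g[:-1], g[1:]):
        if ga == 0.0:
            roots.append(float(a))
        elif ga * gb < 0 and max(abs(ga), abs(gb)) < 0.25:
            # a genuine crossing, not the +-0.5 wrap of the mismatch
            lo, hi = a, b
            glo = float(mismatch(lo))
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if float(mismatch(mid)) * glo <= 0:
                    hi = mid
                else:
                    lo = mid
                    glo = float(mismatch(lo))
            roots.append(0.5 * (lo + hi))
    if not roots:
        raise OutsideLockingRangeError(
            f"1 - TL/T0 = {target:.4f} (mod 1) is outside the phase response curve's range"
        )

    states = [
        EntrainedState(phi_star=r, slope=prc.slope(r), stable=-2.0 < prc.slope(r) < 0.0)
        for r in roots
    ]
    stable = [s for s in states if s.stable]
    if not stable:
        raise OutsideLockingRangeError("fixed points exist but none is stable")
    if len(stable) > 1:
        raise ValueError(f"multiple stable fixed points found: {stable}")
    return stable[0]


def _rising_crossings(
    times: np.ndarray, signal: np.ndarray, rise_fraction: float = 0.2
) -> np.ndarray:
    """Upward crossings of a fractional level of the signal's range."""
    level = np.min(signal) + rise_fraction * (np.max(signal) - np.min(signal))
    below = signal[:-1] < level
    above = signal[1:] >= level
    idx = np.nonzero(below & above)[0]
    frac = (level - signal[idx]) / (signal[idx + 1] - signal[idx])
    return times[idx] + frac * (times[idx + 1] - times[idx])


def measured_entrained_phase(
    trajectory: Trajectory,
    T0: float,
    discard_periods: int = 5,
    drift_tolerance: float = 0.15,
    rise_fraction: float = 0.2,
) -> tuple[float, float]:
    """Entrained phase of y peaks relative to pulse onsets, from a pulse-train run.

    Phase zero is the y expression peak; the reported value is the wrapped
    offset of each post-transient pulse start from the nearest peak, in units
    of T0, averaged circularly over pulses (mean, circular s.d.).

    Peak times are inferred from the *onset* of each y rise (upward crossing
    of ``rise_fraction`` of the trace's range) plus the free-running
    rise-onset-to-peak delay.  A pulse arriving on the rising edge truncates
    the rise and would pin a naive peak detector to the pulse itself; the
    onset marker is untouched by the pulse, so the inferred peak is the one
    the circle map reasons about.  Raises :class:`NotEntrainedError` when the
    phase drifts by more than ``drift_tolerance`` cycles over the analysed
    pulses.
    """
    starts = trajectory.protocol.pulse_starts
    if len(starts) < discard_periods + 3:
        raise ValueError("need at least discard_periods + 3 pulses")

    # onset->peak delay calibrated on a free-running cycle of the same model
    ref = simulate(
        trajectory.params, LightProtocol.constant("off"), t_end=8 * T0, dt=trajectory.dt
    )
    ref_peaks = detect_peaks(ref.times, ref.y)
    ref_onsets = _rising_crossings(ref.times, ref.y, rise_fraction)
    delays = []
    for pk in ref_peaks[2:]:
        before = ref_onsets[ref_onsets < pk]
        if len(before):
            delays.append(pk - before[-1])
    if not delays:
        raise ValueError("could not calibrate the rise-onset-to-peak delay")
    onset_to_peak = float(np.median(delays))

    onsets = _rising_crossings(trajectory.times, trajectory.y, rise_fraction)
    implied_peaks = onsets + onset_to_peak
    if len(implied_peaks) < 3:
        raise ValueError("too few y cycles in the trajectory")

    late = starts[discard_periods:]
    late = late[late < trajectory.times[-1] - 1.0]
    phis = []
    for t_p in late:
        t_pk = implied_peaks[np.argmin(np.abs(implied_peaks - t_p))]
        phis.append(wrap_phase((t_p - t_pk) / T0))
    phis = np.asarray(phis)

    angles = 2 * np.pi * phis
    C, S = np.mean(np.cos(angles)), np.mean(np.sin(angles))
    R = float(np.hypot(C, S))
    mean_phi = float(wrap_phase(np.arctan2(S, C) / (2 * np.pi)))
    # circular spread in cycles
    sd = float(np.sqrt(max(0.0, -2.0 * np.log(max(R, 1e-12)))) / (2 * np.pi))

    dev = wrap_phase(phis - mean_phi)
    if np.max(dev) - np.min(dev) > drift_tolerance:
        raise NotEntrainedError(
            f"pulse-arrival phase drifts over {np.max(dev) - np.min(dev):.3f} cycles"
        )
    return mean_phi, sd
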