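"""Vestibular time constant from post-step nystagmus (TAV paradigm).

After a velocity step the semicircular-canal signal — prolonged by the
velocity-storage mechanism — decays roughly exponentially, and so does the
slow-phase eye velocity.  The envelope is sampled once per inter-quick-phase
segment (median velocity, robust to residual quick-phase tails) and fitted
with ``v0 * exp(-t / tau)`` by nonlinear least squares, initialized from the
log-linear regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailedError, InsufficientDataError
from .segmentation import PhaseLabel, PhaseSegmentation
from .trace import EyeTrace


@dataclass(frozen=True)
class TimeConstantFit:
    tau: float              # s
    v0: float               # deg/s, envelope at the step
    fit_window: tuple[float, float]  # s, relative to the step
    rmse: float             # deg/s
    n_points: int


def slow_phase_envelope(trace: EyeTrace, seg: PhaseSegmentation, step_time: float,
                        settle: float = 0.5, min_samples: int = 4,
                        max_segment: float = 1.0) -> np.ndarray:
    """Per-segment slow-phase velocity after the velocity step.

    Returns an ``(n, 2)`` array of ``(t - step_time, median velocity)`` with
    one row per slow-labelled run starting ``settle`` seconds after the step
    (platform transients excluded).  Segment times are midpoints.  Runs
    shorter than ``min_samples`` are skipped: slivers between densely packed
    quick phases carry mostly filter ringing, not slow-phase velocity.  Runs
    longer than ``max_segment`` seconds (e.g. an entirely quick-phase-free
    decay) are chopped into ``max_segment`` pieces so the envelope still
    resolves the decay.
    """
    t = trace.timestamps
    if not (t[0] <= step_time <= t[-1]):
        raise InsufficientDataError(f"step_time {step_time}s outside the trace")
    usable = (t >= step_time + settle) & (seg.labels == PhaseLabel.SLOW)
    idx = np.flatnonzero(usable)
    if len(idx) == 0:
        raise InsufficientDataError("no slow-labelled samples after the step")
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], splits + 1])
    stops = np.concatenate([splits, [len(idx) - 1]])
    chunk = max(min_samples, int(round(max_segment * trace.sampling_rate)))
    rows = []
    for a, b in zip(starts, stops):
        run = idx[a:b + 1]
        for k in range(0, len(run), chunk):
            sel = run[k:k + chunk]
            if len(sel) < min_samples:
                continue
            rows.append((float(t[sel].mean() - step_time),
                         float(np.median(seg.velocity[sel]))))
    if len(rows) < 4:
        raise InsufficientDataError(
            f"only {len(rows)} slow segments after the step; need >= 4")
    return np.asarray(rows)


def fit_time_constant(envelope: np.ndarray, noise_floor_fraction: float = 0.1
                      ) -> TimeConstantFit:
    """Fit ``v0 * exp(-t/tau)`` to an ``(n, 2)`` envelope.

    Points after the envelope falls below ``noise_floor_fraction`` of its
    initial magnitude are excluded (log-of-noise protection).  All retained
    velocities must share one sign and decay overall, else the fit fails
    loudly rather than returning a meaningless tau.
    """
    env = np.asarray(envelope, dtype=float)
    if env.ndim != 2 or env.shape[1] != 2 or len(env) < 4:
        raise InsufficientDataError("envelope must be (n >= 4, 2)")
    order = np.argsort(env[:, 0])
    t, v = env[order, 0], env[order, 1]
    sign = np.sign(np.median(v[: max(2, len(v) // 5)]))
    if sign == 0:
        raise FitFailedError("initial envelope is zero; cannot fit a decay")
    mag = sign * v
    head = float(np.median(mag[: max(2, len(mag) // 5)]))
    if head <= 0:
        raise FitFailedError("initial envelope is non-positive; cannot fit a decay")
    below = mag < noise_floor_fraction * head
    # truncate at the first *sustained* drop below the noise floor (two
    # consecutive points); an isolated outlier mid-decay is dropped, not
    # allowed to end the fit window
    sustained = below & np.append(below[1:], True)
    cut = int(np.flatnonzero(sustained)[0]) if sustained.any() else len(mag)
    keep = ~below
    keep[cut:] = False
    if keep.sum() < 4:
        keep = np.zeros(len(mag), dtype=bool)
        keep[:4] = True
    if np.any(mag[keep] <= 0):
        raise FitFailedError("envelope velocities change sign inside the fit window")
    t_fit, m_fit = t[keep], mag[keep]
    slope, intercept = np.polyfit(t_fit, np.log(m_fit), 1)
    if slope < 0:
        tau0, v00 = -1.0 / slope, float(np.exp(intercept))
    else:
        # log-linear init defeated by early outliers; fall back to a coarse guess
        tau0, v00 = max((t_fit[-1] - t_fit[0]) / 3.0, 1e-3), head
    try:
        popt, _ = curve_fit(lambda tt, v0, tau: v0 * np.exp(-tt / tau),
                            t_fit, m_fit, p0=(v00, tau0),
                            bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailedError(f"envelope does not fit a decaying exponential: {exc}") from exc
    v0_fit, tau = float(popt[0]), float(popt[1])
    span = float(t_fit[-1] - t_fit[0])
    if tau <= 0 or not np.isfinite(tau) or tau > 20.0 * span:
        raise FitFailedError(
            f"no measurable decay inside the fit window (tau {tau:.3g}s, span {span:.3g}s)")
    resid = m_fit - v0_fit * np.exp(-t_fit / tau)
    return TimeConstantFit(tau=tau, v0=sign * v0_fit,
                           fit_window=(float(t_fit[0]), float(t_fit[-1])),
                           rmse=float(np.sqrt(np.mean(resid ** 2))),
                           n_points=int(keep.sum()))
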