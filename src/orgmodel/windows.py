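"""Observation-window sensitivity of fitted response parameters.

Longer ORG recordings pin down the slow recovery rate better but cost
acquisition and storage; this module quantifies the trade-off.  A full
recording is fitted once to give reference estimates; truncated copies
are then refitted and each parameter's deviation is expressed as a
percentage error PE = |p − p_ref|/|p_ref| × 100 against the full-window
reference.  The minimum adequate window per parameter is the shortest
window from which PE stays below a threshold (default 10%) all the way
to the reference — a sustained criterion, chosen because PE necessarily
converges to zero at the reference window by construction, which would
make a first-crossing rule overly optimistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import fit_single_flash
from .models import ORGTrace

__all__ = [
    "WindowSweepResult",
    "truncation_sweep",
    "minimum_window",
    "default_window_grid",
    "DEFAULT_PE_THRESHOLD_PCT",
]

DEFAULT_PE_THRESHOLD_PCT = 10.0
_PARAM_NAMES = ("a0", "a1", "tau_a", "tau_b")


@dataclass
class WindowSweepResult:
    """Percentage-error curves of the four model parameters vs window.

    windows: post-onset durations, s (strictly increasing; the longest is
    the reference).  pe maps each parameter name to an array of percentage
    errors (NaN where the truncated fit failed).  min_window_at_threshold
    holds the sustained-criterion minimum window per parameter (NaN when
    never achieved).
    """

    windows: np.ndarray
    pe: dict[str, np.ndarray]
    reference_window: float
    min_window_at_threshold: dict[str, float]
    threshold: float


def default_window_grid(reference: float, step: float = 0.05, start: float = 0.3) -> np.ndarray:
    """Window durations from ``start`` to the reference in ``step`` s."""
    grid = np.arange(start, reference + step / 2, step)
    if grid[-1] < reference:
        grid = np.append(grid, reference)
    grid[-1] = reference
    return grid


def truncation_sweep(
    trace: ORGTrace,
    windows: np.ndarray | None = None,
    onset: float | None = None,
    threshold: float = DEFAULT_PE_THRESHOLD_PCT,
) -> WindowSweepResult:
    """Refit truncated copies of a trace and report percentage errors.

    Each window keeps all pre-onset samples plus ``window`` seconds after
    onset; the longest window is the reference against which PE is
    computed, so PE at the reference is exactly zero.  Windows on which
    the fit fails to converge are reported as NaN.
    """
    if onset is None:
        if not trace.stimulus_onsets:
            raise ValueError("onset not given and trace has no stimulus_onsets")
        onset = trace.stimulus_onsets[0]
    rel = trace.relative_to(onset)
    available = float(rel.t[-1])
    if windows is None:
        windows = default_window_grid(available)
    windows = np.sort(np.asarray(windows, dtype=float))
    if np.any(np.diff(windows) <= 0):
        raise ValueError("windows must be strictly increasing")
    if windows[-1] > available + 1e-9:
        raise ValueError("longest window exceeds the post-onset trace duration")

    estimates: dict[str, list[float]] = {n: [] for n in _PARAM_NAMES}
    for window in windows:
        keep = rel.t <= window + 1e-12
        sub = ORGTrace(
            t=rel.t[keep], dopl=rel.dopl[keep], fs=rel.fs,
            stimulus_onsets=(0.0,), meta=dict(rel.meta),
        )
        fit = None
        try:
            fit = fit_single_flash(sub, onset=0.0)
            ok = fit.converged
        except ValueError:
            ok = False
        for name in _PARAM_NAMES:
            estimates[name].append(fit.params[name] if ok and fit else float("nan"))

    pe: dict[str, np.ndarray] = {}
    for name in _PARAM_NAMES:
        est = np.asarray(estimates[name])
        ref = est[-1]
        pe[name] = np.abs(est - ref) / np.abs(ref) * 100.0 if ref != 0 else np.full_like(est, np.nan)
    result = WindowSweepResult(
        windows=windows,
        pe=pe,
        reference_window=float(windows[-1]),
        min_window_at_threshold={},
        threshold=threshold,
    )
    result.min_window_at_threshold = minimum_window(result, threshold)
    return result


def minimum_window(
    sweep: WindowSweepResult, threshold: float = DEFAULT_PE_THRESHOLD_PCT
) -> dict[str, float]:
    """Smallest window from which PE stays below threshold to the reference.

    A parameter whose PE never sustains below the threshold (or whose
    curve is entirely NaN) is reported as NaN (not achieved).
    """
    out: dict[str, float] = {}
    for name, curve in sweep.pe.items():
        below = (curve < threshold) & np.isfinite(curve)
        achieved = float("nan")
        # scan from the long end: the sustained region is a suffix
        for i in range(len(curve) - 1, -1, -1):
            if below[i]:
                achieved = float(sweep.windows[i])
            else:
                break
        out[name] = achieved
    return out
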