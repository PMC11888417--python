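"""Closed-form response models for cone outer-segment optoretinography.

The observable is the change in optical path length (ΔOPL, nm) between the
inner segment/outer segment junction (ISOS) and the cone outer segment tip
(COST), sampled at several hundred Hz around a visible stimulus flash.  A
brief flash produces a fast contraction (a few nm to tens of nm, negative),
a slower osmotic elongation (tens to hundreds of nm), and a yet slower
recovery to baseline.  The primary model is a gated biexponential

    ΔOPL(t) = u(t) · [A0 + A1·(−exp(−τa·t) + exp(−τb·t))]

with contraction amplitude ``A0`` (nm, typically negative), elongation
amplitude ``A1`` (nm), elongation rate ``τa`` (s⁻¹) and recovery rate
``τb`` (s⁻¹); ``u`` is the Heaviside step with u(0) = 1, and t is measured
from flash onset.  Everything in this module is a pure function of its
arguments: nm, s, s⁻¹ throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "ResponseParams",
    "TwoFlashParams",
    "BackgroundParams",
    "AlternativeModelSpec",
    "EnFaceParams",
    "DerivedMetrics",
    "ORGTrace",
    "ALTERNATIVE_MODEL_IDS",
    "heaviside",
    "eval_single_flash",
    "eval_rate",
    "derived_metrics",
    "eval_two_flash",
    "eval_background",
    "eval_alternative",
    "eval_enface_intensity",
]

# Alternative response models are named by the colors conventionally used to
# plot them: magenta is the primary biexponential, green its onset-shifted
# zero-asymptote twin, red a single saturating exponential, blue an
# offset-free biexponential, cyan a sum of two saturating exponentials.
ALTERNATIVE_MODEL_IDS = ("magenta", "green", "red", "blue", "cyan")


def _check_finite_times(t: np.ndarray) -> None:
    if not np.all(np.isfinite(t)):
        raise ValueError("time values must be finite")


def heaviside(t: np.ndarray | float) -> np.ndarray:
    """Unit step gating the flash response: 1 for t >= 0, 0 for t < 0."""
    return np.where(np.asarray(t, dtype=float) >= 0.0, 1.0, 0.0)


@dataclass(frozen=True)
class ResponseParams:
    """Four parameters of the single-flash biexponential response.

    a0
        Contraction amplitude, nm. The model value at t = 0; typically
        negative (early outer-segment contraction).
    a1
        Elongation amplitude, nm. Nonnegative in canonical orientation.
    tau_a
        Fast elongation rate constant, s⁻¹.
    tau_b
        Slow recovery rate constant, s⁻¹.

    The parameterization is degenerate under (a1, tau_a, tau_b) ->
    (-a1, tau_b, tau_a); :meth:`canonical` resolves the ambiguity in
    favour of tau_a >= tau_b with a1 >= 0.
    """

    a0: float
    a1: float
    tau_a: float
    tau_b: float

    def __post_init__(self) -> None:
        if not (self.tau_a > 0 and self.tau_b > 0):
            raise ValueError(
                f"rate constants must be positive, got tau_a={self.tau_a}, "
                f"tau_b={self.tau_b}"
            )

    def canonical(self) -> "ResponseParams":
        """Return the equivalent parameter set with tau_a >= tau_b, a1 >= 0."""
        if self.tau_a >= self.tau_b:
            return self
        return ResponseParams(self.a0, -self.a1, self.tau_b, self.tau_a)

    def as_dict(self) -> dict[str, float]:
        return {"a0": self.a0, "a1": self.a1, "tau_a": self.tau_a, "tau_b": self.tau_b}


@dataclass(frozen=True)
class TwoFlashParams:
    """Parameters of the shifted-sum two-flash model.

    ``alpha`` describes the response to the first flash (onset t = 0) and
    ``beta`` the response to the second, delayed by the inter-stimulus
    interval ``t_isi`` (s, onset-to-onset).
    """

    alpha: ResponseParams
    beta: ResponseParams
    t_isi: float

    def __post_init__(self) -> None:
        if self.t_isi < 0:
            raise ValueError(f"t_isi must be >= 0, got {self.t_isi}")


@dataclass(frozen=True)
class BackgroundParams:
    """Flash response superposed on the steady elongation ramp of an
    adapting background: ΔOPL(t) = flash(t) + m·t, slope ``m`` in nm/s.

    The ramp is not gated by the step function: the background is on
    before the flash, so the linear term is live over the whole record.
    """

    flash: ResponseParams
    m: float


@dataclass(frozen=True)
class AlternativeModelSpec:
    """One of the alternative response models, identified by plot color.

    params maps parameter names to values; all models use subsets of
    {a0, a1, tau_a, tau_b, t0}:

    - ``magenta``: the primary model (a0, a1, tau_a, tau_b)
    - ``green``: a1·(−exp(−τa(t−t0)) + exp(−τb(t−t0))) gated at t = 0,
      with onset shift t0 >= 0; converges to 0 as t → ∞
    - ``red``: a1·(1 − exp(−τa t)) — elongation only
    - ``blue``: a1·(−exp(−τa t) + exp(−τb t)) — elongation and recovery,
      no contraction offset
    - ``cyan``: a0·(1 − exp(−τa t)) + a1·(1 − exp(−τb t)) — two saturating
      exponentials
    """

    model_id: str
    params: Mapping[str, float] = field(default_factory=dict)

    _REQUIRED = {
        "magenta": ("a0", "a1", "tau_a", "tau_b"),
        "green": ("a1", "tau_a", "tau_b", "t0"),
        "red": ("a1", "tau_a"),
        "blue": ("a1", "tau_a", "tau_b"),
        "cyan": ("a0", "a1", "tau_a", "tau_b"),
    }

    def __post_init__(self) -> None:
        if self.model_id not in ALTERNATIVE_MODEL_IDS:
            raise ValueError(
                f"unknown model_id {self.model_id!r}; expected one of "
                f"{ALTERNATIVE_MODEL_IDS}"
            )
        missing = [k for k in self._REQUIRED[self.model_id] if k not in self.params]
        if missing:
            raise ValueError(f"{self.model_id} model missing parameters {missing}")
        for key in ("tau_a", "tau_b"):
            if key in self._REQUIRED[self.model_id] and self.params[key] <= 0:
                raise ValueError(f"{key} must be > 0")
        if self.model_id == "green" and self.params["t0"] < 0:
            raise ValueError("green model requires t0 >= 0")


@dataclass(frozen=True)
class EnFaceParams:
    """Intensity forward model for en-face (2D, common-path) ORG detection.

    ISOS/COST interference turns outer-segment length change into cone
    brightness: I(t) = C1 + C2·cos(n·(4π/λ)·ΔL(t) + φ0) where ΔL is the
    elongation term of the response, n the refractive index, λ the probe
    wavelength in nm and φ0 a static phase offset.
    """

    c1: float
    c2: float
    n: float = 1.38
    lambda_probe: float = 850.0
    phi0: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_probe <= 0:
            raise ValueError("lambda_probe must be > 0")
        if self.c2 < 0:
            raise ValueError("c2 must be >= 0")


@dataclass(frozen=True)
class DerivedMetrics:
    """Figures of merit derived from the single-flash model.

    t_max
        Time of maximum elongation, s: t_max = −log(τb/τa)/(τa − τb),
        with analytic limit 1/τa when τa == τb (``degenerate`` set).
    dopl_max
        ΔOPL at t_max, nm.
    rate_at
        Callable evaluating the elongation rate (nm/s) at a query time.
    """

    t_max: float
    dopl_max: float
    rate_at: Callable[[float], float]
    degenerate: bool = False


@dataclass
class ORGTrace:
    """A uniformly sampled ΔOPL(t) record with stimulus annotations.

    t is in seconds (uniform spacing 1/fs), dopl in nm, fs in Hz;
    stimulus_onsets lists flash onset times on the same clock as t.
    """

    t: np.ndarray
    dopl: np.ndarray
    fs: float
    stimulus_onsets: tuple[float, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dopl = np.asarray(self.dopl, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.t.ndim != 1 or self.t.shape != self.dopl.shape:
            raise ValueError("t and dopl must be 1-D arrays of equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            bad = np.flatnonzero(np.abs(dt - 1.0 / self.fs) > 1e-9)
            if bad.size:
                raise ValueError(
                    f"time grid not uniform at 1/fs: first offending index {bad[0] + 1}"
                )
        self.stimulus_onsets = tuple(float(o) for o in self.stimulus_onsets)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def relative_to(self, onset: float) -> "ORGTrace":
        """Re-zero the time axis at ``onset`` (stimulus clock)."""
        return ORGTrace(
            t=self.t - onset,
            dopl=self.dopl.copy(),
            fs=self.fs,
            stimulus_onsets=tuple(o - onset for o in self.stimulus_onsets),
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def eval_single_flash(params: ResponseParams, t: np.ndarray | float) -> np.ndarray:
    """Evaluate the gated biexponential response at times t (s, onset at 0).

    Returns u(t)·[a0 + a1·(−exp(−τa t) + exp(−τb t))] in nm, vectorized
    over t.  u(0) = 1, so the value at onset is exactly a0.
    """
    t_arr = np.asarray(t, dtype=float)
    _check_finite_times(t_arr)
    gate = heaviside(t_arr)
    # evaluate exponentials only where gated on, to avoid overflow at t << 0
    tt = np.where(gate > 0, t_arr, 0.0)
    val = gate * (
        params.a0
        + params.a1 * (-np.exp(-params.tau_a * tt) + np.exp(-params.tau_b * tt))
    )
    return val if np.ndim(t) else float(val)


def eval_rate(params: ResponseParams, t: np.ndarray | float) -> np.ndarray:
    """Elongation rate dΔOPL/dt (nm/s) at time t > 0.

    The distributional impulse contributed by the step discontinuity at
    t = 0 is excluded: the rate is defined only strictly after onset.
    """
    t_arr = np.asarray(t, dtype=float)
    _check_finite_times(t_arr)
    if np.any(t_arr <= 0):
        raise ValueError("eval_rate is defined only for t > 0")
    val = params.a1 * (
        params.tau_a * np.exp(-params.tau_a * t_arr)
        - params.tau_b * np.exp(-params.tau_b * t_arr)
    )
    return val if np.ndim(t) else float(val)


def derived_metrics(
    params: ResponseParams, rate_time_tol: float = 0.0
) -> DerivedMetrics:
    """Closed-form time and magnitude of maximum elongation.

    t_max = −log(τb/τa)/(τa − τb); when τa == τb (within ``rate_time_tol``
    relative tolerance) the analytic 0/0 limit 1/τa is used and the result
    is flagged degenerate.  dopl_max is the model evaluated at t_max, so
    the pair is exactly self-consistent.
    """
    ta, tb = params.tau_a, params.tau_b
    if abs(ta - tb) <= rate_time_tol * max(ta, tb):
        t_max = 1.0 / ta
        degenerate = True
    else:
        t_max = -np.log(tb / ta) / (ta - tb)
        degenerate = False
    dopl_max = float(eval_single_flash(params, t_max))
    return DerivedMetrics(
        t_max=float(t_max),
        dopl_max=dopl_max,
        rate_at=lambda tq: float(eval_rate(params, tq)),
        degenerate=degenerate,
    )


def eval_two_flash(params: TwoFlashParams, t: np.ndarray | float) -> np.ndarray:
    """Shifted-sum two-flash response: alpha(t) + beta(t − t_isi), nm."""
    t_arr = np.asarray(t, dtype=float)
    val = eval_single_flash(params.alpha, t_arr) + eval_single_flash(
        params.beta, t_arr - params.t_isi
    )
    return val if np.ndim(t) else float(val)


def eval_background(params: BackgroundParams, t: np.ndarray | float) -> np.ndarray:
    """Flash response plus ungated background ramp m·t, nm."""
    t_arr = np.asarray(t, dtype=float)
    val = eval_single_flash(params.flash, t_arr) + params.m * t_arr
    return val if np.ndim(t) else float(val)


def eval_alternative(spec: AlternativeModelSpec, t: np.ndarray | float) -> np.ndarray:
    """Evaluate one of the color-named alternative response models, nm."""
    t_arr = np.asarray(t, dtype=float)
    _check_finite_times(t_arr)
    p = spec.params
    gate = heaviside(t_arr)
    tt = np.where(gate > 0, t_arr, 0.0)
    if spec.model_id == "magenta":
        core = p["a0"] + p["a1"] * (
            -np.exp(-p["tau_a"] * tt) + np.exp(-p["tau_b"] * tt)
        )
    elif spec.model_id == "green":
        ts = tt - p["t0"]
        core = p["a1"] * (-np.exp(-p["tau_a"] * ts) + np.exp(-p["tau_b"] * ts))
    elif spec.model_id == "red":
        core = p["a1"] * (1.0 - np.exp(-p["tau_a"] * tt))
    elif spec.model_id == "blue":
        core = p["a1"] * (-np.exp(-p["tau_a"] * tt) + np.exp(-p["tau_b"] * tt))
    else:  # cyan
        core = p["a0"] * (1.0 - np.exp(-p["tau_a"] * tt)) + p["a1"] * (
            1.0 - np.exp(-p["tau_b"] * tt)
        )
    val = gate * core
    return val if np.ndim(t) else float(val)


def eval_enface_intensity(
    enface: EnFaceParams, params: ResponseParams, t: np.ndarray | float
) -> np.ndarray:
    """Predicted en-face cone intensity (arbitrary units) at times t.

    The elongation term a1·(−exp(−τa t) + exp(−τb t)) of the response enters
    the interference phase as n·(4π/λ)·ΔL(t); the contraction offset a0 is
    not part of the phase argument in this forward model.
    """
    t_arr = np.asarray(t, dtype=float)
    _check_finite_times(t_arr)
    elong = params.a1 * (
        -np.exp(-params.tau_a * t_arr) + np.exp(-params.tau_b * t_arr)
    )
    phase = enface.n * (4.0 * np.pi / enface.lambda_probe) * elong + enface.phi0
    val = enface.c1 + enface.c2 * np.cos(phase)
    return val if np.ndim(t) else float(val)
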