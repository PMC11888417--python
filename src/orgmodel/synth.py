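"""Synthetic ORG traces and complex cone subvolumes.

The generators emulate the study conditions the analysis assumes: 400 Hz
volume rate, 1 s or 3 s records, stimulus onset at 200 ms, additive
Gaussian noise on ΔOPL of ~10 nm, and — for the paired-flash and
pulse-train scenarios — attenuation of the second response by the first:
the contraction amplitude ratio grows linearly with the inter-stimulus
interval (slope 2.3 s⁻¹, reaching 1 at ≈300 ms) and the elongation
amplitude ratio sits at 0.85, inside the observed 0.75–1 band.  These
attenuation constants parameterize the generator; they are conventions
for producing realistic fixtures, not measurements.

Subvolume synthesis inverts the phase-extraction pipeline: per-A-scan
ISOS phasors with fixed random phases, COST phasors advanced by
ΔΦ(t) = ΔOPL·4π/λ (wrapping arises naturally from the complex
representation), plus circular complex Gaussian noise at a chosen
amplitude SNR (unit signal amplitude over RMS noise magnitude).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .models import (
    BackgroundParams,
    ORGTrace,
    ResponseParams,
    TwoFlashParams,
    eval_background,
    eval_single_flash,
    eval_two_flash,
)
from .phase import DEFAULT_WAVELENGTH_NM, ConeSubvolumeSeries

__all__ = [
    "SimulationConfig",
    "attenuation_factors",
    "simulate_single_flash_trace",
    "simulate_two_flash_trace",
    "simulate_pulse_train_trace",
    "simulate_background_trace",
    "simulate_subvolume_series",
    "DEFAULT_A0_ATTENUATION_SLOPE",
    "DEFAULT_A0_ATTENUATION_INTERCEPT",
    "DEFAULT_A1_ATTENUATION_RATIO",
]

#: contraction-ratio trend vs inter-stimulus interval: ratio = slope·t + intercept
DEFAULT_A0_ATTENUATION_SLOPE = 2.3  # 1/s
DEFAULT_A0_ATTENUATION_INTERCEPT = 0.31
#: elongation amplitude ratio of a second response to the first
DEFAULT_A1_ATTENUATION_RATIO = 0.85


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition conditions for a synthetic trace.

    Defaults mirror the measurement protocol: 400 Hz sampling for 3 s
    with the flash at 200 ms and ~10 nm ΔOPL noise.
    """

    fs: float = 400.0
    duration_s: float = 3.0
    onset_s: float = 0.2
    noise_sigma_nm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if not (0 <= self.onset_s < self.duration_s):
            raise ValueError("onset must lie within the record")
        if self.noise_sigma_nm < 0:
            raise ValueError("noise_sigma_nm must be >= 0")

    @property
    def t(self) -> np.ndarray:
        n = int(round(self.duration_s * self.fs))
        return np.arange(n) / self.fs


def attenuation_factors(
    gap_s: float,
    slope: float = DEFAULT_A0_ATTENUATION_SLOPE,
    intercept: float = DEFAULT_A0_ATTENUATION_INTERCEPT,
    a1_ratio: float = DEFAULT_A1_ATTENUATION_RATIO,
) -> tuple[float, float]:
    """(a0 factor, a1 factor) attenuating a response ``gap_s`` after another.

    The contraction factor saturates at 1: min(1, slope·gap + intercept).
    """
    return min(1.0, slope * gap_s + intercept), a1_ratio


def _finish(
    t: np.ndarray, clean: np.ndarray, cfg: SimulationConfig,
    onsets: tuple[float, ...], meta: dict,
) -> ORGTrace:
    rng = np.random.default_rng(cfg.seed)
    noise = rng.normal(0.0, cfg.noise_sigma_nm, size=clean.shape) \
        if cfg.noise_sigma_nm > 0 else np.zeros_like(clean)
    return ORGTrace(
        t=t, dopl=clean + noise, fs=cfg.fs, stimulus_onsets=onsets, meta=meta
    )


def simulate_single_flash_trace(
    params: ResponseParams, cfg: SimulationConfig = SimulationConfig()
) -> ORGTrace:
    """Single-flash model on the uniform grid plus i.i.d. Gaussian noise."""
    t = cfg.t
    clean = eval_single_flash(params, t - cfg.onset_s)
    return _finish(t, clean, cfg, (cfg.onset_s,),
                   {"scenario": "single", "params": params.as_dict()})


def simulate_two_flash_trace(
    alpha: ResponseParams,
    t_isi: float,
    cfg: SimulationConfig = SimulationConfig(),
    slope: float = DEFAULT_A0_ATTENUATION_SLOPE,
    intercept: float = DEFAULT_A0_ATTENUATION_INTERCEPT,
    a1_ratio: float = DEFAULT_A1_ATTENUATION_RATIO,
) -> ORGTrace:
    """Paired-flash trace with the second response attenuated by the first.

    beta is derived from alpha by the attenuation rule; rate constants
    are carried over unchanged.
    """
    f0, f1 = attenuation_factors(t_isi, slope, intercept, a1_ratio)
    beta = ResponseParams(alpha.a0 * f0, alpha.a1 * f1, alpha.tau_a, alpha.tau_b)
    params = TwoFlashParams(alpha=alpha, beta=beta, t_isi=t_isi)
    t = cfg.t
    clean = eval_two_flash(params, t - cfg.onset_s)
    meta = {
        "scenario": "paired", "t_isi": t_isi,
        "alpha": alpha.as_dict(), "beta": beta.as_dict(),
    }
    return _finish(t, clean, cfg, (cfg.onset_s, cfg.onset_s + t_isi), meta)


def simulate_pulse_train_trace(
    base: ResponseParams,
    n: int,
    interval: float,
    cfg: SimulationConfig = SimulationConfig(),
    slope: float = DEFAULT_A0_ATTENUATION_SLOPE,
    intercept: float = DEFAULT_A0_ATTENUATION_INTERCEPT,
    a1_ratio: float = DEFAULT_A1_ATTENUATION_RATIO,
) -> ORGTrace:
    """Train of n flash responses with cumulative attenuation.

    Each flash after the first has its amplitudes multiplied by the
    attenuation factors for the elapsed interval since the previous
    flash, compounded along the train, so responses diminish until they
    sink below the noise floor.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > 1 and interval <= 0:
        raise ValueError("interval must be > 0")
    t = cfg.t
    clean = np.zeros_like(t)
    onsets = []
    f0_cum, f1_cum = 1.0, 1.0
    flash_params = []
    for k in range(n):
        onset_k = cfg.onset_s + k * interval
        if k > 0:
            g0, g1 = attenuation_factors(interval, slope, intercept, a1_ratio)
            f0_cum *= g0
            f1_cum *= g1
        pk = ResponseParams(base.a0 * f0_cum, base.a1 * f1_cum, base.tau_a, base.tau_b)
        flash_params.append(pk.as_dict())
        clean = clean + eval_single_flash(pk, t - onset_k)
        onsets.append(onset_k)
    meta = {"scenario": "train", "n": n, "interval": interval,
            "flash_params": flash_params}
    return _finish(t, clean, cfg, tuple(onsets), meta)


def simulate_background_trace(
    flash: ResponseParams, m: float, cfg: SimulationConfig = SimulationConfig()
) -> ORGTrace:
    """Flash response on a constant-rate background elongation ramp.

    The ramp m·t is live over the whole record (crossing zero at flash
    onset), as under a steady adapting background.
    """
    params = BackgroundParams(flash=flash, m=m)
    t = cfg.t
    clean = eval_background(params, t - cfg.onset_s)
    meta = {"scenario": "background", "m": m, "flash": flash.as_dict()}
    return _finish(t, clean, cfg, (cfg.onset_s,), meta)


def simulate_subvolume_series(
    trace: ORGTrace,
    amplitude_snr: float = np.inf,
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM,
    seed: int = 0,
    n_a_scans: int = 9,
) -> ConeSubvolumeSeries:
    """Encode a ΔOPL trace into a complex ISOS/COST subvolume series.

    Each A-scan gets a fixed random ISOS phase; the COST phase leads it by
    ΔΦ(t) = ΔOPL(t)·4π/λ.  Signal amplitudes are 1; circular complex
    Gaussian noise with RMS magnitude 1/amplitude_snr is added to both
    surfaces (none when amplitude_snr is infinite).
    """
    if amplitude_snr <= 0:
        raise ValueError("amplitude_snr must be > 0")
    rng = np.random.default_rng(seed)
    n_t = len(trace.t)
    psi = rng.uniform(-np.pi, np.pi, size=n_a_scans)
    dphi = trace.dopl * 4.0 * np.pi / wavelength_nm
    isos = np.exp(1j * np.broadcast_to(psi, (n_t, n_a_scans))).astype(complex)
    cost = np.exp(1j * (psi[None, :] + dphi[:, None]))
    if np.isfinite(amplitude_snr):
        sigma = 1.0 / amplitude_snr / np.sqrt(2.0)  # per quadrature component
        for arr in (isos, cost):
            arr += rng.normal(0.0, sigma, arr.shape) \
                + 1j * rng.normal(0.0, sigma, arr.shape)
    return ConeSubvolumeSeries(
        isos=isos,
        cost=cost,
        fs=trace.fs,
        wavelength_nm=wavelength_nm,
        stimulus_onsets=trace.stimulus_onsets,
        meta={"encoded_from": dict(trace.meta), "amplitude_snr": float(amplitude_snr)},
    )
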