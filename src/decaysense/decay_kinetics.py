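"""One-phase decay fitting and half-life extraction.

The measured chemiluminescence signal of a well decays as a single
exponential toward a plateau,

    I(t) = A * exp(-k * t) + c,

with amplitude A > 0 (span above the plateau at t = 0), plateau c
(unconstrained in sign — detector baselines can dip below zero), and decay
rate k > 0 per minute.  The half-lifetime T1/2 = ln(2)/k is the feature the
rest of the pipeline consumes: it is the time for the signal to fall halfway
from its current excess toward the plateau, and is independent of amplitude
scaling.

Fitting is unweighted nonlinear least squares.  Per-well failures are
reported, never raised, so a single bad well cannot abort a plate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitInputError, NonIdentifiableTraceError
from .plate_io import DecayTrace, WellRecord

LN2 = math.log(2.0)


@dataclass(frozen=True)
class FitOptions:
    """Controls for the least-squares fit.

    ``tol`` is the relative tolerance on the cost (SSE) change; ``max_evals``
    caps function evaluations.  Both are recorded in every fit result.
    """

    tol: float = 1e-10
    max_evals: int = 10_000


@dataclass(frozen=True)
class DecayFit:
    """Fitted one-phase decay parameters for a single trace."""

    amplitude: float
    plateau: float
    rate_k: float
    half_life: float
    rss: float
    converged: bool
    message: str = ""
    options: FitOptions = field(default_factory=FitOptions, repr=False)


def half_life_from_rate(rate_k: float) -> float:
    """Half-life in minutes for decay rate ``rate_k`` (per minute): ln(2)/k."""
    if not rate_k > 0:
        raise ValueError(f"rate must be positive, got {rate_k}")
    return LN2 / rate_k


def one_phase_decay(t: np.ndarray, amplitude: float, rate_k: float, plateau: float) -> np.ndarray:
    """Evaluate A*exp(-k*t) + c on times ``t``."""
    return amplitude * np.exp(-rate_k * np.asarray(t, dtype=float)) + plateau


def _initial_guess(times: np.ndarray, intensities: np.ndarray) -> tuple[float, float, float]:
    """Derivative-free start: plateau from the minimum, amplitude from the span,
    rate from the log-linear slope of the first half of the background-subtracted
    trace."""
    plateau0 = float(intensities.min())
    amplitude0 = float(intensities.max() - intensities.min())
    half = max(len(times) // 2, 2)
    # shrink background slightly so early log arguments stay positive
    y = intensities[:half] - plateau0 + 1e-12 * max(amplitude0, 1.0)
    mask = y > 0
    if mask.sum() >= 2:
        slope = np.polyfit(times[:half][mask], np.log(y[mask]), 1)[0]
        k0 = max(-float(slope), 1e-6)
    else:
        k0 = LN2 / max(times[-1] - times[0], 1.0)
    return amplitude0, k0, plateau0


def fit_one_phase_decay(trace: DecayTrace, options: FitOptions | None = None) -> DecayFit:
    """Fit I(t) = A*exp(-k*t) + c to one trace by least squares.

    Returns a :class:`DecayFit`; optimizer failure yields ``converged=False``
    with diagnostics in ``message`` rather than an exception.

    Raises
    ------
    FitInputError
        Fewer than 4 points or non-finite intensities.
    NonIdentifiableTraceError
        A flat trace (zero intensity variance): the rate is undefined.
    """
    options = options or FitOptions()
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.intensities, dtype=float)
    if len(t) < 4:
        raise FitInputError(f"need >= 4 points to fit, got {len(t)}")
    if not np.isfinite(y).all():
        raise FitInputError("non-finite intensities")
    if np.ptp(y) == 0.0:
        raise NonIdentifiableTraceError("flat trace: decay rate is not identifiable")

    a0, k0, c0 = _initial_guess(t, y)

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, k, c = theta
        return a * np.exp(-k * t) + c - y

    try:
        res = least_squares(
            residuals,
            x0=[max(a0, 1e-9), k0, c0],
            bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            ftol=options.tol,
            xtol=1e-14,
            gtol=1e-14,
            max_nfev=options.max_evals,
        )
    except Exception as exc:  # optimizer blow-up: report, don't raise
        return DecayFit(
            amplitude=float("nan"), plateau=float("nan"), rate_k=float("nan"),
            half_life=float("nan"), rss=float("nan"), converged=False,
            message=f"optimizer error: {exc}", options=options,
        )

    amplitude, rate_k, plateau = (float(v) for v in res.x)
    rss = float(np.sum(res.fun**2))
    converged = bool(res.success) and rate_k > 0
    return DecayFit(
        amplitude=amplitude,
        plateau=plateau,
        rate_k=rate_k,
        half_life=LN2 / rate_k if rate_k > 0 else float("nan"),
        rss=rss,
        converged=converged,
        message=str(res.message),
        options=options,
    )


def fit_plate(records: Iterable[WellRecord], options: FitOptions | None = None) -> pd.DataFrame:
    """Fit every well of a plate; one row per input well.

    Per-well failures (flat traces, optimizer breakdown) become
    ``converged=False`` rows with NaN parameters — the plate never aborts.
    Replicates are fitted independently; averaging happens downstream.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record collection")
    rows = []
    for rec in records:
        try:
            fit = fit_one_phase_decay(rec.trace, options)
        except (FitInputError, NonIdentifiableTraceError) as exc:
            fit = DecayFit(
                amplitude=float("nan"), plateau=float("nan"), rate_k=float("nan"),
                half_life=float("nan"), rss=float("nan"), converged=False,
                message=str(exc), options=options or FitOptions(),
            )
        rows.append(
            {
                "well_id": rec.well_id,
                "sample_id": rec.sample_id,
                "compound_id": rec.compound_id,
                "replicate": rec.replicate,
                "amplitude": fit.amplitude,
                "plateau": fit.plateau,
                "rate_k": fit.rate_k,
                "half_life": fit.half_life,
                "rss": fit.rss,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
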