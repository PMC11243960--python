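"""Saturation-pulse (PAM) quenching analysis and rapid-light-curve fitting.

Per-step quenching parameters from a :class:`~fluoromics.containers.LightCurveDataset`::

    ΦPSII = (Fm' - F) / Fm'
    NPQ   = (Fm - Fm') / Fm'
    Fo'   = F0 / (Fv/Fm + F0/Fm')          (Oxborough–Baker estimate)
    qP    = (Fm' - F) / (Fm' - Fo')
    Y(NO) = F / Fm                          (simplified lake-model form)
    rETR  = ΦPSII * PAR * psii_fraction * absorption

and the light curve rETR(PAR) is fitted with the saturating tanh model
``rETR = ETRmax * tanh(alpha * PAR / ETRmax)``, giving the initial slope
alpha, the plateau ETRmax and the light-saturation point Ek = ETRmax/alpha.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .containers import LightCurveDataset
from .errors import FitError, ValidationError

__all__ = [
    "QuenchingParameters",
    "LightCurveFit",
    "quenching_parameters",
    "fit_light_curve",
]

#: default leaf absorption factor and PSII excitation fraction for rETR
ABSORPTION = 0.84
PSII_FRACTION = 0.5


@dataclass
class QuenchingParameters:
    """Per-step quenching parameters plus the dark-adapted Fv/Fm."""

    table: pd.DataFrame    # columns: par, f, fm_prime, phi_psii, npq, qp, y_no, retr, fo_prime
    fv_fm: float
    warnings: list


@dataclass(frozen=True)
class LightCurveFit:
    """Result of fitting rETR = ETRmax * tanh(alpha * PAR / ETRmax)."""

    alpha: float
    etrmax: float
    ek: float          # ETRmax / alpha, by definition
    rss: float
    converged: bool
    n_steps: int


def quenching_parameters(
    ds: LightCurveDataset,
    absorption: float = ABSORPTION,
    psii_fraction: float = PSII_FRACTION,
    y_no_form: str = "simple",
) -> QuenchingParameters:
    """Compute per-step quenching parameters for a light-curve dataset.

    ``y_no_form`` selects Y(NO) = F/Fm (``"simple"``, default) or the Kramer
    form ``1 / (1 + NPQ + qL * (Fm/F0 - 1))`` with qL = qP * Fo'/F
    (``"kramer"``).  Steps where Fm' exceeds the dark Fm (NPQ < 0) or where
    Fm' equals Fo' (qP undefined) are flagged, not silently dropped.
    """
    fv_fm = ds.fv_fm
    par, f, fmp = ds.par, ds.f, ds.fm_prime
    notes: list[str] = []

    phi = (fmp - f) / fmp
    npq = (ds.fm - fmp) / fmp
    if np.any(npq < -1e-12):
        notes.append("Fm' exceeds dark-adapted Fm at some steps; NPQ < 0 there")
    fo_prime = ds.f0 / (fv_fm + ds.f0 / fmp)
    denom = fmp - fo_prime
    qp = np.full_like(par, np.nan)
    ok = np.abs(denom) > 1e-12 * ds.fm
    qp[ok] = (fmp[ok] - f[ok]) / denom[ok]
    if not ok.all():
        notes.append("Fm' == Fo' at some steps; qP undefined there (NaN)")
    if y_no_form == "simple":
        y_no = f / ds.fm
    elif y_no_form == "kramer":
        ql = qp * fo_prime / f
        y_no = 1.0 / (1.0 + npq + ql * (ds.fm / ds.f0 - 1.0))
    else:
        raise ValidationError(f"unknown y_no_form: {y_no_form!r}")
    retr = phi * par * psii_fraction * absorption

    table = pd.DataFrame(
        {
            "par": par, "f": f, "fm_prime": fmp, "phi_psii": phi, "npq": npq,
            "qp": qp, "y_no": y_no, "retr": retr, "fo_prime": fo_prime,
        }
    )
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return QuenchingParameters(table=table, fv_fm=fv_fm, warnings=notes)


def _tanh_model(par: np.ndarray, alpha: float, etrmax: float) -> np.ndarray:
    return etrmax * np.tanh(alpha * par / etrmax)


def fit_light_curve(par: np.ndarray, retr: np.ndarray) -> LightCurveFit:
    """Least-squares fit of the tanh rapid-light-curve model.

    Uses multi-start initialisation: alpha from the slope of the first two
    non-dark steps, ETRmax from the largest observed rETR, plus perturbed
    restarts; the best (lowest-RSS) converged solution is returned.
    Non-convergence raises :class:`FitError` rather than returning silently.
    """
    par = np.asarray(par, dtype=float)
    retr = np.asarray(retr, dtype=float)
    if par.shape != retr.shape:
        raise ValidationError("par and retr must have equal length")
    usable = np.unique(par).size
    if usable < 4:
        raise FitError(f"need >= 4 distinct PAR steps to fit, got {usable}")
    if np.all(retr <= 0):
        raise FitError("all rETR values are <= 0; nothing to fit")

    light = par > 0
    p, r = par[light], retr[light]
    alpha0 = max(r[0] / p[0], 1e-6)
    etrmax0 = max(float(r.max()), 1e-6)

    best: tuple[float, np.ndarray] | None = None
    for fa, fe in ((1.0, 1.0), (0.5, 1.5), (2.0, 0.8), (1.0, 3.0)):
        try:
            popt, _ = curve_fit(
                _tanh_model, par, retr,
                p0=(alpha0 * fa, etrmax0 * fe),
                bounds=((1e-12, 1e-12), (np.inf, np.inf)),
                maxfev=10000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((retr - _tanh_model(par, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise FitError("light-curve fit did not converge from any start")
    rss, (alpha, etrmax) = best
    return LightCurveFit(
        alpha=float(alpha), etrmax=float(etrmax), ek=float(etrmax / alpha),
        rss=rss, converged=True, n_steps=int(par.size),
    )
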