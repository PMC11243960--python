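"""Fast-fluorescence (OJIP) analysis: cardinal points, normalisations,
treatment-minus-control difference curves and the JIP-test parameter set.

Cardinal points follow the standard definitions: O is the minimum
fluorescence, K the 300 µs value, J the 2 ms value, I the 30 ms value and
P the maximum.  Normalisations::

    Ft/Fo                         (O-point standardisation)
    Vt = (Ft - Fo) / (Fm - Fo)    (O-P segment)
    Wt = (Ft - Fo) / (FJ - Fo)    (O-J segment)

Difference curves ΔVt and ΔWt are treatment minus control on the treatment
grid; ΔWk = ΔWt at 300 µs is the K-band statistic: ΔWk > 0 marks elevated
K-band fluorescence, i.e. donor-side (oxygen-evolving-complex) impairment.

The derived parameter set follows the JIP-test of Strasser and co-workers
(the parameter formulary conventionally used with Handy-PEA data); each
formula is given in the corresponding docstring.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._utils import interp_log_time
from .containers import FluorescenceTransient, T_I, T_J, T_K
from .errors import DegenerateTransientError, ValidationError

__all__ = [
    "CardinalPoints",
    "NormalizedCurves",
    "DifferenceCurves",
    "JIPParameterSet",
    "extract_cardinal_points",
    "normalize_transient",
    "difference_curves",
    "jip_parameters",
]


@dataclass(frozen=True)
class CardinalPoints:
    """Fluorescence at the O, K, J, I and P points of one transient."""

    fo: float        # minimum fluorescence (point O)
    fk: float        # fluorescence at 300 µs (point K)
    fj: float        # fluorescence at 2 ms (point J)
    fi: float        # fluorescence at 30 ms (point I)
    fm: float        # maximum fluorescence (point P)
    t_fo: float      # time of the minimum (s)
    t_fm: float      # time of the maximum (s)

    def __post_init__(self) -> None:
        vals = (self.fo, self.fk, self.fj, self.fi, self.fm)
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError("cardinal points must be finite")


@dataclass
class NormalizedCurves:
    """The three standardised curves on the input time grid."""

    time: np.ndarray
    ft_fo: np.ndarray   # Ft/Fo
    vt: np.ndarray      # (Ft - Fo)/(Fm - Fo)
    wt: np.ndarray      # (Ft - Fo)/(FJ - Fo)
    points: CardinalPoints


@dataclass
class DifferenceCurves:
    """ΔVt / ΔWt (treatment minus control) on the treatment grid."""

    time: np.ndarray
    delta_vt: np.ndarray
    delta_wt: np.ndarray
    delta_wk: float      # ΔWt at 300 µs
    control_label: str = ""


def extract_cardinal_points(transient: FluorescenceTransient) -> CardinalPoints:
    """Locate O, K, J, I, P on a transient.

    O (Fo) is the global minimum and P (Fm) the global maximum of the trace;
    K, J and I are read off at exactly 300 µs, 2 ms and 30 ms by
    interpolation linear in log-time (the sampling grid is log-spaced).
    """
    t, f = transient.time, transient.fluorescence
    i_min = int(np.argmin(f))
    i_max = int(np.argmax(f))
    fo, fm = float(f[i_min]), float(f[i_max])
    if fm <= fo:
        raise DegenerateTransientError(
            "flat transient (Fm <= Fo): normalisations are undefined"
        )
    fk, fj, fi = (float(interp_log_time(t, f, tq)) for tq in (T_K, T_J, T_I))
    return CardinalPoints(
        fo=fo, fk=fk, fj=fj, fi=fi, fm=fm,
        t_fo=float(t[i_min]), t_fm=float(t[i_max]),
    )


def normalize_transient(
    transient: FluorescenceTransient, points: CardinalPoints | None = None
) -> NormalizedCurves:
    """Apply the O-point, O-P and O-J standardisations pointwise."""
    if points is None:
        points = extract_cardinal_points(transient)
    if points.fm <= points.fo:
        raise DegenerateTransientError("Fm <= Fo: O-P normalisation undefined")
    if points.fj <= points.fo:
        raise DegenerateTransientError("FJ <= Fo: O-J normalisation undefined")
    f = transient.fluorescence
    return NormalizedCurves(
        time=transient.time.copy(),
        ft_fo=f / points.fo,
        vt=(f - points.fo) / (points.fm - points.fo),
        wt=(f - points.fo) / (points.fj - points.fo),
        points=points,
    )


def difference_curves(
    treatment: NormalizedCurves,
    control: NormalizedCurves,
    control_label: str = "",
) -> DifferenceCurves:
    """ΔVt and ΔWt between a treatment and a control curve.

    The control is re-interpolated (linear in log-time) onto the treatment
    grid, restricted to the overlap of the two records, before subtraction.
    Which group serves as control is the caller's choice — in practice
    different treatments are compared against different references.
    """
    lo = max(treatment.time[0], control.time[0])
    hi = min(treatment.time[-1], control.time[-1])
    if lo >= hi:
        raise ValidationError("treatment and control time ranges do not overlap")
    mask = (treatment.time >= lo) & (treatment.time <= hi)
    t = treatment.time[mask]
    if not (t[0] <= T_K <= t[-1]):
        raise ValidationError("overlap does not contain the K point (300 µs)")
    dvt = treatment.vt[mask] - interp_log_time(control.time, control.vt, t)
    dwt = treatment.wt[mask] - interp_log_time(control.time, control.wt, t)
    dwk = float(interp_log_time(t, dwt, T_K))
    return DifferenceCurves(
        time=t, delta_vt=dvt, delta_wt=dwt, delta_wk=dwk, control_label=control_label
    )


@dataclass
class JIPParameterSet:
    """Derived JIP-test quantities for one transient.

    Dimensionless ratios plus per-cross-section quantities, where the
    absorption per cross section ABS/CS0 is approximated by Fo (the standard
    proxy; recorded here so downstream users know the convention).  ``Mo``
    is in ms⁻¹ and ``Sm`` in ms (area normalised by Fv).  Parameters whose
    formula is undefined for the given transient (e.g. PIabs when Vj hits 0
    or 1) are NaN with the reason recorded in ``flags``.
    """

    fv_fm: float
    vj: float
    vi: float
    wk: float
    mo: float
    sm: float
    psi0: float          # probability a trapped exciton moves an electron past QA: 1 - Vj
    psi_e0: float        # quantum yield of electron transport: phiP0 * (1 - Vj)
    pi_abs: float
    rc_abs: float
    rc_cs0: float
    tr0_cs0: float
    et0_cs0: float
    tr0_rc: float
    et0_rc: float
    flags: dict

    def to_dict(self) -> dict:
        d = {
            "Fv/Fm": self.fv_fm, "Vj": self.vj, "Vi": self.vi, "Wk": self.wk,
            "Mo": self.mo, "Sm": self.sm, "psi0": self.psi0, "PsiE0": self.psi_e0,
            "PIabs": self.pi_abs, "RC/ABS": self.rc_abs, "RC/CS0": self.rc_cs0,
            "TR0/CS0": self.tr0_cs0, "ET0/CS0": self.et0_cs0,
            "TR0/RC": self.tr0_rc, "ET0/RC": self.et0_rc,
        }
        return d


def jip_parameters(
    transient: FluorescenceTransient,
    points: CardinalPoints | None = None,
    curves: NormalizedCurves | None = None,
) -> JIPParameterSet:
    """Compute the JIP-test parameter set from one transient.

    Formulas (phiP0 = Fv/Fm; times in ms where dimensional)::

        Fv/Fm  = (Fm - Fo)/Fm
        Vj     = Vt(2 ms);  Vi = Vt(30 ms);  Wk = Wt(300 µs)
        Mo     = 4 * (FK - Fo)/(Fm - Fo)        [ms^-1]
        Sm     = Area / (Fm - Fo), Area = ∫ (Fm - Ft) dt over [t_O, t_Fm]
        psi0   = 1 - Vj;  PsiE0 = phiP0 * (1 - Vj)
        RC/ABS = phiP0 * Vj / Mo
        PIabs  = RC/ABS * phiP0/(1 - phiP0) * psi0/(1 - psi0)
        TR0/RC = Mo/Vj;  ET0/RC = Mo/Vj * (1 - Vj)
        with ABS/CS0 ≈ Fo:  TR0/CS0 = phiP0*Fo;  ET0/CS0 = PsiE0*Fo;
                            RC/CS0  = RC/ABS * Fo

    The Sm integral is a trapezoid on the native grid between the times of
    O and P, with time in ms.
    """
    if points is None:
        points = extract_cardinal_points(transient)
    if curves is None:
        curves = normalize_transient(transient, points)
    flags: dict[str, str] = {}

    fo, fm = points.fo, points.fm
    phi_p0 = (fm - fo) / fm
    vj = float(interp_log_time(curves.time, curves.vt, T_J))
    vi = float(interp_log_time(curves.time, curves.vt, T_I))
    wk = float(interp_log_time(curves.time, curves.wt, T_K))
    mo = 4.0 * (points.fk - fo) / (fm - fo)   # per ms: 4 = 1/0.25 ms

    # area above the curve between O and P, time in ms
    t_ms = transient.time * 1e3
    mask = (transient.time >= points.t_fo) & (transient.time <= points.t_fm)
    area = float(np.trapezoid(fm - transient.fluorescence[mask], t_ms[mask]))
    sm = area / (fm - fo)

    psi0 = 1.0 - vj
    psi_e0 = phi_p0 * psi0
    if vj <= 0.0 or vj >= 1.0:
        flags["PIabs"] = f"undefined for Vj={vj:g}"
        flags["RC/ABS"] = flags["TR0/RC"] = flags["ET0/RC"] = flags["PIabs"]
        rc_abs = pi_abs = tr0_rc = et0_rc = float("nan")
        rc_cs0 = float("nan")
    else:
        rc_abs = phi_p0 * vj / mo
        pi_abs = rc_abs * (phi_p0 / (1.0 - phi_p0)) * (psi0 / (1.0 - psi0))
        tr0_rc = mo / vj
        et0_rc = tr0_rc * psi0
        rc_cs0 = rc_abs * fo
    return JIPParameterSet(
        fv_fm=phi_p0, vj=vj, vi=vi, wk=wk, mo=mo, sm=sm,
        psi0=psi0, psi_e0=psi_e0, pi_abs=pi_abs, rc_abs=rc_abs,
        rc_cs0=rc_cs0, tr0_cs0=phi_p0 * fo, et0_cs0=psi_e0 * fo,
        tr0_rc=tr0_rc, et0_rc=et0_rc, flags=flags,
    )
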