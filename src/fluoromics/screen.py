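"""Rule-based differential screening of omics feature tables.

Layer-specific calling rules (defaults as used throughout the package):

* metabolites — PLS-DA VIP > 1 and fold change FC >= 1.5 (up) or
  FC <= 0.67 (down);
* proteins — Welch p < 0.05 and FC >= 1.2 (up) or FC <= 0.83 (down);
* transcripts — Benjamini–Hochberg Q < 0.05 and FC > 1 (up) or FC < 1
  (down).

FC is the ratio of linear-scale group means, experimental over control.
A comparison string ``"AvsB"`` reads "control A versus experimental B".
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

from .containers import OmicsFeatureTable
from .errors import ValidationError

__all__ = [
    "ScreenThresholds",
    "parse_comparison",
    "fold_change",
    "welch_test",
    "pls_vip",
    "bh_qvalues",
    "screen_differential",
    "differential_records",
    "zscore_matrix",
]


@dataclass(frozen=True)
class ScreenThresholds:
    """Thresholds of the three layer rules (see module docstring)."""

    metabolite_vip: float = 1.0
    metabolite_fc_up: float = 1.5
    metabolite_fc_down: float = 0.67
    protein_p: float = 0.05
    protein_fc_up: float = 1.2
    protein_fc_down: float = 0.83
    transcript_q: float = 0.05
    transcript_fc_up: float = 1.0
    transcript_fc_down: float = 1.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValidationError(f"threshold {name} must be positive, got {v}")


def parse_comparison(comparison: str) -> tuple[str, str]:
    """Split ``"AvsB"`` into (control, experimental) = ("A", "B")."""
    parts = comparison.split("vs")
    if len(parts) != 2 or not all(parts):
        raise ValidationError(f"comparison must look like 'AvsB', got {comparison!r}")
    return parts[0], parts[1]


def _group_matrices(
    table: OmicsFeatureTable, comparison: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    control, experimental = parse_comparison(comparison)
    xs = {}
    for g in (control, experimental):
        cols = table.samples_in(g)
        if len(cols) < 2:
            raise ValidationError(f"group {g!r} needs >= 2 replicates, found {len(cols)}")
        xs[g] = table.values[cols]
    return xs[control], xs[experimental]


def fold_change(
    table: OmicsFeatureTable, comparison: str, zero_offset: float = 0.0
) -> pd.DataFrame:
    """Per-feature fold change, experimental over control group mean.

    Computed on the linear scale.  ``zero_offset`` is added to both group
    means before the ratio to keep features with zero control mean defined;
    the applied offset is recorded in ``DataFrame.attrs["zero_offset"]``.
    """
    ctrl, expt = _group_matrices(table, comparison)
    mc = ctrl.mean(axis=1) + zero_offset
    me = expt.mean(axis=1) + zero_offset
    if (mc == 0).any():
        bad = list(mc.index[mc == 0][:5])
        raise ValidationError(
            f"control group mean is zero for {bad} and zero_offset=0; FC undefined"
        )
    fc = me / mc
    out = pd.DataFrame({"fc": fc, "log2fc": np.log2(fc)})
    out.attrs["zero_offset"] = zero_offset
    out.attrs["comparison"] = comparison
    return out


def welch_test(
    table: OmicsFeatureTable, comparison: str, log_offset: float = 0.0
) -> pd.Series:
    """Two-sided Welch t-test per feature on log2 abundances.

    Degrees of freedom by Welch–Satterthwaite (scipy's ``equal_var=False``).
    Features with zero variance in both groups and equal means get p = 1 by
    convention (no evidence of change), with a warning.
    """
    ctrl, expt = _group_matrices(table, comparison)
    lc = np.log2(ctrl.values + log_offset)
    le = np.log2(expt.values + log_offset)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(le, lc, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (lc.var(axis=1) == 0) & (le.var(axis=1) == 0)
    equal = np.isclose(lc.mean(axis=1), le.mean(axis=1))
    fix = degenerate & equal & ~np.isfinite(p)
    if fix.any():
        warnings.warn(
            f"{int(fix.sum())} feature(s) constant in both groups; p set to 1",
            stacklevel=2,
        )
        p[fix] = 1.0
    return pd.Series(p, index=table.values.index, name="pvalue")


def pls_vip(
    table: OmicsFeatureTable, comparison: str, n_components: int = 1
) -> pd.Series:
    """Variable-importance-in-projection scores from a two-class PLS model.

    Features are autoscaled (unit variance); the response is the class code
    of the two compared groups.  VIP for feature j over A components::

        VIP_j = sqrt( p * sum_a SSY_a * (w_ja / ||w_a||)^2 / sum_a SSY_a )

    with SSY_a the response variance explained by component a, so that the
    mean of squared VIP over retained features equals 1.  Constant feature
    columns cannot be autoscaled and are dropped (NaN in the output) with a
    warning.
    """
    ctrl, expt = _group_matrices(table, comparison)
    x = pd.concat([ctrl, expt], axis=1).T.values          # samples × features
    y = np.r_[np.zeros(ctrl.shape[1]), np.ones(expt.shape[1])]
    keep = x.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"{int((~keep).sum())} constant feature(s) dropped from the PLS model",
            stacklevel=2,
        )
    xk = x[:, keep]
    if xk.shape[1] < 2:
        raise ValidationError("PLS-VIP needs at least 2 non-constant features")
    n_components = min(n_components, xk.shape[0] - 1, xk.shape[1])
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(xk, y)
    w = pls.x_weights_                      # p × A
    t = pls.x_scores_                       # n × A
    q = pls.y_loadings_.ravel()             # A
    ssy = (q ** 2) * np.sum(t ** 2, axis=0)  # variance of y explained per component
    wnorm2 = np.sum(w ** 2, axis=0)
    p_feat = xk.shape[1]
    vip_kept = np.sqrt(p_feat * (w ** 2 / wnorm2) @ ssy / ssy.sum())
    vip = np.full(x.shape[1], np.nan)
    vip[keep] = vip_kept
    return pd.Series(vip, index=table.values.index, name="vip")


def bh_qvalues(pvalues: pd.Series) -> pd.Series:
    """Benjamini–Hochberg adjusted p-values (monotone in p, capped at 1)."""
    q = multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
    return pd.Series(q, index=pvalues.index, name="qvalue")


def differential_records(
    table: OmicsFeatureTable,
    comparison: str,
    thresholds: ScreenThresholds = ScreenThresholds(),
    n_pls_components: int = 1,
    zero_offset: float = 0.0,
) -> pd.DataFrame:
    """Compute the full per-feature record for a layer, then call it.

    Convenience wrapper: fold change for all layers; Welch p for proteins
    and transcripts (BH Q for transcripts); PLS VIP for metabolites;
    finally :func:`screen_differential`.
    """
    rec = fold_change(table, comparison, zero_offset=zero_offset)
    if table.layer in ("protein", "transcript"):
        rec["pvalue"] = welch_test(table, comparison)
    if table.layer == "transcript":
        rec["qvalue"] = bh_qvalues(rec["pvalue"])
    if table.layer == "metabolite":
        rec["vip"] = pls_vip(table, comparison, n_components=n_pls_components)
    rec["comparison"] = comparison
    return screen_differential(rec, table.layer, thresholds)


def screen_differential(
    records: pd.DataFrame,
    layer: str,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> pd.DataFrame:
    """Apply the layer's calling rule; adds a ``call`` column (up/down/ns).

    ``records`` must carry ``fc`` plus the statistic the layer's rule needs:
    ``vip`` for metabolites, ``pvalue`` for proteins, ``qvalue`` for
    transcripts (published transcript tables that already report Q-values
    can be screened directly).
    """
    th = thresholds
    rec = records.copy()
    fc = rec["fc"]
    if layer == "metabolite":
        if "vip" not in rec:
            raise ValidationError("metabolite rule requires a 'vip' column")
        sig = rec["vip"] > th.metabolite_vip
        up = sig & (fc >= th.metabolite_fc_up)
        down = sig & (fc <= th.metabolite_fc_down)
    elif layer == "protein":
        if "pvalue" not in rec:
            raise ValidationError("protein rule requires a 'pvalue' column")
        sig = rec["pvalue"] < th.protein_p
        up = sig & (fc >= th.protein_fc_up)
        down = sig & (fc <= th.protein_fc_down)
    elif layer == "transcript":
        if "qvalue" not in rec:
            raise ValidationError("transcript rule requires a 'qvalue' column")
        sig = rec["qvalue"] < th.transcript_q
        up = sig & (fc > th.transcript_fc_up)
        down = sig & (fc < th.transcript_fc_down)
    else:
        raise ValidationError(f"unknown layer: {layer!r}")
    rec["call"] = np.where(up, "up", np.where(down, "down", "ns"))
    rec.attrs["thresholds"] = th
    rec.attrs["layer"] = layer
    return rec


def zscore_matrix(
    table: OmicsFeatureTable | pd.DataFrame, subset: list[str] | None = None
) -> pd.DataFrame:
    """Per-feature z-score standardisation (heat-map preparation).

    Each row is centred to mean 0 and scaled to sample sd 1 (ddof=1).
    Constant rows cannot be scaled and come back as NaN, flagged in
    ``attrs["constant_features"]``.
    """
    values = table.values if isinstance(table, OmicsFeatureTable) else table
    if subset is not None:
        values = values.loc[subset]
    if values.shape[1] < 2:
        raise ValidationError("z-score needs at least 2 samples")
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    constant = list(values.index[sd == 0])
    if constant:
        warnings.warn(f"{len(constant)} constant feature(s) produce NaN z-scores",
                      stacklevel=2)
    z = values.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    z.attrs["constant_features"] = constant
    return z
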