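"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (JIP-test, quenching analysis,
differential screening, correlation/Mantel integration) is exercised against
data produced here, so each generator exposes the true parameters it planted:

* :func:`gen_ojip_transient` — a three-exponential OJIP rise with optional
  donor-side damage (extra fast-phase weight raising the K band, and a
  caller-applied Fm reduction);
* :func:`gen_light_curve_dataset` — a tanh rapid light curve with F / Fm′
  back-computed to be exactly consistent with the implied ΦPSII;
* :func:`gen_omics_dataset` — transcript / protein / metabolite tables with
  planted fold changes, TF–target latent factors and gene–metabolite coupling.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
inputs and seed give bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import check_strictly_increasing, log_time_grid
from .containers import FluorescenceTransient, LightCurveDataset, OmicsFeatureTable
from .errors import ValidationError

__all__ = [
    "OJIPModelParams",
    "PlantedOmicsDesign",
    "ojip_model",
    "gen_ojip_transient",
    "with_donor_side_damage",
    "gen_light_curve_dataset",
    "gen_omics_dataset",
]


# --------------------------------------------------------------------------- #
# OJIP transients
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class OJIPModelParams:
    """Parameters of the three-exponential OJIP rise model.

    ``F(t) = Fo + (Fm - Fo) * sum_i w_i (1 - exp(-t / tau_i))``

    The three phases stand for the O-J, J-I and I-P rises; the default time
    constants (0.4 ms, 10 ms, 120 ms) place the J and I inflections near
    their defining times of 2 ms and 30 ms.  ``k_band_weight`` adds extra
    weight to the fastest phase (renormalising the weights), which elevates
    fluorescence around 300 µs — the K-band signature of donor-side
    (oxygen-evolving-complex) impairment.  Multiplicative Gaussian noise of
    relative sd ``noise_sd`` is applied to the noiseless curve.
    """

    fo: float = 500.0
    fm: float = 2500.0
    phase_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    phase_taus: tuple[float, float, float] = (4e-4, 1e-2, 0.12)
    k_band_weight: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.fm > self.fo > 0):
            raise ValidationError("OJIP model requires Fm > Fo > 0")
        w = np.asarray(self.phase_weights, dtype=float)
        if w.size != 3 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValidationError("phase_weights must be 3 non-negative values summing to 1")
        taus = np.asarray(self.phase_taus, dtype=float)
        if taus.size != 3 or np.any(taus <= 0) or np.any(np.diff(taus) <= 0):
            raise ValidationError("phase_taus must be 3 strictly increasing positive values")
        if not (0.0 <= self.k_band_weight < 1.0):
            raise ValidationError("k_band_weight must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def effective_weights(self) -> np.ndarray:
        """Phase weights after K-band injection, renormalised to sum to 1."""
        w = np.asarray(self.phase_weights, dtype=float).copy()
        w[0] += self.k_band_weight
        return w / w.sum()


def ojip_model(params: OJIPModelParams, t: np.ndarray) -> np.ndarray:
    """Evaluate the noiseless OJIP model at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    w = params.effective_weights
    taus = np.asarray(params.phase_taus, dtype=float)
    rise = np.sum(w[:, None] * (1.0 - np.exp(-t[None, :] / taus[:, None])), axis=0)
    return params.fo + (params.fm - params.fo) * rise


def gen_ojip_transient(
    params: OJIPModelParams,
    grid: np.ndarray | None = None,
    label: str = "",
) -> FluorescenceTransient:
    """Generate a (possibly noisy) OJIP transient on a log-spaced time grid.

    The default grid is 120 log-spaced points from 10 µs to 2 s, matching a
    2-second fast-fluorometer acquisition.  Noise is multiplicative:
    ``F_obs = F_model * (1 + eps)`` with ``eps ~ N(0, noise_sd)``.
    """
    if grid is None:
        grid = log_time_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size < 50:
        raise ValidationError("time grid must contain at least 50 points")
    check_strictly_increasing(grid, "time grid")
    if grid[0] <= 0 or grid[-1] > 2.0:
        raise ValidationError("time grid must lie within (0, 2] s")
    f = ojip_model(params, grid)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        f = f * (1.0 + rng.normal(0.0, params.noise_sd, size=grid.size))
        f = np.clip(f, 0.0, None)
    return FluorescenceTransient(time=grid, fluorescence=f, label=label)


def with_donor_side_damage(
    params: OJIPModelParams,
    k_band_weight: float = 0.15,
    fm_scale: float = 0.9,
) -> OJIPModelParams:
    """Variant of ``params`` emulating donor-side (OEC) damage.

    Damage shows up in real leaves both as a raised K band and as a lowered
    Fm, so both are applied: extra fast-phase weight and ``Fm * fm_scale``.
    """
    if not (0 < fm_scale <= 1):
        raise ValidationError("fm_scale must lie in (0, 1]")
    return replace(params, k_band_weight=k_band_weight, fm=params.fm * fm_scale)


# --------------------------------------------------------------------------- #
# PAM rapid light curves
# --------------------------------------------------------------------------- #

DEFAULT_PAR_LEVELS = (0.0, 25.0, 50.0, 100.0, 200.0, 400.0, 700.0, 1100.0)


def gen_light_curve_dataset(
    alpha_true: float = 0.3,
    etrmax_true: float = 60.0,
    npq_max: float = 2.5,
    par_levels: tuple[float, ...] = DEFAULT_PAR_LEVELS,
    noise_sd: float = 0.0,
    seed: int = 0,
    f0: float = 500.0,
    fm: float = 2500.0,
    qp_exponent: float = 0.6,
    absorption: float = 0.84,
    psii_fraction: float = 0.5,
    label: str = "",
) -> LightCurveDataset:
    """Generate a PAM light-curve dataset consistent with a tanh ETR model.

    rETR at each PAR step is drawn from
    ``ETRmax * tanh(alpha * PAR / ETRmax) * (1 + eps)``, which fixes the
    implied ``ΦPSII = rETR / (PAR * psii_fraction * absorption)`` (a
    strictly decreasing function of PAR for the tanh model).  The
    fluorescence pair (F, Fm′) is then back-computed so that
    ``(Fm' - F)/Fm'`` equals that ΦPSII exactly and the photochemical
    quenching coefficient follows the strictly decreasing target
    ``qP = (ΦPSII / (Fv/Fm)) ** qp_exponent``; the resulting NPQ rises
    monotonically with PAR and is capped at ``npq_max``.  The dark step
    (PAR = 0) reproduces the dark-adapted pair (F0, Fm), where ΦPSII =
    Fv/Fm, qP = 1 and NPQ = 0.
    """
    if alpha_true <= 0 or etrmax_true <= 0:
        raise ValidationError("alpha_true and etrmax_true must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if not (0 < qp_exponent < 1):
        raise ValidationError("qp_exponent must lie in (0, 1)")
    par = np.asarray(par_levels, dtype=float)
    check_strictly_increasing(par, "PAR levels")
    if par.max() < 700.0:
        raise ValidationError("PAR levels must include a step >= 700 µmol m-2 s-1")
    rng = np.random.default_rng(seed)
    retr_clean = etrmax_true * np.tanh(alpha_true * par / etrmax_true)
    eps = rng.normal(0.0, noise_sd, size=par.size) if noise_sd > 0 else np.zeros(par.size)
    retr = retr_clean * (1.0 + eps)

    fv_fm = (fm - f0) / fm
    phi = np.empty_like(par)
    light = par > 0
    phi[light] = retr[light] / (par[light] * psii_fraction * absorption)
    phi[~light] = fv_fm
    # keep the back-computed fluorescence physically valid under noise
    phi = np.clip(phi, 1e-6, 0.95)

    # With the Oxborough-Baker Fo' estimate, qP = phi * (Fv/Fm + F0/Fm') / (Fv/Fm),
    # so the target qP fixes u = F0/Fm'; capping u caps NPQ = (Fm/F0)*u - 1.
    qp_target = (phi / fv_fm) ** qp_exponent
    u = fv_fm * (qp_target / phi - 1.0)
    u = np.minimum(u, (1.0 + npq_max) * f0 / fm)
    fm_prime = f0 / u
    f = fm_prime * (1.0 - phi)
    f[~light] = f0
    fm_prime[~light] = fm
    return LightCurveDataset(f0=f0, fm=fm, par=par, f=f, fm_prime=fm_prime, label=label)


# --------------------------------------------------------------------------- #
# Omics tables with planted structure
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class PlantedOmicsDesign:
    """Design of a synthetic three-layer omics experiment.

    Samples are ``reps_per_group`` biological replicates in each of the
    groups (default A=control, B=UV-B, C=UV-B+ABA, D=ABA).  Abundances are
    log-normal: a per-feature baseline on the log2 scale plus group effects,
    latent factors and N(0, sigma) noise, exponentiated to the linear scale.

    * ``planted_log2fc`` plants a B-vs-A log2 fold change per feature, keyed
      by layer then feature id (e.g. ``{"transcript": {"gene_0003": 2.0}}``).
    * ``tf_target_map`` gives each TF transcript a per-sample latent factor
      passed to its targets with signed loadings, creating known-sign
      TF–target correlations.
    * ``coupled_genes`` / ``coupled_metabolites`` share one latent factor of
      strength ``gene_metabolite_coupling``, detectable by a Mantel test.
    """

    n_transcripts: int = 60
    n_proteins: int = 40
    n_metabolites: int = 30
    groups: tuple[str, ...] = ("A", "B", "C", "D")
    reps_per_group: int = 3
    planted_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    tf_target_map: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    coupled_genes: tuple[str, ...] = ()
    coupled_metabolites: tuple[str, ...] = ()
    gene_metabolite_coupling: float = 0.0
    sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps_per_group < 2:
            raise ValidationError("reps_per_group must be >= 2")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        ids = self.feature_ids()
        for layer, fx in self.planted_log2fc.items():
            if layer not in ids:
                raise ValidationError(f"unknown layer in planted_log2fc: {layer!r}")
            unknown = set(fx) - set(ids[layer])
            if unknown:
                raise ValidationError(f"planted features not in {layer} layer: {sorted(unknown)}")
        genes = set(ids["transcript"])
        for tf, targets in self.tf_target_map.items():
            if tf not in genes or any(t not in genes for t, _ in targets):
                raise ValidationError("tf_target_map features must be transcript features")
        if set(self.coupled_genes) - genes:
            raise ValidationError("coupled_genes must be transcript features")
        if set(self.coupled_metabolites) - set(ids["metabolite"]):
            raise ValidationError("coupled_metabolites must be metabolite features")

    def feature_ids(self) -> dict[str, list[str]]:
        return {
            "transcript": [f"gene_{i:04d}" for i in range(self.n_transcripts)],
            "protein": [f"prot_{i:04d}" for i in range(self.n_proteins)],
            "metabolite": [f"met_{i:04d}" for i in range(self.n_metabolites)],
        }

    def sample_table(self) -> pd.Series:
        samples = {
            f"{g}_{r + 1}": g for g in self.groups for r in range(self.reps_per_group)
        }
        return pd.Series(samples, name="group")


def gen_omics_dataset(design: PlantedOmicsDesign) -> dict[str, OmicsFeatureTable]:
    """Generate transcript, protein and metabolite tables per ``design``.

    Returns a dict keyed by layer.  Planted features have expected
    group-mean log2 ratio (B vs A) equal to the planted value; TF–target
    pairs and coupled gene/metabolite blocks share latent factors as
    documented on :class:`PlantedOmicsDesign`.
    """
    rng = np.random.default_rng(design.seed)
    groups = design.sample_table()
    samples = list(groups.index)
    n_samples = len(samples)
    ids = design.feature_ids()

    # latent factors: one per TF, one shared gene-metabolite factor
    tf_factors = {tf: rng.normal(0.0, 1.0, size=n_samples) for tf in design.tf_target_map}
    gm_factor = rng.normal(0.0, 1.0, size=n_samples)
    in_group_b = np.array([groups[s] == "B" for s in samples])

    tables: dict[str, OmicsFeatureTable] = {}
    for layer in ("transcript", "protein", "metabolite"):
        feats = ids[layer]
        baseline = rng.normal(8.0, 1.5, size=len(feats))
        log2x = np.tile(baseline[:, None], (1, n_samples))
        planted = design.planted_log2fc.get(layer, {})
        for i, fid in enumerate(feats):
            if fid in planted:
                log2x[i, in_group_b] += planted[fid]
        if layer == "transcript":
            for tf, targets in design.tf_target_map.items():
                z = tf_factors[tf]
                log2x[feats.index(tf)] += z
                for target, loading in targets:
                    log2x[feats.index(target)] += loading * z
            for fid in design.coupled_genes:
                log2x[feats.index(fid)] += design.gene_metabolite_coupling * gm_factor
        if layer == "metabolite":
            for fid in design.coupled_metabolites:
                log2x[feats.index(fid)] += design.gene_metabolite_coupling * gm_factor
        if design.sigma > 0:
            log2x = log2x + rng.normal(0.0, design.sigma, size=log2x.shape)
        values = pd.DataFrame(np.exp2(log2x), index=feats, columns=samples)
        tables[layer] = OmicsFeatureTable(layer=layer, values=values, design=groups)
    return tables
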