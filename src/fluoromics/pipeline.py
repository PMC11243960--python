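"""End-to-end pipeline: tie the analysis stages together over a directory
of input tables and write one tidy result table per stage.

Input-directory convention (produced by :func:`simulate_inputs` or arranged
by hand from instrument exports)::

    transients/<group>_<rep>.tsv        two-column OJIP records
    light_curves/<group>_<rep>.tsv      PAR/F/Fm' tables with dark header
    omics/<layer>_values.tsv            feature × sample matrices
    omics/design.tsv                    sample, group
    omics/transcript_annotations.tsv    optional: tf_family, ec_number

Every run writes a ``run_metadata.json`` (seed, thresholds) and a
``thresholds.log``; given the same config and seed, result tables are
byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .containers import FluorescenceTransient
from .errors import ConfigError
from .group_stats import anova_lsd
from .integrate import mantel_by_group, mantel_test, tf_correlation_network
from .ojip import difference_curves, jip_parameters, normalize_transient
from .pam import fit_light_curve, quenching_parameters
from .screen import ScreenThresholds, differential_records
from .synthetic import (
    OJIPModelParams,
    PlantedOmicsDesign,
    gen_light_curve_dataset,
    gen_ojip_transient,
    gen_omics_dataset,
    with_donor_side_damage,
)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_inputs"]


@dataclass
class PipelineConfig:
    """Configuration of a pipeline run; loadable from YAML."""

    seed: int = 0
    control_group: str = "A"
    comparisons: tuple[str, ...] = ("AvsB",)
    stages: dict = field(
        default_factory=lambda: {"ojip": True, "pam": True, "screen": True, "integrate": True}
    )
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    permutations: int = 999
    top_k: int = 50
    strong_r: float = 0.9

    def __post_init__(self) -> None:
        if self.permutations < 99:
            raise ConfigError("permutations must be >= 99")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        if not (0 < self.strong_r <= 1):
            raise ConfigError("strong_r must lie in (0, 1]")
        unknown = set(self.stages) - {"ojip", "pam", "screen", "integrate"}
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, seed_override: int | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "thresholds" in raw:
            raw["thresholds"] = ScreenThresholds(**raw["thresholds"])
        if "comparisons" in raw:
            raw["comparisons"] = tuple(raw["comparisons"])
        if seed_override is not None:
            raw["seed"] = seed_override
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad config key: {exc}") from exc

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["comparisons"] = list(self.comparisons)
        return d


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise ConfigError(f"stage {stage!r} is enabled but input {path} is missing")
    return path


def _discover_labelled(directory: Path) -> list[tuple[Path, str, str]]:
    """(path, group, replicate) triples from <group>_<rep>.tsv filenames."""
    out = []
    for p in sorted(directory.glob("*.tsv")):
        stem = p.stem
        group, _, rep = stem.partition("_")
        out.append((p, group, rep or "1"))
    return out


def run_pipeline(config: PipelineConfig, input_dir: str | Path, out_dir: str | Path) -> Path:
    """Run all enabled stages; returns the output directory.

    Missing inputs for an enabled stage raise :class:`ConfigError` before
    any computation starts.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    stages = {k for k, v in config.stages.items() if v}

    # resolve all inputs up front
    if "ojip" in stages:
        transient_files = _discover_labelled(_require(input_dir / "transients", "ojip"))
        if not transient_files:
            raise ConfigError("stage 'ojip' is enabled but no transient tables were found")
    if "pam" in stages:
        lc_files = _discover_labelled(_require(input_dir / "light_curves", "pam"))
        if not lc_files:
            raise ConfigError("stage 'pam' is enabled but no light-curve tables were found")
    if "screen" in stages or "integrate" in stages:
        omics_dir = _require(input_dir / "omics", "screen/integrate")
        design_path = _require(omics_dir / "design.tsv", "screen/integrate")
        layer_paths = {
            layer: omics_dir / f"{layer}_values.tsv"
            for layer in ("transcript", "protein", "metabolite")
            if (omics_dir / f"{layer}_values.tsv").exists()
        }
        if not layer_paths:
            raise ConfigError("no omics layer tables found under omics/")
        if "integrate" in stages:
            for needed in ("transcript", "metabolite"):
                if needed not in layer_paths:
                    raise ConfigError(f"stage 'integrate' needs omics/{needed}_values.tsv")
            ann_path = omics_dir / "transcript_annotations.tsv"
            _require(ann_path, "integrate")

    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed={config.seed}"]

    if "ojip" in stages:
        _run_ojip_stage(config, transient_files, out_dir, log_lines)
    if "pam" in stages:
        _run_pam_stage(config, lc_files, out_dir, log_lines)
    if "screen" in stages or "integrate" in stages:
        tables = {
            layer: fio.read_omics_tables(
                path, design_path, layer,
                annotations_path=(omics_dir / f"{layer}_annotations.tsv")
                if (omics_dir / f"{layer}_annotations.tsv").exists() else None,
            )
            for layer, path in layer_paths.items()
        }
    if "screen" in stages:
        _run_screen_stage(config, tables, out_dir, log_lines)
    if "integrate" in stages:
        _run_integrate_stage(config, tables, out_dir, log_lines)

    (out_dir / "thresholds.log").write_text("\n".join(log_lines) + "\n")
    (out_dir / "run_metadata.json").write_text(
        json.dumps({"config": config.to_jsonable()}, indent=2, sort_keys=True)
    )
    return out_dir


def _run_ojip_stage(config, files, out_dir: Path, log: list[str]) -> None:
    rows = []
    curves_by_group: dict[str, list] = {}
    for path, group, rep in files:
        tr = fio.read_transient_table(path, label=group)
        params = jip_parameters(tr)
        for name, value in params.to_dict().items():
            rows.append((f"{group}_{rep}", group, name, value))
        curves_by_group.setdefault(group, []).append(tr)
    tidy = pd.DataFrame(rows, columns=["sample", "group", "parameter", "value"])
    tidy.to_csv(out_dir / "jip_parameters.csv", index=False, float_format="%.10g")

    # group summary with ANOVA + LSD letters where replication allows
    summaries = []
    for name, sub in tidy.groupby("parameter", sort=True):
        counts = sub.groupby("group")["value"].count()
        if len(counts) >= 2 and (counts >= 2).all() and sub["value"].notna().all():
            cmp_res = anova_lsd(sub["value"], sub["group"])
            s = cmp_res.summary.reset_index()
            s.insert(0, "parameter", name)
            s["anova_p"] = cmp_res.p_value
            summaries.append(s)
    if summaries:
        pd.concat(summaries, ignore_index=True).to_csv(
            out_dir / "jip_summary.csv", index=False, float_format="%.10g"
        )

    # group-mean difference curves vs the configured control
    control = config.control_group
    if control in curves_by_group:
        ctrl_mean = _group_mean_transient(curves_by_group[control], control)
        ctrl_norm = normalize_transient(ctrl_mean)
        diff_rows = []
        for group, members in sorted(curves_by_group.items()):
            if group == control:
                continue
            mean_tr = _group_mean_transient(members, group)
            diff = difference_curves(normalize_transient(mean_tr), ctrl_norm,
                                     control_label=control)
            for t, dv, dw in zip(diff.time, diff.delta_vt, diff.delta_wt):
                diff_rows.append((group, control, t, dv, dw, diff.delta_wk))
        if diff_rows:
            pd.DataFrame(
                diff_rows,
                columns=["treatment", "control", "time_s", "delta_vt", "delta_wt", "delta_wk"],
            ).to_csv(out_dir / "difference_curves.csv", index=False, float_format="%.10g")
    log.append(f"ojip: control_group={control}")


def _group_mean_transient(members, label: str) -> FluorescenceTransient:
    base = members[0]
    stack = [base.fluorescence]
    for tr in members[1:]:
        stack.append(np.interp(np.log(base.time), np.log(tr.time), tr.fluorescence))
    return FluorescenceTransient(
        time=base.time, fluorescence=np.mean(stack, axis=0), label=label
    )


def _run_pam_stage(config, files, out_dir: Path, log: list[str]) -> None:
    step_rows, fit_rows = [], []
    for path, group, rep in files:
        ds = fio.read_light_curve_table(path, label=group)
        qp = quenching_parameters(ds)
        tab = qp.table.copy()
        tab.insert(0, "sample", f"{group}_{rep}")
        tab.insert(1, "group", group)
        step_rows.append(tab)
        fit = fit_light_curve(ds.par, qp.table["retr"].to_numpy())
        fit_rows.append(
            (f"{group}_{rep}", group, qp.fv_fm, fit.alpha, fit.etrmax, fit.ek, fit.rss)
        )
    pd.concat(step_rows, ignore_index=True).to_csv(
        out_dir / "quenching.csv", index=False, float_format="%.10g"
    )
    fits = pd.DataFrame(
        fit_rows, columns=["sample", "group", "fv_fm", "alpha", "etrmax", "ek", "rss"]
    )
    fits.to_csv(out_dir / "light_curve_fits.csv", index=False, float_format="%.10g")

    summaries = []
    for name in ("fv_fm", "alpha", "etrmax", "ek"):
        counts = fits.groupby("group")[name].count()
        if len(counts) >= 2 and (counts >= 2).all():
            cmp_res = anova_lsd(fits[name], fits["group"])
            s = cmp_res.summary.reset_index()
            s.insert(0, "parameter", name)
            s["anova_p"] = cmp_res.p_value
            summaries.append(s)
    if summaries:
        pd.concat(summaries, ignore_index=True).to_csv(
            out_dir / "light_curve_summary.csv", index=False, float_format="%.10g"
        )
    log.append("pam: tanh light-curve model, absorption=0.84, psii_fraction=0.5")


def _run_screen_stage(config, tables, out_dir: Path, log: list[str]) -> None:
    th = config.thresholds
    for layer, table in sorted(tables.items()):
        frames = []
        for comparison in config.comparisons:
            rec = differential_records(table, comparison, thresholds=th)
            rec = rec.reset_index(names="feature")
            frames.append(rec)
        pd.concat(frames, ignore_index=True).to_csv(
            out_dir / f"screening_{layer}.csv", index=False, float_format="%.10g"
        )
    log.append(f"screen: thresholds={dataclasses.asdict(th)}")


def _run_integrate_stage(config, tables, out_dir: Path, log: list[str]) -> None:
    tx = tables["transcript"]
    met = tables["metabolite"]
    ann = tx.annotations
    tf_ids = (
        list(ann.index[ann["tf_family"].notna() & (ann["tf_family"] != "")])
        if ann is not None and "tf_family" in ann
        else []
    )
    if tf_ids:
        gene_ids = [g for g in tx.values.index if g not in tf_ids]
        edges = tf_correlation_network(
            tx.values.loc[tf_ids], tx.values.loc[gene_ids], k=config.top_k
        )
        edges["strong"] = edges["r"].abs() > config.strong_r
        edges.to_csv(out_dir / "network_edges.csv", index=False, float_format="%.10g")
    if ann is not None and "ec_number" in ann:
        grouped = ann.loc[ann["ec_number"].notna() & (ann["ec_number"] != ""), "ec_number"]
        if not grouped.empty:
            mantel = mantel_by_group(
                tx.values, grouped, met.values,
                permutations=config.permutations, seed=config.seed,
            )
            mantel.to_csv(out_dir / "mantel.csv", index=False, float_format="%.10g")
    else:
        res = mantel_test(tx.values, met.values,
                          permutations=config.permutations, seed=config.seed)
        pd.DataFrame(
            [("all", tx.values.shape[0], res.r, res.p, res.permutations)],
            columns=["group", "n_genes", "mantel_r", "p", "permutations"],
        ).to_csv(out_dir / "mantel.csv", index=False, float_format="%.10g")
    log.append(
        f"integrate: top_k={config.top_k}, strong_r={config.strong_r}, "
        f"permutations={config.permutations}"
    )


# --------------------------------------------------------------------------- #
# Demonstration input set
# --------------------------------------------------------------------------- #

def simulate_inputs(out_dir: str | Path, seed: int = 0, reps: int = 3) -> Path:
    """Write a complete synthetic input directory for a pipeline run.

    Emulates the four-group design (A control, B UV-B with donor-side
    damage, C UV-B+ABA with partial damage, D ABA): OJIP transients, rapid
    light curves and three omics layers with planted fold changes, two TF
    latent factors and a coupled gene/metabolite block.
    """
    out_dir = Path(out_dir)
    (out_dir / "transients").mkdir(parents=True, exist_ok=True)
    (out_dir / "light_curves").mkdir(exist_ok=True)
    (out_dir / "omics").mkdir(exist_ok=True)

    base = OJIPModelParams(noise_sd=0.01)
    group_params = {
        "A": base,
        "B": with_donor_side_damage(base, k_band_weight=0.15, fm_scale=0.9),
        "C": with_donor_side_damage(base, k_band_weight=0.07, fm_scale=0.95),
        "D": base,
    }
    group_alpha = {"A": 0.30, "B": 0.22, "C": 0.26, "D": 0.30}
    for gi, (group, params) in enumerate(sorted(group_params.items())):
        for rep in range(1, reps + 1):
            s = seed + 100 * gi + rep
            tr = gen_ojip_transient(dataclasses.replace(params, seed=s), label=group)
            p = fio.write_transient_table(tr, out_dir / "transients" / f"{group}_{rep}.tsv")
            fio.write_sidecar(p, s, group=group)
            lc = gen_light_curve_dataset(
                alpha_true=group_alpha[group], noise_sd=0.03, seed=s, label=group
            )
            p = fio.write_light_curve_table(lc, out_dir / "light_curves" / f"{group}_{rep}.tsv")
            fio.write_sidecar(p, s, group=group, alpha_true=group_alpha[group])

    design = PlantedOmicsDesign(
        planted_log2fc={
            "transcript": {"gene_0000": 2.0, "gene_0001": -2.0},
            "protein": {"prot_0000": 1.5, "prot_0001": -1.5},
            "metabolite": {"met_0000": 2.0, "met_0001": -2.0},
        },
        tf_target_map={
            "gene_0010": [("gene_0011", 1.0), ("gene_0012", -1.0)],
            "gene_0020": [("gene_0021", 1.0)],
        },
        coupled_genes=("gene_0030", "gene_0031"),
        coupled_metabolites=("met_0010", "met_0011"),
        gene_metabolite_coupling=1.5,
        seed=seed,
    )
    tables = gen_omics_dataset(design)
    for layer, table in tables.items():
        fio.write_omics_tables(
            table, out_dir / "omics" / f"{layer}_values.tsv", out_dir / "omics" / "design.tsv"
        )
        fio.write_sidecar(out_dir / "omics" / f"{layer}_values.tsv", design.seed, layer=layer)
    ann = pd.DataFrame(
        {"tf_family": "", "ec_number": ""},
        index=pd.Index(design.feature_ids()["transcript"], name="feature"),
    )
    ann.loc[["gene_0010", "gene_0020"], "tf_family"] = "G2-like"
    ann.loc[["gene_0030", "gene_0031"], "ec_number"] = "EC:4.1.1.39"
    ann.loc[["gene_0032", "gene_0033"], "ec_number"] = "EC:4.1.2.13"
    ann.to_csv(out_dir / "omics" / "transcript_annotations.tsv", sep="\t")
    return out_dir
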