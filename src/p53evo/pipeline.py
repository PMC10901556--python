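"""End-to-end workflows: reconstruction and affinity analysis.

Two arcs tie the modules together.  The reconstruction arc takes an
alignment plus a time-calibrated tree, fits the substitution model, and
emits per-node posterior tables and ML/AltAll sequences.  The affinity arc
takes titration CSVs (and/or the packaged affinity table) and emits fitted
dissociation constants plus the summary analytics.  Every run writes a
deterministic ``manifest.json`` capturing the effective configuration and
package version, so a rerun with the same config reproduces the outputs
byte for byte; runs never mutate their inputs and refuse to reuse a run
directory that already holds a manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .affinity_report import AffinityTable
from .asr import (
    Alignment,
    fit_model_parameters,
    marginal_posteriors,
    model_selection_table,
)
from .binding import fit_fp_competition, fit_fp_saturation, load_fp_experiments
from .evo_models import empirical_frequencies, model_from_name
from .phylo import parse_newick

logger = logging.getLogger("p53evo")


class WorkflowError(RuntimeError):
    pass


@dataclass
class ModelConfig:
    name: str = "JTT+G+I"
    alpha: float = 1.0
    p_inv: float = 0.1
    n_categories: int = 5
    gamma_method: str = "mean"


@dataclass
class AsrConfig:
    primary_cutoff: float = 0.90
    secondary_min: float = 0.10
    branch_mode: str = "scale"
    run_model_selection: bool = False


@dataclass
class BindingConfig:
    probe_kd_uM: float | None = None
    route: str = "conversion"  # primary estimate: conversion | direct
    use_fixture: bool = False


@dataclass
class RunConfig:
    output_dir: str = "p53evo_run"
    alignment: str | None = None
    tree: str | None = None
    titrations: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    model: ModelConfig = field(default_factory=ModelConfig)
    asr: AsrConfig = field(default_factory=AsrConfig)
    binding: BindingConfig = field(default_factory=BindingConfig)

    def __post_init__(self):
        if not (0.0 < self.asr.primary_cutoff < 1.0):
            raise ValueError("primary_cutoff must lie in (0, 1)")
        if not (0.0 < self.asr.secondary_min < 1.0):
            raise ValueError("secondary_min must lie in (0, 1)")
        for attr in ("alignment", "tree", "titrations"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{attr} input does not exist: {path}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a YAML or JSON config file."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            raw = json.loads(text)
        else:
            import yaml

            raw = yaml.safe_load(text)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (("model", ModelConfig), ("asr", AsrConfig), ("binding", BindingConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def effective(self) -> dict:
        return {"version": __version__, "config": asdict(self)}


def _prepare_run_dir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if (out / "manifest.json").exists():
        raise WorkflowError(
            f"run directory {out} already holds a manifest; outputs are "
            "write-once — choose a fresh directory"
        )
    return out


def _write_manifest(out: Path, config: RunConfig, stage_info: dict) -> None:
    manifest = config.effective()
    manifest["outputs"] = stage_info
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_asr_workflow(config: RunConfig) -> dict:
    """Alignment + chronogram -> posteriors, ML/AltAll FASTAs, manifest.

    Returns a dict of output paths plus the fitted parameters.  Every stage
    logs its parameters; failures carry the stage name.
    """
    logging.basicConfig(level=config.log_level)
    if config.alignment is None or config.tree is None:
        raise WorkflowError(
            "stage=inputs: the reconstruction workflow needs both an "
            "alignment (FASTA) and a tree (Newick)"
        )
    out = _prepare_run_dir(config)
    try:
        aln = Alignment.from_fasta(config.alignment)
        tree = parse_newick(Path(config.tree).read_text())
    except Exception as exc:
        raise WorkflowError(f"stage=load: {exc}; check input formats") from exc

    mc = config.model
    logger.info(
        "model=%s alpha=%g p_inv=%g categories=%d gamma_method=%s",
        mc.name, mc.alpha, mc.p_inv, mc.n_categories, mc.gamma_method,
    )
    emp = empirical_frequencies(aln) if mc.name.endswith("+F") else None
    model = model_from_name(
        mc.name, alpha=mc.alpha, p_inv=mc.p_inv, n_categories=mc.n_categories,
        empirical_frequencies_=emp, gamma_method=mc.gamma_method,
    )
    try:
        fit = fit_model_parameters(tree, aln, model, branch_mode=config.asr.branch_mode)
    except Exception as exc:
        raise WorkflowError(f"stage=fit: {exc}") from exc
    logger.info(
        "fitted lnL=%.4f alpha=%s p_inv=%s scale=%g",
        fit.log_likelihood, fit.model.gamma_shape, fit.model.p_invariant,
        fit.branch_scale,
    )
    post = marginal_posteriors(
        tree, aln, fit.model,
        branch_scale=fit.branch_scale,
        branch_lengths=fit.branch_lengths,
        primary_cutoff=config.asr.primary_cutoff,
        secondary_min=config.asr.secondary_min,
    )
    post.to_tsv(out / "posteriors.tsv")
    calls = post.calls()
    with open(out / "ancestral_ml.fasta", "w") as ml_fh, open(
        out / "ancestral_altall.fasta", "w"
    ) as alt_fh:
        for node_id in post.node_ids:
            ml, alt = calls[node_id]
            ml_fh.write(f">node_{node_id}\n{ml}\n")
            alt_fh.write(f">node_{node_id}\n{alt}\n")

    selection_path = None
    if config.asr.run_model_selection:
        table = model_selection_table(tree, aln)
        selection_path = out / "model_selection.tsv"
        table.to_csv(selection_path, sep="\t", index=False)

    fitted = {
        "log_likelihood": fit.log_likelihood,
        "alpha": fit.model.gamma_shape,
        "p_inv": fit.model.p_invariant,
        "branch_scale": fit.branch_scale,
    }
    stage_info = {
        "posteriors": "posteriors.tsv",
        "ml_fasta": "ancestral_ml.fasta",
        "altall_fasta": "ancestral_altall.fasta",
        "model_selection": "model_selection.tsv" if selection_path else None,
        "fitted": fitted,
    }
    _write_manifest(out, config, stage_info)
    return {"output_dir": str(out), "posterior": post, "fit": fit, **stage_info}


def run_binding_workflow(config: RunConfig) -> dict:
    """Titration CSVs and/or the affinity fixture -> K_D table + summary."""
    logging.basicConfig(level=config.log_level)
    if config.titrations is None and not config.binding.use_fixture:
        raise WorkflowError(
            "stage=inputs: the binding workflow needs a titration CSV or "
            "binding.use_fixture=true"
        )
    out = _prepare_run_dir(config)
    stage_info: dict = {}

    rows = []
    if config.titrations is not None:
        experiments = load_fp_experiments(config.titrations)
        if not experiments:
            raise WorkflowError("stage=load: titration CSV contains no experiments")
        probe_kd = config.binding.probe_kd_uM
        saturations = {
            k: e for k, e in experiments.items() if e.mode == "saturation"
        }
        if probe_kd is None:
            if not saturations:
                raise WorkflowError(
                    "stage=calibration: no probe K_D given and no saturation "
                    "experiment found; supply a saturation titration of the "
                    "probe against the protein (mode=saturation) or set "
                    "binding.probe_kd_uM"
                )
            sat_id, sat = next(iter(saturations.items()))
            sat_fit = fit_fp_saturation(sat)
            probe_kd = sat_fit.kd_uM
            logger.info("probe K_D from %s: %.4g uM", sat_id, probe_kd)
            rows.append(
                {
                    "experiment": sat_id,
                    "method": sat_fit.method,
                    "kd_uM": sat_fit.kd_uM,
                    "se_uM": sat_fit.se_uM,
                    "residual_norm": sat_fit.residual_norm,
                    "flag": "",
                }
            )
        for exp_id, exp in experiments.items():
            if exp.mode != "competition":
                continue
            route_a, route_b = fit_fp_competition(exp, probe_kd)
            primary = route_a if config.binding.route == "conversion" else route_b
            secondary = route_b if primary is route_a else route_a
            for est in (primary, secondary):
                rows.append(
                    {
                        "experiment": exp_id,
                        "method": est.method,
                        "kd_uM": est.kd_uM,
                        "se_uM": est.se_uM,
                        "residual_norm": est.residual_norm,
                        "flag": "lower_bound_only" if est.lower_bound_only else "",
                    }
                )
        pd.DataFrame(rows).to_csv(out / "affinities.tsv", sep="\t", index=False)
        stage_info["affinities"] = "affinities.tsv"

    if config.binding.use_fixture:
        table = AffinityTable.packaged_fixture()
        summary = table.summary()
        with open(out / "affinity_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        table.fold_changes(subset="all").rename("fold_change").to_csv(
            out / "fold_changes.tsv", sep="\t"
        )
        stage_info["summary"] = "affinity_summary.json"
        stage_info["fold_changes"] = "fold_changes.tsv"
        stage_info["headline"] = summary

    _write_manifest(out, config, stage_info)
    return {"output_dir": str(out), **stage_info}
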