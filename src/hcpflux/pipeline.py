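"""End-to-end pipeline: load or simulate, normalize, roll up, detect, classify, report.

Driven by a small YAML config::

    outdir: out/
    seed: 1
    design: eight_sample          # six_sample | eight_sample | path to YAML
    psm_table: null               # path, or null to simulate
    simulate: {n_hcp: 200}        # SyntheticParams overrides (when simulating)
    k: 3.0                        # noise threshold multiplier
    noise_floor: null             # explicit threshold for blank-free designs
    min_unique_peptides: 3
    transitions: null             # list of [from, to]; default consecutive
    plots: false

Every run writes a fixed bundle of TSVs plus ``run_metadata.json``. On any
stage failure the partially written outputs are removed and the error is
re-raised with the failing stage named.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import ChannelDesign, eight_sample_design, load_design, six_sample_design, write_design
from .flux import FluxRecord, ThreeLists, hcp_summary, three_lists, transition_ratios
from .io import PsmCollection, load_psm_table, write_protein_report, write_psm_table
from .noise import DetectionCall, NoiseModel, call_detection, fit_noise, set_noise_floor
from .quant import ProteinQuant, global_composition, hc_lc_series, normalize_collection, rollup_proteins
from .report import heatmap_matrix, ratio_histogram, render_heatmap
from .simulate import ClearanceSpec, GroundTruth, SyntheticParams, generate_experiment, truth_summary

__all__ = ["PipelineError", "RunResult", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunResult:
    """Everything one pipeline run produced, in memory plus on disk."""

    design: ChannelDesign
    collection: PsmCollection
    quants: list[ProteinQuant]
    noise: NoiseModel | None
    detections: list[DetectionCall]
    flux: list[FluxRecord]
    lists: dict[str, ThreeLists]
    composition: dict[str, tuple[float, float]]
    hclc: dict[str, float] | None
    summary: pd.DataFrame
    truth: GroundTruth | None
    outputs: dict[str, Path] = field(default_factory=dict)


_DESIGN_FACTORIES = {"six_sample": six_sample_design, "eight_sample": eight_sample_design}

_DEFAULT_CONFIG: dict[str, Any] = {
    "outdir": "hcpflux_out",
    "seed": 0,
    "design": "eight_sample",
    "psm_table": None,
    "simulate": {},
    "k": 3.0,
    "noise_floor": None,
    "min_unique_peptides": 3,
    "transitions": None,
    "plots": False,
}


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    unknown = set(doc) - set(_DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    cfg = dict(_DEFAULT_CONFIG)
    cfg.update(doc)
    return cfg


def _resolve_design(spec: str | Path) -> ChannelDesign:
    if isinstance(spec, str) and spec in _DESIGN_FACTORIES:
        return _DESIGN_FACTORIES[spec]()
    return load_design(spec)


def _build_params(overrides: Mapping[str, Any], seed: int) -> SyntheticParams:
    kwargs = dict(overrides or {})
    clearance = kwargs.pop("clearance", None)
    if clearance:
        kwargs["clearance"] = {t: ClearanceSpec(**spec) for t, spec in clearance.items()}
    kwargs.setdefault("seed", seed)
    return SyntheticParams(**kwargs)


def run_pipeline(config: Mapping[str, Any] | str | Path, outdir: str | Path | None = None) -> RunResult:
    """Execute the full analysis per *config* (mapping or YAML path)."""
    if not isinstance(config, Mapping):
        cfg = load_config(config)
    else:
        unknown = set(config) - set(_DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = dict(_DEFAULT_CONFIG)
        cfg.update(config)
    out = Path(outdir if outdir is not None else cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, filename: str) -> Path:
        path = out / filename
        written[name] = path
        return path

    stage = "configure"
    try:
        stage = "design"
        design = _resolve_design(cfg["design"])
        write_design(design, emit("design", "design.yaml"))

        stage = "load"
        truth: GroundTruth | None = None
        if cfg["psm_table"]:
            coll = load_psm_table(cfg["psm_table"], design)
        else:
            params = _build_params(cfg["simulate"], int(cfg["seed"]))
            coll, truth = generate_experiment(params, design)
            write_psm_table(coll, emit("psm_table", "psm_table.tsv"))
            truth.proteins.to_csv(emit("truth_proteins", "truth_proteins.tsv"), sep="\t")
            truth.mab.to_csv(emit("truth_mab", "truth_mab.tsv"), sep="\t")
            truth_summary(truth).to_csv(emit("truth_summary", "truth_summary.tsv"), sep="\t")

        stage = "normalize"
        normed, factors = normalize_collection(coll)

        stage = "rollup"
        quants = rollup_proteins(normed, min_unique_peptides=int(cfg["min_unique_peptides"]))

        stage = "noise"
        noise: NoiseModel | None = None
        if design.blank_labels:
            noise = fit_noise(normed, k=float(cfg["k"]))
        elif cfg["noise_floor"] is not None:
            noise = set_noise_floor(float(cfg["noise_floor"]))

        stage = "detection"
        detections = call_detection(quants, noise, design) if noise is not None else []

        stage = "flux"
        transitions = cfg["transitions"]
        if transitions is not None:
            transitions = [tuple(t) for t in transitions]
        flux = transition_ratios(
            quants, design, transitions=transitions, detections=detections if noise else None
        )
        lists = three_lists(flux, detections) if noise is not None else {}

        stage = "composition"
        composition = global_composition(quants, design)
        hclc: dict[str, float] | None
        try:
            hclc = hc_lc_series(quants, design)
        except Exception:
            hclc = None  # no quantifiable product chains in this run
        summary = hcp_summary(quants, composition, design, detections=detections)

        stage = "report"
        write_protein_report(quants, detections, emit("protein_report", "protein_report.tsv"), flux=flux)
        comp_df = pd.DataFrame(
            [(l, *composition[l]) for l in design.labels],
            columns=["label", "mab_fraction", "hcp_fraction"],
        )
        comp_df.to_csv(emit("composition", "composition.tsv"), sep="\t", index=False)
        if hclc is not None:
            pd.Series(hclc, name="lc_hc_ratio").rename_axis("stage").to_csv(
                emit("hclc", "hclc.tsv"), sep="\t"
            )
        flux_df = pd.DataFrame(
            [(r.accession, r.transition, r.mean_ratio, r.fate) for r in flux],
            columns=["accession", "transition", "mean_ratio", "fate"],
        )
        flux_df.to_csv(emit("flux", "flux.tsv"), sep="\t", index=False)
        if lists:
            rows = [
                (t, category, acc)
                for t, tl in lists.items()
                for category in ("above_detection", "retained", "decreased")
                for acc in getattr(tl, category)
            ]
            pd.DataFrame(rows, columns=["transition", "list", "accession"]).to_csv(
                emit("three_lists", "three_lists.tsv"), sep="\t", index=False
            )
        summary.to_csv(emit("summary", "summary.tsv"), sep="\t")

        z = heatmap_matrix(quants, design)
        z.to_csv(emit("zscore_matrix", "zscore_matrix.tsv"), sep="\t")
        finite_ratios = [
            v for q in quants if q.quantifiable for v in q.ratio.values() if not np.isnan(v)
        ]
        hist = ratio_histogram(finite_ratios)
        hist.to_frame().to_csv(emit("ratio_histogram", "ratio_histogram.tsv"), sep="\t", index=False)
        if cfg["plots"] and not z.empty:
            render_heatmap(z, emit("heatmap_png", "heatmap.png"))

        stage = "metadata"
        meta = {
            "hcpflux_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": int(cfg["seed"]),
            "k": float(cfg["k"]),
            "min_unique_peptides": int(cfg["min_unique_peptides"]),
            "channel_factors": factors,
            "noise": None
            if noise is None
            else {
                "mu_log": noise.mu_log,
                "sigma_log": noise.sigma_log,
                "n_obs": noise.n_obs,
                "k": noise.k,
                "threshold": noise.threshold,
                "source": noise.source,
            },
            "n_psm": len(coll),
            "n_proteins": len(quants),
            "outputs": {k: str(v) for k, v in written.items()},
        }
        with open(emit("run_metadata", "run_metadata.json"), "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        for path in written.values():
            try:
                path.unlink(missing_ok=True)
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    return RunResult(
        design=design,
        collection=normed,
        quants=quants,
        noise=noise,
        detections=detections,
        flux=flux,
        lists=lists,
        composition=composition,
        hclc=hclc,
        summary=summary,
        truth=truth,
        outputs=written,
    )
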