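"""End-to-end orchestration: drugs → clustering → signature → LOO →
projection → circos, driven by a YAML config.

Every stage is a pure function of (inputs, config, seed); re-running with
an identical config and inputs reproduces identical outputs. The run
manifest records the seed, a hash of the canonical config, and per-stage
status, so a failed run shows exactly where it stopped while earlier
outputs stay intact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as psio
from .circos import build_tracks, export_tracks, resistance_flags
from .consensus import consensus_cluster, subtype_markers
from .datamodel import AxisSemantics, DrugResponseMatrix
from .drug_response import bin_sensitivity, summarize_panel, threshold_ic50
from .preprocess import collapse_probes, recode_cnv_matrix, standard_normalize
from .signature import (
    derive_signature,
    evaluate_separation,
    loo_validate,
    project_signature,
    select_extremes,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_INPUT_KEYS = {"ic50", "probes", "probe_map", "cnv", "mutations", "genes",
               "tumor_counts"}
_PARAM_DEFAULTS = {
    "ceiling": 8.0,
    "effective_cut": 1.0,
    "selective_fold": 20.0,
    "bin_edges": [0.1, 0.5, 1.0, 2.0, 4.0],
    "maxk": 10,
    "resamples": 1000,
    "subsample_fraction": 0.8,
    "alpha": 0.05,
    "drug": None,
    "k_extremes": 5,
    "loo_mode": "fixed_signature",
    "projection_clusters": 2,
}


@dataclass
class PipelineConfig:
    inputs: dict[str, str]
    out_dir: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.inputs) - _INPUT_KEYS
        if unknown:
            raise ValueError(f"unknown input keys: {sorted(unknown)}")
        unknown = set(self.params) - set(_PARAM_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        merged = dict(_PARAM_DEFAULTS)
        merged.update(self.params)
        self.params = merged

    def require(self, *keys: str) -> None:
        missing = [k for k in keys if k not in self.inputs]
        if missing:
            raise ValueError(f"missing required inputs: {missing}")

    def param_hash(self) -> str:
        canon = json.dumps(
            {"inputs": self.inputs, "params": self.params, "seed": self.seed},
            sort_keys=True,
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    version = raw.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema_version {version}")
    allowed = {"inputs", "out_dir", "seed", "params"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(
        inputs={k: str(v) for k, v in raw.get("inputs", {}).items()},
        out_dir=str(raw["out_dir"]),
        seed=int(raw.get("seed", 0)),
        params=raw.get("params", {}) or {},
    )
    missing = [k for k, p in cfg.inputs.items() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(
            f"input files not found: {[cfg.inputs[k] for k in missing]}"
        )
    return cfg


def _read_probe_map(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    manifest: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "parameter_hash": config.param_hash(),
        "stages": {},
    }
    state: dict = {}

    def stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, out)
            raise
        elapsed = time.perf_counter() - t0
        manifest["stages"].setdefault(
            name, {"status": "ok", "seconds": round(elapsed, 3)})
        log.info("stage %-12s %s (%.2fs)", name,
                 manifest["stages"][name]["status"], elapsed)

    def drugs() -> None:
        config.require("ic50")
        raw = psio.read_matrix(config.inputs["ic50"], AxisSemantics.cell_by_drug,
                               units="µM")
        drm = threshold_ic50(
            DrugResponseMatrix(matrix=raw, ceiling=p["ceiling"]), p["ceiling"])
        state["drm"] = drm
        summaries = summarize_panel(drm, p["effective_cut"], p["selective_fold"])
        psio.write_result(summaries, out / "drug_summary.json")
        bins = bin_sensitivity(drm, tuple(p["bin_edges"]))
        psio.write_matrix(bins.binned, out / "sensitivity_bins.tsv")

    def preprocess() -> None:
        config.require("probes", "probe_map")
        probes = psio.read_matrix(config.inputs["probes"],
                                  AxisSemantics.probe_by_sample)
        pmap = _read_probe_map(config.inputs["probe_map"])
        gene = collapse_probes(probes, pmap)
        z = standard_normalize(gene)
        state["expr"] = z
        psio.write_matrix(z, out / "expression_z.tsv")

    def cluster() -> None:
        res = consensus_cluster(
            state["expr"], maxk=p["maxk"], resamples=p["resamples"],
            subsample_fraction=p["subsample_fraction"], seed=config.seed)
        state["consensus"] = res
        psio.write_result(
            {"chosen_k": res.chosen_k, "labels": res.labels,
             "areas": res.areas, "delta_areas": res.delta_areas,
             "pac": res.pac, "seed": res.rng_seed},
            out / "consensus.json")
        markers = subtype_markers(state["expr"], res.labels, p["alpha"])
        markers.to_frame().to_csv(out / "subtype_markers.tsv", sep="\t")

    def signature() -> None:
        drug = p["drug"] or state["drm"].drug_ids[0]
        ic50 = state["drm"].drug_values(drug)
        ic50 = ic50[[c for c in ic50.index if c in state["expr"].col_ids]]
        sens, resi = select_extremes(ic50, p["k_extremes"])
        sig = derive_signature(state["expr"], sens, resi, p["alpha"], drug)
        state["signature"] = sig
        clean, mis = evaluate_separation(
            state["expr"], sig.signature_genes, sens, resi)
        psio.write_result(sig, out / "signature.json")
        psio.write_result({"clean": clean, "misclassified": mis},
                          out / "separation.json")

    def loo() -> None:
        drug = state["signature"].drug_id
        ic50 = state["drm"].drug_values(drug)
        result = loo_validate(state["expr"], ic50, p["k_extremes"], p["alpha"],
                              p["loo_mode"], drug)
        psio.write_result(result, out / "loo.json")

    def projection() -> None:
        if "tumor_counts" not in config.inputs:
            manifest["stages"]["projection"] = {"status": "skipped"}
            return
        counts = psio.read_matrix(config.inputs["tumor_counts"],
                                  AxisSemantics.gene_by_sample, units="counts")
        ref = state["expr"].subset_cols(state["signature"].sensitive_set)
        result = project_signature(state["signature"], counts, ref,
                                   n_clusters=p["projection_clusters"])
        psio.write_result(result, out / "projection.json")

    def circos() -> None:
        config.require("cnv", "mutations", "genes")
        cnv = psio.read_matrix(config.inputs["cnv"],
                               AxisSemantics.gene_by_sample, units="copies")
        recoded = recode_cnv_matrix(cnv)
        muts = psio.read_mutations(config.inputs["mutations"])
        coords = psio.read_gene_coordinates(config.inputs["genes"])
        sig = state["signature"]
        sig_expr = state["expr"].subset_rows(
            [g for g in sig.signature_genes if g in state["expr"].row_ids])
        flags = []
        for cell in sig.sensitive_set + sig.resistant_set:
            bundle = build_tracks(cell, sig_expr, recoded, muts, coords)
            export_tracks(bundle, out / "circos" / cell)
            flags.append(resistance_flags(cell, muts, recoded, coords))
        psio.write_result(flags, out / "resistance_flags.json")

    for name, fn in [("drugs", drugs), ("preprocess", preprocess),
                     ("cluster", cluster), ("signature", signature),
                     ("loo", loo), ("projection", projection),
                     ("circos", circos)]:
        stage(name, fn)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
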