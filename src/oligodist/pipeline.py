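"""End-to-end analysis runs: simulate or load data, compute distributions,
fit the power laws and the resource-precision model, and write a report
bundle (JSON summary + tidy TSVs + a reproducibility manifest).

A run is driven by a config mapping with either input paths or simulation
parameter blocks::

    proteome:
      path: proteome.tsv            # OR  simulate: {n_proteins: 20000, ...}
    network:
      path: interactions.tsv        # OR  simulate: {n_nodes: 10000, ...}
    analysis:
      parity: all
      denominator: all-known
      weighting: count
      support: [2, 4, 6, 8]
      score_min: 0
      min_tail: 10
      n_boot: 200
    seed: 0

CLI flags override config keys; every run writes ``manifest.json`` with the
config, seeds and package version so deterministic stages reproduce
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .distributions import oligomer_frequency, stratified_frequency
from .errors import EmptyInputError, InsufficientDataError, OligodistError
from .io import read_proteome_table, read_string_edges
from .model import (
    DEFAULT_SUPPORT,
    capacity,
    fit_resource_model,
    model_frequency,
)
from .network import (
    correlation_degree_vs_k,
    degree_by_oligomer_class,
    summarize_degrees,
)
from .powerlaw import loglog_ols_fit, select_kmin
from .synthetic import (
    NetworkSimParams,
    ProteomeSimParams,
    generate_degree_sequence,
    generate_proteome,
    realize_edges,
)

logger = logging.getLogger(__name__)

__all__ = ["run_proteome_analysis", "run_ppi_analysis", "load_config"]


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_manifest(outdir: Path, config: dict, seed: Optional[int]) -> None:
    manifest = {
        "package": "oligodist",
        "version": __version__,
        "config_hash": _config_hash(config),
        "config": config,
        "seed": seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _resolve_proteome(config: dict, seed: Optional[int]):
    block = config.get("proteome", {})
    if "path" in block:
        return read_proteome_table(block["path"])
    sim = dict(block.get("simulate", {}))
    if not sim:
        raise OligodistError("config needs proteome.path or proteome.simulate")
    if seed is not None:
        sim.setdefault("seed", seed)
    return generate_proteome(ProteomeSimParams(**sim))


def _resolve_graph(config: dict, seed: Optional[int]):
    block = config.get("network", {})
    if "path" in block:
        score_min = float(config.get("analysis", {}).get("score_min", 0.0))
        return read_string_edges(block["path"], score_min=score_min)
    sim = dict(block.get("simulate", {}))
    if not sim:
        raise OligodistError("config needs network.path or network.simulate")
    if seed is not None:
        sim.setdefault("seed", seed)
    params = NetworkSimParams(**sim)
    degrees = generate_degree_sequence(params)
    g = realize_edges(degrees, seed=params.seed)
    # name nodes like the synthetic proteome so class joins are possible
    import networkx as nx

    return nx.relabel_nodes(g, {i: f"SYN{i:06d}" for i in g.nodes()})


def _dist_payload(dist) -> dict:
    return {
        "label": dist.label,
        "parity": dist.parity,
        "weighting": dist.weighting,
        "total": dist.total,
        "overflow": dist.overflow,
        "counts": {str(k): v for k, v in sorted(dist.counts.items())},
        "freqs": {str(k): v for k, v in sorted(dist.freqs.items())},
    }


def run_proteome_analysis(config: dict, outdir, seed: Optional[int] = None) -> dict:
    """Distributions -> log-log OLS fit -> resource-model fit -> capacity.

    Writes ``proteome_summary.json`` and tidy TSVs under ``outdir`` and
    returns the summary dict. Fits that lack enough points are skipped with
    an explanatory note rather than failing the run.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = config.get("seed")
    analysis = config.get("analysis", {})
    parity = analysis.get("parity", "all")
    denominator = analysis.get("denominator", "all-known")
    weighting = analysis.get("weighting", "count")
    support = tuple(analysis.get("support", DEFAULT_SUPPORT))

    records = _resolve_proteome(config, seed)
    summary: dict = {"n_records": len(records), "seed": seed, "notes": []}

    dist_all = oligomer_frequency(
        records, parity=parity, denominator=denominator, weighting=weighting,
        label="proteome",
    )
    dist_even = oligomer_frequency(
        records, parity="even", denominator="parity-subset", weighting=weighting,
        label="proteome-even",
    )
    summary["distribution"] = _dist_payload(dist_all)
    summary["distribution_even_renormalized"] = _dist_payload(dist_even)

    strata = {}
    labels = sorted({t for r in records for t in r.go_terms})
    for lab in labels:
        try:
            strata[lab] = _dist_payload(stratified_frequency(records, lab))
        except EmptyInputError:
            continue
    if strata:
        summary["strata"] = strata

    even_pts = {k: f for k, f in dist_even.freqs.items() if f > 0}
    try:
        ols = loglog_ols_fit(even_pts)
        summary["ols_fit"] = dataclasses.asdict(ols)
    except (InsufficientDataError, OligodistError) as exc:
        summary["ols_fit"] = None
        summary["notes"].append(f"OLS fit skipped: insufficient points ({exc})")

    try:
        fit = fit_resource_model(dist_even.freqs, support=support, mode="scaled")
        summary["resource_model_fit"] = {
            "support": list(fit.support),
            "mode": fit.mode,
            "scale": fit.scale,
            "r_squared": fit.r_squared,
            "predicted": {str(k): v for k, v in fit.predicted.items()},
            "residuals": {str(k): v for k, v in fit.residuals.items()},
        }
    except OligodistError as exc:
        summary["resource_model_fit"] = None
        summary["notes"].append(f"resource-model fit skipped: {exc}")

    cap = capacity(dist_all)
    summary["capacity"] = {str(k): v for k, v in sorted(cap.values.items())}
    summary["model_frequency_normalized"] = {
        str(k): v for k, v in model_frequency(support).items()
    }

    rows = dist_all.to_tidy_rows() + dist_even.to_tidy_rows()
    pd.DataFrame(rows).to_csv(out / "distributions.tsv", sep="\t", index=False)
    (out / "proteome_summary.json").write_text(
        json.dumps(summary, indent=2, default=str)
    )
    _write_manifest(out, config, seed)
    return summary


def run_ppi_analysis(config: dict, outdir, seed: Optional[int] = None) -> dict:
    """Degree summary -> power-law tail fit (k_min scan + bootstrap) ->
    oligomer-class degree table when annotations are available."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = config.get("seed")
    analysis = config.get("analysis", {})
    min_tail = int(analysis.get("min_tail", 10))
    n_boot = int(analysis.get("n_boot", 200))

    graph = _resolve_graph(config, seed)
    deg = summarize_degrees(graph)
    summary: dict = {
        "seed": seed,
        "notes": [],
        "degree_summary": {
            "n_nodes": deg.n_nodes,
            "n_edges": deg.n_edges,
            "mean_degree": deg.mean_degree,
            "distribution": {str(k): v for k, v in sorted(deg.distribution.items())},
        },
    }

    degrees = [d for d in deg.degree_of.values() if d > 0]
    try:
        fit = select_kmin(degrees, min_tail=min_tail, n_boot=n_boot, seed=seed)
        summary["powerlaw_fit"] = {
            "gamma": fit.gamma,
            "k_min": fit.k_min,
            "n_tail": fit.n_tail,
            "ks_D": fit.ks_D,
            "p_boot": fit.p_boot,
            "n_boot": fit.n_boot,
            "seed": fit.seed,
            "scan": [list(row) for row in fit.scan],
        }
    except OligodistError as exc:
        summary["powerlaw_fit"] = None
        summary["notes"].append(f"power-law fit skipped: {exc}")

    records = None
    if "proteome" in config:
        try:
            records = _resolve_proteome(config, seed)
        except OligodistError:
            records = None
    if records is not None:
        classes = tuple(analysis.get("classes", (2, 4, 6, 8)))
        try:
            table = degree_by_oligomer_class(graph, records, classes=classes)
            class_payload = {
                "members": {str(k): v for k, v in table.members.items()},
                "mean_degree": {str(k): v for k, v in table.mean_degree.items()},
                "missing": {str(k): v for k, v in table.missing.items()},
                "join_rate": table.join_rate,
            }
            try:
                r, slope = correlation_degree_vs_k(table)
                class_payload["pearson_r"] = r
                class_payload["ols_slope"] = slope
            except InsufficientDataError:
                summary["notes"].append("degree-vs-k correlation skipped: <3 classes")
            summary["class_degree_table"] = class_payload
        except EmptyInputError:
            summary["class_degree_table"] = None
            summary["notes"].append("class degree table skipped: no joined proteins")
    else:
        summary["class_degree_table"] = None
        logger.info("no oligomer annotations provided; class degree table absent")
        summary["notes"].append("no oligomer annotations; class degree table absent")

    pd.DataFrame(
        [{"protein_id": p, "degree": d} for p, d in deg.degree_of.items()]
    ).to_csv(out / "degrees.tsv", sep="\t", index=False)
    (out / "ppi_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    _write_manifest(out, config, seed)
    return summary
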