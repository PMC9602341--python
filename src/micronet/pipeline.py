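"""Two-condition experiment orchestration.

Wires the stages end to end for the benign and stress temperature regimes:
synthetic community generation -> observation -> absolute-abundance assembly
-> day-0 removal and prevalence filter -> UIC edge screening -> S-map
sign/strength -> signed-network summaries -> cross-condition comparison
report.  A single run seed fans out deterministically to per-stage seeds, so
re-runs are byte-identical and each stage is individually reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import network as netmod
from . import smap as smapmod
from . import synthetic as syn
from . import uic as uicmod

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConditionArtifacts", "run_condition",
           "compare_conditions", "run_experiment", "stage_seed"]

#: Fixed offsets of the seed fan-out (base SeedSequence spawn keys).
STAGE_OFFSETS = {
    "latent_benign": 0, "observe_benign": 1, "uic_benign": 2,
    "latent_stress": 3, "observe_stress": 4, "uic_stress": 5,
    "scenario": 6,
}


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed.

    Child ``SeedSequence(base_seed).spawn_key = (offset,)`` streams are
    collapsed to 31-bit integers so every stage can also be re-run in
    isolation with a plain integer seed.
    """
    off = STAGE_OFFSETS[stage]
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(off,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class RunConfig:
    """Experiment-level configuration for the synthetic two-regime run."""

    seed: int
    out_dir: Path | str | None = None
    alpha: float = 0.05
    bootstrap: int = 2000
    e_grid: tuple[int, ...] = tuple(range(1, 6))
    theta_grid: tuple[float, ...] = smapmod.DEFAULT_THETA_GRID
    lambda_grid: tuple[float, ...] = smapmod.DEFAULT_LAMBDA_GRID
    max_absent: int = 40
    n_genera: int = 18
    sequencing_depth: int = 100_000


@dataclass
class ConditionArtifacts:
    """Everything one condition produces."""

    condition: str
    timeseries: ab.CommunityTimeSeries
    uic_results: list
    signed_edges: list
    network: netmod.SignedDirectedNetwork
    truth: syn.SyntheticTruth | None = None
    summary: dict = field(default_factory=dict)


def _synthetic_condition_config(run: RunConfig, condition: str) -> syn.SyntheticConfig:
    base = syn.default_scenario(seed=stage_seed(run.seed, "scenario"),
                                n_genera=run.n_genera)
    if condition == "stress":
        cfg = syn.apply_temperature_regime(base)
        return replace(cfg, rng_seed=stage_seed(run.seed, "latent_stress"))
    return replace(base, rng_seed=stage_seed(run.seed, "latent_benign"))


def run_condition(run: RunConfig, condition: str) -> ConditionArtifacts:
    """Run the full pipeline for one condition ("benign" or "stress")."""
    if condition not in ("benign", "stress"):
        raise ValueError("condition must be 'benign' or 'stress'")
    cfg = _synthetic_condition_config(run, condition)
    latent = syn.simulate_latent(cfg)
    obs_cfg = syn.ObservationConfig(
        sequencing_depth=run.sequencing_depth,
        rng_seed=stage_seed(run.seed, f"observe_{condition}"))
    tidy = syn.observe(latent, obs_cfg, step_days=cfg.step_days,
                       genus_labels=cfg.genus_labels)
    ts = ab.assemble(tidy)
    ts = ab.drop_day0(ts)
    ts = ab.prevalence_filter(ts, max_absent=run.max_absent)
    uic_results = uicmod.scan_all_pairs(
        ts, alpha=run.alpha, e_grid=run.e_grid, b=run.bootstrap,
        seed=stage_seed(run.seed, f"uic_{condition}"))
    smap_cfg = smapmod.SMapConfig(theta_grid=run.theta_grid,
                                  lambda_grid=run.lambda_grid)
    signed = smapmod.quantify_network(ts, uic_results, config=smap_cfg)
    net = netmod.build_network(
        [(e.cause, e.effect, e.sign, e.strength) for e in signed],
        nodes=ts.genera, condition=condition)
    truth = syn.ground_truth(cfg)
    summary = {
        "condition": condition,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "connectance": netmod.connectance(net) if net.n_nodes > 1 else None,
        "positive_link_percent": (netmod.positive_link_proportion(net)
                                  if net.n_edges else None),
    }
    art = ConditionArtifacts(condition=condition, timeseries=ts,
                             uic_results=uic_results, signed_edges=signed,
                             network=net, truth=truth, summary=summary)
    if run.out_dir is not None:
        _write_condition(run, art)
    return art


def compare_conditions(a: ConditionArtifacts, b: ConditionArtifacts) -> dict:
    """Full cross-condition comparison report.

    Emits the node partition, connectance and percent changes, positive-link
    proportions (complete networks and common subnetworks), pair-state
    tables, Wilcoxon degree tests of common vs specific genera by sign and
    direction, Spearman degree correlations over common genera, and the
    binary graph correlation between common subnetworks.  Statistics that
    are undefined on the realized networks (e.g. an edgeless subnetwork)
    are reported as None.
    """
    net_a, net_b = a.network, b.network
    part = netmod.partition_nodes(net_a, net_b)
    common = list(part.common)

    def safe(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (ValueError, KeyError):
            return None

    conn_a = safe(netmod.connectance, net_a)
    conn_b = safe(netmod.connectance, net_b)
    report: dict = {
        "conditions": [a.condition, b.condition],
        "partition": {"common": len(part.common),
                      "specific_a": len(part.specific_a),
                      "specific_b": len(part.specific_b)},
        "n_nodes": {"a": net_a.n_nodes, "b": net_b.n_nodes},
        "n_edges": {"a": net_a.n_edges, "b": net_b.n_edges},
        "connectance": {"a": conn_a, "b": conn_b},
        "percent_change": {
            "nodes": safe(netmod.percent_change, net_a.n_nodes, net_b.n_nodes),
            "connectance": (safe(netmod.percent_change, conn_a, conn_b)
                            if conn_a not in (None, 0) and conn_b is not None
                            else None),
        },
        "positive_link_percent": {
            "a": safe(netmod.positive_link_proportion, net_a),
            "b": safe(netmod.positive_link_proportion, net_b),
        },
        "pair_states": {
            "a": safe(netmod.pair_state_table, net_a),
            "b": safe(netmod.pair_state_table, net_b),
        },
    }
    if len(common) >= 2:
        sub_a = netmod.induced_subnetwork(net_a, common)
        sub_b = netmod.induced_subnetwork(net_b, common)
        report["common_subnetwork"] = {
            "positive_link_percent": {
                "a": safe(netmod.positive_link_proportion, sub_a),
                "b": safe(netmod.positive_link_proportion, sub_b),
            },
            "pair_states": {
                "a": safe(netmod.pair_state_table, sub_a),
                "b": safe(netmod.pair_state_table, sub_b),
            },
            "graph_correlation": safe(netmod.graph_correlation, net_a, net_b,
                                      common),
        }
        spearman = {}
        for direction in ("total", "in", "out"):
            spearman[direction] = safe(netmod.spearman_degree_correlation,
                                       net_a, net_b, common, direction)
        report["spearman_degree"] = spearman
    wilcoxon = {}
    for art, net, specific in ((a, net_a, part.specific_a),
                               (b, net_b, part.specific_b)):
        entry = {}
        for sign, sname in ((1, "positive"), (-1, "negative")):
            for direction in ("total", "in", "out"):
                if not common or not specific:
                    entry[f"{sname}_{direction}"] = None
                    continue
                g_common = [netmod.signed_degree(net, n, sign, direction)
                            for n in common]
                g_spec = [netmod.signed_degree(net, n, sign, direction)
                          for n in specific]
                entry[f"{sname}_{direction}"] = safe(
                    netmod.wilcoxon_degree_test, g_common, g_spec)
        wilcoxon[art.condition] = entry
    report["wilcoxon_common_vs_specific"] = wilcoxon
    return report


def run_experiment(run: RunConfig) -> dict:
    """Run both conditions and the comparison; write artifacts if configured."""
    art_a = run_condition(run, "benign")
    art_b = run_condition(run, "stress")
    report = compare_conditions(art_a, art_b)
    if art_a.truth is not None:
        inferred_a = {(e.cause, e.effect): e.sign for e in art_a.signed_edges}
        rec = syn.recovery_metrics(inferred_a, art_a.truth)
        report["recovery_benign"] = {"tpr": rec.tpr, "fpr": rec.fpr,
                                     "sign_accuracy": rec.sign_accuracy}
    if run.out_dir is not None:
        out = Path(run.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _dump_json(report, out / "comparison.json")
        (out / "report.txt").write_text(format_report(report))
    return report


# ---------------------------------------------------------------- I/O helpers

def _sanitize(obj):
    """Replace non-finite floats with None so the JSON stays strict."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (float, np.floating)) and not np.isfinite(obj):
        return None
    return obj


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(_sanitize(obj), indent=1, sort_keys=True,
                               default=_coerce) + "\n")


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, Path):
        return str(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def network_to_json(net: netmod.SignedDirectedNetwork) -> dict:
    return {
        "condition": net.condition,
        "nodes": list(net.nodes),
        "edges": [{"source": u, "target": v, "sign": s, "strength": w}
                  for (u, v), (s, w) in sorted(net.edges.items())],
    }


def network_from_json(doc: dict) -> netmod.SignedDirectedNetwork:
    return netmod.build_network(
        [(e["source"], e["target"], e["sign"], e["strength"])
         for e in doc["edges"]],
        nodes=doc["nodes"], condition=doc.get("condition", ""))


def _write_condition(run: RunConfig, art: ConditionArtifacts) -> None:
    out = Path(run.out_dir) / art.condition
    out.mkdir(parents=True, exist_ok=True)
    art.timeseries.to_tidy().to_csv(out / "timeseries.tsv", sep="\t",
                                    index=False, float_format="%.10g")
    edges = pd.DataFrame(
        [(r.cause, r.effect, r.te, r.p_value, r.e_used, r.significant)
         for r in art.uic_results],
        columns=["cause", "effect", "te", "p_value", "e_used", "significant"])
    edges.to_csv(out / "edges.tsv", sep="\t", index=False,
                 float_format="%.10g")
    signed = pd.DataFrame(
        [(e.cause, e.effect, e.sign, e.strength, e.theta, e.lam)
         for e in art.signed_edges],
        columns=["cause", "effect", "sign", "strength", "theta", "lambda"])
    signed.to_csv(out / "signed_edges.tsv", sep="\t", index=False,
                  float_format="%.10g")
    _dump_json(network_to_json(art.network), out / "network.json")
    _dump_json(art.summary, out / "summary.json")
    manifest = {
        "condition": art.condition,
        # out_dir is where the artifacts land, not an input that shapes them
        "run_config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(run).items() if k != "out_dir"},
        "stage_seeds": {k: stage_seed(run.seed, k) for k in STAGE_OFFSETS},
        "outputs": ["timeseries.tsv", "edges.tsv", "signed_edges.tsv",
                    "network.json", "summary.json"],
    }
    _dump_json(manifest, out / "manifest.json")


def format_report(report: dict) -> str:
    """Human-readable rendering of the comparison report."""
    lines = [f"Conditions: {report['conditions'][0]} vs "
             f"{report['conditions'][1]}"]
    p = report["partition"]
    lines.append(f"Nodes: common={p['common']} "
                 f"specific_a={p['specific_a']} specific_b={p['specific_b']}")
    c = report["connectance"]
    def fmt(v, n=4):
        return "NA" if v is None else f"{v:.{n}f}"
    lines.append(f"Connectance: {fmt(c['a'])} -> {fmt(c['b'])} "
                 f"(change {fmt(report['percent_change']['connectance'], 1)}%)")
    pl = report["positive_link_percent"]
    lines.append(f"Positive links: {fmt(pl['a'], 2)}% -> {fmt(pl['b'], 2)}%")
    for cond, table in (report.get("pair_states") or {}).items():
        if table is None:
            continue
        states = ", ".join(f"{s}={v['percent']:.2f}%"
                           for s, v in table.items())
        lines.append(f"Pair states [{cond}]: {states}")
    return "\n".join(lines) + "\n"
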