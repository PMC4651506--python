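"""Configured, logged, seeded end-to-end runs.

``run_pipeline`` ties the stages together: (optional) probe-level
preprocessing → DEG calling and partition → soft temporal clustering →
co-expression network with hub table → (optional) qPCR validation.
Every intermediate artifact is written as TSV under the run directory,
together with a JSON manifest recording versions, parameters and stage
status; identical config + seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import sklearn
import yaml

from . import __version__
from .clustering import fcm_cluster, select_parameters, standardize_profiles
from .data import ExpressionMatrix
from .diffexpr import call_degs, partition_degs
from .io import (
    read_ct,
    read_expression,
    read_sample_sheet,
    read_table,
    write_table,
)
from .network import BACKGROUND, CoexpressionNetwork
from .preprocess import median_polish_summarize, quantile_normalize
from .qpcr import correlation_network, relative_expression_table

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("endonet")


@dataclass
class PipelineConfig:
    """Flat configuration for one end-to-end run.

    ``expression`` + ``samples`` are required paths; ``probe_matrix`` +
    ``probe_map`` switch on probe-level preprocessing; ``ct_table``
    switches on qPCR validation. ``clustering_c`` / ``clustering_m`` and
    ``network_beta`` accept ``"auto"`` for data-driven selection.
    """

    expression: str = ""
    samples: str = ""
    probe_matrix: str | None = None
    probe_map: str | None = None
    ct_table: str | None = None
    baseline_stage: str = "D12"
    alpha: float = 0.05
    clustering_c: object = "auto"
    clustering_m: object = "auto"
    network_genes: str = "all"  # "all" or "degs"
    network_beta: object = "auto"
    cut_height: float = 0.94
    min_module_size: int = 30
    edge_threshold: float = 0.02
    adjacency_dialect: str = "r2"
    reference_genes: tuple[str, ...] = ("RPL7", "UBB")
    validation_scale: str = "log2"  # or "linear"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "reference_genes" in raw:
            raw["reference_genes"] = tuple(raw["reference_genes"])
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("expression", "samples"):
            if not getattr(self, attr):
                raise ValueError(f"config field {attr!r} is required")
        for attr in ("expression", "samples", "probe_matrix", "probe_map", "ct_table"):
            p = getattr(self, attr)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.network_genes not in ("all", "degs"):
            raise ValueError("network_genes must be 'all' or 'degs'")
        if self.validation_scale not in ("log2", "linear"):
            raise ValueError("validation_scale must be 'log2' or 'linear'")


def _seed_for(base: int, stage: str) -> int:
    """Derive a per-stage seed from the run seed, documented and stable."""
    offsets = {"clustering": 1, "selection": 2}
    return (int(base) * 1000 + offsets[stage]) % (2**31 - 1)


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the full pipeline; returns the run directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest = {
        "package": "endonet",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }
    stage = "setup"
    try:
        stage_of_sample = read_sample_sheet(config.samples)

        if config.probe_matrix:
            stage = "preprocess"
            log.info("preprocess: quantile normalization + median polish")
            probe_df = read_table(config.probe_matrix, index_col=0)
            probe_map = dict(
                read_table(config.probe_map)[["probe", "gene"]].astype(str).to_numpy()
            )
            normalized = quantile_normalize(probe_df)
            summarized = median_polish_summarize(normalized, probe_map)
            expr = ExpressionMatrix(
                summarized, {s: stage_of_sample[s] for s in summarized.columns}
            )
            write_table(expr.values.rename_axis("gene_id"), out / "expression.tsv",
                        index=True)
            manifest["stages"]["preprocess"] = "ok"
        else:
            expr = read_expression(config.expression, stage_of_sample)

        stage = "differential_expression"
        log.info("DEG calling vs baseline %s at alpha %s",
                 config.baseline_stage, config.alpha)
        degs = call_degs(expr, config.baseline_stage, alpha=config.alpha)
        write_table(degs, out / "deg_table.tsv")
        part = partition_degs(degs)
        part_rows = [
            {"set": f"{stage_}_{direction}", "n_genes": len(gs),
             "genes": ",".join(sorted(gs))}
            for (stage_, direction), gs in sorted(part.stage_specific.items())
        ]
        part_rows.append({"set": "shared", "n_genes": len(part.shared),
                          "genes": ",".join(sorted(part.shared))})
        part_rows.append({"set": "total_unique", "n_genes": part.total_unique,
                          "genes": ""})
        write_table(pd.DataFrame(part_rows), out / "deg_partition.tsv")
        manifest["stages"]["differential_expression"] = "ok"
        deg_genes = sorted(set(degs["gene_id"]))
        log.info("%d DEG calls over %d unique genes", len(degs), len(deg_genes))

        stage = "clustering"
        if len(deg_genes) >= 3:
            profiles = standardize_profiles(expr, deg_genes)
            c, m = config.clustering_c, config.clustering_m
            if c == "auto" or m == "auto":
                upper = min(15, profiles.shape[0] - 1)
                c_sel, m_sel, diag = select_parameters(
                    profiles, c_range=range(2, upper + 1),
                    seed=_seed_for(config.seed, "selection"),
                )
                c = c_sel if c == "auto" else int(c)
                m = m_sel if m == "auto" else float(m)
                write_table(
                    pd.DataFrame(
                        {"c": list(diag["min_centroid_distance"]),
                         "min_centroid_distance":
                             list(diag["min_centroid_distance"].values())}
                    ),
                    out / "clustering_c_diagnostics.tsv",
                )
            fit = fcm_cluster(profiles, int(c), float(m),
                              seed=_seed_for(config.seed, "clustering"))
            membership = pd.DataFrame(
                fit.membership_, index=profiles.index,
                columns=[f"cluster_{i + 1}" for i in range(int(c))],
            )
            membership["hard_cluster"] = fit.labels_ + 1
            write_table(membership.rename_axis("gene_id"), out / "membership.tsv",
                        index=True)
            manifest["stages"]["clustering"] = "ok"
            manifest["clustering"] = {"c": int(c), "m": float(m)}
        else:
            log.info("fewer than 3 DEGs; skipping clustering")
            manifest["stages"]["clustering"] = "skipped"

        stage = "network"
        net_expr = expr if config.network_genes == "all" else expr.subset(deg_genes)
        net = CoexpressionNetwork(
            beta=config.network_beta,
            cut_height=config.cut_height,
            min_module_size=config.min_module_size,
            edge_threshold=config.edge_threshold,
            adjacency_dialect=config.adjacency_dialect,
        ).fit(net_expr.values.T)
        write_table(
            net.modules_.rename_axis("gene_id").reset_index(), out / "modules.tsv"
        )
        write_table(net.hub_table_.reset_index(), out / "hub_table.tsv")
        write_table(net.edge_list(), out / "edges.tsv")
        dendro = pd.DataFrame(
            net.linkage_, columns=["child_a", "child_b", "height", "n_members"]
        )
        write_table(dendro, out / "dendrogram.tsv")
        if net.scale_free_ is not None:
            write_table(
                pd.DataFrame(
                    {
                        "beta": net.scale_free_.beta_candidates,
                        "r_squared": net.scale_free_.r_squared,
                        "slope": net.scale_free_.slope,
                        "mean_connectivity": net.scale_free_.mean_connectivity,
                    }
                ),
                out / "scale_free_fit.tsv",
            )
        manifest["stages"]["network"] = "ok"
        manifest["network"] = {
            "beta": net.beta_,
            "n_modules": int((net.module_sizes_ > 0).sum()),
            "n_hubs": int(net.hub_table_["is_hub"].sum()),
        }
        log.info("network: beta=%s, %d modules, %d hubs", net.beta_,
                 manifest["network"]["n_modules"], manifest["network"]["n_hubs"])

        if config.ct_table:
            stage = "validation"
            ct = read_ct(config.ct_table)
            rel = relative_expression_table(
                ct, list(config.reference_genes),
                {s: stage_of_sample[s] for s in ct.columns}, config.baseline_stage
            )
            write_table(rel.rename_axis("gene_id"), out / "relative_expression.tsv",
                        index=True)
            edges = correlation_network(
                rel, alpha=config.alpha,
                log_scale=config.validation_scale == "log2",
            )
            write_table(edges, out / "validation_edges.tsv")
            manifest["stages"]["validation"] = "ok"
        else:
            log.info("no CT table supplied; skipping validation")
            manifest["stages"]["validation"] = "skipped"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        log.error("stage %s failed: %s", stage, exc)
        log.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.removeHandler(handler)
    handler.close()
    return out
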