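"""End-to-end orchestration: simulate -> screen -> describe -> estimate ->
centrality -> adjusted network -> sex comparison -> stability.

A :class:`RunConfig` (YAML-serializable) drives the whole pipeline with a
single master seed; every stochastic stage receives a recorded sub-seed
spawned from it, so a rerun with the same config overwrites every artifact
with identical content.  Artifacts are CSV/TSV/JSON; ``manifest.json``
records per-stage outputs, row counts after every filter, sub-seeds, and
content hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centrality import centrality_table
from .cohort import SyntheticSpec, default_spec, generate_cohort
from .descriptives import build_table_one, cronbach_alpha
from .ggm import (
    EstimatorConfig,
    adjust_for_covariates,
    compare_networks,
    estimate_network,
)
from .nct import network_comparison_test
from .scales import ctq_sf, gad7, phq9
from .screening import screen_cohort
from .stability import DEFAULT_DROP_GRID, stability_report

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run (YAML round-trippable)."""

    out_dir: str = "results/run"
    seed: int = 0
    # input: either a CSV path or a simulation size
    input_csv: str | None = None
    n_participants: int = 20_000
    # estimator
    correlation: str = "spearman"
    gamma: float = 0.5
    n_lambda: int = 100
    # covariate adjustment (empty list disables the adjusted re-estimation)
    adjust_covariates: tuple[str, ...] = (
        "sex",
        "family_type",
        "income_band",
        "only_child",
    )
    # network comparison test
    nct_group: str | None = "sex"
    nct_permutations: int = 1000
    # stability
    stability_replicates: int = 1000
    drop_grid: tuple[float, ...] = tuple(DEFAULT_DROP_GRID.tolist())

    def estimator(self) -> EstimatorConfig:
        return EstimatorConfig(
            method=self.correlation, gamma=self.gamma, n_lambda=self.n_lambda
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["adjust_covariates"] = list(self.adjust_covariates)
        d["drop_grid"] = list(self.drop_grid)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = yaml.safe_load(text)
        d["adjust_covariates"] = tuple(d.get("adjust_covariates", ()))
        d["drop_grid"] = tuple(d.get("drop_grid", DEFAULT_DROP_GRID.tolist()))
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; return (and write) the run manifest.

    Any stage error aborts the run; the partial manifest written so far is
    saved with the failing stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    sub = {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(
            ["simulate", "nct", "stability"], ss.spawn(3)
        )
    }
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "sub_seeds": sub,
        "config": yaml.safe_load(config.to_yaml()),
        "stages": {},
    }
    cfg = config.estimator()

    def record(stage: str, files: list[Path], **info) -> None:
        manifest["stages"][stage] = {
            "outputs": {f.name: _sha256(f) for f in files},
            **info,
        }

    try:
        # -- simulate / load ------------------------------------------------
        if config.input_csv is not None:
            cohort = pd.read_csv(config.input_csv)
            spec = None
            record("simulate", [], skipped=True, input=str(config.input_csv),
                   n_rows=len(cohort))
        else:
            spec = default_spec(config.n_participants, seed=sub["simulate"])
            cohort = generate_cohort(spec)
            cohort_csv = out / "cohort.csv"
            cohort.to_csv(cohort_csv, index=False)
            truth = out / "ground_truth.json"
            _write_json(truth, spec.ground_truth())
            record("simulate", [cohort_csv, truth], n_rows=len(cohort))

        # -- screen ---------------------------------------------------------
        screen = screen_cohort(cohort, ctq_sf())
        analysis = cohort[screen.analysis_mask].reset_index(drop=True)
        screened_csv = out / "screened.csv"
        analysis.to_csv(screened_csv, index=False)
        screen_json = out / "screen.json"
        _write_json(screen_json, screen.summary())
        record(
            "screen",
            [screened_csv, screen_json],
            n_rows_in=len(cohort),
            n_positive=screen.n_positive,
            n_rows_out=len(analysis),
        )

        # -- describe --------------------------------------------------------
        table1 = build_table_one(analysis)
        table1_tsv = out / "table1.tsv"
        table1.to_csv(table1_tsv, sep="\t", index=False)
        alphas = {
            "GAD-7": cronbach_alpha(analysis[list(gad7().items)]),
            "PHQ-9": cronbach_alpha(analysis[list(phq9().items)]),
            "CTQ-SF": cronbach_alpha(analysis[list(ctq_sf().items)]),
        }
        table1_json = out / "table1.json"
        _write_json(table1_json, {"reliability_alpha": alphas})
        record("describe", [table1_tsv, table1_json], n_rows=len(table1))

        # -- estimate ---------------------------------------------------------
        net = estimate_network(analysis, cfg)
        net_json = out / "network.json"
        net.to_json(net_json)
        edges_tsv = out / "edges.tsv"
        net.edge_list(nonzero_only=True).to_csv(edges_tsv, sep="\t", index=False)
        record(
            "estimate",
            [net_json, edges_tsv],
            n_edges=net.edge_count(),
            lambda_selected=net.lambda_selected,
        )

        # -- centrality -------------------------------------------------------
        cent = centrality_table(net, analysis)
        cent_tsv = out / "centrality.tsv"
        cent.to_csv(cent_tsv, sep="\t", index_label="node")
        record("centrality", [cent_tsv],
               mean_predictability=float(cent["predictability"].mean()))

        # -- adjusted network --------------------------------------------------
        if config.adjust_covariates:
            from .cohort import NETWORK_NODES, node_to_column

            item_cols = [node_to_column(nd) for nd in NETWORK_NODES]
            covs = analysis[list(config.adjust_covariates)]
            resid = adjust_for_covariates(analysis[item_cols], covs)
            adj_net = estimate_network(resid, cfg, nodes=NETWORK_NODES)
            adj_json = out / "network_adjusted.json"
            adj_net.to_json(adj_json)
            comp = compare_networks(net, adj_net)
            comp_json = out / "adjusted_comparison.json"
            _write_json(comp_json, comp._asdict())
            record("adjust", [adj_json, comp_json],
                   covariates=list(config.adjust_covariates),
                   spearman_r=comp.spearman_r, t=comp.t)
        else:
            record("adjust", [], skipped=True)

        # -- network comparison test ------------------------------------------
        if config.nct_group and config.nct_group in analysis.columns:
            groups = analysis[config.nct_group]
            levels = sorted(pd.unique(groups))
            if len(levels) == 2:
                g1 = analysis[groups == levels[0]]
                g2 = analysis[groups == levels[1]]
                nct = network_comparison_test(
                    g1, g2,
                    permutations=config.nct_permutations,
                    seed=sub["nct"],
                    config=cfg,
                )
                nct_json = out / "nct.json"
                _write_json(nct_json, {
                    **nct.summary(),
                    "group_levels": [str(l) for l in levels],
                    "edge_diffs": nct.edge_diffs.to_dict(orient="list"),
                    "edge_p_holm": nct.edge_p_holm.tolist(),
                })
                record("compare", [nct_json],
                       groups={str(levels[0]): len(g1), str(levels[1]): len(g2)})
            else:
                record("compare", [], skipped=True,
                       reason=f"{config.nct_group} has {len(levels)} levels")
        else:
            record("compare", [], skipped=True, reason="no group variable")

        # -- stability ----------------------------------------------------------
        rep = stability_report(
            analysis,
            B_edges=config.stability_replicates,
            B_drop=config.stability_replicates,
            seed=sub["stability"],
            config=cfg,
            drop_grid=np.asarray(config.drop_grid),
        )
        stab_json = out / "stability.json"
        _write_json(stab_json, {
            **rep.summary(),
            "cs_curves": {k: v.to_dict(orient="list") for k, v in rep.cs_curves.items()},
            "edge_ci": rep.edge_bootstrap.edge_stats.to_dict(orient="list"),
        })
        record("stability", [stab_json],
               cs=rep.cs_coefficients)
    except Exception as exc:
        manifest["failed_stage"] = {
            "after_stages": list(manifest["stages"]),
            "error": f"{type(exc).__name__}: {exc}",
        }
        _write_json(out / "manifest.json", manifest)
        raise

    _write_json(out / "manifest.json", manifest)
    return manifest
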