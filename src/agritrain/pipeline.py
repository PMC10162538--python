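"""End-to-end pipeline: ingest/generate -> select -> fit -> bootstrap ->
mesh -> policy sweep -> report, under one config and one master seed.

The master seed fans out to stage seeds deterministically (one
``numpy.random.SeedSequence`` child per stage, in the fixed order
generate, split/selection, cross-validation, bootstrap), so any stage can
be rerun in isolation and identical configs give bitwise-identical CSV
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import bootstrap as bt
from . import events as ev
from . import models as md
from . import policy as pol
from . import selection as sel
from . import synthetic as syn

logger = logging.getLogger("agritrain")

_STAGES = ("generate", "selection", "cv", "bootstrap")


@dataclasses.dataclass
class PipelineConfig:
    """Pipeline settings; defaults mirror the study design (10-fold CV,
    80/20 split, B=1000 bootstrap, list sizes 100/50/10, X in 0..100
    by 10)."""

    input: str = "synthetic"            # "synthetic" or "csv"
    events_path: str | None = None
    outdir: str = "agritrain_out"
    seed: int = 0
    n_events: int = 1067
    female_zero_excess: float = 0.238
    run_selection: bool = True
    folds: int = 10
    split_fraction: float = 0.8
    b_bootstrap: int = 1000
    n_menu: tuple[int, ...] = pol.DEFAULT_N_MENU
    x_grid: tuple[int, ...] = pol.DEFAULT_X_GRID
    benchmark: dict = dataclasses.field(
        default_factory=lambda: dict(pol.DEFAULT_BENCHMARK))
    month_fix: str = "jan2019"
    recommended: tuple[int, int] = (50, 50)   # (N, X) headline scenario
    reselect_per_replicate: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.input not in ("synthetic", "csv"):
            raise ValueError("input must be 'synthetic' or 'csv'")
        if cfg.input == "csv" and not cfg.events_path:
            raise ValueError("csv input requires events_path")
        cfg.n_menu = tuple(cfg.n_menu)
        cfg.x_grid = tuple(cfg.x_grid)
        cfg.recommended = tuple(cfg.recommended)
        return cfg


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage 31-bit seeds from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(_STAGES, children)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the run report (also written
    to ``outdir/report.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    logger.info("stage seeds: %s", seeds)
    report: dict = {"config": dataclasses.asdict(config), "seeds": seeds,
                    "files": {}}

    # -- ingest / generate -------------------------------------------------
    if config.input == "csv":
        table = ev.read_events(config.events_path)
    else:
        gen = syn.GeneratorConfig(n_events=config.n_events,
                                  female_zero_excess=config.female_zero_excess,
                                  seed=seeds["generate"])
        table = syn.generate_events(gen)
    events_csv = out / "events.csv"
    ev.write_events(table, events_csv)
    report["files"]["events"] = str(events_csv)
    logger.info("ingest: %d events, %d excluded", table.n_events, table.n_excluded)

    # -- audit + descriptive summaries ------------------------------------
    audit = ev.audit_exclusions(table)
    ev.write_audit(audit, out / "audit.json")
    report["audit"] = audit
    report["files"]["audit"] = str(out / "audit.json")
    for factor in ev.FACTORS:
        summ = ev.summarize_events(table, factor)
        summ.to_csv(out / f"summary_{factor}.csv", index=False)
    report["files"]["summaries"] = [str(out / f"summary_{f}.csv")
                                    for f in ev.FACTORS]

    # -- input selection ---------------------------------------------------
    spec = sel.DesignSpec()
    if config.run_selection:
        terms = {}
        for outcome in ("males", "females"):
            res = sel.select_inputs(table, spec, outcome,
                                    seed=seeds["selection"],
                                    fraction=config.split_fraction,
                                    folds=config.folds)
            res.to_json(out / f"selection_{outcome}.json")
            terms[outcome] = tuple(res.selected_groups)
            report.setdefault("selection", {})[outcome] = {
                "chosen_method": res.chosen_method,
                "selected_groups": res.selected_groups,
                "smse": {m: r["smse"] for m, r in res.per_method.items()},
            }
            logger.info("selection %s: %s via %s", outcome,
                        res.selected_groups, res.chosen_method)
        male_terms, female_terms = terms["males"], terms["females"]
    else:
        male_terms, female_terms = md.DEFAULT_MALE_TERMS, md.DEFAULT_FEMALE_TERMS
        report["selection"] = "skipped (default terms)"

    # -- fit + bootstrap ---------------------------------------------------
    ensemble = bt.bootstrap_models(
        table, male_terms, female_terms, B=config.b_bootstrap,
        seed=seeds["bootstrap"],
        reselect_per_replicate=config.reselect_per_replicate)
    ensemble.male_model.to_json(out / "model_males.json")
    ensemble.female_model.to_json(out / "model_females.json")
    report["files"]["models"] = [str(out / "model_males.json"),
                                 str(out / "model_females.json")]
    report["dispersion"] = {"males": ensemble.male_model.dispersion,
                            "females": ensemble.female_model.dispersion}

    # -- mesh + policy sweep ----------------------------------------------
    mesh = pol.build_mesh(male_terms, female_terms, month_fix=config.month_fix)
    summary = bt.summarize_mesh(ensemble, mesh)
    summary.to_csv(out / "mesh_summary.csv", index=False)
    report["files"]["mesh_summary"] = str(out / "mesh_summary.csv")
    report["mesh_size"] = len(mesh)

    total_list = pol.rank_mesh(summary, "total")
    female_list = pol.rank_mesh(summary, "female")
    pol.top_list_table(total_list).to_csv(out / "top_total.csv", index=False)
    pol.top_list_table(female_list).to_csv(out / "top_female.csv", index=False)
    trade = pol.sweep(total_list, female_list, ensemble, mesh,
                      N_menu=config.n_menu, X_grid=config.x_grid)
    trade.to_csv(out / "tradeoff.csv", index=False)
    report["files"]["tradeoff"] = str(out / "tradeoff.csv")

    N_rec, X_rec = config.recommended
    if N_rec <= len(total_list):
        sel_rec = pol.mix_lists(total_list, female_list, N_rec, X_rec)
        scen = pol.evaluate_scenario(sel_rec, ensemble, mesh)
        flags = pol.benchmark_compare(scen, config.benchmark)
        report["recommended_scenario"] = {"N": N_rec, "X": X_rec, **scen, **flags}

    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    report["files"]["report"] = str(report_path)
    return report
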