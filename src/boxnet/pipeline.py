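"""End-to-end orchestration: simulate -> networks -> metrics -> null ->
communities -> models -> report.

Every stage writes plain-text artifacts (CSV/JSON/GraphML) into the
output directory, and the final report collects the headline summaries:
per-window node/edge counts and edge density, modularity, group counts,
movement events, and model coefficient tables with empirical p-values.
Stages are cached: a stage is skipped when its outputs exist and the
stored config hash matches, so a long randomization run can resume.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import communities as comm
from . import metrics as met
from . import models as mod
from . import networks as net
from . import permutation as perm
from . import simulate as sim
from .windows import WindowSchedule

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one full pipeline run."""

    output_dir: str = "boxnet_out"
    events_path: str | None = None      # existing event log; None -> simulate
    roster_path: str | None = None
    scenario: sim.ScenarioConfig = field(default_factory=sim.ScenarioConfig)
    seed: int = 0
    n_randomizations: int = 1000
    burn_in: int = 1000
    swaps_per_emission: int = 10
    community_objective: str = "map"
    community_restarts: int = 10
    min_group_size: int = 3
    model_responses: tuple[str, ...] = ("d_degree", "d_strength", "d_betweenness")
    model_variants: tuple[str, ...] = ("interaction",)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["scenario"] = self.scenario.to_dict()
        d["model_responses"] = list(self.model_responses)
        d["model_variants"] = list(self.model_variants)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "scenario" in d:
            d["scenario"] = sim.ScenarioConfig.from_dict(d["scenario"])
        for k in ("model_responses", "model_variants"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_inputs(
    events: pd.DataFrame, roster: sim.Roster, schedule: WindowSchedule
) -> dict:
    """Report-only validation of an event log against roster and schedule.

    Flags records with exit <= entry (named), visits by individuals
    absent from the roster (untagged; excluded from analysis), and
    visits overlapping the event gap.
    """
    report: dict = {"n_records": int(len(events)), "flags": []}
    missing_cols = [c for c in sim.EVENT_COLUMNS if c not in events.columns]
    if missing_cols:
        report["flags"].append(f"missing columns: {missing_cols}")
        return report
    bad_time = events[events["exit"] <= events["entry"]]
    for _, r in bad_time.iterrows():
        report["flags"].append(
            f"exit<=entry: {r['individual_id']} box {r['box_id']} entry={r['entry']}"
        )
    known = set(roster.ids)
    untagged = sorted(set(events["individual_id"]) - known)
    if untagged:
        report["flags"].append(f"untagged individuals excluded: {len(untagged)}")
    report["n_untagged"] = len(untagged)
    report["n_bad_time"] = int(len(bad_time))
    pre_end = max(w.end for w in schedule if w.phase == "pre")
    post_start = min(w.start for w in schedule if w.phase == "post")
    in_gap = events[(events["exit"] > pre_end) & (events["entry"] < post_start)]
    report["n_in_event_gap"] = int(len(in_gap))
    if len(in_gap):
        report["flags"].append(f"records overlapping the event gap: {len(in_gap)}")
    report["n_flags"] = len(report["flags"])
    return report


def _stage_done(out: Path, stage: str, cfg_hash: str) -> bool:
    marker = out / f".{stage}.done"
    return marker.exists() and marker.read_text().strip() == cfg_hash


def _mark_stage(out: Path, stage: str, cfg_hash: str) -> None:
    (out / f".{stage}.done").write_text(cfg_hash)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report dict (also written as JSON)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    config.to_yaml(out / "config.yaml")

    # -- data ------------------------------------------------------------
    scenario_cfg = sim.replace(config.scenario, seed=config.scenario.seed or config.seed)
    schedule = scenario_cfg.schedule()
    if config.events_path:
        events = sim.read_events(config.events_path)
        if not config.roster_path:
            raise ValueError("roster_path required when events_path is given")
        roster = sim.read_roster(config.roster_path)
    else:
        if not _stage_done(out, "simulate", h) or not (out / "events.csv").exists():
            scenario = sim.simulate_scenario(scenario_cfg)
            sim.write_events(scenario.events, out / "events.csv")
            sim.write_roster(scenario.roster, out / "roster.csv")
            _mark_stage(out, "simulate", h)
        events = sim.read_events(out / "events.csv")
        roster = sim.read_roster(out / "roster.csv")
    schedule.to_json(out / "schedule.json")

    known = set(roster.ids)
    untagged = set(events["individual_id"]) - known
    validation = validate_inputs(events, roster, schedule)
    (out / "validation.json").write_text(json.dumps(validation, indent=2))
    if untagged:
        events = events[events["individual_id"].isin(known)]

    # -- networks ----------------------------------------------------------
    full, surv = net.make_stacks(events, schedule, roster)
    nets_dir = out / "networks"
    nets_dir.mkdir(exist_ok=True)
    for idx in full.indices:
        net.write_edge_list(full[idx], nets_dir / f"full_w{idx}.csv")
        net.write_graphml(full[idx], nets_dir / f"full_w{idx}.graphml")
        net.write_edge_list(surv[idx], nets_dir / f"survivor_w{idx}.csv")

    missing = roster.missing
    baseline = schedule.last_pre_index
    attrs = net.loss_attributes(full[baseline], missing)
    attrs.to_csv(out / "loss_attributes.csv")

    # -- metrics -----------------------------------------------------------
    metrics_frames = [met.node_metrics(full[i]).reset_index() for i in full.indices]
    pd.concat(metrics_frames, ignore_index=True).to_csv(out / "node_metrics_full.csv", index=False)
    delta = met.delta_from_baseline(surv)
    delta.to_csv(out / "delta_table.csv", index=False)

    # -- communities -------------------------------------------------------
    partitions = [
        comm.detect_communities(
            full[i], config.community_objective, config.community_restarts, config.seed
        )
        for i in full.indices
    ]
    node_sections = {
        i: dict(full[i].nodes(data="section")) for i in full.indices
    }
    dcm = comm.link_windows(partitions, node_sections)
    part_rows = []
    for p in partitions:
        for n, c in sorted(p.membership.items()):
            part_rows.append(
                {"window": p.window, "individual_id": n, "community": c,
                 "persistent_id": dcm.membership[p.window][n]}
            )
    pd.DataFrame(part_rows).to_csv(out / "communities.csv", index=False)
    moves = comm.movement_summary(dcm)
    moves.to_csv(out / "movement_events.csv", index=False)
    comm.alluvial_table(dcm).to_csv(out / "alluvial.csv", index=False)

    group_stats_by_window = {
        p.window: met.group_stats(
            full[p.window],
            {n: dcm.membership[p.window][n] for n in full[p.window].nodes},
            missing,
        )
        for p in partitions
    }

    # -- models with permutation null -------------------------------------
    table = mod.build_response_table(delta, attrs)
    table = table[table["individual_id"].isin(surv.common_nodes)]
    table.to_csv(out / "response_table.csv", index=False)
    chain = perm.generate_swap_chain(
        sorted(set(table["individual_id"])),
        burn_in=config.burn_in,
        swaps_per_emission=config.swaps_per_emission,
        n_emissions=config.n_randomizations,
        seed=config.seed,
    )
    perm_rows = [
        {"emission": r, "identity": i, "position": p}
        for r, pm in chain.permutations()
        for i, p in sorted(pm.items())
    ] if len(chain.pool) <= 50 else []  # full table only for small pools
    if perm_rows:
        pd.DataFrame(perm_rows).to_csv(out / "permutations.csv", index=False)

    model_tables = {}
    for response in config.model_responses:
        for variant in config.model_variants:
            spec = mod.ModelSpec(response=response, variant=variant)
            res, _ = mod.permutation_effect_test(table, spec, chain)
            tab = res.coefficient_table()
            name = f"model_{response}_{variant}"
            tab.to_csv(out / f"{name}.csv")
            model_tables[name] = {
                "converged": res.converged,
                "coefficients": {
                    term: {
                        "estimate": float(row["estimate"]),
                        "lower": float(row["lower"]),
                        "upper": float(row["upper"]),
                        "empirical_p": float(row.get("empirical_p", np.nan)),
                    }
                    for term, row in tab.iterrows()
                },
            }

    # -- report ------------------------------------------------------------
    report = {
        "provenance": {
            "config_hash": h,
            "seed": config.seed,
            "n_randomizations": config.n_randomizations,
        },
        "validation": {k: validation[k] for k in ("n_records", "n_flags")},
        "windows": {
            str(i): {
                "phase": schedule[i].phase,
                "nodes_full": full[i].number_of_nodes(),
                "edges_full": full[i].number_of_edges(),
                "edge_density_full": met.edge_density(full[i]),
                "edge_density_survivor": met.edge_density(surv[i]),
                "modularity": met.modularity(
                    full[i], {n: dcm.membership[i][n] for n in full[i].nodes}
                ),
                "groups_min_size": comm.count_groups(
                    partitions[full.indices.index(i)], config.min_group_size
                ),
            }
            for i in full.indices
        },
        "survivors": len(surv.common_nodes),
        "missing": len(missing),
        "movement_events": moves.to_dict(orient="records"),
        "models": model_tables,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
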