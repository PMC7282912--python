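"""Duration-based association networks from nest-box visit logs.

Edges are simple ratio indices (SRI) on co-occupancy durations: for a dyad
(i, j), ``x_ij`` is the total time the two spent simultaneously inside the
same box during a window, ``t_i`` the total time i spent inside any box,
and

    SRI_ij = x_ij / (t_i + t_j - x_ij)

i.e. shared time over the union of the two individuals' in-box time — the
duration analogue of the standard simple ratio index.  The denominator
variant is isolated in :func:`simple_ratio_index` so alternatives can be
swapped in.  Time intervals are half-open ``[entry, exit)`` in seconds;
visits that merely touch contribute zero overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .simulate import EVENT_COLUMNS, Roster
from .windows import TimeWindow, WindowSchedule

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised for malformed visit records."""


def validate_events(events: pd.DataFrame) -> None:
    """Check the event-log schema and that every visit has exit > entry."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"event log lacks columns: {missing}")
    bad = events[events["exit"] <= events["entry"]]
    if len(bad):
        r = bad.iloc[0]
        raise ValidationError(
            f"visit with exit <= entry: individual {r['individual_id']} in box "
            f"{r['box_id']} at entry={r['entry']}, exit={r['exit']}"
        )


def clip_to_window(events: pd.DataFrame, window: TimeWindow) -> pd.DataFrame:
    """Restrict visits to ``[window.start, window.end)``, dropping empties."""
    e = events.copy()
    e["entry"] = e["entry"].clip(lower=window.start)
    e["exit"] = e["exit"].clip(upper=window.end)
    return e[e["exit"] > e["entry"]].reset_index(drop=True)


def cooccupancy_durations(
    events: pd.DataFrame, window: TimeWindow
) -> tuple[dict[tuple[str, str], float], dict[str, float]]:
    """Dyadic same-box overlap seconds and per-individual in-box totals.

    Returns ``(x, t)`` where ``x[(i, j)]`` (keys with ``i < j``) is the
    total time i and j were simultaneously inside the same box and
    ``t[i]`` is i's total time inside any box, both clipped to the window.
    Computed with a sweep over box-occupancy change points, so an
    individual present in a box for several separate visits accumulates
    every intersection.
    """
    validate_events(events)
    e = clip_to_window(events, window)
    totals: dict[str, float] = {}
    pair: dict[tuple[str, str], float] = {}
    if not len(e):
        return pair, totals

    for i, d in zip(e["individual_id"], (e["exit"] - e["entry"])):
        totals[i] = totals.get(i, 0.0) + float(d)

    for _, box_events in e.groupby("box_id", sort=False):
        starts = box_events["entry"].to_numpy(dtype=float)
        ends = box_events["exit"].to_numpy(dtype=float)
        ids = box_events["individual_id"].to_numpy()
        # sweep: +1 at entry, -1 at exit, accumulating pairwise shared time
        times = np.concatenate([starts, ends])
        deltas = np.concatenate([np.ones(len(starts)), -np.ones(len(ends))])
        who = np.concatenate([ids, ids])
        order = np.lexsort((deltas, times))  # process exits before entries at ties
        occupants: dict[str, int] = {}
        prev_t = None
        for k in order:
            t_k = times[k]
            if prev_t is not None and t_k > prev_t and len(occupants) > 1:
                seg = t_k - prev_t
                present = list(occupants)
                for a_i in range(len(present)):
                    for b_i in range(a_i + 1, len(present)):
                        a, b = present[a_i], present[b_i]
                        key = (a, b) if a < b else (b, a)
                        pair[key] = pair.get(key, 0.0) + seg
            prev_t = t_k
            w = who[k]
            if deltas[k] > 0:
                occupants[w] = occupants.get(w, 0) + 1
            else:
                occupants[w] -= 1
                if occupants[w] == 0:
                    del occupants[w]
    return pair, totals


def simple_ratio_index(x_ij: float, t_i: float, t_j: float) -> float:
    """SRI on durations: shared time over the union of in-box time."""
    if x_ij < 0 or x_ij > min(t_i, t_j) + 1e-9:
        raise ValueError("overlap exceeds an individual's total in-box time")
    denom = t_i + t_j - x_ij
    if denom <= 0:
        raise ValueError("SRI undefined when both totals are zero")
    return x_ij / denom


def build_network(
    events: pd.DataFrame,
    window: TimeWindow,
    roster: Roster | None = None,
) -> nx.Graph:
    """Weighted association network for one window.

    Nodes are individuals with at least one (positive-length) visit in the
    window; edges carry SRI weights for every dyad with positive shared
    time.  Node attributes ``sex``, ``fate``, ``home_group`` come from the
    roster when given; ``section`` is each individual's majority-use
    section within the window.
    """
    x, t = cooccupancy_durations(events, window)
    g = nx.Graph(window=window.index, phase=window.phase)
    if not t:
        logger.warning("window %s: no visits; empty network", window.index)
        return g
    g.add_nodes_from(t)
    for (i, j), overlap in x.items():
        w = simple_ratio_index(overlap, t[i], t[j])
        if w > 0:
            g.add_edge(i, j, weight=w)

    e = clip_to_window(events, window)
    e = e.assign(dur=e["exit"] - e["entry"])
    sec_use = e.groupby(["individual_id", "section"])["dur"].sum()
    majority_section = {
        ind: int(grp.idxmax()[1]) for ind, grp in sec_use.groupby(level=0)
    }
    nx.set_node_attributes(g, majority_section, "section")
    nx.set_node_attributes(g, t, "time_in_box")
    if roster is not None:
        tab = roster.table.set_index("individual_id")
        for attr in ("sex", "fate", "home_group"):
            nx.set_node_attributes(
                g, {n: tab.at[n, attr] for n in g.nodes if n in tab.index}, attr
            )
    return g


@dataclass
class NetworkStack:
    """Ordered per-window networks over a common schedule.

    ``restriction`` is ``"full"`` (all recorded individuals per window) or
    ``"survivor_only"`` (node sets restricted to individuals present in
    every window).  ``baseline_index`` is the window used as the baseline
    for change scores (default: last pre-event window).
    """

    networks: dict[int, nx.Graph]
    schedule: WindowSchedule
    restriction: str = "full"
    baseline_index: int | None = None

    def __post_init__(self) -> None:
        if self.baseline_index is None:
            self.baseline_index = self.schedule.last_pre_index

    @property
    def indices(self) -> list[int]:
        return sorted(self.networks)

    def __getitem__(self, index: int) -> nx.Graph:
        return self.networks[index]

    @property
    def common_nodes(self) -> set[str]:
        sets = [set(g.nodes) for g in self.networks.values()]
        return set.intersection(*sets) if sets else set()


def make_stacks(
    events: pd.DataFrame,
    schedule: WindowSchedule,
    roster: Roster | None = None,
) -> tuple[NetworkStack, NetworkStack]:
    """Build the full and survivor-restricted network stacks.

    The survivor stack keeps only individuals present (>= 1 visit) in
    every window; its networks are node-induced subgraphs of the full
    networks, so retained edges keep their full-network SRI exactly.
    """
    full = {
        w.index: build_network(events, w, roster) for w in schedule
    }
    common = set.intersection(*[set(g.nodes) for g in full.values()]) if full else set()
    survivor = {
        idx: nx.Graph(g.subgraph(common).copy(), window=idx, phase=g.graph["phase"])
        for idx, g in full.items()
    }
    return (
        NetworkStack(full, schedule, restriction="full"),
        NetworkStack(survivor, schedule, restriction="survivor_only"),
    )


def loss_attributes(
    pre_event_network: nx.Graph, missing_ids: Iterable[str]
) -> pd.DataFrame:
    """Per-individual pre-event sociality and proportion of strength lost.

    For each non-missing node of the full pre-event network, returns its
    pre-event weighted degree ``s_pre`` and the loss proportion
    ``l = (sum of SRI to missing associates) / s_pre``.  Individuals with
    zero pre-event strength get ``loss_proportion = NaN`` and
    ``undefined=True``.
    """
    missing = set(missing_ids)
    unknown = missing - set(pre_event_network.nodes)
    if unknown:
        logger.info("%d missing ids absent from the pre-event network", len(unknown))
    rows = []
    for n in pre_event_network.nodes:
        if n in missing:
            continue
        s = 0.0
        s_missing = 0.0
        for _, j, w in pre_event_network.edges(n, data="weight"):
            s += w
            if j in missing:
                s_missing += w
        if s > 0:
            rows.append((n, s, s_missing / s, False))
        else:
            rows.append((n, 0.0, np.nan, True))
    df = pd.DataFrame(rows, columns=["individual_id", "pre_event_sociality",
                                     "loss_proportion", "undefined"])
    return df.set_index("individual_id")


# ---------------------------------------------------------------------------
# I/O


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    rows = [(min(i, j), max(i, j), w) for i, j, w in g.edges(data="weight")]
    pd.DataFrame(sorted(rows), columns=["id_i", "id_j", "sri"]).to_csv(path, index=False)


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, path)
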