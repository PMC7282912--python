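"""Community detection and dynamic community tracking.

Each window's network is partitioned into social groups by greedy
local-move optimization (node moves plus community aggregation passes,
repeated to convergence, best of ``restarts`` seeded restarts) of either
the two-level map-equation codelength (default; flow-based, in bits) or
weighted Newman modularity.

Partitions of consecutive windows are linked into *dynamic communities*
by reciprocal majority identification: community X at window t and Y at
window t+1 share a persistent identity iff Y contains a strict majority
of X's members and X contributes a strict majority of Y's members.
Communities without a reciprocal-majority parent receive fresh persistent
ids.  Movement events are occasions where one or more individuals change
persistent community between consecutive windows, grouped by
(source, destination); an event is cross-section when the two
communities' modal barn sections differ.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd


def _plogp(x: float) -> float:
    return x * np.log2(x) if x > 0 else 0.0


def map_codelength(network: nx.Graph, partition: Mapping[Hashable, Hashable]) -> float:
    """Two-level map-equation codelength (bits) of a partition.

    Node visit rates are strength-proportional (undirected flow); the
    codelength is the expected description length per step of a random
    walk under a two-level (index plus per-module) codebook.
    """
    strength = dict(network.degree(weight="weight"))
    two_w = sum(strength.values())
    if two_w <= 0:
        return 0.0
    modules: dict[Hashable, set] = {}
    for n in network.nodes:
        modules.setdefault(partition[n], set()).add(n)
    node_term = -sum(_plogp(strength[n] / two_w) for n in network.nodes)
    q_total = 0.0
    q_term = 0.0
    mod_term = 0.0
    for mem in modules.values():
        s_m = sum(strength[n] for n in mem)
        w_in = sum(
            w for i, j, w in network.edges(mem, data="weight") if i in mem and j in mem
        )
        q_m = (s_m - 2.0 * w_in) / two_w
        q_total += q_m
        q_term += _plogp(q_m)
        mod_term += _plogp(q_m + s_m / two_w)
    return _plogp(q_total) - 2.0 * q_term + node_term + mod_term


@dataclass
class Partition:
    """A window-local node partition with its objective value."""

    window: int | None
    membership: dict[Hashable, int]
    objective: str = "map"
    value: float = float("nan")

    @property
    def communities(self) -> dict[int, set]:
        out: dict[int, set] = {}
        for n, c in self.membership.items():
            out.setdefault(c, set()).add(n)
        return out

    def relabel(self) -> "Partition":
        """Renumber communities 0..k-1 by decreasing size (ties by member name)."""
        comms = sorted(
            self.communities.items(),
            key=lambda kv: (-len(kv[1]), min(str(n) for n in kv[1])),
        )
        mapping = {old: new for new, (old, _) in enumerate(comms)}
        return Partition(
            self.window,
            {n: mapping[c] for n, c in self.membership.items()},
            self.objective,
            self.value,
        )


class _Level:
    """One aggregation level of the greedy optimizer."""

    def __init__(self, adj: list[dict[int, float]], self_w: np.ndarray):
        self.adj = adj              # neighbour -> weight, no self entries
        self.self_w = self_w        # aggregated internal (self-loop) weight
        self.n = len(adj)
        self.strength = np.array(
            [sum(a.values()) for a in adj], dtype=float
        ) + 2.0 * self_w


def _local_moves(
    level: _Level, objective: str, two_w: float, rng: np.random.Generator,
    max_sweeps: int = 50,
) -> np.ndarray:
    """Greedy single-node moves until no move improves the objective."""
    n = level.n
    comm = np.arange(n)
    s_c = level.strength.copy()
    w_in = level.self_w.copy()
    q_sum = float(np.sum(s_c - 2.0 * w_in)) / two_w

    def module_term(s: float, w: float) -> float:
        q = (s - 2.0 * w) / two_w
        return -2.0 * _plogp(q) + _plogp(q + s / two_w)

    improved = True
    sweeps = 0
    while improved and sweeps < max_sweeps:
        improved = False
        sweeps += 1
        for v in rng.permutation(n):
            s_v = level.strength[v]
            if s_v <= 0:
                continue
            a = comm[v]
            k_to: dict[int, float] = {}
            for u, w in level.adj[v].items():
                cu = comm[u]
                k_to[cu] = k_to.get(cu, 0.0) + w
            k_to.setdefault(a, 0.0)
            candidates = [c for c in k_to if c != a]
            if not candidates:
                continue
            s_a1 = s_c[a] - s_v
            w_a1 = w_in[a] - k_to[a] - level.self_w[v]
            best_c, best_gain = a, 0.0
            if objective == "modularity":
                for c in candidates:
                    gain = 2.0 * (k_to[c] - k_to[a]) / two_w - 2.0 * s_v * (
                        s_c[c] - s_a1
                    ) / (two_w * two_w)
                    if gain > best_gain + 1e-12:
                        best_gain, best_c = gain, c
            else:
                q_a0 = (s_c[a] - 2.0 * w_in[a]) / two_w
                q_a1 = (s_a1 - 2.0 * w_a1) / two_w
                before_a = module_term(s_c[a], w_in[a])
                after_a = module_term(s_a1, w_a1)
                for c in candidates:
                    s_c1 = s_c[c] + s_v
                    w_c1 = w_in[c] + k_to[c] + level.self_w[v]
                    q_c0 = (s_c[c] - 2.0 * w_in[c]) / two_w
                    q_c1 = (s_c1 - 2.0 * w_c1) / two_w
                    dq = q_a1 + q_c1 - q_a0 - q_c0
                    delta = (
                        after_a
                        - before_a
                        + module_term(s_c1, w_c1)
                        - module_term(s_c[c], w_in[c])
                        + _plogp(q_sum + dq)
                        - _plogp(q_sum)
                    )
                    # lower codelength is better: store as positive gain
                    if -delta > best_gain + 1e-12:
                        best_gain, best_c = -delta, c
            if best_c != a:
                c = best_c
                q_before = (s_c[a] - 2 * w_in[a]) / two_w + (s_c[c] - 2 * w_in[c]) / two_w
                s_c[a] -= s_v
                s_c[c] += s_v
                w_in[a] -= k_to[a] + level.self_w[v]
                w_in[c] += k_to[c] + level.self_w[v]
                q_after = (s_c[a] - 2 * w_in[a]) / two_w + (s_c[c] - 2 * w_in[c]) / two_w
                q_sum += q_after - q_before
                comm[v] = c
                improved = True
    return comm


def _aggregate(level: _Level, comm: np.ndarray) -> tuple[_Level, np.ndarray]:
    """Collapse communities to super-nodes; returns (new level, old->new map)."""
    _, inverse = np.unique(comm, return_inverse=True)
    k = int(inverse.max()) + 1
    adj: list[dict[int, float]] = [dict() for _ in range(k)]
    self_w = np.zeros(k)
    for v in range(level.n):
        cv = int(inverse[v])
        self_w[cv] += level.self_w[v]
        for u, w in level.adj[v].items():
            if u <= v:
                continue
            cu = int(inverse[u])
            if cu == cv:
                self_w[cv] += w
            else:
                adj[cv][cu] = adj[cv].get(cu, 0.0) + w
                adj[cu][cv] = adj[cu].get(cv, 0.0) + w
    return _Level(adj, self_w), inverse


def detect_communities(
    network: nx.Graph,
    objective: str = "map",
    restarts: int = 10,
    seed: int = 0,
) -> Partition:
    """Partition a network into social groups.

    Greedy local moves plus aggregation passes, repeated until the
    aggregate no longer shrinks, taking the best of ``restarts`` seeded
    restarts.  ``objective`` is ``"map"`` (minimize two-level map-equation
    codelength, default) or ``"modularity"`` (maximize weighted Q).
    Isolated nodes become singleton communities; an empty network yields
    an empty partition.
    """
    if objective not in ("map", "modularity"):
        raise ValueError("objective must be 'map' or 'modularity'")
    nodes = list(network.nodes)
    window = network.graph.get("window")
    if not nodes:
        return Partition(window, {}, objective, 0.0)
    index = {n: i for i, n in enumerate(nodes)}
    adj0: list[dict[int, float]] = [dict() for _ in nodes]
    for i, j, w in network.edges(data="weight", default=1.0):
        if i == j:
            continue
        a, b = index[i], index[j]
        adj0[a][b] = adj0[a].get(b, 0.0) + w
        adj0[b][a] = adj0[b].get(a, 0.0) + w
    two_w = sum(sum(a.values()) for a in adj0)
    if two_w <= 0:
        return Partition(
            window, {n: i for i, n in enumerate(nodes)}, objective, 0.0
        ).relabel()

    from .metrics import modularity as q_of

    best: Partition | None = None
    for r in range(restarts):
        rng = np.random.default_rng([seed, r])
        level = _Level([dict(a) for a in adj0], np.zeros(len(nodes)))
        assignment = np.arange(len(nodes))
        while True:
            comm = _local_moves(level, objective, two_w, rng)
            new_level, inverse = _aggregate(level, comm)
            assignment = inverse[assignment]
            if new_level.n == level.n:
                break
            level = new_level
        membership = {n: int(assignment[index[n]]) for n in nodes}
        value = (
            q_of(network, membership)
            if objective == "modularity"
            else map_codelength(network, membership)
        )
        part = Partition(window, membership, objective, value)
        better = (
            best is None
            or (objective == "modularity" and value > best.value + 1e-12)
            or (objective == "map" and value < best.value - 1e-12)
        )
        if better:
            best = part
    return best.relabel()


# ---------------------------------------------------------------------------
# dynamic tracking


@dataclass
class DynamicCommunityMap:
    """Window partitions linked into persistent community identities."""

    windows: list[int]
    membership: dict[int, dict[Hashable, str]]      # window -> individual -> pid
    sections: dict[int, dict[str, int | None]] = field(default_factory=dict)
    links: list[tuple[int, int, str, str]] = field(default_factory=list)

    def members(self, window: int, pid: str) -> set:
        return {n for n, p in self.membership[window].items() if p == pid}

    def pids(self, window: int) -> set[str]:
        return set(self.membership[window].values())


def _community_sections(
    partition: Partition, node_sections: Mapping[Hashable, int] | None
) -> dict[int, int | None]:
    out: dict[int, int | None] = {}
    for label, mem in partition.communities.items():
        votes = Counter(
            node_sections[n]
            for n in mem
            if node_sections and node_sections.get(n) is not None
        )
        out[label] = votes.most_common(1)[0][0] if votes else None
    return out


def link_windows(
    partitions: Sequence[Partition],
    node_sections: Mapping[int, Mapping[Hashable, int]] | None = None,
) -> DynamicCommunityMap:
    """Link consecutive partitions by reciprocal majority identification.

    X (window t) and Y (window t+1) share a persistent id iff
    ``|X ∩ Y| > |X|/2`` and ``|X ∩ Y| > |Y|/2`` (strict majorities; ties
    break to no link, so an even split never links).  Persistent ids are
    seeded on the earliest (pre-event) windows and propagated forward;
    unlinked communities receive fresh ids.  ``node_sections`` optionally
    maps window -> node -> barn section for the cross-section flag.
    """
    if len(partitions) < 2:
        raise ValueError("need at least two windows to link")
    counter = itertools.count(1)
    dcm = DynamicCommunityMap(windows=[p.window for p in partitions], membership={})

    def fresh() -> str:
        return f"C{next(counter):03d}"

    first = partitions[0]
    pids = {
        label: fresh()
        for label in sorted(
            first.communities,
            key=lambda c: (-len(first.communities[c]), str(c)),
        )
    }
    dcm.membership[first.window] = {n: pids[c] for n, c in first.membership.items()}
    dcm.sections[first.window] = {
        pids[l]: s
        for l, s in _community_sections(first, (node_sections or {}).get(first.window)).items()
    }

    prev, prev_pids = first, pids
    for cur in partitions[1:]:
        prev_comms = prev.communities
        cur_pids: dict[Hashable, str] = {}
        for y_label, y_mem in cur.communities.items():
            parent = None
            for x_label, x_mem in prev_comms.items():
                inter = len(x_mem & y_mem)
                if inter * 2 > len(x_mem) and inter * 2 > len(y_mem):
                    parent = x_label
                    break
            if parent is not None:
                pid = prev_pids[parent]
                dcm.links.append((prev.window, cur.window, pid, pid))
            else:
                pid = fresh()
            cur_pids[y_label] = pid
        dcm.membership[cur.window] = {n: cur_pids[c] for n, c in cur.membership.items()}
        dcm.sections[cur.window] = {
            cur_pids[l]: s
            for l, s in _community_sections(cur, (node_sections or {}).get(cur.window)).items()
        }
        prev, prev_pids = cur, cur_pids
    return dcm


def movement_events(
    dcm: DynamicCommunityMap, window_pair: tuple[int, int]
) -> pd.DataFrame:
    """Movement events between two consecutive windows.

    One row per (source pid, destination pid) pair with at least one
    mover: the mover ids, their count, and a flag for moves between
    communities whose modal barn sections differ.
    """
    t0, t1 = window_pair
    m0, m1 = dcm.membership[t0], dcm.membership[t1]
    movers: dict[tuple[str, str], list] = {}
    for n in set(m0) & set(m1):
        if m0[n] != m1[n]:
            movers.setdefault((m0[n], m1[n]), []).append(n)
    sec0 = dcm.sections.get(t0, {})
    sec1 = dcm.sections.get(t1, {})
    rows = []
    for (src, dst), ids in sorted(movers.items()):
        s0, s1 = sec0.get(src), sec1.get(dst)
        rows.append(
            {
                "window_from": t0,
                "window_to": t1,
                "source": src,
                "destination": dst,
                "n_movers": len(ids),
                "movers": ",".join(sorted(map(str, ids))),
                "cross_section": bool(s0 is not None and s1 is not None and s0 != s1),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["window_from", "window_to", "source", "destination",
                 "n_movers", "movers", "cross_section"],
    )


def movement_summary(dcm: DynamicCommunityMap) -> pd.DataFrame:
    """Per window pair: event count, mover-count range, cross-section count."""
    rows = []
    for t0, t1 in zip(dcm.windows, dcm.windows[1:]):
        ev = movement_events(dcm, (t0, t1))
        rows.append(
            {
                "window_from": t0,
                "window_to": t1,
                "n_events": len(ev),
                "min_movers": int(ev["n_movers"].min()) if len(ev) else 0,
                "max_movers": int(ev["n_movers"].max()) if len(ev) else 0,
                "n_cross_section": int(ev["cross_section"].sum()) if len(ev) else 0,
            }
        )
    return pd.DataFrame(rows)


def count_groups(partition: Partition, min_size: int = 3) -> int:
    """Number of communities with at least ``min_size`` members."""
    return sum(1 for mem in partition.communities.values() if len(mem) >= min_size)


def alluvial_table(dcm: DynamicCommunityMap) -> pd.DataFrame:
    """Long-format flow table sufficient to draw an alluvial diagram.

    One row per (window pair, source pid, destination pid) counting the
    individuals present in both windows, so flows out of a community sum
    to its persisting membership.
    """
    rows = []
    for t0, t1 in zip(dcm.windows, dcm.windows[1:]):
        m0, m1 = dcm.membership[t0], dcm.membership[t1]
        flows: Counter = Counter()
        for n in set(m0) & set(m1):
            flows[(m0[n], m1[n])] += 1
        for (src, dst), n in sorted(flows.items()):
            rows.append(
                {"window_from": t0, "window_to": t1, "source": src,
                 "destination": dst, "n": n}
            )
    return pd.DataFrame(rows, columns=["window_from", "window_to", "source",
                                       "destination", "n"])
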