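"""Individual- and group-level network statistics.

Degree (number of partners), strength (sum of SRI weights) and weighted
betweenness are the individual statistics; change scores are taken
relative to the survivor stack's baseline window (the window immediately
before the event).  For betweenness, a strong association means a short
path: edge distance is the reciprocal of the SRI weight, and tied
geodesics contribute fractionally (Brandes accounting).  Betweenness is
left unnormalized, which is scale-consistent across the equal-sized
windows of a survivor stack.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .networks import NetworkStack

METRICS = ["degree", "strength", "betweenness"]


def node_metrics(network: nx.Graph) -> pd.DataFrame:
    """Degree, strength and weighted betweenness per node.

    Isolated nodes get zeros.  Returns a frame indexed by individual with
    columns ``degree``, ``strength``, ``betweenness`` and the window index.
    """
    nodes = list(network.nodes)
    deg = dict(network.degree)
    strength = dict(network.degree(weight="weight"))
    for i, j, w in network.edges(data="weight"):
        network.edges[i, j]["distance"] = 1.0 / w
    btw = nx.betweenness_centrality(network, weight="distance", normalized=False)
    df = pd.DataFrame(
        {
            "degree": [deg[n] for n in nodes],
            "strength": [float(strength[n]) for n in nodes],
            "betweenness": [float(btw[n]) for n in nodes],
        },
        index=pd.Index(nodes, name="individual_id"),
    )
    df.insert(0, "window", network.graph.get("window"))
    return df


def delta_from_baseline(stack: NetworkStack) -> pd.DataFrame:
    """Change in each metric relative to the baseline window.

    Rows cover every survivor-stack window except the baseline itself
    (with the default schedule: the first pre-event window plus all
    post-event windows), one row per individual and window, with columns
    ``d_degree``, ``d_strength``, ``d_betweenness``.
    """
    if stack.restriction != "survivor_only":
        raise ValueError("change scores are defined on the survivor stack")
    base = node_metrics(stack[stack.baseline_index])
    frames = []
    for idx in stack.indices:
        if idx == stack.baseline_index:
            continue
        cur = node_metrics(stack[idx])
        if set(cur.index) != set(base.index):
            raise RuntimeError(
                "survivor stack windows disagree on node sets; stack invariant broken"
            )
        cur = cur.reindex(base.index)
        out = pd.DataFrame(index=base.index)
        out["window"] = idx
        out["phase"] = stack.schedule[idx].phase
        for m in METRICS:
            out[f"d_{m}"] = cur[m] - base[m]
        frames.append(out.reset_index())
    if not frames:
        raise ValueError("survivor stack has no non-baseline windows")
    return pd.concat(frames, ignore_index=True)


def edge_density(network: nx.Graph) -> float:
    """Fraction of dyads with a positive-weight edge; NaN below 2 nodes."""
    n = network.number_of_nodes()
    if n < 2:
        return float("nan")
    return network.number_of_edges() / (n * (n - 1) / 2)


def modularity(network: nx.Graph, partition: Mapping[Hashable, Hashable]) -> float:
    """Weighted Newman modularity of a node partition.

    ``Q = sum_c (W_c / W - (S_c / 2W)^2)`` with W the total edge weight,
    W_c the within-community weight and S_c the community strength sum.
    """
    missing = set(network.nodes) - set(partition)
    if missing:
        raise ValueError(f"partition misses {len(missing)} nodes")
    communities: dict[Hashable, set] = {}
    for n in network.nodes:
        communities.setdefault(partition[n], set()).add(n)
    return nx.algorithms.community.modularity(
        network, communities.values(), weight="weight"
    )


def group_stats(
    network: nx.Graph,
    partition: Mapping[Hashable, Hashable],
    missing_ids: Iterable[str] = (),
    baseline_sizes: Mapping[Hashable, int] | None = None,
) -> pd.DataFrame:
    """Per-community size, within-community edge density and loss.

    ``within_density`` is the fraction of realised member dyads (NaN for
    communities below two members).  ``prop_missing`` is the share of
    members in ``missing_ids``; ``pre_size`` joins baseline community
    sizes when provided.
    """
    missing = set(missing_ids)
    members: dict[Hashable, list] = {}
    for n in network.nodes:
        members.setdefault(partition[n], []).append(n)
    rows = []
    for label, mem in sorted(members.items(), key=lambda kv: str(kv[0])):
        n_c = len(mem)
        if n_c >= 2:
            sub = network.subgraph(mem)
            rho = sub.number_of_edges() / (n_c * (n_c - 1) / 2)
        else:
            rho = np.nan
        rows.append(
            {
                "community": label,
                "window": network.graph.get("window"),
                "size": n_c,
                "within_density": rho,
                "prop_missing": sum(1 for m in mem if m in missing) / n_c,
                "pre_size": (baseline_sizes or {}).get(label, np.nan),
            }
        )
    return pd.DataFrame(rows)
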