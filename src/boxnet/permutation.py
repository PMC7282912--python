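"""Synchronized node-swap permutation null.

Randomized network stacks are produced by a Markov chain of node-identity
swaps: each step exchanges the identities of two individuals drawn
uniformly at random, randomizing who occupies which network position
while preserving the topology and weights of every window exactly.  The
same cumulative swap state is applied to every window of a stack, so a
pair swapped in one timestep is swapped in all timesteps.  The default
schedule is a burn-in of 1000 swaps followed by 1000 emissions 10 swaps
apart (11 000 swaps in total).

Observed model effects are compared to the randomized distribution with a
two-sided add-one empirical p-value:

    p = (1 + #{r : |beta_r| >= |beta_obs|}) / (1 + R)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import networkx as nx
import numpy as np

from .networks import NetworkStack


@dataclass(frozen=True)
class SwapChain:
    """A reproducible chain of identity transpositions.

    ``swaps`` holds every transposition as an (id, id) pair; emission
    ``r`` (0-based) corresponds to the cumulative permutation after
    ``burn_in + (r + 1) * swaps_per_emission`` transpositions.
    """

    pool: tuple[str, ...]
    burn_in: int = 1000
    swaps_per_emission: int = 10
    n_emissions: int = 1000
    seed: int = 0
    swaps: tuple[tuple[str, str], ...] = field(default=(), repr=False)

    @property
    def total_swaps(self) -> int:
        return self.burn_in + self.swaps_per_emission * self.n_emissions

    def permutation_at(self, emission: int) -> dict[str, str]:
        """Identity -> occupied position after the given emission."""
        if not (0 <= emission < self.n_emissions):
            raise IndexError(f"emission {emission} outside 0..{self.n_emissions - 1}")
        upto = self.burn_in + (emission + 1) * self.swaps_per_emission
        perm = {i: i for i in self.pool}
        for a, b in self.swaps[:upto]:
            perm[a], perm[b] = perm[b], perm[a]
        return perm

    def permutations(self) -> Iterator[tuple[int, dict[str, str]]]:
        """Iterate (emission, identity->position) maps incrementally."""
        perm = {i: i for i in self.pool}
        k = 0
        for a, b in self.swaps[: self.burn_in]:
            perm[a], perm[b] = perm[b], perm[a]
            k += 1
        for r in range(self.n_emissions):
            stop = self.burn_in + (r + 1) * self.swaps_per_emission
            for a, b in self.swaps[k:stop]:
                perm[a], perm[b] = perm[b], perm[a]
            k = stop
            yield r, dict(perm)


def generate_swap_chain(
    pool: Sequence[str],
    burn_in: int = 1000,
    swaps_per_emission: int = 10,
    n_emissions: int = 1000,
    seed: int = 0,
) -> SwapChain:
    """Draw the full transposition sequence for a swap chain.

    Each swap picks two distinct identities uniformly; pairs may repeat
    across the chain (Markov-chain usage of node-swap nulls).
    """
    pool = tuple(pool)
    if len(pool) < 2:
        raise ValueError("swap pool needs at least two identities")
    total = burn_in + swaps_per_emission * n_emissions
    rng = np.random.default_rng(seed)
    idx = np.empty((total, 2), dtype=int)
    for k in range(total):
        idx[k] = rng.choice(len(pool), size=2, replace=False)
    swaps = tuple((pool[a], pool[b]) for a, b in idx)
    return SwapChain(
        pool=pool,
        burn_in=burn_in,
        swaps_per_emission=swaps_per_emission,
        n_emissions=n_emissions,
        seed=seed,
        swaps=swaps,
    )


@dataclass
class RandomizedStack:
    """One randomized stack: permuted identities, untouched topology."""

    emission: int
    stack: NetworkStack
    permutation: dict[str, str]  # identity -> position whose edges it now holds
    seed: int = 0


# node attributes that travel with the identity, not the position
_IDENTITY_ATTRS = ("sex", "fate", "home_group")


def apply_swaps_synchronized(
    stack: NetworkStack, chain: SwapChain, emission: int
) -> RandomizedStack:
    """Apply one emission's cumulative permutation to every window.

    Identity ``i`` takes over the edges formerly incident to position
    ``perm[i]`` in every window, so per-window degree and strength
    multisets are unchanged; identity-bound node attributes stay with the
    identity.
    """
    if set(chain.pool) != set(stack.common_nodes):
        raise ValueError("swap pool must equal the stack's common node set")
    perm = chain.permutation_at(emission)
    inverse = {pos: ident for ident, pos in perm.items()}
    graphs: dict[int, nx.Graph] = {}
    for idx in stack.indices:
        g = stack[idx]
        h = nx.relabel_nodes(g, inverse, copy=True)
        h.graph.update(g.graph)
        # restore identity-bound attributes onto their identities
        for ident, pos in perm.items():
            for attr in _IDENTITY_ATTRS:
                if attr in g.nodes[ident]:
                    h.nodes[ident][attr] = g.nodes[ident][attr]
        graphs[idx] = h
    return RandomizedStack(
        emission=emission,
        stack=replace(stack, networks=graphs),
        permutation=perm,
        seed=chain.seed,
    )


def empirical_pvalue(
    observed: float, randomized: Sequence[float], sided: str = "two"
) -> float:
    """Add-one empirical p-value of an observed effect against a null sample.

    ``sided`` is ``"two"`` (compare absolute values), ``"greater"`` or
    ``"less"``.  The add-one correction keeps p in (0, 1] and valid at
    finite R.
    """
    randomized = np.asarray(randomized, dtype=float)
    if randomized.size == 0:
        raise ValueError("need at least one randomized value")
    if sided == "two":
        count = int(np.sum(np.abs(randomized) >= abs(observed)))
    elif sided == "greater":
        count = int(np.sum(randomized >= observed))
    elif sided == "less":
        count = int(np.sum(randomized <= observed))
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return (1 + count) / (1 + randomized.size)
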