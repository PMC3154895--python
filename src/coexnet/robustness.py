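"""Attack/error robustness: network diameter under targeted vs. random node removal.

"Attack" removes the most connected nodes first (re-ranking degrees after each
removal by default); "error" removes uniformly random nodes, averaged over
seeded trials.  At each point of a removal-fraction grid the curve records the
network diameter (average shortest-path length over surviving intra-component
pairs) and the size of the largest connected component.  A hub-dominated
network is expected to survive error but collapse under attack.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .topology import network_diameter

CURVE_COLUMNS = [
    "mode",
    "fraction",
    "n_removed",
    "diameter",
    "diameter_defined",
    "lcc_size",
]


def _fraction_grid(f_max: float, step: float) -> np.ndarray:
    if f_max < 0 or step <= 0:
        raise ValueError("invalid removal grid")
    return np.round(np.arange(0.0, f_max + step / 2.0, step), 10)


def _measure(g: nx.Graph) -> tuple[float, bool, int]:
    """Diameter (0 with a flag when no intra-component pair survives) and LCC size."""
    if g.number_of_nodes() == 0:
        return 0.0, False, 0
    lcc = max((len(c) for c in nx.connected_components(g)), default=0)
    if g.number_of_edges() == 0:
        return 0.0, False, lcc
    return network_diameter(g), True, lcc


def _record(
    g: nx.Graph,
    order: Iterable,
    grid: np.ndarray,
    n_total: int,
) -> list[tuple[int, float, bool, int]]:
    """Walk a removal order, measuring at each grid fraction."""
    h = g.copy()
    order = list(order)
    removed = 0
    out = []
    for f in grid:
        target = round(f * n_total)
        while removed < target and removed < len(order):
            h.remove_node(order[removed])
            removed += 1
        diameter, defined, lcc = _measure(h)
        out.append((removed, diameter, defined, lcc))
    return out


def _attack_order(g: nx.Graph, n_remove: int, adaptive: bool) -> list:
    h = g.copy()
    order = []
    if adaptive:
        for _ in range(min(n_remove, h.number_of_nodes())):
            # Highest current degree; ties broken toward the lowest label.
            victim = min(h.nodes, key=lambda v: (-h.degree(v), v))
            order.append(victim)
            h.remove_node(victim)
    else:
        ranked = sorted(g.nodes, key=lambda v: (-g.degree(v), v))
        order = ranked[:n_remove]
    return order


def attack(
    g: nx.Graph,
    f_max: float = 0.2,
    step: float = 0.01,
    adaptive: bool = True,
) -> pd.DataFrame:
    """Targeted hub removal.

    Iteratively deletes the currently highest-degree node (ties toward the
    lowest label), recomputing degrees after every removal when ``adaptive``;
    with ``adaptive=False`` the ranking is fixed on the intact graph.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot attack an empty graph")
    n = g.number_of_nodes()
    grid = _fraction_grid(f_max, step)
    n_remove = round(float(grid[-1]) * n)
    order = _attack_order(g, n_remove, adaptive)
    rows = _record(g, order, grid, n)
    return pd.DataFrame(
        [("attack", float(f), *row) for f, row in zip(grid, rows)], columns=CURVE_COLUMNS
    )


def error(
    g: nx.Graph,
    f_max: float = 0.2,
    step: float = 0.01,
    seed: int = 0,
    n_trials: int = 20,
) -> pd.DataFrame:
    """Random node removal, averaged over ``n_trials`` seeded trials.

    The reported diameter at each fraction is the across-trial mean (an
    undefined diameter enters as 0, mirroring the single-curve convention);
    ``diameter_defined`` is true only if every trial still had a surviving
    connected pair; ``lcc_size`` is the across-trial mean largest component.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot perturb an empty graph")
    if n_trials < 1:
        raise ValueError("need at least one trial")
    n = g.number_of_nodes()
    grid = _fraction_grid(f_max, step)
    nodes = sorted(g.nodes)
    diameters = np.zeros((n_trials, len(grid)))
    defined = np.ones((n_trials, len(grid)), dtype=bool)
    lcc = np.zeros((n_trials, len(grid)))
    for t in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence([seed, t]))
        order = [nodes[i] for i in rng.permutation(n)]
        for j, row in enumerate(_record(g, order, grid, n)):
            _, diameters[t, j], defined[t, j], lcc[t, j] = (
                row[0],
                row[1],
                row[2],
                row[3],
            )
    return pd.DataFrame(
        {
            "mode": "error",
            "fraction": grid.astype(float),
            "n_removed": [round(float(f) * n) for f in grid],
            "diameter": diameters.mean(axis=0),
            "diameter_defined": defined.all(axis=0),
            "lcc_size": lcc.mean(axis=0),
        },
        columns=CURVE_COLUMNS,
    )
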