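"""Purkinje conduction tree and its activation under bundle branch block.

The specialized conduction system is a rooted tree whose root plays the role
of the His bundle.  Left and right bundle branches fan out to terminal nodes
(Purkinje-myocardial junctions) bound to endocardial tissue-mesh nodes.
Propagation is one-dimensional at constant conduction velocity, so an
unblocked terminal activates at root_time + path_length / CV.  Blocking a
branch (LBBB / RBBB) marks every terminal of that branch as not activated by
the conduction system; its territory can still be reached retrogradely
through the myocardium in the tissue solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .util import ConfigurationError

BRANCHES = ("left", "right")


@dataclass
class PurkinjeActivation:
    """Activation times of the Purkinje-myocardial junctions."""

    terminal_nodes: np.ndarray     # tissue-mesh node index per terminal
    times: np.ndarray              # ms; NaN where unactivated-by-Purkinje
    branch: np.ndarray             # branch label per terminal

    @property
    def activated(self) -> np.ndarray:
        return ~np.isnan(self.times)


@dataclass
class PurkinjeTree:
    """Rooted conduction tree with branch labels and block flags."""

    graph: nx.DiGraph              # edges carry 'length' (cm); nodes carry
    coords: np.ndarray             # 'branch' and 'terminal' (tissue node or -1)
    root: int = 0
    conduction_velocity: float = 60.0   # cm/s
    blocked: set = field(default_factory=set)
    seed: int = 0

    def validate(self) -> None:
        g = self.graph
        if not nx.is_arborescence(g):
            raise ConfigurationError("Purkinje graph is not a tree rooted at one node")
        if g.in_degree(self.root) != 0:
            raise ConfigurationError("root node has incoming edges")
        if self.conduction_velocity <= 0:
            raise ConfigurationError("conduction velocity must be positive")
        for u, v, data in g.edges(data=True):
            if data.get("length", 0.0) <= 0:
                raise ConfigurationError(f"edge ({u}, {v}) has non-positive length")
        seen = {}
        for n in self.terminal_graph_nodes():
            t = g.nodes[n]["terminal"]
            if t in seen:
                raise ConfigurationError(f"tissue node {t} bound to two terminals")
            seen[t] = n
        for b in self.blocked:
            if b not in BRANCHES:
                raise ConfigurationError(f"unknown branch {b!r} in block flags")

    def terminal_graph_nodes(self) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d.get("terminal", -1) >= 0]

    def path_length(self, node: int) -> float:
        """Root-to-node path length along the tree (cm)."""
        try:
            return nx.shortest_path_length(self.graph, self.root, node, weight="length")
        except nx.NetworkXNoPath as err:
            raise ConfigurationError(f"node {node} is disconnected from the root") from err

    def with_block(self, *branches: str) -> "PurkinjeTree":
        unknown = set(branches) - set(BRANCHES)
        if unknown:
            raise ConfigurationError(f"unknown branches {sorted(unknown)}")
        return PurkinjeTree(graph=self.graph, coords=self.coords, root=self.root,
                           conduction_velocity=self.conduction_velocity,
                           blocked=set(branches), seed=self.seed)

    def to_frame(self) -> pd.DataFrame:
        """Edge-list table with coordinates, for plain-text interchange."""
        rows = []
        for u, v, data in self.graph.edges(data=True):
            rows.append({
                "parent": u, "child": v, "length_cm": data["length"],
                "x": self.coords[v, 0], "y": self.coords[v, 1], "z": self.coords[v, 2],
                "branch": self.graph.nodes[v].get("branch", ""),
                "terminal_tissue_node": self.graph.nodes[v].get("terminal", -1),
            })
        return pd.DataFrame(rows)

    def save(self, path) -> None:
        frame = self.to_frame()
        frame.attrs["seed"] = self.seed
        with open(path, "w") as fh:
            fh.write(f"# purkinje tree, seed={self.seed}, cv={self.conduction_velocity}\n")
            frame.to_csv(fh, index=False)


def purkinje_activation(tree: PurkinjeTree, root_time: float = 0.0,
                        cv: float | None = None) -> PurkinjeActivation:
    """Activation time of every terminal: root_time + path_length / CV.

    Terminals distal to a blocked branch are NaN (unactivated-by-Purkinje).
    """
    tree.validate()
    velocity = cv if cv is not None else tree.conduction_velocity
    cv_cm_per_ms = velocity / 1000.0
    lengths = nx.single_source_dijkstra_path_length(tree.graph, tree.root,
                                                    weight="length")
    terminals, times, branches = [], [], []
    for n in tree.terminal_graph_nodes():
        if n not in lengths:
            raise ConfigurationError(f"terminal graph node {n} unreachable from root")
        branch = tree.graph.nodes[n].get("branch", "")
        terminals.append(tree.graph.nodes[n]["terminal"])
        branches.append(branch)
        if branch in tree.blocked:
            times.append(np.nan)
        else:
            times.append(root_time + lengths[n] / cv_cm_per_ms)
    return PurkinjeActivation(terminal_nodes=np.asarray(terminals, dtype=np.int64),
                              times=np.asarray(times, dtype=float),
                              branch=np.asarray(branches, dtype=object))
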