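"""Read-outs of a fitted model: the signed interaction network and the
treatment/growth-stage response classification.

The network keeps a (signed) edge for every pair whose coupling J_ij is
significant at level alpha; the classification places each component in
one of four quadrants of the (g_s, g_a) plane:

* Group I   — early-stage components promoted by antibiotic treatment
  (g_s < 0, g_a > 0)
* Group II  — late-stage components promoted by treatment
  (g_s > 0, g_a > 0)
* Group III — early-stage components suppressed by treatment
  (g_s < 0, g_a < 0)
* Group IV  — late-stage components suppressed by treatment
  (g_s > 0, g_a < 0)

Values inside a dead zone of half-width delta around zero (default 0)
stay unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .maxent import FitResult, MaxEntParams

__all__ = ["SignedNetwork", "build_network", "classify_response"]


@dataclass
class SignedNetwork:
    """Significant pairwise couplings as an undirected signed graph."""

    graph: nx.Graph
    alpha: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def to_edgelist(self) -> pd.DataFrame:
        rows = [{"source": u, "target": v, "J": d["weight"],
                 "sign": d["sign"], "p_value": d["p_value"]}
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(
            rows, columns=["source", "target", "J", "sign", "p_value"])

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def write_edgelist_tsv(self, path) -> None:
        self.to_edgelist().to_csv(path, sep="\t", index=False)


def build_network(fit: FitResult, alpha: float = 0.05,
                  min_abs_j: float = 0.0) -> SignedNetwork:
    """Signed network of couplings with p(J_ij) <= alpha.

    Positive couplings (components that favour co-occurrence) and
    negative ones (mutual exclusion) are annotated via the ``sign`` edge
    attribute.  ``min_abs_j`` optionally also thresholds on |J|.
    """
    if fit.p_values is None:
        raise ValueError("fit carries no p-values; run significance() first")
    params = fit.params
    n = params.n_components
    names = params.component_names or [f"c{i:02d}" for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            p = fit.p_values.J[i, j]
            w = params.J[i, j]
            if p <= alpha and abs(w) > min_abs_j:
                g.add_edge(names[i], names[j], weight=float(w),
                           sign="positive" if w > 0 else "negative",
                           p_value=float(p))
    return SignedNetwork(graph=g, alpha=alpha)


def classify_response(params: MaxEntParams,
                      delta: float = 0.0) -> pd.DataFrame:
    """Quadrant classification of components in the (g_s, g_a) plane.

    Returns a table with columns component, g_a, g_s, group; a component
    whose |g_a| or |g_s| does not exceed ``delta`` is 'unclassified'.
    """
    n = params.n_components
    names = params.component_names or [f"c{i:02d}" for i in range(n)]
    groups = []
    for ga, gs in zip(params.g_a, params.g_s):
        if abs(ga) <= delta or abs(gs) <= delta:
            groups.append("unclassified")
        elif ga > 0:
            groups.append("I" if gs < 0 else "II")
        else:
            groups.append("III" if gs < 0 else "IV")
    return pd.DataFrame({"component": names, "g_a": params.g_a,
                         "g_s": params.g_s, "group": groups})
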