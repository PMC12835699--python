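"""Node centrality statistics of a learned network.

Degree is counted on the directed graph (in, out, total); closeness and
betweenness are computed on the undirected, unweighted skeleton, matching
how psychometric network studies report a single per-node value alongside
a separate in/out-degree breakdown.  Standardized columns divide by the
theoretical maxima (betweenness by (n-1)(n-2)/2; classic closeness is
already in [0, 1] on a connected graph).  On a disconnected skeleton,
closeness falls back to harmonic centrality scaled by 1/(n-1).
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .dag import Dag


def centrality(dag: Dag) -> pd.DataFrame:
    """Centrality table, one row per node in declared order."""
    if not dag.nodes:
        raise ValueError("empty node set")
    n = len(dag.nodes)
    g = dag.to_networkx()
    und = g.to_undirected()
    betw = nx.betweenness_centrality(und, normalized=False) if n > 1 else \
        {v: 0.0 for v in dag.nodes}
    connected = n == 1 or nx.is_connected(und)
    if connected:
        close = {v: nx.closeness_centrality(und, v) for v in dag.nodes} if n > 1 \
            else {v: 0.0 for v in dag.nodes}
    else:
        harm = nx.harmonic_centrality(und)
        close = {v: harm[v] / (n - 1) for v in dag.nodes}
    b_max = (n - 1) * (n - 2) / 2.0
    rows = []
    for v in dag.nodes:
        din = g.in_degree(v)
        dout = g.out_degree(v)
        rows.append({
            "node": v,
            "degree_in": din,
            "degree_out": dout,
            "degree_total": din + dout,
            "closeness": close[v],
            "betweenness": betw[v],
            "closeness_std": close[v],
            "betweenness_std": betw[v] / b_max if b_max > 0 else 0.0,
        })
    table = pd.DataFrame(rows).set_index("node")
    table.attrs["closeness_variant"] = "classic" if connected else "harmonic"
    return table
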