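import numpy as np

from qtps.cg_graph import CGParams, Configuration, Edge, ManifoldGraph


def literal_graph(coords, weights, sigma=1.0):
    """Graph with prescribed symmetric edge weights and zero potential."""
    params = CGParams(sigma=sigma)
    configs = [
        Configuration(id=i, coords=np.asarray(c, float))
        for i, c in sorted(coords.items())
    ]
    edges = []
    for (i, j), w in sorted(weights.items()):
        d2 = float(np.sum((np.asarray(coords[i]) - np.asarray(coords[j])) ** 2))
        edges.append(Edge(i=i, j=j, dist2=d2, w_ij=w, w_ji=w, w_sym=w))
    return ManifoldGraph(
        configurations=configs, V_cg=np.zeros(len(configs)), edges=edges, params=params
    )


def random_connected_graph(rng, n_nodes, max_bits=18, w_lo=0.2, w_hi=2.0):
    """Random connected literal graph with node+edge bit count <= max_bits."""
    import networkx as nx

    while True:
        coords = {i: tuple(rng.uniform(0, 3, size=2)) for i in range(n_nodes)}
        max_edges = max_bits - n_nodes
        all_pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
        rng.shuffle(all_pairs)
        g = nx.Graph()
        g.add_nodes_from(range(n_nodes))
        edges = []
        for i, j in all_pairs:
            if len(edges) >= max_edges:
                break
            if not nx.is_connected(g) or rng.random() < 0.4:
                g.add_edge(i, j)
                edges.append((i, j))
        if nx.is_connected(g):
            weights = {tuple(sorted(e)): float(rng.uniform(w_lo, w_hi)) for e in edges}
            return literal_graph(coords, weights)
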