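import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_alignment():
    """Two planted clusters: {s1,s2,s3} near-identical, {s4,s5} divergent."""
    from barcogeo import AlignedMatrix

    transition = str.maketrans("ACGT", "GTAC")
    base = "ACGT" * 25
    far = "".join(
        c.translate(transition) if i % 5 == 0 else c for i, c in enumerate(base)
    )
    rows = [base, base[:-1] + "G", base, far, far[:-1] + "G"]
    return AlignedMatrix([f"s{i+1}" for i in range(5)], rows)


@pytest.fixture
def metadata_file(tmp_path):
    path = tmp_path / "meta.tsv"
    path.write_text(
        "specimen_id\tsite_id\tlatitude\tlongitude\tmorphospecies\tdeformed\tcharacters\n"
        "s1\tA\t42.0\t128.1\tP. sp1\tfalse\tpso_formula=32/033/33343\n"
        "s2\tA\t42.0\t128.1\tP. sp1\t\t\n"
        "s3\tB\t42.5\t128.3\tP. sp2\ttrue\tpso_formula=33/044/33343\n"
    )
    return path


def random_additive_tree(n_taxa, rng):
    """A random binary tree topology with positive branch lengths and the
    exact path-length distance matrix it induces (the NJ oracle input)."""
    import itertools

    labels = [f"t{i}" for i in range(n_taxa)]
    # grow a tree as an adjacency of nodes; start from a 3-star
    next_node = n_taxa
    edges = {}  # (u,v) -> length

    def add_edge(u, v, w):
        edges[(u, v)] = w
        edges[(v, u)] = w

    center = next_node
    next_node += 1
    for leaf in range(3):
        add_edge(leaf, center, float(rng.uniform(0.5, 2.0)))
    attachable = [(0, center), (1, center), (2, center)]
    for leaf in range(3, n_taxa):
        u, v = attachable[rng.integers(0, len(attachable))]
        w = edges[(u, v)]
        mid = next_node
        next_node += 1
        split = float(rng.uniform(0.2, 0.8)) * w
        del edges[(u, v)], edges[(v, u)]
        add_edge(u, mid, split)
        add_edge(mid, v, w - split)
        add_edge(leaf, mid, float(rng.uniform(0.5, 2.0)))
        attachable = [(a, b) for (a, b) in edges if a < b]
    # all-pairs path lengths by BFS over the tree
    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
    D = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nxt, w in adj[cur]:
                if nxt not in dist:
                    dist[nxt] = dist[cur] + w
                    stack.append(nxt)
        for dst in range(n_taxa):
            D[src, dst] = dist[dst]
    D = (D + D.T) / 2.0  # remove float asymmetry from summation order
    true_splits = _splits_from_adjacency(adj, n_taxa)
    return labels, D, true_splits


def _splits_from_adjacency(adj, n_taxa):
    """Non-trivial bipartitions of the true tree, as frozensets of leaves."""
    splits = set()
    for u in adj:
        for v, _ in adj[u]:
            if u < v:
                # leaves on v's side of edge (u, v)
                side = set()
                stack = [(v, u)]
                while stack:
                    cur, parent = stack.pop()
                    if cur < n_taxa:
                        side.add(f"t{cur}")
                    for nxt, _ in adj[cur]:
                        if nxt != parent:
                            stack.append((nxt, cur))
                if 2 <= len(side) <= n_taxa - 2:
                    splits.add(frozenset(side))
    # normalize to the side not containing t0
    leaves = frozenset(f"t{i}" for i in range(n_taxa))
    return {frozenset(leaves - s) if "t0" in s else s for s in splits}
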