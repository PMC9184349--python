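import numpy as np
import pandas as pd
import pytest

from ecoassembly.io import DatedTree, OtuTable, SampleFrame, align, read_tree
from ecoassembly.synth import SynthConfig, simulate_dataset

#: reduced study-shaped configuration used throughout the suite
REDUCED = dict(n_taxa=60, n_sites=2, n_plots=2, n_hosts=2, n_reps=3,
               n_dropout=0, reads_per_sample=1000)


@pytest.fixture(scope="session")
def neutral_ds():
    """24-sample, 60-OTU neutral-drift dataset (fixed seed)."""
    ds, truth = simulate_dataset(SynthConfig(scenario="neutral_drift",
                                             seed=11, **REDUCED))
    return ds, truth


@pytest.fixture(scope="session")
def filtering_ds():
    """Strong environmental filtering with contrasting site environments."""
    ds, truth = simulate_dataset(SynthConfig(
        scenario="env_filtering", sigma_env=0.4, env_contrast=2.0,
        niche_rate=1.0, seed=11, **REDUCED))
    return ds, truth


@pytest.fixture()
def toy_tree():
    return read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture()
def toy_dataset(toy_tree):
    counts = pd.DataFrame([[3, 1, 0], [0, 2, 2], [1, 1, 1]],
                          index=["s1", "s2", "s3"],
                          columns=["A", "B", "C"])
    meta = pd.DataFrame({
        "site": ["S1", "S1", "S1"],
        "plot": ["S1P1", "S1P1", "S1P1"],
        "host": ["H1", "H1", "H2"],
        "season": ["spring"] * 3,
        "x": [0.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0],
        "pH": [7.0, 7.1, 6.9], "OM": [10.0, 11.0, 9.0],
        "GM": [20.0, 21.0, 19.0],
    }, index=pd.Index(["s1", "s2", "s3"], name="sample_id"))
    return align(OtuTable(counts), toy_tree, SampleFrame(meta))


def random_tree(n_leaves: int, seed: int) -> DatedTree:
    """Random birth-death tree with labelled leaves, for oracles."""
    cfg = SynthConfig(n_taxa=n_leaves, seed=seed)
    from ecoassembly.synth import simulate_tree
    return simulate_tree(cfg)


def brute_force_cophenetic(tree: DatedTree) -> dict:
    """Naive per-pair path-walk distances, independent of the library path."""
    node_depth = {}
    parent = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            node_depth[id(node)] = 0.0
        else:
            node_depth[id(node)] = (node_depth[id(node.parent_node)]
                                    + node.edge.length)
        parent[id(node)] = node.parent_node
    leaves = list(tree.tree.leaf_node_iter())
    out = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            pa, seen = a, {}
            while pa is not None:
                seen[id(pa)] = node_depth[id(pa)]
                pa = parent[id(pa)]
            pb = b
            while id(pb) not in seen:
                pb = parent[id(pb)]
            mrca_depth = seen[id(pb)]
            dist = (node_depth[id(a)] - mrca_depth) + \
                   (node_depth[id(b)] - mrca_depth)
            out[frozenset((a.taxon.label, b.taxon.label))] = dist
    return out


def beta_mntd_oracle(f_k, f_l, d) -> float:
    """Brute-force double loop over taxa of both communities."""
    f_k = np.asarray(f_k, float)
    f_l = np.asarray(f_l, float)
    sk = [i for i in range(len(f_k)) if f_k[i] > 0]
    sl = [j for j in range(len(f_l)) if f_l[j] > 0]
    wk = f_k[sk] / f_k[sk].sum()
    wl = f_l[sl] / f_l[sl].sum()
    term1 = sum(w * min(d[i][j] for j in sl) for w, i in zip(wk, sk))
    term2 = sum(w * min(d[j][i] for i in sk) for w, j in zip(wl, sl))
    return 0.5 * (term1 + term2)
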