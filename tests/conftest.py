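from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from m6abreadth.m6a import ConditionProfile
from m6abreadth.topology import SignalingNetwork


def make_profile(cond, rep, peaks, cell_type="ct1", perturbed=()):
    """Build a ConditionProfile from (contig, start, end, strand, score) tuples."""
    df = pd.DataFrame(peaks, columns=["contig", "start", "end", "strand", "score"])
    return ConditionProfile(
        condition_id=cond,
        cell_type=cell_type,
        replicate_id=rep,
        perturbed_components=frozenset(perturbed),
        peaks=df,
    )


def make_network(edges, receptors=(), tfs=()):
    """SignalingNetwork from (source, target, type) tuples."""
    df = pd.DataFrame(edges, columns=["source", "target", "edge_type"])
    return SignalingNetwork(edges=df, receptor_set=frozenset(receptors), tf_set=frozenset(tfs))


def random_signed_network(rng: np.random.Generator, n_nodes: int, n_edges: int,
                          p_repress: float = 0.4) -> SignalingNetwork:
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    rows = []
    for _ in range(n_edges):
        u, v = rng.choice(n_nodes, size=2, replace=False)
        t = "repress" if rng.random() < p_repress else "activate"
        rows.append((nodes[u], nodes[v], t))
    return make_network(rows)


@pytest.fixture
def simple_genes():
    """Two genes on one contig, opposite strands, plus a two-transcript gene."""
    return pd.DataFrame(
        [
            ("gA", "gA.t1", "chr1", 100, 500, "+"),
            ("gB", "gB.t1", "chr1", 1000, 1400, "-"),
            ("gC", "gC.t1", "chr2", 0, 300, "+"),
            ("gC", "gC.t2", "chr2", 200, 600, "+"),
        ],
        columns=["gene_id", "transcript_id", "contig", "start", "end", "strand"],
    )


@pytest.fixture
def chain_network():
    """receptor -> x -> tf chain used for relative-level checks."""
    return make_network(
        [("R", "x", "activate"), ("x", "T", "activate")],
        receptors=["R"],
        tfs=["T"],
    )
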