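import numpy as np
import pytest

import cyclegrn as cg


@pytest.fixture(scope="session")
def small_collection():
    """A compact planted-signal collection shared by read-only tests."""
    cfg = cg.SynthConfig(
        seed=11, n_tfs=15, n_genes=150, out_degree_mean=8, n_datasets=2,
        pairwise_overlap_target=0.2, planted_ffl_count=8,
        phase_sizes={"G1": 10, "S": 6, "S-G2": 6, "G2-M": 8, "M-G1": 6},
        n_phase_tfs=10, tf_phase_effect=0.8, noise_sd=0.05,
    )
    return cg.generate_collection(cfg)


@pytest.fixture()
def fig_grn():
    """The canonical two-TF illustration GRN: TF1 regulates TF2 and three
    targets, TF2 regulates two of them plus one of its own."""
    return cg.GRN.from_edges("demo", [
        ("TF1", "TF2"), ("TF1", "Tar1"), ("TF1", "Tar2"), ("TF1", "Tar3"),
        ("TF2", "Tar2"), ("TF2", "Tar3"), ("TF2", "Tar4"),
    ])


def random_grn(rng: np.random.Generator, n_nodes: int = 10,
               p_edge: float = 0.25) -> cg.GRN:
    """Small random directed graph used against brute-force oracles."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = [(a, b) for a in nodes for b in nodes
             if a != b and rng.random() < p_edge]
    return cg.GRN.from_edges("rand", edges)


def brute_force_ffls(grn: cg.GRN) -> set[cg.FFL]:
    """Exhaustive triple loop over all node triplets."""
    nodes = sorted(grn.genes)
    e = grn.interactions
    out = set()
    for p in nodes:
        for s in nodes:
            for t in nodes:
                if len({p, s, t}) == 3 and (p, s) in e and (p, t) in e \
                        and (s, t) in e:
                    out.add(cg.FFL(p, s, t))
    return out
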