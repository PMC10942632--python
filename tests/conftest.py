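import numpy as np
import pytest

from ratecov.domains import DomainEdge
from ratecov.phylo import TreeSet, read_newick
from ratecov.simulate import ModuleSpec, SimConfig, simulate_study


def make_edges(scores, labels):
    """Edge list between two dummy proteins from parallel score/label lists."""
    return [
        DomainEdge(f"pA_d{i}", f"pB_d{i}", "pA", "pB", float(s), int(l))
        for i, (s, l) in enumerate(zip(scores, labels))
    ]


@pytest.fixture
def master_4tax():
    return read_newick("(((A:1,B:1):1,C:1):1,D:3);")


@pytest.fixture
def balanced_master():
    return read_newick("((A:1,B:2):1,(C:1.5,D:0.5):2);")


@pytest.fixture
def proportional_treeset(balanced_master):
    """Three gene trees that are exact scalar multiples of the master."""
    genes = {}
    for gene, c in [("g1", 1.0), ("g2", 2.0), ("g3", 0.5)]:
        length = {n: c * ln for n, ln in balanced_master.length.items()}
        genes[gene] = type(balanced_master)(
            parent=dict(balanced_master.parent),
            length=length,
            label=dict(balanced_master.label),
            root=balanced_master.root,
        )
    return TreeSet(master=balanced_master, gene_trees=genes)


@pytest.fixture(scope="session")
def small_study():
    """A modest complete study: 2 complexes, 1 pathway, some dropout."""
    cfg = SimConfig(
        S=25,
        n_background_genes=60,
        sigma_noise=0.3,
        dropout=0.1,
        seed=42,
        modules=[
            ModuleSpec("cplxA", "complex", 6, rho_mod=0.4, rho_phys=0.3),
            ModuleSpec("cplxB", "complex", 5, rho_mod=0.3, rho_phys=0.0),
            ModuleSpec("pathC", "pathway", 6, rho_mod=0.5),
        ],
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_study_dir(tmp_path_factory, small_study):
    from ratecov.simulate import _write_study

    out = tmp_path_factory.mktemp("study")
    _write_study(small_study, out)
    return out


@pytest.fixture
def rng():
    # function-scoped so each test's draws are independent of run order
    return np.random.default_rng(12345)
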