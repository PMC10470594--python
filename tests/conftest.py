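import numpy as np
import dendropy
import pytest
from hypothesis import settings

import scoperon as sp
from scoperon.seqio import OperonRecord, Source

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_params():
    return sp.SimParams(
        n_ref_taxa=12, n_queries=12, n_cells=10, n_lineages=4, seed=1
    )


@pytest.fixture(scope="session")
def small_ref(small_params):
    refdb, truth = sp.simulate_reference(small_params)
    return refdb, truth


@pytest.fixture(scope="session")
def default_ref():
    """The default 50-leaf synthetic reference (full operon)."""
    params = sp.SimParams(seed=1)
    refdb, truth = sp.simulate_reference(params)
    return params, refdb, truth


_ROT = {"A": "C", "C": "G", "G": "T", "T": "A"}


def _rot(seq, pos):
    seq = seq.copy()
    for i in pos:
        seq[i] = _ROT[seq[i]]
    return seq


@pytest.fixture(scope="session")
def symmetric_quartet():
    """A fully symmetric 4-leaf reference plus a query engineered to sit
    exactly on the decision boundary between two terminal edges."""
    L = 800
    rng = np.random.default_rng(7)
    base = rng.choice(list("ACGT"), size=L)
    s0 = np.arange(0, 40) * 2
    s1 = s0 + 1
    sa = 100 + np.arange(24) * 8
    sb, sc, sd = sa + 2, sa + 4, sa + 6
    anc_ab = _rot(base, s0)
    anc_cd = _rot(base, s1)
    aln = {
        "A": "".join(_rot(anc_ab, sa)),
        "B": "".join(_rot(anc_ab, sb)),
        "C": "".join(_rot(anc_cd, sc)),
        "D": "".join(_rot(anc_cd, sd)),
    }
    tree = dendropy.Tree.get(
        data="((A:0.03,B:0.03):0.05,(C:0.03,D:0.03):0.05);", schema="newick"
    )
    refdb = sp.ReferenceDB(alignment=aln, tree=tree)
    halfway = _rot(_rot(anc_ab, sa[:12]), sb[12:])
    query = OperonRecord(id="boundary", sequence="".join(halfway), source=Source.OTU)
    return refdb, query
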