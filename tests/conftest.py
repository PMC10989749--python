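import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from markerflow.io_formats import ReferencePack
from markerflow.profiling import TaxonomicProfile


def make_pack(
    newick: str,
    taxonomy: dict[str, str],
    copies: dict[str, float] | None = None,
    ko: dict[str, dict[str, int]] | None = None,
    hierarchy: dict[str, tuple] | None = None,
    nsti: dict[str, float] | None = None,
    sequences: dict[str, str] | None = None,
) -> ReferencePack:
    """Assemble a small in-memory reference pack, defaulting missing tables."""
    tree = TreeNode.read(io.StringIO(newick))
    if tree.length is None:
        tree.length = 0.0
    leaves = [t.name for t in tree.tips()]
    copies = copies or {l: 1.0 for l in leaves}
    ko = ko or {l: {"K1": 1} for l in leaves}
    kos = sorted({k for row in ko.values() for k in row})
    ko_df = pd.DataFrame(
        [[ko[l].get(k, 0) for k in kos] for l in leaves], index=leaves, columns=kos
    )
    hierarchy = hierarchy or {k: (("M1", "C1", "P1"),) for k in kos}
    hierarchy = {
        k: (v,) if v and isinstance(v[0], str) else tuple(v) for k, v in hierarchy.items()
    }
    nsti = nsti or {l: 0.0 for l in leaves}
    pack = ReferencePack(tree, taxonomy, copies, ko_df, hierarchy, nsti, sequences)
    pack.validate()
    return pack


@pytest.fixture
def toy_pack() -> ReferencePack:
    """Hand-built 4-leaf pack: two genera, one leaf with an empty genus."""
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    seqs = {l: "".join(rng.choice(bases, 200)) for l in "ABCD"}
    return make_pack(
        "((A:1.0,B:1.0)N1:0.5,(C:2.0,D:2.0)N2:0.5)root:0.0;",
        taxonomy={
            "A": "k__K;p__P1;c__C1;o__O1;f__F1;g__GX;s__A",
            "B": "k__K;p__P1;c__C1;o__O1;f__F1;g__GX;s__B",
            "C": "k__K;p__P2;c__C2;o__O2;f__F2;g__GY;s__C",
            "D": "k__K;p__P2;c__C2;o__O2;f__F2;g__;s__D",
        },
        copies={"A": 1.0, "B": 4.0, "C": 2.0, "D": 1.0},
        ko={
            "A": {"K1": 2, "K2": 0},
            "B": {"K1": 1, "K2": 3},
            "C": {"K2": 1},
            "D": {"K1": 1, "K2": 1},
        },
        hierarchy={
            "K1": ("M1", "C1a", "P1a"),
            "K2": ("M1", "C1a", "P1b"),
        },
        nsti={"A": 0.02, "B": 0.04, "C": 0.07, "D": 0.0},
        sequences=seqs,
    )


@pytest.fixture
def two_leaf_pack() -> ReferencePack:
    return make_pack(
        "(A:1.0,B:1.0)root:0.0;",
        taxonomy={
            "A": "k__K;p__P;c__C;o__O;f__F;g__G;s__A",
            "B": "k__K;p__P;c__C;o__O;f__F;g__G;s__B",
        },
    )


def profile(sample_id: str, normalized: dict[str, float], counts=None) -> TaxonomicProfile:
    counts = counts if counts is not None else {k: v * 100 for k, v in normalized.items()}
    return TaxonomicProfile(sample_id, counts, normalized, empty=not normalized)
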