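from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from psdmap import (
    load_framework_catalog,
    load_ggm_catalog,
)
from psdmap.structures import (
    Linkage,
    Modification,
    Residue,
    StructureGraph,
)


@pytest.fixture(scope="session")
def ggm_catalog():
    return load_ggm_catalog()


@pytest.fixture(scope="session")
def framework():
    return load_framework_catalog()


def linear_chain(sugar: str, n: int, config: str = "beta",
                 parent_carbon: int = 4, name: str = "chain") -> StructureGraph:
    residues = [Residue.make(i, sugar) for i in range(n)]
    linkages = [
        Linkage(i, i + 1, config, parent_carbon, 1) for i in range(n - 1)
    ]
    return StructureGraph(name, residues, linkages, 0)


def small_ggm(n_backbone: int = 6, branch_at=(2,), acetyl_at=(3,),
              extend_at=()) -> StructureGraph:
    """Hand-built galactoglucomannan fragment for digestion tests."""
    residues = [Residue.make(i, "Man") for i in range(n_backbone)]
    linkages = [
        Linkage(i, i + 1, "beta", 4, 1) for i in range(n_backbone - 1)
    ]
    nid = n_backbone
    for pos in branch_at:
        residues.append(Residue.make(nid, "Gal", backbone=False))
        linkages.append(Linkage(pos, nid, "alpha", 6, 1))
        if pos in extend_at:
            residues.append(Residue.make(nid + 1, "Gal", backbone=False))
            linkages.append(Linkage(nid, nid + 1, "beta", 2, 1))
            nid += 1
        nid += 1
    for pos in acetyl_at:
        res = residues[pos]
        residues[pos] = Residue(
            res.id, res.sugar, res.ring_carbons, res.anomeric_carbon,
            res.backbone, res.modifications + (Modification("acetyl", 2),),
        )
    return StructureGraph("ggm_fragment", residues, linkages, 0)


def six_condition_design(replicates=None) -> pd.DataFrame:
    from psdmap.simulate import CONDITIONS, DEFAULT_REPLICATES

    replicates = replicates or DEFAULT_REPLICATES
    rows = []
    for cond in CONDITIONS:
        for r in range(1, replicates[cond] + 1):
            rows.append({"sample": f"{cond}_{r}", "condition": cond,
                         "replicate": r})
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(20120716)
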