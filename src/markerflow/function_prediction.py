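"""Gene-family (KO) prediction from taxonomic profiles, pathway roll-ups,
and the NSTI prediction-reliability index.

A sample's KO profile is the copy-number-corrected taxon weights pushed
through the reference KO-content matrix and renormalised; pathway
profiles aggregate KOs through a fixed three-level hierarchy. NSTI is
the abundance-weighted mean distance from community members to their
nearest sequenced relatives: low values mean the functional prediction
rests on well-characterised taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AbundanceTable, ReferencePack
from .profiling import TaxonomicProfile

__all__ = [
    "FunctionalProfile",
    "PathwayProfile",
    "predict_ko",
    "compute_nsti",
    "aggregate_pathways",
    "functional_table",
    "pathway_table",
]

UNANNOTATED = "Unannotated"


@dataclass
class FunctionalProfile:
    sample_id: str
    ko_abundance: dict[str, float]  # KO -> relative abundance (sums to 1)
    nsti: float | None  # None for an empty sample

    @property
    def empty(self) -> bool:
        return not self.ko_abundance


@dataclass
class PathwayProfile:
    sample_id: str
    level: int  # 1 | 2 | 3
    abundance: dict[str, float]


def compute_nsti(profile: TaxonomicProfile, pack: ReferencePack) -> float | None:
    """Abundance-weighted mean nearest-sequenced-taxon distance."""
    if profile.empty or not profile.normalized:
        return None
    return float(
        sum(a * pack.nsti_distance[leaf] for leaf, a in profile.normalized.items())
    )


def predict_ko(profile: TaxonomicProfile, pack: ReferencePack) -> FunctionalProfile:
    """Predict a sample's KO profile from its taxon composition.

    raw_k = sum_i (counts_i / copy_i) * ko_content[i, k], then
    normalised to sum 1. The prediction is linear in the taxon weights.
    """
    if profile.empty or not profile.counts:
        return FunctionalProfile(profile.sample_id, {}, None)
    weights = pd.Series(
        {leaf: c / pack.copy_number[leaf] for leaf, c in profile.counts.items()}
    )
    content = pack.ko_content.loc[weights.index]
    raw = content.mul(weights, axis=0).sum(axis=0)
    total = float(raw.sum())
    if total <= 0:
        return FunctionalProfile(profile.sample_id, {}, compute_nsti(profile, pack))
    ko_abundance = {ko: float(v) / total for ko, v in raw.items() if v > 0}
    return FunctionalProfile(profile.sample_id, ko_abundance, compute_nsti(profile, pack))


def aggregate_pathways(fp: FunctionalProfile, pack: ReferencePack, level: int) -> PathwayProfile:
    """Roll KO abundances up to a hierarchy level (1, 2 or 3).

    A KO with several hierarchy paths splits its abundance equally
    across them; KOs absent from the hierarchy pool under "Unannotated".
    The result is renormalised to sum 1.
    """
    if level not in (1, 2, 3):
        raise ValueError("level must be 1, 2 or 3")
    out: dict[str, float] = {}
    for ko, ab in fp.ko_abundance.items():
        paths = pack.hierarchy.get(ko)
        if not paths:
            out[UNANNOTATED] = out.get(UNANNOTATED, 0.0) + ab
            continue
        share = ab / len(paths)
        for path in paths:
            label = path[level - 1]
            out[label] = out.get(label, 0.0) + share
    total = sum(out.values())
    if total > 0:
        out = {k: v / total for k, v in out.items()}
    return PathwayProfile(fp.sample_id, level, out)


def functional_table(fps: list[FunctionalProfile]) -> AbundanceTable:
    """Stack per-sample KO profiles into a samples x KO relative table."""
    kos = sorted({ko for fp in fps for ko in fp.ko_abundance})
    mat = pd.DataFrame(
        [[fp.ko_abundance.get(ko, 0.0) for ko in kos] for fp in fps],
        index=[fp.sample_id for fp in fps],
        columns=kos,
    )
    return AbundanceTable(mat, unit="relative")


def pathway_table(fps: list[FunctionalProfile], pack: ReferencePack, level: int) -> AbundanceTable:
    pps = [aggregate_pathways(fp, pack, level) for fp in fps]
    labels = sorted({lab for pp in pps for lab in pp.abundance})
    mat = pd.DataFrame(
        [[pp.abundance.get(lab, 0.0) for lab in labels] for pp in pps],
        index=[pp.sample_id for pp in pps],
        columns=labels,
    )
    return AbundanceTable(mat, unit="relative")
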