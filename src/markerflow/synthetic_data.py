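"""Deterministic generators for every fixture the pipeline consumes.

Builds a synthetic reference pack (tree, taxonomy, copy numbers, KO
content, pathway hierarchy, NSTI distances, representative sequences),
group-structured cohorts with planted effect taxa, and error-bearing
reads written in the exact manifest/metadata dialects the readers expect.
Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import (
    AbundanceTable,
    MetadataTable,
    RANK_PREFIXES,
    ReferencePack,
    SequenceRecord,
    write_fasta,
    write_reference_pack,
)

__all__ = [
    "SimulationConfig",
    "simulate_reference_pack",
    "simulate_cohort",
    "simulate_reads",
    "simulate_input_dir",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass
class SimulationConfig:
    """Study-design knobs for a two-group synthetic cohort.

    group_effects lists (taxon leaf id, fold_change>0) pairs applied to
    group B's baseline proportions before renormalisation. The per-base
    substitution rate applies when reads are generated from the cohort.
    """

    n_taxa: int = 32
    n_samples_per_group: int = 20
    group_effects: list[tuple[str, float]] = field(default_factory=list)
    reads_per_sample: int = 200
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0,1]")
        for taxon, fc in self.group_effects:
            if fc <= 0:
                raise ValueError(f"fold change for {taxon!r} must be > 0")


def _random_tree(n_taxa: int, rng: np.random.Generator) -> TreeNode:
    """Random bifurcating tree by successive random pair joins.

    Branch lengths are Exponential(mean 0.1); the root edge is 0.
    """
    nodes = [TreeNode(name=f"L{i + 1}") for i in range(n_taxa)]
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        counter += 1
        left.length = float(rng.exponential(0.1))
        right.length = float(rng.exponential(0.1))
        parent = TreeNode(name=f"N{counter}", children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def _taxonomy_from_tree(tree: TreeNode) -> dict[str, str]:
    """Derive a consistent 7-rank lineage per leaf from tree clades.

    The kingdom is shared; phylum..genus labels come from the internal
    node on the root-to-leaf path at the matching depth (clamped to the
    leaf's parent on shallow paths); species is the leaf itself.
    """
    taxonomy = {}
    for tip in tree.tips():
        path = [tree] + list(reversed([a for a in tip.ancestors() if a is not tree])) + [tip]
        # path[0] = root, path[-1] = leaf
        labels = ["k__King"]
        for rank in range(1, 6):  # phylum .. genus
            idx = min(rank, len(path) - 2)
            node = path[idx]
            labels.append(f"{RANK_PREFIXES[rank]}{node.name}")
        labels.append(f"s__{tip.name}")
        taxonomy[tip.name] = ";".join(labels)
    return taxonomy


def _evolve_sequences(tree: TreeNode, length: int, rng: np.random.Generator) -> dict[str, str]:
    """Mutate a random root sequence down the tree.

    Per-site substitution probability on an edge is 1 - exp(-branch
    length), i.e. proportional to length for short edges.
    """
    root_seq = rng.integers(0, 4, size=length)
    seqs: dict[str, str] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            p = 1.0 - np.exp(-(child.length or 0.0))
            child_seq = seq.copy()
            hit = rng.random(length) < p
            if hit.any():
                # substitute to one of the three other bases
                shift = rng.integers(1, 4, size=int(hit.sum()))
                child_seq[hit] = (child_seq[hit] + shift) % 4
            if child.is_tip():
                seqs[child.name] = "".join(_BASES[child_seq])
            else:
                descend(child, child_seq)

    if tree.is_tip():  # degenerate single-leaf tree
        seqs[tree.name] = "".join(_BASES[root_seq])
    else:
        descend(tree, root_seq)
    return seqs


def simulate_reference_pack(n_taxa: int, seed: int, sequence_length: int = 200) -> ReferencePack:
    """Generate a complete synthetic reference pack.

    Copy numbers are uniform integers 1-10, KO content is Poisson(2)
    counts over 30 KOs hanging off a 2/4/8-label three-level hierarchy,
    and NSTI distances are Exponential(mean 0.03).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    tree = _random_tree(n_taxa, rng)
    taxonomy = _taxonomy_from_tree(tree)
    leaves = [t.name for t in tree.tips()]

    copy_number = {leaf: float(rng.integers(1, 11)) for leaf in leaves}
    nsti = {leaf: float(rng.exponential(0.03)) for leaf in leaves}

    n_kos = 30
    kos = [f"K{i + 1:05d}" for i in range(n_kos)]
    # 2 level-1 labels, 2 level-2 under each, 2 level-3 under each of those
    paths = []
    for a in range(2):
        for b in range(2):
            for c in range(2):
                paths.append((f"Metabolism_{a + 1}", f"Class_{a + 1}.{b + 1}", f"Pathway_{a + 1}.{b + 1}.{c + 1}"))
    hierarchy = {ko: (paths[i % len(paths)],) for i, ko in enumerate(kos)}
    ko_content = pd.DataFrame(
        rng.poisson(2.0, size=(n_taxa, n_kos)), index=leaves, columns=kos
    )

    sequences = _evolve_sequences(tree, sequence_length, rng)
    pack = ReferencePack(tree, taxonomy, copy_number, ko_content, hierarchy, nsti, sequences)
    pack.validate()
    return pack


def simulate_cohort(pack: ReferencePack, cfg: SimulationConfig) -> tuple[AbundanceTable, MetadataTable]:
    """Draw a two-group cohort of taxon counts plus matching metadata.

    Baseline taxon proportions come from a symmetric Dirichlet(0.5);
    group B multiplies the configured effect taxa by their fold changes
    and renormalises; per-sample counts are Multinomial draws. The
    metadata carries the group label and one independent numeric
    covariate (Normal(50,10)) for null testing.
    """
    rng = np.random.default_rng(cfg.seed)
    leaves = pack.leaf_ids
    missing = [t for t, _ in cfg.group_effects if t not in leaves]
    if missing:
        raise ValueError(f"effect taxa not in reference pack: {missing}")

    base = rng.dirichlet(np.full(len(leaves), 0.5))
    props = {"A": base}
    shifted = base.copy()
    for taxon, fc in cfg.group_effects:
        shifted[leaves.index(taxon)] *= fc
    props["B"] = shifted / shifted.sum()

    rows, sample_ids, groups = [], [], []
    for g in ("A", "B"):
        for i in range(cfg.n_samples_per_group):
            sample_ids.append(f"{g}{i + 1:02d}")
            groups.append(g)
            rows.append(rng.multinomial(cfg.reads_per_sample, props[g]))
    counts = pd.DataFrame(np.array(rows), index=sample_ids, columns=leaves)

    covariate = rng.normal(50.0, 10.0, size=len(sample_ids))
    meta = pd.DataFrame(
        {"group": groups, "covariate": covariate},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    table = AbundanceTable(counts, unit="counts")
    if cfg.reads_per_sample == 0:
        table.empty_cohort = True  # all-zero table, flagged for callers
    return table, MetadataTable(meta, {"group": "discrete", "covariate": "numeric"})


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    codes = np.searchsorted(_BASES, arr)
    hit = rng.random(len(arr)) < error_rate
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        codes[hit] = (codes[hit] + shift) % 4
        return "".join(_BASES[codes])
    return seq


def simulate_reads(
    true_counts: AbundanceTable,
    pack: ReferencePack,
    error_rate: float,
    seed: int,
    outdir: str | os.PathLike,
    metadata: MetadataTable | None = None,
) -> tuple[str, str | None]:
    """Write per-sample FASTA reads, a ``seqs.list`` manifest and ``meta.txt``.

    Each read copies its taxon's representative sequence with i.i.d.
    substitutions at ``error_rate``. Read ids encode the true source
    taxon after a ``|`` so downstream accuracy checks need no side table.
    Returns (manifest_path, metadata_path).
    """
    if pack.sequences is None:
        raise ValueError("reference pack has no representative sequences")
    rng = np.random.default_rng(seed)
    outdir = str(outdir)
    sampledir = os.path.join(outdir, "samples")
    os.makedirs(sampledir, exist_ok=True)

    manifest_path = os.path.join(outdir, "seqs.list")
    with open(manifest_path, "w") as mfh:
        for sample in true_counts.sample_ids:
            records = []
            i = 0
            for taxon in true_counts.feature_ids:
                n = int(true_counts.data.at[sample, taxon])
                ref = pack.sequences[taxon]
                for _ in range(n):
                    i += 1
                    records.append(
                        SequenceRecord(f"{sample}_r{i}|{taxon}", _mutate(ref, error_rate, rng))
                    )
            fasta = os.path.join(sampledir, f"{sample}.fasta")
            if records:
                write_fasta(records, fasta)
            else:
                with open(fasta, "w") as fh:  # empty sample placeholder
                    fh.write(f">{sample}_placeholder\n{'N' * 1}\n")
            mfh.write(f"{sample}\t{os.path.join('samples', f'{sample}.fasta')}\n")

    meta_path = None
    if metadata is not None:
        meta_path = os.path.join(outdir, "meta.txt")
        write_metadata(metadata, meta_path)
    return manifest_path, meta_path


def write_metadata(metadata: MetadataTable, path: str | os.PathLike) -> str:
    with open(path, "w") as fh:
        cols = list(metadata.data.columns)
        fh.write("#SampleID\t" + "\t".join(cols) + "\n")
        for sid, row in metadata.data.iterrows():
            vals = []
            for c in cols:
                v = row[c]
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    vals.append("NA")
                elif metadata.kinds[c] == "numeric":
                    vals.append(f"{float(v):.6g}")
                else:
                    vals.append(str(v))
            fh.write(sid + "\t" + "\t".join(vals) + "\n")
    return str(path)


def simulate_input_dir(outdir: str | os.PathLike, cfg: SimulationConfig) -> dict[str, str]:
    """Emit a ready-to-run input directory: refs/, samples/, seqs.list, meta.txt."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    pack = simulate_reference_pack(cfg.n_taxa, cfg.seed)
    refdir = write_reference_pack(pack, os.path.join(outdir, "refs"))
    counts, meta = simulate_cohort(pack, cfg)
    manifest, meta_path = simulate_reads(
        counts, pack, cfg.error_rate, cfg.seed + 1, outdir, metadata=meta
    )
    return {"refs": refdir, "manifest": manifest, "metadata": meta_path or ""}
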