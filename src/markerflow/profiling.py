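"""Read-to-taxon assignment, per-sample profiles, and rank collapsing.

Reads are matched to reference leaves by cosine similarity of k-mer
count vectors (both strands), a deliberately alignment-free stand-in for
a full aligner; a TSV import path lets external assignments be used
instead. Classified counts are copy-number corrected into relative
abundances and can be collapsed to any of the seven taxonomic ranks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    AbundanceTable,
    FormatError,
    RANKS,
    ReferencePack,
    SequenceRecord,
)

__all__ = [
    "UNCLASSIFIED",
    "TaxonAssignment",
    "TaxonomicProfile",
    "KmerClassifier",
    "assign_best_hit",
    "assign_reads",
    "read_assignments",
    "write_assignments",
    "build_profile",
    "collapse_to_level",
    "denoise_reads",
]

UNCLASSIFIED = "UNCLASSIFIED"

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class TaxonAssignment:
    """One read's best-hit call.

    ``leaf_ids`` holds every tied best leaf (empty when unclassified);
    ties are resolved at profile time by splitting the count equally,
    which keeps the taxonomy honest at ``shared_rank`` (the lowest rank
    all tied leaves agree on).
    """

    read_id: str
    leaf_ids: tuple[str, ...]
    identity: float
    shared_rank: str | None = None

    @property
    def leaf_id(self) -> str:
        if not self.leaf_ids:
            return UNCLASSIFIED
        if len(self.leaf_ids) == 1:
            return self.leaf_ids[0]
        return self.shared_rank or ";".join(self.leaf_ids)

    @property
    def classified(self) -> bool:
        return bool(self.leaf_ids)


@dataclass
class TaxonomicProfile:
    """Per-sample classified counts and copy-number-corrected abundances."""

    sample_id: str
    counts: dict[str, float]  # leaf -> classified reads (tie splits -> reals)
    normalized: dict[str, float]  # leaf -> relative abundance after correction
    empty: bool = False

    @property
    def total_count(self) -> float:
        return sum(self.counts.values())


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Encode all k-mers of a sequence as integers; k-mers with N are kept
    (N coded as its own symbol) so they count toward the read's norm."""
    codes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    lut[ord("A")], lut[ord("C")], lut[ord("G")], lut[ord("T")], lut[ord("N")] = 0, 1, 2, 3, 4
    x = lut[codes]
    n = len(x) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for i in range(k):
        out = out * 5 + x[i : i + n]
    return out


class KmerClassifier:
    """Precomputed k-mer index over a pack's representative sequences."""

    def __init__(self, pack: ReferencePack, k: int = 8):
        if pack.sequences is None:
            raise ValueError("reference pack has no representative sequences")
        self.pack = pack
        self.k = k
        self.leaves = pack.leaf_ids
        vocab: dict[int, int] = {}
        rows = []
        for leaf in self.leaves:
            codes, counts = np.unique(_kmer_codes(pack.sequences[leaf], k), return_counts=True)
            cols = np.array([vocab.setdefault(int(c), len(vocab)) for c in codes], dtype=np.int64)
            rows.append((cols, counts.astype(float)))
        self.vocab = vocab
        mat = np.zeros((len(self.leaves), len(vocab)))
        for i, (cols, counts) in enumerate(rows):
            mat[i, cols] = counts
        norms = np.linalg.norm(mat, axis=1)
        norms[norms == 0] = 1.0
        self.matrix = mat / norms[:, None]  # rows unit-L2 over the reference vocab

    def _identity_vector(self, seq: str) -> np.ndarray:
        """Cosine similarity of the read's k-mer counts against every leaf."""
        best = np.zeros(len(self.leaves))
        for s in (seq, reverse_complement(seq)):
            codes, counts = np.unique(_kmer_codes(s, self.k), return_counts=True)
            if len(codes) == 0:
                continue
            norm = float(np.linalg.norm(counts))
            keep = [(self.vocab[int(c)], n) for c, n in zip(codes, counts) if int(c) in self.vocab]
            if not keep:
                continue
            cols, vals = zip(*keep)
            sims = self.matrix[:, list(cols)] @ (np.array(vals, dtype=float) / norm)
            best = np.maximum(best, sims)
        return best

    def assign(self, read: SequenceRecord, min_identity: float = 0.97) -> TaxonAssignment:
        if len(read.sequence) < self.k:
            return TaxonAssignment(read.id, (), 0.0)
        sims = self._identity_vector(read.sequence)
        top = float(sims.max())
        if top < min_identity:
            return TaxonAssignment(read.id, (), top)
        tied = tuple(self.leaves[i] for i in np.flatnonzero(sims >= top - 1e-9))
        shared = None
        if len(tied) > 1:
            shared = _lowest_common_rank(self.pack, tied)
        return TaxonAssignment(read.id, tied, top, shared)


def _lowest_common_rank(pack: ReferencePack, leaves: tuple[str, ...]) -> str:
    """Deepest rank label shared by all the given leaves ('k__...' at worst)."""
    lineages = [pack.lineage(leaf) for leaf in leaves]
    shared = "unassigned"
    for i in range(7):
        labels = {lin[i] for lin in lineages}
        if len(labels) == 1:
            shared = labels.pop()
        else:
            break
    return shared


def _classifier(pack: ReferencePack, k: int) -> KmerClassifier:
    cache = getattr(pack, "_kmer_classifiers", None)
    if cache is None:
        cache = {}
        pack._kmer_classifiers = cache
    if k not in cache:
        cache[k] = KmerClassifier(pack, k)
    return cache[k]


def assign_best_hit(
    read: SequenceRecord, pack: ReferencePack, min_identity: float = 0.97, k: int = 8
) -> TaxonAssignment:
    """Best-hit taxon call for one read (see KmerClassifier for the metric)."""
    return _classifier(pack, k).assign(read, min_identity)


def assign_reads(
    reads: list[SequenceRecord], pack: ReferencePack, min_identity: float = 0.97, k: int = 8
) -> list[TaxonAssignment]:
    clf = _classifier(pack, k)
    return [clf.assign(r, min_identity) for r in reads]


def read_assignments(path: str | os.PathLike) -> list[TaxonAssignment]:
    """Import precomputed assignments: ``read_id<TAB>leaf_id<TAB>identity``."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 'read<TAB>leaf<TAB>identity'")
            read_id, leaf, ident = parts
            try:
                identity = float(ident)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad identity {ident!r}") from exc
            leaves = () if leaf == UNCLASSIFIED else tuple(leaf.split(";"))
            out.append(TaxonAssignment(read_id, leaves, identity))
    return out


def write_assignments(assignments: list[TaxonAssignment], path: str | os.PathLike) -> str:
    with open(path, "w") as fh:
        fh.write("#read_id\tleaf_id\tidentity\n")
        for a in assignments:
            leaf = ";".join(a.leaf_ids) if a.leaf_ids else UNCLASSIFIED
            fh.write(f"{a.read_id}\t{leaf}\t{a.identity:.6g}\n")
    return str(path)


def denoise_reads(reads: list[SequenceRecord]) -> list[SequenceRecord]:
    """Hook for ASV denoising / chimera removal; intentionally a no-op."""
    return reads


def build_profile(
    assignments: list[TaxonAssignment], pack: ReferencePack, sample_id: str = ""
) -> TaxonomicProfile:
    """Accumulate assignments into copy-number-corrected relative abundances.

    Tie splits contribute fractional counts; normalised_i is
    (counts_i / copy_i) / sum_j (counts_j / copy_j).
    """
    counts: dict[str, float] = {}
    for a in assignments:
        if not a.classified:
            continue
        share = 1.0 / len(a.leaf_ids)
        for leaf in a.leaf_ids:
            if leaf not in pack.copy_number:
                raise KeyError(f"assignment references unknown leaf {leaf!r}")
            counts[leaf] = counts.get(leaf, 0.0) + share
    if not counts:
        return TaxonomicProfile(sample_id, {}, {}, empty=True)
    weights = {leaf: c / pack.copy_number[leaf] for leaf, c in counts.items()}
    total = sum(weights.values())
    normalized = {leaf: w / total for leaf, w in weights.items()}
    return TaxonomicProfile(sample_id, counts, normalized)


def collapse_to_level(
    profiles: list[TaxonomicProfile], pack: ReferencePack, level: str
) -> AbundanceTable:
    """Sum leaf abundances into lineage prefixes truncated at ``level``.

    Leaves whose label at that rank is empty (bare "g__" etc.) pool into
    ``Unclassified_<deepest non-empty parent label>``.
    """
    if level not in RANKS:
        raise ValueError(f"level must be one of {RANKS}, got {level!r}")
    depth = RANKS.index(level)
    features: dict[str, dict[str, float]] = {}
    for prof in profiles:
        row = features.setdefault(prof.sample_id, {})
        for leaf, ab in prof.normalized.items():
            lineage = pack.lineage(leaf)
            label = lineage[depth]
            if len(label) <= 3:  # bare prefix like "g__": rank missing
                parent = next(
                    (lineage[i] for i in range(depth - 1, -1, -1) if len(lineage[i]) > 3),
                    "root",
                )
                feature = f"Unclassified_{parent}"
            else:
                feature = ";".join(lineage[: depth + 1])
            row[feature] = row.get(feature, 0.0) + ab
    all_features = sorted({f for row in features.values() for f in row})
    sample_ids = [p.sample_id for p in profiles]
    mat = pd.DataFrame(
        [[features[s].get(f, 0.0) for f in all_features] for s in sample_ids],
        index=sample_ids,
        columns=all_features,
    )
    return AbundanceTable(mat, unit="relative")
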