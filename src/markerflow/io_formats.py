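"""Readers and writers for every on-disk format the pipeline touches.

All dialects are fixed here, in one place: FASTA for reads and reference
sequences, Newick for the reference tree, and TSV for the sample manifest
(``seqs.list``), metadata (``meta.txt``), abundance tables, distance
matrices and the reference-pack side tables.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "FormatError",
    "SequenceRecord",
    "SampleManifest",
    "MetadataTable",
    "AbundanceTable",
    "DistanceMatrix",
    "ReferencePack",
    "RANKS",
    "RANK_PREFIXES",
    "read_fasta",
    "write_fasta",
    "read_manifest",
    "read_metadata",
    "read_reference_pack",
    "read_abundance_table",
    "read_distance_matrix",
    "write_table",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

_VALID_BASES = set("ACGTNU")


class FormatError(ValueError):
    """Malformed input file; message carries the offending path/line."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single named nucleotide sequence (uppercased, U mapped to T)."""

    id: str
    sequence: str


@dataclass
class SampleManifest:
    """Ordered ``(sample_id, fasta_path)`` pairs from a ``seqs.list`` file.

    Sample order here defines the row order of every downstream table.
    """

    entries: list[tuple[str, str]] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class MetadataTable:
    """Per-sample variables, each tagged ``discrete`` or ``numeric``.

    ``data`` is indexed by sample id; numeric columns hold floats with NaN
    for missing, discrete columns hold strings with None/NaN for missing.
    """

    data: pd.DataFrame
    kinds: dict[str, str]  # column -> "discrete" | "numeric"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def variables(self, kind: str | None = None) -> list[str]:
        if kind is None:
            return list(self.data.columns)
        return [c for c in self.data.columns if self.kinds[c] == kind]

    def column(self, name: str) -> pd.Series:
        return self.data[name]


@dataclass
class AbundanceTable:
    """Samples x features matrix of counts or relative abundances."""

    data: pd.DataFrame  # rows = samples, columns = features
    unit: str = "relative"  # "counts" | "relative"

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundance table contains negative entries")
        if self.unit == "relative":
            sums = self.data.to_numpy().sum(axis=1)
            bad = ~(np.isclose(sums, 1.0, atol=1e-6) | (sums == 0))
            if bad.any():
                raise ValueError(
                    "relative abundance rows must sum to 1 (or be all-zero); "
                    f"offending samples: {list(self.data.index[bad])[:5]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances with a fixed sample order."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError(f"distance matrix shape {d.shape} != ({n},{n})")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        if (d < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        self.values = d

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def submatrix(self, ids: Iterable[str]) -> "DistanceMatrix":
        ids = list(ids)
        idx = [self.sample_ids.index(s) for s in ids]
        return DistanceMatrix(ids, self.values[np.ix_(idx, idx)])


@dataclass
class ReferencePack:
    """The reference database every pipeline stage reads.

    tree         rooted tree with named leaves and non-negative branch lengths
    taxonomy     leaf id -> 7-rank lineage "k__..;p__..;...;s__.."
    copy_number  leaf id -> marker-gene copies (positive)
    ko_content   leaves x KO gene-count matrix (non-negative integers)
    hierarchy    KO id -> one or more (level1, level2, level3) pathway paths
    nsti_distance leaf id -> phylogenetic distance to nearest sequenced relative
    sequences    leaf id -> representative marker sequence (optional)
    """

    tree: TreeNode
    taxonomy: dict[str, str]
    copy_number: dict[str, float]
    ko_content: pd.DataFrame
    hierarchy: dict[str, tuple[tuple[str, str, str], ...]]
    nsti_distance: dict[str, float]
    sequences: dict[str, str] | None = None

    @property
    def leaf_ids(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    @property
    def ko_ids(self) -> list[str]:
        return list(self.ko_content.columns)

    def lineage(self, leaf_id: str) -> tuple[str, ...]:
        """Split a leaf's taxonomy string into its 7 rank labels."""
        parts = [p.strip() for p in self.taxonomy[leaf_id].split(";")]
        if len(parts) != 7:
            raise FormatError(f"taxonomy of {leaf_id!r} does not have 7 ranks")
        return tuple(parts)

    def validate(self) -> None:
        leaves = self.leaf_ids
        if len(set(leaves)) != len(leaves):
            raise FormatError("reference tree has duplicate leaf ids")
        for node in self.tree.postorder():
            if node is self.tree:
                continue
            if node.length is None:
                raise FormatError(f"tree edge above {node.name or 'internal node'} lacks a branch length")
            if node.length < 0:
                raise FormatError(f"negative branch length above {node.name or 'internal node'}")
        for leaf in leaves:
            for name, table in (
                ("taxonomy", self.taxonomy),
                ("copy_number", self.copy_number),
                ("nsti_distance", self.nsti_distance),
            ):
                if leaf not in table:
                    raise FormatError(f"leaf {leaf!r} missing from {name}")
            if leaf not in self.ko_content.index:
                raise FormatError(f"leaf {leaf!r} missing from ko_content")
            if self.copy_number[leaf] <= 0:
                raise FormatError(f"copy number of {leaf!r} must be positive")
            if self.nsti_distance[leaf] < 0:
                raise FormatError(f"nsti distance of {leaf!r} must be non-negative")
            self.lineage(leaf)
        for ko, paths in self.hierarchy.items():
            for path in paths:
                if len(path) != 3:
                    raise FormatError(f"hierarchy path of {ko!r} must have exactly 3 levels")


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into records, in file order.

    Lowercase is uppercased, U mapped to T; anything outside {A,C,G,T,N}
    after that mapping is rejected. Duplicate ids and empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    rec_id: str | None = None
    chunks: list[str] = []

    def _flush(lineno: int) -> None:
        nonlocal rec_id, chunks
        if rec_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: record {rec_id!r} has an empty sequence")
        records.append(SequenceRecord(rec_id, seq))
        rec_id, chunks = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                rec_id = line[1:].split()[0] if line[1:].split() else ""
                if not rec_id:
                    raise FormatError(f"{path}:{lineno}: empty sequence id")
                if rec_id in seen:
                    raise FormatError(f"{path}:{lineno}: duplicate sequence id {rec_id!r}")
                seen.add(rec_id)
            else:
                if rec_id is None:
                    raise FormatError(f"{path}:{lineno}: sequence data before first header")
                up = line.upper()
                bad = set(up) - _VALID_BASES
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: invalid character(s) {sorted(bad)} in sequence {rec_id!r}"
                    )
                chunks.append(up.replace("U", "T"))
    _flush(-1)
    if not records:
        raise FormatError(f"{path}: no sequences")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> str:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
    return str(path)


def read_manifest(path: str | os.PathLike) -> SampleManifest:
    """Read a ``seqs.list`` manifest: ``sample_id<TAB>fasta_path`` per line.

    Relative paths are resolved against the manifest's own directory;
    ``#`` lines are comments. Every referenced file must exist.
    """
    base = os.path.dirname(os.path.abspath(path))
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise FormatError(
                    f"{path}:{lineno}: expected 'sample_id<TAB>path', got {line!r}"
                )
            sample_id, fasta = parts
            if sample_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate sample id {sample_id!r}")
            seen.add(sample_id)
            if not os.path.isabs(fasta):
                fasta = os.path.normpath(os.path.join(base, fasta))
            if not os.path.exists(fasta):
                raise FormatError(
                    f"{path}:{lineno}: file {fasta!r} for sample {sample_id!r} does not exist"
                )
            entries.append((sample_id, fasta))
    if not entries:
        raise FormatError(f"{path}: empty manifest")
    return SampleManifest(entries)


_MISSING = {"", "NA", "na", "NaN", "nan", "N/A"}


def _parse_numeric(values: list[str]) -> list[float] | None:
    out: list[float] = []
    any_value = False
    for v in values:
        if v.strip() in _MISSING:
            out.append(math.nan)
            continue
        try:
            x = float(v)
        except ValueError:
            return None
        if not math.isfinite(x):
            return None
        out.append(x)
        any_value = True
    return out if any_value else None


def read_metadata(path: str | os.PathLike, manifest: SampleManifest | None = None) -> MetadataTable:
    """Read a ``meta.txt`` TSV: header row, first column holds sample ids.

    A column is numeric iff every non-missing value parses as a finite
    real; otherwise it is discrete. Missing is an empty cell or "NA".
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty metadata file")
    header = lines[0].split("\t")
    if len(header) < 1:
        raise FormatError(f"{path}:1: empty header")
    columns = header[1:]
    rows: dict[str, list[str]] = {}
    for lineno, line in enumerate(lines[1:], 2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
            )
        sid = parts[0]
        if sid in rows:
            raise FormatError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        rows[sid] = parts[1:]

    if manifest is not None:
        missing = [s for s in manifest.sample_ids if s not in rows]
        if missing:
            raise FormatError(f"{path}: samples missing from metadata: {missing}")
        order = manifest.sample_ids
    else:
        order = list(rows)

    kinds: dict[str, str] = {}
    series: dict[str, list] = {}
    for j, col in enumerate(columns):
        raw = [rows[s][j] for s in order]
        numeric = _parse_numeric(raw)
        if numeric is not None:
            kinds[col] = "numeric"
            series[col] = numeric
        else:
            kinds[col] = "discrete"
            series[col] = [None if v.strip() in _MISSING else v for v in raw]
    data = pd.DataFrame(series, index=pd.Index(order, name="sample_id"), columns=columns)
    return MetadataTable(data, kinds)


def _read_two_column(path: str, value_name: str, cast=float) -> dict[str, float]:
    out: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            key, val = parts
            if key in out:
                raise FormatError(f"{path}:{lineno}: duplicate entry {key!r}")
            try:
                out[key] = cast(val)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad {value_name}: {val!r}") from exc
    return out


def read_reference_pack(dirpath: str | os.PathLike) -> ReferencePack:
    """Load a reference pack directory and validate cross-file consistency.

    Expected files: tree.nwk, taxonomy.tsv, copy_number.tsv, ko_content.tsv,
    hierarchy.tsv, nsti.tsv and (optionally) refs.fasta.
    """
    dirpath = str(dirpath)

    def p(name: str) -> str:
        full = os.path.join(dirpath, name)
        if not os.path.exists(full):
            raise FormatError(f"reference pack is missing {name!r} in {dirpath}")
        return full

    tree = TreeNode.read(p("tree.nwk"), convert_underscores=False)
    if tree.length is None:
        tree.length = 0.0  # root edge defaults to 0

    taxonomy = _read_two_column(p("taxonomy.tsv"), "taxonomy", cast=str)
    copy_number = _read_two_column(p("copy_number.tsv"), "copy number")
    nsti = _read_two_column(p("nsti.tsv"), "NSTI distance")

    ko = pd.read_csv(p("ko_content.tsv"), sep="\t", index_col=0)
    if (ko.to_numpy() < 0).any():
        raise FormatError("ko_content.tsv contains negative counts")

    hierarchy: dict[str, tuple[tuple[str, str, str], ...]] = {}
    hpath = p("hierarchy.tsv")
    with open(hpath) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{hpath}:{lineno}: expected 'KO<TAB>L1<TAB>L2<TAB>L3'")
            hierarchy.setdefault(parts[0], ())
            hierarchy[parts[0]] += ((parts[1], parts[2], parts[3]),)

    sequences = None
    refs = os.path.join(dirpath, "refs.fasta")
    if os.path.exists(refs):
        sequences = {r.id: r.sequence for r in read_fasta(refs)}

    pack = ReferencePack(tree, taxonomy, copy_number, ko, hierarchy, nsti, sequences)
    pack.validate()
    return pack


def write_reference_pack(pack: ReferencePack, dirpath: str | os.PathLike) -> str:
    """Write a reference pack as the directory layout read_reference_pack expects."""
    dirpath = str(dirpath)
    os.makedirs(dirpath, exist_ok=True)
    pack.tree.write(os.path.join(dirpath, "tree.nwk"))
    leaves = pack.leaf_ids
    with open(os.path.join(dirpath, "taxonomy.tsv"), "w") as fh:
        for leaf in leaves:
            fh.write(f"{leaf}\t{pack.taxonomy[leaf]}\n")
    with open(os.path.join(dirpath, "copy_number.tsv"), "w") as fh:
        for leaf in leaves:
            fh.write(f"{leaf}\t{_fmt(pack.copy_number[leaf])}\n")
    with open(os.path.join(dirpath, "nsti.tsv"), "w") as fh:
        for leaf in leaves:
            fh.write(f"{leaf}\t{_fmt(pack.nsti_distance[leaf])}\n")
    pack.ko_content.loc[leaves].to_csv(os.path.join(dirpath, "ko_content.tsv"), sep="\t")
    with open(os.path.join(dirpath, "hierarchy.tsv"), "w") as fh:
        for ko in sorted(pack.hierarchy):
            for path in pack.hierarchy[ko]:
                fh.write(ko + "\t" + "\t".join(path) + "\n")
    if pack.sequences:
        write_fasta(
            (SequenceRecord(leaf, pack.sequences[leaf]) for leaf in leaves),
            os.path.join(dirpath, "refs.fasta"),
        )
    return dirpath


# ---------------------------------------------------------------------------
# table writers / readers (6 significant digits, TSV)


def _fmt(x: float) -> str:
    return f"{float(x):.6g}"


def write_table(table: AbundanceTable | DistanceMatrix | pd.DataFrame, path: str | os.PathLike) -> str:
    """Write an abundance table or distance matrix as TSV.

    Row/column order equals the stored order; reals are written with 6
    significant digits, so a round trip through the matching reader
    reproduces values to within 1e-6.
    """
    if isinstance(table, AbundanceTable):
        df = table.data
    elif isinstance(table, DistanceMatrix):
        df = table.to_dataframe()
    else:
        df = table
    with open(path, "w") as fh:
        fh.write("#ID\t" + "\t".join(map(str, df.columns)) + "\n")
        for idx, row in zip(df.index, df.to_numpy()):
            fh.write(str(idx) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")
    return str(path)


def _read_matrix(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return df


def read_abundance_table(path: str | os.PathLike, unit: str = "relative") -> AbundanceTable:
    df = _read_matrix(str(path))
    if unit == "relative":
        sums = df.to_numpy().sum(axis=1)
        nz = sums > 0
        df.loc[nz] = df.loc[nz].div(sums[nz], axis=0)  # repair 6-digit rounding drift
    return AbundanceTable(df, unit=unit)


def read_distance_matrix(path: str | os.PathLike) -> DistanceMatrix:
    df = _read_matrix(str(path))
    d = df.to_numpy(dtype=float)
    d = (d + d.T) / 2.0  # symmetrize rounding drift
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(df.index), d)
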