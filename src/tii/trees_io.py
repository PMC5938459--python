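"""Tree and matrix I/O plus the core unrooted-topology type.

All trees are handled as unrooted leaf-labeled topologies: rooted input has
its degree-2 root suppressed on read, and topological identity is the
canonical set of nontrivial bipartitions (branch lengths ignored).  Parsing
of newick and NEXUS (including MrBayes-style ``.t`` files with translate
tables, and sequential/interleaved character blocks) is delegated to
dendropy; this module owns validation, label normalization, burn-in
handling, and the lightweight in-memory representations the distance
kernels operate on.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

from .errors import ArgumentError, TaxonLookupError, TreeFormatError, ValidationError

__all__ = [
    "Topology",
    "CharacterMatrix",
    "read_trees",
    "write_trees",
    "read_character_matrix",
    "write_character_matrix",
    "write_jackknife_matrices",
    "read_ranking",
    "write_ranking",
]

_WS = re.compile(r"\s+")

# characters that force quoting when writing newick labels
_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}/\\,;:=*'\"`+<>]")


def normalize_label(label: str) -> str:
    """Strip surrounding whitespace and collapse internal whitespace to ``_``."""
    return _WS.sub("_", label.strip())


class Topology:
    """An unrooted leaf-labeled tree with optional branch lengths.

    Nodes are small integers; leaves carry unique nonempty string labels.
    Two topologies compare equal iff their leaf sets and canonical
    nontrivial bipartition sets coincide — branch lengths never affect
    identity or hashing.

    Parameters
    ----------
    adjacency:
        Mapping node -> iterable of neighbor nodes (symmetric).
    leaf_labels:
        Mapping leaf node -> taxon label.
    edge_lengths:
        Optional mapping frozenset({u, v}) -> nonnegative length, one entry
        per edge.  Either every edge has a length or none does.
    """

    __slots__ = ("_adj", "_leaves", "_lengths", "_splits", "_hash")

    def __init__(
        self,
        adjacency: dict[int, Iterable[int]],
        leaf_labels: dict[int, str],
        edge_lengths: dict[frozenset, float] | None = None,
    ):
        adj = {node: tuple(nbrs) for node, nbrs in adjacency.items()}
        adj, leaf_labels, edge_lengths = _suppress_degree_two(adj, leaf_labels, edge_lengths)
        self._adj = adj
        self._leaves = dict(leaf_labels)
        self._lengths = dict(edge_lengths) if edge_lengths is not None else None
        self._splits = None
        self._hash = None
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Topology":
        """Parse a single newick string (rooted input is unrooted)."""
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several DataError flavors
            raise TreeFormatError(f"cannot parse newick tree: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "Topology":
        adjacency: dict[int, list[int]] = {}
        leaf_labels: dict[int, str] = {}
        lengths: dict[frozenset, float] = {}
        ids: dict[int, int] = {}
        all_lengths_present = True

        def nid(node) -> int:
            key = id(node)
            if key not in ids:
                ids[key] = len(ids)
                adjacency[ids[key]] = []
            return ids[key]

        for node in dtree.preorder_node_iter():
            u = nid(node)
            if node.is_leaf():
                label = node.taxon.label if node.taxon else (node.label or "")
                leaf_labels[u] = normalize_label(label)
            for child in node.child_nodes():
                v = nid(child)
                adjacency[u].append(v)
                adjacency[v].append(u)
                if child.edge.length is None:
                    all_lengths_present = False
                else:
                    lengths[frozenset((u, v))] = float(child.edge.length)
        return cls(adjacency, leaf_labels, lengths if all_lengths_present else None)

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        labels = list(self._leaves.values())
        if any(not lab for lab in labels):
            raise ValidationError("leaf labels must be nonempty strings")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate leaf labels: {dupes}")
        if len(labels) < 3:
            raise ValidationError(
                f"a topology needs at least 3 leaves, got {len(labels)}"
            )
        for node, nbrs in self._adj.items():
            deg = len(nbrs)
            if node in self._leaves:
                if deg != 1:
                    raise ValidationError(f"leaf node {node} has degree {deg}")
            elif deg < 3:
                raise ValidationError(f"internal node {node} has degree {deg} < 3")
        if self._lengths is not None:
            edges = self._edge_set()
            if set(self._lengths) != edges:
                raise ValidationError("edge_lengths must cover every edge exactly")
            if any(v < 0 or math.isnan(v) for v in self._lengths.values()):
                raise ValidationError("branch lengths must be nonnegative")

    def _edge_set(self) -> set[frozenset]:
        return {
            frozenset((u, v)) for u, nbrs in self._adj.items() for v in nbrs if u < v
        }

    # -- basic accessors ----------------------------------------------

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(self._leaves.values())

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    @property
    def has_branch_lengths(self) -> bool:
        return self._lengths is not None

    def adjacency(self) -> dict[int, tuple[int, ...]]:
        """A copy of the node adjacency mapping."""
        return dict(self._adj)

    def leaves(self) -> dict[int, str]:
        """A copy of the leaf-node -> label mapping."""
        return dict(self._leaves)

    def is_binary(self) -> bool:
        return all(
            len(nbrs) == 3 for n, nbrs in self._adj.items() if n not in self._leaves
        )

    # -- bipartitions --------------------------------------------------

    def _directed_subtree_labels(self) -> dict[tuple[int, int], frozenset]:
        """For each directed edge (u, v): labels in the subtree on the v side,
        computed rooting at the reference (min-label) leaf."""
        ref = min(self._leaves, key=self._leaves.get)
        out: dict[tuple[int, int], frozenset] = {}
        # iterative postorder from ref
        stack = [(ref, None, False)]
        while stack:
            node, parent, processed = stack.pop()
            if not processed:
                stack.append((node, parent, True))
                for nbr in self._adj[node]:
                    if nbr != parent:
                        stack.append((nbr, node, False))
            else:
                if node in self._leaves and node != ref:
                    labs = frozenset((self._leaves[node],))
                else:
                    labs = frozenset().union(
                        *(out[(node, nbr)] for nbr in self._adj[node] if nbr != parent)
                    )
                if parent is not None:
                    out[(parent, node)] = labs
        return out

    def splits(self) -> frozenset:
        """Canonical nontrivial bipartitions: each as the frozenset of labels
        on the side NOT containing the reference (min) leaf."""
        if self._splits is None:
            n = self.n_leaves
            sub = self._directed_subtree_labels()
            self._splits = frozenset(
                labs for labs in sub.values() if 1 < len(labs) < n - 1
            )
        return self._splits

    def split_lengths(self) -> dict[frozenset, float]:
        """Branch length for every bipartition (trivial ones included), keyed
        by the canonical label-side.  Requires branch lengths."""
        if self._lengths is None:
            raise ArgumentError("topology carries no branch lengths")
        sub = self._directed_subtree_labels()
        out: dict[frozenset, float] = {}
        for (u, v), labs in sub.items():
            out[labs] = self._lengths[frozenset((u, v))]
        # pendant edge of the reference leaf: its canonical side is everything else
        ref = min(self._leaves, key=self._leaves.get)
        (nbr,) = self._adj[ref]
        out[frozenset(self.leaf_labels - {self._leaves[ref]})] = self._lengths[
            frozenset((ref, nbr))
        ]
        return out

    # -- identity ------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return self.leaf_labels == other.leaf_labels and self.splits() == other.splits()

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash((self.leaf_labels, self.splits()))
        return self._hash

    def __repr__(self) -> str:
        return f"<Topology n_leaves={self.n_leaves} {self.to_newick(include_lengths=False)!r}>"

    # -- manipulation --------------------------------------------------

    def prune(self, label: str) -> "Topology":
        """Remove one leaf; the incident edge goes with it, the resulting
        degree-2 node is suppressed (merged edge lengths summed)."""
        matches = [n for n, lab in self._leaves.items() if lab == label]
        if not matches:
            raise TaxonLookupError(f"taxon {label!r} not in tree")
        if self.n_leaves < 4:
            raise ArgumentError("cannot prune a leaf from a 3-leaf topology")
        leaf = matches[0]
        adj = {n: list(nbrs) for n, nbrs in self._adj.items()}
        lengths = dict(self._lengths) if self._lengths is not None else None
        (nbr,) = adj.pop(leaf)
        adj[nbr].remove(leaf)
        if lengths is not None:
            lengths.pop(frozenset((leaf, nbr)))
        leaves = {n: lab for n, lab in self._leaves.items() if n != leaf}
        return Topology(adj, leaves, lengths)

    # -- serialization -------------------------------------------------

    def to_newick(self, include_lengths: bool = True) -> str:
        """Unrooted newick, written from the internal node adjacent to the
        lexicographically first leaf (deterministic)."""
        ref = min(self._leaves, key=self._leaves.get)
        (start,) = self._adj[ref]
        use_lengths = include_lengths and self._lengths is not None

        def fmt_label(lab: str) -> str:
            return f"'{lab}'" if _NEWICK_UNSAFE.search(lab) else lab

        def emit(node: int, parent: int | None) -> str:
            if node in self._leaves:
                s = fmt_label(self._leaves[node])
            else:
                kids = [emit(nbr, node) for nbr in self._adj[node] if nbr != parent]
                s = "(" + ",".join(kids) + ")"
            if use_lengths and parent is not None:
                s += f":{self._lengths[frozenset((node, parent))]:.10g}"
            return s

        return emit(start, None) + ";"


def _suppress_degree_two(adj, leaf_labels, lengths):
    """Remove unlabeled degree-2 nodes (e.g. a rooted tree's root), merging
    their two incident edges and summing lengths when present."""
    adj = {n: list(nbrs) for n, nbrs in adj.items()}
    changed = True
    while changed:
        changed = False
        for node in list(adj):
            if node in leaf_labels or len(adj[node]) != 2:
                continue
            a, b = adj[node]
            adj[a] = [x if x != node else b for x in adj[a]]
            adj[b] = [x if x != node else a for x in adj[b]]
            del adj[node]
            if lengths is not None:
                la = lengths.pop(frozenset((node, a)))
                lb = lengths.pop(frozenset((node, b)))
                lengths[frozenset((a, b))] = la + lb
            changed = True
    return {n: tuple(v) for n, v in adj.items()}, leaf_labels, lengths


# ---------------------------------------------------------------------------
# tree files


def read_trees(
    path,
    format: str = "newick",
    burnin: float = 0.0,
    burnin_count: int | None = None,
) -> list[Topology]:
    """Read a posterior tree sample, discarding a burn-in prefix.

    Parameters
    ----------
    path:
        Newick file (one tree per line / per ``;``) or NEXUS trees block;
        MrBayes ``.t`` files with translate tables are supported, and the
        translate table is applied so trees carry full taxon names.
    format:
        ``"newick"`` or ``"nexus"``.
    burnin:
        Fraction in [0, 1): the first ``floor(burnin * N)`` trees are
        discarded.  MCMC burn-in stated in generations maps directly to a
        fraction of the sampled trees.
    burnin_count:
        Alternative count-based burn-in; overrides ``burnin`` when given.
    """
    if format not in ("newick", "nexus"):
        raise ArgumentError(f"unknown tree format {format!r}")
    if not 0.0 <= burnin < 1.0:
        raise ArgumentError(f"burnin must be a fraction in [0, 1), got {burnin}")
    try:
        tree_list = dendropy.TreeList.get(
            path=str(path), schema=format, preserve_underscores=True
        )
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise TreeFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    topologies = [Topology.from_dendropy(t) for t in tree_list]
    n = len(topologies)
    drop = burnin_count if burnin_count is not None else int(burnin * n)
    if burnin_count is not None and not 0 <= burnin_count <= n:
        raise ArgumentError(f"burnin_count {burnin_count} outside [0, {n}]")
    return topologies[drop:]


def write_trees(topologies: Sequence[Topology], path, include_lengths: bool = True):
    """Write trees as newick, one per line.  Returns the path."""
    path = Path(path)
    with path.open("w") as fh:
        for topo in topologies:
            fh.write(topo.to_newick(include_lengths=include_lengths) + "\n")
    return path


# ---------------------------------------------------------------------------
# character matrices


@dataclass(frozen=True)
class CharacterMatrix:
    """A taxa x characters table of state symbols.

    ``"?"`` is the missing code and ``"-"`` the gap/inapplicable code; all
    other symbols form the declared state set.  Rows are stored verbatim.
    """

    taxa: tuple
    rows: tuple  # tuple of tuples of symbol strings
    datatype: str = "standard"
    symbols: frozenset = field(default=frozenset())

    def __post_init__(self):
        if len(self.taxa) != len(set(self.taxa)):
            raise ValidationError("taxon names must be unique")
        if len(self.taxa) != len(self.rows):
            raise ValidationError("one row per taxon required")
        if self.rows:
            ncols = len(self.rows[0])
            if any(len(r) != ncols for r in self.rows):
                raise ValidationError("ragged rows: all taxa need equal-length rows")
        if not self.symbols:
            observed = {s for row in self.rows for s in row} - {"?", "-"}
            object.__setattr__(self, "symbols", frozenset(observed))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> tuple:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise TaxonLookupError(f"taxon {taxon!r} not in matrix") from None

    def drop(self, taxon: str) -> "CharacterMatrix":
        if taxon not in self.taxa:
            raise TaxonLookupError(f"taxon {taxon!r} not in matrix")
        keep = [i for i, t in enumerate(self.taxa) if t != taxon]
        return CharacterMatrix(
            taxa=tuple(self.taxa[i] for i in keep),
            rows=tuple(self.rows[i] for i in keep),
            datatype=self.datatype,
            symbols=self.symbols,
        )


def read_character_matrix(path) -> CharacterMatrix:
    """Read the first data/characters block of a NEXUS file (sequential or
    interleaved); symbols are preserved verbatim, including ``?`` and ``-``."""
    try:
        ds = dendropy.DataSet.get(path=str(path), schema="nexus")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise TreeFormatError(f"cannot parse {path} as nexus: {exc}") from exc
    if not ds.char_matrices:
        raise TreeFormatError(f"{path}: no data/characters block found")
    cm = ds.char_matrices[0]
    datatype = "dna" if isinstance(cm, dendropy.DnaCharacterMatrix) else "standard"
    taxa, rows = [], []
    for taxon in cm.taxon_namespace:
        if taxon not in cm:
            raise ValidationError(f"taxon {taxon.label!r} declared but has no row")
        taxa.append(normalize_label(taxon.label))
        rows.append(tuple(str(cell) for cell in cm[taxon]))
    return CharacterMatrix(taxa=tuple(taxa), rows=tuple(rows), datatype=datatype)


def write_character_matrix(matrix: CharacterMatrix, path):
    """Write a NEXUS data block (sequential)."""
    path = Path(path)
    lines = ["#NEXUS", "BEGIN DATA;"]
    lines.append(f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};")
    if matrix.datatype == "dna":
        fmt = "    FORMAT DATATYPE=DNA MISSING=? GAP=-;"
    else:
        syms = "".join(sorted(matrix.symbols))
        fmt = f'    FORMAT DATATYPE=STANDARD SYMBOLS="{syms}" MISSING=? GAP=-;'
    lines.append(fmt)
    lines.append("    MATRIX")
    width = max(len(t) for t in matrix.taxa) + 2
    for taxon, row in zip(matrix.taxa, matrix.rows):
        lines.append(f"    {taxon:<{width}}{''.join(row)}")
    lines.extend(["    ;", "END;", ""])
    path.write_text("\n".join(lines))
    return path


def write_jackknife_matrices(matrix: CharacterMatrix, outdir) -> list:
    """Write one NEXUS file per taxon, each dropping that taxon (leave-one-out
    jackknife inputs for re-inference).  File names encode the dropped taxon."""
    if matrix.n_taxa < 4:
        raise ArgumentError(
            f"jackknife matrices need at least 4 taxa, got {matrix.n_taxa}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for taxon in matrix.taxa:
        safe = re.sub(r"[^A-Za-z0-9_.-]", "_", taxon)
        paths.append(write_character_matrix(matrix.drop(taxon), outdir / f"minus_{safe}.nex"))
    return paths


# ---------------------------------------------------------------------------
# ranking files


def write_ranking(ranking, path):
    """Write a ranking as TSV (columns: taxon, score, rank).  Scores carry 17
    significant digits so the round trip preserves ordering exactly."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("taxon\tscore\trank\n")
        for rank, (taxon, score) in enumerate(ranking.entries, start=1):
            fh.write(f"{taxon}\t{score:.17g}\t{rank}\n")
    return path


def read_ranking(path):
    """Read a TSV ranking written by :func:`write_ranking`."""
    from .influence import Ranking  # local import: Ranking lives with the index

    try:
        df = pd.read_csv(
            path, sep="\t", dtype={"taxon": str}, float_precision="round_trip"
        )
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise TreeFormatError(f"cannot parse ranking TSV {path}: {exc}") from exc
    if not {"taxon", "score", "rank"}.issubset(df.columns):
        raise TreeFormatError(
            f"{path}: ranking TSV needs columns taxon, score, rank"
        )
    df = df.sort_values("rank")
    return Ranking(entries=tuple(zip(df["taxon"], df["score"].astype(float))))
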