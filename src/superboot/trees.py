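"""Unrooted tree handling: newick I/O, bipartitions, bootstrap supports.

Trees are `dendropy.Tree` objects; all topology comparison is unrooted
and goes through canonical bipartitions (splits).  A bipartition is
represented by the canonical side of the split: the smaller side, with a
lexicographic tie-break when both sides have equal size.  Trivial splits
(a single leaf against the rest) carry no information and are excluded
everywhere.

Two supports are computed against a replicate tree set R:

* topology support — the fraction of replicates whose unrooted topology
  is identical to the reference (Robinson–Foulds distance 0);
* clade support — per non-trivial reference split, the fraction of
  replicates whose split set contains it.

Tree inference is provided as a self-contained neighbor-joining fallback
on p-distances (deterministic tie-break, intended for testing) plus an
adapter that shells out to any external inference command.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .alignments import GAP, Alignment, write_alignment

logger = logging.getLogger("superboot")

PhyloTree = dendropy.Tree
Bipartition = frozenset  # canonical side of a split, as taxon labels


class TreeError(ValueError):
    """Raised on malformed trees or incompatible leaf sets."""


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse one newick tree; duplicate or empty leaf labels are errors.

    Rooted inputs are handled transparently: every comparison in this
    package is unrooted, so a root bifurcation simply contributes the
    same split twice and is de-duplicated.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"newick parse error: {exc}") from exc
    labels = leaf_labels(tree)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate leaf labels: {', '.join(dupes)}")
    if any(not l for l in labels):
        raise TreeError("empty leaf label")
    tree.is_rooted = False
    return tree


def write_newick(tree: PhyloTree) -> str:
    """Serialize to newick (supports stay as internal-node labels)."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def read_trees(path: str | Path) -> list[PhyloTree]:
    """Read a file with one newick tree per line."""
    trees = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            trees.append(parse_newick(line))
    return trees


def leaf_labels(tree: PhyloTree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def leaf_set(tree: PhyloTree) -> frozenset:
    return frozenset(leaf_labels(tree))


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------

def canonical_split(side: Iterable[str], taxa: frozenset) -> Bipartition:
    """Canonical representative of a split: smaller side, lexicographic
    tie-break; idempotent and complement-invariant."""
    side = frozenset(side)
    other = taxa - side
    if not side or not other:
        raise TreeError("a split must divide the taxon set into two non-empty parts")
    if len(side) != len(other):
        return side if len(side) < len(other) else other
    return side if tuple(sorted(side)) < tuple(sorted(other)) else other


def bipartitions(tree: PhyloTree) -> set[Bipartition]:
    """Non-trivial splits induced by the internal edges of an unrooted tree.

    A fully resolved n-leaf tree yields exactly n - 3; trees with fewer
    than 4 leaves (or a star topology) yield the empty set.
    """
    taxa = leaf_set(tree)
    n = len(taxa)
    if n < 4:
        return set()
    splits: set[Bipartition] = set()
    seed_root = tree.seed_node
    for node in tree.preorder_node_iter():
        if node is seed_root or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(side) <= n - 2:
            splits.add(canonical_split(side, taxa))
    return splits


def _require_same_leaves(reference: PhyloTree, others: Sequence[PhyloTree]) -> None:
    ref = leaf_set(reference)
    for t in others:
        other = leaf_set(t)
        if other != ref:
            missing = sorted(ref - other)
            extra = sorted(other - ref)
            parts = []
            if missing:
                parts.append(f"missing taxa: {', '.join(missing)}")
            if extra:
                parts.append(f"unexpected taxa: {', '.join(extra)}")
            raise TreeError("leaf-set mismatch; " + "; ".join(parts))


# ---------------------------------------------------------------------------
# Bootstrap supports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SupportReport:
    """Topology- and clade-level bootstrap supports (fractions in [0, 1])."""

    tree_support: float
    clade_supports: dict
    replicate_count: int


def topology_support(reference: PhyloTree, replicates: Sequence[PhyloTree]) -> float:
    """Fraction of replicates topologically identical to the reference.

    Identity means equal non-trivial split sets (unrooted RF distance 0);
    a polytomous replicate never matches a fully resolved reference.
    """
    if not replicates:
        raise TreeError("empty replicate list")
    _require_same_leaves(reference, replicates)
    ref_splits = bipartitions(reference)
    hits = sum(1 for t in replicates if bipartitions(t) == ref_splits)
    return hits / len(replicates)


def clade_supports(reference: PhyloTree, replicates: Sequence[PhyloTree]) -> SupportReport:
    """Per-clade support: fraction of replicates containing each
    non-trivial reference split (plus the whole-topology support)."""
    if not replicates:
        raise TreeError("empty replicate list")
    _require_same_leaves(reference, replicates)
    ref_splits = bipartitions(reference)
    counts = {s: 0 for s in ref_splits}
    identical = 0
    for t in replicates:
        rep_splits = bipartitions(t)
        if rep_splits == ref_splits:
            identical += 1
        for s in ref_splits:
            if s in rep_splits:
                counts[s] += 1
    n = len(replicates)
    return SupportReport(
        tree_support=identical / n,
        clade_supports={s: c / n for s, c in counts.items()},
        replicate_count=n,
    )


def annotate_supports(tree: PhyloTree, supports: Mapping[Bipartition, float]) -> PhyloTree:
    """Write clade supports (x100, on the 0-100 scale) onto internal node
    labels of a copy of the tree."""
    out = tree.clone(depth=1)
    taxa = leaf_set(out)
    for node in out.preorder_node_iter():
        if node is out.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(side) <= len(taxa) - 2:
            split = canonical_split(side, taxa)
            if split in supports:
                node.label = f"{100.0 * supports[split]:g}"
    return out


# ---------------------------------------------------------------------------
# Tree inference
# ---------------------------------------------------------------------------

def p_distance_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise p-distances (mismatches / jointly non-gap sites).

    Sites where either sequence is gapped are ignored; a pair with no
    jointly non-gap site is an error.
    """
    mat = aln.char_matrix()
    nongap = mat != GAP
    n = aln.n_sequences
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            m = both.sum()
            if m == 0:
                raise TreeError(
                    f"sequences {aln.ids[i]!r} and {aln.ids[j]!r} share no "
                    "jointly non-gap site"
                )
            d[i, j] = d[j, i] = (mat[i, both] != mat[j, both]).mean()
    return d


def nj_from_distance(d: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Neighbor joining on an explicit distance matrix.

    Deterministic: when the Q-criterion minimum is attained by several
    pairs, the pair with the smallest (row, column) indices is joined.
    Negative branch-length estimates are clamped to 0.
    """
    n = len(labels)
    if n < 4:
        raise TreeError("neighbor joining needs at least 4 sequences")
    d = np.array(d, dtype=float)
    active = list(range(n))
    subtrees = {i: labels[i] for i in range(n)}

    def fmt(name: str, length: float) -> str:
        return f"{name}:{max(length, 0.0):.10g}"

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for c in active:
            if c in (i, j):
                continue
            d[new, c] = d[c, new] = 0.5 * (d[i, c] + d[j, c] - dij)
        subtrees[new] = f"({fmt(subtrees[i], li)},{fmt(subtrees[j], lj)})"
        active = [c for c in active if c not in (i, j)] + [new]

    # final unrooted join of the last three subtrees
    x, y, z = active
    lx = 0.5 * (d[x, y] + d[x, z] - d[y, z])
    ly = 0.5 * (d[x, y] + d[y, z] - d[x, z])
    lz = 0.5 * (d[x, z] + d[y, z] - d[x, y])
    newick = f"({fmt(subtrees[x], lx)},{fmt(subtrees[y], ly)},{fmt(subtrees[z], lz)});"
    return parse_newick(newick)


def nj_tree(aln: Alignment) -> PhyloTree:
    """Neighbor-joining tree from p-distances.

    A self-contained fallback for testing pipelines; no distance
    correction is applied, so it is not a substitute for model-based
    inference on real data.
    """
    return nj_from_distance(p_distance_matrix(aln), aln.ids)


def infer_external(aln: Alignment, command_template: str) -> PhyloTree:
    """Run an external tree-inference command on an alignment.

    ``command_template`` must contain ``{input}`` and ``{output}``
    placeholders; the alignment is written as FASTA, the command run
    through the shell, and the output parsed as newick.  The exact
    command line is logged.
    """
    if "{input}" not in command_template or "{output}" not in command_template:
        raise ValueError("command template must contain {input} and {output}")
    with tempfile.TemporaryDirectory(prefix="superboot_") as tmp:
        inp = Path(tmp) / "input.fasta"
        out = Path(tmp) / "output.nwk"
        write_alignment(aln, inp, "fasta")
        cmd = command_template.format(input=inp, output=out)
        logger.info("running external inference: %s", cmd)
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise TreeError(
                f"external command failed (exit {proc.returncode}): "
                f"{cmd}\nstderr: {proc.stderr.strip()}"
            )
        if not out.exists() or not out.read_text().strip():
            raise TreeError(
                f"external command produced no tree: {cmd}\n"
                f"stderr: {proc.stderr.strip()}"
            )
        return parse_newick(out.read_text())
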