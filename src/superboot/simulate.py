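"""Self-contained synthetic fixtures: evolve sequences, perturb alignments.

The generator provides everything an end-to-end bootstrap test needs
without external aligners or simulators: a known true tree, sequences
evolved along it with a uniform-rate substitution process and simple
single-site indels (so the true alignment is known exactly), and a set
of *alternative* alignments obtained by randomly shifting gap blocks of
the true alignment.  Gap-block shifting preserves every ungapped
sequence, so the variants behave exactly like the outputs of different
aligners run on the same input, with the mutual column agreement
controlled by the shift rate.

What this does NOT emulate: among-site rate heterogeneity, realistic
indel length distributions, empirical substitution matrices, or the
systematic (non-random) disagreement patterns of real aligners.  Green
tests on these fixtures establish that the machinery is correct, not
that any biological benchmark is reproduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignments import GAP, Alignment
from .trees import PhyloTree, parse_newick

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of the substitution/indel process.

    Branch lengths of ``tree`` are expected substitutions per site.  A
    site experiences at least one substitution event on a branch of
    length b with probability 1 - exp(-b); given an event the new
    residue is drawn uniformly from the whole alphabet (it may equal the
    parent residue), so the per-site parent-child match probability
    tends to 1/|alphabet| on long branches.  Indels are single-site:
    per branch each site is deleted with probability indel_rate/2 and a
    new site is inserted after each position with probability
    indel_rate/2.
    """

    tree: PhyloTree
    root_length: int = 150
    alphabet: str = AMINO_ACIDS
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_length < 1:
            raise ValueError("root_length must be >= 1")
        if not 0 <= self.indel_rate < 1:
            raise ValueError("indel_rate must lie in [0, 1)")
        if len(self.alphabet) < 2:
            raise ValueError("alphabet needs at least 2 residues")


@dataclass(frozen=True)
class PerturbationConfig:
    """Parameters of alternative-alignment generation.

    ``gap_shift_rate`` is the per-gap-block probability of being shifted
    by one column (direction random); 0 reproduces the input exactly and
    higher rates lower the expected pairwise column similarity.
    """

    gap_shift_rate: float = 0.2
    n_variants: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gap_shift_rate <= 1:
            raise ValueError("gap_shift_rate must lie in [0, 1]")
        if self.n_variants < 2:
            raise ValueError("need at least 2 variants")


def evolve(config: EvolutionConfig) -> tuple[Alignment, PhyloTree]:
    """Evolve sequences along the tree; return the exact true alignment.

    Sites carry persistent identities, so homology is tracked through
    substitutions, deletions and insertions and the returned alignment
    is the true one by construction.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = list(config.alphabet)
    k = len(alphabet)

    # global column order; each site has a unique id, inserted sites are
    # spliced next to their neighbour so every lineage's local order is a
    # subsequence of the global order
    root_seq = [(uid, alphabet[rng.integers(k)]) for uid in range(config.root_length)]
    columns: list[int] = [uid for uid, _ in root_seq]
    next_uid = config.root_length
    leaf_chars: dict[str, dict[int, str]] = {}
    leaf_order: list[str] = []

    def descend(node, seq: list[tuple[int, str]]) -> None:
        nonlocal next_uid
        if node.is_leaf():
            leaf_order.append(node.taxon.label)
            leaf_chars[node.taxon.label] = dict(seq)
            return
        for child in node.child_nodes():
            b = child.edge.length or 0.0
            p_sub = 1.0 - math.exp(-b)
            child_seq: list[tuple[int, str]] = []
            for uid, ch in seq:
                if rng.random() < p_sub:
                    ch = alphabet[rng.integers(k)]
                child_seq.append((uid, ch))
            if config.indel_rate > 0:
                half = config.indel_rate / 2.0
                surviving = [
                    sc for sc in child_seq if not (len(child_seq) > 1 and rng.random() < half)
                ]
                child_seq = surviving or child_seq[:1]
                with_insertions: list[tuple[int, str]] = []
                for uid, ch in child_seq:
                    with_insertions.append((uid, ch))
                    if rng.random() < half:
                        new = (next_uid, alphabet[rng.integers(k)])
                        next_uid += 1
                        columns.insert(columns.index(uid) + 1, new[0])
                        with_insertions.append(new)
                child_seq = with_insertions
            descend(child, child_seq)

    descend(config.tree.seed_node, root_seq)

    used = set().union(*(set(c) for c in leaf_chars.values()))
    kept = [uid for uid in columns if uid in used]
    rows = [
        "".join(leaf_chars[taxon].get(uid, GAP) for uid in kept)
        for taxon in leaf_order
    ]
    return Alignment(leaf_order, rows, label="true"), config.tree


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """Maximal gap runs as half-open (start, end) intervals."""
    runs = []
    start = None
    for i, ch in enumerate(row + "x"):  # sentinel terminates a final run
        if ch == GAP and start is None:
            start = i
        elif ch != GAP and start is not None:
            runs.append((start, i))
            start = None
    return runs


def _shift_block(row: str, start: int, end: int, direction: int) -> str:
    """Swap a gap block with the adjacent residue; no-op at the edge."""
    if direction < 0:
        if start == 0 or row[start - 1] == GAP:
            return row
        return row[: start - 1] + row[start:end] + row[start - 1] + row[end:]
    if end >= len(row) or row[end] == GAP:
        return row
    return row[:start] + row[end] + row[start:end] + row[end + 1:]


def _drop_all_gap_columns(ids, rows):
    keep = [c for c in range(len(rows[0])) if any(r[c] != GAP for r in rows)]
    return ["".join(r[c] for c in keep) for r in rows]


def perturb_alignment(truth: Alignment, config: PerturbationConfig) -> list[Alignment]:
    """Derive alternative MSAs of the same sequences by gap-block shifts.

    Each variant independently shifts each maximal gap run of each row
    by one column with probability ``gap_shift_rate``; all-gap columns
    created in the process are dropped.  Ungapped sequences are
    preserved, so ``check_same_sequences`` holds over truth + variants.
    """
    rng = np.random.default_rng(config.seed)
    variants = []
    for v in range(config.n_variants):
        rows = []
        for row in truth.rows:
            for start, end in _gap_runs(row):
                if rng.random() < config.gap_shift_rate:
                    direction = 1 if rng.random() < 0.5 else -1
                    row = _shift_block(row, start, end, direction)
            rows.append(row)
        rows = _drop_all_gap_columns(truth.ids, rows)
        variants.append(Alignment(truth.ids, rows, label=f"variant_{v}"))
    return variants


def random_tree(n_leaves: int, seed: int, min_branch: float = 0.05,
                max_branch: float = 0.3) -> PhyloTree:
    """A random fully resolved unrooted tree with uniform branch lengths.

    Topology is drawn by random sequential leaf attachment (uniform over
    labeled topologies); leaves are named t1..tn.
    """
    if n_leaves < 4:
        raise ValueError("need at least 4 leaves")
    rng = np.random.default_rng(seed)

    def bl() -> float:
        return float(rng.uniform(min_branch, max_branch))

    # grow by attaching each new leaf to a uniformly chosen existing edge
    tree = parse_newick(f"(t1:{bl()},t2:{bl()},t3:{bl()});")
    for i in range(4, n_leaves + 1):
        edges = [
            e for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node
        ]
        edge = edges[rng.integers(len(edges))]
        parent = edge.tail_node
        child = edge.head_node
        parent.remove_child(child)
        mid = parent.new_child(edge_length=bl())
        mid.add_child(child)
        child.edge.length = bl()
        leaf = mid.new_child(edge_length=bl())
        leaf.taxon = tree.taxon_namespace.new_taxon(label=f"t{i}")
    # normalize through newick round-trip
    return parse_newick(tree.as_string(schema="newick"))
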