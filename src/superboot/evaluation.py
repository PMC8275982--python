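"""Loss functions and error decompositions for bootstrap evaluation.

Against a known true tree, an estimated topology is scored with

* the All-or-Nothing loss — 1 unless the unrooted topologies are
  identical — and
* the Per-Branch loss, a Robinson–Foulds decomposition into Type I
  error e1 (clades of the estimate absent from the truth; false
  positives) and Type II error e2 (true clades missing from the
  estimate; false negatives), with RF = e1 + e2.

Collapsing every branch whose bootstrap support falls below a threshold
S yields the *reduced bootstrap tree*; sweeping S trades Type I against
Type II error.  Ranking curves, TP-at-FP counts and ROC AUC measure how
well support values separate correct from incorrect trees, and the
support-comparison table cross-tabulates two competing support measures
against topological correctness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .trees import (
    Bipartition,
    PhyloTree,
    SupportReport,
    TreeError,
    _require_same_leaves,
    bipartitions,
    canonical_split,
    leaf_set,
    parse_newick,
)


# ---------------------------------------------------------------------------
# Topology losses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RFDecomposition:
    """Robinson–Foulds distance split into Type I / Type II error counts."""

    e1: int  # estimate clades absent from the truth (false positives)
    e2: int  # true clades absent from the estimate (false negatives)

    @property
    def rf(self) -> int:
        return self.e1 + self.e2


def all_or_nothing(estimate: PhyloTree, truth: PhyloTree) -> int:
    """0 iff the unrooted topologies are identical, else 1."""
    _require_same_leaves(truth, [estimate])
    return 0 if bipartitions(estimate) == bipartitions(truth) else 1


def rf_decompose(estimate: PhyloTree, truth: PhyloTree) -> RFDecomposition:
    """Type I / Type II split of the RF distance over non-trivial splits."""
    _require_same_leaves(truth, [estimate])
    if len(leaf_set(truth)) < 4:
        raise TreeError("RF decomposition needs at least 4 leaves")
    b_est = bipartitions(estimate)
    b_true = bipartitions(truth)
    return RFDecomposition(e1=len(b_est - b_true), e2=len(b_true - b_est))


# ---------------------------------------------------------------------------
# Reduced bootstrap trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReducedTree:
    """A tree with all branches of support below a threshold collapsed."""

    tree: PhyloTree
    threshold: float


def _tree_from_splits(taxa: frozenset, clades: Sequence[frozenset],
                      labels: Mapping[frozenset, str] | None = None) -> PhyloTree:
    """Build an unrooted tree from a laminar family of canonical splits.

    Each split is re-expressed as the side not containing an anchor
    taxon; those sides nest, which directly gives the newick structure.
    """
    anchor = min(taxa)
    sides = []
    for c in clades:
        side = c if anchor not in c else taxa - c
        sides.append(frozenset(side))
        if labels is not None and c in labels:
            labels = dict(labels)
            labels[frozenset(side)] = labels[c]

    def build(members: frozenset) -> str:
        inner = [s for s in sides if s < members]
        maximal = [s for s in inner if not any(s < t for t in inner)]
        covered = frozenset().union(*maximal) if maximal else frozenset()
        parts = [build_group(s) for s in sorted(maximal, key=sorted)]
        parts += sorted(members - covered)
        return ",".join(parts)

    def build_group(s: frozenset) -> str:
        lab = labels.get(s, "") if labels else ""
        return f"({build(s)}){lab}"

    rest = taxa - {anchor}
    return parse_newick(f"({anchor},{build(rest)});")


def reduce_tree(tree: PhyloTree, supports: SupportReport | Mapping[Bipartition, float],
                threshold: float) -> ReducedTree:
    """Collapse every internal edge with support below the threshold.

    ``threshold`` is a percentage in [0, 100]; an edge with
    ``100 * support < threshold`` is contracted (strict less-than, so a
    branch sitting exactly at S survives).  ``supports`` must cover
    every non-trivial split of the tree.
    """
    if isinstance(supports, SupportReport):
        supports = supports.clade_supports
    taxa = leaf_set(tree)
    splits = bipartitions(tree)
    missing = [s for s in splits if s not in supports]
    if missing:
        raise TreeError(
            f"supports missing for {len(missing)} internal edge(s) of the tree"
        )
    kept = [s for s in splits if 100.0 * supports[s] >= threshold]
    labels = {s: f"{100.0 * supports[s]:g}" for s in kept}
    reduced = _tree_from_splits(taxa, kept, labels)
    return ReducedTree(tree=reduced, threshold=threshold)


# ---------------------------------------------------------------------------
# Ranking curves and AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankingCurve:
    """Cumulative (FP, TP) pairs swept over a descending score threshold.

    Tied scores form a block that is admitted in full or not at all, so
    the curve never depends on the order of equal-scored items.
    """

    points: tuple


def _check_scores_labels(scores: Sequence[float], labels: Sequence[bool]) -> None:
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have the same length")
    if not any(labels) or all(labels):
        raise ValueError("need at least one positive and one negative item")


def ranking_curve(scores: Sequence[float], labels: Sequence[bool]) -> RankingCurve:
    """Sweep a descending score cutoff; one curve point per tie block."""
    _check_scores_labels(scores, labels)
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    pts = []
    fp = tp = 0
    i = 0
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    while i < len(order):
        j = i
        while j < len(order) and s[order[j]] == s[order[i]]:
            j += 1
        block = order[i:j]
        tp += int(lab[block].sum())
        fp += int((~lab[block]).sum())
        pts.append((fp, tp))
        i = j
    return RankingCurve(points=tuple(pts))


def tp_at_fp(curve: RankingCurve, fp_budget: int) -> int:
    """Largest TP count reached while admitting at most fp_budget FPs."""
    best = 0
    for fp, tp in curve.points:
        if fp > fp_budget:
            break
        best = tp
    return best


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """ROC AUC by the Mann–Whitney rank statistic (ties count 1/2)."""
    _check_scores_labels(scores, labels)
    return float(roc_auc_score(np.asarray(labels, dtype=int), np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Support-comparison contingency analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SupportComparisonTable:
    """Datasets cross-tabulated by support comparison and correctness.

    ``counts[(stratum, correct)]`` with stratum in ``'>'``, ``'='``,
    ``'<'`` comparing support_a against support_b, and ``correct`` the
    topology-matches-reference flag.
    """

    counts: dict
    n_records: int

    def percent_correct(self, stratum: str) -> float | None:
        """Percentage of correct topologies within one stratum (or None
        if the stratum is empty)."""
        yes = self.counts[(stratum, True)]
        no = self.counts[(stratum, False)]
        if yes + no == 0:
            return None
        return 100.0 * yes / (yes + no)

    @property
    def overall_percent_correct(self) -> float | None:
        if self.n_records == 0:
            return None
        yes = sum(v for (s, ok), v in self.counts.items() if ok)
        return 100.0 * yes / self.n_records


def support_comparison(records: Sequence[tuple],
                       cutoff: float | None = None,
                       side: str | None = None) -> SupportComparisonTable:
    """Cross-tabulate (support_a, support_b, matches_reference) records.

    ``cutoff``/``side`` optionally restrict to records whose supports
    both lie strictly above (``side='above'``) or strictly below
    (``side='below'``) the cutoff, mirroring the common "split the
    datasets at bootstrap 60" analysis.
    """
    if (cutoff is None) != (side is None):
        raise ValueError("cutoff and side must be given together")
    if side is not None and side not in ("above", "below"):
        raise ValueError("side must be 'above' or 'below'")
    counts = {(s, ok): 0 for s in "><=" for ok in (True, False)}
    kept = 0
    for a, b, ok in records:
        if not (0 <= a <= 100 and 0 <= b <= 100):
            raise ValueError("supports must lie in [0, 100]")
        if cutoff is not None:
            if side == "above" and not (a > cutoff and b > cutoff):
                continue
            if side == "below" and not (a < cutoff and b < cutoff):
                continue
        stratum = ">" if a > b else ("<" if a < b else "=")
        counts[(stratum, bool(ok))] += 1
        kept += 1
    return SupportComparisonTable(counts=counts, n_records=kept)
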