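"""Pairwise column similarity between alternative MSAs and sampling weights.

``ColumnSim(x, y)`` is the percentage of x's columns that appear
identically aligned within y — the same residue occurrences co-placed in
one column, decided by the residue-ordinal fingerprint.  Columns with
fewer than two residues are excluded from numerator and denominator:
they cannot be "aligned" with anything.

The per-MSA sampling weight is inversely proportional to an MSA's
average similarity with the other alternatives:

    raw(x) = 100 - mean_{y != x} ColumnSim(x, y)

and the raw weights are normalized to sum to 100.  An aligner whose
output everyone else reproduces is down-weighted; a divergent aligner is
up-weighted.  When all alternatives are mutually identical every raw
weight is 0 and the normalized weights fall back to uniform, so the
scheme degenerates to the standard bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignments import Alignment, check_same_sequences, fingerprints


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square matrix of directed ColumnSim percentages.

    ``values[x, y]`` is the percentage of x's eligible columns matched in
    y.  Not symmetric in general (x and y may have different numbers of
    eligible columns).
    """

    labels: tuple[str, ...]
    values: np.ndarray  # (n, n), entries in [0, 100]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("similarity matrix shape does not match labels")
        if np.any(v < -1e-12) or np.any(v > 100 + 1e-12):
            raise ValueError("similarity values must lie in [0, 100]")


@dataclass(frozen=True)
class WeightVector:
    """Raw and normalized per-MSA sampling weights."""

    labels: tuple[str, ...]
    raw: tuple[float, ...]
    normalized: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(sum(self.normalized) - 100.0) > 1e-9:
            raise ValueError("normalized weights must sum to 100")
        if any(w < 0 for w in self.normalized):
            raise ValueError("normalized weights must be non-negative")


def _eligible_keys(msa: Alignment) -> list[frozenset]:
    return [fp.key for fp in fingerprints(msa) if fp.eligible]


def column_sim(x: Alignment, y: Alignment) -> float:
    """Percentage of x's columns found identically aligned within y.

    Membership is set-based: duplicated columns in x each count when
    their fingerprint occurs anywhere in y.  Raises if the two
    alignments do not hold the same sequences or x has no eligible
    (>= 2 residue) columns.
    """
    if not check_same_sequences([x, y]):
        raise ValueError("column_sim requires alignments of the same sequences")
    x_keys = _eligible_keys(x)
    if not x_keys:
        raise ValueError("alignment has no column with >= 2 aligned residues")
    y_keys = {fp.key for fp in fingerprints(y)}
    matched = sum(1 for k in x_keys if k in y_keys)
    return 100.0 * matched / len(x_keys)


def similarity_matrix(msas: Sequence[Alignment]) -> SimilarityMatrix:
    """All directed ColumnSim values among a set of alternative MSAs."""
    if len(msas) < 2:
        raise ValueError("need at least two alignments")
    if not check_same_sequences(list(msas)):
        raise ValueError("alignments must hold the same sequences")
    labels = tuple(m.label or f"msa_{k}" for k, m in enumerate(msas))
    n = len(msas)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            values[i, j] = column_sim(msas[i], msas[j])
    return SimilarityMatrix(labels=labels, values=values)


def compute_sample_weights(msas: Sequence[Alignment]) -> WeightVector:
    """Per-MSA sampling weights, inverse to average column similarity.

    ``raw[x] = 100 - mean_{y != x} column_sim(x, y)``; normalized to sum
    to 100.  If every raw weight is 0 (all MSAs mutually identical) the
    normalized weights are uniform.
    """
    if len(msas) < 2:
        raise ValueError("need at least two alignments to weight")
    sim = similarity_matrix(msas)
    n = len(msas)
    off = ~np.eye(n, dtype=bool)
    raw = np.array(
        [100.0 - sim.values[i, off[i]].mean() for i in range(n)]
    )
    raw = np.clip(raw, 0.0, 100.0)
    total = raw.sum()
    if total <= 1e-12:
        normalized = np.full(n, 100.0 / n)
    else:
        normalized = raw / total * 100.0
    return WeightVector(
        labels=sim.labels,
        raw=tuple(float(r) for r in raw),
        normalized=tuple(float(w) for w in normalized),
    )
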