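"""Bootstrap replicate sampling from a Super-MSA.

Three schemes:

* ``sboot``  — standard bootstrap on the concatenation: each replicate
  draws as many columns as the full Super-MSA length.
* ``psboot`` — partial bootstrap: replicate length equals the average
  source-MSA length, and N times more replicates are drawn (N = number
  of sources) to keep the total information comparable.
* ``wpsboot`` — weighted partial bootstrap: as ``psboot`` but every
  column is drawn with probability proportional to the sampling weight
  of the source MSA it comes from, favoring divergent aligners.

Sampling is one-stage (flat over columns, weight-proportional); when all
sources have equal length this coincides with first picking a source by
weight and then a column uniformly within it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignments import Alignment, SuperMSA

SCHEMES = ("sboot", "psboot", "wpsboot")


@dataclass(frozen=True)
class SamplingPlan:
    """Replicate length, count and per-column draw probabilities."""

    scheme: str
    replicate_length: int
    replicate_count: int
    column_probabilities: np.ndarray

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown sampling scheme {self.scheme!r}")
        if self.replicate_count < 1 or self.replicate_length < 1:
            raise ValueError("replicate count and length must be >= 1")
        if abs(self.column_probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("column probabilities must sum to 1")


@dataclass(frozen=True)
class Replicate:
    """One bootstrap replicate: column indices into the Super-MSA."""

    column_indices: tuple[int, ...]
    scheme: str
    seed_record: str


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def make_plan(super_msa: SuperMSA, scheme: str, base_count: int = 100) -> SamplingPlan:
    """Build the sampling plan for one of the three schemes.

    ``base_count`` is the replicate count of a standard bootstrap run;
    the partial schemes multiply it by the number of sources.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown sampling scheme {scheme!r}; choose from {SCHEMES}")
    if base_count < 1:
        raise ValueError("base_count must be >= 1")
    L = super_msa.length
    n_sources = super_msa.n_sources
    if scheme == "sboot":
        probs = np.full(L, 1.0 / L)
        return SamplingPlan("sboot", L, base_count, probs)
    mean_len = _round_half_up(sum(super_msa.source_lengths) / n_sources)
    count = n_sources * base_count
    if scheme == "psboot":
        probs = np.full(L, 1.0 / L)
    else:  # wpsboot: per-column probability proportional to source weight
        w = np.asarray(super_msa.weights)
        per_col = w[np.asarray(super_msa.provenance)]
        probs = per_col / per_col.sum()
    return SamplingPlan(scheme, mean_len, count, probs)


def draw_replicates(super_msa: SuperMSA, plan: SamplingPlan, seed: int) -> list[Replicate]:
    """Draw the plan's replicates, i.i.d. with replacement.

    Replicate ``i`` uses a deterministic child stream of the master seed
    (``numpy`` ``SeedSequence.spawn``), so the full replicate set is
    reproducible and independent of generation order.
    """
    if len(plan.column_probabilities) != super_msa.length:
        raise ValueError("sampling plan does not match this Super-MSA")
    children = np.random.SeedSequence(seed).spawn(plan.replicate_count)
    reps: list[Replicate] = []
    probs = plan.column_probabilities
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        idx = rng.choice(super_msa.length, size=plan.replicate_length,
                         replace=True, p=probs)
        reps.append(
            Replicate(
                column_indices=tuple(int(c) for c in idx),
                scheme=plan.scheme,
                seed_record=f"{seed}:{i}",
            )
        )
    return reps


def materialize(super_msa: SuperMSA, rep: Replicate) -> Alignment:
    """Realize a replicate as an alignment (row order preserved)."""
    L = super_msa.length
    if any(not 0 <= c < L for c in rep.column_indices):
        raise IndexError("replicate column index out of range")
    idx = list(rep.column_indices)
    rows = ["".join(row[c] for c in idx) for row in super_msa.alignment.rows]
    return Alignment(super_msa.alignment.ids, rows,
                     label=f"{rep.scheme}:{rep.seed_record}")


def source_draw_fractions(super_msa: SuperMSA, reps: Sequence[Replicate]) -> np.ndarray:
    """Empirical fraction of drawn columns per source MSA."""
    prov = np.asarray(super_msa.provenance)
    counts = np.zeros(super_msa.n_sources)
    for rep in reps:
        src, n = np.unique(prov[list(rep.column_indices)], return_counts=True)
        counts[src] += n
    return counts / counts.sum()
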