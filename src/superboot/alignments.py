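"""Containers and I/O for alternative multiple sequence alignments.

An *alternative MSA set* is two or more alignments of the identical
(ungapped) sequences, typically the outputs of different alignment
programs run on the same input.  Concatenating them column-wise yields a
*Super-MSA*: a super-matrix in which every column remembers which source
alignment it came from.  Bootstrap replicates drawn from the Super-MSA
then reflect alignment uncertainty as well as site sampling.

Column identity across alignments is decided by a *residue-ordinal
fingerprint*: for every taxon, a column either shows a gap or the k-th
residue of that taxon's (gap-free) sequence.  Two columns from different
alignments of the same sequences are "identically aligned" exactly when
their fingerprints agree.  Gap placement differs between aligners, so
raw column position carries no information; the ordinal encoding does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

_FORMAT_MAP = {"fasta": "fasta", "phylip": "phylip-relaxed"}


class AlignmentError(ValueError):
    """Raised when an alignment violates a structural invariant."""


class Alignment:
    """A gap-padded character matrix keyed by unique taxon identifiers.

    Parameters
    ----------
    ids:
        Ordered, unique taxon identifiers.
    rows:
        One gap-padded string per id, all of equal length.  The gap
        symbol is ``-``.
    label:
        Free-text source name, e.g. the aligner that produced the MSA.

    Raises
    ------
    AlignmentError
        On ragged rows (naming the offending id), duplicate ids, empty
        input, all-gap rows or all-gap columns.
    """

    __slots__ = ("ids", "rows", "label")

    def __init__(self, ids: Sequence[str], rows: Sequence[str], label: str = ""):
        self.ids = tuple(ids)
        self.rows = tuple(rows)
        self.label = label
        self._validate()

    def _validate(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment is empty (no sequences)")
        if len(self.ids) != len(self.rows):
            raise AlignmentError(
                f"{len(self.ids)} ids but {len(self.rows)} rows"
            )
        seen = set()
        for i in self.ids:
            if i in seen:
                raise AlignmentError(f"duplicate sequence id: {i!r}")
            seen.add(i)
        length = len(self.rows[0])
        if length < 1:
            raise AlignmentError(f"zero-length row for id {self.ids[0]!r}")
        for i, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise AlignmentError(
                    f"ragged alignment: row {i!r} has length {len(row)}, "
                    f"expected {length}"
                )
            if set(row) == {GAP}:
                raise AlignmentError(f"row {i!r} contains only gaps")
        for c in range(length):
            if all(row[c] == GAP for row in self.rows):
                raise AlignmentError(f"column {c} contains only gaps")

    @property
    def length(self) -> int:
        """Number of columns."""
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def row(self, taxon: str) -> str:
        return self.rows[self.ids.index(taxon)]

    def ungapped(self, taxon: str) -> str:
        """The gap-free sequence of one taxon."""
        return self.row(taxon).replace(GAP, "")

    def reorder(self, ids: Sequence[str]) -> "Alignment":
        """Same alignment with rows permuted into the given id order."""
        if set(ids) != set(self.ids):
            raise AlignmentError("reorder ids do not match alignment ids")
        return Alignment(ids, [self.row(i) for i in ids], label=self.label)

    def char_matrix(self) -> np.ndarray:
        """(n_sequences, length) array of single-byte strings."""
        return np.array([list(r) for r in self.rows], dtype="U1")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Alignment)
            and self.ids == other.ids
            and self.rows == other.rows
        )

    def __hash__(self) -> int:
        return hash((self.ids, self.rows))

    def __repr__(self) -> str:
        lab = f" label={self.label!r}" if self.label else ""
        return f"<Alignment {self.n_sequences}x{self.length}{lab}>"


def _normalize_row(seq: str) -> str:
    # aligner dialects: '.' as gap, lowercase residues
    return seq.upper().replace(".", GAP)


def read_alignment(path: str | Path, format: str = "fasta", label: str | None = None) -> Alignment:
    """Read a gapped FASTA or relaxed-PHYLIP alignment file.

    ``.`` gap characters are normalized to ``-`` and residues upper-cased.
    The sequence order of the file is preserved.  ``label`` defaults to
    the file stem.
    """
    path = Path(path)
    if format not in _FORMAT_MAP:
        raise ValueError(f"unknown alignment format {format!r} (use fasta or phylip)")
    if label is None:
        label = path.stem
    if format == "fasta":
        # SeqIO (not AlignIO) so that ragged input reaches our validator,
        # which names the offending id.
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        try:
            records = list(AlignIO.read(str(path), _FORMAT_MAP[format]))
        except ValueError as exc:
            raise AlignmentError(f"cannot parse {path} as phylip: {exc}") from exc
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    ids = [r.id for r in records]
    rows = [_normalize_row(str(r.seq)) for r in records]
    return Alignment(ids, rows, label=label)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment as gapped FASTA or relaxed PHYLIP."""
    if format not in _FORMAT_MAP:
        raise ValueError(f"unknown alignment format {format!r} (use fasta or phylip)")
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(row), id=taxon, description="")
        for taxon, row in zip(aln.ids, aln.rows)
    )
    AlignIO.write(msa, str(path), _FORMAT_MAP[format])


def check_same_sequences(msas: Sequence[Alignment]) -> bool:
    """True iff all alignments align the same sequences.

    Same id set and, per id, identical ungapped residue strings; gap
    placement is free to differ.
    """
    if not msas:
        raise ValueError("empty alignment list")
    first = msas[0]
    ref = {i: first.ungapped(i) for i in first.ids}
    for m in msas[1:]:
        if set(m.ids) != set(ref):
            return False
        if any(m.ungapped(i) != ref[i] for i in m.ids):
            return False
    return True


# ---------------------------------------------------------------------------
# Column fingerprints
# ---------------------------------------------------------------------------

class ColumnFingerprint:
    """Residue-ordinal encoding of one alignment column.

    ``entries`` maps each taxon id to the 0-based ordinal of the residue
    the column places for that taxon (counting non-gap characters from
    the start of the row), or ``None`` for a gap.  Two columns from
    alignments of the same sequences are identically aligned iff their
    fingerprints compare equal.  Columns with fewer than two non-gap
    entries carry no pairwise alignment information and are never
    counted as matches.
    """

    __slots__ = ("entries", "key")

    def __init__(self, entries: Mapping[str, int | None]):
        self.entries: dict[str, int | None] = dict(entries)
        self.key = frozenset(
            (t, o) for t, o in self.entries.items() if o is not None
        )

    @property
    def n_nongap(self) -> int:
        return len(self.key)

    @property
    def is_valid(self) -> bool:
        """At least one residue present (all-gap columns are invalid)."""
        return self.n_nongap >= 1

    @property
    def eligible(self) -> bool:
        """Eligible for similarity matching: >= 2 residues co-placed."""
        return self.n_nongap >= 2

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ColumnFingerprint)
            and self.key == other.key
            and set(self.entries) == set(other.entries)
        )

    def __hash__(self) -> int:
        return hash(self.key)

    def __repr__(self) -> str:
        return f"ColumnFingerprint({self.entries!r})"


def column_fingerprint(msa: Alignment, col: int) -> ColumnFingerprint:
    """Fingerprint of a single column (see :class:`ColumnFingerprint`)."""
    if not 0 <= col < msa.length:
        raise IndexError(f"column {col} out of range for length {msa.length}")
    entries: dict[str, int | None] = {}
    for taxon, row in zip(msa.ids, msa.rows):
        if row[col] == GAP:
            entries[taxon] = None
        else:
            # ordinal = count of non-gap characters strictly before col
            entries[taxon] = col - row[:col].count(GAP)
    return ColumnFingerprint(entries)


def fingerprints(msa: Alignment) -> list[ColumnFingerprint]:
    """All column fingerprints of an alignment, in column order.

    Linear-time: ordinals come from running per-row residue counters.
    """
    counters = [0] * msa.n_sequences
    out: list[ColumnFingerprint] = []
    for col in range(msa.length):
        entries: dict[str, int | None] = {}
        for r, (taxon, row) in enumerate(zip(msa.ids, msa.rows)):
            if row[col] == GAP:
                entries[taxon] = None
            else:
                entries[taxon] = counters[r]
                counters[r] += 1
        out.append(ColumnFingerprint(entries))
    return out


# ---------------------------------------------------------------------------
# Super-MSA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuperMSA:
    """Column-wise concatenation of alternative MSAs with provenance.

    ``provenance[c]`` is the index of the source MSA that contributed
    column ``c``; ``weights`` are the per-source sampling weights (they
    sum to 100, see :mod:`superboot.similarity`).
    """

    alignment: Alignment
    provenance: tuple[int, ...]
    source_lengths: tuple[int, ...]
    source_labels: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.source_lengths)
        if self.alignment.length != sum(self.source_lengths):
            raise AlignmentError(
                "Super-MSA length does not equal the sum of source lengths"
            )
        if len(self.provenance) != self.alignment.length:
            raise AlignmentError("provenance must cover every column")
        if any(not 0 <= p < n for p in self.provenance):
            raise AlignmentError("provenance index out of range")
        if len(self.source_labels) != n or len(self.weights) != n:
            raise AlignmentError("per-source metadata lengths disagree")
        if abs(sum(self.weights) - 100.0) > 1e-9:
            raise AlignmentError("sampling weights must sum to 100")

    @property
    def length(self) -> int:
        return self.alignment.length

    @property
    def n_sources(self) -> int:
        return len(self.source_lengths)


def concatenate(msas: Sequence[Alignment]) -> SuperMSA:
    """Concatenate >= 2 alternative MSAs of the same sequences.

    Rows are harmonized by id to the order of the first MSA.  Sampling
    weights are initialized with
    :func:`superboot.similarity.compute_sample_weights`.
    """
    if len(msas) < 2:
        raise AlignmentError(
            "concatenation needs at least two alternative MSAs; "
            "for a single MSA use the standard bootstrap"
        )
    first = msas[0]
    bad: list[str] = []
    for m in msas[1:]:
        bad.extend(sorted(set(m.ids) ^ set(first.ids)))
        for i in set(m.ids) & set(first.ids):
            if m.ungapped(i) != first.ungapped(i):
                bad.append(i)
    if bad:
        raise AlignmentError(
            "alternative MSAs do not align the same sequences; offending ids: "
            + ", ".join(sorted(set(bad)))
        )

    from .similarity import compute_sample_weights  # deferred: avoids cycle

    labels = []
    for k, m in enumerate(msas):
        lab = m.label or f"msa_{k}"
        if lab in labels:
            lab = f"{lab}_{k}"
        labels.append(lab)

    order = first.ids
    rows = ["".join(m.reorder(order).rows[r] for m in msas) for r in range(len(order))]
    provenance = tuple(
        k for k, m in enumerate(msas) for _ in range(m.length)
    )
    weights = compute_sample_weights(msas)
    return SuperMSA(
        alignment=Alignment(order, rows, label="super-msa"),
        provenance=provenance,
        source_lengths=tuple(m.length for m in msas),
        source_labels=tuple(labels),
        weights=tuple(weights.normalized),
    )


def write_provenance(super_msa: SuperMSA, path: str | Path) -> None:
    """Write the per-column provenance sidecar (TSV)."""
    with open(path, "w") as fh:
        fh.write("column_index\tsource_index\tsource_label\n")
        for c, p in enumerate(super_msa.provenance):
            fh.write(f"{c}\t{p}\t{super_msa.source_labels[p]}\n")
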