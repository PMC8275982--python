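# Methods

## Model and procedure

The package treats alignment choice as a nuisance variable of
phylogenetic inference. Given N alternative MSAs of the same sequences,
the Super-MSA is their column-wise concatenation; bootstrap replicates
drawn from it mix site-sampling variance with between-aligner
disagreement, so the resulting supports drop for clades that exist only
under some alignment styles.

**Column identity.** Two columns from different alignments of the same
sequences are *identically aligned* when they co-place the same residue
occurrences: for every taxon, either both columns show a gap or both
show the k-th residue of that taxon's ungapped sequence for the same k.
This residue-ordinal fingerprint is the package's operational definition
of column identity; whether the original aln_compare implementation is
position- or fingerprint-based is not documented anywhere we could
verify, so exact parity with that tool is not claimed. Columns with
fewer than two residues are excluded from both the numerator and the
denominator of `ColumnSim`: a column that aligns nothing with anything
carries no pairwise information. All-gap columns are rejected outright
at alignment validation.

**Weights.** `raw(x) = 100 − mean_{y≠x} ColumnSim(x, y)`, normalized to
sum to 100. `ColumnSim` is directional (x's columns searched in y) and
no symmetrization is applied before averaging. Similarities enter the
weight formula at full floating precision. When every raw weight is 0 —
all alternatives mutually identical — the normalization would divide by
zero; we fall back to uniform weights, which makes the weighted scheme
degenerate exactly to the standard bootstrap, the behavior one wants
from identical inputs.

**Sampling.** sboot draws `super.length` columns per replicate,
`base_count` replicates (default 100). psboot/wpsboot draw
`round(mean(source lengths))` columns (half-up rounding; only "average
length" is specified by the underlying method) and `N × base_count`
replicates. wpsboot assigns each *column* a draw probability
proportional to its source's weight — one-stage flat sampling, not
source-then-column two-stage. The two coincide when source lengths are
equal; with unequal lengths a longer divergent MSA contributes
proportionally more columns, which we consider the faithful reading of
"each column having a probability proportional to the weight of the MSA
it comes from". Randomness uses numpy `SeedSequence` substreams, one
per replicate, so replicate sets are reproducible and order-independent.

**Supports.** All topology comparison is unrooted and runs over
canonical non-trivial bipartitions (smaller side, lexicographic
tie-break). Topology support counts replicates with split sets equal to
the reference's; clade support counts replicates containing each
reference split. Polytomous replicates are allowed: a polytomy has
fewer splits, so it can still support a clade but never counts as
topologically identical to a resolved reference.

## Evaluation machinery

* All-or-Nothing loss: 0 iff the unrooted topologies are identical.
* Per-Branch loss: RF decomposed into e1 (estimate splits absent from
  truth, Type I) and e2 (true splits missing, Type II) over non-trivial
  splits. The strand weight of the weighted-RF family is fixed at λ = 1;
  other values are out of scope.
* Reduced bootstrap trees: an edge is collapsed when
  `100·support < S` — strict less-than, so a branch sitting exactly at
  the threshold survives. The reduced tree is rebuilt from the surviving
  (laminar) split set, which guarantees the leaf set is unchanged and
  every surviving edge meets the threshold.
* Ranking curves: items sorted by descending score; tied scores form a
  block admitted in full or not at all, so TP-at-FP counts cannot depend
  on the arbitrary order of equal-scored items. `tp_at_fp` returns the
  largest TP count reachable with FP ≤ budget.
* AUC uses the Mann–Whitney rank formulation (ties count ½), via
  scikit-learn; an explicit positive×negative pair enumeration serves as
  the independent oracle in the tests.
* The support-comparison table cross-tabulates sign(support_a −
  support_b) against topological correctness, with an optional
  restriction to records whose supports both lie strictly above or
  below a cutoff (the "split at bootstrap 60" analysis).

## Tree inference

The built-in neighbor-joining on p-distances exists so that the whole
pipeline is testable without external binaries. It is deterministic —
Q-matrix ties resolved toward the smallest (row, column) pair — ignores
sites where either sequence is gapped, applies no distance correction,
and clamps negative branch-length estimates to 0. It is consistent on
additive matrices (verified against scikit-bio's NJ) but is *not*
publication-grade inference; `infer_external` adapts any command-line
ML program through `{input}`/`{output}` placeholders.

## Synthetic data generator

`evolve` simulates sequences along a known tree: the root is uniform
over a 20-letter amino-acid alphabet; on a branch of length b each site
experiences at least one substitution event with probability
1 − exp(−b), and given an event the new residue is drawn uniformly from
the **full** alphabet. (Drawing only *different* residues would drive
the long-branch parent–child identity to 0 rather than the 1/20 of a
symmetric substitution process; the full-alphabet draw is the standard
Jukes–Cantor-style event semantics and is what the generator's own
saturation test asserts.) Indels are single-site: per branch each site
is deleted with probability `indel_rate/2` and a new site inserted
after each position with probability `indel_rate/2`. Sites carry
persistent identities, so the returned "true alignment" is exact by
construction.

`perturb_alignment` emulates alternative aligners by shifting each
maximal gap run of each row one column left or right with probability
`gap_shift_rate`, then dropping any all-gap columns. Ungapped sequences
are preserved by construction, and the expected pairwise `ColumnSim`
decreases as the rate rises.

Defaults used in the end-to-end tests and the acceptance pipeline: 8
leaves, branch lengths uniform in [0.05, 0.3] substitutions/site (the
moderate-divergence regime where NJ is reliable but not trivial), 150
root sites, `indel_rate` 0.04, 3 alternative alignments at
`gap_shift_rate` 0.1, wpSBOOT with `base_count` 100. These are desk-scale
choices: large enough for supports to be meaningful at binomial
Monte-Carlo error, small enough that the full suite runs in well under a
minute per dataset.

**What a green test establishes.** The generator has uniform rates, no
rate heterogeneity, single-site indels and *random* (not systematic)
aligner disagreement. Tests on it verify the correctness of the
machinery — weights, sampling laws, support bookkeeping, error
decompositions — and the qualitative discrimination property (true
clades out-supported false clades). They do not reproduce any empirical
benchmark numbers, which would require real aligners, real ML inference
and the original gene collections.

## Numerical choices and degenerate inputs

* Weight normalization tolerance 1e-9; column probabilities sum to 1
  within 1e-12.
* Raw weights are clipped to [0, 100] before normalization (floating
  noise can otherwise produce −1e-14).
* A pair of sequences with zero jointly non-gap sites has no defined
  p-distance and is an error, as is an MSA with no ≥2-residue column.
* Concatenation of a single MSA is rejected: it is definitionally the
  standard bootstrap and silently allowing it would hide user error.
* Replicates that leave a taxon with zero residues are rejected at
  materialization (that taxon would have no data for inference).

## Known limitations

* ColumnSim parity with T-Coffee's aln_compare is unverified (see
  above).
* The NJ fallback is uncorrected p-distance; supports computed from it
  on highly divergent data will be distorted.
* One-stage weighted sampling is a documented interpretation; a
  two-stage variant would differ for unequal source lengths.
* The generator's indel model is memoryless and single-site; gap-block
  statistics of real aligners are not reproduced.
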