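import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "superboot",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("superboot")


@pytest.fixture
def toy_triple():
    """Three 3-taxon alternative MSAs with hand-computable weights.

    A and B are identical; C aligns the same sequences with disjoint
    column fingerprints, so ColumnSim(A,B)=100 and A<->C, B<->C are 0,
    giving raw weights (50, 50, 100) -> normalized (25, 25, 50).
    """
    from superboot import Alignment

    a = Alignment(["s1", "s2", "s3"], ["AC--", "-AC-", "--AC"], label="A")
    b = Alignment(["s1", "s2", "s3"], ["AC--", "-AC-", "--AC"], label="B")
    c = Alignment(["s1", "s2", "s3"], ["A-C-", "-A-C", "A--C"], label="C")
    return a, b, c


@pytest.fixture
def nj_replicate_trees():
    """Callable: NJ trees for every replicate of a sampling plan."""
    from superboot import draw_replicates, materialize, nj_tree

    def run(super_msa, plan, seed):
        reps = draw_replicates(super_msa, plan, seed)
        return [nj_tree(materialize(super_msa, r)) for r in reps]

    return run
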