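import numpy as np
import pytest

from cladecall import simulate_genomes, scale_tree, build_database
from cladecall.counts import AlleleCountsMatrix, encode_calls


def counts_from_calls(call_rows, depth=10, positions=None, sample_ids=None):
    """Build a clean AlleleCountsMatrix whose major alleles are ``call_rows``.

    ``call_rows`` is a list of equal-length strings over ACGT (no N); each
    cell receives ``depth`` reads split evenly across strands.
    """
    S, P = len(call_rows), len(call_rows[0])
    counts = np.zeros((S, P, 4, 2), dtype=np.int64)
    for s, row in enumerate(call_rows):
        codes = encode_calls(row)
        for p, code in enumerate(codes):
            counts[s, p, code, 0] = depth - depth // 2
            counts[s, p, code, 1] = depth // 2
    return AlleleCountsMatrix(
        sample_ids or [f"s{i}" for i in range(S)],
        positions if positions is not None else np.arange(1, P + 1),
        counts,
    )


@pytest.fixture(scope="session")
def small_frame():
    """Seed-pinned 16-genome frame shared across tests (cheap)."""
    return simulate_genomes(16, 150_000, seed=11)


@pytest.fixture(scope="session")
def small_db(small_frame):
    import dendropy

    from cladecall.simulate import _refresh_support

    tree = dendropy.Tree(small_frame.tree)   # scale_tree mutates lengths
    _refresh_support(tree)                   # support is rebuilt from labels
    phylo = scale_tree(tree, small_frame.genotypes)
    return build_database(phylo, small_frame.genotypes)
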