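import numpy as np
import pytest

from rnannot.genome_model import Genome, GenomicInterval


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One shared small fixture bundle + pipeline run."""
    from rnannot import fixtures, pipeline

    d = tmp_path_factory.mktemp("bundle")
    fixtures.make_bundle(d, seed=11)
    config = pipeline.PipelineConfig.from_yaml(d / "config.yaml")
    result = pipeline.run_pipeline(config, d / "out")
    return {"dir": d, "config": config, "result": result}


@pytest.fixture
def tiny_genome():
    return Genome(
        {"chr1": "ACGTACGTACGTACGTACGT" * 100, "chr2": "GGCCNNTTAA" * 200},
        {"chr1": True, "chr2": True},
    )


def random_intervals(rng, n, contigs=("c1", "c2"), span=5000, max_len=200):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(
            GenomicInterval(
                str(rng.choice(contigs)), start, start + length,
                str(rng.choice(["+", "-"])),
            )
        )
    return out


def brute_force_components(intervals):
    """O(n^2) transitive closure of the pairwise-overlap graph."""
    from rnannot.genome_model import overlap_len

    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if overlap_len(intervals[i], intervals[j]) >= 1:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    out = [sorted(c) for c in comps.values()]
    out.sort(
        key=lambda c: (
            intervals[c[0]].contig,
            min(intervals[i].start for i in c),
        )
    )
    return out
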