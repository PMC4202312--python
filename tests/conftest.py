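import numpy as np
import pytest

from mosaicnet.io_formats import SequenceRecord, SimilarityHit
from mosaicnet.network import build_network
from mosaicnet.report import PipelineConfig, run_pipeline


def make_network(edges, lengths=None, threshold=1e-5):
    """Build a SimilarityNetwork from shorthand edge tuples
    (u, v, evalue, (s_u, e_u), (s_v, e_v)); intervals default to [1, 50].
    """
    lengths = dict(lengths or {})
    hits = []
    for edge in edges:
        u, v, evalue = edge[0], edge[1], edge[2]
        iu = edge[3] if len(edge) > 3 else (1, 50)
        iv = edge[4] if len(edge) > 4 else (1, 50)
        hits.append(
            SimilarityHit(
                query_id=u, subject_id=v, evalue=evalue, bitscore=50.0,
                q_start=iu[0], q_end=iu[1], s_start=iv[0], s_end=iv[1],
                aln_length=iu[1] - iu[0] + 1,
            )
        )
        lengths.setdefault(u, max(1000, iu[1]))
        lengths.setdefault(v, max(1000, iv[1]))
    records = [SequenceRecord(seq_id=k, length=v, genome_id=f"g_{k}")
               for k, v in lengths.items()]
    return build_network(hits, records, threshold=threshold)


def random_similarity_network(rng: np.random.Generator, n_nodes, p_edge,
                              threshold=1e-5):
    """Random graph with random E-values (spanning the stringency boundary)
    and random hit intervals, for oracle comparisons."""
    lengths = {f"n{i}": int(rng.integers(100, 400)) for i in range(n_nodes)}
    evalue_pool = [1e-30, 1e-12, 1e-9, 1e-6]
    edges = []
    ids = sorted(lengths)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() >= p_edge:
                continue
            u, v = ids[i], ids[j]
            iu = _rand_interval(rng, lengths[u])
            iv = _rand_interval(rng, lengths[v])
            edges.append((u, v, evalue_pool[rng.integers(4)], iu, iv))
    return make_network(edges, lengths=lengths, threshold=threshold)


def _rand_interval(rng, length):
    s = int(rng.integers(1, length))
    e = int(rng.integers(s, length + 1))
    return (s, e)


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline run on the default synthetic conditions (seed 42)."""
    return run_pipeline(PipelineConfig())


@pytest.fixture(scope="session")
def default_dataset(default_result):
    return default_result.dataset
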