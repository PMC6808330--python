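import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def ari():
    """Adjusted Rand index between two partitions over the same taxa."""
    from sklearn.metrics import adjusted_rand_score

    def _ari(p, q):
        taxa = sorted(p.taxa)
        la, lb = p.as_labels(), q.as_labels()
        return adjusted_rand_score([la[t] for t in taxa], [lb[t] for t in taxa])

    return _ari


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records, name="aln.fasta"):
        path = tmp_path / name
        path.write_text("".join(f">{t}\n{s}\n" for t, s in records))
        return path

    return _write


@pytest.fixture
def two_cluster_matrix():
    """Planted two-cluster distance matrix: intra in [0, 0.01], inter in
    [0.10, 0.12] (separation ratio >= 10)."""
    from cyclodelim.alignment import DistanceMatrix

    def _make(seed=0, n_per=4):
        rng = np.random.default_rng(seed)
        taxa = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
        n = 2 * n_per
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                same = (i < n_per) == (j < n_per)
                v = rng.uniform(0.0, 0.01) if same else rng.uniform(0.10, 0.12)
                d[i, j] = d[j, i] = v
        truth = [set(taxa[:n_per]), set(taxa[n_per:])]
        return DistanceMatrix(tuple(taxa), d, "p"), truth

    return _make
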