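import numpy as np
import pandas as pd
import pytest

from divscan.model import GenotypeMatrix, MarkerMap, SampleTable


def make_markers(n, chrom="1", spacing=40_000, start=10_000, alleles=("A", "G")):
    """Evenly spaced marker map on one chromosome."""
    return MarkerMap(pd.DataFrame({
        "snp_id": [f"s{k}" for k in range(n)],
        "chrom": chrom,
        "pos_bp": start + spacing * np.arange(n),
        "allele_a": alleles[0],
        "allele_b": alleles[1],
    }))


def make_samples(breed_sizes: dict[str, int]):
    rows = [
        {"sample_id": f"{b}_{k}", "breed": b}
        for b, n in breed_sizes.items()
        for k in range(n)
    ]
    return SampleTable(pd.DataFrame(rows))


def make_model(values, breed_sizes=None, markers=None):
    """GenotypeMatrix from a raw dosage array (rows grouped by breed)."""
    values = np.asarray(values, dtype=np.int8)
    if breed_sizes is None:
        breed_sizes = {"P": values.shape[0]}
    samples = make_samples(breed_sizes)
    if markers is None:
        markers = make_markers(values.shape[1])
    return GenotypeMatrix(values, markers, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_model(rng, n_samples=20, n_snps=50, breed_sizes=None, missing_rate=0.05):
    """Random multi-breed panel with missingness, for round-trip/oracle tests."""
    if breed_sizes is None:
        breed_sizes = {"P": n_samples}
    total = sum(breed_sizes.values())
    p = rng.uniform(0.05, 0.95, size=n_snps)
    v = rng.binomial(2, p, size=(total, n_snps)).astype(np.int8)
    if missing_rate:
        v[rng.random(v.shape) < missing_rate] = -1
    pairs = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
    choice = rng.integers(0, len(pairs), size=n_snps)
    markers = MarkerMap(pd.DataFrame({
        "snp_id": [f"m{k}" for k in range(n_snps)],
        "chrom": rng.choice(["1", "2"], size=n_snps).tolist(),
        "pos_bp": rng.choice(np.arange(1, 10_000_000), size=n_snps, replace=False),
        "allele_a": [pairs[c][0] for c in choice],
        "allele_b": [pairs[c][1] for c in choice],
    }))
    from divscan.model import sort_model

    markers, v = sort_model(markers, v)
    samples = make_samples(breed_sizes)
    return GenotypeMatrix(v, markers, samples)
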