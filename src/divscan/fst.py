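"""Pairwise Weir-Cockerham F_ST between breeds.

Per SNP the two-population variance-component estimator decomposes allelic
variance into an among-population component ``a``, an among-individual
within-population component ``b`` and a within-individual component ``c``;
the per-SNP estimate is theta = a / (a + b + c).  Two genome-wide summaries
are kept for every breed pair:

* mean F_ST   - the average of per-SNP theta values (this mean and its
  standard deviation are the moments the d_i standardization uses), and
* weighted F_ST - the ratio of sums, sum(a) / sum(a+b+c), the usual
  multi-locus combined estimate.

Negative per-SNP estimates are retained: they are part of the estimator's
sampling distribution, and truncating them would bias the z-scores the
selection scan ranks.  SNPs monomorphic across both breeds of a pair have
no variance to partition and are flagged undefined and excluded from the
summaries (the exclusion mask is kept on the track).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix, SampleTable


@dataclass(frozen=True)
class FstComponents:
    """Weir-Cockerham variance components at one SNP for one breed pair."""

    a: float
    b: float
    c: float

    @property
    def theta(self) -> float:
        denom = self.a + self.b + self.c
        if denom == 0:
            return float("nan")
        return self.a / denom

    @property
    def defined(self) -> bool:
        return (self.a + self.b + self.c) != 0


def _breed_stats(values: np.ndarray):
    """Per-SNP sample size, allele-B frequency and het proportion for one breed."""
    called = values != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, values, 0).sum(axis=0) / (2.0 * n)
        h = (values == 1).sum(axis=0) / n
    return n, p, h


def wc_components(n1, p1, h1, n2, p2, h2):
    """Vectorized two-population Weir-Cockerham (a, b, c) components.

    Arguments are per-SNP arrays of diploid sample size, allele frequency
    and observed heterozygote proportion for each population.  Entries with
    fewer than one sample in either population or with mean sample size
    n_bar <= 1 come out as NaN.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2
            - (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
            / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
    bad = (n1 < 1) | (n2 < 1) | (n_bar <= 1) | (n_c <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_fst_snp(counts_i, counts_j) -> FstComponents:
    """Weir-Cockerham components for one SNP from genotype counts.

    ``counts_i``/``counts_j`` are (n_aa, n_ab, n_bb) tuples for the two
    breeds.  Raises on a breed with zero called genotypes; returns
    components whose ``theta`` is NaN when the SNP is monomorphic across
    both breeds (a+b+c = 0).
    """
    out = []
    for counts in (counts_i, counts_j):
        n_aa, n_ab, n_bb = (float(x) for x in counts)
        n = n_aa + n_ab + n_bb
        if n == 0:
            raise ValueError("breed with zero called genotypes at SNP")
        p = (n_ab + 2.0 * n_bb) / (2.0 * n)
        h = n_ab / n
        out.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = out
    a, b, c = wc_components([n1], [p1], [h1], [n2], [p2], [h2])
    if np.isnan(a[0]):
        raise ValueError("sample sizes too small for the two-population estimator")
    return FstComponents(float(a[0]), float(b[0]), float(c[0]))


@dataclass
class PairFstTrack:
    """Per-SNP pairwise F_ST for one breed pair plus genome-wide summaries.

    ``theta`` is NaN at undefined SNPs; ``defined`` masks the usable ones.
    ``e_fst``/``sd_fst`` are the mean and sample (n-1) standard deviation of
    defined theta values; ``weighted_fst`` is sum(a)/sum(a+b+c).
    """

    breed_i: str
    breed_j: str
    theta: np.ndarray
    defined: np.ndarray
    e_fst: float
    sd_fst: float
    weighted_fst: float
    a: np.ndarray = field(repr=False, default=None)
    abc: np.ndarray = field(repr=False, default=None)

    @property
    def mean_fst(self) -> float:
        return self.e_fst

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())


def pair_fst_track(
    g: GenotypeMatrix,
    breeds: SampleTable | None = None,
    i: str = None,
    j: str = None,
) -> PairFstTrack:
    """Per-SNP theta track and genome-wide summaries for breeds ``i`` vs ``j``."""
    breeds = breeds if breeds is not None else g.samples
    idx_i = breeds.indices_of(i)
    idx_j = breeds.indices_of(j)
    if idx_i.size < 2 or idx_j.size < 2:
        raise ValueError(f"breed pair ({i},{j}) needs >=2 samples each")
    n1, p1, h1 = _breed_stats(g.values[idx_i, :])
    n2, p2, h2 = _breed_stats(g.values[idx_j, :])
    a, b, c = wc_components(n1, p1, h1, n2, p2, h2)
    abc = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / abc
    defined = np.isfinite(theta)
    if not defined.any():
        raise ValueError(f"no SNP with defined F_ST for pair ({i},{j})")
    vals = theta[defined]
    e = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    weighted = float(np.nansum(np.where(defined, a, 0.0))
                     / np.nansum(np.where(defined, abc, 0.0)))
    return PairFstTrack(
        breed_i=i, breed_j=j, theta=theta, defined=defined,
        e_fst=e, sd_fst=sd, weighted_fst=weighted, a=a, abc=abc,
    )


@dataclass
class FstMatrix:
    """Symmetric breed x breed mean and weighted F_ST matrices, zero diagonal."""

    labels: list[str]
    mean: np.ndarray
    weighted: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Single table with mean above and weighted below the diagonal."""
        k = len(self.labels)
        combined = np.zeros((k, k))
        iu = np.triu_indices(k, 1)
        il = np.tril_indices(k, -1)
        combined[iu] = self.mean[iu]
        combined[il] = self.weighted[il]
        return pd.DataFrame(combined, index=self.labels, columns=self.labels)

    def weighted_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weighted, index=self.labels, columns=self.labels)


def fst_matrix(
    g: GenotypeMatrix, breeds: SampleTable | None = None
) -> tuple[FstMatrix, dict[frozenset, PairFstTrack]]:
    """All-pairs F_ST: the breed x breed matrix and the per-pair tracks."""
    breeds = breeds if breeds is not None else g.samples
    labels = breeds.breeds
    if len(labels) < 2:
        raise ValueError("need >=2 breeds")
    for lab in labels:
        if breeds.indices_of(lab).size < 2:
            raise ValueError(f"breed {lab!r} has <2 samples")
    k = len(labels)
    mean = np.zeros((k, k))
    weighted = np.zeros((k, k))
    tracks: dict[frozenset, PairFstTrack] = {}
    for (ii, bi), (jj, bj) in combinations(enumerate(labels), 2):
        tr = pair_fst_track(g, breeds, bi, bj)
        tracks[frozenset((bi, bj))] = tr
        mean[ii, jj] = mean[jj, ii] = tr.e_fst
        weighted[ii, jj] = weighted[jj, ii] = tr.weighted_fst
    return FstMatrix(labels, mean, weighted), tracks
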