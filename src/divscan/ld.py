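"""Linkage disequilibrium and Gabriel-method haplotype blocks.

Haplotype frequencies are estimated from unphased diploid genotypes by EM
(the only ambiguous configuration at two loci is the double heterozygote).
From the four haplotype frequencies the usual measures follow:
D = f(AB) - pA*pB, D' = |D| / D_max with D_max the margin-constrained bound,
and r^2 = D^2 / (pA qA pB qB).

Block finding follows the confidence-interval method: for each marker pair
the likelihood of the genotype data is profiled on a D' grid (margins fixed
at their sample estimates) and normalized; the 5th/95th percentiles of that
mass are the D' confidence bounds.  A pair is in "strong LD" when
ci_low >= 0.70 and ci_high >= 0.98, shows "strong recombination" when
ci_high < 0.90, and is uninformative otherwise.  A block is a maximal
marker span whose outer pair is in strong LD and in which at least 95% of
informative pairs are in strong LD (minimum three informative pairs);
overlapping candidates are resolved greedily, longest span first.  Pairs
farther apart than 500 kb are never evaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix, MarkerMap

MAX_SPAN_BP_DEFAULT = 500_000
STRONG_LD_LOW = 0.70
STRONG_LD_HIGH = 0.98
RECOMB_HIGH = 0.90
STRONG_FRACTION = 0.95
MIN_INFORMATIVE = 3
EM_TOL = 1e-10
EM_MAX_ITER = 1000


# ---------------------------------------------------------------------------
# EM over haplotypes


def _enumerate_pairs(genotype: tuple[int, ...]) -> list[tuple[int, int]]:
    """All unordered haplotype pairs (as bit masks) compatible with a fully
    called multi-locus genotype; heterozygous sites double the count, with
    the first het site pinned to break the mirror symmetry."""
    het = [k for k, d in enumerate(genotype) if d == 1]
    base = sum(1 << k for k, d in enumerate(genotype) if d == 2)
    if not het:
        return [(base, base)]
    pairs = []
    first, rest = het[0], het[1:]
    for assign in range(1 << len(rest)):
        h1 = base | (1 << first)
        h2 = base
        for t, k in enumerate(rest):
            if (assign >> t) & 1:
                h1 |= 1 << k
            else:
                h2 |= 1 << k
        pairs.append((h1, h2))
    return pairs


def haplotype_em(
    values: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    return_loglik: bool = False,
):
    """Maximum-likelihood haplotype frequencies for <=~12 linked SNPs.

    ``values`` is individuals x markers dosage; individuals with any missing
    genotype in the span are dropped.  Returns a dict {bitmask: frequency}
    over haplotypes with positive frequency (bit k set = allele B at marker
    k).  With ``return_loglik`` also returns the per-iteration log-likelihood
    trace (non-decreasing).
    """
    v = np.asarray(values)
    complete = (v != MISSING).all(axis=1)
    v = v[complete]
    if v.shape[0] < 1:
        raise ValueError("no individuals with complete genotypes in span")
    geno_counts: dict[tuple[int, ...], int] = {}
    for row in map(tuple, v.tolist()):
        geno_counts[row] = geno_counts.get(row, 0) + 1
    pair_lists = {gt: _enumerate_pairs(gt) for gt in geno_counts}
    haps = sorted({h for pl in pair_lists.values() for p in pl for h in p})
    hidx = {h: k for k, h in enumerate(haps)}
    freqs = np.full(len(haps), 1.0 / len(haps))
    n_total = v.shape[0]
    trace = []
    for _ in range(max_iter):
        new = np.zeros_like(freqs)
        loglik = 0.0
        for gt, cnt in geno_counts.items():
            pl = pair_lists[gt]
            w = np.array([
                (2.0 if h1 != h2 else 1.0) * freqs[hidx[h1]] * freqs[hidx[h2]]
                for h1, h2 in pl
            ])
            tot = w.sum()
            if tot <= 0:
                w = np.full(len(pl), 1.0 / len(pl))
                tot = 1.0
                loglik += cnt * np.log(1e-300)
            else:
                w = w / tot
                loglik += cnt * np.log(tot)
            for (h1, h2), pw in zip(pl, w):
                new[hidx[h1]] += cnt * pw
                new[hidx[h2]] += cnt * pw
        new /= 2.0 * n_total
        trace.append(loglik)
        delta = np.abs(new - freqs).max()
        freqs = new
        if delta < tol:
            break
    out = {h: float(f) for h, f in zip(haps, freqs) if f > 0}
    if return_loglik:
        return out, trace
    return out


def two_locus_em(values_two: np.ndarray, **kw) -> np.ndarray:
    """Haplotype frequencies (AB, Ab, aB, ab) for two SNPs, where the
    uppercase letter is allele B of the respective marker.  ``values_two``
    is individuals x 2 dosage."""
    v = np.asarray(values_two)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("two_locus_em expects an individuals x 2 matrix")
    complete = (v != MISSING).all(axis=1)
    if complete.sum() < 2:
        raise ValueError("need >=2 individuals called at both SNPs")
    freqs = haplotype_em(v, **kw)
    # bitmask: bit0 = locus 1, bit1 = locus 2; order (AB, Ab, aB, ab)
    return np.array([
        freqs.get(0b11, 0.0), freqs.get(0b01, 0.0),
        freqs.get(0b10, 0.0), freqs.get(0b00, 0.0),
    ])


# ---------------------------------------------------------------------------
# LD measures


def d_measures(hap_freqs) -> tuple[float, float, float]:
    """(D, D', r^2) from (AB, Ab, aB, ab) haplotype frequencies.

    Returns (0, NaN, NaN) when a locus is monomorphic (undefined rather
    than an error)."""
    fAB, fAb, faB, fab = (float(x) for x in hap_freqs)
    total = fAB + fAb + faB + fab
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"haplotype frequencies sum to {total}, not 1")
    pA = fAB + fAb
    pB = fAB + faB
    d = fAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        return 0.0, float("nan"), float("nan")
    if d >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / denom
    return float(d), float(min(d_prime, 1.0)), float(min(r2, 1.0))


def _genotype_table(values_two: np.ndarray) -> np.ndarray:
    """3x3 two-locus genotype count table over fully called individuals."""
    v = np.asarray(values_two)
    complete = (v != MISSING).all(axis=1)
    v = v[complete]
    table = np.zeros((3, 3), dtype=np.int64)
    for g1, g2 in v:
        table[g1, g2] += 1
    return table


def _class_probs(f: np.ndarray) -> np.ndarray:
    """3x3 genotype-class probabilities from (AB, Ab, aB, ab) frequencies
    under random union of gametes; rows index locus-1 dosage."""
    fAB, fAb, faB, fab = f
    p = np.empty((3, 3))
    p[2, 2] = fAB ** 2
    p[2, 1] = 2 * fAB * fAb
    p[2, 0] = fAb ** 2
    p[1, 2] = 2 * fAB * faB
    p[1, 1] = 2 * (fAB * fab + fAb * faB)
    p[1, 0] = 2 * fAb * fab
    p[0, 2] = faB ** 2
    p[0, 1] = 2 * faB * fab
    p[0, 0] = fab ** 2
    return p


def dprime_ci(
    values_two: np.ndarray,
    grid_step: float = 0.001,
    mass: float = 0.90,
) -> tuple[float, float]:
    """Likelihood-based D' confidence bounds for one marker pair.

    The genotype likelihood is evaluated on a D' grid over [0,1] with the
    allele-frequency margins fixed at their sample estimates and the sign of
    D fixed at its ML estimate; the normalized likelihood is treated as a
    mass and the (1-mass)/2 and 1-(1-mass)/2 cumulative grid points are
    returned.
    """
    table = _genotype_table(values_two)
    n = table.sum()
    if n < 2:
        raise ValueError("need >=2 complete observations")
    # margins from genotype counts
    dose1 = (table.sum(axis=1) * np.arange(3)).sum()
    dose2 = (table.sum(axis=0) * np.arange(3)).sum()
    pA = dose1 / (2.0 * n)
    pB = dose2 / (2.0 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic margin; D' undefined")
    hap = two_locus_em(values_two)
    d_ml = hap[0] - pA * pB
    sign = 1.0 if d_ml >= 0 else -1.0
    if sign > 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    lls = np.empty(len(grid))
    nz = table > 0
    for k, dp in enumerate(grid):
        d = sign * dp * d_max
        f = np.array([
            pA * pB + d, pA * (1 - pB) - d,
            (1 - pA) * pB - d, (1 - pA) * (1 - pB) + d,
        ])
        f = np.clip(f, 1e-12, None)
        p = np.clip(_class_probs(f), 1e-300, None)
        lls[k] = (table[nz] * np.log(p[nz])).sum()
    w = np.exp(lls - lls.max())
    w /= w.sum()
    cum = np.cumsum(w)
    lo_q = (1.0 - mass) / 2.0
    hi_q = 1.0 - lo_q
    ci_low = float(grid[np.searchsorted(cum, lo_q)])
    ci_high = float(grid[min(np.searchsorted(cum, hi_q), len(grid) - 1)])
    return ci_low, ci_high


@dataclass
class LDPair:
    """LD summary for one marker pair."""

    snp_a: str
    snp_b: str
    distance_bp: int
    hap_freqs: np.ndarray
    D: float
    d_prime: float
    r2: float
    ci_low: float
    ci_high: float
    n_informative: int
    ld_class: str  # "strong_ld" | "recombination" | "uninformative" | "undefined"


def classify_pair(ci_low: float, ci_high: float) -> str:
    if ci_low >= STRONG_LD_LOW and ci_high >= STRONG_LD_HIGH:
        return "strong_ld"
    if ci_high < RECOMB_HIGH:
        return "recombination"
    return "uninformative"


def ld_pairs(
    m: MarkerMap,
    g: GenotypeMatrix,
    max_span_bp: int = MAX_SPAN_BP_DEFAULT,
    maf_min: float = 0.05,
) -> list[LDPair]:
    """All within-chromosome marker pairs closer than ``max_span_bp``.

    Markers with MAF below ``maf_min`` in the given samples are skipped
    entirely (the usual block-finding convention)."""
    from .qc import snp_maf

    maf = snp_maf(g.values)
    usable = np.flatnonzero(np.nan_to_num(maf) >= maf_min)
    pairs = []
    df = m.df
    for ja, jb in combinations(usable, 2):
        if df["chrom"].iat[ja] != df["chrom"].iat[jb]:
            continue
        dist = int(abs(df["pos_bp"].iat[jb] - df["pos_bp"].iat[ja]))
        if dist > max_span_bp:
            continue
        sub = g.values[:, [ja, jb]]
        try:
            hap = two_locus_em(sub)
            d, dp, r2 = d_measures(hap)
            ci_low, ci_high = dprime_ci(sub)
            cls = classify_pair(ci_low, ci_high)
        except ValueError:
            hap = np.full(4, np.nan)
            d = dp = r2 = ci_low = ci_high = float("nan")
            cls = "undefined"
        pairs.append(LDPair(
            snp_a=df["snp_id"].iat[ja], snp_b=df["snp_id"].iat[jb],
            distance_bp=dist, hap_freqs=hap, D=d, d_prime=dp, r2=r2,
            ci_low=ci_low, ci_high=ci_high,
            n_informative=int(((g.values[:, [ja, jb]] != MISSING).all(axis=1)).sum()),
            ld_class=cls,
        ))
    return pairs


@dataclass
class HaploBlock:
    """A confidence-interval haplotype block with its estimated haplotypes."""

    chrom: str
    marker_indices: list[int]        # column indices into the marker map
    snp_ids: list[str]
    start_bp: int
    stop_bp: int
    haplotypes: list[tuple[str, float]]  # allele strings (in allele_b order)
    top_hap_freq: float

    @property
    def n_markers(self) -> int:
        return len(self.marker_indices)


def block_haplotypes(
    values: np.ndarray, min_freq: float = 0.01, max_markers: int = 12
) -> list[tuple[str, float]]:
    """EM haplotypes (frequency >= ``min_freq``, sorted descending) for the
    block's marker span; spans wider than ``max_markers`` are truncated with
    a warning.  Allele strings use 'B' for allele_b, 'a' for allele_a."""
    v = np.asarray(values)
    n_mark = v.shape[1]
    if n_mark > max_markers:
        warnings.warn(
            f"block of {n_mark} markers truncated to first {max_markers} for "
            "haplotype estimation", stacklevel=2,
        )
        v = v[:, :max_markers]
        n_mark = max_markers
    freqs = haplotype_em(v)
    out = []
    for hap_mask, f in freqs.items():
        if f >= min_freq:
            s = "".join(
                "B" if (hap_mask >> k) & 1 else "a" for k in range(n_mark)
            )
            out.append((s, f))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def gabriel_blocks(
    m: MarkerMap,
    g: GenotypeMatrix,
    max_span_bp: int = MAX_SPAN_BP_DEFAULT,
    maf_min: float = 0.05,
    strong_fraction: float = STRONG_FRACTION,
    min_informative: int = MIN_INFORMATIVE,
) -> list[HaploBlock]:
    """Confidence-interval haplotype blocks per chromosome.

    Candidate spans require a strong-LD outer pair and >= ``strong_fraction``
    of informative inner pairs in strong LD (at least ``min_informative``
    informative pairs); overlapping candidates are resolved greedily by bp
    span, longest first, leftmost on ties.
    """
    from .qc import snp_maf

    maf = snp_maf(g.values)
    blocks: list[HaploBlock] = []
    df = m.df
    for chrom, sub in df.groupby("chrom", sort=False):
        cols = sub.index.to_numpy()
        cols = cols[np.nan_to_num(maf[cols]) >= maf_min]
        if cols.size < 2:
            continue
        pos = df["pos_bp"].to_numpy()[cols]
        k = cols.size
        cls = np.full((k, k), "", dtype=object)
        for x in range(k):
            for y in range(x + 1, k):
                if pos[y] - pos[x] > max_span_bp:
                    cls[x, y] = "far"
                    continue
                try:
                    lo, hi = dprime_ci(g.values[:, [cols[x], cols[y]]])
                    cls[x, y] = classify_pair(lo, hi)
                except ValueError:
                    cls[x, y] = "undefined"
        candidates = []
        for x in range(k):
            for y in range(x + 1, k):
                if cls[x, y] != "strong_ld":
                    continue
                informative = strong = 0
                for u in range(x, y + 1):
                    for w in range(u + 1, y + 1):
                        c = cls[u, w]
                        if c in ("strong_ld", "recombination"):
                            informative += 1
                            strong += c == "strong_ld"
                if informative < min_informative:
                    continue
                if strong / informative >= strong_fraction:
                    candidates.append((pos[y] - pos[x], pos[x], x, y))
        # greedy: longest bp span first, leftmost on ties
        candidates.sort(key=lambda t: (-t[0], t[1]))
        taken: list[tuple[int, int]] = []
        for _, _, x, y in candidates:
            if any(not (y < a or x > b) for a, b in taken):
                continue
            taken.append((x, y))
            idx = [int(c) for c in cols[x:y + 1]]
            haps = block_haplotypes(g.values[:, idx])
            blocks.append(HaploBlock(
                chrom=str(chrom),
                marker_indices=idx,
                snp_ids=[df["snp_id"].iat[c] for c in idx],
                start_bp=int(pos[x]),
                stop_bp=int(pos[y]),
                haplotypes=haps,
                top_hap_freq=haps[0][1] if haps else 0.0,
            ))
    blocks.sort(key=lambda b: (b.chrom, b.start_bp))
    return blocks


def blocks_frame(blocks: list[HaploBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": b.chrom, "start_bp": b.start_bp, "stop_bp": b.stop_bp,
             "n_markers": b.n_markers, "top_hap_freq": b.top_hap_freq,
             "haplotypes": ";".join(f"{s}:{f:.4f}" for s, f in b.haplotypes)}
            for b in blocks
        ],
        columns=["chrom", "start_bp", "stop_bp", "n_markers", "top_hap_freq",
                 "haplotypes"],
    )
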