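"""Sample and marker quality control for a multi-breed SNP panel.

Filters follow standard array-QC practice for selection scans: samples are
kept only above a per-sample call-rate floor; markers are dropped on
whole-population missingness, whole-population minor-allele frequency, and a
per-breed Hardy-Weinberg exact test (markers grossly out of HWE in any one
breed usually flag genotyping artefacts, not biology).  Sex chromosomes are
removed up front because hemizygosity breaks the diploid dosage model.

The panel summary mirrors the familiar per-breed polymorphism table:
monomorphic / low-frequency (0<MAF<0.01) / polymorphic partition, mean MAF,
observed and expected heterozygosity, and the mean inter-marker distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .model import MISSING, GenotypeMatrix, MarkerMap, SampleTable


@dataclass(frozen=True)
class QcThresholds:
    """QC thresholds; defaults are the conventional array-QC values."""

    sample_call_rate_min: float = 0.97  # keep samples with call rate strictly above
    maf_min: float = 0.05               # drop SNPs with population MAF below
    snp_missing_max: float = 0.20       # drop SNPs with missingness at/above
    hwe_p_min: float = 1.0e-6           # drop SNPs below this HWE p in any breed
    low_freq_bound: float = 0.01        # low-frequency / polymorphic boundary

    def __post_init__(self) -> None:
        for name in ("sample_call_rate_min", "maf_min", "snp_missing_max",
                     "hwe_p_min", "low_freq_bound"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} must lie in (0,1)")


DEFAULT_SEX_LABELS = frozenset({"X", "Y", "32", "33"})


def filter_samples_by_call_rate(
    g: GenotypeMatrix, t: QcThresholds = QcThresholds()
) -> GenotypeMatrix:
    """Keep samples whose fraction of called genotypes is strictly above
    ``t.sample_call_rate_min``.  May return an empty-sample matrix."""
    if g.n_snps == 0:
        return g
    call_rate = g.called().mean(axis=1)
    keep = np.flatnonzero(call_rate > t.sample_call_rate_min)
    return g.subset(sample_idx=keep)


def filter_autosomes(
    m: MarkerMap,
    g: GenotypeMatrix,
    sex_labels=DEFAULT_SEX_LABELS,
) -> tuple[MarkerMap, GenotypeMatrix]:
    """Drop markers whose chromosome label is in ``sex_labels``."""
    sex_labels = {str(s) for s in sex_labels}
    keep = np.flatnonzero(~np.isin(m.chrom, list(sex_labels)))
    g2 = g.subset(snp_idx=keep)
    return g2.markers, g2


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test from genotype counts.

    Conditions on the observed allele counts and enumerates every
    heterozygote count consistent with them; the p-value sums the
    probabilities of all tables no more probable than the observed one
    (plain exact test, no mid-p).  Monomorphic tables give p = 1.
    """
    counts = (n_aa, n_ab, n_bb)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("hwe_exact_test needs at least one genotype")
    n_a = 2 * n_aa + n_ab
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return 1.0
    # heterozygote counts share the parity of the rare-allele count
    het = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - het) // 2
    hom_common = n - het - hom_rare
    # P(het | allele counts) up to a constant: n! 2^het / (hom_r! het! hom_c!)
    logp = het * np.log(2.0) - (
        gammaln(hom_rare + 1) + gammaln(het + 1) + gammaln(hom_common + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[np.flatnonzero(het == n_ab)[0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def _genotype_counts(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (n_aa, n_ab, n_bb) over the given sample-rows slice."""
    n_aa = (values == 0).sum(axis=0)
    n_ab = (values == 1).sum(axis=0)
    n_bb = (values == 2).sum(axis=0)
    return n_aa, n_ab, n_bb


def snp_maf(values: np.ndarray) -> np.ndarray:
    """Per-SNP minor-allele frequency over called genotypes (NaN if none)."""
    called = values != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p_b = np.where(called, values, 0).sum(axis=0) / (2.0 * n_called)
    maf = np.minimum(p_b, 1.0 - p_b)
    return np.where(n_called > 0, maf, np.nan)


def filter_markers(
    g: GenotypeMatrix,
    breeds: SampleTable | None = None,
    t: QcThresholds = QcThresholds(),
    return_report: bool = False,
):
    """Apply the marker filters in order: missingness, MAF, per-breed HWE.

    A SNP is dropped when its whole-population missingness is >=
    ``t.snp_missing_max``, or its whole-population MAF is < ``t.maf_min``,
    or its HWE exact p-value is < ``t.hwe_p_min`` in any single breed.
    The first failing rule (in that order) becomes the SNP's reason code.

    With ``return_report=True`` also returns the per-SNP QC DataFrame
    (snp_id, maf, missing_rate, per-breed HWE p, drop_reason).
    """
    breeds = breeds if breeds is not None else g.samples
    if not breeds.breeds:
        raise ValueError("at least one breed required")
    v = g.values
    missing_rate = (v == MISSING).mean(axis=0) if g.n_samples else np.ones(g.n_snps)
    maf = snp_maf(v)

    reason = np.array([""] * g.n_snps, dtype=object)
    reason[missing_rate >= t.snp_missing_max] = "missingness"
    fail_maf = (np.isnan(maf) | (maf < t.maf_min)) & (reason == "")
    reason[fail_maf] = "maf"

    hwe_cols: dict[str, np.ndarray] = {}
    undecided = reason == ""
    for breed in breeds.breeds:
        rows = breeds.indices_of(breed)
        n_aa, n_ab, n_bb = _genotype_counts(v[rows, :])
        pvals = np.ones(g.n_snps)
        # only SNPs still in play and with data in this breed need the test
        todo = np.flatnonzero((n_aa + n_ab + n_bb) > 0)
        for j in todo:
            pvals[j] = hwe_exact_test(int(n_aa[j]), int(n_ab[j]), int(n_bb[j]))
        hwe_cols[f"hwe_p_{breed}"] = pvals
        reason[undecided & (pvals < t.hwe_p_min)] = "hwe"
        undecided = reason == ""

    keep = np.flatnonzero(reason == "")
    out = g.subset(snp_idx=keep)
    out.meta["qc_thresholds"] = t
    if not return_report:
        return out
    report = pd.DataFrame(
        {"snp_id": g.markers.snp_id, "maf": maf, "missing_rate": missing_rate,
         **hwe_cols, "drop_reason": reason}
    )
    return out, report


@dataclass
class PanelSummary:
    """Per-breed polymorphism summary of a (filtered) panel."""

    table: pd.DataFrame  # one row per breed
    mean_intermarker_kb: float
    meta: dict = field(default_factory=dict)


def mean_intermarker_kb(m: MarkerMap) -> float:
    """Mean of successive within-chromosome gaps, in kb (NaN if no gaps)."""
    gaps = []
    for _, sub in m.df.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        if len(pos) > 1:
            gaps.append(np.diff(pos))
    if not gaps:
        return float("nan")
    return float(np.concatenate(gaps).mean() / 1000.0)


def panel_summary(
    g: GenotypeMatrix,
    breeds: SampleTable | None = None,
    m: MarkerMap | None = None,
    t: QcThresholds = QcThresholds(),
    het_over_all_snps: bool = False,
    het_exp_unbiased: bool = False,
) -> PanelSummary:
    """Per-breed panel statistics.

    For each breed: the monomorphic / low-frequency (0<MAF<low_freq_bound) /
    polymorphic (MAF >= low_freq_bound) partition of the panel from
    breed-specific allele counts, mean MAF, observed heterozygosity (mean
    per-SNP heterozygote fraction), and expected heterozygosity (mean
    2p(1-p); ``het_exp_unbiased`` applies the 2n/(2n-1) correction).
    Heterozygosities average over polymorphic-in-breed SNPs unless
    ``het_over_all_snps``.
    """
    breeds = breeds if breeds is not None else g.samples
    m = m if m is not None else g.markers
    rows = []
    for breed in breeds.breeds:
        idx = breeds.indices_of(breed)
        v = g.values[idx, :]
        called = v != MISSING
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_b = np.where(called, v, 0).sum(axis=0) / (2.0 * n_called)
            maf = np.minimum(p_b, 1.0 - p_b)
            het_frac = (v == 1).sum(axis=0) / n_called
        has_data = n_called > 0
        mono = has_data & (maf == 0)
        low = has_data & (maf > 0) & (maf < t.low_freq_bound)
        poly = has_data & (maf >= t.low_freq_bound)
        # SNPs with no called genotypes in this breed count as monomorphic
        mono = mono | ~has_data
        het_mask = has_data if het_over_all_snps else poly
        h_exp = 2.0 * p_b * (1.0 - p_b)
        if het_exp_unbiased:
            with np.errstate(invalid="ignore", divide="ignore"):
                h_exp = h_exp * (2.0 * n_called) / (2.0 * n_called - 1.0)
        rows.append(
            {
                "breed": breed,
                "n_snps_total": int(g.n_snps),
                "n_monomorphic": int(mono.sum()),
                "n_low_freq": int(low.sum()),
                "n_polymorphic": int(poly.sum()),
                "mean_maf": float(np.nanmean(maf)) if has_data.any() else float("nan"),
                "het_obs": float(het_frac[het_mask].mean()) if het_mask.any() else 0.0,
                "het_exp": float(h_exp[het_mask].mean()) if het_mask.any() else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    return PanelSummary(
        table=table,
        mean_intermarker_kb=mean_intermarker_kb(m),
        meta={
            "het_over_all_snps": het_over_all_snps,
            "het_exp_unbiased": het_exp_unbiased,
            "low_freq_bound": t.low_freq_bound,
        },
    )
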