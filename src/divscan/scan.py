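"""Breed-standardized divergence scan (the d_i statistic).

For a focal breed *i*, each pairwise per-SNP F_ST value is z-standardized by
that pair's genome-wide mean and standard deviation,

    z_ij(snp) = (theta_ij(snp) - mean(theta_ij)) / sd(theta_ij),

and d_i(snp) is the sum of z_ij over all non-focal breeds *j*.  Large d_i
marks loci unusually diverged in breed *i* relative to its genome-wide
differentiation from every other breed.  The per-SNP profile is smoothed
with a 10-SNP sliding window (step one SNP, never crossing a chromosome
boundary), and candidate selection-signature regions are the windows at or
above the empirical 99.9th percentile of that profile's window values,
merged when their SNP spans overlap or abut.  Region coordinates are the
first/last SNP positions of the contributing windows and the reported size
is stop - start.  For gene annotation only, regions are padded by 25 kb on
each side.

Type-level comparisons (e.g. light vs draft breeds) average the z tracks of
all cross-type breed pairs at each SNP and then run through the same
window/threshold machinery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fst import PairFstTrack

WINDOW_SIZE_DEFAULT = 10
QUANTILE_DEFAULT = 0.999
EXTENSION_BP_DEFAULT = 25_000


@dataclass(frozen=True)
class ThresholdSpec:
    """Empirical-quantile threshold, applied per focal profile."""

    quantile: float = QUANTILE_DEFAULT

    def __post_init__(self) -> None:
        if not (0.0 < self.quantile < 1.0):
            raise ValueError("quantile must lie in (0,1)")


@dataclass
class DiProfile:
    """Per-SNP and window-averaged d_i values for one focal breed or type pair.

    ``chrom``/``pos_bp``/``di`` cover the SNPs defined in every contributing
    pair (``snp_index`` maps them back to panel columns; ``n_excluded``
    counts SNPs dropped for being undefined in at least one pair).
    ``windows`` has columns chrom, first_snp_pos, last_snp_pos, center_pos,
    window_di once :func:`window_smooth` has run.
    """

    focal: str
    chrom: np.ndarray
    pos_bp: np.ndarray
    di: np.ndarray
    snp_index: np.ndarray
    n_excluded: int = 0
    windows: pd.DataFrame | None = None
    window_size: int | None = None


def standardize_pair(track: PairFstTrack) -> np.ndarray:
    """Per-SNP z-scores of a pair track; NaN propagates at undefined SNPs."""
    if track.sd_fst == 0:
        raise ValueError(
            f"pair ({track.breed_i},{track.breed_j}) has zero F_ST variance; "
            "cannot standardize"
        )
    return (track.theta - track.e_fst) / track.sd_fst


def _combine_z(z_tracks: list[np.ndarray], reduce: str) -> tuple[np.ndarray, np.ndarray]:
    z = np.vstack(z_tracks)
    valid = np.isfinite(z).all(axis=0)
    combined = z.sum(axis=0) if reduce == "sum" else z.mean(axis=0)
    return combined, valid


def di_per_snp(
    focal: str,
    tracks: dict[frozenset, PairFstTrack],
    chrom: np.ndarray,
    pos_bp: np.ndarray,
) -> DiProfile:
    """Sum of pairwise z-scores over all pairs involving ``focal``.

    SNPs undefined in any contributing pair are excluded from the profile
    (and counted in ``n_excluded``).
    """
    pair_tracks = [t for key, t in tracks.items() if focal in key]
    if not pair_tracks:
        raise ValueError(f"no pair tracks involve focal breed {focal!r}")
    z_tracks = [standardize_pair(t) for t in pair_tracks]
    combined, valid = _combine_z(z_tracks, "sum")
    idx = np.flatnonzero(valid)
    return DiProfile(
        focal=focal,
        chrom=np.asarray(chrom)[idx],
        pos_bp=np.asarray(pos_bp)[idx],
        di=combined[idx],
        snp_index=idx,
        n_excluded=int(len(valid) - valid.sum()),
    )


def type_comparison(
    breeds_a: set[str],
    breeds_b: set[str],
    tracks: dict[frozenset, PairFstTrack],
    chrom: np.ndarray,
    pos_bp: np.ndarray,
) -> DiProfile:
    """Cross-type divergence profile: mean of z over all (a in A, b in B) pairs.

    The mean (rather than the sum) keeps one- and two-breed types on a
    common scale.  Within-type pairs do not contribute.
    """
    breeds_a, breeds_b = set(breeds_a), set(breeds_b)
    if not breeds_a or not breeds_b:
        raise ValueError("both type sets must be non-empty")
    if breeds_a & breeds_b:
        raise ValueError(f"type sets overlap: {sorted(breeds_a & breeds_b)}")
    z_tracks = []
    for a in sorted(breeds_a):
        for b in sorted(breeds_b):
            key = frozenset((a, b))
            if key not in tracks:
                raise ValueError(f"missing pair track for ({a},{b})")
            z_tracks.append(standardize_pair(tracks[key]))
    combined, valid = _combine_z(z_tracks, "mean")
    idx = np.flatnonzero(valid)
    label = "+".join(sorted(breeds_a)) + "_vs_" + "+".join(sorted(breeds_b))
    return DiProfile(
        focal=label,
        chrom=np.asarray(chrom)[idx],
        pos_bp=np.asarray(pos_bp)[idx],
        di=combined[idx],
        snp_index=idx,
        n_excluded=int(len(valid) - valid.sum()),
    )


def window_smooth(profile: DiProfile, k: int = WINDOW_SIZE_DEFAULT) -> DiProfile:
    """Sliding k-SNP windows (step 1) over each chromosome of the profile.

    A chromosome with fewer than k SNPs contributes no windows.  Each window
    records the first/last SNP positions, their midpoint as the center, and
    the arithmetic mean of the k per-SNP d_i values.
    """
    if k < 1:
        raise ValueError("window size must be >= 1")
    recs = []
    df = pd.DataFrame({"chrom": profile.chrom, "pos": profile.pos_bp, "di": profile.di})
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        di = sub["di"].to_numpy()
        m = len(pos)
        if m < k:
            continue
        csum = np.concatenate(([0.0], np.cumsum(di)))
        win = (csum[k:] - csum[:-k]) / k
        first = pos[: m - k + 1]
        last = pos[k - 1:]
        recs.append(pd.DataFrame({
            "chrom": chrom,
            "first_snp_pos": first,
            "last_snp_pos": last,
            "center_pos": (first + last) / 2.0,
            "window_di": win,
        }))
    windows = (
        pd.concat(recs, ignore_index=True)
        if recs
        else pd.DataFrame(columns=["chrom", "first_snp_pos", "last_snp_pos",
                                   "center_pos", "window_di"])
    )
    profile.windows = windows
    profile.window_size = k
    return profile


@dataclass
class SelectionRegion:
    """A merged above-threshold interval; size = stop - start by convention."""

    chrom: str
    start: int          # bp of first SNP of first contributing window
    stop: int           # bp of last SNP of last contributing window
    peak_di: float
    n_windows: int
    focal: str

    @property
    def size(self) -> int:
        return self.stop - self.start


def empirical_threshold(values: np.ndarray, quantile: float) -> float:
    """Order-statistic threshold: the ceil((1-q)*N)-th largest value, so that
    at least the top (1-q) fraction of windows reach it (ties included)."""
    n = len(values)
    if n == 0:
        raise ValueError("no window values")
    # tiny backoff so e.g. (1-0.999)*2000 -> 2, not ceil(2.0000000000000018)=3
    k = max(1, math.ceil((1.0 - quantile) * n - 1e-9))
    return float(np.sort(values)[-k])


def call_regions(
    profile: DiProfile, t: ThresholdSpec = ThresholdSpec()
) -> list[SelectionRegion]:
    """Select windows at/above the profile's empirical quantile and merge them.

    Windows whose [first_snp_pos, last_snp_pos] spans overlap or abut on the
    same chromosome collapse into one region; region start/stop are the
    outermost contributing SNP positions.
    """
    if profile.windows is None:
        raise ValueError("profile has no windows; run window_smooth first")
    w = profile.windows
    if len(w) == 0:
        raise ValueError("empty window profile")
    if len(w) < 1000:
        warnings.warn(
            f"only {len(w)} windows; the {t.quantile:.4f} empirical quantile "
            "is degenerate at this size", stacklevel=2,
        )
    thr = empirical_threshold(w["window_di"].to_numpy(), t.quantile)
    sel = w[w["window_di"] >= thr].sort_values(
        ["chrom", "first_snp_pos", "last_snp_pos"], key=None
    )
    regions: list[SelectionRegion] = []
    cur = None
    for row in sel.itertuples(index=False):
        if (
            cur is not None
            and row.chrom == cur["chrom"]
            and row.first_snp_pos <= cur["stop"]  # overlap or shared endpoint
        ):
            cur["stop"] = max(cur["stop"], int(row.last_snp_pos))
            cur["peak"] = max(cur["peak"], float(row.window_di))
            cur["n"] += 1
        else:
            if cur is not None:
                regions.append(_mk_region(cur, profile.focal))
            cur = {
                "chrom": row.chrom,
                "start": int(row.first_snp_pos),
                "stop": int(row.last_snp_pos),
                "peak": float(row.window_di),
                "n": 1,
            }
    if cur is not None:
        regions.append(_mk_region(cur, profile.focal))
    regions.sort(key=lambda r: (_chrom_key(r.chrom), r.start))
    return regions


def _chrom_key(c):
    s = str(c)
    return (0, int(s)) if s.isdigit() else (1, s)


def _mk_region(d: dict, focal: str) -> SelectionRegion:
    return SelectionRegion(
        chrom=str(d["chrom"]), start=d["start"], stop=d["stop"],
        peak_di=d["peak"], n_windows=d["n"], focal=focal,
    )


def extend_regions(
    regions: list[SelectionRegion],
    pad: int = EXTENSION_BP_DEFAULT,
    chrom_lengths: dict[str, int] | None = None,
) -> list[SelectionRegion]:
    """Pad each region by ``pad`` bp per side (floor 1, cap at chromosome
    length when provided).  Used for gene annotation; raw regions are kept
    by the caller."""
    out = []
    for r in regions:
        start = max(1, r.start - pad)
        stop = r.stop + pad
        if chrom_lengths and r.chrom in chrom_lengths:
            stop = min(stop, int(chrom_lengths[r.chrom]))
        out.append(SelectionRegion(
            chrom=r.chrom, start=start, stop=stop,
            peak_di=r.peak_di, n_windows=r.n_windows, focal=r.focal,
        ))
    return out


def regions_frame(regions: list[SelectionRegion]) -> pd.DataFrame:
    """Region report table (focal, chrom, start, stop, size, peak, windows)."""
    return pd.DataFrame(
        [
            {"focal": r.focal, "chrom": r.chrom, "start": r.start,
             "stop": r.stop, "size": r.size, "peak_di": r.peak_di,
             "n_windows": r.n_windows}
            for r in regions
        ],
        columns=["focal", "chrom", "start", "stop", "size", "peak_di", "n_windows"],
    )


# ---------------------------------------------------------------------------
# gene annotation


def read_bed_genes(path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open -> 1-based closed)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs >=3 columns")
    out = pd.DataFrame({
        "chrom": df.iloc[:, 0].astype(str),
        "start": df.iloc[:, 1].astype(np.int64) + 1,
        "stop": df.iloc[:, 2].astype(np.int64),
    })
    out["gene_id"] = (
        df.iloc[:, 3].astype(str)
        if df.shape[1] >= 4
        else [f"feature_{k}" for k in range(len(df))]
    )
    return out


def read_gff3_genes(path, feature_types: set[str] | None = frozenset({"gene"})) -> pd.DataFrame:
    """Gene intervals from GFF3 (1-based closed kept as-is).

    Keeps rows whose type is in ``feature_types`` (None keeps all); the id
    is the attribute ID=, falling back to Name= then a running index.
    """
    cols = ["seqid", "source", "type", "start", "end", "score", "strand",
            "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=cols,
                     dtype={"seqid": str})
    if feature_types is not None:
        df = df[df["type"].isin(feature_types)]

    def _attr_id(attrs: str, k: int) -> str:
        for field_ in str(attrs).split(";"):
            key, _, val = field_.strip().partition("=")
            if key in ("ID", "Name") and val:
                return val
        return f"feature_{k}"

    return pd.DataFrame({
        "chrom": df["seqid"].astype(str),
        "start": df["start"].astype(np.int64),
        "stop": df["end"].astype(np.int64),
        "gene_id": [_attr_id(a, k) for k, a in enumerate(df["attributes"])],
    }).reset_index(drop=True)


def annotate_regions(
    regions: list[SelectionRegion],
    genes: pd.DataFrame,
    pad: int = EXTENSION_BP_DEFAULT,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Genes overlapping each 25 kb-extended region by >=1 bp (closed
    intervals; strand ignored).  Returns one row per (region, gene) hit,
    keyed by the RAW region coordinates.  Warns when the annotation uses
    chromosome labels absent from the regions' chromosomes."""
    required = {"chrom", "start", "stop", "gene_id"}
    if not required <= set(genes.columns):
        raise ValueError(f"gene table needs columns {sorted(required)}")
    region_chroms = {r.chrom for r in regions}
    unmatched = sorted(set(genes["chrom"].astype(str)) - region_chroms)
    if regions and unmatched:
        warnings.warn(
            f"annotation chromosome labels not seen in regions: {unmatched}",
            stacklevel=2,
        )
    extended = extend_regions(regions, pad=pad, chrom_lengths=chrom_lengths)
    hits = []
    for raw, ext in zip(regions, extended):
        sub = genes[genes["chrom"].astype(str) == ext.chrom]
        ov = sub[(sub["start"] <= ext.stop) & (sub["stop"] >= ext.start)]
        for gr in ov.itertuples(index=False):
            hits.append({
                "focal": raw.focal, "chrom": raw.chrom,
                "region_start": raw.start, "region_stop": raw.stop,
                "gene_id": gr.gene_id, "gene_start": int(gr.start),
                "gene_stop": int(gr.stop),
            })
    return pd.DataFrame(
        hits,
        columns=["focal", "chrom", "region_start", "region_stop",
                 "gene_id", "gene_start", "gene_stop"],
    )
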