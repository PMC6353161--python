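"""Seeded multi-breed genotype simulator (Balding-Nichols model).

Each SNP draws an ancestral allele frequency p from a uniform range; every
breed then draws its own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), the
Balding-Nichols parameterization whose drift parameter F equals the
expected differentiation of that breed from the ancestor.  Diploid
genotypes are Binomial(2, p_breed).  On top of this neutral background the
generator can implant

* selection targets - SNP spans where focal breeds' frequencies are forced
  to a near-fixed target (optionally pinning the non-focal breeds low, to
  emulate a breed-specific sweep), and
* LD blocks - SNP spans where genotypes come from a small pool of haplotype
  templates (two templates sampled per individual, plus a 1% per-allele
  noise rate so downstream likelihoods stay non-degenerate).

All randomness flows from the single config seed through one named
generator; the same config reproduces byte-identical PED/MAP output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix, MarkerMap, SampleTable
from .plink import write_plink


@dataclass(frozen=True)
class SelectedLocus:
    """A selection target: ``snp_span`` (start, stop) is an inclusive index
    range into the chromosome's SNPs; focal breeds get ``target_freq`` for
    allele B there; non-focal breeds get ``other_freq`` when given, else
    keep their Balding-Nichols draw."""

    chrom: str
    snp_span: tuple[int, int]
    focal_breeds: tuple[str, ...]
    target_freq: float
    other_freq: float | None = None


@dataclass(frozen=True)
class LdBlockSpec:
    """An LD-block span driven by ``n_templates`` haplotype templates drawn
    once and shared by all breeds, with the given template frequencies."""

    chrom: str
    snp_span: tuple[int, int]
    n_templates: int
    template_freqs: tuple[float, ...]


@dataclass
class SimConfig:
    breeds: tuple[str, ...]
    samples_per_breed: tuple[int, ...]
    chrom_layout: tuple[tuple[str, int, int], ...]  # (label, n_snps, mean spacing bp)
    divergence_F: tuple[float, ...]                 # per breed, in (0,1); 0 allowed = no drift
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    selected_loci: tuple[SelectedLocus, ...] = ()
    ld_blocks: tuple[LdBlockSpec, ...] = ()
    missing_rate: float = 0.0
    block_noise_rate: float = 0.01
    seed: int = 0

    @property
    def n_snps(self) -> int:
        return sum(n for _, n, _ in self.chrom_layout)

    def validate(self) -> None:
        if len(self.breeds) != len(self.samples_per_breed):
            raise ValueError("breeds / samples_per_breed length mismatch")
        if len(self.breeds) != len(self.divergence_F):
            raise ValueError("breeds / divergence_F length mismatch")
        if len(set(self.breeds)) != len(self.breeds):
            raise ValueError("duplicate breed labels")
        lo, hi = self.ancestral_freq_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("bad ancestral frequency range")
        for f in self.divergence_F:
            if not (0.0 <= f < 1.0):
                raise ValueError(f"divergence F {f} outside [0,1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate outside [0,1)")
        layout = {label: n for label, n, _ in self.chrom_layout}
        for locus in self.selected_loci:
            self._check_span(locus.chrom, locus.snp_span, layout, "selected locus")
            unknown = set(locus.focal_breeds) - set(self.breeds)
            if unknown:
                raise ValueError(f"unknown focal breed(s) {sorted(unknown)}")
            if not (0.0 <= locus.target_freq <= 1.0):
                raise ValueError("target_freq outside [0,1]")
        for blk in self.ld_blocks:
            self._check_span(blk.chrom, blk.snp_span, layout, "LD block")
            if len(blk.template_freqs) != blk.n_templates:
                raise ValueError("template_freqs length != n_templates")
            if not np.isclose(sum(blk.template_freqs), 1.0):
                raise ValueError("template frequencies must sum to 1")

    @staticmethod
    def _check_span(chrom, span, layout, what):
        if chrom not in layout:
            raise ValueError(f"{what} on unknown chromosome {chrom!r}")
        s, e = span
        if not (0 <= s <= e < layout[chrom]):
            raise ValueError(f"{what} span {span} outside chromosome {chrom!r}")


@dataclass
class SimTruth:
    """Ground truth of one simulated panel, for test assertions."""

    breed_F: dict
    selected_loci: list
    ld_blocks: list
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {"breed_F": self.breed_F, "selected_loci": self.selected_loci,
             "ld_blocks": self.ld_blocks, "seed": self.seed},
            indent=2, sort_keys=True,
        )


def simulate_panel(
    cfg: SimConfig,
) -> tuple[MarkerMap, SampleTable, GenotypeMatrix, SimTruth]:
    """Generate a sorted marker map, sample table, dosage matrix and the
    ground-truth record, fully reproducible from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_snps = cfg.n_snps

    # marker map: exponential-ish spacing around the requested mean
    chroms, positions, snp_ids = [], [], []
    chrom_offset: dict[str, int] = {}
    for label, n, spacing in cfg.chrom_layout:
        chrom_offset[label] = len(snp_ids)
        gaps = rng.integers(1, 2 * spacing, size=n)
        pos = np.cumsum(gaps)
        chroms.extend([label] * n)
        positions.extend(pos.tolist())
        snp_ids.extend(f"snp_{label}_{k}" for k in range(n))
    alleles_ab = rng.choice(len(_ALLELE_PAIRS), size=n_snps)
    markers = MarkerMap(pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": chroms,
        "pos_bp": positions,
        "allele_a": [_ALLELE_PAIRS[k][0] for k in alleles_ab],
        "allele_b": [_ALLELE_PAIRS[k][1] for k in alleles_ab],
    }))

    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=n_snps)

    # per-breed frequencies via Balding-Nichols
    breed_freqs = {}
    for breed, f_drift in zip(cfg.breeds, cfg.divergence_F):
        if f_drift == 0.0:
            breed_freqs[breed] = p_anc.copy()
        else:
            alpha = p_anc * (1.0 - f_drift) / f_drift
            beta = (1.0 - p_anc) * (1.0 - f_drift) / f_drift
            breed_freqs[breed] = rng.beta(alpha, beta)

    # selection-target overrides
    for locus in cfg.selected_loci:
        s, e = locus.snp_span
        idx = np.arange(chrom_offset[locus.chrom] + s,
                        chrom_offset[locus.chrom] + e + 1)
        for breed in cfg.breeds:
            if breed in locus.focal_breeds:
                breed_freqs[breed][idx] = locus.target_freq
            elif locus.other_freq is not None:
                breed_freqs[breed][idx] = locus.other_freq

    # genotypes
    sample_ids, breed_labels, rows = [], [], []
    for breed, n_ind in zip(cfg.breeds, cfg.samples_per_breed):
        p = breed_freqs[breed]
        geno = rng.binomial(2, p, size=(n_ind, n_snps)).astype(np.int8)
        rows.append(geno)
        sample_ids.extend(f"{breed}_{k:04d}" for k in range(n_ind))
        breed_labels.extend([breed] * n_ind)
    values = (
        np.vstack(rows) if rows else np.empty((0, n_snps), dtype=np.int8)
    )

    # LD-block spans: replace independent draws by template-pool sampling
    truth_blocks = []
    for blk in cfg.ld_blocks:
        s, e = blk.snp_span
        idx = np.arange(chrom_offset[blk.chrom] + s, chrom_offset[blk.chrom] + e + 1)
        width = idx.size
        templates = rng.integers(0, 2, size=(blk.n_templates, width))
        # make templates distinct where possible
        for t in range(1, blk.n_templates):
            while any(np.array_equal(templates[t], templates[u]) for u in range(t)):
                templates[t] = rng.integers(0, 2, size=width)
        probs = np.asarray(blk.template_freqs)
        n_total = values.shape[0]
        pick = rng.choice(blk.n_templates, size=(n_total, 2), p=probs)
        hap_sum = templates[pick[:, 0]] + templates[pick[:, 1]]
        if cfg.block_noise_rate > 0:
            # per-allele flips keep each haplotype draw in {0,1}
            flips = rng.random((n_total, width, 2)) < cfg.block_noise_rate
            h1 = np.where(flips[:, :, 0], 1 - templates[pick[:, 0]], templates[pick[:, 0]])
            h2 = np.where(flips[:, :, 1], 1 - templates[pick[:, 1]], templates[pick[:, 1]])
            hap_sum = h1 + h2
        values[:, idx] = hap_sum.astype(np.int8)
        truth_blocks.append({
            "chrom": blk.chrom,
            "snp_span": [int(s), int(e)],
            "start_bp": int(markers.df["pos_bp"].iloc[idx[0]]),
            "stop_bp": int(markers.df["pos_bp"].iloc[idx[-1]]),
            "templates": templates.tolist(),
            "template_freqs": list(blk.template_freqs),
        })

    # missingness
    if cfg.missing_rate > 0 and values.size:
        mask = rng.random(values.shape) < cfg.missing_rate
        values[mask] = MISSING

    samples = SampleTable(pd.DataFrame({"sample_id": sample_ids,
                                        "breed": breed_labels}))
    g = GenotypeMatrix(values, markers, samples, meta={"seed": cfg.seed})

    truth = SimTruth(
        breed_F=dict(zip(cfg.breeds, cfg.divergence_F)),
        selected_loci=[
            {
                "chrom": l.chrom, "snp_span": list(l.snp_span),
                "focal_breeds": list(l.focal_breeds),
                "target_freq": l.target_freq, "other_freq": l.other_freq,
                "start_bp": int(markers.df["pos_bp"].iloc[chrom_offset[l.chrom] + l.snp_span[0]]),
                "stop_bp": int(markers.df["pos_bp"].iloc[chrom_offset[l.chrom] + l.snp_span[1]]),
            }
            for l in cfg.selected_loci
        ],
        ld_blocks=truth_blocks,
        seed=cfg.seed,
    )
    return markers, samples, g, truth


_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"),
                 ("C", "T"), ("G", "T")]


def six_breed_preset(seed: int = 2019) -> SimConfig:
    """A panel structurally emulating a six-breed SNP-array study: sample
    sizes (124, 56, 116, 99, 107, 69), 10,000 SNPs over 5 chromosomes at
    ~43 kb mean spacing, per-breed drift spanning background pairwise
    weighted F_ST of roughly 0.01-0.15, three implanted 12-SNP selection
    targets and four LD blocks."""
    breeds = ("AR", "MLP", "HC", "KN", "SOK", "SZTUM")
    sizes = (124, 56, 116, 99, 107, 69)
    drift = (0.16, 0.10, 0.12, 0.10, 0.012, 0.016)
    layout = tuple((str(c), 2000, 43_000) for c in range(1, 6))
    selected = (
        SelectedLocus("1", (400, 411), ("KN",), 0.97, other_freq=0.20),
        SelectedLocus("3", (1000, 1011), ("AR",), 0.96, other_freq=0.25),
        SelectedLocus("5", (600, 611), ("SOK", "SZTUM"), 0.97, other_freq=0.22),
    )
    blocks = (
        LdBlockSpec("2", (100, 107), 2, (0.7, 0.3)),
        LdBlockSpec("2", (900, 905), 3, (0.5, 0.3, 0.2)),
        LdBlockSpec("4", (500, 507), 2, (0.5, 0.5)),
        LdBlockSpec("4", (1500, 1505), 3, (0.6, 0.25, 0.15)),
    )
    return SimConfig(
        breeds=breeds,
        samples_per_breed=sizes,
        chrom_layout=layout,
        divergence_F=drift,
        selected_loci=selected,
        ld_blocks=blocks,
        missing_rate=0.002,
        seed=seed,
    )


def write_dataset(cfg: SimConfig, out_dir, prefix: str = "panel"):
    """Simulate and write PED/MAP, a breeds TSV and the ground-truth JSON.

    Returns (map_path, ped_path, breeds_path, truth_path)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    markers, samples, g, truth = simulate_panel(cfg)
    map_path, ped_path = write_plink(markers, samples, g, out_dir / prefix)
    breeds_path = out_dir / f"{prefix}.breeds.tsv"
    samples.df.to_csv(breeds_path, sep="\t", index=False, header=False)
    truth_path = out_dir / f"{prefix}.truth.json"
    truth_path.write_text(truth.to_json() + "\n")
    return map_path, ped_path, breeds_path, truth_path
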