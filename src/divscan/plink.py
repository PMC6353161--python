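"""Text PLINK (PED/MAP) reading and writing.

The PED/MAP pair is the interchange dialect: a 4-column MAP
(chrom, snp_id, cM, pos_bp) and a PED whose rows carry six leading columns
(FID, IID, PAT, MAT, SEX, PHENO) followed by two allele characters per
marker; "0 0" encodes a missing genotype.  By convention here the breed
label rides in the PED family-ID column unless an explicit two-column
sample-to-breed TSV overrides it.

Allele coding: dosages count the lexicographically larger of the two alleles
observed at each SNP (allele_b), unless explicit per-SNP allele roles are
supplied.  Note a SNP where only one allele is ever observed cannot reveal
which role it plays, so callers needing exact round-trips pass roles.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix, MarkerMap, ModelError, SampleTable, sort_model


class PlinkParseError(ValueError):
    """Malformed PED/MAP content (message names the offending line or SNP)."""


def read_map(map_path) -> pd.DataFrame:
    """Read a 4-column PLINK MAP file (chrom, snp_id, cM, pos_bp)."""
    df = pd.read_csv(
        map_path, sep=r"\s+", header=None, comment="#",
        names=["chrom", "snp_id", "cm", "pos_bp"],
        dtype={"chrom": str, "snp_id": str},
    )
    if df.isna().any().any():
        raise PlinkParseError(f"{map_path}: MAP requires 4 columns per line")
    return df


def read_breeds_tsv(path) -> SampleTable:
    """Two-column sample_id / breed TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise PlinkParseError(f"{path}: expected two tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["sample_id", "breed"]
    if df.iloc[0, 0] == "sample_id":  # tolerate a header row
        df = df.iloc[1:]
    return SampleTable(df.reset_index(drop=True))


def read_plink(
    map_path,
    ped_path,
    breeds: SampleTable | None = None,
    alleles: Mapping[str, tuple[str, str]] | None = None,
) -> tuple[MarkerMap, SampleTable, GenotypeMatrix]:
    """Read a PED/MAP pair into the validated in-memory model.

    Parameters
    ----------
    breeds
        Optional external sample-to-breed table; overrides PED family IDs.
    alleles
        Optional mapping snp_id -> (allele_a, allele_b) fixing which allele
        the dosage counts.  Without it, allele_b is the lexicographically
        larger allele observed in the file at that SNP.

    Markers are sorted by (chrom, pos_bp) on load and genotype columns
    reordered accordingly.
    """
    mp = read_map(map_path)
    n_snps = len(mp)
    snp_ids = mp["snp_id"].tolist()

    fids, iids = [], []
    rows = []  # per-sample flat allele strings, length 2*n_snps
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise PlinkParseError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * n_snps} "
                    f"fields, got {len(parts)}"
                )
            fids.append(parts[0])
            iids.append(parts[1])
            rows.append(parts[6:])

    n_samples = len(rows)
    allele_arr = (
        np.array(rows, dtype="U1").reshape(n_samples, n_snps, 2)
        if n_samples
        else np.empty((0, n_snps, 2), dtype="U1")
    )

    dosage = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    a_col = np.empty(n_snps, dtype="U1")
    b_col = np.empty(n_snps, dtype="U1")
    for j in range(n_snps):
        pair = allele_arr[:, j, :]
        called = (pair != "0").all(axis=1)
        half_called = (pair != "0").any(axis=1) & ~called
        if half_called.any():
            raise PlinkParseError(
                f"{ped_path}: half-missing genotype at SNP {snp_ids[j]!r}"
            )
        observed = sorted(set(pair[called].ravel()))
        if len(observed) > 2:
            raise PlinkParseError(
                f"{ped_path}: >2 alleles {observed} at SNP {snp_ids[j]!r}"
            )
        if alleles is not None and snp_ids[j] in alleles:
            a, b = alleles[snp_ids[j]]
            extra = set(observed) - {a, b}
            if extra:
                raise PlinkParseError(
                    f"{ped_path}: allele {extra.pop()!r} at SNP {snp_ids[j]!r} "
                    f"not among declared roles ({a},{b})"
                )
        elif len(observed) == 2:
            a, b = observed  # lexicographic: larger allele is counted
        elif len(observed) == 1:
            a, b = "0", observed[0]
        else:
            a, b = "0", "0"
        a_col[j], b_col[j] = a, b
        if called.any():
            dosage[called, j] = (pair[called] == b).sum(axis=1)

    markers = MarkerMap(
        pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": mp["chrom"],
                "pos_bp": mp["pos_bp"],
                "allele_a": a_col,
                "allele_b": b_col,
            }
        )
    )
    markers, dosage = sort_model(markers, dosage)

    if breeds is not None:
        lookup = dict(zip(breeds.sample_id, breeds.breed))
        missing_ids = [i for i in iids if i not in lookup]
        if missing_ids:
            raise ModelError(
                f"sample {missing_ids[0]!r} absent from breed table"
            )
        breed_labels = [lookup[i] for i in iids]
    else:
        breed_labels = fids
    samples = SampleTable(pd.DataFrame({"sample_id": iids, "breed": breed_labels}))
    return markers, samples, GenotypeMatrix(dosage, markers, samples)


def write_plink(
    markers: MarkerMap,
    samples: SampleTable,
    g: GenotypeMatrix,
    prefix,
) -> tuple[Path, Path]:
    """Write the model as ``<prefix>.ped`` / ``<prefix>.map``.

    Dosage 0/1/2 becomes "a a" / "a b" / "b b" using the map's declared
    allele roles; MISSING becomes "0 0".  The cM column is written as 0.
    Returns the (map_path, ped_path) pair.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    map_path = Path(str(prefix) + ".map")
    ped_path = Path(str(prefix) + ".ped")

    df = markers.df
    with open(map_path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos_bp}\n")

    a = df["allele_a"].to_numpy()
    b = df["allele_b"].to_numpy()
    # genotype word per (dosage, snp): index by dosage with MISSING -> "0 0"
    words = np.empty((4, len(df)), dtype=object)
    words[0] = [f"{x} {x}" for x in a]
    words[1] = [f"{x} {y}" for x, y in zip(a, b)]
    words[2] = [f"{y} {y}" for y in b]
    words[3] = "0 0"
    with open(ped_path, "w") as fh:
        for i in range(g.n_samples):
            dos = g.values[i]
            idx = np.where(dos == MISSING, 3, dos)
            geno = " ".join(words[idx, np.arange(len(df))]) if len(df) else ""
            lead = f"{samples.breed[i]} {samples.sample_id[i]} 0 0 0 -9"
            fh.write(lead + (" " + geno if geno else "") + "\n")
    return map_path, ped_path


def allele_roles(markers: MarkerMap) -> dict[str, tuple[str, str]]:
    """Per-SNP (allele_a, allele_b) mapping, for role-preserving re-reads."""
    return {
        r.snp_id: (r.allele_a, r.allele_b)
        for r in markers.df.itertuples(index=False)
    }
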