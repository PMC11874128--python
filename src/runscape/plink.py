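"""Readers and writers for PLINK-format genotype files.

Supports the text pair (PED/MAP) and the binary triple (BED/BIM/FAM,
SNP-major, bit-exact per the PLINK 1.9 format definition).  Genotypes are
recoded on input to A2-allele dosage (0/1/2) with :data:`~runscape.datamodel.MISSING`
for no-calls.

Allele orientation for text input: the binary BIM file states A1/A2
explicitly; a bare PED has no such declaration, so by convention the first
allele observed in file order at each marker becomes A2 (overridable via
``a2_alleles``).  The assignment is recorded on the returned dataset, and all
run/inbreeding statistics downstream are orientation-invariant.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import MISSING, DataModelError, GenotypeDataset, MarkerMap

_VALID_ALLELES = {"A", "C", "G", "T", "1", "2", "0"}

#: PLINK 1.9 .bed 2-bit genotype codes -> A2 dosage.
#: 00 hom A1, 01 missing, 10 heterozygous, 11 hom A2.
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}
_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = bytes([0x01])


class PlinkFormatError(ValueError):
    """Raised on malformed PLINK input."""


def _read_map(map_path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise PlinkFormatError(
                    f"{map_path}: line {ln}: MAP needs 4 columns, got {len(fields)}"
                )
            rows.append(fields)
    df = pd.DataFrame(rows, columns=["chrom", "snp_id", "cm", "pos_bp"])
    df["chrom"] = _parse_chrom(df["chrom"])
    df["pos_bp"] = df["pos_bp"].astype(np.int64)
    return df[["chrom", "snp_id", "pos_bp"]]


def _parse_chrom(col: pd.Series) -> np.ndarray:
    """Chromosome labels as integers; X/Y/MT and friends map to codes > 29
    so the QC stage can drop them."""
    mapping = {"X": 30, "Y": 31, "XY": 32, "MT": 33, "M": 33}
    out = np.empty(len(col), dtype=np.int64)
    for i, raw in enumerate(col.astype(str)):
        key = raw.upper()
        if key in mapping:
            out[i] = mapping[key]
        else:
            try:
                out[i] = int(raw)
            except ValueError as exc:
                raise PlinkFormatError(f"unparseable chromosome label {raw!r}") from exc
    return out


def read_plink_text(
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
    a2_alleles: np.ndarray | None = None,
) -> GenotypeDataset:
    """Read a PED/MAP pair into a :class:`GenotypeDataset`.

    Parameters
    ----------
    a2_alleles:
        Optional per-marker allele labels to count as A2 (e.g. from a BIM
        file of the same marker set).  Without it, the first allele observed
        in file order at each marker becomes A2.
    """
    marker_tab = _read_map(map_path)
    m = len(marker_tab)
    sample_rows: list[tuple[str, str]] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise PlinkFormatError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * m} fields "
                    f"for {m} markers, got {len(fields)}"
                )
            fid, iid = fields[0], fields[1]
            alleles = np.array(fields[6:], dtype=object)
            bad = set(alleles) - _VALID_ALLELES
            if bad:
                raise PlinkFormatError(
                    f"{ped_path}: line {ln}: invalid allele codes {sorted(bad)}"
                )
            sample_rows.append((iid, fid))
            allele_rows.append(alleles)

    n = len(sample_rows)
    ids = [sid for sid, _ in sample_rows]
    if len(set(ids)) != n:
        dup = next(s for s in ids if ids.count(s) > 1)
        raise PlinkFormatError(f"duplicate sample id {dup!r}")

    # alleles[i, 2j] / alleles[i, 2j+1] are the two calls of sample i, marker j
    allele_mat = np.vstack(allele_rows) if n else np.empty((0, 2 * m), dtype=object)
    a1 = np.empty(m, dtype=object)
    a2 = np.empty(m, dtype=object)
    geno = np.full((n, m), MISSING, dtype=np.int8)
    for j in range(m):
        pair = allele_mat[:, 2 * j : 2 * j + 2]
        flat = pair.ravel()
        observed: list[str] = []
        for al in flat:
            if al != "0" and al not in observed:
                observed.append(al)
        if len(observed) > 2:
            raise PlinkFormatError(
                f"marker {marker_tab['snp_id'].iloc[j]!r} has "
                f"{len(observed)} alleles: {observed}"
            )
        if a2_alleles is not None:
            second = str(a2_alleles[j])
            others = [al for al in observed if al != second]
            if len(others) > 1:
                raise PlinkFormatError(
                    f"marker {marker_tab['snp_id'].iloc[j]!r}: alleles {observed} "
                    f"inconsistent with declared A2 {second!r}"
                )
            first = others[0] if others else "0"
        else:
            second = observed[0] if observed else "0"
            first = observed[1] if len(observed) > 1 else "0"
        a2[j], a1[j] = second, first
        if n:
            called = (pair[:, 0] != "0") & (pair[:, 1] != "0")
            dosage = (pair[:, 0] == second).astype(np.int8) + (
                pair[:, 1] == second
            ).astype(np.int8)
            geno[called, j] = dosage[called]

    samples = pd.DataFrame({"sample_id": ids, "population": [f for _, f in sample_rows]})
    return GenotypeDataset(
        markers=MarkerMap(marker_tab), samples=samples, genotypes=geno, a1=a1, a2=a2
    )


def write_plink_text(
    dataset: GenotypeDataset,
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
) -> None:
    """Write a PED/MAP pair.  The population label goes in the FID column."""
    a1, a2 = _allele_labels(dataset)
    t = dataset.markers.table
    with open(map_path, "w") as fh:
        for chrom, snp, pos in zip(t["chrom"], t["snp_id"], t["pos_bp"]):
            fh.write(f"{chrom}\t{snp}\t0\t{pos}\n")
    geno = dataset.genotypes
    with open(ped_path, "w") as fh:
        for i in range(dataset.n_samples):
            sid = dataset.samples["sample_id"].iloc[i]
            pop = dataset.samples["population"].iloc[i]
            parts = [str(pop), str(sid), "0", "0", "0", "-9"]
            row = geno[i]
            for j in range(dataset.n_markers):
                g = row[j]
                if g == MISSING:
                    parts += ["0", "0"]
                elif g == 0:
                    parts += [a1[j], a1[j]]
                elif g == 1:
                    parts += [a2[j], a1[j]]
                else:
                    parts += [a2[j], a2[j]]
            fh.write(" ".join(parts) + "\n")


def _allele_labels(dataset: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    m = dataset.n_markers
    if dataset.a1 is not None and dataset.a2 is not None:
        a1 = dataset.a1.copy()
        a2 = dataset.a2.copy()
        # placeholder labels for alleles never observed, so files stay valid
        for j in range(m):
            if a2[j] == "0":
                a2[j] = "2" if a1[j] != "2" else "1"
            if a1[j] == "0":
                a1[j] = "1" if a2[j] != "1" else "2"
        return a1, a2
    # PLINK numeric allele labels: A1 = "1", A2 = "2"
    return (
        np.array(["1"] * m, dtype=object),
        np.array(["2"] * m, dtype=object),
    )


def read_plink_binary(
    bed_path: str | os.PathLike,
    bim_path: str | os.PathLike,
    fam_path: str | os.PathLike,
) -> GenotypeDataset:
    """Read a BED/BIM/FAM triple (SNP-major) into a :class:`GenotypeDataset`."""
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    )
    bim["chrom"] = _parse_chrom(bim["chrom"])
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    n, m = len(fam), len(bim)
    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{bed_path}: bad magic bytes {raw[:2]!r} (want 0x6c 0x1b)"
        )
    if raw[2:3] != _SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: not in SNP-major mode")
    nbytes = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * nbytes:
        raise PlinkFormatError(
            f"{bed_path}: {body.size} data bytes, expected {m * nbytes} "
            f"for {n} samples x {m} markers (truncated or padded file)"
        )
    codes = (
        body.reshape(m, nbytes)[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)
    ) & 0b11
    codes = codes.reshape(m, 4 * nbytes)[:, :n]  # (m, n), low bits first
    geno = _BED_DECODE[codes].T.copy()

    markers = MarkerMap(bim[["chrom", "snp_id", "pos_bp"]])
    samples = pd.DataFrame(
        {"sample_id": fam["iid"].astype(str), "population": fam["fid"].astype(str)}
    )
    return GenotypeDataset(
        markers=markers,
        samples=samples,
        genotypes=geno,
        a1=bim["a1"].to_numpy(dtype=object),
        a2=bim["a2"].to_numpy(dtype=object),
    )


def write_plink_binary(
    dataset: GenotypeDataset,
    bed_path: str | os.PathLike,
    bim_path: str | os.PathLike,
    fam_path: str | os.PathLike,
) -> None:
    """Write a BED/BIM/FAM triple (SNP-major)."""
    a1, a2 = _allele_labels(dataset)
    t = dataset.markers.table
    with open(bim_path, "w") as fh:
        for j, (chrom, snp, pos) in enumerate(
            zip(t["chrom"], t["snp_id"], t["pos_bp"])
        ):
            fh.write(f"{chrom}\t{snp}\t0\t{pos}\t{a1[j]}\t{a2[j]}\n")
    with open(fam_path, "w") as fh:
        for i in range(dataset.n_samples):
            sid = dataset.samples["sample_id"].iloc[i]
            pop = dataset.samples["population"].iloc[i]
            fh.write(f"{pop}\t{sid}\t0\t0\t0\t-9\n")

    n, m = dataset.n_samples, dataset.n_markers
    nbytes = (n + 3) // 4
    lut = np.zeros(256, dtype=np.uint8)  # dosage int8 (as uint8 index) -> 2-bit code
    for dosage, code in _BED_ENCODE.items():
        lut[np.uint8(np.int8(dosage))] = code
    codes = lut[dataset.genotypes.astype(np.int8).view(np.uint8)]  # (n, m)
    padded = np.zeros((4 * nbytes, m), dtype=np.uint8)
    padded[:n] = codes
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    grouped = padded.reshape(nbytes, 4, m)
    packed = (grouped << shifts[None, :, None]).sum(axis=1).astype(np.uint8)  # (nbytes, m)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + _SNP_MAJOR)
        fh.write(packed.T.tobytes())  # marker-major
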