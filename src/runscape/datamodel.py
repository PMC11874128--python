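"""Core data containers for SNP-array genotype analysis.

The central object is :class:`GenotypeDataset`: a samples x markers matrix of
A2-allele dosages (0, 1, 2) with a reserved :data:`MISSING` sentinel, plus a
:class:`MarkerMap` (chromosome, identifier, physical position) and per-sample
population labels.  All downstream statistics mask :data:`MISSING` explicitly;
the sentinel never enters arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Reserved genotype code for a missing call.  Stored in an int8 matrix; every
#: statistic masks it explicitly rather than relying on sentinel arithmetic.
MISSING: int = -1

#: Autosome labels admitted for analysis (caprine karyotype: 29 autosomes).
AUTOSOMES: tuple[int, ...] = tuple(range(1, 30))


class DataModelError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker map restricted to autosomes.

    Parameters
    ----------
    table:
        DataFrame with columns ``chrom`` (int), ``snp_id`` (str), ``pos_bp``
        (int, 1-based) and optionally ``quality_score`` (float in [0, 1],
        a stand-in for a chip-specific genotype-call quality score).
        Rows must be sorted by chromosome then position, positions strictly
        increasing within a chromosome, marker ids unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "snp_id", "pos_bp"}
        if not required.issubset(t.columns):
            raise DataModelError(f"marker map needs columns {sorted(required)}")
        if t["snp_id"].duplicated().any():
            dup = t.loc[t["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise DataModelError(f"duplicate marker id {dup!r}")
        if (t["pos_bp"] < 1).any():
            raise DataModelError("positions must be >= 1 (1-based)")
        chroms = t["chrom"].to_numpy()
        if np.any(np.diff(chroms) < 0):
            raise DataModelError("chromosome blocks must be sorted")
        for c, grp in t.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos_bp"].to_numpy()) <= 0):
                raise DataModelError(
                    f"positions not strictly increasing on chromosome {c}"
                )
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[int]:
        return list(pd.unique(self.table["chrom"]))

    @property
    def has_quality_scores(self) -> bool:
        return "quality_score" in self.table.columns

    def chrom_indices(self, chrom: int) -> np.ndarray:
        """Marker (row) indices belonging to one chromosome."""
        return np.flatnonzero(self.table["chrom"].to_numpy() == chrom)

    def chrom_span_bp(self, chrom: int) -> int:
        """bp extent covered by markers on a chromosome (last - first + 1)."""
        pos = self.table.loc[self.table["chrom"] == chrom, "pos_bp"].to_numpy()
        return int(pos[-1] - pos[0] + 1)

    def total_extent_bp(self) -> int:
        """Total autosomal length covered by the map: sum over chromosomes of
        (last marker position - first marker position + 1).  This is the
        denominator of the ROH-based inbreeding coefficient; it is always
        recomputed from the marker set in force, never hard-coded."""
        return int(sum(self.chrom_span_bp(c) for c in self.chromosomes))

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[idx].reset_index(drop=True))


@dataclass
class GenotypeDataset:
    """Diploid genotypes for n samples at m autosomal markers.

    ``genotypes[i, j]`` counts copies of marker j's A2 allele carried by
    sample i: 0, 1, 2 or :data:`MISSING`.  ``samples`` carries ``sample_id``
    and ``population`` columns; ``a1``/``a2`` record the allele labels behind
    the dosage coding so PLINK round-trips are loss-free.
    """

    markers: MarkerMap
    samples: pd.DataFrame
    genotypes: np.ndarray
    a1: np.ndarray | None = None
    a2: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.ndim != 2:
            raise DataModelError("genotype matrix must be 2-D")
        n, m = g.shape
        if len(self.samples) != n:
            raise DataModelError(
                f"{len(self.samples)} sample rows vs {n} genotype rows"
            )
        if self.markers.n_markers != m:
            raise DataModelError(
                f"{self.markers.n_markers} map rows vs {m} genotype columns"
            )
        if not {"sample_id", "population"}.issubset(self.samples.columns):
            raise DataModelError("samples need sample_id and population columns")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples.loc[
                self.samples["sample_id"].duplicated(), "sample_id"
            ].iloc[0]
            raise DataModelError(f"duplicate sample id {dup!r}")
        pops = self.samples["population"].astype(str)
        if (pops.str.len() == 0).any():
            raise DataModelError("population labels must be non-empty")
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataModelError(f"invalid genotype code {g[i, j]} at ({i}, {j})")
        self.genotypes = g
        self.samples = self.samples.reset_index(drop=True)
        for attr in ("a1", "a2"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=object)
                if v.shape != (m,):
                    raise DataModelError(f"{attr} must have one label per marker")
                setattr(self, attr, v)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].astype(str).tolist()

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        return list(pd.unique(self.samples["population"].astype(str)))

    def population_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(
            self.samples["population"].astype(str).to_numpy() == label
        )

    def subset_samples(self, idx: Iterable[int]) -> "GenotypeDataset":
        idx = np.asarray(list(idx), dtype=int)
        return GenotypeDataset(
            markers=self.markers,
            samples=self.samples.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[idx],
            a1=self.a1,
            a2=self.a2,
        )

    def subset_markers(self, idx: Iterable[int]) -> "GenotypeDataset":
        idx = np.asarray(list(idx), dtype=int)
        return GenotypeDataset(
            markers=self.markers.subset(idx),
            samples=self.samples,
            genotypes=self.genotypes[:, idx],
            a1=None if self.a1 is None else self.a1[idx],
            a2=None if self.a2 is None else self.a2[idx],
        )

    def called_mask(self) -> np.ndarray:
        """Boolean matrix: True where a genotype was called."""
        return self.genotypes != MISSING
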