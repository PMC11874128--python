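"""Genomic inbreeding coefficients.

Three estimators are computed per sample:

* ``F_ROH``: summed ROH length divided by ``L_TOTAL``, the autosomal bp
  extent covered by the marker map (recomputed from the map in force, never
  hard-coded), with class-wise components per ROH length class;
* ``F_G``: the diagonal of VanRaden's genomic relationship matrix minus one,
  ``G = Z Z' / (2 Σ p(1-p))`` with ``Z`` the 2p-centred dosage matrix;
* ``F_exH``: excess of observed over expected homozygous genotypes,
  ``(Obs - Exp) / (N - Exp)`` with the bias-corrected expectation
  ``Exp_j = 1 - 2 p_j (1 - p_j) n_j / (n_j - 1)`` summed over the sample's
  called markers.

A ROHet-based heterozygosity coefficient (summed ROHet length over
``L_TOTAL``, or optionally the fraction of markers inside ROHet) and the
Pearson correlation matrix across all coefficients complete the table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MISSING, GenotypeDataset
from .qc import allele_frequencies
from .runs import ROH, ROHET, RunSet

__all__ = [
    "GenomeExtent", "f_roh", "grm_vanraden", "f_exh", "het_coefficient",
    "inbreeding_table", "inbreeding_correlations", "InbreedingError",
]


class InbreedingError(ValueError):
    pass


@dataclass(frozen=True)
class GenomeExtent:
    """Total autosomal bp covered by the analysis marker map."""

    l_total_bp: int

    def __post_init__(self) -> None:
        if self.l_total_bp <= 0:
            raise InbreedingError("L_TOTAL must be positive")

    @classmethod
    def from_dataset(cls, dataset: GenotypeDataset) -> "GenomeExtent":
        return cls(dataset.markers.total_extent_bp())


def f_roh(
    runset: RunSet,
    extent: GenomeExtent,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample F_ROH, total and per length class.

    Samples listed in ``sample_ids`` but carrying no runs get 0.  Class-wise
    values sum to the total by construction.
    """
    if runset.kind != ROH:
        raise InbreedingError(f"need a ROH run set, got {runset.kind}")
    df = runset.to_frame()
    if sample_ids is None:
        sample_ids = sorted(df["sample"].unique())
    classes = list(dict.fromkeys(r.length_class for r in runset.runs))
    from .runs import ROH_CLASS_LABELS

    cols = {f"f_roh_{lab}": 0.0 for lab in ROH_CLASS_LABELS}
    out = pd.DataFrame(0.0, index=pd.Index(sample_ids, name="sample_id"),
                       columns=["f_roh_total", *cols])
    if len(df):
        per_cls = df.groupby(["sample", "class"])["length_bp"].sum()
        for (sid, lab), bp in per_cls.items():
            if sid in out.index:
                out.loc[sid, f"f_roh_{lab}"] = bp / extent.l_total_bp
        out["f_roh_total"] = out[[f"f_roh_{lab}" for lab in ROH_CLASS_LABELS]].sum(axis=1)
    return out


@dataclass
class GRM:
    """VanRaden genomic relationship matrix with its ingredients."""

    g: np.ndarray
    p: np.ndarray
    scale: float
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if not np.allclose(self.g, self.g.T, atol=1e-10):
            raise InbreedingError("G must be symmetric")
        if self.scale <= 0:
            raise InbreedingError("scaling constant must be positive")


def grm_vanraden(
    dataset: GenotypeDataset,
    centered: bool = True,
) -> tuple[GRM, pd.Series]:
    """VanRaden (method 1) G and per-sample ``F_G = G_ii - 1``.

    Frequencies come from the analysed samples.  Missing genotypes are
    imputed to the column mean ``2p`` (contributing zero after centring).
    Monomorphic markers are excluded from the scaling constant with a
    warning; if all markers are monomorphic the scale is zero and an error
    is raised.  ``centered=False`` reproduces the uncentred literal reading
    ``G = M M' / (2 Σ p(1-p))`` for comparison only.
    """
    freqs = allele_frequencies(dataset)
    p = freqs["p"].to_numpy(dtype=float)
    usable = ~np.isnan(p)
    poly = usable & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise InbreedingError(
            "all markers monomorphic: VanRaden scaling constant is zero"
        )
    g = dataset.genotypes[:, poly].astype(float)
    pj = p[poly]
    mean = 2.0 * pj
    miss = dataset.genotypes[:, poly] == MISSING
    g[miss] = np.broadcast_to(mean, g.shape)[miss]
    z = g - mean if centered else g
    scale = float(2.0 * np.sum(pj * (1.0 - pj)))
    G = z @ z.T / scale
    grm = GRM(g=G, p=pj, scale=scale, sample_ids=dataset.sample_ids)
    f_g = pd.Series(
        np.diag(G) - 1.0, index=pd.Index(dataset.sample_ids, name="sample_id"),
        name="f_g",
    )
    return grm, f_g


def f_exh(dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-sample excess-homozygosity inbreeding.

    Returns columns ``obs_homo``, ``exp_homo``, ``total_observation`` and
    ``f_exh``.  Markers with fewer than two called samples are excluded from
    the expectation (the small-sample factor n/(n-1) is undefined there).
    """
    freqs = allele_frequencies(dataset)
    p = freqs["p"].to_numpy(dtype=float)
    n_called = freqs["n_called"].to_numpy(dtype=float)
    usable = (~np.isnan(p)) & (n_called >= 2)
    corr = np.zeros_like(p)
    corr[usable] = n_called[usable] / (n_called[usable] - 1.0)
    exp_hom_marker = np.where(
        usable, 1.0 - 2.0 * p * (1.0 - p) * corr, 0.0
    )

    g = dataset.genotypes
    called = (g != MISSING) & usable[None, :]
    hom = ((g == 0) | (g == 2)) & usable[None, :]
    obs = hom.sum(axis=1).astype(float)
    total = called.sum(axis=1).astype(float)
    exp = called @ exp_hom_marker
    denom = total - exp
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(denom != 0.0, (obs - exp) / denom, 0.0)
    return pd.DataFrame(
        {
            "obs_homo": obs,
            "exp_homo": exp,
            "total_observation": total,
            "f_exh": f,
        },
        index=pd.Index(dataset.sample_ids, name="sample_id"),
    )


def het_coefficient(
    runset: RunSet,
    extent: GenomeExtent,
    sample_ids: list[str] | None = None,
    definition: str = "length",
    dataset: GenotypeDataset | None = None,
) -> pd.Series:
    """ROHet-based heterozygosity coefficient per sample.

    ``definition='length'`` (default): summed ROHet bp over ``L_TOTAL``.
    ``definition='snp_fraction'``: fraction of map markers falling inside
    the sample's ROHet (requires ``dataset``).  The two definitions agree in
    ranking on realistic data; neither is privileged.
    """
    if runset.kind != ROHET:
        raise InbreedingError(f"need a ROHet run set, got {runset.kind}")
    df = runset.to_frame()
    if sample_ids is None:
        sample_ids = sorted(df["sample"].unique())
    out = pd.Series(0.0, index=pd.Index(sample_ids, name="sample_id"),
                    name="het_coefficient")
    if definition == "length":
        if len(df):
            tot = df.groupby("sample")["length_bp"].sum()
            shared = tot.index.intersection(out.index)
            out.loc[shared] = tot.loc[shared] / extent.l_total_bp
        return out
    if definition == "snp_fraction":
        if dataset is None:
            raise InbreedingError("snp_fraction definition needs the dataset")
        t = dataset.markers.table
        chrom = t["chrom"].to_numpy()
        pos = t["pos_bp"].to_numpy()
        m = len(t)
        counts = {sid: 0 for sid in sample_ids}
        for r in runset.runs:
            if r.sample_id in counts:
                inside = (chrom == r.chrom) & (pos >= r.start_bp) & (pos <= r.end_bp)
                counts[r.sample_id] += int(inside.sum())
        for sid in sample_ids:
            out.loc[sid] = counts[sid] / m
        return out
    raise InbreedingError(f"unknown definition {definition!r}")


def inbreeding_table(
    dataset: GenotypeDataset,
    roh_runs: RunSet,
    rohet_runs: RunSet | None = None,
    extent: GenomeExtent | None = None,
) -> pd.DataFrame:
    """Assemble the per-sample coefficient table.

    ``extent`` defaults to the extent of ``dataset``'s marker map; pass the
    run-detection (lenient-QC) extent when the dataset given here is the
    strict-QC one.
    """
    ext = extent or GenomeExtent.from_dataset(dataset)
    ids = dataset.sample_ids
    table = f_roh(roh_runs, ext, sample_ids=ids)
    _, fg = grm_vanraden(dataset)
    table["f_g"] = fg
    exh = f_exh(dataset)
    table = table.join(exh)
    if rohet_runs is not None:
        table["het_coefficient"] = het_coefficient(rohet_runs, ext, sample_ids=ids)
    bad = (table["f_roh_total"] < -1e-12) | (table["f_roh_total"] > 1.0 + 1e-12)
    if bad.any():
        raise InbreedingError("F_ROH outside [0, 1]")
    return table


def inbreeding_correlations(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix (and two-sided p-values) across coefficient
    columns of an inbreeding table."""
    cols = [
        c for c in table.columns
        if c.startswith("f_roh") or c in ("f_g", "f_exh", "het_coefficient")
    ]
    if len(table) < 3:
        raise InbreedingError("need at least 3 samples for correlations")
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            x, y = table[ci].to_numpy(float), table[cj].to_numpy(float)
            if np.std(x) == 0.0 or np.std(y) == 0.0:
                rij, pij = np.nan, np.nan
            else:
                res = stats.pearsonr(x, y)
                rij, pij = float(res.statistic), float(res.pvalue)
            r.loc[ci, cj] = r.loc[cj, ci] = rij
            p.loc[ci, cj] = p.loc[cj, ci] = pij
    return r, p
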