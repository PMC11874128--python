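"""Marker/sample quality control with two tracks.

The *strict* track (relationship/structure analyses) applies, in fixed order:
optional per-marker quality-score filter, marker call rate, sample call rate,
minor allele frequency, and Hardy–Weinberg exact-test filters.  The *lenient*
track (run detection) applies only the quality-score and call-rate filters —
MAF and HWE pruning would delete exactly the monomorphic stretches that runs
of homozygosity are made of.  Non-autosomal markers are dropped first on both
tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datamodel import AUTOSOMES, MISSING, GenotypeDataset

logger = logging.getLogger(__name__)


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for one QC track.  All thresholds live in [0, 1]."""

    maf_min: float = 0.05
    hwe_p_min: float = 1e-5
    marker_call_rate_min: float = 0.90
    sample_call_rate_min: float = 0.90
    quality_score_min: float | None = 0.60
    track: str = "strict"

    def __post_init__(self) -> None:
        if self.track not in ("strict", "lenient"):
            raise QCError(f"unknown QC track {self.track!r}")
        for name in ("maf_min", "hwe_p_min", "marker_call_rate_min",
                     "sample_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise QCError(f"{name}={v} outside [0, 1]")
        if self.quality_score_min is not None and not (
            0.0 <= self.quality_score_min <= 1.0
        ):
            raise QCError("quality_score_min outside [0, 1]")


@dataclass
class QCReport:
    """Per-filter removal counts, in application order, plus retained ids."""

    n_markers_in: int
    n_samples_in: int
    markers_removed: dict[str, int] = field(default_factory=dict)
    samples_removed: dict[str, int] = field(default_factory=dict)
    markers_retained: list[str] = field(default_factory=list)
    samples_retained: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("markers", k, v) for k, v in self.markers_removed.items()]
        rows += [("samples", k, v) for k, v in self.samples_removed.items()]
        rows.append(("markers", "retained", len(self.markers_retained)))
        rows.append(("samples", "retained", len(self.samples_retained)))
        return pd.DataFrame(rows, columns=["axis", "filter", "count"])

    def validate(self) -> None:
        if sum(self.markers_removed.values()) + len(self.markers_retained) \
                != self.n_markers_in:
            raise QCError("marker accounting does not reconcile")
        if sum(self.samples_removed.values()) + len(self.samples_retained) \
                != self.n_samples_in:
            raise QCError("sample accounting does not reconcile")


def allele_frequencies(dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-marker A2 frequency and genotype counts, missing calls excluded.

    Returns a DataFrame with columns ``n_hom1``, ``n_het``, ``n_hom2``,
    ``n_called``, ``p`` (A2 frequency; NaN and ``undefined=True`` where no
    sample was called).
    """
    g = dataset.genotypes
    n_hom1 = (g == 0).sum(axis=0)
    n_het = (g == 1).sum(axis=0)
    n_hom2 = (g == 2).sum(axis=0)
    n_called = n_hom1 + n_het + n_hom2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (n_het + 2.0 * n_hom2) / (2.0 * n_called)
    return pd.DataFrame(
        {
            "snp_id": dataset.markers.table["snp_id"].to_numpy(),
            "n_hom1": n_hom1,
            "n_het": n_het,
            "n_hom2": n_hom2,
            "n_called": n_called,
            "p": p,
            "undefined": n_called == 0,
        }
    )


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact test of Hardy–Weinberg proportions.

    Computes the conditional distribution of the heterozygote count given the
    observed allele counts and sums the probabilities of all configurations
    no more likely than the observed one (Wigginton-style).  Monomorphic
    markers return 1.0 by convention.
    """
    counts = (n_hom1, n_het, n_hom2)
    if any(c < 0 or int(c) != c for c in counts):
        raise QCError(f"genotype counts must be nonnegative integers: {counts}")
    n = int(n_hom1 + n_het + n_hom2)
    if n < 1:
        raise QCError("need at least one genotyped sample")
    n_a2 = 2 * int(n_hom2) + int(n_het)  # copies of the rarer-or-not allele
    rare = min(n_a2, 2 * n - n_a2)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(het = h | allele counts) up to a shared constant:
    # P(h) ∝ n! / (n_AA! h! n_BB!) * 2^h with n_AA=(rare-h)/2, n_BB=n-n_AA-h
    n_aa = (rare - hets) // 2
    n_bb = n - n_aa - hets
    logp = (
        hets * np.log(2.0)
        - gammaln(n_aa + 1.0)
        - gammaln(hets + 1.0)
        - gammaln(n_bb + 1.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == int(n_het)]
    if obs.size != 1:
        raise QCError(
            f"heterozygote count {n_het} inconsistent with allele counts"
        )
    # include ties up to a small relative slack to absorb float rounding
    p = probs[probs <= obs[0] * (1.0 + 1e-9)].sum()
    return float(min(1.0, p))


def hwe_pvalues(dataset: GenotypeDataset) -> np.ndarray:
    """Vectorized convenience: exact HWE p-value per marker (NaN if no calls)."""
    freqs = allele_frequencies(dataset)
    out = np.full(len(freqs), np.nan)
    for i, (h1, het, h2, nc) in enumerate(
        zip(freqs["n_hom1"], freqs["n_het"], freqs["n_hom2"], freqs["n_called"])
    ):
        if nc > 0:
            out[i] = hwe_exact_test(int(h1), int(het), int(h2))
    return out


def apply_qc(
    dataset: GenotypeDataset, config: QCConfig
) -> tuple[GenotypeDataset, QCReport]:
    """Apply one QC track; returns the filtered dataset and a reconciled report.

    Filter order is fixed: non-autosomal drop, quality score, marker call
    rate, sample call rate, then (strict track only) MAF and HWE.  Sample
    call rates are computed after marker removal.
    """
    report = QCReport(n_markers_in=dataset.n_markers, n_samples_in=dataset.n_samples)
    ds = dataset

    autosomal = np.isin(ds.markers.table["chrom"].to_numpy(), AUTOSOMES)
    report.markers_removed["non_autosomal"] = int((~autosomal).sum())
    if not autosomal.all():
        logger.info("dropping %d non-autosomal markers", (~autosomal).sum())
        ds = ds.subset_markers(np.flatnonzero(autosomal))

    if config.quality_score_min is not None and ds.markers.has_quality_scores:
        qs = ds.markers.table["quality_score"].to_numpy(dtype=float)
        keep = qs >= config.quality_score_min
        report.markers_removed["quality_score"] = int((~keep).sum())
        ds = ds.subset_markers(np.flatnonzero(keep))
    else:
        report.markers_removed["quality_score"] = 0

    called = ds.called_mask()
    marker_cr = called.mean(axis=0) if ds.n_samples else np.ones(ds.n_markers)
    keep = marker_cr >= config.marker_call_rate_min
    report.markers_removed["marker_call_rate"] = int((~keep).sum())
    ds = ds.subset_markers(np.flatnonzero(keep))

    called = ds.called_mask()
    sample_cr = called.mean(axis=1) if ds.n_markers else np.ones(ds.n_samples)
    keep_s = sample_cr >= config.sample_call_rate_min
    report.samples_removed["sample_call_rate"] = int((~keep_s).sum())
    ds = ds.subset_samples(np.flatnonzero(keep_s))

    if config.track == "strict":
        freqs = allele_frequencies(ds)
        p = freqs["p"].to_numpy()
        maf = np.minimum(p, 1.0 - p)
        keep = np.where(np.isnan(maf), False, maf >= config.maf_min)
        report.markers_removed["maf"] = int((~keep).sum())
        ds = ds.subset_markers(np.flatnonzero(keep))

        pvals = hwe_pvalues(ds)
        keep = np.where(np.isnan(pvals), False, pvals > config.hwe_p_min)
        report.markers_removed["hwe"] = int((~keep).sum())
        ds = ds.subset_markers(np.flatnonzero(keep))
    else:
        report.markers_removed["maf"] = 0
        report.markers_removed["hwe"] = 0

    if ds.n_markers == 0:
        raise QCError("QC removed every marker; nothing left to analyse")

    report.markers_retained = ds.markers.table["snp_id"].astype(str).tolist()
    report.samples_retained = ds.sample_ids
    report.validate()
    return ds, report
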