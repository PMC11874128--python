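"""Detection of runs of homozygosity (ROH) and runs of heterozygosity (ROHet).

ROH are called with a PLINK-style scanning-window method: windows of
``window_snp`` consecutive markers are flagged as hits when they carry at
most ``window_het_max`` heterozygous and ``window_missing_max`` missing
calls; a marker is ROH-eligible when at least ``window_hit_fraction`` of the
windows overlapping it are hits; maximal eligible stretches, split at
inter-marker gaps above ``max_gap_bp``, yield candidate runs which must also
satisfy marker-count, length, average-density and (by default) a run-level
heterozygote budget.

ROHet are called with the consecutive-marker method: a run is a maximal
stretch with heterozygous terminal markers absorbing at most ``max_missing``
missing and ``max_homozygous`` homozygous calls, subject to marker-count and
length minima.

Both callers emit, per sample and chromosome, the set of *maximal passing
intervals*, selected greedily from the left (smallest start, then longest).
This makes the output a deterministic, non-overlapping set even in edge
cases where budget constraints would otherwise admit several overlapping
maximal intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

ROH = "ROH"
ROHET = "ROHet"

#: length-class lower bounds in Mb; bins are half-open [lo, hi), last open.
ROH_CLASS_EDGES_MB = (1.0, 2.0, 4.0, 8.0)
ROH_CLASS_LABELS = ("1-2 Mb", "2-4 Mb", "4-8 Mb", ">8 Mb")
ROHET_CLASS_EDGES_MB = (0.5, 1.0, 1.5, 2.0)
ROHET_CLASS_LABELS = ("0.5-1 Mb", "1-1.5 Mb", "1.5-2 Mb", ">2 Mb")


class RunDetectionError(ValueError):
    pass


@dataclass(frozen=True)
class ROHParams:
    """Scanning-window ROH criteria (PLINK-flag defaults).

    ``run_het_mode='strict'`` additionally bounds the heterozygote count of a
    final run by ``window_het_max``; ``'permissive'`` applies the budget only
    inside windows.
    """

    window_snp: int = 50
    window_het_max: int = 1
    window_missing_max: int = 1
    window_hit_fraction: float = 0.05
    min_length_bp: int = 1_000_000
    min_snp: int = 50
    max_gap_bp: int = 500_000
    max_density_bp_per_snp: int = 100_000
    run_het_mode: str = "strict"

    def __post_init__(self) -> None:
        if not 0.0 < self.window_hit_fraction <= 1.0:
            raise RunDetectionError("window_hit_fraction must be in (0, 1]")
        for name in ("window_snp", "min_length_bp", "min_snp", "max_gap_bp",
                     "max_density_bp_per_snp"):
            if getattr(self, name) <= 0:
                raise RunDetectionError(f"{name} must be positive")
        if self.window_het_max < 0 or self.window_missing_max < 0:
            raise RunDetectionError("window budgets must be nonnegative")
        if self.run_het_mode not in ("strict", "permissive"):
            raise RunDetectionError(f"unknown run_het_mode {self.run_het_mode!r}")


@dataclass(frozen=True)
class ROHetParams:
    """Consecutive-marker ROHet criteria."""

    min_snp: int = 15
    min_length_bp: int = 500_000
    max_missing: int = 2
    max_homozygous: int = 3

    def __post_init__(self) -> None:
        if self.min_snp <= 0 or self.min_length_bp <= 0:
            raise RunDetectionError("minima must be positive")
        if self.max_missing < 0 or self.max_homozygous < 0:
            raise RunDetectionError("budgets must be nonnegative")


@dataclass(frozen=True)
class Run:
    """One detected run for one sample.

    Coordinates are the first/last member marker positions, 1-based
    inclusive; ``length_bp = end_bp - start_bp + 1``.
    """

    sample_id: str
    population: str
    kind: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snp: int
    length_class: str

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


RUN_COLUMNS = [
    "sample", "population", "kind", "chrom", "start_bp", "end_bp",
    "n_snp", "length_bp", "class",
]


@dataclass
class RunSet:
    """All runs of one kind plus the parameters that produced them."""

    runs: list[Run]
    kind: str
    params: ROHParams | ROHetParams

    def __post_init__(self) -> None:
        for r in self.runs:
            if r.kind != self.kind:
                raise RunDetectionError(f"run kind {r.kind} in a {self.kind} set")
            if r.start_bp > r.end_bp:
                raise RunDetectionError("run start after end")
        by_key: dict[tuple[str, int], list[Run]] = {}
        for r in self.runs:
            by_key.setdefault((r.sample_id, r.chrom), []).append(r)
        for key, rs in by_key.items():
            rs.sort(key=lambda r: r.start_bp)
            for a, b in zip(rs, rs[1:]):
                if b.start_bp <= a.end_bp:
                    raise RunDetectionError(
                        f"overlapping runs for sample {key[0]} chrom {key[1]}"
                    )
        self.runs = sorted(
            self.runs, key=lambda r: (r.sample_id, r.chrom, r.start_bp)
        )

    def __len__(self) -> int:
        return len(self.runs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.sample_id, r.population, r.kind, r.chrom, r.start_bp, r.end_bp,
             r.n_snp, r.length_bp, r.length_class)
            for r in self.runs
        ]
        return pd.DataFrame(rows, columns=RUN_COLUMNS)

    def to_bed_frame(self) -> pd.DataFrame:
        """0-based half-open export."""
        df = self.to_frame()
        return pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start_bp"] - 1,
                "end": df["end_bp"],
                "name": df["sample"] + ":" + df["kind"],
            }
        )


def classify_run_length(length_bp: int, kind: str) -> str:
    """Assign a run length to its class; bins are half-open [lo, hi)."""
    if kind == ROH:
        edges, labels = ROH_CLASS_EDGES_MB, ROH_CLASS_LABELS
    elif kind == ROHET:
        edges, labels = ROHET_CLASS_EDGES_MB, ROHET_CLASS_LABELS
    else:
        raise RunDetectionError(f"unknown run kind {kind!r}")
    mb = length_bp / 1e6
    if mb < edges[0]:
        raise RunDetectionError(
            f"{kind} of {length_bp} bp below the first class bound"
        )
    for lo, hi, label in zip(edges, edges[1:], labels):
        if lo <= mb < hi:
            return label
    return labels[-1]


# ---------------------------------------------------------------------------
# ROH caller

def _roh_eligibility(
    het: np.ndarray, miss: np.ndarray, p: ROHParams
) -> np.ndarray:
    """Per-marker eligibility from the scanning-window hit fraction."""
    m = het.size
    w = p.window_snp
    nwin = m - w + 1
    cs_het = np.concatenate([[0], np.cumsum(het)])
    cs_mis = np.concatenate([[0], np.cumsum(miss)])
    het_in_win = cs_het[w:] - cs_het[:-w]
    mis_in_win = cs_mis[w:] - cs_mis[:-w]
    hit = (het_in_win <= p.window_het_max) & (mis_in_win <= p.window_missing_max)
    cs_hit = np.concatenate([[0], np.cumsum(hit)])
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, nwin - 1)
    n_tot = hi - lo + 1
    n_hit = cs_hit[hi + 1] - cs_hit[lo]
    return (n_hit / n_tot) >= p.window_hit_fraction


def _roh_candidate_passes(
    a: int, b: int, pos: np.ndarray, cs_het: np.ndarray, p: ROHParams
) -> bool:
    n_snp = b - a + 1
    length = int(pos[b] - pos[a] + 1)
    if n_snp < p.min_snp or length < p.min_length_bp:
        return False
    if length / n_snp > p.max_density_bp_per_snp:
        return False
    if p.run_het_mode == "strict":
        if cs_het[b + 1] - cs_het[a] > p.window_het_max:
            return False
    return True


def _roh_one_chrom(
    g: np.ndarray, pos: np.ndarray, p: ROHParams
) -> list[tuple[int, int]]:
    """Maximal passing ROH intervals (marker indices) for one sample and
    chromosome, greedily from the left."""
    m = g.size
    if m < p.window_snp:
        return []
    het = g == 1
    miss = g == MISSING
    hom = (g == 0) | (g == 2)
    eligible = _roh_eligibility(het, miss, p)
    cs_het = np.concatenate([[0], np.cumsum(het)])

    out: list[tuple[int, int]] = []
    # maximal eligible stretches
    bounds = np.flatnonzero(np.diff(np.concatenate([[0], eligible.view(np.int8), [0]])))
    for s, e in zip(bounds[::2], bounds[1::2] - 1):
        # split at inter-marker gaps above max_gap_bp
        gaps = np.flatnonzero(np.diff(pos[s : e + 1]) > p.max_gap_bp) + s
        starts = [s] + [int(gp) + 1 for gp in gaps]
        ends = [int(gp) for gp in gaps] + [e]
        for a0, b0 in zip(starts, ends):
            out.extend(
                _roh_maximal_in_piece(a0, b0, hom, pos, cs_het, p)
            )
    return out


def _roh_maximal_in_piece(
    a0: int, b0: int, hom: np.ndarray, pos: np.ndarray,
    cs_het: np.ndarray, p: ROHParams,
) -> list[tuple[int, int]]:
    """Greedy maximal passing subintervals of one eligible, gap-free piece."""
    hom_idx = np.flatnonzero(hom[a0 : b0 + 1]) + a0
    if hom_idx.size == 0:
        return []
    a, b = int(hom_idx[0]), int(hom_idx[-1])
    if _roh_candidate_passes(a, b, pos, cs_het, p):
        return [(a, b)]
    # a shorter subinterval can still pass when the trimmed piece fails the
    # density or run-level heterozygote constraint (both non-monotone in the
    # interval); marker-count and length minima are monotone, so bail out.
    n_snp = b - a + 1
    if n_snp < p.min_snp or pos[b] - pos[a] + 1 < p.min_length_bp:
        return []
    out: list[tuple[int, int]] = []
    budget = p.window_het_max if p.run_het_mode == "strict" else math.inf
    k = 0
    while k < hom_idx.size:
        ai = int(hom_idx[k])
        # largest end with het budget respected
        lo_, hi_ = ai, int(hom_idx[-1])
        b_budget = hi_
        if budget is not math.inf:
            while cs_het[b_budget + 1] - cs_het[ai] > budget:
                b_budget -= 1
            if b_budget < ai:
                k += 1
                continue
        # try candidate ends (homozygous markers) from longest down
        cand = hom_idx[(hom_idx >= ai) & (hom_idx <= b_budget)]
        emitted = False
        for bi in cand[::-1]:
            if _roh_candidate_passes(ai, int(bi), pos, cs_het, p):
                out.append((ai, int(bi)))
                k = int(np.searchsorted(hom_idx, bi, side="right"))
                emitted = True
                break
        if not emitted:
            k += 1
    return out


def detect_roh(dataset: GenotypeDataset, params: ROHParams | None = None) -> RunSet:
    """Call ROH for every sample on every autosome in the dataset."""
    p = params or ROHParams()
    runs: list[Run] = []
    t = dataset.markers.table
    pops = dataset.samples["population"].astype(str).to_numpy()
    sids = dataset.samples["sample_id"].astype(str).to_numpy()
    for chrom in dataset.markers.chromosomes:
        idx = dataset.markers.chrom_indices(chrom)
        pos = t["pos_bp"].to_numpy()[idx]
        if idx.size < p.window_snp:
            logger.warning(
                "chromosome %s has %d < %d markers; no ROH called there",
                chrom, idx.size, p.window_snp,
            )
            continue
        sub = dataset.genotypes[:, idx]
        for i in range(dataset.n_samples):
            for a, b in _roh_one_chrom(sub[i], pos, p):
                length = int(pos[b] - pos[a] + 1)
                runs.append(
                    Run(
                        sample_id=sids[i], population=pops[i], kind=ROH,
                        chrom=int(chrom), start_bp=int(pos[a]),
                        end_bp=int(pos[b]), n_snp=b - a + 1,
                        length_class=classify_run_length(length, ROH),
                    )
                )
    return RunSet(runs=runs, kind=ROH, params=p)


# ---------------------------------------------------------------------------
# ROHet caller

def _rohet_one_chrom(
    g: np.ndarray, pos: np.ndarray, p: ROHetParams
) -> list[tuple[int, int]]:
    """Maximal passing ROHet intervals (marker indices), greedily from the
    left, for one sample and chromosome."""
    het_idx = np.flatnonzero(g == 1)
    if het_idx.size == 0:
        return []
    cs_hom = np.concatenate([[0], np.cumsum((g == 0) | (g == 2))])
    cs_mis = np.concatenate([[0], np.cumsum(g == MISSING)])
    m = g.size
    out: list[tuple[int, int]] = []
    k = 0
    b_max = 0
    while k < het_idx.size:
        a = int(het_idx[k])
        b_max = max(b_max, a)
        # largest b with both budgets respected on [a, b] (monotone two-pointer)
        while b_max + 1 < m and (
            cs_hom[b_max + 2] - cs_hom[a] <= p.max_homozygous
            and cs_mis[b_max + 2] - cs_mis[a] <= p.max_missing
        ):
            b_max += 1
        # terminal marker must be heterozygous
        j = int(np.searchsorted(het_idx, b_max, side="right")) - 1
        b = int(het_idx[j])
        n_snp = b - a + 1
        if n_snp >= p.min_snp and pos[b] - pos[a] + 1 >= p.min_length_bp:
            out.append((a, b))
            k = int(np.searchsorted(het_idx, b, side="right"))
        else:
            k += 1
    return out


def detect_rohet(dataset: GenotypeDataset, params: ROHetParams | None = None) -> RunSet:
    """Call ROHet for every sample on every autosome in the dataset."""
    p = params or ROHetParams()
    runs: list[Run] = []
    t = dataset.markers.table
    pops = dataset.samples["population"].astype(str).to_numpy()
    sids = dataset.samples["sample_id"].astype(str).to_numpy()
    for chrom in dataset.markers.chromosomes:
        idx = dataset.markers.chrom_indices(chrom)
        pos = t["pos_bp"].to_numpy()[idx]
        if idx.size < p.min_snp:
            logger.warning(
                "chromosome %s has %d < %d markers; no ROHet called there",
                chrom, idx.size, p.min_snp,
            )
            continue
        sub = dataset.genotypes[:, idx]
        for i in range(dataset.n_samples):
            for a, b in _rohet_one_chrom(sub[i], pos, p):
                length = int(pos[b] - pos[a] + 1)
                runs.append(
                    Run(
                        sample_id=sids[i], population=pops[i], kind=ROHET,
                        chrom=int(chrom), start_bp=int(pos[a]),
                        end_bp=int(pos[b]), n_snp=b - a + 1,
                        length_class=classify_run_length(length, ROHET),
                    )
                )
    return RunSet(runs=runs, kind=ROHET, params=p)


# ---------------------------------------------------------------------------
# Summaries

def summarize_runs(
    runset: RunSet,
    samples: pd.DataFrame | None = None,
    by: str = "population",
) -> pd.DataFrame:
    """Per-group run counts and coverage percentages per length class.

    ``samples`` (sample_id/population), when given, supplies group sizes so
    zero-run samples count toward the per-sample mean.  ``by`` may be
    ``"population"`` or ``"sample"``.
    """
    if by not in ("population", "sample"):
        raise RunDetectionError(f"unsupported grouping {by!r}")
    key = "population" if by == "population" else "sample"
    labels = (
        ROH_CLASS_LABELS if runset.kind == ROH else ROHET_CLASS_LABELS
    )
    df = runset.to_frame()
    if samples is not None:
        if by == "population":
            group_sizes = samples.groupby("population").size()
            groups = list(group_sizes.index)
        else:
            groups = samples["sample_id"].astype(str).tolist()
            group_sizes = pd.Series(1, index=groups)
    else:
        groups = sorted(df[key].unique()) if len(df) else []
        group_sizes = (
            df.groupby(key)["sample"].nunique()
            if by == "population"
            else pd.Series(1, index=groups)
        )
    rows = []
    for grp in groups:
        sub = df[df[key] == grp] if len(df) else df
        total_len = sub["length_bp"].sum()
        n_in_group = int(group_sizes.get(grp, 0)) or 1
        for label in labels:
            cls = sub[sub["class"] == label]
            cls_len = cls["length_bp"].sum()
            rows.append(
                {
                    by: grp,
                    "class": label,
                    "n_runs": len(cls),
                    "runs_per_sample": len(cls) / n_in_group,
                    "coverage_pct": (100.0 * cls_len / total_len) if total_len else 0.0,
                    "coverage_defined": bool(total_len),
                }
            )
        rows.append(
            {
                by: grp,
                "class": "total",
                "n_runs": len(sub),
                "runs_per_sample": len(sub) / n_in_group,
                "coverage_pct": 100.0 if total_len else 0.0,
                "coverage_defined": bool(total_len),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[by, "class", "n_runs", "runs_per_sample", "coverage_pct",
                 "coverage_defined"],
    )


def chromosome_coverage(
    runset: RunSet, dataset: GenotypeDataset
) -> pd.DataFrame:
    """Per population and chromosome: run bp over the chromosome's marker
    extent (union of per-sample run lengths divided by n samples)."""
    df = runset.to_frame()
    pops = dataset.samples.groupby("population").size()
    rows = []
    for chrom in dataset.markers.chromosomes:
        span = dataset.markers.chrom_span_bp(chrom)
        for pop, n in pops.items():
            sub = df[(df["chrom"] == chrom) & (df["population"] == pop)]
            mean_bp = sub["length_bp"].sum() / n
            rows.append(
                {
                    "population": pop,
                    "chrom": chrom,
                    "coverage_ratio": mean_bp / span,
                }
            )
    return pd.DataFrame(rows)
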