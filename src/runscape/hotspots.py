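"""Run-incidence tracks, hotspot islands, cross-population overlaps.

For one population and run kind, the incidence track gives, at every marker,
the fraction of genotyped samples whose run covers that marker.  Markers at
or above a resolved threshold — an absolute fraction (e.g. "at least 50% of
the population in a ROH") and/or a top-quantile of the incidence
distribution (e.g. top 0.5% for ROH, top 0.1% for ROHet) — are hotspot
markers; consecutive hotspot markers within a merge gap form islands.
Islands can be intersected across populations and annotated against a
user-supplied BED or GFF3 interval file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeDataset
from .runs import RunSet


class HotspotError(ValueError):
    pass


@dataclass
class IncidenceTrack:
    """Per-marker run incidence for one population and run kind."""

    population: str
    kind: str
    table: pd.DataFrame  # chrom, pos_bp, n_in_run, n_genotyped, fraction

    def __post_init__(self) -> None:
        t = self.table
        if (t["n_in_run"] > t["n_genotyped"]).any():
            raise HotspotError("more samples in runs than genotyped")
        frac = t["fraction"].to_numpy()
        if np.any((frac < 0) | (frac > 1)):
            raise HotspotError("fractions outside [0, 1]")


@dataclass(frozen=True)
class ThresholdSpec:
    """How to turn an incidence track into a hotspot cutoff.

    ``absolute``: use ``value`` as the fraction directly.  ``top_quantile``:
    use the (1 - value)-quantile of the per-marker fractions (``value`` is
    the tail mass, e.g. 0.005).  ``combined``: the larger of the two
    resolved fractions (an absolute floor under a quantile rule).
    """

    mode: str = "combined"
    value: float = 0.50
    quantile_tail: float = 0.005

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "top_quantile", "combined"):
            raise HotspotError(f"unknown threshold mode {self.mode!r}")
        if not 0.0 < self.value < 1.0:
            raise HotspotError("value must be in (0, 1)")
        if not 0.0 < self.quantile_tail < 1.0:
            raise HotspotError("quantile_tail must be in (0, 1)")


@dataclass(frozen=True)
class Island:
    population: str
    kind: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snp: int
    peak_fraction: float
    mean_fraction: float
    resolved_threshold: float


ISLAND_COLUMNS = [
    "population", "kind", "chrom", "start_bp", "end_bp", "n_snp",
    "peak_fraction", "mean_fraction", "resolved_threshold",
]


def islands_to_frame(islands: list[Island]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (i.population, i.kind, i.chrom, i.start_bp, i.end_bp, i.n_snp,
             i.peak_fraction, i.mean_fraction, i.resolved_threshold)
            for i in islands
        ],
        columns=ISLAND_COLUMNS,
    )


def incidence_track(
    runset: RunSet, dataset: GenotypeDataset, population: str | None = None
) -> IncidenceTrack:
    """Fraction of genotyped samples covered by a run at every marker.

    A marker is covered for a sample iff ``start_bp <= pos <= end_bp`` of
    one of that sample's runs.  The denominator is the number of samples
    with a called genotype at the marker, not the population size.
    """
    if population is not None:
        idx = dataset.population_indices(population)
        if idx.size == 0:
            raise HotspotError(f"no samples in population {population!r}")
        ds = dataset.subset_samples(idx)
        label = population
    else:
        ds = dataset
        label = "all"
    t = ds.markers.table
    chrom = t["chrom"].to_numpy()
    pos = t["pos_bp"].to_numpy()
    sample_rows = {sid: i for i, sid in enumerate(ds.sample_ids)}
    in_run = np.zeros((ds.n_samples, ds.n_markers), dtype=bool)
    for r in runset.runs:
        i = sample_rows.get(r.sample_id)
        if i is None:
            continue
        cols = (chrom == r.chrom) & (pos >= r.start_bp) & (pos <= r.end_bp)
        in_run[i, cols] = True
    n_genotyped = ds.called_mask().sum(axis=0)
    n_in_run = in_run.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_genotyped > 0, n_in_run / n_genotyped, 0.0)
    return IncidenceTrack(
        population=label,
        kind=runset.kind,
        table=pd.DataFrame(
            {
                "chrom": chrom,
                "pos_bp": pos,
                "n_in_run": n_in_run,
                "n_genotyped": n_genotyped,
                "fraction": frac,
            }
        ),
    )


def resolve_threshold(track: IncidenceTrack, spec: ThresholdSpec) -> float:
    """Resolve a threshold spec against a track's incidence distribution.

    Quantile mode uses the inclusive upper ("higher") empirical quantile, so
    the resolved threshold is always an observed incidence value and the
    markers at or above it are exactly the top ``quantile_tail`` share of
    the track (plus ties).
    """
    if len(track.table) == 0:
        raise HotspotError("empty incidence track")
    frac = track.table["fraction"].to_numpy()
    if spec.mode == "absolute":
        return spec.value
    quantile = float(np.quantile(frac, 1.0 - spec.quantile_tail, method="higher"))
    if spec.mode == "top_quantile":
        return quantile
    return max(spec.value, quantile)


def call_islands(
    track: IncidenceTrack,
    spec: ThresholdSpec,
    merge_gap_bp: int = 500_000,
) -> list[Island]:
    """Markers at or above the resolved threshold, merged into islands.

    Consecutive hotspot markers on one chromosome at most ``merge_gap_bp``
    apart join one island; island bounds are the first/last member marker
    positions.  Ties at the threshold are included (>= comparison).
    """
    thr = resolve_threshold(track, spec)
    t = track.table
    hot = t["fraction"].to_numpy() >= thr
    chrom = t["chrom"].to_numpy()
    pos = t["pos_bp"].to_numpy()
    frac = t["fraction"].to_numpy()
    islands: list[Island] = []
    members: list[int] = []

    def _flush() -> None:
        if not members:
            return
        sel = np.asarray(members)
        islands.append(
            Island(
                population=track.population,
                kind=track.kind,
                chrom=int(chrom[sel[0]]),
                start_bp=int(pos[sel[0]]),
                end_bp=int(pos[sel[-1]]),
                n_snp=len(sel),
                peak_fraction=float(frac[sel].max()),
                mean_fraction=float(frac[sel].mean()),
                resolved_threshold=thr,
            )
        )
        members.clear()

    for j in np.flatnonzero(hot):
        if members and (
            chrom[j] != chrom[members[-1]]
            or pos[j] - pos[members[-1]] > merge_gap_bp
        ):
            _flush()
        members.append(int(j))
    _flush()
    return islands


def overlap_islands(
    islands_by_population: dict[str, list[Island]]
) -> pd.DataFrame:
    """bp-interval intersections of islands across populations.

    Returns one row per maximal shared region carried by >= 2 populations:
    chrom, start_bp, end_bp, n_populations, populations (comma-joined,
    sorted).
    """
    if len(islands_by_population) < 2:
        raise HotspotError("need islands from at least two populations")
    events: dict[int, list[tuple[int, int, str]]] = {}
    for pop, islands in islands_by_population.items():
        for isl in islands:
            events.setdefault(isl.chrom, []).append(
                (isl.start_bp, isl.end_bp, pop)
            )
    rows = []
    for chrom in sorted(events):
        ivals = events[chrom]
        bounds = sorted(
            {s for s, _, _ in ivals} | {e + 1 for _, e, _ in ivals}
        )
        for lo, hi in zip(bounds, bounds[1:]):
            pops = sorted({p for s, e, p in ivals if s <= lo and e >= hi - 1})
            if len(pops) >= 2:
                rows.append(
                    {
                        "chrom": chrom,
                        "start_bp": lo,
                        "end_bp": hi - 1,
                        "n_populations": len(pops),
                        "populations": ",".join(pops),
                    }
                )
    df = pd.DataFrame(
        rows, columns=["chrom", "start_bp", "end_bp", "n_populations", "populations"]
    )
    # merge adjacent slices with identical carrier sets
    merged: list[dict] = []
    for row in df.to_dict("records"):
        if (
            merged
            and merged[-1]["chrom"] == row["chrom"]
            and merged[-1]["end_bp"] + 1 == row["start_bp"]
            and merged[-1]["populations"] == row["populations"]
        ):
            merged[-1]["end_bp"] = row["end_bp"]
        else:
            merged.append(row)
    return pd.DataFrame(
        merged, columns=["chrom", "start_bp", "end_bp", "n_populations", "populations"]
    )


def _read_bed_intervals(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            # BED is 0-based half-open; convert to 1-based inclusive
            rows.append((int(f[0]), int(f[1]) + 1, int(f[2]), name))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "name"])


def _read_gff3_intervals(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise HotspotError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("Name") or attrs.get("ID") or f[2]
            # GFF3 is already 1-based inclusive
            rows.append((int(f[0]), int(f[3]), int(f[4]), name))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "name"])


def annotate_islands(
    islands: list[Island], annotation_path: str
) -> pd.DataFrame:
    """Features from a BED or GFF3 file overlapping each island by >= 1 bp.

    Coordinates are converted internally to 1-based inclusive; the overlap
    length in bp is reported per (island, feature) pair.
    """
    path = str(annotation_path)
    if path.endswith((".gff", ".gff3")):
        feats = _read_gff3_intervals(path)
    else:
        feats = _read_bed_intervals(path)
    rows = []
    for isl in islands:
        sub = feats[
            (feats["chrom"] == isl.chrom)
            & (feats["start_bp"] <= isl.end_bp)
            & (feats["end_bp"] >= isl.start_bp)
        ]
        for feat in sub.itertuples():
            ov = min(isl.end_bp, feat.end_bp) - max(isl.start_bp, feat.start_bp) + 1
            rows.append(
                {
                    "population": isl.population,
                    "kind": isl.kind,
                    "chrom": isl.chrom,
                    "island_start_bp": isl.start_bp,
                    "island_end_bp": isl.end_bp,
                    "feature": feat.name,
                    "feature_start_bp": feat.start_bp,
                    "feature_end_bp": feat.end_bp,
                    "overlap_bp": ov,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "population", "kind", "chrom", "island_start_bp", "island_end_bp",
            "feature", "feature_start_bp", "feature_end_bp", "overlap_bp",
        ],
    )
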