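"""Synthetic multi-population SNP-array genotypes with known autozygosity.

A pedigree is gene-dropped: founder haplotypes are drawn from a configurable
allele-frequency distribution, offspring haplotypes are formed by meiosis
with a Haldane (no-interference) crossover model at a fixed cM/Mb rate, and
every transmitted chromosome segment remembers which founder haplotype it
came from.  That ancestry bookkeeping yields exact ground truth: pedigree
inbreeding coefficients, the true autozygous (IBD) segments of every sample,
and the coordinates of any planted low-diversity (ROH-island) or
balancing-selection-like (ROHet-island) regions.

The generator emulates recent inbreeding (full-sib loops -> long IBD
segments), background relatedness from small closed populations (short
segments), between-population divergence (Balding–Nichols founder
frequencies) and random missingness.  It does not model mutation, genotyping
error, ascertainment bias or realistic linkage-disequilibrium decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeDataset, MarkerMap


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pedigree

@dataclass(frozen=True)
class Individual:
    id: str
    sire: str | None
    dam: str | None
    generation: int
    population: str


class Pedigree:
    """Ordered pedigree: parents always precede offspring; founders have no
    parents.  Inbreeding coefficients come from the tabular kinship
    recurrence (path counting gives the same numbers; the tests carry an
    independent path-counting oracle)."""

    def __init__(self, individuals: list[Individual]):
        self.individuals = list(individuals)
        self._index = {ind.id: i for i, ind in enumerate(self.individuals)}
        if len(self._index) != len(self.individuals):
            raise SimulationError("duplicate individual id in pedigree")
        for i, ind in enumerate(self.individuals):
            if (ind.sire is None) != (ind.dam is None):
                raise SimulationError(f"{ind.id}: both parents or neither")
            for par in (ind.sire, ind.dam):
                if par is not None:
                    if par not in self._index:
                        raise SimulationError(f"{ind.id}: unknown parent {par}")
                    if self._index[par] >= i:
                        raise SimulationError(
                            f"{ind.id}: parent {par} does not precede offspring"
                        )

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.sire is None]

    def kinship_matrix(self) -> np.ndarray:
        """Full kinship matrix by the tabular method."""
        n = len(self.individuals)
        phi = np.zeros((n, n))
        for i, ind in enumerate(self.individuals):
            if ind.sire is None:
                phi[i, i] = 0.5
                continue
            s, d = self._index[ind.sire], self._index[ind.dam]
            phi[i, i] = 0.5 * (1.0 + phi[s, d])
            for j in range(i):
                phi[i, j] = phi[j, i] = 0.5 * (phi[s, j] + phi[d, j])
        return phi

    def inbreeding(self) -> pd.Series:
        """Pedigree inbreeding coefficient F per individual (kinship of the
        parents; founders are 0 by definition)."""
        phi = self.kinship_matrix()
        out = {}
        for ind in self.individuals:
            if ind.sire is None:
                out[ind.id] = 0.0
            else:
                out[ind.id] = phi[self._index[ind.sire], self._index[ind.dam]]
        return pd.Series(out, name="f_ped")

    def final_generation_ids(self) -> list[str]:
        last = max(ind.generation for ind in self.individuals)
        return [ind.id for ind in self.individuals if ind.generation == last]


@dataclass(frozen=True)
class PopulationDesign:
    """Mating design for one population.

    ``n_founders`` unrelated founders mate in disjoint couples for
    ``n_generations`` generations, ``n_offspring_per_generation`` children
    each generation.  If ``n_fullsib_offspring`` > 0, that many extra
    final-generation individuals are produced from full-sib pairs of the
    penultimate generation (pedigree F = 0.25 when grandparents are
    unrelated); the regular final-generation children are produced from
    non-sib couples.
    """

    label: str
    n_founders: int = 20
    n_generations: int = 2
    n_offspring_per_generation: int = 20
    n_fullsib_offspring: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2 or self.n_founders % 2:
            raise SimulationError("n_founders must be an even number >= 2")
        if self.n_generations < 1:
            raise SimulationError("need at least one bred generation")


def build_pedigree(
    designs: list[PopulationDesign], rng: np.random.Generator
) -> Pedigree:
    """Build a multi-population pedigree from mating designs."""
    individuals: list[Individual] = []
    for design in designs:
        lab = design.label
        founders = [
            Individual(f"{lab}_f{k}", None, None, 0, lab)
            for k in range(design.n_founders)
        ]
        individuals.extend(founders)
        prev = founders
        parent_couple: dict[str, tuple[str, str]] = {}
        for g in range(1, design.n_generations + 1):
            order = rng.permutation(len(prev))
            couples = [
                (prev[order[2 * i]].id, prev[order[2 * i + 1]].id)
                for i in range(len(prev) // 2)
            ]
            if g > 1:
                # keep regular matings outbred where possible: reject couples
                # that happen to be full sibs
                couples = [
                    c for c in couples
                    if parent_couple.get(c[0]) != parent_couple.get(c[1])
                    or parent_couple.get(c[0]) is None
                ]
                if not couples:
                    raise SimulationError(
                        f"{lab}: no non-sib couples available in generation {g}"
                    )
            children: list[Individual] = []
            for k in range(design.n_offspring_per_generation):
                sire, dam = couples[k % len(couples)]
                child = Individual(f"{lab}_g{g}_{k}", sire, dam, g, lab)
                children.append(child)
                parent_couple[child.id] = (sire, dam)
            if g == design.n_generations and design.n_fullsib_offspring > 0:
                sibships: dict[tuple[str, str], list[str]] = {}
                for ind in prev:
                    cp = parent_couple.get(ind.id)
                    if cp is not None:
                        sibships.setdefault(cp, []).append(ind.id)
                pairs = [v[:2] for v in sibships.values() if len(v) >= 2]
                if not pairs:
                    raise SimulationError(
                        f"{lab}: no full-sib pairs available for loop matings"
                    )
                for k in range(design.n_fullsib_offspring):
                    a, b = pairs[k % len(pairs)]
                    child = Individual(f"{lab}_g{g}_fs{k}", a, b, g, lab)
                    children.append(child)
                    parent_couple[child.id] = (a, b)
            individuals.extend(children)
            prev = children
    return Pedigree(individuals)


# ---------------------------------------------------------------------------
# Simulation configuration and truth

@dataclass(frozen=True)
class IslandSpec:
    """A region to overwrite so a known fraction of one population carries a
    run there: ``roh`` plants a shared homozygous haplotype, ``rohet`` plants
    all-heterozygous genotypes."""

    chromosome: int
    start_bp: int
    end_bp: int
    mode: str  # "roh" | "rohet"
    target_carrier_fraction: float
    population_label: str

    def __post_init__(self) -> None:
        if self.mode not in ("roh", "rohet"):
            raise SimulationError(f"unknown island mode {self.mode!r}")
        if not 0.0 < self.target_carrier_fraction <= 1.0:
            raise SimulationError("carrier fraction must be in (0, 1]")
        if self.start_bp > self.end_bp:
            raise SimulationError("island start after end")


@dataclass(frozen=True)
class SimConfig:
    """Genome and sampling model for the generator.

    Defaults give five 50-Mb chromosomes at 1,000 markers each (~50 kb
    spacing, a scaled-down caprine 50–70k array), founder frequencies from a
    Beta(0.5, 0.5) truncated to [0.05, 0.95], a 1 cM/Mb Haldane map, mild
    between-population divergence (Balding–Nichols Fst 0.1) and 0.5%
    missingness.
    """

    rng_seed: int
    pedigree: tuple[PopulationDesign, ...] = ()
    n_chromosomes: int = 5
    chromosome_length_bp: int = 50_000_000
    markers_per_chromosome: int = 1_000
    founder_beta_a: float = 0.5
    founder_beta_b: float = 0.5
    founder_freq_range: tuple[float, float] = (0.05, 0.95)
    population_fst: float = 0.1
    cm_per_mb: float = 1.0
    missing_rate: float = 0.005
    islands: tuple[IslandSpec, ...] = ()

    def __post_init__(self) -> None:
        for name in ("missing_rate", "population_fst"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.markers_per_chromosome < 1 or self.n_chromosomes < 1:
            raise SimulationError("need at least one marker and one chromosome")
        lo, hi = self.founder_freq_range
        if not (0.0 <= lo < hi <= 1.0):
            raise SimulationError("bad founder frequency range")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    f_ped: pd.Series
    ibd_segments: pd.DataFrame  # sample_id, chrom, start_bp, end_bp
    islands: pd.DataFrame  # chrom, start_bp, end_bp, mode, population, fractions
    genome_length_bp: int

    def ibd_fraction(self, sample_ids: list[str] | None = None) -> pd.Series:
        """Fraction of the genome inside true autozygous segments, per sample."""
        ids = list(self.f_ped.index) if sample_ids is None else list(sample_ids)
        lengths = pd.Series(0.0, index=ids)
        if len(self.ibd_segments):
            seg = self.ibd_segments
            tot = (seg["end_bp"] - seg["start_bp"] + 1).groupby(
                seg["sample_id"]
            ).sum()
            lengths.loc[tot.index.intersection(lengths.index)] = tot
        return lengths / float(self.genome_length_bp)


# ---------------------------------------------------------------------------
# Gene drop

#: minimum truth-segment length recorded; below marker resolution anyway
MIN_IBD_SEGMENT_BP = 10_000


def _draw_positions(n: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct sorted 1-based positions on [1, length]."""
    if n > length:
        raise SimulationError("more markers than base pairs")
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return pos.astype(np.int64)


def _truncated_beta(
    a: float, b: float, lo: float, hi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    out = rng.beta(a, b, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _recombine(
    hap_a: tuple[np.ndarray, np.ndarray],
    hap_b: tuple[np.ndarray, np.ndarray],
    length_bp: int,
    cm_per_mb: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One meiosis: Poisson crossover count (Haldane), uniform positions.

    Haplotypes are run-length lists ``(ends, ids)``: ``ends`` are inclusive
    segment end positions (last = chromosome length), ``ids`` founder
    haplotype labels.
    """
    mean_x = length_bp / 1e6 * cm_per_mb / 100.0
    n_x = rng.poisson(mean_x)
    xs = np.unique(rng.integers(1, length_bp, size=n_x)) if n_x else np.array([], dtype=np.int64)
    cur = int(rng.integers(2))
    sources = (hap_a, hap_b)
    out_ends: list[int] = []
    out_ids: list[int] = []
    prev = 0
    for bound in list(xs) + [length_bp]:
        ends, ids = sources[cur]
        i = int(np.searchsorted(ends, prev + 1))
        while prev < bound:
            seg_end = min(int(ends[i]), int(bound))
            if out_ids and out_ids[-1] == int(ids[i]):
                out_ends[-1] = seg_end
            else:
                out_ends.append(seg_end)
                out_ids.append(int(ids[i]))
            prev = seg_end
            i += 1
        cur ^= 1
    return np.asarray(out_ends, dtype=np.int64), np.asarray(out_ids, dtype=np.int64)


def _autozygous_intervals(
    hap0: tuple[np.ndarray, np.ndarray], hap1: tuple[np.ndarray, np.ndarray]
) -> list[tuple[int, int]]:
    """bp intervals where both haplotypes descend from the same founder
    haplotype."""
    bounds = np.unique(np.concatenate([hap0[0], hap1[0]]))
    out: list[tuple[int, int]] = []
    prev = 0
    for b in bounds:
        id0 = hap0[1][np.searchsorted(hap0[0], b)]
        id1 = hap1[1][np.searchsorted(hap1[0], b)]
        if id0 == id1:
            start, end = prev + 1, int(b)
            if out and out[-1][1] + 1 == start:
                out[-1] = (out[-1][0], end)
            else:
                out.append((start, end))
        prev = int(b)
    return [(s, e) for s, e in out if e - s + 1 >= MIN_IBD_SEGMENT_BP]


def gene_drop(pedigree: Pedigree, config: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Drop founder haplotypes through the pedigree.

    Returns the genotype dataset for every pedigree member (callers usually
    subset to the final generation) and the matching :class:`SimTruth`.
    Missingness is applied last; planted islands are applied separately by
    :func:`plant_islands`.
    """
    if config.markers_per_chromosome <= 0:
        raise SimulationError("zero markers requested")
    rng = np.random.default_rng(config.rng_seed)
    L = config.chromosome_length_bp
    chroms = list(range(1, config.n_chromosomes + 1))

    rows = []
    positions: dict[int, np.ndarray] = {}
    for c in chroms:
        pos = _draw_positions(config.markers_per_chromosome, L, rng)
        positions[c] = pos
        rows.append(
            pd.DataFrame(
                {"chrom": c, "snp_id": [f"snp{c}_{k}" for k in range(len(pos))],
                 "pos_bp": pos}
            )
        )
    markers = MarkerMap(pd.concat(rows, ignore_index=True))
    m_total = markers.n_markers
    lo, hi = config.founder_freq_range
    base_p = _truncated_beta(
        config.founder_beta_a, config.founder_beta_b, lo, hi, m_total, rng
    )

    pops = list(dict.fromkeys(ind.population for ind in pedigree.individuals))
    fst = config.population_fst
    pop_freqs: dict[str, np.ndarray] = {}
    for pop in pops:
        if fst > 0.0:
            shape = (1.0 - fst) / fst
            pop_freqs[pop] = rng.beta(base_p * shape, (1.0 - base_p) * shape)
        else:
            pop_freqs[pop] = base_p.copy()

    founders = pedigree.founders()
    hap_of: dict[str, tuple[int, int]] = {}
    n_f = len(founders)
    founder_alleles = np.empty((2 * n_f, m_total), dtype=np.int8)
    for k, ind in enumerate(founders):
        hap_of[ind.id] = (2 * k, 2 * k + 1)
        p = pop_freqs[ind.population]
        founder_alleles[2 * k] = rng.random(m_total) < p
        founder_alleles[2 * k + 1] = rng.random(m_total) < p

    # haplotype run-length lists per individual per chromosome
    haps: dict[str, dict[int, list[tuple[np.ndarray, np.ndarray]]]] = {}
    for ind in pedigree.individuals:
        per_chrom: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
        if ind.sire is None:
            h0, h1 = hap_of[ind.id]
            for c in chroms:
                full = np.array([L], dtype=np.int64)
                per_chrom[c] = [
                    (full.copy(), np.array([h0], dtype=np.int64)),
                    (full.copy(), np.array([h1], dtype=np.int64)),
                ]
        else:
            for c in chroms:
                gametes = []
                for parent in (ind.sire, ind.dam):
                    ph = haps[parent][c]
                    gametes.append(
                        _recombine(ph[0], ph[1], L, config.cm_per_mb, rng)
                    )
                per_chrom[c] = gametes
        haps[ind.id] = per_chrom

    ids = pedigree.ids
    geno = np.empty((len(ids), m_total), dtype=np.int8)
    ibd_rows: list[tuple[str, int, int, int]] = []
    for i, ind_id in enumerate(ids):
        for c in chroms:
            idx = markers.chrom_indices(c)
            pos = positions[c]
            h0, h1 = haps[ind_id][c]
            src0 = h0[1][np.searchsorted(h0[0], pos)]
            src1 = h1[1][np.searchsorted(h1[0], pos)]
            geno[i, idx] = founder_alleles[src0, idx] + founder_alleles[src1, idx]
            for s, e in _autozygous_intervals(h0, h1):
                ibd_rows.append((ind_id, c, s, e))

    if config.missing_rate > 0.0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = MISSING

    samples = pd.DataFrame(
        {
            "sample_id": ids,
            "population": [ind.population for ind in pedigree.individuals],
        }
    )
    dataset = GenotypeDataset(markers=markers, samples=samples, genotypes=geno)
    truth = SimTruth(
        f_ped=pedigree.inbreeding(),
        ibd_segments=pd.DataFrame(
            ibd_rows, columns=["sample_id", "chrom", "start_bp", "end_bp"]
        ),
        islands=pd.DataFrame(
            columns=[
                "chrom", "start_bp", "end_bp", "mode", "population",
                "target_fraction", "realized_fraction",
            ]
        ),
        genome_length_bp=config.n_chromosomes * L,
    )
    return dataset, truth


def plant_islands(
    dataset: GenotypeDataset,
    truth: SimTruth,
    island_specs: list[IslandSpec],
    rng: np.random.Generator,
) -> tuple[GenotypeDataset, SimTruth]:
    """Overwrite genotypes inside each island for round(f * n) carriers.

    ``roh`` islands share one homozygous haplotype across carriers (so the
    region is both homozygous and population-frequent); ``rohet`` islands
    become heterozygous at every member marker.  Realized carrier fractions
    are recorded in the returned truth.
    """
    geno = dataset.genotypes.copy()
    t = dataset.markers.table
    island_rows = [truth.islands] if len(truth.islands) else []
    for spec in island_specs:
        in_region = (
            (t["chrom"].to_numpy() == spec.chromosome)
            & (t["pos_bp"].to_numpy() >= spec.start_bp)
            & (t["pos_bp"].to_numpy() <= spec.end_bp)
        )
        cols = np.flatnonzero(in_region)
        if cols.size == 0:
            raise SimulationError(
                f"island {spec} covers no markers on the current map"
            )
        pop_idx = dataset.population_indices(spec.population_label)
        if pop_idx.size == 0:
            raise SimulationError(f"no samples in population {spec.population_label!r}")
        n_carriers = int(round(spec.target_carrier_fraction * pop_idx.size))
        carriers = rng.choice(pop_idx, size=n_carriers, replace=False)
        if spec.mode == "roh":
            shared = (rng.random(cols.size) < 0.5).astype(np.int8) * 2
            geno[np.ix_(carriers, cols)] = shared[None, :]
        else:
            geno[np.ix_(carriers, cols)] = 1
        island_rows.append(
            pd.DataFrame(
                [{
                    "chrom": spec.chromosome,
                    "start_bp": spec.start_bp,
                    "end_bp": spec.end_bp,
                    "mode": spec.mode,
                    "population": spec.population_label,
                    "target_fraction": spec.target_carrier_fraction,
                    "realized_fraction": n_carriers / pop_idx.size,
                }]
            )
        )
    new_truth = SimTruth(
        f_ped=truth.f_ped,
        ibd_segments=truth.ibd_segments,
        islands=pd.concat(island_rows, ignore_index=True),
        genome_length_bp=truth.genome_length_bp,
    )
    new_ds = GenotypeDataset(
        markers=dataset.markers,
        samples=dataset.samples,
        genotypes=geno,
        a1=dataset.a1,
        a2=dataset.a2,
    )
    return new_ds, new_truth


def simulate_dataset(config: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Pedigree build + gene drop + island planting in one deterministic call."""
    if not config.pedigree:
        raise SimulationError("config.pedigree must list at least one design")
    rng = np.random.default_rng(config.rng_seed)
    pedigree = build_pedigree(list(config.pedigree), rng)
    dataset, truth = gene_drop(pedigree, replace(config, rng_seed=config.rng_seed + 1))
    if config.islands:
        island_rng = np.random.default_rng(config.rng_seed + 2)
        dataset, truth = plant_islands(dataset, truth, list(config.islands), island_rng)
    return dataset, truth
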