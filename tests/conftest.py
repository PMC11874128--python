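from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from runscape import (
    GenotypeDataset, MarkerMap, PopulationDesign, QCConfig, SimConfig,
    apply_qc, detect_roh, detect_rohet, simulate_dataset,
)


def make_dataset(
    genotypes,
    positions=None,
    chrom=None,
    populations=None,
    quality=None,
) -> GenotypeDataset:
    """Small hand-built dataset: rows = samples, columns = markers."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    if positions is None:
        positions = (np.arange(m) + 1) * 10_000
    if chrom is None:
        chrom = np.ones(m, dtype=int)
    table = pd.DataFrame(
        {"chrom": chrom, "snp_id": [f"s{j}" for j in range(m)], "pos_bp": positions}
    )
    if quality is not None:
        table["quality_score"] = quality
    if populations is None:
        populations = ["POP"] * n
    samples = pd.DataFrame(
        {"sample_id": [f"ind{i}" for i in range(n)], "population": populations}
    )
    return GenotypeDataset(markers=MarkerMap(table), samples=samples, genotypes=g)


def fullsib_design(label: str = "POP", n_couples: int = 50) -> PopulationDesign:
    """Two bred generations; final generation is half outbred children of
    unrelated parents (F = 0) and half full-sib-mating offspring (F = 0.25)."""
    return PopulationDesign(
        label=label,
        n_founders=2 * n_couples,
        n_generations=2,
        n_offspring_per_generation=2 * n_couples,
        n_fullsib_offspring=2 * n_couples,
    )


@pytest.fixture(scope="session")
def fullsib_sim():
    """Shared recent-inbreeding simulation: 200 final-generation samples
    (100 outbred, 100 from full-sib loops), 5 x 50 Mb chromosomes, 10,000
    markers (25 kb spacing, so sub-2 Mb runs are resolvable), plus the
    lenient-QC dataset and both run sets."""
    cfg = SimConfig(rng_seed=1234, pedigree=(fullsib_design(),),
                    markers_per_chromosome=2_000)
    ds, truth = simulate_dataset(cfg)
    final = [i for i, s in enumerate(ds.sample_ids) if "_g2_" in s]
    cohort = ds.subset_samples(final)
    lenient, _ = apply_qc(cohort, QCConfig(track="lenient"))
    roh = detect_roh(lenient)
    rohet = detect_rohet(lenient)
    return {
        "dataset": cohort,
        "truth": truth,
        "lenient": lenient,
        "roh": roh,
        "rohet": rohet,
    }


@pytest.fixture(scope="session")
def multipop_sim():
    """Three diverged populations of unrelated final-generation samples."""
    cfg = SimConfig(
        rng_seed=777,
        pedigree=tuple(
            PopulationDesign(lab, n_founders=16, n_generations=1,
                             n_offspring_per_generation=16)
            for lab in ("A", "B", "C")
        ),
        n_chromosomes=2,
        markers_per_chromosome=600,
        chromosome_length_bp=30_000_000,
    )
    ds, truth = simulate_dataset(cfg)
    final = [i for i, s in enumerate(ds.sample_ids) if "_g1_" in s]
    return ds.subset_samples(final), truth
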