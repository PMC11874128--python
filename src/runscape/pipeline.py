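"""End-to-end orchestration: QC -> run detection -> inbreeding -> hotspots ->
structure -> group comparisons, from one YAML config, with a run manifest.

Every stochastic step (simulation only; all analysis stages are
deterministic) is governed by the single ``rng_seed`` in the config, so a
re-run with identical inputs and config reproduces identical output
checksums (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .breed_stats import class_count_comparison, roh_rohet_correlation
from .datamodel import GenotypeDataset
from .diversity import (
    DistanceMatrix, diversity_summary, ibs_distance, nj_tree, pca,
    population_distance_matrix, to_newick,
)
from .hotspots import (
    ThresholdSpec, call_islands, incidence_track, islands_to_frame,
    overlap_islands, annotate_islands,
)
from .inbreeding import GenomeExtent, inbreeding_correlations, inbreeding_table
from .plink import read_plink_binary, read_plink_text, write_plink_text
from .qc import QCConfig, apply_qc
from .runs import ROHParams, ROHetParams, detect_roh, detect_rohet, summarize_runs
from .simulate import IslandSpec, PopulationDesign, SimConfig, simulate_dataset

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; YAML round-trips loss-free."""

    out_dir: str
    rng_seed: int = 0
    input_prefix: str | None = None
    simulate: SimConfig | None = None
    qc_strict: QCConfig = field(default_factory=lambda: QCConfig(track="strict"))
    qc_lenient: QCConfig = field(default_factory=lambda: QCConfig(track="lenient"))
    roh: ROHParams = field(default_factory=ROHParams)
    rohet: ROHetParams = field(default_factory=ROHetParams)
    roh_threshold: ThresholdSpec = field(
        default_factory=lambda: ThresholdSpec(mode="combined", value=0.5, quantile_tail=0.005)
    )
    rohet_threshold: ThresholdSpec = field(
        default_factory=lambda: ThresholdSpec(
            mode="top_quantile", value=0.5, quantile_tail=0.001
        )
    )
    island_merge_gap_bp: int = 500_000
    pca_components: int = 5
    annotation_path: str | None = None

    def __post_init__(self) -> None:
        if (self.input_prefix is None) == (self.simulate is None):
            raise ConfigError("exactly one of input_prefix/simulate required")

    def to_dict(self) -> dict:
        def _conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: _conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [_conv(v) for v in obj]
            return obj

        out = {}
        for f in dataclasses.fields(self):
            out[f.name] = _conv(getattr(self, f.name))
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        try:
            if raw.get("simulate") is not None:
                sim = dict(raw["simulate"])
                sim["pedigree"] = tuple(
                    PopulationDesign(**d) for d in sim.get("pedigree", [])
                )
                sim["islands"] = tuple(
                    IslandSpec(**d) for d in sim.get("islands", [])
                )
                if "founder_freq_range" in sim:
                    sim["founder_freq_range"] = tuple(sim["founder_freq_range"])
                raw["simulate"] = SimConfig(**sim)
            for key, typ in (
                ("qc_strict", QCConfig), ("qc_lenient", QCConfig),
                ("roh", ROHParams), ("rohet", ROHetParams),
                ("roh_threshold", ThresholdSpec), ("rohet_threshold", ThresholdSpec),
            ):
                if isinstance(raw.get(key), dict):
                    raw[key] = typ(**raw[key])
            return cls(**raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad run config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    input_checksums: dict[str, str]
    stage_counts: dict[str, int]
    output_checksums: dict[str, str]
    started: float
    finished: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_input(prefix: str) -> GenotypeDataset:
    if Path(f"{prefix}.bed").exists():
        return read_plink_binary(f"{prefix}.bed", f"{prefix}.bim", f"{prefix}.fam")
    if Path(f"{prefix}.ped").exists():
        return read_plink_text(f"{prefix}.ped", f"{prefix}.map")
    raise ConfigError(f"no PLINK files found at prefix {prefix!r}")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run every stage, write all outputs under ``config.out_dir``, return
    the manifest (also written as ``manifest.json``, last)."""
    started = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}
    input_checksums: dict[str, str] = {}
    stage = "load"
    try:
        if config.input_prefix is not None:
            dataset = _load_input(config.input_prefix)
            for ext in (".bed", ".bim", ".fam", ".ped", ".map"):
                f = Path(f"{config.input_prefix}{ext}")
                if f.exists():
                    input_checksums[f.name] = _sha256(f)
            truth = None
        else:
            dataset, truth = simulate_dataset(config.simulate)
            write_plink_text(dataset, out / "simulated.ped", out / "simulated.map")
            truth.ibd_segments.to_csv(out / "truth_ibd.tsv", sep="\t", index=False)
            truth.f_ped.rename("f_ped").to_csv(out / "truth_f_ped.tsv", sep="\t")
            truth.islands.to_csv(out / "truth_islands.tsv", sep="\t", index=False)
        stage_counts["load_samples"] = dataset.n_samples
        stage_counts["load_markers"] = dataset.n_markers

        stage = "qc"
        ds_lenient, rep_l = apply_qc(dataset, config.qc_lenient)
        ds_strict, rep_s = apply_qc(dataset, config.qc_strict)
        rep_l.to_frame().to_csv(out / "qc_lenient.tsv", sep="\t", index=False)
        rep_s.to_frame().to_csv(out / "qc_strict.tsv", sep="\t", index=False)
        stage_counts["qc_lenient_markers"] = ds_lenient.n_markers
        stage_counts["qc_strict_markers"] = ds_strict.n_markers
        logger.info(
            "QC: %d markers lenient, %d strict, of %d",
            ds_lenient.n_markers, ds_strict.n_markers, dataset.n_markers,
        )

        stage = "run_detection"
        roh_runs = detect_roh(ds_lenient, config.roh)
        rohet_runs = detect_rohet(ds_lenient, config.rohet)
        roh_runs.to_frame().to_csv(out / "runs_roh.tsv", sep="\t", index=False)
        rohet_runs.to_frame().to_csv(out / "runs_rohet.tsv", sep="\t", index=False)
        summarize_runs(roh_runs, ds_lenient.samples).to_csv(
            out / "summary_roh.tsv", sep="\t", index=False
        )
        summarize_runs(rohet_runs, ds_lenient.samples).to_csv(
            out / "summary_rohet.tsv", sep="\t", index=False
        )
        stage_counts["roh_runs"] = len(roh_runs)
        stage_counts["rohet_runs"] = len(rohet_runs)

        stage = "inbreeding"
        extent = GenomeExtent.from_dataset(ds_lenient)
        # coefficient cohort: samples surviving strict QC
        table = inbreeding_table(ds_strict, roh_runs, rohet_runs, extent=extent)
        table.to_csv(out / "inbreeding.tsv", sep="\t")
        corr, corr_p = inbreeding_correlations(table)
        corr.to_csv(out / "inbreeding_correlations.tsv", sep="\t")
        corr_p.to_csv(out / "inbreeding_correlation_pvalues.tsv", sep="\t")
        stage_counts["inbreeding_samples"] = len(table)

        stage = "hotspots"
        islands_by_pop: dict[str, dict[str, list]] = {"ROH": {}, "ROHet": {}}
        track_frames = []
        island_frames = []
        for kind, runset, spec in (
            ("ROH", roh_runs, config.roh_threshold),
            ("ROHet", rohet_runs, config.rohet_threshold),
        ):
            for pop in ds_lenient.populations:
                track = incidence_track(runset, ds_lenient, population=pop)
                tf = track.table.copy()
                tf.insert(0, "population", pop)
                tf.insert(1, "kind", kind)
                track_frames.append(tf)
                islands = call_islands(track, spec, config.island_merge_gap_bp)
                islands_by_pop[kind][pop] = islands
                island_frames.append(islands_to_frame(islands))
        pd.concat(track_frames, ignore_index=True).to_csv(
            out / "incidence_tracks.tsv", sep="\t", index=False
        )
        nonempty = [f for f in island_frames if len(f)]
        all_islands = (
            pd.concat(nonempty, ignore_index=True) if nonempty else island_frames[0]
        )
        all_islands.to_csv(out / "islands.tsv", sep="\t", index=False)
        stage_counts["islands"] = len(all_islands)
        for kind in ("ROH", "ROHet"):
            if len(islands_by_pop[kind]) >= 2:
                shared = overlap_islands(islands_by_pop[kind])
                shared.to_csv(
                    out / f"shared_islands_{kind.lower()}.tsv", sep="\t", index=False
                )
        if config.annotation_path is not None:
            flat = [
                isl
                for kind in islands_by_pop.values()
                for pop_islands in kind.values()
                for isl in pop_islands
            ]
            annotate_islands(flat, config.annotation_path).to_csv(
                out / "island_annotation.tsv", sep="\t", index=False
            )

        stage = "structure"
        diversity_summary(ds_strict).to_csv(
            out / "diversity.tsv", sep="\t", index=False
        )
        dm = ibs_distance(ds_strict)
        dm.to_frame().to_csv(out / "distances.tsv", sep="\t")
        k = min(config.pca_components, ds_strict.n_samples - 1, ds_strict.n_markers - 1)
        res = pca(ds_strict, k=k)
        res.coordinates.to_csv(out / "pca_coordinates.tsv", sep="\t")
        pd.DataFrame(
            {"component": res.coordinates.columns,
             "eigenvalue": res.eigenvalues,
             "variance_pct": res.variance_pct}
        ).to_csv(out / "pca_variance.tsv", sep="\t", index=False)
        pops = ds_strict.samples.set_index("sample_id")["population"]
        if len(pops.unique()) >= 3:
            pop_dm = population_distance_matrix(dm, pops)
            (out / "tree_populations.nwk").write_text(
                to_newick(nj_tree(pop_dm)) + "\n"
            )
        if ds_strict.n_samples >= 3:
            (out / "tree_samples.nwk").write_text(to_newick(nj_tree(dm)) + "\n")
        stage_counts["structure_samples"] = ds_strict.n_samples

        stage = "compare"
        if len(ds_lenient.populations) >= 2:
            class_count_comparison(roh_runs, ds_lenient.samples).to_csv(
                out / "compare_roh.tsv", sep="\t", index=False
            )
            class_count_comparison(rohet_runs, ds_lenient.samples).to_csv(
                out / "compare_rohet.tsv", sep="\t", index=False
            )
        roh_rohet_correlation(roh_runs, rohet_runs, ds_lenient.samples).to_csv(
            out / "roh_rohet_correlation.tsv", sep="\t", index=False
        )
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    config_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    output_checksums = {
        f.name: _sha256(f)
        for f in sorted(out.iterdir())
        if f.is_file() and f.name != "manifest.json"
    }
    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(config_yaml.encode()).hexdigest(),
        input_checksums=input_checksums,
        stage_counts=stage_counts,
        output_checksums=output_checksums,
        started=started,
        finished=time.time(),
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
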