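"""End-to-end pipeline: simulate (or load) data, call, annotate, analyse.

Two modes.  *simulate* generates a full synthetic study from one seed:
GS rounds, pooled amplicon counts per archived round, a truth table of
real allele frequencies, isolate genotypes from the final round and a
deep-sequenced top clone with matched wild-type control.  *analyze*
runs the same calling/trajectory/annotation stages on user-supplied
TSV inputs.  All outputs embed the seed and a config hash; a rerun from
the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calling import AmpliconCounts, CallerConfig, call_frequency_table, fp_filter_call
from .catalogue import (
    LocusCatalogue,
    MutationRecord,
    default_locus_catalogue,
    load_mutation_catalogue,
    roman_to_int,
    summarize_catalogue,
)
from .io import config_hash, read_counts_tsv, read_table, write_table, write_vcf
from .simulate import (
    IsolateGenotypeMatrix,
    PopulationSample,
    SimulationConfig,
    population_fitness,
    run_gs_rounds,
    simulate_amplicon_counts,
    simulate_isolates,
    true_frequency_table,
)
from .trajectory import (
    TrendConfig,
    build_frequency_matrix,
    classify_all_trajectories,
    co_origin_clusters,
    compare_population_vs_isolates,
    isolate_frequency_table,
    rank_candidates,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "ConfigError",
    "InputError",
    "StageError",
    "ReportBundle",
    "load_config",
    "run_end_to_end",
    "write_report",
]

log = logging.getLogger("gshuffle")


class PipelineError(Exception):
    """Base class; ``exit_code`` drives the CLI exit status."""

    exit_code = 4


class ConfigError(PipelineError):
    exit_code = 2


class InputError(PipelineError):
    exit_code = 3


class StageError(PipelineError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Composite configuration for a full pipeline run."""

    mode: str = "simulate"  # "simulate" | "analyze"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    trend: TrendConfig = field(default_factory=TrendConfig)
    mean_coverage: float = 1.35e5  # pooled amplicon coverage per locus
    error_rate: float = 0.003  # per-base sequencing error
    clone_coverage: float = 350.0  # evolved-clone genome sequencing depth
    control_coverage: float = 100.0  # wild-type control depth
    n_isolates: int = 20
    isolate_fitness_bias: float = 2.0
    archive_rounds: tuple = ("UV", "R1", "R3", "R5")
    counts_path: Optional[str] = None  # analyze-mode inputs
    isolates_path: Optional[str] = None
    catalogue_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mean_coverage <= 0 or self.clone_coverage <= 0 or self.control_coverage <= 0:
            raise ConfigError("coverages must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must lie in [0, 1)")
        if self.n_isolates < 1:
            raise ConfigError("n_isolates must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return config_hash(self.to_dict())


def _build_dataclass(cls, data: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s) {sorted(unknown)} under '{path}'")
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid config under '{path}': {exc}") from None


def load_config(path=None, overrides: Optional[dict] = None) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys are rejected by path.

    An empty (or absent) file yields all defaults.  ``overrides`` are
    applied on top of the file's top-level keys (CLI flags).
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        data = loaded
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    nested = {
        "simulation": SimulationConfig,
        "caller": CallerConfig,
        "trend": TrendConfig,
    }
    kwargs: dict = {}
    for key, value in data.items():
        if key in nested:
            if not isinstance(value, dict):
                raise ConfigError(f"config key '{key}' must be a mapping")
            kwargs[key] = _build_dataclass(nested[key], value, key)
        else:
            kwargs[key] = value
    if "archive_rounds" in kwargs and kwargs["archive_rounds"] is not None:
        kwargs["archive_rounds"] = tuple(kwargs["archive_rounds"])
    cfg = _build_dataclass(PipelineConfig, kwargs, "<root>")
    # the simulation seed follows the pipeline seed unless set explicitly
    if "simulation" not in data or "seed" not in (data.get("simulation") or {}):
        cfg = dataclasses.replace(
            cfg, simulation=dataclasses.replace(cfg.simulation, seed=cfg.seed)
        )
    return cfg


@dataclass
class ReportBundle:
    """All analysis artifacts of one run plus reproduction metadata."""

    frequency_table: pd.DataFrame  # long: sample, locus_id, frequency, detected
    frequency_matrix: pd.DataFrame  # loci x rounds
    trajectory_table: pd.DataFrame  # locus, trend, endpoint frequencies
    clusters: list
    catalogue_summary: dict
    ranking: pd.DataFrame
    metadata: dict
    counts: Optional[pd.DataFrame] = None
    truth: Optional[pd.DataFrame] = None
    isolates: Optional[IsolateGenotypeMatrix] = None
    isolate_comparison: Optional[pd.DataFrame] = None
    isolate_summary: Optional[dict] = None
    variant_calls: Optional[pd.DataFrame] = None


def _clone_counts(sample: PopulationSample, catalogue: LocusCatalogue,
                  member: int, coverage: float, error_rate: float,
                  label: str, rng: np.random.Generator) -> pd.DataFrame:
    clone = PopulationSample(label, sample.genotypes[member:member + 1])
    return simulate_amplicon_counts(clone, catalogue, coverage, error_rate, rng)


def _simulate_inputs(config: PipelineConfig):
    """Generate counts, truth, isolates and clone/control counts."""
    catalogue = (
        LocusCatalogue.from_tsv(config.catalogue_path)
        if config.catalogue_path
        else default_locus_catalogue()
    )
    rng_master = np.random.SeedSequence(config.seed)
    sim_rng, seq_rng, iso_rng = (np.random.default_rng(s) for s in rng_master.spawn(3))
    sim_cfg = config.simulation
    samples = run_gs_rounds(sim_cfg, catalogue, rng=sim_rng)
    by_label = {s.round_label: s for s in samples}
    archived = [by_label[l] for l in config.archive_rounds if l in by_label]
    if not archived:
        raise StageError("simulate", "no archived rounds match the simulation")
    log.info("simulated %d rounds; archiving %s", sim_cfg.rounds,
             [s.round_label for s in archived])

    counts = pd.concat(
        [
            simulate_amplicon_counts(
                s, catalogue, config.mean_coverage, config.error_rate, seq_rng
            )
            for s in archived
        ],
        ignore_index=True,
    )
    truth = true_frequency_table(archived, catalogue)

    final_diploid = samples[-1] if samples[-1].ploidy == 2 else None
    isolates = clone_calls = None
    if final_diploid is not None:
        isolates = simulate_isolates(
            final_diploid, catalogue, config.n_isolates,
            config.isolate_fitness_bias, iso_rng,
        )
        # deep-sequence the fittest member as the evolved clone, with a
        # wild-type control subjected to the same protocol
        w = population_fitness(final_diploid, catalogue)
        top = int(np.argmax(w))
        evolved_counts = _clone_counts(
            final_diploid, catalogue, top, config.clone_coverage,
            config.error_rate, "clone", seq_rng,
        )
        wt = PopulationSample(
            "WT", np.zeros((1, 2, len(catalogue)), dtype=np.uint8)
        )
        control_counts = simulate_amplicon_counts(
            wt, catalogue, config.control_coverage, config.error_rate, seq_rng
        )
        clone_calls = _call_variants(evolved_counts, control_counts, catalogue, config)
    return catalogue, counts, truth, isolates, clone_calls


def _call_variants(evolved: pd.DataFrame, control: pd.DataFrame,
                   catalogue: LocusCatalogue, config: PipelineConfig) -> pd.DataFrame:
    ctrl_by_locus = {r.locus_id: r for r in control.itertuples(index=False)}
    rows = []
    for r in evolved.itertuples(index=False):
        ev = AmpliconCounts(r.locus_id, str(r.sample), int(r.total_reads),
                            int(r.alt_reads), float(r.qual_central), float(r.qual_flank_min))
        c = ctrl_by_locus[r.locus_id]
        ct = AmpliconCounts(c.locus_id, str(c.sample), int(c.total_reads),
                            int(c.alt_reads), float(c.qual_central), float(c.qual_flank_min))
        call = fp_filter_call(ev, ct, config.caller)
        locus = catalogue[r.locus_id]
        rows.append(
            {
                "locus_id": call.locus_id,
                "chrom": locus.chromosome,
                "pos": int(round(locus.map_position * 1000)) + 1,  # nominal map coordinate
                "ref": locus.ref_allele,
                "alt": locus.alt_allele,
                "status": call.status,
                "evolved_fraction": call.evolved_fraction,
                "control_fraction": call.control_fraction,
                "control_informative": call.control_informative,
                "zygosity": call.zygosity,
            }
        )
    return pd.DataFrame(rows)


def run_end_to_end(config: PipelineConfig) -> ReportBundle:
    """Run the full pipeline in the configured mode."""
    mutation_records = (
        load_mutation_catalogue()  # packaged catalogue drives annotation
    )
    if config.mode == "simulate":
        catalogue, counts, truth, isolates, clone_calls = _simulate_inputs(config)
    else:
        if not config.counts_path:
            raise InputError("analyze mode requires counts_path")
        counts = read_counts_tsv(config.counts_path)
        truth = clone_calls = None
        catalogue = (
            LocusCatalogue.from_tsv(config.catalogue_path)
            if config.catalogue_path
            else default_locus_catalogue()
        )
        isolates = (
            IsolateGenotypeMatrix.from_tsv(config.isolates_path)
            if config.isolates_path
            else None
        )

    try:
        freq = call_frequency_table(counts, config.caller)
    except ValueError as exc:
        raise StageError("callfreq", str(exc)) from None
    log.info("callfreq: %d count records -> %d detected",
             len(freq), int(freq["detected"].sum()))

    round_order = [l for l in config.archive_rounds if l in set(freq["sample"])]
    if not round_order:
        round_order = list(dict.fromkeys(freq["sample"]))
    try:
        matrix = build_frequency_matrix(freq, round_order=round_order)
        trajectories = classify_all_trajectories(matrix, config.trend)
    except ValueError as exc:
        raise StageError("trajectory", str(exc)) from None

    uv_label = round_order[0]
    uv = freq[freq["sample"] == uv_label].set_index("locus_id")["frequency"]
    clusters = co_origin_clusters(uv.to_dict(), config.trend)
    log.info("trajectory: %d loci, %d co-origin clusters", len(matrix), len(clusters))

    summary = summarize_catalogue(mutation_records)
    ranking = rank_candidates(trajectories, mutation_records)

    iso_table = iso_summary = None
    if isolates is not None:
        final_label = round_order[-1]
        pool = freq[freq["sample"] == final_label].set_index("locus_id")["frequency"]
        iso_freqs = isolate_frequency_table(isolates.calls)
        try:
            iso_table, iso_summary = compare_population_vs_isolates(
                pool.to_dict(), iso_freqs.to_dict()
            )
            iso_table = iso_table.reset_index()
        except ValueError as exc:
            raise StageError("isolates", str(exc)) from None

    metadata = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "gshuffle_version": __version__,
        "mode": config.mode,
        "rounds": list(round_order),
    }
    return ReportBundle(
        frequency_table=freq,
        frequency_matrix=matrix,
        trajectory_table=trajectories,
        clusters=clusters,
        catalogue_summary=summary,
        ranking=ranking,
        metadata=metadata,
        counts=counts,
        truth=truth,
        isolates=isolates,
        isolate_comparison=iso_table,
        isolate_summary=iso_summary,
        variant_calls=clone_calls,
    )


def write_report(bundle: ReportBundle, outdir, config: Optional[PipelineConfig] = None) -> dict:
    """Write every bundle artifact under ``outdir``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": bundle.metadata["seed"], "config_hash": bundle.metadata["config_hash"]}
    paths = {}

    def _write(df, name, **kw):
        path = outdir / name
        write_table(df, path, metadata=meta, **kw)
        paths[name] = str(path)

    _write(bundle.frequency_table, "frequencies.tsv")
    _write(bundle.frequency_matrix.reset_index(), "frequency_matrix.tsv")
    _write(bundle.trajectory_table, "trajectories.tsv")
    _write(bundle.ranking, "ranking.tsv")
    if bundle.counts is not None:
        _write(bundle.counts, "counts.tsv")
    if bundle.truth is not None:
        _write(bundle.truth, "truth.tsv")
    if bundle.isolates is not None:
        path = outdir / "isolates.tsv"
        with open(path, "w") as fh:
            for key, value in meta.items():
                fh.write(f"# {key}={value}\n")
            bundle.isolates.calls.to_csv(fh, sep="\t", index_label="isolate")
        paths["isolates.tsv"] = str(path)
    if bundle.isolate_comparison is not None:
        _write(bundle.isolate_comparison, "isolate_comparison.tsv")
    if bundle.variant_calls is not None:
        _write(bundle.variant_calls, "variant_calls.tsv")
        vcf_path = outdir / "variant_calls.vcf"
        vcf_df = bundle.variant_calls.rename(columns={"locus_id": "id"})[
            ["chrom", "pos", "id", "ref", "alt", "status"]
        ].assign(af=bundle.variant_calls["evolved_fraction"])
        write_vcf(vcf_path, vcf_df, metadata=meta)
        paths["variant_calls.vcf"] = str(vcf_path)

    summary = {
        "metadata": bundle.metadata,
        "config": config.to_dict() if config is not None else None,
        "catalogue_summary": bundle.catalogue_summary,
        "clusters": [
            {
                "member_loci": sorted(c.member_loci),
                "mean_uv_frequency": c.mean_uv_frequency,
                "tolerance_used": c.tolerance_used,
            }
            for c in bundle.clusters
        ],
        "isolate_summary": bundle.isolate_summary,
        "stage_counts": {
            "loci": int(bundle.frequency_matrix.shape[0]),
            "rounds": int(bundle.frequency_matrix.shape[1]),
            "detected_records": int(bundle.frequency_table["detected"].sum()),
            "called_variants": (
                int((bundle.variant_calls["status"] == "called").sum())
                if bundle.variant_calls is not None
                else None
            ),
        },
    }
    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    paths["summary.json"] = str(summary_path)
    return paths
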