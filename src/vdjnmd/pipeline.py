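"""End-to-end experiment orchestration.

One :func:`run_experiment` call reproduces the whole computational
experiment: build the paired A/F allele fixture, simulate homozygous A/A
and F/F thymocyte populations under allelic exclusion, sample DNA /
pre-mRNA / mRNA pools under the configured survival factors, annotate the
pools, tally PTC+/PTC- counts, and compute fold reductions with their
binomial and Monte Carlo tests.  Every stage draws its seed
deterministically from the master seed, and every intermediate artifact is
written to the output directory so individual stages can be re-run from
each other's outputs.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .decay_pools import (
    MOLECULES,
    PoolSet,
    SurvivalParams,
    counts_table,
    generate_pools,
    write_counts_tsv,
)
from .gene_models import Fixture, FixtureParams, make_reference_fixture, write_models_config
from .ptc_annotate import Annotator, EjcParams, annotate_fasta
from .ptc_stats import Report, summarize
from .vdj_sim import SimParams, simulate_population, write_population_tsv

logger = logging.getLogger(__name__)

STAGES = ("fixture", "sim_A", "sim_F", "pools_A", "pools_F", "stats")


class ConfigError(ValueError):
    """Invalid experiment configuration."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete configuration of one synthetic experiment run."""

    fixture: FixtureParams = field(default_factory=FixtureParams)
    sim: SimParams = field(default_factory=lambda: SimParams(n_cells=3000))
    survival: SurvivalParams = field(default_factory=SurvivalParams)
    depth: int = 2000
    ejc: EjcParams = field(default_factory=EjcParams)
    stats_mode: str = "odds"
    n_iter: int = 10_000
    n_boot: int = 10_000
    master_seed: int = 1
    genotypes: tuple[str, ...] = ("A", "F")
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ConfigError("pool depth must be >= 0")
        if self.stats_mode not in ("odds", "fraction"):
            raise ConfigError("stats_mode must be 'odds' or 'fraction'")
        if not set(self.genotypes) <= {"A", "F"}:
            raise ConfigError("genotypes must be drawn from {A, F}")


def stage_seeds(master_seed: int) -> dict[str, np.random.SeedSequence]:
    """Deterministic per-stage seed sequences derived from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return dict(zip(STAGES, children))


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seeds(master_seed)[stage])


# ---------------------------------------------------------------------------
# Flat key-value config I/O
# ---------------------------------------------------------------------------

_INT_KEYS = {
    "depth", "n_iter", "n_boot", "master_seed",
    "fixture.target_ptc_polya_distance", "fixture.seed", "fixture.utr3_length",
    "sim.n_cells", "sim.seed", "ejc.threshold_nt", "ejc.deposit_offset_nt",
}
_FLOAT_KEYS = {"sim.p_if", "sim.trim_mean", "sim.n_mean", "survival.mrna_ptc.A",
               "survival.mrna_ptc.F"}


def config_to_file(config: ExperimentConfig, path) -> None:
    lines = [
        "# vdjnmd experiment configuration",
        f"master_seed = {config.master_seed}",
        f"depth = {config.depth}",
        f"stats_mode = {config.stats_mode}",
        f"n_iter = {config.n_iter}",
        f"n_boot = {config.n_boot}",
        f"genotypes = {','.join(config.genotypes)}",
        f"fixture.target_ptc_polya_distance = {config.fixture.target_ptc_polya_distance}",
        f"fixture.seed = {config.fixture.seed}",
        f"fixture.exon_lengths = {','.join(map(str, config.fixture.exon_lengths))}",
        f"fixture.intron_lengths = {','.join(map(str, config.fixture.intron_lengths))}",
        f"sim.p_if = {config.sim.p_if!r}",
        f"sim.trim_mean = {config.sim.trim_mean!r}",
        f"sim.n_mean = {config.sim.n_mean!r}",
        f"sim.n_cells = {config.sim.n_cells}",
        f"survival.mrna_ptc.A = {config.survival.s_mrna_ptc.get('A', 1.0)!r}",
        f"survival.mrna_ptc.F = {config.survival.s_mrna_ptc.get('F', 1.0)!r}",
        f"ejc.threshold_nt = {config.ejc.threshold_nt}",
        f"ejc.measure_from = {config.ejc.measure_from}",
    ]
    if config.out_dir:
        lines.append(f"out_dir = {config.out_dir}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def config_from_file(path) -> ExperimentConfig:
    kv: dict[str, str] = {}
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
                key, _, value = line.partition("=")
                kv[key.strip()] = value.strip()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    return config_from_mapping(kv)


def config_from_mapping(kv: dict[str, str]) -> ExperimentConfig:
    def get(key, default, cast):
        if key not in kv:
            return default
        try:
            return cast(kv[key])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad value for {key}: {kv[key]!r}") from exc

    int_tuple = lambda s: tuple(int(x) for x in s.split(","))
    try:
        fixture = FixtureParams(
            target_ptc_polya_distance=get("fixture.target_ptc_polya_distance", 700, int),
            exon_lengths=get("fixture.exon_lengths", (60, 150, 200, 150, 150, 260), int_tuple),
            intron_lengths=get("fixture.intron_lengths", (90,) * 5, int_tuple),
            utr3_length=get("fixture.utr3_length", 55, int),
            seed=get("fixture.seed", 0, int),
        )
        sim = SimParams(
            p_if=get("sim.p_if", 1 / 3, float),
            trim_mean=get("sim.trim_mean", 2.0, float),
            n_mean=get("sim.n_mean", 3.0, float),
            n_cells=get("sim.n_cells", 3000, int),
        )
        survival = SurvivalParams(
            s_mrna_ptc={
                "A": get("survival.mrna_ptc.A", 1 / 12, float),
                "F": get("survival.mrna_ptc.F", 1 / 3, float),
            }
        )
        ejc = EjcParams(
            threshold_nt=get("ejc.threshold_nt", 55, int),
            measure_from=kv.get("ejc.measure_from", "last"),
        )
        return ExperimentConfig(
            fixture=fixture,
            sim=sim,
            survival=survival,
            depth=get("depth", 2000, int),
            ejc=ejc,
            stats_mode=kv.get("stats_mode", "odds"),
            n_iter=get("n_iter", 10_000, int),
            n_boot=get("n_boot", 10_000, int),
            master_seed=get("master_seed", 1, int),
            genotypes=tuple(kv.get("genotypes", "A,F").split(",")),
            out_dir=kv.get("out_dir"),
        )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _timed(stage: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    logger.info("stage %s done in %.2f s", stage, time.perf_counter() - t0)
    return result


def run_experiment(config: ExperimentConfig) -> Report:
    """Run every stage in order and return the assembled report.

    With ``config.out_dir`` set, writes: the allele models and exon tables,
    per-genotype population TSVs, pool FASTAs and truth tables, re-derived
    annotation TSVs (cross-checked against the truth tables), the counts
    TSV, and the report (TSV + text).
    """
    seeds = stage_seeds(config.master_seed)
    out = config.out_dir
    if out:
        os.makedirs(out, exist_ok=True)

    fixture: Fixture = _timed("fixture", make_reference_fixture, config.fixture)
    annotators = {
        g: Annotator(fixture.models[g], config.ejc) for g in ("A", "F")
    }
    if out:
        write_models_config(os.path.join(out, "models.config"), fixture)
        pd.concat(
            [fixture.model_a.exon_table(), fixture.model_f.exon_table()]
        ).to_csv(os.path.join(out, "exon_tables.tsv"), sep="\t", index=False)

    populations = {}
    poolsets: dict[str, PoolSet] = {}
    for g in dict.fromkeys(config.genotypes):
        rng_sim = np.random.default_rng(seeds[f"sim_{g}"])
        cells = _timed(
            f"sim_{g}",
            simulate_population,
            config.sim,
            rng_sim,
            genotypes=(g, g),
            mode="sequence",
            models=fixture.models,
            segments=fixture.segments,
            ejc_params=config.ejc,
            annotators=annotators,
        )
        populations[g] = cells
        if out:
            write_population_tsv(cells, os.path.join(out, f"population_{g}.tsv"))
        rng_pool = np.random.default_rng(seeds[f"pools_{g}"])
        poolsets[g] = _timed(
            f"pools_{g}",
            generate_pools,
            cells,
            config.survival,
            config.depth,
            rng_pool,
        )
        if out:
            poolsets[g].write(out)

    # Re-annotate each pool (from FASTA when written, else in memory) and
    # cross-check against the sampling truth tables.
    annotation_sets: dict[tuple[str, str], pd.DataFrame] = {}
    n_rejected_total = 0
    for g, poolset in poolsets.items():
        for (genotype, molecule), truth in poolset.pools.items():
            if out:
                fasta = os.path.join(out, f"pool_{genotype}_{molecule}.fasta")
                if len(truth) == 0:
                    ann = truth.iloc[0:0][["id", "nmd_class"]].copy()
                    n_rej = 0
                else:
                    ann, n_rej = _timed(
                        "annotate",
                        annotate_fasta,
                        fasta,
                        fixture.models[genotype],
                        config.ejc,
                        annotator=annotators[genotype],
                    )
                    ann.to_csv(
                        os.path.join(out, f"annotations_{genotype}_{molecule}.tsv"),
                        sep="\t",
                        index=False,
                    )
            else:
                ann = pd.DataFrame(
                    {
                        "id": truth["id"],
                        "nmd_class": [
                            annotators[genotype].annotate_junction(s).nmd_class
                            for s in truth["junction_seq"]
                        ],
                    }
                )
                n_rej = 0
            n_rejected_total += n_rej
            if len(ann) and not (
                ann["nmd_class"].to_numpy() == truth["nmd_class"].to_numpy()
            ).all():
                raise PipelineError(
                    f"stage 'annotate' failed: re-annotation of pool "
                    f"({genotype}, {molecule}) disagrees with its truth table"
                )
            annotation_sets[(genotype, molecule)] = ann

    counts = _timed("counts", counts_table, annotation_sets)
    if out:
        write_counts_tsv(counts, os.path.join(out, "counts.tsv"))

    rng_stats = np.random.default_rng(seeds["stats"])
    settings = {
        "version": __version__,
        "master_seed": config.master_seed,
        "depth": config.depth,
        "n_cells": config.sim.n_cells,
        "p_if": config.sim.p_if,
        "survival.mrna_ptc.A": config.survival.s_mrna_ptc.get("A"),
        "survival.mrna_ptc.F": config.survival.s_mrna_ptc.get("F"),
        "ejc.threshold_nt": config.ejc.threshold_nt,
        "ejc.measure_from": config.ejc.measure_from,
        "rejected_records": n_rejected_total,
    }
    report = _timed(
        "stats",
        summarize,
        counts,
        mode=config.stats_mode,
        n_iter=config.n_iter,
        n_boot=config.n_boot,
        rng=rng_stats,
        settings=settings,
    )
    if out:
        report.table.to_csv(os.path.join(out, "report.tsv"), sep="\t", index=False)
        with open(os.path.join(out, "report.txt"), "w") as fh:
            fh.write(report.text())
    return report
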