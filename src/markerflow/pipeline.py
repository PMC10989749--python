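"""End-to-end orchestration: input reading, staged analyses on a task
graph, and the fixed on-disk output layout.

Stages (profiling -> function / alpha / beta / markers / network) run as
tasks with declared dependencies; per-sample profiling and function
prediction parallelise at sample grain, pairwise distances at pair
grain. All reductions iterate in manifest order, so outputs are
bit-identical for any thread count.
"""

from __future__ import annotations

import logging
import os
import shutil
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diversity_alpha as da
from . import diversity_beta as db
from .biomarkers import numeric_biomarkers, ranksum_screen, rf_rank
from .function_prediction import functional_table, pathway_table, predict_ko
from .io_formats import (
    AbundanceTable,
    MetadataTable,
    RANKS,
    ReferencePack,
    read_fasta,
    read_manifest,
    read_metadata,
    read_reference_pack,
    write_table,
)
from .network import build_network, network_stats
from .profiling import (
    TaxonomicProfile,
    assign_reads,
    build_profile,
    collapse_to_level,
    denoise_reads,
    write_assignments,
)
from .report import generate_report
from .scheduler import TaskGraph

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = ("profiling", "function", "alpha", "beta", "markers", "network")
_STAGE_DEPS = {
    "function": ("profiling",),
    "alpha": ("profiling",),
    "beta": ("profiling",),
    "markers": ("profiling",),
    "network": ("profiling",),
}


@dataclass
class PipelineConfig:
    manifest: str
    metadata: str
    refpack: str
    outdir: str
    seed: int
    level: str = "genus"
    metric: str = "metastorms-weighted"
    threads: int = 0  # 0 -> detected CPU count
    min_identity: float = 0.97
    kmer: int = 8
    permutations: int = 999
    rf_trees: int = 500
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.threads == 0:
            self.threads = os.cpu_count() or 1
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if self.level not in RANKS:
            raise ValueError(f"level must be one of {RANKS}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in self.stages:
            for dep in _STAGE_DEPS.get(stage, ()):
                if dep not in self.stages:
                    raise ValueError(f"stage {stage!r} requires {dep!r}")


def _stage_seed(seed: int, name: str) -> int:
    import zlib

    return (seed * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)


def run_pipeline(cfg: PipelineConfig) -> str:
    """Run the configured stages and return the output directory.

    Outputs: classification/, Abundance_Tables/, Alpha_Diversity/,
    Distance_Matrix/, Ordination/, Beta_Tests/, Markers/, Network/,
    logs/, summary.txt, script.sh and index.html. Per-sample failures
    are quarantined and logged; the pipeline continues with survivors.
    """
    out = cfg.outdir
    os.makedirs(os.path.join(out, "logs"), exist_ok=True)
    logger = logging.getLogger(f"markerflow.pipeline.{id(cfg)}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(os.path.join(out, "logs", "pipeline.log"))
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    summary: list[str] = []

    try:
        manifest = read_manifest(cfg.manifest)
        metadata = read_metadata(cfg.metadata, manifest)
        pack = read_reference_pack(cfg.refpack)
    except Exception:
        logger.exception("failed to read inputs")
        handler.close()
        raise
    shutil.copyfile(cfg.metadata, os.path.join(out, "meta.txt"))
    logger.info("inputs: %d samples, %d reference leaves", len(manifest), len(pack.leaf_ids))

    graph = TaskGraph()
    dropped: list[str] = []

    # ---- profiling: one task per sample -------------------------------
    def make_profile_task(sample_id: str, fasta: str):
        def task() -> TaxonomicProfile | None:
            # a broken sample is quarantined (returns None), not fatal:
            # downstream stages continue with the survivors
            try:
                reads = denoise_reads(read_fasta(fasta))
                assignments = assign_reads(reads, pack, cfg.min_identity, cfg.kmer)
                os.makedirs(os.path.join(out, "classification"), exist_ok=True)
                write_assignments(
                    assignments, os.path.join(out, "classification", f"{sample_id}.tsv")
                )
                prof = build_profile(assignments, pack, sample_id)
                if prof.empty:
                    logger.warning("sample %s: empty (no classified reads)", sample_id)
                return prof
            except Exception as exc:  # noqa: BLE001
                logger.error("sample %s quarantined: %s", sample_id, exc)
                return None

        return task

    profile_tasks = []
    if "profiling" in cfg.stages:
        # warm the k-mer index once so per-sample tasks share it
        graph.add("kmer-index", lambda: assign_reads([], pack, cfg.min_identity, cfg.kmer))
        for sample_id, fasta in manifest.entries:
            name = f"profile:{sample_id}"
            graph.add(name, make_profile_task(sample_id, fasta), deps=("kmer-index",))
            profile_tasks.append((sample_id, name))

    def collect_profiles() -> list[TaxonomicProfile]:
        profiles = []
        for sample_id, name in profile_tasks:
            prof = graph.results.get(name)
            if prof is None:  # quarantined sample; recorded after the run
                continue
            profiles.append(prof)
        return profiles

    profile_names = [n for _, n in profile_tasks]

    def task_collapse():
        profiles = collect_profiles()
        tabdir = os.path.join(out, "Abundance_Tables")
        os.makedirs(tabdir, exist_ok=True)
        tables = {}
        for rank in RANKS:
            tables[rank] = collapse_to_level(profiles, pack, rank)
            write_table(tables[rank], os.path.join(tabdir, f"taxa.{rank}.tsv"))
        return tables

    if "profiling" in cfg.stages:
        graph.add("collapse", task_collapse, deps=profile_names)

    # ---- function prediction ------------------------------------------
    if "function" in cfg.stages:

        def task_function():
            profiles = collect_profiles()
            fps = [predict_ko(p, pack) for p in profiles]
            tabdir = os.path.join(out, "Abundance_Tables")
            os.makedirs(tabdir, exist_ok=True)
            write_table(functional_table(fps), os.path.join(tabdir, "ko.tsv"))
            for level in (1, 2, 3):
                write_table(
                    pathway_table(fps, pack, level),
                    os.path.join(tabdir, f"pathway.L{level}.tsv"),
                )
            nsti = pd.DataFrame(
                {"NSTI": [fp.nsti if fp.nsti is not None else float("nan") for fp in fps]},
                index=[fp.sample_id for fp in fps],
            )
            write_table(nsti, os.path.join(out, "nsti.tsv"))
            return fps

        graph.add("function", task_function, deps=profile_names)

    # ---- alpha diversity ----------------------------------------------
    if "alpha" in cfg.stages:

        def task_alpha():
            profiles = collect_profiles()
            alphadir = os.path.join(out, "Alpha_Diversity")
            os.makedirs(alphadir, exist_ok=True)
            alpha = da.alpha_diversity(profiles)
            write_table(alpha, os.path.join(alphadir, "alpha.tsv"))
            tests = da.alpha_associations(alpha, metadata)
            tests.to_csv(os.path.join(alphadir, "tests.tsv"), sep="\t", index=False,
                         float_format="%.6g")
            return alpha

        graph.add("alpha", task_alpha, deps=profile_names)

    # ---- beta diversity -----------------------------------------------
    if "beta" in cfg.stages:

        def task_taxa_dist():
            profiles = collect_profiles()
            distdir = os.path.join(out, "Distance_Matrix")
            os.makedirs(distdir, exist_ok=True)
            dist = db.distance_matrix(profiles, pack, cfg.metric, threads=cfg.threads)
            write_table(dist, os.path.join(distdir, "taxa.dist.tsv"))
            return dist

        graph.add("taxa-dist", task_taxa_dist, deps=profile_names)

        if "function" in cfg.stages:

            def task_func_dist():
                fps = graph.results["function"]
                distdir = os.path.join(out, "Distance_Matrix")
                os.makedirs(distdir, exist_ok=True)
                dist = db.distance_matrix(fps, pack, "hierarchical", threads=cfg.threads)
                write_table(dist, os.path.join(distdir, "func.dist.tsv"))
                return dist

            graph.add("func-dist", task_func_dist, deps=["function"])

        def task_ordination():
            dist = graph.results["taxa-dist"]
            tables = graph.results.get("collapse") or {}
            orddir = os.path.join(out, "Ordination")
            os.makedirs(orddir, exist_ok=True)
            if len(dist.sample_ids) >= 3:
                res = db.pcoa(dist, axes=2)
                df = res.to_dataframe()
                write_table(df, os.path.join(orddir, "pcoa.tsv"))
                if cfg.level in tables:
                    write_table(
                        db.pca(tables[cfg.level], axes=2).to_dataframe(),
                        os.path.join(orddir, "pca.tsv"),
                    )
                return res
            logger.warning("ordination skipped: fewer than 3 samples")
            return None

        graph.add("ordination", task_ordination, deps=["taxa-dist", "collapse"])

        def task_beta_tests():
            dist = graph.results["taxa-dist"]
            testdir = os.path.join(out, "Beta_Tests")
            os.makedirs(testdir, exist_ok=True)
            rows = []
            for var in metadata.variables("discrete"):
                col = metadata.column(var)
                seed = _stage_seed(cfg.seed, f"beta:{var}")
                try:
                    f, p = db.permanova(dist, col, cfg.permutations, seed)
                    rows.append(dict(variable=var, method="permanova",
                                     statistic=f, p=p))
                    r, p2 = db.anosim(dist, col, cfg.permutations, seed)
                    rows.append(dict(variable=var, method="anosim", statistic=r, p=p2))
                except ValueError as exc:
                    logger.warning("beta test on %s skipped: %s", var, exc)
            for var in metadata.variables("numeric"):
                seed = _stage_seed(cfg.seed, f"beta:{var}")
                try:
                    slope, r2, p = db.distance_numeric_regression(
                        dist, metadata.column(var), cfg.permutations, seed
                    )
                    rows.append(dict(variable=var, method="mantel-ols",
                                     statistic=slope, p=p))
                except ValueError as exc:
                    logger.warning("beta regression on %s skipped: %s", var, exc)
            pd.DataFrame(rows, columns=["variable", "method", "statistic", "p"]).to_csv(
                os.path.join(testdir, "tests.tsv"), sep="\t", index=False,
                float_format="%.6g",
            )
            return rows

        graph.add("beta-tests", task_beta_tests, deps=["taxa-dist"])

    # ---- biomarkers ----------------------------------------------------
    if "markers" in cfg.stages:

        def task_markers():
            tables = graph.results["collapse"]
            table = tables[cfg.level]
            markdir = os.path.join(out, "Markers")
            os.makedirs(markdir, exist_ok=True)
            frames = []
            for var in metadata.variables("discrete"):
                col = metadata.column(var)
                try:
                    kept = ranksum_screen(table, col)
                except ValueError as exc:
                    logger.warning("marker screen on %s skipped: %s", var, exc)
                    continue
                if len(kept) < 2:
                    logger.info("marker screen on %s kept %d features; RF skipped",
                                var, len(kept))
                    df = pd.DataFrame(
                        [dict(feature=f, screen_p=p, screen_q=q,
                              importance=float("nan"), direction="") for f, p, q in kept],
                        columns=["feature", "screen_p", "screen_q", "importance", "direction"],
                    )
                else:
                    report = rf_rank(table, col, trees=cfg.rf_trees,
                                     seed=_stage_seed(cfg.seed, f"rf:{var}"),
                                     screened=kept)
                    summary.append(
                        f"markers[{var}]: model_error={report.model_error:.4f}"
                    )
                    df = report.to_dataframe()
                df.insert(0, "variable", var)
                frames.append(df)
            for var in metadata.variables("numeric"):
                try:
                    hits = numeric_biomarkers(table, metadata.column(var))
                except ValueError as exc:
                    logger.warning("numeric biomarkers on %s skipped: %s", var, exc)
                    continue
                df = pd.DataFrame(
                    [dict(feature=f, screen_p=p, screen_q=q, importance=rho,
                          direction="pos" if rho > 0 else "neg")
                     for f, rho, p, q in hits],
                    columns=["feature", "screen_p", "screen_q", "importance", "direction"],
                )
                df.insert(0, "variable", var)
                frames.append(df)
            cols = ["variable", "feature", "screen_p", "screen_q", "importance", "direction"]
            frames = [f for f in frames if not f.empty]
            combined = (
                pd.concat(frames, ignore_index=True)[cols] if frames
                else pd.DataFrame(columns=cols)
            )
            combined.to_csv(
                os.path.join(markdir, f"markers.{cfg.level}.tsv"), sep="\t",
                index=False, float_format="%.6g",
            )
            return combined

        graph.add("markers", task_markers, deps=["collapse"])

    # ---- network -------------------------------------------------------
    if "network" in cfg.stages:

        def task_network():
            table = graph.results["collapse"][cfg.level]
            netdir = os.path.join(out, "Network")
            os.makedirs(netdir, exist_ok=True)
            net = build_network(table)
            net.to_dataframe().to_csv(
                os.path.join(netdir, "edges.tsv"), sep="\t", index=False,
                float_format="%.6g",
            )
            ns = network_stats(net)
            pd.DataFrame(
                [dict(density=ns.density, diameter=ns.diameter, radius=ns.radius,
                      centralization=ns.centralization, components=ns.component_count)]
            ).to_csv(os.path.join(netdir, "stats.tsv"), sep="\t", index=False,
                     float_format="%.6g")
            return ns

        graph.add("network", task_network, deps=["collapse"])

    log = graph.run(threads=cfg.threads)
    dropped.extend(
        s for s, name in profile_tasks if graph.results.get(name) is None
    )
    failures = [rec for rec in log if rec.status != "ok"]
    sample_failures = [r for r in failures if r.name.startswith("profile:")]
    hard_failures = [r for r in failures if not r.name.startswith("profile:")]
    for rec in failures:
        logger.error("task %s %s: %s", rec.name, rec.status, rec.error)

    # ---- summary, script, report --------------------------------------
    skipped = [s for s in ALL_STAGES if s not in cfg.stages]
    with open(os.path.join(out, "summary.txt"), "w") as fh:
        fh.write("markerflow pipeline summary\n")
        fh.write(f"samples: {len(manifest)} (dropped: {len(dropped)}"
                 f"{': ' + ','.join(dropped) if dropped else ''})\n")
        fh.write(f"stages run: {', '.join(s for s in ALL_STAGES if s in cfg.stages)}\n")
        if skipped:
            fh.write(f"stages skipped: {', '.join(skipped)}\n")
        fh.write(f"seed: {cfg.seed}; threads: {cfg.threads}; level: {cfg.level}\n")
        for line in summary:
            fh.write(line + "\n")
        for rec in failures:
            fh.write(f"FAILED {rec.name}: {rec.error}\n")

    with open(os.path.join(out, "script.sh"), "w") as fh:
        fh.write("#!/bin/sh\n# step-by-step re-run of this analysis\nset -e\n")
        base = (
            f"markerflow run -i {cfg.manifest} -m {cfg.metadata} -r {cfg.refpack} "
            f"-o {cfg.outdir} --level {cfg.level} --threads {cfg.threads} --seed {cfg.seed}"
        )
        for stage in cfg.stages:
            deps = [s for s in ALL_STAGES if s in _STAGE_DEPS.get(stage, ()) or s == stage]
            fh.write(f"{base} --stages {','.join(deps)}\n")

    generate_report(out)
    handler.close()
    logger.handlers.clear()
    if hard_failures:
        raise RuntimeError(
            "pipeline stages failed: "
            + "; ".join(f"{r.name}: {r.error}" for r in hard_failures)
        )
    return out
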