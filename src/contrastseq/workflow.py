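"""Project-level orchestration of the seven-stage analysis.

Stages: load -> qc -> contrasts -> diff -> venn -> coexpr -> enrich, driven
by a single declarative YAML/dict config over the ``Data/<project>`` /
``Results/<project>`` directory layout.  Every stage logs its parameters to
``run.log``; outputs are pure functions of (inputs, config, seed), so two
identical runs produce identical files.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import coexpression as cx
from . import enrichment as en
from . import io as pio
from . import sets as so
from .contrasts import build_design_matrix, generate_contrasts
from .datatypes import Project, ProjectError
from .glm import NBDifferentialModel, NBDifferentialResults, top_degs
from .normalization import filter_low_expressed, normalization_factors
from .qc import qc_summaries, write_qc_report

__all__ = ["WorkflowConfig", "run_project"]

STAGES = ("load", "qc", "contrasts", "diff", "venn", "coexpr", "enrich")


@dataclass
class WorkflowConfig:
    project: str
    factors: list[str]
    replicate: str | None = None
    data_dir: str = "Data"
    results_dir: str = "Results"
    sample_filters: list[tuple[str, str, str]] = field(default_factory=list)
    filter_strategy: str = "NbConditions"
    cpm_cutoff: float = 1.0
    normalization: str = "TMM"
    interaction: bool = True
    alpha: float = 0.05
    dispersion: str = "tagwise"
    prior_df: float = 10.0
    contrasts: str | list[str] = "all"
    coexpr_mode: str = "union"
    coexpr_contrasts: str | list[str] = "all"
    coexpr_grid: tuple[int, ...] = (5, 10, 15, 20, 25, 30)
    loop1_inits: int = 5
    loop2_inits: int = 40
    mean_filter_cutoff: float = 50.0
    annotation: str | None = None
    enrich_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "WorkflowConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.sample_filters, list):
            cfg.sample_filters = [tuple(r) for r in cfg.sample_filters]
        cfg.coexpr_grid = tuple(cfg.coexpr_grid)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        out = dict(self.__dict__)
        out["sample_filters"] = [list(r) for r in self.sample_filters]
        out["coexpr_grid"] = list(self.coexpr_grid)
        return out


def _safe_dirname(name: str) -> str:
    return re.sub(r"[^\w\[\]\-\.]+", "_", name)


def _selected(names: list[str], selection: str | list[str]) -> list[str]:
    if selection == "all":
        return names
    missing = [s for s in selection if s not in names]
    if missing:
        raise ProjectError(f"unknown contrast name(s) in config: {missing}")
    return [n for n in names if n in set(selection)]


def _condition_means(project: Project, normed: np.ndarray) -> pd.DataFrame:
    design = project.design
    pos = {s: i for i, s in enumerate(project.counts.sample_ids)}
    cols = {}
    for cond in design.conditions:
        idx = [pos[s] for s in design.samples_in_condition(cond)]
        cols["mean_" + "|".join(cond)] = normed[:, idx].mean(axis=1)
    return pd.DataFrame(cols, index=project.counts.gene_ids)


def run_project(
    config: WorkflowConfig, stages: tuple[str, ...] | list[str] = STAGES
) -> Path:
    """Execute the configured stages; returns the results directory.

    Any stage failure aborts with the stage name attached; the
    co-expression stage checkpoints per-K model fits and resumes from them.
    """
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    data_dir = Path(config.data_dir) / config.project
    results = Path(config.results_dir) / config.project
    results.mkdir(parents=True, exist_ok=True)

    logger = logging.getLogger(f"contrastseq.{config.project}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(results / "run.log", mode="a", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.info("config: %s", json.dumps(config.to_dict(), sort_keys=True))

    stage = "load"
    try:
        counts = pio.read_counts(data_dir / f"{config.project}_COUNTS.csv")
        target = pio.read_target(
            data_dir / f"{config.project}_TARGET.csv",
            config.factors,
            config.replicate,
        )
        project = pio.align_and_validate(counts, target, config.project)
        if config.sample_filters:
            project = pio.filter_samples(project, config.sample_filters)
        filtered, report = filter_low_expressed(
            project, config.filter_strategy, config.cpm_cutoff
        )
        norm = normalization_factors(filtered.counts, config.normalization)
        pd.DataFrame(
            {
                "gene": report.kept_genes + report.removed_genes,
                "kept": [True] * len(report.kept_genes)
                + [False] * len(report.removed_genes),
            }
        ).to_csv(results / "filtered_genes.csv", index=False)
        logger.info(
            "load: %d/%d genes kept (%s, cutoff %.3g); %s factors",
            len(report.kept_genes),
            project.n_genes,
            report.strategy,
            report.cpm_cutoff,
            config.normalization,
        )

        if "qc" in stages:
            stage = "qc"
            write_qc_report(qc_summaries(filtered, norm), results / "QC")
            logger.info("qc: written")

        glm_design = build_design_matrix(filtered.design, config.interaction)
        all_contrasts = generate_contrasts(glm_design)
        if "contrasts" in stages:
            stage = "contrasts"
            rows = [
                {"name": c.name, "kind": c.kind}
                | dict(zip(glm_design.coefficient_names, c.vector))
                for c in all_contrasts
            ]
            pd.DataFrame(rows).to_csv(results / "Contrasts.csv", index=False)
            logger.info("contrasts: %d generated", len(all_contrasts))

        diff_results: NBDifferentialResults | None = None
        if {"diff", "venn", "coexpr", "enrich"} & set(stages):
            stage = "diff"
            names = [c.name for c in all_contrasts]
            chosen = _selected(names, config.contrasts)
            model = NBDifferentialModel(
                filtered,
                glm_design,
                norm,
                [c for c in all_contrasts if c.name in set(chosen)],
            )
            diff_results = model.fit(
                dispersion=config.dispersion,
                prior_df=config.prior_df,
                alpha=config.alpha,
            )
            annotation = (
                pio.read_annotation(config.annotation) if config.annotation else None
            )
            if "diff" in stages:
                _write_diff(diff_results, filtered, norm, annotation, results, logger)

        if "venn" in stages and diff_results is not None:
            stage = "venn"
            lists = diff_results.deg_lists()
            if len(lists) >= 2:
                so.write_venn_regions(
                    so.venn_regions(lists), results / "venn_regions.csv"
                )
            (results / "combined_list.txt").write_text(
                "\n".join(so.combine(lists, "union")) + "\n"
            )
            logger.info("venn: written")

        coexpr_results = None
        if "coexpr" in stages and diff_results is not None:
            stage = "coexpr"
            lists = {
                k: v
                for k, v in diff_results.deg_lists().items()
                if config.coexpr_contrasts == "all" or k in config.coexpr_contrasts
            }
            gene_list = so.combine(lists, config.coexpr_mode)
            if not gene_list:
                raise ProjectError("co-expression input gene list is empty")
            coexpr_results = _run_coexpression(
                filtered, norm, gene_list, config, results, logger
            )

        if "enrich" in stages and diff_results is not None:
            stage = "enrich"
            annotation = (
                pio.read_annotation(config.annotation) if config.annotation else None
            )
            if annotation is not None:
                outdir = results / "Enrichment"
                outdir.mkdir(exist_ok=True)
                universe = filtered.counts.gene_ids
                for name, genes in diff_results.deg_lists().items():
                    if genes:
                        en.enrich(
                            genes, annotation, universe, config.enrich_alpha
                        ).to_csv(
                            outdir / f"enrichment_{_safe_dirname(name)}.csv",
                            index=False,
                        )
                if coexpr_results is not None:
                    for c in sorted(coexpr_results.assignments.unique()):
                        if c == 0:
                            continue
                        genes = coexpr_results.assignments[
                            coexpr_results.assignments == c
                        ].index.tolist()
                        en.enrich(
                            genes, annotation, universe, config.enrich_alpha
                        ).to_csv(outdir / f"enrichment_cluster{c}.csv", index=False)
                logger.info("enrich: written")
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise ProjectError(f"stage {stage!r} failed: {exc}") from exc
    return results


def _write_diff(
    res: NBDifferentialResults,
    project: Project,
    norm,
    annotation,
    results: Path,
    logger: logging.Logger,
) -> None:
    from .normalization import normalized_counts

    base = results / "DiffAnalysis"
    base.mkdir(exist_ok=True)
    normed = normalized_counts(project.counts, norm)
    cond_means = _condition_means(project, normed)
    log_norm = pd.DataFrame(
        np.log2(normed + 1.0),
        index=project.counts.gene_ids,
        columns=project.counts.sample_ids,
    )
    ann_map = None
    if annotation is not None:
        ann_map = annotation.pairs.groupby("gene")["term"].apply(";".join)
    counts_rows = []
    for name, test in res.tests.items():
        outdir = base / _safe_dirname(name)
        outdir.mkdir(exist_ok=True)
        table = test.table.join(cond_means)
        if ann_map is not None:
            table = table.join(ann_map.rename("annotation"))
        table.to_csv(outdir / "all_genes.csv")
        table[table["is_deg"]].to_csv(outdir / "DEG.csv")
        diag = res.diagnostics[name]
        pd.DataFrame(
            {
                "bin_upper": np.linspace(0, 1, diag.n_bins + 1)[1:],
                "count": diag.bin_counts,
            }
        ).to_csv(outdir / "pvalue_histogram.csv", index=False)
        top = top_degs(test, 50)
        log_norm.loc[top].to_csv(outdir / "top50_heatmap_data.csv")
        counts_rows.append({"contrast": name, "up": test.n_up, "down": test.n_down})
        if not diag.uniform_tail:
            logger.warning(
                "diff: %s has a non-uniform p-value tail; consider repeating "
                "the analysis with a more stringent filtering cut-off",
                name,
            )
    pd.DataFrame(counts_rows).to_csv(base / "deg_counts.csv", index=False)
    logger.info("diff: %d contrasts tested", len(res.tests))


def _run_coexpression(
    project: Project,
    norm,
    gene_list: list[str],
    config: WorkflowConfig,
    results: Path,
    logger: logging.Logger,
) -> cx.CoexpressionResults:
    outdir = results / "Coexpression"
    outdir.mkdir(exist_ok=True)
    sub = project.counts.subset_genes(gene_list)
    profiles, cluster0 = cx.expression_profiles(sub, norm, config.mean_filter_cutoff)
    transformed = cx.arcsine_transform(profiles)
    res = cx.select_model(
        transformed,
        gene_ids=profiles.index.tolist(),
        cluster0=cluster0,
        grid=config.coexpr_grid,
        loop1_inits=config.loop1_inits,
        loop2_inits=config.loop2_inits,
        seed=config.seed,
        checkpoint_dir=outdir / "checkpoints",
    )
    pd.DataFrame(
        {"cluster": res.assignments, "max_posterior": res.max_posterior}
    ).rename_axis("gene").to_csv(outdir / "cluster_assignments.csv")
    pd.concat(
        [
            res.icl_loop1.rename("ICL").rename_axis("K").reset_index().assign(loop=1),
            res.icl_loop2.rename("ICL").rename_axis("K").reset_index().assign(loop=2),
        ]
    ).to_csv(outdir / "icl_curve.csv", index=False)
    res.cluster_sizes().rename("size").rename_axis("cluster").to_csv(
        outdir / "cluster_sizes.csv"
    )
    # per-cluster mean profile per sample and per condition
    prof_rows = []
    design = project.design
    for c in sorted(res.assignments.unique()):
        if c == 0:
            continue
        members = res.assignments[res.assignments == c].index
        mean_profile = profiles.loc[members].mean(axis=0)
        row = {"cluster": c} | mean_profile.to_dict()
        for cond in design.conditions:
            row["cond_" + "|".join(cond)] = float(
                mean_profile[design.samples_in_condition(cond)].mean()
            )
        prof_rows.append(row)
    pd.DataFrame(prof_rows).to_csv(outdir / "cluster_profiles.csv", index=False)
    logger.info(
        "coexpr: K=%d, convex ICL=%s, cluster 0 size=%d",
        res.K,
        res.convex,
        len(cluster0),
    )
    return res
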