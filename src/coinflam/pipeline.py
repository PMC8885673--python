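"""End-to-end report assembly.

``run_pipeline`` executes the stages in order — cohort summary,
composite index, differential induction, microbiome community,
mediators, covariate correlations — writing versioned CSV/TSV outputs
plus a machine-readable JSON manifest of every statistic and the SHA-256
hashes of the input files.  With a fixed config and seed the manifest is
byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .cohort import summarize_cohort
from .community import (
    LefseModel,
    alpha_diversity_table,
    bray_curtis_matrix,
    collapse_to_rank,
    pcoa,
)
from .differential import PairedInductionModel
from .errors import CoinflamError
from .index import InflammatoryIndexModel
from .mediators import (
    exclude_subgroup,
    fiber_percent_of_iom_target,
    fold_change_of_means,
    mediator_change_table,
    memory_naive_ratio,
    paired_signed_rank,
    pearson_with_p,
)
from .simulate import (
    CohortDesign,
    CommunityEffectModel,
    ExpressionEffectModel,
    generate_covariates,
    generate_expression,
    generate_otu_table,
    visit_labels,
)


@dataclass
class RunConfig:
    """Pipeline configuration; thresholds default to the trial's values."""

    seed: int = 0
    output_dir: str = "coinflam_out"
    n_subjects: int = 25
    # input paths; any left as None is simulated from the seed
    expression_tsv: str | None = None
    gene_sets_gmt: str | None = None
    subjects_csv: str | None = None
    otu_tsv: str | None = None
    analyte_csv: str | None = None
    # thresholds
    fdr_rate: float = 0.20
    responder_threshold: float = 5.0
    direction: str = "less"
    lefse_alpha: float = 0.05
    lefse_lda_cutoff: float = 2.0
    mediator_change_threshold: float = 5.0
    mediator_p_threshold: float = 0.2
    collapse_rank: str = "family"
    target_corr: float = 0.67
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.fdr_rate <= 1:
            raise CoinflamError("fdr_rate must be in (0, 1]")
        if self.responder_threshold <= 0:
            raise CoinflamError("responder_threshold must be > 0")
        if not 0 < self.lefse_alpha <= 1:
            raise CoinflamError("lefse_alpha must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        if extra:
            kwargs["extra"] = extra
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else round(v, 10)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.output_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _jsonable(asdict(config)), "stages": {}}

    # --- stage 0: inputs (load or simulate) -------------------------------
    design = CohortDesign(n_subjects=config.n_subjects, seed=config.seed)
    if config.expression_tsv:
        matrix = cio.read_expression_tsv(config.expression_tsv)
        partition = cio.read_gmt_partition(config.gene_sets_gmt)
        pairs = cio.read_subjects_csv(config.subjects_csv)
        expr_path = Path(config.expression_tsv)
        gmt_path = Path(config.gene_sets_gmt)
        subj_path = Path(config.subjects_csv)
    else:
        matrix, partition, pairs = generate_expression(
            design, ExpressionEffectModel()
        )
        expr_path = out / "inputs" / "expression.tsv"
        gmt_path = out / "inputs" / "gene_sets.gmt"
        subj_path = out / "inputs" / "subjects.csv"
        cio.write_expression_tsv(matrix, expr_path)
        cio.write_gmt_partition(partition, gmt_path)
        cio.write_subjects_csv(pairs, subj_path)

    if config.otu_tsv:
        otu = cio.read_otu_tsv(config.otu_tsv)
        otu_path = Path(config.otu_tsv)
    else:
        otu = generate_otu_table(
            CommunityEffectModel(n_samples_per_visit=config.n_subjects),
            seed=config.seed + 1,
        )
        otu_path = out / "inputs" / "otu_table.tsv"
        cio.write_otu_tsv(otu, otu_path)

    if config.analyte_csv:
        covariates = None
        panel = cio.read_analyte_csv(config.analyte_csv)
        panel_path = Path(config.analyte_csv)
    else:
        covariates = None  # assigned after the index stage (needs delta)
        panel = None
        panel_path = out / "inputs" / "analytes.csv"

    manifest["inputs"] = {
        "expression_tsv": _sha256(expr_path),
        "gene_sets_gmt": _sha256(gmt_path),
        "subjects_csv": _sha256(subj_path),
        "otu_tsv": _sha256(otu_path),
    }

    # --- stage 1: cohort ---------------------------------------------------
    manifest["stages"]["cohort"] = _jsonable(summarize_cohort(pairs).to_dict())

    # --- stage 2: composite index ------------------------------------------
    index_res = InflammatoryIndexModel(matrix, partition, pairs).fit(
        direction=config.direction,
        responder_threshold=config.responder_threshold,
    )
    index_res.per_subject.to_csv(out / "per_subject_index.csv")
    manifest["stages"]["index"] = _jsonable(index_res.to_dict())
    delta_pct = index_res.per_subject["percent_change"]

    # --- stage 3: differential induction ------------------------------------
    diff_res = PairedInductionModel(
        matrix, pairs, subset=partition.all_probes
    ).fit(fdr_rate=config.fdr_rate)
    diff_res.table.to_csv(out / "differential_induction.csv")
    manifest["stages"]["differential"] = _jsonable(
        {
            "n_tested": diff_res.n_tested,
            "n_significant": diff_res.n_significant,
            "fraction_significant": diff_res.fraction_significant,
            "fdr_rate": config.fdr_rate,
        }
    )

    # --- stage 4: microbiome -------------------------------------------------
    collapse = collapse_to_rank(otu, config.collapse_rank)
    alpha = alpha_diversity_table(otu)
    alpha.to_csv(out / "alpha_diversity.csv")
    labels = visit_labels(otu)
    pre_ids = [s for s in otu.sample_ids if labels[s] == "pre"]
    post_ids = [s for s in otu.sample_ids if labels[s] == "post"]
    dm = bray_curtis_matrix(otu)
    cio.write_distance_tsv(dm, out / "bray_curtis.tsv")
    ordination = pcoa(dm)
    ordination.coordinates.iloc[:, :2].to_csv(out / "pcoa_coordinates.csv")
    lefse = LefseModel(collapse.table, visit_labels(collapse.table)).fit(
        alpha=config.lefse_alpha,
        lda_cutoff=config.lefse_lda_cutoff,
        seed=config.seed + 2,
    )
    lefse.table.to_csv(out / "lefse.csv")
    manifest["stages"]["microbiome"] = _jsonable(
        {
            "collapse_rank": config.collapse_rank,
            "mapped_fraction": collapse.mapped_fraction,
            "shannon_mean_pre": alpha.loc[pre_ids, "shannon"].mean(),
            "shannon_mean_post": alpha.loc[post_ids, "shannon"].mean(),
            "richness_mean_pre": alpha.loc[pre_ids, "richness"].mean(),
            "richness_mean_post": alpha.loc[post_ids, "richness"].mean(),
            "pcoa_top_eigenvalues": list(ordination.eigenvalues[:3]),
            "n_negative_eigenvalues": int(
                ordination.negative_eigenvalues.size
            ),
            "lefse_significant": {
                feat: {
                    "enriched_class": row["enriched_class"],
                    "lda_score": row["lda_score"],
                    "p_value": row["p_value"],
                }
                for feat, row in lefse.significant.iterrows()
            },
        }
    )

    # --- stage 5: mediators --------------------------------------------------
    if panel is None:
        covariates = generate_covariates(
            design,
            target_corr=config.target_corr,
            seed=config.seed + 3,
            delta_iicom_pct=delta_pct.to_numpy(),
        )
        panel = covariates.analytes
        cio.write_analyte_csv(panel, panel_path)
    manifest["inputs"]["analyte_csv"] = _sha256(panel_path)

    change_tab = mediator_change_table(
        panel,
        abs_change_threshold=config.mediator_change_threshold,
        p_threshold=config.mediator_p_threshold,
    )
    change_tab.to_csv(out / "mediator_changes.csv", index=False)

    scfa_stats = {}
    but = panel.paired_values("butyrate")
    if len(but):
        scfa_stats["butyrate_fold_change"] = fold_change_of_means(
            but["pre"].mean(), but["post"].mean()
        )
        _, p_but = paired_signed_rank(
            but["pre"].to_numpy(), but["post"].to_numpy(), alternative="greater"
        )
        scfa_stats["butyrate_signed_rank_p_one_sided"] = p_but
        kept = exclude_subgroup(pairs).retained
        kept_ids = [p.subject_id for p in kept if p.subject_id in but.index]
        if len(kept_ids) >= 5:
            sub = but.loc[kept_ids]
            scfa_stats["butyrate_fold_change_excl_multi_aab"] = (
                fold_change_of_means(sub["pre"].mean(), sub["post"].mean())
            )
    manifest["stages"]["mediators"] = _jsonable(
        {
            "change_table": change_tab.to_dict(orient="records"),
            **scfa_stats,
        }
    )

    # --- stage 6: covariate correlations -------------------------------------
    correlations = {}
    if covariates is not None:
        ffq = covariates.ffq.set_index("subject_id")
        pct_iom = np.array(
            [
                fiber_percent_of_iom_target(
                    ffq.loc[s, "fiber_g_per_day"], ffq.loc[s, "kcal_per_day"]
                )
                for s in delta_pct.index
            ]
        )
        r, p = pearson_with_p(pct_iom, delta_pct.to_numpy())
        correlations["fiber_pct_iom_vs_delta_iicom"] = {"r": r, "p": p}

        tc = covariates.tcell.set_index(["subject_id", "visit"])
        ratio_change = []
        for s in delta_pct.index:
            pre = memory_naive_ratio(
                tc.loc[(s, "pre"), "pct_memory"], tc.loc[(s, "pre"), "pct_naive"]
            )
            post = memory_naive_ratio(
                tc.loc[(s, "post"), "pct_memory"],
                tc.loc[(s, "post"), "pct_naive"],
            )
            ratio_change.append(100.0 * (post - pre) / pre)
        r, p = pearson_with_p(np.array(ratio_change), delta_pct.to_numpy())
        correlations["memory_naive_ratio_change_vs_delta_iicom"] = {
            "r": r, "p": p,
        }
        covariates.ffq.to_csv(out / "inputs" / "ffq.csv", index=False)
        covariates.tcell.to_csv(out / "inputs" / "tcell.csv", index=False)
    manifest["stages"]["correlations"] = _jsonable(correlations)

    manifest_text = json.dumps(manifest, indent=2, sort_keys=True)
    (out / "manifest.json").write_text(manifest_text + "\n")
    return manifest
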