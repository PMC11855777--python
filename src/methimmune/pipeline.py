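"""End-to-end orchestration: markers -> deconvolution -> subtyping ->
annotation -> survival, on any cohort with a reference panel and bulk betas.

Thin glue over the analysis modules; every step is also callable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .annotation import AnnotationTable, annotate_subtypes, summarize_annotations
from .data_io import BetaMatrix, RunConfig, SampleSheet, write_matrix, write_table
from .deconvolution import FractionMatrix, GroupComparison, compare_groups, deconvolve_matrix
from .markers import SignatureMatrix, select_markers
from .phenotype import SurvivalCurve, kaplan_meier
from .subtyping import ConsensusResult, subtype_cohort

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    signature: SignatureMatrix
    fractions: FractionMatrix
    comparison: GroupComparison
    subtype_labels: pd.Series
    consensus: dict[str, ConsensusResult]
    annotation: AnnotationTable
    annotation_counts: pd.DataFrame
    annotation_patterns: pd.DataFrame
    survival: dict[str, SurvivalCurve]
    config: RunConfig

    def save(self, outdir) -> None:
        """Write the primary outputs as TSV (deterministic given inputs)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_matrix(self.signature.to_frame(), outdir / "signature.tsv",
                     config=self.config)
        write_matrix(self.fractions.to_frame(), outdir / "fractions.tsv",
                     config=self.config, index_label="sample_id")
        write_table(self.comparison.tumor_vs_normal, outdir / "tumor_vs_normal.tsv",
                    config=self.config)
        write_table(self.comparison.across_cancers, outdir / "across_cancers.tsv",
                    config=self.config)
        write_table(self.subtype_labels.rename_axis("sample_id").reset_index(),
                    outdir / "subtypes.tsv", config=self.config)
        write_table(self.annotation.table, outdir / "annotation.tsv",
                    config=self.config)
        write_table(self.annotation_counts, outdir / "annotation_counts.tsv",
                    config=self.config)
        write_table(self.annotation_patterns, outdir / "annotation_patterns.tsv",
                    config=self.config)
        areas = pd.DataFrame(
            [{"cancer_type": c, "k": k, "cdf_area": a, "chosen_k": r.chosen_k}
             for c, r in sorted(self.consensus.items())
             for k, a in sorted(r.areas.items())])
        write_table(areas, outdir / "consensus_areas.tsv", config=self.config)
        surv = pd.DataFrame(
            [{"cancer_type": c, "logrank_statistic": s.statistic,
              "p_value": s.p_value, "df": s.degrees_freedom}
             for c, s in sorted(self.survival.items())])
        write_table(surv, outdir / "survival_tests.tsv", config=self.config)


def run_pipeline(reference: BetaMatrix, reference_sheet: SampleSheet,
                 bulk: BetaMatrix, sheet: SampleSheet,
                 config: RunConfig | None = None) -> PipelineResult:
    """Run marker selection, deconvolution, per-cancer consensus subtyping,
    subtype annotation, and (where clinical data exist) survival comparison."""
    config = config or RunConfig()
    signature = select_markers(reference, reference_sheet, config)
    fractions = deconvolve_matrix(bulk, signature,
                                  threshold=config.infiltration_threshold)
    comparison = compare_groups(fractions, sheet, alpha=config.alpha,
                                correction=config.correction)
    labels, consensus = subtype_cohort(
        fractions, sheet, k_range=config.k_range, n_resamples=config.n_resamples,
        subsample_fraction=config.subsample_fraction, seed=config.seed,
        select_tolerance=config.select_k_tolerance)
    annotation = annotate_subtypes(fractions, labels, sheet, alpha=config.alpha,
                                   correction=config.correction)
    counts, patterns = summarize_annotations(annotation)

    survival: dict[str, SurvivalCurve] = {}
    meta = sheet.table
    clin = meta.loc[labels.index.intersection(meta.index)]
    clin = clin[clin["survival_time"].notna() & clin["event"].notna()]
    for cancer, sub in clin.groupby("cancer_type"):
        grp = labels[sub["sample_id"]]
        if grp.nunique() < 2 or sub["event"].sum() < 1:
            continue
        survival[cancer] = kaplan_meier(sub["survival_time"], sub["event"].astype(int),
                                        grp)
    return PipelineResult(
        signature=signature, fractions=fractions, comparison=comparison,
        subtype_labels=labels, consensus=consensus, annotation=annotation,
        annotation_counts=counts, annotation_patterns=patterns,
        survival=survival, config=config)
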