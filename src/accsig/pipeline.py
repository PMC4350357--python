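"""End-to-end orchestration of the analysis stages on an in-memory cohort.

The CLI and the example scripts are thin wrappers over
:func:`analyze_cohort` / :func:`write_results`; everything here is plain
library code operating on the containers from :mod:`accsig.types`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import io
from .differential import derive_signature, group_comparison, significant_up
from .errors import DesignError
from .exon_break import call_fusion, calls_to_frame
from .integrate import (chipseq_overlap_fraction, classify_myb_dependence,
                        fisher_enrichment, integrate_mutations,
                        mirna_mrna_links, stratify_by_marker)
from .preprocess import (MIRNA_BASELINE, MRNA_BASELINE, log2_transform,
                         quantile_normalize)
from .simulate import Cohort


@dataclass
class AnalysisParams:
    """Tunable parameters of the full pipeline (defaults: the study design)."""

    alpha: float = 0.05
    min_fold: float = 2.0
    mrna_baseline: float = MRNA_BASELINE
    mirna_baseline: float = MIRNA_BASELINE
    tau: float = 4.0
    min_delta5: float = 1.0
    max_delta3: float = 0.5
    silent_margin: float = 0.5
    marker: str = "MYB"
    k_sd: float = 2.0
    chip_set_name: str = "MYB_CHIP_TARGETS"
    quantile_normalize: bool = True


@dataclass
class AnalysisResult:
    signature: pd.DataFrame
    mirna_signature: pd.DataFrame
    fusion_calls: pd.DataFrame
    strata: pd.Series
    dependence: pd.DataFrame
    enrichment: pd.DataFrame
    mutation_candidates: pd.DataFrame
    mirna_links: pd.DataFrame
    chip_overlap: float
    group_comparison: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def analyze_cohort(cohort: Cohort, params: AnalysisParams | None = None) -> AnalysisResult:
    """Run every pipeline stage on a cohort and collect the result tables."""
    p = params or AnalysisParams()
    mrna = quantile_normalize(cohort.mrna) if p.quantile_normalize else cohort.mrna
    mirna = quantile_normalize(cohort.mirna) if p.quantile_normalize else cohort.mirna

    sig = derive_signature(mrna, cohort.sheet, alpha=p.alpha, min_fold=p.min_fold,
                           min_intensity=p.mrna_baseline)
    mi_sig = derive_signature(mirna, cohort.sheet, alpha=p.alpha, min_fold=p.min_fold,
                              min_intensity=p.mirna_baseline)

    calls = call_fusion(cohort.exon_profile, cohort.sheet, tau=p.tau,
                        min_delta5=p.min_delta5, max_delta3=p.max_delta3,
                        silent_margin=p.silent_margin)

    log2_mrna = log2_transform(mrna)
    strata = stratify_by_marker(log2_mrna, cohort.sheet, p.marker, k_sd=p.k_sd)
    sheet_df = cohort.sheet.data
    patient_of = dict(zip(sheet_df["sample_id"], sheet_df["patient_id"]))
    high_patients = [patient_of[s] for s in strata.index[strata == "marker-high"]]
    low_patients = [patient_of[s] for s in strata.index[strata == "marker-low"]]

    chip = cohort.gene_sets[p.chip_set_name] if p.chip_set_name in cohort.gene_sets else []
    if low_patients and high_patients:
        sig_high = derive_signature(mrna, cohort.sheet, alpha=p.alpha,
                                    min_fold=p.min_fold,
                                    min_intensity=p.mrna_baseline,
                                    patients=high_patients)
        sig_low = derive_signature(mrna, cohort.sheet, alpha=p.alpha,
                                   min_fold=p.min_fold,
                                   min_intensity=p.mrna_baseline,
                                   patients=low_patients)
        dependence = classify_myb_dependence(sig_high, sig_low, chip,
                                             min_fold=p.min_fold)
    else:
        dependence = pd.DataFrame(columns=["gene", "label", "up_in_high",
                                           "up_in_low", "in_chip_set"])

    universe = list(sig.index[sig["passed_baseline"]])
    signature_genes = list(sig.index[sig["significant"]])
    if signature_genes and cohort.gene_sets is not None:
        enrichment = fisher_enrichment(signature_genes, cohort.gene_sets, universe,
                                       alpha=p.alpha)
    else:
        enrichment = pd.DataFrame()
    chip_overlap = (chipseq_overlap_fraction(signature_genes, chip)
                    if signature_genes and chip else float("nan"))

    mutation_candidates = integrate_mutations(sig, cohort.mutations)
    links = mirna_mrna_links(mi_sig, sig, cohort.mirna_map)

    try:
        groups = group_comparison(log2_mrna, cohort.sheet, alpha=p.alpha)
    except DesignError:
        groups = None

    return AnalysisResult(
        signature=sig, mirna_signature=mi_sig, fusion_calls=calls_to_frame(calls),
        strata=strata, dependence=dependence, enrichment=enrichment,
        mutation_candidates=mutation_candidates, mirna_links=links,
        chip_overlap=chip_overlap, group_comparison=groups,
        extras={"n_signature": len(signature_genes),
                "n_mirna_signature": int(mi_sig["significant"].sum()),
                "universe_size": len(universe)},
    )


def write_cohort(cohort: Cohort, outdir) -> list[str]:
    """Write every cohort artifact (data + truth) as TSV/GMT under ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    written = []

    def _w(name, fn):
        fn(out / name)
        written.append(name)

    _w("mrna.tsv", lambda p: io.write_expression_matrix(cohort.mrna, p))
    _w("mirna.tsv", lambda p: io.write_expression_matrix(cohort.mirna, p))
    _w("exon_profile.tsv", lambda p: io.write_exon_profile(cohort.exon_profile, p))
    _w("sample_sheet.tsv", lambda p: io.write_sample_sheet(cohort.sheet, p))
    _w("gene_sets.gmt", lambda p: io.write_gene_sets(cohort.gene_sets, p))
    _w("mirna_target_map.tsv", lambda p: io.write_mirna_target_map(cohort.mirna_map, p))
    _w("mutations.tsv", lambda p: io.write_mutation_table(cohort.mutations, p))
    _w("truth_genes.tsv", lambda p: io.write_table(cohort.truth.genes, p))
    _w("truth_fusions.tsv", lambda p: io.write_table(cohort.truth.fusions, p))
    _w("truth_mirnas.tsv", lambda p: io.write_table(cohort.truth.mirnas, p))
    _w("truth_inverse_pairs.tsv", lambda p: io.write_table(cohort.truth.inverse_pairs, p))
    return written


def write_results(result: AnalysisResult, outdir, params: AnalysisParams) -> list[str]:
    """Write every analysis table as TSV under ``outdir`` (deterministic bytes)."""
    from pathlib import Path

    out = Path(outdir)
    header = (f"alpha={params.alpha} min_fold={params.min_fold} "
              f"mrna_baseline={params.mrna_baseline} mirna_baseline={params.mirna_baseline} "
              f"tau={params.tau} marker={params.marker} "
              "breakpoint = last retained 5' exon (1-based)")
    written = []

    def _w(name, df, index=False):
        io.write_table(df, out / name, header_comment=header, index=index)
        written.append(name)

    _w("signature.tsv", result.signature, index=True)
    _w("mirna_signature.tsv", result.mirna_signature, index=True)
    _w("fusion_calls.tsv", result.fusion_calls)
    _w("strata.tsv", result.strata.rename("stratum").to_frame(), index=True)
    _w("dependence.tsv", result.dependence)
    _w("enrichment.tsv", result.enrichment)
    _w("mutation_candidates.tsv", result.mutation_candidates)
    _w("mirna_links.tsv", result.mirna_links)
    if result.group_comparison is not None:
        _w("group_comparison.tsv", result.group_comparison, index=True)
    return written
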