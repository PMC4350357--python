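"""Post-signature integration: enrichment, MYB-target overlap, MYB-low
stratification and dependence classification, mutation intersection, and
miRNA-mRNA inverse linking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_fdr, significant_up
from .errors import InputError
from .types import ExpressionMatrix, GeneSetCollection, SampleSheet

_REL_EPS = 1.0 + 1e-7  # R-style tolerance for "as extreme" in the two-sided sum


def _hypergeom_pvalues(overlap: int, set_size: int, sig_size: int,
                       universe: int) -> tuple[float, float]:
    """(two_sided, one_sided_enrichment) for a 2x2 table via the hypergeometric
    distribution: overlap ~ Hypergeom(universe, set_size, sig_size)."""
    rv = stats.hypergeom(universe, set_size, sig_size)
    support = np.arange(max(0, sig_size + set_size - universe),
                        min(sig_size, set_size) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(overlap)
    two = float(pmf[pmf <= p_obs * _REL_EPS].sum())
    one = float(pmf[support >= overlap].sum())
    return min(two, 1.0), min(one, 1.0)


def fisher_enrichment(signature, annotation: GeneSetCollection, universe,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Fisher's exact test of each annotation set against the signature.

    Each set is intersected with the universe first; the 2x2 table is
    (in/out signature) x (in/out set). Reports the two-sided p (BH-corrected
    across sets) and the one-sided enrichment p, plus the sample odds ratio.
    """
    universe = set(universe)
    signature = set(signature)
    if not universe or not signature:
        raise InputError("universe and signature must be non-empty")
    if not signature <= universe:
        extra = sorted(signature - universe)[:3]
        raise InputError(f"signature genes outside the universe, e.g. {extra}")
    rows = []
    for name in annotation.names():
        members = set(annotation[name]) & universe
        a = len(signature & members)                    # in sig, in set
        b = len(signature) - a                          # in sig, out of set
        c = len(members) - a                            # out of sig, in set
        d = len(universe) - len(signature) - c
        two, one = _hypergeom_pvalues(a, len(members), len(signature), len(universe))
        odds = (a * d) / (b * c) if b * c else np.inf if a * d else np.nan
        rows.append((name, a, len(members), len(signature), len(universe),
                     odds, two, one))
    table = pd.DataFrame(rows, columns=[
        "set_name", "overlap", "set_size", "signature_size", "universe_size",
        "odds_ratio", "p_two_sided", "p_one_sided"])
    q, sig = bh_fdr(table["p_two_sided"].to_numpy(), alpha)
    table["q"] = q
    table["significant"] = sig
    return table.sort_values(["q", "p_two_sided", "set_name"],
                             kind="stable").reset_index(drop=True)


def chipseq_overlap_fraction(signature, chip_targets) -> float:
    """|signature ∩ ChIP targets| / |signature|."""
    signature = set(signature)
    if not signature:
        raise InputError("signature must be non-empty")
    return len(signature & set(chip_targets)) / len(signature)


def stratify_by_marker(matrix: ExpressionMatrix, sheet: SampleSheet,
                       marker: str, k_sd: float = 2.0) -> pd.Series:
    """Split tumors into marker-high/marker-low against the normal baseline.

    A tumor is marker-low iff its marker value is <= mean(normals) +
    k_sd * sd(normals) on the log2 scale, i.e. indistinguishable from the
    basal level in normal tissue.
    """
    if marker not in matrix.data.index:
        raise InputError(f"marker {marker!r} not in matrix")
    normals = [s for s in sheet.normal_samples() if s in matrix.data.columns]
    tumors = [s for s in sheet.tumor_samples() if s in matrix.data.columns]
    if len(normals) < 2:
        raise InputError("need >= 2 normal samples to set the baseline")
    base = matrix.data.loc[marker, normals]
    threshold = base.mean() + k_sd * base.std(ddof=1)
    values = matrix.data.loc[marker, tumors]
    return pd.Series(np.where(values <= threshold, "marker-low", "marker-high"),
                     index=tumors, name=f"{marker}_stratum")


def classify_myb_dependence(sig_high: pd.DataFrame, sig_low: pd.DataFrame,
                            chip_targets, min_fold: float = 2.0) -> pd.DataFrame:
    """Label activated genes as MYB-independent / dependent-candidate / other.

    "Activated" means significant and up-regulated with fold change >=
    ``min_fold`` in the given stratum's signature table. Labels:

    - ``MYB-independent``: activated in both the MYB-high and MYB-low strata.
    - ``MYB-dependent-candidate``: activated only in MYB-high and present in
      the ChIP target set.
    - ``MYB-associated-unclassified``: activated only in MYB-high, absent
      from the ChIP set.

    Genes not activated in the MYB-high stratum are excluded from the output
    (the classes are defined relative to the MYB-high tumors; with a single
    MYB-low tumor the low stratum alone is too noisy to nominate genes).
    """
    if set(sig_high.index) != set(sig_low.index):
        raise InputError("high/low signature tables derive from different universes")
    chip = set(chip_targets)
    up_high = set(significant_up(sig_high, min_fold))
    up_low = set(significant_up(sig_low, min_fold))
    rows = []
    for gene in sorted(up_high):
        in_low, in_chip = gene in up_low, gene in chip
        if in_low:
            label = "MYB-independent"
        elif in_chip:
            label = "MYB-dependent-candidate"
        else:
            label = "MYB-associated-unclassified"
        rows.append((gene, label, True, in_low, in_chip))
    return pd.DataFrame(rows, columns=["gene", "label", "up_in_high",
                                       "up_in_low", "in_chip_set"])


def integrate_mutations(signature: pd.DataFrame, mutations: pd.DataFrame,
                        classes=("missense", "truncating")) -> pd.DataFrame:
    """Candidate co-driver genes: significantly up-regulated AND mutated.

    Keeps genes carrying >= 1 somatic mutation of an allowed class that are
    significant and up-regulated in the signature; sorted by fold change
    descending.
    """
    up = set(significant_up(signature))
    hits = mutations.loc[mutations["mutation_class"].isin(set(classes))]
    candidates = sorted(up & set(hits["gene"]))
    rows = []
    for gene in candidates:
        gene_hits = hits.loc[hits["gene"] == gene]
        rows.append((gene, float(signature.loc[gene, "fold_change"]),
                     len(gene_hits),
                     ",".join(sorted(set(gene_hits["mutation_class"])))))
    out = pd.DataFrame(rows, columns=["gene", "fold_change", "n_mutations",
                                      "mutation_classes"])
    return out.sort_values("fold_change", ascending=False,
                           kind="stable").reset_index(drop=True)


def mirna_mrna_links(mi_sig: pd.DataFrame, m_sig: pd.DataFrame,
                     target_map: pd.DataFrame) -> pd.DataFrame:
    """Inverse regulatory pairs: both significant, opposite directions, in map.

    Emits one row per (miRNA, target) pair from the map where the miRNA is
    significant in the miRNA signature, the target is significant in the mRNA
    signature, and their directions are opposite; annotated with both fold
    changes.
    """
    rows = []
    for row in target_map.itertuples():
        mi, gene = row.mirna_id, row.target_gene
        if mi not in mi_sig.index or gene not in m_sig.index:
            continue
        if not (mi_sig.loc[mi, "significant"] and m_sig.loc[gene, "significant"]):
            continue
        if mi_sig.loc[mi, "direction"] == m_sig.loc[gene, "direction"]:
            continue
        rows.append((mi, gene,
                     mi_sig.loc[mi, "direction"], float(mi_sig.loc[mi, "fold_change"]),
                     m_sig.loc[gene, "direction"], float(m_sig.loc[gene, "fold_change"])))
    return pd.DataFrame(rows, columns=["mirna_id", "target_gene", "mirna_direction",
                                       "mirna_fold_change", "target_direction",
                                       "target_fold_change"])
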