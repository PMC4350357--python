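"""Paired differential testing, FDR control, group comparison, clustering, PCA.

The signature derivation composes the two preprocessing filters with a
per-probe paired t-test and Benjamini-Hochberg step-up FDR control at
alpha = 0.05, the design used to derive the tumor-vs-normal signature this
package re-implements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .errors import DesignError, InputError
from .preprocess import (DEFAULT_MIN_FOLD, MRNA_BASELINE, baseline_filter,
                         log2_transform, paired_log2_deltas, variation_filter)
from .types import ExpressionMatrix, SampleSheet


def paired_t_test(matrix: ExpressionMatrix, sheet: SampleSheet,
                  patients=None) -> pd.DataFrame:
    """Per-probe paired t-test of tumor vs matched normal (log2 matrix).

    Returns a DataFrame indexed by probe with columns ``t``, ``df``, ``p``,
    ``zero_variance``. t = mean(d) / (sd(d)/sqrt(n)) with d the paired log2
    differences, df = n - 1, two-sided p from the t distribution.
    Zero-variance probes get a flagged missing p rather than p = 0.
    """
    deltas = paired_log2_deltas(matrix, sheet, patients)
    n = deltas.shape[1]
    if n < 2:
        raise DesignError(f"paired t-test needs >= 2 pairs, got {n}")
    d = deltas.to_numpy()
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    zero_var = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[zero_var] = np.nan
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[zero_var] = np.nan
    return pd.DataFrame({"t": t, "df": n - 1, "p": p, "zero_variance": zero_var},
                        index=deltas.index)


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q-values and significance flags.

    q_i = min over j with p_(j) >= p_(i) of (m * p_(j) / j), clipped at 1;
    significant iff q <= alpha. Missing p-values propagate to missing q and
    are never significant; m counts only the observed p-values. Tied p-values
    receive equal q.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    observed = ~np.isnan(p)
    if np.any((p[observed] < 0) | (p[observed] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    m = int(observed.sum())
    if m:
        idx = np.flatnonzero(observed)
        order = np.argsort(p[idx], kind="stable")
        ranked = p[idx][order] * m / np.arange(1, m + 1)
        qs = np.minimum.accumulate(ranked[::-1])[::-1]
        q[idx[order]] = np.minimum(qs, 1.0)
    significant = np.zeros(p.shape, dtype=bool)
    significant[observed] = q[observed] <= alpha
    return q, significant


def derive_signature(matrix: ExpressionMatrix, sheet: SampleSheet,
                     alpha: float = 0.05,
                     min_fold: float = DEFAULT_MIN_FOLD,
                     min_intensity: float = MRNA_BASELINE,
                     patients=None,
                     log2_floor: float = 1.0) -> pd.DataFrame:
    """Full signature table: baseline filter -> variation filter -> paired t -> BH.

    ``matrix`` must be on the linear scale (quantile-normalize it first if
    desired). The returned table covers every input probe with filter flags;
    t/p/q are computed for probes passing both filters. Rows are sorted by q
    ascending, then |log2 fold change| descending, then probe ID; untested
    probes follow. With fewer than 3 resolvable pairs the table degrades to a
    descriptive fold-change rule (significant = passed both filters, test
    columns missing); the mode is recorded in ``table.attrs["mode"]``.
    """
    base_kept, base_report = baseline_filter(matrix, min_intensity)
    log2_all = log2_transform(matrix, floor=log2_floor)
    log2_base = log2_transform(base_kept, floor=log2_floor)
    var_kept, var_report = variation_filter(log2_base, sheet, min_fold,
                                            patients=patients)

    deltas_all = paired_log2_deltas(log2_all, sheet, patients)
    n_pairs = deltas_all.shape[1]
    log2_fc = deltas_all.mean(axis=1)

    table = pd.DataFrame({
        "log2_fc": log2_fc,
        "fold_change": 2.0 ** log2_fc,
        "direction": np.where(log2_fc >= 0, "up", "down"),
        "passed_baseline": base_report.flags["passed_baseline"]
                           .reindex(matrix.data.index, fill_value=False),
        "passed_variation": var_report.flags["passed_variation"]
                            .reindex(matrix.data.index, fill_value=False),
    }, index=matrix.data.index)
    table["tested"] = table["passed_baseline"] & table["passed_variation"]

    mode = "paired_t" if n_pairs >= 3 else "descriptive_fc"
    table["t"] = np.nan
    table["df"] = np.nan
    table["p"] = np.nan
    table["q"] = np.nan
    table["significant"] = False
    table["zero_variance"] = False
    tested_probes = table.index[table["tested"]]
    if mode == "paired_t" and len(tested_probes):
        tres = paired_t_test(log2_all.subset_probes(tested_probes), sheet, patients)
        # A zero-variance probe that reached this point already shows a >=
        # min_fold change in every single pair (the variation filter ran
        # first): the effect is deterministic, i.e. maximal evidence, not a
        # degenerate artifact. Fold it into BH as p=0 but keep the flag.
        p = tres["p"].to_numpy().copy()
        zv = tres["zero_variance"].to_numpy()
        mean_delta = deltas_all.loc[tested_probes].mean(axis=1).to_numpy()
        deterministic = zv & (np.abs(mean_delta) > 0)
        p[deterministic] = 0.0
        q, sig = bh_fdr(p, alpha)
        table.loc[tested_probes, "t"] = np.where(
            deterministic, np.sign(mean_delta) * np.inf, tres["t"])
        table.loc[tested_probes, "df"] = tres["df"]
        table.loc[tested_probes, "p"] = p
        table.loc[tested_probes, "q"] = q
        table.loc[tested_probes, "significant"] = sig
        table.loc[tested_probes, "zero_variance"] = zv
    elif len(tested_probes):
        table.loc[tested_probes, "significant"] = True

    table["abs_log2_fc"] = table["log2_fc"].abs()
    table = _sorted_signature(table).drop(columns="abs_log2_fc")
    table.attrs["mode"] = mode
    table.attrs["params"] = {"alpha": alpha, "min_fold": min_fold,
                             "min_intensity": min_intensity, "n_pairs": n_pairs}
    return table


def _sorted_signature(table: pd.DataFrame) -> pd.DataFrame:
    """Total order: tested first, q asc (NaN last), |log2 FC| desc, probe ID."""
    helper = table.assign(
        _untested=~table["tested"],
        _q=table["q"].fillna(np.inf),
        _nfc=-table["abs_log2_fc"],
        _id=table.index,
    )
    helper = helper.sort_values(["_untested", "_q", "_nfc", "_id"], kind="stable")
    return table.loc[helper.index]


def significant_up(table: pd.DataFrame, min_fold: float | None = None) -> list[str]:
    """Probes significant and up-regulated (optionally with a fold floor)."""
    mask = table["significant"] & (table["direction"] == "up")
    if min_fold is not None:
        mask &= table["fold_change"] >= min_fold
    return list(table.index[mask])


def significant_down(table: pd.DataFrame, max_fold: float | None = None) -> list[str]:
    mask = table["significant"] & (table["direction"] == "down")
    if max_fold is not None:
        mask &= table["fold_change"] <= max_fold
    return list(table.index[mask])


def group_comparison(matrix: ExpressionMatrix, sheet: SampleSheet,
                     grouping: dict[str, str] | None = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-probe two-group comparison of tumors (default: fusion annotation).

    A fixed-effect pooled-variance one-way comparison: F = t^2 on 1 and
    n1+n2-2 degrees of freedom, BH-corrected across probes. ``grouping`` maps
    tumor sample IDs to one of exactly two group labels; by default tumors are
    grouped by their ``fusion_annotation``.
    """
    if grouping is None:
        grouping = {s: sheet.fusion_annotation_of(s) for s in sheet.tumor_samples()
                    if sheet.fusion_annotation_of(s) in ("positive", "negative")}
    labels = sorted(set(grouping.values()))
    if len(labels) != 2:
        raise DesignError(f"need exactly 2 groups, got {labels}")
    g1 = [s for s, g in grouping.items() if g == labels[0] and s in matrix.data.columns]
    g2 = [s for s, g in grouping.items() if g == labels[1] and s in matrix.data.columns]
    if len(g1) < 2 or len(g2) < 2:
        raise DesignError("each group needs >= 2 samples")
    x1 = matrix.data[g1].to_numpy()
    x2 = matrix.data[g2].to_numpy()
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    df2 = n1 + n2 - 2
    pooled = (ss1 + ss2) / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (m1 - m2) ** 2 / (pooled * (1.0 / n1 + 1.0 / n2))
    f[pooled == 0.0] = np.nan
    p = stats.f.sf(f, 1, df2)
    q, sig = bh_fdr(p, alpha)
    return pd.DataFrame({
        f"mean_{labels[0]}": m1, f"mean_{labels[1]}": m2,
        "F": f, "p": p, "q": q, "significant": sig,
    }, index=matrix.data.index)


@dataclass
class ClusterResult:
    """Ward linkage over samples with a deterministic leaf order."""

    linkage: np.ndarray
    sample_ids: list[str]      # order used for the linkage rows
    leaf_order: list[str]

    def cut(self, k: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.sample_ids, labels))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node):
            if node.is_leaf():
                return self.sample_ids[node.id]
            return f"({walk(node.left)},{walk(node.right)}):{node.dist:.6g}"

        return walk(tree) + ";"


def hierarchical_cluster(matrix: ExpressionMatrix, probes) -> ClusterResult:
    """Agglomerative Ward clustering of samples on a probe subset.

    Samples are pre-sorted by ID before linkage so the tree (and its leaf
    order) is invariant to the input column order.
    """
    wanted = set(probes)
    keep = [p for p in matrix.probe_ids if p in wanted]
    if not keep:
        raise InputError("probe subset is disjoint from the matrix")
    samples = sorted(matrix.sample_ids)
    x = matrix.data.loc[keep, samples].to_numpy().T
    if x.shape[0] < 2:
        raise InputError("clustering needs >= 2 samples")
    link = hierarchy.linkage(x, method="ward", metric="euclidean")
    leaves = hierarchy.leaves_list(link)
    return ClusterResult(linkage=link, sample_ids=samples,
                         leaf_order=[samples[i] for i in leaves])


@dataclass
class PcaResult:
    scores: pd.DataFrame       # samples x components
    loadings: pd.DataFrame     # probes x components
    variance_fractions: np.ndarray


def pca(matrix: ExpressionMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of samples over probes centered across samples.

    Components are ordered by decreasing explained variance; each component's
    sign is fixed so its largest-magnitude loading is positive. A constant
    matrix yields all-zero scores and variance fractions.
    """
    if matrix.shape[1] < 2:
        raise InputError("PCA needs >= 2 samples")
    x = matrix.data.to_numpy(dtype=float).T           # samples x probes
    x = x - x.mean(axis=0, keepdims=True)             # center probes across samples
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = (s ** 2).sum()
    k = n_components or len(s)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    flip = np.ones(len(s))
    for c in range(len(s)):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            flip[c] = -1.0
    u = u * flip
    vt = vt * flip[:, None]
    scores = u * s
    fractions = (s ** 2) / total if total > 0 else np.zeros(len(s))
    if total == 0:
        scores = np.zeros_like(scores)
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=matrix.probe_ids, columns=comp_names),
        variance_fractions=fractions,
    )
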