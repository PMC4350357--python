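"""Synthetic paired tumor/normal cohort generator.

Emulates the statistical structure of a salivary-gland adenoid cystic carcinoma
(ACC) expression study: matched tumor/normal pairs on a linear-intensity array
scale, a planted differential signature with MYB as the top gene (18-fold by
default), extracellular-matrix (ECM) genes planted at 2-30-fold, one MYB-low
tumor that retains every non-MYB-driven planted effect, an exon-level profile
of the focal MYB gene with 3' intensity drops at planted breakpoints in
fusion-positive tumors, and a miRNA matrix with planted down-regulated
regulators (miR-150 against MYB, miR-29 against HAPLN1) of planted up-regulated
targets. Ground truth for every planted feature is returned alongside the data
so downstream stages can be scored.

The generative model, per gene g and patient p (log2 scale):

    normal_gp = b_g + a_p + e                        e ~ Normal(0, noise_sd)
    tumor_gp  = b_g + a_p + s_g * log2(fc_g) + e

with gene baselines b_g ~ Normal(baseline_log2_mean, baseline_log2_sd), a
patient random effect a_p ~ Normal(0, patient_sd) shared by both members of a
pair (the within-pair correlation that makes the paired test more powerful
than the unpaired one), and s_g in {+1, -1, 0} the planted direction.
Intensities are emitted as 2**x (linear scale). Because a_p cancels in the
tumor/normal ratio, with noise_sd=0 the realized fold change of every planted
gene equals its configured value exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .types import ExonIntensityProfile, ExpressionMatrix, GeneSetCollection, SampleSheet

MYB = "MYB"
MIR_150 = "hsa-miR-150"
MIR_29 = "hsa-miR-29"

# fold changes fixed by the emulated study design rather than drawn; MYB is the
# top-scoring gene, VCAN the top ECM gene, HAPLN1 its binding partner
FIXED_UP_FC = {MYB: 18.0, "KIT": 5.0, "FGFR1": 4.0, "VCAN": 16.0, "HAPLN1": 14.0}
# up-regulated genes that also carry planted somatic mutations (fold drawn)
NAMED_UP_DRAWN = ("RUNX1", "NOTCH1")
N_ECM = 16  # top differentially expressed ECM genes, incl. VCAN and HAPLN1


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort. Defaults are the study conditions."""

    n_pairs: int = 12
    n_genes: int = 5000
    n_signature_up: int = 100
    n_signature_down: int = 60
    fc_range: tuple[float, float] = (2.0, 30.0)
    myb_fc: float = 18.0
    noise_sd: float = 0.4
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    # planted signature genes emulate transcripts the study detected, so their
    # baselines are floored at a clearly detectable intensity (2^6.5 ~ 90)
    planted_min_baseline_log2: float = 6.5
    patient_sd: float = 0.2
    n_fusion_pos: int = 6
    n_mislabeled_negative: int = 0
    myb_low_index: int | None = None  # tumor index; None = first fusion-negative
    n_myb_dependent: int = 30
    n_myb_associated: int = 10
    exon_count: int = 15
    breakpoint_range: tuple[int, int] = (8, 14)
    exon_delta3: float = 0.0  # residual 3' elevation in fusion-positive tumors
    n_mirna: int = 847
    n_mirna_down: int = 16
    n_mirna_up: int = 6
    mirna_fc_range: tuple[float, float] = (2.0, 8.0)
    seed: int = 0

    @property
    def n_named_up(self) -> int:
        return len(FIXED_UP_FC) + len(NAMED_UP_DRAWN) + (N_ECM - 2)

    def validate(self) -> None:
        if self.n_pairs < 1 or self.n_genes < 1:
            raise ConfigError("n_pairs and n_genes must be positive")
        if self.n_signature_up + self.n_signature_down >= self.n_genes:
            raise ConfigError("n_signature_up + n_signature_down must be < n_genes")
        if self.n_signature_up not in (0,) and self.n_signature_up < self.n_named_up:
            raise ConfigError(
                f"n_signature_up must be 0 or >= {self.n_named_up} "
                "(the named MYB/ECM genes)"
            )
        if not (0 <= self.n_fusion_pos <= self.n_pairs):
            raise ConfigError("n_fusion_pos must lie in [0, n_pairs]")
        if self.n_mislabeled_negative > self.n_fusion_pos:
            raise ConfigError("n_mislabeled_negative cannot exceed n_fusion_pos")
        lo, hi = self.breakpoint_range
        if not (2 <= lo <= hi <= self.exon_count - 1):
            raise ConfigError(
                f"breakpoint_range {self.breakpoint_range} outside [2, exon_count-1]"
            )
        if self.exon_count < 5:
            raise ConfigError("exon_count must be >= 5")
        if self.myb_low_index is not None and not (0 <= self.myb_low_index < self.n_pairs):
            raise ConfigError("myb_low_index out of range")
        free_up = max(0, self.n_signature_up - self.n_named_up)
        if self.n_myb_dependent + self.n_myb_associated > free_up:
            raise ConfigError(
                "n_myb_dependent + n_myb_associated exceeds the free up-gene pool"
            )
        if self.n_mirna_down + self.n_mirna_up >= self.n_mirna:
            raise ConfigError("planted miRNAs must be fewer than n_mirna")
        if self.n_mirna_down == 1:
            raise ConfigError("n_mirna_down must be 0 or >= 2 (miR-150 and miR-29)")
        if self.noise_sd < 0 or self.patient_sd < 0:
            raise ConfigError("standard deviations must be non-negative")


@dataclass
class TruthTables:
    """Ground truth for every planted feature of a synthetic cohort."""

    genes: pd.DataFrame          # gene, direction, fold_change, dependence
    fusions: pd.DataFrame        # sample_id, status, breakpoint, annotated
    myb_low_tumor: str           # sample_id of the planted MYB-low tumor ("" if none)
    mirnas: pd.DataFrame         # mirna_id, direction, fold_change
    inverse_pairs: pd.DataFrame  # mirna_id, target_gene


@dataclass
class Cohort:
    """Everything :func:`generate_cohort` emits, truth included."""

    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    exon_profile: ExonIntensityProfile
    sheet: SampleSheet
    truth: TruthTables
    gene_sets: GeneSetCollection
    mirna_map: pd.DataFrame
    mutations: pd.DataFrame


def _gene_catalog(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Planted gene list: name, direction, fold change, MYB-dependence label.

    Dependence labels drive the MYB-low tumor: "dependent" and "associated"
    genes lose their effect there (dependent ones additionally sit in the
    emitted ChIP target set); "independent" genes keep it, mirroring the
    observation that the signature survives loss of MYB.
    """
    lo, hi = config.fc_range
    if config.n_signature_up == 0:
        up_genes: list[str] = []
        fc_up = np.empty(0)
    else:
        ecm_extra = [f"ECM_{i:02d}" for i in range(1, N_ECM - 1)]
        named = list(FIXED_UP_FC) + list(NAMED_UP_DRAWN) + ecm_extra
        free = [f"UP_{i:03d}" for i in range(1, config.n_signature_up - len(named) + 1)]
        up_genes = named + free
        fc_up = np.empty(len(up_genes))
        for i, g in enumerate(up_genes):
            if g == MYB:
                fc_up[i] = config.myb_fc
            elif g in FIXED_UP_FC:
                # named folds respect the configured ceiling so that narrowing
                # fc_range bounds every non-MYB gene
                fc_up[i] = min(FIXED_UP_FC[g], hi)
            elif g.startswith("ECM_"):
                # top-fold ECM block, kept below MYB's induction
                fc_up[i] = rng.uniform(min(8.0, hi), min(13.0, hi))
            else:
                fc_up[i] = rng.uniform(lo, hi)
    down_genes = [f"DOWN_{i:03d}" for i in range(1, config.n_signature_down + 1)]
    fc_down = rng.uniform(lo, hi, size=len(down_genes))

    free = [g for g in up_genes if g.startswith("UP_")]
    dependent = set(free[: config.n_myb_dependent])
    associated = set(free[config.n_myb_dependent:
                          config.n_myb_dependent + config.n_myb_associated])

    def label(g: str) -> str:
        if g == MYB:
            return "marker"
        if g in dependent:
            return "dependent"
        if g in associated:
            return "associated"
        return "independent"

    return pd.DataFrame({
        "gene": up_genes + down_genes,
        "direction": ["up"] * len(up_genes) + ["down"] * len(down_genes),
        "fold_change": np.concatenate([fc_up, fc_down]),
        "dependence": [label(g) for g in up_genes] + ["none"] * len(down_genes),
    })


def _gene_sets(genes: pd.DataFrame, null_genes: list[str]) -> GeneSetCollection:
    """Annotation GMT sets: a synthetic ChIP target list whose signature overlap
    is ~50%, the planted ECM set, and localization decoys."""
    up = list(genes.loc[genes["direction"] == "up", "gene"])
    down = list(genes.loc[genes["direction"] == "down", "gene"])
    dep = dict(zip(genes["gene"], genes["dependence"]))
    dependent = [g for g in up if dep[g] == "dependent"]
    independent_up = [g for g in up if dep[g] == "independent"]
    ecm = [g for g in up if g in ("VCAN", "HAPLN1") or g.startswith("ECM_")]

    n_half = len(independent_up) // 2
    n_sig = len(up) + len(down)
    chip = (dependent + independent_up[:n_half]
            + down[: max(0, n_sig // 2 - len(dependent) - n_half)]
            + null_genes[:100])
    free_up = [g for g in up if g.startswith("UP_")]
    sets = {
        "MYB_CHIP_TARGETS": chip,
        "extracellular_matrix": ecm,
        "plasma_membrane": [g for g in ("KIT", "FGFR1") if g in up]
                           + free_up[:10] + null_genes[100:120],
        "extracellular_space": free_up[10:18] + null_genes[120:132],
        "nucleus": [g for g in (MYB, "RUNX1", "NOTCH1") if g in up] + null_genes[132:172],
        "cytoplasm": null_genes[172:222],
    }
    sets = {k: v for k, v in sets.items() if v}
    return GeneSetCollection(sets, {k: "synthetic annotation set" for k in sets})


def _mutations(tumor_ids: list[str]) -> pd.DataFrame:
    """Somatic mutation table planting the expression/mutation intersection:
    RUNX1 (missense) and NOTCH1 (truncating) are up-regulated and mutated; the
    other mutated genes are outside the up-signature."""
    pick = lambda i: tumor_ids[min(i, len(tumor_ids) - 1)]
    rows = [
        ("RUNX1", pick(0), "missense"),
        ("RUNX1", pick(2), "missense"),
        ("NOTCH1", pick(1), "truncating"),
        ("TP53", pick(0), "missense"),
        ("FBXW7", pick(3), "other"),
        ("DOWN_001", pick(4), "missense"),
    ]
    return pd.DataFrame(rows, columns=["gene", "sample_id", "mutation_class"])


def generate_cohort(config: SimConfig | None = None, **overrides) -> Cohort:
    """Generate one synthetic paired cohort with ground truth.

    Identical configs (including seed) give bit-identical outputs. The MYB-low
    tumor is always fusion-negative: if ``myb_low_index`` points at a planted
    positive, that tumor is converted to negative.
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = SimConfig(**{**asdict(config), **overrides})
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_pairs

    patients = [f"P{i + 1:02d}" for i in range(n)]
    tumor_ids = [f"ACC{i + 1:02d}_T" for i in range(n)]
    normal_ids = [f"ACC{i + 1:02d}_N" for i in range(n)]

    fusion_true = np.array([i < config.n_fusion_pos for i in range(n)])
    if config.myb_low_index is None:
        negatives = np.flatnonzero(~fusion_true)
        myb_low = int(negatives[0]) if len(negatives) else n - 1
    else:
        myb_low = config.myb_low_index
    fusion_true[myb_low] = False
    annotated = fusion_true.copy()
    if config.n_mislabeled_negative:
        # truly positive tumors carried with annotation 'negative', to be caught
        # by the exon-plot caller; taken from the end of the positive block
        pos_idx = np.flatnonzero(fusion_true)
        for i in pos_idx[len(pos_idx) - config.n_mislabeled_negative:]:
            annotated[i] = False

    genes = _gene_catalog(config, rng)
    planted = list(genes["gene"])
    null_genes = [f"G{i:05d}" for i in range(1, config.n_genes - len(planted) + 1)]
    all_genes = planted + null_genes
    gene_index = {g: i for i, g in enumerate(all_genes)}

    baselines = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                           size=config.n_genes)
    if planted:
        baselines[: len(planted)] = np.maximum(baselines[: len(planted)],
                                               config.planted_min_baseline_log2)
    patient_eff = rng.normal(0.0, config.patient_sd, size=n)

    effect = np.zeros((config.n_genes, n))
    if planted:
        sign = np.where(genes["direction"].to_numpy() == "up", 1.0, -1.0)
        effect[: len(planted), :] = (sign * np.log2(genes["fold_change"].to_numpy()))[:, None]
        myb_driven = genes.loc[genes["dependence"].isin(["marker", "dependent",
                                                         "associated"]), "gene"]
        for g in myb_driven:
            effect[gene_index[g], myb_low] = 0.0

    base = baselines[:, None] + patient_eff[None, :]
    eps_n = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
    eps_t = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
    normals = 2.0 ** (base + eps_n)
    tumors = 2.0 ** (base + effect + eps_t)

    cols, data = [], []
    for i in range(n):  # interleave T/N per patient
        cols += [tumor_ids[i], normal_ids[i]]
        data += [tumors[:, i], normals[:, i]]
    mrna = ExpressionMatrix(
        pd.DataFrame(np.column_stack(data), index=all_genes, columns=cols),
        scale="linear", assay="mRNA",
    )

    sheet = SampleSheet(pd.DataFrame({
        "sample_id": cols,
        "patient_id": [p for p in patients for _ in range(2)],
        "tissue": ["tumor", "normal"] * n,
        "subtype": "ACC",
        "fusion_annotation": [v for i in range(n) for v in
                              (("positive" if annotated[i] else "negative"), "unknown")],
    }))

    # ---- exon profile of the focal gene ------------------------------------
    lo_bp, hi_bp = config.breakpoint_range
    breakpoints = np.full(n, -1)
    n_pos = int(fusion_true.sum())
    if n_pos:
        breakpoints[fusion_true] = rng.integers(lo_bp, hi_bp + 1, size=n_pos)
    myb_planted = MYB in gene_index
    myb_log2fc = np.log2(config.myb_fc) if myb_planted else 0.0
    exon_base = rng.normal(7.0, 0.5, size=config.exon_count)
    exon_pos = np.arange(1, config.exon_count + 1)
    exon_cols, exon_data = [], []
    for i in range(n):
        eps_en = rng.normal(0.0, config.noise_sd, size=config.exon_count)
        eps_et = rng.normal(0.0, config.noise_sd, size=config.exon_count)
        normal_vals = 2.0 ** (exon_base + patient_eff[i] + eps_en)
        if i == myb_low and myb_planted:
            delta = np.zeros(config.exon_count)
        elif fusion_true[i]:
            # retained 5' exons carry the full MYB induction; lost 3' exons only
            # the configured residual (wt/reciprocal allele expression)
            delta = np.where(exon_pos <= breakpoints[i], myb_log2fc, config.exon_delta3)
        else:
            delta = np.full(config.exon_count, myb_log2fc)
        exon_cols += [tumor_ids[i], normal_ids[i]]
        exon_data += [normal_vals * 2.0 ** (delta + eps_et), normal_vals]
    exon_profile = ExonIntensityProfile(
        MYB,
        pd.DataFrame(np.column_stack(exon_data),
                     index=[f"exon_{j:02d}" for j in range(1, config.exon_count + 1)],
                     columns=exon_cols),
        sheet=sheet,
    )

    # ---- miRNA matrix -------------------------------------------------------
    mlo, mhi = config.mirna_fc_range
    down_ids = ([MIR_150, MIR_29]
                + [f"hsa-miR-d{i:03d}" for i in range(1, config.n_mirna_down - 1)]
                if config.n_mirna_down else [])
    up_ids = [f"hsa-miR-u{i:03d}" for i in range(1, config.n_mirna_up + 1)]
    null_mi = [f"hsa-miR-n{i:03d}"
               for i in range(1, config.n_mirna - len(down_ids) - len(up_ids) + 1)]
    mirna_ids = down_ids + up_ids + null_mi

    fixed_mi = {MIR_150: 4.0, MIR_29: 2.5}
    mi_fc = np.array([fixed_mi.get(m, np.nan) for m in down_ids + up_ids])
    draw = np.isnan(mi_fc)
    mi_fc[draw] = rng.uniform(mlo, mhi, size=int(draw.sum()))
    mi_sign = np.array([-1.0] * len(down_ids) + [1.0] * len(up_ids))
    mi_base = np.concatenate([
        rng.normal(12.0, 0.5, size=len(down_ids) + len(up_ids)),
        rng.normal(10.5, 1.2, size=len(null_mi)),
    ])
    mi_effect = np.zeros((config.n_mirna, n))
    if len(mi_sign):
        mi_effect[: len(mi_sign), :] = (mi_sign * np.log2(mi_fc))[:, None]
    mi_basegrid = mi_base[:, None] + patient_eff[None, :]
    mi_norm = 2.0 ** (mi_basegrid + rng.normal(0.0, config.noise_sd, mi_basegrid.shape))
    mi_tum = 2.0 ** (mi_basegrid + mi_effect
                     + rng.normal(0.0, config.noise_sd, mi_basegrid.shape))
    mi_cols, mi_data = [], []
    for i in range(n):
        mi_cols += [tumor_ids[i], normal_ids[i]]
        mi_data += [mi_tum[:, i], mi_norm[:, i]]
    mirna = ExpressionMatrix(
        pd.DataFrame(np.column_stack(mi_data), index=mirna_ids, columns=mi_cols),
        scale="linear", assay="miRNA",
    )

    # ---- miRNA->target map and truth ----------------------------------------
    map_rows, inverse_rows = [], []
    if down_ids and myb_planted:
        map_rows += [(MIR_150, MYB), (MIR_29, "HAPLN1"), (MIR_29, null_genes[0])]
        inverse_rows += [(MIR_150, MYB), (MIR_29, "HAPLN1")]
        if up_ids:
            map_rows.append((up_ids[0], "VCAN"))  # same direction -> no link
        map_rows.append((null_mi[0], "UP_001"))   # miRNA not differential -> no link
    mirna_map = pd.DataFrame(map_rows, columns=["mirna_id", "target_gene"])

    truth = TruthTables(
        genes=genes,
        fusions=pd.DataFrame({
            "sample_id": tumor_ids,
            "status": np.where(fusion_true, "positive", "negative"),
            "breakpoint": [int(b) for b in breakpoints],
            "annotated": np.where(annotated, "positive", "negative"),
        }),
        myb_low_tumor=tumor_ids[myb_low] if myb_planted else "",
        mirnas=pd.DataFrame({
            "mirna_id": down_ids + up_ids,
            "direction": ["down"] * len(down_ids) + ["up"] * len(up_ids),
            "fold_change": mi_fc,
        }),
        inverse_pairs=pd.DataFrame(inverse_rows, columns=["mirna_id", "target_gene"]),
    )

    return Cohort(mrna=mrna, mirna=mirna, exon_profile=exon_profile, sheet=sheet,
                  truth=truth, gene_sets=_gene_sets(genes, null_genes),
                  mirna_map=mirna_map, mutations=_mutations(tumor_ids))


def generate_null_cohort(config: SimConfig | None = None, **overrides) -> Cohort:
    """Cohort with no planted effects: tumors and normals exchangeable per gene."""
    fields = asdict(config) if config is not None else {}
    fields.update(overrides)
    fields.update(n_signature_up=0, n_signature_down=0, n_fusion_pos=0,
                  n_myb_dependent=0, n_myb_associated=0,
                  n_mirna_down=0, n_mirna_up=0, n_mislabeled_negative=0)
    return generate_cohort(SimConfig(**fields))


def generate_exon_profile(status: str, breakpoint: int | None, delta5: float,
                          delta3: float, noise_sd: float, seed: int,
                          exon_count: int = 15,
                          baseline_log2: float = 7.0) -> ExonIntensityProfile:
    """One tumor/normal pair of exon intensities for the focal gene.

    For ``status="positive"`` the tumor is elevated over its matched normal by
    ``delta5`` log2 units on exons 1..breakpoint and by ``delta3`` after it;
    for ``status="negative"`` the single value ``delta5`` (= ``delta3``)
    applies across all exons.
    """
    if status not in ("positive", "negative"):
        raise ConfigError(f"status must be 'positive' or 'negative', got {status!r}")
    if status == "positive":
        if breakpoint is None:
            raise ConfigError("positive profiles need a breakpoint")
        if not (2 <= breakpoint <= exon_count - 1):
            raise ConfigError(f"breakpoint {breakpoint} outside [2, {exon_count - 1}]")
        if not delta5 > delta3:
            raise ConfigError("positive profiles require delta5 > delta3")
    else:
        if delta5 != delta3:
            raise ConfigError("negative profiles use a single delta (delta5 == delta3)")
        breakpoint = None
    rng = np.random.default_rng(seed)
    exon_base = rng.normal(baseline_log2, 0.5, size=exon_count)
    eps_n = rng.normal(0.0, noise_sd, size=exon_count)
    eps_t = rng.normal(0.0, noise_sd, size=exon_count)
    normal_vals = 2.0 ** (exon_base + eps_n)
    if breakpoint is not None:
        delta = np.where(np.arange(1, exon_count + 1) <= breakpoint, delta5, delta3)
    else:
        delta = np.full(exon_count, delta5)
    tumor_vals = normal_vals * 2.0 ** (delta + eps_t)
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": ["SIM_T", "SIM_N"],
        "patient_id": ["SIM", "SIM"],
        "tissue": ["tumor", "normal"],
        "subtype": ["ACC", "ACC"],
        "fusion_annotation": [status, "unknown"],
    }))
    return ExonIntensityProfile(
        "MYB",
        pd.DataFrame(np.column_stack([tumor_vals, normal_vals]),
                     index=[f"exon_{j:02d}" for j in range(1, exon_count + 1)],
                     columns=["SIM_T", "SIM_N"]),
        sheet=sheet,
    )
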