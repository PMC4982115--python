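"""Synthetic olfactory-epithelium study generator with planted ground truth.

The generator emulates the study design the pipeline analyzes: a handful of
olfactory-epithelium (OE) biopsies, one respiratory-epithelium sample, a
panel of control tissues, and a parallel mouse study sharing orthologs.
OR gene means are log-normal (intact above pseudogene), non-OR genes carry
planted overexpression and respiratory contamination, counts are
negative-binomial around FPKM, and every planted signal is recorded in a
truth object so downstream precision/recall is exactly computable.

Default parameter values encode the study conditions: intact OR median
~0.1 FPKM, a ~4x intact/pseudogene gap, a log10-sd of 0.71 for the human OR
rank curve (lognormal Lorenz half-fraction ~5%; the mouse configuration uses
0.40 for ~18%), ~90%/~60% intact/pseudogene expressed fractions, 4-vs-16
human design, fold-8 planted overexpression and dispersion 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .promoter import PWM
from .types import (
    CountMatrix,
    ExpressionMatrix,
    GeneCatalog,
    OlfscreenError,
    OrthologMap,
    TranscriptModel,
)

LN10 = math.log(10.0)

HUMAN_CONTROL_TISSUES = (
    "adipose", "brain", "heart", "kidney", "liver", "lung", "testis",
    "adrenal", "breast", "colon", "lymph", "ovary", "prostate",
    "skeletal_muscle", "thyroid", "blood")
MOUSE_CONTROL_TISSUES = (
    "adipose", "brain", "heart", "kidney", "liver", "lung", "testis",
    "spleen", "thymus", "intestine", "cerebellum")
SHARED_CONTROL_TISSUES = (
    "adipose", "brain", "heart", "kidney", "liver", "lung", "testis")

OLFACTORY_MARKERS = ("OMP", "CNGA2", "GNAL", "RTP1")
RESPIRATORY_MARKERS = ("KRT13", "TMPRSS11D")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 6000
    n_or_intact: int = 391
    n_or_pseudo: int = 466
    n_oe_samples: int = 4
    n_control_tissues: int = 16
    has_respiratory: bool = True
    # log10-FPKM gene-level means
    intact_logmean: float = -1.0
    pseudo_logmean: float = -1.0 - math.log10(4.0)
    logsd: float = 0.71            # OR gene-level spread (rank-curve skew)
    skew_shape: float = 1.0        # multiplier on logsd
    nonor_logmean: float = -0.3
    nonor_logsd: float = 0.9
    intact_silent_fraction: float = 0.10
    pseudo_silent_fraction: float = 0.40
    class_i_fraction: float = 0.15
    class_i_logdrop: float = 0.4   # class I ORs sit below class II
    segregating_fraction: float = 0.33
    ectopic_or_logdrop: float = math.log10(7.0)  # OR drop outside OE
    # planted overexpression
    n_planted_overexpressed: int = 50
    planted_fold: float = 8.0
    planted_logmean: float = 0.5
    planted_logsd: float = 0.5
    n_respiratory_contaminants: int = 10
    respiratory_leak_fraction: float = 0.0  # resp/OE mean for clean planted
    contaminant_leak_fraction: float = 0.5  # resp/OE mean for contaminants
    class_a_fraction: float = 36.0 / 196.0
    # sample-level noise: technical (depth-dependent) + biological floor,
    # plus an OR-specific inter-individual component set by or_pair_corr
    or_pair_corr: float = 0.35     # target OE-pair correlation, OR genes
    or_noise_cap: float = 0.6      # log10 cap on OR inter-individual noise
    bio_noise_sd: float = 0.12     # log10 biological floor, all genes
    tech_noise_cap: float = 1.2    # log10 cap on the technical component
    # between-tissue spread: most genes broad, a minority tissue-specific
    tissue_effect_sd: float = 0.15
    tissue_specific_fraction: float = 0.25
    tissue_specific_sd: float = 1.0
    # counts
    nb_dispersion: float = 0.1
    reads_per_fpkm: float = 30.0
    library_size_cv: float = 0.2
    library_sizes: tuple[float, ...] | None = None
    ortholog_fraction: float = 0.8
    control_tissues: tuple[str, ...] = HUMAN_CONTROL_TISSUES

    def __post_init__(self) -> None:
        n_special = (self.n_or_intact + self.n_or_pseudo
                     + self.n_planted_overexpressed
                     + self.n_respiratory_contaminants
                     + len(OLFACTORY_MARKERS) + len(RESPIRATORY_MARKERS))
        if n_special > self.n_genes:
            raise OlfscreenError(
                f"infeasible config: {n_special} special genes > "
                f"{self.n_genes} genes")
        if not self.planted_fold > 1:
            raise OlfscreenError("planted_fold must exceed 1")
        if self.n_control_tissues > len(self.control_tissues):
            raise OlfscreenError("not enough control tissue names")


def mouse_config(cfg: SimulationConfig) -> SimulationConfig:
    """Mouse companion study: shallower rank-curve skew (half-fraction ~18%),
    ~7x higher overall OR expression, wider intact/pseudogene gap, 3 OE
    samples, 11 control tissues, no respiratory sample."""
    return replace(
        cfg,
        seed=cfg.seed + 10_000,
        skew_shape=0.40 / cfg.logsd,
        intact_logmean=cfg.intact_logmean + math.log10(7.0),
        pseudo_logmean=cfg.intact_logmean + math.log10(7.0) - 1.0,
        intact_silent_fraction=0.05,
        pseudo_silent_fraction=0.30,
        or_pair_corr=0.95,  # mouse OE samples correlate ~0.95 across strains
        n_oe_samples=3,
        n_control_tissues=len(MOUSE_CONTROL_TISSUES),
        control_tissues=MOUSE_CONTROL_TISSUES,
        has_respiratory=False,
        n_respiratory_contaminants=0,
    )


@dataclass
class SimulationTruth:
    planted_overexpressed_gene_ids: list[str] = field(default_factory=list)
    planted_respiratory_contaminant_ids: list[str] = field(default_factory=list)
    planted_aberrant_transcript_ids: list[str] = field(default_factory=list)
    planted_motif_offset_range: tuple[int, int] | None = None
    group_linear_mean: pd.DataFrame | None = None  # gene x group mean FPKM
    noise_sd_log10: pd.Series | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class ExpressionStudy:
    expression: ExpressionMatrix  # unfloored FPKM
    counts: CountMatrix
    catalog: GeneCatalog
    orthologs: OrthologMap
    truth: SimulationTruth


def _mean_one_lognoise(rng: np.random.Generator, sd_log10: np.ndarray,
                       shape: tuple[int, ...]) -> np.ndarray:
    """Multiplicative log-normal noise with expectation exactly 1, so planted
    group-mean ratios are unbiased."""
    sd = np.broadcast_to(np.asarray(sd_log10)[:, None], shape)
    z = rng.standard_normal(shape)
    return np.exp(sd * z * LN10 - 0.5 * (sd * LN10) ** 2)


def _noise_sd_from_corr(gene_level_sd: float, pair_corr: float) -> float:
    """Per-sample log10 noise sd giving a target between-sample Pearson
    correlation over genes whose log-means have sd ``gene_level_sd``."""
    return gene_level_sd * math.sqrt((1.0 - pair_corr) / pair_corr)


def _gene_plan(cfg: SimulationConfig, rng: np.random.Generator,
               prefix: str) -> pd.DataFrame:
    """Lay out gene identities, OR annotations, planted roles and baseline
    log10 means (the OE-context gene-level mean)."""
    n_or = cfg.n_or_intact + cfg.n_or_pseudo
    n_markers = len(OLFACTORY_MARKERS) + len(RESPIRATORY_MARKERS)
    n_plain = (cfg.n_genes - n_or - cfg.n_planted_overexpressed
               - cfg.n_respiratory_contaminants - n_markers)

    rows = []
    for i in range(cfg.n_or_intact):
        rows.append((f"{prefix}ORI{i + 1:04d}", "intact"))
    for i in range(cfg.n_or_pseudo):
        rows.append((f"{prefix}ORP{i + 1:04d}", "pseudogene"))
    for sym in OLFACTORY_MARKERS:
        rows.append((f"{prefix}{sym}", "non_OR"))
    for sym in RESPIRATORY_MARKERS:
        rows.append((f"{prefix}{sym}", "non_OR"))
    for i in range(cfg.n_planted_overexpressed):
        rows.append((f"{prefix}OVX{i + 1:04d}", "non_OR"))
    for i in range(cfg.n_respiratory_contaminants):
        rows.append((f"{prefix}CONT{i + 1:04d}", "non_OR"))
    for i in range(n_plain):
        rows.append((f"{prefix}G{i + 1:06d}", "non_OR"))

    plan = pd.DataFrame(rows, columns=["gene_id", "or_status"]
                        ).set_index("gene_id")
    plan["symbol"] = [g[len(prefix):] for g in plan.index]
    plan["role"] = "none"
    plan.loc[plan.index.str.startswith(prefix + "OVX"), "role"] = "planted"
    plan.loc[plan.index.str.startswith(prefix + "CONT"), "role"] = "contaminant"
    for sym in OLFACTORY_MARKERS:
        plan.loc[prefix + sym, "role"] = "marker_olf"
    for sym in RESPIRATORY_MARKERS:
        plan.loc[prefix + sym, "role"] = "marker_resp"

    is_or = plan["or_status"] != "non_OR"
    n_or_total = int(is_or.sum())

    or_class = np.where(rng.random(n_or_total) < cfg.class_i_fraction, "I", "II")
    plan["or_class"] = pd.Series(np.nan, index=plan.index, dtype="object")
    plan.loc[is_or, "or_class"] = or_class
    plan["segregating_pseudogene"] = False
    plan.loc[is_or, "segregating_pseudogene"] = (
        rng.random(n_or_total) < cfg.segregating_fraction)

    # baseline gene-level log10 mean in the OE context
    or_sd = cfg.logsd * cfg.skew_shape
    mu = np.empty(len(plan))
    intact = (plan["or_status"] == "intact").values
    pseudo = (plan["or_status"] == "pseudogene").values
    classI = (plan["or_class"] == "I").values
    mu[intact] = cfg.intact_logmean + or_sd * rng.standard_normal(intact.sum())
    mu[pseudo] = cfg.pseudo_logmean + or_sd * rng.standard_normal(pseudo.sum())
    mu[classI] -= cfg.class_i_logdrop
    silent = np.zeros(len(plan), dtype=bool)
    silent[intact] = rng.random(intact.sum()) < cfg.intact_silent_fraction
    silent[pseudo] = rng.random(pseudo.sum()) < cfg.pseudo_silent_fraction
    mu[silent] = -5.0

    plain = (plan["role"] == "none").values & ~is_or.values
    mu[plain] = cfg.nonor_logmean + cfg.nonor_logsd * rng.standard_normal(plain.sum())
    planted = plan["role"].isin(["planted", "contaminant"]).values
    mu[planted] = cfg.planted_logmean + cfg.planted_logsd * rng.standard_normal(
        planted.sum())
    markers = plan["role"].isin(["marker_olf", "marker_resp"]).values
    mu[markers] = math.log10(0.5)  # baseline outside the marked tissue
    plan["mu"] = mu
    plan["silent"] = silent

    # functionality (CORP-like) score: intact high, pseudogene low
    score = np.full(len(plan), np.nan)
    score[intact] = np.clip(0.8 + 0.1 * rng.standard_normal(intact.sum()), 0, 1)
    score[pseudo] = np.clip(0.15 + 0.1 * rng.standard_normal(pseudo.sum()), 0, 1)
    plan["functionality_score"] = score

    # literature hits: a class-A-sized subset of planted genes has curated hits
    hits = np.full(len(plan), np.nan)
    pl = planted & (plan["role"] == "planted").values
    hits[pl] = np.where(rng.random(pl.sum()) < cfg.class_a_fraction,
                        1 + rng.poisson(4.0, pl.sum()), 0)
    cont = (plan["role"] == "contaminant").values
    hits[cont] = 0
    plan["literature_hits"] = hits

    # per-gene multiplicative noise sd on the log10 scale: technical noise
    # shrinks with expression (counting noise), all genes share a biological
    # floor, and OR genes carry extra inter-individual variability sized so
    # their between-sample correlation lands near or_pair_corr
    tech_var = np.minimum(
        1.0 / (cfg.reads_per_fpkm * 10.0 ** mu) / LN10 ** 2,
        cfg.tech_noise_cap ** 2)
    var = cfg.bio_noise_sd ** 2 + tech_var
    # extra OR variability toward the target pair correlation, capped so the
    # linear-scale moments stay finite-sample stable
    or_total = min(_noise_sd_from_corr(or_sd, cfg.or_pair_corr),
                   cfg.or_noise_cap) ** 2
    var[is_or.values] = np.clip(var[is_or.values], or_total,
                                cfg.or_noise_cap ** 2)
    plan["noise_sd"] = np.sqrt(var)

    # between-tissue spread: planted/marker genes are tissue-specific in the
    # OE sense only (flat across control tissues); a minority of plain genes
    # is strongly tissue-specific
    tau = np.full(len(plan), cfg.tissue_effect_sd)
    specific = plain & (rng.random(len(plan)) < cfg.tissue_specific_fraction)
    tau[specific] = cfg.tissue_specific_sd
    plan["tissue_sd"] = tau
    return plan


def _group_linear_means(cfg: SimulationConfig, rng: np.random.Generator,
                        plan: pd.DataFrame,
                        tissues: Sequence[str]) -> pd.DataFrame:
    """Per-group mean FPKM (gene x group).  Control-tissue effects are
    multiplicatively centered so the across-control mean equals the baseline."""
    base = 10.0 ** plan["mu"].values
    is_or = (plan["or_status"] != "non_OR").values
    role = plan["role"].values

    groups: dict[str, np.ndarray] = {}
    oe = base.copy()
    fold = cfg.planted_fold
    oe[role == "planted"] *= fold
    oe[role == "contaminant"] *= fold
    oe[role == "marker_olf"] = 30.0
    groups["OE"] = oe

    if cfg.has_respiratory:
        resp = base.copy()
        resp[is_or] = base[is_or] * 10.0 ** (-cfg.ectopic_or_logdrop)
        resp[role == "planted"] = oe[role == "planted"] * cfg.respiratory_leak_fraction
        resp[role == "contaminant"] = (
            oe[role == "contaminant"] * cfg.contaminant_leak_fraction)
        resp[role == "marker_resp"] = 30.0
        groups["respiratory"] = resp

    ctrl_base = base.copy()
    ctrl_base[is_or] *= 10.0 ** (-cfg.ectopic_or_logdrop)
    tau = plan["tissue_sd"].values[:, None]
    effects = 10.0 ** (tau * rng.standard_normal((len(plan), len(tissues))))
    effects /= effects.mean(axis=1, keepdims=True)
    for j, t in enumerate(tissues):
        groups[f"control:{t}"] = ctrl_base * effects[:, j]
    return pd.DataFrame(groups, index=plan.index)


def simulate_expression_study(cfg: SimulationConfig,
                              prefix: str = "") -> ExpressionStudy:
    """Generate FPKM + count matrices, catalog, ortholog stubs and truth."""
    rng = np.random.default_rng(cfg.seed)
    plan = _gene_plan(cfg, rng, prefix)
    tissues = list(cfg.control_tissues[: cfg.n_control_tissues])
    means = _group_linear_means(cfg, rng, plan, tissues)

    sample_groups: dict[str, str] = {}
    columns: list[str] = []
    for i in range(cfg.n_oe_samples):
        name = f"{prefix}OE{i + 1}"
        sample_groups[name] = "OE"
        columns.append(name)
    if cfg.has_respiratory:
        name = f"{prefix}resp"
        sample_groups[name] = "respiratory"
        columns.append(name)
    for t in tissues:
        name = f"{prefix}{t}"
        sample_groups[name] = f"control:{t}"
        columns.append(name)

    sd = plan["noise_sd"].values
    values = np.empty((len(plan), len(columns)))
    for j, s in enumerate(columns):
        group_mean = means[sample_groups[s]].values
        values[:, j] = group_mean * _mean_one_lognoise(
            rng, sd, (len(plan), 1))[:, 0]
    fpkm = pd.DataFrame(values, index=plan.index, columns=columns)

    if cfg.library_sizes is not None:
        libs = np.asarray(cfg.library_sizes, dtype=float)
        if libs.shape[0] != len(columns):
            raise OlfscreenError("library_sizes length != number of samples")
    else:
        libs = np.exp(cfg.library_size_cv * rng.standard_normal(len(columns))
                      - 0.5 * cfg.library_size_cv ** 2)
    count_mean = values * (libs * cfg.reads_per_fpkm)[None, :]
    counts = _nb_counts(rng, count_mean, cfg.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=plan.index, columns=columns)

    catalog = GeneCatalog(pd.DataFrame({
        "symbol": plan["symbol"],
        "or_status": plan["or_status"],
        "or_class": plan["or_class"],
        "segregating_pseudogene": plan["segregating_pseudogene"],
        "ortholog_id": pd.Series(np.nan, index=plan.index, dtype="object"),
        "literature_hits": plan["literature_hits"],
        "functionality_score": plan["functionality_score"],
    }, index=plan.index))

    truth = SimulationTruth(
        planted_overexpressed_gene_ids=list(
            plan.index[plan["role"] == "planted"]),
        planted_respiratory_contaminant_ids=list(
            plan.index[plan["role"] == "contaminant"]),
        group_linear_mean=means,
        noise_sd_log10=plan["noise_sd"],
        extras={"library_sizes": dict(zip(columns, libs)),
                "silent": plan["silent"], "plan": plan},
    )
    return ExpressionStudy(
        expression=ExpressionMatrix(fpkm, sample_groups),
        counts=CountMatrix(counts_df, sample_groups),
        catalog=catalog, orthologs=OrthologMap({}), truth=truth)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Gamma-Poisson counts with Var = m + dispersion * m^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(1.0 / dispersion, dispersion * np.maximum(mean, 1e-300))
    return rng.poisson(lam)


@dataclass
class PairedStudy:
    human: ExpressionStudy
    mouse: ExpressionStudy
    orthologs: OrthologMap


def simulate_paired_study(cfg: SimulationConfig,
                          mcfg: SimulationConfig | None = None,
                          planted_overlap: float = 0.7) -> PairedStudy:
    """Human study plus an independent mouse study sharing orthologs.

    A ``planted_overlap`` fraction of the human planted overexpressed genes
    is also planted in mouse (through the ortholog map), exercising the
    mouse-concordance rescue rule; the remainder of the mouse planted set is
    mouse-specific.
    """
    if mcfg is None:
        mcfg = mouse_config(cfg)
    human = simulate_expression_study(cfg, prefix="")
    mouse = simulate_expression_study(mcfg, prefix="m")

    rng = np.random.default_rng(cfg.seed + 777)
    planted = human.truth.planted_overexpressed_gene_ids
    mouse_ids = set(mouse.catalog.gene_ids)
    mouse_plain = [g for g in mouse.catalog.gene_ids
                   if mouse.truth.extras["plan"].loc[g, "role"] == "none"
                   and mouse.truth.extras["plan"].loc[g, "or_status"] == "non_OR"]
    pairs = {}
    for g in human.catalog.gene_ids:
        mg = "m" + g
        if g in planted:
            continue
        if mg in mouse_ids and rng.random() < cfg.ortholog_fraction:
            pairs[g] = mg
    # planted wiring: the first n_shared human planted genes keep their
    # mouse-planted counterpart (concordant, rescueable); the rest are paired
    # with unplanted mouse genes (discordant orthologs)
    n_shared = int(round(planted_overlap * len(planted)))
    for i, g in enumerate(planted):
        if i < n_shared:
            pairs[g] = "m" + g
        else:
            pairs[g] = mouse_plain[i]
    orthologs = OrthologMap(pairs)
    human.catalog.table["ortholog_id"] = [
        pairs.get(g, np.nan) for g in human.catalog.gene_ids]
    human.orthologs = orthologs
    mouse.truth.extras["shared_planted_human_ids"] = planted[:n_shared]
    return PairedStudy(human=human, mouse=mouse, orthologs=orthologs)


# ---------------------------------------------------------------------------
# focused helpers for calibration studies

def simulate_null_counts(n_genes: int, n_a: int, n_b: int,
                         mean: float = 50.0, dispersion: float = 0.1,
                         seed: int = 0) -> CountMatrix:
    """Two-group count matrix with no differential expression."""
    rng = np.random.default_rng(seed)
    mean_per_gene = mean * 10.0 ** (0.4 * rng.standard_normal(n_genes))
    m = np.repeat(mean_per_gene[:, None], n_a + n_b, axis=1)
    counts = _nb_counts(rng, m, dispersion)
    cols = [f"A{i + 1}" for i in range(n_a)] + [f"B{i + 1}" for i in range(n_b)]
    groups = {c: ("A" if c.startswith("A") else "B") for c in cols}
    df = pd.DataFrame(counts, columns=cols,
                      index=[f"g{i + 1}" for i in range(n_genes)])
    return CountMatrix(df, groups)


def simulate_sample_pair(n_target: int, n_pool: int,
                         target_corr: float, pool_corr: float,
                         seed: int = 0,
                         target_logmean: float = -1.0,
                         target_logsd: float = 0.71,
                         pool_logmean: float = -0.3,
                         pool_logsd: float = 0.9
                         ) -> tuple[ExpressionMatrix, list[str], list[str]]:
    """Two same-tissue samples with a target set whose between-sample
    correlation differs from the pool's (the inter-individual setting).
    With ``target_* == pool_*`` the target set is exchangeable with the pool
    (a null dataset)."""
    rng = np.random.default_rng(seed)
    ids_t = [f"T{i + 1:05d}" for i in range(n_target)]
    ids_p = [f"P{i + 1:05d}" for i in range(n_pool)]
    mu = np.concatenate([
        target_logmean + target_logsd * rng.standard_normal(n_target),
        pool_logmean + pool_logsd * rng.standard_normal(n_pool)])
    sd = np.concatenate([
        np.full(n_target, _noise_sd_from_corr(target_logsd, target_corr)),
        np.full(n_pool, _noise_sd_from_corr(pool_logsd, pool_corr))])
    vals = 10.0 ** (mu[:, None] + sd[:, None]
                    * rng.standard_normal((n_target + n_pool, 2)))
    df = pd.DataFrame(vals, index=ids_t + ids_p, columns=["S1", "S2"])
    m = ExpressionMatrix(df, {"S1": "OE", "S2": "OE"})
    return m, ids_t, ids_p


# ---------------------------------------------------------------------------
# transcript-model generator

@dataclass
class TranscriptSimConfig:
    seed: int = 0
    n_genes: int = 100
    aberrant_fraction: float = 0.1
    orf_length: int = 940
    utr3_mean: float = 2777.0
    utr3_sd: float = 1000.0
    utr3_min: int = 100
    utr5_exon_range: tuple[int, int] = (60, 200)
    n_utr5_exons_range: tuple[int, int] = (0, 3)
    intron_range: tuple[int, int] = (500, 5000)
    max_isoforms: int = 5
    minus_strand_fraction: float = 0.5
    low_fpkm_fraction: float = 0.1       # isoforms planted below 1.0 FPKM
    low_fraction_genes: int = 2          # genes with a <0.15%-of-major isoform
    bad_class_code_fraction: float = 0.05
    gene_spacing: int = 200_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.aberrant_fraction <= 1.0:
            raise OlfscreenError("aberrant_fraction must be in [0, 1]")


def simulate_transcript_models(
        cfg: TranscriptSimConfig) -> tuple[list[TranscriptModel], SimulationTruth]:
    """OR-like transcript models: 0-3 short 5' non-coding exons, one long
    last exon holding the whole ORF plus the 3' UTR, 1-5 isoforms per gene.

    Aberrant isoforms start downstream of the ORF start (their exon union
    excludes the initiating codon), mimicking splice-driven pseudogenization.
    Low-FPKM, low-isoform-fraction and bad-class-code transcripts are planted
    so curation outcomes are known.
    """
    rng = np.random.default_rng(cfg.seed)
    models: list[TranscriptModel] = []
    truth = SimulationTruth()
    aberrant_ids: list[str] = []
    low_fpkm_ids: list[str] = []
    low_fraction_ids: list[str] = []
    bad_code_ids: list[str] = []
    gene_class: dict[str, str] = {}

    n_aberrant_genes = int(round(cfg.aberrant_fraction * cfg.n_genes))
    aberrant_genes = set(
        rng.choice(cfg.n_genes, size=n_aberrant_genes, replace=False).tolist())
    low_frac_genes = set(
        rng.choice(cfg.n_genes, size=min(cfg.low_fraction_genes, cfg.n_genes),
                   replace=False).tolist())

    for g in range(cfg.n_genes):
        gene_id = f"ORG{g + 1:04d}"
        origin = g * cfg.gene_spacing + 10_000
        minus = rng.random() < cfg.minus_strand_fraction
        # plus-strand layout first; reflect at the end if minus
        n5 = int(rng.integers(cfg.n_utr5_exons_range[0],
                              cfg.n_utr5_exons_range[1] + 1))
        utr5_exons: list[tuple[int, int]] = []
        pos = origin
        for _ in range(n5):
            elen = int(rng.integers(*cfg.utr5_exon_range))
            utr5_exons.append((pos, pos + elen))
            pos += elen + int(rng.integers(*cfg.intron_range))
        u_last = int(rng.integers(0, 120))  # 5'UTR tail inside the last exon
        utr3 = max(cfg.utr3_min,
                   int(rng.normal(cfg.utr3_mean, cfg.utr3_sd)))
        last_exon = (pos, pos + u_last + cfg.orf_length + utr3)
        cds = (pos + u_last, pos + u_last + cfg.orf_length)

        n_iso = int(rng.integers(1, cfg.max_isoforms + 1))
        major_fpkm = float(10.0 ** rng.normal(0.8, 0.3))
        in_low_frac = g in low_frac_genes
        if in_low_frac:
            major_fpkm = 1000.0
        gene_aberrant = g in aberrant_genes
        flags: list[bool] = []
        for k in range(n_iso):
            tx_id = f"{gene_id}.{k + 1}"
            make_aberrant = gene_aberrant and (k == n_iso - 1)
            if make_aberrant:
                d = int(rng.integers(50, cfg.orf_length - 200))
                exons = [(cds[0] + d, last_exon[1])]
            else:
                n_use = int(rng.integers(0, n5 + 1)) if n5 else 0
                exons = utr5_exons[n5 - n_use:] + [last_exon]
            if k == 0:
                fpkm = major_fpkm
            elif in_low_frac and k == 1:
                fpkm = 1.2  # >=1 FPKM but <0.15% of the 1000-FPKM major
            else:
                fpkm = major_fpkm * float(10.0 ** rng.normal(-0.5, 0.3))
            class_code = None
            if rng.random() < cfg.bad_class_code_fraction and k > 0:
                class_code = str(rng.choice(["x", "s", "p"]))
                bad_code_ids.append(tx_id)
            elif fpkm < 1.0:
                low_fpkm_ids.append(tx_id)
            if rng.random() < cfg.low_fpkm_fraction and k > 0 and fpkm >= 1.0 \
                    and class_code is None:
                fpkm = float(rng.uniform(0.2, 0.95))
                low_fpkm_ids.append(tx_id)
            if in_low_frac and k == 1 and class_code is None:
                low_fraction_ids.append(tx_id)
            if minus:
                M = 2 * origin + cfg.gene_spacing
                exons = sorted((M - b, M - a) for a, b in exons)
                cds_out = (M - cds[1], M - cds[0])
            else:
                cds_out = cds
            # aberrant isoforms do not carry a CDS of their own; the gene's
            # ORF interval travels in the truth's gene_cds map instead
            model = TranscriptModel(
                transcript_id=tx_id, gene_id=gene_id, chrom="chrSim",
                strand="-" if minus else "+", exons=exons,
                cds=None if make_aberrant else cds_out,
                fpkm=fpkm, class_code=class_code)
            models.append(model)
            gene_cds_map = truth.extras.setdefault("gene_cds", {})
            gene_cds_map[gene_id] = cds_out
            if make_aberrant:
                aberrant_ids.append(tx_id)
            flags.append(not make_aberrant)
        if all(flags):
            gene_class[gene_id] = "all_functional"
        elif any(flags):
            gene_class[gene_id] = "mixed"
        else:
            gene_class[gene_id] = "all_aberrant"

    truth.planted_aberrant_transcript_ids = aberrant_ids
    truth.extras.update({
        "low_fpkm_transcripts": low_fpkm_ids,
        "low_fraction_transcripts": low_fraction_ids,
        "bad_class_code_transcripts": bad_code_ids,
        "gene_class": gene_class,
        "orf_length": cfg.orf_length,
    })
    return models, truth


# ---------------------------------------------------------------------------
# promoter-sequence generator

def simulate_promoters(n_promoters: int, motif: PWM,
                       offset_range: tuple[int, int] = (100, 300),
                       background_gc: float = 0.4,
                       seed: int = 0,
                       seq_length: int = 4000,
                       plant: bool = True
                       ) -> tuple[dict[str, str], SimulationTruth]:
    """Promoter sequences with the TSS at the 3' end of each sequence.

    Each promoter receives one planted motif instance (sampled from the PWM)
    whose 5'-most base lies a uniform-random distance inside ``offset_range``
    upstream of the TSS; the background is i.i.d. with the stated GC content.
    """
    if motif.length > seq_length:
        raise OlfscreenError("motif longer than promoter sequence")
    lo, hi = offset_range
    if plant and not (motif.length <= lo <= hi <= seq_length):
        raise OlfscreenError("offset_range must fit inside the sequence")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - background_gc) / 2, background_gc / 2,
                  background_gc / 2, (1 - background_gc) / 2])
    seqs: dict[str, str] = {}
    offsets: dict[str, int] = {}
    bases = np.array(list("ACGT"))
    for i in range(n_promoters):
        name = f"prom{i + 1:04d}"
        seq = bases[rng.choice(4, size=seq_length, p=p)]
        if plant:
            d = int(rng.integers(lo, hi + 1))
            start = seq_length - d
            inst = motif.sample(rng)
            seq[start:start + motif.length] = list(inst)
            offsets[name] = d
        seqs[name] = "".join(seq)
    truth = SimulationTruth(
        planted_motif_offset_range=(lo, hi) if plant else None,
        extras={"planted_offsets": offsets, "background_gc": background_gc})
    return seqs, truth
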