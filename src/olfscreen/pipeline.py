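"""End-to-end stage orchestration over simulated (or user-supplied) data.

Stages: simulate -> qc / screen / repertoire / interindividual and the
independent structure and promoter stages.  Every stage writes TSV outputs
plus a manifest (seed, config hash, stages, files) so a run is fully
reconstructible; deterministic stages reproduce byte-identical outputs under
the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as oio
from . import qc as oqc
from .interindividual import (
    ResamplingConfig,
    default_control_pool,
    resampling_test,
)
from .promoter import (
    DEFAULT_PROFILE_BP,
    default_threshold,
    ebf_like_pwm,
    motif_enrichment,
    positional_profile,
    scan_pwm,
)
from .repertoire import repertoire_summary, class_comparison
from .screen import ScreenConfig, mouse_significance, run_screen, screen_table
from .simulate import (
    SimulationConfig,
    TranscriptSimConfig,
    simulate_paired_study,
    simulate_promoters,
    simulate_transcript_models,
)
from .structure import (
    CurationConfig,
    curate_transcripts,
    detect_aberrant,
    length_summary,
    structure_table,
)
from .types import OlfscreenError

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "qc", "screen", "repertoire", "interindividual",
              "structure", "promoter")
_NEEDS_STUDY = ("qc", "screen", "repertoire", "interindividual")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results"
    simulation: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    resampling_iterations: int = 10_000
    n_interindividual_pairs: int = 3
    curation: dict = field(default_factory=dict)
    transcript_sim: dict = field(default_factory=dict)
    n_promoters: int = 100
    n_background_promoters: int = 200
    motif_offset_range: tuple[int, int] = (100, 300)
    profile_bin_bp: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise OlfscreenError(f"unknown config keys: {sorted(unknown)}")
        if "motif_offset_range" in data:
            data["motif_offset_range"] = tuple(data["motif_offset_range"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig,
                 stages: Sequence[str] | None = None) -> dict:
    """Run the requested stages in order; returns the in-memory state.

    Raises a named error when a stage's dependency was not produced by an
    earlier stage in the same run.
    """
    stages = list(stages) if stages is not None else list(ALL_STAGES)
    for st in stages:
        if st not in ALL_STAGES:
            raise OlfscreenError(f"unknown stage {st!r}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {"files": []}
    manifest = {"seed": cfg.seed, "config_hash": cfg.config_hash(),
                "config": dataclasses.asdict(cfg), "stages": [],
                "timings_s": {}}

    for stage in stages:
        if stage in _NEEDS_STUDY and "human" not in state:
            raise OlfscreenError(
                f"stage {stage!r} requires the expression study: run "
                f"'simulate' first (missing human expression matrix)")
        t0 = time.perf_counter()
        _STAGE_FUNCS[stage](cfg, state, out)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        manifest["stages"].append(stage)
        logger.info("stage %s done (%.2fs)", stage, manifest["timings_s"][stage])

    manifest["files"] = state["files"]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    state["manifest"] = manifest
    return state


def _write(state: dict, df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", **kwargs)
    state["files"].append(str(path))


def _stage_simulate(cfg: PipelineConfig, state: dict, out: Path) -> None:
    sim_cfg = SimulationConfig(seed=cfg.seed, **cfg.simulation)
    paired = simulate_paired_study(sim_cfg)
    state["paired"] = paired
    state["human"] = paired.human
    state["mouse"] = paired.mouse
    state["human_floored"] = oio.apply_fpkm_floor(paired.human.expression)
    state["mouse_floored"] = oio.apply_fpkm_floor(paired.mouse.expression)
    for species in ("human", "mouse"):
        study = state[species]
        oio.write_expression_table(study.expression, out / f"{species}_fpkm.tsv")
        oio.write_count_table(study.counts, out / f"{species}_counts.tsv")
        oio.write_gene_catalog(study.catalog, out / f"{species}_catalog.tsv")
        state["files"] += [str(out / f"{species}_{n}.tsv")
                           for n in ("fpkm", "counts", "catalog")]
    oio.write_ortholog_map(paired.orthologs, out / "orthologs.tsv")
    state["files"].append(str(out / "orthologs.tsv"))


def _stage_qc(cfg: PipelineConfig, state: dict, out: Path) -> None:
    m = state["human_floored"]
    panel = oqc.MarkerPanel()
    rows = []
    for s in m.sample_ids:
        rows.append({
            "sample": s, "group": m.sample_groups[s],
            "marker_score": oqc.marker_qc_score(m, panel, s),
            "passes": oqc.marker_qc_pass(m, panel, s)})
    _write(state, pd.DataFrame(rows).set_index("sample"),
           out / "qc_marker_scores.tsv")
    subset = oqc.genes_expressed_everywhere(m)
    corr = oqc.tissue_correlation_matrix(m, subset)
    state["correlation"] = corr
    _write(state, corr, out / "qc_tissue_correlation.tsv")


def _stage_screen(cfg: PipelineConfig, state: dict, out: Path) -> None:
    sc = ScreenConfig(**cfg.screen)
    mouse_records = run_screen(
        state["mouse_floored"], state["mouse"].counts, state["mouse"].catalog,
        state["paired"].orthologs, mouse_screen=None, cfg=sc)
    human_records = run_screen(
        state["human_floored"], state["human"].counts,
        state["human"].catalog, state["paired"].orthologs,
        mouse_screen=mouse_significance(mouse_records), cfg=sc)
    state["screen_records"] = human_records
    state["mouse_screen_records"] = mouse_records
    _write(state, screen_table(human_records), out / "screen_human.tsv")
    _write(state, screen_table(mouse_records), out / "screen_mouse.tsv")


def _stage_repertoire(cfg: PipelineConfig, state: dict, out: Path) -> None:
    rows = []
    for species in ("human", "mouse"):
        m = state[f"{species}_floored"]
        catalog = state[species].catalog
        oe = m.samples_in_group("OE")
        for label, cat in (("all", catalog),
                           ("no_segregating", catalog.without_segregating())):
            summ = repertoire_summary(m, cat, oe)
            rows.append({
                "species": species, "gene_set": label,
                "expressed_fraction_intact": summ.expressed_fraction_intact,
                "expressed_fraction_pseudo": summ.expressed_fraction_pseudo,
                "mean_fpkm_intact": summ.mean_fpkm_by_status["intact"][0],
                "mean_fpkm_pseudo": summ.mean_fpkm_by_status["pseudogene"][0],
                "ks_p_intact_vs_pseudo": summ.ks_p_intact_vs_pseudo,
                "half_fraction": summ.half_fraction})
            if label == "all":
                state[f"repertoire_{species}"] = summ
                _write(state, summ.rank_curve,
                       out / f"repertoire_rank_{species}.tsv", index=False)
                _write(state, summ.cumulative_curve,
                       out / f"repertoire_cumulative_{species}.tsv",
                       index=False)
        cc = class_comparison(m, catalog, oe)
        rows[-2]["class_chi2_p"] = cc["chi2_p"]
        rows[-2]["class_ks_p"] = cc["ks_p"]
    _write(state, pd.DataFrame(rows), out / "repertoire_summary.tsv",
           index=False)
    state["repertoire_table"] = pd.DataFrame(rows)


def _stage_interindividual(cfg: PipelineConfig, state: dict,
                           out: Path) -> None:
    m = state["human_floored"]
    catalog = state["human"].catalog
    oe = m.samples_in_group("OE")
    or_all = [g for g in catalog.or_genes if g in m.gene_ids]
    # ORs expressed in all OE samples, mirroring the tested subset
    sub = m.values.loc[or_all, oe]
    or_genes = list(sub.index[(sub >= 0.01).all(axis=1)])
    rows = []
    rcfg_base = ResamplingConfig(n_iterations=cfg.resampling_iterations,
                                 seed=cfg.seed)
    pairs = [(a, b) for i, a in enumerate(oe) for b in oe[i + 1:]]
    for k, (a, b) in enumerate(pairs[: cfg.n_interindividual_pairs]):
        pool = default_control_pool(m, catalog.or_genes, [a, b])
        rcfg = dataclasses.replace(rcfg_base, seed=cfg.seed + 31 * k + 1)
        outc = resampling_test(m, or_genes, pool, a, b, rcfg)
        rows.append({
            "sample_a": a, "sample_b": b, "observed_r": outc.observed_r,
            "null_r_mean": float(np.mean(outc.null_rs)),
            "empirical_p": outc.empirical_p, "p_string": outc.p_string,
            "n_genes": outc.n_matched_genes})
        if k == 0:
            state["resampling_outcome"] = outc
            pd.Series(outc.null_rs).to_csv(
                out / "interindividual_null_rs.tsv", sep="\t",
                index=False, header=["null_r"])
            state["files"].append(str(out / "interindividual_null_rs.tsv"))
    state["interindividual_table"] = pd.DataFrame(rows)
    _write(state, state["interindividual_table"],
           out / "interindividual.tsv", index=False)


def _stage_structure(cfg: PipelineConfig, state: dict, out: Path) -> None:
    tcfg = TranscriptSimConfig(seed=cfg.seed + 101, **cfg.transcript_sim)
    models, truth = simulate_transcript_models(tcfg)
    oio.write_transcript_models(models, out / "transcripts.gtf")
    state["files"].append(str(out / "transcripts.gtf"))
    kept, removed = curate_transcripts(models, CurationConfig(**cfg.curation))
    audit = pd.DataFrame(
        [{"transcript_id": t.transcript_id, "reason": reason}
         for t, reason in removed]).set_index("transcript_id") \
        if removed else pd.DataFrame(columns=["reason"])
    _write(state, audit, out / "curation_audit.tsv")
    table = structure_table(kept, truth.extras["gene_cds"])
    functional, gene_class = detect_aberrant(kept, truth.extras["gene_cds"])
    table["aberrant"] = [not functional.get(t, True) for t in table.index]
    _write(state, table, out / "structure_records.tsv")
    state["structure_models"] = models
    state["structure_kept"] = kept
    state["structure_truth"] = truth
    state["structure_table"] = table
    state["structure_summary"] = length_summary(table)
    state["gene_class"] = gene_class


def _stage_promoter(cfg: PipelineConfig, state: dict, out: Path) -> None:
    pwm = ebf_like_pwm()
    thr = default_threshold(pwm)
    seqs, truth = simulate_promoters(
        cfg.n_promoters, pwm, offset_range=cfg.motif_offset_range,
        seed=cfg.seed + 202)
    bg, _ = simulate_promoters(
        cfg.n_background_promoters, pwm, seed=cfg.seed + 203, plant=False)
    hits = []
    for name, seq in seqs.items():
        hits.extend(scan_pwm(seq, pwm, thr, tss_index=len(seq),
                             window_id=name))
    profile = positional_profile(hits, DEFAULT_PROFILE_BP, cfg.profile_bin_bp)
    prof_df = pd.DataFrame({
        "upstream_bp_lo": np.arange(len(profile)) * cfg.profile_bin_bp,
        "upstream_bp_hi": (np.arange(len(profile)) + 1) * cfg.profile_bin_bp,
        "hits": profile})
    _write(state, prof_df, out / "promoter_profile.tsv", index=False)
    odds, p = motif_enrichment(list(seqs.values()), list(bg.values()),
                               pwm, thr)
    state["promoter_truth"] = truth
    state["promoter_hits"] = hits
    state["promoter_profile"] = profile
    state["promoter_enrichment"] = {"odds_ratio": odds, "p": p}
    with open(out / "promoter_enrichment.json", "w") as fh:
        json.dump(state["promoter_enrichment"], fh, indent=2)
    state["files"].append(str(out / "promoter_enrichment.json"))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "screen": _stage_screen,
    "repertoire": _stage_repertoire,
    "interindividual": _stage_interindividual,
    "structure": _stage_structure,
    "promoter": _stage_promoter,
}
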