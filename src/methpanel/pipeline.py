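"""End-to-end pipeline: simulate, digest, screen, design, call, evaluate.

Each stage delegates to the corresponding module; this file only wires them
together so the analysis drivers, the tests and the acceptance script run
the identical computation. The returned report dictionary is JSON-ready and
validates against the shipped report schema.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assay, classify, msre, rrbs, screen, simulate
from .config import PipelineConfig


def build_reference(cfg: PipelineConfig) -> simulate.ReferenceSequence:
    return simulate.generate_reference(
        n_islands=cfg.n_islands,
        island_len=cfg.island_len,
        inter_island_len=cfg.inter_island_len,
        xmai_density=cfg.xmai_density,
        bsthhi_density=cfg.bsthhi_density,
        seed=cfg.stage_seed("reference"),
    )


def build_library(cfg: PipelineConfig, ref: simulate.ReferenceSequence):
    """XmaI digest + size selection + assayed-CpG enumeration."""
    frags = rrbs.size_select(
        rrbs.digest(ref), min_len=cfg.min_fragment_len, max_len=cfg.max_fragment_len
    )
    assayed = rrbs.enumerate_cpgs(frags, ref)
    return frags, assayed


def build_cohort(cfg: PipelineConfig, ref, assayed):
    specs = simulate.default_marker_specs(ref, n_markers=cfg.n_markers)
    cohort_cfg = simulate.CohortConfig(
        n_responders=cfg.n_responders,
        n_nonresponders=cfg.n_nonresponders,
        marker_specs=specs,
        n_background_cpgs=cfg.n_background_cpgs,
        enrichment=cfg.enrichment,
        missing_rate=cfg.missing_rate,
        seed=cfg.stage_seed("cohort"),
    )
    betas, ann = simulate.generate_cohort(ref, cohort_cfg, positions=assayed)
    return betas, ann, specs


def screen_markers(cfg: PipelineConfig, betas, ann, ref):
    sig = screen.differential_cpgs(betas, ann, alpha=cfg.alpha)
    sig_tss = screen.filter_tss(sig, ref, window=cfg.tss_window)
    sample_labels, sample_summary = screen.cluster_samples(betas, ann, k=2)
    dendro = screen.cluster_cpgs(
        betas.loc[[(c, p) for c, p in zip(sig_tss["chrom"], sig_tss["pos"])]]
    ) if len(sig_tss) >= 2 else None
    return sig_tss, sample_summary, dendro


def design_assays(cfg: PipelineConfig, ref, specs, margin: int = 150):
    """Best MSRE-PCR amplicon per marker TSS region (or None)."""
    designs = {}
    for gene, _f_pr, _f_sd in specs:
        t = ref.tss_position(gene)
        lo = max(0, t - margin)
        region = ref.seq[lo : t + margin]
        found = msre.find_amplicons(
            region,
            min_sites=cfg.min_sites,
            max_product_len=cfg.max_product_len,
            min_clear_flank=cfg.min_clear_flank,
        )
        designs[gene] = found[0] if found else None
    return designs


def run_assay(cfg: PipelineConfig, betas, ref, specs):
    """Platform transfer: binarize marker betas with flip noise, then push
    the calls through simulated lane readings (with rare control failures)
    and the control-aware caller."""
    marker_pos = {(ref.name, ref.tss_position(g)): g for g, _a, _b in specs}
    marker_rows = [key for key in betas.index if tuple(key) in marker_pos]
    marker_betas = betas.loc[marker_rows]
    truth = simulate.degrade_to_binary_calls(
        marker_betas, call_threshold=cfg.call_threshold, flip_prob=0.0,
        seed=0, loci=marker_pos,
    )
    noisy = simulate.degrade_to_binary_calls(
        marker_betas, call_threshold=cfg.call_threshold, flip_prob=cfg.flip_prob,
        seed=cfg.stage_seed("calls"), loci=marker_pos,
    )
    rng = np.random.default_rng(cfg.stage_seed("assay"))
    readings = {}
    for s in noisy.columns:
        readings[s] = assay.LaneReading(
            digested_bands={g: bool(noisy.at[g, s] == simulate.METHYLATED) for g in noisy.index},
            mock_bands={g: True for g in noisy.index},
            dc_digested=bool(rng.random() < cfg.control_fail_prob),
            pc_present=not bool(rng.random() < cfg.control_fail_prob),
        )
    calls, qc = assay.call_matrix(readings)
    calls = calls[list(noisy.columns)]
    # cross-platform concordance: MSRE-PCR calls against sequencing-derived
    # binary truth, over cells valid on both platforms
    both = (calls.to_numpy() != simulate.INVALID) & (truth.loc[calls.index].to_numpy() != simulate.INVALID)
    scores = calls.to_numpy()[both].astype(float)
    labels = truth.loc[calls.index].to_numpy()[both].astype(bool)
    concordance_auc = classify.auc_mann_whitney(scores, labels)
    return truth, calls, qc, float(concordance_auc)


def evaluate(cfg: PipelineConfig, calls, ann):
    cv_seed = cfg.stage_seed("cv")
    cv_params = {"repeats": cfg.cv_repeats, "folds": cfg.cv_folds, "seed": cv_seed}
    stats = classify.marker_stats(calls, ann, cv_params=cv_params, positive=cfg.positive_class)
    groups, pca, _z = classify.independence_groups(calls, k=2)
    candidates = (
        stats["delta"].abs().sort_values(ascending=False).index[: cfg.n_combo_candidates]
    )
    reports = classify.combo_search(
        calls, ann, list(candidates), max_size=cfg.max_combo_size,
        repeats=cfg.cv_repeats, folds=cfg.cv_folds, seed=cv_seed,
        positive=cfg.positive_class, groups=groups, cross_group_only=False,
    )
    best = reports[0]
    x, y, _ = classify._design_from_calls(calls, ann, best.combo, cfg.positive_class)
    fit = classify.fit_logistic(
        x, y, terms=list(best.combo), raise_on_failure=False
    )
    return stats, groups, pca, reports, best, fit


def run_pipeline(cfg: PipelineConfig | None = None) -> dict:
    """Run every stage and return the JSON-ready report."""
    cfg = cfg or PipelineConfig()
    ref = build_reference(cfg)
    frags, assayed = build_library(cfg, ref)
    betas, ann, specs = build_cohort(cfg, ref, assayed)
    sig_tss, sample_summary, _dendro = screen_markers(cfg, betas, ann, ref)
    marker_positions = {ref.tss_position(g) for g, _a, _b in specs}
    recovered = sorted(
        set(sig_tss.loc[sig_tss["pos"].isin(marker_positions), "gene"])
    )
    designs = design_assays(cfg, ref, specs)
    truth, calls, qc, concordance_auc = run_assay(cfg, betas, ref, specs)
    stats, groups, pca, reports, best, fit = evaluate(cfg, calls, ann)

    return {
        "seed": cfg.seed,
        "reference": {
            "length": len(ref.seq),
            "n_islands": len(ref.islands),
            "n_tss": len(ref.tss),
        },
        "library": {
            "n_fragments_selected": len(frags),
            "n_assayed_cpgs": len(assayed),
        },
        "screen": {
            "n_significant_tss_cpgs": int(len(sig_tss)),
            "markers_recovered": recovered,
            "n_markers_recovered": len(recovered),
            "sample_clusters": sample_summary.to_dict(orient="records"),
        },
        "designs": {
            gene: (
                None
                if d is None
                else {
                    "start": d.start, "end": d.end, "length": d.length,
                    "n_sites": d.n_sites,
                    "left_clear_flank": d.left_clear_flank,
                    "right_clear_flank": d.right_clear_flank,
                }
            )
            for gene, d in designs.items()
        },
        "assay": {
            "concordance_auc": concordance_auc,
            "invalid_samples": qc.invalid_samples,
        },
        "marker_stats": (
            stats.reset_index()
            .assign(locus=lambda d: d["locus"].astype(str))
            .replace({np.nan: None})
            .to_dict(orient="records")
        ),
        "independence_groups": {str(k): int(v) for k, v in groups.items()},
        "combos": [r.to_dict() for r in reports[:10]],
        "best": {
            **best.to_dict(),
            "logistic": fit.summary().reset_index(names="term").to_dict(orient="records"),
        },
    }
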