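"""End-to-end composition of the analysis stages on one dataset.

``run_pipeline`` executes the full study design on synthetic (or loaded)
data: simulate -> impute -> phase scoring -> elliptical pseudo-time ->
stage-specific dosage ratios and census -> co-expression signature ->
screen calls and ploidy-specific intersection -> foci report -> kinetics
summary, writing every stage's tables into a report directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .config import GROUPS, PHASES, SimConfig, save_config
from .cycle import SignatureFilterParams, filter_signature, phase_proportions, score_phases
from .dosage import DEParams, cutoff_census, stage_ratio_table
from .foci import ColocParams, stage_stratified_report
from .imputation import DiffusionParams, drop_constant_genes, impute_counts
from .io import write_gene_sets, write_mtx
from .kinetics import stage_durations
from .pseudotime import fit_ellipse, rolling_profile
from .screen import call_essentials, guide_log2fc, ploidy_specific_intersection
from .signatures import SignatureSpec, coexpression_signature, signature_score

log = logging.getLogger("haplocycle")


def global_dosage_ratio(adata, group_col: str = "group") -> float:
    """Ratio of mean per-cell total counts, diploid over haploid — the
    pipeline's global expression summary checked against the 2:1
    genome-doubling expectation."""
    from scipy import sparse

    x = adata.X
    totals = np.asarray(x.sum(axis=1)).ravel() if sparse.issparse(x) else x.sum(axis=1)
    groups = adata.obs[group_col].to_numpy()
    mean_d = totals[groups == "diploid"].mean()
    mean_h = totals[groups == "haploid"].mean()
    return float(mean_d / mean_h)


def run_pipeline(config: SimConfig, outdir: str | Path,
                 diffusion: DiffusionParams | None = None,
                 de_params: DEParams | None = None,
                 radius: float = 0.5, n_anchors: int = 180) -> dict:
    """Run every stage on synthetic data and write a report directory.

    Returns a summary dict of the headline numbers (also written as
    summary.json).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    diffusion = diffusion or DiffusionParams()
    de_params = de_params or DEParams()
    summary: dict = {}

    log.info("simulating %d cells/group x %d genes",
             config.n_cells_per_group, config.n_genes)
    adata, truth = synthetic.simulate_cells(config)
    write_mtx(adata, out / "counts")
    truth.genes.to_csv(out / "gene_truth.csv")
    summary["global_dosage_ratio"] = global_dosage_ratio(adata)

    log.info("imputing (t=%d)", diffusion.t_steps)
    adata = impute_counts(adata, diffusion)
    adata = drop_constant_genes(adata)

    log.info("scoring phases")
    sigs = [
        filter_signature(adata, s, SignatureFilterParams())
        for s in truth.phase_gene_sets()
    ]
    scores = score_phases(adata, sigs)
    scores.to_csv(out / "phase_scores.csv")
    props = phase_proportions(scores, adata.obs["group"])
    props.to_csv(out / "phase_proportions.csv")
    summary["phase_accuracy"] = float(
        (scores["phase"].to_numpy() == adata.obs["true_phase"].to_numpy()).mean()
    )

    log.info("fitting pseudo-time trajectories per group")
    genes_of_interest = [s for sig in sigs for s in sorted(sig.members)][:20]
    for grp in GROUPS:
        mask = (adata.obs["group"] == grp).to_numpy()
        pts = scores.loc[mask, ["G1S", "G2M"]].to_numpy()
        ellipse = fit_ellipse(pts)
        expr = np.asarray(adata[mask, genes_of_interest].layers["imputed"])
        prof = rolling_profile(pts, expr, ellipse,
                               scores.loc[mask, "phase"].to_numpy(),
                               genes=genes_of_interest, radius=radius,
                               n_anchors=n_anchors)
        prof.to_frame().to_csv(out / f"trajectory_{grp}.csv", index=False)

    log.info("stage-specific dosage ratios")
    ratio_table = stage_ratio_table(adata, scores["phase"], min_cells=5)
    ratio_table.to_csv(out / "stage_ratios.csv")
    census, ecdf, linear = cutoff_census(ratio_table, de_params)
    census.to_csv(out / "cutoff_census.tsv", sep="\t")
    ecdf.to_csv(out / "ratio_ecdf.csv", index=False)
    summary["cutoff_linear_equivalent"] = round(linear, 1)
    summary["median_log2_ratio_by_stage"] = {
        s: float(ratio_table.xs(s, level="stage")["log2_ratio"].median())
        for s in PHASES
    }

    log.info("co-expression signature around the first S-phase program gene")
    anchor = sorted(sigs[1].members)[0]
    sig = coexpression_signature(adata, SignatureSpec(anchor_gene=anchor))
    write_gene_sets([sig], out / "coexpression_signature.gmt")
    signature_score(adata, sig).rename("score").to_csv(out / "signature_scores.csv")
    summary["signature_size"] = len(sig)

    log.info("screen calls")
    screen_table, planted = synthetic.simulate_screen(config)
    screen_table.to_csv(out / "screen_counts.csv", index=False)
    mapping = screen_table.set_index("guide")["gene"]
    hap = call_essentials(guide_log2fc(screen_table, "haploid_end"), mapping, screen="haploid")
    dip = call_essentials(guide_log2fc(screen_table, "diploid_end"), mapping, screen="diploid")
    hits, provenance = ploidy_specific_intersection([hap], [dip])
    provenance.to_csv(out / "screen_intersection.tsv", sep="\t")
    planted_set = set(planted)
    summary["screen_sensitivity"] = (
        len(hits & planted_set) / len(planted_set) if planted_set else float("nan")
    )
    summary["screen_hits"] = len(hits)

    log.info("foci report")
    foci_table = synthetic.simulate_foci(config)
    foci_table.cells.to_csv(out / "foci_cells.csv")
    foci_table.foci.to_csv(out / "foci.csv", index=False)
    report = stage_stratified_report(
        foci_table, ColocParams(match_radius=config.foci.match_radius),
        expected_ratio=config.dosage_factor,
    )
    report.to_csv(out / "foci_report.tsv", sep="\t")

    log.info("stage durations from assigned proportions")
    durations = {
        grp: stage_durations(props.loc[grp, list(PHASES)].astype(float), 24.0)
        for grp in GROUPS
    }
    pd.DataFrame(durations).rename_axis("phase").to_csv(out / "stage_durations.tsv", sep="\t")
    summary["g2m_duration_difference_h"] = float(
        (durations["haploid"]["G2"] + durations["haploid"]["G2M"])
        - (durations["diploid"]["G2"] + durations["diploid"]["G2M"])
    )

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
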