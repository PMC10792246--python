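"""End-to-end orchestration: simulate -> efflux -> calibrate -> classify
-> quant -> coloc -> report.

Every stage reads/writes plain TSV (plus JSON for thresholds and
provenance), so any stage can be re-run from its written intermediates and
reproduces the same report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from Bio import AlignIO

from . import __version__
from .classify import (
    DomainMap,
    ThresholdSet,
    annotate_domains,
    calibration_eligible,
    classify,
    derive_benevolent_threshold,
    derive_pathogenic_threshold,
    parse_hgvs_p,
    species_with_alt_as_reference,
)
from .coloc import ColocResult, ImagePair, pearson_coloc, summarize_coloc
from .efflux import WT, process_well_table, summarize_activity
from .errors import CalibrationError
from .fixtures import load_variant_table, make_fixtures
from .quant import stabilization_call, treatment_response
from .stats import auto_t_test

logger = logging.getLogger("effluxkit")

__all__ = ["RunConfig", "run_pipeline", "efflux_stage", "calibrate_stage",
           "classify_stage", "quant_stage", "coloc_stage"]

BOUNDARY_WARNING = (
    "benevolent boundary: the >=80% rule is applied; the alternative "
    "strict > boundary is available via benevolent_boundary='gt'"
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: Path
    input_dir: Optional[Path] = None  # None -> simulate the fixture first
    seed: int = 0
    renilla_normalize: bool = False
    benevolent_boundary: Literal["ge", "gt"] = "ge"
    threshold_overrides: Optional[tuple[float, float]] = None
    human_id: str = "human"
    domain_map: DomainMap = field(default_factory=DomainMap)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.input_dir is not None:
            self.input_dir = Path(self.input_dir)


def efflux_stage(wells: pd.DataFrame, renilla_normalize: bool = False):
    """Well table -> (per-experiment results, per-construct summary)."""
    results = process_well_table(wells, renilla_normalize=renilla_normalize)
    summary = summarize_activity(results)
    return results, summary


def calibrate_stage(
    variants: pd.DataFrame,
    summary: pd.DataFrame,
    msa,
    human_id: str = "human",
    benevolent_boundary: Literal["ge", "gt"] = "ge",
    overrides: Optional[tuple[float, float]] = None,
) -> tuple[ThresholdSet, pd.DataFrame]:
    """Derive the two activity cutoffs from controls and conservation.

    Calibration variants are queries whose alternate residue appears as
    reference in more than two alignment species; the pathogenic anchor is
    the highest-activity pathogenic control.
    """
    act = summary.set_index("construct")["mean_activity"]

    conservation = []
    for row in variants.itertuples():
        var = parse_hgvs_p(row.hgvs_p, role=row.role)
        count = species_with_alt_as_reference(msa, var, human_id=human_id)
        conservation.append(
            {
                "hgvs_p": var.hgvs_p,
                "role": row.role,
                "species_with_alt": count,
                "calibration_eligible": bool(
                    row.role == "query" and calibration_eligible(count)
                ),
            }
        )
    cons_df = pd.DataFrame(conservation)

    if overrides is not None:
        thresholds = ThresholdSet(
            pathogenic_cutoff=float(overrides[0]),
            benevolent_cutoff=float(overrides[1]),
            benevolent_boundary=benevolent_boundary,
        )
        return thresholds, cons_df

    controls = []
    for row in variants.itertuples():
        if row.role == "pathogenic_control" and row.hgvs_p in act.index:
            controls.append((parse_hgvs_p(row.hgvs_p, role=row.role), float(act[row.hgvs_p])))
    if not controls:
        raise CalibrationError("no pathogenic controls with measured activity")
    pathogenic, anchor = derive_pathogenic_threshold(controls)

    eligible = cons_df[cons_df["calibration_eligible"]]
    calib = [
        (parse_hgvs_p(h), float(act[h]))
        for h in eligible["hgvs_p"]
        if h in act.index
    ]
    benevolent = derive_benevolent_threshold([a for _, a in calib])

    thresholds = ThresholdSet(
        pathogenic_cutoff=pathogenic,
        benevolent_cutoff=float(benevolent),
        calibration_variants=tuple(calib),
        control_anchor=anchor,
        benevolent_boundary=benevolent_boundary,
    )
    return thresholds, cons_df


def classify_stage(
    variants: pd.DataFrame,
    summary: pd.DataFrame,
    thresholds: ThresholdSet,
    domain_map: DomainMap,
) -> pd.DataFrame:
    """Three-class call plus domain annotation for every query variant."""
    act = summary.set_index("construct")
    rows = []
    for row in variants.itertuples():
        if row.hgvs_p not in act.index:
            continue
        var = parse_hgvs_p(row.hgvs_p, role=row.role)
        mean = float(act.loc[row.hgvs_p, "mean_activity_reported"])
        rows.append(
            {
                "hgvs_p": var.hgvs_p,
                "role": row.role,
                "mean_activity": mean,
                "sd": float(act.loc[row.hgvs_p, "sd"]),
                "n": int(act.loc[row.hgvs_p, "n"]),
                "call": classify(mean, thresholds),
                "domains": ";".join(annotate_domains(var, domain_map)),
            }
        )
    return pd.DataFrame(rows)


def _blot_percent_wt(blots: pd.DataFrame) -> pd.DataFrame:
    """Per-lane total ABCA1 as percent of same-experiment mock-treated WT."""
    out = []
    for exp, grp in blots.groupby("experiment"):
        wt = grp[(grp["construct"] == WT) & (grp["condition"] == "mock_treated")]
        if wt.empty:
            continue
        wt_ratio = float(
            ((wt["band1"] + wt["band2"]) / wt["actin"]).mean()
        )
        for row in grp.itertuples():
            ratio = (row.band1 + row.band2) / row.actin
            out.append(
                {
                    "construct": row.construct,
                    "condition": row.condition,
                    "experiment": exp,
                    "total_pct_wt": 100.0 * ratio / wt_ratio,
                }
            )
    return pd.DataFrame(out)


def _surface_percent_wt(surface: pd.DataFrame) -> pd.DataFrame:
    """Per-sample surface/total ratio as percent of mock-treated WT."""
    out = []
    for exp, grp in surface.groupby("experiment"):
        wt = grp[(grp["construct"] == WT) & (grp["condition"] == "mock_treated")]
        if wt.empty:
            continue
        wt_ratio = float((wt["surface"] / wt["total"]).mean())
        for row in grp.itertuples():
            out.append(
                {
                    "construct": row.construct,
                    "condition": row.condition,
                    "experiment": exp,
                    "surface_pct_wt": 100.0 * (row.surface / row.total) / wt_ratio,
                }
            )
    return pd.DataFrame(out)


def quant_stage(
    blots: pd.DataFrame, surface: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Total/surface quantification plus treatment-response calls.

    Returns (total-protein table, surface table, response table). Rescue
    responses (epoxomicin, 4-PBA) and ApoA1 stabilization are one-tailed
    increase tests against the matched mock-treated arm.
    """
    totals = _blot_percent_wt(blots)
    surf = _surface_percent_wt(surface)

    responses = []
    for name in sorted(set(totals["construct"])):
        mock_total = totals[
            (totals["construct"] == name) & (totals["condition"] == "mock_treated")
        ]["total_pct_wt"]
        for cond in ("epoxomicin", "pba_4"):
            arm = totals[(totals["construct"] == name) & (totals["condition"] == cond)][
                "total_pct_wt"
            ]
            if len(arm) >= 2 and len(mock_total) >= 2:
                resp = treatment_response(
                    arm.to_list(), mock_total.to_list(), "increase", name, cond
                )
                responses.append(_response_row(resp, "total_protein"))
    for name in sorted(set(surf["construct"])):
        mock_surf = surf[
            (surf["construct"] == name) & (surf["condition"] == "mock_treated")
        ]["surface_pct_wt"]
        for cond in ("epoxomicin", "pba_4", "apoa1"):
            arm = surf[(surf["construct"] == name) & (surf["condition"] == cond)][
                "surface_pct_wt"
            ]
            if len(arm) >= 2 and len(mock_surf) >= 2:
                if cond == "apoa1":
                    resp = stabilization_call(arm.to_list(), mock_surf.to_list(), name)
                else:
                    resp = treatment_response(
                        arm.to_list(), mock_surf.to_list(), "increase", name, cond
                    )
                responses.append(_response_row(resp, "surface"))
    return totals, surf, pd.DataFrame(responses)


def _response_row(resp, readout: str) -> dict:
    return {
        "construct": resp.construct,
        "condition": resp.condition,
        "readout": readout,
        "fold_change": resp.fold_change,
        "p_value": resp.p_value,
        "stars": resp.stat.stars if resp.stat else "",
        "responder": resp.responder,
    }


def coloc_stage(input_dir: Path, image_index: pd.DataFrame) -> pd.DataFrame:
    """Pearson colocalization per construct, summarized across experiments."""
    import tifffile

    per_construct: dict[str, list[ColocResult]] = {}
    for row in image_index.itertuples():
        a = tifffile.imread(input_dir / row.channel_a).astype(float)
        b = tifffile.imread(input_dir / row.channel_b).astype(float)
        res = pearson_coloc(
            ImagePair(a, b), experiment_id=int(row.experiment), replicate_id=int(row.replicate)
        )
        per_construct.setdefault(row.construct, []).append(res)

    rows = []
    for name, results in sorted(per_construct.items()):
        mean, sd, n = summarize_coloc(results)
        rows.append(
            {"construct": name, "coloc_r_mean": mean, "coloc_r_sd": sd, "n_experiments": n}
        )
    return pd.DataFrame(rows)


def _activity_stats_vs_wt(results: pd.DataFrame) -> pd.DataFrame:
    """Two-tailed F-test-gated t-test of each construct vs WT activities."""
    wt = results[results["construct"] == WT]["relative_activity"].to_list()
    rows = []
    for name, grp in results.groupby("construct"):
        if name == WT:
            continue
        vals = grp["relative_activity"].to_list()
        if len(vals) >= 2 and len(wt) >= 2:
            stat = auto_t_test(vals, wt, tails=2)
            rows.append(
                {
                    "construct": name,
                    "p_vs_wt": stat.p_value,
                    "stars_vs_wt": stat.stars,
                    "test": stat.test,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute the full pipeline and write all intermediates plus the report.

    Returns the final per-variant report (one row per classified variant).
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    if config.input_dir is None:
        logger.info("simulating fixture inputs (seed=%d)", config.seed)
        input_dir = out / "inputs"
        make_fixtures(input_dir, seed=config.seed)
    else:
        input_dir = config.input_dir

    wells = pd.read_csv(input_dir / "wells.tsv", sep="\t")
    variants = load_variant_table(input_dir / "variants.tsv")
    msa = AlignIO.read(str(input_dir / "msa.fasta"), "fasta")

    logger.info("efflux stage: %d wells", len(wells))
    results, summary = efflux_stage(wells, renilla_normalize=config.renilla_normalize)
    results.to_csv(out / "efflux_results.tsv", sep="\t", index=False)
    summary.to_csv(out / "activity_summary.tsv", sep="\t", index=False)

    stats_vs_wt = _activity_stats_vs_wt(results)
    stats_vs_wt.to_csv(out / "activity_stats.tsv", sep="\t", index=False)

    logger.info("calibration stage")
    thresholds, conservation = calibrate_stage(
        variants,
        summary,
        msa,
        human_id=config.human_id,
        benevolent_boundary=config.benevolent_boundary,
        overrides=config.threshold_overrides,
    )
    conservation.to_csv(out / "conservation.tsv", sep="\t", index=False)

    calls = classify_stage(variants, summary, thresholds, config.domain_map)
    calls.to_csv(out / "variant_calls.tsv", sep="\t", index=False)

    blots_path = input_dir / "blots.tsv"
    surface_path = input_dir / "surface.tsv"
    totals = surf = responses = None
    if blots_path.exists() and surface_path.exists():
        logger.info("quantification stage")
        totals, surf, responses = quant_stage(
            pd.read_csv(blots_path, sep="\t"), pd.read_csv(surface_path, sep="\t")
        )
        totals.to_csv(out / "total_protein.tsv", sep="\t", index=False)
        surf.to_csv(out / "surface_expression.tsv", sep="\t", index=False)
        responses.to_csv(out / "treatment_responses.tsv", sep="\t", index=False)

    coloc = None
    index_path = input_dir / "images.tsv"
    if index_path.exists():
        logger.info("colocalization stage")
        coloc = coloc_stage(input_dir, pd.read_csv(index_path, sep="\t"))
        coloc.to_csv(out / "colocalization.tsv", sep="\t", index=False)

    report = _assemble_report(calls, stats_vs_wt, totals, surf, responses, coloc)
    report.to_csv(out / "report.tsv", sep="\t", index=False)

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "renilla_normalize": config.renilla_normalize,
        "thresholds": {
            "pathogenic_cutoff": thresholds.pathogenic_cutoff,
            "benevolent_cutoff": thresholds.benevolent_cutoff,
            "benevolent_boundary": thresholds.benevolent_boundary,
            "control_anchor": thresholds.control_anchor.hgvs_p
            if thresholds.control_anchor
            else None,
            "calibration_variants": [
                {"hgvs_p": v.hgvs_p, "mean_activity": a}
                for v, a in thresholds.calibration_variants
            ],
        },
        "warnings": [BOUNDARY_WARNING],
        "n_variants_classified": int(len(report)),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    logger.info("report written: %d variants", len(report))
    return report


def _assemble_report(calls, stats_vs_wt, totals, surf, responses, coloc) -> pd.DataFrame:
    report = calls.merge(stats_vs_wt, left_on="hgvs_p", right_on="construct", how="left")
    report = report.drop(columns=["construct"], errors="ignore")

    def _mean_by_construct(df, value, cond="mock_treated"):
        if df is None or df.empty:
            return pd.Series(dtype=float)
        sub = df[df["condition"] == cond] if "condition" in df.columns else df
        return sub.groupby("construct")[value].mean()

    total_mock = _mean_by_construct(totals, "total_pct_wt")
    surf_mock = _mean_by_construct(surf, "surface_pct_wt")
    report["total_protein_pct_wt"] = report["hgvs_p"].map(total_mock).astype(float)
    report["surface_pct_wt"] = report["hgvs_p"].map(surf_mock).astype(float)

    if responses is not None and not responses.empty:
        for cond, col in (
            ("epoxomicin", "epoxomicin_responder"),
            ("pba_4", "pba_responder"),
            ("apoa1", "apoa1_stabilized"),
        ):
            readout = "surface" if cond == "apoa1" else "total_protein"
            sub = responses[
                (responses["condition"] == cond) & (responses["readout"] == readout)
            ].set_index("construct")["responder"]
            report[col] = report["hgvs_p"].map(sub)

    if coloc is not None and not coloc.empty:
        r = coloc.set_index("construct")["coloc_r_mean"]
        report["coloc_r"] = report["hgvs_p"].map(r).astype(float)
    return report
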