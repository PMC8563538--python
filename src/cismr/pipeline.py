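"""End-to-end analysis: colocalisation screen, gated Mendelian randomisation,
genome-wide comparator contrast, and sensitivity analyses.

The flow per outcome is: harmonise the disease and outcome statistics within
each gene region, compute the colocalisation posterior (with a conditional
re-run when the initial run favours distinct causal variants), gate on the
shared-causal-variant posterior, select instruments (per region, pooled, and
a genome-wide comparator excluding the gene regions), pool by random-effects
IVW, rescale per halving of disease odds, and contrast the cis estimate
against the comparator.  The pooled analysis requires colocalisation at
every gene region; outcomes colocalising at a single region get that
region's MR only.

Every gate decision is logged as one plain-text line; the whole run is
deterministic given its inputs and configuration.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict, replace as dc_replace

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import instruments as inst_mod
from . import mr as mr_mod
from .sumstats import (SumStats, Region, read_sumstats, read_regions,
                       extract_region, harmonise_pair, align_actions, _DROP_ACTIONS)
from .simulate import read_ld_panel

logger = logging.getLogger(__name__)

__all__ = ["AnalysisParams", "AnalysisConfig", "RunReport", "run_study",
           "run_analysis", "render_forest_data"]


@dataclass(frozen=True)
class AnalysisParams:
    """All thresholds and priors of the analysis, with their defaults."""

    pp_threshold: float = 0.8
    r2_mask: float = 0.2
    r2_clump: float = 0.1
    p_exposure: float = 5e-6
    p_biomarker: float = 0.05
    palindrome_eaf_band: float = 0.42
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    prior_sd_quantitative: float = 0.2
    prior_sd_binary: float = 0.15
    pooled_requires_all_regions: bool = True
    exposure_mode: str = "disease"  # "disease" | "biomarker"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (("pp_threshold", 0, 1), ("r2_mask", 0, 1),
                             ("r2_clump", 0, 1), ("p_exposure", 0, 1),
                             ("p_biomarker", 0, 1), ("palindrome_eaf_band", 0, 0.5)):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.exposure_mode not in ("disease", "biomarker"):
            raise ValueError("exposure_mode must be 'disease' or 'biomarker'")

    def priors(self) -> coloc_mod.ColocPriors:
        return coloc_mod.ColocPriors(self.coloc_p1, self.coloc_p2, self.coloc_p12)

    def prior_variance(self, trait_type: str) -> float:
        sd = self.prior_sd_binary if trait_type == "binary" else self.prior_sd_quantitative
        return sd**2


@dataclass(frozen=True)
class AnalysisConfig(AnalysisParams):
    """AnalysisParams plus the file-system inputs of one run."""

    disease_path: str = ""
    disease_trait: str = "disease"
    biomarker_path: str = ""
    biomarker_trait: str = "biomarker"
    outcomes: dict = field(default_factory=dict)  # name -> {path, trait_type}
    ld_manifest: str = ""
    ld_matrix: str = ""
    regions_path: str = ""
    functional_variants: tuple = ()
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "functional_variants" in raw:
            raw["functional_variants"] = tuple(raw["functional_variants"])
        return cls(**raw)

    def fingerprint(self) -> str:
        """Stable hash of every threshold, prior and input path."""
        d = asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Outputs of one pipeline run: the colocalisation table, the MR results
    table, comparator contrasts, the cross-exposure concordance, the config
    fingerprint, and the decision log."""

    coloc: pd.DataFrame
    mr: pd.DataFrame
    contrasts: pd.DataFrame
    concordance: float | None
    fingerprint: str
    log: list


_COLOC_COLUMNS = ["outcome", "region", "run", "n_variants",
                  "PP0", "PP1", "PP2", "PP3", "PP4",
                  "top_disease", "top_outcome", "masked_n",
                  "colocalises", "evidence_path"]

_MR_COLUMNS = ["outcome", "source", "exposure", "beta", "se", "ci_low", "ci_high",
               "pvalue", "Q", "k", "scale", "outcome_scale",
               "odds_ratio", "or_ci_low", "or_ci_high"]

_CONTRAST_COLUMNS = ["outcome", "cis_source", "delta", "se_delta", "z", "pvalue"]


def _coloc_row(outcome: str, region: str, run: str, res: coloc_mod.ColocResult) -> dict:
    row = {"outcome": outcome, "region": region, "run": run,
           "n_variants": res.n_variants, "masked_n": len(res.masked),
           "top_disease": res.top1, "top_outcome": res.top2,
           "colocalises": None, "evidence_path": None}
    for i, h in enumerate(coloc_mod.HYPOTHESES):
        row[h] = float(res.pp[i]) if res.pp is not None else np.nan
    return row


def _mr_row(outcome: str, source: str, exposure: str, est: mr_mod.MrEstimate) -> dict:
    return {"outcome": outcome, "source": source, "exposure": exposure,
            "beta": est.beta, "se": est.se, "ci_low": est.ci_low,
            "ci_high": est.ci_high, "pvalue": est.pvalue, "Q": est.Q,
            "k": est.n_instruments, "scale": est.scale,
            "outcome_scale": est.outcome_scale, "odds_ratio": est.odds_ratio,
            "or_ci_low": est.or_ci_low, "or_ci_high": est.or_ci_high}


def run_study(
    disease: SumStats,
    biomarker: SumStats,
    outcomes: dict[str, SumStats],
    regions: list[Region],
    panel,
    params: AnalysisParams = AnalysisParams(),
    functional_variants: tuple = (),
    fingerprint: str = "",
) -> RunReport:
    """Run the full analysis on in-memory inputs.

    See the module docstring for the flow.  A failure while processing one
    outcome is logged with the stage name and that outcome is skipped;
    results for other outcomes are preserved.
    """
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)
        logger.info(msg)

    priors = params.priors()
    w_dis = params.prior_variance(disease.trait_type)

    coloc_rows: list[dict] = []
    mr_rows: list[dict] = []
    contrast_rows: list[dict] = []

    # comparator instruments are outcome-independent: select once
    gw_inst = inst_mod.select_genomewide(
        disease, biomarker, regions, panel=panel,
        p_exposure=params.p_exposure, p_biomarker=params.p_biomarker,
        r2_clump=params.r2_clump, palindrome_eaf_band=params.palindrome_eaf_band,
    )
    note(f"comparator: {len(gw_inst)} genome-wide instruments after exclusions")

    concord_a: list[float] = []
    concord_b: list[float] = []

    for name, outcome in outcomes.items():
        try:
            w_out = params.prior_variance(outcome.trait_type)
            decisions: dict[str, coloc_mod.ColocDecision] = {}
            conditionals: dict[str, coloc_mod.ColocResult | None] = {}
            for region in regions:
                d_reg = extract_region(disease, region)
                pair = harmonise_pair(d_reg, outcome, params.palindrome_eaf_band)
                if pair.empty:
                    note(f"coloc {name}/{region.name}: no shared variants; not colocalised")
                    decisions[region.name] = coloc_mod.ColocDecision(False, "none")
                    conditionals[region.name] = None
                    continue
                initial = coloc_mod.coloc_posteriors(pair, priors, w_dis, w_out)
                cond = None
                if (initial.pp4 <= params.pp_threshold
                        and initial.modal_hypothesis() == 3):
                    cond = coloc_mod.conditional_coloc(
                        pair, priors, w_dis, w_out, panel=panel, r2_mask=params.r2_mask)
                    note(f"coloc {name}/{region.name}: distinct-signal pattern; "
                         f"conditional re-run masking {len(cond.masked)} variants "
                         f"around {cond.conditioned_on}")
                dec = coloc_mod.coloc_decision(initial, cond, params.pp_threshold)
                decisions[region.name] = dec
                conditionals[region.name] = cond
                row = _coloc_row(name, region.name, "initial", initial)
                row["colocalises"] = dec.colocalises
                row["evidence_path"] = dec.evidence_path
                coloc_rows.append(row)
                if cond is not None:
                    coloc_rows.append(_coloc_row(name, region.name, "conditional", cond))
                note(f"coloc {name}/{region.name}: PP4={initial.pp4:.3f} "
                     f"-> colocalises={dec.colocalises} via {dec.evidence_path}")

            gated = [r for r in regions if decisions.get(r.name, coloc_mod.ColocDecision(False, "none")).colocalises]
            if not gated:
                note(f"gate {name}: no region colocalises; outcome not taken to MR")
                continue
            pooled_ok = (len(gated) == len(regions)) or not params.pooled_requires_all_regions
            note(f"gate {name}: colocalises at {[r.name for r in gated]}; "
                 f"pooled analysis {'enabled' if pooled_ok and len(gated) > 1 else 'not applicable'}")

            # instrument selection per gated region, with the pleiotropy filter
            region_sets: dict[str, inst_mod.InstrumentSet] = {}
            for region in gated:
                cis = inst_mod.select_cis(
                    disease, biomarker, region, panel=panel,
                    p_exposure=params.p_exposure, p_biomarker=params.p_biomarker,
                    r2_clump=params.r2_clump, palindrome_eaf_band=params.palindrome_eaf_band,
                )
                cis = inst_mod.filter_pleiotropy(
                    cis, conditionals.get(region.name), panel=panel, r2_mask=params.r2_mask)
                cis = inst_mod.attach_outcome(cis, outcome, params.palindrome_eaf_band)
                region_sets[region.name] = cis
                note(f"instruments {name}/{region.name}: {len(cis)} retained; "
                     f"provenance={list(cis.provenance)}")

            analysis_sets: dict[str, inst_mod.InstrumentSet] = dict(region_sets)
            if pooled_ok and len(gated) > 1:
                pooled_table = pd.concat([s.table for s in region_sets.values()],
                                         ignore_index=True)
                first = next(iter(region_sets.values()))
                analysis_sets["pooled"] = dc_replace(
                    first, table=pooled_table,
                    provenance=first.provenance + (("pooled_regions", 0),))

            primary_source = "pooled" if "pooled" in analysis_sets else gated[0].name
            primary_est = None
            for source, inst in analysis_sets.items():
                if inst.is_empty:
                    note(f"mr {name}/{source}: empty instrument set; skipped")
                    continue
                est = mr_mod.ivw(inst)
                est_h = mr_mod.rescale_per_halving(est)
                mr_rows.append(_mr_row(name, source, "disease", est_h))
                # alternative exposure definition: same variants, biomarker
                # association as exposure, oriented per 1 SD lower biomarker
                # (the direction of improved glycaemic control)
                bio_inst = inst_mod.with_biomarker_exposure(inst, biomarker.trait)
                bio_est = mr_mod.flip_direction(
                    mr_mod.ivw(bio_inst), f"per-1-SD-lower-{biomarker.trait}")
                mr_rows.append(_mr_row(name, source, "biomarker", bio_est))
                if source == primary_source:
                    primary_est = bio_est if params.exposure_mode == "biomarker" else est_h
                concord_a.append(est_h.beta)
                concord_b.append(bio_est.beta)

            # genome-wide comparator and the cis-vs-comparator contrast
            gw_out = inst_mod.attach_outcome(gw_inst, outcome, params.palindrome_eaf_band)
            if not gw_out.is_empty:
                gw_est = mr_mod.rescale_per_halving(mr_mod.ivw(gw_out))
                mr_rows.append(_mr_row(name, "genomewide", "disease", gw_est))
                if params.exposure_mode == "biomarker":
                    gw_bio = inst_mod.with_biomarker_exposure(gw_out, biomarker.trait)
                    gw_est = mr_mod.flip_direction(
                        mr_mod.ivw(gw_bio), f"per-1-SD-lower-{biomarker.trait}")
                    mr_rows.append(_mr_row(name, "genomewide", "biomarker", gw_est))
                if primary_est is not None:
                    c = mr_mod.compare_estimates(primary_est, gw_est)
                    contrast_rows.append({"outcome": name, "cis_source": primary_source,
                                          "delta": c.delta, "se_delta": c.se_delta,
                                          "z": c.z, "pvalue": c.pvalue})
                    note(f"contrast {name}: {primary_source} vs genomewide "
                         f"delta={c.delta:.4f} p={c.pvalue:.3g}")

            # single-variant sensitivity MR on user-supplied functional variants
            for vid in functional_variants:
                row_d = disease.table.loc[disease.table["variant_id"] == vid]
                row_o = outcome.table.loc[outcome.table["variant_id"] == vid]
                if row_d.empty or row_o.empty:
                    note(f"mr {name}/variant:{vid}: absent from disease or outcome GWAS")
                    continue
                merged = row_d.merge(row_o, on="variant_id", suffixes=("_1", "_2"))
                action = align_actions(merged, params.palindrome_eaf_band).iloc[0]
                if action in _DROP_ACTIONS:
                    note(f"mr {name}/variant:{vid}: alleles {action}; skipped")
                    continue
                sign = -1.0 if action in ("flip", "strand_flip") else 1.0
                est = mr_mod.wald_ratio(
                    float(row_d["beta"].iloc[0]), float(row_d["se"].iloc[0]),
                    sign * float(row_o["beta"].iloc[0]), float(row_o["se"].iloc[0]),
                    outcome_scale="log-OR" if outcome.trait_type == "binary" else "SD-units",
                )
                mr_rows.append(_mr_row(name, f"variant:{vid}", "disease",
                                       mr_mod.rescale_per_halving(est)))
        except Exception as exc:  # keep partial results, report the stage
            note(f"ERROR outcome {name}: {type(exc).__name__}: {exc}")
            logger.exception("pipeline failure for outcome %s", name)

    concordance = None
    if len(concord_a) >= 3:
        concordance = mr_mod.cross_exposure_concordance(concord_a, concord_b)
        note(f"cross-exposure concordance (Pearson r over {len(concord_a)} estimates): "
             f"{concordance:.3f}")

    return RunReport(
        coloc=pd.DataFrame(coloc_rows, columns=_COLOC_COLUMNS),
        mr=pd.DataFrame(mr_rows, columns=_MR_COLUMNS),
        contrasts=pd.DataFrame(contrast_rows, columns=_CONTRAST_COLUMNS),
        concordance=concordance, fingerprint=fingerprint, log=log,
    )


def render_forest_data(report: RunReport) -> pd.DataFrame:
    """Tidy plotting table: per-outcome point estimates with CI bounds plus
    reference lines (the null and the genome-wide comparator estimate).

    Binary outcomes are expressed as odds ratios (null reference 1),
    quantitative outcomes in SD units (null reference 0).  An empty report
    yields an empty table.
    """
    rows = []
    mr = report.mr
    if mr.empty:
        return pd.DataFrame(columns=["outcome", "source", "kind", "value",
                                     "ci_low", "ci_high", "scale"])
    for outcome, grp in mr[mr["exposure"] == "disease"].groupby("outcome", sort=False):
        binary = (grp["outcome_scale"] == "log-OR").any()
        null_value = 1.0 if binary else 0.0
        rows.append({"outcome": outcome, "source": "", "kind": "reference_null",
                     "value": null_value, "ci_low": np.nan, "ci_high": np.nan,
                     "scale": "OR" if binary else "SD-units"})
        for r in grp.itertuples(index=False):
            if binary and r.odds_ratio == r.odds_ratio:  # not NaN
                value, lo, hi, scale = r.odds_ratio, r.or_ci_low, r.or_ci_high, "OR"
            else:
                value, lo, hi, scale = r.beta, r.ci_low, r.ci_high, r.outcome_scale
            kind = "reference_comparator" if r.source == "genomewide" else "estimate"
            rows.append({"outcome": outcome, "source": r.source, "kind": kind,
                         "value": value, "ci_low": lo, "ci_high": hi, "scale": scale})
    return pd.DataFrame(rows)


def run_analysis(config: AnalysisConfig) -> RunReport:
    """Load the configured inputs, run the analysis, and write every output
    table (TSV), the forest-plot table, and the plain-text decision log to
    ``config.out_dir``."""
    disease = read_sumstats(config.disease_path, config.disease_trait, "binary")
    biomarker = read_sumstats(config.biomarker_path, config.biomarker_trait, "quantitative")
    outcomes = {
        name: read_sumstats(spec["path"], name, spec.get("trait_type", "quantitative"))
        for name, spec in config.outcomes.items()
    }
    panel = read_ld_panel(config.ld_manifest, config.ld_matrix)
    regions = read_regions(config.regions_path)

    report = run_study(disease, biomarker, outcomes, regions, panel,
                       params=config, functional_variants=config.functional_variants,
                       fingerprint=config.fingerprint())

    os.makedirs(config.out_dir, exist_ok=True)
    report.coloc.to_csv(os.path.join(config.out_dir, "coloc.tsv"), sep="\t", index=False)
    report.mr.to_csv(os.path.join(config.out_dir, "mr.tsv"), sep="\t", index=False)
    report.contrasts.to_csv(os.path.join(config.out_dir, "contrasts.tsv"), sep="\t", index=False)
    render_forest_data(report).to_csv(os.path.join(config.out_dir, "forest.tsv"),
                                      sep="\t", index=False, float_format="%.17g")
    with open(os.path.join(config.out_dir, "run.log"), "w") as fh:
        fh.write(f"# config fingerprint: {report.fingerprint}\n")
        for line in report.log:
            fh.write(line + "\n")
    return report
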