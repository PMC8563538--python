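"""Selection of genetic proxy variants for the exposure.

Cis instruments are variants inside the target gene regions that associate
with disease liability below a stringent p-value threshold and with the
glycaemic biomarker below a nominal threshold in a concordant direction
(both thresholds strict), thinned by greedy LD clumping.  The genome-wide
comparator set applies the same filters outside the target genes.  A
colocalisation-based filter removes instruments tagging an outcome-specific
signal (potential horizontal pleiotropy).

Every filter appends its removal count to the instrument set's provenance
trail, so the realised set is auditable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .sumstats import SumStats, Region, extract_region, harmonise_pair, align_actions, _DROP_ACTIONS
from .coloc import ColocResult

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentSet", "select_cis", "select_genomewide", "clump",
    "filter_pleiotropy", "attach_outcome", "with_biomarker_exposure",
]

LOG_ODDS_SCALE = "per-1-unit-higher-log-odds"

#: columns of an InstrumentSet table
INSTRUMENT_COLUMNS = [
    "variant_id", "chrom", "pos", "ea", "nea", "region",
    "eaf_exp", "beta_exp", "se_exp", "pvalue_exp", "n_exp",
    "beta_bio", "se_bio", "pvalue_bio",
]


@dataclass
class InstrumentSet:
    """Harmonised exposure (and optionally outcome) estimates for selected
    proxy variants, with the ordered trail of applied filters."""

    table: pd.DataFrame
    provenance: tuple
    exposure_scale: str
    exposure_trait: str
    outcome_trait: str | None = None
    outcome_type: str | None = None

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("InstrumentSet requires a nonempty provenance trail")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def is_empty(self) -> bool:
        return self.table.empty

    def f_statistics(self) -> np.ndarray:
        """Approximate per-instrument F statistics (informational only)."""
        return (self.table["beta_exp"].to_numpy() / self.table["se_exp"].to_numpy()) ** 2

    def write(self, table_path, provenance_path=None) -> None:
        self.table.to_csv(table_path, sep="\t", index=False)
        if provenance_path is not None:
            with open(provenance_path, "w") as fh:
                for name, removed in self.provenance:
                    fh.write(f"{name}\t{removed}\n")


def clump(candidates: pd.DataFrame, panel, r2_threshold: float = 0.1) -> pd.DataFrame:
    """Greedy LD clumping of candidates by ascending p-value.

    Repeatedly takes the smallest-p unprocessed variant as lead, retains it,
    and discards every unprocessed variant with r² strictly greater than
    ``r2_threshold`` against it.  Ties are broken by position, then
    identifier, so the output is deterministic.  ``candidates`` must carry
    ``variant_id``, ``pvalue`` and ``pos`` columns; a candidate absent from
    the panel is a hard error naming it.
    """
    if candidates.empty:
        return candidates.copy()
    ids = candidates["variant_id"].tolist()
    R = panel.submatrix(ids)  # KeyError with the variant name if missing
    r2 = R**2
    order = sorted(
        range(len(candidates)),
        key=lambda i: (candidates["pvalue"].iat[i], candidates["pos"].iat[i], ids[i]),
    )
    available = np.ones(len(candidates), dtype=bool)
    retained = np.zeros(len(candidates), dtype=bool)
    for i in order:
        if not available[i]:
            continue
        retained[i] = True
        available &= ~(r2[i] > r2_threshold)
        available[i] = False
    return candidates.loc[retained].reset_index(drop=True)


def _candidate_table(pair: pd.DataFrame, label) -> pd.DataFrame:
    """Reshape a harmonised disease/biomarker pair into candidate columns."""
    out = pd.DataFrame({
        "variant_id": pair["variant_id"], "chrom": pair["chrom"], "pos": pair["pos"],
        "ea": pair["ea"], "nea": pair["nea"], "region": label,
        "eaf_exp": pair["eaf_1"], "beta_exp": pair["beta_1"], "se_exp": pair["se_1"],
        "pvalue_exp": pair["pvalue_1"], "n_exp": pair["n_1"],
        "beta_bio": pair["beta_2"], "se_bio": pair["se_2"], "pvalue_bio": pair["pvalue_2"],
        "pvalue": pair["pvalue_1"],  # clumping key
    })
    return out


def _apply_filters(
    cand: pd.DataFrame,
    provenance: list,
    panel,
    p_exposure: float,
    p_biomarker: float,
    r2_clump: float,
) -> pd.DataFrame:
    n = len(cand)
    cand = cand.loc[cand["pvalue_exp"] < p_exposure]
    provenance.append((f"exposure_p<{p_exposure:g}", n - len(cand)))
    n = len(cand)
    cand = cand.loc[cand["pvalue_bio"] < p_biomarker]
    provenance.append((f"biomarker_p<{p_biomarker:g}", n - len(cand)))
    n = len(cand)
    concordant = np.sign(cand["beta_exp"]) == np.sign(cand["beta_bio"])
    concordant &= cand["beta_exp"] != 0
    cand = cand.loc[concordant]
    provenance.append(("concordant_direction", n - len(cand)))
    n = len(cand)
    cand = clump(cand.reset_index(drop=True), panel, r2_clump)
    provenance.append((f"clump_r2>{r2_clump:g}", n - len(cand)))
    return cand.drop(columns=["pvalue"]).reset_index(drop=True)


def select_cis(
    disease: SumStats,
    biomarker: SumStats,
    region: Region,
    *,
    panel,
    p_exposure: float = 5e-6,
    p_biomarker: float = 0.05,
    r2_clump: float = 0.1,
    palindrome_eaf_band: float = 0.42,
) -> InstrumentSet:
    """Select cis instruments inside one gene region.

    Retains variants with disease p strictly below ``p_exposure``, biomarker p
    strictly below ``p_biomarker``, and a concordant direction of effect on
    the harmonised allele, then clumps at ``r2_clump``.  An empty final set is
    returned explicitly (MR refuses it informatively downstream).
    """
    provenance: list = []
    d_reg = extract_region(disease, region)
    provenance.append((f"region_{region.name}", len(disease) - len(d_reg)))
    pair = harmonise_pair(d_reg, biomarker, palindrome_eaf_band)
    provenance.append(("harmonise_biomarker", len(d_reg) - len(pair)))
    cand = _candidate_table(pair, region.name)
    cand = _apply_filters(cand, provenance, panel, p_exposure, p_biomarker, r2_clump)
    if cand.empty:
        logger.info("select_cis %s: no instruments survived", region.name)
    return InstrumentSet(cand, tuple(provenance), LOG_ODDS_SCALE, disease.trait)


def select_genomewide(
    disease: SumStats,
    biomarker: SumStats,
    exclude: list[Region],
    *,
    panel,
    p_exposure: float = 5e-6,
    p_biomarker: float = 0.05,
    r2_clump: float = 0.1,
    palindrome_eaf_band: float = 0.42,
) -> InstrumentSet:
    """Select the genome-wide comparator instrument set.

    Applies the same thresholds, concordance rule and clumping as
    :func:`select_cis` across the whole input, after removing every variant
    inside any of the ``exclude`` regions (flanks included).
    """
    provenance: list = []
    chrom = disease.table["chrom"].to_numpy(object)
    pos = disease.table["pos"].to_numpy()
    excluded = np.zeros(len(disease), dtype=bool)
    for region in exclude:
        excluded |= region.contains(chrom, pos)
    from dataclasses import replace as _replace
    d = _replace(disease, table=disease.table.loc[~excluded].reset_index(drop=True))
    provenance.append(("exclude_regions", int(excluded.sum())))
    pair = harmonise_pair(d, biomarker, palindrome_eaf_band)
    provenance.append(("harmonise_biomarker", len(d) - len(pair)))
    cand = _candidate_table(pair, pair["chrom"])
    cand = _apply_filters(cand, provenance, panel, p_exposure, p_biomarker, r2_clump)
    return InstrumentSet(cand, tuple(provenance), LOG_ODDS_SCALE, disease.trait)


def filter_pleiotropy(
    inst: InstrumentSet,
    conditional: ColocResult | None,
    *,
    panel,
    r2_mask: float = 0.2,
) -> InstrumentSet:
    """Remove instruments tagging an outcome-specific association signal.

    When the initial colocalisation favoured distinct causal variants (so a
    conditional re-run was performed), instruments in LD (r² strictly greater
    than ``r2_mask``) with the outcome's distinct top variant are removed —
    the same masking set the conditional re-run used.  Otherwise the set is
    returned unchanged.  The removal is recorded in provenance either way.
    """
    if conditional is None or conditional.conditioned_on is None or inst.is_empty:
        return replace(inst, provenance=inst.provenance + (("pleiotropy_filter", 0),))
    top = conditional.conditioned_on
    ids = inst.table["variant_id"].tolist()
    r = panel.r_with(top, ids)
    remove = (r**2 > r2_mask) | (np.asarray(ids, dtype=object) == top)
    kept = inst.table.loc[~remove].reset_index(drop=True)
    return replace(
        inst, table=kept,
        provenance=inst.provenance + ((f"pleiotropy_filter_r2>{r2_mask:g}", int(remove.sum())),),
    )


def attach_outcome(inst: InstrumentSet, outcome: SumStats,
                   palindrome_eaf_band: float = 0.42) -> InstrumentSet:
    """Merge an outcome's estimates onto the instruments, harmonised to the
    instrument effect allele.  Instruments missing from the outcome GWAS or
    with irreconcilable alleles are dropped (recorded in provenance)."""
    if inst.is_empty:
        return replace(inst, outcome_trait=outcome.trait, outcome_type=outcome.trait_type,
                       provenance=inst.provenance + ((f"attach_{outcome.trait}", 0),))
    m = inst.table.merge(
        outcome.table.rename(columns={
            "ea": "ea_2", "nea": "nea_2", "eaf": "eaf_2", "beta": "beta_2",
            "se": "se_2", "pvalue": "pvalue_2", "n": "n_2",
        })[["variant_id", "ea_2", "nea_2", "eaf_2", "beta_2", "se_2", "pvalue_2", "n_2"]],
        on="variant_id", how="inner",
    )
    aligned = m.rename(columns={"ea": "ea_1", "nea": "nea_1", "eaf_exp": "eaf_1"})
    action = align_actions(aligned, palindrome_eaf_band) if len(m) else pd.Series([], dtype=object)
    keep = ~action.isin(_DROP_ACTIONS)
    m = m.loc[keep].copy()
    action = action.loc[keep]
    flipped = action.isin(("flip", "strand_flip")).to_numpy()
    m.loc[flipped, "beta_2"] = -m.loc[flipped, "beta_2"]
    m.loc[flipped, "eaf_2"] = 1.0 - m.loc[flipped, "eaf_2"]
    table = m.rename(columns={
        "beta_2": "beta_out", "se_2": "se_out", "pvalue_2": "pvalue_out", "n_2": "n_out",
    }).drop(columns=["ea_2", "nea_2", "eaf_2"]).reset_index(drop=True)
    removed = len(inst.table) - len(table)
    return replace(
        inst, table=table,
        provenance=inst.provenance + ((f"attach_{outcome.trait}", removed),),
        outcome_trait=outcome.trait, outcome_type=outcome.trait_type,
    )


def with_biomarker_exposure(inst: InstrumentSet, biomarker_trait: str) -> InstrumentSet:
    """Re-express the instrument set with the biomarker as the exposure.

    The same variants are kept; the exposure columns are replaced by the
    biomarker association estimates (SD units per allele), supporting the
    sensitivity analysis that redefines the exposure.
    """
    t = inst.table.copy()
    t["beta_exp"] = t["beta_bio"]
    t["se_exp"] = t["se_bio"]
    t["pvalue_exp"] = t["pvalue_bio"]
    return replace(
        inst, table=t,
        provenance=inst.provenance + (("exposure=biomarker", 0),),
        exposure_scale=f"per-1-SD-higher-{biomarker_trait}",
        exposure_trait=biomarker_trait,
    )
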