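"""Synthetic GWAS summary statistics under linkage disequilibrium.

The generator produces the inputs the analysis assumes without any external
download: an LD reference (signed allelic correlation matrix plus variant
manifest) and per-trait marginal association estimates.

Model
-----
For a region with correlation matrix ``R`` and sparse per-allele causal
effects ``b``, the marginal (single-variant) effect estimates are drawn as

    beta_hat = R @ b + S @ L @ z,      z ~ N(0, I),  L L' = R,  S = diag(se)

so the expectation is ``R @ b`` and the noise covariance is ``S R S`` — the
standard large-sample behaviour of GWAS marginal estimates.  Drawing the noise
jointly across variants is essential: distinguishing distinct from shared
causal variants in colocalisation is meaningless under independent noise.

Standard errors reflect sample size and allele frequency:

* quantitative trait (SD units):  se = 1 / sqrt(2 N v (1 - v))
* binary trait (log-odds):        se = 1 / sqrt(2 N v (1 - v) phi (1 - phi))

with ``v`` the effect-allele frequency and ``phi`` the case fraction.

All randomness flows from explicit integer seeds; there is no global state.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import toeplitz, block_diag

from .sumstats import SumStats, Region, write_sumstats, write_regions

__all__ = [
    "LdPanel", "Scenario", "TraitSpec", "make_ld_panel", "concat_panels",
    "simulate_trait", "simulate_sumstats", "simulate_genomewide",
    "make_study", "make_study_layout", "write_study",
    "read_ld_panel", "write_ld_panel",
]

# p-values are floored so that extremely strong signals remain representable
# and valid under the (0, 1] invariant
_P_FLOOR = 1e-300

# effect/other allele pairs used for simulated variants; complementary
# (palindromic) pairs are excluded so harmonisation is unambiguous
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class LdPanel:
    """Variant manifest plus signed pairwise allelic correlation matrix.

    ``R`` holds signed r (not r-squared); the r² used by clumping and
    conditioning thresholds is ``R**2`` elementwise.
    """

    variant_ids: np.ndarray
    chrom: np.ndarray
    positions: np.ndarray
    ea: np.ndarray
    nea: np.ndarray
    eaf: np.ndarray
    R: np.ndarray
    _index: dict = field(init=False, repr=False)
    _chol: np.ndarray | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.eaf = np.asarray(self.eaf, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        n = len(self.variant_ids)
        if self.R.shape != (n, n):
            raise ValueError("R dimension does not match number of variants")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-12):
            raise ValueError("R must have unit diagonal")
        if not np.allclose(self.R, self.R.T, atol=1e-12):
            raise ValueError("R must be symmetric")
        if np.any(np.abs(self.R) > 1 + 1e-12):
            raise ValueError("R entries must lie in [-1, 1]")
        for c in np.unique(self.chrom):
            p = self.positions[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != n:
            raise ValueError("duplicate variant identifiers in panel")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in LD panel") from None

    def submatrix(self, variant_ids: Sequence[str]) -> np.ndarray:
        """Signed correlation submatrix for the given variants, in order."""
        idx = [self.index_of(v) for v in variant_ids]
        return self.R[np.ix_(idx, idx)]

    def r_with(self, variant_id: str, variant_ids: Sequence[str]) -> np.ndarray:
        """Signed correlation of one variant with each of a list of variants."""
        i = self.index_of(variant_id)
        idx = [self.index_of(v) for v in variant_ids]
        return self.R[i, idx]

    def cholesky(self) -> np.ndarray:
        if self._chol is None:
            self._chol = np.linalg.cholesky(self.R)
        return self._chol

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variant_id": self.variant_ids, "chrom": self.chrom,
            "pos": self.positions, "ea": self.ea, "nea": self.nea,
            "eaf": self.eaf,
        })


def make_ld_panel(
    n_variants: int,
    decay: float = 0.9,
    maf_low: float = 0.05,
    maf_high: float = 0.45,
    seed: int = 0,
    *,
    chrom: str = "1",
    start: int = 1_000_000,
    spacing: int = 500,
    id_start: int = 1,
) -> LdPanel:
    """Build a first-order autoregressive LD panel.

    Adjacent variants have correlation ``decay`` and correlation decays
    geometrically with index distance (``R[i, j] = decay ** |i - j|``), which
    is positive definite by construction for ``|decay| < 1``.  Allele
    frequencies are drawn uniformly with minor-allele frequency in
    ``[maf_low, maf_high]`` and random orientation.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if not (0 < maf_low <= maf_high < 0.5):
        raise ValueError("require 0 < maf_low <= maf_high < 0.5")
    if not (0 <= decay < 1):
        raise ValueError("decay must lie in [0, 1) for a positive-definite panel")
    rng = np.random.default_rng(seed)
    R = toeplitz(decay ** np.arange(n_variants))
    maf = rng.uniform(maf_low, maf_high, size=n_variants)
    flip = rng.random(n_variants) < 0.5
    eaf = np.where(flip, 1.0 - maf, maf)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_variants)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    nea = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    ids = np.array([f"rs{id_start + i}" for i in range(n_variants)], dtype=object)
    positions = start + spacing * np.arange(n_variants)
    chroms = np.full(n_variants, chrom, dtype=object)
    return LdPanel(ids, chroms, positions, ea, nea, eaf, R)


def concat_panels(panels: Sequence[LdPanel]) -> LdPanel:
    """Concatenate panels into one block-diagonal (mutually unlinked) panel."""
    return LdPanel(
        np.concatenate([p.variant_ids for p in panels]),
        np.concatenate([p.chrom for p in panels]),
        np.concatenate([p.positions for p in panels]),
        np.concatenate([p.ea for p in panels]),
        np.concatenate([p.nea for p in panels]),
        np.concatenate([p.eaf for p in panels]),
        block_diag(*[p.R for p in panels]),
    )


def write_ld_panel(panel: LdPanel, manifest_path, matrix_path) -> None:
    """Write the panel as a variant manifest TSV plus a dense matrix TSV."""
    panel.manifest().to_csv(manifest_path, sep="\t", index=False)
    np.savetxt(matrix_path, panel.R, fmt="%.10g", delimiter="\t")


def read_ld_panel(manifest_path, matrix_path) -> LdPanel:
    man = pd.read_csv(manifest_path, sep="\t", dtype={"chrom": str, "variant_id": str})
    R = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    return LdPanel(
        man["variant_id"].to_numpy(object), man["chrom"].to_numpy(object),
        man["pos"].to_numpy(), man["ea"].to_numpy(object),
        man["nea"].to_numpy(object), man["eaf"].to_numpy(), R,
    )


# ---------------------------------------------------------------------------
# scenarios and trait simulation


@dataclass(frozen=True)
class TraitSpec:
    """Sampling design of one trait's GWAS."""

    n: int
    trait_type: str = "quantitative"
    case_fraction: float | None = None
    name: str = "trait"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("sample size must be >= 2")
        if self.trait_type == "binary":
            if self.case_fraction is None or not (0 < self.case_fraction < 1):
                raise ValueError("binary trait requires case_fraction in (0, 1)")


_HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass(frozen=True)
class Scenario:
    """Causal configuration for a simulated trait pair over one region.

    The hypothesis label encodes the causal configuration the five
    colocalisation hypotheses distinguish: no signal (H0), trait 1 only (H1),
    trait 2 only (H2), distinct causal variants (H3), shared causal variant
    (H4).
    """

    hypothesis: str
    trait1: TraitSpec
    trait2: TraitSpec
    causal1: tuple[int, ...] = ()
    effects1: tuple[float, ...] = ()
    causal2: tuple[int, ...] = ()
    effects2: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hypothesis not in _HYPOTHESES:
            raise ValueError(f"hypothesis must be one of {_HYPOTHESES}")
        if len(self.causal1) != len(self.effects1) or len(self.causal2) != len(self.effects2):
            raise ValueError("causal indices and effects must have equal length")
        if not all(np.isfinite(self.effects1)) or not all(np.isfinite(self.effects2)):
            raise ValueError("causal effects must be finite")
        h = self.hypothesis
        if h == "H0" and (self.causal1 or self.causal2):
            raise ValueError("H0 scenario must have no causal variants")
        if h == "H1" and (not self.causal1 or self.causal2):
            raise ValueError("H1 scenario: trait 1 causal only")
        if h == "H2" and (self.causal1 or not self.causal2):
            raise ValueError("H2 scenario: trait 2 causal only")
        if h == "H3":
            if not self.causal1 or not self.causal2 or set(self.causal1) & set(self.causal2):
                raise ValueError("H3 scenario requires disjoint, nonempty causal sets")
        if h == "H4" and (not self.causal1 or set(self.causal1) != set(self.causal2)):
            raise ValueError("H4 scenario requires identical nonempty causal sets")

    @classmethod
    def null(cls, trait1: TraitSpec, trait2: TraitSpec, seed: int = 0) -> "Scenario":
        return cls("H0", trait1, trait2, seed=seed)

    @classmethod
    def shared(cls, index: int, effect1: float, effect2: float,
               trait1: TraitSpec, trait2: TraitSpec, seed: int = 0) -> "Scenario":
        return cls("H4", trait1, trait2, (index,), (effect1,), (index,), (effect2,), seed)

    @classmethod
    def distinct(cls, index1: int, effect1: float, index2: int, effect2: float,
                 trait1: TraitSpec, trait2: TraitSpec, seed: int = 0) -> "Scenario":
        return cls("H3", trait1, trait2, (index1,), (effect1,), (index2,), (effect2,), seed)


def _standard_errors(panel: LdPanel, spec: TraitSpec) -> np.ndarray:
    v = panel.eaf
    het = 2.0 * v * (1.0 - v)
    if spec.trait_type == "binary":
        phi = spec.case_fraction
        return 1.0 / np.sqrt(spec.n * het * phi * (1.0 - phi))
    return 1.0 / np.sqrt(spec.n * het)


def simulate_trait(
    panel: LdPanel,
    spec: TraitSpec,
    causal: Mapping[int, float] | None,
    rng: np.random.Generator,
) -> SumStats:
    """Draw one trait's marginal summary statistics over a panel.

    ``causal`` maps variant index to per-allele causal effect on the trait's
    native scale (log-odds for binary, SD units for quantitative).
    """
    m = len(panel)
    b = np.zeros(m)
    for idx, eff in (causal or {}).items():
        if not (0 <= idx < m):
            raise IndexError(f"causal index {idx} outside panel of {m} variants")
        b[idx] = eff
    se = _standard_errors(panel, spec)
    mean = panel.R @ b
    noise = panel.cholesky() @ rng.standard_normal(m)
    beta_hat = mean + se * noise
    z = beta_hat / se
    pvalue = np.maximum(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR)
    table = pd.DataFrame({
        "variant_id": panel.variant_ids, "chrom": panel.chrom,
        "pos": panel.positions, "ea": panel.ea, "nea": panel.nea,
        "eaf": panel.eaf, "beta": beta_hat, "se": se, "pvalue": pvalue,
        "n": float(spec.n),
    })
    return SumStats(trait=spec.name, trait_type=spec.trait_type, table=table)


def simulate_sumstats(panel: LdPanel, scenario: Scenario) -> tuple[SumStats, SumStats]:
    """Simulate a trait pair under one causal scenario.

    The two traits' sampling noise is independent (two non-overlapping GWAS
    samples); identical scenarios (including seed) reproduce identical
    tables bit for bit.
    """
    rng = np.random.default_rng(scenario.seed)
    s1 = simulate_trait(panel, scenario.trait1, dict(zip(scenario.causal1, scenario.effects1)), rng)
    s2 = simulate_trait(panel, scenario.trait2, dict(zip(scenario.causal2, scenario.effects2)), rng)
    return s1, s2


# ---------------------------------------------------------------------------
# multi-locus genome and the full synthetic study


@dataclass
class GenomewideStudy:
    """Disease, biomarker and outcome summary statistics over independent loci."""

    disease: SumStats
    biomarker: SumStats
    outcome: SumStats
    panel: LdPanel
    locus_regions: list[Region]
    truth: dict


def simulate_genomewide(
    n_loci: int,
    seed: int = 0,
    *,
    locus_size: int = 10,
    decay: float = 0.9,
    maf_low: float = 0.05,
    maf_high: float = 0.45,
    disease_effect: float = 0.12,
    biomarker_slope: float = 0.15,
    outcome_slope: float = -0.1,
    causal_loci: Sequence[int] | None = None,
    disease_spec: TraitSpec | None = None,
    biomarker_spec: TraitSpec | None = None,
    outcome_spec: TraitSpec | None = None,
    id_start: int = 1_000_000,
    panel_seed: int | None = None,
) -> GenomewideStudy:
    """Simulate a disease/biomarker/outcome trio across independent loci.

    Each locus is an AR(1) block with one causal variant at its centre (for
    the loci listed in ``causal_loci``; all loci by default).  The disease
    per-allele effect alternates in sign across loci; biomarker and outcome
    causal effects are ``biomarker_slope`` and ``outcome_slope`` times the
    disease effect, giving a constant outcome-per-log-odds slope for the
    comparator analysis to recover.  Loci are block-diagonal in LD and tagged
    by their own region label.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if panel_seed is None:
        panel_seed = seed
    prng = np.random.default_rng(panel_seed)
    panels, regions = [], []
    for k in range(n_loci):
        chrom = str(k % 22 + 1)
        base = 30_000_000 + 5_000_000 * (k // 22)
        p = make_ld_panel(locus_size, decay, maf_low, maf_high,
                          seed=int(prng.integers(2**31)), chrom=chrom, start=base,
                          id_start=id_start + k * locus_size)
        panels.append(p)
        regions.append(Region(f"locus{k:02d}", chrom, base, int(p.positions[-1])))
    panel = concat_panels(panels)

    if causal_loci is None:
        causal_loci = range(n_loci)
    b_dis, b_bio, b_out = {}, {}, {}
    for k in causal_loci:
        idx = k * locus_size + locus_size // 2
        eff = disease_effect * (-1.0) ** k
        b_dis[idx] = eff
        b_bio[idx] = biomarker_slope * eff
        b_out[idx] = outcome_slope * eff

    disease_spec = disease_spec or TraitSpec(1_407_282, "binary", 0.162, "disease")
    biomarker_spec = biomarker_spec or TraitSpec(344_182, "quantitative", name="biomarker")
    outcome_spec = outcome_spec or TraitSpec(343_992, "quantitative", name="outcome")
    rng = np.random.default_rng(seed)
    disease = simulate_trait(panel, disease_spec, b_dis, rng)
    biomarker = simulate_trait(panel, biomarker_spec, b_bio, rng)
    outcome = simulate_trait(panel, outcome_spec, b_out, rng)
    truth = {"outcome_slope": outcome_slope, "biomarker_slope": biomarker_slope,
             "disease_effects": b_dis}
    return GenomewideStudy(disease, biomarker, outcome, panel, regions, truth)


#: outcome designs of the default synthetic study.  ``cis_slope`` maps gene
#: region name to the outcome effect per unit higher disease log-odds mediated
#: at that region's causal variant; ``gw_slope`` is the analogous slope at the
#: background (genome-wide) loci; ``extra_causal`` adds an outcome-only causal
#: variant (region, index, per-allele effect) to exercise the conditional
#: colocalisation and pleiotropy-filter paths.
DEFAULT_OUTCOMES: dict[str, dict] = {
    "triacylglycerol": dict(trait_type="quantitative", n=343_992,
                            cis_slope={"GIP": -0.25, "GIPR": -0.25}, gw_slope=-0.1),
    "coronary_artery_disease": dict(trait_type="binary", n=184_305, case_fraction=0.33,
                                    cis_slope={"GIP": 0.97}, gw_slope=0.3),
    "systolic_bp": dict(trait_type="quantitative", n=745_820,
                        cis_slope={"GIP": -0.25}, gw_slope=-0.1,
                        extra_causal=[("GIP", 2, -0.05)]),
    "unrelated_trait": dict(trait_type="quantitative", n=300_000,
                            cis_slope={}, gw_slope=0.0),
}


@dataclass
class StudyLayout:
    """Fixed part of a synthetic study: LD panel, gene regions, background
    loci, and the causal variant indices.  Reused across noise replicates."""

    panel: LdPanel
    gene_regions: list[Region]
    locus_regions: list[Region]
    cis_causal: dict[str, int]          # region name -> causal index in panel
    locus_causal: dict[str, int]        # locus name -> causal index in panel
    region_slices: dict[str, slice]


@dataclass
class SyntheticStudy:
    """A complete synthetic dataset for the pipeline, plus its ground truth."""

    disease: SumStats
    biomarker: SumStats
    outcomes: dict[str, SumStats]
    regions: list[Region]
    locus_regions: list[Region]
    panel: LdPanel
    truth: dict
    layout: StudyLayout


def make_study_layout(
    *,
    panel_seed: int = 7,
    n_region_variants: int = 50,
    region_decay: float = 0.9,
    n_loci: int = 20,
    locus_size: int = 10,
    locus_decay: float = 0.9,
    maf_low: float = 0.05,
    maf_high: float = 0.45,
) -> StudyLayout:
    """Build the LD panel and region map of the synthetic study.

    Two cis gene regions (named GIP on chromosome 17 and GIPR on chromosome
    19, mirroring the drug-target setting) each carry ``n_region_variants``
    variants with AR(1) correlation; ``n_loci`` independent background loci
    supply the genome-wide comparator.  The causal variant of every region or
    locus sits at its centre.
    """
    prng = np.random.default_rng(panel_seed)
    gene_defs = [("GIP", "17"), ("GIPR", "19")]
    panels, gene_regions, cis_causal = [], [], {}
    offset = 0
    region_slices = {}
    for name, chrom in gene_defs:
        p = make_ld_panel(n_region_variants, region_decay, maf_low, maf_high,
                          seed=int(prng.integers(2**31)), chrom=chrom, start=1_000_000,
                          id_start=1 + offset)
        panels.append(p)
        gene_regions.append(Region(name, chrom, 1_000_000, int(p.positions[-1])))
        cis_causal[name] = offset + n_region_variants // 2
        region_slices[name] = slice(offset, offset + n_region_variants)
        offset += n_region_variants

    locus_regions, locus_causal = [], {}
    for k in range(n_loci):
        chrom = str(k % 22 + 1)
        base = 30_000_000 + 5_000_000 * (k // 22)
        p = make_ld_panel(locus_size, locus_decay, maf_low, maf_high,
                          seed=int(prng.integers(2**31)), chrom=chrom, start=base,
                          id_start=1_000_001 + k * locus_size)
        panels.append(p)
        name = f"locus{k:02d}"
        locus_regions.append(Region(name, chrom, base, int(p.positions[-1])))
        locus_causal[name] = offset + locus_size // 2
        region_slices[name] = slice(offset, offset + locus_size)
        offset += locus_size

    return StudyLayout(concat_panels(panels), gene_regions, locus_regions,
                       cis_causal, locus_causal, region_slices)


def make_study(
    seed: int = 0,
    *,
    layout: StudyLayout | None = None,
    disease_effect: float = 0.15,
    locus_disease_effect: float = 0.12,
    biomarker_slope: float = 0.15,
    n_disease: int = 1_407_282,
    disease_case_fraction: float = 0.162,
    n_biomarker: int = 344_182,
    outcomes: Mapping[str, dict] | None = None,
    **layout_kwargs,
) -> SyntheticStudy:
    """Generate a full synthetic study: disease (binary exposure GWAS),
    glycaemic biomarker, and a set of cardiometabolic outcomes over two cis
    gene regions plus independent background loci.

    Defaults emulate the published study conditions: a large case-control
    disease GWAS (N ≈ 1.4 M, case fraction 0.162), a quantitative biomarker
    GWAS (N ≈ 344 k), per-allele cis disease effects of 0.15 on the log-odds
    scale, and outcome effects mediated through disease liability with a
    per-log-odds slope of -0.25 at the target genes versus -0.1 genome-wide.
    ``truth`` records the per-halving effect each analysis should recover.
    """
    if layout is None:
        layout = make_study_layout(**layout_kwargs)
    elif layout_kwargs:
        raise ValueError("layout_kwargs ignored when an explicit layout is given")
    outcomes = DEFAULT_OUTCOMES if outcomes is None else outcomes
    panel = layout.panel
    ln2 = np.log(2.0)

    b_dis = {idx: disease_effect for idx in layout.cis_causal.values()}
    for k, (name, idx) in enumerate(sorted(layout.locus_causal.items())):
        b_dis[idx] = locus_disease_effect * (-1.0) ** k
    b_bio = {idx: biomarker_slope * eff for idx, eff in b_dis.items()}

    rng = np.random.default_rng(seed)
    disease = simulate_trait(
        panel, TraitSpec(n_disease, "binary", disease_case_fraction, "type_2_diabetes"),
        b_dis, rng)
    biomarker = simulate_trait(
        panel, TraitSpec(n_biomarker, "quantitative", name="hba1c"), b_bio, rng)

    out_stats: dict[str, SumStats] = {}
    truth: dict = {"disease_effect": disease_effect, "per_halving": {}, "gw_per_halving": {},
                   "cis_slopes": {}, "gw_slopes": {}}
    for name, spec in outcomes.items():
        b = {}
        for region_name, slope in spec.get("cis_slope", {}).items():
            b[layout.cis_causal[region_name]] = slope * disease_effect
        gw_slope = spec.get("gw_slope", 0.0)
        for locus_name, idx in layout.locus_causal.items():
            if gw_slope:
                b[idx] = gw_slope * b_dis[idx]
        for region_name, rel_idx, eff in spec.get("extra_causal", []):
            b[layout.region_slices[region_name].start + rel_idx] = eff
        tspec = TraitSpec(spec["n"], spec["trait_type"], spec.get("case_fraction"), name)
        out_stats[name] = simulate_trait(panel, tspec, b, rng)
        slopes = set(spec.get("cis_slope", {}).values())
        truth["cis_slopes"][name] = dict(spec.get("cis_slope", {}))
        truth["gw_slopes"][name] = gw_slope
        if len(slopes) == 1:
            truth["per_halving"][name] = -next(iter(slopes)) * ln2
        truth["gw_per_halving"][name] = -gw_slope * ln2

    return SyntheticStudy(disease, biomarker, out_stats, layout.gene_regions,
                          layout.locus_regions, panel, truth, layout)


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Serialise a synthetic study to a directory of plain-text files.

    Writes the tab-delimited summary statistics, the LD manifest and matrix,
    the gene-region definitions, and returns the path map.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_sumstats(study.disease, _p("disease.tsv"))
    write_sumstats(study.biomarker, _p("biomarker.tsv"))
    for name, ss in study.outcomes.items():
        write_sumstats(ss, _p(f"outcome_{name}.tsv"))
    write_ld_panel(study.panel, _p("ld_manifest.tsv"), _p("ld_matrix.tsv"))
    write_regions(study.regions, _p("regions.tsv"))
    return paths
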