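"""GWAS summary statistics: containers, tab-delimited I/O, region subsetting,
and allele harmonisation of trait pairs.

A :class:`SumStats` holds one trait's per-variant marginal association
estimates.  Binary traits are on the log-odds-per-allele scale, quantitative
traits in phenotype-SD units per allele.  Coordinates are 1-based inclusive
throughout, following the dominant published GWAS summary-file convention
(this is *not* the half-open BED convention).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical internal column order of a SumStats table
CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "ea", "nea",
    "eaf", "beta", "se", "pvalue", "n",
]

#: default file header names mapped onto the canonical columns
DEFAULT_HEADER = {
    "variant_id": "SNP", "chrom": "CHR", "pos": "POS", "ea": "EA",
    "nea": "NEA", "eaf": "EAF", "beta": "BETA", "se": "SE",
    "pvalue": "P", "n": "N",
}

TRAIT_TYPES = ("binary", "quantitative")


@dataclass
class SumStats:
    """One trait's GWAS summary statistics.

    Parameters
    ----------
    trait
        Trait name (e.g. ``"type_2_diabetes"``).
    trait_type
        ``"binary"`` (effects are log-odds per allele) or ``"quantitative"``
        (effects in SD units per allele).
    table
        One row per variant with the :data:`CANONICAL_COLUMNS`.
    """

    trait: str
    trait_type: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(f"trait_type must be one of {TRAIT_TYPES}, got {self.trait_type!r}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"SumStats table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class Region:
    """A genomic region, 1-based inclusive on both ends.

    ``flank`` base pairs are added to both sides when subsetting.
    """

    name: str
    chrom: str
    start: int
    end: int
    flank: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start {self.start} > end {self.end}")
        if self.flank < 0:
            raise ValueError(f"region {self.name}: negative flank")

    def contains(self, chrom, pos) -> np.ndarray:
        """Vectorised membership test (flank included)."""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos)
        return (chrom == self.chrom) & (pos >= self.start - self.flank) & (pos <= self.end + self.flank)


def _clean(df: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Drop rows violating the SumStats invariants; log how many were lost."""
    n0 = len(df)
    ok = (
        np.isfinite(df["beta"].to_numpy(float))
        & np.isfinite(df["se"].to_numpy(float))
        & (df["se"].to_numpy(float) > 0)
        & (df["eaf"].to_numpy(float) > 0)
        & (df["eaf"].to_numpy(float) < 1)
        & (df["pvalue"].to_numpy(float) > 0)
        & (df["pvalue"].to_numpy(float) <= 1)
        & (df["n"].to_numpy(float) > 0)
        & df["ea"].isin(VALID_ALLELES).to_numpy()
        & df["nea"].isin(VALID_ALLELES).to_numpy()
        & (df["ea"] != df["nea"]).to_numpy()
    )
    df = df.loc[ok]
    df = df.loc[~df["variant_id"].duplicated(keep="first")]
    dropped = n0 - len(df)
    if dropped:
        logger.warning("%s: dropped %d/%d rows failing validation", trait, dropped, n0)

    # soft cross-check: p-value should agree with |beta/se| under the normal
    # approximation to within two orders of magnitude
    with np.errstate(divide="ignore"):
        z = np.abs(df["beta"].to_numpy(float) / df["se"].to_numpy(float))
        p_expected = np.maximum(2.0 * stats.norm.sf(z), 1e-300)
        lp = np.log10(df["pvalue"].to_numpy(float))
        lpe = np.log10(p_expected)
    inconsistent = int(np.sum(np.abs(lp - lpe) > 2.0))
    if inconsistent:
        logger.warning(
            "%s: %d rows have p-values inconsistent with beta/se by >2 orders of magnitude",
            trait, inconsistent,
        )
    return df.reset_index(drop=True)


def read_sumstats(path, trait: str, trait_type: str, header_map: dict | None = None) -> SumStats:
    """Read a tab-delimited summary-statistics file.

    ``header_map`` maps canonical column names to the file's header names;
    unspecified entries fall back to :data:`DEFAULT_HEADER`.  A missing
    mandatory column or an empty table is a hard error; rows failing the
    per-variant invariants are dropped with a logged count.
    """
    mapping = dict(DEFAULT_HEADER)
    if header_map:
        mapping.update(header_map)
    raw = pd.read_csv(path, sep="\t", dtype={mapping["chrom"]: str, mapping["variant_id"]: str})
    for canonical, name in mapping.items():
        if name not in raw.columns:
            raise ValueError(f"{path}: mandatory column {name!r} (for {canonical!r}) not found")
    df = raw.rename(columns={v: k for k, v in mapping.items()})[CANONICAL_COLUMNS].copy()
    df["pos"] = df["pos"].astype(np.int64)
    for c in ("eaf", "beta", "se", "pvalue"):
        df[c] = df[c].astype(float)
    df["n"] = df["n"].astype(float)
    if df.empty:
        raise ValueError(f"{path}: empty summary-statistics table")
    df = _clean(df, trait)
    if df.empty:
        raise ValueError(f"{path}: no rows survived validation")
    return SumStats(trait=trait, trait_type=trait_type, table=df)


def write_sumstats(ss: SumStats, path) -> None:
    """Write a SumStats to a tab-delimited file with the default header."""
    out = ss.table[CANONICAL_COLUMNS].rename(columns=DEFAULT_HEADER)
    out.to_csv(path, sep="\t", index=False)


def read_regions(path) -> list[Region]:
    """Read region definitions from TSV with columns name, chrom, start, end
    and optional flank.  Coordinates are 1-based inclusive (not BED)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    regions = []
    for row in df.itertuples(index=False):
        flank = int(getattr(row, "flank", 0) or 0)
        regions.append(Region(str(row.name), str(row.chrom), int(row.start), int(row.end), flank))
    return regions


def write_regions(regions: list[Region], path) -> None:
    pd.DataFrame(
        [(r.name, r.chrom, r.start, r.end, r.flank) for r in regions],
        columns=["name", "chrom", "start", "end", "flank"],
    ).to_csv(path, sep="\t", index=False)


def extract_region(ss: SumStats, region: Region) -> SumStats:
    """Subset to variants inside ``region`` (flank included, ends inclusive),
    preserving variant order.  An empty result is allowed."""
    mask = region.contains(ss.table["chrom"].to_numpy(object), ss.table["pos"].to_numpy())
    return replace(ss, table=ss.table.loc[mask].reset_index(drop=True))


# ---------------------------------------------------------------------------
# allele harmonisation


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(COMPLEMENT)


def align_actions(df: pd.DataFrame, palindrome_eaf_band: float) -> pd.Series:
    """Classify each row of a merged two-trait table by the action needed to
    put trait 2 on trait 1's effect allele.

    Expects columns ``ea_1, nea_1, eaf_1, ea_2, nea_2, eaf_2``.  Returns one of
    ``match | flip | strand | strand_flip | palindromic_ambiguous |
    irreconcilable`` per row.  Palindromic (A/T, C/G) variants are oriented by
    allele frequency and dropped as ambiguous when the minor-allele frequency
    exceeds ``palindrome_eaf_band`` on either trait.
    """
    ea1, nea1 = df["ea_1"], df["nea_1"]
    ea2, nea2 = df["ea_2"], df["nea_2"]
    cea2, cnea2 = _complement(ea2), _complement(nea2)

    action = pd.Series("irreconcilable", index=df.index, dtype=object)
    palindromic = (ea1 == _complement(nea1))

    # non-palindromic variants: allele comparison resolves strand and order
    match = (ea2 == ea1) & (nea2 == nea1)
    flip = (ea2 == nea1) & (nea2 == ea1)
    strand = (cea2 == ea1) & (cnea2 == nea1)
    strand_flip = (cea2 == nea1) & (cnea2 == ea1)
    action[match & ~palindromic] = "match"
    action[flip & ~palindromic] = "flip"
    action[strand & ~match & ~palindromic] = "strand"
    action[strand_flip & ~flip & ~palindromic] = "strand_flip"

    # palindromic variants: same allele set either way; orient by frequency
    same_set = palindromic & (match | flip)
    maf1 = np.minimum(df["eaf_1"], 1 - df["eaf_1"])
    maf2 = np.minimum(df["eaf_2"], 1 - df["eaf_2"])
    ambiguous = same_set & ((maf1 > palindrome_eaf_band) | (maf2 > palindrome_eaf_band))
    same_side = (df["eaf_1"] - 0.5) * (df["eaf_2"] - 0.5) > 0
    action[same_set & ~ambiguous & same_side] = "match"
    action[same_set & ~ambiguous & ~same_side] = "flip"
    action[ambiguous] = "palindromic_ambiguous"
    return action


_DROP_ACTIONS = ("palindromic_ambiguous", "irreconcilable")


def harmonise_pair(a: SumStats, b: SumStats, palindrome_eaf_band: float = 0.42) -> pd.DataFrame:
    """Harmonise two traits onto trait *a*'s effect alleles.

    Variants are matched on identifier (the intersection); where *b* is coded
    on the opposite allele its beta is negated and its frequency reflected;
    strand-complement codings are resolved; palindromic variants with
    uninformative frequency (MAF > ``palindrome_eaf_band`` on either trait)
    and irreconcilable allele pairs are dropped, with logged counts.

    Returns a DataFrame with columns ``variant_id, chrom, pos, ea, nea``,
    per-trait ``eaf_i, beta_i, se_i, pvalue_i, n_i`` (i = 1, 2) and the
    ``action`` taken per variant.  Trait metadata is carried in ``attrs``.
    """
    m = a.table.merge(b.table, on="variant_id", suffixes=("_1", "_2"), how="inner")
    if len(m) and (m["pos_1"] != m["pos_2"]).any():
        nbad = int((m["pos_1"] != m["pos_2"]).sum())
        logger.warning("harmonise %s/%s: %d variants disagree on position between inputs",
                       a.trait, b.trait, nbad)
    if m.empty:
        action = pd.Series([], dtype=object)
    else:
        action = align_actions(m, palindrome_eaf_band)
    dropped = int(action.isin(_DROP_ACTIONS).sum())
    if dropped:
        logger.warning("harmonise %s/%s: dropped %d variants (%s)",
                       a.trait, b.trait, dropped,
                       dict(action[action.isin(_DROP_ACTIONS)].value_counts()))
    keep = ~action.isin(_DROP_ACTIONS)
    m = m.loc[keep].copy()
    action = action.loc[keep]

    flipped = action.isin(("flip", "strand_flip")).to_numpy()
    m.loc[flipped, "beta_2"] = -m.loc[flipped, "beta_2"]
    m.loc[flipped, "eaf_2"] = 1.0 - m.loc[flipped, "eaf_2"]

    out = pd.DataFrame({
        "variant_id": m["variant_id"].to_numpy(),
        "chrom": m["chrom_1"].to_numpy(),
        "pos": m["pos_1"].to_numpy(),
        "ea": m["ea_1"].to_numpy(),
        "nea": m["nea_1"].to_numpy(),
    })
    for i in ("1", "2"):
        for c in ("eaf", "beta", "se", "pvalue", "n"):
            out[f"{c}_{i}"] = m[f"{c}_{i}"].to_numpy()
    out["action"] = action.to_numpy()
    out.attrs["trait_1"] = a.trait
    out.attrs["trait_2"] = b.trait
    out.attrs["trait_type_1"] = a.trait_type
    out.attrs["trait_type_2"] = b.trait_type
    return out.reset_index(drop=True)
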