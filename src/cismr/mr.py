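"""Mendelian randomisation estimators on summary data.

Single-instrument Wald ratios, inverse-variance-weighted (IVW) pooling with
multiplicative random effects, rescaling of per-log-odds estimates onto the
per-halving-of-disease-odds scale, a z-test contrasting two independent
estimates, and the cross-exposure concordance report.

Sign convention: upstream estimators express effects per one unit *higher*
disease log-odds.  The per-halving rescaling owns the single sign flip onto
the direction of *lower* disease liability (increased target signalling), so
no other module reasons about direction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .instruments import InstrumentSet, LOG_ODDS_SCALE

__all__ = [
    "MrEstimate", "EstimateContrast", "wald_ratio", "ivw",
    "rescale_per_halving", "compare_estimates", "cross_exposure_concordance",
]

Z95 = 1.959963984540054  # normal 97.5% quantile; symmetric 95% CIs

PER_HALVING_SCALE = "per-halving-of-odds"


@dataclass
class MrEstimate:
    """An MR effect estimate with its uncertainty and scale metadata.

    ``scale`` describes the exposure contrast (e.g. per 1-unit higher
    log-odds, per halving of odds, per 1 SD biomarker); ``outcome_scale`` is
    ``"SD-units"`` for quantitative outcomes or ``"log-OR"`` for binary ones.
    ``Q`` is Cochran's heterogeneity statistic, defined for >= 2 instruments.
    For binary outcomes on the per-halving scale the exponentiated odds ratio
    and its CI are carried alongside the log-scale estimate.
    """

    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_instruments: int
    Q: float | None
    scale: str
    outcome_scale: str
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")
        if self.n_instruments >= 1 and not self.se > 0:
            raise ValueError("standard error must be positive")
        if self.Q is not None and self.Q < -1e-12:
            raise ValueError("heterogeneity statistic must be non-negative")


@dataclass(frozen=True)
class EstimateContrast:
    """z-test of the difference between two independent MR estimates."""

    delta: float
    se_delta: float
    z: float
    pvalue: float


def _normal_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def wald_ratio(
    bx: float, se_x: float, by: float, se_y: float,
    *,
    scale: str = LOG_ODDS_SCALE,
    outcome_scale: str = "SD-units",
    second_order: bool = False,
) -> MrEstimate:
    """Single-instrument causal estimate by/bx.

    The default standard error is first order, ``se_y / |bx|``; with
    ``second_order=True`` the delta-method term ``by² se_x² / bx⁴`` is added.
    A zero exposure effect is a hard error (the ratio is undefined).
    """
    if bx == 0:
        raise ValueError("Wald ratio undefined for zero exposure effect")
    beta = by / bx
    var = se_y**2 / bx**2
    if second_order:
        var += by**2 * se_x**2 / bx**4
    se = math.sqrt(var)
    return MrEstimate(
        beta=beta, se=se, ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pvalue=_normal_p(beta, se), n_instruments=1, Q=None,
        scale=scale, outcome_scale=outcome_scale,
    )


def ivw(inst: InstrumentSet, *, second_order: bool = False) -> MrEstimate:
    """Inverse-variance-weighted pooling of per-instrument Wald ratios with
    multiplicative random effects.

    Ratios ``r_i = by_i / bx_i`` are pooled with weights equal to their
    inverse first-order variances, ``w_i = bx_i² / se_y_i²`` (equivalent to a
    weighted least-squares fit of the outcome on the exposure associations
    through the origin).  Cochran's Q is computed on the same weights and the
    standard error is inflated by ``sqrt(max(1, Q / (k - 1)))`` — the
    multiplicative random-effects model, which never deflates below the
    fixed-effect standard error.
    """
    if inst.is_empty:
        raise ValueError(
            f"no instruments available for exposure {inst.exposure_trait!r}"
            " — instrument selection returned an empty set; nothing to pool"
        )
    t = inst.table
    if "beta_out" not in t.columns:
        raise ValueError("instrument set has no outcome estimates attached")
    bx = t["beta_exp"].to_numpy(float)
    by = t["beta_out"].to_numpy(float)
    se_y = t["se_out"].to_numpy(float)
    if np.any(bx == 0):
        raise ValueError("zero exposure effect among instruments; Wald ratio undefined")
    ratios = by / bx
    var = se_y**2 / bx**2
    if second_order:
        se_x = t["se_exp"].to_numpy(float)
        var += by**2 * se_x**2 / bx**4
    w = 1.0 / var
    k = len(ratios)
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(1.0 / math.sqrt(np.sum(w)))
    if k >= 2:
        Q = float(np.sum(w * (ratios - beta) ** 2))
        inflation = math.sqrt(max(1.0, Q / (k - 1)))
    else:
        Q = None
        inflation = 1.0
    se = se_fixed * inflation
    outcome_scale = "log-OR" if inst.outcome_type == "binary" else "SD-units"
    return MrEstimate(
        beta=beta, se=se, ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pvalue=_normal_p(beta, se), n_instruments=k, Q=Q,
        scale=inst.exposure_scale, outcome_scale=outcome_scale,
    )


def rescale_per_halving(est: MrEstimate) -> MrEstimate:
    """Express a per-unit-log-odds estimate per halving of disease odds.

    Halving the odds lowers the log-odds by ln 2, so the estimate and its
    uncertainty are multiplied by ln 2 and the sign inverted to report the
    effect in the direction of lower disease liability.  Being an exact
    affine map, the p-value is unchanged.  For binary outcomes the rescaled
    log-OR and CI are additionally exponentiated to an odds ratio.  Applying
    the rescaling twice is rejected via the scale descriptor.
    """
    if est.scale != LOG_ODDS_SCALE:
        raise ValueError(
            f"rescale_per_halving expects scale {LOG_ODDS_SCALE!r}, got {est.scale!r}"
        )
    ln2 = math.log(2.0)
    beta = -ln2 * est.beta
    se = ln2 * est.se
    ci_low, ci_high = -ln2 * est.ci_high, -ln2 * est.ci_low
    out = replace(
        est, beta=beta, se=se, ci_low=ci_low, ci_high=ci_high,
        scale=PER_HALVING_SCALE,
    )
    if est.outcome_scale == "log-OR":
        out.odds_ratio = math.exp(beta)
        out.or_ci_low = math.exp(ci_low)
        out.or_ci_high = math.exp(ci_high)
    return out


def flip_direction(est: MrEstimate, new_scale: str) -> MrEstimate:
    """Negate an estimate to re-orient its exposure contrast (e.g. per 1 SD
    lower rather than higher biomarker); p-value and width unchanged."""
    return replace(est, beta=-est.beta, ci_low=-est.ci_high, ci_high=-est.ci_low,
                   scale=new_scale)


def compare_estimates(cis: MrEstimate, gw: MrEstimate) -> EstimateContrast:
    """Two-sided z-test of cis estimate minus comparator estimate.

    Both estimates must be on the same exposure and outcome scales.  The two
    are treated as independent — appropriate here because the cis variants
    are excluded from the comparator set — so the variance of the difference
    is the sum of variances.
    """
    if cis.scale != gw.scale or cis.outcome_scale != gw.outcome_scale:
        raise ValueError(
            f"scale mismatch: ({cis.scale}, {cis.outcome_scale}) vs ({gw.scale}, {gw.outcome_scale})"
        )
    delta = cis.beta - gw.beta
    se_delta = math.sqrt(cis.se**2 + gw.se**2)
    z = delta / se_delta
    return EstimateContrast(delta=delta, se_delta=se_delta, z=z,
                            pvalue=float(2.0 * stats.norm.sf(abs(z))))


def cross_exposure_concordance(
    estimates_a: Sequence, estimates_b: Sequence,
) -> float:
    """Pearson correlation between two matched vectors of MR betas.

    Accepts sequences of :class:`MrEstimate` or plain numbers; requires the
    same outcomes in the same order and at least three pairs.
    """
    if len(estimates_a) != len(estimates_b):
        raise ValueError("estimate lists differ in length")
    if len(estimates_a) < 3:
        raise ValueError("need at least three estimate pairs for a correlation")
    a = np.array([e.beta if isinstance(e, MrEstimate) else float(e) for e in estimates_a])
    b = np.array([e.beta if isinstance(e, MrEstimate) else float(e) for e in estimates_b])
    return float(np.corrcoef(a, b)[0, 1])
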