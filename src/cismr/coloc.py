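"""Bayesian colocalisation of two traits' association signals over a region.

Each variant gets a Wakefield-style approximate Bayes factor per trait,

    log ABF = 1/2 [ log(1 - r) + r z^2 ],    r = w / (w + se^2),  z = beta/se,

comparing a normal prior N(0, w) on the true effect against a point null.
The five-hypothesis posterior (no association / trait 1 only / trait 2 only /
two distinct causal variants / one shared causal variant) follows from
summing configuration likelihoods under a single-causal-variant-per-trait
model with per-variant priors p1, p2 and p12.  All accumulation is done in
log space.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "ColocPriors", "ColocResult", "ColocDecision", "log_abf",
    "coloc_posteriors", "conditional_coloc", "coloc_decision",
    "default_prior_variance",
]

HYPOTHESES = ("PP0", "PP1", "PP2", "PP3", "PP4")

#: default prior standard deviation of true effects: 0.2 SD for quantitative
#: traits, 0.15 on the log-odds scale for binary traits (the published
#: defaults of the colocalisation method)
PRIOR_SD = {"quantitative": 0.2, "binary": 0.15}


def default_prior_variance(trait_type: str) -> float:
    """Prior effect variance w for a trait type (0.2² SD or 0.15² log-odds)."""
    return PRIOR_SD[trait_type] ** 2


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities of causality.

    ``p1``/``p2``: causal for trait 1/2 only; ``p12``: causal for both.
    Defaults are the published defaults of the colocalisation method.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("require p1 + p2 + p12 < 1")


@dataclass
class ColocResult:
    """Posterior probabilities and per-variant log ABFs for one trait pair.

    ``status`` is ``"ok"`` or ``"undeterminable"`` (conditional run with every
    variant masked).  ``masked`` lists variants removed before a conditional
    re-run, and ``conditioned_on`` names the outcome top variant that defined
    the mask.
    """

    pp: np.ndarray | None
    labf1: np.ndarray
    labf2: np.ndarray
    variant_ids: np.ndarray
    positions: np.ndarray
    top1: str | None
    top2: str | None
    n_variants: int
    status: str = "ok"
    masked: tuple = ()
    conditioned_on: str | None = None

    @property
    def pp4(self) -> float:
        return float(self.pp[4]) if self.pp is not None else float("nan")

    def modal_hypothesis(self) -> int | None:
        if self.pp is None:
            return None
        return int(np.argmax(self.pp))


@dataclass(frozen=True)
class ColocDecision:
    """Outcome of the two-stage colocalisation rule."""

    colocalises: bool
    evidence_path: str  # "initial" | "conditional" | "none"


def log_abf(beta, se, w: float):
    """Log approximate Bayes factor for a single-variant association.

    Compares the marginal likelihood of the estimate under a N(0, w) prior on
    the true effect against the point-null model.  Vectorised over
    ``beta``/``se``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if not np.all(np.isfinite(beta)) or not np.all(np.isfinite(se)):
        raise ValueError("beta and se must be finite")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if not np.isfinite(w) or w < 0:
        raise ValueError("prior variance w must be finite and >= 0")
    V = se**2
    r = w / (w + V)
    z2 = (beta / se) ** 2
    out = 0.5 * (np.log1p(-r) + r * z2)
    return out if out.ndim else float(out)


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) with round-off clamped to -inf when b >= a."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def _top_variant(labf: np.ndarray, ids: np.ndarray, positions: np.ndarray) -> str:
    # largest log ABF wins; ties broken by smallest position, then identifier
    best = min(range(len(ids)), key=lambda i: (-labf[i], positions[i], str(ids[i])))
    return str(ids[best])


def coloc_posteriors(
    pair: pd.DataFrame,
    priors: ColocPriors = ColocPriors(),
    w1: float | None = None,
    w2: float | None = None,
) -> ColocResult:
    """Five-hypothesis colocalisation posterior from a harmonised trait pair.

    ``pair`` is the output of :func:`cismr.sumstats.harmonise_pair` (columns
    ``beta_1/se_1`` and ``beta_2/se_2`` on a common effect allele).  ``w1`` and
    ``w2`` are the prior effect variances; when omitted they default from the
    trait types recorded in ``pair.attrs``.

    The unnormalised hypothesis weights are H0: 1; H1: p1 Σ e^{L1};
    H2: p2 Σ e^{L2}; H3: p1 p2 (Σ e^{L1} Σ e^{L2} - Σ e^{L1+L2});
    H4: p12 Σ e^{L1+L2}, accumulated with log-sum-exp.  On a single-variant
    region the H3 weight is exactly zero.
    """
    if len(pair) < 1:
        raise ValueError("colocalisation requires at least one shared variant")
    if w1 is None:
        w1 = default_prior_variance(pair.attrs["trait_type_1"])
    if w2 is None:
        w2 = default_prior_variance(pair.attrs["trait_type_2"])
    l1 = np.asarray(log_abf(pair["beta_1"].to_numpy(), pair["se_1"].to_numpy(), w1), dtype=float).reshape(-1)
    l2 = np.asarray(log_abf(pair["beta_2"].to_numpy(), pair["se_2"].to_numpy(), w2), dtype=float).reshape(-1)

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    lw = np.empty(5)
    lw[0] = 0.0
    lw[1] = np.log(priors.p1) + s1
    lw[2] = np.log(priors.p2) + s2
    # cross term: sum over i != j; log-subtraction guarded against round-off
    lw[3] = np.log(priors.p1) + np.log(priors.p2) + _logdiffexp(s1 + s2, s12)
    lw[4] = np.log(priors.p12) + s12
    pp = np.exp(lw - logsumexp(lw))
    pp /= pp.sum()

    ids = pair["variant_id"].to_numpy(object)
    positions = pair["pos"].to_numpy()
    return ColocResult(
        pp=pp, labf1=l1, labf2=l2, variant_ids=ids, positions=positions,
        top1=_top_variant(l1, ids, positions), top2=_top_variant(l2, ids, positions),
        n_variants=len(pair),
    )


def conditional_coloc(
    pair: pd.DataFrame,
    priors: ColocPriors = ColocPriors(),
    w1: float | None = None,
    w2: float | None = None,
    *,
    panel,
    r2_mask: float = 0.2,
) -> ColocResult:
    """Re-run colocalisation after masking the outcome's top signal.

    The outcome's (trait 2's) most likely causal variant is the argmax of its
    log ABF; it and every variant with r² strictly greater than ``r2_mask``
    against it are removed before re-running the posterior computation.  If
    everything is masked the result is returned with
    ``status="undeterminable"`` rather than raising.
    """
    if len(pair) < 1:
        raise ValueError("conditional colocalisation requires at least one variant")
    if w2 is None:
        w2 = default_prior_variance(pair.attrs["trait_type_2"])
    l2 = np.asarray(log_abf(pair["beta_2"].to_numpy(), pair["se_2"].to_numpy(), w2), dtype=float).reshape(-1)
    ids = pair["variant_id"].to_numpy(object)
    positions = pair["pos"].to_numpy()
    top2 = _top_variant(l2, ids, positions)

    r = panel.r_with(top2, list(ids))
    masked = (r**2 > r2_mask) | (ids == top2)
    masked_ids = tuple(str(v) for v in ids[masked])
    kept = pair.loc[~masked].reset_index(drop=True)
    kept.attrs = dict(pair.attrs)
    if kept.empty:
        return ColocResult(
            pp=None, labf1=np.array([]), labf2=np.array([]),
            variant_ids=np.array([], dtype=object), positions=np.array([], dtype=int),
            top1=None, top2=None, n_variants=0, status="undeterminable",
            masked=masked_ids, conditioned_on=top2,
        )
    res = coloc_posteriors(kept, priors, w1, w2)
    res.masked = masked_ids
    res.conditioned_on = top2
    return res


def coloc_decision(
    initial: ColocResult,
    conditional: ColocResult | None = None,
    pp_threshold: float = 0.8,
) -> ColocDecision:
    """Two-stage colocalisation call.

    Colocalisation is declared when the shared-causal-variant posterior
    strictly exceeds ``pp_threshold`` in the initial run, or — after the
    initial run favoured distinct causal variants — in the conditional
    re-run.
    """
    if initial.pp is not None and initial.pp4 > pp_threshold:
        return ColocDecision(True, "initial")
    if (conditional is not None and conditional.status == "ok"
            and conditional.pp4 > pp_threshold):
        return ColocDecision(True, "conditional")
    return ColocDecision(False, "none")
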