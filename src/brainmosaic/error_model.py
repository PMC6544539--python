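"""Beta-binomial panel error model.

A candidate somatic variant must rise above the local sequencing error
rate, not just differ from the heterozygous allele fraction.  The error
rate at a site is estimated from a panel of other cohort samples: alternate
read counts across panel members are overdispersed relative to a binomial,
so they are modelled as beta-binomial.  The candidate's alternate count is
then tested against the fitted null with a one-sided upper-tail
probability; candidates pass when p < 0.001 (strict).

The fit is method-of-moments: the mean error is the pooled alternate
fraction with a Jeffreys-style pseudocount (0.5 alternate / 1 total read
added to the pooled counts, preventing zero-variance degenerate fits), and
the dispersion rho comes from the depth-weighted between-member variability
of per-member allele fractions (Kleinman estimator).  Panels whose
empirical variance does not exceed binomial fall back to a plain binomial
null (rho = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_PANEL_SIZE = 328
DEFAULT_PANEL_P = 0.001


@dataclass
class PanelErrorFit:
    """Fitted site-specific error distribution.

    ``mean_error`` = alpha/(alpha+beta), ``rho`` = 1/(alpha+beta+1).
    ``fit_method`` is ``"moments"`` or ``"fallback_binomial"`` (rho = 0,
    alpha/beta undefined).
    """

    mean_error: float
    rho: float
    alpha: float | None
    beta: float | None
    fit_method: str
    panel_size: int

    def __post_init__(self) -> None:
        if not 0 < self.mean_error < 1:
            raise ValueError("mean_error must be in (0,1)")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0,1)")


def select_panel(
    sample_ids,
    case_sample_id,
    panel_size: int = DEFAULT_PANEL_SIZE,
    seed: int | np.random.Generator = 0,
    individual_of=None,
):
    """Uniform random comparison panel excluding the case sample and any
    other sample from the same individual.

    When fewer than ``panel_size`` samples remain, all of them are used
    (the clamping is visible in the returned list's length).  Deterministic
    for a fixed seed.
    """
    ids = list(sample_ids)
    if case_sample_id not in ids:
        raise ValueError(f"case sample {case_sample_id!r} not in cohort")
    if individual_of is None:
        eligible = [s for s in ids if s != case_sample_id]
    else:
        case_ind = individual_of.get(case_sample_id, case_sample_id)
        eligible = [
            s for s in ids
            if s != case_sample_id and individual_of.get(s, s) != case_ind
        ]
    if not eligible:
        raise ValueError("no comparison samples")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    k = min(panel_size, len(eligible))
    chosen = rng.choice(len(eligible), size=k, replace=False)
    return [eligible[i] for i in sorted(chosen)]


def fit_site_error(panel_alt_counts, panel_depths) -> PanelErrorFit:
    """Method-of-moments beta-binomial fit to panel counts at one site."""
    x = np.asarray(panel_alt_counts, dtype=float)
    n = np.asarray(panel_depths, dtype=float)
    if x.shape != n.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need matched alt/depth vectors of length >= 2")
    if (x < 0).any() or (x > n).any():
        raise ValueError("alt counts must satisfy 0 <= alt <= depth")
    keep = n >= 1
    x, n = x[keep], n[keep]
    if x.size == 0:
        raise ValueError("uninformative panel: all depths zero")
    m = x.size
    total = n.sum()
    mean = (x.sum() + 0.5) / (total + 1.0)  # pseudocount-stabilized pooled mean

    rho = 0.0
    if m >= 2:
        p_i = x / n
        s = float(np.sum(n * (p_i - mean) ** 2))
        denom_scale = mean * (1 - mean)
        # Kleinman weighted moment estimator for the intraclass correlation
        denom = total - np.sum(n**2) / total - (m - 1)
        if denom_scale > 0 and denom > 0:
            rho = (s / denom_scale - (m - 1)) / denom
    if rho <= 0:
        return PanelErrorFit(
            mean_error=mean, rho=0.0, alpha=None, beta=None,
            fit_method="fallback_binomial", panel_size=m,
        )
    rho = min(rho, 1 - 1e-9)
    ab = (1 - rho) / rho  # alpha + beta, since rho = 1/(alpha+beta+1)
    return PanelErrorFit(
        mean_error=mean, rho=rho, alpha=mean * ab, beta=(1 - mean) * ab,
        fit_method="moments", panel_size=m,
    )


def panel_tail_test(case_alt_count, case_depth, fit: PanelErrorFit):
    """Upper-tail probability P(X >= alt_count) of the case count under the
    fitted panel null.  Accepts scalars or arrays (broadcast together)."""
    k = np.asarray(case_alt_count)
    n = np.asarray(case_depth)
    if (n < 1).any():
        raise ValueError("case depth must be >= 1")
    if ((k < 0) | (k > n)).any():
        raise ValueError("need 0 <= alt_count <= depth")
    if fit.fit_method == "fallback_binomial":
        p = stats.binom.sf(k - 1, n, fit.mean_error)
    else:
        p = stats.betabinom.sf(k - 1, n, fit.alpha, fit.beta)
    return p if p.shape else float(p)


def passes_panel(p_value: float, threshold: float = DEFAULT_PANEL_P) -> bool:
    """Strict threshold: a p-value exactly at the threshold fails."""
    return p_value < threshold
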