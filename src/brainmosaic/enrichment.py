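"""Enrichment tests of somatic variants against genomic backgrounds.

Covers: enrichment at bases methylated in the inner cell mass (exact
binomial against the genome-wide methylated fraction), distribution of
variant-containing genes across brain-expression classes and across
quartiles of germline missense constraint, the Bernoulli/Beta posterior for
the probability that a cohort member carries a somatic variant, and the
Fisher exact test for brain-region sampling bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Canonical brain-expression class labels (Human-Protein-Atlas style).
EXPRESSION_CLASSES = (
    "elevated_brain",
    "expressed_all",
    "mixed",
    "not_in_brain",
    "not_detected",
)
#: Classes counted as "expressed within the brain".
BRAIN_EXPRESSED = ("elevated_brain", "expressed_all", "mixed")

# Synthetic stand-in for genome-wide expression-class proportions (the
# published atlas snapshot is unversioned); override via BackgroundModel.
_DEFAULT_EXPRESSION_PROPORTIONS = {
    "elevated_brain": 0.08,
    "expressed_all": 0.45,
    "mixed": 0.25,
    "not_in_brain": 0.17,
    "not_detected": 0.05,
}


@dataclass
class BackgroundModel:
    """Genome-wide background proportions for the enrichment tests."""

    methylation_fraction: float = 0.154
    expression_class_proportions: dict = field(
        default_factory=lambda: dict(_DEFAULT_EXPRESSION_PROPORTIONS)
    )
    constraint_quartile_proportions: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if not 0 <= self.methylation_fraction <= 1:
            raise ValueError("methylation_fraction must be in [0,1]")
        for name, props in (
            ("expression_class_proportions", self.expression_class_proportions.values()),
            ("constraint_quartile_proportions", self.constraint_quartile_proportions),
        ):
            vals = list(props)
            if any(p < 0 or p > 1 for p in vals):
                raise ValueError(f"{name} must lie in [0,1]")
            if abs(sum(vals) - 1) > 1e-9:
                raise ValueError(f"{name} must sum to 1")


def methylation_background(methylated_bases: int, total_bases: int) -> float:
    """Genome-wide methylated fraction: methylated / total bases."""
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    if not 0 <= methylated_bases <= total_bases:
        raise ValueError("methylated_bases must be in [0, total_bases]")
    return methylated_bases / total_bases


def methylation_background_from_flags(flags: Sequence[bool]) -> float:
    arr = np.asarray(flags, dtype=bool)
    return methylation_background(int(arr.sum()), int(arr.size))


def binomial_enrichment(
    successes: int, trials: int, background: float, sided: str = "greater"
) -> float:
    """Exact binomial test of an observed count against a background
    probability.  ``sided`` is ``"greater"`` (enrichment, the default),
    ``"less"`` or ``"two"``."""
    if not 0 <= successes <= trials:
        raise ValueError("successes must be in [0, trials]")
    if not 0 < background < 1:
        raise ValueError("background must be in (0,1)")
    alternative = {"greater": "greater", "less": "less", "two": "two-sided"}[sided]
    return stats.binomtest(successes, trials, background, alternative=alternative).pvalue


def expression_enrichment(
    classes: Iterable[str], background: BackgroundModel | Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Per-class exact binomial tests of observed expression-class counts
    against genome-wide proportions, plus the brain-expressed aggregate
    (elevated_brain + expressed_all + mixed).

    ``classes`` yields one canonical class label per variant-containing
    gene record.
    """
    if background is None:
        background = BackgroundModel()
    props = (
        background.expression_class_proportions
        if isinstance(background, BackgroundModel)
        else dict(background)
    )
    if abs(sum(props.values()) - 1) > 1e-9:
        raise ValueError("expression-class proportions must sum to 1")
    labels = list(classes)
    unknown = set(labels) - set(EXPRESSION_CLASSES)
    if unknown:
        raise ValueError(f"unknown expression classes: {sorted(unknown)}")
    n = len(labels)
    if n == 0:
        raise ValueError("need at least one annotated variant")
    counts = pd.Series(labels).value_counts()
    rows = []
    for cls in EXPRESSION_CLASSES:
        obs = int(counts.get(cls, 0))
        p_bg = props[cls]
        pval = (
            binomial_enrichment(obs, n, p_bg, sided="two") if 0 < p_bg < 1
            else (1.0 if obs == round(n * p_bg) else 0.0)
        )
        rows.append((cls, obs, n * p_bg, pval))
    obs_brain = int(sum(counts.get(c, 0) for c in BRAIN_EXPRESSED))
    p_brain = sum(props[c] for c in BRAIN_EXPRESSED)
    p_val = (
        binomial_enrichment(obs_brain, n, p_brain, sided="two")
        if 0 < p_brain < 1
        else (1.0 if obs_brain == round(n * p_brain) else 0.0)
    )
    rows.append(("brain_expressed", obs_brain, n * p_brain, p_val))
    return pd.DataFrame(rows, columns=["class", "observed", "expected", "p"])


def constraint_quartile_test(
    quartiles: Iterable[int], proportions: Sequence[float] = (0.25,) * 4
) -> pd.DataFrame:
    """Per-quartile exact binomial test (two-sided) of observed missense
    constraint quartile counts against uniform (or given) proportions."""
    qs = [int(q) for q in quartiles]
    if any(q not in (1, 2, 3, 4) for q in qs):
        raise ValueError("quartiles must be integers 1..4")
    n = len(qs)
    counts = pd.Series(qs).value_counts()
    rows = []
    for q, p_bg in zip((1, 2, 3, 4), proportions):
        obs = int(counts.get(q, 0))
        pval = binomial_enrichment(obs, n, p_bg, sided="two") if n else float("nan")
        rows.append((q, obs, n * p_bg, pval))
    return pd.DataFrame(rows, columns=["quartile", "observed", "expected", "p"])


def cohort_variant_probability(carriers: int, cohort_size: int) -> dict:
    """Posterior for the per-person probability of carrying a somatic
    variant: each cohort member is a Bernoulli trial with probability p and
    p has a uniform prior, giving Beta(carriers+1, cohort_size-carriers+1).

    Returns the posterior mean and central 95% credible interval.
    """
    if carriers < 0 or cohort_size < 0 or carriers > cohort_size:
        raise ValueError("need 0 <= carriers <= cohort_size")
    a = carriers + 1
    b = cohort_size - carriers + 1
    post = stats.beta(a, b)
    return {
        "mean": a / (a + b),
        "ci_low": float(post.ppf(0.025)),
        "ci_high": float(post.ppf(0.975)),
        "alpha": a,
        "beta": b,
    }


def region_bias_test(table: Sequence[Sequence[int]]) -> dict:
    """Two-sided Fisher exact test on a 2x2 table of (variants in a region
    class vs outside) x (samples in that class vs outside).

    A table with an empty margin carries no information; it is reported as
    p = 1 with a note rather than an error.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return {"odds_ratio": float("nan"), "p": 1.0, "note": "zero margin"}
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return {"odds_ratio": float(odds), "p": float(p), "note": ""}
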