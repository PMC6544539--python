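"""Amplicon-resequencing confirmation of candidate somatic variants.

A candidate is confirmed when deep targeted resequencing of the case shows
sufficient coverage and variant support (minimum depth 500x, minimum 40
supporting reads) and a matched control from the same tissue shows the
allele essentially absent (VAF < 1%, strict).  Read-level base-quality and
mapping-quality filtering is an input contract on the deep counts, applied
upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_MIN_DEPTH = 500
DEFAULT_MIN_ALT = 40
DEFAULT_CONTROL_MAX_VAF = 0.01


@dataclass
class DeepCount:
    """Deep targeted counts for one variant on one platform."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    platform: str = "amplicon"  # exome | amplicon | pyro

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError("need 0 <= alt_count <= depth")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0


@dataclass
class ValidationResult:
    key: tuple
    case_vaf: float
    control_vaf: float
    confirmed: bool
    reason: str


def confirm_variant(
    case: DeepCount,
    control: DeepCount,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_alt: int = DEFAULT_MIN_ALT,
    control_max_vaf: float = DEFAULT_CONTROL_MAX_VAF,
) -> ValidationResult:
    """Apply the confirmation rules; the reason names the first failing
    rule (depth, then supporting reads, then control VAF)."""
    if case.key != control.key:
        raise ValueError(f"case/control key mismatch: {case.key} vs {control.key}")
    reason = ""
    if case.depth < min_depth:
        reason = "minimum depth"
    elif case.alt_count < min_alt:
        reason = "minimum supporting reads"
    elif control.vaf >= control_max_vaf:
        reason = "control VAF"
    return ValidationResult(
        key=case.key,
        case_vaf=case.vaf,
        control_vaf=control.vaf,
        confirmed=reason == "",
        reason=reason or "confirmed",
    )


def platform_concordance(pairs) -> dict:
    """Cross-platform VAF concordance for paired measurements.

    ``pairs`` is a sequence of (exome_vaf, amplicon_vaf) tuples; returns
    the mean absolute VAF difference and the Pearson correlation.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (exome, amplicon) VAF pairs")
    x, y = arr[:, 0], arr[:, 1]
    mean_abs = float(np.mean(np.abs(x - y)))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = 1.0 if mean_abs == 0 else float("nan")
    else:
        r = float(stats.pearsonr(x, y)[0])
    return {"mean_abs_diff": mean_abs, "pearson_r": r, "n": int(arr.shape[0])}
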