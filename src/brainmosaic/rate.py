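"""Early-embryonic somatic mutation-rate estimation.

The estimator converts a validated somatic-variant count observed across a
cohort of exomes into a per-base-pair mutation rate, then corrects for the
number of embryonic cells in which a detectable (high allele fraction)
mutation could have arisen, and finally extrapolates the corrected rate to
the whole genome.

The cell-count correction encodes a simple lineage model: a variant with a
tissue-wide allele fraction near 0.25 arose in one of the 2 cells present
after the first cleavage division, one near 0.125 in one of the 4 cells
after the second, giving 6 cell-division opportunities in total.  The
divisor is exposed as ``n_cells`` so alternative lineage models can be
explored.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def per_base_rate(n_validated: int, callable_bp: int, n_samples: int) -> float:
    """Somatic mutation rate per base pair: validated variants over the
    total number of bases interrogated (callable bases per individual times
    the number of individuals sequenced)."""
    if callable_bp <= 0 or n_samples <= 0:
        raise ValueError("callable_bp and n_samples must be positive")
    if n_validated < 0:
        raise ValueError("n_validated must be non-negative")
    return n_validated / (callable_bp * n_samples)


def early_embryonic_rate(rate_per_bp: float, n_cells: int = 6) -> float:
    """Divide the per-base rate by the number of early embryonic cells in
    which a detectable mutation could have occurred (default 6: two cells
    after the first division plus four after the second)."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return rate_per_bp / n_cells

def genome_extrapolation(rate_per_bp_per_individual: float, genome_bp: float = 3e9) -> float:
    """Expected number of genome-wide somatic mutations per individual in
    the modelled divisions."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    if rate_per_bp_per_individual < 0:
        raise ValueError("rate must be non-negative")
    return rate_per_bp_per_individual * genome_bp


@dataclass
class RateEstimate:
    """Full rate-estimation chain with derived quantities."""

    n_validated: int
    callable_bp_per_individual: int
    n_samples: int
    n_cells: int = 6
    genome_bp: float = 3e9
    total_bp: int = field(init=False)
    rate_per_bp: float = field(init=False)
    rate_per_bp_per_individual: float = field(init=False)
    genome_expectation: float = field(init=False)

    def __post_init__(self) -> None:
        self.total_bp = self.callable_bp_per_individual * self.n_samples
        self.rate_per_bp = per_base_rate(
            self.n_validated, self.callable_bp_per_individual, self.n_samples
        )
        self.rate_per_bp_per_individual = early_embryonic_rate(self.rate_per_bp, self.n_cells)
        self.genome_expectation = genome_extrapolation(
            self.rate_per_bp_per_individual, self.genome_bp
        )

    def report(self) -> dict:
        """Human-readable report: rates at three significant figures,
        genome-wide expectation at one decimal."""
        return {
            "n_validated": self.n_validated,
            "callable_bp_per_individual": self.callable_bp_per_individual,
            "n_samples": self.n_samples,
            "total_bp": self.total_bp,
            "rate_per_bp": float(f"{self.rate_per_bp:.3g}"),
            "n_cells": self.n_cells,
            "rate_per_bp_per_individual": float(f"{self.rate_per_bp_per_individual:.3g}"),
            "genome_bp": self.genome_bp,
            "genome_expectation": round(self.genome_expectation, 1),
        }


def estimate_rate(
    n_validated: int,
    callable_bp: int,
    n_samples: int,
    n_cells: int = 6,
    genome_bp: float = 3e9,
) -> RateEstimate:
    """Convenience constructor for the full chain."""
    return RateEstimate(n_validated, callable_bp, n_samples, n_cells, genome_bp)
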