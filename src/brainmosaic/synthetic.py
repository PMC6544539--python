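"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the discovery pipeline assumes, so every
downstream stage is testable without access to a real cohort:

* sequencing depth ~ round(Normal(51.9, 12.9)) truncated at 1, with the
  variance split into a shared per-site capture effect plus within-site
  sample noise so that depth (and hence callability) is correlated across
  samples at a site, as in real capture data;
* germline heterozygous sites with alternate counts drawn around a mean
  VAF of 0.47;
* early-embryonic somatic variants assigned to cleavage divisions, a
  division-``d`` mutation carrying expected tissue VAF 0.5 / 2**d under
  equal lineage contribution (division 1 -> 0.25, division 2 -> 0.125);
* overdispersed per-site base error drawn from a beta-binomial;
* masked regions (blacklist intervals plus per-sample copy-number
  intervals) and annotation backgrounds (trinucleotide contexts as random
  i.i.d. sequence — a stand-in, not a real genome — methylation flags,
  and per-gene expression/constraint annotations).

All randomness flows from one master seed; per-component child seeds are
derived deterministically, so a fixed seed gives bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import _DEFAULT_EXPRESSION_PROPORTIONS
from .spectra import BASES


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass
class SimulationConfig:
    """Cohort simulation parameters.

    ``somatic_rate_per_division`` is the aggregate expected number of
    somatic mutations per base per individual across the modelled
    divisions; per-division expectations are apportioned in proportion to
    the number of daughter cells present (2/6 and 4/6 for two divisions),
    mirroring the cell-count correction used by the rate estimator.
    """

    n_samples: int = 400
    n_sites: int = 5000
    depth_mean: float = 51.9
    depth_sd: float = 12.9
    depth_site_sd: float = 10.9
    het_vaf_mean: float = 0.47
    het_density: float = 1e-3
    somatic_rate_per_division: float = 3e-4
    error_rate_mean: float = 2e-3
    error_overdispersion: float = 0.01
    masked_fraction: float = 0.05
    methylated_fraction: float = 0.154
    n_divisions: int = 2
    sites_per_gene: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be > 0")
        if self.depth_sd < 0:
            raise ConfigurationError("depth_sd must be >= 0")
        if not 0 <= self.depth_site_sd <= self.depth_sd:
            raise ConfigurationError("depth_site_sd must be in [0, depth_sd]")
        if self.n_divisions < 1:
            raise ConfigurationError("n_divisions must be >= 1")
        for name in (
            "het_vaf_mean", "het_density", "error_rate_mean",
            "masked_fraction", "methylated_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0,1]")
        if not 0 <= self.error_overdispersion < 1:
            raise ConfigurationError("error_overdispersion must be in [0,1)")
        if self.somatic_rate_per_division < 0:
            raise ConfigurationError("somatic_rate_per_division must be >= 0")


@dataclass
class SyntheticCohort:
    """Simulated counts grid with ground truth and annotation layers."""

    config: SimulationConfig
    sites: pd.DataFrame  # chrom, pos, ref, alt, context, methylated, gene
    depth: np.ndarray  # (n_samples, n_sites)
    alt_count: np.ndarray  # (n_samples, n_sites)
    sample_ids: list
    truth: pd.DataFrame  # sample_id, site_index, chrom, pos, kind, expected_vaf
    blacklist: pd.DataFrame
    cnv: pd.DataFrame
    annotations: pd.DataFrame  # per-gene table
    popfreq: pd.DataFrame


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, mean: float, rho: float):
    """Draw beta-binomial counts with the given mean and intraclass
    correlation rho (rho = 0 degenerates to binomial)."""
    if mean == 0:
        return np.zeros_like(n)
    if rho == 0:
        return rng.binomial(n, mean)
    ab = (1 - rho) / rho
    p = rng.beta(mean * ab, (1 - mean) * ab, size=n.shape)
    return rng.binomial(n, p)


def _division_weights(n_divisions: int) -> np.ndarray:
    cells = 2.0 ** np.arange(1, n_divisions + 1)
    return cells / cells.sum()


def _random_intervals(
    rng: np.random.Generator, n_sites: int, target_bp: int, mean_len: float = 20.0
) -> pd.DataFrame:
    """Random merged 0-based intervals on the toy contig covering roughly
    ``target_bp`` bases."""
    covered = np.zeros(n_sites, dtype=bool)
    rows = []
    guard = 0
    while covered.sum() < target_bp and guard < 10_000:
        guard += 1
        start = int(rng.integers(0, n_sites))
        length = 1 + int(rng.geometric(1.0 / mean_len))
        end = min(start + length, n_sites)
        covered[start:end] = True
        rows.append(("chr1", start, end))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values("start")
    merged = []
    for _, r in df.iterrows():
        if merged and r["start"] <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], r["end"])
        else:
            merged.append([r["chrom"], r["start"], r["end"]])
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a cohort counts grid with truth table and annotations."""
    ss = np.random.SeedSequence(config.seed)
    (
        s_depth, s_sites, s_mask, s_het, s_som, s_err, s_annot, s_pop
    ) = (np.random.default_rng(c) for c in ss.spawn(8))
    S, L = config.n_samples, config.n_sites
    sample_ids = [f"S{i:04d}" for i in range(S)]

    # site table: toy contig chr1, contiguous 1-based positions
    ref_idx = s_sites.integers(0, 4, size=L)
    ref = np.array(BASES)[ref_idx]
    alt = np.array(
        [BASES[(r + 1 + s_sites.integers(0, 3)) % 4] for r in ref_idx]
    )
    f5 = np.array(BASES)[s_sites.integers(0, 4, size=L)]
    f3 = np.array(BASES)[s_sites.integers(0, 4, size=L)]
    context = np.char.add(np.char.add(f5, ref), f3)
    methylated = s_sites.random(L) < config.methylated_fraction
    gene = np.array([f"GENE{(i // config.sites_per_gene):04d}" for i in range(L)])
    sites = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, L + 1),
            "ref": ref,
            "alt": alt,
            "context": context,
            "methylated": methylated,
            "gene": gene,
        }
    )

    # Depth is site-correlated (capture efficiency): per-site mean effect
    # plus within-site sample noise, with marginal SD equal to depth_sd.
    within_sd = float(np.sqrt(config.depth_sd**2 - config.depth_site_sd**2))
    site_mean = s_depth.normal(config.depth_mean, config.depth_site_sd, size=L)
    depth = np.maximum(
        np.rint(s_depth.normal(site_mean, within_sd, size=(S, L))), 1
    ).astype(int)

    # masks
    blacklist = _random_intervals(
        s_mask, L, int(config.masked_fraction * L)
    )
    cnv_rows = []
    for sid in sample_ids:
        for _ in range(s_mask.poisson(0.2)):
            start = int(s_mask.integers(0, L))
            end = min(start + 10 + int(s_mask.geometric(1 / 20.0)), L)
            cnv_rows.append((sid, "chr1", start, end))
    cnv = pd.DataFrame(cnv_rows, columns=["sample_id", "chrom", "start", "end"])

    # base error everywhere, then overwrite true-variant cells
    alt_count = _beta_binomial(
        s_err, depth, config.error_rate_mean, config.error_overdispersion
    )

    truth_rows = []
    if config.het_density > 0:
        het_mask = s_het.random((S, L)) < config.het_density
        hi, hj = np.nonzero(het_mask)
        draws = s_het.binomial(depth[hi, hj], config.het_vaf_mean)
        alt_count[hi, hj] = draws
        for i, j in zip(hi, hj):
            truth_rows.append(
                (sample_ids[i], int(j), "germline_het", config.het_vaf_mean)
            )

    if config.somatic_rate_per_division > 0:
        weights = _division_weights(config.n_divisions)
        taken = {
            (r[0], r[1]) for r in truth_rows
        }
        for i, sid in enumerate(sample_ids):
            for d in range(1, config.n_divisions + 1):
                lam = config.somatic_rate_per_division * L * weights[d - 1]
                n_mut = s_som.poisson(lam)
                if n_mut == 0:
                    continue
                exp_vaf = 0.5 / 2**d
                js = s_som.choice(L, size=n_mut, replace=False)
                for j in js:
                    if (sid, int(j)) in taken:
                        continue  # collision with an existing event: skip
                    taken.add((sid, int(j)))
                    alt_count[i, j] = s_som.binomial(depth[i, j], exp_vaf)
                    truth_rows.append((sid, int(j), f"somatic_stage{d}", exp_vaf))

    truth = pd.DataFrame(
        truth_rows, columns=["sample_id", "site_index", "kind", "expected_vaf"]
    )
    if len(truth):
        truth["chrom"] = "chr1"
        truth["pos"] = truth["site_index"] + 1
    else:
        truth["chrom"] = pd.Series(dtype=str)
        truth["pos"] = pd.Series(dtype=int)

    # per-gene annotations
    genes = sorted(set(gene))
    classes = list(_DEFAULT_EXPRESSION_PROPORTIONS)
    probs = np.array([_DEFAULT_EXPRESSION_PROPORTIONS[c] for c in classes])
    annotations = pd.DataFrame(
        {
            "gene": genes,
            "expression_class": s_annot.choice(classes, size=len(genes), p=probs),
            "constraint_quartile": s_annot.integers(1, 5, size=len(genes)),
            "sift_class": s_annot.choice(
                ["deleterious", "tolerated"], size=len(genes), p=[0.4, 0.6]
            ),
        }
    )

    # sparse ExAC-like population table over a subset of sites
    n_pop = max(1, int(0.02 * L))
    pop_sites = np.sort(s_pop.choice(L, size=n_pop, replace=False))
    popfreq = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": pop_sites + 1,
            "ref": ref[pop_sites],
            "alt": alt[pop_sites],
            "maf": 10 ** s_pop.uniform(-5, np.log10(0.5), size=n_pop),
        }
    )

    assert (alt_count <= depth).all()
    return SyntheticCohort(
        config=config,
        sites=sites,
        depth=depth,
        alt_count=alt_count,
        sample_ids=sample_ids,
        truth=truth,
        blacklist=blacklist,
        cnv=cnv,
        annotations=annotations,
        popfreq=popfreq,
    )


def simulate_embryonic_lineage(
    rate_per_bp_per_individual: float,
    genome_bp: float,
    n_divisions: int = 2,
    seed: int = 0,
):
    """Simulate early-embryonic mutations and their expected tissue VAFs.

    The rate is the per-base per-individual aggregate over the modelled
    divisions; the expected mutation count ``rate * genome_bp`` is
    apportioned across divisions in proportion to the number of daughter
    cells present (so two divisions split it 2/6 : 4/6).  A division-``d``
    mutation has expected VAF ``0.5 / 2**d`` under equal lineage
    contribution: 0.25 at the first division, 0.125 at the second.

    Returns a list of ``(division_index, expected_vaf)`` per mutation.
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    if n_divisions < 1:
        raise ValueError("n_divisions must be >= 1")
    if rate_per_bp_per_individual < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    weights = _division_weights(n_divisions)
    out = []
    for d in range(1, n_divisions + 1):
        lam = rate_per_bp_per_individual * genome_bp * weights[d - 1]
        for _ in range(rng.poisson(lam)):
            out.append((d, 0.5 / 2**d))
    return out
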