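"""Masking and statistical filters for putative somatic SNVs.

The discovery chain, applied in order to a cohort counts grid:

1. restrict to biallelic SNVs;
2. region mask — a site is callable only if it lies outside blacklist and
   copy-number intervals and has depth >= 30 in *every* sample;
3. VAF window — observations with variant allele fraction above 50% or
   below 10% are removed (boundaries retained);
4. heterozygosity test — two-sided exact binomial test of the alternate
   count against the cohort heterozygous mean VAF (47%); only observations
   with p < 1e-5 (i.e. clearly inconsistent with a germline het) survive;
5. panel error test — one-sided beta-binomial tail test against a panel of
   comparison samples (see :mod:`brainmosaic.error_model`), p < 1e-3;
6. recurrence — any variant seen in more than one individual is removed
   everywhere;
7. population frequency — variants with minor allele frequency > 0.5% in a
   population table are removed; absent entries pass (rare by absence).

Counts and variants use 1-based coordinates (VCF convention); interval
masks are 0-based half-open (BED convention); the conversion lives in
:func:`sites_in_intervals` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

DEFAULT_MIN_DEPTH = 30
DEFAULT_VAF_LOW = 0.10
DEFAULT_VAF_HIGH = 0.50
DEFAULT_HET_P0 = 0.47
DEFAULT_HET_P = 1e-5
DEFAULT_MAX_MAF = 0.005

_FILTER_ORDER = ("snv", "mask", "vaf", "het", "panel", "recurrence", "population")


def _check_intervals(intervals: pd.DataFrame | None, name: str) -> pd.DataFrame:
    if intervals is None or len(intervals) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    df = intervals[["chrom", "start", "end"]].copy()
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(
            f"malformed {name} interval: {bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    return df


def sites_in_intervals(chrom, pos, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean membership of 1-based site positions in 0-based half-open
    intervals.  This is the single 1-based/0-based conversion point."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    out = np.zeros(pos.shape, dtype=bool)
    if intervals is None or len(intervals) == 0:
        return out
    trees: dict[str, IntervalTree] = {}
    for c, grp in intervals.groupby("chrom"):
        trees[str(c)] = IntervalTree.from_tuples(
            zip(grp["start"].astype(int), grp["end"].astype(int))
        )
    for i, (c, p) in enumerate(zip(chrom, pos)):
        tree = trees.get(str(c))
        if tree is not None and tree.overlaps_point(int(p) - 1):
            out[i] = True
    return out


def _runs_to_intervals(sites: pd.DataFrame, excluded: np.ndarray) -> pd.DataFrame:
    """Collapse excluded sites into merged 0-based half-open intervals."""
    rows = []
    for c, grp in sites[excluded].groupby("chrom"):
        pos0 = np.sort(grp["pos"].to_numpy()) - 1
        if pos0.size == 0:
            continue
        breaks = np.where(np.diff(pos0) > 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [pos0.size - 1]])
        for s, e in zip(starts, ends):
            rows.append((c, int(pos0[s]), int(pos0[e]) + 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@dataclass
class RegionMask:
    """Callable-region set after blacklist / CNV / depth exclusions.

    ``callable_sites`` is aligned to the site table it was built from;
    ``callable_bp`` counts surviving sites (one base each).
    """

    exclusions: dict = field(default_factory=dict)
    callable_sites: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    callable_bp: int = 0


def build_region_mask(
    sites: pd.DataFrame,
    depth: np.ndarray,
    blacklist: pd.DataFrame | None = None,
    cnv: pd.DataFrame | None = None,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> RegionMask:
    """A site is callable iff it is outside blacklist and CNV intervals and
    has depth >= ``min_depth`` in every sample."""
    depth = np.asarray(depth)
    if depth.ndim != 2 or depth.shape[1] != len(sites):
        raise ValueError("depth must be (n_samples, n_sites) matching the site table")
    blacklist = _check_intervals(blacklist, "blacklist")
    cnv = _check_intervals(cnv, "cnv")
    in_black = sites_in_intervals(sites["chrom"], sites["pos"], blacklist)
    in_cnv = sites_in_intervals(sites["chrom"], sites["pos"], cnv)
    low_depth = depth.min(axis=0) < min_depth
    callable_sites = ~(in_black | in_cnv | low_depth)
    return RegionMask(
        exclusions={
            "blacklist": blacklist,
            "cnv": cnv,
            "low_depth": _runs_to_intervals(sites, low_depth),
        },
        callable_sites=callable_sites,
        callable_bp=int(callable_sites.sum()),
    )


def vaf_window_filter(
    vaf, depth=None, low: float = DEFAULT_VAF_LOW, high: float = DEFAULT_VAF_HIGH
):
    """Pass iff low <= VAF <= high (closed interval: exactly 10% or 50% is
    retained).  Zero-depth observations fail ("no coverage")."""
    vaf = np.asarray(vaf, dtype=float)
    ok = (vaf >= low) & (vaf <= high)
    if depth is not None:
        ok &= np.asarray(depth) > 0
    return ok if ok.shape else bool(ok)


def het_binomial_test(alt_count, depth, p0: float = DEFAULT_HET_P0, method: str = "double"):
    """Two-sided exact binomial p-value of an alternate count against the
    heterozygous null Binomial(depth, p0).

    ``method="double"`` (default): twice the smaller exact one-sided tail,
    capped at 1.  ``method="minlike"``: minimum-likelihood mass-summation
    convention (scalar inputs only).
    """
    k = np.asarray(alt_count)
    n = np.asarray(depth)
    if (n < 1).any():
        raise ValueError("depth must be >= 1")
    if ((k < 0) | (k > n)).any():
        raise ValueError("need 0 <= alt_count <= depth")
    if method == "minlike":
        if k.shape:
            raise ValueError("minlike method accepts scalars only")
        return stats.binomtest(int(k), int(n), p0, alternative="two-sided").pvalue
    if method != "double":
        raise ValueError(f"unknown method {method!r}")
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    p = np.minimum(2.0 * np.minimum(lower, upper), 1.0)
    return p if p.shape else float(p)


def recurrence_filter(
    candidates: pd.DataFrame, individual_of: dict | None = None
) -> pd.Series:
    """Pass mask over candidate rows: a (chrom, pos, ref, alt) key observed
    in more than one distinct individual is removed in all samples.

    Two samples from the same individual (per ``individual_of``) count
    once."""
    if len(candidates) == 0:
        return pd.Series([], dtype=bool)
    ind = candidates["sample_id"].map(lambda s: (individual_of or {}).get(s, s))
    key = list(zip(candidates["chrom"], candidates["pos"], candidates["ref"], candidates["alt"]))
    n_ind = pd.DataFrame({"key": key, "ind": ind}).groupby("key")["ind"].nunique()
    return pd.Series([n_ind[k] == 1 for k in key], index=candidates.index)


def population_frequency_filter(
    candidates: pd.DataFrame,
    popfreq: pd.DataFrame | None,
    max_maf: float = DEFAULT_MAX_MAF,
) -> pd.Series:
    """Pass mask: fail iff the population table lists MAF > ``max_maf``.
    Variants absent from the table pass (treated as MAF 0)."""
    if len(candidates) == 0:
        return pd.Series([], dtype=bool)
    if popfreq is None or len(popfreq) == 0:
        return pd.Series(True, index=candidates.index)
    table = {
        (r.chrom, r.pos, r.ref, r.alt): r.maf for r in popfreq.itertuples()
    }
    maf = [
        table.get((c, p, r, a), 0.0)
        for c, p, r, a in zip(
            candidates["chrom"], candidates["pos"], candidates["ref"], candidates["alt"]
        )
    ]
    return pd.Series(np.asarray(maf) <= max_maf, index=candidates.index)


def _is_snv(ref: str, alt: str) -> bool:
    return (
        isinstance(ref, str) and isinstance(alt, str)
        and len(ref) == 1 and len(alt) == 1
        and ref in "ACGT" and alt in "ACGT" and ref != alt
    )


def run_discovery(
    sites: pd.DataFrame,
    depth: np.ndarray,
    alt_count: np.ndarray,
    sample_ids,
    blacklist: pd.DataFrame | None = None,
    cnv: pd.DataFrame | None = None,
    popfreq: pd.DataFrame | None = None,
    *,
    min_depth: int = DEFAULT_MIN_DEPTH,
    vaf_low: float = DEFAULT_VAF_LOW,
    vaf_high: float = DEFAULT_VAF_HIGH,
    het_p0: float = DEFAULT_HET_P0,
    het_threshold: float = DEFAULT_HET_P,
    panel_threshold: float = 1e-3,
    panel_size: int = 328,
    seed: int = 0,
    individual_of: dict | None = None,
):
    """Run the full filter chain over a cohort counts grid.

    Returns ``(survivors, audit, mask)``: ``survivors`` is the candidate
    table of observations passing every filter, ``audit`` records every
    observation entering the chain (any cell with alt reads) with a full
    per-filter trail, ``mask`` is the :class:`RegionMask` used.
    """
    from . import error_model

    sample_ids = list(sample_ids)
    depth = np.asarray(depth)
    alt_count = np.asarray(alt_count)
    if depth.shape != alt_count.shape or depth.shape[0] != len(sample_ids):
        raise ValueError("depth/alt_count must be (n_samples, n_sites) over sample_ids")
    mask = build_region_mask(sites, depth, blacklist, cnv, min_depth)

    snv_ok = np.array([_is_snv(r, a) for r, a in zip(sites["ref"], sites["alt"])])
    si, vi = np.nonzero(alt_count > 0)
    audit = pd.DataFrame(
        {
            "sample_id": [sample_ids[i] for i in si],
            "chrom": sites["chrom"].to_numpy()[vi],
            "pos": sites["pos"].to_numpy()[vi],
            "ref": sites["ref"].to_numpy()[vi],
            "alt": sites["alt"].to_numpy()[vi],
            "depth": depth[si, vi],
            "alt_count": alt_count[si, vi],
        }
    )
    audit["vaf"] = np.where(audit["depth"] > 0, audit["alt_count"] / audit["depth"], 0.0)
    audit["pass_snv"] = snv_ok[vi]
    audit["pass_mask"] = mask.callable_sites[vi] & audit["pass_snv"]
    audit["pass_vaf"] = audit["pass_mask"] & vaf_window_filter(
        audit["vaf"], audit["depth"], vaf_low, vaf_high
    )

    audit["het_p"] = np.nan
    audit["pass_het"] = False
    idx = audit.index[audit["pass_vaf"]]
    if len(idx):
        p = het_binomial_test(
            audit.loc[idx, "alt_count"].to_numpy(),
            audit.loc[idx, "depth"].to_numpy(),
            het_p0,
        )
        audit.loc[idx, "het_p"] = p
        audit.loc[idx, "pass_het"] = p < het_threshold

    # Panel error test for observations surviving the het stage.  The panel
    # for a given case/site is a deterministic function of the run seed.
    audit["panel_p"] = np.nan
    audit["pass_panel"] = False
    root = np.random.SeedSequence(seed)
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    for row in audit.index[audit["pass_het"]]:
        site_i = int(vi[audit.index.get_loc(row)])
        case = audit.at[row, "sample_id"]
        child = np.random.SeedSequence(
            entropy=seed, spawn_key=(site_i, sample_index[case])
        )
        panel = error_model.select_panel(
            sample_ids, case, panel_size,
            seed=np.random.default_rng(child), individual_of=individual_of,
        )
        pidx = [sample_index[s] for s in panel]
        fit = error_model.fit_site_error(alt_count[pidx, site_i], depth[pidx, site_i])
        p = error_model.panel_tail_test(
            int(audit.at[row, "alt_count"]), int(audit.at[row, "depth"]), fit
        )
        audit.at[row, "panel_p"] = p
        audit.at[row, "pass_panel"] = p < panel_threshold

    pool = audit[audit["pass_panel"]]
    audit["pass_recurrence"] = False
    audit["pass_population"] = False
    if len(pool):
        rec = recurrence_filter(pool, individual_of)
        audit.loc[pool.index, "pass_recurrence"] = rec & pool["pass_panel"]
        popmask = population_frequency_filter(pool, popfreq)
        audit.loc[pool.index, "pass_population"] = (
            audit.loc[pool.index, "pass_recurrence"] & popmask
        )
    audit["passed"] = audit["pass_population"]
    audit["filter_trail"] = [
        ";".join(
            f"{name}:{'pass' if audit.at[i, 'pass_' + name] else 'fail'}"
            for name in _FILTER_ORDER
        )
        for i in audit.index
    ]
    survivors = audit[audit["passed"]].reset_index(drop=True)
    return survivors, audit, mask


def stage_counts(audit: pd.DataFrame) -> dict:
    """Observation counts surviving each successive filter stage."""
    counts = {"entered": int(len(audit))}
    for name in _FILTER_ORDER:
        counts[name] = int(audit[f"pass_{name}"].sum())
    return counts
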