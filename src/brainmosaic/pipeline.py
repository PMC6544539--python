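"""Pipeline orchestration, configuration and the packaged fixture of the
22 validated somatic variants.

``run_all`` drives the whole analysis on a simulated cohort: discovery ->
deep-resequencing confirmation -> mutational spectra -> enrichment tests ->
mutation-rate estimation, writing TSV/JSON outputs plus a run log with
seeds and per-stage survival counts.  ``load_table1`` returns the packaged
table of 22 amplicon-validated variants (with synthetic trinucleotide
contexts standing in for reference-genome flanks) used by the downstream
characterization stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, filtering, io, rate, spectra, synthetic, validation

_TABLE1_SHA256 = "0c55e296732825621ffaf3547b2812b90d23122e7a7d98f1c127eebb8d7d3c2b"


@dataclass
class PipelineConfig:
    """All pipeline thresholds (defaults are the published operating
    points) plus I/O paths and the master seed."""

    min_depth: int = 30
    vaf_low: float = 0.10
    vaf_high: float = 0.50
    het_p0: float = 0.47
    het_p: float = 1e-5
    panel_p: float = 1e-3
    panel_size: int = 328
    max_maf: float = 0.005
    validation_min_depth: int = 500
    validation_min_alt: int = 40
    control_max_vaf: float = 0.01
    methylation_background: float = 0.154
    n_cells: int = 6
    genome_bp: float = 3e9
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    out_dir: str = "brainmosaic_out"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def load_table1(verify_checksum: bool = True) -> pd.DataFrame:
    """Load the packaged table of 22 validated somatic variants.

    The ``context_synthetic`` column holds constructed trinucleotide flanks
    (consistent with the published per-class CpG counts), not real genome
    sequence.  The table is verified against a frozen checksum and its
    structural invariants (22 records; 17 nonsynonymous/start-loss and
    5 synonymous; VAFs within [0.13, 0.304]).
    """
    ref = resources.files("brainmosaic.data") / "table1_validated_variants.tsv"
    raw = ref.read_bytes()
    if verify_checksum and hashlib.sha256(raw).hexdigest() != _TABLE1_SHA256:
        raise RuntimeError("packaged validated-variant table failed integrity check")
    df = pd.read_csv(
        ref.open("r"), sep="\t",
        dtype={"sample_id": str, "constraint_quartile": "Int64"},
    )
    if len(df) != 22:
        raise RuntimeError("validated-variant table must have 22 records")
    n_syn = (df["consequence"] == "synonymous").sum()
    n_nonsyn = df["consequence"].isin(["nonsynonymous", "start_loss"]).sum()
    if (n_syn, n_nonsyn) != (5, 17):
        raise RuntimeError("expected 17 nonsynonymous/start-loss + 5 synonymous records")
    if not df["exome_vaf"].between(0.13, 0.304).all():
        raise RuntimeError("exome VAFs out of the validated range")
    return df


def characterize_table1(
    table: pd.DataFrame | None = None,
    background: enrichment.BackgroundModel | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Spectrum, enrichment and rate analyses of the validated variants."""
    if table is None:
        table = load_table1()
    if config is None:
        config = PipelineConfig()
    if background is None:
        background = enrichment.BackgroundModel(
            methylation_fraction=config.methylation_background
        )
    spec = spectra.build_spectrum(
        list(zip(table["ref"], table["alt"], table["context_synthetic"]))
    )
    n_cpg, n_ct, frac_cpg = spectra.cpg_fraction(
        zip(table["ref"], table["alt"], table["context_synthetic"])
    )
    coding = table[table["consequence"].isin(["nonsynonymous", "start_loss"])]
    methylated = int((table["methylated_icm"] == "Y").sum())
    meth_p = enrichment.binomial_enrichment(
        methylated, len(table), background.methylation_fraction, sided="greater"
    )
    expr = enrichment.expression_enrichment(
        coding["expression_class"], background
    )
    quart = enrichment.constraint_quartile_test(
        coding["constraint_quartile"].dropna().astype(int)
    )
    n_individuals = table["sample_id"].nunique()
    cerebellum = int((table["brain_region"] == "Cerebellum").sum())
    region = enrichment.region_bias_test(
        [[cerebellum, len(table) - cerebellum], [1281, 1461 - 1281]]
    )
    est = rate.estimate_rate(
        n_validated=len(table),
        callable_bp=5_906_849,
        n_samples=1461,
        n_cells=config.n_cells,
        genome_bp=config.genome_bp,
    )
    return {
        "spectrum": spec,
        "cpg": {"n_cpg": n_cpg, "n_ct": n_ct, "fraction": frac_cpg},
        "methylated": {"observed": methylated, "n": len(table), "p": meth_p},
        "expression": expr,
        "constraint": quart,
        "sift_deleterious": {
            "observed": int((coding["sift_class"] == "deleterious").sum()),
            "n": len(coding),
        },
        "region_bias": region,
        "n_individuals": n_individuals,
        "rate": est,
    }


def simulate_deep_counts(
    survivors: pd.DataFrame,
    truth: pd.DataFrame,
    rng: np.random.Generator,
    depth: int = 1000,
    error: float = 2e-3,
):
    """Simulate amplicon resequencing of discovered candidates: the case is
    re-sequenced at the candidate's true VAF (or the error rate for false
    positives), the control at the error rate."""
    truth_vaf = {
        (r.sample_id, r.pos): r.expected_vaf for r in truth.itertuples()
    }
    pairs = []
    for r in survivors.itertuples():
        vaf = truth_vaf.get((r.sample_id, r.pos), error)
        case = validation.DeepCount(
            r.sample_id, r.chrom, int(r.pos), r.ref, r.alt,
            depth, int(rng.binomial(depth, vaf)), "amplicon",
        )
        control = validation.DeepCount(
            "control", r.chrom, int(r.pos), r.ref, r.alt,
            depth, int(rng.binomial(depth, error)), "amplicon",
        )
        pairs.append((case, control))
    return pairs


def run_all(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the full pipeline on a simulated cohort and the packaged
    validated-variant table; write outputs and return the report bundle."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = synthetic.SimulationConfig(
        seed=config.seed, **config.simulation
    )
    cohort = synthetic.simulate_cohort(sim_cfg)
    survivors, audit, mask = filtering.run_discovery(
        cohort.sites, cohort.depth, cohort.alt_count, cohort.sample_ids,
        blacklist=cohort.blacklist, cnv=cohort.cnv, popfreq=cohort.popfreq,
        min_depth=config.min_depth, vaf_low=config.vaf_low,
        vaf_high=config.vaf_high, het_p0=config.het_p0,
        het_threshold=config.het_p, panel_threshold=config.panel_p,
        panel_size=config.panel_size, seed=config.seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(9)[-1])
    results = [
        validation.confirm_variant(
            case, control,
            config.validation_min_depth, config.validation_min_alt,
            config.control_max_vaf,
        )
        for case, control in simulate_deep_counts(survivors, cohort.truth, rng)
    ]
    confirmed = survivors[[r.confirmed for r in results]] if results else survivors
    table1 = characterize_table1(config=config)
    counts = filtering.stage_counts(audit)

    audit.to_csv(out / "candidates_audit.tsv", sep="\t", index=False)
    survivors.to_csv(out / "candidates.tsv", sep="\t", index=False)
    io.write_counts_vcf(
        out / "cohort_counts.vcf", cohort.sites, cohort.depth,
        cohort.alt_count, cohort.sample_ids,
    )
    io.write_bed(out / "blacklist.bed", cohort.blacklist)
    table1["spectrum"].six_class.to_csv(out / "table1_six_class.tsv", sep="\t")
    table1["spectrum"].channels96.to_csv(out / "table1_channels96.tsv", sep="\t")
    report = {
        "seed": config.seed,
        "stage_counts": counts,
        "callable_bp": mask.callable_bp,
        "n_candidates": int(len(survivors)),
        "n_confirmed": int(len(confirmed)),
        "rate": table1["rate"].report(),
        "depth_mean": float(cohort.depth.mean()),
        "depth_sd": float(cohort.depth.std()),
    }
    (out / "run_log.json").write_text(json.dumps(report, indent=2))
    return {
        "cohort": cohort,
        "survivors": survivors,
        "audit": audit,
        "mask": mask,
        "validation": results,
        "confirmed": confirmed,
        "table1": table1,
        "report": report,
    }
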