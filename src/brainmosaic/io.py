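"""File formats: multi-sample VCF counts grids, BED masks, TSV tables.

Counts travel as VCF v4.2 with per-sample ``AD`` (ref,alt depths) and
``DP`` fields, or as a wide TSV matrix.  Interval masks are BED (0-based
half-open).  Coordinate conventions are converted only in
:func:`brainmosaic.filtering.sites_in_intervals`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def write_counts_vcf(path, sites: pd.DataFrame, depth, alt_count, sample_ids) -> None:
    """Write a counts grid as a multi-sample VCF with AD/DP per sample."""
    depth = np.asarray(depth)
    alt_count = np.asarray(alt_count)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=brainmosaic\n")
        for chrom in pd.unique(sites["chrom"]):
            length = int(sites.loc[sites["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in sample_ids)
            + "\n"
        )
        for j, row in enumerate(sites.itertuples()):
            cells = "\t".join(
                f"./.:{depth[i, j] - alt_count[i, j]},{alt_count[i, j]}:{depth[i, j]}"
                for i in range(depth.shape[0])
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\t"
                f"GT:AD:DP\t{cells}\n"
            )


def read_counts_vcf(path):
    """Read a multi-sample VCF with AD/DP into (sites, depth, alt_count,
    sample_ids).  Indels and multi-allelic records are dropped (the
    pipeline is SNV-only)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, depths, alts = [], [], []
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        if v.REF not in "ACGT" or v.ALT[0] not in "ACGT":
            continue
        ad = v.format("AD")
        dp = v.format("DP")
        if ad is None or dp is None:
            raise ValueError(f"record {v.CHROM}:{v.POS} lacks AD/DP")
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        alts.append(ad[:, 1].astype(int))
        depths.append(dp[:, 0].astype(int))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    depth = np.array(depths).T if depths else np.zeros((len(sample_ids), 0), int)
    alt_count = np.array(alts).T if alts else np.zeros((len(sample_ids), 0), int)
    return sites, depth, alt_count, sample_ids


def write_counts_tsv(path, sites: pd.DataFrame, depth, alt_count, sample_ids) -> None:
    """Long-format TSV counts matrix: one row per sample x site."""
    depth = np.asarray(depth)
    alt_count = np.asarray(alt_count)
    si, vi = np.indices(depth.shape)
    pd.DataFrame(
        {
            "sample_id": np.asarray(sample_ids)[si.ravel()],
            "chrom": sites["chrom"].to_numpy()[vi.ravel()],
            "pos": sites["pos"].to_numpy()[vi.ravel()],
            "ref": sites["ref"].to_numpy()[vi.ravel()],
            "alt": sites["alt"].to_numpy()[vi.ravel()],
            "depth": depth.ravel(),
            "alt_count": alt_count.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def write_bed(path, intervals: pd.DataFrame) -> None:
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], comment="#",
    )
    return df


def read_popfreq_tsv(path) -> pd.DataFrame:
    """Population allele-frequency table: chrom, pos, ref, alt, maf."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "ref", "alt", "maf"}
    if not required <= set(df.columns):
        raise ValueError(f"frequency table must have columns {sorted(required)}")
    if ((df["maf"] < 0) | (df["maf"] > 0.5)).any():
        raise ValueError("MAF values must lie in [0, 0.5]")
    return df
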