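"""Minimal standard-format I/O: VCF writing, VCF reading, TSV tables.

Generated genotypes are written as plain-text VCF 4.2 with GT:DP:GQ fields
(1-based positions); reading goes through cyvcf2 so anything the pipeline
writes round-trips through a standard parser.  Population assignments and
result tables are tab-separated files handled with pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF


def write_vcf(
    path: str | Path,
    chrom: str,
    sites: Sequence[tuple[int, str, str, str]],
    samples: Sequence[str],
    genotypes: dict[str, list[tuple[tuple[str, str] | None, int, float]]],
    contig_len: int = 60_000_000,
) -> Path:
    """Write diploid genotypes as a minimal VCF.

    ``sites`` holds (pos_1based, site_id, ref, alt) per row; ``genotypes``
    maps site_id to per-sample (allele pair | None, depth, genotype quality).
    Missing calls are encoded ./. so no pseudo-haploid representation exists.
    """
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={contig_len}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for pos, site_id, ref, alt in sites:
        row = [chrom, str(pos), site_id, ref, alt, ".", "PASS", ".", "GT:DP:GQ"]
        for alleles, depth, gq in genotypes[site_id]:
            if alleles is None:
                row.append(f"./.:{depth}:0")
            else:
                code = {ref: "0", alt: "1"}
                gt = "/".join(sorted(code.get(a, ".") for a in alleles))
                row.append(f"{gt}:{depth}:{int(round(gq))}")
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf_dosages(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read a VCF into (site_ids, samples, alt-dosage matrix).

    The matrix is (n_sites, n_samples) with np.nan for missing genotypes.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    site_ids, rows = [], []
    for variant in vcf:
        site_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        gts = np.array(variant.genotype.array())[:, :2].astype(float)
        gts[gts < 0] = np.nan
        rows.append(gts.sum(axis=1))
    return site_ids, samples, np.array(rows)


def write_tsv(path: str | Path, frame: pd.DataFrame) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_population_tsv(path: str | Path) -> pd.DataFrame:
    """Sample-to-population assignment table with columns sample, population."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "population"} - set(df.columns)
    if missing:
        raise ValueError(f"population TSV lacks columns: {sorted(missing)}")
    return df
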