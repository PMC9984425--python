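"""Readers and writers for the pipeline's plain-text formats.

Summary statistics, dosage matrices, covariates and expression travel as
TSV; reference-panel sites as minimal GT-only VCF; intervals as BED
(0-based half-open on disk, 1-based inclusive in memory).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import SUMSTAT_COLUMNS, GenomicInterval
from .synthetic import ReferencePanel

log = logging.getLogger("pleioscan")


def read_sumstats(
    path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a summary-statistic TSV; ``column_map`` renames source columns
    onto the canonical chrom/pos/rsid/ea/nea/beta/se/p/n set."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing summary columns {missing}")
    log.info("read %d summary records from %s", len(df), path)
    return df[SUMSTAT_COLUMNS]


def write_sumstats(df: pd.DataFrame, path) -> None:
    df[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False)
    log.info("wrote %d summary records to %s", len(df), path)


def write_dosages(panel: ReferencePanel, path) -> None:
    """Dosage TSV: one row per sample, one column per variant id."""
    pd.DataFrame(
        panel.dosages, columns=panel.variant_ids
    ).to_csv(path, sep="\t", index=False)


def read_dosages(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(values: np.ndarray, path, prefix: str = "c") -> None:
    arr = np.atleast_2d(np.asarray(values))
    cols = [f"{prefix}{i + 1}" for i in range(arr.shape[1])]
    pd.DataFrame(arr, columns=cols).to_csv(path, sep="\t", index=False)


def write_vcf(panel: ReferencePanel, path) -> None:
    """Minimal GT-only VCF of the panel's sites and diploid genotypes."""
    n = panel.n_samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"S{i + 1}" for i in range(n))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        gts = np.array(["0/0", "0/1", "1/1"])
        for j, row in enumerate(panel.variants.itertuples(index=False)):
            calls = "\t".join(gts[panel.dosages[:, j]])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\tBLOCK={row.block}\tGT\t{calls}\n"
            )
    log.info("wrote %d variants to %s", panel.n_variants, path)


def read_vcf(path, block_map: dict[str, int] | None = None) -> ReferencePanel:
    """Read a GT-only VCF back into a ReferencePanel.

    Block assignment is taken from ``block_map`` (variant id -> block),
    else from a BLOCK= INFO key, else defaults to a single block 0.
    """
    rows = []
    dosage_rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos, vid, ref, alt = f[0], int(f[1]), f[2], f[3], f[4]
            if "," in alt:
                log.warning("skipping multi-allelic site %s", vid)
                continue
            dos = [
                sum(int(a) for a in gt.replace("|", "/").split("/"))
                for gt in f[9:]
            ]
            if block_map is not None:
                block = block_map.get(vid, 0)
            elif f[7].startswith("BLOCK="):
                block = int(f[7].removeprefix("BLOCK="))
            else:
                block = 0
            rows.append(
                dict(chrom=chrom, pos=pos, id=vid, ref=ref, alt=alt, block=block)
            )
            dosage_rows.append(dos)
    if not rows:
        raise ValueError(f"no variant records in {path}")
    dosages = np.array(dosage_rows, dtype=np.int8).T
    return ReferencePanel(pd.DataFrame(rows), dosages)


def write_bed(intervals: list[GenomicInterval], path, names=None) -> None:
    """Write intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region{i}"
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\n")


def read_bed(path) -> list[tuple[GenomicInterval, str]]:
    """Read BED into 1-based inclusive intervals (with names)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        name = f[3] if len(f) > 3 else ""
        out.append((GenomicInterval(f[0], int(f[1]) + 1, int(f[2])), name))
    return out
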