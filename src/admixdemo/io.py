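"""Readers and writers for the formats the pipeline touches.

Coordinates are 0-based half-open internally; VCF positions are converted
at the boundary.  Genetic positions serialise with 4 decimals in cM.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    AncestryGenotypeTable,
    AncestryTractSet,
    GenomeMap,
    IBDSegmentSet,
    JointSFS,
)

logger = logging.getLogger("admixdemo")

__all__ = [
    "write_vcf",
    "read_genotypes",
    "write_local_ancestry",
    "read_local_ancestry",
    "write_ibd",
    "read_ibd",
    "write_sfs_text",
    "read_sfs_text",
    "load_config",
]


# ---------------------------------------------------------------------------
# VCF


def write_vcf(table: AncestryGenotypeTable, path) -> None:
    """Write biallelic SNVs with GT; phased if haplotype alleles exist."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=admixdemo\n')
        chroms = list(dict.fromkeys(table.chrom))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.individuals)
            + "\n"
        )
        pos_bp = (
            table.pos_bp
            if table.pos_bp is not None
            else np.round(table.pos_cm * 1e4).astype(np.int64)
        )
        phased = table.hap_alleles is not None
        for s in range(table.n_sites):
            cols = []
            for i in range(table.n_individuals):
                g = table.genotypes[s, i]
                if g < 0:
                    cols.append("./.")
                elif phased:
                    a, b = table.hap_alleles[s, i]
                    cols.append(f"{a}|{b}")
                else:
                    cols.append("0/1" if g == 1 else ("1/1" if g == 2 else "0/0"))
            fh.write(
                f"{table.chrom[s]}\t{pos_bp[s] + 1}\t.\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(cols)
                + "\n"
            )


def read_genotypes(path) -> AncestryGenotypeTable:
    """Read a VCF into the genotype part of an ancestry-genotype table.

    Only biallelic SNVs are kept; multiallelic records are skipped with a
    logged count.  Ancestry calls are left missing (join them from a local
    ancestry file).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    chroms, pos_bp, gts = [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_multi += 1
            continue
        chroms.append(rec.CHROM)
        pos_bp.append(rec.POS - 1)
        row = []
        for g in rec.genotypes:
            a, b = g[0], g[1]
            row.append(-1 if a < 0 or b < 0 else a + b)
        gts.append(row)
    if n_multi:
        logger.info("skipped %d non-biallelic-SNV records", n_multi)
    g = (
        np.array(gts, dtype=np.int8)
        if gts
        else np.zeros((0, len(individuals)), dtype=np.int8)
    )
    pos_bp = np.array(pos_bp, dtype=np.int64)
    return AncestryGenotypeTable(
        genotypes=g,
        ancestry=np.full_like(g, -1),
        chrom=np.array(chroms),
        pos_cm=pos_bp / 1e4,
        individuals=individuals,
        pos_bp=pos_bp,
    )


# ---------------------------------------------------------------------------
# Local-ancestry segments (RFMix-msp-style TSV)


def write_local_ancestry(tracts: AncestryTractSet, path) -> None:
    df = tracts.data.copy()
    df["start_cm"] = df["start_cm"].map(lambda x: f"{x:.4f}")
    df["end_cm"] = df["end_cm"].map(lambda x: f"{x:.4f}")
    df[["chrom", "start_cm", "end_cm", "individual", "hap", "ancestry"]].to_csv(
        path, sep="\t", index=False
    )


def read_local_ancestry(path, genome: GenomeMap) -> AncestryTractSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "individual": str})
    required = {"chrom", "start_cm", "end_cm", "individual", "hap", "ancestry"}
    if not required.issubset(df.columns):
        raise ValueError(f"local-ancestry file must carry columns {sorted(required)}")
    ts = AncestryTractSet(
        df[["individual", "hap", "chrom", "start_cm", "end_cm", "ancestry"]],
        genome,
    )
    ts.validate_tiling()
    return ts


# ---------------------------------------------------------------------------
# IBD segments (GERMLINE-match-style TSV)


def write_ibd(segments: IBDSegmentSet, path) -> None:
    df = segments.data.copy()
    for col in ("start_cm", "end_cm", "length_cm"):
        df[col] = df[col].map(lambda x: f"{x:.4f}")
    df.to_csv(path, sep="\t", index=False)


def read_ibd(path, population_labels: dict[str, str] | None = None) -> IBDSegmentSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id1": str, "id2": str})
    if not len(df):
        df = pd.DataFrame(columns=list(IBDSegmentSet.REQUIRED))
    if population_labels is not None:
        df["across"] = [
            population_labels.get(a) != population_labels.get(b)
            for a, b in zip(df["id1"], df["id2"])
        ]
    return IBDSegmentSet(df)


# ---------------------------------------------------------------------------
# SFS text format


def write_sfs_text(sfs: JointSFS, path) -> None:
    """Three lines: dimensions, row-major counts, row-major mask (0/1)."""
    with Path(path).open("w") as fh:
        fh.write(" ".join(str(d) for d in sfs.counts.shape))
        fh.write("  # " + " ".join(sfs.pop_ids) + "\n")
        fh.write(" ".join(f"{v:.6g}" for v in sfs.counts.ravel()) + "\n")
        fh.write(" ".join("1" if v else "0" for v in sfs.mask.ravel()) + "\n")


def read_sfs_text(path) -> JointSFS:
    with Path(path).open() as fh:
        header = fh.readline()
        dims_part, _, pops_part = header.partition("#")
        shape = tuple(int(x) for x in dims_part.split())
        pop_ids = tuple(pops_part.split()) or tuple(
            f"pop{i}" for i in range(len(shape))
        )
        counts = np.array([float(x) for x in fh.readline().split()]).reshape(shape)
        mask_line = fh.readline().split()
        mask = (
            np.array([x == "1" for x in mask_line]).reshape(shape)
            if mask_line
            else None
        )
    return JointSFS(counts=counts, pop_ids=pop_ids, mask=mask)


# ---------------------------------------------------------------------------
# Config


def load_config(path) -> dict:
    import yaml

    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def dump_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, default=default)
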