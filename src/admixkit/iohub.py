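"""Readers and writers for every on-disk format the pipeline touches.

Formats: VCF v4.2 (genotype interchange; read via cyvcf2, written as plain
text), a 4-column tab-separated genetic map (chrom, id, cM, bp), annotation
and result TSVs, newick trees and a JSON run report.  All bp coordinates on
disk are 1-based and inclusive.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (MISSING, GeneticMap, GenotypeMatrix, HaplotypeSet,
                   validate_variant_table)

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("id", "consequence", "cadd", "curated_lof", "traits")


class FormatError(ValueError):
    """A file violates its declared format."""


@dataclass
class VcfReadResult:
    genotypes: GenotypeMatrix
    haplotypes: HaplotypeSet | None
    n_skipped_multiallelic: int


def read_vcf(path: str | os.PathLike) -> VcfReadResult:
    """Read biallelic SNPs from a VCF with a GT FORMAT field.

    Non-biallelic records are skipped and counted.  Haplotypes are returned
    only when every genotype separator is ``|`` (fully phased file);
    ``./.`` becomes a missing call.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"malformed VCF header in {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, geno_rows, hap_rows = [], [], []
    all_phased = True
    n_skipped = 0
    for line_no, v in enumerate(vcf, start=1):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = v.genotypes  # [[a0, a1, phased], ...]
        g = np.empty(len(samples), dtype=np.int8)
        h = np.empty((len(samples), 2), dtype=np.int8)
        for i, gt in enumerate(gts):
            if len(gt) != 3:
                raise FormatError(
                    f"{path}: inconsistent ploidy at record {line_no} "
                    f"({v.CHROM}:{v.POS})")
            a0, a1, phased = gt[0], gt[1], gt[2]
            if a0 < 0 or a1 < 0:
                g[i] = MISSING
                h[i] = (0, 0)
                all_phased = False  # missing calls cannot claim phase
            else:
                g[i] = a0 + a1
                h[i] = (a0, a1)
                if not phased:
                    all_phased = False
        rows.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}", v.REF, v.ALT[0]))
        geno_rows.append(g)
        hap_rows.append(h)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    calls = (np.array(geno_rows, dtype=np.int8).T if geno_rows
             else np.zeros((len(samples), 0), dtype=np.int8))
    gm = GenotypeMatrix(calls, samples, variants, phased=all_phased)
    haps = None
    if all_phased and geno_rows:
        h = np.array(hap_rows, dtype=np.int8)          # L x N x 2
        h = h.transpose(1, 2, 0).reshape(2 * len(samples), -1)
        haps = HaplotypeSet(h, samples, variants.copy())
    return VcfReadResult(gm, haps, n_skipped)


def write_vcf(path: str | os.PathLike, genotypes: GenotypeMatrix,
              haplotypes: HaplotypeSet | None = None) -> None:
    """Write VCF v4.2.  When haplotypes are given, phased GT with ``|``;
    otherwise unphased ``/`` genotypes."""
    v = genotypes.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(v["chrom"]):
            maxlen = int(v.loc[v["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={maxlen}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        calls = genotypes.calls
        for l in range(genotypes.n_variants):
            row = v.iloc[l]
            fields = [str(row["chrom"]), str(int(row["pos"])), str(row["id"]),
                      str(row["ref"]), str(row["alt"]), ".", "PASS", ".", "GT"]
            if haplotypes is not None:
                h = haplotypes.haplotypes[:, l]
                for i in range(genotypes.n_samples):
                    if calls[i, l] == MISSING:
                        fields.append(".|.")
                    else:
                        fields.append(f"{h[2 * i]}|{h[2 * i + 1]}")
            else:
                gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                fields.extend(gt_map[int(calls[i, l])]
                              for i in range(genotypes.n_samples))
            fh.write("\t".join(fields) + "\n")


def read_genetic_map(path: str | os.PathLike) -> GeneticMap:
    """Read a 4-column tab-separated map: chrom, id, cM, bp."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "id", "cM", "bp"], dtype={"chrom": str})
    if df.isna().any().any():
        raise FormatError(f"{path}: truncated or ragged genetic map")
    try:
        return GeneticMap(df)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_genetic_map(path: str | os.PathLike, gmap: GeneticMap) -> None:
    gmap.table[["chrom", "id", "cM", "bp"]].to_csv(
        path, sep="\t", header=False, index=False)


def interpolate_cM(variants: pd.DataFrame, gmap: GeneticMap | None) -> pd.DataFrame:
    """Attach a cM column by linear interpolation between flanking map points.

    Positions outside the map are clamped to the end values.  With no map at
    all, a constant 1 cM/Mb rate is applied and a warning logged.
    """
    out = variants.copy()
    cm = np.empty(len(out), dtype=float)
    if gmap is None:
        logger.warning("no genetic map supplied; assuming constant 1 cM/Mb")
        cm[:] = (out["pos"].to_numpy(dtype=float) - 1) / 1e6
    else:
        for chrom, sub in out.groupby("chrom", sort=False):
            bp, cmpts = gmap.chrom_points(chrom)
            cm[sub.index.to_numpy()] = np.interp(
                sub["pos"].to_numpy(dtype=float), bp, cmpts)
    out["cM"] = cm
    return out


def read_annotations(path: str | os.PathLike) -> pd.DataFrame:
    """Annotation TSV; mandatory columns id, consequence, cadd, curated_lof,
    traits.  Unknown extra columns are preserved untouched."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    # truncated rows surface as NaN in non-optional columns
    for col in ("id", "consequence", "cadd", "curated_lof"):
        if df[col].isna().any():
            raise FormatError(f"{path}: missing values in column {col!r} "
                              "(truncated file?)")
    df["curated_lof"] = df["curated_lof"].astype(bool)
    df["traits"] = df["traits"].fillna("")
    return df


def write_annotations(path: str | os.PathLike, annotations: pd.DataFrame) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def write_samples(path: str | os.PathLike, samples: pd.DataFrame) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_samples(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in df.columns:
        raise FormatError(f"{path}: missing mandatory column 'sample'")
    return df


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | os.PathLike,
                  run_config: dict | None = None) -> dict[str, str]:
    """Write each table as <name>.tsv plus run_report.json holding the full
    stage-by-stage configuration, seeds and package version."""
    from . import __version__
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = os.path.join(out_dir, f"{name}.tsv")
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    report = {"version": __version__, "config": run_config or {},
              "tables": {k: os.path.basename(v) for k, v in paths.items()}}
    rp = os.path.join(out_dir, "run_report.json")
    with open(rp, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    paths["run_report"] = rp
    return paths
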