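"""Readers and writers for genotype and phenotype files.

Genotypes arrive either as a diploid VCF (parsed with cyvcf2) or as a plain
individuals x loci table of alternate-allele counts with ``species`` /
``accession`` columns. Species assignment for VCF samples comes from
``##SAMPLE=<ID=...,Species=...>`` header lines (written by this package's own
writer) or from an explicit sample->species mapping. Phenotypes are delimited
text, long or wide, returned in canonical long form. Nothing is ever dropped
silently: every excluded record is counted and logged.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    PHENO_COLUMNS,
    GenotypeMatrix,
    PhenotypeTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

_GENO_META_COLS = ("individual", "species", "accession")
_SAMPLE_HEADER_RE = re.compile(r"^##SAMPLE=<(.+)>\s*$")


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------
def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    species_map: Optional[Mapping[str, str]] = None,
    accession_map: Optional[Mapping[str, str]] = None,
) -> GenotypeMatrix:
    """Read a two-species genotype matrix from ``path``.

    ``format="vcf"`` parses a diploid VCF; multiallelic sites are dropped
    (count logged) and ``./.`` calls become missing. ``format="table"``
    expects a delimited file with ``individual``, ``species`` (and optionally
    ``accession``) columns followed by one column per locus.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        g = _read_vcf(path, species_map, accession_map)
    elif format == "table":
        g = _read_table(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return g.validate()


def _parse_sample_headers(raw_header: str) -> dict[str, dict[str, str]]:
    """Extract per-sample metadata from ##SAMPLE header lines."""
    meta: dict[str, dict[str, str]] = {}
    for line in raw_header.splitlines():
        m = _SAMPLE_HEADER_RE.match(line)
        if not m:
            continue
        fields = dict(
            kv.split("=", 1) for kv in m.group(1).split(",") if "=" in kv
        )
        if "ID" in fields:
            meta[fields["ID"]] = fields
    return meta


def _read_vcf(
    path: Path,
    species_map: Optional[Mapping[str, str]],
    accession_map: Optional[Mapping[str, str]],
) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sample_meta = _parse_sample_headers(vcf.raw_header)
    if species_map is None:
        species_map = {
            s: sample_meta.get(s, {}).get("Species", "") for s in samples
        }
        if any(not v for v in species_map.values()):
            raise ValidationError(
                "VCF carries no ##SAMPLE Species annotations; pass species_map="
                "{sample: species_label}"
            )
    if accession_map is None:
        accession_map = {
            s: sample_meta.get(s, {}).get("Accession", s) for s in samples
        }

    columns: list[np.ndarray] = []
    locus_ids: list[str] = []
    n_multiallelic = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multiallelic += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        col = np.full(len(samples), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        columns.append(col)
        locus_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    if n_multiallelic:
        logger.info("dropped %d multiallelic VCF sites", n_multiallelic)
    if not columns:
        raise ValidationError(f"no biallelic sites found in {path}")
    geno = np.column_stack(columns)
    species = np.array([species_map[s] for s in samples], dtype=object)
    return GenotypeMatrix(
        individual_ids=samples,
        species=species,
        geno=geno,
        locus_ids=locus_ids,
        accessions=[accession_map[s] for s in samples],
    )


def _read_table(path: Path) -> GenotypeMatrix:
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("individual", "species"):
        if col not in df.columns:
            raise ValidationError(f"genotype table lacks a {col!r} column")
    locus_cols = [c for c in df.columns if c not in _GENO_META_COLS]
    if not locus_cols:
        raise ValidationError("genotype table has no locus columns")
    geno = df[locus_cols].to_numpy(dtype=float)
    out = np.full(geno.shape, MISSING, dtype=np.int8)
    called = ~np.isnan(geno)
    vals = geno[called]
    if not np.isin(vals, [0, 1, 2]).all():
        bad = vals[~np.isin(vals, [0, 1, 2])][0]
        raise ValidationError(f"genotype table contains value {bad!r} outside {{0,1,2}}")
    out[called] = vals.astype(np.int8)
    accessions = (
        df["accession"].astype(str).tolist()
        if "accession" in df.columns
        else None
    )
    return GenotypeMatrix(
        individual_ids=df["individual"].astype(str).tolist(),
        species=df["species"].to_numpy(dtype=object),
        geno=out,
        locus_ids=locus_cols,
        accessions=accessions,
    )


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str = "vcf") -> Path:
    """Write a genotype matrix as VCF (with ##SAMPLE species/accession
    annotations) or as a flat allele-count table."""
    path = Path(path)
    if format == "vcf":
        _write_vcf(g, path)
    elif format == "table":
        df = pd.DataFrame(
            {
                "individual": g.individual_ids,
                "species": g.species,
                "accession": g.accessions,
            }
        )
        geno = g.geno.astype(object)
        geno[g.geno == MISSING] = np.nan
        df = pd.concat([df, pd.DataFrame(geno, columns=g.locus_ids)], axis=1)
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df.to_csv(path, sep=sep, index=False)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return path


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        for ind, sp, acc in zip(g.individual_ids, g.species, g.accessions):
            fh.write(f"##SAMPLE=<ID={ind},Species={sp},Accession={acc}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for l, locus in enumerate(g.locus_ids):
            calls = "\t".join(_GT_CODE[int(x)] for x in g.geno[:, l])
            fh.write(f"1\t{l + 1}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------
def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype file (long or wide) into canonical long form.

    Long form has ``trait``/``value`` columns; wide form has one column per
    trait. Both need ``individual``, ``species``, ``site``, ``accession``.
    Missing trait cells in wide form become absent rows (a plant that never
    flowered has no floral records, not zeros).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    key_cols = ["individual", "species", "site", "accession"]
    missing = [c for c in key_cols if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype file lacks columns: {missing}")
    if "trait" in df.columns and "value" in df.columns:
        long = df[PHENO_COLUMNS].copy()
    else:
        trait_cols = [c for c in df.columns if c not in key_cols]
        long = df.melt(
            id_vars=key_cols, value_vars=trait_cols,
            var_name="trait", value_name="value",
        )
        n_absent = int(long["value"].isna().sum())
        if n_absent:
            logger.info(
                "%d empty trait cells treated as absent measurements", n_absent
            )
        long = long.dropna(subset=["value"])
    bad = pd.to_numeric(long["value"], errors="coerce").isna() & long["value"].notna()
    if bad.any():
        row = long.index[bad][0]
        raise ValidationError(f"non-numeric trait value at row {row}")
    long["value"] = long["value"].astype(float)
    for c in key_cols + ["trait"]:
        long[c] = long[c].astype(str)
    return PhenotypeTable(long.reset_index(drop=True)).validate()


def write_phenotypes(p: PhenotypeTable, path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    p.data.to_csv(path, sep=sep, index=False)
    return path
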