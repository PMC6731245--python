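"""Readers and writers for the package's tabular interchange formats.

The canonical interchange format is long-format TSV (one row per site x
individual x tissue) because per-tissue counts per individual do not fit
VCF genotype fields cleanly.  VCF is supported for ingest only (biallelic
autosomal SNVs); FASTA supplies trinucleotide context when available.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .pedigree import Individual, Pedigree, is_autosome
from .rates import GermlineDemography, HUMAN, MOUSE

logger = logging.getLogger("germstrata")

PEDIGREE_COLUMNS = [
    "id",
    "sex",
    "role",
    "pedigree",
    "mother",
    "father",
    "litter",
    "parental_age_weeks",
    "tier",
]

CALL_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "individual",
    "tissue",
    "ref_reads",
    "alt_reads",
]


def read_pedigree(path: Union[str, Path]) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PEDIGREE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pedigree file missing columns: {sorted(missing)}")
    individuals = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            is_offspring = row.role == "offspring"
            individuals.append(
                Individual(
                    id=row.id,
                    sex=row.sex,
                    role=row.role,
                    pedigree_id=row.pedigree,
                    mother_id=row.mother if is_offspring else None,
                    father_id=row.father if is_offspring else None,
                    litter_index=int(row.litter) if is_offspring else None,
                    parental_age_weeks=(
                        float(row.parental_age_weeks) if is_offspring else None
                    ),
                    sequencing_tier=row.tier,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {i}: {exc}") from exc
    return Pedigree(individuals)


def write_pedigree(pedigree: Pedigree, path: Union[str, Path]) -> None:
    rows = []
    for ind in pedigree.individuals.values():
        rows.append(
            {
                "id": ind.id,
                "sex": ind.sex,
                "role": ind.role,
                "pedigree": ind.pedigree_id,
                "mother": ind.mother_id or ".",
                "father": ind.father_id or ".",
                "litter": ind.litter_index if ind.litter_index is not None else ".",
                "parental_age_weeks": (
                    ind.parental_age_weeks if ind.parental_age_weeks is not None else "."
                ),
                "tier": ind.sequencing_tier,
            }
        )
    pd.DataFrame(rows, columns=PEDIGREE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls(path: Union[str, Path], pedigree: Optional[Pedigree] = None) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "chrom": str,
            "pos": "int64",
            "ref": str,
            "alt": str,
            "individual": str,
            "tissue": str,
            "ref_reads": "int64",
            "alt_reads": "int64",
        },
    )
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"call table missing columns: {sorted(missing)}")
    bad = df[~df["chrom"].map(is_autosome)]
    if len(bad):
        logger.info("dropping %d non-autosomal call rows", len(bad))
        df = df[df["chrom"].map(is_autosome)]
    if pedigree is not None:
        unknown = set(df["individual"]) - set(pedigree.individuals)
        if unknown:
            raise ValueError(f"call table references unknown individuals: {sorted(unknown)[:5]}")
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_vcf_calls(path: Union[str, Path], tissue: str = "pooled") -> pd.DataFrame:
    """Ingest biallelic autosomal SNVs from a VCF with AD-format genotypes.

    Samples map to individuals by name; indel/multiallelic/sex-chromosome
    records are skipped with a logged count.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = vcf.samples
    rows = []
    skipped = 0
    for rec in vcf:
        if (
            not is_autosome(rec.CHROM)
            or len(rec.ALT) != 1
            or len(rec.REF) != 1
            or len(rec.ALT[0]) != 1
        ):
            skipped += 1
            continue
        ad = rec.format("AD")
        if ad is None:
            skipped += 1
            continue
        for s, counts in zip(samples, ad):
            ref_n, alt_n = int(max(counts[0], 0)), int(max(counts[1], 0))
            rows.append(
                {
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": rec.ALT[0],
                    "individual": s,
                    "tissue": tissue,
                    "ref_reads": ref_n,
                    "alt_reads": alt_n,
                }
            )
    if skipped:
        logger.info("skipped %d non-SNV/non-autosomal VCF records", skipped)
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def fasta_context(
    fasta_path: Union[str, Path], chrom: str, pos: int
) -> tuple[Optional[str], Optional[str]]:
    """5'/3' flanking bases around a 1-based position; ``None`` at contig
    edges or for non-ACGT bases."""
    from pyfaidx import Fasta  # optional dependency

    fa = Fasta(str(fasta_path))
    seq = fa[chrom]
    c5 = str(seq[pos - 2]).upper() if pos >= 2 else None
    c3 = str(seq[pos]).upper() if pos <= len(seq) - 1 else None
    if c5 not in ("A", "C", "G", "T"):
        c5 = None
    if c3 not in ("A", "C", "G", "T"):
        c3 = None
    return c5, c3


def load_demography(spec: str) -> GermlineDemography:
    """``mouse``, ``human``, or a path to a one-row TSV of demography fields."""
    if spec == "mouse":
        return MOUSE
    if spec == "human":
        return HUMAN
    df = pd.read_csv(spec, sep="\t")
    row = df.iloc[0]
    return GermlineDemography(
        species=str(row.get("species", "custom")),
        generation_time_years=float(row["generation_time_years"]),
        divisions_paternal=float(row["divisions_paternal"]),
        divisions_maternal=float(row["divisions_maternal"]),
        age_at_puberty_years=float(row["age_at_puberty_years"]),
        ssc_divisions_per_year=float(row["ssc_divisions_per_year"]),
    )


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must be a key-value mapping")
    return cfg
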