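"""Readers and writers for every external file the pipeline touches.

Formats
-------
* PLINK text ``.ped``/``.map`` (read + write) — genotypes plus case/control
  phenotypes; phenotype column follows the PLINK convention 1=control, 2=case.
* HapMap pairwise-LD text (read) — whitespace-separated, header-less rows
  ``pos1 pos2 pop snp1 snp2 Dprime R2``; a ``simple_tsv`` dialect with header
  ``snp_a  snp_b  r2`` is read and written.
* TSVs with documented headers for the SNP panel, the eQTL/TFBS catalogs and
  plain SNP-id lists.

All writers emit UTF-8, tab-separated, newline-terminated text. Floats are
written with round-trip precision so write-then-read reproduces in-memory
objects exactly.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    EqtlEntry,
    GenotypeMatrix,
    LdTable,
    Phenotype,
    RegulatoryCatalog,
    SnpPanel,
    SnpRecord,
    TfbsEntry,
    canonical_pair,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "{!r}"  # shortest exact-round-trip decimal


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

def read_plink_text(
    map_path: str | Path,
    ped_path: str | Path,
    allow_missing_pheno: bool = False,
    max_missing_rate: float | None = None,
) -> tuple[SnpPanel, GenotypeMatrix, Phenotype]:
    """Read a PLINK text fileset into panel + genotypes + phenotype.

    The minor allele is determined per SNP from the observed allele
    frequencies among non-missing genotypes (ties at 0.5 broken by
    lexicographic allele order); genotype codes count copies of that minor
    allele. ``0 0`` genotype cells become the MISSING sentinel and are
    excluded from the MAF denominator.

    Parameters
    ----------
    max_missing_rate
        If given, SNPs whose missing-call fraction exceeds this rate are
        dropped from the panel and matrix.
    """
    map_rows = _read_map(map_path)
    n_snps = len(map_rows)

    sample_ids: list[str] = []
    pheno_codes: list[int] = []
    allele_cols: list[list[tuple[str, str]]] = []

    with open(ped_path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}: line {ln} has {len(fields)} fields, "
                    f"expected {6 + 2 * n_snps} for {n_snps} SNPs"
                )
            fid, iid, _pat, _mat, _sex, pheno = fields[:6]
            code = int(pheno)
            if code not in (1, 2):
                if code in (0, -9) and allow_missing_pheno:
                    pass
                else:
                    raise ValueError(
                        f"{ped_path}: line {ln}: phenotype code {pheno!r} "
                        "not in {1, 2} (0/-9 require allow_missing_pheno)"
                    )
            sample_ids.append(f"{fid}:{iid}" if fid != iid else iid)
            pheno_codes.append(code)
            allele_cols.append(
                [(fields[6 + 2 * j], fields[7 + 2 * j]) for j in range(n_snps)]
            )

    n_samples = len(sample_ids)
    if n_samples == 0:
        raise ValueError(f"{ped_path}: no samples")

    records: list[SnpRecord] = []
    codes = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    keep: list[int] = []
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        counts: dict[str, int] = {}
        for i in range(n_samples):
            a1, a2 = allele_cols[i][j]
            if a1 == "0" or a2 == "0":
                continue
            counts[a1] = counts.get(a1, 0) + 1
            counts[a2] = counts.get(a2, 0) + 1
        if len(counts) > 2:
            raise ValueError(
                f"SNP {snp_id}: more than two alleles observed: "
                f"{sorted(counts)}"
            )
        if not counts:
            raise ValueError(f"SNP {snp_id}: all genotypes missing")
        alleles = sorted(counts)  # lexicographic tie-break
        if len(alleles) == 1:
            # monomorphic: the minor allele is unobserved -> "0" sentinel
            minor, major = "0", alleles[0]
            maf = 0.0
        else:
            a, b = alleles
            # strictly fewer copies -> minor; tie -> lexicographically first
            minor, major = (a, b) if counts[a] <= counts[b] else (b, a)
            total = counts[a] + counts[b]
            maf = counts[minor] / total
        n_missing = 0
        for i in range(n_samples):
            a1, a2 = allele_cols[i][j]
            if a1 == "0" or a2 == "0":
                n_missing += 1
                continue
            codes[i, j] = int(a1 == minor) + int(a2 == minor)
        if max_missing_rate is not None and n_missing / n_samples > max_missing_rate:
            continue
        keep.append(j)
        records.append(SnpRecord(snp_id, chrom, pos, minor, major, maf))

    codes = codes[:, keep]
    panel = SnpPanel(records)
    genotypes = GenotypeMatrix(codes, sample_ids)
    phenotype = Phenotype(np.array([c == 2 for c in pheno_codes]))
    return panel, genotypes, phenotype


def _read_map(map_path: str | Path) -> list[tuple[str, str, int]]:
    rows = []
    with open(map_path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ValueError(
                    f"{map_path}: line {ln}: expected 4 fields "
                    "(chrom snp_id cM pos)"
                )
            chrom, snp_id, _cm, pos = fields
            rows.append((chrom, snp_id, int(pos)))
    return rows


def write_plink_text(
    panel: SnpPanel,
    genotypes: GenotypeMatrix,
    phenotype: Phenotype,
    map_path: str | Path,
    ped_path: str | Path,
) -> None:
    """Write panel/genotypes/phenotype as a PLINK text fileset."""
    with open(map_path, "w", encoding="utf-8") as fh:
        for r in panel:
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos}\n")
    minors = [r.allele_minor for r in panel]
    majors = [r.allele_major for r in panel]
    with open(ped_path, "w", encoding="utf-8") as fh:
        for i, sid in enumerate(genotypes.sample_ids):
            pheno = 2 if phenotype.is_case[i] else 1
            parts = [sid, sid, "0", "0", "0", str(pheno)]
            row = genotypes.codes[i]
            for j in range(len(panel)):
                c = row[j]
                if c == MISSING:
                    parts += ["0", "0"]
                elif c == 0:
                    parts += [majors[j], majors[j]]
                elif c == 1:
                    # heterozygote written minor-first (fixed convention)
                    parts += [minors[j], majors[j]]
                else:
                    parts += [minors[j], minors[j]]
            fh.write("\t".join(parts) + "\n")


# ---------------------------------------------------------------------------
# SNP panel / SNP list TSVs
# ---------------------------------------------------------------------------

PANEL_COLUMNS = ["snp_id", "chrom", "pos", "allele_minor", "allele_major", "maf"]


def read_snp_panel(path: str | Path) -> SnpPanel:
    # all-string read + Python float(): exact decimal round trip
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing panel columns {sorted(missing)}")
    records = [
        SnpRecord(
            row.snp_id, row.chrom, int(row.pos),
            str(row.allele_minor), str(row.allele_major), float(row.maf),
        )
        for row in df.itertuples(index=False)
    ]
    return SnpPanel(records)


def write_snp_panel(panel: SnpPanel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for r in panel:
            fh.write(
                f"{r.snp_id}\t{r.chrom}\t{r.pos}\t{r.allele_minor}\t"
                f"{r.allele_major}\t{_FLOAT_FMT.format(r.maf)}\n"
            )


def read_snp_list(path: str | Path) -> list[str]:
    """One SNP id per line (a GWAS-Catalog-style list); '#' lines skipped."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.append(s.split("\t")[0])
    return out


def write_snp_list(snp_ids, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in snp_ids:
            fh.write(f"{s}\n")


# ---------------------------------------------------------------------------
# LD tables
# ---------------------------------------------------------------------------

def read_ld_table(path: str | Path, dialect: str = "simple_tsv") -> LdTable:
    """Read a pairwise-LD table.

    ``hapmap``: whitespace-separated, header-less rows
    ``pos1 pos2 pop snp1 snp2 Dprime R2``.
    ``simple_tsv``: header ``snp_a  snp_b  r2``.

    Duplicate canonical pairs keep the maximum r2 (a warning is logged).
    Self-pairs and r2 outside [0, 1] raise.
    """
    if dialect not in ("hapmap", "simple_tsv"):
        raise ValueError(f"unknown LD dialect {dialect!r}")
    table = LdTable()
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        if dialect == "simple_tsv":
            header = fh.readline().split()
            if header and header[:3] != ["snp_a", "snp_b", "r2"]:
                raise ValueError(
                    f"{path}: expected header snp_a/snp_b/r2, got {header}"
                )
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if dialect == "hapmap":
                if len(fields) < 7:
                    raise ValueError(
                        f"{path}: line {ln}: expected 7 fields "
                        "(pos1 pos2 pop snp1 snp2 Dprime R2)"
                    )
                _p1, _p2, pop, a, b, _dprime, r2s = fields[:7]
                if table.population is None:
                    table.population = pop
            else:
                if len(fields) < 3:
                    raise ValueError(f"{path}: line {ln}: expected 3 fields")
                a, b, r2s = fields[:3]
            r2 = float(r2s)
            key = canonical_pair(a, b)
            if key in seen:
                logger.warning(
                    "%s: duplicate LD pair %s; keeping max r2", path, key
                )
            seen.add(key)
            table.add(a, b, r2, keep_max=True)
    return table


def write_ld_table(table: LdTable, path: str | Path) -> None:
    """Write as the simple_tsv dialect, pairs in canonical sorted order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("snp_a\tsnp_b\tr2\n")
        for (a, b), r2 in sorted(table.items()):
            fh.write(f"{a}\t{b}\t{_FLOAT_FMT.format(r2)}\n")


# ---------------------------------------------------------------------------
# Regulatory catalogs
# ---------------------------------------------------------------------------

def read_regulatory_catalog(
    eqtl_path: str | Path | None = None,
    tfbs_path: str | Path | None = None,
) -> RegulatoryCatalog:
    """Load eQTL and/or TFBS catalog TSVs, unfiltered.

    The q < 0.2 and cis-only filters are applied later by the annotation
    operations; this reader only validates field ranges and the category
    vocabulary.
    """
    eqtl_entries: list[EqtlEntry] = []
    tfbs_entries: list[TfbsEntry] = []
    if eqtl_path is not None:
        df = pd.read_csv(eqtl_path, sep="\t", dtype=str)
        for col in ("snp_id", "gene_id", "q_value", "kind"):
            if col not in df.columns:
                raise ValueError(f"{eqtl_path}: missing column {col!r}")
        for i, row in enumerate(df.itertuples(index=False), 2):
            q = float(row.q_value)
            if not (0.0 <= q <= 1.0):
                raise ValueError(
                    f"{eqtl_path}: line {i} ({row.snp_id}): q-value {q} "
                    "outside [0, 1]"
                )
            eqtl_entries.append(EqtlEntry(row.snp_id, row.gene_id, q, row.kind))
    if tfbs_path is not None:
        df = pd.read_csv(tfbs_path, sep="\t", dtype=str)
        for col in ("snp_id", "category"):
            if col not in df.columns:
                raise ValueError(f"{tfbs_path}: missing column {col!r}")
        for i, row in enumerate(df.itertuples(index=False), 2):
            tfbs_entries.append(TfbsEntry(row.snp_id, row.category))
            # vocabulary check with a line-numbered message
            try:
                RegulatoryCatalog(tfbs_entries=[tfbs_entries[-1]])
            except ValueError as exc:
                raise ValueError(f"{tfbs_path}: line {i}: {exc}") from None
    return RegulatoryCatalog(eqtl_entries, tfbs_entries)


def write_regulatory_catalog(
    catalog: RegulatoryCatalog,
    eqtl_path: str | Path | None = None,
    tfbs_path: str | Path | None = None,
) -> None:
    if eqtl_path is not None:
        with open(eqtl_path, "w", encoding="utf-8") as fh:
            fh.write("snp_id\tgene_id\tq_value\tkind\n")
            for e in catalog.eqtl_entries:
                fh.write(
                    f"{e.snp_id}\t{e.gene_id}\t"
                    f"{_FLOAT_FMT.format(e.q_value)}\t{e.kind}\n"
                )
    if tfbs_path is not None:
        with open(tfbs_path, "w", encoding="utf-8") as fh:
            fh.write("snp_id\tcategory\n")
            for t in catalog.tfbs_entries:
                fh.write(f"{t.snp_id}\t{t.category}\n")
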