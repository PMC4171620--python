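"""Case/control association scan and top-SNP selection.

The per-SNP test is the allelic Pearson chi-square: each sample contributes
two alleles (dosage code k contributes k minor and 2-k major alleles), giving
a 2x2 allele-count table (case/control x minor/major) tested with 1 df and no
continuity correction. This is the classic single-SNP GWAS test and — because
the scan is re-executed inside every phenotype permutation — the cheapest to
run a thousand times. The statistic is exposed as a strategy point so a trend
test could be swapped in.

Missing genotypes are dropped per SNP (complete case per marker). Monomorphic
SNPs are flagged degenerate with chi-square 0 and p = 1 rather than aborting
the scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import MISSING, GenotypeMatrix, Phenotype, SnpPanel


@dataclass
class AssocResult:
    snp_id: str
    case_minor: int
    case_major: int
    control_minor: int
    control_major: int
    chi_square: float
    p_value: float
    n_used: int  # samples with non-missing genotype
    degenerate: bool = False


@dataclass
class TopSnpSet:
    """SNPs passing the association threshold, ordered by p ascending
    (snp_id ascending on ties), with their 10-bin MAF histogram."""

    snp_ids: list[str]
    threshold: float
    maf_histogram: np.ndarray  # 10 ints
    expanded_ids: set[str] | None = None  # optional LD proxies


def _chisq_2x2(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray):
    """Vectorized Pearson chi-square for 2x2 tables [[a, b], [c, d]].

    Returns (chi2, p, degenerate) arrays; tables with a zero margin are
    degenerate (chi2 = 0, p = 1).
    """
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    c = c.astype(np.float64)
    d = d.astype(np.float64)
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    degenerate = denom == 0
    chi2 = np.zeros_like(n)
    ok = ~degenerate
    num = a * d - b * c
    chi2[ok] = n[ok] * num[ok] ** 2 / denom[ok]
    p = np.ones_like(n)
    p[ok] = stats.chi2.sf(chi2[ok], df=1)
    return chi2, p, degenerate


def allelic_chisq(genotype_column: np.ndarray, phenotype: Phenotype,
                  snp_id: str = "") -> AssocResult:
    """Allelic 1-df chi-square for one SNP against case/control labels."""
    codes = np.asarray(genotype_column)
    ok = codes != MISSING
    if not ok.any():
        raise ValueError(f"SNP {snp_id or '<unnamed>'}: all genotypes missing")
    case = phenotype.is_case & ok
    ctrl = ~phenotype.is_case & ok
    if not case.any() or not ctrl.any():
        raise ValueError(
            f"SNP {snp_id or '<unnamed>'}: need a non-missing genotype in "
            "both cases and controls"
        )
    cm = int(codes[case].sum())
    km = int(codes[ctrl].sum())
    cM = 2 * int(case.sum()) - cm
    kM = 2 * int(ctrl.sum()) - km
    chi2, p, degen = _chisq_2x2(*(np.array([x]) for x in (cm, cM, km, kM)))
    return AssocResult(
        snp_id=snp_id,
        case_minor=cm, case_major=cM, control_minor=km, control_major=kM,
        chi_square=float(chi2[0]), p_value=float(p[0]),
        n_used=int(ok.sum()), degenerate=bool(degen[0]),
    )


def run_gwas(
    genotypes: GenotypeMatrix,
    phenotype: Phenotype,
    panel: SnpPanel,
) -> list[AssocResult]:
    """Vectorized per-SNP allelic chi-square scan, order-preserving.

    Identical to column-wise :func:`allelic_chisq`; per-SNP degeneracies are
    flagged, never raised, so a permutation scan cannot abort mid-run.
    """
    chi2, p, tables, n_used, degen = _scan_arrays(
        genotypes.codes, phenotype.is_case
    )
    return [
        AssocResult(
            snp_id=panel.records[j].snp_id,
            case_minor=int(tables[0][j]), case_major=int(tables[1][j]),
            control_minor=int(tables[2][j]), control_major=int(tables[3][j]),
            chi_square=float(chi2[j]), p_value=float(p[j]),
            n_used=int(n_used[j]), degenerate=bool(degen[j]),
        )
        for j in range(genotypes.n_snps)
    ]


def _scan_arrays(codes: np.ndarray, is_case: np.ndarray):
    """Array core of the scan; also used directly by the permutation engine."""
    nonmiss = codes != MISSING
    dose = np.where(nonmiss, codes, 0).astype(np.float64)
    case = is_case.astype(np.float64)
    ctrl = 1.0 - case
    cm = case @ dose
    km = ctrl @ dose
    n_case_used = case @ nonmiss
    n_ctrl_used = ctrl @ nonmiss
    cM = 2.0 * n_case_used - cm
    kM = 2.0 * n_ctrl_used - km
    chi2, p, degen = _chisq_2x2(cm, cM, km, kM)
    # a group with zero non-missing samples is degenerate, not an error here
    degen |= (n_case_used == 0) | (n_ctrl_used == 0)
    p[degen] = 1.0
    chi2[degen] = 0.0
    n_used = (n_case_used + n_ctrl_used).astype(np.int64)
    return chi2, p, (cm, cM, km, kM), n_used, degen


def scan_p_values(codes: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    """p-values only — the fast path re-run inside each permutation."""
    _chi2, p, _tables, _n, _degen = _scan_arrays(codes, is_case)
    return p


def select_top_snps(
    results: list[AssocResult],
    panel: SnpPanel,
    threshold: float,
) -> TopSnpSet:
    """Select SNPs with p strictly below the threshold.

    Deterministic ordering (p ascending, snp_id ascending on ties); the MAF
    histogram over the panel's 10 bins is attached for null-set matching.
    Monotone in the threshold and idempotent.
    """
    from .enrichment import maf_bin_histogram  # deferred: enrichment uses this scan

    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    hits = [r for r in results if r.p_value < threshold]
    hits.sort(key=lambda r: (r.p_value, r.snp_id))
    ids = [r.snp_id for r in hits]
    return TopSnpSet(
        snp_ids=ids,
        threshold=threshold,
        maf_histogram=maf_bin_histogram(ids, panel),
    )
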