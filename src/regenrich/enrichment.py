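"""The two null constructions for regulatory enrichment of top GWAS SNPs.

Randomization null
    Draw MAF-matched random SNP sets from the genotyping platform: the
    observed top-SNP set is binned into 10 MAF bins of width 5%, and each of
    the (default 1000) null sets reproduces that histogram exactly, sampled
    uniformly without replacement within each bin. Because the draws ignore
    LD, the null SNPs are nearly independent, which inflates the expected
    number of independent annotated LD blocks and can produce false-negative
    enrichment calls — the motivation for the second construction.

Permutation null
    Randomly swap case/control labels (keeping the case and control counts
    fixed), re-run the full association scan, re-select top SNPs at the same
    p threshold, and push them through the identical downstream pipeline.
    LD structure within individuals is untouched, so the null block counts
    carry the platform's true correlation structure.

In both cases the statistic is the number of independent LD blocks (r2 >=
0.5 single-linkage clusters) among the annotated members of the (optionally
LD-expanded) SNP set, and significance is the right-tail empirical p with
the add-one correction: p = (1 + #{null >= observed}) / (N + 1). Ties count
against significance; p can never be 0 and the N-iteration minimum 1/(N+1)
renders as "< 0.001" at N = 1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import MODE_ESNP, map_esnps, map_tsnps
from .association import TopSnpSet, run_gwas, scan_p_values, select_top_snps
from .ld import LdSource, count_ld_blocks, ld_expand
from .types import GenotypeMatrix, Phenotype, RegulatoryCatalog, SnpPanel

N_MAF_BINS = 10
MAF_BIN_WIDTH = 0.05

METHOD_RANDOMIZATION = "randomization"
METHOD_PERMUTATION = "permutation"


# ---------------------------------------------------------------------------
# MAF bins and matched sampling
# ---------------------------------------------------------------------------

def maf_bin_index(maf: float) -> int:
    """Bin index for the 10 half-open MAF bins [0,.05), [.05,.10), ...,
    [.45,.50]; the top bin is closed so maf = 0.50 falls in bin 9."""
    return min(int(maf / MAF_BIN_WIDTH), N_MAF_BINS - 1)


def maf_bin_histogram(snp_ids, panel: SnpPanel) -> np.ndarray:
    """10-bin MAF histogram of a SNP set over the panel's MAFs."""
    hist = np.zeros(N_MAF_BINS, dtype=np.int64)
    for s in snp_ids:
        if s not in panel:
            raise KeyError(f"SNP {s} absent from panel")
        hist[maf_bin_index(panel.maf(s))] += 1
    return hist


def sample_matched_set(
    panel: SnpPanel,
    target: np.ndarray,
    rng: np.random.Generator,
    exclude: set[str] | None = None,
) -> set[str]:
    """Draw a random SNP set whose MAF histogram equals ``target`` exactly,
    uniformly without replacement within each bin."""
    target = np.asarray(target)
    exclude = exclude or set()
    bins: list[list[str]] = [[] for _ in range(N_MAF_BINS)]
    for r in panel:
        if r.snp_id not in exclude:
            bins[maf_bin_index(r.maf)].append(r.snp_id)
    out: set[str] = set()
    for b in range(N_MAF_BINS):
        need = int(target[b])
        if need == 0:
            continue
        supply = bins[b]
        if need > len(supply):
            lo, hi = b * MAF_BIN_WIDTH, (b + 1) * MAF_BIN_WIDTH
            raise ValueError(
                f"MAF bin {b} [{lo:.2f}, {hi:.2f}): need {need} SNPs, "
                f"panel supplies {len(supply)}"
            )
        out.update(str(s) for s in rng.choice(supply, size=need, replace=False))
    return out


# ---------------------------------------------------------------------------
# Empirical p and result container
# ---------------------------------------------------------------------------

def empirical_p(observed: int, null_blocks) -> float:
    """Right-tail add-one empirical p: (1 + #{null >= observed}) / (N + 1)."""
    null_blocks = np.asarray(null_blocks)
    if null_blocks.size == 0:
        raise ValueError("empty null vector")
    k = int((null_blocks >= observed).sum())
    return (1 + k) / (null_blocks.size + 1)


@dataclass
class EnrichmentResult:
    method: str  # randomization | permutation
    mode: str  # esnp | tsnp_C1 | tsnp_C2
    ld_expanded: bool
    observed_blocks: int
    null_blocks: np.ndarray  # int vector, length n_iterations
    empirical_p: float
    n_iterations: int
    seed: int
    observed_members: set[str] = field(default_factory=set)

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_blocks))

    @property
    def null_sd(self) -> float:
        """Sample standard deviation (N-1 denominator)."""
        return float(np.std(self.null_blocks, ddof=1))


# ---------------------------------------------------------------------------
# Shared downstream pipeline
# ---------------------------------------------------------------------------

def _annotate(snps, catalog: RegulatoryCatalog, mode: str, q_max: float,
              cis_only: bool):
    if mode == MODE_ESNP:
        return map_esnps(snps, catalog, q_max=q_max, cis_only=cis_only)
    if mode in ("tsnp_C1", "tsnp_C2"):
        return map_tsnps(snps, catalog, category_class="C" + mode[-1])
    raise ValueError(f"unknown annotation mode {mode!r}")


def _blocks_for(
    snps,
    catalog: RegulatoryCatalog,
    source: LdSource,
    mode: str,
    ld_expand_flag: bool,
    r2_min: float,
    q_max: float,
    cis_only: bool,
) -> tuple[int, set[str]]:
    """(optional LD expansion) -> annotate -> count independent LD blocks."""
    working = ld_expand(snps, source, r2_min) if ld_expand_flag else set(snps)
    annotated = _annotate(working, catalog, mode, q_max, cis_only)
    part = count_ld_blocks(annotated.members, source, r2_min)
    return part.n_blocks, annotated.members


# ---------------------------------------------------------------------------
# The two tests
# ---------------------------------------------------------------------------

def randomization_test(
    top: TopSnpSet,
    panel: SnpPanel,
    catalog: RegulatoryCatalog,
    source: LdSource,
    mode: str = MODE_ESNP,
    n_sets: int = 1000,
    ld_expand_flag: bool = False,
    seed: int = 0,
    r2_min: float = 0.5,
    q_max: float = 0.2,
    cis_only: bool = True,
) -> EnrichmentResult:
    """MAF-bin-matched randomization enrichment test.

    Null sets are drawn independently across iterations (each set is
    without-replacement internally); each is pushed through the same
    expansion/annotation/block-count pipeline as the observed set. The
    per-iteration RNG stream is derived from (seed, iteration) so runs are
    reproducible and iterations independent.
    """
    observed, members = _blocks_for(
        top.snp_ids, catalog, source, mode, ld_expand_flag,
        r2_min, q_max, cis_only,
    )
    target = maf_bin_histogram(top.snp_ids, panel)
    null = np.empty(n_sets, dtype=np.int64)
    for i in range(n_sets):
        rng = np.random.default_rng([seed, i])
        random_set = sample_matched_set(panel, target, rng)
        null[i], _ = _blocks_for(
            random_set, catalog, source, mode, ld_expand_flag,
            r2_min, q_max, cis_only,
        )
    return EnrichmentResult(
        method=METHOD_RANDOMIZATION, mode=mode, ld_expanded=ld_expand_flag,
        observed_blocks=observed, null_blocks=null,
        empirical_p=empirical_p(observed, null),
        n_iterations=n_sets, seed=seed, observed_members=members,
    )


def permute_labels(
    is_case: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly random relabeling preserving the case/control counts."""
    return rng.permutation(is_case)


def permutation_test(
    genotypes: GenotypeMatrix,
    phenotype: Phenotype,
    panel: SnpPanel,
    catalog: RegulatoryCatalog,
    source: LdSource,
    p_threshold: float,
    mode: str = MODE_ESNP,
    ld_expand_flag: bool = False,
    n_perms: int = 1000,
    seed: int = 0,
    r2_min: float = 0.5,
    q_max: float = 0.2,
    cis_only: bool = True,
) -> EnrichmentResult:
    """Phenotype-permutation enrichment test.

    The observed statistic runs the full pipeline on the true labels. Each
    permutation swaps case/control labels uniformly at random (case and
    control counts preserved exactly), re-runs the association scan,
    re-selects top SNPs at the same threshold, and repeats the downstream
    pipeline. Iteration i's relabeling is fully determined by (seed, i), so
    iterations may be computed in any order or in parallel with bitwise
    identical results.
    """
    results = run_gwas(genotypes, phenotype, panel)
    top = select_top_snps(results, panel, p_threshold)
    observed, members = _blocks_for(
        top.snp_ids, catalog, source, mode, ld_expand_flag,
        r2_min, q_max, cis_only,
    )
    snp_ids = np.array(panel.snp_ids)
    null = np.empty(n_perms, dtype=np.int64)
    for i in range(n_perms):
        rng = np.random.default_rng([seed, i])
        labels = permute_labels(phenotype.is_case, rng)
        p = scan_p_values(genotypes.codes, labels)
        perm_top = snp_ids[p < p_threshold]
        null[i], _ = _blocks_for(
            perm_top, catalog, source, mode, ld_expand_flag,
            r2_min, q_max, cis_only,
        )
    return EnrichmentResult(
        method=METHOD_PERMUTATION, mode=mode, ld_expanded=ld_expand_flag,
        observed_blocks=observed, null_blocks=null,
        empirical_p=empirical_p(observed, null),
        n_iterations=n_perms, seed=seed, observed_members=members,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def format_p(p: float) -> str:
    """Render an empirical p at 3 dp, with the conventional "< 0.001" floor."""
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def summarize(results: list[EnrichmentResult]) -> pd.DataFrame:
    """One report row per result: observed blocks, expected blocks (null
    mean, 2 dp), s.d. (sample, 2 dp) and the formatted empirical p."""
    rows = []
    for r in results:
        rows.append(
            {
                "method": r.method,
                "mode": r.mode,
                "ld_expanded": r.ld_expanded,
                "observed_blocks": r.observed_blocks,
                "expected_blocks": round(r.null_mean, 2),
                "sd": round(r.null_sd, 2) if r.n_iterations > 1 else float("nan"),
                "p_value": format_p(r.empirical_p),
                "n_iterations": r.n_iterations,
            }
        )
    return pd.DataFrame(rows)


def null_histogram(result: EnrichmentResult) -> pd.DataFrame:
    """(block_count, frequency) pairs for plotting the null distribution,
    plus the observed count as a marker column."""
    counts, freqs = np.unique(result.null_blocks, return_counts=True)
    df = pd.DataFrame(
        {"block_count": counts, "frequency": freqs / result.n_iterations}
    )
    df["observed"] = result.observed_blocks
    return df
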