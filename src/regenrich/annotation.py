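"""Map SNP sets onto regulatory catalogs: eSNPs, tSNPs, and their overlap.

eSNPs are SNPs with a cis-eQTL at q-value strictly below 0.2 (both defaults
follow common practice: the q cut is strict, the cis restriction reflects the
fact that trans signals are too sparse for a stable block-count test). tSNPs
are SNPs with RegulomeDB-style TFBS evidence, analysed separately for class 1
(subcategories 1a-1f, eQTL plus binding evidence) and class 2 ("likely to
affect binding"); the classes are never pooled.

The intersection operation reproduces the candidate-SNP procedure: among the
LD proxies of the top associated SNPs, report the SNPs that are
simultaneously eSNPs and tSNPs, with their eQTL target genes and TFBS
categories as supporting evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import EqtlEntry, RegulatoryCatalog, TfbsEntry

MODE_ESNP = "esnp"
MODE_TSNP_C1 = "tsnp_C1"
MODE_TSNP_C2 = "tsnp_C2"


@dataclass
class AnnotatedSet:
    source_id: str
    mode: str  # MODE_ESNP / MODE_TSNP_C1 / MODE_TSNP_C2
    members: set[str] = field(default_factory=set)
    #: per-member supporting catalog entries passing the mode's filter
    evidence: dict[str, list] = field(default_factory=dict)


def map_esnps(
    snp_ids,
    catalog: RegulatoryCatalog,
    q_max: float = 0.2,
    cis_only: bool = True,
    source_id: str = "",
) -> AnnotatedSet:
    """eSNPs: members with >= 1 eQTL entry at q strictly below q_max
    (and kind == cis when cis_only)."""
    if not (0.0 < q_max <= 1.0):
        raise ValueError(f"q_max {q_max} outside (0, 1]")
    snps = set(snp_ids)
    by_snp = catalog.eqtl_by_snp()
    out = AnnotatedSet(source_id=source_id, mode=MODE_ESNP)
    for s in snps:
        support = [
            e for e in by_snp.get(s, [])
            if e.q_value < q_max and (not cis_only or e.kind == "cis")
        ]
        if support:
            out.members.add(s)
            out.evidence[s] = sorted(support, key=lambda e: (e.q_value, e.gene_id))
    return out


def _category_class(category: str) -> str:
    return category[0]


def best_category(entries: list[TfbsEntry], category_class: str) -> str | None:
    """Lexicographically smallest (highest-confidence) category within the
    requested class; bare class labels sort after lettered subcategories."""
    cats = [
        t.category for t in entries if _category_class(t.category) == category_class
    ]
    if not cats:
        return None
    return min(cats, key=lambda c: (len(c) == 1, c))


def map_tsnps(
    snp_ids,
    catalog: RegulatoryCatalog,
    category_class: str,
    source_id: str = "",
) -> AnnotatedSet:
    """tSNPs of one RegulomeDB class: C1 matches 1a-1f (or bare "1"),
    C2 matches 2a-2c (or bare "2"). Classes are never pooled; a SNP with
    entries in both classes appears in both analyses."""
    if category_class not in ("C1", "C2"):
        raise ValueError(f"category_class must be C1 or C2, got {category_class!r}")
    digit = category_class[1]
    mode = MODE_TSNP_C1 if category_class == "C1" else MODE_TSNP_C2
    snps = set(snp_ids)
    by_snp = catalog.tfbs_by_snp()
    out = AnnotatedSet(source_id=source_id, mode=mode)
    for s in snps:
        support = [t for t in by_snp.get(s, []) if _category_class(t.category) == digit]
        if support:
            out.members.add(s)
            out.evidence[s] = sorted(support, key=lambda t: t.category)
    return out


def subcategory_fractions(
    annotated: AnnotatedSet,
    catalog: RegulatoryCatalog,
) -> dict[str, float]:
    """Distribution of members over subcategories, counting each member once
    under its best (lowest-lettered) subcategory within the set's class.

    Members carrying only a bare class label are counted under
    ``"unspecified"``. Fractions sum to 1 for non-empty input.
    """
    if annotated.mode not in (MODE_TSNP_C1, MODE_TSNP_C2):
        raise ValueError("subcategory breakdown applies to tSNP modes only")
    digit = "1" if annotated.mode == MODE_TSNP_C1 else "2"
    by_snp = catalog.tfbs_by_snp()
    counts: dict[str, int] = {}
    for s in annotated.members:
        best = best_category(by_snp.get(s, []), digit)
        key = "unspecified" if best is None or len(best) == 1 else best
        counts[key] = counts.get(key, 0) + 1
    n = len(annotated.members)
    return {k: v / n for k, v in sorted(counts.items())} if n else {}


@dataclass
class DualEvidence:
    snp_id: str
    eqtl: list[EqtlEntry]
    tfbs: list[TfbsEntry]


def intersect_regulatory(
    esnps: AnnotatedSet,
    tsnps: AnnotatedSet,
) -> list[DualEvidence]:
    """SNPs that are both eSNPs and tSNPs, with merged supporting evidence.

    Both annotated sets must come from the same source SNP set.
    """
    if esnps.source_id != tsnps.source_id:
        raise ValueError(
            f"mismatched source sets: {esnps.source_id!r} vs {tsnps.source_id!r}"
        )
    if esnps.mode != MODE_ESNP or tsnps.mode not in (MODE_TSNP_C1, MODE_TSNP_C2):
        raise ValueError("expected an eSNP set and a tSNP set")
    shared = sorted(esnps.members & tsnps.members)
    return [
        DualEvidence(s, list(esnps.evidence[s]), list(tsnps.evidence[s]))
        for s in shared
    ]
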