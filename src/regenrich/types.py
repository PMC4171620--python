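"""Core domain containers shared across the pipeline.

The containers are deliberately thin: a SNP panel (the sampling frame for the
MAF-matched randomization null), a genotype matrix with binary case/control
labels (the substrate of the permutation null), a pairwise-LD table, and a
regulatory catalog holding eQTL and TFBS annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call. Never conflated with 0 copies.
MISSING: int = -1

#: Allowed TFBS category tokens: RegulomeDB class 1 (eQTL + binding evidence,
#: subcategories a-f by decreasing confidence), class 2 ("likely to affect
#: binding", subcategories a-c), or a bare class label.
TFBS_CATEGORIES = frozenset(
    {"1a", "1b", "1c", "1d", "1e", "1f", "2a", "2b", "2c", "1", "2"}
)


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chrom: str
    pos: int  # 1-based bp
    allele_minor: str
    allele_major: str
    maf: float  # minor allele frequency, in [0, 0.5]


class SnpPanel:
    """Ordered collection of SNP metadata; iteration order equals file order."""

    def __init__(self, records: list[SnpRecord]):
        ids = [r.snp_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].tolist()
            raise ValueError(f"duplicate SNP ids in panel: {dupes[:5]}")
        for r in records:
            if not (0.0 <= r.maf <= 0.5):
                raise ValueError(f"{r.snp_id}: MAF {r.maf} outside [0, 0.5]")
            if r.pos < 1:
                raise ValueError(f"{r.snp_id}: position {r.pos} < 1")
        self.records = list(records)
        self._index = {r.snp_id: i for i, r in enumerate(self.records)}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def __getitem__(self, snp_id: str) -> SnpRecord:
        return self.records[self._index[snp_id]]

    def index_of(self, snp_id: str) -> int:
        return self._index[snp_id]

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def maf(self, snp_id: str) -> float:
        return self[snp_id].maf

    def __eq__(self, other) -> bool:
        return isinstance(other, SnpPanel) and self.records == other.records


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage codes in {0, 1, 2, MISSING}.

    Column order matches the associated :class:`SnpPanel`.
    """

    codes: np.ndarray  # int8, shape (n_samples, n_snps)
    sample_ids: list[str]

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("genotype codes must be 2-D (samples x SNPs)")
        valid = np.isin(self.codes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.codes[~valid])
            raise ValueError(f"invalid genotype codes: {bad.tolist()}")
        if len(self.sample_ids) != self.codes.shape[0]:
            raise ValueError("sample_ids length does not match genotype rows")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.codes[:, j]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.codes, other.codes)
        )


@dataclass
class Phenotype:
    """Per-sample case/control labels; True = case."""

    is_case: np.ndarray  # bool, shape (n_samples,)

    def __post_init__(self):
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if self.is_case.ndim != 1:
            raise ValueError("phenotype must be 1-D")
        if not self.is_case.any() or self.is_case.all():
            raise ValueError("need at least one case and one control")

    @property
    def n_samples(self) -> int:
        return self.is_case.size

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    def __eq__(self, other) -> bool:
        return isinstance(other, Phenotype) and np.array_equal(
            self.is_case, other.is_case
        )


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographic) ordering of an unordered SNP pair."""
    return (a, b) if a < b else (b, a)


class LdTable:
    """Pairwise r-squared lookups with symmetric (a, b) == (b, a) access."""

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None,
                 population: str | None = None):
        self.population = population
        self._r2: dict[tuple[str, str], float] = {}
        self._partners: dict[str, set[str]] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float, keep_max: bool = True) -> None:
        if a == b:
            raise ValueError(f"self-pair in LD table: {a}")
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 {r2} outside [0, 1] for pair ({a}, {b})")
        key = canonical_pair(a, b)
        if key in self._r2 and keep_max:
            r2 = max(r2, self._r2[key])
        self._r2[key] = float(r2)
        self._partners.setdefault(a, set()).add(b)
        self._partners.setdefault(b, set()).add(a)

    def r2(self, a: str, b: str) -> float | None:
        """Stored r2, or None when the pair is unlisted ("unknown")."""
        if a == b:
            return 1.0
        return self._r2.get(canonical_pair(a, b))

    def partners(self, snp_id: str) -> set[str]:
        return self._partners.get(snp_id, set())

    def __len__(self) -> int:
        return len(self._r2)

    def items(self):
        return self._r2.items()

    def __eq__(self, other) -> bool:
        if not isinstance(other, LdTable):
            return False
        if set(self._r2) != set(other._r2):
            return False
        return all(
            abs(self._r2[k] - other._r2[k]) < 1e-12 for k in self._r2
        )


@dataclass(frozen=True)
class EqtlEntry:
    snp_id: str
    gene_id: str
    q_value: float
    kind: str  # "cis" or "trans"


@dataclass(frozen=True)
class TfbsEntry:
    snp_id: str
    category: str  # one of TFBS_CATEGORIES


@dataclass
class RegulatoryCatalog:
    """eQTL entries (SNP -> gene with FDR q-value) and TFBS category entries.

    Loaded unfiltered; the q < 0.2 and cis-only filters are applied downstream
    by the annotation operations. A SNP may carry multiple entries.
    """

    eqtl_entries: list[EqtlEntry] = field(default_factory=list)
    tfbs_entries: list[TfbsEntry] = field(default_factory=list)

    def __post_init__(self):
        for e in self.eqtl_entries:
            if not (0.0 <= e.q_value <= 1.0):
                raise ValueError(
                    f"eQTL entry {e.snp_id}->{e.gene_id}: q-value "
                    f"{e.q_value} outside [0, 1]"
                )
            if e.kind not in ("cis", "trans"):
                raise ValueError(
                    f"eQTL entry {e.snp_id}->{e.gene_id}: kind {e.kind!r} "
                    "not cis/trans"
                )
        for t in self.tfbs_entries:
            if t.category not in TFBS_CATEGORIES:
                raise ValueError(
                    f"TFBS entry for {t.snp_id}: unknown category "
                    f"{t.category!r}"
                )

    def eqtl_by_snp(self) -> dict[str, list[EqtlEntry]]:
        out: dict[str, list[EqtlEntry]] = {}
        for e in self.eqtl_entries:
            out.setdefault(e.snp_id, []).append(e)
        return out

    def tfbs_by_snp(self) -> dict[str, list[TfbsEntry]]:
        out: dict[str, list[TfbsEntry]] = {}
        for t in self.tfbs_entries:
            out.setdefault(t.snp_id, []).append(t)
        return out

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RegulatoryCatalog)
            and sorted(map(repr, self.eqtl_entries))
            == sorted(map(repr, other.eqtl_entries))
            and sorted(map(repr, self.tfbs_entries))
            == sorted(map(repr, other.tfbs_entries))
        )
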