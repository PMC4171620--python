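"""Synthetic case/control studies with planted regulatory enrichment.

The generator emits everything the pipeline consumes — an LD-structured
genotype matrix with binary phenotypes, a SNP panel with MAFs, eQTL and TFBS
catalogs, and a pairwise-LD table — together with the ground truth (causal
SNPs, planted annotations, block membership), so every downstream stage has
an exact oracle.

Model
-----
* **LD**: block-diagonal. The panel is ``n_blocks`` independent blocks of
  ``snps_per_block`` SNPs; all SNPs in a block share one population MAF drawn
  from ``maf_range``. Within a block each haplotype carries a latent ancestor
  allele, and each SNP copies it with probability ``within_block_r2 ** 0.25``
  (else draws fresh), which makes the expected pairwise *genotype* r-squared
  within the block equal ``within_block_r2`` and exactly 0 between blocks.
  Blocks are placed 1 Mb apart on one chromosome so distance-windowed LD
  sources also see them as unlinked.
* **Phenotype**: logistic on the causal SNPs (the first SNP of each of
  ``n_causal_blocks`` blocks) with log-odds ``ln(causal_odds_ratio)`` per
  minor-allele copy, intercept centred so the population prevalence is ~50%
  (balanced ascertainment); samples are then collected by bounded rejection
  until exactly ``n_cases``/``n_controls`` are reached, cases stored first.
* **Catalogs**: each SNP is a planted eSNP with probability
  ``base_esnp_rate`` — multiplied by ``enrichment_factor`` in causal blocks —
  with a cis entry at q ~ U[0, 0.2) (strictly below the downstream filter, so
  truth sets are unambiguous); decoy cis entries at q ~ U[0.2, 1] and decoy
  trans entries at q ~ U[0, 1) are added at the base rate to exercise the
  q-value and cis-only filters. Planted tSNPs (probability ``base_tsnp_rate``
  with the same enrichment) draw a category from a fixed distribution
  dominated by 1f within class 1 — mirroring real regulatory catalogs where
  most class-1 evidence is eQTL-backed — with the rest spread over 2a-2c.
* **LD table**: all within-block pairwise genotype r-squared values computed
  from the emitted matrix.

One global RNG is seeded once per study and consumed in a fixed documented
order (block MAFs -> genotype/phenotype batches -> eQTL flags -> q-values ->
TFBS flags -> categories), so identical config + seed give byte-identical
fixtures across process restarts.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from . import io_formats
from .ld import genotype_r2
from .types import (
    EqtlEntry,
    GenotypeMatrix,
    LdTable,
    Phenotype,
    RegulatoryCatalog,
    SnpPanel,
    SnpRecord,
    TfbsEntry,
)

#: TFBS category sampling weights for planted tSNPs. Class 1 carries ~40% of
#: the mass with 1f dominant (95% of class 1); class 2 splits evenly.
TFBS_CATEGORY_WEIGHTS: dict[str, float] = {
    "1a": 0.004, "1b": 0.004, "1c": 0.004, "1d": 0.004, "1e": 0.004,
    "1f": 0.38,
    "2a": 0.20, "2b": 0.20, "2c": 0.20,
}


@dataclass
class SimulationConfig:
    n_cases: int = 1000
    n_controls: int = 1000
    n_blocks: int = 100
    snps_per_block: int = 5
    within_block_r2: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_blocks: int = 20
    causal_odds_ratio: float = 2.0
    base_esnp_rate: float = 0.05
    base_tsnp_rate: float = 0.05
    enrichment_factor: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_causal_blocks > self.n_blocks:
            raise ValueError("n_causal_blocks exceeds n_blocks")
        if not (0.0 <= self.within_block_r2 <= 1.0):
            raise ValueError("within_block_r2 outside [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.causal_odds_ratio < 1.0:
            raise ValueError("causal_odds_ratio must be >= 1")
        if self.enrichment_factor < 0.0:
            raise ValueError("enrichment_factor must be >= 0")
        for rate in (self.base_esnp_rate, self.base_tsnp_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("annotation rates must lie in [0, 1]")
            if rate * self.enrichment_factor > 1.0:
                raise ValueError(
                    "rate * enrichment_factor exceeds 1; infeasible plant "
                    "probability"
                )


@dataclass
class GroundTruth:
    causal_snp_ids: list[str]
    esnp_ids: set[str]
    tsnp_categories: dict[str, str]  # planted tSNP -> category
    block_of: dict[str, int]  # snp_id -> block index

    def to_json(self) -> str:
        return json.dumps(
            {
                "causal_snp_ids": self.causal_snp_ids,
                "esnp_ids": sorted(self.esnp_ids),
                "tsnp_categories": dict(sorted(self.tsnp_categories.items())),
                "block_of": dict(sorted(self.block_of.items())),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            causal_snp_ids=list(d["causal_snp_ids"]),
            esnp_ids=set(d["esnp_ids"]),
            tsnp_categories=dict(d["tsnp_categories"]),
            block_of={k: int(v) for k, v in d["block_of"].items()},
        )


@dataclass
class Study:
    config: SimulationConfig
    panel: SnpPanel
    genotypes: GenotypeMatrix
    phenotype: Phenotype
    catalog: RegulatoryCatalog
    ld_table: LdTable
    truth: GroundTruth


def _snp_id(block: int, j: int) -> str:
    return f"rs{block:03d}{j:02d}"


def _draw_genotype_batch(
    rng: np.random.Generator,
    n: int,
    mafs: np.ndarray,
    copy_prob: float,
    snps_per_block: int,
) -> np.ndarray:
    """Genotype codes (n x n_snps) for all blocks; ancestor-copy scheme."""
    n_blocks = mafs.size
    k = snps_per_block
    p = mafs[None, None, :, None]  # broadcast over (sample, haplotype, block, snp)
    ancestors = rng.random((n, 2, n_blocks, 1)) < p
    copy = rng.random((n, 2, n_blocks, k)) < copy_prob
    fresh = rng.random((n, 2, n_blocks, k)) < p
    hap = np.where(copy, ancestors, fresh)
    codes = hap.sum(axis=1).reshape(n, n_blocks * k)
    return codes.astype(np.int8)


def simulate_study(config: SimulationConfig, max_batches: int = 200) -> Study:
    """Generate one complete synthetic study (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    nb, k = config.n_blocks, config.snps_per_block
    n_snps = nb * k
    lo, hi = config.maf_range
    block_mafs = rng.uniform(lo, hi, size=nb)
    copy_prob = config.within_block_r2 ** 0.25

    causal_blocks = list(range(config.n_causal_blocks))
    causal_cols = np.array([b * k for b in causal_blocks], dtype=np.intp)
    beta = math.log(config.causal_odds_ratio)
    # centre the linear predictor for ~50% prevalence (balanced ascertainment)
    alpha = -beta * float(2.0 * block_mafs[causal_blocks].sum()) if len(
        causal_blocks
    ) else 0.0

    need_cases, need_controls = config.n_cases, config.n_controls
    case_rows: list[np.ndarray] = []
    control_rows: list[np.ndarray] = []
    batch = max(need_cases + need_controls, 200)
    for _attempt in range(max_batches):
        if need_cases <= 0 and need_controls <= 0:
            break
        g = _draw_genotype_batch(rng, batch, block_mafs, copy_prob, k)
        logit = alpha + beta * g[:, causal_cols].sum(axis=1) if len(
            causal_blocks
        ) else np.zeros(batch)
        is_case = rng.random(batch) < expit(logit)
        for i in range(batch):
            if is_case[i]:
                if need_cases > 0:
                    case_rows.append(g[i])
                    need_cases -= 1
            elif need_controls > 0:
                control_rows.append(g[i])
                need_controls -= 1
    if need_cases > 0 or need_controls > 0:
        raise RuntimeError(
            f"case/control sampling did not converge in {max_batches} "
            f"batches (still need {need_cases} cases, {need_controls} "
            "controls); config infeasible"
        )

    codes = np.vstack(case_rows + control_rows)
    n_total = config.n_cases + config.n_controls
    is_case_vec = np.zeros(n_total, dtype=bool)
    is_case_vec[: config.n_cases] = True
    sample_ids = [f"S{i + 1:05d}" for i in range(n_total)]

    # observed minor-allele orientation: the emitted panel records the
    # realized sample MAF so a PLINK write -> read round trip is exact.
    # Simulated allele 'A' has population frequency = block MAF; 'G' is the
    # alternative. Flip columns where 'A' is the sample-major allele.
    records: list[SnpRecord] = []
    count_a = codes.sum(axis=0, dtype=np.int64)
    total_alleles = 2 * n_total
    snp_ids: list[str] = []
    block_of: dict[str, int] = {}
    for b in range(nb):
        for j in range(k):
            col = b * k + j
            sid = _snp_id(b, j)
            snp_ids.append(sid)
            block_of[sid] = b
            pos = b * 1_000_000 + j * 1_000 + 1
            ca = int(count_a[col])
            # integer allele counts, identical arithmetic to the PLINK reader
            if ca > total_alleles - ca:
                codes[:, col] = 2 - codes[:, col]
                minor, major = "G", "A"
                minor_count = total_alleles - ca
            else:
                # tie at 0.5 -> lexicographic: 'A' < 'G' stays minor
                minor, major = "A", "G"
                minor_count = ca
            if minor_count == 0:  # monomorphic: minor allele unobserved
                minor = "0"
            maf = minor_count / total_alleles
            records.append(SnpRecord(sid, "1", pos, minor, major, maf))

    panel = SnpPanel(records)
    genotypes = GenotypeMatrix(codes, sample_ids)
    phenotype = Phenotype(is_case_vec)

    # catalogs: planted signal entries, then decoys, in documented draw order
    causal_set = {s for s, b in block_of.items() if b in set(causal_blocks)}
    plant_e = np.minimum(
        config.base_esnp_rate
        * np.where(
            [sid in causal_set for sid in snp_ids], config.enrichment_factor, 1.0
        ),
        1.0,
    )
    is_esnp = rng.random(n_snps) < plant_e
    q_planted = rng.uniform(0.0, 0.2, size=n_snps)
    decoy_cis = rng.random(n_snps) < config.base_esnp_rate
    q_decoy = rng.uniform(0.2, 1.0, size=n_snps)
    decoy_trans = rng.random(n_snps) < config.base_esnp_rate / 2.0
    q_trans = rng.uniform(0.0, 1.0, size=n_snps)

    plant_t = np.minimum(
        config.base_tsnp_rate
        * np.where(
            [sid in causal_set for sid in snp_ids], config.enrichment_factor, 1.0
        ),
        1.0,
    )
    is_tsnp = rng.random(n_snps) < plant_t
    cats = list(TFBS_CATEGORY_WEIGHTS)
    weights = np.array(list(TFBS_CATEGORY_WEIGHTS.values()))
    weights = weights / weights.sum()
    cat_draw = rng.choice(cats, size=n_snps, p=weights)

    eqtl_entries: list[EqtlEntry] = []
    tfbs_entries: list[TfbsEntry] = []
    esnp_ids: set[str] = set()
    tsnp_categories: dict[str, str] = {}
    for i, sid in enumerate(snp_ids):
        if is_esnp[i]:
            esnp_ids.add(sid)
            eqtl_entries.append(
                EqtlEntry(sid, f"gene_{sid}", float(q_planted[i]), "cis")
            )
        if decoy_cis[i]:
            eqtl_entries.append(
                EqtlEntry(sid, f"gene_{sid}_ns", float(q_decoy[i]), "cis")
            )
        if decoy_trans[i]:
            eqtl_entries.append(
                EqtlEntry(sid, f"gene_{sid}_tr", float(q_trans[i]), "trans")
            )
        if is_tsnp[i]:
            tsnp_categories[sid] = str(cat_draw[i])
            tfbs_entries.append(TfbsEntry(sid, str(cat_draw[i])))
    catalog = RegulatoryCatalog(eqtl_entries, tfbs_entries)

    # within-block pairwise genotype r2 (orientation flips cancel in r2)
    ld_table = LdTable(population="SYN")
    for b in range(nb):
        for j1 in range(k):
            for j2 in range(j1 + 1, k):
                c1, c2 = b * k + j1, b * k + j2
                r2 = genotype_r2(codes[:, c1], codes[:, c2])
                if r2 is not None:
                    ld_table.add(snp_ids[c1], snp_ids[c2], r2)

    truth = GroundTruth(
        causal_snp_ids=[_snp_id(b, 0) for b in causal_blocks],
        esnp_ids=esnp_ids,
        tsnp_categories=tsnp_categories,
        block_of=block_of,
    )
    return Study(config, panel, genotypes, phenotype, catalog, ld_table, truth)


# ---------------------------------------------------------------------------
# Fixture writing / reading
# ---------------------------------------------------------------------------

FIXTURE_FILES = (
    "study.map", "study.ped", "panel.tsv", "eqtl.tsv", "tfbs.tsv",
    "ld.tsv", "truth.json", "config.json",
)


def write_fixtures(
    study: Study, outdir: str | Path, overwrite: bool = False
) -> dict[str, int]:
    """Write the study as plain-text fixtures; returns a manifest of file
    name -> record count. Refuses a non-empty directory unless overwrite."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    existing = [p for p in outdir.iterdir() if p.name in FIXTURE_FILES]
    if existing and not overwrite:
        raise FileExistsError(
            f"{outdir} already contains fixtures "
            f"({existing[0].name}, ...); pass overwrite=True"
        )
    io_formats.write_plink_text(
        study.panel, study.genotypes, study.phenotype,
        outdir / "study.map", outdir / "study.ped",
    )
    io_formats.write_snp_panel(study.panel, outdir / "panel.tsv")
    io_formats.write_regulatory_catalog(
        study.catalog, outdir / "eqtl.tsv", outdir / "tfbs.tsv"
    )
    io_formats.write_ld_table(study.ld_table, outdir / "ld.tsv")
    (outdir / "truth.json").write_text(study.truth.to_json() + "\n")
    cfg = asdict(study.config)
    cfg["maf_range"] = list(cfg["maf_range"])
    (outdir / "config.json").write_text(json.dumps(cfg, indent=1) + "\n")
    return {
        "study.map": len(study.panel),
        "study.ped": study.genotypes.n_samples,
        "panel.tsv": len(study.panel),
        "eqtl.tsv": len(study.catalog.eqtl_entries),
        "tfbs.tsv": len(study.catalog.tfbs_entries),
        "ld.tsv": len(study.ld_table),
        "truth.json": len(study.truth.block_of),
        "config.json": 1,
    }


def read_fixtures(outdir: str | Path) -> Study:
    """Re-read a fixture directory into an in-memory study."""
    outdir = Path(outdir)
    cfg = json.loads((outdir / "config.json").read_text())
    cfg["maf_range"] = tuple(cfg["maf_range"])
    config = SimulationConfig(**cfg)
    panel, genotypes, phenotype = io_formats.read_plink_text(
        outdir / "study.map", outdir / "study.ped"
    )
    panel_tsv = io_formats.read_snp_panel(outdir / "panel.tsv")
    catalog = io_formats.read_regulatory_catalog(
        outdir / "eqtl.tsv", outdir / "tfbs.tsv"
    )
    ld_table = io_formats.read_ld_table(outdir / "ld.tsv", dialect="simple_tsv")
    truth = GroundTruth.from_json((outdir / "truth.json").read_text())
    return Study(config, panel_tsv, genotypes, phenotype, catalog, ld_table, truth)
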