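"""Generate the working synthetic study used by the downstream analyses.

Emits a case/control study with 100 LD blocks of 5 SNPs, 20 causal blocks at
odds ratio 2, and regulatory catalogs whose eSNP/tSNP rates are 5x enriched
in causal blocks, then writes the plain-text fixtures under
results/study/.
"""

from pathlib import Path

import regenrich as rr

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main() -> None:
    config = rr.SimulationConfig(seed=1)
    study = rr.simulate_study(config)
    manifest = rr.write_fixtures(study, OUT, overwrite=True)
    print(f"wrote study to {OUT}")
    for name, count in manifest.items():
        print(f"  {name}: {count} records")
    n_causal = len(study.truth.causal_snp_ids)
    print(
        f"{study.genotypes.n_snps} SNPs x {study.genotypes.n_samples} samples; "
        f"{n_causal} causal SNPs; {len(study.truth.esnp_ids)} planted eSNPs; "
        f"{len(study.truth.tsnp_categories)} planted tSNPs"
    )


if __name__ == "__main__":
    main()
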