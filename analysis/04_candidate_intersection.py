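"""Dual eSNP/tSNP candidate SNPs among the LD proxies of the top set.

Expands the top associated SNPs one hop (r2 >= 0.5), annotates the expanded
set against both catalogs, and intersects: SNPs that are simultaneously
cis-eSNPs and TFBS SNPs are reported with their target genes and categories
— the procedure that flags high-value regulatory candidates even when they
were not directly genotyped.
Writes results/candidates.tsv.
"""

from pathlib import Path

import pandas as pd

import regenrich as rr
from regenrich import io_formats
from regenrich.annotation import intersect_regulatory, map_esnps, map_tsnps
from regenrich.ld import TableLdSource, ld_expand

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study = rr.read_fixtures(ROOT / "study")
    top_ids = io_formats.read_snp_list(ROOT / "top_snps.txt")
    source = TableLdSource(study.ld_table, study.panel)
    expanded = ld_expand(top_ids, source, r2_min=0.5)
    print(f"{len(top_ids)} top SNPs -> {len(expanded)} after LD expansion")

    esnps = map_esnps(expanded, study.catalog, source_id="expanded")
    rows = []
    for category_class in ("C1", "C2"):
        tsnps = map_tsnps(
            expanded, study.catalog, category_class, source_id="expanded"
        )
        for d in intersect_regulatory(esnps, tsnps):
            rows.append(
                {
                    "snp_id": d.snp_id,
                    "class": category_class,
                    "genes": ";".join(e.gene_id for e in d.eqtl),
                    "categories": ";".join(t.category for t in d.tfbs),
                    "truth_esnp": d.snp_id in study.truth.esnp_ids,
                    "truth_tsnp": d.snp_id in study.truth.tsnp_categories,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "candidates.tsv", sep="\t", index=False)
    print(f"{len(df)} dual eSNP/tSNP candidates -> {ROOT / 'candidates.tsv'}")
    if len(df):
        print(df.to_string(index=False))


if __name__ == "__main__":
    main()
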