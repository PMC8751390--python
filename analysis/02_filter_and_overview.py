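"""Filter the count table and summarize community composition and diversity.

Applies the standard 16S cleanup: remove chloroplast / mitochondrial /
eukaryotic / kingdom-unassigned ASVs, then keep taxa with >100 reads
total.  Summarizes phylum-level relative abundance (per-sample ASVs
below 0.05 relative abundance dropped for display, as in stacked-bar
figures), Shannon diversity per sample, and Welch two-sample t tests
of Shannon diversity between genotypes and ploidy levels.

Reads results/study/data/, writes results/study/overview/.
"""

import sys
from pathlib import Path

from rhizodmm import (
    aggregate_by_rank,
    filter_min_total_reads,
    filter_nontarget_taxa,
    to_relative_abundance,
)
from rhizodmm import io as rio
from rhizodmm.pipeline import diversity_suite

BASE = Path(__file__).resolve().parent.parent / "results" / "study"
OUT = BASE / "overview"


def main() -> int:
    ct = rio.read_count_table(BASE / "data" / "counts.tsv")
    tax = rio.read_taxonomy(BASE / "data" / "taxonomy.tsv")
    md = rio.read_metadata(BASE / "data" / "metadata.csv")

    n0 = len(ct.taxon_ids)
    ct = filter_nontarget_taxa(ct, tax)
    n1 = len(ct.taxon_ids)
    ct = filter_min_total_reads(ct, 100)
    n2 = len(ct.taxon_ids)
    print(f"taxa: {n0} -> {n1} after non-target removal -> {n2} with >100 reads")

    OUT.mkdir(parents=True, exist_ok=True)
    rio.write_count_table(ct, OUT / "counts_filtered.tsv")

    comp = to_relative_abundance(ct)
    phyla = aggregate_by_rank(comp, tax, "phylum", min_rel_abund=0.05)
    rio.write_composition(phyla, OUT / "phylum_relative_abundance.tsv")
    dominant = phyla.data.mean(axis=0).sort_values(ascending=False)
    print("dominant phyla (mean rel. abundance, >=0.05/sample ASVs only):")
    for name, value in dominant.head(4).items():
        print(f"  {name}: {value:.3f}")

    div = diversity_suite(ct, md, n_perm=999, seed=1)
    div["shannon"].to_csv(OUT / "shannon.tsv", sep="\t")
    div["welch"].to_csv(OUT / "shannon_welch_tests.tsv", sep="\t", index=False)
    print(f"Shannon diversity (planted samples): {div['shannon_mean']:.2f} "
          f"(+/- {div['shannon_se']:.3f} SE, n={len(div['shannon'])})")
    for row in div["welch"].itertuples():
        verdict = "differs" if row.P < 0.05 else "no significant difference"
        print(f"  {row.comparison}: t={row.t:.2f}, P={row.P:.3f} -> {verdict}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
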