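"""Whole-community structure: PERMANOVA contrasts and principal coordinates.

One-factor PERMANOVA (999 permutations, or exact enumeration when
feasible) on Jaccard (presence/absence) and Bray-Curtis (abundance)
dissimilarities for: plant vs unplanted soil, genotype, ploidy, and
the post hoc Col-4x vs all other rhizospheres contrast.  Also writes
PCoA coordinates of the planted-sample Jaccard matrix.

Reads the filtered table from 02; writes results/study/community/.
"""

import sys
from pathlib import Path

from rhizodmm import io as rio
from rhizodmm.pipeline import diversity_suite

BASE = Path(__file__).resolve().parent.parent / "results" / "study"
OUT = BASE / "community"


def main() -> int:
    ct = rio.read_count_table(BASE / "overview" / "counts_filtered.tsv")
    md = rio.read_metadata(BASE / "data" / "metadata.csv")

    div = diversity_suite(ct, md, n_perm=999, seed=11)
    OUT.mkdir(parents=True, exist_ok=True)
    div["permanova"].to_csv(OUT / "permanova.tsv", sep="\t", index=False)
    div["pcoa_coords"].to_csv(OUT / "pcoa_jaccard_coordinates.tsv", sep="\t")
    div["pcoa_eigenvalues"].to_csv(OUT / "pcoa_jaccard_eigenvalues.tsv", sep="\t")

    print("PERMANOVA (one factor per row):")
    for row in div["permanova"].itertuples():
        verdict = "significant" if row.P < 0.05 else "ns"
        print(f"  {row.contrast:16s} {row.metric:12s} F={row.F:6.2f} "
              f"R2={row.R2:.3f} P={row.P:.3f} [{verdict}]")
    ev = div["pcoa_eigenvalues"]
    rel = ev[ev > 0] / ev[ev > 0].sum()
    print(f"PCoA (Jaccard, planted samples): first two axes explain "
          f"{100 * rel.iloc[0]:.1f}% and {100 * rel.iloc[1]:.1f}% of positive inertia")
    return 0


if __name__ == "__main__":
    sys.exit(main())
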