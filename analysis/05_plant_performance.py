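"""Plant-performance feedback: does the inoculum's previous host matter?

Fixed-effect three-way ANOVA (inoculum + genotype + block) on above-
and belowground biomass from the inoculation experiment, residual
means by inoculum after removing genotype and block (the display
convention), Tukey HSD letters over inoculum groups, and the planned
Col-2x vs Col-4x and Ler-2x vs Ler-4x inoculum contrasts.

Reads results/study/data/phenotypes.csv; writes results/study/performance/.
"""

import sys
from pathlib import Path

from rhizodmm import io as rio
from rhizodmm.pipeline import phenotype_suite

BASE = Path(__file__).resolve().parent.parent / "results" / "study"
OUT = BASE / "performance"


def main() -> int:
    pheno = rio.read_phenotypes(BASE / "data" / "phenotypes.csv")
    suites = phenotype_suite(pheno)
    OUT.mkdir(parents=True, exist_ok=True)
    for resp, tables in suites.items():
        tables["anova"].to_csv(OUT / f"anova_{resp}.tsv", sep="\t")
        tables["tukey"].to_csv(OUT / f"tukey_{resp}.tsv", sep="\t", index=False)
        tables["residual_means"].to_csv(OUT / f"residual_means_{resp}.tsv", sep="\t")
        tables["planned_contrasts"].to_csv(OUT / f"planned_contrasts_{resp}.tsv",
                                           sep="\t", index=False)
        anova = tables["anova"]
        print(f"{resp}: ANOVA inoculum P={anova.loc['inoculum', 'PR(>F)']:.2e}, "
              f"genotype P={anova.loc['genotype', 'PR(>F)']:.2e}, "
              f"block P={anova.loc['block', 'PR(>F)']:.2e}")
        letters = tables["tukey"].attrs["letters"]
        means = tables["residual_means"]["mean"]
        print("  inoculum groups (residual mean, Tukey letter): "
              + ", ".join(f"{g}={means[g]:+.1f}{letters[g]}" for g in means.index))
        for row in tables["planned_contrasts"].itertuples():
            print(f"  planned {row.pair}: estimate={row.estimate:+.2f}, P={row.P:.3g}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
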