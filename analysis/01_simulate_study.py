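"""Simulate the desk-scale study: rhizosphere counts + inoculation phenotypes.

Emulates a 4-group rhizosphere experiment (Col-2x, Col-4x, Ler-2x,
Ler-4x; 8 replicates each) plus 7 unplanted soil controls, with
Dirichlet-multinomial overdispersion (theta = 500), read depths on the
observed 36,033-143,254 range, and a panel of planted multiplicative
effects spanning the fold-change range the differential-abundance
analysis is meant to detect (3.1- to 8-fold, on taxa of 0.3-1.2%
baseline abundance).  A handful of non-target taxa (chloroplast,
mitochondrial, eukaryotic, kingdom-unassigned reads) are included so
the filtering step has real work to do.  The phenotype experiment
plants a -20 biomass-unit penalty on everything grown in the Col-4x
inoculum.

Writes counts (TSV), metadata, placeholder taxonomy, phenotypes and
the ground-truth record under results/study/data/.
"""

import json
import sys
from pathlib import Path

from rhizodmm import Effect, SyntheticSpec, generate_truth, simulate_counts, simulate_phenotypes
from rhizodmm import io as rio
from rhizodmm.simulate import placeholder_taxonomy

OUT = Path(__file__).resolve().parent.parent / "results" / "study" / "data"
SEED = 20260924

# planted effects: (taxon index, target groups, fold, baseline abundance)
PLANTED = [
    (10, ("Ler-2x", "Ler-4x"), 8.0, 0.004),   # strongest genotype effect
    (11, ("Col-2x", "Col-4x"), 4.8, 0.006),
    (12, ("Col-2x", "Ler-2x"), 3.1, 0.010),   # ploidy effects
    (13, ("Col-4x", "Ler-4x"), 4.0, 0.005),
    (14, ("Col-4x",), 6.0, 0.003),            # Col-4x-specific enrichment
    (15, ("Col-4x",), 5.0, 0.008),
]


def main() -> int:
    spec = SyntheticSpec(
        n_taxa=300,
        theta_true=500.0,
        effects=[Effect(i, g, f) for i, g, f, _ in PLANTED],
        fixed_baseline={i: b for i, g, f, b in PLANTED},
        seed=SEED,
    )
    truth = generate_truth(spec)
    ct, md = simulate_counts(truth, spec)
    tax = placeholder_taxonomy(ct.taxon_ids, seed=SEED, n_chloroplast=3,
                               n_mitochondrion=2, n_eukaryote=2, n_kingdom_na=3)
    pheno = simulate_phenotypes(
        inoculum_effects={"Col-4x": -20.0},
        genotype_effects={"Ler-4x": 5.0, "Col-2x": -2.0},
        block_effects={"B1": 3.0, "B3": -2.0},
        grand_mean=100.0, noise_sd=8.0, seed=SEED,
    )

    OUT.mkdir(parents=True, exist_ok=True)
    rio.write_count_table(ct, OUT / "counts.tsv")
    rio.write_metadata(md, OUT / "metadata.csv")
    rio.write_taxonomy(tax, OUT / "taxonomy.tsv")
    pheno.to_csv(OUT / "phenotypes.csv", index=False)
    truth.to_json(OUT / "truth.json")
    with open(OUT / "planted_effects.json", "w") as fh:
        json.dump([{"taxon": f"ASV{i:04d}", "groups": list(g), "fold": f,
                    "baseline": b} for i, g, f, b in PLANTED], fh, indent=2)

    print(f"wrote {ct.shape[0]} samples x {ct.shape[1]} taxa to {OUT}")
    print(f"depths: {ct.depths.min()}-{ct.depths.max()} reads")
    print(f"groups: {md.groups.value_counts().to_dict()}")
    print(f"planted effects: {len(PLANTED)} taxa, folds "
          f"{sorted(f for _, _, f, _ in PLANTED)}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
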