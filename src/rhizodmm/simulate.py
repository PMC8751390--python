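"""Synthetic rhizosphere datasets with known ground truth.

The generator is the exact generative dual of the Dirichlet-multinomial
likelihood fitted by :mod:`rhizodmm.dmm`: each group g has an expected
composition pi_g; each replicate draws its own composition
p ~ Dirichlet(theta_true * pi_g) (theta_true controls replicate-to-
replicate overdispersion) and counts ~ Multinomial(depth, p) with depth
uniform on the study's observed range (36,033-143,254 reads).

Group compositions derive from a common baseline (symmetric Dirichlet
draw) by multiplying planted effect taxa by a fold change and
renormalizing, so every planted effect has a closed-form true log10
fold change recorded in :class:`SyntheticTruth`.  Unplanted soil
controls get their own composition: the baseline perturbed by per-taxon
log-normal fold changes, mimicking the strong but taxon-shared
divergence of bulk soil from rhizosphere communities.

All randomness flows from the single spec seed through named substreams
(baseline, soil, depths, counts, phenotypes), so each stage is
independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tables import GROUPS, SOIL_GROUP, CountTable, SampleMetadata

DEPTH_RANGE = (36_033, 143_254)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of a single integer seed."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class Effect:
    """A planted multiplicative abundance effect.

    ``taxon`` (index into the taxon axis) is multiplied by ``fold`` in
    every group listed in ``groups``, then the composition is
    renormalized.
    """

    taxon: int
    groups: tuple
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold change must be > 0")
        self.groups = tuple(self.groups)


@dataclass
class SyntheticSpec:
    """Design of a synthetic rhizosphere experiment.

    Defaults mirror the emulated study: four planted groups of eight
    replicates plus seven unplanted soil controls, depths uniform on
    the observed read-depth range, and a mildly skewed baseline
    (symmetric Dirichlet with concentration 0.5, giving a few dominant
    and many rare taxa as in real 16S data).  ``theta_true`` sets the
    Dirichlet-multinomial overdispersion; 500 corresponds to strong but
    realistic replicate-to-replicate variation.
    """

    n_taxa: int = 2689
    replicates: dict = field(default_factory=lambda: {g: 8 for g in GROUPS})
    n_soil: int = 7
    base_concentration: float = 0.5
    theta_true: float = 500.0
    effects: list = field(default_factory=list)
    fixed_baseline: dict = field(default_factory=dict)
    soil_lognormal_sd: float = 0.75
    depth_range: tuple = DEPTH_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        if self.depth_range[0] > self.depth_range[1]:
            raise ValueError("depth_range must be (min, max) with min <= max")
        if any(n < 1 for n in self.replicates.values()):
            raise ValueError("replicate counts must be >= 1")
        self.effects = [e if isinstance(e, Effect) else Effect(**e) for e in self.effects]
        for e in self.effects:
            if not 0 <= e.taxon < self.n_taxa:
                raise ValueError(f"effect taxon index {e.taxon} out of range")
            unknown = set(e.groups) - set(self.replicates)
            if unknown:
                raise ValueError(f"effect targets unknown groups {sorted(unknown)}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Generator-side ground truth: per-group pi, theta, planted effects."""

    pi: pd.DataFrame  # groups x taxa, rows sum to 1
    theta: float
    effects: list
    pi_soil: np.ndarray = None

    def __post_init__(self) -> None:
        sums = self.pi.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12), "group compositions must sum to 1"

    def log10_fold_change(self, g1: str, g2: str) -> np.ndarray:
        """True per-taxon log10(pi_g1 / pi_g2)."""
        return np.log10(self.pi.loc[g1].to_numpy() / self.pi.loc[g2].to_numpy())

    def differential_taxa(self, g1: str, g2: str, tol: float = 1e-12) -> list:
        """Taxon indices whose true abundance differs between g1 and g2."""
        lfc = self.log10_fold_change(g1, g2)
        return [int(i) for i in np.nonzero(np.abs(lfc) > tol)[0]]

    def to_json(self, path) -> None:
        doc = {
            "theta": self.theta,
            "groups": list(self.pi.index),
            "taxa": list(self.pi.columns),
            "pi": self.pi.to_numpy().tolist(),
            "pi_soil": None if self.pi_soil is None else list(map(float, self.pi_soil)),
            "effects": [asdict(e) for e in self.effects],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


def _baseline(spec: SyntheticSpec) -> np.ndarray:
    rng = substream(spec.seed, "baseline")
    pi = rng.dirichlet(np.full(spec.n_taxa, spec.base_concentration))
    # keep strictly positive: floor at 1e-9 of total, renormalize
    pi = np.maximum(pi, 1e-9)
    for taxon, abund in spec.fixed_baseline.items():
        others = pi.sum() - pi[taxon]
        pi[taxon] = 0.0
        pi *= (1.0 - abund) / others
        pi[taxon] = abund
    return pi / pi.sum()


def generate_truth(spec: SyntheticSpec) -> SyntheticTruth:
    """Draw the baseline composition and apply planted group effects."""
    base = _baseline(spec)
    taxa = [f"ASV{i:04d}" for i in range(spec.n_taxa)]
    rows = {}
    for g in spec.replicates:
        pi = base.copy()
        for e in spec.effects:
            if g in e.groups:
                pi[e.taxon] *= e.fold
        rows[g] = pi / pi.sum()
    truth_pi = pd.DataFrame(rows).T
    truth_pi.columns = taxa
    rng_soil = substream(spec.seed, "soil")
    pi_soil = base * np.exp(rng_soil.normal(0.0, spec.soil_lognormal_sd, spec.n_taxa))
    pi_soil /= pi_soil.sum()
    return SyntheticTruth(truth_pi, spec.theta_true, list(spec.effects), pi_soil)


def simulate_counts(truth: SyntheticTruth, spec: SyntheticSpec):
    """Draw replicate count vectors under the Dirichlet-multinomial model.

    Returns ``(CountTable, SampleMetadata)`` covering the planted groups
    plus ``spec.n_soil`` unplanted soil controls.
    """
    rng_depth = substream(spec.seed, "depths")
    rng_counts = substream(spec.seed, "counts")
    lo, hi = spec.depth_range
    rows, meta_rows, ids = [], [], []
    plan = [(g, n, truth.pi.loc[g].to_numpy()) for g, n in spec.replicates.items()]
    if spec.n_soil and truth.pi_soil is not None:
        plan.append((SOIL_GROUP, spec.n_soil, truth.pi_soil))
    for g, n, pi in plan:
        alpha = truth.theta * pi
        for j in range(n):
            depth = int(rng_depth.integers(lo, hi + 1))
            p = rng_counts.dirichlet(alpha)
            rows.append(rng_counts.multinomial(depth, p))
            sid = f"{g}-r{j + 1}"
            ids.append(sid)
            if g == SOIL_GROUP:
                meta_rows.append({"sample_id": sid, "genotype": None, "ploidy": None,
                                  "block": f"B{j % 4 + 1}", "is_soil_control": True})
            else:
                if "-" in g and g.rsplit("-", 1)[1] in {"2x", "4x"}:
                    geno, ploidy = g.rsplit("-", 1)
                else:
                    geno, ploidy = g, None
                meta_rows.append({"sample_id": sid, "genotype": geno, "ploidy": ploidy,
                                  "block": f"B{j % 4 + 1}", "is_soil_control": False})
    counts = pd.DataFrame(np.asarray(rows), index=ids, columns=truth.pi.columns)
    ct = CountTable(counts, [{"op": "simulate_counts", "spec": spec.to_dict()}])
    md = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return ct, md


def make_null_dataset(spec: SyntheticSpec):
    """Dataset with no planted effects (identical pi across groups)."""
    null_spec = SyntheticSpec(**{**spec.to_dict(), "effects": []})
    truth = generate_truth(null_spec)
    ct, md = simulate_counts(truth, null_spec)
    return ct, md, truth


PLACEHOLDER_PHYLA = (
    "Proteobacteria", "Bacteroidetes", "Actinobacteria", "Acidobacteria",
    "Firmicutes", "Verrucomicrobia", "Planctomycetes", "Chloroflexi",
)


def placeholder_taxonomy(taxon_ids, seed: int = 0, n_chloroplast: int = 0,
                         n_mitochondrion: int = 0, n_eukaryote: int = 0,
                         n_kingdom_na: int = 0):
    """Synthetic placeholder lineages for a list of taxon ids.

    Assigns each taxon a random bacterial phylum (genus/species left
    "NA", as is common for environmental ASVs); the first
    ``n_chloroplast + n_mitochondrion + n_eukaryote + n_kingdom_na``
    taxa instead get non-target lineages, so the standard filtering
    step has something to remove.  Purely synthetic: no relation to any
    reference database.
    """
    import pandas as pd

    from .tables import NA_RANK, TaxonomyTable

    rng = substream(seed, "taxonomy")
    rows = []
    special = (["chloroplast"] * n_chloroplast + ["mitochondrion"] * n_mitochondrion
               + ["eukaryote"] * n_eukaryote + ["kingdom_na"] * n_kingdom_na)
    if len(special) > len(taxon_ids):
        raise ValueError("more non-target taxa requested than taxon ids")
    for i, taxon in enumerate(taxon_ids):
        kind = special[i] if i < len(special) else "bacteria"
        if kind == "chloroplast":
            rows.append({"kingdom": "Bacteria", "phylum": "Cyanobacteria",
                         "class": "Chloroplast"})
        elif kind == "mitochondrion":
            rows.append({"kingdom": "Bacteria", "phylum": "Proteobacteria",
                         "family": "Mitochondria"})
        elif kind == "eukaryote":
            rows.append({"kingdom": "Eukaryota", "phylum": "Streptophyta"})
        elif kind == "kingdom_na":
            rows.append({"kingdom": NA_RANK})
        else:
            rows.append({"kingdom": "Bacteria",
                         "phylum": PLACEHOLDER_PHYLA[int(rng.integers(len(PLACEHOLDER_PHYLA)))]})
    return TaxonomyTable(pd.DataFrame(rows, index=list(taxon_ids)))


# ---------------------------------------------------------------------------
# phenotypes (inoculation experiment)

GENOTYPES = GROUPS  # four host genotypes, same labels as the inocula


def simulate_phenotypes(
    genotype_effects: dict = None,
    inoculum_effects: dict = None,
    block_effects: dict = None,
    grand_mean: float = 100.0,
    noise_sd: float = 10.0,
    n_per_cell: int = 24,
    n_blocks: int = 4,
    responses: tuple = ("aboveground_biomass", "belowground_biomass"),
    seed: int = 0,
) -> pd.DataFrame:
    """Fully crossed genotype x inoculum factorial with additive effects.

    response = grand mean + genotype effect + inoculum effect + block
    effect + Gaussian noise.  Defaults give 4 x 4 x 24 = 384 plants,
    matching the scale of a biomass harvest, spread evenly over
    ``n_blocks`` blocks.  Effects are dicts mapping level -> additive
    shift (missing levels shift by 0); the same effects apply to every
    response column.
    """
    genotype_effects = genotype_effects or {}
    inoculum_effects = inoculum_effects or {}
    block_effects = block_effects or {}
    rng = substream(seed, "phenotypes")
    recs = []
    plant = 0
    for geno in GENOTYPES:
        for inoc in GENOTYPES:
            for j in range(n_per_cell):
                block = f"B{j % n_blocks + 1}"
                mu = (grand_mean + genotype_effects.get(geno, 0.0)
                      + inoculum_effects.get(inoc, 0.0) + block_effects.get(block, 0.0))
                rec = {"plant_id": f"P{plant:04d}", "genotype": geno,
                       "inoculum": inoc, "block": block}
                for resp in responses:
                    rec[resp] = mu + rng.normal(0.0, noise_sd)
                recs.append(rec)
                plant += 1
    return pd.DataFrame(recs)
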