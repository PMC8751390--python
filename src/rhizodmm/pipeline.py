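"""End-to-end orchestration: simulate, analyze, recovery.

Each stage is a plain function over a :class:`RunConfig`; the CLI and
the numbered analysis scripts are thin wrappers around these.  Every
output directory receives a ``run_log.json`` recording the config, its
hash, the seed, and per-stage timings, so re-running a command with
the same config reproduces outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, io, phenotype
from .dmm import DMMSettings, compare_groups, fit_dmm, gelman_rubin, standard_comparisons
from .filters import filter_min_total_reads, filter_nontarget_taxa, to_relative_abundance
from .simulate import (
    SyntheticSpec,
    generate_truth,
    make_null_dataset,
    simulate_counts,
    simulate_phenotypes,
)
from .tables import SOIL_GROUP, CountTable, SampleMetadata


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Configuration for a pipeline run.

    Exactly one of ``synthetic`` (a SyntheticSpec) or ``counts_path``
    must be provided.  ``min_total_reads`` < 0 disables the
    most-abundant-taxa filter (it is optional, applied before the
    community analyses when enabled).
    """

    out_dir: str = "results/run"
    seed: int = 0
    synthetic: SyntheticSpec = None
    counts_path: str = None
    counts_format: str = "tsv"
    taxonomy_path: str = None
    metadata_path: str = None
    phenotypes_path: str = None
    min_total_reads: int = -1
    dmm: DMMSettings = field(default_factory=DMMSettings)
    n_permutations: int = 999
    overwrite: bool = False

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.counts_path is None):
            raise ConfigError("provide exactly one of synthetic spec or counts_path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "synthetic" in doc and doc["synthetic"] is not None:
            try:
                doc["synthetic"] = SyntheticSpec(**doc["synthetic"])
            except TypeError as exc:
                raise ConfigError(f"invalid synthetic spec: {exc}") from exc
        if "dmm" in doc and doc["dmm"] is not None:
            doc["dmm"] = DMMSettings(**doc["dmm"])
        return cls(**doc)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        return doc

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _prepare_out(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise FileExistsError(f"output directory {out} is not empty (use overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_log(out: Path, config: RunConfig, stages: dict) -> None:
    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {"config": config.to_dict(), "config_hash": config.config_hash(),
             "seed": config.seed, "stage_seconds": stages},
            fh, indent=2, default=str,
        )


def cmd_simulate(config: RunConfig) -> Path:
    """Write a synthetic dataset (counts, metadata, phenotypes, truth)."""
    if config.synthetic is None:
        raise ConfigError("simulate requires a synthetic spec")
    out = _prepare_out(config)
    t0 = time.time()
    spec = dataclasses.replace(config.synthetic, seed=config.seed)
    truth = generate_truth(spec)
    ct, md = simulate_counts(truth, spec)
    io.write_count_table(ct, out / "counts.tsv")
    io.write_count_table(ct, out / "counts.biom", format="biom")
    io.write_metadata(md, out / "metadata.csv")
    truth.to_json(out / "truth.json")
    pheno = simulate_phenotypes(seed=config.seed)
    pheno.to_csv(out / "phenotypes.csv", index=False)
    _write_log(out, config, {"simulate": time.time() - t0})
    return out


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        truth = generate_truth(spec)
        ct, md = simulate_counts(truth, spec)
        pheno = None
    else:
        ct = io.read_count_table(config.counts_path, format=config.counts_format)
        if config.taxonomy_path:
            tax = io.read_taxonomy(config.taxonomy_path)
            ct = filter_nontarget_taxa(ct, tax)
        md = io.read_metadata(config.metadata_path)
        pheno = None
    if config.phenotypes_path:
        pheno = io.read_phenotypes(config.phenotypes_path)
    return ct, md, pheno


#: PERMANOVA contrasts mirroring the study's community-composition table
PERMANOVA_CONTRASTS = {
    "plant_vs_soil": lambda row: SOIL_GROUP if row["is_soil_control"] else "plant",
    "genotype": lambda row: None if row["is_soil_control"] else row["genotype"],
    "ploidy": lambda row: None if row["is_soil_control"] else row["ploidy"],
    "Col4x_vs_others": lambda row: None if row["is_soil_control"] else (
        "Col-4x" if row["group"] == "Col-4x" else "others"
    ),
}


def diversity_suite(ct: CountTable, md: SampleMetadata, n_perm: int = 999,
                    seed: int = 0) -> dict:
    """Dissimilarity, PERMANOVA, PCoA, Shannon, and Welch-t analyses.

    PERMANOVA rows mirror the study's community table: plant vs soil
    (soil controls included), then genotype, ploidy, and Col-4x vs
    others on planted samples only; each on both Jaccard and
    Bray-Curtis.  Distance matrices are computed after subsetting.
    """
    rows = []
    for contrast, rule in PERMANOVA_CONTRASTS.items():
        labels = md.data.apply(rule, axis=1).dropna()
        samples = [s for s in ct.sample_ids if s in labels.index]
        sub = ct.subset_samples(samples)
        for metric, fn in (("jaccard", diversity.jaccard), ("bray_curtis", diversity.bray_curtis)):
            d = fn(sub)
            res = diversity.permanova(d, labels.loc[samples], n_perm=n_perm, seed=seed)
            rows.append({"contrast": contrast, "metric": metric, "F": res.pseudo_f,
                         "R2": res.r2, "P": res.p_value, "n_perm": res.n_permutations,
                         "exact": res.exact})
    permanova_table = pd.DataFrame(rows)

    planted = md.planted()
    planted_samples = [s for s in ct.sample_ids if s in planted.data.index]
    ct_planted = ct.subset_samples(planted_samples)
    d_j = diversity.jaccard(ct_planted)
    coords, eigvals = diversity.pcoa(d_j)

    sh = diversity.shannon(ct_planted)
    geno = planted.data.loc[planted_samples, "genotype"]
    ploidy = planted.data.loc[planted_samples, "ploidy"]
    welch_rows = []
    comparisons = {
        "genotype_Col_vs_Ler": (sh[geno == "Col"], sh[geno == "Ler"]),
        "ploidy_2x_vs_4x": (sh[ploidy == "2x"], sh[ploidy == "4x"]),
        "Col_2x_vs_4x": (sh[(geno == "Col") & (ploidy == "2x")], sh[(geno == "Col") & (ploidy == "4x")]),
        "Ler_2x_vs_4x": (sh[(geno == "Ler") & (ploidy == "2x")], sh[(geno == "Ler") & (ploidy == "4x")]),
    }
    for name, (x, y) in comparisons.items():
        if len(x) >= 2 and len(y) >= 2:
            t, df, p = diversity.welch_t(x, y)
            welch_rows.append({"comparison": name, "t": t, "df": df, "P": p})
    return {
        "permanova": permanova_table,
        "pcoa_coords": coords,
        "pcoa_eigenvalues": eigvals,
        "shannon": sh,
        "shannon_mean": float(sh.mean()),
        "shannon_se": float(sh.sem()),
        "welch": pd.DataFrame(welch_rows),
    }


def phenotype_suite(pheno: pd.DataFrame, responses=("aboveground_biomass",
                                                    "belowground_biomass")) -> dict:
    """ANOVA, residual means, Tukey HSD, and planned contrasts per response."""
    out = {}
    for resp in responses:
        if resp not in pheno.columns:
            continue
        anova = phenotype.fit_anova3(pheno, resp)
        tukey = phenotype.tukey_hsd(pheno, resp, "inoculum")
        resid = phenotype.residual_means_by_inoculum(pheno, resp)
        contrasts = []
        for pair in (("Col-2x", "Col-4x"), ("Ler-2x", "Ler-4x")):
            est, t, p = phenotype.planned_contrast(pheno, resp, pair)
            contrasts.append({"pair": " vs ".join(pair), "estimate": est, "t": t, "P": p})
        out[resp] = {"anova": anova, "tukey": tukey, "residual_means": resid,
                     "planned_contrasts": pd.DataFrame(contrasts)}
    return out


def cmd_analyze(config: RunConfig) -> Path:
    """Full analysis: filters, three DMM contrasts, diversity, phenotypes."""
    out = _prepare_out(config)
    stages = {}
    t0 = time.time()
    ct, md, pheno = _load_inputs(config)
    if config.min_total_reads >= 0:
        ct = filter_min_total_reads(ct, config.min_total_reads)
    stages["load"] = time.time() - t0

    t0 = time.time()
    dmm_settings = dataclasses.replace(config.dmm, seed=config.seed)
    results = standard_comparisons(ct, md, dmm_settings)
    diag = {}
    for name, res in results.items():
        res.table.to_csv(out / f"differential_abundance_{name}.tsv", sep="\t")
        rhat = gelman_rubin(res.posterior)
        diag[name] = {
            "rhat_max": float(rhat.max()), "rhat_mean": float(rhat.mean()),
            "acceptance": res.posterior.acceptance,
            "n_draws": int(res.posterior.n_draws),
            "n_flagged": res.n_flagged,
        }
    with open(out / "dmm_diagnostics.json", "w") as fh:
        json.dump(diag, fh, indent=2)
    stages["dmm"] = time.time() - t0

    t0 = time.time()
    div = diversity_suite(ct, md, n_perm=config.n_permutations, seed=config.seed)
    div["permanova"].to_csv(out / "permanova.tsv", sep="\t", index=False)
    div["pcoa_coords"].to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    div["shannon"].to_csv(out / "shannon.tsv", sep="\t")
    div["welch"].to_csv(out / "shannon_welch_tests.tsv", sep="\t", index=False)
    stages["diversity"] = time.time() - t0

    if pheno is not None:
        t0 = time.time()
        ph = phenotype_suite(pheno)
        for resp, tables in ph.items():
            tables["anova"].to_csv(out / f"anova_{resp}.tsv", sep="\t")
            tables["tukey"].to_csv(out / f"tukey_{resp}.tsv", sep="\t", index=False)
            tables["residual_means"].to_csv(out / f"residual_means_{resp}.tsv", sep="\t")
            tables["planned_contrasts"].to_csv(out / f"planned_contrasts_{resp}.tsv",
                                               sep="\t", index=False)
        stages["phenotype"] = time.time() - t0
    _write_log(out, config, stages)
    return out


def cmd_recovery(config: RunConfig, n_replicates: int = 20,
                 effect_taxon_abundance: float = 0.005,
                 effect_fold: float = 8.0) -> dict:
    """Simulate-and-refit study: coverage, bias, null calibration, power.

    Runs ``n_replicates`` null datasets (recovery + false-flag rate)
    and ``n_replicates`` datasets with a planted fold-change effect
    (power), at the spec in ``config.synthetic``.
    """
    if config.synthetic is None:
        raise ConfigError("recovery requires a synthetic spec")
    base = dataclasses.replace(config.synthetic, effects=[])
    cover, bias, flag_rates, hits = [], [], [], []
    for r in range(n_replicates):
        spec = dataclasses.replace(base, seed=config.seed + 1000 + r)
        ct, md, truth = make_null_dataset(spec)
        groups = md.planted().groups
        levels = list(dict.fromkeys(groups))
        side1 = set(levels[: max(1, len(levels) // 2)])
        two = groups.map(lambda g: "g1" if g in side1 else "g2")
        post = fit_dmm(ct.subset_samples(list(two.index)), two,
                       dataclasses.replace(config.dmm, seed=config.seed + r))
        res = compare_groups(post, "g1", "g2")
        flag_rates.append(float(res.table["flagged"].mean()))
        pi_true = truth.pi.iloc[0].to_numpy()  # null: identical across groups
        for g in ("g1", "g2"):
            draws = post.pooled_pi(g)
            lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
            cover.append(float(((lo <= pi_true) & (pi_true <= hi)).mean()))
            sel = pi_true > 0.005
            if sel.any():
                bias.append(float(np.abs(draws.mean(axis=0) - pi_true)[sel].max()))
    for r in range(n_replicates):
        from .simulate import Effect

        spec = dataclasses.replace(
            base, seed=config.seed + 2000 + r,
            effects=[Effect(0, ("Col-4x",), effect_fold)],
            fixed_baseline={0: effect_taxon_abundance},
        )
        truth = generate_truth(spec)
        ct, md = simulate_counts(truth, spec)
        groups = md.planted().groups
        mapping = groups.map(lambda g: "Col-4x" if g == "Col-4x" else "others")
        post = fit_dmm(ct.subset_samples(list(mapping.index)), mapping,
                       dataclasses.replace(config.dmm, seed=config.seed + r))
        res = compare_groups(post, "Col-4x", "others")
        row = res.table.iloc[0]
        hits.append(bool(row["flagged"]) and row["direction"] == "Col-4x")
    report = {
        "n_replicates": n_replicates,
        "coverage_mean": float(np.mean(cover)),
        "max_abs_error_abundant": float(max(bias)) if bias else float("nan"),
        "null_flagged_fraction_mean": float(np.mean(flag_rates)),
        "power": float(np.mean(hits)),
    }
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "recovery_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
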