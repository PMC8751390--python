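"""Core tabular containers for amplicon count data.

Everything downstream (filtering, the Dirichlet-multinomial model, the
community statistics) consumes these three containers:

``CountTable``
    samples x taxa matrix of non-negative integer read counts.
``TaxonomyTable``
    per-taxon ranked lineage plus derived non-target flags
    (chloroplast / mitochondrion / eukaryote / kingdom-unassigned).
``SampleMetadata``
    per-sample experimental factors: host genotype (Col / Ler), ploidy
    (2x / 4x), block, and a soil-control flag; the group label is the
    deterministic concatenation "<genotype>-<ploidy>" or "soil".

All containers wrap a :class:`pandas.DataFrame` and validate their
invariants at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: literal used for unassigned ranks on input and output
NA_RANK = "NA"

GROUPS = ("Col-2x", "Col-4x", "Ler-2x", "Ler-4x")
SOIL_GROUP = "soil"


class ValidationError(ValueError):
    """Raised when a table violates one of its structural invariants."""


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:10]}")


@dataclass
class CountTable:
    """Samples x taxa read-count matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample id, columns by taxon id, integer counts.
    provenance : list of dict
        Log of operations (filters, simulation parameters) that produced
        this table; carried through every transformation.
    """

    data: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        _check_unique(self.data.columns, "taxon ids")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValidationError("counts must be integer-valued")
            self.data = self.data.astype(np.int64)
            values = self.data.to_numpy()
        if values.size and values.min() < 0:
            bad = self.data.columns[(self.data < 0).any(axis=0)].tolist()
            raise ValidationError(f"negative counts in taxa {bad[:10]}")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def depths(self) -> pd.Series:
        """Per-sample sequencing depth (row sums)."""
        return self.data.sum(axis=1)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def with_provenance(self, entry: dict) -> "CountTable":
        return CountTable(self.data, [*self.provenance, entry])

    def subset_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.data.loc[list(sample_ids)], list(self.provenance))


@dataclass
class CompositionTable:
    """Samples x taxa relative-abundance matrix (rows sum to 1).

    After the per-sample plotting filter (drop ASVs below a relative
    abundance threshold) rows may sum to less than 1; ``partial=True``
    marks that state.
    """

    data: pd.DataFrame
    partial: bool = False

    _TOL = 1e-9

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if values.size:
            if values.min() < -self._TOL or values.max() > 1 + self._TOL:
                raise ValidationError("relative abundances must lie in [0, 1]")
            sums = values.sum(axis=1)
            if self.partial:
                if np.any(sums > 1 + self._TOL):
                    raise ValidationError("row sums exceed 1")
            elif np.any(np.abs(sums - 1.0) > self._TOL):
                bad = self.data.index[np.abs(sums - 1.0) > self._TOL].tolist()
                raise ValidationError(f"rows do not sum to 1: {bad[:10]}")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)


def _flag_lineage(lineage: pd.Series) -> pd.Series:
    """Derive non-target flags from a single taxon's ranked lineage."""
    strings = {r: str(lineage.get(r, NA_RANK)) for r in RANKS}
    joined = ";".join(strings.values()).lower()
    kingdom = strings["kingdom"].strip()
    return pd.Series(
        {
            "is_chloroplast": "chloroplast" in joined,
            "is_mitochondrion": "mitochondri" in joined,
            "is_eukaryote": kingdom.lower() in {"eukaryota", "eukarya", "eukaryote"},
            "kingdom_unassigned": kingdom in {NA_RANK, "", "nan", "None", "Unassigned"},
        }
    )


@dataclass
class TaxonomyTable:
    """Per-taxon ranked lineage with derived non-target flags.

    ``data`` is indexed by taxon id with the seven rank columns; missing
    ranks are stored as the literal ``"NA"``.  ``flags`` is derived
    deterministically from the lineage strings.
    """

    data: pd.DataFrame
    flags: pd.DataFrame = None

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "taxon ids")
        for rank in RANKS:
            if rank not in self.data.columns:
                self.data[rank] = NA_RANK
        self.data = self.data[list(RANKS)].fillna(NA_RANK).astype(str)
        self.data = self.data.replace({"": NA_RANK, "nan": NA_RANK})
        self.flags = self.data.apply(_flag_lineage, axis=1)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.index)

    def nontarget(self) -> pd.Series:
        """Boolean: taxon has any non-target flag (drop it)."""
        return self.flags.any(axis=1)

    def lineage(self, taxon_id: str) -> pd.Series:
        return self.data.loc[taxon_id]


@dataclass
class SampleMetadata:
    """Per-sample factors: genotype, ploidy, block, soil-control flag.

    The ``group`` column is always re-derived: ``"<genotype>-<ploidy>"``
    for planted samples, ``"soil"`` for unplanted controls.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        df = self.data.copy()
        if "is_soil_control" not in df.columns:
            df["is_soil_control"] = df.get("genotype", pd.Series(index=df.index)).isna()
        df["is_soil_control"] = df["is_soil_control"].astype(bool)
        for col in ("genotype", "ploidy"):
            if col not in df.columns:
                df[col] = None
            df[col] = df[col].where(~df["is_soil_control"], other=None)
        soil = df["is_soil_control"]
        if df.loc[~soil, "genotype"].isna().any():
            raise ValidationError("planted samples must have a genotype")
        if df.loc[soil, ["genotype", "ploidy"]].notna().any(axis=1).any():
            raise ValidationError("soil controls must not carry genotype/ploidy")
        planted_group = df["genotype"].astype(str).where(
            df["ploidy"].isna(), df["genotype"].astype(str) + "-" + df["ploidy"].astype(str)
        )
        df["group"] = np.where(soil, SOIL_GROUP, planted_group)
        if "block" not in df.columns:
            df["block"] = "B1"
        self.data = df

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    def planted(self) -> "SampleMetadata":
        """Subset to planted (non-soil) samples."""
        return SampleMetadata(self.data[~self.data["is_soil_control"]].copy())
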