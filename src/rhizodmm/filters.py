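"""Count-table filtering and relative-abundance transforms.

The filtering protocol for 16S rhizosphere data: drop ASVs classified as
chloroplast, mitochondrion, or eukaryote, and ASVs with no kingdom-level
classification (ASVs unassigned at any *lower* rank are retained); then
optionally keep only taxa with more than a minimum total read count
across all samples.  Downstream display aggregates relative abundances
by rank after a per-sample minimum-abundance cut.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import NA_RANK, CompositionTable, CountTable, TaxonomyTable, ValidationError


def filter_nontarget_taxa(ct: CountTable, tax: TaxonomyTable) -> CountTable:
    """Remove chloroplast / mitochondrial / eukaryotic / kingdom-unassigned taxa.

    Every taxon in ``ct`` must be present in ``tax``; taxa whose lineage
    is unassigned below kingdom are retained.
    """
    missing = [t for t in ct.taxon_ids if t not in tax.data.index]
    if missing:
        raise ValidationError(f"taxa missing from taxonomy: {missing[:10]}")
    drop = tax.nontarget()
    keep = [t for t in ct.taxon_ids if not drop.loc[t]]
    out = CountTable(ct.data[keep], list(ct.provenance))
    return out.with_provenance(
        {"op": "filter_nontarget_taxa", "removed": int(len(ct.taxon_ids) - len(keep))}
    )


def filter_min_total_reads(ct: CountTable, threshold: int) -> CountTable:
    """Keep taxa whose total count across all samples is strictly > threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    totals = ct.data.sum(axis=0)
    keep = totals.index[totals > threshold]
    out = CountTable(ct.data[list(keep)], list(ct.provenance))
    return out.with_provenance(
        {
            "op": "filter_min_total_reads",
            "threshold": int(threshold),
            "removed": int(len(ct.taxon_ids) - len(keep)),
        }
    )


def to_relative_abundance(ct: CountTable) -> CompositionTable:
    """Convert counts to per-sample proportions (rows sum to 1)."""
    depths = ct.depths
    zero = depths.index[depths == 0].tolist()
    if zero:
        raise ValidationError(f"zero-depth samples: {zero[:10]}")
    return CompositionTable(ct.data.div(depths, axis=0))


def aggregate_by_rank(
    comp: CompositionTable,
    tax: TaxonomyTable,
    rank: str,
    min_rel_abund: float = 0.0,
) -> CompositionTable:
    """Sum relative abundances within a taxonomy rank.

    ASVs below ``min_rel_abund`` in a sample are dropped (per sample)
    before summing — the display convention for stacked-bar figures —
    so rows may sum to less than 1 when the cut is active.  ASVs with
    the rank unassigned are pooled into an ``"NA"`` bin.
    """
    if rank not in tax.data.columns:
        raise ValueError(f"unknown rank {rank!r}")
    values = comp.data.to_numpy(dtype=float).copy()
    if min_rel_abund > 0:
        values[values < min_rel_abund] = 0.0
    labels = tax.data[rank].reindex(comp.taxon_ids).fillna(NA_RANK)
    df = pd.DataFrame(values, index=comp.data.index, columns=comp.data.columns)
    agg = df.T.groupby(labels.values).sum().T
    agg = agg[sorted(agg.columns, key=lambda c: (c == NA_RANK, c))]
    return CompositionTable(agg, partial=min_rel_abund > 0)


def composition_to_counts(comp: CompositionTable, depths) -> CountTable:
    """Inverse of :func:`to_relative_abundance` for exact proportions."""
    depths = pd.Series(depths, index=comp.data.index) if not isinstance(depths, pd.Series) else depths
    counts = comp.data.mul(depths, axis=0)
    rounded = counts.round()
    if not np.allclose(counts.to_numpy(), rounded.to_numpy(), atol=1e-6):
        raise ValidationError("composition x depth is not integral")
    return CountTable(rounded.astype(np.int64))
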