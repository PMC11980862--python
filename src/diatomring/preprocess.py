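"""Post-bioinformatics filtering and aggregation of abundance tables.

The pipeline consumes taxonomically assigned count tables (denoising and
classification happen upstream) and applies the standard cleaning rules:
non-target and unclassified taxa are discarded, low-abundance cells are
zeroed (fewer than 10 reads *and* under 0.01% of the sample), counts are
converted to relative abundances, and fine taxonomic units are aggregated to
species or genus for community-level comparisons.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import AbundanceTable, TableError

MIN_READS = 10
MIN_FRACTION = 0.0001  # 0.01% of the sample

TARGET_PHYLUM = "Bacillariophyta"


@dataclass
class TaxonomyMap:
    """Taxon id -> (phylum, genus, species, assignment label)."""

    data: pd.DataFrame  # index taxon, columns phylum/genus/species/label

    def __post_init__(self) -> None:
        required = {"phylum", "genus", "species", "label"}
        missing = required - set(self.data.columns)
        if missing:
            raise TableError(f"taxonomy map missing columns {sorted(missing)}")

    def require(self, taxa: Sequence[str]) -> pd.DataFrame:
        missing = [t for t in taxa if t not in self.data.index]
        if missing:
            raise TableError(f"taxa missing from taxonomy: {missing[:5]}")
        return self.data.loc[list(taxa)]

    @classmethod
    def identity(cls, taxa: Sequence[str], phylum: str = TARGET_PHYLUM) -> "TaxonomyMap":
        """Each taxon is its own species of the target phylum (synthetic data)."""
        df = pd.DataFrame(
            {
                "phylum": phylum,
                "genus": [t.split("_")[0] for t in taxa],
                "species": list(taxa),
                "label": list(taxa),
            },
            index=list(taxa),
        )
        return cls(df)


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    return TaxonomyMap(pd.read_csv(path, sep="\t", index_col="taxon"))


def discard_non_target(
    table: AbundanceTable,
    taxonomy: TaxonomyMap,
    target_phylum: str = TARGET_PHYLUM,
) -> AbundanceTable:
    """Drop rows outside the target phylum or labelled ``<phylum>_unclassified``."""
    tax = taxonomy.require(table.taxa)
    keep = (tax["phylum"] == target_phylum) & (
        tax["label"] != f"{target_phylum}_unclassified"
    )
    return AbundanceTable(table.data.loc[keep.to_numpy()].copy(), mode=table.mode)


def filter_low_abundance(
    table: AbundanceTable,
    min_reads: int = MIN_READS,
    min_fraction: float = MIN_FRACTION,
    rule: str = "and",
    per: str = "cell",
) -> AbundanceTable:
    """Zero out low-abundance counts and drop taxa left without any reads.

    The default reading of the cleaning rule is a conjunction applied per
    cell: a count is removed when it is below ``min_reads`` *and* below
    ``min_fraction`` of its sample's pre-filter total.  ``rule="or"`` gives
    the disjunctive reading, ``per="row"`` applies the test to whole taxon
    rows (a row is dropped when every one of its cells meets the removal
    condition).  Empty samples (total 0) are skipped and retained.
    """
    if table.mode != "counts":
        raise TableError("filter_low_abundance requires a counts-mode table")
    if rule not in ("and", "or") or per not in ("cell", "row"):
        raise TableError(f"unknown rule/per: {rule!r}/{per!r}")
    counts = table.data.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    nonempty = totals > 0
    frac = np.divide(counts, np.where(nonempty, totals, 1.0)[None, :])
    low_reads = counts < min_reads
    low_frac = frac < min_fraction
    remove = (low_reads & low_frac) if rule == "and" else (low_reads | low_frac)
    remove &= nonempty[None, :]
    if per == "row":
        row_remove = remove | (counts == 0)
        remove = np.repeat(row_remove.all(axis=1)[:, None], counts.shape[1], axis=1)
    out = table.data.to_numpy().copy()
    out[remove] = 0
    df = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    df = df.loc[df.sum(axis=1) > 0]
    return AbundanceTable(df, mode="counts")


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to per-sample fractions; all-zero samples stay zero."""
    if table.mode != "counts":
        raise TableError("to_relative requires a counts-mode table")
    totals = table.data.sum(axis=0)
    df = table.data / totals.replace(0, 1)
    return AbundanceTable(df.astype(float), mode="relative")


def aggregate_taxa(
    table: AbundanceTable, taxonomy: TaxonomyMap, level: str = "species"
) -> AbundanceTable:
    """Sum rows sharing a species (or genus) label.

    Taxa whose label at the requested level is missing/empty stay as their own
    rows under ``unassigned:<taxon id>``.  Column sums are conserved exactly.
    """
    if level not in ("species", "genus"):
        raise TableError(f"unknown aggregation level {level!r}")
    tax = taxonomy.require(table.taxa)
    labels = tax[level].astype(object)
    labels = pd.Series(
        [
            lab if isinstance(lab, str) and lab else f"unassigned:{taxon}"
            for taxon, lab in labels.items()
        ],
        index=labels.index,
    )
    grouped = table.data.groupby(labels.loc[table.taxa].to_numpy()).sum()
    grouped.index.name = table.data.index.name
    return AbundanceTable(grouped, mode=table.mode)
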