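"""Hill-number diversity and cross-participant variability summaries.

Hill numbers express diversity in effective numbers of taxa for any order q:
q=0 is richness, q=1 the exponential of Shannon entropy, q=2 the inverse
Simpson concentration.  They are weakly decreasing in q, with equality only
for perfectly even communities.  Coefficients of variation of these metrics
across participating laboratories (the radar-chart data) summarise how
reproducible each facet of the inventory is between labs.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import AbundanceTable

Q_ORDERS = (0, 1, 2)


def hill_number(p: Sequence[float] | np.ndarray, q: float) -> float:
    """Diversity of order q of a relative-abundance vector.

    ``(sum p_i^q)^(1/(1-q))``, with the q->1 limit ``exp(-sum p_i ln p_i)``;
    zeros are excluded from the sums.  An all-zero/empty vector has diversity
    0 (an empty sample, flagged upstream).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0 or p.sum() == 0:
        return 0.0
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"abundances must sum to 1, got {p.sum():.6g}")
    if q < 0:
        raise ValueError("order q must be >= 0")
    p = p[p > 0]
    # switch to the entropy form near q=1 where the power form is ill-conditioned
    if abs(q - 1.0) < 1e-9:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def coefficient_of_variation(values: Sequence[float]) -> float:
    """100 * sample SD (n-1 denominator) / mean, in percent.

    Undefined (NaN) for zero mean; requires at least two values.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least two values")
    mean = x.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * x.std(ddof=1) / mean)


def sample_metrics(
    table: AbundanceTable,
    species_table: AbundanceTable | None = None,
    extra: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Per-sample scalar metrics: read counts and Hill q=0,1,2.

    ``table`` should be counts mode at the finest (ASV) level; if a
    species-aggregated table is supplied its Hill numbers are added under
    ``hill_q*_species``.  ``extra`` maps metric name -> {sample: value}
    (e.g. DNA concentrations).  Rows are samples.
    """
    from .preprocess import to_relative

    rel = to_relative(table) if table.mode == "counts" else table
    rows: dict[str, dict[str, float]] = {}
    for s in table.samples:
        p = rel.data[s].to_numpy()
        row = {"reads": float(table.data[s].sum()) if table.mode == "counts" else np.nan}
        for q in Q_ORDERS:
            row[f"hill_q{q}"] = hill_number(p, q)
        rows[s] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    if species_table is not None:
        srel = to_relative(species_table) if species_table.mode == "counts" else species_table
        for q in Q_ORDERS:
            df[f"hill_q{q}_species"] = [
                hill_number(srel.data[s].to_numpy(), q) if s in srel.data else np.nan
                for s in df.index
            ]
    if extra:
        for name, mapping in extra.items():
            df[name] = [mapping.get(s, np.nan) for s in df.index]
    return df


def metric_cv_summary(
    metrics: pd.DataFrame, group_by: pd.Series
) -> pd.DataFrame:
    """CV (in percent) of each metric across participants, per group.

    ``metrics`` is a samples x metrics frame; ``group_by`` assigns each sample
    to a group (typically its sample type).  Groups with fewer than two
    members are skipped.  Output rows are groups, columns metrics — the
    radar-chart data.
    """
    out: dict[str, dict[str, float]] = {}
    for group, idx in metrics.groupby(group_by.reindex(metrics.index)).groups.items():
        if len(idx) < 2:
            continue
        sub = metrics.loc[idx]
        out[str(group)] = {
            col: coefficient_of_variation(sub[col].dropna().to_numpy())
            if sub[col].notna().sum() >= 2
            else float("nan")
            for col in metrics.columns
        }
    return pd.DataFrame.from_dict(out, orient="index")
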