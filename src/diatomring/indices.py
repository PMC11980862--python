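"""Trait-weighted diatom water-quality indices on the 1-20 scale.

Two index families used in European freshwater monitoring:

* **IPS-type** (Specific Pollution Sensitivity): the Zelinka-Marvan
  abundance-weighted average of per-taxon sensitivity values s (1..5 scale),
  weighted by indicator values v (1..3), rescaled to 1-20 by the standard
  affine map ``4.75 * raw - 3.75``.

* **IBD-type** (Biological Diatom Index): each taxon carries a probability
  profile over seven water-quality classes with increasing class scores; the
  abundance- and v-weighted class loadings give an expected class score,
  mapped affinely onto 1-20.

Taxa without trait entries are excluded and abundances renormalised over the
covered ones; the covered fraction is reported as *coverage*, with a
configurable validity threshold (an index computed from too small a fraction
of the community is not interpretable).  Scores map to the five ecological
status classes of the Water Framework Directive via configurable boundaries.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TableError

CLASS_SCORES = tuple(float(c) for c in range(1, 8))
#: scores of the seven quality classes used by the profile index

DEFAULT_MIN_COVERAGE = 0.7

DEFAULT_BOUNDARIES = (5.0, 9.0, 13.0, 17.0)
#: lower bounds of poor/moderate/good/high on the 1-20 scale

STATUS_LABELS = ("bad", "poor", "moderate", "good", "high")


@dataclass
class TraitTable:
    """Per-taxon index traits: sensitivity s, indicator weight v, profiles."""

    s: pd.Series
    v: pd.Series
    profiles: pd.DataFrame | None = None  # taxa x 7 class columns

    def __post_init__(self) -> None:
        bad = self.s.index[(self.s < 1) | (self.s > 5)]
        if len(bad):
            raise TableError(f"sensitivity s out of [1,5] for taxon {bad[0]!r}")
        bad = self.v.index[~self.v.isin([1, 2, 3])]
        if len(bad):
            raise TableError(f"indicator value v not in {{1,2,3}} for taxon {bad[0]!r}")
        if self.profiles is not None:
            if self.profiles.shape[1] != len(CLASS_SCORES):
                raise TableError(
                    f"profiles must have {len(CLASS_SCORES)} class columns"
                )
            sums = self.profiles.sum(axis=1)
            bad = sums.index[np.abs(sums - 1.0) > 1e-6]
            if len(bad):
                raise TableError(
                    f"profile for taxon {bad[0]!r} sums to {sums[bad[0]]:.6g}, not 1"
                )

    @property
    def taxa(self) -> pd.Index:
        return self.s.index


@dataclass
class IndexResult:
    sample: str
    index: str
    score: float | None  # 1-20 scale, None when invalid
    coverage: float
    status: str | None
    valid: bool
    clamped: bool = False
    degenerate: str | None = None


def _renormalised(p: pd.Series, covered: pd.Index) -> tuple[pd.Series, float]:
    a = p.reindex(covered).fillna(0.0)
    total = float(p.sum())
    coverage = float(a.sum() / total) if total > 0 else 0.0
    if a.sum() > 0:
        a = a / a.sum()
    return a, coverage


def _finalise(
    sample: str,
    name: str,
    score: float,
    coverage: float,
    min_coverage: float,
    boundaries: Sequence[float],
) -> IndexResult:
    clamped = score < 1.0 or score > 20.0
    score = float(np.clip(score, 1.0, 20.0))
    valid = coverage >= min_coverage
    return IndexResult(
        sample=sample,
        index=name,
        score=score,
        coverage=coverage,
        status=ecological_class(score, boundaries),
        valid=valid,
        clamped=clamped,
    )


def ips_score(
    p: pd.Series,
    traits: TraitTable,
    sample: str = "",
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
) -> IndexResult:
    """Sensitivity-weighted average index on 1-20.

    ``raw = sum(a_j s_j v_j) / sum(a_j v_j)`` over trait-covered taxa, with
    abundances renormalised over coverage; ``score = 4.75 * raw - 3.75``
    clamped to [1, 20].
    """
    covered = p.index.intersection(traits.taxa)
    covered = covered[p.reindex(covered).to_numpy() > 0]
    a, coverage = _renormalised(p, covered)
    if coverage == 0.0 or a.sum() == 0:
        return IndexResult(sample, "IPS", None, 0.0, None, False, degenerate="no_coverage")
    s = traits.s.reindex(covered).to_numpy()
    v = traits.v.reindex(covered).to_numpy(dtype=float)
    aw = a.to_numpy()
    raw = float(np.sum(aw * s * v) / np.sum(aw * v))
    return _finalise(sample, "IPS", 4.75 * raw - 3.75, coverage, min_coverage, boundaries)


def ibd_score(
    p: pd.Series,
    traits: TraitTable,
    sample: str = "",
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
) -> IndexResult:
    """Seven-class probability-profile index on 1-20.

    Class loadings ``F_i = sum_x a_x P_xi v_x / sum_x a_x v_x``; the expected
    class score ``B = sum F_i c_i / sum F_i`` is mapped affinely from
    [c_1, c_7] onto [1, 20].
    """
    if traits.profiles is None:
        raise TableError("trait table has no class profiles; cannot compute IBD")
    covered = p.index.intersection(traits.profiles.index)
    covered = covered[p.reindex(covered).to_numpy() > 0]
    a, coverage = _renormalised(p, covered)
    if coverage == 0.0 or a.sum() == 0:
        return IndexResult(sample, "IBD", None, 0.0, None, False, degenerate="no_coverage")
    P = traits.profiles.reindex(covered).to_numpy()
    v = traits.v.reindex(covered).to_numpy(dtype=float)
    aw = a.to_numpy()
    F = (aw * v) @ P / np.sum(aw * v)
    c = np.asarray(CLASS_SCORES)
    B = float(F @ c / F.sum())
    score = 1.0 + (B - c[0]) * 19.0 / (c[-1] - c[0])
    return _finalise(sample, "IBD", score, coverage, min_coverage, boundaries)


def ecological_class(
    score: float, boundaries: Sequence[float] = DEFAULT_BOUNDARIES
) -> str:
    """Map a 1-20 index score to its WFD status class.

    Boundaries are the lower bounds of poor/moderate/good/high; intervals are
    half-open on the left (a score equal to a boundary takes the higher
    class), e.g. 17 is already 'high' under the defaults.
    """
    b = tuple(boundaries)
    if len(b) != 4 or any(b[i] >= b[i + 1] for i in range(3)):
        raise ValueError(f"boundaries must be 4 strictly increasing values, got {b}")
    if not 1.0 <= score <= 20.0:
        raise ValueError(f"score {score} outside the 1-20 scale")
    idx = int(np.searchsorted(b, score, side="right"))
    return STATUS_LABELS[idx]


def index_table(
    rel_table,
    traits: TraitTable,
    which: Sequence[str] = ("IPS", "IBD"),
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Compute the requested indices for every sample of a relative table."""
    rows = []
    for s in rel_table.samples:
        p = rel_table.data[s]
        if "IPS" in which:
            rows.append(ips_score(p, traits, sample=s, min_coverage=min_coverage))
        if "IBD" in which and traits.profiles is not None:
            rows.append(ibd_score(p, traits, sample=s, min_coverage=min_coverage))
    return pd.DataFrame([r.__dict__ for r in rows])
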