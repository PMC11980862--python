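"""Proficiency-test statistics: z-scores, Youden error decomposition,
detection thresholds and anomaly diagnosis.

In an inter-laboratory proficiency test every lab analyses the same
calibrated items and is scored against the group consensus.  The performance
statistic is the z-score ``z = (x - mu) / sigma`` with mu and sigma the plain
mean and sample SD over all participants (the scored lab included); |z| <= 2
is in control, 2 < |z| <= 3 a warning, |z| > 3 an action signal, and any
action signal fails the test.

When each lab is scored on two comparable items (here: river and lake), the
paired z-scores form a Youden plot.  Rotating the plane 45 degrees separates
the *systematic* component ``u = (z_R + z_L)/sqrt(2)`` (a lab biased the same
way on both items sits along the diagonal) from the *random* component
``v = (z_R - z_L)/sqrt(2)``; the rotation is an isometry, so u² + v² =
z_R² + z_L².

Two further diagnostics target sample-handling errors rather than protocol
performance: Bray-Curtis matching of an unexpected composition against the
reference communities (detects swapped/mis-pipetted samples, e.g. a blank
that contains a real community), and a closed-form least-squares fit of a
two-community mixture (detects cross-contamination such as a 1:1 mix of two
calibrated samples).
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis
from scipy.stats import chi2

Z_WARNING = 2.0
Z_ACTION = 3.0


class ProficiencyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------

@dataclass
class ZScoreResult:
    participant: str
    x: float
    mu: float
    sigma: float
    z: float
    zone: str  # in_control | warning | action
    degenerate: bool = False  # sigma == 0


def _zone(z: float) -> str:
    if abs(z) > Z_ACTION:
        return "action"
    if abs(z) > Z_WARNING:
        return "warning"
    return "in_control"


def z_scores(
    index_values: Mapping[str, float], robust: bool = False
) -> list[ZScoreResult]:
    """Standardise each participant's score against the group consensus.

    Consensus mu/sigma are the plain mean and sample SD (n-1) over all
    participants including the scored one; with ``robust=True`` the
    median/scaled-MAD pair is used instead (ISO-style resistant statistics).
    When sigma is exactly 0 — every lab returned the identical score — all
    z are defined as 0 and flagged degenerate: no dispersion means nothing
    to standardise against, and the test is trivially passed.
    """
    if len(index_values) < 3:
        raise ProficiencyError("z-scores need at least 3 participants")
    x = np.array(list(index_values.values()), dtype=float)
    if robust:
        mu = float(np.median(x))
        sigma = float(1.4826 * np.median(np.abs(x - mu)))
    else:
        mu = float(x.mean())
        sigma = float(x.std(ddof=1))
    out = []
    for name, xi in index_values.items():
        if sigma == 0.0:
            out.append(ZScoreResult(name, float(xi), mu, 0.0, 0.0, "in_control", True))
        else:
            z = (float(xi) - mu) / sigma
            out.append(ZScoreResult(name, float(xi), mu, sigma, z, _zone(z)))
    return out


def proficiency_verdict(zresults: Sequence[ZScoreResult]) -> tuple[str, list[str]]:
    """``("pass", [])`` unless any |z| > 3, else ``("fail", offenders)``."""
    if not zresults:
        raise ProficiencyError("empty z-score list")
    offenders = sorted(r.participant for r in zresults if abs(r.z) > Z_ACTION)
    return ("fail" if offenders else "pass", offenders)


# ---------------------------------------------------------------------------
# Youden decomposition
# ---------------------------------------------------------------------------

@dataclass
class YoudenClassification:
    participant: str
    z_a: float  # first item (e.g. river)
    z_b: float  # second item (e.g. lake)
    u: float  # systematic component, along the 45-degree line
    v: float  # random component, across the line
    label: str  # in_control | systematic_error | random_error | total_error


def youden_classify(
    z_pairs: Mapping[str, tuple[float, float]],
    box: float = Z_ACTION,
    line_tol: float = Z_WARNING,
) -> list[YoudenClassification]:
    """Classify each lab's paired z-scores into Youden error types.

    Outside the +-``box`` square: close to the 45-degree line (|v| <=
    ``line_tol``) means a systematic error, far from it a total error.
    Inside the box: far from the line means random error, else in control.
    """
    sq2 = math.sqrt(2.0)
    out = []
    for name, (za, zb) in z_pairs.items():
        if za is None or zb is None or np.isnan(za) or np.isnan(zb):
            continue
        u = (za + zb) / sq2
        v = (za - zb) / sq2
        outside = abs(za) > box or abs(zb) > box
        if outside:
            label = "systematic_error" if abs(v) <= line_tol else "total_error"
        else:
            label = "random_error" if abs(v) > line_tol else "in_control"
        out.append(YoudenClassification(name, float(za), float(zb), u, v, label))
    return out


def youden_circle(confidence: float = 0.95) -> float:
    """Radius of the chi-square probability circle on standardised axes."""
    return float(math.sqrt(chi2.ppf(confidence, df=2)))


# ---------------------------------------------------------------------------
# detection thresholds
# ---------------------------------------------------------------------------

def detection_threshold(
    abundances: pd.DataFrame, representative: str = "max"
) -> float:
    """Smallest abundance above which every participant detects every taxon.

    ``abundances`` is taxa x participants relative abundances of one
    calibrated item; a participant *detects* a taxon when its abundance is
    > 0.  Each taxon's representative abundance is the ``max`` (default, as
    a worst-case guarantee) or ``mean`` over the participants that detect it.
    The threshold is the largest representative abundance among taxa missed
    by at least one participant (0 when no taxon is missed): every taxon
    whose representative abundance is strictly above it was seen by all.
    """
    if abundances.shape[1] < 2:
        raise ProficiencyError("detection threshold needs >= 2 participants")
    if representative not in ("max", "mean"):
        raise ProficiencyError(f"unknown representative {representative!r}")
    vals = abundances.to_numpy(dtype=float)
    detected = vals > 0
    present = detected.any(axis=1)
    vals = vals[present]
    detected = detected[present]
    if representative == "max":
        rep = vals.max(axis=1)
    else:
        rep = np.array([row[det].mean() for row, det in zip(vals, detected)])
    missed = ~detected.all(axis=1)
    return float(rep[missed].max()) if missed.any() else 0.0


# ---------------------------------------------------------------------------
# anomaly diagnosis: swaps and mixtures
# ---------------------------------------------------------------------------

@dataclass
class AnomalyReport:
    sample: str
    expected: str | None
    best_match: str | None
    dissimilarity: float | None
    mixture_sources: tuple[str, str] | None
    alpha: float | None
    residual: float | None
    verdict: str  # clean | swap_suspect | mixture_suspect | empty


def _bc(x: np.ndarray, y: np.ndarray) -> float:
    if x.sum() == 0 and y.sum() == 0:
        return float("nan")
    return float(braycurtis(x, y))


def _aligned(query: pd.Series, *others: pd.Series) -> list[np.ndarray]:
    universe = query.index
    for o in others:
        universe = universe.union(o.index)
    return [s.reindex(universe).fillna(0.0).to_numpy() for s in (query, *others)]


def match_composition(
    query: pd.Series, references: Mapping[str, pd.Series]
) -> tuple[str | None, float]:
    """Best Bray-Curtis match among named reference profiles.

    Ties break by reference name order (lexicographic, deterministic).  An
    empty query compared against empty references yields ``(None, nan)``.
    """
    if not references:
        raise ProficiencyError("no reference profiles supplied")
    best_name, best_d = None, float("inf")
    for name in sorted(references):
        q, r = _aligned(query, references[name])
        d = _bc(q, r)
        if not math.isnan(d) and d < best_d:
            best_name, best_d = name, d
    if best_name is None:
        return None, float("nan")
    return best_name, best_d


def fit_mixture(
    query: pd.Series, ref_a: pd.Series, ref_b: pd.Series
) -> tuple[float, float]:
    """Least-squares two-source mixture fit.

    Finds alpha minimising ``||query - (alpha*ref_a + (1-alpha)*ref_b)||_2``
    in closed form (projection of query - ref_b onto ref_a - ref_b), clipped
    to [0,1].  Returns (alpha, residual) where residual is the Bray-Curtis
    dissimilarity between the query and the fitted mixture.
    """
    q, a, b = _aligned(query, ref_a, ref_b)
    d = a - b
    denom = float(d @ d)
    if denom == 0.0:
        raise ProficiencyError("mixture references are identical; alpha undefined")
    alpha = float(np.clip((q - b) @ d / denom, 0.0, 1.0))
    fitted = alpha * a + (1.0 - alpha) * b
    return alpha, _bc(q, fitted)


def diagnose(
    query: pd.Series,
    expected: str | None,
    references: Mapping[str, pd.Series],
    sample: str = "",
    swap_cutoff: float = 0.05,
    mixture_cutoff: float = 0.05,
    alpha_band: tuple[float, float] = (0.2, 0.8),
) -> AnomalyReport:
    """Full anomaly scan of one sample against the reference communities.

    Order of verdicts: a sample close to its expected community is ``clean``;
    one matching a *different* single community within ``swap_cutoff`` is a
    ``swap_suspect``; otherwise, if some two-community mixture fits within
    ``mixture_cutoff`` with alpha inside ``alpha_band``, it is a
    ``mixture_suspect``.  An all-zero query (a clean blank) reports ``empty``.
    """
    if float(query.sum()) == 0.0:
        return AnomalyReport(sample, expected, None, None, None, None, None, "empty")
    best, d = match_composition(query, references)
    if expected is not None and best == expected and d <= swap_cutoff:
        return AnomalyReport(sample, expected, best, d, None, None, None, "clean")
    if best is not None and best != expected and d <= swap_cutoff:
        return AnomalyReport(sample, expected, best, d, None, None, None, "swap_suspect")
    # try all ordered-independent source pairs
    names = sorted(n for n in references if references[n].sum() > 0)
    best_fit: tuple[float, float, tuple[str, str]] | None = None
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            alpha, res = fit_mixture(query, references[na], references[nb])
            if best_fit is None or res < best_fit[1]:
                best_fit = (alpha, res, (na, nb))
    if best_fit is not None:
        alpha, res, pair = best_fit
        if res <= mixture_cutoff and alpha_band[0] <= alpha <= alpha_band[1]:
            return AnomalyReport(
                sample, expected, best, d, pair, alpha, res, "mixture_suspect"
            )
        return AnomalyReport(sample, expected, best, d, pair, alpha, res, "clean")
    return AnomalyReport(sample, expected, best, d, None, None, None, "clean")
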