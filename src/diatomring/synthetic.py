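"""Multi-laboratory metabarcoding community simulator.

Emulates the statistical structure of a cross-laboratory diatom ring trial at
the taxon-count level (no reads, no sequencing error model): a small set of
reference communities — a river biofilm ``R``, a lake biofilm ``L``, a
12-strain mock ``M`` and an empty water blank ``W`` — analysed by many
laboratories, each of which distorts the true composition with

* a *systematic* per-taxon multiplicative bias (log-scale vector, constant
  across that lab's replicates — extraction/PCR taxon-efficiency bias),
* *random* replicate noise (iid lognormal per taxon per replicate),
* *dropout* of rare taxa below a detection floor,

after which reads are drawn multinomially at a configured depth.  Injected
anomalies (a community swapped into a blank, a 1:1 mixture of two
communities, or partial contamination) replace or blend the true community
before the lab effect applies — exactly the failure modes a proficiency test
is meant to catch.

Every sample gets an independent random substream derived from the master
seed and its manifest key, so the generated table is reproducible and
insensitive to manifest ordering.
"""

from __future__ import annotations

import hashlib
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import AbundanceTable, DesignSpec, SampleUnit, expand_design

DEFAULT_DEPTH = 20_000
#: default reads per sample, of the order of the per-sample depth a MiSeq
#: amplicon run shared across ~300 libraries yields

GEOMETRIC_EVENNESS = 0.8
MOCK_SIZE = 12


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ground-truth records
# ---------------------------------------------------------------------------

@dataclass
class LabEffect:
    """One laboratory's systematic and random error model.

    ``systematic_bias`` is a log-scale per-taxon vector b: the lab's expected
    composition is proportional to p * exp(b).  ``random_sd`` is the log-scale
    SD of iid replicate noise.  Taxa whose biased relative abundance falls
    below ``detection_floor`` drop out with probability ``dropout_prob``.
    """

    participant: str
    systematic_bias: pd.Series | None = None  # None = unbiased
    random_sd: float = 0.0
    detection_floor: float = 0.0
    dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.random_sd < 0:
            raise SimulationError(f"lab {self.participant}: random_sd must be >= 0")
        if not 0.0 <= self.detection_floor < 1.0:
            raise SimulationError(f"lab {self.participant}: detection_floor not in [0,1)")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise SimulationError(f"lab {self.participant}: dropout_prob not in [0,1]")


@dataclass
class AnomalySpec:
    """An injected sample-handling error.

    ``swap``: the target unit receives community ``sources[0]`` instead of its
    own.  ``mixture``: alpha * sources[0] + (1-alpha) * sources[1].
    ``contamination``: (1-alpha) * own community + alpha * sources[0].
    """

    target: str  # manifest key
    kind: str  # swap | mixture | contamination
    sources: tuple[str, ...]
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("swap", "mixture", "contamination"):
            raise SimulationError(f"unknown anomaly kind {self.kind!r}")
        if self.kind == "swap" and len(self.sources) != 1:
            raise SimulationError("swap requires exactly 1 source community")
        if self.kind == "mixture":
            if len(self.sources) != 2:
                raise SimulationError("mixture requires exactly 2 source communities")
            if not 0.0 < self.alpha < 1.0:
                raise SimulationError("mixture alpha must be in (0,1)")
        if not 0.0 <= self.alpha <= 1.0:
            raise SimulationError("alpha must be in [0,1]")


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate and to grade a synthetic dataset."""

    profiles: dict[str, pd.Series]  # community id -> relative-abundance profile
    lab_effects: dict[str, LabEffect]  # participant -> effect
    anomalies: list[AnomalySpec] = field(default_factory=list)
    depth: int = DEFAULT_DEPTH
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "depth": self.depth,
            "profiles": {k: v.to_dict() for k, v in self.profiles.items()},
            "lab_effects": {
                k: {
                    "systematic_bias": (
                        None if e.systematic_bias is None else e.systematic_bias.to_dict()
                    ),
                    "random_sd": e.random_sd,
                    "detection_floor": e.detection_floor,
                    "dropout_prob": e.dropout_prob,
                }
                for k, e in self.lab_effects.items()
            },
            "anomalies": [
                {"target": a.target, "kind": a.kind, "sources": list(a.sources), "alpha": a.alpha}
                for a in self.anomalies
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# reference communities
# ---------------------------------------------------------------------------

def _rank_abundances(n: int, model: str, rng: np.random.Generator) -> np.ndarray:
    if model == "geometric":
        p = GEOMETRIC_EVENNESS ** np.arange(n)
    elif model == "lognormal":
        p = np.sort(rng.lognormal(mean=0.0, sigma=1.5, size=n))[::-1]
    else:
        raise SimulationError(f"unknown abundance model {model!r}")
    return p / p.sum()


def make_reference_communities(
    n_taxa_R: int = 60,
    n_taxa_L: int = 60,
    shared_fraction: float = 0.3,
    abundance_model: str = "geometric",
    seed: int = 0,
) -> dict[str, pd.Series]:
    """Build the four reference community profiles.

    R and L are species-rich environmental communities sharing
    ``floor(shared_fraction * min(n_R, n_L))`` taxa; M is a 12-strain mock of
    dedicated taxa; W is the empty blank.  Rank abundances follow the chosen
    model (geometric series by default, ratio 0.8 — abundant taxa at a few
    tens of percent, a long tail of rare ones) and are assigned to taxa in a
    seed-dependent random order.
    """
    if n_taxa_R < 1 or n_taxa_L < 1:
        raise SimulationError("communities need at least one taxon")
    if not 0.0 <= shared_fraction <= 1.0:
        raise SimulationError("shared_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    n_shared = int(shared_fraction * min(n_taxa_R, n_taxa_L))
    shared = [f"sp_shared_{i:03d}" for i in range(n_shared)]
    r_only = [f"sp_river_{i:03d}" for i in range(n_taxa_R - n_shared)]
    l_only = [f"sp_lake_{i:03d}" for i in range(n_taxa_L - n_shared)]
    mock = [f"strain_{i:02d}" for i in range(1, MOCK_SIZE + 1)]

    def profile(taxa: list[str]) -> pd.Series:
        order = rng.permutation(len(taxa))
        vals = _rank_abundances(len(taxa), abundance_model, rng)
        return pd.Series(vals[order], index=taxa, dtype=float)

    return {
        "R": profile(shared + r_only),
        "L": profile(shared + l_only),
        "M": profile(mock),
        "W": pd.Series(dtype=float),
    }


def sample_lab_effects(
    participants: Sequence[str],
    taxa: Sequence[str],
    bias_sd: float = 0.08,
    random_sd: float = 0.04,
    detection_floor: float = 5e-4,
    dropout_prob: float = 0.5,
    seed: int = 0,
) -> dict[str, LabEffect]:
    """Draw iid lognormal lab effects for a set of participants.

    Defaults give modest inter-lab spread (log-bias SD 0.08, replicate noise
    SD 0.04), so between-lab community dissimilarity stays well below the
    anomaly-detection cutoffs while still dominating within-lab replicate
    noise, plus stochastic dropout of taxa under 0.05% relative abundance.
    These magnitudes reproduce the qualitative regime of a successful ring
    trial: metric CVs in the low percent range, index-score SDs of a few
    tenths of a unit, participant effects dominating community variance.
    """
    rng = np.random.default_rng(seed)
    effects = {}
    for p in participants:
        bias = pd.Series(rng.normal(0.0, bias_sd, size=len(taxa)), index=list(taxa))
        effects[p] = LabEffect(p, bias, random_sd, detection_floor, dropout_prob)
    return effects


def sensitivity_aligned_bias(
    traits, effect_size: float, taxa: Sequence[str]
) -> pd.Series:
    """A systematic bias that shifts trait-weighted index scores.

    Biases each taxon proportionally to its centred sensitivity value
    (``effect_size * (s - mean(s))``), so the biased lab over-amplifies
    pollution-sensitive taxa and its quality-index score drifts upward —
    the kind of directional error a z-score is designed to flag.
    """
    s = traits.s.reindex(list(taxa)).fillna(traits.s.mean())
    return (s - s.mean()) * effect_size


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _unit_rng(master_seed: int, key: str) -> np.random.Generator:
    """Independent substream per sample unit, stable under manifest reordering."""
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int.from_bytes(digest, "big")])
    )


def expected_composition(
    unit: SampleUnit, truth: SyntheticTruth, taxa: Sequence[str]
) -> pd.Series:
    """True (pre-lab-effect) composition of a unit, anomalies applied."""
    base = truth.profiles[unit.sample_type].reindex(list(taxa)).fillna(0.0)
    for anom in truth.anomalies:
        if anom.target != unit.key:
            continue
        src = [truth.profiles[s].reindex(list(taxa)).fillna(0.0) for s in anom.sources]
        if anom.kind == "swap":
            base = src[0]
        elif anom.kind == "mixture":
            base = anom.alpha * src[0] + (1.0 - anom.alpha) * src[1]
        else:  # contamination
            mixed = (1.0 - anom.alpha) * base + anom.alpha * src[0]
            tot = mixed.sum()
            base = mixed / tot if tot > 0 else mixed
    return base


def simulate_unit(
    unit: SampleUnit, truth: SyntheticTruth, taxa: Sequence[str]
) -> np.ndarray:
    """Simulate one sample's read counts over the given taxon universe."""
    if unit.participant not in truth.lab_effects:
        raise SimulationError(f"no lab effect for participant {unit.participant!r}")
    effect = truth.lab_effects[unit.participant]
    rng = _unit_rng(truth.seed, unit.key)

    p = expected_composition(unit, truth, taxa).to_numpy(copy=True)
    if p.sum() == 0.0:  # clean blank
        return np.zeros(len(taxa), dtype=np.int64)

    log_w = np.log(np.where(p > 0, p, 1.0))
    if effect.systematic_bias is not None:
        log_w = log_w + effect.systematic_bias.reindex(list(taxa)).fillna(0.0).to_numpy()
    if effect.random_sd > 0:
        log_w = log_w + rng.normal(0.0, effect.random_sd, size=len(taxa))
    w = np.where(p > 0, np.exp(log_w), 0.0)
    w = w / w.sum()

    if effect.dropout_prob > 0 and effect.detection_floor > 0:
        rare = (w > 0) & (w < effect.detection_floor)
        drop = rare & (rng.random(len(w)) < effect.dropout_prob)
        if drop.sum() < (w > 0).sum():  # never drop the whole sample
            w[drop] = 0.0
            w = w / w.sum()

    return rng.multinomial(truth.depth, w).astype(np.int64)


def simulate_dataset(
    design: DesignSpec | Sequence[SampleUnit], truth: SyntheticTruth
) -> AbundanceTable:
    """Simulate counts for every (sequenced) unit of a design or manifest.

    Accepts either a design (expanded in full) or an already-flagged manifest,
    in which case only units flagged ``sequenced`` are simulated.  Column sums
    equal ``truth.depth`` exactly, except for clean blanks (all-zero).
    """
    if isinstance(design, DesignSpec):
        units = expand_design(design)
    else:
        units = [u for u in design if u.sequenced] or list(design)
    taxa = sorted(set().union(*(p.index for p in truth.profiles.values())))
    cols = {u.key: simulate_unit(u, truth, taxa) for u in units}
    df = pd.DataFrame(cols, index=taxa, dtype=np.int64)
    return AbundanceTable(df, mode="counts")


def study_anomalies(alpha: float = 0.5) -> list[AnomalySpec]:
    """The four sample-handling errors documented in the study design.

    Two E1 blanks and one E3 blank received a real community (mis-pipetted
    samples, making them sequenced "false positive" blanks), and one E2 lake
    sample was a 1:1 lake/mock mixture.
    """
    return [
        AnomalySpec("E1/E/W/1", "swap", ("L",)),
        AnomalySpec("E1/Q/W/1", "swap", ("L",)),
        AnomalySpec("E3/O/W/1", "swap", ("R",)),
        AnomalySpec("E2/I/L/1", "mixture", ("L", "M"), alpha=alpha),
    ]


# ---------------------------------------------------------------------------
# synthetic trait tables
# ---------------------------------------------------------------------------

def synthetic_traits(taxa: Sequence[str], seed: int = 0, good_status: bool = True):
    """Generate a synthetic trait table for a taxon list.

    Sensitivities ``s`` are drawn on the 1..5 scale (skewed toward sensitive
    taxa when ``good_status``, matching clean-water reference communities),
    indicator weights ``v`` from {1,2,3}, and each taxon gets a 7-class
    probability profile concentrated around the class its sensitivity maps to.
    Purely synthetic values for testing — not any real trait database.
    """
    from .indices import TraitTable

    rng = np.random.default_rng(seed)
    n = len(taxa)
    if good_status:
        s = np.clip(rng.normal(4.3, 0.5, size=n), 1.0, 5.0)
    else:
        s = rng.uniform(1.0, 5.0, size=n)
    v = rng.choice([1, 2, 3], size=n, p=[0.5, 0.3, 0.2])
    # centre of the 7-class profile tracks sensitivity: s=5 -> class 7, s=1 -> class 1
    centres = 1.0 + (s - 1.0) * 1.5
    classes = np.arange(1, 8)
    prof = np.exp(-0.5 * ((classes[None, :] - centres[:, None]) / 0.8) ** 2)
    prof = prof / prof.sum(axis=1, keepdims=True)
    profiles = pd.DataFrame(
        prof, index=list(taxa), columns=[f"class_{i}" for i in classes]
    )
    return TraitTable(
        s=pd.Series(s, index=list(taxa)),
        v=pd.Series(v, index=list(taxa)),
        profiles=profiles,
    )
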