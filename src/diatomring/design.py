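"""Experimental design, sample manifests, and tabular I/O.

A ring trial (inter-laboratory comparison) is described by a
:class:`DesignSpec`: a list of experiments, each sending a set of calibrated
sample types to a set of participating laboratories with a fixed number of
replicates.  Expanding the design yields one :class:`SampleUnit` per
(experiment, participant, sample_type, replicate) combination — the unit of
everything downstream.  Sequencing-inclusion rules (blanks are not sequenced
unless they amplified unexpectedly; failed amplicons are dropped) are applied
to the expanded manifest as flags, never by deleting units, so the full
accounting stays auditable.

Sample units are keyed by the string ``"<experiment>/<participant>/<type>/<rep>"``
(e.g. ``"E2/G/L/1"``); abundance-table columns use these keys, which makes the
per-sample metadata recoverable from any table without a sidecar.

Tables are tab-separated UTF-8 text with taxa as rows and sample keys as
columns; counts round-trip integer-exactly, fractions to 1e-12.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_TYPES = ("L", "R", "M", "W")
#: canonical sample types: lake biofilm, river biofilm, mock community, water blank

KEY_SEP = "/"

RELATIVE_TOL = 1e-9


class DesignError(ValueError):
    """Invalid experimental design or manifest operation."""


class TableError(ValueError):
    """Invalid abundance or trait table."""


# ---------------------------------------------------------------------------
# design and manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment row of the design: who analyses what, how often."""

    id: str
    material: str  # "biofilm" or "DNA"
    participants: tuple[str, ...]
    replicates: int
    sample_types: tuple[str, ...] = SAMPLE_TYPES

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise DesignError(f"experiment {self.id}: replicates must be >= 1")
        if len(set(self.participants)) != len(self.participants):
            raise DesignError(f"experiment {self.id}: duplicate participant ids")
        if not self.sample_types:
            raise DesignError(f"experiment {self.id}: sample_types must be non-empty")
        unknown = set(self.sample_types) - set(SAMPLE_TYPES)
        if unknown:
            raise DesignError(
                f"experiment {self.id}: unknown sample types {sorted(unknown)}"
            )


@dataclass(frozen=True)
class DesignSpec:
    experiments: tuple[ExperimentSpec, ...]

    def __post_init__(self) -> None:
        ids = [e.id for e in self.experiments]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise DesignError(f"duplicate experiment ids: {sorted(dupes)}")

    def experiment(self, exp_id: str) -> ExperimentSpec:
        for e in self.experiments:
            if e.id == exp_id:
                return e
        raise KeyError(exp_id)


@dataclass(frozen=True)
class SampleUnit:
    """One physical sample handled by one participant in one experiment."""

    experiment: str
    participant: str
    sample_type: str
    replicate: int  # 1-based
    flags: frozenset[str] = frozenset()

    @property
    def key(self) -> str:
        return KEY_SEP.join(
            (self.experiment, self.participant, self.sample_type, str(self.replicate))
        )

    @property
    def sequenced(self) -> bool:
        return "sequenced" in self.flags

    def with_flags(self, *add: str, remove: Iterable[str] = ()) -> "SampleUnit":
        flags = (self.flags | set(add)) - set(remove)
        return dataclasses.replace(self, flags=frozenset(flags))


def parse_key(key: str) -> tuple[str, str, str, int]:
    """Split a manifest key ``"E2/G/L/1"`` into its four fields."""
    parts = key.split(KEY_SEP)
    if len(parts) != 4:
        raise DesignError(f"malformed sample key {key!r}: expected 4 '/'-fields")
    exp, part, stype, rep = parts
    try:
        rep_i = int(rep)
    except ValueError as exc:
        raise DesignError(f"malformed sample key {key!r}: replicate not an integer") from exc
    return exp, part, stype, rep_i


def expand_design(design: DesignSpec) -> list[SampleUnit]:
    """Expand a design into its full sample manifest.

    Returns one unit per (experiment, participant, sample_type, replicate)
    combination, in that deterministic declaration order, so
    ``len(result) == sum(P * T * R)`` over experiments, exactly.
    """
    units: list[SampleUnit] = []
    for exp in design.experiments:
        for participant in exp.participants:
            for stype in exp.sample_types:
                for rep in range(1, exp.replicates + 1):
                    units.append(SampleUnit(exp.id, participant, stype, rep))
    return units


def apply_sequencing_rules(
    units: Sequence[SampleUnit],
    w_exceptions: Iterable[str] = (),
    failed: Iterable[str] = (),
) -> list[SampleUnit]:
    """Flag which units of a manifest go to sequencing.

    Water blanks (W) are not sequenced unless their key is listed in
    ``w_exceptions`` (unexpected amplification; such units are additionally
    flagged ``false_positive_control``).  Every other unit is sequenced unless
    its key is listed in ``failed`` (amplicon quality too low).  Idempotent and
    insensitive to the order of the exception lists; other flags are preserved.
    """
    w_set, failed_set = set(w_exceptions), set(failed)
    by_key = {u.key for u in units}
    for key in sorted(w_set | failed_set):
        if key not in by_key:
            raise DesignError(f"sequencing rule references unknown unit {key!r}")
    for key in sorted(w_set):
        _, _, stype, _ = parse_key(key)
        if stype != "W":
            raise DesignError(f"w_exceptions entry {key!r} is not a W unit")

    out: list[SampleUnit] = []
    for u in units:
        if u.sample_type == "W":
            if u.key in w_set:
                out.append(u.with_flags("sequenced", "false_positive_control"))
            else:
                out.append(u.with_flags(remove=("sequenced", "false_positive_control")))
        else:
            if u.key in failed_set:
                out.append(u.with_flags("failed_amplicon", remove=("sequenced",)))
            else:
                out.append(u.with_flags("sequenced"))
    return out


# ---------------------------------------------------------------------------
# the study design (Table-1-style accounting)
# ---------------------------------------------------------------------------

PARTICIPANTS_17 = tuple("ABCDEFGHIJKLMNOPQ")
#: 17 ring-trial laboratories, coded A..Q

PARTICIPANTS_9 = ("B", "D", "E", "F", "I", "K", "N", "O", "P")
#: the 9 labs that also ran their own-choice protocols (method comparison)

REFERENCE_LAB = "RL"

W_FALSE_POSITIVES = ("E1/E/W/1", "E1/Q/W/1", "E3/O/W/1")
#: blanks that amplified unexpectedly and were therefore sequenced

FAILED_AMPLICONS = ("E2/G/L/1",)
#: amplicons excluded before sequencing (faint band)


def study_design() -> DesignSpec:
    """The four-experiment cross-laboratory design plus the reference lab.

    E1/E2: proficiency tests (fixed DNA-extraction / PCR protocol, 17 labs,
    1 replicate).  E3/E4: method comparison (own-choice protocols, 9 labs,
    3 replicates).  REF: the reference laboratory's own triplicates, treated
    as an ordinary participant.  Each unit covers the four calibrated sample
    types (L, R, M, W).
    """
    return DesignSpec(
        experiments=(
            ExperimentSpec("E1", "biofilm", PARTICIPANTS_17, 1),
            ExperimentSpec("E2", "DNA", PARTICIPANTS_17, 1),
            ExperimentSpec("E3", "biofilm", PARTICIPANTS_9, 3),
            ExperimentSpec("E4", "DNA", PARTICIPANTS_9, 3),
            ExperimentSpec("REF", "biofilm", (REFERENCE_LAB,), 3),
        )
    )


def study_manifest() -> list[SampleUnit]:
    """Full study manifest with the documented sequencing-inclusion calls."""
    return apply_sequencing_rules(
        expand_design(study_design()),
        w_exceptions=W_FALSE_POSITIVES,
        failed=FAILED_AMPLICONS,
    )


def manifest_accounting(units: Sequence[SampleUnit]) -> dict[str, int]:
    """Headline unit counts for a flagged manifest.

    ``retained_<exp>`` counts the sequenced non-blank units per experiment —
    the samples that enter the community analysis (false-positive blanks are
    sequenced but analysed separately as anomalies).
    """
    counts: dict[str, int] = {
        "total_units": len(units),
        "sequenced": sum(1 for u in units if u.sequenced),
    }
    for exp_id in sorted({u.experiment for u in units}):
        exp_units = [u for u in units if u.experiment == exp_id]
        counts[f"units_{exp_id}"] = len(exp_units)
        counts[f"retained_{exp_id}"] = sum(
            1 for u in exp_units if u.sequenced and u.sample_type != "W"
        )
    return counts


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix with a mode tag.

    ``data`` is indexed by taxon id with sample-key columns.  ``mode`` is
    ``"counts"`` (reads) or ``"relative"`` (fractions; every non-empty column
    sums to 1 within 1e-9).
    """

    data: pd.DataFrame
    mode: str = "counts"
    empty_samples: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise TableError(f"unknown mode {self.mode!r}")
        self.data = self.data.astype(float) if self.mode == "relative" else self.data
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate taxon ids: {dupes}")
        if (self.data.to_numpy() < 0).any():
            bad = np.argwhere(self.data.to_numpy() < 0)[0]
            raise TableError(
                f"negative value at taxon {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if self.mode == "relative":
            sums = self.data.sum(axis=0)
            bad = sums.index[(np.abs(sums - 1.0) > RELATIVE_TOL) & (sums != 0.0)]
            if len(bad):
                raise TableError(
                    f"relative-mode column {bad[0]!r} sums to {sums[bad[0]]:.6g}, not 1"
                )
            self.empty_samples = tuple(sums.index[sums == 0.0])

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def sample_meta(self) -> pd.DataFrame:
        """Per-sample metadata parsed from the column keys."""
        rows = [parse_key(c) for c in self.data.columns]
        return pd.DataFrame(
            rows,
            index=self.data.columns,
            columns=["experiment", "participant", "sample_type", "replicate"],
        )

    def subset(self, samples: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise TableError(f"unknown samples {missing}")
        return AbundanceTable(self.data.loc[:, list(samples)].copy(), mode=self.mode)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write a table as TSV (UTF-8, taxa as rows, '#mode' comment header)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#mode\t{table.mode}\n")
        df = table.data
        if table.mode == "counts":
            df = df.astype(np.int64)
        df.to_csv(fh, sep="\t", index_label="taxon", float_format="%.17g")


def read_abundance_table(
    path: str | Path,
    manifest: Sequence[SampleUnit] | None = None,
) -> AbundanceTable:
    """Read a TSV abundance table; validates against a manifest if given."""
    path = Path(path)
    mode = "counts"
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#mode"):
            mode = first.strip().split("\t")[1]
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if df.index.name != "taxon":
        raise TableError(
            f"{path.name}: malformed header — first column must be 'taxon', "
            f"got {df.index.name!r}"
        )
    if manifest is not None:
        known = {u.key for u in manifest}
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise TableError(f"{path.name}: samples not in manifest: {unknown}")
    if mode == "counts":
        df = df.astype(np.int64)
    return AbundanceTable(df, mode=mode)


def read_trait_table(path: str | Path):
    """Read a taxon trait TSV; see :mod:`diatomring.indices` for the model.

    Columns: ``taxon`` (id), ``s`` (sensitivity, 1..5), ``v`` (indicator
    weight, 1/2/3), optionally ``class_1``..``class_7`` (a probability profile
    over the seven water-quality classes, each row summing to 1 within 1e-6).
    """
    from .indices import TraitTable  # deferred: avoids an import cycle

    df = pd.read_csv(path, sep="\t", index_col="taxon")
    profile_cols = [c for c in df.columns if c.startswith("class_")]
    profiles = df[profile_cols] if profile_cols else None
    return TraitTable(s=df["s"], v=df["v"], profiles=profiles)


def write_trait_table(traits, path: str | Path) -> None:
    df = pd.DataFrame({"s": traits.s, "v": traits.v})
    if traits.profiles is not None:
        df = pd.concat([df, traits.profiles], axis=1)
    df.to_csv(path, sep="\t", index_label="taxon")


def write_manifest(units: Sequence[SampleUnit], path: str | Path) -> None:
    rows = [
        {
            "key": u.key,
            "experiment": u.experiment,
            "participant": u.participant,
            "sample_type": u.sample_type,
            "replicate": u.replicate,
            "flags": ";".join(sorted(u.flags)),
        }
        for u in units
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> list[SampleUnit]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        SampleUnit(
            r.experiment,
            str(r.participant),
            r.sample_type,
            int(r.replicate),
            frozenset(f for f in str(r.flags).split(";") if f),
        )
        for r in df.itertuples()
    ]
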