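"""End-to-end orchestration of the ring-trial analyses.

Three entry points mirror how the study is run:

* :func:`simulate` — generate a full synthetic study (counts, manifest,
  traits, ground truth) from a config.
* :func:`run_proficiency` — the proficiency-test track for an experiment:
  filtering, diversity/CV summaries, quality indices, z-scores, Youden
  classification, verdict and anomaly scan.
* :func:`run_comparison` — the method-comparison track: species aggregation,
  Bray-Curtis distances, nMDS, PERMANOVA, MRPP, per-replicate indices and
  Kruskal-Wallis across participants.

Every report embeds the config hash, the seeds and the package version, and
all randomness flows from the single configured seed, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import distance_matrix, kruskal_wallis, mrpp, nmds, permanova
from .design import (
    AbundanceTable,
    read_abundance_table,
    read_manifest,
    read_trait_table,
    study_manifest,
    write_abundance_table,
    write_manifest,
    write_trait_table,
)
from .diversity import metric_cv_summary, sample_metrics
from .indices import index_table
from .preprocess import TaxonomyMap, aggregate_taxa, filter_low_abundance, to_relative
from .proficiency import (
    diagnose,
    proficiency_verdict,
    youden_classify,
    z_scores,
)
from .synthetic import (
    AnomalySpec,
    SyntheticTruth,
    make_reference_communities,
    sample_lab_effects,
    simulate_dataset,
    synthetic_traits,
)

EXIT_PASS, EXIT_ERROR, EXIT_FAIL = 0, 1, 3


@dataclass
class RunConfig:
    """Analysis configuration; YAML-loadable, hashed into every report."""

    output_dir: str = "out"
    seed: int = 0
    counts: str = "counts.tsv"
    manifest: str = "manifest.tsv"
    traits: str = "traits.tsv"
    taxonomy: str | None = None  # None: identity map (each taxon its own species)
    # generator settings
    depth: int = 20_000
    n_taxa_R: int = 60
    n_taxa_L: int = 60
    shared_fraction: float = 0.3
    abundance_model: str = "geometric"
    bias_sd: float = 0.08
    random_sd: float = 0.04
    detection_floor: float = 5e-4
    dropout_prob: float = 0.5
    anomalies: list[dict] = field(default_factory=list)
    biased_participant: str | None = None  # lab receiving an extra trait-aligned bias
    bias_effect: float = 0.5  # log-bias per unit of centred sensitivity
    # analysis thresholds
    min_reads: int = 10
    min_fraction: float = 1e-4
    min_coverage: float = 0.7
    line_tol: float = 2.0
    swap_cutoff: float = 0.05
    mixture_cutoff: float = 0.05
    n_perm: int = 999

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**doc)

    def hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]

    def provenance(self) -> dict[str, Any]:
        return {"config_hash": self.hash(), "seed": self.seed, "version": __version__}


def _outdir(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_json(path: Path, doc: dict) -> None:
    path.write_text(json.dumps(doc, indent=1, sort_keys=True, allow_nan=True) + "\n")


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def simulate(config: RunConfig) -> dict[str, Any]:
    """Generate a synthetic study on disk: counts, manifest, traits, truth."""
    out = _outdir(config)
    profiles = make_reference_communities(
        config.n_taxa_R,
        config.n_taxa_L,
        config.shared_fraction,
        config.abundance_model,
        seed=config.seed,
    )
    manifest = study_manifest()
    participants = sorted({u.participant for u in manifest})
    taxa = sorted(set().union(*(p.index for p in profiles.values())))
    effects = sample_lab_effects(
        participants,
        taxa,
        bias_sd=config.bias_sd,
        random_sd=config.random_sd,
        detection_floor=config.detection_floor,
        dropout_prob=config.dropout_prob,
        seed=config.seed + 1,
    )
    traits = synthetic_traits(taxa, seed=config.seed + 2)
    if config.biased_participant is not None:
        from .synthetic import sensitivity_aligned_bias

        lab = effects[config.biased_participant]
        lab.systematic_bias = lab.systematic_bias + sensitivity_aligned_bias(
            traits, config.bias_effect, taxa
        )
    anomalies = [AnomalySpec(**a) for a in config.anomalies]
    for a in anomalies:
        a.sources = tuple(a.sources)
    truth = SyntheticTruth(profiles, effects, anomalies, config.depth, config.seed)
    table = simulate_dataset(manifest, truth)

    write_abundance_table(table, out / config.counts)
    write_manifest(manifest, out / config.manifest)
    write_trait_table(traits, out / config.traits)
    truth.to_json(out / "truth.json")
    report = {
        "provenance": config.provenance(),
        "n_units": len(manifest),
        "n_sequenced": sum(1 for u in manifest if u.sequenced),
        "n_taxa": len(taxa),
        "files": [config.counts, config.manifest, config.traits, "truth.json"],
    }
    _write_json(out / "simulate_report.json", report)
    return report


# ---------------------------------------------------------------------------
# shared loading
# ---------------------------------------------------------------------------

def _load(config: RunConfig):
    out = _outdir(config)
    manifest = read_manifest(out / config.manifest)
    table = read_abundance_table(out / config.counts, manifest=manifest)
    traits = read_trait_table(out / config.traits)
    table = filter_low_abundance(table, config.min_reads, config.min_fraction)
    return manifest, table, traits


def _taxonomy_for(config: RunConfig, table: AbundanceTable) -> TaxonomyMap:
    if config.taxonomy:
        from .preprocess import read_taxonomy

        return read_taxonomy(Path(config.output_dir) / config.taxonomy)
    return TaxonomyMap.identity(table.taxa)


def _experiment_samples(table: AbundanceTable, manifest, experiment: str):
    keys = [
        u.key
        for u in manifest
        if u.experiment == experiment and u.sequenced and u.key in table.data.columns
    ]
    return table.subset(keys)


# ---------------------------------------------------------------------------
# proficiency track (E1/E2-style)
# ---------------------------------------------------------------------------

def run_proficiency(
    config: RunConfig, experiments: tuple[str, ...] = ("E1", "E2")
) -> dict[str, Any]:
    """Full proficiency-test analysis; returns (and writes) the report bundle."""
    out = _outdir(config)
    manifest, table, traits = _load(config)
    rel = to_relative(table)
    meta = rel.sample_meta()

    report: dict[str, Any] = {"provenance": config.provenance(), "experiments": {}}
    overall_offenders: list[str] = []

    for exp in experiments:
        sub = _experiment_samples(table, manifest, exp)
        sub = AbundanceTable(sub.data.loc[sub.data.sum(axis=1) > 0], mode="counts")
        sub_rel = to_relative(sub)
        sub_meta = sub_rel.sample_meta()
        community = sub_meta[sub_meta.sample_type != "W"].index.tolist()

        metrics = sample_metrics(sub)
        cv = metric_cv_summary(
            metrics.loc[community], sub_meta.loc[community, "sample_type"]
        )
        metrics.to_csv(out / f"{exp}_metrics.tsv", sep="\t", index_label="sample")
        cv.to_csv(out / f"{exp}_cv_radar.tsv", sep="\t", index_label="sample_type")

        idx = index_table(
            AbundanceTable(sub_rel.data[community], mode="relative"),
            traits,
            min_coverage=config.min_coverage,
        )
        idx = idx.merge(sub_meta, left_on="sample", right_index=True)
        idx.to_csv(out / f"{exp}_indices.tsv", sep="\t", index=False)

        exp_report: dict[str, Any] = {}
        z_pairs: dict[str, list[float]] = {}
        for stype in ("R", "L"):
            scores = (
                idx[(idx["index"] == "IPS") & (idx.sample_type == stype)]
                .groupby("participant")["score"]
                .median()
            )
            if len(scores) < 3:
                continue
            zres = z_scores(scores.to_dict())
            verdict, offenders = proficiency_verdict(zres)
            overall_offenders += [f"{exp}/{o}/{stype}" for o in offenders]
            pd.DataFrame([r.__dict__ for r in zres]).to_csv(
                out / f"{exp}_{stype}_zscores.tsv", sep="\t", index=False
            )
            exp_report[stype] = {
                "verdict": verdict,
                "offenders": offenders,
                "mu": zres[0].mu,
                "sigma": zres[0].sigma,
                "degenerate_dispersion": zres[0].degenerate,
            }
            for r in zres:
                z_pairs.setdefault(r.participant, [np.nan, np.nan])[
                    0 if stype == "R" else 1
                ] = r.z

        pairs = {k: (v[0], v[1]) for k, v in z_pairs.items() if not np.isnan(v).any()}
        if pairs:
            ycls = youden_classify(pairs, line_tol=config.line_tol)
            pd.DataFrame([c.__dict__ for c in ycls]).to_csv(
                out / f"{exp}_youden.tsv", sep="\t", index=False
            )
            exp_report["youden"] = {c.participant: c.label for c in ycls}

        # anomaly scan: every sample (incl. sequenced blanks) vs the consensus
        refs = {
            stype: sub_rel.data[sub_meta.index[sub_meta.sample_type == stype]].mean(axis=1)
            for stype in ("R", "L", "M")
            if (sub_meta.sample_type == stype).any()
        }
        refs = {k: v / v.sum() for k, v in refs.items() if v.sum() > 0}
        anomalies = []
        for key in sub_rel.samples:
            stype = sub_meta.loc[key, "sample_type"]
            rep = diagnose(
                sub_rel.data[key],
                stype if stype in refs else None,
                refs,
                sample=key,
                swap_cutoff=config.swap_cutoff,
                mixture_cutoff=config.mixture_cutoff,
            )
            if rep.verdict not in ("clean",):
                anomalies.append(rep.__dict__)
        exp_report["anomalies"] = anomalies
        report["experiments"][exp] = exp_report

    report["verdict"] = "fail" if overall_offenders else "pass"
    report["offenders"] = sorted(overall_offenders)
    _write_json(out / "proficiency_report.json", report)
    return report


# ---------------------------------------------------------------------------
# method-comparison track (E3/E4-style)
# ---------------------------------------------------------------------------

def run_comparison(
    config: RunConfig, experiments: tuple[str, ...] = ("E3", "E4")
) -> dict[str, Any]:
    """Method-comparison analysis; returns (and writes) the report bundle."""
    out = _outdir(config)
    manifest, table, traits = _load(config)
    taxonomy = _taxonomy_for(config, table)

    report: dict[str, Any] = {"provenance": config.provenance(), "experiments": {}}
    for exp in experiments:
        sub = _experiment_samples(table, manifest, exp)
        sub = AbundanceTable(sub.data.loc[sub.data.sum(axis=1) > 0], mode="counts")
        species = aggregate_taxa(sub, taxonomy, level="species")
        rel = to_relative(species)
        meta = rel.sample_meta()
        exp_report: dict[str, Any] = {}

        for stype in ("R", "L"):
            keys = meta.index[meta.sample_type == stype].tolist()
            if len(keys) < 3:
                continue
            block = AbundanceTable(rel.data[keys], mode="relative")
            groups = meta.loc[keys, "participant"].tolist()
            dm = distance_matrix(block)
            dm.to_csv(out / f"{exp}_{stype}_braycurtis.tsv", sep="\t")
            perm = permanova(dm, groups, n_perm=config.n_perm, seed=config.seed)
            mr = mrpp(dm, groups, n_perm=config.n_perm, seed=config.seed)
            coords, stress = nmds(dm, seed=config.seed)
            coords.to_csv(out / f"{exp}_{stype}_nmds.tsv", sep="\t", index_label="sample")

            idx = index_table(block, traits, which=("IPS",), min_coverage=config.min_coverage)
            idx = idx.merge(meta, left_on="sample", right_index=True)
            idx.to_csv(out / f"{exp}_{stype}_indices.tsv", sep="\t", index=False)
            ips = idx[idx["index"] == "IPS"].dropna(subset=["score"])
            h, p_kw = kruskal_wallis(ips["score"].tolist(), ips["participant"].tolist())
            medians = ips.groupby("participant")["score"].median()
            exp_report[stype] = {
                "permanova_R2": perm.effect_size,
                "permanova_p": perm.p_value,
                "mrpp_A": mr.effect_size,
                "mrpp_p": mr.p_value,
                "nmds_stress": stress,
                "kruskal_H": h,
                "kruskal_p": p_kw,
                "ips_participant_medians": medians.round(6).to_dict(),
                "ips_delta": float(medians.max() - medians.min()),
            }
        report["experiments"][exp] = exp_report
    _write_json(out / "comparison_report.json", report)
    return report
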