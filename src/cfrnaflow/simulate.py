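"""Synthetic cfRNA cohort generator with planted ground truth.

Emulates the tabular outputs of the upstream read-level tools that the
analysis consumes: a human gene/circRNA count matrix, two microbial genus
count tables (one per taxonomy pipeline), per-sample QC metrics, sample
metadata, and contamination resources (control-sample profiles and genus
lists).  Counts follow a negative-binomial model with log-normally
distributed library sizes and gene baselines; group effects, a multiplicative
batch factor, and contaminant genera are planted and recorded in a
:class:`SimTruth` object so downstream stages can be checked against truth.

Seeding: a master seed spawns one fixed child stream per stage via
``numpy.random.default_rng([seed, stage_offset])`` with offsets 0 (human
counts), 1 (genus tables) and 2 (QC metrics), so stages are independently
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from cfrnaflow.microbes import GenusTable, ContaminationResources

_STAGE_HUMAN = 0
_STAGE_GENUS = 1
_STAGE_QC = 2

HEALTHY_LABEL = "HD"

#: QC rule identifiers a designed failure can be planted for.
QC_RULE_IDS = (
    "r1",
    "r2",
    "r3",
    "r4_spikein",
    "r4_rrna",
    "r5_mrna_lncrna",
    "r5_unclassified",
    "r5_introns",
)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults encode the generator's reference study conditions: two groups of
    60 plasma samples, 2000 human features of which 100 per non-healthy group
    carry a planted |log2 fold change| of 2, negative-binomial dispersion 0.2,
    and a two-level multiplicative batch factor.
    """

    n_groups: int = 2
    n_per_group: int = 60
    n_genes: int = 2000
    n_genera: int = 60
    n_de_per_group: int = 100
    de_log2fc: float = 2.0
    dispersion: float = 0.2
    libsize_log_mean: float = math.log(2e6)
    libsize_log_sd: float = 0.25
    n_batches: int = 2
    batch_log2_sd: float = 0.5
    n_contaminant_genera: int = 6
    n_control_samples: int = 2
    pipeline_noise: float = 0.3
    seed: int = 0
    # planted discriminative genera per non-healthy group; None derives a
    # count proportional to the human planting density
    n_de_genera_per_group: int | None = None
    # planted effect size in the genus space; None reuses de_log2fc
    genus_de_log2fc: float | None = None

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ConfigurationError("n_groups must be >= 2 (group 0 is HD)")
        for name in ("n_per_group", "n_genes", "n_genera", "n_batches"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_de_per_group < 0:
            raise ConfigurationError("n_de_per_group must be >= 0")
        if self.n_de_per_group * (self.n_groups - 1) > self.n_genes:
            raise ConfigurationError(
                "n_de_per_group * (n_groups - 1) exceeds n_genes"
            )
        if self.de_log2fc <= 0:
            raise ConfigurationError("de_log2fc must be > 0")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if self.batch_log2_sd < 0:
            raise ConfigurationError("batch_log2_sd must be >= 0")
        if not 0.0 <= self.pipeline_noise <= 1.0:
            raise ConfigurationError("pipeline_noise must be in [0, 1]")
        if self.n_contaminant_genera > self.n_genera:
            raise ConfigurationError("n_contaminant_genera exceeds n_genera")
        if self.n_control_samples < 1:
            raise ConfigurationError("n_control_samples must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.n_groups * self.n_per_group

    def group_labels(self) -> list[str]:
        """Group 0 is the healthy-donor group; others are tumor sites."""
        return [HEALTHY_LABEL] + [f"T{i}" for i in range(1, self.n_groups)]

    def derived_n_de_genera(self) -> int:
        if self.n_de_genera_per_group is not None:
            return self.n_de_genera_per_group
        if self.n_de_per_group == 0:
            return 0
        prop = int(round(self.n_de_per_group * self.n_genera / self.n_genes))
        n_de = max(2, prop)
        if n_de * (self.n_groups - 1) > self.n_genera:
            n_de = self.n_genera // max(1, self.n_groups - 1)
        return n_de


@dataclass
class SimTruth:
    """Planted ground truth of one simulated cohort."""

    de_features: dict[str, list[str]] = field(default_factory=dict)
    de_signs: dict[str, dict[str, int]] = field(default_factory=dict)
    batch: dict[str, int] = field(default_factory=dict)
    control_eligible_genes: list[str] = field(default_factory=list)
    de_genera: dict[str, list[str]] = field(default_factory=dict)
    contaminant_rules: dict[str, str] = field(default_factory=dict)
    qc_designed_failures: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    size = 1.0 / dispersion
    mean = np.maximum(mean, 1e-12)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_human_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate the human gene/circRNA count matrix.

    Counts are negative-binomial with mean
    ``library_size * baseline_proportion * 2^(group effect) * 2^(batch effect)``;
    group effects of size ``de_log2fc`` (random sign) are planted on
    ``n_de_per_group`` disjoint genes per non-healthy group, and a batch
    effect of SD ``batch_log2_sd`` (log2 scale) multiplies all features.

    Returns the count matrix (genes x samples), the sample table (group,
    batch) and the truth record.
    """
    rng = np.random.default_rng([config.seed, _STAGE_HUMAN])
    genes = [f"gene{i:04d}" for i in range(config.n_genes)]
    labels = config.group_labels()
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    groups = np.repeat(labels, config.n_per_group)

    # deterministic round-robin batch assignment, then shuffled over samples
    batch = rng.permutation(np.arange(config.n_samples) % config.n_batches)

    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    baseline /= baseline.sum()
    libsize = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd,
                            size=config.n_samples)

    truth = SimTruth()
    truth.batch = dict(zip(sample_ids, (int(b) for b in batch)))

    # plant disjoint discriminative gene sets for each non-healthy group
    de_log2 = np.zeros((config.n_groups, config.n_genes))
    pool = rng.permutation(config.n_genes)
    cursor = 0
    for gi, label in enumerate(labels):
        if gi == 0:
            truth.de_features[label] = []
            truth.de_signs[label] = {}
            continue
        idx = pool[cursor:cursor + config.n_de_per_group]
        cursor += config.n_de_per_group
        signs = rng.choice([-1, 1], size=len(idx))
        de_log2[gi, idx] = signs * config.de_log2fc
        truth.de_features[label] = [genes[j] for j in idx]
        truth.de_signs[label] = {genes[j]: int(s) for j, s in zip(idx, signs)}
    planted = set().union(*truth.de_features.values()) if truth.de_features else set()
    truth.control_eligible_genes = [g for g in genes if g not in planted]

    batch_log2 = rng.normal(0.0, config.batch_log2_sd,
                            size=(config.n_batches, config.n_genes))

    group_index = np.repeat(np.arange(config.n_groups), config.n_per_group)
    mu = (
        libsize[None, :]
        * baseline[:, None]
        * 2.0 ** de_log2[group_index, :].T
        * 2.0 ** batch_log2[batch, :].T
    )
    counts = _nb_draw(rng, mu, config.dispersion)

    count_matrix = pd.DataFrame(counts, index=genes, columns=sample_ids)
    sample_table = pd.DataFrame(
        {"group": groups, "batch": batch}, index=pd.Index(sample_ids, name="sample_id")
    )
    return count_matrix, sample_table, truth


_CONTAMINANT_MECHANISMS = ("control", "ecoli_control", "lab", "skin", "vhost")


def simulate_genus_tables(
    config: SimConfig, truth: SimTruth
) -> tuple[GenusTable, GenusTable, ContaminationResources]:
    """Simulate the two genus count tables and the contamination resources.

    Both tables share one latent negative-binomial abundance draw (one read
    set classified twice): the k-mer table reports the latent counts and the
    alignment table is a per-count binomial thinning with retention rate
    ``1 - pipeline_noise``.  ``n_contaminant_genera`` genera are planted as
    contaminants: each is injected at high abundance into every cohort sample
    and with at least 3 reads into at least one control profile, and the
    contamination rule expected to remove it is recorded in
    ``truth.contaminant_rules``.  Mechanisms other than control-sample
    presence are realized by viral genera placed in a non-E.-coli control
    (which the control rules ignore) plus the matching lab / skin /
    virus-host list.
    """
    rng = np.random.default_rng([config.seed, _STAGE_GENUS])
    genera = [f"Genus_{i:03d}" for i in range(config.n_genera)]
    sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    labels = config.group_labels()
    group_index = np.repeat(np.arange(config.n_groups), config.n_per_group)

    # kingdom tags: fixed composition (65% bacteria, 25% virus, 10% archaea)
    # shuffled over genera, so the viral pool size is deterministic
    n_virus = max(1, int(round(0.25 * config.n_genera)))
    n_archaea = int(round(0.10 * config.n_genera))
    n_bacteria = config.n_genera - n_virus - n_archaea
    tags = (["bacteria"] * n_bacteria + ["virus"] * n_virus
            + ["archaea"] * n_archaea)
    kingdoms = pd.Series(rng.permutation(tags), index=genera, name="kingdom")

    baseline = rng.lognormal(mean=0.0, sigma=1.2, size=config.n_genera)
    baseline /= baseline.sum()
    # microbial read totals are a small fraction of the human library
    libsize = rng.lognormal(config.libsize_log_mean - 4.0, config.libsize_log_sd,
                            size=config.n_samples)

    # choose contaminants first so discriminative genera stay disjoint
    order = rng.permutation(config.n_genera)
    viral_pool = [i for i in order if kingdoms.iloc[i] == "virus"]
    nonviral_pool = [i for i in order if kingdoms.iloc[i] != "virus"]
    n_cont = config.n_contaminant_genera
    mechanisms = [_CONTAMINANT_MECHANISMS[i % len(_CONTAMINANT_MECHANISMS)]
                  for i in range(n_cont)]
    n_viral_needed = sum(1 for m in mechanisms if m != "control")
    if n_viral_needed > len(viral_pool):
        raise ConfigurationError(
            "not enough viral genera to host the requested contaminant mix; "
            "increase n_genera or decrease n_contaminant_genera"
        )
    contaminant_idx: list[int] = []
    vi = ni = 0
    for mech in mechanisms:
        if mech == "control":
            if ni < len(nonviral_pool):
                contaminant_idx.append(nonviral_pool[ni]); ni += 1
            else:
                contaminant_idx.append(viral_pool[vi]); vi += 1
                mech = "ecoli_control"
        else:
            contaminant_idx.append(viral_pool[vi]); vi += 1
    contaminant_set = set(contaminant_idx)

    # planted discriminative genera per non-healthy group, disjoint, never
    # overlapping contaminants
    n_de = config.derived_n_de_genera()
    genus_fc = (config.genus_de_log2fc if config.genus_de_log2fc is not None
                else config.de_log2fc)
    de_pool = [i for i in order if i not in contaminant_set]
    de_log2 = np.zeros((config.n_groups, config.n_genera))
    cursor = 0
    for gi, label in enumerate(labels):
        if gi == 0:
            truth.de_genera[label] = []
            continue
        idx = de_pool[cursor:cursor + n_de]
        cursor += n_de
        signs = rng.choice([-1, 1], size=len(idx))
        de_log2[gi, idx] = signs * genus_fc
        truth.de_genera[label] = [genera[j] for j in idx]

    batch = np.array([truth.batch[s] for s in sample_ids]) if truth.batch else \
        np.zeros(config.n_samples, dtype=int)
    batch_log2 = rng.normal(0.0, config.batch_log2_sd,
                            size=(config.n_batches, config.n_genera))

    mu = (
        libsize[None, :]
        * baseline[:, None]
        * 2.0 ** de_log2[group_index, :].T
        * 2.0 ** batch_log2[batch, :].T
    )
    latent = _nb_draw(rng, mu, config.dispersion)

    # inject contaminants ubiquitously so they clear the consensus threshold
    for j in contaminant_idx:
        latent[j, :] += _nb_draw(rng, np.full(config.n_samples, 60.0), 0.2)

    kmer_counts = latent.copy()
    rate = 1.0 - config.pipeline_noise
    alignment_counts = rng.binomial(latent, rate) if rate < 1.0 else latent.copy()

    # control profiles: control 0 is the E. coli control; background counts
    # for non-contaminant genera stay below the 3-read removal threshold
    control_ids = [f"CTRL{i}" for i in range(config.n_control_samples)]
    is_ecoli = {cid: (i == 0) for i, cid in enumerate(control_ids)}
    profiles = pd.DataFrame(
        rng.integers(0, 3, size=(config.n_genera, config.n_control_samples)),
        index=genera, columns=control_ids,
    )
    non_ecoli = [c for c in control_ids if not is_ecoli[c]]

    lab: set[str] = set()
    skin: set[str] = set()
    vhost: set[str] = set()
    rule_for = {"control": "control_sample", "ecoli_control": "control_sample",
                "lab": "lab_list", "skin": "skin_list", "vhost": "virus_host"}
    for j, mech in zip(contaminant_idx, mechanisms):
        g = genera[j]
        inject = 3 + int(rng.poisson(5.0))
        if mech == "control":
            target = control_ids[int(rng.integers(len(control_ids)))]
        elif mech == "ecoli_control":
            target = control_ids[0]
        else:
            if non_ecoli:
                target = non_ecoli[int(rng.integers(len(non_ecoli)))]
            else:
                # single-control cohorts only have the E. coli control, where
                # the control rule fires first
                target = control_ids[0]
                mech = "ecoli_control"
            if mech == "lab":
                lab.add(g)
            elif mech == "skin":
                skin.add(g)
            elif mech == "vhost":
                vhost.add(g)
        profiles.loc[g, target] = max(inject, int(profiles.loc[g, target]))
        truth.contaminant_rules[g] = rule_for[mech]

    # decoy list entries absent from the cohort must never change the result
    lab.add("Decoylabgenus")
    skin.add("Decoyskingenus")
    vhost.add("Decoyvirusgenus")

    kmer = GenusTable(
        counts=pd.DataFrame(kmer_counts, index=genera, columns=sample_ids),
        kingdoms=kingdoms.copy(), pipeline="kmer",
    )
    alignment = GenusTable(
        counts=pd.DataFrame(alignment_counts, index=genera, columns=sample_ids),
        kingdoms=kingdoms.copy(), pipeline="alignment",
    )
    resources = ContaminationResources(
        control_profiles=profiles, control_is_ecoli=is_ecoli,
        lab_contaminants=lab, skin_genera=skin, nonhuman_host_viruses=vhost,
    )
    return kmer, alignment, resources


def _passing_metrics(rng: np.random.Generator) -> dict[str, float]:
    raw = int(rng.integers(15_000_000, 40_000_000))
    clean = int(raw * rng.uniform(0.55, 0.85))
    dedup = int(clean * rng.uniform(0.10, 0.35))
    return {
        "raw_reads": raw,
        "clean_reads": clean,
        "dedup_aligned_reads": dedup,
        "spikein_fraction": float(rng.uniform(0.01, 0.30)),
        "rrna_fraction": float(rng.uniform(0.05, 0.35)),
        "mrna_lncrna_ratio": float(rng.uniform(0.25, 0.70)),
        "unclassified_ratio": float(rng.uniform(0.02, 0.25)),
        "intron_spanning_pairs": int(rng.integers(150_000, 1_000_000)),
    }


def _break_rule(metrics: dict[str, float], rule: str,
                rng: np.random.Generator) -> None:
    """Mutate one metric so that exactly `rule` is violated."""
    if rule == "r1":
        metrics["raw_reads"] = int(rng.integers(6_000_000, 10_000_001))
        metrics["clean_reads"] = int(rng.integers(5_100_000,
                                                  int(metrics["raw_reads"] * 0.9)))
        metrics["dedup_aligned_reads"] = int(
            metrics["clean_reads"] * rng.uniform(0.12, 0.30))
    elif rule == "r2":
        metrics["clean_reads"] = int(rng.integers(2_000_000, 5_000_001))
        metrics["dedup_aligned_reads"] = int(
            metrics["clean_reads"] * rng.uniform(0.15, 0.35))
    elif rule == "r3":
        metrics["dedup_aligned_reads"] = int(rng.integers(100_000, 500_001))
    elif rule == "r4_spikein":
        metrics["spikein_fraction"] = float(rng.uniform(0.5, 0.62))
    elif rule == "r4_rrna":
        metrics["rrna_fraction"] = float(rng.uniform(0.5, 0.62))
    elif rule == "r5_mrna_lncrna":
        metrics["mrna_lncrna_ratio"] = float(rng.uniform(0.02, 0.20))
    elif rule == "r5_unclassified":
        metrics["unclassified_ratio"] = float(rng.uniform(0.3, 0.5))
    elif rule == "r5_introns":
        metrics["intron_spanning_pairs"] = int(rng.integers(1_000, 100_001))
    else:  # pragma: no cover
        raise ValueError(f"unknown QC rule id: {rule}")


def simulate_qc_metrics(
    sample_table: pd.DataFrame, fail_fraction: float, seed: int
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Attach per-sample QC metrics, planting a fraction of designed failures.

    ``round(fail_fraction * n)`` samples are chosen to violate exactly one QC
    rule each (rules assigned round-robin over :data:`QC_RULE_IDS`); all other
    samples draw metrics comfortably inside every threshold.  Returns the
    augmented sample table and a ``sample_id -> rule_id`` map of the designed
    failures.

    Boundary values (e.g. raw reads exactly 10,000,000) count as failures,
    matching the strict inequalities of the QC gate.
    """
    if not 0.0 <= fail_fraction <= 1.0:
        raise ConfigurationError("fail_fraction must be in [0, 1]")
    rng = np.random.default_rng([seed, _STAGE_QC])
    n = len(sample_table)
    n_fail = int(round(fail_fraction * n))
    fail_ids = list(rng.choice(sample_table.index.to_numpy(), size=n_fail,
                               replace=False)) if n_fail else []

    rows = {}
    designed: dict[str, str] = {}
    for k, sid in enumerate(sample_table.index):
        m = _passing_metrics(rng)
        rows[sid] = m
    for k, sid in enumerate(fail_ids):
        rule = QC_RULE_IDS[k % len(QC_RULE_IDS)]
        _break_rule(rows[sid], rule, rng)
        designed[str(sid)] = rule

    metrics = pd.DataFrame.from_dict(rows, orient="index").loc[sample_table.index]
    out = sample_table.join(metrics)
    return out, designed


def simulate_cohort(config: SimConfig, fail_fraction: float = 0.0):
    """Run all three generator stages and return one coherent cohort.

    Returns ``(human_counts, sample_table, kmer, alignment, resources, truth)``
    where ``sample_table`` carries group, batch and QC metric columns and
    ``truth.qc_designed_failures`` records the planted QC violations.
    """
    human, samples, truth = simulate_human_counts(config)
    kmer, alignment, resources = simulate_genus_tables(config, truth)
    samples, designed = simulate_qc_metrics(samples, fail_fraction, config.seed)
    truth.qc_designed_failures = designed
    return human, samples, kmer, alignment, resources, truth
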