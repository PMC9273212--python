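"""Consensus genus calling and contamination filtering for plasma microbiomes.

Reads escaping the human genome are classified twice — by a k-mer profiler
and by an alignment pipeline — and only genera detected by BOTH pipelines
(at least ``min_reads`` reads in at least ``min_samples`` samples, evaluated
in each pipeline independently) are trusted.  The consensus set is then
screened against four contamination rule families, in a fixed order used
solely for deterministic ledger attribution:

1. ``control_sample`` — bacterial/archaeal genera with >= 3 reads in any
   negative-control sample, and viral genera with >= 3 reads in an E. coli
   control (the only controls informative for viral carry-over);
2. ``lab_list`` — genera on a published common-laboratory-contaminant list;
3. ``skin_list`` — genera abundant in human skin microbiomes (the list is a
   precomputed input: species with CPM > 10 in an external skin dataset);
4. ``virus_host`` — viral genera whose species infect nonhuman eukaryotic
   hosts.

Every input genus receives exactly one ledger entry recording whether and why
it was removed.  All rules are set subtractions, so the kept set is
order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

VALID_KINGDOMS = frozenset({"bacteria", "archaea", "virus"})
REMOVAL_RULES = ("not_consensus", "control_sample", "lab_list",
                 "skin_list", "virus_host")


class GenusTableError(ValueError):
    pass


@dataclass
class GenusTable:
    """Genus x sample count table from one taxonomy pipeline.

    ``counts`` holds non-negative integers, ``kingdoms`` maps each genus to
    bacteria/archaea/virus, and ``pipeline`` tags the origin ("kmer" or
    "alignment").
    """

    counts: pd.DataFrame
    kingdoms: pd.Series
    pipeline: str

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()].unique()
            raise GenusTableError(f"duplicate genus ids: {list(dup)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise GenusTableError("genus counts must be non-negative")
        missing = self.counts.index.difference(self.kingdoms.index)
        if len(missing):
            raise GenusTableError(
                f"genera without kingdom tag: {list(missing)[:5]}"
            )
        bad = set(self.kingdoms.loc[self.counts.index]) - VALID_KINGDOMS
        if bad:
            raise GenusTableError(f"unknown kingdom tags: {sorted(bad)}")

    @property
    def genera(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ContaminationResources:
    """Inputs to the contamination filter.

    ``control_profiles`` is a genus x control-sample count frame;
    ``control_is_ecoli`` tags each control as an E. coli control (relevant
    for the viral rule) or another negative control.  The three genus lists
    are consumed as precomputed sets; matching is exact and case-sensitive
    after whitespace trimming, with no taxonomy-synonym resolution.
    """

    control_profiles: pd.DataFrame
    control_is_ecoli: dict[str, bool]
    lab_contaminants: set[str] = field(default_factory=set)
    skin_genera: set[str] = field(default_factory=set)
    nonhuman_host_viruses: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        missing = [c for c in self.control_profiles.columns
                   if c not in self.control_is_ecoli]
        if missing:
            raise GenusTableError(
                f"control samples without E. coli annotation: {missing}"
            )
        self.lab_contaminants = {g.strip() for g in self.lab_contaminants}
        self.skin_genera = {g.strip() for g in self.skin_genera}
        self.nonhuman_host_viruses = {g.strip()
                                      for g in self.nonhuman_host_viruses}

    @property
    def ecoli_controls(self) -> list[str]:
        return [c for c in self.control_profiles.columns
                if self.control_is_ecoli[c]]


def detect_consensus_genera(
    kmer: GenusTable,
    alignment: GenusTable,
    min_reads: int = 3,
    min_samples: int = 3,
) -> list[str]:
    """Genera detected by both pipelines above the read/sample threshold.

    A genus is kept iff, in EACH pipeline independently, at least
    ``min_samples`` of the shared samples carry at least ``min_reads`` reads
    for it.  Returns genera in the k-mer table's row order.
    """
    shared = [s for s in kmer.samples if s in set(alignment.samples)]
    if not shared:
        raise GenusTableError("the two genus tables share no samples")
    if len(shared) != len(kmer.samples) or len(shared) != len(alignment.samples):
        warnings.warn(
            "genus tables have mismatched sample sets; using the "
            f"intersection of {len(shared)} samples",
            stacklevel=2,
        )

    def detected(table: GenusTable) -> set[str]:
        counts = table.counts[shared]
        n_hit = (counts >= min_reads).sum(axis=1)
        return set(counts.index[n_hit >= min_samples])

    keep = detected(kmer) & detected(alignment)
    return [g for g in kmer.genera if g in keep]


def filter_contaminants(
    genera: list[str],
    kingdoms: pd.Series,
    resources: ContaminationResources,
    control_min_reads: int = 3,
) -> tuple[list[str], pd.DataFrame]:
    """Remove potential contaminant genera, with full ledger attribution.

    Applies the four rule families in the fixed order control_sample ->
    lab_list -> skin_list -> virus_host and records the first matching rule
    per genus.  Returns the kept genera (input order preserved) and a ledger
    frame indexed by genus with columns ``removed``, ``rule``, ``evidence``.
    """
    untagged = [g for g in genera if g not in kingdoms.index]
    if untagged:
        raise GenusTableError(f"genera without kingdom tag: {untagged[:5]}")

    profiles = resources.control_profiles
    ecoli = resources.ecoli_controls
    ledger_rows: dict[str, dict] = {}
    kept: list[str] = []
    for g in genera:
        kingdom = kingdoms[g]
        rule = None
        evidence = ""
        if g in profiles.index:
            hits = profiles.loc[g]
            if kingdom in ("bacteria", "archaea"):
                pos = hits[hits >= control_min_reads]
                if len(pos):
                    rule = "control_sample"
                    evidence = (f"{kingdom} genus with >= {control_min_reads} "
                                f"reads in control(s) {list(pos.index)}")
            elif kingdom == "virus" and ecoli:
                pos = hits[ecoli][hits[ecoli] >= control_min_reads]
                if len(pos):
                    rule = "control_sample"
                    evidence = (f"virus genus with >= {control_min_reads} reads "
                                f"in E. coli control(s) {list(pos.index)}")
        if rule is None and g in resources.lab_contaminants:
            rule = "lab_list"
            evidence = "on common laboratory contaminant list"
        if rule is None and g in resources.skin_genera:
            rule = "skin_list"
            evidence = "on abundant skin-microbiome genus list"
        if rule is None and kingdom == "virus" and g in resources.nonhuman_host_viruses:
            rule = "virus_host"
            evidence = "viral genus with nonhuman eukaryotic hosts"

        if rule is None:
            kept.append(g)
            ledger_rows[g] = {"removed": False, "rule": "", "evidence": ""}
        else:
            ledger_rows[g] = {"removed": True, "rule": rule, "evidence": evidence}

    ledger = pd.DataFrame.from_dict(ledger_rows, orient="index")
    ledger.index.name = "genus"
    return kept, ledger.loc[genera]


def build_trusted_genus_set(
    kmer: GenusTable,
    alignment: GenusTable,
    resources: ContaminationResources,
    min_reads: int = 3,
    min_samples: int = 3,
    control_min_reads: int = 3,
) -> tuple[list[str], pd.DataFrame]:
    """Consensus detection followed by contamination filtering.

    The returned ledger covers every genus present in either pipeline's
    table: genera failing the dual-pipeline detection threshold are recorded
    as ``not_consensus``; consensus genera carry the contamination-filter
    attribution.
    """
    consensus = detect_consensus_genera(kmer, alignment, min_reads, min_samples)
    kept, filter_ledger = filter_contaminants(
        consensus, kmer.kingdoms, resources, control_min_reads
    )
    all_genera = list(dict.fromkeys(kmer.genera + alignment.genera))
    rows = {}
    consensus_set = set(consensus)
    for g in all_genera:
        if g in consensus_set:
            rows[g] = filter_ledger.loc[g].to_dict()
        else:
            rows[g] = {
                "removed": True,
                "rule": "not_consensus",
                "evidence": (f"not detected with >= {min_reads} reads in "
                             f">= {min_samples} samples by both pipelines"),
            }
    ledger = pd.DataFrame.from_dict(rows, orient="index").loc[all_genera]
    ledger.index.name = "genus"
    return kept, ledger


HUMAN_PREFIX = "hs"
MICROBE_PREFIX = "mb"


def merge_feature_spaces(
    human: pd.DataFrame, genera: pd.DataFrame
) -> pd.DataFrame:
    """Row-concatenate human and microbial features over shared samples.

    Feature ids are namespaced as ``hs:<gene>`` and ``mb:<genus>``; the human
    table's sample order is preserved.  Raises on disjoint sample sets or a
    duplicate namespaced id.
    """
    shared = [s for s in human.columns if s in set(genera.columns)]
    if not shared:
        raise GenusTableError("human and genus tables share no samples")
    top = human[shared].copy()
    top.index = [f"{HUMAN_PREFIX}:{i}" for i in top.index]
    bottom = genera[shared].copy()
    bottom.index = [f"{MICROBE_PREFIX}:{i}" for i in bottom.index]
    merged = pd.concat([top, bottom], axis=0)
    if merged.index.has_duplicates:
        dup = merged.index[merged.index.duplicated()].unique()
        raise GenusTableError(f"duplicate namespaced feature ids: {list(dup)[:5]}")
    return merged


def split_feature_spaces(
    merged: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`merge_feature_spaces`."""
    is_human = merged.index.str.startswith(f"{HUMAN_PREFIX}:")
    is_microbe = merged.index.str.startswith(f"{MICROBE_PREFIX}:")
    if not (is_human | is_microbe).all():
        bad = merged.index[~(is_human | is_microbe)]
        raise GenusTableError(f"features without namespace prefix: {list(bad)[:5]}")
    human = merged.loc[is_human].copy()
    human.index = [i.split(":", 1)[1] for i in human.index]
    microbe = merged.loc[is_microbe].copy()
    microbe.index = [i.split(":", 1)[1] for i in microbe.index]
    return human, microbe
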