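"""End-to-end orchestration: simulate/load -> QC -> microbes -> normalize ->
differential -> classification, with a run manifest and stage-tagged errors.

The pipeline realizes the downstream arrows of the analysis design: count
tables enter, a consolidated report bundle leaves.  Every stage writes its
inputs/outputs to the run directory so any stage can be rerun standalone,
and a manifest records the package version, configuration and master seed.
All numeric report output uses 10 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from cfrnaflow import __version__, io
from cfrnaflow.classify import (
    BootstrapSpec,
    aggregate_feature_importance,
    evaluate_binary,
    evaluate_multiclass,
)
from cfrnaflow.differential import differential_features, log2_fold_change
from cfrnaflow.microbes import build_trusted_genus_set, merge_feature_spaces
from cfrnaflow.normalize import TMMParams, cpm, normalize_counts
from cfrnaflow.qc import apply_qc_table
from cfrnaflow.simulate import HEALTHY_LABEL, SimConfig, simulate_cohort

logger = logging.getLogger("cfrnaflow")


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage tag."""


@dataclass
class PipelineConfig:
    """Structured configuration of one pipeline run.

    Either ``simulate`` holds :class:`SimConfig` keyword arguments, or the
    four input paths (``counts``, ``samples``, ``kmer``, ``alignment``) plus
    a contamination ``resources`` directory must be given.
    """

    outdir: str = "cfrnaflow_run"
    seed: int = 0
    simulate: dict | None = None
    fail_fraction: float = 0.1
    counts: str | None = None
    samples: str | None = None
    kmer: str | None = None
    alignment: str | None = None
    resources: str | None = None
    qc_enabled: bool = True
    ruv_k: int = 1
    logratio_trim: float = 0.30
    abundance_trim: float = 0.05
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    bootstrap: dict = field(default_factory=dict)
    run_binary: bool = True
    run_multiclass: bool = True
    multiclass_include_healthy: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise PipelineError(f"[config] unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.simulate is None:
            missing = [name for name in
                       ("counts", "samples", "kmer", "alignment", "resources")
                       if getattr(self, name) is None]
            if missing:
                raise PipelineError(
                    f"[config] no simulation block and missing inputs: {missing}"
                )
            for name in ("counts", "samples", "kmer", "alignment", "resources"):
                if not Path(getattr(self, name)).exists():
                    raise PipelineError(
                        f"[config] input path does not exist: "
                        f"{getattr(self, name)}"
                    )

    def bootstrap_spec(self) -> BootstrapSpec:
        kwargs = dict(self.bootstrap)
        if "depth_grid" in kwargs:
            kwargs["depth_grid"] = tuple(
                None if d in (None, "none", "unbounded") else int(d)
                for d in kwargs["depth_grid"]
            )
        kwargs.setdefault("seed", self.seed)
        return BootstrapSpec(**kwargs)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _setup_logging(outdir: Path, level: str) -> None:
    logger.setLevel(level.upper())
    logger.handlers = [logging.StreamHandler(sys.stderr),
                       logging.FileHandler(outdir / "run.log", mode="w")]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in logger.handlers:
        h.setFormatter(fmt)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every enabled stage; returns the consolidated report dict.

    Any stage error aborts the run with a stage-tagged message; partial
    outputs are retained next to a ``FAILED`` marker file.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, config.log_level)
    report: dict = {"version": __version__, "seed": config.seed,
                    "config_hash": _config_hash(config)}
    stage = "setup"
    try:
        # ---- inputs ----
        if config.simulate is not None:
            stage = "simulate"
            logger.info("simulating synthetic cohort")
            sim = SimConfig(**{**config.simulate, "seed": config.seed})
            human, samples, kmer, alignment, resources, truth = \
                simulate_cohort(sim, fail_fraction=config.fail_fraction)
            io.write_counts(human, outdir / "human_counts.tsv")
            io.write_sample_table(samples, outdir / "samples.tsv")
            io.write_genus_table(kmer, outdir / "genus_kmer.tsv")
            io.write_genus_table(alignment, outdir / "genus_alignment.tsv")
            io.write_resources(resources, outdir / "resources")
            io.write_json(truth.to_dict(), outdir / "truth.json")
        else:
            stage = "load"
            human = io.read_counts(config.counts)
            samples = io.read_sample_table(config.samples)
            kmer = io.read_genus_table(config.kmer, "kmer")
            alignment = io.read_genus_table(config.alignment, "alignment")
            resources = io.read_resources(config.resources)

        # ---- qc ----
        if config.qc_enabled:
            stage = "qc"
            decisions = apply_qc_table(samples)
            decisions.to_csv(outdir / "qc_decisions.tsv", sep="\t")
            keep = decisions.index[decisions["passed"]]
            logger.info("QC: %d/%d samples pass", len(keep), len(samples))
            samples = samples.loc[keep]
            human = human[keep]
            kmer.counts = kmer.counts[keep]
            alignment.counts = alignment.counts[keep]
            report["qc"] = {"n_pass": int(len(keep)),
                            "n_fail": int((~decisions["passed"]).sum())}

        # ---- microbial consensus + decontamination ----
        stage = "microbes"
        kept_genera, ledger = build_trusted_genus_set(kmer, alignment,
                                                      resources)
        ledger.to_csv(outdir / "removal_ledger.tsv", sep="\t")
        logger.info("microbes: %d/%d genera kept", len(kept_genera),
                    len(ledger))
        genus_counts = kmer.counts.loc[kept_genera]
        report["microbes"] = {
            "n_genera_in": int(len(ledger)),
            "n_genera_kept": int(len(kept_genera)),
            "removed_by_rule": ledger.loc[ledger["removed"], "rule"]
            .value_counts().to_dict(),
        }

        # ---- normalization (per feature space) ----
        stage = "normalize"
        groups = samples["group"]
        normdir = outdir / "norm"
        normdir.mkdir(exist_ok=True)
        norm_human = normalize_counts(human, groups, k=config.ruv_k,
                                      params=TMMParams(config.logratio_trim,
                                                       config.abundance_trim))
        spaces = {"human": (human, norm_human)}
        if len(genus_counts) >= 8:
            norm_genus = normalize_counts(genus_counts, groups,
                                          k=config.ruv_k)
            spaces["microbe"] = (genus_counts, norm_genus)
        else:
            logger.warning("too few trusted genera (%d) for a stable "
                           "genus-space normalization; classification uses "
                           "human features only", len(genus_counts))
        for name, (_, norm) in spaces.items():
            norm.tmm_factors.to_csv(normdir / f"{name}_tmm_factors.tsv",
                                    sep="\t")
            norm.W.to_csv(normdir / f"{name}_W.tsv", sep="\t")
            norm.adjusted_logexpr.to_csv(normdir / f"{name}_adjusted.tsv",
                                         sep="\t")
            (normdir / f"{name}_control_genes.txt").write_text(
                "\n".join(norm.control_genes) + "\n")

        # ---- differential abundance (each cancer group vs healthy) ----
        stage = "differential"
        cancer_groups = [g for g in dict.fromkeys(groups)
                         if g != HEALTHY_LABEL]
        human_cpm = cpm(human, norm_human.tmm_factors)
        diff_summary = {}
        for g in cancer_groups:
            table = differential_features(
                human_cpm, groups, g, HEALTHY_LABEL,
                lfc_threshold=config.lfc_threshold,
                fdr_threshold=config.fdr_threshold,
            )
            table.to_csv(outdir / f"diff_{g}_vs_{HEALTHY_LABEL}.tsv",
                         sep="\t")
            diff_summary[g] = int(table["significant"].sum())
        report["differential"] = {"n_significant_vs_healthy": diff_summary}

        # ---- classification ----
        spec = config.bootstrap_spec()
        merged = norm_human.adjusted_logexpr
        if "microbe" in spaces:
            merged = merge_feature_spaces(norm_human.adjusted_logexpr,
                                          spaces["microbe"][1].adjusted_logexpr)
        reportdir = outdir / "report"
        reportdir.mkdir(exist_ok=True)

        if config.run_binary:
            stage = "classify-binary"
            logger.info("binary bootstrap evaluation (%d replicates)",
                        spec.n_replicates)
            binary_labels = pd.Series(
                ["cancer" if g != HEALTHY_LABEL else HEALTHY_LABEL
                 for g in groups], index=groups.index)
            binary = evaluate_binary(merged, binary_labels, spec,
                                     positive_label="cancer")
            binary.oob_roc.to_csv(reportdir / "oob_roc.tsv", sep="\t",
                                  index=False)
            fc = log2_fold_change(
                merge_feature_spaces(human_cpm,
                                     cpm(genus_counts,
                                         spaces["microbe"][1].tmm_factors))
                if "microbe" in spaces else human_cpm,
                binary_labels, "cancer", HEALTHY_LABEL)
            recurrent = aggregate_feature_importance(
                binary.replicates, rank_cutoff=50,
                min_frequency=max(1, int(0.4 * spec.n_replicates)),
                fold_changes=fc)
            recurrent.to_csv(reportdir / "recurrent_features_binary.tsv",
                             sep="\t", index=False)
            report["binary"] = binary.to_json_dict()

        if config.run_multiclass and len(cancer_groups) >= 3:
            stage = "classify-multiclass"
            logger.info("multiclass bootstrap evaluation (%d replicates)",
                        spec.n_replicates)
            if config.multiclass_include_healthy:
                mask = groups.notna()
            else:
                mask = groups != HEALTHY_LABEL
            sub = merged.loc[:, mask.index[mask]]
            multi = evaluate_multiclass(sub, groups[mask], spec)
            multi.confusion_matrix.to_csv(reportdir / "confusion_matrix.tsv",
                                          sep="\t")
            report["multiclass"] = multi.to_json_dict()

        stage = "report"
        io.write_json(report, reportdir / "report.json")
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": _config_hash(config),
        }
        io.write_json(manifest, outdir / "manifest.json")
        logger.info("pipeline complete: %s", outdir)
        return report
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"[{stage}] {exc}") from exc
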