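"""End-to-end orchestration: (simulate | ingest) -> transcriptome -> blacklist
filter -> count -> presence -> normalize -> differential expression ->
survival, with per-stage read accounting in a machine-readable run report.

Defaults reproduce the reference analysis settings: placement cap 10, repeat
blacklist bound 24 bp, counting thresholds 15 nt / 80% / MAPQ >= 1 with
primary alignments only, presence tiers 2 reads in 10 samples (secondary
1 in 25).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import blacklist as bl
from . import expression as ex
from . import io
from . import quantify as qt
from . import simulate as sim
from . import survival as sv
from . import transcriptome as tx

logger = logging.getLogger(__name__)

DEFAULT_CONTRASTS = [
    {"name": "gradeIII_vs_gradeI", "column": "grade", "case": "III", "ref": "I"},
    {"name": "ERneg_vs_ERpos", "column": "er", "case": "neg", "ref": "pos"},
    {
        "name": "gradeIII_vs_gradeI_adjER",
        "column": "grade",
        "case": "III",
        "ref": "I",
        "adjust": "er",
    },
]

DEFAULT_SURVIVAL = [
    {"endpoint": "RFS", "subset": "rt_treated", "er_restrict": "pos"},
    {"endpoint": "BCSS", "subset": "rt_treated", "er_restrict": "pos"},
    {"endpoint": "OS", "subset": "all_invasive_local"},
]


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (defaults = reference settings)."""

    seed: int = 1
    simulate: dict | None = field(default_factory=dict)  # SimConfig overrides
    paths: dict | None = None  # file-based inputs (genome/db/annotations/...)
    max_hits: int = 10
    repeat_min_len_exclusive: int = 24
    min_overlap_nt: int = 15
    frac_overlap: float = 0.80
    min_mapq: int = 1
    presence_min_reads: int = 2
    presence_min_samples: int = 10
    secondary_min_reads: int = 1
    secondary_min_samples: int = 25
    pseudocount: float = 1.0
    contrasts: list = field(default_factory=lambda: [dict(c) for c in DEFAULT_CONTRASTS])
    survival_analyses: list = field(
        default_factory=lambda: [dict(c) for c in DEFAULT_SURVIVAL]
    )
    survival_target: str = "auto"
    censor_date: str = "2015-01-01"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _load_inputs(cfg: RunConfig, out_dir: Path):
    """Simulate the inputs, or load them from configured paths."""
    if cfg.simulate is not None:
        sim_cfg = sim.config_from_dict({"seed": cfg.seed, **cfg.simulate})
        ref = sim.simulate_reference(sim_cfg)
        per_sample, conditions, truth = sim.simulate_alignments(sim_cfg, ref)
        alignments = [r for sid in sorted(per_sample) for r in per_sample[sid]]
        return ref.genome, ref.db, ref.features, alignments, conditions, sim_cfg, truth
    paths = cfg.paths or {}
    for key in ("genome", "db", "alignments"):
        if key not in paths:
            raise ValueError(f"run config: missing input path {key!r}")
    genome = io.read_fasta(paths["genome"])
    db = io.read_db_fasta(paths["db"])
    features = []
    for ann in paths.get("annotations", []):
        reader = io.read_annotation_bed if ann.get("format") == "bed" else io.read_annotation_gff3
        features.extend(reader(ann["path"], ann["feature_class"]))
    alignments = []
    for sam in paths["alignments"]:
        alignments.extend(io.read_sam(sam))
    meta = (
        pd.read_csv(paths["sample_metadata"], sep="\t").set_index("sample_id")
        if "sample_metadata" in paths
        else None
    )
    return genome, db, features, alignments, meta, None, None


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full cascade and write tables plus ``report.json``.

    The returned report contains the resolved config and per-stage read
    accounting (raw -> filtered -> counted); reruns with the same config are
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _resolved_config(cfg), "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return time.time()

    t0 = stage("inputs")
    genome, db, features, alignments, meta, sim_cfg, truth = _load_inputs(cfg, out_dir)
    sample_ids = sorted({a.sample_id for a in alignments})
    if cfg.presence_min_samples > len(sample_ids):
        raise ValueError(
            f"presence_min_samples={cfg.presence_min_samples} exceeds the "
            f"{len(sample_ids)} samples in the input"
        )
    logger.info("inputs ready in %.1fs", time.time() - t0)

    t0 = stage("transcriptome")
    placed, placement_report = tx.place_sequences(db, genome, max_hits=cfg.max_hits)
    tx.write_transcriptome(placed, out_dir / "transcriptome.gtf")
    placement_report.to_csv(out_dir / "placement_report.tsv", sep="\t", index=False)
    report["stages"]["placement"] = {
        "n_db_entries": len(db),
        **{k: int(v) for k, v in placement_report["status"].value_counts().items()},
    }

    t0 = stage("filter")
    mito = sim_cfg.mito_chrom if sim_cfg else (cfg.paths or {}).get("mito_chrom")
    black = bl.build_blacklist(
        features, mito_chrom=mito, repeat_min_len_exclusive=cfg.repeat_min_len_exclusive
    )
    retained, fstats = bl.filter_alignments(alignments, black, valid_chroms=genome)
    fstats.to_frame().to_csv(out_dir / "filter_stats.tsv", sep="\t", index=False)
    report["stages"]["filter"] = {
        "input": fstats.n_input,
        "removed": fstats.n_removed,
        "retained": fstats.n_retained,
        "blacklist_bp": black.total_bp,
    }

    t0 = stage("count")
    counts = qt.count_reads(
        retained,
        placed,
        min_overlap_nt=cfg.min_overlap_nt,
        frac_overlap=cfg.frac_overlap,
        min_mapq=cfg.min_mapq,
        samples=sample_ids,
    )
    counts.to_csv(out_dir / "counts.tsv", sep="\t")
    report["stages"]["count"] = {
        "matrix_sum": int(counts.to_numpy().sum()),
        "n_entries": int(counts.shape[0]),
        "n_samples": int(counts.shape[1]),
    }

    presence = qt.call_presence(
        counts,
        min_reads=cfg.presence_min_reads,
        min_samples=cfg.presence_min_samples,
        sec_min_reads=cfg.secondary_min_reads,
        sec_min_samples=cfg.secondary_min_samples,
    )
    presence.to_csv(out_dir / "presence.tsv", sep="\t")
    report["stages"]["presence"] = {
        k: int(v) for k, v in presence["tier"].value_counts().items()
    }
    present_accs = presence.index[presence["tier"] == "present"].tolist()
    report["present_accessions"] = present_accs

    t0 = stage("normalize")
    factors = ex.size_factors(counts)
    normalized = ex.normalize(counts, factors, pseudocount=cfg.pseudocount)
    normalized.round(6).to_csv(out_dir / "normalized.tsv", sep="\t")

    t0 = stage("differential expression")
    de_summary = {}
    if meta is not None and present_accs:
        de_counts = counts.loc[present_accs]
        for spec_ in cfg.contrasts:
            col = spec_["column"]
            case = meta.index[meta[col] == spec_["case"]].tolist()
            ref_ = meta.index[meta[col] == spec_["ref"]].tolist()
            if len(case) < 2 or len(ref_) < 2:
                de_summary[spec_["name"]] = {"skipped": "too few samples"}
                continue
            adjust = (
                meta.loc[case + ref_, spec_["adjust"]].to_dict()
                if spec_.get("adjust")
                else None
            )
            contrast = ex.Contrast(spec_["name"], case, ref_, adjust)
            res = ex.nb_wald_de(counts[contrast.samples].loc[present_accs], contrast,
                                factors=factors)
            res.round(6).to_csv(out_dir / f"de_{spec_['name']}.tsv", sep="\t")
            de_summary[spec_["name"]] = {
                "n_tested": int(res["p"].notna().sum()),
                "n_significant": int((res["padj"] < 0.05).sum()),
            }
    report["stages"]["differential_expression"] = de_summary

    t0 = stage("survival")
    surv_summary = []
    if meta is not None and present_accs:
        target = cfg.survival_target
        if target == "auto":
            target = counts.loc[present_accs].mean(axis=1).idxmax()
        if sim_cfg is not None:
            clinical, surv_truth = sim.simulate_clinical_survival(
                sim_cfg, meta, normalized, target
            )
            truth = {**(truth or {}), "survival": surv_truth}
        elif cfg.paths and "clinical" in cfg.paths:
            clinical = pd.read_csv(cfg.paths["clinical"], sep="\t")
        else:
            clinical = None
        if clinical is not None:
            clinical.to_csv(out_dir / "clinical.tsv", sep="\t", index=False)
            endpoints = sv.make_endpoints(clinical, cfg.censor_date)
            eligible = sv.eligible_cases(clinical)
            quart = sv.assign_quartiles(normalized.loc[target])
            fits = []
            for an in cfg.survival_analyses:
                subset, plan = sv.treatment_subset(
                    eligible, an["subset"], an.get("er_restrict")
                )
                surv = endpoints[
                    (endpoints["endpoint"] == an["endpoint"])
                    & endpoints["sample_id"].isin(subset["sample_id"])
                ]
                row = {
                    "accession": target,
                    "endpoint": an["endpoint"],
                    "subset": an["subset"],
                    "n": len(subset),
                }
                try:
                    fit = sv.cox_multivariate_stepwise(
                        surv, quart, subset, plan
                    )
                    fit.accession, fit.endpoint, fit.subset = (
                        target,
                        an["endpoint"],
                        an["subset"],
                    )
                    fits.append(fit)
                    row.update(
                        overall_p=_r6(fit.overall_p),
                        n_events=fit.n_events,
                        selected_covariates=fit.selected_covariates,
                        converged=fit.converged,
                        **{
                            f"HR_{t}": _r6(fit.terms.loc[t, "hr"])
                            for t in ("Q2", "Q3", "Q4")
                            if t in fit.terms.index
                        },
                    )
                except ValueError as exc:
                    row["error"] = str(exc)
                surv_summary.append(row)
            sv.overall_fdr(fits)
            for fit, row in zip(fits, [r for r in surv_summary if "error" not in r]):
                row["overall_p_adj"] = _r6(fit.overall_p_adj)
    report["stages"]["survival"] = surv_summary
    if truth is not None:
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True, default=str)

    report["consistency"] = {
        "filter_conserved": report["stages"]["filter"]["input"]
        == report["stages"]["filter"]["removed"] + report["stages"]["filter"]["retained"],
        "counted_le_filtered": report["stages"]["count"]["matrix_sum"]
        <= report["stages"]["filter"]["retained"],
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    _write_text_report(report, out_dir / "report.txt")
    return report


def _r6(x):
    return None if x is None or not np.isfinite(x) else round(float(x), 6)


def _resolved_config(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    if cfg.simulate is not None:
        d["simulate"] = sim.config_to_dict(
            sim.config_from_dict({"seed": cfg.seed, **cfg.simulate})
        )
    return d


def _write_text_report(report: dict, path: Path) -> None:
    lines = ["piratrue run report", "==================="]
    for name, info in report["stages"].items():
        lines.append(f"\n[{name}]")
        if isinstance(info, dict):
            for k, v in sorted(info.items()):
                lines.append(f"  {k}: {v}")
        else:
            for row in info:
                lines.append("  " + json.dumps(row, sort_keys=True, default=str))
    lines.append("")
    path.write_text("\n".join(lines))
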