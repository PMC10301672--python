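"""End-to-end orchestration: detect -> consensus -> classify -> promoters ->
motifs -> stats -> compare, as one configured, reproducible run.

All stage outputs are pure functions of (inputs, config, seed): re-running
with the same configuration reproduces every non-log output byte-for-byte.
Timing and progress go to a logger, never into result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classification import ClassParams, classification_summary, classify_all
from .comparison import deviation_histogram, match_tss_sets
from .errors import ParameterError, RoseError
from .io_formats import (
    load_annotation,
    load_genome,
    load_read_starts,
    read_tss_table,
    write_logo_matrix,
    write_tss_table,
)
from .motif_discovery import (
    discover_motif,
    dual_motif_report,
    extract_promoters,
    filter_by_score,
    logo_counts,
    null_score_cutoff,
    score_sequence,
)
from .promoter_stats import nucleotide_preferences
from .tss_detection import DetectionParams, consensus_tss, detect_tss, estimate_params

logger = logging.getLogger("rose")

STAGES = (
    "detect",
    "consensus",
    "classify",
    "promoters",
    "motifs",
    "stats",
    "compare",
)


@dataclass
class PipelineConfig:
    genome: str
    annotation: str
    replicates: list[dict]  # each: {fw, rv, replicate_id}
    outdir: str
    sample_id: str = "sample"
    # detection: None -> per-replicate automatic estimation
    min_read_starts: int | None = None
    min_fold_enrichment: float = 5.0
    background_window: int = 50
    target_quantile: float = 0.9
    min_support: int = 4
    merge_tolerance: int = 0
    max_upstream_primary: int = 300
    antisense_flank: int = 100
    promoter_window: int = 50
    motif_width: int = 6
    prior_sd: float = 4.0
    n_motif_seeds: int = 5
    null_quantile: float = 0.95
    tolerance: int = 3
    references: dict[str, str] = field(default_factory=dict)
    circular: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        missing = [
            p
            for p in [self.genome, self.annotation]
            + [r[k] for r in self.replicates for k in ("fw", "rv")]
            + list(self.references.values())
            if not Path(p).exists()
        ]
        if missing:
            raise ParameterError(f"missing input files: {missing}")
        if self.min_support > len(self.replicates):
            raise ParameterError("min_support exceeds the number of replicates")

    def resolved(self) -> dict:
        d = dict(vars(self))
        d["references"] = dict(self.references)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []

    genome = load_genome(config.genome)[0]
    genome.circular = config.circular
    genes = load_annotation(config.annotation)

    stage = "detect"
    try:
        calls_by_replicate = []
        for i, rep in enumerate(config.replicates):
            profile = load_read_starts(
                rep["fw"], rep["rv"],
                sample_id=config.sample_id,
                replicate_id=rep.get("replicate_id", f"rep{i + 1}"),
                contig_length=genome.length,
            )
            if config.min_read_starts is None:
                params = estimate_params(
                    profile,
                    target_quantile=config.target_quantile,
                    min_fold_enrichment=config.min_fold_enrichment,
                    background_window=config.background_window,
                )
            else:
                params = DetectionParams(
                    config.min_read_starts,
                    config.min_fold_enrichment,
                    config.background_window,
                )
            calls_by_replicate.append(
                detect_tss(profile, params, genome.length, config.circular)
            )
        logger.info("detect: %s calls across %d replicates",
                    sum(map(len, calls_by_replicate)), len(calls_by_replicate))
        completed.append(stage)

        stage = "consensus"
        consensus = consensus_tss(
            calls_by_replicate, config.min_support, config.merge_tolerance
        )
        if not consensus:
            raise RoseError("no consensus TSS survived the support filter")
        write_tss_table([t.as_record() for t in consensus], outdir / "consensus_tss.tsv")
        completed.append(stage)

        stage = "classify"
        class_params = ClassParams(config.max_upstream_primary, config.antisense_flank)
        classified = classify_all(consensus, genes, class_params)
        write_tss_table([c.as_record() for c in classified], outdir / "classified_tss.tsv")
        summary = {
            cat: {"count": c, "fraction": f}
            for cat, (c, f) in classification_summary(classified).items()
        }
        completed.append(stage)

        stage = "promoters"
        promoters = extract_promoters(genome, consensus, config.promoter_window)
        write_tss_table([p.as_record() for p in promoters], outdir / "promoters.tsv")
        completed.append(stage)

        stage = "motifs"
        W = config.promoter_window
        motif_outputs = {}
        for label, prior_mean in (("minus10", W - 12), ("minus35", W - 37)):
            model = discover_motif(
                promoters,
                width=config.motif_width,
                prior_mean=prior_mean,
                prior_sd=config.prior_sd,
                n_seeds=config.n_motif_seeds,
                seed=config.seed,
            )
            cutoff = null_score_cutoff(
                model, promoters, quantile=config.null_quantile, seed=config.seed
            )
            model.as_frame().to_csv(outdir / f"motif_{label}_model.tsv", sep="\t")
            hits = [
                score_sequence(model, p)
                for p in promoters
                if not p.truncated and not p.has_n
            ]
            write_tss_table(
                [vars(h) for h in hits if h is not None],
                outdir / f"motif_{label}_hits.tsv",
            )
            with open(outdir / f"motif_{label}_cutoff.json", "w") as fh:
                json.dump(
                    {
                        "quantile": cutoff.quantile,
                        "cutoff": cutoff.cutoff,
                        "null_size": cutoff.null_size,
                        "seed": cutoff.seed,
                    },
                    fh,
                    indent=2,
                )
            write_logo_matrix(logo_counts(promoters, model), outdir / f"logo_{label}.tsv")
            passing, _failing = filter_by_score(promoters, model, cutoff)
            motif_outputs[label] = {
                "consensus": model.consensus,
                "total_ic_bits": float(model.information_content().sum()),
                "occurrence_prob": model.occurrence_prob,
                "cutoff_bits": cutoff.cutoff,
                "n_passing": len(passing),
            }
            motif_outputs[label]["_model"] = model
            motif_outputs[label]["_cutoff"] = cutoff
        rows, spacers = dual_motif_report(
            promoters,
            motif_outputs["minus10"]["_model"],
            motif_outputs["minus35"]["_model"],
            motif_outputs["minus10"]["_cutoff"],
            motif_outputs["minus35"]["_cutoff"],
        )
        pd.DataFrame(rows).to_csv(outdir / "dual_motif.tsv", sep="\t", index=False)
        for label in motif_outputs:
            motif_outputs[label].pop("_model")
            motif_outputs[label].pop("_cutoff")
        completed.append(stage)

        stage = "stats"
        plus1, minus1 = nucleotide_preferences(promoters)
        stats = {
            "n_consensus_tss": len(consensus),
            "classification": summary,
            "plus1": plus1.as_dict(),
            "minus1": minus1.as_dict(),
            "motifs": motif_outputs,
            "spacer_distribution": {str(k): v for k, v in spacers.items()},
        }
        with open(outdir / "stats.json", "w") as fh:
            json.dump(stats, fh, indent=2, sort_keys=True)
        completed.append(stage)

        stage = "compare"
        for name, path in config.references.items():
            ref_df = read_tss_table(path)
            reference = list(zip(ref_df["position"], ref_df["strand"]))
            report = match_tss_sets(consensus, reference, config.tolerance)
            hist = deviation_histogram(report) if report.matches else {}
            with open(outdir / f"comparison_{name}.json", "w") as fh:
                json.dump(
                    {
                        "tolerance": config.tolerance,
                        "n_query": report.n_query,
                        "n_matches": len(report.matches),
                        "match_fraction": report.match_fraction,
                        "deviation_histogram": {str(k): v for k, v in hist.items()},
                    },
                    fh,
                    indent=2,
                )
        completed.append(stage)
    except Exception:
        logger.error("stage %r failed", stage)
        raise

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages_completed": completed,
        "config": config.resolved(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
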