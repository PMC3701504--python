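"""End-to-end pipeline: map (or ingest) -> primer screen -> density ->
classification -> summary -> profiles -> gaps -> segments -> hybrid report.

Every stage reads and writes plain-text files so stages are independently
testable; ``run_pipeline`` orchestrates them and writes a manifest
(config echo, version, counters) that makes re-runs byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .align import ingest_sam, iter_reads, map_reads, screen_primers
from .density import (ON_ARM_CATEGORIES, calibrate_threshold,
                      classify_scaffolds, scaffold_density,
                      summarize_categories)
from .segment import (DEFAULT_MAX_DISCORDANT, DEFAULT_MIN_GAP_BP,
                      DEFAULT_MIN_REGION_BP, DEFAULT_SPARSE_CUTOFF,
                      DEFAULT_WINDOW_BP, detect_gaps, flag_hybrids,
                      segment_regions, window_profile, write_bed,
                      write_bedgraph)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of one analysis run.  Parameter defaults are
    the calibrated values used throughout the package (mismatch budget
    v=2, multiplicity m=1, 11 nt primer match, 10 kb windows, 1 hit/kb
    sparse cutoff, 100 kb minimum gap)."""

    genome_fasta: str
    reads_fastq: str | None = None
    alignments_sam: str | None = None
    priors_tsv: str | None = None
    primers_fasta: str | None = None
    output_dir: str = "dissectmap_out"
    v: int = 2
    m: int = 1
    min_match_len: int = 11
    window_bp: int = DEFAULT_WINDOW_BP
    sparse_cutoff: float = DEFAULT_SPARSE_CUTOFF
    min_gap_bp: int = DEFAULT_MIN_GAP_BP
    min_region_bp: int = DEFAULT_MIN_REGION_BP
    max_discordant: int = DEFAULT_MAX_DISCORDANT
    threshold_mode: str = "anchor-scaffold"
    anchor_id: str | None = None
    region: tuple[str, int, int] | None = None
    target_arm: str = "7p"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.reads_fastq is None) == (self.alignments_sam is None):
            raise ValueError("provide exactly one of reads_fastq or "
                             "alignments_sam")
        if self.threshold_mode == "anchor-scaffold" and not self.anchor_id:
            raise ValueError("anchor-scaffold mode requires anchor_id")
        if self.threshold_mode == "region-mean" and not self.region:
            raise ValueError("region-mean mode requires region")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        if d["region"] is not None:
            d["region"] = list(d["region"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d.update({k: v for k, v in overrides.items() if v is not None})
        if d.get("region") is not None:
            d["region"] = tuple(d["region"])
        return cls(**d)


@dataclass
class EvaluationResult:
    """Simulation-truth metrics for one run."""

    precision: float
    recall: float
    f1: float
    hybrid_sensitivity: float
    mean_breakpoint_error_bp: float
    n_true_on_arm: int = 0
    n_called_on_arm: int = 0
    n_hybrids_true: int = 0
    n_hybrids_detected: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def _read_lengths_from_fasta(path: str | Path) -> dict[str, int]:
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the output directory.

    Writes density.tsv, calls.tsv, summary.tsv, profile.bedgraph,
    gaps.bed, segments.bed, hybrids.tsv, unmapped_screen.tsv and
    manifest.yaml.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": yaml.safe_load(yaml.safe_dump(asdict(config))),
                      "version": __version__, "seed": config.seed,
                      "stages": []}
    timings: dict[str, float] = {}

    def stage(name: str):
        logger.info("stage %s", name)
        manifest["stages"].append(name)
        timings[name] = time.perf_counter()

    def done(name: str) -> None:
        logger.info("stage %s finished in %.2fs", name,
                    time.perf_counter() - timings[name])

    try:
        stage("load-genome")
        lengths = _read_lengths_from_fasta(config.genome_fasta)
        done("load-genome")

        stage("alignment")
        if config.reads_fastq:
            table = map_reads(config.reads_fastq, config.genome_fasta,
                              v=config.v, m=config.m)
        else:
            table = ingest_sam(config.alignments_sam)
        table.to_tsv(out / "hits.tsv")
        manifest["counters"] = table.counters
        done("alignment")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("alignment", exc) from exc

    try:
        stage("primer-screen")
        if config.reads_fastq and config.primers_fasta:
            mapped_ids = set(table.hits["read_id"])
            # unmapped here = not uniquely mapped (suppressed or no locus)
            unmapped = [(rid, seq) for rid, seq in
                        iter_reads(config.reads_fastq)
                        if rid not in mapped_ids]
            screen = screen_primers(unmapped, config.primers_fasta,
                                    config.min_match_len)
            pd.DataFrame([{
                "n_unmapped": screen.n_unmapped,
                "n_primer_positive": screen.n_primer_positive,
                "positive_fraction": round(screen.positive_fraction, 4),
                "min_match_len": screen.min_match_len,
                **{f"primer:{k}": v for k, v in screen.per_primer.items()},
            }]).to_csv(out / "unmapped_screen.tsv", sep="\t", index=False)
            manifest["primer_screen"] = {
                "n_unmapped": screen.n_unmapped,
                "n_primer_positive": screen.n_primer_positive,
            }
        done("primer-screen")
    except Exception as exc:
        raise StageError("primer-screen", exc) from exc

    try:
        stage("density")
        densities = scaffold_density(table, lengths)
        densities.to_csv(out / "density.tsv", sep="\t", index=False,
                         float_format="%.6g")
        if config.threshold_mode == "anchor-scaffold":
            threshold = calibrate_threshold(densities,
                                            anchor_id=config.anchor_id)
        else:
            threshold = calibrate_threshold(region=config.region, hits=table)
        manifest["threshold"] = {"mode": threshold.mode,
                                 "value": float(threshold.value),
                                 "anchor_id": threshold.anchor_id,
                                 "region": list(threshold.region)
                                 if threshold.region else None}
        priors = (pd.read_csv(config.priors_tsv, sep="\t")
                  if config.priors_tsv else None)
        calls = classify_scaffolds(densities, threshold, priors,
                                   config.target_arm)
        calls.to_csv(out / "calls.tsv", sep="\t", index=False,
                     float_format="%.6g")
        summary = summarize_categories(calls, table)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        done("density")
    except Exception as exc:
        raise StageError("density", exc) from exc

    try:
        stage("segmentation")
        profiles = [window_profile(table, sid, L, config.window_bp)
                    for sid, L in lengths.items()]
        write_bedgraph(profiles, out / "profile.bedgraph")
        gaps = pd.concat([detect_gaps(p, config.sparse_cutoff,
                                      config.min_gap_bp) for p in profiles],
                         ignore_index=True)
        write_bed(gaps.assign(name=["terminal-gap" if t else "gap"
                                    for t in gaps["terminal"]]),
                  out / "gaps.bed", "name", "mean_density_inside")
        gaps.to_csv(out / "gaps.tsv", sep="\t", index=False,
                    float_format="%.6g")
        segments = pd.concat(
            [segment_regions(p, dense_cutoff=threshold.value,
                             min_region_bp=config.min_region_bp,
                             max_discordant=config.max_discordant)
             for p in profiles], ignore_index=True)
        write_bed(segments, out / "segments.bed", "state", "mean_density")
        segments.to_csv(out / "segments.tsv", sep="\t", index=False,
                        float_format="%.6g")
        hybrids = flag_hybrids(calls, gaps)
        hybrids.to_csv(out / "hybrids.tsv", sep="\t", index=False,
                       float_format="%.6g")
        manifest["hybrids"] = {
            "n_above_threshold": hybrids.attrs["n_above_threshold"],
            "n_flagged": hybrids.attrs["n_flagged"],
            "fraction_flagged": round(hybrids.attrs["fraction_flagged"], 4),
        }
        done("segmentation")
    except Exception as exc:
        raise StageError("segmentation", exc) from exc

    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest,
                                                      sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# Truth evaluation (simulation-backed runs)
# ---------------------------------------------------------------------------

def evaluate_against_truth(calls: pd.DataFrame, true_labels: Mapping[str, str],
                           gaps: pd.DataFrame | None = None,
                           hybrid_truth: Mapping | None = None,
                           ) -> EvaluationResult:
    """Compare scaffold calls and gap calls to simulation truth.

    A scaffold is *predicted on-arm* iff its category is one of
    ``ON_ARM_CATEGORIES``; truth on-arm is the "on-arm" label (hybrid
    scaffolds are excluded from the precision/recall universe since they
    are partially on-arm by construction).  A hybrid join is *detected*
    iff any reported gap overlaps its true off-arm interval; the
    breakpoint error is the distance between the true breakpoint and the
    nearest edge of an overlapping gap.
    """
    unknown = set(calls["scaffold"]) - set(true_labels)
    if unknown:
        raise KeyError(f"calls for scaffolds without truth: {sorted(unknown)}")
    tp = fp = fn = 0
    for row in calls.itertuples(index=False):
        truth = true_labels[row.scaffold]
        if truth == "hybrid":
            continue
        pred_on = row.category in ON_ARM_CATEGORIES
        if pred_on and truth == "on-arm":
            tp += 1
        elif pred_on:
            fp += 1
        elif truth == "on-arm":
            fn += 1
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)

    n_hyb = len(hybrid_truth) if hybrid_truth else 0
    detected = 0
    bp_errors: list[float] = []
    if hybrid_truth:
        for sid, ht in hybrid_truth.items():
            a, b = ht.off_arm_interval
            best: float | None = None
            if gaps is not None and len(gaps):
                for g in gaps[gaps["scaffold"] == sid].itertuples(index=False):
                    if g.start0 < b and g.end0 > a:  # overlap
                        edge = g.start0 if a > 0 else g.end0
                        err = abs(edge - ht.breakpoint)
                        best = err if best is None else min(best, err)
            if best is not None:
                detected += 1
                bp_errors.append(best)
    return EvaluationResult(
        precision=precision,
        recall=recall,
        f1=f1,
        hybrid_sensitivity=detected / n_hyb if n_hyb else 0.0,
        mean_breakpoint_error_bp=(sum(bp_errors) / len(bp_errors)
                                  if bp_errors else 0.0),
        n_true_on_arm=tp + fn,
        n_called_on_arm=tp + fp,
        n_hybrids_true=n_hyb,
        n_hybrids_detected=detected,
    )


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def render_report(output_dir: str | Path, top_n: int = 10) -> str:
    """Aligned-text summary of an output directory.  Every number shown is
    read from the stage TSVs; nothing is recomputed here."""
    out = Path(output_dir)
    summary = pd.read_csv(out / "summary.tsv", sep="\t")
    calls = pd.read_csv(out / "calls.tsv", sep="\t")
    lines = ["Unique-hit category summary", "=" * 60]
    for row in summary.itertuples(index=False):
        lines.append(f"{row.category:<24s} {row.unique_hits:>12,d} "
                     f"{row.percent:>8.2f}%")
    lines.append("")
    newly = calls[calls["category"] == "newly-assigned"].sort_values(
        "hits_per_kb", ascending=False).head(top_n)
    lines.append(f"Top {top_n} densest newly-assigned scaffolds")
    lines.append("-" * 60)
    if newly.empty:
        lines.append("zero newly-assigned scaffolds")
    else:
        for row in newly.itertuples(index=False):
            lines.append(f"{row.scaffold:<24s} {row.hits_per_kb:>10.2f} "
                         f"hits/kb  ({row.length_bp:,d} bp)")
    hybrids_path = out / "hybrids.tsv"
    if hybrids_path.exists():
        hybrids = pd.read_csv(hybrids_path, sep="\t")
        lines.append("")
        lines.append(f"Hybrid-candidate gaps: {len(hybrids)}")
        for row in hybrids.itertuples(index=False):
            lines.append(f"  {row.scaffold}:{row.start0}-{row.end0} "
                         f"({row.span_bp:,d} bp)")
    return "\n".join(lines) + "\n"


def plot_profile(output_dir: str | Path, scaffold: str, path: str | Path,
                 ) -> None:
    """Optional coverage plot with gap/segment overlays (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(output_dir)
    prof = pd.read_csv(out / "profile.bedgraph", sep="\t",
                       names=["scaffold", "start0", "end0", "density"])
    prof = prof[prof["scaffold"] == scaffold]
    gaps = pd.read_csv(out / "gaps.tsv", sep="\t")
    gaps = gaps[gaps["scaffold"] == scaffold]
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.step(prof["start0"] / 1e6, prof["density"], where="post", lw=0.8)
    for g in gaps.itertuples(index=False):
        ax.axvspan(g.start0 / 1e6, g.end0 / 1e6, color="red", alpha=0.2)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("unique hits/kb")
    ax.set_title(scaffold)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
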