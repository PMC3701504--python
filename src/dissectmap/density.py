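"""Per-scaffold unique-hit density, threshold calibration, classification.

The central statistic is hits/kb: the number of uniquely-mapping reads
whose start falls on a scaffold, divided by the scaffold length in
kilobases (full length, N runs included).  An on-arm density threshold is
calibrated either from an *anchor* scaffold of known physical location
(e.g. a scaffold FISH-placed just under the centromere) or as the mean
density of a trusted region, and scaffolds are classified against the
threshold and their prior map placements:

========================  ==================  ======================
density vs threshold      prior placement     category
========================  ==================  ======================
above (inclusive)         target arm          confirmed-on-arm
above                     unmapped            newly-assigned
above                     other location      reassignment-candidate
below                     target arm          prior-conflict
below                     anything else       under-threshold
========================  ==================  ======================

The comparison is inclusive (>=) because the anchor scaffold itself is
physically on the arm and must pass its own threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .align import UniqueHitTable

logger = logging.getLogger(__name__)

CATEGORIES = ["confirmed-on-arm", "newly-assigned", "reassignment-candidate",
              "prior-conflict", "under-threshold"]

#: categories whose scaffolds the pipeline treats as assigned to the arm
ON_ARM_CATEGORIES = ["confirmed-on-arm", "newly-assigned",
                     "reassignment-candidate"]


@dataclass(frozen=True)
class ThresholdSpec:
    """Calibrated hits/kb threshold.

    mode "anchor-scaffold": value is the density of a scaffold of known
    physical location.  mode "region-mean": value is total unique hits in
    a genomic region divided by region length in kb.
    """

    mode: str
    value: float
    anchor_id: str | None = None
    region: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("anchor-scaffold", "region-mean"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if not self.value > 0:
            raise ValueError("threshold value must be positive")


def scaffold_density(hits: UniqueHitTable | pd.DataFrame,
                     scaffold_lengths: Mapping[str, int]) -> pd.DataFrame:
    """One row per scaffold (zero-hit scaffolds included) with columns
    ``scaffold, length_bp, unique_hits, hits_per_kb``."""
    table = hits.hits if isinstance(hits, UniqueHitTable) else hits
    counts = table["scaffold"].value_counts()
    unknown = set(counts.index) - set(scaffold_lengths)
    if unknown:
        raise KeyError(f"hits on scaffolds with no length: {sorted(unknown)}")
    df = pd.DataFrame({
        "scaffold": list(scaffold_lengths),
        "length_bp": [scaffold_lengths[s] for s in scaffold_lengths],
    })
    df["unique_hits"] = [int(counts.get(s, 0)) for s in df["scaffold"]]
    df["hits_per_kb"] = df["unique_hits"] / (df["length_bp"] / 1000.0)
    return df


def calibrate_threshold(densities: pd.DataFrame | None = None,
                        anchor_id: str | None = None,
                        region: tuple[str, int, int] | None = None,
                        hits: UniqueHitTable | pd.DataFrame | None = None,
                        ) -> ThresholdSpec:
    """Calibrate the on-arm threshold.

    Anchor mode (``anchor_id``): the threshold is the anchor scaffold's
    hits/kb.  Region mode (``region=(scaffold, start0, end0)``): the
    threshold is the mean density of the region, computed from the hit
    table (hits whose start lies in [start0, end0)).
    """
    if (anchor_id is None) == (region is None):
        raise ValueError("provide exactly one of anchor_id or region")
    if anchor_id is not None:
        if densities is None:
            raise ValueError("anchor mode needs the density table")
        row = densities.loc[densities["scaffold"] == anchor_id]
        if row.empty:
            raise KeyError(f"anchor scaffold {anchor_id!r} not in densities")
        value = float(row["hits_per_kb"].iloc[0])
        if value <= 0:
            raise ValueError(
                f"anchor scaffold {anchor_id!r} has zero density "
                "(uninformative anchor)")
        return ThresholdSpec("anchor-scaffold", value, anchor_id=anchor_id)
    scaffold, start, end = region
    if not end > start:
        raise ValueError("empty region")
    if hits is None:
        raise ValueError("region mode needs the hit table")
    table = hits.hits if isinstance(hits, UniqueHitTable) else hits
    sel = table[(table["scaffold"] == scaffold)
                & (table["pos0"] >= start) & (table["pos0"] < end)]
    value = len(sel) / ((end - start) / 1000.0)
    if value <= 0:
        raise ValueError("region contains no hits (uninformative region)")
    return ThresholdSpec("region-mean", value, region=region)


def classify_scaffolds(densities: pd.DataFrame, threshold: ThresholdSpec,
                       priors: pd.DataFrame | None, target_arm: str,
                       ) -> pd.DataFrame:
    """Apply the decision table; returns the density table plus columns
    ``above_threshold, prior, category``.

    ``priors`` has columns ``scaffold, assigned_location`` and optionally
    ``source`` (with both "physical" and "meiotic" placements, the
    physical one wins).  Scaffolds without a prior are treated as
    "unmapped" and logged.
    """
    prior_map: dict[str, str] = {}
    if priors is not None and len(priors):
        ordered = priors
        if "source" in priors.columns:
            rank = priors["source"].map({"physical": 0, "meiotic": 1}).fillna(2)
            ordered = priors.assign(_rank=rank).sort_values(
                ["scaffold", "_rank"], kind="stable")
        for row in ordered.itertuples(index=False):
            prior_map.setdefault(row.scaffold, row.assigned_location)
    missing = [s for s in densities["scaffold"] if s not in prior_map]
    if missing and priors is not None:
        logger.info("%d scaffolds without prior placement treated as "
                    "unmapped", len(missing))

    out = densities.copy()
    out["above_threshold"] = out["hits_per_kb"] >= threshold.value
    out["prior"] = [prior_map.get(s, "unmapped") for s in out["scaffold"]]

    def category(above: bool, prior: str) -> str:
        if above:
            if prior == target_arm:
                return "confirmed-on-arm"
            if prior == "unmapped":
                return "newly-assigned"
            return "reassignment-candidate"
        return "prior-conflict" if prior == target_arm else "under-threshold"

    out["category"] = [category(a, p) for a, p in
                       zip(out["above_threshold"], out["prior"])]
    return out


def category_percentages(parts: Mapping[str, int], total: int | None = None,
                         residual_name: str = "remainder") -> pd.DataFrame:
    """Worked-table arithmetic: per-part percentage of the total, rounded
    to two decimals, with a residual row guaranteeing exact conservation
    of counts."""
    part_sum = sum(parts.values())
    if total is None:
        total = part_sum
    if part_sum > total:
        raise ValueError("parts exceed the stated total")
    rows = [{"category": k, "unique_hits": int(v),
             "percent": round(100.0 * v / total, 2)}
            for k, v in parts.items()]
    residual = total - part_sum
    if residual:
        rows.append({"category": residual_name, "unique_hits": int(residual),
                     "percent": round(100.0 * residual / total, 2)})
    rows.append({"category": "total", "unique_hits": int(total),
                 "percent": 100.0})
    return pd.DataFrame(rows)


def summarize_categories(calls: pd.DataFrame,
                         hits: UniqueHitTable | int | None = None,
                         ) -> pd.DataFrame:
    """Category accounting: unique hits per classification category and
    percentage of all unique hits (two decimals), with a residual row if
    some hits fall on scaffolds absent from the calls."""
    per_cat = calls.groupby("category")["unique_hits"].sum().to_dict()
    parts = {c: int(per_cat.get(c, 0)) for c in CATEGORIES}
    if hits is None:
        total = sum(parts.values())
    elif isinstance(hits, int):
        total = hits
    else:
        total = hits.mapped_unique
    return category_percentages(parts, total=total,
                                residual_name="unclassified")
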