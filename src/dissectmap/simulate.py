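"""Synthetic microdissected-chromosome-arm sequencing experiment.

Generates a multi-scaffold genome with known truth and a single-end read
set that mimics the statistical structure of sequencing a laser-dissected
chromosome arm after whole-genome amplification (WGA):

* most reads originate from a designated "on-arm" subset of scaffolds,
  with a small off-arm contamination fraction;
* WGA is modelled as a pool of fragment start positions with lognormal
  amplification weights, so duplicate reads share a start coordinate;
* read density tapers linearly to zero inside a window at the dissection
  boundary (the laser-cut path), placed at the end of one designated
  on-arm "border" scaffold;
* a configurable fraction of reads are primer chimeras whose 5' or 3'
  end is replaced by an exact primer substring;
* per-base substitution errors;
* repeat families copied verbatim into several scaffolds (both labels)
  to induce multi-mapping;
* optional hybrid scaffolds concatenating an on-arm and an off-arm
  segment with a recorded breakpoint, emulating misassembled joins.

Everything is driven by one integer seed; identical configs produce
byte-identical FASTA/FASTQ/TSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .align import codes_to_seq, revcomp_codes, seq_to_codes

# Minimum coverage-gap span the downstream detector reports; hybrid segments
# must be at least this long to be detectable at all.
GAP_DETECTION_MIN_BP = 100_000

# Default primers available for chimera implantation and screening: the
# public Nextera transposase motif plus a synthetic stand-in for a
# proprietary WGA adapter (arbitrary fixed sequence, not a real adapter).
DEFAULT_PRIMERS: list[tuple[str, str]] = [
    ("nextera_transposase", "CTGTCTCTTATACACATCTCCGAGCCCACGAGAC"),
    ("wga_adapter_synthetic", "GTGGTAACCGTCAGATGTGTATAAGAGACAGCC"),
]


@dataclass
class SimulationConfig:
    """Knobs of the simulated experiment.  Defaults are desk-scale study
    conditions: 60 scaffolds of 50-300 kb, 200k 80 bp reads, 5% off-arm
    contamination."""

    seed: int = 0
    n_scaffolds: int = 60
    scaffold_length_range: tuple[int, int] = (50_000, 300_000)
    arm_fraction: float = 0.4
    read_length: int = 80
    n_reads: int = 200_000
    contamination_rate: float = 0.05
    error_rate: float = 0.005
    wga_lognormal_sigma: float = 1.0
    primer_chimera_rate: float = 0.05
    min_primer_insert: int = 11
    repeat_family_count: int = 5
    repeat_copy_number: int = 20
    repeat_unit_length: int = 200
    n_hybrid_scaffolds: int = 0
    hybrid_segment_min: int = 200_000
    boundary_taper_width: int = 100_000

    def validate(self) -> None:
        for name in ("arm_fraction", "contamination_rate", "error_rate",
                     "primer_chimera_rate"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} not in [0, 1]")
        if self.read_length < self.min_primer_insert:
            raise ValueError("read_length must be >= min_primer_insert")
        if self.n_scaffolds < 1 or self.n_reads < 1:
            raise ValueError("need at least one scaffold and one read")
        lo, hi = self.scaffold_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid scaffold_length_range")
        if lo < self.read_length:
            raise ValueError("scaffolds must be at least one read long")
        if self.n_hybrid_scaffolds:
            if self.hybrid_segment_min < GAP_DETECTION_MIN_BP:
                raise ValueError(
                    "hybrid_segment_min below the gap-detection minimum "
                    f"({GAP_DETECTION_MIN_BP} bp); implanted joins would be "
                    "undetectable")
            if 2 * self.hybrid_segment_min > hi:
                raise ValueError(
                    "hybrid segments cannot fit: scaffold_length_range max "
                    f"{hi} < 2*hybrid_segment_min {2 * self.hybrid_segment_min}")
        if self.wga_lognormal_sigma < 0 or self.boundary_taper_width < 0:
            raise ValueError("dispersion/taper parameters must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["scaffold_length_range"] = list(self.scaffold_length_range)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["scaffold_length_range"] = tuple(d["scaffold_length_range"])
        return cls(**d)


@dataclass(frozen=True)
class Scaffold:
    id: str
    sequence: str
    true_label: str  # "on-arm" | "off-arm" | "hybrid"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HybridTruth:
    """Breakpoint of a misassembled (hybrid) scaffold: positions
    [0, breakpoint) carry left_label, [breakpoint, length) right_label."""

    scaffold: str
    breakpoint: int
    left_label: str
    right_label: str
    length: int

    @property
    def off_arm_interval(self) -> tuple[int, int]:
        if self.left_label == "off-arm":
            return (0, self.breakpoint)
        return (self.breakpoint, self.length)


@dataclass
class GenomeModel:
    """Simulated genome with truth annotations."""

    scaffolds: list[Scaffold]
    repeat_annotations: dict[str, list[tuple[int, int]]]
    hybrid_truth: dict[str, HybridTruth]
    border_scaffold: str  # on-arm scaffold carrying the laser-cut boundary
    boundary_pos: int     # boundary coordinate on that scaffold (its end)
    config: SimulationConfig = field(repr=False, default=None)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.scaffolds]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate scaffold ids")
        for ht in self.hybrid_truth.values():
            if not 0 < ht.breakpoint < ht.length:
                raise ValueError(f"breakpoint outside {ht.scaffold}")
        for sid, ivs in self.repeat_annotations.items():
            L = self.lengths()[sid]
            for s, e in ivs:
                if not 0 <= s < e <= L:
                    raise ValueError(f"repeat interval outside {sid}")

    def scaffold_sequences(self) -> Iterator[tuple[str, str]]:
        for s in self.scaffolds:
            yield s.id, s.sequence

    def lengths(self) -> dict[str, int]:
        return {s.id: len(s) for s in self.scaffolds}

    def labels(self) -> dict[str, str]:
        return {s.id: s.true_label for s in self.scaffolds}

    def ids_with_label(self, label: str) -> list[str]:
        return [s.id for s in self.scaffolds if s.true_label == label]

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for s in self.scaffolds:
                fh.write(f">{s.id}\n")
                for i in range(0, len(s.sequence), width):
                    fh.write(s.sequence[i:i + width] + "\n")

    def write_hybrid_bed(self, path: str | Path) -> None:
        """Off-arm segment of each hybrid scaffold as 0-based half-open BED."""
        with open(path, "w") as fh:
            for ht in self.hybrid_truth.values():
                a, b = ht.off_arm_interval
                fh.write(f"{ht.scaffold}\t{a}\t{b}\toff-arm-segment\n")


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def build_genome(config: SimulationConfig) -> GenomeModel:
    """Sample a labelled scaffold universe.

    Non-repeat sequence is i.i.d. uniform ACGT.  Repeat families are fixed
    units copied verbatim into randomly chosen scaffolds of both labels.
    Hybrid scaffolds concatenate an on-arm and an off-arm segment (order
    randomised), each at least ``hybrid_segment_min`` long.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.scaffold_length_range

    n = config.n_scaffolds
    n_hybrid = config.n_hybrid_scaffolds
    if n_hybrid >= n:
        raise ValueError("n_hybrid_scaffolds must be < n_scaffolds")
    n_on = max(1, round(config.arm_fraction * (n - n_hybrid)))

    labels = (["on-arm"] * n_on
              + ["off-arm"] * (n - n_hybrid - n_on)
              + ["hybrid"] * n_hybrid)
    rng.shuffle(labels)

    scaffolds: list[Scaffold] = []
    hybrid_truth: dict[str, HybridTruth] = {}
    for i, label in enumerate(labels):
        sid = f"scaffold_{i:03d}"
        if label == "hybrid":
            length = int(rng.integers(max(lo, 2 * config.hybrid_segment_min),
                                      hi + 1))
            bp = int(rng.integers(config.hybrid_segment_min,
                                  length - config.hybrid_segment_min + 1))
            left, right = (("on-arm", "off-arm") if rng.random() < 0.5
                           else ("off-arm", "on-arm"))
            hybrid_truth[sid] = HybridTruth(sid, bp, left, right, length)
        else:
            length = int(rng.integers(lo, hi + 1))
        seq = codes_to_seq(rng.integers(0, 4, length).astype(np.uint8))
        scaffolds.append(Scaffold(sid, seq, label))

    # implant repeat families (verbatim copies across scaffolds)
    repeat_annotations: dict[str, list[tuple[int, int]]] = {
        s.id: [] for s in scaffolds}
    unit_len = config.repeat_unit_length
    seq_arrays = {s.id: bytearray(s.sequence, "ascii") for s in scaffolds}
    for _fam in range(config.repeat_family_count):
        unit = codes_to_seq(rng.integers(0, 4, unit_len).astype(np.uint8))
        for _copy in range(config.repeat_copy_number):
            target = scaffolds[int(rng.integers(0, n))]
            L = len(target)
            if L <= unit_len:
                continue
            pos = int(rng.integers(0, L - unit_len + 1))
            seq_arrays[target.id][pos:pos + unit_len] = unit.encode("ascii")
            repeat_annotations[target.id].append((pos, pos + unit_len))
    scaffolds = [Scaffold(s.id, seq_arrays[s.id].decode("ascii"), s.true_label)
                 for s in scaffolds]
    for sid in repeat_annotations:
        repeat_annotations[sid].sort()

    on_arm = [s for s in scaffolds if s.true_label == "on-arm"]
    if not on_arm:
        raise ValueError("no on-arm scaffold generated")
    # the border scaffold sits inside the laser-cut decline zone; designate
    # the shortest on-arm scaffold so the taper depresses its whole length,
    # mirroring the depressed density of a real boundary anchor
    border_scaffold = min(on_arm, key=len)
    border = border_scaffold.id
    boundary_pos = len(border_scaffold)
    return GenomeModel(scaffolds, repeat_annotations, hybrid_truth,
                       border, boundary_pos, config)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["read_id", "scaffold", "pos0", "origin_label",
                 "is_chimera", "is_contaminant"]


def _eligible_intervals(model: GenomeModel, which: str,
                        read_length: int) -> list[tuple[str, int, int]]:
    """Start-position intervals (scaffold, lo, hi exclusive) for read
    sampling.  On-arm sources include the on-arm segment of hybrids; the
    off-arm (contaminant) source is off-arm scaffolds only."""
    out = []
    for s in model.scaffolds:
        if which == "on":
            if s.true_label == "on-arm":
                out.append((s.id, 0, len(s) - read_length + 1))
            elif s.true_label == "hybrid":
                ht = model.hybrid_truth[s.id]
                a, b = ((0, ht.breakpoint) if ht.left_label == "on-arm"
                        else (ht.breakpoint, ht.length))
                if b - a >= read_length:
                    out.append((s.id, a, b - read_length + 1))
        elif which == "off" and s.true_label == "off-arm":
            out.append((s.id, 0, len(s) - read_length + 1))
    return out


def _taper_weight(pos: np.ndarray, boundary: int, width: int) -> np.ndarray:
    """Linear decline of sampling weight to 0 at the boundary coordinate."""
    if width <= 0:
        return np.ones_like(pos, dtype=float)
    dist = boundary - pos
    w = np.clip(dist / width, 0.0, 1.0)
    return w


def _sample_fragment_positions(model: GenomeModel, intervals, n_frag: int,
                               rng: np.random.Generator,
                               apply_taper: bool) -> tuple[np.ndarray, np.ndarray]:
    """Sample fragment (scaffold_index, start) pairs proportional to the
    taper-adjusted mass of each interval, via rejection inside the border
    scaffold."""
    cfg = model.config
    masses = []
    for sid, a, b in intervals:
        if apply_taper and sid == model.border_scaffold:
            pos = np.arange(a, b)
            masses.append(float(_taper_weight(pos, model.boundary_pos,
                                              cfg.boundary_taper_width).sum()))
        else:
            masses.append(float(b - a))
    p = np.asarray(masses) / np.sum(masses)
    which = rng.choice(len(intervals), size=n_frag, p=p)
    starts = np.empty(n_frag, dtype=np.int64)
    for i, (sid, a, b) in enumerate(intervals):
        mask = which == i
        k = int(mask.sum())
        if k == 0:
            continue
        if apply_taper and sid == model.border_scaffold:
            got = np.empty(0, dtype=np.int64)
            while len(got) < k:
                prop = rng.integers(a, b, size=2 * k)
                acc = rng.random(2 * k) < _taper_weight(
                    prop, model.boundary_pos, cfg.boundary_taper_width)
                got = np.concatenate([got, prop[acc]])
            starts[mask] = got[:k]
        else:
            starts[mask] = rng.integers(a, b, size=k)
    return which, starts


def simulate_reads(model: GenomeModel, config: SimulationConfig | None = None,
                   primers: list[tuple[str, str]] | None = None,
                   ) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw the read set and its truth table.

    Returns ``(reads, truth)`` where reads is a list of (read_id, sequence)
    and truth is a DataFrame with one row per read (columns
    ``read_id, scaffold, pos0, origin_label, is_chimera, is_contaminant``).
    ``pos0`` is always the forward-strand 0-based start, regardless of the
    sequenced strand.
    """
    cfg = config or model.config
    cfg.validate()
    if primers is None:
        primers = DEFAULT_PRIMERS
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    rl = cfg.read_length
    n = cfg.n_reads

    on_iv = _eligible_intervals(model, "on", rl)
    if not on_iv:
        raise ValueError("no on-arm scaffold can source reads")
    off_iv = _eligible_intervals(model, "off", rl)

    is_contaminant = rng.random(n) < cfg.contamination_rate
    if is_contaminant.any() and not off_iv:
        raise ValueError("contamination requested but no off-arm scaffold")

    # WGA fragment pools: positions with lognormal amplification weights;
    # reads resample fragments, so duplicates share a start coordinate.
    frag_scaf = np.empty(n, dtype=np.int64)
    frag_start = np.empty(n, dtype=np.int64)
    interval_names: list[str] = []
    for source, iv, taper in (("on", on_iv, True), ("off", off_iv, False)):
        mask = ~is_contaminant if source == "on" else is_contaminant
        k = int(mask.sum())
        if k == 0 or not iv:
            continue
        n_frag = max(1, k)
        w_scaf, w_start = _sample_fragment_positions(model, iv, n_frag, rng,
                                                     apply_taper=taper)
        weights = rng.lognormal(0.0, cfg.wga_lognormal_sigma, n_frag)
        pick = rng.choice(n_frag, size=k, p=weights / weights.sum())
        base = len(interval_names)
        frag_scaf[mask] = base + w_scaf[pick]
        frag_start[mask] = w_start[pick]
        interval_names.extend(sid for sid, _a, _b in iv)
    name_arr = np.array(interval_names, dtype=object)

    # pull sequences from the genome
    seqs = {s.id: seq_to_codes(s.sequence) for s in model.scaffolds}
    reads_mat = np.empty((n, rl), dtype=np.uint8)
    for i in range(n):
        sid = name_arr[frag_scaf[i]]
        reads_mat[i] = seqs[sid][frag_start[i]:frag_start[i] + rl]

    # substitution errors (uniform among the 3 other bases)
    err = rng.random((n, rl)) < cfg.error_rate
    shift = rng.integers(1, 4, size=(n, rl)).astype(np.uint8)
    reads_mat = np.where(err, (reads_mat + shift) % 4, reads_mat)

    # primer chimeras: replace a read end with an exact primer substring
    is_chimera = rng.random(n) < cfg.primer_chimera_rate
    chim_idx = np.flatnonzero(is_chimera)
    max_insert = min(rl - 1, max(len(p[1]) for p in primers))
    for i in chim_idx:
        pname, pseq = primers[int(rng.integers(0, len(primers)))]
        ins = int(rng.integers(cfg.min_primer_insert,
                               min(max_insert, len(pseq)) + 1))
        pcodes = seq_to_codes(pseq)
        if rng.random() < 0.5:  # prefix <- primer 3' end
            reads_mat[i, :ins] = pcodes[-ins:]
        else:                   # suffix <- primer 5' start
            reads_mat[i, rl - ins:] = pcodes[:ins]

    # sequencing strand (truth keeps the forward start coordinate)
    flip = rng.random(n) < 0.5
    reads_mat[flip] = revcomp_codes(reads_mat[flip])

    ids = [f"read{i:07d}" for i in range(n)]
    reads = [(ids[i], codes_to_seq(reads_mat[i])) for i in range(n)]
    labels = model.labels()
    truth = pd.DataFrame({
        "read_id": ids,
        "scaffold": name_arr[frag_scaf],
        "pos0": frag_start,
        "origin_label": [labels[s] for s in name_arr[frag_scaf]],
        "is_chimera": is_chimera,
        "is_contaminant": is_contaminant,
    })
    return reads, truth


def truth_expected_density(model: GenomeModel, truth: pd.DataFrame,
                           read_length: int | None = None) -> pd.DataFrame:
    """Oracle hits/kb per scaffold from true read origins (contaminants and
    chimeras counted at their true origin).  ``read_length`` is accepted for
    interface symmetry; origins are point coordinates so it does not enter
    the density."""
    lengths = model.lengths()
    counts = truth["scaffold"].value_counts()
    rows = [{
        "scaffold": sid,
        "length_bp": L,
        "true_reads": int(counts.get(sid, 0)),
        "hits_per_kb": float(counts.get(sid, 0)) / (L / 1000.0),
    } for sid, L in lengths.items()]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Emulated prior placements (meiotic / physical map stand-in)
# ---------------------------------------------------------------------------

def make_prior_placements(model: GenomeModel, target_arm: str = "7p",
                          mapped_fraction: float = 0.8,
                          misplaced_fraction: float = 0.05,
                          seed: int = 0) -> pd.DataFrame:
    """Emulate a linkage/physical map: most scaffolds carry a prior arm
    label, some are unmapped, and a small fraction of on-arm scaffolds are
    misplaced onto another arm (the reassignment-candidate situation)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    other_arms = ["7q", "8q", "3p"]
    rows = []
    for s in model.scaffolds:
        r = rng.random()
        if r > mapped_fraction:
            loc = "unmapped"
        elif s.true_label == "on-arm" or (
                s.true_label == "hybrid"
                and model.hybrid_truth[s.id].left_label == "on-arm"):
            loc = (other_arms[int(rng.integers(0, len(other_arms)))]
                   if rng.random() < misplaced_fraction else target_arm)
        else:
            loc = other_arms[int(rng.integers(0, len(other_arms)))]
        rows.append({"scaffold": s.id, "assigned_location": loc,
                     "source": "meiotic"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    """Phred-33 FASTQ with constant quality 'I' (Q40)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_tsv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_priors_tsv(priors: pd.DataFrame, path: str | Path) -> None:
    priors.to_csv(path, sep="\t", index=False)


def write_primers_fasta(primers: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in primers:
            fh.write(f">{name}\n{seq}\n")
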