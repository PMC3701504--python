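"""Uniqueness-filtered short-read mapping.

Implements the mapping contract used for microdissected-chromosome read
analysis: a read is *reported* only if it aligns to exactly one genomic
location with at most ``v`` mismatches (multiplicity filter ``m=1``,
mismatch budget ``v=2`` by default — for 80 bp reads this is an identity
floor of (80-2)/80 = 97.5%).  Uniqueness is decided by multiplicity, not by
best-hit: a read with two equally good or unequally good locations within
the mismatch budget is suppressed entirely.

Three routes produce the same ``UniqueHitTable``:

* :func:`map_reads` — the production mapper, built on a pigeonhole seed
  index (split each read into ``v+1`` segments; under ≤v mismatches at
  least one segment matches the genome exactly).
* :func:`enumerate_alignments` + :func:`unique_filter` — an exhaustive
  scan of every genomic position on both strands; the independent oracle
  for small instances.
* :func:`ingest_sam` — accepts output of an external aligner.

Unmapped reads can be screened for amplification/sequencing primer
carry-over with :func:`screen_primers`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

# Base encoding: A,C,G,T -> 0..3; N -> 4 (mismatches everything, including
# another N); inter-scaffold padding -> 5.  Complement of code c<4 is 3-c.
_CODE_N = 4
_CODE_PAD = 5
_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_CODE[ord(_b)] = _i
    _BASE_TO_CODE[ord(_b.lower())] = _i
_BASE_TO_CODE[ord("N")] = _CODE_N
_BASE_TO_CODE[ord("n")] = _CODE_N
_CODE_TO_BASE = np.frombuffer(b"ACGTN-", dtype=np.uint8)

# Seed k-mers are packed 2 bits/base into uint64; cap length so 4**k fits.
_MAX_SEED_LEN = 31


class ReadFormatError(ValueError):
    """A read contains characters outside the ACGTN alphabet."""


class SAMFormatError(ValueError):
    """A SAM record could not be parsed."""


def seq_to_codes(seq: str) -> np.ndarray:
    codes = _BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) == 255:
        bad = chr(np.frombuffer(seq.encode(), dtype=np.uint8)[codes == 255][0])
        raise ReadFormatError(f"non-ACGTN character {bad!r} in sequence")
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    rc = np.where(codes < 4, 3 - codes, codes)
    return rc[::-1] if rc.ndim == 1 else rc[:, ::-1]


def revcomp(seq: str) -> str:
    return codes_to_seq(revcomp_codes(seq_to_codes(seq)))


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentHit:
    """One gapless alignment of a read; pos0 is the leftmost aligned base
    on forward scaffold coordinates for either strand."""

    read_id: str
    scaffold: str
    pos0: int
    strand: str  # "+" or "-"
    mismatches: int


HIT_COLUMNS = ["read_id", "scaffold", "pos0", "strand", "mismatches"]


@dataclass
class UniqueHitTable:
    """Per-read unique alignments plus the mapping counters.

    ``hits`` has one row per *kept* read (columns ``read_id, scaffold,
    pos0, strand, mismatches``).  Counters satisfy
    ``mapped_unique + suppressed_multi = mapped_any`` and
    ``mapped_any + unmapped = total_reads``.
    """

    hits: pd.DataFrame
    total_reads: int
    mapped_any: int
    mapped_unique: int
    suppressed_multi: int
    unmapped: int
    read_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mapped_unique + self.suppressed_multi != self.mapped_any:
            raise ValueError("counter invariant broken: unique + multi != any")
        if self.mapped_any + self.unmapped != self.total_reads:
            raise ValueError("counter invariant broken: any + unmapped != total")
        if len(self.hits) != self.mapped_unique:
            raise ValueError("hit rows != mapped_unique")

    @property
    def counters(self) -> dict[str, int]:
        return {
            "total_reads": self.total_reads,
            "mapped_any": self.mapped_any,
            "mapped_unique": self.mapped_unique,
            "suppressed_multi": self.suppressed_multi,
            "unmapped": self.unmapped,
        }

    def to_tsv(self, path: str | Path) -> None:
        self.hits.to_csv(path, sep="\t", index=False)

    def to_sam(self, path: str | Path, scaffold_lengths: Mapping[str, int],
               read_seqs: Mapping[str, str] | None = None) -> None:
        """Write kept hits as minimal single-end SAM (CIGAR <len>M, NM tag)."""
        default_len = next(iter(self.read_lengths.values()), 0)
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unknown\n")
            for name, length in scaffold_lengths.items():
                fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
            for row in self.hits.itertuples(index=False):
                rl = self.read_lengths.get(row.read_id, default_len)
                seq = read_seqs.get(row.read_id, "*") if read_seqs else "*"
                if seq != "*" and row.strand == "-":
                    seq = revcomp(seq)
                flag = 16 if row.strand == "-" else 0
                fh.write(
                    f"{row.read_id}\t{flag}\t{row.scaffold}\t{row.pos0 + 1}"
                    f"\t255\t{rl}M\t*\t0\t0\t{seq}\t*\tNM:i:{row.mismatches}\n"
                )


@dataclass
class PrimerScreenResult:
    """Outcome of the exact-substring primer screen on unmapped reads."""

    n_unmapped: int
    n_primer_positive: int
    min_match_len: int
    per_primer: dict[str, int]

    @property
    def positive_fraction(self) -> float:
        return self.n_primer_positive / self.n_unmapped if self.n_unmapped else 0.0


# ---------------------------------------------------------------------------
# Input adapters
# ---------------------------------------------------------------------------

def _load_genome(genome) -> dict[str, str]:
    """Accept a FASTA path, a mapping name->sequence, or an object exposing
    ``scaffold_sequences()`` (the synthetic GenomeModel)."""
    if hasattr(genome, "scaffold_sequences"):
        return dict(genome.scaffold_sequences())
    if isinstance(genome, Mapping):
        return dict(genome)
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome), "fasta")}


def iter_reads(reads) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ path or an iterable of pairs."""
    if isinstance(reads, (str, Path)):
        with open(reads) as fh:
            for title, seq, _qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq
    else:
        for item in reads:
            yield item[0], item[1]


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def enumerate_alignments(read: str, genome, v: int = 2,
                         read_id: str = "read") -> list[AlignmentHit]:
    """Exhaustively align one read against every position on both strands.

    Counts Hamming mismatches of the forward or reverse-complemented read
    at every genomic offset; any comparison against N counts as a mismatch.
    Intended as the small-scale oracle (quadratic in genome size).
    """
    seqs = _load_genome(genome)
    rcodes = seq_to_codes(read)
    L = len(rcodes)
    queries = (("+", rcodes), ("-", revcomp_codes(rcodes)))
    hits: list[AlignmentHit] = []
    for name, seq in seqs.items():
        g = seq_to_codes(seq)
        if len(g) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(g, L)
        g_is_n = windows >= _CODE_N
        for strand, q in queries:
            mism = ((windows != q) | g_is_n | (q >= _CODE_N)).sum(axis=1)
            for pos in np.flatnonzero(mism <= v):
                hits.append(AlignmentHit(read_id, name, int(pos), strand,
                                         int(mism[pos])))
    hits.sort(key=lambda h: (h.scaffold, h.pos0, h.strand))
    return hits


def unique_filter(hits: Sequence[AlignmentHit], m: int = 1) -> AlignmentHit | None:
    """Multiplicity filter: suppress the read entirely if it has more than
    ``m`` alignments, regardless of relative mismatch counts (Bowtie ``-m``
    semantics).  Returns the kept hit or None."""
    if len(hits) == 0 or len(hits) > m:
        return None
    if len(hits) == 1:
        return hits[0]
    # m>1 with several survivors has no single canonical answer; report the
    # deterministic best (fewest mismatches, then coordinate order).
    return min(hits, key=lambda h: (h.mismatches, h.scaffold, h.pos0, h.strand))


# ---------------------------------------------------------------------------
# Production mapper: pigeonhole seed index
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Concatenated 2-bit-packed genome with a sorted exact k-mer index.

    Scaffolds are joined with padding sentinels (longer than any read) so a
    window can never silently span two scaffolds; candidate alignments are
    additionally bounds-checked against their scaffold.
    """

    def __init__(self, genome, k: int, pad: int = 128):
        seqs = _load_genome(genome)
        if not seqs:
            raise ValueError("empty genome")
        self.names = list(seqs)
        self.lengths = np.array([len(seqs[n]) for n in self.names], dtype=np.int64)
        self.k = int(k)
        parts, offsets, pos = [], [], 0
        padding = np.full(pad, _CODE_PAD, dtype=np.uint8)
        for name in self.names:
            offsets.append(pos)
            codes = seq_to_codes(seqs[name])
            parts.append(codes)
            parts.append(padding)
            pos += len(codes) + pad
        self.offsets = np.array(offsets, dtype=np.int64)
        self.concat = np.concatenate(parts)
        self._build_index()

    def _build_index(self) -> None:
        k, g = self.k, self.concat
        n_win = len(g) - k + 1
        code = np.zeros(n_win, dtype=np.uint64)
        for j in range(k):
            code = code * np.uint64(4) + g[j:j + n_win]
        bad = (g >= _CODE_N).astype(np.int64)
        cum = np.concatenate([[0], np.cumsum(bad)])
        valid = (cum[k:] - cum[:-k]) == 0
        self._positions = np.flatnonzero(valid).astype(np.int64)
        codes = code[self._positions]
        order = np.argsort(codes, kind="stable")
        self._sorted_codes = codes[order]
        self._sorted_pos = self._positions[order]

    def lookup(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self._sorted_codes, codes, side="left")
        hi = np.searchsorted(self._sorted_codes, codes, side="right")
        return lo, hi

    def scaffold_of(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.offsets, gpos, side="right") - 1

    def within_scaffold(self, start: np.ndarray, L: int) -> np.ndarray:
        idx = self.scaffold_of(start)
        local = start - self.offsets[idx]
        return (local >= 0) & (local + L <= self.lengths[idx])


def _seed_layout(read_len: int, v: int) -> list[tuple[int, int]]:
    """Offsets and length of exact seeds: partition the read into v+1
    segments; take the leading ≤31-mer of each segment."""
    nseg = v + 1
    bounds = [round(i * read_len / nseg) for i in range(nseg + 1)]
    k = min(b - a for a, b in zip(bounds[:-1], bounds[1:]))
    k = min(k, _MAX_SEED_LEN)
    if k < 1:
        raise ValueError(f"read length {read_len} too short for v={v}")
    return [(bounds[i], k) for i in range(nseg)]


def _pack_columns(mat: np.ndarray, start: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit-pack columns [start, start+k) of a code matrix; also return a
    validity mask (False where the slice contains an N)."""
    code = np.zeros(mat.shape[0], dtype=np.uint64)
    sl = mat[:, start:start + k]
    for j in range(k):
        code = code * np.uint64(4) + sl[:, j]
    return code, (sl < _CODE_N).all(axis=1)


def map_reads(reads, genome, v: int = 2, m: int = 1) -> UniqueHitTable:
    """Map fixed-length reads and apply the uniqueness filter.

    Equivalent, read by read, to ``enumerate_alignments`` followed by
    ``unique_filter`` but scales to hundreds of thousands of reads against
    tens of megabases via the pigeonhole seed index.
    """
    ids: list[str] = []
    seq_list: list[str] = []
    for rid, seq in iter_reads(reads):
        ids.append(rid)
        seq_list.append(seq)
    n = len(ids)
    if n == 0:
        return UniqueHitTable(pd.DataFrame(columns=HIT_COLUMNS), 0, 0, 0, 0, 0)
    L = len(seq_list[0])
    if any(len(s) != L for s in seq_list):
        raise ReadFormatError("map_reads requires fixed-length reads")

    R = _BASE_TO_CODE[
        np.frombuffer("".join(seq_list).encode("ascii"), dtype=np.uint8)
    ].reshape(n, L)
    if R.max() == 255:
        raise ReadFormatError("non-ACGTN character in reads")
    RC = revcomp_codes(R)

    seeds = _seed_layout(L, v)
    index = GenomeIndex(genome, k=seeds[0][1])
    if L > int(index.lengths.max()):
        raise ValueError("read length exceeds every scaffold length")

    cand_read: list[np.ndarray] = []
    cand_strand: list[np.ndarray] = []
    cand_start: list[np.ndarray] = []
    for strand_code, mat in ((0, R), (1, RC)):
        for offset, k in seeds:
            codes, ok = _pack_columns(mat, offset, k)
            lo, hi = index.lookup(codes)
            counts = np.where(ok, hi - lo, 0)
            total = int(counts.sum())
            if total == 0:
                continue
            read_idx = np.repeat(np.arange(n), counts)
            base = np.repeat(np.cumsum(counts) - counts, counts)
            sel = np.arange(total) - base + np.repeat(lo, counts)
            gstart = index._sorted_pos[sel] - offset
            cand_read.append(read_idx)
            cand_strand.append(np.full(total, strand_code, dtype=np.int64))
            cand_start.append(gstart)

    if cand_read:
        read_idx = np.concatenate(cand_read)
        strand = np.concatenate(cand_strand)
        start = np.concatenate(cand_start)
        glen = np.int64(len(index.concat))
        keep = (start >= 0) & (start + L <= glen)
        keep &= index.within_scaffold(np.where(keep, start, 0), L) & keep
        read_idx, strand, start = read_idx[keep], strand[keep], start[keep]
        # dedupe alignments found through several seeds
        key = (read_idx * 2 + strand) * glen + start
        _, first = np.unique(key, return_index=True)
        read_idx, strand, start = read_idx[first], strand[first], start[first]
        # verify full-length Hamming distance in chunks
        keep_mask = np.zeros(len(start), dtype=bool)
        nm = np.zeros(len(start), dtype=np.int64)
        span = np.arange(L)
        for s in range(0, len(start), 1_000_000):
            e = min(s + 1_000_000, len(start))
            gwin = index.concat[start[s:e, None] + span]
            rwin = np.where(strand[s:e, None] == 0,
                            R[read_idx[s:e]], RC[read_idx[s:e]])
            mism = ((gwin != rwin) | (gwin >= _CODE_N) | (rwin >= _CODE_N)
                    ).sum(axis=1)
            nm[s:e] = mism
            keep_mask[s:e] = mism <= v
        read_idx, strand, start, nm = (read_idx[keep_mask], strand[keep_mask],
                                       start[keep_mask], nm[keep_mask])
    else:
        read_idx = strand = start = nm = np.empty(0, dtype=np.int64)

    per_read = np.bincount(read_idx, minlength=n)
    mapped_any = int((per_read > 0).sum())
    unique_reads = per_read == 1
    mapped_unique = int(unique_reads.sum())
    suppressed_multi = int((per_read > m).sum()) if m == 1 else mapped_any - int(
        (per_read[per_read > 0] <= m).sum())
    # m>1 is accepted for API symmetry with unique_filter but the table still
    # stores at most one hit per read; keep the deterministic best.
    sel = unique_reads[read_idx] if m == 1 else np.zeros(0, dtype=bool)
    if m == 1:
        read_idx, strand, start, nm = (read_idx[sel], strand[sel],
                                       start[sel], nm[sel])
    else:
        order = np.lexsort((strand, start, nm, read_idx))
        read_idx, strand, start, nm = (read_idx[order], strand[order],
                                       start[order], nm[order])
        keep_first = np.ones(len(read_idx), dtype=bool)
        keep_first[1:] = read_idx[1:] != read_idx[:-1]
        ok_count = per_read[read_idx] <= m
        sel = keep_first & ok_count
        read_idx, strand, start, nm = (read_idx[sel], strand[sel],
                                       start[sel], nm[sel])
        mapped_unique = len(read_idx)
        suppressed_multi = mapped_any - mapped_unique

    scaf_idx = index.scaffold_of(start) if len(start) else start
    hits = pd.DataFrame({
        "read_id": np.array(ids, dtype=object)[read_idx],
        "scaffold": np.array(index.names, dtype=object)[scaf_idx],
        "pos0": start - index.offsets[scaf_idx] if len(start) else start,
        "strand": np.where(strand == 0, "+", "-"),
        "mismatches": nm,
    })
    hits = hits.sort_values("read_id", kind="stable").reset_index(drop=True)
    return UniqueHitTable(
        hits=hits,
        total_reads=n,
        mapped_any=mapped_any,
        mapped_unique=mapped_unique,
        suppressed_multi=mapped_any - mapped_unique if m == 1 else suppressed_multi,
        unmapped=n - mapped_any,
        read_lengths={ids[0]: L} if n else {},
    )


# ---------------------------------------------------------------------------
# SAM ingestion
# ---------------------------------------------------------------------------

def ingest_sam(sam_path: str | Path, policy: str = "record-count") -> UniqueHitTable:
    """Build a UniqueHitTable from external single-end alignments.

    policy "record-count": a read is unique iff exactly one non-secondary,
    non-supplementary aligned record exists for it.  policy "tag": the NH
    multiplicity tag decides (NH==1 keeps the read).
    """
    import pysam

    if policy not in ("record-count", "tag"):
        raise ValueError(f"unknown uniqueness policy {policy!r}")
    counts: dict[str, int] = {}
    kept: dict[str, AlignmentHit] = {}
    unmapped_ids: set[str] = set()
    read_lengths: dict[str, int] = {}
    lengths_seen: set[int] = set()
    try:
        fh = pysam.AlignmentFile(str(sam_path), "r", check_sq=False)
    except ValueError as exc:
        raise SAMFormatError(f"{sam_path}: {exc}") from exc
    with fh:
        lineno = fh.text.count("\n")
        for rec in fh:
            lineno += 1
            try:
                qname = rec.query_name
                if qname is None:
                    raise ValueError("missing QNAME")
                if rec.query_length:
                    read_lengths[qname] = rec.query_length
                    lengths_seen.add(rec.query_length)
                if rec.is_unmapped:
                    unmapped_ids.add(qname)
                    continue
                if rec.is_secondary or rec.is_supplementary:
                    continue
                if policy == "tag":
                    multiplicity = rec.get_tag("NH") if rec.has_tag("NH") else 1
                else:
                    multiplicity = None
                counts[qname] = counts.get(qname, 0) + 1
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                hit = AlignmentHit(qname, rec.reference_name,
                                   rec.reference_start,
                                   "-" if rec.is_reverse else "+", int(nm))
                if policy == "tag":
                    if multiplicity == 1:
                        kept[qname] = hit
                else:
                    kept[qname] = hit  # discarded later if count > 1
            except (ValueError, KeyError) as exc:
                raise SAMFormatError(
                    f"{sam_path} line {lineno}: {exc}") from exc
    if len(lengths_seen) > 1:
        logger.warning("mixed read lengths in %s: %s", sam_path,
                       sorted(lengths_seen))

    if policy == "record-count":
        unique_ids = [q for q, c in counts.items() if c == 1]
    else:
        unique_ids = [q for q in counts if q in kept]
    rows = [kept[q] for q in sorted(unique_ids)]
    mapped_any = len(counts)
    mapped_unique = len(rows)
    total = mapped_any + len(unmapped_ids)
    hits = pd.DataFrame([h.__dict__ for h in rows], columns=HIT_COLUMNS)
    return UniqueHitTable(
        hits=hits,
        total_reads=total,
        mapped_any=mapped_any,
        mapped_unique=mapped_unique,
        suppressed_multi=mapped_any - mapped_unique,
        unmapped=len(unmapped_ids),
        read_lengths=read_lengths,
    )


# ---------------------------------------------------------------------------
# Primer screen
# ---------------------------------------------------------------------------

def _load_primers(primers) -> list[tuple[str, str]]:
    if isinstance(primers, (str, Path)):
        out = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(str(primers), "fasta")]
    elif isinstance(primers, Mapping):
        out = [(k, v.upper()) for k, v in primers.items()]
    else:
        out = [(name, seq.upper()) for name, seq in primers]
    if not out:
        raise ValueError("no primer sequences supplied")
    return out


def screen_primers(unmapped_reads: Iterable[tuple[str, str]] | str | Path,
                   primers, min_match_len: int = 11) -> PrimerScreenResult:
    """Count unmapped reads that carry an exact ≥min_match_len nt substring
    of any primer (either strand).  Detection is by the set of all
    min_match_len-mers of the primers, so a single shared k-mer suffices."""
    if min_match_len < 8:
        raise ValueError("min_match_len below 8 would match by chance")
    primer_list = _load_primers(primers)
    kmer_sets: list[tuple[str, frozenset[str]]] = []
    for name, seq in primer_list:
        kmers = set()
        for s in (seq, revcomp(seq)):
            kmers.update(s[i:i + min_match_len]
                         for i in range(len(s) - min_match_len + 1))
        kmer_sets.append((name, frozenset(kmers)))

    n_unmapped = 0
    n_positive = 0
    per_primer = {name: 0 for name, _ in kmer_sets}
    for _rid, seq in iter_reads(unmapped_reads):
        n_unmapped += 1
        seq = seq.upper()
        windows = {seq[i:i + min_match_len]
                   for i in range(len(seq) - min_match_len + 1)}
        hit_any = False
        for name, kmers in kmer_sets:
            if windows & kmers:
                per_primer[name] += 1
                hit_any = True
        if hit_any:
            n_positive += 1
    return PrimerScreenResult(n_unmapped, n_positive, min_match_len, per_primer)
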