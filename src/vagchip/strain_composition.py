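"""Strain-level composition of defined bacterial consortia from shotgun reads.

Multi-strain *L. crispatus* consortia are quantified by mapping shotgun reads
to a database of strain-specific marker genes: single-copy genes uniquely
present in exactly one strain's genome. The pipeline here is

1. sliding-window quality trimming of the reads (window 4 bp, mean Q >= 20),
2. marker selection: a gene is a marker for its strain iff it matches no
   other gene within the strain (single-copy) and no gene of any other strain
   (unique), where "matches" means a best local alignment with >= 70%
   identity over >= 70% of the shorter sequence,
3. read assignment to markers by exact shared 31-mers (built-in path) or
   ingestion of external SAM alignments,
4. per-gene coverage, then per-strain relative abundance as the median marker
   coverage normalized by the sum of medians over all strains.

Coverage and composition tables are plain pandas DataFrames (columns
documented on the producing functions).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

logger = logging.getLogger(__name__)

__all__ = [
    "QualityRead",
    "StrainGeneSet",
    "MarkerSelectionParams",
    "MarkerGeneSet",
    "AssignmentResult",
    "trim_read_sliding_window",
    "trim_reads",
    "cross_match",
    "select_marker_genes",
    "assign_reads",
    "per_gene_coverage",
    "estimate_composition",
    "read_sam_coverage",
    "estimate_strains",
]

_ALPHABET = frozenset("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QualityRead:
    """A sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(f"read {self.id!r}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def prefix(self, n: int) -> "QualityRead":
        return QualityRead(self.id, self.sequence[:n], self.qualities[:n])


@dataclass(frozen=True)
class StrainGeneSet:
    """All annotated genes of one strain: (gene_id, sequence) pairs."""

    strain_id: str
    genes: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"strain {self.strain_id}: duplicate gene ids")
        for gid, seq in self.genes:
            if not seq:
                raise ValueError(f"gene {gid}: empty sequence")


@dataclass(frozen=True)
class MarkerSelectionParams:
    """Thresholds of the marker cross-match rule.

    A pair of genes "matches" when the best local alignment reaches
    ``identity_threshold`` identity over at least ``overlap_threshold`` of the
    denominator sequence (the shorter one by default).
    """

    identity_threshold: float = 0.70
    overlap_threshold: float = 0.70
    overlap_denominator: str = "shorter"   # or "longer"

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "overlap_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.overlap_denominator not in ("shorter", "longer"):
            raise ValueError("overlap_denominator must be 'shorter' or 'longer'")


@dataclass(frozen=True)
class MarkerGeneSet:
    """Strain-specific single-copy marker genes."""

    strain_id: str
    markers: tuple[tuple[str, str], ...]   # (gene_id, sequence)

    @property
    def lengths(self) -> dict[str, int]:
        return {gid: len(seq) for gid, seq in self.markers}


# --------------------------------------------------------------------------
# read trimming
# --------------------------------------------------------------------------

def trim_read_sliding_window(read: QualityRead, window_bp: int = 4,
                             min_mean_q: float = 20.0,
                             min_len: int = 15) -> QualityRead | None:
    """Quality-trim a read with a 5'->3' sliding window.

    At the first window (offset i .. i+w-1) whose mean quality drops below
    ``min_mean_q`` the read is truncated before offset i; the output is always
    a prefix of the input. Reads shorter than the window are evaluated as a
    single window. Returns None if the trimmed read is shorter than
    ``min_len`` (dropped).
    """
    if window_bp < 1:
        raise ValueError(f"window_bp must be >= 1, got {window_bp}")
    q = np.asarray(read.qualities, dtype=float)
    n = len(q)
    if n == 0:
        return None
    if n < window_bp:
        cut = 0 if q.mean() < min_mean_q else n
    else:
        csum = np.concatenate([[0.0], np.cumsum(q)])
        means = (csum[window_bp:] - csum[:-window_bp]) / window_bp
        failing = np.flatnonzero(means < min_mean_q)
        cut = int(failing[0]) if failing.size else n
    if cut < min_len:
        return None
    return read if cut == n else read.prefix(cut)


def trim_reads(reads, window_bp: int = 4, min_mean_q: float = 20.0,
               min_len: int = 15) -> tuple[list[QualityRead], dict]:
    """Trim an iterable of reads; returns (kept reads, summary stats)."""
    kept: list[QualityRead] = []
    n_in = n_trimmed = bases_in = bases_out = 0
    for read in reads:
        n_in += 1
        bases_in += len(read)
        out = trim_read_sliding_window(read, window_bp, min_mean_q, min_len)
        if out is None:
            continue
        if len(out) < len(read):
            n_trimmed += 1
        bases_out += len(out)
        kept.append(out)
    stats = {"reads_in": n_in, "reads_kept": len(kept),
             "reads_dropped": n_in - len(kept), "reads_trimmed": n_trimmed,
             "bases_in": bases_in, "bases_out": bases_out}
    return kept, stats


# --------------------------------------------------------------------------
# marker gene selection
# --------------------------------------------------------------------------

def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


def cross_match(a: str, b: str,
                params: MarkerSelectionParams = MarkerSelectionParams()) -> bool:
    """Do two gene sequences match under the identity/overlap criterion?

    The best local alignment is computed by exact dynamic programming
    (match +1, mismatch -1, gap -2). Identity is identities per alignment
    column; overlap is the fraction of the denominator sequence (shorter by
    default) covered by aligned (non-gap) positions.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner()
    alignments = aligner.align(a, b)
    if not alignments or alignments.score <= 0:
        return False
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return False
    identity = counts.identities / columns
    t_blocks, q_blocks = aln.aligned
    span_a = int(sum(e - s for s, e in t_blocks))
    span_b = int(sum(e - s for s, e in q_blocks))
    if params.overlap_denominator == "shorter":
        denom_span = span_a if len(a) <= len(b) else span_b
        denom_len = min(len(a), len(b))
    else:
        denom_span = span_a if len(a) >= len(b) else span_b
        denom_len = max(len(a), len(b))
    overlap = denom_span / denom_len
    return (identity >= params.identity_threshold
            and overlap >= params.overlap_threshold)


def _kmer_set(seq: str, k: int) -> set[str]:
    s = set()
    rc = reverse_complement(seq)
    for t in (seq, rc):
        for i in range(len(t) - k + 1):
            kmer = t[i:i + k]
            if "N" not in kmer:
                s.add(kmer)
    return s


def select_marker_genes(consortium: list[StrainGeneSet],
                        params: MarkerSelectionParams = MarkerSelectionParams(),
                        prescreen_k: int | None = 11) -> list[MarkerGeneSet]:
    """Select strain-specific single-copy marker genes.

    A gene is a marker for its strain iff it cross-matches no other gene
    within the strain and no gene of any other strain. ``prescreen_k`` skips
    the alignment for pairs sharing no exact k-mer (a heuristic that is safe
    well above the identity threshold; pass None for exhaustive all-vs-all).
    Strains left with zero markers are retained with an empty set and a
    warning.
    """
    if not consortium:
        raise ValueError("consortium must contain at least one strain")
    genes = [(gs.strain_id, gid, seq)
             for gs in consortium for gid, seq in gs.genes]
    if prescreen_k is not None:
        kmers = [_kmer_set(seq, prescreen_k) for _, _, seq in genes]
    excluded: set[tuple[str, str]] = set()
    for i in range(len(genes)):
        si, gi, seq_i = genes[i]
        for j in range(i + 1, len(genes)):
            sj, gj, seq_j = genes[j]
            if prescreen_k is not None and kmers[i].isdisjoint(kmers[j]):
                continue
            if cross_match(seq_i, seq_j, params):
                # same strain -> both copies fail single-copy;
                # different strains -> both fail uniqueness
                excluded.add((si, gi))
                excluded.add((sj, gj))
    out = []
    for gs in sorted(consortium, key=lambda g: g.strain_id):
        markers = tuple(sorted(
            (gid, seq) for gid, seq in gs.genes
            if (gs.strain_id, gid) not in excluded))
        if not markers:
            warnings.warn(f"strain {gs.strain_id} has no marker genes",
                          stacklevel=2)
            logger.warning("strain %s has no marker genes", gs.strain_id)
        out.append(MarkerGeneSet(strain_id=gs.strain_id, markers=markers))
    return out


# --------------------------------------------------------------------------
# read assignment (exact k-mer path)
# --------------------------------------------------------------------------

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical k-mer codes (uint64) of a sequence; windows with N dropped."""
    n = len(seq)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    fwd = _encode(seq)
    rev = _encode(reverse_complement(seq))
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    win_f = np.lib.stride_tricks.sliding_window_view(fwd, k)
    win_r = np.lib.stride_tricks.sliding_window_view(rev, k)
    valid = ~np.any(win_f < 0, axis=1)
    cf = (win_f.astype(np.uint64) * powers).sum(axis=1)
    cr = (win_r.astype(np.uint64) * powers).sum(axis=1)[::-1]
    canon = np.minimum(cf, cr)
    return canon[valid]


@dataclass
class AssignmentResult:
    """Per-gene read counts plus read-level accounting."""

    counts: dict[tuple[str, str], int]   # (strain_id, gene_id) -> reads
    n_reads: int
    n_assigned: int
    n_ambiguous: int
    n_unassigned: int
    gene_lengths: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def unassigned_fraction(self) -> float:
        return self.n_unassigned / self.n_reads if self.n_reads else 0.0


def assign_reads(reads: list[QualityRead], markers: list[MarkerGeneSet],
                 k: int = 31) -> AssignmentResult:
    """Assign reads to marker genes by exact shared k-mers.

    A read is assigned to a gene iff it shares at least one exact k-mer
    (forward or reverse complement) with that gene and with no other gene;
    reads hitting more than one gene (within or across strains) are discarded
    as ambiguous, since markers are unique by construction and such collisions
    flag repeats or errors. Reads shorter than k are unassignable.
    """
    gene_keys: list[tuple[str, str]] = []
    gene_lengths: dict[tuple[str, str], int] = {}
    code_chunks, gid_chunks = [], []
    for ms in markers:
        for gid, seq in ms.markers:
            key = (ms.strain_id, gid)
            gene_lengths[key] = len(seq)
            codes = np.unique(_kmer_codes(seq, k))
            code_chunks.append(codes)
            gid_chunks.append(np.full(codes.size, len(gene_keys),
                                      dtype=np.int64))
            gene_keys.append(key)
    if not gene_keys:
        raise ValueError("no marker genes to assign against")
    index_codes = np.concatenate(code_chunks)
    index_genes = np.concatenate(gid_chunks)
    order = np.argsort(index_codes, kind="stable")
    index_codes, index_genes = index_codes[order], index_genes[order]

    read_chunks, read_ids = [], []
    for r_idx, read in enumerate(reads):
        codes = _kmer_codes(read.sequence, k)
        if codes.size:
            codes = np.unique(codes)
            read_chunks.append(codes)
            read_ids.append(np.full(codes.size, r_idx, dtype=np.int64))
    counts: dict[tuple[str, str], int] = {key: 0 for key in gene_keys}
    if not read_chunks:
        return AssignmentResult(counts, len(reads), 0, 0, len(reads),
                                gene_lengths)
    all_codes = np.concatenate(read_chunks)
    all_rids = np.concatenate(read_ids)
    lo = np.searchsorted(index_codes, all_codes, side="left")
    hi = np.searchsorted(index_codes, all_codes, side="right")
    span = hi - lo
    hit = span > 0
    # expand multi-gene k-mers (rare) into one row per (read, gene) hit
    rep_rids = np.repeat(all_rids[hit], span[hit])
    offsets = np.repeat(lo[hit], span[hit]) + _ranges(span[hit])
    rep_genes = index_genes[offsets]
    pair = rep_rids * len(gene_keys) + rep_genes
    uniq = np.unique(pair)
    u_rids = uniq // len(gene_keys)
    u_genes = uniq % len(gene_keys)
    rid_vals, rid_counts = np.unique(u_rids, return_counts=True)
    unambiguous = set(rid_vals[rid_counts == 1].tolist())
    n_ambiguous = int(np.sum(rid_counts > 1))
    n_assigned = 0
    for rid, gidx in zip(u_rids.tolist(), u_genes.tolist()):
        if rid in unambiguous:
            counts[gene_keys[gidx]] += 1
            n_assigned += 1
    n_unassigned = len(reads) - n_assigned - n_ambiguous
    return AssignmentResult(counts, len(reads), n_assigned, n_ambiguous,
                            n_unassigned, gene_lengths)


def _ranges(lengths: np.ndarray) -> np.ndarray:
    """Concatenated [0..l) ranges for an array of lengths."""
    if lengths.size == 0:
        return np.empty(0, dtype=np.int64)
    total = int(lengths.sum())
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    starts = np.cumsum(lengths)[:-1]
    out[starts] = 1 - lengths[:-1]
    return np.cumsum(out)


# --------------------------------------------------------------------------
# coverage and composition
# --------------------------------------------------------------------------

def per_gene_coverage(counts: dict[tuple[str, str], int],
                      gene_lengths: dict[tuple[str, str], int],
                      read_length: int = 150) -> pd.DataFrame:
    """Coverage table under the uniform-depth model.

    Columns: strain_id, gene_id, length_bp, reads,
    coverage_x = reads * read_length / length_bp.
    """
    rows = []
    for (strain, gid), length in sorted(gene_lengths.items()):
        if length <= 0:
            raise ValueError(f"gene {gid}: length must be > 0")
        n = counts.get((strain, gid), 0)
        rows.append((strain, gid, length, n, n * read_length / length))
    return pd.DataFrame(rows, columns=["strain_id", "gene_id", "length_bp",
                                       "reads", "coverage_x"])


def estimate_composition(table: pd.DataFrame) -> pd.DataFrame:
    """Strain relative abundances from a coverage table.

    Per strain, the median coverage over its marker genes; relative abundance
    is each median divided by the sum of medians. With an even number of
    markers the median is the mean of the two central values. If every median
    is zero the result is an explicit no-signal table (NaN abundances,
    ``attrs["no_signal"] = True``).

    Columns: strain_id, n_markers, median_coverage, relative_abundance.
    """
    if table.empty:
        raise ValueError("coverage table is empty")
    med = (table.groupby("strain_id", sort=True)
           .agg(n_markers=("gene_id", "size"),
                median_coverage=("coverage_x", "median"))
           .reset_index())
    total = med["median_coverage"].sum()
    out = med.copy()
    if total > 0:
        out["relative_abundance"] = out["median_coverage"] / total
        out.attrs["no_signal"] = False
    else:
        out["relative_abundance"] = np.nan
        out.attrs["no_signal"] = True
        logger.warning("all strain medians are zero: no composition signal")
    return out


def read_sam_coverage(path, markers: list[MarkerGeneSet],
                      min_mapq: int = 0, read_length: int = 150
                      ) -> pd.DataFrame:
    """Coverage table from external alignments in SAM format.

    Primary alignments with mapping quality >= ``min_mapq`` contribute their
    reference-aligned bases; coverage_x = aligned bases / gene length.
    Reference names must match marker gene ids.
    """
    import pysam

    gene_lengths: dict[tuple[str, str], int] = {}
    by_gid: dict[str, tuple[str, str]] = {}
    for ms in markers:
        for gid, seq in ms.markers:
            key = (ms.strain_id, gid)
            gene_lengths[key] = len(seq)
            by_gid[gid] = key
    bases: dict[tuple[str, str], int] = {k: 0 for k in gene_lengths}
    counts: dict[tuple[str, str], int] = {k: 0 for k in gene_lengths}
    unknown: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            ref = rec.reference_name
            if ref not in by_gid:
                unknown.add(ref)
                continue
            key = by_gid[ref]
            bases[key] += rec.reference_length or 0
            counts[key] += 1
    if unknown:
        raise ValueError(
            f"SAM references not in the marker set: {sorted(unknown)}")
    rows = [(s, g, L, counts[(s, g)], bases[(s, g)] / L)
            for (s, g), L in sorted(gene_lengths.items())]
    return pd.DataFrame(rows, columns=["strain_id", "gene_id", "length_bp",
                                       "reads", "coverage_x"])


def estimate_strains(reads: list[QualityRead], markers: list[MarkerGeneSet],
                     k: int = 31, read_length: int | None = None,
                     trim: bool = True) -> tuple[pd.DataFrame, pd.DataFrame,
                                                 AssignmentResult]:
    """End-to-end built-in pipeline: trim -> assign -> coverage -> composition.

    Returns (coverage table, composition table, assignment accounting).
    ``read_length`` defaults to the mean kept-read length.
    """
    if trim:
        reads, stats = trim_reads(reads)
        logger.info("trimming: kept %d/%d reads", stats["reads_kept"],
                    stats["reads_in"])
    result = assign_reads(reads, markers, k=k)
    if read_length is None:
        read_length = (int(round(np.mean([len(r) for r in reads])))
                       if reads else 150)
    coverage = per_gene_coverage(result.counts, result.gene_lengths,
                                 read_length)
    composition = estimate_composition(coverage)
    return coverage, composition, result
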