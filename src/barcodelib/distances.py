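"""Pairwise alignment and uncorrected p-distance computation.

Distances are uncorrected proportions of differing sites ("p-distances")
with pairwise deletion: alignment columns containing a gap or an ambiguity
code in either member of the pair are excluded from both numerator and
denominator for that pair only.

Two matrix modes are supported:

``pairwise_align``
    Every pair is globally aligned on its own (affine gaps, end gaps free)
    and then scored.  This is the default and matches libraries of unaligned
    fragments of differing length.
``msa``
    Sequences are assumed to be rows of one multiple alignment (equal
    length); distances are computed column-wise with no re-alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .library_model import Library, ungapped

logger = logging.getLogger(__name__)

#: Unambiguous bases; anything else is excluded under pairwise deletion.
_ACGT = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring; a gap run of length k costs open + k * extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -8.0
    gap_extend: float = -1.0
    free_end_gaps: bool = True


DEFAULT_SCORING = AlignmentScoring()


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # Biopython charges open_gap_score for the first gapped position and
    # extend_gap_score for each further one; shift so a k-run costs
    # open + k * extend as documented here.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    if scoring.free_end_gaps:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # Biopython < 1.86 naming
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def orient_sequence(seq: str, reference: str, k: int = 11) -> str:
    """Return *seq* or its reverse complement, whichever shares more exact
    k-mers with *reference* (ties keep the forward strand)."""
    ref_kmers = _kmer_set(reference, k)
    fwd = len(_kmer_set(seq, k) & ref_kmers)
    rc = reverse_complement(seq)
    rev = len(_kmer_set(rc, k) & ref_kmers)
    return rc if rev > fwd else seq


def pairwise_align(
    seq_a: str,
    seq_b: str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> tuple[str, str, float]:
    """Globally align two ungapped sequences; returns (aligned_a, aligned_b, score).

    Ties between co-optimal alignments are broken deterministically by taking
    the aligner's first enumeration order.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_align requires non-empty sequences")
    if "-" in seq_a or "-" in seq_b:
        raise ValueError("pairwise_align requires ungapped input")
    aligner = _make_aligner(scoring)
    alignment = aligner.align(seq_a, seq_b)[0]
    return str(alignment[0]), str(alignment[1]), alignment.score


def p_distance(aligned_a: str, aligned_b: str) -> tuple[float | None, int]:
    """Uncorrected distance under pairwise deletion.

    Returns ``(distance, compared_sites)``; distance is ``None`` (masked)
    when no comparable sites exist — never 0.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    compared = 0
    mismatches = 0
    for x, y in zip(aligned_a, aligned_b):
        if x in _ACGT and y in _ACGT:
            compared += 1
            if x != y:
                mismatches += 1
    if compared == 0:
        return None, 0
    return mismatches / compared, compared


@dataclass
class DistanceMatrix:
    """Symmetric uncorrected-distance matrix with compared-site counts.

    ``d`` holds fractions in [0, 1] with ``nan`` marking masked cells
    (zero comparable sites); ``sites`` holds the per-pair compared-site
    counts.  Invariants: zero diagonal, symmetry, ``d`` masked exactly
    where ``sites`` is 0 off the diagonal.
    """

    ids: list[str]
    d: np.ndarray
    sites: np.ndarray
    marker: str = ""
    mode: str = "pairwise_align"

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n) or self.sites.shape != (n, n):
            raise ValueError("matrix shape inconsistent with ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, record_id: str) -> int:
        return self.ids.index(record_id)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.d[self.index_of(id_a), self.index_of(id_b)])

    def submatrix(self, keep_ids: list[str]) -> "DistanceMatrix":
        idx = [self.index_of(i) for i in keep_ids]
        return DistanceMatrix(
            ids=list(keep_ids),
            d=self.d[np.ix_(idx, idx)].copy(),
            sites=self.sites[np.ix_(idx, idx)].copy(),
            marker=self.marker,
            mode=self.mode,
        )

    def write_tsv(self, path) -> None:
        """Square TSV with id header row/column; masked cells as "NA"."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, rid in enumerate(self.ids):
                cells = [
                    "NA" if np.isnan(v) else f"{v:.6f}" for v in self.d[i]
                ]
                fh.write(rid + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def read_tsv(cls, path, marker: str = "", mode: str = "pairwise_align"):
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")[1:]
                rows.append([np.nan if p == "NA" else float(p) for p in parts])
        d = np.asarray(rows, dtype=float)
        sites = np.where(np.isnan(d), 0, 1).astype(int)
        np.fill_diagonal(sites, 0)
        return cls(ids=header, d=d, sites=sites, marker=marker, mode=mode)


_BASE_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}


def _encode(seqs: list[str]) -> np.ndarray:
    """Rows of equal length encoded A..T -> 1..4, everything else 0."""
    length = len(seqs[0])
    arr = np.zeros((len(seqs), length), dtype=np.uint8)
    for i, s in enumerate(seqs):
        arr[i] = [_BASE_CODE.get(c, 0) for c in s]
    return arr


def _msa_distance_arrays(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    enc = _encode(seqs)
    valid = enc > 0
    n = len(seqs)
    d = np.zeros((n, n), dtype=float)
    sites = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid  # (n, length)
        comp = both.sum(axis=1)
        mism = ((enc[i] != enc) & both).sum(axis=1)
        sites[i] = comp
        with np.errstate(invalid="ignore", divide="ignore"):
            d[i] = np.where(comp > 0, mism / np.maximum(comp, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(sites, 0)
    return d, sites


def distance_matrix(
    library: Library,
    marker: str,
    mode: str = "pairwise_align",
    scoring: AlignmentScoring = DEFAULT_SCORING,
    normalize_strand: bool = True,
) -> DistanceMatrix:
    """All-pairs p-distance matrix over the records of one marker.

    In ``pairwise_align`` mode each pair is aligned independently (ungapped
    input taken from the records, with optional strand normalization of the
    shorter sequence against the longer).  In ``msa`` mode the stored,
    already-aligned sequences are compared column-wise and must all have
    equal length.
    """
    records = library.by_marker(marker)
    if len(records) < 2:
        raise ValueError(f"need >=2 records of marker {marker}")
    ids = [r.sample_id for r in records]
    if mode == "msa":
        seqs = [r.sequence for r in records]
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("msa mode requires equal-length sequences")
        d, sites = _msa_distance_arrays(seqs)
    elif mode == "pairwise_align":
        seqs = [ungapped(r.sequence) for r in records]
        n = len(seqs)
        d = np.zeros((n, n), dtype=float)
        sites = np.zeros((n, n), dtype=np.int64)
        for i in range(n):
            for j in range(i + 1, n):
                a, b = seqs[i], seqs[j]
                if normalize_strand:
                    if len(b) <= len(a):
                        b = orient_sequence(b, a)
                    else:
                        a = orient_sequence(a, b)
                aligned_a, aligned_b, _ = pairwise_align(a, b, scoring)
                dist, comp = p_distance(aligned_a, aligned_b)
                d[i, j] = d[j, i] = np.nan if dist is None else dist
                sites[i, j] = sites[j, i] = comp
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DistanceMatrix(ids=ids, d=d, sites=sites, marker=marker, mode=mode)


def star_align(
    library: Library,
    marker: str,
    reference_id: str | None = None,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    normalize_strand: bool = True,
) -> tuple[list[str], list[str]]:
    """Project every sequence of a marker into the coordinates of one
    reference (default: the longest sequence) via pairwise alignment.

    Returns (ids, rows): equal-length rows padded with '-' outside each
    fragment and at reference-deletion sites; insertions relative to the
    reference are dropped.  This is a star-alignment approximation used to
    make all-pairs distances on large libraries tractable (O(n) alignments
    plus vectorized column comparison instead of O(n^2) alignments).
    """
    records = library.by_marker(marker)
    if len(records) < 2:
        raise ValueError(f"need >=2 records of marker {marker}")
    seqs = {r.sample_id: ungapped(r.sequence) for r in records}
    if reference_id is None:
        reference_id = max(seqs, key=lambda k: len(seqs[k]))
    reference = seqs[reference_id]
    ids: list[str] = []
    rows: list[str] = []
    for r in records:
        seq = seqs[r.sample_id]
        if normalize_strand:
            seq = orient_sequence(seq, reference)
        aligned_seq, aligned_ref, _ = pairwise_align(seq, reference, scoring)
        row = [
            x
            for x, ref in zip(aligned_seq, aligned_ref)
            if ref != "-"  # drop insertions relative to the reference
        ]
        ids.append(r.sample_id)
        rows.append("".join(row))
    return ids, rows


def star_distance_matrix(
    library: Library,
    marker: str,
    reference_id: str | None = None,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> DistanceMatrix:
    """All-pairs p-distances from a star alignment (see :func:`star_align`)."""
    ids, rows = star_align(library, marker, reference_id, scoring)
    d, sites = _msa_distance_arrays(rows)
    return DistanceMatrix(ids=ids, d=d, sites=sites, marker=marker, mode="msa")


def length_summary(library: Library, marker: str) -> tuple[int, int, int]:
    """(mean, min, max) of ungapped lengths; mean rounded to nearest bp."""
    lengths = [r.ungapped_length for r in library.by_marker(marker)]
    if not lengths:
        raise ValueError(f"no records of marker {marker}")
    mean = int(round(sum(lengths) / len(lengths)))
    return mean, min(lengths), max(lengths)
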