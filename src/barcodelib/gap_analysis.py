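"""Taxonomy-partitioned distance summaries, barcode-gap statistics and
anomaly flags (deep intraspecific lineages, zero-distance species pairs).

Pair classes
------------
Every unordered record pair of one marker falls in exactly one class:

* ``intraspecific`` — same species name (open-nomenclature names such as
  "Oreochromis sp." are distinct species-level terminals);
* ``congeneric_interspecific`` — same genus, different species;
* ``intergeneric`` — different genera, families included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .library_model import BarcodeRecord, Library

logger = logging.getLogger(__name__)

PAIR_CLASSES = ("intraspecific", "congeneric_interspecific", "intergeneric")


def classify_pair(rec_a: BarcodeRecord, rec_b: BarcodeRecord) -> str:
    """Pair class from the two records' taxonomy (same-marker pairs only)."""
    if rec_a.marker != rec_b.marker:
        raise ValueError("classify_pair requires records of the same marker")
    if rec_a.species_name == rec_b.species_name:
        return "intraspecific"
    if rec_a.genus == rec_b.genus:
        return "congeneric_interspecific"
    return "intergeneric"


@dataclass
class ClassStats:
    n_pairs: int
    mean_pct: float | None
    min_pct: float | None
    max_pct: float | None


@dataclass
class PartitionSummary:
    """Distance statistics (in %) per pair class over unmasked pairs."""

    subset: str
    classes: dict[str, ClassStats] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in PAIR_CLASSES:
            st = self.classes.get(name, ClassStats(0, None, None, None))
            rows.append(
                {
                    "class": name,
                    "n_pairs": st.n_pairs,
                    "mean_pct": st.mean_pct,
                    "min_pct": st.min_pct,
                    "max_pct": st.max_pct,
                }
            )
        return pd.DataFrame(rows)


def _aligned_records(
    matrix: DistanceMatrix, library: Library
) -> list[BarcodeRecord]:
    wanted = set(matrix.ids)
    by_id = {r.sample_id: r for r in library if r.sample_id in wanted}
    # Prefer records of the matrix's marker when a sample has several markers.
    if matrix.marker:
        for r in library:
            if r.marker == matrix.marker and r.sample_id in wanted:
                by_id[r.sample_id] = r
    missing = [i for i in matrix.ids if i not in by_id]
    if missing:
        raise ValueError(f"matrix ids missing from library: {missing[:5]}")
    return [by_id[i] for i in matrix.ids]


def partition_summary(
    matrix: DistanceMatrix,
    library: Library,
    subset: str = "all",
    record_filter=None,
    exclude_ids: set[str] | None = None,
) -> PartitionSummary:
    """Per-class pair counts and distance statistics (percent, one decimal
    precision retained as floats) over unmasked pairs passing the filter."""
    records = _aligned_records(matrix, library)
    exclude_ids = exclude_ids or set()
    keep = [
        i
        for i, r in enumerate(records)
        if r.sample_id not in exclude_ids and (record_filter is None or record_filter(r))
    ]
    values: dict[str, list[float]] = {c: [] for c in PAIR_CLASSES}
    for a_pos, i in enumerate(keep):
        for j in keep[a_pos + 1 :]:
            dist = matrix.d[i, j]
            if np.isnan(dist):
                continue
            values[classify_pair(records[i], records[j])].append(dist * 100.0)
    summary = PartitionSummary(subset=subset)
    for name, vals in values.items():
        if vals:
            summary.classes[name] = ClassStats(
                n_pairs=len(vals),
                mean_pct=float(np.mean(vals)),
                min_pct=float(np.min(vals)),
                max_pct=float(np.max(vals)),
            )
        else:
            summary.classes[name] = ClassStats(0, None, None, None)
    return summary


def barcode_gap_per_species(
    matrix: DistanceMatrix,
    library: Library,
    exclude_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Per species: max intraspecific distance, min distance to the nearest
    non-conspecific, and the barcode-gap flag (min_inter > max_intra).

    Singleton species have ``max_intra_pct`` masked (NaN) and an
    indeterminate (``None``) gap flag.  A gap flag is false whenever
    ``min_inter <= max_intra`` or ``min_inter == 0``.
    """
    records = _aligned_records(matrix, library)
    exclude_ids = exclude_ids or set()
    keep = [i for i, r in enumerate(records) if r.sample_id not in exclude_ids]
    species: dict[str, list[int]] = {}
    for i in keep:
        species.setdefault(records[i].species_name, []).append(i)
    rows = []
    for name, idxs in sorted(species.items()):
        intra: list[float] = []
        inter: list[float] = []
        for i in idxs:
            for j in keep:
                if j == i:
                    continue
                dist = matrix.d[i, j]
                if np.isnan(dist):
                    continue
                if records[j].species_name == name:
                    if j > i:
                        intra.append(dist * 100.0)
                else:
                    inter.append(dist * 100.0)
        max_intra = max(intra) if intra else np.nan
        min_inter = min(inter) if inter else np.nan
        if np.isnan(max_intra) or np.isnan(min_inter):
            gap = None
        else:
            gap = bool(min_inter > max_intra and min_inter > 0)
        rows.append(
            {
                "species": name,
                "n_samples": len(idxs),
                "max_intra_pct": max_intra,
                "min_inter_pct": min_inter,
                "gap": gap,
            }
        )
    return pd.DataFrame(rows)


def _single_linkage_clusters(d: np.ndarray, threshold: float) -> list[int]:
    """Union-find single linkage: edges where d <= threshold merge clusters."""
    n = d.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if not np.isnan(d[i, j]) and d[i, j] <= threshold:
                parent[find(i)] = find(j)
    roots: dict[int, int] = {}
    labels = []
    for i in range(n):
        root = find(i)
        labels.append(roots.setdefault(root, len(roots)))
    return labels


#: Below this threshold single-linkage degenerates to per-haplotype clusters;
#: deep-lineage flags are suppressed.
MIN_DEEP_THRESHOLD_PCT = 0.5


def deep_lineage_flags(
    matrix: DistanceMatrix,
    library: Library,
    threshold_pct: float = 3.0,
    exclude_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Flag species splitting into >=2 single-linkage clusters at the
    distance threshold (percent); reports cluster membership and the minimum
    between-cluster distance.  Flags are suppressed for thresholds below
    ``MIN_DEEP_THRESHOLD_PCT``."""
    records = _aligned_records(matrix, library)
    exclude_ids = exclude_ids or set()
    suppressed = threshold_pct < MIN_DEEP_THRESHOLD_PCT
    if suppressed:
        logger.warning(
            "deep-lineage threshold %.2f%% below %.2f%%: flags suppressed",
            threshold_pct,
            MIN_DEEP_THRESHOLD_PCT,
        )
    species: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        if r.sample_id not in exclude_ids:
            species.setdefault(r.species_name, []).append(i)
    rows = []
    for name, idxs in sorted(species.items()):
        if len(idxs) < 2:
            continue
        sub = matrix.d[np.ix_(idxs, idxs)]
        labels = _single_linkage_clusters(sub, threshold_pct / 100.0)
        n_clusters = len(set(labels))
        flagged = n_clusters >= 2 and not suppressed
        between = np.nan
        if n_clusters >= 2:
            vals = [
                sub[i, j]
                for i in range(len(idxs))
                for j in range(i + 1, len(idxs))
                if labels[i] != labels[j] and not np.isnan(sub[i, j])
            ]
            if vals:
                between = float(min(vals)) * 100.0
        members = {
            records[idx].sample_id: lab for idx, lab in zip(idxs, labels)
        }
        rows.append(
            {
                "species": name,
                "n_samples": len(idxs),
                "n_clusters": n_clusters,
                "flagged": flagged,
                "min_between_pct": between,
                "clusters": members,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "n_samples",
            "n_clusters",
            "flagged",
            "min_between_pct",
            "clusters",
        ],
    )


def zero_distance_species_pairs(
    matrix: DistanceMatrix,
    library: Library,
    exclude_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Unordered species pairs with at least one zero cross-pair distance."""
    records = _aligned_records(matrix, library)
    exclude_ids = exclude_ids or set()
    keep = [i for i, r in enumerate(records) if r.sample_id not in exclude_ids]
    counts: dict[tuple[str, str], int] = {}
    for a_pos, i in enumerate(keep):
        for j in keep[a_pos + 1 :]:
            if records[i].species_name == records[j].species_name:
                continue
            dist = matrix.d[i, j]
            if not np.isnan(dist) and dist == 0.0:
                pair = tuple(sorted((records[i].species_name, records[j].species_name)))
                counts[pair] = counts.get(pair, 0) + 1
    rows = [
        {"species_a": a, "species_b": b, "n_zero_pairs": n}
        for (a, b), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["species_a", "species_b", "n_zero_pairs"])
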