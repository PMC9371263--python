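"""Library curation: deduplication, fragment and geography filters, sample
merging, taxonomy updates, pseudogene screening and summary tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .library_model import (
    BarcodeRecord,
    Library,
    LibraryError,
    genus_of,
    normalize_species_name,
    ungapped,
)
from .distances import AlignmentScoring, p_distance, pairwise_align, orient_sequence

logger = logging.getLogger(__name__)


@dataclass
class CurationLog:
    """Per-step removal/flag bookkeeping; removal counts sum to input - output."""

    events: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, step: str, record_id: str, reason: str) -> None:
        self.events.append((step, record_id, reason))

    def count(self, step: str | None = None) -> int:
        return sum(1 for s, _, _ in self.events if step is None or s == step)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["step", "record", "reason"])


def deduplicate(
    records: list[BarcodeRecord], log: CurationLog | None = None
) -> list[BarcodeRecord]:
    """Collapse records identical in (accession, marker, sequence) to one.

    Identical sequences from distinct samples with no shared accession are
    biological signal and are kept.
    """
    log = log if log is not None else CurationLog()
    seen: set[tuple[str, str, str]] = set()
    out: list[BarcodeRecord] = []
    for r in records:
        key = (r.accession, r.marker, r.sequence)
        if r.accession and key in seen:
            log.add("deduplicate", r.sample_id, f"duplicate of accession {r.accession}")
            continue
        seen.add(key)
        out.append(r)
    removed = len(records) - len(out)
    if removed:
        logger.info("deduplicate: removed %d duplicate record(s)", removed)
    return out


# Alignment scoring for anchor matching: local-ish behaviour via free end gaps.
_ANCHOR_SCORING = AlignmentScoring()


def filter_target_fragment(
    records: list[BarcodeRecord],
    anchors: dict[str, str],
    min_overlap: int = 150,
    min_identity: float = 0.60,
    log: CurationLog | None = None,
) -> list[BarcodeRecord]:
    """Keep records whose alignment to their marker's anchor sequence covers
    >= *min_overlap* comparable positions at >= *min_identity*.

    Records of a marker with no anchor are retained with a warning.
    """
    log = log if log is not None else CurationLog()
    out: list[BarcodeRecord] = []
    for r in records:
        anchor = anchors.get(r.marker)
        if not anchor:
            logger.warning(
                "%s: no anchor for marker %s, retained unchecked", r.sample_id, r.marker
            )
            out.append(r)
            continue
        seq = orient_sequence(ungapped(r.sequence), anchor)
        aligned_a, aligned_b, _ = pairwise_align(seq, anchor, _ANCHOR_SCORING)
        dist, compared = p_distance(aligned_a, aligned_b)
        identity = 0.0 if dist is None else 1.0 - dist
        if compared >= min_overlap and identity >= min_identity:
            out.append(r)
        else:
            log.add(
                "filter_target_fragment",
                r.sample_id,
                f"anchor overlap {compared} bp at identity {identity:.2f}",
            )
    removed = len(records) - len(out)
    if removed:
        logger.info("filter_target_fragment: removed %d record(s)", removed)
    return out


def filter_geography(
    records: list[BarcodeRecord],
    country: str = "Madagascar",
    whitelist: set[str] | None = None,
    log: CurationLog | None = None,
) -> list[BarcodeRecord]:
    """Remove records not originating from *country* (case-insensitive prefix
    match on the country field, so "Madagascar: Nosy Be" passes).

    Sample ids in *whitelist* (reference-panel members) are always kept.
    Empty country fields are removed and logged as "unknown origin".
    """
    log = log if log is not None else CurationLog()
    whitelist = whitelist or set()
    target = country.strip().lower()
    out: list[BarcodeRecord] = []
    for r in records:
        if r.sample_id in whitelist:
            out.append(r)
            continue
        rec_country = r.country.strip().lower()
        if not rec_country:
            log.add("filter_geography", r.sample_id, "unknown origin")
            continue
        if rec_country.startswith(target):
            out.append(r)
        else:
            log.add("filter_geography", r.sample_id, f"foreign origin {r.country!r}")
    return out


def merge_sample_rows(
    records: list[BarcodeRecord], log: CurationLog | None = None
) -> Library:
    """Link records sharing a sample id and enforce (sample_id, marker)
    uniqueness.

    Later rows duplicating a (sample_id, marker) pair with the *same*
    sequence are dropped with a warning; a different sequence keeps both
    records and flags the sample "conflict".  Conflicting taxonomy across a
    sample's markers is flagged and the majority (ties: first seen) label
    applied to all of the sample's records.
    """
    log = log if log is not None else CurationLog()
    by_key: dict[tuple[str, str], BarcodeRecord] = {}
    out: list[BarcodeRecord] = []
    conflicted_samples: set[str] = set()
    for r in records:
        key = (r.sample_id, r.marker)
        prior = by_key.get(key)
        if prior is not None:
            if prior.sequence == r.sequence:
                log.add("merge_sample_rows", r.sample_id, f"duplicate {r.marker} row")
                continue
            conflicted_samples.add(r.sample_id)
            log.add(
                "merge_sample_rows", r.sample_id, f"conflicting {r.marker} sequences"
            )
        else:
            by_key[key] = r
        out.append(r)

    # Majority species label per sample across markers.
    by_sample: dict[str, list[int]] = {}
    for i, r in enumerate(out):
        by_sample.setdefault(r.sample_id, []).append(i)
    for sample_id, idxs in by_sample.items():
        names = [out[i].species_name for i in idxs]
        if len(set(names)) > 1:
            majority = max(names, key=lambda n: (names.count(n), -names.index(n)))
            conflicted_samples.add(sample_id)
            log.add(
                "merge_sample_rows",
                sample_id,
                f"taxonomy conflict across markers, majority {majority!r}",
            )
            for i in idxs:
                r = out[i]
                if r.species_name != majority:
                    r = replace(
                        r, species_name=majority, genus=genus_of(majority)
                    )
                out[i] = r.with_flag("taxonomy_conflict")
    for i, r in enumerate(out):
        if r.sample_id in conflicted_samples and "conflict" not in r.flags:
            out[i] = r.with_flag("conflict")
    return Library(out)


def read_synonym_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (old name, new name) -> mapping."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    return {
        normalize_species_name(old): normalize_species_name(new)
        for old, new in zip(frame[0], frame[1])
    }


def _transitive_closure(synonyms: dict[str, str]) -> dict[str, str]:
    closed: dict[str, str] = {}
    for start in synonyms:
        target = synonyms[start]
        seen = {start}
        while target in synonyms:
            if target in seen:
                raise LibraryError(f"cycle in synonym map at {target!r}")
            seen.add(target)
            target = synonyms[target]
        closed[start] = target
    return closed


def apply_taxonomy_updates(
    library: Library,
    synonyms: dict[str, str],
    log: CurationLog | None = None,
) -> Library:
    """Rewrite species names through the transitive closure of the synonym
    map, re-deriving genus; chains A->B, B->C send A to C; cycles are fatal."""
    log = log if log is not None else CurationLog()
    closed = _transitive_closure(synonyms)
    out: list[BarcodeRecord] = []
    for r in library:
        new_name = closed.get(r.species_name)
        if new_name is None or new_name == r.species_name:
            out.append(r)
            continue
        log.add("apply_taxonomy_updates", r.sample_id, f"{r.species_name} -> {new_name}")
        out.append(replace(r, species_name=new_name, genus=genus_of(new_name)))
    return Library(out)


#: Vertebrate mitochondrial stop codons.
MT_STOP_CODONS = frozenset({"TAA", "TAG", "AGA", "AGG"})

_AMBIGUOUS = frozenset("RYSWKMBDHVN?")


def _stops_in_frame(seq: str, frame: int) -> int:
    count = 0
    for i in range(frame, len(seq) - 2, 3):
        if seq[i : i + 3] in MT_STOP_CODONS:
            count += 1
    return count


def numt_screen(records: list[BarcodeRecord], marker: str = "COI") -> dict[str, str]:
    """Screen protein-coding records for pseudogene signatures.

    For each record the forward reading frame (of 3) minimizing internal
    stop codons is chosen; a record is flagged "suspect" if that best frame
    still contains a stop, "unscreenable" if >20% of its sites are
    ambiguity codes, otherwise "ok".
    """
    result: dict[str, str] = {}
    for r in records:
        if r.marker != marker:
            continue
        seq = ungapped(r.sequence)
        ambiguous = sum(1 for c in seq if c in _AMBIGUOUS)
        if ambiguous > 0.2 * len(seq):
            result[r.sample_id] = "unscreenable"
            continue
        best = min(_stops_in_frame(seq, f) for f in range(3))
        result[r.sample_id] = "suspect" if best >= 1 else "ok"
    return result


def summarize_library(library: Library) -> pd.DataFrame:
    """Counts of records per family x marker (wide table with a Total row),
    plus the family's environment class.

    Environment per family is reported as the most frequent class among the
    family's records; per-marker columns count records.
    """
    markers = ["COI", "16S", "ND2"]
    rows: dict[str, dict[str, int]] = {}
    envs: dict[str, list[str]] = {}
    for r in library:
        fam = r.family or "(unknown)"
        row = rows.setdefault(fam, {m: 0 for m in markers})
        if r.marker in row:
            row[r.marker] += 1
        envs.setdefault(fam, []).append(r.environment)
    data = []
    for fam in sorted(rows):
        env_list = [e for e in envs[fam] if e]
        env = max(set(env_list), key=env_list.count) if env_list else ""
        data.append({"family": fam, "environment": env, **rows[fam]})
    frame = pd.DataFrame(data, columns=["family", "environment", *markers])
    total = {"family": "Total", "environment": ""}
    for m in markers:
        total[m] = int(frame[m].sum()) if len(frame) else 0
    return pd.concat([frame, pd.DataFrame([total])], ignore_index=True)


def tally_by(library: Library, attribute: str) -> pd.DataFrame:
    """Record counts grouped by a record attribute (e.g. environment)."""
    counts: dict[str, int] = {}
    for r in library:
        counts[getattr(r, attribute) or "(blank)"] = (
            counts.get(getattr(r, attribute) or "(blank)", 0) + 1
        )
    return pd.DataFrame(
        sorted(counts.items()), columns=[attribute, "n_records"]
    )


def curate(
    records: list[BarcodeRecord],
    anchors: dict[str, str] | None = None,
    country: str | None = "Madagascar",
    whitelist: set[str] | None = None,
    synonyms: dict[str, str] | None = None,
    min_overlap: int = 150,
    min_identity: float = 0.60,
    log: CurationLog | None = None,
) -> Library:
    """Full curation chain: deduplicate, fragment filter, geography filter,
    sample merge, taxonomy update.  Idempotent on its own output."""
    log = log if log is not None else CurationLog()
    records = deduplicate(records, log)
    if anchors:
        records = filter_target_fragment(
            records, anchors, min_overlap, min_identity, log
        )
    if country:
        records = filter_geography(records, country, whitelist, log)
    library = merge_sample_rows(records, log)
    if synonyms:
        library = apply_taxonomy_updates(library, synonyms, log)
    return library
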