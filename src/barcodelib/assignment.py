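"""Threshold-based species assignment against a reference panel, cross-marker
label transfer within samples, and per-locality co-occurrence reports.

Identity between a query and a panel exemplar is ``100 * (1 - p_distance)``
over the compared sites of their pairwise alignment; per species the maximum
identity over its exemplars is used (best-close-match style).  Calls:

* ``assigned`` — best identity >= *assign_thr* (default 99.0%)
* ``cf`` — in [*cf_thr*, *assign_thr*) (default band 97.5–99.0%)
* ``undetermined`` — below *cf_thr*
* ``ambiguous`` — two species within 0.5% identity at the top
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .distances import (
    AlignmentScoring,
    DEFAULT_SCORING,
    orient_sequence,
    p_distance,
    pairwise_align,
)
from .library_model import (
    BarcodeRecord,
    Library,
    genus_of,
    normalize_sequence,
    read_fasta,
)

logger = logging.getLogger(__name__)

AMBIGUITY_BAND_PCT = 0.5


@dataclass(frozen=True)
class PanelEntry:
    species_name: str
    marker: str
    sequence: str
    accession: str = ""


@dataclass
class ReferencePanel:
    """Reliably identified sequences of one marker used for assignment."""

    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("reference panel must have >=1 entry")
        markers = {e.marker for e in self.entries}
        if len(markers) != 1:
            raise ValueError(f"panel mixes markers: {sorted(markers)}")

    @property
    def marker(self) -> str:
        return self.entries[0].marker

    def species(self) -> list[str]:
        return sorted({e.species_name for e in self.entries})

    @classmethod
    def from_fasta(cls, path: str | Path, marker: str) -> "ReferencePanel":
        """Headers are "species|accession" with underscores for spaces."""
        entries = []
        for header, seq in read_fasta(path):
            species, _, accession = header.partition("|")
            entries.append(
                PanelEntry(
                    species_name=species.replace("_", " "),
                    marker=marker,
                    sequence=normalize_sequence(seq),
                    accession=accession,
                )
            )
        return cls(entries)

    @classmethod
    def from_library(cls, library: Library, marker: str) -> "ReferencePanel":
        entries = [
            PanelEntry(r.species_name, r.marker, r.sequence, r.accession)
            for r in library.by_marker(marker)
        ]
        return cls(entries)


@dataclass
class AssignmentResult:
    query_id: str
    best_species: str | None
    best_identity_pct: float | None
    margin_pct: float | None
    call: str  # assigned | cf | undetermined | ambiguous | unalignable


def best_match(
    query: str,
    panel: ReferencePanel,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    normalize_strand: bool = True,
) -> list[tuple[str, float]]:
    """Ranked (species, identity%) list, best first.

    Per species the maximum identity over its exemplars is kept; ties are
    ordered alphabetically by species name.  Empty result means the query
    had zero comparable sites against every exemplar.
    """
    per_species: dict[str, float] = {}
    for entry in panel.entries:
        seq = query
        if normalize_strand:
            seq = orient_sequence(query, entry.sequence)
        a, b, _ = pairwise_align(seq, entry.sequence, scoring)
        dist, compared = p_distance(a, b)
        if dist is None:
            continue
        identity = 100.0 * (1.0 - dist)
        if identity > per_species.get(entry.species_name, -1.0):
            per_species[entry.species_name] = identity
    return sorted(per_species.items(), key=lambda kv: (-kv[1], kv[0]))


def assign_species(
    query_id: str,
    query: str,
    panel: ReferencePanel,
    assign_thr: float = 99.0,
    cf_thr: float = 97.5,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> AssignmentResult:
    """Threshold call for one query sequence against the panel."""
    ranked = best_match(query, panel, scoring)
    if not ranked:
        return AssignmentResult(query_id, None, None, None, "unalignable")
    best_species, best_identity = ranked[0]
    margin = best_identity - ranked[1][1] if len(ranked) > 1 else None
    if margin is not None and margin < AMBIGUITY_BAND_PCT and best_identity >= cf_thr:
        call = "ambiguous"
    elif best_identity >= assign_thr:
        call = "assigned"
    elif best_identity >= cf_thr:
        call = "cf"
    else:
        call = "undetermined"
    return AssignmentResult(query_id, best_species, best_identity, margin, call)


def assign_library(
    library: Library,
    panel: ReferencePanel,
    assign_thr: float = 99.0,
    cf_thr: float = 97.5,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> dict[str, AssignmentResult]:
    """Assign every record of the panel's marker, keyed by sample id."""
    results: dict[str, AssignmentResult] = {}
    for r in library.by_marker(panel.marker):
        results[r.sample_id] = assign_species(
            r.sample_id, r.sequence, panel, assign_thr, cf_thr, scoring
        )
    return results


def _label_for(result: AssignmentResult) -> str | None:
    """Species label implied by an assignment, or None when uninformative."""
    if result.call == "assigned":
        return result.best_species
    if result.call == "cf" and result.best_species:
        genus, _, epithet = result.best_species.partition(" ")
        return f"{genus} cf. {epithet}" if epithet else result.best_species
    if result.call == "undetermined" and result.best_species:
        return f"{genus_of(result.best_species)} sp."
    return None


def transfer_assignments(
    library: Library,
    assignments: dict[str, AssignmentResult],
    assigned_marker: str,
) -> Library:
    """Propagate assignment-derived species labels to the other markers of
    the same sample.

    *assigned_marker* is the marker the assignments were computed on; its
    own records are left untouched.  Unlabelled records (or records whose
    label already matches) of the sample's other markers inherit the label
    with flag ``transferred``; a conflicting existing label is flagged
    ``transfer_conflict`` and not overwritten.  Undetermined assignments
    yield open-nomenclature "Genus sp." lineage labels."""
    out: list[BarcodeRecord] = []
    for r in library:
        result = assignments.get(r.sample_id)
        label = _label_for(result) if result else None
        if label is None or r.marker == assigned_marker:
            out.append(r)
            continue
        if r.species_name and r.species_name != label:
            out.append(r.with_flag("transfer_conflict"))
        elif r.species_name == label:
            out.append(r)
        else:
            out.append(
                replace(
                    r, species_name=label, genus=genus_of(label)
                ).with_flag("transferred")
            )
    return Library(out)


def syntopy_report(
    library: Library,
    assignments: dict[str, AssignmentResult] | None = None,
    coord_decimals: int = 3,
) -> pd.DataFrame:
    """Distinct species/lineages per locality, sorted, with counts.

    Localities are keyed by name, falling back to coordinates rounded to
    *coord_decimals*; records with neither are pooled under "unlocalized".
    When assignments are given they override nominal labels for the assigned
    samples."""
    sites: dict[str, set[str]] = {}
    for r in library:
        if r.locality:
            key = r.locality
        elif r.latitude is not None and r.longitude is not None:
            key = f"{round(r.latitude, coord_decimals)},{round(r.longitude, coord_decimals)}"
        else:
            key = "unlocalized"
        label = r.species_name
        if assignments and r.sample_id in assignments:
            transferred = _label_for(assignments[r.sample_id])
            if transferred:
                label = transferred
        sites.setdefault(key, set()).add(label)
    rows = [
        {
            "locality": site,
            "n_species": len(species),
            "species": "; ".join(sorted(species)),
        }
        for site, species in sorted(sites.items())
    ]
    return pd.DataFrame(rows, columns=["locality", "n_species", "species"])
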