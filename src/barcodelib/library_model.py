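"""Core data types and I/O for tabular barcode libraries, GenBank flatfiles and FASTA.

A *library* is a curated collection of single-marker sequence records, one per
(sample, marker) pair, each carrying taxonomy, environment class, origin
status and locality metadata.  Libraries are serialized as UTF-8 tab-delimited
tables with a header row; per-marker sequence sets are exported as FASTA.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

MARKERS = ("COI", "16S", "ND2")
ENVIRONMENTS = ("F", "FF", "MF", "M")
ORIGIN_STATUSES = ("native", "introduced")
SOURCES = ("genbank", "bold", "new")

#: IUPAC nucleotide codes plus gap symbols; sequences are stored uppercase.
IUPAC_GAP_ALPHABET = frozenset("ACGTRYSWKMBDHVN-?.")

#: Open-nomenclature qualifiers that make a name a distinct terminal taxon.
OPEN_NOMENCLATURE = ("cf.", "sp.", "aff.")

_WS = re.compile(r"\s+")


class LibraryError(Exception):
    """Fatal configuration or consistency error in library handling."""


def normalize_species_name(name: str) -> str:
    """Collapse repeated whitespace in a species name, keep qualifiers."""
    return _WS.sub(" ", name.strip())


def genus_of(species_name: str) -> str:
    """First whitespace-separated token of a (normalized) species name."""
    name = normalize_species_name(species_name)
    return name.split(" ", 1)[0] if name else ""


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map U to T."""
    return seq.strip().upper().replace("U", "T")


def ungapped(seq: str) -> str:
    """Sequence with gap/padding symbols removed."""
    return seq.replace("-", "").replace("?", "").replace(".", "")


@dataclass(frozen=True)
class BarcodeRecord:
    """One sequence of one marker from one sample.

    ``species_name`` may carry an open-nomenclature qualifier ("cf.", "sp.",
    "aff."); such names are treated as distinct terminal taxa throughout.
    """

    sample_id: str
    species_name: str
    genus: str
    family: str
    marker: str
    sequence: str
    environment: str = ""
    origin_status: str = ""
    country: str = ""
    locality: str = ""
    latitude: float | None = None
    longitude: float | None = None
    accession: str = ""
    source: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.sample_id}: empty sequence")
        bad = set(self.sequence) - IUPAC_GAP_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.sample_id}: non-IUPAC symbols {sorted(bad)!r}"
            )
        if self.marker not in MARKERS:
            raise ValueError(
                f"record {self.sample_id}: marker {self.marker!r} not in {MARKERS}"
            )
        if self.genus != genus_of(self.species_name):
            raise ValueError(
                f"record {self.sample_id}: genus {self.genus!r} does not match "
                f"species name {self.species_name!r}"
            )
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"record {self.sample_id}: latitude out of range")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"record {self.sample_id}: longitude out of range")

    @property
    def ungapped_length(self) -> int:
        return len(ungapped(self.sequence))

    def with_flag(self, flag: str) -> "BarcodeRecord":
        if flag in self.flags:
            return self
        return replace(self, flags=self.flags + (flag,))


def make_record(
    sample_id: str,
    species_name: str,
    marker: str,
    sequence: str,
    **kwargs,
) -> BarcodeRecord:
    """Build a record with name/sequence normalization and genus derivation."""
    kwargs.setdefault("family", "")
    species_name = normalize_species_name(species_name)
    return BarcodeRecord(
        sample_id=str(sample_id),
        species_name=species_name,
        genus=genus_of(species_name),
        marker=marker,
        sequence=normalize_sequence(sequence),
        **kwargs,
    )


class Library:
    """Collection of :class:`BarcodeRecord`, indexed by sample id and marker.

    After curation, (sample_id, marker) pairs are unique; construction itself
    does not enforce this so that raw ingests can be curated in place.
    """

    def __init__(self, records: Iterable[BarcodeRecord] = ()) -> None:
        self.records: list[BarcodeRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BarcodeRecord]:
        return iter(self.records)

    def by_marker(self, marker: str) -> list[BarcodeRecord]:
        return [r for r in self.records if r.marker == marker]

    def by_sample(self, sample_id: str) -> list[BarcodeRecord]:
        return [r for r in self.records if r.sample_id == sample_id]

    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.sample_id, None)
        return list(seen)

    def species_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species_name, None)
        return list(seen)

    def markers(self) -> list[str]:
        return [m for m in MARKERS if any(r.marker == m for r in self.records)]

    def subset(self, predicate) -> "Library":
        return Library(r for r in self.records if predicate(r))


#: Default header-name mapping for the tabular format.  Keys are canonical
#: field names, values are accepted column names (first match wins).
DEFAULT_COLUMN_MAP: dict[str, tuple[str, ...]] = {
    "sample_id": ("sample_id", "specimenid", "specimen_id", "sample", "voucher"),
    "species_name": ("species_name", "species", "organism", "taxon"),
    "family": ("family",),
    "marker": ("marker", "gene", "locus"),
    "sequence": ("sequence", "seq", "nucleotides"),
    "environment": ("environment", "env", "habitat"),
    "origin_status": ("origin_status", "origin", "status"),
    "country": ("country",),
    "locality": ("locality", "isolation_source", "site"),
    "latitude": ("latitude", "lat"),
    "longitude": ("longitude", "lon", "long"),
    "accession": ("accession", "genbank_accession", "accession_number"),
    "source": ("source", "database"),
}

MANDATORY_FIELDS = ("sample_id", "species_name", "family", "marker", "sequence")

_TABLE_COLUMNS = (
    "sample_id",
    "species_name",
    "genus",
    "family",
    "marker",
    "sequence",
    "environment",
    "origin_status",
    "country",
    "locality",
    "latitude",
    "longitude",
    "accession",
    "source",
    "flags",
)


def _resolve_columns(
    header: Sequence[str], column_map: Mapping[str, tuple[str, ...]]
) -> dict[str, str]:
    lower = {h.strip().lower(): h for h in header}
    resolved: dict[str, str] = {}
    for canon, aliases in column_map.items():
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    missing = [f for f in MANDATORY_FIELDS if f not in resolved]
    if missing:
        raise LibraryError(f"mandatory column(s) missing from table: {missing}")
    return resolved


def _parse_coordinate(value, low: float, high: float) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip().rstrip("°")
    if not text:
        return None
    coord = float(text)  # raises ValueError for malformed input
    if not low <= coord <= high:
        raise ValueError(f"coordinate {coord} outside [{low}, {high}]")
    return coord


def read_library_table(
    path: str | Path,
    column_map: Mapping[str, tuple[str, ...]] | None = None,
) -> Library:
    """Read a tab-delimited library table into a :class:`Library`.

    Rows with an empty sequence are rejected with a logged reason; malformed
    coordinates are dropped (record kept) with a warning.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(frame.columns, column_map or DEFAULT_COLUMN_MAP)

    records: list[BarcodeRecord] = []
    for i, row in frame.iterrows():
        def get(canon: str, default: str = "") -> str:
            col = cols.get(canon)
            return str(row[col]).strip() if col is not None else default

        sequence = normalize_sequence(get("sequence"))
        if not sequence:
            logger.warning("row %d (%s): empty sequence, rejected", i, get("sample_id"))
            continue
        lat = lon = None
        try:
            lat = _parse_coordinate(get("latitude") or None, -90, 90)
            lon = _parse_coordinate(get("longitude") or None, -180, 180)
        except ValueError as exc:
            logger.warning(
                "row %d (%s): malformed coordinates dropped (%s)", i, get("sample_id"), exc
            )
            lat = lon = None
        flags = tuple(f for f in get("flags").split(";") if f)
        records.append(
            make_record(
                sample_id=get("sample_id"),
                species_name=get("species_name"),
                marker=get("marker"),
                sequence=sequence,
                family=get("family"),
                environment=get("environment"),
                origin_status=get("origin_status"),
                country=get("country"),
                locality=get("locality"),
                latitude=lat,
                longitude=lon,
                accession=get("accession"),
                source=get("source"),
                flags=flags,
            )
        )
    return Library(records)


def library_to_frame(library: Library) -> pd.DataFrame:
    """Library as a pandas DataFrame with the canonical column set."""
    rows = []
    for r in library:
        rows.append(
            {
                "sample_id": r.sample_id,
                "species_name": r.species_name,
                "genus": r.genus,
                "family": r.family,
                "marker": r.marker,
                "sequence": r.sequence,
                "environment": r.environment,
                "origin_status": r.origin_status,
                "country": r.country,
                "locality": r.locality,
                "latitude": "" if r.latitude is None else repr(r.latitude),
                "longitude": "" if r.longitude is None else repr(r.longitude),
                "accession": r.accession,
                "source": r.source,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_library_table(library: Library, path: str | Path) -> None:
    """Write the canonical tab-delimited table (UTF-8, header row)."""
    library_to_frame(library).to_csv(path, sep="\t", index=False, encoding="utf-8")


# --- GenBank flatfiles -----------------------------------------------------

#: Keyword map from gene/product qualifier text to marker id (lowercased
#: substring match, first hit wins).
DEFAULT_MARKER_KEYWORDS: tuple[tuple[str, str], ...] = (
    ("cox1", "COI"),
    ("coi", "COI"),
    ("co1", "COI"),
    ("cytochrome c oxidase subunit 1", "COI"),
    ("cytochrome oxidase subunit 1", "COI"),
    ("cytochrome c oxidase subunit i", "COI"),
    ("cytochrome oxidase subunit i", "COI"),
    ("16s", "16S"),
    ("nd2", "ND2"),
    ("nadh dehydrogenase subunit 2", "ND2"),
    ("nadh dehydrogenase 2", "ND2"),
)


def _infer_marker(texts: Iterable[str], keywords=DEFAULT_MARKER_KEYWORDS) -> str:
    for text in texts:
        low = text.lower()
        for key, marker in keywords:
            if key in low:
                return marker
    return "unknown"


def read_genbank_flatfile(
    path: str | Path,
    marker_keywords=DEFAULT_MARKER_KEYWORDS,
    source: str = "genbank",
) -> list[BarcodeRecord]:
    """Parse a GenBank flatfile into records (one per LOCUS entry, input order).

    The organism qualifier becomes the species name; ``/country`` (or the
    newer ``/geo_loc_name``) is split on the first colon into country and
    locality, with ``/isolation_source`` as a locality fallback.  Marker is
    inferred from gene/product qualifiers; records with no inferable marker
    are emitted with marker ``"unknown"`` via a plain dict so callers can
    exclude them downstream.
    """
    records: list[BarcodeRecord] = []
    for entry in SeqIO.parse(str(path), "genbank"):
        try:
            seq = str(entry.seq)
        except Exception:  # undefined sequence (no ORIGIN block)
            seq = ""
        if not seq or set(seq) == {"N"}:
            logger.warning("%s: no ORIGIN sequence, skipped", entry.id)
            continue
        organism = ""
        country = locality = ""
        isolation_source = ""
        lat = lon = None
        gene_texts: list[str] = []
        for feat in entry.features:
            quals = feat.qualifiers
            if feat.type == "source":
                organism = quals.get("organism", [""])[0]
                geo = quals.get("country", quals.get("geo_loc_name", [""]))[0]
                if geo:
                    country, _, locality = (p.strip() for p in geo.partition(":"))
                isolation_source = quals.get("isolation_source", [""])[0]
                lat_lon = quals.get("lat_lon", [""])[0]
                if lat_lon:
                    lat, lon = _parse_lat_lon(lat_lon)
            gene_texts.extend(quals.get("gene", []))
            gene_texts.extend(quals.get("product", []))
        gene_texts.append(entry.description)
        marker = _infer_marker(gene_texts, marker_keywords)
        if marker == "unknown":
            logger.warning("%s: unmappable gene name, marker set 'unknown'", entry.id)
            continue
        records.append(
            make_record(
                sample_id=entry.id,
                species_name=organism,
                marker=marker,
                sequence=seq,
                family="",
                country=country,
                locality=locality or isolation_source,
                latitude=lat,
                longitude=lon,
                accession=entry.id,
                source=source,
            )
        )
    return records


def _parse_lat_lon(text: str) -> tuple[float | None, float | None]:
    m = re.match(r"([\d.]+)\s*([NS])\s+([\d.]+)\s*([EW])", text.strip())
    if not m:
        return None, None
    lat = float(m.group(1)) * (1 if m.group(2) == "N" else -1)
    lon = float(m.group(3)) * (1 if m.group(4) == "E" else -1)
    return lat, lon


# --- FASTA -----------------------------------------------------------------

def fasta_header(record: BarcodeRecord) -> str:
    """``sample_id|species_name|accession`` with spaces as underscores."""
    return "|".join(
        part.replace(" ", "_")
        for part in (record.sample_id, record.species_name, record.accession)
    )


def write_fasta(library: Library, marker: str, path: str | Path, width: int = 80) -> int:
    """Write one FASTA entry per record of *marker*; returns the entry count.

    Gaps in pre-aligned sequences are written verbatim.
    """
    records = library.by_marker(marker)
    if not records:
        logger.warning("no records of marker %s; writing empty FASTA", marker)
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f">{fasta_header(r)}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")
    return len(records)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; id is the full header line minus '>'."""
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.description, str(rec.seq)))
    return out
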