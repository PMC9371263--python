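"""Seeded generator of barcode libraries, reference panels and truth tables.

The generator emulates a curated multi-marker library with nested taxonomy
(family > genus > species > samples) and three divergence strata: it evolves
sequences down a star-of-stars hierarchy under independent-site,
Jukes–Cantor-style substitution, with branch rates calibrated so that the
*expected* uncorrected p-distance of each pair class hits its configured
target (multiple hits saturate towards 0.75).

Optional anomalies mirror the failure modes a barcode-library audit must
detect: a shared haplotype between two nominal species, a deep intraspecific
split, and an orphan lineage distant from every reference-panel exemplar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assignment import PanelEntry, ReferencePanel
from .library_model import BarcodeRecord, Library, make_record

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "AGA", "AGG"}
_SAFE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)


def expected_p_distance(rate: float) -> float:
    """Expected p-distance after *rate* substitutions/site (JC saturation)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return 0.75 * (1.0 - math.exp(-4.0 * rate / 3.0))


def rate_for_p_distance(target: float) -> float:
    """Inverse of :func:`expected_p_distance`; fatal for targets >= 0.75."""
    if not 0.0 <= target < 0.75:
        raise ValueError(f"target p-distance {target} unreachable (must be < 0.75)")
    return -0.75 * math.log(1.0 - 4.0 * target / 3.0)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 42
    n_families: int = 2
    n_genera_per_family: int = 2
    n_species_per_genus: int = 3
    n_samples_per_species: int = 4
    seq_length: int = 600
    d_w: float = 0.01  # expected intraspecific p-distance
    d_c: float = 0.06  # expected congeneric interspecific p-distance
    d_g: float = 0.20  # expected intergeneric p-distance
    marker: str = "COI"
    n_sites: int = 6
    shared_haplotype_pair: bool = False
    deep_split_species: bool = False
    deep_split_depth: float = 0.04  # p-distance between sub-clusters (exact)
    orphan_lineage: bool = False
    orphan_distance: float = 0.10  # expected p-distance to nearest panel exemplar
    orphan_n_samples: int = 2
    truncate_range: tuple[int, int] | None = None  # e.g. (245, 700)

    def __post_init__(self) -> None:
        if not (0.0 <= self.d_w < self.d_c < self.d_g <= 0.75):
            raise ValueError("require 0 <= d_w < d_c < d_g <= 0.75")
        for name in (
            "n_families",
            "n_genera_per_family",
            "n_species_per_genus",
            "n_samples_per_species",
            "seq_length",
            "n_sites",
            "orphan_n_samples",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.deep_split_species and self.deep_split_depth <= self.d_w:
            raise ValueError("deep_split_depth must exceed d_w")


@dataclass
class TruthTable:
    """Ground truth for every emitted record and site."""

    records: pd.DataFrame  # sample_id, true_species, cluster_id, anomaly
    sites: pd.DataFrame  # site, species (sorted, ';'-joined)

    def anomalous(self, tag: str) -> list[str]:
        mask = self.records["anomaly"].str.contains(tag, regex=False)
        return list(self.records.loc[mask, "sample_id"])

    def species_of(self, tag: str) -> list[str]:
        mask = self.records["anomaly"].str.contains(tag, regex=False)
        return sorted(set(self.records.loc[mask, "true_species"]))


def _random_root(rng: np.random.Generator, length: int) -> str:
    """Codon-structured random sequence with no frame-1 stop codons."""
    n_codons, remainder = divmod(length, 3)
    codons = rng.choice(len(_SAFE_CODONS), size=n_codons)
    tail = "".join(rng.choice(list(_BASES), size=remainder))
    return "".join(_SAFE_CODONS[i] for i in codons) + tail


def _evolve(seq: str, rate: float, rng: np.random.Generator, frame_safe: bool) -> str:
    """One JC branch: each site stays with prob 1/4 + 3/4·exp(-4r/3), else
    moves to a different base (uniform over the three alternatives).

    With *frame_safe*, a changing site picks among the alternatives that do
    not create a frame-1 stop codon in the current sequence context, so the
    per-site substitution probability -- and hence the expected p-distance
    calibration -- is preserved while keeping coding frames open.
    """
    p_stay = 0.25 + 0.75 * math.exp(-4.0 * rate / 3.0)
    out = list(seq)
    n = len(seq)
    u = rng.random(n)
    picks = rng.integers(0, 3, size=n)
    for i in range(n):
        if u[i] < p_stay:
            continue
        others = [b for b in _BASES if b != out[i]]
        rotated = others[picks[i] :] + others[: picks[i]]
        if not frame_safe:
            out[i] = rotated[0]
            continue
        start = (i // 3) * 3
        for candidate in rotated:
            if start + 3 <= n:
                codon = out[start : start + 3]
                codon[i - start] = candidate
                if "".join(codon) in _STOPS:
                    continue
            out[i] = candidate
            break
    return "".join(out)


def _mutate_sites(
    seq: str, positions: list[int], rng: np.random.Generator, frame_safe: bool
) -> str:
    """Substitute a different base at each listed position; with *frame_safe*
    replacement bases creating frame-1 stop codons are avoided (a position is
    left unchanged in the vanishingly rare case that all three would)."""
    out = list(seq)
    for i in positions:
        choices = [b for b in _BASES if b != out[i]]
        order = rng.permutation(3)
        for idx in order:
            candidate = choices[int(idx)]
            if frame_safe:
                start = (i // 3) * 3
                if start + 3 <= len(out):
                    codon = out[start:start + 3]
                    codon[i - start] = candidate
                    if "".join(codon) in _STOPS:
                        continue
            out[i] = candidate
            break
    return "".join(out)


def simulate_library(
    config: SimulationConfig,
) -> tuple[Library, ReferencePanel, TruthTable]:
    """Simulate a library, a one-exemplar-per-species panel and ground truth.

    Branch rates along root -> genus -> species -> sample are chosen so the
    expected pairwise p-distances equal (d_w, d_c, d_g) for the three pair
    classes.  Panel exemplars are the species-ancestor sequences; anomalies
    (never represented in the panel) are injected per the config switches.
    Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    frame_safe = config.marker == "COI"
    t_w = rate_for_p_distance(config.d_w)
    t_c = rate_for_p_distance(config.d_c)
    t_g = rate_for_p_distance(config.d_g)
    branch_sample = t_w / 2.0
    branch_species = (t_c - t_w) / 2.0
    branch_genus = (t_g - t_c) / 2.0

    root = _random_root(rng, config.seq_length)
    records: list[BarcodeRecord] = []
    panel_entries: list[PanelEntry] = []
    truth_rows: list[dict] = []
    sites = [f"site_{i + 1:02d}" for i in range(config.n_sites)]
    site_coords = {
        s: (
            round(float(rng.uniform(-25.0, -12.0)), 5),
            round(float(rng.uniform(43.0, 50.0)), 5),
        )
        for s in sites
    }

    # Taxonomy scaffold: genera are globally unique, star-spaced at d_g.
    genus_names: list[tuple[str, str]] = []  # (family, genus)
    idx = 0
    for f in range(config.n_families):
        family = f"Family{f + 1}"
        for g in range(config.n_genera_per_family):
            genus_names.append((family, f"Genus{chr(65 + idx)}"))
            idx += 1

    genus_anc = {
        genus: _evolve(root, branch_genus, rng, frame_safe)
        for _, genus in genus_names
    }

    species_list: list[tuple[str, str, str, str]] = []  # family, genus, species, anc
    for family, genus in genus_names:
        for s in range(config.n_species_per_genus):
            anc = _evolve(genus_anc[genus], branch_species, rng, frame_safe)
            species_list.append((family, genus, f"{genus} species{s + 1}", anc))

    # Anomaly: shared haplotype between the first two species of the first
    # genus -- their ancestors coincide and one sample is copied verbatim.
    shared_pair: tuple[str, str] | None = None
    if config.shared_haplotype_pair:
        if config.n_species_per_genus < 2:
            raise ValueError("shared_haplotype_pair requires >=2 species per genus")
        fam0, gen0, name0, anc0 = species_list[0]
        fam1, gen1, name1, _ = species_list[1]
        species_list[1] = (fam1, gen1, name1, anc0)
        shared_pair = (name0, name1)

    # Anomaly: deep split inside the last species (different genus than the
    # shared pair whenever there are >=2 genera).
    # The deep split is a constructed anomaly: substitutions are placed on
    # exactly counted, mutually disjoint site sets so the realized distances
    # are deterministic -- sub-clusters sit symmetrically at depth/2 from the
    # species ancestor (= the panel exemplar) and exactly `depth` apart,
    # while intra-cluster pairs sit exactly at d_w.
    deep_species_name: str | None = None
    deep_ancs: tuple[str, str] | None = None
    deep_sample_sites: list[list[int]] = []
    if config.deep_split_species:
        if config.n_samples_per_species < 2:
            raise ValueError("deep_split_species requires >=2 samples per species")
        deep_species_name = species_list[-1][2]
        length = config.seq_length
        n_w = max(1, round(length * config.d_w / 2))
        n_half = max(1, round(length * (config.deep_split_depth - config.d_w) / 2))
        needed = 2 * n_half + config.n_samples_per_species * n_w
        if needed > length:
            raise ValueError("deep_split_depth too large for sequence length")
        perm = [int(i) for i in rng.permutation(length)]
        block_a = perm[:n_half]
        block_b = perm[n_half : 2 * n_half]
        offset = 2 * n_half
        for _ in range(config.n_samples_per_species):
            deep_sample_sites.append(perm[offset : offset + n_w])
            offset += n_w
        deep_root = species_list[-1][3]
        deep_ancs = (
            _mutate_sites(deep_root, block_a, rng, frame_safe),
            _mutate_sites(deep_root, block_b, rng, frame_safe),
        )

    sample_counter = 0

    def next_sample_id() -> str:
        nonlocal sample_counter
        sample_counter += 1
        return f"S{sample_counter:04d}"

    copy_from: str | None = None
    for family, genus, species_name, anc in species_list:
        panel_entries.append(
            PanelEntry(
                species_name=species_name,
                marker=config.marker,
                sequence=anc,
                accession=f"PANEL{len(panel_entries) + 1:03d}",
            )
        )
        for k in range(config.n_samples_per_species):
            anomaly = []
            cluster = 0
            if species_name == deep_species_name:
                cluster = int(k >= config.n_samples_per_species // 2)
                seq = _mutate_sites(
                    deep_ancs[cluster], deep_sample_sites[k], rng, frame_safe
                )
                anomaly.append("deep_split")
            else:
                seq = _evolve(anc, branch_sample, rng, frame_safe)
            sample_id = next_sample_id()
            if shared_pair and species_name == shared_pair[0] and k == 0:
                copy_from = seq
                anomaly.append("shared_haplotype")
            if shared_pair and species_name == shared_pair[1]:
                anomaly.append("shared_haplotype")
                if k == 0 and copy_from is not None:
                    seq = copy_from  # exact zero-distance cross pair
            site = sites[int(rng.integers(0, config.n_sites))]
            if config.truncate_range is not None:
                lo, hi = config.truncate_range
                target_len = int(rng.integers(lo, min(hi, len(seq)) + 1))
                start = int(rng.integers(0, len(seq) - target_len + 1))
                seq = seq[start : start + target_len]
            lat, lon = site_coords[site]
            records.append(
                make_record(
                    sample_id=sample_id,
                    species_name=species_name,
                    marker=config.marker,
                    sequence=seq,
                    family=family,
                    environment="F",
                    origin_status="native",
                    country="Madagascar",
                    locality=site,
                    latitude=lat,
                    longitude=lon,
                    source="new",
                )
            )
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "true_species": species_name,
                    "cluster_id": cluster,
                    "anomaly": ";".join(anomaly),
                    "site": site,
                }
            )

    # Anomaly: orphan lineage, nominally "<first genus> sp.", evolved off the
    # first genus ancestor so its expected distance to that genus's panel
    # exemplars equals orphan_distance; absent from the panel.
    if config.orphan_lineage:
        t_orph = rate_for_p_distance(config.orphan_distance) - branch_species
        if t_orph <= 0:
            raise ValueError("orphan_distance must exceed half the congeneric target")
        family0, genus0 = genus_names[0]
        orphan_name = f"{genus0} sp."
        orphan_anc = _evolve(genus_anc[genus0], t_orph, rng, frame_safe)
        for _ in range(config.orphan_n_samples):
            seq = _evolve(orphan_anc, branch_sample, rng, frame_safe)
            sample_id = next_sample_id()
            site = sites[int(rng.integers(0, config.n_sites))]
            lat, lon = site_coords[site]
            records.append(
                make_record(
                    sample_id=sample_id,
                    species_name=orphan_name,
                    marker=config.marker,
                    sequence=seq,
                    family=family0,
                    environment="F",
                    origin_status="introduced",
                    country="Madagascar",
                    locality=site,
                    latitude=lat,
                    longitude=lon,
                    source="new",
                )
            )
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "true_species": orphan_name,
                    "cluster_id": 0,
                    "anomaly": "orphan",
                    "site": site,
                }
            )

    truth_records = pd.DataFrame(
        truth_rows, columns=["sample_id", "true_species", "cluster_id", "anomaly", "site"]
    )
    site_truth = (
        truth_records.groupby("site")["true_species"]
        .apply(lambda s: "; ".join(sorted(set(s))))
        .reset_index()
        .rename(columns={"true_species": "species"})
    )
    truth = TruthTable(records=truth_records, sites=site_truth)
    return Library(records), ReferencePanel(panel_entries), truth


def write_truth_table(truth: TruthTable, records_path, sites_path) -> None:
    truth.records.to_csv(records_path, sep="\t", index=False)
    truth.sites.to_csv(sites_path, sep="\t", index=False)
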