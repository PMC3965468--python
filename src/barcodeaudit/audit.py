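"""Species-level diagnosability audit of a barcode reference library.

Given pairwise K2P distances, species labels and a BIN-proxy cluster
partition, this module classifies every species along the axes a
reference-library study reports:

* **sharing** — the species possesses a barcode haplotype identical (within
  ``sharing_epsilon``) to another species', so specimens cannot be assigned
  unambiguously; sharing species form *assemblages*, the connected
  components of the species-level sharing graph.
* **low divergence** — diagnosable, but nearest-neighbour distance below
  ``t_low`` (default 2%).
* **deep divergence** — maximum intraspecific distance above ``t_deep``
  (default 2%), a cryptic-structure signal.
* **concordance** — MATCH (one private cluster), SPLIT (several private
  clusters), MERGE (single cluster shared with another species), MIXED
  (split and shared).

Identification success is the percentage of species not involved in
sharing; evaluated nationally and per region, where sharing is recomputed
within the regional species pool (a pair shares regionally only if both
species occur in the region).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .clustering import ClusterPartition, single_linkage_clusters
from .distances import DistanceMatrix, SpeciesSummary, species_summaries
from .errors import ValidationError
from .library_io import ReferenceLibrary


@dataclass(frozen=True)
class AuditConfig:
    """Thresholds of the audit, all in percent (sites for ``min_overlap``)."""

    t_deep: float = 2.0
    t_low: float = 2.0
    sharing_epsilon: float = 0.0
    cluster_threshold: float = 2.2
    min_overlap: int = 300

    def __post_init__(self) -> None:
        for name in ("t_deep", "t_low", "sharing_epsilon", "cluster_threshold"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


class Concordance(str, Enum):
    MATCH = "MATCH"
    SPLIT = "SPLIT"
    MERGE = "MERGE"
    MIXED = "MIXED"


@dataclass
class SpeciesAudit:
    species: str
    sharing: bool
    sharing_partners: list[str]
    low_divergence: bool
    deep_divergence: bool
    n_clusters: int
    concordance: Concordance

    def __post_init__(self) -> None:
        if self.sharing and not self.sharing_partners:
            raise ValidationError(
                f"{self.species}: sharing flagged without partners"
            )


def min_interspecific_distances(
    matrix: DistanceMatrix, species_map: dict[str, str]
) -> pd.DataFrame:
    """Species × species matrix of minimum between-species specimen distances."""
    species_of = np.array([species_map[l] for l in matrix.labels])
    uniq = sorted(set(species_of.tolist()))
    out = pd.DataFrame(np.inf, index=uniq, columns=uniq)
    vals = np.where(np.isnan(matrix.values), np.inf, matrix.values)
    for i, sp_a in enumerate(uniq):
        ia = np.nonzero(species_of == sp_a)[0]
        for sp_b in uniq[i + 1 :]:
            ib = np.nonzero(species_of == sp_b)[0]
            m = float(np.min(vals[np.ix_(ia, ib)]))
            out.loc[sp_a, sp_b] = out.loc[sp_b, sp_a] = m
    return out


def detect_sharing(
    matrix: DistanceMatrix,
    species_map: dict[str, str],
    config: AuditConfig = AuditConfig(),
) -> list[set[str]]:
    """Sharing assemblages: connected components of the species graph whose
    edges join species pairs with minimum interspecific distance at or below
    ``sharing_epsilon`` (default 0, i.e. identical haplotypes)."""
    min_inter = min_interspecific_distances(matrix, species_map)
    species = list(min_inter.index)
    parent = {s: s for s in species}

    def find(s: str) -> str:
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            if min_inter.loc[a, b] <= config.sharing_epsilon:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for s in species:
        groups.setdefault(find(s), set()).add(s)
    return sorted(
        (g for g in groups.values() if len(g) > 1), key=lambda g: sorted(g)[0]
    )


def detect_overlap(
    matrix: DistanceMatrix,
    species_map: dict[str, str],
    summaries: list[SpeciesSummary],
) -> list[tuple[str, str]]:
    """Relaxed two-tier flag: species pairs whose minimum interspecific
    distance is below the maximum intraspecific distance of either species
    (overlapping, though not necessarily identical, haplotype clouds).
    Reported separately from sharing; never folded into the success metric."""
    min_inter = min_interspecific_distances(matrix, species_map)
    max_intra = {s.species: s.max_intra for s in summaries}
    pairs = []
    species = list(min_inter.index)
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            cap = np.nanmax([max_intra.get(a, np.nan), max_intra.get(b, np.nan)])
            if not math.isnan(cap) and min_inter.loc[a, b] < cap:
                pairs.append((a, b))
    return pairs


def classify_species(
    summaries: list[SpeciesSummary],
    sharing_groups: list[set[str]],
    partition: ClusterPartition,
    species_map: dict[str, str],
    config: AuditConfig = AuditConfig(),
) -> list[SpeciesAudit]:
    """Assign every species its diagnosability flags and concordance class."""
    partners: dict[str, set[str]] = {}
    for group in sharing_groups:
        for sp in group:
            partners[sp] = group - {sp}

    clusters_of_species: dict[str, set[int]] = {}
    species_in_cluster: dict[int, set[str]] = {}
    for specimen, cluster in partition.assignment.items():
        if specimen not in species_map:
            raise ValidationError(f"specimen {specimen!r} missing from species map")
        sp = species_map[specimen]
        clusters_of_species.setdefault(sp, set()).add(cluster)
        species_in_cluster.setdefault(cluster, set()).add(sp)

    audits = []
    for s in sorted(summaries, key=lambda x: x.species):
        if s.species not in clusters_of_species:
            raise ValidationError(
                f"species {s.species!r} absent from cluster partition"
            )
        own = clusters_of_species[s.species]
        n_clusters = len(own)
        any_shared = any(len(species_in_cluster[c]) > 1 for c in own)
        if n_clusters == 1:
            concordance = Concordance.MERGE if any_shared else Concordance.MATCH
        else:
            concordance = Concordance.MIXED if any_shared else Concordance.SPLIT
        sharing = s.species in partners
        audits.append(
            SpeciesAudit(
                species=s.species,
                sharing=sharing,
                sharing_partners=sorted(partners.get(s.species, set())),
                low_divergence=(
                    not sharing
                    and not math.isnan(s.nn_dist)
                    and 0.0 < s.nn_dist < config.t_low
                ),
                deep_divergence=(
                    not math.isnan(s.max_intra) and s.max_intra > config.t_deep
                ),
                n_clusters=n_clusters,
                concordance=concordance,
            )
        )
    return audits


@dataclass
class AuditSummary:
    """Library-wide aggregate of the per-species audit."""

    n_species: int
    n_sharing: int
    pct_id_success: float
    n_match: int
    n_split: int
    n_merge: int
    n_mixed: int
    n_deep: int
    n_low_divergence: int
    cluster_count_histogram: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_match + self.n_split + self.n_merge + self.n_mixed != self.n_species:
            raise ValidationError("concordance classes must partition the species set")


def identification_success(n_species: int, n_sharing: int) -> float:
    """Percent of species diagnosable by barcodes: 100·(1 − sharing/species)."""
    if n_species == 0:
        return float("nan")
    return 100.0 * (n_species - n_sharing) / n_species


def concordance_counts(audits: list[SpeciesAudit]) -> AuditSummary:
    """Aggregate audit flags into the Table-8-style summary."""
    n_species = len(audits)
    n_sharing = sum(a.sharing for a in audits)
    by_class = {c: 0 for c in Concordance}
    hist: dict[int, int] = {}
    for a in audits:
        by_class[a.concordance] += 1
        hist[a.n_clusters] = hist.get(a.n_clusters, 0) + 1
    return AuditSummary(
        n_species=n_species,
        n_sharing=n_sharing,
        pct_id_success=identification_success(n_species, n_sharing),
        n_match=by_class[Concordance.MATCH],
        n_split=by_class[Concordance.SPLIT],
        n_merge=by_class[Concordance.MERGE],
        n_mixed=by_class[Concordance.MIXED],
        n_deep=sum(a.deep_divergence for a in audits),
        n_low_divergence=sum(a.low_divergence for a in audits),
        cluster_count_histogram=dict(sorted(hist.items())),
    )


def regional_success(
    library: ReferenceLibrary,
    matrix: DistanceMatrix,
    config: AuditConfig = AuditConfig(),
    regions: list[str] | None = None,
) -> dict[str, tuple[float, int, int]]:
    """Identification success per region.

    Sharing is recomputed within each regional species pool: only specimens
    collected in the region enter the distance comparison, so a species pair
    can share nationally yet be diagnosable in a region where one partner is
    absent.  Returns region → (percent success, n diagnosable, n species).
    """
    present = sorted({r.region for r in library.records if r.region != "unknown"})
    if regions is None:
        regions = present
    unknown = [r for r in regions if r not in present]
    out: dict[str, tuple[float, int, int]] = {}
    for region in regions:
        if region in unknown:
            continue
        idx = [
            i for i, rec in enumerate(library.records) if rec.region == region
        ]
        labels = [library.specimen_ids[i] for i in idx]
        sub = DistanceMatrix(
            labels=labels,
            values=matrix.values[np.ix_(idx, idx)],
            overlaps=matrix.overlaps[np.ix_(idx, idx)],
            saturated=matrix.saturated[np.ix_(idx, idx)],
        )
        species_map = {l: library.species_map[l] for l in labels}
        n_species = len(set(species_map.values()))
        groups = detect_sharing(sub, species_map, config)
        n_sharing = sum(len(g) for g in groups)
        out[region] = (
            identification_success(n_species, n_sharing),
            n_species - n_sharing,
            n_species,
        )
    return out


def genus_size_sharing(
    audits: list[SpeciesAudit], genus_map: dict[str, str]
) -> tuple[pd.DataFrame, tuple[list[int], list[float]]]:
    """Genus-size structure of sharing incidence.

    Bins genera by floor(log2(number of species)) and reports, per bin, the
    number of genera and species and the percentage of species in sharing
    groups.  Also returns per-genus vectors (genus size, fraction of the
    genus' species that share) for a rank-correlation test.
    """
    for a in audits:
        if a.species not in genus_map:
            raise ValidationError(f"species {a.species!r} has no genus label")
    by_genus: dict[str, list[SpeciesAudit]] = {}
    for a in audits:
        by_genus.setdefault(genus_map[a.species], []).append(a)
    sizes: list[int] = []
    incidences: list[float] = []
    rows = []
    for genus in sorted(by_genus):
        members = by_genus[genus]
        size = len(members)
        share = sum(m.sharing for m in members)
        sizes.append(size)
        incidences.append(share / size)
        rows.append((genus, size, share, int(math.floor(math.log2(size)))))
    per_genus = pd.DataFrame(rows, columns=["genus", "n_species", "n_sharing", "bin"])
    table = (
        per_genus.groupby("bin")
        .agg(
            n_genera=("genus", "size"),
            n_species=("n_species", "sum"),
            n_sharing=("n_sharing", "sum"),
        )
        .reset_index()
    )
    table["pct_sharing"] = 100.0 * table["n_sharing"] / table["n_species"]
    return table, (sizes, incidences)


def run_full_audit(
    library: ReferenceLibrary,
    config: AuditConfig = AuditConfig(),
) -> tuple[list[SpeciesAudit], AuditSummary, list[SpeciesSummary], DistanceMatrix, ClusterPartition]:
    """Distances → summaries → sharing → clustering → classification, in one call."""
    from .distances import distance_matrix

    matrix = distance_matrix(library, min_overlap=config.min_overlap)
    summaries = species_summaries(matrix, library.species_map)
    groups = detect_sharing(matrix, library.species_map, config)
    partition = single_linkage_clusters(matrix, config.cluster_threshold)
    audits = classify_species(
        summaries, groups, partition, library.species_map, config
    )
    return audits, concordance_counts(audits), summaries, matrix, partition


def audits_frame(audits: list[SpeciesAudit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": a.species,
                "sharing": a.sharing,
                "sharing_partners": ";".join(a.sharing_partners),
                "low_divergence": a.low_divergence,
                "deep_divergence": a.deep_divergence,
                "n_clusters": a.n_clusters,
                "concordance": a.concordance.value,
            }
            for a in audits
        ]
    )
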