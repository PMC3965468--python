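"""Synthetic barcode libraries with known ground truth.

The generator emulates the structure a reference-library audit assumes:
tight within-species haplotype clouds, well-separated congeners, occasional
haplotype sharing between congeners (as after mitochondrial introgression),
deep intraspecific splits (a second cloud at a known offset), regional
species pools, and origin/host-plant trait labels.

Sequences evolve along a star-of-stars genealogy: a root sequence spawns
genus ancestors, genus ancestors spawn species ancestors, species ancestors
spawn specimen haplotypes.  Substitutions are applied per site with
independent transition/transversion rates (ratio ``ts_tv_ratio``), so the
K2P estimator is matched to the generating process.  Branch "lengths" are
expressed as the expected *pairwise* divergence they induce: a specimen
sits ``intra_divergence/2`` from its species ancestor so conspecific pairs
sit about ``intra_divergence`` apart, and similarly for congeners.

A sharing event replaces one congener's ancestral haplotype with the
donor's and copies one specimen verbatim, guaranteeing an identical shared
haplotype.  Mutations that would create an in-frame stop codon (TAA/TAG
under the invertebrate mitochondrial code) are deterministically reverted
at the third codon position so every emitted sequence passes the
reading-frame QC filter; at the divergences used here this touches a
handful of sites per species and does not visibly bias realized distances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .audit import SpeciesAudit
from .errors import ValidationError
from .library_io import ReferenceLibrary, SequenceRecord, _pad_to_common_frame

_BASES = "ACGT"
# encoded codons that are stops under the invertebrate mito code
_STOP_CODONS = {(3, 0, 0), (3, 0, 2)}  # TAA, TAG

_DEFAULT_REGIONS = {"WEST": 0.5, "CENTRAL": 0.6, "EAST": 0.4}
_DEFAULT_HOSTS = {
    "grass_herb": 0.38,
    "tree_shrub": 0.38,
    "detritus_fungi_lichen": 0.06,
    "generalist": 0.18,
}


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic library; divergences in percent."""

    n_species: int = 100
    seqs_per_species: tuple[int, int] = (10, 10)
    seq_length: int = 658
    intra_divergence: float = 0.3
    inter_divergence: float = 8.0
    n_genera: int = 25
    n_families: int = 3
    p_share: float = 0.05
    p_deep: float = 0.1
    delta_deep: float = 4.0
    p_introduced: float = 0.02
    introduced_extra_divergence: float = 4.0
    regions: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_REGIONS))
    host_probabilities: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_HOSTS)
    )
    region_disjoint_sharing: bool = False
    ts_tv_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_genera < 1 or self.n_families < 1:
            raise ValidationError("counts must be positive")
        lo, hi = self.seqs_per_species
        if not (1 <= lo <= hi):
            raise ValidationError("seqs_per_species must be a (lo, hi) range, lo >= 1")
        for name in ("p_share", "p_deep", "p_introduced"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        if self.delta_deep <= self.intra_divergence:
            raise ValidationError("delta_deep must exceed intra_divergence")
        if self.delta_deep >= self.inter_divergence:
            raise ValidationError(
                "delta_deep must stay below inter_divergence, else deep clouds "
                "are indistinguishable from heterospecifics"
            )
        if any(not 0.0 <= p <= 1.0 for p in self.regions.values()):
            raise ValidationError("region occupancy probabilities must be in [0, 1]")
        if abs(sum(self.host_probabilities.values()) - 1.0) > 1e-9:
            raise ValidationError("host category probabilities must sum to 1")
        if self.region_disjoint_sharing and len(self.regions) < 2:
            raise ValidationError("region-disjoint sharing needs >= 2 regions")
        if self.ts_tv_ratio <= 0:
            raise ValidationError("ts_tv_ratio must be positive")


@dataclass
class SpeciesTruth:
    species: str
    genus: str
    family: str
    sharing_partners: list[str]
    deep_split: bool
    n_clusters: int
    regions: list[str]
    origin: str
    host_category: str


@dataclass
class TruthTable:
    species: dict[str, SpeciesTruth]
    specimen_lineage: dict[str, str]  # specimen_id -> "main" | "deep"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species": {k: v.__dict__ for k, v in self.species.items()},
            "specimen_lineage": self.specimen_lineage,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @property
    def sharing_species(self) -> set[str]:
        return {s for s, t in self.species.items() if t.sharing_partners}

    @property
    def deep_species(self) -> set[str]:
        return {s for s, t in self.species.items() if t.deep_split}


def _random_orf(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random encoded sequence whose frame-1 codons avoid stop codons."""
    seq = rng.integers(0, 4, size=length).astype(np.uint8)
    return _repair_orf(seq)


def _repair_orf(seq: np.ndarray) -> np.ndarray:
    """Rewrite frame-1 TAA/TAG codons to TAT (third position -> T)."""
    n_codons = len(seq) // 3
    codons = seq[: n_codons * 3].reshape(n_codons, 3)
    is_stop = (codons[:, 0] == 3) & (codons[:, 1] == 0) & (
        (codons[:, 2] == 0) | (codons[:, 2] == 2)
    )
    codons[is_stop, 2] = 3
    return seq


def _mutate(
    seq: np.ndarray, divergence_pct: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Apply per-site substitutions at expected density divergence_pct/100.

    A hit is a transition with probability kappa/(kappa+2) (two transversion
    targets share the remaining mass), mirroring K2P's rate structure.
    """
    out = seq.copy()
    p = divergence_pct / 100.0
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    if len(hits):
        is_ts = rng.random(len(hits)) < kappa / (kappa + 2.0)
        # transition partner flips within purine/pyrimidine class: +2 mod 4
        # transversion partner crosses classes: +1 or +3 mod 4
        tv_step = np.where(rng.random(len(hits)) < 0.5, 1, 3).astype(np.uint8)
        step = np.where(is_ts, 2, tv_step).astype(np.uint8)
        out[hits] = (out[hits] + step) % 4
    return _repair_orf(out)


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[b] for b in seq)


def simulate_library(params: SimulationParams) -> tuple[ReferenceLibrary, TruthTable]:
    """Generate a library plus its ground-truth table, deterministically per seed."""
    rng = np.random.default_rng(params.seed)
    root = _random_orf(rng, params.seq_length)

    # skewed genus sizes (weight ~ 1/rank) so genus-size analyses see spread
    weights = 1.0 / np.arange(1, params.n_genera + 1)
    weights /= weights.sum()
    genus_of = rng.choice(params.n_genera, size=params.n_species, p=weights)
    genus_of = np.sort(genus_of)  # species grouped by genus, names stay ordered

    genus_anc = {
        g: _mutate(root, params.inter_divergence, params.ts_tv_ratio, rng)
        for g in range(params.n_genera)
    }
    species_names = [
        f"Genus{genus_of[i]:03d}_sp{i:03d}" for i in range(params.n_species)
    ]
    genus_names = {i: f"Genus{genus_of[i]:03d}" for i in range(params.n_species)}
    family_names = {
        i: f"family_{(genus_of[i] % params.n_families) + 1}"
        for i in range(params.n_species)
    }
    species_anc = [
        _mutate(
            genus_anc[int(genus_of[i])],
            params.inter_divergence / 2.0,
            params.ts_tv_ratio,
            rng,
        )
        for i in range(params.n_species)
    ]

    # --- sharing events: union-find over congeneric pairs ---------------
    parent = list(range(params.n_species))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for g in range(params.n_genera):
        members = [i for i in range(params.n_species) if genus_of[i] == g]
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                if rng.random() < params.p_share:
                    ra, rb = find(members[ai]), find(members[bi])
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)

    components: dict[int, list[int]] = {}
    for i in range(params.n_species):
        components.setdefault(find(i), []).append(i)
    share_component = {i: sorted(c) for c in components.values() if len(c) > 1
                       for i in c}
    # every member of a sharing component inherits the representative's ancestor
    for i, comp in share_component.items():
        species_anc[i] = species_anc[comp[0]]

    # --- introduced species (sister absent): extra divergence -----------
    introduced: set[int] = set()
    for i in range(params.n_species):
        is_introduced = rng.random() < params.p_introduced
        if is_introduced and i not in share_component:
            introduced.add(i)
            species_anc[i] = _mutate(
                species_anc[i],
                params.introduced_extra_divergence,
                params.ts_tv_ratio,
                rng,
            )

    # --- deep splits ------------------------------------------------------
    lo, hi = params.seqs_per_species
    n_seqs = rng.integers(lo, hi + 1, size=params.n_species)
    deep_flags = [
        bool(rng.random() < params.p_deep) and int(n_seqs[i]) >= 2
        for i in range(params.n_species)
    ]
    deep_anc = [
        _mutate(species_anc[i], params.delta_deep, params.ts_tv_ratio, rng)
        if deep_flags[i]
        else None
        for i in range(params.n_species)
    ]

    # --- regions, traits --------------------------------------------------
    region_labels = list(params.regions)
    occupancy: list[list[str]] = []
    for i in range(params.n_species):
        occ = [r for r in region_labels if rng.random() < params.regions[r]]
        if not occ:
            occ = [region_labels[int(rng.integers(len(region_labels)))]]
        occupancy.append(occ)
    if params.region_disjoint_sharing:
        for comp in {tuple(c) for c in share_component.values()}:
            for k, i in enumerate(comp):
                occupancy[i] = [region_labels[k % len(region_labels)]]
    hosts = rng.choice(
        list(params.host_probabilities),
        size=params.n_species,
        p=list(params.host_probabilities.values()),
    )

    # --- specimens --------------------------------------------------------
    records: list[SequenceRecord] = []
    lineage: dict[str, str] = {}
    clouds: dict[int, list[np.ndarray]] = {}
    for i in range(params.n_species):
        n = int(n_seqs[i])
        n_main = n - n // 2 if deep_flags[i] else n
        seqs = []
        for k in range(n):
            base = species_anc[i] if k < n_main else deep_anc[i]
            seqs.append(
                _mutate(base, params.intra_divergence / 2.0, params.ts_tv_ratio, rng)
            )
        clouds[i] = seqs
    # verbatim haplotype copy inside each sharing component
    for i, comp in share_component.items():
        if i != comp[0]:
            clouds[i][0] = clouds[comp[0]][0].copy()

    for i in range(params.n_species):
        n = int(n_seqs[i])
        n_main = n - n // 2 if deep_flags[i] else n
        for k in range(n):
            sid = f"SIM{i:04d}-{k:02d}"
            region = occupancy[i][int(rng.integers(len(occupancy[i])))]
            records.append(
                SequenceRecord(
                    specimen_id=sid,
                    sequence=_decode(clouds[i][k]),
                    species=species_names[i],
                    genus=genus_names[i],
                    family=family_names[i],
                    region=region,
                    country="SIMLAND",
                    origin="introduced" if i in introduced else "native",
                    host_category=str(hosts[i]),
                )
            )
            lineage[sid] = "deep" if k >= n_main else "main"

    truth = TruthTable(
        species={
            species_names[i]: SpeciesTruth(
                species=species_names[i],
                genus=genus_names[i],
                family=family_names[i],
                sharing_partners=sorted(
                    species_names[j]
                    for j in share_component.get(i, [])
                    if j != i
                ),
                deep_split=deep_flags[i],
                n_clusters=2 if deep_flags[i] else 1,
                regions=sorted(set(r.region for r in records
                                   if r.species == species_names[i])),
                origin="introduced" if i in introduced else "native",
                host_category=str(hosts[i]),
            )
            for i in range(params.n_species)
        },
        specimen_lineage=lineage,
    )
    return _pad_to_common_frame(records), truth


def truth_eval(
    audits: list[SpeciesAudit], truth: TruthTable
) -> dict[str, dict[str, int]]:
    """Confusion counts (TP/FP/FN) of audit flags against simulator truth.

    Classifications compared: ``sharing``, ``deep_divergence`` and ``split``
    (two or more clusters).
    """
    audit_species = {a.species for a in audits}
    if audit_species != set(truth.species):
        raise ValidationError(
            "audit and truth cover different species sets: "
            f"{sorted(audit_species ^ set(truth.species))[:10]}"
        )
    predicted = {
        "sharing": {a.species for a in audits if a.sharing},
        "deep_divergence": {a.species for a in audits if a.deep_divergence},
        "split": {a.species for a in audits if a.n_clusters >= 2},
    }
    actual = {
        "sharing": truth.sharing_species,
        "deep_divergence": truth.deep_species,
        "split": {s for s, t in truth.species.items() if t.n_clusters >= 2},
    }
    return {
        key: {
            "tp": len(predicted[key] & actual[key]),
            "fp": len(predicted[key] - actual[key]),
            "fn": len(actual[key] - predicted[key]),
        }
        for key in predicted
    }
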