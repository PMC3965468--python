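"""End-to-end pipeline runner: config in, report bundle out.

``run_audit`` wires QC → distances → clustering → audit → stats and writes
every intermediate (QC report, species summaries, cluster partition,
per-family Newick trees, per-species audit TSV, JSON summary, stats
blocks), so each number in the bundle can be recomputed from serialized
intermediates.  The bundle is deterministic under a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import audit as audit_mod
from . import stats as stats_mod
from .audit import AuditConfig, SpeciesAudit
from .clustering import nj_tree, single_linkage_clusters
from .distances import (
    DistanceMatrix,
    SpeciesSummary,
    distance_matrix,
    species_summaries,
    write_summaries,
)
from .errors import ConfigError
from .library_io import ReferenceLibrary, qc_filter, read_library, write_library
from .simulate import SimulationParams, simulate_library

log = logging.getLogger("barcodeaudit")

_CONTRASTS = ("origin", "host_category", "genus_size")


@dataclass
class RunConfig:
    """One audit run: either real input files or simulation parameters."""

    fasta: str | None = None
    metadata: str | None = None
    simulation: SimulationParams | None = None
    audit: AuditConfig = field(default_factory=AuditConfig)
    regions: list[str] | None = None
    contrasts: tuple[str, ...] = _CONTRASTS
    output_dir: str = "audit_output"
    trees: bool = True
    min_length: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.fasta is not None or self.metadata is not None
        if has_files and self.simulation is not None:
            raise ConfigError("supply input files OR simulation params, not both")
        if not has_files and self.simulation is None:
            raise ConfigError("supply input files (fasta + metadata) or simulation params")
        if has_files and (self.fasta is None or self.metadata is None):
            raise ConfigError("both fasta and metadata paths are required")
        unknown = [c for c in self.contrasts if c not in _CONTRASTS]
        if unknown:
            raise ConfigError(f"unknown contrast(s) {unknown}; valid: {_CONTRASTS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationParams(**raw["simulation"])
        if "audit" in raw and raw["audit"] is not None:
            raw["audit"] = AuditConfig(**raw["audit"])
        if "contrasts" in raw and raw["contrasts"] is not None:
            raw["contrasts"] = tuple(raw["contrasts"])
        return cls(**raw)


def family_summary(
    audits: list[SpeciesAudit],
    summaries: list[SpeciesSummary],
    family_map: dict[str, str],
) -> pd.DataFrame:
    """Per-family audit table plus a species-count-weighted totals row."""
    nn = {s.species: s.nn_dist for s in summaries}
    n_seqs = {s.species: s.n_seqs for s in summaries}
    rows: dict[str, dict[str, float]] = {}
    for a in audits:
        fam = family_map[a.species]
        row = rows.setdefault(
            fam, {"n_species": 0, "n_sequences": 0, "nn_sum": 0.0, "nn_n": 0,
                  "n_sharing": 0}
        )
        row["n_species"] += 1
        row["n_sequences"] += n_seqs[a.species]
        if not math.isnan(nn[a.species]) and math.isfinite(nn[a.species]):
            row["nn_sum"] += nn[a.species]
            row["nn_n"] += 1
        row["n_sharing"] += int(a.sharing)
    table = []
    for fam in sorted(rows):
        r = rows[fam]
        table.append(
            {
                "family": fam,
                "n_species": int(r["n_species"]),
                "n_sequences": int(r["n_sequences"]),
                "mean_nn_dist": r["nn_sum"] / r["nn_n"] if r["nn_n"] else float("nan"),
                "pct_id_success": audit_mod.identification_success(
                    int(r["n_species"]), int(r["n_sharing"])
                ),
                "n_sharing": int(r["n_sharing"]),
            }
        )
    df = pd.DataFrame(table)
    weights = df["n_species"]
    total = {
        "family": "Total",
        "n_species": int(weights.sum()),
        "n_sequences": int(df["n_sequences"].sum()),
        "mean_nn_dist": float(np.average(df["mean_nn_dist"].fillna(0.0), weights=weights)),
        "pct_id_success": float(np.average(df["pct_id_success"], weights=weights)),
        "n_sharing": int(df["n_sharing"].sum()),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def _stats_blocks(
    library: ReferenceLibrary,
    summaries: list[SpeciesSummary],
    audits: list[SpeciesAudit],
    contrasts: tuple[str, ...],
    seed: int,
) -> dict:
    """Origin / host / genus-size contrasts on per-species NN distances."""
    origin_of = {r.species: r.origin for r in library.records}
    host_of = {r.species: r.host_category for r in library.records}
    nn = {
        s.species: s.nn_dist
        for s in summaries
        if not math.isnan(s.nn_dist) and math.isfinite(s.nn_dist)
    }
    blocks: dict = {}
    if "origin" in contrasts:
        groups = {
            lvl: [nn[sp] for sp in nn if origin_of[sp] == lvl]
            for lvl in ("native", "introduced")
        }
        block: dict = {
            "group_means": stats_mod.group_means(groups),
        }
        if all(len(v) >= 2 for v in groups.values()):
            med = stats_mod.moods_median_test(groups)
            t, df, p = stats_mod.welch_t(groups["native"], groups["introduced"])
            block["moods_median"] = dataclasses.asdict(med)
            block["welch_t"] = {"t": t, "df": df, "p": p}
        blocks["origin"] = block
    if "host_category" in contrasts:
        groups = {}
        for lvl in ("grass_herb", "tree_shrub", "detritus_fungi_lichen", "generalist"):
            vals = [nn[sp] for sp in nn if host_of[sp] == lvl]
            if vals:
                groups[lvl] = vals
        block = {"group_means": stats_mod.group_means(groups)}
        if len(groups) >= 2:
            block["moods_median"] = dataclasses.asdict(
                stats_mod.moods_median_test(groups)
            )
            block["anova"] = dataclasses.asdict(stats_mod.one_way_anova(groups))
            n_min = min(len(v) for v in groups.values())
            if n_min >= 2:
                balanced = stats_mod.balanced_resample(groups, n_min, seed)
                block["anova_balanced"] = dataclasses.asdict(
                    stats_mod.one_way_anova(balanced)
                )
                block["balanced_n"] = n_min
        blocks["host_category"] = block
    if "genus_size" in contrasts:
        genus_map = library.genus_map
        table, (sizes, incidence) = audit_mod.genus_size_sharing(audits, genus_map)
        rho, p = (
            stats_mod.spearman(sizes, incidence)
            if len(sizes) >= 3
            else (float("nan"), float("nan"))
        )
        blocks["genus_size"] = {
            "log2_bins": table.to_dict(orient="records"),
            "spearman_rho": rho,
            "spearman_p": p,
        }
    return blocks


def run_audit(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the audit summary, regional success, stats blocks
    and the paths written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info(
        "audit thresholds: t_deep=%.3g t_low=%.3g sharing_epsilon=%.3g "
        "cluster_threshold=%.3g min_overlap=%d",
        config.audit.t_deep, config.audit.t_low, config.audit.sharing_epsilon,
        config.audit.cluster_threshold, config.audit.min_overlap,
    )
    if config.simulation is not None:
        library, truth = simulate_library(config.simulation)
        write_library(library, out / "library.fasta", out / "metadata.tsv")
        truth.to_json(out / "truth.json")
    else:
        library = read_library(config.fasta, config.metadata)

    library, qc = qc_filter(library.records, min_length=config.min_length)
    qc.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    log.info("QC: %d in, %d retained", qc.n_input, qc.n_retained)

    matrix = distance_matrix(library, min_overlap=config.audit.min_overlap)
    summaries = species_summaries(matrix, library.species_map)
    write_summaries(summaries, out / "species_summaries.tsv")

    partition = single_linkage_clusters(matrix, config.audit.cluster_threshold)
    partition.write_tsv(out / "clusters.tsv")

    groups = audit_mod.detect_sharing(matrix, library.species_map, config.audit)
    audits = audit_mod.classify_species(
        summaries, groups, partition, library.species_map, config.audit
    )
    audit_mod.audits_frame(audits).to_csv(out / "species_audit.tsv", sep="\t", index=False)
    summary = audit_mod.concordance_counts(audits)

    regional = audit_mod.regional_success(
        library, matrix, config.audit, regions=config.regions
    )
    fam_table = family_summary(audits, summaries, library.family_map)
    fam_table.to_csv(out / "family_summary.tsv", sep="\t", index=False)

    if config.trees:
        families = sorted({r.family for r in library.records})
        for fam in families:
            idx = [i for i, r in enumerate(library.records) if r.family == fam]
            if len(idx) < 2:
                continue
            labels = [library.specimen_ids[i] for i in idx]
            sub = DistanceMatrix(
                labels=labels,
                values=matrix.values[np.ix_(idx, idx)],
                overlaps=matrix.overlaps[np.ix_(idx, idx)],
                saturated=matrix.saturated[np.ix_(idx, idx)],
            )
            tree = nj_tree(sub)
            safe = fam.replace("/", "_")
            tree.write_newick(out / f"nj_{safe}.nwk")
            if tree.n_clamped:
                log.info("NJ %s: clamped %d negative branch length(s)", fam, tree.n_clamped)

    stats_blocks = _stats_blocks(
        library, summaries, audits, config.contrasts, config.seed
    )
    result = {
        "qc": {"n_input": qc.n_input, "n_retained": qc.n_retained},
        "summary": dataclasses.asdict(summary),
        "regional_success": {
            r: {"pct": v[0], "n_diagnosable": v[1], "n_species": v[2]}
            for r, v in regional.items()
        },
        "stats": stats_blocks,
    }
    (out / "audit_summary.json").write_text(
        json.dumps(result, indent=1, sort_keys=True, default=float)
    )
    result["output_dir"] = str(out)
    return result
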