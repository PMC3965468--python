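"""Kimura two-parameter (K2P) distances and per-species divergence summaries.

The K2P model distinguishes transitions (A<->G, C<->T; proportion P) from
transversions (proportion Q) and corrects the observed proportions for
multiple hits:

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Distances are reported in percent throughout, matching the convention of
barcode reference-library studies.  Sites where either sequence carries a
gap, ``N`` or an IUPAC ambiguity code are excluded pair-by-pair (pairwise
deletion); the number of compared sites is retained for every pair.

When the log argument is non-positive the pair is saturated: the distance
is reported as ``+inf`` and flagged, never raised, so one bad pair cannot
abort a library-scale run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientOverlapError, ValidationError
from .library_io import ReferenceLibrary

#: Unambiguous base codes; anything else is treated as missing.
_BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}
_MISSING = 4

#: Default minimum pairwise overlap in compared sites.
DEFAULT_MIN_OVERLAP = 300


def encode_sequences(sequences: list[str]) -> np.ndarray:
    """Encode sequences as a (n, L) uint8 array; non-ACGT characters → missing."""
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise ValidationError(f"sequences have unequal lengths {sorted(lengths)}")
    lut = np.full(256, _MISSING, dtype=np.uint8)
    for base, code in _BASE_CODES.items():
        lut[ord(base)] = code
        lut[ord(base.lower())] = code
    raw = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    return lut[raw].reshape(len(sequences), -1)


@dataclass(frozen=True)
class DistanceResult:
    """K2P distance between one sequence pair."""

    d: float  # percent
    P: float  # transition proportion
    Q: float  # transversion proportion
    n_sites: int
    saturated: bool = False


def _k2p_from_proportions(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized K2P correction; returns (distance in percent, saturated mask)."""
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    saturated = (arg1 <= 0.0) | (arg2 <= 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -0.5 * np.log(arg1) - 0.25 * np.log(arg2)
    d = np.where(saturated, np.inf, d) * 100.0 + 0.0  # +0.0 normalizes -0.0
    return d, saturated


def pairwise_k2p(
    a: str, b: str, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> DistanceResult:
    """K2P distance between two aligned sequences under pairwise deletion."""
    if min_overlap <= 0:
        raise ValidationError("min_overlap must be positive")
    enc = encode_sequences([a, b])
    x, y = enc[0], enc[1]
    valid = (x != _MISSING) & (y != _MISSING)
    n_sites = int(valid.sum())
    if n_sites < min_overlap:
        raise InsufficientOverlapError(
            f"only {n_sites} compared sites, fewer than min_overlap={min_overlap}"
        )
    diff = valid & (x != y)
    # transitions are within the purine {A,G} or pyrimidine {C,T} classes,
    # i.e. both codes share parity under the A=0,C=1,G=2,T=3 encoding
    transitions = diff & ((x % 2) == (y % 2))
    P = float(transitions.sum()) / n_sites
    Q = float(diff.sum() - transitions.sum()) / n_sites
    d, saturated = _k2p_from_proportions(np.asarray(P), np.asarray(Q))
    return DistanceResult(
        d=float(d), P=P, Q=Q, n_sites=n_sites, saturated=bool(saturated)
    )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distance matrix over specimen labels.

    ``values`` holds distances in percent (``inf`` where saturated, ``nan``
    where a pair was masked for insufficient overlap under the permissive
    mode); ``overlaps`` holds compared-site counts.
    """

    labels: list[str]
    values: np.ndarray
    overlaps: np.ndarray
    saturated: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n) or self.overlaps.shape != (n, n):
            raise ValidationError("matrix dimensions do not match label count")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        finite = np.isfinite(self.values) | np.isinf(self.values)
        sym_ok = np.array_equal(
            np.where(finite, self.values, -1), np.where(finite.T, self.values.T, -1)
        )
        if not sym_ok:
            raise ValidationError("distance matrix must be exactly symmetric")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="specimen_id")


def distance_matrix(
    library: ReferenceLibrary,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    on_insufficient: str = "error",
) -> DistanceMatrix:
    """All-pairs K2P distances for a library.

    Transition/transversion counting is vectorized through one-hot indicator
    products, which makes library-scale (thousands of specimens) matrices
    cheap; the result is identical to looping `pairwise_k2p` over all pairs.

    ``on_insufficient`` controls pairs with fewer than ``min_overlap``
    compared sites: ``"error"`` raises listing the offending pairs,
    ``"mask"`` records them as ``nan``.
    """
    if len(library) == 0:
        raise ValidationError("cannot build a distance matrix from an empty library")
    if on_insufficient not in ("error", "mask"):
        raise ValidationError("on_insufficient must be 'error' or 'mask'")
    enc = encode_sequences([r.sequence for r in library.records])
    indicators = [(enc == code).astype(np.float64) for code in range(4)]
    valid = sum(indicators)

    n_sites = valid @ valid.T
    same = sum(ind @ ind.T for ind in indicators)
    m_ag = indicators[0] @ indicators[2].T  # A vs G
    m_ct = indicators[1] @ indicators[3].T  # C vs T
    transitions = m_ag + m_ag.T + m_ct + m_ct.T

    n_sites = np.rint(n_sites)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(n_sites > 0, transitions / n_sites, 0.0)
        Q = np.where(n_sites > 0, (n_sites - same - transitions) / n_sites, 0.0)
    d, saturated = _k2p_from_proportions(P, Q)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(saturated, False)
    # exact symmetry regardless of float summation order
    d = np.minimum(d, d.T)

    low = n_sites < min_overlap
    np.fill_diagonal(low, False)
    if low.any():
        ii, jj = np.nonzero(np.triu(low, k=1))
        pairs = [
            (library.specimen_ids[i], library.specimen_ids[j])
            for i, j in zip(ii.tolist(), jj.tolist())
        ]
        if on_insufficient == "error":
            raise InsufficientOverlapError(
                f"{len(pairs)} pair(s) below min_overlap={min_overlap}: "
                f"{pairs[:10]}{'...' if len(pairs) > 10 else ''}"
            )
        d[low] = np.nan
    return DistanceMatrix(
        labels=library.specimen_ids,
        values=d,
        overlaps=n_sites.astype(np.int64),
        saturated=saturated & ~low,
    )


@dataclass
class SpeciesSummary:
    """Per-species divergence summary (all values in percent).

    ``max_intra``/``mean_intra`` are ``nan`` for singleton species;
    ``nn_dist`` is ``nan`` when the library holds a single species.
    ``nn_tie`` flags a nearest-neighbour distance attained by more than one
    heterospecific species (the lexicographically first is reported).
    """

    species: str
    n_seqs: int
    max_intra: float
    mean_intra: float
    nn_dist: float
    nn_species: str
    nn_tie: bool = False


def species_summaries(
    matrix: DistanceMatrix, species_map: dict[str, str]
) -> list[SpeciesSummary]:
    """Summarize intraspecific divergence and nearest-neighbour distances.

    The nearest-neighbour (NN) distance of a species is the minimum K2P
    distance over all heterospecific specimen pairs; the NN species is the
    species attaining that minimum.
    """
    missing = [l for l in matrix.labels if l not in species_map]
    if missing:
        raise ValidationError(f"specimens without a species label: {missing[:10]}")
    labels = matrix.labels
    species_of = np.array([species_map[l] for l in labels])
    uniq = sorted(set(species_of.tolist()))
    out: list[SpeciesSummary] = []
    for sp in uniq:
        mask = species_of == sp
        idx = np.nonzero(mask)[0]
        n = len(idx)
        if n > 1:
            block = matrix.values[np.ix_(idx, idx)]
            tri = block[np.triu_indices(n, k=1)]
            max_intra = float(np.max(tri))
            mean_intra = float(np.mean(tri))
        else:
            max_intra = float("nan")
            mean_intra = float("nan")
        other = np.nonzero(~mask)[0]
        if len(other) == 0:
            out.append(
                SpeciesSummary(sp, n, max_intra, mean_intra, float("nan"), "", False)
            )
            continue
        inter = matrix.values[np.ix_(idx, other)]
        per_other = np.nanmin(inter, axis=0)  # min distance to each other specimen
        nn_dist = float(np.nanmin(per_other))
        attaining = sorted(set(species_of[other[per_other == nn_dist]].tolist()))
        out.append(
            SpeciesSummary(
                species=sp,
                n_seqs=n,
                max_intra=max_intra,
                mean_intra=mean_intra,
                nn_dist=nn_dist,
                nn_species=attaining[0],
                nn_tie=len(attaining) > 1,
            )
        )
    return out


def summaries_frame(summaries: list[SpeciesSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def write_summaries(summaries: list[SpeciesSummary], path: str | Path) -> None:
    summaries_frame(summaries).to_csv(path, sep="\t", index=False)
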