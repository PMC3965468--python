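from __future__ import annotations

import numpy as np
import pytest

from barcodeaudit.distances import DistanceMatrix
from barcodeaudit.library_io import ReferenceLibrary, SequenceRecord

#: A stop-free codon repeated to barcode length (Thr under the invertebrate
#: mitochondrial code in every copy of frame 1).
CLEAN_658 = ("ACG" * 220)[:658]

BASES = "ACGT"


def make_library(rows) -> ReferenceLibrary:
    """Build a library from (id, seq, species[, genus, family, region,
    origin, host]) tuples, padding sequences to a common length."""
    records = []
    length = max(len(r[1]) for r in rows)
    for row in rows:
        sid, seq, species = row[:3]
        genus = row[3] if len(row) > 3 else species.split("_")[0]
        family = row[4] if len(row) > 4 else "Famdefault"
        region = row[5] if len(row) > 5 else "unknown"
        origin = row[6] if len(row) > 6 else "unknown"
        host = row[7] if len(row) > 7 else "unknown"
        records.append(
            SequenceRecord(
                specimen_id=sid,
                sequence=seq.ljust(length, "-"),
                species=species,
                genus=genus,
                family=family,
                region=region,
                origin=origin,
                host_category=host,
            )
        )
    return ReferenceLibrary(records=records, alignment_length=length)


def matrix_from_array(values, labels=None) -> DistanceMatrix:
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    labels = labels or [f"s{i}" for i in range(n)]
    return DistanceMatrix(
        labels=list(labels),
        values=values,
        overlaps=np.full((n, n), 658, dtype=np.int64),
        saturated=np.zeros((n, n), dtype=bool),
    )


def random_acgt(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[b] for b in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def small_sim():
    """A 30-species simulated library with planted events, shared by tests."""
    from barcodeaudit.simulate import SimulationParams, simulate_library

    params = SimulationParams(
        n_species=30, seqs_per_species=(4, 8), p_share=0.08, p_deep=0.15, seed=11
    )
    return simulate_library(params)
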