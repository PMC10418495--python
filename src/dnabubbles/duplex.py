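"""Double-stranded DNA sequence representation and region bookkeeping.

The model treats the duplex as an ordered list of base pairs.  Chain 1
carries the bases of the input strand, chain 2 their Watson--Crick
complements.  All user-facing positions are 1-based and inclusive, matching
the convention of gene annotation tables; internal numpy arrays are 0-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "COMPLEMENT",
    "GeneDuplex",
    "Region",
    "RegionPartition",
    "DEFAULT_REGIONS",
    "read_duplex",
    "duplex_from_string",
    "partition_regions",
    "composition_table",
]

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: A base pair is A–T ("AT") when chain 1 carries A, T–A ("TA") when it
#: carries T, and so on.  A–T/T–A pairs share one hydrogen-bond strength,
#: G–C/C–G pairs another.
WEAK_PAIRS = frozenset({"AT", "TA"})


@dataclass(frozen=True)
class GeneDuplex:
    """An n-pair duplex; ``bases[i]`` is the chain-1 base of pair i+1."""

    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) < 2:
            raise ValueError("a duplex needs at least 2 base pairs")
        bad = [k + 1 for k, b in enumerate(self.bases) if b not in COMPLEMENT]
        if bad:
            raise ValueError(
                f"invalid base at position {bad[0]}: "
                f"{self.bases[bad[0] - 1]!r} (alphabet is A, C, G, T)"
            )

    @property
    def n(self) -> int:
        return len(self.bases)

    @property
    def positions(self) -> np.ndarray:
        """1-based positions 1..n."""
        return np.arange(1, self.n + 1)

    @property
    def pairs(self) -> list[str]:
        """Pair kinds as two-letter strings, e.g. ``"AT"`` for A–T."""
        return [b + COMPLEMENT[b] for b in self.bases]

    def complement_strand(self) -> str:
        return "".join(COMPLEMENT[b] for b in self.bases)

    def is_weak(self) -> np.ndarray:
        """Boolean array: True where the pair is A–T / T–A (two H-bonds)."""
        return np.array([b in "AT" for b in self.bases])


@dataclass(frozen=True)
class Region:
    name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RegionPartition:
    """Contiguous, non-overlapping cover of 1..n by named regions."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("partition needs at least one region")
        expected = 1
        for r in self.regions:
            if r.start != expected:
                raise ValueError(
                    f"region {r.name!r} starts at {r.start}, expected {expected} "
                    "(gap or overlap)"
                )
            if r.end < r.start:
                raise ValueError(f"region {r.name!r} has end < start")
            expected = r.end + 1

    @property
    def n(self) -> int:
        return self.regions[-1].end

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def sizes(self) -> dict[str, int]:
        return {r.name: r.size for r in self.regions}

    def region_of(self, position: int) -> str:
        """Region name for a 1-based position."""
        if not 1 <= position <= self.n:
            raise ValueError(f"position {position} outside 1..{self.n}")
        for r in self.regions:
            if r.start <= position <= r.end:
                return r.name
        raise AssertionError("unreachable: partition covers 1..n")

    @classmethod
    def from_bounds(cls, bounds: Sequence[tuple[str, int, int]]) -> "RegionPartition":
        return cls(tuple(Region(*b) for b in bounds))


#: Promoter / coding region / termination sequence of the modeled gene
#: (980 bp): parts I, II, III.
DEFAULT_REGIONS = RegionPartition.from_bounds(
    [("I", 1, 49), ("II", 50, 619), ("III", 620, 980)]
)


def duplex_from_string(seq: str) -> GeneDuplex:
    """Build a duplex directly from a raw sequence string (case-folded)."""
    return GeneDuplex(seq.strip().upper())


def read_duplex(fasta_text: str) -> GeneDuplex:
    """Parse a single-record FASTA text into a :class:`GeneDuplex`.

    Rejects multi-record files, empty sequences and ambiguity codes.
    """
    records = list(SeqIO.parse(io.StringIO(fasta_text), "fasta"))
    if not records:
        # Accept bare sequence text without a header as a convenience.
        stripped = fasta_text.strip()
        if stripped and not stripped.startswith(">"):
            return duplex_from_string(stripped)
        raise ValueError("no FASTA record found in input")
    if len(records) > 1:
        raise ValueError(f"expected a single FASTA record, found {len(records)}")
    seq = str(records[0].seq).upper()
    if not seq:
        raise ValueError("FASTA record has an empty sequence")
    return GeneDuplex(seq)


def partition_regions(duplex: GeneDuplex, partition: RegionPartition) -> dict[int, str]:
    """Map every 1-based position of *duplex* to its region name."""
    if partition.n != duplex.n:
        raise ValueError(
            f"partition covers 1..{partition.n} but duplex has n={duplex.n}"
        )
    return {p: partition.region_of(p) for p in range(1, duplex.n + 1)}


def composition_table(duplex: GeneDuplex, partition: RegionPartition):
    """Per-region pair counts and A–T / G–C percentages.

    Returns a pandas DataFrame indexed by region name with columns
    ``n``, ``at``, ``gc``, ``at_pct``, ``gc_pct``.
    """
    import pandas as pd

    if partition.n != duplex.n:
        raise ValueError(
            f"partition covers 1..{partition.n} but duplex has n={duplex.n}"
        )
    weak = duplex.is_weak()
    rows = []
    for r in partition.regions:
        w = weak[r.start - 1 : r.end]
        n = r.size
        at = int(w.sum())
        rows.append(
            {
                "region": r.name,
                "n": n,
                "at": at,
                "gc": n - at,
                "at_pct": 100.0 * at / n,
                "gc_pct": 100.0 * (n - at) / n,
            }
        )
    return pd.DataFrame(rows).set_index("region")
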