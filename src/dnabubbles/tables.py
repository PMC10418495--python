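"""Access to the packaged published range-count and composition tables.

The package ships, as plain TSV, the published per-(energy, region, group)
counts of substitution positions falling in the "Maximum" and "Minimum"
ranges of a 980-bp gene (with their A–T tallies), plus the gene's region
composition.  They let the aggregation and statistics stages be exercised
and checked without rerunning the hours-scale full-gene simulation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .duplex import RegionPartition

__all__ = ["PackagedTables", "load_packaged_tables"]

_DATA = "dnabubbles.data"


@dataclass(frozen=True)
class PackagedTables:
    """maximum / minimum: long-format cells (energy, region, group, n, at,
    all_closed); composition: per-region sizes and A–T / G–C percentages."""

    maximum: pd.DataFrame
    minimum: pd.DataFrame
    composition: pd.DataFrame

    def partition(self) -> RegionPartition:
        return RegionPartition.from_bounds(
            [(r.region, int(r.start), int(r.end)) for r in self.composition.itertuples()]
        )


def _read(name: str, checksums: dict) -> bytes:
    raw = resources.files(_DATA).joinpath(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if checksums.get(name) != digest:
        raise ValueError(f"packaged data file {name} failed its checksum")
    return raw


def load_packaged_tables() -> PackagedTables:
    """Load and checksum-verify the packaged tables."""
    manifest = json.loads(resources.files(_DATA).joinpath("manifest.json").read_text())
    checksums = manifest["files"]

    def frame(name: str) -> pd.DataFrame:
        import io

        return pd.read_csv(io.BytesIO(_read(name, checksums)), sep="\t", dtype={"energy": str})

    maximum = frame("range_maximum.tsv")
    minimum = frame("range_minimum.tsv")
    composition = frame("composition.tsv")
    for df, label in ((maximum, "maximum"), (minimum, "minimum")):
        if (df["at"] > df["n"]).any():
            raise ValueError(f"corrupt {label} table: an A–T tally exceeds its count")
    return PackagedTables(maximum=maximum, minimum=minimum, composition=composition)
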