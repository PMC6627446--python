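"""Exact (100% identity) dereplication of amplicon reads into OTUs.

Two reads belong to the same OTU iff their sequences are identical
strings — same length, same characters, 'N' compared literally.  This is
deliberately stricter than conventional 97% OTU picking: the goal is to
find sequences shared *verbatim* between body sites, where any relaxed
identity would need an alignment definition and would blur the
co-occurrence signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from cooccur.io_formats import ReadRecord, SampleManifest


class ConsistencyError(ValueError):
    """A read references a sample absent from the manifest."""


@dataclass(frozen=True, slots=True)
class ExactOtu:
    """A cluster of character-identical reads.

    `members` lists (read_id, sample_id) pairs; every member's sequence
    equals `representative` exactly.
    """

    otu_id: str
    representative: str
    members: tuple[tuple[str, str], ...]

    @property
    def size(self) -> int:
        return len(self.members)


def dereplicate(reads: list[ReadRecord]) -> list[ExactOtu]:
    """Partition reads into OTUs by exact sequence equality.

    OTU ids are "OTU{rank:06d}" by order of first appearance after
    sorting reads by (sample_id, read_id), so the labelling is a pure
    function of the read multiset: shuffling the input yields the same
    partition and the same ids.
    """
    ordered = sorted(reads, key=lambda r: (r.sample_id, r.read_id))
    clusters: dict[str, list[tuple[str, str]]] = {}
    for rec in ordered:
        clusters.setdefault(rec.sequence, []).append((rec.read_id, rec.sample_id))
    return [
        ExactOtu(otu_id=f"OTU{rank:06d}", representative=seq, members=tuple(members))
        for rank, (seq, members) in enumerate(clusters.items(), start=1)
    ]


@dataclass(frozen=True)
class OtuTable:
    """OTU x sample count matrix (rows: otu_ids, columns: sample_ids)."""

    counts: pd.DataFrame

    @property
    def otu_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def n_otus(self) -> int:
        return len(self.counts)

    def sample_depths(self) -> pd.Series:
        return self.counts.sum(axis=0)


def build_otu_table(
    otus: list[ExactOtu],
    manifest: SampleManifest,
    timepoint: str | None = None,
) -> OtuTable:
    """Tabulate OTU member counts per sample.

    Columns are the manifest's samples (optionally restricted to one
    timepoint) in manifest order; a member sample_id outside that set
    raises :class:`ConsistencyError`.  Column sums equal per-sample read
    counts and no row is all-zero (every OTU has at least one member).
    """
    if timepoint is None:
        sample_ids = manifest.sample_ids
    else:
        sample_ids = manifest.samples_at(timepoint)["sample_id"].tolist()
    col_index = {s: j for j, s in enumerate(sample_ids)}

    import numpy as np

    mat = np.zeros((len(otus), len(sample_ids)), dtype=np.int64)
    for i, otu in enumerate(otus):
        for _read_id, sample_id in otu.members:
            j = col_index.get(sample_id)
            if j is None:
                raise ConsistencyError(
                    f"OTU {otu.otu_id}: member sample {sample_id!r} not in manifest"
                    + (f" at timepoint {timepoint}" if timepoint else "")
                )
            mat[i, j] += 1

    counts = pd.DataFrame(mat, index=[o.otu_id for o in otus], columns=sample_ids)
    counts.index.name = "otu_id"
    return OtuTable(counts=counts)


def write_membership(otus: list[ExactOtu], path: str | Path) -> None:
    """Write OTU membership as TSV (otu_id, read_id, sample_id)."""
    rows = [
        {"otu_id": o.otu_id, "read_id": rid, "sample_id": sid}
        for o in otus
        for rid, sid in o.members
    ]
    pd.DataFrame(rows, columns=["otu_id", "read_id", "sample_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.counts.reset_index().to_csv(path, sep="\t", index=False)
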