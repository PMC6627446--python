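"""Reading and writing of the project file formats.

Three formats cross the package boundary: per-sample FASTA read sets, a
tab-separated sample manifest tying each read set to its subject, body
site, timepoint and clinical group, and TSV tables for all results.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SITES = ("saliva", "feces")
TIMEPOINTS = ("F1", "F2")
GROUPS = ("Control", "INR", "IR", "VU")

_ALPHABET = frozenset("ACGTN")

MANIFEST_COLUMNS = ("sample_id", "subject_id", "site", "timepoint", "group", "fasta_path")


class FastaFormatError(ValueError):
    """Malformed FASTA input (position reported as a line number)."""


class ManifestError(ValueError):
    """Missing columns, unknown category tokens, or duplicate keys in a manifest."""


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """A single amplicon read attributed to one sample.

    The sequence is an uppercase string over {A, C, G, T, N}; any other
    character is rejected at parse time because downstream clustering is
    literal string equality and a stray character would silently split
    an OTU.
    """

    read_id: str
    sample_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"read {self.read_id!r}: invalid characters {sorted(bad)!r} "
                "(alphabet is A,C,G,T,N; sequences must be uppercase)"
            )


def parse_fasta(path: str | Path, sample_id: str) -> list[ReadRecord]:
    """Parse a FASTA file into validated :class:`ReadRecord` objects.

    Wrapped sequence lines are concatenated and uppercased.  Raises
    :class:`FastaFormatError` naming the offending line number when
    sequence data precedes any header or a header has no sequence, and
    :class:`ValueError` on alphabet violations or duplicate read ids
    within the sample.
    """
    records: list[ReadRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FastaFormatError(
                f"{path}: header {header!r} at line {header_line} has no sequence"
            )
        if header in seen:
            raise ValueError(f"{path}: duplicate read id {header!r} in sample {sample_id!r}")
        seen.add(header)
        records.append(ReadRecord(read_id=header, sample_id=sample_id, sequence=seq))

    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaFormatError(f"{path}: empty FASTA header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"{path}: sequence data before any '>' header at line {lineno}"
                    )
                chunks.append(line)
        flush()
    return records


def write_fasta(records: Iterable[ReadRecord], path: str | Path) -> None:
    """Write reads as single-line-sequence FASTA (one record per read)."""
    with open(path, "w", encoding="utf-8") as handle:
        for rec in records:
            handle.write(f">{rec.read_id}\n{rec.sequence}\n")


@dataclass(frozen=True)
class SampleManifest:
    """Validated sample sheet: one row per (subject, site, timepoint).

    The manifest is the pairing backbone of the analysis: a *paired
    subject* at a timepoint is one contributing both a saliva and a
    feces sample there.  Rows are kept in a canonical sort order so two
    manifests with the same rows compare equal regardless of input
    order.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest missing column(s): {missing}")
        for col, allowed in (("site", SITES), ("timepoint", TIMEPOINTS)):
            bad = sorted(set(df[col]) - set(allowed))
            if bad:
                raise ManifestError(f"unknown {col} value(s) {bad}; allowed: {list(allowed)}")
        if (df["group"].str.len() == 0).any():
            raise ManifestError("empty group label")
        dup_samples = df["sample_id"][df["sample_id"].duplicated()].tolist()
        if dup_samples:
            raise ManifestError(f"duplicate sample_id(s): {sorted(set(dup_samples))}")
        key = df[["subject_id", "site", "timepoint"]]
        dups = df.loc[key.duplicated(), "subject_id"].tolist()
        if dups:
            raise ManifestError(
                f"duplicate (subject, site, timepoint) for subject(s): {sorted(set(dups))}"
            )
        canonical = (
            df.loc[:, list(MANIFEST_COLUMNS)]
            .sort_values(["subject_id", "site", "timepoint"], kind="mergesort")
            .reset_index(drop=True)
        )
        object.__setattr__(self, "frame", canonical)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleManifest):
            return NotImplemented
        return self.frame.equals(other.frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def samples_at(self, timepoint: str, site: str | None = None) -> pd.DataFrame:
        """Manifest rows for one timepoint, optionally one site."""
        mask = self.frame["timepoint"] == timepoint
        if site is not None:
            mask &= self.frame["site"] == site
        return self.frame.loc[mask]

    def paired_subjects(self, timepoint: str) -> list[str]:
        """Subjects with both a saliva and a feces sample at `timepoint`, sorted."""
        rows = self.samples_at(timepoint)
        per_subject = rows.groupby("subject_id")["site"].agg(set)
        return sorted(per_subject.index[per_subject.apply(lambda s: set(SITES) <= s)])

    def sample_for(self, subject_id: str, site: str, timepoint: str) -> str:
        """The sample_id of one (subject, site, timepoint) cell."""
        df = self.frame
        hit = df.loc[
            (df["subject_id"] == subject_id)
            & (df["site"] == site)
            & (df["timepoint"] == timepoint),
            "sample_id",
        ]
        if hit.empty:
            raise KeyError(f"no sample for ({subject_id!r}, {site!r}, {timepoint!r})")
        return hit.iloc[0]

    def group_of(self, subject_id: str) -> str:
        df = self.frame
        hit = df.loc[df["subject_id"] == subject_id, "group"]
        if hit.empty:
            raise KeyError(f"unknown subject {subject_id!r}")
        return hit.iloc[0]


def parse_manifest(path: str | Path) -> SampleManifest:
    """Read a TSV manifest (header row, UTF-8, '#' comment lines ignored)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    return SampleManifest(df)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.frame.to_csv(path, sep="\t", index=False)


def write_tsv(frame: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    """Write a result table as TSV with a header row."""
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def frame_to_tsv_bytes(frame: pd.DataFrame, float_format: str = "%.10g") -> bytes:
    buf = io.StringIO()
    frame.to_csv(buf, sep="\t", index=False, float_format=float_format)
    return buf.getvalue().encode()


def manifest_from_rows(rows: Sequence[dict]) -> SampleManifest:
    """Build a manifest from an in-memory list of row dicts."""
    return SampleManifest(pd.DataFrame(list(rows), dtype=str))
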