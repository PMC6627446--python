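"""Synthetic paired-site amplicon cohorts with planted ground truth.

Emulates the study design the pipeline targets: four clinical groups
(uninfected controls and three HIV-infected strata), every subject
sampled at two body sites (saliva, feces) and two timepoints (F1
baseline, F2 after a six-week prebiotic course).

Each site has its own taxon pool whose reference sequences are disjoint
from the other site's, so at zero sequencing error a sequence can only
appear in both of a subject's sites if it was *planted* there: every
subject carries ``n_shared_subject_taxa`` private taxa placed in both
sites at a fixed relative abundance.  These planted taxa are the ground
truth for co-occurrence recovery — anything else called an event is a
false positive by construction.

Community abundances are log-normal; reads are a multinomial draw of
fixed depth with optional i.i.d. per-base substitution error (no
indels, so error perturbs identity without changing read length).  The
post-intervention state raises every relative abundance to the power
1/``intervention_evenness_factor`` and renormalises: a factor below 1
sharpens the abundance distribution, lowering evenness and hence
Shannon/Simpson diversity, the qualitative direction observed after
prebiotics.  All randomness flows from one integer seed and output is
byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cooccur.io_formats import (
    ReadRecord,
    SampleManifest,
    manifest_from_rows,
    write_fasta,
    write_manifest,
)

# Table-style default design: 14 controls, 9 immunological non-responders,
# 18 responders, 12 viremic untreated = 53 subjects.
DEFAULT_GROUPS = (("Control", 14), ("INR", 9), ("IR", 18), ("VU", 12))

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the cohort generator.

    depth: reads per sample (every sample gets exactly this many).
    n_taxa_site: taxa in each site-wide pool (every subject's community
        draws from the full pool with subject-specific abundances).
    n_shared_subject_taxa: taxa planted in BOTH sites of each subject.
    shared_abundance: relative abundance given to each planted taxon in
        each site (the remaining mass goes to the site pool).
    lognormal_sigma: dispersion of log-normal pool abundances.
    error_rate: per-base substitution probability on every read.
    intervention_evenness_factor: in (0, 1]; F2 abundances are F1
        abundances to the power 1/factor, renormalised (1 = no effect).
    amplicon_length: reference sequence length (V3-V4-like scale).
    """

    groups: tuple[tuple[str, int], ...] = DEFAULT_GROUPS
    depth: int = 500
    n_taxa_site: int = 200
    n_shared_subject_taxa: int = 2
    shared_abundance: float = 0.02
    lognormal_sigma: float = 1.0
    error_rate: float = 0.0
    intervention_evenness_factor: float = 0.5
    seed: int = 0
    amplicon_length: int = 250

    def __post_init__(self) -> None:
        if not self.groups or any(n < 1 for _, n in self.groups):
            raise ValueError("groups must be non-empty with positive sizes")
        if len({label for label, _ in self.groups}) != len(self.groups):
            raise ValueError("duplicate group labels")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_taxa_site < 1:
            raise ValueError("n_taxa_site must be >= 1")
        if self.n_shared_subject_taxa < 0:
            raise ValueError("n_shared_subject_taxa must be >= 0")
        if self.n_shared_subject_taxa and not (
            0.0 < self.shared_abundance
            and self.shared_abundance * self.n_shared_subject_taxa < 1.0
        ):
            raise ValueError("shared_abundance * n_shared_subject_taxa must be in (0, 1)")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0.0 < self.intervention_evenness_factor <= 1.0):
            raise ValueError("intervention_evenness_factor must be in (0, 1]")
        if self.amplicon_length < 50:
            raise ValueError("amplicon_length must be >= 50")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")

    def to_dict(self) -> dict:
        return {
            "groups": [list(g) for g in self.groups],
            "depth": self.depth,
            "n_taxa_site": self.n_taxa_site,
            "n_shared_subject_taxa": self.n_shared_subject_taxa,
            "shared_abundance": self.shared_abundance,
            "lognormal_sigma": self.lognormal_sigma,
            "error_rate": self.error_rate,
            "intervention_evenness_factor": self.intervention_evenness_factor,
            "seed": self.seed,
            "amplicon_length": self.amplicon_length,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticConfig":
        data = dict(data)
        if "groups" in data:
            data["groups"] = tuple((str(l), int(n)) for l, n in data["groups"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated cohort held in memory.

    `truth` has one row per taxon: its reference sequence, owner
    (subject id for planted taxa, "site_pool" otherwise), the sites it
    was placed in, and — for planted taxa — the realised relative
    abundances per site and timepoint.  Pool-taxon abundances vary per
    subject and are left blank.
    """

    config: SyntheticConfig
    manifest: SampleManifest
    reads: dict[str, list[ReadRecord]]
    truth: pd.DataFrame

    def reads_at(self, timepoint: str) -> list[ReadRecord]:
        wanted = set(self.manifest.samples_at(timepoint)["sample_id"])
        out: list[ReadRecord] = []
        for sample_id in self.manifest.sample_ids:
            if sample_id in wanted:
                out.extend(self.reads[sample_id])
        return out


def _random_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seqs = ["".join(chr(b) for b in rng.choice(_BASES, size=length)) for _ in range(n)]
    assert len(set(seqs)) == n, "reference sequence collision (astronomically unlikely)"
    return seqs


def _mutate_reads(ref: str, n: int, error_rate: float, rng: np.random.Generator) -> list[str]:
    """`n` copies of `ref` with i.i.d. substitutions (never to the same base)."""
    if error_rate == 0.0 or n == 0:
        return [ref] * n
    idx = np.searchsorted(_BASES, np.frombuffer(ref.encode(), dtype=np.uint8))
    mat = np.tile(idx, (n, 1))
    mask = rng.random(mat.shape) < error_rate
    shifts = rng.integers(1, 4, size=mat.shape)
    mat = np.where(mask, (mat + shifts) % 4, mat)
    return [bytes(_BASES[row]).decode() for row in mat]


def generate_cohort(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full cohort (manifest, per-sample reads, truth table)."""
    rng = np.random.default_rng(config.seed)
    L = config.amplicon_length
    sites = ("saliva", "feces")
    subjects = [
        (f"{label}{i + 1:02d}", label)
        for label, n in config.groups
        for i in range(n)
    ]

    # Reference sequences: two disjoint site pools + private planted taxa.
    n_pool = config.n_taxa_site
    n_planted = config.n_shared_subject_taxa * len(subjects)
    all_seqs = _random_sequences(rng, 2 * n_pool + n_planted, L)
    pool_seqs = {"saliva": all_seqs[:n_pool], "feces": all_seqs[n_pool : 2 * n_pool]}
    planted_iter = iter(all_seqs[2 * n_pool :])
    pool_taxa = {
        site: [f"{site}_pool_{j + 1:04d}" for j in range(n_pool)] for site in sites
    }

    planted: dict[str, list[tuple[str, str]]] = {}  # subject -> [(taxon_id, seq)]
    for subject_id, _ in subjects:
        planted[subject_id] = [
            (f"shared_{subject_id}_{k + 1:02d}", next(planted_iter))
            for k in range(config.n_shared_subject_taxa)
        ]

    power = 1.0 / config.intervention_evenness_factor
    shared_mass = config.shared_abundance * config.n_shared_subject_taxa

    manifest_rows: list[dict] = []
    reads: dict[str, list[ReadRecord]] = {}
    truth_rows: list[dict] = []
    planted_ab: dict[tuple[str, str, str], np.ndarray] = {}

    for site in sites:
        for tid, seq in zip(pool_taxa[site], pool_seqs[site]):
            truth_rows.append(
                {
                    "taxon_id": tid,
                    "reference_sequence": seq,
                    "subject_id": "site_pool",
                    "sites": site,
                    "ab_saliva_F1": np.nan,
                    "ab_feces_F1": np.nan,
                    "ab_saliva_F2": np.nan,
                    "ab_feces_F2": np.nan,
                }
            )

    for subject_id, group in subjects:
        for site in sites:
            # Subject community: log-normal pool abundances scaled to the
            # non-planted mass, plus the planted taxa at fixed abundance.
            w = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=n_pool)
            pool_ab = w / w.sum() * (1.0 - shared_mass)
            ab_f1 = np.concatenate(
                [pool_ab, np.full(config.n_shared_subject_taxa, config.shared_abundance)]
            )
            ab_f2 = ab_f1**power
            ab_f2 /= ab_f2.sum()
            planted_ab[(subject_id, site, "F1")] = ab_f1[n_pool:]
            planted_ab[(subject_id, site, "F2")] = ab_f2[n_pool:]
            taxa = list(zip(pool_taxa[site], pool_seqs[site])) + planted[subject_id]

            for tp, ab in (("F1", ab_f1), ("F2", ab_f2)):
                sample_id = f"{subject_id}-{site}-{tp}"
                counts = rng.multinomial(config.depth, ab)
                recs: list[ReadRecord] = []
                r = 0
                for (taxon_id, seq), m in zip(taxa, counts):
                    for mutated in _mutate_reads(seq, int(m), config.error_rate, rng):
                        r += 1
                        recs.append(
                            ReadRecord(
                                read_id=f"{sample_id}_r{r:05d}",
                                sample_id=sample_id,
                                sequence=mutated,
                            )
                        )
                reads[sample_id] = recs
                manifest_rows.append(
                    {
                        "sample_id": sample_id,
                        "subject_id": subject_id,
                        "site": site,
                        "timepoint": tp,
                        "group": group,
                        "fasta_path": f"{sample_id}.fasta",
                    }
                )

    for subject_id, _ in subjects:
        for k, (taxon_id, seq) in enumerate(planted[subject_id]):
            truth_rows.append(
                {
                    "taxon_id": taxon_id,
                    "reference_sequence": seq,
                    "subject_id": subject_id,
                    "sites": "saliva;feces",
                    "ab_saliva_F1": planted_ab[(subject_id, "saliva", "F1")][k],
                    "ab_feces_F1": planted_ab[(subject_id, "feces", "F1")][k],
                    "ab_saliva_F2": planted_ab[(subject_id, "saliva", "F2")][k],
                    "ab_feces_F2": planted_ab[(subject_id, "feces", "F2")][k],
                }
            )

    truth = pd.DataFrame(truth_rows)
    return SyntheticDataset(
        config=config,
        manifest=manifest_from_rows(manifest_rows),
        reads=reads,
        truth=truth,
    )


def write_dataset(
    dataset: SyntheticDataset, out_dir: str | Path, overwrite: bool = False
) -> dict[str, Path]:
    """Materialise a cohort: one FASTA per sample, manifest, truth, config echo."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)

    for sample_id in dataset.manifest.sample_ids:
        write_fasta(dataset.reads[sample_id], out / f"{sample_id}.fasta")

    paths = {
        "manifest": out / "manifest.tsv",
        "truth": out / "truth.tsv",
        "config": out / "config.yaml",
    }
    write_manifest(dataset.manifest, paths["manifest"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    return paths


def truth_taxonomy(truth: pd.DataFrame) -> dict[str, str]:
    """Map reference sequence -> taxon id (for labelling error-free OTUs)."""
    return dict(zip(truth["reference_sequence"], truth["taxon_id"]))


def expected_shared_taxa(truth: pd.DataFrame) -> pd.DataFrame:
    """Truth rows of planted subject-shared taxa."""
    return truth.loc[truth["subject_id"] != "site_pool"].reset_index(drop=True)
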