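"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: the
co-occurrence oracle compares read sequences pairwise with a literal
double loop, and the clustering oracle is O(n^2) all-pairs string
comparison.
"""

from __future__ import annotations

import math
from collections import Counter

import pytest

from cooccur.io_formats import ReadRecord, manifest_from_rows


def make_cohort(site_reads: dict, group: str = "Control", timepoint: str = "F1"):
    """Build (manifest, reads) from {subject: {site: [sequences]}}.

    Subjects may be given as plain labels or (label, group) tuples.
    """
    rows, reads = [], []
    for subject, sites in site_reads.items():
        if isinstance(subject, tuple):
            subject, subj_group = subject
        else:
            subj_group = group
        for site, seqs in sites.items():
            sample_id = f"{subject}-{site}-{timepoint}"
            rows.append(
                {
                    "sample_id": sample_id,
                    "subject_id": subject,
                    "site": site,
                    "timepoint": timepoint,
                    "group": subj_group,
                    "fasta_path": f"{sample_id}.fasta",
                }
            )
            for i, seq in enumerate(seqs):
                reads.append(
                    ReadRecord(
                        read_id=f"{sample_id}_r{i + 1:04d}",
                        sample_id=sample_id,
                        sequence=seq,
                    )
                )
    return manifest_from_rows(rows), reads


def cooccurrence_oracle(site_reads: dict) -> dict:
    """Brute-force co-occurrence scores from {subject: {site: [seqs]}}.

    Enumerates every same-subject (saliva read, feces read) pair with a
    literal double loop and counts, per sequence, the pairs in which
    both reads equal that sequence.  Returns
    {sequence: (pair_count, prob_s, prob_f, prob_sf, llr)} for every
    sequence seen in any paired subject.
    """
    paired = {
        subj: sites
        for subj, sites in site_reads.items()
        if sites.get("saliva") and sites.get("feces")
    }
    total_pairs = 0
    pair_counts: Counter = Counter()
    s_counts: Counter = Counter()
    f_counts: Counter = Counter()
    n_s = n_f = 0
    for sites in paired.values():
        for rs in sites["saliva"]:
            for rf in sites["feces"]:
                total_pairs += 1
                if rs == rf:
                    pair_counts[rs] += 1
        s_counts.update(sites["saliva"])
        f_counts.update(sites["feces"])
        n_s += len(sites["saliva"])
        n_f += len(sites["feces"])

    out = {}
    for seq in set(s_counts) | set(f_counts):
        ps = s_counts[seq] / n_s
        pf = f_counts[seq] / n_f
        psf = pair_counts[seq] / total_pairs
        if psf > 0:
            llr = math.log2(psf / (ps * pf))
        else:
            llr = -math.inf
        out[seq] = (pair_counts[seq], ps, pf, psf, llr)
    return out


def brute_force_partition(reads) -> set[frozenset]:
    """O(n^2) all-pairs exact-equality clustering: partition of read ids."""
    reads = list(reads)
    assigned: list[set] = []
    for rec in reads:
        for cluster, rep in assigned:
            same = len(rec.sequence) == len(rep) and all(
                a == b for a, b in zip(rec.sequence, rep)
            )
            if same:
                cluster.add((rec.read_id, rec.sample_id))
                break
        else:
            assigned.append(({(rec.read_id, rec.sample_id)}, rec.sequence))
    return {frozenset(cluster) for cluster, _ in assigned}


@pytest.fixture
def two_subject_cohort():
    """Two paired subjects, 10 reads/sample; taxon A fills subject 1,
    taxon B fills subject 2 (both sites)."""
    a, b = "ACGT" * 10, "TTTT" * 10
    return make_cohort(
        {
            "s1": {"saliva": [a] * 10, "feces": [a] * 10},
            "s2": {"saliva": [b] * 10, "feces": [b] * 10},
        }
    )
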