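"""Saliva-feces co-occurrence scoring and biological-event calling.

For each OTU the evidence that its presence in an individual's saliva
(S) and feces (F) is coupled — rather than two independent draws from
the site-wide pools — is a base-2 pointwise mutual information

    llr = log2( P(S,F) / (P(S) * P(F)) )

estimated over all *paired* subjects (those with both sites sampled at
the timepoint).  In the default ``read_pair`` mode the probabilities are
read-pair frequencies: for subject i with saliva depth d_i^S, feces
depth d_i^F and OTU-k counts c_ik^S, c_ik^F,

    pair_count_k = sum_i c_ik^S * c_ik^F
    P(S,F) = pair_count_k / sum_i d_i^S * d_i^F
    P(S)   = sum_i c_ik^S / sum_i d_i^S
    P(F)   = sum_i c_ik^F / sum_i d_i^F

so llr > 0 means same-subject cross-site pairing beyond what the two
marginal abundances explain.  ``presence`` mode replaces counts with
per-subject presence indicators and depths with 1.  An OTU with at
least one same-subject S-F read pair and llr strictly above the
threshold (default 0.5, a conservative margin over the independence
point 0) is called a biological co-occurrence event.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist
from skbio.tree import TreeNode

from cooccur.exact_cluster import ConsistencyError, OtuTable
from cooccur.io_formats import SampleManifest

logger = logging.getLogger(__name__)

DEFAULT_LLR_THRESHOLD = 0.5


class ConfigurationError(ValueError):
    """The requested scoring cannot be set up (e.g. no paired subjects)."""


@dataclass(frozen=True, slots=True)
class CooccurrenceConfig:
    threshold: float = DEFAULT_LLR_THRESHOLD
    mode: str = "read_pair"  # or "presence"
    timepoint: str = "F1"

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ConfigurationError("llr threshold must be finite")
        if self.mode not in ("read_pair", "presence"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.timepoint not in ("F1", "F2"):
            raise ConfigurationError(f"unknown timepoint {self.timepoint!r}")


@dataclass(frozen=True, slots=True)
class CooccurrenceScore:
    """Per-OTU co-occurrence evidence.

    `llr` may be -inf (OTU never pairs across sites within a subject);
    such OTUs are never biological events.
    """

    otu_id: str
    pair_count: int
    n_subjects_with_pair: int
    prob_s: float
    prob_f: float
    prob_sf: float
    llr: float
    is_biological: bool


def score_cooccurrence(
    table: OtuTable,
    manifest: SampleManifest,
    config: CooccurrenceConfig = CooccurrenceConfig(),
) -> list[CooccurrenceScore]:
    """Score every OTU of `table` for same-subject cross-site co-occurrence.

    The table must be built from the samples of ``config.timepoint``.
    Subjects lacking one of the two sites there cannot form S-F pairs
    and are excluded from the probability universe (their reads still
    shaped the clustering); a paired subject with zero depth in either
    sample is likewise dropped, with a warning.  OTUs absent from every
    paired subject have no defined score and are omitted.
    """
    tp = config.timepoint
    subjects = manifest.paired_subjects(tp)
    if not subjects:
        raise ConfigurationError(f"no paired subjects at timepoint {tp}")

    cols = set(table.sample_ids)
    s_cols, f_cols, kept = [], [], []
    for subj in subjects:
        s_id = manifest.sample_for(subj, "saliva", tp)
        f_id = manifest.sample_for(subj, "feces", tp)
        if s_id not in cols or f_id not in cols:
            raise ConsistencyError(f"samples of paired subject {subj!r} missing from table")
        if table.counts[s_id].sum() == 0 or table.counts[f_id].sum() == 0:
            logger.warning("excluding paired subject %r: zero read depth at %s", subj, tp)
            continue
        s_cols.append(s_id)
        f_cols.append(f_id)
        kept.append(subj)
    if not kept:
        raise ConfigurationError(f"all paired subjects at {tp} have zero-depth samples")

    cs = table.counts[s_cols].to_numpy(dtype=np.float64)  # OTU x subject
    cf = table.counts[f_cols].to_numpy(dtype=np.float64)
    if config.mode == "presence":
        cs = (cs > 0).astype(np.float64)
        cf = (cf > 0).astype(np.float64)
        ds = np.ones(len(kept))
        df = np.ones(len(kept))
    else:
        ds = cs.sum(axis=0)
        df = cf.sum(axis=0)

    pair_counts = (cs * cf).sum(axis=1)
    n_subj_pair = ((cs > 0) & (cf > 0)).sum(axis=1)
    denom_sf = float((ds * df).sum())
    prob_sf = pair_counts / denom_sf
    prob_s = cs.sum(axis=1) / ds.sum()
    prob_f = cf.sum(axis=1) / df.sum()

    scores: list[CooccurrenceScore] = []
    for k, otu_id in enumerate(table.otu_ids):
        if prob_s[k] == 0.0 and prob_f[k] == 0.0:
            continue  # OTU absent from all paired subjects: llr undefined
        if pair_counts[k] > 0:
            llr = math.log2(prob_sf[k] / (prob_s[k] * prob_f[k]))
        else:
            llr = -math.inf
        scores.append(
            CooccurrenceScore(
                otu_id=otu_id,
                pair_count=int(round(pair_counts[k])),
                n_subjects_with_pair=int(n_subj_pair[k]),
                prob_s=float(prob_s[k]),
                prob_f=float(prob_f[k]),
                prob_sf=float(prob_sf[k]),
                llr=llr,
                is_biological=(pair_counts[k] >= 1 and llr > config.threshold),
            )
        )
    return scores


def call_events(
    scores: list[CooccurrenceScore], threshold: float = DEFAULT_LLR_THRESHOLD
) -> list[CooccurrenceScore]:
    """Biological events: pair_count >= 1 and llr strictly above threshold.

    Returned sorted by descending llr (ties broken by otu_id).
    """
    events = [s for s in scores if s.pair_count >= 1 and s.llr > threshold]
    return sorted(events, key=lambda s: (-s.llr, s.otu_id))


@dataclass(frozen=True)
class GroupCooccurrenceProfile:
    """Event summary of one (group, timepoint) cell.

    `taxon_frequencies` is the relative frequency of each taxon among
    the group's events; it sums to 1 whenever event_count > 0.
    """

    group: str
    timepoint: str
    event_count: int
    n_paired_subjects: int
    events_per_paired_subject: float
    taxon_frequencies: dict[str, float] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.group}.{self.timepoint}"


def summarize_group_profiles(
    events: list[CooccurrenceScore],
    table: OtuTable,
    manifest: SampleManifest,
    taxonomy: dict[str, str],
    timepoint: str = "F1",
) -> list[GroupCooccurrenceProfile]:
    """Attribute events to clinical groups and tabulate taxon spectra.

    An event OTU counts for a group if at least one subject of that
    group contributes a same-subject S-F read pair to it, so an OTU
    driven by subjects of several groups appears in each of their
    profiles.  Per-subject normalisation (events_per_paired_subject)
    makes groups of different size comparable.
    """
    for ev in events:
        if ev.otu_id not in table.counts.index:
            raise ConsistencyError(f"event OTU {ev.otu_id!r} absent from table")

    groups = sorted(set(manifest.frame["group"]))
    subjects = manifest.paired_subjects(timepoint)
    by_group: dict[str, list[str]] = {g: [] for g in groups}
    for subj in subjects:
        by_group[manifest.group_of(subj)].append(subj)

    profiles: list[GroupCooccurrenceProfile] = []
    for group in groups:
        members = by_group[group]
        s_cols = [manifest.sample_for(s, "saliva", timepoint) for s in members]
        f_cols = [manifest.sample_for(s, "feces", timepoint) for s in members]
        taxon_counts: dict[str, int] = {}
        n_events = 0
        for ev in events:
            row = table.counts.loc[ev.otu_id]
            contributes = any(
                row[s] > 0 and row[f] > 0 for s, f in zip(s_cols, f_cols)
            )
            if contributes:
                n_events += 1
                taxon = taxonomy.get(ev.otu_id, "unclassified")
                taxon_counts[taxon] = taxon_counts.get(taxon, 0) + 1
        freqs = (
            {t: c / n_events for t, c in sorted(taxon_counts.items())} if n_events else {}
        )
        profiles.append(
            GroupCooccurrenceProfile(
                group=group,
                timepoint=timepoint,
                event_count=n_events,
                n_paired_subjects=len(members),
                events_per_paired_subject=(n_events / len(members) if members else 0.0),
                taxon_frequencies=freqs,
            )
        )
    return profiles


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative clustering of group taxon-frequency profiles."""

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray
    newick: str


def cluster_profiles(
    profiles: list[GroupCooccurrenceProfile],
    metric: str = "bray_curtis",
    linkage: str = "average",
) -> Dendrogram:
    """Cluster taxon-frequency profiles hierarchically.

    Profiles are aligned on the union of their taxa (absent taxa = 0),
    sorted by label for deterministic tie-breaking, and merged by
    average linkage under Bray-Curtis or Pearson-correlation distance.
    """
    if len(profiles) < 2:
        raise ConfigurationError("profile clustering needs at least 2 profiles")
    if metric not in ("bray_curtis", "correlation"):
        raise ConfigurationError(f"unknown metric {metric!r}")
    if linkage != "average":
        raise ConfigurationError(f"unsupported linkage {linkage!r}")

    ordered = sorted(profiles, key=lambda p: p.label)
    taxa = sorted({t for p in ordered for t in p.taxon_frequencies})
    if not taxa:
        raise ConfigurationError("all profiles are empty; nothing to cluster")
    mat = np.array(
        [[p.taxon_frequencies.get(t, 0.0) for t in taxa] for p in ordered], dtype=float
    )
    scipy_metric = "braycurtis" if metric == "bray_curtis" else "correlation"
    dists = np.nan_to_num(pdist(mat, metric=scipy_metric), nan=0.0)
    z = scipy_linkage(dists, method="average")
    labels = tuple(p.label for p in ordered)
    tree = TreeNode.from_linkage_matrix(z, list(labels))
    return Dendrogram(labels=labels, linkage_matrix=z, newick=str(tree).strip())


def scores_frame(scores: list[CooccurrenceScore]) -> pd.DataFrame:
    """Scores as a table ready for TSV output."""
    return pd.DataFrame(
        [
            {
                "otu_id": s.otu_id,
                "pair_count": s.pair_count,
                "n_subjects_with_pair": s.n_subjects_with_pair,
                "prob_s": s.prob_s,
                "prob_f": s.prob_f,
                "prob_sf": s.prob_sf,
                "llr": s.llr,
                "is_biological": s.is_biological,
            }
            for s in scores
        ],
        columns=[
            "otu_id",
            "pair_count",
            "n_subjects_with_pair",
            "prob_s",
            "prob_f",
            "prob_sf",
            "llr",
            "is_biological",
        ],
    )


def profiles_frame(profiles: list[GroupCooccurrenceProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        if p.taxon_frequencies:
            for taxon, freq in p.taxon_frequencies.items():
                rows.append(
                    {
                        "group": p.group,
                        "timepoint": p.timepoint,
                        "event_count": p.event_count,
                        "n_paired_subjects": p.n_paired_subjects,
                        "events_per_paired_subject": p.events_per_paired_subject,
                        "taxon": taxon,
                        "frequency": freq,
                    }
                )
        else:
            rows.append(
                {
                    "group": p.group,
                    "timepoint": p.timepoint,
                    "event_count": 0,
                    "n_paired_subjects": p.n_paired_subjects,
                    "events_per_paired_subject": 0.0,
                    "taxon": "",
                    "frequency": 0.0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "timepoint",
            "event_count",
            "n_paired_subjects",
            "events_per_paired_subject",
            "taxon",
            "frequency",
        ],
    )
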