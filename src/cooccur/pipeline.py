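"""End-to-end orchestration: simulate/load -> cluster -> score -> call ->
summarize -> diversity -> group statistics.

Each stage is an ordinary library call; :func:`run_pipeline` wires them
together, writes every result as TSV (plus a Newick dendrogram and a
JSON run report) and fails with a stage-named error if any step breaks.
Outputs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from cooccur.cooccurrence import (
    CooccurrenceConfig,
    call_events,
    cluster_profiles,
    profiles_frame,
    score_cooccurrence,
    scores_frame,
    summarize_group_profiles,
)
from cooccur.diversity import DIVERSITY_INDICES, diversity_table
from cooccur.exact_cluster import build_otu_table, dereplicate, write_otu_table
from cooccur.group_stats import bh_adjust, wilcoxon_rank_sum
from cooccur.io_formats import SampleManifest, parse_fasta, parse_manifest, write_tsv
from cooccur.synthetic_data import (
    SyntheticConfig,
    generate_cohort,
    truth_taxonomy,
    write_dataset,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """One of `synthetic` / `manifest_path` selects the input source."""

    synthetic: SyntheticConfig | None = None
    manifest_path: str | None = None
    timepoints: tuple[str, ...] = ("F1", "F2")
    llr_threshold: float = 0.5
    mode: str = "read_pair"
    rare_threshold: int = 10
    out_dir: str = "results"
    seed: int | None = None  # overrides synthetic.seed when given

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.manifest_path is None):
            raise ValueError("exactly one of synthetic / manifest_path must be set")
        if not self.timepoints:
            raise ValueError("at least one timepoint required")

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.get("synthetic")
        kwargs = dict(
            synthetic=SyntheticConfig.from_dict(synth) if synth is not None else None,
            manifest_path=raw.get("manifest"),
            timepoints=tuple(raw.get("timepoints", ("F1", "F2"))),
            llr_threshold=float(raw.get("llr_threshold", 0.5)),
            mode=raw.get("mode", "read_pair"),
            rare_threshold=int(raw.get("rare_threshold", 10)),
            seed=raw.get("seed"),
        )
        if out_dir is not None:
            kwargs["out_dir"] = out_dir
        elif "out_dir" in raw:
            kwargs["out_dir"] = raw["out_dir"]
        return cls(**kwargs)

    def effective_synthetic(self) -> SyntheticConfig | None:
        if self.synthetic is None:
            return None
        if self.seed is None or self.seed == self.synthetic.seed:
            return self.synthetic
        return SyntheticConfig.from_dict(
            {**self.synthetic.to_dict(), "seed": self.seed}
        )


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: dict
    total_otus: dict[str, int] = field(default_factory=dict)
    distinct_events: dict[str, int] = field(default_factory=dict)
    events_per_group: dict[str, dict[str, int]] = field(default_factory=dict)
    median_shannon: dict[str, dict[str, float]] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "total_otus": self.total_otus,
                "distinct_events": self.distinct_events,
                "events_per_group": self.events_per_group,
                "median_shannon": self.median_shannon,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


def compare_timepoints(
    diversity_f1: pd.DataFrame,
    diversity_f2: pd.DataFrame,
    group_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group Wilcoxon rank-sum F1-vs-F2 comparison of each index.

    Runs one two-sided test per (group, site, index) cell on the two
    diversity tables (as produced by :func:`diversity_table` with a
    manifest) and applies Benjamini-Hochberg correction across the
    whole battery.  Groups present at only one timepoint are skipped
    with a warning.
    """
    if group_labels is None:
        group_labels = sorted(
            set(diversity_f1.get("group", pd.Series(dtype=str)))
            | set(diversity_f2.get("group", pd.Series(dtype=str)))
        )
    rows = []
    for group in group_labels:
        g1 = diversity_f1.loc[diversity_f1["group"] == group]
        g2 = diversity_f2.loc[diversity_f2["group"] == group]
        if g1.empty or g2.empty:
            logger.warning("group %r present at only one timepoint; skipped", group)
            continue
        sites = sorted(set(g1["site"]) & set(g2["site"]))
        for site in sites:
            a_rows = g1.loc[g1["site"] == site]
            b_rows = g2.loc[g2["site"] == site]
            for index in DIVERSITY_INDICES:
                a = a_rows[index].dropna().to_numpy()
                b = b_rows[index].dropna().to_numpy()
                if a.size == 0 or b.size == 0:
                    logger.warning(
                        "no finite %s values for group %r site %r; skipped",
                        index, group, site,
                    )
                    continue
                res = wilcoxon_rank_sum(a, b, labels=(f"{group}.F1", f"{group}.F2"))
                rows.append(
                    {
                        "group": group,
                        "site": site,
                        "index": index,
                        "n_f1": a.size,
                        "n_f2": b.size,
                        "median_f1": float(pd.Series(a).median()),
                        "median_f2": float(pd.Series(b).median()),
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                    }
                )
    out = pd.DataFrame(
        rows,
        columns=[
            "group", "site", "index", "n_f1", "n_f2",
            "median_f1", "median_f2", "statistic", "p_value",
        ],
    )
    if not out.empty:
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out


def _load_reads(manifest: SampleManifest, base_dir: Path, timepoint: str):
    reads = []
    for _, row in manifest.samples_at(timepoint).iterrows():
        fasta = Path(row["fasta_path"])
        if not fasta.is_absolute():
            fasta = base_dir / fasta
        reads.extend(parse_fasta(fasta, row["sample_id"]))
    return reads


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full analysis and write all outputs under config.out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={})
    taxonomy_by_seq: dict[str, str] = {}

    stage = "input"
    try:
        t0 = time.perf_counter()
        synth = config.effective_synthetic()
        if synth is not None:
            dataset = generate_cohort(synth)
            data_dir = out / "data"
            write_dataset(dataset, data_dir, overwrite=True)
            manifest = dataset.manifest
            base_dir = data_dir
            taxonomy_by_seq = truth_taxonomy(dataset.truth)
            report.config = {"synthetic": synth.to_dict()}
        else:
            manifest = parse_manifest(config.manifest_path)
            base_dir = Path(config.manifest_path).parent
            report.config = {"manifest": str(config.manifest_path)}
        report.config.update(
            timepoints=list(config.timepoints),
            llr_threshold=config.llr_threshold,
            mode=config.mode,
            rare_threshold=config.rare_threshold,
        )
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        all_profiles = []
        diversity_frames: dict[str, pd.DataFrame] = {}
        for tp in config.timepoints:
            stage = f"cluster[{tp}]"
            t0 = time.perf_counter()
            reads = _load_reads(manifest, base_dir, tp)
            otus = dereplicate(reads)
            table = build_otu_table(otus, manifest, timepoint=tp)
            write_otu_table(table, out / f"otu_table.{tp}.tsv")
            report.total_otus[tp] = table.n_otus
            logger.info("stage %s: %d OTUs in %.2fs", stage, table.n_otus,
                        time.perf_counter() - t0)

            stage = f"cooccur[{tp}]"
            t0 = time.perf_counter()
            cfg = CooccurrenceConfig(
                threshold=config.llr_threshold, mode=config.mode, timepoint=tp
            )
            scores = score_cooccurrence(table, manifest, cfg)
            events = call_events(scores, config.llr_threshold)
            write_tsv(scores_frame(scores), out / f"cooccurrence_scores.{tp}.tsv")
            write_tsv(scores_frame(events), out / f"events.{tp}.tsv")
            report.distinct_events[tp] = len(events)

            taxonomy = {
                o.otu_id: taxonomy_by_seq.get(o.representative, "unclassified")
                for o in otus
            }
            profiles = summarize_group_profiles(events, table, manifest, taxonomy, tp)
            all_profiles.extend(profiles)
            report.events_per_group[tp] = {p.group: p.event_count for p in profiles}
            logger.info("stage %s: %d events in %.2fs", stage, len(events),
                        time.perf_counter() - t0)

            stage = f"diversity[{tp}]"
            t0 = time.perf_counter()
            div = diversity_table(table, manifest, rare_threshold=config.rare_threshold)
            diversity_frames[tp] = div
            report.median_shannon[tp] = {
                f"{g}.{s}": float(sub["shannon"].median())
                for (g, s), sub in div.groupby(["group", "site"])
            }
            logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        stage = "profiles"
        write_tsv(profiles_frame(all_profiles), out / "group_profiles.tsv")
        nonempty = [p for p in all_profiles if p.taxon_frequencies]
        if len(nonempty) >= 2:
            dendro = cluster_profiles(nonempty)
            (out / "profiles.nwk").write_text(dendro.newick + "\n")
            report.outputs["profiles_nwk"] = "profiles.nwk"
        else:
            logger.warning("fewer than 2 non-empty profiles; dendrogram skipped")

        stage = "diversity_output"
        div_all = pd.concat(diversity_frames.values(), ignore_index=True)
        write_tsv(div_all, out / "diversity.tsv")

        stage = "stats"
        if {"F1", "F2"} <= set(diversity_frames):
            stats = compare_timepoints(diversity_frames["F1"], diversity_frames["F2"])
        else:
            stats = pd.DataFrame()
        write_tsv(stats, out / "stats.tsv")

        stage = "report"
        for tp in config.timepoints:
            report.outputs[f"otu_table_{tp}"] = f"otu_table.{tp}.tsv"
            report.outputs[f"scores_{tp}"] = f"cooccurrence_scores.{tp}.tsv"
            report.outputs[f"events_{tp}"] = f"events.{tp}.tsv"
        report.outputs.update(
            group_profiles="group_profiles.tsv",
            diversity="diversity.tsv",
            stats="stats.tsv",
            report="report.json",
        )
        (out / "report.json").write_text(report.to_json() + "\n")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return report
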