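"""Co-occurrence scoring: oracle equivalence, analytic laws, event calling."""

import math
import random

import numpy as np
import pytest

from cooccur.cooccurrence import (
    ConfigurationError,
    CooccurrenceConfig,
    CooccurrenceScore,
    call_events,
    cluster_profiles,
    score_cooccurrence,
    summarize_group_profiles,
)
from cooccur.cooccurrence import GroupCooccurrenceProfile
from cooccur.exact_cluster import build_otu_table, dereplicate

from conftest import cooccurrence_oracle, make_cohort


def _score(site_reads, mode="read_pair", threshold=0.5):
    manifest, reads = make_cohort(site_reads)
    table = build_otu_table(dereplicate(reads), manifest, timepoint="F1")
    cfg = CooccurrenceConfig(threshold=threshold, mode=mode, timepoint="F1")
    otus = dereplicate(reads)
    rep = {o.otu_id: o.representative for o in otus}
    scores = score_cooccurrence(table, manifest, cfg)
    return {rep[s.otu_id]: s for s in scores}


# distinct 20-mer ACGT sequences keyed by a letter, for readable cohorts
SEQ = {
    letter: unit * 10
    for letter, unit in zip("ABCDEFGH", ["AC", "AG", "AT", "CG", "CT", "GT", "AA", "CC"])
}


def seqs(letters):
    return [SEQ[c] for c in letters]


class TestScoreCooccurrence:
    def test_two_subject_exclusive_taxa(self, two_subject_cohort):
        """Taxon filling both sites of its own subject only: pair_count
        d^2, all probabilities 1/2, llr = 1, biological."""
        manifest, reads = two_subject_cohort
        table = build_otu_table(dereplicate(reads), manifest, timepoint="F1")
        scores = score_cooccurrence(table, manifest, CooccurrenceConfig())
        assert len(scores) == 2
        for s in scores:
            assert s.pair_count == 100
            assert s.prob_s == s.prob_f == s.prob_sf == pytest.approx(0.5)
            assert s.llr == pytest.approx(1.0)
            assert s.is_biological

    def test_saliva_only_otu_minus_infinity(self):
        by_seq = _score(
            {
                "s1": {"saliva": seqs("AAB"), "feces": seqs("BBC")},
            }
        )
        a = by_seq[SEQ["A"]]
        assert a.pair_count == 0 and a.prob_sf == 0.0
        assert a.llr == -math.inf and not a.is_biological

    def test_uniform_taxon_llr_zero(self):
        """Identical relative abundance in every subject's saliva and in
        every feces (equal depths) -> llr = 0: P(S,F) = P(S)P(F)."""
        composition = {"saliva": seqs("AAB"), "feces": seqs("ACC")}
        by_seq = _score({f"s{i}": composition for i in range(4)})
        assert by_seq[SEQ["A"]].llr == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_subjects", [2, 3, 5])
    def test_matches_pair_enumeration_oracle(self, n_subjects):
        rng = random.Random(n_subjects)
        pool = seqs("ABCDEFGH")
        cohort = {
            f"s{i}": {
                "saliva": [rng.choice(pool) for _ in range(rng.randint(3, 30))],
                "feces": [rng.choice(pool) for _ in range(rng.randint(3, 30))],
            }
            for i in range(n_subjects)
        }
        oracle = cooccurrence_oracle(cohort)
        got = _score(cohort)
        assert set(got) == set(oracle)
        for seq, s in got.items():
            pair_count, ps, pf, psf, llr = oracle[seq]
            assert s.pair_count == pair_count
            assert s.prob_s == pytest.approx(ps, abs=1e-12)
            assert s.prob_f == pytest.approx(pf, abs=1e-12)
            assert s.prob_sf == pytest.approx(psf, abs=1e-12)
            if math.isfinite(llr):
                assert abs(s.llr - llr) < 1e-9
            else:
                assert s.llr == -math.inf

    @pytest.mark.parametrize("n_subjects", [2, 4, 8])
    def test_subject_exclusive_shared_taxon_law(self, n_subjects):
        """A subject-exclusive taxon shared across sites at equal depths
        scores exactly log2(I) over I paired subjects."""
        pool = seqs("ABCDEFGH")
        filler = "TG" * 10  # ubiquitous taxon, distinct from the pool
        cohort = {
            f"s{i}": {"saliva": [pool[i]] * 3 + [filler] * 3,
                      "feces": [pool[i]] * 2 + [filler] * 4}
            for i in range(n_subjects)
        }
        by_seq = _score(cohort)
        for i in range(n_subjects):
            assert by_seq[pool[i]].llr == pytest.approx(math.log2(n_subjects), abs=1e-12)
        # the ubiquitous filler taxon is exactly at independence
        assert by_seq[filler].llr == pytest.approx(0.0, abs=1e-12)

    def test_presence_mode_satisfies_llr_invariant(self):
        cohort = {
            "s1": {"saliva": seqs("AAB"), "feces": seqs("AB")},
            "s2": {"saliva": seqs("BC"), "feces": seqs("CC")},
        }
        for s in _score(cohort, mode="presence").values():
            if s.pair_count > 0:
                assert s.llr == pytest.approx(
                    math.log2(s.prob_sf / (s.prob_s * s.prob_f)), abs=1e-12
                )

    def test_conservation_of_pairs(self):
        rng = random.Random(99)
        pool = seqs("ABCD")
        cohort = {
            f"s{i}": {
                "saliva": [rng.choice(pool) for _ in range(10)],
                "feces": [rng.choice(pool) for _ in range(10)],
            }
            for i in range(3)
        }
        scores = _score(cohort)
        total = sum(s.pair_count for s in scores.values())
        matching = sum(cooccurrence_oracle(cohort)[q][0] for q in scores)
        assert total == matching <= 3 * 10 * 10

    def test_unpaired_subject_excluded_from_universe(self):
        """A saliva-only subject contributes no pairs: probabilities are
        computed over paired subjects only."""
        cohort = {
            "s1": {"saliva": seqs("AA"), "feces": seqs("AA")},
            "lonely": {"saliva": seqs("BB")},
        }
        by_seq = _score(cohort)
        assert SEQ["B"] not in by_seq  # absent from all paired subjects
        assert by_seq[SEQ["A"]].prob_s == 1.0

    def test_no_paired_subjects_raises(self):
        manifest, reads = make_cohort({"s1": {"saliva": seqs("A")}})
        table = build_otu_table(dereplicate(reads), manifest, timepoint="F1")
        with pytest.raises(ConfigurationError, match="no paired subjects"):
            score_cooccurrence(table, manifest, CooccurrenceConfig())


def _fake_score(otu_id, llr, pair_count=1):
    return CooccurrenceScore(
        otu_id=otu_id,
        pair_count=pair_count,
        n_subjects_with_pair=1 if pair_count else 0,
        prob_s=0.1,
        prob_f=0.1,
        prob_sf=0.01 * 2**llr if math.isfinite(llr) else 0.0,
        llr=llr,
        is_biological=pair_count >= 1 and llr > 0.5,
    )


class TestCallEvents:
    def test_strict_threshold_semantics(self):
        """llr exactly 0.5 is not an event; anything strictly above is."""
        scores = [
            _fake_score("a", -math.inf, pair_count=0),
            _fake_score("b", 0.0),
            _fake_score("c", 0.5),
            _fake_score("d", 0.51),
            _fake_score("e", 1.0),
        ]
        events = call_events(scores, 0.5)
        assert [e.otu_id for e in events] == ["e", "d"]  # sorted by llr desc

    def test_empty_input(self):
        assert call_events([], 0.5) == []

    def test_pair_count_required(self):
        assert call_events([_fake_score("a", 3.0, pair_count=0)], 0.5) == []

    def test_threshold_monotonicity(self):
        rng = random.Random(5)
        scores = [_fake_score(f"o{i}", rng.uniform(-2, 3)) for i in range(50)]
        counts = [len(call_events(scores, t)) for t in np.linspace(-2, 3, 21)]
        assert counts == sorted(counts, reverse=True)


class TestGroupProfiles:
    def _setup(self):
        cohort = {
            ("s1", "IR"): {"saliva": seqs("AAB"), "feces": seqs("AB")},
            ("s2", "VU"): {"saliva": seqs("AC"), "feces": seqs("AC")},
        }
        manifest, reads = make_cohort(cohort)
        otus = dereplicate(reads)
        table = build_otu_table(otus, manifest, timepoint="F1")
        scores = score_cooccurrence(table, manifest, CooccurrenceConfig(threshold=-10))
        events = call_events(scores, -10)
        rep = {o.otu_id: o.representative for o in otus}
        taxonomy = {oid: f"tax_{rep[oid][0]}" for oid in rep}
        return events, table, manifest, taxonomy

    def test_no_events_empty_profiles(self):
        _, table, manifest, taxonomy = self._setup()
        profiles = summarize_group_profiles([], table, manifest, taxonomy, "F1")
        assert all(p.event_count == 0 and p.taxon_frequencies == {} for p in profiles)

    def test_frequencies_normalized(self):
        events, table, manifest, taxonomy = self._setup()
        profiles = summarize_group_profiles(events, table, manifest, taxonomy, "F1")
        for p in profiles:
            if p.event_count:
                assert sum(p.taxon_frequencies.values()) == pytest.approx(1.0)

    def test_multi_group_attribution(self):
        """An OTU with same-subject pairs in two groups is counted in both."""
        events, table, manifest, taxonomy = self._setup()
        profiles = {p.group: p for p in
                    summarize_group_profiles(events, table, manifest, taxonomy, "F1")}
        # sequence A pairs within s1 (IR) and within s2 (VU)
        assert profiles["IR"].event_count >= 1
        assert profiles["VU"].event_count >= 1
        assert "tax_A" in profiles["IR"].taxon_frequencies
        assert "tax_A" in profiles["VU"].taxon_frequencies

    def test_known_frequency_split(self):
        """3 events in one group, 2 of taxon X and 1 of taxon Y ->
        frequencies {X: 2/3, Y: 1/3}."""
        cohort = {
            ("s1", "IR"): {
                "saliva": seqs("ABC") * 2,
                "feces": seqs("ABC") * 2,
            }
        }
        manifest, reads = make_cohort(cohort)
        otus = dereplicate(reads)
        table = build_otu_table(otus, manifest, timepoint="F1")
        scores = score_cooccurrence(table, manifest, CooccurrenceConfig(threshold=-10))
        events = call_events(scores, -10)
        rep = {o.otu_id: o.representative for o in otus}
        taxonomy = {
            oid: ("X" if rep[oid] in (SEQ["A"], SEQ["B"]) else "Y") for oid in rep
        }
        profiles = {p.group: p for p in
                    summarize_group_profiles(events, table, manifest, taxonomy, "F1")}
        assert profiles["IR"].taxon_frequencies == {
            "X": pytest.approx(2 / 3),
            "Y": pytest.approx(1 / 3),
        }


def _profile(group, tp, freqs):
    return GroupCooccurrenceProfile(
        group=group,
        timepoint=tp,
        event_count=len(freqs),
        n_paired_subjects=5,
        events_per_paired_subject=len(freqs) / 5,
        taxon_frequencies=freqs,
    )


class TestClusterProfiles:
    def test_identical_profiles_merge_at_zero(self):
        p1 = _profile("IR", "F1", {"x": 0.5, "y": 0.5})
        p2 = _profile("VU", "F1", {"x": 0.5, "y": 0.5})
        d = cluster_profiles([p1, p2])
        assert d.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_disjoint_profiles_bray_curtis_one(self):
        p1 = _profile("IR", "F1", {"x": 1.0})
        p2 = _profile("VU", "F1", {"y": 1.0})
        d = cluster_profiles([p1, p2], metric="bray_curtis")
        assert d.linkage_matrix[0, 2] == pytest.approx(1.0)

    def test_identical_pair_merges_first(self):
        same = {"x": 0.7, "y": 0.3}
        p1 = _profile("Control", "F1", same)
        p2 = _profile("IR", "F1", same)
        p3 = _profile("VU", "F1", {"z": 1.0})
        d = cluster_profiles([p1, p2, p3])
        first = d.linkage_matrix[0]
        assert first[2] == pytest.approx(0.0)
        labels = {d.labels[int(first[0])], d.labels[int(first[1])]}
        assert labels == {"Control.F1", "IR.F1"}
        assert "VU.F1" in d.newick

    def test_too_few_profiles(self):
        with pytest.raises(ConfigurationError):
            cluster_profiles([_profile("IR", "F1", {"x": 1.0})])
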