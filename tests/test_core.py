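import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmrna_curator.core import (
    FlatfileError,
    GeneForm,
    GeneRecord,
    Provenance,
    RejectReason,
    Segment,
    SegmentMap,
    Status,
    Thresholds,
    assign_names,
    curate_funnel,
    deduplicate,
    read_flatfile,
    write_flatfile,
)
from tmrna_curator.synth import GenConfig, gen_funnel_batch, gen_gene


def _rec(rid, seq, count=1, provs=()):
    return GeneRecord(
        id=rid,
        sequence=seq,
        form=GeneForm.STANDARD,
        instance_count=count,
        provenance=tuple(provs),
    )


def _prov(n, contig="c1"):
    return Provenance("ASM", contig, n, n + 99, "+")


class TestDomainTypes:
    def test_record_rejected_iff_reasons(self):
        with pytest.raises(ValueError):
            GeneRecord(id="x", sequence="ACGT", form=GeneForm.STANDARD, status=Status.REJECTED)
        rec = _rec("x", "ACGT").rejected(RejectReason.TAG_ORF)
        assert rec.status is Status.REJECTED

    def test_segments_must_fit_sequence(self):
        with pytest.raises(ValueError):
            GeneRecord(
                id="x",
                sequence="ACGT",
                form=GeneForm.STANDARD,
                segments=SegmentMap((Segment("TRNA5", 0, 10),)),
            )

    def test_segment_overlap_rejected(self):
        with pytest.raises(ValueError):
            SegmentMap((Segment("A", 0, 5), Segment("B", 3, 8)))

    def test_cca_must_be_three(self):
        with pytest.raises(ValueError):
            SegmentMap((Segment("CCA", 0, 2),))
        SegmentMap((Segment("CCA", 0, 3),))  # fine

    def test_threshold_defaults(self, thresholds):
        assert thresholds.aragorn_strong == 103
        assert thresholds.infernal_strong == 140
        assert thresholds.rfind_strong == 90
        assert thresholds.trna_overlap_bp == 5
        assert thresholds.trna_score == 42
        assert thresholds.flank_bp == 250
        assert thresholds.intron_min_len == 500
        assert thresholds.intron_min_bits == 150

    def test_thresholds_non_negative(self):
        with pytest.raises(ValueError):
            Thresholds(flank_bp=-1)


class TestDeduplicate:
    def test_exact_duplicates_collapse(self):
        recs = [_rec("a", "ACGT", provs=[_prov(1)]), _rec("b", "ACGT", provs=[_prov(200)])]
        out = deduplicate(recs)
        assert len(out) == 1
        assert out[0].instance_count == 2
        assert len(out[0].provenance) == 2

    def test_one_base_difference_retained(self):
        out = deduplicate([_rec("a", "ACGT"), _rec("b", "ACGA")])
        assert len(out) == 2

    def test_case_and_u_insensitive(self):
        out = deduplicate([_rec("a", "acgu"), _rec("b", "ACGT")])
        assert len(out) == 1

    def test_empty_input(self):
        assert deduplicate([]) == []

    @given(
        st.lists(
            st.tuples(st.sampled_from(["ACG", "ACT", "GGT", "TTA"]), st.integers(1, 5)),
            max_size=12,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_conserves_instance_count(self, items):
        recs = [_rec(f"r{i}", seq, count=c) for i, (seq, c) in enumerate(items)]
        out = deduplicate(recs)
        assert sum(r.instance_count for r in out) == sum(c for _, c in items)

    def test_order_independent(self):
        recs = [_rec(f"r{i}", s) for i, s in enumerate(["TTT", "AAA", "CCC", "AAA"])]
        a = deduplicate(recs)
        b = deduplicate(list(reversed(recs)))
        assert [r.norm_sequence for r in a] == [r.norm_sequence for r in b]


def _naming_oracle(config):
    """Brute-force rank computation over (sequence -> {species: count})."""
    chosen = {}
    for seq, species_counts in config.items():
        top = max(species_counts.values())
        species = min(s for s, c in species_counts.items() if c == top)
        chosen[seq] = (species, sum(species_counts.values()))
    names = {}
    per_species = {}
    for seq, (species, total) in chosen.items():
        per_species.setdefault(species, []).append((total, seq))
    for species, entries in per_species.items():
        entries.sort(key=lambda t: (-t[0], t[1]))
        for k, (_, seq) in enumerate(entries, 1):
            names[seq] = f"{species}.{k}"
    return names


def _records_from_config(config):
    recs, mapping = [], {}
    pos = 1
    for i, (seq, species_counts) in enumerate(sorted(config.items())):
        provs = []
        for species, count in sorted(species_counts.items()):
            for _ in range(count):
                p = _prov(pos)
                pos += 200
                mapping[p] = species
                provs.append(p)
        recs.append(_rec(f"r{i}", seq, count=len(provs), provs=provs))
    return recs, mapping


class TestAssignNames:
    def test_rank_within_species(self):
        config = {"AAAA": {"SpA": 5}, "CCCC": {"SpA": 2}}
        recs, mapping = _records_from_config(config)
        names = assign_names(recs, mapping)
        by_seq = {r.norm_sequence: names[r.id] for r in recs}
        assert by_seq == {"AAAA": "SpA.1", "CCCC": "SpA.2"}

    def test_most_frequent_species_wins(self):
        config = {"AAAA": {"SpA": 3, "SpB": 1}}
        recs, mapping = _records_from_config(config)
        names = assign_names(recs, mapping)
        assert names[recs[0].id] == "SpA.1"

    def test_single_record(self):
        recs, mapping = _records_from_config({"ACGT": {"SpZ": 1}})
        assert assign_names(recs, mapping) == {recs[0].id: "SpZ.1"}

    def test_missing_species_label_errors(self):
        recs, mapping = _records_from_config({"ACGT": {"SpZ": 1}})
        with pytest.raises(ValueError, match="no species label"):
            assign_names(recs, {})

    def test_names_unique_and_stable_under_reordering(self):
        rng = random.Random(0)
        config = {
            "".join(rng.choice("ACGT") for _ in range(8)): {
                f"Sp{rng.randint(0, 3)}": rng.randint(1, 4)
            }
            for _ in range(10)
        }
        recs, mapping = _records_from_config(config)
        names = assign_names(recs, mapping)
        assert len(set(names.values())) == len(names)
        shuffled = recs[:]
        rng.shuffle(shuffled)
        assert assign_names(shuffled, mapping) == names

    def test_matches_bruteforce_oracle(self):
        rng = random.Random(42)
        for _ in range(50):
            config = {}
            for _ in range(rng.randint(1, 8)):
                seq = "".join(rng.choice("ACGT") for _ in range(6))
                config[seq] = {
                    f"Sp{rng.randint(0, 2)}": rng.randint(1, 5)
                    for _ in range(rng.randint(1, 3))
                }
            recs, mapping = _records_from_config(config)
            names = assign_names(recs, mapping)
            expect = _naming_oracle(config)
            assert {r.norm_sequence: names[r.id] for r in recs} == expect


class TestFunnel:
    def test_planted_batch_counts(self):
        bundles, trnas = gen_funnel_batch(seed=3, n_clean=10, n_trna_decoys=3, n_truncated=2)
        report = curate_funnel(bundles, trnas, [])
        assert report.counts() == (15, 15, 12, 12, 10, 10)
        assert len(report.accepted) == 10

    def test_empty_batch(self):
        report = curate_funnel([], [], [])
        assert report.counts() == (0, 0, 0, 0, 0, 0)

    def test_all_identical_to_database_dropped(self):
        refs = [gen_gene(GenConfig(seed=600 + i))[0] for i in range(3)]
        bundles, trnas = gen_funnel_batch(
            seed=4, n_clean=0, n_trna_decoys=0, n_truncated=0, n_duplicates=3, references=refs
        )
        report = curate_funnel(bundles, trnas, refs)
        assert report.counts()[0] == 3
        assert report.counts()[1] == 0
        assert all(
            RejectReason.DUPLICATE in r.reject_reasons for r in report.rejected
        )

    def test_counts_non_increasing(self):
        bundles, trnas = gen_funnel_batch(seed=5)
        report = curate_funnel(bundles, trnas, [])
        counts = report.counts()[1:]  # first stage is raw hit count
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_every_drop_carries_reason(self):
        bundles, trnas = gen_funnel_batch(seed=6)
        report = curate_funnel(bundles, trnas, [])
        assert all(r.reject_reasons for r in report.rejected)


class TestFlatfile:
    def test_round_trip(self):
        recs = [gen_gene(GenConfig(seed=200 + i))[0] for i in range(5)]
        assert read_flatfile(write_flatfile(recs)) == recs

    def test_round_trip_intron_record(self, intron_gene):
        rec, truth = intron_gene
        (back,) = read_flatfile(write_flatfile([rec]))
        assert back == rec
        assert back.segments.first("INTRON").start == truth.intron_start

    def test_corrupt_form_token(self):
        recs = [gen_gene(GenConfig(seed=300))[0]]
        text = write_flatfile(recs).replace("standard", "standrad")
        with pytest.raises(FlatfileError, match="line 2"):
            read_flatfile(text)

    def test_round_trip_all_forms(self):
        recs = []
        for i, form in enumerate(GeneForm):
            cfg = GenConfig(seed=400 + i, form=form)
            recs.append(gen_gene(cfg)[0])
        assert read_flatfile(write_flatfile(recs)) == recs
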