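import pytest

from atcmap import (
    EntryBucket,
    GoldAnnotation,
    NAME_ONLY,
    RadKind,
    RadTarget,
    StandardizedRecord,
    classify_entry,
    evaluate,
    load_gold_tsv,
    standardize,
    summarize,
    write_gold_tsv,
)


def record(entry_id="e1", anti=(), additional=(), medication=(), study=(), info=()):
    return StandardizedRecord(
        entry_id=entry_id,
        original_text="x",
        antineoplastic_medication=tuple(anti),
        additional_medication=tuple(additional),
        medication=tuple(medication),
        study=tuple(study),
        info=tuple(info),
    )


class TestClassifyEntry:
    def test_expected_code_present_is_success(self):
        gold = GoldAnnotation("e1", expected_tokens=(("METHOTREXAT", "L01BA01"),))
        out = classify_entry(record(anti=("L01BA01",)), gold)
        assert out.bucket == EntryBucket.SUCCESS
        assert (out.n_token_success, out.n_token_failure) == (1, 0)

    def test_missing_expected_code_is_error(self):
        gold = GoldAnnotation(
            "e1",
            expected_tokens=(("CISPLATIN", "L01XA01"), ("ETOPOSID", "L01CB01")),
        )
        out = classify_entry(record(anti=("L01XA01",)), gold)
        assert out.bucket == EntryBucket.ERROR
        assert out.n_token_failure == 1
        assert out.failed_tokens == ("ETOPOSID",)

    def test_code_found_in_either_code_column(self):
        gold = GoldAnnotation("e1", expected_tokens=(("ONDANSETRON", "A04AA01"),))
        out = classify_entry(record(additional=("A04AA01",)), gold)
        assert out.bucket == EntryBucket.SUCCESS

    def test_nothing_expected_nothing_produced_is_no_info(self):
        out = classify_entry(record(), GoldAnnotation("e1"))
        assert out.bucket == EntryBucket.NO_INFO

    def test_info_only_entry_is_success_not_no_info(self):
        gold = GoldAnnotation("e1", expected_info=("best supportive care",))
        out = classify_entry(record(info=("best supportive care",)), gold)
        assert out.bucket == EntryBucket.SUCCESS
        assert out.has_additional_info

    def test_missing_name_only_token_is_error(self):
        gold = GoldAnnotation("e1", expected_tokens=(("PLACEBOMYCIN", NAME_ONLY),))
        assert classify_entry(record(), gold).bucket == EntryBucket.ERROR
        ok = classify_entry(record(medication=("PLACEBOMYCIN",)), gold)
        assert ok.bucket == EntryBucket.SUCCESS

    def test_entry_id_mismatch_is_hard_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            classify_entry(record("e1"), GoldAnnotation("e2"))


class TestSummarize:
    def test_rate_arithmetic(self):
        outcomes = []
        for i in range(9):
            gold = GoldAnnotation(f"e{i}", expected_tokens=(("T", "L01BA01"),))
            outcomes.append(classify_entry(record(f"e{i}", anti=("L01BA01",)), gold))
        gold = GoldAnnotation("e9", expected_tokens=(("T", "L01CB01"),))
        outcomes.append(classify_entry(record("e9"), gold))
        summary = summarize(outcomes)
        assert summary.entry_rates[EntryBucket.SUCCESS] == 90.0
        assert summary.token_rates[EntryBucket.SUCCESS] == 90.0
        assert summary.n_tokens == 10

    def test_every_entry_in_exactly_one_bucket(self):
        outcomes = [
            classify_entry(record("a", anti=("L01BA01",)),
                           GoldAnnotation("a", expected_tokens=(("T", "L01BA01"),))),
            classify_entry(record("b"),
                           GoldAnnotation("b", expected_tokens=(("T", "L01BA01"),))),
            classify_entry(record("c"), GoldAnnotation("c")),
        ]
        summary = summarize(outcomes)
        assert sum(summary.entry_counts.values()) == 3
        assert set(o.bucket for o in outcomes) == {
            EntryBucket.SUCCESS, EntryBucket.ERROR, EntryBucket.NO_INFO,
        }

    def test_no_info_entries_count_one_token_each(self):
        outcomes = [classify_entry(record("a"), GoldAnnotation("a"))]
        summary = summarize(outcomes)
        assert summary.n_tokens == 1
        assert summary.token_counts[EntryBucket.NO_INFO] == 1

    def test_empty_input_rates_are_null(self):
        summary = summarize([])
        assert summary.n_entries == summary.n_tokens == 0
        assert all(r is None for r in summary.entry_rates.values())

    def test_two_path_aggregation_consistency(self, fixture_set):
        """Recomputing aggregates from per-entry outcomes equals direct sums."""
        atc, rad, stop, corpus = fixture_set
        records = standardize(corpus.entries, atc, rad, stop)
        outcomes, summary = evaluate(records, corpus.gold_annotations)
        assert summary.token_counts[EntryBucket.SUCCESS] == sum(
            o.n_token_success for o in outcomes
        )
        assert summary.entry_counts[EntryBucket.SUCCESS] == sum(
            o.bucket == EntryBucket.SUCCESS for o in outcomes
        )
        assert summary.n_entries_with_additional_info == sum(
            o.has_additional_info for o in outcomes
        )


class TestEvaluate:
    def test_orphaned_ids_are_hard_error(self):
        with pytest.raises(ValueError, match="orphaned ids: e2"):
            evaluate([record("e1")], [GoldAnnotation("e1"), GoldAnnotation("e2")])

    def test_closed_loop_is_perfect_on_clean_corpus(self, fixture_set):
        atc, rad, stop, corpus = fixture_set
        records = standardize(corpus.entries, atc, rad, stop)
        _, summary = evaluate(records, corpus.gold_annotations)
        assert summary.token_rates[EntryBucket.SUCCESS] == 100.0
        assert summary.entry_rates[EntryBucket.SUCCESS] == 100.0

    def test_rad_fix_never_decreases_success(self, fixture_set):
        """Adding a correct RAD entry for a failing abbreviation is monotone."""
        from atcmap import RawEntry, RegimenDictionary

        atc, rad, stop, _ = fixture_set
        name = sorted(atc.keys())[0]
        code_sorted = sorted(atc.entries[name])
        l_codes = [c for c in code_sorted if c.startswith("L")]
        expected = l_codes[0] if l_codes else code_sorted[0]
        entries = [RawEntry("E00001", f"ZZABBREV + {name.capitalize()}")]
        gold = [
            GoldAnnotation(
                "E00001",
                expected_tokens=(("ZZABBREV", expected), (name, expected)),
            )
        ]

        _, before = evaluate(standardize(entries, atc, rad, stop), gold)
        fixed = RegimenDictionary(entries=dict(rad.entries))
        fixed.add("ZZABBREV", RadTarget(kind=RadKind.EXPANSION, names=(name,)))
        _, after = evaluate(standardize(entries, atc, fixed, stop), gold)
        for level in ("entry_rates", "token_rates"):
            b = getattr(before, level)[EntryBucket.SUCCESS] or 0.0
            a = getattr(after, level)[EntryBucket.SUCCESS] or 0.0
            assert a >= b
        assert after.token_rates[EntryBucket.SUCCESS] == 100.0


class TestGoldIO:
    def test_round_trip(self, tmp_path, fixture_set):
        _, _, _, corpus = fixture_set
        path = tmp_path / "gold.tsv"
        write_gold_tsv(corpus.gold_annotations, path)
        loaded = load_gold_tsv(path)
        assert len(loaded) == len(corpus.gold_annotations)
        for gold in corpus.gold_annotations:
            again = loaded[gold.entry_id]
            assert set(again.expected_tokens) == set(gold.expected_tokens)
            assert again.expected_study == gold.expected_study
            assert again.expected_info == gold.expected_info

    def test_empty_gold_file_is_hard_error(self, tmp_path):
        path = tmp_path / "gold.tsv"
        path.write_text("# entry_id\ttoken\texpected\n", encoding="utf-8")
        with pytest.raises(ValueError, match="empty gold file"):
            load_gold_tsv(path)

    def test_malformed_expected_value_rejected(self, tmp_path):
        path = tmp_path / "gold.tsv"
        path.write_text("e1\tTOK\tNOTACODE\n", encoding="utf-8")
        with pytest.raises(ValueError, match="NOTACODE"):
            load_gold_tsv(path)
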