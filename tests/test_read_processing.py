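"""Read processing: clip, demultiplex, trim, count, assemble-and-filter."""
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from bcstarprom.errors import (
    ConfigError,
    PipelineOrderError,
    QCError,
    TooShortReadError,
)
from bcstarprom.library_design import design_indexes
from bcstarprom.read_processing import (
    ReadLayout,
    SampleSheet,
    assemble_and_filter,
    clip_reporter_tail,
    count_barcodes,
    demultiplex,
    process_reads,
    trim_barcode_window,
)


def make_sheet(n=4, seed=3):
    idx = design_indexes(n, seed=seed)
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "index": [x.seq for x in idx],
                "treatment": ["drug"] * (n // 2) + ["DMSO"] * (n - n // 2),
                "time": list(range(n)),
            }
        )
    )


def make_read(index, barcode, tail="G" * 48):
    assert len(index) == 6 and len(barcode) == 20
    return index + "C" * 20 + barcode + "TCTAGA" + tail


class TestClip:
    def test_clip_at_anchor(self):
        head = "A" * 46
        assert clip_reporter_tail(head + "TCTAGA" + "G" * 40) == head

    def test_missing_anchor_flagged(self):
        assert clip_reporter_tail("A" * 100) is None

    def test_anchor_before_min_pos_ignored(self):
        # an anchor-like hexamer inside the protected window is skipped
        read = "A" * 10 + "TCTAGA" + "A" * 30 + "TCTAGA" + "C" * 10
        assert clip_reporter_tail(read) == "A" * 10 + "TCTAGA" + "A" * 30
        assert clip_reporter_tail("A" * 10 + "TCTAGA" + "A" * 20) is None


class TestDemultiplex:
    def test_exact_and_single_mismatch_assignment(self):
        sheet = make_sheet()
        idx = sheet.index_of["S1"]
        mutated = ("A" if idx[2] != "A" else "C").join([idx[:2], idx[3:]])
        reads = [("r0", make_read(idx, "A" * 20), "I" * 100),
                 ("r1", make_read(mutated, "A" * 20), "I" * 100)]
        assigned, unassigned = demultiplex(reads, sheet, max_mismatch=1)
        assert [r[0] for r in assigned["S1"]] == ["r0", "r1"]
        assert unassigned == []

    def test_two_mismatches_unassigned(self):
        sheet = make_sheet()
        idx = sheet.index_of["S0"]
        # mutate two positions: beyond the correction radius floor((3-1)/2)=1
        bad = "".join(
            ("A" if c != "A" else "C") if i < 2 else c for i, c in enumerate(idx)
        )
        others = set(sheet.index_of.values())
        if bad not in others:  # distance-3 code: 2 subs may still hit another index
            assigned, unassigned = demultiplex(
                [("r0", make_read(bad, "A" * 20), "I")], sheet, max_mismatch=1
            )
            assert len(unassigned) == 1

    def test_partition_property(self, rng):
        sheet = make_sheet()
        indexes = list(sheet.index_of.values())
        reads = []
        for i in range(200):
            if rng.random() < 0.8:
                idx = indexes[rng.integers(0, len(indexes))]
            else:
                idx = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 6)])
            reads.append((f"r{i}", make_read(idx, "A" * 20), "I"))
        assigned, unassigned = demultiplex(reads, sheet)
        total = sum(len(v) for v in assigned.values()) + len(unassigned)
        assert total == len(reads)
        ids = [r[0] for v in assigned.values() for r in v] + [r[0] for r in unassigned]
        assert len(set(ids)) == len(reads)

    def test_mismatch_monotonicity(self, rng):
        sheet = make_sheet()
        indexes = list(sheet.index_of.values())
        reads = []
        for i in range(300):
            idx = indexes[rng.integers(0, len(indexes))]
            if rng.random() < 0.5:
                pos = rng.integers(0, 6)
                idx = idx[:pos] + "ACGT"[rng.integers(0, 4)] + idx[pos + 1 :]
            reads.append((f"r{i}", make_read(idx, "A" * 20), "I"))
        a0, _ = demultiplex(reads, sheet, max_mismatch=0)
        a1, _ = demultiplex(reads, sheet, max_mismatch=1)
        for s in sheet.sample_ids:
            assert len(a1[s]) >= len(a0[s])

    def test_duplicate_indexes_rejected(self):
        frame = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "index": ["AAATTT", "AAATTT"],
                "treatment": ["drug", "DMSO"],
                "time": [0, 0],
            }
        )
        with pytest.raises(ConfigError):
            SampleSheet(frame)


class TestTrimAndCount:
    def test_trim_window(self):
        read = make_read("AAACCC", "T" * 20)
        assert trim_barcode_window(read) == "T" * 20
        # manual slice oracle: 1-based 27..46 == 0-based 26:46
        assert trim_barcode_window(read) == read[26:46]

    def test_too_short(self):
        with pytest.raises(TooShortReadError):
            trim_barcode_window("A" * 45)

    def test_counting(self):
        counts, off = count_barcodes(["X" * 20, "X" * 20, "X" * 20, "Y" * 20])
        assert counts == Counter({"X" * 20: 3, "Y" * 20: 1})
        assert sum(counts.values()) == 4 and not off

    def test_whitelist_split(self):
        counts, off = count_barcodes(["X" * 20, "Y" * 20], whitelist={"X" * 20})
        assert counts == Counter({"X" * 20: 1})
        assert off == Counter({"Y" * 20: 1})

    def test_untrimmed_input_rejected(self):
        with pytest.raises(PipelineOrderError):
            count_barcodes(["SHORT"])

    def test_matches_bruteforce_on_simulated_stream(self, rng):
        pool = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 20)]) for _ in range(30)]
        stream = [pool[rng.integers(0, 30)] for _ in range(10_000)]
        counts, _ = count_barcodes(stream)
        brute = {}
        for bc in stream:
            brute[bc] = brute.get(bc, 0) + 1
        assert dict(counts) == brute


class TestAssembleAndFilter:
    def test_filter_rules(self, truth_assoc):
        known = list(truth_assoc.barcodes)[:3]
        everywhere, partial, unknown = known[0], known[1], "A" * 20
        maps = {
            "S0": Counter({everywhere: 5, partial: 2, unknown: 7}),
            "S1": Counter({everywhere: 3, unknown: 1}),
        }
        table = assemble_and_filter(maps, truth_assoc)
        assert list(table.index) == [everywhere]
        qc = table.attrs["qc"]
        assert qc["dropped_not_everywhere"] == 1
        assert qc["dropped_unassociated"] == 1

    def test_zero_read_sample_is_qc_error(self, truth_assoc):
        with pytest.raises(QCError):
            assemble_and_filter({"S0": Counter({"A" * 20: 1}), "S1": Counter()},
                                truth_assoc)


class TestStreamingPipeline:
    def test_process_reads_equals_composed_ops(self, rng, truth_assoc):
        sheet = make_sheet()
        barcodes = list(truth_assoc.barcodes)[:6]
        reads = []
        for i in range(2000):
            idx = list(sheet.index_of.values())[rng.integers(0, 4)]
            bc = barcodes[rng.integers(0, len(barcodes))]
            reads.append((f"r{i}", make_read(idx, bc), "I" * 100))
        counts, qc = process_reads(iter(reads), sheet)
        assert qc["reads_in"] == 2000
        assert sum(qc["assigned"].values()) == 2000
        # composed-operation oracle
        assigned, _ = demultiplex(reads, sheet)
        for s, recs in assigned.items():
            trimmed = [
                trim_barcode_window(clip_reporter_tail(r[1])) for r in recs
            ]
            expect, _ = count_barcodes(trimmed)
            assert counts[s] == expect
        # column sums equal parsed reads per sample
        for s in sheet.sample_ids:
            assert sum(counts[s].values()) == qc["assigned"][s]

    def test_read_order_invariance(self, rng, truth_assoc):
        sheet = make_sheet()
        barcodes = list(truth_assoc.barcodes)[:4]
        reads = [
            (f"r{i}", make_read(list(sheet.index_of.values())[i % 4],
                                barcodes[rng.integers(0, 4)]), "I")
            for i in range(500)
        ]
        c1, _ = process_reads(iter(reads), sheet)
        c2, _ = process_reads(iter(reads[::-1]), sheet)
        assert c1 == c2
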