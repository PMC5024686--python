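"""Screen read processing: multiplexed FASTQ -> filtered barcode count table.

The screen amplicon has a fixed architecture on each 100-nt read: a 6-nt
sample index (positions 1-6), a 20-nt constant spacer (7-26), the 20-nt
barcode (27-46) and the XbaI site (TCTAGA) opening the reporter 3'UTR tail.
Processing mirrors the classic barcode-splitter pipeline: clip the tail at
the XbaI anchor, demultiplex on the index (with single-substitution
correction justified by the Hamming-3 index design), trim the fixed barcode
window, count exact barcode sequences per sample, and keep barcodes that are
observed in every sample and whose promoter association is known.

Paper-style coordinates are 1-based inclusive at this module's API boundary
(`ReadLayout`); everything internal is 0-based half-open.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

from ._dna import hamming_distance
from .errors import ConfigError, PipelineOrderError, QCError, TooShortReadError
from .association import AssociationTable

__all__ = [
    "ReadLayout",
    "SampleSheet",
    "clip_reporter_tail",
    "build_index_lookup",
    "demultiplex",
    "trim_barcode_window",
    "count_barcodes",
    "process_reads",
    "assemble_and_filter",
]


@dataclass(frozen=True)
class ReadLayout:
    """Fixed amplicon geometry, spans in 1-based inclusive coordinates."""

    index_span: tuple[int, int] = (1, 6)
    barcode_span: tuple[int, int] = (27, 46)
    tail_anchor: str = "TCTAGA"

    def __post_init__(self):
        if self.index_span[1] >= self.barcode_span[0]:
            raise ConfigError("index and barcode spans must be ordered and disjoint")

    @property
    def index_slice(self) -> slice:
        return slice(self.index_span[0] - 1, self.index_span[1])

    @property
    def barcode_slice(self) -> slice:
        return slice(self.barcode_span[0] - 1, self.barcode_span[1])

    @property
    def barcode_length(self) -> int:
        return self.barcode_span[1] - self.barcode_span[0] + 1

    @property
    def index_length(self) -> int:
        return self.index_span[1] - self.index_span[0] + 1

    @property
    def min_anchor_pos(self) -> int:
        """First 1-based position at which the tail anchor may legitimately
        start (immediately after the barcode window)."""
        return self.barcode_span[1] + 1


@dataclass
class SampleSheet:
    """Sample metadata: one row per demultiplexed sample.

    ``frame`` columns: sample_id, index, treatment, time, replicate.
    """

    frame: pd.DataFrame
    min_index_dist: int = 3

    REQUIRED = ("sample_id", "index", "treatment", "time")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ConfigError(f"sample sheet missing columns: {missing}")
        if "replicate" not in self.frame.columns:
            self.frame = self.frame.assign(replicate=1)
        ids = self.frame["sample_id"]
        if ids.duplicated().any():
            raise ConfigError("duplicate sample_ids in sample sheet")
        idx = list(self.frame["index"])
        if len(set(idx)) != len(idx):
            raise ConfigError("duplicate indexes in sample sheet")
        if len(set(map(len, idx))) > 1:
            raise ConfigError("indexes have unequal lengths")
        for i, a in enumerate(idx):
            for b in idx[i + 1 :]:
                if hamming_distance(a, b) < self.min_index_dist:
                    raise ConfigError(
                        f"indexes {a} and {b} closer than Hamming {self.min_index_dist}"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def index_of(self) -> dict[str, str]:
        return dict(zip(self.frame["sample_id"], self.frame["index"]))

    def samples_where(self, **criteria) -> list[str]:
        mask = pd.Series(True, index=self.frame.index)
        for col, val in criteria.items():
            if callable(val):
                mask &= self.frame[col].map(val)
            else:
                mask &= self.frame[col] == val
        return list(self.frame.loc[mask, "sample_id"])


# ---------------------------------------------------------------------------
# per-read operations
# ---------------------------------------------------------------------------

def clip_reporter_tail(read: str, anchor: str = "TCTAGA", min_pos: int = 47) -> str | None:
    """Truncate a read immediately before the first anchor occurrence at or
    after 1-based position ``min_pos``; None flags an anchor-less read.

    ``min_pos`` protects the barcode window: anchor-like subsequences inside
    the barcode itself are ignored.
    """
    i = read.find(anchor, min_pos - 1)
    return read[:i] if i != -1 else None


def build_index_lookup(sheet: SampleSheet, max_mismatch: int = 1) -> dict[str, str]:
    """Exact lookup table from (possibly corrupted) index to sample_id.

    With indexes at pairwise Hamming distance >= 3, radius-1 balls around the
    indexes are disjoint, so single-substitution correction is unambiguous;
    the construction still guards against accidental ball overlap.
    """
    if max_mismatch not in (0, 1):
        raise ConfigError("max_mismatch must be 0 or 1")
    lookup: dict[str, str] = {}
    for sid, idx in sheet.index_of.items():
        lookup[idx] = sid
    if max_mismatch == 1:
        for sid, idx in sheet.index_of.items():
            for pos in range(len(idx)):
                for b in "ACGT":
                    if b == idx[pos]:
                        continue
                    variant = idx[:pos] + b + idx[pos + 1 :]
                    prior = lookup.get(variant)
                    if prior is not None and prior != sid:
                        raise ConfigError(
                            f"index neighborhood collision between {prior} and {sid}"
                        )
                    lookup[variant] = sid
    return lookup


def demultiplex(
    reads: Iterable[tuple[str, str, str]],
    sheet: SampleSheet,
    max_mismatch: int = 1,
    layout: ReadLayout = ReadLayout(),
) -> tuple[dict[str, list[tuple[str, str, str]]], list[tuple[str, str, str]]]:
    """Partition reads by sample index; returns (per-sample streams, unassigned)."""
    lookup = build_index_lookup(sheet, max_mismatch)
    sl = layout.index_slice
    assigned: dict[str, list[tuple[str, str, str]]] = {s: [] for s in sheet.sample_ids}
    unassigned: list[tuple[str, str, str]] = []
    for rec in reads:
        sid = lookup.get(rec[1][sl])
        if sid is None:
            unassigned.append(rec)
        else:
            assigned[sid].append(rec)
    return assigned, unassigned


def trim_barcode_window(read: str, layout: ReadLayout = ReadLayout()) -> str:
    """Extract the fixed barcode window (1-based inclusive span)."""
    if len(read) < layout.barcode_span[1]:
        raise TooShortReadError(
            f"read of length {len(read)} shorter than barcode window end "
            f"{layout.barcode_span[1]}"
        )
    return read[layout.barcode_slice]


def count_barcodes(
    trimmed: Iterable[str],
    whitelist: set[str] | None = None,
    barcode_length: int = 20,
) -> tuple[Counter, Counter]:
    """Exact-sequence counting of trimmed barcodes.

    Returns (whitelisted counts, off-whitelist counts); with no whitelist the
    second counter stays empty and everything lands in the first.
    """
    kept: Counter = Counter()
    off: Counter = Counter()
    for bc in trimmed:
        if len(bc) != barcode_length:
            raise PipelineOrderError(
                f"barcode of length {len(bc)} reached counting; trim first"
            )
        if whitelist is not None and bc not in whitelist:
            off[bc] += 1
        else:
            kept[bc] += 1
    return kept, off


# ---------------------------------------------------------------------------
# streaming pipeline
# ---------------------------------------------------------------------------

def process_reads(
    reads: Iterable[tuple[str, str, str]],
    sheet: SampleSheet,
    layout: ReadLayout = ReadLayout(),
    max_mismatch: int = 1,
    whitelist: set[str] | None = None,
) -> tuple[dict[str, Counter], dict]:
    """Single-pass clip + demultiplex + trim + count over a read stream.

    Semantically identical to composing the individual operations, but
    streaming so that multi-million-read runs never hold reads in memory.
    Returns per-sample barcode counters and a QC funnel dict.
    """
    lookup = build_index_lookup(sheet, max_mismatch)
    isl = layout.index_slice
    bsl = layout.barcode_slice
    anchor = layout.tail_anchor
    min0 = layout.min_anchor_pos - 1
    need = layout.barcode_span[1]
    counts: dict[str, Counter] = {s: Counter() for s in sheet.sample_ids}
    qc = {
        "reads_in": 0,
        "unassigned": 0,
        "no_anchor": 0,
        "too_short": 0,
        "off_whitelist": 0,
        "assigned": Counter(),
    }
    for _rid, seq, _qual in reads:
        qc["reads_in"] += 1
        i = seq.find(anchor, min0)
        if i == -1:
            qc["no_anchor"] += 1
            continue
        clipped = seq[:i]
        sid = lookup.get(clipped[isl])
        if sid is None:
            qc["unassigned"] += 1
            continue
        if len(clipped) < need:
            qc["too_short"] += 1
            continue
        bc = clipped[bsl]
        if whitelist is not None and bc not in whitelist:
            qc["off_whitelist"] += 1
            continue
        counts[sid][bc] += 1
        qc["assigned"][sid] += 1
    qc["assigned"] = dict(qc["assigned"])
    return counts, qc


def assemble_and_filter(
    count_maps: Mapping[str, Counter | Mapping[str, int]],
    association: AssociationTable,
    min_count: int = 1,
) -> pd.DataFrame:
    """Join per-sample counts into a barcode x sample table and filter.

    Retained barcodes have count >= ``min_count`` in *every* sample and a
    known promoter association; spurious sequences born of sequencing errors
    fail one of the two. The dropped-row tally is stored in ``.attrs['qc']``.
    """
    if not count_maps:
        raise QCError("no samples to assemble")
    for sid, cm in count_maps.items():
        if sum(cm.values()) == 0:
            raise QCError(f"sample {sid!r} has zero parsed reads")
    table = pd.DataFrame(count_maps).fillna(0).astype(int)
    table.index.name = "barcode"
    table = table[list(count_maps)]
    everywhere = (table >= min_count).all(axis=1)
    known = table.index.to_series().isin(association.barcodes)
    kept = table[everywhere & known].sort_index()
    kept.attrs["qc"] = {
        "barcodes_seen": int(len(table)),
        "dropped_not_everywhere": int((~everywhere).sum()),
        "dropped_unassociated": int((everywhere & ~known).sum()),
        "retained": int(len(kept)),
    }
    return kept
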