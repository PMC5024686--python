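"""Barcode-to-promoter association.

Each reporter plasmid carries its barcode ~1.7 kb downstream of the promoter
repeats, too far apart for a short read. Two strategies link them:

* long reads spanning the whole NheI-XbaI fragment (promoter + barcode);
* short junction reads: the NheI-XbaI fragment is self-ligated into a circle,
  which brings the barcode (fragment 3' end) directly next to the first
  promoter repeat (fragment 5' start); reopening the circle with one of three
  backbone cutters (ApaI/FspI/HincII, pooled aliquots) yields PCR-able
  templates whose junction a 150-nt read can cover.

Parsed (barcode, promoter) pairs are aggregated into an association table;
barcodes supported by more than ``min_reads`` reads are retained, and a
barcode claiming two promoters is dropped and reported (the degenerate
barcode space is in vast excess over the library, so such collisions indicate
chimeric molecules rather than true double assignments).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._dna import fuzzy_find, matches_within, reverse_complement
from .errors import ValidationError
from .library_design import (
    LINEARIZATION_ENZYMES,
    RESTRICTION_SITES,
    Construct,
    VectorTemplate,
    default_template,
)

__all__ = [
    "Fragment",
    "AssociationTable",
    "AssociationReport",
    "insilico_digest",
    "nhe_xba_fragment",
    "circularize_fragment",
    "linearize_circle",
    "junction_window",
    "parse_junction_read",
    "parse_long_read",
    "build_association_table",
    "validate_association",
    "write_association",
    "read_association",
]

#: Junction-read geometry: bases kept upstream (barcode side) and downstream
#: (promoter side) of the circularization junction; 40 + 110 = 150-nt reads.
JUNCTION_UP = 40
JUNCTION_DOWN = 110

DEFAULT_MIN_READS = 50  # retained rows need support strictly greater than this


@dataclass
class Fragment:
    seq: str
    source_id: str = ""
    kind: str = "linear"  # or "circular"

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AssociationReport:
    collisions: list[str]
    multi_barcode_promoters: list[str]


@dataclass
class AssociationTable:
    """Barcode -> promoter mapping with read support.

    ``table`` has columns (barcode, promoter_id, read_support); ``conflicts``
    lists barcodes excluded because two promoters both exceeded the support
    threshold.
    """

    table: pd.DataFrame
    conflicts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["barcode", "promoter_id", "read_support"]
        )
    )
    min_reads: int = DEFAULT_MIN_READS

    def __len__(self) -> int:
        return len(self.table)

    @property
    def barcodes(self) -> set[str]:
        return set(self.table["barcode"])

    def promoter_of(self, barcode: str) -> str:
        hit = self.table.loc[self.table["barcode"] == barcode, "promoter_id"]
        if hit.empty:
            raise KeyError(barcode)
        return str(hit.iloc[0])

    def barcode_to_promoter(self) -> dict[str, str]:
        return dict(zip(self.table["barcode"], self.table["promoter_id"]))


# ---------------------------------------------------------------------------
# in-silico restriction chemistry
# ---------------------------------------------------------------------------

def insilico_digest(
    seq: str, sites: Sequence[tuple[str, str]], source_id: str = ""
) -> list[Fragment]:
    """Cut a linear sequence at every occurrence of the recognition 6-mers.

    All enzymes used here are palindromic, so scanning the forward strand
    finds every site regardless of strand. Cuts are modeled blunt at the
    site start.
    """
    if not seq:
        raise ValueError("cannot digest an empty sequence")
    cuts: list[int] = []
    for _name, site in sites:
        start = 0
        while True:
            i = seq.find(site, start)
            if i == -1:
                break
            cuts.append(i)
            start = i + 1
    cuts = sorted(set(cuts))
    bounds = [0] + cuts + [len(seq)]
    return [
        Fragment(seq=seq[a:b], source_id=source_id)
        for a, b in zip(bounds, bounds[1:])
        if b > a
    ]


def nhe_xba_fragment(construct: Construct) -> Fragment:
    """The gel-purified NheI-XbaI fragment carrying promoter and barcode."""
    frags = insilico_digest(
        construct.sequence,
        [("NheI", RESTRICTION_SITES["NheI"]), ("XbaI", RESTRICTION_SITES["XbaI"])],
        source_id=construct.library_id,
    )
    for f in frags:
        if construct.barcode in f.seq and construct.promoter.seq in f.seq:
            return f
    raise ValidationError(
        f"no single NheI-XbaI fragment of {construct.library_id} contains both "
        "promoter and barcode"
    )


def circularize_fragment(f: Fragment) -> Fragment:
    """Intramolecular ligation: former 3' end abuts the former 5' end."""
    if f.kind == "circular":
        raise ValueError("fragment is already circular")
    return Fragment(seq=f.seq, source_id=f.source_id, kind="circular")


def linearize_circle(
    c: Fragment, enzymes: Sequence[tuple[str, str]] = LINEARIZATION_ENZYMES
) -> list[Fragment]:
    """Reopen a circle independently with each enzyme and pool the aliquots.

    For each enzyme with at least one site the circle is opened at its first
    site; enzymes without a site contribute nothing. An uncut circle (no
    enzyme has a site) yields an empty pool with a warning -- such a molecule
    would simply never amplify.
    """
    if c.kind != "circular":
        raise ValueError("linearize_circle requires a circular fragment")
    if not enzymes:
        raise ValueError("enzyme list is empty")
    doubled = c.seq + c.seq
    out: list[Fragment] = []
    for name, site in enzymes:
        i = doubled.find(site)
        if i == -1 or i >= len(c.seq):
            continue
        out.append(
            Fragment(
                seq=c.seq[i:] + c.seq[:i],
                source_id=f"{c.source_id}|{name}" if c.source_id else name,
            )
        )
    if not out:
        warnings.warn(
            f"no linearization enzyme cuts circle {c.source_id or '<anonymous>'}; "
            "template lost",
            stacklevel=2,
        )
    return out


def junction_window(
    fragment_seq: str, up: int = JUNCTION_UP, down: int = JUNCTION_DOWN
) -> str:
    """Sequence across the circularization junction of a fragment's circle.

    ``up`` bases from the fragment 3' end (constant spacer tail + barcode)
    followed by ``down`` bases from its 5' start (NheI + first repeat).
    """
    return fragment_seq[-up:] + fragment_seq[:down]


# ---------------------------------------------------------------------------
# read parsing
# ---------------------------------------------------------------------------

def parse_junction_read(
    read: str,
    template: VectorTemplate | None = None,
    whitelist: set[str] | None = None,
    max_anchor_mismatch: int = 1,
) -> tuple[str, str] | None:
    """Extract (barcode, first-repeat core prefix) from a junction read.

    Anchors (the 20-nt constant spacer, the NheI site and the repeat left
    flank) tolerate up to one substitution each; the barcode itself is taken
    verbatim -- the random 3^20 space guarantees no minimum distance, so no
    error correction is attempted. Returns None when the read cannot be
    parsed or the barcode is off-whitelist.
    """
    tpl = template or default_template()
    bc_len = len(tpl.pattern)
    i = fuzzy_find(read, tpl.constant_spacer, max_anchor_mismatch)
    if i == -1:
        return None
    p = i + len(tpl.constant_spacer)
    if p + bc_len + 6 + len(tpl.left_flank) > len(read):
        return None
    barcode = read[p : p + bc_len]
    p += bc_len
    if not matches_within(read[p : p + 6], RESTRICTION_SITES["NheI"], max_anchor_mismatch):
        return None
    p += 6
    lf = tpl.left_flank
    if not matches_within(read[p : p + len(lf)], lf, max_anchor_mismatch):
        return None
    p += len(lf)
    prefix = read[p : p + tpl.core_length]
    if not prefix:
        return None
    if whitelist is not None and barcode not in whitelist:
        return None
    return barcode, prefix


def parse_long_read(
    read: str,
    template: VectorTemplate | None = None,
    max_anchor_mismatch: int = 1,
    _retry: bool = True,
) -> tuple[list[str], str] | None:
    """Recover all repeat cores and the barcode from a full-fragment read.

    The read is expected to span the NheI-XbaI fragment; anchored splitting
    on the constant flanks pulls out every 68-mer core and the 20-nt barcode.
    If the forward orientation fails, the reverse complement is tried once.
    """
    tpl = template or default_template()
    if len(read) == tpl.fragment_length:
        parsed = _parse_long_fixed(read, tpl, max_anchor_mismatch)
        if parsed is not None:
            return parsed
    if _retry:
        return parse_long_read(
            reverse_complement(read), tpl, max_anchor_mismatch, _retry=False
        )
    return None


def _parse_long_fixed(
    read: str, tpl: VectorTemplate, mm: int
) -> tuple[list[str], str] | None:
    p = 0
    if not matches_within(read[:6], RESTRICTION_SITES["NheI"], mm):
        return None
    p = 6
    cores: list[str] = []
    for _ in range(tpl.n_repeats):
        if not matches_within(read[p : p + len(tpl.left_flank)], tpl.left_flank, mm):
            return None
        p += len(tpl.left_flank)
        cores.append(read[p : p + tpl.core_length])
        p += tpl.core_length
        if not matches_within(read[p : p + len(tpl.right_flank)], tpl.right_flank, mm):
            return None
        p += len(tpl.right_flank)
    if not matches_within(read[p : p + 6], RESTRICTION_SITES["HindIII"], mm):
        return None
    bc_len = len(tpl.pattern)
    spacer_start = len(read) - bc_len - len(tpl.constant_spacer)
    if not matches_within(
        read[spacer_start : spacer_start + len(tpl.constant_spacer)],
        tpl.constant_spacer,
        mm,
    ):
        return None
    return cores, read[len(read) - bc_len :]


# ---------------------------------------------------------------------------
# table construction and validation
# ---------------------------------------------------------------------------

def build_association_table(
    pairs: Iterable[tuple[str, str]], min_reads: int = DEFAULT_MIN_READS
) -> AssociationTable:
    """Aggregate parsed (barcode, promoter) pairs into an association table.

    Support is the number of identical pairs observed; rows are retained when
    support is strictly greater than ``min_reads``. A barcode for which two
    promoters both pass the threshold is excluded from the table and recorded
    in ``conflicts``.
    """
    counts: dict[tuple[str, str], int] = {}
    for bc, prom in pairs:
        key = (bc, prom)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"barcode": bc, "promoter_id": prom, "read_support": n}
        for (bc, prom), n in counts.items()
        if n > min_reads
    ]
    df = pd.DataFrame(rows, columns=["barcode", "promoter_id", "read_support"])
    dup = df["barcode"].duplicated(keep=False)
    conflicts = df[dup].sort_values(["barcode", "promoter_id"]).reset_index(drop=True)
    table = (
        df[~dup]
        .sort_values(["promoter_id", "barcode"])
        .reset_index(drop=True)
    )
    return AssociationTable(table=table, conflicts=conflicts, min_reads=min_reads)


def validate_association(t: AssociationTable) -> AssociationReport:
    """QC report: barcode collisions (must be empty for a valid table) and
    promoters legitimately carrying several barcodes (internal replicates)."""
    collisions = sorted(
        set(t.table.loc[t.table["barcode"].duplicated(keep=False), "barcode"])
        | set(t.conflicts["barcode"])
    )
    by_prom = t.table.groupby("promoter_id")["barcode"].nunique()
    multi = sorted(by_prom[by_prom > 1].index)
    return AssociationReport(collisions=collisions, multi_barcode_promoters=multi)


def write_association(t: AssociationTable, path: str | Path,
                      meta: dict | None = None) -> Path:
    from .io import write_tsv

    path = Path(path)
    write_tsv(t.table, path, meta=meta)
    if len(t.conflicts):
        write_tsv(t.conflicts, path.with_suffix(".conflicts.tsv"), meta=meta)
    return path


def read_association(path: str | Path) -> AssociationTable:
    from .io import read_tsv

    return AssociationTable(table=read_tsv(path))
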