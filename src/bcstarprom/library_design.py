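"""Design of the combinatorial reporter library.

A library plasmid couples a synthetic promoter -- six tandem 84-bp repeat
units, each holding a 68-bp random core between fixed 8-bp flanks -- to a
20-nt degenerate barcode in the reporter 3'UTR. Barcodes are synthesized from
an IUPAC pattern in which every position admits exactly three nucleotides
(codes H, D, V, B), which avoids homopolymer runs and makes single sequencing
errors detectable. Multiplexed samples are tagged with 6-nt indexes kept at
pairwise Hamming distance >= 3 so that any single substitution in the index
is still uniquely assignable.
"""
from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._dna import IUPAC, hamming_distance
from .errors import (
    CapacityError,
    InfeasibleDesignError,
    InvalidPatternError,
    ValidationError,
)

__all__ = [
    "CANONICAL_BARCODE_PATTERN",
    "RESTRICTION_SITES",
    "LINEARIZATION_ENZYMES",
    "DegeneratePattern",
    "SampleIndex",
    "RepeatUnit",
    "PromoterInsert",
    "Construct",
    "VectorTemplate",
    "default_template",
    "hamming_distance",
    "degenerate_space_size",
    "matches_pattern",
    "sample_barcodes",
    "design_indexes",
    "generate_repeat_unit",
    "generate_promoter_insert",
    "assemble_construct",
    "motif_occupancy_estimate",
    "screened_random_bp",
    "write_library",
    "load_manifest",
]

#: Degenerate synthesis pattern of the 20-nt barcode: every position admits
#: exactly three nucleotides, giving 3^20 ~ 3.5e9 possible barcodes.
CANONICAL_BARCODE_PATTERN = "HHDDDDHHBBVVDDDDHDBV"

#: Palindromic 6-cutter recognition sites used as cloning/linearization
#: landmarks. HincII is represented by its GTTAAC blunt site.
RESTRICTION_SITES = {
    "NheI": "GCTAGC",
    "HindIII": "AAGCTT",
    "XbaI": "TCTAGA",
    "ApaI": "GGGCCC",
    "FspI": "TGCGCA",
    "HincII": "GTTAAC",
}

#: Enzymes used to reopen barcode-promoter circles; each library circle is
#: digested with the three enzymes independently and the aliquots pooled, so
#: a site falling inside the junction region in one aliquot is rescued by the
#: other two.
LINEARIZATION_ENZYMES = [(n, RESTRICTION_SITES[n]) for n in ("ApaI", "FspI", "HincII")]

#: Hexamers that must not occur inside random repeat cores: a spurious
#: cloning-site occurrence would fragment the construct during the
#: association digest.
FORBIDDEN_CORE_SITES = tuple(RESTRICTION_SITES[n] for n in ("NheI", "HindIII", "XbaI"))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DegeneratePattern:
    """IUPAC pattern describing a degenerate synthesis scheme."""

    pattern: str

    def __post_init__(self):
        for c in self.pattern:
            if c not in IUPAC:
                raise InvalidPatternError(f"unknown IUPAC code {c!r} in pattern")

    def __len__(self) -> int:
        return len(self.pattern)

    @property
    def position_choices(self) -> list[str]:
        return [IUPAC[c] for c in self.pattern]


@dataclass(frozen=True)
class SampleIndex:
    seq: str
    sample_id: str


@dataclass(frozen=True)
class RepeatUnit:
    """One 84-bp tandem-repeat unit: 8-bp flank + 68-bp random core + 8-bp flank."""

    left_flank: str
    random_core: str
    right_flank: str

    @property
    def seq(self) -> str:
        return self.left_flank + self.random_core + self.right_flank

    def __len__(self) -> int:
        return len(self.left_flank) + len(self.random_core) + len(self.right_flank)


@dataclass(frozen=True)
class PromoterInsert:
    promoter_id: str
    units: tuple[RepeatUnit, ...]

    @property
    def seq(self) -> str:
        return "".join(u.seq for u in self.units)

    @property
    def cores(self) -> tuple[str, ...]:
        return tuple(u.random_core for u in self.units)

    @property
    def total_random_bp(self) -> int:
        return sum(len(u.random_core) for u in self.units)


@dataclass(frozen=True)
class Construct:
    """One assembled reporter plasmid region with its restriction landmarks."""

    library_id: str
    promoter: PromoterInsert
    barcode: str
    sequence: str
    landmarks: dict[str, int] = field(compare=False)


@dataclass(frozen=True)
class VectorTemplate:
    """Constant backbone context shared by every construct of a library.

    The published design fixes only the restriction landmarks and the repeat
    geometry; the flank/backbone sequences themselves are configuration, so
    the packaged defaults are arbitrary constants generated once (and checked
    to be free of spurious landmark sites).
    """

    upstream: str
    downstream: str
    reporter_stub: str
    constant_spacer: str        # 20-nt constant immediately 5' of the barcode
    left_flank: str             # 8-nt flank 5' of every random core
    right_flank: str            # 8-nt flank 3' of every random core
    barcode_pattern: str = CANONICAL_BARCODE_PATTERN
    n_repeats: int = 6
    core_length: int = 68

    @property
    def pattern(self) -> DegeneratePattern:
        return DegeneratePattern(self.barcode_pattern)

    @property
    def fragment_length(self) -> int:
        """Length of the NheI-XbaI fragment carrying promoter and barcode."""
        repeat = len(self.left_flank) + self.core_length + len(self.right_flank)
        return (
            6 + self.n_repeats * repeat + 6 + len(self.reporter_stub)
            + len(self.constant_spacer) + len(self.pattern)
        )


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _clean_random_dna(rng: np.random.Generator, length: int, forbidden: Sequence[str]) -> str:
    while True:
        seq = _random_dna(rng, length)
        if not any(f in seq for f in forbidden):
            return seq


@functools.lru_cache(maxsize=1)
def default_template() -> VectorTemplate:
    """Build the packaged default backbone template.

    The reporter stub stands in for the luciferase ORF/3'UTR between the
    HindIII site and the barcode; it carries single ApaI, FspI and HincII
    sites placed far (>200 bp) from both fragment ends so that reopening a
    circle at any of them leaves the barcode/promoter junction intact. The
    stub length is chosen so the NheI-XbaI fragment is 2275 bp for the
    default six-repeat geometry.
    """
    rng = np.random.default_rng(20160815)
    left_flank = "GACCTGGA"
    right_flank = "CTTCAGGC"
    constant_spacer = "ACGGCGATCTTGCCGTCAAT"
    forbidden = list(RESTRICTION_SITES.values()) + [constant_spacer]
    while True:
        s1 = _random_dna(rng, 400)
        s2 = _random_dna(rng, 400)
        s3 = _random_dna(rng, 400)
        s4 = _random_dna(rng, 501)
        stub = (
            s1 + RESTRICTION_SITES["ApaI"] + s2 + RESTRICTION_SITES["FspI"]
            + s3 + RESTRICTION_SITES["HincII"] + s4
        )
        counts = {f: stub.count(f) for f in forbidden}
        if (
            counts[RESTRICTION_SITES["ApaI"]] == 1
            and counts[RESTRICTION_SITES["FspI"]] == 1
            and counts[RESTRICTION_SITES["HincII"]] == 1
            and all(
                counts[f] == 0
                for f in forbidden
                if f not in (RESTRICTION_SITES["ApaI"], RESTRICTION_SITES["FspI"],
                             RESTRICTION_SITES["HincII"])
            )
        ):
            break
    upstream = _clean_random_dna(rng, 30, forbidden)
    downstream = _clean_random_dna(rng, 60, forbidden)
    return VectorTemplate(
        upstream=upstream,
        downstream=downstream,
        reporter_stub=stub,
        constant_spacer=constant_spacer,
        left_flank=left_flank,
        right_flank=right_flank,
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def degenerate_space_size(pattern: str | DegeneratePattern) -> int:
    """Number of distinct sequences admitted by a degenerate IUPAC pattern."""
    if not isinstance(pattern, DegeneratePattern):
        pattern = DegeneratePattern(pattern)
    return math.prod(len(c) for c in pattern.position_choices)


def matches_pattern(seq: str, pattern: str | DegeneratePattern) -> bool:
    """Position-by-position IUPAC membership test."""
    if not isinstance(pattern, DegeneratePattern):
        pattern = DegeneratePattern(pattern)
    if len(seq) != len(pattern):
        return False
    return all(b in c for b, c in zip(seq, pattern.position_choices))


def sample_barcodes(
    pattern: str | DegeneratePattern,
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Draw ``n`` distinct barcodes uniformly from a degenerate pattern space."""
    if not isinstance(pattern, DegeneratePattern):
        pattern = DegeneratePattern(pattern)
    space = degenerate_space_size(pattern)
    if n > space:
        raise CapacityError(f"requested {n} barcodes from a space of size {space}")
    if n == 0:
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    choices = [np.array(list(c)) for c in pattern.position_choices]
    seen: dict[str, None] = {}
    remaining = n
    while remaining > 0:
        draws = [c[rng.integers(0, len(c), size=remaining)] for c in choices]
        for row in zip(*draws):
            seen.setdefault("".join(row), None)
        remaining = n - len(seen)
    return list(seen)[:n]


def barcode_is_clonable(barcode: str, template: VectorTemplate | None = None) -> bool:
    """True when the barcode creates no spurious cloning site in context.

    A barcode containing (or creating, together with its constant
    neighbors) an NheI/XbaI/HindIII hexamer would be cut during library
    construction and fragment the association digest, so such barcodes are
    excluded at design time.
    """
    tpl = template or default_template()
    context = tpl.constant_spacer + barcode + RESTRICTION_SITES["XbaI"]
    return (
        context.count(RESTRICTION_SITES["XbaI"]) == 1
        and RESTRICTION_SITES["NheI"] not in context
        and RESTRICTION_SITES["HindIII"] not in context
    )


def design_indexes(
    n: int,
    length: int = 6,
    min_dist: int = 3,
    seed: int | np.random.Generator = 0,
    max_attempts: int = 50_000,
) -> list[SampleIndex]:
    """Greedy randomized construction of a Hamming-separated index set.

    Candidates are drawn uniformly and kept when they sit at distance
    >= ``min_dist`` from every accepted index; the search fails with
    :class:`InfeasibleDesignError` after ``max_attempts`` candidate draws,
    which (well before the sphere-packing bound) signals an infeasible request.
    """
    if n < 1:
        raise ValueError("need at least one index")
    if min_dist > length:
        raise ValueError("min_dist cannot exceed index length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    kept: list[str] = []
    attempts = 0
    while len(kept) < n:
        if attempts >= max_attempts:
            raise InfeasibleDesignError(
                f"could not place {n} indexes of length {length} at distance "
                f">= {min_dist} within {max_attempts} attempts ({len(kept)} placed)"
            )
        attempts += 1
        cand = "".join(bases[rng.integers(0, 4, size=length)])
        if all(hamming_distance(cand, k) >= min_dist for k in kept):
            kept.append(cand)
    return [SampleIndex(seq=s, sample_id=f"S{i + 1}") for i, s in enumerate(kept)]


def generate_repeat_unit(
    rng: np.random.Generator,
    left_flank: str | None = None,
    right_flank: str | None = None,
    core_length: int = 68,
    forbidden: Sequence[str] = FORBIDDEN_CORE_SITES,
) -> RepeatUnit:
    """One repeat unit with a uniformly random core.

    Cores are rejection-sampled so that the flanked unit contains none of the
    cloning hexamers (all palindromic, so one strand suffices); a spurious
    NheI/XbaI/HindIII site inside a repeat would break construct assembly and
    the association digest.
    """
    tpl = default_template()
    lf = left_flank if left_flank is not None else tpl.left_flank
    rf = right_flank if right_flank is not None else tpl.right_flank
    while True:
        core = _random_dna(rng, core_length)
        if not any(f in lf + core + rf for f in forbidden):
            return RepeatUnit(left_flank=lf, random_core=core, right_flank=rf)


def generate_promoter_insert(
    n_repeats: int,
    rng: np.random.Generator,
    promoter_id: str = "P0",
    left_flank: str | None = None,
    right_flank: str | None = None,
    core_length: int = 68,
) -> PromoterInsert:
    if n_repeats < 1:
        raise ValueError("a promoter insert needs at least one repeat unit")
    units = tuple(
        generate_repeat_unit(rng, left_flank, right_flank, core_length)
        for _ in range(n_repeats)
    )
    return PromoterInsert(promoter_id=promoter_id, units=units)


def assemble_construct(
    promoter: PromoterInsert,
    barcode: str,
    template: VectorTemplate | None = None,
    library_id: str | None = None,
) -> Construct:
    """Assemble backbone + promoter + reporter stub + barcode into one construct.

    Landmark offsets are 0-based positions of the recognition-site starts; the
    canonical order NheI < promoter < HindIII < stub < barcode < XbaI holds by
    construction and is re-checked.
    """
    tpl = template or default_template()
    if not matches_pattern(barcode, tpl.pattern):
        raise ValidationError(
            f"barcode {barcode!r} does not match pattern {tpl.barcode_pattern}"
        )
    parts = [
        tpl.upstream,
        RESTRICTION_SITES["NheI"],
        promoter.seq,
        RESTRICTION_SITES["HindIII"],
        tpl.reporter_stub,
        tpl.constant_spacer,
        barcode,
        RESTRICTION_SITES["XbaI"],
        tpl.downstream,
    ]
    seq = "".join(parts)
    off = len(tpl.upstream)
    landmarks: dict[str, int] = {"NheI": off}
    off += 6
    landmarks["promoter_start"] = off
    off += len(promoter.seq)
    landmarks["HindIII"] = off
    off += 6
    stub_start = off
    for enz in ("ApaI", "FspI", "HincII"):
        landmarks[enz] = stub_start + tpl.reporter_stub.index(RESTRICTION_SITES[enz])
    off += len(tpl.reporter_stub)
    landmarks["constant_spacer"] = off
    off += len(tpl.constant_spacer)
    landmarks["barcode_start"] = off
    off += len(barcode)
    landmarks["XbaI"] = off
    order = ["NheI", "promoter_start", "HindIII", "ApaI", "FspI", "HincII",
             "constant_spacer", "barcode_start", "XbaI"]
    offsets = [landmarks[k] for k in order]
    if offsets != sorted(offsets) or len(set(offsets)) != len(offsets):
        raise ValidationError("landmark order violated during assembly")
    return Construct(
        library_id=library_id or promoter.promoter_id,
        promoter=promoter,
        barcode=barcode,
        sequence=seq,
        landmarks=landmarks,
    )


def extract_barcode(construct: Construct) -> str:
    """Recover the barcode between its landmarks (round-trip check helper)."""
    s = construct.landmarks["barcode_start"]
    return construct.sequence[s : construct.landmarks["XbaI"]]


def extract_promoter(construct: Construct) -> str:
    s = construct.landmarks["promoter_start"]
    return construct.sequence[s : construct.landmarks["HindIII"]]


def motif_occupancy_estimate(
    motif_width: int,
    n_degenerate_variants: int = 1,
    total_random_bp: int = 416_840,
    strands: int = 2,
) -> tuple[float, float]:
    """Expected motif occurrences in the library's random sequence space.

    The premise of the screen is that binding sites are frequent in random
    DNA: a width-``w`` motif with ``v`` degenerate variants has expected hit
    count ``strands * v * (L - w + 1) / 4**w`` in ``L`` bp of uniform random
    sequence, and the chance of at least one occurrence follows the Poisson
    approximation ``1 - exp(-expected)``.
    """
    if motif_width < 1:
        raise ValueError("motif width must be >= 1")
    if total_random_bp < motif_width:
        raise ValueError("total random bp must be >= motif width")
    expected = (
        strands * n_degenerate_variants
        * (total_random_bp - motif_width + 1) / 4 ** motif_width
    )
    return expected, 1.0 - math.exp(-expected)


def screened_random_bp(n_barcodes: int, core_bp: int = 68, strands: int = 2) -> int:
    """Total random base pairs functionally screened.

    Each retained barcode reads out one 68-bp random core per repeat position
    screened on both DNA strands; the headline figure counts one core per
    barcode on both strands.
    """
    return n_barcodes * core_bp * strands


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_library(constructs: Iterable[Construct], out_dir: str | Path,
                  meta: dict | None = None) -> tuple[Path, Path]:
    """Write construct FASTA plus a TSV manifest (ids, barcode, landmarks)."""
    from .io import write_tsv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "library.fasta"
    rows = []
    with open(fasta, "w") as fh:
        for c in constructs:
            fh.write(f">{c.library_id}\n{c.sequence}\n")
            row = {
                "library_id": c.library_id,
                "promoter_id": c.promoter.promoter_id,
                "barcode": c.barcode,
                "cores": ";".join(c.promoter.cores),
            }
            row.update({f"offset_{k}": v for k, v in c.landmarks.items()})
            rows.append(row)
    manifest = out_dir / "manifest.tsv"
    write_tsv(pd.DataFrame(rows), manifest, meta=meta)
    return fasta, manifest


def load_manifest(path: str | Path) -> pd.DataFrame:
    from .io import read_tsv

    return read_tsv(path)
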