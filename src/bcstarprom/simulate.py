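"""Synthetic-data generator with known ground truth.

The simulator emulates the statistical structure the analysis assumes:

* a plasmid library of a few thousand constructs, each a six-repeat random
  promoter tied to a distinct degenerate barcode, with a small fraction of
  promoters deliberately duplicated under extra barcodes (as happens when
  the barcode space is in large excess);
* baseline reporter abundances spread over orders of magnitude (log-normal
  in log10 read units), emulating the wide basal-expression range of random
  promoters;
* drug induction as a gamma-like pulse 1 + A * (t/tau) * exp(1 - t/tau)
  that is exactly 1 at t = 0 and peaks with fold change 1 + A at t = tau;
  immediate-early responses use tau ~ 1-2 h, delayed responses tau ~ 3-4 h;
* screen sampling as a per-sample multinomial of the configured depth over
  the expected abundances, written as fixed-layout 100-nt reads (6-nt index,
  20-nt constant spacer, 20-nt barcode, XbaI anchor, constant filler) with
  i.i.d. substitution errors;
* association reads either as full NheI-XbaI fragments (long mode) or as
  150-nt reads across the circularization junction produced by the digest ->
  circularize -> linearize chain (junction mode).

Everything is driven by one seed; identical configurations give
byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._dna import IUPAC, reverse_complement
from .errors import ConfigError
from .association import (
    circularize_fragment,
    junction_window,
    linearize_circle,
    nhe_xba_fragment,
)
from .library_design import (
    CANONICAL_BARCODE_PATTERN,
    Construct,
    PromoterInsert,
    VectorTemplate,
    assemble_construct,
    default_template,
    design_indexes,
    generate_promoter_insert,
    sample_barcodes,
)
from .read_processing import SampleSheet

__all__ = [
    "PlantedGroup",
    "SimulationConfig",
    "default_groups",
    "simulate_library",
    "make_sample_sheet",
    "simulate_expression",
    "pulse",
    "simulate_counts",
    "simulate_screen_reads",
    "simulate_association_reads",
    "truth_association",
]

SCREEN_TIMES = (0, 1, 2, 4, 8)  # hours after treatment
READ_LENGTH = 100
JUNCTION_READ_LENGTH = 150


@dataclass(frozen=True)
class PlantedGroup:
    """A set of promoters carrying one motif and one induction program.

    ``consensus`` is an IUPAC string planted once per member promoter;
    ``amplitude``/``tau_hours`` parameterize the induction pulse under the
    drugs named in ``drugs``. Membership is set by ``fraction`` of the
    library or an explicit ``n_members``; ``amplitudes`` optionally gives a
    per-member amplitude schedule (length must equal the member count).
    """

    name: str
    consensus: str
    amplitude: float = 9.0
    tau_hours: float = 1.0
    drugs: tuple[str, ...] = ("jasplakinolide",)
    fraction: float | None = None
    n_members: int | None = None
    amplitudes: tuple[float, ...] | None = None

    def member_count(self, n_plasmids: int) -> int:
        if self.n_members is not None:
            return self.n_members
        if self.fraction is not None:
            return int(round(self.fraction * n_plasmids))
        raise ConfigError(f"group {self.name}: set fraction or n_members")


def default_groups() -> tuple[PlantedGroup, ...]:
    """Four kinetic archetypes mirroring the screen's response groups:
    immediate-early both-drug (CArG/SRF-like), strong immediate-early
    single-drug, delayed NFkB-like, and delayed AP-1-like."""
    both = ("jasplakinolide", "vinblastine")
    return (
        PlantedGroup("group1_carg_ie", "CCWWWWWWGG", amplitude=9.0,
                     tau_hours=1.0, drugs=both, fraction=0.005),
        PlantedGroup("group2_carg_strong", "CCWWWWWWGG", amplitude=29.0,
                     tau_hours=1.0, drugs=("jasplakinolide",), fraction=0.005),
        PlantedGroup("group3_nfkb_delayed", "GGGACTTTCC", amplitude=8.0,
                     tau_hours=3.0, drugs=("jasplakinolide",), fraction=0.005),
        PlantedGroup("group4_ap1_delayed", "TGACTCA", amplitude=8.0,
                     tau_hours=3.0, drugs=both, fraction=0.005),
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_plasmids: int = 3000
    n_repeats: int = 6
    barcode_pattern: str = CANONICAL_BARCODE_PATTERN
    baseline_log10_mu: float = 2.0
    baseline_log10_sigma: float = 0.8
    groups: tuple[PlantedGroup, ...] = field(default_factory=default_groups)
    drugs: tuple[str, ...] = ("jasplakinolide",)
    control_treatment: str = "DMSO"
    times: tuple[float, ...] = SCREEN_TIMES
    depth: int = 100_000
    error_rate: float = 0.0
    multi_barcode_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        total = sum(g.member_count(self.n_plasmids) for g in self.groups)
        if total > self.n_plasmids:
            raise ConfigError(
                f"planted groups claim {total} plasmids but the library has "
                f"{self.n_plasmids}"
            )
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ConfigError("error_rate must lie in [0, 1)")
        for g in self.groups:
            if g.tau_hours <= 0:
                raise ConfigError(f"group {g.name}: tau must be positive")
            for c in g.consensus:
                if c not in IUPAC:
                    raise ConfigError(f"group {g.name}: bad IUPAC code {c!r}")
        if 0 not in self.times:
            raise ConfigError("time 0 (pre-treatment control) must be present")


# ---------------------------------------------------------------------------
# library
# ---------------------------------------------------------------------------

def _clonable_barcodes(
    pattern: str, n: int, rng: np.random.Generator, tpl: VectorTemplate
) -> list[str]:
    """Distinct pattern-conforming barcodes that pass the clonability screen."""
    from .library_design import barcode_is_clonable

    kept: list[str] = []
    seen: set[str] = set()
    while len(kept) < n:
        for b in sample_barcodes(pattern, n - len(kept) + 8, rng):
            if b not in seen and barcode_is_clonable(b, tpl):
                seen.add(b)
                kept.append(b)
    return kept[:n]


def _resolve_iupac(consensus: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC[c][rng.integers(0, len(IUPAC[c]))] for c in consensus)


def _plant_site(
    promoter: PromoterInsert, site: str, rng: np.random.Generator
) -> tuple[PromoterInsert, int, int]:
    """Overwrite a random stretch of a random core with ``site``."""
    unit_i = int(rng.integers(0, len(promoter.units)))
    unit = promoter.units[unit_i]
    off = int(rng.integers(0, len(unit.random_core) - len(site) + 1))
    core = unit.random_core[:off] + site + unit.random_core[off + len(site) :]
    units = list(promoter.units)
    units[unit_i] = replace(unit, random_core=core)
    return replace(promoter, units=tuple(units)), unit_i, off


def simulate_library(
    cfg: SimulationConfig, template: VectorTemplate | None = None
) -> tuple[list[Construct], pd.DataFrame]:
    """Generate the plasmid library and its ground-truth table.

    Returns the constructs and a truth frame with one row per barcode:
    (barcode, promoter_id, group, motif, repeat_index, motif_offset,
    amplitude, tau, drugs). Planted consensus sites are written into a
    random repeat core with degenerate positions resolved randomly; a
    configurable fraction of promoters is duplicated under fresh barcodes to
    emulate multi-barcode promoters.
    """
    tpl = template or default_template()
    rng = np.random.default_rng(cfg.seed)
    r_lib, r_plant, r_dup = rng.spawn(3)

    n = cfg.n_plasmids
    promoters = [
        generate_promoter_insert(cfg.n_repeats, r_lib, promoter_id=f"P{i:05d}")
        for i in range(n)
    ]
    # assign group membership over a shuffled plasmid order
    order = r_plant.permutation(n)
    rows: list[dict] = []
    assignment: dict[int, tuple[PlantedGroup, float]] = {}
    cursor = 0
    for g in cfg.groups:
        count = g.member_count(n)
        amps = g.amplitudes if g.amplitudes is not None else (g.amplitude,) * count
        if len(amps) != count:
            raise ConfigError(f"group {g.name}: {len(amps)} amplitudes for {count} members")
        for j in range(count):
            assignment[int(order[cursor])] = (g, float(amps[j]))
            cursor += 1

    planted_meta: dict[int, tuple[str, int, int]] = {}
    for i in range(n):
        if i in assignment:
            g, _amp = assignment[i]
            site = _resolve_iupac(g.consensus, r_plant)
            promoters[i], unit_i, off = _plant_site(promoters[i], site, r_plant)
            planted_meta[i] = (site, unit_i, off)

    n_extra = int(round(cfg.multi_barcode_fraction * n))
    barcodes = _clonable_barcodes(cfg.barcode_pattern, n + n_extra, r_lib, tpl)
    constructs: list[Construct] = []
    for i in range(n):
        bc = barcodes[i]
        c = assemble_construct(promoters[i], bc, tpl, library_id=f"L{i:05d}")
        constructs.append(c)
        g, amp = assignment.get(i, (None, 0.0))
        site, unit_i, off = planted_meta.get(i, ("", -1, -1))
        rows.append(
            {
                "barcode": bc,
                "promoter_id": promoters[i].promoter_id,
                "group": g.name if g else "",
                "motif": site,
                "repeat_index": unit_i,
                "motif_offset": off,
                "amplitude": amp,
                "tau": g.tau_hours if g else 0.0,
                "drugs": ";".join(g.drugs) if g else "",
            }
        )
    # duplicate promoters under extra barcodes
    dup_targets = r_dup.choice(n, size=n_extra, replace=False) if n_extra else []
    for j, i in enumerate(dup_targets):
        bc = barcodes[n + j]
        c = assemble_construct(promoters[i], bc, tpl, library_id=f"L{n + j:05d}")
        constructs.append(c)
        base = rows[i]
        rows.append({**base, "barcode": bc})
    truth = pd.DataFrame(rows)
    return constructs, truth


# ---------------------------------------------------------------------------
# expression and counts
# ---------------------------------------------------------------------------

def pulse(t: float, amplitude: float, tau: float) -> float:
    """Gamma-like induction pulse: 1 at t = 0, maximum 1 + A at t = tau."""
    if tau <= 0:
        raise ConfigError("tau must be positive")
    return 1.0 + amplitude * (t / tau) * np.exp(1.0 - t / tau)


def make_sample_sheet(cfg: SimulationConfig, replicate: int = 1) -> SampleSheet:
    """One sample per (treatment, time): each drug plus the vehicle control."""
    rng = np.random.default_rng(cfg.seed + 104729 * replicate)
    treatments = list(cfg.drugs) + [cfg.control_treatment]
    n_samples = len(treatments) * len(cfg.times)
    indexes = design_indexes(n_samples, length=6, min_dist=3, seed=rng)
    rows = []
    i = 0
    for treat in treatments:
        for t in cfg.times:
            rows.append(
                {
                    "sample_id": f"{treat}_t{t:g}_r{replicate}",
                    "index": indexes[i].seq,
                    "treatment": treat,
                    "time": t,
                    "replicate": replicate,
                }
            )
            i += 1
    return SampleSheet(pd.DataFrame(rows))


def simulate_expression(
    truth: pd.DataFrame, cfg: SimulationConfig, sheet: SampleSheet
) -> pd.DataFrame:
    """Expected abundance (arbitrary read units) per barcode x sample.

    Baseline abundances are log-normal per *promoter* (barcodes of the same
    promoter share a baseline, as they share a plasmid); responsive groups
    are multiplied by the induction pulse under their drugs, controls stay
    at baseline.
    """
    rng = np.random.default_rng(cfg.seed + 7919)
    promoters = truth["promoter_id"].unique()
    base_per_prom = pd.Series(
        10 ** rng.normal(cfg.baseline_log10_mu, cfg.baseline_log10_sigma,
                         size=len(promoters)),
        index=promoters,
    )
    baseline = truth["promoter_id"].map(base_per_prom).to_numpy()
    cols = {}
    drugs_per_bc = truth["drugs"].str.split(";").apply(set)
    for _, srow in sheet.frame.iterrows():
        treat, t = srow["treatment"], srow["time"]
        factor = np.ones(len(truth))
        if treat != "" and t > 0:
            responsive = drugs_per_bc.apply(lambda d: treat in d).to_numpy()
            if responsive.any():
                amps = truth["amplitude"].to_numpy()
                taus = truth["tau"].to_numpy()
                pf = np.ones(len(truth))
                idx = np.flatnonzero(responsive)
                pf[idx] = 1.0 + amps[idx] * (t / taus[idx]) * np.exp(1.0 - t / taus[idx])
                factor = pf
        cols[srow["sample_id"]] = baseline * factor
    out = pd.DataFrame(cols, index=pd.Index(truth["barcode"], name="barcode"))
    return out


def simulate_counts(
    abundance: pd.DataFrame, depth: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Multinomial read counts per sample given expected abundances."""
    cols = {}
    for s in abundance.columns:
        p = abundance[s].to_numpy()
        cols[s] = rng.multinomial(depth, p / p.sum())
    out = pd.DataFrame(cols, index=abundance.index)
    return out


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    if hit.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


def screen_read(
    index: str, barcode: str, template: VectorTemplate | None = None,
    length: int = READ_LENGTH,
) -> str:
    """Error-free screen read: index + constant spacer + barcode + XbaI tail."""
    tpl = template or default_template()
    body = index + tpl.constant_spacer + barcode + "TCTAGA" + tpl.downstream
    return body[:length]


def simulate_screen_reads(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    cfg: SimulationConfig,
    template: VectorTemplate | None = None,
) -> Iterable[tuple[str, str, str]]:
    """Yield multiplexed (id, seq, qual) screen reads matching a count table.

    Per sample, each barcode contributes exactly its count of reads (the
    multinomial draw happened in :func:`simulate_counts`); substitution
    errors are applied i.i.d. at the configured rate. Qualities are a
    constant placeholder (the pipeline ignores them, as did the original
    FastA-based processing).
    """
    tpl = template or default_template()
    rng = np.random.default_rng(cfg.seed + 15485863)
    index_of = sheet.index_of
    qual = "I" * READ_LENGTH
    rid = 0
    for s in counts.columns:
        idx = index_of[s]
        for bc, c in counts[s].items():
            if c == 0:
                continue
            base = screen_read(idx, bc, tpl)
            if cfg.error_rate > 0:
                for _ in range(int(c)):
                    yield f"r{rid}", _mutate(base, cfg.error_rate, rng), qual
                    rid += 1
            else:
                for _ in range(int(c)):
                    yield f"r{rid}", base, qual
                    rid += 1


def simulate_association_reads(
    constructs: Sequence[Construct],
    mode: str = "junction",
    coverage: int = 60,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, str]]:
    """Association reads for every construct, with ground-truth read names.

    junction mode: each construct's NheI-XbaI fragment is circularized and
    reopened independently with ApaI, FspI and HincII; ``coverage`` 150-nt
    reads across the barcode/promoter junction are emitted from the pooled
    aliquots whose junction stayed intact (a cut inside the junction region
    in one aliquot is covered by the others -- the reason three enzymes are
    used). long mode: ``coverage`` full-fragment reads in random orientation.
    """
    if mode not in ("junction", "long"):
        raise ConfigError(f"unknown association read mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    for c in constructs:
        frag = nhe_xba_fragment(c)
        if mode == "long":
            for j in range(coverage):
                seq = frag.seq if rng.random() < 0.5 else reverse_complement(frag.seq)
                reads.append((f"{c.library_id}/long/{j}", _mutate(seq, error_rate, rng)))
            continue
        circ = circularize_fragment(frag)
        window = junction_window(frag.seq)
        intact = [lin for lin in linearize_circle(circ) if window in lin.seq]
        if not intact:
            continue
        for j in range(coverage):
            reads.append(
                (f"{c.library_id}/junction/{j}", _mutate(window, error_rate, rng))
            )
    return reads


def truth_association(truth: pd.DataFrame) -> dict[str, str]:
    """Ground-truth barcode -> promoter mapping from the truth table."""
    return dict(zip(truth["barcode"], truth["promoter_id"]))
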