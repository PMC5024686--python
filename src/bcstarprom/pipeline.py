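"""End-to-end pipeline driver: associate -> count -> quantify -> cluster -> enrich.

Each stage reads/writes TSV artifacts under the configured output directory
and records a QC block; a failing stage aborts the run with a stage-named
error so the provenance of a failure is explicit.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .association import (
    AssociationTable,
    build_association_table,
    parse_junction_read,
    parse_long_read,
    read_association,
    validate_association,
    write_association,
)
from .errors import BCStarPromError, StageError
from .io import PipelineConfig, read_fasta, read_fastq, read_tsv, write_tsv
from .library_design import default_template
from .motif_enrichment import enrich_all, parse_jaspar, pwm_scan
from .quantify import (
    drug_response_score,
    fold_changes,
    median_normalize,
    merge_replicates_and_cluster,
    promoter_profiles,
)
from .read_processing import SampleSheet, assemble_and_filter, process_reads

log = logging.getLogger("bcstarprom")

__all__ = ["run_pipeline", "associate_stage", "count_stage", "quantify_stage"]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except (BCStarPromError, OSError, ValueError, KeyError) as exc:
                raise StageError(name, str(exc)) from exc

        wrapper.__name__ = fn.__name__
        wrapper.__doc__ = fn.__doc__
        return wrapper

    return deco


def _load_sheet(cfg: PipelineConfig) -> SampleSheet:
    if cfg.sample_sheet is None:
        raise StageError("config", "sample_sheet path is required")
    return SampleSheet(read_tsv(cfg.sample_sheet))


@_stage("associate")
def associate_stage(cfg: PipelineConfig, out: Path) -> AssociationTable:
    """Parse association reads into a validated barcode -> promoter table."""
    if cfg.association_table:
        assoc = read_association(cfg.association_table)
        log.info("associate: loaded %d associations", len(assoc))
        return assoc
    if not cfg.association_reads or not cfg.library_manifest:
        raise StageError(
            "associate", "need association_reads + library_manifest (or association_table)"
        )
    manifest = read_tsv(cfg.library_manifest)
    cores = manifest["cores"].str.split(";")
    first_core_to_prom = dict(zip(cores.str[0], manifest["promoter_id"]))
    all_cores_to_prom = dict(zip(cores.str.join(";"), manifest["promoter_id"]))
    tpl = default_template()
    pairs = []
    n_reads = n_unparsed = 0
    for _rid, seq in read_fasta(cfg.association_reads):
        n_reads += 1
        if cfg.association_mode == "junction":
            hit = parse_junction_read(seq, tpl)
            if hit is None:
                n_unparsed += 1
                continue
            bc, prefix = hit
            prom = first_core_to_prom.get(prefix)
        else:
            hit = parse_long_read(seq, tpl)
            if hit is None:
                n_unparsed += 1
                continue
            cores_read, bc = hit
            prom = all_cores_to_prom.get(";".join(cores_read))
        if prom is None:
            n_unparsed += 1
            continue
        pairs.append((bc, prom))
    assoc = build_association_table(pairs, min_reads=cfg.min_reads)
    report = validate_association(assoc)
    write_association(assoc, out / "association.tsv", meta=cfg.meta())
    qc = {
        "reads": n_reads,
        "unparsed": n_unparsed,
        "associations": len(assoc),
        "collisions": report.collisions,
        "multi_barcode_promoters": len(report.multi_barcode_promoters),
    }
    (out / "associate.qc.json").write_text(json.dumps(qc, indent=2))
    log.info("associate: %s", qc)
    return assoc


@_stage("count")
def count_stage(cfg: PipelineConfig, assoc: AssociationTable, out: Path) -> pd.DataFrame:
    """Demultiplex, trim and count screen reads into a filtered count table."""
    if not cfg.screen_fastq:
        raise StageError("count", "screen_fastq path is required")
    sheet = _load_sheet(cfg)
    counts, qc = process_reads(
        read_fastq(cfg.screen_fastq), sheet, max_mismatch=cfg.max_mismatch
    )
    table = assemble_and_filter(counts, assoc)
    write_tsv(table, out / "counts.tsv", meta=cfg.meta())
    qc.update(table.attrs.get("qc", {}))
    (out / "count.qc.json").write_text(json.dumps(qc, indent=2))
    log.info("count: %s", qc)
    return table


@_stage("quantify")
def quantify_stage(
    cfg: PipelineConfig, table: pd.DataFrame, out: Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize counts, compute fold changes and the drug-response ranking."""
    sheet = _load_sheet(cfg)
    norm = median_normalize(table)
    fc = fold_changes(
        norm, sheet, control_treatments=(cfg.control_treatment,),
        pseudocount=cfg.pseudocount,
    )
    ranked = drug_response_score(fc, sheet, drug=cfg.drug)
    write_tsv(norm, out / "normalized.tsv", meta=cfg.meta())
    write_tsv(fc, out / "fold_changes.tsv", meta=cfg.meta())
    write_tsv(ranked, out / "ranking.tsv", meta=cfg.meta())
    return fc, ranked


@_stage("cluster")
def cluster_stage(
    cfg: PipelineConfig,
    fc: pd.DataFrame,
    ranked: pd.DataFrame,
    assoc: AssociationTable,
    out: Path,
) -> pd.Series:
    """Merge strongest responders and cluster their log2 profiles into groups."""
    b2p = assoc.barcode_to_promoter()
    profiles = promoter_profiles(fc, b2p)
    prom_rank = (
        ranked.assign(promoter_id=ranked.index.map(b2p))
        .dropna(subset=["promoter_id"])
        .groupby("promoter_id")["score"]
        .max()
        .sort_values(ascending=False)
        .to_frame()
    )
    groups = merge_replicates_and_cluster(
        [prom_rank], profiles, top_k=cfg.top_k, k_groups=cfg.k_groups
    )
    write_tsv(groups.to_frame(), out / "response_groups.tsv", meta=cfg.meta())
    return groups


@_stage("enrich")
def enrich_stage(
    cfg: PipelineConfig,
    ranked: pd.DataFrame,
    assoc: AssociationTable,
    out: Path,
) -> pd.DataFrame:
    """Scan promoter cores with the motif panel and test ranking enrichment."""
    if not cfg.motifs or not cfg.library_manifest:
        raise StageError("enrich", "need motifs + library_manifest")
    motifs_list = parse_jaspar(
        Path(cfg.motifs).read_text(), rel_score_threshold=cfg.rel_score_threshold
    )
    manifest = read_tsv(cfg.library_manifest)
    seq_of = dict(
        zip(manifest["promoter_id"], manifest["cores"].str.replace(";", "", regex=False))
    )
    b2p = assoc.barcode_to_promoter()
    prom_rank = (
        ranked.assign(promoter_id=ranked.index.map(b2p))
        .dropna(subset=["promoter_id"])
        .groupby("promoter_id")["score"]
        .max()
        .sort_values(ascending=False)
        .to_frame()
    )
    incidence: dict[str, set[str]] = {}
    hit_rows = []
    for m in motifs_list:
        members = set()
        for pid in prom_rank.index:
            hits = pwm_scan(seq_of[pid], m, promoter_id=pid)
            if hits:
                members.add(pid)
                best = max(hits, key=lambda h: h.rel_score)
                hit_rows.append(
                    {"promoter_id": pid, "motif_id": m.motif_id,
                     "offset": best.offset, "strand": best.strand,
                     "rel_score": best.rel_score}
                )
        if 0 < len(members) < len(prom_rank):
            incidence[m.motif_id] = members
    write_tsv(pd.DataFrame(hit_rows), out / "motif_hits.tsv", meta=cfg.meta())
    if not incidence:
        raise StageError("enrich", "no motif produced a testable promoter set")
    enr = enrich_all(prom_rank, incidence, n_perm=cfg.n_perm, seed=cfg.seed)
    write_tsv(enr, out / "enrichment.tsv", meta=cfg.meta())
    return enr


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run all stages in order; returns the artifact paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    assoc = associate_stage(cfg, out)
    table = count_stage(cfg, assoc, out)
    fc, ranked = quantify_stage(cfg, table, out)
    artifacts = {
        "association": out / "association.tsv",
        "counts": out / "counts.tsv",
        "normalized": out / "normalized.tsv",
        "fold_changes": out / "fold_changes.tsv",
        "ranking": out / "ranking.tsv",
    }
    cluster_stage(cfg, fc, ranked, assoc, out)
    artifacts["response_groups"] = out / "response_groups.tsv"
    if cfg.motifs:
        enrich_stage(cfg, ranked, assoc, out)
        artifacts["enrichment"] = out / "enrichment.tsv"
    return artifacts
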