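"""End-to-end orchestration: filter -> pileup -> normalize -> TSS -> classify -> REP.

A :class:`PipelineConfig` names the inputs (genome FASTA, GFF3 annotation,
SAM alignments grouped into condition replicates, optional predicted-TSS BED)
and every tunable parameter; :func:`run_pipeline` executes the six stages and
writes TSV/bedGraph reports plus a JSON manifest recording all parameters and
input checksums, so a run can be replayed byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .genome import (
    Feature,
    GenomeSequence,
    Interval,
    NCRNA,
    PROTEIN_CODING,
    annotated_five_prime,
    read_bed6,
    read_fasta,
    read_gff3,
)
from .orientation import (
    DIVERGENT,
    antisense_overlap_length,
    classify_arrangement,
    inter_tss_distance,
    is_bona_fide,
    nearest_neighbor,
    summarize_distances,
)
from .pileup import (
    ConditionGroup,
    FivePrimeTrack,
    build_track,
    normalize_and_average,
    replicate_table,
    write_bedgraph,
)
from .reads import perfect_match_filter, read_sam
from .rep import RepScanParams, builtin_consensuses, rep_transcription_report
from .tss import DEFAULT_MIN_HEIGHT, DEFAULT_WINDOW, call_tss, concordance, tss_offset

logger = logging.getLogger(__name__)

STAGES = ("filter-sam", "pileup", "normalize", "call-tss", "classify", "rep-scan")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


@dataclass
class PipelineParams:
    window: int = DEFAULT_WINDOW
    min_height: float = DEFAULT_MIN_HEIGHT
    concordance_tolerance: int = 0
    max_mismatches: int = 3
    min_t_run: int = 4
    min_stem: int = 4
    max_loop: int = 8
    min_loop: int = 3
    hairpin_window: int = 20
    min_igr_gap: int = 50


@dataclass
class PipelineConfig:
    genome: Path
    annotation: Path
    conditions: dict[str, list[Path]]  # condition label -> replicate SAM paths
    outdir: Path
    predicted_tss: Optional[Path] = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            genome=Path(raw["genome"]),
            annotation=Path(raw["annotation"]),
            conditions={c: [Path(p) for p in ps] for c, ps in raw["conditions"].items()},
            outdir=Path(raw["outdir"]),
            predicted_tss=Path(raw["predicted_tss"]) if raw.get("predicted_tss") else None,
            params=PipelineParams(**raw.get("params", {})),
        )

    def validate(self) -> None:
        paths = [self.genome, self.annotation]
        if self.predicted_tss is not None:
            paths.append(self.predicted_tss)
        for ps in self.conditions.values():
            paths.extend(ps)
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")


@dataclass
class PipelineResult:
    """In-memory report bundle; everything is also written under ``outdir``."""

    genome: GenomeSequence
    annotation: list[Feature]
    filter_stats: pd.DataFrame
    replicate_table: pd.DataFrame
    condition_tracks: dict[str, FivePrimeTrack]
    tss_calls: pd.DataFrame
    arrangements: pd.DataFrame
    distance_summary: Optional[pd.DataFrame]
    rep_report: pd.DataFrame
    manifest: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def primary_calls(tss_calls: pd.DataFrame) -> pd.DataFrame:
    """Per feature, the overall primary TSS: the highest primary call across
    conditions (ties toward the lower position, deterministically)."""
    prim = tss_calls[tss_calls["rank"] == "primary"].copy()
    prim = prim.sort_values(["feature", "height", "position"], ascending=[True, False, True])
    return prim.groupby("feature", as_index=False).first()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    t0 = time.monotonic()
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params
    completed: list[str] = []

    genomes = read_fasta(config.genome)
    if len(genomes) != 1:
        raise PipelineError("filter-sam", f"expected a single-sequence genome, got {len(genomes)}")
    genome = genomes[0]
    annotation = read_gff3(config.annotation)
    predicted = read_bed6(config.predicted_tss) if config.predicted_tss else []

    # stage 1: perfect-match filtering of every replicate SAM
    stage = "filter-sam"
    filtered: dict[str, list] = {}
    stats_rows = []
    try:
        for cond, sam_paths in config.conditions.items():
            for i, sam in enumerate(sam_paths):
                records = read_sam(sam)
                kept, stats = perfect_match_filter(records)
                label = f"{cond}_rep{i + 1}"
                filtered[label] = kept
                stats_rows.append(
                    {
                        "replicate": label,
                        "condition": cond,
                        "sam": str(sam),
                        "n_records": stats.n_input,
                        "n_mapped": stats.n_mapped,
                        "n_perfect": stats.n_perfect,
                    }
                )
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, str(exc)) from exc
    filter_stats = pd.DataFrame(stats_rows)
    completed.append(stage)
    logger.info("stage %s done (%.2fs)", stage, time.monotonic() - t0)

    # stage 2: strand-specific 5'-end pileups
    stage = "pileup"
    try:
        tracks = {label: build_track(recs, ref_id=genome.id) for label, recs in filtered.items()}
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    completed.append(stage)

    # stage 3: per-condition normalization and averaging
    stage = "normalize"
    try:
        groups = {
            cond: ConditionGroup(
                cond,
                [tracks[f"{cond}_rep{i + 1}"] for i in range(len(ps))],
                [f"{cond}_rep{i + 1}" for i in range(len(ps))],
            )
            for cond, ps in config.conditions.items()
        }
        condition_tracks = {cond: normalize_and_average(g) for cond, g in groups.items()}
        rep_table = replicate_table(groups.values())
        _write_tsv(rep_table, outdir / "replicate_table.tsv")
        for cond, track in condition_tracks.items():
            for strand, tag in (("+", "plus"), ("-", "minus")):
                write_bedgraph(track, strand, outdir / f"{cond}_5p_{tag}.bedgraph")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    completed.append(stage)

    # stage 4: TSS calling near every annotated transcription unit
    stage = "call-tss"
    try:
        call_rows = []
        for cond, track in sorted(condition_tracks.items()):
            for feature in annotation:
                if feature.kind not in (NCRNA, PROTEIN_CODING):
                    continue
                calls = call_tss(track, feature, params.window, params.min_height, cond)
                conc = concordance(calls, predicted, params.concordance_tolerance)
                for call, crec in zip(calls, conc):
                    call_rows.append(
                        {
                            "feature": feature.name,
                            "kind": feature.kind,
                            "condition": cond,
                            "position": call.position,
                            "strand": call.strand,
                            "height": call.height,
                            "rank": call.rank,
                            "offset": tss_offset(call, feature),
                            "annotated_5p": annotated_five_prime(feature),
                            "predicted_position": crec.predicted_position,
                            "predicted_distance": crec.distance,
                            "matched_prediction": crec.matched,
                        }
                    )
        tss_calls = pd.DataFrame(call_rows)
        _write_tsv(tss_calls, outdir / "tss_calls.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    completed.append(stage)

    # stage 5: orientation taxonomy and inter-TSS distances
    stage = "classify"
    try:
        prim = primary_calls(tss_calls) if not tss_calls.empty else pd.DataFrame()
        prim_by_feature = (
            {r["feature"]: r for _, r in prim.iterrows()} if not prim.empty else {}
        )
        arr_rows = []
        from .orientation import ArrangementCall  # local import to avoid cycle confusion

        arrangement_calls = []
        for ncrna in (f for f in annotation if f.kind == NCRNA):
            neighbor = nearest_neighbor(ncrna, annotation)
            call = classify_arrangement(ncrna, neighbor)
            nc_prim = prim_by_feature.get(ncrna.name)
            gene_prim = prim_by_feature.get(neighbor.name)
            refined_overlap = (
                antisense_overlap_length(
                    ncrna,
                    neighbor,
                    int(nc_prim["position"]) if nc_prim is not None else None,
                    int(gene_prim["position"]) if gene_prim is not None else None,
                )
                if ncrna.strand != neighbor.strand
                else 0
            )
            dist = None
            if call.arrangement == DIVERGENT and nc_prim is not None and gene_prim is not None:
                dist = inter_tss_distance(call, int(nc_prim["position"]), int(gene_prim["position"]))
                call = ArrangementCall(
                    call.ncrna, call.neighbor, call.arrangement, call.bona_fide,
                    call.antisense_overlap, dist,
                )
            arrangement_calls.append(call)
            arr_rows.append(
                {
                    "ncrna": ncrna.name,
                    "neighbor": neighbor.name,
                    "arrangement": call.arrangement,
                    "bona_fide_vs_annotation": is_bona_fide(ncrna, annotation),
                    "antisense_overlap": call.antisense_overlap,
                    "refined_antisense_overlap": refined_overlap,
                    "ncrna_primary_tss": int(nc_prim["position"]) if nc_prim is not None else None,
                    "neighbor_primary_tss": int(gene_prim["position"]) if gene_prim is not None else None,
                    "inter_tss_distance": dist,
                }
            )
        arrangements = pd.DataFrame(arr_rows)
        _write_tsv(arrangements, outdir / "arrangements.tsv")
        distance_summary = None
        divergent_with_dist = [c for c in arrangement_calls if c.arrangement == DIVERGENT and c.inter_tss_distance is not None]
        if divergent_with_dist:
            summ = summarize_distances(divergent_with_dist)
            distance_summary = pd.DataFrame(
                [{"n_pairs": summ.n_pairs, "min_bp": summ.min, "median_bp": summ.median, "max_bp": summ.max}]
            )
            _write_tsv(distance_summary, outdir / "inter_tss_summary.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    completed.append(stage)

    # stage 6: REP read-through screen over collinear-gene intergenic regions
    stage = "rep-scan"
    try:
        rep_params = RepScanParams(
            max_mismatches=params.max_mismatches,
            min_t_run=params.min_t_run,
            min_stem=params.min_stem,
            max_loop=params.max_loop,
            min_loop=params.min_loop,
            hairpin_window=params.hairpin_window,
            min_tss_height=params.min_height,
        )
        consensuses = builtin_consensuses(params.max_mismatches)
        pooled = _pool_tracks(list(condition_tracks.values()), genome.id)
        genes = sorted((f for f in annotation if f.kind == PROTEIN_CODING), key=lambda f: f.start)
        rep_rows = []
        for left, right in zip(genes, genes[1:]):
            if left.strand != right.strand:
                continue
            if right.start - left.end - 1 < params.min_igr_gap:
                continue
            igr = Interval(left.end + 1, right.start - 1)
            report = rep_transcription_report(igr, annotation, genome, pooled, consensuses, rep_params)
            if not report.rep_matches:
                continue
            rep_rows.append(
                {
                    "igr_start": igr.start,
                    "igr_end": igr.end,
                    "left_gene": left.name,
                    "right_gene": right.name,
                    "transcribed_strand": report.transcribed_strand,
                    "n_rep_matches": len({(m.start, m.end) for m in report.rep_matches}),
                    "rep_first_start": min(m.start for m in report.rep_matches),
                    "rep_last_end": max(m.end for m in report.rep_matches),
                    "divergent_tss": report.divergent_tss.position if report.divergent_tss else None,
                    "tss_to_rep_distance": report.tss_to_rep_distance,
                    "n_tn_tracks": len(report.tn_tracks),
                    "hairpin_upstream_of_tn": report.hairpin_upstream_of_tn,
                    "read_through": report.read_through,
                }
            )
        rep_report = pd.DataFrame(rep_rows)
        _write_tsv(rep_report, outdir / "rep_report.tsv")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    completed.append(stage)

    manifest = {
        "divtss_version": __version__,
        "stages_completed": completed,
        "parameters": asdict(params),
        "inputs": {
            "genome": {"path": str(config.genome), "sha256": _sha256(Path(config.genome))},
            "annotation": {"path": str(config.annotation), "sha256": _sha256(Path(config.annotation))},
            "predicted_tss": (
                {"path": str(config.predicted_tss), "sha256": _sha256(Path(config.predicted_tss))}
                if config.predicted_tss
                else None
            ),
            "conditions": {
                cond: [{"path": str(p), "sha256": _sha256(Path(p))} for p in ps]
                for cond, ps in config.conditions.items()
            },
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    logger.info("pipeline finished in %.2fs", time.monotonic() - t0)
    return PipelineResult(
        genome=genome,
        annotation=annotation,
        filter_stats=filter_stats,
        replicate_table=rep_table,
        condition_tracks=condition_tracks,
        tss_calls=tss_calls,
        arrangements=arrangements,
        distance_summary=distance_summary,
        rep_report=rep_report,
        manifest=manifest,
    )


def _pool_tracks(tracks: list[FivePrimeTrack], ref_id: str) -> FivePrimeTrack:
    """Mean of condition-level tracks, used where a single profile is needed."""
    pooled = FivePrimeTrack(ref_id=ref_id)
    n = len(tracks)
    for strand in "+-":
        acc = pooled.counts(strand)
        for t in tracks:
            for pos, v in t.counts(strand).items():
                acc[pos] = acc.get(pos, 0.0) + v / n
    pooled.total_perfect_reads = sum(t.total_perfect_reads for t in tracks) / max(n, 1)
    return pooled
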