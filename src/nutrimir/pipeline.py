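"""End-to-end orchestration: preprocess -> map -> annotate -> quant -> discover -> targets.

Stages whose inputs are absent are skipped with a logged notice; every output
table is written as TSV with deterministic row order, and the run log records
all parameters and the seed, so a fixed configuration reproduces byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import annotate, discover, mapper, preprocess, quant, targets
from .io import read_degradome, read_fasta, read_gff3, read_reads, write_tsv

logger = logging.getLogger("nutrimir")


@dataclass
class PipelineConfig:
    # inputs (None or missing file -> dependent stage skipped with a notice)
    genome: str | None = None
    annotations: str | None = None
    reads_a: str | None = None
    reads_b: str | None = None
    mature: str | None = None
    transcriptome: str | None = None
    degradome: str | None = None
    # labels for the two conditions in reports (e.g. "+N" / "-N")
    label_a: str = "A"
    label_b: str = "B"
    # preprocessing
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str | None = None
    min_overlap: int = preprocess.DEFAULT_MIN_OVERLAP
    min_len: int = preprocess.DEFAULT_MIN_LEN
    max_len: int = preprocess.DEFAULT_MAX_LEN
    # annotation
    stranded: bool = True
    # quantification
    known_ratio_threshold: float = quant.DEFAULT_KNOWN_RATIO
    novel_ratio_threshold: float = quant.DEFAULT_NOVEL_RATIO
    min_evidence: int = quant.DEFAULT_MIN_EVIDENCE
    # discovery
    merge_distance: int = discover.DEFAULT_MERGE_DISTANCE
    min_count: int = discover.DEFAULT_MIN_COUNT
    max_nloci: int = discover.DEFAULT_MAX_NLOCI
    long_flank: int = discover.DEFAULT_LONG_FLANK
    short_flank: int = discover.DEFAULT_SHORT_FLANK
    max_unpaired_mature: int = discover.DEFAULT_MAX_UNPAIRED_MATURE
    max_bulge: int = discover.DEFAULT_MAX_BULGE
    # targets
    penalty_threshold: float = targets.DEFAULT_PENALTY_THRESHOLD
    gu_penalty: float = 0.5
    cleavage_window: int = targets.DEFAULT_CLEAVAGE_WINDOW
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    table: preprocess.ReadTagTable | None = None
    mapped: list | None = None
    classes: dict[str, str] = field(default_factory=dict)
    class_summary: pd.DataFrame | None = None
    overlap_summary: pd.DataFrame | None = None
    length_profile: pd.DataFrame | None = None
    window_fractions: dict[str, float] = field(default_factory=dict)
    mapping_summary: pd.DataFrame | None = None
    known_expression: pd.DataFrame | None = None
    novel_candidates: pd.DataFrame | None = None
    candidates: list = field(default_factory=list)
    target_report: pd.DataFrame | None = None


def _available(path: str | None, stage: str) -> bool:
    if path is None or not Path(path).exists():
        logger.warning("input for stage %r missing (%s); stage skipped", stage, path)
        return False
    return True


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    result = PipelineResult()
    try:
        logger.info("parameters: %s", config.to_dict())
        if not (_available(config.reads_a, "preprocess") and _available(config.reads_b, "preprocess")):
            raise RuntimeError("preprocess: both read libraries are required")

        # --- preprocess --------------------------------------------------
        raw_a = read_reads(config.reads_a)
        raw_b = read_reads(config.reads_b)
        inserts_a, rej_a = preprocess.trim_library(
            raw_a, config.adapter3, config.min_overlap,
            config.min_len, config.max_len, config.adapter5,
        )
        inserts_b, rej_b = preprocess.trim_library(
            raw_b, config.adapter3, config.min_overlap,
            config.min_len, config.max_len, config.adapter5,
        )
        logger.info(
            "trim: A %d/%d clean (rejects %s), B %d/%d clean (rejects %s)",
            len(inserts_a), len(raw_a), dict(rej_a),
            len(inserts_b), len(raw_b), dict(rej_b),
        )
        table = preprocess.collapse_reads(inserts_a, inserts_b)
        result.table = table
        profile, fractions = preprocess.length_profile(table)
        result.length_profile = profile
        result.window_fractions = fractions
        write_tsv(table.df, out / "tag_table.tsv")
        write_tsv(profile, out / "length_profile.tsv")

        # --- map ---------------------------------------------------------
        if not _available(config.genome, "map"):
            return result
        chroms = read_fasta(config.genome)
        index = mapper.build_index(chroms)
        mapped, unmapped, map_summary = mapper.locate(table, index)
        result.mapped = mapped
        result.mapping_summary = map_summary
        logger.info("map: %d tags mapped, %d unmapped", len(mapped), len(unmapped))
        write_tsv(map_summary, out / "mapping_summary.tsv")
        mapped_tab = mapper.mapped_table(table, mapped)

        # --- annotate ----------------------------------------------------
        annotations = (
            read_gff3(config.annotations)
            if _available(config.annotations, "annotate")
            else []
        )
        classes = annotate.classify_tags(mapped, annotations, config.stranded)
        result.classes = classes
        result.class_summary = annotate.class_summary(mapped_tab, classes)
        result.overlap_summary = annotate.library_overlap(mapped_tab)
        write_tsv(result.class_summary, out / "class_summary.tsv")
        write_tsv(result.overlap_summary, out / "overlap_summary.tsv")

        total_a = max(1, mapped_tab.total_A)
        total_b = max(1, mapped_tab.total_B)

        # --- quant (known miRNAs) ----------------------------------------
        known_seqs: set[str] = set()
        if _available(config.mature, "quant"):
            mature = read_fasta(config.mature)
            known_seqs = set(mature.values())
            records = quant.match_known(mapped_tab, mature)
            result.known_expression = quant.expression_table(
                records, total_a, total_b,
                ratio_threshold=config.known_ratio_threshold,
                min_evidence=config.min_evidence,
            )
            write_tsv(result.known_expression, out / "known_expression.tsv")

        # --- discover ----------------------------------------------------
        found = discover.discover_candidates(
            mapped, classes, mapped_tab, chroms,
            known_matures=known_seqs,
            merge_distance=config.merge_distance,
            min_count=config.min_count,
            max_nloci=config.max_nloci,
            long_flank=config.long_flank,
            short_flank=config.short_flank,
            max_unpaired_mature=config.max_unpaired_mature,
            max_bulge=config.max_bulge,
        )
        result.candidates = found
        result.novel_candidates = novel_table(
            found, total_a, total_b,
            ratio_threshold=config.novel_ratio_threshold,
            min_evidence=config.min_evidence,
        )
        write_tsv(result.novel_candidates, out / "novel_candidates.tsv")
        _write_precursors(found, out / "novel_precursors.txt")

        # --- targets -----------------------------------------------------
        if _available(config.transcriptome, "targets"):
            transcripts = read_fasta(config.transcriptome)
            degradome = (
                read_degradome(config.degradome)
                if _available(config.degradome, "degradome")
                else None
            )
            mirnas = [
                (row.id, row.sequence)
                for row in result.novel_candidates.itertuples(index=False)
            ]
            if result.known_expression is not None:
                mirnas += [
                    (r.id, r.sequence)
                    for r in result.known_expression.itertuples(index=False)
                    if r.response in (quant.NSS, quant.NSI)
                ]
            result.target_report = predict_and_validate(
                mirnas, transcripts, degradome,
                penalty_threshold=config.penalty_threshold,
                gu_penalty=config.gu_penalty,
                cleavage_window=config.cleavage_window,
            )
            write_tsv(result.target_report, out / "target_report.tsv")
        return result
    except Exception:
        logger.exception("pipeline aborted; partial outputs retained in %s", out)
        raise
    finally:
        handler.close()
        logger.removeHandler(handler)


def novel_table(
    found: list,
    total_a: int,
    total_b: int,
    ratio_threshold: float = quant.DEFAULT_NOVEL_RATIO,
    min_evidence: int = quant.DEFAULT_MIN_EVIDENCE,
) -> pd.DataFrame:
    """Novel-candidate summary (sequence, length, counts, fold, response, star)."""
    rows = []
    for i, (cluster, cand) in enumerate(
        sorted(
            found,
            key=lambda fc: (
                fc[0].locus.chrom, fc[0].locus.start, fc[0].locus.strand
            ),
        )
    ):
        rows.append(
            {
                "id": f"mirN{i + 1:02d}",
                "sequence": cluster.representative,
                "length": len(cluster.representative),
                "count_A": cluster.count_A,
                "count_B": cluster.count_B,
                "star_supported": cand.star_supported,
                "precursor_chrom": cluster.locus.chrom,
                "precursor_start0": cand.window_span[0] if cand.window_span else "",
                "precursor_end": cand.window_span[1] if cand.window_span else "",
                "strand": cluster.locus.strand,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "id", "sequence", "length", "count_A", "count_B", "star_supported",
            "precursor_chrom", "precursor_start0", "precursor_end", "strand",
        ],
    )
    if df.empty:
        df["log2fc"] = []
        df["response"] = []
        return df
    expr = quant.expression_table(
        df[["id", "count_A", "count_B"]].copy(), max(1, total_a), max(1, total_b),
        ratio_threshold=ratio_threshold, min_evidence=min_evidence,
    )
    df["log2fc"] = expr["log2fc"]
    df["response"] = expr["response"]
    return df


def _write_precursors(found: list, path: Path) -> None:
    lines = []
    for i, (cluster, cand) in enumerate(
        sorted(found, key=lambda fc: (fc[0].locus.chrom, fc[0].locus.start, fc[0].locus.strand))
    ):
        lines.append(f">mirN{i + 1:02d} {cluster.locus.chrom}:{cluster.locus.start}-{cluster.locus.end}({cluster.locus.strand})")
        lines.append(cand.precursor)
        lines.append(cand.structure)
    path.write_text("\n".join(lines) + "\n")


def predict_and_validate(
    mirnas: list[tuple[str, str]],
    transcripts: dict[str, str],
    degradome: pd.DataFrame | None,
    penalty_threshold: float = targets.DEFAULT_PENALTY_THRESHOLD,
    gu_penalty: float = 0.5,
    cleavage_window: int = targets.DEFAULT_CLEAVAGE_WINDOW,
) -> pd.DataFrame:
    """Target scan for a set of miRNAs plus degradome grading (NA columns if absent)."""
    evidences = []
    for mid, seq in mirnas:
        for site in targets.scan_targets(
            mid, seq, transcripts, penalty_threshold, gu_penalty
        ):
            if degradome is not None:
                evidences.append(
                    targets.degradome_support(site, degradome, cleavage_window)
                )
            else:
                evidences.append(
                    targets.DegradomeEvidence(
                        site, targets.cleavage_position(site), 0, 0, targets.CATEGORY_NONE
                    )
                )
    return targets.target_report(evidences, has_degradome=degradome is not None)
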