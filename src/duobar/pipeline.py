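"""End-to-end orchestration: merge -> demultiplex -> gates -> dereplicate ->
chimera filter -> cluster -> fragment pairing -> barcode calling.

Each stage logs an in/out/dropped line to a :class:`StageReport`; the report
enforces read conservation (in == out + dropped at every stage), mirroring
the count-based way amplicon pipelines are usually audited. The pipeline is
fully deterministic: no stage draws randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .calling import BarcodeRecord, ReferenceDb, call_barcodes, identify
from .cluster import Cluster, dereplicate, detect_chimeras, greedy_cluster
from .demux import Demultiplexer, DemuxRecord, PrimerSet
from .io import ReadPair, WellAssignment
from .merge import MergeConfig, length_gate, merge_pair, quality_gate
from .pairing import AssembledBarcode, pair_specimen

__all__ = ["PipelineConfig", "StageCount", "StageReport", "PipelineResult", "run_all"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline thresholds; the defaults are the standard printed
    parameterization of every stage."""

    merge: MergeConfig = MergeConfig()
    cluster_identity: float = 0.99
    chimera_min_parent_fold: float = 2.0
    chimera_min_div: float = 0.008
    chimera_min_score: float = 0.28
    screen_min_identity: float = 0.98
    screen_min_len: int = 25
    screen_max_mismatch: int = 2
    assemble_min_overlap: int = 80
    assemble_max_mismatch_frac: float = 0.02
    min_frac: float = 0.10
    mid_mismatch: int = 0
    length_gate_on_insert: bool = False  # default: gate the raw merged read


@dataclass
class StageCount:
    stage: str
    n_in: int
    n_out: int
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


@dataclass
class StageReport:
    stages: list[StageCount] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int, **dropped: int) -> None:
        sc = StageCount(stage=stage, n_in=n_in, n_out=n_out,
                        dropped={k: v for k, v in dropped.items() if v})
        if sc.n_in != sc.n_out + sc.n_dropped:
            raise AssertionError(
                f"stage {stage}: {sc.n_in} in != {sc.n_out} out "
                f"+ {sc.n_dropped} dropped")
        self.stages.append(sc)

    def get(self, stage: str) -> StageCount:
        merged: StageCount | None = None
        for sc in self.stages:
            if sc.stage != stage:
                continue
            if merged is None:
                merged = StageCount(stage=stage, n_in=0, n_out=0, dropped={})
            merged.n_in += sc.n_in
            merged.n_out += sc.n_out
            for k, v in sc.dropped.items():
                merged.dropped[k] = merged.dropped.get(k, 0) + v
        if merged is None:
            raise KeyError(stage)
        return merged

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"stage": sc.stage, "in": sc.n_in, "out": sc.n_out,
                 "dropped": sc.n_dropped,
                 "reasons": ";".join(f"{k}={v}" for k, v in sorted(sc.dropped.items()))}
                for sc in self.stages]
        return pd.DataFrame(rows, columns=["stage", "in", "out", "dropped", "reasons"])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class PipelineResult:
    records: list[BarcodeRecord]
    assembled: dict[str, list[AssembledBarcode]]
    clusters: dict[tuple[str, str], list[Cluster]]  # (specimen, fragment)
    demux_records: list[DemuxRecord]
    chimeras: dict[tuple[str, str], set[str]]
    report: StageReport

    def calls_table(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            if not rec.sequences:
                rows.append({"specimen": rec.specimen, "status": rec.status,
                             "rank": 0, "abundance_fraction": 0.0,
                             "label": None, "identity": None, "sequence": None})
            for rank, cs in enumerate(rec.sequences, start=1):
                rows.append({"specimen": rec.specimen, "status": rec.status,
                             "rank": rank,
                             "abundance_fraction": round(cs.abundance_fraction, 4),
                             "label": cs.label, "identity": cs.identity,
                             "sequence": cs.sequence})
        return pd.DataFrame(rows, columns=[
            "specimen", "status", "rank", "abundance_fraction", "label",
            "identity", "sequence"])


def run_all(
    reads: Mapping[tuple[str, str], Iterable[ReadPair]],
    mapping: list[WellAssignment],
    primers: PrimerSet,
    cfg: PipelineConfig = PipelineConfig(),
    reference_db: ReferenceDb | None = None,
) -> PipelineResult:
    """Run the full pipeline on per-(plate, fragment) read pools.

    ``reads`` maps ``(plate, fragment)`` to an iterable of read pairs (the
    file-level pooling of a dual-indexed run). Specimens are enumerated
    from the tag map, so wells without surviving reads still appear in the
    output with status ``none``. When ``reference_db`` is given every
    called sequence is annotated with its best hit.
    """
    report = StageReport()
    demux_records: list[DemuxRecord] = []

    for (plate, fragment), pool in sorted(reads.items()):
        pool = list(pool)
        plate_assign = [wa for wa in mapping
                        if wa.plate == plate and wa.fragment == fragment]
        demux = Demultiplexer(plate_assign, primers,
                              mid_mismatch=cfg.mid_mismatch)

        merged = []
        for pair in pool:
            m = merge_pair(pair, cfg.merge)
            if m is not None:
                merged.append(m)
        report.add(f"merge[{plate}:{fragment}]",
                   len(pool), len(merged), unmerged=len(pool) - len(merged))

        passed_q = [m for m in merged if quality_gate(m, cfg.merge)]
        report.add(f"quality[{plate}:{fragment}]", len(merged), len(passed_q),
                   low_quality=len(merged) - len(passed_q))

        if not cfg.length_gate_on_insert:
            gated = [m for m in passed_q
                     if length_gate(m, cfg.merge, fragment=fragment)]
            report.add(f"length[{plate}:{fragment}]", len(passed_q), len(gated),
                       off_length=len(passed_q) - len(gated))
        else:
            gated = passed_q

        assigned = [rec for m in gated
                    if (rec := demux.assign(m.read)) is not None]
        report.add(f"demux[{plate}:{fragment}]", len(gated), len(assigned),
                   no_tag=demux.stats.unassigned_no_tag,
                   ambiguous=demux.stats.unassigned_ambiguous,
                   empty_insert=demux.stats.unassigned_empty_insert)

        if cfg.length_gate_on_insert:
            kept = [r for r in assigned if length_gate(r, cfg.merge)]
            report.add(f"length[{plate}:{fragment}]", len(assigned), len(kept),
                       off_length=len(assigned) - len(kept))
            assigned = kept
        demux_records.extend(assigned)

    # group inserts per specimen x fragment
    grouped: dict[tuple[str, str], list[str]] = {}
    for rec in demux_records:
        grouped.setdefault((rec.specimen, rec.fragment), []).append(rec.insert)

    clusters: dict[tuple[str, str], list[Cluster]] = {}
    chimeras: dict[tuple[str, str], set[str]] = {}
    for key in sorted(grouped):
        specimen, fragment = key
        inserts = grouped[key]
        uniques = dereplicate(inserts, specimen=specimen, fragment=fragment)
        report.add(f"dereplicate[{specimen}:{fragment}]",
                   len(inserts), len(inserts))  # counts conserved, not reads
        flagged = detect_chimeras(
            uniques,
            min_parent_fold=cfg.chimera_min_parent_fold,
            min_div=cfg.chimera_min_div,
            min_score=cfg.chimera_min_score,
        )
        chimeras[key] = flagged
        survivors = [u for u in uniques if u.sequence not in flagged]
        n_flagged_reads = sum(u.count for u in uniques if u.sequence in flagged)
        report.add(f"chimera[{specimen}:{fragment}]",
                   len(inserts), len(inserts) - n_flagged_reads,
                   chimeric=n_flagged_reads)
        clusters[key] = greedy_cluster(survivors, identity=cfg.cluster_identity)

    specimens = sorted({wa.specimen for wa in mapping})
    assembled: dict[str, list[AssembledBarcode]] = {}
    records: list[BarcodeRecord] = []
    for specimen in specimens:
        fc = clusters.get((specimen, "FC"), [])
        br = clusters.get((specimen, "BR"), [])
        asm = pair_specimen(
            fc, br,
            min_identity=cfg.screen_min_identity,
            min_len=cfg.screen_min_len,
            max_mismatch=cfg.screen_max_mismatch,
            min_overlap=cfg.assemble_min_overlap,
            max_mismatch_frac=cfg.assemble_max_mismatch_frac,
            specimen=specimen,
        )
        assembled[specimen] = asm
        records.append(call_barcodes(asm, min_frac=cfg.min_frac,
                                     specimen=specimen))

    if reference_db is not None:
        identify(records, reference_db)

    return PipelineResult(
        records=records, assembled=assembled, clusters=clusters,
        demux_records=demux_records, chimeras=chimeras, report=report,
    )
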