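"""Peptide-driven genome reannotation: event classification and start inference.

Validated peptides are placed against the existing annotation.  A peptide
lying inside an annotated CDS (in frame) confirms it; a peptide in the same
stop-to-stop ORF as an annotated gene but upstream of its start codon is
evidence for an N-terminal extension; a peptide in an ORF with no in-frame
CDS overlap is evidence for a novel ORF.  Start codons are inferred from
dimethyl N-terminome evidence where available (honouring aminopeptidase
initiator removal), otherwise by scanning upstream from the most upstream
supporting peptide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import yaml

from .constants import INITIATOR_REMOVAL_RESIDUES, START_CODONS
from .digestion import LYSARGINASE, TRYPSIN, digest_database, semi_digest
from .mass_model import CARBAMIDOMETHYL_C, DIMETHYL_K, DIMETHYL_N_TERM
from .mirror_analysis import (
    MirrorPair,
    NovelPeptideEvidence,
    aggregate_evidence,
    find_mirror_pairs,
)
from .sixframe_db import (
    Genome,
    OrfEntry,
    SixFrameDb,
    codon_at,
    map_protein_to_genome,
    read_genome_fasta,
    six_frame_orfs,
)
from .spectra_scoring import (
    Psm,
    SearchSettings,
    filter_qvalue,
    read_mgf,
    reversed_decoys,
    search_spectra,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated CDS, 1-based inclusive forward-strand coordinates.

    Coordinates include the stop codon, as in bacterial GFF3 CDS features.
    """

    gene_id: str
    strand: str
    cds_start: int
    cds_end: int
    product: str = ""


def read_annotation(path: str | Path) -> list[AnnotationRecord]:
    """Read CDS records from GFF3 (``.gff``/``.gff3``) or a simple TSV.

    The TSV dialect has columns gene_id, strand, cds_start, cds_end and an
    optional product column.  CDS lengths that are not a multiple of three
    raise a warning but the record is kept.
    """
    path = Path(path)
    records: list[AnnotationRecord] = []
    if path.suffix.lower() in (".gff", ".gff3"):
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        for feat in db.features_of_type("CDS", order_by=("start",)):
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            product = feat.attributes.get("product", [""])[0]
            records.append(
                AnnotationRecord(
                    gene_id=gene_id,
                    strand=feat.strand,
                    cds_start=feat.start,
                    cds_end=feat.end,
                    product=product,
                )
            )
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        for row in df.itertuples(index=False):
            records.append(
                AnnotationRecord(
                    gene_id=str(row.gene_id),
                    strand=str(row.strand),
                    cds_start=int(row.cds_start),
                    cds_end=int(row.cds_end),
                    product=str(getattr(row, "product", "")),
                )
            )
    for rec in records:
        if rec.cds_start > rec.cds_end:
            raise ValueError(f"{rec.gene_id}: cds_start > cds_end")
        if (rec.cds_end - rec.cds_start + 1) % 3 != 0:
            warnings.warn(
                f"{rec.gene_id}: CDS length not a multiple of 3", stacklevel=2
            )
    return records


def write_annotation_gff3(
    records: Iterable[AnnotationRecord], path: str | Path, genome_id: str,
    source: str = "mirrorpg",
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = f"ID={rec.gene_id}"
            if rec.product:
                attrs += f";product={rec.product}"
            fh.write(
                f"{genome_id}\t{source}\tCDS\t{rec.cds_start}\t{rec.cds_end}"
                f"\t.\t{rec.strand}\t0\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Classification


@dataclass
class InferredStart:
    """An inferred translation initiation site."""

    aa_pos: int  # 1-based residue position in the ORF
    codon: str
    genome_start: int
    genome_end: int
    strand: str
    initiator_removed: bool
    non_canonical: bool
    confidence: str  # "high" (dimethyl evidence) | "low" (upstream scan)


@dataclass
class NovelEvent:
    """A classified reannotation event with its supporting evidence."""

    event_type: str  # "n_term_extension" | "novel_orf"
    orf_id: str
    gene_id: str | None = None
    peptides: list[NovelPeptideEvidence] = field(default_factory=list)
    inferred_start: InferredStart | None = None
    filters_passed: dict[str, bool] = field(default_factory=dict)
    reportable: bool = False

    @property
    def unique_peptides(self) -> set[str]:
        return {e.sequence for e in self.peptides}


def _in_frame(rec: AnnotationRecord, orf: OrfEntry) -> bool:
    if rec.strand != orf.strand:
        return False
    if rec.cds_end < orf.start or rec.cds_start > orf.end + 3:
        return False
    if orf.strand == "+":
        return (rec.cds_start - orf.start) % 3 == 0
    return (orf.end - rec.cds_end) % 3 == 0


def _shares_stop(rec: AnnotationRecord, orf: OrfEntry) -> bool:
    """CDS stop codon coincides with the ORF's bounding stop (or its end)."""
    if not _in_frame(rec, orf):
        return False
    if orf.strand == "+":
        return rec.cds_end in (orf.end + 3, orf.end)
    return rec.cds_start in (orf.start - 3, orf.start)


def classify_peptides(
    evidence: Sequence[NovelPeptideEvidence],
    db: SixFrameDb,
    annotation: Sequence[AnnotationRecord],
) -> tuple[list[NovelEvent], list[NovelPeptideEvidence]]:
    """Split evidence into annotated peptides and novel events.

    Returns (events, annotated_evidence).  Extension events are keyed by
    gene, novel-ORF events by ORF; each event merges all its peptides.
    """
    orfs = db.by_id()
    events: dict[tuple[str, str], NovelEvent] = {}
    annotated: list[NovelPeptideEvidence] = []
    for ev in evidence:
        orf = orfs[ev.orf_id]
        g_start, g_end, strand = ev.interval
        in_frame = [rec for rec in annotation if _in_frame(rec, orf)]
        if not in_frame:
            key = ("novel_orf", ev.orf_id)
            event = events.setdefault(
                key, NovelEvent(event_type="novel_orf", orf_id=ev.orf_id)
            )
            event.peptides.append(ev)
            continue
        host = next((r for r in in_frame if _shares_stop(r, orf)), in_frame[0])
        if strand == "+":
            upstream = g_start < host.cds_start
            within = g_start >= host.cds_start and g_end <= host.cds_end
        else:
            upstream = g_end > host.cds_end
            within = g_end <= host.cds_end and g_start >= host.cds_start
        if within:
            annotated.append(ev)
        elif upstream:
            key = ("n_term_extension", host.gene_id)
            event = events.setdefault(
                key,
                NovelEvent(
                    event_type="n_term_extension",
                    orf_id=ev.orf_id,
                    gene_id=host.gene_id,
                ),
            )
            event.peptides.append(ev)
        else:
            # inside the ORF, downstream of the CDS: treated as annotated
            # (can only arise from unusual annotations, not from digestion)
            annotated.append(ev)
    return [events[k] for k in sorted(events)], annotated


# ---------------------------------------------------------------------------
# Start-codon inference


def infer_start_codon(
    event: NovelEvent,
    nterm_positions: Sequence[int],
    orf: OrfEntry,
    genome: Genome,
) -> InferredStart | None:
    """Infer the start codon of an event's ORF.

    With dimethyl N-terminome evidence at ORF residue p the initiator rule
    is applied first: if residue p is an aminopeptidase substrate's
    follower (small residue) the codon at p-1 is proposed with the
    initiator removed, accepting a non-canonical codon under direct
    dimethyl evidence; otherwise the codon at p must itself be a start.
    Without such evidence the nearest in-frame canonical start at or
    upstream of the most upstream supporting peptide is proposed with low
    confidence.  Returns None when no candidate exists in the ORF.
    """
    if nterm_positions:
        p = min(nterm_positions)
        confidence, dimethyl = "high", True
    else:
        if not event.peptides:
            raise ValueError("event has no supporting peptides")
        p = min(ev.aa_start for ev in event.peptides)
        confidence, dimethyl = "low", False

    def result(aa_pos: int, codon: str, removed: bool) -> InferredStart:
        s, e, strand = map_protein_to_genome(orf, aa_pos, aa_pos)
        return InferredStart(
            aa_pos=aa_pos,
            codon=codon,
            genome_start=s,
            genome_end=e,
            strand=strand,
            initiator_removed=removed,
            non_canonical=codon not in START_CODONS,
            confidence=confidence,
        )

    removable = p >= 2 and orf.aa_sequence[p - 1] in INITIATOR_REMOVAL_RESIDUES
    if removable:
        prev = codon_at(orf, p - 1, genome)
        if prev in START_CODONS:
            return result(p - 1, prev, removed=True)
    here = codon_at(orf, p, genome)
    if here in START_CODONS:
        return result(p, here, removed=False)
    if dimethyl and removable:
        # direct N-terminal labeling: accept a non-canonical codon (flagged)
        return result(p - 1, codon_at(orf, p - 1, genome), removed=True)
    for q in range(p - 1, 0, -1):
        cq = codon_at(orf, q, genome)
        if cq in START_CODONS:
            return result(q, cq, removed=False)
    return None


# ---------------------------------------------------------------------------
# Event filters


@dataclass
class FilterThresholds:
    """Event-level acceptance thresholds."""

    min_unique_peptides: int = 2
    require_mirror_or_two_products: bool = True
    min_by_pairs: int = 3
    cosine_threshold: float = 0.9


def filter_events(
    events: Sequence[NovelEvent],
    thresholds: FilterThresholds | None = None,
    n15_present: bool = True,
) -> list[NovelEvent]:
    """Annotate each event with per-filter pass/fail and a reportable flag.

    Filters: >= min_unique_peptides distinct peptide sequences; >= 1 mirror
    pair or >= 2 distinct protease products; cosine-validated 15N spectrum
    on >= 1 peptide (only when 15N data were searched); >= min_by_pairs b/y
    pair positions on >= 1 peptide (merged metrics for mirror members).
    """
    thresholds = thresholds or FilterThresholds()
    for event in events:
        peps = event.peptides
        flags = {
            "unique_peptides": len(event.unique_peptides)
            >= thresholds.min_unique_peptides,
            "mirror_or_products": (
                not thresholds.require_mirror_or_two_products
                or any(e.is_mirror for e in peps)
                or len({e.protease for e in peps}) >= 2
            ),
            "n15_cosine": (not n15_present) or any(e.n15_validated for e in peps),
            "by_pairs": any(
                e.pair_count >= thresholds.min_by_pairs for e in peps
            ),
        }
        event.filters_passed = flags
        event.reportable = all(flags.values())
    return list(events)


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end reannotation run."""

    genome: str
    annotation: str
    mgf_trypsin_14n: str
    mgf_lysarginase_14n: str
    mgf_trypsin_15n: str | None = None
    mgf_lysarginase_15n: str | None = None
    mgf_nterm: str | None = None
    out_dir: str = "."
    min_len: int = 7
    max_len: int = 45
    max_missed: int = 2
    nterm_max_missed: int = 3
    tol_ppm: float = 20.0
    fdr: float = 0.01
    cosine_threshold: float = 0.9
    min_unique_peptides: int = 2
    min_by_pairs: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


@dataclass
class ReannotationReport:
    """Outputs of a pipeline run."""

    db: SixFrameDb
    psms: dict[tuple[str, str], list[Psm]]  # (protease, isotope) -> q-passing
    pairs: list[MirrorPair]
    evidence: list[NovelPeptideEvidence]
    events: list[NovelEvent]
    annotated_evidence: list[NovelPeptideEvidence]

    @property
    def reportable_events(self) -> list[NovelEvent]:
        return [e for e in self.events if e.reportable]


def _search_run(
    mgf_path: str,
    target_peptides,
    decoys,
    isotope_mode: str,
    cfg: PipelineConfig,
) -> list[Psm]:
    spectra = read_mgf(mgf_path)
    settings = SearchSettings(
        fixed_mods=(CARBAMIDOMETHYL_C,),
        isotope_mode=isotope_mode,
        tol_ppm=cfg.tol_ppm,
    )
    psms = search_spectra(spectra, target_peptides, settings, decoys)
    return filter_qvalue(psms, cfg.fdr)


def _nterm_search(
    cfg: PipelineConfig, candidate_orfs: Sequence[OrfEntry]
) -> dict[str, list[int]]:
    """Targeted semi-tryptic dimethyl N-terminome search.

    Searches the N-terminome MGF against the semi-specific tryptic digest
    of the candidate ORFs only (dimethyl fixed at K and at every peptide
    N-terminus).  Returns, per ORF, the peptide start positions supported
    by a q-passing dimethyl PSM.
    """
    if cfg.mgf_nterm is None or not candidate_orfs:
        return {}

    def semi_peptides(entries) -> list:
        out = []
        for orf in entries:
            out.extend(
                semi_digest(
                    orf.aa_sequence,
                    TRYPSIN,
                    max_missed=cfg.nterm_max_missed,
                    min_len=cfg.min_len,
                    max_len=cfg.max_len,
                    parent_id=orf.orf_id,
                )
            )
        return out

    peptides = semi_peptides(candidate_orfs)
    if not peptides:
        return {}
    settings = SearchSettings(
        fixed_mods=(CARBAMIDOMETHYL_C, DIMETHYL_K),
        isotope_mode="14N",
        tol_ppm=cfg.tol_ppm,
        nterm_mod=DIMETHYL_N_TERM,
    )
    spectra = read_mgf(cfg.mgf_nterm)
    psms = filter_qvalue(
        search_spectra(
            spectra, peptides, settings,
            semi_peptides(reversed_decoys(candidate_orfs)),
        ),
        cfg.fdr,
    )
    positions: dict[str, list[int]] = {}
    for psm in psms:
        positions.setdefault(psm.peptide.parent_id, []).append(psm.peptide.start)
    return positions


def run_pipeline(cfg: PipelineConfig) -> ReannotationReport:
    """Execute the full workflow: sixframe, digest, search, mirror, classify.

    Deterministic given the configuration and input files.  Writes
    ``events.tsv``, ``corrected.gff3``, ``novel_orfs.gff3`` and ``run.log``
    into ``cfg.out_dir``.
    """
    for name in ("genome", "annotation", "mgf_trypsin_14n", "mgf_lysarginase_14n"):
        value = getattr(cfg, name)
        if value is None or not Path(value).exists():
            raise FileNotFoundError(f"config input {name} missing: {value}")

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    genome = read_genome_fasta(cfg.genome)
    annotation = read_annotation(cfg.annotation)
    db = six_frame_orfs(genome, cfg.min_len)
    orfs = db.by_id()
    log_lines.append(f"six-frame database: {len(db)} entries (min_len {cfg.min_len})")

    decoy_entries = reversed_decoys(db.entries)
    peptides = {}
    decoys = {}
    for protease, rule in (("trypsin", TRYPSIN), ("lysarginase", LYSARGINASE)):
        kwargs = dict(
            max_missed=cfg.max_missed, min_len=cfg.min_len, max_len=cfg.max_len
        )
        peptides[protease] = digest_database(db.entries, rule, **kwargs)
        decoys[protease] = digest_database(decoy_entries, rule, **kwargs)
        log_lines.append(f"{protease}: {len(peptides[protease])} target peptides")

    mgfs = {
        ("trypsin", "14N"): cfg.mgf_trypsin_14n,
        ("lysarginase", "14N"): cfg.mgf_lysarginase_14n,
        ("trypsin", "15N"): cfg.mgf_trypsin_15n,
        ("lysarginase", "15N"): cfg.mgf_lysarginase_15n,
    }
    psms: dict[tuple[str, str], list[Psm]] = {}
    for (protease, isotope), mgf_path in mgfs.items():
        if mgf_path is None:
            continue
        psms[(protease, isotope)] = _search_run(
            mgf_path, peptides[protease], decoys[protease], isotope, cfg
        )
        log_lines.append(
            f"{protease}/{isotope}: {len(psms[(protease, isotope)])} PSMs at "
            f"q < {cfg.fdr}"
        )

    pairs = find_mirror_pairs(
        psms.get(("trypsin", "14N"), []),
        psms.get(("lysarginase", "14N"), []),
        orfs,
    )
    log_lines.append(f"mirror pairs: {len(pairs)}")

    evidence = aggregate_evidence(
        {
            "trypsin": psms.get(("trypsin", "14N"), []),
            "lysarginase": psms.get(("lysarginase", "14N"), []),
        },
        pairs,
        orfs,
        {
            "trypsin": psms.get(("trypsin", "15N"), []),
            "lysarginase": psms.get(("lysarginase", "15N"), []),
        },
        cosine_threshold=cfg.cosine_threshold,
    )

    events, annotated = classify_peptides(evidence, db, annotation)
    log_lines.append(
        f"evidence: {len(evidence)} peptides ({len(annotated)} annotated); "
        f"{len(events)} candidate events"
    )

    nterm_positions = _nterm_search(
        cfg, [orfs[e.orf_id] for e in events]
    )
    for event in events:
        event.inferred_start = infer_start_codon(
            event, nterm_positions.get(event.orf_id, []), orfs[event.orf_id], genome
        )

    thresholds = FilterThresholds(
        min_unique_peptides=cfg.min_unique_peptides,
        min_by_pairs=cfg.min_by_pairs,
        cosine_threshold=cfg.cosine_threshold,
    )
    n15_present = cfg.mgf_trypsin_15n is not None or cfg.mgf_lysarginase_15n is not None
    filter_events(events, thresholds, n15_present=n15_present)
    log_lines.append(
        f"reportable events: {sum(e.reportable for e in events)} of {len(events)}"
    )

    report = ReannotationReport(
        db=db,
        psms=psms,
        pairs=pairs,
        evidence=evidence,
        events=events,
        annotated_evidence=annotated,
    )
    _write_outputs(report, annotation, genome, out_dir)
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report


def _event_row(event: NovelEvent) -> dict:
    start = event.inferred_start
    return {
        "event_type": event.event_type,
        "orf_id": event.orf_id,
        "gene_id": event.gene_id or "",
        "n_unique_peptides": len(event.unique_peptides),
        "n_mirror": sum(e.is_mirror for e in event.peptides),
        "best_q": min(e.q_best for e in event.peptides),
        "best_score": max(e.raw_score_best for e in event.peptides),
        "max_by_pairs": max(e.pair_count for e in event.peptides),
        "n15_validated": any(e.n15_validated for e in event.peptides),
        "start_codon": start.codon if start else "",
        "start_pos": start.genome_start if start else "",
        "initiator_removed": start.initiator_removed if start else "",
        "start_confidence": start.confidence if start else "unresolved",
        "reportable": event.reportable,
        "filters_failed": ";".join(
            sorted(k for k, v in event.filters_passed.items() if not v)
        ),
        "peptides": ";".join(sorted(event.unique_peptides)),
    }


def _write_outputs(
    report: ReannotationReport,
    annotation: Sequence[AnnotationRecord],
    genome: Genome,
    out_dir: Path,
) -> None:
    columns = [
        "event_type", "orf_id", "gene_id", "n_unique_peptides", "n_mirror",
        "best_q", "best_score", "max_by_pairs", "n15_validated", "start_codon",
        "start_pos", "initiator_removed", "start_confidence", "reportable",
        "filters_failed", "peptides",
    ]
    rows = [_event_row(e) for e in report.events]
    pd.DataFrame(rows, columns=columns).to_csv(
        out_dir / "events.tsv", sep="\t", index=False
    )

    by_gene = {rec.gene_id: rec for rec in annotation}
    corrected: list[AnnotationRecord] = []
    novel: list[AnnotationRecord] = []
    for event in report.reportable_events:
        start = event.inferred_start
        if event.event_type == "n_term_extension" and event.gene_id:
            rec = by_gene[event.gene_id]
            if start is None:
                continue
            if rec.strand == "+":
                corrected.append(
                    AnnotationRecord(
                        rec.gene_id, "+", start.genome_start, rec.cds_end,
                        rec.product,
                    )
                )
            else:
                corrected.append(
                    AnnotationRecord(
                        rec.gene_id, "-", rec.cds_start, start.genome_end,
                        rec.product,
                    )
                )
        elif event.event_type == "novel_orf":
            orf = report.db.by_id()[event.orf_id]
            if start is not None:
                lo = start.genome_start if orf.strand == "+" else orf.start - 3
                hi = orf.end + 3 if orf.strand == "+" else start.genome_end
            else:  # no start candidate: report the peptide-supported ORF span
                lo = orf.start if orf.strand == "+" else orf.start - 3
                hi = orf.end + 3 if orf.strand == "+" else orf.end
            novel.append(
                AnnotationRecord(event.orf_id, orf.strand, lo, hi, "novel ORF")
            )
    write_annotation_gff3(corrected, out_dir / "corrected.gff3", genome.id)
    write_annotation_gff3(novel, out_dir / "novel_orfs.gff3", genome.id)
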