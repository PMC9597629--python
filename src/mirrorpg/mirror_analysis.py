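"""Mirror peptide pairing and merged b/y ion coverage.

A tryptic peptide and a lysargiNase peptide form a mirror pair when, after
trimming the tryptic C-terminal K/R run and the lysargiNase N-terminal K/R
run, the remaining cores are the same string at the same genomic locus.
The union string (lysargiNase K/R prefix + core + tryptic K/R suffix) is
the pair's super-sequence; evidence from both members is projected onto its
backbone bonds to compute merged coverage, which can only improve on either
member alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .digestion import trim_c_terminal_kr, trim_n_terminal_kr
from .sixframe_db import OrfEntry, map_protein_to_genome
from .spectra_scoring import (
    CoverageMetrics,
    Psm,
    coverage_from_positions,
    cosine_similarity,
    ion_coverage,
    matched_bond_positions,
)


class MirrorMappingError(ValueError):
    """Inconsistent member offsets when projecting onto a super-sequence."""


@dataclass
class MirrorPair:
    """A tryptic/lysargiNase PSM pair sharing a core sequence and locus."""

    tryptic: Psm
    lysarginase: Psm
    core: str
    super_sequence: str
    orf_id: str
    locus: tuple[int, int, str]  # forward-strand interval of super_sequence

    @property
    def tryptic_offset(self) -> int:
        """Residue offset of the tryptic member within the super-sequence."""
        return len(self.super_sequence) - len(self.tryptic.sequence)

    @property
    def lysarginase_offset(self) -> int:
        return 0


def _core_span(psm: Psm, protease: str) -> tuple[str, int, int]:
    """Core string and its 1-based span in the parent protein."""
    if protease == "trypsin":
        core, suffix = trim_c_terminal_kr(psm.sequence)
        return core, psm.peptide.start, psm.peptide.end - len(suffix)
    core, prefix = trim_n_terminal_kr(psm.sequence)
    return core, psm.peptide.start + len(prefix), psm.peptide.end


def find_mirror_pairs(
    psms_trypsin: Sequence[Psm],
    psms_lysarginase: Sequence[Psm],
    orfs_by_id: Mapping[str, OrfEntry],
) -> list[MirrorPair]:
    """Pair tryptic and lysargiNase PSMs with identical cores at one locus.

    Identical peptide sequences mapping to different ORFs never pair.  Each
    tryptic peptide sequence pairs with at most one lysargiNase peptide
    sequence (the best-scoring counterpart), and vice versa.
    """
    by_core: dict[tuple[str, str, int], Psm] = {}
    for psm in psms_lysarginase:
        core, lo, _hi = _core_span(psm, "lysarginase")
        if not core:
            continue
        key = (psm.peptide.parent_id, core, lo)
        prev = by_core.get(key)
        if prev is None or psm.raw_score > prev.raw_score:
            by_core[key] = psm

    best_t: dict[tuple[str, str, int], Psm] = {}
    for psm in psms_trypsin:
        core, lo, _hi = _core_span(psm, "trypsin")
        if not core:
            continue
        key = (psm.peptide.parent_id, core, lo)
        if key not in by_core:
            continue
        prev = best_t.get(key)
        if prev is None or psm.raw_score > prev.raw_score:
            best_t[key] = psm

    pairs: list[MirrorPair] = []
    for key, psm_t in sorted(best_t.items()):
        psm_l = by_core[key]
        parent_id, core, lo = key
        orf = orfs_by_id[parent_id]
        _, prefix = trim_n_terminal_kr(psm_l.sequence)
        _, suffix = trim_c_terminal_kr(psm_t.sequence)
        super_seq = prefix + core + suffix
        aa_lo = psm_l.peptide.start
        aa_hi = psm_t.peptide.end
        g_start, g_end, strand = map_protein_to_genome(orf, aa_lo, aa_hi)
        pairs.append(
            MirrorPair(
                tryptic=psm_t,
                lysarginase=psm_l,
                core=core,
                super_sequence=super_seq,
                orf_id=parent_id,
                locus=(g_start, g_end, strand),
            )
        )
    return pairs


def merged_coverage(pair: MirrorPair) -> CoverageMetrics:
    """Merged b/y coverage of both members on the super-sequence bonds.

    A member's b_i covers super bond offset+i; its y_j covers super bond
    offset + (n_member - j).  Denominator is the super-sequence bond count.
    """
    m = len(pair.super_sequence)
    if m < 2:
        raise MirrorMappingError("super-sequence too short")
    b_all: set[int] = set()
    y_all: set[int] = set()
    for psm, offset in (
        (pair.tryptic, pair.tryptic_offset),
        (pair.lysarginase, pair.lysarginase_offset),
    ):
        n = len(psm.sequence)
        if offset < 0 or offset + n > m:
            raise MirrorMappingError(
                f"member {psm.sequence} does not fit super {pair.super_sequence}"
            )
        b_pos, y_pos = matched_bond_positions(n, psm.matched.keys())
        b_all.update(p + offset for p in b_pos)
        y_all.update(p + offset for p in y_pos)
    return coverage_from_positions(m - 1, b_all, y_all)


@dataclass
class NovelPeptideEvidence:
    """Aggregated evidence for one distinct peptide at one locus."""

    sequence: str
    protease: str
    orf_id: str
    aa_start: int
    aa_end: int
    interval: tuple[int, int, str]
    q_best: float
    raw_score_best: float
    is_mirror: bool = False
    n15_validated: bool = False
    cosine: float | None = None
    pair_count: int = 0
    max_continuous_pairs: int = 0
    merged: CoverageMetrics | None = None
    psms: list[Psm] = field(default_factory=list)


def aggregate_evidence(
    psms_by_protease: Mapping[str, Sequence[Psm]],
    pairs: Sequence[MirrorPair],
    orfs_by_id: Mapping[str, OrfEntry],
    n15_psms_by_protease: Mapping[str, Sequence[Psm]] | None = None,
    cosine_threshold: float = 0.9,
) -> list[NovelPeptideEvidence]:
    """One evidence record per distinct (peptide, locus).

    All input PSMs must already be q-value filtered.  The 15N validation
    flag is set when a 15N PSM of the same peptide exists and the aligned
    fragment-intensity cosine with the best 14N PSM exceeds the threshold.
    Mirror-pair members additionally carry the pair's merged metrics.
    """
    n15_psms_by_protease = n15_psms_by_protease or {}

    records: dict[tuple[str, str, int], NovelPeptideEvidence] = {}
    for protease, psms in sorted(psms_by_protease.items()):
        for psm in psms:
            key = (protease, psm.sequence, psm.peptide.start)
            rec = records.get(key)
            if rec is None:
                cov = ion_coverage(psm)
                orf = orfs_by_id[psm.peptide.parent_id]
                records[key] = rec = NovelPeptideEvidence(
                    sequence=psm.sequence,
                    protease=protease,
                    orf_id=psm.peptide.parent_id,
                    aa_start=psm.peptide.start,
                    aa_end=psm.peptide.end,
                    interval=map_protein_to_genome(
                        orf, psm.peptide.start, psm.peptide.end
                    ),
                    q_best=psm.q_value if psm.q_value is not None else 0.0,
                    raw_score_best=psm.raw_score,
                    pair_count=cov.pair_count,
                    max_continuous_pairs=cov.max_continuous_pairs,
                )
            else:
                rec.q_best = min(rec.q_best, psm.q_value or 0.0)
                rec.raw_score_best = max(rec.raw_score_best, psm.raw_score)
                cov = ion_coverage(psm)
                rec.pair_count = max(rec.pair_count, cov.pair_count)
                rec.max_continuous_pairs = max(
                    rec.max_continuous_pairs, cov.max_continuous_pairs
                )
            rec.psms.append(psm)

    # mirror membership and merged metrics
    for pair in pairs:
        merged = merged_coverage(pair)
        for protease, psm in (
            ("trypsin", pair.tryptic),
            ("lysarginase", pair.lysarginase),
        ):
            rec = records.get((protease, psm.sequence, psm.peptide.start))
            if rec is None:
                continue
            rec.is_mirror = True
            rec.merged = merged
            rec.pair_count = max(rec.pair_count, merged.pair_count)
            rec.max_continuous_pairs = max(
                rec.max_continuous_pairs, merged.max_continuous_pairs
            )

    # 15N spectral validation
    n15_index: dict[tuple[str, str, int], list[Psm]] = {}
    for protease, psms in sorted(n15_psms_by_protease.items()):
        for psm in psms:
            n15_index.setdefault(
                (protease, psm.sequence, psm.peptide.start), []
            ).append(psm)
    for key, rec in records.items():
        counterparts = n15_index.get(key, [])
        if not counterparts:
            continue
        best14 = max(rec.psms, key=lambda p: p.raw_score)
        best_cos = 0.0
        for psm15 in counterparts:
            try:
                cos = cosine_similarity(best14.intensities, psm15.intensities)
            except ValueError:
                continue
            best_cos = max(best_cos, cos)
        rec.cosine = best_cos
        rec.n15_validated = best_cos > cosine_threshold

    out = [records[k] for k in sorted(records)]
    return out
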