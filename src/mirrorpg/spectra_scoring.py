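"""Spectrum I/O, fragment matching, PSM scoring, target-decoy q-values.

The matching model is deliberately small: centroided peak lists, b/y
fragments matched at a ppm tolerance (boundary inclusive), a documented
surrogate raw score, and classical target-decoy q-value estimation with
decoys built by whole-entry sequence reversal of the search database.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .digestion import DigestPeptide
from .mass_model import (
    FragmentIon,
    ModAssignment,
    apply_fixed_mods,
    fragment_ions,
    peptide_mass,
    PROTON,
)

logger = logging.getLogger(__name__)

FragmentKey = tuple[str, int, int]  # (series, index, charge)


class MgfParseError(ValueError):
    """Malformed MGF input."""


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum; peaks are kept m/z-ascending."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray
    label: str | None = None  # "14N" | "15N" | None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        # merge duplicate m/z values (sum intensities) so mz is strictly ascending
        if len(self.mz) > 1:
            uniq, inverse = np.unique(self.mz, return_inverse=True)
            if len(uniq) < len(self.mz):
                summed = np.zeros_like(uniq)
                np.add.at(summed, inverse, self.intensity)
                self.mz, self.intensity = uniq, summed

    def __len__(self) -> int:
        return len(self.mz)


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into spectra (charge from the CHARGE line)."""
    out: list[Spectrum] = []
    try:
        with _mgf.MGF(str(path)) as reader:
            for i, entry in enumerate(reader):
                params = entry["params"]
                charge_field = params.get("charge")
                charge = int(charge_field[0]) if charge_field else 2
                out.append(
                    Spectrum(
                        spectrum_id=str(params.get("title", f"spectrum_{i}")),
                        precursor_mz=float(params["pepmass"][0]),
                        precursor_charge=charge,
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                        label=params.get("label"),
                    )
                )
    except (KeyError, ValueError, TypeError) as exc:
        raise MgfParseError(f"malformed MGF {path}: {exc}") from exc
    return out


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        params = {
            "title": s.spectrum_id,
            "pepmass": s.precursor_mz,
            "charge": [s.precursor_charge],
        }
        if s.label:
            params["label"] = s.label
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _mgf.write(entries, str(path), file_mode="w")


@dataclass(frozen=True)
class FragmentMatch:
    """One matched theoretical fragment with its peak and ppm error."""

    fragment: FragmentIon
    peak_index: int
    ppm_error: float
    intensity: float


def match_peaks(
    spectrum: Spectrum,
    fragments: Sequence[FragmentIon],
    tol_ppm: float = 20.0,
) -> dict[FragmentKey, FragmentMatch]:
    """Match theoretical fragments to peaks at a ppm tolerance (inclusive).

    Each fragment takes the closest peak within tolerance; one peak may
    satisfy several fragments.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    mz = spectrum.mz
    matches: dict[FragmentKey, FragmentMatch] = {}
    for frag in fragments:
        # 1e-12 relative slack keeps the boundary inclusive under rounding
        tol = frag.mz * tol_ppm * 1e-6 * (1.0 + 1e-12)
        lo = bisect.bisect_left(mz, frag.mz - tol)
        hi = bisect.bisect_right(mz, frag.mz + tol)
        if lo == hi:
            continue
        idx = lo + int(np.argmin(np.abs(mz[lo:hi] - frag.mz)))
        ppm = (mz[idx] - frag.mz) / frag.mz * 1e6
        matches[frag.key] = FragmentMatch(
            fragment=frag,
            peak_index=idx,
            ppm_error=ppm,
            intensity=float(spectrum.intensity[idx]),
        )
    return matches


def raw_score(
    spectrum: Spectrum, matched: Mapping[FragmentKey, FragmentMatch]
) -> float:
    """Surrogate PSM reliability score.

    Number of matched fragments plus the fraction of total peak intensity
    carried by matched peaks.  Deterministic, higher is better.  Absolute
    values are not comparable with any search engine's internal score.
    """
    if not matched:
        return 0.0
    total = float(spectrum.intensity.sum())
    matched_peaks = {m.peak_index for m in matched.values()}
    explained = float(spectrum.intensity[sorted(matched_peaks)].sum())
    frac = explained / total if total > 0 else 0.0
    return len(matched) + frac


@dataclass
class Psm:
    """A peptide-spectrum match with score, q-value and coverage bookkeeping."""

    spectrum_id: str
    peptide: DigestPeptide
    mods: dict[int, object] = field(default_factory=dict)
    charge: int = 2
    isotope_mode: str = "14N"
    matched: dict[FragmentKey, FragmentMatch] = field(default_factory=dict)
    raw_score: float = 0.0
    q_value: float | None = None
    is_decoy: bool = False

    @property
    def sequence(self) -> str:
        return self.peptide.sequence

    @property
    def intensities(self) -> dict[FragmentKey, float]:
        """Annotated fragment intensities, keyed (series, index, charge)."""
        return {k: m.intensity for k, m in self.matched.items()}


def target_decoy_qvalues(psms: Sequence[Psm]) -> list[Psm]:
    """Assign q-values by the classical target-decoy ranking.

    PSMs are ranked by raw score (descending); at equal score decoys rank
    above targets (conservative).  FDR at a rank is (#decoys at or above) /
    max(1, #targets at or above); the q-value is the running minimum of FDR
    from the bottom of the list upward.  Returns the ranked list.
    """
    if not psms:
        return []
    ranked = sorted(
        psms,
        key=lambda p: (
            -p.raw_score,
            not p.is_decoy,
            p.sequence,
            p.peptide.parent_id,
            p.spectrum_id,
        ),
    )
    n_decoys = sum(p.is_decoy for p in ranked)
    if n_decoys == 0:
        logger.warning("no decoy PSMs present; all q-values set to 0")
        for p in ranked:
            p.q_value = 0.0
        return ranked
    fdrs = []
    d = t = 0
    for p in ranked:
        if p.is_decoy:
            d += 1
        else:
            t += 1
        fdrs.append(d / max(1, t))
    running = np.minimum.accumulate(np.asarray(fdrs)[::-1])[::-1]
    for p, q in zip(ranked, running):
        p.q_value = float(q)
    return ranked


@dataclass(frozen=True)
class CoverageMetrics:
    """Per-PSM (or merged) b/y backbone coverage summary.

    Coverage fractions are over the n-1 backbone bond positions; a "pair
    position" is a bond i with both b_i and its complementary y_{n-i}
    matched at any charge.
    """

    n_positions: int
    b_coverage: float
    y_coverage: float
    by_pair_positions: frozenset[int]
    max_continuous_pairs: int

    @property
    def pair_count(self) -> int:
        return len(self.by_pair_positions)


def _longest_run(positions: frozenset[int]) -> int:
    best = run = 0
    prev = None
    for p in sorted(positions):
        run = run + 1 if prev is not None and p == prev + 1 else 1
        best = max(best, run)
        prev = p
    return best


def coverage_from_positions(
    n_positions: int, b_positions: Iterable[int], y_positions: Iterable[int]
) -> CoverageMetrics:
    """Coverage metrics from bond positions hit by b and by y ions."""
    if n_positions < 1:
        raise ValueError("peptide too short for coverage metrics")
    b_set = frozenset(b_positions)
    y_set = frozenset(y_positions)
    pairs = b_set & y_set
    return CoverageMetrics(
        n_positions=n_positions,
        b_coverage=len(b_set) / n_positions,
        y_coverage=len(y_set) / n_positions,
        by_pair_positions=pairs,
        max_continuous_pairs=_longest_run(pairs),
    )


def matched_bond_positions(
    n: int, matched_keys: Iterable[FragmentKey]
) -> tuple[set[int], set[int]]:
    """Backbone bond positions (1..n-1) covered by b ions and by y ions.

    b_i sits on bond i; y_j sits on bond n - j.
    """
    b_pos: set[int] = set()
    y_pos: set[int] = set()
    for series, index, _charge in matched_keys:
        if series == "b":
            b_pos.add(index)
        elif series == "y":
            y_pos.add(n - index)
    return b_pos, y_pos


def ion_coverage(psm: Psm) -> CoverageMetrics:
    """b/y coverage metrics of a single PSM."""
    n = len(psm.peptide.sequence)
    if n < 2:
        raise ValueError("coverage undefined for peptides shorter than 2")
    b_pos, y_pos = matched_bond_positions(n, psm.matched.keys())
    return coverage_from_positions(n - 1, b_pos, y_pos)


def cosine_similarity(
    intensities_a: Mapping[FragmentKey, float],
    intensities_b: Mapping[FragmentKey, float],
) -> float:
    """Cosine of two annotated-fragment intensity vectors.

    Vectors are taken over the union of fragment keys (absent key = zero
    intensity), so the value is scale-invariant and lies in [0, 1].
    """
    keys = sorted(set(intensities_a) | set(intensities_b))
    if not keys:
        raise ValueError("cosine undefined: no annotated fragments")
    a = np.array([intensities_a.get(k, 0.0) for k in keys])
    b = np.array([intensities_b.get(k, 0.0) for k in keys])
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined: all-zero intensity vector")
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Database search


DECOY_PREFIX = "DECOY_"


def reversed_decoys(entries: Iterable) -> list:
    """Decoy database entries by whole-entry sequence reversal.

    Entries expose ``orf_id`` and ``aa_sequence``; decoys keep coordinates
    but reverse the protein and prefix the identifier, and are digested
    with the same rule as the targets.
    """
    return [
        replace(e, orf_id=DECOY_PREFIX + e.orf_id, aa_sequence=e.aa_sequence[::-1])
        for e in entries
    ]


@dataclass
class SearchSettings:
    """Settings of one database search run."""

    fixed_mods: tuple = ()
    isotope_mode: str = "14N"
    tol_ppm: float = 20.0
    fragment_charges: tuple[int, ...] = (1,)
    nterm_mod: object | None = None  # applied to every peptide N-terminus
    min_matched_fragments: int = 2


def _peptide_mods(sequence: str, settings: SearchSettings) -> dict:
    mods = apply_fixed_mods(sequence, list(settings.fixed_mods))
    if settings.nterm_mod is not None:
        mods[0] = settings.nterm_mod
    return mods


def search_spectra(
    spectra: Sequence[Spectrum],
    target_peptides: Sequence[DigestPeptide],
    settings: SearchSettings,
    decoy_peptides: Sequence[DigestPeptide] | None = None,
) -> list[Psm]:
    """Rank-1 search of spectra against target and decoy peptides.

    Precursors are matched at ``tol_ppm`` on m/z at the spectrum charge; the
    best-scoring candidate per spectrum is retained (ties broken decoy-first,
    then lexicographically).  Decoy peptides normally come from digesting
    the whole-entry-reversed database (see ``reversed_decoys``).  Returns
    PSMs with q-values assigned.
    """
    if decoy_peptides is None:
        decoy_peptides = ()
    candidates: list[tuple[DigestPeptide, bool]] = [
        (p, False) for p in target_peptides
    ] + [(p, True) for p in decoy_peptides]

    mod_cache: dict[str, dict] = {}
    mz_list = np.empty(len(candidates))
    for i, (pep, _) in enumerate(candidates):
        mods = mod_cache.get(pep.sequence)
        if mods is None:
            mods = mod_cache[pep.sequence] = _peptide_mods(pep.sequence, settings)
        mz_list[i] = peptide_mass(pep.sequence, mods, settings.isotope_mode)
    order = np.argsort(mz_list)
    sorted_masses = mz_list[order]

    frag_cache: dict[str, list[FragmentIon]] = {}
    psms: list[Psm] = []
    for spectrum in spectra:
        z = spectrum.precursor_charge
        neutral = spectrum.precursor_mz * z - z * PROTON
        tol = neutral * settings.tol_ppm * 1e-6
        lo = np.searchsorted(sorted_masses, neutral - tol, side="left")
        hi = np.searchsorted(sorted_masses, neutral + tol, side="right")
        best: Psm | None = None
        best_key = None
        for j in order[lo:hi]:
            pep, is_decoy = candidates[j]
            mods = mod_cache[pep.sequence]
            frags = frag_cache.get(pep.sequence)
            if frags is None:
                frags = frag_cache[pep.sequence] = fragment_ions(
                    pep.sequence, mods, settings.isotope_mode,
                    settings.fragment_charges,
                )
            matched = match_peaks(spectrum, frags, settings.tol_ppm)
            if len(matched) < settings.min_matched_fragments:
                continue
            score = raw_score(spectrum, matched)
            key = (-score, not is_decoy, pep.sequence, pep.parent_id)
            if best is None or key < best_key:
                best_key = key
                best = Psm(
                    spectrum_id=spectrum.spectrum_id,
                    peptide=pep,
                    mods=mods,
                    charge=z,
                    isotope_mode=settings.isotope_mode,
                    matched=matched,
                    raw_score=score,
                    is_decoy=is_decoy,
                )
        if best is not None:
            psms.append(best)
    return target_decoy_qvalues(psms)


def filter_qvalue(psms: Iterable[Psm], q_threshold: float = 0.01) -> list[Psm]:
    """Target PSMs passing the q-value threshold."""
    return [
        p
        for p in psms
        if not p.is_decoy and p.q_value is not None and p.q_value < q_threshold
    ]
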