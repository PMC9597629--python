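"""In-silico digestion by the mirror proteases trypsin and lysargiNase.

Trypsin cleaves C-terminal to K/R; lysargiNase cleaves N-terminal to K/R.
Digesting the same protein with both therefore yields "mirror" peptide
pairs sharing an identical interior sequence and differing only in which
terminus carries the K/R.  Full and semi-specific modes are supported, with
a missed-cleavage budget and length window.

Cleavage is modelled with boundary positions: 0-based cut points between
residues, always including both protein termini.  A peptide is a window
between two boundaries; its missed-cleavage count is the number of internal
boundaries it spans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

TERMINUS = "-"


class AlphabetError(ValueError):
    """Raised when a protein contains residues outside the 20 canonical + X."""


_CANONICAL = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteaseRule:
    """A cleavage rule: which residues, and on which side of them."""

    name: str
    cleave_residues: frozenset[str] = frozenset("KR")
    side: str = "C"  # "C": cut after the residue; "N": cut before it
    proline_exception: bool = False

    def __post_init__(self) -> None:
        if self.side not in ("C", "N"):
            raise ValueError("side must be 'C' or 'N'")


TRYPSIN = ProteaseRule(name="trypsin", side="C")
LYSARGINASE = ProteaseRule(name="lysarginase", side="N")

PROTEASES = {"trypsin": TRYPSIN, "lysarginase": LYSARGINASE}


@dataclass(frozen=True)
class DigestPeptide:
    """One digestion product with provenance in its parent protein."""

    sequence: str
    parent_id: str
    start: int  # 1-based inclusive position in parent
    end: int
    missed_cleavages: int
    preceding: str  # residue before the peptide, or '-' at the terminus
    following: str
    protease: str
    specificity: str = "full"  # full | semi_n | semi_c

    def __len__(self) -> int:
        return len(self.sequence)


def _check_alphabet(protein: str) -> None:
    bad = set(protein) - _CANONICAL
    if bad:
        raise AlphabetError(f"unknown residues in protein: {sorted(bad)!r}")


def cleavage_boundaries(protein: str, rule: ProteaseRule) -> list[int]:
    """Sorted 0-based cut points, always including 0 and len(protein).

    For side='C' a residue at index i contributes boundary i+1; for
    side='N' it contributes boundary i.  A protein-terminal K/R therefore
    contributes no extra cut (position 1 is a free N-terminus for
    lysargiNase; a C-terminal K/R needs no cut for trypsin).
    """
    n = len(protein)
    cuts = {0, n}
    for i, res in enumerate(protein):
        if res not in rule.cleave_residues:
            continue
        if rule.proline_exception:
            if rule.side == "C" and i + 1 < n and protein[i + 1] == "P":
                continue
            if rule.side == "N" and i - 1 >= 0 and protein[i - 1] == "P":
                continue
        cuts.add(i + 1 if rule.side == "C" else i)
    return sorted(cuts)


def _flank(protein: str, idx: int) -> str:
    return protein[idx] if 0 <= idx < len(protein) else TERMINUS


def _make_peptide(
    protein: str,
    parent_id: str,
    lo: int,
    hi: int,
    missed: int,
    rule: ProteaseRule,
    specificity: str,
) -> DigestPeptide:
    return DigestPeptide(
        sequence=protein[lo:hi],
        parent_id=parent_id,
        start=lo + 1,
        end=hi,
        missed_cleavages=missed,
        preceding=_flank(protein, lo - 1),
        following=_flank(protein, hi),
        protease=rule.name,
        specificity=specificity,
    )


def digest(
    protein: str,
    rule: ProteaseRule,
    max_missed: int = 2,
    min_len: int = 7,
    max_len: int | None = None,
    parent_id: str = "protein",
) -> list[DigestPeptide]:
    """All fully-specific peptides within the missed-cleavage and length limits.

    Peptides containing 'X' (ambiguous translation) are never emitted.
    """
    _check_alphabet(protein)
    if not protein:
        raise ValueError("protein is empty")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bounds = cleavage_boundaries(protein, rule)
    out: list[DigestPeptide] = []
    for bi, lo in enumerate(bounds[:-1]):
        for missed, hi in enumerate(bounds[bi + 1 : bi + 2 + max_missed]):
            length = hi - lo
            if length < min_len or (max_len is not None and length > max_len):
                continue
            if "X" in protein[lo:hi]:
                continue
            out.append(_make_peptide(protein, parent_id, lo, hi, missed, rule, "full"))
    return out


def semi_digest(
    protein: str,
    rule: ProteaseRule,
    max_missed: int = 3,
    min_len: int = 7,
    max_len: int | None = None,
    parent_id: str = "protein",
) -> list[DigestPeptide]:
    """Full digest plus peptides with exactly one non-specific terminus.

    A semi_n peptide has a non-specific N-terminus (its C-terminus lies on a
    cleavage boundary); semi_c is the converse.  Fully-specific windows keep
    specificity "full"; no (start, end) window is emitted twice.
    """
    _check_alphabet(protein)
    bounds = cleavage_boundaries(protein, rule)
    bound_set = set(bounds)
    n = len(protein)
    max_len_eff = n if max_len is None else max_len

    def internal(lo: int, hi: int) -> int:
        return sum(1 for b in bounds if lo < b < hi)

    out = digest(protein, rule, max_missed, min_len, max_len, parent_id)
    seen = {(p.start, p.end) for p in out}
    for lo in bounds[:-1]:
        # non-specific C-terminus, specific N-terminus
        for hi in range(lo + min_len, min(lo + max_len_eff, n) + 1):
            if hi in bound_set:
                continue
            if internal(lo, hi) > max_missed:
                break
            if "X" in protein[lo:hi] or (lo + 1, hi) in seen:
                continue
            seen.add((lo + 1, hi))
            out.append(
                _make_peptide(protein, parent_id, lo, hi, internal(lo, hi), rule, "semi_c")
            )
    for hi in bounds[1:]:
        for lo in range(hi - min_len, max(hi - max_len_eff, 0) - 1, -1):
            if lo in bound_set:
                continue
            if internal(lo, hi) > max_missed:
                break
            if "X" in protein[lo:hi] or (lo + 1, hi) in seen:
                continue
            seen.add((lo + 1, hi))
            out.append(
                _make_peptide(protein, parent_id, lo, hi, internal(lo, hi), rule, "semi_n")
            )
    return out


def digest_database(
    entries: Iterable, rule: ProteaseRule, **kwargs
) -> list[DigestPeptide]:
    """Digest every entry of a six-frame (or any) protein database.

    ``entries`` must expose ``orf_id`` and ``aa_sequence`` attributes.
    """
    out: list[DigestPeptide] = []
    for entry in entries:
        out.extend(digest(entry.aa_sequence, rule, parent_id=entry.orf_id, **kwargs))
    return out


def trim_c_terminal_kr(sequence: str) -> tuple[str, str]:
    """Split off the trailing K/R run: returns (core, trimmed_suffix)."""
    i = len(sequence)
    while i > 0 and sequence[i - 1] in "KR":
        i -= 1
    return sequence[:i], sequence[i:]


def trim_n_terminal_kr(sequence: str) -> tuple[str, str]:
    """Split off the leading K/R run: returns (core, trimmed_prefix)."""
    i = 0
    while i < len(sequence) and sequence[i] in "KR":
        i += 1
    return sequence[i:], sequence[:i]


def mirror_counterpart_exists(
    protein: str, pep_t: DigestPeptide, max_missed: int = 2, min_len: int = 1
) -> bool:
    """Does the lysargiNase digest contain a mirror counterpart of ``pep_t``?

    The tryptic peptide's core (C-terminal K/R run trimmed) must overlap a
    lysargiNase peptide's core (N-terminal K/R run trimmed) at the same
    parent positions.
    """
    core_t, suffix = trim_c_terminal_kr(pep_t.sequence)
    if not core_t:
        return False
    t_lo, t_hi = pep_t.start, pep_t.end - len(suffix)  # core span, 1-based
    for pep_l in digest(
        protein, LYSARGINASE, max_missed, min_len, parent_id=pep_t.parent_id
    ):
        core_l, prefix = trim_n_terminal_kr(pep_l.sequence)
        if not core_l:
            continue
        l_lo, l_hi = pep_l.start + len(prefix), pep_l.end
        if max(t_lo, l_lo) <= min(t_hi, l_hi):
            return True
    return False
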