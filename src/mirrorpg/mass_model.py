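"""Monoisotopic peptide and fragment mass computation with 15N support.

Masses are monoisotopic throughout.  The 15N metabolic-labeling mode models
full labeling: every nitrogen atom in the peptide (including nitrogens
introduced by modifications, e.g. carbamidomethyl) is shifted by the
15N-14N mass difference of 0.9970349 Da.  Only b and y fragment series are
modelled; a/c/z ions, neutral losses and isotope envelopes are not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

WATER = 18.0105646837
PROTON = 1.00727646677
DELTA_15N = 0.9970349

#: Monoisotopic residue masses (Da), standard amino-acid composition.
MONO_MASS: dict[str, float] = {
    "G": 57.02146372057, "A": 71.03711378471, "S": 87.03202840427,
    "P": 97.05276384885, "V": 99.06841391299, "T": 101.04767846841,
    "C": 103.00918478471, "L": 113.08406397713, "I": 113.08406397713,
    "N": 114.04292744114, "D": 115.02694302383, "Q": 128.05857750528,
    "K": 128.09496301400, "E": 129.04259308797, "M": 131.04048491299,
    "H": 137.05891185845, "F": 147.06841391299, "R": 156.10111102360,
    "Y": 163.06332853255, "W": 186.07931294986,
}

#: Nitrogen atoms per residue (backbone amide + side chain).
NITROGEN_COUNT: dict[str, int] = {
    **{aa: 1 for aa in MONO_MASS},
    "N": 2, "Q": 2, "K": 2, "W": 2, "H": 3, "R": 4,
}

ISOTOPE_MODES = ("14N", "15N")

#: Site key 0 denotes the peptide N-terminus in a modification assignment;
#: keys 1..n are residue positions.
N_TERM = 0


class ModificationError(ValueError):
    """Raised for inapplicable or conflicting modification assignments."""


@dataclass(frozen=True)
class ModificationSpec:
    """A named mass modification with its target sites.

    ``nitrogen_delta`` is the net change in nitrogen-atom count, used by the
    15N labeling mode (carbamidomethyl adds one N; pyroGlu from Q loses one).
    """

    name: str
    delta: float
    targets: frozenset[str] = frozenset()  # residue letters
    terminus: str | None = None  # None | "peptide_n" | "protein_n"
    mode: str = "fixed"  # fixed | variable
    nitrogen_delta: int = 0


# Unimod standard deltas.
CARBAMIDOMETHYL_C = ModificationSpec(
    "carbamidomethyl[C]", 57.021464, frozenset("C"), mode="fixed", nitrogen_delta=1
)
OXIDATION_M = ModificationSpec(
    "oxidation[M]", 15.994915, frozenset("M"), mode="variable"
)
ACETYL_PROTEIN_N = ModificationSpec(
    "acetyl[proteinN]", 42.010565, terminus="protein_n", mode="variable"
)
DIMETHYL_K = ModificationSpec("dimethyl[K]", 28.031300, frozenset("K"), mode="fixed")
DIMETHYL_N_TERM = ModificationSpec(
    "dimethyl[peptideN]", 28.031300, terminus="peptide_n", mode="variable"
)
PYROGLU_E = ModificationSpec(
    "pyroglu[E]", -18.010565, frozenset("E"), terminus="peptide_n", mode="variable"
)
PYROGLU_Q = ModificationSpec(
    "pyroglu[Q]", -17.026549, frozenset("Q"), terminus="peptide_n",
    mode="variable", nitrogen_delta=-1,
)

MODIFICATIONS: dict[str, ModificationSpec] = {
    m.name: m
    for m in (
        CARBAMIDOMETHYL_C, OXIDATION_M, ACETYL_PROTEIN_N,
        DIMETHYL_K, DIMETHYL_N_TERM, PYROGLU_E, PYROGLU_Q,
    )
}

ModAssignment = Mapping[int, ModificationSpec]


def apply_fixed_mods(
    sequence: str, specs: Sequence[ModificationSpec]
) -> dict[int, ModificationSpec]:
    """Deterministically assign fixed modifications to every matching site.

    Returns a site -> spec mapping (site 0 = peptide N-terminus).  Two fixed
    specs competing for one site is a configuration error.
    """
    assignment: dict[int, ModificationSpec] = {}
    for spec in specs:
        if spec.mode != "fixed":
            raise ModificationError(f"{spec.name} is not a fixed modification")
        sites: list[int] = []
        if spec.terminus in ("peptide_n", "protein_n"):
            sites.append(N_TERM)
        else:
            sites.extend(i + 1 for i, aa in enumerate(sequence) if aa in spec.targets)
        for site in sites:
            if site in assignment:
                raise ModificationError(
                    f"fixed modifications {assignment[site].name} and {spec.name} "
                    f"both target site {site}"
                )
            assignment[site] = spec
    return assignment


def _validate_mods(sequence: str, mods: ModAssignment) -> None:
    n = len(sequence)
    for site, spec in mods.items():
        if site == N_TERM:
            if spec.terminus is None and not (
                sequence[:1] and sequence[0] in spec.targets
            ):
                raise ModificationError(f"{spec.name} cannot sit on the N-terminus")
            continue
        if not (1 <= site <= n):
            raise ModificationError(f"modification site {site} outside peptide")
        if spec.targets and sequence[site - 1] not in spec.targets:
            raise ModificationError(
                f"{spec.name} does not apply to residue "
                f"{sequence[site - 1]!r} at position {site}"
            )


def peptide_nitrogens(sequence: str, mods: ModAssignment | None = None) -> int:
    """Total nitrogen atoms in the (modified) peptide."""
    n = sum(NITROGEN_COUNT[aa] for aa in sequence)
    if mods:
        n += sum(spec.nitrogen_delta for spec in mods.values())
    return n


def peptide_mass(
    sequence: str,
    mods: ModAssignment | None = None,
    isotope_mode: str = "14N",
) -> float:
    """Neutral monoisotopic mass of a peptide with its modifications."""
    _check(sequence, isotope_mode)
    if mods:
        _validate_mods(sequence, mods)
    mass = sum(MONO_MASS[aa] for aa in sequence) + WATER
    if mods:
        mass += sum(spec.delta for spec in mods.values())
    if isotope_mode == "15N":
        mass += DELTA_15N * peptide_nitrogens(sequence, mods)
    return mass


def precursor_mz(
    sequence: str,
    mods: ModAssignment | None = None,
    isotope_mode: str = "14N",
    charge: int = 2,
) -> float:
    return (peptide_mass(sequence, mods, isotope_mode) + charge * PROTON) / charge


@dataclass(frozen=True)
class FragmentIon:
    """A b or y backbone fragment at a given charge."""

    series: str  # "b" | "y"
    index: int  # 1..n-1
    charge: int
    mz: float
    nitrogen_count: int

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.series, self.index, self.charge)


def fragment_ions(
    sequence: str,
    mods: ModAssignment | None = None,
    isotope_mode: str = "14N",
    charges: Iterable[int] = (1,),
) -> list[FragmentIon]:
    """The full b and y series of a peptide at the requested charges.

    b_i covers residues 1..i plus any N-terminal modification; y_j covers
    residues n-j+1..n plus water.  In 15N mode each ion is shifted by
    DELTA_15N times the nitrogens it contains.
    """
    _check(sequence, isotope_mode)
    n = len(sequence)
    if n < 2:
        raise ValueError("fragmentation needs a peptide of length >= 2")
    mods = dict(mods or {})
    _validate_mods(sequence, mods)

    res_mass = [MONO_MASS[aa] for aa in sequence]
    res_nitro = [NITROGEN_COUNT[aa] for aa in sequence]
    for site, spec in mods.items():
        idx = 0 if site == N_TERM else site - 1
        res_mass[idx] += spec.delta
        res_nitro[idx] += spec.nitrogen_delta

    heavy = DELTA_15N if isotope_mode == "15N" else 0.0
    ions: list[FragmentIon] = []
    prefix_mass = 0.0
    prefix_n = 0
    total_mass = sum(res_mass)
    total_n = sum(res_nitro)
    for i in range(1, n):
        prefix_mass += res_mass[i - 1]
        prefix_n += res_nitro[i - 1]
        b_neutral = prefix_mass + heavy * prefix_n
        y_neutral = (total_mass - prefix_mass) + WATER + heavy * (total_n - prefix_n)
        for z in charges:
            ions.append(
                FragmentIon("b", i, z, (b_neutral + z * PROTON) / z, prefix_n)
            )
            ions.append(
                FragmentIon(
                    "y", n - i, z, (y_neutral + z * PROTON) / z, total_n - prefix_n
                )
            )
    return ions


def _check(sequence: str, isotope_mode: str) -> None:
    if isotope_mode not in ISOTOPE_MODES:
        raise ValueError(f"isotope_mode must be one of {ISOTOPE_MODES}")
    bad = set(sequence) - set(MONO_MASS)
    if bad:
        raise ValueError(f"non-canonical residues: {sorted(bad)!r}")
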