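"""Shared biological constants: genetic code, start/stop codons, aminopeptidase rule.

These constants are shared between the synthetic-data generator and the
reannotation logic so that start-codon inference operates under exactly the
same assumptions the simulator uses.
"""

from __future__ import annotations

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Canonical bacterial start codons considered by start-codon inference.
#: Non-canonical starts (e.g. GTC observed via direct N-terminal labeling)
#: are accepted only with dimethyl N-terminome evidence and flagged.
START_CODONS = frozenset({"ATG", "GTG", "TTG", "CTG"})

#: Start codons the synthetic generator actually plants (the common
#: bacterial set; CTG is rare and kept out of the generator on purpose).
GENERATOR_START_CODONS = ("ATG", "GTG", "TTG")

#: Residues after which the initiator residue is removed by aminopeptidase.
#: Methionine-aminopeptidase specificity (small penultimate residues),
#: generalized to non-Met initiators (V/L from GTG/TTG/CTG starts).
INITIATOR_REMOVAL_RESIDUES = frozenset("ASTGPVC")

_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

#: Standard genetic code, codon -> one-letter residue ('*' for stops).
CODON_TABLE: dict[str, str] = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

COMPLEMENT = str.maketrans("ACGTNRYKMSWBDHVacgtnrykmswbdhv",
                           "TGCANYRMKSWVHDBtgcanyrmkswvhdb")

#: IUPAC nucleotide codes accepted on genome input.
IUPAC_NT = frozenset("ACGTUNRYKMSWBDHV")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon; any codon containing a non-ACGT base yields 'X'."""
    aa = CODON_TABLE.get(codon)
    return aa if aa is not None else "X"
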