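"""Shared sequence primitives: codon table, translation, numeric encodings.

Numeric encodings (bases -> 0..3, amino acids -> indices into the BLOSUM62
alphabet) are used by the alignment kernels; string helpers are used
everywhere else.
"""
from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: BLOSUM62 alphabet (includes ambiguity codes B, Z, X and the stop symbol *)
BLOSUM62 = substitution_matrices.load("BLOSUM62")
AA_ALPHABET = str(BLOSUM62.alphabet)
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
STOP_AA = AA_INDEX["*"]
X_AA = AA_INDEX["X"]

#: BLOSUM62 as a plain float64 matrix indexed by AA_INDEX
BLOSUM62_MATRIX = np.array(BLOSUM62, dtype=np.float64)

STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a nucleotide string codon by codon (standard code).

    Trailing partial codons are ignored; stops appear as '*'.
    """
    n = len(cds) - len(cds) % 3
    return str(Seq(cds[:n]).translate())


def encode_dna(seq: str) -> np.ndarray:
    """Encode DNA as int8: A,C,G,T -> 0..3, anything else -> 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        arr[np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(base)] = idx
    return arr


def encode_protein(seq: str) -> np.ndarray:
    """Encode protein as int8 indices into the BLOSUM62 alphabet."""
    return np.array([AA_INDEX.get(a, X_AA) for a in seq.upper()], dtype=np.int8)


def _build_codon_aa_table() -> np.ndarray:
    """codon index (16*b0 + 4*b1 + b2) -> AA index; 64 entries."""
    table = np.zeros(64, dtype=np.int8)
    for i, b0 in enumerate(BASES):
        for j, b1 in enumerate(BASES):
            for k, b2 in enumerate(BASES):
                aa = translate(b0 + b1 + b2)
                table[16 * i + 4 * j + k] = AA_INDEX[aa]
    return table


#: maps codon index to AA index (stop codons -> STOP_AA)
CODON_AA_TABLE = _build_codon_aa_table()

#: the 61 sense codons as strings, sorted
SENSE_CODONS = sorted(
    b0 + b1 + b2
    for b0 in BASES
    for b1 in BASES
    for b2 in BASES
    if b0 + b1 + b2 not in STOP_CODONS
)

#: synonymous alternatives for every sense codon (may be empty)
SYNONYMOUS = {
    c: [d for d in SENSE_CODONS if d != c and translate(d) == translate(c)]
    for c in SENSE_CODONS
}


def _build_ord_blosum() -> list[list[float]]:
    table = [[-4.0] * 128 for _ in range(128)]
    for a in AA_ALPHABET:
        for b in AA_ALPHABET:
            table[ord(a)][ord(b)] = float(BLOSUM62[a, b])
    return table


#: BLOSUM62 indexed by ord(char) for fast inner loops; unknowns score -4
BLOSUM62_ORD = _build_ord_blosum()


def codon_index(codon: str) -> int:
    return 16 * BASE_INDEX[codon[0]] + 4 * BASE_INDEX[codon[1]] + BASE_INDEX[codon[2]]


def is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})
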