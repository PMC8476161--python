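"""Genetic code tables: the standard code and block-preserving random codes.

The standard genetic code (SGC) maps the 64 RNA codons to 20 amino acids
plus three stop signals (UAA, UAG, UGA).  Random genetic codes (RGCs) are
generated by the classic label-shuffle null: the partition of the 61 sense
codons into 20 synonymous codon sets ("blocks") and the positions of the
stop codons are kept fixed, and only the amino-acid labels of the 20 sets
are permuted.  The space of such codes has 20! ~ 2.4e18 members.

Conventions
-----------
* Codons are written in the RNA alphabet (A, C, G, U); DNA input with T is
  accepted and canonicalized.
* Codon indexing is lexicographic over (A, C, G, U); stop codons keep
  their indices and are masked downstream.
* Amino acids are keyed by one-letter code, ordered alphabetically
  (A, C, D, ..., Y); three-letter codes and full names are normalized on
  input.
* Codon sets are ordered by the one-letter code of the amino acid they
  carry in the SGC, so set ``a`` is "the SGC block of ``AMINO_ACIDS[a]``".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "U")
_NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}

#: One-letter amino acid codes in alphabetical order (internal ordering).
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

STOP_LABEL = "*"

#: All 64 codons in lexicographic order over (A, C, G, U).
CODONS: tuple[str, ...] = tuple(
    n1 + n2 + n3 for n1 in NUCLEOTIDES for n2 in NUCLEOTIDES for n3 in NUCLEOTIDES
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

SGC_STOP_CODONS: frozenset[str] = frozenset({"UAA", "UAG", "UGA"})

_THREE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_FULL_NAME = {
    "ALANINE": "A", "ARGININE": "R", "ASPARAGINE": "N", "ASPARTATE": "D",
    "ASPARTICACID": "D", "CYSTEINE": "C", "GLUTAMINE": "Q", "GLUTAMATE": "E",
    "GLUTAMICACID": "E", "GLYCINE": "G", "HISTIDINE": "H", "ISOLEUCINE": "I",
    "LEUCINE": "L", "LYSINE": "K", "METHIONINE": "M", "PHENYLALANINE": "F",
    "PROLINE": "P", "SERINE": "S", "THREONINE": "T", "TRYPTOPHAN": "W",
    "TYROSINE": "Y", "VALINE": "V",
}

# The standard genetic code, RNA alphabet.  Cross-checked in the test
# suite against Biopython's standard RNA codon table.
_SGC_MAPPING: dict[str, str] = {
    "UUU": "F", "UUC": "F", "UUA": "L", "UUG": "L",
    "CUU": "L", "CUC": "L", "CUA": "L", "CUG": "L",
    "AUU": "I", "AUC": "I", "AUA": "I", "AUG": "M",
    "GUU": "V", "GUC": "V", "GUA": "V", "GUG": "V",
    "UCU": "S", "UCC": "S", "UCA": "S", "UCG": "S",
    "CCU": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACU": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCU": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "UAU": "Y", "UAC": "Y", "UAA": "*", "UAG": "*",
    "CAU": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAU": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAU": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "UGU": "C", "UGC": "C", "UGA": "*", "UGG": "W",
    "CGU": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGU": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGU": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class CodeTableError(ValueError):
    """A genetic code table violates a structural invariant."""


def normalize_codon(codon: str) -> str:
    """Canonicalize a codon string to uppercase RNA (T -> U).

    Raises
    ------
    CodeTableError
        If the input is not exactly three A/C/G/U/T symbols.
    """
    c = codon.strip().upper().replace("T", "U")
    if len(c) != 3 or any(nt not in _NT_INDEX for nt in c):
        raise CodeTableError(f"invalid codon {codon!r}: expected 3 symbols from A/C/G/U/T")
    return c


def normalize_amino_acid(label: str) -> str:
    """Canonicalize an amino acid label to its one-letter code.

    Accepts one-letter codes, three-letter codes, full names, and
    'STOP'/'*' for the termination signal.
    """
    s = label.strip().upper().replace(" ", "").replace("-", "")
    if s in {"*", "STOP", "TER", "TERM"}:
        return STOP_LABEL
    if len(s) == 1 and s in AA_INDEX:
        return s
    if s in _THREE_LETTER:
        return _THREE_LETTER[s]
    if s in _FULL_NAME:
        return _FULL_NAME[s]
    raise CodeTableError(f"unrecognized amino acid label {label!r}")


def _sgc_partition() -> tuple[tuple[frozenset[str], ...], np.ndarray]:
    sets: list[frozenset[str]] = []
    for aa in AMINO_ACIDS:
        sets.append(frozenset(c for c, lab in _SGC_MAPPING.items() if lab == aa))
    set_of_codon = np.full(64, -1, dtype=np.int64)
    for a, block in enumerate(sets):
        for c in block:
            set_of_codon[CODON_INDEX[c]] = a
    return tuple(sets), set_of_codon


#: The 20 synonymous codon sets of the SGC, ordered by their SGC amino acid.
SGC_CODON_SETS: tuple[frozenset[str], ...]
#: For each codon index, the index of its synonymous set (-1 for stops).
SET_OF_CODON: np.ndarray
SGC_CODON_SETS, SET_OF_CODON = _sgc_partition()

SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in SGC_STOP_CODONS)


@dataclass(frozen=True)
class CodonSetPartition:
    """The fixed partition of the 61 sense codons into 20 synonym sets.

    ``labels[a]`` is the one-letter amino acid carried by set ``a`` under a
    particular code; the sets themselves are identical for the SGC and
    every RGC.
    """

    sets: tuple[frozenset[str], ...]
    labels: tuple[str, ...]

    def label_of(self, codon: str) -> str:
        a = SET_OF_CODON[CODON_INDEX[normalize_codon(codon)]]
        if a < 0:
            raise CodeTableError(f"{codon} is a stop codon; it belongs to no set")
        return self.labels[a]


@dataclass(frozen=True)
class CodeTable:
    """A total map from the 64 codons to 20 amino acids plus stop.

    Attributes
    ----------
    mapping : dict
        codon -> one-letter amino acid, or ``"*"`` for stops.
    provenance : str
        ``"SGC"`` or ``"RGC"``.
    permutation : tuple of int, optional
        For an RGC, ``permutation[a]`` is the amino-acid index (into
        :data:`AMINO_ACIDS`) assigned to SGC codon set ``a``.
    seed : int, optional
        Seed recorded for reproducibility of a sampled RGC.
    """

    mapping: Mapping[str, str]
    provenance: str = "SGC"
    permutation: tuple[int, ...] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        validate_code(self.mapping)

    def label(self, codon: str) -> str:
        return self.mapping[normalize_codon(codon)]

    @property
    def set_labels(self) -> np.ndarray:
        """Amino-acid index carried by each of the 20 codon sets."""
        out = np.empty(20, dtype=np.int64)
        for a, block in enumerate(SGC_CODON_SETS):
            out[a] = AA_INDEX[self.mapping[next(iter(block))]]
        return out

    def to_tsv(self, path: str | Path) -> None:
        lines = ["codon\tlabel"]
        for c in CODONS:
            lab = self.mapping[c]
            lines.append(f"{c}\t{'STOP' if lab == STOP_LABEL else lab}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str = "RGC") -> "CodeTable":
        mapping: dict[str, str] = {}
        lines = Path(path).read_text().splitlines()
        for ln in lines:
            if not ln.strip() or ln.startswith("codon"):
                continue
            codon, label = ln.split("\t")
            mapping[normalize_codon(codon)] = normalize_amino_acid(label)
        return cls(mapping=mapping, provenance=provenance)


def validate_code(mapping: Mapping[str, str]) -> None:
    """Check the structural invariants of a code table.

    Raises :class:`CodeTableError` naming the violated invariant: total on
    64 codons, stops exactly the SGC's three, blocks intact (every SGC
    synonym set carries one label), and labels a bijection onto the 20
    amino acids.
    """
    if set(mapping) != set(CODONS):
        raise CodeTableError("code table must map exactly the 64 codons")
    stops = {c for c, lab in mapping.items() if lab == STOP_LABEL}
    if stops != set(SGC_STOP_CODONS):
        raise CodeTableError(
            f"stop codons must be exactly UAA/UAG/UGA; found {sorted(stops)}"
        )
    labels = []
    for block in SGC_CODON_SETS:
        block_labels = {mapping[c] for c in block}
        if len(block_labels) != 1:
            raise CodeTableError(
                f"block structure broken: synonym set {sorted(block)} carries "
                f"labels {sorted(block_labels)}"
            )
        labels.append(next(iter(block_labels)))
    if sorted(labels) != sorted(AMINO_ACIDS):
        raise CodeTableError("set labels are not a bijection onto the 20 amino acids")


def build_sgc() -> CodeTable:
    """Return the standard genetic code table (deterministic, idempotent)."""
    return CodeTable(
        mapping=dict(_SGC_MAPPING),
        provenance="SGC",
        permutation=tuple(range(20)),
    )


def code_from_permutation(
    permutation: Sequence[int], provenance: str = "RGC", seed: int | None = None
) -> CodeTable:
    """Build the code that assigns amino acid ``permutation[a]`` to SGC set ``a``."""
    perm = tuple(int(p) for p in permutation)
    if sorted(perm) != list(range(20)):
        raise CodeTableError("permutation must be a bijection on 0..19")
    mapping = {c: STOP_LABEL for c in SGC_STOP_CODONS}
    for a, block in enumerate(SGC_CODON_SETS):
        aa = AMINO_ACIDS[perm[a]]
        for c in block:
            mapping[c] = aa
    return CodeTable(mapping=mapping, provenance=provenance, permutation=perm, seed=seed)


def sample_rgc(rng: np.random.Generator, seed: int | None = None) -> CodeTable:
    """Sample a random genetic code by permuting the 20 amino-acid labels.

    The stop codons stay at UAA/UAG/UGA and the synonymous block structure
    is preserved; only the assignment of amino acids to the 20 codon sets
    is shuffled, uniformly over the 20! possibilities.
    """
    perm = rng.permutation(20)
    return code_from_permutation(perm, provenance="RGC", seed=seed)


def codon_sets(code: CodeTable) -> CodonSetPartition:
    """Materialize the synonymous codon sets of a code with their labels.

    The sets are the SGC blocks for every valid code (the RGC sampler
    preserves them); only the labels differ between codes.
    """
    validate_code(code.mapping)
    labels = tuple(code.mapping[next(iter(block))] for block in SGC_CODON_SETS)
    return CodonSetPartition(sets=SGC_CODON_SETS, labels=labels)
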