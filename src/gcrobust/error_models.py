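"""Pairwise codon-change weight matrices for mismatch and frameshift errors.

Three error models feed the mean-squared-difference (MS) statistic:

* **uniform mismatch** (MS1): every pair of sense codons that differ at
  exactly one position gets weight 1; all codons are taken to be equally
  frequent.
* **mistranslation** (MS2): single-position changes are weighted by a
  relative per-position error rate ``E_p`` times a per-position
  transition/transversion rate ratio ``kappa_p`` (transversion rate
  normalized to 1 per change).  Transitions are A<->G and C<->U.
* **frameshift** (MS3): a +1 frameshift converts codon n1n2n3 followed by
  nucleotide n4 into codon n2n3n4.  Each (sense source, next nucleotide)
  event whose outcome is also sense contributes unit weight.  There are
  61*4 - 3*4 = 232 such events; -1 frameshifts induce the transposed
  matrix and therefore the same MS, so only +1 is exposed.

Frameshift events are further split into *mismatch-like* events — those
whose amino-acid change could also be produced by some single-nucleotide
mismatch between a codon of the source amino acid and a codon of the
outcome amino acid — and *mismatch-unlike* events (121 and 111 of the 232,
respectively).  The split depends only on the fixed block structure of the
sense codons, so it is identical for the SGC and every label-shuffled
random code.

Every matrix is stored over ordered codon pairs (64x64, lexicographic
indexing) with stop rows and columns identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .genetic_code import (
    CODONS,
    CODON_INDEX,
    NUCLEOTIDES,
    SET_OF_CODON,
    SGC_CODON_SETS,
    SGC_STOP_CODONS,
    CodonSetPartition,
    build_sgc,
    normalize_codon,
)

#: Unordered transition pairs; every other nucleotide change is a transversion.
TRANSITIONS = frozenset({frozenset({"A", "G"}), frozenset({"C", "U"})})

FrameshiftSubset = Literal["all", "mismatch-like", "mismatch-unlike"]

_STOP_IDX = np.array(sorted(CODON_INDEX[c] for c in SGC_STOP_CODONS))
_SENSE_MASK = np.ones(64, dtype=bool)
_SENSE_MASK[_STOP_IDX] = False


class ErrorModelError(ValueError):
    pass


@dataclass(frozen=True)
class MistranslationParams:
    """Relative per-codon-position mistranslation parameters.

    ``E = (E1, E2, E3)`` are relative error frequencies at codon positions
    1-3 (dimensionless; conventionally E2 = 1), and
    ``kappa = (k1, k2, k3)`` are per-change transition/transversion rate
    ratios at each position (a transversion has rate 1).  All entries must
    be strictly positive.  The defaults are an explicit all-ones
    placeholder under which the mistranslation model reduces to the
    uniform mismatch model; empirically estimated values are loaded from a
    config file.
    """

    E: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kappa: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        for name, vals in (("E", self.E), ("kappa", self.kappa)):
            if len(vals) != 3 or any(not np.isfinite(v) or v <= 0 for v in vals):
                raise ErrorModelError(
                    f"{name} must be three strictly positive finite numbers, got {vals}"
                )

    @classmethod
    def from_file(cls, path: str | Path) -> "MistranslationParams":
        """Read a flat ``key = value`` file with keys E1..E3, kappa1..kappa3."""
        values: dict[str, float] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.replace("=", " = ").partition("=")
            values[key.strip().lower()] = float(val.strip())
        try:
            return cls(
                E=(values["e1"], values["e2"], values["e3"]),
                kappa=(values["kappa1"], values["kappa2"], values["kappa3"]),
            )
        except KeyError as exc:
            raise ErrorModelError(f"missing mistranslation parameter {exc} in {path}")


@dataclass(frozen=True)
class PairWeightMatrix:
    """Nonnegative weights over ordered sense-codon pairs for one error model."""

    matrix: np.ndarray  # (64, 64), lexicographic codon indexing
    model: str

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (64, 64):
            raise ErrorModelError(f"weight matrix must be 64x64, got {m.shape}")
        if np.any(m < 0):
            raise ErrorModelError("weights must be nonnegative")
        if m[_STOP_IDX, :].any() or m[:, _STOP_IDX].any():
            raise ErrorModelError("stop codon rows/columns must be zero")

    @property
    def total(self) -> float:
        return float(self.matrix.sum())

    def weight(self, codon_i: str, codon_j: str) -> float:
        return float(
            self.matrix[
                CODON_INDEX[normalize_codon(codon_i)],
                CODON_INDEX[normalize_codon(codon_j)],
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write nonzero entries as three columns: codon_i, codon_j, weight."""
        lines = ["codon_i\tcodon_j\tweight"]
        ii, jj = np.nonzero(self.matrix)
        for i, j in zip(ii, jj):
            lines.append(f"{CODONS[i]}\t{CODONS[j]}\t{self.matrix[i, j]:.12g}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class FrameshiftEvent:
    """One +1 frameshift: sense codon + incoming nucleotide -> sense codon."""

    source: str
    next_nt: str
    outcome: str
    source_aa: str
    outcome_aa: str
    label: str | None = None  # "mismatch-like" | "mismatch-unlike"


def _mismatch_position(i: int, j: int) -> int | None:
    """Position (0-2) at which codons i and j differ, if exactly one."""
    a, b = CODONS[i], CODONS[j]
    diff = [p for p in range(3) if a[p] != b[p]]
    return diff[0] if len(diff) == 1 else None


def uniform_mismatch_weights() -> PairWeightMatrix:
    """Weight 1 for every ordered sense-codon pair one mismatch apart."""
    w = np.zeros((64, 64))
    for i in range(64):
        if not _SENSE_MASK[i]:
            continue
        for j in range(64):
            if i == j or not _SENSE_MASK[j]:
                continue
            if _mismatch_position(i, j) is not None:
                w[i, j] = 1.0
    return PairWeightMatrix(matrix=w, model="uniform-mismatch")


def mistranslation_weights(params: MistranslationParams) -> PairWeightMatrix:
    """Position- and change-type-weighted mismatch matrix.

    A single change at codon position ``p`` gets weight ``E_p * kappa_p``
    if it is a transition (A<->G, C<->U) and ``E_p`` if a transversion;
    everything else (multi-position changes, stop pairs) is zero.  The
    matrix is symmetric because each parameter is a rate ratio of the
    unordered change.
    """
    w = np.zeros((64, 64))
    for i in range(64):
        if not _SENSE_MASK[i]:
            continue
        for j in range(64):
            if i == j or not _SENSE_MASK[j]:
                continue
            p = _mismatch_position(i, j)
            if p is None:
                continue
            pair = frozenset({CODONS[i][p], CODONS[j][p]})
            rate = params.kappa[p] if pair in TRANSITIONS else 1.0
            w[i, j] = params.E[p] * rate
    return PairWeightMatrix(matrix=w, model="mistranslation")


def enumerate_frameshift_events() -> list[FrameshiftEvent]:
    """All +1 frameshift events between sense codons.

    A +1 shift of codon n1n2n3 followed by n4 yields n2n3n4.  Events whose
    source or outcome is a stop codon are excluded, leaving
    61*4 - 3*4 = 232 events (each of the 12 excluded ones has an outcome
    of the form n2n3n4 equal to a stop).  Amino acids recorded on the
    event are the SGC's; the classification below does not use them.
    """
    sgc = build_sgc()
    events = []
    for source in CODONS:
        if source in SGC_STOP_CODONS:
            continue
        for nt in NUCLEOTIDES:
            outcome = source[1:] + nt
            if outcome in SGC_STOP_CODONS:
                continue
            events.append(
                FrameshiftEvent(
                    source=source,
                    next_nt=nt,
                    outcome=outcome,
                    source_aa=sgc.label(source),
                    outcome_aa=sgc.label(outcome),
                )
            )
    return events


def _set_mismatch_adjacency() -> np.ndarray:
    """adj[a, b]: some codon of set a and some codon of set b differ at one position."""
    adj = np.zeros((20, 20), dtype=bool)
    w = uniform_mismatch_weights().matrix
    ii, jj = np.nonzero(w)
    for i, j in zip(ii, jj):
        adj[SET_OF_CODON[i], SET_OF_CODON[j]] = True
    return adj


_SET_ADJ = _set_mismatch_adjacency()


def classify_frameshift_events(
    events: Iterable[FrameshiftEvent],
    partition: CodonSetPartition | None = None,
) -> list[FrameshiftEvent]:
    """Label each frameshift event mismatch-like or mismatch-unlike.

    An event is *mismatch-like* iff some codon of the source amino acid's
    synonym set and some codon of the outcome amino acid's synonym set
    differ at exactly one position — i.e. the amino-acid change the
    frameshift causes is also achievable by a single mismatch.  Events
    that leave the amino acid unchanged are tested the same way (the set
    must contain a one-mismatch pair).  Because the synonym sets are fixed
    across all label-shuffled codes, the labels are code-invariant; the
    ``partition`` argument only selects which code's sets to read (they
    are always the SGC blocks).
    """
    out = []
    for ev in events:
        a = SET_OF_CODON[CODON_INDEX[ev.source]]
        b = SET_OF_CODON[CODON_INDEX[ev.outcome]]
        label = "mismatch-like" if _SET_ADJ[a, b] else "mismatch-unlike"
        out.append(replace(ev, label=label))
    return out


def frameshift_weights(subset: FrameshiftSubset = "all") -> PairWeightMatrix:
    """Event-count matrix for +1 frameshifts, optionally restricted by class.

    ``w[i, j]`` is the number of events (0 or 1, since the next nucleotide
    determines the outcome uniquely) in the chosen subset that convert
    codon i into codon j.  Totals: 232 (all), 121 (mismatch-like),
    111 (mismatch-unlike).
    """
    if subset not in ("all", "mismatch-like", "mismatch-unlike"):
        raise ErrorModelError(
            f"unknown frameshift subset {subset!r}; "
            "expected all | mismatch-like | mismatch-unlike"
        )
    w = np.zeros((64, 64))
    for ev in classify_frameshift_events(enumerate_frameshift_events()):
        if subset != "all" and ev.label != subset:
            continue
        w[CODON_INDEX[ev.source], CODON_INDEX[ev.outcome]] += 1.0
    return PairWeightMatrix(matrix=w, model=f"frameshift:{subset}")


def aggregate_weights_to_sets(
    w: PairWeightMatrix, partition: CodonSetPartition | None = None
) -> np.ndarray:
    """Collapse a 64x64 codon-pair matrix onto the 20 fixed synonym sets.

    ``W[a, b]`` sums the weight of all ordered codon pairs (i in set a,
    j in set b).  Total weight is conserved, and the MS statistic becomes
    a quadratic form in the 20 per-set property values (the diagonal
    carries synonymous weight, which contributes zero to MS).
    """
    W = np.zeros((20, 20))
    m = w.matrix
    ii, jj = np.nonzero(m)
    for i, j in zip(ii, jj):
        W[SET_OF_CODON[i], SET_OF_CODON[j]] += m[i, j]
    return W
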