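"""Loading, validating, and serializing amino acid property tables.

A *property* is a named vector of 20 numeric values, one per amino acid —
for example the polar requirement, a hydropathy index, or an AAindex
entry.  Properties with any missing value are dropped at load time (the
MS statistic needs a value for every amino acid).

Two on-disk formats are supported:

* the package's canonical TSV dialect: UTF-8, tab-separated, header
  ``property_id`` followed by the 20 one-letter codes in the AAindex
  amino-acid order (A R N D C Q E G H I L K M F P S T W Y V), one row per
  property;
* AAindex flat files (``H`` accession lines, ``I`` header followed by two
  lines of ten values in the canonical A/L R/K ... order; ``NA`` cells
  mark missing values).

Internally values are stored as a (n_properties, 20) array with columns
in alphabetical one-letter order (A, C, D, ..., Y).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import AA_INDEX, AMINO_ACIDS

logger = logging.getLogger(__name__)

#: Column order of the TSV dialect (the AAindex amino-acid order).
AAINDEX_ORDER: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")


class PropertyTableError(ValueError):
    pass


@dataclass
class PropertyTable:
    """An ordered collection of named amino acid properties.

    Attributes
    ----------
    ids : list of str
        Unique property identifiers (e.g. AAindex accessions), in input
        order.
    values : ndarray, shape (n_properties, 20)
        Property values with columns ordered alphabetically by one-letter
        amino acid code.
    provenance : str
        ``"real"``, ``"fake-uniform"`` or ``"fake-normal"``.
    skipped : list of (str, str)
        (identifier, reason) for properties dropped at load time.
    """

    ids: list[str]
    values: np.ndarray
    provenance: str = "real"
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.ids), 20):
            raise PropertyTableError(
                f"values must have shape ({len(self.ids)}, 20), got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            bad = self.ids[int(np.where(~np.isfinite(self.values))[0][0])]
            raise PropertyTableError(f"property {bad!r} has a non-finite value")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise PropertyTableError(f"duplicate property ids: {dupes}")

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, property_id: str) -> dict[str, float]:
        try:
            row = self.values[self.ids.index(property_id)]
        except ValueError:
            raise KeyError(property_id) from None
        return dict(zip(AMINO_ACIDS, row.tolist()))

    def vector(self, property_id: str) -> np.ndarray:
        """Values of one property in alphabetical amino-acid order."""
        return self.values[self.ids.index(property_id)].copy()

    def subset(self, ids: Sequence[str]) -> "PropertyTable":
        idx = [self.ids.index(i) for i in ids]
        return PropertyTable(
            ids=list(ids), values=self.values[idx].copy(), provenance=self.provenance
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=list(AMINO_ACIDS))

    def to_tsv(self, path: str | Path) -> None:
        """Write the canonical TSV dialect (AAindex column order)."""
        order = [AA_INDEX[aa] for aa in AAINDEX_ORDER]
        df = pd.DataFrame(
            self.values[:, order], columns=list(AAINDEX_ORDER), index=self.ids
        )
        df.to_csv(path, sep="\t", index_label="property_id", float_format="%.10g")


def _from_records(
    records: Iterable[tuple[str, Mapping[str, float | None]]], provenance: str
) -> PropertyTable:
    ids: list[str] = []
    rows: list[np.ndarray] = []
    skipped: list[tuple[str, str]] = []
    seen: set[str] = set()
    for pid, mapping in records:
        if pid in seen:
            raise PropertyTableError(f"duplicate property id {pid!r}")
        seen.add(pid)
        missing = [aa for aa in AMINO_ACIDS if mapping.get(aa) is None]
        if missing:
            reason = f"missing value for {', '.join(missing)}"
            logger.warning("skipping property %s: %s", pid, reason)
            skipped.append((pid, reason))
            continue
        rows.append(np.array([mapping[aa] for aa in AMINO_ACIDS], dtype=float))
        ids.append(pid)
    values = np.vstack(rows) if rows else np.empty((0, 20))
    table = PropertyTable(ids=ids, values=values, provenance=provenance)
    table.skipped = skipped
    logger.info(
        "loaded %d properties (%d skipped for missing values)", len(ids), len(skipped)
    )
    return table


def _parse_cell(pid: str, aa: str, cell: str) -> float | None:
    s = cell.strip()
    if s in {"", "NA", "NaN", "nan", "N/A", "-"}:
        return None
    try:
        return float(s)
    except ValueError:
        raise PropertyTableError(
            f"non-numeric value {cell!r} for amino acid {aa} in property {pid!r}"
        ) from None


def read_property_tsv(path: str | Path, provenance: str = "real") -> PropertyTable:
    """Read the canonical property TSV (header names the amino acid columns)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise PropertyTableError(f"{path}: empty property file")
    header = lines[0].rstrip("\n").split("\t")
    if header[0] != "property_id":
        raise PropertyTableError(f"{path}: first column must be 'property_id'")
    aa_cols = header[1:]
    unknown = [c for c in aa_cols if c not in AA_INDEX]
    if unknown:
        raise PropertyTableError(f"{path}: unknown amino acid column(s) {unknown}")
    if len(set(aa_cols)) != 20:
        raise PropertyTableError(f"{path}: header must name all 20 amino acids once")

    def records():
        for ln in lines[1:]:
            if not ln.strip():
                continue
            cells = ln.split("\t")
            if len(cells) != 21:
                raise PropertyTableError(
                    f"{path}: row {cells[0]!r} has {len(cells) - 1} values, expected 20"
                )
            pid = cells[0].strip()
            yield pid, {
                aa: _parse_cell(pid, aa, cell) for aa, cell in zip(aa_cols, cells[1:])
            }

    return _from_records(records(), provenance)


def read_aaindex(path: str | Path, provenance: str = "real") -> PropertyTable:
    """Read an AAindex flat file (H/I record blocks; NA entries drop the property)."""
    text = Path(path).read_text(encoding="utf-8")

    def records():
        accession: str | None = None
        for block in text.split("//"):
            accession = None
            lines = block.splitlines()
            for k, ln in enumerate(lines):
                if ln.startswith("H "):
                    accession = ln[2:].strip()
                if ln.startswith("I "):
                    if accession is None:
                        raise PropertyTableError("AAindex I record without H accession")
                    if k + 2 >= len(lines):
                        raise PropertyTableError(
                            f"AAindex entry {accession}: truncated value lines"
                        )
                    cells = lines[k + 1].split() + lines[k + 2].split()
                    if len(cells) != 20:
                        raise PropertyTableError(
                            f"AAindex entry {accession}: expected 20 values, "
                            f"got {len(cells)}"
                        )
                    yield accession, {
                        aa: _parse_cell(accession, aa, cell)
                        for aa, cell in zip(AAINDEX_ORDER, cells)
                    }
                    break

    return _from_records(records(), provenance)


def load_property_table(source: str | Path, provenance: str = "real") -> PropertyTable:
    """Load a property table, sniffing TSV vs AAindex flat-file format."""
    path = Path(source)
    head = path.read_text(encoding="utf-8", errors="replace")[:2048]
    if head.startswith("H ") or "\nI " in head:
        return read_aaindex(path, provenance)
    return read_property_tsv(path, provenance)
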