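"""Fake amino acid property generation.

Fake properties are i.i.d. draws of 20 values per property — uniform on
(-1, 1) or standard normal — and serve as a null control: a genetic code
should show no significant robustness in a property whose values carry no
structure, while intrinsic correlations between mismatch- and
frameshift-robustness (which come from the code's degeneracy, not from
the property) should persist.

Fake tables use the same :class:`~gcrobust.properties_io.PropertyTable`
container and TSV dialect as real ones, so they are interchangeable
throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .properties_io import PropertyTable

Distribution = Literal["uniform", "normal"]


@dataclass(frozen=True)
class FakePropertySpec:
    """How many fake properties to draw, from which distribution, with what seed."""

    count: int = 564
    distribution: Distribution = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if self.distribution not in ("uniform", "normal"):
            raise ValueError(
                f"distribution must be 'uniform' or 'normal', got {self.distribution!r}"
            )


def generate_fake_properties(spec: FakePropertySpec) -> PropertyTable:
    """Draw ``spec.count`` fake properties of 20 i.i.d. values each.

    Deterministic given the seed; ids are FAKE0001, FAKE0002, ...
    """
    rng = np.random.default_rng(spec.seed)
    if spec.distribution == "uniform":
        values = rng.uniform(-1.0, 1.0, size=(spec.count, 20))
    else:
        values = rng.standard_normal(size=(spec.count, 20))
    ids = [f"FAKE{k + 1:04d}" for k in range(spec.count)]
    return PropertyTable(ids=ids, values=values, provenance=f"fake-{spec.distribution}")
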