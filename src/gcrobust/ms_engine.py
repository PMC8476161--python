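"""The mean-squared-difference (MS) statistic and its ensemble computation.

For an amino acid property P and a genetic code, the MS under an error
model with codon-pair weights ``w_ij`` is

    MS = sum_ij w_ij (P_i - P_j)^2 / sum_ij w_ij

where the sums run over sense codons and ``P_i`` is the property value of
the amino acid codon *i* encodes.  Lower MS means the code is more robust
to that error type.  The named metrics are MS1 (uniform mismatch), MS2
(mistranslation-weighted mismatch), MS3 (+1 frameshift), and the
restricted variants MS3-like / MS3-unlike (mismatch-like / -unlike
frameshift events only).

Because every admissible code carries the same synonymous block
structure, MS reduces exactly to a quadratic form over the 20 codon sets:
with ``W_ab`` the aggregated set-pair weight and ``x_a`` the property
value of the amino acid labelling set ``a``,

    MS = sum_ab W_ab (x_a - x_b)^2 / sum_ab W_ab.

Ensembles of random codes are evaluated in blocks through this 20x20
form; for a block of codes the per-code set weights are gathered with the
inverse label permutation and all properties are handled in one matrix
product, which makes one million codes by hundreds of properties
tractable on a single CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .error_models import (
    MistranslationParams,
    PairWeightMatrix,
    aggregate_weights_to_sets,
    frameshift_weights,
    mistranslation_weights,
    uniform_mismatch_weights,
)
from .genetic_code import AA_INDEX, CODONS, STOP_LABEL, CodeTable
from .properties_io import PropertyTable

#: Metrics the engine knows how to compute.
KNOWN_METRICS: tuple[str, ...] = ("MS1", "MS2", "MS3", "MS3-like", "MS3-unlike")

DEFAULT_BLOCK_SIZE = 1 << 16


class MSComputationError(ValueError):
    pass


def metric_weights(
    metric: str, params: MistranslationParams | None = None
) -> PairWeightMatrix:
    """The codon-pair weight matrix behind a named metric."""
    if metric == "MS1":
        return uniform_mismatch_weights()
    if metric == "MS2":
        return mistranslation_weights(params or MistranslationParams())
    if metric == "MS3":
        return frameshift_weights("all")
    if metric == "MS3-like":
        return frameshift_weights("mismatch-like")
    if metric == "MS3-unlike":
        return frameshift_weights("mismatch-unlike")
    raise MSComputationError(
        f"unknown metric {metric!r}; expected one of {KNOWN_METRICS}"
    )


def compute_ms(
    property_values: Mapping[str, float] | np.ndarray,
    code: CodeTable,
    weights: PairWeightMatrix,
) -> float:
    """MS of one property under one code and one weight model.

    ``property_values`` is either a mapping from one-letter amino acid
    codes to values or a length-20 vector in alphabetical order.  This is
    the reference implementation: a direct double sum over all ordered
    codon pairs (stop codons carry zero weight by construction).
    """
    if isinstance(property_values, Mapping):
        vec = np.array([property_values[aa] for aa in sorted(AA_INDEX)], dtype=float)
    else:
        vec = np.asarray(property_values, dtype=float)
        if vec.shape != (20,):
            raise MSComputationError(f"expected 20 property values, got {vec.shape}")
    total = weights.matrix.sum()
    if total <= 0:
        raise MSComputationError("weight matrix sums to zero; MS is undefined")
    p = np.zeros(64)
    for k, codon in enumerate(CODONS):
        label = code.mapping[codon]
        if label != STOP_LABEL:
            p[k] = vec[AA_INDEX[label]]
    diff = p[:, None] - p[None, :]
    return float((weights.matrix * diff**2).sum() / total)


@dataclass
class MSEnsemble:
    """MS values for an ensemble of random codes plus the standard code.

    ``values[metric]`` has shape (n_codes + 1, n_properties); row 0 is the
    SGC and rows 1..n are the sampled random codes, in draw order.
    """

    values: dict[str, np.ndarray]
    property_ids: list[str]
    n_codes: int
    seed: int
    params_digest: str = ""

    def __post_init__(self) -> None:
        for metric, arr in self.values.items():
            if arr.shape != (self.n_codes + 1, len(self.property_ids)):
                raise MSComputationError(
                    f"{metric}: expected shape {(self.n_codes + 1, len(self.property_ids))}, "
                    f"got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise MSComputationError(f"{metric}: MS values must be finite and >= 0")

    @property
    def metrics(self) -> tuple[str, ...]:
        return tuple(self.values)

    def sgc(self, metric: str, property_id: str | None = None):
        """SGC row for a metric, or a single SGC value if a property is named."""
        row = self.values[metric][0]
        if property_id is None:
            return row
        return float(row[self.property_ids.index(property_id)])

    def rgc(self, metric: str, property_id: str | None = None) -> np.ndarray:
        """Random-code rows for a metric (or one property's column)."""
        block = self.values[metric][1:]
        if property_id is None:
            return block
        return block[:, self.property_ids.index(property_id)]

    def save(self, directory: str | Path) -> None:
        """Persist as one TSV per metric plus a JSON metadata file."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for metric, arr in self.values.items():
            df = pd.DataFrame(arr, columns=self.property_ids)
            df.insert(0, "code", ["SGC"] + [f"RGC{k}" for k in range(1, self.n_codes + 1)])
            df.to_csv(directory / f"{metric}.tsv", sep="\t", index=False)
        meta = {
            "n_codes": self.n_codes,
            "seed": self.seed,
            "metrics": list(self.values),
            "n_properties": len(self.property_ids),
            "params_digest": self.params_digest,
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "MSEnsemble":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        values: dict[str, np.ndarray] = {}
        property_ids: list[str] | None = None
        for metric in meta["metrics"]:
            df = pd.read_csv(directory / f"{metric}.tsv", sep="\t")
            property_ids = list(df.columns[1:])
            values[metric] = df.iloc[:, 1:].to_numpy(dtype=float)
        assert property_ids is not None
        return cls(
            values=values,
            property_ids=property_ids,
            n_codes=meta["n_codes"],
            seed=meta["seed"],
            params_digest=meta.get("params_digest", ""),
        )


def sample_permutations(rng: np.random.Generator, n: int) -> np.ndarray:
    """n independent uniform permutations of 0..19, one per row."""
    base = np.tile(np.arange(20, dtype=np.int64), (n, 1))
    return rng.permuted(base, axis=1)


def _squared_difference_matrix(values: np.ndarray) -> np.ndarray:
    """(400, n_properties) flattened (P_x - P_y)^2 over amino-acid pairs."""
    diff = values[:, :, None] - values[:, None, :]  # (P, 20, 20)
    return (diff**2).reshape(values.shape[0], 400).T.copy()


def compute_ms_ensemble(
    properties: PropertyTable,
    n_codes: int,
    seed: int,
    metrics: Sequence[str] = ("MS1", "MS2", "MS3"),
    params: MistranslationParams | None = None,
    block_size: int = DEFAULT_BLOCK_SIZE,
    permutations: np.ndarray | None = None,
) -> MSEnsemble:
    """MS of every (code, property, metric) triple for a random-code ensemble.

    Codes are drawn with replacement from the 20! label permutations
    (duplicates are vanishingly rare and allowed); row 0 of the result is
    always the SGC (identity permutation).  Computation proceeds in
    blocks of ``block_size`` codes with a fixed accumulation order, so the
    result is reproducible bit-for-bit given (seed, block size).

    ``permutations`` injects an explicit (n_codes, 20) permutation array
    instead of sampling — used for oracles and exact reproductions.
    """
    if n_codes < 1:
        raise MSComputationError("n_codes must be >= 1")
    unknown = [m for m in metrics if m not in KNOWN_METRICS]
    if unknown:
        raise MSComputationError(f"unknown metrics {unknown}; expected {KNOWN_METRICS}")
    params = params or MistranslationParams()

    set_weights: dict[str, np.ndarray] = {}
    totals: dict[str, float] = {}
    for metric in metrics:
        W = aggregate_weights_to_sets(metric_weights(metric, params))
        set_weights[metric] = W
        totals[metric] = float(W.sum())

    D = _squared_difference_matrix(properties.values)  # (400, P)
    n_props = len(properties)
    out = {m: np.empty((n_codes + 1, n_props)) for m in metrics}

    rng = np.random.default_rng(seed)
    identity = np.arange(20, dtype=np.int64)[None, :]
    done = 0
    while done < n_codes + 1:
        size = min(block_size, n_codes + 1 - done)
        if done == 0:
            if permutations is None:
                perms = np.vstack([identity, sample_permutations(rng, size - 1)])
            else:
                perms = np.vstack([identity, permutations[: size - 1]])
        else:
            if permutations is None:
                perms = sample_permutations(rng, size)
            else:
                perms = permutations[done - 1 : done - 1 + size]
        inv = np.argsort(perms, axis=1)  # inverse permutations
        for metric in metrics:
            W = set_weights[metric]
            gathered = W[inv[:, :, None], inv[:, None, :]].reshape(size, 400)
            out[metric][done : done + size] = gathered @ D / totals[metric]
        done += size

    digest = f"E={params.E},kappa={params.kappa}" if "MS2" in metrics else ""
    return MSEnsemble(
        values=out,
        property_ids=list(properties.ids),
        n_codes=n_codes,
        seed=seed,
        params_digest=digest,
    )
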