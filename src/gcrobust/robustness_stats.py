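"""Inference on MS ensembles: empirical P values, FDR, and control tests.

The core question is whether the standard genetic code (SGC) is unusually
robust to an error type for a given amino acid property, and — when it is
robust to frameshifts — whether that is explainable as a byproduct of its
mismatch-robustness.  All inference is nonparametric against the
random-code ensemble:

* **empirical P** — the fraction of random codes with MS strictly lower
  than the focal code's; significance across properties is controlled
  with Benjamini–Hochberg FDR.
* **per-code significance counts** — for every code in the ensemble, the
  number of properties (N1/N2/N3 for MS1/MS2/MS3) in which it is
  significantly robust relative to the rest of the ensemble.
* **band control** — among random codes whose mismatch count (N1 or N2)
  is within a band (default 80–120%) of the SGC's, the fraction whose
  frameshift count N3 exceeds the SGC's.
* **MS-matched control** — among random codes whose mismatch MS is equal
  to or smaller than the SGC's, the fraction whose frameshift MS is
  strictly smaller than the SGC's.  The joint variant intersects several
  such constraints (used to control cross-talk between correlated
  properties).
* **correlation profile** — per-property Pearson correlation between
  mismatch and frameshift MS across the ensemble, plus the full
  cross-property correlation matrix for cross-talk screening.

Conventions: "lower" is strict (<) everywhere except the MS-matched
control-set membership, which is inclusive (<=); a focal code is excluded
from its own comparison set (denominator N-1); empirical P = 0 is kept as
0 (no pseudocount) and the 1/N resolution limit is recorded in run
metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ms_engine import MSEnsemble

logger = logging.getLogger(__name__)


class RobustnessStatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# empirical P and FDR


def empirical_p(sgc_ms: float, ensemble_ms: np.ndarray) -> float:
    """Fraction of ensemble codes with MS strictly below the focal value.

    The focal code is not part of ``ensemble_ms`` (pass the RGC column
    only); possible values are 0, 1/N, ..., 1 for an ensemble of size N.
    """
    col = np.asarray(ensemble_ms, dtype=float)
    if col.size == 0:
        raise RobustnessStatsError("empty ensemble: empirical P undefined")
    return float(np.count_nonzero(col < sgc_ms) / col.size)


def bh_significant(
    p_values: Sequence[float] | np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (monotone adjusted P values, flags).

    A property is flagged when its adjusted P is <= ``alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise RobustnessStatsError("P values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise RobustnessStatsError(f"alpha must be in (0, 1), got {alpha}")
    flags, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, flags


def _empirical_p_matrix(values: np.ndarray) -> np.ndarray:
    """Per-column leave-self-out empirical P for every row of ``values``.

    ``values`` is (n_codes, n_properties); entry (i, p) is the fraction of
    the other codes with a strictly smaller value in column p.  One sort
    per column; ties are handled by counting strict inequalities only
    (a code never counts against itself since it is not < itself).
    """
    m, n_props = values.shape
    if m < 2:
        raise RobustnessStatsError("need at least 2 codes for per-code P values")
    out = np.empty_like(values, dtype=float)
    for p in range(n_props):
        col = values[:, p]
        order = np.sort(col)
        out[:, p] = np.searchsorted(order, col, side="left") / (m - 1)
    return out


def _bh_flag_counts(p_matrix: np.ndarray, alpha: float) -> np.ndarray:
    """Row-wise BH: number of flagged properties per row (vectorized).

    Equivalent to running :func:`bh_significant` on each row; the adjusted
    values along the sorted axis are nondecreasing after the running
    minimum from the right, so the flag count is a single comparison.
    """
    m = p_matrix.shape[1]
    order = np.sort(p_matrix, axis=1)
    adj = order * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[:, ::-1], axis=1)[:, ::-1]
    return np.count_nonzero(adj <= alpha, axis=1)


def per_code_significance_counts(
    ensemble: MSEnsemble,
    alpha: float = 0.05,
    metrics: Sequence[str] | None = None,
) -> pd.DataFrame:
    """N counts (significantly robust properties) for every code.

    For each code (SGC row included) and metric, the empirical P of each
    property is taken against the *other* codes, BH-corrected across
    properties, and the flagged properties counted.  Returns a DataFrame
    with one row per code (index 0 = SGC) and one column per metric.
    """
    metrics = list(metrics or ensemble.metrics)
    counts = {}
    for metric in metrics:
        p_matrix = _empirical_p_matrix(ensemble.values[metric])
        counts[metric] = _bh_flag_counts(p_matrix, alpha)
    df = pd.DataFrame(counts)
    df.index.name = "code"
    return df


# ---------------------------------------------------------------------------
# control tests


@dataclass(frozen=True)
class ControlResult:
    """Outcome of a control test.

    ``fraction`` is None when the control set is empty — an explicitly
    reportable outcome, distinct from an observed 0.
    """

    control_size: int
    n_beyond: int

    @property
    def fraction(self) -> float | None:
        if self.control_size == 0:
            return None
        return self.n_beyond / self.control_size

    @property
    def empty(self) -> bool:
        return self.control_size == 0


def band_control_test(
    control_counts: np.ndarray,
    target_counts: np.ndarray,
    sgc_control_count: int,
    sgc_target_count: int,
    band: tuple[float, float] = (0.8, 1.2),
) -> ControlResult:
    """Band-matched count control.

    The control set contains the random codes whose mismatch count lies
    in the closed interval [lower * SGC count, upper * SGC count]; the
    result is the fraction of those codes whose target (frameshift) count
    is strictly greater than the SGC's.
    """
    lo, hi = band
    if not lo < hi:
        raise RobustnessStatsError(f"band lower bound must be < upper, got {band}")
    control_counts = np.asarray(control_counts)
    target_counts = np.asarray(target_counts)
    if control_counts.shape != target_counts.shape:
        raise RobustnessStatsError("control and target count vectors must align")
    in_band = (control_counts >= lo * sgc_control_count) & (
        control_counts <= hi * sgc_control_count
    )
    n = int(np.count_nonzero(in_band))
    if n == 0:
        logger.warning("band control: empty control set for band %s", band)
        return ControlResult(0, 0)
    beyond = int(np.count_nonzero(target_counts[in_band] > sgc_target_count))
    return ControlResult(n, beyond)


def ms_control_test(
    control_column: np.ndarray,
    target_column: np.ndarray,
    sgc_control: float,
    sgc_target: float,
) -> ControlResult:
    """MS-matched control for one property.

    Control set: random codes with control MS <= the SGC's (inclusive,
    so codes exactly as mismatch-robust count as controls).  Result: the
    fraction of them with target MS strictly < the SGC's — the P value of
    the null that the SGC's frameshift MS is not smaller than that of
    equally mismatch-robust codes.
    """
    control_column = np.asarray(control_column, dtype=float)
    target_column = np.asarray(target_column, dtype=float)
    if control_column.shape != target_column.shape:
        raise RobustnessStatsError("control and target columns must align")
    in_set = control_column <= sgc_control
    n = int(np.count_nonzero(in_set))
    if n == 0:
        logger.warning("MS control: empty control set")
        return ControlResult(0, 0)
    beyond = int(np.count_nonzero(target_column[in_set] < sgc_target))
    return ControlResult(n, beyond)


def joint_control_test(
    ensemble: MSEnsemble,
    constraints: Sequence[tuple[str, str, float | None]],
    target: tuple[str, str, float | None],
) -> ControlResult:
    """MS-matched control intersecting several (metric, property) constraints.

    Each constraint (metric, property_id, value) keeps the random codes
    whose MS for that metric/property is <= value; a value of None reads
    the SGC's own MS from the ensemble.  The result is the fraction of
    the surviving codes whose target MS is strictly < the target value.
    Adding constraints can only shrink the control set; an empty set is
    reported as such.
    """
    if not constraints:
        raise RobustnessStatsError("at least one constraint is required")

    def resolve(metric: str, pid: str, value: float | None) -> float:
        return ensemble.sgc(metric, pid) if value is None else float(value)

    mask = np.ones(ensemble.n_codes, dtype=bool)
    for metric, pid, value in constraints:
        mask &= ensemble.rgc(metric, pid) <= resolve(metric, pid, value)
    n = int(np.count_nonzero(mask))
    if n == 0:
        logger.warning("joint control: empty control set for %d constraints", len(constraints))
        return ControlResult(0, 0)
    t_metric, t_pid, t_value = target
    beyond = int(
        np.count_nonzero(ensemble.rgc(t_metric, t_pid)[mask] < resolve(t_metric, t_pid, t_value))
    )
    return ControlResult(n, beyond)


# ---------------------------------------------------------------------------
# correlation structure


def _colwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of two (n, p) matrices."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / denom
    if np.any(denom == 0):
        logger.warning(
            "zero-variance column(s) in correlation profile; r reported as NaN"
        )
    return r


def ms_correlation_profile(
    ensemble: MSEnsemble,
    pairs: Sequence[tuple[str, str]] = (("MS1", "MS3"), ("MS2", "MS3")),
) -> pd.DataFrame:
    """Per-property Pearson correlation between two metrics across RGCs.

    Returns a DataFrame indexed by property id with one ``r(X,Y)`` column
    per requested metric pair.  Correlations are over the random codes
    only (the SGC is a fixed point, not an ensemble draw); zero-variance
    columns yield NaN, never a silent 0.
    """
    if ensemble.n_codes < 3:
        raise RobustnessStatsError("need >= 3 codes for a correlation profile")
    cols = {}
    for mx, my in pairs:
        cols[f"r({mx},{my})"] = _colwise_pearson(ensemble.rgc(mx), ensemble.rgc(my))
    df = pd.DataFrame(cols, index=pd.Index(ensemble.property_ids, name="property_id"))
    return df


def cross_correlation_matrix(
    ensemble: MSEnsemble, metric_x: str = "MS1", metric_y: str = "MS3"
) -> pd.DataFrame:
    """Cross-talk matrix: r(metric_x of property i, metric_y of property j).

    Row i / column j is the Pearson correlation across RGCs between the
    mismatch MS of property i and the frameshift MS of property j.  Used
    to pick the strongest cross-talking properties for joint controls.
    """
    a = ensemble.rgc(metric_x)
    b = ensemble.rgc(metric_y)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sa = np.sqrt((a**2).sum(axis=0))
    sb = np.sqrt((b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a.T @ b) / np.outer(sa, sb)
    ids = ensemble.property_ids
    return pd.DataFrame(r, index=pd.Index(ids, name=metric_x), columns=ids)


def top_crosstalk_properties(
    ensemble: MSEnsemble,
    target_property: str,
    metric_x: str = "MS1",
    metric_y: str = "MS3",
    k: int = 4,
) -> list[str]:
    """Properties whose mismatch MS correlates most with the target's MS3."""
    a = ensemble.rgc(metric_x)
    b = ensemble.rgc(metric_y, target_property)
    r = _colwise_pearson(a, b[:, None] * np.ones((1, a.shape[1])))
    order = np.argsort(-np.nan_to_num(r, nan=-np.inf))
    return [ensemble.property_ids[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# distribution-level tests and report assembly


def distribution_tests(
    p_by_metric: Mapping[str, np.ndarray],
    corr_profile: pd.DataFrame | None = None,
    like_unlike: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """The three figure-legend tests, via standard library routines.

    * Kolmogorov–Smirnov between the property-wise P-value distributions
      of each mismatch metric and MS3;
    * a binomial test on how many properties fall above vs below the
      P(MS3) = P(MS1/MS2) diagonal;
    * Wilcoxon signed-rank between the per-property correlation
      distributions restricted to mismatch-like vs mismatch-unlike
      frameshift events (when supplied).
    """
    rows = []
    p3 = p_by_metric.get("MS3")
    for metric in ("MS1", "MS2"):
        pm = p_by_metric.get(metric)
        if pm is None or p3 is None:
            continue
        ks = stats.ks_2samp(pm, p3)
        rows.append(("KS", f"P({metric}) vs P(MS3)", ks.statistic, ks.pvalue))
        above = int(np.count_nonzero(p3 > pm))
        below = int(np.count_nonzero(p3 < pm))
        if above + below:
            bt = stats.binomtest(above, above + below, 0.5)
            rows.append(
                ("binomial", f"P(MS3) above vs below P({metric})", above / (above + below), bt.pvalue)
            )
    if like_unlike is not None:
        r_like, r_unlike = like_unlike
        ok = np.isfinite(r_like) & np.isfinite(r_unlike)
        if np.any(r_like[ok] != r_unlike[ok]):
            wt = stats.wilcoxon(r_like[ok], r_unlike[ok])
            rows.append(
                ("wilcoxon", "r(mismatch, like-MS3) vs r(mismatch, unlike-MS3)",
                 float(np.median(r_like[ok] - r_unlike[ok])), wt.pvalue)
            )
    _ = corr_profile  # reserved for future per-pair summaries
    return pd.DataFrame(rows, columns=["test", "comparison", "statistic", "p_value"])


@dataclass
class RobustnessReport:
    """Assembled results of a robustness analysis run.

    ``per_property``: one row per property with empirical P, BH-adjusted
    P and significance flag per metric, plus correlation columns.
    ``controls``: one row per control test (name, parameters, control-set
    size, count beyond, fraction).  ``sgc_counts``: N values of the SGC.
    ``tests``: distribution-level test results.  ``metadata``: seed,
    ensemble size, alpha, band, P-value resolution.
    """

    per_property: pd.DataFrame
    controls: pd.DataFrame
    sgc_counts: dict[str, int]
    tests: pd.DataFrame
    metadata: dict[str, object] = field(default_factory=dict)
    n_counts: pd.DataFrame | None = None

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.per_property.to_csv(directory / "per_property.tsv", sep="\t")
        self.controls.to_csv(directory / "controls.tsv", sep="\t", index=False)
        self.tests.to_csv(directory / "distribution_tests.tsv", sep="\t", index=False)
        if self.n_counts is not None:
            self.n_counts.to_csv(directory / "n_counts.tsv", sep="\t")
        meta_lines = [f"{k}\t{v}" for k, v in {**self.metadata, **{f"N_{m}": v for m, v in self.sgc_counts.items()}}.items()]
        (directory / "run_metadata.tsv").write_text("\n".join(meta_lines) + "\n")


def build_report(
    ensemble: MSEnsemble,
    alpha: float = 0.05,
    band: tuple[float, float] = (0.8, 1.2),
    compute_n_counts: bool = False,
    run_property_controls: bool = True,
) -> RobustnessReport:
    """Full inference pass over an ensemble.

    Computes per-property empirical P and BH flags for every metric, the
    correlation profile (including like/unlike MS3 variants when the
    ensemble carries them), distribution-level tests, MS-matched controls
    for every property flagged frameshift-robust, and — when
    ``compute_n_counts`` is set (quadratic in ensemble size times
    properties; expensive at millions of codes) — per-code N counts with
    the band control tests.
    """
    metrics = list(ensemble.metrics)
    n = ensemble.n_codes
    per_prop = pd.DataFrame(index=pd.Index(ensemble.property_ids, name="property_id"))
    p_by_metric: dict[str, np.ndarray] = {}
    flags_by_metric: dict[str, np.ndarray] = {}
    for metric in metrics:
        sgc_row = ensemble.sgc(metric)
        rgc = ensemble.rgc(metric)
        p = np.count_nonzero(rgc < sgc_row[None, :], axis=0) / n
        p_adj, flags = bh_significant(p, alpha)
        p_by_metric[metric] = p
        flags_by_metric[metric] = flags
        per_prop[f"P_{metric}"] = p
        per_prop[f"adjP_{metric}"] = p_adj
        per_prop[f"sig_{metric}"] = flags

    corr_pairs = [(mx, "MS3") for mx in ("MS1", "MS2") if mx in metrics and "MS3" in metrics]
    like_unlike = None
    if corr_pairs:
        extra = [
            (mx, my)
            for mx in ("MS1", "MS2")
            if mx in metrics
            for my in ("MS3-like", "MS3-unlike")
            if my in metrics
        ]
        prof = ms_correlation_profile(ensemble, corr_pairs + extra)
        per_prop = per_prop.join(prof)
        if {"MS3-like", "MS3-unlike"} <= set(metrics) and "MS1" in metrics:
            like_unlike = (
                prof["r(MS1,MS3-like)"].to_numpy(),
                prof["r(MS1,MS3-unlike)"].to_numpy(),
            )

    tests = distribution_tests(p_by_metric, like_unlike=like_unlike)

    sgc_counts = {m: int(flags_by_metric[m].sum()) for m in metrics}

    control_rows: list[dict[str, object]] = []
    if run_property_controls and "MS3" in metrics:
        for control_metric in ("MS1", "MS2"):
            if control_metric not in metrics:
                continue
            for pid in np.array(ensemble.property_ids)[flags_by_metric["MS3"]]:
                res = ms_control_test(
                    ensemble.rgc(control_metric, pid),
                    ensemble.rgc("MS3", pid),
                    ensemble.sgc(control_metric, pid),
                    ensemble.sgc("MS3", pid),
                )
                control_rows.append(
                    {
                        "test": "ms_control",
                        "parameters": f"control={control_metric},property={pid}",
                        "control_size": res.control_size,
                        "n_beyond": res.n_beyond,
                        "fraction": res.fraction,
                    }
                )

    n_counts_df = None
    if compute_n_counts:
        n_counts_df = per_code_significance_counts(ensemble, alpha)
        if "MS3" in n_counts_df.columns:
            for control_metric in ("MS1", "MS2"):
                if control_metric not in n_counts_df.columns:
                    continue
                res = band_control_test(
                    n_counts_df[control_metric].to_numpy()[1:],
                    n_counts_df["MS3"].to_numpy()[1:],
                    int(n_counts_df[control_metric].iloc[0]),
                    int(n_counts_df["MS3"].iloc[0]),
                    band=band,
                )
                control_rows.append(
                    {
                        "test": "band_control",
                        "parameters": f"control=N({control_metric}),band={band}",
                        "control_size": res.control_size,
                        "n_beyond": res.n_beyond,
                        "fraction": res.fraction,
                    }
                )
        # per-code counts replace the SGC-only flags (identical for the SGC row)
        sgc_counts = {m: int(n_counts_df[m].iloc[0]) for m in n_counts_df.columns}

    controls = pd.DataFrame(
        control_rows,
        columns=["test", "parameters", "control_size", "n_beyond", "fraction"],
    )
    metadata = {
        "n_codes": n,
        "seed": ensemble.seed,
        "alpha": alpha,
        "band": f"{band[0]}-{band[1]}",
        "p_resolution": 1.0 / n,
        "params_digest": ensemble.params_digest,
    }
    if n_counts_df is not None:
        metadata["n_counts_computed"] = True
    return RobustnessReport(
        per_property=per_prop,
        controls=controls,
        sgc_counts=sgc_counts,
        tests=tests,
        metadata=metadata,
        n_counts=n_counts_df,
    )
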