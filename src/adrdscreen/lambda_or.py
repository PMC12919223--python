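"""Misclassification-corrected, ridge-regularized odds ratios (the Λ-OR).

In large observational cohorts the case/control labels behind a 2×2
exposure table are themselves noisy — derived from diagnosis codes or a
classifier with sensitivity ``p`` and specificity ``q``.  In expectation the
observed table T̃ relates to the true table T through the row-stochastic
misclassification matrix K:

    T̃ = T K,        K = [[p, 1−p], [1−q, q]],

with exposure indexing rows and label status indexing columns of both
tables (row i of K is the distribution of the observed label given true
label i, so column j of T̃ blends the true columns by the chance each true
label is *observed* as j).  Direct inversion of K can produce negative or
unstable "counts", so the corrected table uses a ridge-regularized inverse,

    T(λ) = T̃ (K + λI)⁻¹,

with λ the smallest value (found by bisection) at which every recovered
cell exceeds a small floor ε, preserving interpretability as approximate
counts.  The corrected log odds ratio log(ad/bc) gets a classical
1/a+1/b+1/c+1/d variance plus, when p and q were estimated on a validation
cohort of size n_val, a delta-method extra-variance term; Wald inference
follows.

Worked sign convention (exposure rows, label columns): with p = q = 0.9 and
T̃ = [[90, 10], [10, 90]], K⁻¹ = (1/0.8)·[[0.9, −0.1], [−0.1, 0.9]] and
T(0) = [[100, 0], [0, 100]] — the noiseless table is recovered exactly.
With asymmetric noise, say p = 0.9, q = 0.8 and true T = [[100, 0], [0, 100]],
the observed table is T̃ = T·K = [[90, 10], [20, 80]] and T̃ K⁻¹ restores T.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NoisyTable",
    "MisclassSpec",
    "LambdaORResult",
    "misclassification_matrix",
    "correct_table",
    "find_min_lambda",
    "naive_log_or",
    "extra_variance",
    "propagated_variance",
    "lambda_or",
    "build_stratified_table",
    "volcano_table",
    "exposure_prevalence",
    "label_prevalence",
]

#: Near-singularity guard: K is not usefully invertible when p + q ≈ 1.
DEGENERACY_TOL = 1e-3

#: Default feasibility floor for recovered counts (midpoint of the typical
#: [0.1, 1] range).
DEFAULT_EPSILON = 0.5


@dataclass(frozen=True)
class NoisyTable:
    """Observed 2×2 counts under noisy labels.

    a = exposed & labeled-case, b = exposed & labeled-control,
    c = unexposed & labeled-case, d = unexposed & labeled-control.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("table counts must be nonnegative")
        if sum(cells) <= 0:
            raise ValueError("table total must be positive")

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swapped_exposure(self) -> "NoisyTable":
        """Rows exchanged: the unexposed become the exposed."""
        return NoisyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class MisclassSpec:
    """Label sensitivity/specificity, optionally with the validation size behind them."""

    p: float  # sensitivity P(labeled case | true case)
    q: float  # specificity P(labeled control | true control)
    n_val: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1) or not (0 < self.q <= 1):
            raise ValueError("p and q must lie in (0, 1]")
        if abs(self.p + self.q - 1) < DEGENERACY_TOL:
            raise ValueError(
                f"misclassification matrix is nearly singular (p+q-1 = "
                f"{self.p + self.q - 1:.2e}); labels this noisy cannot be inverted"
            )
        if self.n_val is not None and self.n_val <= 1:
            raise ValueError("n_val must exceed 1 when present")


def misclassification_matrix(p: float, q: float) -> np.ndarray:
    """The stochastic matrix K = [[p, 1−p], [1−q, q]].

    Warns (rather than refusing) near p + q = 1 so the matrix can still be
    inspected; estimation through `MisclassSpec` refuses that regime.
    """
    if not (0 < p <= 1) or not (0 < q <= 1):
        raise ValueError("p and q must lie in (0, 1]")
    if abs(p + q - 1) < DEGENERACY_TOL:
        warnings.warn(f"K is nearly singular: p+q-1 = {p + q - 1:.2e}")
    return np.array([[p, 1 - p], [1 - q, q]], dtype=float)


def _as_cells(table: "NoisyTable | np.ndarray") -> tuple[float, float, float, float]:
    """Accept a NoisyTable or a raw 2×2 array (which may be degenerate)."""
    if isinstance(table, NoisyTable):
        return table.a, table.b, table.c, table.d
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(arr < 0):
        raise ValueError("table counts must be nonnegative")
    return arr[0, 0], arr[0, 1], arr[1, 0], arr[1, 1]


def correct_table(
    table: "NoisyTable | np.ndarray", spec: MisclassSpec, lam: float = 0.0
) -> np.ndarray:
    """Recover T(λ) = T̃ (K + λI)⁻¹; exact matrix algebra, no clipping."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    a, b, c, d = _as_cells(table)
    K = np.array([[spec.p, 1 - spec.p], [1 - spec.q, spec.q]])
    M = K + lam * np.eye(2)
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    if abs(det) < 1e-12:
        raise ValueError("K + lambda*I is singular; increase lambda")
    return np.array([[a, b], [c, d]]) @ np.linalg.inv(M)


def _cells_vs_lambda(table, spec: MisclassSpec, lams: np.ndarray) -> np.ndarray:
    """Vectorized T(λ) cells for an array of λ values; shape (len(lams), 4)."""
    p, q = spec.p, spec.q
    # M = K + λI = [[p+λ, 1−p], [1−q, q+λ]]
    det = (p + lams) * (q + lams) - (1 - p) * (1 - q)
    at, bt, ct, dt = _as_cells(table)
    a = (at * (q + lams) - bt * (1 - q)) / det
    b = (-at * (1 - p) + bt * (p + lams)) / det
    c = (ct * (q + lams) - dt * (1 - q)) / det
    d = (-ct * (1 - p) + dt * (p + lams)) / det
    return np.column_stack([a, b, c, d])


def find_min_lambda(
    table: "NoisyTable | np.ndarray",
    spec: MisclassSpec,
    epsilon: float = DEFAULT_EPSILON,
    lam_max: Optional[float] = None,
    rel_tol: float = 1e-9,
) -> Optional[float]:
    """Smallest λ ≥ 0 with all four cells of T(λ) ≥ ε, or None when infeasible.

    The feasible λ form an interval (each cell rises through its zero then
    decays like 1/λ), so after a coarse scan locates one feasible point,
    bisection pins the left edge to relative tolerance ``rel_tol``.
    Returns 0.0 when the plain inverse is already feasible.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if lam_max is None:
        lam_max = 10.0 * max(_as_cells(table))
    if lam_max <= 0:
        return None

    def feasible(lam: float) -> bool:
        return bool(np.all(_cells_vs_lambda(table, spec, np.array([lam]))[0] >= epsilon))

    if feasible(0.0):
        return 0.0
    # coarse scan for any feasible point (dense linear grid; the feasible
    # interval, when nonempty, is wide relative to lam_max for count data)
    grid = np.linspace(0.0, lam_max, 4097)[1:]
    cells = _cells_vs_lambda(table, spec, grid)
    ok = np.all(cells >= epsilon, axis=1)
    if not ok.any():
        return None
    hi = float(grid[int(np.argmax(ok))])
    lo = 0.0
    while hi - lo > rel_tol * max(hi, 1e-30):
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return hi


def naive_log_or(table: np.ndarray | NoisyTable) -> tuple[float, float]:
    """Classical log odds ratio log(ad/bc) and its variance 1/a+1/b+1/c+1/d."""
    if isinstance(table, NoisyTable):
        table = table.as_matrix()
    a, b = table[0]
    c, d = table[1]
    if min(a, b, c, d) <= 0:
        raise ValueError("all four cells must be positive for the classical log OR")
    return math.log(a * d / (b * c)), 1 / a + 1 / b + 1 / c + 1 / d


def extra_variance(spec: MisclassSpec) -> float:
    """Delta-method variance from estimating (p, q) on a validation cohort.

    Zero when n_val is absent (p, q known exactly).  Vanishes as
    n_val → ∞ and at p = q = 1.
    """
    if spec.n_val is None:
        return 0.0
    p, q, n = spec.p, spec.q, spec.n_val
    den = (p + q - 1) ** 2
    return ((1 - q) / den) ** 2 * 2 * p * (1 - p) / n + ((1 - p) / den) ** 2 * 2 * q * (1 - q) / n


def propagated_variance(table: NoisyTable, spec: MisclassSpec, lam: float) -> float:
    """Sampling variance of log Λ-OR propagated through the ridge inverse.

    Delta method treating the four observed cells as independent Poisson
    counts.  At p = q = 1 and λ = 0 this reduces exactly to the classical
    1/a+1/b+1/c+1/d.  Reported as a diagnostic alongside the closed-form
    total variance, which ignores the noise amplification of the inversion
    and can be anticonservative under strong label noise.
    """
    p, q = spec.p, spec.q
    det = (p + lam) * (q + lam) - (1 - p) * (1 - q)
    T = correct_table(table, spec, lam)
    a, b = T[0]
    c, d = T[1]
    if min(a, b, c, d) <= 0:
        return math.nan
    g_at = (q + lam) / (a * det) + (1 - p) / (b * det)
    g_bt = -((1 - q) / (a * det) + (p + lam) / (b * det))
    g_ct = -((q + lam) / (c * det) + (1 - p) / (d * det))
    g_dt = (1 - q) / (c * det) + (p + lam) / (d * det)
    return float(
        g_at**2 * table.a + g_bt**2 * table.b + g_ct**2 * table.c + g_dt**2 * table.d
    )


@dataclass(frozen=True)
class LambdaORResult:
    corrected_table: Optional[np.ndarray]
    lam: Optional[float]
    epsilon: float
    feasible: bool
    log_or: float = math.nan
    var_naive: float = math.nan
    var_extra: float = math.nan
    var_total: float = math.nan
    var_propagated: float = math.nan  # diagnostic, not used for the Wald test
    z: float = math.nan
    p_two_sided: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan


def lambda_or(
    table: NoisyTable,
    spec: MisclassSpec,
    epsilon: float = DEFAULT_EPSILON,
    alpha: float = 0.05,
    lam_max: Optional[float] = None,
) -> LambdaORResult:
    """Full Λ-OR pipeline: λ search, table correction, Wald inference.

    Infeasibility (no λ recovers all cells above ε) is a reported state,
    not an exception: the result carries ``feasible=False`` and NaN
    estimates.
    """
    lam = find_min_lambda(table, spec, epsilon=epsilon, lam_max=lam_max)
    if lam is None:
        return LambdaORResult(corrected_table=None, lam=None, epsilon=epsilon, feasible=False)
    T = correct_table(table, spec, lam)
    log_or, var_naive = naive_log_or(T)
    var_extra = extra_variance(spec)
    var_total = var_naive + var_extra
    z = log_or / math.sqrt(var_total)
    p_two = 2 * norm.sf(abs(z))
    zcrit = norm.ppf(1 - alpha / 2)
    half = zcrit * math.sqrt(var_total)
    return LambdaORResult(
        corrected_table=T,
        lam=lam,
        epsilon=epsilon,
        feasible=True,
        log_or=log_or,
        var_naive=var_naive,
        var_extra=var_extra,
        var_total=var_total,
        var_propagated=propagated_variance(table, spec, lam) + var_extra,
        z=z,
        p_two_sided=float(p_two),
        ci_low=log_or - half,
        ci_high=log_or + half,
    )


def build_stratified_table(
    scores: Sequence[float],
    exposed: Sequence[bool],
    risk_threshold: float,
) -> NoisyTable:
    """Cross-tabulate exposure against model-risk strata at a threshold.

    High risk = score ≥ threshold.  The high-risk stratum plays the role of
    the (noisily) labeled cases: a = exposed∧high, b = exposed∧low,
    c = unexposed∧high, d = unexposed∧low.
    """
    scores = np.asarray(scores, dtype=float)
    exposed = np.asarray(exposed, dtype=bool)
    if scores.shape != exposed.shape:
        raise ValueError("scores and exposure indicators must align")
    if not (scores.min() <= risk_threshold <= scores.max()):
        warnings.warn("risk threshold lies outside the observed score range")
    high = scores >= risk_threshold
    a = int(np.sum(exposed & high))
    b = int(np.sum(exposed & ~high))
    c = int(np.sum(~exposed & high))
    d = int(np.sum(~exposed & ~high))
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        warnings.warn("a margin of the stratified table is empty")
    return NoisyTable(a, b, c, d)


def volcano_table(results: Mapping[str, LambdaORResult], fdr_q: float = 0.05):
    """Rank per-code Λ-OR results for a volcano display.

    Columns: code, log Λ-OR, −log10 p (total and naive-variance versions),
    Benjamini–Hochberg q, significance flag at ``fdr_q``, and direction
    (risk when OR > 1, protective when OR < 1); sorted by |log Λ-OR|
    descending.  Infeasible results are dropped.
    """
    import pandas as pd

    if not results:
        raise ValueError("volcano_table requires at least one result")
    rows = []
    for code, r in results.items():
        if not r.feasible:
            continue
        p_naive = 2 * norm.sf(abs(r.log_or) / math.sqrt(r.var_naive))
        rows.append(
            {
                "code": code,
                "log_lambda_or": r.log_or,
                "p": r.p_two_sided,
                "p_naive_var": float(p_naive),
                "neg_log10_p": -math.log10(max(r.p_two_sided, 1e-300)),
                "direction": "risk" if r.log_or > 0 else "protective",
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        reject, qvals, _, _ = multipletests(df["p"].values, alpha=fdr_q, method="fdr_bh")
        df["q_bh"] = qvals
        df["significant"] = reject
        df = df.reindex(
            df["log_lambda_or"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)
    return df


def exposure_prevalence(table: NoisyTable) -> tuple[float, float]:
    """Exposure fraction among labeled cases and labeled controls (a/(a+c), b/(b+d))."""
    return table.a / (table.a + table.c), table.b / (table.b + table.d)


def label_prevalence(table: NoisyTable) -> float:
    """Fraction of labeled cases in the table, (a+c) / total."""
    return (table.a + table.c) / (table.a + table.b + table.c + table.d)
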