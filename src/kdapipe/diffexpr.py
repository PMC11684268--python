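"""Normalization and two-group differential analysis for both omics.

The transcriptomic path: rank-invariant per-sample scaling on the original
intensity scale, then an unequal-variance (Welch) t-test per gene on log2
intensities, Benjamini–Hochberg adjustment, and an optional Storey q-value.
The metabolomic path: per-metabolite minimum imputation of below-detection
values, tests on log2 abundances, fold changes as ratios of arithmetic
group means on the original scale (the convention of targeted metabolomics
reports).

Fold change is always treated/control.  The family size m for FDR is the
number of features actually tested (>=2 non-missing values per group),
which is logged when features are dropped.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .ioformats import ExpressionMatrix, MetaboliteTable

logger = logging.getLogger("kdapipe.diffexpr")

RESULT_COLUMNS = [
    "mean_control", "mean_treated", "fold_change", "log2fc",
    "t", "df", "p", "adj_p", "q",
]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def rank_invariant_normalize(
    matrix: ExpressionMatrix,
    reference: str = "median",
    rank_tolerance: float = 0.05,
    min_invariant: int | None = None,
) -> ExpressionMatrix:
    """Rank-invariant per-sample scaling of original-scale intensities.

    For each sample, probes whose rank differs from the reference profile's
    rank by at most ``rank_tolerance * n_probes`` form the candidate
    invariant set; a second pass trims probes whose sample/reference
    log-ratio deviates from the set median by more than twice the set MAD.
    The sample is then divided by the median invariant-probe ratio, so a
    sample identical (or exactly proportional) to the reference maps onto
    it.  ``reference`` is a sample id or ``"median"`` (per-probe median
    pseudo-sample).

    Intensities must be strictly positive (original scale, not log).
    Raises when the invariant set falls below ``min_invariant`` (default:
    the smaller of 50 and 5% of probes, at least 1) — pick another
    reference in that case.
    """
    X = matrix.values
    if X.shape[1] < 2:
        raise ParameterError("need >=2 samples to normalize")
    if (X <= 0).any().any() or X.isna().any().any():
        raise ParameterError("rank-invariant normalization needs strictly positive intensities")
    n = X.shape[0]
    if min_invariant is None:
        min_invariant = max(1, min(50, math.ceil(0.05 * n)))

    if reference == "median":
        ref = X.median(axis=1)
    elif reference in X.columns:
        ref = X[reference]
    else:
        raise ParameterError(f"reference sample {reference!r} not in matrix")
    ref_ranks = ref.rank(method="average")

    out = X.copy()
    tol = rank_tolerance * n
    for sample in X.columns:
        col = X[sample]
        invariant = (col.rank(method="average") - ref_ranks).abs() <= tol
        if invariant.sum() >= 1:
            log_ratio = np.log(ref[invariant] / col[invariant])
            med = np.median(log_ratio)
            mad = np.median(np.abs(log_ratio - med))
            keep = np.abs(log_ratio - med) <= 2 * mad + 1e-12
            idx = log_ratio.index[keep]
        else:
            idx = col.index[invariant]
        if len(idx) < min_invariant:
            raise ParameterError(
                f"sample {sample!r}: rank-invariant set has {len(idx)} probes "
                f"(< {min_invariant}); try a different reference"
            )
        factor = float(np.median(ref[idx] / col[idx]))
        out[sample] = col * factor
    return ExpressionMatrix(values=out, groups=dict(matrix.groups))


# ---------------------------------------------------------------------------
# tests and FDR
# ---------------------------------------------------------------------------

def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p)`` with ``t = (mean(x) - mean(y)) / se`` and the
    Welch–Satterthwaite degrees of freedom; p is two-sided.  Fewer than two
    non-missing values in either group yields ``(nan, nan, nan)`` rather
    than an exception.  Two zero-variance groups give t = 0, p = 1 when the
    means agree and p = 0 (logged) when they differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        return (math.nan, math.nan, math.nan)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    sx2, sy2 = vx / len(x), vy / len(y)
    se2 = sx2 + sy2
    if se2 == 0.0:
        if mx == my:
            return (0.0, float(len(x) + len(y) - 2), 1.0)
        logger.info("zero variance in both groups with unequal means: p set to 0")
        return (math.copysign(math.inf, mx - my), float(len(x) + len(y) - 2), 0.0)
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / (sx2**2 / (len(x) - 1) + sy2**2 / (len(y) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return (float(t), float(df), float(p))


def student_test(x, y) -> tuple[float, float, float]:
    """Pooled-variance (Student) two-sample t-test; same conventions as Welch."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        return (math.nan, math.nan, math.nan)
    nx, ny = len(x), len(y)
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    se2 = sp2 * (1 / nx + 1 / ny)
    if se2 == 0.0:
        if x.mean() == y.mean():
            return (0.0, float(df), 1.0)
        logger.info("zero variance in both groups with unequal means: p set to 0")
        return (math.copysign(math.inf, x.mean() - y.mean()), float(df), 0.0)
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return (float(t), float(df), float(p))


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Missing entries pass through untouched and do not count toward the
    family size m.  Values outside [0, 1] raise, naming the index.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    bad = np.where(mask & ((p < 0) | (p > 1)))[0]
    if bad.size:
        raise ParameterError(f"p-value out of [0, 1] at index {bad[0]}: {p[bad[0]]}")
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


def q_values(p, method: str = "bh", lambdas=None) -> np.ndarray:
    """Estimate per-feature q-values (positive FDR).

    ``method="bh"`` returns the BH-adjusted p-values (pi0 = 1).  ``"storey"``
    estimates pi0 from the flat right tail of the p-value histogram: pi0(l)
    = #{p > l} / (m (1 - l)) over the lambda grid 0.05..0.95, smoothed with
    a cubic fit and evaluated at the largest lambda.  Storey estimation
    needs >= 100 p-values; smaller families fall back to BH with a warning.
    """
    p = np.asarray(p, dtype=float)
    if method == "bh":
        return bh_adjust(p)
    if method != "storey":
        raise ParameterError(f"unknown q-value method {method!r}")
    mask = ~np.isnan(p)
    m = int(mask.sum())
    if m < 100:
        warnings.warn("storey q-values need >=100 p-values; falling back to BH")
        return bh_adjust(p)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pv = p[mask]
    pi0_l = np.array([(pv > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    coef = np.polynomial.polynomial.polyfit(lambdas, pi0_l, 3)
    pi0 = float(np.polynomial.polynomial.polyval(lambdas[-1], coef))
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    out = np.full(p.shape, np.nan)
    out[mask] = np.minimum(pi0 * bh_adjust(pv), 1.0)
    return out


# ---------------------------------------------------------------------------
# per-feature differential tables
# ---------------------------------------------------------------------------

def impute_min(abundances: pd.DataFrame) -> pd.DataFrame:
    """Replace missing abundances by the per-feature observed minimum."""
    mins = abundances.min(axis=1)
    return abundances.apply(lambda col: col.fillna(mins))


def differential_table(
    matrix: ExpressionMatrix | MetaboliteTable,
    control: str,
    treated: str,
    test: str = "welch",
    q_method: str = "storey",
) -> pd.DataFrame:
    """Per-feature two-group differential statistics.

    Returns a DataFrame indexed by feature with columns ``mean_control``,
    ``mean_treated``, ``fold_change`` (treated/control, ratio of arithmetic
    means on the original scale), ``log2fc``, ``t``, ``df``, ``p``,
    ``adj_p`` (BH) and ``q``.  Expression matrices are assumed log2 and are
    exponentiated for the means; metabolite tables are min-imputed and
    log2-transformed for testing.  Features with fewer than two non-missing
    values in either group are reported with missing statistics and do not
    count toward the FDR family size.
    """
    if test not in ("welch", "student"):
        raise ParameterError(f"test must be 'welch' or 'student', got {test!r}")
    test_fn = welch_test if test == "welch" else student_test

    if isinstance(matrix, MetaboliteTable):
        groups = matrix.groups
        raw = matrix.abundances
        _check_labels(groups, control, treated)
        ctrl_cols = matrix.samples_in_group(control)
        trt_cols = matrix.samples_in_group(treated)
        testable = (
            raw[ctrl_cols].notna().sum(axis=1).ge(2)
            & raw[trt_cols].notna().sum(axis=1).ge(2)
        )
        imputed = impute_min(raw)
        original = imputed
        with np.errstate(divide="ignore"):
            log_values = np.log2(imputed.where(imputed > 0))
    else:
        groups = matrix.groups
        _check_labels(groups, control, treated)
        ctrl_cols = matrix.samples_in_group(control)
        trt_cols = matrix.samples_in_group(treated)
        log_values = matrix.values
        testable = (
            log_values[ctrl_cols].notna().sum(axis=1).ge(2)
            & log_values[trt_cols].notna().sum(axis=1).ge(2)
        )
        original = np.power(2.0, log_values)

    n_dropped = int((~testable).sum())
    if n_dropped:
        logger.info("%d feature(s) untestable (<2 values in a group); excluded from FDR m",
                    n_dropped)

    mean_c = original[ctrl_cols].mean(axis=1)
    mean_t = original[trt_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_t / mean_c

    lx = log_values[trt_cols].to_numpy(dtype=float)
    ly = log_values[ctrl_cols].to_numpy(dtype=float)
    stats_rows = [
        test_fn(lx[i], ly[i]) if testable.iloc[i] else (math.nan, math.nan, math.nan)
        for i in range(len(log_values))
    ]
    t_arr, df_arr, p_arr = (np.array(col) for col in zip(*stats_rows))

    res = pd.DataFrame(index=log_values.index)
    res.index.name = "feature"
    res["mean_control"] = mean_c
    res["mean_treated"] = mean_t
    res["fold_change"] = fc
    with np.errstate(divide="ignore", invalid="ignore"):
        res["log2fc"] = np.log2(fc)
    res["t"] = t_arr
    res["df"] = df_arr
    res["p"] = p_arr
    res["adj_p"] = bh_adjust(p_arr)
    res["q"] = q_values(p_arr, method=q_method)
    return res


def _check_labels(groups, control, treated) -> None:
    labels = set(groups.values())
    for lab in (control, treated):
        if lab not in labels:
            raise ParameterError(f"group label {lab!r} not present (have {sorted(labels)})")


# ---------------------------------------------------------------------------
# signatures and overlaps
# ---------------------------------------------------------------------------

@dataclass
class Signature:
    """A directional differential signature for one contrast."""

    name: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)
    threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ParameterError("signature up and down sets overlap")

    @property
    def genes(self) -> set[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


def make_signature(results: pd.DataFrame, threshold: float = 0.05,
                   name: str = "signature") -> Signature:
    """Call a directional signature at an adjusted-p cutoff.

    up: adj_p <= threshold and fold_change > 1; down: adj_p <= threshold
    and fold_change < 1.  A significant feature with fold change exactly 1
    belongs to neither direction and is logged.
    """
    if results.empty:
        raise ParameterError("differential results are empty")
    sig = results["adj_p"].le(threshold)
    up = set(results.index[sig & results["fold_change"].gt(1)])
    down = set(results.index[sig & results["fold_change"].lt(1)])
    flat = results.index[sig & results["fold_change"].eq(1)]
    if len(flat):
        logger.info("%d significant feature(s) with fold change exactly 1 left undirected",
                    len(flat))
    return Signature(name=name, up=up, down=down, threshold=threshold)


def venn_counts(a: Signature, b: Signature) -> pd.DataFrame:
    """Two-signature overlap counts per direction.

    Rows ``up``/``down``; columns ``a_only``, ``shared``, ``b_only`` —
    the numbers a two-circle Venn diagram of the contrasts displays.
    """
    rows = {}
    for direction in ("up", "down"):
        sa, sb = getattr(a, direction), getattr(b, direction)
        rows[direction] = {
            "a_only": len(sa - sb),
            "shared": len(sa & sb),
            "b_only": len(sb - sa),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
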