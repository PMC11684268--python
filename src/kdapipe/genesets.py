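"""Gene-set and metabolite-pathway enrichment.

Two complementary approaches:

* **Over-representation analysis (ORA)** on a called significant set.  For a
  pathway, with k significant members, K detected members, n significant
  features overall and N detected features overall, the fold enrichment is

      Enrichment = (k/K) / (n/N)

  and the p-value is the upper hypergeometric tail P(X >= k).  This is the
  standard fold-enrichment convention of KEGG-style metabolite pathway
  analysis.

* **GSEA** on a ranked feature list: the weighted Kolmogorov–Smirnov-like
  running sum, with hit increments proportional to |score|^w (normalized to
  sum 1) and miss decrements 1/(N - |S|); the enrichment score ES is the
  running-sum extremum of largest magnitude.  Significance comes from
  permutations (gene-set membership by default, phenotype labels when the
  design allows), with NES = ES / mean |same-sign permuted ES| and a
  sign-stratified pooled FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .ioformats import ExpressionMatrix, GeneSetCollection
from .diffexpr import bh_adjust, differential_table
from .synthdata import child_seed

logger = logging.getLogger("kdapipe.genesets")


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def fold_enrichment(k: int, K: int, n: int, N: int) -> float:
    """(k/K) / (n/N); NaN when a denominator vanishes."""
    if K == 0 or n == 0 or N == 0:
        return float("nan")
    return (k / K) / (n / N)


def ora(
    significant: set[str],
    detected: set[str],
    pathways: GeneSetCollection,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``significant`` per pathway.

    Pathways are intersected with ``detected`` before counting; pathways
    with no detected member are skipped.  ``alternative="greater"`` tests
    enrichment (upper tail, the default); ``"less"`` tests depletion.
    Returns a DataFrame with columns set_name, k, K, n, N, fold_enrichment,
    p_value, adj_p (BH across pathways), sorted by p then name.
    """
    significant = set(significant)
    detected = set(detected)
    stray = significant - detected
    if stray:
        raise ParameterError(
            f"significant features not in detected universe: {sorted(stray)[:5]}"
        )
    if alternative not in ("greater", "less"):
        raise ParameterError(f"alternative must be 'greater' or 'less', got {alternative!r}")

    n = len(significant)
    N = len(detected)
    rows = []
    for name, members in pathways:
        in_path = set(members) & detected
        K = len(in_path)
        if K == 0:
            continue
        k = len(in_path & significant)
        if alternative == "greater":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            p = float(stats.hypergeom.cdf(k, N, K, n))
        rows.append({
            "set_name": name, "k": k, "K": K, "n": n, "N": N,
            "fold_enrichment": fold_enrichment(k, K, n, N), "p_value": p,
        })
    out = pd.DataFrame(rows, columns=[
        "set_name", "k", "K", "n", "N", "fold_enrichment", "p_value",
    ])
    out["adj_p"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    return out.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def rank_features(results: pd.DataFrame, metric: str = "signed_log_p") -> pd.DataFrame:
    """Rank a differential table for GSEA.

    Metrics: ``signed_log_p`` = sign(log2fc) * -log10(p) (p floored at
    1e-300), ``log2fc``, or ``t``.  Features with missing scores are
    dropped with a log message.  Descending score; ties broken by feature
    id ascending, so the ranking is a deterministic function of the table.
    """
    if results.index.has_duplicates:
        dups = results.index[results.index.duplicated()].unique()
        raise ParameterError(f"duplicate feature id(s): {list(dups[:5])}")
    if metric == "signed_log_p":
        p = results["p"].clip(lower=1e-300)
        score = np.sign(results["log2fc"]) * (-np.log10(p))
    elif metric == "log2fc":
        score = results["log2fc"]
    elif metric == "t":
        score = results["t"]
    else:
        raise ParameterError(f"unknown ranking metric {metric!r}")
    score = pd.Series(score, index=results.index, name="score")
    score = score.replace([np.inf, -np.inf], np.nan)
    n_drop = int(score.isna().sum())
    if n_drop:
        logger.info("dropping %d feature(s) with undefined ranking score", n_drop)
        score = score.dropna()
    out = score.reset_index()
    out.columns = ["feature", "score"]
    return out.sort_values(
        ["score", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def gsea_es(
    ranked: pd.DataFrame,
    gene_set,
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted running-sum enrichment score for one set.

    ``ranked`` is the output of :func:`rank_features` (columns feature,
    score, descending).  Hit steps are |score|^weight_exponent normalized
    to sum 1 (uniform when every hit score is 0); miss steps are
    1/(N - |S|).  Returns (ES, running sum over all N positions).
    """
    if weight_exponent < 0:
        raise ParameterError("weight_exponent must be nonnegative")
    features = ranked["feature"].to_numpy()
    scores = ranked["score"].to_numpy(dtype=float)
    hit = np.isin(features, list(gene_set))
    n_hit = int(hit.sum())
    N = len(features)
    if n_hit == 0:
        raise ParameterError("gene set is disjoint from the ranked universe")
    if n_hit == N:
        raise ParameterError("gene set covers the entire ranked universe")
    weights = np.where(hit, np.abs(scores) ** weight_exponent, 0.0)
    total = weights.sum()
    if total == 0.0:
        weights = hit / n_hit
    else:
        weights = weights / total
    steps = weights - (~hit) / (N - n_hit)
    running = np.cumsum(steps)
    es_idx = int(np.argmax(np.abs(running)))
    return float(running[es_idx]), running


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, N: int
) -> float:
    """ES given sorted 0-based hit positions and their (unnormalized) weights.

    Equivalent to the full running sum but O(|S|): between hits the running
    sum decreases linearly, so its extrema occur right after a hit (local
    max candidates) or right before one (local min candidates).
    """
    s = len(positions)
    total = weights.sum()
    w = weights / total if total > 0 else np.full(s, 1.0 / s)
    cum = np.cumsum(w)
    miss = 1.0 / (N - s)
    j = np.arange(1, s + 1)
    after = cum - (positions + 1 - j) * miss
    before = np.concatenate(([0.0], cum[:-1])) - (positions - (j - 1)) * miss
    # the sum decays linearly between hits and ends at exactly 0, so every
    # extremum is an "after" (peak) or "before" (trough) value
    candidates = np.concatenate((after, before))
    idx = int(np.argmax(np.abs(candidates)))
    return float(candidates[idx])


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    q_value: float
    size: int
    leading_edge: list[str]


def leading_edge(ranked: pd.DataFrame, gene_set, running: np.ndarray) -> list[str]:
    """Members driving the ES: hits at/before a positive peak, after a negative one."""
    features = ranked["feature"].to_numpy()
    hit = np.isin(features, list(gene_set))
    es_idx = int(np.argmax(np.abs(running)))
    if running[es_idx] >= 0:
        sel = hit[: es_idx + 1]
        return list(features[: es_idx + 1][sel])
    sel = hit[es_idx:]
    return list(features[es_idx:][sel])


def gsea(
    matrix: ExpressionMatrix,
    pathways: GeneSetCollection,
    control: str,
    treated: str,
    n_permutations: int = 1000,
    permutation_type: str = "gene_set",
    weight_exponent: float = 1.0,
    metric: str = "signed_log_p",
    min_size: int = 15,
    max_size: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation GSEA over a gene-set collection.

    The ranking comes from :func:`differential_table` +
    :func:`rank_features`.  ``permutation_type="gene_set"`` draws random
    same-size sets from the ranked universe; ``"phenotype"`` permutes group
    labels and recomputes the ranking (falls back to gene_set with a logged
    warning when either group has < 3 samples).  Per set: NES = ES /
    mean |same-sign permuted ES|, nominal p from the same-sign tail with
    +1 continuity, and FDR q from sign-stratified pooling of permuted NES.

    Returns a DataFrame (set_name, size, es, nes, p_value, q_value,
    leading_edge) sorted by p then name.
    """
    if n_permutations < 100:
        raise ParameterError("n_permutations must be >= 100")
    if permutation_type not in ("gene_set", "phenotype"):
        raise ParameterError(f"unknown permutation_type {permutation_type!r}")
    n_ctrl = len(matrix.samples_in_group(control))
    n_trt = len(matrix.samples_in_group(treated))
    if permutation_type == "phenotype" and min(n_ctrl, n_trt) < 3:
        logger.warning(
            "phenotype permutation needs >=3 samples/group (have %d/%d); "
            "falling back to gene_set permutation", n_ctrl, n_trt,
        )
        permutation_type = "gene_set"

    results = differential_table(matrix, control=control, treated=treated)
    ranked = rank_features(results, metric=metric)
    universe = set(ranked["feature"])
    N = len(universe)

    kept: list[tuple[str, set[str]]] = []
    for name, members in pathways:
        inter = set(members) & universe
        if min_size <= len(inter) <= max_size and len(inter) < N:
            kept.append((name, inter))
    if not kept:
        raise ParameterError(
            f"no gene set within size bounds [{min_size}, {max_size}] after "
            "intersection with the ranked universe"
        )

    obs = {}
    run = {}
    for name, members in kept:
        es, running = gsea_es(ranked, members, weight_exponent)
        obs[name] = es
        run[name] = running

    rng = np.random.default_rng(child_seed(seed, "gsea"))
    if permutation_type == "gene_set":
        perm_es = _geneset_permutations(ranked, kept, n_permutations, weight_exponent, rng)
    else:
        perm_es = _phenotype_permutations(
            matrix, kept, control, treated, n_permutations, weight_exponent, metric, rng
        )

    rows = []
    nes_obs = {}
    nes_perm_all = []
    for name, members in kept:
        es = obs[name]
        perms = perm_es[name]
        same = perms[np.sign(perms) == np.sign(es)] if es != 0 else perms
        if len(same) == 0:
            nes, p = np.nan, 1.0 / (n_permutations + 1)
            nes_perm = np.array([])
        else:
            denom = np.abs(same).mean()
            nes = es / denom if denom > 0 else np.nan
            p = (1 + int((np.abs(same) >= abs(es)).sum())) / (1 + len(same))
            nes_perm = perms / denom
        nes_obs[name] = nes
        nes_perm_all.append(nes_perm)
        rows.append({
            "set_name": name, "size": len(members), "es": es, "nes": nes,
            "p_value": p,
            "leading_edge": ",".join(leading_edge(ranked, members, run[name])),
        })

    pooled = np.concatenate(nes_perm_all) if nes_perm_all else np.array([])
    obs_nes = np.array([nes_obs[name] for name, _ in kept])
    qs = {}
    for name, _ in kept:
        qs[name] = _gsea_fdr(nes_obs[name], obs_nes, pooled)
    out = pd.DataFrame(rows)
    out["q_value"] = [qs[r["set_name"]] for r in rows]
    out = out[["set_name", "size", "es", "nes", "p_value", "q_value", "leading_edge"]]
    return out.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)


def _gsea_fdr(nes: float, obs_nes: np.ndarray, pooled: np.ndarray) -> float:
    """Sign-stratified pooled FDR for one observed NES."""
    if not np.isfinite(nes):
        return float("nan")
    sign = 1.0 if nes >= 0 else -1.0
    pool_same = pooled[np.sign(pooled) == sign] if len(pooled) else pooled
    obs_same = obs_nes[np.isfinite(obs_nes) & (np.sign(obs_nes) == sign)]
    if len(pool_same) == 0 or len(obs_same) == 0:
        return float("nan")
    num = (np.abs(pool_same) >= abs(nes)).mean()
    den = (np.abs(obs_same) >= abs(nes)).mean()
    if den == 0:
        return float("nan")
    return float(min(1.0, num / den))


def _geneset_permutations(
    ranked: pd.DataFrame,
    kept: list[tuple[str, set[str]]],
    n_permutations: int,
    weight_exponent: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Null ES per set from random same-size position draws (shared by size)."""
    N = len(ranked)
    absw = np.abs(ranked["score"].to_numpy(dtype=float)) ** weight_exponent
    by_size: dict[int, np.ndarray] = {}
    for size in sorted({len(m) for _, m in kept}):
        es = np.empty(n_permutations)
        for i in range(n_permutations):
            pos = np.sort(rng.choice(N, size=size, replace=False))
            es[i] = _es_from_positions(pos, absw[pos], N)
        by_size[size] = es
    return {name: by_size[len(members)] for name, members in kept}


def _phenotype_permutations(
    matrix: ExpressionMatrix,
    kept: list[tuple[str, set[str]]],
    control: str,
    treated: str,
    n_permutations: int,
    weight_exponent: float,
    metric: str,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Null ES per set from group-label permutations (ranking recomputed)."""
    ctrl = matrix.samples_in_group(control)
    trt = matrix.samples_in_group(treated)
    cols = ctrl + trt
    X = matrix.values[cols].to_numpy(dtype=float)
    n_c = len(ctrl)
    features = matrix.values.index.to_numpy()

    out = {name: np.empty(n_permutations) for name, _ in kept}
    member_arrays = {name: np.array(sorted(m)) for name, m in kept}
    for i in range(n_permutations):
        perm = rng.permutation(X.shape[1])
        scores = _metric_scores(X[:, perm[n_c:]], X[:, perm[:n_c]], metric)
        order = np.lexsort((features, -scores))
        feats_sorted = features[order]
        scores_sorted = scores[order]
        rdf = pd.DataFrame({"feature": feats_sorted, "score": scores_sorted})
        for name in out:
            es, _ = gsea_es(rdf, member_arrays[name], weight_exponent)
            out[name][i] = es
    return out


def _metric_scores(Xt: np.ndarray, Xc: np.ndarray, metric: str) -> np.ndarray:
    """Vectorized per-feature ranking scores for permuted labels."""
    mt, mc = Xt.mean(axis=1), Xc.mean(axis=1)
    vt = Xt.var(axis=1, ddof=1) / Xt.shape[1]
    vc = Xc.var(axis=1, ddof=1) / Xc.shape[1]
    se = np.sqrt(vt + vc)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mt - mc) / se
    t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
    if metric == "t":
        return t
    if metric == "log2fc":
        return mt - mc
    # signed_log_p
    df = (vt + vc) ** 2 / (
        vt**2 / max(Xt.shape[1] - 1, 1) + vc**2 / max(Xc.shape[1] - 1, 1)
    )
    p = np.clip(2.0 * stats.t.sf(np.abs(t), df), 1e-300, 1.0)
    return np.sign(t) * (-np.log10(p))
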