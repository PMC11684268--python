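"""Random-Forest classification of exposure groups from metabolite profiles.

A bagged ensemble of randomized decision trees (CART with sqrt-feature
subsampling at each split) is trained on log2 abundances, with
below-detection values min-imputed per metabolite.  Accuracy is estimated
out-of-bag by default — each sample scored only by the trees whose
bootstrap missed it — with leave-one-out cross-validation offered because
out-of-bag estimates are noisy at metabolomics-scale designs (n = 5/group).

Feature relevance is out-of-bag permutation importance: per tree, the drop
in out-of-bag accuracy when one metabolite's values are shuffled, averaged
over the ensemble.  Unlike impurity-based importance it is comparable
across abundance scales, and scoring on held-out samples avoids rewarding
overfit splits.  The ranking feeds the familiar "biochemical importance"
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .errors import ParameterError
from .diffexpr import impute_min
from .ioformats import MetaboliteTable
from .synthdata import child_seed

logger = logging.getLogger("kdapipe.classify")


@dataclass
class ClassificationReport:
    """Outcome of one forest run: accuracy, confusion and ranked importance."""

    accuracy_estimate: float
    scheme: str
    classes: list[str]
    confusion: pd.DataFrame  # true class x predicted class counts
    importance: pd.DataFrame  # metabolite, importance, super_pathway (ranked)
    n_trees: int
    seed: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy_estimate": self.accuracy_estimate,
            "scheme": self.scheme,
            "classes": self.classes,
            "confusion": {
                t: {p: int(self.confusion.loc[t, p]) for p in self.confusion.columns}
                for t in self.confusion.index
            },
            "n_trees": self.n_trees,
            "seed": self.seed,
            "params": self.params,
        }


def _design_matrix(table: MetaboliteTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    fully_missing = table.abundances.index[table.abundances.isna().all(axis=1)]
    if len(fully_missing):
        raise ParameterError(
            f"metabolite(s) entirely missing: {', '.join(map(str, fully_missing[:5]))}"
        )
    imputed = impute_min(table.abundances)
    with np.errstate(divide="ignore"):
        X = np.log2(imputed.to_numpy(dtype=float).T)  # samples x features
    y = np.array([table.groups[s] for s in table.sample_ids])
    return X, y, table.metabolite_ids


class _Forest:
    """CART-tree ensemble with feature subsampling, optional bagging.

    With ``bootstrap=True`` each tree sees a bootstrap resample and records
    its out-of-bag indices.  With ``bootstrap=False`` every tree is grown on
    the full sample and differs only through the random feature subsets
    considered at each split (the random-subspace variant) — preferable at
    very small n, where a bootstrap both discards a third of the samples
    and lets noise features separate the in-bag points perfectly by chance.
    """

    def __init__(self, X: np.ndarray, y_codes: np.ndarray, n_classes: int,
                 n_trees: int, rng: np.random.Generator, bootstrap: bool = True):
        n = len(y_codes)
        self.n_classes = n_classes
        self.trees: list[DecisionTreeClassifier] = []
        self.oob: list[np.ndarray] = []
        for _ in range(n_trees):
            idx = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
            # balanced class weights: leave-one-out folds are inherently
            # imbalanced (4 vs 5), which would bias uninformative trees
            # toward the majority class
            tree = DecisionTreeClassifier(
                max_features="sqrt",
                class_weight="balanced",
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], y_codes[idx])
            self.trees.append(tree)
            self.oob.append(np.setdiff1d(np.arange(n), idx))

    def predict(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros((len(X), self.n_classes), dtype=int)
        for tree in self.trees:
            pred = tree.predict(X).astype(int)
            votes[np.arange(len(X)), pred] += 1
        return votes.argmax(axis=1)

    def oob_predict(self, X: np.ndarray) -> np.ndarray:
        """Majority out-of-bag vote per sample; -1 where no tree held it out."""
        votes = np.zeros((len(X), self.n_classes), dtype=int)
        for tree, oob in zip(self.trees, self.oob):
            if len(oob) == 0:
                continue
            pred = tree.predict(X[oob]).astype(int)
            votes[oob, pred] += 1
        out = votes.argmax(axis=1)
        out[votes.sum(axis=1) == 0] = -1
        return out

    def oob_permutation_importance(
        self, X: np.ndarray, y_codes: np.ndarray,
        rng: np.random.Generator, n_repeats: int = 5,
    ) -> np.ndarray:
        """Mean per-tree drop in out-of-bag accuracy under feature shuffling.

        Only features a tree actually splits on can change its predictions,
        so each tree evaluates just its own split features (the rest
        contribute an exact zero), stacked into a single predict call.
        """
        d = X.shape[1]
        imp = np.zeros(d)
        for tree, oob in zip(self.trees, self.oob):
            if len(oob) < 1:
                continue
            Xo = X[oob]
            yo = y_codes[oob]
            base = (tree.predict(Xo).astype(int) == yo).mean()
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            if len(used) == 0:
                continue
            blocks = []
            for f in used:
                for _ in range(n_repeats):
                    Xp = Xo.copy()
                    Xp[:, f] = Xo[rng.permutation(len(oob)), f]
                    blocks.append(Xp)
            preds = tree.predict(np.vstack(blocks)).astype(int)
            acc = (
                (preds == np.tile(yo, len(blocks)))
                .reshape(len(used), n_repeats, len(oob))
                .mean(axis=(1, 2))
            )
            imp[used] += base - acc
        return imp / len(self.trees)


def _leave_one_per_class_out(
    X: np.ndarray, y_codes: np.ndarray, n_classes: int,
    n_trees: int, rng: np.random.Generator,
) -> np.ndarray:
    """Cross-validated predictions with one held-out sample per class.

    Plain leave-ONE-out makes every training fold class-imbalanced (e.g. 4
    vs 5 at n=5/group); with hundreds of trees the small majority tilt of
    uninformative trees is amplified by the vote into systematically wrong
    predictions for the held-out sample.  Holding out one sample per class
    keeps every fold balanced, so null-data accuracy sits at chance.  Each
    sample's final call aggregates the tree votes from every fold that held
    it out.
    """
    by_class = [np.where(y_codes == c)[0] for c in range(n_classes)]
    votes = np.zeros((len(y_codes), n_classes), dtype=int)
    from itertools import product
    folds = list(product(*by_class))  # one held-out index per class
    # each sample is held out in several folds; split the ensemble budget so
    # every sample still accumulates ~n_trees held-out votes
    folds_per_sample = min(len(folds) // len(idx) for idx in by_class)
    per_fold = max(1, -(-n_trees // folds_per_sample))
    for combo in folds:
        held = np.array(combo)
        train = np.setdiff1d(np.arange(len(y_codes)), held)
        fold = _Forest(X[train], y_codes[train], n_classes, per_fold, rng,
                       bootstrap=False)
        for tree in fold.trees:
            pred = tree.predict(X[held]).astype(int)
            votes[held, pred] += 1
    return votes.argmax(axis=1)


def rf_classify(
    table: MetaboliteTable,
    n_trees: int = 500,
    scheme: str = "auto",
    seed: int = 0,
    n_importance_repeats: int = 5,
) -> ClassificationReport:
    """Classify sample groups from metabolite abundances with a Random Forest.

    ``scheme="oob"`` scores each sample by the bagged trees that did not see
    it in their bootstrap (requires >= 3 samples per group).
    ``scheme="loocv"`` grows a random-subspace forest (full-sample trees,
    feature subsampling only) once per held-out sample — the appropriate
    estimate for metabolomics-scale designs, where bootstrapping n <= 10
    samples makes out-of-bag votes dominated by chance in-bag separators.
    ``"auto"`` picks loocv when the smallest group has <= 5 samples, oob
    otherwise.  Importance is always out-of-bag permutation importance from
    a bagged forest on the full table.  Accuracy and the importance ranking
    are deterministic under a fixed seed.
    """
    X, y, metabolites = _design_matrix(table)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("need >= 2 groups to classify")
    if scheme == "auto":
        scheme = "loocv" if counts.min() <= 5 else "oob"
    if scheme not in ("oob", "loocv"):
        raise ParameterError(f"scheme must be 'oob', 'loocv' or 'auto', got {scheme!r}")
    if scheme == "oob" and counts.min() < 3:
        raise ParameterError(
            "out-of-bag accuracy needs >= 3 samples/group; use scheme='loocv'"
        )
    code = {c: i for i, c in enumerate(classes)}
    y_codes = np.array([code[v] for v in y])

    rng = np.random.default_rng(child_seed(seed, "classify"))
    forest = _Forest(X, y_codes, len(classes), n_trees, rng, bootstrap=True)

    if scheme == "oob":
        pred_codes = forest.oob_predict(X)
        voted = pred_codes >= 0
        if not voted.all():
            logger.info("%d sample(s) with no out-of-bag vote", int((~voted).sum()))
        accuracy = float((pred_codes[voted] == y_codes[voted]).mean()) if voted.any() else float("nan")
    else:
        pred_codes = _leave_one_per_class_out(X, y_codes, len(classes), n_trees, rng)
        voted = np.ones(len(y), dtype=bool)
        accuracy = float((pred_codes == y_codes).mean())

    confusion = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for truth, guess in zip(y_codes[voted], pred_codes[voted]):
        confusion.iloc[truth, guess] += 1

    imp = forest.oob_permutation_importance(
        X, y_codes, rng, n_repeats=n_importance_repeats)
    importance = pd.DataFrame({
        "metabolite": metabolites,
        "importance": imp,
        "super_pathway": table.annotations["super_pathway"].to_numpy(),
    })
    importance = importance.sort_values(
        ["importance", "metabolite"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)

    return ClassificationReport(
        accuracy_estimate=accuracy,
        scheme=scheme,
        classes=[str(c) for c in classes],
        confusion=confusion,
        importance=importance,
        n_trees=n_trees,
        seed=seed,
        params={"n_importance_repeats": n_importance_repeats},
    )


def importance_table(report: ClassificationReport) -> pd.DataFrame:
    """Ranked importance table: rank, metabolite, importance, super_pathway."""
    out = report.importance.copy()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
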