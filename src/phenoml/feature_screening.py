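"""All-relevant feature selection with shadow features (Boruta-style).

Each iteration appends one permuted "shadow" copy of every still-undecided
real feature, fits a random forest, and scores each feature with the
Z-score of its out-of-bag permutation importance (mean accuracy loss over
trees divided by its standard error).  A real feature scores a *hit* when
its Z-score exceeds the maximum shadow Z-score.  Accuracy-loss Z-scores —
rather than raw impurity shares — are essential here: greedy impurity
importance is strongly convex in a feature's sample correlation with the
response, so the single most chance-correlated noise feature beats every
freshly permuted shadow almost deterministically and is falsely confirmed.
Accumulated hits are tested against the Binomial(iterations, 1/2) null
with two one-sided binomial tests at level ``alpha``, Bonferroni-corrected
over the undecided features: significantly many hits confirm a feature,
significantly few reject it.  Features still undecided at ``max_iter`` are
reported tentative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

__all__ = ["ScreeningResult", "boruta_screen"]


@dataclass
class ScreeningResult:
    """Outcome of a shadow-feature screen; the three sets partition the input."""

    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    hits: dict[str, int]
    n_iter: int
    alpha: float
    max_iter: int

    def retained(self) -> list[str]:
        """Features passed on to models: confirmed plus tentative
        (all-relevant philosophy keeps undecided candidates)."""
        return self.confirmed + self.tentative

    def to_dict(self) -> dict:
        return {
            "confirmed": self.confirmed,
            "rejected": self.rejected,
            "tentative": self.tentative,
            "hits": self.hits,
            "n_iter": self.n_iter,
            "alpha": self.alpha,
            "max_iter": self.max_iter,
        }


def _shadow_design(
    X: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Append one independently row-permuted copy per real column."""
    shadows = np.column_stack(
        [rng.permutation(X[:, j]) for j in range(X.shape[1])]
    )
    return np.hstack([X, shadows]), X.shape[1]


def _oob_permutation_z(
    design: np.ndarray,
    y: np.ndarray,
    seed: int,
    rng: np.random.Generator,
    n_estimators: int,
) -> np.ndarray:
    """Z-scores of out-of-bag permutation importance for every column.

    For each tree, each column is permuted among that tree's out-of-bag
    rows and the increase in out-of-bag MSE recorded; the Z-score is the
    across-tree mean divided by its standard error.
    """
    n, p = design.shape
    rf = RandomForestRegressor(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    ).fit(design, y)
    per_tree = np.empty((n_estimators, p))
    for t, tree in enumerate(rf.estimators_):
        # reproduce sklearn's bootstrap draw for this tree to find OOB rows
        sampled = np.random.RandomState(tree.random_state).randint(0, n, n)
        oob = np.ones(n, dtype=bool)
        oob[sampled] = False
        Xo = design[oob]
        yo = y[oob]
        m = len(yo)
        base = ((tree.predict(Xo) - yo) ** 2).mean()
        big = np.broadcast_to(Xo, (p, m, p)).copy()
        for j in range(p):
            big[j, :, j] = rng.permutation(Xo[:, j])
        preds = tree.predict(big.reshape(p * m, p)).reshape(p, m)
        per_tree[t] = ((preds - yo) ** 2).mean(axis=1) - base
    mu = per_tree.mean(axis=0)
    se = per_tree.std(axis=0, ddof=1) / np.sqrt(n_estimators)
    return mu / (se + 1e-12)


def boruta_screen(
    X: pd.DataFrame,
    y,
    max_iter: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
    n_estimators: int = 100,
) -> ScreeningResult:
    """Screen ``X`` for all features relevant to ``y``.

    ``X`` may contain NaNs (median-imputed internally, zero for all-NaN
    columns); ``y`` must be non-constant.  Deterministic for fixed seed.
    """
    if max_iter < 20:
        raise ValueError("max_iter must be >= 20")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    y = np.asarray(y, dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError("constant response; nothing to screen")

    names = list(X.columns)
    Xi = X.fillna(X.median()).fillna(0.0).to_numpy(dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(7,)))

    undecided = list(range(len(names)))
    hits = np.zeros(len(names), dtype=int)
    confirmed: list[int] = []
    rejected: list[int] = []
    n_iter = 0
    for it in range(1, max_iter + 1):
        n_iter = it
        sub = Xi[:, undecided]
        design, n_real = _shadow_design(sub, rng)
        z = _oob_permutation_z(
            design, y, int(rng.integers(2**31)), rng, n_estimators
        )
        max_shadow = z[n_real:].max() if n_real else 0.0
        for k, j in enumerate(undecided):
            if z[k] > max_shadow:
                hits[j] += 1
        threshold = alpha / len(undecided)
        still = []
        for j in undecided:
            p_hi = stats.binom.sf(hits[j] - 1, it, 0.5)  # P(H >= hits)
            p_lo = stats.binom.cdf(hits[j], it, 0.5)  # P(H <= hits)
            if p_hi < threshold:
                confirmed.append(j)
            elif p_lo < threshold:
                rejected.append(j)
            else:
                still.append(j)
        undecided = still
        if not undecided:
            break

    return ScreeningResult(
        confirmed=[names[j] for j in sorted(confirmed)],
        rejected=[names[j] for j in sorted(rejected)],
        tentative=[names[j] for j in sorted(undecided)],
        hits={names[j]: int(hits[j]) for j in range(len(names))},
        n_iter=n_iter,
        alpha=alpha,
        max_iter=max_iter,
    )
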