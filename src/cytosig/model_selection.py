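"""Latent-variable selection and model significance testing.

The number of latent variables is chosen by repeated random-subsampling
cross-validation: the held-out set is one third of the samples when n > 30
and one fifth when n <= 30, candidate models with 1..5 components are
scored on every split (RMSECV for numeric responses, classification
accuracy for discriminant models), and the component count with the best
mean score wins (ties go to the smaller model).

Significance is assessed by a permutation test that shuffles the response,
re-runs the identical cross-validation at the chosen component count, and
compares the observed score with the Gaussian fit (mean, SD) of the null
score distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError
from . import pls

__all__ = [
    "CvResult",
    "PermutationResult",
    "make_splits",
    "rmsecv",
    "cross_validate",
    "permutation_test",
]


def rmsecv(predicted, actual) -> float:
    """Root mean squared error over one held-out test set:
    sqrt( Σ_j (P_j − A_j)² / n )."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.size == 0:
        raise FitError("rmsecv: empty input")
    if p.shape != a.shape:
        raise FitError("rmsecv: length mismatch")
    return float(np.sqrt(np.mean((p - a) ** 2)))


def _test_size(n: int) -> int:
    # one third of the data when n > 30, one fifth otherwise (n = 30
    # exactly falls to the 1/5 rule)
    return int(np.round(n / 3)) if n > 30 else int(np.round(n / 5))


def make_splits(
    n: int,
    n_iter: int = 100,
    seed: int = 0,
    *,
    labels: Optional[Sequence] = None,
):
    """Repeated random-subsampling train/test splits.

    ``labels`` triggers stratification (used for discriminant models): the
    test set takes a proportional share of each class, and every class is
    guaranteed at least one training member.  Deterministic given ``seed``.
    """
    if n < 5:
        raise FitError(f"make_splits: need n >= 5, got {n}")
    rng = np.random.default_rng(seed)
    n_test = _test_size(n)
    splits = []
    if labels is None:
        for _ in range(n_iter):
            perm = rng.permutation(n)
            splits.append((np.sort(perm[n_test:]), np.sort(perm[:n_test])))
        return splits
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        bad = classes[counts < 2].tolist()
        raise FitError(f"make_splits: class(es) {bad} have < 2 members")
    # proportional per-class test counts (largest remainder), capped so
    # each class keeps at least one training sample
    raw = counts * n_test / n
    base = np.floor(raw).astype(int)
    rem = n_test - base.sum()
    order = np.argsort(-(raw - base))
    for k in order[:rem]:
        base[k] += 1
    base = np.minimum(base, counts - 1)
    idx_by_class = [np.flatnonzero(labels == c) for c in classes]
    for _ in range(n_iter):
        test = np.concatenate(
            [rng.permutation(ix)[:m] for ix, m in zip(idx_by_class, base)]
        )
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        splits.append((np.flatnonzero(mask), np.sort(test)))
    return splits


@dataclass
class CvResult:
    candidates: list
    scores: np.ndarray  # n_candidates x n_iterations
    mean_scores: np.ndarray
    chosen: int
    mode: str  # "rmsecv" | "accuracy"
    n_iterations: int
    test_size: int
    n_failures: int = 0

    @property
    def chosen_score(self) -> float:
        return float(self.mean_scores[self.candidates.index(self.chosen)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores.T, columns=[f"A={a}" for a in self.candidates])
        df.index.name = "iteration"
        return df


def _cv_scores(X, response, candidates, splits, mode, classes=None):
    """Score every candidate LV count on every split. Core loop, array-only."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(response)
    n_cand = len(candidates)
    out = np.full((n_cand, len(splits)), np.nan)
    failures = 0
    for it, (tr, te) in enumerate(splits):
        Xtr, Xte = X[tr], X[te]
        mean = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        if (sd <= 1e-12).any():
            failures += 1
            continue
        Xs = (Xtr - mean) / sd
        Xts = (Xte - mean) / sd
        if mode == "accuracy":
            Ytr = np.column_stack([(y[tr] == c).astype(float) for c in classes])
        else:
            Ytr = y[tr].astype(float)[:, None]
        ym = Ytr.mean(axis=0)
        ysd = Ytr.std(axis=0, ddof=1)
        if (ysd <= 1e-12).any():
            failures += 1
            continue
        Ys = (Ytr - ym) / ysd
        a_req = min(max(candidates), len(tr) - 1, X.shape[1])
        while a_req >= 1:
            # residual exhaustion (exact fits) degrades gracefully to the
            # largest attainable component count
            try:
                W, P, T, Q = pls._nipals(Xs, Ys, a_req)
                break
            except FitError:
                a_req -= 1
        else:
            failures += 1
            continue
        for ci, a in enumerate(candidates):
            a_eff = min(a, T.shape[1])
            Wstar = W[:, :a_eff] @ np.linalg.inv(P[:, :a_eff].T @ W[:, :a_eff])
            B = Wstar @ Q[:, :a_eff].T
            Yhat = (Xts @ B) * ysd + ym
            if mode == "accuracy":
                pred = np.argmax(Yhat, axis=1)
                truth = np.array([classes.index(v) for v in y[te]])
                out[ci, it] = float(np.mean(pred == truth))
            else:
                out[ci, it] = rmsecv(Yhat[:, 0], y[te])
    return out, failures


def cross_validate(
    X,
    response,
    candidates: Sequence[int] = (1, 2, 3, 4, 5),
    splits=None,
    *,
    n_iter: int = 100,
    seed: int = 0,
) -> CvResult:
    """Choose the latent-variable count by repeated-subsampling CV.

    Numeric responses are scored by per-test-set RMSECV (averaged across
    iterations); class labels by classification accuracy.  Autoscaling is
    refit on every training fold.  Iterations where a fit fails are skipped
    and counted; more than 10% failures raises.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(response)
    candidates = sorted(candidates)
    numeric = y.dtype.kind in "fiu"
    mode = "rmsecv" if numeric else "accuracy"
    classes = None if numeric else sorted(pd.unique(y).tolist())
    if splits is None:
        splits = make_splits(
            len(y), n_iter=n_iter, seed=seed,
            labels=None if numeric else y,
        )
    scores, failures = _cv_scores(X, y, candidates, splits, mode, classes)
    if failures > 0.1 * len(splits):
        raise FitError(
            f"cross_validate: {failures}/{len(splits)} iterations failed"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(scores, axis=1)
    # best mean score; ties resolved toward the smaller model
    best = np.nanmin(means) if mode == "rmsecv" else np.nanmax(means)
    ok = np.isclose(means, best, rtol=0, atol=1e-12)
    chosen = candidates[int(np.flatnonzero(ok)[0])]
    return CvResult(
        candidates=list(candidates),
        scores=scores,
        mean_scores=means,
        chosen=chosen,
        mode=mode,
        n_iterations=len(splits),
        test_size=len(splits[0][1]),
        n_failures=failures,
    )


@dataclass
class PermutationResult:
    observed: float
    null_scores: np.ndarray
    null_mean: float
    null_sd: float
    z: float
    p_value: float
    n_permutations: int
    n_lv: int
    mode: str
    seed: int


def permutation_test(
    X,
    response,
    n_lv: int,
    n_perm: int = 100,
    seed: int = 0,
    *,
    n_iter: int = 100,
) -> PermutationResult:
    """Model significance by response-shuffling.

    Each permutation shuffles the response across samples (the predictor
    landscape is untouched), reruns the full repeated-subsampling CV at the
    fixed component count, and records the mean score.  The p-value is the
    one-sided Gaussian tail of z = (observed − μ₀)/σ₀ — upper tail for
    accuracy, lower tail for RMSECV.
    """
    if n_perm < 20:
        raise FitError("permutation_test: need n_perm >= 20")
    X = np.asarray(X, dtype=float)
    y = np.asarray(response)
    numeric = y.dtype.kind in "fiu"
    mode = "rmsecv" if numeric else "accuracy"
    classes = None if numeric else sorted(pd.unique(y).tolist())
    rng = np.random.default_rng(seed)

    def _mean_score(resp, split_seed):
        splits = make_splits(
            len(resp), n_iter=n_iter, seed=split_seed,
            labels=None if numeric else resp,
        )
        scores, failures = _cv_scores(X, resp, [n_lv], splits, mode, classes)
        if failures > 0.1 * len(splits):
            raise FitError("permutation_test: too many failed CV iterations")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(np.nanmean(scores))

    sub = rng.integers(0, 2**31 - 1, size=n_perm + 1)
    observed = _mean_score(y, int(sub[0]))
    null = np.array(
        [_mean_score(rng.permutation(y), int(sub[k + 1])) for k in range(n_perm)]
    )
    mu0, sd0 = float(null.mean()), float(null.std(ddof=1))
    if sd0 <= 0:
        raise FitError("permutation_test: degenerate null (zero variance)")
    z = (observed - mu0) / sd0
    p = float(stats.norm.sf(z)) if mode == "accuracy" else float(stats.norm.cdf(z))
    p = min(max(p, np.nextafter(0, 1)), np.nextafter(1, 0))
    return PermutationResult(
        observed=observed,
        null_scores=null,
        null_mean=mu0,
        null_sd=sd0,
        z=float(z),
        p_value=p,
        n_permutations=n_perm,
        n_lv=n_lv,
        mode=mode,
        seed=seed,
    )
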