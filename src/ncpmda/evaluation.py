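"""Cross-validation frameworks and rank-based ROC/AUC.

Three validation schemes are provided, mirroring how link-prediction
methods on bipartite association networks are conventionally benchmarked:

* **global LOOCV** -- each known association is masked in turn and its score
  is ranked against every pair unknown in the *original* network;
* **local LOOCV** -- same masking, but the left-out pair competes only
  against the unknown microbes of its own disease;
* **repeated k-fold CV** -- the positives are randomly split into k groups;
  each group is masked wholesale and ranked against the unknown pairs, and
  the split is repeated to average out partition noise.

Because the GIP kernels are themselves functions of the adjacency matrix,
leaving the test association inside them leaks the test label through the
similarity network. All three schemes therefore recompute the kernels from
the masked matrix by default; ``recompute_kernels=False`` switches to
kernels trained once on the full matrix, which is useful for quantifying
exactly how much that leakage inflates the AUC.

AUC follows the mid-rank (Mann-Whitney) convention: ties between a test
score and a candidate score count one half. The ROC curve is produced by
sweeping a threshold over the pooled score values, so its trapezoidal area
coincides with the Mann-Whitney statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .associations import AssociationNetwork
from .gip import KernelSimilarityMatrix, disease_kernel, microbe_kernel
from .projection import (
    combine_projections,
    disease_space_projection,
    microbe_space_projection,
    predict,
)

__all__ = ["CVResult", "rank_based_roc", "global_loocv", "local_loocv", "kfold_cv"]


@dataclass(frozen=True)
class CVResult:
    """Outcome of one cross-validation run.

    ``roc`` is an ``(n, 2)`` array of (FPR, TPR) points from (0, 0) to
    (1, 1); ``ranks`` holds, per test case, the mid-rank of the test score
    within {test} u candidates together with that candidate-set size (the
    set including the test pair itself). ``auc_mean``/``auc_sd`` summarise
    fold-level AUCs for k-fold CV; for the LOOCV modes they are None.
    """

    mode: str
    auc: float
    roc: np.ndarray
    ranks: tuple[tuple[float, int], ...]
    repeats: int = 1
    seed: int | None = None
    folds: np.ndarray | None = None
    auc_mean: float | None = None
    auc_sd: float | None = None
    n_skipped: int = 0
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# rank-based ROC / AUC
# ---------------------------------------------------------------------------


def _midrank_auc(test_scores: np.ndarray, candidate_scores: np.ndarray) -> float:
    """Mann-Whitney AUC, ties counted one half, via mid-ranks."""
    nt, nc = len(test_scores), len(candidate_scores)
    ranks = rankdata(np.concatenate([test_scores, candidate_scores]))
    return float((ranks[:nt].sum() - nt * (nt + 1) / 2) / (nt * nc))


def rank_based_roc(
    test_scores: Sequence[float],
    candidate_scores: Sequence[float],
    max_points: int | None = None,
) -> tuple[np.ndarray, float]:
    """ROC points and AUC for test scores ranked among candidate scores.

    Thresholds sweep the pooled score values in descending order; at each
    threshold TPR is the fraction of test scores strictly above it plus half
    the ties, FPR likewise over candidates. The returned AUC is the exact
    Mann-Whitney statistic P(test > candidate) + 1/2 P(test = candidate); the
    curve's trapezoidal area equals it. ``max_points`` thins the stored curve
    (endpoints kept) without affecting the AUC.
    """
    tests = np.asarray(test_scores, dtype=float)
    cands = np.asarray(candidate_scores, dtype=float)
    if tests.size == 0 or cands.size == 0:
        raise ValueError("test and candidate score lists must be non-empty")
    auc = _midrank_auc(tests, cands)

    thresholds = np.unique(np.concatenate([tests, cands]))[::-1]
    tests_sorted = np.sort(tests)
    cands_sorted = np.sort(cands)

    def _rates(sorted_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # per threshold value: strictly above plus half the exact ties
        # (the mid-rank operating point), and above-or-equal (the end of
        # the tie diagonal, needed for the curve to integrate exactly)
        right = np.searchsorted(sorted_scores, thresholds, side="right")
        left = np.searchsorted(sorted_scores, thresholds, side="left")
        above = sorted_scores.size - right
        mid = (above + 0.5 * (right - left)) / sorted_scores.size
        full = (above + (right - left)) / sorted_scores.size
        return mid, full

    tpr_mid, tpr_full = _rates(tests_sorted)
    fpr_mid, fpr_full = _rates(cands_sorted)
    # interleave: ..., mid point at v, end of v's tie diagonal, ...
    fpr = np.empty(2 * thresholds.size + 1)
    tpr = np.empty_like(fpr)
    fpr[0] = tpr[0] = 0.0
    fpr[1::2], fpr[2::2] = fpr_mid, fpr_full
    tpr[1::2], tpr[2::2] = tpr_mid, tpr_full
    roc = np.vstack([fpr, tpr]).T  # last full point is (1, 1) by construction
    if max_points is not None and roc.shape[0] > max_points:
        idx = np.unique(
            np.linspace(0, roc.shape[0] - 1, max_points).round().astype(int)
        )
        roc = roc[idx]
    return roc, auc


def _rank_among(test: float, cands: np.ndarray) -> tuple[float, int]:
    """Mid-rank of ``test`` within {test} u candidates (1 = top)."""
    above = int((cands > test).sum())
    ties = int((cands == test).sum())
    return 1.0 + above + 0.5 * ties, cands.size + 1


# ---------------------------------------------------------------------------
# fold machinery
# ---------------------------------------------------------------------------


def _masked_score_matrix(
    net: AssociationNetwork,
    mask_pairs: np.ndarray,
    gamma_prime_d: float,
    gamma_prime_m: float,
    recompute_kernels: bool,
    KD0: KernelSimilarityMatrix | None,
    KM0: KernelSimilarityMatrix | None,
) -> np.ndarray:
    """Score matrix after zeroing ``mask_pairs`` (rows of (i, j) indices)."""
    A = np.array(net.A, dtype=np.int8)
    A[mask_pairs[:, 0], mask_pairs[:, 1]] = 0
    masked = net.with_matrix(A)
    if recompute_kernels:
        return predict(masked, gamma_prime_d, gamma_prime_m).S
    ncp_d = disease_space_projection(KD0, masked)
    ncp_m = microbe_space_projection(masked, KM0)
    return combine_projections(ncp_d, ncp_m, KD0, KM0, masked).S


def _prepare(
    net: AssociationNetwork,
    gamma_prime_d: float,
    gamma_prime_m: float,
    recompute_kernels: bool,
):
    positives = np.argwhere(net.A == 1)
    zero_mask = np.asarray(net.A) == 0
    KD0 = KM0 = None
    if not recompute_kernels:
        KD0 = disease_kernel(net, gamma_prime_d)
        KM0 = microbe_kernel(net, gamma_prime_m)
    return positives, zero_mask, KD0, KM0


# ---------------------------------------------------------------------------
# the three frameworks
# ---------------------------------------------------------------------------


def global_loocv(
    net: AssociationNetwork,
    gamma_prime_d: float = 1.0,
    gamma_prime_m: float = 1.0,
    recompute_kernels: bool = True,
    max_roc_points: int | None = 2001,
) -> CVResult:
    """Leave-one-association-out CV against all unknown pairs.

    Each known association is zeroed in turn, the model is refit on the
    masked matrix, and the left-out pair's score is pooled -- together with
    that fold's scores for every pair unknown in the original network --
    into one threshold sweep. Deterministic.
    """
    positives, zero_mask, KD0, KM0 = _prepare(
        net, gamma_prime_d, gamma_prime_m, recompute_kernels
    )
    if len(positives) < 2:
        raise ValueError("global LOOCV needs at least two known associations")
    test_scores = np.empty(len(positives))
    candidate_scores = []
    ranks = []
    for f, (i, j) in enumerate(positives):
        S = _masked_score_matrix(
            net, positives[f : f + 1], gamma_prime_d, gamma_prime_m,
            recompute_kernels, KD0, KM0,
        )
        test_scores[f] = S[i, j]
        cands = S[zero_mask]
        candidate_scores.append(cands)
        ranks.append(_rank_among(S[i, j], cands))
    roc, auc = rank_based_roc(
        test_scores, np.concatenate(candidate_scores), max_points=max_roc_points
    )
    return CVResult(
        mode="global_loocv",
        auc=auc,
        roc=roc,
        ranks=tuple(ranks),
        params={
            "gamma_prime_d": gamma_prime_d,
            "gamma_prime_m": gamma_prime_m,
            "recompute_kernels": recompute_kernels,
        },
    )


def local_loocv(
    net: AssociationNetwork,
    gamma_prime_d: float = 1.0,
    gamma_prime_m: float = 1.0,
    recompute_kernels: bool = True,
) -> CVResult:
    """Leave-one-out CV against the unknown microbes of the same disease.

    Every fold contributes one per-case AUC (the left-out pair vs its local
    candidates); the overall AUC is their unweighted mean. Folds whose
    disease has no unknown microbe left are skipped and counted in
    ``n_skipped``. The stored ROC is the empirical distribution of the
    per-fold false-positive rate at the test score, whose area equals the
    mean per-case AUC.
    """
    positives, _, KD0, KM0 = _prepare(
        net, gamma_prime_d, gamma_prime_m, recompute_kernels
    )
    if len(positives) < 2:
        raise ValueError("local LOOCV needs at least two known associations")
    A = np.asarray(net.A)
    fold_fpr = []
    ranks = []
    n_skipped = 0
    for f, (i, j) in enumerate(positives):
        local_cands_mask = A[i] == 0
        if not local_cands_mask.any():
            n_skipped += 1
            continue
        S = _masked_score_matrix(
            net, positives[f : f + 1], gamma_prime_d, gamma_prime_m,
            recompute_kernels, KD0, KM0,
        )
        cands = S[i, local_cands_mask]
        above = (cands > S[i, j]).sum()
        ties = (cands == S[i, j]).sum()
        fold_fpr.append((above + 0.5 * ties) / cands.size)
        ranks.append(_rank_among(S[i, j], cands))
    if not fold_fpr:
        raise ValueError("every local LOOCV fold was skipped")
    fold_fpr = np.asarray(fold_fpr)
    auc = float(np.mean(1.0 - fold_fpr))
    # ROC = CDF of the per-fold FPR at the test score; area == mean AUC.
    # The step function is stored with explicit vertical risers so its
    # trapezoidal integral is exact.
    xs = np.unique(fold_fpr)
    cdf = np.searchsorted(np.sort(fold_fpr), xs, side="right") / fold_fpr.size
    fpr_pts = np.concatenate([[0.0], np.repeat(xs, 2), [1.0]])
    tpr_pts = np.concatenate([[0.0, 0.0], np.repeat(cdf, 2)[:-1], [1.0]])
    roc = np.vstack([fpr_pts, tpr_pts]).T
    return CVResult(
        mode="local_loocv",
        auc=auc,
        roc=roc,
        ranks=tuple(ranks),
        n_skipped=n_skipped,
        params={
            "gamma_prime_d": gamma_prime_d,
            "gamma_prime_m": gamma_prime_m,
            "recompute_kernels": recompute_kernels,
        },
    )


def kfold_cv(
    net: AssociationNetwork,
    k: int = 5,
    repeats: int = 100,
    seed: int = 42,
    gamma_prime_d: float = 1.0,
    gamma_prime_m: float = 1.0,
    recompute_kernels: bool = True,
) -> CVResult:
    """Repeated k-fold CV over the known associations.

    Per repeat the positives are shuffled with a seeded generator and split
    into k groups whose sizes differ by at most one; each group is masked
    wholesale, the model refit, and a fold AUC computed with the group as
    tests and the originally-unknown pairs as candidates. Reports the mean
    and sample standard deviation over all ``k * repeats`` fold AUCs; the
    stored ROC vertically averages the fold curves on a fixed FPR grid.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    positives, zero_mask, KD0, KM0 = _prepare(
        net, gamma_prime_d, gamma_prime_m, recompute_kernels
    )
    n_pos = len(positives)
    if n_pos < k:
        raise ValueError(f"need at least k={k} known associations, have {n_pos}")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, 201)
    fold_aucs = []
    tpr_sum = np.zeros_like(grid)
    assignments = np.empty((repeats, n_pos), dtype=np.int64)
    ranks = []
    for r in range(repeats):
        perm = rng.permutation(n_pos)
        for fold_id, fold in enumerate(np.array_split(perm, k)):
            assignments[r, fold] = fold_id
            pairs = positives[fold]
            S = _masked_score_matrix(
                net, pairs, gamma_prime_d, gamma_prime_m,
                recompute_kernels, KD0, KM0,
            )
            tests = S[pairs[:, 0], pairs[:, 1]]
            cands = S[zero_mask]
            roc_f, auc_f = rank_based_roc(tests, cands, max_points=2001)
            fold_aucs.append(auc_f)
            tpr_sum += np.interp(grid, roc_f[:, 0], roc_f[:, 1])
            for t in tests:
                ranks.append(_rank_among(float(t), cands))
    fold_aucs = np.asarray(fold_aucs)
    roc = np.vstack([grid, tpr_sum / fold_aucs.size]).T
    roc[0] = (0.0, 0.0)
    roc[-1] = (1.0, 1.0)
    auc_mean = float(fold_aucs.mean())
    auc_sd = float(fold_aucs.std(ddof=1)) if fold_aucs.size > 1 else 0.0
    return CVResult(
        mode="kfold",
        auc=auc_mean,
        roc=roc,
        ranks=tuple(ranks),
        repeats=repeats,
        seed=seed,
        folds=assignments,
        auc_mean=auc_mean,
        auc_sd=auc_sd,
        params={
            "k": k,
            "gamma_prime_d": gamma_prime_d,
            "gamma_prime_m": gamma_prime_m,
            "recompute_kernels": recompute_kernels,
        },
    )
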