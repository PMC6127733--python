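"""Repeated k-fold cross-validation of genomic predictive ability.

For each replicate the individuals are randomly partitioned into k folds
(sized as evenly as possible); per fold, variance components are
re-estimated on the training individuals, genetic values of the held-out
individuals are predicted, and predictive ability is the Pearson
correlation between predictions and the (pre-adjusted) phenotypes of the
test fold.  The kernel is phenotype-free, so it is computed once on all
individuals and only the model fit is repeated per fold.

The summary follows the "mean +/- SE" convention with the SE taken over
all replicate x fold correlation cells; the per-cell values are always
stored so any alternative summary can be recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixed_model import MixedModelSpec, blup_predict, reml_fit
from .similarity_kernels import RelatednessMatrix


@dataclass
class CVResult:
    """Per-(replicate, fold) predictive abilities and their summary."""

    cells: pd.DataFrame  # columns: replicate, fold, correlation, n_test
    fold_assignments: np.ndarray  # (n_replicates, n_individuals) fold of each
    seed: int

    @property
    def correlations(self) -> np.ndarray:
        return self.cells["correlation"].to_numpy()

    @property
    def mean(self) -> float:
        return float(self.correlations.mean())

    @property
    def se(self) -> float:
        r = self.correlations
        return float(r.std(ddof=1) / np.sqrt(r.size))


def _fold_partition(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold labels, fold sizes differing by at most one."""
    labels = np.arange(n) % n_folds
    rng.shuffle(labels)
    return labels


def cross_validate(
    kernel: RelatednessMatrix,
    response: np.ndarray,
    n_replicates: int = 20,
    n_folds: int = 5,
    seed: int = 0,
    psd_repair: bool = True,
) -> CVResult:
    """Repeated k-fold CV of predictive ability for one kernel.

    Parameters
    ----------
    kernel : RelatednessMatrix
        Relatedness among all individuals, aligned with ``response``.
    response : array
        Phenotypes, already adjusted for fixed effects if needed.
    n_replicates, n_folds : int
        Repetition structure; the default 20 x 5 gives 100 cells.
    seed : int
        Master seed; the same seed reproduces fold assignments and every
        correlation exactly.
    """
    y = np.asarray(response, dtype=float).ravel()
    n = y.size
    if kernel.n_individuals != n:
        raise ValueError("kernel and response are not aligned")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    ids = np.asarray(kernel.individual_ids)
    rng = np.random.default_rng(seed)
    rows = []
    assignments = np.empty((n_replicates, n), dtype=np.int64)
    for rep in range(n_replicates):
        folds = _fold_partition(n, n_folds, rng)
        assignments[rep] = folds
        for fold in range(n_folds):
            test = folds == fold
            train = ~test
            if train.sum() < 3:
                raise ValueError(
                    f"fold {fold} of replicate {rep} leaves only "
                    f"{int(train.sum())} training individuals (need >= 3)"
                )
            if test.sum() < 2:
                raise ValueError(
                    f"fold {fold} of replicate {rep} has a single test "
                    "individual; a per-fold correlation is undefined"
                )
            K_tt = RelatednessMatrix(
                list(ids[train]), kernel.restrict(list(ids[train])), "averaged"
            )
            fit = reml_fit(
                MixedModelSpec(y=y[train], K=K_tt), psd_repair=psd_repair
            )
            ghat = blup_predict(fit, kernel, list(ids[train]), list(ids[test]))
            if np.std(ghat) == 0 or np.std(y[test]) == 0:
                corr = 0.0  # no genetic signal: predictive ability is nil
            else:
                corr = float(stats.pearsonr(ghat, y[test])[0])
            rows.append((rep, fold, corr, int(test.sum())))
    cells = pd.DataFrame(rows, columns=["replicate", "fold", "correlation", "n_test"])
    return CVResult(cells=cells, fold_assignments=assignments, seed=seed)
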