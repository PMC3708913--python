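"""Multifactor dimensionality reduction (MDR) interaction search.

MDR collapses a k-locus genotype combination into one binary attribute:
a multilocus cell is labelled high-risk when its training case:control
ratio reaches a threshold (default: the training-fold case:control
ratio), and the attribute is scored as a Bayes classifier by balanced
accuracy, (sensitivity + specificity)/2.  The search is exhaustive over
locus subsets within stratified 10-fold cross-validation: per fold the
combination with maximal training balanced accuracy is selected; the
per-k best model is the combination selected most often (its
cross-validation consistency, CVC), reported with its mean testing
balanced accuracy over folds.  Significance of the best model comes
from permuting case/control labels and re-running the search.

Conventions: a cell exactly at threshold is high-risk; cells empty of
controls but holding cases are high, the reverse low; cells unseen in
training predict "control" at testing time.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np

from .data import MISSING, CohortTable

HIGH, LOW, EMPTY = 1, 0, -9


@dataclasses.dataclass
class MDRModel:
    loci: tuple[str, ...]
    cell_labels: dict[tuple[int, ...], int]   # genotype combo -> HIGH/LOW/EMPTY
    training_ba: float
    testing_ba: float
    cvc: int
    n_folds: int
    p_perm: float | None = None


def cell_index(doses: np.ndarray) -> np.ndarray:
    """Map a (n x k) dose matrix to flat base-3 cell indices; -1 if any missing."""
    idx = np.zeros(len(doses), dtype=int)
    for j in range(doses.shape[1]):
        idx = idx * 3 + doses[:, j]
    idx[(doses == MISSING).any(axis=1)] = -1
    return idx


def label_cells(status: np.ndarray, cells: np.ndarray, n_cells: int,
                threshold: float | None = None) -> np.ndarray:
    """High/low/empty label per cell from training case:control ratios.

    ``threshold`` defaults to the training case:control ratio; a cell is
    high-risk iff cases/controls >= threshold (case-holding cells with
    zero controls are high, control-holding cells with zero cases low).
    """
    valid = cells >= 0
    case_n = np.bincount(cells[valid & (status == 1)], minlength=n_cells).astype(float)
    ctrl_n = np.bincount(cells[valid & (status == 0)], minlength=n_cells).astype(float)
    if threshold is None:
        n_ca, n_co = status[valid].sum(), (1 - status[valid]).sum()
        if n_co == 0:
            raise ValueError("training data has no controls")
        threshold = n_ca / n_co
    labels = np.full(n_cells, EMPTY, dtype=int)
    occupied = (case_n + ctrl_n) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        high = np.where(ctrl_n > 0, case_n / np.maximum(ctrl_n, 1e-300) >= threshold,
                        case_n > 0)
    labels[occupied] = np.where(high[occupied], HIGH, LOW)
    return labels


def balanced_accuracy(labels: np.ndarray, status: np.ndarray, cells: np.ndarray) -> float:
    """Balanced accuracy of the MDR attribute on an evaluation set.

    Subjects in high-risk cells are predicted cases; low, empty and
    unseen cells predict controls.  Requires both classes present.
    """
    valid = cells >= 0
    status, cells = status[valid], cells[valid]
    if status.sum() == 0 or status.sum() == len(status):
        raise ValueError("evaluation set lacks one class")
    pred = labels[cells] == HIGH
    sens = pred[status == 1].mean()
    spec = (~pred[status == 0]).mean()
    return float((sens + spec) / 2.0)


def stratified_folds(status: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold id per subject, class-stratified, shuffled under ``rng``."""
    fold = np.empty(len(status), dtype=int)
    for grp in (0, 1):
        idx = np.flatnonzero(status == grp)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def _search_fixed_folds(status: np.ndarray, cell_mats: dict[int, np.ndarray],
                        combos_by_k: dict[int, list[tuple[int, ...]]],
                        fold: np.ndarray, n_folds: int) -> dict[int, tuple[tuple[int, ...], int, float, float]]:
    """Best model per k for one fold assignment.

    Returns {k: (combo, cvc, mean_testing_ba, mean_training_ba)}.  The
    testing estimate is the cross-validated prediction accuracy: the
    testing balanced accuracy of each fold's training-selected
    combination, averaged over folds.  Averaging the fold winners (not
    the modal combination) is what makes the estimate honest about the
    selection step — at large k the fold winners overfit their training
    folds and the average drops accordingly.  ``cell_mats[k]`` is
    (n_subjects x n_combos) of flat cell indices.
    """
    out = {}
    for k, combos in combos_by_k.items():
        n_cells = 3 ** k
        cells = cell_mats[k]
        n_combos = cells.shape[1]
        train_ba = np.zeros((n_folds, n_combos))
        test_ba = np.zeros((n_folds, n_combos))
        for f in range(n_folds):
            tr = fold != f
            te = ~tr
            for c in range(n_combos):
                labels = label_cells(status[tr], cells[tr, c], n_cells)
                train_ba[f, c] = balanced_accuracy(labels, status[tr], cells[tr, c])
                test_ba[f, c] = balanced_accuracy(labels, status[te], cells[te, c])
        picked = train_ba.argmax(axis=1)          # ties -> lowest index = lexicographic
        votes = np.bincount(picked, minlength=n_combos)
        best_c = int(votes.argmax())
        cvc = int(votes[best_c])
        rows = np.arange(n_folds)
        out[k] = (combos[best_c], cvc, float(test_ba[rows, picked].mean()),
                  float(train_ba[rows, picked].mean()))
    return out


def mdr_search(cohort: CohortTable, k_min: int = 1, k_max: int = 5,
               n_folds: int = 10, seed: int = 0,
               loci: Sequence[str] | None = None) -> tuple[list[MDRModel], MDRModel]:
    """Exhaustive MDR search over locus subsets of size k_min..k_max.

    Returns the per-k best models and the overall best (maximal testing
    balanced accuracy; ties broken toward higher CVC, then smaller k,
    then lexicographic locus order).
    """
    names = [l.name for l in cohort.panel] if loci is None else list(loci)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if k_max > len(names):
        raise ValueError("k_max exceeds panel size")
    status = cohort.status
    doses = cohort.doses(names)
    rng = np.random.default_rng(seed)
    fold = stratified_folds(status, n_folds, rng)
    for f in range(n_folds):
        for part in (fold == f, fold != f):
            if status[part].min(initial=1) == status[part].max(initial=0):
                raise ValueError("a fold split lacks one class; use fewer folds")

    combos_by_k = {k: list(itertools.combinations(range(len(names)), k))
                   for k in range(k_min, k_max + 1)}
    cell_mats = {
        k: np.column_stack([cell_index(doses[:, list(c)]) for c in combos_by_k[k]])
        for k in combos_by_k
    }
    per_fold = _search_fixed_folds(status, cell_mats, combos_by_k, fold, n_folds)

    models = []
    for k in sorted(combos_by_k):
        combo, cvc, test_ba, train_ba = per_fold[k]
        cells = cell_index(doses[:, list(combo)])
        labels = label_cells(status, cells, 3 ** k)
        models.append(MDRModel(tuple(names[i] for i in combo),
                               {tuple(np.unravel_index(i, (3,) * k)): int(l)
                                for i, l in enumerate(labels)},
                               train_ba, test_ba, cvc, n_folds))
    # the single best model has maximal testing accuracy AND maximal CVC;
    # when the two criteria disagree, parsimony (smaller k) decides
    te_winner = max(models, key=lambda m: (m.testing_ba, m.cvc, -len(m.loci)))
    cvc_winner = max(models, key=lambda m: (m.cvc, m.testing_ba, -len(m.loci)))
    best = min((te_winner, cvc_winner), key=lambda m: len(m.loci))
    return models, best


def mdr_permutation_test(cohort: CohortTable, model: MDRModel, n_perm: int = 1000,
                         n_folds: int = 10, seed: int = 0,
                         loci: Sequence[str] | None = None) -> float:
    """Permutation p for an MDR model's testing balanced accuracy.

    Case/control labels are permuted and the full search at the model's
    subset size is re-run per permutation; p = (1 + #{BA* >= BA_obs}) /
    (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    names = [l.name for l in cohort.panel] if loci is None else list(loci)
    k = len(model.loci)
    status = cohort.status
    doses = cohort.doses(names)
    combos = {k: list(itertools.combinations(range(len(names)), k))}
    cells = {k: np.column_stack([cell_index(doses[:, list(c)]) for c in combos[k]])}
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm_status = status[rng.permutation(len(status))]
        fold = stratified_folds(perm_status, n_folds, rng)
        res = _search_fixed_folds(perm_status, cells, combos, fold, n_folds)
        if res[k][2] >= model.testing_ba:
            exceed += 1
    return (1.0 + exceed) / (n_perm + 1.0)
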