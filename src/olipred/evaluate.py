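"""Evaluation machinery: leakage-safe cross-validation and metrics.

The central protocol is a stratified 10-fold cross-validation in which every
training-fold artifact is derived from training records only: binding-motif
PSSMs are built per fold from that fold's positive *training* sequences (to
avoid circularity), and SMOTE balancing touches training folds only.  Every
record is scored exactly once out-of-fold, and an explicit audit trail
proves that no test-fold identifier contributed to PSSM construction or
balancing.

Metrics: AUC as the Mann-Whitney probability that a random positive outranks
a random negative (ties counted 1/2), precision at a 0.5 score threshold,
the Matthews correlation coefficient, and pooled out-of-fold ROC/PR curves.
Method comparison uses the two-sided Wilcoxon signed-rank test on paired
per-protein AUCs.  Confidence intervals for the AUC come from repeating the
whole cross-validation over disjoint redraws of the negative set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from . import model as model_mod
from .balance import BalancePlan, balance_training_fold
from .encoding import (
    FeatureSchema,
    get_schema,
    tetra_counts,
    top_motif_scores,
)
from .exceptions import DomainError, ProtocolError, SchemaMismatchError
from .formats import LabeledDataset, Pssm, RnaSequence
from .model import GridSpec, TrainedModel
from .structure import StructureFeatures

#: A per-fold PSSM provider: receives ONLY the fold's positive training
#: sequences and returns the PSSMs to score with (None disables the block).
PssmSource = Callable[[Sequence[RnaSequence]], list[Pssm]]


# ---------------------------------------------------------------------------
# Counts and scalar metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DomainError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_at(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred_pos = scores >= threshold
    pos = labels == +1
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & pos)),
        fp=int(np.sum(pred_pos & ~pos)),
        tn=int(np.sum(~pred_pos & ~pos)),
        fn=int(np.sum(~pred_pos & pos)),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    num = c.tp * c.tn - c.fp * c.fn
    den = math.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    return 0.0 if den == 0 else num / den


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == +1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise DomainError("AUC undefined: one class absent")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    return (float(ranks[pos].sum()) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


@dataclass(frozen=True)
class PrecisionResult:
    value: float
    no_positive_predictions: bool = False

    def __float__(self) -> float:
        return self.value


def precision_at(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> PrecisionResult:
    """tp / (tp + fp) at the threshold; 0 (flagged) when nothing is predicted
    positive."""
    if not 0.0 <= threshold <= 1.0:
        raise DomainError("threshold must lie in [0, 1]")
    c = confusion_at(scores, labels, threshold)
    if c.tp + c.fp == 0:
        return PrecisionResult(0.0, no_positive_predictions=True)
    return PrecisionResult(c.tp / (c.tp + c.fp))


def curves(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled ROC and PR curves from a threshold sweep over unique scores.

    Returns ``(roc, pr)`` where ``roc`` has columns (FPR, TPR) and ``pr``
    columns (recall, precision).  The trapezoidal area under the ROC equals
    :func:`auc`.
    """
    from sklearn.metrics import precision_recall_curve, roc_curve

    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DomainError("curves undefined: one class absent")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    prec, rec, _ = precision_recall_curve(labels, scores)
    roc = np.column_stack([fpr, tpr])
    pr = np.column_stack([rec[::-1], prec[::-1]])  # recall ascending
    return roc, pr


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold: int
    test_ids: tuple[str, ...]
    confusion: ConfusionCounts
    auc: float
    precision: float
    mcc: float
    chosen_C: float


@dataclass
class CvReport:
    protein: str
    schema_name: str
    fold_results: list[FoldResult]
    oof: pd.DataFrame  # columns: id, score, label — each record exactly once
    leakage_audit: list[dict] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.fold_results]))

    @property
    def sd_auc(self) -> float:
        return float(np.std([f.auc for f in self.fold_results], ddof=1))

    @property
    def mean_precision(self) -> float:
        return float(np.mean([f.precision for f in self.fold_results]))

    @property
    def pooled_auc(self) -> float:
        return auc(self.oof["score"].to_numpy(), self.oof["label"].to_numpy())

    @property
    def pooled_precision(self) -> float:
        return precision_at(
            self.oof["score"].to_numpy(), self.oof["label"].to_numpy()
        ).value

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "fold": f.fold,
                "tp": f.confusion.tp,
                "fp": f.confusion.fp,
                "tn": f.confusion.tn,
                "fn": f.confusion.fn,
                "auc": f.auc,
                "precision": f.precision,
                "mcc": f.mcc,
                "chosen_C": f.chosen_C,
            }
            for f in self.fold_results
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        return (
            f"protein={self.protein} schema={self.schema_name} "
            f"folds={len(self.fold_results)} "
            f"mean_auc={self.mean_auc:.3f}±{self.sd_auc:.3f} "
            f"pooled_auc={self.pooled_auc:.3f} "
            f"mean_precision={self.mean_precision:.3f}"
        )


def run_cv(
    ds: LabeledDataset,
    schema: FeatureSchema | str,
    pssm_source: PssmSource | None = None,
    plan: BalancePlan | None = None,
    grid: GridSpec | None = None,
    folds: int = 10,
    seed: int = 0,
    structures: Mapping[str, StructureFeatures] | None = None,
    normalize: bool = False,
    per_motif: bool = False,
    permute_labels: bool = False,
) -> CvReport:
    """Stratified k-fold cross-validation with per-fold motif discovery and
    training-only SMOTE.

    ``pssm_source`` is called once per fold with that fold's positive
    TRAINING sequences only; the ids it saw are recorded in the leakage
    audit and checked against the test fold.
    """
    if isinstance(schema, str):
        schema = get_schema(schema)
    if plan is None:
        plan = BalancePlan(seed=seed)
    if grid is None:
        grid = GridSpec(seed=seed)
    seqs = ds.sequences
    labels = ds.labels.copy()
    n_pos = int(np.sum(labels == +1))
    n_neg = int(np.sum(labels == -1))
    if n_pos < folds or n_neg < folds:
        raise DomainError(
            f"need at least {folds} records per class for {folds}-fold CV "
            f"(have {n_pos} positives, {n_neg} negatives)"
        )
    master = np.random.default_rng(seed)
    if permute_labels:
        labels = master.permutation(labels)
    if schema.name in ("olimo", "olimoss") and pssm_source is None:
        raise ProtocolError(f"schema {schema.name!r} requires a pssm_source")

    # fold-independent feature blocks
    tetra = np.vstack([tetra_counts(s, normalize=normalize) for s in seqs])
    struct_block = None
    if schema.name == "olimoss":
        if structures is None:
            raise ProtocolError("schema 'olimoss' requires per-sequence structures")
        from .encoding import accessibility_features

        rows = []
        for s in seqs:
            if s.id not in structures:
                raise ProtocolError(f"no structure supplied for {s.id!r}")
            sf = structures[s.id]
            rows.append(
                np.concatenate(
                    [
                        [sf.energy, sf.stem_density, float(sf.n_stems)],
                        accessibility_features(s, sf),
                    ]
                )
            )
        struct_block = np.vstack(rows)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    ids = np.array([s.id for s in seqs])
    fold_results: list[FoldResult] = []
    audit: list[dict] = []
    oof_rows = []
    for fold_idx, (train_idx, test_idx) in enumerate(skf.split(tetra, labels)):
        test_ids = set(ids[test_idx])
        train_pos_seqs = [seqs[i] for i in train_idx if labels[i] == +1]
        pssm_input_ids = [s.id for s in train_pos_seqs]
        if test_ids & set(pssm_input_ids):
            raise ProtocolError(
                f"fold {fold_idx}: test ids leaked into PSSM construction"
            )

        blocks_train = [tetra[train_idx]]
        blocks_test = [tetra[test_idx]]
        if schema.name in ("olimo", "olimoss"):
            pssms = pssm_source(train_pos_seqs)
            motif_all = np.vstack(
                [
                    top_motif_scores(seqs[i], pssms, per_motif=per_motif)
                    for i in np.concatenate([train_idx, test_idx])
                ]
            )
            blocks_train.append(motif_all[: len(train_idx)])
            blocks_test.append(motif_all[len(train_idx):])
        if struct_block is not None:
            blocks_train.append(struct_block[train_idx])
            blocks_test.append(struct_block[test_idx])
        X_train = np.hstack(blocks_train)
        X_test = np.hstack(blocks_test)
        y_train = labels[train_idx]
        y_test = labels[test_idx]

        fold_seed = int(master.integers(2**31))
        fold_plan = BalancePlan(plan.k_neighbors, plan.target_ratio, fold_seed)
        X_bal, y_bal, synth_mask = balance_training_fold(X_train, y_train, fold_plan)
        smote_input_ids = list(ids[train_idx])
        if test_ids & set(smote_input_ids):
            raise ProtocolError(f"fold {fold_idx}: test ids leaked into SMOTE")

        trained = model_mod.train(
            X_bal,
            y_bal,
            GridSpec(grid.c_values, grid.inner_folds, fold_seed),
            protein=ds.protein,
            schema=schema,
        )
        scores, pred = model_mod.predict(trained, X_test)
        c = confusion_at(scores, y_test)
        fold_results.append(
            FoldResult(
                fold=fold_idx,
                test_ids=tuple(ids[test_idx]),
                confusion=c,
                auc=auc(scores, y_test),
                precision=precision_at(scores, y_test).value,
                mcc=mcc(c),
                chosen_C=trained.C,
            )
        )
        audit.append(
            {
                "fold": fold_idx,
                "test_ids": sorted(test_ids),
                "pssm_input_ids": sorted(pssm_input_ids),
                "smote_input_ids": sorted(smote_input_ids),
                "n_synthetic": int(synth_mask.sum()),
            }
        )
        for i, s, yl in zip(test_idx, scores, y_test):
            oof_rows.append({"id": ids[i], "score": float(s), "label": int(yl)})

    oof = pd.DataFrame(oof_rows)
    if oof["id"].duplicated().any() or len(oof) != len(seqs):
        raise ProtocolError("out-of-fold scoring must cover each record exactly once")
    return CvReport(ds.protein, schema.name, fold_results, oof, audit)


# ---------------------------------------------------------------------------
# Method comparison and confidence intervals
# ---------------------------------------------------------------------------

def compare_methods(
    auc_a: Sequence[float], auc_b: Sequence[float], alpha: float = 0.01
) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test on paired per-protein AUCs.

    Zero differences are dropped (the classic convention); all-zero
    differences give p = 1, not significant.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 5:
        raise DomainError("need paired lists of equal length >= 5")
    if np.all(a == b):
        return 0.0, 1.0, False
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


@dataclass
class NegativeResamplingResult:
    mean_auc: float
    ci: tuple[float, float]
    draw_aucs: list[float]
    degenerate: bool = False


def negative_resampling_ci(
    positives: Sequence[RnaSequence],
    negative_pool: Sequence[RnaSequence],
    schema: FeatureSchema | str,
    pssm_source: PssmSource | None = None,
    plan: BalancePlan | None = None,
    grid: GridSpec | None = None,
    draws: int = 10,
    draw_size: int | None = None,
    folds: int = 10,
    seed: int = 0,
    alpha: float = 0.01,
    protein: str = "",
    structures: Mapping[str, StructureFeatures] | None = None,
) -> NegativeResamplingResult:
    """Confidence interval for the CV AUC over redraws of the negative set.

    The whole cross-validation is repeated ``draws`` times, each with a fresh
    negative set; when the pool is large enough the draws are pairwise
    disjoint (a partition of a shuffled pool), otherwise each draw samples
    without replacement with a warning.  A Student-t interval at level
    ``alpha`` summarizes the draw AUCs.
    """
    if draw_size is None:
        draw_size = len(negative_pool) // draws
    if draw_size > len(negative_pool):
        raise DomainError(
            f"draw_size {draw_size} exceeds negative pool of {len(negative_pool)}"
        )
    rng = np.random.default_rng(seed)
    pool = list(negative_pool)
    disjoint = len(pool) >= draws * draw_size
    if disjoint:
        perm = rng.permutation(len(pool))
        draws_idx = [
            perm[d * draw_size : (d + 1) * draw_size] for d in range(draws)
        ]
    else:
        warnings.warn(
            "negative pool too small for disjoint draws; sampling without "
            "replacement per draw",
            stacklevel=2,
        )
        draws_idx = [
            rng.choice(len(pool), size=draw_size, replace=False)
            for _ in range(draws)
        ]
    draw_aucs = []
    for d, idx in enumerate(draws_idx):
        ds = LabeledDataset(
            protein,
            [(s, +1) for s in positives] + [(pool[i], -1) for i in idx],
        )
        report = run_cv(
            ds,
            schema,
            pssm_source=pssm_source,
            plan=plan,
            grid=grid,
            folds=folds,
            seed=int(rng.integers(2**31)),
            structures=structures,
        )
        draw_aucs.append(report.pooled_auc)
    mean = float(np.mean(draw_aucs))
    if draws < 2:
        warnings.warn("single draw: degenerate confidence interval", stacklevel=2)
        return NegativeResamplingResult(mean, (mean, mean), draw_aucs, degenerate=True)
    sem = float(np.std(draw_aucs, ddof=1)) / math.sqrt(draws)
    tcrit = float(stats.t.ppf(1 - alpha / 2, df=draws - 1))
    return NegativeResamplingResult(
        mean, (mean - tcrit * sem, mean + tcrit * sem), draw_aucs
    )


# ---------------------------------------------------------------------------
# Feature ranking and cross-protein sensitivity
# ---------------------------------------------------------------------------

def _entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def information_gain(x: np.ndarray, y01: np.ndarray) -> float:
    """IG of the best single threshold split of feature *x* on binary labels.

    The threshold scans the midpoints of consecutive sorted unique values;
    IG = H(label) - H(label | split).  Constant features score 0.
    """
    x = np.asarray(x, dtype=float)
    y01 = np.asarray(y01, dtype=int)
    n = len(x)
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y01[order]
    base = _entropy(float(ys.mean()))
    # candidate split after position i (left = first i+1 points) wherever the
    # value changes
    change = np.nonzero(np.diff(xs))[0]
    if change.size == 0:
        return 0.0
    cum_pos = np.cumsum(ys)
    best = 0.0
    total_pos = cum_pos[-1]
    for i in change:
        n_l = i + 1
        n_r = n - n_l
        p_l = cum_pos[i] / n_l
        p_r = (total_pos - cum_pos[i]) / n_r
        ig = base - (n_l / n) * _entropy(float(p_l)) - (n_r / n) * _entropy(float(p_r))
        best = max(best, ig)
    return best


def information_gain_ranking(
    features: pd.DataFrame, labels: Sequence[int]
) -> list[tuple[str, float]]:
    """Rank features by best-split information gain, descending (ties by name)."""
    y01 = (np.asarray(labels, dtype=int) == +1).astype(int)
    if set(np.unique(y01)) - {0, 1}:
        raise DomainError("labels must be binary")
    scored = [
        (name, information_gain(features[name].to_numpy(), y01))
        for name in features.columns
    ]
    return sorted(scored, key=lambda t: (-t[1], t[0]))


def cross_rbp_sensitivity(
    models: Sequence[TrainedModel],
    positive_features: Sequence[np.ndarray | pd.DataFrame],
    diagonal_oof: Sequence[float] | None = None,
) -> np.ndarray:
    """Sensitivity matrix: entry (i, j) = fraction of protein j's positives
    labeled +1 by model i.

    Off-diagonal entries are plain model applications.  The diagonal is a
    resubstitution estimate unless ``diagonal_oof`` supplies out-of-fold
    sensitivities from each model's own cross-validation.
    """
    versions = {m.schema.version for m in models}
    if len(versions) > 1:
        raise SchemaMismatchError("all models must share one feature schema")
    n = len(models)
    if len(positive_features) != n:
        raise DomainError("one positive feature matrix required per model")
    mat = np.zeros((n, n))
    for i, m in enumerate(models):
        for j, feats in enumerate(positive_features):
            _, pred = model_mod.predict(m, feats)
            mat[i, j] = float(np.mean(pred == +1))
    if diagonal_oof is not None:
        for i, v in enumerate(diagonal_oof):
            mat[i, i] = v
    return mat
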