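"""Target-gene search: separability scoring, multivariate feature selection,
and clinical-stratum association contrasts.

Candidates are the protein-coding up/down-regulated genes from the
consensus. Each candidate is scored by Gini separability — the normalized
Gini-impurity gain of the best single-threshold split of its expression
between groups (1 = perfectly separable, 0 = no split helps), NOT the
Lorenz-curve Gini of economics (a ``lorenz`` variant is available for
sensitivity analysis). Candidates past the separability floor enter a
recursive feature elimination with a seeded tree ensemble and k-fold
cross-validation; the retained set maximizes mean balanced accuracy (ties
broken toward the smaller set). Clinical contrasts re-run the selection
between case strata defined on CAG repeat length, onset age, Vonsattel
grade, or post-onset lifespan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from .consensus import ConsensusResult
from .io import GeneAnnotation, SampleTable
from .preprocess import NormalizedMatrix

__all__ = ["TargetScore", "StratumSpec", "AssociationResult",
           "gini_separability", "select_targets", "stratify_clinical",
           "associate_targets", "correlate_clinical", "group_compare"]


@dataclass
class StratumSpec:
    """Two disjoint case subgroups defined on one clinical feature."""

    feature: str
    group_a: list[str]
    group_b: list[str]
    label_a: str
    label_b: str

    def __post_init__(self) -> None:
        if set(self.group_a) & set(self.group_b):
            raise ValueError("stratum groups overlap")
        for name, grp in ((self.label_a, self.group_a), (self.label_b, self.group_b)):
            if len(grp) < 3:
                raise ValueError(f"stratum group {name!r} has < 3 samples")


@dataclass
class AssociationResult:
    stratum: StratumSpec
    table: pd.DataFrame  # per-gene gini, importance, selected, direction
    n_up: int
    n_down: int


def gini_separability(expr: np.ndarray, labels: np.ndarray) -> float:
    """Normalized impurity gain of the best single-threshold split in [0, 1].

    ``labels`` is boolean (case membership). Candidate thresholds are the
    midpoints between consecutive distinct expression values; the score is
    (Gini(parent) - min weighted Gini(children)) / Gini(parent). Invariant
    to strictly monotone transforms of the expression values.
    """
    expr = np.asarray(expr, float)
    labels = np.asarray(labels, bool)
    n = expr.size
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    if np.ptp(expr) == 0:
        return 0.0
    order = np.argsort(expr, kind="mergesort")
    x, y = expr[order], labels[order].astype(float)
    n_pos = y.sum()
    parent = 2.0 * (n_pos / n) * (1.0 - n_pos / n)
    if parent == 0:
        return 0.0
    cum_pos = np.cumsum(y)[:-1]
    nl = np.arange(1, n, dtype=float)
    valid = x[1:] != x[:-1]  # split only between distinct values
    if not valid.any():
        return 0.0
    nl, cum_pos = nl[valid], cum_pos[valid]
    nr = n - nl
    pl, pr = cum_pos / nl, (n_pos - cum_pos) / nr
    child = (nl * 2 * pl * (1 - pl) + nr * 2 * pr * (1 - pr)) / n
    return float((parent - child.min()) / parent)


def gini_lorenz(expr: np.ndarray) -> float:
    """Lorenz-curve Gini coefficient of a non-negative vector (the
    economics statistic; offered only for sensitivity analysis)."""
    x = np.sort(np.asarray(expr, float))
    if x.sum() == 0:
        return 0.0
    n = x.size
    return float((2 * np.arange(1, n + 1) - n - 1) @ x / (n * x.sum()))


def _candidate_genes(consensus: ConsensusResult,
                     annotation: GeneAnnotation | None) -> list[str]:
    t = consensus.table
    cand = [g for g in t.index if t.at[g, "label"] in ("URG", "DRG")]
    if annotation is not None:
        cand = [g for g in cand
                if g in annotation and annotation.biotype(g) == "protein_coding"]
    return cand


def select_targets(consensus: ConsensusResult, normmat: NormalizedMatrix,
                   labels: np.ndarray, annotation: GeneAnnotation | None = None,
                   *, g_min: float = 0.3, folds: int = 5,
                   drop_fraction: float = 0.1, seed: int = 0,
                   n_estimators: int = 100,
                   candidates: list[str] | None = None) -> pd.DataFrame:
    """Distribution-based target selection over the consensus DEGs.

    Returns a per-candidate table (gini, importance, selected, direction).
    ``selected`` genes pass both the separability floor ``g_min`` and the
    cross-validated recursive elimination. Deterministic under ``seed`` and
    invariant to candidate order.
    """
    labels = np.asarray(labels, bool)
    if labels.sum() < 6 or (~labels).sum() < 6:
        raise ValueError("need >= 6 samples per group")
    if candidates is None:
        candidates = _candidate_genes(consensus, annotation)
    candidates = sorted(candidates)
    if not candidates:
        warnings.warn("no candidate genes; empty target table")
        return pd.DataFrame(columns=["gini", "importance", "selected", "direction"])

    pos = {g: i for i, g in enumerate(normmat.gene_ids)}
    expr = normmat.values[[pos[g] for g in candidates]]
    ginis = np.array([gini_separability(expr[i], labels)
                      for i in range(len(candidates))])
    floor_pass = ginis >= g_min

    directions = np.where(consensus.table.loc[candidates, "log2fc"] >= 0,
                          "up", "down")

    keep_idx = np.where(floor_pass)[0]
    selected = np.zeros(len(candidates), bool)
    importance = np.zeros(len(candidates))
    if keep_idx.size:
        sel_local, imp_local = _rfe_select(expr[keep_idx].T, labels, folds,
                                           drop_fraction, seed, n_estimators)
        selected[keep_idx[sel_local]] = True
        importance[keep_idx] = imp_local
    return pd.DataFrame({"gini": ginis, "importance": importance,
                         "selected": selected, "direction": directions},
                        index=candidates)


def _rfe_select(X: np.ndarray, y: np.ndarray, folds: int, drop_fraction: float,
                seed: int, n_estimators: int) -> tuple[np.ndarray, np.ndarray]:
    """Recursive feature elimination maximizing CV balanced accuracy.

    Returns (indices of the best feature set, final importances aligned to
    the input features). Ties in accuracy go to the larger set: the object
    of interest is a target panel, so every gene whose removal does not
    improve discrimination stays a candidate (a minimal-classifier tie-break
    would collapse a panel of equally separable genes to a single survivor).
    """
    n_feat = X.shape[1]
    active = np.arange(n_feat)
    history: list[tuple[float, np.ndarray]] = []
    full_importance = np.zeros(n_feat)
    k = min(folds, int(min(y.sum(), (~y).sum())))
    first = True
    while active.size >= 1:
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        accs, imps = [], np.zeros(active.size)
        for tr, te in cv.split(X[:, active], y):
            clf = RandomForestClassifier(n_estimators=n_estimators,
                                         random_state=seed, n_jobs=1)
            clf.fit(X[tr][:, active], y[tr])
            accs.append(balanced_accuracy_score(y[te], clf.predict(X[te][:, active])))
            imps += clf.feature_importances_
        imps /= k
        history.append((float(np.mean(accs)), active.copy()))
        if first:
            full_importance[active] = imps
            first = False
        if active.size == 1:
            break
        n_drop = max(1, int(np.ceil(drop_fraction * active.size)))
        order = np.argsort(imps, kind="mergesort")  # lowest importance first
        active = np.sort(active[order[n_drop:]])
    best_acc = max(a for a, _ in history)
    best = max((feats for a, feats in history if a >= best_acc - 1e-12), key=len)
    return best, full_importance


def stratify_clinical(samples: SampleTable, feature: str) -> StratumSpec:
    """Case strata on a clinical feature.

    cag / lifespan: bottom vs top quartile among cases; onset_age: early
    (< 35 y) vs late (> 50 y); vonsattel: grade 2 vs grade 4.
    """
    df = samples.data
    cases = df[df["condition"] == "case"]
    if feature == "lifespan":
        vals = (cases["death_age"] - cases["onset_age"]).dropna()
    elif feature in ("cag", "onset_age", "vonsattel"):
        vals = cases[feature].dropna().astype(float)
    else:
        raise ValueError(f"unknown clinical feature {feature!r}")
    if len(vals) < 6:
        raise ValueError(f"feature {feature!r} present for < 6 cases")

    if feature == "onset_age":
        a = list(vals.index[vals < 35])
        b = list(vals.index[vals > 50])
        la, lb = "onset<35", "onset>50"
    elif feature == "vonsattel":
        a = list(vals.index[vals == 2])
        b = list(vals.index[vals == 4])
        la, lb = "grade2", "grade4"
    else:
        q1, q3 = vals.quantile([0.25, 0.75])
        a = list(vals.index[vals <= q1])
        b = list(vals.index[vals >= q3])
        la, lb = f"{feature}-low", f"{feature}-high"
    for name, grp in ((la, a), (lb, b)):
        if len(grp) < 3:
            raise ValueError(f"stratum group {name!r} has < 3 samples")
    return StratumSpec(feature, a, b, la, lb)


def associate_targets(targets: pd.DataFrame, consensus: ConsensusResult,
                      normmat: NormalizedMatrix, spec: StratumSpec,
                      *, seed: int = 0, g_min: float = 0.3,
                      folds: int = 5) -> AssociationResult:
    """Stratum contrast: re-select among the targets between two case strata."""
    if targets.empty:
        raise ValueError("empty target table")
    ids = spec.group_a + spec.group_b
    sub = normmat.subset_samples(ids)
    labels = np.r_[np.zeros(len(spec.group_a), bool),
                   np.ones(len(spec.group_b), bool)]
    table = select_targets(consensus, sub, labels,
                           candidates=list(targets.index),
                           g_min=g_min, folds=min(folds, 3), seed=seed)
    sel = table[table["selected"]]
    n_up = int((sel["direction"] == "up").sum())
    n_down = int((sel["direction"] == "down").sum())
    return AssociationResult(spec, table, n_up, n_down)


def correlate_clinical(x: np.ndarray, y: np.ndarray
                       ) -> tuple[float, float, tuple[float, float]]:
    """Pearson r, two-sided p, and the least-squares line (slope, intercept)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need n >= 3 finite pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return float(r), float(p), (float(slope), float(intercept))


def group_compare(values_by_group: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA with a Tukey HSD post-hoc pairwise table."""
    groups = {k: np.asarray(v, float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for k, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} is a singleton")
    F, p = stats.f_oneway(*groups.values())
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    vals = np.concatenate(list(groups.values()))
    labs = np.concatenate([[k] * v.size for k, v in groups.items()])
    tk = pairwise_tukeyhsd(vals, labs, alpha=0.05)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return {"F": float(F), "p": float(p), "tukey": tukey}
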