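"""Recursive Method Combination (RMC) consensus and the six-class gene taxonomy.

Evidence from the ensemble of differential-expression tests is merged into
one call per gene:

1. a weighted Stouffer combination Z_g = sum_m w_m Phi^-1(1 - p_mg) /
   sqrt(sum_m w_m^2) with combined p = P(N(0,1) > Z_g); the inputs are
   already two-sided, so only a large positive Z is evidence (direction
   lives in the effect, not the p); weights w_m = min(1, alpha /
   alpha_hat_m) from permutation calibration, or unit;
2. BH adjustment of the combined p within the tested gene set;
3. consensus log2FC = median of the methods' native effects;
4. a DEG call requires consensus FDR < 0.05, |consensus log2FC| >= 0.40,
   and a voting quorum: at least ceil(M/2) methods individually voting in
   the consensus direction (FDR < 0.05 and effect past +-0.40);
5. type-II rescue recursion: genes passing FDR + effect but blocked by the
   quorum are re-combined on the method subset excluding the single most
   discordant method (largest |Phi^-1(1-p_mg) - Z_g|, ties by method name),
   repeated while >= 3 methods remain; a pass at any depth marks the gene
   rescued;
6. every gene gets exactly one class label: ZCG (all raw counts zero), LCG
   (mean normalized count < 10), EEG (FDR >= 0.05), NRG (significant but
   |log2FC| < 0.40, or significant-looking genes the ensemble refuses to
   back), DRG (log2FC <= -0.40) or URG (log2FC >= +0.40).

The quorum suppresses single-method false positives (type I); the rescue
recursion recovers quorum-blocked true calls (type II).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import (DesignSpec, MethodResult, bh_adjust, estimate_log2fc,
                 run_method, MANDATORY_METHODS, OPTIONAL_METHODS)
from .io import CountMatrix
from .preprocess import NormalizedMatrix, normalize

__all__ = ["RMCConfig", "ConsensusResult", "classify_gene", "vote_matrix",
           "rmc_combine", "compare_with_single_method", "RMCModel", "RMCResults"]

CLASSES = ["ZCG", "LCG", "EEG", "NRG", "URG", "DRG"]

_P_CLAMP = 1e-15


@dataclass
class RMCConfig:
    """Thresholds of the consensus layer (the printed classification rules)."""

    fdr_threshold: float = 0.05
    effect_threshold: float = 0.40
    low_count_threshold: float = 10.0
    min_methods: int = 3

    def __post_init__(self) -> None:
        if min(self.fdr_threshold, self.effect_threshold,
               self.low_count_threshold) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class ConsensusResult:
    """Per-gene consensus statistics, votes, rescue flags, and class labels."""

    table: pd.DataFrame  # log2fc, p, fdr, n_up, n_down, n_none, is_deg, rescued, label
    weights: dict[str, float]
    config: RMCConfig = field(default_factory=RMCConfig)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def class_counts(self) -> pd.Series:
        return self.table["label"].value_counts().reindex(CLASSES, fill_value=0)

    def deg_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_deg"]])


def classify_gene(raw_row_sum: int, mean_norm_count: float, log2fc: float,
                  fdr: float, *, fdr_threshold: float = 0.05,
                  effect_threshold: float = 0.40,
                  low_count_threshold: float = 10.0) -> str:
    """Six-class precedence: ZCG, LCG, EEG, NRG, then DRG/URG by effect sign."""
    if raw_row_sum == 0:
        return "ZCG"
    if mean_norm_count < low_count_threshold:
        return "LCG"
    if fdr is None or (isinstance(fdr, float) and math.isnan(fdr)):
        raise ValueError("missing FDR for a gene past the low-count gate")
    if fdr >= fdr_threshold:
        return "EEG"
    if log2fc is None or (isinstance(log2fc, float) and math.isnan(log2fc)):
        raise ValueError("missing log2FC for a significant gene")
    if abs(log2fc) < effect_threshold:
        return "NRG"
    return "DRG" if log2fc <= -effect_threshold else "URG"


def _aligned(results: list[MethodResult]) -> list[str]:
    universe = results[0].gene_ids
    for r in results[1:]:
        if r.gene_ids != universe:
            raise ValueError("method results cover different gene universes")
    return universe


def vote_matrix(results: list[MethodResult],
                shared_effect: pd.Series | None = None,
                config: RMCConfig | None = None) -> pd.DataFrame:
    """Per gene x method votes: up / down / none.

    A method votes up when its FDR < 0.05 and its effect >= +0.40 (down
    mirrored, boundaries inclusive); methods without native effects vote on
    the shared pseudocounted mean-ratio effect.
    """
    cfg = config or RMCConfig()
    if len(results) < cfg.min_methods:
        raise ValueError(f"need >= {cfg.min_methods} methods")
    universe = _aligned(results)
    votes = {}
    for r in results:
        eff = r.table["log2fc"]
        if not r.native_effect:
            if shared_effect is None:
                raise ValueError(f"method {r.method!r} has no native effect and "
                                 "no shared effect was given")
            eff = shared_effect.loc[universe]
        sig = r.table["fdr"].to_numpy() < cfg.fdr_threshold
        e = eff.to_numpy()
        v = np.where(sig & (e >= cfg.effect_threshold), "up",
                     np.where(sig & (e <= -cfg.effect_threshold), "down", "none"))
        votes[r.method] = v
    return pd.DataFrame(votes, index=universe)


def rmc_combine(results: list[MethodResult], counts: CountMatrix,
                normmat: NormalizedMatrix | None = None,
                design: DesignSpec | None = None,
                weights: dict[str, float] | None = None,
                config: RMCConfig | None = None) -> ConsensusResult:
    """Combine the ensemble into one consensus call per gene (see module doc)."""
    cfg = config or RMCConfig()
    if len(results) < cfg.min_methods:
        raise ValueError(f"need >= {cfg.min_methods} methods")
    universe = _aligned(results)
    if list(counts.gene_ids) != universe:
        raise ValueError("count matrix and method results differ in gene universe")
    if normmat is None:
        normmat = normalize(counts, "size_factor")

    row_sum = counts.counts.sum(axis=1)
    mean_norm = normmat.values.mean(axis=1)
    tested = (row_sum > 0) & (mean_norm >= cfg.low_count_threshold)

    shared_eff = None
    if design is not None:
        shared_eff = estimate_log2fc(normmat, design)
    methods = [r.method for r in results]
    w = np.array([min(1.0, 0.05 / max(weights.get(m, 1.0), 1e-6))
                  if weights else 1.0 for m in methods])

    P = np.column_stack([r.table["p"].to_numpy() for r in results])
    P = np.clip(P, _P_CLAMP, 1 - _P_CLAMP)
    Zm = stats.norm.isf(P)  # Phi^-1(1 - p), per gene x method
    denom = np.sqrt((w ** 2).sum())
    Z = (Zm * w[None, :]).sum(axis=1) / denom
    # the method p-values are two-sided already: evidence accumulates only
    # in the upper tail (concordant large p must NOT look significant)
    p_comb = stats.norm.sf(Z)

    fdr = np.full(len(universe), np.nan)
    fdr[tested] = bh_adjust(p_comb[tested])

    native = [i for i, r in enumerate(results) if r.native_effect]
    if native:
        eff_mat = np.column_stack([results[i].table["log2fc"].to_numpy()
                                   for i in native])
        lfc = np.nanmedian(eff_mat, axis=1)
    elif shared_eff is not None:
        lfc = shared_eff.to_numpy()
    else:
        raise ValueError("no native effects and no design to derive a shared one")

    votes = vote_matrix(results, shared_eff, cfg)
    vup = (votes.to_numpy() == "up").sum(axis=1)
    vdown = (votes.to_numpy() == "down").sum(axis=1)
    M = len(results)
    quorum = math.ceil(M / 2)

    sig = tested & (fdr < cfg.fdr_threshold) & (np.abs(lfc) >= cfg.effect_threshold)
    concord = np.where(lfc >= 0, vup, vdown)
    called = sig & (concord >= quorum)
    rescued = np.zeros(len(universe), bool)

    # p-level cutoff equivalent to the FDR threshold on the tested set
    sig_p = p_comb[tested & (fdr < cfg.fdr_threshold)]
    p_crit = float(sig_p.max()) if sig_p.size else cfg.fdr_threshold / max(tested.sum(), 1)

    vote_arr = votes.to_numpy()
    for g in np.where(sig & ~called)[0]:
        keep = list(range(M))
        z_g = Zm[g].copy()
        direction = "up" if lfc[g] >= 0 else "down"
        while len(keep) > cfg.min_methods:
            wk = w[keep]
            Zk = float((z_g[keep] * wk).sum() / np.sqrt((wk ** 2).sum()))
            # drop the single most discordant method; ties by method-name order
            disc = np.abs(z_g[keep] - Zk)
            top = disc.max()
            cand = [keep[i] for i in range(len(keep)) if disc[i] >= top - 1e-12]
            drop = min(cand, key=lambda i: methods[i])
            keep.remove(drop)
            wk = w[keep]
            Zk = float((z_g[keep] * wk).sum() / np.sqrt((wk ** 2).sum()))
            p_sub = float(stats.norm.sf(Zk))
            conc = int((vote_arr[g, keep] == direction).sum())
            if p_sub <= p_crit and conc >= math.ceil(len(keep) / 2):
                rescued[g] = True
                called[g] = True
                break

    labels = np.empty(len(universe), object)
    for g in range(len(universe)):
        if row_sum[g] == 0:
            labels[g] = "ZCG"
        elif mean_norm[g] < cfg.low_count_threshold:
            labels[g] = "LCG"
        else:
            labels[g] = classify_gene(
                int(row_sum[g]), float(mean_norm[g]), float(lfc[g]), float(fdr[g]),
                fdr_threshold=cfg.fdr_threshold,
                effect_threshold=cfg.effect_threshold,
                low_count_threshold=cfg.low_count_threshold)
            # ensemble veto: significant effect without quorum support is
            # demoted to non-relevant rather than called differential
            if labels[g] in ("URG", "DRG") and not called[g]:
                labels[g] = "NRG"

    table = pd.DataFrame({
        "log2fc": lfc, "p": p_comb, "fdr": fdr,
        "n_up": vup, "n_down": vdown, "n_none": M - vup - vdown,
        "is_deg": called, "rescued": rescued, "label": labels,
    }, index=universe)
    return ConsensusResult(table, {m: float(x) for m, x in zip(methods, w)}, cfg)


def single_method_classes(result: MethodResult, counts: CountMatrix,
                          normmat: NormalizedMatrix | None = None,
                          shared_effect: pd.Series | None = None,
                          config: RMCConfig | None = None) -> pd.Series:
    """Apply the six-class rules to one method's output (the traditional path)."""
    cfg = config or RMCConfig()
    if normmat is None:
        normmat = normalize(counts, "size_factor")
    row_sum = counts.counts.sum(axis=1)
    mean_norm = normmat.values.mean(axis=1)
    eff = result.table["log2fc"]
    if not result.native_effect:
        if shared_effect is None:
            raise ValueError("need a shared effect for this method")
        eff = shared_effect.loc[result.gene_ids]
    fdr_tested = result.table["fdr"].to_numpy().copy()
    tested = (row_sum > 0) & (mean_norm >= cfg.low_count_threshold)
    if tested.any():  # re-adjust within the tested set, as the consensus does
        fdr_tested[tested] = bh_adjust(
            result.table["p"].to_numpy()[tested])
    labels = []
    e = eff.to_numpy()
    for g in range(len(row_sum)):
        if row_sum[g] == 0:
            labels.append("ZCG")
        elif mean_norm[g] < cfg.low_count_threshold:
            labels.append("LCG")
        else:
            labels.append(classify_gene(
                int(row_sum[g]), float(mean_norm[g]), float(e[g]),
                float(fdr_tested[g]), fdr_threshold=cfg.fdr_threshold,
                effect_threshold=cfg.effect_threshold,
                low_count_threshold=cfg.low_count_threshold))
    return pd.Series(labels, index=result.gene_ids, name=result.method)


def compare_with_single_method(consensus: ConsensusResult,
                               single_labels: pd.Series,
                               protein_coding: set[str] | None = None
                               ) -> tuple[dict, pd.DataFrame]:
    """Venn counts of DEG sets and the class-flow (Sankey) table.

    Returns ``(venn, flow)`` where venn has keys shared / consensus_only /
    single_only (optionally restricted to protein-coding genes) and flow is
    a source-class x destination-class count table whose row sums equal the
    single-method class counts.
    """
    if list(single_labels.index) != consensus.gene_ids:
        raise ValueError("gene universes differ")
    cons_deg = {g for g, lab in consensus.table["label"].items()
                if lab in ("URG", "DRG")}
    single_deg = {g for g, lab in single_labels.items() if lab in ("URG", "DRG")}
    if protein_coding is not None:
        cons_deg &= protein_coding
        single_deg &= protein_coding
    venn = {"shared": len(cons_deg & single_deg),
            "consensus_only": len(cons_deg - single_deg),
            "single_only": len(single_deg - cons_deg)}
    flow = pd.crosstab(single_labels, consensus.table["label"])
    flow = flow.reindex(index=CLASSES, columns=CLASSES, fill_value=0)
    flow.index.name = "single"
    flow.columns.name = "consensus"
    return venn, flow


class RMCModel:
    """statsmodels-style front end: counts + design in, fitted consensus out.

    >>> model = RMCModel(counts, design, methods=["nb_wald", "voom_like", ...])
    >>> res = model.fit()
    >>> res.summary(); res.consensus.class_counts()
    """

    def __init__(self, counts: CountMatrix, design: DesignSpec,
                 methods: list[str] | None = None,
                 config: RMCConfig | None = None):
        self.counts = counts
        self.design = design
        self.methods = methods or (MANDATORY_METHODS + OPTIONAL_METHODS)
        if len(self.methods) < 3:
            raise ValueError("the consensus needs >= 3 methods")
        self.config = config or RMCConfig()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, samples, **kw) -> "RMCModel":
        counts = CountMatrix.from_frame(frame)
        design = DesignSpec.from_samples(samples, counts.sample_ids)
        return cls(counts, design, **kw)

    def fit(self, weights: dict[str, float] | None = None) -> "RMCResults":
        results = [run_method(m, self.counts, self.design) for m in self.methods]
        normmat = normalize(self.counts, "size_factor")
        consensus = rmc_combine(results, self.counts, normmat, self.design,
                                weights=weights, config=self.config)
        return RMCResults(self, results, consensus, normmat)


class RMCResults:
    """Fitted consensus: per-method tables, combined calls, class taxonomy."""

    def __init__(self, model: RMCModel, method_results: list[MethodResult],
                 consensus: ConsensusResult, normmat: NormalizedMatrix):
        self.model = model
        self.method_results = {r.method: r for r in method_results}
        self.consensus = consensus
        self.normmat = normmat

    def compare_with(self, method: str,
                     protein_coding: set[str] | None = None):
        shared = estimate_log2fc(self.normmat, self.model.design)
        labels = single_method_classes(self.method_results[method],
                                       self.model.counts, self.normmat,
                                       shared, self.model.config)
        return compare_with_single_method(self.consensus, labels, protein_coding)

    def summary(self) -> str:
        cc = self.consensus.class_counts()
        t = self.consensus.table
        lines = [
            "Recursive Method Combination consensus",
            f"  methods: {', '.join(self.method_results)}",
            f"  genes: {len(t)}   tested: {int(t['fdr'].notna().sum())}",
            "  class counts: " + "  ".join(f"{k}={v}" for k, v in cc.items()),
            f"  DEGs called: {int(t['is_deg'].sum())} "
            f"(rescued: {int(t['rescued'].sum())})",
        ]
        return "\n".join(lines)
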