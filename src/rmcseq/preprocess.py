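"""Normalization, batch-effect adjustment, and embedding-based outlier removal.

Two between-sample normalization factor estimators are provided — the
median-of-ratios estimator (robust per-sample ratio to a geometric-mean
pseudo-reference) and the trimmed mean of M-values (TMM) — plus CPM /
log2-CPM transforms. Batch effects are removed on the count scale by
per-gene negative-binomial quantile mapping that preserves the condition
term. Outlier samples are found by density clustering (DBSCAN) of a 2-D
embedding (UMAP in pipeline mode, deterministic PCA in tests); samples the
clustering labels as noise (-1) are the outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix

__all__ = ["NormalizedMatrix", "OutlierReport", "size_factors_median_ratio",
           "tmm_factors", "normalize", "batch_adjust", "detect_outliers"]


@dataclass
class NormalizedMatrix:
    """Real-valued gene x sample matrix with the scheme that produced it."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    scheme: str                      # size_factor | cpm | log2cpm
    factors: np.ndarray              # size factors or library sizes used
    pseudocount: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "NormalizedMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return NormalizedMatrix(self.values[:, idx], list(self.gene_ids),
                                list(sample_ids), self.scheme,
                                self.factors[idx], self.pseudocount)


@dataclass
class OutlierReport:
    embedding: pd.DataFrame          # 2 coordinates per sample
    labels: pd.Series                # cluster label per sample; -1 = noise
    outliers: list[str]
    params: dict


def size_factors_median_ratio(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    factor_s = median over reference genes of count_gs / geomean_g where the
    reference set is genes positive in every sample; if no such gene exists,
    geometric means over positive counts only are used (flagged).
    """
    c = counts.counts.astype(float)
    if not c.any():
        raise ValueError("all-zero count matrix")
    allpos = (c > 0).all(axis=1)
    if allpos.any():
        logc = np.log(c[allpos])
        loggeo = logc.mean(axis=1)
        factors = np.exp(np.median(logc - loggeo[:, None], axis=0))
    else:
        warnings.warn("no gene positive in all samples; using positive-count "
                      "geometric means")
        with np.errstate(divide="ignore"):
            logc = np.where(c > 0, np.log(c), np.nan)
        loggeo = np.nanmean(logc, axis=1)
        ratios = logc - loggeo[:, None]
        factors = np.exp(np.nanmedian(ratios, axis=0))
    return factors


def tmm_factors(counts: CountMatrix, reference: str | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    Per sample, M (log ratio) and A (log abundance) values versus a reference
    sample are computed on doubly-positive genes; after trimming 30% on M and
    5% on A (two-sided), the factor is 2 to the precision-weighted mean M.
    The reference defaults to the sample whose upper-quartile CPM is closest
    to the mean upper quartile.
    """
    c = counts.counts.astype(float)
    n = c.shape[1]
    if n < 2:
        raise ValueError("need >= 2 samples")
    lib = c.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    if reference is None:
        uq = np.array([np.quantile(c[:, j] / lib[j], 0.75) for j in range(n)])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref = counts.sample_ids.index(reference)

    factors = np.ones(n)
    for j in range(n):
        if j == ref:
            continue
        pos = (c[:, j] > 0) & (c[:, ref] > 0)
        if not pos.any():
            warnings.warn(f"no doubly-positive genes for sample "
                          f"{counts.sample_ids[j]!r}; factor set to 1")
            continue
        yj, yr = c[pos, j] / lib[j], c[pos, ref] / lib[ref]
        M = np.log2(yj / yr)
        A = 0.5 * np.log2(yj * yr)
        # binomial delta-method weights (asymptotic precision of M)
        w = 1.0 / ((1 - c[pos, j] / lib[j]) / c[pos, j]
                   + (1 - c[pos, ref] / lib[ref]) / c[pos, ref] + 1e-12)
        keep = _double_trim_mask(M, A, trim_m, trim_a)
        if not keep.any():
            continue
        factors[j] = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    # effective scaling = composition factor x library size, geometric mean 1:
    # counts divided by these are comparable across samples
    factors = factors * lib / lib[ref]
    return factors / np.exp(np.mean(np.log(factors)))


def _double_trim_mask(M: np.ndarray, A: np.ndarray, trim_m: float,
                      trim_a: float) -> np.ndarray:
    keep = np.ones(M.size, bool)
    for v, t in ((M, trim_m), (A, trim_a)):
        lo, hi = np.quantile(v, [t, 1 - t])
        keep &= (v >= lo) & (v <= hi)
    return keep


def normalize(counts: CountMatrix, scheme: str = "size_factor",
              pseudocount: float = 0.5,
              factors: np.ndarray | None = None) -> NormalizedMatrix:
    """Normalize counts: ``size_factor`` (count/factor), ``cpm``, or ``log2cpm``."""
    c = counts.counts.astype(float)
    if scheme == "size_factor":
        f = size_factors_median_ratio(counts) if factors is None else factors
        values = c / f[None, :]
    elif scheme in ("cpm", "log2cpm"):
        lib = c.sum(axis=0) if factors is None else factors
        f = lib
        cpm = c * 1e6 / lib[None, :]
        if scheme == "cpm":
            values = cpm
        else:
            if pseudocount <= 0:
                raise ValueError("pseudocount must be positive for log2cpm")
            values = np.log2(cpm + pseudocount)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if (np.asarray(f) <= 0).any():
        raise ValueError("non-positive normalization factor")
    return NormalizedMatrix(values, list(counts.gene_ids), list(counts.sample_ids),
                            scheme, np.asarray(f, float), pseudocount)


def batch_adjust(counts: CountMatrix, batch: pd.Series,
                 condition: pd.Series) -> CountMatrix:
    """Remove multiplicative batch effects by NB quantile mapping.

    Per gene, batch- and condition-specific NB means are estimated on a
    log-linear additive model with a library-size offset, with a per-batch
    moment dispersion; each observed count is pushed through its batch NB
    CDF (midpoint-corrected) and pulled back through the batch-free NB
    quantile function, preserving the condition term. Single-batch input is
    returned unchanged. Batches fully confounded with condition raise.
    """
    batch = batch.loc[counts.sample_ids]
    condition = condition.loc[counts.sample_ids]
    levels = sorted(batch.unique())
    if len(levels) < 2:
        return CountMatrix(list(counts.gene_ids), list(counts.sample_ids),
                           counts.counts.copy(), counts.gene_meta)
    confounded = [b for b in levels
                  if condition[batch == b].nunique() < condition.nunique()]
    if confounded:
        raise ValueError(f"condition confounded with batch(es): {confounded}")

    c = counts.counts.astype(float)
    # within-batch size factors: between-batch scale differences are treated
    # as batch effect (to be removed), not as library-size variation
    sf = np.ones(c.shape[1])
    for b in sorted(batch.unique()):
        cols = np.where((batch == b).to_numpy())[0]
        sub = CountMatrix(list(counts.gene_ids),
                          [counts.sample_ids[j] for j in cols], counts.counts[:, cols])
        f = size_factors_median_ratio(sub)
        sf[cols] = f / np.exp(np.mean(np.log(f)))
    norm = c / sf[None, :]
    G, n = c.shape
    is_case = (condition == "case").to_numpy()
    b_idx = {b: (batch == b).to_numpy() for b in levels}

    # log-additive decomposition on normalized means: mu = base * cond_effect * batch_effect
    eps = 1e-8
    cond_mean = {g: None for g in (True, False)}
    out = c.copy()
    # per (batch, condition) cell means
    for gi_chunk in np.array_split(np.arange(G), max(G // 512, 1)):
        sub = norm[gi_chunk]
        cell_mean = {}
        cell_var = {}
        for b in levels:
            for cs in (True, False):
                m = b_idx[b] & (is_case == cs)
                if m.sum() == 0:
                    cell_mean[(b, cs)] = None
                    continue
                cell_mean[(b, cs)] = sub[:, m].mean(axis=1)
                cell_var[(b, cs)] = sub[:, m].var(axis=1, ddof=1) if m.sum() > 1 else None
        # condition means pooled over batches (batch-free targets)
        cond_target = {}
        for cs in (True, False):
            ms = [cell_mean[(b, cs)] for b in levels if cell_mean[(b, cs)] is not None]
            cond_target[cs] = np.exp(np.mean([np.log(m + eps) for m in ms], axis=0))
        # per-batch multiplicative effect: ratio of in-batch to target, averaged
        # over conditions present (log scale)
        for b in levels:
            ratios = []
            for cs in (True, False):
                if cell_mean[(b, cs)] is not None:
                    ratios.append(np.log((cell_mean[(b, cs)] + eps)
                                         / (cond_target[cs] + eps)))
            batch_eff = np.exp(np.mean(ratios, axis=0))
            # per-batch moment dispersion pooled over conditions
            phis = []
            for cs in (True, False):
                mu_c = cell_mean[(b, cs)]
                v_c = cell_var.get((b, cs))
                if mu_c is None or v_c is None:
                    continue
                phis.append((v_c - mu_c) / np.maximum(mu_c, eps) ** 2)
            phi = np.clip(np.mean(phis, axis=0), 1e-4, 10.0) if phis else \
                np.full(len(gi_chunk), 0.1)
            for s in np.where(b_idx[b])[0]:
                cs = bool(is_case[s])
                mu_old = np.maximum(cell_mean[(b, cs)], eps) * sf[s]
                mu_new = np.maximum(cond_target[cs], eps) * sf[s]
                out[gi_chunk, s] = _nb_quantile_map(c[gi_chunk, s], mu_old,
                                                    mu_new, phi)
    return CountMatrix(list(counts.gene_ids), list(counts.sample_ids),
                       np.maximum(np.round(out), 0).astype(np.int64),
                       counts.gene_meta)


def _nb_quantile_map(y: np.ndarray, mu_old: np.ndarray, mu_new: np.ndarray,
                     phi: np.ndarray) -> np.ndarray:
    """Map counts through NB(mu_old, phi) CDF into NB(mu_new, phi) quantiles."""
    r = 1.0 / phi
    p_old = r / (r + mu_old)
    p_new = r / (r + mu_new)
    upper = stats.nbinom.cdf(y, r, p_old)
    lower = stats.nbinom.cdf(y - 1, r, p_old)
    u = np.clip((upper + lower) / 2.0, 1e-10, 1 - 1e-10)  # midpoint correction
    return stats.nbinom.ppf(u, r, p_new)


def _knee_eps(dists: np.ndarray) -> float:
    """Knee of the sorted k-NN distance curve: the point farthest from the
    chord joining its endpoints (max-curvature heuristic)."""
    d = np.sort(dists)
    n = len(d)
    if n < 3 or d[-1] == d[0]:
        return float(d[-1]) if d[-1] > 0 else 1.0
    x = np.arange(n, dtype=float)
    # distance from each point to the line through (0, d0) and (n-1, dn)
    dx, dy = n - 1.0, d[-1] - d[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * x - dx * (d - d[0])) / norm
    return float(d[int(np.argmax(dist))])


def detect_outliers(normmat: NormalizedMatrix, method: str = "pca",
                    min_samples: int = 5, eps: float | None = None,
                    seed: int = 0, n_neighbors: int = 15,
                    min_dist: float = 0.1) -> OutlierReport:
    """Embed samples to 2-D and label density-clustering noise as outliers.

    ``method='umap'`` uses the stochastic UMAP embedding (seed mandatory in
    pipeline mode); ``method='pca'`` is the deterministic fallback used in
    tests. DBSCAN ``eps`` defaults to the knee of the ``min_samples``-NN
    distance curve.
    """
    X = normmat.values.T  # samples x genes
    ids = list(normmat.sample_ids)
    if len(ids) < max(10, min_samples):
        warnings.warn("too few samples for outlier detection; empty report")
        emb = pd.DataFrame(np.zeros((len(ids), 2)), index=ids,
                           columns=["dim1", "dim2"])
        return OutlierReport(emb, pd.Series(0, index=ids), [],
                             {"method": method, "skipped": True})
    # deterministic sample ordering, then map back
    order = np.argsort(ids)
    X = X[order]
    ids_sorted = [ids[i] for i in order]

    if method == "umap":
        import umap

        emb2 = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                         n_components=2, random_state=seed).fit_transform(X)
    elif method == "pca":
        emb2 = PCA(n_components=2, random_state=seed).fit_transform(
            X - X.mean(axis=0))
    else:
        raise ValueError(f"unknown embedding method {method!r}")

    k = min(min_samples, len(ids_sorted) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb2)
    kdist = nn.kneighbors(emb2)[0][:, -1]
    if eps is not None:
        eps_used = float(eps)
    else:
        # knee of the k-distance curve, floored at 20x the median k-distance:
        # a single homogeneous cloud's k-distance tail reaches ~10-15x its
        # median in 2-D embeddings of a few dozen samples, while genuinely
        # aberrant samples sit orders of magnitude away
        eps_used = max(_knee_eps(kdist), 20.0 * float(np.median(kdist)))
    if eps_used <= 0:
        eps_used = 1.0
    labels = DBSCAN(eps=eps_used, min_samples=min_samples).fit_predict(emb2)

    emb = pd.DataFrame(emb2, index=ids_sorted, columns=["dim1", "dim2"]).loc[ids]
    lab = pd.Series(labels, index=ids_sorted).loc[ids]
    outliers = sorted(lab.index[lab == -1])
    return OutlierReport(emb, lab, outliers,
                         {"method": method, "eps": eps_used,
                          "min_samples": min_samples, "seed": seed})
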