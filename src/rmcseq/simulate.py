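"""Seeded synthetic-study generator.

Emulates the statistical structure the pipeline assumes: negative-binomial
counts with a mean-dispersion trend phi(mu) = a0/mu + a1, log-normal baseline
means and library-size factors, planted differentially expressed genes,
linear (on the log2 scale) age-dependent expression drift, multiplicative
batch effects, and case clinical covariates (CAG repeat length, onset age,
death age, Vonsattel grade) with the negative CAG-onset correlation observed
in Huntington's disease cohorts. Truth tables record every planted signal so
each downstream stage can be scored.

One random stream per study, split hierarchically by purpose (counts /
clinical / outliers), so e.g. injecting outliers never perturbs the counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import CountMatrix, SampleTable

__all__ = ["SimulationConfig", "SyntheticStudy", "simulate_counts",
           "simulate_clinical", "inject_outliers"]


@dataclass
class ClinicalParams:
    """Case clinical-covariate model.

    CAG drawn uniformly on 40..60; onset = intercept - slope*CAG + noise
    (longer repeats -> earlier onset); death = onset + lifespan(CAG) + noise;
    Vonsattel grade = monotone binning of CAG with +-1 jitter. Defaults give
    |r(CAG, onset)| about 0.85 at n = 146.
    """

    cag_min: int = 40
    cag_max: int = 60
    onset_intercept: float = 95.0
    onset_slope: float = 0.9  # years earlier per extra repeat
    onset_sd: float = 3.5
    lifespan_intercept: float = 28.0
    lifespan_slope: float = 0.2  # years of post-onset survival lost per repeat
    lifespan_sd: float = 3.0
    vonsattel_jitter: float = 0.35


@dataclass
class SimulationConfig:
    """Full description of a synthetic case/control bulk RNA-Seq study."""

    n_genes: int = 2000
    n_cases: int = 20
    n_controls: int = 20
    baseline_meanlog: float = float(np.log(60.0))
    baseline_sdlog: float = 1.0
    dispersion_a0: float = 3.0
    dispersion_a1: float = 0.1
    libsize_sdlog: float = 0.2
    pi_de: float = 0.1
    lfc_min: float = 0.4
    lfc_max: float = 3.0
    n_batches: int = 1
    batch_sdlog2: float = 0.5
    pi_age: float = 0.0
    age_slope_sd: float = 0.02  # log2 units per year for drifting genes
    case_age_mean: float = 58.0
    case_age_sd: float = 11.0
    control_age_mean: float = 70.0
    control_age_sd: float = 10.0
    age_center: float = 60.0
    clinical: ClinicalParams = field(default_factory=ClinicalParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pi_de <= 1 and 0 <= self.pi_age <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 cases and 2 controls")
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise ValueError("dispersion coefficients must be >= 0")
        if self.n_batches < 1:
            raise ValueError("need >= 1 batch")


@dataclass
class SyntheticStudy:
    """A simulated study plus the ground truth planted into it."""

    counts: CountMatrix
    samples: SampleTable
    true_lfc: pd.Series          # signed log2FC, nonzero only for DE genes
    true_age_slope: pd.Series    # log2-per-year slope, nonzero only for drift genes
    true_outliers: list[str]
    batches: pd.Series
    config: SimulationConfig

    @property
    def true_de_genes(self) -> list[str]:
        return list(self.true_lfc.index[self.true_lfc != 0.0])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mu, phi) with var = mu + phi*mu^2, via the gamma-Poisson mixture."""
    phi = np.broadcast_to(phi, mu.shape)
    lam = np.where(phi > 0,
                   rng.gamma(np.where(phi > 0, 1.0 / np.maximum(phi, 1e-12), 1.0),
                             np.maximum(phi, 1e-12) * mu),
                   mu)
    return rng.poisson(lam)


def simulate_counts(config: SimulationConfig) -> SyntheticStudy:
    """Generate a study; identical config (incl. seed) gives identical output."""
    root = np.random.SeedSequence(config.seed)
    counts_ss, clinical_ss, _outlier_ss = root.spawn(3)
    rng = np.random.default_rng(counts_ss)

    G, nc, nk = config.n_genes, config.n_cases, config.n_controls
    n = nc + nk
    gene_ids = [f"G{i:05d}" for i in range(G)]
    sample_ids = [f"case{i:03d}" for i in range(nc)] + [f"ctrl{i:03d}" for i in range(nk)]
    is_case = np.r_[np.ones(nc, bool), np.zeros(nk, bool)]

    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, G)
    sizefac = rng.lognormal(0.0, config.libsize_sdlog, n)

    lfc = np.zeros(G)
    n_de = int(round(config.pi_de * G))
    if n_de:
        de_idx = rng.choice(G, n_de, replace=False)
        mag = rng.uniform(config.lfc_min, config.lfc_max, n_de)
        sign = rng.choice([-1.0, 1.0], n_de)
        lfc[de_idx] = mag * sign

    age_slope = np.zeros(G)
    n_age = int(round(config.pi_age * G))
    if n_age:
        age_idx = rng.choice(G, n_age, replace=False)
        age_slope[age_idx] = rng.normal(0.0, config.age_slope_sd, n_age)

    ages = np.empty(n)
    ages[:nc] = rng.normal(config.case_age_mean, config.case_age_sd, nc)
    ages[nc:] = rng.normal(config.control_age_mean, config.control_age_sd, nk)
    ages = np.clip(ages, 1.0, None)

    batch = rng.integers(0, config.n_batches, n)
    batch_effect = np.zeros((G, config.n_batches))
    if config.n_batches > 1:
        batch_effect = rng.normal(0.0, config.batch_sdlog2, (G, config.n_batches))

    log2mu = (np.log2(baseline)[:, None]
              + np.log2(sizefac)[None, :]
              + lfc[:, None] * is_case[None, :]
              + age_slope[:, None] * (ages - config.age_center)[None, :]
              + batch_effect[:, batch])
    mu = np.exp2(np.clip(log2mu, -30, 30))
    phi = config.dispersion_a0 / np.maximum(mu, 1e-8) + config.dispersion_a1
    counts = _nb_draw(rng, mu, phi)

    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "condition": np.where(is_case, "case", "control"),
        "age": np.round(ages, 1),
        "batch": [f"b{b}" for b in batch],
    })
    clin = simulate_clinical(nc, config.clinical, rng=np.random.default_rng(clinical_ss))
    for col in clin.columns:
        meta[col] = np.nan
        meta.loc[: nc - 1, col] = clin[col].to_numpy()
    samples = SampleTable(meta)

    return SyntheticStudy(
        counts=CountMatrix(gene_ids, sample_ids, counts),
        samples=samples,
        true_lfc=pd.Series(lfc, index=gene_ids, name="log2fc"),
        true_age_slope=pd.Series(age_slope, index=gene_ids, name="age_slope"),
        true_outliers=[],
        batches=pd.Series([f"b{b}" for b in batch], index=sample_ids, name="batch"),
        config=config,
    )


def simulate_clinical(n_cases: int, params: ClinicalParams | None = None,
                      seed: int | None = None, *,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Clinical covariate columns (cag, onset_age, death_age, vonsattel) for cases."""
    if n_cases < 3:
        raise ValueError("need n_cases >= 3")
    p = params or ClinicalParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    cag = rng.integers(p.cag_min, p.cag_max + 1, n_cases)
    onset = p.onset_intercept - p.onset_slope * cag + rng.normal(0, p.onset_sd, n_cases)
    if (onset <= 0).any():
        warnings.warn("clipped non-positive onset ages to 1 year")
        onset = np.clip(onset, 1.0, None)
    lifespan = (p.lifespan_intercept - p.lifespan_slope * cag
                + rng.normal(0, p.lifespan_sd, n_cases))
    lifespan = np.clip(lifespan, 0.0, None)  # death never precedes onset
    death = onset + lifespan
    # monotone 5-grade binning of CAG with mild jitter
    span = max(p.cag_max - p.cag_min, 1)
    grade = (cag - p.cag_min) / span * 4.0 + rng.normal(0, p.vonsattel_jitter * 2, n_cases)
    vonsattel = np.clip(np.round(grade), 0, 4).astype(int)
    return pd.DataFrame({
        "cag": cag,
        "onset_age": np.round(onset, 1),
        "death_age": np.round(death, 1),
        "vonsattel": vonsattel,
    })


def inject_outliers(study: SyntheticStudy, k: int, magnitude: float = 2.0
                    ) -> SyntheticStudy:
    """Replace k samples' profiles with draws from a distorted baseline.

    Each outlier's expected profile is the study baseline shifted by
    ``magnitude`` log2 units per gene with an independent random sign — the
    signature of an aberrant sample (tissue mix-up, degraded RNA): a profile
    distortion of typical size ``magnitude``. A uniform shift would be
    removed by library-size normalization and is deliberately not used.
    The affected sample ids are recorded in ``true_outliers``; counts for
    unaffected samples are untouched (the outlier stream is independent).
    """
    if k <= 0:
        warnings.warn("k <= 0: no outliers injected")
        return study
    if k >= study.counts.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    root = np.random.SeedSequence(study.config.seed)
    _, _, outlier_ss = root.spawn(3)
    rng = np.random.default_rng(outlier_ss)

    n = study.counts.n_samples
    pick = rng.choice(n, k, replace=False)
    counts = study.counts.counts.copy()
    cfg = study.config
    base_log2 = np.log2(np.maximum(counts.mean(axis=1), 0.5))
    for j in pick:
        signs = rng.choice([-1.0, 1.0], counts.shape[0])
        shifted = np.exp2(base_log2 + magnitude * signs)
        phi = cfg.dispersion_a0 / np.maximum(shifted, 1e-8) + cfg.dispersion_a1
        counts[:, j] = _nb_draw(rng, shifted, phi)
    outlier_ids = [study.counts.sample_ids[j] for j in sorted(pick)]
    return SyntheticStudy(
        counts=CountMatrix(list(study.counts.gene_ids),
                           list(study.counts.sample_ids), counts),
        samples=study.samples,
        true_lfc=study.true_lfc,
        true_age_slope=study.true_age_slope,
        true_outliers=outlier_ids,
        batches=study.batches,
        config=study.config,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
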