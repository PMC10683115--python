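"""Seedable generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes:

* expression — a latent Gaussian copula over log2 expression whose
  correlation is ``rho_within`` inside each of the two gene clusters and
  ``rho_between`` (negative) across them, exponentiated and rounded to
  counts, with dropout producing non-detected zeros;
* outcomes — exponential event times with hazard h0 * exp(beta * z(score)),
  uniform censoring and administrative truncation at the follow-up maximum,
  plus a binormal progression label whose population AUC against the marker
  is Phi(auc_effect / sqrt(2));
* ATAC peak sets — consensus peaks on one synthetic chromosome with
  negative-binomial replicate counts, a background differential rate
  multiplied by ``enrichment_fold`` near the anchor, and a fraction of
  differential peaks that are condition-unique;
* contact matrices — Poisson counts around a power-law distance decay with
  cross-boundary attenuation;
* eQTL links — SNPs uniform over the locus with same-side target preference.

Every generator is a pure function of (config, seed): per-generator
independent RNG streams are derived from the root seed by fixed offsets, so
adding one generator never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .genome import GenomicInterval, LocusModel, default_mmp_locus
from .accessibility import PeakSet
from .architecture import ContactMatrix
from .outcomes import OutcomeTable

__all__ = [
    "SimulationConfig",
    "tnbc_preset",
    "dcis_preset",
    "simulate_expression",
    "simulate_outcomes",
    "simulate_peaksets",
    "simulate_contact_matrix",
    "simulate_eqtl_links",
    "synthetic_anchor",
]

# Fixed stream offsets: one sub-stream per generator.
_STREAMS = {
    "expression": 11,
    "outcomes": 23,
    "peaks": 37,
    "contacts": 41,
    "eqtl": 53,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with the study-scale defaults.

    Defaults echo the analysis anchors: 10-kb contact bins, a 60-month
    follow-up restriction, windows spanned by a 20-Mb synthetic chromosome,
    three ATAC replicates per condition, and a 3x boundary-proximal
    differential enrichment within +/- 0.5 Mb of the anchor.
    """

    n_samples: int = 200
    rho_within: float = 0.5
    rho_between: float = -0.3
    mu: float = 8.0  # per-gene log2 location
    sigma: float = 1.0  # per-gene log2 scale
    delta_3prime: float = 0.0  # planted mean shift on the 3' block (log2)
    dropout_rate: float = 0.05
    include_neighbors: bool = False

    # outcomes
    beta_survival: float = 0.283  # log-hazard per SD of ratio score
    baseline_hazard: float = 0.012  # events per month at z = 0
    censor_rate: float = 0.3
    followup_max_months: float = 60.0
    auc_effect: float = 1.045  # binormal separation; AUC = Phi(d / sqrt 2)
    progression_prevalence: float = 14.0 / 85.0

    # ATAC peaks
    n_peaks: int = 34047  # study-scale consensus peak count
    frac_differential_background: float = 0.10
    enrichment_fold: float = 3.0
    enrichment_halfwidth: int = 500_000
    n_replicates: int = 3
    unique_fraction: float = 0.2  # differential peaks emitted condition-unique
    peak_width: int = 600
    mean_count: float = 200.0
    nb_dispersion: float = 0.01  # clonal cell-line replicates are tight
    chrom_length: int = 20_000_000
    lfc_range: tuple[float, float] = (2.0, 3.0)

    # contact matrix
    bin_size: int = 10_000
    n_bins: int = 100
    boundary_bin: int | None = None  # default: n_bins // 2
    decay_exponent: float = 1.0
    attenuation: float = 0.2
    contact_depth: float = 100.0  # expected adjacent-bin count
    poisson_noise: bool = True
    matrix_chrom: str = "chr11"
    matrix_origin: int = 102_233_350  # puts IE8's midpoint in bin 50

    # eQTL
    n_links: int = 200
    same_side_prob: float = 0.9

    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho_between <= self.rho_within < 1.0):
            raise ValueError("require -1 < rho_between <= rho_within < 1")
        for name in (
            "dropout_rate",
            "censor_rate",
            "frac_differential_background",
            "unique_fraction",
            "same_side_prob",
            "progression_prevalence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.frac_differential_background * self.enrichment_fold > 1.0:
            raise ValueError(
                "frac_differential_background * enrichment_fold exceeds 1"
            )
        bb = self.boundary_bin if self.boundary_bin is not None else self.n_bins // 2
        if not 0 < bb < self.n_bins:
            raise ValueError("boundary bin must be strictly inside (0, n_bins)")

    def locus(self) -> LocusModel:
        return default_mmp_locus(include_neighbors=self.include_neighbors)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lfc_range"] = list(d["lfc_range"])
        return d


def tnbc_preset(seed: int = 0, **overrides) -> SimulationConfig:
    """Invasive-cohort preset: n = 417 with a planted 3'-shift."""
    cfg = SimulationConfig(n_samples=417, delta_3prime=0.5, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def dcis_preset(seed: int = 0, **overrides) -> SimulationConfig:
    """In situ cohort preset: 85 samples of which ~14 progress."""
    cfg = SimulationConfig(
        n_samples=85, progression_prevalence=14.0 / 85.0, seed=seed
    )
    return replace(cfg, **overrides) if overrides else cfg


def _cluster_correlation(n5: int, n3: int, rho_w: float, rho_b: float) -> np.ndarray:
    n = n5 + n3
    block = np.full((n, n), rho_b)
    block[:n5, :n5] = rho_w
    block[n5:, n5:] = rho_w
    np.fill_diagonal(block, 1.0)
    eig = np.linalg.eigvalsh(block)
    if eig.min() < -1e-10:
        raise ValueError(
            f"correlation target not positive semi-definite for "
            f"rho_within={rho_w}, rho_between={rho_b} "
            f"(block sizes {n5}/{n3}, min eigenvalue {eig.min():.3g})"
        )
    return block


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, list[str]]:
    """Raw-count expression matrix with the two anti-correlated clusters.

    Latent per-sample log2 values are multivariate normal with the
    block-structured correlation target, location ``mu`` (plus
    ``delta_3prime`` on the 3' block) and scale ``sigma``; counts are
    ``round(2**latent - 1)`` clipped at zero, and dropout zeroes cells at
    ``dropout_rate``.  Genes are ordered by genomic coordinate.
    """
    rng = _rng(config.seed, "expression")
    locus = config.locus()
    genes = [g for g in locus.genes if g.cluster_label != "none"]
    five = [g for g in genes if g.cluster_label == "5prime"]
    three = [g for g in genes if g.cluster_label == "3prime"]
    ordered = five + three  # build correlation in block order
    corr = _cluster_correlation(
        len(five), len(three), config.rho_within, config.rho_between
    )
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(ordered)))
    z = rng.standard_normal((config.n_samples, len(ordered))) @ chol.T
    mu = np.full(len(ordered), config.mu, dtype=float)
    mu[len(five):] += config.delta_3prime
    latent = mu + config.sigma * z
    counts = np.clip(np.round(2.0**latent - 1.0), 0, None)
    if config.dropout_rate > 0:
        drop = rng.random(counts.shape) < config.dropout_rate
        counts = np.where(drop, 0.0, counts)
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    # Re-sort rows into genomic coordinate order.
    df = pd.DataFrame(
        counts.T, index=[g.gene_id for g in ordered], columns=sample_ids
    )
    coord_order = [g.gene_id for g in locus.genes if g.gene_id in df.index]
    df = df.loc[coord_order]
    return ExpressionMatrix(df), sample_ids


def simulate_outcomes(scores, config: SimulationConfig) -> OutcomeTable:
    """Survival times and progression labels driven by a per-sample score.

    Event times are exponential with hazard
    ``baseline_hazard * exp(beta_survival * z)`` where z is the standardized
    score.  A ``censor_rate`` fraction of subjects receives an independent
    Uniform(0, followup_max) censoring time, and everything is
    administratively truncated at ``followup_max_months``.

    Progression labels follow the binormal model: scores are mapped through
    their ranks onto the binormal marginal, and each sample is labelled with
    the posterior class probability of that model, so the population AUC of
    score vs label is Phi(auc_effect / sqrt(2)).
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    rng = _rng(config.seed, "outcomes")
    n = scores.size
    sd = scores.std()
    z = (scores - scores.mean()) / sd if sd > 0 else np.zeros(n)

    hazard = config.baseline_hazard * np.exp(config.beta_survival * z)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = np.full(n, np.inf)
    is_censored = rng.random(n) < config.censor_rate
    censor_time[is_censored] = rng.uniform(
        0.0, config.followup_max_months, size=int(is_censored.sum())
    )
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    beyond = time > config.followup_max_months
    time = np.where(beyond, config.followup_max_months, time)
    event = event & ~beyond
    time = np.maximum(time, 1e-6)

    # Binormal progression labels via the rank-to-marginal transform.
    d = config.auc_effect
    pi = config.progression_prevalence
    grid = np.linspace(-8.0, 8.0 + d, 4001)
    mixture_cdf = (1 - pi) * stats.norm.cdf(grid) + pi * stats.norm.cdf(grid - d)
    ranks = stats.rankdata(z, method="average")
    u = np.interp((ranks - 0.5) / n, mixture_cdf, grid)
    post = pi * stats.norm.pdf(u - d)
    post = post / (post + (1 - pi) * stats.norm.pdf(u))
    labels = rng.random(n) < post

    sample_ids = [f"S{i:04d}" for i in range(n)]
    return OutcomeTable(sample_ids, time, event, labels, scores)


def simulate_peaksets(
    config: SimulationConfig,
) -> tuple[PeakSet, pd.DataFrame]:
    """Consensus peaks with replicate counts and planted differentials.

    Peak positions are uniform on one synthetic chromosome with the anchor
    at its midpoint.  A peak is differential with probability
    ``frac_differential_background``, multiplied by ``enrichment_fold``
    within ``enrichment_halfwidth`` of the anchor.  Differential peaks are
    either condition-unique (mean zero in one condition) or intensity
    shifts with |log2 fold change| drawn from ``lfc_range``.  Replicate
    counts are negative binomial around the condition means.

    Returns the PeakSet (conditions ``wt`` then ``disrupted``) and a truth
    table (columns: is_differential, direction, is_unique, in_window).
    """
    rng = _rng(config.seed, "peaks")
    anchor_mid = config.chrom_length // 2
    if anchor_mid - config.enrichment_halfwidth < 0 or (
        anchor_mid + config.enrichment_halfwidth > config.chrom_length
    ):
        raise ValueError("enrichment region exceeds the chromosome span")

    starts = np.sort(
        rng.integers(0, config.chrom_length - config.peak_width, size=config.n_peaks)
    )
    mids = starts + config.peak_width / 2.0
    in_window = np.abs(mids - anchor_mid) < config.enrichment_halfwidth
    p_diff = np.where(
        in_window,
        config.frac_differential_background * config.enrichment_fold,
        config.frac_differential_background,
    )
    is_diff = rng.random(config.n_peaks) < p_diff
    direction = np.where(rng.random(config.n_peaks) < 0.5, 1.0, -1.0)
    direction[~is_diff] = 0.0
    is_unique = is_diff & (rng.random(config.n_peaks) < config.unique_fraction)

    base_mean = rng.lognormal(
        mean=np.log(config.mean_count), sigma=0.5, size=config.n_peaks
    )
    lfc = rng.uniform(*config.lfc_range, size=config.n_peaks) * direction
    mean_wt = base_mean * 2.0 ** (-lfc / 2.0)
    mean_dis = base_mean * 2.0 ** (lfc / 2.0)
    # Condition-unique peaks: flat zero in the condition they are absent from.
    mean_wt = np.where(is_unique & (direction > 0), 0.0, mean_wt)
    mean_dis = np.where(is_unique & (direction < 0), 0.0, mean_dis)

    def nb_draw(means: np.ndarray) -> np.ndarray:
        r = 1.0 / config.nb_dispersion
        out = np.zeros((config.n_peaks, config.n_replicates), dtype=int)
        pos = means > 0
        for rep in range(config.n_replicates):
            lam = rng.gamma(r, means[pos] / r)
            out[pos, rep] = rng.poisson(lam)
        return out

    counts_wt = nb_draw(mean_wt)
    counts_dis = nb_draw(mean_dis)
    # Guarantee the unique-presence branch sees full presence on its side.
    counts_wt[is_unique & (direction < 0)] = np.maximum(
        counts_wt[is_unique & (direction < 0)], 1
    )
    counts_dis[is_unique & (direction > 0)] = np.maximum(
        counts_dis[is_unique & (direction > 0)], 1
    )

    peaks = [
        GenomicInterval("chrSyn", int(s), int(s) + config.peak_width, ".", f"peak_{i}")
        for i, s in enumerate(starts)
    ]
    ps = PeakSet(peaks, {"wt": counts_wt, "disrupted": counts_dis})
    truth = pd.DataFrame(
        {
            "is_differential": is_diff,
            "direction": direction,
            "is_unique": is_unique,
            "in_window": in_window,
        }
    )
    return ps, truth


def synthetic_anchor(config: SimulationConfig) -> GenomicInterval:
    """The anchor interval at the midpoint of the synthetic chromosome."""
    mid = config.chrom_length // 2
    return GenomicInterval("chrSyn", mid - 550, mid + 550, "+", "anchor")


def simulate_contact_matrix(config: SimulationConfig) -> ContactMatrix:
    """Two-domain contact matrix with power-law decay and a boundary.

    Expected contacts are ``depth * |i - j| ** -decay_exponent`` (depth on
    the diagonal), multiplied by ``attenuation`` when i and j straddle the
    boundary bin.  Entries are Poisson sampled (symmetrically) unless
    ``poisson_noise`` is off.
    """
    rng = _rng(config.seed, "contacts")
    n = config.n_bins
    b = config.boundary_bin if config.boundary_bin is not None else n // 2
    if not 0 < b < n:
        raise ValueError("boundary bin must be strictly inside (0, n_bins)")
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    dist = np.abs(i - j).astype(float)
    with np.errstate(divide="ignore"):
        mu = config.contact_depth * np.where(
            dist == 0, 1.0, dist**-config.decay_exponent
        )
    # Pairs strictly straddling the boundary bin (i < b < j) are attenuated;
    # the boundary bin itself talks to both domains, which makes the
    # insulation minimum unique at b in the noiseless case.
    straddle = ((i < b) & (j > b)) | ((i > b) & (j < b))
    mu = np.where(straddle, mu * config.attenuation, mu)
    if config.poisson_noise:
        upper = np.triu(rng.poisson(mu))
        counts = upper + np.triu(upper, 1).T
    else:
        counts = mu
    return ContactMatrix(
        config.matrix_chrom, config.bin_size, config.matrix_origin, counts
    )


def simulate_eqtl_links(
    config: SimulationConfig, locus: LocusModel | None = None
) -> pd.DataFrame:
    """eQTL link table with a same-side target preference.

    Each link's SNP is uniform over the locus span; its target gene is
    drawn from the genes on the SNP's side of the boundary with probability
    ``same_side_prob``, from the other side otherwise.
    """
    rng = _rng(config.seed, "eqtl")
    locus = locus or config.locus()
    span = locus.span
    mid = locus.boundary.midpoint
    genes = [g for g in locus.genes if g.cluster_label != "none"]
    up = [g for g in genes if g.tss <= mid]
    down = [g for g in genes if g.tss > mid]
    if not up or not down:
        raise ValueError("need genes on both sides of the boundary")
    rows = []
    snps = rng.integers(span.start, span.end, size=config.n_links)
    same = rng.random(config.n_links) < config.same_side_prob
    for pos, s in zip(snps, same):
        snp_up = pos <= mid
        pool = (up if snp_up else down) if s else (down if snp_up else up)
        g = pool[rng.integers(len(pool))]
        rows.append(
            {
                "snp_pos": int(pos),
                "target_gene_id": g.gene_id,
                "target_tss": int(g.tss),
                "effect_sign": int(rng.choice([-1, 1])),
                "p_value": float(10.0 ** -rng.uniform(2, 10)),
            }
        )
    return pd.DataFrame(rows)
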