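"""Differential chromatin accessibility and anchor-centric enrichment.

A consensus peak is classified differential either because it is present in
every replicate of exactly one condition (unique presence) or because its
normalized intensity shifts significantly between conditions (Welch t-test
on log2 CPM, Benjamini-Hochberg across tested peaks, with a fold-change
floor).  Regional enrichment around an anchor uses the representation
factor RF = (k/n)/(K/N) with an upper-tail hypergeometric p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .genome import ElementAnnotation, GeneAnnotation, GenomicInterval, overlaps
from .signatures import group_compare

__all__ = [
    "PeakSet",
    "DifferentialPeaks",
    "EnrichmentResult",
    "consensus_peaks",
    "normalize_counts",
    "differential_peaks",
    "representation_factor",
    "windowed_enrichment",
    "tss_delta_profiles",
    "annotate_peaks",
    "DifferentialPeakClassifier",
]

DEFAULT_HALFWIDTHS = (500_000, 1_000_000, 2_000_000, 5_000_000, 10_000_000)


@dataclass
class PeakSet:
    """Consensus peaks with per-replicate counts for two conditions."""

    peaks: list[GenomicInterval]
    counts: dict[str, np.ndarray]  # condition -> (n_peaks, n_replicates)

    def __post_init__(self) -> None:
        if len(self.counts) != 2:
            raise ValueError("PeakSet requires exactly two conditions")
        for cond, arr in self.counts.items():
            arr = np.asarray(arr)
            if arr.ndim != 2 or arr.shape[0] != len(self.peaks):
                raise ValueError(f"count table for {cond!r} must be peaks x replicates")
            if (arr < 0).any():
                raise ValueError(f"negative counts in {cond!r}")
            self.counts[cond] = arr
        reps = {arr.shape[1] for arr in self.counts.values()}
        if min(reps) < 2:
            raise ValueError("need >= 2 replicates per condition")

    @property
    def conditions(self) -> tuple[str, str]:
        return tuple(self.counts)  # insertion order: (reference, perturbed)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def consensus_peaks(
    replicate_peak_lists: list[list[GenomicInterval]], min_overlap_bp: int = 1
) -> list[GenomicInterval]:
    """Peaks of the first replicate supported by every other replicate.

    A first-replicate peak enters the consensus iff every other replicate
    contains a peak overlapping it by at least ``min_overlap_bp``.  The
    consensus keeps the first replicate's coordinates, so identical
    replicate lists return the input list unchanged.
    """
    if len(replicate_peak_lists) < 2:
        raise ValueError("need >= 2 replicate peak lists")
    if any(len(lst) == 0 for lst in replicate_peak_lists):
        warnings.warn("a replicate has no peaks; consensus is empty", stacklevel=2)
        return []
    out = []
    for cand in replicate_peak_lists[0]:
        ok = True
        for other in replicate_peak_lists[1:]:
            if not any(
                p.chrom == cand.chrom
                and min(p.end, cand.end) - max(p.start, cand.start) >= min_overlap_bp
                for p in other
            ):
                ok = False
                break
        if ok:
            out.append(cand)
    return out


def normalize_counts(p: PeakSet) -> dict[str, np.ndarray]:
    """Per-replicate counts-per-million, then log2(x + 1)."""
    out = {}
    for cond, arr in p.counts.items():
        totals = arr.sum(axis=0).astype(float)
        if (totals == 0).any():
            raise ValueError(f"all-zero replicate in condition {cond!r}")
        cpm = arr / totals * 1e6
        out[cond] = np.log2(cpm + 1.0)
    return out


@dataclass
class DifferentialPeaks:
    """Per-peak differential classification; one row per consensus peak.

    Columns: ``class`` in {gained, lost, unchanged}, ``reason`` in
    {unique-presence, intensity-shift, none}, ``log2fc`` (perturbed minus
    reference, log2 CPM scale), ``fdr`` (NaN for untested/unique peaks).
    """

    peaks: list[GenomicInterval]
    table: pd.DataFrame

    @property
    def is_differential(self) -> np.ndarray:
        return (self.table["class"] != "unchanged").to_numpy()


def differential_peaks(
    p: PeakSet, alpha_fdr: float = 0.05, min_abs_log2fc: float = 1.0
) -> DifferentialPeaks:
    """Classify every consensus peak as gained / lost / unchanged.

    The perturbed condition is the second key of ``p.counts``; ``gained``
    means more accessible there.
    """
    ref, alt = p.conditions
    raw_ref, raw_alt = p.counts[ref], p.counts[alt]
    norm = normalize_counts(p)
    log_ref, log_alt = norm[ref], norm[alt]
    log2fc = log_alt.mean(axis=1) - log_ref.mean(axis=1)

    present_ref = (raw_ref > 0).all(axis=1)
    absent_ref = (raw_ref == 0).all(axis=1)
    present_alt = (raw_alt > 0).all(axis=1)
    absent_alt = (raw_alt == 0).all(axis=1)
    unique = (present_ref & absent_alt) | (present_alt & absent_ref)

    classes = np.full(p.n_peaks, "unchanged", dtype=object)
    reasons = np.full(p.n_peaks, "none", dtype=object)
    fdr = np.full(p.n_peaks, np.nan)

    classes[present_alt & absent_ref] = "gained"
    classes[present_ref & absent_alt] = "lost"
    reasons[unique] = "unique-presence"

    tested = ~unique
    if tested.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            tres = stats.ttest_ind(
                log_alt[tested], log_ref[tested], axis=1, equal_var=False
            )
        pvals = np.where(np.isnan(tres.pvalue), 1.0, tres.pvalue)
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        fdr[tested] = qvals
        hit = tested & (fdr < alpha_fdr) & (np.abs(log2fc) >= min_abs_log2fc)
        classes[hit & (log2fc > 0)] = "gained"
        classes[hit & (log2fc < 0)] = "lost"
        reasons[hit] = "intensity-shift"

    table = pd.DataFrame(
        {"class": classes, "reason": reasons, "log2fc": log2fc, "fdr": fdr}
    )
    return DifferentialPeaks(list(p.peaks), table)


def representation_factor(k: int, n: int, K: int, N: int) -> tuple[float, float]:
    """RF = (k/n)/(K/N) with the exact upper-tail hypergeometric p, P(X >= k).

    X counts successes in ``n`` draws without replacement from ``N`` items of
    which ``K`` are successes.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError("require 0 <= k <= min(n, K), n <= N, K <= N")
    if n == 0 or K == 0:
        raise ValueError("representation factor undefined for n = 0 or K = 0")
    rf = (k / n) / (K / N)
    p = hypergeom_upper_tail(k, N, K, n)
    return float(rf), float(p)


def hypergeom_upper_tail(k, N, K, n):
    """Vectorized P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return stats.hypergeom.sf(np.asarray(k) - 1, N, K, n)


@dataclass
class EnrichmentResult:
    halfwidth: int | None  # None = whole-chromosome control row
    k: int  # differential peaks inside the window
    n: int  # peaks inside the window
    K: int  # differential peaks in the universe
    N: int  # peaks in the universe
    rf: float
    p: float


def windowed_enrichment(
    d: DifferentialPeaks,
    anchor: GenomicInterval,
    halfwidths: tuple[int, ...] = DEFAULT_HALFWIDTHS,
) -> list[EnrichmentResult]:
    """Differential-peak enrichment in nested windows around an anchor.

    Membership is by peak midpoint in ``[anchor_mid - hw, anchor_mid + hw)``.
    The universe is the consensus peaks on the anchor's chromosome, and a
    whole-chromosome control row (halfwidth None) is appended, where RF = 1
    by construction.
    """
    if not d.peaks:
        raise ValueError("empty consensus peak set")
    on_chrom = np.array([pk.chrom == anchor.chrom for pk in d.peaks])
    mids = np.array([pk.midpoint for pk in d.peaks])
    diff = d.is_differential
    N = int(on_chrom.sum())
    K = int((on_chrom & diff).sum())
    if N == 0:
        raise ValueError(f"no peaks on anchor chromosome {anchor.chrom}")
    amid = anchor.midpoint
    results = []
    for hw in sorted(halfwidths):
        inside = on_chrom & (mids >= amid - hw) & (mids < amid + hw)
        n = int(inside.sum())
        k = int((inside & diff).sum())
        if n == 0 or K == 0:
            results.append(EnrichmentResult(int(hw), k, n, K, N, np.nan, 1.0))
            continue
        rf, p = representation_factor(k, n, K, N)
        results.append(EnrichmentResult(int(hw), k, n, K, N, rf, p))
    if K > 0:
        rf, p = representation_factor(K, N, K, N)
    else:
        rf, p = np.nan, 1.0
    results.append(EnrichmentResult(None, K, N, K, N, rf, p))
    return results


def tss_delta_profiles(
    p: PeakSet,
    genes: list[GeneAnnotation],
    flank: int = 2000,
    n_bins: int = 40,
) -> tuple[pd.DataFrame, dict]:
    """Accessibility change around each TSS and a 5'-vs-3' cluster test.

    For each gene, normalized intensity (mean log2 CPM over replicates) of
    peaks overlapping each bin of ``[tss - flank, tss + flank)`` is averaged
    per condition; the profile delta is perturbed minus reference, with the
    bin order flipped for minus-strand genes so bins always run 5' to 3'.
    Unknown strand is treated as plus.

    Returns a per-gene table (columns: gene_id, cluster, mean_delta,
    has_peaks, and bin_0..bin_{n_bins-1}) and a summary dict holding the
    rank-test comparison of per-gene mean deltas between the 5' and 3'
    clusters.
    """
    if any(g.tss is None for g in genes):
        raise ValueError("all genes need a TSS")
    ref, alt = p.conditions
    norm = normalize_counts(p)
    sig_ref = norm[ref].mean(axis=1)
    sig_alt = norm[alt].mean(axis=1)
    edges = np.linspace(-flank, flank, n_bins + 1)

    rows = []
    for g in genes:
        lo, hi = g.tss - flank, g.tss + flank
        window = GenomicInterval(g.interval.chrom, max(0, lo), hi)
        hits = [
            i
            for i, pk in enumerate(p.peaks)
            if overlaps(pk, window)
        ]
        prof = np.zeros(n_bins)
        has = bool(hits)
        if has:
            for b in range(n_bins):
                b_lo, b_hi = g.tss + edges[b], g.tss + edges[b + 1]
                in_bin = [
                    i
                    for i in hits
                    if p.peaks[i].start < b_hi and p.peaks[i].end > b_lo
                ]
                if in_bin:
                    prof[b] = float(
                        np.mean([sig_alt[i] - sig_ref[i] for i in in_bin])
                    )
        strand = g.interval.strand
        if strand == "-":
            prof = prof[::-1]
        mean_delta = float(
            np.mean(
                [sig_alt[i] - sig_ref[i] for i in hits]
            )
        ) if has else 0.0
        rows.append(
            {
                "gene_id": g.gene_id,
                "cluster": g.cluster_label,
                "mean_delta": mean_delta,
                "has_peaks": has,
                **{f"bin_{b}": prof[b] for b in range(n_bins)},
            }
        )
    table = pd.DataFrame(rows)

    d5 = table.loc[table["cluster"] == "5prime", "mean_delta"].to_numpy()
    d3 = table.loc[table["cluster"] == "3prime", "mean_delta"].to_numpy()
    summary: dict = {"n_5prime": int(d5.size), "n_3prime": int(d3.size)}
    if d5.size and d3.size:
        u, pval = group_compare(d5, d3)
        summary.update(
            {
                "mean_delta_5prime": float(d5.mean()),
                "mean_delta_3prime": float(d3.mean()),
                "u_statistic": u,
                "p_value": pval,
            }
        )
    return table, summary


_PRIORITY = ("promoter", "insulator", "enhancer")


def annotate_peaks(
    d: DifferentialPeaks, elements: list[ElementAnnotation]
) -> pd.DataFrame:
    """Element-class composition of the differential peaks.

    Each differential peak takes the class of an overlapping element, with
    ties broken promoter > insulator > enhancer; peaks overlapping nothing
    are ``other``.  Returns one row per class with counts and fractions.
    """
    for el in elements:
        if el.kind not in {"promoter", "insulator", "enhancer", "other"}:
            raise ValueError(f"unknown element kind {el.kind!r}")
    labels = []
    for pk, is_diff in zip(d.peaks, d.is_differential):
        if not is_diff:
            continue
        kinds = {el.kind for el in elements if overlaps(pk, el.interval)}
        label = next((k for k in _PRIORITY if k in kinds), "other")
        labels.append(label)
    counts = pd.Series(labels, dtype=object).value_counts()
    out = pd.DataFrame(
        {
            "element_class": list(_PRIORITY) + ["other"],
        }
    )
    out["n_peaks"] = [int(counts.get(c, 0)) for c in out["element_class"]]
    total = out["n_peaks"].sum()
    out["fraction"] = out["n_peaks"] / total if total else 0.0
    return out


class DifferentialPeakClassifier(BaseEstimator):
    """Estimator wrapping the two-branch differential-peak classification.

    Fit on a :class:`PeakSet`; fitted attributes: ``labels_`` (gained / lost
    / unchanged per peak), ``reason_``, ``log2fc_``, ``fdr_``, ``table_``
    and ``result_`` (the full :class:`DifferentialPeaks`).

    Parameters
    ----------
    alpha_fdr : float
        BH false-discovery threshold for the intensity branch.
    min_abs_log2fc : float
        Minimum absolute log2 fold change for the intensity branch.
    """

    def __init__(self, alpha_fdr: float = 0.05, min_abs_log2fc: float = 1.0) -> None:
        self.alpha_fdr = alpha_fdr
        self.min_abs_log2fc = min_abs_log2fc

    def fit(self, X: PeakSet, y=None) -> "DifferentialPeakClassifier":
        res = differential_peaks(
            X, alpha_fdr=self.alpha_fdr, min_abs_log2fc=self.min_abs_log2fc
        )
        self.result_ = res
        self.table_ = res.table
        self.labels_ = res.table["class"].to_numpy()
        self.reason_ = res.table["reason"].to_numpy()
        self.log2fc_ = res.table["log2fc"].to_numpy()
        self.fdr_ = res.table["fdr"].to_numpy()
        return self

    def enrichment(
        self,
        anchor: GenomicInterval,
        halfwidths: tuple[int, ...] = DEFAULT_HALFWIDTHS,
    ) -> list[EnrichmentResult]:
        if not hasattr(self, "result_"):
            raise RuntimeError("classifier is not fitted")
        return windowed_enrichment(self.result_, anchor, halfwidths)
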