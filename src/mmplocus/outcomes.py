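"""Survival stratification and progression classification statistics.

Everything here is implemented from first principles so each statistic has a
brute-force oracle: the Kaplan-Meier product-limit estimator, the two-group
log-rank test with hypergeometric variance, the O/E (Pike) hazard-ratio
estimator, and the ROC/AUC as the midrank Mann-Whitney concordance
probability with a stratified percentile bootstrap CI.

Conventions: times are in months; censored subjects tied with an event time
remain at risk at that time; follow-up restriction administratively censors
at the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OutcomeTable",
    "KMCurve",
    "LogrankResult",
    "RocResult",
    "restrict_followup",
    "dichotomize",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
    "roc_auc",
]


@dataclass
class OutcomeTable:
    """Per-sample time-to-event data with optional progression label/score."""

    sample_ids: list[str]
    time: np.ndarray  # months, > 0
    event: np.ndarray  # bool; True = relapse/death observed
    progression_label: np.ndarray | None = None
    score: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length must match sample_ids")
        if (self.time <= 0).any():
            raise ValueError("times must be positive")
        if self.progression_label is not None:
            self.progression_label = np.asarray(self.progression_label, dtype=bool)
            if self.progression_label.shape != (n,):
                raise ValueError("progression_label length mismatch")
        if self.score is not None:
            self.score = np.asarray(self.score, dtype=float)
            if self.score.shape != (n,):
                raise ValueError("score length mismatch")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, mask: np.ndarray) -> "OutcomeTable":
        mask = np.asarray(mask, dtype=bool)
        ids = [s for s, m in zip(self.sample_ids, mask) if m]
        return OutcomeTable(
            ids,
            self.time[mask],
            self.event[mask],
            None if self.progression_label is None else self.progression_label[mask],
            None if self.score is None else self.score[mask],
        )

    def to_dataframe(self) -> pd.DataFrame:
        d = {"sample_id": self.sample_ids, "time": self.time, "event": self.event.astype(int)}
        if self.progression_label is not None:
            d["progression"] = self.progression_label.astype(int)
        if self.score is not None:
            d["score"] = self.score
        return pd.DataFrame(d)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OutcomeTable":
        return cls(
            [str(s) for s in df["sample_id"]],
            df["time"].to_numpy(float),
            df["event"].to_numpy(bool),
            df["progression"].to_numpy(bool) if "progression" in df else None,
            df["score"].to_numpy(float) if "score" in df else None,
        )


def restrict_followup(t: OutcomeTable, max_months: float = 60.0) -> OutcomeTable:
    """Administratively censor every subject beyond ``max_months``."""
    if max_months <= 0:
        raise ValueError("max_months must be positive")
    beyond = t.time > max_months
    time = np.where(beyond, max_months, t.time)
    event = t.event & ~beyond
    return OutcomeTable(list(t.sample_ids), time, event, t.progression_label, t.score)


def dichotomize(
    scores, method: str = "median", cutoff: float | None = None
) -> np.ndarray:
    """Label each sample high (True, score > threshold) or low (False)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need >= 2 samples to dichotomize")
    if method == "median":
        thr = float(np.median(scores))
    elif method == "value":
        if cutoff is None:
            raise ValueError("method='value' requires a cutoff")
        thr = float(cutoff)
    else:
        raise ValueError("method must be 'median' or 'value'")
    labels = scores > thr
    if labels.all() or (~labels).all():
        raise ValueError("dichotomization produced a single group (constant scores?)")
    return labels


@dataclass
class KMCurve:
    """Product-limit survival estimate at each distinct event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    observed: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(t: OutcomeTable) -> KMCurve:
    """Kaplan-Meier: S(t) = prod over event times t_i <= t of (1 - d_i/n_i)."""
    if len(t) == 0:
        raise ValueError("empty outcome table")
    times, events = t.time, t.event
    uniq = np.unique(times[events])
    surv, at_risk, observed = [], [], []
    s = 1.0
    for ti in uniq:
        n_i = int(np.sum(times >= ti))
        d_i = int(np.sum((times == ti) & events))
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        observed.append(d_i)
        surv.append(s)
    return KMCurve(
        uniq, np.asarray(surv), np.asarray(at_risk), np.asarray(observed)
    )


@dataclass
class LogrankResult:
    chi2: float
    p: float
    observed1: float
    expected1: float
    observed2: float
    expected2: float
    variance: float


def logrank_test(g1: OutcomeTable, g2: OutcomeTable) -> LogrankResult:
    """Two-group log-rank test.

    At each distinct event time, the expected number of events in group 1 is
    d * n1/n and the variance is the hypergeometric
    d (n1/n)(n2/n)(n - d)/(n - 1); chi2 = (O1 - E1)^2 / V with df = 1.
    """
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")
    t = np.concatenate([g1.time, g2.time])
    e = np.concatenate([g1.event, g2.event])
    grp = np.concatenate([np.zeros(len(g1), bool), np.ones(len(g2), bool)])
    if not e.any():
        raise ValueError("no events in either group")
    o1 = e1 = o2 = e2 = v = 0.0
    for ti in np.unique(t[e]):
        at = t >= ti
        n = at.sum()
        n1 = (at & ~grp).sum()
        n2 = n - n1
        died = (t == ti) & e
        d = died.sum()
        d1 = (died & ~grp).sum()
        o1 += d1
        o2 += d - d1
        e1 += d * n1 / n
        e2 += d * n2 / n
        if n > 1:
            v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    chi2 = (o1 - e1) ** 2 / v if v > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if v > 0 else 1.0
    return LogrankResult(float(chi2), p, float(o1), float(e1), float(o2), float(e2), float(v))


def hazard_ratio(
    g1: OutcomeTable, g2: OutcomeTable, conf_level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """O/E (Pike) hazard-ratio estimate of group 1 vs group 2 with CI.

    HR = (O1/E1)/(O2/E2); SE(log HR) = sqrt(1/E1 + 1/E2).
    """
    lr = logrank_test(g1, g2)
    if lr.expected1 <= 0 or lr.expected2 <= 0:
        raise ValueError("both groups need positive expected events")
    if lr.observed1 == 0 or lr.observed2 == 0:
        raise ValueError("both groups need at least one observed event")
    hr = (lr.observed1 / lr.expected1) / (lr.observed2 / lr.expected2)
    se = np.sqrt(1.0 / lr.expected1 + 1.0 / lr.expected2)
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    lo = hr * np.exp(-z * se)
    hi = hr * np.exp(z * se)
    return float(hr), (float(lo), float(hi))


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci: tuple[float, float] | None


def _auc_midrank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney concordance probability via midranks."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores, method="average")
    r_pos = ranks[labels].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def roc_auc(
    scores,
    labels,
    n_bootstrap: int = 2000,
    random_state: int | np.random.Generator | None = None,
    conf_level: float = 0.95,
) -> RocResult:
    """ROC curve and AUC for a continuous score against binary labels.

    The AUC is the midrank Mann-Whitney concordance probability (ties count
    one half).  The CI is a percentile bootstrap stratified by class; pass
    ``n_bootstrap=0`` to skip it.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("labels must contain both classes")
    auc = _auc_midrank(scores, labels)

    # ROC points at every distinct threshold (descending).
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = labels[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tps = np.cumsum(l_sorted)[distinct]
    fps = np.cumsum(~l_sorted)[distinct]
    tpr = np.r_[0.0, tps / labels.sum()]
    fpr = np.r_[0.0, fps / (~labels).sum()]
    thresholds = np.r_[np.inf, s_sorted[distinct]]

    ci = None
    if n_bootstrap:
        rng = np.random.default_rng(random_state)
        pos = np.nonzero(labels)[0]
        neg = np.nonzero(~labels)[0]
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            ip = rng.choice(pos, size=pos.size, replace=True)
            ineg = rng.choice(neg, size=neg.size, replace=True)
            idx = np.concatenate([ip, ineg])
            lab = np.concatenate(
                [np.ones(pos.size, bool), np.zeros(neg.size, bool)]
            )
            boots[b] = _auc_midrank(scores[idx], lab)
        alpha = 1.0 - conf_level
        ci = (
            float(np.quantile(boots, alpha / 2)),
            float(np.quantile(boots, 1 - alpha / 2)),
        )
    return RocResult(fpr, tpr, thresholds, float(auc), ci)
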