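"""Patient bipartition and two-group survival testing for gene sets.

For a candidate gene set, each patient's feature vector is the expression of
those genes; patients are split into two groups by K-means (K=2) under the
correlation distance ``1 - PCC``, and the groups' survival is compared with
the Kaplan-Meier estimator and the unstratified log-rank test (chi-square
with 1 degree of freedom).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .network import ExpressionMatrix, SubNetwork

__all__ = [
    "ClinicalTable",
    "SurvivalTestResult",
    "kmeans_bipartition",
    "km_curve",
    "logrank_test",
    "genes_survival_test",
    "subnetwork_survival_test",
    "derive_seed",
]


def derive_seed(master_seed: int, name: str) -> int:
    """Stable per-stage seed below 2**31 from a master seed and a label."""
    tag = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ClinicalTable:
    """Right-censored survival records aligned to expression samples.

    time : follow-up in days (>= 0, finite).
    event : True when death was observed (DECEASED), False when the patient
        was censored alive at last follow-up (LIVING).
    """

    sample_ids: list
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers in clinical table")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if self.time.shape != (len(self.sample_ids),) or self.event.shape != self.time.shape:
            raise ValueError("time/event lengths must match sample_ids")
        if not np.all(np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValueError("survival times must be finite and non-negative")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
        idx = np.array([self._index[s] for s in sample_ids], dtype=int)
        return self.time[idx], self.event[idx]


@dataclass
class SurvivalTestResult:
    subnetwork_id: str
    group_labels: np.ndarray
    chi_square: float
    pvalue: float
    group_sizes: tuple
    sample_ids: list


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    if np.any(norms <= 1e-300):
        raise ValueError(
            "zero-variance sample feature vector: correlation distance undefined"
        )
    return Xc / norms


def kmeans_bipartition(
    features: np.ndarray,
    replicates: int = 100,
    rng_seed: int = 0,
    max_iter: int = 100,
) -> np.ndarray:
    """K=2 clustering of samples under the correlation distance.

    ``features`` is samples x genes.  Each row is centred and scaled to unit
    norm so the distance between samples is ``1 - PCC`` of their feature
    vectors; centroids are means of member rows, re-standardized.  The best
    of ``replicates`` random restarts (lowest total within-cluster distance)
    wins; restarts with an earlier index win ties, so the labels are
    deterministic for a given seed.  Labels are canonicalized so sample 0 is
    in group 0.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 genes")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    Xs = _standardize_rows(X)
    if np.all(np.abs(Xs - Xs[0]) < 1e-12):
        raise ValueError("degenerate feature matrix: all samples identical")
    n = Xs.shape[0]
    rng = np.random.default_rng(rng_seed)
    best_obj = np.inf
    best_labels: Optional[np.ndarray] = None
    for _ in range(replicates):
        init = rng.choice(n, size=2, replace=False)
        C = Xs[init].copy()
        labels = np.full(n, -1, dtype=int)
        for _ in range(max_iter):
            sim = Xs @ C.T  # correlation with each centroid
            new = np.argmax(sim, axis=1)
            for k in (0, 1):
                if not np.any(new == k):
                    # revive the empty cluster at the worst-fitting sample
                    d_own = 1.0 - sim[np.arange(n), new]
                    far = int(np.argmax(d_own))
                    new[far] = k
            if np.array_equal(new, labels):
                break
            labels = new
            for k in (0, 1):
                mean = Xs[labels == k].mean(axis=0)
                norm = np.linalg.norm(mean)
                if norm <= 1e-300:
                    far = int(np.argmax(1.0 - (Xs @ C.T)[np.arange(n), labels]))
                    mean, norm = Xs[far], 1.0
                C[k] = mean / norm
        sim = Xs @ C.T
        obj = float(np.sum(1.0 - sim[np.arange(n), labels]))
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_labels = labels.copy()
    assert best_labels is not None
    if best_labels[0] == 1:
        best_labels = 1 - best_labels
    return best_labels


def km_curve(time: Sequence[float], event: Sequence[bool]) -> Tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit estimate as a step function.

    Returns ``(times, survival)`` with the curve starting at ``S(0) = 1``;
    ``survival`` is non-increasing.  With no censoring it reduces to the
    empirical survival function.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.size == 0 or t.shape != e.shape:
        raise ValueError("time and event must be equal-length, non-empty")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank_test(
    time1: Sequence[float],
    event1: Sequence[bool],
    time2: Sequence[float],
    event2: Sequence[bool],
) -> Tuple[float, float]:
    """Unweighted two-group log-rank test.

    Tied event times are handled with the standard hypergeometric variance on
    the pooled risk set.  Returns ``(chi_square, pvalue)`` where the p-value
    is the upper tail of chi-square with 1 df.
    """
    t1 = np.asarray(time1, dtype=float)
    t2 = np.asarray(time2, dtype=float)
    e1 = np.asarray(event1, dtype=bool)
    e2 = np.asarray(event2, dtype=bool)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be non-empty")
    for t in (t1, t2):
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise ValueError("times must be finite and non-negative")
    if int(e1.sum()) + int(e2.sum()) == 0:
        raise ValueError("no events: log-rank test undefined")
    res = _lifelines_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return float(res.test_statistic), float(res.p_value)


def genes_survival_test(
    genes: Sequence[str],
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    rng_seed: int = 0,
    replicates: int = 100,
    test_id: str = "",
) -> SurvivalTestResult:
    """Bipartition patients on a gene list's expression and log-rank the groups.

    Samples present in the expression matrix but absent from the clinical
    table are dropped with a warning; at least 2 shared samples are required.
    """
    gene_list = sorted(set(genes))
    if len(gene_list) < 2:
        raise ValueError("need at least 2 genes for correlation-distance features")
    clin_set = set(clin.sample_ids)
    shared = [s for s in expr.sample_ids if s in clin_set]
    n_dropped = expr.n_samples - len(shared)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} expression sample(s) missing from clinical table; dropped",
            stacklevel=2,
        )
    if len(shared) < 2:
        raise ValueError("fewer than 2 samples shared between expression and clinical data")
    pos = {s: i for i, s in enumerate(expr.sample_ids)}
    sidx = [pos[s] for s in shared]
    feats = expr.submatrix(gene_list)[:, sidx].T  # samples x genes
    labels = kmeans_bipartition(feats, replicates=replicates, rng_seed=rng_seed)
    time, event = clin.subset(shared)
    g0, g1 = labels == 0, labels == 1
    chi, p = logrank_test(time[g0], event[g0], time[g1], event[g1])
    return SurvivalTestResult(
        subnetwork_id=test_id,
        group_labels=labels,
        chi_square=chi,
        pvalue=p,
        group_sizes=(int(g0.sum()), int(g1.sum())),
        sample_ids=shared,
    )


def subnetwork_survival_test(
    sub: SubNetwork,
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    rng_seed: int = 0,
    replicates: int = 100,
) -> SurvivalTestResult:
    """Survival screen for one mined sub-network (features = its genes)."""
    missing = [g for g in sub.members if g not in set(expr.gene_ids)]
    if missing:
        raise KeyError(f"sub-network genes absent from expression matrix: {missing[:5]}")
    return genes_survival_test(
        sub.sorted_members,
        expr,
        clin,
        rng_seed=rng_seed,
        replicates=replicates,
        test_id=sub.id,
    )
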