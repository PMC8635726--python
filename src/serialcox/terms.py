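"""Risk-term extraction: which phrases separate high- from low-risk patients.

The pipeline mirrors the model-interpretation analysis: collect all
N-grams from the reports of the predicted high- and low-risk tertiles,
keep those whose patient-level presence differs significantly between
the groups (Fisher's exact test with Benjamini-Hochberg control), then
cluster the surviving N-grams by normalized Levenshtein distance
(single linkage) and report one representative phrase per cluster.
Each representative can be validated by a log-rank test between the
patients whose reports contain it and those whose reports do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from scipy import stats as _stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .corpus import Cohort
from .encoder import tokenize
from .evaluation import UndefinedResultError, logrank_test

__all__ = [
    "NGramStats",
    "NGramCluster",
    "extract_ngrams",
    "differential_ngrams",
    "edit_distance",
    "normalized_edit_distance",
    "cluster_ngrams",
    "term_survival_test",
    "embed_patients",
    "project_2d",
]


def extract_ngrams(cohort: Cohort, n_min: int = 1, n_max: int = 5,
                   max_tokens: int = 512) -> dict[str, set[str]]:
    """Map each N-gram (joined by spaces) to the set of patients whose
    reports contain it.

    Presence is patient-level: an N-gram appearing in several reports of
    one patient counts that patient once.
    """
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    if n_min > n_max:
        raise ValueError(f"n_min {n_min} > n_max {n_max}")
    presence: dict[str, set[str]] = {}
    for rec in cohort:
        for rep in rec.reports:
            toks = tokenize(rep.text, max_tokens=max_tokens).tokens
            for n in range(n_min, n_max + 1):
                for i in range(len(toks) - n + 1):
                    gram = " ".join(toks[i : i + n])
                    presence.setdefault(gram, set()).add(rec.patient_id)
    return presence


@dataclass(frozen=True)
class NGramStats:
    """Presence counts and differential-frequency test for one N-gram."""

    ngram: str
    count_high: int
    count_low: int
    p_value: float
    q_value: float
    direction: str  # "high-risk" | "low-risk"


def differential_ngrams(presence: dict[str, set[str]], high_ids, low_ids,
                        alpha: float = 0.05,
                        min_patients: int = 5) -> list[NGramStats]:
    """N-grams whose patient-level presence differs between risk groups.

    Per N-gram a 2x2 table (present/absent x high/low) is tested with
    Fisher's exact test; Benjamini-Hochberg controls the FDR at
    ``alpha``.  N-grams present in fewer than ``min_patients`` of the
    two groups combined are not tested.  Direction is the group with the
    higher presence proportion.  Returned sorted by q-value then name.
    """
    high = set(high_ids)
    low = set(low_ids)
    if not high or not low:
        raise ValueError("both risk groups must be non-empty")
    if high & low:
        raise ValueError("risk groups must be disjoint")
    n_high, n_low = len(high), len(low)

    grams, pvals, counts = [], [], []
    for gram, patients in presence.items():
        a = len(patients & high)
        b = len(patients & low)
        if a + b < min_patients:
            continue
        table = [[a, n_high - a], [b, n_low - b]]
        _, p = _stats.fisher_exact(table, alternative="two-sided")
        grams.append(gram)
        pvals.append(p)
        counts.append((a, b))
    if not grams:
        return []
    qvals = _stats.false_discovery_control(np.asarray(pvals), method="bh")
    out = []
    for gram, p, q, (a, b) in zip(grams, pvals, qvals, counts):
        if q > alpha:
            continue
        direction = "high-risk" if a / n_high >= b / n_low else "low-risk"
        out.append(NGramStats(gram, a, b, float(p), float(q), direction))
    out.sort(key=lambda s: (s.q_value, s.p_value, s.ngram))
    return out


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance on characters."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, task="distance")["editDistance"])


def normalized_edit_distance(a: str, b: str) -> float:
    """Levenshtein distance divided by the longer string's length."""
    if not a and not b:
        return 0.0
    return edit_distance(a, b) / max(len(a), len(b))


@dataclass(frozen=True)
class NGramCluster:
    """A group of near-duplicate N-grams with one representative."""

    members: tuple[NGramStats, ...]
    representative: NGramStats

    @property
    def size(self) -> int:
        return len(self.members)


def cluster_ngrams(stats: list[NGramStats],
                   threshold: float = 0.3) -> list[NGramCluster]:
    """Single-linkage clustering of N-grams by normalized edit distance.

    Clusters are merged while the single-linkage distance is <= the
    threshold.  The representative of a cluster is the member with the
    highest total presence count; ties go to the lowest p-value, then to
    the longest N-gram (with patient-level presence a phrase and its
    sub-phrases have identical support, and the most specific phrase is
    the informative one), then lexicographic order.
    """
    if not stats:
        raise ValueError("cluster_ngrams needs at least one N-gram")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    n = len(stats)
    if n == 1:
        return [NGramCluster(members=tuple(stats), representative=stats[0])]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = normalized_edit_distance(
                stats[i].ngram, stats[j].ngram
            )
    labels = fcluster(linkage(squareform(dist, checks=False), method="single"),
                      t=threshold, criterion="distance")
    clusters = []
    for lab in np.unique(labels):
        members = tuple(stats[i] for i in np.flatnonzero(labels == lab))
        rep = min(
            members,
            key=lambda s: (-(s.count_high + s.count_low), s.p_value,
                           -len(s.ngram), s.ngram),
        )
        clusters.append(NGramCluster(members=members, representative=rep))
    clusters.sort(key=lambda c: c.representative.p_value)
    return clusters


def term_survival_test(cohort: Cohort, term: str,
                       max_tokens: int = 512) -> tuple[float, float, dict[str, int]]:
    """Log-rank test between patients with and without a term.

    A patient carries the term if it appears, as a token N-gram, in any
    of their reports.  Returns (chi2, p, group sizes).
    """
    term_tokens = tokenize(term, max_tokens=max_tokens).tokens
    n = len(term_tokens)
    gram = " ".join(term_tokens)
    with_term, without = [], []
    for rec in cohort:
        found = False
        for rep in rec.reports:
            toks = tokenize(rep.text, max_tokens=max_tokens).tokens
            if any(" ".join(toks[i : i + n]) == gram
                   for i in range(len(toks) - n + 1)):
                found = True
                break
        (with_term if found else without).append(rec)
    if not with_term or not without:
        raise UndefinedResultError(
            f"term {term!r} does not split the cohort (present in "
            f"{len(with_term)}/{len(cohort)} patients)"
        )
    chi2, p = logrank_test(
        [r.outcome.time for r in with_term], [r.outcome.event for r in with_term],
        [r.outcome.time for r in without], [r.outcome.event for r in without],
    )
    return chi2, p, {"with_term": len(with_term), "without_term": len(without)}


def embed_patients(results, cohort: Cohort,
                   first_report_only: bool = True) -> dict[str, np.ndarray]:
    """Final-hidden-state embedding per patient.

    By default only the first report feeds the recurrence, matching the
    visualization protocol for patient embedding vectors.
    """
    mode = "first_report" if first_report_only else "serial"
    vectors = results.patient_vectors(cohort, mode=mode)
    return {pid: vectors[i] for i, pid in enumerate(cohort.patient_ids)}


def project_2d(vectors: dict[str, np.ndarray], method: str = "pca",
               seed: int = 0) -> dict[str, tuple[float, float]]:
    """Project patient embeddings to 2-D for scatter visualization.

    ``method`` is "tsne" (established t-SNE implementation) or "pca"
    (deterministic fallback suited to tests and small cohorts).
    """
    if len(vectors) < 2:
        raise ValueError("project_2d needs at least 2 vectors")
    ids = list(vectors)
    X = np.stack([np.asarray(vectors[i], dtype=float) for i in ids])
    if method == "pca":
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, random_state=seed).fit_transform(X)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(2.0, (len(ids) - 1) / 3.0))
        coords = TSNE(n_components=2, random_state=seed, init="pca",
                      perplexity=perplexity).fit_transform(X)
    else:
        raise ValueError(f"unknown projection method {method!r}")
    return {pid: (float(x), float(y)) for pid, (x, y) in zip(ids, coords)}
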