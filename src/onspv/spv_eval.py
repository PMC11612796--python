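"""Scoring of simulated-prosthetic-vision task responses and chance baselines.

Three psychophysical tasks are scored: counting objects (absolute and
relative error), ordering objects by distance or size (Kendall's rank
correlation, computed only when the reported count is correct) and 3-way
object classification (error fraction). Virtual "random subjects" provide
the chance-level baseline: counts drawn from the empirical count
distribution of the stimulus set, orderings drawn as uniform random
permutations, and classification with independent uniform target and answer.
Group differences are assessed with a Kruskal-Wallis test followed, when
significant, by pairwise Dunn tests with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "count_errors",
    "ordering_tau",
    "classification_error",
    "CountDistribution",
    "simulate_random_subjects",
    "compare_groups",
    "dunn_test",
]


def count_errors(n_true: int, n: int) -> tuple[float, float]:
    """Absolute and relative object-count errors: |n_true - n|, |n_true - n| / n_true."""
    if n_true < 1:
        raise ValueError("relative error undefined for n_true < 1")
    eps_a = abs(n_true - n)
    return float(eps_a), float(eps_a / n_true)


def ordering_tau(truth, answer) -> float | None:
    """Kendall's tau between two orderings given as permutations of 1..n.

    Returns ``None`` when the lengths differ (the respondent reported the
    wrong number of objects); such trials are excluded from aggregation
    rather than scored.
    """
    truth = np.asarray(truth, dtype=int)
    answer = np.asarray(answer, dtype=int)
    if truth.size != answer.size:
        return None
    for name, perm in (("truth", truth), ("answer", answer)):
        if sorted(perm.tolist()) != list(range(1, perm.size + 1)):
            raise ValueError(f"{name} is not a permutation of 1..n")
    return float(stats.kendalltau(truth, answer).statistic)


def classification_error(truth_labels, answers) -> float:
    """Fraction of mislabeled samples."""
    truth_labels = list(truth_labels)
    answers = list(answers)
    if len(truth_labels) != len(answers):
        raise ValueError("label lists must have equal length")
    if not truth_labels:
        raise ValueError("empty label lists")
    wrong = sum(t != a for t, a in zip(truth_labels, answers))
    return wrong / len(truth_labels)


@dataclass(frozen=True)
class CountDistribution:
    """Empirical probability over object counts (the respondent's prior)."""

    counts: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "probabilities", p / p.sum())

    @classmethod
    def from_counts(cls, observed_counts) -> "CountDistribution":
        vals, freq = np.unique(np.asarray(observed_counts, dtype=int), return_counts=True)
        return cls(counts=vals, probabilities=freq / freq.sum())

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(self.counts, size=size, p=self.probabilities)


def simulate_random_subjects(
    dist: CountDistribution,
    scene_truths: list[dict],
    n_subjects: int = 10,
    seed: int = 0,
    n_labels: int = 3,
) -> dict:
    """Chance-level performance of ``n_subjects`` random-answer subjects.

    Per scene, a virtual subject reports a count drawn from ``dist``;
    orderings are uniform random permutations of 1..M (M the true count),
    scored only on trials where the reported count happens to be correct;
    classification draws target and answer independently and uniformly over
    ``n_labels`` classes. Returns per-subject scores and their quartiles.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        eps_a, eps_r, taus_d, taus_s, cls_pairs = [], [], [], [], []
        for truth in scene_truths:
            n_true = int(truth["count"])
            n_said = int(dist.sample(rng, 1)[0])
            ea, er = count_errors(n_true, n_said)
            eps_a.append(ea)
            eps_r.append(er)
            if n_said == n_true and n_true >= 2:
                base = np.arange(1, n_true + 1)
                taus_d.append(ordering_tau(base, rng.permutation(base)))
                taus_s.append(ordering_tau(base, rng.permutation(base)))
            cls_pairs.append(
                (int(rng.integers(n_labels)), int(rng.integers(n_labels)))
            )
        rows.append(
            {
                "subject": s,
                "count_abs_error": float(np.mean(eps_a)),
                "count_rel_error": float(np.mean(eps_r)),
                "tau_distance": float(np.mean(taus_d)) if taus_d else np.nan,
                "tau_size": float(np.mean(taus_s)) if taus_s else np.nan,
                "classification_error": classification_error(
                    [t for t, _ in cls_pairs], [a for _, a in cls_pairs]
                ),
            }
        )
    table = pd.DataFrame(rows).set_index("subject")
    quartiles = table.quantile([0.25, 0.50, 0.75])
    return {"scores": table, "quartiles": quartiles}


def dunn_test(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Dunn tests on rank sums with Bonferroni correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)), with
    T the tie correction sum(t^3 - t) / (12 (N - 1)).
    """
    names = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(data)
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for k, d in zip(names, data):
        mean_ranks[k] = ranks[start : start + d.size].mean()
        sizes[k] = d.size
        start += d.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": z,
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, p_raw * n_pairs),
            }
        )
    return pd.DataFrame(rows)


def compare_groups(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """Kruskal-Wallis across groups; pairwise Dunn-Bonferroni if significant."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    data = [np.asarray(v, dtype=float) for v in groups.values()]
    try:
        kw = stats.kruskal(*data)
        kw_stat, kw_p = float(kw.statistic), float(kw.pvalue)
    except ValueError:  # all numbers identical: the test is undefined
        return {"kruskal_statistic": np.nan, "kruskal_p": np.nan,
                "significant": False, "dunn": None, "note": "all values identical"}
    report = {
        "kruskal_statistic": kw_stat,
        "kruskal_p": kw_p,
        "significant": bool(kw_p < alpha),
        "dunn": None,
    }
    if report["significant"]:
        report["dunn"] = dunn_test(groups)
    return report
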