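"""Individual atypicality scores and their extreme-value distribution.

Each subject's largest departures from the normative model are summarized
by the trimmed mean of the top 1% absolute Z values — globally across all
vertices and within each parcel. Because these scores behave like sample
maxima of near-Gaussian deviations, their cross-subject distribution is
modeled with a Gumbel (type I extreme value) law, fit by maximum
likelihood. A top-k cohort-membership test asks whether the k most
atypical subjects are enriched for cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


def extreme_score(z_row, fraction: float = 0.01) -> float:
    """Trimmed mean of the ``ceil(fraction * m)`` largest absolute Z values."""
    z_row = np.asarray(z_row, dtype=float).ravel()
    if z_row.size == 0:
        raise ValueError("empty Z row")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    a = np.abs(z_row)
    k = max(1, math.ceil(fraction * a.size))
    top = np.partition(a, a.size - k)[a.size - k:]
    return float(np.mean(top))


def extreme_scores(Z, fraction: float = 0.01) -> np.ndarray:
    """Row-wise :func:`extreme_score` over a subjects x vertices array."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    a = np.abs(Z)
    k = max(1, math.ceil(fraction * a.shape[1]))
    top = np.partition(a, a.shape[1] - k, axis=1)[:, a.shape[1] - k:]
    return top.mean(axis=1)


def regional_extreme_scores(Z, region_of_vertex, fraction: float = 0.01
                            ) -> np.ndarray:
    """Per-region trimmed-top scores: subjects x regions array.

    The trimming count floors at one vertex, so small parcels reduce to
    the regional maximum |Z|.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    region_of_vertex = np.asarray(region_of_vertex, dtype=int)
    if region_of_vertex.size != Z.shape[1]:
        raise ValueError("parcellation does not cover all vertices")
    regions = np.unique(region_of_vertex)
    out = np.empty((Z.shape[0], regions.size))
    for i, r in enumerate(regions):
        verts = region_of_vertex == r
        if not verts.any():
            raise ValueError(f"region {r} is empty")
        out[:, i] = extreme_scores(Z[:, verts], fraction)
    return out


@dataclass
class ExtremeScoreSet:
    """Per-subject global and per-region atypicality scores."""

    global_scores: np.ndarray           # subjects
    regional_scores: np.ndarray         # subjects x regions
    region_ids: np.ndarray
    fraction: float
    subject_ids: np.ndarray | None = None


def score_subjects(Z, region_of_vertex, fraction: float = 0.01,
                   subject_ids=None) -> ExtremeScoreSet:
    region_of_vertex = np.asarray(region_of_vertex, dtype=int)
    return ExtremeScoreSet(
        global_scores=extreme_scores(Z, fraction),
        regional_scores=regional_extreme_scores(Z, region_of_vertex, fraction),
        region_ids=np.unique(region_of_vertex),
        fraction=fraction,
        subject_ids=None if subject_ids is None else np.asarray(subject_ids),
    )


@dataclass
class GumbelFit:
    loc: float      # mu
    scale: float    # beta, > 0
    loglik: float
    n: int
    converged: bool


def fit_gumbel(scores) -> GumbelFit:
    """Maximum-likelihood Gumbel fit via the 1-D profile likelihood.

    The scale solves beta = mean(x) - sum(x e^{-x/beta}) / sum(e^{-x/beta})
    (bracketed bisection on the profile score); the location then follows in
    closed form, mu = -beta * log(mean(e^{-x/beta})).
    """
    x = np.asarray(scores, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 scores for an extreme-value fit")
    sd = x.std()
    if sd == 0:
        raise ValueError("scores are constant; Gumbel scale degenerate")
    xbar = x.mean()

    def profile_score(beta: float) -> float:
        w = np.exp(-(x - xbar) / beta)  # shift-invariant, avoids overflow
        return beta - xbar + float(np.sum(x * w) / np.sum(w))

    # moment estimate brackets the root
    beta0 = sd * np.sqrt(6.0) / np.pi
    lo, hi = beta0, beta0
    while profile_score(lo) > 0 and lo > 1e-12:
        lo /= 2.0
    while profile_score(hi) < 0 and hi < 1e12:
        hi *= 2.0
    converged = True
    try:
        beta = float(optimize.brentq(profile_score, lo, hi, xtol=1e-12,
                                     rtol=1e-12))
    except ValueError:
        beta, converged = beta0, False
    mu = -beta * np.log(np.mean(np.exp(-(x - xbar) / beta))) + xbar
    loglik = float(np.sum(stats.gumbel_r.logpdf(x, loc=mu, scale=beta)))
    return GumbelFit(loc=float(mu), scale=beta, loglik=loglik, n=x.size,
                     converged=converged)


def fit_extreme_value(scores, family: str = "gumbel"):
    """Gumbel by default; generalized extreme value behind a flag."""
    if family == "gumbel":
        return fit_gumbel(scores)
    if family == "gev":
        shape, loc, scale = stats.genextreme.fit(np.asarray(scores, float))
        ll = float(np.sum(stats.genextreme.logpdf(scores, shape, loc, scale)))
        return {"shape": shape, "loc": loc, "scale": scale, "loglik": ll}
    raise ValueError(f"unknown extreme-value family {family!r}")


@dataclass
class TopKResult:
    k: int
    n_cases_in_top: int
    p_value: float
    null: str
    top_subjects: np.ndarray


def topk_membership_test(scores, group_labels, k: int = 15,
                         null: str = "hypergeometric",
                         case_label="ASD") -> TopKResult:
    """Are the k most atypical subjects enriched for cases?

    Subjects are ranked by score descending (ties broken by stable input
    order, which is reported via ``top_subjects``). The p-value is the
    upper tail P(X >= observed) under the chosen null: ``hypergeometric``
    (sampling without replacement from the realized cohort sizes),
    ``binomial-cohort`` (with-replacement at the cohort case proportion),
    or ``binomial-half`` (coin-flip null, success probability 0.5).
    """
    scores = np.asarray(scores, dtype=float)
    group_labels = np.asarray(group_labels)
    n = scores.size
    if group_labels.size != n:
        raise ValueError("labels do not match scores")
    if not 1 <= k <= n:
        raise ValueError("k must lie in [1, n]")
    if np.unique(group_labels).size < 2:
        raise ValueError("need two groups for a membership test")
    order = np.argsort(-scores, kind="stable")
    top = order[:k]
    x = int(np.sum(group_labels[top] == case_label))
    n_case = int(np.sum(group_labels == case_label))
    if null == "hypergeometric":
        p = float(stats.hypergeom.sf(x - 1, n, n_case, k))
    elif null == "binomial-cohort":
        p = float(stats.binom.sf(x - 1, k, n_case / n))
    elif null == "binomial-half":
        p = float(stats.binom.sf(x - 1, k, 0.5))
    else:
        raise ValueError(f"unknown null {null!r}")
    return TopKResult(k=k, n_cases_in_top=x, p_value=p, null=null,
                      top_subjects=top)


def scores_frame(scores: ExtremeScoreSet, cohort: pd.DataFrame | None = None
                 ) -> pd.DataFrame:
    """Tidy per-subject score table (global + one column per region)."""
    df = pd.DataFrame({"global": scores.global_scores})
    for i, r in enumerate(scores.region_ids):
        df[f"region_{r}"] = scores.regional_scores[:, i]
    if scores.subject_ids is not None:
        df.insert(0, "subject_id", scores.subject_ids)
    elif cohort is not None:
        df.insert(0, "subject_id", cohort["subject_id"].to_numpy())
    return df
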