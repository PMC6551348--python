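"""Cohort-level views of the individual deviation maps.

Two complementary summaries: (1) overlap maps counting, at every vertex,
how many subjects of each cohort/schedule deviate significantly in each
direction — the individual-centric view; (2) the classical mass-univariate
case-control GLM on the raw measurements — the group-centric view. The
package's central property is that sparse, subject-specific deviations
produce widespread overlap-map signal while leaving the GLM nearly empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deviations import bh_fdr


@dataclass
class OverlapMap:
    """Signed deviation counts per vertex for each (cohort, schedule) cell.

    ``counts[(cohort, schedule, sign)]`` is a per-vertex subject count
    (schedule "all" pools the cohort); ``proportions`` holds the fraction
    of the cell's subjects with at least one significant vertex;
    ``group_sizes`` the cell sizes.
    """

    counts: dict
    proportions: dict
    group_sizes: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (cohort, schedule, sign), arr in self.counts.items():
            for v, c in enumerate(arr):
                rows.append((cohort, schedule, sign, v, int(c)))
        return pd.DataFrame(
            rows, columns=["cohort", "schedule", "sign", "vertex", "count"])

    def total_deviating(self, cohort: str, schedule: str = "all") -> int:
        """Summed deviating-vertex count over subjects of a cell."""
        return int(self.counts[(cohort, schedule, "positive")].sum()
                   + self.counts[(cohort, schedule, "negative")].sum())


def overlap_map(masks, cohort_labels, schedule_labels=None) -> OverlapMap:
    """Count subjects with significant positive/negative deviations at each
    vertex, per cohort and (optionally) per schedule."""
    masks = np.atleast_2d(np.asarray(masks))
    cohort_labels = np.asarray(cohort_labels)
    if cohort_labels.size != masks.shape[0]:
        raise ValueError("cohort labels do not match mask rows")
    if schedule_labels is not None:
        schedule_labels = np.asarray(schedule_labels)
        if schedule_labels.size != masks.shape[0]:
            raise ValueError("schedule labels do not match mask rows")

    counts: dict = {}
    proportions: dict = {}
    sizes: dict = {}

    def add_cell(cohort: str, schedule: str, sel: np.ndarray) -> None:
        sub = masks[sel]
        counts[(cohort, schedule, "positive")] = (sub > 0).sum(axis=0)
        counts[(cohort, schedule, "negative")] = (sub < 0).sum(axis=0)
        sizes[(cohort, schedule)] = int(sel.sum())
        for sign, arr in (("positive", sub > 0), ("negative", sub < 0)):
            with_any = (arr.any(axis=1)).sum()
            proportions[(cohort, schedule, sign)] = (
                float(with_any) / sel.sum() if sel.sum() else 0.0)

    for cohort in np.unique(cohort_labels):
        sel = cohort_labels == cohort
        add_cell(str(cohort), "all", sel)
        if schedule_labels is not None:
            for sched in np.unique(schedule_labels[sel]):
                add_cell(str(cohort), str(sched),
                         sel & (schedule_labels == sched))
    return OverlapMap(counts=counts, proportions=proportions,
                      group_sizes=sizes)


class CollinearDesignError(ValueError):
    """Raised when the GLM design matrix is rank deficient."""


def _build_design(diagnosis, age, sex, age_powers, include_sex, interaction):
    diagnosis = np.asarray(diagnosis, dtype=float)
    age_c = np.asarray(age, dtype=float) - np.mean(age)
    cols = [np.ones_like(diagnosis), diagnosis]
    names = ["intercept", "diagnosis"]
    for power in sorted(age_powers):
        cols.append(age_c ** power)
        names.append(f"age^{power}")
    if include_sex and sex is not None:
        cols.append(np.asarray(sex, dtype=float))
        names.append("sex")
    if interaction:
        cols.append(diagnosis * age_c)
        names.append("diagnosis:age")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise CollinearDesignError(
            f"design matrix rank deficient; collinear columns: {bad}")
    return X, names


def _ols_tmap(X, Y, term_idx):
    """Vectorized per-vertex OLS: t statistic and p for one design column."""
    n, k = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y              # k x V
    resid = Y - X @ beta
    dof = n - k
    sigma2 = np.sum(resid ** 2, axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[term_idx, term_idx], 1e-300))
    t = beta[term_idx] / se
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    return beta[term_idx], t, np.clip(p, np.finfo(float).tiny, 1.0), dof


def glm_case_control(Y, diagnosis, age, sex=None, age_powers=(1,),
                     include_sex: bool = True, interaction: bool = False,
                     stratify_by_sex: bool = False, q: float = 0.05):
    """Mass-univariate case-control GLM per vertex.

    Ordinary least squares of each vertex's measurement on diagnosis
    (1 = case), centered age polynomial terms, and optionally sex; the test
    is on the diagnosis coefficient, or on the diagnosis-by-age interaction
    when ``interaction=True``. BH-FDR across vertices at level ``q``.

    With ``stratify_by_sex`` returns ``{"male": DataFrame, "female":
    DataFrame}`` of sex-specific models (sex column dropped); otherwise one
    DataFrame with columns vertex, beta, t, p, significant, plus a model
    descriptor in ``df.attrs``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if not set(age_powers) <= {1, 2, 3}:
        raise ValueError("age_powers must be a subset of {1, 2, 3}")
    if stratify_by_sex:
        if sex is None:
            raise ValueError("stratify_by_sex requires sex labels")
        sex = np.asarray(sex, dtype=float)
        out = {}
        for label, val in (("male", 1.0), ("female", 0.0)):
            sel = sex == val
            out[label] = glm_case_control(
                Y[sel], np.asarray(diagnosis, float)[sel],
                np.asarray(age, float)[sel], sex=None, age_powers=age_powers,
                include_sex=False, interaction=interaction, q=q)
        return out

    X, names = _build_design(diagnosis, age, sex, age_powers,
                             include_sex, interaction)
    term = names.index("diagnosis:age" if interaction else "diagnosis")
    beta, t, p, dof = _ols_tmap(X, Y, term)
    significant = bh_fdr(p, q) if q > 0 else np.zeros(Y.shape[1], dtype=bool)
    df = pd.DataFrame({
        "vertex": np.arange(Y.shape[1]), "beta": beta, "t": t, "p": p,
        "significant": significant,
    })
    df.attrs["model"] = {"terms": names, "tested": names[term], "dof": dof,
                         "q": q}
    return df
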