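"""Associations between atypicality scores and symptom severity.

Spearman rank correlations of the global and regional extreme deviation
scores with each symptom instrument domain, overall and stratified by sex.
Regional correlations are corrected by BH-FDR within each
(symptom x stratum) family across regions; the global correlation is
reported at nominal alpha in its own right. Post hoc confound checks
(IQ, image-quality surrogate) are reported descriptively without FDR.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .config import SYMPTOM_MOMENTS
from .deviations import bh_fdr
from .extremes import ExtremeScoreSet

#: below this sample size the Spearman p-value is computed by exhaustive
#: permutation rather than the t approximation
_EXACT_N = 10


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    Pairs with a missing value in either vector are dropped; at least 3
    complete pairs are required. The p-value uses the t approximation for
    n >= 10 and an exact two-sided permutation enumeration below that.
    Zero rank variance in either input yields ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if rx.std() == 0 or ry.std() == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n >= _EXACT_N:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho ** 2, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    else:
        rx_c = (rx - rx.mean()) / (rx.std() * np.sqrt(n))
        ry_c = (ry - ry.mean()) / (ry.std() * np.sqrt(n))
        obs = abs(rho)
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = float(np.dot(rx_c, ry_c[list(perm)]))
            if abs(r) >= obs - 1e-12:
                count += 1
            total += 1
        p = count / total
    return rho, min(p, 1.0)


def _strata(cohort_sex: np.ndarray):
    yield "all", np.ones(cohort_sex.size, dtype=bool)
    yield "male", cohort_sex == "male"
    yield "female", cohort_sex == "female"


def associate(scores: ExtremeScoreSet, cohort: pd.DataFrame,
              q: float = 0.05, symptoms=None) -> pd.DataFrame:
    """Correlate extreme deviation scores with symptom scores among cases.

    Returns a tidy table keyed by (scope, symptom, stratum) with rho, p,
    n, and a significance flag: for regional rows, BH-FDR at level ``q``
    within the (symptom x stratum) family across regions; for the global
    row, the nominal p < ``q`` test.
    """
    if scores.global_scores.size != len(cohort):
        raise ValueError("scores do not align with cohort rows")
    symptoms = list(symptoms) if symptoms is not None else [
        s for s in SYMPTOM_MOMENTS if s in cohort.columns]
    asd = (cohort["group"] == "ASD").to_numpy()
    if not asd.any():
        return pd.DataFrame(columns=["scope", "symptom", "stratum", "rho",
                                     "p", "n", "significant", "computable"])
    sex = cohort["sex"].to_numpy()[asd]
    g = scores.global_scores[asd]
    regional = scores.regional_scores[asd]

    rows = []
    for symptom in symptoms:
        s = cohort[symptom].to_numpy(float)[asd]
        if not np.isfinite(s).any():
            continue
        for stratum, sel in _strata(sex):
            scopes = [("global", g[sel])] + [
                (f"region_{r}", regional[sel][:, i])
                for i, r in enumerate(scores.region_ids)]
            fam_rows = []
            for scope, vals in scopes:
                n_pairs = int(np.sum(np.isfinite(vals)
                                     & np.isfinite(s[sel])))
                if n_pairs < 3:
                    fam_rows.append([scope, symptom, stratum, np.nan,
                                     np.nan, n_pairs, False, False])
                    continue
                rho, p = spearman(vals, s[sel])
                fam_rows.append([scope, symptom, stratum, rho, p,
                                 n_pairs, False, np.isfinite(rho)])
            fam = pd.DataFrame(fam_rows, columns=[
                "scope", "symptom", "stratum", "rho", "p", "n",
                "significant", "computable"])
            # regional family: BH across regions; global: nominal alpha
            is_region = fam["scope"].str.startswith("region_")
            testable = is_region & fam["computable"]
            if testable.any() and q > 0:
                fam.loc[testable, "significant"] = bh_fdr(
                    fam.loc[testable, "p"].to_numpy(), q)
            is_global = fam["scope"] == "global"
            fam.loc[is_global, "significant"] = (
                fam.loc[is_global, "computable"]
                & (fam.loc[is_global, "p"] < q))
            rows.append(fam)
    if not rows:
        return pd.DataFrame(columns=["scope", "symptom", "stratum", "rho",
                                     "p", "n", "significant", "computable"])
    return pd.concat(rows, ignore_index=True)


def confound_checks(scores: ExtremeScoreSet, cohort: pd.DataFrame,
                    confounds=("iq", "quality_surrogate")) -> pd.DataFrame:
    """Post hoc Spearman associations of the global score with potential
    confounds, per cohort; descriptive (no FDR), flagged ``post_hoc``."""
    if scores.global_scores.size != len(cohort):
        raise ValueError("scores do not align with cohort rows")
    rows = []
    for group in ("TD", "ASD"):
        sel = (cohort["group"] == group).to_numpy()
        if not sel.any():
            continue
        g = scores.global_scores[sel]
        for conf in confounds:
            if conf not in cohort.columns:
                continue
            c = cohort[conf].to_numpy(float)[sel]
            n_pairs = int(np.sum(np.isfinite(c) & np.isfinite(g)))
            if n_pairs < 3:
                rows.append([group, conf, np.nan, np.nan, n_pairs, False])
                continue
            rho, p = spearman(g, c)
            rows.append([group, conf, rho, p, n_pairs, np.isfinite(rho)])
    df = pd.DataFrame(rows, columns=["cohort", "confound", "rho", "p", "n",
                                     "computable"])
    df["post_hoc"] = True
    return df
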