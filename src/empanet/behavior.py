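"""Scoring and descriptive statistics for the Empathic Experience Scale.

The EES is a 30-item self-report questionnaire answered on a 1-5 Likert
scale. It yields two subscale sums: vicarious experience (VE, the 15
odd-numbered items) and intuitive understanding (IU, the 15 even-numbered
items); no item is reverse-coded, so each subscale ranges 15-75. Raw sums
are Box-Cox transformed (profile-ML lambda) to improve normality, and by
default standardized, before entering mixed-effects brain-behavior models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

N_ITEMS = 30
ITEM_COLUMNS = tuple(f"item_{i:02d}" for i in range(1, N_ITEMS + 1))
#: 1-based odd item numbers -> vicarious experience
VE_ITEMS = tuple(i for i in range(1, N_ITEMS + 1) if i % 2 == 1)
IU_ITEMS = tuple(i for i in range(1, N_ITEMS + 1) if i % 2 == 0)


def score_ees(items) -> tuple[int, int]:
    """Subscale sums (ve_raw, iu_raw) from 30 Likert responses.

    VE sums the odd-numbered items, IU the even-numbered ones (1-based
    numbering); nothing is inverted. Raises on missing or out-of-range
    responses, naming the offending 1-based item index.
    """
    items = np.asarray(items, dtype=float)
    if items.shape != (N_ITEMS,):
        raise ValueError(f"expected exactly {N_ITEMS} responses, got {items.shape}")
    bad = np.flatnonzero(~np.isin(items, [1, 2, 3, 4, 5]))
    if bad.size:
        raise ValueError(
            f"invalid response at item {bad[0] + 1}: {items[bad[0]]!r} "
            "(must be an integer in 1..5)"
        )
    ve = int(items[::2].sum())  # 0-based even positions = 1-based odd items
    iu = int(items[1::2].sum())
    return ve, iu


def boxcox(scores, lmbda: float | None = None) -> tuple[np.ndarray, float]:
    """Box-Cox transform y = (x^lambda - 1)/lambda (log x at lambda = 0).

    When ``lmbda`` is not supplied it is estimated by profile maximum
    likelihood (scipy's Brent optimization of the profile log-likelihood).
    Scores must be strictly positive.
    """
    x = np.asarray(scores, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive scores")
    if lmbda is None:
        if np.ptp(x) == 0:
            # constant input: likelihood flat in lambda; identity convention
            return x - 1.0, 1.0
        y, lam = stats.boxcox(x)
        return np.asarray(y), float(lam)
    return stats.boxcox(x, lmbda=float(lmbda)), float(lmbda)


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha of an (n_subjects, k_items) response matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the sum);
    NaN when the total score has zero variance.
    """
    x = np.asarray(items, dtype=float)
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    item_var = x.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1.0 - item_var / total_var)


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int, tuple[float, float]]:
    """Two-sample pooled-variance t-test with mean-difference CI."""
    nx_, ny = x.size, y.size
    df = nx_ + ny - 2
    sp2 = ((nx_ - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1 / nx_ + 1 / ny))
    diff = x.mean() - y.mean()
    t = diff / se
    p = 2 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    return float(t), float(p), int(df), (float(diff - tcrit * se), float(diff + tcrit * se))


@dataclass
class BehavioralDescriptives:
    """Internal consistency, subscale correlation, and sex contrasts."""

    alpha_ve: float
    alpha_iu: float
    r_ve_iu: float
    r_p: float
    r_ci: tuple[float, float]
    sex_tests: dict[str, dict]
    n_subjects: int

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "alpha_ve": self.alpha_ve,
            "alpha_iu": self.alpha_iu,
            "r_ve_iu": self.r_ve_iu,
            "r_p": self.r_p,
            "r_ci": list(self.r_ci),
            "sex_tests": self.sex_tests,
        }


def behavioral_descriptives(cohort: pd.DataFrame) -> BehavioralDescriptives:
    """Descriptive behavioral statistics of a scored cohort.

    Expects one row per subject with columns item_01..item_30, sex
    ('female'/'male'), and scored ve_raw/iu_raw (see :func:`score_cohort`).
    Reports Cronbach's alpha per subscale, the Pearson correlation between
    subscales with a Fisher-z 95% CI, and a pooled-variance two-sample
    t-test (df = n - 2) of each subscale by sex (female minus male).
    """
    ve_items = cohort[[f"item_{i:02d}" for i in VE_ITEMS]].to_numpy(float)
    iu_items = cohort[[f"item_{i:02d}" for i in IU_ITEMS]].to_numpy(float)
    ve = cohort["ve_raw"].to_numpy(float)
    iu = cohort["iu_raw"].to_numpy(float)
    n = len(cohort)

    r, r_p = stats.pearsonr(ve, iu)
    zr = np.arctanh(r)
    zse = 1.0 / np.sqrt(n - 3)
    r_ci = (float(np.tanh(zr - 1.959963985 * zse)), float(np.tanh(zr + 1.959963985 * zse)))

    female = cohort["sex"] == "female"
    sex_tests = {}
    for name, score in (("ve", ve), ("iu", iu)):
        t, p, df, ci = _pooled_t(score[female.to_numpy()], score[~female.to_numpy()])
        sex_tests[name] = {"t": t, "p": p, "df": df, "ci_mean_diff": list(ci)}

    return BehavioralDescriptives(
        alpha_ve=cronbach_alpha(ve_items),
        alpha_iu=cronbach_alpha(iu_items),
        r_ve_iu=float(r),
        r_p=float(r_p),
        r_ci=r_ci,
        sex_tests=sex_tests,
        n_subjects=n,
    )


def score_cohort(cohort: pd.DataFrame, standardize: bool = True) -> pd.DataFrame:
    """Score every subject and attach raw and Box-Cox trait columns.

    Adds ve_raw/iu_raw (subscale sums), ve_t/iu_t (Box-Cox transformed,
    standardized to mean 0 / SD 1 unless ``standardize=False``), and stores
    the fitted lambdas in ``frame.attrs['boxcox_lambda']``.
    """
    out = cohort.copy()
    items = out[list(ITEM_COLUMNS)].to_numpy(float)
    scored = np.array([score_ees(row) for row in items])
    out["ve_raw"], out["iu_raw"] = scored[:, 0], scored[:, 1]
    lambdas = {}
    for name in ("ve", "iu"):
        y, lam = boxcox(out[f"{name}_raw"].to_numpy(float))
        if standardize:
            sd = y.std(ddof=1)
            y = (y - y.mean()) / sd if sd > 0 else y - y.mean()
        out[f"{name}_t"] = y
        lambdas[name] = lam
    out.attrs["boxcox_lambda"] = lambdas
    return out
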