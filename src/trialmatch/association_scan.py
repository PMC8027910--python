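"""Covariate x trial-characteristic association scan among participants.

For every disease domain, each participant covariate is cross-tabulated
against each trial design characteristic and tested for independence with a
chi-square test (no continuity correction).  Small tables fall back to an
exact test under the classical Cochran criterion (some expected count < 5):
the conditional hypergeometric Fisher exact test for 2x2 tables, and a
seeded Monte-Carlo exact p (fixed-margin resampling of the chi-square
statistic) for larger tables.  Degenerate pairings — a covariate or
characteristic constant within the domain — are skipped and do not count
toward the family size.

Multiplicity is handled with a Bonferroni correction within each disease
domain at a two-tailed base level of P < .01: a cell is significant iff
p < 0.01 / m_domain, where m_domain counts the pairings that produced a
p-value in that domain.  Manhattan-like plots place -log10 p per covariate
with a dashed line at the domain threshold.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

ALPHA = 0.01
MC_RESAMPLES = 10_000


def build_table(covariate: pd.Series, characteristic: pd.Series) -> pd.DataFrame | None:
    """Cross-tab of covariate level x characteristic level; None if degenerate.

    Degenerate means fewer than two observed levels on either axis (no
    independence test is defined for such a pairing).
    """
    table = pd.crosstab(covariate, characteristic)
    if table.to_numpy().sum() == 0 or table.shape[0] < 2 or table.shape[1] < 2:
        return None
    return table


def expected_counts(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    return np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()


def fisher_exact_2x2(table) -> float:
    """Two-sided conditional Fisher exact p by hypergeometric enumeration.

    Sums, over the support of the fixed-margin 2x2 family, the probabilities
    of every table no more probable than the observed one.  Weights are
    compared as exact integers, so ties are classified without rounding.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValidationError("Fisher exact needs a nonnegative 2x2 table")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        raise ValidationError("empty table")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    numer = sum(w for w in weights.values() if w <= w_obs)
    return numer / math.comb(n, c1)


def monte_carlo_exact(table, rng: np.random.Generator,
                      n_resamples: int = MC_RESAMPLES) -> float:
    """Exact-style p for an r x c table by fixed-margin resampling.

    Resamples tables with the observed margins and compares their chi-square
    statistic with the observed one; p = (1 + #{T* >= T_obs}) / (1 + N).
    """
    arr = np.asarray(table, dtype=np.int64)
    expected = expected_counts(arr)
    obs_stat = ((arr - expected) ** 2 / expected).sum()
    sampler = stats.random_table(arr.sum(axis=1), arr.sum(axis=0), seed=rng)
    draws = sampler.rvs(n_resamples)
    stats_star = ((draws - expected) ** 2 / expected).sum(axis=(1, 2))
    exceed = int((stats_star >= obs_stat - 1e-9).sum())
    return (1 + exceed) / (1 + n_resamples)


def test_table(table, rng: np.random.Generator | None = None,
               n_resamples: int = MC_RESAMPLES) -> tuple[str, float]:
    """Independence test for a non-degenerate contingency table.

    Chi-square without continuity correction by default; Fisher exact for
    2x2 tables with any expected count < 5; seeded Monte-Carlo exact p for
    larger sparse tables.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("degenerate table: need >= 2 rows and columns")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValidationError("degenerate table: zero marginal")
    expected = expected_counts(arr)
    if (expected < 5).any():
        if arr.shape == (2, 2):
            return "fisher_exact", fisher_exact_2x2(arr)
        if rng is None:
            rng = np.random.default_rng(0)
        return "fisher_simulated", monte_carlo_exact(arr, rng, n_resamples)
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return "chi_square", min(float(p), 1.0) if p > 0 else float(np.nextafter(0, 1))


def bonferroni_family(cells: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Attach per-domain Bonferroni thresholds and significance flags.

    m_domain counts only the pairings of that domain that produced a p-value;
    a cell is significant iff p < alpha / m_domain (strict).
    """
    out = cells.copy()
    m = out.groupby("domain")["p_value"].transform("count")
    out["m_domain"] = m.astype(int)
    out["bonferroni_threshold"] = alpha / out["m_domain"]
    out["significant"] = out["p_value"] < out["bonferroni_threshold"]
    out["neg_log10_p"] = -np.log10(out["p_value"])
    return out


def odds_ratio_2x2(table) -> tuple[float, tuple[float, float]]:
    """Sample cross-product odds ratio with a Wald log-scale 95% CI.

    Zero cells get the Haldane 0.5 correction; an all-zero margin is an error.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValidationError("odds ratio needs a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("odds ratio undefined with an all-zero margin")
    if (arr == 0).any():
        arr = arr + 0.5
    a, b, c, d = arr.ravel()
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - 1.959963984540054 * se), \
        math.exp(math.log(or_) + 1.959963984540054 * se)
    return float(or_), (float(lo), float(hi))


def scan(participant_covariates: pd.DataFrame,
         participant_trials: pd.Series,
         trial_categorical: pd.DataFrame,
         domain_members: Mapping[str, Iterable[int]],
         covariate_columns: Iterable[str] | None = None,
         characteristics: Iterable[str] | None = None,
         alpha: float = ALPHA,
         seed: int = 0,
         n_resamples: int = MC_RESAMPLES) -> pd.DataFrame:
    """Full association scan: one tested cell per (domain, covariate,
    characteristic) pairing with at least two levels on both axes.

    ``participant_covariates`` is a covariate_matrix frame (with _person_id);
    ``participant_trials`` maps participant person_id -> trial_id;
    ``domain_members`` maps domain label -> participant person ids.
    """
    rng = np.random.default_rng(seed)
    cats = trial_categorical.set_index("trial_id")
    if characteristics is None:
        characteristics = [c for c in cats.columns if c != "status_group"]
    if covariate_columns is None:
        covariate_columns = [c for c in participant_covariates.columns
                             if participant_covariates[c].dtype == bool
                             and not c.startswith("Age ")]
        if "age_group" in participant_covariates.columns:
            covariate_columns = ["age_group"] + covariate_columns
    frame = participant_covariates.set_index("_person_id")
    rows = []
    for domain in sorted(domain_members):
        ids = [p for p in domain_members[domain] if p in frame.index]
        sub = frame.loc[ids]
        trial_ids = participant_trials.loc[ids]
        # factorize each axis once per domain; tables then come from bincount
        cov_codes = {}
        for covariate in covariate_columns:
            codes, levels = pd.factorize(sub[covariate].to_numpy(), sort=True)
            cov_codes[covariate] = (codes, len(levels))
        for characteristic in characteristics:
            char_values = trial_ids.map(cats[characteristic]).astype(str)
            ccodes, clevels = pd.factorize(char_values.to_numpy(), sort=True)
            ncol = len(clevels)
            for covariate in covariate_columns:
                rcodes, nrow = cov_codes[covariate]
                if nrow < 2 or ncol < 2 or len(rcodes) == 0:
                    rows.append({"domain": domain, "covariate": covariate,
                                 "characteristic": characteristic,
                                 "test_used": "skipped_degenerate",
                                 "p_value": float("nan")})
                    continue
                table = np.bincount(rcodes * ncol + ccodes,
                                    minlength=nrow * ncol).reshape(nrow, ncol)
                test_used, p = test_table(table, rng, n_resamples)
                rows.append({"domain": domain, "covariate": covariate,
                             "characteristic": characteristic,
                             "test_used": test_used, "p_value": p})
    cells = pd.DataFrame(rows, columns=["domain", "covariate", "characteristic",
                                        "test_used", "p_value"])
    if len(cells) == 0:
        return cells.assign(m_domain=pd.Series(dtype=int),
                            bonferroni_threshold=pd.Series(dtype=float),
                            significant=pd.Series(dtype=bool),
                            neg_log10_p=pd.Series(dtype=float))
    return bonferroni_family(cells, alpha)


def manhattan_output(cells: pd.DataFrame, out_dir: str | Path,
                     fmt: str = "svg") -> dict[str, Path]:
    """Manhattan-like panels per domain plus plain-table plot data.

    One panel per trial characteristic: x = covariates, y = -log10 p, with a
    horizontal dashed line at -log10(domain threshold).  Points on the line
    are not significant (strict inequality).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    plt.rcParams["svg.hashsalt"] = "trialmatch"

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    tested = cells.dropna(subset=["p_value"])
    for domain, sub in tested.groupby("domain"):
        data_path = out_dir / f"manhattan_{domain}.csv"
        sub.sort_values(["characteristic", "covariate"]).to_csv(data_path, index=False)
        written[f"manhattan_{domain}_data"] = data_path

        chars = sorted(sub["characteristic"].unique())
        covs = sorted(sub["covariate"].unique())
        xpos = {c: i for i, c in enumerate(covs)}
        ncols = 2
        nrows = (len(chars) + ncols - 1) // ncols
        fig, axes = plt.subplots(nrows, ncols, figsize=(11, 2.4 * nrows),
                                 squeeze=False, sharex=True)
        threshold = float(sub["bonferroni_threshold"].iloc[0])
        for ax, characteristic in zip(axes.ravel(), chars):
            panel = sub[sub["characteristic"] == characteristic]
            ax.scatter([xpos[c] for c in panel["covariate"]],
                       panel["neg_log10_p"], s=10, color="#1f77b4")
            ax.axhline(-math.log10(threshold), linestyle="--", color="gray")
            ax.set_title(characteristic, fontsize=8)
            ax.set_ylabel("-log10 p", fontsize=7)
            ax.tick_params(labelsize=6)
        for ax in axes.ravel()[len(chars):]:
            ax.set_visible(False)
        fig.suptitle(f"{domain}: covariate vs trial-characteristic associations",
                     fontsize=10)
        fig.tight_layout()
        fig_path = out_dir / f"manhattan_{domain}.{fmt}"
        fig.savefig(fig_path, metadata={"Date": None} if fmt == "svg" else None)
        plt.close(fig)
        written[f"manhattan_{domain}"] = fig_path
    return written
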