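"""Survival analysis and expression-outcome utilities.

Kaplan-Meier curves with log-rank comparison, Cox proportional hazards with
the clinical covariates (age at surgery, sex, distant metastasis, tumor
origin), the DEG threshold filter (adjusted P < 0.05, |log2FC| >= 1), and
hypergeometric pathway over-representation with Benjamini-Hochberg control.

Median survival follows the convention: the first time at which the KM
estimate drops to 0.5 or below.  Cox fits use Efron tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DegParams",
    "km_median_and_logrank",
    "cox_ph",
    "deg_filter",
    "hypergeom_enrichment",
]

DEFAULT_COVARIATES = ("age_at_surgery", "sex", "distant_metastasis", "tumor_origin")


def km_median_and_logrank(
    clinical: pd.DataFrame,
    group_col: str,
    time_col: str = "time_months",
    event_col: str = "event",
) -> tuple[dict[str, float], float]:
    """Per-group KM median survival and the log-rank p-value.

    Median = first time with S(t) <= 0.5 (``inf`` when the curve never
    reaches 0.5).  Two groups use the standard log-rank statistic against
    chi-squared(1); more use its multivariate generalization.
    """
    groups = clinical[group_col]
    if isinstance(groups.dtype, pd.CategoricalDtype):
        levels = list(groups.cat.categories)  # declared levels, even if empty
    else:
        levels = [g for g in groups.unique()]
    if any((groups == g).sum() == 0 for g in levels) or not levels:
        raise ValueError("every group must contain at least one sample")
    if clinical[event_col].sum() == 0:
        raise ValueError("no events observed")
    medians: dict[str, float] = {}
    for g in levels:
        sub = clinical[groups == g]
        km = KaplanMeierFitter().fit(sub[time_col], sub[event_col])
        medians[str(g)] = float(km.median_survival_time_)
    if len(levels) == 2:
        a = clinical[groups == levels[0]]
        b = clinical[groups == levels[1]]
        res = logrank_test(
            a[time_col], b[time_col], event_observed_A=a[event_col],
            event_observed_B=b[event_col],
        )
    else:
        res = multivariate_logrank_test(
            clinical[time_col], groups, clinical[event_col]
        )
    return medians, float(res.p_value)


def cox_ph(
    clinical: pd.DataFrame,
    exposure: str,
    covariates: Sequence[str] = (),
    time_col: str = "time_months",
    event_col: str = "event",
) -> dict[str, float]:
    """Cox proportional-hazards fit (Efron ties) for a binary/numeric exposure.

    Categorical columns are dummy-coded against their first (sorted) level.
    Returns the exposure's hazard ratio with its Wald 95% CI and p-value.
    """
    cols = [time_col, event_col, exposure, *covariates]
    df = clinical[cols].copy()
    for c in [exposure, *covariates]:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} has a single level")
        if df[c].dtype == object or isinstance(df[c].dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(df[c], prefix=c, drop_first=True, dtype=float)
            df = pd.concat([df.drop(columns=[c]), dummies], axis=1)
            if c == exposure:
                if dummies.shape[1] != 1:
                    raise ValueError("exposure must be binary or numeric")
                exposure = dummies.columns[0]
    n_params = df.shape[1] - 2
    if df[event_col].sum() < n_params:
        raise ValueError("fewer events than parameters")
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # lifelines ConvergenceError and kin
        raise RuntimeError(
            "Cox fit failed to converge (possible complete separation); "
            "consider an exact or penalized fit"
        ) from exc
    s = fitter.summary.loc[exposure]
    return {
        "hr": float(s["exp(coef)"]),
        "ci_low": float(s["exp(coef) lower 95%"]),
        "ci_high": float(s["exp(coef) upper 95%"]),
        "coef": float(s["coef"]),
        "p": float(s["p"]),
    }


@dataclass(frozen=True)
class DegParams:
    max_adjusted_p: float = 0.05
    min_abs_log2fc: float = 1.0

    def __post_init__(self) -> None:
        if self.max_adjusted_p <= 0 or self.min_abs_log2fc <= 0:
            raise ValueError("DEG thresholds must be positive")


def deg_filter(stats_table: pd.DataFrame, params: DegParams = DegParams()) -> list[str]:
    """Genes with adjusted p strictly below threshold and |log2FC| >= cutoff
    (inclusive).  The table is indexed by gene with columns ``log2fc`` and
    ``adjusted_p``."""
    for col in ("log2fc", "adjusted_p"):
        if col not in stats_table.columns:
            raise ValueError(f"stats table missing column {col!r}")
    keep = (stats_table["adjusted_p"] < params.max_adjusted_p) & (
        stats_table["log2fc"].abs() >= params.min_abs_log2fc
    )
    return stats_table.index[keep].tolist()


def hypergeom_enrichment(
    deg_list: Iterable[str],
    pathway_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    top_k: int | None = None,
) -> pd.DataFrame:
    """Over-representation test per pathway with BH-adjusted q-values.

    p = upper-tail hypergeometric probability of the observed overlap given
    the universe size, pathway size and DEG-list size.  Output is sorted by
    ascending p (ties by pathway name); ``top_k`` truncates the report.
    """
    universe = set(universe)
    degs = set(deg_list)
    outside = sorted(degs - universe)
    if outside:
        raise ValueError(f"DEG genes outside the universe: {outside[:5]}")
    N, n = len(universe), len(degs)
    rows = []
    for name, genes in pathway_sets.items():
        genes = set(genes) & universe
        if not genes:
            raise ValueError(f"pathway {name!r} empty after universe restriction")
        K = len(genes)
        k = len(degs & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway": name, "overlap": k, "pathway_size": K, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df = df.sort_values(["p", "pathway"], kind="stable").set_index("pathway")
    return df.head(top_k) if top_k else df
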