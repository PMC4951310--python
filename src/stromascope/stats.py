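"""Cohort-level statistics for the stroma-metric panel.

Implements the analysis design applied to the per-case metric table:

* Spearman correlation matrix over the 13 metrics with the reference
  flagging rules (p < 0.05 "*", p < 0.01 "**", and the highlighted class
  |rho| > 0.5 together with p < 0.01);
* per-metric primary-vs-metastasis concordance on paired cases;
* dichotomization (mean split, or lowest quartile vs the rest);
* Kaplan-Meier curves with group medians and the two-group log-rank test;
* uni- and multivariate Cox proportional-hazards fits (Efron ties by
  default, Breslow selectable) with Wald CIs, plus backward selection;
* chi-square association of dichotomized metrics with clinical categories.

Benjamini-Hochberg adjusted p-values are emitted alongside raw ones for
transparency, but flags follow the raw-p reference rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CoxConfig",
    "spearman_matrix",
    "site_concordance",
    "dichotomize",
    "km_logrank",
    "cox_fit",
    "backward_selection",
    "chi_square_association",
    "plot_correlation_heatmap",
    "plot_km",
]

#: Design of the survival models: age continuous, FIGO stage vs I+II,
#: grade vs 1, residual tumor vs none.
CLINICAL_COVARIATES = ["age", "figo_stage", "grade", "residual_tumor"]


# --------------------------------------------------------------------------
# correlation
# --------------------------------------------------------------------------

def _flag(rho: float, p: float) -> str:
    if not np.isfinite(rho) or not np.isfinite(p):
        return "none"
    if p < 0.01 and abs(rho) > 0.5:
        return "highlighted"
    if p < 0.01:
        return "double_star"
    if p < 0.05:
        return "star"
    return "none"


def _spearman(x: np.ndarray, y: np.ndarray, min_n: int = 3) -> tuple[float, float, int]:
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < min_n:
        return float("nan"), float("nan"), n
    if np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
        return float("nan"), float("nan"), n  # constant input: rho undefined
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = sps.spearmanr(x[ok], y[ok])
    return float(rho), float(p), n


def spearman_matrix(table: pd.DataFrame, metrics: list[str]) -> pd.DataFrame:
    """All-pairs Spearman correlations with pairwise-complete deletion.

    Returns a long-form frame (metric_a, metric_b, rho, p_value, n, flag,
    q_value) covering unordered pairs including the diagonal; midrank ties,
    two-tailed p via the t-approximation (scipy default).
    """
    rows = []
    for i, a in enumerate(metrics):
        for b in metrics[i:]:
            if a == b:
                rows.append({"metric_a": a, "metric_b": b, "rho": 1.0,
                             "p_value": 0.0, "n": int(table[a].notna().sum())})
                continue
            rho, p, n = _spearman(table[a].to_numpy(float), table[b].to_numpy(float))
            rows.append({"metric_a": a, "metric_b": b, "rho": rho, "p_value": p, "n": n})
    out = pd.DataFrame(rows)
    out["flag"] = [_flag(r, p) for r, p in zip(out["rho"], out["p_value"])]
    offdiag = out["metric_a"] != out["metric_b"]
    out["q_value"] = np.nan
    valid = offdiag & out["p_value"].notna()
    if valid.any():
        out.loc[valid, "q_value"] = multipletests(out.loc[valid, "p_value"], method="fdr_bh")[1]
    return out


def site_concordance(paired: pd.DataFrame, metrics: list[str],
                     significance_cutoff: float = 0.01) -> pd.DataFrame:
    """Primary-vs-metastasis Spearman concordance per metric.

    Expects a paired table with ``<metric>_primary`` / ``<metric>_metastasis``
    columns; a metric with fewer than 3 complete pairs is reported missing.
    ``significant`` applies the p < 0.01 cut-off used for the extended-cohort
    carry-forward decision.
    """
    rows = []
    for m in metrics:
        rho, p, n = _spearman(paired[f"{m}_primary"].to_numpy(float),
                              paired[f"{m}_metastasis"].to_numpy(float))
        rows.append({"metric": m, "rho": rho, "p_value": p, "n_pairs": n,
                     "significant": bool(p < significance_cutoff) if np.isfinite(p) else False})
    out = pd.DataFrame(rows)
    valid = out["p_value"].notna()
    out["q_value"] = np.nan
    if valid.any():
        out.loc[valid, "q_value"] = multipletests(out.loc[valid, "p_value"], method="fdr_bh")[1]
    return out


# --------------------------------------------------------------------------
# dichotomization
# --------------------------------------------------------------------------

def dichotomize(values, rule: str = "mean_split") -> np.ndarray:
    """Split a metric into high/low labels; returns a boolean 'high' array.

    ``mean_split``: high <=> value > arithmetic mean.
    ``lowest_quartile_vs_rest``: low <=> value <= first quartile (linear /
    type-7 quantile), high otherwise.  The cut is computed on non-missing
    values; NaN entries compare False, so mask missing values before use.
    Raises on < 4 non-missing values or a degenerate (all-equal) split.
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < 4:
        raise ValueError("at least 4 non-missing values are required")
    if np.all(finite == finite[0]):
        raise ValueError("degenerate split: all values equal")
    if rule == "mean_split":
        cut = finite.mean()
        return v > cut
    if rule == "lowest_quartile_vs_rest":
        q1 = np.quantile(finite, 0.25)  # numpy default 'linear' == type 7
        return v > q1
    raise ValueError(f"unknown dichotomization rule {rule!r}")


# --------------------------------------------------------------------------
# survival
# --------------------------------------------------------------------------

@dataclass
class CoxConfig:
    tie_handling: str = "efron"  # or "breslow"
    selection_threshold: float = 0.05
    min_events_per_coef: int = 10

    def validate(self) -> None:
        if self.tie_handling not in ("efron", "breslow"):
            raise ValueError("tie_handling must be 'efron' or 'breslow'")


def km_logrank(high: np.ndarray, os_months: np.ndarray, event: np.ndarray) -> dict:
    """Kaplan-Meier group medians and the two-group log-rank test.

    Median = earliest time with S(t) <= 0.5 (inf when the curve never
    reaches 0.5).  Returns NaN p when neither group has an event.
    """
    high = np.asarray(high, bool)
    t = np.asarray(os_months, float)
    e = np.asarray(event, int)
    if high.all() or (~high).all():
        raise ValueError("both groups must be non-empty")
    out: dict = {}
    fitters = {}
    for name, mask in (("low", ~high), ("high", high)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=name)
        out[f"median_{name}"] = float(kmf.median_survival_time_)
        out[f"n_{name}"] = int(mask.sum())
        fitters[name] = kmf
    if e.sum() == 0:
        out["logrank_p"] = float("nan")
    else:
        res = logrank_test(t[high], t[~high], event_observed_A=e[high],
                           event_observed_B=e[~high])
        out["logrank_p"] = float(res.p_value)
        out["logrank_statistic"] = float(res.test_statistic)
    out["_fitters"] = fitters
    return out


def _design_matrix(table: pd.DataFrame, metric_col: str | None,
                   covariates: list[str]) -> pd.DataFrame:
    """Dummy-coded design with the reference categories of the cohort design."""
    cols = {}
    for cov in covariates:
        if cov == "age":
            cols["age"] = table["age"].astype(float)
        elif cov == "figo_stage":
            cols["stage_III"] = (table["figo_stage"] == "III").astype(float)
            cols["stage_IV"] = (table["figo_stage"] == "IV").astype(float)
        elif cov == "grade":
            cols["grade_2"] = (table["grade"].astype(str) == "2").astype(float)
            cols["grade_3"] = (table["grade"].astype(str) == "3").astype(float)
        elif cov == "residual_tumor":
            cols["residual_tumor"] = (table["residual_tumor"] == "present").astype(float)
        else:
            cols[cov] = table[cov].astype(float)
    if metric_col is not None:
        cols[metric_col] = table[metric_col].astype(float)
    return pd.DataFrame(cols, index=table.index)


#: maps each dummy column to its parent covariate for group-wise selection
_PARENT = {"stage_III": "figo_stage", "stage_IV": "figo_stage",
           "grade_2": "grade", "grade_3": "grade"}


def cox_fit(table: pd.DataFrame, metric_col: str | None, mode: str = "multivariate",
            covariates: list[str] | None = None,
            config: CoxConfig | None = None) -> pd.DataFrame:
    """Cox proportional-hazards fit; returns a tidy per-term summary.

    ``metric_col`` names a numeric column (typically a 0/1 high indicator);
    univariate mode fits it alone, multivariate adds the clinical design
    (age continuous; stage vs I+II; grade vs 1; residual vs none).
    Listwise deletion on the fitted columns; Efron ties via lifelines,
    Breslow via statsmodels PHReg.  Raises on non-convergence/separation.
    """
    cfg = config or CoxConfig()
    cfg.validate()
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    covs = covariates if covariates is not None else CLINICAL_COVARIATES
    X = _design_matrix(table, metric_col, covs if mode == "multivariate" else [])
    df = X.copy()
    df["os_months"] = table["os_months"].astype(float)
    df["event"] = table["event"].astype(int)
    df = df.dropna()
    n_events = int(df["event"].sum())
    n_coef = X.shape[1]
    if n_events < cfg.min_events_per_coef * n_coef:
        warnings.warn(f"only {n_events} events for {n_coef} coefficients; "
                      "estimates may be unstable", stacklevel=2)
    return _fit_terms(df, [c for c in X.columns], cfg)


def _fit_terms(df: pd.DataFrame, terms: list[str], cfg: CoxConfig) -> pd.DataFrame:
    if cfg.tie_handling == "efron":
        cph = CoxPHFitter()
        try:
            cph.fit(df[terms + ["os_months", "event"]], duration_col="os_months",
                    event_col="event")
        except Exception as exc:  # noqa: BLE001 - relabel with diagnostics
            raise RuntimeError(f"Cox fit failed (possible separation): {exc}") from exc
        s = cph.summary
        out = pd.DataFrame({
            "term": s.index,
            "coef": s["coef"].to_numpy(),
            "hr": s["exp(coef)"].to_numpy(),
            "ci_low": np.exp(s["coef lower 95%"].to_numpy()),
            "ci_high": np.exp(s["coef upper 95%"].to_numpy()),
            "p_value": s["p"].to_numpy(),
        })
    else:
        from statsmodels.duration.hazard_regression import PHReg
        try:
            res = PHReg(df["os_months"], df[terms], status=df["event"],
                        ties="breslow").fit()
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"Cox fit failed (possible separation): {exc}") from exc
        z = sps.norm.ppf(0.975)
        out = pd.DataFrame({
            "term": terms,
            "coef": res.params,
            "hr": np.exp(res.params),
            "ci_low": np.exp(res.params - z * res.bse),
            "ci_high": np.exp(res.params + z * res.bse),
            "p_value": 2 * sps.norm.sf(np.abs(res.params / res.bse)),
        })
    if not np.all(np.isfinite(out["coef"])) or np.any(np.abs(out["coef"]) > 50):
        raise RuntimeError("Cox fit did not converge (diverging coefficients)")
    out["n"] = len(df)
    out["n_events"] = int(df["event"].sum())
    return out.reset_index(drop=True)


def backward_selection(table: pd.DataFrame, metric_col: str,
                       covariates: list[str] | None = None,
                       config: CoxConfig | None = None) -> dict:
    """Backward elimination from the multivariate model.

    Iteratively refits after removing the least significant covariate
    (Wald p above the threshold; dummy blocks such as stage or grade are
    removed as a whole, judged by their smallest member p) until every
    remaining covariate is significant.  Deterministic for a fixed dataset.
    Returns the final summary, the retained terms, whether the metric term
    survived, and the elimination order.
    """
    cfg = config or CoxConfig()
    covs = list(covariates if covariates is not None else CLINICAL_COVARIATES)
    current_metric: str | None = metric_col
    dropped: list[str] = []
    while True:
        if current_metric is None and not covs:
            fit = pd.DataFrame(columns=["term", "coef", "hr", "ci_low", "ci_high",
                                        "p_value", "n", "n_events"])
            break
        fit = cox_fit(table, current_metric, "multivariate", covs, cfg)
        groups: dict[str, float] = {}
        for _, row in fit.iterrows():
            parent = _PARENT.get(row["term"], row["term"])
            groups[parent] = min(groups.get(parent, np.inf), row["p_value"])
        removable = {k: v for k, v in groups.items() if v > cfg.selection_threshold}
        if not removable:
            break
        worst = max(removable, key=removable.get)
        dropped.append(worst)
        if worst == current_metric:
            current_metric = None
        else:
            covs.remove(worst)
    return {
        "final_fit": fit,
        "retained_terms": list(fit["term"]),
        "metric_retained": current_metric is not None,
        "eliminated": dropped,
    }


def chi_square_association(high: np.ndarray, clinical: pd.DataFrame,
                           covariates: list[str] | None = None) -> pd.DataFrame:
    """Pearson chi-square (no continuity correction) of the high/low label
    against each clinical categorical covariate.

    Degenerate tables (a single row or column) are reported missing; a
    warning is raised when any expected count is below 5.
    """
    covs = covariates if covariates is not None else ["figo_stage", "grade", "residual_tumor"]
    labels = pd.Series(np.where(np.asarray(high, bool), "high", "low"),
                       index=clinical.index)
    rows = []
    for cov in covs:
        tab = pd.crosstab(labels, clinical[cov].astype(str))
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            rows.append({"covariate": cov, "statistic": np.nan, "p_value": np.nan,
                         "dof": np.nan})
            continue
        stat, p, dof, expected = sps.chi2_contingency(tab.to_numpy(), correction=False)
        if (expected < 5).any():
            warnings.warn(f"chi-square for {cov}: some expected counts < 5", stacklevel=2)
        rows.append({"covariate": cov, "statistic": float(stat), "p_value": float(p),
                     "dof": int(dof)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# plots
# --------------------------------------------------------------------------

def plot_correlation_heatmap(corr_long: pd.DataFrame, metrics: list[str], path: str) -> None:
    """Correlation-matrix heatmap with the reference flagging marks."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(metrics)
    mat = np.full((n, n), np.nan)
    flags = np.empty((n, n), dtype=object)
    idx = {m: i for i, m in enumerate(metrics)}
    for _, row in corr_long.iterrows():
        i, j = idx[row["metric_a"]], idx[row["metric_b"]]
        mat[i, j] = mat[j, i] = row["rho"]
        flags[i, j] = flags[j, i] = row["flag"]
    fig, ax = plt.subplots(figsize=(9, 8))
    im = ax.imshow(mat, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(n), metrics, rotation=90, fontsize=7)
    ax.set_yticks(range(n), metrics, fontsize=7)
    marks = {"star": "*", "double_star": "**", "highlighted": "**"}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if flags[i, j] == "highlighted":
                ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False,
                                           edgecolor="red", lw=1.5))
            if flags[i, j] in marks:
                ax.text(j, i, marks[flags[i, j]], ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_km(km_result: dict, path: str, title: str = "") -> None:
    """Kaplan-Meier curves of the high/low groups."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for name, kmf in km_result["_fitters"].items():
        kmf.plot_survival_function(ax=ax)
    p = km_result.get("logrank_p", float("nan"))
    ax.set_xlabel("overall survival (months)")
    ax.set_ylabel("S(t)")
    ax.set_title(f"{title} (log-rank p = {p:.3g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
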