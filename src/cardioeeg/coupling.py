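"""Cross-modal statistics: Spearman correlograms, group ANOVA with
Bonferroni, and best-subset OLS regression with residual diagnostics.

The Spearman p-value uses the exact permutation null for n <= 9 (full
enumeration, cached per rank configuration) and the t-approximation above;
the printed rho = -1.00, p = 0.000 cells of small control groups are only
reachable with exact small-n logic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Reporting filter of the correlation tables.
REPORT_RHO_MIN = 0.5
REPORT_P_MAX = 0.05

#: Predictor order used for tie-breaking in subset selection.
PREDICTOR_ORDER = ("F", "C", "P", "T", "O")

EXACT_PERMUTATION_MAX_N = 9

HRV_PARAMS = ("SDNN", "RMSSD", "SD1", "HF")


@dataclass
class CouplingCell:
    group: str
    hemisphere: str
    roi: str
    hrv_param: str
    band: str
    rho: float
    p: float
    undefined: bool = False

    @property
    def passes_report_filter(self) -> bool:
        return (not self.undefined) and abs(self.rho) >= REPORT_RHO_MIN and self.p < REPORT_P_MAX


@dataclass
class RegressionFit:
    band: str
    hemisphere: str
    hrv_param: str
    included_predictors: tuple[str, ...]
    coefficients: dict          # predictor -> estimate; "intercept" included
    standard_errors: dict
    r2: float
    r2_adj: float
    pearson_residuals: np.ndarray
    shapiro_w: float
    shapiro_p: float
    saturated: bool = False
    meta: dict = field(default_factory=dict)


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


@lru_cache(maxsize=64)
def _exact_null(rx_sorted: tuple, ry_sorted: tuple) -> np.ndarray:
    """Null distribution of |rho| over all permutations of the y ranks.

    Depends on the rank multisets only, so the cache is hit once per sample
    size for tie-free data.
    """
    rx = np.asarray(rx_sorted, dtype=float)
    n = rx.size
    perms = np.array(list(itertools.permutations(ry_sorted)), dtype=float)
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc**2).sum() * (pc**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        rhos = pc @ rxc / denom
    return np.abs(rhos)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with average-rank ties and a two-sided p-value.

    Exact permutation p for n <= 9, t-approximation otherwise.  Returns
    (nan, nan) when either variable has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    rx, ry = _rank(x), _rank(y)
    rho = _rho_of_ranks(rx, ry)
    if np.isnan(rho):
        return np.nan, np.nan
    if n <= EXACT_PERMUTATION_MAX_N:
        null = _exact_null(tuple(sorted(rx)), tuple(sorted(ry)))
        p = float(np.mean(null >= abs(rho) - 1e-12))
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df=n - 2)) if abs(rho) < 1 else 0.0
    return rho, min(p, 1.0)


def spearman_correlogram(
    powers: pd.DataFrame,
    hrv: pd.DataFrame,
    group: str,
) -> list[CouplingCell]:
    """Full band × (ROI, hemisphere) × HRV-parameter Spearman correlogram.

    Parameters
    ----------
    powers : DataFrame
        Tidy table with columns subject, band, roi, hemisphere, power_db
        (one group's subjects).
    hrv : DataFrame
        Indexed or keyed by subject with columns sdnn_ms, rmssd_ms, sd1_ms,
        hf_ms2.
    group : str
        Label recorded in every cell.
    """
    hrv = hrv.set_index("subject") if "subject" in hrv.columns else hrv
    col_of = {"SDNN": "sdnn_ms", "RMSSD": "rmssd_ms", "SD1": "sd1_ms", "HF": "hf_ms2"}
    cells = []
    for (band, roi, hemi), sub in powers.groupby(["band", "roi", "hemisphere"]):
        sub = sub.set_index("subject")
        common = sub.index.intersection(hrv.index)
        if common.size < 5:
            raise ValueError(f"need >= 5 matched subjects, got {common.size}")
        x = sub.loc[common, "power_db"].to_numpy()
        for param in HRV_PARAMS:
            y = hrv.loc[common, col_of[param]].to_numpy()
            rho, p = spearman(x, y)
            undefined = np.isnan(rho)
            if undefined:
                logger.warning(
                    "constant variable in cell %s/%s/%s/%s: correlation undefined",
                    band, roi, hemi, param,
                )
            cells.append(CouplingCell(
                group=group, hemisphere=hemi, roi=roi, hrv_param=param,
                band=band, rho=rho, p=p, undefined=undefined,
            ))
    return cells


def correlogram_frame(cells: list[CouplingCell]) -> pd.DataFrame:
    rows = [{
        "group": c.group, "hemisphere": c.hemisphere, "roi": c.roi,
        "hrv_param": c.hrv_param, "band": c.band, "rho": c.rho, "p": c.p,
        "passes_report_filter": c.passes_report_filter,
    } for c in cells]
    return pd.DataFrame(rows)


def group_compare(
    values_a: dict[str, np.ndarray],
    values_b: dict[str, np.ndarray],
    family_size: int | None = None,
) -> dict[str, dict]:
    """One-way ANOVA per variable with Bonferroni correction within the
    declared family (default: the number of variables compared).

    ``values_a``/``values_b`` map variable name -> per-subject values.
    Returns {variable: {"f": F, "p_raw": p, "p_corrected": min(1, m·p)}}.
    """
    if set(values_a) != set(values_b):
        raise ValueError("groups must share the same variable set")
    m = family_size if family_size is not None else len(values_a)
    out = {}
    for name in values_a:
        a = np.asarray(values_a[name], dtype=float)
        b = np.asarray(values_b[name], dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"variable {name}: need >= 2 subjects per group")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise ValueError(f"variable {name}: degenerate variance in both groups")
        f, p = stats.f_oneway(a, b)
        out[name] = {
            "f": float(f),
            "p_raw": float(p),
            "p_corrected": float(min(1.0, m * p)),
            "family_size": m,
        }
    return out


def _ols_qr(X: np.ndarray, y: np.ndarray):
    """OLS via QR decomposition; returns (beta, residuals, rank)."""
    q, r = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())))
    if rank < X.shape[1]:
        return None
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    return beta, resid


def best_subset_regression(
    predictors: pd.DataFrame,
    y: np.ndarray,
    *,
    band: str = "",
    hemisphere: str = "",
    hrv_param: str = "",
) -> RegressionFit:
    """Exhaustive best-subset OLS over the F/C/P/T/O predictors.

    Every non-empty subset with n > k+1 is fit by least squares (QR solve,
    intercept included); the subset maximizing adjusted R-squared wins, ties
    broken toward fewer predictors then lexicographically in the order
    F < C < P < T < O.  Pearson residuals, the Shapiro-Wilk normality test,
    and a ``saturated`` flag (residual df == 1) are attached.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError(f"need >= 4 subjects, got {n}")
    names = [p for p in PREDICTOR_ORDER if p in predictors.columns]
    if not names:
        raise ValueError("no known predictors in table")
    Xfull = predictors[names].to_numpy(dtype=float)
    if not np.all(np.isfinite(Xfull)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite predictor or response values")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("response has zero variance")

    best = None  # (r2_adj, k, order_key, record)
    for k in range(1, len(names) + 1):
        if n <= k + 1:
            break
        for subset in itertools.combinations(range(len(names)), k):
            X = np.column_stack([np.ones(n), Xfull[:, subset]])
            sol = _ols_qr(X, y)
            if sol is None:
                logger.info("rank-deficient subset %s skipped",
                            [names[i] for i in subset])
                continue
            beta, resid = sol
            sse = float((resid**2).sum())
            r2 = 1.0 - sse / tss
            r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
            key = (-r2_adj, k, subset)
            rec = (subset, beta, resid, sse, r2, r2_adj, X)
            if best is None or key < best[0]:
                best = (key, rec)
    if best is None:
        raise ValueError("all predictor subsets were rank-deficient")

    subset, beta, resid, sse, r2, r2_adj, X = best[1]
    k = len(subset)
    dof = n - k - 1
    sigma2 = sse / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    included = tuple(names[i] for i in subset)
    coeffs = {"intercept": float(beta[0])}
    errors = {"intercept": float(se[0])}
    for j, nm in enumerate(included, start=1):
        coeffs[nm] = float(beta[j])
        errors[nm] = float(se[j])
    scale = np.sqrt(sigma2) if sigma2 > 0 else 1.0
    pearson = resid / scale
    if resid.size >= 3 and np.ptp(resid) > 0:
        w, p_sw = stats.shapiro(resid)
    else:
        w, p_sw = np.nan, np.nan
    return RegressionFit(
        band=band, hemisphere=hemisphere, hrv_param=hrv_param,
        included_predictors=included,
        coefficients=coeffs, standard_errors=errors,
        r2=float(r2), r2_adj=float(r2_adj),
        pearson_residuals=pearson,
        shapiro_w=float(w), shapiro_p=float(p_sw),
        saturated=(dof == 1),
        meta={"n": n, "residual_df": dof,
              "normality_rejected": bool(p_sw < 0.05) if np.isfinite(p_sw) else None},
    )


def regression_battery(
    powers: pd.DataFrame,
    hrv: pd.DataFrame,
    *,
    group: str,
    hrv_params: tuple[str, ...] = ("HF", "RMSSD", "SDNN"),
) -> list[RegressionFit]:
    """Best-subset regression for every band × hemisphere × HRV parameter.

    ``powers`` is the tidy per-subject band/ROI table of one group; ROI
    powers are pivoted into the F/C/P/T/O predictor columns per hemisphere.
    """
    hrv = hrv.set_index("subject") if "subject" in hrv.columns else hrv
    col_of = {"SDNN": "sdnn_ms", "RMSSD": "rmssd_ms", "SD1": "sd1_ms", "HF": "hf_ms2"}
    fits = []
    for (band, hemi), sub in powers.groupby(["band", "hemisphere"]):
        wide = sub.pivot_table(index="subject", columns="roi", values="power_db")
        common = wide.index.intersection(hrv.index)
        wide = wide.loc[common]
        for param in hrv_params:
            yv = hrv.loc[common, col_of[param]].to_numpy()
            fit = best_subset_regression(
                wide, yv, band=band, hemisphere=hemi, hrv_param=param,
            )
            fit.meta["group"] = group
            fits.append(fit)
    return fits


def regression_frame(fits: list[RegressionFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        row = {
            "group": f.meta.get("group", ""), "band": f.band,
            "hemisphere": f.hemisphere, "hrv_param": f.hrv_param,
            "predictors": "+".join(f.included_predictors),
            "r2": f.r2, "r2_adj": f.r2_adj,
            "shapiro_w": f.shapiro_w, "shapiro_p": f.shapiro_p,
            "saturated": f.saturated,
        }
        for p in PREDICTOR_ORDER:
            row[f"se_{p}"] = f.standard_errors.get(p, np.nan)
            row[f"coef_{p}"] = f.coefficients.get(p, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
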