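"""Mixed-effects analysis of the nine sway/coordination parameters.

Each parameter is analyzed with a linear mixed model: fixed effects for
carrying mode, load level, their interaction, and centered relative speed;
a random intercept and a random slope on centered relative speed per
participant (with a fallback ladder to simpler structures when the fit is
singular). The empty-handed reference trials are shared between modes: for
the crossed mode x load layout they are split evenly between the two mode
columns, which leaves every no-load summary invariant to the labelling
because the trials are exchangeable.

Estimated marginal means are cell predictions at the covariate's mean
(centered relative speed = 0); pairwise contrasts are Bonferroni-adjusted
within their family (mode-within-load: 4 families of 1 comparison;
load-within-mode: 2 families of 6).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm

from .io_config import GaitloadError, StatsConfig

logger = logging.getLogger("gaitload")

RESPONSES = [
    "rom_T6_coronal", "rom_S1_coronal",
    "rom_T6_transverse", "rom_S1_transverse",
    "rom_T6_sagittal", "rom_S1_sagittal",
    "mrp_coronal", "mrp_transverse", "mrp_sagittal",
]

LOAD_ORDER = [0.0, 4.5, 9.1, 13.6]
LOAD_LABELS = {0.0: "NL", 4.5: "L", 9.1: "M", 13.6: "H"}
MODES = ["side", "anterior"]

PARAM_COLS = RESPONSES + ["cycle_duration_s", "stride_length_m",
                          "relative_speed", "centered_relative_speed"]


def aggregate_trial(features: pd.DataFrame) -> pd.DataFrame:
    """Average cycle rows to one row per (participant, mode, load, trial).

    Flagged/missing cycles are simply absent or NaN and are skipped by the
    mean; a trial keeps whatever parameters its remaining cycles support.
    """
    keys = ["participant_id", "carry_mode", "load_kg", "trial_index"]
    cols = [c for c in PARAM_COLS if c in features.columns]
    return (
        features.groupby(keys, as_index=False, sort=True)[cols]
        .mean()
    )


def assign_mode_slots(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Map the shared no-load trials onto the crossed mode x load layout.

    No-load trials (carry_mode='none') are split evenly between the side and
    anterior columns per participant, in trial order. Loaded trials keep
    their mode. Adds a 'mode' column and a 'load_label' column.
    """
    df = trial_table.copy()
    df["mode"] = df["carry_mode"]
    for pid, sub in df[df["carry_mode"] == "none"].groupby("participant_id"):
        ordered = sub.sort_values("trial_index").index
        half = (len(ordered) + 1) // 2
        df.loc[ordered[:half], "mode"] = "side"
        df.loc[ordered[half:], "mode"] = "anterior"
    df["load_label"] = df["load_kg"].map(LOAD_LABELS)
    return df


# ---------------------------------------------------------------------------
# design matrix (sum coding) and model fit
# ---------------------------------------------------------------------------


def _sum_code_load(load_kg: float) -> np.ndarray:
    """Sum (deviation) coding of the 4 load levels, last level as -1 row."""
    row = np.zeros(3)
    i = LOAD_ORDER.index(load_kg)
    if i < 3:
        row[i] = 1.0
    else:
        row[:] = -1.0
    return row


def _design_row(mode: str, load_kg: float, crs: float) -> np.ndarray:
    s = 1.0 if mode == "side" else -1.0
    l = _sum_code_load(load_kg)
    return np.concatenate([[1.0, s], l, s * l, [crs]])


DESIGN_NAMES = (
    ["const", "mode"]
    + [f"load{i}" for i in range(3)]
    + [f"mode:load{i}" for i in range(3)]
    + ["crs"]
)

TERMS = {
    "mode": [1],
    "load": [2, 3, 4],
    "mode:load": [5, 6, 7],
    "crs": [8],
}


@dataclass
class LmmFit:
    """A fitted mixed model for one response, plus everything reporting needs."""

    response: str
    params: np.ndarray            # fixed effects (9,)
    cov: np.ndarray               # fixed-effects covariance (9, 9)
    ddf: float                    # containment-style denominator df
    anova: pd.DataFrame           # term, F, df1, df2, p
    structure: str                # 'intercept+slope' | 'intercept' | 'ols' | 'degenerate'
    converged: bool
    n_obs: int
    n_participants: int
    data: pd.DataFrame = field(repr=False, default=None)
    resid: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)


def _wald_f(params, cov, idx, ddf):
    C = np.zeros((len(idx), len(params)))
    for r, j in enumerate(idx):
        C[r, j] = 1.0
    cb = C @ params
    middle = C @ cov @ C.T
    try:
        stat = float(cb @ np.linalg.solve(middle, cb))
    except np.linalg.LinAlgError:
        return np.nan, np.nan
    q = len(idx)
    f = stat / q
    p = float(sstats.f.sf(f, q, ddf))
    return f, p


def fit_lmm(trial_table: pd.DataFrame, response: str,
            cfg: StatsConfig | None = None) -> LmmFit:
    """Fit the mixed model for one response on the trial-level table.

    The table must carry 'mode' (after :func:`assign_mode_slots`), 'load_kg',
    'centered_relative_speed', 'participant_id' and the response column.
    Wald F tests per term use a containment-style residual denominator df
    (n_obs - rank(X) - (n_participants - 1)).
    """
    cfg = cfg or StatsConfig()
    df = trial_table.dropna(subset=[response, "centered_relative_speed"]).copy()
    if df["participant_id"].nunique() < 2:
        raise GaitloadError("need at least 2 participants")
    y = df[response].to_numpy(dtype=float)
    X = np.vstack(
        [
            _design_row(m, l, c)
            for m, l, c in zip(df["mode"], df["load_kg"], df["centered_relative_speed"])
        ]
    )
    groups = df["participant_id"].to_numpy()
    n_obs, p = X.shape
    n_groups = df["participant_id"].nunique()
    ddf = max(n_obs - p - (n_groups - 1), 1)

    if np.ptp(y) == 0.0:
        # constant response: no variance to model
        anova = pd.DataFrame(
            [
                {"term": t, "F": 0.0, "df1": len(ix), "df2": ddf, "p": 1.0}
                for t, ix in TERMS.items()
            ]
        )
        return LmmFit(
            response=response, params=np.zeros(p), cov=np.zeros((p, p)),
            ddf=ddf, anova=anova, structure="degenerate", converged=False,
            n_obs=n_obs, n_participants=n_groups, data=df,
            resid=np.zeros(n_obs), fitted=y.copy(),
        )

    exog_re_full = np.column_stack(
        [np.ones(n_obs), df["centered_relative_speed"].to_numpy(dtype=float)]
    )
    attempts = [
        ("intercept+slope", exog_re_full),
        ("intercept", exog_re_full[:, :1]),
        ("ols", None),
    ]
    res = None
    structure = "ols"
    converged = False
    for name, exog_re in attempts:
        if exog_re is None:
            ols = sm.OLS(y, X).fit()
            params = ols.params
            cov = ols.cov_params()
            resid = ols.resid
            fitted = ols.fittedvalues
            structure, converged = name, True
            break
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(y, X, groups=groups, exog_re=exog_re)
                res = model.fit(reml=True, method=["lbfgs", "cg"], maxiter=200)
            cov_fe = np.asarray(res.cov_params())[:p, :p]
            ok = (
                res.converged
                and np.all(np.isfinite(res.fe_params))
                and np.all(np.isfinite(cov_fe))
                and np.all(np.linalg.eigvalsh(res.cov_re) > -1e-8)
                # fixed-effects covariance must be PSD for Wald tests
                and np.linalg.eigvalsh(cov_fe).min()
                > -1e-8 * max(np.abs(cov_fe).max(), 1.0)
            )
        except Exception as exc:  # singular fits raise LinAlgError and friends
            logger.warning("%s: %s fit failed (%s)", response, name, exc)
            ok = False
        if ok:
            params = np.asarray(res.fe_params)
            cov = np.asarray(res.cov_params())[:p, :p]
            fitted = X @ params
            resid = y - fitted
            structure, converged = name, True
            break
        logger.warning("%s: %s structure singular, falling back", response, name)

    anova_rows = []
    for term, idx in TERMS.items():
        f, pval = _wald_f(params, cov, idx, ddf)
        anova_rows.append({"term": term, "F": f, "df1": len(idx), "df2": ddf, "p": pval})
    anova = pd.DataFrame(anova_rows)

    return LmmFit(
        response=response, params=params, cov=cov, ddf=ddf, anova=anova,
        structure=structure, converged=converged, n_obs=n_obs,
        n_participants=n_groups, data=df, resid=np.asarray(resid),
        fitted=np.asarray(fitted),
    )


# ---------------------------------------------------------------------------
# estimated marginal means and contrasts
# ---------------------------------------------------------------------------


def _quad_se(v: np.ndarray, cov: np.ndarray) -> float:
    # REML covariance can be indefinite at machine precision: clip at zero
    return float(np.sqrt(max(v @ cov @ v, 0.0)))


def _cell_estimate(fit: LmmFit, mode: str, load_kg: float):
    x = _design_row(mode, load_kg, 0.0)   # covariate at its (centered) mean
    emm = float(x @ fit.params)
    se = _quad_se(x, fit.cov)
    return emm, se, x


def emmeans(fit: LmmFit) -> pd.DataFrame:
    """Estimated marginal mean ± SE per mode x load cell at mean covariate."""
    rows = []
    for mode in MODES:
        for load in LOAD_ORDER:
            emm, se, _ = _cell_estimate(fit, mode, load)
            rows.append(
                {
                    "response": fit.response,
                    "mode": mode,
                    "load_kg": load,
                    "load_label": LOAD_LABELS[load],
                    "emm": emm,
                    "se": se,
                }
            )
    return pd.DataFrame(rows)


def emm_noload(fit: LmmFit) -> float:
    """The shared no-load EMM: average of the two mode-labelled NL cells."""
    a, _, _ = _cell_estimate(fit, "side", 0.0)
    b, _, _ = _cell_estimate(fit, "anterior", 0.0)
    return 0.5 * (a + b)


def _contrast(fit: LmmFit, x1: np.ndarray, x0: np.ndarray, m: int):
    d = x1 - x0
    est = float(d @ fit.params)
    se = _quad_se(d, fit.cov)
    if se == 0.0:
        return est, se, np.nan, np.nan, np.nan
    tval = est / se
    p_raw = 2.0 * float(sstats.t.sf(abs(tval), fit.ddf))
    p_adj = min(1.0, m * p_raw)
    return est, se, tval, p_raw, p_adj


def bonferroni_contrasts(fit: LmmFit, cfg: StatsConfig | None = None) -> pd.DataFrame:
    """Pairwise mode-within-load and load-within-mode comparisons.

    Adjusted p = min(1, m * p_raw) with m the family size: each
    mode-within-load comparison is its own family (m from config, default 1);
    the six load pairs within a mode form one family (default m = 6).
    """
    cfg = cfg or StatsConfig()
    rows = []
    for load in LOAD_ORDER:
        _, _, x1 = _cell_estimate(fit, "side", load)
        _, _, x0 = _cell_estimate(fit, "anterior", load)
        est, se, tval, p_raw, p_adj = _contrast(fit, x1, x0, cfg.m_mode_within_load)
        rows.append(
            {
                "response": fit.response, "family": "mode_within_load",
                "level": LOAD_LABELS[load],
                "comparison": "side - anterior",
                "estimate": est, "se": se, "t": tval, "df": fit.ddf,
                "p_raw": p_raw, "p_adj": p_adj,
            }
        )
    for mode in MODES:
        for la, lb in itertools.combinations(LOAD_ORDER, 2):
            _, _, x1 = _cell_estimate(fit, mode, lb)
            _, _, x0 = _cell_estimate(fit, mode, la)
            est, se, tval, p_raw, p_adj = _contrast(fit, x1, x0, cfg.m_load_within_mode)
            rows.append(
                {
                    "response": fit.response, "family": "load_within_mode",
                    "level": mode,
                    "comparison": f"{LOAD_LABELS[lb]} - {LOAD_LABELS[la]}",
                    "estimate": est, "se": se, "t": tval, "df": fit.ddf,
                    "p_raw": p_raw, "p_adj": p_adj,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlations and diagnostics
# ---------------------------------------------------------------------------


def correlations(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pearson correlation matrix of the nine sway/coordination parameters.

    Zero-variance columns yield NaN entries (reported as missing).
    """
    columns = columns or [c for c in RESPONSES if c in table.columns]
    if len(table) < 3:
        raise GaitloadError("need at least 3 rows for correlations")
    return table[columns].corr(method="pearson")


def diagnostics(fit: LmmFit) -> dict:
    """Residual diagnostics: normality and homogeneity summaries plus the
    residual table (for external plotting)."""
    resid = fit.resid
    table = fit.data[["participant_id", "mode", "load_kg"]].copy()
    table["fitted"] = fit.fitted
    table["residual"] = resid
    sub = resid if len(resid) <= 5000 else resid[:: len(resid) // 5000]
    if np.ptp(sub) == 0:
        shapiro_w, shapiro_p = np.nan, np.nan
    else:
        shapiro_w, shapiro_p = sstats.shapiro(sub)
    groups = [g["residual"].to_numpy() for _, g in table.groupby(["mode", "load_kg"]) if len(g) > 1]
    if len(groups) >= 2 and all(np.ptp(g) > 0 for g in groups):
        lev_stat, lev_p = sstats.levene(*groups)
    else:
        lev_stat, lev_p = np.nan, np.nan
    return {
        "residual_table": table,
        "shapiro_w": float(shapiro_w),
        "shapiro_p": float(shapiro_p),
        "levene_stat": float(lev_stat) if np.isfinite(lev_stat) else np.nan,
        "levene_p": float(lev_p) if np.isfinite(lev_p) else np.nan,
        "structure": fit.structure,
        "converged": fit.converged,
    }


def analyze_all(trial_table: pd.DataFrame, cfg: StatsConfig | None = None):
    """Fit all nine responses; returns dict response -> (fit, emm, contrasts)."""
    cfg = cfg or StatsConfig()
    out = {}
    for response in RESPONSES:
        if response not in trial_table.columns:
            continue
        fit = fit_lmm(trial_table, response, cfg)
        out[response] = {
            "fit": fit,
            "anova": fit.anova,
            "emmeans": emmeans(fit),
            "contrasts": bonferroni_contrasts(fit, cfg),
            "diagnostics": diagnostics(fit),
        }
    return out
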