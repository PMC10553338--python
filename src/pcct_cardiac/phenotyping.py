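"""Cardiac function metrics, cohort bookkeeping and statistical analysis.

Metrics per animal, from segmentation-derived LV volumes:

* SV  = DLVV - SLVV              (stroke volume, mL)
* EF  = 100 * SV / DLVV          (ejection fraction, %)
* CO  = SV * HR                  (cardiac output, mL/min; HR in bpm)
* CI  = CO / body weight         (cardiac index, mL/(min*g); body weight
                                  replaces body surface area)

Statistics: age outliers removed per (isoform x sex) group by the 1.5 IQR
rule (type-7 quantiles); full-factorial ordinary-least-squares models such
as ``CO ~ Sex*Age*Weight*HN*Genotype`` with type-II ANOVA computed by model
comparison (robust to structural aliasing - the knockout line has no
humanized-NOS2 variant, so HN x KO interactions carry no degrees of
freedom); Tukey-adjusted post-hoc contrasts on estimated marginal means;
Cohen F effect sizes; point-biserial correlation for binary-vs-continuous
associations (diet vs body weight).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from .physics import lv_mask_volume_ml

__all__ = [
    "CardiacRecord", "derive_metrics", "derive_metrics_frame", "lv_volume",
    "load_cohort_counts", "summarize_cohort", "remove_age_outliers",
    "ModelResult", "fit_factorial_model", "posthoc_contrasts",
    "biserial_correlation", "cohen_f", "make_synthetic_cohort",
]

GENOTYPES = ("APOE2", "APOE3", "APOE4", "KO")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class CardiacRecord:
    subject_id: str
    genotype: str
    hn: int
    sex: str
    diet: str
    age_months: float
    weight_g: float
    dlvv_ml: float
    slvv_ml: float
    hr_bpm: float
    sv_ml: float | None = None
    ef_pct: float | None = None
    co_ml_min: float | None = None
    ci_ml_min_g: float | None = None


def lv_volume(mask: np.ndarray, voxel_size_mm: float) -> float:
    """LV volume (mL) from a binary mask.

    3D masks: voxel count x voxel volume.  2D masks are treated as the
    equatorial slice of a spherical ventricle (area converted to the volume
    of the sphere with that equatorial area).
    """
    return lv_mask_volume_ml(mask, voxel_size_mm)


def derive_metrics(record: CardiacRecord) -> CardiacRecord:
    """Populate SV / EF / CO / CI from DLVV, SLVV, HR and weight."""
    if record.dlvv_ml < record.slvv_ml:
        raise ValueError("DLVV must be >= SLVV")
    if record.dlvv_ml == 0:
        raise ValueError("EF undefined for DLVV = 0")
    if record.weight_g <= 0 or record.hr_bpm <= 0:
        raise ValueError("heart rate and weight must be positive")
    record.sv_ml = record.dlvv_ml - record.slvv_ml
    record.ef_pct = 100.0 * record.sv_ml / record.dlvv_ml
    record.co_ml_min = record.sv_ml * record.hr_bpm
    record.ci_ml_min_g = record.co_ml_min / record.weight_g
    return record


def derive_metrics_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized metric derivation over a cohort table."""
    out = df.copy()
    if (out["dlvv_ml"] < out["slvv_ml"]).any():
        raise ValueError("DLVV must be >= SLVV for every record")
    out["sv_ml"] = out["dlvv_ml"] - out["slvv_ml"]
    out["ef_pct"] = 100.0 * out["sv_ml"] / out["dlvv_ml"]
    out["co_ml_min"] = out["sv_ml"] * out["hr_bpm"]
    out["ci_ml_min_g"] = out["co_ml_min"] / out["weight_g"]
    return out


# ---------------------------------------------------------------------------
# cohort bookkeeping
# ---------------------------------------------------------------------------

def load_cohort_counts() -> pd.DataFrame:
    """Packaged study-group counts (diet x genotype-with-HN x sex)."""
    with resources.files("pcct_cardiac.data").joinpath(
            "cohort_counts.csv").open() as fh:
        return pd.read_csv(fh)


def _isoform(genotype: str) -> tuple[str, int | None]:
    g = genotype.replace(" ", "")
    if g in ("APOEKO", "KO"):
        return "KO", None  # no humanized-NOS2 knockout line exists
    if g.endswith("HN"):
        return g[:-2], 1
    return g, 0


def summarize_cohort(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-isoform male/female totals and %HN / %HFD summaries.

    HN and non-HN lines are pooled per isoform; the KO %HN is reported as
    NaN (not applicable).  Percentages are in [0, 100].
    """
    df = counts.copy()
    iso = df["genotype"].map(lambda g: _isoform(g)[0])
    hn = df["genotype"].map(lambda g: _isoform(g)[1])
    df["isoform"], df["hn"] = iso, hn
    rows = []
    for isoform in ("APOE2", "APOE3", "APOE4", "KO"):
        sub = df[df["isoform"] == isoform]
        total = sub["count"].sum()
        male = sub.loc[sub["sex"] == "Male", "count"].sum()
        female = sub.loc[sub["sex"] == "Female", "count"].sum()
        if isoform == "KO":
            pct_hn = np.nan
        else:
            pct_hn = 100.0 * sub.loc[sub["hn"] == 1, "count"].sum() / total
        pct_hfd = 100.0 * sub.loc[sub["diet"] == "HFD", "count"].sum() / total
        rows.append({"isoform": isoform, "male": int(male),
                     "female": int(female), "total": int(total),
                     "pct_hn": pct_hn, "pct_hfd": pct_hfd})
    out = pd.DataFrame(rows)
    out.attrs["total_subjects"] = int(out["total"].sum())
    return out


def remove_age_outliers(df: pd.DataFrame, iqr_factor: float = 1.5,
                        min_group: int = 4):
    """Drop age outliers per (isoform x sex) group by the 1.5 IQR rule.

    Quartiles use linear interpolation (type-7).  Groups smaller than
    ``min_group`` pass through unfiltered with a warning.  Returns
    (filtered frame, removal log frame).
    """
    df = df.copy()
    iso = df["genotype"].map(lambda g: _isoform(g)[0])
    keep = np.ones(len(df), dtype=bool)
    log = []
    for (isoform, sex), idx in df.groupby([iso, df["sex"]]).groups.items():
        ages = df.loc[idx, "age_months"].to_numpy(float)
        if len(ages) < min_group:
            warnings.warn(
                f"group {isoform}/{sex} has {len(ages)} records; "
                f"IQR rule skipped")
            continue
        q1, q3 = np.percentile(ages, [25, 75], method="linear")
        iqr = q3 - q1
        lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
        bad = (ages < lo) | (ages > hi)
        for j, b in zip(idx, bad):
            if b:
                keep[df.index.get_loc(j)] = False
                log.append({"subject_id": df.loc[j].get("subject_id", str(j)),
                            "group": f"{isoform}/{sex}",
                            "age_months": df.loc[j, "age_months"],
                            "bounds": (lo, hi)})
    return df[keep], pd.DataFrame(log)


# ---------------------------------------------------------------------------
# factorial linear model + type-II ANOVA
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    formula: str
    anova: pd.DataFrame  # term, df, ss, F, p
    resid_df: float
    mse: float
    ss_total: float
    aliased: list
    beta: np.ndarray
    design_info: object
    data: pd.DataFrame
    response: str
    xtx_pinv: np.ndarray


def _sse(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    if X.shape[1] == 0:
        return float(np.sum(y**2)), 0
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), int(np.linalg.matrix_rank(X))


def fit_factorial_model(df: pd.DataFrame, response: str,
                        formula_rhs: str = "Sex*Age*Weight*HN*Genotype",
                        column_map: dict | None = None) -> ModelResult:
    """OLS fit with full factorial expansion and type-II ANOVA.

    ``column_map`` renames model variables to dataframe columns (defaults
    map Sex/Age/Weight/HN/Genotype/Diet onto the cohort schema).  Terms made
    structurally aliased by the design (e.g. HN within the knockout line)
    lose the corresponding degrees of freedom and are reported in
    ``aliased``; a term with zero residual degrees of freedom in its
    comparison contributes no ANOVA row F/p.
    """
    cmap = {"Sex": "sex", "Age": "age_months", "Weight": "weight_g",
            "HN": "hn", "Genotype": "genotype", "Diet": "diet"}
    if column_map:
        cmap.update(column_map)
    work = df.copy()
    for var, col in cmap.items():
        if col in work.columns and var not in work.columns:
            work[var] = work[col]
    if "Genotype" in work.columns:
        work["Genotype"] = [
            _isoform(g)[0] if isinstance(g, str) else g
            for g in work["Genotype"]
        ]

    if response in cmap and cmap[response] in work.columns:
        y_col = cmap[response]
    else:
        y_col = response
    formula = f"Q('{y_col}') ~ {formula_rhs}"
    y_mat, X_mat = patsy.dmatrices(formula, work, return_type="dataframe")
    y = np.asarray(y_mat).ravel()
    X = np.asarray(X_mat)
    di = X_mat.design_info

    sse_full, rank_full = _sse(X, y)
    n = len(y)
    resid_df = n - rank_full
    if resid_df <= 0:
        raise ValueError("model saturates the data; no residual df")
    mse = sse_full / resid_df
    ss_total = float(np.sum((y - y.mean()) ** 2))

    terms = [t for t in di.terms if t.name() != "Intercept"]
    cols_of = {t: list(range(*di.term_slices[t].indices(X.shape[1])))
               for t in di.terms}

    def contains(a, b):
        return set(b.factors) < set(a.factors)

    rows, aliased = [], []
    for t in terms:
        base_terms = [u for u in di.terms
                      if u is not t and not contains(u, t)]
        base_cols = sorted(itertools.chain.from_iterable(
            cols_of[u] for u in base_terms))
        with_cols = sorted(base_cols + cols_of[t])
        sse0, rank0 = _sse(X[:, base_cols], y)
        sse1, rank1 = _sse(X[:, with_cols], y)
        df_t = rank1 - rank0
        if df_t < len(cols_of[t]):
            aliased.append(t.name())
        if df_t == 0:
            rows.append({"term": t.name(), "df": 0, "ss": 0.0,
                         "F": np.nan, "p": np.nan})
            continue
        ss_t = max(sse0 - sse1, 0.0)
        if mse == 0:  # degenerate perfect fit (e.g. constant response)
            F = 0.0 if ss_t <= 1e-30 else np.inf
            p = 1.0 if F == 0.0 else 0.0
        else:
            F = (ss_t / df_t) / mse
            p = stats.f.sf(F, df_t, resid_df)
        rows.append({"term": t.name(), "df": df_t, "ss": ss_t,
                     "F": F, "p": p})
    anova = pd.DataFrame(rows)

    beta = np.linalg.pinv(X) @ y
    xtx_pinv = np.linalg.pinv(X.T @ X)
    return ModelResult(formula=formula, anova=anova, resid_df=resid_df,
                       mse=mse, ss_total=ss_total, aliased=aliased,
                       beta=beta, design_info=di, data=work,
                       response=y_col, xtx_pinv=xtx_pinv)


# ---------------------------------------------------------------------------
# post-hoc contrasts (estimated marginal means, Tukey adjustment)
# ---------------------------------------------------------------------------

_STRUCTURAL_FIX = {"Genotype": {"KO": {"HN": 0}}}


def _cell_rows(fit: ModelResult, assignment: dict) -> np.ndarray:
    """Mean design row for a counterfactual cell.

    The dataset is replayed with the cell's factor levels substituted
    (covariates keep their observed values), honoring structural constraints
    such as HN = 0 for the knockout line, and the design rows are averaged.
    """
    new = fit.data.copy()
    assignment = dict(assignment)
    for fac, level in list(assignment.items()):
        fix = _STRUCTURAL_FIX.get(fac, {}).get(level)
        if fix:
            assignment.update(fix)
    for fac, level in assignment.items():
        new[fac] = level
    (Xn,) = patsy.build_design_matrices([fit.design_info], new)
    return np.asarray(Xn).mean(axis=0)


def posthoc_contrasts(fit: ModelResult, factor: str,
                      within: dict | None = None,
                      levels=None, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-adjusted pairwise contrasts of estimated marginal means.

    ``factor`` names the model variable whose levels are compared;
    ``within`` fixes other factors (e.g. diet contrasts within one
    genotype).  Marginal means average model predictions over the observed
    covariate/factor distribution with the cell levels substituted.
    """
    within = within or {}
    if levels is None:
        levels = list(pd.unique(fit.data[factor]))
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two levels to contrast")
    rows_by_level = {
        lv: _cell_rows(fit, {factor: lv, **within}) for lv in levels
    }
    out = []
    df_resid = fit.resid_df
    for a, b in itertools.combinations(levels, 2):
        c = rows_by_level[a] - rows_by_level[b]
        est = float(c @ fit.beta)
        var = float(c @ fit.xtx_pinv @ c) * fit.mse
        se = np.sqrt(max(var, 0.0))
        if se == 0:
            t_stat, p_unadj, p_tukey = np.nan, np.nan, np.nan
            ci = (est, est)
        else:
            t_stat = est / se
            p_unadj = 2 * stats.t.sf(abs(t_stat), df_resid)
            q_obs = abs(t_stat) * np.sqrt(2.0)
            p_tukey = float(stats.studentized_range.sf(q_obs, k, df_resid))
            q_crit = stats.studentized_range.ppf(1 - alpha, k, df_resid)
            half = q_crit / np.sqrt(2.0) * se
            ci = (est - half, est + half)
        out.append({"pair": f"{a}-{b}", "estimate": est, "se": se,
                    "t": t_stat, "p_unadj": p_unadj, "p_tukey": p_tukey,
                    "ci_low": ci[0], "ci_high": ci[1],
                    "within": str(within) if within else ""})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# effect sizes and correlations
# ---------------------------------------------------------------------------

def cohen_f(fit: ModelResult, factor: str) -> float:
    """Cohen F from the factor's ANOVA sum of squares: sqrt(eta2/(1-eta2))."""
    row = fit.anova[fit.anova["term"] == factor]
    if row.empty:
        raise KeyError(f"term '{factor}' not in ANOVA table")
    if fit.ss_total == 0:
        return 0.0
    eta2 = float(row["ss"].iloc[0]) / fit.ss_total
    eta2 = min(eta2, 1 - 1e-12)
    return float(np.sqrt(eta2 / (1 - eta2)))


def biserial_correlation(binary, continuous) -> tuple[float, float]:
    """Point-biserial correlation and its exact-t p-value."""
    b = np.asarray(binary)
    if b.dtype.kind in "OUS":
        levels = pd.unique(b)
        if len(levels) != 2:
            raise ValueError("binary variable must have exactly two levels")
        b = (b == levels[1]).astype(float)
    else:
        if len(np.unique(b)) != 2:
            raise ValueError("binary variable must have exactly two levels")
        b = b.astype(float)
    r, p = stats.pointbiserialr(b, np.asarray(continuous, float))
    return float(r), float(p)


# ---------------------------------------------------------------------------
# synthetic cohort generator
# ---------------------------------------------------------------------------

def make_synthetic_cohort(n: int | None = None, seed: int = 0,
                          shifts=(), counts: pd.DataFrame | None = None
                          ) -> pd.DataFrame:
    """Synthetic cohort table with the study's group structure.

    Group membership follows the packaged count table (resampled to ``n``
    subjects when given).  Baselines emulate the cohort scale: age about 12
    months, weight by diet (control ~29 g, high-fat ~43 g), DLVV ~0.045 mL,
    EF ~50%, HR ~450 bpm.  ``shifts`` injects known effects: each entry is a
    dict(column=..., where={col: level}, delta=...) added after generation,
    with ``delta_sd`` accepted as a multiple of the column's baseline SD.
    """
    rng = np.random.default_rng(seed)
    counts = counts if counts is not None else load_cohort_counts()
    expanded = counts.loc[counts.index.repeat(counts["count"])]
    if n is not None:
        idx = rng.choice(len(expanded), size=n, replace=n > len(expanded))
        expanded = expanded.iloc[idx]
    rows = []
    for i, (_, g) in enumerate(expanded.iterrows()):
        isoform, hn = _isoform(g["genotype"])
        hfd = g["diet"] == "HFD"
        weight = rng.normal(43.0 if hfd else 29.0, 5.0)
        dlvv = max(rng.normal(0.045, 0.010), 0.015)
        ef = float(np.clip(rng.normal(50.0, 12.0), 15.0, 85.0))
        slvv = dlvv * (1 - ef / 100.0)
        rows.append({
            "subject_id": f"m{i:03d}",
            "genotype": isoform,
            "hn": 0 if hn is None else hn,
            "sex": g["sex"],
            "diet": g["diet"],
            "age_months": rng.normal(12.0, 1.2),
            "weight_g": max(weight, 15.0),
            "dlvv_ml": dlvv,
            "slvv_ml": slvv,
            "hr_bpm": float(np.clip(rng.normal(450.0, 40.0), 310.0, 590.0)),
        })
    df = pd.DataFrame(rows).reset_index(drop=True)
    df = derive_metrics_frame(df)
    for shift in shifts:
        col = shift["column"]
        delta = shift.get("delta")
        if delta is None:
            delta = shift["delta_sd"] * df[col].std()
        mask = np.ones(len(df), dtype=bool)
        for c, lv in shift.get("where", {}).items():
            mask &= (df[c] == lv).to_numpy()
        df.loc[mask, col] += delta
    return df
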