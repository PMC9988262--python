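"""Brain-age-gap computation and the inferential suite around it.

BAG is predicted minus chronological age (positive = older-appearing). Age
enters every test as a covariate (or by residualization for group plots) to
correct the regression-dilution bias of brain-age models. The suite covers:
demographic Welch t and Yates χ² tests, omnibus ANOVA with FDR-corrected
pairwise contrasts on age-residualized BAG, Levene's variance test, Williams's
test for dependent correlations sharing one variable (model-performance
comparison), linear BAG models with partial η² effect sizes, continuous
biomarker/cognition associations with group interactions, amyloid-positivity
classification from the biomarker panel, and the global cognitive composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_cohort import BiomarkerPanel

#: amyloid-PET / CSF positivity cutoffs
PIB_CUTOFF = 1.42          # SUVR, positive strictly above
AV45_CUTOFF = 1.19         # SUVR, positive strictly above
CSF_AB42_AB40_CUTOFF = 0.0673  # ratio, positive strictly below

GROUP_ORDER = ("CN_Aneg", "CN_Apos", "CI")


@dataclass
class BagEstimate:
    id: str
    model_tag: str            # FC | S | S+FC
    age: float
    predicted_age: float
    bag: float
    residual_bag: float = float("nan")

    def __post_init__(self) -> None:
        if not np.isfinite(self.bag):
            raise ValueError(f"{self.id}: non-finite BAG")


@dataclass
class EffectEstimate:
    term: str
    beta: float
    se: float
    stat: float               # t (or F for multi-df terms)
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.partial_eta_sq <= 1 + 1e-12:
            raise ValueError("partial eta^2 outside [0, 1]")


@dataclass
class GroupContrastResult:
    omnibus_f: float
    df1: int
    df2: int
    omnibus_p: float
    pairwise: pd.DataFrame     # columns: pair, t, df, p_raw, p_fdr
    levene_stat: float
    levene_p: float
    normality: dict = field(default_factory=dict)


def partial_eta_sq_from_t(t: float, df_resid: int) -> float:
    """η_p² for a 1-df term: t² / (t² + residual df)."""
    return t * t / (t * t + df_resid)


# --------------------------------------------------------------------------
# BAG

def compute_bag(predictions: pd.DataFrame, reference_ids=None) -> pd.DataFrame:
    """BAG = predicted − chronological age, plus age-residualized BAG.

    ``predictions`` needs columns ``id`` (or id index), ``model_tag``,
    ``age`` and ``pred_age``. The age→BAG line for residualization is fit by
    OLS per model tag within ``reference_ids`` (default: all rows), and its
    residuals are evaluated for every row.
    """
    df = predictions.reset_index() if "id" not in predictions.columns else predictions.copy()
    required = {"id", "model_tag", "age", "pred_age"}
    if not required <= set(df.columns):
        raise ValueError(f"predictions table needs columns {sorted(required)}")
    df = df.copy()
    df["bag"] = df["pred_age"] - df["age"]
    out = []
    for tag, sub in df.groupby("model_tag", sort=False):
        ref = sub if reference_ids is None else sub[sub["id"].isin(reference_ids)]
        if len(ref) < 3 or ref["age"].nunique() < 2:
            # degenerate reference: fall back to intercept-only centering
            slope, intercept = 0.0, float(ref["bag"].mean())
        else:
            slope, intercept = np.polyfit(ref["age"], ref["bag"], 1)
        sub = sub.copy()
        sub["residual_bag"] = sub["bag"] - (intercept + slope * sub["age"])
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def residualize(values, ages) -> np.ndarray:
    """OLS residuals of ``values`` on age (with intercept)."""
    slope, intercept = np.polyfit(np.asarray(ages, float), np.asarray(values, float), 1)
    return np.asarray(values, float) - (intercept + slope * np.asarray(ages, float))


# --------------------------------------------------------------------------
# demographic tests

def welch_t_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Welch's two-sample t from group summaries: (t, df, two-sided p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("SDs must be positive in at least one group")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi2_yates(table) -> tuple[float, int, float]:
    """Yates-corrected χ² for a 2×2 table: (χ², df=1, p).

    The continuity correction is clamped at zero, so perfectly proportional
    tables give χ² = 0 exactly.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("chi2_yates expects a 2x2 table")
    if (obs < 0).any():
        raise ValueError("negative counts")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=True)
    if (expected <= 0).any():
        raise ValueError("a cell has zero expected count")
    return float(chi2), int(dof), float(p)


def williams_t(r12: float, r13: float, r23: float, n: int):
    """Williams's test for two dependent correlations sharing variable 1.

    Tests r12 = r13 given their mutual correlation r23, on n observations;
    returns (t, df = n − 3, two-sided p).
    """
    for r in (r12, r13, r23):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("need n > 3")
    corr = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1]])
    if np.linalg.eigvalsh(corr)[0] < -1e-10:
        raise ValueError("correlation triple is not positive semidefinite")
    det = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
    rbar = (r12 + r13) / 2
    denom = 2 * ((n - 1) / (n - 3)) * det + rbar**2 * (1 - r23) ** 3
    t = (r12 - r13) * np.sqrt((n - 1) * (1 + r23) / denom)
    df = n - 3
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


# --------------------------------------------------------------------------
# linear BAG models (Table-2 style)

def _ols_effects(model, terms=None) -> list[EffectEstimate]:
    df_resid = int(model.df_resid)
    out = []
    names = terms if terms is not None else model.params.index
    for name in names:
        t = float(model.tvalues[name])
        out.append(EffectEstimate(
            term=name, beta=float(model.params[name]), se=float(model.bse[name]),
            stat=t, df_num=1, df_den=df_resid, p=float(model.pvalues[name]),
            partial_eta_sq=partial_eta_sq_from_t(t, df_resid)))
    return out


def fit_bag_model(bags: pd.DataFrame, participants: pd.DataFrame,
                  model_tag: str) -> tuple[list[EffectEstimate], int]:
    """OLS of BAG on impairment and amyloid status with covariates.

    Terms: CDR>0 indicator, amyloid-positive indicator, age, sex, education,
    plus mean FD for FC-containing model tags. Complete cases only. Returns
    the per-term effects (with η_p² = t²/(t²+df_resid)) and the n used.
    """
    part = participants.reset_index().drop(columns=["age"], errors="ignore")
    sub = bags[bags["model_tag"] == model_tag].merge(part, on="id", how="inner")
    cols = ["bag", "age", "sex", "education", "cdr", "amyloid_positive"]
    use_fd = model_tag in ("FC", "S+FC")
    if use_fd:
        cols.append("mean_fd")
    data = sub.dropna(subset=[c for c in cols if c in sub.columns]).copy()
    data["cdr_pos"] = (data["cdr"] > 0).astype(float)
    data["amyloid_pos"] = data["amyloid_positive"].astype(float)
    data["female"] = (data["sex"] == "female").astype(float)
    formula = "bag ~ cdr_pos + amyloid_pos + age + female + education"
    if use_fd:
        formula += " + mean_fd"
    if data.shape[0] <= formula.count("+") + 2:
        raise ValueError("too few complete cases for the BAG model")
    model = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("rank-deficient design in BAG model")
    return _ols_effects(model), int(model.nobs)


def fit_group_shift_model(bags: pd.DataFrame, participants: pd.DataFrame,
                          model_tag: str,
                          reference: str = "CN_Aneg") -> dict[str, EffectEstimate]:
    """Group-dummy OLS of BAG: the direct estimator of per-group shifts.

    ``bag ~ C(group) + age + sex + education (+ mean FD for FC tags)`` with
    the given reference group; the dummy coefficients estimate each group's
    BAG shift relative to the reference, which is the estimand when effects
    are planted per group (unlike the additive CDR/amyloid model, which
    splits a group shift across two correlated indicators).
    """
    part = participants.reset_index().drop(columns=["age"], errors="ignore")
    sub = bags[bags["model_tag"] == model_tag].merge(part, on="id", how="inner")
    use_fd = model_tag in ("FC", "S+FC")
    cols = ["bag", "age", "sex", "education", "group"] + (["mean_fd"] if use_fd else [])
    data = sub.dropna(subset=cols).copy()
    data["female"] = (data["sex"] == "female").astype(float)
    levels = [reference] + [g for g in GROUP_ORDER if g != reference
                            and (data["group"] == g).any()]
    data["group"] = pd.Categorical(data["group"], categories=levels)
    rhs = "C(group) + age + female + education" + (" + mean_fd" if use_fd else "")
    model = smf.ols(f"bag ~ {rhs}", data=data).fit()
    df_resid = int(model.df_resid)
    out = {}
    for g in levels[1:]:
        name = f"C(group)[T.{g}]"
        t = float(model.tvalues[name])
        out[g] = EffectEstimate(
            term=g, beta=float(model.params[name]), se=float(model.bse[name]),
            stat=t, df_num=1, df_den=df_resid, p=float(model.pvalues[name]),
            partial_eta_sq=partial_eta_sq_from_t(t, df_resid))
    return out


# --------------------------------------------------------------------------
# group contrasts

def group_contrasts(residual_bags, groups, fdr_alpha: float = 0.05) -> GroupContrastResult:
    """Omnibus ANOVA plus FDR-corrected pairwise Welch t on residual BAG.

    Levene's test (centered at the mean) reports variance homogeneity; the
    BH family is the set of pairwise contrasts within this model.
    """
    vals = np.asarray(residual_bags, dtype=float)
    g = pd.Categorical(groups)
    levels = [l for l in GROUP_ORDER if l in g.categories] or list(g.categories)
    samples = [vals[np.asarray(groups) == l] for l in levels]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) < 3 for s in samples):
        raise ValueError("each group needs n >= 3")

    f, p = stats.f_oneway(*samples)
    if not np.isfinite(f):       # identical values in all groups
        f, p = 0.0, 1.0
    df1 = len(samples) - 1
    df2 = vals.size - len(samples)
    lev, lev_p = stats.levene(*samples, center="mean")
    if not np.isfinite(lev):
        lev, lev_p = 0.0, 1.0

    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = samples[i], samples[j]
            if np.ptp(np.concatenate([a, b])) == 0:
                t, pr, df = 0.0, 1.0, len(a) + len(b) - 2
            else:
                res = stats.ttest_ind(a, b, equal_var=False)
                t, pr, df = float(res.statistic), float(res.pvalue), float(res.df)
            rows.append({"pair": f"{levels[i]} vs {levels[j]}", "t": t,
                         "df": df, "p_raw": pr})
    pw = pd.DataFrame(rows)
    pw["p_fdr"] = multipletests(pw["p_raw"], alpha=fdr_alpha, method="fdr_bh")[1]

    sw = {l: stats.shapiro(s).pvalue if 3 <= len(s) <= 5000 else np.nan
          for l, s in zip(levels, samples)}
    return GroupContrastResult(omnibus_f=float(f), df1=df1, df2=df2,
                               omnibus_p=float(p), pairwise=pw,
                               levene_stat=float(lev), levene_p=float(lev_p),
                               normality=sw)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


# --------------------------------------------------------------------------
# continuous biomarker / cognition associations

AMYLOID_OUTCOMES = {"amyloid_centiloid", "csf_ab42_ab40"}
LOG_OUTCOMES = {"csf_ptau_ab40"}


def biomarker_association(bags: pd.DataFrame, participants: pd.DataFrame,
                          outcome: str, model_tag: str,
                          min_n: int = 20) -> dict:
    """Linear model of a biomarker/cognition outcome on residual BAG × group.

    Treatment coding with the lowest-severity group present as reference;
    covariates sex and education (plus mean FD for FC-containing tags).
    CN/A− is excluded from continuous-amyloid models (their biomarker range
    is restricted by definition); pTau/Aβ40 is log-transformed. Returns the
    BAG main effect, the interaction terms, and per-group simple slopes.
    """
    part = participants.reset_index().drop(columns=["age"], errors="ignore")
    sub = bags[bags["model_tag"] == model_tag].merge(part, on="id", how="inner")
    if outcome not in sub.columns:
        raise ValueError(f"unknown outcome column {outcome!r}")
    if outcome in AMYLOID_OUTCOMES:
        sub = sub[sub["group"] != "CN_Aneg"]
    use_fd = model_tag in ("FC", "S+FC")
    covars = ["sex", "education"] + (["mean_fd"] if use_fd else [])
    data = sub.dropna(subset=[outcome, "residual_bag"] + covars).copy()
    if data.shape[0] < min_n:
        raise ValueError(f"only {data.shape[0]} participants with {outcome}; "
                         f"need >= {min_n}")
    y = data[outcome].astype(float)
    if outcome in LOG_OUTCOMES:
        if (y <= 0).any():
            raise ValueError("log transform requires positive values")
        y = np.log(y)
    if y.std() == 0:
        raise ValueError("outcome is constant")
    data["y"] = y
    data["female"] = (data["sex"] == "female").astype(float)
    present = [g for g in GROUP_ORDER if (data["group"] == g).any()]
    data["group"] = pd.Categorical(data["group"], categories=present)

    rhs = "residual_bag * group + female + education"
    if use_fd:
        rhs += " + mean_fd"
    model = smf.ols(f"y ~ {rhs}", data=data).fit()
    df_resid = int(model.df_resid)

    effects = {"main": _ols_effects(model, ["residual_bag"])[0],
               "interactions": _ols_effects(
                   model, [t for t in model.params.index
                           if t.startswith("residual_bag:")]),
               "n": int(model.nobs), "reference_group": present[0]}

    # per-group simple slopes via linear contrasts on the fitted model
    slopes = {}
    for g in present:
        contrast = np.zeros(len(model.params))
        contrast[list(model.params.index).index("residual_bag")] = 1.0
        inter = f"residual_bag:group[T.{g}]"
        if inter in model.params.index:
            contrast[list(model.params.index).index(inter)] = 1.0
        tt = model.t_test(contrast)
        t = float(np.squeeze(tt.tvalue))
        slopes[g] = EffectEstimate(
            term=f"slope[{g}]", beta=float(np.squeeze(tt.effect)),
            se=float(np.squeeze(tt.sd)), stat=t, df_num=1, df_den=df_resid,
            p=float(np.squeeze(tt.pvalue)),
            partial_eta_sq=partial_eta_sq_from_t(t, df_resid))
    effects["simple_slopes"] = slopes
    return effects


# --------------------------------------------------------------------------
# biomarker positivity & cognition

def amyloid_positivity(panel: BiomarkerPanel) -> tuple[bool, list[str]]:
    """Amyloid status from the panel with published cutoffs.

    Positive iff PIB SUVR > 1.42, AV45 SUVR > 1.19, or CSF Aβ42/Aβ40 <
    0.0673 (strict inequalities); PET/CSF discordance counts as positive.
    Returns the status and the list of measures in the positive range.
    """
    if not panel.has_amyloid_measure():
        raise ValueError("no amyloid measure available")
    sources = []
    if panel.pib_suvr is not None and panel.pib_suvr > PIB_CUTOFF:
        sources.append("pib_suvr")
    if panel.av45_suvr is not None and panel.av45_suvr > AV45_CUTOFF:
        sources.append("av45_suvr")
    if panel.csf_ab42_ab40 is not None and panel.csf_ab42_ab40 < CSF_AB42_AB40_CUTOFF:
        sources.append("csf_ab42_ab40")
    return bool(sources), sources


#: timed tasks are negated so that higher composite = better cognition
TIMED_TASKS = ("trails_a", "trails_b")
COMPOSITE_TASKS = ("trails_a", "trails_b", "animal_naming", "free_recall")


def cognitive_composite(scores: dict, reference: dict) -> float:
    """Equal-weight global cognition composite.

    Each available task score is z-scored against the CN/A− reference
    ``{task: (mean, sd)}``; timed tasks (Trails A/B) are sign-flipped; the
    composite is the mean of available task z-scores.
    """
    zs = []
    for task in COMPOSITE_TASKS:
        val = scores.get(task)
        if val is None:
            continue
        mean, sd = reference[task]
        if sd <= 0:
            raise ValueError(f"non-positive reference SD for {task}")
        z = (val - mean) / sd
        if task in TIMED_TASKS:
            z = -z
        zs.append(z)
    if not zs:
        raise ValueError("no composite tasks available")
    return float(np.mean(zs))
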