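"""Group-level statistics for the olfactory-network analysis.

Implements the analysis grid applied to the cohort: one-way ANOVAs over
behavioral scores, the sex chi-square, Pearson correlations between UPSIT
and cognitive scores / network betas / ROI volumes, the M +/- 2.5 SD outlier
rule, olfactory classification from UPSIT, and the two-way ANCOVA testing
the UPSIT x DRS-memory interaction on effective connectivity.

Boundary conventions: UPSIT < 20 is anosmic, 20-30 inclusive hyposmic,
> 30 normosmic.  Post-hoc tests are pairwise Welch t tests, uncorrected by
default.  The ANCOVA uses Type-III sums of squares on mean-centered
covariates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

ANOSMIC = "anosmic"
HYPOSMIC = "hyposmic"
NORMOSMIC = "normosmic"

UPSIT_RANGE = (0.0, 40.0)


# ---------------------------------------------------------------------------
# mechanical rules
# ---------------------------------------------------------------------------

def classify_olfaction(upsit: float) -> str:
    """Olfactory class from a UPSIT score.

    < 20 anosmic; 20-30 (inclusive) hyposmic; > 30 normosmic.  Scores
    outside the instrument range [0, 40] are rejected.
    """
    if not np.isfinite(upsit) or upsit < UPSIT_RANGE[0] or upsit > UPSIT_RANGE[1]:
        raise ValueError(f"UPSIT score {upsit!r} outside [0, 40]")
    if upsit < 20:
        return ANOSMIC
    if upsit <= 30:
        return HYPOSMIC
    return NORMOSMIC


def remove_outliers(values, k: float = 2.5):
    """Single-pass M +/- k SD exclusion.

    The mean and SD are computed once on the full input; values farther
    than ``k`` SD from the mean are excluded.  Returns ``(retained,
    report)`` where the report lists the excluded values and indices.
    A zero-SD input excludes nothing (with a warning in the report).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D sample of at least 3 values")
    m = x.mean()
    sd = x.std(ddof=1)
    report = {"mean": m, "sd": sd, "k": k, "excluded_values": [], "excluded_indices": []}
    if sd == 0:
        report["warning"] = "zero SD; nothing excluded"
        return x.copy(), report
    keep = np.abs(x - m) <= k * sd
    report["excluded_values"] = x[~keep].tolist()
    report["excluded_indices"] = np.nonzero(~keep)[0].tolist()
    return x[keep], report


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

@dataclass
class ANOVAResult:
    f: float
    df_between: int
    df_within: float
    p: float
    group_stats: pd.DataFrame  # label, n, mean, sd
    posthoc: Optional[pd.DataFrame] = None  # pair, t, df, p


def _welch_t_from_summary(m1, s1, n1, m2, s2, n2):
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return t, df, p


def _posthoc_table(stats: pd.DataFrame, bonferroni: bool) -> pd.DataFrame:
    rows = []
    pairs = list(itertools.combinations(stats.index, 2))
    for a, b in pairs:
        t, df, p = _welch_t_from_summary(
            stats.loc[a, "mean"], stats.loc[a, "sd"], stats.loc[a, "n"],
            stats.loc[b, "mean"], stats.loc[b, "sd"], stats.loc[b, "n"],
        )
        if bonferroni:
            p = min(1.0, p * len(pairs))
        rows.append({"pair": f"{a} vs {b}", "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)


def oneway_anova(
    groups: Mapping[str, Sequence[float]],
    posthoc: bool = True,
    bonferroni: bool = False,
) -> ANOVAResult:
    """Classical fixed-effects one-way ANOVA with Welch pairwise post-hocs."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has n < 2")
    f, p = sps.f_oneway(*arrays.values())
    stats = pd.DataFrame(
        {
            "n": {k: v.size for k, v in arrays.items()},
            "mean": {k: v.mean() for k, v in arrays.items()},
            "sd": {k: v.std(ddof=1) for k, v in arrays.items()},
        }
    )
    n_total = int(stats["n"].sum())
    result = ANOVAResult(
        f=float(f),
        df_between=len(arrays) - 1,
        df_within=n_total - len(arrays),
        p=float(p),
        group_stats=stats,
    )
    if posthoc:
        result.posthoc = _posthoc_table(stats, bonferroni)
    return result


def oneway_anova_from_summary(
    means: Sequence[float],
    sds: Sequence[float],
    ns: Sequence[int],
    labels: Optional[Sequence[str]] = None,
    posthoc: bool = True,
    bonferroni: bool = False,
) -> ANOVAResult:
    """One-way ANOVA from group means, SDs, and sizes only.

    Algebraically identical to :func:`oneway_anova` on the raw data.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    if means.size < 2:
        raise ValueError("need at least 2 groups")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"g{i}" for i in range(means.size)]
    n_total = int(ns.sum())
    grand = float(np.sum(ns * means) / n_total)
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(np.sum((ns - 1) * sds**2))
    dfb = means.size - 1
    dfw = n_total - means.size
    if ssw == 0:
        f = np.inf if ssb > 0 else 0.0
    else:
        f = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(f, dfb, dfw))
    stats = pd.DataFrame({"n": ns, "mean": means, "sd": sds}, index=list(labels))
    result = ANOVAResult(f=float(f), df_between=dfb, df_within=dfw, p=p, group_stats=stats)
    if posthoc:
        result.posthoc = _posthoc_table(stats, bonferroni)
    return result


# ---------------------------------------------------------------------------
# chi-square, correlation
# ---------------------------------------------------------------------------

def chi_square_independence(table) -> Tuple[float, int, float]:
    """Pearson chi-square of independence (no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("need a 2-D table of non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float
    labels: Tuple[str, str] = ("x", "y")


def pearson(x, y, labels: Tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Product-moment correlation with the two-tailed t-based p value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(f"constant input for {labels}: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=int(x.size), p=float(p), labels=labels)


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------

@dataclass
class ANCOVAResult:
    table: pd.DataFrame  # index: term; columns: sum_sq, df, F, p
    ss_type: str = "III"
    centered: bool = True


def ancova_interaction(
    data: pd.DataFrame,
    response: str = "ec",
    covariates: Tuple[str, str] = ("upsit", "drs_memory"),
    include_age: bool = False,
    center: bool = True,
) -> ANCOVAResult:
    """Two-way ANCOVA with continuous covariates and their interaction.

    Fits ``response ~ a + b + a:b (+ age)`` by OLS and reports Type-III
    sums of squares.  Covariates are mean-centered by default so the
    interaction test is stable under location shifts.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    a_name, b_name = covariates
    cols = [response, a_name, b_name] + (["age"] if include_age else [])
    for c in cols:
        if c not in data.columns:
            raise KeyError(f"missing column {c!r}")
    df = data[cols].dropna().copy()
    n_terms = 4 + (1 if include_age else 0)
    if len(df) < n_terms + 2:
        raise ValueError(f"need at least {n_terms + 2} rows, got {len(df)}")
    work = pd.DataFrame({"y": df[response].to_numpy(float)})
    for name, col in [("a", a_name), ("b", b_name)] + (
        [("age", "age")] if include_age else []
    ):
        v = df[col].to_numpy(float)
        work[name] = v - v.mean() if center else v

    design = np.column_stack(
        [work["a"], work["b"], work["a"] * work["b"]]
        + ([work["age"]] if include_age else [])
    )
    design_i = np.column_stack([np.ones(len(work)), design])
    if np.linalg.matrix_rank(design_i) < design_i.shape[1]:
        corr = np.corrcoef(design, rowvar=False)
        bad = [
            (i, j)
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"singular ANCOVA design; collinear term pairs: {bad}")

    formula = "y ~ a + b + a:b" + (" + age" if include_age else "")
    fit = smf.ols(formula, data=work).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(fit, typ=3)
    rename = {"a": a_name, "b": b_name, "a:b": f"{a_name}:{b_name}"}
    tab = tab.rename(index=rename)
    tab = tab.rename(columns={"PR(>F)": "p", "sum_sq": "sum_sq", "F": "F"})
    return ANCOVAResult(table=tab, ss_type="III", centered=center)


# ---------------------------------------------------------------------------
# full analysis grid
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ["upsit", "mmse", "drs2", "drs_memory", "cvlt2", "gds"]
GROUPS = ["CN", "MCI", "AD"]


def _by_group(df: pd.DataFrame, col: str) -> Dict[str, np.ndarray]:
    return {
        g: df.loc[df["group"] == g, col].to_numpy(float)
        for g in GROUPS
        if (df["group"] == g).sum() > 0
    }


def _safe(call, log, label):
    try:
        return call()
    except (ValueError, KeyError) as err:
        log.append(f"{label}: skipped ({err})")
        return None


def behavioral_report(
    subjects: pd.DataFrame,
    condition_summary: Optional[pd.DataFrame] = None,
    ec: Optional[pd.DataFrame] = None,
    outlier_k: float = 2.5,
) -> dict:
    """Run the full cohort analysis grid and return a results bundle.

    ``subjects`` needs the behavioral/QC columns of the participants table;
    ``condition_summary`` the per-subject per-network condition-mean betas;
    ``ec`` per-subject DMN->ON effective-connectivity values.  Sections whose
    inputs are missing or degenerate are skipped with a log entry.
    """
    required = ["subject_id", "group", "upsit"]
    for c in required:
        if c not in subjects.columns:
            raise KeyError(f"missing column {c!r} in subjects table")
    log: list = []
    out: dict = {"log": log}

    # group ANOVAs over every behavioral score
    anovas = {}
    for score in SCORE_COLUMNS:
        if score not in subjects.columns:
            log.append(f"anova[{score}]: missing column")
            continue
        anovas[score] = _safe(
            lambda s=score: oneway_anova(_by_group(subjects, s)), log, f"anova[{score}]"
        )
    out["score_anovas"] = anovas

    # sex ratio chi-square
    if "sex" in subjects.columns:
        table = pd.crosstab(subjects["group"], subjects["sex"])
        out["sex_chi2"] = _safe(
            lambda: chi_square_independence(table.to_numpy()), log, "sex_chi2"
        )

    # UPSIT vs cognition, all subjects and MCI+AD combined
    corr = {}
    mci_ad = subjects[subjects["group"].isin(["MCI", "AD"])]
    for score in ["cvlt2", "drs2", "mmse"]:
        if score not in subjects.columns:
            continue
        corr[f"upsit_vs_{score}_all"] = _safe(
            lambda s=score: pearson(subjects["upsit"], subjects[s], ("upsit", s)),
            log, f"upsit_vs_{score}_all",
        )
        corr[f"upsit_vs_{score}_mci_ad"] = _safe(
            lambda s=score: pearson(mci_ad["upsit"], mci_ad[s], ("upsit", s)),
            log, f"upsit_vs_{score}_mci_ad",
        )
    if "drs_memory" in subjects.columns:
        ad = subjects[subjects["group"] == "AD"]
        corr["upsit_vs_drs_memory_ad"] = _safe(
            lambda: pearson(ad["upsit"], ad["drs_memory"], ("upsit", "drs_memory")),
            log, "upsit_vs_drs_memory_ad",
        )
        corr["upsit_vs_drs_memory_all"] = _safe(
            lambda: pearson(
                subjects["upsit"], subjects["drs_memory"], ("upsit", "drs_memory")
            ),
            log, "upsit_vs_drs_memory_all",
        )
    out["correlations"] = corr

    # ROI volumes
    vols = {}
    for vol in ["poc_volume", "hippocampus_volume"]:
        if vol not in subjects.columns:
            continue
        vols[f"{vol}_anova"] = _safe(
            lambda v=vol: oneway_anova(_by_group(subjects, v)), log, f"{vol}_anova"
        )
        for score in ["upsit", "drs_memory"]:
            if score in subjects.columns:
                vols[f"{vol}_vs_{score}"] = _safe(
                    lambda v=vol, s=score: pearson(subjects[v], subjects[s], (v, s)),
                    log, f"{vol}_vs_{score}",
                )
    out["volumes"] = vols

    # network betas: ON activation, DMN suppression
    if condition_summary is not None:
        out["betas"] = _beta_section(subjects, condition_summary, outlier_k, log)
    else:
        log.append("betas: no condition summary provided")

    # MCI-only EC analysis with the UPSIT > 20 filter
    if ec is not None:
        out["ec"] = _ec_section(subjects, ec, log)
    else:
        log.append("ec: no EC table provided")
    return out


def _beta_section(subjects, condition_summary, outlier_k, log):
    from .templates import DMN, ON

    sec: dict = {}
    merged = condition_summary.merge(
        subjects[["subject_id", "group", "upsit"]], on="subject_id"
    )
    for network, col in [(ON, "odor_visual"), (DMN, "odor_visual")]:
        sub = merged[merged["network"] == network]
        if sub.empty:
            log.append(f"betas[{network}]: no rows")
            continue
        vals = sub[col].to_numpy(float)
        if vals.size >= 3:
            _, report = remove_outliers(vals, k=outlier_k)
            keep = np.ones(len(sub), bool)
            keep[report["excluded_indices"]] = False
        else:
            keep = np.ones(len(sub), bool)
            report = {"excluded_indices": []}
        kept = sub[keep]
        sec[f"{network}_outliers"] = report
        sec[f"{network}_odor_anova"] = _safe(
            lambda k=kept: oneway_anova(_by_group(k, col)), log,
            f"betas[{network}]_odor_anova",
        )
        sec[f"{network}_diff_anova"] = _safe(
            lambda k=kept: oneway_anova(_by_group(k, "difference")), log,
            f"betas[{network}]_diff_anova",
        )
        sec[f"{network}_odor_vs_upsit_combined"] = _safe(
            lambda k=kept: pearson(k[col], k["upsit"], (f"{network}_beta", "upsit")),
            log, f"betas[{network}]_vs_upsit",
        )
        for g in GROUPS:
            gk = kept[kept["group"] == g]
            sec[f"{network}_odor_vs_upsit_{g}"] = _safe(
                lambda k=gk: pearson(k[col], k["upsit"], (f"{network}_beta", "upsit")),
                log, f"betas[{network}]_vs_upsit_{g}",
            )
    return sec


def _ec_section(subjects, ec, log):
    from .eusem import age_correct

    sec: dict = {}
    cols = ["subject_id", "group", "upsit"] + (
        ["drs_memory"] if "drs_memory" in subjects.columns else []
    ) + (["age"] if "age" in subjects.columns else [])
    merged = ec.merge(subjects[cols], on="subject_id")
    mci = merged[(merged["group"] == "MCI") & (merged["upsit"] > 20)]
    sec["n_mci_retained"] = int(len(mci))
    if len(mci) < 3:
        log.append("ec: fewer than 3 retained MCI subjects; section skipped")
        return sec
    ec_vals = mci["ec"].to_numpy(float)
    if "age" in mci.columns:
        ec_used = age_correct(ec_vals, mci["age"].to_numpy(float))
    else:
        ec_used = ec_vals - ec_vals.mean()
        log.append("ec: no age column; EC mean-centered, not age-corrected")
    sec["ec_vs_upsit_mci"] = _safe(
        lambda: pearson(ec_used, mci["upsit"], ("ec_age_corrected", "upsit")),
        log, "ec_vs_upsit_mci",
    )
    if "drs_memory" in mci.columns:
        sec["ec_vs_drs_memory_mci"] = _safe(
            lambda: pearson(ec_used, mci["drs_memory"], ("ec_age_corrected", "drs_memory")),
            log, "ec_vs_drs_memory_mci",
        )
        frame = pd.DataFrame(
            {"ec": ec_used, "upsit": mci["upsit"], "drs_memory": mci["drs_memory"]}
        )
        sec["ancova"] = _safe(
            lambda: ancova_interaction(frame), log, "ec_ancova"
        )
    return sec
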