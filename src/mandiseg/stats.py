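"""Statistical battery for the mandibular-volumetry study design.

Covers the published analysis plan: Shapiro-Wilk normality gate, paired
and pooled-variance independent t-tests, Pearson chi-square for sex
proportions, one-way ANOVA (raw or from sufficient statistics) with
Tukey-HSD or Bonferroni-adjusted pairwise post hoc comparisons,
percentage volume differences, intraclass correlation coefficients from
two-way ANOVA mean squares, the Dahlberg method error, and an a-priori
two-sample-t sample size based on noncentral-t power.

Conventions (each is the classical reading of the underspecified source
analysis, see docs/methods.md): independent t pools variances (Welch by
flag); chi-square without continuity correction (flag available);
ICC(2,1) two-way random absolute agreement by default; a failed normality
gate logs a warning but the pipeline stays parametric.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "PosthocTable",
    "shapiro_gate",
    "t_test",
    "chi_square_counts",
    "oneway_anova",
    "summary_anova",
    "posthoc",
    "percent_difference",
    "icc",
    "dahlberg",
    "required_n_two_means",
    "reliability_report",
    "full_study_report",
    "StudyReport",
]

ALPHA_DEFAULT = 0.05


def _summaries(groups: Sequence[np.ndarray],
               names: Optional[Sequence[str]] = None) -> List[dict]:
    out = []
    for i, g in enumerate(groups):
        g = np.asarray(g, float)
        out.append({
            "name": names[i] if names else f"group{i + 1}",
            "n": int(g.size),
            "mean": float(np.mean(g)),
            "sd": float(np.std(g, ddof=1)) if g.size > 1 else 0.0,
        })
    return out


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | Tuple[float, float]
    p: float
    method: str
    groups: List[dict] = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError("p-value outside [0, 1]")

    def to_dict(self) -> dict:
        df = self.df
        return {
            "statistic": float(self.statistic),
            "df": list(df) if isinstance(df, tuple) else float(df),
            "p": float(self.p),
            "method": self.method,
            "groups": self.groups,
        }


@dataclass(frozen=True)
class PosthocTable:
    method: str
    alpha: float
    rows: List[dict]

    def to_dict(self) -> dict:
        return {"method": self.method, "alpha": self.alpha, "rows": self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def shapiro_gate(values, alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Shapiro-Wilk normality check; warns (does not fail) on rejection."""
    x = np.asarray(values, float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant input")
    w, p = sps.shapiro(x)
    if p < alpha:
        warnings.warn(
            f"normality rejected (Shapiro-Wilk p={p:.3g}); "
            "proceeding parametric", stacklevel=2,
        )
    return TestResult(float(w), float(x.size), float(p), "shapiro_wilk",
                      _summaries([x]))


def t_test(a, b, paired: bool = False, pooled: bool = True) -> TestResult:
    """Two-tailed t-test.

    Independent samples pool variances by default (``pooled=False`` gives
    Welch).  Degenerate zero-variance inputs follow the conventions:
    identical constant groups give t=0, p=1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        if a.size < 2:
            raise ValueError("need n >= 2")
        d = a - b
        if np.ptp(d) == 0 and d[0] == 0:
            return TestResult(0.0, float(a.size - 1), 1.0, "t_paired",
                              _summaries([a, b]))
        t, p = sps.ttest_rel(a, b)
        return TestResult(float(t), float(a.size - 1), float(p), "t_paired",
                          _summaries([a, b]))
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            df = float(a.size + b.size - 2)
            return TestResult(0.0, df, 1.0, "t_independent_pooled",
                              _summaries([a, b]))
        df = float(a.size + b.size - 2)
        return TestResult(math.inf, df, 0.0, "t_independent_pooled",
                          _summaries([a, b]))
    t, p = sps.ttest_ind(a, b, equal_var=pooled)
    if pooled:
        df: float = float(a.size + b.size - 2)
        method = "t_independent_pooled"
    else:
        va, vb = np.var(a, ddof=1) / a.size, np.var(b, ddof=1) / b.size
        df = float((va + vb) ** 2 / (va ** 2 / (a.size - 1)
                                     + vb ** 2 / (b.size - 1)))
        method = "t_independent_welch"
    return TestResult(float(t), df, float(p), method, _summaries([a, b]))


def chi_square_counts(table, correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 count table (no Yates correction by
    default)."""
    obs = np.asarray(table, float)
    if obs.shape != (2, 2) or np.any(obs < 0) or np.any(obs != np.round(obs)):
        raise ValueError("expected a 2x2 table of nonnegative integers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: zero row or column margin")
    res = sps.chi2_contingency(obs, correction=correction)
    return TestResult(float(res.statistic), float(res.dof), float(res.pvalue),
                      "chi_square" + ("_yates" if correction else ""))


def oneway_anova(groups: Sequence, names: Optional[Sequence[str]] = None
                 ) -> TestResult:
    """One-way ANOVA on raw samples."""
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if all(np.ptp(g) == 0 for g in gs) and len({float(g[0]) for g in gs}) == 1:
        k, N = len(gs), sum(g.size for g in gs)
        return TestResult(0.0, (float(k - 1), float(N - k)), 1.0,
                          "anova_oneway", _summaries(gs, names))
    f, p = sps.f_oneway(*gs)
    k, N = len(gs), sum(g.size for g in gs)
    return TestResult(float(f), (float(k - 1), float(N - k)), float(p),
                      "anova_oneway", _summaries(gs, names))


def summary_anova(means, sds, ns,
                  names: Optional[Sequence[str]] = None) -> TestResult:
    """One-way ANOVA from per-group sufficient statistics (mean, SD, n)."""
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, int)
    if means.size < 2 or np.any(ns < 2):
        raise ValueError("need >= 2 groups with n >= 2 each")
    N = int(ns.sum())
    k = means.size
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds ** 2).sum())
    dfb, dfw = k - 1, N - k
    if ssw == 0:
        f = 0.0 if ssb == 0 else math.inf
        p = 1.0 if ssb == 0 else 0.0
    else:
        f = (ssb / dfb) / (ssw / dfw)
        p = float(sps.f.sf(f, dfb, dfw))
    groups = [
        {"name": names[i] if names else f"group{i + 1}",
         "n": int(ns[i]), "mean": float(means[i]), "sd": float(sds[i])}
        for i in range(k)
    ]
    return TestResult(float(f), (float(dfb), float(dfw)), float(p),
                      "anova_oneway_summary", groups)


def posthoc(groups: Sequence, method: str = "bonferroni",
            alpha: float = ALPHA_DEFAULT,
            names: Optional[Sequence[str]] = None) -> PosthocTable:
    """All pairwise comparisons after a one-way ANOVA.

    ``bonferroni``: pairwise pooled-variance t-tests with p multiplied by
    the number of pairs (capped at 1).  ``tukey``: studentized-range HSD.
    """
    gs = [np.asarray(g, float) for g in groups]
    names = list(names) if names else [f"group{i + 1}" for i in range(len(gs))]
    pairs = list(itertools.combinations(range(len(gs)), 2))
    rows: List[dict] = []
    if method == "tukey":
        res = sps.tukey_hsd(*gs)
        for i, j in pairs:
            p_adj = float(res.pvalue[i, j])
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "mean_difference": float(np.mean(gs[i]) - np.mean(gs[j])),
                "p_adjusted": p_adj,
                "significant": bool(p_adj < alpha),
            })
    elif method == "bonferroni":
        m = len(pairs)
        for i, j in pairs:
            res = t_test(gs[i], gs[j], paired=False, pooled=True)
            p_adj = min(1.0, res.p * m)
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "mean_difference": float(np.mean(gs[i]) - np.mean(gs[j])),
                "p_raw": res.p,
                "p_adjusted": p_adj,
                "significant": bool(p_adj < alpha),
            })
    else:
        raise ValueError("method must be 'tukey' or 'bonferroni'")
    return PosthocTable(method=method, alpha=alpha, rows=rows)


def percent_difference(mean_ref: float, mean_other: float) -> float:
    """Percentage difference relative to the reference (first) mean."""
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (mean_ref - mean_other) / mean_ref


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------

def icc(ratings, model: str = "icc2_1") -> float:
    """Single-rater intraclass correlation from a subjects x raters matrix.

    ``icc2_1``: two-way random effects, absolute agreement.
    ``icc3_1``: two-way mixed effects, consistency.
    """
    x = np.asarray(ratings, float)
    if x.ndim != 2 or x.shape[0] < 5 or x.shape[1] < 2:
        raise ValueError("need a full matrix with >= 5 subjects, >= 2 raters")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cells are not supported")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if msr <= 1e-12 * max(abs(grand), 1.0) ** 2 and ssr <= 1e-12 * max(sst, 1.0):
        raise ValueError("ICC undefined: no between-subject variance")
    if model == "icc2_1":
        return float((msr - mse)
                     / (msr + (k - 1) * mse + k * (msc - mse) / n))
    if model == "icc3_1":
        return float((msr - mse) / (msr + (k - 1) * mse))
    raise ValueError("model must be 'icc2_1' or 'icc3_1'")


def dahlberg(pairs) -> float:
    """Dahlberg method error sqrt(sum d_i^2 / 2n) over repeated pairs."""
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("expected a nonempty (n, 2) array of repeated pairs")
    d = arr[:, 0] - arr[:, 1]
    return float(np.sqrt((d ** 2).sum() / (2.0 * len(d))))


def reliability_report(
    intra: Mapping[str, np.ndarray],
    inter: Mapping[str, np.ndarray],
    model: str = "icc2_1",
) -> pd.DataFrame:
    """Per-segment reliability table: intra/inter ICC and Dahlberg error.

    ``intra``/``inter`` map segment name to an (n_subjects, 2) matrix of
    repeated measurements (same rater twice, resp. two raters).  The
    Dahlberg error is computed on the intra-rater pairs.
    """
    rows = []
    for segment in intra:
        m_intra = np.asarray(intra[segment], float)
        m_inter = np.asarray(inter[segment], float)
        rows.append({
            "segment": segment,
            "icc_intra": icc(m_intra, model),
            "icc_inter": icc(m_inter, model),
            "dahlberg_mm3": dahlberg(m_intra),
            "icc_model": model,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sample size
# ---------------------------------------------------------------------------

def required_n_two_means(
    m1: float, sd1: float, m2: float, sd2: float,
    alpha: float = 0.05, power: float = 0.95,
    tails: int = 2, sd_mode: str = "pooled",
    n_max: int = 1_000_000,
) -> int:
    """Smallest per-group n for a two-sample t-test to reach target power.

    Effect size d = |m1 - m2| / sd with sd per ``sd_mode`` ('pooled' =
    sqrt((sd1^2+sd2^2)/2), 'group1', 'group2'); power from the noncentral
    t with ncp = d * sqrt(n/2) and df = 2n - 2.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    sd = {
        "pooled": math.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0),
        "group1": sd1,
        "group2": sd2,
    }[sd_mode]
    d = abs(m1 - m2) / sd
    if d == 0:
        raise ValueError("zero effect size: target power unreachable")
    for n in range(2, n_max + 1):
        df = 2 * n - 2
        ncp = d * math.sqrt(n / 2.0)
        if tails == 2:
            tcrit = sps.t.ppf(1 - alpha / 2, df)
            achieved = (sps.nct.sf(tcrit, df, ncp)
                        + sps.nct.cdf(-tcrit, df, ncp))
        else:
            tcrit = sps.t.ppf(1 - alpha, df)
            achieved = sps.nct.sf(tcrit, df, ncp)
        if achieved >= power:
            return n
    raise ValueError("target power not reached below n_max")


# ---------------------------------------------------------------------------
# Full study report
# ---------------------------------------------------------------------------

_SEGMENTS = ("hemimandible", "condyle", "ramus", "hemibody")

#: Table-4-style contrasts: (minuend group, subtrahend group) keyed by label.
_DIFF_PAIRS = (
    ("uni_unaff", "uni_aff"),
    ("uni_aff", "bil"),
    ("ctrl", "uni_aff"),
    ("uni_unaff", "bil"),
    ("uni_unaff", "ctrl"),
    ("ctrl", "bil"),
)


@dataclass
class StudyReport:
    """Serializable container mirroring the study's results tables."""

    alpha: float
    compatibility: Dict[str, dict]
    side_contrasts: Dict[str, Dict[str, dict]]
    anova: Dict[str, dict]
    differences: List[dict]
    normality_flags: List[dict]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "compatibility": self.compatibility,
            "side_contrasts": self.side_contrasts,
            "anova": self.anova,
            "differences": self.differences,
            "normality_flags": self.normality_flags,
        }

    def tables(self) -> Dict[str, pd.DataFrame]:
        """Tidy CSV-ready frames for each report section."""
        compat = pd.DataFrame([
            {"variable": k, **{kk: vv for kk, vv in v.items()
                               if not isinstance(vv, (list, dict))}}
            for k, v in self.compatibility.items()
        ])
        side = pd.DataFrame([
            {"arm": arm, "segment": seg,
             "statistic": r["statistic"], "p": r["p"], "method": r["method"]}
            for arm, segs in self.side_contrasts.items()
            for seg, r in segs.items()
        ])
        anova = pd.DataFrame([
            {"segment": seg, "F": r["anova"]["statistic"],
             "p": r["anova"]["p"],
             "significant": r["anova"]["p"] < self.alpha}
            for seg, r in self.anova.items()
        ])
        ph_rows = []
        for seg, r in self.anova.items():
            for row in r["posthoc"]["rows"]:
                ph_rows.append({"segment": seg, **row})
        return {
            "compatibility": compat,
            "side_contrasts": side,
            "anova": anova,
            "posthoc": pd.DataFrame(ph_rows),
            "differences": pd.DataFrame(self.differences),
        }


def _subject_level(df: pd.DataFrame) -> pd.DataFrame:
    return df.drop_duplicates("subject")[
        ["subject", "group", "age", "sex", "anb", "divergence"]
    ]


def _segment_values(df: pd.DataFrame, segment: str, **filters) -> np.ndarray:
    sel = df["segment"] == segment
    for col, val in filters.items():
        sel &= df[col] == val
    return df.loc[sel, "volume_mm3"].to_numpy()


def _side_averaged(df: pd.DataFrame, segment: str) -> np.ndarray:
    sub = df[(df["segment"] == segment) & (df["side"].isin(["L", "R"]))]
    return sub.groupby("subject")["volume_mm3"].mean().to_numpy()


def full_study_report(
    cohorts: Mapping[str, pd.DataFrame],
    alpha: float = ALPHA_DEFAULT,
    posthoc_method: str = "bonferroni",
) -> StudyReport:
    """Assemble the full comparison report from the three study arms.

    ``cohorts`` maps arm name (uni_jia, bil_jia, control) to a long-format
    cohort table.  The four-group ANOVA per segment compares the
    unilateral affected side, the unilateral unaffected side, the
    bilateral arm (per-subject side average) and controls (side average);
    the total-mandible ANOVA compares the three arms.
    """
    required = {"uni_jia", "bil_jia", "control"}
    missing = required - set(cohorts)
    if missing:
        raise ValueError(f"missing study arms: {', '.join(sorted(missing))}")
    uni, bil, ctrl = (cohorts[k] for k in ("uni_jia", "bil_jia", "control"))

    # --- compatibility (table-1 analogue): JIA arms pooled vs control ----
    jia_subj = pd.concat([_subject_level(uni), _subject_level(bil)])
    ctrl_subj = _subject_level(ctrl)
    sex_table = np.array([
        [(jia_subj["sex"] == "M").sum(), (ctrl_subj["sex"] == "M").sum()],
        [(jia_subj["sex"] == "F").sum(), (ctrl_subj["sex"] == "F").sum()],
    ])
    compatibility = {
        "age": t_test(jia_subj["age"], ctrl_subj["age"]).to_dict(),
        "anb": t_test(jia_subj["anb"], ctrl_subj["anb"]).to_dict(),
        "divergence": t_test(jia_subj["divergence"],
                             ctrl_subj["divergence"]).to_dict(),
        "sex": chi_square_counts(sex_table).to_dict(),
    }

    # --- per-arm side contrasts (table-2 analogue) -----------------------
    def paired_by_subject(df, segment, col, val_a, val_b):
        sub = df[(df["segment"] == segment) & (df["side"].isin(["L", "R"]))]
        piv = sub.pivot_table(index="subject", columns=col,
                              values="volume_mm3", aggfunc="first")
        return piv[val_a].to_numpy(), piv[val_b].to_numpy()

    side_contrasts: Dict[str, Dict[str, dict]] = {}
    for arm_name, df, col, a_val, b_val in (
        ("uni_jia", uni, "affected", True, False),
        ("bil_jia", bil, "side", "R", "L"),
        ("control", ctrl, "side", "R", "L"),
    ):
        side_contrasts[arm_name] = {}
        for seg in _SEGMENTS:
            a, b = paired_by_subject(df, seg, col, a_val, b_val)
            side_contrasts[arm_name][seg] = t_test(a, b, paired=True).to_dict()

    # --- normality gates --------------------------------------------------
    normality_flags: List[dict] = []

    def gated(values, label):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = shapiro_gate(values, alpha)
        if res.p < alpha:
            normality_flags.append({"sample": label, "shapiro_p": res.p})
        return values

    # --- four-group ANOVA per segment (table-3 analogue) ------------------
    anova_section: Dict[str, dict] = {}
    for seg in _SEGMENTS:
        groups = [
            gated(_segment_values(uni, seg, affected=True), f"{seg}/uni_aff"),
            gated(_segment_values(uni, seg, affected=False),
                  f"{seg}/uni_unaff"),
            gated(_side_averaged(bil, seg), f"{seg}/bil"),
            gated(_side_averaged(ctrl, seg), f"{seg}/ctrl"),
        ]
        names = ["uni_aff", "uni_unaff", "bil", "ctrl"]
        res = oneway_anova(groups, names)
        ph = posthoc(groups, posthoc_method, alpha, names)
        anova_section[seg] = {"anova": res.to_dict(), "posthoc": ph.to_dict()}

    tot_groups = [
        gated(_segment_values(uni, "mandible_total"), "total/uni"),
        gated(_segment_values(bil, "mandible_total"), "total/bil"),
        gated(_segment_values(ctrl, "mandible_total"), "total/ctrl"),
    ]
    tot_names = ["uni", "bil", "ctrl"]
    anova_section["mandible_total"] = {
        "anova": oneway_anova(tot_groups, tot_names).to_dict(),
        "posthoc": posthoc(tot_groups, posthoc_method, alpha,
                           tot_names).to_dict(),
    }

    # --- mean/percentage differences (table-4 analogue) -------------------
    group_values = {seg: {
        "uni_aff": _segment_values(uni, seg, affected=True),
        "uni_unaff": _segment_values(uni, seg, affected=False),
        "bil": _side_averaged(bil, seg),
        "ctrl": _side_averaged(ctrl, seg),
    } for seg in _SEGMENTS}
    differences: List[dict] = []
    for seg in _SEGMENTS:
        vals = group_values[seg]
        for ga, gb in _DIFF_PAIRS:
            ma, mb = float(np.mean(vals[ga])), float(np.mean(vals[gb]))
            ref, other = (ma, mb) if ma >= mb else (mb, ma)
            differences.append({
                "segment": seg,
                "contrast": f"{ga}-{gb}",
                "mean_difference": ma - mb,
                "percent_difference": percent_difference(ref, other),
            })
    totals = {
        "uni": float(np.mean(tot_groups[0])),
        "bil": float(np.mean(tot_groups[1])),
        "ctrl": float(np.mean(tot_groups[2])),
    }
    for ga, gb in (("uni", "bil"), ("uni", "ctrl"), ("bil", "ctrl")):
        ma, mb = totals[ga], totals[gb]
        ref, other = (ma, mb) if ma >= mb else (mb, ma)
        differences.append({
            "segment": "mandible_total",
            "contrast": f"{ga}-{gb}",
            "mean_difference": ma - mb,
            "percent_difference": percent_difference(ref, other),
        })

    return StudyReport(
        alpha=alpha,
        compatibility=compatibility,
        side_contrasts=side_contrasts,
        anova=anova_section,
        differences=differences,
        normality_flags=normality_flags,
    )
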