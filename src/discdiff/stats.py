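"""Cohort statistics for post-contrast disc enhancement.

Nonparametric battery matching the study design: two-group comparisons by
Wilcoxon rank-sum (exact permutation p for small samples, normal
approximation with tie correction otherwise), multi-group comparisons by
Kruskal–Wallis followed by Dunn's multiple-comparison z-tests, Spearman
rank correlations, SPSS-style univariate analysis of variance with
partial (Type-III) sums of squares for the multivariate models, a
one-sample t-test for the noise analysis, and a Shapiro–Wilk normality
gate.  All tests are two-sided at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

log = logging.getLogger(__name__)

__all__ = [
    "ALPHA",
    "StatResult",
    "AnovaResult",
    "mc_group",
    "rank_sum_test",
    "kruskal_dunn",
    "spearman",
    "one_sample_t",
    "normality_gate",
    "univariate_anova",
    "run_paper_analyses",
    "PaperReport",
]

#: Two-sided significance level used throughout.
ALPHA = 0.05

#: Maximum number of labelings enumerated by the exact rank-sum test.
_EXACT_ENUM_LIMIT = 500_000


@dataclass
class StatResult:
    test: str
    statistic: float
    p: float
    group_sizes: tuple[int, ...]
    significant: bool
    pairwise: pd.DataFrame | None = None
    note: str = ""


@dataclass
class AnovaResult:
    """Per-variable F and p for one least-squares model."""

    response: str
    table: pd.DataFrame  # index: variable; columns: F, p
    nobs: int

    def f(self, variable: str) -> float:
        return float(self.table.loc[variable, "F"])

    def p(self, variable: str) -> float:
        return float(self.table.loc[variable, "p"])


# ---------------------------------------------------------------------------
# Group construction
# ---------------------------------------------------------------------------

def mc_group(mc_upper: str, mc_lower: str) -> str:
    """Disc-level Modic group from the two endplate types.

    A disc with any type I/II endplate, or type I on one endplate and
    type II on the other, is grouped as ``MCI/II``; otherwise the single
    present type decides (``MCI``/``MCII``); ``MC0`` if both endplates
    are clear.  A type III endplate (absent from the reference cohort)
    gets its own ``MCIII`` label and a warning; callers exclude it from
    the Modic comparison.
    """
    types = {str(mc_upper), str(mc_lower)} - {"0"}
    if not types:
        return "MC0"
    if "III" in types:
        warnings.warn("Modic type III encountered; grouped separately and "
                      "excluded from the MC comparison", stacklevel=2)
        return "MCIII"
    if "I/II" in types or types == {"I", "II"}:
        return "MCI/II"
    return "MCI" if types == {"I"} else "MCII"


# ---------------------------------------------------------------------------
# Rank-based tests
# ---------------------------------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def rank_sum_test(x, y, method: str = "auto") -> StatResult:
    """Two-sided Wilcoxon/Mann–Whitney rank-sum test.

    ``method="exact"`` enumerates every labeling of the pooled sample
    (ties handled through midranks); ``"asymptotic"`` uses the normal
    approximation with tie correction (no continuity correction);
    ``"auto"`` picks the exact test when min(n) <= 8 and the enumeration
    is affordable.  Two identical constant samples give p = 1 by
    convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return StatResult("rank-sum", 0.0, 1.0, (n, m), False,
                          note="all values identical")

    ranks = _midranks(pooled)
    t_obs = ranks[:n].sum()
    expect = n * (n + m + 1) / 2.0

    if method == "auto":
        method = "exact" if (min(n, m) <= 8
                             and math.comb(n + m, min(n, m)) <= _EXACT_ENUM_LIMIT
                             ) else "asymptotic"

    if method == "exact":
        dev_obs = abs(t_obs - expect)
        count = 0
        total = 0
        # Enumerate over the smaller side for speed; the deviation |T - E|
        # is identical whichever group's rank sum is used.
        k = min(n, m)
        e_k = k * (n + m + 1) / 2.0
        tol = 1e-9
        for comb in itertools.combinations(range(n + m), k):
            t = ranks[list(comb)].sum()
            if abs(t - e_k) >= dev_obs - tol:
                count += 1
            total += 1
        p = count / total
        stat = t_obs
    elif method == "asymptotic":
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        p = float(res.pvalue)
        stat = float(res.statistic)
    else:
        raise ValueError("method must be 'auto', 'exact' or 'asymptotic'")
    return StatResult("rank-sum", float(stat), float(min(p, 1.0)), (n, m),
                      p < ALPHA, note=method)


def _tie_term(ranks_source: np.ndarray) -> float:
    """Sum of (t^3 - t) over tie groups of the pooled sample."""
    _, counts = np.unique(ranks_source, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_dunn(groups, labels=None, gate_omnibus: bool = True) -> StatResult:
    """Kruskal–Wallis omnibus test with Dunn's pairwise follow-up.

    ``groups`` is a sequence of samples (or a mapping label -> sample).
    The omnibus H uses the tie-corrected chi-square approximation; Dunn's
    z statistics compare mean ranks with the pooled-variance standard
    error (tie-corrected) and a Bonferroni-style adjustment over the
    k(k-1)/2 pairs.  With ``gate_omnibus`` (the pipeline's decision
    logic) no pair is declared significant unless the omnibus test is.
    """
    if isinstance(groups, dict):
        labels = list(groups.keys())
        samples = [np.asarray(g, dtype=float) for g in groups.values()]
    else:
        samples = [np.asarray(g, dtype=float) for g in groups]
        if labels is None:
            labels = [f"group{i}" for i in range(len(samples))]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    sizes = [len(s) for s in samples]
    if any(sz == 0 for sz in sizes):
        raise ValueError("every group must be non-empty")

    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        h_stat, p_omni = 0.0, 1.0
    else:
        h_stat, p_omni = sps.kruskal(*samples)

    ranks = _midranks(pooled)
    big_n = len(pooled)
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start:start + sz].mean())
        start += sz
    tie = _tie_term(pooled)
    var_unit = big_n * (big_n + 1) / 12.0 - tie / (12.0 * (big_n - 1))

    n_pairs = len(samples) * (len(samples) - 1) // 2
    rows = []
    omnibus_sig = p_omni < ALPHA
    for (i, j) in itertools.combinations(range(len(samples)), 2):
        se = math.sqrt(var_unit * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = abs(mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_adj = min(1.0, n_pairs * 2.0 * sps.norm.sf(z))
        sig = p_adj < ALPHA and (omnibus_sig or not gate_omnibus)
        rows.append({
            "group1": labels[i], "group2": labels[j],
            "mean_rank1": mean_ranks[i], "mean_rank2": mean_ranks[j],
            "z": z, "p_adj": p_adj, "significant": sig,
        })
    pairwise = pd.DataFrame(rows)
    return StatResult("kruskal-wallis+dunn", float(h_stat), float(p_omni),
                      tuple(sizes), omnibus_sig, pairwise=pairwise)


def spearman(x, y) -> StatResult:
    """Spearman rank-order correlation (midranks for ties, t-approx p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in ranks: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return StatResult("spearman", float(rho), float(p), (len(x),), p < ALPHA)


def one_sample_t(values, mu0: float = 0.0) -> StatResult:
    """Classical one-sample t-test against ``mu0`` (two-sided)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need n >= 2")
    if np.ptp(v) == 0:
        # degenerate sample: identically mu0 -> t = 0, p = 1; otherwise
        # infinitely far from mu0 in t units.
        if v[0] == mu0:
            return StatResult("one-sample-t", 0.0, 1.0, (len(v),), False,
                              note="zero variance at mu0")
        return StatResult("one-sample-t", math.inf, 0.0, (len(v),), True,
                          note="zero variance away from mu0")
    t, p = sps.ttest_1samp(v, mu0)
    return StatResult("one-sample-t", float(t), float(p), (len(v),), p < ALPHA)


def normality_gate(values) -> StatResult | None:
    """Shapiro–Wilk test; the pipeline records it and stays nonparametric.

    Returns None (gate skipped, with a warning) when n is outside
    [3, 5000].  A significant result (p < 0.05) marks the sample as
    non-normal.
    """
    v = np.asarray(values, dtype=float)
    if not 3 <= len(v) <= 5000:
        warnings.warn(f"normality gate skipped: n={len(v)} outside [3, 5000]",
                      stacklevel=2)
        return None
    if np.ptp(v) == 0:
        raise ValueError("constant sample: Shapiro-Wilk undefined")
    w, p = sps.shapiro(v)
    return StatResult("shapiro-wilk", float(w), float(p), (len(v),), p < ALPHA)


# ---------------------------------------------------------------------------
# Univariate (multivariable) analysis of variance
# ---------------------------------------------------------------------------

def univariate_anova(
    data: pd.DataFrame,
    response: str,
    covariates: list[str],
    categorical: tuple[str, ...] = (),
) -> AnovaResult:
    """Least-squares model with per-variable partial (Type-III) F tests.

    Continuous covariates enter linearly; names listed in ``categorical``
    become sum-to-zero-coded factors.  Raises on missing values and on a
    rank-deficient design, naming the aliased columns.
    """
    cols = [response] + list(covariates)
    df = data[cols]
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}")
    df = df.copy()
    # booleans as 0/1 numerics unless declared categorical
    for c in covariates:
        if df[c].dtype == bool and c not in categorical:
            df[c] = df[c].astype(int)

    terms = [f"C({c}, Sum)" if c in categorical else c for c in covariates]
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify aliased columns via the QR diagonal
        _, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        aliased = [model.exog_names[i] for i in np.nonzero(
            diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    fit = model.fit()
    tbl = anova_lm(fit, typ=3)
    tbl = tbl.drop(index=[i for i in ("Intercept", "Residual") if i in tbl.index])
    out = pd.DataFrame({"F": tbl["F"], "p": tbl["PR(>F)"]})
    # map the patsy term names back to the covariate names
    renames = {f"C({c}, Sum)": c for c in categorical}
    out = out.rename(index=renames)
    return AnovaResult(response=response, table=out, nobs=int(fit.nobs))


# ---------------------------------------------------------------------------
# The full battery
# ---------------------------------------------------------------------------

@dataclass
class PaperReport:
    """Structured output of the full statistical battery."""

    tests: pd.DataFrame
    pairwise: pd.DataFrame
    anova: pd.DataFrame
    notes: list[str] = field(default_factory=list)

    def lookup(self, family: str, time: str | None = None) -> pd.DataFrame:
        sel = self.tests[self.tests["family"] == family]
        if time is not None:
            sel = sel[sel["time"] == time]
        return sel


def _central_wide(table: pd.DataFrame) -> pd.DataFrame:
    """disc_id x time matrix of central-disc enhancement."""
    cen = table[table["roi"] == "Central"]
    return cen.pivot(index="disc_id", columns="time", values="enhancement")


def run_paper_analyses(
    table: pd.DataFrame,
    quant: pd.DataFrame,
    meta: pd.DataFrame,
    timecurve_subset: list[str] | None = None,
) -> PaperReport:
    """Execute the full cohort battery and return a structured report.

    Parameters
    ----------
    table : tidy enhancement table (disc_id, roi, time, enhancement, ...).
    quant : per-disc frame with a ``csf_adj_t2`` column.
    meta : cohort metadata (pfirrmann, mc_*, defect_*, irregular, age,
        height_mm) keyed by disc_id.
    timecurve_subset : disc ids with defect-free endplates for the
        ROI-profile comparisons; defaults to the rule-based selection.
    """
    from .segmentation import select_timecurve_subset

    meta = meta.set_index("disc_id", drop=False)
    quant = quant.set_index("disc_id") if "disc_id" in quant.columns else quant
    central = _central_wide(table)
    times = [t for t in table["time"].unique()]
    # preserve acquisition order
    order = {t: i for i, t in enumerate(
        table.drop_duplicates("time")["time"])}
    times.sort(key=order.get)

    merged = central.join(meta, how="inner").join(
        quant[["csf_adj_t2"]], how="left")
    merged["mc_grp"] = [mc_group(u, l) for u, l in
                        zip(merged["mc_upper"], merged["mc_lower"])]
    merged["any_mc"] = merged["mc_grp"] != "MC0"
    merged["any_defect"] = (merged["defect_upper"].astype(bool)
                            | merged["defect_lower"].astype(bool))

    rows = []
    pair_rows = []
    anova_rows = []
    notes: list[str] = []

    def add(family, name, time, res: StatResult | None, extra=None):
        if res is None:
            return
        rows.append({
            "family": family, "name": name, "time": time,
            "test": res.test, "statistic": res.statistic, "p": res.p,
            "significant": res.significant,
            "n": int(sum(res.group_sizes)), **(extra or {}),
        })
        if res.pairwise is not None:
            for _, pr in res.pairwise.iterrows():
                pair_rows.append({"family": family, "name": name,
                                  "time": time, **pr.to_dict()})

    # --- normality gate (recorded; battery is nonparametric regardless) ---
    for t in times:
        vals = merged[t].dropna()
        if len(vals) >= 3:
            add("normality", "central enhancement", t, normality_gate(vals))

    # --- ROI time-curve comparisons on the defect-free subset ---
    if timecurve_subset is None:
        timecurve_subset = select_timecurve_subset(meta)
    sub_tab = table[table["disc_id"].isin(timecurve_subset)]
    if len(timecurve_subset) >= 2:
        for roi in sub_tab["roi"].unique():
            r_tab = sub_tab[sub_tab["roi"] == roi].pivot(
                index="disc_id", columns="time", values="enhancement")
            for t0, t1 in zip(times[:-1], times[1:]):
                if t0 in r_tab and t1 in r_tab:
                    res = rank_sum_test(r_tab[t1].dropna(), r_tab[t0].dropna(),
                                        method="asymptotic")
                    add("timecurve", f"{roi}: {t1} vs {t0}", t1, res)
    else:
        notes.append("time-curve subset too small; ROI comparisons skipped")

    # --- Pfirrmann groups on central enhancement ---
    for t in times:
        grp = {g: merged.loc[merged["pfirrmann"] == g, t].dropna().values
               for g in sorted(merged["pfirrmann"].unique())}
        grp = {g: v for g, v in grp.items() if len(v) >= 2}
        if len(grp) >= 3:
            add("pfirrmann", "central enhancement by grade", t,
                kruskal_dunn({f"P{g}": v for g, v in grp.items()}))
        else:
            notes.append(f"pfirrmann comparison at {t} skipped (empty groups)")

    # --- CSF-adjusted T2 by Pfirrmann grade ---
    if merged["csf_adj_t2"].notna().any():
        grp = {f"P{g}": merged.loc[merged["pfirrmann"] == g, "csf_adj_t2"]
               .dropna().values for g in sorted(merged["pfirrmann"].unique())}
        grp = {g: v for g, v in grp.items() if len(v) >= 2}
        if len(grp) >= 3:
            add("csf_t2", "csf-adjusted T2 by grade", None, kruskal_dunn(grp))

    # --- Spearman correlations of central enhancement ---
    low_med = merged[merged["pfirrmann"].isin([1, 2, 3])]
    for t in times:
        for var in ("csf_adj_t2", "age", "height_mm"):
            for label, frame in (("all discs", merged),
                                 ("pfirrmann 1-3", low_med)):
                d = frame[[t, var]].dropna()
                if len(d) >= 3 and np.ptp(d[var].values) > 0:
                    add("correlation", f"enhancement vs {var} ({label})", t,
                        spearman(d[var].values, d[t].values))
    for var in ("age", "height_mm"):
        d = merged[["csf_adj_t2", var]].dropna()
        if len(d) >= 3:
            add("correlation", f"csf_adj_t2 vs {var}", None,
                spearman(d[var].values, d["csf_adj_t2"].values))

    # --- Modic changes ---
    mc_ok = merged[merged["mc_grp"] != "MCIII"]
    for t in times:
        with_mc = mc_ok.loc[mc_ok["any_mc"], t].dropna()
        without = mc_ok.loc[~mc_ok["any_mc"], t].dropna()
        if len(with_mc) >= 2 and len(without) >= 2:
            add("mc_any", "any MC vs none", t,
                rank_sum_test(with_mc, without, method="asymptotic"))
        grp = {g: mc_ok.loc[mc_ok["mc_grp"] == g, t].dropna().values
               for g in ("MC0", "MCI", "MCII", "MCI/II")}
        grp = {g: v for g, v in grp.items() if len(v) >= 2}
        if len(grp) >= 3:
            add("mc_type", "enhancement by MC type", t, kruskal_dunn(grp))

    # --- Endplate defects and irregular endplates ---
    severe = merged[merged["pfirrmann"].isin([4, 5])]
    for t in times:
        a = merged.loc[merged["any_defect"], t].dropna()
        b = merged.loc[~merged["any_defect"], t].dropna()
        if len(a) >= 2 and len(b) >= 2:
            add("defect", "any endplate defect vs none", t,
                rank_sum_test(a, b, method="asymptotic"))
        a = merged.loc[merged["irregular"].astype(bool), t].dropna()
        b = merged.loc[~merged["irregular"].astype(bool), t].dropna()
        if len(a) >= 2 and len(b) >= 2:
            add("irregular", "irregular endplate vs rest", t,
                rank_sum_test(a, b, method="asymptotic"))
        a = severe.loc[severe["irregular"].astype(bool), t].dropna()
        b = severe.loc[~severe["irregular"].astype(bool), t].dropna()
        if len(a) >= 2 and len(b) >= 2:
            add("irregular_severe", "irregular vs other severely degenerated",
                t, rank_sum_test(a, b, method="asymptotic"))

    # --- Multivariate models (three covariate sets per late time point) ---
    model_sets = {
        "grade": ["height_mm", "any_defect", "any_mc", "pfirrmann"],
        "csf_t2": ["height_mm", "any_defect", "any_mc", "csf_adj_t2"],
        "irregular": ["height_mm", "irregular", "any_mc", "pfirrmann"],
    }
    for t in ("POST_2H", "POST_4H", "POST_6H"):
        if t not in merged:
            continue
        for set_name, covs in model_sets.items():
            d = merged[[t] + covs].dropna().copy()
            d = d.rename(columns={t: "enh"})
            if len(d) <= len(covs) + 1:
                continue
            try:
                res = univariate_anova(d, "enh", covs)
            except ValueError as exc:
                notes.append(f"anova {set_name} at {t} failed: {exc}")
                continue
            for var in res.table.index:
                anova_rows.append({
                    "model": set_name, "time": t, "variable": var,
                    "F": res.f(var), "p": res.p(var),
                    "significant": res.p(var) < ALPHA, "n": res.nobs,
                })

    # --- noise analysis: early central enhancement of healthy discs ---
    if "POST_5MIN" in merged:
        noise_vals = merged.loc[merged["pfirrmann"].isin([1, 2]),
                                "POST_5MIN"].dropna()
        if len(noise_vals) >= 2:
            res = one_sample_t(noise_vals, 0.0)
            add("noise", "central POST_5MIN in grade 1-2 vs 0", "POST_5MIN",
                res, extra={"mean": float(noise_vals.mean()),
                            "sd": float(noise_vals.std(ddof=1))})

    tests = pd.DataFrame(rows)
    pairwise = pd.DataFrame(pair_rows)
    anova = pd.DataFrame(anova_rows)
    return PaperReport(tests=tests, pairwise=pairwise, anova=anova, notes=notes)
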