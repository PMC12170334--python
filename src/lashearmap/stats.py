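"""Per-case statistics: correlations, TAWSS quartiles, fibrosis prevalence.

The analysis plan mirrors standard practice in electro-structural atrial
studies: Pearson correlations per case between the hemodynamic indices and
the clinical fields (bipolar voltage BV, image intensity ratio IIR, blood
age BA); TAWSS quartile summaries with Kruskal-Wallis tests; a pooled
quartile x fibrosis-flag chi-square; Fisher-z comparison of correlation
coefficients between groups; and a normality-driven choice between ANOVA,
Welch's ANOVA and Kruskal-Wallis.  Significance is two-sided at 0.05 with
no multiplicity correction.  Vertices are treated as observations, which
pseudo-replicates within a case; regional or case-level summaries should be
preferred for inference across cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.oneway import anova_oneway

DEFAULT_PAIRS = (
    ("TAWSS", "BV"),
    ("TAWSS", "IIR"),
    ("TAWSS", "BA"),
    ("BA", "BV"),
    ("BV", "IIR"),
)

IIR_FIBROSIS_THRESHOLD = 1.2  # inclusive: IIR >= 1.2 flags fibrosis
BV_SCAR_THRESHOLD_MV = 0.5  # strict: BV < 0.5 mV flags electrical scar


@dataclass
class FibrosisLabels:
    fibrosis: np.ndarray  # bool, IIR-based
    scar: np.ndarray  # bool, BV-based
    iir_threshold: float
    bv_threshold_mv: float
    defined_fibrosis: np.ndarray = None
    defined_scar: np.ndarray = None

    def counts(self) -> dict:
        return {
            "fibrosis": int(self.fibrosis[self.defined_fibrosis].sum()),
            "scar": int(self.scar[self.defined_scar].sum()),
            "n_fibrosis_defined": int(self.defined_fibrosis.sum()),
            "n_scar_defined": int(self.defined_scar.sum()),
        }


def per_case_correlations(case_table: pd.DataFrame, pairs=DEFAULT_PAIRS) -> pd.DataFrame:
    """Pearson r with two-sided p for each variable pair of one case.

    Non-finite entries are deleted pairwise; the retained n is reported.
    Pairs with fewer than 10 complete observations or zero variance get
    NaN r with an explanatory reason column.
    """
    rows = []
    for a, b in pairs:
        if a not in case_table or b not in case_table:
            rows.append((a, b, np.nan, np.nan, 0, f"missing column {a if a not in case_table else b}"))
            continue
        x = case_table[a].to_numpy(dtype=float)
        y = case_table[b].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        if n < 10:
            rows.append((a, b, np.nan, np.nan, n, "fewer than 10 paired values"))
            continue
        if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            rows.append((a, b, np.nan, np.nan, n, "zero variance"))
            continue
        r, p = sps.pearsonr(x[ok], y[ok])
        rows.append((a, b, float(r), float(p), n, ""))
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "p", "n", "reason"])


def assign_quartiles(values: np.ndarray) -> np.ndarray:
    """Quartile index 1..4 by the empirical 25/50/75 percentiles.

    Values equal to a cut point go to the lower quartile; non-finite values
    get 0.  Heavy ties can collapse a quartile; the assignment is kept and
    it is the caller's business to note it.
    """
    values = np.asarray(values, dtype=float)
    out = np.zeros(len(values), dtype=np.int64)
    ok = np.isfinite(values)
    cuts = np.percentile(values[ok], [25, 50, 75])
    out[ok] = 1 + np.searchsorted(cuts, values[ok], side="left")
    return out


def quartile_analysis(
    case_table: pd.DataFrame, by: str = "TAWSS", responses=("BV", "IIR", "BA")
) -> dict:
    """Quartile the stratifying variable and summarize the responses.

    Returns per-quartile summaries (n, mean, SD, median, IQR) and a
    two-sided Kruskal-Wallis p across the four quartiles for each response.
    """
    if by not in case_table:
        raise ValueError(f"column {by!r} not in case table")
    q = assign_quartiles(case_table[by].to_numpy(dtype=float))
    summaries = {}
    tests = {}
    for resp in responses:
        if resp not in case_table:
            continue
        y = case_table[resp].to_numpy(dtype=float)
        rows = []
        groups = []
        for k in (1, 2, 3, 4):
            g = y[(q == k) & np.isfinite(y)]
            groups.append(g)
            if len(g):
                q1, med, q3 = np.percentile(g, [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            rows.append(
                {
                    "quartile": k,
                    "n": len(g),
                    "mean": g.mean() if len(g) else np.nan,
                    "sd": g.std(ddof=1) if len(g) > 1 else np.nan,
                    "median": med,
                    "iqr": q3 - q1,
                }
            )
        summaries[resp] = pd.DataFrame(rows)
        nonempty = [g for g in groups if len(g)]
        if len(nonempty) >= 2 and any(np.ptp(g) > 0 for g in nonempty):
            stat, p = sps.kruskal(*nonempty)
        else:
            stat, p = 0.0, 1.0
        tests[resp] = {"test": "kruskal-wallis", "statistic": float(stat), "p": float(p)}
    return {"quartile": q, "by": by, "summaries": summaries, "tests": tests}


def classify_fibrosis(
    iir, bv, iir_threshold: float = IIR_FIBROSIS_THRESHOLD,
    bv_threshold_mv: float = BV_SCAR_THRESHOLD_MV,
) -> FibrosisLabels:
    """Flag fibrosis (IIR >= threshold, inclusive) and electrical scar
    (BV < threshold, strict), per the standard diagnostic criteria."""
    iir_v = np.asarray(getattr(iir, "values", iir), dtype=float)
    bv_v = np.asarray(getattr(bv, "values", bv), dtype=float)
    if len(iir_v) != len(bv_v):
        raise ValueError("IIR and BV must live on the same mesh")
    def_i = np.isfinite(iir_v)
    def_b = np.isfinite(bv_v)
    return FibrosisLabels(
        fibrosis=def_i & (iir_v >= iir_threshold),
        scar=def_b & (bv_v < bv_threshold_mv),
        iir_threshold=iir_threshold,
        bv_threshold_mv=bv_threshold_mv,
        defined_fibrosis=def_i,
        defined_scar=def_b,
    )


def pooled_quartile_chisq(flags: np.ndarray, quartiles: np.ndarray) -> dict:
    """4x2 chi-square (quartile x flag), no continuity correction.

    ``flags`` and ``quartiles`` are pooled over cases; quartile 0 entries
    (undefined) are excluded.  Returns the statistic, df, two-sided p and
    the per-quartile prevalence.
    """
    flags = np.asarray(flags, dtype=bool)
    quartiles = np.asarray(quartiles)
    ok = quartiles > 0
    flags, quartiles = flags[ok], quartiles[ok]
    table = np.zeros((4, 2), dtype=np.int64)
    for k in (1, 2, 3, 4):
        sel = quartiles == k
        if not sel.any():
            raise ValueError(f"quartile {k} is empty")
        table[k - 1] = [int(flags[sel].sum()), int((~flags[sel]).sum())]
    res = sps.chi2_contingency(table, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn("chi-square expected counts below 5", stacklevel=2)
    prevalence = table[:, 0] / table.sum(axis=1)
    return {
        "statistic": float(res.statistic),
        "df": int(res.dof),
        "p": float(res.pvalue),
        "table": table,
        "prevalence": prevalence,
    }


def compare_correlations_fisher(group_a, group_b) -> dict:
    """Compare two groups of per-case correlation coefficients.

    Each r is variance-stabilized with Fisher's z = atanh(r); the group
    means of z are compared with Welch's two-sample t test (two-sided).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 correlations per group")
    if (np.abs(a) >= 1).any() or (np.abs(b) >= 1).any():
        raise ValueError("|r| = 1 cannot be Fisher-z transformed")
    za, zb = np.arctanh(a), np.arctanh(b)
    t, p = sps.ttest_ind(za, zb, equal_var=False)
    return {"t": float(t), "p": float(p), "z_mean_a": float(za.mean()), "z_mean_b": float(zb.mean())}


def auto_test_selection(groups, alpha: float = 0.05) -> dict:
    """Normality-driven omnibus test selection across >= 2 groups.

    Shapiro-Wilk per group: any non-normal -> Kruskal-Wallis.  Otherwise
    Levene: equal variances -> one-way ANOVA; unequal -> Welch's ANOVA.
    The decision trail is returned alongside the chosen test's result.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 3 for g in groups):
        raise ValueError("need >= 2 groups with >= 3 observations each")
    trail = []
    try:
        sw = [sps.shapiro(g).pvalue for g in groups]
        trail.append({"step": "shapiro-wilk", "p": [float(p) for p in sw]})
        normal = all(p >= alpha for p in sw)
    except ValueError:
        warnings.warn("Shapiro-Wilk unavailable for these sizes; using Kruskal-Wallis", stacklevel=2)
        normal = False
        trail.append({"step": "shapiro-wilk", "p": None})
    if not normal:
        stat, p = sps.kruskal(*groups)
        chosen = "kruskal-wallis"
    else:
        lev = sps.levene(*groups)
        trail.append({"step": "levene", "p": float(lev.pvalue)})
        if lev.pvalue >= alpha:
            stat, p = sps.f_oneway(*groups)
            chosen = "anova"
        else:
            res = anova_oneway(groups, use_var="unequal", welch_correction=True)
            stat, p = res.statistic, res.pvalue
            chosen = "welch-anova"
    return {"test": chosen, "statistic": float(stat), "p": float(p), "trail": trail}


@dataclass
class CaseResult:
    """Full per-case analysis bundle."""

    case_id: str
    table: pd.DataFrame
    correlations: pd.DataFrame
    quartiles: dict
    fibrosis: FibrosisLabels
    chisq_fibrosis: dict = None
    chisq_scar: dict = None
    meta: dict = field(default_factory=dict)


def analyze_case(case_id: str, table: pd.DataFrame) -> CaseResult:
    """Run the whole per-case plan on a vertex table with columns among
    TAWSS, OSI, ECAP, RRT, HOLMES, WSSG, BA, BV, IIR."""
    corr = per_case_correlations(table)
    quart = quartile_analysis(table)
    fib = classify_fibrosis(
        table["IIR"].to_numpy() if "IIR" in table else np.full(len(table), np.nan),
        table["BV"].to_numpy() if "BV" in table else np.full(len(table), np.nan),
    )
    q = quart["quartile"]

    def guarded_chisq(flags, defined):
        # a flag with zero variance gives a degenerate contingency table
        if not defined.any() or flags[defined].all() or not flags[defined].any():
            return None
        return pooled_quartile_chisq(flags[defined], q[defined])

    chis_f = guarded_chisq(fib.fibrosis, fib.defined_fibrosis)
    chis_s = guarded_chisq(fib.scar, fib.defined_scar)
    return CaseResult(
        case_id=case_id,
        table=table,
        correlations=corr,
        quartiles=quart,
        fibrosis=fib,
        chisq_fibrosis=chis_f,
        chisq_scar=chis_s,
        meta={"n_vertices": len(table)},
    )
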