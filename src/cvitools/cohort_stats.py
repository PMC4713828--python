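"""Paired cohort statistics for per-eye metric tables.

The battery mirrors common longitudinal ophthalmic practice: paired
Wilcoxon signed-rank tests between visits, Welch/paired t-tests and
one-way ANOVA (with R^2 = SS_between / SS_total) between groups, group
summaries as mean +/- sample sd with range, and percent-change
comparisons.  P-values are two-sided throughout and no multiple-testing
correction is applied (a deliberate caveat: each comparison is reported
at its nominal level).

The signed-rank test follows the drop-zeros convention: zero differences
are discarded, ties in |d| get average ranks, the statistic is
W = min(W+, W-), and the null distribution is exact (full convolution
over sign assignments, honouring tied ranks) for n <= 25, with a
normal approximation including continuity and tie corrections above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

NAN = float("nan")

GROUPS = ("study", "control")
VISITS = ("baseline", "followup")


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_effective: int
    extra: dict = field(default_factory=dict)


def _exact_signedrank_pmf(ranks2: np.ndarray) -> np.ndarray:
    """Null pmf of 2*W+ by dynamic-programming convolution over signs.

    ``ranks2`` are the doubled ranks (integers even with average-rank
    ties).  Entry j of the result is P(2*W+ = j) under random signs.
    """
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[:-r] if r else pmf
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_signed_rank(pairs) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on (baseline, followup) pairs.

    Exact p for n_effective <= 25 (valid with tied ranks); otherwise a
    normal approximation with continuity correction and the tie term
    sum(t^3 - t)/48 removed from the variance.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim == 1:  # allow passing precomputed differences
        d = arr
    else:
        d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; signed-rank p set to 1", stacklevel=2)
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, 0)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    if n <= 25:
        ranks2 = np.rint(2 * ranks).astype(int)
        pmf = _exact_signedrank_pmf(ranks2)
        cdf = np.cumsum(pmf)
        j = int(round(2 * w_plus))
        p_le = float(cdf[j])
        p_ge = float(1.0 - (cdf[j - 1] if j > 0 else 0.0))
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mn = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(((counts**3 - counts)).sum()) / 48.0
        se = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_plus - mn - 0.5 * np.sign(w_plus - mn)) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult("wilcoxon_signed_rank", w, min(p, 1.0), n)


def t_tests(a, b, paired: bool = False) -> TestResult:
    """Paired t-test or Welch two-sample t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and a.shape != b.shape:
        raise ValueError("paired t-test needs equal-length samples")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-tests need at least 2 observations per sample")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():  # identical constants: no evidence of difference
            return TestResult("t_paired" if paired else "t_welch", 0.0, 1.0,
                              len(a) if paired else len(a) + len(b))
        warnings.warn("zero variance in both samples; t-test p undefined", stacklevel=2)
        return TestResult("t_paired" if paired else "t_welch", NAN, NAN,
                          len(a) if paired else len(a) + len(b))
    if paired:
        if (a == b).all():  # identical samples: no difference, by convention t = 0, p = 1
            return TestResult("t_paired", 0.0, 1.0, len(a))
        res = stats.ttest_rel(a, b)
        return TestResult("t_paired", float(res.statistic), float(res.pvalue), len(a))
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult("t_welch", float(res.statistic), float(res.pvalue), len(a) + len(b))


def one_way_anova(groups) -> TestResult:
    """One-way ANOVA across >= 2 groups, with R^2 = SS_between / SS_total."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 1 value each")
    n_total = sum(len(g) for g in groups)
    if n_total <= len(groups):
        raise ValueError("ANOVA needs more observations than groups")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    if ss_total == 0:
        warnings.warn("all values identical; ANOVA F undefined, R^2 = 0", stacklevel=2)
        return TestResult("anova_oneway", NAN, NAN, n_total, {"R2": 0.0})
    f, p = stats.f_oneway(*groups)
    return TestResult("anova_oneway", float(f), float(p), n_total,
                      {"R2": ss_between / ss_total})


@dataclass
class PairedCohortTable:
    """Long-format per-eye metric table.

    Columns: ``eye_id`` (str), ``group`` (study/control), ``visit``
    (baseline/followup), ``metric`` (str), ``value`` (float).  Each
    (eye_id, visit, metric) combination appears at most once.
    """

    data: pd.DataFrame

    REQUIRED = ("eye_id", "group", "visit", "metric", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing column(s): {missing}")
        dup = self.data.duplicated(subset=["eye_id", "visit", "metric"])
        if dup.any():
            first = self.data[dup].iloc[0]
            raise ValueError(
                f"duplicate entry for eye {first['eye_id']!r}, visit {first['visit']!r}, "
                f"metric {first['metric']!r}"
            )

    @classmethod
    def from_records(cls, records) -> "PairedCohortTable":
        return cls(pd.DataFrame.from_records(records, columns=list(cls.REQUIRED)))

    @classmethod
    def from_metrics_frames(cls, frames: dict[tuple[str, str], pd.DataFrame]) -> "PairedCohortTable":
        """Build from wide metric frames keyed by (group, visit).

        Each frame needs an ``eye_id`` column; every other numeric column
        is treated as a metric.
        """
        rows = []
        for (group, visit), df in frames.items():
            melted = df.melt(id_vars=["eye_id"], var_name="metric", value_name="value")
            melted["group"], melted["visit"] = group, visit
            rows.append(melted[list(cls.REQUIRED)])
        return cls(pd.concat(rows, ignore_index=True))

    def select(self, metric: str, group: str | None = None, visit: str | None = None) -> pd.DataFrame:
        df = self.data[self.data["metric"] == metric]
        if group is not None:
            df = df[df["group"] == group]
        if visit is not None:
            df = df[df["visit"] == visit]
        return df

    def paired_values(self, metric: str, group: str) -> tuple[np.ndarray, np.ndarray]:
        """(baseline, followup) arrays aligned on eye_id; unpaired eyes dropped."""
        base = self.select(metric, group, "baseline").set_index("eye_id")["value"]
        foll = self.select(metric, group, "followup").set_index("eye_id")["value"]
        common = base.index.intersection(foll.index)
        return base.loc[common].to_numpy(), foll.loc[common].to_numpy()


def summarize(table: PairedCohortTable, metric: str, group: str, visit: str):
    """(mean, sample sd, min, max) of one metric/group/visit cell."""
    vals = table.select(metric, group, visit)["value"].to_numpy(dtype=float)
    if len(vals) == 0:
        raise ValueError(f"no rows for metric={metric!r}, group={group!r}, visit={visit!r}")
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else NAN
    return float(vals.mean()), sd, float(vals.min()), float(vals.max())


def percent_changes(table: PairedCohortTable, metric: str, group: str) -> np.ndarray:
    """Per-eye percent change 100*(baseline - followup)/baseline for one group."""
    from .choroid_metrics import percent_change

    base, foll = table.paired_values(metric, group)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vals = np.array([percent_change(b, f) for b, f in zip(base, foll)])
    return vals[~np.isnan(vals)]


def cohort_battery(table: PairedCohortTable) -> pd.DataFrame:
    """The full comparison battery as a tidy frame.

    For every metric present: per-group baseline-vs-followup signed-rank
    test; between-group Welch t and ANOVA (with R^2) at each visit; and a
    between-group Welch t on percent changes when both groups are paired.
    Output columns: metric, group, comparison, method, statistic, p, R2.
    """
    rows = []

    def add(metric, group, comparison, res: TestResult):
        rows.append({
            "metric": metric, "group": group, "comparison": comparison,
            "method": res.method, "statistic": res.statistic, "p": res.p_value,
            "R2": res.extra.get("R2", NAN),
        })

    for metric in sorted(table.data["metric"].unique()):
        groups_present = [g for g in GROUPS if not table.select(metric, g).empty]
        for group in groups_present:
            base, foll = table.paired_values(metric, group)
            if len(base) >= 1:
                add(metric, group, "baseline_vs_followup", wilcoxon_signed_rank(np.column_stack([base, foll])))
        if len(groups_present) == 2:
            for visit in VISITS:
                a = table.select(metric, "study", visit)["value"].to_numpy(dtype=float)
                b = table.select(metric, "control", visit)["value"].to_numpy(dtype=float)
                if len(a) >= 2 and len(b) >= 2:
                    add(metric, "both", f"study_vs_control_{visit}", t_tests(a, b))
                    add(metric, "both", f"study_vs_control_{visit}", one_way_anova([a, b]))
            pc_s = percent_changes(table, metric, "study")
            pc_c = percent_changes(table, metric, "control")
            if len(pc_s) >= 2 and len(pc_c) >= 2:
                add(metric, "both", "pct_change_study_vs_control", t_tests(pc_s, pc_c))
    return pd.DataFrame(rows, columns=["metric", "group", "comparison", "method",
                                       "statistic", "p", "R2"])


def read_study_spreadsheet(path, sheet=0) -> PairedCohortTable:
    """Load a deposited per-eye spreadsheet (.xlsx) into a cohort table.

    Accepts either the long format (columns eye_id/group/visit/metric/value,
    case-insensitive) or a wide format with an ``eye_id`` column, an
    optional ``group``/``visit`` column pair, and one column per metric.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    if set(PairedCohortTable.REQUIRED) <= set(df.columns):
        return PairedCohortTable(df[list(PairedCohortTable.REQUIRED)])
    if "eye_id" not in df.columns:
        raise ValueError(f"{path}: no eye_id column; cannot map spreadsheet to cohort table")
    id_vars = [c for c in ("eye_id", "group", "visit") if c in df.columns]
    melted = df.melt(id_vars=id_vars, var_name="metric", value_name="value")
    if "group" not in melted.columns:
        melted["group"] = "study"
    if "visit" not in melted.columns:
        melted["visit"] = "baseline"
    return PairedCohortTable(melted[list(PairedCohortTable.REQUIRED)])
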