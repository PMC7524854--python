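"""Cohort-level accuracy statistics.

Per-group mean ± sample SD, Shapiro–Wilk normality checks, pooled-variance
two-sample and paired t-tests with 95% confidence intervals — the analysis
applied to per-patient manual and semi-automatic TREs across the two study
phases. A packaged per-patient TRE table ("table3") ships with the package
for regression testing.

Variant notes, pinned by recomputation from the packaged table:
- SDs are sample SDs (n−1 denominator); the population variant does not
  reproduce the published summaries.
- The between-phase manual comparison uses the *pooled* independent t-test
  (df = n1+n2−2); only this variant reproduces the published CI and p.
- The within-phase-2 manual-vs-semiautomatic contrast is reported both
  paired (by patient) and pooled-independent, since the published interval
  for that contrast is not recoverable from the rounded per-patient values
  under either variant; the estimate is identical under both.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .errors import (
    InsufficientDataError,
    SchemaError,
    UnsupportedSampleSizeError,
)

COHORT_COLUMNS = ["patient_id", "phase", "tre_manual", "tre_semiauto"]


@dataclass(frozen=True)
class CohortRow:
    patient_id: str
    phase: int
    tre_manual_mm: float | None
    tre_semiauto_mm: float | None


@dataclass(frozen=True)
class CohortTable:
    rows: tuple

    def __post_init__(self):
        ids = [r.patient_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise SchemaError("patient_ids must be unique")
        for r in self.rows:
            if r.phase not in (1, 2):
                raise SchemaError(f"{r.patient_id}: phase must be 1 or 2")
            if r.phase == 1 and r.tre_semiauto_mm is not None:
                raise SchemaError(
                    f"{r.patient_id}: phase-1 rows carry no semi-automatic TRE"
                )
            if r.phase == 2 and (r.tre_manual_mm is None or r.tre_semiauto_mm is None):
                raise SchemaError(
                    f"{r.patient_id}: phase-2 rows need both manual and semi-automatic TREs"
                )
        object.__setattr__(self, "rows", tuple(self.rows))

    def phase1_manual(self) -> np.ndarray:
        return np.array([r.tre_manual_mm for r in self.rows if r.phase == 1], float)

    def phase2_manual(self) -> np.ndarray:
        return np.array([r.tre_manual_mm for r in self.rows if r.phase == 2], float)

    def phase2_semiauto(self) -> np.ndarray:
        return np.array([r.tre_semiauto_mm for r in self.rows if r.phase == 2], float)


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean_mm: float
    sd_mm: float  # sample SD, n-1 denominator

    def rounded(self) -> str:
        return f"{self.mean_mm:.1f} ± {self.sd_mm:.1f}"


@dataclass(frozen=True)
class TestResult:
    estimate_mm: float  # mean difference
    ci95_mm: tuple
    t_stat: float
    df: float
    p_two_sided: float
    test_kind: str  # "pooled-independent" | "paired"
    note: str | None = None

    def to_dict(self) -> dict:
        return {
            "estimate_mm": self.estimate_mm,
            "ci95_mm": list(self.ci95_mm),
            "t_stat": self.t_stat,
            "df": self.df,
            "p_two_sided": self.p_two_sided,
            "test_kind": self.test_kind,
            "note": self.note,
            "rounded": {
                "estimate_mm": round(self.estimate_mm, 1),
                "ci95_mm": [round(self.ci95_mm[0], 1), round(self.ci95_mm[1], 1)],
                "p": round(self.p_two_sided, 3),
            },
        }


def summarize(values) -> GroupSummary:
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise InsufficientDataError(f"need >= 2 values for mean ± SD, got {v.size}")
    return GroupSummary(int(v.size), float(v.mean()), float(v.std(ddof=1)))


# -- Shapiro–Wilk (Royston's AS R94 approximation, n in [3, 50]) -------------

def shapiro_wilk(values) -> tuple[float, float]:
    """(W, two-... one-sided p) via Royston's small-sample approximation.

    Implemented from the published algorithm rather than delegated, so the
    test suite can cross-check it against an independent reference
    implementation. Supported for 3 <= n <= 50.
    """
    x = np.sort(np.asarray(list(values), dtype=float))
    n = x.size
    if not (3 <= n <= 50):
        raise UnsupportedSampleSizeError(f"Shapiro–Wilk supported for 3 <= n <= 50, got {n}")
    ss = float(np.sum((x - x.mean()) ** 2))
    if ss <= 0:
        raise InsufficientDataError("zero variance: W undefined")

    m = _stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    ssm = float(np.sum(m * m))
    rsn = 1.0 / np.sqrt(n)
    a = m / np.sqrt(ssm)
    if n > 3:
        an = (
            -2.706056 * rsn**5 + 4.434685 * rsn**4 - 2.071190 * rsn**3
            - 0.147981 * rsn**2 + 0.221157 * rsn + m[-1] / np.sqrt(ssm)
        )
        if n > 5:
            an1 = (
                -3.582633 * rsn**5 + 5.682633 * rsn**4 - 1.752461 * rsn**3
                - 0.293762 * rsn**2 + 0.042981 * rsn + m[-2] / np.sqrt(ssm)
            )
            phi = (ssm - 2 * m[-1] ** 2 - 2 * m[-2] ** 2) / (1 - 2 * an**2 - 2 * an1**2)
            a = m / np.sqrt(phi)
            a[-1], a[-2] = an, an1
            a[0], a[1] = -an, -an1
        else:
            phi = (ssm - 2 * m[-1] ** 2) / (1 - 2 * an**2)
            a = m / np.sqrt(phi)
            a[-1] = an
            a[0] = -an

    W = float(np.dot(a, x) ** 2 / ss)
    W = min(W, 1.0)

    if n == 3:
        p = 6.0 / np.pi * (np.arcsin(np.sqrt(W)) - np.arcsin(np.sqrt(0.75)))
        p = float(np.clip(p, 0.0, 1.0))
    elif n <= 11:
        g = -2.273 + 0.459 * n
        mu = 0.5440 - 0.39978 * n + 0.025054 * n**2 - 0.0006714 * n**3
        sigma = np.exp(1.3822 - 0.77857 * n + 0.062767 * n**2 - 0.0020322 * n**3)
        z = (-np.log(g - np.log1p(-W)) - mu) / sigma
        p = float(_stats.norm.sf(z))
    else:
        ln_n = np.log(n)
        mu = -1.5861 - 0.31082 * ln_n - 0.083751 * ln_n**2 + 0.0038915 * ln_n**3
        sigma = np.exp(-0.4803 - 0.082676 * ln_n + 0.0030302 * ln_n**2)
        z = (np.log1p(-W) - mu) / sigma
        p = float(_stats.norm.sf(z))
    return W, p


# -- t-tests -----------------------------------------------------------------

def two_sample_t_pooled(a, b) -> TestResult:
    """Pooled-variance independent two-sample t-test, df = n1 + n2 − 2."""
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    diff = float(a.mean() - b.mean())
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    se = float(np.sqrt(sp2 * (1 / a.size + 1 / b.size)))
    if se == 0.0:
        if diff == 0.0:
            return TestResult(0.0, (0.0, 0.0), 0.0, df, 1.0, "pooled-independent")
        return TestResult(
            diff, (diff, diff), float(np.sign(diff)) * np.inf, df, 0.0,
            "pooled-independent", note="zero pooled variance with unequal means",
        )
    t = diff / se
    p = float(2 * _stats.t.sf(abs(t), df))
    tq = float(_stats.t.ppf(0.975, df))
    return TestResult(diff, (diff - tq * se, diff + tq * se), float(t), df, p,
                      "pooled-independent")


def paired_t(a, b) -> TestResult:
    """Paired t-test on per-subject differences a − b, df = n − 1."""
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if a.size != b.size:
        raise SchemaError(f"paired groups must match in length ({a.size} vs {b.size})")
    if a.size < 2:
        raise InsufficientDataError("need >= 2 pairs")
    d = a - b
    est = float(d.mean())
    df = d.size - 1
    se = float(d.std(ddof=1) / np.sqrt(d.size))
    if se == 0.0:
        if est == 0.0:
            return TestResult(0.0, (0.0, 0.0), 0.0, df, 1.0, "paired")
        return TestResult(est, (est, est), float(np.sign(est)) * np.inf, df, 0.0,
                          "paired", note="zero difference variance with nonzero mean")
    t = est / se
    p = float(2 * _stats.t.sf(abs(t), df))
    tq = float(_stats.t.ppf(0.975, df))
    return TestResult(est, (est - tq * se, est + tq * se), float(t), df, p, "paired")


# -- whole-cohort report -----------------------------------------------------

def analyze_cohort(table: CohortTable) -> dict:
    """Summaries, normality checks and between/within-group tests.

    Between-phase manual comparison: pooled independent t. Phase-2 manual vs
    semi-automatic: both the paired and pooled variants are reported (see the
    module docstring for why). Components that lack data are skipped with an
    explicit notice instead of failing the whole report.
    """
    groups = {
        "phase1_manual": table.phase1_manual(),
        "phase2_manual": table.phase2_manual(),
        "phase2_semiauto": table.phase2_semiauto(),
    }
    report: dict = {"groups": {}, "tests": {}, "notices": []}
    for name, vals in groups.items():
        if vals.size < 2:
            report["notices"].append(f"{name}: n={vals.size} < 2, no summary")
            continue
        s = summarize(vals)
        entry = {
            "n": s.n, "mean_mm": s.mean_mm, "sd_mm": s.sd_mm,
            "rounded": s.rounded(), "values_mm": vals.tolist(),
        }
        try:
            W, p = shapiro_wilk(vals)
            entry["shapiro_wilk"] = {"W": W, "p": p}
        except (UnsupportedSampleSizeError, InsufficientDataError) as e:
            report["notices"].append(f"{name}: Shapiro–Wilk skipped ({e})")
        report["groups"][name] = entry

    p1m, p2m, p2s = groups["phase1_manual"], groups["phase2_manual"], groups["phase2_semiauto"]
    if p1m.size >= 2 and p2m.size >= 2:
        report["tests"]["manual_phase1_vs_phase2_pooled"] = two_sample_t_pooled(
            p1m, p2m
        ).to_dict()
    else:
        report["notices"].append(
            "independent manual phase-1 vs phase-2 test skipped: a phase is missing"
        )
    if p2m.size >= 2 and p2s.size >= 2:
        if p2m.size == p2s.size:
            report["tests"]["phase2_manual_vs_semiauto_paired"] = paired_t(
                p2m, p2s
            ).to_dict()
        report["tests"]["phase2_manual_vs_semiauto_pooled"] = two_sample_t_pooled(
            p2m, p2s
        ).to_dict()
    else:
        report["notices"].append(
            "phase-2 manual vs semi-automatic tests skipped: insufficient phase-2 data"
        )
    return report


# -- CSV schema and packaged fixture ----------------------------------------

def _row_from_record(rec: dict, line: int | None = None) -> CohortRow:
    def _num(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).upper() == "NA":
            return None
        try:
            return float(v)
        except (TypeError, ValueError) as e:
            raise SchemaError(f"non-numeric TRE value {v!r} (row {line})") from e

    try:
        phase = int(rec["phase"])
    except (TypeError, ValueError) as e:
        raise SchemaError(f"non-integer phase {rec.get('phase')!r} (row {line})") from e
    return CohortRow(str(rec["patient_id"]), phase, _num(rec["tre_manual"]),
                     _num(rec["tre_semiauto"]))


def cohort_from_dataframe(df: pd.DataFrame) -> CohortTable:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing column(s): {', '.join(missing)}")
    rows = [
        _row_from_record(rec, line=i + 2)  # +2: header + 1-based
        for i, rec in enumerate(df[COHORT_COLUMNS].to_dict("records"))
    ]
    return CohortTable(tuple(rows))


def read_cohort_csv(path) -> CohortTable:
    df = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=True,
                     na_values=["NA"], float_precision="round_trip")
    return cohort_from_dataframe(df)


def write_cohort_csv(table: CohortTable, path) -> None:
    recs = [
        {
            "patient_id": r.patient_id,
            "phase": r.phase,
            "tre_manual": "NA" if r.tre_manual_mm is None else f"{r.tre_manual_mm:.6g}",
            "tre_semiauto": "NA" if r.tre_semiauto_mm is None else f"{r.tre_semiauto_mm:.6g}",
        }
        for r in table.rows
    ]
    pd.DataFrame(recs, columns=COHORT_COLUMNS).to_csv(path, index=False)


def load_fixture(name: str = "table3") -> CohortTable:
    """Load a packaged per-patient TRE table by name."""
    ref = resources.files("lapreg.data").joinpath(f"{name}.csv")
    if not ref.is_file():
        raise SchemaError(f"no packaged fixture named {name!r}")
    with resources.as_file(ref) as p:
        return read_cohort_csv(p)
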