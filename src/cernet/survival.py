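"""Prognostic screening of selected triplets by survival analysis.

For each selected triplet the three RNAs are dichotomized at their median
expression over the tumor samples (strictly above the median = "high", at or
below = "low").  Patients are split on the lncRNA/mRNA pattern only:

    Group 1 — opposite levels (lnc high & mRNA low, or lnc low & mRNA high)
    Group 2 — same levels   (both high, or both low)

The miRNA level is carried in the labeling but does not drive grouping (it was
found non-predictive of survival).  Within each group the two sub-patterns form
a binary covariate for a univariate Cox proportional-hazards fit (Efron tie
handling); a triplet is called prognostic when at least one of its two group
fits has a Wald p-value below the screening threshold (default 0.01).
Kaplan-Meier curves and log-rank tests are provided for the same dichotomies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy.stats import false_discovery_control

from .associations import Triplet
from .errors import NotEstimableError, ParseError, SampleLookupError

GROUP1 = "Group1"
GROUP2 = "Group2"
HIGH = "high"
LOW = "low"


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in days and event flag (1 = death)."""

    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.sample_id}")
        if self.event not in (0, 1):
            raise ValueError(f"event flag must be 0/1, got {self.event}")


def survival_frame(records) -> pd.DataFrame:
    """Coerce survival input to a canonical frame indexed by sample id.

    Accepts an iterable of SurvivalRecords, a frame with columns
    (sample_id, time, event), or a frame with (time, event) columns indexed by
    sample id.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "sample_id" not in df.columns and {"time", "event"} <= set(df.columns):
            df = df.rename_axis("sample_id").reset_index()
    else:
        df = pd.DataFrame(
            [(r.sample_id, r.time, r.event) for r in records],
            columns=["sample_id", "time", "event"],
        )
    missing = {"sample_id", "time", "event"} - set(df.columns)
    if missing:
        raise ParseError(f"survival table lacks columns {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    if (df["time"] < 0).any():
        raise ParseError("negative survival times")
    if not df["event"].isin((0, 1)).all():
        raise ParseError("event flags must be 0/1")
    if df["sample_id"].duplicated().any():
        raise ParseError("duplicate sample ids in survival table")
    return df.set_index("sample_id")


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV with columns sample_id, time, event."""
    return survival_frame(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


# ---------------------------------------------------------------------------
# Dichotomization and grouping
# ---------------------------------------------------------------------------

def median_dichotomize(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Label samples high/low against the median of their values.

    Strictly above the median -> "high"; equal or below -> "low" (deterministic
    tie rule).  The median is taken over the samples supplied, i.e. the tumor
    cohort when screening.  All-equal input yields all-low with a warning.
    """
    ser = pd.Series(values, dtype=float)
    if len(ser) < 2:
        raise ValueError("median dichotomization needs >= 2 samples")
    med = float(ser.median())
    if float(ser.max()) == float(ser.min()):
        warnings.warn("all expression values identical; every sample labeled 'low'", stacklevel=2)
    return pd.Series(np.where(ser.to_numpy() > med, HIGH, LOW), index=ser.index, name="level")


def assign_groups(
    lnc_levels: pd.Series,
    mi_levels: pd.Series,
    mrna_levels: pd.Series,
) -> pd.DataFrame:
    """Assign each sample to Group 1/2 from its lncRNA and mRNA levels.

    Returns a frame indexed by sample id with columns lnc_level, mi_level,
    mrna_level, pattern_group and sub_pattern (the "<lnc>-<mrna>" level pair,
    the within-group configuration used as the Cox covariate).
    """
    lnc, mi, mrna = (pd.Series(s) for s in (lnc_levels, mi_levels, mrna_levels))
    samples = lnc.index
    for name, ser in (("miRNA", mi), ("mRNA", mrna)):
        if not samples.equals(ser.index):
            if set(samples) != set(ser.index):
                raise SampleLookupError(f"{name} level map does not cover the same samples")
    mi = mi.reindex(samples)
    mrna = mrna.reindex(samples)
    opposite = lnc.to_numpy() != mrna.to_numpy()
    df = pd.DataFrame(
        {
            "lnc_level": lnc,
            "mi_level": mi,
            "mrna_level": mrna,
            "pattern_group": np.where(opposite, GROUP1, GROUP2),
            "sub_pattern": lnc.str.cat(mrna, sep="-"),
        },
        index=samples,
    )
    return df


# ---------------------------------------------------------------------------
# Cox proportional hazards / Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox fit for one triplet within one patient group."""

    triplet: Triplet
    group: str
    coefficient: float
    hazard_ratio: float
    p_value: float
    n_samples: int
    n_events: int
    q_value: float = float("nan")


def cox_univariate(surv: pd.DataFrame, covariate: pd.Series) -> tuple[float, float, float, int, int]:
    """Fit a univariate Cox PH model with one binary covariate.

    Returns (coefficient, hazard_ratio, wald_p, n_samples, n_events).  Efron
    approximation for tied event times.  Raises NotEstimableError when the
    analyzed set has no events, when one covariate arm is empty, or when the
    partial likelihood is monotone (complete separation).
    """
    surv = survival_frame(surv)
    cov = pd.Series(covariate).reindex(surv.index)
    if cov.isna().any():
        raise SampleLookupError("covariate missing for some samples in the survival set")
    cov = cov.astype(float)
    arms = cov.nunique()
    if arms < 2:
        raise NotEstimableError("covariate has a single arm; hazard ratio not estimable")
    if int(surv["event"].sum()) < 1:
        raise NotEstimableError("no observed events; Cox model not estimable")
    df = pd.DataFrame({"time": surv["time"], "event": surv["event"], "x": cov})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event", fit_options={"precision": 1e-9})
        except (ConvergenceError, ValueError) as exc:
            raise NotEstimableError(f"Cox fit failed: {exc}") from exc
    coef = float(cph.params_["x"])
    p = float(cph.summary.loc["x", "p"])
    return coef, float(np.exp(coef)), p, int(len(df)), int(df["event"].sum())


class KMResult(NamedTuple):
    """Kaplan-Meier curves per arm plus the two-group log-rank test."""

    curves: pd.DataFrame
    statistic: float
    p_value: float


def km_logrank(surv: pd.DataFrame, covariate: pd.Series) -> KMResult:
    """Product-limit curves per covariate arm and the log-rank chi-square test.

    The curve table has columns arm, time, survival, at_risk, censored.
    """
    surv = survival_frame(surv)
    cov = pd.Series(covariate).reindex(surv.index)
    if cov.isna().any():
        raise SampleLookupError("covariate missing for some samples in the survival set")
    arm_values = sorted(cov.unique(), key=str)
    if len(arm_values) != 2:
        raise NotEstimableError(f"log-rank needs exactly 2 nonempty arms, found {len(arm_values)}")
    curves = []
    arm_data = {}
    for arm in arm_values:
        sel = cov == arm
        times = surv.loc[sel, "time"]
        events = surv.loc[sel, "event"]
        arm_data[arm] = (times, events)
        kmf = KaplanMeierFitter()
        kmf.fit(times, events, label=str(arm))
        tbl = kmf.event_table
        curve = pd.DataFrame(
            {
                "arm": str(arm),
                "time": tbl.index.to_numpy(dtype=float),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tbl["at_risk"].to_numpy(),
                "censored": tbl["censored"].to_numpy(),
            }
        )
        curves.append(curve)
    (t0, e0), (t1, e1) = (arm_data[a] for a in arm_values)
    res = logrank_test(t0, t1, event_observed_A=e0, event_observed_B=e1)
    return KMResult(pd.concat(curves, ignore_index=True), float(res.test_statistic), float(res.p_value))


# ---------------------------------------------------------------------------
# Triplet screening
# ---------------------------------------------------------------------------

class ScreenOutcome(NamedTuple):
    """All per-(triplet, group) Cox fits, the retained results, and failures."""

    results: list[CoxResult]
    retained: list[CoxResult]
    prognostic: set[Triplet]
    failures: dict[tuple[Triplet, str], str]


def screen_triplets(
    selected,
    tumor_expr: pd.DataFrame,
    surv: pd.DataFrame,
    alpha: float = 0.01,
) -> ScreenOutcome:
    """Screen selected triplets for prognostic value (Cox p < alpha per group).

    For each triplet: median-dichotomize the three RNAs over the tumor samples
    shared between expression and survival, assign Group 1/2, and within each
    group fit the univariate Cox model on the sub-pattern indicator.  Raw p
    drives the screen; Benjamini-Hochberg q-values over all fits are attached
    for reporting only.  Per-triplet estimation failures are recorded, never
    fatal.
    """
    surv = survival_frame(surv)
    shared = tumor_expr.columns.intersection(surv.index)
    if len(shared) < 4:
        raise NotEstimableError(f"only {len(shared)} samples shared between expression and survival")
    expr = tumor_expr.loc[:, shared]
    surv = surv.loc[shared]
    results: list[CoxResult] = []
    failures: dict[tuple[Triplet, str], str] = {}
    for t in sorted(set(selected)):
        missing = [g for g in t if g not in expr.index]
        if missing:
            failures[(t, "both")] = f"genes absent from tumor expression: {missing}"
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labeling = assign_groups(
                median_dichotomize(expr.loc[t.lncrna]),
                median_dichotomize(expr.loc[t.mirna]),
                median_dichotomize(expr.loc[t.mrna]),
            )
        for group in (GROUP1, GROUP2):
            members = labeling.index[labeling["pattern_group"] == group]
            if len(members) == 0:
                failures[(t, group)] = "empty group"
                continue
            covariate = (labeling.loc[members, "lnc_level"] == HIGH).astype(int)
            try:
                coef, hr, p, n, ev = cox_univariate(surv.loc[members], covariate)
            except NotEstimableError as exc:
                failures[(t, group)] = str(exc)
                continue
            results.append(CoxResult(t, group, coef, hr, p, n, ev))
    if results:
        qs = false_discovery_control([r.p_value for r in results], method="bh")
        results = [replace(r, q_value=float(q)) for r, q in zip(results, qs)]
    retained = [r for r in results if r.p_value < alpha]
    return ScreenOutcome(results, retained, {r.triplet for r in retained}, failures)


def cox_results_frame(results) -> pd.DataFrame:
    rows = [
        (r.triplet.lncrna, r.triplet.mirna, r.triplet.mrna, r.group,
         r.coefficient, r.hazard_ratio, r.p_value, r.q_value, r.n_samples, r.n_events)
        for r in results
    ]
    return pd.DataFrame(rows, columns=[
        "lncRNA", "miRNA", "mRNA", "group",
        "coefficient", "hazard_ratio", "p_value", "q_value", "n_samples", "n_events",
    ])


def plot_km(result: KMResult, path: str | Path, *, title: str = "", years: bool = False) -> Path:
    """Write a Kaplan-Meier step plot (format from the file suffix, .svg/.png).

    Censored observations are marked with ticks; ``years=True`` rescales the
    time axis from days to years.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    scale = 365.25 if years else 1.0
    fig, ax = plt.subplots(figsize=(5, 4))
    for arm, curve in result.curves.groupby("arm"):
        t = np.concatenate([[0.0], curve["time"].to_numpy()]) / scale
        s = np.concatenate([[1.0], curve["survival"].to_numpy()])
        ax.step(t, s, where="post", label=str(arm))
        cens = curve[curve["censored"] > 0]
        ax.plot(cens["time"] / scale, cens["survival"], "|", color=ax.lines[-1].get_color())
    ax.set_xlabel("years" if years else "days")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend(title=f"log-rank p = {result.p_value:.2g}")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def eight_level_screen(surv: pd.DataFrame, labeling: pd.DataFrame) -> float:
    """Likelihood-ratio p for the 8-level (lnc, mi, mRNA) pattern as a categorical covariate.

    Optional coarse screen preceding the within-group analysis; returns the
    LRT p-value of the Cox model with the full 8-category pattern against the
    null model.
    """
    surv = survival_frame(surv)
    pattern = labeling["lnc_level"] + "/" + labeling["mi_level"] + "/" + labeling["mrna_level"]
    dummies = pd.get_dummies(pattern.reindex(surv.index), drop_first=True, dtype=float)
    df = pd.concat([surv[["time", "event"]], dummies], axis=1)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, ValueError) as exc:
            raise NotEstimableError(f"8-level Cox fit failed: {exc}") from exc
    return float(cph.log_likelihood_ratio_test().p_value)
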