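"""Patient-specific ceRNA network construction by single-sample differential partial correlation.

The model: for a candidate triplet (lncRNA x, miRNA z, mRNA y) the ceRNA coupling
between x and y, net of their shared regulator z, is the first-order partial
correlation

    rho(x, y | z) = (PCC(x,y) - PCC(x,z) PCC(y,z))
                    / (sqrt(1 - PCC^2(x,z)) sqrt(1 - PCC^2(y,z)))

where PCC is the Pearson product-moment correlation.  A *reference* network is
built from the n normal samples (one rho_n per triplet).  For each tumor sample
the partial correlations are recomputed on the n+1 samples obtained by appending
that single sample to the normals (*perturbed* network, rho_{n+1}); the
patient-specific network is their difference,

    delta_rho(x, y | z) = | rho_{n+1}(x, y | z) - rho_n(x, y | z) |,

one value per triplet per patient, used as the edge weight.  Triplet selection
applies a per-sample edge filter (|rho_{n+1}| > 0.7 and p < 0.05 by default) and
then a one-sample Z-test of mean delta_rho over the passing samples.

Because the test statistic delta_rho is nonnegative, the Z-test by itself is not
a calibrated null test; specificity in this procedure is supplied by the edge
filter and the minimum-passing-samples requirement (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .associations import Triplet
from .errors import (
    DegenerateInputError,
    GeneLookupError,
    InsufficientSamplesError,
    ParseError,
    SampleLookupError,
)

NORMAL = "normal"
TUMOR = "tumor"

#: denominators smaller than this are treated as degenerate (zero variance /
#: perfectly correlated conditioning variable)
DEGENERACY_TOL = 1e-12


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with a normal/tumor label per sample.

    ``values`` rows are gene ids, columns are sample ids; entries must be finite
    (missing values are rejected at load — impute upstream).  ``sample_class``
    maps every sample id to ``"normal"`` or ``"tumor"``.
    """

    values: pd.DataFrame
    sample_class: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()[:5]
            raise ParseError(f"duplicate gene ids: {dup}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()[:5]
            raise ParseError(f"duplicate sample ids: {dup}")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ParseError("expression matrix contains missing or non-finite values")
        self.sample_class = self.sample_class.reindex(v.columns)
        if self.sample_class.isna().any():
            missing = self.sample_class.index[self.sample_class.isna()].tolist()[:5]
            raise ParseError(f"samples without a normal/tumor label: {missing}")
        bad = set(self.sample_class.unique()) - {NORMAL, TUMOR}
        if bad:
            raise ParseError(f"unknown sample classes {sorted(bad)}; expected '{NORMAL}' or '{TUMOR}'")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def normal(self) -> pd.DataFrame:
        return self.values.loc[:, self.sample_class == NORMAL]

    @property
    def tumor(self) -> pd.DataFrame:
        return self.values.loc[:, self.sample_class == TUMOR]

    def transformed(self, log2p1: bool = True) -> "ExpressionMatrix":
        """Return a copy on the log2(v+1) scale (the default analysis scale)."""
        if not log2p1:
            return ExpressionMatrix(self.values.copy(), self.sample_class.copy())
        return ExpressionMatrix(np.log2(self.values + 1.0), self.sample_class.copy())


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene id, header row sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ParseError(f"{path}: empty expression matrix")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression values ({exc})") from exc
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return df


def read_sample_classes(path: str | Path) -> pd.Series:
    """Read a sample_id<TAB>normal|tumor table into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "sample_class"], dtype=str)
    first = df.iloc[0]
    if first["sample_id"].lower() in {"sample_id", "sample"}:
        df = df.iloc[1:]
    ser = pd.Series(
        df["sample_class"].str.strip().to_numpy(),
        index=df["sample_id"].str.strip().to_numpy(),
        name="sample_class",
    )
    bad = set(ser.unique()) - {NORMAL, TUMOR}
    if bad:
        raise ParseError(f"{path}: unknown sample classes {sorted(bad)}")
    return ser


def load_expression(expr_path: str | Path, class_path: str | Path) -> ExpressionMatrix:
    return ExpressionMatrix(read_expression_tsv(expr_path), read_sample_classes(class_path))


# ---------------------------------------------------------------------------
# Correlation primitives
# ---------------------------------------------------------------------------

def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two 1-d vectors of equal length")
    if x.size < 3:
        raise InsufficientSamplesError(f"pearson needs >= 3 observations, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt(xc @ xc) * np.sqrt(yc @ yc)
    if den <= DEGENERACY_TOL:
        raise DegenerateInputError("zero variance")
    return float(np.clip((xc @ yc) / den, -1.0, 1.0))


def partial_correlation(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """First-order partial correlation rho(x, y | z).

    Computed from the three pairwise Pearson correlations; the result is clipped
    to [-1, 1] against floating-point overshoot.  Raises DegenerateInputError
    when any vector has zero variance or when |PCC(x,z)| or |PCC(y,z)| is so
    close to 1 that the denominator vanishes.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise InsufficientSamplesError(f"partial correlation needs n >= 4, got {x.size}")
    r_xy = pearson(x, y)
    r_xz = pearson(x, z)
    r_yz = pearson(y, z)
    den = np.sqrt(1.0 - r_xz**2) * np.sqrt(1.0 - r_yz**2)
    if den <= DEGENERACY_TOL:
        raise DegenerateInputError("conditioning variable is collinear with x or y")
    return float(np.clip((r_xy - r_xz * r_yz) / den, -1.0, 1.0))


def partial_correlation_pvalue(rho: float, n: int) -> float:
    """Two-sided p-value for a first-order partial correlation.

    Uses the t statistic ``t = rho * sqrt((n - 3) / (1 - rho^2))`` on n - 3
    degrees of freedom (one conditioning variable).  ``rho = +/-1`` maps to 0.
    """
    if n < 4:
        raise InsufficientSamplesError(f"p-value needs n >= 4, got {n}")
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"|rho| must be <= 1, got {rho}")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 3) / (1.0 - rho**2))
    return float(2.0 * sps.t.sf(abs(t), df=n - 3))


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartialCorrelation:
    """One estimated rho with its sample count and two-sided p-value."""

    rho: float
    n: int
    p_value: float


@dataclass(frozen=True)
class PerSampleStat:
    """rho_{n+1}, delta_rho and the edge-filter verdict for one tumor sample."""

    rho_pert: PartialCorrelation
    delta_rho: float
    passes_edge_filter: bool


@dataclass
class TripletStatRecord:
    """Reference rho_n plus the per-tumor-sample perturbation statistics of one triplet."""

    triplet: Triplet
    rho_ref: PartialCorrelation
    per_sample: dict[str, PerSampleStat] = field(default_factory=dict)


@dataclass(frozen=True)
class SelectionThresholds:
    """Edge-filter and Z-test settings.

    threshold_abs / threshold_p implement the per-sample edge filter
    |rho_{n+1}| > threshold_abs and p < threshold_p; ztest_alpha is the
    two-sided level of the Z-test on mean delta_rho; min_samples is the minimum
    number of edge-filter-passing tumor samples a triplet needs to enter the
    Z-test.  ``use_edge_filter=False`` pools all tumor samples into the Z-test;
    ``filter_reference=True`` additionally requires |rho_n| > threshold_abs and
    reference p < threshold_p; ``one_sided=True`` uses an upper-tail Z-test.
    """

    threshold_abs: float = 0.7
    threshold_p: float = 0.05
    ztest_alpha: float = 0.05
    min_samples: int = 3
    use_edge_filter: bool = True
    filter_reference: bool = False
    one_sided: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_abs < 1.0:
            raise ValueError(f"threshold_abs must be in (0, 1), got {self.threshold_abs}")
        for name in ("threshold_p", "ztest_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass
class PatientNetwork:
    """Edges (triplets) specific to one tumor sample, weighted by delta_rho."""

    sample_id: str
    edges: dict[Triplet, float]


class ReferenceNetwork(NamedTuple):
    """Per-triplet reference partial correlations plus excluded triplets with reasons."""

    correlations: dict[Triplet, PartialCorrelation]
    excluded: dict[Triplet, str]


# ---------------------------------------------------------------------------
# Vectorized cohort engine
# ---------------------------------------------------------------------------

def _gene_indices(gene_index: pd.Index, triplets: list[Triplet]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pos = {g: i for i, g in enumerate(gene_index)}
    ix = np.empty(len(triplets), dtype=np.intp)
    iz = np.empty(len(triplets), dtype=np.intp)
    iy = np.empty(len(triplets), dtype=np.intp)
    for k, t in enumerate(triplets):
        for member in t:
            if member not in pos:
                raise GeneLookupError(f"gene {member!r} of triplet {t.label()} absent from expression matrix")
        ix[k], iz[k], iy[k] = pos[t.lncrna], pos[t.mirna], pos[t.mrna]
    return ix, iz, iy


def _pair_rho(n: float, su, sv, suu, svv, suv) -> np.ndarray:
    """Pearson r from raw sums; degenerate pairs -> nan."""
    vu = n * suu - su * su
    vv = n * svv - sv * sv
    with np.errstate(invalid="ignore", divide="ignore"):
        den = np.sqrt(np.maximum(vu, 0.0)) * np.sqrt(np.maximum(vv, 0.0))
        r = (n * suv - su * sv) / den
    r = np.where(den <= DEGENERACY_TOL * n * n, np.nan, r)
    return np.clip(r, -1.0, 1.0)


def _partial_from_pairs(r_xy: np.ndarray, r_xz: np.ndarray, r_yz: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        den = np.sqrt(np.maximum(1.0 - r_xz**2, 0.0)) * np.sqrt(np.maximum(1.0 - r_yz**2, 0.0))
        rho = (r_xy - r_xz * r_yz) / den
    rho = np.where(den <= DEGENERACY_TOL, np.nan, rho)
    return np.clip(rho, -1.0, 1.0)


def _pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 3) / np.maximum(1.0 - rho**2, 0.0))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 3)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return np.where(np.isnan(rho), np.nan, p)


class _TripletSums:
    """Raw per-triplet sufficient statistics over the normal samples.

    Appending one tumor sample to n normals only updates these sums, so the
    n+1-sample partial correlation of every triplet for every tumor sample is
    computed in O(#triplets) per sample without re-touching the normal matrix.
    """

    def __init__(self, normal_values: np.ndarray, ix: np.ndarray, iz: np.ndarray, iy: np.ndarray):
        X = np.asarray(normal_values, dtype=float)
        self.n = X.shape[1]
        self.ix, self.iz, self.iy = ix, iz, iy
        a, z, b = X[ix], X[iz], X[iy]          # lncRNA, miRNA, mRNA rows, (T, n)
        self.s = {
            "x": a.sum(1), "y": b.sum(1), "z": z.sum(1),
            "xx": (a * a).sum(1), "yy": (b * b).sum(1), "zz": (z * z).sum(1),
            "xy": (a * b).sum(1), "xz": (a * z).sum(1), "yz": (b * z).sum(1),
        }

    def rho_ref(self) -> np.ndarray:
        n, s = float(self.n), self.s
        r_xy = _pair_rho(n, s["x"], s["y"], s["xx"], s["yy"], s["xy"])
        r_xz = _pair_rho(n, s["x"], s["z"], s["xx"], s["zz"], s["xz"])
        r_yz = _pair_rho(n, s["y"], s["z"], s["yy"], s["zz"], s["yz"])
        return _partial_from_pairs(r_xy, r_xz, r_yz)

    def rho_augmented(self, sample_values: np.ndarray) -> np.ndarray:
        """rho_{n+1} per triplet after appending one sample's per-gene values."""
        v = np.asarray(sample_values, dtype=float)
        a, z, b = v[self.ix], v[self.iz], v[self.iy]
        n1, s = float(self.n + 1), self.s
        r_xy = _pair_rho(n1, s["x"] + a, s["y"] + b, s["xx"] + a * a, s["yy"] + b * b, s["xy"] + a * b)
        r_xz = _pair_rho(n1, s["x"] + a, s["z"] + z, s["xx"] + a * a, s["zz"] + z * z, s["xz"] + a * z)
        r_yz = _pair_rho(n1, s["y"] + b, s["z"] + z, s["yy"] + b * b, s["zz"] + z * z, s["yz"] + b * z)
        return _partial_from_pairs(r_xy, r_xz, r_yz)


def reference_network(normal: pd.DataFrame | ExpressionMatrix, triplets: Iterable[Triplet]) -> ReferenceNetwork:
    """Compute the reference partial correlation rho_n for every triplet.

    ``normal`` is a genes x samples frame of normal samples only (an
    ExpressionMatrix is accepted and restricted to its normal columns).
    Triplets whose member genes are degenerate (zero variance, collinear
    conditioning) are excluded with a reason rather than failing the run.
    """
    frame = normal.normal if isinstance(normal, ExpressionMatrix) else normal
    n = frame.shape[1]
    if n < 4:
        raise InsufficientSamplesError(f"reference network needs >= 4 normal samples, got {n}")
    trip_list = sorted(set(triplets))
    ix, iz, iy = _gene_indices(frame.index, trip_list)
    sums = _TripletSums(frame.to_numpy(dtype=float), ix, iz, iy)
    rho = sums.rho_ref()
    p = _pvalues(rho, n)
    correlations: dict[Triplet, PartialCorrelation] = {}
    excluded: dict[Triplet, str] = {}
    for k, t in enumerate(trip_list):
        if np.isnan(rho[k]):
            excluded[t] = "zero variance or collinear conditioning variable"
        else:
            correlations[t] = PartialCorrelation(float(rho[k]), n, float(p[k]))
    return ReferenceNetwork(correlations, excluded)


def _edge_pass(rho: np.ndarray, p: np.ndarray, thresholds: SelectionThresholds) -> np.ndarray:
    return (np.abs(rho) > thresholds.threshold_abs) & (p < thresholds.threshold_p)


def perturb_one_sample(
    normal: pd.DataFrame | ExpressionMatrix,
    tumor_sample: Mapping[str, float] | pd.Series,
    triplets: Iterable[Triplet],
    ref: ReferenceNetwork,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> dict[Triplet, PerSampleStat]:
    """Perturbation statistics for one tumor sample appended to the normals.

    Returns, per (non-excluded) triplet, rho_{n+1} on the n+1 samples with its
    p-value, delta_rho = |rho_{n+1} - rho_n| and the edge-filter verdict.
    """
    frame = normal.normal if isinstance(normal, ExpressionMatrix) else normal
    trip_list = sorted(t for t in set(triplets) if t in ref.correlations)
    ix, iz, iy = _gene_indices(frame.index, trip_list)
    sample = pd.Series(tumor_sample).reindex(frame.index)
    if sample.isna().any():
        missing = frame.index[sample.isna()].tolist()[:5]
        raise GeneLookupError(f"tumor sample lacks values for genes {missing}")
    sums = _TripletSums(frame.to_numpy(dtype=float), ix, iz, iy)
    rho1 = sums.rho_augmented(sample.to_numpy(dtype=float))
    n1 = sums.n + 1
    p1 = _pvalues(rho1, n1)
    passes = _edge_pass(rho1, p1, thresholds)
    out: dict[Triplet, PerSampleStat] = {}
    for k, t in enumerate(trip_list):
        if np.isnan(rho1[k]):
            continue
        rc = ref.correlations[t]
        out[t] = PerSampleStat(
            rho_pert=PartialCorrelation(float(rho1[k]), n1, float(p1[k])),
            delta_rho=abs(float(rho1[k]) - rc.rho),
            passes_edge_filter=bool(passes[k]),
        )
    return out


def perturb_cohort(
    expr: ExpressionMatrix,
    triplets: Iterable[Triplet],
    thresholds: SelectionThresholds = SelectionThresholds(),
    *,
    log2p1: bool = True,
) -> tuple[dict[Triplet, TripletStatRecord], dict[Triplet, str]]:
    """Run the full reference + per-tumor-sample perturbation over a cohort.

    Applies the log2(v+1) transform by default, builds the reference network on
    the normal samples and appends each tumor sample in sorted-id order.
    Returns (records keyed by triplet, excluded triplets with reasons).
    """
    mat = expr.transformed(log2p1)
    normal = mat.normal
    tumor = mat.tumor
    ref = reference_network(normal, triplets)
    trip_list = sorted(ref.correlations)
    ix, iz, iy = _gene_indices(normal.index, trip_list)
    sums = _TripletSums(normal.to_numpy(dtype=float), ix, iz, iy)
    n1 = sums.n + 1
    records = {t: TripletStatRecord(t, ref.correlations[t]) for t in trip_list}
    rho_ref = np.array([ref.correlations[t].rho for t in trip_list])
    tumor_values = tumor.to_numpy(dtype=float)
    for sample_id in sorted(tumor.columns):
        col = tumor_values[:, tumor.columns.get_loc(sample_id)]
        rho1 = sums.rho_augmented(col)
        p1 = _pvalues(rho1, n1)
        passes = _edge_pass(rho1, p1, thresholds)
        delta = np.abs(rho1 - rho_ref)
        ok = ~np.isnan(rho1)
        for k in np.flatnonzero(ok):
            records[trip_list[k]].per_sample[sample_id] = PerSampleStat(
                rho_pert=PartialCorrelation(float(rho1[k]), n1, float(p1[k])),
                delta_rho=float(delta[k]),
                passes_edge_filter=bool(passes[k]),
            )
    return records, ref.excluded


# ---------------------------------------------------------------------------
# Triplet selection (Z-test) and per-patient networks
# ---------------------------------------------------------------------------

def ztest_statistics(
    records: Iterable[TripletStatRecord] | Mapping[Triplet, TripletStatRecord],
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> pd.DataFrame:
    """Per-triplet Z-test table: m, mean/sd of delta_rho, z, p, verdict, flag.

    With the edge filter enabled (default) only tumor samples whose perturbed
    partial correlation passes |rho| > threshold_abs and p < threshold_p
    contribute delta_rho values; triplets with fewer than ``min_samples``
    contributing samples are dropped with reason "insufficient passing samples".
    A zero standard deviation with positive mean yields an infinite z (kept,
    flagged "degenerate-sd").
    """
    if isinstance(records, Mapping):
        records = records.values()
    rows = []
    for rec in records:
        if thresholds.filter_reference:
            rc = rec.rho_ref
            if not (abs(rc.rho) > thresholds.threshold_abs and rc.p_value < thresholds.threshold_p):
                rows.append(_zrow(rec.triplet, 0, np.nan, np.nan, np.nan, np.nan, False, "reference failed edge filter"))
                continue
        deltas = [
            st.delta_rho
            for st in rec.per_sample.values()
            if st.passes_edge_filter or not thresholds.use_edge_filter
        ]
        m = len(deltas)
        if m < thresholds.min_samples:
            rows.append(_zrow(rec.triplet, m, np.nan, np.nan, np.nan, np.nan, False, "insufficient passing samples"))
            continue
        arr = np.asarray(deltas)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if m > 1 else 0.0
        flag = ""
        if sd <= 0.0:
            if mean > 0.0:
                z, p = np.inf, 0.0
                flag = "degenerate-sd"
            else:
                z, p = 0.0, 1.0
        else:
            z = mean / (sd / np.sqrt(m))
            p = float(sps.norm.sf(z)) if thresholds.one_sided else float(2.0 * sps.norm.sf(abs(z)))
        selected = p < thresholds.ztest_alpha
        rows.append(_zrow(rec.triplet, m, mean, sd, float(z), float(p), bool(selected), flag))
    cols = ["lncRNA", "miRNA", "mRNA", "m", "mean_delta_rho", "sd_delta_rho", "z", "p_value", "selected", "flag"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["lncRNA", "miRNA", "mRNA"], ignore_index=True)


def _zrow(t: Triplet, m, mean, sd, z, p, selected, flag):
    return (t.lncrna, t.mirna, t.mrna, m, mean, sd, z, p, selected, flag)


def ztest_select(
    records: Iterable[TripletStatRecord] | Mapping[Triplet, TripletStatRecord],
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> set[Triplet]:
    """Triplets kept by the Z-test on mean delta_rho (see ztest_statistics)."""
    df = ztest_statistics(records, thresholds)
    return {
        Triplet(r.lncRNA, r.miRNA, r.mRNA)
        for r in df.itertuples(index=False)
        if r.selected
    }


def patient_network(
    records: Mapping[Triplet, TripletStatRecord],
    sample_id: str,
) -> PatientNetwork:
    """The delta_rho-weighted network of one tumor sample (edge-filter survivors)."""
    known = any(sample_id in rec.per_sample for rec in records.values())
    if not known:
        raise SampleLookupError(f"sample {sample_id!r} not present in perturbation records")
    edges = {
        t: rec.per_sample[sample_id].delta_rho
        for t, rec in records.items()
        if sample_id in rec.per_sample and rec.per_sample[sample_id].passes_edge_filter
    }
    if not edges:
        warnings.warn(f"patient network for {sample_id!r} is empty", stacklevel=2)
    return PatientNetwork(sample_id, edges)


def stat_records_frame(records: Mapping[Triplet, TripletStatRecord]) -> pd.DataFrame:
    """Long-format table of every (triplet, tumor sample) perturbation statistic."""
    rows = []
    for t in sorted(records):
        rec = records[t]
        for sid in sorted(rec.per_sample):
            st = rec.per_sample[sid]
            rows.append((
                t.lncrna, t.mirna, t.mrna, sid,
                rec.rho_ref.rho, rec.rho_ref.p_value,
                st.rho_pert.rho, st.rho_pert.p_value,
                st.delta_rho, st.passes_edge_filter,
            ))
    return pd.DataFrame(rows, columns=[
        "lncRNA", "miRNA", "mRNA", "sample_id",
        "rho_ref", "p_ref", "rho_pert", "p_pert", "delta_rho", "passes_edge_filter",
    ])


def write_stat_records(path: str | Path, records: Mapping[Triplet, TripletStatRecord]) -> None:
    stat_records_frame(records).to_csv(path, sep="\t", index=False)


def read_stat_records(path: str | Path) -> dict[Triplet, TripletStatRecord]:
    """Rebuild TripletStatRecords from a TSV written by write_stat_records.

    The reference sample count is not stored per row; it is recovered from the
    perturbed n as n_pert - 1 (the engine always uses all normals plus one).
    """
    df = pd.read_csv(path, sep="\t")
    needed = {"lncRNA", "miRNA", "mRNA", "sample_id", "rho_ref", "p_ref", "rho_pert", "p_pert",
              "delta_rho", "passes_edge_filter"}
    missing = needed - set(df.columns)
    if missing:
        raise ParseError(f"{path}: stat-record table lacks columns {sorted(missing)}")
    n1 = df["sample_id"].nunique() + 1 if len(df) else 0
    records: dict[Triplet, TripletStatRecord] = {}
    for row in df.itertuples(index=False):
        t = Triplet(row.lncRNA, row.miRNA, row.mRNA)
        rec = records.get(t)
        if rec is None:
            rec = TripletStatRecord(t, PartialCorrelation(float(row.rho_ref), n1 - 1, float(row.p_ref)))
            records[t] = rec
        rec.per_sample[str(row.sample_id)] = PerSampleStat(
            rho_pert=PartialCorrelation(float(row.rho_pert), n1, float(row.p_pert)),
            delta_rho=float(row.delta_rho),
            passes_edge_filter=bool(row.passes_edge_filter),
        )
    return records
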