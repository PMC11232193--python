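"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the statistical structure the network method assumes,
not RNA-seq count mechanics: each gene's log2 expression is Gaussian
(log-normal on the raw scale) and planted triplets follow a latent Gaussian
model in which the lncRNA and mRNA both load on their shared miRNA and their
residuals are correlated, so the lncRNA-mRNA partial correlation given the
miRNA equals a prescribed rho* exactly on the latent scale.  In tumor samples
the residual correlation of a planted triplet is shifted by delta, which is
what the single-sample perturbation statistics are meant to detect.  Decoy
associations among independent background genes exercise specificity.

Survival is exponential: hazard lambda * exp(beta * indicator), where the
indicator marks tumor samples showing the planted prognostic sub-pattern
(lncRNA high & mRNA low) of a chosen triplet; censoring is independent uniform,
scaled to achieve the configured censoring fraction in expectation under the
baseline hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .associations import LNC_MI, MRNA_MI, AssociationTable, Triplet
from .errors import ConfigError
from .network import NORMAL, TUMOR, ExpressionMatrix
from .survival import GROUP1, HIGH, LOW, SurvivalRecord


@dataclass(frozen=True)
class PlantedTriplet:
    """One triplet with prescribed latent conditional correlation and tumor shift."""

    triplet: Triplet
    rho_star: float
    delta: float


@dataclass(frozen=True)
class SurvivalSpec:
    """Exponential survival generator settings (time unit: days)."""

    baseline_hazard: float = 1.0 / 1000.0
    log_hr: float = 0.0
    censoring_rate: float = 0.3


@dataclass
class SimulationConfig:
    """Cohort generator settings.

    Defaults define the package's standard study conditions: 50 normal and 50
    tumor samples; 20 planted triplets with latent conditional correlation
    rho* = 0.9 shifted by delta = -0.5 in tumor samples; 480 decoy triplets
    (120 decoy miRNAs, each with 2 lncRNA and 2 mRNA partners) for a 500-triplet
    candidate set; log2 expression ~ N(8, 1.2^2) plus independent measurement
    noise of sd 0.1 on the log scale.
    """

    n_normal: int = 50
    n_tumor: int = 50
    n_planted: int = 20
    rho_star: float = 0.9
    delta: float = -0.5
    mirna_coupling: float = 0.5
    n_decoy_mirna: int = 120
    decoy_lnc_per_mi: int = 2
    decoy_mrna_per_mi: int = 2
    n_background: int = 10
    noise_sd: float = 0.1
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 1.2
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_normal", "n_tumor"):
            if getattr(self, name) < 4:
                raise ConfigError(f"{name} must be >= 4")
        for name in ("n_planted", "n_decoy_mirna", "decoy_lnc_per_mi", "decoy_mrna_per_mi", "n_background"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not abs(self.rho_star) < 1.0:
            raise ConfigError(f"|rho_star| must be < 1, got {self.rho_star}")
        if not abs(self.rho_star + self.delta) < 1.0:
            raise ConfigError(
                f"shifted conditional correlation rho*+delta = {self.rho_star + self.delta} is infeasible"
            )
        if not 0.0 < abs(self.mirna_coupling) < 1.0:
            raise ConfigError("mirna_coupling must be in (0, 1)")
        if self.noise_sd < 0 or self.baseline_log_sd <= 0:
            raise ConfigError("noise_sd must be >= 0 and baseline_log_sd > 0")
        if self.survival.baseline_hazard <= 0:
            raise ConfigError("baseline hazard must be positive")
        if not 0.0 <= self.survival.censoring_rate < 1.0:
            raise ConfigError("censoring rate must be in [0, 1)")


class SimulatedCohort(NamedTuple):
    """Expression matrix, association tables and the planted-truth table."""

    expression: ExpressionMatrix
    lnc_mi: AssociationTable
    mrna_mi: AssociationTable
    truth: pd.DataFrame
    planted: list[PlantedTriplet]


def _names(prefix: str, count: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, count + 1)]


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort under the latent-Gaussian-then-exponentiate model.

    Raw expression is ``2 ** (mu + sigma * g)`` with g the standardized latent
    value, so the pipeline's log2(v+1) transform recovers an almost-affine
    image of the latent scale (exactly affine up to the +1 offset; with
    mu = 8 the distortion is negligible, see docs/methods.md).
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_normal + cfg.n_tumor
    tumor_mask = np.zeros(n_samples, dtype=bool)
    tumor_mask[cfg.n_normal:] = True

    planted_lnc = _names("LNC-P", cfg.n_planted)
    planted_mi = _names("mir-P", cfg.n_planted)
    planted_mrna = _names("MRNA-P", cfg.n_planted)
    n_dlnc = cfg.n_decoy_mirna * cfg.decoy_lnc_per_mi
    n_dmrna = cfg.n_decoy_mirna * cfg.decoy_mrna_per_mi
    decoy_lnc = _names("LNC-D", n_dlnc)
    decoy_mi = _names("mir-D", cfg.n_decoy_mirna)
    decoy_mrna = _names("MRNA-D", n_dmrna)
    bg = [_names(p, cfg.n_background) for p in ("LNC-B", "mir-B", "MRNA-B")]

    gene_ids = planted_lnc + decoy_lnc + bg[0] + planted_mi + decoy_mi + bg[1] + planted_mrna + decoy_mrna + bg[2]
    latent = rng.standard_normal((len(gene_ids), n_samples))
    pos = {g: i for i, g in enumerate(gene_ids)}

    planted: list[PlantedTriplet] = []
    w = cfg.mirna_coupling
    res_scale = np.sqrt(1.0 - w * w)
    for lnc, mi, mrna in zip(planted_lnc, planted_mi, planted_mrna):
        t = Triplet(lnc, mi, mrna)
        planted.append(PlantedTriplet(t, cfg.rho_star, cfg.delta))
        z = rng.standard_normal(n_samples)
        rho_c = np.where(tumor_mask, cfg.rho_star + cfg.delta, cfg.rho_star)
        e1 = rng.standard_normal(n_samples)
        e2 = rho_c * e1 + np.sqrt(1.0 - rho_c**2) * rng.standard_normal(n_samples)
        latent[pos[lnc]] = w * z + res_scale * e1
        latent[pos[mrna]] = w * z + res_scale * e2
        latent[pos[mi]] = z

    if cfg.noise_sd > 0:
        noisy = latent + cfg.noise_sd * rng.standard_normal(latent.shape)
        latent = noisy / np.sqrt(1.0 + cfg.noise_sd**2)
    log2_expr = cfg.baseline_log_mean + cfg.baseline_log_sd * latent
    values = np.exp2(log2_expr)

    sample_ids = [f"N{i:04d}" for i in range(1, cfg.n_normal + 1)] + [
        f"T{i:04d}" for i in range(1, cfg.n_tumor + 1)
    ]
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        pd.Series(np.where(tumor_mask, TUMOR, NORMAL), index=sample_ids, name="sample_class"),
    )

    lnc_pairs = {(p.triplet.lncrna, p.triplet.mirna) for p in planted}
    mrna_pairs = {(p.triplet.mrna, p.triplet.mirna) for p in planted}
    decoy_triplets: list[Triplet] = []
    for k, mi in enumerate(decoy_mi):
        lncs = decoy_lnc[k * cfg.decoy_lnc_per_mi:(k + 1) * cfg.decoy_lnc_per_mi]
        mrnas = decoy_mrna[k * cfg.decoy_mrna_per_mi:(k + 1) * cfg.decoy_mrna_per_mi]
        lnc_pairs.update((l, mi) for l in lncs)
        mrna_pairs.update((m, mi) for m in mrnas)
        decoy_triplets.extend(Triplet(l, mi, m) for l in lncs for m in mrnas)

    truth_rows = [
        (p.triplet.lncrna, p.triplet.mirna, p.triplet.mrna, True, p.rho_star, p.delta)
        for p in planted
    ] + [(t.lncrna, t.mirna, t.mrna, False, 0.0, 0.0) for t in decoy_triplets]
    truth = pd.DataFrame(
        truth_rows, columns=["lncRNA", "miRNA", "mRNA", "planted", "rho_star", "delta"]
    ).sort_values(["lncRNA", "miRNA", "mRNA"], ignore_index=True)

    return SimulatedCohort(
        expression=expr,
        lnc_mi=AssociationTable(frozenset(lnc_pairs), LNC_MI),
        mrna_mi=AssociationTable(frozenset(mrna_pairs), MRNA_MI),
        truth=truth,
        planted=planted,
    )


def _uniform_censor_bound(hazard: float, rate: float) -> float:
    """Upper bound c of U(0, c) censoring giving the target expected censoring rate.

    For T ~ Exp(hazard) and C ~ U(0, c), P(censored) = (1 - exp(-hazard*c)) / (hazard*c),
    which decreases from 1 (c -> 0) to 0 (c -> inf); solved by bisection.
    """
    f = lambda c: (1.0 - np.exp(-hazard * c)) / (hazard * c) - rate
    lo, hi = 1e-9 / hazard, 1.0 / hazard
    while f(hi) > 0:
        hi *= 2.0
    return float(brentq(f, lo, hi))


def simulate_survival(
    cfg: SimulationConfig,
    labelings: pd.DataFrame,
    *,
    seed: int | None = None,
) -> list[SurvivalRecord]:
    """Exponential survival for the tumor samples covered by ``labelings``.

    ``labelings`` is an assign_groups frame for the prognostic triplet; tumor
    samples with the planted sub-pattern (Group 1, lncRNA high & mRNA low) have
    hazard ``lambda * exp(beta)``, everyone else ``lambda``.  Censoring is
    uniform, calibrated to the configured rate in expectation under the
    baseline hazard (a rate of 0 means every event is observed).
    """
    spec = cfg.survival
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    sample_ids = list(labelings.index)
    indicator = (
        (labelings["pattern_group"] == GROUP1)
        & (labelings["lnc_level"] == HIGH)
        & (labelings["mrna_level"] == LOW)
    ).to_numpy()
    hazards = spec.baseline_hazard * np.exp(spec.log_hr * indicator)
    event_times = rng.exponential(1.0 / hazards)
    if spec.censoring_rate == 0.0:
        times, events = event_times, np.ones(len(sample_ids), dtype=int)
    else:
        c = _uniform_censor_bound(spec.baseline_hazard, spec.censoring_rate)
        censor_times = rng.uniform(0.0, c, size=len(sample_ids))
        events = (event_times <= censor_times).astype(int)
        times = np.minimum(event_times, censor_times)
    return [
        SurvivalRecord(sid, float(t), int(e))
        for sid, t, e in zip(sample_ids, times, events)
    ]


# ---------------------------------------------------------------------------
# File writers (the exact formats the pipeline consumes)
# ---------------------------------------------------------------------------

def write_cohort(
    cohort: SimulatedCohort,
    outdir: str | Path,
    survival: Sequence[SurvivalRecord] | None = None,
) -> dict[str, Path]:
    """Write expression, sample-class, association, truth (and clinical) TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "sample_classes": outdir / "sample_classes.tsv",
        "lnc_mi": outdir / "lncRNA_miRNA.tsv",
        "mrna_mi": outdir / "mRNA_miRNA.tsv",
        "truth": outdir / "truth.tsv",
    }
    expr = cohort.expression
    expr.values.round(6).to_csv(paths["expression"], sep="\t", index_label="gene_id")
    expr.sample_class.to_csv(paths["sample_classes"], sep="\t", header=False)
    for key, table in (("lnc_mi", cohort.lnc_mi), ("mrna_mi", cohort.mrna_mi)):
        with paths[key].open("w") as fh:
            for reg, mi in sorted(table.pairs):
                fh.write(f"{reg}\t{mi}\n")
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    if survival is not None:
        paths["clinical"] = outdir / "clinical.tsv"
        with paths["clinical"].open("w") as fh:
            fh.write("sample_id\ttime\tevent\n")
            for rec in survival:
                fh.write(f"{rec.sample_id}\t{rec.time:.6f}\t{rec.event}\n")
    return paths
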