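"""End-to-end orchestration: associations -> network -> selection -> survival -> export.

The pipeline reads the input files named in a PipelineConfig (YAML), assembles
candidate triplets, runs the reference/perturbation network computation, the
Z-test selection and the prognostic Cox screen, and writes all tables, the
Cytoscape-loadable networks (SIF + GraphML) and a JSON run manifest with
per-stage counts.  Counts are monotone non-increasing along the filter chain:
initial triplets >= edge-filter survivors >= Z-test selections >= prognostic
triplets.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

from . import associations as assoc
from . import network as net
from . import survival as surv_mod
from .associations import Triplet
from .errors import ConfigError, EmptyInputError
from .network import PatientNetwork, SelectionThresholds, TripletStatRecord

logger = logging.getLogger("cernet")


@dataclass
class PipelineConfig:
    """Paths, thresholds and switches for a full run (loadable from YAML)."""

    expression: str
    sample_classes: str
    lnc_mi: list[str]
    mrna_mi: list[str]
    clinical: str
    outdir: str = "cernet_out"
    id_mapping: str | None = None
    collapse_arms: bool = False
    log2p1: bool = True
    threshold_abs: float = 0.7
    threshold_p: float = 0.05
    ztest_alpha: float = 0.05
    min_samples: int = 3
    use_edge_filter: bool = True
    filter_reference: bool = False
    one_sided: bool = False
    cox_alpha: float = 0.01
    export_patient_networks: bool = True
    seed: int = 0

    def thresholds(self) -> SelectionThresholds:
        return SelectionThresholds(
            threshold_abs=self.threshold_abs,
            threshold_p=self.threshold_p,
            ztest_alpha=self.ztest_alpha,
            min_samples=self.min_samples,
            use_edge_filter=self.use_edge_filter,
            filter_reference=self.filter_reference,
            one_sided=self.one_sided,
        )

    def validate(self) -> None:
        paths = [self.expression, self.sample_classes, self.clinical, *self.lnc_mi, *self.mrna_mi]
        if self.id_mapping:
            paths.append(self.id_mapping)
        missing = [p for p in paths if not Path(p).is_file()]
        if missing:
            raise ConfigError(f"input files not found: {missing}")
        if not self.lnc_mi or not self.mrna_mi:
            raise ConfigError("at least one association file per side is required")
        if not 0.0 < self.cox_alpha <= 1.0:
            raise ConfigError(f"cox_alpha must be in (0, 1], got {self.cox_alpha}")
        self.thresholds()  # validates threshold ranges

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("lnc_mi", "mrna_mi"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = [raw[key]]
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _pkg_version(name: str) -> str:
    try:
        return version(name)
    except PackageNotFoundError:
        return "unknown"


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run manifest.

    Writes into cfg.outdir: triplets.tsv, stat_records.tsv, ztest.tsv,
    selected_triplets.tsv, cox_results.tsv, networks/ (per-patient and pooled
    SIF + GraphML) and manifest.json.  Identical config + inputs give identical
    manifest counts.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {
            "cernet": _pkg_version("cernet"),
            "numpy": _pkg_version("numpy"),
            "pandas": _pkg_version("pandas"),
            "lifelines": _pkg_version("lifelines"),
        },
        "counts": {},
        "stages_completed": [],
    }
    mapping = assoc.read_id_mapping(cfg.id_mapping) if cfg.id_mapping else None

    # --- stage 1: associations -> candidate triplets -----------------------
    lnc_tables = [
        assoc.read_association_file(p, assoc.LNC_MI, collapse_arms=cfg.collapse_arms, id_mapping=mapping)
        for p in cfg.lnc_mi
    ]
    mrna_tables = [
        assoc.read_association_file(p, assoc.MRNA_MI, collapse_arms=cfg.collapse_arms, id_mapping=mapping)
        for p in cfg.mrna_mi
    ]
    lnc_mi = assoc.intersect_associations(lnc_tables)
    mrna_mi = assoc.intersect_associations(mrna_tables)
    manifest["counts"]["lnc_mi_associations"] = len(lnc_mi)
    manifest["counts"]["mrna_mi_associations"] = len(mrna_mi)
    if len(lnc_mi) == 0 or len(mrna_mi) == 0:
        raise EmptyInputError("association intersection is empty; no triplets can be assembled")

    expr = net.load_expression(cfg.expression, cfg.sample_classes)
    gene_ids = set(expr.gene_ids)
    triplets = assoc.build_initial_triplets(lnc_mi, mrna_mi, gene_ids, gene_ids, gene_ids)
    manifest["counts"]["initial_triplets"] = len(triplets)
    logger.info("assembled %d initial triplets", len(triplets))
    if not triplets:
        raise EmptyInputError("no candidate triplets: association lists do not overlap the expression matrix")
    assoc.write_triplets(outdir / "triplets.tsv", triplets)
    manifest["stages_completed"].append("associations")

    # --- stage 2: reference + perturbed networks ---------------------------
    thresholds = cfg.thresholds()
    records, excluded = net.perturb_cohort(expr, triplets, thresholds, log2p1=cfg.log2p1)
    net.write_stat_records(outdir / "stat_records.tsv", records)
    manifest["counts"]["excluded_triplets"] = len(excluded)
    manifest["counts"]["normal_samples"] = int((expr.sample_class == net.NORMAL).sum())
    manifest["counts"]["tumor_samples"] = int((expr.sample_class == net.TUMOR).sum())
    manifest["stages_completed"].append("network")

    # --- stage 3: Z-test selection -----------------------------------------
    ztab = net.ztest_statistics(records, thresholds)
    ztab.to_csv(outdir / "ztest.tsv", sep="\t", index=False)
    selected = {
        Triplet(r.lncRNA, r.miRNA, r.mRNA) for r in ztab.itertuples(index=False) if r.selected
    }
    survivors = int((ztab["m"] >= thresholds.min_samples).sum())
    manifest["counts"]["edge_filter_survivors"] = survivors
    manifest["counts"]["selected_triplets"] = len(selected)
    assoc.write_triplets(outdir / "selected_triplets.tsv", selected)
    logger.info("Z-test kept %d / %d triplets", len(selected), len(triplets))
    manifest["stages_completed"].append("selection")

    # --- stage 4: per-patient and pooled networks --------------------------
    netdir = outdir / "networks"
    if cfg.export_patient_networks:
        patient_nets = []
        for sid in sorted(expr.tumor.columns):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pn = net.patient_network(records, sid)
            pn.edges = {t: w for t, w in pn.edges.items() if t in selected}
            patient_nets.append(pn)
        export_cytoscape(patient_nets, netdir)
        export_cytoscape(patient_nets, netdir, pooled=True)
        manifest["counts"]["nonempty_patient_networks"] = sum(1 for pn in patient_nets if pn.edges)
    manifest["stages_completed"].append("export")

    # --- stage 5: prognostic screening -------------------------------------
    clinical = surv_mod.read_clinical_tsv(cfg.clinical)
    tumor_expr = expr.tumor
    outcome = surv_mod.screen_triplets(selected, tumor_expr, clinical.reset_index(), alpha=cfg.cox_alpha)
    surv_mod.cox_results_frame(outcome.results).to_csv(outdir / "cox_results.tsv", sep="\t", index=False)
    assoc.write_triplets(outdir / "prognostic_triplets.tsv", outcome.prognostic)
    manifest["counts"]["cox_fits"] = len(outcome.results)
    manifest["counts"]["cox_failures"] = len(outcome.failures)
    manifest["counts"]["prognostic_triplets"] = len(outcome.prognostic)
    manifest["stages_completed"].append("survival")

    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Cytoscape export
# ---------------------------------------------------------------------------

_RNA_TYPES = ("lncRNA", "miRNA", "mRNA")


def _triplet_graph(edge_weights: Mapping[Triplet, float | None]) -> nx.Graph:
    """Bipartite-through-miRNA graph: each triplet contributes x-z and z-y edges.

    Node attribute ``rna_type``; edge attributes ``interaction`` and, when a
    weight is given, ``delta_rho`` (the maximum over contributing triplets when
    several triplets share an edge).
    """
    g = nx.Graph()
    for t, w in edge_weights.items():
        g.add_node(t.lncrna, rna_type="lncRNA")
        g.add_node(t.mirna, rna_type="miRNA")
        g.add_node(t.mrna, rna_type="mRNA")
        for u, v, kind in ((t.lncrna, t.mirna, "lncRNA-miRNA"), (t.mirna, t.mrna, "miRNA-mRNA")):
            if g.has_edge(u, v) and w is not None:
                prev = g.edges[u, v].get("delta_rho")
                g.edges[u, v]["delta_rho"] = w if prev is None else max(prev, w)
            else:
                attrs = {"interaction": kind}
                if w is not None:
                    attrs["delta_rho"] = float(w)
                g.add_edge(u, v, **attrs)
    return g


def _write_sif(g: nx.Graph, path: Path) -> None:
    with path.open("w") as fh:
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{data['interaction']}\t{v}\n")
        for node in sorted(nx.isolates(g)):
            fh.write(f"{node}\n")


def export_cytoscape(
    networks: PatientNetwork | Iterable[PatientNetwork] | Iterable[Triplet],
    outdir: str | Path,
    *,
    pooled: bool = False,
) -> dict[str, Path]:
    """Write SIF and GraphML files loadable by Cytoscape.

    ``networks`` is one PatientNetwork, an iterable of them, or (for a pooled
    export) a plain collection of triplets.  With ``pooled=True`` patient
    networks are merged into a single network whose edge weight is the maximum
    delta_rho across patients.  Empty networks are written with a warning.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(networks, PatientNetwork):
        networks = [networks]
    networks = list(networks)
    written: dict[str, Path] = {}

    if networks and isinstance(networks[0], Triplet):
        graphs = {"pooled": _triplet_graph({t: None for t in networks})}
    elif pooled:
        merged: dict[Triplet, float] = {}
        for pn in networks:
            for t, w in pn.edges.items():
                merged[t] = max(merged.get(t, 0.0), w)
        graphs = {"pooled": _triplet_graph(merged)}
    else:
        graphs = {pn.sample_id: _triplet_graph(pn.edges) for pn in networks}

    for name, g in graphs.items():
        if g.number_of_edges() == 0:
            warnings.warn(f"network {name!r} is empty", stacklevel=2)
        sif = outdir / f"{name}.sif"
        gml = outdir / f"{name}.graphml"
        _write_sif(g, sif)
        nx.write_graphml(g, gml)
        written[f"{name}.sif"] = sif
        written[f"{name}.graphml"] = gml
    return written
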