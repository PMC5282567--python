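"""End-to-end orchestration: simulate -> DE -> targets -> network -> enrichment -> biomarker.

A run is driven by one RunConfig (YAML-friendly dict of per-stage
parameters plus a single root seed). Outputs are plain text (TSV / FASTA /
BED / GMT / GraphML / JSON) under a fixed directory layout; identical
config + seed reproduces byte-identical files, with wall-clock timestamps
quarantined so they never enter determinism comparisons.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from . import biomarker as bm
from . import enrichment as en
from . import network as nw
from . import simulate as sim
from . import targets as tg
from .expression import DETABLE_COLUMNS, ExpressionMatrix, differential_expression

logger = logging.getLogger(__name__)

STAGES = ("simulate", "de", "targets", "network", "enrich", "biomarker")


@dataclass
class RunConfig:
    """Everything one pipeline run needs. ``seed`` governs all randomness."""

    outdir: str = "cernet_run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    simulation: dict = field(default_factory=dict)
    de: dict = field(default_factory=lambda: {
        "method": "auto", "fc_threshold": 2.0, "q_threshold": 0.05,
        "log2fc_floor": 1.5, "p_floor": 0.01, "copy_floor": 30.0,
        "signal_floor": 500.0, "adjust": "bh"})
    targets: dict = field(default_factory=lambda: {
        "cis_window": 100_000, "r_threshold": 0.9, "trans_method": "pearson",
        "min_site_type": "7mer-m8"})
    network: dict = field(default_factory=lambda: {"gate": "de", "require_r": None})
    enrichment: dict = field(default_factory=lambda: {
        "min_term_size": 3, "q_threshold": 0.05})
    biomarker: dict = field(default_factory=lambda: {
        "reference_gene": "GAPDH", "calibrator_group": "control",
        "target_gene": None, "correlation_method": "spearman"})
    inputs: dict = field(default_factory=dict)  # user-supplied file overrides

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        if self.stages.get("simulate") and self.seed is None:
            raise ValueError("seed is mandatory when simulation is enabled")
        for path in self.inputs.values():
            if not Path(path).exists():
                raise FileNotFoundError(f"input file {path!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def semantic_dict(self) -> dict:
        """Everything that affects results (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.semantic_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _input(config: RunConfig, outdir: Path, key: str, default: str) -> Path:
    return Path(config.inputs.get(key, outdir / default))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the RunReport."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    counts: dict = {}
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s\t%(levelname)s\t%(message)s"))
    stage_logger = logging.getLogger("cernet.run")
    stage_logger.setLevel(logging.INFO)
    stage_logger.addHandler(handler)
    try:
        _run_stages(config, outdir, counts, stage_logger)
    except Exception as exc:
        failed_marker.write_text(str(exc) + "\n")
        raise
    finally:
        stage_logger.removeHandler(handler)
        handler.close()
    report = {
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "stages": {s: bool(config.stages.get(s, True)) for s in STAGES},
        "counts": counts,
        "timestamps": {"started": t0, "finished": time.time()},
    }
    io.write_json(report, outdir / "report.json")
    return report


def _run_stages(config: RunConfig, outdir: Path, counts: dict,
                log: logging.Logger) -> None:
    if config.stages.get("simulate", True):
        try:
            sim_config = sim.SimulationConfig(seed=config.seed, **config.simulation)
            truth = sim.simulate_all(sim_config, outdir / "sim")
        except Exception as exc:
            raise StageError("simulate", exc) from exc
        counts["simulate"] = {
            "de_features": len(truth.de_features),
            "triads": len(truth.triads),
            "planted_sites": len(truth.planted_sites),
        }
        log.info("simulate\tde_features=%d\ttriads=%d",
                 len(truth.de_features), len(truth.triads))

    de_tables: dict[str, pd.DataFrame] = {}
    expr: dict[str, ExpressionMatrix] = {}
    if config.stages.get("de", True):
        try:
            counts["de"] = {}
            groups_path = _input(config, outdir, "groups", "sim/groups.tsv")
            for cls, fname in (("mirna", "mirna_expr.tsv"),
                               ("lncrna", "lncrna_expr.tsv"),
                               ("mrna", "mrna_expr.tsv")):
                expr_path = _input(config, outdir, f"{cls}_expr", f"sim/{fname}")
                matrix = ExpressionMatrix.from_tsv(expr_path, groups_path, cls)
                expr[cls] = matrix
                table = differential_expression(matrix, **config.de)
                io.write_tsv(table, outdir / "de" / f"de_{cls}.tsv")
                de_tables[cls] = table
                counts["de"][cls] = {
                    "up": int((table["direction"] == "up").sum()),
                    "down": int((table["direction"] == "down").sum()),
                    "candidates": int(table["passes_candidate"].sum()),
                }
                log.info("de\tclass=%s\tup=%d\tdown=%d", cls,
                         counts["de"][cls]["up"], counts["de"][cls]["down"])
        except StageError:
            raise
        except Exception as exc:
            raise StageError("de", exc) from exc
    else:
        for cls in ("mirna", "lncrna", "mrna"):
            path = _input(config, outdir, f"de_{cls}", f"de/de_{cls}.tsv")
            if Path(path).exists():
                de_tables[cls] = io.read_tsv(path)

    if config.stages.get("targets", True):
        try:
            mirnas = [tg.MatureMiRNA(i, s) for i, s in
                      io.read_fasta(_input(config, outdir, "mirna_fa", "sim/mirna.fa")).items()]
            utrs = [tg.TranscriptSeq(i, "utr3", s) for i, s in
                    io.read_fasta(_input(config, outdir, "utr_fa", "sim/utr.fa")).items()]
            lncs = [tg.TranscriptSeq(i, "lncrna", s) for i, s in
                    io.read_fasta(_input(config, outdir, "lnc_fa", "sim/lncrna.fa")).items()]
            pairs = tg.seed_pairs(mirnas, utrs, config.targets["min_site_type"])
            pairs += tg.seed_pairs(mirnas, lncs, config.targets["min_site_type"])
            bed = io.read_bed(_input(config, outdir, "bed", "sim/loci.bed"))
            loci = [tg.GeneLocus(r.name, r.chrom, r.start, r.end, r.strand)
                    for r in bed.itertuples(index=False)]
            lnc_loci = [l for l in loci if l.id.startswith("lnc")]
            mrna_loci = [l for l in loci if not l.id.startswith("lnc")]
            pairs += tg.cis_pairs(lnc_loci, mrna_loci, config.targets["cis_window"])
            if expr.get("lncrna") is not None and expr.get("mrna") is not None:
                pairs += tg.trans_pairs(expr["lncrna"], expr["mrna"],
                                        config.targets["r_threshold"],
                                        config.targets["trans_method"])
            table_path = config.inputs.get("interaction_table")
            if table_path:
                pairs += tg.load_interaction_table(table_path)
            io.write_tsv(tg.pairs_to_frame(pairs), outdir / "targets" / "pairs.tsv")
            by_ev: dict[str, int] = {}
            for p in pairs:
                by_ev[p.evidence] = by_ev.get(p.evidence, 0) + 1
            counts["targets"] = by_ev
            log.info("targets\t%s", json.dumps(by_ev, sort_keys=True))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("targets", exc) from exc

    if config.stages.get("network", True):
        try:
            pairs = tg.frame_to_pairs(io.read_tsv(
                _input(config, outdir, "pairs", "targets/pairs.tsv")))
            edges = nw.anticorrelation_filter(
                pairs, de_tables, gate=config.network.get("gate", "de"),
                require_r=config.network.get("require_r"),
                expr=expr if config.network.get("require_r") else None)
            split = {kind: [] for kind in nw.PAIRWISE_KINDS}
            for e in edges:
                for kind, classes in nw.PAIRWISE_KINDS.items():
                    if {e.regulator_class, e.target_class} == set(classes):
                        split[kind].append(e)
            nets = {kind: nw.build_pair_network(es, kind)
                    for kind, es in split.items()}
            (mi_net, mi_sum), (l_net, l_sum) = nw.integrate_tripartite(
                nets["mirna_mrna"], nets["mirna_lncrna"], nets["lncrna_mrna"])
            ndir = outdir / "network"
            edge_frame = pd.DataFrame(
                [(e.regulator, e.regulator_class, e.regulator_direction,
                  e.target, e.target_class, e.target_direction, e.evidence, e.score)
                 for e in edges],
                columns=["regulator", "regulator_class", "regulator_direction",
                         "target", "target_class", "target_direction",
                         "evidence", "score"])
            io.write_tsv(edge_frame, ndir / "edges.tsv")
            for kind, net in nets.items():
                nw.export_network(net, "graphml", ndir / f"{kind}.graphml")
            nw.export_network(mi_net, "graphml", ndir / "mirna_mrna_lncrna.graphml")
            nw.export_network(l_net, "graphml", ndir / "lncrna_mirna_mrna.graphml")
            nw.export_network(l_net, "sif", ndir / "lncrna_mirna_mrna.sif")
            io.write_tsv(nw.triads_to_frame(l_sum, l_net.edges), ndir / "triads.tsv")
            io.write_json({"mirna_centered": mi_sum.venn,
                           "lncrna_centered": l_sum.venn}, ndir / "venn.json")
            counts["network"] = {
                "edges": len(edges),
                **{kind: net.n_edges for kind, net in nets.items()},
                "triads": len(l_sum.triads),
            }
            log.info("network\tedges=%d\ttriads=%d", len(edges), len(l_sum.triads))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("network", exc) from exc

    if config.stages.get("enrich", True):
        try:
            gmt_path = _input(config, outdir, "gmt", "sim/gene_sets.gmt")
            collection = en.GeneSetCollection.from_gmt(gmt_path)
            mrna_table = de_tables["mrna"]
            universe = frozenset(mrna_table["feature"]) & frozenset().union(
                *(m for _, m in collection.terms.values()))
            collection = collection.intersected(universe)
            query = set(mrna_table.loc[mrna_table["passes_de"], "feature"]) & universe
            result = en.enrich(query, collection, **config.enrichment)
            io.write_tsv(result, outdir / "enrich" / "enrichment.tsv")
            counts["enrich"] = {"terms_tested": int(len(result)),
                                "significant": int(result["significant"].sum())
                                if len(result) else 0}
            log.info("enrich\ttested=%d\tsignificant=%d",
                     counts["enrich"]["terms_tested"], counts["enrich"]["significant"])
        except StageError:
            raise
        except Exception as exc:
            raise StageError("enrich", exc) from exc

    if config.stages.get("biomarker", True):
        try:
            ct = io.read_tsv(_input(config, outdir, "ct", "sim/ct.tsv"))
            clinical = io.read_tsv(_input(config, outdir, "clinical", "sim/clinical.tsv"))
            target_gene = config.biomarker.get("target_gene")
            if target_gene is None:
                candidates = sorted(set(ct["gene"]) - set(sim.REFERENCE_GENES))
                muscle_genes = [g for g in candidates if g.startswith("gene")]
                target_gene = (muscle_genes or candidates)[0]
            rel = bm.ddct(ct, target_gene, config.biomarker["reference_gene"],
                          config.biomarker["calibrator_group"])
            bdir = outdir / "biomarker"
            io.write_tsv(rel, bdir / "rq.tsv")
            muscle_roc = bm.roc(rel["rq"].to_numpy(), rel["group"].to_numpy())
            serum_roc = bm.roc(clinical["serum_marker"].to_numpy(),
                               clinical["group"].to_numpy())
            lactate_roc = bm.roc(clinical["lactate"].to_numpy(),
                                 clinical["group"].to_numpy())
            comparison = bm.compare_markers(serum_roc, lactate_roc)
            io.write_tsv(serum_roc.thresholds, bdir / "roc_thresholds.tsv")
            method = config.biomarker.get("correlation_method", "spearman")
            correlations = {}
            for cov in ("lactate", "nmdas", "mutation_load"):
                if cov in clinical.columns:
                    res = bm.correlate(clinical["serum_marker"], clinical[cov],
                                       method=method, name=cov)
                    correlations[cov] = {"r": res.r, "p": res.p, "n": res.n}
            summary = {
                "muscle_marker": {
                    "gene": target_gene,
                    "auc": muscle_roc.auc,
                    "ci": [muscle_roc.ci_lo, muscle_roc.ci_hi],
                },
                "serum_marker": {
                    "auc": serum_roc.auc,
                    "ci": [serum_roc.ci_lo, serum_roc.ci_hi],
                    "orientation": serum_roc.orientation,
                    "cutoff": serum_roc.optimal_cutoff,
                    "sensitivity": serum_roc.sensitivity,
                    "specificity": serum_roc.specificity,
                },
                "lactate": {"auc": lactate_roc.auc,
                            "ci": [lactate_roc.ci_lo, lactate_roc.ci_hi]},
                "serum_vs_lactate": {"delta_auc": comparison.delta_auc,
                                     "p": comparison.p},
                "correlations": correlations,
            }
            io.write_json(summary, bdir / "biomarker_summary.json")
            counts["biomarker"] = {"serum_auc": serum_roc.auc,
                                   "lactate_auc": lactate_roc.auc,
                                   "muscle_auc": muscle_roc.auc}
            log.info("biomarker\tserum_auc=%.3f\tlactate_auc=%.3f",
                     serum_roc.auc, lactate_roc.auc)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("biomarker", exc) from exc


def output_hashes(outdir: str | Path) -> dict[str, str]:
    """SHA-256 of every run output, with timestamps canonicalized away."""
    outdir = Path(outdir)
    hashes = {}
    for path in sorted(outdir.rglob("*")):
        if not path.is_file() or path.name == "run.log":
            continue
        rel = str(path.relative_to(outdir))
        data = path.read_bytes()
        if path.name == "report.json":
            obj = json.loads(data)
            obj.pop("timestamps", None)
            data = json.dumps(obj, sort_keys=True).encode()
        hashes[rel] = hashlib.sha256(data).hexdigest()
    return hashes


def validate_outputs(outdir: str | Path) -> list[str]:
    """Schema and referential-integrity checks on a completed run directory.

    Returns a list of violation messages (empty = clean).
    """
    outdir = Path(outdir)
    violations: list[str] = []
    report_path = outdir / "report.json"
    if not report_path.exists():
        return [f"missing {report_path.name}"]
    try:
        report = io.read_json(report_path)
    except Exception as exc:
        return [f"report.json unreadable: {exc}"]
    stages = report.get("stages", {})

    de_features: set[str] = set()
    directions: dict[str, str] = {}
    if stages.get("de"):
        for cls in ("mirna", "lncrna", "mrna"):
            path = outdir / "de" / f"de_{cls}.tsv"
            if not path.exists():
                violations.append(f"missing de/de_{cls}.tsv")
                continue
            table = io.read_tsv(path)
            missing = set(DETABLE_COLUMNS) - set(table.columns)
            if missing:
                violations.append(f"de_{cls}.tsv missing columns {sorted(missing)}")
                continue
            bad_fc = np.abs(table["fc"] - 2.0 ** table["log2fc"]) > 1e-6 * table["fc"]
            if bad_fc.any():
                violations.append(f"de_{cls}.tsv: FC != 2^log2FC for "
                                  f"{int(bad_fc.sum())} rows")
            if ((table["q"] < table["p"] - 1e-9) | (table["q"] > 1)).any():
                violations.append(f"de_{cls}.tsv: q outside [p, 1]")
            de_features |= set(table["feature"])
            directions.update(zip(table["feature"], table["direction"]))

    if stages.get("targets"):
        path = outdir / "targets" / "pairs.tsv"
        if not path.exists():
            violations.append("missing targets/pairs.tsv")
        else:
            pairs = io.read_tsv(path)
            self_pairs = pairs["source"] == pairs["target"]
            if self_pairs.any():
                violations.append(f"pairs.tsv: {int(self_pairs.sum())} self-pairs")

    if stages.get("network"):
        path = outdir / "network" / "edges.tsv"
        if not path.exists():
            violations.append("missing network/edges.tsv")
        else:
            edges = io.read_tsv(path)
            for row in edges.itertuples():
                for endpoint in (row.regulator, row.target):
                    if de_features and endpoint not in de_features:
                        violations.append(
                            f"edges.tsv row {row.Index}: unknown feature {endpoint!r}")
                if row.regulator_direction == row.target_direction:
                    violations.append(
                        f"edges.tsv row {row.Index}: endpoints share direction")
            edge_set = set(zip(edges["regulator"], edges["target"]))
            tri_path = outdir / "network" / "triads.tsv"
            if tri_path.exists():
                triads = io.read_tsv(tri_path)
                for row in triads.itertuples():
                    if (row.mirna, row.lncrna) not in edge_set or \
                            (row.mirna, row.mrna) not in edge_set:
                        violations.append(
                            f"triads.tsv row {row.Index}: edges missing from edges.tsv")
            for name in ("mirna_mrna_lncrna.graphml", "lncrna_mirna_mrna.graphml"):
                gpath = outdir / "network" / name
                if not gpath.exists():
                    violations.append(f"missing network/{name}")
                    continue
                try:
                    nw.read_graphml(gpath)
                except Exception as exc:
                    violations.append(f"{name}: parse failure ({exc})")

    if stages.get("enrich"):
        path = outdir / "enrich" / "enrichment.tsv"
        if not path.exists():
            violations.append("missing enrich/enrichment.tsv")
        else:
            table = io.read_tsv(path)
            if len(table):
                if ((table["k"] > table[["K", "n"]].min(axis=1))).any():
                    violations.append("enrichment.tsv: k > min(K, n)")
                if ((table["rich_factor"] < 0) | (table["rich_factor"] > 1)).any():
                    violations.append("enrichment.tsv: rich_factor outside [0, 1]")

    if stages.get("biomarker"):
        path = outdir / "biomarker" / "biomarker_summary.json"
        if not path.exists():
            violations.append("missing biomarker/biomarker_summary.json")
        else:
            summary = io.read_json(path)
            for key in ("muscle_marker", "serum_marker", "lactate"):
                auc = summary[key]["auc"]
                lo, hi = summary[key]["ci"]
                if not (lo - 1e-9 <= auc <= hi + 1e-9):
                    violations.append(f"biomarker summary: {key} CI does not bracket AUC")
    return violations
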