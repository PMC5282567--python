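"""Synthetic case-control transcriptome generator with recorded ground truth.

Emulates the statistical structure of a pooled/grouped case-control ncRNA
study: three feature-by-sample matrices (miRNA microarray signal, lncRNA
and mRNA FPKM) with planted differential-expression directions, planted
ceRNA triads (lncRNA, miRNA, mRNA) whose sequences carry real canonical
seed-match sites, genomic loci for cis pairing, qPCR Ct tables consistent
with the planted fold changes, and a binormal serum marker correlated with
clinical covariates through a Gaussian copula.

Noise is log-normal on the log2 scale (continuous intensity/FPKM value
types, not counts). All randomness derives from the single config seed;
identical configs give bit-identical outputs.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io
from .expression import ExpressionMatrix
from .targets import reverse_complement

RNA_ALPHABET = np.array(list("ACGU"))
REFERENCE_GENES = ("U6", "GAPDH", "cel-miR-39")

# stream keys: one independent generator per output kind
_STREAM = {"expression": 0, "sequences": 1, "annotation": 2,
           "qpcr": 3, "clinical": 4, "gene_sets": 5}


class SiteConstraintError(RuntimeError):
    """Raised when seed-site presence/absence cannot be satisfied."""


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults emulate the study design scale
    (20 cases vs 20 controls, 2000 features across the three classes)."""

    seed: int = 0
    n_case: int = 20
    n_control: int = 20
    n_mirna: int = 200
    n_lncrna: int = 500
    n_mrna: int = 1300
    frac_de: float = 0.1
    planted_log2fc: float = 2.0
    noise_sd: float = 0.5
    n_triads: int = 50
    utr_length: int = 400
    lnc_length: int = 600
    mirna_length: int = 22
    cis_fraction: float = 0.5
    cis_window: int = 100_000
    n_chromosomes: int = 10
    chromosome_length: int = 10_000_000
    biomarker_auc: float = 0.879
    clinical_r: dict = field(default_factory=lambda: {
        "lactate": -0.43, "nmdas": -0.644, "mutation_load": -0.709})
    ct_noise_sd: float = 0.2
    triad_factor_loading: float = 0.3

    def __post_init__(self) -> None:
        counts = {"n_case": self.n_case, "n_control": self.n_control,
                  "n_mirna": self.n_mirna, "n_lncrna": self.n_lncrna,
                  "n_mrna": self.n_mrna, "utr_length": self.utr_length,
                  "lnc_length": self.lnc_length, "mirna_length": self.mirna_length,
                  "n_chromosomes": self.n_chromosomes,
                  "chromosome_length": self.chromosome_length}
        for name, val in counts.items():
            if int(val) != val or val <= 0:
                raise ValueError(f"{name} must be a positive integer, got {val!r}")
        for name, val in (("frac_de", self.frac_de), ("planted_log2fc", self.planted_log2fc),
                          ("noise_sd", self.noise_sd), ("cis_fraction", self.cis_fraction),
                          ("biomarker_auc", self.biomarker_auc),
                          ("ct_noise_sd", self.ct_noise_sd)):
            if not math.isfinite(val):
                raise ValueError(f"{name} must be finite")
        if not 0 <= self.frac_de < 1:
            raise ValueError("frac_de must lie in [0, 1)")
        if not 0 <= self.cis_fraction <= 1:
            raise ValueError("cis_fraction must lie in [0, 1]")
        if not 0.5 <= self.biomarker_auc < 1:
            raise ValueError("biomarker_auc must lie in [0.5, 1)")
        for name, r in self.clinical_r.items():
            if not (math.isfinite(r) and abs(r) < 1):
                raise ValueError(f"clinical_r[{name!r}] must satisfy |r| < 1")
        if self.noise_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.n_triads < 0 or int(self.n_triads) != self.n_triads:
            raise ValueError("n_triads must be a non-negative integer")
        if self.mirna_length < 16:
            raise ValueError("mirna_length must be >= 16")
        n_de_lnc = round(self.frac_de * self.n_lncrna)
        n_de_mrna = round(self.frac_de * self.n_mrna)
        n_de_mirna = round(self.frac_de * self.n_mirna)
        if self.n_triads > 0:
            if self.n_triads > min(n_de_lnc, n_de_mrna) or n_de_mirna < 1:
                raise ValueError(
                    "n_triads exceeds the number of DE lncRNAs/mRNAs implied by "
                    "frac_de; raise frac_de or feature counts")
        if self.cis_window > self.chromosome_length:
            raise ValueError("cis_window exceeds the chromosome model length")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAM[stream]])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})


@dataclass
class SyntheticTruth:
    """Ground-truth record accompanying one simulated dataset."""

    de_features: dict[str, str] = field(default_factory=dict)  # id -> up/down
    triads: list[tuple[str, str, str]] = field(default_factory=list)  # (lnc, mir, gene)
    planted_sites: list[tuple[str, str, tuple[int, int]]] = field(default_factory=list)
    biomarker_params: dict = field(default_factory=dict)
    planted_correlations: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        io.write_json({
            "de_features": self.de_features,
            "triads": [list(t) for t in self.triads],
            "planted_sites": [[m, t, list(iv)] for m, t, iv in self.planted_sites],
            "biomarker_params": self.biomarker_params,
            "planted_correlations": self.planted_correlations,
        }, path)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = io.read_json(path)
        return cls(
            de_features=d["de_features"],
            triads=[tuple(t) for t in d["triads"]],
            planted_sites=[(m, t, tuple(iv)) for m, t, iv in d["planted_sites"]],
            biomarker_params=d["biomarker_params"],
            planted_correlations=d["planted_correlations"],
        )


def _feature_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}-{i:04d}" for i in range(1, n + 1)]


def mirna_ids(config: SimulationConfig) -> list[str]:
    return _feature_ids("miR", config.n_mirna)


def lncrna_ids(config: SimulationConfig) -> list[str]:
    return _feature_ids("lnc", config.n_lncrna)


def mrna_ids(config: SimulationConfig) -> list[str]:
    return _feature_ids("gene", config.n_mrna)


def generate_expression(config: SimulationConfig
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix,
                                   ExpressionMatrix, SyntheticTruth]:
    """Simulate the three feature-by-sample matrices plus the truth record.

    log2 values = feature baseline + group effect (+/- planted_log2fc in
    cases for DE features) + shared triad latent factor (opposite-sign
    loading on the miRNA vs its partners) + N(0, noise_sd); values are
    2**log2 so matrices are strictly positive. Baselines are drawn high
    enough that planted features clear the abundance screens.
    """
    rng = config.rng("expression")
    ids = {"mirna": mirna_ids(config), "lncrna": lncrna_ids(config),
           "mrna": mrna_ids(config)}
    n_de = {cls: round(config.frac_de * len(ids[cls])) for cls in ids}

    de_sets = {cls: sorted(rng.choice(ids[cls], size=n_de[cls], replace=False))
               for cls in ids}
    truth = SyntheticTruth()

    # triad members come from the DE sets: lncRNA/mRNA without replacement,
    # miRNAs may repeat (one miRNA can anchor several triads)
    triad_lnc = list(de_sets["lncrna"][:config.n_triads])
    triad_gene = list(de_sets["mrna"][:config.n_triads])
    triad_mir = (list(rng.choice(de_sets["mirna"], size=config.n_triads,
                                 replace=True)) if config.n_triads else [])
    truth.triads = list(zip(triad_lnc, triad_mir, triad_gene))

    directions: dict[str, str] = {}
    for m in sorted(set(triad_mir)):
        directions[m] = "up" if rng.random() < 0.5 else "down"
    for (l, m, g) in truth.triads:
        partner_dir = "down" if directions[m] == "up" else "up"
        directions[l] = partner_dir
        directions[g] = partner_dir
    for cls in ids:
        for f in de_sets[cls]:
            if f not in directions:
                directions[f] = "up" if rng.random() < 0.5 else "down"
    truth.de_features = dict(sorted(directions.items()))

    samples = ([f"case{i:02d}" for i in range(1, config.n_case + 1)]
               + [f"control{i:02d}" for i in range(1, config.n_control + 1)])
    groups = pd.Series(["case"] * config.n_case + ["control"] * config.n_control,
                       index=samples)
    case_mask = (groups == "case").to_numpy()

    baseline_range = {"mirna": (9.5, 13.0), "lncrna": (5.5, 9.0), "mrna": (5.5, 9.0)}
    matrices = {}
    triad_factors = rng.normal(size=(config.n_triads, len(samples)))
    loading_by_feature: dict[str, list[tuple[int, float]]] = {}
    for t, (l, m, g) in enumerate(truth.triads):
        a = config.triad_factor_loading
        loading_by_feature.setdefault(m, []).append((t, -a))
        loading_by_feature.setdefault(l, []).append((t, a))
        loading_by_feature.setdefault(g, []).append((t, a))

    for cls in ("mirna", "lncrna", "mrna"):
        feats = ids[cls]
        lo, hi = baseline_range[cls]
        base = rng.uniform(lo, hi, size=len(feats))
        log2 = np.tile(base[:, None], (1, len(samples)))
        for i, f in enumerate(feats):
            d = directions.get(f)
            if d is not None:
                shift = config.planted_log2fc if d == "up" else -config.planted_log2fc
                log2[i, case_mask] += shift
            for t, a in loading_by_feature.get(f, []):
                log2[i, :] += a * triad_factors[t]
        log2 += rng.normal(scale=config.noise_sd, size=log2.shape) \
            if config.noise_sd > 0 else 0.0
        values = pd.DataFrame(2.0 ** log2, index=feats, columns=samples)
        lnc_cat = None
        if cls == "lncrna":
            cats = rng.choice(["antisense", "intergenic", "intronic", "processed_transcript"],
                              size=len(feats), p=[0.35, 0.35, 0.15, 0.15])
            lnc_cat = pd.Series(cats, index=feats)
        matrices[cls] = ExpressionMatrix(values, groups.copy(), cls, lnc_cat)
    return matrices["mirna"], matrices["lncrna"], matrices["mrna"], truth


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(RNA_ALPHABET[rng.integers(0, 4, size=length)])


def _scan_strong_sites(seq: str, rc7_map: dict[str, str]
                       ) -> dict[str, list[tuple[int, int]]]:
    """All 7mer-m8/8mer sites in one pass via a 7mer lookup table."""
    hits: dict[str, list[tuple[int, int]]] = {}
    for i in range(len(seq) - 6):
        mir = rc7_map.get(seq[i:i + 7])
        if mir is not None:
            end = i + 8 if seq[i + 7:i + 8] == "A" else i + 7
            hits.setdefault(mir, []).append((i, end))
    return hits


def generate_sequences(config: SimulationConfig, truth: SyntheticTruth,
                       max_retries: int = 200
                       ) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Mature miRNA, mRNA-3'UTR and lncRNA sequences honouring the truth.

    Every planted (miRNA, target) edge gets >= 1 exact 7mer-m8 or 8mer site
    for that miRNA; all other (miRNA, target) combinations carry none
    (rejection-sampled; weak 6mer/7mer-A1 sites may occur by chance and are
    tolerated). Planted site intervals are recorded in the truth.
    """
    rng = config.rng("sequences")
    mirnas: dict[str, str] = {}
    seeds_seen: set[str] = set()
    for mid in mirna_ids(config):
        for _ in range(1000):
            seq = _random_rna(rng, config.mirna_length)
            if seq[1:8] not in seeds_seen:
                seeds_seen.add(seq[1:8])
                mirnas[mid] = seq
                break
        else:
            raise SiteConstraintError("could not draw a unique miRNA seed")

    rc7_map = {reverse_complement(seq[1:8]): mid for mid, seq in mirnas.items()}
    edges: dict[str, set[str]] = {}
    for l, m, g in truth.triads:
        edges.setdefault(l, set()).add(m)
        edges.setdefault(g, set()).add(m)

    def make_target(tid: str, length: int) -> str:
        # Plant the required sites, then repair chance strong sites of other
        # miRNAs by point mutation (pure rejection would almost never accept:
        # a few hundred 7mer windows against a few hundred seeds yields
        # several chance matches per target on average).
        wanted = sorted(edges.get(tid, set()))
        for _ in range(max_retries):
            seq = list(_random_rna(rng, length))
            occupied: list[tuple[int, int]] = []
            ok = True
            for mid in wanted:
                site = reverse_complement(mirnas[mid][1:8])
                if rng.random() < 0.5:
                    site += "A"  # 8mer
                placed = False
                for _ in range(50):
                    pos = int(rng.integers(0, length - len(site) + 1))
                    if all(pos + len(site) <= s or pos >= e for s, e in occupied):
                        seq[pos:pos + len(site)] = list(site)
                        occupied.append((pos, pos + len(site)))
                        placed = True
                        break
                if not placed:
                    ok = False
                    break
            if not ok:
                continue
            occupied_pos = {p for s, e in occupied for p in range(s, e)}
            for _ in range(100):
                joined = "".join(seq)
                hits = _scan_strong_sites(joined, rc7_map)
                offending = [iv for mid, ivs in hits.items() if mid not in wanted
                             for iv in ivs]
                if not offending:
                    if set(hits) == set(wanted):
                        for mid in wanted:
                            for interval in hits[mid]:
                                truth.planted_sites.append((mid, tid, interval))
                        return joined
                    break  # a planted site was lost; resample
                repaired = True
                for s, e in offending:
                    free = [p for p in range(s, e) if p not in occupied_pos]
                    if not free:
                        repaired = False
                        break
                    p = free[int(rng.integers(0, len(free)))]
                    choices = [b for b in "ACGU" if b != seq[p]]
                    seq[p] = choices[int(rng.integers(0, 3))]
                if not repaired:
                    break  # unrepairable overlap with a planted site; resample
        raise SiteConstraintError(
            f"could not satisfy site constraints for target {tid!r} "
            f"after {max_retries} attempts")

    utrs = {gid: make_target(gid, config.utr_length) for gid in mrna_ids(config)}
    lncs = {lid: make_target(lid, config.lnc_length) for lid in lncrna_ids(config)}
    return mirnas, utrs, lncs


def generate_annotation(truth: SyntheticTruth, config: SimulationConfig) -> pd.DataFrame:
    """BED loci on a pseudo-genome (n_chromosomes x chromosome_length).

    round(cis_fraction * n_triads) of the triad lncRNA-mRNA pairs are placed
    within the cis window on one chromosome; the remaining triad pairs go on
    distinct chromosomes; non-triad features are placed uniformly.
    """
    rng = config.rng("annotation")
    chroms = [f"chr{i}" for i in range(1, config.n_chromosomes + 1)]
    n_cis = round(config.cis_fraction * len(truth.triads))
    order = rng.permutation(len(truth.triads))
    cis_idx = set(order[:n_cis].tolist())

    rows = []

    def locus_length() -> int:
        return int(rng.integers(1_000, 10_000))

    def random_locus(name: str, exclude_chrom: str | None = None) -> tuple[str, int, int]:
        options = [c for c in chroms if c != exclude_chrom]
        chrom = options[int(rng.integers(0, len(options)))]
        length = locus_length()
        start = int(rng.integers(0, config.chromosome_length - length))
        return chrom, start, start + length

    placed: dict[str, tuple[str, int, int]] = {}
    for t, (l, _, g) in enumerate(truth.triads):
        if t in cis_idx:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            llen, glen = locus_length(), locus_length()
            max_span = llen + glen + config.cis_window
            lstart = int(rng.integers(0, config.chromosome_length - max_span))
            gap = int(rng.integers(0, config.cis_window + 1))
            gstart = lstart + llen + gap
            placed[l] = (chrom, lstart, lstart + llen)
            placed[g] = (chrom, gstart, gstart + glen)
        else:
            placed[l] = random_locus(l)
            placed[g] = random_locus(g, exclude_chrom=placed[l][0])

    for lid in lncrna_ids(config):
        if lid not in placed:
            placed[lid] = random_locus(lid)
    for gid in mrna_ids(config):
        if gid not in placed:
            placed[gid] = random_locus(gid)

    for name in lncrna_ids(config) + mrna_ids(config):
        chrom, start, end = placed[name]
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((chrom, start, end, name, 0, strand))
    return pd.DataFrame(rows, columns=io.BED_COLUMNS)


def generate_qpcr(truth: SyntheticTruth, config: SimulationConfig,
                  n_replicates: int = 3) -> pd.DataFrame:
    """Triplicate Ct tables for triad-member genes plus reference analogues.

    For a gene with planted signed log2FC d (positive = up in case), case
    samples have expected Ct lower by d; references are group-invariant. A
    per-sample global Ct offset emulates loading variation, so reference
    normalization is required to recover the planted fold change.
    """
    rng = config.rng("qpcr")
    genes = sorted({f for triad in truth.triads for f in triad})
    genes.extend(REFERENCE_GENES)
    samples = ([f"case{i:02d}" for i in range(1, config.n_case + 1)]
               + [f"control{i:02d}" for i in range(1, config.n_control + 1)])
    group = {s: ("case" if s.startswith("case") else "control") for s in samples}

    base_ct = {g: float(rng.uniform(18.0, 28.0)) for g in genes}
    sample_offset = {s: float(rng.normal(scale=0.3)) for s in samples}
    signed_lfc = {}
    for g in genes:
        d = truth.de_features.get(g)
        signed_lfc[g] = (config.planted_log2fc if d == "up"
                         else -config.planted_log2fc if d == "down" else 0.0)

    rows = []
    for s in samples:
        for g in genes:
            mu = base_ct[g] + sample_offset[s]
            if group[s] == "case":
                mu -= signed_lfc[g]
            noise = (rng.normal(scale=config.ct_noise_sd, size=n_replicates)
                     if config.ct_noise_sd > 0 else np.zeros(n_replicates))
            for rep in range(1, n_replicates + 1):
                rows.append((s, group[s], g, rep, mu + noise[rep - 1]))
    df = pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])
    df["ct"] = df["ct"].clip(0.5, 45.0)
    return df


def required_marker_separation(auc: float) -> float:
    """Delta/sigma of a binormal marker achieving a target AUC:
    AUC = Phi(Delta / (sigma * sqrt(2)))."""
    return math.sqrt(2.0) * float(stats.norm.ppf(auc))


def generate_clinical(config: SimulationConfig,
                      truth: SyntheticTruth | None = None) -> pd.DataFrame:
    """Serum marker plus clinical covariates via a Gaussian copula.

    The latent marker is N(0,1) in controls and N(-Delta,1) in cases with
    Delta = sqrt(2) * Phi^-1(biomarker_auc) (marker reduced in cases). Each
    covariate's latent normal is correlated with the marker's copula normal
    at rho_pearson = 2 sin(pi * rho_s / 6) so the planted Spearman rho_s is
    hit in expectation; marginals are then transformed to plausible
    lactate / severity-score / mutation-load scales (monotone, so rank
    correlations and AUC are preserved). The exported marker is
    2**(0.5 * latent), an rq-like positive scale.
    """
    rng = config.rng("clinical")
    n_case, n_control = config.n_case, config.n_control
    n = n_case + n_control
    delta = required_marker_separation(config.biomarker_auc)

    corr_names = sorted(config.clinical_r)
    rho_s = np.array([config.clinical_r[c] for c in corr_names])
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
    # single-factor structure: marker latent + independent residuals.
    # assemble the implied full correlation matrix and verify it is PSD.
    k = len(corr_names)
    full = np.eye(k + 1)
    full[0, 1:] = rho_p
    full[1:, 0] = rho_p
    for i in range(k):
        for j in range(k):
            if i != j:
                full[1 + i, 1 + j] = rho_p[i] * rho_p[j]
    eigvals = np.linalg.eigvalsh(full)
    if eigvals.min() < -1e-9:
        raise ValueError("infeasible correlation matrix (not positive semi-definite)")

    latent = np.concatenate([rng.normal(-delta, 1.0, size=n_case),
                             rng.normal(0.0, 1.0, size=n_control)])
    groups = np.array(["case"] * n_case + ["control"] * n_control)
    w_case, w_control = n_case / n, n_control / n
    u = w_case * stats.norm.cdf(latent + delta) + w_control * stats.norm.cdf(latent)
    z_m = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))

    out = pd.DataFrame({
        "sample": ([f"case{i:02d}" for i in range(1, n_case + 1)]
                   + [f"control{i:02d}" for i in range(1, n_control + 1)]),
        "group": groups,
        "serum_marker": 2.0 ** (0.5 * latent),
    })
    transforms = {
        "lactate": lambda z: 1.8 * np.exp(0.45 * z),       # mmol/L, right-skewed
        "nmdas": lambda z: 60.0 * stats.norm.cdf(z),       # severity score scale
        "mutation_load": lambda z: 100.0 * stats.norm.cdf(z),  # percent heteroplasmy
    }
    for name, rp in zip(corr_names, rho_p):
        eps = rng.normal(size=n)
        z_c = rp * z_m + math.sqrt(max(0.0, 1.0 - rp ** 2)) * eps
        out[name] = transforms.get(name, lambda z: z)(z_c)

    if truth is not None:
        truth.biomarker_params = {
            "mu_case": -delta, "mu_control": 0.0, "sd": 1.0,
            "target_auc": config.biomarker_auc, "delta_over_sigma": delta,
        }
        truth.planted_correlations = {c: float(config.clinical_r[c]) for c in corr_names}
    return out


def generate_gene_sets(truth: SyntheticTruth, config: SimulationConfig,
                       n_terms: int = 60, n_enriched: int = 6
                       ) -> dict[str, tuple[str, list[str]]]:
    """A synthetic GMT-style collection over the mRNA universe.

    Mostly random terms, plus ``n_enriched`` terms whose members are drawn
    preferentially from the planted DE mRNAs, so that over-representation
    analysis of the DE set has signal to find.
    """
    rng = config.rng("gene_sets")
    universe = np.array(mrna_ids(config))
    de_mrna = np.array(sorted(f for f in truth.de_features if f.startswith("gene")))
    namespaces = ["BP", "MF", "CC", "KEGG"]
    terms: dict[str, tuple[str, list[str]]] = {}
    max_size = min(50, len(universe))
    for i in range(n_terms):
        ns = namespaces[i % len(namespaces)]
        size = int(rng.integers(min(5, max_size), max_size + 1))
        if i < n_enriched and len(de_mrna) >= 3:
            n_sig = min(len(de_mrna), max(3, int(round(size * 0.6))))
            sig = rng.choice(de_mrna, size=n_sig, replace=False)
            rest = rng.choice(universe, size=max(0, size - n_sig), replace=False)
            members = sorted(set(sig) | set(rest))
        else:
            members = sorted(rng.choice(universe, size=size, replace=False))
        terms[f"{ns}:T{i + 1:04d}"] = (f"synthetic term {i + 1}", members)
    return terms


def simulate_all(config: SimulationConfig, outdir: str | Path) -> SyntheticTruth:
    """Run every generator and write the full input bundle for a pipeline run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mirna, lnc, mrna, truth = generate_expression(config)
    mirna.to_tsv(outdir / "mirna_expr.tsv", outdir / "groups.tsv")
    lnc.to_tsv(outdir / "lncrna_expr.tsv")
    mrna.to_tsv(outdir / "mrna_expr.tsv")
    mir_seqs, utr_seqs, lnc_seqs = generate_sequences(config, truth)
    io.write_fasta(mir_seqs, outdir / "mirna.fa")
    io.write_fasta(utr_seqs, outdir / "utr.fa")
    io.write_fasta(lnc_seqs, outdir / "lncrna.fa")
    bed = generate_annotation(truth, config)
    io.write_bed(bed, outdir / "loci.bed")
    ct = generate_qpcr(truth, config)
    io.write_tsv(ct, outdir / "ct.tsv")
    clinical = generate_clinical(config, truth)
    io.write_tsv(clinical, outdir / "clinical.tsv")
    io.write_gmt(generate_gene_sets(truth, config), outdir / "gene_sets.gmt")
    truth.to_json(outdir / "truth.json")
    return truth
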