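"""Candidate regulator-target pair prediction.

Three evidence sources, mirroring how miRNA/lncRNA target relationships are
nominated in practice:

* canonical seed-site scanning (miRNA -> mRNA 3'UTR, miRNA -> lncRNA):
  exact Watson-Crick complementarity to the miRNA seed (nucleotides 2-8),
  classified into the standard 6mer / 7mer-A1 / 7mer-m8 / 8mer site types;
* genomic proximity for lncRNA-mRNA cis pairs (same chromosome, interval
  gap within a window);
* co-expression for lncRNA-mRNA trans pairs (|Pearson r| above a threshold
  across shared samples).

Precomputed interaction tables (e.g. database exports) can be ingested as a
fourth evidence channel.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_VALID_CLASSES = {"mirna", "lncrna", "mrna"}

#: Canonical site types, strongest first.
SITE_TYPE_ORDER = ("8mer", "7mer-m8", "7mer-A1", "6mer")
SITE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}
#: Site types treated as confident evidence for an edge.
STRONG_SITE_TYPES = ("8mer", "7mer-m8")


def normalize_rna(seq: str) -> str:
    """Uppercase and map T -> U; reject anything outside {A, C, G, U}."""
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid nucleotides {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, 5'->3'. The seed is nucleotides 2-8."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if len(self.sequence) < 16:
            raise ValueError(f"miRNA {self.id}: length must be >= 16")

    @property
    def seed(self) -> str:
        """Nucleotides 2-8 (1-based), the canonical seed region."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class TranscriptSeq:
    """A target sequence (mRNA 3'UTR or lncRNA transcript), 5'->3'."""

    id: str
    kind: str
    sequence: str

    def __post_init__(self) -> None:
        if self.kind not in ("utr3", "lncrna"):
            raise ValueError(f"unknown transcript kind {self.kind!r}")
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if len(self.sequence) < 30:
            raise ValueError(f"transcript {self.id}: length must be >= 30")


@dataclass(frozen=True)
class SeedMatch:
    """A canonical seed site on a target, 0-based half-open interval."""

    mirna: str
    target: str
    site_type: str
    start: int
    end: int


@dataclass(frozen=True)
class GeneLocus:
    """A gene locus: chromosome, 0-based half-open interval, strand."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.id}: need 0 <= start < end")


@dataclass(frozen=True)
class InteractionPair:
    """A predicted regulator-target link with its evidence channel."""

    source: str
    source_class: str
    target: str
    target_class: str
    evidence: str
    score: float

    def __post_init__(self) -> None:
        if self.source_class not in ("mirna", "lncrna"):
            raise ValueError(f"source class must be mirna or lncrna, got {self.source_class!r}")
        if self.target_class not in _VALID_CLASSES:
            raise ValueError(f"unknown target class {self.target_class!r}")
        if self.source == self.target:
            raise ValueError(f"self-pair {self.source!r}")


def find_seed_matches(mirna: MatureMiRNA, transcript: TranscriptSeq) -> list[SeedMatch]:
    """Scan a target 5'->3' for canonical seed sites of one miRNA.

    Matches on the target are the reverse complement of the seed region:
    8mer = rc(2-8) + A, 7mer-m8 = rc(2-8), 7mer-A1 = rc(2-7) + A,
    6mer = rc(2-7). Overlapping candidates are reported at the strongest
    type only (8mer > 7mer-m8 > 7mer-A1 > 6mer).
    """
    rc28 = reverse_complement(mirna.sequence[1:8])  # 7 nt, seed 2-8
    rc27 = reverse_complement(mirna.sequence[1:7])  # 6 nt, seed 2-7
    patterns = {
        "8mer": rc28 + "A",
        "7mer-m8": rc28,
        "7mer-A1": rc27 + "A",
        "6mer": rc27,
    }
    seq = transcript.sequence
    candidates: list[SeedMatch] = []
    for site_type in SITE_TYPE_ORDER:
        pat = patterns[site_type]
        start = seq.find(pat)
        while start != -1:
            candidates.append(SeedMatch(mirna.id, transcript.id, site_type,
                                        start, start + len(pat)))
            start = seq.find(pat, start + 1)
    # suppress any candidate overlapped by a kept, strictly stronger site
    strength = {t: i for i, t in enumerate(SITE_TYPE_ORDER)}
    candidates.sort(key=lambda s: (strength[s.site_type], s.start))
    kept: list[SeedMatch] = []
    for cand in candidates:
        overlapped = any(
            strength[k.site_type] < strength[cand.site_type]
            and cand.start < k.end and k.start < cand.end
            for k in kept
        )
        if not overlapped:
            kept.append(cand)
    kept.sort(key=lambda s: (s.start, strength[s.site_type]))
    return kept


def seed_pairs(mirnas: Sequence[MatureMiRNA], transcripts: Sequence[TranscriptSeq],
               min_site_type: str = "7mer-m8") -> list[InteractionPair]:
    """miRNA->transcript pairs supported by at least one confident seed site.

    ``min_site_type`` sets the weakest site class that counts as evidence
    (default: 7mer-m8, i.e. only 7mer-m8 and 8mer sites create an edge);
    the score is the number of qualifying sites.
    """
    strength = {t: i for i, t in enumerate(SITE_TYPE_ORDER)}
    if min_site_type not in strength:
        raise ValueError(f"unknown site type {min_site_type!r}")
    max_rank = strength[min_site_type]
    pairs = []
    for mirna in mirnas:
        for transcript in transcripts:
            sites = [s for s in find_seed_matches(mirna, transcript)
                     if strength[s.site_type] <= max_rank]
            if sites:
                target_class = "mrna" if transcript.kind == "utr3" else "lncrna"
                pairs.append(InteractionPair(mirna.id, "mirna", transcript.id,
                                             target_class, "seed", float(len(sites))))
    return pairs


def load_interaction_table(path: str | Path) -> list[InteractionPair]:
    """Ingest a precomputed regulator-target TSV (e.g. a database export).

    Expected columns: source, source_class, target, target_class, score.
    Duplicate (source, target, evidence) rows are collapsed; malformed rows
    raise with their line number.
    """
    pairs: dict[tuple[str, str, str], InteractionPair] = {}
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            return []
        required = {"source", "source_class", "target", "target_class", "score"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                pair = InteractionPair(
                    source=row["source"], source_class=row["source_class"],
                    target=row["target"], target_class=row["target_class"],
                    evidence="table", score=float(row["score"]))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            pairs.setdefault((pair.source, pair.target, pair.evidence), pair)
    return list(pairs.values())


def _interval_gap(a: GeneLocus, b: GeneLocus) -> int:
    """Gap in nt between two intervals on the same chromosome (0 if overlapping)."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def cis_pairs(lnc_loci: Sequence[GeneLocus], mrna_loci: Sequence[GeneLocus],
              window: int = 100_000) -> list[InteractionPair]:
    """lncRNA-mRNA pairs within ``window`` nt on the same chromosome.

    The gap is 0 for overlapping loci; a gap exactly equal to the window
    still pairs. Strand is ignored. The score is the gap in nt.
    """
    pairs = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for locus in mrna_loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    for lnc in lnc_loci:
        for gene in by_chrom.get(lnc.chrom, []):
            if lnc.id == gene.id:
                continue
            gap = _interval_gap(lnc, gene)
            if gap <= window:
                pairs.append(InteractionPair(lnc.id, "lncrna", gene.id, "mrna",
                                             "cis", float(gap)))
    return pairs


def trans_pairs(lnc_expr: ExpressionMatrix, mrna_expr: ExpressionMatrix,
                r_threshold: float = 0.9, method: str = "pearson") -> list[InteractionPair]:
    """lncRNA-mRNA pairs co-expressed with |r| >= r_threshold.

    Correlation is computed across the samples shared by both matrices;
    the signed r is kept as the score. Constant features never pair.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    shared = [s for s in lnc_expr.values.columns if s in set(mrna_expr.values.columns)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples for co-expression")
    lv = lnc_expr.values[shared].to_numpy(dtype=float)
    mv = mrna_expr.values[shared].to_numpy(dtype=float)
    if method == "spearman":
        from scipy.stats import rankdata
        lv = rankdata(lv, axis=1)
        mv = rankdata(mv, axis=1)
    lz = lv - lv.mean(axis=1, keepdims=True)
    mz = mv - mv.mean(axis=1, keepdims=True)
    lsd = np.sqrt((lz ** 2).sum(axis=1))
    msd = np.sqrt((mz ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (lz @ mz.T) / np.outer(lsd, msd)
    pairs = []
    lnc_ids = list(lnc_expr.values.index)
    mrna_ids = list(mrna_expr.values.index)
    rows, cols = np.where(np.abs(corr) >= r_threshold - 1e-12)
    for i, j in zip(rows, cols):
        r = float(corr[i, j])
        if not math.isfinite(r) or lnc_ids[i] == mrna_ids[j]:
            continue
        pairs.append(InteractionPair(lnc_ids[i], "lncrna", mrna_ids[j], "mrna",
                                     "trans", r))
    return pairs


def pairs_to_frame(pairs: Iterable[InteractionPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.source, p.source_class, p.target, p.target_class, p.evidence, p.score)
         for p in pairs],
        columns=["source", "source_class", "target", "target_class", "evidence", "score"],
    )


def frame_to_pairs(df: pd.DataFrame) -> list[InteractionPair]:
    return [InteractionPair(r.source, r.source_class, r.target, r.target_class,
                            r.evidence, float(r.score))
            for r in df.itertuples(index=False)]
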