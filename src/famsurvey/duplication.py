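"""Gene structure statistics, chromosomal localization, and tandem /
segmental duplication classification.

Classification rules
--------------------
* Tandem: two family members on the same chromosome separated by at most
  one intervening gene (counted over ALL annotated genes, not only family
  members) whose proteins reach a configurable global-alignment identity
  (default 70%).
* Segmental: a member pair, not classified tandem, with global-alignment
  identity strictly above 80% and mutual coverage of at least 0.5 in both
  directions.  The strict inequality means a pair at exactly 80.0% is
  excluded.

Pairs are reported canonically (gene_a < gene_b lexicographically) and the
two result sets are disjoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import pandas as pd

from .exceptions import ConsistencyError
from .homology import global_align_identity
from .io import GeneModel, natural_key


@dataclass
class DuplicationPair:
    gene_a: str
    gene_b: str
    mode: str                 # "tandem" | "segmental"
    identity_pct: float
    intervening: int | None   # tandem only
    chromosomes: tuple[str, str]

    def __post_init__(self) -> None:
        if self.gene_a > self.gene_b:
            self.gene_a, self.gene_b = self.gene_b, self.gene_a
            self.chromosomes = (self.chromosomes[1], self.chromosomes[0])

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def gene_structure_stats(model: GeneModel) -> tuple[int, int, bool]:
    """(exon_count, intron_count, intronless) for one gene model."""
    n_exons = len(model.exons)
    if n_exons == 0:
        raise ConsistencyError(f"gene {model.gene_id} has no exons")
    return n_exons, n_exons - 1, n_exons == 1


def detect_tandem(members: Mapping[str, str] | set,
                  models: list[GeneModel],
                  proteins: Mapping[str, str],
                  min_identity_pct: float = 70.0) -> list[DuplicationPair]:
    """Tandem pairs: same chromosome, <=1 intervening annotated gene,
    protein identity >= threshold.

    ``models`` must include EVERY annotated gene on each chromosome so
    intervening counts are correct.  A gene may appear in several pairs
    (tandem arrays).
    """
    by_id = {m.gene_id: m for m in models}
    for gene_id in members:
        if gene_id not in by_id:
            raise KeyError(f"member {gene_id} has no gene model")

    pairs: list[DuplicationPair] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene_id in members:
        m = by_id[gene_id]
        by_chrom.setdefault(m.chromosome, []).append(m)
    for chrom, chrom_members in sorted(by_chrom.items(),
                                       key=lambda kv: natural_key(kv[0])):
        chrom_members.sort(key=lambda m: m.rank_on_chromosome)
        for a, b in combinations(chrom_members, 2):
            intervening = abs(b.rank_on_chromosome - a.rank_on_chromosome) - 1
            if intervening > 1:
                continue
            identity, _, _ = global_align_identity(
                proteins[a.gene_id], proteins[b.gene_id])
            if identity >= min_identity_pct:
                pairs.append(DuplicationPair(
                    gene_a=a.gene_id, gene_b=b.gene_id, mode="tandem",
                    identity_pct=identity, intervening=intervening,
                    chromosomes=(chrom, chrom),
                ))
    pairs.sort(key=lambda p: p.key)
    return pairs


def detect_segmental(members: Mapping[str, str] | set,
                     models: list[GeneModel],
                     proteins: Mapping[str, str],
                     min_identity_pct: float = 80.0,
                     min_mutual_coverage: float = 0.5,
                     tandem_pairs: list[DuplicationPair] | None = None,
                     ) -> list[DuplicationPair]:
    """Segmental pairs from all-against-all global alignment.

    Identity must be strictly above ``min_identity_pct`` and coverage at
    least ``min_mutual_coverage`` in both directions; pairs already
    classified tandem are excluded.  When ``tandem_pairs`` is omitted it
    is computed at default thresholds.
    """
    by_id = {m.gene_id: m for m in models}
    if tandem_pairs is None:
        tandem_pairs = detect_tandem(members, models, proteins)
    tandem_keys = {p.key for p in tandem_pairs}

    pairs: list[DuplicationPair] = []
    for id_a, id_b in combinations(sorted(members), 2):
        if (id_a, id_b) in tandem_keys:
            continue
        identity, cov_a, cov_b = global_align_identity(
            proteins[id_a], proteins[id_b])
        if identity > min_identity_pct and min(cov_a, cov_b) >= min_mutual_coverage:
            pairs.append(DuplicationPair(
                gene_a=id_a, gene_b=id_b, mode="segmental",
                identity_pct=identity, intervening=None,
                chromosomes=(by_id[id_a].chromosome, by_id[id_b].chromosome),
            ))
    pairs.sort(key=lambda p: p.key)
    return pairs


def chromosome_map(members: Mapping[str, str],
                   models: list[GeneModel]) -> pd.DataFrame:
    """Per-chromosome localization table for named members.

    One row per member (chromosome, start, end, strand, family name),
    grouped by chromosome in natural order and sorted by start.
    """
    by_id = {m.gene_id: m for m in models}
    rows = []
    for gene_id, name in members.items():
        m = by_id[gene_id]
        rows.append({
            "chromosome": m.chromosome, "start": m.start, "end": m.end,
            "strand": m.strand, "gene_id": gene_id, "family_name": name,
        })
    df = pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "strand",
                       "gene_id", "family_name"])
    if df.empty:
        return df
    df["_key"] = df["chromosome"].map(natural_key)
    df = df.sort_values(["_key", "start"]).drop(columns="_key")
    return df.reset_index(drop=True)
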