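"""Synthetic annotated genomes with planted ground truth.

The generator emulates, at desk scale, the setting of a genome-wide
ABC-transporter-style family survey: multi-chromosome genomes carrying

* family genes whose proteins contain the three diagnostic
  nucleotide-binding-domain motifs (a Walker A-like segment, an
  LSGGQ-signature-like segment, and a Walker B-like segment, in N-to-C
  order), derived from two template proteins that define two subfamilies;
* decoy genes whose proteins are scrubbed of all three motifs;
* tandem clusters (pair members adjacent, or separated by exactly one
  decoy gene) at high protein identity;
* segmental pairs on different chromosomes at a configured identity above
  the 80% classification boundary, plus distractor pairs below it;
* intronless genes (introns are inserted only between complete codons, so
  conceptual translation of the spliced CDS reproduces the protein
  exactly);
* promoters with cis-elements planted at recorded non-overlapping
  sense-strand offsets, and with every unplanted dictionary occurrence
  scrubbed so that planted counts are exactly recoverable.

Everything is drawn from one seeded generator: the same configuration and
seed produce byte-identical FASTA/GFF3/TSV output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .exceptions import ParameterError, SizingError
from .homology import SIGNATURE, WALKER_A, WALKER_B
from .io import (AMINO_ACIDS, IUPAC_DNA, CisElementDefinition, GeneModel,
                 natural_key, write_fasta, write_gff3)
from .motifs import reverse_complement

# standard genetic code, inverted: residue -> codon choices
_CODONS: dict[str, list[str]] = {}
_BASES = "TCAG"
_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_TABLE):
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    _CODONS.setdefault(_aa, []).append(_codon)
STOP_CODONS = _CODONS.pop("*")

_MARGIN = 4500          # bp reserved around every gene (promoter + spacer)
_PROMOTER_LEN = 2000
_UTR_LEN = 50

# motif segments planted into family templates (satisfy the NBD patterns)
_WALKER_A_SEG = "GPSGSGKT"
_SIGNATURE_SEG = "LSGGQ"
_WALKER_B_SEG = "ILLLDE"

# elements planted by default (all non-degenerate, none contains another)
DEFAULT_PLANTABLE = ["W-box", "ABRE", "MBS", "LTR", "CGTCA-motif",
                     "TGA-element", "ARE", "ERE", "TCA-element"]


@dataclass
class SyntheticConfig:
    n_chromosomes: int = 4
    chromosome_length: int = 120_000
    n_family_genes: int = 16
    n_decoy_genes: int = 14
    n_tandem_clusters: int = 2
    intervening_per_cluster: int = 1
    n_segmental_pairs: int = 2
    segmental_identity: float = 0.88
    n_distractor_pairs: int = 1
    distractor_identity: float = 0.75
    intronless_fraction: float = 0.25
    planted_elements: list[tuple[str, int, int]] | None = None
    rng_seed: int = 0

    def validate(self) -> None:
        counts = [self.n_chromosomes, self.chromosome_length,
                  self.n_family_genes, self.n_decoy_genes,
                  self.n_tandem_clusters, self.n_segmental_pairs,
                  self.n_distractor_pairs]
        if any(c < 0 for c in counts) or self.n_chromosomes == 0:
            raise ParameterError("all counts must be >= 0 (and >= 1 chromosome)")
        if self.intervening_per_cluster not in (0, 1):
            raise ParameterError("intervening_per_cluster must be 0 or 1")
        if not 0.8 < self.segmental_identity <= 1.0:
            raise ParameterError("segmental_identity must be in (0.8, 1.0]")
        if not 0.0 <= self.intronless_fraction <= 1.0:
            raise ParameterError("intronless_fraction must be in [0, 1]")
        paired = 2 * (self.n_tandem_clusters + self.n_segmental_pairs
                      + self.n_distractor_pairs)
        if paired > self.n_family_genes:
            raise SizingError(
                f"n_family_genes budget violated: {paired} genes needed for "
                f"tandem/segmental/distractor pairs but only "
                f"{self.n_family_genes} configured"
            )
        if self.n_tandem_clusters * self.intervening_per_cluster > self.n_decoy_genes:
            raise SizingError(
                "n_decoy_genes budget violated: not enough decoys to "
                "intervene in tandem clusters"
            )
        if self.n_segmental_pairs + self.n_distractor_pairs > 0 and self.n_chromosomes < 2:
            raise SizingError(
                "n_chromosomes budget violated: cross-chromosome pairs need "
                ">= 2 chromosomes"
            )


@dataclass
class TruthTables:
    family_members: set[str] = field(default_factory=set)
    tandem_pairs: set[tuple[str, str]] = field(default_factory=set)
    segmental_pairs: set[tuple[str, str]] = field(default_factory=set)
    intronless: set[str] = field(default_factory=set)
    element_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    subfamilies: dict[str, str] = field(default_factory=dict)


@dataclass
class SurveyDataset:
    genome: dict[str, str]
    models: list[GeneModel]
    utrs: dict[str, tuple[int, int]]
    proteome: dict[str, str]
    queries: dict[str, str]
    truth: TruthTables
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# Protein construction
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
    return "M" + body


def _signature_windows(seq: str, max_mismatch: int = 1) -> list[int]:
    width = len(SIGNATURE)
    out = []
    for i in range(len(seq) - width + 1):
        mism = sum(1 for a, b in zip(seq[i:i + width], SIGNATURE) if a != b)
        if mism <= max_mismatch:
            out.append(i)
    return out


def _scrub_protein(seq: str, rng: np.random.Generator,
                   budget: int = 200) -> str:
    """Remove every NBD-motif occurrence (decoys must carry none)."""
    chars = list(seq)
    for _ in range(budget):
        s = "".join(chars)
        match = WALKER_A.search(s)
        if match is not None:
            chars[match.start() + 6] = "P"  # the invariant K of GK[ST]
            continue
        match = WALKER_B.search(s)
        if match is not None:
            chars[match.start() + 2] = "P"  # P is not hydrophobic
            continue
        sig = _signature_windows(s)
        if sig:
            i = sig[0]
            chars[i + 1] = "P"
            chars[i + 3] = "W"
            continue
        return s
    raise RuntimeError("protein scrub budget exhausted")


def _build_template(rng: np.random.Generator, length: int = 380) -> str:
    chars = list(_random_protein(rng, length))
    for pos, seg in ((60, _WALKER_A_SEG), (200, _SIGNATURE_SEG),
                     (240, _WALKER_B_SEG)):
        chars[pos:pos + len(seg)] = seg
    return "".join(chars)


def _protected_positions(length: int) -> set[int]:
    protected = {0}
    for pos, seg in ((60, _WALKER_A_SEG), (200, _SIGNATURE_SEG),
                     (240, _WALKER_B_SEG)):
        protected.update(range(pos, pos + len(seg)))
    return protected


def _mutate(seq: str, target_identity: float, rng: np.random.Generator,
            protected: set[int] | None = None) -> str:
    """Substitution-only mutation to a position-wise identity target."""
    protected = protected or set()
    length = len(seq)
    k = int(round((1.0 - target_identity) * length))
    candidates = np.array([i for i in range(length) if i not in protected])
    if k > len(candidates):
        raise ParameterError(
            "target identity unreachable with protected positions")
    positions = rng.choice(candidates, size=k, replace=False)
    chars = list(seq)
    for pos in sorted(int(p) for p in positions):
        alternatives = [a for a in AMINO_ACIDS if a != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def mutate_protein(seq: str, target_identity: float, seed: int) -> str:
    """Return a same-length substitution mutant at the identity target.

    Realized position-wise identity is within half a substitution of the
    target (well inside +/-2 percentage points for proteins of 25+
    residues).
    """
    if not seq:
        raise ParameterError("sequence must be non-empty")
    if not 0.0 < target_identity <= 1.0:
        raise ParameterError("target_identity must be in (0, 1]")
    return _mutate(seq, target_identity, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Gene construction
# ---------------------------------------------------------------------------

def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = _CODONS[aa]
        codons.append(options[int(rng.integers(len(options)))])
    codons.append(STOP_CODONS[int(rng.integers(len(STOP_CODONS)))])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@dataclass
class _GenePlan:
    kind: str                   # family | decoy
    protein: str
    subfamily: str | None = None
    intronless: bool = False
    gene_id: str = ""


def _build_gene_parts(plan: _GenePlan, rng: np.random.Generator,
                      ) -> tuple[str, list[tuple[int, int]], list[tuple[int, int]], tuple[int, int]]:
    """Sense-strand gene sequence plus relative exon/CDS/UTR intervals
    (1-based within the gene)."""
    cds = _reverse_translate(plan.protein, rng)
    if plan.intronless:
        n_introns = 0
    else:
        n_introns = int(rng.integers(1, 4))
    n_codon_slots = len(cds) // 3
    cuts = sorted(
        int(c) for c in rng.choice(np.arange(1, n_codon_slots), size=n_introns,
                                   replace=False)
    ) if n_introns else []
    cds_parts = []
    prev = 0
    for cut in cuts + [n_codon_slots]:
        cds_parts.append(cds[prev * 3:cut * 3])
        prev = cut

    utr = _random_dna(rng, _UTR_LEN)
    seq_parts: list[str] = []
    exons: list[tuple[int, int]] = []
    cds_ivs: list[tuple[int, int]] = []
    pos = 0

    # first exon = 5' UTR + first CDS chunk
    first = utr + cds_parts[0]
    seq_parts.append(first)
    exons.append((pos + 1, pos + len(first)))
    cds_ivs.append((pos + _UTR_LEN + 1, pos + len(first)))
    utr_iv = (pos + 1, pos + _UTR_LEN)
    pos += len(first)
    for part in cds_parts[1:]:
        intron = "GT" + _random_dna(rng, int(rng.integers(60, 200))) + "AG"
        seq_parts.append(intron)
        pos += len(intron)
        seq_parts.append(part)
        exons.append((pos + 1, pos + len(part)))
        cds_ivs.append((pos + 1, pos + len(part)))
        pos += len(part)
    return "".join(seq_parts), exons, cds_ivs, utr_iv


def _map_to_genome(rel: tuple[int, int], gene_start: int, gene_len: int,
                   strand: str) -> tuple[int, int]:
    if strand == "+":
        return (gene_start + rel[0] - 1, gene_start + rel[1] - 1)
    return (gene_start + gene_len - rel[1], gene_start + gene_len - rel[0])


# ---------------------------------------------------------------------------
# Promoter element planting and scrubbing
# ---------------------------------------------------------------------------

def _promoter_genome_window(model: GeneModel) -> tuple[int, int, str]:
    """(genome start, genome end, strand) of the 2 kb promoter window."""
    tss = model.cds_start
    if model.strand == "+":
        return tss - _PROMOTER_LEN, tss - 1, "+"
    return tss + 1, tss + _PROMOTER_LEN, "-"


def _sense_to_genome(model: GeneModel, sense_pos: int, length: int,
                     ) -> tuple[int, int]:
    """Genome interval of a sense-strand promoter placement."""
    lo, hi, strand = _promoter_genome_window(model)
    if strand == "+":
        return lo + sense_pos - 1, lo + sense_pos - 1 + length - 1
    return hi - (sense_pos + length - 1) + 1, hi - sense_pos + 1


def _write_genome(chrom: bytearray, start: int, seq: str) -> None:
    chrom[start - 1:start - 1 + len(seq)] = seq.encode()


def _element_instance(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        sym if len(IUPAC_DNA[sym]) == 1
        else IUPAC_DNA[sym][int(rng.integers(len(IUPAC_DNA[sym])))]
        for sym in pattern
    )


def _iupac_mismatch_base(sym: str) -> str:
    allowed = set(IUPAC_DNA[sym])
    for base in "ACGT":
        if base not in allowed:
            return base
    return ""


def _scrub_promoters(genome: dict[str, bytearray],
                     family_models: list[GeneModel],
                     dictionary: list[CisElementDefinition],
                     planted: dict[tuple[str, str], list[int]],
                     budget: int = 500) -> None:
    """Mutate away every unplanted dictionary occurrence in each family
    promoter (sense strand), leaving planted placements intact."""
    from .motifs import iupac_regex

    patterns = {e.name: (e.pattern, iupac_regex(e.pattern)) for e in dictionary}
    for model in family_models:
        lo, hi, strand = _promoter_genome_window(model)
        chrom = genome[model.chromosome]
        protected: set[int] = set()  # sense-strand positions, 1-based
        for (gene_id, name), offsets in planted.items():
            if gene_id != model.gene_id:
                continue
            width = len(patterns[name][0])
            for off in offsets:
                protected.update(range(off, off + width))
        for _ in range(budget):
            window = chrom[lo - 1:hi].decode()
            sense = window if strand == "+" else reverse_complement(window)
            dirty = None
            for name, (pattern, regex) in patterns.items():
                allowed_offsets = set(planted.get((model.gene_id, name), []))
                pos = 0
                while True:
                    match = regex.search(sense, pos)
                    if match is None:
                        break
                    offset = match.start() + 1
                    if offset not in allowed_offsets:
                        dirty = (name, pattern, offset)
                        break
                    pos = match.start() + 1
                if dirty:
                    break
            if dirty is None:
                break
            name, pattern, offset = dirty
            hit_pos = None
            for j in range(len(pattern)):
                if (offset + j) not in protected and _iupac_mismatch_base(pattern[j]):
                    hit_pos = j
                    break
            if hit_pos is None:
                raise RuntimeError(
                    f"cannot scrub {name} at {model.gene_id}:{offset} "
                    "without touching a planted element"
                )
            g_lo, g_hi = _sense_to_genome(model, offset + hit_pos, 1)
            base = _iupac_mismatch_base(pattern[hit_pos])
            chrom[g_lo - 1:g_lo] = (
                base if strand == "+" else reverse_complement(base)
            ).encode()
        else:
            raise RuntimeError("promoter scrub budget exhausted")


# ---------------------------------------------------------------------------
# Top-level generator
# ---------------------------------------------------------------------------

def generate_survey_dataset(config: SyntheticConfig,
                            dictionary: list[CisElementDefinition] | None = None,
                            ) -> SurveyDataset:
    """Generate genome, annotation, proteome, seed queries, and truth."""
    config.validate()
    if dictionary is None:
        from .resources import default_cis_elements
        dictionary = default_cis_elements()
    by_name = {e.name: e for e in dictionary}
    plantable = [n for n in DEFAULT_PLANTABLE if n in by_name]

    rng = np.random.default_rng(config.rng_seed)
    template_a = _build_template(rng)
    template_b = _build_template(rng)
    templates = {"SubfamilyA": template_a, "SubfamilyB": template_b}
    protected = _protected_positions(len(template_a))

    # --- family gene plans --------------------------------------------------
    subfam_cycle = ["SubfamilyA", "SubfamilyB"]
    plans_tandem: list[list[_GenePlan]] = []
    plans_segmental: list[tuple[_GenePlan, _GenePlan]] = []
    plans_distractor: list[tuple[_GenePlan, _GenePlan]] = []
    plans_single: list[_GenePlan] = []
    used = 0

    def new_member(subfam: str, identity: float = 0.62,
                   base: str | None = None) -> _GenePlan:
        source = base if base is not None else templates[subfam]
        protein = _mutate(source, identity, rng, protected)
        return _GenePlan(kind="family", protein=protein, subfamily=subfam)

    for i in range(config.n_tandem_clusters):
        subfam = subfam_cycle[i % 2]
        first = new_member(subfam)
        second = _GenePlan(kind="family", subfamily=subfam,
                           protein=_mutate(first.protein, 0.92, rng, protected))
        plans_tandem.append([first, second])
        used += 2
    for i in range(config.n_segmental_pairs):
        subfam = subfam_cycle[i % 2]
        first = new_member(subfam)
        second = _GenePlan(kind="family", subfamily=subfam,
                           protein=_mutate(first.protein,
                                           config.segmental_identity, rng,
                                           protected))
        plans_segmental.append((first, second))
        used += 2
    for i in range(config.n_distractor_pairs):
        subfam = subfam_cycle[i % 2]
        first = new_member(subfam)
        second = _GenePlan(kind="family", subfamily=subfam,
                           protein=_mutate(first.protein,
                                           config.distractor_identity, rng,
                                           protected))
        plans_distractor.append((first, second))
        used += 2
    for i in range(config.n_family_genes - used):
        plans_single.append(new_member(subfam_cycle[i % 2]))

    # --- decoys -------------------------------------------------------------
    n_intervening = config.n_tandem_clusters * config.intervening_per_cluster
    decoys = [
        _GenePlan(kind="decoy",
                  protein=_scrub_protein(
                      _random_protein(rng, int(rng.integers(150, 300))), rng))
        for _ in range(config.n_decoy_genes)
    ]
    intervening_decoys = decoys[:n_intervening]
    free_decoys = decoys[n_intervening:]

    # --- intronless assignment (family genes only) --------------------------
    family_plans = ([p for cluster in plans_tandem for p in cluster]
                    + [p for pair in plans_segmental for p in pair]
                    + [p for pair in plans_distractor for p in pair]
                    + plans_single)
    n_intronless = int(round(config.intronless_fraction * len(family_plans)))
    if family_plans and n_intronless:
        chosen = rng.choice(len(family_plans), size=n_intronless, replace=False)
        for idx in chosen:
            family_plans[int(idx)].intronless = True
    for decoy in decoys:
        decoy.intronless = bool(rng.integers(4) == 0)

    # --- chromosome layout: blocks keep tandem clusters contiguous ----------
    chrom_blocks: list[list[list[_GenePlan]]] = [[] for _ in range(config.n_chromosomes)]
    cursor = 0
    for i, cluster in enumerate(plans_tandem):
        block = [cluster[0]]
        if config.intervening_per_cluster:
            block.append(intervening_decoys[i])
        block.append(cluster[1])
        chrom_blocks[cursor % config.n_chromosomes].append(block)
        cursor += 1
    for first, second in plans_segmental + plans_distractor:
        chrom_blocks[cursor % config.n_chromosomes].append([first])
        chrom_blocks[(cursor + 1) % config.n_chromosomes].append([second])
        cursor += 1
    for plan in plans_single + free_decoys:
        chrom_blocks[cursor % config.n_chromosomes].append([plan])
        cursor += 1
    for blocks in chrom_blocks:
        order = rng.permutation(len(blocks))
        blocks[:] = [blocks[int(i)] for i in order]

    # --- build genes and genome --------------------------------------------
    genome: dict[str, bytearray] = {}
    models: list[GeneModel] = []
    utrs: dict[str, tuple[int, int]] = {}
    proteome: dict[str, str] = {}
    truth = TruthTables()

    for c, blocks in enumerate(chrom_blocks):
        chrom_name = f"chr{c + 1}"
        chrom = bytearray(_random_dna(rng, config.chromosome_length).encode())
        position = _MARGIN + 1
        index = 0
        for block in blocks:
            for plan in block:
                index += 1
                gene_id = f"{chrom_name}_g{index:02d}"
                plan.gene_id = gene_id
                strand = "+" if rng.integers(2) == 0 else "-"
                sense_seq, exons_rel, cds_rel, utr_rel = _build_gene_parts(plan, rng)
                gene_len = len(sense_seq)
                start = position
                end = start + gene_len - 1
                if end + _MARGIN > config.chromosome_length:
                    raise SizingError(
                        f"chromosome_length budget violated on {chrom_name}: "
                        f"gene {gene_id} would end at {end + _MARGIN}"
                    )
                genomic = sense_seq if strand == "+" else reverse_complement(sense_seq)
                _write_genome(chrom, start, genomic)
                model = GeneModel(
                    gene_id=gene_id, chromosome=chrom_name, strand=strand,
                    start=start, end=end,
                    exons=sorted(_map_to_genome(iv, start, gene_len, strand)
                                 for iv in exons_rel),
                    cds=sorted(_map_to_genome(iv, start, gene_len, strand)
                               for iv in cds_rel),
                )
                models.append(model)
                utrs[gene_id] = _map_to_genome(utr_rel, start, gene_len, strand)
                proteome[gene_id] = plan.protein
                position = end + _MARGIN + 1
        genome[chrom_name] = chrom

    by_id = {m.gene_id: m for m in models}

    # --- truth: membership, pairs, intronless -------------------------------
    for plan in family_plans:
        truth.family_members.add(plan.gene_id)
        truth.subfamilies[plan.gene_id] = plan.subfamily
        if plan.intronless:
            truth.intronless.add(plan.gene_id)
    for cluster in plans_tandem:
        truth.tandem_pairs.add(tuple(sorted(p.gene_id for p in cluster)))
    for pair in plans_segmental:
        truth.segmental_pairs.add(tuple(sorted(p.gene_id for p in pair)))

    # --- plant promoter elements -------------------------------------------
    planted: dict[tuple[str, str], list[int]] = {}
    family_models = [by_id[p.gene_id] for p in family_plans]
    if config.planted_elements is not None:
        requests: dict[str, list[tuple[str, int]]] = {}
        for name, gene_index, count in config.planted_elements:
            gene_id = family_plans[gene_index].gene_id
            requests.setdefault(gene_id, []).append((name, count))
    else:
        requests = {}
        for plan in family_plans:
            total = int(rng.integers(5, 9))
            picks = rng.choice(len(plantable), size=total, replace=True)
            per: dict[str, int] = {}
            for pick in picks:
                name = plantable[int(pick)]
                per[name] = per.get(name, 0) + 1
            requests[plan.gene_id] = sorted(per.items())

    for model in family_models:
        gene_id = model.gene_id
        occupied: list[tuple[int, int]] = []
        for name, count in requests.get(gene_id, []):
            pattern = by_name[name].pattern
            width = len(pattern)
            for _ in range(count):
                for _attempt in range(200):
                    off = int(rng.integers(1, _PROMOTER_LEN - width + 1))
                    iv = (off - 3, off + width + 2)  # 3 bp clearance
                    if all(iv[1] < lo or iv[0] > hi for lo, hi in occupied):
                        break
                else:
                    raise SizingError(
                        f"cannot place {count} x {name} in promoter of {gene_id}"
                    )
                occupied.append((off, off + width - 1))
                instance = _element_instance(pattern, rng)
                g_lo, _g_hi = _sense_to_genome(model, off, width)
                _write_genome(
                    genome[model.chromosome], g_lo,
                    instance if model.strand == "+" else reverse_complement(instance),
                )
                planted.setdefault((gene_id, name), []).append(off)
            truth.element_counts[(gene_id, name)] = count

    _scrub_promoters(genome, family_models, dictionary, planted)

    models.sort(key=lambda m: (natural_key(m.chromosome), m.start))
    rank = 0
    current = None
    for model in models:
        if model.chromosome != current:
            current = model.chromosome
            rank = 0
        rank += 1
        model.rank_on_chromosome = rank
    return SurveyDataset(
        genome={name: bytes(chrom).decode() for name, chrom in genome.items()},
        models=models,
        utrs=utrs,
        proteome=proteome,
        queries={"RefSubfamilyA": template_a, "RefSubfamilyB": template_b},
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# On-disk output
# ---------------------------------------------------------------------------

def write_survey_dataset(dataset: SurveyDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA/GFF3/TSV artifacts; paths keyed by artifact name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "annotation": outdir / "annotation.gff3",
        "proteome": outdir / "proteome.fasta",
        "queries": outdir / "queries.fasta",
        "truth_members": outdir / "truth_members.tsv",
        "truth_pairs": outdir / "truth_pairs.tsv",
        "truth_elements": outdir / "truth_elements.tsv",
    }
    write_fasta(dataset.genome, paths["genome"])
    write_gff3(dataset.models, paths["annotation"], utrs=dataset.utrs)
    write_fasta(dataset.proteome, paths["proteome"])
    write_fasta(dataset.queries, paths["queries"])

    lines = ["gene_id\tsubfamily\tintronless"]
    for gene_id in sorted(dataset.truth.family_members):
        lines.append(f"{gene_id}\t{dataset.truth.subfamilies[gene_id]}"
                     f"\t{int(gene_id in dataset.truth.intronless)}")
    paths["truth_members"].write_text("\n".join(lines) + "\n")

    lines = ["gene_a\tgene_b\tmode"]
    for a, b in sorted(dataset.truth.tandem_pairs):
        lines.append(f"{a}\t{b}\ttandem")
    for a, b in sorted(dataset.truth.segmental_pairs):
        lines.append(f"{a}\t{b}\tsegmental")
    paths["truth_pairs"].write_text("\n".join(lines) + "\n")

    lines = ["gene_id\telement\tcount"]
    for (gene_id, name), count in sorted(dataset.truth.element_counts.items()):
        lines.append(f"{gene_id}\t{name}\t{count}")
    paths["truth_elements"].write_text("\n".join(lines) + "\n")
    return paths
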