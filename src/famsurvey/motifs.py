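"""Protein motif scanning, promoter extraction, cis-element scanning, and
promoter allele comparison.

Protein motifs are mismatch-tolerant consensus strings over an extended
amino-acid alphabet (B = {N,D}, Z = {Q,E}, J = {I,L}, X = any); hits per
motif are non-overlapping and leftmost-greedy, like discovered motif sites.
Cis-elements are IUPAC nucleotide patterns scanned on the sense strand of
the promoter only, with every overlapping occurrence counted, like a
promoter-database report.  The asymmetry is intentional.

The promoter is defined as the region upstream of the translation start
site (the first CDS base on the coding strand), not the transcription
start.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import ComparisonError, ConsistencyError
from .homology import make_aligner
from .io import (AMINO_ACIDS, IUPAC_DNA, CisElementDefinition, GeneModel,
                 MotifDefinition)

# extended alphabet: which concrete residues satisfy each consensus symbol
_EXTENDED_SETS = {
    **{a: {a} for a in AMINO_ACIDS},
    "B": {"N", "D"},
    "Z": {"Q", "E"},
    "J": {"I", "L"},
    "X": set(AMINO_ACIDS),
}

_AA_CODE = {a: i for i, a in enumerate(AMINO_ACIDS)}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifHit:
    motif_id: str
    protein_id: str
    start: int  # 1-based residue position
    mismatches: int


@dataclass
class PromoterRecord:
    gene_id: str
    sequence: str          # 5'->3' on the gene's sense strand
    length: int
    truncated: bool = False
    element_counts: dict[str, int] = field(default_factory=dict)
    hit_positions: dict[str, list[int]] = field(default_factory=dict)


@dataclass
class DeletionSegment:
    sequence: str
    length: int
    offset: int      # 1-based offset in the allele that carries the bases
    in_allele: str   # "a" or "b": which input allele contains the sequence


@dataclass
class VariantComparison:
    allele_a_id: str
    allele_b_id: str
    identity_pct: float
    deletion_segments: list[DeletionSegment]
    lost_elements: dict[str, int]    # present in a, missing in b
    gained_elements: dict[str, int]  # present in b, missing in a


# ---------------------------------------------------------------------------
# Protein motif scanning
# ---------------------------------------------------------------------------

def scan_protein_motifs(protein: str, motifs: list[MotifDefinition],
                        max_mismatch_fraction: float = 0.1,
                        protein_id: str = "protein") -> list[MotifHit]:
    """Non-overlapping leftmost-greedy consensus hits, in N-to-C order.

    A window matches when its mismatch count is at most
    ``floor(width * max_mismatch_fraction)``.  Motifs wider than the
    protein simply yield no hits.
    """
    protein = protein.upper()
    n = len(protein)
    codes = np.array([_AA_CODE.get(c, -1) for c in protein], dtype=np.int16)
    hits: list[MotifHit] = []
    for motif in motifs:
        width = motif.width
        if width > n:
            continue
        budget = int(width * max_mismatch_fraction)
        # allowed[j, c] = does residue code c satisfy consensus position j
        allowed = np.zeros((width, 21), dtype=bool)
        for j, sym in enumerate(motif.consensus):
            for aa in _EXTENDED_SETS.get(sym, set()):
                allowed[j, _AA_CODE[aa]] = True
        windows = np.lib.stride_tricks.sliding_window_view(codes, width)
        valid = windows >= 0
        ok = np.zeros_like(valid)
        ok[valid] = allowed[
            np.broadcast_to(np.arange(width), windows.shape)[valid],
            windows[valid],
        ]
        mismatches = width - ok.sum(axis=1)
        pos = 0
        n_windows = n - width + 1
        while pos < n_windows:
            if mismatches[pos] <= budget:
                hits.append(MotifHit(motif.motif_id, protein_id,
                                     pos + 1, int(mismatches[pos])))
                pos += width  # non-overlapping per motif
            else:
                pos += 1
    hits.sort(key=lambda h: (h.start, h.motif_id))
    return hits


def motif_width_stats(motifs: list[MotifDefinition]) -> tuple[int, int, int]:
    """(count, min_width, max_width), widths recomputed from consensus."""
    if not motifs:
        raise ValueError("motif_width_stats needs at least one motif")
    widths = [m.width for m in motifs]
    return len(motifs), min(widths), max(widths)


# ---------------------------------------------------------------------------
# Promoter extraction and cis-element scanning
# ---------------------------------------------------------------------------

def extract_promoter(genome: Mapping[str, str], model: GeneModel,
                     length: int = 2000) -> PromoterRecord:
    """Sense-strand promoter upstream of the translation start site.

    Plus strand: genomic interval [cds_start - length, cds_start - 1] read
    5'->3'.  Minus strand: [cds_end + 1, cds_end + length]
    reverse-complemented.  Truncation at a contig edge is flagged.
    """
    if not model.cds:
        raise ConsistencyError(f"gene {model.gene_id} has no CDS")
    contig = genome[model.chromosome]
    tss = model.cds_start
    if model.strand == "+":
        start = max(1, tss - length)
        seq = contig[start - 1:tss - 1]
        truncated = (tss - length) < 1
    else:
        end = min(len(contig), tss + length)
        seq = reverse_complement(contig[tss:end])
        truncated = (tss + length) > len(contig)
    return PromoterRecord(
        gene_id=model.gene_id, sequence=seq.upper(),
        length=len(seq), truncated=truncated,
    )


def iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for sym in pattern:
        bases = IUPAC_DNA[sym]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def scan_sequence_elements(seq: str,
                           dictionary: list[CisElementDefinition],
                           ) -> dict[str, list[int]]:
    """All (overlapping) occurrences of each element; 1-based offsets."""
    positions: dict[str, list[int]] = {}
    for element in dictionary:
        regex = iupac_regex(element.pattern)
        offsets = []
        pos = 0
        while True:
            match = regex.search(seq, pos)
            if match is None:
                break
            offsets.append(match.start() + 1)
            pos = match.start() + 1  # overlapping occurrences all count
        positions[element.name] = offsets
    return positions


def scan_cis_elements(promoter: PromoterRecord,
                      dictionary: list[CisElementDefinition]) -> PromoterRecord:
    """Fill element counts and hit offsets on the sense strand only."""
    positions = scan_sequence_elements(promoter.sequence, dictionary)
    promoter.hit_positions = positions
    promoter.element_counts = {name: len(offs) for name, offs in positions.items()}
    return promoter


# ---------------------------------------------------------------------------
# Allele comparison
# ---------------------------------------------------------------------------

_DNA_MATRIX = None


def _dna_aligner():
    global _DNA_MATRIX
    from Bio.Align import substitution_matrices
    if _DNA_MATRIX is None:
        mat = substitution_matrices.Array("ACGTN", dims=2)
        for a in "ACGT":
            for b in "ACGT":
                mat[a, b] = 2.0 if a == b else -3.0
        _DNA_MATRIX = mat
    return make_aligner(_DNA_MATRIX, gap_open=10.0, gap_extend=0.5,
                        mode="global")


def compare_promoter_alleles(allele_a: str, allele_b: str,
                             dictionary: list[CisElementDefinition],
                             allele_a_id: str = "allele_a",
                             allele_b_id: str = "allele_b",
                             min_identity_pct: float = 50.0,
                             ) -> VariantComparison:
    """Globally align two promoter alleles and diff their element content.

    Contiguous gap runs become deletion segments (sequence taken from the
    allele that retains the bases).  Elements are counted on each allele
    separately; ``lost_elements`` holds positive count differences a - b,
    ``gained_elements`` the reverse, so swapping alleles swaps the two.
    Alignments below ``min_identity_pct`` identity are refused.
    """
    if not allele_a or not allele_b:
        raise ComparisonError("both alleles must be non-empty")
    aligner = _dna_aligner()
    alignment = aligner.align(allele_a.upper(), allele_b.upper())[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])

    paired = identical = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            paired += 1
            identical += x == y
    identity = 100.0 * identical / paired if paired else 0.0
    if identity < min_identity_pct:
        raise ComparisonError(
            f"alleles align at {identity:.1f}% identity over {paired} "
            f"columns; below {min_identity_pct}% the comparison is not "
            "meaningful"
        )

    segments: list[DeletionSegment] = []
    pos_a = pos_b = 0
    run_start = None  # (which_row_gapped, offset_in_other, chars)
    for x, y in zip(row_a, row_b):
        if y == "-" and x != "-":          # bases present in a, missing in b
            if run_start is None or run_start[0] != "b":
                if run_start is not None:
                    segments.append(_close_run(run_start))
                run_start = ("b", pos_a + 1, [])
            run_start[2].append(x)
        elif x == "-" and y != "-":        # bases present in b, missing in a
            if run_start is None or run_start[0] != "a":
                if run_start is not None:
                    segments.append(_close_run(run_start))
                run_start = ("a", pos_b + 1, [])
            run_start[2].append(y)
        else:
            if run_start is not None:
                segments.append(_close_run(run_start))
                run_start = None
        pos_a += x != "-"
        pos_b += y != "-"
    if run_start is not None:
        segments.append(_close_run(run_start))

    counts_a = {name: len(v) for name, v in
                scan_sequence_elements(allele_a.upper(), dictionary).items()}
    counts_b = {name: len(v) for name, v in
                scan_sequence_elements(allele_b.upper(), dictionary).items()}
    lost = {name: counts_a[name] - counts_b[name]
            for name in counts_a if counts_a[name] > counts_b[name]}
    gained = {name: counts_b[name] - counts_a[name]
              for name in counts_a if counts_b[name] > counts_a[name]}

    return VariantComparison(
        allele_a_id=allele_a_id, allele_b_id=allele_b_id,
        identity_pct=identity, deletion_segments=segments,
        lost_elements=lost, gained_elements=gained,
    )


def _close_run(run: tuple[str, int, list[str]]) -> DeletionSegment:
    gapped_in, offset, chars = run
    return DeletionSegment(
        sequence="".join(chars), length=len(chars), offset=offset,
        in_allele="a" if gapped_in == "b" else "b",
    )
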