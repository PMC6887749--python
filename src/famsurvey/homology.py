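"""Family-member identification: local-alignment screening against seed
queries, nucleotide-binding-domain (NBD) confirmation, and chromosomal
naming.

The screen stands in for a BLASTp search: every proteome entry is aligned
locally (Smith-Waterman with affine gaps, BLOSUM62 by default) against each
seed query and retained when identity and query-coverage thresholds are met.
Candidates are then confirmed by an ordered consensus search for the three
diagnostic NBD motifs -- Walker A ([AG]x4GK[ST]), the ABC signature (LSGGQ,
one mismatch tolerated), and Walker B (four hydrophobics followed by DE) --
which must appear in N-to-C order.

Gap costs follow the BLAST convention: a gap of length L costs
``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices

from .exceptions import AlphabetError, FamSurveyError
from .io import AMINO_ACIDS, GeneModel, natural_key

_PROTEIN_ALPHABET = set(AMINO_ACIDS) | {"X"}

WALKER_A = re.compile(r"[AG].{4}GK[ST]")
WALKER_B = re.compile(r"[ILVFMA]{4}DE")
SIGNATURE = "LSGGQ"


@dataclass
class LocalAlignment:
    """Best local alignment of a query against a subject."""

    query_id: str
    subject_id: str
    score: float
    identity_pct: float
    query_coverage: float
    aligned_span: tuple[int, int] | None  # subject interval, 1-based inclusive


@dataclass
class DomainEvidence:
    """Placement of the three diagnostic NBD motifs on a protein.

    ``confirmed`` is true iff all three intervals are present in
    N-to-C order (Walker A < signature < Walker B).
    """

    walker_a: tuple[int, int] | None
    signature: tuple[int, int] | None
    walker_b: tuple[int, int] | None

    @property
    def confirmed(self) -> bool:
        if None in (self.walker_a, self.signature, self.walker_b):
            return False
        return self.walker_a[1] < self.signature[0] and self.signature[1] < self.walker_b[0]


def _check_alphabet(seq: str, label: str) -> None:
    bad = set(seq) - _PROTEIN_ALPHABET
    if bad:
        raise AlphabetError(f"{label}: non-amino-acid characters {sorted(bad)}")
    if not seq:
        raise AlphabetError(f"{label}: empty sequence")


def simple_protein_matrix(match: float, mismatch: float):
    """Uniform match/mismatch substitution table over the 20-aa alphabet + X."""
    mat = substitution_matrices.Array(AMINO_ACIDS + "X", dims=2)
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            mat[a, b] = match if a == b else mismatch
    return mat


def make_aligner(matrix: str | object = "BLOSUM62",
                 gap_open: float = 11.0, gap_extend: float = 1.0,
                 mode: str = "local") -> Align.PairwiseAligner:
    """Affine-gap pairwise aligner; gap of length L costs open + L*extend."""
    if isinstance(matrix, str):
        matrix = substitution_matrices.load(matrix)
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = matrix
    aligner.mode = mode
    # Biopython charges open_gap_score for the first gap position and
    # extend_gap_score per additional one; shift to the BLAST convention.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, int, tuple[int, int] | None]:
    """(identical, aligned_columns, query_residues_aligned, subject_span)."""
    target, query = str(alignment.target), str(alignment.query)
    t_blocks, q_blocks = alignment.aligned
    identical = 0
    columns = 0
    q_res = 0
    # residue-paired columns from aligned blocks
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        columns += te - ts
        q_res += qe - qs
        identical += sum(
            1 for a, b in zip(target[ts:te], query[qs:qe]) if a == b
        )
    # gap columns between consecutive blocks also count as aligned columns
    for i in range(1, len(t_blocks)):
        columns += (t_blocks[i][0] - t_blocks[i - 1][1])
        columns += (q_blocks[i][0] - q_blocks[i - 1][1])
    if len(t_blocks):
        span = (int(t_blocks[0][0]) + 1, int(t_blocks[-1][1]))
    else:
        span = None
    return identical, columns, q_res, span


def local_align(query: str, subject: str,
                matrix: str | object = "BLOSUM62",
                gap_open: float = 11.0, gap_extend: float = 1.0,
                query_id: str = "query", subject_id: str = "subject") -> LocalAlignment:
    """Optimal Smith-Waterman local alignment with affine gaps.

    Identity is the percentage of identical residues over aligned columns
    (gap columns included); coverage is the fraction of query residues on
    the traceback path.
    """
    _check_alphabet(query, "query")
    _check_alphabet(subject, "subject")
    aligner = make_aligner(matrix, gap_open, gap_extend, "local")
    alignments = aligner.align(subject, query)
    score = float(alignments.score)
    if score <= 0:
        return LocalAlignment(query_id, subject_id, max(score, 0.0), 0.0, 0.0, None)
    identical, columns, q_res, span = _alignment_stats(alignments[0])
    identity = 100.0 * identical / columns if columns else 0.0
    coverage = q_res / len(query)
    return LocalAlignment(query_id, subject_id, score,
                          float(identity), float(coverage), span)


def global_align_identity(a: str, b: str,
                          matrix: str | object = "BLOSUM62",
                          gap_open: float = 11.0, gap_extend: float = 1.0,
                          ) -> tuple[float, float, float]:
    """Needleman-Wunsch global alignment summary.

    Returns (identity_pct over residue-paired columns, coverage of a,
    coverage of b), where coverage is the fraction of a sequence's residues
    sitting in residue-paired (non-gap) columns.
    """
    _check_alphabet(a, "sequence a")
    _check_alphabet(b, "sequence b")
    aligner = make_aligner(matrix, gap_open, gap_extend, "global")
    alignment = aligner.align(a, b)[0]
    t_blocks, q_blocks = alignment.aligned
    paired = sum(te - ts for ts, te in t_blocks)
    identical = sum(
        1
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks)
        for x, y in zip(a[ts:te], b[qs:qe])
        if x == y
    )
    if paired == 0:
        return 0.0, 0.0, 0.0
    return 100.0 * identical / paired, paired / len(a), paired / len(b)


def screen_candidates(queries: Mapping[str, str], proteome: Mapping[str, str],
                      min_identity_pct: float = 30.0,
                      min_query_coverage: float = 0.5,
                      matrix: str | object = "BLOSUM62",
                      gap_open: float = 11.0, gap_extend: float = 1.0,
                      ) -> dict[str, LocalAlignment]:
    """Retain proteome entries matched by ANY seed query at the thresholds.

    Each retained subject records its best-scoring qualifying alignment.
    """
    if not queries:
        raise FamSurveyError("screen_candidates requires at least one query")
    hits: dict[str, LocalAlignment] = {}
    for subject_id, subject in proteome.items():
        best: LocalAlignment | None = None
        for query_id, query in queries.items():
            aln = local_align(query, subject, matrix, gap_open, gap_extend,
                              query_id=query_id, subject_id=subject_id)
            if aln.identity_pct >= min_identity_pct and aln.query_coverage >= min_query_coverage:
                if best is None or aln.score > best.score:
                    best = aln
        if best is not None:
            hits[subject_id] = best
    return hits


def _find_signature(protein: str, start: int, max_mismatch: int = 1) -> tuple[int, int] | None:
    width = len(SIGNATURE)
    for i in range(start, len(protein) - width + 1):
        mismatches = sum(1 for a, b in zip(protein[i:i + width], SIGNATURE) if a != b)
        if mismatches <= max_mismatch:
            return (i + 1, i + width)
    return None


def confirm_domain(protein: str) -> DomainEvidence:
    """Ordered consensus search for Walker A, ABC signature, and Walker B.

    The leftmost N-to-C chain is reported when one exists; otherwise the
    leftmost independent occurrence of each motif (evidence for diagnosis)
    with ``confirmed`` false.
    """
    if not protein:
        raise AlphabetError("confirm_domain: empty sequence")
    # try every Walker A anchor until a full ordered chain completes
    for wa in WALKER_A.finditer(protein):
        wa_iv = (wa.start() + 1, wa.end())
        sig_iv = _find_signature(protein, wa.end())
        if sig_iv is None:
            break  # no signature anywhere right of this or any later anchor
        wb = WALKER_B.search(protein, sig_iv[1])
        if wb is not None:
            return DomainEvidence(wa_iv, sig_iv, (wb.start() + 1, wb.end()))
    # no ordered chain: report independent leftmost matches
    wa = WALKER_A.search(protein)
    wb = WALKER_B.search(protein)
    return DomainEvidence(
        (wa.start() + 1, wa.end()) if wa else None,
        _find_signature(protein, 0),
        (wb.start() + 1, wb.end()) if wb else None,
    )


def identify_members(queries: Mapping[str, str], proteome: Mapping[str, str],
                     min_identity_pct: float = 30.0,
                     min_query_coverage: float = 0.5,
                     ) -> dict[str, tuple[LocalAlignment, DomainEvidence]]:
    """Screen then confirm: the family-member call used by the pipeline."""
    candidates = screen_candidates(queries, proteome,
                                   min_identity_pct, min_query_coverage)
    members = {}
    for subject_id, aln in candidates.items():
        evidence = confirm_domain(proteome[subject_id])
        if evidence.confirmed:
            members[subject_id] = (aln, evidence)
    return members


def assign_names(members: Iterable[str], models: list[GeneModel],
                 prefix: str) -> dict[str, str]:
    """Name members prefix+1..prefix+n by chromosomal position.

    Sorting is natural-order on chromosome identifier (chr2 before chr10),
    then ascending start; the result is independent of input order.
    """
    by_id = {m.gene_id: m for m in models}
    member_models = []
    for gene_id in members:
        if gene_id not in by_id:
            raise KeyError(f"member {gene_id} has no gene model")
        member_models.append(by_id[gene_id])
    member_models.sort(key=lambda m: (natural_key(m.chromosome), m.start))
    return {m.gene_id: f"{prefix}{i}" for i, m in enumerate(member_models, 1)}
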