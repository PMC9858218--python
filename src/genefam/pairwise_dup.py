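"""Global alignment, paralog detection and duplication-type classification.

Paralogy follows the classical coverage/similarity rule: two family members
are paralogs when the alignable region covers more than 75% of the longer
sequence and more than 75% of the aligned columns are similar
(positive-scoring under the substitution matrix).  A paralogous pair is a
tandem duplication when the genes lie on the same chromosome with at most
five intervening annotated genes within 100 kb (start-to-start); every
other pair is a segmental duplication.

The aligner is Needleman-Wunsch with affine gaps (Gotoh's three-state
recurrence).  A gap of length L costs ``gap_open + (L - 1) * gap_extend``;
setting the two penalties equal recovers a linear gap cost.  Traceback is
deterministic with tie order diagonal > up > left.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import GeneModel

NEG_INF = float("-inf")


def blosum62() -> dict[tuple[str, str], float]:
    """BLOSUM62 as a plain dict keyed by residue pairs."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    table: dict[tuple[str, str], float] = {}
    for a in m.alphabet:
        for b in m.alphabet:
            table[(a, b)] = float(m[a, b])
    return table


_BLOSUM62: dict[tuple[str, str], float] | None = None


def _default_matrix() -> dict[tuple[str, str], float]:
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = blosum62()
    return _BLOSUM62


@dataclass
class AlignmentResult:
    """A scored global alignment with coverage/similarity/identity summaries.

    coverage
        Fraction of the longer sequence's residues sitting in columns where
        both rows carry a residue.
    similarity
        Fraction of both-residue columns whose substitution score is > 0.
    identity
        Fraction of both-residue columns with equal residues.
    """

    aligned_a: str
    aligned_b: str
    score: float
    coverage: float
    similarity: float
    identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings differ in length")


@dataclass
class ParalogPair:
    """Two family members passing the paralog criteria, with a verdict."""

    member_a: str
    member_b: str
    alignment: AlignmentResult
    duplication_type: str | None = None  # "tandem" | "segmental"
    intervening_genes: int | None = None
    span_bp: int | None = None


def global_align(a: str, b: str,
                 matrix: Mapping[tuple[str, str], float] | None = None,
                 gap_open: float = 10.0,
                 gap_extend: float = 0.5) -> AlignmentResult:
    """Optimal global alignment of two protein sequences (affine gaps)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    sub = matrix if matrix is not None else _default_matrix()
    n, m = len(a), len(b)

    # Three-state DP: M (diagonal), X (gap in b, "up"), Y (gap in a, "left").
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)

    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = sub[(ai, b[j - 1])]
            Mi[j] = max(Mp[j - 1], Xp[j - 1], Yp[j - 1]) + s
            Xi[j] = max(Mp[j] - gap_open, Xp[j] - gap_extend, Yp[j] - gap_open)
            Yi[j] = max(Mi[j - 1] - gap_open, Xi[j - 1] - gap_open,
                        Yi[j - 1] - gap_extend)

    # Traceback, tie order diagonal (M) > up (X) > left (Y).
    i, j = n, m
    finals = (M[i][j], X[i][j], Y[i][j])
    score = max(finals)
    state = finals.index(score)  # 0=M, 1=X, 2=Y
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            s = sub[(a[i - 1], b[j - 1])]
            prev = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            target = M[i][j] - s
            state = _pick(prev, target)
            i -= 1
            j -= 1
        elif state == 1:
            ra.append(a[i - 1])
            rb.append("-")
            prev = (M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                    Y[i - 1][j] - gap_open)
            state = _pick(prev, X[i][j])
            i -= 1
        else:
            ra.append("-")
            rb.append(b[j - 1])
            prev = (M[i][j - 1] - gap_open, X[i][j - 1] - gap_open,
                    Y[i][j - 1] - gap_extend)
            state = _pick(prev, Y[i][j])
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    aligned_a = "".join(reversed(ra))
    aligned_b = "".join(reversed(rb))
    cov, sim, ident = alignment_stats(aligned_a, aligned_b, sub)
    return AlignmentResult(aligned_a, aligned_b, score, cov, sim, ident)


def _pick(candidates: tuple[float, float, float], target: float) -> int:
    for k, v in enumerate(candidates):
        if abs(v - target) < 1e-9:
            return k
    # fall back to the best predecessor (guards float drift)
    return candidates.index(max(candidates))


def alignment_stats(aligned_a: str, aligned_b: str,
                    matrix: Mapping[tuple[str, str], float] | None = None,
                    ) -> tuple[float, float, float]:
    """(coverage, similarity, identity) of a gapped alignment pair."""
    sub = matrix if matrix is not None else _default_matrix()
    both = sim = ident = 0
    len_a = sum(c != "-" for c in aligned_a)
    len_b = sum(c != "-" for c in aligned_b)
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-" and cb != "-":
            both += 1
            if sub[(ca, cb)] > 0:
                sim += 1
            if ca == cb:
                ident += 1
    longer = max(len_a, len_b)
    coverage = both / longer if longer else 0.0
    similarity = sim / both if both else 0.0
    identity = ident / both if both else 0.0
    return coverage, similarity, identity


def detect_paralogs(sequences: Mapping[str, str],
                    coverage_min: float = 0.75,
                    similarity_min: float = 0.75,
                    matrix: Mapping[tuple[str, str], float] | None = None,
                    gap_open: float = 10.0,
                    gap_extend: float = 0.5) -> list[ParalogPair]:
    """Test all unordered pairs; keep those strictly above both thresholds."""
    ids = sorted(sequences)
    pairs: list[ParalogPair] = []
    for i, ida in enumerate(ids):
        for idb in ids[i + 1:]:
            aln = global_align(sequences[ida], sequences[idb],
                               matrix=matrix, gap_open=gap_open,
                               gap_extend=gap_extend)
            if aln.coverage > coverage_min and aln.similarity > similarity_min:
                pairs.append(ParalogPair(ida, idb, aln))
    return pairs


def classify_duplication(pair: ParalogPair,
                         gene_of: Mapping[str, GeneModel],
                         all_genes: Sequence[GeneModel],
                         max_intervening: int = 5,
                         max_span_bp: int = 100_000) -> ParalogPair:
    """Label a paralog pair tandem or segmental.

    Tandem requires same chromosome, at most ``max_intervening`` annotated
    genes lying wholly between the two gene spans, and a start-to-start
    span of at most ``max_span_bp``.
    """
    ga = gene_of[pair.member_a]
    gb = gene_of[pair.member_b]
    if ga.chromosome != gb.chromosome:
        pair.duplication_type = "segmental"
        return pair
    left, right = (ga, gb) if ga.start <= gb.start else (gb, ga)
    span = abs(ga.start - gb.start)
    intervening = sum(
        1 for g in all_genes
        if g.chromosome == ga.chromosome
        and g.gene_id not in (ga.gene_id, gb.gene_id)
        and g.start > left.end and g.end < right.start
    )
    pair.intervening_genes = intervening
    pair.span_bp = span
    if intervening <= max_intervening and span <= max_span_bp:
        pair.duplication_type = "tandem"
    else:
        pair.duplication_type = "segmental"
    return pair
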