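"""One-to-one ortholog curation and partner presence/absence partitioning.

The curation rule mirrors standard orthology hygiene for a query protein with
many family members: collapse multiple strains of one species to a single
representative, then, per organism, assign the candidate with the highest
percent identity to the query as the one-to-one ortholog — but only if that
identity strictly exceeds the candidate's identity to every supplied query
paralog (otherwise the candidate is likelier a co-ortholog of the paralog and
is rejected). Organisms are finally split by presence/absence of an assigned
partner-protein ortholog.

Percent identities come from an affine-gap global alignment (Gotoh
three-state recurrence) computed in-package so the procedure is
self-contained and deterministic. Conventions, stated because they vary
between tools:

* gap cost for a run of length k = ``gap_open + (k-1) * gap_extend``;
* identity denominator = all alignment columns (gapped columns count
  against identity);
* traceback tie-break prefers diagonal over up (gap in second sequence)
  over left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .io import GAP, SequenceRecord

_NEG = -1e30


def load_blosum62():
    return substitution_matrices.load("BLOSUM62")


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float


def _encode(seq: str, index: dict[str, int], name: str) -> np.ndarray:
    try:
        return np.array([index[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"sequence {name}: residue {exc.args[0]!r} not in substitution matrix")


def global_align(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences under affine gaps.

    Three-state dynamic programming: M (match/mismatch), Ix (gap in ``b``,
    i.e. a residue of ``a`` over a gap), Iy (gap in ``a``). Returns the
    optimal score and one deterministic traceback.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if matrix is None:
        matrix = load_blosum62()
    alphabet = str(matrix.alphabet)
    index = {c: i for i, c in enumerate(alphabet)}
    sub = np.asarray(matrix, dtype=float)
    ea = _encode(a, index, "a")
    eb = _encode(b, index, "b")
    la, lb = len(a), len(b)

    M = np.full((la + 1, lb + 1), _NEG)
    Ix = np.full((la + 1, lb + 1), _NEG)
    Iy = np.full((la + 1, lb + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        Ix[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, lb + 1):
        Iy[0, j] = -gap_open - (j - 1) * gap_extend

    js = np.arange(lb)
    for i in range(1, la + 1):
        srow = sub[ea[i - 1], eb]  # scores vs every b residue
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = srow + prev_best[:-1]
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:] - gap_open, Iy[i - 1, 1:] - gap_open),
            Ix[i - 1, 1:] - gap_extend,
        )
        Ix[i, 0] = -gap_open - (i - 1) * gap_extend
        # Iy along the row via a running-max scan:
        # Iy[j] = max_k<=j (cand[k] - (j-k)*extend), cand[j] = max(M,Ix)[j-1] - open
        cand = np.maximum(M[i, :-1], Ix[i, :-1]) - gap_open
        Iy[i, 1:] = np.maximum.accumulate(cand + js * gap_extend) - js * gap_extend

    # traceback; prefer M (diagonal) over Ix (up) over Iy (left) on ties
    i, j = la, lb
    finals = (M[i, j], Ix[i, j], Iy[i, j])
    state = int(np.argmax(finals))  # argmax returns first max -> M preferred
    score = float(finals[state])
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            cands = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = int(np.argmax(cands))
        elif state == 1:  # Ix: a[i-1] over gap
            out_a.append(a[i - 1])
            out_b.append(GAP)
            cands = (M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend, Iy[i - 1, j] - gap_open)
            i -= 1
            if i == 0 and j == 0:
                break
            state = int(np.argmax(cands))
            if i == 0 and j > 0:
                state = 2
        else:  # Iy: gap over b[j-1]
            out_a.append(GAP)
            out_b.append(b[j - 1])
            cands = (M[i, j - 1] - gap_open, Ix[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend)
            j -= 1
            if i == 0 and j == 0:
                break
            state = int(np.argmax(cands))
            if j == 0 and i > 0:
                state = 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    aln = PairwiseAlignment(aligned_a=aligned_a, aligned_b=aligned_b, score=score, identity=0.0)
    aln.identity = percent_identity(aln)
    return aln


def percent_identity(aln: PairwiseAlignment) -> float:
    """Identical-residue columns divided by total alignment columns."""
    cols = len(aln.aligned_a)
    if cols != len(aln.aligned_b) or cols == 0:
        raise ValueError("invalid alignment")
    same = sum(
        1
        for x, y in zip(aln.aligned_a, aln.aligned_b)
        if x == y and x != GAP
    )
    return same / cols


def _identity(
    rec: SequenceRecord,
    other: SequenceRecord,
    cache: dict | None,
    **align_kwargs,
) -> float:
    if cache is not None:
        key = (rec.id, other.id)
        if key in cache:
            return cache[key]
    ident = global_align(rec.sequence, other.sequence, **align_kwargs).identity
    if cache is not None:
        cache[(rec.id, other.id)] = ident
    return ident


def deduplicate_strains(
    records: list[SequenceRecord],
    query: SequenceRecord,
    cache: dict | None = None,
    **align_kwargs,
) -> list[SequenceRecord]:
    """Keep exactly one record per species_key.

    Among strains sharing a key the record with the highest identity to the
    query wins; ties go to the longer sequence, then the lexicographically
    smallest id. Input order of distinct species is preserved.
    """
    by_key: dict[str, SequenceRecord] = {}
    order: list[str] = []
    for rec in records:
        key = rec.species_key
        if key not in by_key:
            by_key[key] = rec
            order.append(key)
            continue
        cur = by_key[key]
        if _beats(rec, cur, query, cache, **align_kwargs):
            by_key[key] = rec
    return [by_key[k] for k in order]


def _beats(
    challenger: SequenceRecord,
    incumbent: SequenceRecord,
    query: SequenceRecord,
    cache: dict | None,
    **align_kwargs,
) -> bool:
    """Strain tie-break: identity to query desc, then length desc, then id asc."""
    a = _identity(challenger, query, cache, **align_kwargs)
    b = _identity(incumbent, query, cache, **align_kwargs)
    if a != b:
        return a > b
    if len(challenger.sequence) != len(incumbent.sequence):
        return len(challenger.sequence) > len(incumbent.sequence)
    return challenger.id < incumbent.id


@dataclass
class Assignment:
    record: SequenceRecord | None
    reason: str | None  # None when assigned; else a machine-readable code
    identity_query: float = float("nan")
    identity_best_paralog: float = float("nan")


def assign_one_to_one(
    candidates_by_organism: dict[str, list[SequenceRecord]],
    query: SequenceRecord,
    paralogs: list[SequenceRecord],
    cache: dict | None = None,
    **align_kwargs,
) -> dict[str, Assignment]:
    """Per organism, pick the one-to-one ortholog of the query.

    The candidate with the highest identity to the query (ties broken by
    lexicographic id) is assigned iff that identity strictly exceeds its
    identity to every query paralog; otherwise the organism is rejected with
    reason ``paralog_closer``. Empty candidate sets give ``no_candidate``.
    Output is invariant to candidate ordering.
    """
    out: dict[str, Assignment] = {}
    for organism in sorted(candidates_by_organism):
        cands = candidates_by_organism[organism]
        if not cands:
            out[organism] = Assignment(record=None, reason="no_candidate")
            continue
        best = cands[0]
        best_ident = _identity(best, query, cache, **align_kwargs)
        for rec in cands[1:]:
            ident = _identity(rec, query, cache, **align_kwargs)
            if ident > best_ident or (ident == best_ident and rec.id < best.id):
                best, best_ident = rec, ident
        id_query = best_ident
        id_par = max(
            (_identity(best, p, cache, **align_kwargs) for p in paralogs),
            default=float("-inf"),
        )
        if id_query > id_par:
            out[organism] = Assignment(
                record=best, reason=None, identity_query=id_query, identity_best_paralog=id_par
            )
        else:
            out[organism] = Assignment(
                record=None,
                reason="paralog_closer",
                identity_query=id_query,
                identity_best_paralog=id_par,
            )
    return out


@dataclass
class PartitionResult:
    assigned: dict[str, SequenceRecord]
    partner_positive: set[str]
    partner_negative: set[str]
    rejected: dict[str, str] = field(default_factory=dict)


def partition_by_partner(
    assignments: dict[str, Assignment] | dict[str, SequenceRecord],
    partner_organisms: set[str],
) -> PartitionResult:
    """Split organisms with an assigned ortholog by partner presence.

    ``partner_organisms`` is the authoritative set of organisms in which a
    one-to-one partner ortholog was detected. Both sides of the partition
    must be non-empty, else the comparison downstream is impossible.
    """
    assigned: dict[str, SequenceRecord] = {}
    rejected: dict[str, str] = {}
    for organism, val in assignments.items():
        if isinstance(val, Assignment):
            if val.record is not None:
                assigned[organism] = val.record
            else:
                rejected[organism] = val.reason or "unassigned"
        else:
            assigned[organism] = val
    if not assigned:
        raise ValueError("no assigned orthologs to partition")
    positive = set(assigned) & set(partner_organisms)
    negative = set(assigned) - positive
    if not positive or not negative:
        raise ValueError(
            "degenerate partition: partner-positive and partner-negative sets "
            f"have sizes ({len(positive)}, {len(negative)})"
        )
    return PartitionResult(
        assigned=assigned,
        partner_positive=positive,
        partner_negative=negative,
        rejected=rejected,
    )
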