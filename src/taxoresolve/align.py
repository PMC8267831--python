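"""Sequence alignment primitives.

Identity convention used everywhere in this package: matches divided by
aligned columns, excluding columns gapped in both sequences and excluding
terminal-gap columns.  Ambiguity codes count as mismatches.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX*"
_AA_INDEX = {a: i for i, a in enumerate(PROTEIN_ALPHABET)}


@lru_cache(maxsize=None)
def protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


@lru_cache(maxsize=None)
def nucleotide_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    aligner.mode = mode
    return aligner


def _sanitize_protein(seq: str) -> str:
    return "".join(c if c in _AA_INDEX else "X" for c in seq.upper())


def _sanitize_nucleotide(seq: str) -> str:
    return "".join(c if c in "ACGT" else "N" for c in seq.upper())


def identity_from_rows(row_a: str, row_b: str,
                       kind: str = "protein") -> tuple[int, int]:
    """(matches, comparable columns) for two equal-length gapped rows.

    Both-gap columns are excluded; so are terminal-gap columns of either
    row.  A gap opposite a residue counts as a comparable mismatch.
    Identical ambiguity codes (X for proteins, N for nucleotides) do not
    count as matches.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows have unequal length")
    a = np.frombuffer(row_a.encode(), dtype=np.uint8)
    b = np.frombuffer(row_b.encode(), dtype=np.uint8)
    gap = ord(GAP)
    nongap_a = a != gap
    nongap_b = b != gap
    lo = 0
    hi = len(a)
    if nongap_a.any() and nongap_b.any():
        lo = max(np.argmax(nongap_a), np.argmax(nongap_b))
        hi = min(
            len(a) - np.argmax(nongap_a[::-1]),
            len(b) - np.argmax(nongap_b[::-1]),
        )
    if hi <= lo:
        return 0, 0
    core = np.zeros(len(a), dtype=bool)
    core[lo:hi] = True
    comparable = core & (nongap_a | nongap_b)
    matches = comparable & (a == b) & nongap_a
    ambiguous = b"N" if kind == "nucleotide" else b"X"
    matches &= ~np.isin(a, np.frombuffer(ambiguous, dtype=np.uint8))
    return int(matches.sum()), int(comparable.sum())


def global_identity(seq_a: str, seq_b: str, kind: str = "protein") -> float:
    """Global-alignment identity (fraction in [0, 1]) of two sequences."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if kind == "protein":
        aligner = protein_aligner()
        sa, sb = _sanitize_protein(seq_a), _sanitize_protein(seq_b)
    else:
        aligner = nucleotide_aligner()
        sa, sb = _sanitize_nucleotide(seq_a), _sanitize_nucleotide(seq_b)
    aln = aligner.align(sa, sb)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches, columns = identity_from_rows(row_a, row_b, kind)
    if columns == 0:
        return 0.0
    return matches / columns


def aligned_rows(seq_a: str, seq_b: str, kind: str = "protein") -> tuple[str, str]:
    if kind == "protein":
        aligner = protein_aligner()
        sa, sb = _sanitize_protein(seq_a), _sanitize_protein(seq_b)
    else:
        aligner = nucleotide_aligner()
        sa, sb = _sanitize_nucleotide(seq_a), _sanitize_nucleotide(seq_b)
    aln = aligner.align(sa, sb)[0]
    return str(aln[0]), str(aln[1])


# ------------------------------------------------------------------ k-mers

@lru_cache(maxsize=65536)
def kmer_set(seq: str, k: int = 4) -> frozenset:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def kmer_containment(a: frozenset, b: frozenset) -> float:
    if not a or not b:
        return 0.0
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    return len(small & large) / len(small)


# ------------------------------------------- progressive profile alignment

_blosum = substitution_matrices.load("BLOSUM62")
_SCORE = np.zeros((len(PROTEIN_ALPHABET), len(PROTEIN_ALPHABET)))
for _i, _a in enumerate(PROTEIN_ALPHABET):
    for _j, _b in enumerate(PROTEIN_ALPHABET):
        _aa = _a if _a in _blosum.alphabet else "X"
        _bb = _b if _b in _blosum.alphabet else "X"
        _SCORE[_i, _j] = _blosum[_aa, _bb]


def _profile_matrix(rows: list[str]) -> np.ndarray:
    """Column frequency profile over the protein alphabet (gaps dropped)."""
    length = len(rows[0])
    prof = np.zeros((length, len(PROTEIN_ALPHABET)))
    for row in rows:
        for i, ch in enumerate(row):
            if ch != GAP:
                prof[i, _AA_INDEX.get(ch, _AA_INDEX["X"])] += 1
    totals = prof.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return prof / totals


def _profile_align(rows_a: list[str], rows_b: list[str],
                   gap_open: float = -11.0, gap_extend: float = -1.0
                   ) -> tuple[list[str], list[str]]:
    """Gotoh profile-profile alignment; returns gapped copies of both groups."""
    pa = _profile_matrix(rows_a)
    pb = _profile_matrix(rows_b)
    la, lb = pa.shape[0], pb.shape[0]
    sub = pa @ _SCORE @ pb.T  # (la, lb) expected column score

    neg = -1e30
    m = np.full((la + 1, lb + 1), neg)
    ix = np.full((la + 1, lb + 1), neg)  # gap in b (consume a)
    iy = np.full((la + 1, lb + 1), neg)  # gap in a (consume b)
    m[0, 0] = 0.0
    ix[1:, 0] = gap_open + gap_extend * np.arange(la)
    iy[0, 1:] = gap_open + gap_extend * np.arange(lb)
    ptr_m = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_x = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_y = np.zeros((la + 1, lb + 1), dtype=np.int8)

    for i in range(1, la + 1):
        prev_m, prev_x, prev_y = m[i - 1], ix[i - 1], iy[i - 1]
        # Ix: vertical moves depend only on the previous row.
        cand = np.stack([prev_m + gap_open, prev_x + gap_extend,
                         prev_y + gap_open])
        ptr_x[i] = np.argmax(cand, axis=0)
        ix[i] = cand[ptr_x[i], np.arange(lb + 1)]
        # M and Iy need a sequential pass along j.
        row_m = m[i]
        row_y = iy[i]
        srow = sub[i - 1]
        for j in range(1, lb + 1):
            best = prev_m[j - 1]
            arg = 0
            if prev_x[j - 1] > best:
                best, arg = prev_x[j - 1], 1
            if prev_y[j - 1] > best:
                best, arg = prev_y[j - 1], 2
            row_m[j] = best + srow[j - 1]
            ptr_m[i, j] = arg
            go = row_m[j - 1] + gap_open
            gx = ix[i, j - 1] + gap_open
            gy = row_y[j - 1] + gap_extend
            best, arg = go, 0
            if gx > best:
                best, arg = gx, 1
            if gy > best:
                best, arg = gy, 2
            row_y[j] = best
            ptr_y[i, j] = arg

    i, j = la, lb
    state = int(np.argmax([m[i, j], ix[i, j], iy[i, j]]))
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            ops.append("M")
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            ops.append("X")
            state = int(ptr_x[i, j])
            i -= 1
        elif state == 2 and j > 0:
            ops.append("Y")
            state = int(ptr_y[i, j])
            j -= 1
        elif i > 0:
            ops.append("X")
            i -= 1
        else:
            ops.append("Y")
            j -= 1
    ops.reverse()

    def expand(rows: list[str], consume: str) -> list[str]:
        out = []
        for row in rows:
            buf = []
            pos = 0
            for op in ops:
                if op == consume or op == "M":
                    buf.append(row[pos])
                    pos += 1
                else:
                    buf.append(GAP)
            out.append("".join(buf))
        return out

    return expand(rows_a, "X"), expand(rows_b, "Y")


def progressive_align(seqs: list[str]) -> list[str]:
    """Progressive multiple protein alignment.

    Guide tree: UPGMA on k-mer distance; merges: Gotoh profile-profile
    alignment with affine gaps.  Deterministic for a fixed input order.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    seqs = [_sanitize_protein(s) for s in seqs]
    n = len(seqs)
    if n == 1:
        return list(seqs)

    ksets = [kmer_set(s, 3) for s in seqs]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - kmer_containment(ksets[i], ksets[j])
            dist[i, j] = dist[j, i] = d

    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    order = linkage(squareform(dist, checks=False), method="average")

    groups: dict[int, tuple[list[str], list[int]]] = {
        i: ([seqs[i]], [i]) for i in range(n)
    }
    next_id = n
    for a, b, _, _ in order:
        rows_a, idx_a = groups.pop(int(a))
        rows_b, idx_b = groups.pop(int(b))
        new_a, new_b = _profile_align(rows_a, rows_b)
        groups[next_id] = (new_a + new_b, idx_a + idx_b)
        next_id += 1

    (rows, idx), = groups.values()
    out = [""] * n
    for row, i in zip(rows, idx):
        out[i] = row
    return out
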