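"""Pairwise genomic similarity metrics.

ANI follows the fragment-alignment recipe: the query genome is cut into
fixed-length fragments, each is locally aligned to its best-matching site
in the subject, fragments passing identity/coverage filters are averaged,
and the two reciprocal directions are averaged for symmetry.

dDDH maps the pooled fragment-match divergence d = 1 - matches/columns
through a monotone calibration curve with f(0) = 100.  The calibration is
config data: the default exponential constant is anchored so that the 95%
ANI and 70% dDDH species boundaries coincide (d = 0.05 -> 70).
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import align
from .coregenome import ConcatenatedAlignment
from .model import MetricRecord, StrainRecord

log = logging.getLogger(__name__)

#: Decay constant of the default dDDH calibration: ln(100/70) / 0.05.
DDDH_DECAY = math.log(100.0 / 70.0) / 0.05


@dataclass
class FragmentParams:
    fragment_length: int = 1020
    min_identity: float = 0.3
    min_coverage: float = 0.7
    kmer: int = 12
    kmer_stride: int = 4
    window_pad: int = 400


# ------------------------------------------------------------------- G+C

def gc_content(record: StrainRecord) -> float:
    """Percent G+C over unambiguous bases of the whole genome."""
    if not record.genome or all(len(s) == 0 for s in record.genome):
        raise ValueError(f"strain {record.strain_id}: empty genome")
    gc = 0
    total = 0
    for seq in record.genome:
        gc += seq.count("G") + seq.count("C")
        total += sum(seq.count(b) for b in "ACGT")
    if total == 0:
        raise ValueError(f"strain {record.strain_id}: no unambiguous bases")
    return 100.0 * gc / total


# ----------------------------------------------------------- ANI and dDDH

def _fragments(genome: list[str], length: int) -> list[str]:
    frags = []
    for contig in genome:
        for start in range(0, len(contig) - length + 1, length):
            frags.append(contig[start:start + length])
        tail = len(contig) % length
        if tail >= max(100, length // 4) and len(contig) >= length:
            frags.append(contig[len(contig) - tail:])
        elif len(contig) < length and len(contig) >= 100:
            frags.append(contig)
    return frags


def _subject_index(subject: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(0, len(subject) - k + 1):
        index[subject[i:i + k]].append(i)
    return index


def _best_window(fragment: str, subject: str, index, params: FragmentParams
                 ) -> Optional[tuple[int, int]]:
    k = params.kmer
    votes: dict[int, int] = defaultdict(int)
    bin_width = 100
    for q in range(0, len(fragment) - k + 1, params.kmer_stride):
        for p in index.get(fragment[q:q + k], ()):
            votes[(p - q) // bin_width] += 1
    if not votes:
        return None
    best_bin = min(b for b, v in votes.items()
                   if v == max(votes.values()))
    diag = best_bin * bin_width
    start = max(0, diag - params.window_pad)
    end = min(len(subject), diag + len(fragment) + params.window_pad)
    if end <= start:
        return None
    return start, end


def _match_fragments(query: list[str], subject: list[str],
                     params: FragmentParams) -> list[tuple[int, int]]:
    """(matches, columns) per retained fragment of one direction."""
    subject_concat = "#".join(s for s in subject if s)
    if not subject_concat:
        return []
    index = _subject_index(subject_concat, params.kmer)
    aligner = align.nucleotide_aligner("local")
    out = []
    for frag in _fragments(query, params.fragment_length):
        window = _best_window(frag, subject_concat, index, params)
        if window is None:
            continue
        target = subject_concat[window[0]:window[1]]
        aln = aligner.align(frag.replace("#", "N"), target)
        if len(aln) == 0:
            continue
        best = aln[0]
        row_q, row_s = str(best[0]), str(best[1])
        matches, columns = align.identity_from_rows(row_q, row_s,
                                                    "nucleotide")
        if columns == 0:
            continue
        identity = matches / columns
        # Coverage: aligned query residues relative to the fragment length.
        aligned_query = sum(e - s for s, e in best.aligned[0])
        coverage = aligned_query / len(frag)
        if identity > params.min_identity and coverage > params.min_coverage:
            out.append((matches, columns))
    return out


def ani(a: StrainRecord, b: StrainRecord,
        params: FragmentParams | None = None) -> Optional[float]:
    """Average nucleotide identity (%), mean of the reciprocal directions."""
    params = params or FragmentParams()
    if not a.genome or not b.genome:
        raise ValueError("empty genome")
    directions = []
    for query, subject in ((a, b), (b, a)):
        hits = _match_fragments(query.genome, subject.genome, params)
        if not hits:
            log.warning("ANI %s vs %s: no retained fragments",
                        query.strain_id, subject.strain_id)
            return None
        directions.append(
            sum(m / c for m, c in hits) / len(hits)
        )
    return 100.0 * (directions[0] + directions[1]) / 2.0


def ddd_hybridization(a: StrainRecord, b: StrainRecord,
                      params: FragmentParams | None = None,
                      decay: float = DDDH_DECAY) -> Optional[float]:
    """dDDH (%) from the pooled fragment matches of both directions."""
    params = params or FragmentParams()
    if not a.genome or not b.genome:
        raise ValueError("empty genome")
    matches = 0
    columns = 0
    for query, subject in ((a, b), (b, a)):
        hits = _match_fragments(query.genome, subject.genome, params)
        matches += sum(m for m, _ in hits)
        columns += sum(c for _, c in hits)
    if columns == 0:
        log.warning("dDDH %s vs %s: no matched segments",
                    a.strain_id, b.strain_id)
        return None
    d = 1.0 - matches / columns
    return 100.0 * math.exp(-decay * d)


# -------------------------------------------------------------------- AAI

def aai(a: StrainRecord, b: StrainRecord,
        min_identity: float = 0.3, min_coverage: float = 0.7,
        n_candidates: int = 2) -> Optional[float]:
    """Mean identity over reciprocal-best-hit protein pairs (%)."""
    prot_a = {g.gene_id: g.protein_seq for g in a.proteome()}
    prot_b = {g.gene_id: g.protein_seq for g in b.proteome()}
    if not prot_a or not prot_b:
        raise ValueError("empty proteome")

    cache: dict = {}
    best_ab, info_ab = _best_hits(prot_a, prot_b, n_candidates, cache)
    best_ba, _ = _best_hits(prot_b, prot_a, n_candidates, cache)

    identities = []
    for ga, gb in best_ab.items():
        if best_ba.get(gb) != ga:
            continue
        identity, columns = info_ab[ga]
        if columns == 0:
            continue
        coverage = columns / min(len(prot_a[ga]), len(prot_b[gb]))
        if identity < min_identity or coverage < min_coverage:
            continue
        identities.append(identity)
    if not identities:
        log.warning("AAI %s vs %s: no reciprocal best hits retained",
                    a.strain_id, b.strain_id)
        return None
    return 100.0 * sum(identities) / len(identities)


def _best_hits(query: dict[str, str], subject: dict[str, str],
               n_candidates: int, cache: Optional[dict] = None
               ) -> tuple[dict[str, str], dict[str, tuple[float, int]]]:
    """Best subject protein per query protein (3-mer prescreened).

    Returns the hit map and, per query, (identity, comparable columns)
    of its best alignment.  ``cache`` memoizes alignments across the two
    reciprocal passes (global alignment is symmetric).
    """
    if cache is None:
        cache = {}
    kindex: dict[str, set[str]] = defaultdict(set)
    for sid, seq in subject.items():
        for kmer in align.kmer_set(seq, 3):
            kindex[kmer].add(sid)
    aligner = align.protein_aligner()
    hits: dict[str, str] = {}
    info: dict[str, tuple[float, int]] = {}

    def score_pair(sa: str, sb: str) -> tuple[float, float, int]:
        key = (sa, sb) if sa <= sb else (sb, sa)
        hit = cache.get(key)
        if hit is None:
            aln = aligner.align(align._sanitize_protein(key[0]),
                                align._sanitize_protein(key[1]))[0]
            matches, columns = align.identity_from_rows(
                str(aln[0]), str(aln[1]), "protein")
            identity = matches / columns if columns else 0.0
            hit = (float(aln.score), identity, columns)
            cache[key] = hit
        return hit

    for qid in sorted(query):
        qseq = query[qid]
        shared: dict[str, int] = defaultdict(int)
        for kmer in align.kmer_set(qseq, 3):
            for sid in kindex.get(kmer, ()):
                shared[sid] += 1
        if not shared:
            continue
        candidates = sorted(shared, key=lambda s: (-shared[s], s))[:n_candidates]
        best = None
        for sid in candidates:
            score, identity, columns = score_pair(qseq, subject[sid])
            key = (score, identity)
            if (best is None or key > (best[0], best[1])
                    or (key == (best[0], best[1]) and sid < best[2])):
                best = (score, identity, sid, columns)
        if best is not None:
            hits[qid] = best[2]
            info[qid] = (best[1], best[3])
    return hits, info


# ---------------------------------------------------- alignment-based CP

def codon_position_similarity(alignment: ConcatenatedAlignment,
                              a: str, b: str
                              ) -> tuple[float, float, float]:
    """Percent identity at codon positions 1-3 of the nt alignment."""
    row_a = alignment.nucleotide[a]
    row_b = alignment.nucleotide[b]
    ca = np.frombuffer(row_a.encode(), dtype=np.uint8)
    cb = np.frombuffer(row_b.encode(), dtype=np.uint8)
    gap = ord("-")
    nongap_a = ca != gap
    nongap_b = cb != gap
    comparable = nongap_a | nongap_b
    # Terminal gap trimming per the shared identity definition.
    if nongap_a.any() and nongap_b.any():
        lo = max(int(np.argmax(nongap_a)), int(np.argmax(nongap_b)))
        hi = min(len(ca) - int(np.argmax(nongap_a[::-1])),
                 len(cb) - int(np.argmax(nongap_b[::-1])))
        core = np.zeros(len(ca), dtype=bool)
        core[lo:hi] = True
        comparable &= core
    eq = (ca == cb) & nongap_a & ~np.isin(ca, np.frombuffer(b"N", dtype=np.uint8))
    out = []
    for k in range(3):
        cols = np.zeros(len(ca), dtype=bool)
        cols[k::3] = True
        denom = int((comparable & cols).sum())
        if denom == 0:
            raise ValueError(f"no codon-position-{k + 1} columns for ({a}, {b})")
        out.append(100.0 * int((eq & comparable & cols).sum()) / denom)
    return tuple(out)


# ---------------------------------------------------------------- 16S id

def s16_identity(a: StrainRecord, b: StrainRecord) -> Optional[float]:
    ga, gb = a.gene_16s(), b.gene_16s()
    if ga is None or gb is None:
        log.warning("16S missing for %s or %s",
                    a.strain_id, b.strain_id)
        return None
    return 100.0 * align.global_identity(
        ga.nucleotide_seq, gb.nucleotide_seq, "nucleotide")


# ------------------------------------------------------------ assembly

def pair_record(a: StrainRecord, b: StrainRecord,
                alignment: Optional[ConcatenatedAlignment] = None,
                pd: Optional[float] = None,
                with_ani: bool = False,
                params: FragmentParams | None = None) -> MetricRecord:
    """Assemble a MetricRecord for one pair (ANI/dDDH optional: costly)."""
    cp1 = cp2 = cp3 = None
    if alignment is not None:
        cp1, cp2, cp3 = codon_position_similarity(
            alignment, a.strain_id, b.strain_id)
    return MetricRecord(
        strain_a=a.strain_id,
        strain_b=b.strain_id,
        ani=ani(a, b, params) if with_ani else None,
        aai=aai(a, b),
        dddh=ddd_hybridization(a, b, params) if with_ani else None,
        cp1=cp1, cp2=cp2, cp3=cp3,
        pd=pd,
        s16_identity=s16_identity(a, b),
        gc_a=gc_content(a) if a.genome else None,
        gc_b=gc_content(b) if b.genome else None,
    )
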