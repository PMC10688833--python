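"""Pairwise intergenomic nucleotide similarity.

The intergenomic similarity of two genomes is the percentage of their
total paired length covered by identically aligned nucleotides:

    sim(a, b) = 100 * (id_a + id_b) / (len_a + len_b)

where ``id_a`` is the number of query positions of ``a`` matched in
local alignments against ``b`` (each position counted at most once) and
``id_b`` likewise for ``b``.  Unaligned genome fraction therefore
depresses similarity, which is what makes the 70% genus and 95% species
demarcations meaningful for genomes of unequal length.

Alignments are found by seed-and-extend: exact ``k``-mer seeds (k = 11)
on both strands, grouped by diagonal into candidate regions.  Small
regions are resolved by exact affine-gap local dynamic programming with
iterative masking (so multiple HSPs per region are recovered); regions
too large for full DP — in practice near-full-length homologies between
long genomes — are resolved gaplessly per seed diagonal by enumerating
all maximal-scoring segments (Ruzzo–Tompa).  Scoring is BLASTN-like:
match +2, mismatch −3, gap of length L costs 5 + 2L, and alignments
scoring below 50 are discarded.  N never scores as a match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .records import GenomeRecord, SimilarityMatrix

__all__ = [
    "AlignmentParams",
    "LocalAlignment",
    "PairSimilarity",
    "local_alignments",
    "merge_coverage",
    "intergenomic_similarity",
    "similarity_matrix",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Seed-and-extend parameters (BLASTN-like defaults)."""

    seed_k: int = 11
    match: int = 2
    mismatch: int = 3  # penalty, applied as a negative score
    gap_open: int = 5  # gap of length L scores -(gap_open + gap_extend * L)
    gap_extend: int = 2
    min_score: int = 50
    # candidate-region construction
    diag_band: int = 50
    margin: int = 50
    strong_seed_count: int = 3
    escalate_score: int = 40
    max_dp_area: int = 16_000_000
    max_dp_iters: int = 64

    def __post_init__(self) -> None:
        if self.seed_k < 4:
            raise ValueError("seed_k must be >= 4")
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")


@dataclass
class LocalAlignment:
    """One local alignment (HSP) between a query and a subject genome.

    Coordinates are 0-based half-open on the forward strand of both
    genomes; for ``strand == '-'`` the aligned subject segment is the
    reverse complement of ``sequence[sstart:send]``.  ``columns`` hold
    the residue-residue aligned positions (gap columns excluded).
    """

    query_id: str
    subject_id: str
    qstart: int
    qend: int
    sstart: int
    send: int
    strand: str
    identities: int
    score: float
    qpos: np.ndarray = field(repr=False)  # aligned query positions
    spos: np.ndarray = field(repr=False)  # aligned subject positions (fwd coords)
    match: np.ndarray = field(repr=False)  # per-column identity flags
    qlen: int = 0
    slen: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend):
            raise ValueError("invalid query interval")
        if self.identities > min(self.qend - self.qstart, abs(self.send - self.sstart)):
            raise ValueError("identities exceed alignment span")
        if self.score <= 0:
            raise ValueError("alignment score must be positive")


@dataclass(frozen=True)
class PairSimilarity:
    """Intergenomic similarity of one genome pair with coverage detail."""

    intergenomic_similarity: float
    aligned_fraction_a: float
    aligned_fraction_b: float
    length_ratio: float


# ---------------------------------------------------------------------------
# sequence encoding and seeding

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate("ACGTN"):
    _CODE[ord(_ch)] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return np.where(codes < 4, 3 - codes, codes)[::-1]


def _kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (hashes, valid) for every k-window; windows with N are invalid."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    hashes = (win.astype(np.int64) * powers).sum(axis=1)
    return hashes, valid


def _seed_positions(
    qh: np.ndarray, qvalid: np.ndarray, sh: np.ndarray, svalid: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """All (query_pos, subject_pos) pairs sharing an exact k-mer."""
    if len(qh) == 0 or len(sh) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    table = np.zeros(4**k, dtype=bool)
    qh_valid = qh[qvalid]
    table[qh_valid] = True
    s_idx = np.nonzero(svalid & table[sh])[0]
    if len(s_idx) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    qpos_all = np.nonzero(qvalid)[0]
    order = np.argsort(qh_valid, kind="stable")
    sorted_h = qh_valid[order]
    ch = sh[s_idx]
    left = np.searchsorted(sorted_h, ch, side="left")
    right = np.searchsorted(sorted_h, ch, side="right")
    counts = right - left
    total = int(counts.sum())
    s_out = np.repeat(s_idx, counts)
    offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts) + np.repeat(
        left, counts
    )
    q_out = qpos_all[order[offs]]
    return q_out, s_out


# ---------------------------------------------------------------------------
# gapless diagonal HSPs (Ruzzo–Tompa enumeration)


def _ruzzo_tompa(values: np.ndarray) -> list[tuple[int, int, float]]:
    """All maximal-scoring subsequences of a score vector.

    Input is run-compressed before applying the algorithm, so the cost
    is linear in the number of sign changes.  Returns (start, end, score)
    element intervals.
    """
    # run-length compress consecutive equal-sign stretches
    sign = np.sign(values)
    breaks = np.nonzero(np.diff(sign))[0] + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [len(values)]))
    run_scores = np.add.reduceat(values, starts)
    # Ruzzo–Tompa over runs
    subs: list[list[float | int]] = []  # [start_run, end_run, L, R]
    cum = 0.0
    for ridx, v in enumerate(run_scores):
        L, cum = cum, cum + float(v)
        if v <= 0:
            continue
        cur = [ridx, ridx + 1, L, cum]
        while True:
            j = None
            for jj in range(len(subs) - 1, -1, -1):
                if subs[jj][2] < cur[2]:
                    j = jj
                    break
            if j is None or subs[j][3] >= cur[3]:
                subs.append(cur)
                break
            cur = [subs[j][0], cur[1], subs[j][2], cur[3]]
            del subs[j:]
    return [
        (int(starts[s[0]]), int(ends[s[1] - 1]), float(s[3] - s[2])) for s in subs
    ]


def _diagonal_hsps(
    qcodes: np.ndarray,
    scodes: np.ndarray,
    diag: int,
    params: AlignmentParams,
) -> list[tuple[int, int, float, np.ndarray]]:
    """Maximal gapless HSPs on one diagonal (diag = qpos - spos).

    Returns (qstart, qend, score, match_flags) with score >= min_score.
    """
    q0 = max(0, diag)
    q1 = min(len(qcodes), len(scodes) + diag)
    if q1 - q0 < 1:
        return []
    qs = qcodes[q0:q1]
    ss = scodes[q0 - diag : q1 - diag]
    match = (qs == ss) & (qs < 4)
    scores = np.where(match, float(params.match), -float(params.mismatch))
    out = []
    # A maximal-scoring subsequence has strictly positive prefix sums, so
    # it never spans a position where the best subarray ending there is
    # <= 0 (a Kadane reset).  Split at resets and enumerate only the
    # segments that can reach min_score.
    cum = np.cumsum(scores)
    best_ending = cum - np.minimum.accumulate(np.concatenate(([0.0], cum[:-1])))
    alive = best_ending > 0
    padded = np.concatenate(([False], alive, [False]))
    edges = np.nonzero(np.diff(padded.astype(np.int8)))[0]
    for s, e in zip(edges[::2], edges[1::2]):
        if best_ending[s:e].max() < params.min_score:
            continue
        for rs, re_, sc in _ruzzo_tompa(scores[s:e]):
            if sc >= params.min_score:
                out.append((q0 + s + rs, q0 + s + re_, sc, match[s + rs : s + re_]))
    return out


# ---------------------------------------------------------------------------
# exact DP on candidate windows


@lru_cache(maxsize=8)
def _nt_aligner(match: int, mismatch: int, gap_open: int, gap_extend: int) -> PairwiseAligner:
    alphabet = "ACGTNXY"
    mat = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a in "XY" or b in "XY":
                mat[a, b] = -1_000_000.0  # mask symbols never align
            elif a == b and a in "ACGT":
                mat[a, b] = float(match)
            else:
                mat[a, b] = -float(mismatch)  # N never matches, even N vs N
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _dp_window_hsps(
    qseq: str,
    sseq: str,
    q_off: int,
    s_off: int,
    params: AlignmentParams,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, float]]:
    """Iterated masked local DP inside one window.

    Returns per-HSP (query_positions, subject_positions, match_flags,
    score) in window-local coordinates shifted by the offsets.
    """
    aligner = _nt_aligner(params.match, params.mismatch, params.gap_open, params.gap_extend)
    qchars = list(qseq)
    schars = list(sseq)
    hsps = []
    for _ in range(params.max_dp_iters):
        alns = aligner.align("".join(qchars), "".join(schars))
        if alns.score < params.min_score:
            break
        aln = alns[0]
        qblocks, sblocks = aln.aligned
        qp, sp, mt = [], [], []
        for (qb0, qb1), (sb0, sb1) in zip(qblocks, sblocks):
            for o in range(qb1 - qb0):
                a, b = qchars[qb0 + o], schars[sb0 + o]
                qp.append(qb0 + o)
                sp.append(sb0 + o)
                mt.append(a == b and a in "ACGT")
        if not qp:
            break
        for p in qp:
            qchars[p] = "X"
        for p in sp:
            schars[p] = "Y"
        hsps.append(
            (
                np.asarray(qp, dtype=np.int64) + q_off,
                np.asarray(sp, dtype=np.int64) + s_off,
                np.asarray(mt, dtype=bool),
                float(alns.score),
            )
        )
    return hsps


# ---------------------------------------------------------------------------
# seed clustering into candidate regions


def _candidate_regions(
    qpos: np.ndarray, spos: np.ndarray, params: AlignmentParams
) -> tuple[list[dict], list[int]]:
    """Group seeds into boxes (strong diagonals) and stray diagonals.

    Returns (boxes, weak_diags).  Each box records its diagonal range
    and seed extent; weak diagonals are those with too few seeds to
    anchor a region and are screened separately.
    """
    diags = qpos - spos
    uniq, inverse, counts = np.unique(diags, return_inverse=True, return_counts=True)
    strong = counts >= params.strong_seed_count
    boxes: list[dict] = []
    if strong.any():
        sdiags = uniq[strong]
        group: list[int] = []
        prev = None
        groups = []
        for d in sdiags:
            if prev is not None and d - prev > params.diag_band:
                groups.append(group)
                group = []
            group.append(int(d))
            prev = d
        groups.append(group)
        for g in groups:
            sel = np.isin(diags, g)
            boxes.append(
                {
                    "diags": g,
                    "qmin": int(qpos[sel].min()),
                    "qmax": int(qpos[sel].max()),
                    "smin": int(spos[sel].min()),
                    "smax": int(spos[sel].max()),
                }
            )
    weak = []
    for d, c in zip(uniq, counts):
        if c >= params.strong_seed_count:
            continue
        in_box = any(
            b["diags"][0] - params.diag_band <= d <= b["diags"][-1] + params.diag_band
            for b in boxes
        )
        if not in_box:
            weak.append(int(d))
    return boxes, weak


def _screen_weak_diag(
    qcodes: np.ndarray,
    scodes: np.ndarray,
    diag: int,
    seeds_q: np.ndarray,
    params: AlignmentParams,
    radius: int = 64,
) -> bool:
    """Cheap gapless screen: does any seed context reach escalate_score?"""
    for q in seeds_q:
        w0 = max(max(0, diag), q - radius)
        w1 = min(min(len(qcodes), len(scodes) + diag), q + params.seed_k + radius)
        qs = qcodes[w0:w1]
        ss = scodes[w0 - diag : w1 - diag]
        match = (qs == ss) & (qs < 4)
        scores = np.where(match, float(params.match), -float(params.mismatch))
        cum = np.cumsum(scores)
        best = (cum - np.minimum.accumulate(np.concatenate(([0.0], cum[:-1])))).max()
        if best >= params.escalate_score:
            return True
    return False


def local_alignments(
    a: GenomeRecord, b: GenomeRecord, params: AlignmentParams = AlignmentParams()
) -> list[LocalAlignment]:
    """Seed-and-extend local alignments of b against a, both strands.

    Returns alignments sorted by descending score (ties by query start,
    then subject start).  Genomes sharing no exact seed k-mer yield an
    empty list.
    """
    k = params.seed_k
    qcodes = _encode(a.sequence)
    qh, qvalid = _kmer_hashes(qcodes, k)
    results: list[LocalAlignment] = []

    for strand in "+-":
        if strand == "+":
            scodes = _encode(b.sequence)
        else:
            scodes = _revcomp_codes(_encode(b.sequence))
        sh, svalid = _kmer_hashes(scodes, k)
        qpos, spos = _seed_positions(qh, qvalid, sh, svalid, k)
        if len(qpos) == 0:
            continue
        boxes, weak_diags = _candidate_regions(qpos, spos, params)
        diags = qpos - spos

        rt_diags: set[int] = set()
        for box in boxes:
            q0 = max(0, box["qmin"] - params.margin)
            q1 = min(a.length, box["qmax"] + k + params.margin)
            s0 = max(0, box["smin"] - params.margin)
            s1 = min(len(scodes), box["smax"] + k + params.margin)
            if (q1 - q0) * (s1 - s0) <= params.max_dp_area:
                qseq = a.sequence[q0:q1]
                if strand == "+":
                    sseq = b.sequence[s0:s1]
                else:
                    sseq = _decode(scodes[s0:s1])
                for qp, sp, mt, score in _dp_window_hsps(qseq, sseq, q0, s0, params):
                    results.append(
                        _make_alignment(a, b, qp, sp, mt, score, strand, len(scodes))
                    )
            else:
                rt_diags.update(box["diags"])

        for d in weak_diags:
            seeds_q = qpos[diags == d]
            if _screen_weak_diag(qcodes, scodes, d, seeds_q, params):
                rt_diags.add(d)

        for d in sorted(rt_diags):
            for qs_, qe_, score, mt in _diagonal_hsps(qcodes, scodes, d, params):
                qp = np.arange(qs_, qe_, dtype=np.int64)
                sp = qp - d
                results.append(
                    _make_alignment(a, b, qp, sp, mt, score, strand, len(scodes))
                )

    results.sort(key=lambda h: (-h.score, h.qstart, h.sstart))
    return results


def _decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def _make_alignment(
    a: GenomeRecord,
    b: GenomeRecord,
    qp: np.ndarray,
    sp: np.ndarray,
    mt: np.ndarray,
    score: float,
    strand: str,
    slen: int,
) -> LocalAlignment:
    if strand == "-":
        sp = slen - 1 - sp
    s0, s1 = int(sp.min()), int(sp.max()) + 1
    return LocalAlignment(
        query_id=a.id,
        subject_id=b.id,
        qstart=int(qp.min()),
        qend=int(qp.max()) + 1,
        sstart=s0,
        send=s1,
        strand=strand,
        identities=int(mt.sum()),
        score=score,
        qpos=qp,
        spos=sp,
        match=mt,
        qlen=a.length,
        slen=slen,
    )


def merge_coverage(
    hits: list[LocalAlignment], side: str = "query", length: int | None = None
) -> list[tuple[int, int, int]]:
    """Resolve overlapping HSPs into disjoint covered intervals.

    Hits are processed in descending score order (ties by start on the
    chosen side, then by the opposite id); each hit contributes only
    positions not already covered, so per-position identities are
    counted at most once.  Returns (start, end, identities) intervals.
    """
    if side not in ("query", "subject"):
        raise ValueError("side must be 'query' or 'subject'")
    if not hits:
        return []
    own = "query_id" if side == "query" else "subject_id"
    other = "subject_id" if side == "query" else "query_id"
    ids = {getattr(h, own) for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits mix several {side} ids: {sorted(ids)}")
    if length is None:
        length = max((h.qlen if side == "query" else h.slen) for h in hits)

    startkey = "qstart" if side == "query" else "sstart"
    order = sorted(hits, key=lambda h: (-h.score, getattr(h, startkey), getattr(h, other)))
    covered = np.zeros(length, dtype=bool)
    identical = np.zeros(length, dtype=bool)
    for h in order:
        pos = h.qpos if side == "query" else h.spos
        novel = ~covered[pos]
        covered[pos[novel]] = True
        identical[pos[novel]] = h.match[novel]

    out = []
    padded = np.concatenate(([False], covered, [False]))
    edges = np.nonzero(np.diff(padded.astype(np.int8)))[0]
    for s, e in zip(edges[::2], edges[1::2]):
        out.append((int(s), int(e), int(identical[s:e].sum())))
    return out


def intergenomic_similarity(
    a: GenomeRecord, b: GenomeRecord, params: AlignmentParams = AlignmentParams()
) -> PairSimilarity:
    """VIRIDIC-style intergenomic similarity of one genome pair.

    The pair is canonicalized by id before alignment so the measure is
    exactly symmetric in its arguments.
    """
    swapped = b.id < a.id
    x, y = (b, a) if swapped else (a, b)
    if x.id == y.id and x.sequence == y.sequence:
        return PairSimilarity(100.0, 1.0, 1.0, 1.0)
    hits = local_alignments(x, y, params)
    idx = cov_x = idy = cov_y = 0
    for s, e, ident in merge_coverage(hits, "query", x.length) if hits else []:
        idx += ident
        cov_x += e - s
    for s, e, ident in merge_coverage(hits, "subject", y.length) if hits else []:
        idy += ident
        cov_y += e - s
    sim = 100.0 * (idx + idy) / (x.length + y.length)
    frac_x = cov_x / x.length
    frac_y = cov_y / y.length
    if swapped:
        frac_x, frac_y = frac_y, frac_x
    return PairSimilarity(
        intergenomic_similarity=min(sim, 100.0),
        aligned_fraction_a=frac_x,
        aligned_fraction_b=frac_y,
        length_ratio=min(a.length, b.length) / max(a.length, b.length),
    )


def similarity_matrix(
    genomes: list[GenomeRecord], params: AlignmentParams = AlignmentParams()
) -> SimilarityMatrix:
    """All-vs-all intergenomic similarity (each unordered pair computed once)."""
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    n = len(genomes)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            s = intergenomic_similarity(genomes[i], genomes[j], params)
            values[i, j] = values[j, i] = s.intergenomic_similarity
    return SimilarityMatrix(ids, values, "nucleotide")
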