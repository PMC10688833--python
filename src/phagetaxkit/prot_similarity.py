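"""Fragmented, translated, self-score-normalized genome comparison.

Each query genome is cut into overlapping fixed-length nucleotide
fragments (200 bp, 100 bp step by default).  Every fragment is
translated in all six reading frames and locally aligned (BLOSUM62,
affine gaps) against the six translated frames of a target genome; a
fragment's contribution is its single best alignment score, floored at
zero.  The directional similarity of query q against target t is

    score(q -> t) = 100 * sum_f best(f, t) / sum_f best(f, q)

i.e. the fragments' best scores expressed as a percentage of the score
the genome obtains against itself.  The resulting percent matrix is
asymmetric in general: a genome entirely contained in a larger one
scores 100 in the containment direction but less in the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .records import GenomeRecord, SimilarityMatrix

__all__ = [
    "FragmentationParams",
    "Fragment",
    "fragment_genome",
    "six_frame_translations",
    "translated_best_score",
    "gegenees_score",
    "FragmentScoreTable",
    "fragment_score_table",
    "proteome_matrix",
    "symmetrize",
]

#: Score assigned to a stop-codon symbol against every residue.
STOP_SCORE = -4.0


@dataclass(frozen=True)
class FragmentationParams:
    """Fragment length and step in nucleotides (defaults 200/100)."""

    fragment_length: int = 200
    step: int = 100

    def __post_init__(self) -> None:
        if not (1 <= self.step <= self.fragment_length):
            raise ValueError("require 1 <= step <= fragment_length")


@dataclass(frozen=True)
class Fragment:
    """A 0-based half-open slice of a parent genome."""

    parent_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence) or self.end <= self.start:
            raise ValueError("fragment interval does not match its sequence")


def fragment_genome(g: GenomeRecord, p: FragmentationParams = FragmentationParams()) -> list[Fragment]:
    """Overlapping fragments covering every nucleotide of the genome.

    Fragments start at 0, step, 2*step, ... while a full-length fragment
    fits; if the tail would otherwise be uncovered a final full-length
    fragment ending at the genome end is appended.  Genomes shorter than
    one fragment yield themselves as a single fragment.
    """
    L, F, S = g.length, p.fragment_length, p.step
    if L <= F:
        return [Fragment(g.id, 0, L, g.sequence)]
    starts = list(range(0, L - F + 1, S))
    if starts[-1] != L - F:
        starts.append(L - F)
    return [Fragment(g.id, s, s + F, g.sequence[s : s + F]) for s in starts]


def six_frame_translations(seq: str) -> list[str]:
    """Translations of the three forward and three reverse frames.

    Stop codons appear as ``*``; codons containing N translate to X.
    Frames shorter than one codon are dropped.
    """
    out = []
    rc = str(Seq(seq).reverse_complement())
    for s in (seq, rc):
        for off in (0, 1, 2):
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            if len(sub) >= 3:
                out.append(str(Seq(sub).translate()))
    return out


@lru_cache(maxsize=4)
def _protein_aligner(gap_open: int, gap_extend: int) -> PairwiseAligner:
    mat = substitution_matrices.load("BLOSUM62")
    for sym in mat.alphabet:
        mat[sym, "*"] = STOP_SCORE
        mat["*", sym] = STOP_SCORE
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    # a gap of length L scores -(gap_open + gap_extend * L)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def translated_best_score(
    f: Fragment | str,
    target: GenomeRecord | list[str],
    gap_open: int = 11,
    gap_extend: int = 1,
) -> float:
    """Best translated local-alignment score of a fragment vs a genome.

    The maximum over all 6 x 6 reading-frame combinations of the local
    BLOSUM62 alignment score, floored at 0.  ``target`` may be given as
    precomputed frame translations to amortize work across fragments.
    """
    frag_seq = f.sequence if isinstance(f, Fragment) else f
    target_frames = (
        target if isinstance(target, list) else six_frame_translations(target.sequence)
    )
    aligner = _protein_aligner(gap_open, gap_extend)
    best = 0.0
    for qf in six_frame_translations(frag_seq):
        for tf in target_frames:
            s = aligner.score(qf, tf)
            if s > best:
                best = s
    return best


def gegenees_score(
    query: GenomeRecord,
    target: GenomeRecord,
    p: FragmentationParams = FragmentationParams(),
) -> float:
    """Directional fragmented-proteome similarity, percent in [0, 100]."""
    frags = fragment_genome(query, p)
    qframes = six_frame_translations(query.sequence)
    tframes = six_frame_translations(target.sequence)
    denom = sum(translated_best_score(f, qframes) for f in frags)
    if denom == 0:
        raise ValueError(f"genome {query.id!r} has zero self-score (degenerate sequence)")
    num = sum(translated_best_score(f, tframes) for f in frags)
    return float(np.clip(100.0 * num / denom, 0.0, 100.0))


@dataclass
class FragmentScoreTable:
    """Per-fragment best scores of every genome against every genome.

    ``scores[i]`` has shape (n_fragments_of_genome_i, n_genomes); column
    j holds each fragment's best score against genome j.  Column i is
    the self-score used as the normalization denominator, so replicate
    matrices under fragment resampling (bootstrap) can be recomputed
    without re-aligning anything.
    """

    ids: list[str]
    scores: list[np.ndarray]

    def matrix(self, fragment_idx: list[np.ndarray] | None = None) -> SimilarityMatrix:
        """Percent matrix, optionally from resampled fragment indices."""
        n = len(self.ids)
        values = np.full((n, n), 100.0)
        for i in range(n):
            S = self.scores[i]
            if fragment_idx is not None:
                S = S[fragment_idx[i]]
            denom = S[:, i].sum()
            if denom == 0:
                raise ValueError(
                    f"genome {self.ids[i]!r} has zero self-score (degenerate sequence)"
                )
            for j in range(n):
                if j != i:
                    values[i, j] = np.clip(100.0 * S[:, j].sum() / denom, 0.0, 100.0)
        return SimilarityMatrix(self.ids, values, "proteome")

    @property
    def n_fragments(self) -> list[int]:
        return [s.shape[0] for s in self.scores]


def fragment_score_table(
    genomes: list[GenomeRecord], p: FragmentationParams = FragmentationParams()
) -> FragmentScoreTable:
    ids = [g.id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome ids")
    frames = [six_frame_translations(g.sequence) for g in genomes]
    frag_sets = [fragment_genome(g, p) for g in genomes]
    scores = []
    for i, frags in enumerate(frag_sets):
        S = np.zeros((len(frags), len(genomes)))
        for fi, f in enumerate(frags):
            qframes = six_frame_translations(f.sequence)
            for j in range(len(genomes)):
                best = 0.0
                aligner = _protein_aligner(11, 1)
                for qf in qframes:
                    for tf in frames[j]:
                        s = aligner.score(qf, tf)
                        if s > best:
                            best = s
                S[fi, j] = best
        scores.append(S)
    return FragmentScoreTable(ids, scores)


def proteome_matrix(
    genomes: list[GenomeRecord], p: FragmentationParams = FragmentationParams()
) -> SimilarityMatrix:
    """Full ordered-pair fragmented-proteome percent matrix (asymmetric)."""
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    return fragment_score_table(genomes, p).matrix()


def symmetrize(m: SimilarityMatrix) -> SimilarityMatrix:
    """Average each ordered pair: entries become (m[i,j] + m[j,i]) / 2."""
    return SimilarityMatrix(m.ids, (m.values + m.values.T) / 2.0, m.kind)
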