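"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: alignment scores come
from exhaustive enumeration of alignment paths, and information content from
a plain counting loop.
"""

import itertools
import math

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def brute_force_align_score(a, b, gap_open=11.0, gap_extend=1.0):
    """Optimal global alignment score by exhaustive path enumeration.

    A gap of length k costs gap_open + k * gap_extend. Exponential in the
    input lengths; only usable for very short sequences.
    """
    best = -math.inf

    def rec(i, j, score, state):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + _B62[a[i], b[j]], "M")
        if i < len(a):
            cost = gap_extend if state == "I" else gap_open + gap_extend
            rec(i + 1, j, score - cost, "I")
        if j < len(b):
            cost = gap_extend if state == "D" else gap_open + gap_extend
            rec(i, j + 1, score - cost, "D")

    rec(0, 0, 0.0, "start")
    return best


def all_sequences(alphabet, max_len):
    """Every sequence over ``alphabet`` of length 1..max_len."""
    for length in range(1, max_len + 1):
        for letters in itertools.product(alphabet, repeat=length):
            yield "".join(letters)


def enumerate_alignment_paths(la, lb, gap_open=11.0, gap_extend=1.0):
    """All global alignment paths for lengths (la, lb).

    Each path is (match_pairs, gap_cost): the 0-based (i, j) pairs aligned
    residue-to-residue, and the total affine gap cost of the path (a gap of
    length k costs gap_open + k * gap_extend).
    """
    paths = []

    def rec(i, j, matches, gap_cost, state):
        if i == la and j == lb:
            paths.append((tuple(matches), gap_cost))
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, matches + [(i, j)], gap_cost, "M")
        if i < la:
            step = gap_extend if state == "I" else gap_open + gap_extend
            rec(i + 1, j, matches, gap_cost + step, "I")
        if j < lb:
            step = gap_extend if state == "D" else gap_open + gap_extend
            rec(i, j + 1, matches, gap_cost + step, "D")

    rec(0, 0, [], 0.0, "start")
    return paths


def brute_force_scores_all_pairs(alphabet, la, lb):
    """Optimal scores for every ordered pair of sequences of lengths (la, lb).

    Vectorised over sequence pairs: enumerate alignment paths once per length
    combination, then evaluate each path's match sum for all sequence pairs
    simultaneously. Returns (seqs_a, seqs_b, score_matrix).
    """
    import numpy as np

    letters = list(alphabet)
    sub = np.array([[_B62[x, y] for y in letters] for x in letters], dtype=float)
    seqs_a = ["".join(t) for t in itertools.product(letters, repeat=la)]
    seqs_b = ["".join(t) for t in itertools.product(letters, repeat=lb)]
    enc_a = np.array([[letters.index(c) for c in s] for s in seqs_a])
    enc_b = np.array([[letters.index(c) for c in s] for s in seqs_b])
    best = np.full((len(seqs_a), len(seqs_b)), -math.inf)
    for matches, gap_cost in enumerate_alignment_paths(la, lb):
        score = np.full_like(best, -gap_cost)
        for i, j in matches:
            score = score + sub[enc_a[:, i][:, None], enc_b[:, j][None, :]]
        np.maximum(best, score, out=best)
    return seqs_a, seqs_b, best


def brute_force_information(letters):
    """Logo information content of a column given as raw letters.

    Counts canonical residues with a plain loop, then log2(20) + sum p log2 p.
    """
    canonical = "ACDEFGHIKLMNPQRSTVWY"
    counts = {}
    for letter in letters:
        if letter in canonical:
            counts[letter] = counts.get(letter, 0) + 1
    n = sum(counts.values())
    if n == 0:
        return 0.0
    total = math.log2(20.0)
    for c in counts.values():
        p = c / n
        total += p * math.log2(p)
    return total
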