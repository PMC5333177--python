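"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results from first principles (exhaustive
alignment enumeration, neighbor/pathway enumeration for NG86) and share no
code with the implementation they check.
"""

import math
from itertools import permutations

from Bio.Seq import Seq

NUCS = "ACGT"


def enumerate_alignments(a: str, b: str):
    """All global alignments as (aligned_a, aligned_b) pairs."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def score_alignment(aligned_a: str, aligned_b: str, matrix, open_pen=11.0, ext_pen=1.0):
    """Score one alignment from scratch: matrix sum minus affine run costs."""
    score = 0.0
    for x, y in zip(aligned_a, aligned_b):
        if x != "-" and y != "-":
            score += matrix[x, y]
    for s in (aligned_a, aligned_b):
        run = 0
        for ch in s + "x":  # sentinel flushes the last run
            if ch == "-":
                run += 1
            elif run:
                score -= open_pen + ext_pen * run
                run = 0
    return score


def best_alignment_score(a: str, b: str, matrix) -> float:
    return max(
        score_alignment(ra, rb, matrix)
        for ra, rb in enumerate_alignments(a, b)
        if not any(x == "-" and y == "-" for x, y in zip(ra, rb))
    )


def oracle_ng86(codons_a, codons_b):
    """Plain NG86 reimplementation: neighbor-enumerated site fractions,
    equal-weight pathway averaging, Jukes-Cantor correction.

    Returns (ka, ks, Sd, Nd); raises ValueError/ZeroDivisionError when the
    correction saturates or no synonymous site exists.
    """

    def aa(codon):
        return str(Seq(codon).translate())

    def sites(codon):
        s = 0.0
        for pos in range(3):
            for n in NUCS:
                if n != codon[pos]:
                    alt = codon[:pos] + n + codon[pos + 1:]
                    if aa(alt) == aa(codon) and aa(alt) != "*":
                        s += 1 / 3
        return s

    pairs = [
        (x, y) for x, y in zip(codons_a, codons_b)
        if "-" not in x and "-" not in y and aa(x) != "*" and aa(y) != "*"
    ]
    S = sum((sites(x) + sites(y)) / 2 for x, y in pairs)
    N = 3 * len(pairs) - S
    Sd = Nd = 0.0
    for x, y in pairs:
        diffs = [i for i in range(3) if x[i] != y[i]]
        if not diffs:
            continue
        paths = []
        for order in permutations(diffs):
            cur, sd, nd, blocked = x, 0.0, 0.0, False
            for i in order:
                nxt = cur[:i] + y[i] + cur[i + 1:]
                if aa(nxt) == "*" and nxt != y:
                    blocked = True
                if aa(nxt) == aa(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((blocked, sd, nd))
        usable = [(s, n) for bl, s, n in paths if not bl] or [
            (s, n) for _, s, n in paths
        ]
        Sd += sum(p[0] for p in usable) / len(usable)
        Nd += sum(p[1] for p in usable) / len(usable)
    pS, pN = Sd / S, Nd / N
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    return jc(pN), jc(pS), Sd, Nd
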