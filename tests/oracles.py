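"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: plain-Python
enumeration of every orientation x frame x run alignment for the read
classifier, quadratic substring search for restriction sites, and
closed-form correlation formulas.  They are slow and only run on small
inputs.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, "N") for b in reversed(seq))


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def oracle_accepts(
    read: str,
    motif: str = "TTTAGGG",
    min_units: int = 8,
    min_fraction: float = 0.6,
    min_identity: float = 0.8,
    max_mm_per_unit: int = 1,
) -> bool:
    """Accept/reject by exhaustive enumeration of runs of in-frame unit matches.

    Considers both orientations, all 7 frames, and every (start, end)
    sub-run of consecutive unit matches; accepts if any satisfies the
    three rules (run length, telomeric fraction, identity).
    """
    n = len(read)
    if n < 7 * min_units:
        return False
    for seq in (read, revcomp(read)):
        for frame in range(7):
            starts = range(frame, n - 6, 7)
            mm = [hamming(seq[s : s + 7], motif) for s in starts]
            for i in range(len(mm)):
                total = 0
                for j in range(i, len(mm)):
                    if mm[j] > max_mm_per_unit:
                        break
                    total += mm[j]
                    run = j - i + 1
                    bases = 7 * run
                    if (
                        run >= min_units
                        and bases / n >= min_fraction
                        and (bases - total) / bases >= min_identity
                    ):
                        return True
    return False


def naive_find_sites(seq: str, site: str) -> list[int]:
    """Quadratic substring search, overlap-allowed."""
    return [i for i in range(len(seq) - len(site) + 1) if seq[i : i + len(site)] == site]


def closed_form_pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def average_ranks(v) -> list[float]:
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def closed_form_spearman(x, y) -> float:
    return closed_form_pearson(average_ranks(x), average_ranks(y))
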