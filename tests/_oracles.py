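"""Independent brute-force oracles used by the tests.

These re-derive expected values by exhaustive enumeration, deliberately
sharing no control flow with the package's implementations (published
thermodynamic constants are shared — the enumeration is the independent
part).
"""

from __future__ import annotations

from primerpanel.thermo import NN_PARAMS, _loop_penalty

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def brute_force_nw_score(
    a: str, b: str, match: float, mismatch: float, gap_open: float, gap_extend: float
) -> float:
    """Exhaustive maximum over every global alignment of a and b.

    An alignment is scored as sum of column scores, with each maximal gap
    run costing gap_open + (k-1)*gap_extend.  Pure recursion over the three
    column types; feasible for lengths <= 8.
    """

    best = [float("-inf")]

    def rec(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "m")
        if i < len(a):  # a[i] over a gap
            g = gap_extend if last == "x" else gap_open
            rec(i + 1, j, score + g, "x")
        if j < len(b):
            g = gap_extend if last == "y" else gap_open
            rec(i, j + 1, score + g, "y")

    rec(0, 0, 0.0, "m")
    return best[0]


def brute_force_hairpin(seq: str) -> tuple[float, int, int]:
    """Minimum stem-loop ΔG by direct triple loop over (arm start, stem
    length, loop length); returns (0, 0, 0) when nothing stabilizing
    exists."""
    n = len(seq)
    best: tuple[float, int, int] | None = None
    for i in range(n):
        for stem in range(2, n + 1):
            for loop in range(3, n + 1):
                k = i + stem + loop
                if k + stem > n:
                    continue
                ok = all(
                    _WC.get(seq[i + t]) == seq[k + stem - 1 - t] for t in range(stem)
                )
                if not ok:
                    continue
                dg = _loop_penalty(loop)
                for t in range(stem - 1):
                    h, s = NN_PARAMS[seq[i + t: i + t + 2]]
                    dg += h - 310.15 * s / 1000.0
                cand = (dg, stem, loop)
                if best is None or (dg, -stem, loop) < (best[0], -best[1], best[2]):
                    best = cand
    if best is None or best[0] > 0:
        return (0.0, 0, 0)
    return best


def exact_site_scan(template: str, primer_expansions: set[str]) -> set[tuple[int, str]]:
    """All (start, strand) exact occurrences of any expansion of a primer on
    a template, by naive string search; minus-strand hits are occurrences of
    the reverse-complemented expansion on the top strand."""
    comp = str.maketrans("ACGT", "TGCA")
    hits: set[tuple[int, str]] = set()
    for exp in primer_expansions:
        rc = exp.translate(comp)[::-1]
        for pattern, strand in ((exp, "+"), (rc, "-")):
            start = template.find(pattern)
            while start != -1:
                hits.add((start, strand))
                start = template.find(pattern, start + 1)
    return hits
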