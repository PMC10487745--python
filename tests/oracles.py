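"""Independent brute-force oracles used by the test suite.

Everything here is implemented from first principles, without calling
into the package, so that tests compare two independent routes to the
same answer.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Dict, List, Sequence, Tuple

Interval = Tuple[int, int]  # (start, end), 1-based inclusive


def _overlap_fraction(a: Interval, b: Interval) -> float:
    o = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if o <= 0:
        return 0.0
    len_a = a[1] - a[0] + 1
    len_b = b[1] - b[0] + 1
    return min(o / len_a, o / len_b)


def bruteforce_single_linkage(intervals: Sequence[Interval],
                              threshold: float = 0.70) -> List[List[int]]:
    """Connected components over the pairwise >=threshold overlap graph,
    found by breadth-first search over an explicit adjacency matrix."""
    n = len(intervals)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if _overlap_fraction(intervals[i], intervals[j]) >= threshold:
                adj[i][j] = adj[j][i] = True
    seen = [False] * n
    components: List[List[int]] = []
    for i in range(n):
        if seen[i]:
            continue
        queue, comp = [i], []
        seen[i] = True
        while queue:
            cur = queue.pop()
            comp.append(cur)
            for j in range(n):
                if adj[cur][j] and not seen[j]:
                    seen[j] = True
                    queue.append(j)
        components.append(sorted(comp))
    return sorted(components, key=min)


def exact_hwe_pvalue(n_rr: int, n_het: int, n_aa: int) -> float:
    """Conditional exact Hardy-Weinberg test with exact rational arithmetic.

    Sums the probabilities of all heterozygote configurations (given the
    observed allele counts) that are no more probable than the observed one.
    """
    n = n_rr + n_het + n_aa
    n_alt = n_het + 2 * n_aa
    if n_alt == 0 or n_alt == 2 * n:
        return 1.0

    def prob(k_het: int) -> Fraction:
        k_aa2 = n_alt - k_het
        if k_aa2 < 0 or k_aa2 % 2:
            return Fraction(0)
        k_aa = k_aa2 // 2
        k_rr = n - k_het - k_aa
        if k_rr < 0:
            return Fraction(0)
        num = (
            Fraction(math.factorial(n),
                     math.factorial(k_rr) * math.factorial(k_het)
                     * math.factorial(k_aa))
            * 2**k_het
            * math.factorial(n_alt) * math.factorial(2 * n - n_alt)
        )
        return num / math.factorial(2 * n)

    p_obs = prob(n_het)
    total = Fraction(0)
    for k in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2):
        p = prob(k)
        if p <= p_obs:
            total += p
    return float(min(total, Fraction(1)))


# --------------------------------------------------------- pattern verifier

REF, HET, HOM, MISS = "hom_ref", "het", "hom_alt", "missing"
CARRIER = (HET, HOM)


def verify_planted_pattern(
    pattern: str,
    genotypes: Dict[str, str],
    family: List[dict],
) -> bool:
    """Re-derive whether one family's genotypes realize a strict model.

    ``family`` rows carry: id, father, mother, sex ('M'/'F'), affected
    (bool).  Written independently of the package's classifier.
    """
    by_id = {m["id"]: m for m in family}

    def g(member) -> str:
        gt = genotypes.get(member["id"], REF)
        if pattern.startswith("x_") and member["sex"] == "M" and gt == HET:
            return HOM
        return gt

    kids = [m for m in family
            if m["father"] in by_id and m["mother"] in by_id]

    if pattern in ("de_novo", "x_linked_de_novo"):
        ok = False
        for c in kids:
            f, m = by_id[c["father"]], by_id[c["mother"]]
            child_ok = (g(c) == HET if pattern == "de_novo"
                        else g(c) in CARRIER)
            if (c["affected"] and child_ok and g(f) == REF and g(m) == REF
                    and not f["affected"] and not m["affected"]):
                ok = True
        if not ok:
            return False
        return not any(not m["affected"] and g(m) in CARRIER for m in family)

    if pattern in ("autosomal_recessive", "x_linked_recessive"):
        for c in kids:
            f, m = by_id[c["father"]], by_id[c["mother"]]
            if not (c["affected"] and g(c) == HOM):
                continue
            if f["affected"] or m["affected"]:
                continue
            if pattern == "autosomal_recessive":
                if g(f) != HET or g(m) != HET:
                    continue
            else:
                if g(m) != HET or g(f) != REF:
                    continue
            sibs = [s for s in kids if s["father"] == c["father"]
                    and s["mother"] == c["mother"] and s["affected"]]
            if all(g(s) == HOM for s in sibs):
                return True
        return False

    if pattern in ("autosomal_dominant", "x_linked_dominant"):
        affecteds = [m for m in family if m["affected"]]
        if not affecteds or any(g(a) not in CARRIER for a in affecteds):
            return False
        pair = False
        for a in affecteds:
            parents = [by_id[p] for p in (a["father"], a["mother"])
                       if p in by_id]
            if parents:
                if not any(p["affected"] for p in parents):
                    return False
                pair = True
        if not pair:
            return False
        return not any(not m["affected"] and g(m) in CARRIER for m in family)

    raise ValueError(pattern)
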