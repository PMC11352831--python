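"""Quine-McCluskey minimization with Petrick minimum-cover selection.

An implicant over k variables is a pair (mask, value): variable i is fixed
to bit i of `value` when bit i of `mask` is set, and free otherwise.  Prime
implicants are found by iterated merging of adjacent implicants; a minimum
sum-of-products cover is then chosen by Petrick's method with deterministic
lexicographic tie-breaking (fewest implicants, then fewest literals, then
lexicographic by the implicant (mask, value) lists), so the result is unique
and reproducible.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["simplify_qm", "prime_implicants", "implicant_to_str", "dnf_to_str"]

Implicant = tuple[int, int]  # (mask, value)


def prime_implicants(minterms: set[int], k: int) -> list[Implicant]:
    """All prime implicants of the function with the given 1-set."""
    if not minterms:
        return []
    current: set[Implicant] = {((1 << k) - 1, m) for m in minterms}
    primes: set[Implicant] = set()
    while current:
        merged: set[Implicant] = set()
        used: set[Implicant] = set()
        cur = sorted(current)
        by_mask: dict[int, list[Implicant]] = {}
        for imp in cur:
            by_mask.setdefault(imp[0], []).append(imp)
        for mask, group in by_mask.items():
            for a, b in itertools.combinations(group, 2):
                diff = a[1] ^ b[1]
                if diff.bit_count() == 1:
                    merged.add((mask & ~diff, a[1] & ~diff))
                    used.add(a)
                    used.add(b)
        primes |= current - used
        current = merged
    return sorted(primes)


def _covers(imp: Implicant, m: int) -> bool:
    mask, value = imp
    return (m & mask) == value


def _petrick_min_cover(primes: list[Implicant], minterms: set[int]
                       ) -> list[Implicant]:
    """Minimum cover: essential primes first, Petrick expansion for the rest."""
    chosen: set[int] = set()
    remaining = set(minterms)
    # essential prime implicants: sole cover of some minterm
    while True:
        new = set()
        for m in remaining:
            cands = [i for i, p in enumerate(primes) if _covers(p, m)]
            if len(cands) == 1:
                new.add(cands[0])
        if not new - chosen:
            break
        chosen |= new
        remaining = {m for m in remaining
                     if not any(_covers(primes[i], m) for i in chosen)}
    if not remaining:
        return sorted(primes[i] for i in chosen)
    # exact minimum cover of the remaining minterms: branch and bound on
    # the least-covered minterm, with a deterministic tie-break key
    # (cover size, literal count, lexicographic implicant list)
    cand_of: dict[int, list[int]] = {
        m: [i for i, p in enumerate(primes) if _covers(p, m)]
        for m in remaining}
    cover_of: dict[int, frozenset[int]] = {
        i: frozenset(m for m in remaining if _covers(primes[i], m))
        for i in range(len(primes))}

    def literals(idx) -> int:
        return sum(primes[i][0].bit_count() for i in idx)

    def key(idx) -> tuple:
        return (len(idx), literals(idx), sorted(primes[i] for i in idx))

    best: list = [None]

    def search(uncovered: frozenset[int], picked: tuple[int, ...],
               banned: frozenset[int]):
        if not uncovered:
            k2 = key(picked)
            if best[0] is None or k2 < best[0][0]:
                best[0] = (k2, picked)
            return
        if best[0] is not None and len(picked) + 1 > best[0][0][0]:
            return
        m = min(uncovered, key=lambda x: (len(cand_of[x]), x))
        cands = [i for i in cand_of[m] if i not in banned]
        for j, i in enumerate(sorted(cands)):
            # ban earlier siblings so each cover is enumerated once
            search(uncovered - cover_of[i], picked + (i,),
                   banned | set(sorted(cands)[:j]))

    search(frozenset(remaining), (), frozenset())
    return sorted(primes[i] for i in set(chosen) | set(best[0][1]))


def simplify_qm(truth_table: np.ndarray) -> list[Implicant]:
    """Minimal sum-of-products of a truth table (bit i of index = input i).

    Returns a sorted list of (mask, value) implicants; the empty list is the
    constant-0 function, and a single implicant with mask 0 is constant 1.
    Logically equivalent to the input by construction.
    """
    if hasattr(truth_table, "truth_table"):  # accept a BooleanRule
        truth_table = truth_table.truth_table
    tt = np.asarray(truth_table).ravel()
    n = len(tt)
    k = n.bit_length() - 1
    if 1 << k != n:
        raise ValueError("truth table length must be a power of two")
    minterms = {i for i in range(n) if tt[i]}
    if not minterms:
        return []
    if len(minterms) == n:
        return [(0, 0)]
    primes = prime_implicants(minterms, k)
    return _petrick_min_cover(primes, minterms)


def implicant_to_str(imp: Implicant, names: list[str]) -> str:
    mask, value = imp
    lits = []
    for i, name in enumerate(names):
        if mask & (1 << i):
            lits.append(name if value & (1 << i) else f"~{name}")
    return "".join(lits) if lits else "1"


def dnf_to_str(dnf: list[Implicant], names: list[str]) -> str:
    if not dnf:
        return "0"
    return " + ".join(implicant_to_str(i, names) for i in dnf)


def evaluate_dnf(dnf: list[Implicant], k: int) -> np.ndarray:
    """Truth table of a DNF (for equivalence checks)."""
    tt = np.zeros(1 << k, dtype=np.uint8)
    for m in range(1 << k):
        tt[m] = any(_covers(imp, m) for imp in dnf)
    return tt
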