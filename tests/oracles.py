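"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (exhaustive
enumeration, exact rational arithmetic, literal rule application) and share
no code with the package implementation they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

MISSING = -1  # mirrors the package sentinel without importing it


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test by exact-fraction enumeration

def hwe_exact_oracle(n_hom1: int, n_het: int, n_hom2: int) -> Fraction:
    """Two-sided exact HWE p-value as an exact rational.

    Enumerates every genotype configuration (n_AA, n_AB, n_BB) with the same
    sample size and allele counts; each has conditional probability
    proportional to the multinomial coefficient times 2^n_AB.  The p-value
    sums the probabilities of all configurations no more likely than the
    observed one.
    """
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het  # copies of the first allele
    weights: dict[int, int] = {}
    for h in range(n + 1):
        if (n_a - h) % 2 or n_a - h < 0:
            continue
        aa = (n_a - h) // 2
        bb = n - aa - h
        if bb < 0:
            continue
        weights[h] = comb(n, aa) * comb(n - aa, h) * 2**h
    total = sum(weights.values())
    obs = weights[n_het]
    p = sum(Fraction(w, total) for w in weights.values() if w <= obs)
    return min(p, Fraction(1))


# ---------------------------------------------------------------------------
# Pedigree inbreeding by Wright's path counting

def wright_inbreeding(parents: dict[str, tuple[str | None, str | None]],
                      individual: str) -> float:
    """F by path counting: sum over common ancestors A and distinct
    sire/dam paths meeting only at A of (1/2)^(n_s + n_d + 1) (1 + F_A)."""
    sire, dam = parents[individual]
    if sire is None or dam is None:
        return 0.0

    def paths_up(start: str) -> list[list[str]]:
        out = [[start]]
        s, d = parents[start]
        for par in (s, d):
            if par is not None:
                out.extend([[start] + p for p in paths_up(par)])
        return out

    total = 0.0
    for ps in paths_up(sire):
        for pd_ in paths_up(dam):
            if ps[-1] != pd_[-1]:
                continue
            # paths may share only the common ancestor itself
            if set(ps[:-1]) & set(pd_[:-1]):
                continue
            a = ps[-1]
            total += 0.5 ** (len(ps) + len(pd_) - 1) * (
                1.0 + wright_inbreeding(parents, a)
            )
    return total


# ---------------------------------------------------------------------------
# Run callers by literal interval enumeration

def _select_greedy(passing: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Deterministic selection: repeatedly take the passing interval with the
    smallest start (ties: longest), discard everything overlapping it."""
    chosen: list[tuple[int, int]] = []
    pool = sorted(passing, key=lambda ab: (ab[0], -ab[1]))
    while pool:
        a, b = pool[0]
        chosen.append((a, b))
        pool = [iv for iv in pool if iv[0] > b]
    return chosen


def roh_oracle(genotypes: list[int], positions: list[int], params) -> list[tuple[int, int]]:
    """All maximal passing ROH intervals of one sample/chromosome, by
    checking every marker interval against the window-eligibility, gap,
    trim, marker-count, length, density and heterozygote rules, then
    selecting greedily from the left.  Returns (start_index, end_index)."""
    m = len(genotypes)
    w = params.window_snp
    if m < w:
        return []
    het = [g == 1 for g in genotypes]
    mis = [g == MISSING for g in genotypes]
    hom = [g in (0, 2) for g in genotypes]

    # window hits
    hits = []
    for i in range(m - w + 1):
        window = genotypes[i : i + w]
        n_het = sum(1 for g in window if g == 1)
        n_mis = sum(1 for g in window if g == MISSING)
        hits.append(n_het <= params.window_het_max and n_mis <= params.window_missing_max)

    eligible = []
    for j in range(m):
        lo = max(0, j - w + 1)
        hi = min(j, m - w)
        covering = hits[lo : hi + 1]
        eligible.append(sum(covering) / len(covering) >= params.window_hit_fraction)

    # prefix sums for O(1) interval checks
    cs_het = [0]
    for v in het:
        cs_het.append(cs_het[-1] + v)
    strict = params.run_het_mode == "strict"

    passing = []
    for a in range(m):
        if not (eligible[a] and hom[a]):
            continue
        n_het_run = 0
        for b in range(a, m):
            if not eligible[b]:
                break
            if b > a and positions[b] - positions[b - 1] > params.max_gap_bp:
                break
            if not hom[b]:
                continue
            n_snp = b - a + 1
            length = positions[b] - positions[a] + 1
            if n_snp < params.min_snp or length < params.min_length_bp:
                continue
            if length / n_snp > params.max_density_bp_per_snp:
                continue
            if strict and cs_het[b + 1] - cs_het[a] > params.window_het_max:
                continue
            passing.append((a, b))
    return _select_greedy(passing)


def rohet_oracle(genotypes: list[int], positions: list[int], params) -> list[tuple[int, int]]:
    """All maximal passing ROHet intervals, by checking every interval with
    heterozygous terminals against the missing/homozygous budgets and the
    marker-count and length minima, then selecting greedily from the left."""
    m = len(genotypes)
    passing = []
    for a in range(m):
        if genotypes[a] != 1:
            continue
        n_hom = 0
        n_mis = 0
        for b in range(a, m):
            if genotypes[b] in (0, 2):
                n_hom += 1
            elif genotypes[b] == MISSING:
                n_mis += 1
            if n_hom > params.max_homozygous or n_mis > params.max_missing:
                break
            if genotypes[b] != 1:
                continue
            n_snp = b - a + 1
            length = positions[b] - positions[a] + 1
            if n_snp >= params.min_snp and length >= params.min_length_bp:
                passing.append((a, b))
    return _select_greedy(passing)


# ---------------------------------------------------------------------------
# Random instance generators for run-caller equivalence checks

def random_roh_instance(rng, max_snps: int = 200):
    """Homozygosity-rich genotype/position vectors that exercise windows,
    gaps, trimming and budget edge cases."""
    m = int(rng.integers(60, max_snps + 1))
    g = rng.choice([0, 2, 1, MISSING], size=m, p=[0.46, 0.46, 0.05, 0.03])
    gaps = rng.integers(5_000, 60_000, size=m)
    big = rng.random(m) < 0.02
    gaps[big] = rng.integers(450_000, 800_000, size=int(big.sum()))
    pos = 1 + gaps.cumsum()
    return [int(x) for x in g], [int(x) for x in pos]


def random_rohet_instance(rng, max_snps: int = 200):
    """Heterozygosity-rich instances for the consecutive caller."""
    m = int(rng.integers(40, max_snps + 1))
    g = rng.choice([1, 0, 2, MISSING], size=m, p=[0.70, 0.12, 0.12, 0.06])
    pos = 1 + rng.integers(10_000, 80_000, size=m).cumsum()
    return [int(x) for x in g], [int(x) for x in pos]


# ---------------------------------------------------------------------------
# Additive distance matrices from random trees

def random_additive_matrix(rng, n_taxa):
    """Random binary tree -> exact path-length matrix (independent of any
    neighbor-joining code; used to check tree reconstruction)."""
    ids = [f"t{i}" for i in range(n_taxa)]
    # grow a tree by random attachment; store as parent pointers with lengths
    parent = {}
    length = {}
    nodes = ["t0", "t1", "t2"]
    root = "r0"
    for x in nodes:
        parent[x] = root
        length[x] = rng.uniform(0.1, 2.0)
    next_internal = 1
    for k in range(3, n_taxa):
        leaf = ids[k]
        target = nodes[int(rng.integers(len(nodes)))]
        new = f"r{next_internal}"
        next_internal += 1
        parent[new] = parent[target]
        length[new] = rng.uniform(0.1, 2.0)
        parent[target] = new
        length[target] = rng.uniform(0.1, 2.0)
        parent[leaf] = new
        length[leaf] = rng.uniform(0.1, 2.0)
        nodes.append(leaf)
        nodes.append(new)

    def path_to_root(x):
        out = {}
        acc = 0.0
        while x in parent:
            out[x] = acc
            acc += length[x]
            x = parent[x]
        out[x] = acc
        return out

    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        pi = path_to_root(ids[i])
        for j in range(i + 1, n_taxa):
            pj = path_to_root(ids[j])
            shared = [x for x in pi if x in pj]
            dist = min(pi[x] + pj[x] for x in shared)
            d[i, j] = d[j, i] = dist
    return d, ids
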