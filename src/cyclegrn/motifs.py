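"""Feed-forward-loop enumeration and expected-count statistics.

A feed-forward loop (FFL) is the three-node motif in which a primary TF
regulates a secondary TF and both regulate a common target: edges p→s, p→t
and s→t. The expected number of FFLs in a randomly wired network with the
same mean connectivity λ (edges per node) is approximated by λ³ with a
Poisson-like standard deviation √λ³, giving a z-score for enrichment.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .grn import GRN


@dataclass(frozen=True, order=True)
class FFL:
    """Ordered motif triplet: primary TF, secondary TF, common target."""

    primary: str
    secondary: str
    target: str


@dataclass
class MotifStats:
    observed: int
    lam: float
    expected_mean: float
    expected_sd: float
    z: float


def enumerate_ffls(grn: GRN) -> set[FFL]:
    """All FFLs in a GRN.

    Returns every ordered triplet (p, s, t) with p→s, p→t, s→t present,
    p ≠ s and t ∉ {p, s}. Self-loops never contribute. Mutually regulating
    TF pairs that share a target yield both role-ordered triplets.
    """
    out: dict[str, set[str]] = {}
    for tf, tg in grn.interactions:
        out.setdefault(tf, set()).add(tg)
    ffls: set[FFL] = set()
    for p, p_targets in out.items():
        for s in p_targets:
            if s == p or s not in out:
                continue
            for t in p_targets & out[s]:
                if t != p and t != s:
                    ffls.add(FFL(p, s, t))
    return ffls


def expected_ffl_stats(grn: GRN, observed: int) -> MotifStats:
    """Expected FFL count λ³ (λ = interactions / nodes) and the z-score
    (observed − λ³) / √λ³."""
    n_nodes = len(grn.genes)
    if n_nodes == 0:
        return MotifStats(observed=observed, lam=0.0, expected_mean=0.0,
                          expected_sd=0.0, z=math.inf if observed > 0 else 0.0)
    lam = len(grn) / n_nodes
    mean = lam ** 3
    sd = math.sqrt(mean)
    if sd > 0:
        z = (observed - mean) / sd
    else:
        z = math.inf if observed > 0 else 0.0
    return MotifStats(observed=observed, lam=lam, expected_mean=mean,
                      expected_sd=sd, z=z)


def ffl_overlap(ffl_sets: list[set[FFL]]) -> tuple[float, int]:
    """Fraction of FFLs unique to one set and count common to all sets,
    over the union of several datasets' FFL sets."""
    if len(ffl_sets) < 2:
        raise ValueError("need at least two FFL sets")
    mult: Counter[FFL] = Counter()
    for s in ffl_sets:
        for f in s:
            mult[f] += 1
    if not mult:
        return 0.0, 0
    n_sets = len(ffl_sets)
    unique = sum(1 for c in mult.values() if c == 1)
    common = sum(1 for c in mult.values() if c == n_sets)
    return unique / len(mult), common


def write_ffls(ffls: set[FFL], path) -> None:
    lines = ["primary\tsecondary\ttarget"]
    lines += [f"{f.primary}\t{f.secondary}\t{f.target}" for f in sorted(ffls)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ffls(path) -> set[FFL]:
    rows = Path(path).read_text().splitlines()
    out: set[FFL] = set()
    for row in rows:
        row = row.strip()
        if not row or row.startswith("primary\t"):
            continue
        p, s, t = row.split("\t")[:3]
        out.add(FFL(p, s, t))
    return out
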