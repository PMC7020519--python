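"""Gene regulatory network container, edge-list I/O and cross-dataset comparison.

A GRN here is a set of directed TF → target interactions over opaque,
case-sensitive gene identifiers. Datasets derived from different assays
(ChIP-chip binding, deletion-mutant expression, motif scans, protein-binding
microarrays) describe the same underlying network very differently, so the
module provides the comparison statistics used to quantify that disagreement:
raw overlap and overlap coefficient, a degree-preserving randomization null
with a two-tailed z-test, per-TF degree correlation, and interaction
uniqueness across a collection of datasets.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

Interaction = tuple[str, str]


@dataclass(frozen=True)
class GRN:
    """A named set of directed TF → target interactions.

    Self-loops (a TF targeting itself) are retained; duplicates are
    impossible by construction (interactions is a frozenset).
    """

    name: str
    interactions: frozenset[Interaction]

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(tf for tf, _ in self.interactions)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(t for _, t in self.interactions)

    @property
    def genes(self) -> frozenset[str]:
        return self.tfs | self.targets

    def out_degrees(self) -> dict[str, int]:
        """Number of targets per TF."""
        deg: Counter[str] = Counter(tf for tf, _ in self.interactions)
        return dict(deg)

    def targets_of(self, tf: str) -> frozenset[str]:
        return frozenset(t for f, t in self.interactions if f == tf)

    def __len__(self) -> int:
        return len(self.interactions)

    @classmethod
    def from_edges(cls, name: str, edges) -> "GRN":
        return cls(name=name, interactions=frozenset((str(a), str(b)) for a, b in edges))


@dataclass
class OverlapStats:
    """Observed overlap between two GRNs against a randomization null."""

    observed_overlap: int
    overlap_coefficient: float
    null_mean: float
    null_sd: float
    z: float
    p_two_tailed: float
    n_permutations: int
    z_defined: bool = True


@dataclass
class ParseReport:
    parsed: int = 0
    duplicates: int = 0
    skipped: int = 0
    header_skipped: bool = False


def _looks_like_header(first: list[str], body_tokens: set[str]) -> bool:
    # First line is a header if neither of its leading tokens ever reappears
    # as a gene id in the body of the file.
    return all(tok not in body_tokens for tok in first[:2])


def read_edge_list(
    path,
    name: str | None = None,
    *,
    header: str = "auto",
) -> GRN:
    """Read a 2+ column TSV/whitespace edge list into a GRN.

    Parameters
    ----------
    path : str or Path
        File with one ``tf<TAB>target`` pair per line. Extra columns ignored.
    name : str, optional
        Label for the GRN; defaults to the file stem.
    header : {"auto", "yes", "no"}
        "auto" treats the first line as a header when neither of its tokens
        reappears as a gene id elsewhere in the file.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    raw = path.read_text().splitlines()
    rows: list[list[str]] = []
    report = ParseReport()
    for line in raw:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split("\t") if "\t" in line else line.split()
        rows.append([t.strip() for t in toks])
    if not rows:
        raise ValueError(f"empty edge list: {path}")

    if header == "yes":
        drop_first = True
    elif header == "no":
        drop_first = False
    else:
        body_tokens = {tok for row in rows[1:] for tok in row[:2]}
        drop_first = len(rows) > 1 and _looks_like_header(rows[0], body_tokens)
    if drop_first:
        rows = rows[1:]
        report.header_skipped = True

    seen: set[Interaction] = set()
    for row in rows:
        if len(row) < 2 or not row[0] or not row[1]:
            report.skipped += 1
            logger.warning("skipping malformed line in %s: %r", path, row)
            continue
        pair = (row[0], row[1])
        if pair in seen:
            report.duplicates += 1
        else:
            seen.add(pair)
            report.parsed += 1
    if not seen:
        raise ValueError(f"no valid interactions parsed from {path}")
    logger.info(
        "%s: %d interactions (%d duplicate, %d skipped lines)",
        path, report.parsed, report.duplicates, report.skipped,
    )
    grn = GRN(name=name, interactions=frozenset(seen))
    object.__setattr__(grn, "parse_report", report)  # metadata on a frozen dataclass
    return grn


def write_edge_list(grn: GRN, path) -> None:
    """Write a GRN as a sorted 2-column TSV (tf, target)."""
    lines = [f"{tf}\t{tg}" for tf, tg in sorted(grn.interactions)]
    Path(path).write_text("\n".join(lines) + "\n")


def pairwise_overlap(a: GRN, b: GRN) -> tuple[int, float]:
    """Observed interaction overlap and overlap coefficient |A∩B|/min(|A|,|B|).

    Symmetric in its arguments; raises on an empty GRN.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("overlap undefined for an empty GRN")
    observed = len(a.interactions & b.interactions)
    coeff = observed / min(len(a), len(b))
    return observed, coeff


def _randomize(grn: GRN, pool: np.ndarray, rng: np.random.Generator) -> set[Interaction]:
    """Degree-preserving rewiring: each TF draws its out-degree worth of
    unique targets uniformly from the shared pool."""
    edges: set[Interaction] = set()
    for tf, d in sorted(grn.out_degrees().items()):
        idx = rng.choice(len(pool), size=d, replace=False)
        for t in pool[idx]:
            edges.add((tf, t))
    return edges


def randomized_overlap_null(
    a: GRN,
    b: GRN,
    pool: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> OverlapStats:
    """Compare observed overlap of two GRNs against a degree-preserving null.

    For each permutation every TF in each GRN receives a uniform random
    subset of ``pool`` of size equal to its true out-degree (without
    replacement); the interaction overlap of the two rewired networks is
    recorded. The observed overlap is placed on the resulting null via a
    two-tailed z-test under a normal approximation.
    """
    observed, coeff = pairwise_overlap(a, b)
    pool_arr = np.array(sorted(pool))
    for g in (a, b):
        for tf, d in g.out_degrees().items():
            if d > len(pool_arr):
                raise ValueError(
                    f"TF {tf!r} out-degree {d} exceeds pool size {len(pool_arr)}"
                )
    rng = np.random.default_rng(seed)
    overlaps = np.empty(n_perm)
    for i in range(n_perm):
        ra = _randomize(a, pool_arr, rng)
        rb = _randomize(b, pool_arr, rng)
        overlaps[i] = len(ra & rb)
    null_mean = float(overlaps.mean())
    null_sd = float(overlaps.std(ddof=1)) if n_perm > 1 else 0.0
    if null_sd > 0:
        z = (observed - null_mean) / null_sd
        p = 2.0 * stats.norm.sf(abs(z))
        defined = True
    else:
        z, p, defined = math.nan, math.nan, False
    return OverlapStats(
        observed_overlap=observed,
        overlap_coefficient=coeff,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p_two_tailed=float(p) if defined else math.nan,
        n_permutations=n_perm,
        z_defined=defined,
    )


def per_tf_degree_correlation(a: GRN, b: GRN, *, mode: str = "shared") -> float:
    """Pearson correlation of per-TF out-degrees between two GRNs.

    mode="shared" (default) restricts to TFs present in both networks;
    mode="union" zero-fills missing TFs, which inflates |r| and is provided
    for comparison only.
    """
    da, db = a.out_degrees(), b.out_degrees()
    if mode == "shared":
        tfs = sorted(set(da) & set(db))
    elif mode == "union":
        tfs = sorted(set(da) | set(db))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(tfs) < 3:
        raise ValueError("need at least 3 TFs in the comparison set")
    x = np.array([da.get(t, 0) for t in tfs], dtype=float)
    y = np.array([db.get(t, 0) for t in tfs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degree vector is constant; correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r)


@dataclass
class UniquenessStats:
    multiplicity: dict[Interaction, int] = field(default_factory=dict)
    fraction_unique: float = 0.0
    n_union: int = 0
    tf_majority_unique: dict[str, bool] = field(default_factory=dict)
    fraction_tfs_majority_unique: float = 0.0


def interaction_uniqueness(grns: list[GRN]) -> UniquenessStats:
    """Dataset multiplicity of every interaction in the union of several GRNs.

    Reports the fraction of interactions found in exactly one dataset and,
    per TF, whether a majority (>50%) of its pooled interactions are unique
    to a single dataset.
    """
    if len(grns) < 2:
        raise ValueError("need at least two GRNs")
    mult: Counter[Interaction] = Counter()
    for g in grns:
        for e in g.interactions:
            mult[e] += 1
    n_union = len(mult)
    n_unique = sum(1 for c in mult.values() if c == 1)
    per_tf_total: Counter[str] = Counter()
    per_tf_unique: Counter[str] = Counter()
    for (tf, _), c in mult.items():
        per_tf_total[tf] += 1
        if c == 1:
            per_tf_unique[tf] += 1
    majority = {
        tf: per_tf_unique[tf] / per_tf_total[tf] > 0.5 for tf in per_tf_total
    }
    return UniquenessStats(
        multiplicity=dict(mult),
        fraction_unique=n_unique / n_union,
        n_union=n_union,
        tf_majority_unique=majority,
        fraction_tfs_majority_unique=(
            sum(majority.values()) / len(majority) if majority else 0.0
        ),
    )
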