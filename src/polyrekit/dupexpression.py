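"""Expression divergence between WGT duplicates: the exact conditional
(binomial) test per pair per replicate, Bonferroni correction within each
tissue/replicate family, three-copy pairwise handling, replicate
consistency, and tissue-level summaries.

The exact conditional test conditions on the pair's total read count in a
sample: under equal expression, gene A's reads are Binomial(a+b, p0) with
p0 = 0.5 (optionally a CDS-length correction p0 = len_a/(len_a+len_b)).
A pair is a DEGP (differentially expressed gene pair) in a tissue when
every replicate is significant after Bonferroni correction with a
consistent direction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "DupPairTest",
    "DegpSummary",
    "pair_exact_test",
    "test_duplicate_groups",
    "summarize_degp",
]


@dataclass
class DupPairTest:
    gene_a: str
    gene_b: str
    tissue: str
    counts_a: tuple[int, ...]
    counts_b: tuple[int, ...]
    p_values: tuple[float, ...]       # per replicate, uncorrected
    corrected_p: tuple[float, ...]    # Bonferroni within tissue+replicate
    directions: tuple[int, ...]       # sign(a - b) per replicate
    consistent_significant: bool
    null_p0: float = 0.5

    @property
    def direction(self) -> int:
        return self.directions[0] if self.consistent_significant else 0


@dataclass
class DegpSummary:
    tissue: str
    n_tested_pairs: int
    n_degp: int
    fraction: float
    n_groups_by_class: dict = field(default_factory=dict)


def pair_exact_test(count_a: int, count_b: int,
                    null_p0: float = 0.5) -> float:
    """Exact two-sided binomial p for count_a successes in count_a +
    count_b trials under null_p0 (outcome probabilities <= the observed
    outcome's probability are summed)."""
    if not 0.0 < null_p0 < 1.0:
        raise ValueError(f"null_p0={null_p0} outside (0, 1)")
    if count_a < 0 or count_b < 0:
        raise ValueError("negative counts")
    n = count_a + count_b
    if n < 1:
        raise ValueError("pair with zero total count is excluded upstream")
    return float(binomtest(int(count_a), int(n), null_p0).pvalue)


def _group_pairs(groups) -> list[tuple[str, str]]:
    pairs = []
    for g in groups:
        if g.copy_class in (2, 3):
            pairs.extend(itertools.combinations(g.members, 2))
    return pairs


def test_duplicate_groups(counts, groups, alpha: float = 0.05,
                          null_mode: str = "equal",
                          cds_lengths: dict | None = None
                          ) -> list[DupPairTest]:
    """Run the exact conditional test for every duplicate pair, per
    tissue, per replicate.

    Two-copy groups contribute one pair; three-copy groups contribute
    their three pairwise comparisons. Pairs with a zero total count in
    any replicate of a tissue are excluded from that tissue's family.
    The Bonferroni divisor is the number of tests performed per tissue
    per replicate. A DEGP call requires all replicates significant at
    ``alpha`` after correction with the same nonzero direction.
    """
    if null_mode not in ("equal", "length"):
        raise ValueError("null_mode must be 'equal' or 'length'")
    mat = counts.counts
    known = set(mat.index)
    pairs = [(a, b) for a, b in _group_pairs(groups)
             if a in known and b in known]
    results = []
    for tissue in counts.tissues:
        cols = counts.tissue_samples(tissue)
        if not cols:
            raise ValueError(f"tissue {tissue!r} has zero replicates")
        sub = mat[cols]
        tested = []
        for a, b in pairs:
            ca = sub.loc[a].to_numpy()
            cb = sub.loc[b].to_numpy()
            if ((ca + cb) < 1).any():
                continue
            tested.append((a, b, ca, cb))
        m = len(tested)
        for a, b, ca, cb in tested:
            if null_mode == "length":
                if cds_lengths is None:
                    raise ValueError("length correction needs cds_lengths")
                p0 = cds_lengths[a] / (cds_lengths[a] + cds_lengths[b])
            else:
                p0 = 0.5
            pvals = tuple(pair_exact_test(int(x), int(y), p0)
                          for x, y in zip(ca, cb))
            corr = tuple(min(1.0, p * m) for p in pvals)
            dirs = tuple(int(np.sign(x / (x + y) - p0))
                         for x, y in zip(ca, cb))
            sig = all(c < alpha for c in corr)
            consistent = sig and len(set(dirs)) == 1 and dirs[0] != 0
            results.append(DupPairTest(
                gene_a=a, gene_b=b, tissue=tissue,
                counts_a=tuple(int(v) for v in ca),
                counts_b=tuple(int(v) for v in cb),
                p_values=pvals, corrected_p=corr, directions=dirs,
                consistent_significant=consistent, null_p0=p0))
    return results


def summarize_degp(tests, groups) -> tuple[list[DegpSummary], set]:
    """Per-tissue DEGP summaries plus the cross-tissue intersection set.

    The fraction is n_degp / n_tested per tissue; the intersection is
    the set of pairs called DEGP in every tissue in which any pair was
    tested; group counts tally groups (by copy class) with >= 1 DEGP
    member pair.
    """
    member_class = {}
    pair_group = {}
    for g in groups:
        for pair in itertools.combinations(g.members, 2):
            pair_group[tuple(sorted(pair))] = g
    by_tissue: dict[str, list] = {}
    for t in tests:
        by_tissue.setdefault(t.tissue, []).append(t)
    summaries = []
    degp_sets = {}
    for tissue in sorted(by_tissue):
        ts = by_tissue[tissue]
        degp = {tuple(sorted((t.gene_a, t.gene_b)))
                for t in ts if t.consistent_significant}
        degp_sets[tissue] = degp
        counts = {1: 0, 2: 0, 3: 0}
        seen = set()
        for pair in degp:
            g = pair_group.get(pair)
            if g is not None and g.copy_class in counts and \
                    g.group_id not in seen:
                counts[g.copy_class] += 1
                seen.add(g.group_id)
        n_tested = len(ts)
        summaries.append(DegpSummary(
            tissue=tissue, n_tested_pairs=n_tested, n_degp=len(degp),
            fraction=len(degp) / n_tested if n_tested else 0.0,
            n_groups_by_class=counts))
    intersection = set.intersection(*degp_sets.values()) if degp_sets \
        else set()
    return summaries, intersection
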