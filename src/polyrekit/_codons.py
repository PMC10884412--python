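"""Shared codon-level machinery: genetic code tables, NG86 site counts,
per-codon substitution classification.

Codons are encoded as integers 0..63 (base-4 over A,C,G,T in alphabetical
order). Stop codons are valid codes but are rejected inside coding
sequences; a single-nucleotide change *into* a stop codon is counted as
nonsynonymous for site counting (see ``syn_site_counts``).
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCS = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

CODONS = ["".join(c) for c in itertools.product(NUCS, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

STOP_CODONS = frozenset(CODON_INDEX[c] for c in standard_dna_table.stop_codons)
AA = {CODON_INDEX[c]: aa for c, aa in standard_dna_table.forward_table.items()}
SENSE_CODONS = [i for i in range(64) if i not in STOP_CODONS]


def encode(seq: str) -> np.ndarray:
    """Encode an in-frame DNA string as an array of codon integers."""
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    try:
        nt = np.array([NUC_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character in sequence: {exc}") from None
    return nt[0::3] * 16 + nt[1::3] * 4 + nt[2::3]


def decode(codons: np.ndarray) -> str:
    return "".join(CODONS[int(c)] for c in codons)


def _mutate(codon: int, pos: int, new_nuc: int) -> int:
    shift = 4 ** (2 - pos)
    old = (codon // shift) % 4
    return codon + (new_nuc - old) * shift


@lru_cache(maxsize=1)
def mutation_tables():
    """Per-codon lists of possible single-nucleotide changes.

    Returns (syn, nonsyn): for each sense codon, the list of resulting
    codons for synonymous / nonsynonymous (non-stop) changes. Changes into
    stop codons appear in neither list (they are never applied by the
    simulator) but do count toward nonsynonymous *sites*.
    """
    syn: list[list[int]] = [[] for _ in range(64)]
    nonsyn: list[list[int]] = [[] for _ in range(64)]
    for c in SENSE_CODONS:
        for pos in range(3):
            shift = 4 ** (2 - pos)
            old = (c // shift) % 4
            for new in range(4):
                if new == old:
                    continue
                m = _mutate(c, pos, new)
                if m in STOP_CODONS:
                    continue
                (syn if AA[m] == AA[c] else nonsyn)[c].append(m)
    return syn, nonsyn


@lru_cache(maxsize=1)
def syn_site_counts() -> np.ndarray:
    """NG86 synonymous site count per codon (array of 64; stops are NaN).

    Each codon position contributes (number of synonymous changes)/3;
    changes to stop codons count as nonsynonymous, so the nonsynonymous
    sites of a codon are 3 minus its synonymous sites.
    """
    s = np.full(64, np.nan)
    for c in SENSE_CODONS:
        total = 0.0
        for pos in range(3):
            shift = 4 ** (2 - pos)
            old = (c // shift) % 4
            nsyn = 0
            for new in range(4):
                if new == old:
                    continue
                m = _mutate(c, pos, new)
                if m not in STOP_CODONS and AA[m] == AA[c]:
                    nsyn += 1
            total += nsyn / 3.0
        s[c] = total
    return s


def _diff_positions(a: int, b: int) -> list[int]:
    out = []
    for pos in range(3):
        shift = 4 ** (2 - pos)
        if (a // shift) % 4 != (b // shift) % 4:
            out.append(pos)
    return out


def _path_steps(a: int, b: int, order: tuple[int, ...]):
    """Codon states visited when changing a into b position-by-position."""
    cur = a
    steps = []
    for pos in order:
        shift = 4 ** (2 - pos)
        new = (b // shift) % 4
        nxt = _mutate(cur, pos, new)
        steps.append((cur, nxt))
        cur = nxt
    return steps


@lru_cache(maxsize=1)
def substitution_count_tables():
    """64x64 matrices of NG86 (Sd, Nd) between codon pairs.

    Multi-hit codons average over all minimal mutational pathways with
    equal weight; pathways passing through an intermediate stop codon are
    excluded unless every pathway does (then all are used). Entries
    involving stop codons are NaN.
    """
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for a in SENSE_CODONS:
        for b in SENSE_CODONS:
            diffs = _diff_positions(a, b)
            if not diffs:
                sd[a, b] = nd[a, b] = 0.0
                continue
            paths = []
            for order in itertools.permutations(diffs):
                steps = _path_steps(a, b, order)
                through_stop = any(
                    s in STOP_CODONS for _, s in steps[:-1]
                )
                paths.append((through_stop, steps))
            usable = [st for ok, st in paths if not ok] or [st for _, st in paths]
            s_tot = n_tot = 0.0
            for steps in usable:
                for x, y in steps:
                    if y in STOP_CODONS or x in STOP_CODONS:
                        n_tot += 1  # stop transitions counted nonsynonymous
                    elif AA[x] == AA[y]:
                        s_tot += 1
                    else:
                        n_tot += 1
            sd[a, b] = s_tot / len(usable)
            nd[a, b] = n_tot / len(usable)
    return sd, nd


def random_sense_sequence(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    """Uniform random stop-free codon sequence."""
    return rng.choice(np.array(SENSE_CODONS), size=n_codons)
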