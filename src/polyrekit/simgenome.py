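"""Synthetic genome-evolution generator.

Emulates the history this toolkit is built to detect: an ancestral diploid
genome is triplicated (or k-plicated), the polyploid splits into two
lineages, and each lineage independently fractionates (loses duplicate
copies) and rearranges its chromosomes (inversions, fusions, fissions).
Every downstream input — gene tables, aligned CDS pairs with known Ks,
homology hits, expression count matrices, folded site-frequency spectra
with divergence counts, and gene-family trees with a WGD retention burst —
is generated here with full ground truth, so each analysis stage can be
validated by parameter recovery.

All randomness flows from one explicit ``numpy`` generator seeded from
``SimConfig.seed``; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _codons

__all__ = [
    "SimConfig",
    "SimGene",
    "GenomeLayout",
    "SimTruth",
    "simulate_wgt_genomes",
    "replay_events",
    "simulate_codon_pairs",
    "simulate_cds_pair",
    "max_simulable_ks",
    "simulate_expression_counts",
    "simulate_selection_data",
    "simulate_gene_family_trees",
    "truth_homology_hits",
]


# --------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """All tunable parameters of the synthetic history.

    Probabilities are per-copy / per-pair; rates are expected event counts
    per lineage; Ks parameters are synonymous substitutions per synonymous
    site.
    """

    seed: int = 0
    n_anc_chromosomes: int = 8
    n_anc_genes: int = 2000
    wgt_multiplier: int = 3
    loss_prob: float = 0.35
    bias: float = 0.0
    inv_rate: float = 3.0
    fus_rate: float = 1.0
    fis_rate: float = 1.0
    ks_wgt_peak: float = 0.5
    ks_speciation_peak: float = 0.18
    ks_sd: float = 0.10
    omega: float = 0.2
    dfe_shape: float = 0.4
    dfe_mean_nes: float = 2000.0
    alpha_true: float = 0.3
    theta_site: float = 0.01
    n_chrom_sampled: int = 24
    degp_fraction: float = 0.6
    degp_log2_offset: float = 2.0
    nb_dispersion: float = 0.1
    retention_rate: float = 0.2

    def validate(self) -> None:
        for name in ("loss_prob", "bias", "degp_fraction", "retention_rate",
                     "alpha_true"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("inv_rate", "fus_rate", "fis_rate", "ks_wgt_peak",
                     "ks_speciation_peak", "ks_sd", "nb_dispersion",
                     "theta_site", "omega"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.wgt_multiplier < 1:
            raise ValueError("wgt_multiplier must be >= 1")
        if self.n_anc_genes < self.n_anc_chromosomes:
            raise ValueError("n_anc_genes < n_anc_chromosomes")
        if self.n_chrom_sampled < 2:
            raise ValueError("n_chrom_sampled must be >= 2")
        if self.dfe_shape <= 0:
            raise ValueError("dfe_shape must be > 0")
        if self.dfe_mean_nes < 0:
            raise ValueError("dfe_mean_nes must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# --------------------------------------------------------------------------
# layouts and truth


@dataclass(frozen=True)
class SimGene:
    """A gene copy on a simulated chromosome.

    ``anc_gene`` indexes the ancestral gene it descends from; ``sign`` is
    its orientation relative to the ancestral layout (flipped by
    inversions).
    """

    gene_id: str
    anc_gene: int
    anc_chrom: int
    subgenome: int
    sign: int = 1


@dataclass
class GenomeLayout:
    """Ordered genes on chromosomes of one (simulated) genome."""

    species: str
    chromosomes: list[list[SimGene]]

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def genes(self):
        for chrom in self.chromosomes:
            yield from chrom

    def to_gene_table(self) -> pd.DataFrame:
        """Tabular gene positions (1-based inclusive coordinates).

        Coordinates are synthesized from rank order: gene at rank r spans
        [1000*r + 1, 1000*r + 600] on its chromosome.
        """
        rows = []
        for ci, chrom in enumerate(self.chromosomes):
            for r, g in enumerate(chrom):
                start = 1000 * r + 1
                rows.append((g.gene_id, self.species, f"chr{ci + 1}",
                             start, start + 599,
                             "+" if g.sign > 0 else "-"))
        return pd.DataFrame(
            rows, columns=["gene_id", "species", "chromosome",
                           "start", "end", "strand"])


@dataclass
class SimTruth:
    """Ground truth of one simulated history."""

    config: SimConfig
    # per lineage: ancestral gene -> number of surviving copies
    copy_class: dict[str, np.ndarray]
    # per lineage: ordered, replayable event log
    event_log: dict[str, list[tuple]]
    # per lineage: list of (gene_id, gene_id) WGT paralog pairs
    paralog_pairs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    # cross-lineage ortholog pairs (same ancestral gene + subgenome)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    # filled by downstream generators
    pair_true_ks: dict[tuple[str, str], float] = field(default_factory=dict)
    degp_pairs: set[tuple[str, str]] = field(default_factory=set)

    def copy_class_of(self, lineage: str, anc_gene: int) -> int:
        return int(self.copy_class[lineage][anc_gene])


def _gene_id(species: str, anc_gene: int, subgenome: int) -> str:
    return f"{species}_g{anc_gene:05d}s{subgenome}"


def _ancestor_layout(config: SimConfig) -> GenomeLayout:
    per = np.full(config.n_anc_chromosomes, config.n_anc_genes
                  // config.n_anc_chromosomes)
    per[: config.n_anc_genes % config.n_anc_chromosomes] += 1
    chroms, gid = [], 0
    for ci, n in enumerate(per):
        chroms.append([SimGene(_gene_id("anc", g, 0), g, ci, 0)
                       for g in range(gid, gid + int(n))])
        gid += int(n)
    return GenomeLayout("anc", chroms)


def triplicate(ancestor: GenomeLayout, species: str,
               multiplier: int) -> GenomeLayout:
    """Whole-genome multiplication: one chromosome set per subgenome."""
    chroms = []
    for sub in range(multiplier):
        for chrom in ancestor.chromosomes:
            chroms.append([replace(g, gene_id=_gene_id(species, g.anc_gene, sub),
                                   subgenome=sub) for g in chrom])
    return GenomeLayout(species, chroms)


def _apply_event(layout: GenomeLayout, ev: tuple) -> None:
    kind = ev[0]
    if kind == "loss":
        _, anc_gene, sub = ev
        for chrom in layout.chromosomes:
            for i, g in enumerate(chrom):
                if g.anc_gene == anc_gene and g.subgenome == sub:
                    del chrom[i]
                    return
        raise ValueError(f"loss event for absent copy ({anc_gene}, {sub})")
    if kind == "inversion":
        _, ci, i, j = ev
        seg = layout.chromosomes[ci][i:j]
        layout.chromosomes[ci][i:j] = [replace(g, sign=-g.sign)
                                       for g in reversed(seg)]
        return
    if kind == "fusion":
        _, ci, cj = ev
        layout.chromosomes[ci].extend(layout.chromosomes[cj])
        del layout.chromosomes[cj]
        return
    if kind == "fission":
        _, ci, pos = ev
        chrom = layout.chromosomes[ci]
        layout.chromosomes[ci] = chrom[:pos]
        layout.chromosomes.append(chrom[pos:])
        return
    raise ValueError(f"unknown event kind {kind!r}")


def replay_events(ancestor: GenomeLayout, species: str, multiplier: int,
                  events: list[tuple]) -> GenomeLayout:
    """Rebuild a descendant layout by replaying a truth event log."""
    layout = triplicate(ancestor, species, multiplier)
    pruned = False
    for ev in events:
        if not pruned and ev[0] != "loss":
            # rearrangement indices refer to the post-fractionation layout
            # with empty chromosomes already removed
            layout.chromosomes = [c for c in layout.chromosomes if c]
            pruned = True
        _apply_event(layout, ev)
    layout.chromosomes = [c for c in layout.chromosomes if c]
    return layout


def _fractionate(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """Survival matrix (n_anc_genes x multiplier) of booleans.

    Per-copy independent Bernoulli loss with a multiplicative bias making
    subgenome 0 the least-fractionated; a group losing every copy keeps
    one uniformly chosen survivor, so each ancestral gene retains >= 1
    copy.
    """
    m = config.wgt_multiplier
    p = np.full(m, config.loss_prob)
    p[0] = config.loss_prob * (1.0 - config.bias)
    lost = rng.random((config.n_anc_genes, m)) < p[None, :]
    all_lost = lost.all(axis=1)
    if all_lost.any():
        keep = rng.integers(0, m, size=int(all_lost.sum()))
        lost[np.flatnonzero(all_lost), keep] = False
    return ~lost


def _rearrange(rng: np.random.Generator, layout: GenomeLayout,
               config: SimConfig, log: list[tuple]) -> None:
    n_inv = rng.poisson(config.inv_rate)
    n_fus = rng.poisson(config.fus_rate)
    n_fis = rng.poisson(config.fis_rate)
    ops = (["inversion"] * n_inv + ["fusion"] * n_fus + ["fission"] * n_fis)
    rng.shuffle(ops)
    for op in ops:
        chroms = layout.chromosomes
        if op == "inversion":
            eligible = [i for i, c in enumerate(chroms) if len(c) >= 2]
            if not eligible:
                continue
            ci = int(rng.choice(eligible))
            n = len(chroms[ci])
            i, j = sorted(rng.choice(n + 1, size=2, replace=False))
            if j - i < 2:
                j = min(i + 2, n)
                if j - i < 2:
                    continue
            ev = ("inversion", ci, int(i), int(j))
        elif op == "fusion":
            if len(chroms) < 2:
                continue
            ci, cj = rng.choice(len(chroms), size=2, replace=False)
            ev = ("fusion", int(min(ci, cj)), int(max(ci, cj)))
        else:
            eligible = [i for i, c in enumerate(chroms) if len(c) >= 2]
            if not eligible:
                continue
            ci = int(rng.choice(eligible))
            pos = int(rng.integers(1, len(chroms[ci])))
            ev = ("fission", ci, pos)
        _apply_event(layout, ev)
        log.append(ev)


def simulate_wgt_genomes(config: SimConfig):
    """Simulate the full WGT history.

    Returns (ancestor, (descendant_a, descendant_b), truth). Each
    descendant gene carries its ancestral gene id and subgenome label;
    truth records per-lineage copy classes and a replayable event log.
    """
    config.validate()
    rng = config.rng()
    ancestor = _ancestor_layout(config)
    m = config.wgt_multiplier

    copy_class, logs, paralogs = {}, {}, {}
    descendants = []
    for species in ("spA", "spB"):
        log: list[tuple] = []
        survive = _fractionate(rng, config)
        layout = triplicate(ancestor, species, m)
        for g in range(config.n_anc_genes):
            for sub in range(m):
                if not survive[g, sub]:
                    log.append(("loss", g, sub))
        # apply losses in bulk (order-independent), then rearrangements
        keep_layout = GenomeLayout(species, [])
        for chrom in layout.chromosomes:
            kept = [g for g in chrom if survive[g.anc_gene, g.subgenome]]
            if kept:
                keep_layout.chromosomes.append(kept)
        _rearrange(rng, keep_layout, config, log)
        copy_class[species] = survive.sum(axis=1).astype(np.int64)
        logs[species] = log
        pairs = []
        for g in range(config.n_anc_genes):
            subs = np.flatnonzero(survive[g])
            for i in range(len(subs)):
                for j in range(i + 1, len(subs)):
                    pairs.append((_gene_id(species, g, int(subs[i])),
                                  _gene_id(species, g, int(subs[j]))))
        paralogs[species] = pairs
        descendants.append(keep_layout)

    orthologs = []
    ids_a = {g.gene_id for g in descendants[0].genes()}
    ids_b = {g.gene_id for g in descendants[1].genes()}
    for g in range(config.n_anc_genes):
        for sub in range(m):
            ga = _gene_id("spA", g, sub)
            gb = _gene_id("spB", g, sub)
            if ga in ids_a and gb in ids_b:
                orthologs.append((ga, gb))

    truth = SimTruth(config=config, copy_class=copy_class, event_log=logs,
                     paralog_pairs=paralogs, ortholog_pairs=orthologs)
    return ancestor, tuple(descendants), truth


# --------------------------------------------------------------------------
# codon pairs

#: targets above this imply an expected synonymous p-distance beyond 95% of
#: the Jukes-Cantor ceiling (3/4) and are rejected as saturated.
MAX_TARGET_KS = -0.75 * math.log(0.05)


def max_simulable_ks() -> float:
    return MAX_TARGET_KS


def _apply_mutations(rng: np.random.Generator, codons: np.ndarray,
                     n_syn: int, n_non: int) -> np.ndarray:
    """Apply point mutations chosen uniformly among all possible
    synonymous (resp. nonsynonymous, non-stop) single-nucleotide changes,
    in random interleaved order."""
    syn_tab, non_tab = _codons.mutation_tables()
    n_syn_opts = np.array([len(s) for s in syn_tab], dtype=float)
    n_non_opts = np.array([len(s) for s in non_tab], dtype=float)
    codons = codons.copy()
    kinds = np.array([0] * n_syn + [1] * n_non)
    rng.shuffle(kinds)
    for kind in kinds:
        opts = n_syn_opts if kind == 0 else n_non_opts
        w = opts[codons]
        tot = w.sum()
        if tot == 0:
            continue
        idx = rng.choice(len(codons), p=w / tot)
        table = syn_tab if kind == 0 else non_tab
        choices = table[int(codons[idx])]
        codons[idx] = choices[int(rng.integers(len(choices)))]
    return codons


def simulate_cds_pair(rng: np.random.Generator, n_codons: int,
                      ks: float, ka: float) -> tuple[str, str]:
    """One aligned in-frame CDS pair with target divergence (Ks, Ka).

    Substitution counts are Poisson around ks*S and ka*N where S, N are
    the NG86 site counts of the ancestral sequence; mutations never create
    stop codons.
    """
    if ks < 0 or ka < 0:
        raise ValueError("negative divergence target")
    if ks > MAX_TARGET_KS or ka > MAX_TARGET_KS:
        raise ValueError(
            f"target divergence beyond Jukes-Cantor saturation "
            f"(max {MAX_TARGET_KS:.3f}): Ks={ks}, Ka={ka}")
    anc = _codons.random_sense_sequence(rng, n_codons)
    s_sites = _codons.syn_site_counts()[anc].sum()
    n_sites = 3.0 * n_codons - s_sites
    n_syn = int(rng.poisson(ks * s_sites)) if ks > 0 else 0
    n_non = int(rng.poisson(ka * n_sites)) if ka > 0 else 0
    der = _apply_mutations(rng, anc, n_syn, n_non)
    return _codons.decode(anc), _codons.decode(der)


def simulate_codon_pairs(truth: SimTruth, config: SimConfig,
                         rng: np.random.Generator | None = None,
                         n_codons: int = 300,
                         species: str | None = None,
                         max_pairs: int | None = None) -> pd.DataFrame:
    """Aligned CDS pairs for the truth's paralog and ortholog pairs.

    Paralog pairs draw their true Ks lognormally around ``ks_wgt_peak``;
    ortholog pairs around ``ks_speciation_peak``; Ka = omega * Ks. True
    values are recorded in ``truth.pair_true_ks`` and returned alongside
    the sequences.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    jobs = []
    lineages = [species] if species else list(truth.paralog_pairs)
    for sp in lineages:
        for pair in truth.paralog_pairs[sp]:
            jobs.append((pair, config.ks_wgt_peak))
    if species is None:
        for pair in truth.ortholog_pairs:
            jobs.append((pair, config.ks_speciation_peak))
    if max_pairs is not None and len(jobs) > max_pairs:
        idx = rng.choice(len(jobs), size=max_pairs, replace=False)
        jobs = [jobs[i] for i in sorted(idx)]
    rows = []
    for (ga, gb), peak in jobs:
        if peak > 0:
            ks = float(rng.lognormal(math.log(peak), config.ks_sd))
            ks = min(ks, MAX_TARGET_KS)
        else:
            ks = 0.0
        ka = config.omega * ks
        seq_a, seq_b = simulate_cds_pair(rng, n_codons, ks, ka)
        truth.pair_true_ks[(ga, gb)] = ks
        rows.append((ga, gb, seq_a, seq_b, ks, ka))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "seq_a", "seq_b",
                                       "ks_true", "ka_true"])


def ancestor_descendant_hits(ancestor: GenomeLayout,
                             layout: GenomeLayout) -> pd.DataFrame:
    """Ideal ancestor-vs-descendant homology table: every surviving gene
    hits its ancestral gene."""
    anc_ids = {g.anc_gene: g.gene_id for g in ancestor.genes()}
    rows = [(anc_ids[g.anc_gene], g.gene_id, 85.0, 0.0, 1.0, 1.0, 500.0)
            for g in layout.genes()]
    return pd.DataFrame(rows, columns=["query", "subject", "identity",
                                       "evalue", "coverage_q", "coverage_s",
                                       "bitscore"])


def truth_homology_hits(truth: SimTruth, species: str) -> pd.DataFrame:
    """Ideal within-species homology table derived from the truth pairs
    (identity/e-value/coverage passing the standard filters)."""
    rows = [(ga, gb, 85.0, 0.0, 1.0, 1.0, 500.0)
            for ga, gb in truth.paralog_pairs[species]]
    return pd.DataFrame(rows, columns=["query", "subject", "identity",
                                       "evalue", "coverage_q", "coverage_s",
                                       "bitscore"])


# --------------------------------------------------------------------------
# expression counts


def simulate_expression_counts(truth: SimTruth, config: SimConfig,
                               n_replicates: int = 3, n_tissues: int = 4,
                               species: str = "spA",
                               rng: np.random.Generator | None = None,
                               mean_log: float = math.log(200.0),
                               mean_sd: float = 1.0):
    """Negative-binomial read counts for the WGT duplicate genes.

    A fraction ``degp_fraction`` of retention groups is truly diverged:
    members of a diverged group are shifted apart so that every pair
    within it differs by at least ``degp_log2_offset`` log2 units (two
    members get opposite half-offsets; in a triplet the third stays at
    the base mean), making the pair-level true DEGP fraction equal to
    ``degp_fraction``. All members of a group share a lognormal
    tissue-level base mean; counts are NB with var = mu + phi*mu^2
    (Poisson when phi = 0). The true DEGP pair set is stored in
    ``truth.degp_pairs``.

    Returns an :class:`~polyrekit.ioformats.CountMatrix`.
    """
    from .ioformats import CountMatrix

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    cc = truth.copy_class[species]
    m = config.wgt_multiplier
    groups = []  # (anc_gene, member gene ids)
    survive_ids: dict[int, list[str]] = {}
    for ga, gb in truth.paralog_pairs[species]:
        anc = int(ga.split("_g")[1].split("s")[0])
        survive_ids.setdefault(anc, [])
    for anc in survive_ids:
        ids = sorted({g for pair in truth.paralog_pairs[species]
                      for g in pair
                      if int(g.split("_g")[1].split("s")[0]) == anc})
        survive_ids[anc] = ids
    groups = [(anc, ids) for anc, ids in sorted(survive_ids.items())
              if len(ids) >= 2]

    genes = [g for _, ids in groups for g in ids]
    samples = [(f"t{t + 1}", r + 1) for t in range(n_tissues)
               for r in range(n_replicates)]
    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    truth.degp_pairs = set()
    phi = config.nb_dispersion
    row = 0
    for anc, ids in groups:
        diverged = rng.random() < config.degp_fraction
        log2_mult = np.zeros(len(ids))
        if diverged:
            # spread members so every pair differs by >= the offset
            k = len(ids)
            half = config.degp_log2_offset / 2.0
            levels = np.linspace(-half * (k - 1), half * (k - 1), k)
            rng.shuffle(levels)
            log2_mult = levels
            for i in range(k):
                for j in range(i + 1, k):
                    truth.degp_pairs.add(tuple(sorted((ids[i], ids[j]))))
        base = rng.lognormal(mean_log, mean_sd, size=n_tissues)
        for gi, g in enumerate(ids):
            mult = 2.0 ** log2_mult[gi]
            col = 0
            for t in range(n_tissues):
                mu = base[t] * mult
                for _ in range(n_replicates):
                    if phi <= 0:
                        counts[row, col] = rng.poisson(mu)
                    else:
                        n_nb = 1.0 / phi
                        counts[row, col] = rng.negative_binomial(
                            n_nb, n_nb / (n_nb + mu))
                    col += 1
            row += 1
    frame = pd.DataFrame(counts, index=genes,
                         columns=[f"{t}:{r}" for t, r in samples])
    meta = pd.DataFrame(samples, columns=["tissue", "replicate"],
                        index=frame.columns)
    return CountMatrix(frame, meta)


# --------------------------------------------------------------------------
# selection data


def simulate_selection_data(config: SimConfig, n_genes_per_class: int,
                            l0_per_gene: int = 600, l4_per_gene: int = 200,
                            class_params: dict | None = None,
                            rng: np.random.Generator | None = None):
    """Folded SFS + divergence counts per copy class under a gamma DFE.

    Synonymous (four-fold) sites are neutral; nonsynonymous (zero-fold)
    segregating sites follow the Poisson-random-field expected folded SFS
    mixed over a gamma distribution of |Nes|. Divergence is Poisson with
    neutral per-site divergence ``ks_speciation_peak``; a fraction
    ``alpha_true`` of nonsynonymous divergence is adaptive.

    ``class_params`` may override ``dfe_shape``, ``dfe_mean_nes`` and
    ``alpha_true`` per copy class (keys 1, 2, 3), e.g. to grade selection
    strength across retention classes.

    Returns {copy_class: SelectionInput}.
    """
    from .selectionrx import SelectionInput, dfe_expected_folded_sfs, \
        dfe_fixation_factor, neutral_folded_sfs

    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    n = config.n_chrom_sampled
    out = {}
    for klass in (1, 2, 3):
        p = dict(shape=config.dfe_shape, mean_nes=config.dfe_mean_nes,
                 alpha=config.alpha_true)
        if class_params and klass in class_params:
            p.update(class_params[klass])
        theta0 = config.theta_site * l0_per_gene
        theta4 = config.theta_site * l4_per_gene
        e_syn = neutral_folded_sfs(theta4, n)
        if p["mean_nes"] <= 0:
            e_non = neutral_folded_sfs(theta0, n)
            fix = 1.0
        else:
            e_non = dfe_expected_folded_sfs(p["shape"], p["mean_nes"],
                                            theta0, n)
            fix = dfe_fixation_factor(p["shape"], p["mean_nes"])
        d_neutral = config.ks_speciation_peak
        e_ds = l4_per_gene * d_neutral
        e_dn_na = l0_per_gene * d_neutral * fix
        e_dn = e_dn_na / (1.0 - p["alpha"]) if p["alpha"] < 1 else e_dn_na
        g = n_genes_per_class
        sfs_zero = rng.poisson(np.broadcast_to(e_non, (g, e_non.size)))
        sfs_four = rng.poisson(np.broadcast_to(e_syn, (g, e_syn.size)))
        dn = rng.poisson(e_dn, size=g)
        ds = rng.poisson(e_ds, size=g)
        genes = pd.DataFrame({
            "gene": [f"c{klass}_g{i}" for i in range(g)],
            "L0": l0_per_gene, "L4": l4_per_gene,
            "Pn": sfs_zero.sum(axis=1), "Ps": sfs_four.sum(axis=1),
            "Dn": dn, "Ds": ds,
        })
        out[klass] = SelectionInput(copy_class=klass, n_chrom=n, genes=genes,
                                    sfs_zero=sfs_zero, sfs_four=sfs_four,
                                    true_params=p)
    return out


# --------------------------------------------------------------------------
# gene-family trees


def simulate_gene_family_trees(species_tree, birth: float, death: float,
                               wgd_node: str | None, retention_rate: float,
                               n_families: int, seed: int):
    """Gene-family trees under birth-death along a species tree, with an
    optional WGD burst.

    ``species_tree`` is a dendropy ultrametric tree with edge lengths;
    ``wgd_node`` names an internal node (its ``label``): every gene
    lineage reaching that node duplicates and the extra copy survives
    with probability ``retention_rate`` (otherwise it is lost
    immediately). Leaf labels are ``species|g<k>``.

    Returns a list of dendropy Trees, each ultrametric on the species
    timescale.
    """
    import dendropy

    if birth < 0 or death < 0:
        raise ValueError("negative birth/death rate")
    if not 0.0 <= retention_rate <= 1.0:
        raise ValueError("retention_rate outside [0, 1]")
    rng = np.random.default_rng(seed)

    species_tree.calc_node_ages(ultrametricity_precision=1e-6)
    root_age = species_tree.seed_node.age
    wgd_sp_node = None
    if wgd_node is not None:
        want = wgd_node.replace(" ", "_")
        for nd in species_tree.preorder_node_iter():
            labels = [nd.label, nd.taxon.label if nd.taxon else None]
            if any(l and l.replace(" ", "_") == want for l in labels):
                wgd_sp_node = nd
                break
        if wgd_sp_node is None or wgd_sp_node.is_leaf():
            raise ValueError(f"wgd_node {wgd_node!r} is not an internal "
                             f"node of the species tree")

    def depth(nd) -> float:
        return root_age - nd.age

    def evolve_edge(sp_node, t0: float, counter: list[int]):
        """Evolve one gene lineage from depth t0 to sp_node (the edge's
        child end); return a node dict or None if no sampled descendants."""
        t_end = depth(sp_node)
        rate = birth + death
        t = t0
        while rate > 0:
            dt = rng.exponential(1.0 / rate)
            if t + dt >= t_end:
                break
            t += dt
            if rng.random() < birth / rate:
                left = evolve_edge(sp_node, t, counter)
                right = evolve_edge(sp_node, t, counter)
                if left and right:
                    return {"depth": t, "children": [left, right]}
                return left or right
            return None  # death
        return arrive(sp_node, counter)

    def arrive(sp_node, counter):
        if sp_node.is_leaf():
            counter[0] += 1
            return {"depth": depth(sp_node), "children": [],
                    "label": f"{sp_node.taxon.label}|g{counter[0]}"}
        if sp_node is wgd_sp_node:
            main = speciate(sp_node, counter)
            extra = (speciate(sp_node, counter)
                     if rng.random() < retention_rate else None)
            if main and extra:
                return {"depth": depth(sp_node), "children": [main, extra]}
            return main or extra
        return speciate(sp_node, counter)

    def speciate(sp_node, counter):
        kids = [evolve_edge(ch, depth(sp_node), counter)
                for ch in sp_node.child_nodes()]
        kids = [k for k in kids if k]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return {"depth": depth(sp_node), "children": kids}

    trees = []
    for _ in range(n_families):
        counter = [0]
        root = evolve_edge(species_tree.seed_node, 0.0, counter)
        # seed edge has length 0 in depth terms; evolve from depth 0
        if root is None or not root["children"]:
            continue
        tree = _build_dendropy_tree(root)
        trees.append(tree)
    return trees


def _build_dendropy_tree(root: dict):
    import dendropy

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(node_dict, parent_depth):
        nd = dendropy.Node()
        nd.edge.length = node_dict["depth"] - parent_depth
        if not node_dict["children"]:
            nd.taxon = taxa.require_taxon(label=node_dict["label"])
        for ch in node_dict["children"]:
            nd.add_child(build(ch, node_dict["depth"]))
        return nd

    for ch in root["children"]:
        tree.seed_node.add_child(build(ch, root["depth"]))
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree
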