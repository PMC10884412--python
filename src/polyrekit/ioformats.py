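"""Readers and writers for every on-disk format, plus configuration and
logging. This is the only module that touches files.

Conventions: coordinates are 1-based inclusive on disk (GFF) and in
memory; gene ranks are recomputed from coordinates on read; readers
reject malformed input (naming the line) rather than silently repairing
it.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("polyrekit")

GENE_TABLE_COLUMNS = ["gene_id", "species", "chromosome", "start", "end",
                      "strand"]
HOMOLOGY_COLUMNS = ["query", "subject", "identity", "evalue",
                    "coverage_q", "coverage_s", "bitscore"]
OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore"]
LTR_COLUMNS = ["element_id", "ltr5_len", "ltr3_len", "spacing_to_next",
               "ltr_similarity", "has_gag_pol", "ltr_divergence_K",
               "family"]


def log_stage(stage: str, **params) -> None:
    """One structured log line per pipeline stage, for threshold
    provenance."""
    kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    logger.info("stage=%s %s", stage, kv)


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# --------------------------------------------------------------------------
# gene tables


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int = -1


def _validate_gene_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    if (df["start"] <= 0).any() or (df["end"] <= 0).any():
        bad = df.index[(df["start"] <= 0) | (df["end"] <= 0)][0]
        raise ValueError(f"{source}: nonpositive coordinate at row {bad}")
    if (df["start"] > df["end"]).any():
        bad = df.index[df["start"] > df["end"]][0]
        raise ValueError(f"{source}: start > end at row {bad}")
    dup = df.duplicated(subset=["species", "gene_id"])
    if dup.any():
        raise ValueError(
            f"{source}: duplicate gene_id "
            f"{df.loc[dup, 'gene_id'].iloc[0]!r}")
    return df


def add_ranks(df: pd.DataFrame) -> pd.DataFrame:
    """Recompute rank (0-based order along each chromosome) from start
    coordinates."""
    df = df.sort_values(["species", "chromosome", "start"],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = df.groupby(["species", "chromosome"]).cumcount()
    return df


def read_gene_table(path) -> pd.DataFrame:
    """Read a TSV gene table (gene_id, species, chromosome, start, end,
    strand); ranks are recomputed from coordinates."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str,
                                                "chromosome": str})
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse gene table: {exc}") from exc
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return add_ranks(_validate_gene_frame(df[GENE_TABLE_COLUMNS], str(path)))


def write_gene_table(df: pd.DataFrame, path) -> None:
    df[GENE_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gff3_genes(path, species: str,
                    feature_type: str = "gene") -> pd.DataFrame:
    """Read gene features from a GFF3 file into the internal gene table
    (coordinates kept 1-based inclusive as in the file)."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:",
                            merge_strategy="create_unique",
                            keep_order=True)
    rows = []
    for feat in db.features_of_type(feature_type, order_by="start"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append((gid, species, feat.seqid, feat.start, feat.end,
                     feat.strand if feat.strand in "+-" else "+"))
    if not rows:
        raise ValueError(f"{path}: no {feature_type!r} features")
    df = pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)
    return add_ranks(_validate_gene_frame(df, str(path)))


# --------------------------------------------------------------------------
# homology


@dataclass(frozen=True)
class HomologyHit:
    query: str
    subject: str
    identity: float
    evalue: float
    coverage_q: float
    coverage_s: float
    bitscore: float


def read_homology(path, query_lengths: dict | None = None,
                  subject_lengths: dict | None = None) -> pd.DataFrame:
    """Read homology hits.

    Accepts either the internal 7-column TSV (query, subject, identity,
    evalue, coverage_q, coverage_s, bitscore), a 12-column BLAST
    outfmt-6 table (coverages computed from the supplied length maps),
    or a 14-column outfmt-6 extended with qlen/slen.
    """
    with _open(path) as fh:
        first = fh.readline()
    ncols = len(first.rstrip("\n").split("\t"))
    if first.startswith("query\t"):
        df = pd.read_csv(path, sep="\t")
        missing = set(HOMOLOGY_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        df = df[HOMOLOGY_COLUMNS]
    elif ncols in (12, 14):
        names = OUTFMT6_COLUMNS + (["qlen", "slen"] if ncols == 14 else [])
        raw = pd.read_csv(path, sep="\t", names=names, header=None)
        if ncols == 14:
            qlen, slen = raw["qlen"], raw["slen"]
        else:
            if query_lengths is None or subject_lengths is None:
                raise ValueError(
                    f"{path}: 12-column outfmt-6 needs query/subject "
                    f"length maps to compute coverage")
            qlen = raw["qseqid"].map(query_lengths)
            slen = raw["sseqid"].map(subject_lengths)
            if qlen.isna().any() or slen.isna().any():
                bad = raw.loc[qlen.isna() | slen.isna()].index[0]
                raise ValueError(f"{path}: unknown sequence length at line "
                                 f"{bad + 1}")
        df = pd.DataFrame({
            "query": raw["qseqid"], "subject": raw["sseqid"],
            "identity": raw["pident"], "evalue": raw["evalue"],
            "coverage_q": raw["length"] / qlen,
            "coverage_s": raw["length"] / slen,
            "bitscore": raw["bitscore"],
        })
    else:
        raise ValueError(f"{path}: unrecognized homology format "
                         f"({ncols} columns)")
    if (df["evalue"] < 0).any():
        bad = df.index[df["evalue"] < 0][0]
        raise ValueError(f"{path}: negative e-value at row {bad}")
    if ((df["identity"] < 0) | (df["identity"] > 100)).any():
        raise ValueError(f"{path}: identity outside [0, 100]")
    return df


def write_homology(df: pd.DataFrame, path) -> None:
    df[HOMOLOGY_COLUMNS].to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# counts


@dataclass
class CountMatrix:
    """genes x samples non-negative integer counts with sample metadata
    (tissue, replicate)."""

    counts: pd.DataFrame
    samples: pd.DataFrame  # index = sample name; columns tissue, replicate

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("sample metadata does not match count columns")
        per = self.samples.groupby("tissue")["replicate"].nunique()
        n_per = self.samples.groupby("tissue").size()
        if not (per == n_per).all():
            raise ValueError("duplicate replicate labels within a tissue")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.samples["tissue"].unique())

    def tissue_samples(self, tissue: str) -> list[str]:
        sub = self.samples[self.samples["tissue"] == tissue]
        return list(sub.sort_values("replicate").index)


def read_counts(path) -> CountMatrix:
    """Read a counts TSV whose columns are named ``tissue:replicate``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = []
    for col in df.columns:
        if ":" not in col:
            raise ValueError(f"{path}: sample column {col!r} is not "
                             f"'tissue:replicate'")
        tissue, rep = col.rsplit(":", 1)
        meta.append((tissue, int(rep)))
    samples = pd.DataFrame(meta, columns=["tissue", "replicate"],
                           index=df.columns)
    if not np.issubdtype(df.values.dtype, np.integer):
        if not np.allclose(df.values, np.round(df.values)):
            raise ValueError(f"{path}: non-integer counts")
        df = df.round().astype(np.int64)
    return CountMatrix(df, samples)


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


# --------------------------------------------------------------------------
# trees


def read_newick(path):
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree, path) -> None:
    tree.write(path=str(path), schema="newick")


# --------------------------------------------------------------------------
# folded SFS


@dataclass
class FoldedSFS:
    """Folded site-frequency spectrum: counts per minor-allele class
    1..floor(n_chrom/2)."""

    n_chrom: int
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.n_chrom < 2:
            raise ValueError("n_chrom must be >= 2")
        if self.counts.size != self.n_chrom // 2:
            raise ValueError(
                f"folded SFS for n={self.n_chrom} needs "
                f"{self.n_chrom // 2} classes, got {self.counts.size}")
        if (self.counts < 0).any():
            raise ValueError("negative SFS counts")


def read_sfs(path) -> dict[str, FoldedSFS]:
    """Read an SFS TSV: first line ``#n_chrom=<n>``, then a header
    ``class<TAB>name...`` and one row per frequency class. Returns one
    FoldedSFS per data column."""
    with _open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#n_chrom="):
            raise ValueError(f"{path}: line 1: expected '#n_chrom=<int>'")
        n_chrom = int(first.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t")
    if "class" not in df.columns:
        raise ValueError(f"{path}: missing 'class' column")
    expected = list(range(1, n_chrom // 2 + 1))
    if list(df["class"]) != expected:
        raise ValueError(f"{path}: class column must be {expected}")
    return {col: FoldedSFS(n_chrom, df[col].to_numpy())
            for col in df.columns if col != "class"}


def write_sfs(spectra: dict[str, FoldedSFS], path) -> None:
    n = {s.n_chrom for s in spectra.values()}
    if len(n) != 1:
        raise ValueError("mixed n_chrom in SFS set")
    n_chrom = n.pop()
    df = pd.DataFrame({"class": np.arange(1, n_chrom // 2 + 1)})
    for name, s in spectra.items():
        df[name] = s.counts
    with open(path, "wt") as fh:
        fh.write(f"#n_chrom={n_chrom}\n")
        df.to_csv(fh, sep="\t", index=False)


# --------------------------------------------------------------------------
# LTR candidates


@dataclass(frozen=True)
class LTRCandidate:
    element_id: str
    ltr5_len: int
    ltr3_len: int
    spacing_to_next: int
    ltr_similarity: float
    has_gag_pol: bool
    ltr_divergence_K: float
    family: str = "other"


def read_ltr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(LTR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if ((df["ltr5_len"] <= 0) | (df["ltr3_len"] <= 0)).any():
        raise ValueError(f"{path}: nonpositive LTR length")
    if ((df["ltr_similarity"] < 0) | (df["ltr_similarity"] > 100)).any():
        raise ValueError(f"{path}: similarity outside [0, 100]")
    if (df["ltr_divergence_K"] < 0).any():
        raise ValueError(f"{path}: negative LTR divergence")
    return df[LTR_COLUMNS]


def write_ltr_table(df: pd.DataFrame, path) -> None:
    df[LTR_COLUMNS].to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# FASTA


def write_fasta(records: dict[str, str], path) -> None:
    with _open(path, "wt") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    with _open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


# --------------------------------------------------------------------------
# configuration


def load_config(path):
    """Load a YAML run configuration into a SimConfig plus extra
    per-stage sections (returned as a dict)."""
    from .simgenome import SimConfig

    with _open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_kwargs = raw.pop("simulate", {})
    config = SimConfig(**sim_kwargs)
    config.validate()
    return config, raw


def save_config(config, extra: dict, path) -> None:
    from dataclasses import asdict

    payload = {"simulate": asdict(config), **extra}
    with open(path, "wt") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
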