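"""Ka/Ks estimation, Ks-peak detection, block/pair Ks filtering, LTR
dating, and strict-clock WGT age estimation.

The Ka/Ks estimator is Nei-Gojobori (1986) counting with Jukes-Cantor
correction: synonymous/nonsynonymous site fractions per codon, averaged
over both sequences; observed differences averaged with equal weight over
all minimal mutational pathways for multi-hit codons; Ks = -3/4 ln(1 -
4/3 pS) and analogously Ka. Changes into stop codons count as
nonsynonymous sites; pathways through intermediate stops are excluded
when any stop-free pathway exists. A pair with pS or pN >= 3/4 is flagged
saturated and carries no Ks/Ka.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _codons

__all__ = [
    "PairKs",
    "KsPeak",
    "ClockCalibration",
    "WgtAge",
    "ng86_ka_ks",
    "pairs_ka_ks",
    "block_median_ks_filter",
    "detect_ks_peaks",
    "filter_intact_ltr",
    "ltr_insertion_age",
    "estimate_wgt_age",
]


@dataclass
class PairKs:
    gene_a: str
    gene_b: str
    ka: float | None
    ks: float | None
    omega: float | None
    n_codons: int
    saturated: bool


@dataclass
class KsPeak:
    mode: float   # Ks units (exp of the log-scale mean)
    weight: float
    sd: float     # log-scale standard deviation


@dataclass
class ClockCalibration:
    """Strict-clock calibration: an orthologous Ks peak of known age.

    ``rate_2r`` is the two-lineage synonymous divergence rate in Ks per
    Mya, i.e. ks_orth_peak / t_calibration.
    """

    ks_orth_peak: float
    t_calibration: float  # Mya

    def __post_init__(self):
        if self.ks_orth_peak <= 0 or self.t_calibration <= 0:
            raise ValueError("calibration values must be positive")

    @property
    def rate_2r(self) -> float:
        return self.ks_orth_peak / self.t_calibration


@dataclass
class WgtAge:
    age_mya: float
    ci_low: float
    ci_high: float
    bootstrap_ages: np.ndarray


def peak_from_values(ks_values) -> KsPeak:
    """The peak implied by a set of Ks values attributed to one event:
    mode = geometric mean (the lognormal median), sd on the log scale.
    This is the statistic the dating bootstrap resamples, so using it as
    the point estimate keeps the two consistent."""
    ks = np.asarray(ks_values, dtype=float)
    ks = ks[np.isfinite(ks) & (ks > 0)]
    if ks.size == 0:
        raise ValueError("no positive finite Ks values")
    logs = np.log(ks)
    return KsPeak(mode=float(np.exp(logs.mean())), weight=1.0,
                  sd=float(logs.std()))


def _jc(p: float) -> float | None:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return None
    return -0.75 * math.log(arg)


def ng86_ka_ks(cds_a: str, cds_b: str, gene_a: str = "a",
               gene_b: str = "b") -> PairKs:
    """NG86 Ka/Ks for one aligned in-frame CDS pair (no gaps, no internal
    stops, equal lengths divisible by 3)."""
    if len(cds_a) != len(cds_b):
        raise ValueError(f"length mismatch: {len(cds_a)} vs {len(cds_b)}")
    a = _codons.encode(cds_a)
    b = _codons.encode(cds_b)
    for name, arr in (("first", a), ("second", b)):
        stops = np.isin(arr, list(_codons.STOP_CODONS))
        if stops.any():
            raise ValueError(f"internal stop codon in {name} sequence at "
                             f"codon {int(np.flatnonzero(stops)[0])}")
    s_sites = _codons.syn_site_counts()
    sd_tab, nd_tab = _codons.substitution_count_tables()
    s = float((s_sites[a].sum() + s_sites[b].sum()) / 2.0)
    n = 3.0 * len(a) - s
    sd = float(sd_tab[a, b].sum())
    nd = float(nd_tab[a, b].sum())
    ps = sd / s if s > 0 else 0.0
    pn = nd / n if n > 0 else 0.0
    ks = _jc(ps)
    ka = _jc(pn)
    saturated = ks is None or ka is None
    omega = None
    if not saturated and ks is not None and ks > 0:
        omega = ka / ks
    return PairKs(gene_a, gene_b, None if saturated else ka,
                  None if saturated else ks, omega, len(a), saturated)


def pairs_ka_ks(pairs: pd.DataFrame) -> pd.DataFrame:
    """Vectorized NG86 over a frame with columns gene_a, gene_b, seq_a,
    seq_b; returns the PairKs table."""
    rows = []
    for ga, gb, sa, sb in pairs[["gene_a", "gene_b", "seq_a",
                                 "seq_b"]].itertuples(index=False):
        r = ng86_ka_ks(sa, sb, ga, gb)
        rows.append((r.gene_a, r.gene_b, r.ka, r.ks, r.omega, r.n_codons,
                     r.saturated))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "ka", "ks",
                                       "omega", "n_codons", "saturated"])


# --------------------------------------------------------------------------
# Ks filtering


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def block_median_ks_filter(blocks, ks_table: pd.DataFrame,
                           median_low: float = 0.2,
                           median_high: float = 1.0,
                           pair_max: float = 1.26) -> pd.DataFrame:
    """Keep gene pairs in blocks whose median anchor Ks lies in
    [median_low, median_high], excluding pairs with Ks above pair_max;
    saturated pairs are always excluded.

    Returns the retained rows of ``ks_table`` (one row per kept pair).
    """
    ks_by_pair = {}
    for ga, gb, ks, sat in ks_table[["gene_a", "gene_b", "ks",
                                     "saturated"]].itertuples(index=False):
        ks_by_pair[_pair_key(ga, gb)] = (ks, bool(sat))
    kept_keys = set()
    for b in blocks:
        anchor_ks = []
        for ga, gb in b.anchors:
            ks, sat = ks_by_pair.get(_pair_key(ga, gb), (None, True))
            if not sat and ks is not None:
                anchor_ks.append(ks)
        if not anchor_ks:
            continue
        med = float(np.median(anchor_ks))
        if not (median_low <= med <= median_high):
            continue
        for ga, gb in b.anchors:
            ks, sat = ks_by_pair.get(_pair_key(ga, gb), (None, True))
            if sat or ks is None or ks > pair_max:
                continue
            kept_keys.add(_pair_key(ga, gb))
    mask = [_pair_key(ga, gb) in kept_keys
            for ga, gb in ks_table[["gene_a", "gene_b"]].itertuples(
                index=False)]
    return ks_table.loc[mask].reset_index(drop=True)


# --------------------------------------------------------------------------
# peak detection


def detect_ks_peaks(ks_values, max_components: int = 4,
                    min_values: int = 50,
                    random_state: int = 0) -> list[KsPeak]:
    """Gaussian-mixture peaks on log-Ks; component count by BIC (ties
    toward fewer components). Peaks are returned sorted by mode; weights
    sum to 1."""
    from sklearn.mixture import GaussianMixture

    ks = np.asarray(ks_values, dtype=float)
    ks = ks[np.isfinite(ks) & (ks > 0)]
    if ks.size < min_values:
        raise ValueError(f"need >= {min_values} finite positive Ks values, "
                         f"got {ks.size}")
    x = np.log(ks)[:, None]
    if np.ptp(x) < 1e-12:
        return [KsPeak(mode=float(ks[0]), weight=1.0, sd=0.0)]
    best = None
    for k in range(1, max_components + 1):
        gm = GaussianMixture(n_components=k, n_init=3,
                             random_state=random_state)
        gm.fit(x)
        bic = gm.bic(x)
        if best is None or bic < best[0] - 1e-9:
            best = (bic, gm)
    gm = best[1]
    peaks = [KsPeak(mode=float(np.exp(m)), weight=float(w),
                    sd=float(np.sqrt(v)))
             for m, w, v in zip(gm.means_.ravel(), gm.weights_,
                                gm.covariances_.ravel())]
    peaks.sort(key=lambda p: p.mode)
    return peaks


# --------------------------------------------------------------------------
# LTR dating


def filter_intact_ltr(candidates: pd.DataFrame, min_ltr: int = 100,
                      max_ltr: int = 3000, min_similarity: float = 80.0,
                      min_spacing: int = 1000, max_spacing: int = 15000,
                      require_gag_pol: bool = True) -> pd.DataFrame:
    """Intact LTR-RT criteria: both LTRs within [min_ltr, max_ltr] bp,
    LTR similarity above min_similarity, spacing to the next candidate
    within [min_spacing, max_spacing] bp, and (optionally) a complete
    Gag-Pol."""
    keep = ((candidates["ltr5_len"] >= min_ltr)
            & (candidates["ltr5_len"] <= max_ltr)
            & (candidates["ltr3_len"] >= min_ltr)
            & (candidates["ltr3_len"] <= max_ltr)
            & (candidates["ltr_similarity"] > min_similarity)
            & (candidates["spacing_to_next"] >= min_spacing)
            & (candidates["spacing_to_next"] <= max_spacing))
    if require_gag_pol:
        keep &= candidates["has_gag_pol"].astype(bool)
    return candidates.loc[keep].reset_index(drop=True)


def ltr_insertion_age(K, rate: float = 1.3e-8):
    """Insertion age in years from 5'-3' LTR divergence K:
    age = K / (2 * rate). Linear in K; vectorized."""
    K = np.asarray(K, dtype=float)
    if (K < 0).any():
        raise ValueError("negative LTR divergence")
    if rate <= 0:
        raise ValueError("rate must be positive")
    age = K / (2.0 * rate)
    return float(age) if age.ndim == 0 else age


# --------------------------------------------------------------------------
# WGT dating


def estimate_wgt_age(wgt_peak: KsPeak, calibration: ClockCalibration,
                     ks_values=None, n_boot: int = 200,
                     rng: np.random.Generator | None = None) -> WgtAge:
    """Strict-clock WGT age: peak mode / calibration rate, with a
    bootstrap interval over the Ks values feeding the peak (the
    geometric-mean mode is recomputed per resample)."""
    rate = calibration.rate_2r
    if rate <= 0:
        raise ValueError("zero calibration rate")
    age = wgt_peak.mode / rate
    if ks_values is None or len(ks_values) == 0:
        return WgtAge(age, age, age, np.array([age]))
    if rng is None:
        rng = np.random.default_rng(0)
    ks = np.asarray(ks_values, dtype=float)
    ks = ks[np.isfinite(ks) & (ks > 0)]
    logs = np.log(ks)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        sample = logs[rng.integers(0, logs.size, size=logs.size)]
        boots[i] = math.exp(float(sample.mean())) / rate
    lo, hi = np.quantile(boots, [0.025, 0.975])
    lo, hi = min(lo, age), max(hi, age)
    return WgtAge(age, float(lo), float(hi), boots)
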