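"""Pooled knockout barcode-screen analysis.

Reads carrying 20-bp strain barcodes are tallied into a strain × sample
count table; strains enriched or depleted under drug relative to control
are found with a negative-binomial Wald test (median-of-ratios size
factors, moment-based dispersion shrunk toward a mean–dispersion trend,
Benjamini–Hochberg adjustment); hits are called at a fold-change and FDR
cutoff; overlap with an annotated strain set is tested with Fisher's exact
test; and gene sets are scored by a Welch-t set-enrichment analog.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountTable",
    "HitCall",
    "ScreenEnrichmentModel",
    "ScreenResults",
    "count_barcodes",
    "filter_low_counts",
    "estimate_size_factors",
    "wald_enrichment",
    "call_hits",
    "fisher_overlap",
    "classify_slow_growers",
    "set_enrichment",
]

PSEUDOCOUNT = 0.5


@dataclass
class CountTable:
    """Barcode × sample counts with condition labels.

    ``counts``: DataFrame indexed by strain id, one column per sample.
    ``condition``: Series mapping sample -> {"drug", "control"}.
    ``size_factors``: per-sample normalization factors (set after
    :func:`estimate_size_factors`).
    """

    counts: pd.DataFrame
    condition: pd.Series
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.condition.index)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")
        bad = set(self.condition.loc[list(self.counts.columns)]) - {"drug", "control"}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    def samples(self, condition: str) -> list:
        cond = self.condition.loc[list(self.counts.columns)]
        return [s for s in self.counts.columns if cond[s] == condition]

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("size factors not estimated")
        return self.counts / self.size_factors


def _read_barcode_db(db) -> dict[str, str]:
    """FASTA (path or handle) -> {barcode sequence: strain id}; validates
    uniqueness and uniform length."""
    seqs = {}
    lengths = set()
    for rec in SeqIO.parse(db, "fasta"):
        bc = str(rec.seq).upper()
        if bc in seqs:
            raise ValueError(f"duplicate barcode {bc} ({rec.id} / {seqs[bc]})")
        seqs[bc] = rec.id
        lengths.add(len(bc))
    if not seqs:
        raise ValueError("empty barcode database")
    if len(lengths) != 1:
        raise ValueError(f"barcodes must share one length, got {sorted(lengths)}")
    return seqs


def _neighbors(kmer: str):
    for i, base in itertools.product(range(len(kmer)), "ACGT"):
        if kmer[i] != base:
            yield kmer[:i] + base + kmer[i + 1:]


def count_barcodes(reads, db, max_mismatch: int = 0) -> tuple[pd.Series, int]:
    """Assign each read to at most one barcode; return counts + unassigned.

    Exact substring match is tried first on the read and its reverse
    complement; with ``max_mismatch=1`` unmatched reads are rescued when a
    single k-mer position matches exactly one barcode at Hamming distance 1.
    Conservation: ``counts.sum() + unassigned == number of reads``.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    bc_map = _read_barcode_db(db)
    L = len(next(iter(bc_map)))
    counts: dict[str, int] = {sid: 0 for sid in bc_map.values()}
    unassigned = 0
    for rec in SeqIO.parse(reads, "fastq"):
        seq = str(rec.seq).upper()
        hit = _match_read(seq, bc_map, L, max_mismatch)
        if hit is None:
            hit = _match_read(str(Seq(seq).reverse_complement()), bc_map, L, max_mismatch)
        if hit is None:
            unassigned += 1
        else:
            counts[hit] += 1
    return pd.Series(counts, name="count"), unassigned


def _match_read(seq: str, bc_map: dict[str, str], L: int, max_mismatch: int):
    kmers = [seq[i:i + L] for i in range(len(seq) - L + 1)]
    for k in kmers:
        if k in bc_map:
            return bc_map[k]
    if max_mismatch == 1:
        found = set()
        for k in kmers:
            for nb in _neighbors(k):
                if nb in bc_map:
                    found.add(bc_map[nb])
        if len(found) == 1:
            return found.pop()
    return None


def filter_low_counts(table: CountTable, min_count: int = 10) -> CountTable:
    """Drop strains whose maximum count across all samples is < ``min_count``."""
    keep = table.counts.max(axis=1) >= min_count
    return CountTable(table.counts.loc[keep].copy(), table.condition,
                      table.size_factors)


def estimate_size_factors(table: CountTable) -> pd.Series:
    """Median-of-ratios size factors (ratio to per-strain geometric mean)."""
    counts = table.counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    expressed = np.all(np.isfinite(logc), axis=1)
    if not expressed.any():
        raise ValueError("no strain has nonzero counts in all samples")
    log_geo = logc[expressed].mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc[expressed] - log_geo, axis=0))
    sf = pd.Series(factors, index=table.counts.columns, name="size_factor")
    table.size_factors = sf
    return sf


# ---------------------------------------------------------------------------
# NB Wald enrichment


class ScreenEnrichmentModel:
    """Per-strain negative-binomial enrichment model for a count table.

    NB variance ``Var = mu + alpha mu^2``.  Gene-wise dispersions are
    moment estimates from within-condition variance of normalized counts,
    shrunk in log space toward a parametric mean–dispersion trend
    ``alpha(mu) = a0 + a1/mu`` fitted across strains.  The Wald statistic
    is ``log2fc / SE(log2fc)`` with a delta-method SE.
    """

    #: weight of the fitted trend in the log-space dispersion shrinkage;
    #: heavy shrinkage reflects the few (3) replicates per condition.
    TREND_WEIGHT = 0.7

    def __init__(self, table: CountTable):
        if table.size_factors is None:
            estimate_size_factors(table)
        for cond in ("drug", "control"):
            if len(table.samples(cond)) < 2:
                raise ValueError(f"need >= 2 {cond!r} samples")
        self.table = table

    def fit(self) -> "ScreenResults":
        tab = self.table
        norm = tab.normalized()
        drug_s, ctrl_s = tab.samples("drug"), tab.samples("control")
        nd, nc = len(drug_s), len(ctrl_s)
        drug = norm[drug_s].to_numpy()
        ctrl = norm[ctrl_s].to_numpy()

        nonzero = tab.counts.sum(axis=1).to_numpy() > 0
        if (~nonzero).any():
            warnings.warn(f"excluding {(~nonzero).sum()} all-zero strains", stacklevel=2)

        mu_d = drug.mean(axis=1)
        mu_c = ctrl.mean(axis=1)
        base_mean = norm.to_numpy().mean(axis=1)

        # Moment dispersion pooled over conditions: E[(x-mu)^2] = mu + a mu^2.
        var_d = drug.var(axis=1, ddof=1)
        var_c = ctrl.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a_raw = ((var_d - mu_d) + (var_c - mu_c)) / (mu_d**2 + mu_c**2)
        a_raw = np.clip(np.nan_to_num(a_raw, nan=0.0), 1e-8, 10.0)

        alpha = self._shrink_dispersion(base_mean, a_raw, nonzero)

        log2fc = np.log2(mu_d + PSEUDOCOUNT) - np.log2(mu_c + PSEUDOCOUNT)

        # Delta-method SE of log2 of a condition mean of normalized NB
        # counts: Var(K_j/s_j) = mu/s_j + alpha mu^2.
        inv_s_d = (1.0 / tab.size_factors[drug_s].to_numpy()).mean()
        inv_s_c = (1.0 / tab.size_factors[ctrl_s].to_numpy()).mean()
        var_mean_d = (mu_d * inv_s_d + alpha * mu_d**2) / nd
        var_mean_c = (mu_c * inv_s_c + alpha * mu_c**2) / nc
        ln2sq = math.log(2.0) ** 2
        se = np.sqrt(var_mean_d / np.maximum(mu_d + PSEUDOCOUNT, PSEUDOCOUNT) ** 2 / ln2sq
                     + var_mean_c / np.maximum(mu_c + PSEUDOCOUNT, PSEUDOCOUNT) ** 2 / ln2sq)
        se = np.maximum(se, 1e-12)

        z = log2fc / se
        p = 2.0 * stats.norm.sf(np.abs(z))

        stats_df = pd.DataFrame({
            "base_mean": base_mean, "log2fc": log2fc, "dispersion": alpha,
            "se": se, "wald_z": z, "p": p,
        }, index=tab.counts.index)
        stats_df = stats_df.loc[nonzero]
        stats_df["q"] = multipletests(stats_df["p"], method="fdr_bh")[1]
        return ScreenResults(self, stats_df)

    def _shrink_dispersion(self, mean: np.ndarray, a_raw: np.ndarray,
                           use: np.ndarray) -> np.ndarray:
        m = np.maximum(mean, PSEUDOCOUNT)
        # Parametric trend alpha = a0 + a1/mu, least squares on raw moments.
        X = np.column_stack([np.ones_like(m[use]), 1.0 / m[use]])
        coef, *_ = np.linalg.lstsq(X, a_raw[use], rcond=None)
        trend = np.clip(coef[0] + coef[1] / m, 1e-8, 10.0)
        w = self.TREND_WEIGHT
        return np.exp((1.0 - w) * np.log(a_raw) + w * np.log(trend))


@dataclass
class ScreenResults:
    """Per-strain enrichment statistics and hit calling."""

    model: ScreenEnrichmentModel = field(repr=False)
    stats: pd.DataFrame

    def call_hits(self, fc_cutoff: float = 16.0, q_cutoff: float = 0.05) -> "HitCall":
        return call_hits(self.stats, fc_cutoff, q_cutoff)

    def summary(self) -> str:
        hits = self.call_hits()
        return "\n".join([
            "NB Wald barcode-screen enrichment",
            "-" * 38,
            f"strains tested:     {len(self.stats)}",
            f"resistant (>=16x, q<0.05): {len(hits.resistant)}",
            f"sensitive (<=1/16x, q<0.05): {len(hits.sensitive)}",
            f"median dispersion:  {self.stats['dispersion'].median():.4g}",
        ])


@dataclass(frozen=True)
class HitCall:
    resistant: tuple
    sensitive: tuple
    fc_cutoff: float = 16.0
    q_cutoff: float = 0.05


def wald_enrichment(table: CountTable) -> pd.DataFrame:
    """Per-strain NB Wald statistics (see :class:`ScreenEnrichmentModel`)."""
    return ScreenEnrichmentModel(table).fit().stats


def call_hits(stats_df: pd.DataFrame, fc_cutoff: float = 16.0,
              q_cutoff: float = 0.05) -> HitCall:
    """Resistant: log2fc >= log2(fc) and q < q_cutoff; sensitive: mirrored."""
    if len(stats_df) == 0:
        return HitCall((), (), fc_cutoff, q_cutoff)
    lfc = math.log2(fc_cutoff)
    res = stats_df.index[(stats_df["log2fc"] >= lfc) & (stats_df["q"] < q_cutoff)]
    sen = stats_df.index[(stats_df["log2fc"] <= -lfc) & (stats_df["q"] < q_cutoff)]
    return HitCall(tuple(res), tuple(sen), fc_cutoff, q_cutoff)


def fisher_overlap(hits, annotated, universe) -> tuple[np.ndarray, float]:
    """One-tailed Fisher's exact test of hit/annotation overlap.

    Returns the 2×2 table ``[[both, hits only], [annotated only,
    neither]]`` and the exact hypergeometric tail probability of an
    overlap at least as large as observed.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits, annotated = set(hits) & universe, set(annotated) & universe
    a = len(hits & annotated)
    b = len(hits - annotated)
    c = len(annotated - hits)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="greater")
    return table, float(p)


def classify_slow_growers(growth_od24: pd.Series, cutoff: float = 0.11) -> set:
    """Strains whose 24-h OD on minimal medium is strictly below ``cutoff``."""
    if (growth_od24 < 0).any():
        raise ValueError("OD values must be >= 0")
    return set(growth_od24.index[growth_od24 < cutoff])


def set_enrichment(stats_df: pd.DataFrame, sets: dict, q_cutoff: float = 0.1,
                   min_size: int = 3) -> pd.DataFrame:
    """Welch-t gene-set enrichment of member vs non-member log2 fold changes.

    One-sided p-values in each direction ("up" = members more enriched
    under drug), BH-adjusted per direction across sets.  Sets with fewer
    than ``min_size`` scored members, or with an empty complement, are
    skipped with a warning.
    """
    lfc = stats_df["log2fc"]
    rows = []
    for name, members in sets.items():
        members = [m for m in members if m in lfc.index]
        if len(members) < min_size:
            warnings.warn(f"set {name!r} has < {min_size} scored members; skipped",
                          stacklevel=2)
            continue
        in_mask = lfc.index.isin(members)
        x, y = lfc[in_mask], lfc[~in_mask]
        if len(y) < 2:
            warnings.warn(f"set {name!r} has no usable complement; skipped", stacklevel=2)
            continue
        t_up = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
        t_dn = stats.ttest_ind(x, y, equal_var=False, alternative="less")
        rows.append({"set": name, "n": len(x), "t": float(t_up.statistic),
                     "p_up": float(t_up.pvalue), "p_down": float(t_dn.pvalue)})
    out = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["n", "t", "p_up", "p_down", "q_up", "q_down"])
    if len(out):
        out["q_up"] = multipletests(out["p_up"], method="fdr_bh")[1]
        out["q_down"] = multipletests(out["p_down"], method="fdr_bh")[1]
        out["significant"] = (out["q_up"] < q_cutoff) | (out["q_down"] < q_cutoff)
    return out
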