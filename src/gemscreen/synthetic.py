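"""Synthetic-data generators emulating each experimental design.

Every generator is seeded and deterministic, and produces data with the
statistical structure its downstream analysis stage assumes: negative-
binomial barcode counts with planted resistors, logistic growth curves
scaled by Hill inhibition, degradation-coupled spheroid area grids,
Lea–Coulson mutant-count distributions thinned by plating, conservation
profiles with biased mutation-position sampling, and single-mutation CDS
edits for annotation round trips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .doseresponse import PlateSeries
from .screen import CountTable
from .spheroid import SpheroidGrid

__all__ = [
    "ScreenSimConfig", "GrowthSimConfig", "SpheroidSimConfig", "FluctuationSimConfig",
    "simulate_screen_counts", "simulate_screen_reads", "make_barcode_db",
    "simulate_growth_curves", "serial_dilution_doses", "STRAIN_PRESETS",
    "simulate_spheroid_plate", "simulate_fluctuation", "simulate_conservation",
    "Substitution", "Deletion", "Insertion", "Transposon",
    "mutate_sequence", "expected_class", "random_cds", "random_mutation_spec",
    "simulate_breakdown_cohort",
]

#: fixed amplicon flanks surrounding the 20-bp barcode in synthetic reads
FLANK_5 = "ACGCTCTTCCGATCTCTGAC"
FLANK_3 = "AGATCGGAAGAGCACACGTC"

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Pooled barcode screen


@dataclass
class ScreenSimConfig:
    """Design of a synthetic pooled knockout screen.

    3680 knockout strains by default (the barcoded-library size), three
    replicates per condition, negative-binomial counts with
    ``Var = mu + dispersion * mu^2``.  ``planted_resistors`` /
    ``planted_sensitives`` are (strain id, true log2 fold change) pairs
    applied to the drug-condition means.
    """

    n_strains: int = 3680
    planted_resistors: list = field(default_factory=list)
    planted_sensitives: list = field(default_factory=list)
    dispersion: float = 0.02
    depth: float = 1e6
    n_reps: int = 3
    abundance_sigma: float = 0.5  # lognormal spread of baseline abundances
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains <= 0 or self.depth <= 0 or self.dispersion <= 0:
            raise ValueError("n_strains, depth and dispersion must be positive")
        ids = [s for s, _ in self.planted_resistors + self.planted_sensitives]
        if len(ids) != len(set(ids)):
            raise ValueError("planted strain ids must be unique")
        valid = set(self.strain_ids)
        if not set(ids) <= valid:
            raise ValueError("planted ids must be within the library")

    @property
    def strain_ids(self) -> list[str]:
        return [f"s{i:04d}" for i in range(self.n_strains)]


def simulate_screen_counts(config: ScreenSimConfig) -> CountTable:
    """NB-distributed strain × sample counts with planted effects."""
    rng = np.random.default_rng(config.seed)
    ids = config.strain_ids
    abund = rng.lognormal(0.0, config.abundance_sigma, config.n_strains)
    abund /= abund.sum()

    lfc = np.zeros(config.n_strains)
    index = {s: i for i, s in enumerate(ids)}
    for s, v in config.planted_resistors + config.planted_sensitives:
        lfc[index[s]] = v

    cols, data, cond = [], [], {}
    for condition, shift in (("control", 0.0), ("drug", 1.0)):
        base = abund * np.exp2(lfc * shift)
        mu = config.depth * base / base.sum()
        for r in range(config.n_reps):
            if config.dispersion < 1e-8:
                k = rng.poisson(mu)
            else:
                lam = rng.gamma(1.0 / config.dispersion, mu * config.dispersion)
                k = rng.poisson(lam)
            name = f"{condition}_{r + 1}"
            cols.append(name)
            data.append(k)
            cond[name] = condition
    counts = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)
    return CountTable(counts, pd.Series(cond))


def make_barcode_db(n: int, length: int = 20, min_dist: int = 3, seed: int = 0
                    ) -> list[SeqRecord]:
    """Random barcode FASTA records with pairwise Hamming distance >= min_dist."""
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    while len(chosen) < n:
        cand = rng.integers(0, 4, length)
        if all(int((cand != c).sum()) >= min_dist for c in chosen):
            chosen.append(cand)
    return [SeqRecord(Seq("".join(BASES[c])), id=f"s{i:04d}", description="")
            for i, c in enumerate(chosen)]


def simulate_screen_reads(counts, barcode_seqs: dict[str, str],
                          error_rate: float = 0.0, seed: int = 0) -> list[SeqRecord]:
    """FASTQ records embedding each barcode between the fixed flanks.

    ``counts``: mapping strain id -> read count (e.g. one CountTable
    column).  Per-base substitution errors are applied at ``error_rate``.
    """
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    unknown = set(counts.keys()) - set(barcode_seqs)
    if unknown:
        raise ValueError(f"unknown barcode ids in counts: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    reads: list[SeqRecord] = []
    i = 0
    for sid, n in counts.items():
        template = FLANK_5 + barcode_seqs[sid] + FLANK_3
        for _ in range(int(n)):
            seq = np.array(list(template))
            if error_rate > 0:
                hit = rng.random(len(seq)) < error_rate
                for j in np.nonzero(hit)[0]:
                    seq[j] = rng.choice(BASES[BASES != seq[j]])
            rec = SeqRecord(Seq("".join(seq)), id=f"read{i}", description="")
            rec.letter_annotations["phred_quality"] = [38] * len(seq)
            reads.append(rec)
            i += 1
    perm = rng.permutation(len(reads))
    return [reads[j] for j in perm]


# ---------------------------------------------------------------------------
# Growth curves under Hill inhibition


@dataclass
class GrowthSimConfig:
    """Logistic growth with dose-dependent Hill scaling.

    OD(t; d) = blank + K/(1+(d/ic50)^hill) * logistic(t), read every
    10 min for 18 h by default; ``rate`` in 1/h, ``lag`` in h.
    """

    carrying_capacity: float = 1.0
    rate: float = 0.8
    lag: float = 2.0
    ic50_true: float = 10.0
    hill: float = 2.0
    noise_sd: float = 0.0
    blank_od: float = 0.04
    t_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 18.0 * 60.0 + 1, 10.0))
    seed: int = 0

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if min(self.carrying_capacity, self.rate, self.ic50_true, self.hill) <= 0:
            raise ValueError("carrying_capacity, rate, ic50_true, hill must be positive")
        if self.lag < 0 or self.noise_sd < 0:
            raise ValueError("lag and noise_sd must be non-negative")
        if np.any(np.diff(self.t_grid) <= 0):
            raise ValueError("t_grid must be strictly increasing")


#: strain presets: inhibitory concentrations of the most sensitive (F-18)
#: and most resistant (BW25113) E. coli strains, with dose ranges bracketing
#: them on a 12-point 1.6-fold dilution series
STRAIN_PRESETS = {
    "F-18": {"ic50_true": 0.7, "hill": 2.0, "top_dose": 20.0},
    "BW25113": {"ic50_true": 103.0, "hill": 2.0, "top_dose": 2000.0},
}


def serial_dilution_doses(top: float, factor: float = 1.6, n: int = 12) -> np.ndarray:
    """``n``-point dose series: zero plus ``n - 1`` ``factor``-fold dilutions."""
    if top <= 0 or factor <= 1 or n < 2:
        raise ValueError("need top > 0, factor > 1, n >= 2")
    return np.concatenate([[0.0], top / factor ** np.arange(n - 2, -1, -1.0)])


def _logistic(t_min: np.ndarray, cfg: GrowthSimConfig) -> np.ndarray:
    od0 = 0.01 * cfg.carrying_capacity
    t = np.maximum(t_min / 60.0 - cfg.lag, 0.0)
    e = np.exp(cfg.rate * t)
    return cfg.carrying_capacity * od0 * e / (cfg.carrying_capacity + od0 * (e - 1.0))


def simulate_growth_curves(config: GrowthSimConfig, doses, replicates: int = 3,
                           n_blanks: int = 3, strain: str = "synthetic") -> PlateSeries:
    """Plate-reader series: one logistic curve per dose × replicate + blanks.

    The plateau (and the whole curve) is scaled by the Hill inhibition
    factor ``1/(1+(d/ic50_true)^hill)``, so the blank-subtracted relative
    growth at any timepoint equals that factor exactly when noise is 0.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    rng = np.random.default_rng(config.seed)
    base = _logistic(config.t_grid, config)
    rows, layout = [], []
    for d in doses:
        w = 1.0 / (1.0 + (d / config.ic50_true) ** config.hill)
        for r in range(replicates):
            well = f"d{d:g}_r{r + 1}"
            od = config.blank_od + w * base
            if config.noise_sd > 0:
                od = od + rng.normal(0.0, config.noise_sd, od.shape)
            rows.append(pd.DataFrame({"well": well, "time_min": config.t_grid,
                                      "od600": od}))
            layout.append({"well": well, "strain": strain, "dose_um": d,
                           "replicate": r + 1, "is_blank": False})
    for b in range(n_blanks):
        well = f"blank_{b + 1}"
        od = np.full_like(config.t_grid, config.blank_od)
        if config.noise_sd > 0:
            od = od + rng.normal(0.0, config.noise_sd, od.shape)
        rows.append(pd.DataFrame({"well": well, "time_min": config.t_grid,
                                  "od600": od}))
        layout.append({"well": well, "strain": "blank", "dose_um": np.nan,
                       "replicate": b + 1, "is_blank": True})
    return PlateSeries(pd.concat(rows, ignore_index=True), pd.DataFrame(layout))


# ---------------------------------------------------------------------------
# Spheroid plates


@dataclass
class SpheroidSimConfig:
    """Degradation-coupled spheroid plate.

    The effective dose seen by a spheroid co-cultured with bacteria at
    (scaled) level ``y`` is ``d_eff = d * exp(-degradation_coefficient*y)``:
    positive coefficients (degraders) shield the spheroid, negative ones
    (import-dead slow degraders are modelled upstream as coefficient <= 0
    relative to wild type) expose it.  Spheroid area follows a Hill
    response to ``d_eff``.
    """

    n_doses: int = 12
    n_bacteria: int = 8
    top_dose: float = 50.0
    dilution_factor_drug: float = 1.6
    degradation_coefficient: float = 0.0
    ec50_cell: float = 5.0
    hill: float = 1.5
    base_response: float = 0.1  # residual relative area at saturating drug
    growth_factor: float = 8.0  # week-long fold growth without drug
    t0_area: float = 6e4  # um^2 at time zero
    noise_sd: float = 0.0  # relative area noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_doses < 2 or self.n_bacteria < 2:
            raise ValueError("grid must be at least 2x2")
        if self.dilution_factor_drug <= 1:
            raise ValueError("dilution_factor_drug must be > 1")


def simulate_spheroid_plate(config: SpheroidSimConfig) -> SpheroidGrid:
    """Area grid [bacteria_level, dose] with degradation-shifted response."""
    rng = np.random.default_rng(config.seed)
    doses = serial_dilution_doses(config.top_dose, config.dilution_factor_drug,
                                  config.n_doses)
    levels = np.linspace(0.0, 1.0, config.n_bacteria)
    d_eff = doses[None, :] * np.exp(-config.degradation_coefficient * levels[:, None])
    resp = config.base_response + (1.0 - config.base_response) / (
        1.0 + (d_eff / config.ec50_cell) ** config.hill)
    t0 = config.t0_area * (1.0 + 0.05 * rng.standard_normal(resp.shape))
    end = t0 * config.growth_factor * resp
    if config.noise_sd > 0:
        end = end * np.maximum(1.0 + config.noise_sd * rng.standard_normal(resp.shape),
                               0.05)
    return SpheroidGrid(end, t0, doses_um=doses, bacteria_levels=levels)


# ---------------------------------------------------------------------------
# Fluctuation cultures


@dataclass
class FluctuationSimConfig:
    """Lea–Coulson fluctuation cultures with partial plating."""

    mu: float = 1e-7
    N0: float = 730.0
    Nt: float = 1e8
    epsilon: float = 1.0 / 40.0
    n_cultures: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError("epsilon must be in (0, 1]")
        if not (self.Nt > self.N0 > 0):
            raise ValueError("need Nt > N0 > 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


def simulate_fluctuation(config: FluctuationSimConfig) -> np.ndarray:
    """Observed mutant colonies per culture.

    Per culture: ``M ~ Poisson(m)`` mutational events with
    ``m = mu (Nt - N0)``; each event founds a clone of final size
    ``j = floor(1/U)`` (the exact inverse CDF of ``P(j) = 1/(j(j+1))``,
    via ``P(j >= k) = 1/k``), truncated at ``Nt``; plating keeps
    ``Binomial(j, epsilon)`` colonies of each clone.
    """
    rng = np.random.default_rng(config.seed)
    m = config.mu * (config.Nt - config.N0)
    counts = np.zeros(config.n_cultures, dtype=int)
    n_events = rng.poisson(m, config.n_cultures)
    for i, M in enumerate(n_events):
        if M == 0:
            continue
        u = rng.random(M)
        j = np.minimum(np.floor(1.0 / u), config.Nt).astype(np.int64)
        counts[i] = int(rng.binomial(j, config.epsilon).sum())
    return counts


# ---------------------------------------------------------------------------
# Conservation profiles and CDS mutations


def simulate_conservation(length: int, bias: float, n_mut: int, seed: int = 0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue 1–9 conservation scores + biased mutated positions.

    Positions are sampled without replacement with probability proportional
    to ``bias ** ((score - 1) / 8)``; ``bias = 1`` is unbiased, ``bias > 1``
    favors conserved residues.  Positions are 1-based.
    """
    if not (1 <= n_mut <= length):
        raise ValueError("need length >= n_mut >= 1")
    if bias <= 0:
        raise ValueError("bias must be positive")
    rng = np.random.default_rng(seed)
    scores = rng.integers(1, 10, length)
    w = bias ** ((scores - 1) / 8.0)
    pos = rng.choice(length, size=n_mut, replace=False, p=w / w.sum()) + 1
    return scores, np.sort(pos)


@dataclass(frozen=True)
class Substitution:
    pos: int  # 1-based nt position on the CDS
    base: str


@dataclass(frozen=True)
class Deletion:
    pos: int
    length: int


@dataclass(frozen=True)
class Insertion:
    pos: int
    seq: str


@dataclass(frozen=True)
class Transposon:
    pos: int
    element: str


def mutate_sequence(ref_cds: str, spec, seed: int = 0) -> str:
    """Apply one mutation descriptor to the reference CDS."""
    ref_cds = str(ref_cds).upper()
    if len(ref_cds) % 3 != 0:
        raise ValueError("ref_cds length must be divisible by 3")
    i = spec.pos - 1
    if isinstance(spec, Substitution):
        if not (0 <= i < len(ref_cds)):
            raise ValueError("substitution position out of range")
        return ref_cds[:i] + spec.base.upper() + ref_cds[i + 1:]
    if isinstance(spec, Deletion):
        if not (0 <= i and i + spec.length <= len(ref_cds)):
            raise ValueError("deletion out of range")
        return ref_cds[:i] + ref_cds[i + spec.length:]
    if isinstance(spec, (Insertion, Transposon)):
        ins = spec.seq if isinstance(spec, Insertion) else spec.element
        if not (0 <= i <= len(ref_cds)):
            raise ValueError("insertion position out of range")
        return ref_cds[:i] + ins.upper() + ref_cds[i:]
    raise TypeError(f"unknown mutation spec {type(spec).__name__}")


def expected_class(ref_cds: str, spec) -> str:
    """Mutation class the annotation stage should recover for ``spec``."""
    ref_cds = str(ref_cds).upper()
    if isinstance(spec, Substitution):
        i = spec.pos - 1
        if ref_cds[i] == spec.base.upper():
            return "none"
        ci = i // 3
        codon = ref_cds[ci * 3: ci * 3 + 3]
        mut = codon[: i % 3] + spec.base.upper() + codon[i % 3 + 1:]
        ref_aa, alt_aa = str(Seq(codon).translate()), str(Seq(mut).translate())
        if alt_aa == ref_aa:
            return "none"
        return "nonsense" if alt_aa == "*" else "missense"
    if isinstance(spec, Deletion):
        return "transposon/junction" if spec.length >= 30 else "indel"
    if isinstance(spec, Insertion):
        return "transposon/junction" if len(spec.seq) >= 30 else "indel"
    if isinstance(spec, Transposon):
        return "transposon/junction"
    raise TypeError(f"unknown mutation spec {type(spec).__name__}")


def random_cds(n_codons: int = 400, seed: int = 0) -> str:
    """Random CDS: ATG start, no internal stop codons, TAA stop."""
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(BASES, 3))
        if c not in stops:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def random_mutation_spec(ref_cds: str, rng: np.random.Generator):
    """Random single-mutation descriptor for round-trip testing.

    Positions keep 40 bp clear of the CDS ends (terminal events are
    soft-clipped by the free-end-gap alignment, as with real trimmed Sanger
    consensi) and transposon elements stay >= 350 bp from the 3' end so the
    full-length alignment dominates the clipped one.
    """
    n = len(ref_cds)
    kind = rng.choice(["sub", "del", "ins", "tn"], p=[0.5, 0.2, 0.2, 0.1])
    if kind == "sub":
        pos = int(rng.integers(40, n - 40)) + 1
        base = str(rng.choice(BASES[BASES != ref_cds[pos - 1]]))
        return Substitution(pos, base)
    if kind == "del":
        length = int(rng.integers(1, 7))
        pos = int(rng.integers(40, n - 40 - length)) + 1
        return Deletion(pos, length)
    if kind == "ins":
        length = int(rng.integers(1, 7))
        seq = "".join(rng.choice(BASES, length))
        pos = int(rng.integers(40, n - 40)) + 1
        return Insertion(pos, seq)
    element = "".join(rng.choice(BASES, 300))
    pos = int(rng.integers(50, max(n - 350, 51))) + 1
    return Transposon(pos, element)


# ---------------------------------------------------------------------------
# Breakdown-assay cohorts


def simulate_breakdown_cohort(n_fast: int = 10, n_slow: int = 23, n_null: int = 55,
                              effect_sd: float = 3.0, auc_mean: float = 2.0,
                              auc_sd: float = 0.15, n_ko_reps: int = 3,
                              n_wt_reps: int = 18, seed: int = 0) -> pd.DataFrame:
    """AUC table for a planted fast/slow/null degrader cohort.

    Fast degraders clear the drug before the 15-min sampling, so their
    conditioned buffer lets the reporter grow ``effect_sd`` standard
    deviations more than wild type at 15 min; slow degraders leave drug
    behind at 45 min, lowering the reporter AUC by the same amount.  The
    default 10/23/55 split of 88 strains mirrors a screen where a third of
    tested knockouts modulate degradation.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def add(strain, t, mean, n):
        for v in rng.normal(mean, auc_sd, n):
            rows.append({"strain": strain, "timepoint": t, "auc": float(v)})

    add("WT", 15, auc_mean, n_wt_reps)
    add("WT", 45, auc_mean, n_wt_reps)
    truth = {}
    k = 0
    for klass, n_strains, d15, d45 in (
            ("fast", n_fast, effect_sd * auc_sd, 0.0),
            ("slow", n_slow, 0.0, -effect_sd * auc_sd),
            ("none", n_null, 0.0, 0.0)):
        for _ in range(n_strains):
            sid = f"ko{k:03d}"
            truth[sid] = klass
            add(sid, 15, auc_mean + d15, n_ko_reps)
            add(sid, 45, auc_mean + d45, n_ko_reps)
            k += 1
    df = pd.DataFrame(rows)
    df.attrs["truth"] = truth
    return df
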