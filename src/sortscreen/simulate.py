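"""Synthetic pooled-screen generator with known ground truth.

The generative model mirrors the design of a FACS-sorted shRNA screen for a
surface reporter (membrane PD-L1):

1. Each gene is an *enhancer*, *suppressor*, *essential* or *null* gene;
   each hairpin has a knockdown efficiency drawn from a Beta distribution.
2. Hairpin abundance drifts from uniform by fitness:
   ``a_s ∝ exp(-fitness(gene) · kd_eff(s) · generations)`` (essential genes
   only), emulating dropout over passaging.
3. A cell's reporter is LogNormal: log-intensity ``~ Normal(μ0 + Δ(s), σ)``
   with ``Δ(s) = -effect_enh · kd_eff(s)`` for enhancer targets (knockdown
   lowers the reporter), ``+effect_sup · kd_eff(s)`` for suppressors.
4. Gate thresholds are quantiles of the abundance-weighted mixture giving
   the configured high / intermediate / low fractions; per-hairpin sort
   probabilities are exact Gaussian tail integrals on the log scale.
5. Sequencing counts are Dirichlet-Multinomial around the sorted-bin
   composition, so column totals are exact and overdispersion is explicit.

Optionally, the simulated counts are rendered as a multiplexed paired-end
FASTQ lane (stagger regions, per-sample barcodes on read 2, substitution
errors) so the deconvolution stage can be exercised end to end.
"""

from __future__ import annotations

import gzip
import io
import itertools
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.stats import norm

from .library_io import (
    CONTROL_GENE,
    SampleMeta,
    ScreenCounts,
    ShRNALibrary,
    ValidationError,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGT", "TGCA")

DEFAULT_ADAPTER5 = "CTTGTGGAAAGG"
DEFAULT_ADAPTER3 = "TTTTTGAATTCT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Study conditions for one synthetic screen.

    Defaults follow the screen design being emulated: ~1000× sequencing
    coverage, high gate 1–2% and intermediate gate 13–15% of sorted cells,
    32 nontargeting controls, single integration per cell, and time points
    at 3 / 13 / 20 days of selection (≈1 doubling per day).
    """

    n_genes: int = 1000
    shrnas_per_gene: int = 5
    n_controls: int = 32
    frac_enhancer: float = 0.04
    frac_suppressor: float = 0.025
    frac_essential: float = 0.05
    effect_size_enh: float = 1.5
    effect_size_sup: float = 1.5
    kd_efficiency_dist: tuple[float, float] = (2.0, 2.0)
    fitness_essential: float = 0.3
    reporter_sigma: float = 0.6
    gate_high: tuple[float, float] = (0.01, 0.02)
    gate_int: tuple[float, float] = (0.13, 0.15)
    gate_low_frac: float = 0.02
    coverage: float = 1000.0
    dispersion: float = 50000.0
    passages: Mapping[str, float] = field(
        default_factory=lambda: {"t0": 3.0, "t1": 13.0, "t2": 20.0}
    )
    # knockdown-phenotype onset: fraction of the full reporter shift
    # expressed at each time point (day-3 baseline precedes phenotype)
    effect_onset: Mapping[str, float] = field(
        default_factory=lambda: {"t0": 0.0, "t1": 1.0, "t2": 1.0}
    )
    n_cells_sorted: int = 18_000_000
    seq_len: int = 21
    max_mismatch: int = 3
    driver_frac: float = 0.136  # fraction of genes labelled cancer-driver
    # FASTQ rendering
    read_len: int = 100
    adapter5: str = DEFAULT_ADAPTER5
    adapter3: str = DEFAULT_ADAPTER3
    stagger_max: int = 7
    barcode_len: int = 6
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.coverage:
            raise ValidationError("coverage must be > 0")
        for name in ("frac_enhancer", "frac_suppressor", "frac_essential",
                     "gate_low_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.gate_high[1] + self.gate_int[1] + self.gate_low_frac >= 1:
            raise ValidationError("gate fractions must sum to < 1")
        if (self.frac_enhancer + self.frac_suppressor
                + self.frac_essential) > 1:
            raise ValidationError("class fractions must sum to <= 1")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        kwargs = dict(raw)
        for key in ("kd_efficiency_dist", "gate_high", "gate_int"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["passages"] = dict(self.passages)
        d["effect_onset"] = dict(self.effect_onset)
        return d


@dataclass
class SimTruth:
    """Planted ground truth: per-gene effect class, per-hairpin knockdown
    efficiency, and per-gene fitness penalty (essential genes only)."""

    gene_class: dict
    kd_eff: dict
    fitness: dict

    def genes_of_class(self, cls: str) -> list[str]:
        return sorted(g for g, c in self.gene_class.items() if c == cls)

    def to_frame(self, library: ShRNALibrary) -> pd.DataFrame:
        gene_of = library.gene_of()
        rows = []
        for sid in library.shrna_ids:
            g = gene_of[sid]
            rows.append(
                (sid, g,
                 self.gene_class.get(g, "control"),
                 self.kd_eff[sid],
                 self.fitness.get(g, 0.0))
            )
        return pd.DataFrame(
            rows, columns=["shrna_id", "gene", "gene_class", "kd_eff",
                           "fitness"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SimTruth":
        gene_class = {}
        fitness = {}
        for r in df.itertuples():
            if r.gene_class != "control":
                gene_class[r.gene] = r.gene_class
            if r.fitness:
                fitness[r.gene] = float(r.fitness)
        kd = dict(zip(df["shrna_id"], df["kd_eff"].astype(float)))
        return cls(gene_class, kd, fitness)


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

def _random_separated_seqs(rng: np.random.Generator, n: int, length: int,
                           min_dist: int, max_rounds: int = 200) -> np.ndarray:
    """n random DNA sequences with all pairwise Hamming distances >= min_dist.

    Rejection sampling: regenerate any row that clashes with an
    earlier-accepted row until the set is clash-free.
    """
    if 4 ** length < 10 * n or min_dist > length:
        raise ValidationError(
            f"cannot place {n} sequences of length {length} at pairwise "
            f"distance >= {min_dist}; increase the sequence length"
        )
    seqs = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    chunk = 512
    for _ in range(max_rounds):
        bad: set[int] = set()
        for start in range(0, n, chunk):
            block = seqs[start:start + chunk]
            # distances of this block against every earlier-or-equal row
            d = (block[:, None, :] != seqs[None, :start + len(block), :]).sum(2)
            ii, jj = np.nonzero(d < min_dist)
            for i, j in zip(ii, jj):
                gi = start + i
                if j < gi:  # clash with an earlier row: regenerate the later
                    bad.add(gi)
        if not bad:
            return seqs
        idx = np.fromiter(bad, dtype=np.int64)
        seqs[idx] = rng.integers(0, 4, size=(len(idx), length), dtype=np.uint8)
    raise ValidationError(
        f"could not satisfy the pairwise-distance constraint for {n} "
        f"sequences of length {length}; increase the sequence length"
    )


def simulate_library(config: SimConfig) -> tuple[ShRNALibrary, SimTruth]:
    """Generate a random library plus its planted ground truth.

    Sequences are kept at pairwise Hamming distance > 2·max_mismatch + 1 so
    that mismatch-tolerant matching is provably unambiguous: a read with at
    most max_mismatch errors is strictly closer to its source hairpin than
    to any other.
    """
    rng = np.random.default_rng([config.seed, 11])
    n_sh = config.n_genes * config.shrnas_per_gene + config.n_controls
    min_dist = 2 * config.max_mismatch + 2  # strict '>' on 2m+1
    seq_arr = _random_separated_seqs(rng, n_sh, config.seq_len, min_dist)
    seqs = ["".join(chr(b) for b in _BASES[row]) for row in seq_arr]

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    n_driver = int(round(config.driver_frac * config.n_genes))
    cat_order = rng.permutation(config.n_genes)
    gene_cat = {}
    for rank, gi in enumerate(cat_order):
        gene_cat[genes[gi]] = "driver" if rank < n_driver else "druggable"

    rows = []
    k = 0
    for g in genes:
        for j in range(config.shrnas_per_gene):
            rows.append((f"{g}.sh{j + 1}", g, seqs[k], gene_cat[g]))
            k += 1
    for j in range(config.n_controls):
        rows.append((f"NC{j + 1:03d}", CONTROL_GENE, seqs[k], "control"))
        k += 1
    library = ShRNALibrary(
        pd.DataFrame(rows, columns=["shrna_id", "gene", "sense_seq",
                                    "category"]),
        seq_len=config.seq_len,
    )

    n_enh = int(round(config.frac_enhancer * config.n_genes))
    n_sup = int(round(config.frac_suppressor * config.n_genes))
    n_ess = int(round(config.frac_essential * config.n_genes))
    perm = rng.permutation(config.n_genes)
    gene_class = {g: "null" for g in genes}
    for gi in perm[:n_enh]:
        gene_class[genes[gi]] = "enhancer"
    for gi in perm[n_enh:n_enh + n_sup]:
        gene_class[genes[gi]] = "suppressor"
    for gi in perm[n_enh + n_sup:n_enh + n_sup + n_ess]:
        gene_class[genes[gi]] = "essential"

    a, b = config.kd_efficiency_dist
    kd = rng.beta(a, b, size=n_sh)
    kd_eff = dict(zip(library.shrna_ids, kd))
    fitness = {g: config.fitness_essential
               for g, c in gene_class.items() if c == "essential"}
    return library, SimTruth(gene_class, kd_eff, fitness)


# ---------------------------------------------------------------------------
# screen generation
# ---------------------------------------------------------------------------

def _reporter_shifts(library: ShRNALibrary, truth: SimTruth,
                     config: SimConfig) -> np.ndarray:
    """Per-hairpin shift of the log-reporter mean."""
    gene_of = library.gene_of()
    shifts = np.zeros(len(library))
    for i, sid in enumerate(library.shrna_ids):
        g = gene_of[sid]
        cls = truth.gene_class.get(g, "null")
        if cls == "enhancer":
            shifts[i] = -config.effect_size_enh * truth.kd_eff[sid]
        elif cls == "suppressor":
            shifts[i] = config.effect_size_sup * truth.kd_eff[sid]
    return shifts


def _abundance(library: ShRNALibrary, truth: SimTruth,
               generations: float) -> np.ndarray:
    gene_of = library.gene_of()
    fit = np.array([
        truth.fitness.get(gene_of[sid], 0.0) * truth.kd_eff[sid]
        for sid in library.shrna_ids
    ])
    a = np.exp(-fit * generations)
    return a / a.sum()


def _mixture_quantile(q: float, weights: np.ndarray, means: np.ndarray,
                      sigma: float) -> float:
    """Quantile of the abundance-weighted Gaussian mixture on the log scale."""

    lo = means.min() - 8 * sigma
    hi = means.max() + 8 * sigma

    def cdf_minus_q(x: float) -> float:
        return float(weights @ norm.cdf((x - means) / sigma)) - q

    return brentq(cdf_minus_q, lo, hi, xtol=1e-12)


def gate_probabilities(abundance: np.ndarray, shifts: np.ndarray,
                       sigma: float, f_low: float, f_int: float,
                       f_high: float) -> pd.DataFrame:
    """Exact per-hairpin probabilities of sorting into each FACS gate.

    Thresholds are quantiles of the mixture reporter distribution chosen so
    the population fractions in the low / intermediate / high gates equal
    the requested values; individual probabilities are Gaussian tail
    integrals, so low + intermediate + high + unsorted-remainder == 1.
    """
    x_low = _mixture_quantile(f_low, abundance, shifts, sigma)
    x_int = _mixture_quantile(1 - f_high - f_int, abundance, shifts, sigma)
    x_high = _mixture_quantile(1 - f_high, abundance, shifts, sigma)
    z = lambda x: (x - shifts) / sigma  # noqa: E731
    p_low = norm.cdf(z(x_low))
    p_int = norm.cdf(z(x_high)) - norm.cdf(z(x_int))
    p_high = norm.sf(z(x_high))
    rest = 1.0 - p_low - p_int - p_high
    return pd.DataFrame({
        "low": p_low, "intermediate": p_int, "high": p_high, "rest": rest,
    })


def _dirichlet_multinomial(rng: np.random.Generator, total: int,
                           composition: np.ndarray,
                           concentration: float) -> np.ndarray:
    """Multinomial draw around a Dirichlet-perturbed composition.

    Concentration parameter of the Dirichlet is ``concentration *
    composition``; zero-composition categories stay exactly zero.
    """
    alpha = concentration * composition
    g = np.zeros_like(composition)
    pos = alpha > 0
    g[pos] = rng.gamma(alpha[pos])
    if g.sum() == 0:
        raise ValidationError("empty gate: all sort probabilities are zero")
    return rng.multinomial(total, g / g.sum())


def simulate_screen(library: ShRNALibrary, truth: SimTruth,
                    config: SimConfig) -> ScreenCounts:
    """Simulate sequencing counts for every (timepoint, population) sample.

    Sorted bins exist at every time point; unsorted pools at t0 and t2 only,
    matching the screen design. Per-sample total reads = coverage × library
    size.
    """
    rng = np.random.default_rng([config.seed, 22])
    shifts = _reporter_shifts(library, truth, config)
    total_reads = int(round(config.coverage * len(library)))
    n_cells = config.n_cells_sorted

    columns: dict[str, np.ndarray] = {}
    samples: list[SampleMeta] = []
    for tp, gens in config.passages.items():
        a = _abundance(library, truth, gens)
        f_high = rng.uniform(*config.gate_high)
        f_int = rng.uniform(*config.gate_int)
        f_low = config.gate_low_frac
        onset = config.effect_onset.get(tp, 1.0)
        gates = gate_probabilities(a, onset * shifts, config.reporter_sigma,
                                   f_low, f_int, f_high)
        for pop, frac in (("low", f_low), ("intermediate", f_int),
                          ("high", f_high)):
            comp = a * gates[pop].to_numpy()
            s = comp.sum()
            if s <= 0:
                raise ValidationError(f"empty gate {pop} at {tp}")
            comp /= s
            sid = f"{tp}_{pop}"
            columns[sid] = _dirichlet_multinomial(
                rng, total_reads, comp, config.dispersion)
            samples.append(SampleMeta(sid, tp, pop, total_reads,
                                      max(1, int(round(frac * n_cells)))))
        if tp in ("t0", "t2"):
            sid = f"{tp}_unsorted"
            columns[sid] = _dirichlet_multinomial(
                rng, total_reads, a, config.dispersion)
            samples.append(SampleMeta(sid, tp, "unsorted", total_reads,
                                      n_cells))
    matrix = pd.DataFrame(columns, index=library.shrna_ids).astype(np.int64)
    matrix.index.name = "shrna_id"
    return ScreenCounts(matrix, samples, library)


# ---------------------------------------------------------------------------
# FASTQ rendering
# ---------------------------------------------------------------------------

def _open_write(path):
    path = str(path)
    if path.endswith(".gz"):
        # fixed mtime so identical content is byte-identical on disk
        return io.TextIOWrapper(gzip.GzipFile(path, "wb", mtime=0),
                                encoding="ascii")
    return open(path, "w")


def assign_barcodes(sample_ids, barcode_len: int,
                    rng: np.random.Generator) -> dict:
    """Distinct per-sample barcodes at pairwise Hamming distance >= 2."""
    codes: dict[str, str] = {}
    chosen: list[str] = []
    for sid in sample_ids:
        for _ in range(10000):
            bc = "".join("ACGT"[i] for i in rng.integers(0, 4, barcode_len))
            if all(sum(a != b for a, b in zip(bc, c)) >= 2 for c in chosen):
                chosen.append(bc)
                codes[sid] = bc
                break
        else:  # pragma: no cover
            raise ValidationError("cannot assign distinct barcodes")
    return codes


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for p in pos:
        options = [b for b in "ACGT" if b != chars[p]]
        chars[p] = options[rng.integers(0, 3)]
    return "".join(chars)


def emit_fastq(counts: ScreenCounts, library: ShRNALibrary, config: SimConfig,
               r1_path, r2_path) -> dict:
    """Render counts as one multiplexed paired-end lane.

    Read 1: stagger (length cycling 0..stagger_max) + adapter5 + sense
    hairpin + adapter3, padded to read_len — the stagger shifts the
    adapter, maintaining base diversity in the first sequencing cycles.
    Read 2: sample barcode + stagger + adapter5 + reverse-complement
    hairpin + adapter3, padded.
    Substitution errors are injected at ``config.error_rate`` per base.
    Returns the sample -> barcode map.
    """
    rng = np.random.default_rng([config.seed, 33])
    barcodes = assign_barcodes(counts.matrix.columns, config.barcode_len, rng)
    seq_of = library.table.set_index("shrna_id")["sense_seq"]
    stagger_cycle = itertools.cycle(range(config.stagger_max + 1))
    qual = "I" * config.read_len

    def pad(s: str) -> str:
        if len(s) < config.read_len:
            s = s + "A" * (config.read_len - len(s))
        return s[: config.read_len]

    with _open_write(r1_path) as f1, _open_write(r2_path) as f2:
        ridx = 0
        for sid in counts.matrix.columns:
            bc = barcodes[sid]
            col = counts.matrix[sid]
            for shrna, c in col.items():
                sense = seq_of[shrna]
                anti_rc = revcomp(sense)
                for _ in range(int(c)):
                    ridx += 1
                    st1 = next(stagger_cycle)
                    st2 = next(stagger_cycle)
                    stag1 = "".join(
                        "ACGT"[i] for i in rng.integers(0, 4, st1))
                    stag2 = "".join(
                        "ACGT"[i] for i in rng.integers(0, 4, st2))
                    r1 = pad(stag1 + config.adapter5 + sense + config.adapter3)
                    r2 = pad(bc + stag2 + config.adapter5 + anti_rc
                             + config.adapter3)
                    r1 = _mutate(r1, rng, config.error_rate)
                    r2 = _mutate(r2, rng, config.error_rate)
                    name = f"read{ridx}"
                    f1.write(f"@{name}/1\n{r1}\n+\n{qual}\n")
                    f2.write(f"@{name}/2\n{r2}\n+\n{qual}\n")
    return barcodes


# ---------------------------------------------------------------------------
# survival cohort generation
# ---------------------------------------------------------------------------

def simulate_cohort(n: int = 300, cut_quantile: float = 0.4,
                    hazard_ratio: float = 3.0, baseline_hazard: float = 0.08,
                    censor_hazard: float = 0.03,
                    seed: int = 0) -> pd.DataFrame:
    """Synthetic patient cohort with a planted threshold effect.

    Expression is standard normal; patients above its ``cut_quantile``
    quantile have their event hazard multiplied by ``hazard_ratio``
    (high expression = worse outcome). Exponential event and censoring
    times; returns columns patient, expr, time, event.
    """
    rng = np.random.default_rng([seed, 44])
    expr = rng.normal(size=n)
    thr = np.quantile(expr, cut_quantile)
    hazard = np.where(expr > thr, baseline_hazard * hazard_ratio,
                      baseline_hazard)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / censor_hazard, size=n)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    return pd.DataFrame({
        "patient": [f"P{i:04d}" for i in range(n)],
        "expr": expr,
        "time": np.round(time, 6) + 1e-6,
        "event": event.astype(int),
    })
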