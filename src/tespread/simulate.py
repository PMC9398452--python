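"""Synthetic data generator with known ground truth.

Emulates the statistical structure the pipeline assumes so that every
downstream estimator can be tested against truth:

* annotations — TEs and genes packed without overlap on one or more
  chromosomes, with a euchromatin boundary file covering the chromosomes;
* coverage — per-25-bp-bin input coverage around a configurable mean and
  ChIP coverage whose spike-in-normalized ratio has, in expectation, the
  background HMD (~1) plus an exponential-decay excess A * exp(-d / lambda)
  with distance d from the nearest TE boundary.  Per-TE amplitudes are
  drawn lognormal around the configured mean so TEs differ in their true
  effect.  On a TE side that faces the promoter of a highly expressed gene
  (true RPKM >= 10) the decay length is multiplied by a restraint factor
  between the TE edge and that promoter, mimicking transcription-limited
  spreading;
* spike-in barcode counts consistent with the configured ChIP/input ratio;
* expression — true per-gene RPKM (lognormal) observed in two noisy
  replicates;
* population evidence — per-strain presence/absence with contig alignments
  whose geometry satisfies the caller's rules, plus an optional fraction of
  strains with degraded evidence exercising the missing-data path.

Counts are Poisson by default; ``noise_dispersion`` > 0 switches to a
gamma-Poisson (negative binomial) mixture.  A fixed seed makes every
output bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import TeRecord
from .genes import GeneRecord
from .popfreq import ContigAlignment

HIGH_RPKM = 10.0
RESTRAINT_RANGE = 20_000  # bp; promoters farther than this exert no restraint

_FAMILIES = [
    ("roo", "LTR"), ("297", "LTR"), ("copia", "LTR"),
    ("jockey", "non-LTR/LINE"), ("Doc", "non-LTR/LINE"), ("Cr1a", "non-LTR/LINE"),
    ("pogo", "TIR/DNA"), ("1360", "TIR/DNA"), ("H", "TIR/DNA"),
]


class CapacityError(ValueError):
    """Requested elements do not fit in the configured genome."""


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 2_000_000          # bp per chromosome
    n_chromosomes: int = 1
    n_tes: int = 15
    te_length_range: tuple[int, int] = (500, 5000)
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (1000, 3000)
    min_gap: int = 0                        # bp enforced between adjacent elements
    spread_amplitude: float = 2.0           # mean HMD excess at the TE boundary
    amplitude_cv: float = 0.5               # between-TE variation of the amplitude
    decay_length: float = 2000.0            # bp
    genic_restraint_factor: float = 0.5     # multiplier on lambda toward a busy promoter
    background_hmd: float = 1.0
    noise_dispersion: float = 0.0           # 0 = Poisson counts
    mean_input_coverage: float = 25.0       # fragments per bin
    spikein_ratio: float = 1.0              # E_si: barcode fragments ChIP/input
    mean_barcode_fragments: float = 400.0   # input-library spike-in depth
    bin_size: int = 25
    # population-evidence parameters
    n_strains: int = 20
    high_frequency_fraction: float = 0.5    # fraction of TEs segregating in the population
    presence_prob: float = 0.3              # per-strain presence prob for segregating TEs
    degraded_fraction: float = 0.0          # strains with unusable evidence
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome dimensions must be positive")
        if self.spread_amplitude < 0:
            raise ValueError("spread_amplitude must be >= 0")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be > 0")
        if not 0 < self.genic_restraint_factor <= 1:
            raise ValueError("genic_restraint_factor must be in (0, 1]")
        if self.mean_input_coverage <= 0 or self.spikein_ratio <= 0:
            raise ValueError("coverage parameters must be positive")
        if self.background_hmd <= 0:
            raise ValueError("background_hmd must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth for every simulated element."""

    te_table: pd.DataFrame      # te_id, amplitude, true_magnitude, freq_class
    gene_table: pd.DataFrame    # gene_id, true_rpkm
    strain_states: pd.DataFrame | None = None  # te_id x strain presence states


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _chrom_names(config: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chromosomes)]


def generate_annotations(
    config: SimulationConfig,
) -> tuple[list[TeRecord], list[GeneRecord], pd.DataFrame]:
    """Non-overlapping TE and gene placement plus euchromatin boundaries.

    Elements are distributed round-robin over chromosomes and packed by
    stick-breaking of the free space, so intervals are sorted and disjoint
    by construction.  Raises CapacityError when the requested elements
    exceed genome capacity.
    """
    rng = _rng(config, 0)
    chroms = _chrom_names(config)
    n_total = config.n_tes + config.n_genes
    kinds = ["te"] * config.n_tes + ["gene"] * config.n_genes
    rng.shuffle(kinds)
    per_chrom: dict[str, list[str]] = {c: [] for c in chroms}
    for i, kind in enumerate(kinds):
        per_chrom[chroms[i % len(chroms)]].append(kind)

    tes: list[TeRecord] = []
    genes: list[GeneRecord] = []
    te_i = gene_i = 0
    for chrom in chroms:
        items = per_chrom[chrom]
        lengths = []
        for kind in items:
            lo, hi = config.te_length_range if kind == "te" else config.gene_length_range
            lengths.append(int(rng.integers(lo, hi + 1)))
        margin = 100  # keep elements off the extreme chromosome ends
        reserved = config.min_gap * (len(items) + 1)
        free = config.genome_length - sum(lengths) - 2 * margin - reserved
        if free < len(items) + 1:
            raise CapacityError(
                f"{len(items)} elements totalling {sum(lengths)} bp do not fit in "
                f"{config.genome_length} bp on {chrom}"
            )
        gaps = rng.dirichlet(np.ones(len(items) + 1)) * free
        gaps = np.maximum(np.floor(gaps).astype(int), 1) + config.min_gap
        pos = margin
        for kind, length, gap in zip(items, lengths, gaps):
            pos += int(gap)
            start, end = pos, pos + length
            # snap to the bin grid so windows align with track bins
            start = (start // config.bin_size) * config.bin_size
            end = start + ((length // config.bin_size) or 1) * config.bin_size
            if kind == "te":
                te_i += 1
                family, te_class = _FAMILIES[int(rng.integers(len(_FAMILIES)))]
                tes.append(
                    TeRecord(f"te{te_i:04d}", chrom, start, end, te_class=te_class, family=family)
                )
            else:
                gene_i += 1
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneRecord(f"g{gene_i:04d}", chrom, start, end, strand=strand))
            pos = end
        if pos > config.genome_length:
            raise CapacityError(f"packing overran {chrom}")

    # true expression: lognormal RPKM, observed in two noisy replicates
    if genes:
        true_rpkm = rng.lognormal(mean=np.log(8.0), sigma=1.5, size=len(genes))
        for g, r in zip(genes, true_rpkm):
            noise = rng.lognormal(0, 0.05, size=2)
            g.rpkm_rep1 = float(r * noise[0])
            g.rpkm_rep2 = float(r * noise[1])
            g.rpkm_mean = (g.rpkm_rep1 + g.rpkm_rep2) / 2

    boundaries = pd.DataFrame(
        {"chrom": chroms, "start": 0, "end": config.genome_length}
    )
    return tes, genes, boundaries


# ---------------------------------------------------------------------------
# coverage


def _true_amplitudes(config: SimulationConfig, n: int) -> np.ndarray:
    """Per-TE boundary amplitudes, lognormal with the configured mean/CV."""
    if config.spread_amplitude == 0 or n == 0:
        return np.zeros(n)
    if config.amplitude_cv == 0:
        return np.full(n, config.spread_amplitude)
    rng = _rng(config, 1)
    sigma = np.sqrt(np.log1p(config.amplitude_cv**2))
    mu = np.log(config.spread_amplitude) - sigma**2 / 2
    return rng.lognormal(mu, sigma, size=n)


def _side_decay_profile(
    config: SimulationConfig, amplitude: float, d: np.ndarray, promoter_distance: float | None
) -> np.ndarray:
    """Expected HMD excess at distances d from a TE edge on one side.

    With a busy promoter at ``promoter_distance``, the decay length is
    shortened by the restraint factor between the edge and the promoter;
    beyond it the decay continues at the unrestrained rate from the value
    reached at the promoter (continuous profile).
    """
    lam = config.decay_length
    if promoter_distance is None or config.genic_restraint_factor == 1.0:
        return amplitude * np.exp(-d / lam)
    lam_r = lam * config.genic_restraint_factor
    out = np.where(
        d <= promoter_distance,
        amplitude * np.exp(-d / lam_r),
        amplitude * np.exp(-promoter_distance / lam_r) * np.exp(-(d - promoter_distance) / lam),
    )
    return out


def _promoter_distances(
    te: TeRecord, genes: list[GeneRecord]
) -> tuple[float | None, float | None]:
    """Distance from each TE edge to the nearest busy promoter it faces.

    Returns (left, right): distance to the promoter (TSS) of the nearest
    gene with true RPKM >= 10 on that side, or None when no such promoter
    exists within RESTRAINT_RANGE of the edge (spreading never reaches a
    promoter tens of kb away, so distant genes exert no restraint).
    """
    left = right = None
    for g in genes:
        if g.chrom != te.chrom or g.rpkm_mean is None or g.rpkm_mean < HIGH_RPKM:
            continue
        if g.tss <= te.start:
            d = te.start - g.tss
            if d <= RESTRAINT_RANGE:
                left = d if left is None else min(left, d)
        elif g.tss >= te.end:
            d = g.tss - te.end
            if d <= RESTRAINT_RANGE:
                right = d if right is None else min(right, d)
    return left, right


def expected_hmd(
    tes: list[TeRecord],
    genes: list[GeneRecord],
    config: SimulationConfig,
    amplitudes: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Noise-free expected HMD per bin and chromosome."""
    if amplitudes is None:
        amplitudes = _true_amplitudes(config, len(tes))
    bs = config.bin_size
    n_bins = config.genome_length // bs
    reach = int(12 * config.decay_length // bs) + 1  # beyond this exp() is negligible
    out = {c: np.full(n_bins, config.background_hmd) for c in _chrom_names(config)}
    for te, amp in zip(tes, amplitudes):
        arr = out[te.chrom]
        sb, eb = te.start // bs, te.end // bs
        arr[sb:eb] = config.background_hmd + amp  # silenced TE body
        left_prom, right_prom = _promoter_distances(te, genes)
        # left flank: bin centers at distance (off + 0.5) * bs from the edge
        lo = max(sb - reach, 0)
        if lo < sb:
            d = (np.arange(sb - lo) + 0.5) * bs
            arr[lo:sb] += _side_decay_profile(config, amp, d, left_prom)[::-1]
        hi = min(eb + reach, n_bins)
        if hi > eb:
            d = (np.arange(hi - eb) + 0.5) * bs
            arr[eb:hi] += _side_decay_profile(config, amp, d, right_prom)
    return out


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
        return rng.poisson(lam)
    return rng.poisson(mean)


@dataclass
class CoverageSet:
    """One replicate's simulated fragment coverage and spike-in counts."""

    chip: dict[str, np.ndarray]
    input: dict[str, np.ndarray]
    chip_barcode: int
    input_barcode: int
    bin_size: int


def simulate_coverage(
    tes: list[TeRecord],
    genes: list[GeneRecord],
    config: SimulationConfig,
    replicate: int = 1,
    amplitudes: np.ndarray | None = None,
) -> CoverageSet:
    """Simulate one ChIP/input replicate.

    Input coverage is drawn around ``mean_input_coverage`` per bin; ChIP
    coverage around ``mean_input_coverage * expected_HMD * spikein_ratio``,
    so that (chip/input)/E_si has the expected HMD as its mean.  Spike-in
    barcode counts are drawn consistent with ``spikein_ratio``.
    """
    exp_hmd = expected_hmd(tes, genes, config, amplitudes)
    rng = _rng(config, 100 + replicate)
    chip, inp = {}, {}
    for chrom, h in exp_hmd.items():
        inp[chrom] = _draw_counts(rng, np.full_like(h, config.mean_input_coverage), config.noise_dispersion)
        chip[chrom] = _draw_counts(
            rng, config.mean_input_coverage * h * config.spikein_ratio, config.noise_dispersion
        )
    input_barcode = max(1, int(rng.poisson(config.mean_barcode_fragments)))
    chip_barcode = max(1, int(rng.poisson(config.mean_barcode_fragments * config.spikein_ratio)))
    return CoverageSet(chip, inp, chip_barcode, input_barcode, config.bin_size)


# ---------------------------------------------------------------------------
# truth


def true_magnitude(
    te: TeRecord, genes: list[GeneRecord], config: SimulationConfig, amplitude: float
) -> float:
    """Noise-free per-TE magnitude: median expected m-HMD of the first 1-kb
    windows, averaged over the two sides."""
    bs = config.bin_size
    n = 1000 // bs
    d = (np.arange(n) + 0.5) * bs
    left_prom, right_prom = _promoter_distances(te, genes)
    sides = []
    for prom in (left_prom, right_prom):
        excess = _side_decay_profile(config, amplitude, d, prom)
        sides.append(np.median(config.background_hmd + excess) / config.background_hmd)
    return float(np.mean(sides))


def expected_extent(
    config: SimulationConfig,
    amplitude: float | None = None,
    n_mc: int = 400,
    n_windows: int = 20,
    seed: int | None = None,
) -> float:
    """Monte-Carlo expected extent (kb) under the generator's noise model.

    Directly simulates, window by window, the median of 40 per-bin HMD
    values (counts drawn exactly as in ``simulate_coverage``) normalized by
    a simulated 20-40-kb background median, and returns the mean length of
    the initial run of windows whose median exceeds 1.  This is the
    generator's own account of what the estimator should recover — it does
    not run the estimation pipeline.
    """
    if amplitude is None:
        amplitude = config.spread_amplitude
    rng = np.random.default_rng(config.seed + 7_000_000 if seed is None else seed)
    bs = config.bin_size
    per_window = 1000 // bs
    n_bg = 2 * (20_000 // bs)
    mean_in = config.mean_input_coverage
    r = config.spikein_ratio
    runs = np.zeros(n_mc)
    d_all = (np.arange(n_windows * per_window) + 0.5) * bs
    h_all = config.background_hmd + amplitude * np.exp(-d_all / config.decay_length)
    for m in range(n_mc):
        inp_bg = _draw_counts(rng, np.full(n_bg, mean_in), config.noise_dispersion)
        chip_bg = _draw_counts(
            rng, np.full(n_bg, mean_in * config.background_hmd * r), config.noise_dispersion
        )
        ok = inp_bg >= 5
        bg = np.median(chip_bg[ok] / inp_bg[ok] / r)
        inp = _draw_counts(rng, np.full_like(h_all, mean_in), config.noise_dispersion)
        chip = _draw_counts(rng, mean_in * h_all * r, config.noise_dispersion)
        run = 0
        for k in range(n_windows):
            sl = slice(k * per_window, (k + 1) * per_window)
            okw = inp[sl] >= 5
            if okw.sum() < 10:
                break
            mhmd = np.median(chip[sl][okw] / inp[sl][okw] / r) / bg
            if mhmd <= 1:
                break
            run += 1
        runs[m] = run
    return float(runs.mean())


def build_truth(
    tes: list[TeRecord],
    genes: list[GeneRecord],
    config: SimulationConfig,
    amplitudes: np.ndarray | None = None,
    freq_classes: dict[str, str] | None = None,
) -> SyntheticTruth:
    if amplitudes is None:
        amplitudes = _true_amplitudes(config, len(tes))
    te_rows = [
        {
            "te_id": te.te_id,
            "amplitude": float(a),
            "true_magnitude": true_magnitude(te, genes, config, float(a)),
            "freq_class": (freq_classes or {}).get(te.te_id, "unknown"),
        }
        for te, a in zip(tes, amplitudes)
    ]
    gene_rows = [
        {"gene_id": g.gene_id, "true_rpkm": g.rpkm_mean if g.rpkm_mean is not None else 0.0}
        for g in genes
    ]
    return SyntheticTruth(
        te_table=pd.DataFrame(te_rows).set_index("te_id") if te_rows else pd.DataFrame(),
        gene_table=pd.DataFrame(gene_rows).set_index("gene_id") if gene_rows else pd.DataFrame(),
    )


# ---------------------------------------------------------------------------
# population evidence


def simulate_population(
    tes: list[TeRecord],
    config: SimulationConfig,
) -> tuple[dict[str, dict[str, list[ContigAlignment]]], pd.DataFrame]:
    """Per-strain contig-alignment evidence with known presence states.

    Each TE is first classed: with probability ``high_frequency_fraction``
    it segregates in the population (each strain present with
    ``presence_prob``, at least one forced present), otherwise it is a
    singleton of the focal strain (absent everywhere).  Evidence geometry:
    present strains get either two boundary contigs or one boundary contig
    plus an internal contig; absent strains get one contig spanning the TE
    with 25 bp margins; strains drawn into the degraded fraction get a
    single boundary contig, which satisfies no rule (missing).

    Returns ({te_id: {strain: [ContigAlignment]}}, truth frame of true
    per-strain states indexed by te_id).
    """
    rng = _rng(config, 2)
    strains = [f"strain{i + 1:02d}" for i in range(config.n_strains)]
    evidence: dict[str, dict[str, list[ContigAlignment]]] = {}
    rows = []
    for te in tes:
        s, e = te.start, te.end
        segregating = rng.random() < config.high_frequency_fraction
        if segregating:
            present = rng.random(config.n_strains) < config.presence_prob
            if not present.any():
                present[int(rng.integers(config.n_strains))] = True
        else:
            present = np.zeros(config.n_strains, dtype=bool)
        degraded = rng.random(config.n_strains) < config.degraded_fraction
        per_strain: dict[str, list[ContigAlignment]] = {}
        states = {}
        for strain, pres, degr in zip(strains, present, degraded):
            cid = f"{te.te_id}_{strain}"
            if degr:
                per_strain[strain] = [
                    ContigAlignment(cid + "_c1", te.chrom, s - 25, s + 35)
                ]
                states[strain] = "missing"
            elif pres:
                if rng.random() < 0.5:
                    per_strain[strain] = [
                        ContigAlignment(cid + "_c1", te.chrom, s - 25, s + 35),
                        ContigAlignment(cid + "_c2", te.chrom, e - 35, e + 25),
                    ]
                else:
                    mid = (s + e) // 2
                    per_strain[strain] = [
                        ContigAlignment(cid + "_c1", te.chrom, s - 25, s + 35),
                        ContigAlignment(
                            cid + "_c2", te.chrom, max(s, mid - 30), min(e, mid + 30)
                        ),
                    ]
                states[strain] = "present"
            else:
                per_strain[strain] = [
                    ContigAlignment(cid + "_c1", te.chrom, s - 25, e + 25)
                ]
                states[strain] = "absent"
        evidence[te.te_id] = per_strain
        rows.append({"te_id": te.te_id, **states})
    truth = pd.DataFrame(rows).set_index("te_id") if rows else pd.DataFrame()
    return evidence, truth


def population_evidence_to_frame(
    evidence: dict[str, dict[str, list[ContigAlignment]]]
) -> pd.DataFrame:
    """Flatten evidence to the TSV exchange format."""
    rows = []
    for te_id, per_strain in evidence.items():
        for strain, alns in per_strain.items():
            for a in alns:
                rows.append(
                    {
                        "te_id": te_id,
                        "strain": strain,
                        "contig": a.contig_id,
                        "chrom": a.chrom,
                        "start": a.start,
                        "end": a.end,
                    }
                )
    return pd.DataFrame(rows)
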