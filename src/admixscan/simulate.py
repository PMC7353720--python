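"""Forward-time two-way admixture simulator under the hybrid-isolation model.

A single admixture event founds the population ``t`` generations ago: each
founding haploid genome is African with probability ``m`` and European
otherwise, across all chromosomes.  Every subsequent generation is produced by
random mating of two distinct parents; each transmitted chromosome is a
recombinant of the parent's two haplotypes with a Poisson(length-in-Morgans)
number of crossovers at uniform genetic positions (Haldane's model, no
interference).  No further gene flow occurs after founding.

Optional two-locus epistatic selection acts on offspring viability: a proposed
offspring with identical diploid ancestry dosage at the two selected loci has
relative fitness 1 + s versus 1, implemented by rejection sampling (accept
with probability w / (1 + s)).  This is the simulator's own generative model
of fitness epistasis; the scan only ever detects its signature.

Under this model the expected ancestry correlation between loci at genetic
distance d Morgans without selection is (1 - d)^t ~ exp(-t d), the admixture
linkage-disequilibrium decay that the scan fits and subtracts.

RNG contract: a single ``numpy.random.Generator`` seeded from the config
drives every draw in a fixed documented order (per offspring: parent pair,
then per chromosome the crossover count, crossover positions and starting
haplotype, then one acceptance uniform when selection is active), so identical
config + seed gives bit-identical output.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass
from itertools import chain

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import BinManifest, LocalAncestryMatrix, MANIFEST_COLUMNS

EUR = 0
AFR = 1

# A haplotype is (ends, ancestries): tract k covers [ends[k-1], ends[k]) in cM
# (ends[-1] == chromosome length); ancestries[k] in {EUR, AFR}; adjacent
# tracts differ in ancestry.
Haplotype = tuple[list[float], list[int]]


@dataclass(frozen=True)
class EpistasisConfig:
    """Two-locus viability selection: loci at cM positions on one chromosome."""

    chrom: str
    locus_i_cM: float
    locus_j_cM: float
    s_selection: float


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated admixed cohort.

    chromosomes: per chromosome (length_morgans, length_bp); chromosome names
    are "1", "2", ... in list order.  The cM<->bp map is linear per
    chromosome.
    """

    n_individuals: int
    t_generations: int
    m_admixture: float
    chromosomes: tuple[tuple[float, int], ...]
    bin_size_bp: int = 400_000
    epistasis: EpistasisConfig | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ConfigError("n_individuals must be >= 2")
        if self.t_generations < 0:
            raise ConfigError("t_generations must be >= 0")
        if not (0.0 <= self.m_admixture <= 1.0):
            raise ConfigError("m_admixture must be in [0, 1]")
        if self.bin_size_bp <= 0:
            raise ConfigError("bin_size_bp must be positive")
        if not self.chromosomes:
            raise ConfigError("at least one chromosome required")
        for morgans, bp in self.chromosomes:
            if morgans <= 0 or bp <= 0:
                raise ConfigError("chromosome lengths must be positive")
        epi = self.epistasis
        if epi is not None:
            if epi.s_selection < 0:
                raise ConfigError("s_selection must be >= 0")
            names = [str(c + 1) for c in range(len(self.chromosomes))]
            if str(epi.chrom) not in names:
                raise ConfigError(f"epistasis chromosome {epi.chrom!r} not simulated")
            idx = names.index(str(epi.chrom))
            length_cM = self.chromosomes[idx][0] * 100.0
            for pos in (epi.locus_i_cM, epi.locus_j_cM):
                if not (0.0 <= pos <= length_cM):
                    raise ConfigError(
                        f"epistasis locus {pos} cM outside chromosome span "
                        f"[0, {length_cM}] cM"
                    )


class TractCollection:
    """Ground-truth ancestry tracts for every haplotype of every individual.

    ``haplotypes[c][h]`` is the Haplotype of haplotype h (individual h // 2)
    on chromosome index c.
    """

    def __init__(self, haplotypes: list[list[Haplotype]], lengths_cM: list[float]):
        self.haplotypes = haplotypes
        self.lengths_cM = lengths_cM

    @property
    def n_individuals(self) -> int:
        return len(self.haplotypes[0]) // 2

    def ancestry_at(self, chrom_idx: int, hap_idx: int, positions_cM: np.ndarray) -> np.ndarray:
        """Ancestry of one haplotype at the given cM positions."""
        ends, anc = self.haplotypes[chrom_idx][hap_idx]
        ends_arr = np.asarray(ends)
        anc_arr = np.asarray(anc, dtype=np.int8)
        idx = np.searchsorted(ends_arr, positions_cM, side="right")
        idx = np.minimum(idx, len(ends_arr) - 1)
        return anc_arr[idx]

    def dosage_at(self, chrom_idx: int, positions_cM: np.ndarray) -> np.ndarray:
        """Diploid AFR dosage (n_individuals x n_positions) at cM positions."""
        n = self.n_individuals
        out = np.empty((n, len(positions_cM)), dtype=np.int8)
        for i in range(n):
            out[i] = self.ancestry_at(chrom_idx, 2 * i, positions_cM) + self.ancestry_at(
                chrom_idx, 2 * i + 1, positions_cM
            )
        return out

    def switch_counts(self, chrom_idx: int) -> np.ndarray:
        """Number of ancestry switches (tract boundaries) per haplotype."""
        return np.array(
            [len(ends) - 1 for ends, _ in self.haplotypes[chrom_idx]], dtype=int
        )

    def to_tsv(self, path, sample_ids: list[str] | None = None) -> None:
        rows = []
        for c, haps in enumerate(self.haplotypes):
            chrom = str(c + 1)
            for h, (ends, anc) in enumerate(haps):
                sid = sample_ids[h // 2] if sample_ids else f"ind{h // 2:05d}"
                hap_id = f"{sid}.{h % 2}"
                start = 0.0
                for e, a in zip(ends, anc):
                    rows.append(
                        (hap_id, chrom, start, e, "AFR" if a == AFR else "EUR")
                    )
                    start = e
        pd.DataFrame(
            rows, columns=["haplotype_id", "chrom", "start_cM", "end_cM", "ancestry"]
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def expected_null_correlation(t: int, d_cM: float) -> float:
    """Model ancestry correlation (1 - d)^t at genetic distance d (given in cM).

    This is the hybrid-isolation admixture-LD decay used as the simulator's
    ground truth; d is converted to Morgans internally and the correlation is
    0 beyond 1 Morgan where (1 - d) would go negative.
    """
    if t < 0 or d_cM < 0:
        raise ConfigError("t and d must be non-negative")
    d_morgans = d_cM / 100.0
    if d_morgans >= 1.0:
        return 0.0
    return float((1.0 - d_morgans) ** t)


def _splice(
    ends_out: list[float],
    anc_out: list[int],
    ends: list[float],
    anc: list[int],
    a: float,
    b: float,
) -> None:
    """Append the tracts of (ends, anc) restricted to [a, b), merging equal neighbours."""
    i = bisect.bisect_right(ends, a)
    if i >= len(ends):
        i = len(ends) - 1
    while True:
        e = ends[i]
        seg_end = e if e < b else b
        code = anc[i]
        if anc_out and anc_out[-1] == code:
            ends_out[-1] = seg_end
        else:
            ends_out.append(seg_end)
            anc_out.append(code)
        if e >= b:
            return
        i += 1


def _meiosis(hap_a: Haplotype, hap_b: Haplotype, length_cM: float, rng) -> Haplotype:
    """One recombinant gamete: Poisson(length in Morgans) crossovers at uniform cM."""
    n_x = rng.poisson(length_cM / 100.0)
    cur = int(rng.integers(2))
    haps = (hap_a, hap_b)
    if n_x == 0:
        ends, anc = haps[cur]
        return list(ends), list(anc)
    xs = np.sort(rng.random(n_x)) * length_cM
    ends_out: list[float] = []
    anc_out: list[int] = []
    prev = 0.0
    for x in chain(xs.tolist(), (length_cM,)):
        if x > prev:
            _splice(ends_out, anc_out, *haps[cur], prev, x)
            prev = x
        cur ^= 1
    ends_out[-1] = length_cM
    return ends_out, anc_out


def _ancestry_at_point(hap: Haplotype, pos: float) -> int:
    ends, anc = hap
    i = bisect.bisect_right(ends, pos)
    if i >= len(ends):
        i = len(ends) - 1
    return anc[i]


def simulate_population(
    config: SimulationConfig,
) -> tuple[LocalAncestryMatrix, BinManifest, TractCollection]:
    """Run the forward simulation and report dosage at bin midpoints.

    Returns the diploid local-ancestry matrix (dosage at each bin's midpoint),
    the bin manifest (consecutive ``bin_size_bp`` windows with a linear cM
    map), and the ground-truth tract collection of the final generation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    lengths_cM = [morgans * 100.0 for morgans, _ in config.chromosomes]
    n_chrom = len(config.chromosomes)

    # Founding generation: one ancestry draw per haploid genome.
    founder_anc = (rng.random(2 * n) < config.m_admixture).astype(int)
    pop: list[list[Haplotype]] = [
        [([lengths_cM[c]], [AFR if founder_anc[h] else EUR]) for h in range(2 * n)]
        for c in range(n_chrom)
    ]

    epi = config.epistasis
    s = epi.s_selection if epi is not None else 0.0
    select = epi is not None and s > 0.0
    if epi is not None:
        epi_c = int(str(epi.chrom)) - 1

    for _ in range(config.t_generations):
        new_pop: list[list[Haplotype]] = [[None] * (2 * n) for _ in range(n_chrom)]
        for child in range(n):
            while True:
                p1 = int(rng.integers(n))
                p2 = int(rng.integers(n - 1))
                if p2 >= p1:
                    p2 += 1
                gametes = []
                for c in range(n_chrom):
                    g1 = _meiosis(pop[c][2 * p1], pop[c][2 * p1 + 1], lengths_cM[c], rng)
                    g2 = _meiosis(pop[c][2 * p2], pop[c][2 * p2 + 1], lengths_cM[c], rng)
                    gametes.append((g1, g2))
                if select:
                    g1, g2 = gametes[epi_c]
                    dos_i = _ancestry_at_point(g1, epi.locus_i_cM) + _ancestry_at_point(
                        g2, epi.locus_i_cM
                    )
                    dos_j = _ancestry_at_point(g1, epi.locus_j_cM) + _ancestry_at_point(
                        g2, epi.locus_j_cM
                    )
                    w = 1.0 + s * (dos_i == dos_j)
                    if rng.random() >= w / (1.0 + s):
                        continue
                for c in range(n_chrom):
                    new_pop[c][2 * child] = gametes[c][0]
                    new_pop[c][2 * child + 1] = gametes[c][1]
                break
        pop = new_pop

    tracts = TractCollection(pop, lengths_cM)
    manifest = _build_manifest(config)
    matrix = _dosage_from_tracts(tracts, manifest, config)
    return matrix, manifest, tracts


def _build_manifest(config: SimulationConfig) -> BinManifest:
    rows = []
    for c, (morgans, length_bp) in enumerate(config.chromosomes):
        chrom = str(c + 1)
        length_cM = morgans * 100.0
        n_bins = -(-length_bp // config.bin_size_bp)
        for k in range(n_bins):
            start = k * config.bin_size_bp + 1
            end = min((k + 1) * config.bin_size_bp, length_bp)
            mid_bp = (start + end) // 2
            mid_cM = mid_bp / length_bp * length_cM
            rows.append(
                {
                    "bin_id": f"{chrom}:{start}-{end}",
                    "chrom": chrom,
                    "start_bp": start,
                    "end_bp": end,
                    "mid_bp": mid_bp,
                    "mid_cM": mid_cM,
                }
            )
    return BinManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))


def _dosage_from_tracts(
    tracts: TractCollection, manifest: BinManifest, config: SimulationConfig
) -> LocalAncestryMatrix:
    n = config.n_individuals
    blocks = []
    bin_ids: list[str] = []
    for c in range(len(config.chromosomes)):
        chrom = str(c + 1)
        sub = manifest.for_chrom(chrom)
        mids = sub["mid_cM"].to_numpy(dtype=float)
        blocks.append(tracts.dosage_at(c, mids))
        bin_ids.extend(sub["bin_id"])
    dosage = np.concatenate(blocks, axis=1)
    sample_ids = [f"ind{i:05d}" for i in range(n)]
    df = pd.DataFrame(dosage, index=sample_ids, columns=bin_ids)
    return LocalAncestryMatrix(df, cohort_label="simulated")
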