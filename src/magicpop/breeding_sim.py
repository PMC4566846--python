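"""Forward simulation of an eight-founder MAGIC funnel breeding design.

The design crosses 8 inbred founders (labelled A..H) in a half-diallel of
two-way hybrids, intercrosses disjoint two-ways into four-way hybrids
pooled by the four founder labels they carry, crosses complementary pools
into eight-way hybrids (one funnel per complementary pool pair), and
advances lines by single seed descent (SSD) to near-fixation.  Because one
two-way hybrid (here C x F, i.e. B96 x HP301) failed in the field, every
four-way cross with that two-way as a parent can be replaced by a
substitute two-way (B x I, i.e. B73 x CML91), which introduces a ninth
founder at low frequency.

The simulator tracks the exact founder mosaic of every line (the ground
truth against which HMM reconstruction is scored) and genotypes the
mosaics array-style with configurable error and missingness.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .genome_model import FounderPanel, GeneticMap, GenotypeMatrix, MapError

__all__ = [
    "FunnelDesign",
    "Homolog",
    "MosaicGenome",
    "DesignSummary",
    "enumerate_design",
    "expected_contributions",
    "design_expectations",
    "simulate_meiosis",
    "simulate_funnel_population",
    "simulate_founder_panel",
    "genotype_mosaics",
    "synthetic_map",
    "EIGHT_FOUNDERS",
    "NINTH_FOUNDER",
]

EIGHT_FOUNDERS = ["A", "B", "C", "D", "E", "F", "G", "H"]
NINTH_FOUNDER = "I"
# the field-failed two-way and its substitute (B96 x HP301 -> B73 x CML91)
LATE_PAIR = ("C", "F")
DONOR_PAIR = ("B", "I")


@dataclass
class FunnelDesign:
    """Parameters of the funnel breeding scheme."""

    n_founders: int = 8
    n_funnels: int = 35
    lines_per_funnel: int = 15
    ssd_generations: int = 5  # selfings after the eight-way F1 -> F6
    substitution: bool = True
    founder_het_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_founders != 8:
            raise ValueError("the funnel design is defined for 8 founders")
        if self.ssd_generations < 1:
            raise ValueError("need at least one SSD generation")
        max_funnels = math.comb(8, 4) // 2
        if not 1 <= self.n_funnels <= max_funnels:
            raise ValueError(f"n_funnels must be in 1..{max_funnels}")

    @property
    def founder_ids(self) -> list[str]:
        return EIGHT_FOUNDERS + ([NINTH_FOUNDER] if self.substitution else [])

    @property
    def generation(self) -> str:
        return f"F{self.ssd_generations + 1}"


@dataclass
class DesignSummary:
    n_two_way: int
    n_four_way_crosses: int
    n_pools: int
    n_funnel_pairs: int
    expected_contribution: dict[str, Fraction] | None = None
    expected_junctions: float | None = None
    expected_heterozygosity: float | None = None
    rix_count: int | None = None


def enumerate_design(n_founders: int) -> DesignSummary:
    """Combinatorics of the funnel scheme for ``n_founders`` founders.

    Counts two-way hybrids (unordered founder pairs), four-way crosses
    (unordered pairs of disjoint two-ways), four-allele pools and
    complementary pool pairs (funnels).
    """
    n = n_founders
    if n < 4 or n % 2:
        raise ValueError("design needs an even founder count >= 4")
    n_two_way = math.comb(n, 2)
    n_four_way = math.comb(n, 2) * math.comb(n - 2, 2) // 2
    n_pools = math.comb(n, 4)
    return DesignSummary(
        n_two_way=n_two_way,
        n_four_way_crosses=n_four_way,
        n_pools=n_pools,
        n_funnel_pairs=n_pools // 2 if n == 8 else n_pools,
    )


def _pool_components(pool: tuple[str, ...], substitution: bool):
    """The three four-way crosses of a pool, as ((p1, p2), (p3, p4)) pairs
    of two-way parents, with the substitution rule applied."""
    a, b, c, d = pool
    comps = [
        ((a, b), (c, d)),
        ((a, c), (b, d)),
        ((a, d), (b, c)),
    ]
    if substitution and set(LATE_PAIR) <= set(pool):
        fixed = []
        for p1, p2 in comps:
            if set(p1) == set(LATE_PAIR):
                p1 = DONOR_PAIR
            if set(p2) == set(LATE_PAIR):
                p2 = DONOR_PAIR
            fixed.append((p1, p2))
        comps = fixed
    return comps


def expected_contributions(design: FunnelDesign) -> dict[str, Fraction]:
    """Exact expected genome-length share of each founder.

    Averages, in rational arithmetic, over all C(8,4) = 70 four-allele
    pools (each funnel contributes a pool and its complement with weight
    1/2 each) and over the uniform choice among each pool's three
    component four-way crosses.  Each four-way parent two-way contributes
    1/4 of the eight-way genome, split equally between its two founders.
    """
    labels = design.founder_ids
    totals = {f: Fraction(0) for f in EIGHT_FOUNDERS + [NINTH_FOUNDER]}
    pools = list(itertools.combinations(EIGHT_FOUNDERS, 4))
    for pool in pools:
        comps = _pool_components(pool, design.substitution)
        for p1, p2 in comps:
            for f in (*p1, *p2):
                # pool weight 1/70, component choice 1/3, founder slot 1/4
                totals[f] += Fraction(1, len(pools)) * Fraction(1, 3) / 4
    # each funnel's genome is half pool-side, half complement-side; the
    # uniform average over all 70 pools covers both sides, so totals sum to 1
    assert sum(totals.values()) == 1
    return {f: totals[f] for f in labels}


def design_expectations(
    map_length_morgans: float, generation: int, n_lines: int
) -> DesignSummary:
    """Design expectations at generation ``F_k`` for a map of given length.

    Expected junction (recombination) count per inbred line is 4 x L: one
    effective round of recombination in each of G1, G2 and the first
    selfing, plus one more round accumulated over SSD as heterozygosity
    halves each generation (a geometric series summing to ~1).  Expected
    residual heterozygosity at F_k is 0.5^(k-1).  ``rix_count`` is the
    number of distinct recombinant inbred intercross F1s, C(n_lines, 2).
    """
    k = generation
    if k < 2:
        raise ValueError("generation must be F2 or later")
    summary = enumerate_design(8)
    summary.expected_junctions = 4.0 * map_length_morgans
    summary.expected_heterozygosity = 0.5 ** (k - 1)
    summary.rix_count = n_lines * (n_lines - 1) // 2
    return summary


# ---------------------------------------------------------------------------
# mosaic genomes


@dataclass
class Homolog:
    """One chromosome copy as founder-labelled segments.

    Segment ``i`` covers ``(ends[i-1], ends[i]]`` in bp (1-based inclusive
    ends); the first segment starts at the chromosome start.
    """

    ends: np.ndarray  # int64, strictly increasing, last == chrom end
    founders: np.ndarray  # int8 founder indices

    def founder_at(self, bp: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.ends, bp)
        return self.founders[np.minimum(idx, len(self.founders) - 1)]

    def copy(self) -> "Homolog":
        return Homolog(self.ends.copy(), self.founders.copy())


def _merge(ends: np.ndarray, founders: np.ndarray) -> Homolog:
    if len(founders) > 1:
        keep = np.append(founders[1:] != founders[:-1], True)
        ends, founders = ends[keep], founders[keep]
    return Homolog(ends, founders)


def constant_homolog(chrom_end: int, founder_idx: int) -> Homolog:
    return Homolog(
        np.array([chrom_end], dtype=np.int64),
        np.array([founder_idx], dtype=np.int8),
    )


@dataclass
class MosaicGenome:
    """Diploid founder mosaic: two homologs per chromosome."""

    homologs: dict[int, tuple[Homolog, Homolog]]
    generation: str = ""
    funnel: int = -1
    line_id: str = ""
    nine_founder: bool = False

    def founder_shares(self, n_founders: int = 9) -> np.ndarray:
        """Genome-length fraction contributed by each founder index."""
        tot = np.zeros(n_founders)
        length = 0.0
        for h0, h1 in self.homologs.values():
            start = 0
            for h in (h0, h1):
                prev = start
                for e, f in zip(h.ends, h.founders):
                    tot[f] += e - prev
                    prev = e
                length += h.ends[-1] - start
        return tot / length

    def junction_count(self) -> float:
        """Mean junction (founder switch) count of the two homologs, summed
        over chromosomes: the per-line recombination-event count of a
        sampled gamete lineage.  Expected ~3.94 x map length (Morgans) at
        F6, approaching the inbred-limit 4 x L."""
        n = 0
        for h0, h1 in self.homologs.values():
            for h in (h0, h1):
                n += int(np.sum(h.founders[1:] != h.founders[:-1]))
        return n / 2.0

    def heterozygosity(self) -> float:
        """Genome-length fraction where the two homologs carry different
        founder labels (heterozygosity by descent)."""
        het = 0.0
        tot = 0.0
        for h0, h1 in self.homologs.values():
            ends = np.union1d(h0.ends, h1.ends)
            f0 = h0.founder_at(ends)
            f1 = h1.founder_at(ends)
            seglen = np.diff(np.concatenate(([0], ends)))
            het += float(seglen[f0 != f1].sum())
            tot += float(ends[-1])
        return het / tot


# ---------------------------------------------------------------------------
# meiosis


class _ChromFrame:
    """Per-chromosome bp/cM interpolation tables from a genetic map."""

    def __init__(self, gmap: GeneticMap):
        if not gmap.is_interpolated:
            raise MapError("map must be interpolated before simulation")
        self.chroms: list[int] = []
        self.bp: dict[int, np.ndarray] = {}
        self.cm: dict[int, np.ndarray] = {}
        self.length_m: dict[int, float] = {}
        for chrom, grp in gmap.table.groupby("chromosome"):
            c = int(chrom)
            self.chroms.append(c)
            self.bp[c] = grp["position_bp"].to_numpy(dtype=float)
            self.cm[c] = grp["position_cM"].to_numpy(dtype=float)
            self.length_m[c] = (self.cm[c][-1] - self.cm[c][0]) / 100.0

    def crossover_positions(self, chrom: int, rng: np.random.Generator):
        """Poisson crossover count on the cM scale, positions mapped to bp."""
        L = self.length_m[chrom]
        n_xo = rng.poisson(L)
        if n_xo == 0:
            return np.empty(0, dtype=np.int64)
        cm = self.cm[chrom]
        u = rng.uniform(cm[0], cm[-1], size=n_xo)
        bp = np.interp(u, cm, self.bp[chrom])
        return np.unique(np.round(bp).astype(np.int64))

    def chrom_end(self, chrom: int) -> int:
        return int(self.bp[chrom][-1])


def _recombine(
    h0: Homolog, h1: Homolog, xo_bp: np.ndarray, start: int
) -> Homolog:
    """Gamete homolog from two parental homologs with crossovers at xo_bp."""
    pair = (h0, h1)
    if len(xo_bp) == 0:
        return pair[start].copy()
    bounds = np.concatenate((xo_bp, [h0.ends[-1]]))
    ends_out: list[np.ndarray] = []
    fnd_out: list[np.ndarray] = []
    prev = 0
    cur = start
    for b in bounds:
        h = pair[cur]
        i0 = np.searchsorted(h.ends, prev, side="right")
        i1 = np.searchsorted(h.ends, b, side="left")
        seg_ends = np.append(h.ends[i0:i1], b)
        seg_fnd = h.founders[i0 : i1 + 1]
        if len(seg_fnd) < len(seg_ends):  # b beyond last stored end
            seg_fnd = np.append(seg_fnd, h.founders[-1])
        ends_out.append(seg_ends)
        fnd_out.append(seg_fnd[: len(seg_ends)])
        prev = b
        cur = 1 - cur
    return _merge(np.concatenate(ends_out), np.concatenate(fnd_out))


def simulate_meiosis(
    parent: MosaicGenome, frame: _ChromFrame, rng: np.random.Generator
) -> dict[int, Homolog]:
    """One gamete from a diploid parent: per chromosome, a Poisson number
    of crossovers (no interference) placed uniformly on the cM scale."""
    gamete = {}
    for chrom in frame.chroms:
        h0, h1 = parent.homologs[chrom]
        xo = frame.crossover_positions(chrom, rng)
        start = int(rng.integers(2))
        gamete[chrom] = _recombine(h0, h1, xo, start)
    return gamete


def _cross(
    p1: MosaicGenome,
    p2: MosaicGenome,
    frame: _ChromFrame,
    rng: np.random.Generator,
) -> MosaicGenome:
    g1 = simulate_meiosis(p1, frame, rng)
    g2 = simulate_meiosis(p2, frame, rng)
    return MosaicGenome({c: (g1[c], g2[c]) for c in frame.chroms})


def _founder_genome(frame: _ChromFrame, idx: int) -> MosaicGenome:
    return MosaicGenome(
        {
            c: (
                constant_homolog(frame.chrom_end(c), idx),
                constant_homolog(frame.chrom_end(c), idx),
            )
            for c in frame.chroms
        }
    )


def simulate_funnel_population(
    design: FunnelDesign,
    gmap: GeneticMap,
    rng: np.random.Generator | int | None = None,
) -> list[MosaicGenome]:
    """Simulate the full funnel population to the requested SSD generation.

    Funnels are the complementary pool pairs of the design (all 35 when
    ``n_funnels=35``).  Pooling of the three four-way component crosses is
    modelled as a uniform choice per seed; the substitution rule replaces
    the failed two-way parent wherever it would occur.  Returns one
    ``MosaicGenome`` per line with funnel id and pedigree flag set.
    """
    rng = np.random.default_rng(rng)
    frame = _ChromFrame(gmap)
    label_to_idx = {f: i for i, f in enumerate(EIGHT_FOUNDERS + [NINTH_FOUNDER])}
    founder_genomes = {
        f: _founder_genome(frame, i) for f, i in label_to_idx.items()
    }

    pools = list(itertools.combinations(EIGHT_FOUNDERS, 4))
    pairs = []
    seen = set()
    for pool in pools:
        comp = tuple(sorted(set(EIGHT_FOUNDERS) - set(pool)))
        key = frozenset((pool, comp))
        if key not in seen:
            seen.add(key)
            pairs.append((pool, comp))
    # deterministic funnel subset: first n_funnels complementary pairs
    pairs = pairs[: design.n_funnels]

    lines: list[MosaicGenome] = []
    for funnel_id, (pool, comp) in enumerate(pairs, start=1):
        for line_no in range(1, design.lines_per_funnel + 1):
            nine = False
            side_gametes = []
            for side_pool in (pool, comp):
                comps = _pool_components(side_pool, design.substitution)
                p1, p2 = comps[int(rng.integers(3))]
                if NINTH_FOUNDER in (*p1, *p2):
                    nine = True
                two1 = _cross(
                    founder_genomes[p1[0]], founder_genomes[p1[1]], frame, rng
                )
                two2 = _cross(
                    founder_genomes[p2[0]], founder_genomes[p2[1]], frame, rng
                )
                four = _cross(two1, two2, frame, rng)
                side_gametes.append(simulate_meiosis(four, frame, rng))
            g1, g2 = side_gametes
            indiv = MosaicGenome({c: (g1[c], g2[c]) for c in frame.chroms})
            for _ in range(design.ssd_generations):
                indiv = _cross(indiv, indiv, frame, rng)
            indiv.generation = design.generation
            indiv.funnel = funnel_id
            indiv.line_id = f"{funnel_id}_{line_no}"
            indiv.nine_founder = nine
            lines.append(indiv)
    return lines


# ---------------------------------------------------------------------------
# synthetic marker panels and array-style genotyping


#: physical chromosome sizes (Mb), maize-like relative proportions
_CHROM_MB = np.array([301, 237, 232, 242, 217, 169, 176, 175, 157, 149])


def synthetic_map(
    n_markers: int = 5000,
    total_cm: float = 1996.0,
    n_chromosomes: int = 10,
    seed: int | None = 0,
) -> GeneticMap:
    """A fully anchored synthetic SNP-array map.

    Ten chromosomes with maize-like relative physical sizes; markers placed
    uniformly at random, cM linear in bp per chromosome so the total map
    length is ``total_cm`` (19.96 Morgans by default).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    mb = _CHROM_MB[:n_chromosomes].astype(float)
    cm_per_chrom = total_cm * mb / mb.sum()
    counts = np.maximum(
        2, np.round(n_markers * mb / mb.sum()).astype(int)
    )
    rows = []
    for c in range(n_chromosomes):
        size_bp = int(mb[c] * 1e6)
        pos = np.sort(
            rng.choice(np.arange(1, size_bp + 1), size=counts[c], replace=False)
        )
        pos[0], pos[-1] = 1, size_bp  # pin ends so map spans the chromosome
        cm = (pos - 1) / (size_bp - 1) * cm_per_chrom[c]
        for i, (bp, x) in enumerate(zip(pos, cm)):
            rows.append((f"m{c + 1}_{i + 1}", c + 1, int(bp), float(x)))
    table = pd.DataFrame(
        rows, columns=["marker_id", "chromosome", "position_bp", "position_cM"]
    )
    return GeneticMap(table)


def simulate_founder_panel(
    gmap: GeneticMap,
    design: FunnelDesign | None = None,
    seed: int | None = 0,
) -> FounderPanel:
    """Synthetic biallelic founder calls at the map markers.

    Per marker, the number of alternate-allele founders k is drawn
    uniformly from 1..7 and k of the eight founders carry the alternate
    homozygous call, giving the k/8 minor-allele-frequency spectrum of an
    array designed on polymorphic sites.  The ninth founder (if present)
    gets an independent random allele; optional per-founder residual
    heterozygosity injects ``1`` calls at random markers.
    """
    design = design or FunnelDesign()
    rng = np.random.default_rng(seed)
    labels = design.founder_ids
    m = gmap.n_markers
    calls = np.zeros((len(labels), m), dtype=np.int8)
    k = rng.integers(1, 8, size=m)
    for j in range(m):
        alt = rng.choice(8, size=k[j], replace=False)
        calls[alt, j] = 2
    if len(labels) == 9:
        calls[8] = np.where(rng.random(m) < 0.5, 2, 0)
    for fid, het_rate in design.founder_het_rates.items():
        i = labels.index(fid)
        mask = rng.random(m) < het_rate
        calls[i, mask] = 1
    return FounderPanel(list(labels), calls, marker_ids=gmap.marker_ids)


def genotype_mosaics(
    mosaics: list[MosaicGenome],
    founders: FounderPanel,
    gmap: GeneticMap,
    error_rate: float = 0.01,
    missing_rate: float = 0.15,
    rng: np.random.Generator | int | None = None,
) -> GenotypeMatrix:
    """Array-style genotyping of mosaic genomes.

    Each line x marker call is the sum of the two homologs' founder
    alleles (heterozygous founder calls contribute a random allele);
    calls are then flipped to a random wrong value with probability
    ``error_rate`` and masked missing with probability ``missing_rate``,
    emulating assay error and the ~85% call rate of array data.
    """
    rng = np.random.default_rng(rng)
    n = len(mosaics)
    m = gmap.n_markers
    chrom_col = gmap.table["chromosome"].to_numpy()
    bp_col = gmap.table["position_bp"].to_numpy()

    # founder allele per founder x marker in {0, 1}; het founder calls
    # resolved to a random allele once per line below
    fcalls = founders.calls
    calls = np.zeros((n, m), dtype=np.int8)
    marker_index = {c: np.flatnonzero(chrom_col == c) for c in gmap.chromosomes}
    for i, mos in enumerate(mosaics):
        f0 = np.empty(m, dtype=np.int16)
        f1 = np.empty(m, dtype=np.int16)
        for c, idx in marker_index.items():
            h0, h1 = mos.homologs[c]
            f0[idx] = h0.founder_at(bp_col[idx])
            f1[idx] = h1.founder_at(bp_col[idx])
        cols = np.arange(m)
        a0 = fcalls[f0, cols].astype(np.int16)
        a1 = fcalls[f1, cols].astype(np.int16)
        for a in (a0, a1):
            het = a == 1
            if het.any():
                a[het] = rng.integers(0, 2, size=int(het.sum())) * 2
            miss = a == -1
            if miss.any():
                a[miss] = rng.integers(0, 2, size=int(miss.sum())) * 2
        calls[i] = ((a0 + a1) // 2).astype(np.int8)

    if error_rate > 0:
        err = rng.random((n, m)) < error_rate
        shift = rng.integers(1, 3, size=int(err.sum()))
        calls[err] = ((calls[err] + shift) % 3).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random((n, m)) < missing_rate] = -1

    return GenotypeMatrix(
        line_ids=[mos.line_id or f"line_{i}" for i, mos in enumerate(mosaics)],
        calls=calls,
        marker_ids=gmap.marker_ids,
        pedigree_flags=[
            "nine-founder" if mos.nine_founder else "eight-founder"
            for mos in mosaics
        ],
    )
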