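"""Marker QC, diversity summaries, and linkage-disequilibrium statistics.

Implements the diversity/LD toolbox for a multi-parent RIL panel: founder
replicate merging, call-rate/polymorphism filtering, minor-allele
frequency (computed only at markers homozygous and called in every
founder) and per-line heterozygosity, pairwise r^2 with its decay profile
and halving distance, marker-centred local LD with percentile bands, and
greedy LD pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import FounderPanel, GeneticMap, GenotypeMatrix

__all__ = [
    "merge_founder_replicates",
    "qc_filter_markers",
    "compute_maf_het",
    "ld_r2",
    "ld_decay",
    "local_ld",
    "ld_prune",
    "LDProfile",
]


def merge_founder_replicates(rep1: np.ndarray, rep2: np.ndarray):
    """Consensus of two replicate call vectors/matrices.

    A missing call in one replicate is replaced by the other's; agreeing
    calls pass through; conflicting non-missing calls become missing and
    are flagged.

    Returns (consensus, conflict mask).
    """
    rep1 = np.asarray(rep1, dtype=np.int8)
    rep2 = np.asarray(rep2, dtype=np.int8)
    if rep1.shape != rep2.shape:
        raise ValueError("replicates must have the same shape")
    out = rep1.copy()
    out[rep1 == -1] = rep2[rep1 == -1]
    conflict = (rep1 != -1) & (rep2 != -1) & (rep1 != rep2)
    out[conflict] = -1
    return out, conflict


def qc_filter_markers(
    genotypes: GenotypeMatrix, min_call_rate: float = 0.8
) -> np.ndarray:
    """Indices of markers that are polymorphic with call rate strictly
    above ``min_call_rate`` among the lines."""
    calls = genotypes.calls
    called = calls != -1
    call_rate = called.mean(axis=0)
    poly = np.zeros(calls.shape[1], dtype=bool)
    for j in range(calls.shape[1]):
        seen = np.unique(calls[called[:, j], j])
        poly[j] = len(seen) >= 2
    return np.flatnonzero((call_rate > min_call_rate) & poly)


def compute_maf_het(
    genotypes: GenotypeMatrix, founders: FounderPanel
) -> dict:
    """MAF spectra and per-line heterozygosity.

    MAF uses only markers where every founder is homozygous and called
    (heterozygous or missing founder calls disqualify the marker).
    Founder MAF is the minor allele count over the founder panel divided
    by the founder count (with nine founders it cannot reach 0.5); line
    MAF is the minor allele frequency over non-missing line calls.
    Heterozygosity is each line's fraction of ``1`` calls among its
    non-missing calls.
    """
    fc = founders.calls
    ok = ((fc == 0) | (fc == 2)).all(axis=0)
    alt = (fc[:, ok] == 2).sum(axis=0)
    nf = founders.n_founders
    founder_maf = np.minimum(alt, nf - alt) / nf

    lc = genotypes.calls[:, ok]
    called = lc != -1
    alt_dose = np.where(called, lc, 0).sum(axis=0).astype(float)
    n_alleles = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_alleles > 0, alt_dose / n_alleles, np.nan)
    line_maf = np.minimum(p_alt, 1.0 - p_alt)

    calls = genotypes.calls
    nonmiss = calls != -1
    het = (calls == 1).sum(axis=1) / np.maximum(nonmiss.sum(axis=1), 1)
    return {
        "marker_mask": ok,
        "founder_maf": founder_maf,
        "line_maf": line_maf,
        "line_het": het,
    }


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of allele dosages over pairwise-complete
    lines; NaN when either column is monomorphic or fewer than two
    complete pairs exist."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != -1) & (g2 != -1)
    if ok.sum() < 2:
        return float("nan")
    a, b = g1[ok], g2[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_matrix(calls: np.ndarray) -> np.ndarray:
    """Pairwise r^2 between marker columns, missing as -1.

    Uses pairwise-complete standardization; entries for monomorphic
    columns are NaN.
    """
    X = calls.astype(float)
    miss = X == -1
    X[miss] = np.nan
    # pairwise-complete correlation via masked arrays is slow at scale;
    # with moderate missingness the mean-imputed approximation stays
    # within numerical noise for QC purposes, but here we stay exact.
    df = pd.DataFrame(X)
    r = df.corr(min_periods=2).to_numpy()
    return r**2


@dataclass
class LDProfile:
    decay: pd.DataFrame | None = None  # chromosome, bin midpoint, mean r2
    halving_mb: dict[int, float] = field(default_factory=dict)
    local: pd.DataFrame | None = None  # per-marker local mean r2 + bands
    sparse_bins: int = 0


def ld_decay(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    max_dist_mb: float = 10.0,
    bin_kb: float = 100.0,
    min_pairs: int = 10,
) -> LDProfile:
    """LD decay with physical distance, per chromosome.

    All marker pairs within ``max_dist_mb`` are binned by distance in
    ``bin_kb`` windows.  The halving distance is the first bin whose mean
    r^2 falls to the baseline-adjusted half of the first bin's mean,
    where the baseline is the mean r^2 of the farthest 20% of bins (the
    relatedness floor of a family-structured RIL panel).
    """
    chrom_col = gmap.table["chromosome"].to_numpy()
    bp = gmap.table["position_bp"].to_numpy()
    rows = []
    halving = {}
    sparse = 0
    for c in gmap.chromosomes:
        idx = np.flatnonzero(chrom_col == c)
        r2 = _r2_matrix(genotypes.calls[:, idx])
        pos = bp[idx]
        i, j = np.triu_indices(len(idx), k=1)
        dist = pos[j] - pos[i]
        keep = (dist <= max_dist_mb * 1e6) & ~np.isnan(r2[i, j])
        dist = dist[keep]
        vals = r2[i, j][keep]
        bins = (dist // (bin_kb * 1e3)).astype(int)
        prof = []
        for b in np.unique(bins):
            sel = bins == b
            if sel.sum() < min_pairs:
                sparse += 1
            mid = (b + 0.5) * bin_kb * 1e3
            prof.append((c, mid, float(vals[sel].mean()), int(sel.sum())))
            rows.append(prof[-1])
        if len(prof) >= 3:
            means = np.array([p[2] for p in prof])
            n_tail = max(1, len(means) // 5)
            baseline = float(means[-n_tail:].mean())
            target = baseline + (means[0] - baseline) / 2.0
            below = np.flatnonzero(means <= target)
            if len(below):
                halving[int(c)] = float(prof[below[0]][1] / 1e6)
    decay = pd.DataFrame(
        rows, columns=["chromosome", "dist_mid_bp", "mean_r2", "n_pairs"]
    )
    return LDProfile(decay=decay, halving_mb=halving, sparse_bins=sparse)


def local_ld(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    flank_mb: float = 1.0,
    window_markers: int = 100,
) -> LDProfile:
    """Marker-centred local LD: per-marker mean r^2 with neighbours within
    +/- ``flank_mb``, smoothed (with 25th/75th percentile bands) by a
    ``window_markers``-wide sliding mean advancing one marker at a time."""
    chrom_col = gmap.table["chromosome"].to_numpy()
    bp = gmap.table["position_bp"].to_numpy()
    frames = []
    for c in gmap.chromosomes:
        idx = np.flatnonzero(chrom_col == c)
        r2 = _r2_matrix(genotypes.calls[:, idx])
        pos = bp[idx]
        local = np.full(len(idx), np.nan)
        for k in range(len(idx)):
            near = np.abs(pos - pos[k]) <= flank_mb * 1e6
            near[k] = False
            vals = r2[k, near]
            vals = vals[~np.isnan(vals)]
            if len(vals):
                local[k] = vals.mean()
        w = min(window_markers, len(idx))
        s = pd.Series(local)
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": c,
                    "marker_id": gmap.table["marker_id"].to_numpy()[idx],
                    "position_bp": pos,
                    "local_r2": local,
                    "smoothed_r2": s.rolling(w, center=True, min_periods=1)
                    .mean()
                    .to_numpy(),
                    "q25": s.rolling(w, center=True, min_periods=1)
                    .quantile(0.25)
                    .to_numpy(),
                    "q75": s.rolling(w, center=True, min_periods=1)
                    .quantile(0.75)
                    .to_numpy(),
                }
            )
        )
    return LDProfile(local=pd.concat(frames, ignore_index=True))


def ld_prune(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    r2_threshold: float = 0.4,
    window_kb: float = 500.0,
) -> np.ndarray:
    """Greedy left-to-right LD pruning.

    Walking each chromosome, a marker is dropped when its r^2 with any
    already-retained marker within ``window_kb`` exceeds the threshold;
    the result is stable under re-pruning.  Returns retained marker
    indices.
    """
    chrom_col = gmap.table["chromosome"].to_numpy()
    bp = gmap.table["position_bp"].to_numpy()
    keep: list[int] = []
    for c in gmap.chromosomes:
        idx = np.flatnonzero(chrom_col == c)
        r2 = _r2_matrix(genotypes.calls[:, idx])
        pos = bp[idx]
        retained: list[int] = []
        for k in range(len(idx)):
            ok = True
            for r in reversed(retained):
                if pos[k] - pos[r] > window_kb * 1e3:
                    break
                v = r2[k, r]
                if np.isfinite(v) and v > r2_threshold:
                    ok = False
                    break
            if ok:
                retained.append(k)
        keep.extend(idx[retained].tolist())
    return np.asarray(sorted(keep), dtype=int)
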