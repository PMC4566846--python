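"""Association mapping by imputing founder SNP alleles onto RIL mosaics.

Founder inbreds carry known alleles at (sequencing-derived) variant sites
that are denser than the genotyping array.  Each line's founder posterior
vector at the nearest array marker transfers those alleles as an expected
dosage

    g_ij = sum_s P_i(s) a_s,       a_s in {0, 2},

which is then tested one site at a time with the same mixed model as the
linkage scan, y = g beta_g + gamma + eps.  A rounded (0/1 founder-allele
indicator) companion matrix serves the interval LD profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import GeneticMap
from .qtl_linkage import KinshipMatrix, MixedModelContext, ScanResult, _rss

__all__ = [
    "ImputedGenotypes",
    "impute_founder_snps",
    "association_scan",
    "association_threshold",
    "interval_ld_profile",
    "read_founder_variants",
]


@dataclass
class ImputedGenotypes:
    """Imputed allele dosages at founder variant sites.

    ``dosage`` is continuous in [0, 2]; ``rounded`` is the nearest-integer
    companion used for LD; ``sites`` holds chrom/bp and the per-founder
    allele vector of each site.
    """

    line_ids: list[str]
    dosage: np.ndarray  # (n_lines, n_sites)
    rounded: np.ndarray  # (n_lines, n_sites) int8
    sites: pd.DataFrame  # chromosome, position_bp, alleles (G,) per row
    founder_alleles: np.ndarray  # (n_sites, G) in {0, 2} (-1 missing)

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]


def read_founder_variants(vcf_path, founder_ids: list[str], region=None):
    """Founder allele matrix from a VCF of inbred founder genotypes.

    Returns a DataFrame (chromosome, position_bp) and an array
    (n_sites, n_founders) coded 0/2 (homozygous ref/alt, -1 missing).
    Heterozygous founder calls are treated as missing (founders are
    inbred; residual hets are uninformative for imputation).
    ``region`` is an optional "chrom:start-end" string.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_idx = []
    for f in founder_ids:
        if f not in vcf.samples:
            raise KeyError(f"founder {f!r} not a VCF sample")
        sample_idx.append(vcf.samples.index(f))
    rows = []
    alleles = []
    it = vcf(region) if region else vcf
    for var in it:
        if len(var.ALT) != 1:
            continue
        gt = np.array(var.gt_types)[sample_idx]  # 0 hom-ref,1 het,2 miss,3 hom-alt
        a = np.full(len(sample_idx), -1, dtype=np.int8)
        a[gt == 0] = 0
        a[gt == 3] = 2
        if (a == -1).all():
            continue
        rows.append((int(var.CHROM), int(var.POS)))
        alleles.append(a)
    sites = pd.DataFrame(rows, columns=["chromosome", "position_bp"])
    return sites, np.array(alleles, dtype=np.int8)


def impute_founder_snps(
    posteriors: np.ndarray,
    gmap: GeneticMap,
    sites: pd.DataFrame,
    founder_alleles: np.ndarray,
    line_ids: list[str] | None = None,
) -> ImputedGenotypes:
    """Expected allele dosages at variant sites from founder posteriors.

    Each site takes the posterior vector of the nearest array marker on
    its chromosome (ties broken to the left); dosage = sum_s P(s) a_s
    with missing founder alleles imputed at the site's mean allele.
    Sites where all founder alleles are missing are dropped.
    """
    n, M, G = posteriors.shape
    if founder_alleles.shape[0] != len(sites):
        raise ValueError("allele matrix rows != variant sites")
    keep = ~(founder_alleles == -1).all(axis=1)
    sites = sites.loc[keep].reset_index(drop=True)
    founder_alleles = founder_alleles[keep]

    chrom_col = gmap.table["chromosome"].to_numpy()
    bp_col = gmap.table["position_bp"].to_numpy()
    dosage = np.empty((n, len(sites)))
    for c in sites["chromosome"].unique():
        m_idx = np.flatnonzero(chrom_col == c)
        if len(m_idx) == 0:
            raise ValueError(f"no array markers on chromosome {c}")
        s_rows = np.flatnonzero(sites["chromosome"].to_numpy() == c)
        pos = sites["position_bp"].to_numpy()[s_rows]
        mbp = bp_col[m_idx]
        right = np.searchsorted(mbp, pos)
        left = np.clip(right - 1, 0, len(mbp) - 1)
        right = np.clip(right, 0, len(mbp) - 1)
        d_left = np.abs(pos - mbp[left])
        d_right = np.abs(mbp[right] - pos)
        nearest = np.where(d_right < d_left, right, left)  # ties -> left
        a = founder_alleles[s_rows].astype(float)  # (S, G)
        col_mean = np.where(
            a == -1, np.nan, a
        )
        means = np.nanmean(col_mean, axis=1)
        a = np.where(a == -1, means[:, None], a)
        P = posteriors[:, m_idx[nearest], :]  # (n, S, G)
        dosage[:, s_rows] = np.einsum("nsg,sg->ns", P, a)
    # rounded companion: haploid founder-allele indicator in {0, 1}
    rounded = (dosage >= 1.0).astype(np.int8)
    return ImputedGenotypes(
        line_ids=line_ids or [f"line_{i}" for i in range(n)],
        dosage=dosage,
        rounded=rounded,
        sites=sites,
        founder_alleles=founder_alleles,
    )


def association_scan(
    y: np.ndarray,
    imputed: ImputedGenotypes,
    K: KinshipMatrix,
    trait: str = "",
) -> ScanResult:
    """Single-dosage mixed-model scan over imputed variant sites."""
    y = np.asarray(y, dtype=float)
    n, S = imputed.dosage.shape
    ctx = MixedModelContext(y, K)
    Gw = ctx.whiten(imputed.dosage)
    yw = ctx.yw
    ones_w = ctx.ones_w[:, 0]
    rss0 = _rss(yw, ctx.ones_w)

    # per site: regression on [1, dosage] whitened
    o2 = ones_w @ ones_w
    og = ones_w @ Gw
    gg = np.einsum("ns,ns->s", Gw, Gw)
    oy = ones_w @ yw
    gy = yw @ Gw
    det = o2 * gg - og**2
    ok = det > 1e-12 * np.maximum(o2 * gg, 1e-30)
    beta_g = np.where(ok, (o2 * gy - og * oy) / np.where(ok, det, 1.0), 0.0)
    beta_0 = np.where(ok, (gg * oy - og * gy) / np.where(ok, det, 1.0), oy / o2)
    rss1 = (
        np.einsum("n->", yw**2)
        - beta_0 * oy
        - beta_g * gy
    )
    rss1 = np.clip(rss1, 1e-12, None)
    lod = (n / 2.0) * np.log10(np.clip(rss0 / rss1, 1.0, None))
    lod[~ok] = 0.0  # monomorphic dosage
    table = imputed.sites.copy()
    table["marker_id"] = [
        f"snp_{c}_{p}"
        for c, p in zip(table["chromosome"], table["position_bp"])
    ]
    table["lod"] = lod
    table["varexp"] = 1.0 - 10.0 ** (-2.0 * lod / n)
    table["beta_g"] = beta_g
    return ScanResult(
        table=table,
        founder_effects=beta_g[:, None],
        trait=trait,
    )


def association_threshold(
    y: np.ndarray,
    imputed: ImputedGenotypes,
    K: KinshipMatrix,
    n_perm: int = 500,
    rng: np.random.Generator | int | None = None,
    pct: float = 90.0,
) -> float:
    """Region-wide significance threshold: the 90th percentile of the
    per-permutation maximum LOD over the scanned sites."""
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    rng = np.random.default_rng(rng)
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        yp = rng.permutation(np.asarray(y, dtype=float))
        maxima[p] = association_scan(yp, imputed, K).max_lod()
    return float(np.percentile(maxima, pct))


def interval_ld_profile(
    imputed: ImputedGenotypes,
    window_kb: float = 100.0,
    smooth_per_kb: float = 200.0,
) -> pd.DataFrame:
    """Mean pairwise r^2 of each site with its +/- ``window_kb`` neighbours.

    Uses the rounded founder-allele indicators; the raw profile is then
    smoothed with a rolling window sized to the mean site count per
    ``smooth_per_kb`` kilobases.  Returns a frame with one row per site.
    """
    S = imputed.n_sites
    if S < 2:
        return pd.DataFrame(
            columns=["chromosome", "position_bp", "mean_r2", "smoothed_r2"]
        )
    X = imputed.rounded.astype(float)
    out_mean = np.full(S, np.nan)
    chroms = imputed.sites["chromosome"].to_numpy()
    pos_all = imputed.sites["position_bp"].to_numpy()
    for c in np.unique(chroms):
        s_rows = np.flatnonzero(chroms == c)
        pos = pos_all[s_rows]
        Xc = X[:, s_rows]
        sd = Xc.std(axis=0)
        Z = np.where(sd > 0, (Xc - Xc.mean(axis=0)) / np.where(sd > 0, sd, 1), 0.0)
        r2 = (Z.T @ Z / len(Z)) ** 2
        informative = sd > 0
        half = window_kb * 1e3
        for j, pj in enumerate(pos):
            in_window = (np.abs(pos - pj) <= half) & (np.arange(len(pos)) != j)
            near = in_window & informative
            if informative[j] and near.any():
                out_mean[s_rows[j]] = r2[j, near].mean()
    prof = imputed.sites[["chromosome", "position_bp"]].copy()
    prof["mean_r2"] = out_mean
    # rolling smooth sized to mean marker count per smooth_per_kb
    span_kb = (pos_all.max() - pos_all.min()) / 1e3
    mean_per_window = max(1, int(round(S * smooth_per_kb / max(span_kb, 1))))
    prof["smoothed_r2"] = (
        prof["mean_r2"]
        .rolling(mean_per_window, center=True, min_periods=1)
        .mean()
    )
    return prof
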