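"""Multi-founder linkage mapping on haplotype posterior probabilities.

The scan regresses a phenotype on the per-marker founder-probability
columns produced by mosaic reconstruction,

    y_i = sum_s p_im(s) beta_s + gamma_i + eps_i,

where gamma is a polygenic random effect with covariance sigma_g^2 K and
K is the kinship matrix of posterior inner products, computed with the
leave-one-chromosome-out (LOCO) rule.  Variance components are estimated
once under the null by REML (EMMA-style eigendecomposition) and fixed
across markers; each marker is then tested by generalized least squares
on the rotated data, with LOD = (n/2) log10(RSS0 / RSS1).

Genome-wide significance thresholds come from permutations of the
phenotype: the 99th percentile of the per-permutation maximum LOD is the
strong threshold (genome-wide P < 0.01) and the 37th percentile the
suggestive threshold (P < 0.63).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genome_model import GeneticMap

__all__ = [
    "KinshipMatrix",
    "ScanResult",
    "QTLPeak",
    "compute_kinship",
    "drop_ninth_founder",
    "linkage_scan",
    "permutation_thresholds",
    "call_peaks",
    "covariate_scan",
]


@dataclass
class KinshipMatrix:
    K: np.ndarray
    loco_excluded_chromosome: int | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")


def compute_kinship(
    posteriors: np.ndarray,
    chromosomes: np.ndarray | None = None,
    exclude_chromosome: int | None = None,
) -> KinshipMatrix:
    """Kinship as the mean inner product of founder posteriors.

    K_ij = (1/M') sum_m sum_s P_im(s) P_jm(s) over the M' markers not on
    the excluded chromosome (LOCO).
    """
    n, M, G = posteriors.shape
    if exclude_chromosome is None:
        keep = np.arange(M)
    else:
        if chromosomes is None:
            raise ValueError("need chromosome labels to exclude a chromosome")
        keep = np.flatnonzero(np.asarray(chromosomes) != exclude_chromosome)
    if len(keep) == 0:
        raise ValueError("no markers left after LOCO exclusion")
    P = posteriors[:, keep, :].reshape(n, -1)
    K = (P @ P.T) / len(keep)
    return KinshipMatrix(K=K, loco_excluded_chromosome=exclude_chromosome)


def drop_ninth_founder(posteriors: np.ndarray):
    """Remove the ninth (substitution-donor) founder column and renormalize.

    The donor is rare at every marker, which makes its mapping coefficient
    unstable; its probability mass is redistributed over the eight main
    founders.  Rows that were entirely ninth-founder become uniform and are
    flagged.

    Returns (posteriors with G=8, flags boolean array of all-ninth rows).
    """
    if posteriors.shape[-1] != 9:
        raise ValueError("expected nine-state posteriors")
    p8 = posteriors[..., :8].copy()
    s = p8.sum(axis=-1, keepdims=True)
    flags = s[..., 0] <= 1e-12
    s[s <= 1e-12] = 1.0
    p8 /= s
    p8[flags] = 1.0 / 8
    return p8, flags


# ---------------------------------------------------------------------------
# mixed model machinery


def _reml_delta(yr: np.ndarray, xr: np.ndarray, d: np.ndarray) -> float:
    """REML estimate of delta = sigma_e^2 / sigma_g^2 on rotated data.

    yr, xr are U'y and U'X for the eigendecomposition K = U diag(d) U';
    the variance of rotated residuals is sigma_g^2 (d + delta).
    """
    n, p = xr.shape

    def neg_restricted_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = 1.0 / (d + delta)
        xtwx = (xr * w[:, None]).T @ xr
        xtwy = (xr * w[:, None]).T @ yr
        try:
            beta = np.linalg.solve(xtwx, xtwy)
        except np.linalg.LinAlgError:
            return 1e30
        resid = yr - xr @ beta
        rss = float(resid @ (w * resid))
        sig = rss / (n - p)
        _, logdet_xtwx = np.linalg.slogdet(xtwx)
        return 0.5 * (
            (n - p) * np.log(sig)
            - np.log(w).sum()
            + logdet_xtwx
            + (n - p)
        )

    res = minimize_scalar(
        neg_restricted_ll, bounds=(-10.0, 10.0), method="bounded"
    )
    return float(np.exp(res.x))


class MixedModelContext:
    """Precomputed rotation and weights for scans against one kinship."""

    def __init__(self, y: np.ndarray, K: KinshipMatrix):
        self.n = len(y)
        d, U = np.linalg.eigh(K.K)
        self.d = np.clip(d, 1e-9, None)
        self.U = U
        self.ones_r = self.U.T @ np.ones((self.n, 1))
        self.y = np.asarray(y, dtype=float)
        self._set_weights(self.y)

    def _set_weights(self, y: np.ndarray) -> None:
        yr = self.U.T @ y
        self.delta = _reml_delta(yr, self.ones_r, self.d)
        self.sqrt_w = 1.0 / np.sqrt(self.d + self.delta)
        self.yw = self.sqrt_w * yr
        self.ones_w = self.sqrt_w[:, None] * self.ones_r

    def rotate(self, X: np.ndarray) -> np.ndarray:
        """Apply the eigenvector rotation U' along the line axis."""
        flat = X.reshape(self.n, -1)
        return (self.U.T @ flat).reshape(X.shape)

    def weight(self, Xr: np.ndarray) -> np.ndarray:
        """Apply the current variance weights to rotated columns."""
        return self.sqrt_w.reshape(
            (self.n,) + (1,) * (Xr.ndim - 1)
        ) * Xr

    def whiten(self, X: np.ndarray) -> np.ndarray:
        """Rotate and weight columns (convenience for one-shot scans)."""
        return self.weight(self.rotate(X))

    def with_phenotype(self, y: np.ndarray, reestimate: bool = True):
        """Context for a new phenotype sharing this kinship rotation."""
        import copy

        other = copy.copy(self)
        other.y = np.asarray(y, dtype=float)
        if reestimate:
            other._set_weights(other.y)
        else:
            other.yw = self.sqrt_w * (self.U.T @ y)
        return other


def _rss(yw: np.ndarray, Xw: np.ndarray) -> float:
    beta, rss, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rss.size == 0:
        rss = np.array([float(np.sum((yw - Xw @ beta) ** 2))])
    return float(rss[0])


def _marker_scan(
    ctx: "MixedModelContext",
    Pr: np.ndarray,
    base_r: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """LOD and coefficients for each marker's founder posterior columns.

    Pr: (n, M, G) rotated (U') founder columns; base_r: rotated covariate
    columns included in both null and alternative models (the whitened
    intercept is always included in the null).  The context's current
    variance weights are applied here, so permutation contexts that
    re-estimate variance components stay consistent.
    Returns (lod (M,), betas (M, G), rss0).
    """
    Pw = ctx.weight(Pr)
    base_w = None if base_r is None else ctx.weight(base_r)
    n, M, G = Pw.shape
    yw = ctx.yw
    null_cols = ctx.ones_w if base_w is None else np.hstack(
        [ctx.ones_w, base_w]
    )
    rss0 = _rss(yw, null_cols)

    # alternative: founder columns replace the intercept (they sum to it);
    # covariates stay.  Solve per-marker normal equations in batch.
    if base_w is None:
        A = np.einsum("nmg,nmh->mgh", Pw, Pw)
        b = np.einsum("nmg,n->mg", Pw, yw)
        betas = np.linalg.solve(
            A + 1e-10 * np.eye(G)[None], b[..., None]
        )[..., 0]
        rss1 = np.einsum("n->", yw**2) - np.einsum("mg,mg->m", betas, b)
    else:
        q = base_w.shape[1]
        A = np.einsum("nmg,nmh->mgh", Pw, Pw)
        B = np.einsum("nmg,nq->mgq", Pw, base_w)
        C = base_w.T @ base_w
        b = np.einsum("nmg,n->mg", Pw, yw)
        c = base_w.T @ yw
        Cinv = np.linalg.pinv(C)
        S = A - B @ Cinv @ B.transpose(0, 2, 1)
        r = b - (B @ (Cinv @ c))
        coef = np.linalg.solve(
            S + 1e-10 * np.eye(G)[None], r[..., None]
        )[..., 0]
        rss_base = float(yw @ yw - c @ Cinv @ c)
        rss1 = rss_base - np.einsum("mg,mg->m", coef, r)
        betas = coef
    rss1 = np.clip(rss1, 1e-12, None)
    lod = (n / 2.0) * np.log10(np.clip(rss0 / rss1, 1.0, None))
    # monomorphic / degenerate designs: zero column variance -> LOD 0
    degenerate = np.ptp(Pw, axis=0).max(axis=1) < 1e-12
    lod[degenerate] = 0.0
    return lod, betas, rss0


@dataclass
class ScanResult:
    table: pd.DataFrame  # marker_id, chromosome, position_bp, lod, varexp
    founder_effects: np.ndarray  # (M, G) deviations from their mean
    thresholds: dict = field(default_factory=dict)
    trait: str = ""

    @property
    def lod(self) -> np.ndarray:
        return self.table["lod"].to_numpy()

    def max_lod(self) -> float:
        return float(self.table["lod"].max())


@dataclass
class QTLPeak:
    chromosome: int
    marker_id: str
    position_bp: int
    lod: float
    interval_bp: tuple[int, int]
    variance_explained: float
    founder_effects: np.ndarray
    above_strong: bool


def loco_kinships(
    posteriors: np.ndarray, chrom_col: np.ndarray
) -> dict[int, KinshipMatrix]:
    """Per-chromosome LOCO kinship matrices from one pass over the data."""
    n, M, G = posteriors.shape
    chroms = np.unique(chrom_col)
    grams = {}
    for c in chroms:
        idx = np.flatnonzero(chrom_col == c)
        Pc = posteriors[:, idx, :].reshape(n, -1)
        grams[int(c)] = (Pc @ Pc.T, len(idx))
    total = sum(g for g, _ in grams.values())
    out = {}
    for c, (g, m) in grams.items():
        out[c] = KinshipMatrix(
            K=(total - g) / (M - m), loco_excluded_chromosome=c
        )
    return out


def _loco_contexts(
    y: np.ndarray,
    posteriors: np.ndarray,
    chrom_col: np.ndarray,
    loco: bool = True,
    K: KinshipMatrix | None = None,
):
    """One (chromosome, marker index, context, rotated P) per chromosome."""
    chroms = np.unique(chrom_col)
    kin = None
    if K is None:
        if loco:
            kin = loco_kinships(posteriors, chrom_col)
        else:
            K = compute_kinship(posteriors)
    out = []
    ctx_global = None
    for c in chroms:
        idx = np.flatnonzero(chrom_col == c)
        if kin is not None:
            ctx = MixedModelContext(y, kin[int(c)])
        else:
            if ctx_global is None:
                ctx_global = MixedModelContext(y, K)
            ctx = ctx_global
        Pr = ctx.rotate(posteriors[:, idx, :])
        out.append((int(c), idx, ctx, Pr))
    return out


def linkage_scan(
    y: np.ndarray,
    posteriors: np.ndarray,
    gmap: GeneticMap,
    loco: bool = True,
    K: KinshipMatrix | None = None,
    trait: str = "",
) -> ScanResult:
    """Genome scan of ``y`` on founder posteriors with kinship correction.

    ``posteriors`` has shape (n_lines, n_markers, 8); nine-state input
    should first go through :func:`drop_ninth_founder`.  Founder effects
    are reported as deviations from their mean (the founder columns sum to
    one, so only contrasts are identifiable).
    """
    y = np.asarray(y, dtype=float)
    n, M, G = posteriors.shape
    if len(y) != n:
        raise ValueError("phenotype length != number of lines")
    chrom_col = gmap.table["chromosome"].to_numpy()
    lod = np.empty(M)
    varexp = np.empty(M)
    betas = np.empty((M, G))
    for c, idx, ctx, Pr in _loco_contexts(y, posteriors, chrom_col, loco, K):
        l, b, rss0 = _marker_scan(ctx, Pr)
        lod[idx] = l
        betas[idx] = b
        varexp[idx] = 1.0 - 10.0 ** (-2.0 * l / n)
    table = gmap.table[["marker_id", "chromosome", "position_bp"]].copy()
    table["lod"] = lod
    table["varexp"] = varexp
    effects = betas - betas.mean(axis=1, keepdims=True)
    return ScanResult(table=table, founder_effects=effects, trait=trait)


def permutation_thresholds(
    y: np.ndarray,
    posteriors: np.ndarray,
    gmap: GeneticMap,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    loco: bool = True,
    reestimate: bool = True,
    strong_pct: float = 99.0,
    suggestive_pct: float = 37.0,
) -> dict:
    """Permutation thresholds from the genome-wide maximum-LOD distribution.

    The raw phenotype is shuffled across lines ``n_perm`` times; each
    permutation is scanned genome-wide and its maximum LOD recorded.  The
    99th percentile of the maxima is the strong threshold (genome-wide
    P < 0.01), the 37th the suggestive one (P < 0.63).  Variance
    components are re-estimated for each permutation unless
    ``reestimate=False``.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    rng = np.random.default_rng(rng)
    y = np.asarray(y, dtype=float)
    chrom_col = gmap.table["chromosome"].to_numpy()
    contexts = _loco_contexts(y, posteriors, chrom_col, loco)
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        yp = rng.permutation(y)
        best = 0.0
        for c, idx, ctx, Pr in contexts:
            ctx_p = ctx.with_phenotype(yp, reestimate=reestimate)
            l, _, _ = _marker_scan(ctx_p, Pr)
            best = max(best, float(l.max()))
        maxima[p] = best
    strong = float(np.percentile(maxima, strong_pct))
    suggestive = float(np.percentile(maxima, suggestive_pct))
    return {"strong": strong, "suggestive": suggestive, "maxima": maxima}


def call_peaks(
    scan: ScanResult,
    suggestive: float,
    strong: float | None = None,
    min_gap_markers: int = 50,
) -> list[QTLPeak]:
    """QTL peaks above the suggestive threshold with -2 LOD intervals.

    Local maxima on the same chromosome are reported as separate peaks
    only when at least ``min_gap_markers`` consecutive markers between
    them fall below the suggestive threshold; the support interval spans
    the nearest flanking markers at 2 LOD below each peak (or the
    chromosome ends).
    """
    peaks: list[QTLPeak] = []
    t = scan.table
    for c, grp in t.groupby("chromosome"):
        lod = grp["lod"].to_numpy()
        bp = grp["position_bp"].to_numpy()
        ids = grp["marker_id"].to_numpy()
        above = lod > suggestive
        if not above.any():
            continue
        # cluster candidate markers: a new cluster starts after a run of
        # >= min_gap_markers consecutive sub-suggestive markers
        idx_above = np.flatnonzero(above)
        clusters = [[idx_above[0]]]
        for i in idx_above[1:]:
            if i - clusters[-1][-1] - 1 >= min_gap_markers:
                clusters.append([i])
            else:
                clusters[-1].append(i)
        for members in clusters:
            members = np.asarray(members)
            peak_i = members[np.argmax(lod[members])]
            peak_lod = lod[peak_i]
            lo = peak_i
            while lo > 0 and lod[lo] > peak_lod - 2.0:
                lo -= 1
            hi = peak_i
            while hi < len(lod) - 1 and lod[hi] > peak_lod - 2.0:
                hi += 1
            gi = grp.index[peak_i]
            peaks.append(
                QTLPeak(
                    chromosome=int(c),
                    marker_id=str(ids[peak_i]),
                    position_bp=int(bp[peak_i]),
                    lod=float(peak_lod),
                    interval_bp=(int(bp[lo]), int(bp[hi])),
                    variance_explained=float(t.loc[gi, "varexp"]),
                    founder_effects=scan.founder_effects[
                        t.index.get_loc(gi)
                    ].copy(),
                    above_strong=(
                        strong is not None and peak_lod > strong
                    ),
                )
            )
    return peaks


def covariate_scan(
    y: np.ndarray,
    posteriors: np.ndarray,
    gmap: GeneticMap,
    covariate_marker: str,
    loco: bool = True,
    trait: str = "",
) -> ScanResult:
    """Genome scan conditioning on the founder columns of one marker.

    The covariate marker's posterior columns enter both the null and the
    alternative model, so its own LOD (and that of markers in perfect LD
    with it) drops to ~0 while independent QTL retain their signal.
    """
    y = np.asarray(y, dtype=float)
    marker_ids = gmap.table["marker_id"].to_numpy()
    hit = np.flatnonzero(marker_ids == covariate_marker)
    if len(hit) == 0:
        raise KeyError(f"covariate marker {covariate_marker!r} not in map")
    cov_idx = int(hit[0])
    n, M, G = posteriors.shape
    chrom_col = gmap.table["chromosome"].to_numpy()
    lod = np.empty(M)
    varexp = np.empty(M)
    betas = np.empty((M, G))
    # drop one founder column of the covariate to avoid collinearity with
    # the tested marker's columns (both sum to one)
    cov_cols = posteriors[:, cov_idx, : G - 1]
    for c, idx, ctx, Pr in _loco_contexts(y, posteriors, chrom_col, loco):
        base_r = ctx.rotate(cov_cols)
        l, b, rss0 = _marker_scan(ctx, Pr, base_r=base_r)
        lod[idx] = l
        betas[idx] = b
        varexp[idx] = 1.0 - 10.0 ** (-2.0 * l / n)
    table = gmap.table[["marker_id", "chromosome", "position_bp"]].copy()
    table["lod"] = lod
    table["varexp"] = varexp
    effects = betas - betas.mean(axis=1, keepdims=True)
    return ScanResult(table=table, founder_effects=effects, trait=trait)
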