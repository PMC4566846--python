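"""Phenotype simulation and power / false-discovery estimation.

Twenty QTL with geometrically decaying effects (QTL i has effect 0.9^i)
are placed at random markers, two per chromosome.  Each QTL's minor
allele is contributed by a random set F of 1-4 founders; a line's
genotype at the QTL condenses its founder posterior to

    f_ij = 2 * sum_{s in F} P_ij(s) - 1   in [-1, 1].

The genetic value is the effect-weighted sum over QTL, standardized to
unit variance, and phenotypes add Gaussian noise so the genetic part
explains h^2 of the total variance.  Mapping uses forward stepwise
selection of founder-posterior regressions tested by a 7-df
likelihood-ratio chi-square; the entry rule is either the nominal
P <= 0.01 or (default for the study) a genome-wide threshold calibrated
as the 99th percentile of the null maximum LOD, the same genome-wide
P < 0.01 convention used for trait permutation thresholds.  A simulated
QTL counts as detected when a selected marker lies within +/- 5 Mb on
its chromosome.
Power and FDR are averaged over runs and minor-allele-frequency settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genome_model import GeneticMap

__all__ = [
    "QTLScenario",
    "SimTruth",
    "PowerTable",
    "condense_founder_genotype",
    "simulate_phenotype",
    "stepwise_map",
    "evaluate_detection",
    "run_power_study",
]


@dataclass
class QTLScenario:
    """One cell of the power-study grid."""

    maf_founders: int
    n_lines: int
    h2: float
    n_qtl: int = 20
    effect_base: float = 0.9
    n_runs: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.h2 <= 1:
            raise ValueError("h2 must be in (0, 1]")
        if self.n_qtl < 1:
            raise ValueError("need at least one QTL")
        if not 1 <= self.maf_founders <= 4:
            raise ValueError("maf_founders must be 1..4")


@dataclass
class SimTruth:
    """Ground truth of one simulated phenotype run."""

    line_rows: np.ndarray  # indices into the posterior array
    qtl_markers: np.ndarray  # (n_qtl,) marker indices
    founder_sets: list[np.ndarray]  # minor-allele founders per QTL
    effects: np.ndarray  # (n_qtl,) 0.9^i
    genetic_values: np.ndarray  # per line, standardized
    explained_variance: np.ndarray  # realized per-QTL fraction of var(y)


def condense_founder_genotype(
    posteriors: np.ndarray, founder_set: np.ndarray
) -> np.ndarray:
    """f = 2 * sum_{s in F} P(s) - 1 for posterior rows.

    +1 for a line entirely from founders in F, -1 entirely outside.
    """
    founder_set = np.asarray(founder_set)
    if founder_set.size == 0:
        raise ValueError("founder set must be non-empty")
    return 2.0 * np.take(posteriors, founder_set, axis=-1).sum(axis=-1) - 1.0


def simulate_phenotype(
    posteriors: np.ndarray,
    gmap: GeneticMap,
    scenario: QTLScenario,
    rng: np.random.Generator | int | None = None,
):
    """Simulate one phenotype vector under a scenario.

    Samples ``n_lines`` lines without replacement, picks two QTL markers
    per chromosome, draws an independent founder set per QTL, builds the
    geometric-effect genetic value, standardizes it, and adds noise so it
    explains h^2 of the phenotypic variance.

    Returns (y, SimTruth).
    """
    rng = np.random.default_rng(rng)
    n_all, M, G = posteriors.shape
    if scenario.n_lines > n_all:
        raise ValueError("not enough reconstructed lines for scenario")
    chrom_col = gmap.table["chromosome"].to_numpy()
    chroms = gmap.chromosomes
    per_chrom = scenario.n_qtl // len(chroms)
    if per_chrom < 1 or scenario.n_qtl % len(chroms):
        raise ValueError(
            f"{scenario.n_qtl} QTL do not spread evenly over "
            f"{len(chroms)} chromosomes"
        )
    rows = rng.choice(n_all, size=scenario.n_lines, replace=False)
    markers = []
    for c in chroms:
        idx = np.flatnonzero(chrom_col == c)
        if len(idx) < per_chrom:
            raise ValueError(f"chromosome {c} has fewer than {per_chrom} markers")
        markers.append(rng.choice(idx, size=per_chrom, replace=False))
    qtl_markers = np.concatenate(markers)
    order = rng.permutation(scenario.n_qtl)  # effect rank independent of chrom
    qtl_markers = qtl_markers[order]

    effects = scenario.effect_base ** np.arange(1, scenario.n_qtl + 1)
    founder_sets = [
        rng.choice(min(G, 8), size=scenario.maf_founders, replace=False)
        for _ in range(scenario.n_qtl)
    ]
    F = np.zeros((scenario.n_qtl, scenario.n_lines))
    for i, (m, fs) in enumerate(zip(qtl_markers, founder_sets)):
        F[i] = condense_founder_genotype(posteriors[rows, m, :], fs)
    g_raw = effects @ F
    sd = g_raw.std()
    if sd == 0:
        sd = 1.0
    g = (g_raw - g_raw.mean()) / sd
    e = rng.standard_normal(scenario.n_lines)
    y = np.sqrt(scenario.h2) * g + np.sqrt(1.0 - scenario.h2) * e
    var_y = y.var()
    contrib = (effects[:, None] * F) * np.sqrt(scenario.h2) / sd
    explained = contrib.var(axis=1) / var_y
    truth = SimTruth(
        line_rows=rows,
        qtl_markers=qtl_markers,
        founder_sets=founder_sets,
        effects=effects,
        genetic_values=g,
        explained_variance=explained,
    )
    return y, truth


# ---------------------------------------------------------------------------
# stepwise mapping


class _StepwiseEngine:
    """Batched forward stepwise founder-posterior regression.

    Works on the intercept + 7 founder-contrast columns per marker.  All
    per-marker cross products are precomputed; each step solves the
    Schur-complement normal equations of [selected columns, marker
    columns] for every marker at once.
    """

    def __init__(self, posteriors: np.ndarray, dtype=np.float32):
        n_all, M, G = posteriors.shape
        self.M = M
        self.G7 = G - 1
        self.P7_all = np.ascontiguousarray(
            posteriors[:, :, : self.G7], dtype=dtype
        )
        # full-population per-marker Gram; subsets subtract the complement
        self.A_all = np.einsum(
            "nmg,nmh->mgh", self.P7_all, self.P7_all
        )
        self.colsum_all = self.P7_all.sum(axis=0)

    def subset(self, rows: np.ndarray):
        n_all = self.P7_all.shape[0]
        comp = np.setdiff1d(np.arange(n_all), rows)
        P7 = self.P7_all[rows]
        if len(comp) <= len(rows):
            Pc = self.P7_all[comp]
            A = self.A_all - np.einsum("nmg,nmh->mgh", Pc, Pc)
            colsum = self.colsum_all - Pc.sum(axis=0)
        else:
            A = np.einsum("nmg,nmh->mgh", P7, P7)
            colsum = P7.sum(axis=0)
        return _StepwiseRun(self, P7, A, colsum)


class _StepwiseRun:
    def __init__(self, engine, P7, A, colsum):
        self.engine = engine
        self.P7 = P7  # (n, M, 7)
        self.A = A  # (M, 7, 7) raw Grams
        self.colsum = colsum  # (M, 7)
        self.n = P7.shape[0]

    def null_max_lod(
        self,
        n_reps: int = 1000,
        rng: np.random.Generator | int | None = None,
        chunk: int = 250,
    ) -> np.ndarray:
        """Genome-wide maximum LOD of ``n_reps`` null phenotypes.

        Under the null the trait is exchangeable across lines, so i.i.d.
        standard-normal draws give the same maximum-LOD distribution as
        permutations of a real trait.  Replicates are processed in
        chunks to bound memory.
        """
        rng = np.random.default_rng(rng)
        n, M, G7 = self.P7.shape
        colsum = self.colsum.astype(np.float64)
        A_res = self.A.astype(np.float64) - np.einsum(
            "mg,mh->mgh", colsum, colsum
        ) / n
        ridge = 1e-9 * np.trace(A_res, axis1=1, axis2=2) + 1e-12
        A_res += ridge[:, None, None] * np.eye(G7)[None]
        out = []
        done = 0
        while done < n_reps:
            k = min(chunk, n_reps - done)
            Y = rng.standard_normal((n, k))
            B = np.tensordot(self.P7, Y.astype(self.P7.dtype), axes=(0, 0))
            B = B.astype(np.float64)  # (M, 7, k)
            ysum = Y.sum(axis=0)
            R = B - colsum[:, :, None] * (ysum[None, None, :] / n)
            coef = np.linalg.solve(A_res, R)
            delta = np.einsum("mgr,mgr->mr", coef, R)
            rss0 = (Y**2).sum(axis=0) - ysum**2 / n
            rss1 = np.clip(rss0[None, :] - delta, 1e-12, None)
            lod = (n / 2.0) * np.log10(
                np.clip(rss0[None, :] / rss1, 1.0, None)
            )
            out.append(lod.max(axis=0))
            done += k
        return np.concatenate(out)

    def fit(
        self,
        y: np.ndarray,
        p_enter: float = 0.01,
        max_steps: int = 30,
        lod_threshold: float | None = None,
    ):
        """Forward selection by sweeping the per-marker normal equations.

        Keeps the per-marker Gram blocks residualized with respect to the
        intercept and every selected marker, so each step costs one
        cross-product pass plus batched 7x7 solves.  Entry is controlled
        by the nominal 7-df likelihood-ratio P value, or, when
        ``lod_threshold`` is given, by the genome-wide maximum LOD
        exceeding that (permutation-calibrated) threshold.
        """
        n, M, G7 = self.P7.shape
        y64 = np.asarray(y, dtype=np.float64)
        yty = float(y64 @ y64)
        ysum = float(y64.sum())
        b = np.tensordot(
            y64.astype(self.P7.dtype), self.P7, axes=(0, 0)
        ).astype(np.float64)  # (M, 7)
        colsum = self.colsum.astype(np.float64)

        # residualize everything on the intercept
        A_res = self.A.astype(np.float64) - np.einsum(
            "mg,mh->mgh", colsum, colsum
        ) / n
        r_res = b - colsum * (ysum / n)
        rss_base = yty - ysum**2 / n
        trace0 = np.trace(A_res, axis1=1, axis2=2)
        eye = np.eye(G7)

        hist: list[tuple[np.ndarray, np.ndarray]] = []  # (U_k, Sinv_k)
        selected: list[int] = []
        lods: list[float] = []
        pvals: list[float] = []
        for _ in range(max_steps):
            # keep enough residual df for a meaningful 7-df test
            if n - (1 + G7 * len(selected)) - G7 < 10 or rss_base <= 1e-9 * yty:
                break
            ridge = 1e-9 * np.trace(A_res, axis1=1, axis2=2) + 1e-12
            coef = np.linalg.solve(
                A_res + ridge[:, None, None] * eye[None], r_res[..., None]
            )[..., 0]
            delta = np.einsum("mg,mg->m", coef, r_res)
            # markers with no residual variance left (collinear with the
            # model) cannot be tested
            delta[np.trace(A_res, axis1=1, axis2=2) < 1e-8 * trace0] = 0.0
            delta = np.clip(delta, 0.0, rss_base)
            best = int(np.argmax(delta))
            rss1 = max(rss_base - delta[best], 1e-9 * yty)
            lrt = n * np.log(rss_base / rss1)
            if not np.isfinite(lrt):
                break
            p = float(chi2.sf(lrt, G7))
            lod = float(n / 2.0 * np.log10(rss_base / rss1))
            if lod_threshold is not None:
                if lod <= lod_threshold:
                    break
            elif p > p_enter:
                break
            selected.append(best)
            lods.append(lod)
            pvals.append(p)
            # sweep the accepted marker out of every remaining block
            S = A_res[best] + (ridge[best]) * eye
            Sinv = np.linalg.inv(S)
            Xk = np.tensordot(
                self.P7[:, best, :], self.P7, axes=(0, 0)
            ).transpose(1, 0, 2).astype(np.float64)  # (M, 7, 7) = P_m' P_k^T?
            # tensordot gives (7, M, 7) = P_k' P_m; transpose to (M, 7k, 7m)
            # then swap to get P_m' P_k per marker
            Xk = Xk.transpose(0, 2, 1)  # (M, 7m, 7k)
            Xk -= np.einsum("mg,h->mgh", colsum, colsum[best]) / n
            for U_j, Sinv_j in hist:
                Xk -= U_j @ (Sinv_j @ U_j[best].T)
            rss_base = float(rss1)
            rb = r_res[best].copy()
            A_res = A_res - Xk @ Sinv @ Xk.transpose(0, 2, 1)
            r_res = r_res - Xk @ (Sinv @ rb)
            hist.append((Xk, Sinv))
        return selected, lods, pvals


def stepwise_map(
    y: np.ndarray,
    posteriors: np.ndarray,
    p_enter: float = 0.01,
    max_steps: int = 30,
    lod_threshold: float | None = None,
    engine: _StepwiseEngine | None = None,
    rows: np.ndarray | None = None,
):
    """Forward stepwise selection of QTL markers.

    Repeatedly scans all markers with the current model and adds the
    highest-LOD marker while it passes the entry rule: nominal 7-df
    likelihood-ratio P value at most ``p_enter``, or, when
    ``lod_threshold`` is given, genome-wide maximum LOD above that
    threshold.  Returns (selected marker indices, per-step LODs,
    per-step P values).
    """
    if engine is None:
        engine = _StepwiseEngine(posteriors)
        rows = np.arange(posteriors.shape[0])
    run = engine.subset(np.asarray(rows))
    return run.fit(
        np.asarray(y, dtype=float), p_enter, max_steps, lod_threshold
    )


def evaluate_detection(
    selected: np.ndarray,
    truth: SimTruth,
    gmap: GeneticMap,
    window_mb: float = 5.0,
):
    """Match selected markers to simulated QTL within +/- window, same
    chromosome, nearest-first and one-to-one.

    Returns (detected boolean per QTL, fdr).
    """
    selected = np.asarray(selected, dtype=int)
    chrom_col = gmap.table["chromosome"].to_numpy()
    bp_col = gmap.table["position_bp"].to_numpy()
    n_qtl = len(truth.qtl_markers)
    detected = np.zeros(n_qtl, dtype=bool)
    if len(selected) == 0:
        return detected, 0.0
    window = window_mb * 1e6
    pairs = []
    for si, s in enumerate(selected):
        for qi, q in enumerate(truth.qtl_markers):
            if chrom_col[s] != chrom_col[q]:
                continue
            dist = abs(int(bp_col[s]) - int(bp_col[q]))
            if dist <= window:
                pairs.append((dist, si, qi))
    pairs.sort()
    used_sel: set[int] = set()
    for dist, si, qi in pairs:
        if si in used_sel or detected[qi]:
            continue
        detected[qi] = True
        used_sel.add(si)
    fdr = (len(selected) - len(used_sel)) / len(selected)
    return detected, fdr


@dataclass
class PowerTable:
    """Aggregated power/FDR of the simulation study."""

    by_scenario: pd.DataFrame
    by_variance_bin: pd.DataFrame
    records: pd.DataFrame


def run_power_study(
    posteriors: np.ndarray,
    gmap: GeneticMap,
    scenarios: list[QTLScenario],
    seed: int | None = None,
    p_enter: float = 0.01,
    max_steps: int = 30,
    window_mb: float = 5.0,
    varexp_bin_pct: float = 2.0,
    entry: str = "permutation",
    threshold_pct: float = 99.0,
    n_null_reps: int = 1000,
) -> PowerTable:
    """Run the full power study over a scenario grid.

    For each scenario, ``n_runs`` independent phenotype simulations are
    mapped by stepwise selection and scored.  Per-QTL records carry the
    realized explained variance, so power can be binned by explained
    variance (bins of ``varexp_bin_pct`` width) and by effect-size
    quartile; scenario cells report power averaged over runs and, in the
    conventional summary, over the four MAF settings per (n, h2).

    ``entry`` selects the stepwise stopping rule: ``"permutation"``
    (default) enters markers while the genome-wide maximum LOD exceeds
    the ``threshold_pct`` percentile of ``n_null_reps`` null scans
    (cached per sample size; 1,000 replicates match the permutation
    count used for trait thresholds); ``"lrt"`` uses the nominal 7-df
    likelihood-ratio P value against ``p_enter``.
    """
    if entry not in ("lrt", "permutation"):
        raise ValueError("entry must be 'lrt' or 'permutation'")
    rng = np.random.default_rng(seed)
    engine = _StepwiseEngine(posteriors)
    recs = []
    run_recs = []
    thresholds: dict[int, float] = {}
    for sc in scenarios:
        lod_thr = None
        if entry == "permutation":
            if sc.n_lines not in thresholds:
                t_rng = np.random.default_rng(rng.integers(2**31))
                rows = t_rng.choice(
                    posteriors.shape[0], size=sc.n_lines, replace=False
                )
                maxima = engine.subset(rows).null_max_lod(
                    n_null_reps, t_rng
                )
                thresholds[sc.n_lines] = float(
                    np.percentile(maxima, threshold_pct)
                )
            lod_thr = thresholds[sc.n_lines]
        for rep in range(sc.n_runs):
            run_rng = np.random.default_rng(rng.integers(2**31))
            y, truth = simulate_phenotype(posteriors, gmap, sc, run_rng)
            run = engine.subset(truth.line_rows)
            selected, lods, pvals = run.fit(y, p_enter, max_steps, lod_thr)
            detected, fdr = evaluate_detection(
                selected, truth, gmap, window_mb
            )
            quart = np.repeat([1, 2, 3, 4], sc.n_qtl // 4)[: sc.n_qtl]
            for i in range(sc.n_qtl):
                recs.append(
                    (
                        sc.maf_founders,
                        sc.n_lines,
                        sc.h2,
                        rep,
                        i + 1,
                        quart[i],
                        truth.explained_variance[i],
                        bool(detected[i]),
                    )
                )
            run_recs.append(
                (sc.maf_founders, sc.n_lines, sc.h2, rep, len(selected), fdr)
            )
    records = pd.DataFrame(
        recs,
        columns=[
            "maf_founders",
            "n_lines",
            "h2",
            "run",
            "qtl_rank",
            "quartile",
            "explained_variance",
            "detected",
        ],
    )
    runs = pd.DataFrame(
        run_recs,
        columns=["maf_founders", "n_lines", "h2", "run", "n_selected", "fdr"],
    )

    by_scenario = (
        records.groupby(["n_lines", "h2"])
        .agg(power=("detected", "mean"))
        .reset_index()
    )
    qpow = (
        records.pivot_table(
            index=["n_lines", "h2"],
            columns="quartile",
            values="detected",
            aggfunc="mean",
        )
        .rename(columns=lambda q: f"power_q{q}")
        .reset_index()
    )
    fdr = (
        runs.groupby(["n_lines", "h2"]).agg(fdr=("fdr", "mean")).reset_index()
    )
    by_scenario = by_scenario.merge(qpow, on=["n_lines", "h2"]).merge(
        fdr, on=["n_lines", "h2"]
    )

    records["varexp_bin_pct"] = (
        np.round(records["explained_variance"] * 100.0 / varexp_bin_pct)
        * varexp_bin_pct
    )
    by_bin = (
        records.groupby(["n_lines", "h2", "varexp_bin_pct"])
        .agg(power=("detected", "mean"), n_qtl=("detected", "size"))
        .reset_index()
    )
    return PowerTable(
        by_scenario=by_scenario, by_variance_bin=by_bin, records=records
    )
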