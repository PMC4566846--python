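"""Founder-mosaic reconstruction from RIL genotype calls.

A hidden Markov model per line and chromosome whose hidden states are the
G homozygous founder genotypes (G = 8, or 9 for lines carrying the
substitution donor).  Emission distributions over the observed symbols
{0, 1, 2} derive from the founder calls at each marker; transition
probabilities between adjacent markers come from the two-point
recombination probability of an eight-way selfing RIL,

    R(r) = r * (4 - r) / (1 + 2 * r),

split equally among the G - 1 alternative founders.  Posterior state
probabilities are computed by a scaled forward-backward pass, and the
emission probabilities are refined by expectation-maximization pooled
across lines.  Observed heterozygous calls are treated as emission noise
against the homozygous hidden states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_model import FounderPanel, GeneticMap, GenotypeMatrix, cm_to_recfrac

__all__ = [
    "transition_probability",
    "init_emissions",
    "forward_backward",
    "em_fit",
    "count_junctions",
    "founder_contribution_per_locus",
    "EmissionModel",
    "TransitionModel",
    "ReconstructionResult",
    "EMResult",
]


def transition_probability(r):
    """State-change probability R(r) = r(4-r)/(1+2r) for an 8-way selfing
    RIL; at the unlinked limit r=0.5 this is 7/8 (two independent loci
    share a founder with probability 1/8)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    R = r * (4.0 - r) / (1.0 + 2.0 * r)
    return float(R) if R.ndim == 0 else R


@dataclass
class TransitionModel:
    """Per-chromosome arrays of state-change probabilities R between
    adjacent markers, for a G-state chain."""

    R: dict[int, np.ndarray]
    n_states: int

    @classmethod
    def from_map(
        cls,
        gmap: GeneticMap,
        n_states: int,
        damping: float = 1.0,
        mode: str = "haldane",
    ) -> "TransitionModel":
        R = {}
        for chrom, grp in gmap.table.groupby("chromosome"):
            d = np.diff(grp["position_cM"].to_numpy(dtype=float))
            r = cm_to_recfrac(d, damping=damping, mode=mode)
            R[int(chrom)] = transition_probability(np.asarray(r))
        return cls(R=R, n_states=n_states)


@dataclass
class EmissionModel:
    """P(observed symbol | founder state) per marker.

    ``probs`` has shape (n_markers, n_states, 3) over symbols {0, 1, 2};
    missing observations are emitted uniformly by all states and carry no
    information.  ``uninformative`` flags markers where every founder call
    was missing.
    """

    probs: np.ndarray
    smoothing: float = 0.01
    uninformative: np.ndarray = field(default=None)

    def likelihood(self, obs: np.ndarray, marker: int) -> np.ndarray:
        """Emission likelihood for observations at one marker.

        ``obs`` is an int array of calls; returns (len(obs), n_states)."""
        out = np.ones((len(obs), self.probs.shape[1]))
        seen = obs >= 0
        out[seen] = self.probs[marker, :, obs[seen]]
        return out


def init_emissions(
    founders: FounderPanel, smoothing: float = 0.01
) -> EmissionModel:
    """Initial emissions from the founder calls.

    A founder homozygous 0 (or 2) puts its mass on that symbol; a
    heterozygous founder call splits the mass 0.5/0.5 between the two
    homozygous symbols; a missing founder call gives a uniform
    distribution (flagged if all founders are missing, which the panel
    forbids anyway).  ``smoothing`` is then added to near-zero entries and
    each state's distribution renormalized, allowing for genotyping error.
    """
    calls = founders.calls
    G, M = calls.shape
    probs = np.empty((M, G, 3))
    base = {
        0: np.array([1.0, 0.0, 0.0]),
        1: np.array([0.5, 0.0, 0.5]),
        2: np.array([0.0, 0.0, 1.0]),
        -1: np.array([1.0, 1.0, 1.0]) / 3.0,
    }
    for code, vec in base.items():
        probs[np.where((calls == code).T)] = vec
    if smoothing > 0:
        probs = _smooth(probs, smoothing)
    uninformative = (calls == -1).all(axis=0)
    return EmissionModel(
        probs=probs, smoothing=smoothing, uninformative=uninformative
    )


def _smooth(probs: np.ndarray, smoothing: float) -> np.ndarray:
    out = probs + np.where(probs < smoothing, smoothing, 0.0)
    return out / out.sum(axis=-1, keepdims=True)


def _chain_posteriors(
    obs: np.ndarray, emis: EmissionModel, R: np.ndarray, marker_idx: np.ndarray
):
    """Scaled forward-backward for a batch of lines on one chromosome.

    obs: (n_lines, M_chrom) calls; R: (M_chrom - 1,) change probabilities;
    marker_idx: global marker indices of this chromosome's markers.
    Returns posteriors (n_lines, M_chrom, G) and per-line log-likelihood.
    """
    n, Mc = obs.shape
    G = emis.probs.shape[1]
    alpha = np.empty((n, Mc, G))
    scale = np.empty((n, Mc))

    a = emis.likelihood(obs[:, 0], marker_idx[0]) / G
    s = a.sum(axis=1)
    s[s == 0] = 1.0
    alpha[:, 0] = a / s[:, None]
    scale[:, 0] = s
    for t in range(1, Mc):
        Rt = R[t - 1]
        stay = 1.0 - Rt - Rt / (G - 1)
        prev = alpha[:, t - 1]
        pred = stay * prev + (Rt / (G - 1)) * prev.sum(axis=1, keepdims=True)
        a = pred * emis.likelihood(obs[:, t], marker_idx[t])
        s = a.sum(axis=1)
        s[s == 0] = 1.0
        alpha[:, t] = a / s[:, None]
        scale[:, t] = s

    beta = np.ones((n, G))
    post = np.empty((n, Mc, G))
    post[:, Mc - 1] = alpha[:, Mc - 1]
    exp_switch = np.zeros(n)
    for t in range(Mc - 2, -1, -1):
        Rt = R[t]
        mix = Rt / (G - 1)
        stay = 1.0 - Rt - mix
        bl = beta * emis.likelihood(obs[:, t + 1], marker_idx[t + 1])
        # posterior expected stay mass across the t -> t+1 interval
        abl = (alpha[:, t] * bl).sum(axis=1)
        denom = stay * abl + mix * bl.sum(axis=1)
        exp_switch += 1.0 - (1.0 - Rt) * abl / denom
        beta = stay * bl + mix * bl.sum(axis=1, keepdims=True)
        beta /= scale[:, t + 1][:, None]
        p = alpha[:, t] * beta
        p /= p.sum(axis=1, keepdims=True)
        post[:, t] = p

    loglik = np.log(scale).sum(axis=1)
    return post, loglik, exp_switch


def forward_backward(
    line_calls: np.ndarray,
    emissions: EmissionModel,
    transitions: TransitionModel,
    gmap: GeneticMap,
):
    """Posterior founder probabilities for a single line, all chromosomes.

    Returns (posteriors (n_markers, G), log-likelihood).  The prior over
    states is uniform (1/G) at the start of every chromosome.
    """
    obs = np.asarray(line_calls)[None, :]
    M = obs.shape[1]
    G = transitions.n_states
    post = np.empty((M, G))
    ll = 0.0
    chrom_col = gmap.table["chromosome"].to_numpy()
    for chrom in gmap.chromosomes:
        idx = np.flatnonzero(chrom_col == chrom)
        p, l, _ = _chain_posteriors(
            obs[:, idx], emissions, transitions.R[chrom], idx
        )
        post[idx] = p[0]
        ll += float(l[0])
    return post, ll


@dataclass
class ReconstructionResult:
    line_id: str
    posteriors: np.ndarray  # (n_markers, G)
    loglik: float
    n_states: int
    #: posterior expected number of recombination events (sum over marker
    #: intervals of the probability that the founder state changes)
    expected_junctions: float = float("nan")


@dataclass
class EMResult:
    emissions: EmissionModel
    results: list[ReconstructionResult]
    loglik_trace: list[float]

    @property
    def n_iter(self) -> int:
        return len(self.loglik_trace) - 1


def em_fit(
    population: GenotypeMatrix,
    founders: FounderPanel,
    gmap: GeneticMap,
    max_iter: int = 20,
    smoothing: float = 0.01,
    resmooth: bool = True,
    damping: float = 1.0,
    mode: str = "haldane",
    tol_frac: float = 1e-3,
) -> EMResult:
    """EM refinement of the emission model with per-line posteriors.

    The E-step runs forward-backward for every line (lines flagged
    nine-founder use the 9-state chain; others the 8-state chain over the
    first eight founders).  The M-step re-estimates each marker x state
    emission distribution from posterior-weighted observed symbols pooled
    across lines, re-applying smoothing by default.  Iteration stops when
    the total log-likelihood changes by less than 1/1000th of its initial
    magnitude (or ``tol_frac``), or at ``max_iter``.
    """
    if founders.n_founders == 8 and any(
        f == "nine-founder" for f in population.pedigree_flags
    ):
        raise ValueError("nine-founder lines need a 9-founder panel")

    obs = population.calls
    n, M = obs.shape
    Gmax = founders.n_founders
    emis = init_emissions(founders, smoothing)
    trans = {
        G: TransitionModel.from_map(gmap, G, damping=damping, mode=mode)
        for G in {8, Gmax}
    }
    flags = np.array(
        [f == "nine-founder" for f in population.pedigree_flags]
    )
    groups = [(8, np.flatnonzero(~flags))]
    if flags.any():
        groups.append((Gmax, np.flatnonzero(flags)))

    chrom_col = gmap.table["chromosome"].to_numpy()
    chrom_idx = [np.flatnonzero(chrom_col == c) for c in gmap.chromosomes]

    post_full = np.zeros((n, M, Gmax))
    loglik_trace: list[float] = []
    prev_ll = None
    for it in range(max_iter + 1):
        total_ll = 0.0
        for G, rows in groups:
            if len(rows) == 0:
                continue
            sub_emis = EmissionModel(
                probs=emis.probs[:, :G], smoothing=smoothing
            )
            for idx in chrom_idx:
                chrom = int(chrom_col[idx[0]])
                p, l, _ = _chain_posteriors(
                    obs[np.ix_(rows, idx)],
                    sub_emis,
                    trans[G].R[chrom],
                    idx,
                )
                post_full[np.ix_(rows, idx, np.arange(G))] = p
                total_ll += float(l.sum())
        loglik_trace.append(total_ll)
        if prev_ll is not None:
            if total_ll < prev_ll - abs(loglik_trace[0]) * 1e-9:
                raise RuntimeError(
                    f"EM log-likelihood decreased at iteration {it}: "
                    f"{prev_ll} -> {total_ll}"
                )
            if abs(total_ll - prev_ll) < abs(loglik_trace[0]) * tol_frac:
                break
        if it == max_iter:
            break
        prev_ll = total_ll

        # M-step: pooled posterior-weighted symbol counts
        new = np.zeros((M, Gmax, 3))
        for sym in range(3):
            mask = obs == sym  # (n, M)
            new[:, :, sym] = np.einsum("nm,nmg->mg", mask, post_full)
        denom = new.sum(axis=2, keepdims=True)
        safe = denom[:, :, 0] > 0
        probs = emis.probs.copy()
        probs[safe] = new[safe] / denom[safe]
        if resmooth:
            probs = _smooth(probs, smoothing)
        emis = EmissionModel(
            probs=probs,
            smoothing=smoothing,
            uninformative=emis.uninformative,
        )

    results = []
    for i, lid in enumerate(population.line_ids):
        G = Gmax if flags[i] else 8
        # per-line loglik not retained per iteration; recompute cheap sum
        results.append(
            ReconstructionResult(
                line_id=lid,
                posteriors=post_full[i, :, :G].copy(),
                loglik=float("nan"),
                n_states=G,
            )
        )
    # fill per-line logliks from a final E pass bookkeeping
    for G, rows in groups:
        if len(rows) == 0:
            continue
        sub_emis = EmissionModel(probs=emis.probs[:, :G], smoothing=smoothing)
        ll_rows = np.zeros(len(rows))
        ej_rows = np.zeros(len(rows))
        for idx in chrom_idx:
            chrom = int(chrom_col[idx[0]])
            _, l, ej = _chain_posteriors(
                obs[np.ix_(rows, idx)], sub_emis, trans[G].R[chrom], idx
            )
            ll_rows += l
            ej_rows += ej
        for j, row in enumerate(rows):
            results[row].loglik = float(ll_rows[j])
            results[row].expected_junctions = float(ej_rows[j])
    return EMResult(emissions=emis, results=results, loglik_trace=loglik_trace)


def count_junctions(
    result: ReconstructionResult,
    gmap: GeneticMap,
    min_prob: float = 0.8,
) -> int:
    """Recombination events as argmax-state changes along a chromosome.

    Markers whose maximum posterior falls below ``min_prob`` (the blending
    zones around junctions, where founders are locally indistinguishable)
    are masked out first; a junction is a change in argmax state between
    consecutive confident markers."""
    post = result.posteriors
    arg = post.argmax(axis=1)
    conf = post.max(axis=1) >= min_prob
    chrom_col = gmap.table["chromosome"].to_numpy()
    n = 0
    for chrom in gmap.chromosomes:
        idx = np.flatnonzero(chrom_col == chrom)
        a = arg[idx][conf[idx]]
        if len(a) > 1:
            n += int(np.sum(a[1:] != a[:-1]))
    return n


def founder_contribution_per_locus(
    results: list[ReconstructionResult], n_founders: int | None = None
) -> np.ndarray:
    """Mean posterior founder contribution at each marker across lines.

    Lines reconstructed with fewer states contribute zero to the missing
    trailing founders.  Rows sum to 1.
    """
    if not results:
        raise ValueError("no reconstructions given")
    G = n_founders or max(r.n_states for r in results)
    M = results[0].posteriors.shape[0]
    acc = np.zeros((M, G))
    for r in results:
        acc[:, : r.n_states] += r.posteriors
    return acc / len(results)
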