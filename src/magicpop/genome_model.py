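"""Genome coordinate system: genetic maps, founder panels, genotype matrices.

Coordinates are 1-based inclusive base pairs; genetic positions are
real-valued centimorgans (cM).  Genotype calls are coded ``0`` (homozygous
reference), ``2`` (homozygous alternate), ``1`` (heterozygous) and ``-1``
(missing), the additive dosage convention of SNP-array pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "FounderPanel",
    "GenotypeMatrix",
    "interpolate_cm",
    "cm_to_recfrac",
    "MapError",
]

VALID_CALLS = (-1, 0, 1, 2)

# recombination-fraction clamp: floor keeps HMM transitions non-degenerate,
# cap keeps loci formally linked
REC_FRAC_FLOOR = 1e-12
REC_FRAC_CAP = 0.499


class MapError(ValueError):
    """Raised for violations of genetic-map ordering/anchoring contracts."""


@dataclass
class GeneticMap:
    """Ordered marker map over chromosomes.

    Parameters
    ----------
    table:
        DataFrame with columns ``marker_id``, ``chromosome`` (int),
        ``position_bp`` (int, 1-based) and ``position_cM`` (float; NaN marks
        an unanchored marker awaiting interpolation).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["marker_id", "chromosome", "position_bp", "position_cM"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise MapError(f"map table missing columns {missing}")
        t = self.table.reset_index(drop=True)
        t["chromosome"] = t["chromosome"].astype(int)
        t["position_bp"] = t["position_bp"].astype(np.int64)
        t["position_cM"] = t["position_cM"].astype(float)
        if (t["position_bp"] < 1).any():
            bad = t.loc[t["position_bp"] < 1, "marker_id"].iloc[0]
            raise MapError(f"position_bp must be >= 1 (marker {bad})")
        if t["marker_id"].duplicated().any():
            dup = t.loc[t["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise MapError(f"duplicate marker id {dup!r}")
        # markers must come sorted by (chromosome, bp) and strictly increasing
        for chrom, grp in t.groupby("chromosome", sort=False):
            bp = grp["position_bp"].to_numpy()
            if np.any(np.diff(bp) <= 0):
                i = int(np.argmax(np.diff(bp) <= 0))
                a, b = grp["marker_id"].iloc[i], grp["marker_id"].iloc[i + 1]
                raise MapError(
                    f"position_bp not strictly increasing on chromosome "
                    f"{chrom} between markers {a!r} and {b!r}"
                )
        self.table = t

    # -- basic accessors -------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.table["chromosome"].unique().tolist())

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    def chrom_slice(self, chrom: int) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom]

    @property
    def is_interpolated(self) -> bool:
        return not self.table["position_cM"].isna().any()

    def total_length_morgans(self) -> float:
        """Total map length in Morgans, summed over chromosomes."""
        if not self.is_interpolated:
            raise MapError("map has unanchored markers; interpolate first")
        tot = 0.0
        for _, grp in self.table.groupby("chromosome"):
            cm = grp["position_cM"]
            tot += (cm.max() - cm.min()) / 100.0
        return tot

    def interpolate(self) -> "GeneticMap":
        return interpolate_cm(self)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.to_csv(path, sep="\t", index=False, na_rep="")

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        t = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
        return cls(t)


def interpolate_cm(gmap: GeneticMap) -> GeneticMap:
    """Fill unanchored cM positions by linear interpolation on physical bp.

    Between consecutive anchored markers the cM position is linear in bp;
    beyond the terminal anchors of a chromosome the map is extrapolated at
    the chromosome's mean cM/bp rate.  Anchored values are left untouched,
    so the operation is idempotent.

    Raises
    ------
    MapError
        If any chromosome has fewer than two anchors, or anchors decrease
        in cM along the chromosome.
    """
    t = gmap.table.copy()
    out_cm = t["position_cM"].to_numpy(dtype=float, copy=True)
    for chrom, grp in t.groupby("chromosome", sort=False):
        idx = grp.index.to_numpy()
        bp = grp["position_bp"].to_numpy(dtype=float)
        cm = grp["position_cM"].to_numpy(dtype=float)
        anchored = ~np.isnan(cm)
        if anchored.sum() < 2:
            raise MapError(
                f"chromosome {chrom} has {int(anchored.sum())} anchored "
                "markers; need at least 2 to interpolate"
            )
        a_bp = bp[anchored]
        a_cm = cm[anchored]
        d = np.diff(a_cm)
        if np.any(d < 0):
            i = int(np.argmax(d < 0))
            ids = grp.loc[grp.index[anchored], "marker_id"].to_numpy()
            raise MapError(
                f"anchors decreasing in cM on chromosome {chrom}: "
                f"{ids[i]!r} ({a_cm[i]} cM) -> {ids[i + 1]!r} ({a_cm[i + 1]} cM)"
            )
        filled = np.interp(bp, a_bp, a_cm)
        # np.interp clamps outside the anchor range; extrapolate instead at
        # the chromosome's mean recombination rate (cM per bp)
        rate = (a_cm[-1] - a_cm[0]) / (a_bp[-1] - a_bp[0])
        left = bp < a_bp[0]
        right = bp > a_bp[-1]
        filled[left] = a_cm[0] - (a_bp[0] - bp[left]) * rate
        filled[right] = a_cm[-1] + (bp[right] - a_bp[-1]) * rate
        filled[anchored] = a_cm
        filled = np.maximum.accumulate(np.clip(filled, 0.0, None))
        filled[anchored] = a_cm
        out_cm[idx] = filled
    t["position_cM"] = out_cm
    return GeneticMap(t)


def cm_to_recfrac(
    d_cm: float | np.ndarray,
    damping: float = 1.0,
    mode: str = "haldane",
) -> float | np.ndarray:
    """Convert a genetic distance in cM to a recombination fraction.

    The default is the Haldane inverse ``r = 0.5 * (1 - exp(-2 d/100))``,
    consistent with the no-interference (Poisson) crossover process used by
    the breeding simulator.  ``mode="linear"`` gives the small-distance
    approximation ``r = d / 100``.  The result is multiplied by ``damping``
    (a tuning factor that can down-weight state switching in the HMM) and
    clamped to ``[1e-12, 0.499]``.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise ValueError("cM distance must be finite and non-negative")
    if mode == "haldane":
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    elif mode == "linear":
        r = d / 100.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    r = np.clip(r * damping, REC_FRAC_FLOOR, REC_FRAC_CAP)
    return float(r) if np.isscalar(d_cm) else r


def _check_calls(calls: np.ndarray, what: str) -> np.ndarray:
    calls = np.asarray(calls, dtype=np.int8)
    bad = ~np.isin(calls, VALID_CALLS)
    if bad.any():
        raise ValueError(
            f"{what} contains invalid call value "
            f"{calls[bad].flat[0]} (allowed: {VALID_CALLS})"
        )
    return calls


@dataclass
class FounderPanel:
    """Genotype calls of the founder inbred lines at the map markers.

    ``calls`` has shape (n_founders, n_markers).  Eight-founder designs use
    labels A..H; a ninth founder (the substitution donor) may be appended.
    """

    founder_ids: list[str]
    calls: np.ndarray
    marker_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = _check_calls(self.calls, "founder panel")
        if len(self.founder_ids) not in (8, 9):
            raise ValueError(
                f"founder count must be 8 or 9, got {len(self.founder_ids)}"
            )
        if self.calls.shape[0] != len(self.founder_ids):
            raise ValueError("calls row count != number of founders")
        if self.marker_ids is not None:
            self.marker_ids = np.asarray(self.marker_ids)
            if len(self.marker_ids) != self.calls.shape[1]:
                raise ValueError("marker_ids length != calls column count")
        all_missing = (self.calls == -1).all(axis=0)
        if all_missing.any():
            raise ValueError(
                f"marker column {int(np.argmax(all_missing))} has no "
                "non-missing founder call"
            )

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]


@dataclass
class GenotypeMatrix:
    """RIL genotype calls (lines x markers) plus per-line pedigree flags.

    ``pedigree_flags`` marks each line ``"eight-founder"`` or
    ``"nine-founder"`` (carrying the substitution donor).
    """

    line_ids: list[str]
    calls: np.ndarray
    marker_ids: np.ndarray | None = None
    pedigree_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = _check_calls(self.calls, "genotype matrix")
        if self.calls.shape[0] != len(self.line_ids):
            raise ValueError("calls row count != number of lines")
        if not self.pedigree_flags:
            self.pedigree_flags = ["eight-founder"] * len(self.line_ids)
        if len(self.pedigree_flags) != len(self.line_ids):
            raise ValueError("pedigree_flags length != number of lines")
        if self.marker_ids is not None:
            self.marker_ids = np.asarray(self.marker_ids)
            if len(self.marker_ids) != self.calls.shape[1]:
                raise ValueError("marker_ids length != calls column count")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def call_rate(self) -> np.ndarray:
        """Per-line fraction of non-missing calls."""
        return (self.calls != -1).mean(axis=1)
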