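"""Readers and writers for the package's plain-text formats.

All tables are TSV.  Genotype files have lines as rows and markers as
columns with cells in {0, 1, 2, NA}; founder panels use the same layout
preceded by a ``#founders`` header row listing the founder labels.
Truth segments are BED-like (0-based half-open in the file; 1-based
inclusive in memory).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .breeding_sim import Homolog, MosaicGenome
from .genome_model import FounderPanel, GeneticMap, GenotypeMatrix

__all__ = [
    "read_map",
    "write_map",
    "read_genotypes",
    "write_genotypes",
    "read_founders",
    "write_founders",
    "read_phenotypes",
    "write_phenotypes",
    "write_truth_segments",
    "read_truth_segments",
    "write_posteriors",
    "read_posteriors",
]


def read_map(path) -> GeneticMap:
    return GeneticMap.from_tsv(path)


def write_map(gmap: GeneticMap, path) -> None:
    gmap.to_tsv(path)


def _calls_to_frame(calls: np.ndarray, index, columns) -> pd.DataFrame:
    df = pd.DataFrame(calls, index=index, columns=columns, dtype="Int64")
    return df.mask(df == -1)


def _frame_to_calls(df: pd.DataFrame) -> np.ndarray:
    vals = df.to_numpy(dtype=float)
    vals = np.where(np.isnan(vals), -1, vals)
    bad = ~np.isin(vals, (-1, 0, 1, 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype call {vals[i, j]!r} at row "
            f"{df.index[i]!r}, column {df.columns[j]!r}"
        )
    return vals.astype(np.int8)


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    cols = (
        genotypes.marker_ids
        if genotypes.marker_ids is not None
        else [f"m{j}" for j in range(genotypes.n_markers)]
    )
    df = _calls_to_frame(genotypes.calls, genotypes.line_ids, cols)
    df.insert(0, "pedigree", genotypes.pedigree_flags)
    df.to_csv(path, sep="\t", index_label="line_id", na_rep="NA")


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="line_id")
    flags = df.pop("pedigree").tolist()
    return GenotypeMatrix(
        line_ids=[str(x) for x in df.index],
        calls=_frame_to_calls(df),
        marker_ids=np.asarray(df.columns, dtype=str),
        pedigree_flags=flags,
    )


def write_founders(founders: FounderPanel, path) -> None:
    path = Path(path)
    cols = (
        founders.marker_ids
        if founders.marker_ids is not None
        else [f"m{j}" for j in range(founders.n_markers)]
    )
    with open(path, "w") as fh:
        fh.write("#founders\t" + "\t".join(founders.founder_ids) + "\n")
        df = _calls_to_frame(founders.calls, founders.founder_ids, cols)
        df.to_csv(fh, sep="\t", index_label="founder_id", na_rep="NA")


def read_founders(path) -> FounderPanel:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "#founders":
            raise ValueError("founder file must start with a '#founders' row")
        labels = header[1:]
        df = pd.read_csv(fh, sep="\t", index_col="founder_id")
    if list(df.index) != labels:
        raise ValueError("founder rows do not match the '#founders' header")
    return FounderPanel(
        founder_ids=labels,
        calls=_frame_to_calls(df),
        marker_ids=np.asarray(df.columns, dtype=str),
    )


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="line_id")
    df.index = df.index.astype(str)
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="line_id", na_rep="NA")


def write_truth_segments(mosaics: list[MosaicGenome], path, founder_ids) -> None:
    """Truth mosaics as BED-like TSV: line chrom start end homolog founder.

    Coordinates in the file are 0-based half-open (BED convention);
    in-memory segments are 1-based inclusive.
    """
    rows = []
    for mos in mosaics:
        for c, pair in sorted(mos.homologs.items()):
            for h, hom in enumerate(pair):
                prev = 0
                for e, f in zip(hom.ends, hom.founders):
                    rows.append(
                        (mos.line_id, c, prev, int(e), h, founder_ids[int(f)])
                    )
                    prev = int(e)
    pd.DataFrame(
        rows,
        columns=["line", "chrom", "start_bp", "end_bp", "homolog", "founder"],
    ).to_csv(path, sep="\t", index=False)


def read_truth_segments(path, founder_ids) -> list[MosaicGenome]:
    df = pd.read_csv(path, sep="\t")
    fidx = {f: i for i, f in enumerate(founder_ids)}
    mosaics = []
    for line, grp in df.groupby("line", sort=False):
        homologs = {}
        for c, cgrp in grp.groupby("chrom"):
            pair = []
            for h in (0, 1):
                hg = cgrp[cgrp["homolog"] == h].sort_values("start_bp")
                ends = hg["end_bp"].to_numpy(dtype=np.int64)
                founders = np.array(
                    [fidx[f] for f in hg["founder"]], dtype=np.int8
                )
                pair.append(Homolog(ends, founders))
            homologs[int(c)] = (pair[0], pair[1])
        mos = MosaicGenome(homologs)
        mos.line_id = str(line)
        mosaics.append(mos)
    return mosaics


def write_posteriors(results, marker_ids, founder_labels, out_dir) -> None:
    """One TSV per line (markers x founders) plus a summary table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = []
    for r in results:
        df = pd.DataFrame(
            r.posteriors,
            index=marker_ids,
            columns=founder_labels[: r.n_states],
        )
        df.to_csv(out_dir / f"{r.line_id}.tsv", sep="\t", index_label="marker_id")
        summary.append(
            (r.line_id, r.loglik, r.n_states, r.expected_junctions)
        )
    pd.DataFrame(
        summary,
        columns=["line_id", "loglik", "n_states", "expected_junctions"],
    ).to_csv(out_dir / "summary.tsv", sep="\t", index=False)


def read_posteriors(out_dir, line_ids=None):
    """Posterior matrices written by :func:`write_posteriors` as an array.

    Returns (line_ids, posterior array (n, M, Gmax), founder labels).
    Lines reconstructed with fewer states are zero-padded.
    """
    out_dir = Path(out_dir)
    summary = pd.read_csv(out_dir / "summary.tsv", sep="\t")
    ids = line_ids or summary["line_id"].astype(str).tolist()
    mats = []
    labels: list[str] = []
    for lid in ids:
        df = pd.read_csv(out_dir / f"{lid}.tsv", sep="\t", index_col="marker_id")
        if len(df.columns) > len(labels):
            labels = [str(c) for c in df.columns]
        mats.append(df.to_numpy())
    G = max(m.shape[1] for m in mats)
    P = np.zeros((len(mats), mats[0].shape[0], G))
    for i, m in enumerate(mats):
        P[i, :, : m.shape[1]] = m
    return ids, P, labels
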