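"""Run configuration, deterministic seeding, and the end-to-end pipeline.

A single master seed drives every stochastic stage; per-stage seeds are
derived by stable hashing of (master seed, stage name, index), so stages
are reproducible independently of each other.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io_formats as io
from .breeding_sim import (
    FunnelDesign,
    genotype_mosaics,
    simulate_founder_panel,
    simulate_funnel_population,
    synthetic_map,
)
from .genome_model import GeneticMap
from .hmm_reconstruct import em_fit
from .phenosim_power import QTLScenario, run_power_study
from .qtl_linkage import (
    call_peaks,
    drop_ninth_founder,
    linkage_scan,
    permutation_thresholds,
)

logger = logging.getLogger("magicpop")

__all__ = ["RunConfig", "derive_seed", "pipeline_run"]


def derive_seed(master: int, stage: str, index: int = 0) -> int:
    """Stable per-stage seed below 2^31 from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    out_dir: str
    seed: int = 0
    # simulation stage (used when no genotype files are given)
    n_markers: int = 5000
    n_funnels: int = 35
    lines_per_funnel: int = 15
    ssd_generations: int = 5
    substitution: bool = True
    error_rate: float = 0.01
    missing_rate: float = 0.15
    # optional input files (override simulation)
    map_file: str | None = None
    founder_file: str | None = None
    genotype_file: str | None = None
    phenotype_file: str | None = None
    trait: str | None = None
    # mapping stage
    n_permutations: int = 1000
    run_scan: bool = False
    # power stage
    run_power: bool = False
    power_n_lines: tuple[int, ...] = (500,)
    power_h2: tuple[float, ...] = (0.7,)
    power_maf: tuple[int, ...] = (1, 2, 3, 4)
    power_runs: int = 25
    em_max_iter: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for attr in ("map_file", "founder_file", "genotype_file",
                     "phenotype_file"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        if self.genotype_file and not (self.map_file and self.founder_file):
            raise ValueError(
                "genotype input needs map_file and founder_file as well"
            )


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def pipeline_run(cfg: RunConfig) -> dict:
    """Execute simulate -> reconstruct -> (scan | power) per the config.

    Writes all artifacts under ``cfg.out_dir`` and returns the manifest
    (also written as ``manifest.json``) with stage timings, record counts
    and output hashes.  Identical config + seed give identical hashes for
    every deterministic stage.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in vars(cfg).items()},
                      "stages": {}}

    def stage(name):
        logger.info("stage %s", name)
        return time.time()

    # --- inputs or simulation -------------------------------------------
    t = stage("simulate")
    design = FunnelDesign(
        n_funnels=cfg.n_funnels,
        lines_per_funnel=cfg.lines_per_funnel,
        ssd_generations=cfg.ssd_generations,
        substitution=cfg.substitution,
    )
    if cfg.genotype_file:
        gmap = io.read_map(cfg.map_file).interpolate()
        founders = io.read_founders(cfg.founder_file)
        genotypes = io.read_genotypes(cfg.genotype_file)
        mosaics = None
    else:
        gmap = (
            io.read_map(cfg.map_file).interpolate()
            if cfg.map_file
            else synthetic_map(cfg.n_markers, seed=derive_seed(cfg.seed, "map"))
        )
        founders = (
            io.read_founders(cfg.founder_file)
            if cfg.founder_file
            else simulate_founder_panel(
                gmap, design, seed=derive_seed(cfg.seed, "founders")
            )
        )
        mosaics = simulate_funnel_population(
            design, gmap, rng=derive_seed(cfg.seed, "population")
        )
        genotypes = genotype_mosaics(
            mosaics,
            founders,
            gmap,
            error_rate=cfg.error_rate,
            missing_rate=cfg.missing_rate,
            rng=derive_seed(cfg.seed, "genotyping"),
        )
        io.write_map(gmap, out / "map.tsv")
        io.write_founders(founders, out / "founders.tsv")
        io.write_genotypes(genotypes, out / "genotypes.tsv")
        io.write_truth_segments(
            mosaics, out / "truth_segments.tsv", design.founder_ids
        )
    manifest["stages"]["simulate"] = {
        "seconds": round(time.time() - t, 2),
        "n_lines": genotypes.n_lines,
        "n_markers": genotypes.n_markers,
    }

    # --- reconstruction --------------------------------------------------
    t = stage("reconstruct")
    fit = em_fit(genotypes, founders, gmap, max_iter=cfg.em_max_iter)
    io.write_posteriors(
        fit.results, gmap.marker_ids, founders.founder_ids, out / "posteriors"
    )
    manifest["stages"]["reconstruct"] = {
        "seconds": round(time.time() - t, 2),
        "em_iterations": fit.n_iter,
        "loglik": fit.loglik_trace[-1],
    }

    Gmax = founders.n_founders
    P = np.zeros((genotypes.n_lines, gmap.n_markers, Gmax))
    for i, r in enumerate(fit.results):
        P[i, :, : r.n_states] = r.posteriors
    P8 = drop_ninth_founder(P)[0] if Gmax == 9 else P

    # --- optional trait scan ---------------------------------------------
    if cfg.run_scan:
        t = stage("scan")
        if not cfg.phenotype_file:
            raise ValueError("run_scan requires a phenotype_file")
        pheno = io.read_phenotypes(cfg.phenotype_file)
        trait = cfg.trait or pheno.columns[0]
        y = pheno.loc[genotypes.line_ids, trait].to_numpy(dtype=float)
        scan = linkage_scan(y, P8, gmap, trait=trait)
        thr = permutation_thresholds(
            y, P8, gmap, n_perm=cfg.n_permutations,
            rng=derive_seed(cfg.seed, "permutations"),
        )
        scan.thresholds = {
            "strong": thr["strong"], "suggestive": thr["suggestive"]
        }
        peaks = call_peaks(scan, thr["suggestive"], thr["strong"])
        scan.table.to_csv(out / f"scan_{trait}.tsv", sep="\t", index=False)
        with open(out / f"thresholds_{trait}.json", "w") as fh:
            json.dump(scan.thresholds, fh, indent=1)
        manifest["stages"]["scan"] = {
            "seconds": round(time.time() - t, 2),
            "trait": trait,
            "n_peaks": len(peaks),
            "max_lod": scan.max_lod(),
        }

    # --- optional power study --------------------------------------------
    if cfg.run_power:
        t = stage("power")
        scenarios = [
            QTLScenario(maf_founders=m, n_lines=n, h2=h, n_runs=cfg.power_runs)
            for n in cfg.power_n_lines
            for h in cfg.power_h2
            for m in cfg.power_maf
        ]
        table = run_power_study(
            P8.astype(np.float32), gmap, scenarios,
            seed=derive_seed(cfg.seed, "power"),
        )
        table.by_scenario.to_csv(out / "power.tsv", sep="\t", index=False)
        table.by_variance_bin.to_csv(
            out / "power_by_varexp.tsv", sep="\t", index=False
        )
        manifest["stages"]["power"] = {
            "seconds": round(time.time() - t, 2),
            "n_scenarios": len(scenarios),
        }

    manifest["outputs"] = {
        p.name: _hash_file(p) for p in sorted(out.glob("*.tsv"))
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
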