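"""End-to-end analysis pipeline: one call reproduces every report table.

:func:`run_all` drives the full workflow on a marker matrix (plus optional
GPS coordinates): primer informativeness, per-population diversity, AMOVA
with permutation test, pairwise Φ_ST and Nei distances, the differentiation
summary (G_ST, G'_ST, Jost D, N_M), PCoA of the pairwise-Φ_ST matrix, the
Mantel isolation-by-distance test on Slatkin-linearized Φ_ST vs great-circle
distance, and the admixture K-scan with the Evanno ΔK table.

Every stochastic stage receives its own child seed spawned from the master
seed with a fixed counter order (AMOVA → pairwise Φ_ST → Mantel → K-scan),
recorded in the JSON manifest, so a rerun with the same master seed is
byte-identical and independent of which stages are enabled downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .admixture import evanno, fit_admixture, pop_membership, run_k_scan, AdmixtureConfig
from .amova import amova_matrix, amova_table, pairwise_fst
from .differentiation import (combined_distance_table, diversity_partition,
                              nei_distance_matrix, slatkin_linearized)
from .diversity import FreqModel, diversity_table
from .informativeness import primer_table
from .marker_data import GeoTable, MarkerMatrix, classify_loci
from .ordination import geographic_distance, mantel, pcoa

log = logging.getLogger("dompop")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    out_dir: str | Path = "dompop_out"
    freq_model: FreqModel = field(default_factory=FreqModel)
    n_perm_amova: int = 10100
    n_perm_mantel: int = 10000
    pcoa_dialect: str = "gower_raw"     # canonical for F_ST-matrix ordination
    k_min: int = 1
    k_max: int = 10
    n_runs: int = 10
    burn_in: int = 1000
    reps: int = 100_000
    run_structure: bool = True
    seed: int | None = None
    precision: int = 3


def _stage_seeds(master: int | None, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(master if master is not None else 0)
    return [int(s) for s in ss.generate_state(n)]


def _write(df: pd.DataFrame, path: Path, precision: int) -> None:
    df.round(precision).to_csv(path, sep="\t")


def run_all(m: MarkerMatrix, geo: GeoTable | None = None,
            cfg: RunConfig | None = None) -> dict:
    """Run the full pipeline; returns results and writes TSV/JSON artifacts."""
    cfg = cfg or RunConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    timings: dict[str, float] = {}
    results: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s started", name)
            try:
                value = fn()
            except Exception:
                log.exception("stage %s failed", name)
                raise RuntimeError(f"pipeline stage {name!r} failed") from None
            timings[name] = time.perf_counter() - t0
            log.info("stage %s done in %.2fs", name, timings[name])
            results[name] = value
            return value
        return deco

    @stage("primer_stats")
    def _primers():
        t = primer_table(m)
        _write(t, out / "primer_stats.tsv", cfg.precision)
        return t

    @stage("diversity")
    def _div():
        t = diversity_table(m, cfg.freq_model)
        _write(t, out / "diversity.tsv", cfg.precision)
        return t

    @stage("amova")
    def _amova():
        res = amova_matrix(m, n_perm=cfg.n_perm_amova, seed=seeds[0])
        _write(amova_table(res), out / "amova.tsv", cfg.precision)
        return res

    @stage("pairwise_fst")
    def _pw():
        fst, pvals = pairwise_fst(m, n_perm=min(cfg.n_perm_amova, 1000),
                                  seed=seeds[1])
        _write(fst, out / "pairwise_fst.tsv", cfg.precision)
        _write(pvals, out / "pairwise_fst_pvalues.tsv", cfg.precision)
        return fst

    fst_matrix = results["pairwise_fst"]

    @stage("nei_distance")
    def _nei():
        nd = nei_distance_matrix(m, cfg.freq_model)
        _write(nd, out / "nei_distance.tsv", cfg.precision)
        combined = combined_distance_table(nd, fst_matrix)
        combined.to_csv(out / "distance_fst_combined.tsv", sep="\t")
        return nd

    @stage("differentiation")
    def _diff():
        summary = diversity_partition(m, cfg.freq_model,
                                      fst=results["amova"].phi_st)
        pd.Series(asdict(summary)).to_json(out / "differentiation.json", indent=2)
        return summary

    @stage("pcoa")
    def _pcoa():
        res = pcoa(fst_matrix, dialect=cfg.pcoa_dialect)
        _write(res.coordinates, out / "pcoa_coordinates.tsv", cfg.precision)
        pd.Series(res.percent, name="pct_variation").round(2).to_csv(
            out / "pcoa_percent.tsv", sep="\t")
        return res

    if geo is not None:
        @stage("mantel")
        def _mantel():
            gd = geographic_distance(geo, m)
            _write(gd, out / "geographic_km.tsv", cfg.precision)
            lin = slatkin_linearized(fst_matrix)
            _write(lin, out / "slatkin_linearized.tsv", cfg.precision)
            res = mantel(gd, lin, n_perm=cfg.n_perm_mantel, seed=seeds[2])
            pd.Series({"r": res.r, "r2": res.r2, "p": res.p_value,
                       "n_perm": res.n_perm}).to_json(
                out / "mantel.json", indent=2)
            return res

    if cfg.run_structure:
        @stage("structure")
        def _structure():
            ks = range(cfg.k_min, cfg.k_max + 1)
            lnp = run_k_scan(m, ks, cfg.n_runs, seed=seeds[3],
                             burn_in=cfg.burn_in, reps=cfg.reps)
            _write(lnp, out / "lnP_runs.tsv", cfg.precision)
            ev = evanno(lnp) if len(list(ks)) >= 3 and cfg.n_runs >= 2 else None
            best_k = None
            if ev is not None:
                _write(ev, out / "evanno.tsv", cfg.precision)
                best_k = ev.attrs["optimal_K"]
            if best_k is not None:
                fit = fit_admixture(m, AdmixtureConfig(
                    K=best_k, burn_in=cfg.burn_in, reps=cfg.reps,
                    seed=seeds[4]))
                _write(fit.Q, out / "Q_matrix.tsv", cfg.precision)
                _write(pop_membership(fit, m.pop_labels),
                       out / "pop_membership.tsv", cfg.precision)
            return {"lnP": lnp, "evanno": ev, "optimal_K": best_k}

    manifest = {
        "dompop_version": __version__,
        "n_samples": m.n_samples,
        "n_loci": m.n_loci,
        "populations": {p: int(s) for p, s in m.pop_sizes.items()},
        "polymorphic_bands": int(classify_loci(m).loc["Total", "PB"]),
        "master_seed": cfg.seed,
        "stage_seeds": {"amova": seeds[0], "pairwise_fst": seeds[1],
                        "mantel": seeds[2], "k_scan": seeds[3],
                        "final_fit": seeds[4]},
        "config": {k: (v if isinstance(v, (int, float, str, bool, type(None)))
                       else str(v)) for k, v in asdict(cfg).items()},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
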