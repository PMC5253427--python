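"""End-to-end orchestration: simulate/load -> distances -> genetics -> tests.

``run_pipeline`` executes the enabled stages in dependency order on one
behaviour subgroup and writes a bundle of CSV/JSON artifacts: distance
matrices, a Mantel summary table (one row per landscape hypothesis x genetic
response), an RCM support matrix with verdicts, DISTLM tables (marginal /
conditional / sequential), a directional migration table with credible
intervals, and a run manifest.  Every numeric output carries the seed and
permutation count in a comment header; a rerun with the same config is
bit-identical.

Unclassified individuals are included in the ``all`` subgroup and excluded
from both behaviour subgroups.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_data import (
    DistanceMatrix,
    GenotypeTable,
    PopulationAttributes,
    read_barriers,
    read_genotypes,
    read_population_attributes,
    read_resistance,
    write_genotypes,
    write_matrix,
)
from .distlm import (
    PredictorSet,
    distlm_conditional,
    distlm_forward,
    distlm_marginal,
    distlm_population_level,
    migration_to_distance,
)
from .errors import ValidationError
from .genetic_distance import pairwise_fst, rousset_ar
from .landscape_distance import barrier_count_matrix, euclidean_matrix, lcp_matrix
from .matrix_stats import mantel, rcm
from .migration_mcmc import MCMCConfig, MigrationMatrix, net_emigration, run_bayesass
from .relatedness import ml_relatedness
from .synthetic_data import SimulationConfig, make_landscape, simulate_genotypes

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, toggles and run plan for one pipeline execution."""

    output_dir: str = "landgenkit_run"
    genotypes: str | None = None  # path; None -> simulate
    genotype_format: str = "csv"
    simulation: SimulationConfig | None = None
    surfaces: dict = field(default_factory=dict)  # surface_id -> path
    barriers: dict = field(default_factory=dict)  # class -> path
    attributes: str | None = None  # population attributes CSV
    subgroup: str = "all"
    seed: int = 0
    n_perm_mantel: int = 100_000
    n_perm_distlm: int = 9_999
    n_perm_rcm: int = 999
    run_relatedness: bool = True
    run_rcm: bool = True
    run_distlm: bool = True
    run_migration: bool = True
    mcmc: MCMCConfig | None = None

    def validate(self) -> None:
        if self.subgroup not in ("all", "migratory", "sedentary"):
            raise ValidationError(f"unknown subgroup {self.subgroup!r}")
        for path in filter(None, [self.genotypes, self.attributes]):
            if not Path(path).exists():
                raise ValidationError(f"input path does not exist: {path}")
        for name, path in {**self.surfaces, **self.barriers}.items():
            if not (isinstance(path, str) and Path(path).exists()) and isinstance(path, str):
                raise ValidationError(f"input path does not exist: {path} ({name})")
        if self.genotypes is None and self.simulation is None:
            raise ValidationError("either a genotype file or a simulation config is required")
        if self.run_migration and self.mcmc is None:
            raise ValidationError("run_migration requires an MCMCConfig")


def _header(cfg: PipelineConfig, extra: str = "") -> str:
    return f"landgenkit {__version__} seed={cfg.seed} {extra}".strip()


def _write_rows(rows: list[dict], path: Path, cfg: PipelineConfig, extra: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_header(cfg, extra)}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all enabled stages; returns the in-memory report bundle."""
    cfg.validate()  # dry-run validation before any computation
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "subgroup": cfg.subgroup,
        "stages": [],
        "skipped": [],
        "inputs": {
            "genotypes": cfg.genotypes,
            "surfaces": {k: str(v) for k, v in cfg.surfaces.items()},
            "barriers": {k: str(v) for k, v in cfg.barriers.items()},
            "attributes": cfg.attributes,
        },
    }
    bundle: dict = {}
    rng_root = np.random.SeedSequence(cfg.seed)
    seeds = rng_root.generate_state(16) % (2**31)

    # ---- stage: load or simulate -----------------------------------------
    surfaces: dict = {}
    simulated_surface = None
    if cfg.genotypes is not None:
        table = read_genotypes(cfg.genotypes, cfg.genotype_format)
        truth = None
    else:
        sim = dataclasses.replace(cfg.simulation, rng_seed=int(seeds[0]))
        if sim.migration_model == "resistance_decay" or cfg.run_rcm:
            simulated_surface, _ = make_landscape(sim)
        table, truth = simulate_genotypes(sim, simulated_surface)
        write_genotypes(table, out / "genotypes.csv", "csv")
        with open(out / "truth.json", "w") as fh:
            json.dump(
                {
                    "migration_matrix": np.asarray(truth.migration_matrix).tolist(),
                    "source_population": truth.source_population,
                    "behaviours": truth.behaviours,
                },
                fh,
                sort_keys=True,
            )
    manifest["stages"].append("load")
    full_table = table

    # behaviour filter applied before any distance computation
    table = table.filter_behaviour(cfg.subgroup)
    if table.n_individuals < 4:
        raise ValidationError(
            f"subgroup {cfg.subgroup!r} has only {table.n_individuals} individuals"
        )
    for sid, src in cfg.surfaces.items():
        surfaces[sid] = read_resistance(src) if isinstance(src, str) else src
    if simulated_surface is not None and not surfaces:
        surfaces["RSF"] = simulated_surface

    # ---- stage: distances -------------------------------------------------
    dists: dict[str, DistanceMatrix] = {}
    dists["IBD"] = euclidean_matrix(table, log_transform=True)
    for sid, surf in surfaces.items():
        dists[f"LCP_{sid}"] = lcp_matrix(table, surf, surface_id=sid).matrix
    for bclass, src in cfg.barriers.items():
        bset = read_barriers(src, bclass) if isinstance(src, str) else src
        dists[f"IBB_{bclass}"] = barrier_count_matrix(table, bset)
    for name, dm in dists.items():
        write_matrix(dm, out / f"dist_{name}.csv", header_comment=_header(cfg))
    manifest["stages"].append("distances")
    bundle["distances"] = dists

    # ---- stage: genetic distances -----------------------------------------
    ar = rousset_ar(table)
    write_matrix(ar, out / "genetic_ar.csv", header_comment=_header(cfg))
    bundle["ar"] = ar
    responses = {"genetic_ar": (ar, "greater")}
    if cfg.run_relatedness:
        rel, _ = ml_relatedness(table)
        write_matrix(rel, out / "relatedness.csv", header_comment=_header(cfg))
        bundle["relatedness"] = rel
        responses["relatedness"] = (rel, "less")
    else:
        manifest["skipped"].append("relatedness")
    manifest["stages"].append("genetics")

    # ---- stage: Mantel table ----------------------------------------------
    mantel_rows = []
    for gi, (gname, (gmat, tail)) in enumerate(responses.items()):
        for di, (dname, dmat) in enumerate(dists.items()):
            res = mantel(
                gmat,
                dmat,
                n_perm=cfg.n_perm_mantel,
                tail=tail,
                seed=int(seeds[1] + 31 * gi + di),
            )
            mantel_rows.append(
                {
                    "hypothesis": dname,
                    "subgroup": cfg.subgroup,
                    "response": gname,
                    "mantel_r": res.r,
                    "p": res.p,
                    "tail": tail,
                    "n_perm": res.n_perm,
                }
            )
    _write_rows(mantel_rows, out / "mantel_table.csv", cfg, f"n_perm={cfg.n_perm_mantel}")
    manifest["stages"].append("mantel")
    bundle["mantel"] = mantel_rows

    # ---- stage: RCM --------------------------------------------------------
    if cfg.run_rcm and len(dists) >= 2:
        support = rcm(ar, dists, n_perm=cfg.n_perm_rcm, seed=int(seeds[2]))
        k = len(support.model_labels)
        with open(out / "rcm_support.csv", "w") as fh:
            fh.write(f"# {_header(cfg, f'n_perm={cfg.n_perm_rcm}')}\n")
            fh.write("alternative\\principal," + ",".join(support.model_labels) + "\n")
            for i in range(k):
                fh.write(
                    support.model_labels[i]
                    + ","
                    + ",".join(repr(float(v)) for v in support.entries[i])
                    + "\n"
                )
        _write_rows(
            [
                {"model": lab, "verdict": support.verdicts[lab]}
                for lab in support.model_labels
            ],
            out / "rcm_verdicts.csv",
            cfg,
        )
        bundle["rcm"] = support
        manifest["stages"].append("rcm")
    elif cfg.run_rcm:
        manifest["skipped"].append("rcm (needs >= 2 model matrices)")
    else:
        manifest["skipped"].append("rcm")

    # ---- stage: DISTLM -----------------------------------------------------
    if cfg.run_distlm:
        data = pd.DataFrame(
            {
                "longitude": table.x,
                "latitude": table.y,
                "local_population": table.population_ids,
            }
        )
        if len(set(table.du_ids)) > 1:
            data["DU"] = table.du_ids
        if table.covariates is not None:
            for col in table.covariates.columns:
                data[col] = table.covariates[col].to_numpy()
        preds = PredictorSet(
            data=data,
            unit_labels=list(table.individual_ids),
            groups={"coordinates": ["longitude", "latitude"]},
        )
        marg = distlm_marginal(ar, preds, n_perm=cfg.n_perm_distlm, seed=int(seeds[3]))
        cond = distlm_conditional(
            ar, preds, covariates="coordinates", n_perm=cfg.n_perm_distlm, seed=int(seeds[4])
        )
        seq = distlm_forward(ar, preds, n_perm=cfg.n_perm_distlm, seed=int(seeds[5]))
        rows = [
            {
                "predictor": r.predictor,
                "test": r.test_type,
                "pseudo_F": r.pseudo_F,
                "p": r.p,
                "pct_var": r.pct_var,
            }
            for r in marg + cond + seq
        ]
        _write_rows(rows, out / "distlm.csv", cfg, f"n_perm={cfg.n_perm_distlm}")
        bundle["distlm"] = rows
        manifest["stages"].append("distlm")
    else:
        manifest["skipped"].append("distlm")

    # ---- stage: population level (F_ST + migration MCMC) -------------------
    if cfg.run_migration:
        fst = pairwise_fst(full_table)
        write_matrix(fst, out / "fst.csv", header_comment=_header(cfg))
        mcmc = dataclasses.replace(cfg.mcmc, seed=int(seeds[6]))
        mig, trace = run_bayesass(full_table, mcmc)
        rows = mig.to_table()
        for r in rows:
            r["net_emigration_of_source"] = net_emigration(mig, r["source"])
        _write_rows(rows, out / "migration.csv", cfg, f"n_iter={mcmc.n_iter}")
        bundle["migration"] = mig
        bundle["fst"] = fst
        # population-level DISTLM when attributes are available
        attrs = None
        if cfg.attributes:
            attrs = read_population_attributes(cfg.attributes)
        elif cfg.simulation is not None:
            sim = cfg.simulation
            cents = sim.centroids()
            attrs = PopulationAttributes(
                population_ids=[f"pop{k + 1}" for k in range(sim.n_populations)],
                n_census=np.asarray(sim.pop_sizes, dtype=float),
                n_effective=np.asarray(sim.pop_sizes, dtype=float),
                centroid_x=cents[:, 0],
                centroid_y=cents[:, 1],
            )
        if attrs is not None and len(fst.labels) >= 4:
            order = [attrs.population_ids.index(p) for p in fst.labels]
            cents = np.column_stack([attrs.centroid_x[order], attrs.centroid_y[order]])
            geo = DistanceMatrix(
                labels=fst.labels,
                values=np.hypot(
                    cents[:, None, 0] - cents[None, :, 0],
                    cents[:, None, 1] - cents[None, :, 1],
                ),
                kind="euclidean",
            )
            m1 = migration_to_distance(mig.mean, mig.labels, "upper").align(fst.labels)
            m2 = migration_to_distance(mig.mean, mig.labels, "lower").align(fst.labels)
            pop_rows = []
            try:
                res = distlm_population_level(
                    fst, m1, m2, attrs, geo, n_perm=cfg.n_perm_distlm, seed=int(seeds[7])
                )
            except ValidationError as e:
                # e.g. constant N_e/N_c across populations -> singular design
                manifest["skipped"].append(f"distlm_population ({e})")
                res = {}
            for resp, tables in res.items():
                for ttype, rws in tables.items():
                    for r in rws:
                        pop_rows.append(
                            {
                                "response": resp,
                                "test": ttype,
                                "predictor": r.predictor,
                                "pseudo_F": r.pseudo_F,
                                "p": r.p,
                                "pct_var": r.pct_var,
                            }
                        )
            if pop_rows:
                _write_rows(pop_rows, out / "distlm_population.csv", cfg)
                bundle["distlm_population"] = pop_rows
        manifest["stages"].append("migration")
    else:
        manifest["skipped"].append("migration")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    bundle["manifest"] = manifest
    return bundle
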