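"""End-to-end orchestration: simulate or load data, run the genetic and
phenotypic analyses in dependency order, and emit table-shaped reports.

Stage order: genotypes -> heterozygosity / relatedness / g2 ->
timing + centroid matrices -> Mantel battery; condition covariates ->
model fits -> shrinkage refit -> residual diagnostics.  Every output
CSV carries a provenance header line (package version, seed, config
hash).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .bayes import (
    McmcSettings,
    fit_beta_fat,
    fit_negbin,
    predicted_day_difference,
    residual_plot_data,
    shrinkage_refit,
)
from .design import Covariate, DesignSpec
from .genotypes import GenotypeTable, read_genotype_table
from .mantel import mantel_test, partial_mantel_test
from .matrices import write_matrix_csv
from .migration import correct_to_earliest, timing_distance_matrix
from .popgen import fis_by_group, g2_identity_disequilibrium, heterozygosity_profile
from .relatedness import queller_goodnight
from .simulate import SimConfig, simulate_dataset

log = logging.getLogger("hetmig")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    out_dir: str = "hetmig_out"
    seed: int = 0
    simulate: bool = True
    genotypes_path: Optional[str] = None
    migration_path: Optional[str] = None
    condition_path: Optional[str] = None
    n_permutations: int = 10_000
    n_boot: int = 1000
    g2_permutations: int = 1000
    n_chains: int = 4
    n_iter: int = 10_000
    age_degree: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Flat key = value config file; '#' starts a comment."""
        kw: dict = {}
        types = {f.name: f.type for f in __import__("dataclasses").fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, val = (s.strip() for s in line.partition("="))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown setting {key!r}")
            t = types[key]
            if t == "int":
                kw[key] = int(val)
            elif t == "bool":
                kw[key] = val.lower() in ("1", "true", "yes", "on")
            else:
                kw[key] = val
        return cls(**kw)

    def config_hash(self) -> str:
        # hash the analysis settings only, not where the outputs land
        d = asdict(self)
        d.pop("out_dir", None)
        d.pop("log_level", None)
        return hashlib.md5(json.dumps(d, sort_keys=True).encode()).hexdigest()[:10]


def _write(df: pd.DataFrame, path: Path, cfg: RunConfig, index: bool = False) -> None:
    header = f"# hetmig {__version__} seed={cfg.seed} config={cfg.config_hash()}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=index, float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the requested stages end-to-end; returns a dict of in-memory
    results keyed by report name."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # ---- inputs --------------------------------------------------------
    if cfg.simulate:
        sim_cfg = SimConfig(seed=cfg.seed)
        table, truth, migration, condition = simulate_dataset(sim_cfg, out / "data")
        results["truth"] = truth
    else:
        if not cfg.genotypes_path:
            raise ValueError("genotypes_path required when simulate is off")
        table = read_genotype_table(cfg.genotypes_path)
        migration = pd.read_csv(cfg.migration_path, comment="#") if cfg.migration_path else None
        condition = pd.read_csv(cfg.condition_path, comment="#") if cfg.condition_path else None

    # ---- genotype statistics ------------------------------------------
    log.info("genotype statistics: %d individuals x %d loci (%.1f%% complete)",
             table.n_individuals, table.n_loci, 100 * table.completeness())
    prof = heterozygosity_profile(table)
    _write(prof.to_frame(), out / "heterozygosity.csv", cfg, index=True)
    g2 = g2_identity_disequilibrium(table, cfg.g2_permutations, seed=cfg.seed)
    fis_vals = fis_by_group(table) if table.group else {}
    geno_stats = pd.DataFrame(
        [{"statistic": "g2", "value": g2.g2, "p_value": g2.p_value}]
        + [{"statistic": f"fis_{g}", "value": v, "p_value": np.nan} for g, v in fis_vals.items()]
    )
    _write(geno_stats, out / "genotype_stats.csv", cfg)
    results["genotype_stats"] = geno_stats

    rel = queller_goodnight(table)
    write_matrix_csv(rel.as_pairwise(), out / "relatedness_qg.csv")
    results["relatedness"] = rel

    # ---- Mantel battery (relatedness vs timing distances) -------------
    mantel_rows = []
    if migration is not None:
        mig = migration.set_index("id")
        from .migration import RangeCentroids, centroid_distance_matrix

        cents = None
        if {"winter_x", "winter_y", "summer_x", "summer_y"}.issubset(mig.columns):
            cents = RangeCentroids(
                winter={i: (row["winter_x"], row["winter_y"]) for i, row in mig.iterrows()},
                summer={i: (row["summer_x"], row["summer_y"]) for i, row in mig.iterrows()},
            )
        for metric in ("spring_start", "spring_end", "fall_start", "fall_end"):
            if metric not in mig.columns:
                continue
            dates = {i: (None if pd.isna(v) else float(v)) for i, v in mig[metric].items()}
            try:
                tdm = timing_distance_matrix(dates)
            except ValueError:
                continue
            shared = [i for i in tdm.ids if i in rel.ids]
            if len(shared) < 4:
                continue
            a = rel.as_pairwise().align(shared)
            b = tdm.align(shared)
            res = mantel_test(a, b, cfg.n_permutations, cfg.n_boot, seed=cfg.seed)
            mantel_rows.append(
                {"metric": metric, "conditioning": "none", "r": res.r,
                 "ci_lower": res.ci_lower, "ci_upper": res.ci_upper, "p": res.p_value}
            )
            if cents is not None:
                for season in ("winter", "summer"):
                    cdm = centroid_distance_matrix(cents, season).align(shared)
                    pres = partial_mantel_test(
                        a, b, cdm, cfg.n_permutations, cfg.n_boot, seed=cfg.seed
                    )
                    mantel_rows.append(
                        {"metric": metric, "conditioning": f"{season}_distance",
                         "r": pres.r, "ci_lower": pres.ci_lower,
                         "ci_upper": pres.ci_upper, "p": pres.p_value}
                    )
        mantel_df = pd.DataFrame(mantel_rows)
        _write(mantel_df, out / "table2_mantel.csv", cfg)
        results["mantel"] = mantel_df

    # ---- negative-binomial migration model (Table-1-like) -------------
    mcmc = McmcSettings(n_chains=cfg.n_chains, n_iter=cfg.n_iter)
    if migration is not None and condition is not None:
        per_ind = condition.drop_duplicates("id").set_index("id")
        mig = migration.set_index("id")
        sub = mig[mig.get("mtdna_sequenced", True) & mig["fall_end"].notna()].index
        sub = [i for i in sub if i in per_ind.index]
        if len(sub) >= 10:
            dat = per_ind.loc[sub, ["age", "winter_range", "haplogroup"]].copy()
            counts = correct_to_earliest(
                {i: float(mig.loc[i, "fall_end"]) for i in sub}
            )
            dat["fall_end_days"] = [counts[i] for i in sub]
            spec = DesignSpec(
                response="fall_end_days",
                covariates=[
                    Covariate("age", "continuous", standardized=True),
                    Covariate("winter_range", "dummy_set", reference="NM"),
                    Covariate("haplogroup", "dummy_set", reference="1"),
                ],
            )
            fit = fit_negbin(spec, dat.reset_index(), mcmc, seed=cfg.seed)
            tbl1 = fit.summary.loc[fit.coef_names, ["median", "p_neg", "p_pos"]]
            _write(tbl1, out / "table1_negbin_fall_termination.csv", cfg, index=True)
            results["negbin_fit"] = fit
            hap_cols = [c for c in fit.coef_names if c.startswith("haplogroup[")]
            if hap_cols:
                dd = predicted_day_difference(fit, hap_cols[0])
                results["day_difference"] = dd
                log.info("haplogroup day shift: %d days (raw %.2f)", dd.days, dd.raw)

    # ---- hierarchical beta fat model (Table-3-like) --------------------
    if condition is not None:
        cond = condition.copy()
        prof_slh = prof.slh
        for locus in prof_slh.columns:
            col = cond["id"].map(prof_slh[locus])
            cond[f"slh_{locus}"] = col.fillna(col.mean())
        spec3 = DesignSpec(
            response="fat_fraction" if "fat_fraction" in cond else "fat_percent",
            covariates=[
                Covariate("age", "continuous", standardized=True, degree=cfg.age_degree),
                Covariate("march_capture", "binary"),
                Covariate("winter_range", "dummy_set", reference="NM"),
            ]
            + [Covariate(f"slh_{locus}", "binary") for locus in prof_slh.columns],
            random_intercept="id",
        )
        fit3 = fit_beta_fat(spec3, cond, mcmc, seed=cfg.seed)
        tbl3 = fit3.summary.loc[fit3.coef_names, ["median", "p_neg", "p_pos"]]
        _write(tbl3, out / "table3_beta_fat.csv", cfg, index=True)
        results["beta_fit"] = fit3
        refit, comparison = shrinkage_refit(fit3, "auto", mcmc, seed=cfg.seed)
        _write(comparison, out / "table3_shrinkage_comparison.csv", cfg)
        results["shrinkage"] = comparison
        _write(residual_plot_data(fit3), out / "beta_fat_residuals.csv", cfg)

    log.info("pipeline complete; outputs in %s", out)
    return results
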