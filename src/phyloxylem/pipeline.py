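"""End-to-end orchestration of the comparative analysis.

Stages, in order: load (or simulate) tree and traits -> square-root
transform of tissue fractions and log10 vessel metrics -> descriptive
summaries -> Pagel's lambda per fraction -> bivariate trait x climate
battery -> three-step model selection per fraction -> independent-contrast
correlations -> latitude regressions (phylogenetic and ordinary) ->
phylogeny/climate variance partition at the configured tree cuts.  Every
run writes a manifest with the config hash, seed, package version, stage
outputs and warning counts; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pgls import bivariate_battery, pgls_fit
from .pic import IndependentContrasts, pic_correlation
from .partition import partition_suite
from .selection import select_model
from .signal import lambda_table
from .simulate import SimConfig, simulate_dataset
from .traits import (
    CLIMATE_INDICES,
    FRACTION_COLUMNS,
    load_traits,
    match_tree_and_table,
    sqrt_fractions,
    summarize,
    vessel_metrics,
)
from .tree import read_newick

logger = logging.getLogger(__name__)

_version = "0.1.0"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Declarative configuration of a full run.

    Exactly one of (``tree_path`` + ``traits_path``) or ``simulate`` must
    be given.
    """

    tree_path: str | None = None
    traits_path: str | None = None
    simulate: SimConfig | dict | None = None
    column_map: dict | None = None
    sqrt_transform: bool = True
    r2_threshold: float = 0.02
    cut_times: tuple[float, ...] = (59.0, 28.0)
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        has_paths = self.tree_path is not None or self.traits_path is not None
        has_sim = self.simulate is not None
        if has_paths == has_sim:
            raise ValueError("exactly one of input paths or a simulate block required")
        if has_paths and (self.tree_path is None or self.traits_path is None):
            raise ValueError("both tree_path and traits_path are required")
        if isinstance(self.simulate, dict):
            self.simulate = SimConfig(**self.simulate)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def latitude_models(traits: pd.DataFrame, latitude, C, columns=None) -> pd.DataFrame:
    """Per-trait regressions on midpoint latitude, with (PGLS) and without
    (OLS) the phylogenetic correlation structure — the dual-line
    comparison.  Returns slope, p and AIC for both models per trait."""
    columns = list(columns or traits.columns)
    lat = np.asarray(latitude, dtype=float)
    rows = []
    for trait in columns:
        y = traits[trait].astype(float)
        mask = y.notna() & np.isfinite(lat)
        yv = y[mask].to_numpy()
        xv = lat[np.asarray(mask)]
        sub = C.subset(list(y[mask].index))
        phy = pgls_fit(yv, xv[:, None], sub)
        ols = pgls_fit(yv, xv[:, None], None)
        rows.append(
            {
                "trait": trait,
                "n": len(yv),
                "slope_pgls": phy.coef_[0],
                "p_pgls": phy.p_values_[1],
                "aic_pgls": phy.aic_,
                "r2_phy": phy.r2_phy_,
                "slope_ols": ols.coef_[0],
                "p_ols": ols.p_values_[1],
                "aic_ols": ols.aic_,
                "pgls_aic_lower": phy.aic_ < ols.aic_,
            }
        )
    return pd.DataFrame(rows).set_index("trait")


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str):
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, float_format="%.10g")


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    All tables are also written under ``cfg.out_dir``.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    manifest: dict = {
        "config_hash": chash,
        "seed": cfg.seed,
        "version": _version,
        "stages": {},
        "warnings": {},
    }
    ground_truth = None

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                with open(out / "manifest.json", "w") as fh:
                    json.dump(manifest, fh, indent=2, default=str)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
            return result

        return deco

    # -- load or simulate --------------------------------------------------
    if cfg.simulate is not None:
        sim = dataclasses.replace(cfg.simulate, seed=cfg.seed)
        ds = simulate_dataset(sim)
        tree, table = ds.tree, ds.table
        ground_truth = ds.ground_truth
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(ground_truth, fh, indent=2, default=str)
        manifest["stages"]["input"] = {"status": "ok", "source": "simulated"}
    else:
        tree = read_newick(cfg.tree_path)
        table = load_traits(cfg.traits_path, column_map=cfg.column_map)
        tree, table = match_tree_and_table(tree, table)
        manifest["warnings"]["species_dropped_tree"] = table.attrs.get(
            "n_dropped_tree", 0
        )
        manifest["warnings"]["species_dropped_table"] = table.attrs.get(
            "n_dropped_table", 0
        )
        manifest["stages"]["input"] = {"status": "ok", "source": "files"}

    species = tree.tip_labels
    table = table.loc[species]
    fractions = [c for c in FRACTION_COLUMNS if c in table.columns]
    climate_cols = [c for c in CLIMATE_INDICES if c in table.columns]
    C = tree.vcv(species)

    # -- transform ---------------------------------------------------------
    work = sqrt_fractions(table, fractions) if cfg.sqrt_transform else table.copy()
    if {"A", "N"} <= set(table.columns):
        vm = vessel_metrics(table["A"].to_numpy(), table["N"].to_numpy())
        work["logF"], work["logS"] = vm.logF, vm.logS

    # -- summaries (raw percent scale) -------------------------------------
    summary = stage("summary")(
        lambda: summarize(table, fractions + [c for c in ("A", "N") if c in table])
    )
    _write_csv(summary, out / "summary.csv", chash)

    # -- phylogenetic signal ----------------------------------------------
    lam = stage("signal")(lambda: lambda_table(work, fractions, C))
    _write_csv(lam, out / "lambda.csv", chash)

    # -- bivariate battery -------------------------------------------------
    biv = stage("bivariate")(
        lambda: bivariate_battery(work[fractions], table[climate_cols], C)
    )
    _write_csv(biv.set_index(["trait", "climate"]), out / "bivariate.csv", chash)

    # -- three-step selection ----------------------------------------------
    def _select():
        traces, rows = {}, []
        selected = {}
        for trait in fractions:
            trace, final = select_model(
                work[trait].to_numpy(),
                table[climate_cols],
                C,
                r2_threshold=cfg.r2_threshold,
            )
            traces[trait] = trace
            selected[trait] = trace["final"]["model"]
            for term, b, f, p in zip(
                final.term_names_, final.beta_, final.f_values_, final.p_values_
            ):
                rows.append(
                    {
                        "trait": trait,
                        "term": term,
                        "beta": b,
                        "F": f,
                        "p": p,
                        "r2_phy": final.r2_phy_,
                        "aic": final.aic_,
                        "df_resid": final.df_resid_,
                    }
                )
        return traces, selected, pd.DataFrame(rows)

    traces, selected, final_models = stage("selection")(_select)
    with open(out / "selection_trace.json", "w") as fh:
        json.dump(traces, fh, indent=2, default=str)
    _write_csv(final_models.set_index(["trait", "term"]), out / "top_models.csv", chash)

    # -- independent contrasts ---------------------------------------------
    def _pic():
        ic = IndependentContrasts(tree=tree)
        ctab = ic.transform(work[fractions])
        return ctab, pic_correlation(ctab)

    ctab, corr = stage("pic")(_pic)
    _write_csv(ctab, out / "contrasts.csv", chash)
    _write_csv(corr["r"], out / "pic_correlation.csv", chash)
    _write_csv(corr["r_origin"], out / "pic_correlation_origin.csv", chash)

    # -- latitude models ---------------------------------------------------
    lat_cols = fractions + [c for c in ("logF", "logS") if c in work.columns]
    latmod = stage("latitude")(
        lambda: latitude_models(work[lat_cols], table["lat_mid"], C)
    )
    _write_csv(latmod, out / "latitude_models.csv", chash)

    # -- variance partition ------------------------------------------------
    part = stage("partition")(
        lambda: partition_suite(
            work[fractions],
            table[climate_cols],
            tree,
            cut_times=cfg.cut_times,
            predictors={t: selected.get(t, []) for t in fractions},
        )
    )
    _write_csv(part.set_index(["trait", "cut_time"]), out / "partition.csv", chash)

    manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.is_file())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
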