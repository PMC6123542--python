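"""Configuration-driven end-to-end runs.

A :class:`RunConfig` (usually loaded from YAML) describes either a
simulated cohort or input files, plus the preprocessing, quantification,
multivariate, univariate and network settings.  :func:`run_pipeline`
executes the fixed stage order

    simulate/read -> excise -> bin -> PQN -> integrate
    -> OPLS-DA per contrast -> stats -> networks per group

writes every intermediate as TSV/CSV/GraphML under the output directory,
and records a manifest (config echo, stage log, file list).  Re-running
the same config reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations, opls, quantify, stats, synthdata
from .binning import adaptive_bin
from .normalize import pareto_scale, pqn_normalize
from .spectra import excise_region, read_annotations, read_matrix_csv, write_annotations, write_matrix_csv

__all__ = ["RunConfig", "load_config", "run_pipeline"]


@dataclass
class RunConfig:
    out: str
    simulate: dict | None = None  # {matrix, groups: [{label, n}], seed, ...}
    input: dict | None = None  # {spectra, annotations}
    excise: list[tuple[float, float]] = field(default_factory=lambda: [(4.54, 5.18)])
    binning: dict = field(default_factory=dict)  # min_width, max_width, min_prominence
    pqn: dict = field(default_factory=lambda: {"reference": "median-all"})
    assignments: str = "default"
    contrasts: list[tuple[str, str]] = field(default_factory=list)
    opls: dict = field(default_factory=lambda: {"n_orth": 1, "repeats": 20, "n_perm": 0, "seed": 0})
    network: dict = field(default_factory=lambda: {"threshold": 0.6, "reactions": "default"})

    def validate(self) -> None:
        if (self.simulate is None) == (self.input is None):
            raise ValueError("config must provide exactly one of 'simulate' or 'input'")
        if not self.contrasts:
            raise ValueError("config must list at least one contrast")
        for pair in self.contrasts:
            if len(pair) != 2:
                raise ValueError(f"contrast must be a (group_a, group_b) pair, got {pair}")
        for lo, hi in self.excise:
            if not lo < hi:
                raise ValueError(f"excision interval must have lo < hi, got ({lo}, {hi})")
        if self.simulate is not None:
            if "matrix" not in self.simulate or "groups" not in self.simulate:
                raise ValueError("simulate config needs 'matrix' and 'groups'")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["excise"] = [tuple(x) for x in raw.get("excise", [(4.54, 5.18)])]
    raw["contrasts"] = [tuple(x) for x in raw.get("contrasts", [])]
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _simulate(cfg: RunConfig):
    sim = dict(cfg.simulate)
    matrix = sim.pop("matrix")
    groups = [(g["label"], int(g["n"])) for g in sim.pop("groups")]
    library = synthdata.load_default_library(matrix)
    effects = synthdata.load_default_effects(matrix)
    axis_cfg = sim.pop("axis", {})
    axis = synthdata.default_axis(**axis_cfg)
    design = synthdata.design_from_effects(effects, groups=groups, **sim)
    return synthdata.simulate_cohort(library, design, axis)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    cfg.validate()
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": [], "files": {}}

    def stage(name: str):
        t0 = time.perf_counter()

        def done(**extra):
            manifest["stages"].append(
                {"stage": name, "seconds": round(time.perf_counter() - t0, 3), **extra}
            )

        return done

    try:
        # --- acquire spectra
        done = stage("acquire")
        truth = None
        if cfg.simulate is not None:
            spectra, truth = _simulate(cfg)
            files = synthdata.write_fixture(spectra, truth, out)
            manifest["files"].update({k: str(v) for k, v in files.items()})
        else:
            ann = read_annotations(cfg.input["annotations"])
            spectra = read_matrix_csv(cfg.input["spectra"], ann)
            write_matrix_csv(spectra, out / "spectra.csv")
            write_annotations(spectra, out / "annotations.tsv")
        matrix_kind = spectra.annotations["matrix_kind"].iloc[0]
        done(n_samples=spectra.n_samples, n_points=int(spectra.ppm.size))

        # --- preprocess
        done = stage("preprocess")
        for lo, hi in cfg.excise:
            spectra = excise_region(spectra, lo, hi)
        bins = adaptive_bin(spectra, **cfg.binning)
        bins.to_frame().to_csv(out / "bins.tsv", sep="\t", index=False)
        pqn_kwargs = dict(cfg.pqn)
        ref = pqn_kwargs.pop("reference", "median-all")
        features, factors = pqn_normalize(
            bins, reference=ref, groups=spectra.annotations["group"], **pqn_kwargs
        )
        factors.rename_axis("sample_id").to_frame().to_csv(out / "factors.tsv", sep="\t")
        scaled = pareto_scale(features)
        scaled.values.rename_axis("sample_id").to_csv(out / "features.tsv", sep="\t")
        manifest["files"].update(
            {k: str(out / f"{k}.tsv") for k in ("bins", "factors", "features")}
        )
        done(n_bins=len(bins.bins))

        # --- quantify
        done = stage("quantify")
        if cfg.assignments == "default":
            assign = quantify.load_default_assignments(matrix_kind)
        else:
            assign = quantify.AssignmentTable.from_tsv(cfg.assignments)
        conc = quantify.integrate_metabolites(bins_pqn(bins, factors), assign)
        conc.values.rename_axis("sample_id").to_csv(out / "concentrations.tsv", sep="\t")
        manifest["files"]["concentrations"] = str(out / "concentrations.tsv")
        done(n_metabolites=conc.values.shape[1])

        # --- multivariate, per contrast
        done = stage("multivariate")
        ann = spectra.annotations
        ocfg = dict(cfg.opls)
        seed = int(ocfg.pop("seed", 0))
        n_perm = int(ocfg.pop("n_perm", 0))
        repeats = int(ocfg.pop("repeats", 20))
        n_orth = int(ocfg.pop("n_orth", 1))
        q2s = {}
        for ga, gb in cfg.contrasts:
            mask = ann["group"].isin([ga, gb]).to_numpy()
            X = scaled.values.to_numpy()[mask]
            Xu = features.values.to_numpy()[mask]
            y = ann.loc[mask, "group"].to_numpy()
            model = opls.OPLSDA(n_orth=n_orth).fit(X, y)
            q2 = opls.cross_validate_q2(Xu, y, repeats=repeats, n_orth=n_orth, seed=seed)
            cdir = out / f"opls_{ga}_vs_{gb}"
            cdir.mkdir(exist_ok=True)
            scores, loadings = opls.scores_loadings_export(
                model,
                sample_ids=ann.loc[mask, "sample_id"].tolist(),
                groups=y,
                feature_names=[f"{lo:.4f}..{hi:.4f}" for lo, hi in bins.bins],
            )
            scores.to_csv(cdir / "scores.tsv", sep="\t", index=False)
            loadings.to_csv(cdir / "loadings.tsv", sep="\t", index=False)
            meta = {
                "contrast": [ga, gb],
                "n_orth": n_orth,
                "repeats": repeats,
                "seed": seed,
                "r2y": model.r2y_,
                "q2y": q2,
                "class_encoding": {str(k): int(v) for k, v in model.class_encoding_.items()},
            }
            if q2 > model.r2y_:
                meta["flag"] = "q2y exceeds r2y"
            if n_perm:
                perm = opls.permutation_test(
                    Xu, y, n_perm=n_perm, seed=seed, repeats=repeats, n_orth=n_orth
                )
                meta["permutation_p"] = perm.p_value
                pd.DataFrame({"permuted_q2": perm.permuted_q2}).to_csv(
                    cdir / "permutation.tsv", sep="\t", index=False
                )
            (cdir / "model.json").write_text(json.dumps(meta, indent=1))
            q2s[f"{ga}/{gb}"] = q2
        done(q2y=q2s)

        # --- univariate stats
        done = stage("stats")
        compact, full = stats.stats_table(conc, ann, cfg.contrasts)
        compact.rename_axis("metabolite").to_csv(out / "stats.tsv", sep="\t")
        full.rename_axis("metabolite").to_csv(out / "stats_full.tsv", sep="\t")
        stats.write_stats_html(compact, out / "stats.html")
        manifest["files"]["stats"] = str(out / "stats.tsv")
        done(n_contrasts=len(cfg.contrasts))

        # --- networks per group
        done = stage("networks")
        ncfg = dict(cfg.network)
        threshold = float(ncfg.get("threshold", 0.6))
        reactions = ncfg.get("reactions", "default")
        reactions = None if reactions == "default" else reactions
        primary = full.loc[full["contrast"] == f"{cfg.contrasts[0][0]}/{cfg.contrasts[0][1]}"]
        written = []
        for g in ann["group"].unique():
            sub = quantify.ConcentrationTable(conc.group_values(ann, g), conc.provenance)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net = associations.build_network(sub, primary, threshold=threshold)
                net = associations.overlay_reactions(net, reactions)
            p = out / f"network_{g}.graphml"
            associations.write_network(net, p)
            written.append(str(p))
        manifest["files"]["networks"] = written
        done(n_groups=len(written))

    except Exception as err:  # partial outputs get a failure marker
        manifest["failed_stage"] = manifest["stages"][-1]["stage"] if manifest["stages"] else "setup"
        manifest["error"] = f"{type(err).__name__}: {err}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def bins_pqn(bins, factors):
    """Bin table divided by per-sample PQN factors (normalized, unscaled)."""
    from .binning import BinTable

    values = bins.values.div(factors, axis=0)
    return BinTable(bins.bins, values, {**bins.provenance, "normalized": True})
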