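"""Configuration-driven end-to-end runner.

Sequences the full analysis — residualization, per-group SC matrices,
noise-edge exclusion, edge-wise contrasts with permutation and FDR, the
leave-out clinical link on significant edges, the cross-measure analysis,
and the global rank-sum tests — and writes all result tables plus a
reproducibility manifest (config, seeds, versions, counts, warnings).
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import RegionAtlas, load_atlas
from .clinical import CONTRASTS, evaluate_link
from .crossmeasure import (
    MEASURE_PAIRS,
    cross_cov,
    crossmeasure_contrast_test,
    rank_sum_global_regions,
)
from .data import MEASURES, StudyDataset, assemble_study
from .edgewise import (
    PermutationConfig,
    compute_sc,
    exclude_noise_edges,
    n_edges,
    permutation_test_edges,
    rank_sum_global,
)
from .io import (
    read_clinical_table,
    read_confound_table,
    read_region_table,
    write_region_table,
)
from . import synthetic

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

_SCENARIOS = {
    "paper_like": synthetic.paper_like_model,
}


@dataclass
class RunConfig:
    """Validated pipeline settings, serialized verbatim into the manifest."""

    scenario: Optional[str] = None  # named synthetic scenario ...
    inputs: Optional[Mapping] = None  # ... or file paths per group/measure
    contrasts: Tuple[str, ...] = ("HC_vs_ETpre", "ETpost_vs_ETpre")
    measures: Tuple[str, ...] = MEASURES
    n_perm: int = 300_000
    seed: int = 0
    paired: bool = False
    alpha: float = 0.05
    r2_threshold: float = 0.2
    r_max: int = 10
    outdir: str = "morphosca_results"

    def validate(self) -> None:
        if (self.scenario is None) == (self.inputs is None):
            raise ValueError("config needs exactly one of 'scenario' or 'inputs'")
        if self.scenario is not None and self.scenario not in _SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; known: {sorted(_SCENARIOS)}"
            )
        for c in self.contrasts:
            if c not in CONTRASTS:
                raise ValueError(
                    f"unknown contrast {c!r}; known: {sorted(CONTRASTS)}"
                )
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.r_max < 1:
            raise ValueError("r_max must be >= 1")


def load_config(path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("contrasts", "measures"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _load_input_study(cfg: RunConfig) -> StudyDataset:
    spec = dict(cfg.inputs)
    atlas = load_atlas(spec.get("atlas"))
    tables = []
    for group, per_measure in spec["tables"].items():
        for measure, path in per_measure.items():
            tables.append(
                read_region_table(path, "tsv", atlas, group=group, measure=measure)
            )
    confounds = {
        g: read_confound_table(p) for g, p in spec["confounds"].items()
    }
    clinical = (
        read_clinical_table(spec["clinical"]) if spec.get("clinical") else None
    )
    return assemble_study(tables, confounds, clinical, atlas)


def run_pipeline(cfg: RunConfig) -> Dict:
    """Execute the full analysis and write results under ``cfg.outdir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    Any stage failure aborts with a stage-named error.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    collected_warnings: List[str] = []

    manifest: Dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "version": __version__,
        "numpy": np.__version__,
        "stages": {},
        "warnings": collected_warnings,
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"][name] = {"t_start": round(time.time() - t0, 2)}
        return manifest["stages"][name]

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        # ---- data -------------------------------------------------------
        info = stage("data")
        try:
            if cfg.scenario is not None:
                model = _SCENARIOS[cfg.scenario](seed=cfg.seed)
                study = synthetic.build_study(model, seed=cfg.seed)
            else:
                study = _load_input_study(cfg)
        except Exception as exc:
            raise RuntimeError(f"stage 'data' failed: {exc}") from exc
        atlas = study.atlas
        info["group_sizes"] = study.group_sizes()
        info["n_regions"] = atlas.n_regions
        info["n_candidate_edges"] = n_edges(atlas.n_regions)

        measures = [m for m in cfg.measures if m in study.measures]

        # ---- SC matrices and noise mask ----------------------------------
        info = stage("sc_matrices")
        sc = {}
        for g in study.groups:
            for m in measures:
                sc[(g, m)] = compute_sc(study.table(g, m))
                pd.DataFrame(
                    sc[(g, m)].R, index=atlas.names, columns=atlas.names
                ).to_csv(outdir / f"sc_{g}_{m}.tsv", sep="\t")
        masks = {}
        info["kept_edges"] = {}
        for m in measures:
            masks[m] = exclude_noise_edges(
                [sc[(g, m)] for g in study.groups], cfg.r2_threshold
            )
            info["kept_edges"][m] = {
                "n_kept": masks[m].n_kept,
                "n_excluded": masks[m].n_excluded,
                "percent_kept": masks[m].percent_kept,
            }

        # ---- edge-wise contrasts -----------------------------------------
        info = stage("edgewise_contrasts")
        info["significant"] = {}
        edge_results: Dict[Tuple[str, str], pd.DataFrame] = {}
        rng = np.random.SeedSequence([cfg.seed, 3741])
        seeds = iter(rng.generate_state(4 * len(measures) * len(cfg.contrasts)))
        for contrast in cfg.contrasts:
            ga, gb, _ = CONTRASTS[contrast]
            if ga not in study.groups or gb not in study.groups:
                raise RuntimeError(
                    f"stage 'edgewise_contrasts' failed: contrast {contrast} "
                    f"needs groups {ga} and {gb}"
                )
            for m in measures:
                pcfg = PermutationConfig(
                    n_perm=cfg.n_perm, seed=int(next(seeds)) % (2**31),
                    paired=cfg.paired,
                )
                res = permutation_test_edges(
                    study.table(ga, m), study.table(gb, m), masks[m], pcfg,
                    alpha=cfg.alpha, region_names=atlas.names,
                )
                res.to_csv(outdir / f"edges_{m}_{contrast}.csv", index=False)
                edge_results[(m, contrast)] = res
                info["significant"][f"{m}_{contrast}"] = int(res["significant"].sum())

        # ---- global rank-sum tests ---------------------------------------
        info = stage("global_tests")
        rows = []
        for contrast in cfg.contrasts:
            ga, gb, _ = CONTRASTS[contrast]
            for m in measures:
                z, p = rank_sum_global(sc[(ga, m)], sc[(gb, m)], masks[m])
                rows.append(
                    {"analysis": "edgewise", "measure": m, "contrast": contrast,
                     "z": z, "p": p}
                )

        # ---- clinical link on significant edges --------------------------
        info = stage("clinical_link")
        link_rows = []
        if study.clinical is not None:
            for (m, contrast), res in edge_results.items():
                tables = {
                    g: study.table(g, m) for g in CONTRASTS[contrast][:2]
                }
                for _, row in res[res["significant"]].iterrows():
                    edge = (int(row["region_i"]), int(row["region_j"]))
                    link = evaluate_link(
                        tables, study.clinical, edge, contrast, cfg.r_max
                    )
                    link_rows.append(
                        {
                            "measure": m,
                            "contrast": contrast,
                            "region_i": atlas.names[edge[0]],
                            "region_j": atlas.names[edge[1]],
                            "score": link.score_name,
                            "mu_sc": link.mu_sc,
                            "beta_sc": link.beta_sc,
                            "associated": link.associated,
                            **{
                                f"sc1_r{r+1}": v
                                for r, v in enumerate(link.sc1_curve)
                            },
                            **{
                                f"sc2_r{r+1}": v
                                for r, v in enumerate(link.sc2_curve)
                            },
                        }
                    )
        link_df = pd.DataFrame(link_rows)
        link_df.to_csv(outdir / "clinical_link.csv", index=False)
        info["n_edges_evaluated"] = len(link_rows)
        info["n_associated"] = int(link_df["associated"].sum()) if len(link_df) else 0

        # ---- cross-measure analysis --------------------------------------
        info = stage("crossmeasure")
        info["significant"] = {}
        have_pairs = [
            (x, y) for x, y in MEASURE_PAIRS if x in measures and y in measures
        ]
        for contrast in cfg.contrasts:
            ga, gb, _ = CONTRASTS[contrast]
            for pair in have_pairs:
                x, y = pair
                pcfg = PermutationConfig(
                    n_perm=cfg.n_perm, seed=int(next(seeds)) % (2**31)
                )
                res = crossmeasure_contrast_test(
                    (study.table(ga, x), study.table(ga, y)),
                    (study.table(gb, x), study.table(gb, y)),
                    atlas, pcfg, alpha=cfg.alpha,
                )
                res.to_csv(
                    outdir / f"crossmeasure_{x}_{y}_{contrast}.csv", index=False
                )
                info["significant"][f"{x}/{y}_{contrast}"] = int(
                    res["significant"].sum()
                )
                ca = cross_cov(study.table(ga, x), study.table(ga, y), atlas)
                cb = cross_cov(study.table(gb, x), study.table(gb, y), atlas)
                z, p = rank_sum_global_regions(ca, cb)
                rows.append(
                    {"analysis": "crossmeasure", "measure": f"{x}/{y}",
                     "contrast": contrast, "z": z, "p": p}
                )
        pd.DataFrame(rows).to_csv(outdir / "global_tests.csv", index=False)

        collected_warnings.extend(str(w.message) for w in wrec)

    manifest["runtime_seconds"] = round(time.time() - t0, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
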