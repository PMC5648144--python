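"""Factorial experiment driver.

Runs the full design — every species crossed with the three predictor sets
(C, E, CE) and the four algorithms (GAM, MElq, RF, SVM) — on a synthetic
world, then feeds the resulting long-format table to the repeated-measures
comparison layer.  Each treatment draws its own seed from the global seed
and the treatment labels, so serial and parallel execution, or re-running a
single treatment from the manifest, give identical numbers.
"""

from __future__ import annotations

import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import design as design_mod
from . import models as models_mod
from . import occurrences as occ_mod
from . import predictors as pred_mod
from . import stats as stats_mod
from . import synth as synth_mod
from .evaluation import evaluate_treatment, kendall_map_tau
from .raster import GridStack

__all__ = ["ExperimentConfig", "SpeciesSpec", "build_design", "run_experiment"]

log = logging.getLogger("enmfactorial")

PREDICTOR_LABELS = ("C", "E", "CE")
ALGORITHMS = models_mod.ALGORITHMS


@dataclass
class SpeciesSpec:
    """Recipe for one virtual species in the roster."""

    species_id: str
    niche_family: str = "edaphic"   # which family the niche loads on
    n_layers: int = 2               # how many layers of that family
    breadth: float = 0.5
    n_records: int = 60
    # breadth of a broad tolerance envelope on layers of the *other*
    # family (None = niche loads on one family only); real plants have a
    # sharp soil niche inside a wide climatic tolerance, and vice versa
    envelope_breadth: float | None = None
    n_envelope_layers: int = 2


@dataclass
class ExperimentConfig:
    world: synth_mod.WorldConfig = field(default_factory=synth_mod.WorldConfig)
    n_species: int = 24
    niche_family: str = "edaphic"
    n_niche_layers: int = 2
    breadth: float = 0.5
    envelope_breadth: float | None = 1.0
    n_envelope_layers: int = 2
    n_records: int = 60
    pca_threshold: float = 0.95
    r_min: float = 0.5
    r_max: float = 15.0
    r_step: float = 0.5
    thin_resolution: float | None = None  # default: model cell size
    year_range: tuple[int, int] | None = None
    algorithms: tuple[str, ...] = ALGORITHMS
    predictor_labels: tuple[str, ...] = PREDICTOR_LABELS
    pa_mode: str = "spatial"
    connectivity: int = 4
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.algorithms) - set(ALGORITHMS)
        if bad:
            raise ValueError(f"unknown algorithms: {sorted(bad)}")
        bad = set(self.predictor_labels) - set(PREDICTOR_LABELS)
        if bad:
            raise ValueError(f"unknown predictor labels: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ExperimentConfig":
        raw = dict(raw)
        world = synth_mod.WorldConfig.from_dict(raw.pop("world", {}))
        known = set(cls.__dataclass_fields__) - {"world"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        for key in ("algorithms", "predictor_labels"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if kwargs.get("year_range") is not None:
            kwargs["year_range"] = tuple(kwargs["year_range"])
        return cls(world=world, **kwargs)


def derive_seed(global_seed: int, *labels) -> int:
    """Stable per-treatment seed below 2^31."""
    key = ":".join([str(global_seed), *map(str, labels)]).encode()
    return zlib.crc32(key) % (2**31)


def build_design(
    species_ids: Sequence[str],
    predictor_labels: Sequence[str] = PREDICTOR_LABELS,
    algorithms: Sequence[str] = ALGORITHMS,
) -> list[tuple[str, str, str]]:
    """Full species x predictor x algorithm cross in deterministic order."""
    if not species_ids or not predictor_labels or not algorithms:
        raise ValueError("design factors must all be non-empty")
    return [
        (s, p, a)
        for s in species_ids
        for p in predictor_labels
        for a in algorithms
    ]


def make_roster(cfg: ExperimentConfig) -> list[SpeciesSpec]:
    return [
        SpeciesSpec(
            species_id=f"vs{k + 1:03d}",
            niche_family=cfg.niche_family,
            n_layers=cfg.n_niche_layers,
            breadth=cfg.breadth,
            n_records=cfg.n_records,
            envelope_breadth=cfg.envelope_breadth,
            n_envelope_layers=cfg.n_envelope_layers,
        )
        for k in range(cfg.n_species)
    ]


def _species_occurrences(
    spec: SpeciesSpec,
    climate: GridStack,
    edaphic: GridStack,
    cfg: ExperimentConfig,
) -> tuple[synth_mod.VirtualSpecies, pd.DataFrame]:
    rng = np.random.default_rng(derive_seed(cfg.seed, "species", spec.species_id))
    stack = edaphic if spec.niche_family == "edaphic" else climate
    combined = climate.concat(edaphic)
    names = list(rng.choice(stack.names, size=min(spec.n_layers, len(stack)),
                            replace=False))
    responses = [
        (name, float(rng.uniform(-1.0, 1.0)), spec.breadth) for name in names
    ]
    if spec.envelope_breadth is not None:
        other = climate if spec.niche_family == "edaphic" else edaphic
        env_names = rng.choice(
            other.names, size=min(spec.n_envelope_layers, len(other)),
            replace=False,
        )
        responses.extend(
            (str(n), float(rng.uniform(-1.0, 1.0)), spec.envelope_breadth)
            for n in env_names
        )
    vs = synth_mod.make_virtual_species(
        combined, responses, species_id=spec.species_id,
        seed=derive_seed(cfg.seed, "vs", spec.species_id),
    )
    occ = synth_mod.sample_occurrences(
        vs, spec.n_records, seed=derive_seed(cfg.seed, "occ", spec.species_id)
    )
    geom = combined.geometry
    bbox = geom.bounds
    occ = occ_mod.clean_records(occ, bbox, cfg.year_range)
    thin_res = cfg.thin_resolution or geom.cell_size
    occ = occ_mod.thin_systematic(
        occ, thin_res, seed=derive_seed(cfg.seed, "thin", spec.species_id),
        anchor=(geom.origin_x, geom.origin_y),
    )
    return vs, occ


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute the full factorial experiment on a synthetic world.

    Returns a dict with the evaluation table, pairwise-tau table, ANOVA
    results per metric, per-species profiles, and the run manifest.
    Individual treatment failures become NA rows; more than 50% failures
    abort the run.
    """
    log.info("generating world: %s", cfg.world)
    climate, edaphic = synth_mod.gen_environment(cfg.world)
    sets = pred_mod.build_sets(climate, edaphic, cfg.pca_threshold)
    mask = edaphic.layers[0].copy()
    mask.valid &= climate.joint_valid & edaphic.joint_valid
    geom = climate.geometry
    anchor = (geom.origin_x, geom.origin_y)

    roster = make_roster(cfg)
    treatments = build_design(
        [s.species_id for s in roster], cfg.predictor_labels, cfg.algorithms
    )
    log.info("design: %d species x %d predictors x %d algorithms = %d treatments",
             len(roster), len(cfg.predictor_labels), len(cfg.algorithms),
             len(treatments))

    # background sample for the presence/background learner, shared per run
    bg_rng = np.random.default_rng(derive_seed(cfg.seed, "background"))
    records, tau_rows, profiles = [], [], []
    n_fail = 0
    suit_maps: dict[tuple[str, str, str], object] = {}

    for spec in roster:
        sid = spec.species_id
        try:
            vs, occ = _species_occurrences(spec, climate, edaphic, cfg)
            points = design_mod.build_training_points(
                occ, mask, anchor,
                seed=derive_seed(cfg.seed, "design", sid),
                r_min=cfg.r_min, r_max=cfg.r_max, step=cfg.r_step,
                pa_mode=cfg.pa_mode,
            )
            profiles.append(
                occ_mod.geo_profile(
                    occ, geom, {lbl: sets[lbl].pc1 for lbl in cfg.predictor_labels},
                    species_id=sid,
                )
            )
        except Exception as exc:  # degenerate species: log, NA all treatments
            log.warning("species %s failed in prep: %s", sid, exc)
            n_fail += len(cfg.predictor_labels) * len(cfg.algorithms)
            for p in cfg.predictor_labels:
                for a in cfg.algorithms:
                    records.append(_na_record(sid, p, a))
            continue

        for plabel in cfg.predictor_labels:
            scores = sets[plabel].score_layers
            bg_mat, _ = scores.to_matrix(where_valid=True)
            if len(bg_mat) > 10000:
                idx = bg_rng.choice(len(bg_mat), 10000, replace=False)
                bg_mat = bg_mat[idx]
            for alg in cfg.algorithms:
                seed = derive_seed(cfg.seed, sid, plabel, alg)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        rec, smap = evaluate_treatment(
                            points, scores,
                            lambda: models_mod.make_model(alg, seed),
                            plabel, alg,
                            background=bg_mat if alg == "MElq" else None,
                            connectivity=cfg.connectivity,
                        )
                    records.append(rec.to_dict())
                    suit_maps[(sid, plabel, alg)] = smap
                except Exception as exc:
                    log.warning("treatment (%s, %s, %s) failed: %s",
                                sid, plabel, alg, exc)
                    n_fail += 1
                    records.append(_na_record(sid, plabel, alg))
        # pairwise map correlations for this species
        tau_rows.extend(_species_taus(sid, suit_maps, cfg))
        # free per-species maps
        for key in [k for k in suit_maps if k[0] == sid]:
            del suit_maps[key]

    if n_fail > 0.5 * len(treatments):
        raise RuntimeError(
            f"{n_fail}/{len(treatments)} treatments failed; aborting"
        )

    eval_table = pd.DataFrame.from_records(records)
    tau_table = pd.DataFrame(tau_rows)
    anova = {}
    ok = eval_table.dropna(subset=["TSS"])
    complete = (
        ok.groupby("species")["TSS"].count()
        == len(cfg.predictor_labels) * len(cfg.algorithms)
    )
    keep = complete[complete].index
    balanced = ok[ok["species"].isin(keep)]
    can_anova = (
        len(keep) >= 2
        and len(cfg.predictor_labels) >= 2
        and len(cfg.algorithms) >= 2
    )
    if can_anova:
        for metric in ("TSS", "TPR", "AUC", "SI"):
            tbl = balanced.copy()
            if metric == "TSS":
                tbl["TSS"] = stats_mod.arcsine_transform(tbl["TSS"])
            anova[metric] = stats_mod.rm_anova(tbl, metric)

    tau_summary = {}
    if len(tau_table):
        for comparison in tau_table["comparison"].unique():
            sub = tau_table[tau_table["comparison"] == comparison]
            tau_summary[comparison] = stats_mod.summarize_pairwise_tau(
                sub, group=("within", "pair")
            )

    manifest = {
        "seed": cfg.seed,
        "world": {**cfg.world.__dict__, "shape": list(cfg.world.shape),
                  "origin": list(cfg.world.origin)},
        "n_species": cfg.n_species,
        "predictor_labels": list(cfg.predictor_labels),
        "algorithms": list(cfg.algorithms),
        "pca_threshold": cfg.pca_threshold,
        "pca_k": {lbl: sets[lbl].k for lbl in cfg.predictor_labels},
        "partition_candidates": [cfg.r_min, cfg.r_max, cfg.r_step],
        "n_treatments": len(treatments),
        "n_failed": n_fail,
        "treatment_seeds": {
            f"{s}:{p}:{a}": derive_seed(cfg.seed, s, p, a)
            for s, p, a in treatments
        },
    }
    result = {
        "eval_table": eval_table,
        "tau_table": tau_table,
        "tau_summary": tau_summary,
        "anova": anova,
        "profiles": occ_mod.profiles_to_frame(profiles),
        "manifest": manifest,
        "predictor_sets": sets,
    }
    if cfg.out_dir:
        write_outputs(result, cfg.out_dir)
    return result


def _na_record(sid: str, plabel: str, alg: str) -> dict:
    return {
        "species": sid, "predictor": plabel, "algorithm": alg,
        "TSS": np.nan, "TPR": np.nan, "AUC": np.nan, "SI": np.nan,
        "threshold": np.nan, "n_train": np.nan, "n_test": np.nan,
        "resolution": np.nan,
    }


def _species_taus(sid: str, maps: dict, cfg: ExperimentConfig) -> list[dict]:
    rows = []
    # predictor pairs within each algorithm
    for alg in cfg.algorithms:
        for i, p1 in enumerate(cfg.predictor_labels):
            for p2 in cfg.predictor_labels[i + 1:]:
                m1, m2 = maps.get((sid, p1, alg)), maps.get((sid, p2, alg))
                if m1 is None or m2 is None:
                    continue
                try:
                    tau = kendall_map_tau(m1, m2)
                except ValueError:
                    continue
                rows.append({"species": sid, "comparison": "predictor_pair",
                             "within": alg, "pair": f"{p1}-{p2}", "tau": tau})
    # algorithm pairs within each predictor set
    for plabel in cfg.predictor_labels:
        for i, a1 in enumerate(cfg.algorithms):
            for a2 in cfg.algorithms[i + 1:]:
                m1, m2 = maps.get((sid, plabel, a1)), maps.get((sid, plabel, a2))
                if m1 is None or m2 is None:
                    continue
                try:
                    tau = kendall_map_tau(m1, m2)
                except ValueError:
                    continue
                rows.append({"species": sid, "comparison": "algorithm_pair",
                             "within": plabel, "pair": f"{a1}-{a2}", "tau": tau})
    return rows


def write_outputs(result: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["eval_table"].to_csv(out / "evaluation.csv", index=False)
    result["tau_table"].to_csv(out / "kendall_tau.csv", index=False)
    result["profiles"].to_csv(out / "geo_profiles.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result["manifest"], fh, indent=2, sort_keys=True)
    lines = []
    for metric, res in result["anova"].items():
        lines.append(f"== Repeated-measures ANOVA: {metric} ==")
        lines.append(res.to_frame().to_string(index=False))
        lines.append("")
    for comparison, df in result["tau_summary"].items():
        lines.append(f"== Kendall tau summary: {comparison} ==")
        lines.append(df.to_string(index=False))
        lines.append("")
    (out / "anova_report.txt").write_text("\n".join(lines))
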