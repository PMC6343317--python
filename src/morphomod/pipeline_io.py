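"""Readers, writers, run configuration and the pipeline orchestrator.

External formats are deliberately plain: landmark coordinates as CSV (long
interchange format ``specimen,point,x,y,z`` or wide with ``<point>_x/_y/_z``
columns), trees as Newick, region maps, traits, sliding specs and candidate
modularity models as small CSVs, run configuration as YAML, and reports as
JSON + TSV.  :func:`run_pipeline` executes the published stage order —
superimpose, trait correlations, likelihood model selection, post-hoc
merging, per-module comparative statistics — and returns a
:class:`ReportBundle` whose per-module table mirrors the study-style
summary (rate, disparity, within-module correlation, allometry, phylogenetic
and ecological signal, with raw and FDR-adjusted p-values).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .datatypes import (AlignedShapes, AnalysisConfig, CurveSpec, LandmarkDataset,
                        RegionMap, TraitTable, centroid_size)
from .modularity import (CorrelationMatrix, ModularityModel, ModulePartition,
                         congruence_matrix, cr_test, emmli_fit, merge_regions,
                         model_from_region_grouping, phylo_corrected_blocks,
                         region_model)
from .ordination import pca
from .phylo_comparative import (Phylogeny, bh_adjust, k_mult, phylo_anova,
                                pgls_fit)
from .rates_disparity import (compare_rates_groups, compare_rates_modules,
                              landmark_evo_map, pairwise_disparity_tests,
                              procrustes_variance, sigma2_mult)
from .superimposition import SlidingSpec, superimpose

logger = logging.getLogger("morphomod")

# ---------------------------------------------------------------------------
# Deterministic per-stage seeds
# ---------------------------------------------------------------------------

STAGE_INDEX = {
    "superimpose": 0,
    "emmli": 1,
    "jackknife": 2,
    "cr": 3,
    "k_mult": 4,
    "allometry": 5,
    "anova": 6,
    "rates": 7,
    "rate_shifts": 8,
    "disparity": 9,
    "band": 10,
    "simulate": 11,
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Child seed for a named stage: SeedSequence((master, stage index)).

    The counter scheme lets any stage be re-run in isolation with the seed
    it would have received inside the full pipeline.
    """
    ss = np.random.SeedSequence((int(master_seed), STAGE_INDEX[stage]))
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# Landmark CSV
# ---------------------------------------------------------------------------

def write_landmark_csv(dataset: LandmarkDataset, path, dialect: str = "long") -> None:
    path = Path(path)
    if dialect == "long":
        rows = []
        for i, s in enumerate(dataset.specimen_ids):
            for j, p in enumerate(dataset.point_ids):
                x, y, z = dataset.coords[i, j]
                rows.append((s, p, repr(float(x)), repr(float(y)), repr(float(z)),
                             dataset.point_role[j], dataset.side[j]))
        df = pd.DataFrame(rows, columns=["specimen", "point", "x", "y", "z",
                                         "role", "side"])
        df.to_csv(path, index=False)
    elif dialect == "wide":
        cols = {}
        for j, p in enumerate(dataset.point_ids):
            for d, ax in enumerate("xyz"):
                cols[f"{p}_{ax}"] = [repr(float(v)) for v in dataset.coords[:, j, d]]
        df = pd.DataFrame({"specimen": dataset.specimen_ids, **cols})
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_landmark_csv(path, dialect: Optional[str] = None) -> LandmarkDataset:
    """Read a landmark table; dialect autodetected from the header if omitted.

    Raises a format error naming the specimen for ragged rows and a parse
    error with the cell address for non-numeric coordinates.
    """
    path = Path(path)
    header = pd.read_csv(path, nrows=0).columns.tolist()
    if dialect is None:
        dialect = "long" if {"specimen", "point", "x", "y", "z"} <= set(header) \
            else "wide"
    df = pd.read_csv(path, dtype=str, keep_default_na=False)

    def parse_cell(val: str, where: str) -> float:
        try:
            return float(val)
        except ValueError:
            raise ValueError(f"non-numeric coordinate at {where}: {val!r}") from None

    if dialect == "long":
        specimens = list(dict.fromkeys(df["specimen"]))
        points = list(dict.fromkeys(df["point"]))
        pt_index = {p: i for i, p in enumerate(points)}
        coords = np.full((len(specimens), len(points), 3), np.nan)
        roles = {p: "landmark" for p in points}
        sides = {p: "right" for p in points}
        counts = {s: 0 for s in specimens}
        for r, row in enumerate(df.itertuples(index=False)):
            s, p = row.specimen, row.point
            i, j = specimens.index(s), pt_index[p]
            for d, ax in enumerate("xyz"):
                coords[i, j, d] = parse_cell(getattr(row, ax),
                                             f"row {r + 2}, column {ax}")
            if hasattr(row, "role") and row.role:
                roles[p] = row.role
            if hasattr(row, "side") and row.side:
                sides[p] = row.side
            counts[s] += 1
        ragged = [s for s, c in counts.items() if c != len(points)]
        if ragged:
            raise ValueError(f"ragged input: specimen(s) {ragged[:5]} do not have "
                             f"one row per point ({len(points)} expected)")
        ds = LandmarkDataset(specimen_ids=specimens, point_ids=points, coords=coords,
                             point_role=[roles[p] for p in points],
                             side=[sides[p] for p in points])
    elif dialect == "wide":
        specimens = df["specimen"].tolist()
        coord_cols = [c for c in df.columns if c != "specimen"]
        points = list(dict.fromkeys(c.rsplit("_", 1)[0] for c in coord_cols))
        coords = np.empty((len(specimens), len(points), 3))
        for j, p in enumerate(points):
            for d, ax in enumerate("xyz"):
                col = f"{p}_{ax}"
                if col not in df.columns:
                    raise ValueError(f"ragged input: missing column {col}")
                for i, val in enumerate(df[col]):
                    coords[i, j, d] = parse_cell(
                        val, f"row {i + 2}, column {col}")
        ds = LandmarkDataset(specimen_ids=specimens, point_ids=points, coords=coords)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    finite = [i for i in range(ds.n_specimens) if np.all(np.isfinite(ds.coords[i]))]
    if finite:
        cs = np.array([centroid_size(ds.coords[i]) for i in finite])
        if np.all(np.abs(cs - 1.0) < 0.1):
            warnings.warn(
                "all centroid sizes are near 1: coordinates may already be "
                "Procrustes-superimposed")
    return ds


# ---------------------------------------------------------------------------
# Other readers/writers
# ---------------------------------------------------------------------------

def read_tree_newick(path) -> Phylogeny:
    return Phylogeny.from_file(path)


def write_tree_newick(phylogeny: Phylogeny, path) -> None:
    phylogeny.write_newick(path)


def read_region_map(path) -> RegionMap:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    region_of = dict(zip(df["point_id"], df["region_id"]))
    regions = list(dict.fromkeys(df["region_id"]))
    anchors: Dict[str, str] = {}
    if "anchor" in df.columns:
        for region, anchor in zip(df["region_id"], df["anchor"]):
            if anchor:
                anchors[region] = anchor
    return RegionMap(region_of_point=region_of, region_ids=regions,
                     anchor_of_region=anchors)


def write_region_map(region_map: RegionMap, path) -> None:
    rows = [(p, r, region_map.anchor_of_region.get(r, ""))
            for p, r in region_map.region_of_point.items()]
    pd.DataFrame(rows, columns=["point_id", "region_id", "anchor"]).to_csv(
        path, index=False)


def read_traits(path) -> TraitTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    specimens = df["specimen"].tolist()

    def opt(v: str) -> Optional[str]:
        return None if v in ("", "NA", "nan") else v

    return TraitTable(
        specimen_ids=specimens,
        fossoriality={s: int(f) for s, f in zip(specimens, df["fossoriality"])},
        aquatic=dict(zip(specimens, df["aquatic"])),
        reproduction={s: opt(v) for s, v in zip(specimens, df["reproduction"])},
        life_history={s: opt(v) for s, v in zip(specimens, df["life_history"])},
    )


def write_traits(traits: TraitTable, path) -> None:
    rows = [(s, traits.fossoriality[s], traits.aquatic[s],
             traits.reproduction[s] or "NA", traits.life_history[s] or "NA")
            for s in traits.specimen_ids]
    pd.DataFrame(rows, columns=["specimen", "fossoriality", "aquatic",
                                "reproduction", "life_history"]).to_csv(
        path, index=False)


def read_sliding_spec(path, slide_iterations: int = 3,
                      tolerance: float = 1e-6) -> SlidingSpec:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    curves: Dict[str, List[Tuple[int, str, str, str]]] = {}
    for row in df.itertuples(index=False):
        curves.setdefault(row.curve_id, []).append(
            (int(row.rank), row.point_id, row.anchor_start, row.anchor_end))
    specs = []
    for cid, items in curves.items():
        items.sort()
        ranks = [r for r, *_ in items]
        if ranks != list(range(len(ranks))):
            raise ValueError(f"curve {cid}: ranks not contiguous 0..k-1: {ranks}")
        specs.append(CurveSpec(curve_id=cid, point_ids=[p for _, p, _, _ in items],
                               anchor_start=items[0][2] or None,
                               anchor_end=items[0][3] or None))
    return SlidingSpec(curves=specs, slide_iterations=slide_iterations,
                       tolerance=tolerance)


def read_config(path) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig(**data)


def load_candidate_models(region_map: RegionMap, point_ids: Sequence[str],
                          path=None) -> List[ModularityModel]:
    """Candidate modularity models from a CSV (model_name, region_id, module_label).

    Without a path, the packaged synthetic candidate set is used: 15 models
    over the default 16 region ids, spanning one-module, two-module splits,
    six-module amniote-style groupings and their refinements, up to the
    fully partitioned model.
    """
    if path is None:
        ref = resources.files("morphomod.data") / "candidate_models_synthetic.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    models = []
    for name, grp in df.groupby("model_name", sort=False):
        grouping = dict(zip(grp["region_id"], grp["module_label"]))
        missing = [r for r in region_map.region_ids if r not in grouping]
        if missing:
            raise ValueError(f"model {name} missing regions {missing}")
        models.append(model_from_region_grouping(name, region_map, point_ids, grouping))
    return models


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

@dataclass
class ReportBundle:
    module_table: pd.DataFrame
    global_stats: Dict[str, float]
    partition: ModulePartition
    emmli_aicc: Dict[str, float]
    provenance: Dict[str, object] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "module_table": self.module_table.to_dict(orient="records"),
            "global": self.global_stats,
            "partition": self.partition.module_of_region,
            "emmli_aicc": self.emmli_aicc,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, default=float)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        human = self.module_table.copy()
        for col in human.columns:
            if col.startswith("p_"):
                human[col] = human[col].map(lambda v: f"{v:.4f}")
            elif human[col].dtype.kind == "f":
                human[col] = human[col].map(lambda v: f"{v:.3g}")
        human.to_csv(out / "module_table.tsv", sep="\t", index=False)


def _log_stage(stage: str, seed: Optional[int], t0: float) -> None:
    logger.info("stage=%s seed=%s elapsed=%.2fs", stage, seed, time.time() - t0)


def run_pipeline(config: AnalysisConfig, dataset: LandmarkDataset,
                 region_map: RegionMap, tree: Phylogeny, traits: TraitTable,
                 models: Optional[List[ModularityModel]] = None) -> ReportBundle:
    """Execute the full analysis and build the report.

    Stage order: superimpose -> congruence (phylogenetically corrected via
    independent contrasts) -> likelihood model selection -> post-hoc region
    merging -> per-module rates, disparity, allometry, phylogenetic and
    ecological signal -> report.  Every stochastic stage consumes a child
    seed derived from the master seed (see :func:`stage_seed`), so repeat
    runs are byte-identical.
    """
    names = set(dataset.specimen_ids)
    if names != set(tree.tip_labels) or names != set(traits.specimen_ids):
        offenders = sorted(names.symmetric_difference(tree.tip_labels) |
                           names.symmetric_difference(traits.specimen_ids))
        raise ValueError(f"specimen/tip/trait name mismatch: {offenders[:10]}")
    region_map.validate_total(dataset.point_ids)

    def run_stage(stage, fn, *args, **kwargs):
        t0 = time.time()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        _log_stage(stage, kwargs.get("seed"), t0)
        return out

    # 1. superimposition
    sliding = SlidingSpec.from_dataset(dataset,
                                       slide_iterations=config.slide_iterations,
                                       tolerance=config.tolerance)
    aligned = run_stage("superimpose", superimpose, dataset, region_map, sliding)
    order = aligned.specimen_ids

    # 2. phylogenetically corrected congruence + model selection
    contrasts = run_stage("contrasts", phylo_corrected_blocks, aligned, tree)
    corr = congruence_matrix(contrasts, point_ids=aligned.point_ids,
                             n_eff=aligned.n_specimens - 1)
    if models is None:
        models = load_candidate_models(region_map, aligned.point_ids)
    finest = region_model(region_map, aligned.point_ids, name="sixteen_module")
    if finest.name not in {m.name for m in models}:
        models = list(models) + [finest]
    fit = run_stage("emmli", emmli_fit, corr, models)
    finest_fit = emmli_fit(corr, [finest])

    # 3. post-hoc merging on the finest model's region correlations
    partition = merge_regions(finest_fit.rho_within, finest_fit.rho_between,
                              threshold=config.merge_threshold)
    merged_to_single = partition.n_modules < 2
    if merged_to_single:
        # a fully integrated outcome leaves nothing to compare; fall back to
        # the region partition for per-module statistics and the CR test
        partition = ModulePartition(
            module_of_region={r: r for r in region_map.region_ids},
            threshold=config.merge_threshold)
    module_points = {
        m: [p for r in regions for p in region_map.points_in(r, aligned.point_ids)]
        for m, regions in partition.modules().items()
    }
    merged_model = ModularityModel(
        name="merged",
        partition={p: m for m, pts in module_points.items() for p in pts})
    merged_fit = emmli_fit(corr, [merged_model])

    # 4. global statistics
    Y = aligned.flat()
    log_cs = np.log(aligned.centroid_size)[:, None]
    kres = run_stage("k_mult", k_mult, tree, Y, order,
                     n_perm=config.n_permutations,
                     seed=stage_seed(config.seed, "k_mult"))
    allo = run_stage("allometry", pgls_fit, tree, Y, log_cs, order,
                     n_perm=config.n_permutations,
                     seed=stage_seed(config.seed, "allometry"))
    crres = run_stage("cr", cr_test, aligned, merged_model.partition,
                      n_perm=config.n_permutations,
                      seed=stage_seed(config.seed, "cr"))
    foss = [traits.fossoriality[s] for s in order]
    anova_glob = run_stage("anova", phylo_anova, tree, Y, foss, order,
                           n_perm=config.n_permutations,
                           seed=stage_seed(config.seed, "anova"))
    rate_res = run_stage("rates", compare_rates_modules, tree, aligned,
                         module_points, n_sim=config.n_sim_rates,
                         seed=stage_seed(config.seed, "rates"))
    disp_res = run_stage("disparity", pairwise_disparity_tests, aligned,
                         module_points, n_perm=config.n_permutations,
                         seed=stage_seed(config.seed, "disparity"),
                         alpha=config.bh_alpha)

    # ecological rate shifts (two-group), BH-corrected as a family
    shift_groups = {}
    aq = {"obligate": [], "non-obligate": []}
    for s in order:
        aq[traits.aquatic[s]].append(s)
    if all(len(v) >= 2 for v in aq.values()):
        shift_groups["aquatic"] = (aq, "obligate")
    rep = {"viviparous": [], "oviparous": []}
    for s in order:
        v = traits.reproduction[s]
        if v:
            rep[v].append(s)
    if all(len(v) >= 2 for v in rep.values()):
        shift_groups["viviparity"] = (rep, "viviparous")
    lh = {"direct": [], "larval": []}
    for s in order:
        v = traits.life_history[s]
        if v:
            lh[v].append(s)
    if all(len(v) >= 2 for v in lh.values()):
        shift_groups["direct_development"] = (lh, "direct")
    shifts = {}
    for i, (name, (groups, focal)) in enumerate(sorted(shift_groups.items())):
        shifts[name] = run_stage(
            f"rate_shift:{name}", compare_rates_groups, tree, aligned, groups,
            focal=focal, n_sim=config.n_sim_rates,
            seed=stage_seed(config.seed, "rate_shifts") + i)
    if shifts:
        adj, _ = bh_adjust([shifts[k].p_value for k in sorted(shifts)],
                           alpha=config.bh_alpha)
        shift_p_adj = dict(zip(sorted(shifts), adj))
    else:
        shift_p_adj = {}

    # 5. per-module statistics
    rows = []
    mod_names = sorted(module_points)
    k_seeds = stage_seed(config.seed, "k_mult")
    for mi, m in enumerate(mod_names):
        pts = module_points[m]
        sub = aligned.subset_points(pts)
        Ym = sub.flat()
        km = k_mult(tree, Ym, order, n_perm=config.n_permutations,
                    seed=k_seeds + 1 + mi)
        al = pgls_fit(tree, Ym, log_cs, order, n_perm=config.n_permutations,
                      seed=stage_seed(config.seed, "allometry") + 1 + mi)
        an = phylo_anova(tree, Ym, foss, order, n_perm=config.n_permutations,
                         seed=stage_seed(config.seed, "anova") + 1 + mi)
        rows.append({
            "module": m,
            "rate_sigma2": rate_res.rates[m],
            "disparity": disp_res.disparity[m],
            "rho_within": merged_fit.rho_within.get(m, np.nan),
            "allometry_r2": al.r_squared,
            "p_allometry": al.p_value,
            "k_mult": km.k_mult,
            "p_k_mult": km.p_value,
            "anova_r2": an.r_squared,
            "p_anova": an.p_value,
        })
    table = pd.DataFrame(rows)
    for col in ("p_allometry", "p_k_mult", "p_anova"):
        adj, _ = bh_adjust(table[col].to_numpy(), alpha=config.bh_alpha)
        table[col + "_bh"] = adj

    global_stats = {
        "n_specimens": aligned.n_specimens,
        "n_points": aligned.n_points,
        "n_modules": partition.n_modules,
        "best_model": fit.best_model,
        "k_mult": kres.k_mult,
        "p_k_mult": kres.p_value,
        "allometry_r2": allo.r_squared,
        "p_allometry": allo.p_value,
        "cr": crres.cr,
        "p_cr": crres.p_value,
        "anova_fossoriality_r2": anova_glob.r_squared,
        "p_anova_fossoriality": anova_glob.p_value,
        "rate_ratio_max_min": rate_res.ratio,
        "p_rate_ratio": rate_res.p_value,
        "n_disparity_pairs_significant": disp_res.n_significant,
    }
    for name, res in shifts.items():
        global_stats[f"rate_shift_{name}_ratio"] = res.ratio
        global_stats[f"rate_shift_{name}_p"] = res.p_value
        global_stats[f"rate_shift_{name}_p_bh"] = float(shift_p_adj[name])

    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]
    bundle = ReportBundle(
        module_table=table, global_stats=global_stats, partition=partition,
        emmli_aicc=dict(fit.aicc),
        provenance={"config_hash": cfg_hash, "seed": config.seed,
                    "slide_passes": aligned.provenance.get("slide_passes"),
                    "merged_to_single_module": merged_to_single},
    )
    return bundle
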