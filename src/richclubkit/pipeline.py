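"""End-to-end orchestration of the rich-club group analysis.

Sequence: threshold each subject's matrix -> per-group 60%-prevalence
group-averaged networks -> top-12% hubs per group (and the common hub set) ->
per-subject rich/feeder/local classification and class metrics -> normalized
rich-club profiles of the group-averaged networks -> permutation contrasts
(6 group pairs x {strength, density} x 3 classes) with BH-FDR within the
family -> covariate-adjusted correlations (CTQ scores with metrics in
patients and controls separately; HAMD/HAMA in patients) -> permutation
contrasts of nodal degree in the common rich-club regions.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from richclubkit import __version__
from richclubkit.core_network import (
    ConnectivityMatrix,
    group_average_network,
    node_degree,
    threshold_matrix,
)
from richclubkit.rich_club import (
    EDGE_CLASSES,
    class_metrics,
    classify_edges,
    identify_rich_club_nodes,
    normalized_rich_club,
)
from richclubkit.stats import fdr_correct, partial_correlation, permutation_test, validate_cohort

logger = logging.getLogger(__name__)

GROUP_ORDER = ("MDD-CM", "MDD-nCM", "HC-CM", "HC-nCM")
CTQ_SCORES = ("CTQ", "EA", "PA", "SA", "EN", "PN")
METRIC_COLUMNS = tuple(
    f"{measure}_{cls}" for measure in ("strength", "density") for cls in EDGE_CLASSES
)


@dataclass
class RunConfig:
    """Analysis parameters; the defaults are the standard published choices
    (edge floor of 3 streamlines, 60% prevalence, top-12% hubs, 1000 nulls,
    10000 permutations)."""

    min_streamlines: int = 3
    prevalence: float = 0.60
    hub_fraction: float = 0.12
    survivor_rule: str = "ge"
    n_random: int = 1000
    n_swap_per_edge: int = 10
    n_perm: int = 10000
    fdr_alpha: float = 0.05
    seed: int = 0


@dataclass
class ResultsBundle:
    class_metrics: pd.DataFrame
    hubs: pd.DataFrame
    profiles: pd.DataFrame
    contrasts: pd.DataFrame
    correlations: pd.DataFrame
    nodal_degree: pd.DataFrame
    run_manifest: dict = field(default_factory=dict)


def _subject_metrics_table(
    mats: list[ConnectivityMatrix],
    cohort: pd.DataFrame,
    hubs_by_group: dict[str, tuple[str, ...]],
) -> pd.DataFrame:
    group_of = dict(zip(cohort["subject_id"], cohort["group"]))
    rows = []
    for mat in mats:
        group = group_of[mat.subject_id]
        part = classify_edges(mat, hubs_by_group[group])
        cm = class_metrics(mat, part)
        rows.append(
            {
                "subject_id": mat.subject_id,
                "group": group,
                "strength_rich": cm.strength_rich,
                "strength_feeder": cm.strength_feeder,
                "strength_local": cm.strength_local,
                "density_rich": cm.density_rich,
                "density_feeder": cm.density_feeder,
                "density_local": cm.density_local,
            }
        )
    return pd.DataFrame(rows)


def _contrast_table(
    metrics: pd.DataFrame, config: RunConfig, value_columns: tuple[str, ...] = METRIC_COLUMNS
) -> pd.DataFrame:
    """All pairwise group permutation contrasts for each metric column, with
    BH-FDR across the whole family."""
    groups = [g for g in GROUP_ORDER if g in set(metrics["group"])]
    rows = []
    contrast_seed = itertools.count(config.seed)
    for col in value_columns:
        for ga, gb in itertools.combinations(groups, 2):
            a = metrics.loc[metrics["group"] == ga, col].dropna().to_numpy()
            b = metrics.loc[metrics["group"] == gb, col].dropna().to_numpy()
            res = permutation_test(
                a, b, n_perm=config.n_perm, seed=next(contrast_seed),
                group_pair=(ga, gb), metric_name=col,
            )
            rows.append(
                {
                    "metric": col,
                    "group_a": ga,
                    "group_b": gb,
                    "mean_a": float(np.mean(a)),
                    "mean_b": float(np.mean(b)),
                    "observed_diff": res.observed_diff,
                    "p_raw": res.p_value,
                }
            )
    table = pd.DataFrame(rows)
    table["p_fdr"] = fdr_correct(table["p_raw"])
    table["significant"] = table["p_fdr"] < config.fdr_alpha
    return table


def _correlation_table(metrics: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Partial correlations (age, sex, education regressed out) between
    clinical scores and class metrics, within patients and controls."""
    merged = metrics.merge(cohort, on=["subject_id", "group"])
    merged["sex01"] = (merged["sex"] == "M").astype(float)
    rows = []
    populations = {"MDD": list(CTQ_SCORES) + ["HAMD", "HAMA"], "HC": list(CTQ_SCORES)}
    for dx, scores in populations.items():
        sub = merged[merged["diagnosis"] == dx]
        if sub.empty:
            continue
        cov = sub[["age", "sex01", "education"]].astype(float)
        for score in scores:
            y = sub[score].astype(float)
            if y.isna().any() or y.nunique() < 2:
                continue
            for col in METRIC_COLUMNS:
                r, p = partial_correlation(sub[col].to_numpy(), y.to_numpy(), cov)
                rows.append(
                    {"population": dx, "score": score, "metric": col, "r": r, "p": p}
                )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_fdr"] = table.groupby("population")["p"].transform(
            lambda s: fdr_correct(s.to_numpy())
        )
    return table


def _nodal_degree_table(
    mats: list[ConnectivityMatrix],
    cohort: pd.DataFrame,
    common_hubs: tuple[str, ...],
    config: RunConfig,
) -> pd.DataFrame:
    """Permutation contrasts of per-subject binary degree at each common
    rich-club region."""
    if not common_hubs:
        return pd.DataFrame(
            columns=["metric", "group_a", "group_b", "mean_a", "mean_b",
                     "observed_diff", "p_raw", "p_fdr", "significant"]
        )
    degrees = []
    labels = mats[0].node_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    for mat in mats:
        deg = node_degree(mat)
        degrees.append({"subject_id": mat.subject_id,
                        **{f"degree_{h}": int(deg[idx[h]]) for h in common_hubs}})
    table = pd.DataFrame(degrees).merge(
        cohort[["subject_id", "group"]], on="subject_id"
    )
    cfg = RunConfig(**{**asdict(config), "seed": config.seed + 90001})
    return _contrast_table(
        table, cfg, value_columns=tuple(f"degree_{h}" for h in common_hubs)
    )


def run_analysis(
    mats: list[ConnectivityMatrix],
    cohort: pd.DataFrame,
    config: RunConfig | None = None,
) -> ResultsBundle:
    """Run the full analysis on in-memory matrices and a phenotype table."""
    if config is None:
        config = RunConfig()
    cohort = validate_cohort(cohort)
    known = set(cohort["subject_id"])
    missing = [m.subject_id for m in mats if m.subject_id not in known]
    if missing:
        raise ValueError(f"matrices without phenotype rows: {missing}")
    no_matrix = known - {m.subject_id for m in mats}
    if no_matrix:
        raise ValueError(f"subjects in cohort without a matrix: {sorted(no_matrix)}")

    mats = [threshold_matrix(m, config.min_streamlines) for m in mats]
    by_group: dict[str, list[ConnectivityMatrix]] = {}
    group_of = dict(zip(cohort["subject_id"], cohort["group"]))
    for m in mats:
        by_group.setdefault(group_of[m.subject_id], []).append(m)

    groups = [g for g in GROUP_ORDER if g in by_group]
    hubs_by_group: dict[str, tuple[str, ...]] = {}
    hub_rows = []
    profile_rows = []
    for gi, g in enumerate(groups):
        gnet = group_average_network(by_group[g], config.prevalence, group_id=g)
        hubs = identify_rich_club_nodes(gnet, config.hub_fraction)
        hubs_by_group[g] = hubs
        gdeg = node_degree(gnet)
        deg_of = dict(zip(gnet.node_labels, gdeg))
        hub_rows += [{"group": g, "node": h, "degree": int(deg_of[h])} for h in hubs]
        profile = normalized_rich_club(
            gnet, n_random=config.n_random, n_swap_per_edge=config.n_swap_per_edge,
            seed=config.seed + 1000 + gi, survivor_rule=config.survivor_rule,
        )
        for k, phi, phi_r, phi_n in zip(
            profile.k_values, profile.phi, profile.phi_random, profile.phi_norm
        ):
            profile_rows.append(
                {"group": g, "k": int(k), "phi": phi, "phi_random": phi_r, "phi_norm": phi_n}
            )
    common = tuple(
        h for h in hubs_by_group[groups[0]]
        if all(h in hubs_by_group[g] for g in groups)
    )
    logger.info("common rich-club regions across groups: %d", len(common))

    metrics = _subject_metrics_table(mats, cohort, hubs_by_group)
    contrasts = _contrast_table(metrics, config)
    correlations = _correlation_table(metrics, cohort)
    nodal = _nodal_degree_table(mats, cohort, common, config)

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "n_subjects": len(mats),
        "groups": {g: len(v) for g, v in by_group.items()},
        "common_rich_club_regions": list(common),
    }
    return ResultsBundle(
        class_metrics=metrics,
        hubs=pd.DataFrame(hub_rows),
        profiles=pd.DataFrame(profile_rows),
        contrasts=contrasts,
        correlations=correlations,
        nodal_degree=nodal,
        run_manifest=manifest,
    )


def write_results(bundle: ResultsBundle, out_dir: str | Path) -> None:
    """Write every result table as TSV plus a JSON run manifest."""
    from richclubkit.io import write_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"richclubkit_version": __version__}
    write_tsv(bundle.class_metrics, out / "class_metrics.tsv", meta)
    write_tsv(bundle.hubs, out / "hubs.tsv", meta)
    write_tsv(bundle.profiles, out / "richclub_profiles.tsv", meta)
    write_tsv(bundle.contrasts, out / "contrasts.tsv", meta)
    write_tsv(bundle.correlations, out / "correlations.tsv", meta)
    write_tsv(bundle.nodal_degree, out / "nodal_degree.tsv", meta)
    (out / "run_manifest.json").write_text(json.dumps(bundle.run_manifest, indent=2) + "\n")
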