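"""End-to-end orchestration: tables → phylogeny → GLM → D → regressions.

``run_pipeline`` executes every stage on one dataset and writes the
per-family summary, per-group fit and D tables, the regression table, the
optional randomized baseline, and a run-metadata JSON.  Identical inputs and
seed give byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import HostIslandsError, DegenerateResponseError, ValidationError
from . import glm, regressions, signal_d, tables
from .phylo import cophenetic_distances, prune_to_labels, read_newick

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    tree_path: str
    family_path: str
    matrix_path: str
    outdir: str
    measure: str = "species"
    mainland_fraction: float = 0.10
    n_perm: int = 1000
    baseline_reps: int = 0          # 0 disables the randomized baseline
    baseline_probs: tuple = regressions.BASELINE_PROBS
    min_host_families: int = 10
    exclude_self: bool = False
    seed: int = 0

    def validate(self) -> None:
        for p in (self.tree_path, self.family_path, self.matrix_path):
            if not Path(p).exists():
                raise ValidationError(f"input file not found: {p}")
        if self.measure not in tables.APPARENCY_MEASURES:
            raise ValidationError(f"unknown apparency measure {self.measure!r}")


def _fmt(x) -> object:
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else x


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Raises :class:`HostIslandsError` subclasses with stage-tagged messages.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    root_seq = np.random.SeedSequence(config.seed)
    seed_signal, seed_baseline = root_seq.spawn(2)

    # -- stage: tables -----------------------------------------------------
    try:
        load = tables.read_family_table(config.family_path)
        matrix = tables.read_utilization_matrix(
            config.matrix_path, min_host_families=config.min_host_families)
    except HostIslandsError as exc:
        raise type(exc)(f"[tables] {exc}") from exc
    fam_index = {r.family for r in load.records}
    unknown = set(matrix.families) - fam_index
    if unknown:
        raise ValidationError(
            f"[tables] matrix families missing from apparency table: "
            f"{sorted(unknown)[:5]}")

    # -- stage: phylo ------------------------------------------------------
    try:
        tree = read_newick(config.tree_path)
        tip_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
        not_in_tree = set(matrix.families) - tip_labels
        if not_in_tree:
            raise ValidationError(
                f"matrix families absent from tree: {sorted(not_in_tree)[:5]}")
        analysis_tree = (prune_to_labels(tree, set(matrix.families))
                         if tip_labels - set(matrix.families) else tree)
        dm = cophenetic_distances(analysis_tree)
    except HostIslandsError as exc:
        raise type(exc)(f"[phylo] {exc}") from exc

    records = [r for r in load.records if r.family in set(matrix.families)]

    # -- stage: family summaries ------------------------------------------
    ur = tables.utilizer_ratio(matrix)
    mainland = tables.select_mainland(records, config.measure,
                                      config.mainland_fraction)
    pdm = tables.pd_min(dm, mainland, exclude_self=config.exclude_self)
    summaries = [
        tables.FamilySummary(r.family, float(ur[r.family]),
                             float(pdm[r.family]),
                             r.apparency(config.measure))
        for r in records
    ]
    fam_df = pd.DataFrame(
        [(s.family, s.apparency, s.UR, s.PD_min, s.family in mainland)
         for s in summaries],
        columns=["family", "apparency", "UR", "PD_min", "mainland"],
    ).sort_values("family")
    fam_df.to_csv(out / "family_summaries.csv", index=False)

    # -- stage: glm + signal_d per group -----------------------------------
    pa = np.array([r.apparency(config.measure) for r in records])
    fam_order = [r.family for r in records]
    group_rows, d_rows, group_summaries = [], [], []
    signal_children = seed_signal.spawn(len(matrix.groups))
    for g, child in zip(matrix.groups, signal_children):
        presence = matrix.presence(g).reindex(fam_order)
        y = presence.to_numpy(dtype=float)
        hf = int(y.sum())
        gsum = regressions.GroupSummary(group=g, HF=hf)
        row = {"group": g, "measure": config.measure, "n": len(y),
               "a": np.nan, "var_a": np.nan, "b": np.nan, "var_b": np.nan,
               "G": np.nan, "p_G": np.nan, "PA_05": np.nan,
               "PA_095": np.nan, "UP_0": np.nan,
               "converged": False, "separated": False}
        try:
            fit = glm.fit_binomial_logit(pa, y)
            gsum.fit = fit
            row.update(a=fit.a, var_a=fit.var_a, b=fit.b, var_b=fit.var_b,
                       converged=fit.converged, separated=fit.separated)
            if not fit.separated:
                gval, pval = glm.g_statistic(fit)
                row.update(G=gval, p_G=pval)
                if fit.a != 0:
                    dq = glm.derived_quantities(fit)
                    gsum.derived = dq
                    row.update(PA_05=dq.PA_05, PA_095=dq.PA_095,
                               UP_0=dq.UP_0)
        except DegenerateResponseError:
            logger.warning("group %s: degenerate response, no GLM fit", g)
        group_rows.append(row)

        gseed = int(child.generate_state(1)[0] % (2 ** 31))
        try:
            dres = signal_d.phylo_d(
                analysis_tree, dict(zip(fam_order, y.astype(int))),
                n_perm=config.n_perm, seed=gseed)
            gsum.d_result = dres
            d_rows.append({
                "group": g, "n_tips_used": dres.n_tips,
                "prevalence": dres.prevalence, "sum_d_obs": dres.sum_d_obs,
                "mean_random": dres.mean_sum_d_random,
                "mean_brownian": dres.mean_sum_d_brownian, "D": dres.D,
                "p_random": dres.p_random, "p_brownian": dres.p_brownian,
                "n_perm": dres.n_perm, "seed": gseed})
        except HostIslandsError as exc:
            logger.warning("group %s: D not computed (%s)", g, exc)
            d_rows.append({"group": g, "seed": gseed})
        group_summaries.append(gsum)

    pd.DataFrame(group_rows).to_csv(out / "group_fits.csv", index=False)
    pd.DataFrame(d_rows).to_csv(out / "group_signal.csv", index=False)

    # -- stage: regressions -------------------------------------------------
    reg_rows, exclusions = [], []
    fam_rel = regressions.family_relationships(summaries)
    for name, res in fam_rel.items():
        reg_rows.append({"name": name, **asdict(res)})
    try:
        group_rel, exclusions = regressions.group_relationships(
            group_summaries)
        for name, res in group_rel.items():
            if res is not None:
                reg_rows.append({"name": name, **asdict(res)})
    except ValidationError as exc:
        logger.warning("cross-group regressions skipped: %s", exc)
    reg_df = pd.DataFrame(reg_rows)
    reg_df.to_csv(out / "regressions.csv", index=False)

    # -- stage: randomized baseline -----------------------------------------
    baseline_summary = None
    if config.baseline_reps > 0:
        baseline = regressions.randomized_baseline(
            pa, probs=config.baseline_probs, n_reps=config.baseline_reps,
            seed=int(seed_baseline.generate_state(1)[0] % (2 ** 31)))
        baseline.to_csv(out / "baseline.csv", index=False)
        baseline_summary = regressions.summarize_baseline(baseline)
        baseline_summary.to_csv(out / "baseline_summary.csv", index=False)

    meta = {
        "version": __version__,
        "seed": config.seed,
        "measure": config.measure,
        "mainland_fraction": config.mainland_fraction,
        "mainland_size": len(mainland),
        "n_perm": config.n_perm,
        "baseline_reps": config.baseline_reps,
        "min_host_families": config.min_host_families,
        "exclude_self": config.exclude_self,
        "n_families": len(records),
        "n_groups": matrix.n_groups,
        "dropped_groups": matrix.dropped_groups,
        "load_report": load.report,
        "exclusions": [list(e) for e in exclusions],
    }
    with open(out / "run_meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
    return out
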