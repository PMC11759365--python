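"""End-to-end orchestration: filter -> normalize -> dispersion -> turnover ->
RC-Bray -> neutral fit -> beta diversity, from one configuration.

``run_all`` executes every stage in dependency order, writes each stage's
tables under the output directory and assembles a markdown report whose
numbers are read back from the stage files (no recomputation drift).  All
randomness flows from the config seed through deterministic child seeds, so
identical configs yield byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beta_diversity as bd
from . import community_io as cio
from . import neutral_model as nm
from . import phylo_dispersion as pdisp
from . import phylo_turnover as pturn
from . import taxonomic_turnover as tturn
from .synthetic_data import SimScenario, child_seeds, simulate_scenario

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "validate_design", "balanced_subset"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either point ``counts_path``/``metadata_path``/``tree_path`` at real
    inputs, or leave them unset to analyse a synthetic scenario.  The default
    synthetic scenario is deliberately small so a full run stays fast; the
    generator itself defaults to study-scale parameters.
    """

    counts_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    scenario: dict = field(default_factory=lambda: {
        "n_taxa": 150, "reads_per_sample": 2000, "filter_strength": 0.6,
        "bm_sigma": 1.0, "m_true": 0.05, "pool_shape": 0.995,
        "species_sizes": {"sp_A": 12, "sp_B": 9, "sp_C": 12},
    })
    filter_threshold: float = 0.001
    filter_scope: str = "overall"
    group_factor: str = "host_plant"          # null-model stratum
    species_factor: str = "fly_species"       # t-test pooling / Sloan groups
    null_models: tuple = ("taxa_labels", "independent_swap")
    n_perm_dispersion: int = 199
    n_perm_turnover: int = 199
    n_swaps: int = 500
    n_reps_rc: int = 199
    n_perm_permanova: int = 999
    unifrac_alpha: float = 0.5
    ci_level: float = 0.95
    seed: int = 0
    out_dir: str = "results/run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def validate_design(metadata: pd.DataFrame, factors) -> pd.DataFrame:
    """Cell counts of the crossed design; empty cells flagged, not dropped."""
    fa, fb = factors
    tab = metadata.groupby([fa, fb]).size().unstack(fill_value=0)
    empty = [(a, b) for a in tab.index for b in tab.columns if tab.loc[a, b] == 0]
    if empty:
        logger.warning("validate_design: empty cells %s", empty)
    return tab


def balanced_subset(metadata: pd.DataFrame, factors, seed: int | None = None) -> list[str]:
    """Balanced sample subset for analyses that require a complete crossing.

    Levels of the second factor with any empty cell are excluded; remaining
    cells are down-sampled (seeded) to the minimum cell size.
    """
    fa, fb = factors
    tab = validate_design(metadata, factors)
    keep_b = [b for b in tab.columns if (tab[b] > 0).all()]
    if not keep_b:
        raise ValueError("no level of the second factor is occupied by every level of the first")
    min_n = int(tab[keep_b].to_numpy().min())
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for a in tab.index:
        for b in keep_b:
            cell = metadata.index[(metadata[fa] == a) & (metadata[fb] == b)].to_numpy()
            pick = rng.choice(cell, size=min_n, replace=False)
            chosen.extend(sorted(pick))
    return chosen


def _write(frame: pd.DataFrame, path: Path, index=False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index)


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; returns a dict of stage outputs and file paths."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed, 10)
    report_sections: list[str] = []
    outputs: dict = {"files": {}}

    # --- inputs -----------------------------------------------------------
    if config.counts_path:
        if not config.tree_path or not Path(config.tree_path).exists():
            raise RuntimeError("pipeline stage 'community_io' failed: tree file missing")
        if not Path(config.counts_path).exists() or not Path(config.metadata_path).exists():
            raise RuntimeError("pipeline stage 'community_io' failed: counts/metadata file missing")
        table = cio.read_community_table(config.counts_path, config.metadata_path)
        tree = cio.read_tree(config.tree_path)
        newick = tree.as_string(schema="newick").strip()
    else:
        scen = SimScenario(seed=seeds[0], **config.scenario)
        sim = simulate_scenario(scen)
        table, newick = sim.table, sim.tree
        cio.write_community_table(table, out / "counts.tsv", out / "metadata.tsv")
        (out / "tree.nwk").write_text(newick + "\n")
        pool = sim.pool.rename("pool_abundance").to_frame()
        pool.index.name = "asv_id"
        _write(pool, out / "pool.tsv", index=True)
        truth = {k: v for k, v in sim.truth.items() if k != "trait"}
        (out / "truth.json").write_text(json.dumps(truth, indent=1, default=str))
        tree = cio.read_tree(newick)

    # --- filtering / normalization ---------------------------------------
    design = validate_design(table.metadata, (config.species_factor, config.group_factor))
    _write(design.reset_index(), out / "design.tsv")
    table = cio.abundance_filter(table, config.filter_threshold, scope=config.filter_scope)
    dist = cio.cophenetic_matrix(tree)
    table, dist = cio.align_table_tree(table, dist)
    rel = cio.normalize_proportions(table)

    # --- phylogenetic dispersion ------------------------------------------
    for i, null in enumerate(config.null_models):
        ses, tests = pdisp.dispersion_analysis(
            rel, dist, null_model=null, n_perm=config.n_perm_dispersion,
            group_by=config.group_factor, test_by=config.species_factor,
            seed=seeds[1] + i, n_swaps=config.n_swaps)
        _write(ses, out / f"ses_mntd_{null}.tsv")
        _write(tests, out / f"ses_mntd_{null}_ttests.tsv")
        outputs[f"ses_mntd_{null}"] = (ses, tests)
        report_sections.append(f"## ses.MNTD ({null} null)\n\n" + tests.to_string(index=False))

    # --- phylogenetic turnover --------------------------------------------
    pair_ses, bt_tests = pturn.turnover_analysis(
        rel, dist, n_perm=config.n_perm_turnover,
        group_by=(config.species_factor, config.group_factor),
        pool_by=config.species_factor, seed=seeds[2])
    _write(pair_ses, out / "ses_bmntd.tsv")
    _write(bt_tests, out / "ses_bmntd_ttests.tsv")
    outputs["ses_bmntd"] = (pair_ses, bt_tests)
    report_sections.append("## ses.betaMNTD (tip shuffle null)\n\n" + bt_tests.to_string(index=False))

    # --- taxonomic turnover (RC-Bray) -------------------------------------
    rc, rc_tests = tturn.rc_analysis(
        table, group_by=(config.species_factor, config.group_factor),
        pool_by=config.species_factor, n_reps=config.n_reps_rc, seed=seeds[3])
    _write(rc, out / "rc_bray.tsv")
    _write(rc_tests, out / "rc_bray_ttests.tsv")
    outputs["rc_bray"] = (rc, rc_tests)
    report_sections.append("## RC-Bray\n\n" + rc_tests.to_string(index=False))

    # --- neutral model -----------------------------------------------------
    fits = []
    part_rows = []
    for sp in sorted(table.metadata[config.species_factor].astype(str).unique()):
        ids = list(table.metadata.index[table.metadata[config.species_factor].astype(str) == sp])
        fit = nm.fit_sloan(table, sample_ids=ids, group=sp, ci_level=config.ci_level)
        fits.append(fit)
        rec = fit.records.reset_index()
        _write(rec, out / f"sloan_{sp}_records.tsv")
        part = nm.partition(fit, table, sample_ids=ids)
        part.insert(0, "group", sp)
        part_rows.append(part)
    part_all = pd.concat(part_rows, ignore_index=True)
    _write(part_all, out / "sloan_partition.tsv")
    fit_summary = pd.DataFrame([{k: getattr(f, k) for k in
                                 ("group", "m", "N", "d", "rmse", "rmse_binomial",
                                  "rmse_poisson", "n_asv", "n_samples")} for f in fits])
    _write(fit_summary, out / "sloan_fits.tsv")
    shared_above = sorted(nm.shared_signatures(fits, "above")) if len(fits) >= 2 else []
    shared_below = sorted(nm.shared_signatures(fits, "below")) if len(fits) >= 2 else []
    (out / "sloan_shared.json").write_text(json.dumps(
        {"above": shared_above, "below": shared_below}, indent=1))
    outputs["sloan"] = (fits, part_all, shared_above, shared_below)
    report_sections.append("## Sloan neutral model\n\n" + fit_summary.to_string(index=False)
                           + f"\n\nShared above: {len(shared_above)}; shared below: {len(shared_below)}")

    # --- beta diversity -----------------------------------------------------
    bal_ids = balanced_subset(table.metadata, (config.species_factor, config.group_factor),
                              seed=seeds[4])
    rel_bal = cio.normalize_proportions(table.subset_samples(bal_ids))
    perm_rows = []
    for metric in ("unweighted", "generalized"):
        dm = bd.unifrac_matrix(rel_bal, tree, metric=metric, alpha=config.unifrac_alpha)
        _write(dm.to_frame().reset_index(), out / f"unifrac_{metric}.tsv")
        coords, pct = bd.pcoa(dm, n_axes=2)
        coords = coords.copy()
        coords.index.name = "sample_id"
        _write(coords.reset_index(), out / f"pcoa_{metric}.tsv")
        pt = bd.permanova_two_way(dm, rel_bal.metadata, config.species_factor,
                                  config.group_factor, n_perm=config.n_perm_permanova,
                                  seed=seeds[5])
        pt.insert(0, "metric", metric)
        perm_rows.append(pt)
        ph = bd.pairwise_permanova(dm, rel_bal.metadata[config.species_factor],
                                   n_perm=config.n_perm_permanova, seed=seeds[6])
        _write(ph, out / f"permanova_posthoc_{metric}.tsv")
        outputs[f"betadiv_{metric}"] = (dm, pt, ph, pct)
    perm_all = pd.concat(perm_rows, ignore_index=True)
    _write(perm_all, out / "permanova.tsv")
    report_sections.append("## PERMANOVA\n\n" + perm_all.to_string(index=False))

    # --- report -------------------------------------------------------------
    report = "# Community-assembly analysis report\n\n" + "\n\n".join(report_sections) + "\n"
    (out / "report.md").write_text(report)
    prov = {"config": dataclasses.asdict(config), "seeds": seeds,
            "wall_time_s": round(time.time() - t0, 2)}
    (out / "provenance.json").write_text(json.dumps(prov, indent=1, default=str))
    outputs["files"] = {p.name: str(p) for p in sorted(out.iterdir())}
    outputs["report"] = report
    return outputs
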