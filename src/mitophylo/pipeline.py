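"""End-to-end orchestration: prep -> tree -> tests -> states -> dates -> rates.

A single YAML config drives all stages. Every random draw derives from the
master seed through named per-stage seeds recorded in the output manifest,
so a re-run with the same config is reproducible output-for-output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import ancrecon, chronos, divrate, phylolik, seqprep, synthgen, treetest
from .alignment import load_partitioned_alignment
from .seqprep import DatasetVariant
from .substmodels import SubstModelParams
from .treeio import write_newick

log = logging.getLogger("mitophylo")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "mitophylo_run",
    "variant": "12n3rRTn",
    "simulate": {"n_taxa": 8, "lengths": {"codon1": 300, "codon2": 300,
                                          "codon3": 300, "rRNA": 200, "tRNA": 100}},
    "model": {"alpha": 0.5, "n_categories": 4},
    "search": "nni",
    "autest": {"replicates": 2000},
    "ancrec": {"states": 4},
    "date": {"enabled": True, "burnin": 400, "n_samples": 300, "sample_every": 1},
    "divrate": {"epsilons": [0.0, 0.95]},
}


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["simulate", "autest", "date"]
    state = np.random.SeedSequence(seed).generate_state(len(names))
    return {n: int(s >> np.uint32(1)) for n, s in zip(names, state)}


def load_config(path: str | Path | dict) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    user = path if isinstance(path, dict) else yaml.safe_load(Path(path).read_text())
    for k, v in (user or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: dict | str | Path) -> dict:
    """Run all configured stages; returns a manifest of outputs and seeds.

    Any stage failure halts the run with the stage name; outputs of earlier
    stages are left in place.
    """
    cfg = load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]))
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {"config": cfg, "seeds": seeds, "outputs": {}}
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]

    def record(stage: str, **paths):
        manifest["outputs"][stage] = {k: str(v) for k, v in paths.items()}
        log.info("stage %s done: %s", stage, paths)

    try:
        # -- data ---------------------------------------------------------
        stage = "simulate"
        if cfg.get("simulate"):
            sim = cfg["simulate"]
            bd = synthgen.BirthDeathParams(b=0.055, d=0.025, t_max=400.0,
                                           n_target=int(sim.get("n_taxa", 8)))
            ds = synthgen.make_dataset(seeds["simulate"], bd=bd,
                                       lengths=sim.get("lengths"),
                                       missing_taxa_fraction=sim.get("missing_taxa_fraction", 0.0))
            datadir = outdir / "data"
            synthgen.write_dataset(ds, datadir)
            aln_path, part_path = datadir / "alignment.fasta", datadir / "partitions.tsv"
            trait = ds.trait
            true_tree = ds.tree
            record(stage, alignment=aln_path, partitions=part_path,
                   tree=datadir / "tree.nwk", trait=datadir / "trait.csv")
        else:
            inputs = cfg["inputs"]
            aln_path, part_path = inputs["alignment"], inputs["partitions"]
            trait = ancrecon.load_trait_csv(inputs["trait"]) if "trait" in inputs else None
            true_tree = None
            record(stage, alignment=aln_path, partitions=part_path)

        # -- prep ---------------------------------------------------------
        stage = "prep"
        aln = load_partitioned_alignment(aln_path, part_path)
        variant = DatasetVariant(cfg["variant"])
        prepped = seqprep.ry_recode(aln, variant)
        prep_path = outdir / f"alignment_{variant.name}.fasta"
        prepped.write(prep_path)
        prepped.write_partition_json(outdir / "partition_map.json")
        record(stage, alignment=prep_path)

        # -- ML tree ------------------------------------------------------
        stage = "mltree"
        params = SubstModelParams(pi=prepped.empirical_base_frequencies(),
                                  alpha=cfg["model"]["alpha"],
                                  n_categories=cfg["model"]["n_categories"])
        start = phylolik.nj_start_tree(prepped)
        if cfg.get("search") == "nni":
            search = phylolik.nni_search(prepped, start, params)
            ml_tree, ml_lnl = search.tree, search.log_likelihood
        else:
            res = phylolik.optimize_branch_lengths(prepped, start, params)
            ml_tree, ml_lnl = res.tree, res.log_likelihood
        ml_path = outdir / "ml_tree.nwk"
        write_newick(ml_tree, ml_path)
        record(stage, tree=ml_path, log_likelihood=f"{ml_lnl:.4f}")

        # -- site lnL + AU test -------------------------------------------
        stage = "sitelnl"
        candidates = {"ml": ml_tree, "nj": phylolik.nj_start_tree(prepped)}
        table = np.vstack([phylolik.site_log_likelihoods(prepped, t, params)
                           for t in candidates.values()])
        table_path = outdir / "site_lnl.tsv"
        treetest.write_site_lnl_table(table, list(candidates), table_path)
        record(stage, table=table_path)

        stage = "autest"
        report = treetest.constrained_vs_unconstrained_report(
            table, list(candidates), replicates=int(cfg["autest"]["replicates"]),
            seed=seeds["autest"])
        au_path = outdir / "au_test.tsv"
        report.to_csv(au_path, sep="\t", index=False)
        record(stage, report=au_path)

        # -- ancestral states ---------------------------------------------
        stage = "ancrec"
        if trait is not None:
            rec = ancrecon.reconstruct(ml_tree, trait, k=int(cfg["ancrec"]["states"]))
            anc_path = outdir / "ancestral_states.tsv"
            rec.to_frame().to_csv(anc_path, sep="\t", index=False)
            record(stage, table=anc_path, q=f"{rec.model.q:.6g}")

        # -- dating --------------------------------------------------------
        stage = "date"
        if cfg["date"].get("enabled") and true_tree is not None:
            root_age = true_tree.seed_node.age
            cons = [chronos.CalibrationConstraint(
                taxa=tuple(lf.taxon.label for lf in true_tree.leaf_node_iter()),
                lower=0.7 * root_age, upper=1.3 * root_age)]
            settings = chronos.ChainSettings(
                burnin=int(cfg["date"]["burnin"]),
                n_samples=int(cfg["date"]["n_samples"]),
                sample_every=int(cfg["date"]["sample_every"]),
                seed=seeds["date"])
            priors = chronos.ChronosPriors(rttm=root_age, rttmsd=root_age)
            post = chronos.two_step_date(aln, ml_tree, cons, priors=priors,
                                         settings=settings)
            date_path = outdir / "node_ages.tsv"
            post.summary().to_csv(date_path, sep="\t", index=False)
            record(stage, table=date_path,
                   rhat=f"{post.rhat_root_age:.3f}" if post.rhat_root_age else "")

        # -- diversification -----------------------------------------------
        stage = "divrate"
        inputs = divrate.packaged_table("table8_inputs")
        rates = divrate.diversification_table(inputs,
                                              epsilons=cfg["divrate"]["epsilons"])
        cover = divrate.coverage_summary(
            seqprep.load_diversity_table(divrate.packaged_path("table1_diversity")))
        rates_path = outdir / "diversification_rates.csv"
        cover_path = outdir / "taxon_coverage.csv"
        rates.to_csv(rates_path, index=False)
        cover.to_csv(cover_path)
        record(stage, rates=rates_path, coverage=cover_path)
    except Exception as exc:  # noqa: BLE001 - annotate with the stage name
        log.removeHandler(handler)
        raise StageError(stage, exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    log.removeHandler(handler)
    return manifest
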