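"""One-command orchestration of the whole super-barcoding analysis.

``run_all`` reproduces the study design end to end on either a synthetic
bundle or user data: variation profiles (per-region and sliding-window pi),
the K2P matrix, the six-panel window diagnostics, the barcoding-gap and
diagnostic-character report, ASAP-style partitioning, a neighbor-joining
tree, GMYC on an ultrametrized tree and PTP on the substitutions tree, and
a cross-method comparison.  Each stage writes plain TSV/JSON/Newick outputs
under one directory; a JSON manifest records per-stage status and output
hashes, and failures in one stage do not stop later independent stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignio, asap, barcode, compare, divstats, gmyc, ptp, simulate, trees

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and settings of one pipeline run.

    Either ``synth`` (a :class:`~superbarcode.simulate.SynthConfig` or the
    name ``"calypogeia-like"``) or the ``alignment``/``species_map`` paths
    must be given.  Defaults mirror the published analysis settings:
    500/50 sliding windows, and MCMC 500,000 generations, thinning 100,
    seed 123 for Bayesian PTP.
    """

    outdir: str = "superbarcode_run"
    alignment: str | None = None
    species_map: str | None = None
    regions: str | None = None
    tree: str | None = None  # substitutions-scaled Newick for GMYC/PTP
    synth: object | None = None
    exclude: list[tuple[int, int]] = field(default_factory=list)
    width: int = 500
    step: int = 50
    n_perm_gap: int = 1000
    n_perm_asap: int = 999
    run_ptp_bayes: bool = False
    mcmc_generations: int = 500_000
    mcmc_thinning: int = 100
    mcmc_seed: int = 123
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        if isinstance(d.get("synth"), dict):
            d["synth"] = simulate.SynthConfig.from_json(json.dumps(d["synth"]))
        if d.get("exclude"):
            d["exclude"] = [tuple(iv) for iv in d["exclude"]]
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Runner:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.out = Path(cfg.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"stages": {}, "outputs": {}}
        self.results: dict = {}
        self.log_path = self.out / "run.log"
        self._log_fh = open(self.log_path, "w")

    def log(self, stage: str, message: str) -> None:
        line = f"{stage}: {message}"
        logger.info(line)
        self._log_fh.write(line + "\n")
        self._log_fh.flush()

    def stage(self, name: str, fn, *deps: str) -> None:
        missing = [d for d in deps if self.manifest["stages"].get(d, {}).get("status") != "ok"]
        if missing:
            self.manifest["stages"][name] = {"status": "skipped",
                                             "reason": f"needs {missing}"}
            self.log(name, f"skipped (needs {missing})")
            return
        t0 = time.perf_counter()
        try:
            outputs = fn() or []
            entry = {"status": "ok",
                     "outputs": {p.name: _sha256(p) for p in outputs}}
            self.manifest["stages"][name] = entry
            self.manifest["outputs"].update(entry["outputs"])
            self.log(name, f"ok ({time.perf_counter() - t0:.2f}s) "
                           f"outputs={[p.name for p in outputs]}")
        except Exception as exc:
            self.manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            self.log(name, f"FAILED: {exc}\n{traceback.format_exc()}")


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json).

    The manifest's ``stages`` entries carry ``ok``/``failed``/``skipped``
    status; callers that need a hard failure should check
    ``all_ok(manifest)``.
    """
    # input validation up front, before any compute
    if cfg.synth is None:
        if not cfg.alignment or not cfg.species_map:
            raise alignio.AlignmentError(
                "need either a synth config or alignment + species_map paths"
            )
        for label, p in (("alignment", cfg.alignment), ("species map", cfg.species_map)):
            if not Path(p).exists():
                raise alignio.AlignmentError(f"missing {label} file: {p}")

    r = _Runner(cfg)
    ctx: dict = {}

    def load_data():
        if cfg.synth is not None:
            synth = cfg.synth
            if synth == "calypogeia-like":
                synth = simulate.calypogeia_like(seed=cfg.seed)
            ds = simulate.make_dataset(synth)
            paths = simulate.write_bundle(ds, r.out / "dataset")
            ctx["aln"] = ds.alignment
            ctx["regions"] = ds.regions
            ctx["truth"] = ds.true_partition
            ctx["gene_tree"] = ds.gene_tree
            return [Path(p) for p in paths.values()]
        ctx["aln"] = alignio.read_alignment(cfg.alignment, cfg.species_map)
        ctx["regions"] = alignio.read_regions(cfg.regions) if cfg.regions else None
        ctx["truth"] = None
        ctx["gene_tree"] = trees.read_tree(cfg.tree) if cfg.tree else None
        return []

    def exclude():
        ctx["aln"] = alignio.drop_columns(ctx["aln"], cfg.exclude)
        return []

    def windows():
        ws = divstats.windowed_pi(ctx["aln"], cfg.width, cfg.step)
        p = r.out / "windows_pi.tsv"
        ws.to_frame().to_csv(p, sep="\t", index=False)
        return [p]

    def regions_stage():
        if ctx["regions"] is None:
            raise alignio.AlignmentError("no region table given")
        df = divstats.region_stats(ctx["aln"], ctx["regions"])
        p = r.out / "region_stats.tsv"
        df.to_csv(p, sep="\t", index=False)
        contrast = divstats.coding_noncoding_contrast(ctx["aln"], ctx["regions"])
        p2 = r.out / "coding_noncoding.json"
        p2.write_text(json.dumps(contrast, indent=2, sort_keys=True))
        return [p, p2]

    def k2p_stage():
        dm = barcode.k2p_matrix(ctx["aln"])
        ctx["dm"] = dm
        p = r.out / "k2p_matrix.tsv"
        dm.to_frame().to_csv(p, sep="\t")
        return [p]

    def window_suite():
        wd = barcode.window_diagnostics(ctx["aln"], cfg.width, cfg.step)
        p = r.out / "window_diagnostics.tsv"
        wd.frame.to_csv(p, sep="\t", index=False)
        r.manifest["baseline_prop_zero_cells"] = wd.baseline_prop_zero_cells
        return [p]

    def gap_stage():
        df = barcode.barcoding_gap(ctx["dm"], ctx["aln"].species_of,
                                   n_perm=cfg.n_perm_gap, seed=cfg.seed,
                                   aln=ctx["aln"])
        p = r.out / "gap_report.tsv"
        df.to_csv(p, sep="\t", index=False)
        return [p]

    def asap_stage():
        res = asap.AsapModel(ctx["dm"]).fit(n_perm=cfg.n_perm_asap, seed=cfg.seed)
        ctx["asap"] = res
        p = r.out / "asap_partitions.tsv"
        res.summary().to_csv(p, sep="\t", index=False)
        p2 = r.out / "asap_best_partition.tsv"
        pd.DataFrame(sorted(res.best.groups.items()),
                     columns=["specimen_id", "group"]).to_csv(p2, sep="\t", index=False)
        p3 = r.out / "asap_dendrogram.nwk"
        p3.write_text(res.dendrogram_newick() + "\n")
        return [p, p2, p3]

    def nj_stage():
        tree = barcode.nj_tree(ctx["dm"])
        ctx["nj"] = tree
        p = r.out / "nj_tree.nwk"
        trees.write_tree(tree, p)
        return [p]

    def gmyc_stage():
        base = ctx.get("gene_tree")
        if base is not None and trees.is_ultrametric(base):
            um = base
        else:
            src = base if base is not None else ctx["nj"]
            um = trees.ultrametrize(trees.midpoint_root(src))
        res = gmyc.GmycModel(um).fit()
        ctx["gmyc"] = res
        p = r.out / "gmyc.json"
        p.write_text(json.dumps({
            "threshold_time": res.threshold_time, "n_entities": res.n_entities,
            "lambda_yule": res.lambda_yule, "p_yule": res.p_yule,
            "lambda_coal": res.lambda_coal, "p_coal": res.p_coal,
            "logL_alt": res.logL_alt, "logL_null": res.logL_null,
            "LR": res.LR, "p_value": res.p_value,
            "entities": {k: int(v) for k, v in sorted(res.entities.items())},
        }, indent=2, sort_keys=True))
        return [p]

    def ptp_stage():
        base = ctx.get("gene_tree") or ctx.get("nj")
        if base is None:
            raise ptp.PtpError("no tree available")
        model = ptp.PtpModel(trees.midpoint_root(base))
        res = model.fit(seed=cfg.seed)
        ctx["ptp"] = res
        payload = {
            "n_species": res.n_species, "logL": res.logL,
            "lambda_spec": res.lambda_spec, "lambda_within": res.lambda_within,
            "partition": {k: int(v) for k, v in sorted(res.ml_partition.items())},
            "flags": res.flags,
        }
        out = [r.out / "ptp_ml.json"]
        out[0].write_text(json.dumps(payload, indent=2, sort_keys=True))
        if cfg.run_ptp_bayes:
            bres = model.fit_mcmc(generations=cfg.mcmc_generations,
                                  thinning=cfg.mcmc_thinning, seed=cfg.mcmc_seed)
            ctx["ptp_bayes"] = bres
            bp = r.out / "ptp_bayes.json"
            bp.write_text(json.dumps({
                "n_species": bres.n_species, "logL": bres.logL,
                "partition": {k: int(v) for k, v in sorted(bres.ml_partition.items())},
                "support": {",".join(sorted(sp)): bres.posterior_support.get(sp, 0.0)
                            for sp in bres.species},
                "mcmc": bres.mcmc,
            }, indent=2, sort_keys=True))
            out.append(bp)
        return out

    def compare_stage():
        parts = {}
        if "asap" in ctx:
            parts["asap"] = ctx["asap"].best.groups
        if "gmyc" in ctx:
            parts["gmyc"] = ctx["gmyc"].entities
        if "ptp" in ctx:
            parts["ptp_ml"] = ctx["ptp"].ml_partition
        rep = compare.delimitation_report(parts, truth=ctx.get("truth"))
        p = r.out / "method_comparison.tsv"
        rep["summary"].to_csv(p, sep="\t", index=False)
        p2 = r.out / "method_pairwise_ari.tsv"
        rep["pairwise_ari"].to_csv(p2, sep="\t")
        p3 = r.out / "disagreements.json"
        p3.write_text(json.dumps(rep["disagreements"], indent=2))
        return [p, p2, p3]

    r.stage("load_data", load_data)
    r.stage("exclude_columns", exclude, "load_data")
    r.stage("windowed_pi", windows, "exclude_columns")
    r.stage("region_stats", regions_stage, "exclude_columns")
    r.stage("k2p_matrix", k2p_stage, "exclude_columns")
    r.stage("window_diagnostics", window_suite, "exclude_columns")
    r.stage("barcoding_gap", gap_stage, "k2p_matrix")
    r.stage("asap", asap_stage, "k2p_matrix")
    r.stage("nj_tree", nj_stage, "k2p_matrix")
    r.stage("gmyc", gmyc_stage, "load_data")
    r.stage("ptp", ptp_stage, "load_data")
    r.stage("compare", compare_stage, "asap")

    r.manifest["config"] = {
        k: (json.loads(v.to_json()) if isinstance(v, simulate.SynthConfig) else v)
        for k, v in dataclasses.asdict(cfg).items()
    }
    (r.out / "manifest.json").write_text(
        json.dumps(r.manifest, indent=2, sort_keys=True, default=str)
    )
    r._log_fh.close()
    r.manifest["_results"] = r.results or ctx
    return r.manifest


def all_ok(manifest: dict, required: tuple[str, ...] | None = None) -> bool:
    """True if no stage failed (or if every `required` stage is ok)."""
    stages = manifest["stages"]
    if required is not None:
        return all(stages.get(n, {}).get("status") == "ok" for n in required)
    return not any(s["status"] == "failed" for s in stages.values())
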