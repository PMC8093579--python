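"""End-to-end driver: catalog -> signatures -> clusters -> APOBEC -> pairs.

A :class:`RunConfig` carries every stage parameter (defaults are the
pipeline's canonical thresholds: 80% subsampling, 1000 consensus
iterations, K max 9, DEG |log2FC| > 1 and FDR < 0.05, imbalance 0.90,
CPGPS minimum 6 cohorts, FDR 0.05, beta threshold 0.3) plus a master
seed from which each stage draws its own deterministic substream, so
adding a stage never perturbs earlier stages' randomness.  ``run_all``
executes the stages in order, records provenance (parameters, seeds,
input/output SHA-256 hashes, durations) in a machine-readable run
report, skips downstream stages after a failure, and on re-run resumes
from completed stage outputs whose hashes still match.
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
import yaml

from . import __version__
from .apobec import apobec_enrichment
from .catalog import MutationCatalog, RejectLog, build_catalog, read_maf
from .consensus import ConsensusCluster
from .cosmic import load_reference
from .nmf import SignatureModel
from .pairs import ExpressionCohort, GenePairScreen
from .simulate import CatalogSimSpec, CohortSimSpec, simulate_catalog, simulate_cohorts

log = logging.getLogger("crcsig")

STAGES = ("catalog", "extract", "cluster", "apobec", "pairs")


@dataclass
class RunConfig:
    """All pipeline parameters; paper-stated defaults are the defaults."""

    out_dir: str = "crcsig_run"
    seed: int = 0
    # inputs: either real files or simulation
    maf: str | None = None
    ref_fasta: str | None = None
    cohort_manifest: str | None = None  # YAML: cohort_id -> {expr, clinical}
    simulate: bool = True
    sim_catalog: dict = field(default_factory=dict)
    sim_cohorts: dict = field(default_factory=dict)
    # stage parameters
    use_frequencies: bool = False
    ranks: tuple[int, int] = (2, 6)
    n_restarts: int = 30
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    k_max: int = 9
    cluster_iters: int = 1000
    subsample_fraction: float = 0.8
    apobec_flank: int = 20
    deg_list: str | None = None        # file with one gene per line, or None
    deg_lfc_min: float = 1.0
    deg_fdr_max: float = 0.05
    imbalance_max: float = 0.90
    min_cohorts: int = 6
    fdr_max: float = 0.05
    beta_threshold: float = 0.3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ranks" in raw:
            raw["ranks"] = tuple(raw["ranks"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ranks"] = list(d["ranks"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([master, idx]).generate_state(1)[0] % (2**31))


class _Report:
    def __init__(self, out: Path, config: RunConfig):
        self.path = out / "run_report.json"
        self.data = {
            "version": __version__,
            "config": config.to_dict(),
            "stages": {},
        }
        self.previous = {}
        if self.path.exists():
            try:
                self.previous = json.loads(self.path.read_text()).get("stages", {})
            except (json.JSONDecodeError, OSError):
                self.previous = {}

    def can_resume(self, stage: str) -> bool:
        prev = self.previous.get(stage)
        if not prev or prev.get("status") != "ok":
            return False
        for f, digest in prev.get("outputs", {}).items():
            p = Path(f)
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, stage: str, status: str, outputs: dict[str, str],
               seconds: float, seed: int | None = None, error: str | None = None):
        self.data["stages"][stage] = {
            "status": status,
            "outputs": outputs,
            "seconds": round(seconds, 3),
            "seed": seed,
            "error": error,
        }
        self.path.write_text(json.dumps(self.data, indent=2))


def _hash_outputs(paths: list[Path]) -> dict[str, str]:
    return {str(p): _sha256(p) for p in paths if p.exists()}


def _load_cohorts(config: RunConfig) -> tuple[list[ExpressionCohort], list[str]]:
    if config.simulate:
        spec = CohortSimSpec(
            **{**config.sim_cohorts, "seed": config.sim_cohorts.get(
                "seed", _stage_seed(config.seed, "pairs"))}
        )
        cohorts, truth = simulate_cohorts(spec)
        return cohorts, truth.candidate_genes
    if config.cohort_manifest is None:
        raise ValueError("cohort_manifest required when simulate is false")
    with open(config.cohort_manifest) as fh:
        manifest = yaml.safe_load(fh)
    cohorts = []
    for cid, paths in manifest.items():
        expr = pd.read_csv(paths["expr"], sep="\t", index_col=0)
        clin = pd.read_csv(paths["clinical"], sep="\t", index_col=0)
        cohorts.append(ExpressionCohort(cid, expr, clin))
    if config.deg_list:
        genes = [ln.strip() for ln in open(config.deg_list) if ln.strip()]
    else:
        raise ValueError("deg_list required for non-simulated cohort runs "
                         "(the DEG screen needs subtype labels)")
    return cohorts, genes


def run_all(config: RunConfig) -> dict:
    """Execute all stages; returns the run report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = _Report(out, config)
    failed = False

    # ------------------------------------------------------------- catalog
    catalog: MutationCatalog | None = None
    records = None
    reference = None
    t0 = time.time()
    stage_seed = _stage_seed(config.seed, "catalog")
    cat_path = out / "catalog.tsv"
    try:
        if report.can_resume("catalog"):
            catalog = MutationCatalog.read(cat_path)
            report.record("catalog", "ok", _hash_outputs([cat_path]),
                          time.time() - t0, stage_seed)
        elif config.simulate:
            spec = CatalogSimSpec(**{**config.sim_catalog,
                                     "seed": config.sim_catalog.get("seed", stage_seed)})
            catalog, truth = simulate_catalog(spec)
            truth.to_csv(out / "catalog_truth.tsv", sep="\t")
        else:
            if not config.maf or not config.ref_fasta:
                raise ValueError("maf and ref_fasta required when simulate is false")
            import pyfaidx

            reference = pyfaidx.Fasta(config.ref_fasta)
            rejects = RejectLog()
            records = read_maf(config.maf, rejects)
            catalog = build_catalog(records, reference, reject_log=rejects)
            rejects.write(out / "reject_log.tsv")
        catalog.write(cat_path)
        report.record("catalog", "ok", _hash_outputs([cat_path]),
                      time.time() - t0, stage_seed)
    except Exception as exc:  # noqa: BLE001 - report and halt downstream
        log.exception("catalog stage failed")
        report.record("catalog", "failed", {}, time.time() - t0, stage_seed,
                      str(exc))
        failed = True

    # ------------------------------------------------------------- extract
    exposures = None
    if not failed:
        t0 = time.time()
        stage_seed = _stage_seed(config.seed, "extract")
        try:
            model = SignatureModel(catalog, use_frequencies=config.use_frequencies)
            lo, hi = config.ranks
            sel = model.select_rank(range(lo, hi + 1), config.n_restarts,
                                    config.nmf_max_iter, config.nmf_tol,
                                    seed=stage_seed)
            res = sel.best
            res.profiles.to_csv(out / "profiles.tsv", sep="\t")
            res.exposures.to_csv(out / "exposures.tsv", sep="\t")
            sel.metrics.to_csv(out / "rank_metrics.tsv", sep="\t")
            ann = res.annotate(load_reference())
            ann.to_json(out / "annotation.json", orient="index", indent=2)
            exposures = res
            outs = [out / f for f in
                    ("profiles.tsv", "exposures.tsv", "rank_metrics.tsv",
                     "annotation.json")]
            report.record("extract", "ok", _hash_outputs(outs),
                          time.time() - t0, stage_seed)
        except Exception as exc:  # noqa: BLE001
            log.exception("extract stage failed")
            report.record("extract", "failed", {}, time.time() - t0,
                          stage_seed, str(exc))
            failed = True

    # ------------------------------------------------------------- cluster
    if not failed:
        t0 = time.time()
        stage_seed = _stage_seed(config.seed, "cluster")
        try:
            frac = exposures.exposure_fractions().T  # samples x signatures
            cc = ConsensusCluster(frac).fit(
                k_max=config.k_max, n_iter=config.cluster_iters,
                subsample_fraction=config.subsample_fraction, seed=stage_seed,
            )
            cc.labels_frame().to_csv(out / "cluster_labels.tsv", sep="\t")
            cc.summary().to_csv(out / "pac.tsv", sep="\t")
            outs = [out / "cluster_labels.tsv", out / "pac.tsv"]
            report.record("cluster", "ok", _hash_outputs(outs),
                          time.time() - t0, stage_seed)
        except Exception as exc:  # noqa: BLE001
            log.exception("cluster stage failed")
            report.record("cluster", "failed", {}, time.time() - t0,
                          stage_seed, str(exc))
            failed = True

    # ------------------------------------------------------------- apobec
    if not failed:
        t0 = time.time()
        stage_seed = _stage_seed(config.seed, "apobec")
        try:
            if config.simulate or records is None:
                # no per-mutation records in simulated catalogs; stage is a
                # no-op recorded as skipped rather than failed
                report.record("apobec", "skipped", {}, time.time() - t0,
                              stage_seed, "no MAF records available")
            else:
                res = apobec_enrichment(records, reference,
                                        flank=config.apobec_flank)
                res.to_csv(out / "apobec.tsv", sep="\t")
                report.record("apobec", "ok",
                              _hash_outputs([out / "apobec.tsv"]),
                              time.time() - t0, stage_seed)
        except Exception as exc:  # noqa: BLE001
            log.exception("apobec stage failed")
            report.record("apobec", "failed", {}, time.time() - t0,
                          stage_seed, str(exc))
            failed = True

    # --------------------------------------------------------------- pairs
    if not failed:
        t0 = time.time()
        stage_seed = _stage_seed(config.seed, "pairs")
        try:
            cohorts, genes = _load_cohorts(config)
            screen = GenePairScreen(cohorts, genes)
            res = screen.fit(min_cohorts=config.min_cohorts,
                             fdr_max=config.fdr_max,
                             max_fraction=config.imbalance_max)
            outs = []
            for cid, df in res.screens.items():
                p = out / f"pair_screen_{cid}.tsv"
                df.to_csv(p, sep="\t")
                outs.append(p)
            cp = out / "cpgps.json"
            res.cpgps.reset_index().to_json(cp, orient="records", indent=2)
            outs.append(cp)
            mt = out / "metastasis.tsv"
            res.metastasis.to_csv(mt, sep="\t", index=False)
            outs.append(mt)
            report.record("pairs", "ok", _hash_outputs(outs),
                          time.time() - t0, stage_seed)
        except Exception as exc:  # noqa: BLE001
            log.exception("pairs stage failed")
            report.record("pairs", "failed", {}, time.time() - t0,
                          stage_seed, str(exc))
            failed = True

    return report.data
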