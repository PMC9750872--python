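"""End-to-end orchestration of the screen and association stages.

A run is driven by a :class:`RunConfig` (YAML-serializable); every output
directory receives the resolved config, the result tables, and a JSON
provenance record (package/library versions, config hash, seeds, per-stage
timings and warning tallies) so any output can be traced to the exact
configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .counting import CountTable, SampleInfo, count_reads, mapping_stats, read_counts
from .genescore import (
    GeneScoreResult,
    make_negative_control_genes,
    plot_volcano,
    score_genes,
    volcano_table,
)
from .library import SgRNALibrary, load_library
from .mutassoc import (
    RAS_RAF_GENES,
    build_matrix,
    filter_mutations,
    geneset_association,
    read_mutation_table,
    wilcoxon_association,
)
from .phenotype import PhenotypeParams, compute_phenotypes
from .sim import SimConfig, simulate_library, simulate_screen

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Serializable configuration of a full run.

    Exactly one count source is used: ``sim`` (simulate), ``fastq`` (count
    reads against ``library``), or ``counts`` (pre-made table + sidecar).
    """

    seed: int = 0
    library: str | None = None
    counts: str | None = None
    fastq: dict[str, str] = field(default_factory=dict)  # sample name -> path
    samples: list[dict] = field(default_factory=list)    # name/role/doublings
    sim: dict | None = None                              # SimConfig overrides
    offset: int = 0
    scan: bool = False
    phenotype: dict = field(default_factory=dict)        # PhenotypeParams fields
    scoring: dict = field(default_factory=dict)          # threshold/top_k/n_pseudo/...
    assoc: dict = field(default_factory=dict)            # maf/ic50/cadd_min/...

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _provenance(config: RunConfig, stages: dict, extra: dict | None = None) -> dict:
    import numpy, scipy  # noqa: PLC0415

    rec = {
        "chemscreen_version": __version__,
        "numpy_version": numpy.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stages,
    }
    if extra:
        rec.update(extra)
    return rec


class _StageTimer:
    def __init__(self) -> None:
        self.stages: dict[str, dict] = {}
        self._name: str | None = None
        self._t0 = 0.0
        self._warns: warnings.catch_warnings | None = None
        self._log: list = []

    def stage(self, name: str):
        timer = self

        class _Ctx:
            def __enter__(self):
                timer._name = name
                timer._t0 = time.perf_counter()
                timer._warns = warnings.catch_warnings(record=True)
                timer._log = timer._warns.__enter__()
                warnings.simplefilter("always")
                return self

            def __exit__(self, exc_type, exc, tb):
                elapsed = time.perf_counter() - timer._t0
                n_warn = len(timer._log)
                msgs = [str(w.message) for w in timer._log]
                timer._warns.__exit__(None, None, None)
                timer.stages[name] = {
                    "seconds": round(elapsed, 3),
                    "warnings": n_warn,
                    "warning_messages": msgs[:20],
                }
                if exc is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: %.2fs, %d warnings", name, elapsed, n_warn)

        return _Ctx()


def run_screen_pipeline(config: RunConfig, outdir: str | Path) -> GeneScoreResult:
    """Simulate-or-count -> phenotypes -> gene scores -> reports.

    Writes library/counts/truth (simulation runs), ``phenotypes.tsv``,
    ``gene_scores.tsv`` (TSS-collapsed) + ``gene_scores_per_tss.tsv`` +
    ``pseudo_gene_scores.tsv``, ``hits.tsv``, ``volcano.tsv`` /
    ``volcano.png``, the resolved config and ``provenance.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timer = _StageTimer()
    extra: dict = {}

    with timer.stage("inputs"):
        if config.sim is not None:
            sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
            library = simulate_library(sim_cfg)
            counts, truth = simulate_screen(library, sim_cfg)
            library.to_csv(outdir / "library.csv")
            counts.write(outdir / "counts.tsv")
            truth.write(outdir / "truth_genes.tsv", outdir / "truth_sgrnas.tsv")
            phen_defaults = {
                "doublings_untreated": sim_cfg.doublings_untreated,
                "doubling_difference": sim_cfg.doubling_difference,
            }
        else:
            if config.library is None:
                raise ValueError("a library path is required without simulation")
            library = load_library(config.library)
            samples = [SampleInfo(**s) for s in config.samples]
            if config.fastq:
                counts = count_reads(dict(config.fastq), library, samples,
                                     offset=config.offset, scan=config.scan)
                counts.write(outdir / "counts.tsv")
            elif config.counts:
                counts = read_counts(config.counts, library,
                                     samples=samples or None)
            else:
                raise ValueError("one of sim / fastq / counts must be provided")
            phen_defaults = {}
        extra["mapping_stats"] = mapping_stats(counts)

    with timer.stage("phenotype"):
        params = PhenotypeParams(**{**phen_defaults, **config.phenotype})
        phen = compute_phenotypes(counts, library, params)
        phen.write(outdir / "phenotypes.tsv")

    with timer.stage("genescore"):
        sc = dict(config.scoring)
        n_genes = library.targeting.groupby(["gene", "tss"]).ngroups
        modal = int(library.targeting.groupby(["gene", "tss"]).size().mode()[0])
        ncg = make_negative_control_genes(
            library,
            n_pseudo=sc.pop("n_pseudo", None) or n_genes,
            size=sc.pop("pseudo_size", None) or modal,
            seed=sc.pop("ncg_seed", None) or config.seed,
        )
        result = score_genes(phen.table, ncg, **sc)
        result.per_tss.to_csv(outdir / "gene_scores_per_tss.tsv", sep="\t", index=False)
        result.write(outdir / "gene_scores.tsv")
        result.pseudo.to_csv(outdir / "pseudo_gene_scores.tsv", sep="\t", index=False)
        result.hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
        volcano_table(result).to_csv(outdir / "volcano.tsv", sep="\t", index=False)
        plot_volcano(result, outdir / "volcano.png")
        extra["n_hits"] = int(result.hits.shape[0])
        extra["mu_ncg"] = result.mu_ncg
        extra["sigma_ncg"] = result.sigma_ncg

    config.write(outdir / "config_resolved.yaml")
    (outdir / "provenance.json").write_text(
        json.dumps(_provenance(config, timer.stages, extra), indent=2)
    )
    return result


def run_assoc_pipeline(config: RunConfig, outdir: str | Path) -> pd.DataFrame:
    """Mutation filtering -> binary matrix -> per-gene and gene-set Wilcoxon
    association with IC50s; writes the sorted report and provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timer = _StageTimer()
    a = dict(config.assoc)
    extra: dict = {}

    with timer.stage("load"):
        records = read_mutation_table(a["maf"], column_map=a.get("column_map"))
        ic50_tab = pd.read_csv(a["ic50"])
        if not {"cell_line", "ic50"} <= set(ic50_tab.columns):
            raise ValueError("IC50 table needs columns cell_line, ic50")
        ic50 = ic50_tab.set_index("cell_line")["ic50"].astype(float)

    with timer.stage("filter"):
        retained = filter_mutations(
            records, cadd_min=a.get("cadd_min", 15.0),
            class_map=a.get("class_map"), strict=a.get("strict", False),
        )
        matrix = build_matrix(retained, list(ic50.index),
                              on_unknown_line=a.get("on_unknown_line", "drop"))
        matrix.to_csv(outdir / "mutation_matrix.tsv", sep="\t")
        extra["n_records_in"] = int(len(records))
        extra["n_records_retained"] = int(len(retained))

    with timer.stage("associate"):
        report = wilcoxon_association(matrix, ic50, min_group=a.get("min_group", 2))
        gene_set = tuple(a.get("gene_set", RAS_RAF_GENES))
        try:
            gs = geneset_association(matrix, ic50, genes=gene_set,
                                     min_group=a.get("min_group", 2))
            gs_row = pd.DataFrame([gs.__dict__]).rename(columns={"label": "gene"})
            gs_row["bh_fdr"] = float("nan")
            report_all = pd.concat([gs_row, report], ignore_index=True)
        except ValueError as err:
            warnings.warn(f"gene-set association unavailable: {err}", stacklevel=2)
            report_all = report
        report_all.to_csv(outdir / "association.tsv", sep="\t", index=False)
        extra["n_testable_genes"] = int(report["p_value"].notna().sum())

    config.write(outdir / "config_resolved.yaml")
    (outdir / "provenance.json").write_text(
        json.dumps(_provenance(config, timer.stages, extra), indent=2)
    )
    return report_all


def run_demo(outdir: str | Path, seed: int = 0) -> dict:
    """Minute-scale smoke test: a 20-gene simulated screen with two strong
    planted sensitizing genes must return exactly those genes as hits."""
    from .sim import Dist

    cfg = RunConfig(
        seed=seed,
        sim={
            "n_genes": 20,
            "n_nontargeting": 50,
            "frac_hit_genes": 0.1,
            "rho_effect_dist": Dist("signed_uniform", (0.5, 0.8, 1.0)),
            "mean_reads_per_sgrna": 2000.0,
        },
    )
    result = run_screen_pipeline(cfg, outdir)
    truth = pd.read_csv(Path(outdir) / "truth_genes.tsv", sep="\t")
    planted = set(truth.loc[truth["true_rho"] != 0, "gene"])
    called = set(result.hits["gene"])
    return {
        "planted": sorted(planted),
        "called": sorted(called),
        "recovered": planted == called,
    }
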