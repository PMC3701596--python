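"""End-to-end orchestration of the staged analysis.

Stages run in order — (optional) simulate, stage-1 state test, stage-2
strict classification, variance screen + dispersion trajectories,
(optional) gene-set enrichment, report — with every intermediate table
written to disk so the pipeline is restartable, per-stage counts logged,
and one global seed expanded into independent per-stage child seeds.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffstate, report, setops, simdata, syncvar, trendclass
from .study import ExpressionStudy, read_study, write_study, write_table

log = logging.getLogger(__name__)

_STAGES = ("simulate", "de", "strict", "variability", "enrich", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    outdir: str = "periphsleep_run"
    matrix: str | None = None
    samples: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None
    simulate: bool = False
    n_probes: int = 5000
    n_baseline: int = 10
    n_per_group: int = 8
    tissues: tuple = ("heart", "lung")
    fdr_de: float = 0.01
    fdr_slope: float = 0.01
    q_bartlett: float = 0.01
    p_bf: float = 0.01
    n_perm: int = 1000
    seed: int = 0
    cv_scale: str = "linear"
    enrich_q: float = 0.05

    def __post_init__(self):
        for name in ("fdr_de", "fdr_slope", "q_bartlett", "p_bf", "enrich_q"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.cv_scale not in ("linear", "log2"):
            raise ValueError("cv_scale must be 'linear' or 'log2'")
        if not self.simulate and (self.matrix is None or self.samples is None):
            raise ValueError("provide matrix+samples paths or set simulate: true")
        self.tissues = tuple(self.tissues)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_manifest(self) -> dict:
        return {f"config:{k}": v for k, v in dataclasses.asdict(self).items()}


def _child_seeds(seed: int, n: int):
    """Expand the global seed into per-stage seeds below 2**31."""
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns ``{product name: path}``.

    Any stage failure raises :class:`PipelineError` naming the stage.
    Stage contracts (strict set within DE set; flagged variability probes
    within the Bartlett survivors) are asserted at run time.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(_STAGES, _child_seeds(config.seed, len(_STAGES))))
    tables: dict[str, pd.DataFrame] = {}

    # -- inputs ----------------------------------------------------------
    stage = "simulate"
    try:
        annotation = None
        if config.simulate:
            spec = simdata.DesignSpec(
                n_baseline=config.n_baseline, n_per_group=config.n_per_group,
                tissues=config.tissues, n_probes=config.n_probes,
            )
            studies, truth = simdata.generate_study(spec, seed=seeds["simulate"])
            simdata.write_truth(truth, outdir / "truth.tsv")
            for tissue, study in studies.items():
                write_study(study, outdir / f"matrix_{tissue}.tsv",
                            outdir / f"samples_{tissue}.tsv")
            annotation = simdata.probe_annotation(config.n_probes)
            log.info("simulated %d probes x %d tissues (seed %d)",
                     config.n_probes, len(studies), seeds["simulate"])
        else:
            full = read_study(config.matrix, config.samples)
            studies = {t: full.subset(tissue=t) for t in full.tissues()
                       if t in config.tissues or not config.tissues}
            if not studies:
                raise ValueError(
                    f"no requested tissue among {full.tissues()}"
                )
            if config.annotation:
                annotation = pd.read_csv(config.annotation, sep="\t")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage 1 + 2 per tissue ------------------------------------------
    labels_by_tissue = {}
    for tissue, study in studies.items():
        stage = "de"
        try:
            de = diffstate.state_analysis(
                study, tissue, fdr_threshold=config.fdr_de,
                n_perm=config.n_perm, seed=seeds["de"],
            )
            tables[f"de_{tissue}"] = de
            log.info("[de] %s: %d probes tested, %d called",
                     tissue, len(de), int(de["is_de"].sum()))
        except Exception as exc:
            raise PipelineError(stage, f"{tissue}: {exc}") from exc
        stage = "strict"
        try:
            de_probes = de.index[de["is_de"]]
            trend = trendclass.fit_trend(study, tissue, probes=de_probes,
                                         fdr_threshold=config.fdr_slope)
            labels = trendclass.classify_strict(de, trend,
                                               fdr_threshold=config.fdr_slope)
            strict_set = set(labels.index[labels["label"] != "unclassified"])
            assert strict_set <= set(de_probes), "strict set escaped the DE set"
            labels_by_tissue[tissue] = labels
            tables[f"strict_{tissue}"] = labels
            log.info("[strict] %s: %d strict probes", tissue, len(strict_set))
        except Exception as exc:
            raise PipelineError(stage, f"{tissue}: {exc}") from exc
        stage = "variability"
        try:
            screen = syncvar.two_stage_screen(study, tissue,
                                              q1=config.q_bartlett,
                                              p2=config.p_bf)
            flagged = set(screen.index[screen["flagged"]])
            survivors = set(screen.index[screen["q_bartlett"] < config.q_bartlett])
            assert flagged <= survivors, "flagged set escaped Bartlett survivors"
            disp = syncvar.dispersion_table(study, tissue, scale=config.cv_scale)
            traj = syncvar.trajectory_summary(disp, subset=flagged or None)
            tables[f"variability_{tissue}"] = screen
            tables[f"dispersion_{tissue}"] = disp.set_index("probe_id")
            tables[f"cv_medians_{tissue}"] = traj["medians"]
            for pairing, tab in traj["tables"].items():
                tables[f"cv_{pairing}_{tissue}"] = tab.set_index("probe_id")
            log.info("[variability] %s: %d flagged", tissue, len(flagged))
        except Exception as exc:
            raise PipelineError(stage, f"{tissue}: {exc}") from exc

    # -- enrichment ------------------------------------------------------
    stage = "enrich"
    try:
        if config.gene_sets and annotation is not None:
            collection = setops.read_gmt(config.gene_sets)
            probe_to_gene = annotation.set_index("probe_id")["gene"]
            background = sorted(set(probe_to_gene.dropna()))
            for tissue, labels in labels_by_tissue.items():
                strict = labels.index[labels["label"] != "unclassified"]
                genes = sorted(set(probe_to_gene.reindex(strict).dropna()))
                if genes:
                    tables[f"enrichment_{tissue}"] = setops.enrich(
                        genes, collection, background)
                    n_sig = int((tables[f"enrichment_{tissue}"]["q"]
                                 < config.enrich_q).sum())
                    log.info("[enrich] %s: %d terms at q < %g",
                             tissue, n_sig, config.enrich_q)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- cross-tissue report --------------------------------------------
    stage = "report"
    try:
        if len(studies) >= 2:
            vectors = report.diff_vectors(studies, labels_by_tissue)
            order = report.agglomerative_order(vectors)
            tables["heatmap_matrix"] = vectors.loc[order]
            summary = trendclass.summarize_strict(
                labels_by_tissue,
                annotation.set_index("probe_id")["gene"]
                if annotation is not None else None,
            )
            tables["strict_summary"] = pd.json_normalize(summary, sep="_")
        manifest_extra = config.to_manifest()
        manifest_extra.update({f"seed:{k}": v for k, v in seeds.items()})
        paths = report.export_products(outdir, tables, manifest_extra)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    return paths
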