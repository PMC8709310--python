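"""End-to-end orchestration: run every stage whose inputs are provided.

``run_pipeline`` ties the stages together — annotate → properties →
duplications → cluster → scan → differential expression → traits →
climate → phylogenetic signal — writing one TSV per stage plus a run
manifest (config hash, package version, seed).  Stages are independent:
only those whose inputs appear in the input bundle execute.  A stage
failure aborts with an error naming the stage; outputs written so far are
retained.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .config import PipelineConfig
from . import climate as climate_mod
from . import clustering, expression, io, loci as loci_mod, phylosignal
from . import promoters as promoters_mod
from . import properties as properties_mod
from . import segments, traits as traits_mod

__all__ = ["PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: PipelineConfig,
    inputs: Mapping[str, Any],
    outdir: str | Path,
) -> dict[str, Path]:
    """Execute all stages supported by ``inputs`` and write their tables.

    Recognized input keys (paths or in-memory objects):

    - ``proteins``: protein FASTA → architecture + property tables
    - ``loci``: locus TSV → duplication calls and merged events
    - ``panel``: multi-FASTA (``ecotype|gene`` ids) → cluster assignments
    - ``promoters`` + ``pwms``: promoter FASTA + JASPAR text → CRE hits
    - ``tpm`` + ``design``: TSVs → DE, percent change, correlations
    - ``traits``: TSV → trait change summary (+ regressions when tpm given)
    - ``climate``: TSV → niche classes
    - ``tree`` + ``tip_trait``: newick + TSV → K and λ signal tests

    Returns a name → path map of everything written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = outdir / f"{name}.tsv"
        io.write_tsv(frame, path, index=index)
        written[name] = path

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineStageError(name, exc) from exc
        return _Ctx()

    if "proteins" in inputs:
        with stage("annotate"):
            seqs = _as_seqs(inputs["proteins"])
            emit("architectures", segments.annotate_panel(
                seqs, max_mismatch=config.max_mismatch, mode=config.dehydrin_mode))
        with stage("properties"):
            emit("properties", properties_mod.properties_table(seqs))

    if "loci" in inputs:
        with stage("duplications"):
            locus_list = (
                io.read_loci_tsv(inputs["loci"])
                if isinstance(inputs["loci"], (str, Path))
                else list(inputs["loci"])
            )
            calls = loci_mod.call_duplications(locus_list, config.tandem_max_gap)
            groups = {l.genome_id: l.genome_group for l in locus_list}
            events = loci_mod.merge_duplication_events(calls, groups)
            emit("duplication_calls", loci_mod.calls_table(calls))
            emit("duplication_events", loci_mod.events_table(events))

    if "panel" in inputs:
        with stage("cluster"):
            panel = _as_seqs(inputs["panel"])
            _, assignments = clustering.cluster_panel(
                panel, config.cluster_threshold, config.cluster_min_size)
            emit("clusters", assignments)

    if "promoters" in inputs and "pwms" in inputs:
        with stage("scan"):
            proms = _as_seqs(inputs["promoters"])
            pwms = (
                io.read_jaspar_pwms(inputs["pwms"], config.pwm_pseudocount)
                if isinstance(inputs["pwms"], (str, Path))
                else list(inputs["pwms"])
            )
            windows = [
                promoters_mod.PromoterWindow(gid, seq, "+", -config.promoter_upstream)
                for gid, seq in proms.items()
            ]
            emit("cre_hits", promoters_mod.scan_panel(windows, pwms, config.pwm_threshold))

    tpm = design = None
    if "tpm" in inputs and "design" in inputs:
        with stage("de"):
            tpm = _as_frame(inputs["tpm"], index_col=0)
            design = _as_frame(inputs["design"], index_col=0)
            emit("de_wilcoxon", expression.wilcoxon_de(tpm, design, "WD", config.bh_alpha))
            per_gene, detail = expression.percent_change(tpm, design)
            emit("percent_change", per_gene.reset_index())
            emit("percent_change_by_ecotype", detail)
            emit("gene_correlation", expression.gene_correlation(tpm, design))

    if "traits" in inputs:
        with stage("traits"):
            traits = _as_frame(inputs["traits"])
            emit("trait_changes", traits_mod.trait_change_summary(traits))
            if tpm is not None:
                sel = design["water"] == "D"
                expr = (
                    tpm.loc[:, sel.values].T
                    .groupby(design.loc[sel, "ecotype"]).mean()
                )
                emit("trait_regressions", traits_mod.regress_panel(traits, expr))

    if "climate" in inputs:
        with stage("climate"):
            clim = _as_frame(inputs["climate"], index_col=0)
            res = climate_mod.climate_pc1_classes(
                clim, config.climate_cutoff, config.climate_anchor)
            frame = pd.DataFrame({"pc1": res.scores, "climate_class": res.classes})
            frame.index.name = "ecotype"
            emit("climate_classes", frame, index=True)

    if "tree" in inputs and "tip_trait" in inputs:
        with stage("physig"):
            tree = (
                io.read_tree(inputs["tree"])
                if isinstance(inputs["tree"], (str, Path))
                else inputs["tree"]
            )
            tip = inputs["tip_trait"]
            if isinstance(tip, (str, Path)):
                tip = io.read_tsv(tip, index_col=0).iloc[:, 0]
            C = phylosignal.tree_vcv(tree)
            k = phylosignal.blomberg_k(C, tip, config.n_permutations, seed=config.seed)
            lam = phylosignal.pagel_lambda(C, tip)
            emit("phylo_signal", pd.DataFrame([k.__dict__, lam.__dict__]))

    manifest = {
        "package": "dhnkit",
        "version": __version__,
        "python": platform.python_version(),
        "config": json.loads(config.to_json()),
        "config_digest": config.digest,
        "seed": config.seed,
        "outputs": {k: str(v) for k, v in written.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = manifest_path
    return written


def _as_seqs(obj) -> dict[str, str]:
    if isinstance(obj, (str, Path)):
        return io.read_fasta(obj)
    return dict(obj)


def _as_frame(obj, index_col=None) -> pd.DataFrame:
    if isinstance(obj, (str, Path)):
        return io.read_tsv(obj, index_col=index_col)
    return obj
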