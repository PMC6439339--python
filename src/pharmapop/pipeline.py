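"""End-to-end pipeline: simulate/read -> orient -> popgen -> ancestry ->
divergence -> association -> concordance.

The pipeline is a pure function of its configuration and input files:
identical inputs produce byte-identical outputs. Every stage logs counts
in and out, and a run manifest records parameters and SHA-256 hashes of
the inputs consumed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from . import popgen
from .ancestry import ancestry_association, estimate_ancestry
from .concordance import ConfusionMatrix, assay_metrics, build_confusion, calls_from_matrix, format_report
from .divergence import DEFAULT_LEVELS, divergence, effect_allele_frequencies, screen_of_interest
from .simulate import SimulationConfig, simulate_study, write_study

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """All inputs and tunables of one pipeline run."""

    out_dir: str = "pharmapop_run"
    seed: int = 17

    # Either simulate (default) or read these files.
    vcf: str | None = None
    manifest: str | None = None
    annotation: str | None = None
    panel: str | None = None
    recalled_vcf: str | None = None

    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides

    # Stage toggles.
    run_prune: bool = True
    run_mds: bool = True
    run_concordance: bool = True

    # Tunables.
    r2_threshold: float = 0.5
    prune_window: int = 50
    prune_step: int = 5
    mds_dims: int = 2
    ancestry_tol: float = 1e-6
    ancestry_max_iter: int = 2000
    e_threshold: float = 0.5
    evidence_levels: tuple = DEFAULT_LEVELS
    study_populations: tuple | None = None  # (pop1, pop2); default: first two

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("evidence_levels", "study_populations"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("vcf", "manifest", "annotation", "panel", "recalled_vcf"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config: {name} file not found: {p}")
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.prune_window < 1 or self.prune_step < 1:
            raise ValueError("prune window and step must be >= 1")
        if self.e_threshold < 0:
            raise ValueError("e_threshold must be >= 0")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns paths and headline numbers.

    Raises on the first failing stage, naming it.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: dict[str, str] = {}
    inputs: dict[str, str] = {}
    summary: dict = {}
    stage = "setup"
    try:
        # -- acquire data ---------------------------------------------------
        if cfg.vcf is None:
            stage = "simulate"
            sim_cfg = SimulationConfig(**{"seed": cfg.seed, **cfg.simulate})
            study = simulate_study(sim_cfg)
            data_paths = write_study(study, out / "data")
            produced.update({f"data/{k}": v for k, v in data_paths.items()})
            gm = study["genotypes"]
            manifest = study["manifest"]
            annotations = study["annotations"]
            panel = pd.DataFrame(
                study["panel"].T, index=pd.Index(gm.variant_ids, name="id"),
                columns=list(sim_cfg.component_names),
            )
            recalled = study["recalled"]
            truth = study["truth"]
            logger.info("simulate: %d samples, %d variants, %d annotated",
                        gm.n_samples, gm.n_variants, len(annotations))
        else:
            stage = "read"
            for name in ("vcf", "manifest", "annotation", "panel"):
                if getattr(cfg, name) is None:
                    raise ValueError(f"config: {name} required when vcf is given")
            gm = pio.read_vcf(cfg.vcf)
            manifest = pio.read_manifest(cfg.manifest)
            annotations = pio.read_annotation(cfg.annotation)
            panel = pd.read_csv(cfg.panel, sep="\t", index_col="id")
            recalled = pio.read_vcf(cfg.recalled_vcf) if cfg.recalled_vcf else None
            truth = None
            for name in ("vcf", "manifest", "annotation", "panel", "recalled_vcf"):
                p = getattr(cfg, name)
                if p:
                    inputs[name] = _sha256(Path(p))
        manifest.check_covers(gm)

        pops = (cfg.study_populations if cfg.study_populations
                else tuple(manifest.populations[:2]))
        if len(pops) < 2:
            raise ValueError("need two study populations")

        # -- orientation ----------------------------------------------------
        stage = "orient"
        oriented, orient_report = pio.orient_to_effect_allele(gm, annotations)
        logger.info("orient: %d oriented (%d flipped), %d dropped",
                    orient_report.n_oriented, orient_report.n_flipped,
                    len(orient_report.dropped))
        summary["n_pharma_oriented"] = orient_report.n_oriented

        # -- pruning --------------------------------------------------------
        analysis_gm = gm
        if cfg.run_prune:
            stage = "prune"
            kept = popgen.ld_prune(gm, cfg.r2_threshold, cfg.prune_window,
                                   cfg.prune_step)
            analysis_gm = gm.take_variants(kept)
            pd.Series(kept, name="id").to_csv(out / "pruned_variants.tsv",
                                              sep="\t", index=False)
            produced["pruned_variants"] = str(out / "pruned_variants.tsv")
            logger.info("prune: %d -> %d variants", gm.n_variants, len(kept))
            summary["n_pruned"] = len(kept)

        # -- frequencies and F_ST -------------------------------------------
        stage = "freqs"
        groups = {p: manifest.samples_of(p) for p in manifest.populations}
        pop_freqs = popgen.population_frequencies(analysis_gm, groups)
        freq_tab = popgen.compute_freq(analysis_gm)
        freq_out = freq_tab.join(pop_freqs.add_prefix("f_"))
        _write_tsv(freq_out, out / "frequencies.tsv")
        produced["frequencies"] = str(out / "frequencies.tsv")

        stage = "fst"
        fst_tab = popgen.compute_fst(pop_freqs)
        _write_tsv(fst_tab, out / "fst.tsv")
        produced["fst"] = str(out / "fst.tsv")
        summary["mean_fst"] = popgen.mean_fst(fst_tab)

        # -- distances and MDS ----------------------------------------------
        if cfg.run_mds:
            stage = "distances"
            dm = popgen.ibs_distance(analysis_gm)
            _write_tsv(pd.DataFrame(dm.data, index=list(dm.ids),
                                    columns=list(dm.ids)), out / "distances.tsv")
            produced["distances"] = str(out / "distances.tsv")
            stage = "mds"
            coords = popgen.classical_mds(dm, dims=cfg.mds_dims)
            _write_tsv(coords, out / "mds.tsv")
            produced["mds"] = str(out / "mds.tsv")

        # -- ancestry --------------------------------------------------------
        stage = "ancestry"
        est = estimate_ancestry(analysis_gm, panel, tol=cfg.ancestry_tol,
                                max_iter=cfg.ancestry_max_iter)
        anc_out = est.fractions.join(est.loglik).join(est.n_iter)
        _write_tsv(anc_out, out / "ancestry.tsv")
        produced["ancestry"] = str(out / "ancestry.tsv")
        if truth is not None:
            mae = float(
                (est.fractions - truth.loc[est.fractions.index]).abs().to_numpy().mean()
            )
            summary["ancestry_mae_vs_truth"] = mae
            logger.info("ancestry: mean |q_hat - q_true| = %.4f", mae)

        # -- divergence screen -----------------------------------------------
        stage = "divergence"
        eff = effect_allele_frequencies(oriented, manifest, pops[0], pops[1])
        div = divergence(eff["f_pop1"], eff["f_pop2"], eff["n1"], eff["n2"],
                         index=eff.index, pop1=pops[0], pop2=pops[1])
        _write_tsv(div.join(eff[["n1", "n2"]]), out / "divergence.tsv")
        produced["divergence"] = str(out / "divergence.tsv")
        screen = screen_of_interest(div, annotations, cfg.e_threshold,
                                    cfg.evidence_levels)
        _write_tsv(screen, out / "screen.tsv", index=False)
        produced["screen"] = str(out / "screen.tsv")
        summary["n_screened"] = int(len(screen))

        # -- association ------------------------------------------------------
        stage = "association"
        assoc = ancestry_association(oriented, est.fractions)
        _write_tsv(assoc, out / "association.tsv", index=False)
        produced["association"] = str(out / "association.tsv")

        # -- concordance ------------------------------------------------------
        if cfg.run_concordance and recalled is not None:
            stage = "concordance"
            recalled_oriented, _ = pio.orient_to_effect_allele(recalled, annotations)
            counts = np.zeros((3, 3), dtype=np.int64)
            shared = [v for v in oriented.variant_ids
                      if v in set(recalled_oriented.variant_ids)]
            for vid in shared:
                cm_v = build_confusion(calls_from_matrix(oriented, vid),
                                       calls_from_matrix(recalled_oriented, vid))
                counts += cm_v.counts
            cm = ConfusionMatrix(counts, label=f"pooled over {len(shared)} variants")
            _write_tsv(cm.to_frame(), out / "concordance.tsv")
            _write_tsv(assay_metrics(cm), out / "concordance_metrics.tsv")
            produced["concordance"] = str(out / "concordance.tsv")
            produced["concordance_metrics"] = str(out / "concordance_metrics.tsv")
            summary["concordance_accuracy"] = cm.accuracy
            logger.info("concordance:\n%s", format_report(cm))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    def _rel(p: str) -> str:
        try:
            return str(Path(p).relative_to(out))
        except ValueError:
            return p

    # record paths relative to the run directory so identical configs give
    # byte-identical bundles wherever they are written
    recorded_cfg = {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(cfg).items() if k != "out_dir"}
    run_manifest = {
        "config": recorded_cfg,
        "inputs_sha256": inputs,
        "outputs": {k: _rel(v) for k, v in produced.items()},
        "summary": summary,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)
    return {"out_dir": str(out), "outputs": produced, "summary": summary}
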