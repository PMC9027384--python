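"""End-to-end orchestration: filter -> cluster -> enrich -> levels -> export.

All randomness flows from the single ``seed`` in the run configuration;
stage seeds are derived through numpy ``SeedSequence`` spawning so each
stage is independently reproducible. A run manifest (config snapshot, input
checksums, seeds, stage timings, output list) is written atomically at the
end of every run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import clustering, coregulation, enrichment, expression, regnet, synthetic
from .expression import Config

logger = logging.getLogger(__name__)

__all__ = ["StageError", "STAGE_EXIT_CODES", "load_config", "run_all", "simulate"]

STAGE_EXIT_CODES = {
    "input": 2,
    "filter": 3,
    "cluster": 4,
    "enrich": 5,
    "levels": 6,
    "export": 7,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for exit-code mapping."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")

    @property
    def exit_code(self) -> int:
        return STAGE_EXIT_CODES.get(self.stage, 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML/JSON key-value run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return doc


def _make_config(settings: Mapping[str, Any]) -> Config:
    kwargs = {}
    for name in ("deg_threshold", "min_genes", "alpha_enrich", "alpha_level",
                 "repeats_per_k", "seed", "max_mustlink_pairs"):
        if name in settings:
            kwargs[name] = settings[name]
    if "k_min" in settings or "k_max" in settings:
        kwargs["k_range"] = (int(settings.get("k_min", 2)), int(settings.get("k_max", 30)))
    elif "k_range" in settings:
        kwargs["k_range"] = tuple(settings["k_range"])
    return Config(**kwargs)


def run_all(settings: Mapping[str, Any] | str | Path, outdir: str | Path | None = None) -> Path:
    """Execute the whole analysis and return the output directory.

    ``settings`` is a mapping (or a YAML/JSON file path) with keys
    ``expression``, ``network``, optional ``go``, optional ``universe``
    ("annotation" or "array"), ``outdir``, plus any :class:`Config` field
    (``k_min``/``k_max`` accepted as a convenience).
    """
    if isinstance(settings, (str, Path)):
        settings = load_config(settings)
    settings = dict(settings)
    cfg = _make_config(settings)
    outdir = Path(outdir or settings.get("outdir", "regclust_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    universe_mode = settings.get("universe", "annotation")
    if universe_mode not in ("annotation", "array"):
        raise StageError("input", ValueError(f"unknown universe mode {universe_mode!r}"))

    timings: dict[str, float] = {}
    inputs: dict[str, str] = {}
    outputs: list[str] = []

    def timed(stage):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
            def __exit__(self, et, ev, tb):
                timings[stage] = timings.get(stage, 0.0) + time.perf_counter() - self.t0
                if ev is not None and not isinstance(ev, StageError):
                    raise StageError(stage, ev) from ev
        return _T()

    with timed("input"):
        expr_path = Path(settings["expression"])
        net_path = Path(settings["network"])
        for p in (expr_path, net_path):
            if not p.exists():
                raise FileNotFoundError(f"input file not found: {p}")
        matrix = expression.read_expression(expr_path)
        interactions = regnet.read_network(net_path)
        go_map = None
        if settings.get("go"):
            go_path = Path(settings["go"])
            if not go_path.exists():
                raise FileNotFoundError(f"input file not found: {go_path}")
            go_map = enrichment.read_go_annotation(go_path)
            inputs[str(go_path)] = _sha256(go_path)
        inputs[str(expr_path)] = _sha256(expr_path)
        inputs[str(net_path)] = _sha256(net_path)

    logger.info(
        "thresholds: deg_threshold=%g min_genes=%d alpha_enrich=%g alpha_level=%g "
        "k_range=%s repeats_per_k=%d seed=%d",
        cfg.deg_threshold, cfg.min_genes, cfg.alpha_enrich, cfg.alpha_level,
        cfg.k_range, cfg.repeats_per_k, cfg.seed,
    )

    with timed("filter"):
        degs = expression.filter_degs(matrix, cfg.deg_threshold)
        scaled = expression.scale_profiles(matrix, degs)

    with timed("cluster"):
        signatures = regnet.build_signatures(interactions, matrix.gene_ids)
        constraints = regnet.derive_mustlinks(
            signatures, degs.gene_ids, cfg.max_mustlink_pairs
        )
        result = clustering.select_k(scaled, constraints, cfg)
        assign_path = outdir / "assignments.tsv"
        with open(assign_path, "w", encoding="utf-8") as fh:
            fh.write("gene\tcluster\n")
            for g in scaled.gene_ids:
                fh.write(f"{g}\t{result.assignments[g]}\n")
        sil_path = outdir / "silhouette.tsv"
        with open(sil_path, "w", encoding="utf-8") as fh:
            fh.write("k\tmean\tsd\n")
            for k, (m, s) in sorted(result.silhouette_by_k.items()):
                fh.write(f"{k}\t{m:.6f}\t{s:.6f}\n")
        outputs += [str(assign_path), str(sil_path)]

    with timed("enrich"):
        if universe_mode == "array":
            universe = frozenset(matrix.gene_ids)
        else:
            annotated = {it.gene for it in interactions}
            if go_map:
                annotated |= {g for genes in go_map.values() for g in genes}
            universe = annotated & set(matrix.gene_ids)
        combo_index = regnet.build_combination_index(signatures)
        tfsf_records = enrichment.enrich(result.assignments, combo_index, universe, cfg)
        important = enrichment.select_important(tfsf_records)
        tfsf_path = outdir / "enrichment_tfsf.tsv"
        enrichment.records_to_frame(tfsf_records).to_csv(tfsf_path, sep="\t", index=False)
        outputs.append(str(tfsf_path))
        go_records = []
        if go_map:
            go_records = enrichment.enrich(result.assignments, go_map, universe, cfg)
            go_path_out = outdir / "enrichment_go.tsv"
            enrichment.records_to_frame(go_records).to_csv(go_path_out, sep="\t", index=False)
            revigo_path = outdir / "revigo.tsv"
            enrichment.export_revigo(go_records, revigo_path)
            outputs += [str(go_path_out), str(revigo_path)]

    with timed("levels"):
        groups, tests = [], []
        if important:
            groups, tests = coregulation.run_level_analysis(
                degs.gene_ids, important, signatures, matrix, cfg
            )
            lg_path = outdir / "level_groups.tsv"
            with open(lg_path, "w", encoding="utf-8") as fh:
                fh.write("group\tlevel\tdirection\tn_genes\tfisher_p_raw\t"
                         "fisher_p_adj\tdecisive\tgenes\n")
                for g in groups:
                    fh.write(
                        f"{g.label()}\t{g.level}\t{g.direction}\t{len(g.genes)}\t"
                        f"{g.fisher_p_raw:.6e}\t{g.fisher_p_adj:.6e}\t"
                        f"{g.decisive}\t{','.join(g.genes)}\n"
                    )
            hm_path = outdir / "heatmap.tsv"
            coregulation.export_heatmap(tests, hm_path)
            outputs += [str(lg_path), str(hm_path)]
        else:
            logger.warning("no important TF/SF combinations; level stage skipped")

    with timed("export"):
        manifest = {
            "config": asdict(cfg),
            "universe_mode": universe_mode,
            "inputs": inputs,
            "seed": cfg.seed,
            "clustering_seeds": result.seeds,
            "selected_k": result.k,
            "n_degs": len(degs),
            "n_important": len(important),
            "n_groups": len(groups),
            "n_decisive": sum(g.decisive for g in groups),
            "timings_s": {k: round(v, 4) for k, v in timings.items()},
            "outputs": outputs,
        }
        tmp = outdir / "manifest.json.tmp"
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, outdir / "manifest.json")
    return outdir


def simulate(
    outdir: str | Path,
    n_genes: int = 1200,
    noise_sd: float = 0.2,
    seed: int = 42,
) -> dict[str, Path]:
    """Write a complete synthetic fixture directory (delegates to synthetic)."""
    truth = synthetic.make_truth(n_genes=n_genes, noise_sd=noise_sd, seed=seed)
    return synthetic.write_fixtures(truth, outdir)
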