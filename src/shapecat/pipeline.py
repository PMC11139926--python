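"""End-to-end orchestration: simulate -> preprocess -> tuning -> rsa ->
decode -> cnn -> report.

Each stage writes its outputs under the run directory and records the
content hash of the configuration it ran with; a stage is skipped on rerun
when its hash matches (delete the stage file or change the config to force
recomputation). Identical config + seed gives identical numeric outputs.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cnn as cnn_mod
from . import decode as decode_mod
from . import rdm as rdm_mod
from . import synth, tuning
from .config import AnalysisConfig, save_config
from .io import load_dataset, save_dataset, save_json, save_rdm
from .preprocess import compute_net_mua

__all__ = ["run_pipeline", "PipelineError", "STAGES"]

log = logging.getLogger("shapecat")

STAGES = ("simulate", "preprocess", "tuning", "rsa", "decode", "cnn", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _stage_hash_path(run_dir: Path, stage: str) -> Path:
    return run_dir / f".{stage}.hash"


def _should_run(run_dir: Path, stage: str, cfg_hash: str) -> bool:
    p = _stage_hash_path(run_dir, stage)
    return not (p.exists() and p.read_text().strip() == cfg_hash)


def _mark_done(run_dir: Path, stage: str, cfg_hash: str) -> None:
    _stage_hash_path(run_dir, stage).write_text(cfg_hash)


def run_pipeline(
    cfg: AnalysisConfig,
    out_dir: str | Path,
    population: synth.PopulationSpec | None = None,
    stages: tuple[str, ...] = STAGES,
) -> Path:
    """Run the pipeline stages in dependency order under ``out_dir``.

    ``population`` configures the simulated recording (defaults to the
    study-condition population with the config's seed). Returns the run
    directory, which ends up holding the dataset bundle, tuning.csv,
    RDM CSVs, rsa.json, decode.json, cnn.json, report.md and
    provenance.json.
    """
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.content_hash()
    save_config(cfg, run_dir / "config.yaml")
    t_all = time.time()

    for stage in stages:
        if stage not in STAGES:
            raise PipelineError(stage, f"unknown stage; expected one of {STAGES}")

    def _timed(stage, fn):
        if not _should_run(run_dir, stage, cfg_hash):
            log.info("stage %s cached, skipping", stage)
            return
        t0 = time.time()
        try:
            fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise PipelineError(stage, str(exc)) from exc
        _mark_done(run_dir, stage, cfg_hash)
        log.info("stage %s done in %.1f s", stage, time.time() - t0)

    # ---- simulate ----------------------------------------------------
    if "simulate" in stages:

        def _simulate():
            spec = population or synth.PopulationSpec(seed=cfg.substream_seed("simulate"))
            design = synth.generate_design()
            design = synth.generate_silhouettes(design, seed=cfg.substream_seed("silhouettes"))
            data, gt = synth.generate_trials(design, spec)
            save_dataset(data, run_dir / "dataset")
            gt.to_csv(run_dir / "dataset" / "ground_truth.csv", index=False)
            shape_rdm, cat_rdm = synth.generate_behavioral_rdms(
                design, seed=cfg.substream_seed("behavioral")
            )
            save_rdm(shape_rdm, run_dir / "behavioral_shape_rdm.csv")
            save_rdm(cat_rdm, run_dir / "behavioral_category_rdm.csv")

        _timed("simulate", _simulate)

    downstream = {"preprocess", "tuning", "rsa", "decode", "cnn", "report"}
    if not downstream & set(stages):
        return run_dir
    data = load_dataset(run_dir / "dataset")

    # ---- preprocess + tuning ----------------------------------------
    if "tuning" in stages:

        def _tuning():
            table = tuning.tuning_table(
                data,
                epoch=cfg.epoch_window,
                responsive_window=cfg.responsive_window,
                latency_bin_ms=cfg.latency_bin_ms,
                alpha=cfg.alpha,
            )
            table.to_csv(run_dir / "tuning.csv", index=False)
            resp = table[table["responsive"]]
            counts = resp["selectivity_class"].value_counts().to_dict()
            lats = resp["latency_ms"].dropna().to_numpy()
            summary = {
                "n_channels": int(len(table)),
                "n_responsive": int(len(resp)),
                "class_counts": counts,
                "median_s_width": float(resp["s_width"].median()),
                "median_d_prime": float(resp["d_prime"].median()),
                "analysis_window_ms": list(tuning.select_analysis_window(lats))
                if lats.size
                else list(cfg.epoch_window),
            }
            save_json(summary, run_dir / "tuning_summary.json")

        _timed("tuning", _tuning)

    if not ({"rsa", "decode", "cnn", "report"} & set(stages)):
        return run_dir
    tuning_df = pd.read_csv(run_dir / "tuning.csv")
    responsive_idx = np.flatnonzero(tuning_df["responsive"].to_numpy())
    import json

    window = tuple(json.loads((run_dir / "tuning_summary.json").read_text())["analysis_window_ms"])

    # ---- representational analysis ----------------------------------
    if "rsa" in stages:

        def _rsa():
            if responsive_idx.size < 2:
                raise ValueError("fewer than 2 responsive channels")
            crm = compute_net_mua(data, epoch=window)
            neural = rdm_mod.splithalf_rdm(
                crm.per_trial[responsive_idx],
                data.design.stimulus_ids,
                n_iter=cfg.splithalf_iterations,
                seed=cfg.rng("splithalf"),
            )
            save_rdm(neural, run_dir / "neural_rdm.csv")
            from .io import load_rdm

            models = {
                "shape": load_rdm(run_dir / "behavioral_shape_rdm.csv", "behavioral_shape"),
                "category": load_rdm(
                    run_dir / "behavioral_category_rdm.csv", "behavioral_category"
                ),
            }
            if data.design.silhouettes:
                models["silhouette"] = rdm_mod.silhouette_rdm(data.design)
                models["aspect_ratio"] = rdm_mod.aspect_ratio_rdm(data.design)
                save_rdm(models["silhouette"], run_dir / "silhouette_rdm.csv")
                save_rdm(models["aspect_ratio"], run_dir / "aspect_ratio_rdm.csv")
            results = {"method": cfg.rsa_method, "analysis_window_ms": list(window)}
            for name, model in models.items():
                rho, p = rdm_mod.rsa_permutation(
                    neural,
                    model,
                    n_perm=cfg.rsa_permutations,
                    seed=cfg.rng(f"rsa_{name}"),
                    method=cfg.rsa_method,
                )
                results[name] = {"rho": rho, "p": p}
            coords, stress = rdm_mod.mds_embed(
                neural, n_dims=2, seed=cfg.substream_seed("mds"), n_init=cfg.mds_restarts
            )
            pd.DataFrame(
                {
                    "stimulus_id": data.design.stimulus_ids,
                    "x": coords[:, 0],
                    "y": coords[:, 1],
                }
            ).to_csv(run_dir / "mds_coordinates.csv", index=False)
            results["mds_stress_2d"] = stress
            for dim in ("shape", "category"):
                dd = rdm_mod.intra_inter_distances(coords, data.design.labels_for(dim))
                results[f"mds_{dim}_clustering"] = {
                    "intra_mean": dd["intra_mean"],
                    "inter_mean": dd["inter_mean"],
                    "t": dd["t"],
                    "p": dd["p"],
                }
            _, flat = rdm_mod.cluster_hierarchical(neural, max_clusters=cfg.max_clusters)
            results["cluster_labels"] = flat.tolist()
            save_json(results, run_dir / "rsa.json")

        _timed("rsa", _rsa)

    # ---- decoding ---------------------------------------------------
    if "decode" in stages:

        def _decode():
            out = {}
            min_trials = int(data.trials_per_stimulus().min())
            folds = min(cfg.decode_folds, min_trials)
            for dim, n_groups in (("shape", data.design.n_shape_types), ("category", data.design.n_categories)):
                spec = decode_mod.DecodeSpec(
                    dimension=dim,
                    window_ms=cfg.decode_window_ms,
                    step_ms=cfg.decode_step_ms,
                    folds=folds,
                    c=cfg.svm_c,
                    alpha=cfg.alpha,
                    seed=cfg.substream_seed(f"decode_{dim}"),
                )
                null = decode_mod.arbitrary_group_null(
                    data,
                    spec,
                    n_groups=n_groups,
                    window=window,
                    channels=responsive_idx,
                    n_rep=cfg.arbitrary_group_reps,
                    seed=cfg.substream_seed(f"null_{dim}"),
                )
                result = decode_mod.sliding_window_decode(
                    data,
                    spec,
                    channels=responsive_idx,
                    chance_level=null["mean"],
                    confusion_window=window,
                )
                cross = decode_mod.cross_dimension_decode(
                    data,
                    spec,
                    window=window,
                    channels=responsive_idx,
                    n_splits=cfg.cross_dimension_splits,
                )
                out[dim] = {
                    **result.to_dict(),
                    "null_mean": null["mean"],
                    "null_p95": null["p95"],
                    "cross_dimension_accuracy": cross["accuracy"],
                }
                np.savetxt(
                    run_dir / f"confusion_{dim}.csv", result.confusion, fmt="%d", delimiter=","
                )
            save_json(out, run_dir / "decode.json")

        _timed("decode", _decode)

    # ---- cnn comparison ---------------------------------------------
    if "cnn" in stages and data.design.silhouettes:

        def _cnn():
            from .io import load_rdm

            extractor = cnn_mod.FilterBankExtractor()
            layers = cnn_mod.layer_rdms(extractor, data.design)
            neural = load_rdm(run_dir / "neural_rdm.csv")
            sil = rdm_mod.silhouette_rdm(data.design)
            out = {}
            for ref_name, ref in (("neural", neural), ("silhouette", sil)):
                rhos, peak = cnn_mod.correlate_layer_rdms(layers, ref)
                out[ref_name] = {"per_layer": rhos, "peak_layer": peak}
            for name, layer_rdm in layers.items():
                save_rdm(layer_rdm, run_dir / f"cnn_layer_{name}_rdm.csv")
            save_json(out, run_dir / "cnn.json")

        _timed("cnn", _cnn)

    # ---- report -----------------------------------------------------
    if "report" in stages:

        def _report():
            lines = ["# shapecat run report", ""]
            import json as _json

            tsum = _json.loads((run_dir / "tuning_summary.json").read_text())
            lines += [
                "## Channel tuning",
                "",
                f"- responsive channels: {tsum['n_responsive']} / {tsum['n_channels']}",
                f"- selectivity classes: {tsum['class_counts']}",
                f"- median Swidth: {tsum['median_s_width']:.3f}",
                f"- median d': {tsum['median_d_prime']:.3f}",
                f"- analysis window: {tsum['analysis_window_ms']} ms",
                "",
            ]
            if (run_dir / "rsa.json").exists():
                rsa = _json.loads((run_dir / "rsa.json").read_text())
                lines += ["## Representational similarity", ""]
                for k in ("shape", "category", "silhouette", "aspect_ratio"):
                    if k in rsa:
                        lines.append(
                            f"- {k}: rho = {rsa[k]['rho']:.3f}, p = {rsa[k]['p']:.4f}"
                        )
                lines.append("")
            if (run_dir / "decode.json").exists():
                dec = _json.loads((run_dir / "decode.json").read_text())
                lines += ["## Decoding", ""]
                for dim, d in dec.items():
                    peak = max(d["mean_accuracy"])
                    lines.append(
                        f"- {dim}: peak accuracy {peak:.3f} "
                        f"(empirical chance {d['null_mean']:.3f}), "
                        f"onset {d['onset_ms']} ms, "
                        f"cross-dimension accuracy {d['cross_dimension_accuracy']:.3f}"
                    )
                lines.append("")
            (run_dir / "report.md").write_text("\n".join(lines))
            from . import __version__

            save_json(
                {
                    "config_hash": cfg_hash,
                    "seed": cfg.seed,
                    "package_version": __version__,
                    "elapsed_s": time.time() - t_all,
                },
                run_dir / "provenance.json",
            )

        _timed("report", _report)

    return run_dir
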