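"""End-to-end pipeline: reference table -> statistics -> corpus -> GAN ->
generated table -> fidelity + utility reports.

The reference table (the "ground truth") only contributes its extracted
statistics to the corpus builder; the table itself is held out and is
never written into the training corpus.  Every stage derives its own seed
deterministically from the master seed, so a run is reproducible from the
config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .fidelity import fidelity_report
from .gan import (
    DiscriminatorConfig,
    GeneratorConfig,
    TrainConfig,
    generate_table,
    save_checkpoint,
    train,
)
from .schema import Table, TableSchema, extract_statistics
from .synthesis import build_training_corpus, make_reference_table, pima_schema
from .utility import run_tstr_trtr

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("statsynth.pipeline")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from one master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; paths are created on demand."""

    out_dir: Path
    schema: TableSchema | None = None          # default: the PIMA-like schema
    reference_csv: Path | None = None          # real table; default: fixture
    n_tables: int = 10_000
    amplitude: float = 0.01
    n_rows: int | None = None
    gen_layer_widths: tuple[int, ...] = (256, 256, 256)
    noise_dim: int = 128
    disc_layer_widths: tuple[int, ...] = (256, 128)
    lr_generator: float = 0.0001
    lr_discriminator: float = 0.00005
    batch_size: int = 64
    max_epochs: int = 70
    master_seed: int = 0
    evaluate_fidelity: bool = True
    evaluate_utility: bool = True
    save_scatter_plots: bool = False

    def resolved_schema(self) -> TableSchema:
        return self.schema if self.schema is not None else pima_schema()


def _save_scatter(history, out_dir: Path) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    for epoch, x, y in history.scatter:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(x, y, s=4, alpha=0.5)
        ax.set_title(f"epoch {epoch}")
        p = out_dir / f"scatter_epoch_{epoch:04d}.png"
        fig.savefig(p, dpi=80)
        plt.close(fig)
        paths.append(str(p))
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = config.resolved_schema()
    manifest: dict = {"master_seed": config.master_seed, "stages": {}}

    def stage(name: str):
        seed = stage_seed(config.master_seed, name)
        log.info("stage %s (seed %d)", name, seed)
        return seed

    try:
        seed = stage("reference")
        if config.reference_csv is not None:
            reference = Table.from_csv(config.reference_csv, schema)
        else:
            reference = make_reference_table(schema, seed=seed)
        ref_path = out / "reference.csv"
        reference.to_csv(ref_path)
        manifest["stages"]["reference"] = {"path": str(ref_path),
                                           "n_rows": reference.n_rows}

        stage("statistics")
        base_stats = extract_statistics(reference)
        stats_path = out / "base_statistics.csv"
        from .schema import write_statistics_csv
        write_statistics_csv(stats_path, [base_stats])
        manifest["stages"]["statistics"] = {"path": str(stats_path),
                                            "n_values": len(base_stats.values)}

        seed = stage("corpus")
        corpus = build_training_corpus(
            base_stats, schema, n_tables=config.n_tables,
            amplitude=config.amplitude, seed=seed,
            out_dir=out / "corpus", n_rows=config.n_rows)
        manifest["stages"]["corpus"] = {
            "manifest": str(out / "corpus" / "manifest.json"),
            "n_pairs": corpus.n_pairs,
        }

        seed = stage("train")
        n_rows = config.n_rows or schema.n_rows_default
        gen_cfg = GeneratorConfig(
            stat_dim=schema.stat_dim, noise_dim=config.noise_dim,
            layer_widths=config.gen_layer_widths,
            output_shape=(n_rows, schema.n_cols))
        disc_cfg = DiscriminatorConfig(
            stat_dim=schema.stat_dim, input_shape=(n_rows, schema.n_cols),
            layer_widths=config.disc_layer_widths)
        train_cfg = TrainConfig(
            lr_generator=config.lr_generator,
            lr_discriminator=config.lr_discriminator,
            batch_size=config.batch_size, max_epochs=config.max_epochs,
            seed=seed)
        generator, history = train(corpus, gen_cfg, disc_cfg, train_cfg)
        ckpt_path = out / "checkpoint.npz"
        save_checkpoint(ckpt_path, generator, schema)
        hist_path = out / "history.csv"
        history.save_csv(hist_path)
        manifest["stages"]["train"] = {
            "checkpoint": str(ckpt_path), "history": str(hist_path),
            "iterations": history.n_iterations,
        }
        if config.save_scatter_plots:
            manifest["stages"]["train"]["scatter"] = _save_scatter(history, out)

        seed = stage("generate")
        generated = generate_table(generator, base_stats, schema, seed=seed)
        gen_path = out / "generated.csv"
        generated.to_csv(gen_path)
        manifest["stages"]["generate"] = {"path": str(gen_path),
                                          "n_rows": generated.n_rows}

        if config.evaluate_fidelity:
            stage("fidelity")
            rep = fidelity_report(reference, generated, schema)
            fid_path = out / "fidelity.csv"
            rep.to_dataframe().to_csv(fid_path, index=False)
            (out / "fidelity.txt").write_text(rep.summary() + "\n")
            manifest["stages"]["fidelity"] = {
                "path": str(fid_path),
                "metric_labels": rep.metric_labels,
                "ura_label": rep.ura_label,
            }

        if config.evaluate_utility:
            seed = stage("utility")
            rep = run_tstr_trtr(reference, generated, split_seed=seed)
            util_path = out / "utility.csv"
            rep.to_dataframe().to_csv(util_path, index=False)
            manifest["stages"]["utility"] = {
                "path": str(util_path),
                "label": rep.label,
                "max_difference": rep.max_difference,
            }
    except Exception as exc:
        failed = len(manifest["stages"])
        names = ["reference", "statistics", "corpus", "train", "generate",
                 "fidelity", "utility"]
        name = names[min(failed, len(names) - 1)]
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
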