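"""Configurable end-to-end pipeline over the analysis stages.

Stages (``simulate``, ``preprocess``, ``connectivity``, ``modules``,
``geometry``, ``decode``, ``boundary``) exchange files in a working
directory: HDF5 sessions, CSV spike/trial tables, TSV networks and
partitions, JSON reports.  Every stage writes a ``<stage>_meta.json``
with the resolved configuration hash and the seeds used.

A single global seed is expanded deterministically: stage ``k`` draws
from ``SeedSequence([seed, k])`` and per-session generators from
``SeedSequence([seed, k, session])``, so any stage can be re-run in
isolation and reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as mio
from .decode import (
    boundary_response_similarity,
    shuffle_across_accuracy,
    shuffle_within_accuracy,
    train_module_classifier,
    transform_rates,
    trial_shuffle_significance,
)
from .geometry import boundary_gc_contrast, boundary_pairs, module_geometry
from .granger import band_contributions, conditional_gc_matrix, gc_significance, spectral_conditional_gc
from .layout import make_layout
from .multilayer import build_multilayer, louvain_optimize, normalized_persistence, stationarity
from .preprocess import preprocess_session
from .session import BlockSet
from .synth import (
    generate_spikes,
    generate_var_lfp,
    modular_var_truth,
    module_tuning,
    plant_modules,
)

__all__ = ["PipelineConfig", "run", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "connectivity", "modules", "geometry", "decode", "boundary")


@dataclass
class PipelineConfig:
    """Resolved parameters for every stage; serialized next to outputs."""

    seed: int = 0
    sim: dict = field(
        default_factory=lambda: {
            "rows": 6,
            "cols": 6,
            "pitch": 0.4,
            "n_modules": 4,
            "n_sessions": 3,
            "n_blocks": 20,
            "block_len": 5.0,
            "fs": 1000.0,
            "var_order": 8,
            "within_strength": 1.0,
            "across_strength": 0.25,
            "units_per_electrode": 1,
            "gain": 3.0,
            "tuning_correlation": 1.0,
            "n_trials": 240,
        }
    )
    preprocess: dict = field(
        default_factory=lambda: {
            "n_clips": 20,
            "clip_len": 30.0,
            "block_len": 5.0,
            "detrend_window": 0.5,
            "detrend_step": 0.25,
            "line_base": 60.0,
        }
    )
    gc: dict = field(
        default_factory=lambda: {"order": 8, "alpha": 0.05, "pooling": "pooled"}
    )
    spectral: dict = field(default_factory=lambda: {"enabled": True, "n_freq": 256})
    mlmod: dict = field(
        default_factory=lambda: {"gamma": 1.0, "omega_rule": "median", "restarts": 500}
    )
    surrogate: dict = field(
        default_factory=lambda: {"n": 500, "passes": 100, "weight_rule": "source"}
    )
    decode: dict = field(
        default_factory=lambda: {
            "n_folds": 20,
            "es_draws": 50,
            "shuffle_iters": 100,
            "partition_layer": -1,
        }
    )

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        cfg = cls()
        for k, v in data.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key: {k}")
            if isinstance(v, dict):
                getattr(cfg, k).update(v)
            else:
                setattr(cfg, k, v)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage_seed(cfg: PipelineConfig, stage: str, *extra) -> np.random.SeedSequence:
    return np.random.SeedSequence([cfg.seed, STAGES.index(stage), *extra])


def _meta(cfg: PipelineConfig, stage: str, outdir: Path, **info) -> None:
    mio.write_json(
        outdir / f"{stage}_meta.json",
        {"stage": stage, "config_hash": cfg.hash(), "seed": cfg.seed, **info,
         "config": cfg.to_dict()},
    )


def _session_blocks(outdir: Path, cfg: PipelineConfig) -> list[BlockSet]:
    truth = mio.read_json(outdir / "truth.json")
    n_blocks, block_len = truth["n_blocks"], truth["block_len"]
    out = []
    for s in range(truth["n_sessions"]):
        rec = mio.read_session_h5(outdir / f"session-{s:02d}.h5")
        bs = int(round(block_len * rec.fs))
        blocks = [rec.lfp[:, k * bs : (k + 1) * bs] for k in range(n_blocks)]
        out.append(BlockSet(blocks=blocks, fs=rec.fs, session_id=rec.session_id))
    return out


def run_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    p = cfg.sim
    outdir.mkdir(parents=True, exist_ok=True)
    layout = make_layout(p["rows"], p["cols"], p["pitch"])
    ss = _stage_seed(cfg, "simulate")
    seeds = ss.generate_state(4 + p["n_sessions"]) % (2**31)
    pm = plant_modules(layout, p["n_modules"], seed=int(seeds[0]))
    truth = modular_var_truth(
        pm,
        layout,
        order=p["var_order"],
        fs=p["fs"],
        within_strength=p["within_strength"],
        across_strength=p["across_strength"],
        seed=int(seeds[1]),
    )
    for s in range(p["n_sessions"]):
        rec, _, _ = generate_var_lfp(
            pm,
            truth,
            n_blocks=p["n_blocks"],
            block_len=p["block_len"],
            fs=p["fs"],
            seed=int(seeds[4 + s]),
            session_id=f"session-{s:02d}",
        )
        rec.layout = layout
        mio.write_session_h5(outdir / f"session-{s:02d}.h5", rec)
    tuning = module_tuning(
        pm,
        units_per_electrode=p["units_per_electrode"],
        gain=p["gain"],
        tuning_correlation=p["tuning_correlation"],
        seed=int(seeds[2]),
    )
    spikes, trials = generate_spikes(pm, tuning, n_trials=p["n_trials"], seed=int(seeds[3]))
    mio.write_spikes_csv(outdir / "spikes.csv", spikes, units_path=outdir / "units.csv")
    mio.write_trials_csv(outdir / "trials.csv", trials, baselines_path=outdir / "baselines.json")
    mio.write_json(
        outdir / "truth.json",
        {
            "labels": pm.labels,
            "n_modules": pm.n_modules,
            "n_sessions": p["n_sessions"],
            "n_blocks": p["n_blocks"],
            "block_len": p["block_len"],
            "rows": p["rows"],
            "cols": p["cols"],
            "pitch": p["pitch"],
            "spectral_radius": truth.spectral_radius(),
            "band_profile": {k: list(v) for k, v in truth.band_profile.items()},
        },
    )
    _meta(cfg, "simulate", outdir)


def run_preprocess(cfg: PipelineConfig, indir: Path, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    reports = {}
    paths = sorted(indir.glob("session-*.h5"))
    if not paths:
        raise FileNotFoundError(f"no session-*.h5 files in {indir}")
    for path in paths:
        rec = mio.read_session_h5(path)
        blocks, report = preprocess_session(rec, **cfg.preprocess)
        np.save(outdir / f"{path.stem}-blocks.npy", np.array(blocks.blocks))
        reports[path.stem] = dataclasses.asdict(report)
    mio.write_json(outdir / "preprocess_report.json", reports)
    _meta(cfg, "preprocess", outdir)


def run_connectivity(cfg: PipelineConfig, indir: Path, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if not (indir / "truth.json").exists():
        raise FileNotFoundError(f"missing {indir / 'truth.json'}")
    sessions = _session_blocks(indir, cfg)
    for s, blocks in enumerate(sessions):
        gcm = conditional_gc_matrix(blocks, cfg.gc["order"])
        sig = gc_significance(gcm, alpha=cfg.gc["alpha"])
        mio.write_network_tsv(outdir / f"network-{s:02d}.tsv", sig)
        if cfg.spectral["enabled"]:
            sgc = spectral_conditional_gc(blocks, cfg.gc["order"], n_freq=cfg.spectral["n_freq"])
            bands = band_contributions(sgc, normalize=True)
            mio.write_band_tsv(outdir / f"bands-{s:02d}.tsv", bands)
    _meta(cfg, "connectivity", outdir, n_sessions=len(sessions))


def run_modules(cfg: PipelineConfig, indir: Path, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = sorted(indir.glob("network-*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no network-*.tsv files in {indir}")
    nets = [network_from_gc_file(p, k) for k, p in enumerate(paths)]
    mlnet = build_multilayer(nets)
    seed = int(_stage_seed(cfg, "modules").generate_state(1)[0] % (2**31))
    part = louvain_optimize(
        mlnet, gamma=cfg.mlmod["gamma"], n_restarts=cfg.mlmod["restarts"], seed=seed
    )
    mio.write_partition_tsv(outdir / "partition.tsv", part)
    metrics = {
        "Q_ml": part.quality,
        "omega": part.omega,
        "gamma": part.gamma,
        "stationarity": stationarity(part) if part.n_layers > 1 else None,
        "persistence": normalized_persistence(part) if part.n_layers > 1 else None,
    }
    mio.write_json(outdir / "module_metrics.json", metrics)
    _meta(cfg, "modules", outdir, stage_seed=seed)


def network_from_gc_file(path, k: int):
    from .networks import FunctionalNetwork

    return FunctionalNetwork(adjacency=mio.read_network_tsv(path), session_id=f"session-{k:02d}")


def _load_partition_labels(workdir: Path) -> np.ndarray:
    return mio.read_partition_tsv(workdir / "partition.tsv")


def run_geometry(cfg: PipelineConfig, indir: Path, outdir: Path) -> None:
    import pandas as pd

    outdir.mkdir(parents=True, exist_ok=True)
    truth = mio.read_json(indir / "truth.json")
    layout = make_layout(truth["rows"], truth["cols"], truth["pitch"])
    labels = _load_partition_labels(indir)
    rows = []
    for s in range(labels.shape[1]):
        geom = module_geometry(labels[:, s], layout)
        for m in geom.diameter:
            rows.append(
                {
                    "module": m,
                    "layer": s,
                    "diameter_mm": geom.diameter[m],
                    "compactness": geom.compactness[m],
                    "n_members": int(np.sum(labels[:, s] == m)),
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "geometry.tsv", sep="\t", index=False)
    _meta(cfg, "geometry", outdir)


def _consensus_labels(labels: np.ndarray, layer: int) -> np.ndarray:
    return labels[:, layer]


def run_decode(cfg: PipelineConfig, indir: Path, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    spikes = mio.read_spikes_csv(indir / "spikes.csv", units_path=indir / "units.csv")
    trials = mio.read_trials_csv(indir / "trials.csv", baselines_path=indir / "baselines.json")
    labels = _load_partition_labels(indir)[:, cfg.decode["partition_layer"]]
    rates = transform_rates(spikes, trials)
    seed = int(_stage_seed(cfg, "decode").generate_state(1)[0] % (2**31))
    results = {}
    fitted = {}
    for m in np.unique(labels):
        electrodes = np.nonzero(labels == m)[0]
        units = spikes.units.loc[
            spikes.units["electrode"].isin(electrodes), "unit_id"
        ].to_numpy()
        units = [u for u in units if u in set(rates.unit_ids)]
        if len(units) < 2:
            continue
        res = train_module_classifier(
            rates, trials, units,
            seed=seed + int(m),
            n_folds=cfg.decode["n_folds"],
            es_draws=cfg.decode["es_draws"],
        )
        sig = trial_shuffle_significance(res, seed=seed + 1000 + int(m))
        fitted[int(m)] = res
        results[int(m)] = {
            "n_units": len(units),
            "accuracy": res.accuracy,
            "fold_accuracies": res.fold_accuracies,
            "shuffle_p": sig["p"],
            "surrogate_accuracy": sig["surrogate_mean"],
        }
    mods = sorted(fitted)
    for a in mods:
        res = fitted[a]
        sw = shuffle_within_accuracy(res, n_iter=cfg.decode["shuffle_iters"], seed=seed + 7)
        others = [b for b in mods if b != a]
        sa = [
            shuffle_across_accuracy(
                res, rates,
                spikes.units.loc[spikes.units["unit_id"].isin(fitted[b].unit_subset), "unit_id"],
                n_iter=cfg.decode["shuffle_iters"], seed=seed + 9 + b,
            )
            for b in others
        ]
        results[a]["shuffle_within"] = sw
        results[a]["shuffle_across"] = float(np.mean(sa)) if sa else None
    mio.write_json(outdir / "decode_results.json", results)
    _meta(cfg, "decode", outdir, stage_seed=seed)


def run_boundary(cfg: PipelineConfig, indir: Path, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    truth = mio.read_json(indir / "truth.json")
    layout = make_layout(truth["rows"], truth["cols"], truth["pitch"])
    labels = _load_partition_labels(indir)
    layer = cfg.decode["partition_layer"]
    pairs = boundary_pairs(labels[:, layer], layout)
    paths = sorted(indir.glob("network-*.tsv"))
    adj = np.mean([mio.read_network_tsv(p) for p in paths], axis=0)
    contrast = boundary_gc_contrast(adj, pairs)
    out = {"gc_contrast": {
        "per_module": {str(k): v for k, v in contrast["per_module"].items()},
        "inside_mean": contrast["inside_mean"],
        "outside_mean": contrast["outside_mean"],
    }}
    spike_path = indir / "spikes.csv"
    if spike_path.exists():
        spikes = mio.read_spikes_csv(spike_path, units_path=indir / "units.csv")
        trials = mio.read_trials_csv(indir / "trials.csv", baselines_path=indir / "baselines.json")
        rates = transform_rates(spikes, trials)
        sim = boundary_response_similarity(rates, spikes.units, pairs, trials)
        out["response_similarity"] = {
            "per_module": {str(k): v for k, v in sim["per_module"].items()},
            "within_mean": sim["within_mean"],
            "across_mean": sim["across_mean"],
        }
    mio.write_json(outdir / "boundary_results.json", out)
    _meta(cfg, "boundary", outdir)


def run(
    subcommand: str,
    config: PipelineConfig | None = None,
    indir=None,
    outdir=None,
) -> int:
    """Run one stage (or ``all``) and return an exit status."""
    cfg = config or PipelineConfig()
    outdir = Path(outdir or ".")
    indir = Path(indir) if indir is not None else outdir
    try:
        if subcommand == "simulate":
            run_simulate(cfg, outdir)
        elif subcommand == "preprocess":
            run_preprocess(cfg, indir, outdir)
        elif subcommand == "connectivity":
            run_connectivity(cfg, indir, outdir)
        elif subcommand == "modules":
            run_modules(cfg, indir, outdir)
        elif subcommand == "geometry":
            run_geometry(cfg, indir, outdir)
        elif subcommand == "decode":
            run_decode(cfg, indir, outdir)
        elif subcommand == "boundary":
            run_boundary(cfg, indir, outdir)
        elif subcommand == "all":
            run_simulate(cfg, outdir)
            run_connectivity(cfg, outdir, outdir)
            run_modules(cfg, outdir, outdir)
            run_geometry(cfg, outdir, outdir)
            run_decode(cfg, outdir, outdir)
            run_boundary(cfg, outdir, outdir)
        else:
            logger.error("unknown subcommand: %s", subcommand)
            return 2
    except (FileNotFoundError, ValueError) as exc:
        logger.error("%s", exc)
        return 1
    return 0
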