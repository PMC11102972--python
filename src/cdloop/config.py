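"""Run configuration, seed fan-out and the staged pipeline driver.

A :class:`RunConfig` holds every knob of the pipeline (simulation, sample
building, the two trainings, calling, evaluation) and round-trips through
YAML unchanged.  One global seed fans out to per-stage seeds by fixed
offsets so each stage is independently reproducible; every artifact is
stamped with the config hash and the stage seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import yaml

from . import caller, diffusion, evaluate, prior, samples, simulate
from .io import kr_normalize, read_bedpe, write_bedpe, write_sparse_text, load_contacts

__all__ = ["RunConfig", "desk_config", "stage_seeds", "run_pipeline", "STAGES"]

log = logging.getLogger("cdloop")

STAGES = ("simulate", "build", "train-prior", "train-diff", "call", "evaluate")

# fixed per-stage seed offsets, logged with every artifact
_SEED_OFFSETS = {"simulate": 1, "labels": 2, "build": 3, "train-prior": 4,
                 "train-diff": 5, "call": 6, "shuffle": 7, "labels2": 8}


@dataclasses.dataclass
class RunConfig:
    # genome / matrix
    resolution: int = 5000
    window: int = 14
    layer: str = "balanced"  # layer used for windows and the min_if prefilter
    # simulation
    n_bins: int = 1200
    loop_count: int = 60
    loop_amplitude: float = 8.0
    loop_width: float = 2.5
    loop_sep_range: tuple[int, int] = (8, 13)
    decay_amp: float = 20.0
    decay_exp: float = 1.0
    label_jitter_bins: int = 2
    chrom: str = "chrS1"
    # sample building
    min_dist: int = 30_000
    max_dist: int = 3_000_000
    flip_mode: str = "hv+both"
    # diffusion schedule
    T: int = 100
    beta_start: float = 1e-4
    beta_end: float = 0.02
    # networks / training
    prior_channels: tuple[int, int] = (6, 16)
    prior_widths: tuple[int, int] = (120, 84)
    eps_width: int = 128
    lr: float = 1e-3
    batch: int = 128
    prior_epochs: int = 15
    diff_epochs: int = 15
    # calling
    min_if: float = 1.0
    max_zeros: int = 200
    score_cutoff: float = 0.5
    square: int = 5
    min_neighbors: int = 15
    delta_min: float = 5.0
    n_draws: int = 10
    # evaluation
    eval_tol_bp: int = 5000
    # seeds
    seed: int = 1

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["loop_sep_range"] = list(d["loop_sep_range"])
        d["prior_channels"] = list(d["prior_channels"])
        d["prior_widths"] = list(d["prior_widths"])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, src) -> "RunConfig":
        text = Path(src).read_text() if isinstance(src, (str, Path)) and "\n" not in str(src) \
            else str(src)
        d = yaml.safe_load(text)
        for key in ("loop_sep_range", "prior_channels", "prior_widths"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def desk_config(seed: int = 1) -> RunConfig:
    """The desk-scale study conditions: a 1200-bin synthetic chromosome with
    60 planted loops at amplitude 8, a T=100 schedule and short trainings
    sized for a single CPU."""
    return RunConfig(seed=seed)


def stage_seeds(seed: int) -> dict[str, int]:
    """Fan one global seed out to per-stage seeds by fixed offsets."""
    return {k: (seed * 10_007 + off) % (2 ** 31 - 1) for k, off in _SEED_OFFSETS.items()}


def _stamp(cfg: RunConfig, stage: str, seeds: dict[str, int]) -> str:
    return f"cdloop stage={stage} config={cfg.digest()} seed={seeds.get(stage, cfg.seed)}"


def run_pipeline(cfg: RunConfig, out_dir, stages=STAGES, progress=None) -> dict:
    """Run the requested stages in dependency order under ``out_dir``.

    Artifacts: sparse-text matrix + truth/label BEDPE (simulate), a sample
    archive (build), network checkpoints + history CSVs (train-*), final
    loops BEDPE + sidecar TSV + audit counts (call), a JSON report
    (evaluate).  Raises if a stage's upstream artifact is missing.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    stages = list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    say = progress or log.info
    results: dict = {"config_hash": cfg.digest(), "seeds": seeds}

    mat_path = out / "matrix.txt"
    truth_path = out / "truth.bedpe"
    # two label sources, emulating CTCF ChIA-PET + H3K27ac HiChIP anchors
    labels_paths = (out / "labels_ctcf.bedpe", out / "labels_h3k27ac.bedpe")
    samples_path = out / "samples.npz"
    prior_path = out / "prior.npz"
    eps_path = out / "eps.npz"
    loops_path = out / "loops.bedpe"
    sidecar_path = out / "loops_stats.tsv"
    scores_path = out / "scores.tsv"
    report_path = out / "report.json"

    if "simulate" in stages:
        p = simulate.SimParams(
            n_bins=cfg.n_bins, resolution=cfg.resolution, decay_amp=cfg.decay_amp,
            decay_exp=cfg.decay_exp, loop_count=cfg.loop_count,
            loop_sep_range=cfg.loop_sep_range, loop_amplitude=cfg.loop_amplitude,
            loop_width=cfg.loop_width, chrom=cfg.chrom, seed=seeds["simulate"],
        )
        m, truth = simulate.simulate_map(p)
        write_sparse_text(m, mat_path, header=_stamp(cfg, "simulate", seeds))
        truth_pairs = [simulate.BedpePair(cfg.chrom, a * cfg.resolution, (a + 1) * cfg.resolution,
                                          cfg.chrom, b * cfg.resolution, (b + 1) * cfg.resolution)
                       for a, b in truth]
        write_bedpe(truth_pairs, truth_path, header=_stamp(cfg, "simulate", seeds))
        for path, seed_key in zip(labels_paths, ("labels", "labels2")):
            labels = simulate.simulate_labels(truth, cfg.label_jitter_bins, seeds[seed_key],
                                              resolution=cfg.resolution, chrom=cfg.chrom)
            write_bedpe(labels, path, header=_stamp(cfg, "simulate", seeds))
        say(f"simulate: {m.n_bins} bins, {len(truth)} planted loops")
        results["n_truth"] = len(truth)

    def _matrix():
        if not mat_path.exists():
            raise FileNotFoundError(f"missing artifact {mat_path}; run the simulate stage first")
        m = load_contacts(mat_path, cfg.chrom, cfg.resolution)
        kr_normalize(m)
        return m

    if "build" in stages:
        m = _matrix()
        for path in labels_paths:
            if not path.exists():
                raise FileNotFoundError(f"missing artifact {path}")
        # concatenate both label sources; collect_positives dedups pixels
        labels = [p for path in labels_paths for p in read_bedpe(path)]
        pos = samples.collect_positives(labels, m, min_d=cfg.min_dist, max_d=cfg.max_dist)
        neg = samples.sample_negatives(pos, m, seed=seeds["build"])
        built = samples.build_samples(pos, neg, m, w=cfg.window, layer=cfg.layer)
        n_before = len(built)
        built = samples.drop_allzero(built)
        say(f"build: {len(pos)} positive pixels, {n_before - len(built)} all-zero "
            f"negatives dropped")
        built = samples.augment_flips(built, mode=cfg.flip_mode)
        x, y = samples.samples_to_arrays(built)
        origin = np.array([s.origin for s in built])
        distance = np.array([s.distance for s in built], dtype=np.int64)
        np.savez_compressed(samples_path, x=x, y=y, origin=origin,
                            distance=distance, stamp=_stamp(cfg, "build", seeds))
        say(f"build: {len(y)} samples after augmentation "
            f"({int(y.sum())} positive / {int((1 - y).sum())} negative)")
        results["n_samples"] = len(y)

    def _samples():
        if not samples_path.exists():
            raise FileNotFoundError(f"missing artifact {samples_path}; run the build stage first")
        with np.load(samples_path) as d:
            return d["x"], d["y"]

    if "train-prior" in stages:
        x, y = _samples()
        net = prior.build_prior_net(w=cfg.window, channels=cfg.prior_channels,
                                    widths=cfg.prior_widths, seed=seeds["train-prior"])
        net, hist = prior.train_prior(net, x, y, lr=cfg.lr, batch=cfg.batch,
                                      epochs=cfg.prior_epochs, seed=seeds["train-prior"])
        net.save(prior_path)
        _write_history(hist, out / "prior_history.csv")
        say(f"train-prior: final train acc {hist[-1]['train_acc']:.3f}")
        results["prior_train_acc"] = hist[-1]["train_acc"]

    if "train-diff" in stages:
        x, y = _samples()
        if not prior_path.exists():
            raise FileNotFoundError(f"missing checkpoint {prior_path}; train the prior first")
        pnet = prior.PriorNet.load(prior_path)
        sched = diffusion.make_schedule(cfg.T, cfg.beta_start, cfg.beta_end)
        enet = diffusion.EpsNet(w=cfg.window, width=cfg.eps_width, seed=seeds["train-diff"])
        enet, hist = diffusion.train_diffusion(enet, pnet, x, y, sched, lr=cfg.lr,
                                               batch=cfg.batch, epochs=cfg.diff_epochs,
                                               seed=seeds["train-diff"])
        enet.save(eps_path)
        _write_history(hist, out / "diff_history.csv")
        say(f"train-diff: final eps-MSE {hist[-1]['train_loss']:.4f}")
        results["diff_train_loss"] = hist[-1]["train_loss"]

    if "call" in stages:
        m = _matrix()
        if not prior_path.exists() or not eps_path.exists():
            raise FileNotFoundError("missing network checkpoints; train both nets first")
        pnet = prior.PriorNet.load(prior_path)
        enet = diffusion.EpsNet.load(eps_path)
        sched = diffusion.make_schedule(cfg.T, cfg.beta_start, cfg.beta_end)
        final, counts, scored = caller.call_loops(
            m, pnet, enet, sched, w=cfg.window, min_d=cfg.min_dist, max_d=cfg.max_dist,
            min_if=cfg.min_if, max_zeros=cfg.max_zeros, score_cutoff=cfg.score_cutoff,
            square=cfg.square, min_neighbors=cfg.min_neighbors, delta_min=cfg.delta_min,
            n_draws=cfg.n_draws, seed=seeds["call"], layer=cfg.layer,
            log=lambda msg: say(f"call: {msg}"),
        )
        bedpe = caller.loops_to_bedpe(final, cfg.chrom, cfg.resolution)
        write_bedpe(bedpe, loops_path, header=_stamp(cfg, "call", seeds))
        with open(scores_path, "w") as fh:
            fh.write("# " + _stamp(cfg, "call", seeds) + "\n")
            fh.write("bin_i\tbin_j\tscore\n")
            for c in scored:
                fh.write(f"{c.i}\t{c.j}\t{c.score:.8g}\n")
        with open(sidecar_path, "w") as fh:
            fh.write("# " + _stamp(cfg, "call", seeds) + "\n")
            fh.write("chrom\tbin_i\tbin_j\tscore\tci_low\tci_high\tt_pvalue\trho\tdelta\n")
            for c in final:
                fh.write(f"{cfg.chrom}\t{c.i}\t{c.j}\t{c.score:.6g}\t{c.ci_low:.6g}"
                         f"\t{c.ci_high:.6g}\t{c.t_pvalue:.6g}\t{c.rho}\t{c.delta:.6g}\n")
        results["call_counts"] = counts

    if "evaluate" in stages:
        if not loops_path.exists():
            raise FileNotFoundError(f"missing artifact {loops_path}; run the call stage first")
        if not truth_path.exists():
            raise FileNotFoundError(f"missing artifact {truth_path}")
        pred = read_bedpe(loops_path)
        truth_pairs = read_bedpe(truth_path)
        res = evaluate.match_loops(pred, truth_pairs, tol_bp=cfg.eval_tol_bp)
        report = {"config_hash": cfg.digest(), "seed": cfg.seed,
                  "n_pred": res.n_pred, "n_ref": res.n_ref, "n_matched": res.n_matched,
                  "precision": res.precision, "recall": res.recall, "f1": res.f1}
        report_path.write_text(json.dumps(report, indent=2))
        say(f"evaluate: precision {res.precision:.3f} recall {res.recall:.3f} "
            f"f1 {res.f1:.3f}")
        results["evaluation"] = report

    return results


def _write_history(history: list[dict], path) -> None:
    if not history:
        return
    keys = sorted({k for rec in history for k in rec})
    with open(path, "w") as fh:
        fh.write(",".join(keys) + "\n")
        for rec in history:
            fh.write(",".join(str(rec.get(k, "")) for k in keys) + "\n")
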