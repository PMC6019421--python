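"""End-to-end orchestration of the simulated studies.

``run_pipeline`` chains the stages: stimulus/observer simulation →
behavioral statistics → (two-category designs only) quintile subgroups →
six texture averages → difference images → slice correlations → notch.
Every artifact is written under the configured output directory together
with a provenance manifest (config hash, seed, package and numpy
versions); an identical config and seed reproduces identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import yaml

from . import __version__, behavior, io, slices as slc
from .averaging import build_six_averages
from .synth import (CueParams, DEFAULT_CROP, default_panel,
                    make_stimulus_set, simulate_trials)
from .types import Category

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    design: str = "exp2"
    seed: int = 0
    n_observers: int = 30
    cue: CueParams = field(default_factory=CueParams)
    crop: Tuple[int, int, int, int] = DEFAULT_CROP
    n_slices: int = 30
    correction: str = "loglinear"
    exclude: Tuple[str, ...] = ()
    outdir: str = "maskcue_out"
    write_stimuli: bool = False

    def __post_init__(self) -> None:
        if self.design not in ("exp1", "exp2"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_observers < 1:
            raise ValueError("n_observers must be positive")
        if isinstance(self.cue, dict):
            self.cue = CueParams(**self.cue)
        self.crop = tuple(int(v) for v in self.crop)  # type: ignore[assignment]
        if len(self.crop) != 4:
            raise ValueError("crop must be (top, left, height, width)")
        if self.crop[2] % self.n_slices != 0:
            raise ValueError("crop height must be divisible by n_slices")
        if self.correction not in ("none", "loglinear"):
            raise ValueError(f"unknown correction {self.correction!r}")
        self.exclude = tuple(self.exclude)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        data = io.load_config_dict(path)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the configured study end to end; returns the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict = {"design": config.design, "seed": config.seed,
                    "stages": [], "counts": {}}
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "maskcue_version": __version__,
        "numpy_version": np.__version__,
        "outputs": [],
    }

    def _write(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"].append(name)

    def _manifest() -> None:
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    stage = "simulate"
    try:
        stimuli = make_stimulus_set(config.design, config.cue, config.seed)
        panel = default_panel(config.n_observers, rng_seed=config.seed)
        trials = simulate_trials(stimuli, panel, rng_seed=config.seed,
                                 crop=config.crop)
        logger.info("simulate: %d stimuli, %d observers, %d trials",
                    len(stimuli), len(panel), len(trials))
        report["stages"].append(stage)
        report["counts"]["stimuli"] = len(stimuli)
        report["counts"]["observers"] = len(panel)
        report["counts"]["trials"] = len(trials)
        report["counts"]["trials_per_participant"] = len(stimuli)
        _write("trials.csv", lambda p: io.write_trials(trials, p))
        _write("landmarks.csv", lambda p: io.write_landmarks(
            {s.id: s.landmarks for s in stimuli}, p))
        if config.write_stimuli:
            (out / "stimuli").mkdir(exist_ok=True)
            for s in stimuli:
                io.write_image(s.pixels, out / "stimuli" / f"{s.id}.png")

        stage = "behav"
        acc, acc_stats = behavior.condition_accuracy(trials)
        _write("accuracy_by_participant.csv",
               lambda p: acc.to_csv(p, index=False, float_format=io.FLOAT_FORMAT))
        _write("accuracy_group_stats.csv",
               lambda p: io.group_stats_frame(acc_stats).to_csv(
                   p, index=False, float_format=io.FLOAT_FORMAT))
        rt_per, rt_stats = behavior.rt_summary(trials)
        _write("rt_group_stats.csv",
               lambda p: io.group_stats_frame(rt_stats).to_csv(
                   p, index=False, float_format=io.FLOAT_FORMAT))

        tests: Dict[str, behavior.TestResult] = {}
        pivot = acc.pivot(index="participant_id", columns="condition",
                          values="accuracy").sort_index()
        if config.design == "exp1":
            hi = pivot[Category.HIGH_REALISM_MASK.value].to_numpy()
            lo = pivot[Category.LOW_REALISM_MASK.value].to_numpy()
            tests["acc_low_vs_high_realism_t"] = behavior.paired_t(lo, hi)
            tests["acc_high_vs_low_realism_r"] = behavior.pearson(hi, lo)
            rt_pivot = rt_per.pivot(index="participant_id", columns="condition",
                                    values="mean_rt_ms")
            both = rt_pivot.dropna()
            tests["rt_high_vs_low_realism_t"] = behavior.paired_t(
                both[Category.HIGH_REALISM_MASK.value].to_numpy(),
                both[Category.LOW_REALISM_MASK.value].to_numpy())
            report["group_stats"] = {k: vars(v) for k, v in acc_stats.items()}
        else:
            mask_acc = pivot[Category.HIGH_REALISM_MASK.value]
            face_acc = pivot[Category.REAL_FACE.value]
            tests["acc_face_vs_mask_t"] = behavior.paired_t(
                face_acc.to_numpy(), mask_acc.to_numpy())
            tests["acc_mask_vs_face_r"] = behavior.pearson(
                mask_acc.to_numpy(), face_acc.to_numpy())
            sdt_all = behavior.sdt_by_participant(trials, config.correction)
            _write("sdt_by_participant.csv",
                   lambda p: io.sdt_frame(sdt_all).to_csv(
                       p, index=False, float_format=io.FLOAT_FORMAT))
            pk = {o.id: o.prior_knowledge for o in panel}
            pids = sorted(pk)
            pkv = np.array([pk[p] for p in pids], dtype=float)
            tests["prior_knowledge_vs_mask_acc_r"] = behavior.pearson(
                pkv, mask_acc.loc[pids].to_numpy())
            tests["prior_knowledge_vs_dprime_r"] = behavior.pearson(
                pkv, np.array([sdt_all[p].dprime for p in pids]))
            report["sdt_group"] = {
                "dprime_mean": float(np.mean([s.dprime for s in sdt_all.values()])),
                "criterion_mean": float(np.mean([s.criterion for s in sdt_all.values()])),
                "pcorrect_mean": float(np.mean([s.pcorrect for s in sdt_all.values()])),
            }
            report["group_stats"] = {k: vars(v) for k, v in acc_stats.items()}

        report["stages"].append("behav")

        if config.design == "exp2":
            stage = "subgroups"
            split = behavior.quintile_split(mask_acc.to_dict())
            _write("quintiles.csv",
                   lambda p: split.to_csv(p, index=False,
                                          float_format=io.FLOAT_FORMAT))
            high = split.loc[split["subgroup"] == "high", "participant_id"].tolist()
            low = split.loc[split["subgroup"] == "low", "participant_id"].tolist()
            anova = behavior.mixed_anova_2x2(
                {p: mask_acc[p] for p in high + low},
                {p: face_acc[p] for p in high + low},
                {p: ("high" if p in high else "low") for p in high + low})
            tests.update({f"anova_{k}": v for k, v in anova.items()})
            report["counts"]["subgroup_size"] = len(high)
            report["stages"].append("subgroups")

            stage = "average"
            averages = build_six_averages(stimuli, trials, high, low,
                                          exclude=config.exclude)
            for label, avg in averages.items():
                io.write_image(avg.texture, out / f"avg_{label}.png")
                manifest["outputs"].append(f"avg_{label}.png")
            logger.info("average: %d stimuli excluded, perceived response "
                        "counts %s", len(config.exclude),
                        {k: v.total_responses for k, v in averages.items()
                         if v.total_responses})
            report["counts"]["perceived_response_totals"] = {
                k: v.total_responses for k, v in averages.items()
                if v.total_responses is not None}
            report["stages"].append("average")

            stage = "slices"
            diffs = {
                "veridical": slc.diff_image(averages["veridical_mask"],
                                            averages["veridical_face"]),
                "high": slc.diff_image(averages["perceived_mask_high"],
                                       averages["perceived_face_high"]),
                "low": slc.diff_image(averages["perceived_mask_low"],
                                      averages["perceived_face_low"]),
            }
            rows = []
            notches: Dict[str, int] = {}
            slice_tables = {}
            for name in ("high", "low"):
                a = slc.crop_internal(diffs[name], config.crop)
                b = slc.crop_internal(diffs["veridical"], config.crop)
                table = slc.slice_correlations(
                    a, b, config.n_slices, comparison=f"{name}_vs_veridical")
                slice_tables[name] = table
                notches[name] = slc.find_notch(table)
                for k in range(config.n_slices):
                    rows.append((table.comparison, int(table.slice_index[k]),
                                 table.r[k], bool(table.defined[k]),
                                 table.n_pixels))
            import pandas as pd
            _write("slice_correlations.csv",
                   lambda p: pd.DataFrame(
                       rows, columns=["comparison", "slice_index", "r",
                                      "defined", "n_pixels"]).to_csv(
                           p, index=False, float_format=io.FLOAT_FORMAT))
            for name, diff in diffs.items():
                io.write_image(slc.rescale_for_visualization(diff),
                               out / f"diff_{name}.png")
                io.write_grid(diff.values, out / f"diff_{name}.csv")
                manifest["outputs"] += [f"diff_{name}.png", f"diff_{name}.csv"]
            _plot_slice_bars(slice_tables, out / "slice_correlations.png")
            manifest["outputs"].append("slice_correlations.png")
            report["notch"] = notches
            report["slice_r"] = {
                name: {"min": float(np.nanmin(t.r)),
                       "slice15": float(t.r[14]) if config.n_slices >= 15 else None}
                for name, t in slice_tables.items()}
            report["stages"].append("slices")

        _write("tests.csv", lambda p: io.test_results_frame(tests).to_csv(
            p, index=False, float_format=io.FLOAT_FORMAT))
        report["tests"] = {k: {"name": v.name, "value": v.value, "df": v.df,
                               "p": v.p, "effect_size": v.effect_size}
                           for k, v in tests.items()}
    except Exception as exc:
        manifest["failed_stage"] = stage
        _manifest()
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    io.save_config(config, out / "config.yaml")
    manifest["outputs"].append("config.yaml")
    _manifest()
    return report


def _plot_slice_bars(tables: Dict[str, "slc.SliceCorrelationTable"],
                     path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(tables), figsize=(4 * len(tables), 5),
                             sharey=True)
    if len(tables) == 1:
        axes = [axes]
    for ax, (name, t) in zip(axes, tables.items()):
        ax.barh(t.slice_index, np.where(t.defined, t.r, 0.0), color="0.6")
        ax.invert_yaxis()
        ax.set_xlabel("Pearson r")
        ax.set_title(f"{name} vs veridical")
        ax.set_xlim(-1, 1)
    axes[0].set_ylabel("image slice (top to bottom)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
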