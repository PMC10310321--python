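"""End-to-end synthetic study orchestration.

``run_synthetic_study`` executes simulate -> features -> readout ->
consistency (-> neural fit) on synthetic data, writing every intermediate
artifact plus a machine-readable ``summary.json`` and a plain-text log of
per-stage seeds.  A run is fully determined by its configuration: the master
seed fans out to per-stage seeds through a stable hash, so any stage can be
re-run independently and reproduces its outputs exactly.

``replicate_paper`` runs the same stages on user-supplied real data (stimulus
directories, behavioral CSVs, optionally electrode arrays and a pretrained
encoder); it never downloads anything and degrades gracefully when only part
of the data is present.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._rng import derive_seed
from .behavior import ChoiceTable, ObserverParams, simulate_observer
from .consistency import (
    between_subject_consistency,
    compare_groups,
    empirical_percentile,
    fit_model_to_behavior,
    split_half_reliability,
)
from .electrodes import simulate_electrodes
from .encoders import RandomConvEncoder, extract_feature_layers, extract_features, flatten_pixels
from .neural_fit import NeuralEncodingModel
from .readout import CategoryReadout, ReadoutConfig, aggregate_morph_level
from .stimuli import generate_morph_stimuli

__all__ = ["RunConfig", "run_synthetic_study", "replicate_paper", "MissingDataError"]


class MissingDataError(FileNotFoundError):
    """Raised when a replication run lacks required input files."""


@dataclass
class RunConfig:
    """Serializable configuration of a full synthetic run."""

    master_seed: int = 0
    stimuli: dict = field(
        default_factory=lambda: {"n_sequences": 7, "n_levels": 11, "image_size": 64, "colinearity": 0.9}
    )
    observers: list = field(
        default_factory=lambda: [
            {"subject_id": f"s{i}", "group": g, "slope": 0.15, "bias": 50.0, "lapse": 0.02, "image_effect_sd": 1.0}
            for i, g in enumerate(["intact"] * 3 + ["lesioned"] * 3)
        ]
    )
    n_reps: int = 10
    encoder: dict = field(default_factory=lambda: {"name": "random-cnn", "layer": "fc6", "seed": 0})
    readout: dict = field(default_factory=lambda: {"n_iterations": 100, "sequence_holdout": False})
    consistency: dict = field(default_factory=lambda: {"n_iter": 100, "min_reps": None})
    electrodes: dict = field(
        default_factory=lambda: {"enabled": False, "n_electrodes": 8, "n_repetitions": 10, "noise_sd": 1.0}
    )

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        base = cls()
        for key, value in data.items():
            current = getattr(base, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(base, key, value)
        return base


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _stat_dict(stat) -> dict:
    df = list(stat.df) if isinstance(stat.df, tuple) else stat.df
    out = {"beta": stat.beta, "statistic": stat.statistic, "df": df, "p": stat.p, "kind": stat.kind}
    if stat.r_squared is not None:
        out["r_squared"] = stat.r_squared
    return out


def run_synthetic_study(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    summary: dict = {"config": dataclasses.asdict(config)}

    def log(msg: str) -> None:
        log_lines.append(msg)

    def stage_seed(name: str) -> int:
        s = derive_seed(config.master_seed, name)
        log(f"stage {name}: seed {s}")
        return s

    try:
        # -- stimuli ---------------------------------------------------------
        stim = generate_morph_stimuli(seed=stage_seed("stimuli"), **config.stimuli)
        stim.to_dir(outdir / "stimuli")
        summary["n_images"] = len(stim)

        # -- observers -------------------------------------------------------
        obs_tables = []
        for spec in config.observers:
            spec = dict(spec)
            sid, grp = spec.pop("subject_id"), spec.pop("group")
            params = ObserverParams(seed=stage_seed(f"observer:{sid}"), **spec)
            obs_tables.append(simulate_observer(stim, params, config.n_reps, subject_id=sid, group=grp))
        choices = ChoiceTable.concat(obs_tables)
        choices.to_csv(outdir / "choices.csv")

        # -- features --------------------------------------------------------
        enc = RandomConvEncoder(seed=int(config.encoder.get("seed", 0)))
        layer = config.encoder.get("layer", "fc6")
        feats = extract_features(enc, stim, layer)
        feats.save(outdir / "features" / f"{enc.name}_{layer}")
        pixels = flatten_pixels(stim)
        pixels.save(outdir / "features" / "pixels")

        # -- readout ---------------------------------------------------------
        rd_seed = stage_seed("readout")
        rcfg = ReadoutConfig(n_iterations=int(config.readout.get("n_iterations", 100)), seed=rd_seed)
        results = {"model": CategoryReadout.from_stimuli(feats, stim, rcfg).fit()}
        if config.readout.get("sequence_holdout", False):
            hcfg = dataclasses.replace(rcfg, split_mode="sequence_holdout")
            results["model_sequence_holdout"] = CategoryReadout.from_stimuli(feats, stim, hcfg).fit()
            results["pixels_sequence_holdout"] = CategoryReadout.from_stimuli(pixels, stim, hcfg).fit()
            results["pixels"] = CategoryReadout.from_stimuli(pixels, stim, rcfg).fit()
        (outdir / "readout").mkdir(exist_ok=True)
        summary["readout"] = {}
        extremes = [int(stim.morph_levels().min()), int(stim.morph_levels().max())]
        for name, res in results.items():
            res.per_iteration.to_csv(outdir / "readout" / f"{name}_per_iteration.csv", index=False)
            res.per_image.to_csv(outdir / "readout" / f"{name}_per_image.csv", index=False)
            curve = res.morph_curve()
            curve.to_csv(outdir / "readout" / f"{name}_morph_curve.csv", index=False)
            summary["readout"][name] = {
                "accuracy": res.accuracy(),
                "extreme_accuracy": res.accuracy(levels=extremes),
                "morph_curve": curve.to_dict(orient="list"),
            }
        if config.readout.get("sequence_holdout", False):
            summary["readout"]["holdout_contrast"] = {
                "pixels_random_minus_holdout": summary["readout"]["pixels"]["extreme_accuracy"]
                - summary["readout"]["pixels_sequence_holdout"]["extreme_accuracy"],
                "model_random_minus_holdout": summary["readout"]["model"]["extreme_accuracy"]
                - summary["readout"]["model_sequence_holdout"]["extreme_accuracy"],
            }

        # -- behavior curves & model-behavior fits ---------------------------
        (outdir / "consistency").mkdir(exist_ok=True)
        group_curves = {}
        for grp in ("intact", "lesioned"):
            sub = ChoiceTable(choices.df[choices.df["group"] == grp])
            if len(sub.df):
                curve = aggregate_morph_level(sub)
                curve.to_csv(outdir / "consistency" / f"curve_{grp}.csv", index=False)
                group_curves[grp] = curve
        model_curve = results["model"].morph_curve()
        summary["behavior_curves"] = {}
        for table in obs_tables:
            sid = table.df["subject_id"].iloc[0]
            summary["behavior_curves"][sid] = aggregate_morph_level(table).to_dict(orient="list")
        summary["model_behavior"] = {}
        for grp, curve in group_curves.items():
            merged = curve.merge(model_curve, on="morph_level_pct", suffixes=("_subj", "_model"))
            stat = fit_model_to_behavior(merged["prop_dog_model"], merged["prop_dog_subj"])
            summary["model_behavior"][f"morph_level_{grp}"] = _stat_dict(stat)
        if len(group_curves) == 2:
            summary["group_comparison"] = _stat_dict(
                compare_groups(group_curves["intact"], group_curves["lesioned"])
            )

        # -- consistency -----------------------------------------------------
        cs_seed = stage_seed("consistency")
        n_iter = int(config.consistency.get("n_iter", 100))
        min_reps = config.consistency.get("min_reps", None)
        if min_reps is None:
            min_reps = 8 if config.n_reps >= 8 else 2
        per_subj = {t.df["subject_id"].iloc[0]: t for t in obs_tables}
        rel_rows = []
        within, between = {}, {}
        subjects = list(per_subj)
        for i, si in enumerate(subjects):
            for sj in subjects[i:]:
                if si == sj:
                    dist = split_half_reliability(
                        per_subj[si], level="image", n_iter=n_iter, seed=cs_seed, min_reps=min_reps
                    )
                    within[si] = dist
                else:
                    dist = between_subject_consistency(
                        per_subj[si], per_subj[sj], level="image", n_iter=n_iter, seed=cs_seed, min_reps=min_reps
                    )
                    between[(si, sj)] = dist
                for it, val in enumerate(dist.values):
                    rel_rows.append({"pair_i": si, "pair_j": sj, "iteration": it, "value": val})
        import pandas as pd

        pd.DataFrame(rel_rows).to_csv(outdir / "consistency" / "image_level_reliability.csv", index=False)
        summary["consistency"] = {
            "within_subject_median": {s: d.median for s, d in within.items()},
            "between_subject_median": {f"{a}|{b}": d.median for (a, b), d in between.items()},
        }

        # image-level model fit and empirical percentile vs between-subject ref
        per_image = results["model"].per_image.set_index("image_id")["mean_predicted_label"]
        percentiles, fits = [], {}
        for si, table in per_subj.items():
            subj_means = table.df.groupby("image_id")["response"].mean()
            shared = subj_means.index.intersection(per_image.index)
            if len(shared) >= 3 and np.ptp(per_image.loc[shared].to_numpy()) > 0:
                stat = fit_model_to_behavior(per_image.loc[shared], subj_means.loc[shared])
                fits[si] = stat
        if between and fits:
            reference = np.concatenate([d.values for d in between.values()])
            model_r2 = np.array([s.r_squared for s in fits.values()])
            summary["model_behavior"]["image_level"] = {
                s: _stat_dict(stat) for s, stat in fits.items()
            }
            summary["model_behavior"]["empirical_percentile_image_level"] = empirical_percentile(
                model_r2, reference
            )

        # -- neural fit (optional) -------------------------------------------
        if config.electrodes.get("enabled", False):
            ne_seed = stage_seed("electrodes")
            layer_feats = extract_feature_layers(enc, stim, list(enc.layers))
            gen_layer = config.electrodes.get("generating_layer", layer)
            eset = simulate_electrodes(
                layer_feats[gen_layer],
                n_electrodes=int(config.electrodes.get("n_electrodes", 8)),
                n_repetitions=int(config.electrodes.get("n_repetitions", 10)),
                noise_sd=float(config.electrodes.get("noise_sd", 1.0)),
                seed=ne_seed,
            )
            eset.save(outdir / "electrodes" / "electrodes")
            (outdir / "neural_fit").mkdir(exist_ok=True)
            nres = NeuralEncodingModel(layer_feats, eset).fit(seed=ne_seed)
            nres.summary().to_csv(outdir / "neural_fit" / "layer_summary.csv", index=False)
            nres.per_electrode_frame().to_csv(outdir / "neural_fit" / "per_electrode.csv", index=False)
            peak = nres.peak_layer()
            contrast = nres.contrast_layer_halves()
            summary["neural_fit"] = {
                "peak_layer": peak[0],
                "peak_median_r_corrected": peak[1],
                "peak_dispersion": peak[2],
                "early_vs_late": _stat_dict(contrast),
            }
    except Exception as exc:
        log(f"FAILED: {type(exc).__name__}: {exc}")
        (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
        raise

    RunConfig(**dataclasses.asdict(config)).to_yaml(outdir / "config.yaml")
    (outdir / "summary.json").write_text(
        json.dumps(_round_floats(summary), sort_keys=True, indent=1) + "\n"
    )
    (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return outdir


def replicate_paper(
    stimuli_dir: str | Path | None,
    choices_csv: str | Path | None,
    outdir: str | Path,
    electrodes_path: str | Path | None = None,
    encoder=None,
    n_iterations: int = 100,
    seed: int = 0,
) -> Path:
    """Run the analysis stages on user-supplied real data.

    Refuses to download anything.  With behavior only, the consistency
    analyses run and the feature-based stages are skipped with a notice.
    Raises :class:`MissingDataError` when no usable inputs are present.
    """
    from .stimuli import StimulusSet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    notices: list[str] = []
    summary: dict = {}

    stim = choices = None
    if stimuli_dir is not None:
        stimuli_dir = Path(stimuli_dir)
        if not stimuli_dir.exists():
            raise MissingDataError(
                f"stimulus directory {stimuli_dir} not found; expected layout "
                "<root>/<experiment>/<sequence>/<level>.png plus index.csv"
            )
        stim = StimulusSet.from_dir(stimuli_dir)
    if choices_csv is not None:
        choices_csv = Path(choices_csv)
        if not choices_csv.exists():
            raise MissingDataError(f"choice table {choices_csv} not found; expected the documented CSV schema")
        choices = ChoiceTable.from_csv(choices_csv)
    if stim is None and choices is None:
        raise MissingDataError("no inputs: provide a stimulus directory and/or a choice CSV")

    if choices is not None:
        for grp in sorted(choices.df["group"].unique()):
            sub = ChoiceTable(choices.df[choices.df["group"] == grp])
            aggregate_morph_level(sub).to_csv(outdir / f"curve_{grp}.csv", index=False)
        summary["behavior_groups"] = sorted(choices.df["group"].unique())
    if stim is not None:
        encoder = encoder or RandomConvEncoder(seed=0)
        feats = extract_features(encoder, stim, encoder.layers[-1])
        res = CategoryReadout.from_stimuli(feats, stim, ReadoutConfig(n_iterations=n_iterations, seed=seed)).fit()
        res.morph_curve().to_csv(outdir / "model_morph_curve.csv", index=False)
        summary["model_accuracy"] = res.accuracy()
    else:
        notices.append("feature analyses skipped: no stimuli supplied")
    if electrodes_path is not None:
        notices.append("electrode fitting requires stimuli and a documented array container")
    summary["notices"] = notices
    (outdir / "summary.json").write_text(json.dumps(_round_floats(summary), sort_keys=True, indent=1) + "\n")
    return outdir
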