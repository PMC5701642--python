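"""Config-driven replay of the model-simplification study.

For every combination of reference source, source orientation class
(quasi-radial / quasi-tangential), noise level (low / high), forward model
(shell-cascade level and/or perturbation level), filter constraint and
localization criterion (variance / kurtosis), the driver simulates the
measurement with the *reference* forward model, scans with the *simplified*
model's leadfields (the model-mismatch design), localizes, and records the
localization error.  The whole pipeline is a pure function of the
configuration and its master seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import forward, simulate
from .beamformer import CONSTRAINTS, scan
from .localize import ErrorSummary, localize, tukey_summary


@dataclass
class ExperimentConfig:
    """Study-design parameters; defaults follow the simulation protocol."""

    modality: str = "eeg"
    n_reference_sources: int = 60
    n_source_nodes: int = 8000
    perturbation_levels: Tuple[float, ...] = (0.0, 0.02, 0.05, 0.1, 0.2)
    cascade_levels: Tuple[str, ...] = ()
    noise_levels: Tuple[str, ...] = ("low", "high")
    noise_variances: Optional[Tuple[float, float]] = None  # override (low, high)
    constraints: Tuple[str, ...] = CONSTRAINTS
    criteria: Tuple[str, ...] = ("variance", "kurtosis")
    orientation_classes: Tuple[str, ...] = ("quasi_tangential", "quasi_radial")
    seed: int = 0
    replicates: int = 1
    rate: float = 1200.0
    duration_s: float = 20.0
    amplitude_nam: float = 100.0
    spike_onsets_s: Tuple[float, ...] = (5.0, 13.0)
    loading: float = 0.0
    n_terms: int = 60
    n_eeg_channels: int = 80
    n_meg_channels: int = 273

    def __post_init__(self):
        if self.modality not in ("eeg", "meg"):
            raise ValueError("modality must be 'eeg' or 'meg'")
        for c in self.constraints:
            if c not in CONSTRAINTS:
                raise ValueError(f"unknown constraint {c!r}")
        for lvl in self.cascade_levels:
            forward.make_shell_model(lvl)  # raises on unknown levels
        if self.cascade_levels and self.modality == "meg":
            raise ValueError("the conductivity cascade has no MEG effect in a "
                             "spherical conductor; use perturbation_levels")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def _seed_for(master: int, *stream: int) -> int:
    """Stated counter scheme: seeds derive from (master, stream indices)."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF] + [int(s) for s in stream])
    return int(ss.generate_state(1)[0])


def _model_list(cfg: ExperimentConfig) -> List[Tuple[str, object]]:
    models: List[Tuple[str, object]] = [("cascade", lvl) for lvl in cfg.cascade_levels]
    models += [("perturb", lvl) for lvl in cfg.perturbation_levels]
    if not models:
        models = [("perturb", 0.0)]
    return models


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """One row per (replicate, source, orientation, noise, model, constraint,
    criterion); failures are recorded per row, never dropped."""
    shells = forward.make_shell_model("reference")
    cortex_r = 0.875 * shells.inner_radius
    refs = forward.make_reference_sources(cfg.n_reference_sources, cortex_r,
                                          seed=_seed_for(cfg.seed, 1))
    space = forward.build_source_space(cfg.n_source_nodes, shells, refs,
                                       seed=_seed_for(cfg.seed, 2),
                                       cortex_radius=cortex_r)

    meg_sensors = forward.make_meg_sensors(cfg.n_meg_channels)
    sensors = (forward.make_eeg_sensors(cfg.n_eeg_channels, shells)
               if cfg.modality == "eeg" else meg_sensors)

    # both orientation classes come from the MEG gain at the true position
    meg_ref = forward.compute_leadfields(shells, meg_sensors, refs)
    orientations = {}
    for i in range(refs.shape[0]):
        quasi_radial, quasi_tangential = forward.reference_orientations(meg_ref.node_gain(i))
        orientations[i] = {"quasi_radial": quasi_radial,
                           "quasi_tangential": quasi_tangential}

    ref_lead = forward.compute_leadfields(shells, sensors, refs, n_terms=cfg.n_terms)
    base_scan_lead = forward.compute_leadfields(shells, sensors, space.node_positions,
                                                n_terms=cfg.n_terms)
    cascade_leads = {lvl: forward.compute_leadfields(forward.make_shell_model(lvl),
                                                     sensors, space.node_positions,
                                                     n_terms=cfg.n_terms)
                     for lvl in cfg.cascade_levels}

    waveform = simulate.make_spike_waveform(cfg.rate)
    onsets = [int(round(s * cfg.rate)) for s in cfg.spike_onsets_s]
    if cfg.noise_variances is not None:
        variances = dict(zip(("low", "high"), cfg.noise_variances))
    else:
        variances = dict(zip(("low", "high"), simulate.NOISE_VARIANCES[cfg.modality]))

    models = _model_list(cfg)
    rows = []
    for rep in range(cfg.replicates):
        noise_seed = _seed_for(cfg.seed, 3, rep)
        scan_leads = {}
        for kind, lvl in models:
            if kind == "cascade":
                scan_leads[(kind, lvl)] = cascade_leads[lvl]
            else:
                scan_leads[(kind, lvl)] = forward.perturb_leadfield(
                    base_scan_lead, lvl, seed=_seed_for(cfg.seed, 4, rep,
                                                        models.index((kind, lvl))))
        for src in range(refs.shape[0]):
            for ori_name in cfg.orientation_classes:
                ori = orientations[src][ori_name]
                clean = simulate.assemble_measurement(
                    ref_lead.node_gain(src) @ ori, waveform, onsets,
                    duration_s=cfg.duration_s, rate=cfg.rate,
                    amplitude_nam=cfg.amplitude_nam, modality=cfg.modality)
                for noise_name in cfg.noise_levels:
                    meas = simulate.add_white_noise(clean, variances[noise_name],
                                                    seed=noise_seed)
                    if cfg.modality == "eeg":
                        meas = simulate.common_average_reference(meas)
                    meas = simulate.demean_channels(meas)
                    for (kind, lvl) in models:
                        label = lvl if kind == "cascade" else f"perturb{lvl:g}"
                        for constraint in cfg.constraints:
                            base = {
                                "replicate": rep, "source": src,
                                "modality": cfg.modality,
                                "orientation_class": ori_name,
                                "noise": noise_name,
                                "noise_variance": variances[noise_name],
                                "model": label, "model_kind": kind,
                                "model_level": lvl if kind == "perturb" else np.nan,
                                "constraint": constraint,
                            }
                            try:
                                outs = scan(space, scan_leads[(kind, lvl)], meas,
                                            constraint, loading=cfg.loading)
                            except Exception as e:  # record, keep driving
                                for criterion in cfg.criteria:
                                    rows.append({**base, "criterion": criterion,
                                                 "error_mm": np.nan,
                                                 "estimated_node": -1, "tie": False,
                                                 "status": "error", "note": str(e)})
                                continue
                            for criterion in cfg.criteria:
                                try:
                                    res = localize(outs, criterion,
                                                   true_position=refs[src])
                                    rows.append({**base, "criterion": criterion,
                                                 "error_mm": res.error_mm,
                                                 "estimated_node": res.estimated_node,
                                                 "tie": res.tie, "status": "ok",
                                                 "note": ""})
                                except Exception as e:
                                    rows.append({**base, "criterion": criterion,
                                                 "error_mm": np.nan,
                                                 "estimated_node": -1, "tie": False,
                                                 "status": "error", "note": str(e)})
    return pd.DataFrame(rows)


GROUP_COLS = ["modality", "orientation_class", "noise", "model", "constraint", "criterion"]


def summarize_experiment(table: pd.DataFrame, cap: float = 40.0,
                         whisker_anchor: str = "median"):
    """One Tukey summary per condition group.

    Returns (summary_frame, summaries) where ``summaries`` maps the group key
    tuple to its :class:`~beamcascade.localize.ErrorSummary`.  Groups whose
    rows all failed are flagged (n = 0), not dropped.
    """
    if table.empty:
        raise ValueError("empty results table")
    out_rows, summaries = [], {}
    for key, grp in table.groupby(GROUP_COLS, sort=True):
        errs = grp.loc[grp["status"] == "ok", "error_mm"].to_numpy()
        row = dict(zip(GROUP_COLS, key))
        if errs.size == 0:
            row.update({"n": 0, "median_mm": np.nan, "q1_mm": np.nan, "q3_mm": np.nan,
                        "whisker_low_mm": np.nan, "whisker_high_mm": np.nan,
                        "n_outliers": 0, "flagged_empty": True})
            summaries[key] = None
        else:
            s = tukey_summary(errs, cap=cap, whisker_anchor=whisker_anchor)
            row.update({"n": s.n, "median_mm": s.median, "q1_mm": s.q1, "q3_mm": s.q3,
                        "whisker_low_mm": s.whisker_low, "whisker_high_mm": s.whisker_high,
                        "n_outliers": int(s.outliers.size), "flagged_empty": False})
            summaries[key] = s
        out_rows.append(row)
    return pd.DataFrame(out_rows), summaries


def render_summary(summary_frame: pd.DataFrame, cap: float = 40.0) -> pd.DataFrame:
    """Reporting view with medians/quartiles capped at ``cap`` and rounded to mm."""
    view = summary_frame.copy()
    for col in ["median_mm", "q1_mm", "q3_mm", "whisker_low_mm", "whisker_high_mm"]:
        view[col] = view[col].clip(upper=cap).round().astype("Int64")
    return view


def plot_summaries(table: pd.DataFrame, path, cap: float = 40.0,
                   whisker_anchor: str = "median"):
    """Boxplot grid (constraint rows x condition columns), errors capped for display."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    constraints = sorted(table["constraint"].unique())
    conds = sorted(table.loc[table["status"] == "ok"]
                   .groupby(["orientation_class", "noise", "criterion"]).groups)
    fig, axes = plt.subplots(len(constraints), len(conds),
                             figsize=(3.2 * len(conds), 2.6 * len(constraints)),
                             squeeze=False)
    for i, con in enumerate(constraints):
        for j, (ori, noise, crit) in enumerate(conds):
            ax = axes[i][j]
            sub = table[(table["constraint"] == con) & (table["orientation_class"] == ori)
                        & (table["noise"] == noise) & (table["criterion"] == crit)
                        & (table["status"] == "ok")]
            models = sorted(sub["model"].unique())
            data = [np.clip(sub.loc[sub["model"] == m, "error_mm"].dropna(), 0, cap)
                    for m in models]
            if data:
                ax.boxplot(data, tick_labels=models)
            ax.axhline(cap, ls="--", lw=0.5, color="gray")
            ax.set_ylim(0, cap * 1.05)
            if i == 0:
                ax.set_title(f"{ori[:7]} {noise} {crit[:4]}", fontsize=8)
            if j == 0:
                ax.set_ylabel(f"{con}\nerror (mm)", fontsize=8)
            ax.tick_params(labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
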