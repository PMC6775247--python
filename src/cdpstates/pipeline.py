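"""End-to-end orchestration: simulate -> extract -> analyze -> graphs -> report.

The pipeline ties the stages together under one YAML-configurable,
seed-reproducible run: synthesize a multi-segment recording with known
condition schedule, extract and classify CDP events (or start from the
ground-truth labels when no continuous signal is wanted), compute per-step
histograms, RMS matrices and t-tests, fit per-step Markov models and their
similarity matrices, build per-segment and consensus graphs with WalkTrap
communities, correlate segment pairs over windows, and write every artifact
plus a manifest to the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import segment_correlation as sc
from . import state_graphs as sg
from . import step_histograms as sh
from . import synthetic_data as sd
from . import waveform_dictionary as wd
from .markov_similarity import similarity_matrix

logger = logging.getLogger("cdpstates")

#: Fields a config file must provide explicitly.
REQUIRED_FIELDS = ("schedule", "step_length_s", "seed")

#: Step counts of the demonstration schedule (control, capsaicin,
#: lidocaine restoration/relapse, spinalization).
DEMO_SCHEDULE = (("control", 3), ("capsaicin", 9), ("lidocaine1", 11), ("spinal", 2))


@dataclass
class PipelineConfig:
    """Validated parameters of one pipeline run."""

    schedule: tuple[tuple[str, int], ...] = DEMO_SCHEDULE
    step_length_s: float = 600.0
    seed: int = 0
    outdir: str = "cdpstates_run"
    fs: float = sd.DEFAULT_FS
    n_classes: int = sd.DEFAULT_N_CLASSES
    channels: tuple[str, ...] = ("L5rL", "L5rR", "L6rL", "L6rR")
    event_rate: float = 4.0
    sync_rho: float = 0.3
    noise_sigma: float = 4.0
    restore_fraction: float = 0.8
    use_raw: bool = True
    threshold_k: float = 4.0
    dead_time_s: float = 0.05
    graph_k: int = sg.DEFAULT_K
    graph_S: float = sg.DEFAULT_S
    consensus_k: int = sg.DEFAULT_CONSENSUS_K
    mst: float = sg.DEFAULT_MST
    k2: int = sg.DEFAULT_K2
    correlation_window_s: float | None = None   # default: step length
    make_figures: bool = True

    def __post_init__(self) -> None:
        self.schedule = tuple((str(c), int(n)) for c, n in self.schedule)
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("config field 'seed' must be an integer")
        for name in ("event_rate", "step_length_s", "fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load and validate a YAML config, naming any missing required field."""
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        for name in REQUIRED_FIELDS:
            if name not in raw:
                raise ValueError(f"config is missing required field {name!r}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def build_schedule(self) -> sd.ConditionSchedule:
        return sd.ConditionSchedule(phases=self.schedule, step_length_s=self.step_length_s)

    def build_state(self) -> sd.GenerativeState:
        return sd.GenerativeState(
            channel_ids=tuple(self.channels), n_classes=self.n_classes,
            event_rate=self.event_rate, sync_rho=self.sync_rho,
            noise_sigma=self.noise_sigma, dead_time_s=self.dead_time_s,
            restore_fraction=self.restore_fraction,
        )


@dataclass
class RunReport:
    """Manifest of a completed run."""

    outdir: str
    seed: int
    n_steps: int
    artifacts: dict[str, str] = field(default_factory=dict)
    summaries: dict[str, object] = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump({"outdir": self.outdir, "seed": self.seed,
                       "n_steps": self.n_steps, "artifacts": self.artifacts,
                       "summaries": self.summaries}, f, indent=2, default=str)


def _heatmap(path, matrix: np.ndarray, title: str, labels: list[int]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    # dark = similar (low RMS / high similarity handled by caller's matrix sense)
    im = ax.imshow(matrix, cmap="viridis")
    ax.set_title(title)
    ax.set_xlabel("step")
    ax.set_ylabel("step")
    ticks = np.arange(len(labels))
    if len(labels) <= 30:
        ax.set_xticks(ticks, labels)
        ax.set_yticks(ticks, labels)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    """Synthesize the recording (and/or ground-truth events) and write them."""
    schedule = cfg.build_schedule()
    state = cfg.build_state()
    artifacts: dict[str, str] = {}
    if cfg.use_raw:
        rec, truth = sd.synthesize_recording(schedule, state, fs=cfg.fs, seed=cfg.seed)
        h5 = outdir / "recording.h5"
        sd.write_recording_h5(h5, rec)
        artifacts["recording"] = str(h5)
    else:
        rec, truth = None, sd.synthesize_events(schedule, state, seed=cfg.seed)
    truth_csv = outdir / "ground_truth_events.csv"
    sd.write_events_csv(truth_csv, truth)
    artifacts["ground_truth"] = str(truth_csv)
    return {"recording": rec, "truth": truth, "schedule": schedule,
            "state": state, "artifacts": artifacts}


def stage_extract(cfg: PipelineConfig, sim: dict, outdir: Path) -> dict:
    """Detect, build control dictionaries, and classify all events."""
    schedule: sd.ConditionSchedule = sim["schedule"]
    artifacts: dict[str, str] = {}
    if not cfg.use_raw:
        events = sim["truth"].copy()
        artifacts["events"] = str(outdir / "labeled_events.csv")
        events.to_csv(artifacts["events"], index=False)
        return {"events": events, "dictionaries": {}, "artifacts": artifacts}

    filtered = wd.bandpass_filter(sim["recording"])
    snippets = wd.detect_events(filtered, threshold_k=cfg.threshold_k,
                                dead_time_s=cfg.dead_time_s)
    n_control_steps = dict(cfg.schedule).get("control", 0)
    control_end = n_control_steps * cfg.step_length_s
    frames = []
    dictionaries: dict[str, wd.Dictionary] = {}
    for ch in filtered.channel_ids:
        ch_snips = [s for s in snippets if s.channel_id == ch]
        control = [s for s in ch_snips if s.peak_time_s < control_end]
        dic = wd.build_dictionary(control, cfg.n_classes)
        dictionaries[ch] = dic
        dpath = outdir / f"dictionary_{ch}.json"
        wd.write_dictionary(dpath, dic)
        artifacts[f"dictionary_{ch}"] = str(dpath)
        frames.append(wd.classify_events(ch_snips, dic, schedule))
    events = pd.concat(frames, ignore_index=True)
    epath = outdir / "labeled_events.csv"
    events.to_csv(epath, index=False)
    artifacts["events"] = str(epath)
    return {"events": events, "dictionaries": dictionaries, "artifacts": artifacts}


def stage_analyze(cfg: PipelineConfig, sim: dict, events: pd.DataFrame,
                  outdir: Path) -> dict:
    """Histograms, RMS matrices, t-tests, and Markov similarity matrices."""
    schedule: sd.ConditionSchedule = sim["schedule"]
    conds = schedule.step_conditions
    steps = list(range(1, schedule.n_steps + 1))
    artifacts: dict[str, str] = {}
    sims: dict[str, np.ndarray] = {}
    sim_keys: dict[str, list[int]] = {}
    frac_rows = []
    for ch in sorted(events["channel"].unique()):
        ch_ev = events[events["channel"] == ch]
        hists = [sh.fractional_probabilities(ch_ev, s, cfg.n_classes, channel=ch)
                 for s in steps]
        usable = [h for h in hists if h.total > 0]
        for h in hists:
            frac_rows.append({"channel": ch, "step": h.step_index,
                              "condition": conds[h.step_index - 1], "N": h.total,
                              **{f"class_{i + 1}": f
                                 for i, f in enumerate(np.nan_to_num(h.fractions))}})
        R = sh.rms_matrix(usable)
        rpath = outdir / f"rms_matrix_{ch}.csv"
        pd.DataFrame(R, index=[h.step_index for h in usable],
                     columns=[h.step_index for h in usable]).to_csv(rpath)
        artifacts[f"rms_matrix_{ch}"] = str(rpath)
        if cfg.make_figures:
            fpath = outdir / f"rms_matrix_{ch}.png"
            _heatmap(fpath, R, f"RMS of significances — {ch}",
                     [h.step_index for h in usable])
            artifacts[f"rms_heatmap_{ch}"] = str(fpath)

        # Welch t-tests of each maneuver phase vs control, per class
        fr = np.stack([h.fractions for h in hists])
        ctrl_rows = [i for i, c in enumerate(conds) if c == "control"]
        t_frames = []
        for phase in dict.fromkeys(conds):
            if phase == "control":
                continue
            rows = [i for i, c in enumerate(conds) if c == phase]
            if len(ctrl_rows) < 2 or len(rows) < 2:
                logger.warning("skipping t-test for %s/%s: <2 steps in a group", ch, phase)
                continue
            tt = sh.ttest_table(sh.class_probability_ttest(fr[ctrl_rows], fr[rows]))
            tt.insert(0, "phase", phase)
            t_frames.append(tt)
        if t_frames:
            tpath = outdir / f"ttests_{ch}.csv"
            pd.concat(t_frames, ignore_index=True).to_csv(tpath, index=False)
            artifacts[f"ttests_{ch}"] = str(tpath)

        # per-step Markov models and the similarity matrix
        seqs = {s: ch_ev[ch_ev["step"] == s].sort_values("time_s")["class"].to_numpy()
                for s in steps}
        S, keys = similarity_matrix(seqs, cfg.n_classes)
        sims[ch], sim_keys[ch] = S, keys
        spath = outdir / f"similarity_matrix_{ch}.csv"
        pd.DataFrame(S, index=keys, columns=keys).to_csv(spath)
        artifacts[f"similarity_matrix_{ch}"] = str(spath)

    fpath = outdir / "fractional_probabilities.csv"
    pd.DataFrame(frac_rows).to_csv(fpath, index=False)
    artifacts["fractions"] = str(fpath)
    return {"similarities": sims, "similarity_keys": sim_keys, "artifacts": artifacts}


def stage_graphs(cfg: PipelineConfig, sim: dict, analysis: dict, outdir: Path) -> dict:
    """Per-segment graphs, consensus graph, communities, transition narrative."""
    schedule: sd.ConditionSchedule = sim["schedule"]
    conds = schedule.step_conditions
    artifacts: dict[str, str] = {}
    sims = analysis["similarities"]
    keys = analysis["similarity_keys"]

    common = None
    for ch in sims:
        common = set(keys[ch]) if common is None else common & set(keys[ch])
    common_keys = sorted(common or set())
    if len(common_keys) < 2:
        raise ValueError("fewer than 2 steps usable across all segments")

    aligned: list[np.ndarray] = []
    for ch, S in sims.items():
        idx = [keys[ch].index(s) for s in common_keys]
        S2 = S[np.ix_(idx, idx)]
        aligned.append(S2)
        g = sg.build_similarity_graph(S2, k=cfg.graph_k, S=cfg.graph_S,
                                      step_keys=common_keys,
                                      conditions=[conds[s - 1] for s in common_keys])
        sg.community_clusters(g)
        gpath = outdir / f"similarity_graph_{ch}.graphml"
        sg.write_graphml(gpath, g)
        artifacts[f"similarity_graph_{ch}"] = str(gpath)

    votes = sg.collect_votes(aligned, mst=cfg.mst, k=cfg.consensus_k)
    vpath = outdir / "votes.csv"
    sg.write_votes_csv(vpath, votes, common_keys)
    artifacts["votes"] = str(vpath)

    consensus = sg.build_consensus_graph(votes, k2=cfg.k2, step_keys=common_keys,
                                         conditions=[conds[s - 1] for s in common_keys])
    cpath = outdir / "consensus_graph.graphml"
    sg.write_graphml(cpath, consensus)
    artifacts["consensus_graph"] = str(cpath)

    narrative = consensus.membership_table()
    npath = outdir / "state_transitions.csv"
    narrative.to_csv(npath, index=False)
    artifacts["state_transitions"] = str(npath)
    return {"consensus": consensus, "narrative": narrative, "votes": votes,
            "artifacts": artifacts}


def stage_correlation(cfg: PipelineConfig, sim: dict, outdir: Path) -> dict:
    """Windowed channel-pair correlations and between-window set similarity."""
    artifacts: dict[str, str] = {}
    if sim["recording"] is None:
        return {"artifacts": artifacts}
    window = cfg.correlation_window_s or cfg.step_length_s
    filtered = wd.bandpass_filter(sim["recording"])
    sets = sc.windowed_correlation(filtered, window_s=window)
    table = sc.correlation_table(sets)
    cpath = outdir / "correlograms.csv"
    table.to_csv(cpath)
    artifacts["correlograms"] = str(cpath)
    idx = [sc.coefficient_set_similarity(sets[0].r, s.r) for s in sets]
    ipath = outdir / "correlation_set_similarity.csv"
    pd.DataFrame({"window": [s.window_index for s in sets],
                  "similarity_vs_control0": idx}).to_csv(ipath, index=False)
    artifacts["correlation_set_similarity"] = str(ipath)
    if cfg.make_figures:
        fpath = outdir / "correlograms.png"
        _heatmap(fpath, table.to_numpy().T, "windowed pairwise correlation",
                 list(table.index))
        artifacts["correlogram_figure"] = str(fpath)
    return {"artifacts": artifacts}


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute all stages in order; fully deterministic under a fixed seed."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(outdir=str(outdir), seed=int(cfg.seed),
                       n_steps=cfg.build_schedule().n_steps)

    stage = "simulate"
    try:
        sim = stage_simulate(cfg, outdir)
        report.artifacts.update(sim["artifacts"])
        report.summaries["n_ground_truth_events"] = int(len(sim["truth"]))

        stage = "extract"
        ext = stage_extract(cfg, sim, outdir)
        report.artifacts.update(ext["artifacts"])
        report.summaries["n_labeled_events"] = int(len(ext["events"]))

        stage = "analyze"
        ana = stage_analyze(cfg, sim, ext["events"], outdir)
        report.artifacts.update(ana["artifacts"])

        stage = "graphs"
        gr = stage_graphs(cfg, sim, ana, outdir)
        report.artifacts.update(gr["artifacts"])
        report.summaries["n_consensus_communities"] = int(
            len(set(gr["consensus"].communities.tolist())))

        stage = "correlation"
        corr = stage_correlation(cfg, sim, outdir)
        report.artifacts.update(corr["artifacts"])
    except Exception:
        partial = outdir / "run_report_partial.json"
        report.summaries["failed_stage"] = stage
        report.save(partial)
        logger.error("pipeline aborted during stage %r; partial manifest at %s",
                     stage, partial)
        raise

    rpath = outdir / "run_report.json"
    report.save(rpath)
    report.artifacts["report"] = str(rpath)
    return report
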