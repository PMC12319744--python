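"""End-to-end orchestration of the multi-modal state analysis suite.

Given a study of brain blocks, per-piece stimulus feature streams and
per-excerpt cursor tracks, the pipeline:

1. PCA-reduces and fits a Gaussian HMM to the brain blocks, decodes state
   paths, and computes per-block and condition-averaged state metrics;
2. fits a second HMM to the z-scored stimulus features and keeps state
   fractional occupancy per piece (the stimulus sampling rate is too low
   for meaningful lifetimes or visit counts);
3. assigns cursor samples to quadrant states and computes the same metric
   family;
4. runs the latent-variable analysis suite: between-task mean-centred PLS
   on each brain metric and on vectorized transition probabilities;
   within-task behavioural PLS linking brain metrics and transitions to
   cursor metrics; brain x stimulus and behaviour x stimulus correlation
   analyses (including the category-averaged contrast between context-free
   and context-dependent stimulus states); and a tri-modal behavioural PLS
   against neutral-quadrant behaviour;
5. optionally assesses fit stability across repeated HMM runs.

Everything is driven by one seeded configuration; identical configurations
give bit-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import hmm as hm
from . import metrics as mx
from . import pls as pl
from . import stability as stb
from . import synth
from .datasets import StudyDataset


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis suite.

    Defaults mirror the emulated study design: a 12-state brain model and a
    5-state stimulus model, 90% PCA variance, 256 Hz working rate, 500
    permutations and 100 bootstrap estimations per PLS.  Stimulus states
    1–3 are grouped as context-free (acoustic) and 4–5 as
    context-dependent (structural).
    """

    K_brain: int = 12
    K_music: int = 5
    variance_fraction: float = 0.9
    resample_hz: float = 256.0
    n_perm: int = 500
    n_boot: int = 100
    n_restarts: int = 2
    stability_runs: int = 0  # 0 skips the stability stage
    seed: int = 0
    music_category_map: dict[int, str] = field(
        default_factory=lambda: {1: "context_free", 2: "context_free",
                                 3: "context_free", 4: "context_dependent",
                                 5: "context_dependent"}
    )
    quadrant_labels: dict[int, str] = field(
        default_factory=lambda: {1: "Q1", 2: "Q2", 3: "Q3", 4: "Q4", 5: "neutral"}
    )

    def __post_init__(self) -> None:
        states = sorted(self.music_category_map)
        if states != list(range(1, self.K_music + 1)):
            raise ValueError(
                "music_category_map must cover every music state exactly once"
            )

    def categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for k in sorted(self.music_category_map):
            seen.setdefault(self.music_category_map[k], None)
        return list(seen)

    # -------------------------------------------------------------- YAML

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "K_brain": self.K_brain,
            "K_music": self.K_music,
            "variance_fraction": self.variance_fraction,
            "resample_hz": self.resample_hz,
            "n_perm": self.n_perm,
            "n_boot": self.n_boot,
            "n_restarts": self.n_restarts,
            "stability_runs": self.stability_runs,
            "seed": self.seed,
            "music_category_map": {int(k): v for k, v in self.music_category_map.items()},
            "quadrant_labels": {int(k): v for k, v in self.quadrant_labels.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        payload = yaml.safe_load(Path(path).read_text())
        for key in ("music_category_map", "quadrant_labels"):
            if key in payload:
                payload[key] = {int(k): v for k, v in payload[key].items()}
        return cls(**payload)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                k: (sorted(v.items()) if isinstance(v, dict) else v)
                for k, v in self.__dict__.items()
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def demo_study_config(seed: int = 0) -> synth.SynthStudyConfig:
    """A reduced study small enough for interactive runs and tests."""
    return synth.SynthStudyConfig(
        n_participants=6,
        n_excerpts_control=3,
        n_excerpts_experiment=3,
        n_rest_blocks=1,
        n_channels=10,
        sample_rate=32.0,
        block_duration=8.0,
        K_true=3,
        separation=6.0,
        seed=seed,
    )


def demo_analysis_config(seed: int = 0, **overrides) -> AnalysisConfig:
    """Analysis settings matched to :func:`demo_study_config` scale."""
    defaults = dict(
        K_brain=3,
        K_music=5,
        variance_fraction=0.9,
        resample_hz=32.0,
        n_perm=200,
        n_boot=50,
        n_restarts=1,
        stability_runs=0,
        seed=seed,
        music_category_map={1: "context_free", 2: "context_free", 3: "context_free",
                            4: "context_dependent", 5: "context_dependent"},
    )
    defaults.update(overrides)
    return AnalysisConfig(**defaults)


# --------------------------------------------------------------------------
# stacking helpers


def _stack_condition_matrices(
    cms: dict[str, mx.ConditionMatrix], conditions: list[str] | None = None
):
    """Stack per-condition participant matrices into one labelled table.

    Returns (X DataFrame, condition labels, participant labels).  Columns
    containing NaN anywhere (undefined transition rows or lifetimes) are
    dropped with a warning so the SVD stays defined.
    """
    if conditions is None:
        conditions = list(cms)
    frames, labels, parts = [], [], []
    for c in conditions:
        df = cms[c].values
        frames.append(df)
        labels.extend([c] * len(df))
        parts.extend(df.index.tolist())
    X = pd.concat(frames, axis=0)
    bad = X.columns[X.isna().any(axis=0)]
    if len(bad):
        warnings.warn(
            f"dropping {len(bad)} columns with undefined entries", stacklevel=2
        )
        X = X.drop(columns=bad)
    return X, np.asarray(labels), np.asarray(parts, dtype=object)


def _drop_nan_columns(df: pd.DataFrame) -> pd.DataFrame:
    bad = df.columns[df.isna().any(axis=0)]
    if len(bad):
        warnings.warn(
            f"dropping {len(bad)} columns with undefined entries", stacklevel=2
        )
        df = df.drop(columns=bad)
    return df


def _spawn_seed(master: np.random.Generator) -> int:
    return int(master.integers(2**31 - 1))


# --------------------------------------------------------------------------
# analysis families


def run_between_task(
    cond_matrices: dict[str, dict[str, mx.ConditionMatrix]],
    config: AnalysisConfig,
    seed: int | None = None,
) -> dict[str, pl.PLSResult]:
    """Between-task mean-centred PLS per metric, plus music-only follow-ups.

    One decomposition per scalar metric (fo, visits, lifetimes) and one on
    the vectorized transition probabilities, across all conditions present;
    follow-up contrasts between the two music conditions only.
    """
    master = np.random.default_rng(seed if seed is not None else config.seed)
    out: dict[str, pl.PLSResult] = {}
    conditions = list(next(iter(cond_matrices.values())))
    if len(conditions) < 2:
        raise ValueError("between-task analysis needs >= 2 conditions")
    music_conditions = [c for c in conditions if c in ("control", "experiment")]
    for metric in ("fo", "visits", "lifetimes", "transition"):
        X, labels, parts = _stack_condition_matrices(cond_matrices[metric], conditions)
        out[metric] = pl.mean_centered_pls(
            X, labels,
            n_perm=config.n_perm, n_boot=config.n_boot,
            seed=_spawn_seed(master), participants=parts,
        )
        if len(music_conditions) == 2 and len(conditions) > 2:
            Xm, lm, pm = _stack_condition_matrices(
                cond_matrices[metric], music_conditions
            )
            out[f"{metric}_music_only"] = pl.mean_centered_pls(
                Xm, lm,
                n_perm=config.n_perm, n_boot=config.n_boot,
                seed=_spawn_seed(master), participants=pm,
            )
    return out


def run_within_task_behavioral(
    brain_matrices: dict[str, dict[str, mx.ConditionMatrix]],
    mouse_matrices: dict[str, dict[str, mx.ConditionMatrix]],
    config: AnalysisConfig,
    seed: int | None = None,
) -> dict[str, pl.PLSResult]:
    """Per-condition behavioural PLS linking brain metrics to cursor metrics.

    For each music condition: one analysis pairing the concatenated brain
    metric columns (visits | lifetimes | fo) with the concatenated cursor
    metric columns, and three analyses pairing vectorized brain transition
    probabilities with each cursor metric separately.
    """
    master = np.random.default_rng(seed if seed is not None else config.seed)
    out: dict[str, pl.PLSResult] = {}
    conditions = [c for c in next(iter(mouse_matrices.values())) if c != "rest"]
    for cond in conditions:
        brain_parts = brain_matrices["fo"][cond].values.index
        mouse_parts = mouse_matrices["fo"][cond].values.index
        if not brain_parts.equals(mouse_parts):
            missing = sorted(set(brain_parts) ^ set(mouse_parts))
            raise ValueError(f"participant mismatch in {cond!r}: {missing}")
        X = pd.concat(
            [brain_matrices[m][cond].values for m in ("visits", "lifetimes", "fo")],
            axis=1,
        )
        Y = pd.concat(
            [mouse_matrices[m][cond].values for m in ("fo", "visits", "lifetimes")],
            axis=1,
        )
        X, Y = _drop_nan_columns(X), _drop_nan_columns(Y)
        out[f"{cond}:metrics"] = pl.behavioral_pls(
            X, Y, ["all"] * len(X),
            n_perm=config.n_perm, n_boot=config.n_boot,
            seed=_spawn_seed(master), participants=np.asarray(brain_parts, object),
        )
        T = _drop_nan_columns(brain_matrices["transition"][cond].values)
        for mmetric in ("fo", "visits", "lifetimes"):
            Ym = _drop_nan_columns(mouse_matrices[mmetric][cond].values)
            out[f"{cond}:transitions_x_mouse_{mmetric}"] = pl.behavioral_pls(
                T, Ym, ["all"] * len(T),
                n_perm=config.n_perm, n_boot=config.n_boot,
                seed=_spawn_seed(master), participants=np.asarray(brain_parts, object),
            )
    return out


def _per_excerpt_brain_matrices(
    metric_sets: list[mx.StateMetricSet], condition: str, K: int
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], list[str], list[str]]:
    """Per participant: excerpts x (3K) brain metric matrix and excerpts x K^2
    transition-vector matrix, in a shared excerpt order."""
    sets = [m for m in metric_sets if m.condition == condition and m.excerpt_id]
    excerpts = sorted({m.excerpt_id for m in sets})
    participants = sorted({m.participant for m in sets})
    by_pe = {(m.participant, m.excerpt_id): m for m in sets}
    A: dict[str, np.ndarray] = {}
    TV: dict[str, np.ndarray] = {}
    for p in participants:
        rows, trows = [], []
        for e in excerpts:
            m = by_pe[(p, e)]
            life = np.where(m.visits > 0, m.lifetimes, 0.0)
            rows.append(np.concatenate([m.visits, life, m.fo]))
            trows.append(mx.vectorize_transitions(m.transition))
        A[p] = np.asarray(rows)
        TV[p] = np.asarray(trows)
    names = (
        [f"visits_state{k + 1:02d}" for k in range(K)]
        + [f"lifetimes_state{k + 1:02d}" for k in range(K)]
        + [f"fo_state{k + 1:02d}" for k in range(K)]
    )
    return A, TV, excerpts, names


def _music_fo_matrix(
    music_fo: dict[str, np.ndarray], excerpts: list[str]
) -> np.ndarray:
    return np.asarray([music_fo[e] for e in excerpts])


def run_brain_stimulus(
    metric_sets: list[mx.StateMetricSet],
    music_fo: dict[str, np.ndarray],
    config: AnalysisConfig,
    seed: int | None = None,
) -> dict[str, pl.PLSResult]:
    """Brain x stimulus correlation analyses.

    Within each participant and condition, brain metrics per excerpt are
    correlated with stimulus-state fractional occupancy across excerpts;
    the participant-row correlation blocks feed a between-task mean-centred
    PLS.  The same construction on vectorized per-excerpt transition
    probabilities gives the transition-correlation analysis, and averaging
    those correlations within stimulus-state categories gives the
    context-free vs context-dependent contrast (two K x K correlation
    matrices per participant per condition).
    """
    master = np.random.default_rng(seed if seed is not None else config.seed)
    K = metric_sets[0].K
    Km = config.K_music
    conditions = [
        c for c in ("control", "experiment")
        if any(m.condition == c and m.excerpt_id for m in metric_sets)
    ]
    out: dict[str, pl.PLSResult] = {}
    metric_frames, trans_frames, labels, parts = [], [], [], []
    for cond in conditions:
        A, TV, excerpts, names = _per_excerpt_brain_matrices(metric_sets, cond, K)
        if len(excerpts) < 3:
            raise ValueError(f"condition {cond!r} has fewer than 3 excerpts")
        B = _music_fo_matrix(music_fo, excerpts)
        mus_names = [f"mirfo_state{k + 1:02d}" for k in range(Km)]
        Bmap = {p: B for p in A}
        metric_frames.append(
            mx.correlate_blocks(A, Bmap, a_names=names, b_names=mus_names)
        )
        tnames = [f"trans_{j + 1:02d}_{k + 1:02d}" for j in range(K) for k in range(K)]
        trans_frames.append(
            mx.correlate_blocks(TV, Bmap, a_names=tnames, b_names=mus_names)
        )
        labels.extend([cond] * len(metric_frames[-1]))
        parts.extend(metric_frames[-1].index.tolist())

    Xm = _drop_nan_columns(pd.concat(metric_frames, axis=0))
    Xt = _drop_nan_columns(pd.concat(trans_frames, axis=0))
    labels_arr = np.asarray(labels)
    parts_arr = np.asarray(parts, dtype=object)
    if len(conditions) >= 2:
        out["metrics_corr_between_task"] = pl.mean_centered_pls(
            Xm, labels_arr, n_perm=config.n_perm, n_boot=config.n_boot,
            seed=_spawn_seed(master), participants=parts_arr,
        )
        out["transition_corr_between_task"] = pl.mean_centered_pls(
            Xt, labels_arr, n_perm=config.n_perm, n_boot=config.n_boot,
            seed=_spawn_seed(master), participants=parts_arr,
        )

    # category-averaged transition correlations: context-free vs -dependent
    cat_rows, cat_labels, cat_parts = [], [], []
    categories = config.categories()
    state_cats = [config.music_category_map[k + 1] for k in range(Km)]
    full = pd.concat(trans_frames, axis=0)
    arr = full.to_numpy().reshape(len(full), -1, Km)  # rows x K^2 x Km
    for cat in categories:
        cols = [i for i, c in enumerate(state_cats) if c == cat]
        avg = np.nanmean(arr[:, :, cols], axis=2)
        cat_rows.append(avg)
        cat_labels.extend(
            [f"{l}:{cat}" for l in labels_arr]
        )
        cat_parts.extend(parts_arr.tolist())
    Xc = pd.DataFrame(
        np.vstack(cat_rows),
        columns=[f"trans_{j + 1:02d}_{k + 1:02d}" for j in range(K) for k in range(K)],
    )
    Xc = _drop_nan_columns(Xc)
    out["category_averaged"] = pl.mean_centered_pls(
        Xc, np.asarray(cat_labels), n_perm=config.n_perm, n_boot=config.n_boot,
        seed=_spawn_seed(master), participants=np.asarray(cat_parts, dtype=object),
    )
    # stash the transition-correlation block for the tri-modal analysis
    out["transition_corr_between_task_block"] = (Xt, labels_arr, parts_arr)  # type: ignore[assignment]
    return out


def _per_excerpt_mouse_matrices(
    mouse_sets: list[mx.StateMetricSet], condition: str
) -> tuple[dict[str, np.ndarray], list[str], list[str]]:
    sets = [m for m in mouse_sets if m.condition == condition and m.excerpt_id]
    excerpts = sorted({m.excerpt_id for m in sets})
    participants = sorted({m.participant for m in sets})
    by_pe = {(m.participant, m.excerpt_id): m for m in sets}
    A: dict[str, np.ndarray] = {}
    for p in participants:
        rows = []
        for e in excerpts:
            m = by_pe[(p, e)]
            life = np.where(m.visits > 0, m.lifetimes, 0.0)
            rows.append(np.concatenate([m.fo, life]))
        A[p] = np.asarray(rows)
    names = [f"mousefo_q{k}" for k in range(1, 6)] + [
        f"mouselt_q{k}" for k in range(1, 6)
    ]
    return A, excerpts, names


def run_behavior_stimulus(
    mouse_sets: list[mx.StateMetricSet],
    music_fo: dict[str, np.ndarray],
    config: AnalysisConfig,
    seed: int | None = None,
) -> dict[str, pl.PLSResult]:
    """Behaviour x stimulus correlation analyses.

    Cursor fractional occupancy and lifetimes per excerpt are correlated
    with stimulus-state occupancy across excerpts, then contrasted between
    tasks by mean-centred PLS; the follow-up averages the correlations over
    cursor states within each stimulus state before the contrast.
    """
    master = np.random.default_rng(seed if seed is not None else config.seed)
    Km = config.K_music
    conditions = [
        c for c in ("control", "experiment")
        if any(m.condition == c and m.excerpt_id for m in mouse_sets)
    ]
    frames, labels, parts = [], [], []
    for cond in conditions:
        A, excerpts, names = _per_excerpt_mouse_matrices(mouse_sets, cond)
        if len(excerpts) < 3:
            raise ValueError(f"condition {cond!r} has fewer than 3 excerpts")
        B = _music_fo_matrix(music_fo, excerpts)
        mus_names = [f"mirfo_state{k + 1:02d}" for k in range(Km)]
        frames.append(
            mx.correlate_blocks(
                A, {p: B for p in A}, a_names=names, b_names=mus_names
            )
        )
        labels.extend([cond] * len(frames[-1]))
        parts.extend(frames[-1].index.tolist())
    X = pd.concat(frames, axis=0)
    labels_arr = np.asarray(labels)
    parts_arr = np.asarray(parts, dtype=object)
    out: dict[str, pl.PLSResult] = {}
    out["corr_between_task"] = pl.mean_centered_pls(
        _drop_nan_columns(X), labels_arr,
        n_perm=config.n_perm, n_boot=config.n_boot,
        seed=_spawn_seed(master), participants=parts_arr,
    )
    # follow-up: average over the cursor-state axis per stimulus state and metric
    arr = X.to_numpy().reshape(len(X), 2, 5, Km)  # rows x metric x quadrant x music
    avg = np.nanmean(arr, axis=2).reshape(len(X), 2 * Km)
    cols = [f"{m}_avg*mirfo_state{k + 1:02d}" for m in ("fo", "lt") for k in range(Km)]
    out["corr_averaged_followup"] = pl.mean_centered_pls(
        _drop_nan_columns(pd.DataFrame(avg, columns=cols)), labels_arr,
        n_perm=config.n_perm, n_boot=config.n_boot,
        seed=_spawn_seed(master), participants=parts_arr,
    )
    return out


def run_tri_modal(
    trans_corr_block: pd.DataFrame,
    labels: np.ndarray,
    participants: np.ndarray,
    mouse_matrices: dict[str, dict[str, mx.ConditionMatrix]],
    config: AnalysisConfig,
    seed: int | None = None,
) -> pl.PLSResult:
    """Behavioural PLS of stimulus-transition correlations vs neutral behaviour.

    The behaviour matrix has exactly two columns per condition — visits and
    lifetimes in the neutral (centre) cursor state, the only state
    comparable between the two rating tasks.
    """
    master = np.random.default_rng(seed if seed is not None else config.seed)
    rows = []
    for lab, p in zip(labels, participants):
        v = mouse_matrices["visits"][lab].values.loc[p, "visits_state05"]
        lt = mouse_matrices["lifetimes"][lab].values.loc[p, "lifetimes_state05"]
        rows.append([v, lt])
    Y = pd.DataFrame(rows, columns=["neutral_visits", "neutral_lifetimes"])
    Y = Y.fillna(0.0)  # a never-visited neutral state contributes no dwell time
    return pl.behavioral_pls(
        trans_corr_block, Y, labels,
        n_perm=config.n_perm, n_boot=config.n_boot,
        seed=_spawn_seed(master), participants=participants,
    )


# --------------------------------------------------------------------------
# full pipeline


@dataclass
class AnalysisReport:
    """All fitted models, metric tables and PLS results of one run."""

    config: AnalysisConfig
    study_config: synth.SynthStudyConfig
    brain_model: hm.GaussianHMMModel
    music_model: hm.GaussianHMMModel
    brain_matrices: dict[str, dict[str, mx.ConditionMatrix]]
    mouse_matrices: dict[str, dict[str, mx.ConditionMatrix]]
    music_fo: dict[str, np.ndarray]
    results: dict[str, pl.PLSResult]
    stability: stb.StabilityReport | None = None
    provenance: dict = field(default_factory=dict)

    def result_hash(self) -> str:
        """Deterministic digest of every numerical result (no timestamps)."""
        h = hashlib.sha256()
        h.update(self.config.config_hash().encode())
        for arr in (
            self.brain_model.transition,
            self.brain_model.means,
            self.music_model.transition,
        ):
            h.update(np.ascontiguousarray(arr).tobytes())
        for metric in sorted(self.brain_matrices):
            for cond in sorted(self.brain_matrices[metric]):
                h.update(
                    np.ascontiguousarray(
                        self.brain_matrices[metric][cond].values.to_numpy()
                    ).tobytes()
                )
        for key in sorted(self.results):
            r = self.results[key]
            h.update(key.encode())
            h.update(np.ascontiguousarray(r.singular_values).tobytes())
            h.update(np.ascontiguousarray(r.variable_saliences).tobytes())
            if r.perm_p is not None:
                h.update(np.ascontiguousarray(r.perm_p).tobytes())
            if r.bootstrap_ratios is not None:
                h.update(np.ascontiguousarray(r.bootstrap_ratios).tobytes())
        return h.hexdigest()

    def summary(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.results):
            r = self.results[key]
            rows.append(
                {
                    "analysis": key,
                    "mode": r.mode,
                    "n_lv": r.n_lv,
                    "sv1": r.singular_values[0] if r.n_lv else np.nan,
                    "p_lv1": (
                        r.perm_p[0]
                        if r.perm_p is not None and r.perm_p.size
                        else np.nan
                    ),
                }
            )
        return pd.DataFrame(rows)

    def write(self, directory: str | Path) -> Path:
        """Write CSV tables, the config and a markdown summary to a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(directory / "analysis.yaml")
        for metric in self.brain_matrices:
            for cond, cm in self.brain_matrices[metric].items():
                cm.to_csv(directory / f"brain_{metric}_{cond}.csv")
        for metric in self.mouse_matrices:
            for cond, cm in self.mouse_matrices[metric].items():
                cm.to_csv(directory / f"mouse_{metric}_{cond}.csv")
        sidecar = {
            "K_brain": self.config.K_brain,
            "K_music": self.config.K_music,
            "rate_hz": self.config.resample_hz,
            "transition_vectorization": "row-major",
            "lifetime_units": "samples",
        }
        (directory / "metadata.json").write_text(json.dumps(sidecar, indent=2))
        summary = self.summary()
        summary.to_csv(directory / "pls_summary.csv", index=False)
        lines = [
            "# Analysis report",
            "",
            f"- config hash: `{self.config.config_hash()}`",
            f"- result hash: `{self.result_hash()}`",
            f"- brain model: K={self.brain_model.K}, "
            f"fit score {self.brain_model.fit_score:.4f}",
            f"- stimulus model: K={self.music_model.K}, "
            f"fit score {self.music_model.fit_score:.4f}",
            "",
            summary.to_markdown(index=False),
        ]
        if self.stability is not None:
            lines.insert(
                -1,
                f"- stability: fit-score sd/|mean| = "
                f"{self.stability.relative_dispersion:.4f} over "
                f"{self.stability.fit_scores.size} runs",
            )
        (directory / "report.md").write_text("\n".join(lines) + "\n")
        return directory


def run_all(
    config: AnalysisConfig,
    study_config: synth.SynthStudyConfig | None = None,
    effect: synth.ConditionEffect | None = None,
    coupling: synth.MouseCoupling | None = None,
) -> AnalysisReport:
    """Generate a synthetic study and execute the full analysis suite.

    All randomness derives from ``config.seed`` (the study uses its own
    ``study_config.seed``), so two runs with identical configurations
    produce identical reports.
    """
    t0 = time.time()
    if study_config is None:
        study_config = demo_study_config(config.seed)
    master = np.random.default_rng(config.seed)

    # ---- synthetic inputs
    study, truth = synth.generate_brain_study(study_config, effect)
    n_pieces = study_config.n_excerpts_control + study_config.n_excerpts_experiment
    piece_ids = [f"ctrl{i + 1:02d}" for i in range(study_config.n_excerpts_control)] + [
        f"exp{i + 1:02d}" for i in range(study_config.n_excerpts_experiment)
    ]
    music = synth.generate_music_features(
        n_pieces=n_pieces,
        durations=40.0,
        seed=_spawn_seed(master),
        K=config.K_music,
        piece_ids=piece_ids,
    )
    tracks = synth.generate_mouse_tracks(
        study, coupling, seed=_spawn_seed(master), rate=10.0
    )

    # ---- brain: reduce, fit, decode, metrics
    blocks = study.matrices()
    if study_config.sample_rate != config.resample_hz:
        blocks = [
            hm.resample_rate(b, study_config.sample_rate, config.resample_hz)
            for b in blocks
        ]
    reduced, reduction = hm.pca_reduce_blocks(blocks, config.variance_fraction)
    brain_model = hm.fit_gaussian_hmm(
        reduced,
        K=config.K_brain,
        n_restarts=config.n_restarts,
        seed=_spawn_seed(master),
        reduction=reduction,
    )
    brain_sets = []
    for b, X in zip(study, reduced):
        path = hm.viterbi_decode(brain_model, X, block_id=b.block_id, rate=config.resample_hz)
        brain_sets.append(
            mx.compute_metrics(
                path, K=config.K_brain, rate=config.resample_hz,
                block_id=b.block_id, participant=b.participant,
                condition=b.condition, excerpt_id=b.excerpt_id,
            )
        )
    brain_matrices = mx.aggregate_by_condition(brain_sets)

    # ---- stimulus: z-score features, fit, per-piece occupancy
    feat = np.vstack([f.to_numpy() for f in music.features])
    mu, sd = feat.mean(axis=0), feat.std(axis=0)
    sd[sd == 0] = 1.0
    music_blocks = [(f.to_numpy() - mu) / sd for f in music.features]
    music_model = hm.fit_gaussian_hmm(
        music_blocks,
        K=config.K_music,
        n_restarts=config.n_restarts,
        seed=_spawn_seed(master),
    )
    music_fo: dict[str, np.ndarray] = {}
    for pid, Xp in zip(music.piece_ids, music_blocks):
        path = hm.viterbi_decode(music_model, Xp)
        music_fo[pid] = mx.fractional_occupancy(path.states, config.K_music)

    # ---- behaviour: quadrant states and metrics
    excerpt_condition = {
        b.excerpt_id: b.condition for b in study if b.excerpt_id is not None
    }
    mouse_sets = []
    for (pid, eid), track in tracks.items():
        qp = bhv.assign_mouse_states(
            track, excerpt_id=eid, participant_id=pid,
            condition=excerpt_condition[eid],
        )
        mouse_sets.append(bhv.behavior_metrics(qp))
    mouse_matrices = mx.aggregate_by_condition(mouse_sets)

    # ---- stability (optional)
    stability_report = None
    if config.stability_runs >= 2:
        stability_report = stb.stability_suite(
            reduced, K=config.K_brain, n_runs=config.stability_runs,
            seed=_spawn_seed(master),
        )

    # ---- analysis suite
    results: dict[str, pl.PLSResult] = {}
    for key, r in run_between_task(
        brain_matrices, config, seed=_spawn_seed(master)
    ).items():
        results[f"between_task:{key}"] = r
    for key, r in run_within_task_behavioral(
        brain_matrices, mouse_matrices, config, seed=_spawn_seed(master)
    ).items():
        results[f"within_task:{key}"] = r
    bs = run_brain_stimulus(brain_sets, music_fo, config, seed=_spawn_seed(master))
    trans_block = bs.pop("transition_corr_between_task_block")
    for key, r in bs.items():
        results[f"brain_stimulus:{key}"] = r
    for key, r in run_behavior_stimulus(
        mouse_sets, music_fo, config, seed=_spawn_seed(master)
    ).items():
        results[f"behavior_stimulus:{key}"] = r
    Xt, t_labels, t_parts = trans_block
    results["tri_modal"] = run_tri_modal(
        Xt, t_labels, t_parts, mouse_matrices, config, seed=_spawn_seed(master)
    )

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "study_seed": study_config.seed,
        "n_blocks": len(study),
        "elapsed_s": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return AnalysisReport(
        config=config,
        study_config=study_config,
        brain_model=brain_model,
        music_model=music_model,
        brain_matrices=brain_matrices,
        mouse_matrices=mouse_matrices,
        music_fo=music_fo,
        results=results,
        stability=stability_report,
        provenance=provenance,
    )
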