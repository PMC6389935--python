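"""Synthetic study-shaped data with known ground truth.

Emulates the structure of a constant-routine adipose biopsy study: a handful
of subjects, each sampled five times at roughly six-hour intervals on their
own melatonin-referenced (DLMO) time axis; a minority of probes carry a 24-h
cosinor signal with a bimodal peak-time distribution; subject-level baseline
offsets and additive log2-scale noise on top. Melatonin curves and a small
catalogue of flux-consistent toy metabolic networks give every downstream
stage a parameter-recovery surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .metabolic import MetabolicModel, Reaction

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_melatonin",
    "make_toy_metabolic_model",
    "TOY_MODEL_CATALOGUE",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic expression study.

    Defaults mirror the study design being emulated: 7 subjects x 5 biopsies
    at ~6-h spacing, ~2% rhythmic probes with peak times concentrated just
    before DLMO (evening) and ~9 h after it (morning).
    """

    n_subjects: int = 7
    n_timepoints: int = 5
    sampling_interval_h: float = 6.0
    #: half-width of the uniform jitter added to each sampling time (hours)
    sampling_jitter_h: float = 0.5
    #: range of the per-subject first-biopsy offset after DLMO (hours)
    sampling_start_range_h: tuple[float, float] = (2.0, 5.0)
    n_probes: int = 1000
    rhythmic_fraction: float = 0.02
    #: cosinor amplitude range for rhythmic probes (log2 units)
    amplitude_range: tuple[float, float] = (0.5, 2.0)
    #: circular means of the two peak-time modes, hours relative to DLMO
    peak_time_modes: tuple[float, float] = (-1.0, 9.0)
    #: wrapped-normal SDs of the two modes (hours)
    peak_time_sds: tuple[float, float] = (1.5, 1.5)
    #: mixture weight of the first (evening) mode
    peak_time_weight: float = 0.69
    subject_intercept_sd: float = 0.25
    noise_sd: float = 0.35
    #: "t" gives heavy-tailed noise for robustness checks
    noise_dist: str = "gaussian"
    noise_t_df: float = 3.0
    mesor_range: tuple[float, float] = (6.0, 12.0)
    trend_slope_sd: float = 0.01
    #: probability that a (probe, sample) cell is QC-flagged
    flag_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("n_subjects", self.n_subjects >= 1),
            ("n_timepoints", self.n_timepoints >= 1),
            ("sampling_interval_h", self.sampling_interval_h > 0),
            ("sampling_jitter_h", self.sampling_jitter_h >= 0),
            ("sampling_start_range_h",
             self.sampling_start_range_h[0] <= self.sampling_start_range_h[1]),
            ("n_probes", self.n_probes >= 1),
            ("rhythmic_fraction", 0.0 <= self.rhythmic_fraction <= 1.0),
            ("amplitude_range", 0 < self.amplitude_range[0] <= self.amplitude_range[1]),
            ("peak_time_sds", min(self.peak_time_sds) >= 0),
            ("peak_time_weight", 0.0 <= self.peak_time_weight <= 1.0),
            ("subject_intercept_sd", self.subject_intercept_sd >= 0),
            ("noise_sd", self.noise_sd >= 0),
            ("noise_dist", self.noise_dist in ("gaussian", "t")),
            ("mesor_range", self.mesor_range[0] <= self.mesor_range[1]),
            ("trend_slope_sd", self.trend_slope_sd >= 0),
            ("flag_prob", 0.0 <= self.flag_prob <= 1.0),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid SimulationConfig field: {name}")


@dataclass
class GroundTruth:
    """True generating parameters, one record per probe plus subject info.

    ``probes`` columns: probe_id, is_rhythmic, amplitude, peak_time_h, mesor,
    trend_slope. ``subjects`` columns: subject_id, dlmo_clock_time_h.
    ``intercepts`` is the probe x subject matrix of baseline offsets.
    """

    probes: pd.DataFrame
    subjects: pd.DataFrame
    intercepts: pd.DataFrame


def _wrap_to_half_period(x: np.ndarray | float, period: float = 24.0):
    """Wrap hours into [-period/2, period/2)."""
    return (np.asarray(x) + period / 2) % period - period / 2


def simulate_expression(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a probe x sample log2 expression matrix with ground truth.

    Each rhythmic probe follows

        y = mesor + slope * t + A * cos(2*pi*(t - phi)/24) + u_subject + eps

    on the subject's DLMO-referenced time axis t. Non-rhythmic probes have
    A = 0. Returns ``(expression, metadata, truth)`` where metadata has one
    row per sample: sample_id, subject_id, clock_time_h, time_rel_dlmo_h and
    a per-sample flag column list stored separately when ``flag_prob > 0``
    (see :func:`simulate_flags`).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    subj_ids = [f"S{i + 1:02d}" for i in range(cfg.n_subjects)]
    dlmo_clock = rng.uniform(20.5, 23.5, size=cfg.n_subjects)

    # Per-subject DLMO-referenced sampling grid: a subject-specific start
    # offset plus the nominal interval, with uniform jitter on every point.
    start = rng.uniform(*cfg.sampling_start_range_h, size=cfg.n_subjects)
    base = np.arange(cfg.n_timepoints) * cfg.sampling_interval_h
    jitter = rng.uniform(
        -cfg.sampling_jitter_h, cfg.sampling_jitter_h,
        size=(cfg.n_subjects, cfg.n_timepoints),
    )
    t_rel = start[:, None] + base[None, :] + jitter  # (subjects, timepoints)

    meta = pd.DataFrame(
        {
            "sample_id": [
                f"{s}_T{k + 1}" for s in subj_ids for k in range(cfg.n_timepoints)
            ],
            "subject_id": np.repeat(subj_ids, cfg.n_timepoints),
            "clock_time_h": (np.repeat(dlmo_clock, cfg.n_timepoints)
                             + t_rel.ravel()),
            "time_rel_dlmo_h": t_rel.ravel(),
        }
    )

    n = cfg.n_probes
    probe_ids = [f"P{i + 1:05d}" for i in range(n)]
    n_rhythmic = int(round(cfg.rhythmic_fraction * n))
    is_rhythmic = np.zeros(n, dtype=bool)
    is_rhythmic[:n_rhythmic] = True

    amplitude = np.zeros(n)
    amplitude[is_rhythmic] = rng.uniform(*cfg.amplitude_range, size=n_rhythmic)
    # bimodal wrapped-normal mixture of peak times
    mode = rng.random(n_rhythmic) < cfg.peak_time_weight
    mu = np.where(mode, cfg.peak_time_modes[0], cfg.peak_time_modes[1])
    sd = np.where(mode, cfg.peak_time_sds[0], cfg.peak_time_sds[1])
    peak = np.full(n, np.nan)
    peak[is_rhythmic] = _wrap_to_half_period(mu + sd * rng.standard_normal(n_rhythmic))

    mesor = rng.uniform(*cfg.mesor_range, size=n)
    slope = rng.normal(0.0, cfg.trend_slope_sd, size=n)
    intercepts = rng.normal(0.0, cfg.subject_intercept_sd, size=(n, cfg.n_subjects))

    t = t_rel.ravel()[None, :]  # (1, n_samples)
    cosine = np.where(
        is_rhythmic[:, None],
        amplitude[:, None] * np.cos(
            2 * np.pi * (t - np.nan_to_num(peak)[:, None]) / 24.0
        ),
        0.0,
    )
    subj_idx = np.repeat(np.arange(cfg.n_subjects), cfg.n_timepoints)
    values = (
        mesor[:, None]
        + slope[:, None] * t
        + cosine
        + intercepts[:, subj_idx]
    )
    if cfg.noise_sd > 0:
        if cfg.noise_dist == "t":
            df = cfg.noise_t_df
            scale = cfg.noise_sd / np.sqrt(df / (df - 2))
            values = values + scale * rng.standard_t(df, size=values.shape)
        else:
            values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)

    expr = pd.DataFrame(values, index=probe_ids, columns=meta["sample_id"])
    expr.index.name = "probe_id"

    truth = GroundTruth(
        probes=pd.DataFrame(
            {
                "probe_id": probe_ids,
                "is_rhythmic": is_rhythmic,
                "amplitude": amplitude,
                "peak_time_h": peak,
                "mesor": mesor,
                "trend_slope": slope,
            }
        ),
        subjects=pd.DataFrame(
            {"subject_id": subj_ids, "dlmo_clock_time_h": dlmo_clock}
        ),
        intercepts=pd.DataFrame(intercepts, index=probe_ids, columns=subj_ids),
    )
    return expr, meta, truth


def simulate_flags(config: SimulationConfig, expr: pd.DataFrame) -> pd.DataFrame:
    """Bernoulli per-cell QC flag matrix matching ``expr`` (seeded)."""
    rng = np.random.default_rng(config.seed + 1)
    flags = rng.random(expr.shape) < config.flag_prob
    return pd.DataFrame(flags, index=expr.index, columns=expr.columns)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def simulate_melatonin(
    true_dlmo_times: np.ndarray,
    seed: int | None = None,
    *,
    baseline: float = 2.0,
    peak: float = 60.0,
    noise_sd: float = 0.0,
    rise_scale_h: float = 1.2,
    fall_midpoint_offset_h: float = 12.0,
    fall_scale_h: float = 1.5,
    start_clock_h: float = 12.0,
    duration_h: float = 36.0,
    interval_h: float = 1.0,
) -> pd.DataFrame:
    """Hourly plasma melatonin profiles with a known onset per subject.

    Each profile is a flat daytime baseline, a sigmoidal evening rise to a
    nocturnal plateau near ``peak`` pg/ml, and a morning decline. The rise
    midpoint is calibrated (fixed-point, three iterations) so that the
    continuous curve crosses 25% of its own maximum exactly at the subject's
    true DLMO; the threshold-crossing estimator applied to the noise-free
    hourly samples therefore recovers the true onset to within interpolation
    error. Returns a long-format frame: subject_id, clock_time_h,
    concentration_pg_ml. Clock times are continuous hours from study start
    (may exceed 24).
    """
    true_dlmo_times = np.asarray(true_dlmo_times, dtype=float)
    rng = np.random.default_rng(seed)
    grid = start_clock_h + np.arange(0.0, duration_h + 1e-9, interval_h)
    fine = start_clock_h + np.linspace(0.0, duration_h, 2000)

    rows = []
    for i, dlmo in enumerate(true_dlmo_times):
        t_fall = dlmo + fall_midpoint_offset_h

        def curve(t, t_rise):
            return baseline + (peak - baseline) * _logistic(
                (t - t_rise) / rise_scale_h
            ) * _logistic((t_fall - t) / fall_scale_h)

        if peak > baseline:
            # calibrate rise midpoint: 25% of max crosses exactly at dlmo
            t_rise = dlmo
            for _ in range(3):
                m = curve(fine, t_rise).max()
                fall_at = _logistic((t_fall - dlmo) / fall_scale_h)
                lstar = (0.25 * m - baseline) / ((peak - baseline) * fall_at)
                lstar = np.clip(lstar, 1e-9, 1 - 1e-9)
                t_rise = dlmo - rise_scale_h * np.log(lstar / (1 - lstar))
            conc = curve(grid, t_rise)
        else:
            conc = np.full_like(grid, baseline)
        if noise_sd > 0:
            conc = np.maximum(conc + rng.normal(0, noise_sd, size=conc.shape), 0.0)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": f"S{i + 1:02d}",
                    "clock_time_h": grid,
                    "concentration_pg_ml": conc,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _rxn(id, stoich, gpr="", lb=0.0, ub=1000.0, subsystem="", exchange=False):
    return Reaction(
        id=id, stoich=dict(stoich), lb=lb, ub=ub, gpr=gpr,
        subsystem=subsystem, exchange=exchange,
    )


def _chain3() -> MetabolicModel:
    """Uptake -> R1 -> R2 -> excretion; steady state forces equal flux."""
    return MetabolicModel(
        id="chain3",
        metabolites=["A", "B", "C"],
        genes=["g1", "g2"],
        reactions=[
            _rxn("EX_A", {"A": 1.0}, exchange=True, lb=-1000.0),
            _rxn("R1", {"A": -1.0, "B": 1.0}, gpr="g1", subsystem="chain"),
            _rxn("R2", {"B": -1.0, "C": 1.0}, gpr="g2", subsystem="chain"),
            _rxn("EX_C", {"C": -1.0}, exchange=True, lb=-1000.0),
        ],
    )


def _chain5() -> MetabolicModel:
    """Longer chain with an AND complex and an OR isoenzyme pair."""
    return MetabolicModel(
        id="chain5",
        metabolites=["A", "B", "C", "D"],
        genes=["g1", "g2", "g3", "g4", "g5"],
        reactions=[
            _rxn("EX_A", {"A": 1.0}, exchange=True, lb=-1000.0),
            _rxn("R1", {"A": -1.0, "B": 1.0}, gpr="g1 and g2", subsystem="upper"),
            _rxn("R2", {"B": -1.0, "C": 1.0}, gpr="g3 or g4", subsystem="upper"),
            _rxn("R3", {"C": -1.0, "D": 1.0}, gpr="g5", subsystem="lower"),
            _rxn("EX_D", {"D": -1.0}, exchange=True, lb=-1000.0),
        ],
    )


def _branch() -> MetabolicModel:
    """One input feeding two competing outputs."""
    return MetabolicModel(
        id="branch",
        metabolites=["A", "B", "C"],
        genes=["g1", "g2"],
        reactions=[
            _rxn("EX_A", {"A": 1.0}, exchange=True, lb=-1000.0),
            _rxn("R1", {"A": -1.0, "B": 1.0}, gpr="g1", subsystem="left"),
            _rxn("R2", {"A": -1.0, "C": 1.0}, gpr="g2", subsystem="right"),
            _rxn("EX_B", {"B": -1.0}, exchange=True, lb=-1000.0),
            _rxn("EX_C", {"C": -1.0}, exchange=True, lb=-1000.0),
        ],
    )


def _loop() -> MetabolicModel:
    """Internal cycle A->B->C->A plus a throughput path with exchanges."""
    return MetabolicModel(
        id="loop",
        metabolites=["A", "B", "C"],
        genes=["g1", "g2", "g3", "g4"],
        reactions=[
            _rxn("EX_A", {"A": 1.0}, exchange=True, lb=-1000.0),
            _rxn("R1", {"A": -1.0, "B": 1.0}, gpr="g1", subsystem="cycle"),
            _rxn("R2", {"B": -1.0, "C": 1.0}, gpr="g2", subsystem="cycle"),
            _rxn("R3", {"C": -1.0, "A": 1.0}, gpr="g3", subsystem="cycle",
                 lb=-1000.0),
            _rxn("R4", {"B": -1.0, "C": 1.0}, gpr="g4", subsystem="bypass"),
            _rxn("EX_C", {"C": -1.0}, exchange=True, lb=-1000.0),
        ],
    )


def _diamond() -> MetabolicModel:
    """Two parallel two-step routes from A to D (redundant pathways)."""
    return MetabolicModel(
        id="diamond",
        metabolites=["A", "B", "C", "D"],
        genes=["g1", "g2", "g3", "g4"],
        reactions=[
            _rxn("EX_A", {"A": 1.0}, exchange=True, lb=-1000.0),
            _rxn("R1", {"A": -1.0, "B": 1.0}, gpr="g1", subsystem="top"),
            _rxn("R2", {"B": -1.0, "D": 1.0}, gpr="g2", subsystem="top"),
            _rxn("R3", {"A": -1.0, "C": 1.0}, gpr="g3", subsystem="bottom"),
            _rxn("R4", {"C": -1.0, "D": 1.0}, gpr="g4", subsystem="bottom"),
            _rxn("EX_D", {"D": -1.0}, exchange=True, lb=-1000.0),
        ],
    )


TOY_MODEL_CATALOGUE = {
    "chain3": _chain3,
    "chain5": _chain5,
    "branch": _branch,
    "loop": _loop,
    "diamond": _diamond,
}


def make_toy_metabolic_model(name: str) -> MetabolicModel:
    """Build a named toy network from the fixed catalogue.

    All catalogue models are stoichiometrically consistent (a feasible
    nonzero steady-state flux exists) and every non-exchange reaction
    carries a GPR rule.
    """
    try:
        factory = TOY_MODEL_CATALOGUE[name]
    except KeyError:
        raise ValueError(
            f"unknown toy model {name!r}; available: "
            f"{sorted(TOY_MODEL_CATALOGUE)}"
        ) from None
    model = factory()
    model.validate()
    return model


# ---------------------------------------------------------------------------
# writers

def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t")


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def write_melatonin_csv(mel: pd.DataFrame, path) -> None:
    mel.to_csv(path, index=False)


def write_ground_truth_tsv(truth: GroundTruth, path) -> None:
    truth.probes.to_csv(path, sep="\t", index=False)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
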