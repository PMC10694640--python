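"""Synthetic cohorts: week-long step-event streams with known ground truth.

The generator emulates what a week of ambulatory monitoring of an older
adult yields after step detection: each day a participant produces a
handful of walking bouts whose lengths straddle the 200-step analysis
threshold; within a bout, stride intervals follow a long-range-correlated
process (fractional Gaussian noise with participant-specific mean,
coefficient of variation and Hurst exponent, optionally mixed with a white
component), and each stride splits into two step intervals with a small
left/right asymmetry plus step-timing jitter that cancels within the
stride pair. Twelve-month fall counts are then drawn from a negative
binomial model whose log rate is a linear function of the participants'
standardized *true* gait parameters, so every downstream stage can be
checked against known coefficients.

"True" values of derived parameters (CoV, DFA, SampEn, cadence) are
defined as the estimator values on long seeded reference realizations of
the participant's interval process — the population quantity the bout
medians estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .parameters import dfa_exponent, sample_entropy
from .streams import OutcomeRecord, StepEventSeries

__all__ = [
    "SimConfig",
    "fractional_gaussian_noise",
    "gen_stride_process",
    "gen_participant_stream",
    "gen_outcomes",
    "simulate_cohort",
    "parameter_cohort",
    "DIRECTION_BETA",
    "DIRECTION_CORR",
    "TRUTH_PARAM_NAMES",
]

#: Sign pattern of the published six-parameter model: risk rises with more
#: steps, faster cadence and higher stride-time variability, and falls with
#: higher complexity. Magnitudes are generator defaults on the standardized
#: scale, chosen to give a realistic spread of annual fall rates.
DIRECTION_BETA: dict[str, float] = {
    "total_steps": 0.4,
    "cadence": 0.6,
    "cov_stride_time": 0.5,
    "dfa_step": -0.8,
    "sampen_step": -0.6,
    "sampen_stride": -0.6,
}

#: Plausible correlation structure for parameter-level cohorts: the three
#: complexity measures share variance, faster walkers are less variable,
#: and more active participants walk slightly faster.
DIRECTION_CORR_NAMES = (
    "total_steps",
    "cadence",
    "cov_stride_time",
    "dfa_step",
    "sampen_step",
    "sampen_stride",
)
DIRECTION_CORR = np.array(
    [
        [1.00, 0.40, 0.00, 0.00, 0.00, 0.00],
        [0.40, 1.00, -0.45, 0.00, 0.00, 0.00],
        [0.00, -0.45, 1.00, 0.00, 0.00, 0.00],
        [0.00, 0.00, 0.00, 1.00, 0.50, 0.50],
        [0.00, 0.00, 0.00, 0.50, 1.00, 0.50],
        [0.00, 0.00, 0.00, 0.50, 0.50, 1.00],
    ]
)

TRUTH_PARAM_NAMES = (
    "n_bouts",
    "total_steps",
    "avg_steps_per_bout",
    "cadence",
    "mean_step_time",
    "mean_stride_time",
    "cov_step_time",
    "cov_stride_time",
    "dfa_step",
    "dfa_stride",
    "sampen_step",
    "sampen_stride",
)


class SimConfigError(ValueError):
    """Invalid generative configuration."""


@dataclass
class SimConfig:
    """Full generative specification of a synthetic cohort.

    Population defaults describe community-dwelling older adults: stride
    time ~1.1 s, stride-time CoV a few percent, persistent stride dynamics
    (Hurst ~0.75), about two walking bouts per waking day of which most of
    the longer ones clear the 200-step threshold.
    """

    n_participants: int = 300
    days: int = 7
    seed: int = 0
    # daily bout structure (per-participant rates drawn once)
    bouts_per_day_mean: float = 2.0
    bouts_per_day_shape: float = 4.0  # gamma shape of the participant rate
    p_long_bout_min: float = 0.2
    p_long_bout_max: float = 0.9
    long_bout_mean: float = 320.0
    long_bout_sd: float = 80.0
    short_bout_mean: float = 80.0
    short_bout_sd: float = 40.0
    # stride-interval process
    stride_mean_mean: float = 1.10
    stride_mean_sd: float = 0.08
    stride_cov_mean: float = 0.035
    stride_cov_sd: float = 0.012
    hurst_mean: float = 0.75
    hurst_sd: float = 0.08
    step_asymmetry: float = 0.02
    step_jitter_mean_s: float = 0.010
    step_jitter_sd_s: float = 0.005
    white_frac_max: float = 0.4
    # outcome model on standardized true parameters
    true_beta: dict[str, float] = field(default_factory=lambda: dict(DIRECTION_BETA))
    nb_intercept: float = math.log(0.8)
    nb_dispersion: float = 1.0
    group_beta: float = 0.0
    # bout placement
    waking_start_h: float = 7.0
    waking_end_h: float = 22.0
    min_interbout_gap_s: float = 60.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimConfigError("seed is mandatory")
        if not (0 < self.hurst_mean < 1):
            raise SimConfigError("hurst_mean must lie in (0, 1)")
        for name in ("stride_mean_mean", "stride_cov_mean", "long_bout_mean"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        unknown = set(self.true_beta) - set(TRUTH_PARAM_NAMES)
        if unknown:
            raise SimConfigError(f"true_beta names without true values: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def fractional_gaussian_noise(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact unit-variance fGn of length n by circulant embedding.

    The autocovariance gamma(k) = 0.5(|k+1|^2H - 2|k|^2H + |k-1|^2H) is
    embedded in a circulant matrix whose eigenvalues are obtained by FFT
    (Davies-Harte); eigenvalues are provably non-negative for fGn, so only
    round-off is clipped.
    """
    if not (0 < hurst < 1):
        raise SimConfigError(f"hurst must lie in (0, 1), got {hurst}")
    if n < 1:
        raise SimConfigError("n must be positive")
    if n == 1:
        return rng.standard_normal(1)
    k = np.arange(n, dtype=float)
    h2 = 2 * hurst
    gamma = 0.5 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8:
        raise SimConfigError("circulant embedding produced negative eigenvalues")
    lam = np.clip(lam, 0.0, None)
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    # real part of the complex sample carries covariance C/2; rescale by sqrt(2)
    x = np.fft.fft(np.sqrt(lam / m) * z)
    return x.real[:n]


def gen_stride_process(
    n: int,
    mean_s: float,
    cov: float,
    hurst: float,
    rng: np.random.Generator,
    white_frac: float = 0.0,
) -> tuple[np.ndarray, int]:
    """Stride-interval sequence with target mean, CoV and Hurst exponent.

    The correlated component is exact fGn; ``white_frac`` of the variance
    is replaced by an independent white component (sensor/physiological
    noise) which lowers the effective long-range correlation. Intervals
    are truncated below at 0.2*mean to preserve positivity; the number of
    truncated values is returned alongside the sequence.
    """
    if mean_s <= 0 or cov < 0:
        raise SimConfigError("mean_s must be positive and cov non-negative")
    if not 0 <= white_frac <= 1:
        raise SimConfigError("white_frac must lie in [0, 1]")
    if cov == 0:
        return np.full(n, mean_s), 0
    noise = math.sqrt(1 - white_frac) * fractional_gaussian_noise(n, hurst, rng)
    if white_frac > 0:
        noise = noise + math.sqrt(white_frac) * rng.standard_normal(n)
    intervals = mean_s + cov * mean_s * noise
    floor = 0.2 * mean_s
    n_trunc = int(np.count_nonzero(intervals < floor))
    return np.maximum(intervals, floor), n_trunc


def _steps_from_strides(
    strides: np.ndarray, asymmetry: float, jitter_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Split each stride into two step intervals.

    A fixed asymmetry ratio models left/right differences; zero-sum jitter
    on the split point adds step-level irregularity that cancels exactly
    within each stride pair, so stride-level parameters are untouched.
    """
    eps = rng.normal(0.0, jitter_sd, size=strides.size) if jitter_sd > 0 else np.zeros(strides.size)
    first = (0.5 + asymmetry) * strides + eps
    second = (0.5 - asymmetry) * strides - eps
    steps = np.empty(2 * strides.size)
    steps[0::2] = first
    steps[1::2] = second
    return np.clip(steps, 0.05, 1.9)


@dataclass(frozen=True)
class ParticipantDials:
    """Per-participant generative parameters (one draw from the population)."""

    participant_id: str
    group: int
    stride_mean: float
    stride_cov: float
    hurst: float
    white_frac: float
    jitter_sd: float
    bouts_per_day: float
    p_long: float


def _draw_dials(config: SimConfig, i: int, rng: np.random.Generator) -> ParticipantDials:
    scale = config.bouts_per_day_mean / config.bouts_per_day_shape
    return ParticipantDials(
        participant_id=f"P{i + 1:04d}",
        group=int(rng.integers(0, 2)),
        stride_mean=float(np.clip(rng.normal(config.stride_mean_mean, config.stride_mean_sd), 0.6, 2.0)),
        stride_cov=float(np.clip(rng.normal(config.stride_cov_mean, config.stride_cov_sd), 0.005, 0.15)),
        hurst=float(np.clip(rng.normal(config.hurst_mean, config.hurst_sd), 0.05, 0.95)),
        white_frac=float(rng.uniform(0.0, config.white_frac_max)),
        jitter_sd=float(max(rng.normal(config.step_jitter_mean_s, config.step_jitter_sd_s), 0.0)),
        bouts_per_day=float(rng.gamma(config.bouts_per_day_shape, scale)),
        p_long=float(rng.uniform(config.p_long_bout_min, config.p_long_bout_max)),
    )


def _true_derived_parameters(
    dials: ParticipantDials,
    config: SimConfig,
    rng: np.random.Generator,
    n_ref_strides: int = 1200,
    window_steps: int = 200,
) -> dict[str, float]:
    """Estimator values on a long reference realization of the participant's process.

    Complexity values average the window estimator over consecutive
    199-step / 99-stride windows, mirroring the middle-200 convention the
    pipeline applies to real bouts.
    """
    strides, _ = gen_stride_process(
        n_ref_strides, dials.stride_mean, dials.stride_cov, dials.hurst, rng, dials.white_frac
    )
    steps = _steps_from_strides(strides, config.step_asymmetry, dials.jitter_sd, rng)
    out = {
        "cadence": 60.0 / float(steps.mean()),
        "mean_step_time": float(steps.mean()),
        "mean_stride_time": float(strides.mean()),
        "cov_step_time": float(steps.std(ddof=1) / steps.mean()),
        "cov_stride_time": float(strides.std(ddof=1) / strides.mean()),
    }
    w_step = window_steps - 1
    w_stride = (window_steps - 1) // 2
    dfa_s, dfa_t, se_s, se_t = [], [], [], []
    for start in range(0, steps.size - w_step + 1, w_step):
        win = steps[start : start + w_step]
        dfa_s.append(dfa_exponent(win))
        se_s.append(sample_entropy(win))
    for start in range(0, strides.size - w_stride + 1, w_stride):
        win = strides[start : start + w_stride]
        dfa_t.append(dfa_exponent(win))
        se_t.append(sample_entropy(win))
    out["dfa_step"] = float(np.nanmean(dfa_s))
    out["dfa_stride"] = float(np.nanmean(dfa_t))
    out["sampen_step"] = float(np.nanmean(se_s))
    out["sampen_stride"] = float(np.nanmean(se_t))
    return out


def gen_participant_stream(
    dials: ParticipantDials, config: SimConfig, rng: np.random.Generator
) -> tuple[StepEventSeries, dict[str, float]]:
    """One participant's week of step events plus their ground truth.

    Per day, a Poisson number of bouts with lengths drawn from a
    short/long mixture spanning the 200-step threshold; bouts are placed
    in waking hours with a minimum inter-bout gap. Returns the event
    series and a truth row (dials, realized kept-bout totals, true derived
    parameters).
    """
    day_s = 86400.0
    all_ts: list[np.ndarray] = []
    kept_lengths: list[int] = []
    for day in range(config.days):
        n_bouts = int(rng.poisson(dials.bouts_per_day))
        if n_bouts == 0:
            continue
        lengths = []
        for _ in range(n_bouts):
            if rng.uniform() < dials.p_long:
                n_steps = int(max(round(rng.normal(config.long_bout_mean, config.long_bout_sd)), 210))
            else:
                n_steps = int(np.clip(round(rng.normal(config.short_bout_mean, config.short_bout_sd)), 15, 200))
            lengths.append(n_steps)
        bouts = []
        for n_steps in lengths:
            n_strides = (n_steps - 1 + 1) // 2 + 1
            strides, _ = gen_stride_process(
                n_strides, dials.stride_mean, dials.stride_cov, dials.hurst, rng, dials.white_frac
            )
            steps = _steps_from_strides(strides, config.step_asymmetry, dials.jitter_sd, rng)
            rel = np.concatenate([[0.0], np.cumsum(steps[: n_steps - 1])])
            bouts.append(rel)
            if n_steps > 200:
                kept_lengths.append(n_steps)
        window_lo = day * day_s + config.waking_start_h * 3600.0
        window_hi = day * day_s + config.waking_end_h * 3600.0
        starts = np.sort(rng.uniform(window_lo, window_hi, size=len(bouts)))
        prev_end = -np.inf
        for start, rel in zip(starts, bouts):
            start = max(start, prev_end + config.min_interbout_gap_s)
            ts = start + rel
            all_ts.append(ts)
            prev_end = ts[-1]
    timestamps = np.concatenate(all_ts) if all_ts else np.empty(0)
    series = StepEventSeries(dials.participant_id, timestamps)
    truth: dict[str, float] = {
        "participant_id": dials.participant_id,
        "group": dials.group,
        "stride_mean": dials.stride_mean,
        "stride_cov": dials.stride_cov,
        "hurst": dials.hurst,
        "white_frac": dials.white_frac,
        "jitter_sd": dials.jitter_sd,
        "n_bouts": float(len(kept_lengths)),
        "total_steps": float(sum(length - 10 for length in kept_lengths)),
        "avg_steps_per_bout": (
            float(np.mean([length - 10 for length in kept_lengths])) if kept_lengths else math.nan
        ),
    }
    truth.update(_true_derived_parameters(dials, config, rng))
    return series, truth


def _sample_nb(rate: np.ndarray, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """NB2 counts via the gamma-Poisson mixture; Poisson in the alpha->0 limit."""
    rate = np.asarray(rate, dtype=float)
    if alpha < 1e-8:
        return rng.poisson(rate)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * rate)
    return rng.poisson(lam)


def gen_outcomes(
    truth: pd.DataFrame,
    true_beta: dict[str, float],
    nb_dispersion: float,
    rng: np.random.Generator,
    nb_intercept: float = math.log(0.8),
    group_beta: float = 0.0,
) -> tuple[list[OutcomeRecord], pd.DataFrame]:
    """Draw 12-month fall counts from the NB model on standardized true values.

    Standardization (mean 0, SD 1, sample SD) is over the simulated
    cohort's true parameter values. Returns outcome records and the truth
    table augmented with the linear predictor, rate and realized count.
    """
    truth = truth.copy()
    lp = np.full(len(truth), nb_intercept)
    for name, beta in true_beta.items():
        if name not in truth.columns:
            raise SimConfigError(f"true_beta names unresolved parameter {name!r}")
        col = truth[name].to_numpy(dtype=float)
        fill = np.nanmean(col)
        col = np.where(np.isnan(col), fill, col)
        sd = np.std(col, ddof=1)
        if sd == 0:
            raise SimConfigError(f"true parameter {name!r} is constant; cannot standardize")
        lp += beta * (col - col.mean()) / sd
    lp += group_beta * truth["group"].to_numpy(dtype=float)
    rate = np.exp(lp)
    counts = _sample_nb(rate, nb_dispersion, rng)
    truth["true_linear_predictor"] = lp
    truth["true_fall_rate"] = rate
    truth["fall_count"] = counts
    records = [
        OutcomeRecord(str(r.participant_id), int(r.group), int(r.fall_count))
        for r in truth.itertuples(index=False)
    ]
    return records, truth


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[StepEventSeries], list[OutcomeRecord], pd.DataFrame]:
    """Generate a full synthetic cohort: streams, outcomes and ground truth.

    Deterministic given the config (including its seed): per-participant
    substreams come from spawned seed sequences, so the cohort is
    reproducible participant-by-participant.
    """
    root = np.random.SeedSequence(config.seed)
    pop_rng = np.random.default_rng(root.spawn(1)[0])
    children = root.spawn(config.n_participants + 1)
    series_list, truth_rows = [], []
    for i in range(config.n_participants):
        rng = np.random.default_rng(children[i])
        dials = _draw_dials(config, i, rng)
        series, truth = gen_participant_stream(dials, config, rng)
        assert np.all(np.diff(series.timestamps) > 0), "generated stream not monotone"
        series_list.append(series)
        truth_rows.append(truth)
    truth_df = pd.DataFrame(truth_rows)
    outcome_rng = np.random.default_rng(children[-1])
    outcomes, truth_df = gen_outcomes(
        truth_df,
        config.true_beta,
        config.nb_dispersion,
        outcome_rng,
        nb_intercept=config.nb_intercept,
        group_beta=config.group_beta,
    )
    del pop_rng
    return series_list, outcomes, truth_df


def parameter_cohort(
    n: int,
    beta: dict[str, float],
    names: tuple[str, ...] | None = None,
    corr: np.ndarray | None = None,
    obs_noise_sd: float = 0.0,
    nb_intercept: float = math.log(0.8),
    nb_dispersion: float = 1.0,
    group_beta: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Parameter-level cohort for model-stage simulations.

    True parameter vectors are multivariate normal (identity correlation
    unless ``corr`` is given), fall counts follow the NB model on the true
    values, and observed parameters add independent Gaussian noise of SD
    ``obs_noise_sd`` (emulating bout-median estimation error). Returns a
    cohort table directly usable by the model stage.
    """
    rng = np.random.default_rng(seed)
    names = tuple(names) if names is not None else tuple(beta)
    missing = set(beta) - set(names)
    if missing:
        raise SimConfigError(f"beta names outside cohort parameters: {sorted(missing)}")
    k = len(names)
    if corr is None:
        true = rng.standard_normal((n, k))
    else:
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (k, k):
            raise SimConfigError("corr shape must match the number of parameters")
        true = rng.multivariate_normal(np.zeros(k), corr, size=n, method="cholesky")
    group = rng.integers(0, 2, size=n)
    lp = np.full(n, nb_intercept) + group_beta * group
    for j, name in enumerate(names):
        b = beta.get(name, 0.0)
        if b:
            col = true[:, j]
            lp += b * (col - col.mean()) / np.std(col, ddof=1)
    counts = _sample_nb(np.exp(lp), nb_dispersion, rng)
    observed = true + obs_noise_sd * rng.standard_normal((n, k))
    df = pd.DataFrame(observed, columns=list(names))
    df.insert(0, "participant_id", [f"S{i + 1:05d}" for i in range(n)])
    df["group"] = group
    df["fall_count"] = counts
    df["faller"] = (counts >= 1).astype(int)
    return df
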