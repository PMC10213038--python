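"""Synthetic cohort generator: EEG spectral phenotypes with planted
treatment-response structure.

This module emulates the study design that the rest of the pipeline is built
for: a cohort of adolescents (default 56 subjects), each contributing four
resting-state eyes-closed EEG sessions (32 channels, 500 Hz, 120 s) and a
table of behavioral task performance (Flanker / N-Back / CPT; accuracy and
reaction time) under active vs sham stimulation, concurrent vs non-concurrent
task, in two stimulation groups (A: lDLPFC, B: rIFG).

Each subject is drawn from one of four spectral phenotype archetypes:

1. neurotypical posterior-dominant alpha;
2. slowing: power shifted from alpha toward theta;
3. low alpha at 10 Hz with elevated beta/gamma;
4. strong alpha with an additional 20 Hz beta peak and a flattened
   frontal-parietal alpha gradient.

EEG sessions are synthesized as stationary Gaussian processes with a
prescribed power spectral density: a weak 1/f background plus per-band
plateaus scaled channel-wise by the phenotype's band topography, plus
narrowband oscillatory peaks at the alpha (and optionally beta) peak
frequency. Constructing the signal in the frequency domain gives direct
analytic control over relative band power -- the only feature downstream
stages consume.

Behavioral outcomes plant a cluster-linked treatment effect: subjects of a
designated "positive responder" phenotype receive an accuracy benefit (and
RT reduction) under active vs sham stimulation on a designated endpoint;
"negative responder" phenotypes the reverse; everyone else no effect. A weak
linear age confound on reaction time exercises the covariate adjustment in
the correlation stage.
"""

from __future__ import annotations

import functools

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .montage import (
    ANALYSIS_CHANNELS,
    BAND_NAMES,
    BANDS,
    CENTRAL,
    CHANNELS_32,
    FRONTAL,
    POSTERIOR,
    REFERENCE,
    feature_names,
)

TASKS = ("Flanker", "N-Back", "CPT")
METRICS = ("accuracy", "rt")
CONCURRENCIES = ("concurrent", "non-concurrent")
GROUPS = ("A", "B")
RESPONDER_CLASSES = ("positive", "negative", "non")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeSpec:
    """One spectral archetype: per-band per-channel power weights plus
    oscillatory peak frequencies and a 1/f background exponent."""

    phenotype_id: int
    band_topography: dict[str, np.ndarray]  # band -> (32,) nonnegative weights
    alpha_peak_hz: float
    beta_peak_hz: float | None = None
    background_exponent: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.phenotype_id <= 4:
            raise ValueError("phenotype_id must be in 1..4")
        if not 8.0 <= self.alpha_peak_hz <= 13.0:
            raise ValueError("alpha_peak_hz must lie within the alpha band")
        if self.background_exponent <= 0:
            raise ValueError("background_exponent must be > 0")
        any_positive = False
        for band in BAND_NAMES:
            w = np.asarray(self.band_topography[band], dtype=float)
            if w.shape != (len(CHANNELS_32),):
                raise ValueError(f"band {band}: expected {len(CHANNELS_32)} weights")
            if (w < 0).any():
                raise ValueError(f"band {band}: weights must be nonnegative")
            any_positive = any_positive or (w > 0).any()
        if not any_positive:
            raise ValueError("at least one band must have a positive weight")

    def weight_matrix(self) -> np.ndarray:
        """(n_bands, 32) stacked weights in delta..gamma order."""
        return np.stack([np.asarray(self.band_topography[b], float) for b in BAND_NAMES])

    def target_rbp(self, channels: tuple[str, ...] = CHANNELS_32) -> np.ndarray:
        """Normalized per-channel relative band power implied by the
        topography, shape (len(channels), n_bands)."""
        W = self.weight_matrix()  # (bands, 32)
        idx = [CHANNELS_32.index(c) for c in channels]
        W = W[:, idx]
        totals = W.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("every channel needs positive total weight")
        return (W / totals).T


@dataclass(frozen=True)
class SubjectTruth:
    """Ground-truth record for one synthetic subject."""

    subject_id: str
    phenotype_id: int
    group: str
    age: float
    sex: str
    iq: float
    handedness: float
    responder_class: str
    effect_size: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if not 10 <= self.age <= 17:
            raise ValueError("age must be in [10, 17] years")
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        if self.iq < 80:
            raise ValueError("iq must be >= 80")
        if not -100 <= self.handedness <= 100:
            raise ValueError("handedness must be an EHI score in [-100, 100]")
        if self.responder_class not in RESPONDER_CLASSES:
            raise ValueError(f"responder_class must be one of {RESPONDER_CLASSES}")
        if (self.effect_size == 0) != (self.responder_class == "non"):
            raise ValueError("effect_size must be 0 iff responder_class is 'non'")


@dataclass
class SessionRecording:
    """One subject-session multichannel EEG segment (microvolts)."""

    subject_id: str
    session_index: int
    channel_names: tuple[str, ...]
    fs: float
    data: np.ndarray  # (n_channels, n_samples), microvolts
    duration: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("row count must equal number of channel names")
        expected = int(round(self.duration * self.fs))
        if self.data.shape[1] != expected:
            raise ValueError(f"expected {expected} samples, got {self.data.shape[1]}")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite values")

    def to_mne_raw(self):
        """View as an :class:`mne.io.RawArray` (data converted to volts)."""
        import mne

        info = mne.create_info(list(self.channel_names), self.fs, ch_types="eeg")
        return mne.io.RawArray(self.data * 1e-6, info, verbose="error")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ResponderPlan:
    """Which phenotype responds, in which direction, on which endpoint."""

    phenotype_id: int
    responder_class: str  # 'positive' | 'negative'
    task: str
    metric: str


@dataclass
class CohortConfig:
    n_subjects: int = 56
    n_sessions: int = 4
    proportions: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    effect_size: float = 4.5
    expression_range: tuple[float, float] = (0.4, 1.0)  # archetype expression grade
    separation: float = 1.0           # scales archetype contrast (ARI dial)
    session_jitter_cv: float = 0.05   # CV of per-session topography jitter
    feature_noise_sd: float = 0.004   # additive RBP noise (fast path)
    background_fraction: float = 0.05  # share of channel power in 1/f background
    duration: float = 120.0
    fs: float = 500.0
    rms_uv: float = 10.0              # average per-channel RMS amplitude
    artifact_bursts_per_session: float = 0.0
    responder_plans: tuple[ResponderPlan, ...] = (
        ResponderPlan(2, "positive", "N-Back", "accuracy"),
        ResponderPlan(3, "negative", "Flanker", "rt"),
    )
    # behavioral model scales (latent scale; see docs/methods.md)
    accuracy_latent_mu: float = 1.2
    accuracy_latent_sd: float = 0.35
    rt_log_mu: float = float(np.log(450.0))
    rt_log_sd: float = 0.06
    arm_noise_acc: float = 0.15
    arm_noise_rt: float = 0.08
    age_rt_level_slope: float = 0.010   # log-RT per year (affects both arms)
    age_rt_delta_slope: float = 0.004   # log-RT delta per year (confound)

    def __post_init__(self) -> None:
        props = np.asarray(self.proportions, float)
        if props.ndim != 1 or len(props) == 0:
            raise ValueError("proportions must be a non-empty sequence")
        if (props < 0).any() or not np.isclose(props.sum(), 1.0):
            raise ValueError("proportions must be nonnegative and sum to 1")
        if self.n_subjects < len(props):
            raise ValueError("n_subjects must be >= number of phenotypes")
        for name in ("session_jitter_cv", "feature_noise_sd", "background_fraction",
                     "arm_noise_acc", "arm_noise_rt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        plans = raw.pop("responder_plans", None)
        cfg = cls(**{k: v for k, v in raw.items()})
        if plans is not None:
            cfg.responder_plans = tuple(ResponderPlan(**p) for p in plans)
        if "proportions" in raw:
            cfg.proportions = tuple(raw["proportions"])
        return cfg


# ---------------------------------------------------------------------------
# Phenotype archetypes
# ---------------------------------------------------------------------------

def _region_weights(posterior: float, central: float, frontal: float) -> np.ndarray:
    w = np.empty(len(CHANNELS_32))
    for i, ch in enumerate(CHANNELS_32):
        if ch in POSTERIOR:
            w[i] = posterior
        elif ch in CENTRAL:
            w[i] = central
        else:
            w[i] = frontal
    return w


def default_phenotypes() -> tuple[PhenotypeSpec, ...]:
    """The four archetypes, parameterized from their qualitative spectral
    descriptions; amplitudes are free parameters of this package."""
    flat = _region_weights
    p1 = PhenotypeSpec(
        1,
        {
            "delta": flat(0.8, 1.0, 1.2),
            "theta": flat(1.0, 1.2, 1.4),
            "alpha": flat(5.0, 2.5, 1.5),   # posterior-dominant alpha
            "beta": flat(1.0, 1.2, 1.0),
            "gamma": flat(0.4, 0.5, 0.5),
        },
        alpha_peak_hz=10.0,
    )
    p2 = PhenotypeSpec(
        2,
        {
            "delta": flat(1.4, 1.6, 1.8),
            "theta": flat(4.5, 4.0, 3.5),   # slowing: theta dominates
            "alpha": flat(1.8, 1.4, 1.0),
            "beta": flat(0.9, 1.0, 0.9),
            "gamma": flat(0.4, 0.4, 0.4),
        },
        alpha_peak_hz=8.5,
    )
    p3 = PhenotypeSpec(
        3,
        {
            "delta": flat(0.9, 1.0, 1.1),
            "theta": flat(1.0, 1.1, 1.2),
            "alpha": flat(1.2, 1.0, 0.8),   # low amplitude at 10 Hz
            "beta": flat(3.2, 3.4, 3.0),    # large high-frequency power
            "gamma": flat(1.6, 1.8, 1.6),
        },
        alpha_peak_hz=10.0,
    )
    p4 = PhenotypeSpec(
        4,
        {
            "delta": flat(0.7, 0.8, 0.9),
            "theta": flat(0.9, 1.0, 1.1),
            "alpha": flat(6.5, 5.5, 5.0),   # strong alpha, flat gradient
            "beta": flat(2.2, 2.4, 2.0),    # 20 Hz peak folded into beta
            "gamma": flat(0.5, 0.5, 0.5),
        },
        alpha_peak_hz=10.0,
        beta_peak_hz=20.0,
    )
    return (p1, p2, p3, p4)


def _expressed_phenotype(phenos: tuple[PhenotypeSpec, ...], phenotype_id: int,
                         expression: float, separation: float = 1.0) -> PhenotypeSpec:
    """A subject's individual spectral profile: the archetype's relative
    band-power topography interpolated toward the cohort-average profile.

    ``expression`` in (0, 1] grades how strongly the subject expresses the
    archetype (1 = the archetype itself); partial expression moves the
    profile toward the mean of all archetypes, so cluster membership becomes
    a continuous individual trait rather than a binary one. Interpolation is
    done in relative band-power space, which keeps rows nonnegative and
    normalized."""
    rbps = np.stack([p.target_rbp() for p in phenos])       # (P, 32, 5)
    neutral = rbps.mean(axis=0)
    own = rbps[phenotype_id - 1]
    mix = neutral + separation * expression * (own - neutral)  # (32, 5)
    base = phenos[phenotype_id - 1]
    topo = {band: mix[:, b].copy() for b, band in enumerate(BAND_NAMES)}
    return replace(base, band_topography=topo)


def _jitter_phenotype(pheno: PhenotypeSpec, cv: float, rng: np.random.Generator) -> PhenotypeSpec:
    """Multiplicative lognormal jitter of every band-channel weight with
    coefficient of variation ``cv`` (session-to-session variability)."""
    if cv <= 0:
        return pheno
    sigma = float(np.sqrt(np.log1p(cv**2)))
    topo = {
        band: np.asarray(w, float)
        * rng.lognormal(-sigma**2 / 2, sigma, size=len(CHANNELS_32))
        for band, w in pheno.band_topography.items()
    }
    return replace(pheno, band_topography=topo)


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def synthesize_eeg(
    truth: SubjectTruth,
    pheno: PhenotypeSpec,
    session_index: int,
    seed: int,
    *,
    duration: float = 120.0,
    fs: float = 500.0,
    background_fraction: float = 0.05,
    rms_uv: float = 10.0,
    compensate_filter: bool = True,
) -> SessionRecording:
    """Synthesize one resting-state session as a Gaussian process whose PSD
    realizes the phenotype's relative band-power profile.

    Per channel the PSD is composed of a 1/f^exponent broadband background
    (a configured small fraction of total power), per-band flat components
    whose integrals complete each band's power budget, and Gaussian-shaped
    narrowband peaks at ``alpha_peak_hz`` (and ``beta_peak_hz`` if set)
    carrying part of their band's budget. A complex-Gaussian spectrum with
    this amplitude profile is inverted to the time domain, which is
    equivalent to summing band-pass filtered noise and narrowband
    oscillations but gives exact band-power control.
    """
    n = int(round(duration * fs))
    rng = np.random.default_rng([seed & 0x7FFFFFFF, session_index])

    W = pheno.weight_matrix()  # (bands, 32)
    totals = W.sum(axis=0)
    if np.all(totals == 0):
        data = np.zeros((len(CHANNELS_32), n))
        return SessionRecording(truth.subject_id, session_index, CHANNELS_32, fs, data, duration)

    # Mean channel variance rms_uv^2; channels scaled by their total weight.
    mean_total = totals[totals > 0].mean()
    chan_power = (rms_uv**2) * totals / mean_total  # microvolts^2
    # The reference electrode is synthesized quiet (2% power) so that
    # re-referencing leaves per-channel relative band power essentially
    # unchanged -- the idealization of a low-noise reference.
    chan_power[CHANNELS_32.index(REFERENCE)] *= 0.02

    shapes, M, v_bg = _spectral_components(
        n, fs, pheno.alpha_peak_hz, pheno.beta_peak_hz,
        pheno.background_exponent, compensate_filter,
    )
    bg_emph, band_emph = shapes  # (n_rfft,), (5, n_rfft) pre-emphasized shapes

    psd = np.zeros((len(CHANNELS_32), bg_emph.size))
    for c in range(len(CHANNELS_32)):
        if chan_power[c] == 0 or totals[c] == 0:
            continue
        target = chan_power[c] * W[:, c] / totals[c]
        bg_power = background_fraction * chan_power[c]
        # Solve the leakage model M @ budget = target - bg contribution, so
        # the *expected measured* band powers equal the target exactly.
        budget = np.linalg.solve(M, target - bg_power * v_bg)
        budget = np.clip(budget, 0.0, None)
        psd[c] = bg_power * bg_emph + budget @ band_emph

    # PSD -> time series: X(f) = sqrt(PSD * df * n^2 / 2) * complex unit noise
    df = fs / n
    amp = np.sqrt(np.maximum(psd, 0.0) * df) * n / np.sqrt(2.0)
    z = rng.standard_normal(psd.shape) + 1j * rng.standard_normal(psd.shape)
    spec = amp * z / np.sqrt(2.0)  # E|z/sqrt(2)|^2 = 1
    spec[:, 0] = 0.0
    if n % 2 == 0:
        spec[:, -1] = spec[:, -1].real
    data = np.fft.irfft(spec, n=n, axis=1)
    if not np.isfinite(data).all():
        raise FloatingPointError("EEG synthesis produced non-finite samples")
    return SessionRecording(truth.subject_id, session_index, CHANNELS_32, fs, data, duration)


@functools.lru_cache(maxsize=8)
def _spectral_components(
    n: int, fs: float, alpha_peak: float, beta_peak: float | None,
    exponent: float, compensate_filter: bool,
    window_s: float = 4.0, taps: int = 1000,
) -> tuple[tuple[np.ndarray, np.ndarray], np.ndarray, np.ndarray]:
    """Unit-power spectral component shapes plus their leakage calibration.

    Returns ``((bg, bands), M, v_bg)`` where ``bg`` (n_rfft,) and ``bands``
    (5, n_rfft) are unit-integral PSD shapes for the 1/f background and each
    band (flat plateau plus the Gaussian oscillatory peak inside alpha, and
    beta when a beta peak is set), already pre-emphasized by the inverse
    squared magnitude response of the analysis band-pass filter. ``M[b', b]``
    is the *expected measured* power in band b' (Hann periodogram of
    ``window_s`` epochs of the filtered signal, bins summed over the
    half-open band interval) of unit component b, and ``v_bg`` the same for
    the background. Solving ``M @ budget = target`` makes the expectation of
    the downstream relative band-power measurement hit the target profile:
    the generator accounts for filter roll-off at the passband edges and for
    spectral leakage across band boundaries instead of leaving them as
    biases of a few percent."""
    from scipy import signal as _signal

    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    df = freqs[1] - freqs[0]
    band_masks = [(freqs >= lo) & (freqs < hi) for _, lo, hi in BANDS]
    lo_edge, hi_edge = BANDS[0][1], BANDS[-1][2]
    in_pass = (freqs >= lo_edge) & (freqs < hi_edge)

    def unit(shape_on_mask: np.ndarray, mask: np.ndarray) -> np.ndarray:
        out = np.zeros_like(freqs)
        out[mask] = shape_on_mask
        s = out.sum() * df
        return out / s if s > 0 else out

    bg = unit(freqs[in_pass] ** (-exponent), in_pass)
    bands = []
    for b, (name, lo, hi) in enumerate(BANDS):
        mask = band_masks[b]
        flat = np.ones(mask.sum()) / (mask.sum() * df)
        comp = flat.copy()
        if name == "alpha":
            comp = 0.7 * flat + _gaussian_peak(freqs[mask], alpha_peak, 1.2, 0.3, df)
        elif name == "beta" and beta_peak is not None:
            comp = 0.7 * flat + _gaussian_peak(freqs[mask], beta_peak, 1.5, 0.3, df)
        bands.append(unit(comp, mask))
    bands = np.stack(bands)

    # Continue the outermost plateaus half a Hertz beyond the 2 / 45 Hz
    # edges so the edge periodogram bins are not starved by the cliff.
    ext_lo = (freqs >= lo_edge - 0.5) & (freqs < lo_edge)
    ext_hi = (freqs >= hi_edge) & (freqs < hi_edge + 0.5)
    first_in = np.searchsorted(freqs, lo_edge)
    last_in = np.searchsorted(freqs, hi_edge) - 1
    for comp in (bg, bands[0]):
        comp[ext_lo] = comp[first_in]
    for comp in (bg, bands[-1]):
        comp[ext_hi] = comp[last_in]

    # Inverse pre-emphasis of the analysis filter (floored to bound boost).
    if compensate_filter:
        h = _signal.firwin(taps, [lo_edge, hi_edge], pass_zero=False, fs=fs)
        _, H = _signal.freqz(h, worN=freqs, fs=fs)
        gain2 = np.abs(H) ** 2
        emph = 1.0 / np.clip(gain2, 0.02, None)
    else:
        gain2 = np.ones_like(freqs)
        emph = np.ones_like(freqs)
    bg_emph = bg * emph
    bands_emph = bands * emph

    # Leakage operator: expected Hann periodogram of the filtered signal.
    nper = int(round(window_s * fs))
    win = _signal.get_window("hann", nper)
    Wf = np.fft.fft(win, n)
    kernel = np.abs(Wf) ** 2
    kernel /= kernel.sum() * df
    kern_f = np.fft.fft(kernel)
    coarse = np.fft.rfftfreq(nper, 1.0 / fs)
    coarse_idx = {
        b: np.round(coarse[(coarse >= lo) & (coarse < hi)] / df).astype(int)
        for b, (_, lo, hi) in enumerate(BANDS)
    }
    df_coarse = fs / nper

    def measured(shape_emph: np.ndarray) -> np.ndarray:
        post = shape_emph * gain2          # PSD after the analysis filter
        two_sided = np.zeros(n)
        two_sided[: post.size] = post
        two_sided[-(post.size - 1):] += post[1:][::-1]
        conv = np.real(np.fft.ifft(np.fft.fft(two_sided) * kern_f)) * df
        return np.array([conv[idx].sum() * df_coarse for idx in coarse_idx.values()])

    v_bg = measured(bg_emph)
    M = np.stack([measured(bands_emph[b]) for b in range(len(BANDS))], axis=1)
    return (bg_emph, bands_emph), M, v_bg


def _gaussian_peak(f: np.ndarray, center: float, width: float, power: float, df: float) -> np.ndarray:
    """Gaussian PSD bump with total integral ``power`` over the given bins."""
    shape = np.exp(-0.5 * ((f - center) / width) ** 2)
    integral = shape.sum() * df
    if integral <= 0:
        return np.zeros_like(f)
    return shape * (power / integral)


def _insert_bursts(rec: SessionRecording, n_bursts: int, rng: np.random.Generator,
                   amplitude_uv: float = 150.0) -> None:
    """Superimpose brief high-amplitude bursts (artifact emulation)."""
    n = rec.data.shape[1]
    for _ in range(n_bursts):
        center = rng.integers(0, n)
        width = int(0.2 * rec.fs)
        lo, hi = max(0, center - width), min(n, center + width)
        t = np.arange(lo, hi) - center
        bump = amplitude_uv * np.exp(-0.5 * (t / (0.05 * rec.fs)) ** 2)
        ch = rng.integers(0, rec.data.shape[0])
        rec.data[ch, lo:hi] += bump


# ---------------------------------------------------------------------------
# Behavioral synthesis
# ---------------------------------------------------------------------------

def _endpoint_shift(plans: tuple[ResponderPlan, ...], effect_size: float,
                    task: str, metric: str,
                    membership_target: np.ndarray) -> float:
    """Planted latent-scale active-minus-sham shift for one endpoint.

    The treatment response is a dose-response in phenotype membership: every
    responder plan contributes ``effect_size`` scaled by the subject's
    weight in that plan's phenotype, so a subject strongly expressing a
    positive-responder phenotype shifts strongly and one with marginal
    membership shifts marginally. Positive responders gain accuracy and
    lose RT under active stimulation; negative responders the reverse.
    ``effect_size`` standardizes the shift against the active-sham delta
    noise at full membership."""
    shift = 0.0
    for plan in plans:
        if (task, metric) != (plan.task, plan.metric):
            continue
        dose = float(membership_target[plan.phenotype_id - 1])
        sign = 1.0 if plan.responder_class == "positive" else -1.0
        if metric == "rt":
            sign = -sign  # faster responses are better
        shift += sign * effect_size * dose
    return shift


def true_membership(phenos: tuple[PhenotypeSpec, ...],
                    profile_rbp: np.ndarray, exponent: float = 2.0) -> np.ndarray:
    """Ground-truth soft membership of a subject profile in each archetype:
    normalized inverse Euclidean distance (raised to ``exponent``) in
    relative band-power space. The exponent sharpens the dose so that a
    subject's weight in its own archetype dominates; distances between
    profiles concentrate in 135 dimensions and the plain inverse distance
    would compress the dose range."""
    refs = np.stack([p.target_rbp(ANALYSIS_CHANNELS).ravel() for p in phenos])
    d = np.linalg.norm(refs - profile_rbp.ravel(), axis=1)
    if (d <= 1e-300).any():
        u = (d <= 1e-300).astype(float)
        return u / u.sum()
    inv = d ** (-exponent)
    return inv / inv.sum()


def generate_behavior(
    truth: SubjectTruth,
    membership_target: np.ndarray | None,
    seed: int,
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """Behavioral records for one subject: every task x metric x
    stimulation x concurrency cell.

    Sham values come from a subject baseline (accuracy: logistic-bounded
    Gaussian latent; RT: log-normal); active values add the planted
    cluster-linked shift on the latent scale. A weak linear age effect on
    RT (level and delta) provides the covariate confound."""
    cfg = config or CohortConfig()
    if not np.isfinite(truth.effect_size):
        raise ValueError("effect_size must be finite")
    if membership_target is None:
        # default: a one-hot membership in the subject's own phenotype,
        # scaled so a subject of a non-responder phenotype shifts by zero
        membership_target = np.zeros(max(4, truth.phenotype_id))
        if truth.responder_class != "non":
            membership_target[truth.phenotype_id - 1] = 1.0
    membership_target = np.asarray(membership_target, float)

    rng = np.random.default_rng([seed & 0x7FFFFFFF, 7])
    age_centered = truth.age - 13.5
    rows = []
    for task in TASKS:
        acc_base = rng.normal(cfg.accuracy_latent_mu, cfg.accuracy_latent_sd)
        rt_base = rng.normal(cfg.rt_log_mu, cfg.rt_log_sd) + cfg.age_rt_level_slope * age_centered
        for concurrency in CONCURRENCIES:
            for metric in METRICS:
                arm_sd = cfg.arm_noise_acc if metric == "accuracy" else cfg.arm_noise_rt
                # effect_size standardizes the delta, whose noise SD is sqrt(2)*arm_sd
                shift = _endpoint_shift(cfg.responder_plans, cfg.effect_size,
                                        task, metric, membership_target)
                shift *= np.sqrt(2.0) * arm_sd
                for stim in ("sham", "active"):
                    if metric == "accuracy":
                        latent = acc_base + rng.normal(0.0, arm_sd)
                        if stim == "active":
                            latent += shift
                        value = float(1.0 / (1.0 + np.exp(-latent)))
                    else:
                        latent = rt_base + rng.normal(0.0, arm_sd)
                        if stim == "active":
                            latent += shift + cfg.age_rt_delta_slope * age_centered
                        value = float(np.exp(latent))
                    rows.append(
                        dict(subject_id=truth.subject_id, task=task, metric=metric,
                             stimulation=stim, concurrency=concurrency, value=value)
                    )
    return pd.DataFrame(rows)


def generate_baseline_behavior(truths: list[SubjectTruth], seed: int,
                               config: CohortConfig | None = None) -> pd.DataFrame:
    """Pre-treatment (first-session) task performance: phenotype-independent
    by construction, used to check that clusters carry no baseline structure."""
    cfg = config or CohortConfig()
    rows = []
    for i, truth in enumerate(truths):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 11, i])
        age_centered = truth.age - 13.5
        for task in TASKS:
            acc = 1.0 / (1.0 + np.exp(-rng.normal(cfg.accuracy_latent_mu, cfg.accuracy_latent_sd)))
            rt = np.exp(rng.normal(cfg.rt_log_mu, cfg.rt_log_sd)
                        + cfg.age_rt_level_slope * age_centered)
            rows.append(dict(subject_id=truth.subject_id, task=task, metric="accuracy", value=acc))
            rows.append(dict(subject_id=truth.subject_id, task=task, metric="rt", value=float(rt)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _draw_truths(config: CohortConfig, rng: np.random.Generator) -> list[SubjectTruth]:
    n = config.n_subjects
    props = np.asarray(config.proportions, float)
    counts = np.floor(props * n).astype(int)
    # distribute the remainder to the largest fractional parts
    frac = props * n - counts
    for i in np.argsort(-frac)[: n - counts.sum()]:
        counts[i] += 1
    phenotype_ids = np.repeat(np.arange(1, len(props) + 1), counts)
    rng.shuffle(phenotype_ids)
    plan_map = {p.phenotype_id: p for p in config.responder_plans}

    truths = []
    for i in range(n):
        pid = int(phenotype_ids[i])
        plan = plan_map.get(pid)
        responder = plan.responder_class if plan is not None else "non"
        effect = config.effect_size if responder != "non" else 0.0
        if responder != "non" and effect == 0.0:
            responder = "non"
        truths.append(
            SubjectTruth(
                subject_id=f"S{i + 1:03d}",
                phenotype_id=pid,
                group=GROUPS[i % 2],
                age=float(rng.uniform(10.0, 17.0)),
                sex="female" if rng.random() < 0.5 else "male",
                iq=float(np.clip(rng.normal(105.0, 12.0), 80.0, 160.0)),
                handedness=float(np.clip(rng.normal(70.0, 30.0), -100.0, 100.0)),
                responder_class=responder,
                effect_size=effect,
            )
        )
    return truths


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    phenotypes: tuple[PhenotypeSpec, ...] | None = None,
) -> tuple[list[SubjectTruth], list[SessionRecording], pd.DataFrame]:
    """Full cohort: ground truths, EEG session recordings, behavioral table.

    Deterministic for a fixed seed. Each subject's sessions share one
    phenotype realization perturbed per session by multiplicative weight
    jitter (default 5% CV), keeping intra-subject variability well below
    inter-phenotype separation."""
    cfg = config or CohortConfig()
    phenos = phenotypes or default_phenotypes()
    if len(phenos) != len(cfg.proportions):
        raise ValueError("need one phenotype spec per mixing proportion")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    truths = _draw_truths(cfg, rng)

    recordings: list[SessionRecording] = []
    behavior_frames = []
    for i, truth in enumerate(truths):
        subject_seed = int(rng.integers(0, 2**31 - 1))
        expression = float(rng.uniform(*cfg.expression_range))
        base = _expressed_phenotype(phenos, truth.phenotype_id, expression,
                                    cfg.separation)
        for s in range(1, cfg.n_sessions + 1):
            sess_rng = np.random.default_rng([subject_seed, s])
            jittered = _jitter_phenotype(base, cfg.session_jitter_cv, sess_rng)
            rec = synthesize_eeg(
                truth, jittered, s, subject_seed,
                duration=cfg.duration, fs=cfg.fs,
                background_fraction=cfg.background_fraction, rms_uv=cfg.rms_uv,
            )
            if cfg.artifact_bursts_per_session > 0:
                n_bursts = sess_rng.poisson(cfg.artifact_bursts_per_session)
                _insert_bursts(rec, int(n_bursts), sess_rng)
            recordings.append(rec)
        membership = true_membership(phenos, base.target_rbp(ANALYSIS_CHANNELS))
        behavior_frames.append(generate_behavior(truth, membership, subject_seed, cfg))
    behavior = pd.concat(behavior_frames, ignore_index=True)
    return truths, recordings, behavior


def generate_feature_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    phenotypes: tuple[PhenotypeSpec, ...] | None = None,
) -> tuple[list[SubjectTruth], pd.DataFrame, pd.DataFrame]:
    """Fast path: sample session feature vectors (135-dim relative band
    powers) directly from the phenotype topographies, with the same
    session-jitter model as the EEG path, skipping waveform synthesis.

    Returns (truths, features, behavior) where ``features`` has one row per
    subject-session with columns subject_id, session_index and the 135
    named feature columns."""
    cfg = config or CohortConfig()
    phenos = phenotypes or default_phenotypes()
    if len(phenos) != len(cfg.proportions):
        raise ValueError("need one phenotype spec per mixing proportion")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    truths = _draw_truths(cfg, rng)

    rows = []
    behavior_frames = []
    names = feature_names()
    for truth in truths:
        subject_seed = int(rng.integers(0, 2**31 - 1))
        expression = float(rng.uniform(*cfg.expression_range))
        base = _expressed_phenotype(phenos, truth.phenotype_id, expression,
                                    cfg.separation)
        for s in range(1, cfg.n_sessions + 1):
            sess_rng = np.random.default_rng([subject_seed, s])
            jittered = _jitter_phenotype(base, cfg.session_jitter_cv, sess_rng)
            rbp = jittered.target_rbp(ANALYSIS_CHANNELS)  # (27, 5)
            noise = sess_rng.normal(0.0, cfg.feature_noise_sd, rbp.shape)
            rbp = np.clip(rbp + noise, 1e-9, None)
            rbp /= rbp.sum(axis=1, keepdims=True)
            row = dict(subject_id=truth.subject_id, session_index=s)
            row.update(zip(names, rbp.ravel()))
            rows.append(row)
        membership = true_membership(phenos, base.target_rbp(ANALYSIS_CHANNELS))
        behavior_frames.append(generate_behavior(truth, membership, subject_seed, cfg))
    features = pd.DataFrame(rows)
    behavior = pd.concat(behavior_frames, ignore_index=True)
    return truths, features, behavior


def covariates_frame(truths: list[SubjectTruth]) -> pd.DataFrame:
    """Subject covariate/ground-truth table (one row per subject)."""
    return pd.DataFrame(
        dict(
            subject_id=t.subject_id, group=t.group, age=t.age, sex=t.sex,
            iq=t.iq, handedness=t.handedness, phenotype_id=t.phenotype_id,
            responder_class=t.responder_class,
        )
        for t in truths
    )


def save_recordings_fif(recordings: list[SessionRecording], out_dir) -> list[str]:
    """Write each session as an MNE FIF file ``<subject>_ses<k>_raw.fif``."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in recordings:
        path = out / f"{rec.subject_id}_ses{rec.session_index}_raw.fif"
        rec.to_mne_raw().save(path, overwrite=True, verbose="error")
        paths.append(str(path))
    return paths
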