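"""Seedable synthetic-cohort generator.

Emulates the statistical structure the analysis pipeline assumes in a
bedside music-therapy study of clinically stable preterm neonates: a
55-minute, 9-interval session with two 10-minute singing intervals; two
response subgroups (cerebral StO2 rising by about +3.2% in the first singing
interval versus falling by about -1.2%); a habituated (attenuated) response
to the second singing interval; a sex imbalance across subgroups; a
haematocrit level that covaries with the magnitude and sign of the response;
1/f physiological drift plus white measurement noise; and sporadic motion
artifact bursts visible in the accelerometer with coincident spikes in the
physiological channels.

Every draw flows from a single ``numpy`` Generator, so a seed reproduces the
cohort byte-for-byte, and a ``GroundTruth`` record preserves the planted
subgroups, amplitudes and artifact positions for recovery testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .session_io import (
    SessionRecording,
    StudyProtocol,
    SubjectMetadata,
    default_protocol,
    write_metadata_table,
    write_session,
)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "pink_noise",
    "response_shape",
    "generate_metadata",
    "generate_session",
    "generate_cohort",
]


@dataclass
class SubgroupModel:
    """Latent response model.  ``sex_log_odds`` is the additive shift in the
    log odds of a positive response for females (base odds refer to males);
    defaults reproduce an 8F/2M vs 2F/5M style imbalance on average.
    ``hct_coefficient`` maps haematocrit (volume fraction) to response
    amplitude in %StO2 per unit Hct."""

    sex_log_odds: float = 2.303
    male_log_odds: float = -0.916  # ln(2/5): odds of positive response, males
    hct_coefficient: float = 10.0
    amplitude_mean_pos: float = 3.2
    amplitude_mean_neg: float = -1.2
    amplitude_sd: float = 0.5


@dataclass
class CouplingModel:
    """How systemic channels follow the cerebral response, per subgroup.

    Positive responders couple mainly through arterial saturation (with an
    optional quadratic pulse-rate component); negative responders couple
    mainly through pulse rate."""

    spo2_gain: float  # %SpO2 per %StO2 of response
    pr_gain: float  # bpm per %StO2
    pr_quadratic: float = 0.0  # bpm per (%StO2)^2


@dataclass
class NoiseModel:
    pink_sd: dict = field(
        default_factory=lambda: {"sto2": 0.3, "spo2": 0.15, "pr": 1.0}
    )
    white_sd: dict = field(
        default_factory=lambda: {"sto2": 0.3, "spo2": 0.15, "pr": 1.0}
    )


@dataclass
class ArtifactModel:
    rate_per_hour: float = 2.0
    burst_duration_s: float = 10.0
    burst_amplitude: float = 10.0
    physio_spike: float = 5.0  # amplitude of the coincident physiological spike
    accel_noise_sd: float = 0.1


@dataclass
class Baselines:
    sto2_mean: float = 70.0
    sto2_sd: float = 4.0
    spo2_mean: float = 97.0
    spo2_sd: float = 1.0
    pr_mean: float = 150.0
    pr_sd: float = 10.0


@dataclass
class CohortConfig:
    n_subjects: int = 17
    p_female: float = 10.0 / 17.0
    subgroup_model: SubgroupModel = field(default_factory=SubgroupModel)
    habituation_factor: float = 0.5
    coupling_pos: CouplingModel = field(
        default_factory=lambda: CouplingModel(spo2_gain=0.25, pr_gain=2.0,
                                              pr_quadratic=0.3)
    )
    coupling_neg: CouplingModel = field(
        default_factory=lambda: CouplingModel(spo2_gain=0.05, pr_gain=3.0)
    )
    noise: NoiseModel = field(default_factory=NoiseModel)
    artifact: ArtifactModel = field(default_factory=ArtifactModel)
    baselines: Baselines = field(default_factory=Baselines)
    pfc_fraction: float = 0.75  # prefrontal response relative to auditory
    ramp_s: float = 60.0
    fs_sto2: float = 1.0
    fs_vitals: float = 0.25
    fs_accel: float = 1.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted facts per subject, for recovery tests."""

    subgroup: dict  # subject_id -> 1 | 2
    amplitude: dict  # subject_id -> [first-singing, second-singing] %StO2
    artifact_spans: dict  # subject_id -> [(start_idx, end_idx), ...] accel idx
    haematocrit: dict
    sex: dict

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))
        return path


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def pink_noise(n: int, rng: np.random.Generator, sd: float = 1.0) -> np.ndarray:
    """Gaussian noise with a 1/f amplitude spectrum, normalized to ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0  # avoid division by zero at DC
    spec = spec / np.sqrt(f)
    spec[0] = 0.0  # zero-mean
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def response_shape(
    t: np.ndarray, protocol: StudyProtocol, ramp_s: float
) -> np.ndarray:
    """Unit-amplitude evoked-response template: trapezoid over each singing
    interval (linear onset/offset ramps, plateau at 1), scaled later per
    interval.  Returns shape (n_singing, len(t))."""
    shapes = []
    for iv in protocol.intervals:
        if iv.label != "singing":
            continue
        lo, hi = iv.start * 60.0, iv.end * 60.0
        up = np.clip((t - lo) / ramp_s, 0.0, 1.0)
        down = np.clip((hi - t) / ramp_s, 0.0, 1.0)
        shapes.append(np.where((t >= lo) & (t < hi), np.minimum(up, down), 0.0))
    return np.array(shapes)


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_metadata(
    cfg: CohortConfig, rng: np.random.Generator
) -> tuple[list[SubjectMetadata], GroundTruth]:
    """Draw covariates, subgroups and latent response amplitudes.

    Subgroup 1 (positive response) is sampled with sex-dependent log odds;
    the latent first-singing amplitude is the subgroup mean plus a
    haematocrit term ``hct_coefficient * (Hct - cohort mean)`` plus Gaussian
    jitter, so higher haematocrit shifts responses positive.  Covariate
    distributions are centred on a moderately preterm cohort (median
    gestational age ~33.7 weeks, birth weight ~1730 g).
    """
    sm = cfg.subgroup_model
    metas: list[SubjectMetadata] = []
    truth = GroundTruth({}, {}, {}, {}, {})
    hct_mean = 0.45
    for i in range(cfg.n_subjects):
        sid = f"S{i + 1:02d}"
        female = rng.random() < cfg.p_female
        sex = "female" if female else "male"
        hct = float(np.clip(rng.normal(hct_mean, 0.05), 0.30, 0.65))
        logit = sm.male_log_odds + (sm.sex_log_odds if female else 0.0)
        positive = rng.random() < _sigmoid(logit)
        mu = sm.amplitude_mean_pos if positive else sm.amplitude_mean_neg
        amp = mu + sm.hct_coefficient * (hct - hct_mean) + rng.normal(0.0, sm.amplitude_sd)
        ga = float(np.clip(rng.normal(33.7, 1.8), 30.0, 36.9))
        bw = float(np.clip(rng.normal(1730.0, 420.0), 800.0, 3200.0))
        metas.append(
            SubjectMetadata(
                subject_id=sid,
                sex=sex,
                gestational_age=ga,
                postnatal_age=float(np.clip(rng.normal(9.0, 6.0), 1.0, 40.0)),
                birth_weight=bw,
                weight_at_measurement=bw * float(rng.uniform(1.0, 1.15)),
                length_at_birth=float(np.clip(rng.normal(42.0, 3.0), 34.0, 50.0)),
                length_at_measurement=float(np.clip(rng.normal(43.5, 3.0), 34.0, 52.0)),
                head_circumference_at_birth=float(np.clip(rng.normal(29.5, 1.8), 24.0, 35.0)),
                head_circumference_at_measurement=float(np.clip(rng.normal(30.5, 1.8), 24.0, 36.0)),
                apgar_1min=int(rng.integers(5, 10)),
                apgar_5min=int(rng.integers(7, 11)),
                mode_of_delivery=str(rng.choice(["vaginal", "caesarean"])),
                haematocrit=hct,
                behavioural_state_mean=float(rng.uniform(1.0, 3.0)),
                behavioural_state_std=float(rng.uniform(0.0, 1.0)),
            )
        )
        truth.subgroup[sid] = 1 if positive else 2
        truth.amplitude[sid] = [float(amp), float(amp * cfg.habituation_factor)]
        truth.haematocrit[sid] = hct
        truth.sex[sid] = sex
    return metas, truth


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def generate_session(
    meta: SubjectMetadata,
    truth: GroundTruth,
    cfg: CohortConfig,
    rng: np.random.Generator,
    protocol: StudyProtocol | None = None,
) -> SessionRecording:
    """Synthesize one session consistent with the subject's planted truth."""
    protocol = protocol or default_protocol()
    dur = protocol.duration_min * 60.0
    n1 = int(round(dur * cfg.fs_sto2))
    nv = int(round(dur * cfg.fs_vitals))
    na = int(round(dur * cfg.fs_accel))
    t1 = np.arange(n1) / cfg.fs_sto2
    tv = np.arange(nv) / cfg.fs_vitals
    ta = np.arange(na) / cfg.fs_accel

    sid = meta.subject_id
    amps = truth.amplitude[sid]
    subgroup = truth.subgroup[sid]
    coup = cfg.coupling_pos if subgroup == 1 else cfg.coupling_neg
    bl = cfg.baselines
    noise = cfg.noise

    shapes1 = response_shape(t1, protocol, cfg.ramp_s)  # (2, n1)
    shapesv = response_shape(tv, protocol, cfg.ramp_s)
    resp1 = sum(a * s for a, s in zip(amps, shapes1))  # %StO2 on 1 Hz grid
    respv = sum(a * s for a, s in zip(amps, shapesv))

    sto2_base = rng.normal(bl.sto2_mean, bl.sto2_sd)
    spo2_base = rng.normal(bl.spo2_mean, bl.spo2_sd)
    pr_base = rng.normal(bl.pr_mean, bl.pr_sd)

    def chan(n, key):
        return pink_noise(n, rng, noise.pink_sd[key]) + rng.normal(
            0.0, noise.white_sd[key], n
        )

    sto2_ac = sto2_base + resp1 + chan(n1, "sto2")
    sto2_pfc = sto2_base + rng.normal(0.0, 1.0) + cfg.pfc_fraction * resp1 + chan(n1, "sto2")
    spo2 = spo2_base + coup.spo2_gain * respv + chan(nv, "spo2")
    pr = (
        pr_base
        + coup.pr_gain * respv
        + coup.pr_quadratic * respv**2
        + chan(nv, "pr")
    )

    # motion artifacts: Poisson bursts in acceleration + coincident spikes
    art = cfg.artifact
    accel = rng.normal(0.0, art.accel_noise_sd, size=(3, na))
    n_bursts = rng.poisson(art.rate_per_hour * dur / 3600.0)
    burst_len = max(1, int(round(art.burst_duration_s * cfg.fs_accel)))
    spans = []
    for _ in range(n_bursts):
        start = int(rng.integers(0, max(1, na - burst_len)))
        stop = start + burst_len
        spans.append((start, stop))
        wave = art.burst_amplitude * rng.standard_normal((3, stop - start))
        accel[:, start:stop] += wave
        # coincident spike in the physiological channels
        lo_t, hi_t = ta[start], ta[stop - 1]
        for series, tt in ((sto2_ac, t1), (sto2_pfc, t1), (spo2, tv), (pr, tv)):
            hit = (tt >= lo_t) & (tt <= hi_t)
            series[hit] += art.physio_spike * rng.standard_normal(hit.sum())
    truth.artifact_spans[sid] = spans

    sto2_ac = np.clip(sto2_ac, 0.0, 100.0)
    sto2_pfc = np.clip(sto2_pfc, 0.0, 100.0)
    spo2 = np.clip(spo2, 0.0, 100.0)
    pr = np.clip(pr, 1.0, None)

    return SessionRecording(
        subject_id=sid,
        sto2_ac=sto2_ac,
        sto2_pfc=sto2_pfc,
        spo2=spo2,
        pr=pr,
        accel=accel,
        fs_sto2=cfg.fs_sto2,
        fs_vitals=cfg.fs_vitals,
        fs_accel=cfg.fs_accel,
    )


def generate_cohort(
    cfg: CohortConfig,
    out_dir: str | Path | None = None,
    protocol: StudyProtocol | None = None,
) -> tuple[list[SessionRecording], list[SubjectMetadata], GroundTruth]:
    """Generate the full cohort; optionally write the CSV/TSV/JSON bundle.

    Deterministic given ``cfg.seed``: the same config and seed reproduce the
    files byte for byte.
    """
    rng = np.random.default_rng(cfg.seed)
    metas, truth = generate_metadata(cfg, rng)
    sessions = [generate_session(m, truth, cfg, rng, protocol) for m in metas]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in sessions:
            write_session(rec, out / f"{rec.subject_id}.csv")
        write_metadata_table(metas, out / "metadata.tsv")
        truth.to_json(out / "truth.json")
    return sessions, metas, truth
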