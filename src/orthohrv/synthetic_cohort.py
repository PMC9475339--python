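"""Synthetic tilt-test RR cohorts with programmed autonomic structure.

Beats are produced by an integral pulse frequency modulation (IPFM)
generator: an instantaneous heart rate signal

    m(t) = r0(t) * [1 + a_LF(t) sin(2π f_LF t + φ1)
                      + a_HF(t) sin(2π f_HF t + φ2)] + noise

is integrated, and a beat is emitted each time the integral crosses the
next integer.  This yields tachograms with genuine LF and HF oscillatory
band structure, which is the property the spectral analysis stage assumes.

The default scenario emulates a four-group tilt cohort: phase-wise mean
heart rate rises on tilt and recovers on resupine, and the HF (vagal)
modulation amplitude is withdrawn during tilt with group-specific
strength — the "Vata-like" group shows the largest parasympathetic
withdrawal and heart-rate rise, the "Kapha-like" group the most blunted
response, with "Pitta-like" and Mixed in between.  Baseline HF amplitude
also declines with age so that age-band contrasts are exercisable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_protocol import ProtocolDefinition, RRSeries, write_rr


@dataclass
class GroupProfile:
    """Programmed effect sizes for one subject group.

    ``hr_supine_bpm`` and ``delta1_hr_pct`` are target group medians;
    ``hf_tilt_factor`` is the multiplicative HF-amplitude withdrawal on
    tilt (amplitude ratio, so HF *power* scales with its square).  The
    ``*_sd`` fields are between-subject dispersions.
    """

    n_subjects: int = 40
    hr_supine_bpm: float = 70.0
    hr_supine_sd: float = 8.0
    delta1_hr_pct: float = 18.0
    delta1_hr_sd: float = 4.5
    hr_resupine_jitter_pct: float = 1.5
    a_hf_supine: float = 0.046
    a_hf_sd: float = 0.010
    hf_tilt_factor: float = 0.65
    hf_tilt_factor_sd: float = 0.06
    hf_resupine_factor: float = 1.05
    a_lf_supine: float = 0.045
    a_lf_sd: float = 0.010
    lf_tilt_factor: float = 1.15
    a_vlf_supine: float = 0.030
    a_vlf_sd: float = 0.008
    vlf_tilt_factor: float = 1.5
    bmi_mean: float = 22.0
    bmi_sd: float = 4.0
    sbp_mean: float = 110.0
    sbp_sd: float = 10.0
    dbp_mean: float = 71.0
    dbp_sd: float = 12.0


def default_groups(n_per_group: int | dict[str, int] = 40) -> dict[str, GroupProfile]:
    """The four-group default scenario.

    Group medians (supine HR, %Δ1 HR, HF withdrawal) follow the ordering
    Vata ≈ Pitta > Mixed > Kapha in tilt response, with Kapha blunted; the
    HF tilt factor is the square root of the programmed fractional HF-power
    retention.
    """
    profiles = {
        "Vata": GroupProfile(hr_supine_bpm=68.51, delta1_hr_pct=19.79,
                             hf_tilt_factor=0.576, a_hf_supine=0.048,
                             bmi_mean=17.72, bmi_sd=1.93,
                             sbp_mean=108.64, sbp_sd=8.91,
                             dbp_mean=69.65, dbp_sd=14.29),
        "Pitta": GroupProfile(hr_supine_bpm=70.54, delta1_hr_pct=19.21,
                              hf_tilt_factor=0.653, a_hf_supine=0.048,
                              bmi_mean=22.42, bmi_sd=2.87,
                              sbp_mean=109.42, sbp_sd=10.32,
                              dbp_mean=70.12, dbp_sd=11.50),
        "Kapha": GroupProfile(hr_supine_bpm=72.27, delta1_hr_pct=14.32,
                              hf_tilt_factor=0.796, a_hf_supine=0.042,
                              bmi_mean=28.76, bmi_sd=3.86,
                              sbp_mean=113.62, sbp_sd=10.33,
                              dbp_mean=75.53, dbp_sd=7.89),
        "Mixed": GroupProfile(hr_supine_bpm=70.78, delta1_hr_pct=15.74,
                              hf_tilt_factor=0.657, a_hf_supine=0.046,
                              bmi_mean=22.03, bmi_sd=4.38,
                              sbp_mean=111.39, sbp_sd=11.71,
                              dbp_mean=71.01, dbp_sd=15.93),
    }
    if isinstance(n_per_group, int):
        for p in profiles.values():
            p.n_subjects = n_per_group
    else:
        profiles = {g: profiles[g] for g in n_per_group}
        for g, n in n_per_group.items():
            profiles[g].n_subjects = n
    return profiles


@dataclass
class GeneratorConfig:
    """Cohort-level generator settings (see :func:`default_groups`)."""

    groups: dict[str, GroupProfile] = field(default_factory=default_groups)
    f_lf_range: tuple[float, float] = (0.08, 0.12)
    f_hf_range: tuple[float, float] = (0.20, 0.30)
    f_vlf_range: tuple[float, float] = (0.012, 0.03)
    noise_frac: float = 0.015
    age_range: tuple[float, float] = (18.0, 40.0)
    age_hf_slope: float = 0.012  # fractional HF-amplitude loss per year past 18
    protocol: ProtocolDefinition = field(default_factory=ProtocolDefinition.default)
    grid_dt_s: float = 0.125
    seed: int = 0

    def validate(self) -> None:
        for name, p in self.groups.items():
            if p.n_subjects < 0:
                raise ValueError(f"group {name}: n_subjects must be >= 0")
            worst = ((p.a_lf_supine + 3 * p.a_lf_sd) * max(1.0, p.lf_tilt_factor)
                     + (p.a_hf_supine + 3 * p.a_hf_sd) * max(1.0, p.hf_resupine_factor)
                     + (p.a_vlf_supine + 3 * p.a_vlf_sd) * max(1.0, p.vlf_tilt_factor))
            if worst >= 1.0:
                raise ValueError(f"group {name}: modulation amplitudes too "
                                 f"large (a_LF + a_HF must stay < 1)")


def _phase_profile(t: np.ndarray, protocol: ProtocolDefinition,
                   phase_values: list[float]) -> np.ndarray:
    """Piecewise-constant per-phase values with smooth cosine ramps
    across the excluded transition windows."""
    out = np.full_like(t, phase_values[0])
    for (name, start, end), v in zip(protocol.phases, phase_values):
        out[(t >= start) & (t < end)] = v
    for i, (ws, we) in enumerate(protocol.excluded_windows):
        if i + 1 >= len(phase_values):
            break
        va, vb = phase_values[i], phase_values[i + 1]
        mask = (t >= ws) & (t < we)
        frac = (t[mask] - ws) / (we - ws)
        out[mask] = va + (vb - va) * 0.5 * (1 - np.cos(np.pi * frac))
    # after the final phase keep the last value
    out[t >= protocol.phases[-1][2]] = phase_values[-1]
    return out


def _ipfm_beats(rate_hz: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Beat times where the integral of the rate crosses successive
    integers; the first beat is anchored at t[0]."""
    dt = np.diff(t)
    integral = np.concatenate([[0.0], np.cumsum(0.5 * (rate_hz[:-1] + rate_hz[1:]) * dt)])
    n_beats = int(np.floor(integral[-1]))
    targets = np.arange(1, n_beats + 1, dtype=float)
    crossings = np.interp(targets, integral, t)
    return np.concatenate([[t[0]], crossings])


def gen_subject_rr(config: GeneratorConfig, group: str,
                   subject_seed: int, subject_id: str | None = None,
                   age: float | None = None,
                   return_truth: bool = False):
    """Generate one subject's 13-minute RR recording.

    Deterministic given ``subject_seed``.  ``return_truth=True`` also
    returns the realized per-subject parameters (phase heart rates,
    programmed %Δ1 HR, modulation amplitudes).
    """
    config.validate()
    profile = config.groups[group]
    rng = np.random.default_rng(subject_seed)
    sid = subject_id or f"{group[:1]}{subject_seed:06d}"

    if age is None:
        age = float(rng.uniform(*config.age_range))
    age_factor = max(0.25, 1.0 - config.age_hf_slope * (age - config.age_range[0]))

    hr_sup = float(np.clip(rng.normal(profile.hr_supine_bpm, profile.hr_supine_sd),
                           45.0, 110.0))
    d1_hr = float(rng.normal(profile.delta1_hr_pct, profile.delta1_hr_sd))
    hr_tilt = hr_sup * (1 + d1_hr / 100.0)
    hr_resup = hr_sup * (1 + rng.normal(0.0, profile.hr_resupine_jitter_pct) / 100.0)

    # Withdrawal/surge factors are defined on RR-interval amplitudes; the
    # rate-fraction amplitude during tilt is compensated by the heart-rate
    # ratio so that e.g. HF power in ms^2 scales by hf_tilt_factor^2.
    hr_ratio = 1 + d1_hr / 100.0
    a_hf0 = max(0.0, float(rng.normal(profile.a_hf_supine, profile.a_hf_sd))) * age_factor
    wf = float(np.clip(rng.normal(profile.hf_tilt_factor, profile.hf_tilt_factor_sd),
                       0.05, 1.2))
    a_hf = [a_hf0, a_hf0 * wf * hr_ratio, a_hf0 * profile.hf_resupine_factor]
    a_lf0 = max(0.0, float(rng.normal(profile.a_lf_supine, profile.a_lf_sd)))
    a_lf = [a_lf0, a_lf0 * profile.lf_tilt_factor * hr_ratio, a_lf0]
    a_vlf0 = max(0.0, float(rng.normal(profile.a_vlf_supine, profile.a_vlf_sd)))
    a_vlf = [a_vlf0, a_vlf0 * profile.vlf_tilt_factor * hr_ratio, a_vlf0]

    f_lf = float(rng.uniform(*config.f_lf_range))
    f_hf = float(rng.uniform(*config.f_hf_range))
    f_vlf = float(rng.uniform(*config.f_vlf_range))
    phi1, phi2, phi3 = rng.uniform(0, 2 * np.pi, size=3)

    proto = config.protocol
    t = np.arange(0.0, proto.total_duration_s + config.grid_dt_s, config.grid_dt_s)
    r0 = _phase_profile(t, proto, [hr_sup, hr_tilt, hr_resup]) / 60.0
    alf = _phase_profile(t, proto, a_lf)
    ahf = _phase_profile(t, proto, a_hf)
    avlf = _phase_profile(t, proto, a_vlf)

    m = r0 * (1.0
              + alf * np.sin(2 * np.pi * f_lf * t + phi1)
              + ahf * np.sin(2 * np.pi * f_hf * t + phi2)
              + avlf * np.sin(2 * np.pi * f_vlf * t + phi3))
    m = m + config.noise_frac * r0 * rng.standard_normal(len(t))
    m = np.clip(m, 0.2, None)

    beat_times = _ipfm_beats(m, t)
    rr_ms = np.diff(beat_times) * 1000.0
    series = RRSeries(sid, beat_times, rr_ms)

    if not return_truth:
        return series
    truth = {
        "subject_id": sid, "group": group, "age": age,
        "hr_supine_bpm": hr_sup, "hr_tilt_bpm": hr_tilt,
        "hr_resupine_bpm": hr_resup, "delta1_hr_pct": d1_hr,
        "a_hf": a_hf, "a_lf": a_lf, "a_vlf": a_vlf,
        "f_lf_hz": f_lf, "f_hf_hz": f_hf, "f_vlf_hz": f_vlf,
    }
    return series, truth


@dataclass
class CohortData:
    series: dict[str, RRSeries]
    metadata: pd.DataFrame
    truth: dict


def gen_cohort(config: GeneratorConfig | None = None,
               out_dir: str | Path | None = None) -> CohortData:
    """Generate a full cohort: RR series, metadata table, ground truth.

    Deterministic given ``config.seed``.  With ``out_dir`` set, writes one
    plain-ms RR file per subject, ``metadata.csv`` and ``truth.json``.
    """
    config = config or GeneratorConfig()
    config.validate()
    n_total = sum(p.n_subjects for p in config.groups.values())
    child_seeds = np.random.SeedSequence(config.seed).generate_state(2 * n_total)

    series: dict[str, RRSeries] = {}
    meta_rows = []
    truths = []
    idx = 0
    for group, profile in config.groups.items():
        for k in range(profile.n_subjects):
            sid = f"{group[:1].upper()}{k + 1:03d}"
            if sid in series:
                raise ValueError(f"duplicate subject id {sid}")
            sub_seed = int(child_seeds[idx] % (2 ** 31))
            meta_rng = np.random.default_rng(int(child_seeds[n_total + idx] % (2 ** 31)))
            idx += 1
            age = float(meta_rng.uniform(*config.age_range))
            s, truth = gen_subject_rr(config, group, sub_seed, subject_id=sid,
                                      age=age, return_truth=True)
            series[sid] = s
            truths.append(truth)
            height = float(meta_rng.normal(160.0, 9.0))
            bmi = float(np.clip(meta_rng.normal(profile.bmi_mean, profile.bmi_sd),
                                14.0, 45.0))
            meta_rows.append({
                "subject_id": sid, "group_label": group,
                "age": round(age, 1),
                "sex": "F" if meta_rng.random() < 0.55 else "M",
                "height_cm": round(height, 1),
                "weight_kg": round(bmi * (height / 100.0) ** 2, 1),
                "bmi": round(bmi, 2),
                "sbp": round(float(meta_rng.normal(profile.sbp_mean, profile.sbp_sd)), 1),
                "dbp": round(float(meta_rng.normal(profile.dbp_mean, profile.dbp_sd)), 1),
            })

    metadata = pd.DataFrame(meta_rows)
    truth = {
        "seed": config.seed,
        "programmed": {
            g: {"n": p.n_subjects,
                "hr_supine_bpm": p.hr_supine_bpm,
                "delta1_hr_pct": p.delta1_hr_pct,
                "hf_tilt_factor": p.hf_tilt_factor,
                "delta1_hf_power_pct": 100.0 * (p.hf_tilt_factor ** 2 - 1.0)}
            for g, p in config.groups.items()
        },
        "subjects": truths,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sid, s in series.items():
            write_rr(s, out_dir / f"{sid}.txt", dialect="plain_ms")
        metadata.to_csv(out_dir / "metadata.csv", index=False)
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))

    return CohortData(series=series, metadata=metadata, truth=truth)
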