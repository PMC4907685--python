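"""Ground-truth synthetic cohorts for end-to-end validation.

The generator emulates the study design: eleven subjects, each providing
per-condition (rest / grip / post-grip) spectra from a known laminar
circuit.  Two modes are available:

``spectral``
    The linearised prediction at the subject's true parameters, corrupted
    by i.i.d. Gaussian noise on log-power (SD 0.1 by default) — fast, and
    exactly matched to the forward model the inversion uses.
``time``
    Trials of the task are simulated with the stochastic neural-mass
    model (600 Hz virtual electrode, 60 handgrip trials with condition
    modulators switching at cue onset and grip release), then passed
    through the empirical feature pipeline.

Default condition effects follow the group result directions: during grip
the deep-to-superficial, superficial/middle reciprocal and middle
self-connections strengthen (+0.3 log units); post-grip the superficial
and deep exogenous inputs increase (+0.3 log units).  Between-subject
variability is modelled as N(0, 0.1^2) jitter on the intrinsic gammas.
Everything is reproducible bit-for-bit from (seed, config).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import load_default_config
from .dynamics import generate_endogenous_noise, simulate_schedule
from .errors import InstabilityError, M1DCMError, ParameterError
from .features import epoch_and_concatenate, estimate_psd, VirtualElectrodeRecording
from .forward import SpectralForwardOperator
from .model_space import CONDITIONS, ModelSpec
from .params import NoiseSpec

__all__ = ["GroundTruth", "SubjectData", "default_ground_truth",
           "subject_theta", "synth_subject", "synth_cohort", "Cohort"]


@dataclass
class GroundTruth:
    """Population-level truth of a synthetic cohort."""

    model_name: str = "winning_m1"
    theta_mean: list[float] = field(default_factory=list)
    n_subjects: int = 11
    jitter_sd: float = 0.1
    spectral_noise_sd: float = 0.1
    mode: str = "spectral"  # or "time"
    seed: int = 0
    n_trials: int = 60
    fs: float = 600.0

    def __post_init__(self):
        if self.mode not in ("spectral", "time"):
            raise ParameterError("mode must be 'spectral' or 'time'")


@dataclass
class SubjectData:
    subject_id: str
    freqs: np.ndarray
    spectra: dict[str, np.ndarray]
    theta: np.ndarray
    recording: VirtualElectrodeRecording | None = None


def _operator(truth: GroundTruth) -> SpectralForwardOperator:
    from .estimator import resolve_model

    return SpectralForwardOperator(resolve_model(truth.model_name))


def default_ground_truth(
    model: "ModelSpec | str" = "winning_m1",
    config: dict | None = None,
    mode: str = "spectral",
    seed: int = 0,
    n_subjects: int | None = None,
    effect: float | None = None,
) -> GroundTruth:
    """Truth at the prior means plus the configured condition effects."""
    from .estimator import resolve_model

    config = config or load_default_config()
    synth = config["synthetic"]
    model = resolve_model(model)
    fwd = SpectralForwardOperator(model, config=config)
    lay = fwd.layout
    effect = float(synth["effect_log_units"]) if effect is None else effect

    theta = np.zeros(lay.size)
    beta = theta[lay.slice_of("beta_grip")]
    mod_conn = list(fwd.design.modulated_connections)
    for edge in synth["grip_increase"]:
        src, tgt = edge.split("->")
        if model.has_connection(src, tgt):
            beta[mod_conn.index(model.connection_index(src, tgt))] += effect
    ib = theta[lay.slice_of("input_beta_post_grip")]
    for label in synth["post_grip_input_increase"]:
        if label in fwd.design.modulated_inputs:
            ib[fwd.design.modulated_inputs.index(label)] += effect

    return GroundTruth(
        model_name=model.name if model.name != "m1_core+dp_sp" else "winning_m1",
        theta_mean=theta.tolist(),
        n_subjects=int(synth["n_subjects"]) if n_subjects is None else n_subjects,
        jitter_sd=float(synth["jitter_sd_log"]),
        spectral_noise_sd=float(synth["spectral_noise_sd_log"]),
        mode=mode,
        seed=seed,
        n_trials=int(synth["n_trials"]),
        fs=float(synth["fs_hz"]),
    )


def _subject_rng(truth: GroundTruth, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=truth.seed, spawn_key=(index,))
    )


def subject_theta(truth: GroundTruth, index: int,
                  fwd: SpectralForwardOperator | None = None) -> np.ndarray:
    """True packed parameters of subject ``index``: the population mean
    plus seeded between-subject jitter on the intrinsic gammas."""
    fwd = _operator(truth) if fwd is None else fwd
    rng = _subject_rng(truth, index)
    theta = np.asarray(truth.theta_mean, dtype=float).copy()
    g = fwd.layout.slice_of("gamma")
    theta[g] = theta[g] + rng.normal(0.0, truth.jitter_sd, g.stop - g.start)
    return theta


def synth_subject(truth: GroundTruth, index: int,
                  fwd: SpectralForwardOperator | None = None) -> SubjectData:
    """Generate one subject: spectra (and, in time mode, the recording)
    plus the exact true parameters used."""
    fwd = _operator(truth) if fwd is None else fwd
    rng = _subject_rng(truth, index)
    theta = np.asarray(truth.theta_mean, dtype=float).copy()
    g = fwd.layout.slice_of("gamma")
    theta[g] = theta[g] + rng.normal(0.0, truth.jitter_sd, g.stop - g.start)
    subject_id = f"sub-{index + 1:02d}"

    if truth.mode == "spectral":
        psd = fwd.psd(theta)
        if not np.isfinite(psd).all():
            raise InstabilityError(
                f"true parameters of {subject_id} yield an unstable circuit "
                f"(gamma jitter too large?)"
            )
        noisy = psd * np.exp(
            rng.normal(0.0, truth.spectral_noise_sd, psd.shape)
        )
        spectra = {c: noisy[i] for i, c in enumerate(fwd.design.conditions)}
        return SubjectData(subject_id, fwd.freqs.copy(), spectra, theta)

    return _synth_subject_time(truth, theta, rng, fwd, subject_id)


def _synth_subject_time(truth, theta, rng, fwd, subject_id) -> SubjectData:
    model = fwd.model
    params_full = fwd.full_params(theta)
    synaptic = params_full.synaptic
    # trial: 1 s pre-cue rest, 4 s grip, 2 s post-grip (cue at 1 s)
    grip = params_full.beta_for(model, "grip")
    post = params_full.beta_for(model, "post_grip")
    segments = []
    for _ in range(truth.n_trials):
        segments += [
            (1.0, None, None),
            (4.0, grip.connections, grip.inputs),
            (2.0, post.connections, post.inputs),
        ]
    dt = 1000.0 / truth.fs
    noise = NoiseSpec(
        white_amplitude=params_full.noise.white_amplitude,
        pink_amplitude=params_full.noise.pink_amplitude,
        pink_exponent=params_full.noise.pink_exponent,
        input_gains=params_full.noise.input_gains,
        seed=0,  # rng below supersedes the seed
    )
    try:
        sim = simulate_schedule(model, synaptic, noise, segments, dt=dt, rng=rng)
    except InstabilityError as err:
        raise InstabilityError(f"{subject_id}: {err}") from err
    obs = params_full.observation
    signal = (obs.gain * obs.contributions) @ sim.voltages
    # additive white channel noise at the configured density
    if obs.channel_noise_white > 0:
        signal = signal + rng.normal(
            0.0, np.sqrt(obs.channel_noise_white * truth.fs / 2.0), signal.size
        )
    events = 1.0 + 7.0 * np.arange(truth.n_trials)
    rec = VirtualElectrodeRecording(
        samples=signal[:-1], fs=truth.fs, events=events, subject_id=subject_id
    )
    epochs = epoch_and_concatenate(rec)
    spectra = {
        cond: estimate_psd(epochs.segments[cond], rec.fs, condition=cond).psd
        for cond in CONDITIONS
    }
    return SubjectData(subject_id, fwd.freqs.copy(), spectra, theta, recording=rec)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    truth: GroundTruth
    subjects: list[SubjectData]
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def synth_cohort(
    truth: GroundTruth | None = None,
    out_dir: "str | Path | None" = None,
    overwrite: bool = False,
) -> Cohort:
    """Generate a cohort (optionally writing it to ``out_dir``).

    Writes one spectra CSV per subject (plus the recording CSV in time
    mode) and a ``manifest.json`` carrying the truth, per-subject true
    parameters and file digests.  Refuses to overwrite an existing
    manifest unless ``overwrite`` is set.  Deterministic given the truth.
    """
    truth = default_ground_truth() if truth is None else truth
    fwd = _operator(truth)
    subjects = [
        synth_subject(truth, i, fwd=fwd) for i in range(truth.n_subjects)
    ]

    manifest = {
        "schema_version": 1,
        "truth": asdict(truth),
        "conditions": list(CONDITIONS),
        "subjects": [
            {"id": s.subject_id, "theta": s.theta.tolist()} for s in subjects
        ],
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        manifest_path = out_dir / "manifest.json"
        if manifest_path.exists() and not overwrite:
            raise M1DCMError(
                f"{manifest_path} exists; pass overwrite=True to replace it"
            )
        out_dir.mkdir(parents=True, exist_ok=True)
        for entry, s in zip(manifest["subjects"], subjects):
            spectra_path = out_dir / f"{s.subject_id}_spectra.csv"
            df = pd.DataFrame({"freq_hz": s.freqs})
            for cond in CONDITIONS:
                df[f"psd_{cond}"] = s.spectra[cond]
            df.to_csv(spectra_path, index=False, float_format="%.17g")
            entry["spectra_file"] = spectra_path.name
            entry["spectra_sha256"] = _sha256(spectra_path)
            if s.recording is not None:
                rec_path = out_dir / f"{s.subject_id}_recording.csv"
                s.recording.to_csv(rec_path)
                entry["recording_file"] = rec_path.name
                entry["recording_sha256"] = _sha256(rec_path)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return Cohort(truth=truth, subjects=subjects, manifest=manifest)


def load_cohort_spectra(cohort_dir) -> tuple[dict, list[dict]]:
    """Read a written cohort back: (manifest, list of per-subject dicts
    with 'id', 'freqs', 'spectra', 'theta')."""
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    out = []
    for entry in manifest["subjects"]:
        df = pd.read_csv(cohort_dir / entry["spectra_file"], float_precision="round_trip")
        spectra = {
            c: df[f"psd_{c}"].to_numpy() for c in manifest["conditions"]
        }
        out.append(
            {
                "id": entry["id"],
                "freqs": df["freq_hz"].to_numpy(),
                "spectra": spectra,
                "theta": np.array(entry["theta"]),
            }
        )
    return manifest, out
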