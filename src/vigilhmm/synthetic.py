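"""Synthetic operator datasets with the structure the detector assumes.

Each simulated operator owns a pair of generating Gaussian HMMs -- one for
normal vigilance ("+"), one for hypovigilance ("-") -- whose emission-mean
centroids are separated by a requested amount (in pooled-standard-deviation
units, the covariances being identity by construction). Operator-to-operator
variation comes from the seed: base state means, transition stickiness and
the direction of the class shift all differ across operators, emulating the
individual-specific character of scalp EEG. Slow nonstationarity can be
added as a sinusoidal drift of the emission means.

The generator also renders feature sequences back into raw multichannel
signals (sums of band-limited sinusoids whose per-frame power follows a
per-state band profile, plus broadband noise) so the preprocessing chain
can be exercised against known band structure. The default experiment shape
mirrors a five-operator simulated-cockpit study: 10 repetitions of 3
difficult + 3 easy tasks per operator, one observation vector per second.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import cycle
from pathlib import Path

import numpy as np

from vigilhmm import hmm_core
from vigilhmm.detector import (
    DIFFICULT_TASKS,
    EASY_TASKS,
    EEGSequence,
    HYPO,
    NORMAL,
)
from vigilhmm.hmm_core import GaussianHMM, InputError
from vigilhmm.preprocess import BAND_EDGES, BAND_NAMES, RawRecording

#: nominal carrier frequency (Hz) used when rendering each band
BAND_CENTERS = {name: (lo + hi) / 2.0 for name, (lo, hi) in BAND_EDGES.items()}

#: default experiment shape: repetitions of 3 difficult + 3 easy tasks
DEFAULT_N_OPERATORS = 5
DEFAULT_N_REPETITIONS = 10
DEFAULT_SEQ_LEN = 360  # frames at 1 frame/s; one task lasts about six minutes


@dataclass
class OperatorProfile:
    """Ground truth for one simulated operator."""

    operator_id: str
    gen_plus: GaussianHMM
    gen_minus: GaussianHMM
    separation: float
    drift: float = 0.0
    band_profile: np.ndarray | None = None  # (G, 4) band powers per state

    def __post_init__(self) -> None:
        if self.gen_plus.obs_dim != self.gen_minus.obs_dim:
            raise InputError("generators must share obs_dim")
        if self.band_profile is not None:
            self.band_profile = np.atleast_2d(np.asarray(self.band_profile, dtype=float))

    def achieved_separation(self) -> float:
        """Distance between the class emission-mean centroids."""
        return float(
            np.linalg.norm(self.gen_plus.means.mean(axis=0) - self.gen_minus.means.mean(axis=0))
        )


@dataclass
class SyntheticDataset:
    profiles: list[OperatorProfile]
    sequences: list[EEGSequence]
    manifest: dict = field(default_factory=dict)


def _sticky_transition(rng: np.random.Generator, G: int) -> np.ndarray:
    """Ergodic transition matrix with dominant self-transitions."""
    A = np.empty((G, G))
    for i in range(G):
        stay = rng.uniform(0.80, 0.95)
        off = rng.dirichlet(np.ones(G - 1)) * (1 - stay) if G > 1 else np.array([])
        row = np.insert(off, i, stay)
        A[i] = row
    return A


def make_profile(
    operator_id: str,
    seed: int,
    separation: float = 3.0,
    G: int = 2,
    obs_dim: int = 4,
    drift: float = 0.0,
    state_spread: float = 2.0,
    direction: np.ndarray | None = None,
) -> OperatorProfile:
    """Build one operator's generating HMM pair, deterministic per seed.

    The operator has a seed-specific baseline (state means drawn with scale
    ``state_spread``, a sticky transition matrix, an initial vector) shared
    by both vigilance classes; the classes differ *only* in their emission
    means, displaced symmetrically by +/- separation/2 along a random
    operator-specific unit direction. The distance between class mean
    centroids therefore equals ``separation`` exactly (covariances are
    identity, making the pooled within-class sd 1), at separation 0 the two
    generators are identical, and -- because the displacement direction is
    operator-specific -- data pooled across operators mixes the classes,
    which is what makes per-operator modelling necessary.

    ``direction`` overrides the drawn displacement direction (it is
    normalised internally); ``make_dataset`` uses this to impose a
    zero-mean response-direction structure across a panel of operators.
    """
    if separation < 0:
        raise InputError("separation must be non-negative")
    if G < 1 or obs_dim < 1:
        raise InputError("G and obs_dim must be positive")
    rng = np.random.default_rng(seed)
    base_means = rng.normal(0.0, state_spread, size=(G, obs_dim))
    if direction is None:
        direction = rng.standard_normal(obs_dim)
    else:
        direction = np.asarray(direction, dtype=float)
        if direction.shape != (obs_dim,) or not np.linalg.norm(direction) > 0:
            raise InputError("direction must be a nonzero vector of length obs_dim")
    direction = direction / np.linalg.norm(direction)
    covs = np.tile(np.eye(obs_dim), (G, 1, 1))
    A = _sticky_transition(rng, G)
    pi = rng.dirichlet(np.ones(G) * 5.0)
    shift = 0.5 * separation * direction
    gen_minus = GaussianHMM(
        transition=A.copy(), means=base_means - shift,
        covariances=covs.copy(), initial=pi.copy(),
    )
    gen_plus = GaussianHMM(
        transition=A.copy(), means=base_means + shift,
        covariances=covs.copy(), initial=pi.copy(),
    )
    band_profile = rng.uniform(0.5, 2.0, size=(G, len(BAND_NAMES)))
    return OperatorProfile(
        operator_id=operator_id,
        gen_plus=gen_plus,
        gen_minus=gen_minus,
        separation=separation,
        drift=drift,
        band_profile=band_profile,
    )


def generate_sequences(
    profile: OperatorProfile,
    n_per_class: int,
    L: int,
    seed: int,
    task_names: tuple[tuple[str, ...], tuple[str, ...]] = (DIFFICULT_TASKS, EASY_TASKS),
) -> list[EEGSequence]:
    """Sample labelled sequences from both of an operator's generators.

    ``n_per_class`` sequences per vigilance label, each of ``L`` frames,
    tagged with task names cycled from the difficult/easy groups. The
    generating state path is retained on each sequence for diagnostics.
    A nonzero profile drift adds ``drift * sin(2*pi*l/L)`` to every feature
    dimension, emulating slow nonstationarity.
    """
    if n_per_class < 1 or L < 1:
        raise InputError("n_per_class and L must be >= 1")
    difficult_names, easy_names = task_names
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) % (2**31) for s in ss.generate_state(2 * n_per_class)]
    out: list[EEGSequence] = []
    specs = [
        (NORMAL, "difficult", profile.gen_plus, cycle(difficult_names)),
        (HYPO, "easy", profile.gen_minus, cycle(easy_names)),
    ]
    idx = 0
    for label, difficulty, gen, names in specs:
        for i in range(n_per_class):
            path, seq = hmm_core.sample(gen, L, seeds[idx])
            idx += 1
            if profile.drift > 0:
                l = np.arange(L)
                seq = seq + profile.drift * np.sin(2 * np.pi * l / L)[:, None]
            out.append(
                EEGSequence(
                    features=seq,
                    operator_id=profile.operator_id,
                    task_id=f"{next(names)}#{i + 1}",
                    difficulty=difficulty,
                    vigilance=label,
                    state_path=path.states,
                )
            )
    return out


def render_raw(
    seq: EEGSequence,
    profile: OperatorProfile,
    sampling_rate: float = 128.0,
    n_channels: int = 4,
    seed: int = 0,
    noise_sd: float = 0.1,
    pad_seconds: float = 5.0,
) -> RawRecording:
    """Render a feature sequence into a raw multichannel signal.

    Each one-second frame is a sum over the four bands of sinusoids at the
    band-centre frequencies, with amplitude sqrt(power) taken from the
    profile's band profile for the frame's generating state, plus white
    noise. ``pad_seconds`` of noise-only signal are prepended and appended
    so that edge truncation recovers exactly the L frames.
    """
    if sampling_rate <= 60:
        raise InputError("sampling_rate must exceed 60 Hz to carry the beta band")
    if seq.state_path is None:
        raise InputError("sequence lacks a generating state path")
    if profile.band_profile is None:
        raise InputError("profile lacks a band profile")
    rng = np.random.default_rng(seed)
    L = seq.length
    fs = sampling_rate
    n_pad = int(round(pad_seconds * fs))
    frame_len = int(round(fs))
    total = 2 * n_pad + L * frame_len
    t = np.arange(total) / fs
    samples = rng.normal(0.0, noise_sd, size=(n_channels, total))
    phases = rng.uniform(0, 2 * np.pi, size=(n_channels, len(BAND_NAMES)))
    for l in range(L):
        state = int(seq.state_path[l])
        powers = profile.band_profile[state]
        sl = slice(n_pad + l * frame_len, n_pad + (l + 1) * frame_len)
        tt = t[sl]
        for b, name in enumerate(BAND_NAMES):
            f = BAND_CENTERS[name]
            amp = np.sqrt(max(powers[b], 0.0))
            samples[:, sl] += amp * np.sin(2 * np.pi * f * tt[None, :] + phases[:, [b]])
    return RawRecording(
        samples=samples,
        sampling_rate=fs,
        operator_id=seq.operator_id,
        task_id=seq.task_id,
    )


def make_dataset(
    n_operators: int = DEFAULT_N_OPERATORS,
    n_repetitions: int = DEFAULT_N_REPETITIONS,
    L: int = DEFAULT_SEQ_LEN,
    separation: float = 3.0,
    G: int = 2,
    obs_dim: int = 4,
    drift: float = 0.0,
    seed: int = 0,
    heterogeneous: bool = True,
) -> SyntheticDataset:
    """Full multi-operator dataset in the default experiment shape.

    Each repetition contributes one sequence per task (3 difficult + 3
    easy), so an operator has ``3 * n_repetitions`` sequences per class.
    ``heterogeneous=True`` gives every operator its own seed-derived
    generators (the realistic case); ``False`` reuses operator 1's profile
    for everyone (useful as an exchangeability control).

    The heterogeneous panel emulates the feature space the detector
    actually sees: per-sequence normalisation removes baseline differences
    between people, so operators share the baseline state constellation,
    and what is individual is *which way* the band features move under
    load -- the class-displacement direction. Directions are assigned in
    antipodal pairs (u, -u, v, -v, ...), the structural statement that
    across the panel there is no universal vigilance signature: a response
    axis that rises under load for one operator falls for another. A model
    pooled across such a panel has (near) identical class marginals and is
    genuinely handicapped, while each per-operator model sees a clean
    within-operator contrast. ``heterogeneous=False`` reuses one profile,
    direction included, for every operator (an exchangeability control
    under which pooling costs nothing).
    """
    ss = np.random.SeedSequence(seed)
    prof_seeds = [int(s) % (2**31) for s in ss.generate_state(n_operators)]
    seq_seeds = [int(s) % (2**31) for s in ss.spawn(1)[0].generate_state(n_operators)]
    n_per_class = len(DIFFICULT_TASKS) * n_repetitions

    directions: list[np.ndarray | None] = [None] * n_operators
    if heterogeneous and n_operators > 1 and separation > 0:
        rng_dir = np.random.default_rng(prof_seeds)
        for i in range(n_operators):
            if i % 2 == 0:
                u = rng_dir.standard_normal(obs_dim)
                directions[i] = u / np.linalg.norm(u)
            else:
                directions[i] = -directions[i - 1]

    profiles = []
    sequences = []
    for i in range(n_operators):
        prof = make_profile(
            f"op{i + 1}", prof_seeds[0], separation=separation, G=G, obs_dim=obs_dim,
            drift=drift, direction=directions[i],
        )
        profiles.append(prof)
        sequences.extend(generate_sequences(prof, n_per_class, L, seq_seeds[i]))
    manifest = {
        "seed": seed,
        "n_operators": n_operators,
        "n_repetitions": n_repetitions,
        "L": L,
        "separation": separation,
        "G": G,
        "obs_dim": obs_dim,
        "drift": drift,
        "heterogeneous": heterogeneous,
    }
    return SyntheticDataset(profiles=profiles, sequences=sequences, manifest=manifest)


# ---------------------------------------------------------------------------
# on-disk layout (CSV features + JSON manifests + ground-truth JSON)


def write_dataset(ds: SyntheticDataset, directory: Path) -> None:
    """Write features as CSV+manifest pairs plus a separate ground truth file."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth = {"manifest": ds.manifest, "sequences": [], "profiles": {}}
    for prof in ds.profiles:
        truth["profiles"][prof.operator_id] = {
            "gen_plus": prof.gen_plus.to_dict(),
            "gen_minus": prof.gen_minus.to_dict(),
            "separation": prof.separation,
            "drift": prof.drift,
            "band_profile": prof.band_profile.tolist()
            if prof.band_profile is not None
            else None,
        }
    for i, s in enumerate(ds.sequences):
        stem = f"seq{i:04d}"
        np.savetxt(
            directory / f"{stem}.csv",
            s.features,
            delimiter=",",
            header=",".join(f"f{j}" for j in range(s.obs_dim)),
            comments="",
            fmt="%.10g",
        )
        (directory / f"{stem}.json").write_text(
            json.dumps(
                {
                    "operator_id": s.operator_id,
                    "task_id": s.task_id,
                    "difficulty": s.difficulty,
                    "frame_rate": 1.0,
                }
            )
        )
        truth["sequences"].append(
            {
                "file": f"{stem}.csv",
                "vigilance": s.vigilance,
                "state_path": s.state_path.tolist() if s.state_path is not None else None,
            }
        )
    (directory / "ground_truth.json").write_text(json.dumps(truth))


def load_dataset(directory: Path, with_labels: bool = True) -> list[EEGSequence]:
    """Load a written dataset back into labelled sequences."""
    directory = Path(directory)
    truth_path = directory / "ground_truth.json"
    labels = {}
    if with_labels and truth_path.exists():
        truth = json.loads(truth_path.read_text())
        labels = {rec["file"]: rec["vigilance"] for rec in truth["sequences"]}
    out = []
    for csv_path in sorted(directory.glob("seq*.csv")):
        manifest = json.loads(csv_path.with_suffix(".json").read_text())
        features = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
        out.append(
            EEGSequence(
                features=features,
                operator_id=manifest["operator_id"],
                task_id=manifest["task_id"],
                difficulty=manifest["difficulty"],
                vigilance=labels.get(csv_path.name, "unknown"),
            )
        )
    return out
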